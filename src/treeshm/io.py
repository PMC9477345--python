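"""Readers, writers and run manifests.

Tabular data travels as CSV (header row required), structures and trained
models as JSON.  All writes go through a write-temp-then-rename helper so an
interrupted run never leaves a truncated file behind.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from . import __version__
from .clinical import N_DAYS, PatientSeries
from .core import LabelTable, LabeledDataset, TreeStructure
from .trainer import ConflictSystem, Deduction, TrainResult, Witness

MODEL_FORMAT_VERSION = 1


def atomic_write_text(path: Path | str, text: str) -> None:
    """Write via a temp file in the target directory, then rename."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as handle:
            handle.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def sha256_of(path: Path | str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


# -- structures ------------------------------------------------------------


def read_structure(path: Path | str) -> TreeStructure:
    with open(path) as handle:
        obj = json.load(handle)
    structure = TreeStructure.from_json(obj)
    if "column_order" in obj:
        order = obj["column_order"]
        if sorted(order) != list(range(1, structure.d + 1)):
            raise ValueError("column_order must permute positions 1..d")
    return structure


def write_structure(path: Path | str, structure: TreeStructure) -> None:
    atomic_write_text(path, json.dumps(structure.to_json(), indent=2) + "\n")


def column_order(path: Path | str) -> list[int] | None:
    """Optional 1-based input-column permutation recorded in a structure file."""
    with open(path) as handle:
        obj = json.load(handle)
    return obj.get("column_order")


# -- datasets --------------------------------------------------------------


def read_dataset(
    path: Path | str,
    structure: TreeStructure,
    order: list[int] | None = None,
) -> LabeledDataset:
    """Read a labeled CSV: d binary feature columns then one label column.

    Rows with non-binary cells are rejected with their location; duplicate
    feature vectors are deduplicated when their labels agree and rejected
    (with row numbers) when they conflict.  ``order`` optionally maps file
    columns onto structure positions (1-based) for non-contiguous data.
    """
    frame = pd.read_csv(path)
    if frame.shape[1] != structure.d + 1:
        raise ValueError(
            f"{path}: expected {structure.d} feature columns plus a label "
            f"column, found {frame.shape[1]} columns"
        )
    values = frame.to_numpy()
    bad = ~np.isin(values, (0, 1))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: non-binary value {values[r, c]!r} at data row {r + 1}, "
            f"column {frame.columns[c]!r}"
        )
    X = values[:, :-1].astype(np.uint8)
    if order is not None:
        if sorted(order) != list(range(1, structure.d + 1)):
            raise ValueError("column order must permute positions 1..d")
        remapped = np.empty_like(X)
        for file_col, position in enumerate(order):
            remapped[:, position - 1] = X[:, file_col]
        X = remapped
    y = values[:, -1].astype(np.uint8)
    weights = 1 << np.arange(structure.d - 1, -1, -1, dtype=np.int64)
    codes = X.astype(np.int64) @ weights
    keep: dict[int, int] = {}
    for row, (code, label) in enumerate(zip(codes, y)):
        code = int(code)
        if code in keep:
            if y[keep[code]] != label:
                raise ValueError(
                    f"{path}: rows {keep[code] + 1} and {row + 1} repeat the "
                    "same feature vector with conflicting labels"
                )
        else:
            keep[code] = row
    rows = sorted(keep.values())
    return LabeledDataset(structure, X[rows], y[rows])


def write_dataset(path: Path | str, dataset: LabeledDataset) -> None:
    cols = [f"x{j}" for j in range(1, dataset.structure.d + 1)] + ["label"]
    frame = pd.DataFrame(
        np.column_stack([dataset.X, dataset.y]), columns=cols
    )
    atomic_write_text(path, frame.to_csv(index=False))


def read_features(path: Path | str, structure: TreeStructure) -> np.ndarray:
    """Unlabeled feature CSV (d binary columns)."""
    frame = pd.read_csv(path)
    if frame.shape[1] == structure.d + 1 and frame.columns[-1] == "label":
        frame = frame.iloc[:, :-1]
    if frame.shape[1] != structure.d:
        raise ValueError(f"{path}: expected {structure.d} feature columns")
    values = frame.to_numpy()
    if not np.isin(values, (0, 1)).all():
        raise ValueError(f"{path}: features must be binary")
    return values.astype(np.uint8)


# -- trained models --------------------------------------------------------


def write_model(path: Path | str, result: TrainResult) -> None:
    """Serialise a trained model: cells with provenance, deduction order,
    per-module colour classes and the conflict count."""
    from .trainer import extract_module_functions

    funcs = extract_module_functions(result)
    cells = {
        str(int(code)): {
            "label": int(result.table.values()[code]),
            "provenance": result.provenance(int(code)),
        }
        for code in result.table.defined_codes()
    }
    obj = {
        "format": MODEL_FORMAT_VERSION,
        "software": f"treeshm {__version__}",
        "block_sizes": list(result.structure.block_sizes),
        "cells": cells,
        "deductions": [
            {
                "code": ded.code,
                "label": ded.label,
                "module": ded.witness.module_index,
                "pair": list(ded.witness.pair),
                "context_code": ded.witness.context_code,
            }
            for ded in result.deductions
        ],
        "color_classes": [c.tolist() for c in funcs.colorings],
        "unique_coloring": funcs.unique,
        "conflicts": result.conflicts,
        "sweeps": result.sweeps,
        "majority_label": result.majority_label,
    }
    atomic_write_text(path, json.dumps(obj, indent=2) + "\n")


def read_model(path: Path | str) -> TrainResult:
    """Rebuild a TrainResult from its JSON export.

    Training cells are re-indexed in code order and deductions replayed in
    their recorded order, reproducing the end-of-training graph state.
    """
    with open(path) as handle:
        obj = json.load(handle)
    if obj.get("format") != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"{path}: unsupported model format {obj.get('format')!r} "
            f"(expected {MODEL_FORMAT_VERSION})"
        )
    structure = TreeStructure(tuple(obj["block_sizes"]))
    table = LabelTable(structure)
    training_codes = []
    for code_str, cell in obj["cells"].items():
        if cell["provenance"] == "training":
            training_codes.append(int(code_str))
    for code in sorted(training_codes):
        table.define(code, obj["cells"][str(code)]["label"])
    system = ConflictSystem(structure, table)
    deductions = []
    for ded in obj["deductions"]:
        system.define(ded["code"], ded["label"])
        deductions.append(
            Deduction(
                ded["code"],
                ded["label"],
                Witness(ded["module"], tuple(ded["pair"]), ded["context_code"]),
            )
        )
    return TrainResult(
        structure=structure,
        table=table,
        graphs=system.graphs,
        deductions=deductions,
        conflicts=obj["conflicts"],
        sweeps=obj["sweeps"],
        training_codes=frozenset(training_codes),
        majority_label=obj["majority_label"],
    )


# -- patients --------------------------------------------------------------


def read_patients(
    static_path: Path | str, series_path: Path | str
) -> list[PatientSeries]:
    """Load patients from a static CSV (patient_id, age, bmi, outcome) and a
    long-format series CSV (patient_id, day, parameter, value)."""
    static = pd.read_csv(static_path, dtype={"patient_id": str})
    series = pd.read_csv(series_path, dtype={"patient_id": str})
    for col in ("patient_id", "age", "bmi", "outcome"):
        if col not in static.columns:
            raise ValueError(f"{static_path}: missing column {col!r}")
    for col in ("patient_id", "day", "parameter", "value"):
        if col not in series.columns:
            raise ValueError(f"{series_path}: missing column {col!r}")
    grouped = series.groupby(["patient_id", "parameter", "day"])["value"].apply(list)
    patients = []
    for row in static.itertuples():
        daily: dict[str, list[list[float]]] = {}
        for param in series.loc[
            series["patient_id"] == row.patient_id, "parameter"
        ].unique():
            daily[param] = [
                list(grouped.get((row.patient_id, param, day), []))
                for day in range(1, N_DAYS + 1)
            ]
        patients.append(
            PatientSeries(
                patient_id=row.patient_id,
                age=float(row.age),
                bmi=float(row.bmi),
                daily_values=daily,
                outcome=str(row.outcome),
            )
        )
    return patients


def write_patients(
    static_path: Path | str,
    series_path: Path | str,
    patients: Iterable[PatientSeries],
) -> None:
    static_rows, series_rows = [], []
    for p in patients:
        static_rows.append(
            {"patient_id": p.patient_id, "age": p.age, "bmi": p.bmi,
             "outcome": p.outcome}
        )
        for param, days in p.daily_values.items():
            for day, values in enumerate(days, start=1):
                for value in values:
                    series_rows.append(
                        {"patient_id": p.patient_id, "day": day,
                         "parameter": param, "value": value}
                    )
    atomic_write_text(static_path, pd.DataFrame(static_rows).to_csv(index=False))
    atomic_write_text(series_path, pd.DataFrame(series_rows).to_csv(index=False))


# -- run manifests ---------------------------------------------------------


@dataclass
class RunManifest:
    """Provenance record written beside every CLI output."""

    command: str
    config: dict
    seed: int | None
    software_version: str = __version__
    started: str = ""
    finished: str = ""
    inputs: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)

    @classmethod
    def start(cls, command: str, config: dict, seed: int | None) -> "RunManifest":
        return cls(
            command=command,
            config=config,
            seed=seed,
            started=_dt.datetime.now(_dt.timezone.utc).isoformat(),
        )

    def record_input(self, path: Path | str) -> None:
        self.inputs[str(path)] = sha256_of(path)

    def record_output(self, path: Path | str) -> None:
        self.outputs[str(path)] = sha256_of(path)

    def finish(self, path: Path | str) -> None:
        self.finished = _dt.datetime.now(_dt.timezone.utc).isoformat()
        atomic_write_text(path, json.dumps(self.__dict__, indent=2) + "\n")
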