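"""Synthetic benchmark universe: random structures, ground truths, samples.

The default configuration matches the benchmark the learner is evaluated
on throughout this package: 30 random tree structures with k = 3 first-layer
modules of 2–6 inputs each and total dimension d ∈ {8, …, 12}; a random
tree-SHM per structure (every truth-table entry an independent fair coin);
training sets drawn uniformly without replacement at fractions 20/30/40 %
of the 2**d cells, five samples per structure and fraction; optional
independent label-flip noise.

Randomness flows through named child streams spawned from one root seed, so
enabling a later stage (e.g. noise) never perturbs the draws of an earlier
one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

from .core import (
    DEFAULT_ENUMERATION_CAP,
    GroundTruthSHM,
    LabelTable,
    LabeledDataset,
    TreeStructure,
)

#: Order in which child RNG streams are spawned from the root seed.
STREAM_NAMES = ("structure", "functions", "sampling", "noise")


def child_generators(seed: int) -> dict[str, np.random.Generator]:
    """Per-purpose RNG streams derived from one root seed."""
    children = np.random.SeedSequence(seed).spawn(len(STREAM_NAMES))
    return {name: np.random.default_rng(s) for name, s in zip(STREAM_NAMES, children)}


@dataclass(frozen=True)
class GeneratorConfig:
    """Benchmark design parameters (defaults = the study conditions)."""

    d_range: tuple[int, ...] = (8, 9, 10, 11, 12)
    k: int = 3
    block_size_range: tuple[int, int] = (2, 6)
    n_structures: int = 30
    fractions: tuple[float, ...] = (0.20, 0.30, 0.40)
    samples_per_structure: int = 5
    noise_p: float = 0.0
    seed: int = 0
    reject_constant: bool = False

    def __post_init__(self) -> None:
        if not self.d_range:
            raise ValueError("d_range must be nonempty")
        lo, hi = self.block_size_range
        if not 1 <= lo <= hi:
            raise ValueError(f"invalid block_size_range {self.block_size_range}")
        if any(not 0 < f <= 1 for f in self.fractions):
            raise ValueError("training fractions must lie in (0, 1]")
        if not 0 <= self.noise_p <= 1:
            raise ValueError("noise_p must lie in [0, 1]")
        if not feasible_block_tuples(self.k, self.block_size_range, self.d_range):
            raise ValueError("no block-size tuple satisfies the constraints")


def feasible_block_tuples(
    k: int, block_size_range: tuple[int, int], d_range: Sequence[int]
) -> list[tuple[int, ...]]:
    """All ordered k-tuples with entries in the range and sum in ``d_range``."""
    lo, hi = block_size_range
    targets = set(d_range)
    out: list[tuple[int, ...]] = []

    def extend(prefix: tuple[int, ...], total: int) -> None:
        if len(prefix) == k:
            if total in targets:
                out.append(prefix)
            return
        remaining = k - len(prefix)
        for n in range(lo, hi + 1):
            if total + n + (remaining - 1) * lo <= max(targets):
                extend(prefix + (n,), total + n)

    extend((), 0)
    return out


def generate_structure(
    rng: np.random.Generator, config: GeneratorConfig
) -> TreeStructure:
    """Uniform draw from the feasible block-size tuples."""
    tuples = feasible_block_tuples(config.k, config.block_size_range, config.d_range)
    return TreeStructure(tuples[int(rng.integers(len(tuples)))])


def generate_ground_truth(
    rng: np.random.Generator,
    structure: TreeStructure,
    reject_constant: bool = False,
) -> GroundTruthSHM:
    """Random tree-SHM: every truth-table entry an independent fair coin.

    With ``reject_constant`` the (rare) constant module or output functions
    are resampled, guaranteeing every module influences some input.
    """

    def draw(size: int) -> np.ndarray:
        while True:
            t = rng.integers(0, 2, size=size, dtype=np.uint8)
            if not reject_constant or (t.min() == 0 and t.max() == 1):
                return t

    module_tables = tuple(draw(1 << n) for n in structure.block_sizes)
    output_table = draw(1 << structure.k)
    return GroundTruthSHM(structure, module_tables, output_table)


def full_label_table(
    m: GroundTruthSHM, cap: int = DEFAULT_ENUMERATION_CAP
) -> LabelTable:
    """Total label table: every cell evaluated through the SHM."""
    d = m.structure.d
    if d > cap:
        raise ValueError(f"d={d} exceeds the enumeration cap {cap}")
    labels = m.evaluate_codes(np.arange(1 << d, dtype=np.int64))
    return LabelTable.from_values(m.structure, labels.astype(np.int8))


def sample_training_set(
    rng: np.random.Generator, table: LabelTable, fraction: float
) -> LabeledDataset:
    """Uniform sample without replacement of ``round(fraction * 2**d)`` cells."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    if not table.is_total:
        raise ValueError("sampling requires a total label table")
    n_cells = table.n_cells
    size = int(np.floor(fraction * n_cells + 0.5))  # round half up
    if size == 0:
        raise ValueError(f"fraction {fraction} rounds to an empty training set")
    codes = np.sort(rng.choice(n_cells, size=size, replace=False))
    labels = table.values()[codes]
    return LabeledDataset.from_codes(codes, labels, table.structure)


def sample_training_set_n(
    rng: np.random.Generator, table: LabelTable, n: int
) -> LabeledDataset:
    """Like :func:`sample_training_set` but with an absolute count."""
    if not 0 < n <= table.n_cells:
        raise ValueError(f"n={n} must lie in 1..{table.n_cells}")
    codes = np.sort(rng.choice(table.n_cells, size=n, replace=False))
    labels = table.values()[codes]
    return LabeledDataset.from_codes(codes, labels, table.structure)


def add_label_noise(
    rng: np.random.Generator, dataset: LabeledDataset, p: float
) -> LabeledDataset:
    """Flip each record's label independently with probability ``p``."""
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    flips = rng.random(len(dataset)) < p
    y = dataset.y ^ flips.astype(np.uint8)
    return LabeledDataset(dataset.structure, dataset.X.copy(), y)


@dataclass(frozen=True)
class BenchmarkRun:
    """One generated instance: structure, ground truth, truth table, sample."""

    structure: TreeStructure
    shm: GroundTruthSHM
    truth: LabelTable
    training: LabeledDataset
    fraction: float | None = None
    n_training: int | None = None

    @property
    def test_codes(self) -> np.ndarray:
        mask = np.ones(self.truth.n_cells, dtype=bool)
        mask[self.training.codes] = False
        return np.nonzero(mask)[0]

    @property
    def empty_test_set(self) -> bool:
        return len(self.training) == self.truth.n_cells


def benchmark_runs(config: GeneratorConfig) -> Iterator[BenchmarkRun]:
    """The full fraction-based design: structures × fractions × samples."""
    rngs = child_generators(config.seed)
    for _ in range(config.n_structures):
        structure = generate_structure(rngs["structure"], config)
        shm = generate_ground_truth(
            rngs["functions"], structure, config.reject_constant
        )
        truth = full_label_table(shm)
        for fraction in config.fractions:
            for _ in range(config.samples_per_structure):
                training = sample_training_set(rngs["sampling"], truth, fraction)
                if config.noise_p > 0:
                    training = add_label_noise(
                        rngs["noise"], training, config.noise_p
                    )
                yield BenchmarkRun(structure, shm, truth, training, fraction=fraction)


def fixed_n_experiment(
    rng: np.random.Generator | None,
    config: GeneratorConfig,
    N: int,
) -> Iterator[BenchmarkRun]:
    """Design with an absolute training-set size ``N`` per run.

    Used for the dimensionality and noise sweeps, where the training budget
    (e.g. N = 200 patients) is held fixed while d or the noise level varies.
    When ``rng`` is None the config's per-purpose streams are used.
    """
    rngs = child_generators(config.seed)
    sample_rng = rng if rng is not None else rngs["sampling"]
    for _ in range(config.n_structures):
        structure = generate_structure(rngs["structure"], config)
        if N > (1 << structure.d):
            raise ValueError(
                f"N={N} exceeds the {1 << structure.d} cells of d={structure.d}"
            )
        shm = generate_ground_truth(
            rngs["functions"], structure, config.reject_constant
        )
        truth = full_label_table(shm)
        for _ in range(config.samples_per_structure):
            training = sample_training_set_n(sample_rng, truth, N)
            if config.noise_p > 0:
                training = add_label_noise(rngs["noise"], training, config.noise_p)
            yield BenchmarkRun(structure, shm, truth, training, n_training=N)
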