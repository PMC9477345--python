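"""Domain types for tree-structured hybrid models on binary inputs.

A tree-structured hybrid model (tree-SHM) wires ``d`` binary input features
into ``k`` independent first-layer black-box modules.  Module ``i`` reads a
contiguous block of ``n_i`` features and emits one intermediate bit; a single
output module maps the ``k`` intermediate bits to the overall binary label.
The full input-output relation is a ``k``-dimensional orthotope whose
``i``-th axis enumerates the ``2**n_i`` possible block inputs, so the
orthotope has ``2**d`` cells in total.

Bit conventions
---------------
A length-``d`` bit vector is written leftmost-first and its integer *code*
takes the leftmost bit as most significant.  Lexicographic order on bit
strings therefore coincides with numeric order on codes: the all-zeros
vector is smallest and ``1^d`` is largest.  Module indices and input
positions are 1-based in all public interfaces.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

#: Cells above this dimension are never enumerated in full by default.
DEFAULT_ENUMERATION_CAP = 20

#: Sentinel for an undefined orthotope cell.
UNDEFINED = -1

Bits = tuple[int, ...]


def as_bits(x: Sequence[int]) -> Bits:
    """Validate and normalise a 0/1 sequence to a tuple of ints."""
    bits = tuple(int(b) for b in x)
    if any(b not in (0, 1) for b in bits):
        raise ValueError(f"bit-vector entries must be 0 or 1, got {tuple(x)!r}")
    return bits


def bits_to_code(bits: Sequence[int]) -> int:
    """Integer code of a bit vector, leftmost bit most significant."""
    code = 0
    for b in as_bits(bits):
        code = (code << 1) | b
    return code


def code_to_bits(code: int, length: int) -> Bits:
    """Inverse of :func:`bits_to_code` for a vector of known length."""
    if not 0 <= code < (1 << length):
        raise ValueError(f"code {code} out of range for length {length}")
    return tuple((code >> (length - 1 - j)) & 1 for j in range(length))


@dataclass(frozen=True)
class TreeStructure:
    """Ordered partition of ``d`` input positions into ``k`` module blocks.

    ``block_sizes`` lists ``n_1 .. n_k``; block ``i`` owns the contiguous
    1-based positions ``sum(n_1..n_{i-1}) + 1 .. sum(n_1..n_i)``.
    """

    block_sizes: tuple[int, ...]

    def __post_init__(self) -> None:
        sizes = tuple(int(n) for n in self.block_sizes)
        if len(sizes) < 1:
            raise ValueError("a structure needs at least one module")
        if any(n < 1 for n in sizes):
            raise ValueError(f"every block size must be >= 1, got {sizes}")
        object.__setattr__(self, "block_sizes", sizes)

    @property
    def d(self) -> int:
        return sum(self.block_sizes)

    @property
    def k(self) -> int:
        return len(self.block_sizes)

    def _check_module(self, i: int) -> None:
        if not 1 <= i <= self.k:
            raise IndexError(f"module index {i} out of range 1..{self.k}")

    def block_start(self, i: int) -> int:
        """0-based offset of the first position of block ``i`` (1-based)."""
        self._check_module(i)
        return sum(self.block_sizes[: i - 1])

    def block_slice(self, i: int) -> slice:
        start = self.block_start(i)
        return slice(start, start + self.block_sizes[i - 1])

    # -- integer-code arithmetic (fast path used by the trainer) ----------

    def shift(self, i: int) -> int:
        """Right-shift that brings block ``i`` to the least-significant end."""
        self._check_module(i)
        return self.d - (self.block_start(i) + self.block_sizes[i - 1])

    def block_mask(self, i: int) -> int:
        return ((1 << self.block_sizes[i - 1]) - 1) << self.shift(i)

    def project_code(self, code: int, i: int) -> int:
        return (code >> self.shift(i)) & ((1 << self.block_sizes[i - 1]) - 1)

    def context_code(self, code: int, i: int) -> int:
        """Code with block ``i`` zeroed; equal iff the contexts are equal."""
        return code & ~self.block_mask(i)

    def compose_code(self, v: int, i: int, ctx_code: int) -> int:
        return ctx_code | (v << self.shift(i))

    # -- serialisation ----------------------------------------------------

    def to_json(self) -> dict:
        return {"block_sizes": list(self.block_sizes)}

    @classmethod
    def from_json(cls, obj: dict) -> "TreeStructure":
        return cls(tuple(obj["block_sizes"]))

    def __str__(self) -> str:
        return f"TreeStructure(blocks={'+'.join(map(str, self.block_sizes))}, d={self.d})"


def project_block(x: Sequence[int], i: int, structure: TreeStructure) -> Bits:
    """The ``n_i`` bits of ``x`` owned by module ``i``, in input order."""
    bits = as_bits(x)
    if len(bits) != structure.d:
        raise ValueError(f"expected a length-{structure.d} vector, got {len(bits)}")
    return bits[structure.block_slice(i)]


def context(x: Sequence[int], i: int, structure: TreeStructure) -> Bits:
    """All bits of ``x`` outside block ``i``, in input order.

    Two full-length vectors are *equivalent i-extensions* exactly when their
    contexts for module ``i`` are equal.
    """
    bits = as_bits(x)
    if len(bits) != structure.d:
        raise ValueError(f"expected a length-{structure.d} vector, got {len(bits)}")
    s = structure.block_slice(i)
    return bits[: s.start] + bits[s.stop :]


def compose_extension(
    v: Sequence[int], i: int, ctx: Sequence[int], structure: TreeStructure
) -> Bits:
    """Unique ``x`` with ``project_block(x, i) == v`` and ``context(x, i) == ctx``."""
    vb, cb = as_bits(v), as_bits(ctx)
    if len(vb) != structure.block_sizes[i - 1]:
        raise ValueError(
            f"block {i} expects {structure.block_sizes[i - 1]} bits, got {len(vb)}"
        )
    if len(cb) != structure.d - len(vb):
        raise ValueError(
            f"context for block {i} expects {structure.d - len(vb)} bits, got {len(cb)}"
        )
    s = structure.block_slice(i)
    return cb[: s.start] + vb + cb[s.start :]


def enumerate_inputs(
    structure: TreeStructure, cap: int = DEFAULT_ENUMERATION_CAP
) -> Iterator[Bits]:
    """All ``2**d`` input vectors in lexicographic (== numeric code) order."""
    if structure.d > cap:
        raise ValueError(
            f"d={structure.d} exceeds the enumeration cap {cap}; raise `cap` explicitly"
        )
    for code in range(1 << structure.d):
        yield code_to_bits(code, structure.d)


class LabelTable:
    """Write-once partial map from ``{0,1}^d`` to ``{0,1}``.

    Equivalently the k-dimensional orthotope of the structure: one cell per
    input vector, indexed by integer code.  Cells start undefined and, once
    defined, can never change value.
    """

    __slots__ = ("structure", "_cells")

    def __init__(self, structure: TreeStructure):
        self.structure = structure
        self._cells = np.full(1 << structure.d, UNDEFINED, dtype=np.int8)

    @classmethod
    def from_values(cls, structure: TreeStructure, values: np.ndarray) -> "LabelTable":
        values = np.asarray(values, dtype=np.int8)
        if values.shape != (1 << structure.d,):
            raise ValueError("values must have one entry per orthotope cell")
        if not np.all(np.isin(values, (UNDEFINED, 0, 1))):
            raise ValueError("cell values must be 0, 1 or undefined")
        table = cls(structure)
        table._cells[:] = values
        return table

    @property
    def n_cells(self) -> int:
        return self._cells.size

    @property
    def n_defined(self) -> int:
        return int(np.count_nonzero(self._cells != UNDEFINED))

    @property
    def is_total(self) -> bool:
        return self.n_defined == self.n_cells

    def values(self) -> np.ndarray:
        """Read-only view of the cell array (UNDEFINED where unset)."""
        view = self._cells.view()
        view.flags.writeable = False
        return view

    def label_of(self, code: int) -> int | None:
        val = int(self._cells[code])
        return None if val == UNDEFINED else val

    def define(self, code: int, label: int) -> None:
        if label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {label!r}")
        current = int(self._cells[code])
        if current == label:
            return
        if current != UNDEFINED:
            raise ValueError(
                f"cell {code} already defined as {current}; cells are write-once"
            )
        self._cells[code] = label

    def defined_codes(self) -> np.ndarray:
        return np.nonzero(self._cells != UNDEFINED)[0]

    def undefined_codes(self) -> np.ndarray:
        return np.nonzero(self._cells == UNDEFINED)[0]

    def copy(self) -> "LabelTable":
        return LabelTable.from_values(self.structure, self._cells.copy())


@dataclass
class LabeledDataset:
    """Distinct binary feature vectors with binary labels, tied to a structure."""

    structure: TreeStructure
    X: np.ndarray  # (n, d) uint8
    y: np.ndarray  # (n,) uint8

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=np.uint8)
        y = np.asarray(self.y, dtype=np.uint8)
        if X.ndim != 2 or X.shape[1] != self.structure.d:
            raise ValueError(
                f"features must be (n, {self.structure.d}), got {X.shape}"
            )
        if y.shape != (X.shape[0],):
            raise ValueError("labels must align with feature rows")
        if X.size and X.max() > 1:
            raise ValueError("features must be binary")
        if y.size and y.max() > 1:
            raise ValueError("labels must be binary")
        codes = self._codes_of(X)
        if np.unique(codes).size != codes.size:
            raise ValueError("feature vectors must be distinct")
        self.X, self.y = X, y

    def _codes_of(self, X: np.ndarray) -> np.ndarray:
        weights = 1 << np.arange(self.structure.d - 1, -1, -1, dtype=np.int64)
        return X.astype(np.int64) @ weights

    @property
    def codes(self) -> np.ndarray:
        return self._codes_of(self.X)

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[Sequence[int], int]], structure: TreeStructure
    ) -> "LabeledDataset":
        rows = [(as_bits(x), int(label)) for x, label in records]
        X = np.array([r[0] for r in rows], dtype=np.uint8).reshape(
            len(rows), structure.d
        )
        y = np.array([r[1] for r in rows], dtype=np.uint8)
        return cls(structure, X, y)

    @classmethod
    def from_codes(
        cls, codes: Sequence[int], labels: Sequence[int], structure: TreeStructure
    ) -> "LabeledDataset":
        codes = np.asarray(codes, dtype=np.int64)
        d = structure.d
        shifts = np.arange(d - 1, -1, -1, dtype=np.int64)
        X = ((codes[:, None] >> shifts[None, :]) & 1).astype(np.uint8)
        return cls(structure, X, np.asarray(labels, dtype=np.uint8))

    def __len__(self) -> int:
        return len(self.y)

    def records(self) -> Iterator[tuple[Bits, int]]:
        for row, label in zip(self.X, self.y):
            yield tuple(int(b) for b in row), int(label)

    def to_table(self) -> LabelTable:
        table = LabelTable(self.structure)
        for code, label in zip(self.codes, self.y):
            table.define(int(code), int(label))
        return table


@dataclass(frozen=True)
class GroundTruthSHM:
    """A fully specified tree-SHM: per-module truth tables plus output table.

    ``module_tables[i-1]`` maps every block-``i`` input code to the module's
    intermediate bit; ``output_table`` maps the code of the k intermediate
    bits (module 1 most significant) to the overall label.
    """

    structure: TreeStructure
    module_tables: tuple[np.ndarray, ...]
    output_table: np.ndarray

    def __post_init__(self) -> None:
        tables = tuple(
            np.asarray(t, dtype=np.uint8) for t in self.module_tables
        )
        out = np.asarray(self.output_table, dtype=np.uint8)
        if len(tables) != self.structure.k:
            raise ValueError("one truth table per first-layer module required")
        for n_i, t in zip(self.structure.block_sizes, tables):
            if t.shape != (1 << n_i,):
                raise ValueError(f"module table must have {1 << n_i} entries")
            if t.size and t.max() > 1:
                raise ValueError("truth tables must be binary")
        if out.shape != (1 << self.structure.k,):
            raise ValueError(f"output table must have {1 << self.structure.k} entries")
        if out.size and out.max() > 1:
            raise ValueError("truth tables must be binary")
        object.__setattr__(self, "module_tables", tables)
        object.__setattr__(self, "output_table", out)

    def evaluate_code(self, code: int) -> int:
        z = 0
        for i in range(1, self.structure.k + 1):
            z = (z << 1) | int(self.module_tables[i - 1][self.structure.project_code(code, i)])
        return int(self.output_table[z])

    def evaluate_codes(self, codes: np.ndarray) -> np.ndarray:
        """Vectorised evaluation over an array of input codes."""
        codes = np.asarray(codes, dtype=np.int64)
        z = np.zeros_like(codes)
        for i in range(1, self.structure.k + 1):
            shift = self.structure.shift(i)
            mask = (1 << self.structure.block_sizes[i - 1]) - 1
            block = (codes >> shift) & mask
            z = (z << 1) | self.module_tables[i - 1][block].astype(np.int64)
        return self.output_table[z]

    def to_json(self) -> dict:
        return {
            "block_sizes": list(self.structure.block_sizes),
            "module_tables": [t.tolist() for t in self.module_tables],
            "output_table": self.output_table.tolist(),
        }

    @classmethod
    def from_json(cls, obj: dict) -> "GroundTruthSHM":
        return cls(
            TreeStructure(tuple(obj["block_sizes"])),
            tuple(np.array(t, dtype=np.uint8) for t in obj["module_tables"]),
            np.array(obj["output_table"], dtype=np.uint8),
        )


def evaluate_shm(m: GroundTruthSHM, x: Sequence[int]) -> int:
    """Overall label ``g(f_1(block_1(x)), ..., f_k(block_k(x)))``."""
    bits = as_bits(x)
    if len(bits) != m.structure.d:
        raise ValueError(f"expected a length-{m.structure.d} vector, got {len(bits)}")
    return m.evaluate_code(bits_to_code(bits))
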