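"""Learning strategy for tree-SHMs: conflict graphs and odd-cycle forcing.

The trainer turns labeled cells of the orthotope into per-module *conflict
graphs*: the vertices of graph ``G_i`` are the ``2**n_i`` possible inputs of
module ``i``, and an edge joins two vertices whenever some pair of
equivalent i-extensions (same context, the two block values) carries
opposite overall labels.  Data consistent with a tree-SHM always yields
bipartite graphs, because colouring each vertex with the module's hidden
intermediate bit is a proper 2-colouring.

Label determination exploits the converse direction (a graph is 2-colourable
iff it has no odd cycle): a candidate label for an empty cell is infeasible
when one of the edges it would induce closes an odd cycle, in which case the
opposite label is forced.  Alternating edge insertion and forcing sweeps
until a fixpoint extrapolates the training labels — often to the entire
input space.

Odd cycles are detected with a union-find structure augmented with parity
(the relative colour of each vertex within its component), which supports
incremental edge insertion and near-constant-time same-colour queries.  A
breadth-first recolouring serves as the reference implementation in the test
suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .core import (
    UNDEFINED,
    Bits,
    GroundTruthSHM,
    LabelTable,
    LabeledDataset,
    TreeStructure,
    as_bits,
    bits_to_code,
    code_to_bits,
)

ContradictionPolicy = Literal["count", "strict"]
FallbackPolicy = Literal["majority", "abstain", "random"]


class TrainingConflictError(RuntimeError):
    """Raised in strict mode when the data contradicts the tree structure."""


class InconsistentModelError(RuntimeError):
    """Raised when defined cells with a common colour tuple disagree in label."""


class ParityDSU:
    """Union-find with parity: tracks each vertex's colour relative to its root."""

    __slots__ = ("parent", "rank", "parity")

    def __init__(self, n: int):
        self.parent = list(range(n))
        self.rank = [0] * n
        self.parity = [0] * n

    def find(self, v: int) -> tuple[int, int]:
        """Root of ``v``'s component and ``v``'s colour relative to the root."""
        parent, parity = self.parent, self.parity
        root, p = v, 0
        while parent[root] != root:
            p ^= parity[root]
            root = parent[root]
        result = p
        # path compression with parity accumulation
        while parent[v] != root:
            nxt = parent[v]
            nxt_p = p ^ parity[v]
            parent[v], parity[v] = root, p
            v, p = nxt, nxt_p
        return root, result

    def union(self, u: int, v: int, rel: int = 1) -> bool:
        """Constrain colours of ``u`` and ``v`` to differ by ``rel``.

        Returns False (and changes nothing) if the constraint contradicts
        the existing parity state.
        """
        ru, pu = self.find(u)
        rv, pv = self.find(v)
        if ru == rv:
            return (pu ^ pv) == rel
        if self.rank[ru] < self.rank[rv]:
            ru, rv = rv, ru
            pu, pv = pv, pu
        self.parent[rv] = ru
        self.parity[rv] = pu ^ pv ^ rel
        if self.rank[ru] == self.rank[rv]:
            self.rank[ru] += 1
        return True

    def same_color(self, u: int, v: int) -> bool:
        ru, pu = self.find(u)
        rv, pv = self.find(v)
        return ru == rv and pu == pv


class ConflictGraph:
    """Conflict graph of one first-layer module, with incremental parity state."""

    def __init__(self, module_index: int, n_bits: int):
        self.module_index = module_index
        self.n_bits = n_bits
        self.n_vertices = 1 << n_bits
        self.edges: set[tuple[int, int]] = set()
        self.dropped_edges: list[tuple[int, int]] = []
        self._dsu = ParityDSU(self.n_vertices)

    @property
    def tainted(self) -> bool:
        """True once an inconsistent edge has been dropped (noisy data)."""
        return bool(self.dropped_edges)

    def add_edge(self, u: int, v: int) -> str:
        """Insert edge {u, v}; returns 'added', 'present' or 'conflict'."""
        if u == v:
            raise ValueError(
                f"self-loop at vertex {u} in G_{self.module_index}: "
                "identical block inputs cannot conflict"
            )
        key = (u, v) if u < v else (v, u)
        if key in self.edges:
            return "present"
        if not self._dsu.union(u, v, rel=1):
            self.dropped_edges.append(key)
            return "conflict"
        self.edges.add(key)
        return "added"

    def closes_odd_cycle(self, u: int, v: int) -> bool:
        """Would inserting edge {u, v} break 2-colourability?"""
        if u == v:
            return True
        return self._dsu.same_color(u, v)

    def component_coloring(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-vertex colour and component id, anchored per component.

        The lexicographically smallest vertex of each component receives
        colour 0, so the colouring is canonical up to the (unresolvable)
        global flip of each component.
        """
        colors = np.zeros(self.n_vertices, dtype=np.uint8)
        comp = np.zeros(self.n_vertices, dtype=np.int64)
        anchor_parity: dict[int, int] = {}
        for v in range(self.n_vertices):
            root, p = self._dsu.find(v)
            if root not in anchor_parity:
                anchor_parity[root] = p  # v is the smallest vertex of its component
            colors[v] = p ^ anchor_parity[root]
            comp[v] = root
        return colors, comp

    @property
    def n_components(self) -> int:
        return len({self._dsu.find(v)[0] for v in range(self.n_vertices)})

    @property
    def is_connected(self) -> bool:
        return self.n_components == 1


def is_connected_2coloring(g: ConflictGraph) -> tuple[bool, np.ndarray]:
    """Whether ``G_i`` spans one component, and its anchored 2-colouring.

    The colouring assigns 0 to the lexicographically smallest vertex of each
    component; it is the unique proper 2-colouring (up to flip) exactly when
    the graph is connected.
    """
    if g.tainted:
        raise TrainingConflictError(
            f"G_{g.module_index} holds dropped (conflicting) edges; "
            "its colouring is not well defined"
        )
    colors, _ = g.component_coloring()
    return g.is_connected, colors


@dataclass(frozen=True)
class Witness:
    """The odd-cycle obstruction that forced a deduction.

    Inserting the edge ``pair`` (two block-``module_index`` inputs that the
    rejected label would have connected through context ``context_code``)
    would have merged two same-coloured vertices.
    """

    module_index: int
    pair: tuple[int, int]
    context_code: int

    def describe(self, structure: TreeStructure) -> str:
        i = self.module_index
        n = structure.block_sizes[i - 1]
        u, v = self.pair
        return (
            f"edge {code_to_bits(u, n)}–{code_to_bits(v, n)} in G_{i} "
            f"would close an odd cycle"
        )


@dataclass(frozen=True)
class ForcedLabel:
    status: Literal["forced", "undetermined", "contradiction"]
    label: int | None = None
    witness: Witness | None = None
    counter_witness: Witness | None = None


@dataclass(frozen=True)
class Deduction:
    code: int
    label: int
    witness: Witness


class ConflictSystem:
    """Incremental trainer state: label table, context groups, conflict graphs.

    ``groups[i-1]`` maps each context code of module ``i`` to two lists of
    block-``i`` vertices — the defined cells in that context slice carrying
    label 0 and label 1.  Every cross pair of the two lists is an edge of
    ``G_i``; edges are inserted (and deduplicated) as cells are defined, so
    the graphs always equal the batch construction over the defined cells.
    """

    def __init__(
        self,
        structure: TreeStructure,
        table: LabelTable,
        policy: ContradictionPolicy = "count",
    ):
        if table.structure != structure:
            raise ValueError("table/structure mismatch")
        self.structure = structure
        self.table = table
        self.policy = policy
        self.graphs = [
            ConflictGraph(i, n) for i, n in enumerate(structure.block_sizes, start=1)
        ]
        self.groups: list[dict[int, tuple[list[int], list[int]]]] = [
            {} for _ in range(structure.k)
        ]
        self.conflicts = 0
        self._shifts = [structure.shift(i) for i in range(1, structure.k + 1)]
        self._vmasks = [
            (1 << n) - 1 for n in structure.block_sizes
        ]
        self._cmasks = [~structure.block_mask(i) for i in range(1, structure.k + 1)]
        for code in table.defined_codes():
            self._index_cell(int(code), int(table.values()[code]))

    # -- state updates ----------------------------------------------------

    def _index_cell(self, code: int, label: int) -> None:
        for m in range(self.structure.k):
            v = (code >> self._shifts[m]) & self._vmasks[m]
            ctx = code & self._cmasks[m]
            grp = self.groups[m].get(ctx)
            if grp is None:
                grp = ([], [])
                self.groups[m][ctx] = grp
            graph = self.graphs[m]
            for u in grp[1 - label]:
                if graph.add_edge(v, u) == "conflict":
                    self.conflicts += 1
                    if self.policy == "strict":
                        raise TrainingConflictError(
                            f"edge between block inputs {v} and {u} contradicts "
                            f"the parity state of G_{m + 1}"
                        )
            grp[label].append(v)

    def define(self, code: int, label: int) -> None:
        """Write a cell (write-once) and update groups, edges and parity."""
        self.table.define(code, label)
        self._index_cell(code, label)

    # -- queries ----------------------------------------------------------

    def induced_odd_cycle(self, code: int, label: int) -> Witness | None:
        """First odd-cycle obstruction created by assigning ``label`` to ``code``."""
        for m in range(self.structure.k):
            grp = self.groups[m].get(code & self._cmasks[m])
            if grp is None:
                continue
            opp = grp[1 - label]
            if not opp:
                continue
            v = (code >> self._shifts[m]) & self._vmasks[m]
            graph = self.graphs[m]
            if grp[label] and not graph.tainted:
                # Both labels occur in this slice, so all opposite-label
                # vertices already sit in one component with equal colour:
                # one representative decides the query.
                candidates: Sequence[int] = (opp[0],)
            else:
                candidates = opp
            for u in candidates:
                if graph.closes_odd_cycle(v, u):
                    return Witness(m + 1, (v, u), code & self._cmasks[m])
        return None

    def forced_label(self, code: int) -> ForcedLabel:
        if self.table.label_of(code) is not None:
            raise ValueError(f"cell {code} is already defined")
        w0 = self.induced_odd_cycle(code, 0)
        w1 = self.induced_odd_cycle(code, 1)
        if w0 is not None and w1 is not None:
            return ForcedLabel("contradiction", None, w0, w1)
        if w0 is not None:
            return ForcedLabel("forced", 1, w0)
        if w1 is not None:
            return ForcedLabel("forced", 0, w1)
        return ForcedLabel("undetermined")

    def sweep(self) -> tuple[list[Deduction], bool]:
        """One lexicographic pass over the undefined cells.

        Forced labels are written immediately and their induced edges
        inserted, so later cells of the same pass see earlier deductions.
        """
        updates: list[Deduction] = []
        for code in self.table.undefined_codes():
            code = int(code)
            fl = self.forced_label(code)
            if fl.status == "forced":
                assert fl.label is not None and fl.witness is not None
                self.define(code, fl.label)
                updates.append(Deduction(code, fl.label, fl.witness))
            elif fl.status == "contradiction":
                self.conflicts += 1
                if self.policy == "strict":
                    raise TrainingConflictError(
                        f"cell {code}: both labels would close an odd cycle"
                    )
        return updates, bool(updates)


@dataclass
class TrainResult:
    """Output of :func:`train`: the (partial) label table plus provenance."""

    structure: TreeStructure
    table: LabelTable
    graphs: list[ConflictGraph]
    deductions: list[Deduction]
    conflicts: int
    sweeps: int
    training_codes: frozenset[int]
    majority_label: int

    @property
    def deduced_codes(self) -> frozenset[int]:
        return frozenset(ded.code for ded in self.deductions)

    def provenance(self, code: int) -> str | None:
        if code in self.training_codes:
            return "training"
        if self.table.label_of(code) is not None:
            return "deduced"
        return None


# -- public operations ----------------------------------------------------


def build_conflict_edges(
    table: LabelTable,
    structure: TreeStructure,
    policy: ContradictionPolicy = "count",
) -> list[ConflictGraph]:
    """Conflict graphs of all modules for the defined cells of ``table``.

    For each module, defined cells are grouped by context; every pair with
    opposite labels inside a group contributes an edge.  Equivalent to (and
    tested against) the naive scan over all cell pairs.
    """
    if table.n_defined == 0:
        raise ValueError("the table has no defined cells")
    return ConflictSystem(structure, table, policy).graphs


def forced_label(
    x: Sequence[int] | int,
    table: LabelTable,
    structure: TreeStructure,
    system: ConflictSystem | None = None,
) -> ForcedLabel:
    """Label of cell ``x`` forced by odd-cycle avoidance, if any.

    A candidate label is infeasible when one of the conflict-graph edges it
    would induce joins two vertices already known to have equal colour.
    Passing a prebuilt ``system`` avoids re-deriving graphs from the table.
    """
    code = x if isinstance(x, int) else bits_to_code(as_bits(x))
    if system is None:
        system = ConflictSystem(structure, table)
    return system.forced_label(code)


def label_determination_sweep(
    table: LabelTable,
    structure: TreeStructure,
    system: ConflictSystem | None = None,
    policy: ContradictionPolicy = "count",
) -> tuple[list[Deduction], bool]:
    """One lexicographic sweep of forced-label deduction over ``table``.

    Mutates ``table`` (and ``system`` when given) in place.
    """
    if system is None:
        system = ConflictSystem(structure, table, policy)
    return system.sweep()


def train(
    dataset: LabeledDataset,
    structure: TreeStructure | None = None,
    policy: ContradictionPolicy = "count",
    max_sweeps: int | None = None,
) -> TrainResult:
    """Run the full strategy: seed the table, then sweep to a fixpoint.

    Conflict-graph edges are maintained incrementally as cells are defined,
    which yields the same graphs as rebuilding them from scratch between
    sweeps; sweeps repeat until the table is total or a pass deduces
    nothing new.
    """
    if structure is None:
        structure = dataset.structure
    elif structure != dataset.structure:
        raise ValueError("dataset was built for a different structure")
    table = LabelTable(structure)
    order = np.argsort(dataset.codes, kind="stable")
    for idx in order:
        table.define(int(dataset.codes[idx]), int(dataset.y[idx]))
    system = ConflictSystem(structure, table, policy)
    deductions: list[Deduction] = []
    sweeps = 0
    while not table.is_total:
        if max_sweeps is not None and sweeps >= max_sweeps:
            break
        updates, any_update = system.sweep()
        sweeps += 1
        deductions.extend(updates)
        if not any_update:
            break
    ones = int(dataset.y.sum())
    majority = 1 if 2 * ones >= len(dataset) else 0  # ties break to 1
    return TrainResult(
        structure=structure,
        table=table,
        graphs=system.graphs,
        deductions=deductions,
        conflicts=system.conflicts,
        sweeps=sweeps,
        training_codes=frozenset(int(c) for c in dataset.codes),
        majority_label=majority,
    )


def predict(
    result: TrainResult,
    x: Sequence[int] | int,
    fallback: FallbackPolicy = "majority",
    rng: np.random.Generator | None = None,
) -> tuple[int | None, bool]:
    """Label for ``x``: the table value when determined, else the fallback.

    Returns ``(label, determined)``; under ``abstain`` the label is ``None``
    for undetermined cells so callers can exclude them from metrics.
    """
    code = x if isinstance(x, int) else bits_to_code(as_bits(x))
    val = result.table.label_of(code)
    if val is not None:
        return val, True
    if fallback == "majority":
        return result.majority_label, False
    if fallback == "abstain":
        return None, False
    if fallback == "random":
        if rng is None:
            raise ValueError("fallback='random' needs an rng")
        return int(rng.integers(2)), False
    raise ValueError(f"unknown fallback {fallback!r}")


def predict_codes(
    result: TrainResult,
    codes: np.ndarray,
    fallback: FallbackPolicy = "majority",
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised :func:`predict`: labels (-1 marks abstentions) and a
    determined mask."""
    codes = np.asarray(codes, dtype=np.int64)
    values = result.table.values()[codes].astype(np.int8)
    determined = values != UNDEFINED
    out = values.copy()
    if fallback == "majority":
        out[~determined] = result.majority_label
    elif fallback == "abstain":
        pass  # leave UNDEFINED as the abstention marker
    elif fallback == "random":
        if rng is None:
            raise ValueError("fallback='random' needs an rng")
        out[~determined] = rng.integers(2, size=int((~determined).sum()), dtype=np.int8)
    else:
        raise ValueError(f"unknown fallback {fallback!r}")
    return out, determined


@dataclass
class ModuleFunctions:
    """Per-module colourings (intermediate truth tables up to flip) and the
    induced output table on observed colour tuples."""

    colorings: list[np.ndarray]
    unique: list[bool]
    output_table: dict[tuple[int, ...], int]
    clashes: list[tuple[tuple[int, ...], int, int]] = field(default_factory=list)


def extract_module_functions(result: TrainResult) -> ModuleFunctions:
    """Recover module i-o functions (up to per-module 0/1 flips) and the
    output function on the colour tuples that the defined cells exhibit.

    A module's function is unique exactly when its conflict graph is
    connected.  Two defined cells mapping to the same colour tuple but
    different labels signal an internal inconsistency when every module
    colouring involved is unique; with ambiguous (disconnected) colourings
    the clash is recorded instead.
    """
    colorings, unique = [], []
    for g in result.graphs:
        colors, _ = g.component_coloring()
        colorings.append(colors)
        unique.append(g.is_connected)
    structure = result.structure
    output: dict[tuple[int, ...], int] = {}
    clashes: list[tuple[tuple[int, ...], int, int]] = []
    values = result.table.values()
    for code in result.table.defined_codes():
        code = int(code)
        tup = tuple(
            int(colorings[m][structure.project_code(code, m + 1)])
            for m in range(structure.k)
        )
        label = int(values[code])
        if tup in output and output[tup] != label:
            if all(unique):
                raise InconsistentModelError(
                    f"colour tuple {tup} maps to both labels"
                )
            clashes.append((tup, output[tup], label))
        else:
            output[tup] = label
    return ModuleFunctions(colorings, unique, output, clashes)
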