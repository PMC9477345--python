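"""Small worked instances used in documentation and tests."""

from __future__ import annotations

from dataclasses import dataclass

from .core import Bits, LabeledDataset, TreeStructure


@dataclass(frozen=True)
class WorkedExample:
    structure: TreeStructure
    dataset: LabeledDataset
    query: Bits
    expected_label: int
    expected_module: int
    expected_pair: tuple[Bits, Bits]


def odd_cycle_worked_example() -> WorkedExample:
    """A 9-bit deduction driven by an odd cycle in the module-1 graph.

    Five labeled cells of the (3, 3, 3) orthotope give G_1 the path
    (0,0,0) – (0,0,1) – (1,0,1), so (0,0,0) and (1,0,1) share a colour.
    The cell (0,0,0,0,0,0,0,0,1) shares its module-1 context with the
    1-labeled cell (1,0,1,0,0,0,0,0,1): assigning it label 0 would create
    the edge (0,0,0)–(1,0,1), closing an odd cycle — so its label is
    forced to 1.
    """
    structure = TreeStructure((3, 3, 3))
    records = [
        ((0, 0, 0, 0, 0, 0, 0, 0, 0), 0),
        ((0, 0, 1, 0, 0, 0, 0, 0, 0), 1),  # edge (0,0,0)-(0,0,1) in G_1
        ((0, 0, 1, 1, 1, 1, 1, 1, 1), 0),
        ((1, 0, 1, 1, 1, 1, 1, 1, 1), 1),  # edge (0,0,1)-(1,0,1) in G_1
        ((1, 0, 1, 0, 0, 0, 0, 0, 1), 1),  # shares the query's module-1 context
    ]
    dataset = LabeledDataset.from_records(records, structure)
    return WorkedExample(
        structure=structure,
        dataset=dataset,
        query=(0, 0, 0, 0, 0, 0, 0, 0, 1),
        expected_label=1,
        expected_module=1,
        expected_pair=((0, 0, 0), (1, 0, 1)),
    )
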