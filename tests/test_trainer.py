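"""Conflict-graph construction, odd-cycle forcing and the training loop."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from treeshm.core import LabelTable, LabeledDataset, TreeStructure
from treeshm.examples import odd_cycle_worked_example
from treeshm.synthetic import (
    GeneratorConfig,
    benchmark_runs,
    full_label_table,
    generate_ground_truth,
    sample_training_set,
)
from treeshm.trainer import (
    ConflictGraph,
    ConflictSystem,
    ParityDSU,
    TrainingConflictError,
    build_conflict_edges,
    extract_module_functions,
    forced_label,
    is_connected_2coloring,
    label_determination_sweep,
    predict,
    train,
)

from conftest import bfs_two_coloring, naive_conflict_edges


class TestParityDSU:
    @settings(derandomize=True, max_examples=80)
    @given(st.lists(st.tuples(st.integers(0, 9), st.integers(0, 9)), max_size=40))
    def test_agrees_with_bfs_recoloring(self, pairs):
        """Incremental parity state must match a BFS recolouring of the
        accepted edges: same accept/reject verdicts, same colour classes."""
        dsu = ParityDSU(10)
        accepted: set[tuple[int, int]] = set()
        for u, v in pairs:
            if u == v:
                continue
            key = (min(u, v), max(u, v))
            ref = bfs_two_coloring(10, accepted | {key})
            ok = dsu.union(u, v, rel=1)
            assert ok == (ref is not None)
            if ok:
                accepted.add(key)
        ref = bfs_two_coloring(10, accepted)
        assert ref is not None
        colors, comp = ref
        for a in range(10):
            for b in range(10):
                same_comp = comp[a] == comp[b]
                assert (dsu.find(a)[0] == dsu.find(b)[0]) == same_comp
                if same_comp:
                    assert dsu.same_color(a, b) == (colors[a] == colors[b])


class TestBuildConflictEdges:
    def test_opposite_labels_single_block_difference(self):
        s = TreeStructure((2, 2))
        table = LabelTable(s)
        table.define(0b0110, 0)
        table.define(0b1010, 1)  # differs only inside block 1
        graphs = build_conflict_edges(table, s)
        assert graphs[0].edges == {(1, 2)}
        assert graphs[1].edges == set()

    def test_different_contexts_no_edges(self):
        s = TreeStructure((2, 2))
        table = LabelTable(s)
        table.define(0b0000, 0)
        table.define(0b1111, 1)
        graphs = build_conflict_edges(table, s)
        assert all(g.edges == set() for g in graphs)

    def test_matches_naive_pair_scan(self, rng):
        for blocks in [(2, 2), (3, 2), (2, 3, 2), (3, 3, 3)]:
            s = TreeStructure(blocks)
            m = generate_ground_truth(rng, s)
            truth = full_label_table(m)
            ds = sample_training_set(rng, truth, 0.3)
            table = ds.to_table()
            graphs = build_conflict_edges(table, s)
            reference = naive_conflict_edges(table, s)
            for g, ref in zip(graphs, reference):
                assert g.edges == ref
                assert not g.dropped_edges

    def test_empty_table_rejected(self):
        s = TreeStructure((2,))
        with pytest.raises(ValueError):
            build_conflict_edges(LabelTable(s), s)


class TestTwoColoring:
    def test_edgeless_graph(self):
        g = ConflictGraph(1, 3)
        connected, colors = is_connected_2coloring(g)
        assert not connected
        assert colors.tolist() == [0] * 8

    def test_spanning_path_alternates(self):
        g = ConflictGraph(1, 3)
        for v in range(7):
            g.add_edge(v, v + 1)
        connected, colors = is_connected_2coloring(g)
        assert connected
        assert colors.tolist() == [0, 1, 0, 1, 0, 1, 0, 1]

    def test_matches_brute_force_proper_colorings(self, rng):
        """On a random bipartite 8-vertex graph the anchored colouring must
        coincide (up to global flip) with the proper colouring found by
        exhausting all 2^8 assignments per component."""
        truth = rng.integers(0, 2, size=8)
        g = ConflictGraph(1, 3)
        edges = set()
        for _ in range(12):
            u, v = rng.integers(8), rng.integers(8)
            if u != v and truth[u] != truth[v]:
                g.add_edge(int(u), int(v))
                edges.add((min(u, v), max(u, v)))
        _, colors = is_connected_2coloring(g)
        proper = []
        for assign in range(256):
            cand = [(assign >> j) & 1 for j in range(8)]
            if all(cand[u] != cand[v] for u, v in edges):
                proper.append(cand)
        assert any(
            all(colors[v] == c[v] for v in range(8)) for c in proper
        )

    def test_tainted_graph_names_module(self):
        g = ConflictGraph(2, 2)
        g.add_edge(0, 1)
        g.add_edge(1, 2)
        g.add_edge(0, 2)  # odd triangle: dropped
        assert g.tainted
        with pytest.raises(TrainingConflictError, match="G_2"):
            is_connected_2coloring(g)


class TestForcedLabel:
    def test_worked_example_forces_one(self):
        ex = odd_cycle_worked_example()
        table = ex.dataset.to_table()
        fl = forced_label(ex.query, table, ex.structure)
        assert fl.status == "forced" and fl.label == ex.expected_label
        assert fl.witness.module_index == ex.expected_module

    def test_no_constraints_undetermined(self):
        s = TreeStructure((2, 2))
        table = LabelTable(s)
        table.define(0b1111, 1)
        fl = forced_label((0, 0, 0, 0), table, s)
        assert fl.status == "undetermined"

    def test_defined_cell_rejected(self):
        s = TreeStructure((2,))
        table = LabelTable(s)
        table.define(0, 0)
        with pytest.raises(ValueError):
            forced_label(0, table, s)


class TestSweep:
    def test_total_table_no_updates(self, rng):
        s = TreeStructure((2, 2))
        truth = full_label_table(generate_ground_truth(rng, s))
        updates, any_update = label_determination_sweep(truth, s)
        assert updates == [] and not any_update

    def test_fixpoint_order_insensitive(self, rng):
        """Sweeping to a fixpoint in lexicographic order, in reverse order,
        and one-assignment-at-a-time (the prose variant) must deduce the
        same final table."""
        for _ in range(10):
            s = TreeStructure(tuple(rng.choice([2, 3], size=3)))
            truth = full_label_table(generate_ground_truth(rng, s))
            ds = sample_training_set(rng, truth, 0.3)

            lex = train(ds)

            def fixpoint(order_fn):
                table = ds.to_table()
                system = ConflictSystem(s, table)
                while True:
                    changed = False
                    for code in order_fn(table):
                        fl = system.forced_label(int(code))
                        if fl.status == "forced":
                            system.define(int(code), fl.label)
                            changed = True
                    if not changed:
                        return table

            reverse = fixpoint(lambda t: t.undefined_codes()[::-1])
            # prose variant: restart from the smallest cell after each write
            prose_table = ds.to_table()
            prose = ConflictSystem(s, prose_table)
            while True:
                for code in prose_table.undefined_codes():
                    fl = prose.forced_label(int(code))
                    if fl.status == "forced":
                        prose.define(int(code), fl.label)
                        break
                else:
                    break
            assert np.array_equal(lex.table.values(), reverse.values())
            assert np.array_equal(lex.table.values(), prose_table.values())


class TestTrain:
    def test_full_training_set_no_deductions(self, rng):
        s = TreeStructure((2, 2))
        truth = full_label_table(generate_ground_truth(rng, s))
        ds = sample_training_set(rng, truth, 1.0)
        result = train(ds)
        assert result.deductions == []
        assert np.array_equal(result.table.values(), truth.values())

    def test_training_cells_preserved_and_disjoint_from_deductions(self, rng):
        s = TreeStructure((3, 2, 2))
        truth = full_label_table(generate_ground_truth(rng, s))
        ds = sample_training_set(rng, truth, 0.3)
        result = train(ds)
        for code, label in zip(ds.codes, ds.y):
            assert result.table.label_of(int(code)) == label
        assert result.deduced_codes.isdisjoint(result.training_codes)

    def test_soundness_and_bipartiteness_small(self, rng):
        for _ in range(25):
            s = TreeStructure(tuple(rng.choice([2, 3], size=3)))
            truth = full_label_table(generate_ground_truth(rng, s))
            ds = sample_training_set(rng, truth, float(rng.choice([0.2, 0.3, 0.4])))
            result = train(ds)
            assert result.conflicts == 0
            vals = result.table.values()
            defined = vals != -1
            assert np.array_equal(vals[defined], truth.values()[defined])

    def test_incremental_edges_equal_batch_reconstruction(self, rng):
        """After training, the graphs held by the result must equal a batch
        rebuild over the final defined cells (Algorithm-style lines 6-12)."""
        s = TreeStructure((3, 3))
        truth = full_label_table(generate_ground_truth(rng, s))
        ds = sample_training_set(rng, truth, 0.25)
        result = train(ds)
        rebuilt = build_conflict_edges(result.table, s)
        for g_inc, g_batch in zip(result.graphs, rebuilt):
            assert g_inc.edges == g_batch.edges

    def test_idempotence_on_own_deductions(self, rng):
        s = TreeStructure((2, 3, 2))
        truth = full_label_table(generate_ground_truth(rng, s))
        ds = sample_training_set(rng, truth, 0.3)
        first = train(ds)
        codes = first.table.defined_codes()
        augmented = LabeledDataset.from_codes(
            codes, first.table.values()[codes], s
        )
        second = train(augmented)
        assert second.deductions == []
        assert np.array_equal(first.table.values(), second.table.values())

    def test_monotone_under_nested_training_sets(self, rng):
        s = TreeStructure((3, 2, 3))
        truth = full_label_table(generate_ground_truth(rng, s))
        big = sample_training_set(rng, truth, 0.4)
        keep = rng.choice(len(big), size=len(big) // 2, replace=False)
        small = LabeledDataset(s, big.X[keep], big.y[keep])
        res_small, res_big = train(small), train(big)
        vs, vb = res_small.table.values(), res_big.table.values()
        determined_small = vs != -1
        assert np.all(vb[determined_small] != -1)
        assert np.array_equal(vs[determined_small], vb[determined_small])

    def test_contradictory_data_counted_or_raises(self):
        # a triangle 0-1-2 in G_1, built through three block-2 contexts,
        # is an odd cycle: no tree-SHM on (2, 2) fits these labels
        s = TreeStructure((2, 2))
        codes = [0b0000, 0b0100, 0b0101, 0b1001, 0b0010, 0b1010]
        labels = [0, 1, 0, 1, 0, 1]
        ds = LabeledDataset.from_codes(codes, labels, s)
        result = train(ds)
        assert result.conflicts > 0
        assert any(g.tainted for g in result.graphs)
        with pytest.raises(TrainingConflictError):
            train(ds, policy="strict")


class TestPredict:
    def test_defined_cell_returns_value(self, rng):
        s = TreeStructure((2, 2))
        truth = full_label_table(generate_ground_truth(rng, s))
        ds = sample_training_set(rng, truth, 1.0)
        result = train(ds)
        assert predict(result, 5) == (truth.label_of(5), True)

    def test_majority_fallback_ties_to_one(self):
        s = TreeStructure((2, 2))
        ds = LabeledDataset.from_codes([0, 1], [0, 1], s)
        result = train(ds)
        label, determined = predict(result, 15, fallback="majority")
        assert (label, determined) == (1, False)

    def test_abstain_fallback_flags(self):
        s = TreeStructure((2, 2))
        ds = LabeledDataset.from_codes([0], [0], s)
        result = train(ds)
        assert predict(result, 15, fallback="abstain") == (None, False)


class TestExtractModuleFunctions:
    def test_single_module_recovered_up_to_flip(self, rng):
        s = TreeStructure((3,))
        m = generate_ground_truth(rng, s, reject_constant=True)
        truth = full_label_table(m)
        ds = sample_training_set(rng, truth, 1.0)
        funcs = extract_module_functions(train(ds))
        # with k=1 the module function is the label table itself
        target = m.output_table[m.module_tables[0]]
        got = funcs.colorings[0]
        assert (
            np.array_equal(got, target) or np.array_equal(1 - got, target)
        )

    def test_edgeless_graphs_flagged_non_unique(self):
        s = TreeStructure((2, 2))
        ds = LabeledDataset.from_codes([0], [1], s)
        funcs = extract_module_functions(train(ds))
        assert funcs.unique == [False, False]

    def test_covid_shape_table_sizes(self):
        s = TreeStructure((3, 2))
        ds = LabeledDataset.from_codes([0, 31], [0, 1], s)
        funcs = extract_module_functions(train(ds))
        assert [len(c) for c in funcs.colorings] == [8, 4]
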