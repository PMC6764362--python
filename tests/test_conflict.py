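"""Conflict classification, pies, time slices, gene scores, regions."""

import numpy as np
import pandas as pd
import pytest

from phyloconflict import (
    CONCORDANT,
    CONFLICT,
    UNINFORMATIVE,
    SimulationConfig,
    classify_node,
    map_all,
    parse_newick,
    region_summary,
    score_genes,
    simulate_gene_trees,
    simulate_reference,
    time_slice,
)
from phyloconflict.conflict import (
    MISSING_TAXA,
    PAPER_BINS,
    assign_bin,
    reference_nodes,
)
from phyloconflict.trees import Bipartition


@pytest.fixture
def small_scenario():
    cfg = SimulationConfig(
        seed=11, n_taxa=12, n_genes=20, conflict_fraction=0.25,
        p_high_support=1.0, dropout_prob=0.0,
    )
    ref, ages = simulate_reference(cfg)
    genes, truth = simulate_gene_trees(ref, cfg)
    return ref, ages, genes, truth


def _split_for_clade(ref, clade):
    for nid, split, c in reference_nodes(ref):
        if c == frozenset(clade):
            return nid, split
    raise AssertionError("clade not found")


class TestClassifyNode:
    def test_methods_worked_example(self):
        # reference contains ((A,B),C); the gene is missing B but has (A,C):
        # concordant at the {A,B,C} node, uninformative at (A,B)
        ref = parse_newick("(((A,B),C),(D,(E,O)));")
        gene = parse_newick("(((A,C)95,D)95,(E,O)95);")
        _, split_ab = _split_for_clade(ref, {"A", "B"})
        _, split_abc = _split_for_clade(ref, {"A", "B", "C"})
        c1 = classify_node(gene, split_ab, 70)
        assert c1.category == UNINFORMATIVE and c1.reason == MISSING_TAXA
        assert classify_node(gene, split_abc, 70).category == CONCORDANT

    def test_identical_tree_concordant_everywhere(self, small_scenario):
        ref, _, _, _ = small_scenario
        gene = ref.copy()
        for n in gene.internal_nodes(exclude_root=True):
            n.support = 100.0
        for _, split, _ in reference_nodes(ref):
            assert classify_node(gene, split, 70).category == CONCORDANT

    def test_support_below_cutoff_uninformative(self):
        ref = parse_newick("((A,B),(C,D));")
        gene = parse_newick("((A,B)69,(C,D));")
        split = next(iter(__import__("phyloconflict").extract_bipartitions(ref)))
        assert classify_node(gene, split, 70).category == UNINFORMATIVE
        assert classify_node(gene, split, None).category == CONCORDANT

    def test_conflicting_split_recorded(self):
        ref = parse_newick("((A,B),(C,D));")
        gene = parse_newick("((A,C)99,(B,D));")
        split = Bipartition.make({"A", "B"}, set("ABCD"))
        cls = classify_node(gene, split, 70)
        assert cls.category == CONFLICT
        assert cls.conflicting == Bipartition.make({"A", "C"}, set("ABCD"))

    def test_agrees_with_bruteforce_oracle(self, rng):
        # oracle: enumerate the restricted gene tree's clades directly
        from conftest import random_binary_tree

        for _ in range(20):
            ref = random_binary_tree(rng, 8)
            gene = random_binary_tree(rng, 8)
            for n in gene.internal_nodes(exclude_root=True):
                n.support = float(rng.choice([40, 80, 100]))
            for _, split, _ in reference_nodes(ref):
                got = classify_node(gene, split, 70)
                want = _oracle_classify(gene, split, 70)
                assert got.category == want


def _oracle_classify(gene, ref_split, cutoff):
    taxa = gene.leaf_labels() & ref_split.taxon_set
    a = ref_split.side_a & taxa
    b = ref_split.side_b & taxa
    if len(a) < 2 or len(b) < 2:
        return UNINFORMATIVE
    splits = []
    for node in gene.postorder():
        if node.is_leaf or node is gene.root:
            continue
        if cutoff is not None and (node.support is None or node.support < cutoff):
            continue
        clade = frozenset(l.label for l in _leaves(node)) & taxa
        other = taxa - clade
        if len(clade) >= 2 and len(other) >= 2:
            splits.append((clade, other))
    for clade, other in splits:
        if clade in (a, b):
            return CONCORDANT
    for clade, other in splits:
        if clade & a and clade & b and other & a and other & b:
            return CONFLICT
    return UNINFORMATIVE


def _leaves(node):
    stack = [node]
    while stack:
        n = stack.pop()
        if n.is_leaf:
            yield n
        else:
            stack.extend(n.children)


class TestMapAll:
    def test_identical_genes_fully_concordant(self, small_scenario):
        ref, _, _, _ = small_scenario
        genes = []
        for i in range(10):
            g = ref.copy()
            for n in g.internal_nodes(exclude_root=True):
                n.support = 100.0
            genes.append((f"g{i}", g))
        summaries, _ = map_all(genes, ref, 70)
        for s in summaries.values():
            assert (s.n_concordant, s.n_dominant_alt, s.n_other_conflict,
                    s.n_uninformative) == (10, 0, 0, 0)

    def test_planted_conflict_ratio_and_dominant_split(self, small_scenario):
        ref, _, genes, truth = small_scenario
        summaries, _ = map_all(genes, ref, 70)
        nid = next(iter(truth.focal))
        s = summaries[nid]
        assert s.n_concordant == 15 and s.n_dominant_alt == 5
        assert s.n_other_conflict == 0 and s.n_uninformative == 0
        assert s.dominant_alt == truth.focal[nid]["alt_split"]

    def test_zero_support_saturates_to_uninformative(self, small_scenario):
        ref, _, genes, _ = small_scenario
        muted = []
        for name, g in genes:
            g = g.copy()
            for n in g.internal_nodes(exclude_root=True):
                n.support = 0.0
            muted.append((name, g))
        summaries, _ = map_all(muted, ref, 70)
        for s in summaries.values():
            assert s.n_concordant == 0 and s.n_uninformative == len(muted)

    def test_counts_always_sum_to_gene_number(self, small_scenario):
        ref, _, genes, _ = small_scenario
        for cutoff in (None, 50, 70, 90):
            summaries, _ = map_all(genes, ref, cutoff)
            assert all(s.n_total == len(genes) for s in summaries.values())

    def test_cutoff_monotonicity(self, small_scenario):
        ref, _, genes, _ = small_scenario
        cfg = SimulationConfig(seed=12, n_taxa=12, n_genes=20, p_high_support=0.5)
        genes2, _ = simulate_gene_trees(ref, cfg)
        prev = None
        for cutoff in (0, 25, 50, 75, 100):
            summaries, _ = map_all(genes2, ref, cutoff)
            cur = {
                nid: (s.n_concordant, s.n_dominant_alt + s.n_other_conflict,
                      s.n_uninformative)
                for nid, s in summaries.items()
            }
            if prev is not None:
                for nid in cur:
                    assert cur[nid][0] <= prev[nid][0]
                    assert cur[nid][1] <= prev[nid][1]
                    assert cur[nid][2] >= prev[nid][2]
            prev = cur


class TestTimeSlice:
    @pytest.mark.parametrize(
        "age,expected",
        [(95, "120-91"), (30, "30-0"), (121, "150-121"), (150, "150-121"),
         (91, "120-91"), (90.5, "90-61"), (31, "60-31"), (0, "30-0")],
    )
    def test_bin_assignment(self, age, expected):
        assert assign_bin(age, PAPER_BINS) == expected

    def test_age_outside_bins_errors(self):
        with pytest.raises(ValueError):
            assign_bin(151, PAPER_BINS)
        with pytest.raises(ValueError):
            assign_bin(-1, PAPER_BINS)

    def test_fully_concordant_gene_scores_one_everywhere(self):
        cfg = SimulationConfig(seed=3, n_taxa=30, n_genes=1,
                               conflict_fraction=0.0, p_high_support=1.0,
                               dropout_prob=0.0)
        ref, ages = simulate_reference(cfg)
        genes, _ = simulate_gene_trees(ref, cfg)
        _, matrix = map_all(genes, ref, 70)
        node_ages = dict(zip(ages["node_id"], ages["age"]))
        prof = time_slice(matrix, node_ages)
        tab = prof.table
        nonempty = tab[tab["n_evaluable"] > 0]
        assert (nonempty["proportion"] == 1.0).all()
        assert len(nonempty) > 0

    def test_missing_age_errors(self, small_scenario):
        ref, ages, genes, _ = small_scenario
        _, matrix = map_all(genes, ref, 70)
        with pytest.raises(ValueError, match="without ages"):
            time_slice(matrix, {}, PAPER_BINS)

    def test_denominator_excludes_missing_taxa_nodes(self):
        ref = parse_newick("(((A,B),C),(D,(E,O)));")
        gene = parse_newick("(((A,C)95,D)95,(E,O)95);")  # B missing
        summaries, matrix = map_all([("g", gene)], ref, 70)
        ages = {nid: 10.0 * (i + 1) for i, nid in enumerate(matrix.node_ids)}
        prof = time_slice(matrix, ages)
        total_eval = prof.table["n_evaluable"].sum()
        n_voided = sum(
            1 for nid in matrix.node_ids
            if matrix.get("g", nid).reason == MISSING_TAXA
        )
        assert n_voided >= 1
        assert total_eval == len(matrix.node_ids) - n_voided


class TestGeneScores:
    def test_identical_gene_scores_all_nodes(self, small_scenario):
        ref, _, _, _ = small_scenario
        g = ref.copy()
        for n in g.internal_nodes(exclude_root=True):
            n.support = 100.0
        genes = [("g", g)]
        _, m_ns = map_all(genes, ref, None)
        _, m_s = map_all(genes, ref, 70)
        score = score_genes(m_ns, m_s)[0]
        n_nodes = len(reference_nodes(ref))
        assert score.n_concordant_nosupport == n_nodes
        assert score.n_concordant_support == n_nodes
        assert score.n_available == n_nodes

    def test_support_counts_never_exceed_nosupport(self, small_scenario):
        ref, _, genes, _ = small_scenario
        _, m_ns = map_all(genes, ref, None)
        _, m_s = map_all(genes, ref, 70)
        for s in score_genes(m_ns, m_s):
            assert s.n_concordant_support <= s.n_concordant_nosupport <= s.n_available

    def test_missing_taxon_reduces_available_by_voided_nodes(self):
        cfg = SimulationConfig(seed=7, n_taxa=10, n_genes=1,
                               conflict_fraction=0.0, p_high_support=1.0,
                               dropout_prob=0.0)
        ref, _ = simulate_reference(cfg)
        dropped = sorted(ref.leaf_labels())[2]
        g = ref.prune_to(ref.leaf_labels() - {dropped})
        for n in g.internal_nodes(exclude_root=True):
            n.support = 100.0
        genes = [("g", g)]
        _, m_ns = map_all(genes, ref, None)
        _, m_s = map_all(genes, ref, 70)
        score = score_genes(m_ns, m_s)[0]
        # oracle: nodes voided are exactly those whose restricted split
        # collapses without the dropped taxon
        kept = ref.leaf_labels() - {dropped}
        voided = sum(
            1 for _, split, _ in reference_nodes(ref)
            if split.restrict(kept) is None
        )
        assert score.n_available == len(reference_nodes(ref)) - voided
        assert voided >= 1

    def test_sorted_by_gene_name(self, small_scenario):
        ref, _, genes, _ = small_scenario
        _, m_ns = map_all(genes, ref, None)
        _, m_s = map_all(genes, ref, 70)
        names = [s.gene for s in score_genes(m_ns, m_s)]
        assert names == sorted(names)


class TestRegionSummary:
    def _scores(self, small_scenario):
        ref, _, genes, _ = small_scenario
        _, m_ns = map_all(genes, ref, None)
        _, m_s = map_all(genes, ref, 70)
        return score_genes(m_ns, m_s)

    def test_single_region_equals_global(self, small_scenario):
        scores = self._scores(small_scenario)
        regions = {s.gene: "LSC" for s in scores}
        out = region_summary(scores, regions)
        assert out.loc["LSC", "n_concordant_support"] == sum(
            s.n_concordant_support for s in scores
        )

    def test_two_regions_additive(self, small_scenario):
        scores = self._scores(small_scenario)
        regions = {
            s.gene: ("LSC" if i % 2 else "IR") for i, s in enumerate(scores)
        }
        out = region_summary(scores, regions)
        assert out["n_concordant_nosupport"].sum() == sum(
            s.n_concordant_nosupport for s in scores
        )

    def test_unlabeled_gene_errors(self, small_scenario):
        scores = self._scores(small_scenario)
        with pytest.raises(ValueError, match="without region"):
            region_summary(scores, {})

    def test_planted_region_rate_contrast(self):
        from phyloconflict import build_scenarios, tree_stats

        cfg = SimulationConfig(seed=21, n_taxa=12, n_genes=30)
        sc = build_scenarios(cfg)["conflict"]
        tl = {}
        for name, tree in sc.gene_trees:
            tl.setdefault(sc.region_map[name], []).append(
                tree_stats(tree).tree_length
            )
        # LSC genes were planted with a higher rate multiplier than IR
        assert np.mean(tl["LSC"]) > np.mean(tl["IR"])
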