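"""Overlap statistics, enrichment scores and permutation calibration.

Brute-force oracles: exhaustive draw enumeration for the hypergeometric
tail, and an explicit running-sum walk for the enrichment score.
"""

import itertools

import numpy as np
import pandas as pd
import pytest

from ampliconmap import synthetic_data as sd
from ampliconmap.enrichment import (
    TargetList,
    build_target_list,
    consolidate_signatures,
    correlated_target_lists,
    gsea,
    gsea_batch,
    gsea_es,
    hypergeometric_overlap,
    leading_edge,
    rank_genes_by_phenotype,
    _es_from_hit_ranks,
)
from ampliconmap.io_formats import ExpressionMatrix, GeneSet, ValidationError


def enumerate_overlap_tail(n_universe, n_a, n_b, k) -> float:
    """P(|A & B| >= k) by enumerating every possible draw of B."""
    universe = list(range(n_universe))
    a = set(universe[:n_a])
    hits = total = 0
    for draw in itertools.combinations(universe, n_b):
        total += 1
        hits += len(a & set(draw)) >= k
    return hits / total


def brute_force_es(scores, hit_mask, weight) -> float:
    """Explicit running-sum walk; signed max deviation, positive on ties."""
    n = len(scores)
    nh = int(np.sum(hit_mask))
    wsum = float(np.sum(np.abs(scores[hit_mask]) ** weight))
    running, value = [], 0.0
    for i in range(n):
        if hit_mask[i]:
            value += (np.abs(scores[i]) ** weight / wsum) if wsum > 0 else 1.0 / nh
        else:
            value -= 1.0 / (n - nh) if n > nh else 0.0
        running.append(value)
    hi, lo = max(max(running), 0.0), min(min(running), 0.0)
    return hi if hi >= -lo else lo


class TestHypergeometricOverlap:
    def test_worked_example(self):
        universe = [f"g{i}" for i in range(10)]
        res = hypergeometric_overlap(universe[:4], universe[1:6], universe)
        assert res.n_overlap == 3
        assert res.p_value == pytest.approx(66 / 252)

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            n_u = int(rng.integers(3, 13))
            n_a = int(rng.integers(1, n_u + 1))
            n_b = int(rng.integers(1, n_u + 1))
            universe = [f"g{i}" for i in range(n_u)]
            a = set(rng.choice(universe, n_a, replace=False))
            b = set(rng.choice(universe, n_b, replace=False))
            res = hypergeometric_overlap(a, b, universe)
            expected = enumerate_overlap_tail(n_u, n_a, n_b, len(a & b))
            assert res.p_value == pytest.approx(expected, rel=1e-9)

    def test_b_equals_universe(self):
        universe = [f"g{i}" for i in range(8)]
        res = hypergeometric_overlap(universe[:3], universe, universe)
        assert res.n_overlap == 3
        assert res.p_value == pytest.approx(1.0)

    def test_zero_overlap_upper_tail_is_one(self):
        universe = [f"g{i}" for i in range(6)]
        res = hypergeometric_overlap(universe[:2], universe[4:], universe)
        assert res.n_overlap == 0
        assert res.p_value == pytest.approx(1.0)

    def test_stray_symbols_named(self):
        with pytest.raises(ValidationError, match="XX"):
            hypergeometric_overlap(["XX"], ["A"], ["A", "B"])


class TestBuildTargetList:
    def test_component_sizes_give_345(self):
        bound, differential = sd.make_target_components()
        tl = build_target_list(bound, differential)
        assert len(tl.activated) == 242
        assert len(tl.repressed) == 103
        assert len(tl) == 345

    def test_disjoint_components_empty(self):
        tl = build_target_list(["A", "B"], {"C": "up", "D": "down"})
        assert len(tl) == 0

    def test_partitions_always_disjoint(self):
        bound, differential = sd.make_target_components(20, 10, 5, 5)
        tl = build_target_list(bound, differential)
        assert len(tl.activated | tl.repressed) == len(tl)

    def test_bad_direction_rejected(self):
        with pytest.raises(ValidationError, match="direction"):
            build_target_list(["A"], {"A": "sideways"})

    def test_conflicting_partition_rejected(self):
        with pytest.raises(ValidationError, match="both"):
            TargetList(activated=frozenset({"A"}), repressed=frozenset({"A"}))


def tiny_matrix(values, labels=None):
    values = pd.DataFrame(
        values,
        index=[f"G{i}" for i in range(len(values))],
        columns=[f"S{i}" for i in range(len(values[0]))],
    )
    labels = labels or {c: "tumor" for c in values.columns}
    return ExpressionMatrix(values, labels)


class TestRankGenesByPhenotype:
    def test_self_correlation_ranks_first(self):
        rng = np.random.default_rng(0)
        profile = rng.normal(0, 1, 10)
        m = tiny_matrix([profile, rng.normal(0, 1, 10), rng.normal(0, 1, 10)])
        ranked = rank_genes_by_phenotype(m, profile)
        assert ranked.index[0] == "G0"
        assert ranked.iloc[0] == pytest.approx(1.0)

    def test_sign_flip_reverses_ranking(self):
        rng = np.random.default_rng(1)
        rows = [rng.normal(0, 1, 8) for _ in range(5)]
        m = tiny_matrix(rows)
        profile = rng.normal(0, 1, 8)
        fwd = rank_genes_by_phenotype(m, profile)
        rev = rank_genes_by_phenotype(m, -profile)
        assert list(fwd.index) == list(rev.index[::-1])
        np.testing.assert_allclose(fwd.to_numpy(), -rev.to_numpy()[::-1], atol=1e-12)

    def test_zero_variance_gene_scores_zero(self):
        rng = np.random.default_rng(2)
        m = tiny_matrix([np.full(6, 3.0), rng.normal(0, 1, 6)])
        ranked = rank_genes_by_phenotype(m, rng.normal(0, 1, 6))
        assert ranked.loc["G0"] == 0.0

    def test_class_labels_use_signal_to_noise(self):
        values = [[5, 5.1, 4.9, 1, 1.1, 0.9], [1, 2, 3, 1, 2, 3]]
        labels = {f"S{i}": ("tumor" if i < 3 else "normal") for i in range(6)}
        m = tiny_matrix(values, labels)
        ranked = rank_genes_by_phenotype(m, labels)
        a = np.array(values[0][:3])
        b = np.array(values[0][3:])
        expected = (a.mean() - b.mean()) / (a.std(ddof=1) + b.std(ddof=1))
        assert ranked.loc["G0"] == pytest.approx(expected)
        assert ranked.index[0] == "G0"

    def test_gene_name_phenotype(self, expression_dataset):
        matrix, truth = expression_dataset
        ranked = rank_genes_by_phenotype(matrix, truth.sox2_gene)
        assert ranked.index[0] == truth.sox2_gene
        top60 = set(ranked.index[:60])
        positives = set(truth.activated_targets)
        assert len(positives & top60) >= 0.9 * len(positives)


class TestEnrichmentScore:
    def _ranked(self, n):
        scores = np.linspace(1, -1, n)
        return pd.Series(scores, index=[f"G{i}" for i in range(n)])

    def test_top_gene_unweighted(self):
        curve = gsea_es(self._ranked(4), {"G0"}, weight=0.0)
        assert curve.es == pytest.approx(1.0)

    def test_bottom_gene_unweighted(self):
        curve = gsea_es(self._ranked(4), {"G3"}, weight=0.0)
        assert curve.es == pytest.approx(-1.0)

    def test_full_list_degenerate(self):
        curve = gsea_es(self._ranked(5), {f"G{i}" for i in range(5)})
        assert curve.es == pytest.approx(1.0)

    def test_no_overlap_rejected(self):
        with pytest.raises(ValidationError, match="no overlap"):
            gsea_es(self._ranked(4), {"NOPE"})

    def test_matches_brute_force_on_random_instances(self):
        """1000 random instances, N <= 50, random weights: full agreement
        with the explicit running-sum oracle."""
        rng = np.random.default_rng(3)
        for _ in range(1000):
            n = int(rng.integers(2, 51))
            k = int(rng.integers(1, n + 1))
            scores = np.sort(rng.normal(0, 1, n))[::-1]
            ranked = pd.Series(scores, index=[f"G{i}" for i in range(n)])
            members = rng.choice(n, k, replace=False)
            hit_mask = np.zeros(n, dtype=bool)
            hit_mask[members] = True
            weight = float(rng.choice([0.0, 1.0, 2.0]))
            es = gsea_es(ranked, {f"G{i}" for i in members}, weight).es
            assert es == pytest.approx(
                brute_force_es(scores, hit_mask, weight), abs=1e-10
            )
            # the vectorized hit-rank path agrees with the full walk
            # (sign may flip when max and |min| deviation tie to the ulp)
            fast = _es_from_hit_ranks(
                np.abs(scores) ** weight, np.sort(members)[None, :]
            )[0]
            assert abs(fast) == pytest.approx(abs(es), abs=1e-10)
            if abs(fast + es) > 1e-9:
                assert fast == pytest.approx(es, abs=1e-10)

    def test_es_bounded_and_reversal_negates(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            n = int(rng.integers(3, 40))
            k = int(rng.integers(1, n))
            scores = np.sort(rng.normal(0, 1, n))[::-1]
            ranked = pd.Series(scores, index=[f"G{i}" for i in range(n)])
            members = {f"G{i}" for i in rng.choice(n, k, replace=False)}
            es = gsea_es(ranked, members, weight=0.0).es
            assert -1.0 <= es <= 1.0
            reversed_ranked = pd.Series(
                -scores[::-1], index=list(ranked.index[::-1])
            )
            es_rev = gsea_es(reversed_ranked, members, weight=0.0).es
            if abs(es) != abs(es_rev):  # exact magnitude ties may flip sign
                assert es_rev == pytest.approx(-es, abs=1e-10)


class TestLeadingEdge:
    def test_single_top_gene(self):
        ranked = pd.Series([1.0, 0.5, -0.5], index=["A", "B", "C"])
        curve = gsea_es(ranked, {"A"})
        assert leading_edge(ranked, curve) == ["A"]

    def test_subset_of_set(self):
        rng = np.random.default_rng(5)
        scores = np.sort(rng.normal(0, 1, 30))[::-1]
        ranked = pd.Series(scores, index=[f"G{i}" for i in range(30)])
        members = {f"G{i}" for i in rng.choice(30, 8, replace=False)}
        curve = gsea_es(ranked, members)
        le = leading_edge(ranked, curve)
        assert set(le) <= members

    def test_captures_embedded_targets(self, expression_dataset):
        matrix, truth = expression_dataset
        ranked = rank_genes_by_phenotype(matrix, truth.sox2_gene)
        members = set(truth.activated_targets)
        curve = gsea_es(ranked, members)
        le = set(leading_edge(ranked, curve))
        assert len(le & members) >= 0.9 * len(members)


class TestGSEA:
    def test_embedded_module_is_enriched(self, expression_dataset):
        matrix, truth = expression_dataset
        module = GeneSet.from_iterable("MODULE", "", truth.module_genes)
        res = gsea(matrix, matrix.labels, module, n_perm=500, seed=11)
        assert res.es > 0
        assert res.nes > 0
        assert res.fdr_q < 0.05
        assert res.permutation_scheme == "phenotype"

    def test_same_seed_reproducible(self, expression_dataset):
        matrix, truth = expression_dataset
        module = GeneSet.from_iterable("MODULE", "", truth.module_genes)
        a = gsea(matrix, matrix.labels, module, n_perm=200, seed=7)
        b = gsea(matrix, matrix.labels, module, n_perm=200, seed=7)
        assert (a.es, a.nes, a.p_value, a.fdr_q) == (b.es, b.nes, b.p_value, b.fdr_q)

    def test_scheme_auto_switches_on_small_classes(self):
        rng = np.random.default_rng(6)
        values = rng.normal(8, 1, size=(50, 8))
        labels = {f"S{i}": ("tumor" if i < 4 else "normal") for i in range(8)}
        m = tiny_matrix(list(values), labels)
        s = GeneSet.from_iterable("S", "", [f"G{i}" for i in range(5)])
        res = gsea(m, labels, s, n_perm=100, seed=1)
        assert res.permutation_scheme == "gene_set"

    def test_continuous_phenotype_scheme(self, expression_dataset):
        matrix, truth = expression_dataset
        s = GeneSet.from_iterable("ACT", "", truth.activated_targets)
        res = gsea(matrix, truth.sox2_gene, s, n_perm=300, seed=2)
        assert res.permutation_scheme == "phenotype"
        assert res.nes > 0
        assert res.fdr_q < 0.05

    def test_low_permutation_count_warns(self, expression_dataset):
        matrix, truth = expression_dataset
        s = GeneSet.from_iterable("M", "", truth.module_genes)
        with pytest.warns(UserWarning, match="n_perm"):
            gsea(matrix, matrix.labels, s, n_perm=50, seed=1)


class TestCorrelatedTargets:
    def test_fixture_recovers_97(self):
        matrix, targets, truth = sd.make_correlated_expression_fixture()
        res = correlated_target_lists(matrix, "SOX2", targets)
        assert len(res.correlated_activated) == 71
        assert len(res.anticorrelated_repressed) == 26
        assert len(res) == truth["combined_size"] == 97
        assert set(res.correlated_activated) == set(truth["correlated_activated"])

    def test_empty_targets(self):
        matrix, _, _ = sd.make_correlated_expression_fixture(n_background=10)
        empty = TargetList(activated=frozenset(), repressed=frozenset())
        res = correlated_target_lists(matrix, "SOX2", empty)
        assert len(res) == 0

    def test_partition_matches_coefficient_signs(self, expression_dataset):
        matrix, truth = expression_dataset
        targets = TargetList(
            activated=frozenset(truth.activated_targets),
            repressed=frozenset(truth.repressed_targets),
        )
        res = correlated_target_lists(matrix, truth.sox2_gene, targets)
        assert set(res.correlated_activated) == set(truth.activated_targets)
        assert set(res.anticorrelated_repressed) == set(truth.repressed_targets)

    def test_missing_driver_gene(self):
        matrix, targets, _ = sd.make_correlated_expression_fixture(n_background=5)
        with pytest.raises(ValidationError, match="NOPE"):
            correlated_target_lists(matrix, "NOPE", targets)


class TestConsolidateSignatures:
    def test_fixture_consolidates_to_142(self):
        sox2_sig, lungs = sd.make_consolidation_fixture()
        res = consolidate_signatures(sox2_sig, lungs)
        assert len(res) == 142
        assert set(res.genes) <= sox2_sig.members

    def test_empty_driver_signature(self):
        from ampliconmap.expression_drivers import GeneSignature

        _, lungs = sd.make_consolidation_fixture()
        res = consolidate_signatures(GeneSignature(up=[], down=[]), lungs)
        assert len(res) == 0

    def test_requires_cohort_signature(self):
        sox2_sig, _ = sd.make_consolidation_fixture()
        with pytest.raises(ValidationError):
            consolidate_signatures(sox2_sig, [])

    def test_result_always_subset_of_driver_signature(self):
        sox2_sig, lungs = sd.make_consolidation_fixture(
            n_consolidated=30, n_sox2_total=100, n_sig1_only=10, n_sig2_only=10
        )
        res = consolidate_signatures(sox2_sig, lungs)
        assert set(res.genes) <= sox2_sig.members
        assert len(res) == 30
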