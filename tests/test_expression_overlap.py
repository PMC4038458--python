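"""Gene counting, the exact binomial DE test, and hypergeometric overlap."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from spliceratio.annotation_io import GeneModel
from spliceratio.expression_overlap import (
    de_test,
    detectable_universe,
    gene_counts,
    overlap_test,
    upregulated_set,
)
from spliceratio.synthetic_data import MUT_A, MUT_B, WT, SimConfig, make_truth, simulate_sample

from conftest import make_read, random_gene_models, random_reads
from oracles import (
    brute_gene_assignment,
    enum_binom_two_sided,
    enum_hypergeom_pmf_sum,
    enum_hypergeom_tail,
)


class TestGeneCounts:
    def test_contained_read_assigned(self, toy_genes):
        reads = {"S": [make_read("r1", [(10, 60)])]}
        counts, discarded = gene_counts(reads, toy_genes)
        assert counts.loc["gA", "S"] == 1
        assert discarded["S"] == {"unassigned": 0, "ambiguous": 0}

    def test_read_outside_every_span_discarded(self, toy_genes):
        reads = {"S": [make_read("r1", [(600, 700)])]}
        counts, discarded = gene_counts(reads, toy_genes)
        assert counts["S"].sum() == 0
        assert discarded["S"]["unassigned"] == 1

    def test_read_fitting_two_spans_is_ambiguous(self):
        genes = [
            GeneModel("g1", "chrI", "+", ((0, 500),)),
            GeneModel("g2", "chrI", "+", ((100, 400),)),
        ]
        reads = {"S": [make_read("r1", [(150, 350)])]}
        counts, discarded = gene_counts(reads, genes)
        assert counts["S"].sum() == 0
        assert discarded["S"]["ambiguous"] == 1

    def test_read_overhanging_span_not_assigned(self, toy_genes):
        reads = {"S": [make_read("r1", [(450, 520)])]}  # leaves gA's span
        counts, discarded = gene_counts(reads, toy_genes)
        assert counts["S"].sum() == 0

    def test_matches_bruteforce_on_simulated_reads(self):
        rng = np.random.default_rng(303)
        genes = random_gene_models(rng, 5)
        reads = random_reads(rng, genes, 500)
        counts, _ = gene_counts({"S": reads}, genes)
        brute = brute_gene_assignment(reads, genes)
        assert counts["S"].to_dict() == brute


class TestDeTest:
    @staticmethod
    def _frame(rows: dict[str, tuple[int, int]]) -> pd.DataFrame:
        return pd.DataFrame(
            {"WT": {g: v[0] for g, v in rows.items()},
             "M": {g: v[1] for g, v in rows.items()}}
        )

    def test_symmetric_null_p_one(self):
        """k1 = k2 with equal libraries is the modal outcome: p = 1."""
        counts = self._frame({"g1": (25, 25)})
        (res,) = de_test(counts, {"WT": 10000, "M": 10000}, "WT", "M")
        assert res.p_value == pytest.approx(1.0)
        assert not res.up_flag

    def test_extreme_asymmetry_closed_form(self):
        """k1=0, k2=10, equal libraries: p = 2 * (1/2)^10."""
        counts = self._frame({"g1": (0, 10)})
        (res,) = de_test(counts, {"WT": 10000, "M": 10000}, "WT", "M")
        assert res.p_value == pytest.approx(2 * 0.5**10)
        assert res.up_flag

    def test_zero_total_gene_p_one(self):
        counts = self._frame({"g1": (0, 0)})
        (res,) = de_test(counts, {"WT": 10000, "M": 10000}, "WT", "M")
        assert res.p_value == 1.0 and not res.up_flag

    def test_negative_count_rejected(self):
        counts = self._frame({"g1": (-1, 3)})
        with pytest.raises(ValueError, match="negative"):
            de_test(counts, {"WT": 100, "M": 100}, "WT", "M")

    def test_matches_enumeration_oracle(self):
        """p-values equal full outcome enumeration for all n = k1+k2 <= 50,
        including unequal library sizes."""
        rng = np.random.default_rng(11)
        rows = {}
        for i in range(60):
            n = int(rng.integers(1, 51))
            k2 = int(rng.integers(0, n + 1))
            rows[f"g{i:02d}"] = (n - k2, k2)
        sizes = {"WT": 40000, "M": 60000}
        results = de_test(self._frame(rows), sizes, "WT", "M")
        p_null = sizes["M"] / (sizes["WT"] + sizes["M"])
        for res in results:
            n = res.baseline_count + res.test_count
            expected = enum_binom_two_sided(res.test_count, n, p_null)
            assert res.p_value == pytest.approx(expected, rel=1e-9)

    def test_null_p_values_super_uniform(self):
        """Type-I control: on simulated null data, P(p < 0.05) <= 0.05+3SE."""
        rng = np.random.default_rng(12)
        n_genes, mean = 400, 50
        k1 = rng.poisson(mean, n_genes)
        k2 = rng.poisson(mean, n_genes)
        counts = pd.DataFrame({"WT": k1, "M": k2}, index=[f"g{i}" for i in range(n_genes)])
        results = de_test(counts, {"WT": 100000, "M": 100000}, "WT", "M")
        rate = np.mean([r.p_value < 0.05 for r in results])
        assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_genes)


class TestUpregulatedSet:
    def test_alpha_zero_empty(self):
        counts = pd.DataFrame({"WT": {"g1": 0}, "M": {"g1": 30}})
        results = de_test(counts, {"WT": 1000, "M": 1000}, "WT", "M")
        assert upregulated_set(results, alpha=0.0) == set()
        assert upregulated_set(results, alpha=0.05) == {"g1"}

    def test_direction_matters(self):
        counts = pd.DataFrame({"WT": {"gup": 2, "gdown": 40}, "M": {"gup": 40, "gdown": 2}})
        results = de_test(counts, {"WT": 1000, "M": 1000}, "WT", "M")
        assert upregulated_set(results) == {"gup"}


class TestOverlapTest:
    def test_identical_sets_full_intersection(self):
        genes = {f"g{i}" for i in range(6)}
        res = overlap_test(genes, genes, 20)
        assert res.intersection == 6

    def test_zero_intersection_p_one_when_feasible(self):
        res = overlap_test({"a", "b"}, {"c", "d"}, 20)
        assert res.intersection == 0
        assert res.p_value == pytest.approx(1.0)

    def test_set_larger_than_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            overlap_test({f"g{i}" for i in range(5)}, set(), 4)

    def test_matches_enumeration_for_small_universes(self):
        """Tail P(X >= k) equals exhaustive enumeration for N <= 20."""
        rng = np.random.default_rng(21)
        for _ in range(40):
            universe = int(rng.integers(4, 21))
            ids = [f"g{i}" for i in range(universe)]
            a = set(rng.choice(ids, size=int(rng.integers(1, universe + 1)), replace=False))
            b = set(rng.choice(ids, size=int(rng.integers(1, universe + 1)), replace=False))
            res = overlap_test(a, b, universe)
            expected = enum_hypergeom_tail(res.intersection, universe, len(a), len(b))
            assert res.p_value == pytest.approx(expected, rel=1e-9)

    def test_pmf_sums_to_one_small_universes(self):
        for universe, a, b in [(5, 2, 3), (12, 6, 7), (20, 9, 15)]:
            assert enum_hypergeom_pmf_sum(universe, a, b) == pytest.approx(1.0)


class TestTruthRecovery:
    def test_shared_up_genes_populate_intersection(self):
        """Genes up in both mutants land in the intersection; genes up in
        exactly one do not, at adequate depth."""
        config = SimConfig(
            n_genes=60, depth=100000, seed=77, fold_change=4.0,
            frac_up_a=0.15, frac_up_b=0.15, frac_up_shared=0.05,
            frac_misspliced_a=0.0, frac_misspliced_b=0.0,
        )
        truth = make_truth(config)
        alignments = {
            cond: simulate_sample(truth, cond, 1000 + i)
            for i, cond in enumerate(truth.conditions)
        }
        counts, _ = gene_counts(alignments, list(truth.genes))
        sizes = {s: len(a) for s, a in alignments.items()}
        up = {}
        for cond in (MUT_A, MUT_B):
            results = de_test(counts, sizes, WT, cond)
            up[cond] = upregulated_set(results)
        shared_truth = truth.upregulated[MUT_A] & truth.upregulated[MUT_B]
        only_one_truth = truth.upregulated[MUT_A] ^ truth.upregulated[MUT_B]
        intersection = up[MUT_A] & up[MUT_B]
        assert shared_truth <= intersection
        assert not (only_one_truth & intersection)
        universe = detectable_universe(counts)
        res = overlap_test(up[MUT_A], up[MUT_B], len(universe))
        assert res.intersection == len(intersection)
        assert 0.0 < res.p_value <= 1.0
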