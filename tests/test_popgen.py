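"""Diversity, HWE, differentiation estimators, and the hierarchical AMOVA."""

import warnings

import numpy as np
import pandas as pd
import pytest

import seaflow as sf
from seaflow.genotypes import GenotypeTable
from conftest import build_genotypes

from _oracles import amova_balanced_longhand, pair_metrics_longhand


class TestDiversity:
    def test_all_heterozygotes_single_locus(self):
        n = 10
        arr = np.tile(np.array([[1, 2]], dtype=np.int32), (n, 1)).reshape(n, 1, 2)
        gt = build_genotypes({"A": arr})
        div = sf.diversity(gt)
        assert div.loc["A", "Ho"] == 1.0
        assert div.loc["A", "He"] == pytest.approx((2 * n / (2 * n - 1)) * 0.5)

    def test_rarefied_richness_combinatorial_case(self):
        # allele counts {A: 5, B: 5}, rarefied to g = 2 genes
        arr = np.array([[1, 1], [1, 1], [2, 2], [2, 2], [1, 2]],
                       dtype=np.int32).reshape(5, 1, 2)
        gt = build_genotypes({"A": arr})
        ar = sf.diversity(gt, rarefaction_n=1).loc["A", "AR"]
        assert ar == pytest.approx(2 * (1 - 10 / 45))

    def test_monomorphic_population(self):
        arr = np.full((8, 2, 2), 7, dtype=np.int32)
        gt = build_genotypes({"A": arr})
        div = sf.diversity(gt)
        assert div.loc["A", "Ho"] == 0.0 and div.loc["A", "He"] == 0.0
        assert div.loc["A", "AR"] == 1.0


class TestHWE:
    def test_heterozygote_excess_detected(self):
        arr = np.tile(np.array([[1, 2]], dtype=np.int32), (20, 1)).reshape(20, 1, 2)
        gt = build_genotypes({"A": arr})
        assert sf.hwe_test(gt, "A", "L1", n_perm=999, seed=1) < 0.05

    def test_equilibrium_counts_not_rejected(self):
        arr = np.concatenate([
            np.full((25, 1, 2), 1, dtype=np.int32),
            np.tile(np.array([[1, 2]], dtype=np.int32), (50, 1)).reshape(50, 1, 2),
            np.full((25, 1, 2), 2, dtype=np.int32),
        ])
        gt = build_genotypes({"A": arr})
        assert sf.hwe_test(gt, "A", "L1", n_perm=999, seed=1) > 0.5

    def test_monomorphic_is_one_by_convention(self):
        gt = build_genotypes({"A": np.full((10, 1, 2), 3, dtype=np.int32)})
        assert sf.hwe_test(gt, "A", "L1", n_perm=99) == 1.0

    def test_too_few_individuals_rejected(self):
        gt = build_genotypes({"A": np.full((4, 1, 2), 3, dtype=np.int32)})
        with pytest.raises(ValueError, match=">= 5"):
            sf.hwe_test(gt, "A", "L1")


class TestPairwiseDifferentiation:
    def test_complete_fixation_gives_one_for_every_metric(self):
        gt = build_genotypes({"A": np.full((100, 1, 2), 20, dtype=np.int32),
                              "B": np.full((120, 1, 2), 30, dtype=np.int32)})
        d = sf.pair_differentiation(gt, "A", "B")
        for metric in ("GST", "GpST", "JostD", "RST"):
            assert d[metric] == pytest.approx(1.0)

    def test_no_differentiation_is_near_zero_on_average(self):
        """Two samples from one panmictic pool: mean estimate ~ 0 over replicates."""
        means = {m: [] for m in ("GST", "JostD", "RST")}
        for rep in range(50):
            rng = np.random.default_rng(rep)
            pool = rng.integers(10, 16, size=(60, 4, 2)).astype(np.int32)
            gt = build_genotypes({"A": pool[:30], "B": pool[30:]})
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # near-zero D triggers the fallback note
                d = sf.pair_differentiation(gt, "A", "B")
            for m in means:
                means[m].append(d[m])
        for m, vals in means.items():
            vals = np.asarray(vals)
            se = vals.std(ddof=1) / np.sqrt(len(vals))
            assert abs(vals.mean()) < 2 * se + 1e-3, m

    def test_matches_longhand_oracle_exactly(self, two_pop_random):
        d = sf.pair_differentiation(two_pop_random, "A", "B")
        idx = two_pop_random.population_indices()
        geno = {p: [[tuple(two_pop_random.alleles[i, j]) for j in range(3)]
                    for i in idx[p]] for p in ("A", "B")}
        oracle = pair_metrics_longhand(geno["A"], geno["B"])
        for m in ("GST", "GpST", "JostD", "RST"):
            assert d[m] == pytest.approx(oracle[m], abs=1e-12), m

    def test_relabeling_alleles_preserves_frequency_metrics_not_rst(self):
        rng = np.random.default_rng(7)
        a = rng.integers(10, 14, size=(20, 2, 2)).astype(np.int32)
        b = rng.integers(11, 15, size=(20, 2, 2)).astype(np.int32)
        gt = build_genotypes({"A": a, "B": b})
        # spread the allele sizes apart: frequencies unchanged, variances not
        remap = {10: 10, 11: 30, 12: 60, 13: 100, 14: 150}
        gt2 = build_genotypes({"A": np.vectorize(remap.get)(a).astype(np.int32),
                               "B": np.vectorize(remap.get)(b).astype(np.int32)})
        d1, d2 = (sf.pair_differentiation(g, "A", "B") for g in (gt, gt2))
        for m in ("GST", "GpST", "JostD"):
            assert d1[m] == pytest.approx(d2[m], abs=1e-12)
        assert d1["RST"] != pytest.approx(d2["RST"], abs=1e-6)

    def test_pairwise_matrix_symmetric_zero_diagonal(self, two_pop_random):
        dm = sf.pairwise_diff(two_pop_random, "GST")
        v = dm.values.values
        assert np.allclose(v, v.T) and np.allclose(np.diag(v), 0)


class TestLinearize:
    def test_elementwise_transform(self):
        df = pd.DataFrame([[0.0, 0.5], [0.5, 0.0]], index=["A", "B"], columns=["A", "B"])
        lin = sf.linearize(sf.DiffMatrix(df, metric="GST"))
        assert lin.values.loc["A", "B"] == 1.0 and lin.linearized

    @pytest.mark.parametrize("x,expected", [(0.0, 0.0), (0.9, 9.0)])
    def test_known_values(self, x, expected):
        df = pd.DataFrame([[0.0, x], [x, 0.0]], index=["A", "B"], columns=["A", "B"])
        lin = sf.linearize(sf.DiffMatrix(df, metric="JostD"))
        assert lin.values.loc["A", "B"] == pytest.approx(expected)

    def test_value_one_warns_and_gives_inf(self):
        df = pd.DataFrame([[0.0, 1.0], [1.0, 0.0]], index=["A", "B"], columns=["A", "B"])
        with pytest.warns(UserWarning, match="A, B"):
            lin = sf.linearize(sf.DiffMatrix(df, metric="GST"))
        assert np.isinf(lin.values.loc["A", "B"])


class TestAMOVA:
    def test_identical_homozygotes_reported_degenerate(self):
        gt = build_genotypes({"A": np.full((10, 2, 2), 5, dtype=np.int32),
                              "B": np.full((10, 2, 2), 5, dtype=np.int32)})
        res = sf.amova(gt, n_perm=0)
        assert res.degenerate and res.table["percent"].isna().all()

    def test_region_fixation_loads_top_level(self):
        gt = build_genotypes({"A": np.full((10, 1, 2), 5, dtype=np.int32),
                              "B": np.full((10, 1, 2), 9, dtype=np.int32)})
        res = sf.amova(gt, region_of={"A": "R1", "B": "R2"}, n_perm=0)
        assert res.table.loc["among_regions", "percent"] == pytest.approx(100.0)
        assert res.table.loc["within_individuals", "sigma"] == pytest.approx(0.0)

    def test_balanced_toy_matches_longhand_oracle(self):
        """2 regions x 2 pops x 2 locations x 3 individuals, 1 locus."""
        rng = np.random.default_rng(12)
        rows, alle = [], []
        region_of = {}
        k = 0
        for r in range(2):
            for p in range(2):
                pop = f"R{r}P{p}"
                region_of[pop] = f"R{r}"
                for l in range(2):
                    for i in range(3):
                        rows.append({"id": f"i{k}", "site": f"{pop}L{l}", "population": pop})
                        k += 1
        alle = rng.integers(1, 5, size=(k, 1, 2)).astype(np.int32)
        gt = GenotypeTable(pd.DataFrame(rows), ["L1"], alle)
        res = sf.amova(gt, region_of=region_of, n_perm=0)

        ind = gt.individuals
        pops = sorted(ind["population"].unique())
        sig_oracle = amova_balanced_longhand(
            alle[:, 0, :],
            ind["population"].map(region_of).tolist(),
            ind["population"].tolist(),
            ind["site"].tolist())
        assert np.allclose(res.table["sigma"].to_numpy(), sig_oracle, atol=1e-10)
        assert res.table["percent"].sum() == pytest.approx(100.0, abs=1e-6)

    def test_percent_sums_to_100_with_missing_data(self):
        rng = np.random.default_rng(3)
        arr = rng.integers(4, 9, size=(24, 3, 2)).astype(np.int32)
        arr[rng.random(arr.shape[:2]) < 0.1] = -1
        gt = build_genotypes({"A": arr[:12], "B": arr[12:]},
                             sites={"A": "sA", "B": "sB"})
        res = sf.amova(gt, region_of={"A": "R1", "B": "R1"}, n_perm=0)
        assert res.table["percent"].sum() == pytest.approx(100.0, abs=1e-6)

    def test_structured_data_gives_small_p(self):
        rng = np.random.default_rng(4)
        a = rng.integers(4, 7, size=(15, 3, 2)).astype(np.int32)
        b = rng.integers(8, 11, size=(15, 3, 2)).astype(np.int32)
        gt = build_genotypes({"A": a, "B": b})
        res = sf.amova(gt, n_perm=99, seed=2)
        assert res.table.loc["among_populations_within_region", "p_value"] <= 0.05

    def test_null_pvalues_approximately_uniform(self):
        """Permutation p for the population level is ~U(0,1) under panmixia."""
        from scipy.stats import kstest
        pvals = []
        for rep in range(60):
            rng = np.random.default_rng(200 + rep)
            arr = rng.integers(4, 10, size=(24, 2, 2)).astype(np.int32)
            gt = build_genotypes({p: arr[6 * i:6 * (i + 1)] for i, p in
                                  enumerate(["A", "B", "C", "D"])})
            res = sf.amova(gt, n_perm=39, seed=rep)
            pvals.append(res.table.loc["among_populations_within_region", "p_value"])
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_allele_size_distance_option(self):
        gt = build_genotypes({"A": np.full((8, 1, 2), 10, dtype=np.int32),
                              "B": np.full((8, 1, 2), 20, dtype=np.int32)})
        res = sf.amova(gt, n_perm=0, distance="allele_size")
        assert res.table.loc["among_populations_within_region", "percent"] == \
            pytest.approx(100.0)
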