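"""Mantel tests (symmetric and directional), pair frames, asymmetry flags."""

import numpy as np
import pandas as pd
import pytest

import seaflow as sf
from seaflow.flowstats import MigrationMatrix

from _oracles import asym_mantel_exact_p, mantel_exact_p, partial_corr_longhand


def sym(rng, n):
    a = rng.random((n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 0)
    return a


def asym(rng, n):
    a = rng.random((n, n))
    np.fill_diagonal(a, 0)
    return a


class TestMantel:
    def test_identical_matrices_perfect_correlation(self):
        rng = np.random.default_rng(0)
        x = sym(rng, 8)
        res = sf.mantel(x, x.copy(), n_perm=99, n_boot=0, seed=1)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 100)

    def test_matches_skbio_oracle(self):
        from skbio.stats.distance import mantel as skbio_mantel
        rng = np.random.default_rng(3)
        x, y = sym(rng, 9), sym(rng, 9)
        r_ref, p_ref, _ = skbio_mantel(x, y, permutations=999, alternative="greater")
        res = sf.mantel(x, y, n_perm=999, n_boot=0, seed=0)
        assert res.r == pytest.approx(r_ref, abs=1e-12)
        assert res.p == pytest.approx(p_ref, abs=0.05)

    def test_p_matches_exhaustive_enumeration_4x4(self):
        rng = np.random.default_rng(5)
        x, y = sym(rng, 4), sym(rng, 4)
        exact = mantel_exact_p(x, y)
        res = sf.mantel(x, y, n_perm=9999, n_boot=0, seed=2)
        se = np.sqrt(exact * (1 - exact) / 9999)
        assert abs(res.p - exact) < 4 * se + 2e-4

    def test_constant_matrix_rejected(self):
        x = np.zeros((5, 5))
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="constant"):
            sf.mantel(x, sym(rng, 5), n_perm=9)

    def test_bootstrap_ci_brackets_r(self):
        rng = np.random.default_rng(8)
        x = sym(rng, 10)
        y = 2 * x + 0.05 * sym(rng, 10)
        res = sf.mantel(x, y, n_perm=99, n_boot=500, seed=3)
        assert res.ci_low <= res.r <= res.ci_high


class TestPartialMantel:
    def test_constant_confounder_reduces_to_simple(self):
        rng = np.random.default_rng(1)
        x, y = sym(rng, 7), sym(rng, 7)
        z = np.ones((7, 7)) - np.eye(7)
        simple = sf.mantel(x, y, n_perm=49, n_boot=0, seed=4)
        partial = sf.partial_mantel(x, y, z, n_perm=49, n_boot=0, seed=4)
        assert partial.r == pytest.approx(simple.r, abs=1e-12)

    def test_fully_explained_matrix_gives_zero(self):
        rng = np.random.default_rng(2)
        x, y = sym(rng, 7), sym(rng, 7)
        res = sf.partial_mantel(x, y, y, n_perm=49, seed=0)
        assert res.r == 0.0 and res.p == 1.0

    def test_matches_residual_correlation_oracle(self):
        rng = np.random.default_rng(6)
        x, y, z = sym(rng, 5), sym(rng, 5), sym(rng, 5)
        il = np.tril_indices(5, k=-1)
        oracle = partial_corr_longhand(x[il], y[il], z[il])
        res = sf.partial_mantel(x, y, z, n_perm=9, n_boot=0, seed=0)
        assert res.r == pytest.approx(oracle, abs=1e-12)


class TestAsymMantel:
    def test_symmetric_input_reproduces_mantel_r_exactly(self):
        rng = np.random.default_rng(4)
        x, y = sym(rng, 7), sym(rng, 7)
        assert sf.asym_mantel(x, y, n_perm=9, seed=0).r == \
            sf.mantel(x, y, n_perm=9, n_boot=0, seed=0).r

    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(5)
        x = asym(rng, 6)
        assert sf.asym_mantel(x, x.copy(), n_perm=9, seed=0).r == pytest.approx(1.0)

    def test_p_matches_exhaustive_vector_enumeration_3x3(self):
        rng = np.random.default_rng(9)
        x, y = asym(rng, 3), asym(rng, 3)  # 6 entries -> 720 permutations
        exact = asym_mantel_exact_p(x, y)
        res = sf.asym_mantel(x, y, n_perm=9999, seed=1)
        se = np.sqrt(exact * (1 - exact) / 9999)
        assert abs(res.p - exact) < 4 * se + 2e-4

    def test_partial_variant_residualizes_on_z(self):
        rng = np.random.default_rng(11)
        x, y, z = asym(rng, 5), asym(rng, 5), asym(rng, 5)
        off = ~np.eye(5, dtype=bool)
        oracle = partial_corr_longhand(x[off], y[off], z[off])
        res = sf.asym_mantel(x, y, n_perm=9, seed=0, partial_z=z)
        assert res.r == pytest.approx(oracle, abs=1e-12)

    def test_dimension_mismatch_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="conformable"):
            sf.asym_mantel(asym(rng, 4), asym(rng, 5), n_perm=9)


class TestPairFrame:
    def _mats(self, n=5):
        rng = np.random.default_rng(0)
        labels = [f"P{i}" for i in range(n)]
        resp = pd.DataFrame(sym(rng, n), index=labels, columns=labels)
        pred = pd.DataFrame(sym(rng, n), index=labels, columns=labels)
        return resp, pred

    def test_symmetric_mode_row_count(self):
        resp, pred = self._mats(5)
        frame = sf.make_pair_frame(resp, {"d": pred})
        assert len(frame) == 10
        assert not (frame["pop_i"] == frame["pop_j"]).any()

    def test_asymmetric_mode_row_count(self):
        resp, pred = self._mats(5)
        frame = sf.make_pair_frame(resp, {"d": pred}, mode="asymmetric")
        assert len(frame) == 20

    def test_scaling_recorded_and_applied(self):
        resp, pred = self._mats(6)
        frame = sf.make_pair_frame(resp, {"d": pred}, scale=True)
        assert frame["d"].mean() == pytest.approx(0.0, abs=1e-12)
        assert frame["d"].std(ddof=0) == pytest.approx(1.0)
        assert "d" in frame.attrs["scaling"]

    def test_label_mismatch_rejected(self):
        resp, _ = self._mats(5)
        other = pd.DataFrame(np.zeros((4, 4)), index=list("abcd"), columns=list("abcd"))
        with pytest.raises(ValueError, match="labels"):
            sf.make_pair_frame(resp, {"d": other})


class TestTransforms:
    def test_log10_distance_off_diagonal(self):
        df = pd.DataFrame([[0.0, 100.0], [100.0, 0.0]], index=["A", "B"], columns=["A", "B"])
        out = sf.transform_distance(df)
        assert out.loc["A", "B"] == pytest.approx(2.0)
        assert out.loc["A", "A"] == 0.0

    def test_fourth_root(self):
        df = pd.DataFrame([[0.0, 0.0016], [0.0001, 0.0]], index=["A", "B"], columns=["A", "B"])
        out = sf.fourth_root(df)
        assert out.loc["A", "B"] == pytest.approx(0.2)
        assert out.loc["B", "A"] == pytest.approx(0.1)


class TestAsymmetryFlag:
    def _mm(self, m12, s12, m21, s21):
        labels = ["P1", "P2"]
        r = pd.DataFrame([[0.8, m12], [m21, 0.8]], index=labels, columns=labels)
        s = pd.DataFrame([[0.0, s12], [s21, 0.0]], index=labels, columns=labels)
        return MigrationMatrix(r, s)

    def test_separated_intervals_flagged(self):
        flagged = sf.flag_asymmetric_pairs(self._mm(0.10, 0.01, 0.02, 0.005))
        assert flagged == [("P1", "P2")]

    def test_overlapping_intervals_not_flagged(self):
        assert sf.flag_asymmetric_pairs(self._mm(0.10, 0.01, 0.09, 0.01)) == []

    def test_interval_including_zero_not_flagged(self):
        assert sf.flag_asymmetric_pairs(self._mm(0.10, 0.01, 0.01, 0.02)) == []

    def test_missing_sds_rejected(self):
        labels = ["P1", "P2"]
        mm = MigrationMatrix(pd.DataFrame([[0.9, 0.1], [0.1, 0.9]],
                                          index=labels, columns=labels))
        with pytest.raises(ValueError, match="standard deviations"):
            sf.flag_asymmetric_pairs(mm)


class TestMigrationIO:
    def test_row_sum_validation(self):
        labels = ["A", "B"]
        bad = pd.DataFrame([[0.8, 0.4], [0.1, 0.9]], index=labels, columns=labels)
        with pytest.raises(ValueError, match="row sums"):
            MigrationMatrix(bad)

    def test_bayesass_text_parser(self, tmp_path):
        text = """populations: UK LK EG
m[1][1]: 0.90(0.010) m[1][2]: 0.06(0.005) m[1][3]: 0.04(0.004)
m[2][1]: 0.02(0.003) m[2][2]: 0.95(0.012) m[2][3]: 0.03(0.002)
m[3][1]: 0.01(0.001) m[3][2]: 0.01(0.002) m[3][3]: 0.98(0.011)
"""
        path = tmp_path / "bayesass.txt"
        path.write_text(text)
        mm = MigrationMatrix.from_bayesass_text(path)
        assert mm.labels == ["UK", "LK", "EG"]
        assert mm.rates.loc["UK", "LK"] == pytest.approx(0.06)
        assert mm.sds.loc["EG", "UK"] == pytest.approx(0.001)
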