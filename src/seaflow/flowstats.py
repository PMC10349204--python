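"""Matrix correlation tests relating gene flow to seascape predictors.

Symmetric Mantel and partial Mantel tests (lower-triangle vectors, null by
jointly permuting rows and columns of one matrix) plus the asymmetric
variants for directional matrices: the full off-diagonal vector is
correlated and the null is built by permuting the *entries of one vector*,
not rows/columns — directional migration and connectivity matrices are not
exchangeable row/column-wise.  On symmetric inputs the asymmetric statistic
equals the symmetric Mantel r exactly (every unordered pair simply appears
twice).  Also here: pair-frame assembly with the standard normality
transforms, and the directional-migration asymmetry flag.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .matrices import DirectionalMatrix


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    ci_low: float = np.nan
    ci_high: float = np.nan
    alternative: str = "greater"

    def as_dict(self) -> dict:
        return {"r": self.r, "p": self.p, "n_perm": self.n_perm,
                "ci_low": self.ci_low, "ci_high": self.ci_high,
                "alternative": self.alternative}


def _square(x) -> np.ndarray:
    a = x.values.values if isinstance(x, DirectionalMatrix) else np.asarray(
        getattr(x, "values", x), dtype=float)
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("expected a square matrix")
    return a


def _check_symmetric(a, name):
    if not np.allclose(a, a.T):
        raise ValueError(f"{name} must be symmetric for the symmetric Mantel test")


def _lower(a) -> np.ndarray:
    return a[np.tril_indices(a.shape[0], k=-1)]


def _offdiag(a) -> np.ndarray:
    return a[~np.eye(a.shape[0], dtype=bool)]


def _pearson(x, y) -> float:
    xs, ys = x - x.mean(), y - y.mean()
    denom = np.sqrt((xs**2).sum() * (ys**2).sum())
    if denom == 0:
        raise ValueError("correlation undefined: a vector is constant")
    return float((xs * ys).sum() / denom)


def _tail_p(r_obs, r_perm, alternative, n_perm):
    r_perm = np.asarray(r_perm)
    if alternative == "greater":
        hits = int((r_perm >= r_obs - 1e-12).sum())
    elif alternative == "less":
        hits = int((r_perm <= r_obs + 1e-12).sum())
    elif alternative == "two-sided":
        hits = int((np.abs(r_perm) >= abs(r_obs) - 1e-12).sum())
    else:
        raise ValueError("alternative must be 'greater', 'less' or 'two-sided'")
    return (hits + 1) / (n_perm + 1)


def _boot_ci(vec_x, vec_y, n_boot, rng, resid_fn=None):
    """Percentile bootstrap CI for r, resampling pair indices with replacement."""
    if n_boot <= 0:
        return np.nan, np.nan
    m = vec_x.size
    rs = []
    for _ in range(n_boot):
        idx = rng.integers(0, m, size=m)
        try:
            if resid_fn is None:
                rs.append(_pearson(vec_x[idx], vec_y[idx]))
            else:
                rs.append(resid_fn(idx))
        except ValueError:  # degenerate resample
            continue
    if not rs:
        return np.nan, np.nan
    lo, hi = np.percentile(rs, [2.5, 97.5])
    return float(lo), float(hi)


def _residuals(v, z):
    X = np.column_stack([np.ones_like(z), z])
    beta, *_ = np.linalg.lstsq(X, v, rcond=None)
    return v - X @ beta


def _degenerate(resid, orig) -> bool:
    """Residual vector numerically zero: the confounder explains it fully."""
    return float(np.linalg.norm(resid)) < 1e-10 * max(1.0, float(np.linalg.norm(orig)))


def mantel(x, y, n_perm: int = 9999, n_boot: int = 1000, seed: int = 0,
           alternative: str = "greater") -> MantelResult:
    """Mantel test between two symmetric zero-diagonal matrices.

    r is the Pearson correlation of the lower-triangle vectors; the null
    jointly permutes rows and columns of ``y``.  ``alternative`` sets the
    one-sided direction of the hypothesis (positive for a distance effect,
    negative — use ``"less"`` — for a connectivity effect).  The 95% CI is a
    percentile bootstrap over pair indices.
    """
    a, b = _square(x), _square(y)
    if a.shape != b.shape:
        raise ValueError("matrices must be conformable")
    _check_symmetric(a, "x")
    _check_symmetric(b, "y")
    vx, vy = _lower(a), _lower(b)
    r_obs = _pearson(vx, vy)
    rng = np.random.default_rng(seed)
    n = a.shape[0]
    r_perm = []
    for _ in range(n_perm):
        p = rng.permutation(n)
        r_perm.append(_pearson(vx, _lower(b[np.ix_(p, p)])))
    pval = _tail_p(r_obs, r_perm, alternative, n_perm)
    lo, hi = _boot_ci(vx, vy, n_boot, rng)
    return MantelResult(r_obs, pval, n_perm, lo, hi, alternative)


def partial_mantel(x, y, z, n_perm: int = 9999, n_boot: int = 1000, seed: int = 0,
                   alternative: str = "greater") -> MantelResult:
    """Partial Mantel: correlation of x and y residuals after regressing on z.

    The null permutes rows/columns of ``x`` and recomputes the residual
    correlation (raw-matrix permutation, as in the standard method).
    """
    a, b, c = _square(x), _square(y), _square(z)
    for m, nm in ((a, "x"), (b, "y"), (c, "z")):
        _check_symmetric(m, nm)
    vz = _lower(c)
    if np.ptp(vz) == 0:  # constant confounder: reduces to the simple test
        ry = _lower(b)
        rx_full = _lower(a)
    else:
        rx_full = _residuals(_lower(a), vz)
        ry = _residuals(_lower(b), vz)
    if _degenerate(rx_full, _lower(a)) or _degenerate(ry, _lower(b)):
        # a matrix is fully explained by the confounder: no partial association
        return MantelResult(0.0, 1.0, n_perm, 0.0, 0.0, alternative)
    r_obs = _pearson(rx_full, ry)
    rng = np.random.default_rng(seed)
    n = a.shape[0]
    r_perm = []
    for _ in range(n_perm):
        p = rng.permutation(n)
        vxp = _lower(a[np.ix_(p, p)])
        rxp = vxp if np.ptp(vz) == 0 else _residuals(vxp, vz)
        r_perm.append(_pearson(rxp, ry))
    pval = _tail_p(r_obs, r_perm, alternative, n_perm)

    vx0 = _lower(a)

    def resid_r(idx):
        if np.ptp(vz[idx]) == 0:
            return _pearson(vx0[idx], _lower(b)[idx])
        return _pearson(_residuals(vx0[idx], vz[idx]), _residuals(_lower(b)[idx], vz[idx]))

    lo, hi = _boot_ci(vx0, _lower(b), n_boot, rng, resid_fn=resid_r)
    return MantelResult(r_obs, pval, n_perm, lo, hi, alternative)


def asym_mantel(x, y, n_perm: int = 9999, seed: int = 0, partial_z=None,
                alternative: str = "greater", n_boot: int = 1000) -> MantelResult:
    """Mantel-style test for directional (not necessarily symmetric) matrices.

    Both matrices are flattened to their n(n-1) off-diagonal entries in a
    fixed row-major order (diagonals excluded) and correlated; the null
    distribution permutes the entries of the x vector freely — this breaks
    row/column exchangeability on purpose and is the test's defining choice.
    With ``partial_z``, both vectors are first residualized on z's vector.
    On symmetric inputs r equals the symmetric Mantel r exactly.
    """
    a, b = _square(x), _square(y)
    if a.shape != b.shape:
        raise ValueError("matrices must be conformable")
    vx, vy = _offdiag(a), _offdiag(b)
    if partial_z is not None:
        vz = _offdiag(_square(partial_z))
        if np.ptp(vz) > 0:
            vx_r, vy_r = _residuals(vx, vz), _residuals(vy, vz)
            if _degenerate(vx_r, vx) or _degenerate(vy_r, vy):
                return MantelResult(0.0, 1.0, n_perm, 0.0, 0.0, alternative)
        else:
            vx_r, vy_r = vx, vy
    else:
        vx_r, vy_r = vx, vy
    if partial_z is None and np.allclose(a, a.T) and np.allclose(b, b.T):
        # symmetric inputs: every unordered pair appears twice in the vectors,
        # so r equals the symmetric Mantel r; computing it from the lower
        # triangle makes the agreement exact to the last bit
        r_obs = _pearson(_lower(a), _lower(b))
    else:
        r_obs = _pearson(vx_r, vy_r)
    rng = np.random.default_rng(seed)
    r_perm = []
    for _ in range(n_perm):
        vxp = vx[rng.permutation(vx.size)]
        if partial_z is not None and np.ptp(vz) > 0:
            vxp = _residuals(vxp, vz)
        r_perm.append(_pearson(vxp, vy_r))
    pval = _tail_p(r_obs, r_perm, alternative, n_perm)
    lo, hi = _boot_ci(vx_r, vy_r, n_boot, rng)
    return MantelResult(r_obs, pval, n_perm, lo, hi, alternative)


# ---------------------------------------------------------------------------
# Pair frames
# ---------------------------------------------------------------------------

def make_pair_frame(response, predictors: dict, mode: str = "symmetric",
                    scale: bool = True) -> pd.DataFrame:
    """Flatten matrices into a tidy population-pair table for regression.

    ``response`` and each predictor is a labeled square matrix (DataFrame,
    DirectionalMatrix, DiffMatrix, ConnectivityMatrix...).  ``mode``
    "symmetric" keeps the n(n-1)/2 unordered pairs (lower triangle);
    "asymmetric" keeps all n(n-1) ordered pairs.  ``scale`` centers and
    scales predictors; the applied mean/sd are recorded in ``frame.attrs``.
    """
    mats = {"response": response, **predictors}
    frames = {}
    labels = None
    for name, m in mats.items():
        df = m.values if hasattr(m, "values") and isinstance(m.values, pd.DataFrame) else m
        if not isinstance(df, pd.DataFrame):
            raise ValueError(f"{name}: need a labeled DataFrame-backed matrix")
        if labels is None:
            labels = list(df.index)
        if list(df.index) != labels or list(df.columns) != labels:
            raise ValueError(f"{name}: labels differ from response labels")
        frames[name] = df.values.astype(float)

    n = len(labels)
    if mode == "symmetric":
        ii, jj = np.tril_indices(n, k=-1)
    elif mode == "asymmetric":
        ii, jj = np.nonzero(~np.eye(n, dtype=bool))
    else:
        raise ValueError("mode must be 'symmetric' or 'asymmetric'")

    out = pd.DataFrame({"pop_i": [labels[i] for i in ii], "pop_j": [labels[j] for j in jj]})
    scaling = {}
    for name, arr in frames.items():
        v = arr[ii, jj]
        if scale and name != "response":
            mu, sd = float(v.mean()), float(v.std(ddof=0))
            scaling[name] = {"mean": mu, "sd": sd}
            v = (v - mu) / sd if sd > 0 else v - mu
        out[name] = v
    out.attrs["mode"] = mode
    out.attrs["scaling"] = scaling
    return out


def transform_distance(water_km: pd.DataFrame) -> pd.DataFrame:
    """log10 water distance (off-diagonal; diagonal left at 0)."""
    v = water_km.values.astype(float).copy()
    off = ~np.eye(v.shape[0], dtype=bool)
    if (v[off] <= 0).any():
        raise ValueError("water distances must be positive off-diagonal")
    v[off] = np.log10(v[off])
    return pd.DataFrame(v, index=water_km.index, columns=water_km.columns)


def fourth_root(m: pd.DataFrame) -> pd.DataFrame:
    """Fourth-root transform used to normalize migration rates."""
    v = np.asarray(m.values, dtype=float)
    if (v < 0).any():
        raise ValueError("migration rates must be non-negative")
    return pd.DataFrame(v**0.25, index=m.index, columns=m.columns)


# ---------------------------------------------------------------------------
# Directional migration input and the asymmetry flag
# ---------------------------------------------------------------------------

@dataclass
class MigrationMatrix:
    """Directional per-generation migration rates with standard deviations.

    ``rates[i, j]`` is the fraction of population i derived from population j
    each generation (the convention of Bayesian assignment-based estimators);
    the diagonal is self-recruitment (retention).  Reversing this convention
    flips every directional conclusion, hence the explicit docstring.
    """

    rates: pd.DataFrame
    sds: pd.DataFrame | None = None

    def __post_init__(self):
        v = self.rates.values
        if (v < 0).any() or (v > 1).any():
            raise ValueError("migration rates must lie in [0, 1]")
        if (v.sum(axis=1) > 1 + 1e-6).any():
            raise ValueError("migration row sums exceed 1")
        if self.sds is not None and self.sds.shape != self.rates.shape:
            raise ValueError("sds must match rates shape")

    @property
    def labels(self):
        return list(self.rates.index)

    @classmethod
    def from_csv(cls, rates_path, sds_path=None) -> "MigrationMatrix":
        rates = pd.read_csv(rates_path, index_col=0)
        rates.index.name = None
        sds = None
        if sds_path is not None:
            sds = pd.read_csv(sds_path, index_col=0)
            sds.index.name = None
        return cls(rates, sds)

    @classmethod
    def from_bayesass_text(cls, path) -> "MigrationMatrix":
        """Parse a BayesAss-style summary: lines ``m[i][j]: rate(sd)``.

        Population indices are 1-based in the text; an optional header line
        ``populations: A B C`` names them.
        """
        import re
        text = Path(path).read_text()
        labels = None
        mm = re.search(r"populations:\s*(.+)", text)
        if mm:
            labels = mm.group(1).split()
        entries = re.findall(r"m\[(\d+)\]\[(\d+)\]\s*:\s*([0-9.eE+-]+)\s*\(([0-9.eE+-]+)\)", text)
        if not entries:
            raise ValueError("no m[i][j]: rate(sd) entries found")
        n = max(max(int(a), int(b)) for a, b, _, _ in entries)
        labels = labels or [f"pop{i + 1}" for i in range(n)]
        rates = np.zeros((n, n))
        sds = np.zeros((n, n))
        for a, b, r, s in entries:
            rates[int(a) - 1, int(b) - 1] = float(r)
            sds[int(a) - 1, int(b) - 1] = float(s)
        return cls(pd.DataFrame(rates, index=labels, columns=labels),
                   pd.DataFrame(sds, index=labels, columns=labels))


def flag_asymmetric_pairs(m: MigrationMatrix, z: float = 1.96) -> list:
    """Pairs with directional gene flow: both CIs exclude 0 and do not overlap.

    CI_ij = m_ij +- z * sd_ij.  Returns ordered pairs (source-of-the-larger
    first): each flagged (i, j) means migration into i from j differs from
    migration into j from i beyond CI overlap, with both rates nonzero.
    """
    if m.sds is None:
        raise ValueError("standard deviations are required to flag asymmetry")
    labels = m.labels
    r = m.rates.values
    s = m.sds.values
    flagged = []
    for i, j in itertools.combinations(range(len(labels)), 2):
        lo_ij, hi_ij = r[i, j] - z * s[i, j], r[i, j] + z * s[i, j]
        lo_ji, hi_ji = r[j, i] - z * s[j, i], r[j, i] + z * s[j, i]
        excl0 = lo_ij > 0 and lo_ji > 0
        overlap = not (hi_ij < lo_ji or hi_ji < lo_ij)
        if excl0 and not overlap:
            pair = (labels[i], labels[j]) if r[i, j] > r[j, i] else (labels[j], labels[i])
            flagged.append(pair)
    return flagged
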