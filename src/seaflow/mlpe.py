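"""Maximum-likelihood population effects (MLPE) regression on population pairs.

Pairwise responses (genetic distances, migration rates) are not independent:
two pairs that share a population are correlated.  MLPE models this with a
working correlation matrix C where C[q, q] = 1 and C[q, r] = rho whenever
pairs q and r share exactly one population.  (rho, beta, sigma^2) are found
by maximizing the Gaussian likelihood, profiling the likelihood over rho on
[0, 0.499] — the positive-definiteness bound for this structure — with
golden-section/Brent search.  Models are compared with small-sample AICc and
Akaike weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

RHO_MAX = 0.499


def share_matrix(pairs: pd.DataFrame) -> np.ndarray:
    """0/1 matrix over pair rows: 1 where two pairs share exactly one population."""
    pi = pairs["pop_i"].to_numpy()
    pj = pairs["pop_j"].to_numpy()
    n = len(pairs)
    shared = np.zeros((n, n))
    for q in range(n):
        sq = {pi[q], pj[q]}
        for r in range(q + 1, n):
            if len(sq & {pi[r], pj[r]}) == 1:
                shared[q, r] = shared[r, q] = 1.0
    return shared


@dataclass
class MLPEFit:
    """A fitted MLPE model.

    ``beta`` is indexed by term name (intercept first); ``rho`` is the
    correlation between pairs sharing one population; ``k`` counts estimated
    parameters (betas + sigma^2 + rho).
    """

    beta: pd.Series
    se: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    p_values: pd.Series
    rho: float
    sigma2: float
    log_lik: float
    k: int
    n: int
    formula: str
    aicc: float = field(init=False)

    def __post_init__(self):
        denom = self.n - self.k - 1
        if denom <= 0:
            raise ValueError("too few pairs for AICc with this many parameters")
        self.aicc = -2.0 * self.log_lik + 2.0 * self.k + 2.0 * self.k * (self.k + 1) / denom

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"beta": self.beta, "se": self.se, "ci_low": self.ci_low,
                             "ci_high": self.ci_high, "p": self.p_values})


def _profile_loglik(rho, y, X, A):
    n = y.size
    C = np.eye(n) + rho * A
    try:
        L = linalg.cholesky(C, lower=True)
    except linalg.LinAlgError:
        return -np.inf, None
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    Xi = linalg.solve_triangular(L, X, lower=True)
    yi = linalg.solve_triangular(L, y, lower=True)
    beta, *_ = np.linalg.lstsq(Xi, yi, rcond=None)
    resid = yi - Xi @ beta
    sigma2 = float(resid @ resid) / n
    if sigma2 <= 0:
        return -np.inf, None
    ll = -0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdet + n)
    return ll, (beta, sigma2, Xi)


def mlpe_fit(pairs: pd.DataFrame, predictors: list | None = None,
             response: str = "response") -> MLPEFit:
    """Fit an MLPE model to a pair frame.

    ``pairs`` must have columns pop_i, pop_j, the response, and the listed
    predictor columns (``None`` uses every column except identifiers and the
    response; an interaction term ``"a:b"`` multiplies two columns).  At
    least 6 populations are required for the shared-population structure to
    be informative.
    """
    if predictors is None:
        predictors = [c for c in pairs.columns if c not in ("pop_i", "pop_j", response)]
    n_pops = len(set(pairs["pop_i"]) | set(pairs["pop_j"]))
    if n_pops < 6:
        raise ValueError(f"MLPE needs >= 6 populations; got {n_pops}")
    y = pairs[response].to_numpy(dtype=float)
    if not np.isfinite(y).all():
        raise ValueError("response contains non-finite values")

    cols = [np.ones(len(pairs))]
    names = ["(intercept)"]
    for term in predictors:
        if ":" in term:
            a, b = term.split(":")
            cols.append(pairs[a].to_numpy(float) * pairs[b].to_numpy(float))
        else:
            cols.append(pairs[term].to_numpy(float))
        names.append(term)
    X = np.column_stack(cols)
    if not np.isfinite(X).all():
        raise ValueError("predictors contain non-finite values")
    A = share_matrix(pairs)

    res = optimize.minimize_scalar(lambda r: -_profile_loglik(r, y, X, A)[0],
                                   bounds=(0.0, RHO_MAX), method="bounded",
                                   options={"xatol": 1e-6})
    rho = float(res.x)
    ll, (beta, sigma2, Xi) = _profile_loglik(rho, y, X, A)
    ll0, _ = _profile_loglik(0.0, y, X, A)
    if ll0 > ll:  # boundary: rho = 0 dominates
        rho, (ll, (beta, sigma2, Xi)) = 0.0, _profile_loglik(0.0, y, X, A)

    cov = sigma2 * np.linalg.inv(Xi.T @ Xi)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    ci = 1.959963984540054 * se
    k = X.shape[1] + 2  # betas + sigma^2 + rho
    idx = pd.Index(names)
    return MLPEFit(beta=pd.Series(beta, index=idx), se=pd.Series(se, index=idx),
                   ci_low=pd.Series(beta - ci, index=idx), ci_high=pd.Series(beta + ci, index=idx),
                   p_values=pd.Series(p, index=idx), rho=rho, sigma2=float(sigma2),
                   log_lik=float(ll), k=k, n=y.size,
                   formula=f"{response} ~ " + " + ".join(predictors) if predictors else response)


def aicc_table(fits: list) -> pd.DataFrame:
    """Rank fitted models by AICc with Akaike weights.

    Models within 2 AICc of the best are flagged ``equally_likely``.  All
    fits must share the same response rows (checked via n).
    """
    if not fits:
        raise ValueError("no fits supplied")
    if len({f.n for f in fits}) != 1:
        raise ValueError("fits compare different row sets (n differs)")
    aicc = np.array([f.aicc for f in fits])
    delta = aicc - aicc.min()
    w = np.exp(-delta / 2.0)
    w = w / w.sum()
    df = pd.DataFrame({
        "formula": [f.formula for f in fits],
        "k": [f.k for f in fits],
        "log_lik": [f.log_lik for f in fits],
        "AICc": aicc,
        "dAICc": delta,
        "weight": w,
        "equally_likely": delta <= 2.0,
    }).sort_values("AICc").reset_index(drop=True)
    return df


def akaike_weights(log_liks, k, n) -> np.ndarray:
    """Closed-form AICc Akaike weights for models with given logLik and k."""
    log_liks = np.asarray(log_liks, dtype=float)
    k = np.broadcast_to(np.asarray(k, dtype=float), log_liks.shape)
    aicc = -2.0 * log_liks + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)
    delta = aicc - aicc.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def simulate_mlpe(n_pops: int, beta: np.ndarray, rho: float, sigma2: float = 1.0,
                  seed: int = 0) -> pd.DataFrame:
    """Draw a pair frame from the MLPE generative model (for calibration).

    Predictors are iid standard normal per pair; the error is multivariate
    normal with covariance sigma^2 (I + rho A) over the n(n-1)/2 unordered
    pairs.
    """
    rng = np.random.default_rng(seed)
    pops = [f"P{i + 1}" for i in range(n_pops)]
    rows = [(a, b) for i, a in enumerate(pops) for b in pops[i + 1:]]
    frame = pd.DataFrame(rows, columns=["pop_i", "pop_j"])
    n = len(frame)
    beta = np.asarray(beta, dtype=float)
    X = np.column_stack([np.ones(n)] + [rng.normal(size=n) for _ in range(beta.size - 1)])
    A = share_matrix(frame)
    L = linalg.cholesky(np.eye(n) + rho * A, lower=True)
    eps = np.sqrt(sigma2) * (L @ rng.normal(size=n))
    frame["response"] = X @ beta + eps
    for j in range(1, beta.size):
        frame[f"x{j}"] = X[:, j]
    return frame
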