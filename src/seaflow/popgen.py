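"""Diversity, Hardy-Weinberg tests, differentiation metrics, and AMOVA.

Differentiation is computed pairwise (k = 2 populations at a time) with
sample-size-corrected Hs/Ht estimators (Nei & Chesser style) by default:

    Hs = (n~ / (n~ - 1)) * (1 - mean_pop sum_a p_a^2 - Ho / (2 n~))
    Ht = 1 - sum_a pbar_a^2 + Hs / (n~ k) - Ho / (2 n~ k)

with n~ the harmonic mean sample size.  From the multilocus means,
G_ST = (Ht - Hs) / Ht; Hedrick's G'_ST rescales G_ST by its maximum given
within-population heterozygosity; Jost's D uses allelic diversity,
D = (k/(k-1)) (Ht - Hs)/(1 - Hs), combined across loci by harmonic mean;
R_ST comes from allele-size variance components and so respects stepwise
mutation.  Negative estimates are reported as computed (a clamped view is
available) so downstream matrix correlations are not silently biased.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genotypes import MISSING, GenotypeTable
from .matrices import DiffMatrix

METRICS = ("GST", "GpST", "JostD", "RST")


# ---------------------------------------------------------------------------
# Diversity
# ---------------------------------------------------------------------------

def _log_comb(n, k):
    n = np.asarray(n, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def diversity(genotypes: GenotypeTable, rarefaction_n: int | None = None) -> pd.DataFrame:
    """Per-population Ho, unbiased He, rarefied allelic richness, and n.

    Ho and He are means over loci; He uses the unbiased small-sample factor
    2n/(2n-1).  Allelic richness is rarefied to g genes, where g defaults to
    twice the smallest per-population, per-locus sample size with data:
    AR = sum_a [1 - C(N - N_a, g) / C(N, g)] averaged over loci.  Monomorphic
    loci contribute He = 0 and AR = 1.
    """
    pops = genotypes.populations
    idx = genotypes.population_indices()
    alleles = genotypes.alleles

    # smallest typed sample over (population, locus)
    min_n = None
    for p in pops:
        typed = (~genotypes.missing_mask()[idx[p]]).sum(axis=0)
        m = typed[typed > 0].min() if (typed > 0).any() else None
        if m is not None:
            min_n = m if min_n is None else min(min_n, m)
    g = 2 * (rarefaction_n if rarefaction_n is not None else int(min_n or 1))

    rows = []
    for p in pops:
        sub = alleles[idx[p]]
        ho_l, he_l, ar_l = [], [], []
        for j in range(genotypes.n_loci):
            calls = sub[:, j]
            ok = (calls != MISSING).all(axis=1)
            n = int(ok.sum())
            if n == 0:
                continue
            a = calls[ok]
            ho_l.append(float((a[:, 0] != a[:, 1]).mean()))
            vals, counts = np.unique(a.ravel(), return_counts=True)
            freqs = counts / counts.sum()
            he_l.append((2 * n / (2 * n - 1)) * (1 - np.sum(freqs**2)) if n > 1
                        else 1 - np.sum(freqs**2))
            N = counts.sum()
            if N >= g:
                with np.errstate(invalid="ignore"):
                    term = np.where(N - counts >= g,
                                    np.exp(_log_comb(N - counts, g) - _log_comb(N, g)), 0.0)
                ar_l.append(float(np.sum(1.0 - term)))
        rows.append({"population": p, "n": len(idx[p]),
                     "Ho": float(np.mean(ho_l)), "He": float(np.mean(he_l)),
                     "AR": float(np.mean(ar_l)) if ar_l else np.nan})
    return pd.DataFrame(rows).set_index("population")


# ---------------------------------------------------------------------------
# Hardy-Weinberg
# ---------------------------------------------------------------------------

def hwe_test(genotypes: GenotypeTable, population, locus, n_perm: int = 9999,
             seed: int = 0) -> float:
    """Monte-Carlo exact-style HWE test for one population x locus.

    The statistic is the chi-square of genotype counts against their
    Hardy-Weinberg expectation from the sample allele frequencies; the null
    is built by re-pairing the pooled alleles at random among individuals.
    Returns the one-sided permutation p-value; monomorphic data give p = 1.
    """
    j = genotypes.loci.index(str(locus))
    rows = genotypes.population_indices()[population]
    calls = genotypes.alleles[rows, j]
    calls = calls[(calls != MISSING).all(axis=1)]
    n = calls.shape[0]
    if n < 5:
        raise ValueError(f"need >= 5 typed individuals; got {n}")
    pool = calls.ravel()
    uniq = np.unique(pool)
    if uniq.size == 1:
        return 1.0

    code = np.searchsorted(uniq, calls)
    A = uniq.size

    def chi2(geno_codes):
        lo = geno_codes.min(axis=1)
        hi = geno_codes.max(axis=1)
        obs = np.zeros((A, A))
        np.add.at(obs, (lo, hi), 1.0)
        freq = np.bincount(geno_codes.ravel(), minlength=A) / (2.0 * n)
        exp = np.zeros((A, A))
        for a in range(A):
            exp[a, a] = n * freq[a] ** 2
            for b in range(a + 1, A):
                exp[a, b] = 2.0 * n * freq[a] * freq[b]
        mask = exp > 0
        return float(((obs[mask] - exp[mask]) ** 2 / exp[mask]).sum())

    obs_stat = chi2(code)
    rng = np.random.default_rng(seed)
    pooled = code.ravel().copy()
    hits = 0
    for _ in range(n_perm):
        rng.shuffle(pooled)
        if chi2(pooled.reshape(n, 2)) >= obs_stat - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)


# ---------------------------------------------------------------------------
# Pairwise differentiation
# ---------------------------------------------------------------------------

def _locus_pair_stats(calls1, calls2, corrected=True):
    """Per-locus Hs/Ht/Ho estimators and allele-size variance components
    for a pair of populations; returns None when a side has no data."""
    ok1 = (calls1 != MISSING).all(axis=1)
    ok2 = (calls2 != MISSING).all(axis=1)
    n1, n2 = int(ok1.sum()), int(ok2.sum())
    if n1 == 0 or n2 == 0:
        return None
    a1, a2 = calls1[ok1], calls2[ok2]
    ho = 0.5 * ((a1[:, 0] != a1[:, 1]).mean() + (a2[:, 0] != a2[:, 1]).mean())

    pool = np.unique(np.concatenate([a1.ravel(), a2.ravel()]))
    f1 = np.bincount(np.searchsorted(pool, a1.ravel()), minlength=pool.size) / (2.0 * n1)
    f2 = np.bincount(np.searchsorted(pool, a2.ravel()), minlength=pool.size) / (2.0 * n2)
    fbar = 0.5 * (f1 + f2)
    hs0 = 1.0 - 0.5 * (np.sum(f1**2) + np.sum(f2**2))
    ht0 = 1.0 - np.sum(fbar**2)
    if corrected:
        ntilde = 2.0 / (1.0 / n1 + 1.0 / n2)
        hs = ntilde / (ntilde - 1.0) * (hs0 - ho / (2.0 * ntilde)) if ntilde > 1 else hs0
        ht = ht0 + hs / (2.0 * ntilde) - ho / (4.0 * ntilde)
    else:
        hs, ht = hs0, ht0

    # allele-size variance components (one-way ANOVA, alleles as units)
    x1, x2 = a1.ravel().astype(float), a2.ravel().astype(float)
    N1, N2 = x1.size, x2.size
    N = N1 + N2
    ssw = np.sum((x1 - x1.mean()) ** 2) + np.sum((x2 - x2.mean()) ** 2)
    gm = (x1.sum() + x2.sum()) / N
    ssb = N1 * (x1.mean() - gm) ** 2 + N2 * (x2.mean() - gm) ** 2
    msw = ssw / (N - 2) if N > 2 else 0.0
    n0 = (N - (N1**2 + N2**2) / N)  # / (k-1) with k=2
    sig_b = (ssb / 1.0 - msw) / n0 if n0 > 0 else 0.0
    return {"n1": n1, "n2": n2, "ho": ho, "hs": hs, "ht": ht,
            "sig_w": msw, "sig_b": sig_b}


def pair_differentiation(genotypes: GenotypeTable, pop_a, pop_b, corrected: bool = True,
                         jost_combine: str = "harmonic") -> dict:
    """All four differentiation metrics for one population pair (k = 2).

    Loci with no data in either population are skipped (pairwise deletion).
    Jost's D is combined across loci by harmonic mean when every per-locus
    estimate is positive, else by arithmetic mean with a warning.
    """
    idx = genotypes.population_indices()
    k = 2.0
    hs_l, ht_l, d_l, sb_l, sw_l = [], [], [], [], []
    for j in range(genotypes.n_loci):
        st = _locus_pair_stats(genotypes.alleles[idx[pop_a], j],
                               genotypes.alleles[idx[pop_b], j], corrected)
        if st is None:
            continue
        hs_l.append(st["hs"])
        ht_l.append(st["ht"])
        if st["hs"] < 1.0:
            d_l.append((k / (k - 1.0)) * (st["ht"] - st["hs"]) / (1.0 - st["hs"]))
        sb_l.append(st["sig_b"])
        sw_l.append(st["sig_w"])
    if not hs_l:
        raise ValueError(f"no locus has data in both {pop_a} and {pop_b}")
    hs, ht = float(np.mean(hs_l)), float(np.mean(ht_l))
    gst = (ht - hs) / ht if ht > 0 else 0.0
    gpst = gst * (k - 1.0 + hs) / ((k - 1.0) * (1.0 - hs)) if hs < 1.0 else np.nan

    d_arr = np.asarray(d_l, dtype=float)
    if jost_combine == "harmonic" and d_arr.size and (d_arr > 0).all():
        d = float(d_arr.size / np.sum(1.0 / d_arr))
    else:
        if jost_combine == "harmonic" and d_arr.size and not (d_arr > 0).all():
            warnings.warn("non-positive per-locus Jost's D; falling back to arithmetic mean")
        d = float(np.mean(d_arr)) if d_arr.size else 0.0

    sb, sw = float(np.sum(sb_l)), float(np.sum(sw_l))
    rst = sb / (sb + sw) if (sb + sw) > 0 else 0.0
    return {"GST": gst, "GpST": gpst, "JostD": d, "RST": rst,
            "Hs": hs, "Ht": ht, "n_loci": len(hs_l)}


def pairwise_diff(genotypes: GenotypeTable, metric: str, corrected: bool = True,
                  jost_combine: str = "harmonic") -> DiffMatrix:
    """Symmetric matrix of one differentiation metric over all population pairs."""
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    pops = genotypes.populations
    n = len(pops)
    out = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            val = pair_differentiation(genotypes, pops[a], pops[b], corrected,
                                       jost_combine)[metric]
            out[a, b] = out[b, a] = val
    return DiffMatrix(pd.DataFrame(out, index=pops, columns=pops), metric=metric)


def linearize(diff: DiffMatrix) -> DiffMatrix:
    """Rousset linearization x -> x/(1-x), applied off-diagonal."""
    v = diff.values.values.copy()
    labels = diff.labels
    at_one = (v >= 1.0) & ~np.eye(len(labels), dtype=bool)
    if at_one.any():
        for i, j in zip(*np.nonzero(at_one)):
            warnings.warn(f"{diff.metric}({labels[i]}, {labels[j]}) = 1: linearized value is inf")
    with np.errstate(divide="ignore"):
        lin = v / (1.0 - v)
    np.fill_diagonal(lin, 0.0)
    return DiffMatrix(pd.DataFrame(lin, index=labels, columns=labels),
                      metric=diff.metric, linearized=True)


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

LEVEL_NAMES = ["among_regions", "among_populations_within_region",
               "among_locations_within_population", "among_individuals_within_location",
               "within_individuals"]


@dataclass
class AMOVAResult:
    table: pd.DataFrame  # index: level; columns: df, sigma, percent, phi, p_value
    degenerate: bool = False

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="level")


def _group_ss(values, groups, n_groups, distance):
    """SS within each group: for 0/1 allele mismatch, (n_g - sum_a c_ga^2/n_g)/2;
    for allele size, the within-group sum of squared deviations."""
    n_g = np.bincount(groups, minlength=n_groups).astype(float)
    if distance == "allele_diff":
        A = int(values.max()) + 1
        cnt = np.bincount(groups * A + values, minlength=n_groups * A).astype(float)
        sumsq = (cnt.reshape(n_groups, A) ** 2).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            w = np.where(n_g > 0, (n_g - sumsq / np.where(n_g > 0, n_g, 1)) / 2.0, 0.0)
    else:
        s1 = np.bincount(groups, weights=values.astype(float), minlength=n_groups)
        s2 = np.bincount(groups, weights=values.astype(float) ** 2, minlength=n_groups)
        with np.errstate(invalid="ignore", divide="ignore"):
            w = np.where(n_g > 0, s2 - s1**2 / np.where(n_g > 0, n_g, 1), 0.0)
    return w, n_g


def _amova_components(loci_data, ind_to_loc, loc_to_pop, pop_to_region,
                      n_region, n_pop, n_loc, distance):
    """Variance components (5-vector, NaN where df = 0) summed over loci.

    ``loci_data`` is a list of (allele_codes_or_sizes, ind_index) per locus.
    Uses the nested ANOVA identity: the coefficient of component m in
    E[SS at level a] is sum over level-a groups of (sum of squared level-m
    subgroup sizes / group size), minus the same sum over level-(a-1) groups.
    """
    total = np.zeros(5)
    any_df = np.zeros(5, dtype=bool)
    for values, ind_idx in loci_data:
        loc_idx = ind_to_loc[ind_idx]
        pop_idx = loc_to_pop[loc_idx]
        reg_idx = pop_to_region[pop_idx]
        n_ind = ind_to_loc.size

        groupings = [np.zeros(values.size, dtype=np.int64), reg_idx, pop_idx,
                     loc_idx, ind_idx]
        sizes = [1, n_region, n_pop, n_loc, n_ind]
        W, NG = [], []
        for grp, ng in zip(groupings, sizes):
            w, n_g = _group_ss(values, grp, ng, distance)
            W.append(w)
            NG.append(n_g)
        # per-unit "groups" level for the error coefficient
        n_units = float(values.size)

        present = [float((n_g > 0).sum()) for n_g in NG]
        df = np.array([present[1] - present[0], present[2] - present[1],
                       present[3] - present[2], present[4] - present[3],
                       n_units - present[4]])
        ss = np.array([W[0].sum() - W[1].sum(), W[1].sum() - W[2].sum(),
                       W[2].sum() - W[3].sum(), W[3].sum() - W[4].sum(),
                       W[4].sum()])

        # S_m(level a) = sum over level-a groups of sum(level-m subgroup n^2)/n_group
        def S(a, m):
            ga, gm = groupings[a], groupings[m]
            n_gm = np.bincount(gm, minlength=sizes[m]).astype(float)
            # map each level-m subgroup to its level-a parent
            parent = np.full(sizes[m], -1, dtype=np.int64)
            parent[gm] = ga
            n_ga = NG[a - 0]
            valid = n_gm > 0
            contrib = np.zeros(sizes[a])
            np.add.at(contrib, parent[valid], n_gm[valid] ** 2)
            with np.errstate(invalid="ignore", divide="ignore"):
                return float(np.sum(np.where(n_ga > 0, contrib / np.where(n_ga > 0, n_ga, 1), 0.0)))

        # coefficient matrix: rows = SS levels 1..5, cols = components 1..5
        C = np.zeros((5, 5))
        for a in range(1, 5):          # SS among level-a groups within level-(a-1)
            for m in range(a, 5):      # coefficient of the level-m component
                C[a - 1, m - 1] = S(a, m) - S(a - 1, m)
            C[a - 1, 4] = df[a - 1]    # error (within-individual) component
        C[4, 4] = df[4]

        # drop degenerate rows/components (df = 0)
        live = df > 0
        sig = np.full(5, np.nan)
        if live.any():
            Csub = C[np.ix_(live, live)]
            sssub = ss[live]
            try:
                sig_live = np.linalg.solve(Csub, sssub)
            except np.linalg.LinAlgError:
                sig_live = np.full(int(live.sum()), np.nan)
            sig[live] = sig_live
        total += np.where(np.isnan(sig), 0.0, sig)
        any_df |= live
    total = np.where(any_df, total, np.nan)
    return total


def _phi_from_components(sig):
    tot = np.nansum(sig)
    phi = np.full(5, np.nan)
    if tot <= 0:
        return phi
    for m in range(4):
        tail = np.nansum(sig[m:])
        if not np.isnan(sig[m]) and tail > 0:
            phi[m] = sig[m] / tail
    if not np.isnan(sig[4]):
        phi[4] = 1.0 - sig[4] / tot
    return phi


def amova(genotypes: GenotypeTable, region_of: dict | None = None,
          n_perm: int = 999, distance: str = "allele_diff", seed: int = 0) -> AMOVAResult:
    """Hierarchical AMOVA: region / population / location / individual / allele.

    ``region_of`` maps population labels to region labels (omit it for a
    single region, whose among-regions component is then undefined).
    ``distance`` is ``"allele_diff"`` (0/1 allele mismatch, the default) or
    ``"allele_size"`` (squared repeat-count difference).  Significance is by
    permutation at the appropriate level: populations among regions,
    locations among populations within regions, individuals among locations
    within populations, alleles among individuals within locations, and
    alleles among all individuals for the within-individual component;
    p = (hits + 1) / (n_perm + 1) on the phi statistic.
    """
    if distance not in ("allele_diff", "allele_size"):
        raise ValueError("distance must be 'allele_diff' or 'allele_size'")
    ind = genotypes.individuals
    pops = genotypes.populations
    locs = sorted(ind["site"].unique())
    region_of = region_of or {p: "all" for p in pops}
    regions = sorted(set(region_of.values()))

    loc_list = locs
    loc_pos = {v: i for i, v in enumerate(loc_list)}
    pop_pos = {v: i for i, v in enumerate(pops)}
    reg_pos = {v: i for i, v in enumerate(regions)}

    ind_to_loc = ind["site"].map(loc_pos).to_numpy(dtype=np.int64)
    # location -> population (must nest cleanly)
    loc_to_pop = np.full(len(loc_list), -1, dtype=np.int64)
    for site, pop in ind[["site", "population"]].drop_duplicates().itertuples(index=False):
        prev = loc_to_pop[loc_pos[site]]
        if prev not in (-1, pop_pos[pop]):
            raise ValueError(f"location {site} appears in more than one population")
        loc_to_pop[loc_pos[site]] = pop_pos[pop]
    pop_to_region = np.array([reg_pos[region_of[p]] for p in pops], dtype=np.int64)

    loci_data = []
    for j in range(genotypes.n_loci):
        calls = genotypes.alleles[:, j]
        ok = (calls != MISSING).all(axis=1)
        if not ok.any():
            continue
        a = calls[ok]
        ind_idx = np.repeat(np.nonzero(ok)[0], 2).astype(np.int64)
        if distance == "allele_diff":
            vals = np.unique(a.ravel(), return_inverse=True)[1].astype(np.int64)
        else:
            vals = a.ravel().astype(np.int64)
        loci_data.append((vals, ind_idx))

    def components(i2l, l2p, p2r, loci=loci_data):
        return _amova_components(loci, i2l, l2p, p2r, len(regions), len(pops),
                                 len(loc_list), distance)

    sig = components(ind_to_loc, loc_to_pop, pop_to_region)
    tot = np.nansum(sig)
    degenerate = not (tot > 0)
    percent = 100.0 * sig / tot if not degenerate else np.full(5, np.nan)
    phi = _phi_from_components(sig)

    rng = np.random.default_rng(seed)
    pvals = np.full(5, np.nan)
    if not degenerate and n_perm > 0:
        n_ind = len(ind)
        for m in range(5):
            if np.isnan(phi[m]):
                continue
            hits = 0
            for _ in range(n_perm):
                i2l, l2p, p2r = ind_to_loc, loc_to_pop, pop_to_region
                loci = loci_data
                if m == 0:      # populations among regions
                    p2r = pop_to_region[rng.permutation(len(pops))]
                elif m == 1:    # among populations, within regions
                    if len(loc_list) > len(pops):
                        # permute whole locations among populations (keeps
                        # location cohesion)
                        l2p = loc_to_pop.copy()
                        for r in range(len(regions)):
                            sel = np.nonzero(pop_to_region[loc_to_pop] == r)[0]
                            l2p[sel] = loc_to_pop[rng.permutation(sel)]
                    else:
                        # one location per population: permute individuals
                        # among populations within each region instead
                        i2l = ind_to_loc.copy()
                        reg_of_ind = pop_to_region[loc_to_pop[ind_to_loc]]
                        for r in range(len(regions)):
                            sel = np.nonzero(reg_of_ind == r)[0]
                            i2l[sel] = ind_to_loc[sel][rng.permutation(sel.size)]
                elif m == 2:    # individuals among locations, within populations
                    i2l = ind_to_loc.copy()
                    for p in range(len(pops)):
                        sel = np.nonzero(loc_to_pop[ind_to_loc] == p)[0]
                        i2l[sel] = ind_to_loc[sel][rng.permutation(sel.size)]
                elif m in (3, 4):  # alleles among individuals (within locations / overall)
                    loci = []
                    for vals, ind_idx in loci_data:
                        new_idx = ind_idx.copy()
                        if m == 3:
                            for lidx in np.unique(ind_to_loc[ind_idx]):
                                sel = np.nonzero(ind_to_loc[ind_idx] == lidx)[0]
                                new_idx[sel] = ind_idx[sel][rng.permutation(sel.size)]
                        else:
                            new_idx = ind_idx[rng.permutation(ind_idx.size)]
                        loci.append((vals, new_idx))
                sig_p = components(i2l, l2p, p2r, loci)
                phi_p = _phi_from_components(sig_p)
                if not np.isnan(phi_p[m]) and phi_p[m] >= phi[m] - 1e-12:
                    hits += 1
            pvals[m] = (hits + 1) / (n_perm + 1)

    df_out = pd.DataFrame({"sigma": sig, "percent": percent, "phi": phi,
                           "p_value": pvals}, index=LEVEL_NAMES)
    return AMOVAResult(df_out, degenerate=degenerate)
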