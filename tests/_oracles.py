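"""Independent reference implementations used only by the tests.

Everything here is deliberately written the slow, literal way (explicit
loops, dictionaries, full enumeration) so it shares no code path with the
package implementations it checks.
"""

import heapq
import itertools
import math

import numpy as np


# ---------------------------------------------------------------------------
# grid shortest path (vs geometry.water_distance)
# ---------------------------------------------------------------------------

def grid_dijkstra(land, step_costs, start, goal):
    """Plain heapq Dijkstra on a grid; ``step_costs[(dy, dx)]`` gives the cost."""
    ny, nx = land.shape
    dist = {start: 0.0}
    heap = [(0.0, start)]
    done = set()
    while heap:
        d, cell = heapq.heappop(heap)
        if cell in done:
            continue
        done.add(cell)
        if cell == goal:
            return d
        y, x = cell
        for (dy, dx), w in step_costs.items():
            ny2, nx2 = y + dy, x + dx
            if 0 <= ny2 < ny and 0 <= nx2 < nx and not land[ny2, nx2]:
                nd = d + w
                if nd < dist.get((ny2, nx2), math.inf):
                    dist[(ny2, nx2)] = nd
                    heapq.heappush(heap, (nd, (ny2, nx2)))
    return math.inf


# ---------------------------------------------------------------------------
# best-product path enumeration (vs connectivity.network_connectivity)
# ---------------------------------------------------------------------------

def best_product_oc(p, directed=True):
    """OC by exhaustive simple-path enumeration on a small graph.

    For every ordered pair, enumerate all simple paths over positive edges,
    find the maximum product of edge probabilities, and divide by the number
    of intermediate nodes (floored at 1).  Product ties within 1e-12 resolve
    to the fewest intermediates.
    """
    n = p.shape[0]
    out = np.zeros((n, n))

    def edges_from(i):
        for j in range(n):
            w = p[i, j] if directed else max(p[i, j], p[j, i])
            if j != i and w > 0:
                yield j, w

    for s in range(n):
        for t in range(n):
            if s == t:
                continue
            best = (0.0, 0)
            stack = [(s, {s}, 1.0)]
            while stack:
                node, seen, prod = stack.pop()
                for j, w in edges_from(node):
                    if j in seen:
                        continue
                    np_prod = prod * w
                    if j == t:
                        inter = len(seen) - 1
                        if (np_prod > best[0] + 1e-12
                                or (abs(np_prod - best[0]) <= 1e-12 and inter < best[1])):
                            best = (np_prod, inter)
                    else:
                        stack.append((j, seen | {j}, np_prod))
            out[s, t] = best[0] / max(1, best[1])
    return out


# ---------------------------------------------------------------------------
# Nei-Chesser pair estimators, longhand (vs popgen.pair_differentiation)
# ---------------------------------------------------------------------------

def pair_metrics_longhand(geno_a, geno_b):
    """G_ST, G'_ST, Jost's D (harmonic), R_ST for two populations.

    ``geno_a``/``geno_b``: lists of (allele1, allele2) int tuples per
    individual, one list per locus is derived by column.  Written with
    dictionaries and explicit sums.
    """
    n_loci = len(geno_a[0])
    hs_list, ht_list, d_list = [], [], []
    sb_sum, sw_sum = 0.0, 0.0
    for j in range(n_loci):
        a = [ind[j] for ind in geno_a]
        b = [ind[j] for ind in geno_b]
        n1, n2 = len(a), len(b)
        ho1 = sum(1 for x, y in a if x != y) / n1
        ho2 = sum(1 for x, y in b if x != y) / n2
        ho = (ho1 + ho2) / 2

        def freqs(g):
            c = {}
            for x, y in g:
                c[x] = c.get(x, 0) + 1
                c[y] = c.get(y, 0) + 1
            tot = sum(c.values())
            return {k: v / tot for k, v in c.items()}

        f1, f2 = freqs(a), freqs(b)
        alleles = set(f1) | set(f2)
        sum_p2 = (sum(v**2 for v in f1.values()) + sum(v**2 for v in f2.values())) / 2
        sum_pbar2 = sum(((f1.get(k, 0.0) + f2.get(k, 0.0)) / 2) ** 2 for k in alleles)
        ntil = 2.0 / (1.0 / n1 + 1.0 / n2)
        hs = ntil / (ntil - 1.0) * (1.0 - sum_p2 - ho / (2 * ntil))
        ht = 1.0 - sum_pbar2 + hs / (2 * ntil) - ho / (4 * ntil)
        hs_list.append(hs)
        ht_list.append(ht)
        if hs < 1:
            d_list.append(2.0 * (ht - hs) / (1.0 - hs))

        # allele-size ANOVA
        xs1 = [v for pair in a for v in pair]
        xs2 = [v for pair in b for v in pair]
        m1 = sum(xs1) / len(xs1)
        m2 = sum(xs2) / len(xs2)
        gm = (sum(xs1) + sum(xs2)) / (len(xs1) + len(xs2))
        ssw = sum((v - m1) ** 2 for v in xs1) + sum((v - m2) ** 2 for v in xs2)
        ssb = len(xs1) * (m1 - gm) ** 2 + len(xs2) * (m2 - gm) ** 2
        N = len(xs1) + len(xs2)
        msw = ssw / (N - 2)
        n0 = N - (len(xs1) ** 2 + len(xs2) ** 2) / N
        sb_sum += (ssb - msw) / n0
        sw_sum += msw

    hs_bar = sum(hs_list) / len(hs_list)
    ht_bar = sum(ht_list) / len(ht_list)
    gst = (ht_bar - hs_bar) / ht_bar
    gpst = gst * (1.0 + hs_bar) / (1.0 - hs_bar)
    if all(d > 0 for d in d_list):
        d_multi = len(d_list) / sum(1.0 / d for d in d_list)
    else:
        d_multi = sum(d_list) / len(d_list)
    rst = sb_sum / (sb_sum + sw_sum)
    return {"GST": gst, "GpST": gpst, "JostD": d_multi, "RST": rst}


# ---------------------------------------------------------------------------
# balanced nested AMOVA, longhand (vs popgen.amova)
# ---------------------------------------------------------------------------

def amova_balanced_longhand(alleles, region_of_ind, pop_of_ind, loc_of_ind):
    """Variance components for a balanced region/pop/location/individual design.

    ``alleles``: (n_ind, 2) integer allele codes for a single locus, complete
    data.  SS are computed from explicit pairwise mismatches; expected mean
    squares use the textbook balanced-design coefficients.
    """
    n_ind = alleles.shape[0]
    units = [(alleles[i, k], region_of_ind[i], pop_of_ind[i], loc_of_ind[i], i)
             for i in range(n_ind) for k in range(2)]

    def ss_within(group_key):
        groups = {}
        for u in units:
            groups.setdefault(group_key(u), []).append(u[0])
        total = 0.0
        for vals in groups.values():
            mism = sum(1 for i, j in itertools.combinations(range(len(vals)), 2)
                       if vals[i] != vals[j])
            total += mism / len(vals)
        return total

    W_tot = ss_within(lambda u: 0)
    W_reg = ss_within(lambda u: u[1])
    W_pop = ss_within(lambda u: u[2])
    W_loc = ss_within(lambda u: u[3])
    W_ind = ss_within(lambda u: u[4])

    R = len(set(region_of_ind))
    P = len(set(pop_of_ind))
    Lc = len(set(loc_of_ind))
    I = n_ind
    n_per_loc = 2 * I // Lc          # alleles per location
    n_per_pop = 2 * I // P
    n_per_reg = 2 * I // R

    ss = [W_tot - W_reg, W_reg - W_pop, W_pop - W_loc, W_loc - W_ind, W_ind]
    df = [R - 1, P - R, Lc - P, I - Lc, 2 * I - I]
    ms = [s / d for s, d in zip(ss, df)]
    # balanced-design EMS, solved bottom-up
    sig_e = ms[4]
    sig_d = (ms[3] - sig_e) / 2.0
    sig_c = (ms[2] - sig_e - 2 * sig_d) / n_per_loc
    sig_b = (ms[1] - sig_e - 2 * sig_d - n_per_loc * sig_c) / n_per_pop
    sig_a = (ms[0] - sig_e - 2 * sig_d - n_per_loc * sig_c - n_per_pop * sig_b) / n_per_reg
    return [sig_a, sig_b, sig_c, sig_d, sig_e]


# ---------------------------------------------------------------------------
# Mantel enumerations (vs flowstats)
# ---------------------------------------------------------------------------

def _corr(x, y):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xs, ys = x - x.mean(), y - y.mean()
    return float((xs * ys).sum() / math.sqrt((xs**2).sum() * (ys**2).sum()))


def mantel_exact_p(x, y, alternative="greater"):
    """Exact permutation p for a symmetric Mantel test by full enumeration."""
    n = x.shape[0]
    il = np.tril_indices(n, k=-1)
    vx = x[il]
    r_obs = _corr(vx, y[il])
    rs = []
    for perm in itertools.permutations(range(n)):
        yp = y[np.ix_(perm, perm)]
        rs.append(_corr(vx, yp[il]))
    rs = np.asarray(rs)
    if alternative == "greater":
        return float((rs >= r_obs - 1e-12).mean())
    return float((rs <= r_obs + 1e-12).mean())


def asym_mantel_exact_p(x, y, alternative="greater"):
    """Exact p for the vector-permutation test (all entry permutations)."""
    off = ~np.eye(x.shape[0], dtype=bool)
    vx, vy = x[off], y[off]
    r_obs = _corr(vx, vy)
    rs = [_corr(np.asarray(perm), vy) for perm in itertools.permutations(vx)]
    rs = np.asarray(rs)
    if alternative == "greater":
        return float((rs >= r_obs - 1e-12).mean())
    return float((rs <= r_obs + 1e-12).mean())


def partial_corr_longhand(vx, vy, vz):
    """Residual correlation of vx and vy after OLS on vz (explicit algebra)."""
    z = np.asarray(vz, float)
    zc = z - z.mean()

    def resid(v):
        v = np.asarray(v, float)
        beta = (zc * (v - v.mean())).sum() / (zc**2).sum()
        return v - v.mean() - beta * zc

    return _corr(resid(vx), resid(vy))
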