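"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately naive (loops, enumeration, O(n^2) scans) and
shares no code with the package implementations it checks.
"""

import itertools
import math

import numpy as np

MISSING = -1


# ----------------------------------------------------------------- filter cascade


def brute_force_cascade(g, depth, gt_min_depth=10, site_max_missing=0.5,
                        ind_min_mean_depth=12.0, ind_max_missing=0.5,
                        depth_iqr_mult=1.5, maf_min=0.05):
    """Elementwise re-implementation of the full filter cascade.

    Returns (site_keep_indices_in_original, sample_keep_indices, masked_g).
    """
    g = np.array(g, dtype=int)
    depth = np.array(depth, dtype=float)
    n_sites, n_ind = g.shape
    for i in range(n_sites):
        for j in range(n_ind):
            if depth[i, j] < gt_min_depth:
                g[i, j] = MISSING

    sites = list(range(n_sites))
    sites = [i for i in sites
             if sum(g[i, j] == MISSING for j in range(n_ind)) / n_ind <= site_max_missing]

    inds = []
    for j in range(n_ind):
        md = sum(depth[i, j] for i in sites) / len(sites)
        miss = sum(g[i, j] == MISSING for i in sites) / len(sites)
        if md >= ind_min_mean_depth and miss <= ind_max_missing:
            inds.append(j)

    sites = [i for i in sites
             if sum(g[i, j] == MISSING for j in inds) / len(inds) <= site_max_missing]

    def maf(i):
        alleles = [g[i, j] for j in inds if g[i, j] != MISSING]
        if not alleles:
            return -1.0
        alt = sum(alleles)
        tot = 2 * len(alleles)
        return min(alt / tot, 1 - alt / tot)

    sites = [i for i in sites if maf(i) >= maf_min]

    while len(sites) >= 4 and math.isfinite(depth_iqr_mult):
        means = [sum(depth[i, j] for j in inds) / len(inds) for i in sites]
        q75, q25 = np.percentile(means, [75, 25])
        bound = np.mean(means) + depth_iqr_mult * (q75 - q25)
        new_sites = [i for i, m in zip(sites, means) if m <= bound]
        if len(new_sites) == len(sites):
            break
        sites = new_sites

    sites2 = [i for i in sites if maf(i) >= maf_min]
    return sites2, inds, g


# ----------------------------------------------------------------- exact HWE


def hwe_exact_distribution(n_het_obs, n_hom1, n_hom2):
    """Exact HWE P by direct factorial enumeration of heterozygote counts."""
    n = n_het_obs + n_hom1 + n_hom2
    n_rare = 2 * min(n_hom1, n_hom2) + n_het_obs
    n_common = 2 * n - n_rare
    probs = {}
    for het in range(n_rare % 2, n_rare + 1, 2):
        hom_rare = (n_rare - het) // 2
        hom_common = (n_common - het) // 2
        if hom_common < 0:
            continue
        p = (math.factorial(n) / (math.factorial(hom_rare) * math.factorial(het)
                                  * math.factorial(hom_common))
             * 2 ** het
             * math.factorial(n_rare) * math.factorial(n_common) / math.factorial(2 * n))
        probs[het] = p
    obs = probs[n_het_obs]
    return min(1.0, sum(p for p in probs.values() if p <= obs * (1 + 1e-12)))


# ----------------------------------------------------------------- ANOVA


def anova_f_oracle(g, y):
    """One-way ANOVA F via statsmodels OLS (independent of the package path)."""
    import pandas as pd
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    keep = np.asarray(g) != MISSING
    d = pd.DataFrame({"y": np.asarray(y, float)[keep],
                      "g": np.asarray(g)[keep].astype(str)})
    if d["g"].nunique() < 2:
        return None
    fit = smf.ols("y ~ C(g)", data=d).fit()
    table = sm.stats.anova_lm(fit, typ=1)
    return float(table["F"].iloc[0]), int(table["df"].iloc[0])


# ----------------------------------------------------------------- permutation


def exact_het_perm_p(het_flags, n_males):
    """Exact one-sided P for the heterozygote difference by full enumeration.

    ``het_flags``: per-individual heterozygosity at one site (no missing).
    Enumerates all assignments of ``n_males`` labels, orienting the tail by
    the observed difference (first n_males individuals are the males).
    """
    het = list(het_flags)
    n = len(het)
    obs_m = sum(het[:n_males]) / n_males
    obs_f = sum(het[n_males:]) / (n - n_males)
    d_obs = obs_m - obs_f
    count = total = 0
    for combo in itertools.combinations(range(n), n_males):
        males = set(combo)
        hm = sum(het[i] for i in males) / n_males
        hf = sum(het[i] for i in range(n) if i not in males) / (n - n_males)
        d = hm - hf
        total += 1
        if d_obs > 0 and d >= d_obs - 1e-12:
            count += 1
        elif d_obs < 0 and d <= d_obs + 1e-12:
            count += 1
        elif d_obs == 0:
            count += 1
    return count / total


# ----------------------------------------------------------------- dxy


def dxy_hand(gA, gB):
    """Mean pairwise allele difference between groups at one site, by looping
    over all allele-copy pairs. Genotypes coded 0/1/2/-1."""
    def alleles(gs):
        out = []
        for g in gs:
            if g == MISSING:
                continue
            out += [1] * g + [0] * (2 - g)
        return out

    a, b = alleles(gA), alleles(gB)
    if not a or not b:
        return None
    return sum(x != y for x in a for y in b) / (len(a) * len(b))


# ----------------------------------------------------------------- credible interval


def bayes_interval_oracle(lod, coverage=0.95):
    """Smallest contiguous index span containing the peak with >= coverage mass,
    by scanning every candidate interval."""
    lod = np.asarray(lod, dtype=float)
    post = 10.0 ** (lod - lod.max())
    post = post / post.sum()
    peak = int(np.argmax(post))
    best = None
    n = len(post)
    for lo in range(0, peak + 1):
        for hi in range(peak, n):
            if post[lo:hi + 1].sum() >= coverage:
                width = hi - lo
                if best is None or width < best[0]:
                    best = (width, lo, hi)
                break
    if best is None:
        return 0, n - 1
    return best[1], best[2]


# ----------------------------------------------------------------- run smoothing


def smooth_runs_oracle(v, max_run=3, flank=5):
    """Direct re-check of the run-replacement rule at every index window."""
    v = list(v)
    n = len(v)
    out = list(v)
    i = 0
    while i < n:
        j = i
        while j < n and v[j] == v[i]:
            j += 1
        run_len = j - i
        if run_len <= max_run and v[i] != MISSING:
            left = v[i - flank:i] if i - flank >= 0 else None
            right = v[j:j + flank] if j + flank <= n else None
            if (left is not None and right is not None
                    and len(set(left)) == 1 and len(set(right)) == 1
                    and left[0] == right[0] != MISSING
                    and left[0] != v[i]
                    # flanks must themselves be runs: adjacent values beyond the
                    # window must differ or the window is inside a longer run,
                    # which is fine (still >= flank equal neighbours)
                    ):
                out[i:j] = [left[0]] * run_len
        i = j
    return out
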