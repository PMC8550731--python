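"""Binary-trait association scans for phenotypic sex in an F2 intercross.

Two routes to the same question ("which chromosome carries the sex
determiner?"):

* single-marker regression: a one-way ANOVA of sex (coded 0/1) on the
  genotype factor at every marker, converted to a LOD score via
  ``LOD = (n/2) * log10(F * df / (n - df - 1) + 1)`` and to the percentage
  of variance explained via ``PVE = (1 - 10^(-2 LOD / n)) * 100``, with
  Bonferroni correction across markers;
* standard interval mapping with a binary single-QTL model: conditional
  genotype probabilities from a hidden-Markov chain over the intercross
  genotypes (states hom/het/hom, transitions from the map function,
  symmetric genotyping-error emissions) on a fixed-step pseudomarker grid,
  then a maximum-likelihood binary model fitted by EM at every position.
  Genome-wide significance thresholds come from permutations of the sex
  labels, and localisation from 95% Bayesian credible intervals on the
  10^LOD posterior.

Also here: the exact binomial sex-ratio test and the cM -> bp smoothing
spline used to place unmapped positions on physical coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import GenotypeTable, PedigreeTable, MISSING
from .maps import map_function

__all__ = [
    "anova_lod",
    "lod_from_f",
    "pve_from_lod",
    "bonferroni",
    "marker_regression_scan",
    "LinkageMap",
    "conditional_genotype_probs",
    "interval_scan_binary",
    "genome_scan_binary",
    "permutation_threshold",
    "bayes_interval",
    "binomial_sex_ratio_test",
    "cm_bp_interpolate",
]

LOD_CAP = 50.0  # complete-separation cap for the binary model


def lod_from_f(F: float, n: int, df: int) -> float:
    """LOD score from an ANOVA F statistic: (n/2) * log10(F * df/(n - df - 1) + 1)."""
    if n - df - 1 <= 0:
        return 0.0
    return (n / 2.0) * np.log10(F * df / (n - df - 1) + 1.0)


def pve_from_lod(lod: float, n: int) -> float:
    """Percentage of phenotypic variance explained: (1 - 10^(-2 LOD / n)) * 100."""
    return (1.0 - 10.0 ** (-2.0 * np.asarray(lod, dtype=float) / n)) * 100.0


def anova_lod(genotypes: np.ndarray, sex01: np.ndarray):
    """One-way ANOVA of binary sex on the genotype factor at one site.

    Missing genotypes are dropped. Returns ``(F, df, n, lod, pve, p)``;
    with fewer than two genotype classes the site is degenerate and
    ``lod = 0`` by convention (F and p are NaN).
    """
    g = np.asarray(genotypes)
    y = np.asarray(sex01, dtype=float)
    keep = g != MISSING
    g, y = g[keep], y[keep]
    n = len(y)
    classes = np.unique(g)
    k = len(classes)
    if k < 2 or n <= k:
        return np.nan, max(k - 1, 0), n, 0.0, 0.0, np.nan
    grand = y.mean()
    ssb = ssw = 0.0
    for c in classes:
        yc = y[g == c]
        ssb += len(yc) * (yc.mean() - grand) ** 2
        ssw += ((yc - yc.mean()) ** 2).sum()
    df = k - 1
    df_err = n - k
    if ssw <= 0:
        # perfect separation by genotype: F is infinite; cap the LOD
        return np.inf, df, n, LOD_CAP, float(pve_from_lod(LOD_CAP, n)), 0.0
    F = (ssb / df) / (ssw / df_err)
    p = float(stats.f.sf(F, df, df_err))
    lod = float(lod_from_f(F, n, df))
    return float(F), df, n, lod, float(pve_from_lod(lod, n)), p


def bonferroni(p: np.ndarray) -> np.ndarray:
    """Bonferroni adjustment: min(1, p * m) over the supplied family of tests."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one P value")
    return np.minimum(1.0, p * p.size)


def marker_regression_scan(gt: GenotypeTable, ped: PedigreeTable,
                           family: str | None = None,
                           family_covariate: bool = False) -> pd.DataFrame:
    """Single-marker ANOVA scan over all sites for the F2 of one (or all) families.

    With ``family_covariate=True`` the genotype effect is tested after an
    additive family term (extra-sum-of-squares F test).
    """
    f2 = ped.subset(generation="F2", family=family)
    f2 = f2[f2["sex"].isin(["M", "F"])]
    ids = [s for s in f2["sample_id"] if s in set(gt.samples)]
    cols = gt.sample_index(ids)
    y = (f2.set_index("sample_id").loc[ids, "sex"] == "M").to_numpy(dtype=float)
    fam_labels = f2.set_index("sample_id").loc[ids, "family"].to_numpy()

    rows = []
    for i in range(gt.n_sites):
        g = gt.gt[i, cols]
        if family_covariate:
            F, df, n, lod, pve, p = _anova_with_covariate(g, y, fam_labels)
        else:
            F, df, n, lod, pve, p = anova_lod(g, y)
        rows.append((i, F, df, n, lod, pve, p))
    out = pd.DataFrame(rows, columns=["site", "F", "df", "n", "lod", "pve", "p"])
    out["chrom"] = gt.markers["chrom"].values
    out["bp"] = gt.markers["bp"].values
    valid = out["p"].notna()
    out["p_bonf"] = np.nan
    if valid.any():
        out.loc[valid, "p_bonf"] = bonferroni(out.loc[valid, "p"].to_numpy())
    return out


def _anova_with_covariate(g, y, fam):
    keep = g != MISSING
    g, y, fam = g[keep], y[keep], fam[keep]
    n = len(y)
    classes = np.unique(g)
    k = len(classes)
    if k < 2 or n <= k + 1:
        return np.nan, max(k - 1, 0), n, 0.0, 0.0, np.nan

    def design(with_geno: bool):
        cols = [np.ones(n)]
        for f in np.unique(fam)[1:]:
            cols.append((fam == f).astype(float))
        if with_geno:
            for c in classes[1:]:
                cols.append((g == c).astype(float))
        return np.column_stack(cols)

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r), X.shape[1]

    rss0, p0 = rss(design(False))
    rss1, p1 = rss(design(True))
    df = p1 - p0
    df_err = n - p1
    if df_err <= 0 or rss1 <= 1e-12:
        return np.inf, df, n, LOD_CAP, float(pve_from_lod(LOD_CAP, n)), 0.0
    F = ((rss0 - rss1) / df) / (rss1 / df_err)
    p = float(stats.f.sf(F, df, df_err))
    lod = float(lod_from_f(F, n, df))
    return float(F), df, n, lod, float(pve_from_lod(lod, n)), p


# --------------------------------------------------------------------- interval mapping


@dataclass
class LinkageMap:
    """Marker map for interval mapping: chrom, marker_id, bp, cM per marker."""

    markers: pd.DataFrame
    map_function: str = "kosambi"
    step_cM: float = 1.0
    genotyping_error_rate: float = 0.05

    def __post_init__(self):
        need = {"chrom", "marker_id", "bp", "cM"}
        if not need.issubset(self.markers.columns):
            raise ValueError(f"map needs columns {sorted(need)}")
        for chrom, sub in self.markers.groupby("chrom", sort=False):
            cm = sub["cM"].to_numpy()
            bp = sub["bp"].to_numpy()
            if np.any(np.diff(cm) < 0):
                raise ValueError(f"cM positions must be non-decreasing on {chrom}")
            if np.any(np.diff(bp) <= 0):
                raise ValueError(f"bp positions must be strictly increasing on {chrom}")

    def chromosomes(self) -> list:
        return list(dict.fromkeys(self.markers["chrom"]))


def _transition(r: float) -> np.ndarray:
    """F2 intercross genotype transition matrix for recombination fraction r."""
    s, t = 1.0 - r, r
    return np.array([
        [s * s, 2 * s * t, t * t],
        [s * t, s * s + t * t, s * t],
        [t * t, 2 * s * t, s * s],
    ])


def conditional_genotype_probs(genotypes: np.ndarray, cm: np.ndarray,
                               step_cM: float = 1.0,
                               error_rate: float = 0.05,
                               map_function_name: str = "kosambi"):
    """Forward-backward genotype probabilities on a pseudomarker grid (one chromosome).

    ``genotypes``: (n_markers, n_ind) coded 0/1/2/-1. Returns
    ``(positions, is_marker, probs)`` where ``probs`` has shape
    (n_positions, n_ind, 3) and rows sum to 1.
    """
    cm = np.asarray(cm, dtype=float)
    if np.any(np.diff(cm) < 0):
        raise ValueError("marker cM positions must be non-decreasing")
    g = np.asarray(genotypes)
    n_mark, n_ind = g.shape
    if n_mark != len(cm):
        raise ValueError("genotypes and cm must agree on the number of markers")

    grid = np.arange(cm[0], cm[-1] + 1e-9, step_cM) if cm[-1] > cm[0] else np.array([cm[0]])
    pos = np.unique(np.concatenate([cm, grid]))
    marker_at = {}
    for j, x in enumerate(cm):
        k = int(np.argmin(np.abs(pos - x)))
        marker_at.setdefault(k, []).append(j)
    is_marker = np.zeros(len(pos), dtype=bool)
    is_marker[list(marker_at)] = True

    e = error_rate
    emit_lookup = np.full((4, 3), 1.0)  # rows: missing, obs0, obs1, obs2
    for obs in range(3):
        for true in range(3):
            emit_lookup[obs + 1, true] = 1.0 - e if obs == true else e / 2.0

    rfun = map_function(map_function_name)
    P = len(pos)
    trans = [_transition(float(rfun(pos[k + 1] - pos[k]))) for k in range(P - 1)]

    def emission(k: int) -> np.ndarray:
        out = np.ones((n_ind, 3))
        for j in marker_at.get(k, []):
            out *= emit_lookup[g[j] + 1]
        return out

    prior = np.array([0.25, 0.5, 0.25])
    alpha = np.empty((P, n_ind, 3))
    scale = np.empty((P, n_ind))
    a = prior * emission(0)
    scale[0] = a.sum(axis=1)
    alpha[0] = a / scale[0][:, None]
    for k in range(1, P):
        a = (alpha[k - 1] @ trans[k - 1]) * emission(k)
        scale[k] = a.sum(axis=1)
        alpha[k] = a / scale[k][:, None]
    beta = np.empty((P, n_ind, 3))
    beta[-1] = 1.0
    for k in range(P - 2, -1, -1):
        b = (beta[k + 1] * emission(k + 1)) @ trans[k].T
        beta[k] = b / b.sum(axis=1, keepdims=True)
    probs = alpha * beta
    probs /= probs.sum(axis=2, keepdims=True)
    return pos, is_marker, probs


def _binary_model_lod(probs: np.ndarray, y: np.ndarray, max_iter: int = 60,
                      tol: float = 1e-8):
    """EM fit of the binary single-QTL model at many positions at once.

    ``probs``: (P, N, 3) genotype probabilities; ``y``: (N,) binary.
    Likelihood per individual: sum_k p_ik * pi_k^y (1-pi_k)^(1-y).
    Returns (lod (P,), separation flag (P,)).
    """
    Ppos, N, _ = probs.shape
    y = np.asarray(y, dtype=float)
    p1 = y.mean()
    p1 = min(max(p1, 1e-12), 1 - 1e-12)
    ll0 = y.sum() * np.log(p1) + (N - y.sum()) * np.log(1 - p1)

    denom = probs.sum(axis=1)
    pi = (probs * y[None, :, None]).sum(axis=1) / np.maximum(denom, 1e-12)
    lo, hi = 1e-6, 1 - 1e-6
    pi = np.clip(pi, lo, hi)
    ll_old = np.full(Ppos, -np.inf)
    for _ in range(max_iter):
        lik = probs * np.where(y[None, :, None] > 0.5, pi[:, None, :], 1 - pi[:, None, :])
        L = lik.sum(axis=2)  # (P, N)
        ll = np.log(np.maximum(L, 1e-300)).sum(axis=1)
        w = lik / np.maximum(L[:, :, None], 1e-300)
        wsum = w.sum(axis=1)
        pi = np.clip((w * y[None, :, None]).sum(axis=1) / np.maximum(wsum, 1e-12), lo, hi)
        if np.all(np.abs(ll - ll_old) < tol):
            ll_old = ll
            break
        ll_old = ll
    lod = (ll_old - ll0) / np.log(10.0)
    lod = np.maximum(lod, 0.0)
    separated = (pi <= lo + 1e-12).any(axis=1) | (pi >= hi - 1e-12).any(axis=1)
    lod = np.minimum(lod, LOD_CAP)
    return lod, separated


def interval_scan_binary(probs: np.ndarray, y: np.ndarray) -> np.ndarray:
    """LOD scores of the binary model at each position of a probability grid."""
    lod, _ = _binary_model_lod(probs, y)
    return lod


def genome_scan_binary(gt: GenotypeTable, lmap: LinkageMap, ped: PedigreeTable,
                       family: str | None = None) -> pd.DataFrame:
    """Interval-mapping scan over all chromosomes of a linkage map.

    Returns one row per marker/pseudomarker position with chrom, cM,
    interpolated bp, LOD, PVE and a separation flag.
    """
    f2 = ped.subset(generation="F2", family=family)
    f2 = f2[f2["sex"].isin(["M", "F"])]
    ids = [s for s in f2["sample_id"] if s in set(gt.samples)]
    cols = gt.sample_index(ids)
    y = (f2.set_index("sample_id").loc[ids, "sex"] == "M").to_numpy(dtype=float)

    marker_pos = {m: i for i, m in enumerate(gt.markers["marker_id"])}
    rows = []
    for chrom in lmap.chromosomes():
        sub = lmap.markers[lmap.markers["chrom"] == chrom]
        have = sub[sub["marker_id"].isin(marker_pos)]
        if len(have) == 0:
            continue
        sites = np.array([marker_pos[m] for m in have["marker_id"]])
        cm = have["cM"].to_numpy(dtype=float)
        order = np.argsort(cm, kind="stable")
        sites, cm = sites[order], cm[order]
        g = gt.gt[np.ix_(sites, cols)]
        pos, is_marker, probs = conditional_genotype_probs(
            g, cm, lmap.step_cM, lmap.genotyping_error_rate, lmap.map_function)
        lod, sep = _binary_model_lod(probs, y)
        bp_pred = np.interp(pos, cm, have["bp"].to_numpy(dtype=float)[order])
        for k in range(len(pos)):
            rows.append((chrom, pos[k], bp_pred[k], not is_marker[k], lod[k],
                         float(pve_from_lod(lod[k], len(y))), sep[k]))
    return pd.DataFrame(rows, columns=["chrom", "cM", "bp", "is_pseudomarker",
                                       "lod", "pve", "separation"])


def permutation_threshold(gt: GenotypeTable, lmap: LinkageMap, ped: PedigreeTable,
                          n_perm: int = 1000, alphas=(0.05, 0.1),
                          seed: int | None = None,
                          family: str | None = None) -> dict:
    """Genome-wide LOD thresholds from permutations of the sex labels.

    Returns ``{alpha: threshold}`` at the 1 - alpha quantiles of the maximum
    genome-wide LOD under the permutation null.
    """
    f2 = ped.subset(generation="F2", family=family)
    f2 = f2[f2["sex"].isin(["M", "F"])]
    ids = [s for s in f2["sample_id"] if s in set(gt.samples)]
    cols = gt.sample_index(ids)
    y = (f2.set_index("sample_id").loc[ids, "sex"] == "M").to_numpy(dtype=float)
    rng = np.random.default_rng(seed)

    # precompute probability grids once per chromosome
    marker_pos = {m: i for i, m in enumerate(gt.markers["marker_id"])}
    grids = []
    for chrom in lmap.chromosomes():
        sub = lmap.markers[lmap.markers["chrom"] == chrom]
        have = sub[sub["marker_id"].isin(marker_pos)]
        if len(have) == 0:
            continue
        sites = np.array([marker_pos[m] for m in have["marker_id"]])
        cm = have["cM"].to_numpy(dtype=float)
        order = np.argsort(cm, kind="stable")
        g = gt.gt[np.ix_(sites[order], cols)]
        _, _, probs = conditional_genotype_probs(
            g, cm[order], lmap.step_cM, lmap.genotyping_error_rate, lmap.map_function)
        grids.append(probs)
    if not grids:
        raise ValueError("no map markers found in the genotype table")

    max_lod = np.empty(n_perm)
    for b in range(n_perm):
        yp = rng.permutation(y)
        best = 0.0
        for probs in grids:
            lod, _ = _binary_model_lod(probs, yp)
            best = max(best, float(lod.max()))
        max_lod[b] = best
    return {a: float(np.quantile(max_lod, 1.0 - a)) for a in alphas}


def bayes_interval(scan: pd.DataFrame, chrom: str, coverage: float = 0.95):
    """95% Bayesian credible interval for the QTL position on one chromosome.

    Normalises 10^LOD over the chromosome's scan positions as a posterior
    and returns the smallest contiguous span that contains the peak and at
    least ``coverage`` of the mass (exact search); endpoints are then
    expanded outward to the nearest true markers (when any exist beyond
    them).
    """
    sub = scan[scan["chrom"] == chrom].sort_values("cM").reset_index(drop=True)
    if len(sub) == 0:
        raise ValueError(f"no scan positions on {chrom}")
    lod = sub["lod"].to_numpy(dtype=float)
    post = 10.0 ** (lod - lod.max())
    post /= post.sum()
    peak = int(np.argmax(post))
    n = len(post)
    cum = np.concatenate([[0.0], np.cumsum(post)])
    # exact smallest contiguous span containing the peak with >= coverage mass
    best = (n - 1, 0, n - 1)
    hi = peak
    for lo in range(0, peak + 1):
        while hi < n and cum[hi + 1] - cum[lo] < coverage - 1e-12:
            hi += 1
        if hi >= n:
            break
        if hi - lo < best[0]:
            best = (hi - lo, lo, hi)
    _, lo, hi = best
    if "is_pseudomarker" in sub.columns:
        markers = np.flatnonzero(~sub["is_pseudomarker"].to_numpy(dtype=bool))
        before = markers[markers <= lo]
        after = markers[markers >= hi]
        if len(before):
            lo = int(before[-1])
        if len(after):
            hi = int(after[0])
    return float(sub["cM"].iloc[lo]), float(sub["cM"].iloc[hi])


def binomial_sex_ratio_test(n_males: int, n_females: int) -> float:
    """Exact two-sided binomial P for a deviation from a 1:1 sex ratio."""
    n = n_males + n_females
    if n < 1:
        raise ValueError("need at least one individual")
    return float(stats.binomtest(n_males, n, 0.5, alternative="two-sided").pvalue)


def cm_bp_interpolate(map_df: pd.DataFrame):
    """Per-chromosome smooth predictors bp(cM), fitted on mapped markers.

    A cubic smoothing spline (generalised cross-validation picks the
    penalty) per chromosome; predictions are clipped to the mapped bp range
    and made non-decreasing along cM. Chromosomes with fewer than 5 markers
    fall back to linear interpolation. Returns ``{chrom: callable}``.
    """
    from scipy.interpolate import make_smoothing_spline

    predictors = {}
    for chrom, sub in map_df.groupby("chrom", sort=False):
        sub = sub.sort_values("cM")
        cm = sub["cM"].to_numpy(dtype=float)
        bp = sub["bp"].to_numpy(dtype=float)
        cm_u, idx = np.unique(cm, return_index=True)
        bp_u = np.array([bp[cm == x].mean() for x in cm_u])
        lo_bp, hi_bp = bp.min(), bp.max()
        if len(cm_u) >= 5:
            spl = make_smoothing_spline(cm_u, bp_u)

            def predict(x, _spl=spl, _lo=lo_bp, _hi=hi_bp):
                x = np.atleast_1d(np.asarray(x, dtype=float))
                order = np.argsort(x, kind="stable")
                vals = np.clip(_spl(x[order]), _lo, _hi)
                vals = np.maximum.accumulate(vals)
                out = np.empty_like(vals)
                out[order] = vals
                return out
        else:
            def predict(x, _cm=cm_u, _bp=bp_u, _lo=lo_bp, _hi=hi_bp):
                return np.clip(np.interp(np.atleast_1d(x), _cm, _bp), _lo, _hi)
        predictors[chrom] = predict
    return predictors
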