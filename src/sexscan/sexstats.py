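"""Sex-contrasted per-site genotype statistics.

Three complementary signals identify a sex-determining chromosome in an F2
intercross:

* the frequency of the grandpaternal homozygous genotype among F2 males vs
  females at species-diagnostic, F1-heterozygous sites (expected 25%/25%
  at autosomes; 50% in males and 0% in females at a fully sex-linked
  locus in an XY system);
* the difference in heterozygote proportion between the sexes
  (``het_diff = h_m - h_f``), positive at Y-linked variants (XY) and
  negative at W-linked variants (ZW), with significance from an empirical
  permutation test of the sex labels;
* female/male read-depth ratios in large windows, which would reveal a
  degenerated (missing) Y or W.

The permutation test shuffles the sex labels jointly across all sites per
replicate and counts, per site and one-sided in the direction of the
observed difference, how many permuted differences are as extreme or more
extreme (ties count as extreme). A site is flagged significant when at most
``max_extreme`` (default 1) of the permutations reach the observed value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GenotypeTable, PedigreeTable, MISSING

__all__ = [
    "punnett_gp_freq",
    "grandpaternal_genotype_freq",
    "het_freq_diff",
    "permutation_test",
    "HeterogametyCall",
    "call_heterogamety",
    "depth_ratio_windows",
]


def punnett_gp_freq(sex_linked: bool, system: str = "XY") -> dict:
    """Expected grandpaternal-homozygote frequency per sex by Punnett enumeration.

    Enumerates the four F1 gamete combinations at a species-diagnostic locus
    (grandmother alleles 'A', grandfather alleles 'B'). At an autosomal locus
    each combination occurs in both sexes; at a fully sex-linked locus the
    determiner-carrying gamete fixes the offspring sex.
    """
    if system == "XY":
        dam_gametes = [("A", False), ("B", False)]          # X_A, X_B
        sire_gametes = [("A", False), ("B", True)]          # X_A, Y_B
        det_sex = "M"
    elif system == "ZW":
        dam_gametes = [("A", True), ("B", False)]           # W_A, Z_B
        sire_gametes = [("A", False), ("B", False)]         # Z_A, Z_B
        det_sex = "F"
    else:
        raise ValueError("system must be XY or ZW")
    if not sex_linked:
        dam_gametes = [(a, False) for a, _ in dam_gametes]
        sire_gametes = [(a, False) for a, _ in sire_gametes]
    counts = {"M": [0, 0], "F": [0, 0]}  # sex -> [n_offspring, n_grandpaternal_hom]
    for da, d_det in dam_gametes:
        for sa, s_det in sire_gametes:
            gp_hom = da == "B" and sa == "B"
            if sex_linked:
                sex = det_sex if (d_det or s_det) else ("F" if det_sex == "M" else "M")
                sexes = [sex]
            else:
                sexes = ["M", "F"]
            for sex in sexes:
                counts[sex][0] += 1
                counts[sex][1] += int(gp_hom)
    return {sex: n_gp / n for sex, (n, n_gp) in counts.items()}


def _sex_columns(gt: GenotypeTable, ped: PedigreeTable):
    in_table = set(gt.samples)
    males = gt.sample_index([s for s in ped.f2_males() if s in in_table])
    females = gt.sample_index([s for s in ped.f2_females() if s in in_table])
    return males, females


def _freq(g: np.ndarray, cols: np.ndarray, value: int):
    sub = g[:, cols]
    nonmiss = (sub != MISSING).sum(axis=1)
    hits = (sub == value).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(nonmiss > 0, hits / np.maximum(nonmiss, 1), np.nan)
    return freq, nonmiss


def grandpaternal_genotype_freq(gt: GenotypeTable, ped: PedigreeTable,
                                sites=None) -> pd.DataFrame:
    """Frequency of the grandfather-species homozygote (code 2) per F2 sex.

    Genotypes must already be polarized so code 2 is the grandpaternal
    homozygote. A sex with zero non-missing genotypes at a site yields NaN
    (undefined), not 0.
    """
    sites = np.arange(gt.n_sites) if sites is None else np.asarray(sites)
    males, females = _sex_columns(gt, ped)
    g = gt.gt[sites]
    fm, nm = _freq(g, males, 2)
    ff, nf = _freq(g, females, 2)
    return pd.DataFrame({
        "site": sites,
        "chrom": gt.markers["chrom"].values[sites],
        "bp": gt.markers["bp"].values[sites],
        "freq_gp_m": fm, "freq_gp_f": ff, "n_m": nm, "n_f": nf,
    })


def het_freq_diff(gt: GenotypeTable, ped: PedigreeTable, sites=None) -> pd.DataFrame:
    """Per-site heterozygote proportion among F2 males and females and their difference."""
    sites = np.arange(gt.n_sites) if sites is None else np.asarray(sites)
    males, females = _sex_columns(gt, ped)
    g = gt.gt[sites]
    hm, nm = _freq(g, males, 1)
    hf, nf = _freq(g, females, 1)
    return pd.DataFrame({
        "site": sites,
        "chrom": gt.markers["chrom"].values[sites],
        "bp": gt.markers["bp"].values[sites],
        "h_m": hm, "h_f": hf, "het_diff": hm - hf, "n_m": nm, "n_f": nf,
    })


def permutation_test(gt: GenotypeTable, ped: PedigreeTable, sites=None,
                     n_perm: int = 10_000, seed: int | None = None,
                     max_extreme: int = 1, chunk: int = 2_000) -> pd.DataFrame:
    """Empirical one-sided permutation P for the heterozygote-frequency difference.

    One shuffled sex-label vector per replicate is shared across all sites
    (per-site missingness is preserved because proportions are computed over
    each site's non-missing genotypes). The one-sided tail is oriented by the
    observed sign of ``het_diff``; ties count as extreme. ``p_emp`` carries
    the +1 pseudo-count correction for ranking; the ``significant`` flag uses
    the raw rule "at most ``max_extreme`` of ``n_perm`` as extreme".
    """
    sites = np.arange(gt.n_sites) if sites is None else np.asarray(sites)
    males, females = _sex_columns(gt, ped)
    if len(males) < 2 or len(females) < 2:
        raise ValueError("need at least two F2 individuals of each sex")
    obs = het_freq_diff(gt, ped, sites)
    d_obs = obs["het_diff"].to_numpy()

    cols = np.concatenate([males, females])
    g = gt.gt[np.ix_(sites, cols)]
    H = ((g == 1)).astype(np.float32)
    V = (g != MISSING).astype(np.float32)
    n_m = len(males)
    n_tot = len(cols)
    rng = np.random.default_rng(seed)
    Hs = H.sum(axis=1, keepdims=True)
    Vs = V.sum(axis=1, keepdims=True)

    n_extreme = np.zeros(len(sites), dtype=np.int64)
    eps = 1e-4  # well below the 1/n granularity of heterozygote proportions
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        # permutation matrix: column = one shuffled male-indicator vector
        M = np.empty((n_tot, b), dtype=np.float32)
        for j in range(b):
            pick = rng.permutation(n_tot)[:n_m]
            col = np.zeros(n_tot, dtype=np.float32)
            col[pick] = 1.0
            M[:, j] = col
        HM = H @ M
        VM = V @ M
        with np.errstate(invalid="ignore", divide="ignore"):
            h_m = HM / VM
            h_f = (Hs - HM) / (Vs - VM)
        diff = h_m - h_f
        pos = d_obs > eps
        neg = d_obs < -eps
        with np.errstate(invalid="ignore"):
            n_extreme[pos] += np.nansum(diff[pos] >= (d_obs[pos, None] - eps), axis=1)
            n_extreme[neg] += np.nansum(diff[neg] <= (d_obs[neg, None] + eps), axis=1)
        n_extreme[~(pos | neg)] += b  # het_diff == 0 (or undefined): everything is as extreme
        done += b

    obs = obs.copy()
    obs["n_extreme"] = n_extreme
    obs["p_emp"] = (1.0 + n_extreme) / (1.0 + n_perm)
    obs["significant"] = n_extreme <= max_extreme
    obs.loc[~np.isfinite(d_obs), ["p_emp"]] = np.nan
    obs.loc[~np.isfinite(d_obs), "significant"] = False
    return obs


@dataclass
class HeterogametyCall:
    """Per-chromosome heterogamety verdict from significant het-diff sites."""

    chromosome: str
    n_significant: int
    n_positive: int
    n_negative: int
    direction: str  # XY | ZW | none
    supporting_sites: np.ndarray


def call_heterogamety(perm_stats: pd.DataFrame, min_sites: int = 3,
                      min_share: float = 0.8) -> list[HeterogametyCall]:
    """Call XY/ZW per chromosome from permutation-significant sites.

    A chromosome is called XY (ZW) when at least ``min_sites`` significant
    sites exist and at least ``min_share`` of them have positive (negative)
    ``het_diff``; otherwise 'none'.
    """
    calls = []
    for chrom, sub in perm_stats.groupby("chrom", sort=False):
        sig = sub[sub["significant"]]
        n_pos = int((sig["het_diff"] > 0).sum())
        n_neg = int((sig["het_diff"] < 0).sum())
        n_sig = len(sig)
        direction = "none"
        if n_sig >= min_sites:
            if n_pos / n_sig >= min_share:
                direction = "XY"
            elif n_neg / n_sig >= min_share:
                direction = "ZW"
        calls.append(HeterogametyCall(chrom, n_sig, n_pos, n_neg, direction,
                                      sig["site"].to_numpy()))
    return calls


def best_heterogamety_call(calls: list[HeterogametyCall]) -> HeterogametyCall | None:
    """The directional call with the most significant sites, if any."""
    directional = [c for c in calls if c.direction != "none"]
    if not directional:
        return None
    return max(directional, key=lambda c: c.n_significant)


def depth_ratio_windows(gt: GenotypeTable, ped: PedigreeTable,
                        window_bp: int = 5_000_000) -> pd.DataFrame:
    """Female/male mean-depth ratio in half-open genomic windows.

    Per site the mean depth over F2 individuals of each sex is computed; per
    window the site values are averaged and the female/male ratio reported.
    Windows without sites are omitted; a degenerate Y (W) produces ratios
    above (below) 1 at the affected span.
    """
    males, females = _sex_columns(gt, ped)
    dm = gt.depth[:, males].mean(axis=1)
    df_ = gt.depth[:, females].mean(axis=1)
    win = (gt.markers["bp"].values - 1) // window_bp
    tab = pd.DataFrame({
        "chrom": gt.markers["chrom"].values,
        "window": win, "depth_m": dm, "depth_f": df_,
    })
    out = (tab.groupby(["chrom", "window"], sort=False)
           .agg(n_sites=("depth_m", "size"), depth_m=("depth_m", "mean"),
                depth_f=("depth_f", "mean"))
           .reset_index())
    out["start"] = out["window"] * window_bp + 1
    out["end"] = (out["window"] + 1) * window_bp
    with np.errstate(invalid="ignore", divide="ignore"):
        out["ratio_fm"] = np.where(out["depth_m"] > 0, out["depth_f"] / out["depth_m"], np.nan)
    return out[["chrom", "start", "end", "n_sites", "depth_f", "depth_m", "ratio_fm"]]
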