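"""Windowed per-individual heterozygosity and between-group divergence (dxy).

Used to quantify how diverged Y is from X (or W from Z): individuals
carrying two different sex chromosomes show elevated heterozygosity on the
sex chromosome relative to homogametic individuals, and dxy between groups
of individuals measures between-lineage divergence on the same scale.

Site filters (in order): sites with more than 25% missing data removed,
genotypes with fewer than 10 reads set missing, SNPs whose minor allele is
seen only once or twice (likely sequencing errors) removed.

Proportions are per genotyped SNP by default; a per-window callable-site
count can be supplied so values are per sequenced position (SNP-only
call sets cannot provide that denominator themselves).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import GenotypeTable, PedigreeTable, MISSING

__all__ = [
    "divergence_site_filter",
    "individual_heterozygosity_windows",
    "dxy_windows",
]


def divergence_site_filter(gt: GenotypeTable, max_missing: float = 0.25,
                           min_depth: int = 10, min_copies: int = 3) -> GenotypeTable:
    """Apply the divergence-analysis site filters (missingness, depth, rare copies)."""
    keep = (gt.gt == MISSING).mean(axis=1) <= max_missing
    out = gt.take_sites(keep)
    out.gt[out.depth < min_depth] = MISSING
    nonmiss = out.gt != MISSING
    alt = np.where(nonmiss, out.gt, 0).sum(axis=1)
    total = 2 * nonmiss.sum(axis=1)
    minor = np.minimum(alt, total - alt)
    variant = (alt > 0) & (alt < total)
    # monomorphic sites pass (they carry no allele-count evidence of error)
    keep2 = ~variant | (minor >= min_copies)
    return out.take_sites(keep2)


def _windows_of(gt: GenotypeTable, window_bp: int):
    win = (gt.markers["bp"].values - 1) // window_bp
    return gt.markers["chrom"].values, win


def individual_heterozygosity_windows(gt: GenotypeTable, individual: str,
                                      window_bp: int = 1_000_000,
                                      callable_sites: pd.DataFrame | None = None) -> pd.DataFrame:
    """Heterozygous proportion per half-open window for one individual.

    Denominator: the individual's non-missing genotyped sites in the window,
    or (if ``callable_sites`` with columns chrom/start/n_callable is given)
    the callable-position count, making the value a per-sequenced-position
    heterozygosity. Windows with zero sites are omitted.
    """
    j = gt.sample_index([individual])[0]
    g = gt.gt[:, j]
    chroms, win = _windows_of(gt, window_bp)
    tab = pd.DataFrame({"chrom": chroms, "window": win,
                        "het": (g == 1), "nonmiss": (g != MISSING)})
    out = (tab.groupby(["chrom", "window"], sort=False)
           .agg(n_sites=("nonmiss", "sum"), n_het=("het", "sum"))
           .reset_index())
    out["start"] = out["window"] * window_bp + 1
    out["end"] = (out["window"] + 1) * window_bp
    if callable_sites is not None:
        merged = out.merge(callable_sites, on=["chrom", "start"], how="left")
        denom = merged["n_callable"].to_numpy(dtype=float)
    else:
        denom = out["n_sites"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out["heterozygosity"] = np.where(denom > 0, out["n_het"] / np.maximum(denom, 1), np.nan)
    out["individual"] = individual
    return out[["individual", "chrom", "start", "end", "n_sites", "n_het", "heterozygosity"]]


def dxy_windows(gt: GenotypeTable, group_a, group_b,
                window_bp: int = 1_000_000) -> pd.DataFrame:
    """Mean pairwise between-group allele difference per window.

    Per site, with alt-allele frequencies p_A and p_B over non-missing
    alleles, the between-group difference is p_A(1-p_B) + p_B(1-p_A); the
    window value is the mean over sites where both groups have data.
    Symmetric in the two groups.
    """
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    ca = gt.sample_index(group_a)
    cb = gt.sample_index(group_b)

    def freqs(cols):
        g = gt.gt[:, cols]
        nonmiss = g != MISSING
        alt = np.where(nonmiss, g, 0).sum(axis=1)
        total = 2 * nonmiss.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(total > 0, alt / np.maximum(total, 1), np.nan)

    pa, pb = freqs(ca), freqs(cb)
    d = pa * (1 - pb) + pb * (1 - pa)
    chroms, win = _windows_of(gt, window_bp)
    tab = pd.DataFrame({"chrom": chroms, "window": win, "dxy": d})
    tab = tab[np.isfinite(d)]
    out = (tab.groupby(["chrom", "window"], sort=False)
           .agg(n_sites=("dxy", "size"), dxy=("dxy", "mean"))
           .reset_index())
    out["start"] = out["window"] * window_bp + 1
    out["end"] = (out["window"] + 1) * window_bp
    return out[["chrom", "start", "end", "n_sites", "dxy"]]
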