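"""Site and individual filtering of intercross genotype data.

Implements the RAD-seq filter cascade used upstream of all analyses:
genotype-level depth masking, site missingness, individual mean-depth and
missingness thresholds, a site mean-depth IQR outlier rule, minor-allele
frequency and (F2-only) Hardy-Weinberg exact-test filters, plus the
ascertainment of species-diagnostic sites and of sites heterozygous in the
F1 parents.

Boundary semantics follow the thresholds as printed: missingness "> 50%"
strict, individual depth "< 12" strict, MAF "at least 0.05" inclusive,
HWE "P > 0.1" strict.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GenotypeTable, PedigreeTable, MISSING

log = logging.getLogger(__name__)

__all__ = [
    "FilterConfig",
    "EmptyTableError",
    "mask_low_depth",
    "filter_sites_individuals",
    "depth_iqr_site_filter",
    "maf_filter",
    "hwe_filter",
    "hwe_exact_p",
    "apply_filter_cascade",
    "correct_f0_allelic_balance",
    "select_f0_diagnostic_sites",
    "infer_f1_het_sites_by_af",
    "polarization_orientation",
    "polarize",
]


class EmptyTableError(ValueError):
    """All sites or all individuals were removed by a filter."""


@dataclass
class FilterConfig:
    """Thresholds of the filter cascade (defaults as used on RAD intercross data)."""

    site_max_missing: float = 0.5     # sites with MORE than this fraction missing are dropped
    ind_min_mean_depth: float = 12.0  # individuals with mean depth strictly below are dropped
    ind_max_missing: float = 0.5
    depth_iqr_mult: float = 1.5       # site mean depth upper bound: mean + mult * IQR
    gt_min_depth: int = 10            # genotypes with depth strictly below are set missing
    maf_min: float = 0.05             # inclusive
    hwe_p_min: float = 0.1            # strict: keep P > hwe_p_min (within F2 only)
    het_excess_max: float = 0.75      # paralog filter: drop sites with F2 het proportion above
    f1_het_af_band: tuple = (0.45, 0.55)

    def __post_init__(self):
        for name in ("site_max_missing", "ind_max_missing", "maf_min", "hwe_p_min", "het_excess_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.f1_het_af_band
        if not 0.0 <= lo <= hi <= 1.0:
            raise ValueError("f1_het_af_band must be an ordered sub-interval of [0, 1]")


# ------------------------------------------------------------------ elementwise / site filters


def mask_low_depth(gt: GenotypeTable, min_depth: int = 10) -> GenotypeTable:
    """Set genotypes with depth strictly below ``min_depth`` to missing."""
    out = gt.copy()
    out.gt[out.depth < min_depth] = MISSING
    return out


def _site_missing_fraction(gt: GenotypeTable) -> np.ndarray:
    return (gt.gt == MISSING).mean(axis=1)


def filter_sites_individuals(gt: GenotypeTable, cfg: FilterConfig) -> GenotypeTable:
    """Site missingness -> individual depth/missingness -> site missingness again -> MAF.

    Mirrors the sequential narrative of the cascade; raises
    :class:`EmptyTableError` if nothing survives.
    """
    keep_sites = _site_missing_fraction(gt) <= cfg.site_max_missing
    if not keep_sites.any():
        raise EmptyTableError("no site passes the missingness filter")
    gt = gt.take_sites(keep_sites)

    mean_depth = gt.depth.mean(axis=0)
    ind_missing = (gt.gt == MISSING).mean(axis=0)
    keep_ind = (mean_depth >= cfg.ind_min_mean_depth) & (ind_missing <= cfg.ind_max_missing)
    if not keep_ind.any():
        raise EmptyTableError("no individual passes the depth/missingness filter")
    gt = gt.take_samples([s for s, k in zip(gt.samples, keep_ind) if k])

    keep_sites = _site_missing_fraction(gt) <= cfg.site_max_missing
    gt = gt.take_sites(keep_sites)
    gt = maf_filter(gt, cfg.maf_min)
    if gt.n_sites == 0:
        raise EmptyTableError("no site passes the missingness/MAF re-filter")
    return gt


def depth_iqr_site_filter(gt: GenotypeTable, mult: float = 1.5) -> GenotypeTable:
    """Drop sites whose mean depth exceeds mean-of-site-means + ``mult`` x IQR.

    The rule is read as an (inclusive) upper bound of mean + mult * IQR on
    site mean depths, and is applied repeatedly until no further site is
    removed, so that the surviving set itself satisfies the bound and the
    filter (hence the whole cascade) is idempotent. With fewer than 4 sites
    the IQR is undefined and the table passes through with a warning.
    """
    if gt.n_sites < 4:
        warnings.warn("fewer than 4 sites: IQR undefined, depth filter skipped")
        return gt.copy()
    if not np.isfinite(mult):
        return gt.copy()
    # trim to a fixed point so the whole cascade is idempotent
    keep = np.ones(gt.n_sites, dtype=bool)
    site_means = gt.depth.mean(axis=1)
    while keep.sum() >= 4:
        m = site_means[keep]
        q75, q25 = np.percentile(m, [75, 25])
        bound = m.mean() + mult * (q75 - q25)
        new_keep = keep & (site_means <= bound)
        if new_keep.sum() == keep.sum():
            break
        keep = new_keep
    return gt.take_sites(keep)


def _allele_counts(gt: GenotypeTable, sample_idx=None):
    g = gt.gt if sample_idx is None else gt.gt[:, sample_idx]
    nonmiss = (g != MISSING)
    alt = np.where(nonmiss, g, 0).sum(axis=1)
    total = 2 * nonmiss.sum(axis=1)
    return alt, total


def maf_filter(gt: GenotypeTable, maf_min: float = 0.05) -> GenotypeTable:
    """Keep sites with minor allele frequency >= ``maf_min`` (non-missing alleles)."""
    alt, total = _allele_counts(gt)
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(total > 0, alt / np.maximum(total, 1), np.nan)
    maf = np.minimum(af, 1.0 - af)
    return gt.take_sites(np.nan_to_num(maf, nan=-1.0) >= maf_min)


def hwe_exact_p(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Two-sided exact Hardy-Weinberg test P value for one site.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts no more probable than the observed one (the
    standard exact HWE formulation for SNPs).
    """
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        return 1.0
    n_rare = 2 * min(n_hom1, n_hom2) + n_het
    # enumerate heterozygote counts with the observed parity
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    from scipy.special import gammaln

    n_common = 2 * n - n_rare
    logp = (
        gammaln(n + 1)
        - gammaln((n_rare - hets) / 2 + 1)
        - gammaln(hets + 1)
        - gammaln((n_common - hets) / 2 + 1)
        + hets * np.log(2.0)
        + gammaln(n_rare + 1) + gammaln(n_common + 1) - gammaln(2 * n + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    obs = probs[np.flatnonzero(hets == n_het)[0]]
    return float(min(1.0, probs[probs <= obs * (1 + 1e-12)].sum()))


def hwe_filter(gt: GenotypeTable, p_min: float = 0.1,
               ped: PedigreeTable | None = None) -> GenotypeTable:
    """Keep sites with exact HWE P strictly above ``p_min``, tested within F2 only."""
    if ped is not None:
        f2 = [s for s in ped.ids(generation="F2") if s in set(gt.samples)]
        idx = gt.sample_index(f2)
    else:
        idx = np.arange(gt.n_samples)
    g = gt.gt[:, idx]
    keep = np.empty(gt.n_sites, dtype=bool)
    for i in range(gt.n_sites):
        row = g[i]
        n_het = int((row == 1).sum())
        n0 = int((row == 0).sum())
        n2 = int((row == 2).sum())
        keep[i] = hwe_exact_p(n_het, n0, n2) > p_min
    return gt.take_sites(keep)


def apply_filter_cascade(gt: GenotypeTable, cfg: FilterConfig | None = None) -> GenotypeTable:
    """Full cascade: depth mask -> site/individual filters -> depth-IQR -> MAF.

    Order: genotype-level depth mask, site missingness, individual
    depth/missingness, site missingness again, depth-IQR site filter, MAF.
    Idempotent: applying it twice equals applying it once.
    """
    cfg = cfg or FilterConfig()
    n0_sites, n0_ind = gt.n_sites, gt.n_samples
    gt = mask_low_depth(gt, cfg.gt_min_depth)
    gt = filter_sites_individuals(gt, cfg)
    gt = depth_iqr_site_filter(gt, cfg.depth_iqr_mult)
    gt = maf_filter(gt, cfg.maf_min)
    if gt.n_sites == 0:
        raise EmptyTableError("no site survives the filter cascade")
    log.info("filter cascade: %d -> %d sites, %d -> %d individuals",
             n0_sites, gt.n_sites, n0_ind, gt.n_samples)
    return gt


# ------------------------------------------------------------------ ascertainment


def correct_f0_allelic_balance(gt: GenotypeTable, ped: PedigreeTable,
                               min_minor_fraction: float = 0.2,
                               minor_reads: np.ndarray | None = None) -> GenotypeTable:
    """Recode skewed heterozygous F0 calls to the majority homozygote.

    Approximation of an allelic-balance correction: a heterozygous F0 call
    whose minor-allele read fraction is below ``min_minor_fraction`` is
    treated as a homozygote of the majority allele. Without per-allele read
    counts (``minor_reads``, same shape as the genotype matrix) the VCF
    carries only total depth, so the correction is a no-op and is logged.
    """
    if minor_reads is None:
        log.info("allelic-balance correction skipped: no per-allele read counts available")
        return gt.copy()
    out = gt.copy()
    f0 = [s for s in ped.ids(generation="F0") if s in set(gt.samples)]
    cols = out.sample_index(f0)
    for j in cols:
        het = out.gt[:, j] == 1
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(out.depth[:, j] > 0, minor_reads[:, j] / np.maximum(out.depth[:, j], 1), 0.5)
        skew = het & (frac < min_minor_fraction)
        # majority homozygote: minor fraction < 0.5 means the major allele dominates;
        # without phased counts, call the ref homozygote when minor reads are alt-like
        out.gt[skew, j] = np.where(minor_reads[skew, j] * 2 < out.depth[skew, j], 0, 2)
    return out


def _group_columns(gt: GenotypeTable, ped: PedigreeTable, **kw) -> np.ndarray:
    ids = [s for s in ped.ids(**kw) if s in set(gt.samples)]
    return gt.sample_index(ids)


def select_f0_diagnostic_sites(gt: GenotypeTable, ped: PedigreeTable,
                               require_f1_het: bool = True,
                               mode: str = "pedigree") -> np.ndarray:
    """Sites fixed for alternative alleles between the founder species.

    ``pedigree`` mode: the two F0 are opposite homozygotes and, if
    ``require_f1_het``, every F1 present is heterozygous; no missing data
    allowed among the individuals examined. ``surrogate`` mode: all species-A
    surrogates share one homozygote and all species-B surrogates the other.
    Returns the sorted array of site indices.
    """
    if mode == "pedigree":
        f0 = _group_columns(gt, ped, generation="F0")
        if len(f0) == 0:
            raise ValueError("no F0 individuals in pedigree/genotype table")
        g0 = gt.gt[:, f0]
        ok = np.all((g0 == 0) | (g0 == 2), axis=1)
        if g0.shape[1] >= 2:
            ok &= (g0.min(axis=1) == 0) & (g0.max(axis=1) == 2)
        if require_f1_het:
            f1 = _group_columns(gt, ped, generation="F1")
            if len(f1):
                g1 = gt.gt[:, f1]
                ok &= np.all(g1 == 1, axis=1)
    elif mode == "surrogate":
        a = _group_columns(gt, ped, generation="species_surrogate", species="A")
        b = _group_columns(gt, ped, generation="species_surrogate", species="B")
        if len(a) == 0 or len(b) == 0:
            raise ValueError("surrogate mode requires surrogates of both species")
        ga, gb = gt.gt[:, a], gt.gt[:, b]
        a_fixed0 = np.all(ga == 0, axis=1)
        a_fixed2 = np.all(ga == 2, axis=1)
        b_fixed0 = np.all(gb == 0, axis=1)
        b_fixed2 = np.all(gb == 2, axis=1)
        ok = (a_fixed0 & b_fixed2) | (a_fixed2 & b_fixed0)
    else:
        raise ValueError(f"mode must be pedigree|surrogate, got {mode!r}")
    return np.flatnonzero(ok)


def infer_f1_het_sites_by_af(gt: GenotypeTable, ped: PedigreeTable,
                             band: tuple = (0.45, 0.55),
                             het_excess_max: float = 0.75) -> np.ndarray:
    """Sites likely heterozygous in both F1 parents, inferred from F2 allele frequencies.

    The alternative-allele frequency is computed separately among F2 males
    and among F2 females; sites whose average of the two lies within
    ``band`` are kept, and the paralog filter then removes sites whose F2
    heterozygote proportion exceeds ``het_excess_max``.
    """
    males = _group_columns(gt, ped, generation="F2", sex="M")
    females = _group_columns(gt, ped, generation="F2", sex="F")
    if len(males) == 0 or len(females) == 0:
        raise ValueError("both F2 sexes must be present to infer F1-heterozygous sites")
    with np.errstate(invalid="ignore", divide="ignore"):
        af = []
        for cols in (males, females):
            alt, total = _allele_counts(gt, cols)
            af.append(np.where(total > 0, alt / np.maximum(total, 1), np.nan))
    mean_af = (af[0] + af[1]) / 2.0
    lo, hi = band
    ok = (mean_af >= lo) & (mean_af <= hi)

    f2 = np.concatenate([males, females])
    g2 = gt.gt[:, f2]
    nonmiss = (g2 != MISSING).sum(axis=1)
    het = (g2 == 1).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        hprop = np.where(nonmiss > 0, het / np.maximum(nonmiss, 1), 0.0)
    ok &= hprop <= het_excess_max
    return np.flatnonzero(np.nan_to_num(ok.astype(float)) > 0)


# ------------------------------------------------------------------ polarization


def polarization_orientation(gt: GenotypeTable, ped: PedigreeTable,
                             mode: str = "pedigree") -> np.ndarray:
    """Per-site orientation: +1 keep coding, -1 flip (so 2 = grandfather-species hom).

    At sites where the grandmother (or species-A surrogates) is homozygous
    alt and the grandfather (species B) homozygous ref, the coding is
    flipped; everywhere else it is kept. Flipping maps g -> 2 - g with
    missing fixed; swapping the two founder labels inverts every flip.
    """
    orient = np.ones(gt.n_sites, dtype=np.int8)
    if mode == "pedigree":
        gm = gt.sample_index([ped.grandmother()])[0]
        gf = gt.sample_index([ped.grandfather()])[0]
        flip = (gt.gt[:, gm] == 2) & (gt.gt[:, gf] == 0)
    else:
        a = _group_columns(gt, ped, generation="species_surrogate", species="A")
        b = _group_columns(gt, ped, generation="species_surrogate", species="B")
        flip = np.all(gt.gt[:, a] == 2, axis=1) & np.all(gt.gt[:, b] == 0, axis=1)
    orient[flip] = -1
    return orient


def polarize(gt: GenotypeTable, orient: np.ndarray) -> GenotypeTable:
    """Apply an orientation vector: flip sites with orient == -1 (g -> 2 - g)."""
    out = gt.copy()
    flip = orient == -1
    sub = out.gt[flip]
    nonmiss = sub != MISSING
    sub[nonmiss] = 2 - sub[nonmiss]
    out.gt[flip] = sub
    return out
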