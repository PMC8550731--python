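"""Forward simulation of F0 -> F1 -> F2 interspecific crosses.

The simulator emulates the structure of RAD-seq genotype data from an
intercross between two species: two F0 grandparents (one per species), F1
sibling pairs that found families, and F2 offspring genotyped at thousands
of SNPs across many chromosomes. A configurable sex-determination
architecture (none, XY or ZW; a single determiner locus, optionally a
second modifier locus and composition-specific viability) generates
phenotypic sex, and RAD-like noise (negative-binomial read depth,
missingness, genotype errors) corrupts the emitted genotypes. A
:class:`TruthRecord` keeps the simulated ground truth (sex-chromosome
composition per F2, grandparental haplotype paintings, site classes) so
every downstream inference can be scored.

Marker classes
--------------
* *diagnostic* sites are fixed for alternative alleles between the two
  founder species (grandmother homozygous ref, grandfather homozygous alt);
  they reveal grandparental origin in the F2.
* *gametolog* sites carry a variant private to the Y (or W) copy of the sex
  chromosome: the heterogametic founder is heterozygous, everyone else
  homozygous. They are placed in the determiner-linked region at rate
  ``gametolog_divergence`` per marker.
* remaining sites are monomorphic within each founder (both founders
  homozygous for the same allele, ref or alt at random), emulating
  invariant RAD sites that survive SNP calling; ``founder_het_rate`` can
  re-introduce within-founder polymorphism.

Recombination
-------------
Crossovers between adjacent loci are exchanged independently with
probability r(d) of the configured map function (Haldane: exactly the
Poisson/no-interference process; Kosambi: the standard adjacent-interval
Markov approximation also used by intercross HMMs). A configurable
zero-recombination window around the determiner is applied to meioses of
heterogametic parents only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core import GenotypeTable, PedigreeTable, MARKER_COLUMNS, PEDIGREE_COLUMNS
from .maps import map_function

__all__ = [
    "ModifierConfig",
    "CrossConfig",
    "TruthRecord",
    "SimulationError",
    "simulate_founders",
    "simulate_f2",
    "meiosis",
    "write_truth",
    "read_truth",
    "composition_from_paintings",
]

SPECIES = ("A", "B")  # A = grandmother's species, B = grandfather's species


class SimulationError(RuntimeError):
    pass


@dataclass
class ModifierConfig:
    """A second sex-determination locus that can override the main determiner.

    The modifier allele sits on one haplotype of the founder named by
    ``origin`` and segregates like any other locus. Carriers of at least one
    copy have their sex forced to the modifier's direction with probability
    ``penetrance`` (evaluated after the main determiner).
    """

    chromosome: int
    position_cM: float
    effect: str = "feminizing"  # or "masculinizing"
    penetrance: float = 1.0
    origin: str = "grandmother"  # or "grandfather"

    def __post_init__(self):
        if self.effect not in ("feminizing", "masculinizing"):
            raise ValueError(f"modifier effect must be feminizing|masculinizing, got {self.effect!r}")
        if self.origin not in ("grandmother", "grandfather"):
            raise ValueError(f"modifier origin must be grandmother|grandfather, got {self.origin!r}")
        if not 0.0 <= self.penetrance <= 1.0:
            raise ValueError("modifier penetrance must be in [0, 1]")


@dataclass
class CrossConfig:
    """Design of one simulated F2 cross.

    Defaults mirror a RAD-seq intercross of the kind the package targets:
    ~10,000 SNPs over 22 chromosomes, two F0, two families of F1 x F1
    offspring, 12-50x read depth, a single fully penetrant XY determiner.
    """

    n_chromosomes: int = 22
    chrom_lengths_bp: int | tuple = 40_000_000
    chrom_lengths_cM: float | tuple = 60.0
    n_markers: int = 10_000
    map_function: str = "kosambi"
    n_f2: int = 180
    n_families: int = 2
    diagnostic_rate: float = 0.2
    founder_het_rate: float = 0.0
    sd_system: str = "XY"  # none | XY | ZW
    sd_chromosome: int = 0
    sd_position_cM: float = 30.0
    penetrance: float = 1.0
    modifier: ModifierConfig | None = None
    gametolog_divergence: float = 0.05
    sd_linked_region_cM: float = 15.0  # half-width for gametolog placement
    zero_recomb_window_cM: float = 2.0  # half-width, heterogametic meioses only
    viability: dict | None = None  # (composition, sex) -> survival probability
    depth_mean: float = 25.0
    depth_dispersion: float | None = 8.0  # NB size; None -> Poisson
    missing_rate: float = 0.05
    genotype_error_rate: float = 0.01
    n_surrogates_per_species: int = 0
    deletion_span: tuple | None = None  # (chrom_index, start_bp, end_bp): halve Y/W-carrier depth
    place_marker_at_sd: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_chromosomes < 1:
            raise ValueError("need at least one chromosome")
        if self.n_markers < 1:
            raise ValueError("need at least one marker")
        if self.sd_system not in ("none", "XY", "ZW"):
            raise ValueError(f"sd_system must be none|XY|ZW, got {self.sd_system!r}")
        for name in ("penetrance", "missing_rate", "genotype_error_rate",
                     "gametolog_divergence", "founder_het_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.diagnostic_rate <= 1.0:
            raise ValueError("diagnostic_rate must be in (0, 1]")
        if np.isscalar(self.chrom_lengths_bp):
            self.chrom_lengths_bp = tuple([int(self.chrom_lengths_bp)] * self.n_chromosomes)
        else:
            self.chrom_lengths_bp = tuple(int(x) for x in self.chrom_lengths_bp)
        if np.isscalar(self.chrom_lengths_cM):
            self.chrom_lengths_cM = tuple([float(self.chrom_lengths_cM)] * self.n_chromosomes)
        else:
            self.chrom_lengths_cM = tuple(float(x) for x in self.chrom_lengths_cM)
        if len(self.chrom_lengths_bp) != self.n_chromosomes or len(self.chrom_lengths_cM) != self.n_chromosomes:
            raise ValueError("chromosome length vectors must have n_chromosomes entries")
        if self.sd_system != "none":
            if not 0 <= self.sd_chromosome < self.n_chromosomes:
                raise ValueError("sd_chromosome out of range")
            if not 0.0 <= self.sd_position_cM <= self.chrom_lengths_cM[self.sd_chromosome]:
                raise ValueError("sd_position_cM exceeds chromosome map length")
        if self.viability is not None:
            for p in self.viability.values():
                if not 0.0 <= p <= 1.0:
                    raise ValueError("viability probabilities must be in [0, 1]")
        if self.n_f2 < 1 or self.n_families < 1:
            raise ValueError("n_f2 and n_families must be positive")

    def chrom_name(self, c: int) -> str:
        return f"chr{c + 1:02d}"


@dataclass
class TruthRecord:
    """Ground truth of one simulated cross, for scoring downstream inference."""

    system: str
    sd_chromosome: int | None
    sd_position_cM: float | None
    modifier: ModifierConfig | None
    f2: pd.DataFrame  # sample_id, family, sex, composition, carries_yw, det_hap_m, det_hap_p
    sites: pd.DataFrame  # marker_id, chrom, bp, cM, diagnostic, gametolog
    paintings: dict  # chrom name -> int8 array (n_f2, 2, n_markers_on_chrom), founder hap ids 0..3
    f2_order: list

    def hap_label(self, hap_id: int) -> str:
        return _hap_label(self.system, hap_id)


def _hap_label(system: str, hap_id: int) -> str:
    """Founder haplotype id (0,1 = grandmother; 2,3 = grandfather) -> sex-chromosome allele label."""
    if system == "XY":
        return {0: "X_A", 1: "X_A", 2: "X_B", 3: "Y_B"}[hap_id]
    if system == "ZW":
        return {0: "Z_A", 1: "W_A", 2: "Z_B", 3: "Z_B"}[hap_id]
    return "autosome"


def composition_label(system: str, hap_m: int, hap_p: int) -> str:
    return " ".join(sorted([_hap_label(system, hap_m), _hap_label(system, hap_p)]))


# --------------------------------------------------------------------------- genome scaffold


def _sample_positions(rng: np.random.Generator, length: int, n: int) -> np.ndarray:
    """n distinct 1-based positions on [1, length], sorted (rejection sampling)."""
    pos = np.unique(rng.integers(0, length, size=n))
    while len(pos) < n:
        extra = rng.integers(0, length, size=2 * (n - len(pos)))
        pos = np.unique(np.concatenate([pos, extra]))
    return np.sort(rng.permutation(pos)[:n]) + 1


class _Genome:
    """Marker scaffold plus founder haplotypes, per chromosome."""

    def __init__(self, config: CrossConfig, rng: np.random.Generator):
        self.config = config
        cfg = config
        # allocate markers to chromosomes proportional to bp length
        lens = np.asarray(cfg.chrom_lengths_bp, dtype=float)
        counts = rng.multinomial(cfg.n_markers, lens / lens.sum())
        # make sure every chromosome has at least one marker when possible
        while (counts == 0).any() and counts.max() > 1:
            i, j = int(np.argmin(counts)), int(np.argmax(counts))
            counts[i] += 1
            counts[j] -= 1

        rows = []
        self.loci_cm = []      # per chrom: cM of all loci (markers + pseudo)
        self.is_marker = []    # per chrom: bool mask over loci
        self.det_col = [None] * cfg.n_chromosomes
        self.mod_col = [None] * cfg.n_chromosomes
        self.marker_cm = []    # per chrom: cM of markers only
        bases = ["A", "C", "G", "T"]
        for c in range(cfg.n_chromosomes):
            L_bp, L_cm = cfg.chrom_lengths_bp[c], cfg.chrom_lengths_cM[c]
            n_c = int(counts[c])
            bp = _sample_positions(rng, L_bp, min(n_c, L_bp))
            cm = bp / L_bp * L_cm
            if cfg.place_marker_at_sd and cfg.sd_system != "none" and c == cfg.sd_chromosome and len(bp):
                k = int(np.argmin(np.abs(cm - cfg.sd_position_cM)))
                cm[k] = cfg.sd_position_cM
                bp[k] = max(1, int(round(cfg.sd_position_cM / L_cm * L_bp)))
                order = np.argsort(cm, kind="stable")
                bp, cm = bp[order], cm[order]
            chrom = cfg.chrom_name(c)
            ref = rng.choice(bases, size=len(bp))
            shift = rng.integers(1, 4, size=len(bp))
            alt = np.array(bases)[(np.searchsorted(bases, ref) + shift) % 4]
            for p, q, r_, a_ in zip(bp, cm, ref, alt):
                rows.append((chrom, int(p), f"{chrom}_{int(p)}", r_, a_))
            self.marker_cm.append(cm.astype(float))

        self.markers = pd.DataFrame(rows, columns=MARKER_COLUMNS)
        self.markers["cM"] = np.concatenate(self.marker_cm) if rows else []
        self.chrom_marker_index = {
            cfg.chrom_name(c): np.flatnonzero(self.markers["chrom"].values == cfg.chrom_name(c))
            for c in range(cfg.n_chromosomes)
        }

        # insert pseudo loci (determiner, modifier) into the per-chromosome locus chains
        for c in range(cfg.n_chromosomes):
            cm = list(self.marker_cm[c])
            marker_flags = [True] * len(cm)
            inserts = []
            if cfg.sd_system != "none" and c == cfg.sd_chromosome:
                inserts.append(("det", cfg.sd_position_cM))
            if cfg.modifier is not None and c == cfg.modifier.chromosome:
                inserts.append(("mod", cfg.modifier.position_cM))
            for kind, pos in inserts:
                j = int(np.searchsorted(np.asarray(cm), pos))
                cm.insert(j, pos)
                marker_flags.insert(j, False)
                if kind == "det":
                    self.det_col[c] = j
                else:
                    self.mod_col[c] = j
                    if self.det_col[c] is not None and j <= self.det_col[c]:
                        self.det_col[c] += 1
            self.loci_cm.append(np.asarray(cm, dtype=float))
            self.is_marker.append(np.asarray(marker_flags, dtype=bool))

        self._build_founders(rng)

    def _build_founders(self, rng: np.random.Generator) -> None:
        cfg = self.config
        n_mark = len(self.markers)
        diagnostic = rng.random(n_mark) < cfg.diagnostic_rate
        at_sd = np.zeros(n_mark, dtype=bool)
        if cfg.place_marker_at_sd and cfg.sd_system != "none":
            chrom_sd = cfg.chrom_name(cfg.sd_chromosome)
            midx = self.chrom_marker_index[chrom_sd]
            cm_sd = self.marker_cm[cfg.sd_chromosome]
            hit = np.abs(cm_sd - cfg.sd_position_cM) < 1e-9
            at_sd[midx[hit]] = True
            diagnostic[at_sd] = True  # the fully linked marker must be informative
        founder_het = (~diagnostic) & (rng.random(n_mark) < cfg.founder_het_rate)
        mono_alt = (~diagnostic) & (~founder_het) & (rng.random(n_mark) < 0.5)
        gametolog = np.zeros(n_mark, dtype=bool)

        # haplotypes: rows 0,1 = grandmother (species A); 2,3 = grandfather (species B)
        # Y is row 3 in an XY system; W is row 1 in a ZW system.
        self.founder_haps = {}
        for c in range(cfg.n_chromosomes):
            chrom = cfg.chrom_name(c)
            midx = self.chrom_marker_index[chrom]
            L = len(self.loci_cm[c])
            haps = np.zeros((4, L), dtype=np.int8)
            mcols = np.flatnonzero(self.is_marker[c])
            diag_c = diagnostic[midx]
            haps[2:, mcols[diag_c]] = 1  # grandfather homozygous alt at diagnostic sites
            het_c = founder_het[midx]
            if het_c.any():
                haps[:, mcols[het_c]] = rng.integers(0, 2, size=(4, int(het_c.sum()))).astype(np.int8)
            haps[:, mcols[mono_alt[midx]]] = 1
            if cfg.sd_system != "none" and c == cfg.sd_chromosome:
                cm = self.marker_cm[c]
                in_region = np.abs(cm - cfg.sd_position_cM) <= cfg.sd_linked_region_cM
                gam_c = in_region & (rng.random(len(cm)) < cfg.gametolog_divergence) \
                    & ~at_sd[midx]
                cols = mcols[gam_c]
                haps[:, cols] = 0
                yw_row = 3 if cfg.sd_system == "XY" else 1
                haps[yw_row, cols] = 1
                gametolog[midx[gam_c]] = True
                diagnostic[midx[gam_c]] = False
                det = self.det_col[c]
                haps[:, det] = 0
                haps[yw_row, det] = 1
            if cfg.modifier is not None and c == cfg.modifier.chromosome:
                mod_row = 1 if cfg.modifier.origin == "grandmother" else 3
                haps[:, self.mod_col[c]] = 0
                haps[mod_row, self.mod_col[c]] = 1
            self.founder_haps[chrom] = haps

        self.diagnostic = diagnostic
        self.gametolog = gametolog

    def base_r(self, c: int) -> np.ndarray:
        rfun = map_function(self.config.map_function)
        d = np.diff(self.loci_cm[c])
        return np.asarray(rfun(d), dtype=float)

    def r_for_parent(self, c: int, heterogametic: bool) -> np.ndarray:
        r = self.base_r(c)
        cfg = self.config
        if heterogametic and cfg.sd_system != "none" and c == cfg.sd_chromosome and cfg.zero_recomb_window_cM > 0:
            lo = cfg.sd_position_cM - cfg.zero_recomb_window_cM
            hi = cfg.sd_position_cM + cfg.zero_recomb_window_cM
            cm = self.loci_cm[c]
            overlap = (cm[1:] > lo) & (cm[:-1] < hi)
            r = r.copy()
            r[overlap] = 0.0
        return r

    @property
    def sites(self) -> pd.DataFrame:
        out = self.markers[["marker_id", "chrom", "bp", "cM"]].copy()
        out["diagnostic"] = self.diagnostic
        out["gametolog"] = self.gametolog
        return out


# --------------------------------------------------------------------------- meiosis


def _recombine(alleles2: np.ndarray, origins2: np.ndarray, r: np.ndarray,
               rng: np.random.Generator, n: int):
    """Draw ``n`` gametes from a diploid (2 x L alleles, 2 x L origins).

    Adjacent-interval exchanges are independent Bernoulli(r_j); the chain
    starts on a uniformly chosen haplotype.
    """
    L = alleles2.shape[1]
    start = rng.integers(0, 2, size=(n, 1))
    if L > 1:
        switches = (rng.random((n, L - 1)) < r).astype(np.int8)
        state = np.concatenate([start, switches], axis=1).cumsum(axis=1) % 2
    else:
        state = start
    cols = np.arange(L)
    return alleles2[state, cols], origins2[state, cols]


def meiosis(alleles2, cm_positions, map_function_name: str = "kosambi",
            rng: np.random.Generator | None = None, n: int = 1) -> np.ndarray:
    """Public single-chromosome meiosis: gamete haplotype(s) from a diploid.

    ``alleles2`` is a (2, L) array of haplotype alleles ordered by the
    (non-decreasing) ``cm_positions``. Returns an (n, L) array of gametes.
    """
    rng = np.random.default_rng() if rng is None else rng
    alleles2 = np.asarray(alleles2, dtype=np.int8)
    cm = np.asarray(cm_positions, dtype=float)
    if alleles2.shape != (2, len(cm)):
        raise ValueError("alleles2 must be (2, L) matching cm_positions")
    r = np.asarray(map_function(map_function_name)(np.diff(cm)), dtype=float)
    gam, _ = _recombine(alleles2, np.zeros_like(alleles2), r, rng, n)
    return gam


# --------------------------------------------------------------------------- individuals


class _Individual:
    """Alleles and founder-haplotype origins per chromosome, plus sex."""

    __slots__ = ("alleles", "origins", "sex")

    def __init__(self, alleles: dict, origins: dict, sex: str):
        self.alleles = alleles
        self.origins = origins
        self.sex = sex

    def carries_yw(self, genome: _Genome) -> bool:
        cfg = genome.config
        if cfg.sd_system == "none":
            return False
        c = cfg.sd_chromosome
        det = genome.det_col[c]
        return bool(self.alleles[cfg.chrom_name(c)][:, det].sum() > 0)


def _founder(genome: _Genome, which: str) -> _Individual:
    cfg = genome.config
    rows = (0, 1) if which == "grandmother" else (2, 3)
    alleles, origins = {}, {}
    for c in range(cfg.n_chromosomes):
        chrom = cfg.chrom_name(c)
        haps = genome.founder_haps[chrom]
        alleles[chrom] = haps[list(rows)].copy()
        origins[chrom] = np.tile(np.asarray(rows, dtype=np.int8)[:, None], (1, haps.shape[1]))
    return _Individual(alleles, origins, "F" if which == "grandmother" else "M")


def _is_heterogametic(ind: _Individual, genome: _Genome) -> bool:
    return ind.carries_yw(genome)


def _gamete_set(parent: _Individual, genome: _Genome, rng, n: int):
    """n gametes across all chromosomes: dict chrom -> (alleles (n,L), origins (n,L))."""
    het = _is_heterogametic(parent, genome)
    out = {}
    for c in range(genome.config.n_chromosomes):
        chrom = genome.config.chrom_name(c)
        r = genome.r_for_parent(c, het)
        out[chrom] = _recombine(parent.alleles[chrom], parent.origins[chrom], r, rng, n)
    return out


def _implied_sex(carrier: np.ndarray, system: str) -> np.ndarray:
    # carrier of the determiner allele: male in XY, female in ZW
    if system == "XY":
        return np.where(carrier, "M", "F")
    return np.where(carrier, "F", "M")


# --------------------------------------------------------------------------- public API


def simulate_founders(config: CrossConfig, rng: np.random.Generator | None = None):
    """Simulate the two F0 grandparents (plus optional conspecific surrogates).

    Returns a noise-free :class:`GenotypeTable` (depths drawn from the read
    model, genotypes exact) and the matching :class:`PedigreeTable`.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    genome = _Genome(config, rng)
    gm, gf = _founder(genome, "grandmother"), _founder(genome, "grandfather")
    table, ped = _emit_tables(genome, [("F0_GM", "F0", "-", gm.sex, "A", gm),
                                       ("F0_GF", "F0", "-", gf.sex, "B", gf)]
                              + _surrogate_rows(genome, rng),
                              rng, noisy=False)
    return table, ped


def _surrogate_rows(genome: _Genome, rng) -> list:
    cfg = genome.config
    rows = []
    if cfg.n_surrogates_per_species == 0:
        return rows
    for sp, which in (("A", "grandmother"), ("B", "grandfather")):
        base = _founder(genome, which)
        hap_rows = (0, 1) if which == "grandmother" else (2, 3)
        het_sp = (cfg.sd_system == "ZW" and sp == "A") or (cfg.sd_system == "XY" and sp == "B")
        het_sex = "F" if cfg.sd_system == "ZW" else "M"
        for i in range(cfg.n_surrogates_per_species):
            sex = ("M", "F")[i % 2]
            alleles = {}
            for c in range(cfg.n_chromosomes):
                chrom = cfg.chrom_name(c)
                haps = genome.founder_haps[chrom]
                if het_sp and sex != het_sex:
                    # homogametic-sex conspecific: two copies of the X/Z haplotype
                    xz = hap_rows[0]
                    alleles[chrom] = np.vstack([haps[xz], haps[xz]])
                else:
                    alleles[chrom] = haps[list(hap_rows)].copy()
            ind = _Individual(alleles, base.origins, sex)
            rows.append((f"SUR_{sp}_{i + 1}", "species_surrogate", "-", sex, sp, ind))
    return rows


def simulate_f2(config: CrossConfig):
    """Simulate a full F0 -> F1 -> F2 cross.

    Returns ``(GenotypeTable, PedigreeTable, TruthRecord)``. Genotypes of all
    emitted individuals carry read-depth, missingness and genotype-error
    noise; the truth record stores the noise-free architecture.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    genome = _Genome(cfg, rng)
    gm, gf = _founder(genome, "grandmother"), _founder(genome, "grandfather")

    rows = [("F0_GM", "F0", "-", gm.sex, "A", gm), ("F0_GF", "F0", "-", gf.sex, "B", gf)]
    families = [chr(ord("A") + i) for i in range(cfg.n_families)]
    f1_parents = {}
    for fam in families:
        dam, sire = _draw_f1_pair(gm, gf, genome, rng)
        f1_parents[fam] = (dam, sire)
        rows.append((f"F1_{fam}_D", "F1", fam, "F", "-", dam))
        rows.append((f"F1_{fam}_S", "F1", fam, "M", "-", sire))
    rows.extend(_surrogate_rows(genome, rng))

    per_family = _split(cfg.n_f2, cfg.n_families)
    f2_rows, truth_rows, paint_chunks = [], [], []
    for fam, n_fam in zip(families, per_family):
        dam, sire = f1_parents[fam]
        kept = _draw_f2(dam, sire, genome, rng, n_fam)
        for k, (ind, comp, hap_m, hap_p) in enumerate(kept):
            sid = f"F2_{fam}_{k + 1:03d}"
            f2_rows.append((sid, "F2", fam, ind.sex, "-", ind))
            truth_rows.append((sid, fam, ind.sex, comp, ind.carries_yw(genome),
                               hap_m, hap_p))
            paint_chunks.append(ind)
    rows.extend(f2_rows)

    table, ped = _emit_tables(genome, rows, rng, noisy=True)

    f2_df = pd.DataFrame(truth_rows, columns=["sample_id", "family", "sex", "composition",
                                              "carries_yw", "det_hap_m", "det_hap_p"])
    paintings = {}
    for c in range(cfg.n_chromosomes):
        chrom = cfg.chrom_name(c)
        mcols = np.flatnonzero(genome.is_marker[c])
        paintings[chrom] = np.stack([ind.origins[chrom][:, mcols] for ind in paint_chunks]) \
            if paint_chunks else np.empty((0, 2, len(mcols)), np.int8)
    truth = TruthRecord(
        system=cfg.sd_system,
        sd_chromosome=cfg.sd_chromosome if cfg.sd_system != "none" else None,
        sd_position_cM=cfg.sd_position_cM if cfg.sd_system != "none" else None,
        modifier=cfg.modifier,
        f2=f2_df,
        sites=genome.sites,
        paintings=paintings,
        f2_order=list(f2_df["sample_id"]),
    )
    return table, ped, truth


def _split(n: int, k: int) -> list[int]:
    base = n // k
    out = [base] * k
    for i in range(n - base * k):
        out[i] += 1
    return out


def _draw_f1_pair(gm, gf, genome, rng, max_tries: int = 2000):
    """Sample F1 offspring until a (dam, sire) pair exists within the family."""
    cfg = genome.config
    dam = sire = None
    for t in range(max_tries):
        g1 = _gamete_set(gm, genome, rng, 1)
        g2 = _gamete_set(gf, genome, rng, 1)
        alleles = {c: np.vstack([g1[c][0][0], g2[c][0][0]]) for c in g1}
        origins = {c: np.vstack([g1[c][1][0], g2[c][1][0]]) for c in g1}
        ind = _Individual(alleles, origins, "unknown")
        if cfg.sd_system == "none":
            ind.sex = "F" if dam is None else "M"
        elif cfg.sd_system == "XY":
            ind.sex = "M" if ind.carries_yw(genome) else "F"
        else:
            ind.sex = "F" if ind.carries_yw(genome) else "M"
        if ind.sex == "F" and dam is None:
            dam = ind
        elif ind.sex == "M" and sire is None:
            sire = ind
        if dam is not None and sire is not None:
            return dam, sire
    raise SimulationError("could not obtain one F1 dam and one F1 sire")


def _draw_f2(dam, sire, genome, rng, n_needed: int):
    """F2 offspring of one family with sex assignment and viability selection."""
    cfg = genome.config
    kept = []
    attempts = 0
    max_attempts = max(200 * n_needed, 2000)
    while len(kept) < n_needed:
        batch = max(2 * (n_needed - len(kept)), 8)
        if attempts >= max_attempts:
            raise SimulationError(
                f"viability selection rejected all offspring after {attempts} attempts")
        attempts += batch
        gd = _gamete_set(dam, genome, rng, batch)
        gs = _gamete_set(sire, genome, rng, batch)
        sd_chrom = cfg.chrom_name(cfg.sd_chromosome) if cfg.sd_system != "none" else None
        if sd_chrom is not None:
            det = genome.det_col[cfg.sd_chromosome]
            carrier = (gd[sd_chrom][0][:, det] + gs[sd_chrom][0][:, det]) > 0
            implied = _implied_sex(carrier, cfg.sd_system)
            coin = np.where(rng.random(batch) < 0.5, "M", "F")
            use = rng.random(batch) < cfg.penetrance
            sex = np.where(use, implied, coin)
        else:
            sex = np.where(rng.random(batch) < 0.5, "M", "F")
        if cfg.modifier is not None:
            mc = cfg.chrom_name(cfg.modifier.chromosome)
            mcol = genome.mod_col[cfg.modifier.chromosome]
            mod_carrier = (gd[mc][0][:, mcol] + gs[mc][0][:, mcol]) > 0
            override = rng.random(batch) < cfg.modifier.penetrance
            forced = "F" if cfg.modifier.effect == "feminizing" else "M"
            sex = np.where(mod_carrier & override, forced, sex)
        for i in range(batch):
            if len(kept) >= n_needed:
                break
            alleles = {c: np.vstack([gd[c][0][i], gs[c][0][i]]) for c in gd}
            origins = {c: np.vstack([gd[c][1][i], gs[c][1][i]]) for c in gd}
            if sd_chrom is not None:
                hap_m = int(origins[sd_chrom][0, det])
                hap_p = int(origins[sd_chrom][1, det])
                comp = composition_label(cfg.sd_system, hap_m, hap_p)
            else:
                hap_m = hap_p = -1
                comp = "autosomal"
            s = str(sex[i])
            if cfg.viability is not None:
                surv = cfg.viability.get((comp, s), 1.0)
                if rng.random() >= surv:
                    continue
            kept.append((_Individual(alleles, origins, s), comp, hap_m, hap_p))
    return kept


def _emit_tables(genome: _Genome, rows, rng, noisy: bool):
    """Assemble GenotypeTable + PedigreeTable from (_Individual) rows."""
    cfg = genome.config
    n_mark = len(genome.markers)
    samples = [r[0] for r in rows]
    gt = np.empty((n_mark, len(rows)), dtype=np.int8)
    yw_carrier = np.zeros(len(rows), dtype=bool)
    for j, (_, _, _, _, _, ind) in enumerate(rows):
        parts = []
        for c in range(cfg.n_chromosomes):
            chrom = cfg.chrom_name(c)
            mcols = np.flatnonzero(genome.is_marker[c])
            parts.append(ind.alleles[chrom][:, mcols].sum(axis=0))
        gt[:, j] = np.concatenate(parts)
        yw_carrier[j] = ind.carries_yw(genome)

    # read depth
    m = cfg.depth_mean
    if cfg.depth_dispersion is None or not np.isfinite(cfg.depth_dispersion):
        depth = rng.poisson(m, size=gt.shape)
    else:
        k = cfg.depth_dispersion
        depth = rng.negative_binomial(k, k / (k + m), size=gt.shape)
    if cfg.deletion_span is not None:
        c, lo, hi = cfg.deletion_span
        chrom = cfg.chrom_name(c)
        mk = genome.markers
        span = (mk["chrom"].values == chrom) & (mk["bp"].values >= lo) & (mk["bp"].values < hi)
        cols = np.flatnonzero(yw_carrier)
        if span.any() and len(cols):
            sub = depth[np.ix_(span, cols)]
            depth[np.ix_(span, cols)] = rng.binomial(sub, 0.5)
    depth = depth.astype(np.int32)

    if noisy:
        err = rng.random(gt.shape) < cfg.genotype_error_rate
        if err.any():
            shift = rng.integers(1, 3, size=int(err.sum()))
            gt[err] = (gt[err] + shift) % 3
        miss = rng.random(gt.shape) < cfg.missing_rate
        gt[miss] = -1

    markers = genome.markers[MARKER_COLUMNS].copy()
    table = GenotypeTable(markers, samples, gt, depth)
    ped = PedigreeTable(pd.DataFrame(
        [(r[0], r[1], r[2], r[3], r[4]) for r in rows], columns=PEDIGREE_COLUMNS))
    return table, ped


# --------------------------------------------------------------------------- truth I/O


def write_truth(truth: TruthRecord, prefix) -> None:
    """Write the truth record as a set of tab-separated text files.

    ``prefix.f2.tsv`` (per-F2 rows), ``prefix.sites.tsv`` (site classes),
    ``prefix.paintings.tsv`` (run-length-encoded haplotype paintings) and
    ``prefix.meta.json``. Lossless round trip with :func:`read_truth`.
    """
    prefix = str(prefix)
    truth.f2.to_csv(prefix + ".f2.tsv", sep="\t", index=False)
    truth.sites.to_csv(prefix + ".sites.tsv", sep="\t", index=False)
    with open(prefix + ".paintings.tsv", "w") as fh:
        fh.write("sample_id\tchrom\thap\tstart\tend\torigin\n")
        for chrom, arr in truth.paintings.items():
            for i, sid in enumerate(truth.f2_order):
                for h in range(2):
                    v = arr[i, h]
                    if len(v) == 0:
                        continue
                    breaks = np.flatnonzero(np.diff(v) != 0) + 1
                    starts = np.concatenate([[0], breaks])
                    ends = np.concatenate([breaks, [len(v)]])
                    for s, e in zip(starts, ends):
                        fh.write(f"{sid}\t{chrom}\t{h}\t{s}\t{e}\t{v[s]}\n")
    meta = {
        "system": truth.system,
        "sd_chromosome": truth.sd_chromosome,
        "sd_position_cM": truth.sd_position_cM,
        "modifier": asdict(truth.modifier) if truth.modifier is not None else None,
        "f2_order": truth.f2_order,
        "chrom_n_markers": {c: int(a.shape[2]) for c, a in truth.paintings.items()},
    }
    with open(prefix + ".meta.json", "w") as fh:
        json.dump(meta, fh, indent=1)


def read_truth(prefix) -> TruthRecord:
    prefix = str(prefix)
    with open(prefix + ".meta.json") as fh:
        meta = json.load(fh)
    f2 = pd.read_csv(prefix + ".f2.tsv", sep="\t")
    sites = pd.read_csv(prefix + ".sites.tsv", sep="\t")
    order = meta["f2_order"]
    idx = {s: i for i, s in enumerate(order)}
    paintings = {c: np.zeros((len(order), 2, n), dtype=np.int8)
                 for c, n in meta["chrom_n_markers"].items()}
    rle = pd.read_csv(prefix + ".paintings.tsv", sep="\t")
    for row in rle.itertuples(index=False):
        paintings[row.chrom][idx[row.sample_id], row.hap, row.start:row.end] = row.origin
    modifier = ModifierConfig(**meta["modifier"]) if meta["modifier"] else None
    return TruthRecord(meta["system"], meta["sd_chromosome"], meta["sd_position_cM"],
                       modifier, f2, sites, paintings, order)


def composition_from_paintings(truth: TruthRecord, chrom_names=None) -> pd.Series:
    """Re-derive each F2's sex-chromosome composition from its painting at the
    marker closest to the determiner (independent of the stored labels)."""
    if truth.system == "none" or truth.sd_chromosome is None:
        raise ValueError("no sex-determination system in this truth record")
    sites = truth.sites
    chrom = sorted(truth.paintings)[truth.sd_chromosome] if chrom_names is None \
        else chrom_names[truth.sd_chromosome]
    on = sites[sites["chrom"] == chrom]
    k = int((on["cM"] - truth.sd_position_cM).abs().to_numpy().argmin())
    arr = truth.paintings[chrom][:, :, k]
    labels = [composition_label(truth.system, int(a), int(b)) for a, b in arr]
    return pd.Series(labels, index=truth.f2_order)
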