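"""Core containers and file I/O.

``GenotypeTable`` holds a sites x individuals matrix of coded genotypes
(0 = hom ref, 1 = het, 2 = hom alt, -1 = missing) plus per-genotype read
depth and marker coordinates. After polarization against the grandparents,
code 0 means "homozygous for the grandmother-species allele" and 2
"homozygous for the grandfather-species allele".

``PedigreeTable`` records generation (F0/F1/F2/species_surrogate), family,
phenotypic sex and species-of-origin per sample.

VCF 4.2 is the on-disk genotype format (GT + DP per genotype, contigs
declared); pedigree and marker maps are tab-separated text.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MISSING = -1

MARKER_COLUMNS = ["chrom", "bp", "marker_id", "ref", "alt"]
PEDIGREE_COLUMNS = ["sample_id", "generation", "family", "sex", "species"]


@dataclass
class GenotypeTable:
    """Sites x individuals genotype matrix with depths and marker coordinates."""

    markers: pd.DataFrame  # columns: chrom, bp, marker_id, ref, alt (bp = VCF POS, 1-based)
    samples: list[str]
    gt: np.ndarray  # int8, shape (n_sites, n_samples), values in {-1, 0, 1, 2}
    depth: np.ndarray  # int32, shape (n_sites, n_samples), reads per genotype

    def __post_init__(self) -> None:
        self.gt = np.asarray(self.gt, dtype=np.int8)
        self.depth = np.asarray(self.depth, dtype=np.int32)
        n_sites, n_samples = self.gt.shape
        if len(self.markers) != n_sites:
            raise ValueError(f"{len(self.markers)} markers but genotype matrix has {n_sites} rows")
        if len(self.samples) != n_samples:
            raise ValueError(f"{len(self.samples)} samples but genotype matrix has {n_samples} columns")
        if self.depth.shape != self.gt.shape:
            raise ValueError("depth matrix shape must match genotype matrix shape")
        bad = ~np.isin(self.gt, (-1, 0, 1, 2))
        if bad.any():
            raise ValueError("coded genotypes must be in {-1, 0, 1, 2}")
        if (self.depth < 0).any():
            raise ValueError("depths must be non-negative")

    @property
    def n_sites(self) -> int:
        return self.gt.shape[0]

    @property
    def n_samples(self) -> int:
        return self.gt.shape[1]

    def sample_index(self, ids) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.asarray([pos[s] for s in ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"sample {e.args[0]!r} not in genotype table") from None

    def take_sites(self, idx) -> "GenotypeTable":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeTable(
            markers=self.markers.iloc[idx].reset_index(drop=True),
            samples=list(self.samples),
            gt=self.gt[idx],
            depth=self.depth[idx],
        )

    def take_samples(self, ids) -> "GenotypeTable":
        j = self.sample_index(ids)
        return GenotypeTable(
            markers=self.markers.copy(),
            samples=[self.samples[k] for k in j],
            gt=self.gt[:, j],
            depth=self.depth[:, j],
        )

    def copy(self) -> "GenotypeTable":
        return GenotypeTable(self.markers.copy(), list(self.samples), self.gt.copy(), self.depth.copy())

    # ------------------------------------------------------------------ I/O

    def write_vcf(self, path, contig_lengths: dict | None = None) -> None:
        """Write a VCF 4.2 file with GT and DP per genotype and declared contigs."""
        markers = self.markers
        if contig_lengths is None:
            contig_lengths = markers.groupby("chrom", sort=False)["bp"].max().to_dict()
        gt_strings = np.array(["./.", "0/0", "0/1", "1/1"])
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write("##source=sexscan\n")
            for chrom, length in contig_lengths.items():
                fh.write(f"##contig=<ID={chrom},length={int(length)}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(self.samples) + "\n")
            for i in range(self.n_sites):
                row = markers.iloc[i]
                cells = [
                    f"{gt_strings[self.gt[i, j] + 1]}:{self.depth[i, j]}"
                    for j in range(self.n_samples)
                ]
                fh.write(
                    f"{row.chrom}\t{int(row.bp)}\t{row.marker_id}\t{row.ref}\t{row.alt}"
                    "\t.\t.\t.\tGT:DP\t" + "\t".join(cells) + "\n"
                )


def read_vcf(path, pedigree: "PedigreeTable | None" = None) -> GenotypeTable:
    """Load bi-allelic SNP records from a VCF into a :class:`GenotypeTable`.

    Multi-allelic and non-SNP records are dropped (count logged). If a
    pedigree is given, every VCF sample must appear in it.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    if pedigree is not None:
        known = set(pedigree.df["sample_id"])
        for s in samples:
            if s not in known:
                raise ValueError(f"VCF sample {s!r} absent from pedigree")
    rows, gts, dps = [], [], []
    n_dropped = 0
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1 or v.ALT[0] not in "ACGT":
            n_dropped += 1
            continue
        g = np.asarray(v.gt_types, dtype=np.int8)
        g[g == 3] = MISSING
        dp = v.format("DP")
        if dp is None:
            dp = np.zeros(len(samples), dtype=np.int32)
        else:
            dp = np.asarray(dp, dtype=np.int32).reshape(-1)
            dp[dp < 0] = 0
        rows.append((v.CHROM, v.POS, v.ID or f"{v.CHROM}_{v.POS}", v.REF, v.ALT[0]))
        gts.append(g)
        dps.append(dp)
    if n_dropped:
        log.info("read_vcf: dropped %d multi-allelic/non-SNP records", n_dropped)
    markers = pd.DataFrame(rows, columns=MARKER_COLUMNS)
    if not rows:
        return GenotypeTable(markers, samples, np.empty((0, len(samples)), np.int8),
                             np.empty((0, len(samples)), np.int32))
    return GenotypeTable(markers, samples, np.vstack(gts), np.vstack(dps))


@dataclass
class PedigreeTable:
    """Per-sample metadata: generation, family, phenotypic sex, species of origin."""

    df: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=PEDIGREE_COLUMNS))

    def __post_init__(self) -> None:
        missing = [c for c in PEDIGREE_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"pedigree is missing column(s): {missing}")
        self.df = self.df.reset_index(drop=True)
        bad_gen = set(self.df["generation"]) - {"F0", "F1", "F2", "species_surrogate"}
        if bad_gen:
            raise ValueError(f"unknown generation label(s): {sorted(bad_gen)}")
        bad_sex = set(self.df["sex"]) - {"M", "F", "unknown"}
        if bad_sex:
            raise ValueError(f"unknown sex label(s): {sorted(bad_sex)}")

    def subset(self, generation=None, sex=None, family=None, species=None) -> pd.DataFrame:
        d = self.df
        if generation is not None:
            gens = [generation] if isinstance(generation, str) else list(generation)
            d = d[d["generation"].isin(gens)]
        if sex is not None:
            d = d[d["sex"] == sex]
        if family is not None:
            d = d[d["family"] == family]
        if species is not None:
            d = d[d["species"] == species]
        return d

    def ids(self, **kw) -> list[str]:
        return list(self.subset(**kw)["sample_id"])

    def f2_males(self, family=None) -> list[str]:
        return self.ids(generation="F2", sex="M", family=family)

    def f2_females(self, family=None) -> list[str]:
        return self.ids(generation="F2", sex="F", family=family)

    def f0(self) -> pd.DataFrame:
        return self.subset(generation="F0")

    def grandmother(self) -> str:
        """The F0 dam (phenotypic female)."""
        ids = self.ids(generation="F0", sex="F")
        if len(ids) != 1:
            raise ValueError(f"expected exactly one female F0, found {len(ids)}")
        return ids[0]

    def grandfather(self) -> str:
        ids = self.ids(generation="F0", sex="M")
        if len(ids) != 1:
            raise ValueError(f"expected exactly one male F0, found {len(ids)}")
        return ids[0]

    def sex_of(self) -> dict:
        return dict(zip(self.df["sample_id"], self.df["sex"]))

    def write(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


def read_pedigree(path) -> PedigreeTable:
    return PedigreeTable(pd.read_csv(path, sep="\t", dtype={"sample_id": str, "family": str}))


def write_map(map_df: pd.DataFrame, path) -> None:
    """Write a marker map (chrom, marker_id, bp, cM) as TSV."""
    map_df.to_csv(path, sep="\t", index=False)


def read_map(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
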