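"""Tracing Y/W-linked alleles back to the grandparental species.

Once a chromosome and its heterogamety (XY or ZW) are known, sites carrying
Y- (or W-) linked alleles are those heterozygous in the heterogametic-sex
F0 and F1 but homozygous in the homogametic line (or, without pedigree
genotypes, heterozygous in conspecific surrogates of the heterogametic-sex
grandparent). Heterozygous F2 at such sites carry the Y/W allele.

Each F2 is then assigned a two-allele sex-chromosome composition (e.g.
``X_A Y_B``: one X from the grandmother's species A, the Y from the
grandfather's species B) by combining its genotype at the most strongly
sex-linked Y/W-diagnostic site with its genotype at the most strongly
sex-linked species-diagnostic site (which distinguishes grandmaternal from
grandpaternal X/Z copies). "Most strongly sex-linked" ranks by smallest
permutation P, then largest absolute heterozygote-frequency difference,
then position.

A run-smoothing rule denoises genotype vectors along the sex-linked sites:
runs of up to three equal genotypes flanked on both sides by at least five
equal genotypes different from the run are replaced by the flanking
genotype.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GenotypeTable, PedigreeTable, MISSING
from scipy import stats as _sps

__all__ = [
    "SexLinkedSiteSet",
    "select_sex_linked_sites",
    "smooth_genotype_runs",
    "pick_tracing_sites",
    "assign_composition",
    "composition_summary",
    "export_genotype_matrix_plot",
    "write_genotype_matrix_text",
    "read_genotype_matrix_text",
]


@dataclass
class SexLinkedSiteSet:
    """Ordered candidate-chromosome sites carrying Y- or W-linked alleles."""

    sites: np.ndarray  # indices into the genotype table, ordered by bp
    mode: str  # pedigree | surrogate
    heterogametic_sex: str  # M (XY) | F (ZW)

    def __len__(self):
        return len(self.sites)


def _cols(gt: GenotypeTable, ped: PedigreeTable, **kw):
    ids = [s for s in ped.ids(**kw) if s in set(gt.samples)]
    return gt.sample_index(ids)


def select_sex_linked_sites(gt: GenotypeTable, ped: PedigreeTable,
                            heterogametic_sex: str, chrom: str | None = None,
                            mode: str = "pedigree") -> SexLinkedSiteSet:
    """Sites heterozygous in the heterogametic line, homozygous in the other.

    ``pedigree`` mode requires the F0 and F1 of the heterogametic sex to be
    heterozygous and those of the homogametic sex homozygous (missing
    genotypes disqualify a site). ``surrogate`` mode uses conspecific
    surrogates: heterogametic-sex individuals of the grandfather's species
    (XY) / grandmother's species (ZW) heterozygous, surrogates of the other
    species homozygous. Returns sites ordered by position; empty set is a
    valid result.
    """
    if heterogametic_sex not in ("M", "F"):
        raise ValueError("heterogametic_sex must be 'M' or 'F'")
    homo_sex = "F" if heterogametic_sex == "M" else "M"
    if mode == "pedigree":
        het_cols = np.concatenate([
            _cols(gt, ped, generation="F0", sex=heterogametic_sex),
            _cols(gt, ped, generation="F1", sex=heterogametic_sex),
        ]).astype(int)
        hom_cols = np.concatenate([
            _cols(gt, ped, generation="F0", sex=homo_sex),
            _cols(gt, ped, generation="F1", sex=homo_sex),
        ]).astype(int)
    elif mode == "surrogate":
        het_species = "B" if heterogametic_sex == "M" else "A"
        homo_species = "A" if het_species == "B" else "B"
        het_cols = _cols(gt, ped, generation="species_surrogate",
                         species=het_species, sex=heterogametic_sex)
        hom_cols = _cols(gt, ped, generation="species_surrogate", species=homo_species)
        if len(het_cols) == 0 or len(hom_cols) == 0:
            raise ValueError("surrogate mode requires surrogates of both species")
    else:
        raise ValueError(f"mode must be pedigree|surrogate, got {mode!r}")

    ghet = gt.gt[:, het_cols]
    ghom = gt.gt[:, hom_cols]
    ok = np.all(ghet == 1, axis=1) & np.all((ghom == 0) | (ghom == 2), axis=1)
    if len(het_cols) == 0:
        ok[:] = False
    if chrom is not None:
        ok &= gt.markers["chrom"].values == chrom
    idx = np.flatnonzero(ok)
    order = np.argsort(gt.markers["bp"].values[idx], kind="stable")
    return SexLinkedSiteSet(idx[order], mode, heterogametic_sex)


def smooth_genotype_runs(genotypes: np.ndarray, max_run: int = 3,
                         flank: int = 5) -> np.ndarray:
    """Replace short discordant genotype runs by their flanking genotype.

    A maximal run of length <= ``max_run`` is replaced when the ``flank``
    genotypes immediately on each side are all equal to one another (both
    sides the same value), different from the run, and non-missing. The rule
    is evaluated on the input vector in a single left-to-right pass (no
    cascading onto already-replaced values); missing genotypes break both
    runs and flanks.
    """
    v = np.asarray(genotypes).copy()
    n = len(v)
    if n == 0:
        return v
    # run-length encode the input
    breaks = np.flatnonzero(np.diff(v) != 0) + 1
    starts = np.concatenate([[0], breaks])
    ends = np.concatenate([breaks, [n]])
    values = v[starts]
    out = v.copy()
    for k in range(len(starts)):
        run_len = ends[k] - starts[k]
        if run_len > max_run or values[k] == MISSING:
            continue
        if k == 0 or k == len(starts) - 1:
            continue
        left_ok = (ends[k - 1] - starts[k - 1] >= flank and values[k - 1] != MISSING)
        right_ok = (ends[k + 1] - starts[k + 1] >= flank and values[k + 1] != MISSING)
        if left_ok and right_ok and values[k - 1] == values[k + 1] and values[k - 1] != values[k]:
            out[starts[k]:ends[k]] = values[k - 1]
    return out


def pick_tracing_sites(perm_stats: pd.DataFrame, yw_sites: np.ndarray,
                       diagnostic_sites: np.ndarray,
                       gp_stats: pd.DataFrame | None = None,
                       markers: pd.DataFrame | None = None):
    """The most strongly sex-linked Y/W-diagnostic and species-diagnostic site.

    Y/W candidates are ranked by permutation ``p_emp`` (ascending), then
    ``|het_diff|`` (descending), then site order. Species-diagnostic sites
    show no heterozygote-frequency contrast, so their sex linkage is
    measured by the grandpaternal-genotype frequency difference between the
    sexes (``gp_stats`` with columns site/freq_gp_m/freq_gp_f/n_m/n_f);
    because that contrast is flat within sampling error across the linked
    region, all candidates within one standard error of the maximum are
    treated as ties and the one closest (bp) to the chosen Y/W site is
    taken (requires ``markers``). Without ``gp_stats`` both classes use the
    permutation ranking.
    """
    ranked = perm_stats.copy()
    ranked["abs_diff"] = ranked["het_diff"].abs()
    ranked = ranked.sort_values(["p_emp", "abs_diff", "site"],
                                ascending=[True, False, True])

    def best(pool, order):
        pool = set(int(x) for x in pool)
        for s in order:
            if int(s) in pool:
                return int(s)
        raise ValueError("no candidate site available for tracing")

    yw_site = best(yw_sites, ranked["site"])

    if gp_stats is not None:
        gp = gp_stats[gp_stats["site"].isin(set(int(x) for x in diagnostic_sites))].copy()
        if len(gp) == 0:
            raise ValueError("no candidate site available for tracing")
        gp["contrast"] = (gp["freq_gp_m"] - gp["freq_gp_f"]).abs()
        gp = gp[np.isfinite(gp["contrast"])]
        k = gp["contrast"].idxmax()
        se = np.sqrt(gp.loc[k, "freq_gp_m"] * (1 - gp.loc[k, "freq_gp_m"])
                     / max(gp.loc[k, "n_m"], 1)
                     + gp.loc[k, "freq_gp_f"] * (1 - gp.loc[k, "freq_gp_f"])
                     / max(gp.loc[k, "n_f"], 1))
        near_max = gp[gp["contrast"] >= gp["contrast"].max() - se]
        if markers is not None and len(near_max) > 1:
            bp_yw = markers["bp"].iloc[yw_site]
            dist = (markers["bp"].iloc[near_max["site"]].to_numpy() - bp_yw)
            dg_site = int(near_max["site"].iloc[int(np.argmin(np.abs(dist)))])
        else:
            dg_site = int(gp.loc[k, "site"])
        return yw_site, dg_site

    return yw_site, best(diagnostic_sites, ranked["site"])


def assign_composition(gt: GenotypeTable, ped: PedigreeTable, yw_site: int,
                       diagnostic_site: int, system: str,
                       species=("A", "B")) -> pd.DataFrame:
    """Per-F2 sex-chromosome composition from two sites.

    ``yw_site``: heterozygotes carry the Y (XY) or W (ZW) allele.
    ``diagnostic_site`` (polarized: 0 = grandmother-species hom, 2 =
    grandfather-species hom) counts grandpaternal alleles, distinguishing
    grandmaternal from grandpaternal X/Z. Compositions inconsistent with the
    cross (e.g. a Y carrier with no grandpaternal allele) are flagged
    recombinant; a missing genotype at either chosen site gives
    ``unresolved``. ``discordant`` marks phenotype vs genotype-predicted sex
    disagreement.
    """
    if system not in ("XY", "ZW"):
        raise ValueError("system must be XY or ZW")
    a, b = species
    f2 = ped.subset(generation="F2")
    ids = [s for s in f2["sample_id"] if s in set(gt.samples)]
    cols = gt.sample_index(ids)
    sex = f2.set_index("sample_id").loc[ids, "sex"].to_numpy()

    g_yw = gt.gt[yw_site, cols]
    g_dg = gt.gt[diagnostic_site, cols]
    rows = []
    for i, sid in enumerate(ids):
        yw, dg = int(g_yw[i]), int(g_dg[i])
        unresolved = yw == MISSING or dg == MISSING
        carries = (yw == 1) and not unresolved
        recomb = False
        if unresolved:
            a1 = a2 = "unresolved"
            pred = "unknown"
        elif system == "XY":
            if carries:
                pred = "M"
                if dg == 0:       # Y carrier without a grandpaternal allele
                    recomb = True
                    a1, a2 = f"X_{a}", f"Y_{b}"
                elif dg == 1:
                    a1, a2 = f"X_{a}", f"Y_{b}"
                else:
                    a1, a2 = f"X_{b}", f"Y_{b}"
            else:
                pred = "F"
                if dg == 0:
                    a1, a2 = f"X_{a}", f"X_{a}"
                elif dg == 1:
                    a1, a2 = f"X_{a}", f"X_{b}"
                else:
                    a1, a2 = f"X_{b}", f"X_{b}"
                    recomb = True  # two grandpaternal X in an XY cross implies exchange with Y
        else:  # ZW, W derives from the grandmother (species a)
            if carries:
                pred = "F"
                if dg == 2:
                    recomb = True
                    a1, a2 = f"W_{a}", f"Z_{b}"
                elif dg == 1:
                    a1, a2 = f"W_{a}", f"Z_{b}"
                else:
                    a1, a2 = f"W_{a}", f"Z_{a}"
            else:
                pred = "M"
                if dg == 0:
                    a1, a2 = f"Z_{a}", f"Z_{a}"
                    recomb = True  # two grandmaternal Z implies exchange with W
                elif dg == 1:
                    a1, a2 = f"Z_{a}", f"Z_{b}"
                else:
                    a1, a2 = f"Z_{b}", f"Z_{b}"
        rows.append({
            "sample_id": sid,
            "sex": sex[i],
            "allele_1": a1,
            "allele_2": a2,
            "composition": "unresolved" if unresolved else " ".join(sorted([a1, a2])),
            "carries_yw": carries,
            "predicted_sex": pred,
            "recombinant": recomb,
            "discordant": (not unresolved) and pred != sex[i],
            "unresolved": unresolved,
        })
    return pd.DataFrame(rows)


def _mendelian_expectation(system: str, species=("A", "B")) -> dict:
    """Expected composition fractions from the F1 x F1 cross (each gamete pair 1/4)."""
    a, b = species
    if system == "XY":
        dam = [f"X_{a}", f"X_{b}"]
        sire = [f"X_{a}", f"Y_{b}"]
    else:
        dam = [f"W_{a}", f"Z_{b}"]
        sire = [f"Z_{a}", f"Z_{b}"]
    out = {}
    for g1 in dam:
        for g2 in sire:
            key = " ".join(sorted([g1, g2]))
            out[key] = out.get(key, 0.0) + 0.25
    return out


def composition_summary(calls: pd.DataFrame, system: str,
                        species=("A", "B")) -> pd.DataFrame:
    """Composition x sex contingency with sex-ratio-corrected fractions and
    exact binomial tests against the Mendelian expectation.

    The corrected fraction reweights each sex to 0.5 before pooling, undoing
    sex-ratio distortion; the binomial test compares each composition's raw
    count with its Mendelian expectation among resolved calls.
    """
    resolved = calls[~calls["unresolved"]]
    if len(resolved) == 0:
        raise ValueError("no resolved composition calls to summarise")
    expect = _mendelian_expectation(system, species)
    n = len(resolved)
    n_m = max(int((resolved["sex"] == "M").sum()), 0)
    n_f = max(int((resolved["sex"] == "F").sum()), 0)
    rows = []
    for comp in sorted(set(expect) | set(resolved["composition"])):
        sub = resolved[resolved["composition"] == comp]
        c_m = int((sub["sex"] == "M").sum())
        c_f = int((sub["sex"] == "F").sum())
        corrected = 0.0
        if n_m:
            corrected += 0.5 * c_m / n_m
        if n_f:
            corrected += 0.5 * c_f / n_f
        e = expect.get(comp, 0.0)
        p = float(_sps.binomtest(len(sub), n, e).pvalue) if 0.0 < e < 1.0 else np.nan
        rows.append({"composition": comp, "n_males": c_m, "n_females": c_f,
                     "n_total": len(sub), "fraction": len(sub) / n,
                     "fraction_sex_corrected": corrected,
                     "expected_fraction": e, "p_binomial": p})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------- visualisation

GENOTYPE_CHARS = {0: "0", 1: "1", 2: "2", MISSING: "."}
GENOTYPE_COLORS = {  # grandmother hom, het (carries Y/W), grandfather hom, missing
    0: "#d62728", 1: "#ff7f0e", 2: "#ffdf00", MISSING: "#bbbbbb",
}


def write_genotype_matrix_text(gt: GenotypeTable, sample_ids, sites, path) -> None:
    """Plain-text individuals x sites genotype matrix (diffable, parse-back safe)."""
    cols = gt.sample_index(sample_ids)
    sub = gt.gt[np.ix_(np.asarray(sites, dtype=int), cols)]
    with open(path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(gt.markers["marker_id"].values[np.asarray(sites, dtype=int)]) + "\n")
        for j, sid in enumerate(sample_ids):
            fh.write(sid + "\t" + "\t".join(GENOTYPE_CHARS[int(x)] for x in sub[:, j]) + "\n")


def read_genotype_matrix_text(path):
    """Parse a text genotype matrix back into (sample_ids, marker_ids, codes)."""
    inv = {v: k for k, v in GENOTYPE_CHARS.items()}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        marker_ids = header[1:]
        samples, rows = [], []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            samples.append(parts[0])
            rows.append([inv[x] for x in parts[1:]])
    return samples, marker_ids, np.asarray(rows, dtype=np.int8)


def export_genotype_matrix_plot(gt: GenotypeTable, ped: PedigreeTable,
                                sites, path, smooth: bool = True) -> None:
    """Render F2 genotypes at the sex-linked sites with the 3-colour scheme.

    Rows are F2 individuals (females then males), columns the sites ordered
    by position; red = grandmother-allele homozygote, orange = heterozygote
    (Y/W carrier), yellow = grandfather-allele homozygote, grey = missing.
    A sibling ``.tsv`` text matrix is written next to the image.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    sites = np.asarray(sites, dtype=int)
    f2 = ped.subset(generation="F2")
    ids = [s for s in f2["sample_id"] if s in set(gt.samples)]
    sex = f2.set_index("sample_id").loc[ids, "sex"]
    ids = sorted(ids, key=lambda s: (sex[s] != "F", s))
    cols = gt.sample_index(ids)
    mat = gt.gt[np.ix_(sites, cols)].T.astype(int)  # individuals x sites
    if smooth:
        mat = np.vstack([smooth_genotype_runs(row) for row in mat])

    cmap = ListedColormap([GENOTYPE_COLORS[MISSING], GENOTYPE_COLORS[0],
                           GENOTYPE_COLORS[1], GENOTYPE_COLORS[2]])
    fig, ax = plt.subplots(figsize=(max(4, 0.12 * len(sites)), max(3, 0.08 * len(ids))))
    ax.imshow(mat + 1, cmap=cmap, vmin=0, vmax=3, aspect="auto", interpolation="nearest")
    ax.set_xlabel("sex-linked sites (by position)")
    ax.set_ylabel("F2 individuals (females on top)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    text_path = str(path) + ".tsv"
    write_genotype_matrix_text(gt, ids, sites, text_path)
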