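"""End-to-end pipeline: simulate/load -> filter -> sex stats -> scan -> trace -> windows.

One :class:`RunConfig` drives a reproducible run. A single global seed fans
out to per-stage child seeds through ``numpy.random.SeedSequence.spawn``
(stage order: simulate, sexstats, scan), so each stage is independently
reproducible. All tabular outputs are TSV; the machine-readable summary is
JSON.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import GenotypeTable, PedigreeTable, read_vcf, read_pedigree, read_map
from .filters import (FilterConfig, apply_filter_cascade, hwe_filter,
                      select_f0_diagnostic_sites, infer_f1_het_sites_by_af,
                      polarization_orientation, polarize)
from .sexstats import (grandpaternal_genotype_freq, permutation_test,
                       call_heterogamety, best_heterogamety_call, depth_ratio_windows)
from .scan import (marker_regression_scan, binomial_sex_ratio_test, LinkageMap,
                   genome_scan_binary, permutation_threshold, bayes_interval,
                   pve_from_lod)
from .simulate import CrossConfig, simulate_f2, write_truth
from .tracing import (select_sex_linked_sites, pick_tracing_sites,
                      assign_composition, composition_summary)
from .windows import divergence_site_filter, individual_heterozygosity_windows

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "validate_inputs"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Inputs, stage toggles and per-stage settings of one pipeline run."""

    outdir: str = "sexscan_run"
    # either simulate ...
    simulate: CrossConfig | None = None
    # ... or load
    vcf: str | None = None
    pedigree: str | None = None
    map_path: str | None = None

    filter: FilterConfig = field(default_factory=FilterConfig)
    founder_mode: str = "pedigree"  # pedigree | surrogate
    heterogamety: str = "auto"  # auto | XY | ZW (override for tracing/windows)
    n_perm_sites: int = 10_000
    n_perm_scan: int = 0  # 0 disables permutation thresholds
    run_interval_scan: bool = False
    run_trace: bool = True
    run_windows: bool = True
    window_bp: int = 1_000_000
    depth_window_bp: int = 5_000_000
    seed: int = 0

    def stage_seeds(self) -> dict:
        children = np.random.SeedSequence(self.seed).spawn(3)
        return {name: int(ss.generate_state(1)[0] % (2**31))
                for name, ss in zip(("simulate", "sexstats", "scan"), children)}


def validate_inputs(gt: GenotypeTable, ped: PedigreeTable,
                    map_df: pd.DataFrame | None = None) -> dict:
    """Cross-check samples, sexes and markers; returns {'errors': [...], 'warnings': [...]}."""
    errors, warnings_ = [], []
    ped_ids = set(ped.df["sample_id"])
    for s in gt.samples:
        if s not in ped_ids:
            errors.append(f"sample {s!r} in genotypes but not in pedigree")
    bad_sex = set(ped.df["sex"]) - {"M", "F", "unknown"}
    if bad_sex:
        errors.append(f"unknown sex labels: {sorted(bad_sex)}")
    if map_df is not None:
        have = set(gt.markers["marker_id"])
        missing = [m for m in map_df["marker_id"] if m not in have]
        if missing:
            warnings_.append(f"{len(missing)} map markers absent from genotype table")
    return {"errors": errors, "warnings": warnings_}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages and return (and write) the summary report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = config.stage_seeds()
    report: dict = {"version": __version__, "seed": config.seed, "stage_seeds": seeds}
    log_lines = [f"sexscan {__version__} | seed {config.seed}"]

    # ---------------- inputs
    truth = None
    if config.simulate is not None:
        sim_cfg = config.simulate
        if sim_cfg.seed != seeds["simulate"]:
            sim_cfg = CrossConfig(**{**sim_cfg.__dict__, "seed": seeds["simulate"]})
        try:
            gt, ped, truth = simulate_f2(sim_cfg)
        except Exception as e:  # noqa: BLE001
            raise PipelineError("simulate", str(e)) from e
        gt.write_vcf(outdir / "genotypes.vcf",
                     dict(zip([sim_cfg.chrom_name(c) for c in range(sim_cfg.n_chromosomes)],
                              sim_cfg.chrom_lengths_bp)))
        ped.write(outdir / "pedigree.tsv")
        truth.sites[["chrom", "marker_id", "bp", "cM"]].to_csv(
            outdir / "map.tsv", sep="\t", index=False)
        write_truth(truth, outdir / "truth")
        map_df = truth.sites[["chrom", "marker_id", "bp", "cM"]]
        log_lines.append(f"simulated cross: {gt.n_sites} markers, {gt.n_samples} samples")
    else:
        if config.vcf is None or config.pedigree is None:
            raise PipelineError("inputs", "either a simulate config or vcf+pedigree paths are required")
        for p in (config.vcf, config.pedigree) + ((config.map_path,) if config.map_path else ()):
            if not Path(p).exists():
                raise PipelineError("inputs", f"input file not found: {p}")
        ped = read_pedigree(config.pedigree)
        gt = read_vcf(config.vcf, ped)
        map_df = read_map(config.map_path) if config.map_path else None

    diag = validate_inputs(gt, ped, map_df)
    if diag["errors"]:
        raise PipelineError("validate", "; ".join(diag["errors"]))
    report["validation_warnings"] = diag["warnings"]

    # ---------------- filter
    try:
        filtered = apply_filter_cascade(gt, config.filter)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("filter", str(e)) from e
    report["filter"] = {"sites_in": gt.n_sites, "sites_out": filtered.n_sites,
                        "samples_in": gt.n_samples, "samples_out": filtered.n_samples}
    log_lines.append(f"filter: {gt.n_sites}->{filtered.n_sites} sites, "
                     f"{gt.n_samples}->{filtered.n_samples} samples")

    orient = polarization_orientation(filtered, ped, mode=config.founder_mode)
    polarized = polarize(filtered, orient)
    try:
        diag_sites = select_f0_diagnostic_sites(polarized, ped, mode=config.founder_mode)
    except ValueError:
        diag_sites = np.array([], dtype=int)
    f1het_sites = infer_f1_het_sites_by_af(
        polarized, ped, config.filter.f1_het_af_band, config.filter.het_excess_max)

    # ---------------- sex-contrast statistics
    gp_sites = diag_sites if len(diag_sites) else f1het_sites
    gp = grandpaternal_genotype_freq(polarized, ped, gp_sites) if len(gp_sites) else None
    perm = permutation_test(polarized, ped, None, config.n_perm_sites,
                            seed=seeds["sexstats"])
    perm.to_csv(outdir / "sexstats.tsv", sep="\t", index=False)
    if gp is not None:
        gp.to_csv(outdir / "grandpaternal_freq.tsv", sep="\t", index=False)
    calls = call_heterogamety(perm)
    best = best_heterogamety_call(calls)
    report["heterogamety"] = {
        "per_chromosome": [
            {"chrom": c.chromosome, "n_significant": c.n_significant,
             "direction": c.direction} for c in calls],
        "call": best.direction if best else "none",
        "chromosome": best.chromosome if best else None,
    }
    depth_ratio = depth_ratio_windows(filtered, ped, config.depth_window_bp)
    depth_ratio.to_csv(outdir / "depth_ratio.tsv", sep="\t", index=False)
    finite_ratio = depth_ratio["ratio_fm"].dropna()
    report["depth_ratio_range"] = [float(finite_ratio.min()), float(finite_ratio.max())] \
        if len(finite_ratio) else None

    # ---------------- association scan
    n_m = len(ped.f2_males())
    n_f = len(ped.f2_females())
    report["sex_ratio"] = {"n_males": n_m, "n_females": n_f,
                           "p_binomial": binomial_sex_ratio_test(n_m, n_f)}
    hwe_ok = hwe_filter(polarized, config.filter.hwe_p_min, ped)
    smr = marker_regression_scan(hwe_ok, ped)
    smr.to_csv(outdir / "marker_scan.tsv", sep="\t", index=False)
    valid = smr.dropna(subset=["lod"])
    peak = valid.loc[valid["lod"].idxmax()] if len(valid) else None
    if peak is not None:
        report["marker_scan"] = {
            "peak_chrom": str(peak["chrom"]), "peak_bp": int(peak["bp"]),
            "lod": float(peak["lod"]), "pve": float(peak["pve"]),
            "p_bonf": float(peak["p_bonf"]) if np.isfinite(peak["p_bonf"]) else 0.0,
            "n_markers": int(len(valid)),
        }

    if config.run_interval_scan and map_df is not None:
        # interval mapping runs on the linkage-map marker set: species-diagnostic sites
        if len(diag_sites):
            diag_ids = set(polarized.markers["marker_id"].values[diag_sites])
            map_used = map_df[map_df["marker_id"].isin(diag_ids)]
        else:
            map_used = map_df
        lmap = LinkageMap(map_used.reset_index(drop=True))
        iscan = genome_scan_binary(polarized, lmap, ped)
        iscan.to_csv(outdir / "interval_scan.tsv", sep="\t", index=False)
        ipk = iscan.loc[iscan["lod"].idxmax()]
        ci = bayes_interval(iscan, str(ipk["chrom"]))
        entry = {"peak_chrom": str(ipk["chrom"]), "peak_cM": float(ipk["cM"]),
                 "lod": float(ipk["lod"]),
                 "pve": float(pve_from_lod(ipk["lod"], n_m + n_f)),
                 "credible_interval_cM": [ci[0], ci[1]]}
        if config.n_perm_scan > 0:
            thr = permutation_threshold(polarized, lmap, ped, config.n_perm_scan,
                                        seed=seeds["scan"])
            entry["thresholds"] = {str(a): t for a, t in thr.items()}
        report["interval_scan"] = entry

    # ---------------- tracing
    # the candidate system/chromosome come from the heterogamety call, unless
    # the system is asserted up front; then the scan peak names the chromosome
    if config.heterogamety != "auto":
        direction = config.heterogamety
        candidate_chrom = best.chromosome if best is not None and \
            best.direction == direction else (
                str(peak["chrom"]) if peak is not None else None)
    else:
        direction = best.direction if best is not None else None
        candidate_chrom = best.chromosome if best is not None else None
    report["candidate"] = {"system": direction, "chromosome": candidate_chrom}

    if config.run_trace and direction in ("XY", "ZW") and candidate_chrom is not None:
        het_sex = "M" if direction == "XY" else "F"
        yw = select_sex_linked_sites(polarized, ped, het_sex, candidate_chrom,
                                     mode=config.founder_mode)
        on_chrom = set(np.flatnonzero(polarized.markers["chrom"].values == candidate_chrom))
        diag_on = np.array(sorted(set(diag_sites.tolist()) & on_chrom), dtype=int)
        if len(yw) and len(diag_on):
            yw_site, dg_site = pick_tracing_sites(perm, yw.sites, diag_on, gp,
                                                  polarized.markers)
            comps = assign_composition(polarized, ped, yw_site, dg_site, direction)
            comps.to_csv(outdir / "compositions.tsv", sep="\t", index=False)
            summary = composition_summary(comps, direction)
            summary.to_csv(outdir / "composition_summary.tsv", sep="\t", index=False)
            report["tracing"] = {
                "n_yw_sites": int(len(yw)),
                "yw_site": int(yw_site), "diagnostic_site": int(dg_site),
                "n_discordant": int(comps["discordant"].sum()),
                "n_unresolved": int(comps["unresolved"].sum()),
                "compositions": summary[["composition", "n_males", "n_females",
                                         "fraction_sex_corrected"]].to_dict("records"),
            }
        else:
            report["tracing"] = {"n_yw_sites": int(len(yw)),
                                 "note": "insufficient sex-linked or diagnostic sites"}

    # ---------------- windowed heterozygosity on the candidate chromosome
    if config.run_windows and candidate_chrom is not None:
        div = divergence_site_filter(filtered)
        on = div.take_sites(div.markers["chrom"].values == candidate_chrom)
        if on.n_sites:
            f2_ids = [s for s in ped.ids(generation="F2") if s in set(on.samples)]
            het_tabs = [individual_heterozygosity_windows(on, s, config.window_bp)
                        for s in f2_ids]
            het = pd.concat(het_tabs, ignore_index=True)
            het.to_csv(outdir / "heterozygosity_windows.tsv", sep="\t", index=False)
            report["windows"] = {"chromosome": candidate_chrom,
                                 "n_sites": int(on.n_sites),
                                 "mean_f2_heterozygosity":
                                     float(het["heterozygosity"].mean())}

    if truth is not None:
        report["truth"] = {"system": truth.system,
                           "sd_chromosome": (None if truth.sd_chromosome is None else
                                             config.simulate.chrom_name(truth.sd_chromosome)),
                           "sd_position_cM": truth.sd_position_cM}

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=str)
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return report
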