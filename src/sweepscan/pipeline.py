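"""End-to-end orchestration: simulate -> filter -> QC -> diversity -> scans -> genes.

A single structured config drives every stage with the scan defaults
(50-kb/25-kb windows, 0.1% empirical tails, MAF 5%, call rate 95%,
indep-pairwise 50/10/0.1) so that one file is the source of truth for a run.
The report is emitted both as deterministic JSON and as readable text.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from sweepscan import annotate, diversity, filtering, qc, scan, vcfio
from sweepscan.matrix import GenotypeMatrix
from sweepscan.simulate import ConfigError, SimulationConfig, generate_cohort

logger = logging.getLogger(__name__)


@dataclass
class Thresholds:
    min_dp: float = 5.0
    dp_sd_mult: float = 3.0
    maf_min: float = 0.05
    call_rate_min: float = 0.95
    ld_window: int = 50
    ld_step: int = 10
    ld_r2_max: float = 0.1
    window_size: int = scan.DEFAULT_WINDOW_SIZE
    window_step: int = scan.DEFAULT_WINDOW_STEP
    tail_fraction: float = scan.DEFAULT_TAIL_FRACTION
    sample_call_rate_min: float = 0.95
    ibs_max: float = 0.90


@dataclass
class RunConfig:
    outdir: Path
    seed: int = 0
    simulate: Optional[SimulationConfig] = None
    vcf: Optional[Path] = None
    sample_map: Optional[Path] = None
    genes: Optional[Path] = None
    scaffold_lengths: Optional[Path] = None
    fst_pair: Optional[tuple[str, str]] = None
    hp_cohorts: Optional[dict[str, list[str]]] = None  # name -> population list
    thresholds: Thresholds = field(default_factory=Thresholds)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        sim = raw.get("simulate")
        if sim is not None:
            sim = SimulationConfig.from_dict({"seed": raw.get("seed", 0), **sim})
        thresholds = Thresholds(**raw.get("thresholds", {}))
        fst_pair = raw.get("fst_pair")
        return cls(
            outdir=Path(raw["outdir"]),
            seed=int(raw.get("seed", 0)),
            simulate=sim,
            vcf=Path(raw["vcf"]) if raw.get("vcf") else None,
            sample_map=Path(raw["sample_map"]) if raw.get("sample_map") else None,
            genes=Path(raw["genes"]) if raw.get("genes") else None,
            scaffold_lengths=(
                Path(raw["scaffold_lengths"]) if raw.get("scaffold_lengths") else None
            ),
            fst_pair=tuple(fst_pair) if fst_pair else None,
            hp_cohorts={k: list(v) for k, v in raw["hp_cohorts"].items()}
            if raw.get("hp_cohorts")
            else None,
            thresholds=thresholds,
        )


def _round(x: float, nd: int = 6) -> float:
    return float(np.round(x, nd))


def _region_rows(regions: list[scan.Region]) -> list[dict]:
    return [
        {
            "scaffold": r.scaffold,
            "start": int(r.start),
            "end": int(r.end),
            "n_windows": r.n_windows,
            "extreme": _round(r.extreme),
        }
        for r in regions
    ]


def _write_window_tsv(path, stats: list[scan.WindowStat], fst_mode: bool) -> None:
    with open(path, "w") as fh:
        if fst_mode:
            fh.write("scaffold\tstart\tend\tn_snps\tfst_weighted\n")
            for s in stats:
                fh.write(
                    f"{s.window.scaffold}\t{s.window.start}\t{s.window.end}\t"
                    f"{s.n_snps}\t{s.fst_weighted:.6f}\n"
                )
        else:
            fh.write("scaffold\tstart\tend\tn_snps\tsum_nmaj\tsum_nmin\thp\tzhp\n")
            for s in stats:
                fh.write(
                    f"{s.window.scaffold}\t{s.window.start}\t{s.window.end}\t"
                    f"{s.n_snps}\t{s.sum_nmaj}\t{s.sum_nmin}\t{s.hp:.6f}\t{s.zhp:.6f}\n"
                )


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns (and writes) the run report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {}, "files": {}}
    thr = config.thresholds

    # ---------------- stage: inputs / simulation
    if config.simulate is not None:
        cohort, paths = generate_cohort(config.simulate, outdir / "sim")
        vcf_path = paths["vcf"]
        sample_map_path = paths["sample_map"]
        genes_path = paths["genes"]
        scaffold_lengths = dict(config.simulate.scaffolds)
        report["files"]["simulation"] = {
            k: str(Path(v).relative_to(outdir)) for k, v in paths.items()
        }
        report["stages"]["simulate"] = {
            "n_sites": len(cohort.sites),
            "n_samples": len(cohort.samples),
            "n_truth_sweeps": len(cohort.truth.sweep_intervals),
            "n_truth_diff": len(cohort.truth.diff_intervals),
            "n_failing_sites": len(cohort.truth.failing_sites),
        }
    else:
        if config.vcf is None or config.sample_map is None:
            raise ConfigError("either 'simulate' or 'vcf' + 'sample_map' is required")
        vcf_path = config.vcf
        sample_map_path = config.sample_map
        genes_path = config.genes
        if config.scaffold_lengths is None:
            raise ConfigError("scaffold_lengths is required for windowing")
        scaffold_lengths = vcfio.read_scaffold_lengths(config.scaffold_lengths)

    population_of = vcfio.read_sample_map(sample_map_path)
    populations = list(dict.fromkeys(population_of.values()))

    hp_cohorts = config.hp_cohorts or {"all": populations, **{p: [p] for p in populations}}
    for name, pops in hp_cohorts.items():
        unknown = [p for p in pops if p not in populations]
        if unknown:
            raise ConfigError(f"cohort {name!r} references unknown populations {unknown}")
    fst_pair = config.fst_pair or (tuple(populations[:2]) if len(populations) >= 2 else None)
    if fst_pair is not None:
        unknown = [p for p in fst_pair if p not in populations]
        if unknown:
            raise ConfigError(f"fst_pair references unknown populations {unknown}")

    # ---------------- stage: variant filtering
    samples, records = vcfio.read_vcf(vcf_path)
    freport = filtering.FilterReport()
    try:
        freport.tstv_before = filtering.compute_tstv(
            r for r in records if r.is_snp and r.is_biallelic
        )
    except filtering.TsTvUndefinedError:
        freport.tstv_before = None
    retained, _ = filtering.apply_hard_filters(records, report=freport)
    retained, _ = filtering.apply_depth_filters(
        retained, min_dp=thr.min_dp, sd_mult=thr.dp_sd_mult, report=freport
    )
    retained, _ = filtering.restrict_sites(retained, report=freport)
    try:
        freport.tstv_after = filtering.compute_tstv(retained)
    except filtering.TsTvUndefinedError:
        freport.tstv_after = None
    filtered_vcf = outdir / "filtered.vcf"
    vcfio.write_vcf(filtered_vcf, samples, retained, contigs=scaffold_lengths)
    freport.write_tsv(outdir / "filter_report.tsv")
    report["files"]["filtered_vcf"] = str(filtered_vcf.relative_to(outdir))
    report["stages"]["filter"] = {
        "stages": freport.to_rows(),
        "tstv_before": None if freport.tstv_before is None else _round(freport.tstv_before, 4),
        "tstv_after": None if freport.tstv_after is None else _round(freport.tstv_after, 4),
    }

    matrix = vcfio.records_to_matrix(samples, retained, population_of)

    # ---------------- stage: diversity panel (MAF + call rate + LD pruning)
    div_matrix, div_qc = qc.filter_snps(
        matrix, maf_min=thr.maf_min, call_rate_min=thr.call_rate_min, apply_maf=True
    )
    kept, n_ld_removed = qc.ld_prune(
        div_matrix, window_snps=thr.ld_window, step_snps=thr.ld_step, r2_max=thr.ld_r2_max
    )
    div_qc.removed_ld = n_ld_removed
    div_qc.n_sites_out -= n_ld_removed
    div_matrix = div_matrix.subset_sites(kept)
    div_qc.failed_samples = qc.sample_qc(
        div_matrix, call_rate_min=thr.sample_call_rate_min, ibs_max=thr.ibs_max
    )
    div_qc.validate()
    div_qc.write_tsv(outdir / "qc_report.tsv")
    report["stages"]["qc_diversity_panel"] = {
        row["item"]: row["count"] for row in div_qc.to_rows()
    }
    report["stages"]["qc_diversity_panel"]["failed_samples"] = [
        list(t) for t in div_qc.failed_samples
    ]

    result = diversity.diversity_summary(div_matrix)
    result.write_tsv(outdir / "diversity.tsv")
    rel = diversity.relatedness_ajk(div_matrix)
    rel.write_tsv(outdir / "relatedness.tsv")
    by_pop = {
        row["population"]: {
            "observed_het_mean": _round(row["observed_het_mean"]),
            "f_hat_mean": _round(row["f_hat_mean"]),
        }
        for _, row in result.per_population.iterrows()
    }
    report["stages"]["diversity"] = {
        "per_population": by_pop,
        "n_related_pairs": len(rel.related_pairs()),
    }

    # ---------------- stage: Hp scans per cohort (call-rate filter only)
    windows = scan.make_windows(scaffold_lengths, thr.window_size, thr.window_step)
    report["stages"]["hp"] = {}
    hp_regions: dict[str, list[scan.Region]] = {}
    hp_tested: dict[str, list[scan.GenomicWindow]] = {}
    for name, pops in hp_cohorts.items():
        sub = matrix.for_populations(pops)
        sub, _ = qc.filter_snps(
            sub, call_rate_min=thr.call_rate_min, apply_maf=False
        )
        stats = scan.window_hp(sub, windows)
        if len(stats) < 2:
            raise ConfigError(f"cohort {name!r}: fewer than 2 windows retained")
        scan.attach_zhp(stats)
        hits, cutoff = scan.significant_windows(stats, thr.tail_fraction, side="lower")
        regions = scan.merge_significant(hits, mode="min")
        hp_regions[name] = regions
        hp_tested[name] = [s.window for s in stats]
        _write_window_tsv(outdir / f"hp_windows_{name}.tsv", stats, fst_mode=False)
        vcfio.write_bed(
            outdir / f"hp_regions_{name}.bed",
            [(r.scaffold, r.start, r.end, f"zhp_min={r.extreme:.4f}") for r in regions],
        )
        report["stages"]["hp"][name] = {
            "n_snps": sub.n_sites,
            "n_windows": len(stats),
            "zhp_cutoff": _round(cutoff, 4),
            "n_significant_windows": len(hits),
            "n_regions": len(regions),
            "regions": _region_rows(regions),
        }

    # ---------------- stage: Fst scan between the two contrast cohorts
    fst_regions: list[scan.Region] = []
    fst_tested: list[scan.GenomicWindow] = []
    if fst_pair is not None:
        pair_matrix = matrix.for_populations(fst_pair)
        pair_matrix, _ = qc.filter_snps(
            pair_matrix, call_rate_min=thr.call_rate_min, apply_maf=False
        )
        stats = scan.window_fst(pair_matrix, fst_pair[0], fst_pair[1], windows)
        if len(stats) >= 2:
            hits, cutoff = scan.significant_windows(stats, thr.tail_fraction, side="upper")
            fst_regions = scan.merge_significant(hits, mode="max")
            fst_tested = [s.window for s in stats]
            _write_window_tsv(outdir / "fst_windows.tsv", stats, fst_mode=True)
            vcfio.write_bed(
                outdir / "fst_regions.bed",
                [
                    (r.scaffold, r.start, r.end, f"fst_max={r.extreme:.4f}")
                    for r in fst_regions
                ],
            )
            report["stages"]["fst"] = {
                "pair": list(fst_pair),
                "n_snps": pair_matrix.n_sites,
                "n_windows": len(stats),
                "fst_cutoff": _round(cutoff, 4),
                "n_significant_windows": len(hits),
                "n_regions": len(fst_regions),
                "regions": _region_rows(fst_regions),
            }

    # ---------------- stage: gene annotation
    if genes_path is not None:
        genes = annotate.load_genes(genes_path)
        report["stages"]["genes"] = {}
        for name, regions in {**hp_regions, "fst": fst_regions}.items():
            if name == "fst" and not fst_regions:
                continue
            hit = annotate.intersect_regions_genes(regions, genes)
            tested = hp_tested.get(name, fst_tested)
            background = annotate.background_genes(tested, genes)
            gene_ids = sorted(g.gene_id for g in hit.unique_genes)
            with open(outdir / f"genes_{name}.txt", "w") as fh:
                fh.write("\n".join(gene_ids) + ("\n" if gene_ids else ""))
            with open(outdir / f"background_genes_{name}.txt", "w") as fh:
                fh.write("\n".join(sorted(background)) + ("\n" if background else ""))
            report["stages"]["genes"][name] = {
                "n_genes": len(hit.unique_genes),
                "n_regions_with_genes": hit.n_regions_with_genes,
                "n_background_genes": len(background),
            }

    # ---------------- report
    report_json = json.dumps(report, indent=2, sort_keys=True)
    (outdir / "report.json").write_text(report_json + "\n")
    with open(outdir / "report.txt", "w") as fh:
        fh.write(_render_text_report(report))
    return report


def _render_text_report(report: dict) -> str:
    lines = [f"sweepscan run report (seed={report['seed']})", ""]
    stages = report["stages"]
    if "simulate" in stages:
        s = stages["simulate"]
        lines.append(
            f"simulate: {s['n_sites']} sites x {s['n_samples']} samples; "
            f"{s['n_truth_sweeps']} truth sweeps, {s['n_failing_sites']} filter-violating sites"
        )
    if "filter" in stages:
        for row in stages["filter"]["stages"]:
            lines.append(
                f"filter/{row['stage']}: {row['n_input']} -> {row['n_retained']} "
                f"({row['n_removed']} removed)"
            )
        lines.append(
            f"filter: Ts/Tv before={stages['filter']['tstv_before']} "
            f"after={stages['filter']['tstv_after']}"
        )
    if "hp" in stages:
        for name, h in stages["hp"].items():
            lines.append(
                f"hp[{name}]: {h['n_windows']} windows, cutoff ZHp={h['zhp_cutoff']}, "
                f"{h['n_significant_windows']} significant -> {h['n_regions']} regions"
            )
    if "fst" in stages:
        f = stages["fst"]
        lines.append(
            f"fst[{f['pair'][0]} vs {f['pair'][1]}]: {f['n_windows']} windows, "
            f"cutoff Fst={f['fst_cutoff']}, {f['n_significant_windows']} significant "
            f"-> {f['n_regions']} regions"
        )
    if "genes" in stages:
        for name, g in stages["genes"].items():
            lines.append(
                f"genes[{name}]: {g['n_genes']} genes in "
                f"{g['n_regions_with_genes']} regions (background {g['n_background_genes']})"
            )
    return "\n".join(lines) + "\n"
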