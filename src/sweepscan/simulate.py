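"""Reproducible synthetic cohort generator.

Produces a sparse GBS-like diploid SNP panel over multiple scaffolds for two
or more populations whose allele frequencies diverge under the
Balding-Nichols Beta model, with optional implanted low-heterozygosity
(sweep) regions, high-differentiation regions, per-genotype missingness, and
a controlled fraction of sites whose INFO annotations violate one named hard
filter. Outputs are plain text (VCF v4.2, TSV sample map, GFF3 genes, BED
truth intervals) and byte-identical for identical configurations.

A single RNG stream seeded from the config drives everything, with this
fixed draw order:

1. site positions, per scaffold in config order;
2. ancestral allele frequencies (Uniform(0.05, 0.95));
3. transition/transversion choice, then REF base, then ALT base;
4. Balding-Nichols per-population frequencies (populations in config order);
5. sweep adjustments, per sweep region in config order (target populations in
   config order for ``"all"``);
6. differentiation adjustments, per region in config order;
7. genotypes, per population in config order;
8. missingness mask;
9. INFO values (QD, FS, MQ, MQRankSum, ReadPosRankSum, DP, QUAL);
10. filter-violating site selection;
11. synthetic gene intervals, per scaffold in config order.

All interval parameters (sweep/diff regions) use 0-based half-open BED
coordinates; a 1-based VCF position p falls in [start, end) iff
start <= p - 1 < end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from sweepscan import vcfio
from sweepscan.filtering import VariantRecord
from sweepscan.matrix import MISSING, GenotypeMatrix

TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
TRANSVERSIONS = {"A": ("C", "T"), "G": ("C", "T"), "C": ("A", "G"), "T": ("A", "G")}
BASES = "ACGT"

#: Hard-filter names cycled through when assigning violating sites, and the
#: just-past-threshold values written for them.
FILTER_VIOLATION_VALUES: dict[str, float] = {
    "QD": 1.9,
    "FS": 60.01,
    "MQ": 39.9,
    "QUAL": 29.9,
    "MQRankSum": -12.51,
    "ReadPosRankSum": -8.01,
}


class DegenerateFrequencyError(ValueError):
    """Ancestral frequency of 0 or 1: the site is monomorphic by construction."""


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SweepRegionSpec:
    scaffold: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    population: str = "all"
    fixation_level: float = 0.98


@dataclass(frozen=True)
class DiffRegionSpec:
    scaffold: str
    start: int
    end: int
    delta_freq: float = 0.5


@dataclass
class SimulationConfig:
    seed: int
    scaffolds: list[tuple[str, int]]
    populations: list[tuple[str, int]]
    snp_density: float = 1.0 / 1000
    F_divergence: float = 0.0
    sweep_regions: list[SweepRegionSpec] = field(default_factory=list)
    diff_regions: list[DiffRegionSpec] = field(default_factory=list)
    missing_rate: float = 0.0
    info_fail_fraction: float = 0.0
    tstv_target: float = 2.0

    def __post_init__(self) -> None:
        if not self.scaffolds:
            raise ConfigError("at least one scaffold is required")
        if not self.populations or sum(n for _, n in self.populations) == 0:
            raise ConfigError("at least one individual is required")
        if not (0.0 <= self.F_divergence < 1.0):
            raise ConfigError("F_divergence must be in [0, 1)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigError("missing_rate must be in [0, 1)")
        if not (0.0 <= self.info_fail_fraction <= 1.0):
            raise ConfigError("info_fail_fraction must be in [0, 1]")
        if self.snp_density <= 0:
            raise ConfigError("snp_density must be positive")
        lengths = dict(self.scaffolds)
        pop_names = {name for name, _ in self.populations}
        self.sweep_regions = [
            r if isinstance(r, SweepRegionSpec) else SweepRegionSpec(*r)
            for r in self.sweep_regions
        ]
        self.diff_regions = [
            r if isinstance(r, DiffRegionSpec) else DiffRegionSpec(*r)
            for r in self.diff_regions
        ]
        for r in self.sweep_regions:
            if r.scaffold not in lengths or not (0 <= r.start < r.end <= lengths[r.scaffold]):
                raise ConfigError(f"sweep region {r} outside its scaffold")
            if not (0.5 <= r.fixation_level <= 1.0):
                raise ConfigError("fixation_level must be in [0.5, 1]")
            if r.population != "all" and r.population not in pop_names:
                raise ConfigError(f"unknown sweep target population {r.population!r}")
        for r in self.diff_regions:
            if r.scaffold not in lengths or not (0 <= r.start < r.end <= lengths[r.scaffold]):
                raise ConfigError(f"diff region {r} outside its scaffold")
            if not (0.0 < r.delta_freq <= 1.0):
                raise ConfigError("delta_freq must be in (0, 1]")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        d["scaffolds"] = [tuple(s) for s in d["scaffolds"]]
        d["populations"] = [tuple(p) for p in d["populations"]]
        d["sweep_regions"] = [
            SweepRegionSpec(**r) if isinstance(r, dict) else SweepRegionSpec(*r)
            for r in d.get("sweep_regions", [])
        ]
        d["diff_regions"] = [
            DiffRegionSpec(**r) if isinstance(r, dict) else DiffRegionSpec(*r)
            for r in d.get("diff_regions", [])
        ]
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class SimTruth:
    """Ground truth of a simulated cohort, for recovery testing."""

    sweep_intervals: list[SweepRegionSpec]
    diff_intervals: list[DiffRegionSpec]
    ancestral_freq: np.ndarray  # per site
    pop_freq: np.ndarray  # (n_pops, n_sites), post sweep/diff adjustment
    failing_sites: pd.DataFrame  # columns scaffold, pos, filter
    populations: list[str] = field(default_factory=list)


@dataclass
class SimCohort:
    config: SimulationConfig
    samples: list[str]
    population_of: dict[str, str]
    sites: pd.DataFrame  # scaffold, pos, ref, alt
    records: list[VariantRecord]
    matrix: GenotypeMatrix
    truth: SimTruth
    genes: pd.DataFrame  # scaffold, start, end, strand, gene_id


# ----------------------------------------------------------------------
def sample_bn_frequencies(
    p_anc: float, F: float, n_pops: int, rng: np.random.Generator
) -> np.ndarray:
    """Balding-Nichols per-population allele frequencies.

    For drift F > 0 each population frequency is a Beta draw with mean
    ``p_anc`` and variance ``F * p_anc * (1 - p_anc)``; for F = 0 all
    populations get ``p_anc`` exactly.
    """
    if not (0.0 < p_anc < 1.0):
        raise DegenerateFrequencyError(f"ancestral frequency {p_anc} is monomorphic")
    if not (0.0 <= F < 1.0):
        raise ValueError("F must be in [0, 1)")
    if F == 0.0:
        return np.full(n_pops, p_anc)
    scale = (1.0 - F) / F
    return rng.beta(p_anc * scale, (1.0 - p_anc) * scale, size=n_pops)


def implant_sweep(
    freqs: np.ndarray,
    scaffolds: Sequence[str],
    positions: np.ndarray,
    region: SweepRegionSpec,
    fixation_level: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Push the major allele of in-region sites to frequency >= fixation_level.

    ``freqs`` is one population's per-site frequency vector aligned with
    ``scaffolds``/``positions`` (1-based). Sites outside the region are
    untouched; a region containing no site warns and no-ops.
    """
    if fixation_level < 0.5:
        raise ValueError("fixation_level must be >= 0.5")
    freqs = np.asarray(freqs, dtype=float).copy()
    pos0 = np.asarray(positions) - 1
    mask = (
        (np.asarray(scaffolds) == region.scaffold)
        & (pos0 >= region.start)
        & (pos0 < region.end)
    )
    k = int(mask.sum())
    if k == 0:
        warnings.warn(
            f"sweep region {region.scaffold}:[{region.start},{region.end}) "
            "contains no sites; skipped",
            stacklevel=2,
        )
        return freqs
    major = rng.uniform(fixation_level, 1.0, size=k)
    freqs[mask] = np.where(freqs[mask] >= 0.5, major, 1.0 - major)
    return freqs


def _implant_diff(
    pop_freq: np.ndarray,
    scaffolds: np.ndarray,
    positions: np.ndarray,
    region: DiffRegionSpec,
    rng: np.random.Generator,
) -> None:
    """Force |p_pop0 - p_pop1| = delta_freq for in-region sites (in place).

    The first two configured populations are contrasted; others untouched.
    """
    pos0 = positions - 1
    mask = (scaffolds == region.scaffold) & (pos0 >= region.start) & (pos0 < region.end)
    k = int(mask.sum())
    if k == 0:
        warnings.warn(
            f"diff region {region.scaffold}:[{region.start},{region.end}) "
            "contains no sites; skipped",
            stacklevel=2,
        )
        return
    delta = region.delta_freq
    hi = rng.uniform(min(delta + 0.01, 1.0), 1.0, size=k) if delta < 0.99 else np.ones(k)
    pop_freq[0, mask] = hi
    pop_freq[1, mask] = hi - delta


# ----------------------------------------------------------------------
def _draw_sites(config: SimulationConfig, rng: np.random.Generator):
    scaffold_col: list[str] = []
    pos_col: list[int] = []
    for name, length in config.scaffolds:
        n = int(round(config.snp_density * length))
        n = min(n, length)
        pos = np.sort(rng.choice(length, size=n, replace=False)) + 1
        scaffold_col.extend([name] * n)
        pos_col.extend(int(p) for p in pos)
    return np.asarray(scaffold_col, dtype=object), np.asarray(pos_col, dtype=np.int64)


def _draw_alleles(m: int, tstv_target: float, rng: np.random.Generator):
    p_ts = tstv_target / (tstv_target + 1.0)
    is_ts = rng.random(m) < p_ts
    ref_idx = rng.integers(0, 4, size=m)
    tv_pick = rng.integers(0, 2, size=m)
    refs = np.array([BASES[i] for i in ref_idx], dtype=object)
    alts = np.empty(m, dtype=object)
    for i in range(m):
        r = refs[i]
        alts[i] = TRANSITION[r] if is_ts[i] else TRANSVERSIONS[r][tv_pick[i]]
    return refs, alts


def simulate_cohort(config: SimulationConfig) -> SimCohort:
    """Run the full simulation in memory. See module docstring for draw order."""
    rng = np.random.default_rng(config.seed)

    # 1-3: sites, ancestral frequencies, alleles
    scaffolds, positions = _draw_sites(config, rng)
    m = len(positions)
    p_anc = rng.uniform(0.05, 0.95, size=m)
    refs, alts = _draw_alleles(m, config.tstv_target, rng)

    # 4: Balding-Nichols population frequencies
    pop_names = [name for name, _ in config.populations]
    n_pops = len(pop_names)
    if config.F_divergence == 0.0:
        pop_freq = np.tile(p_anc, (n_pops, 1))
    else:
        scale = (1.0 - config.F_divergence) / config.F_divergence
        pop_freq = np.empty((n_pops, m))
        for i in range(n_pops):
            pop_freq[i] = rng.beta(p_anc * scale, (1.0 - p_anc) * scale)

    # 5: sweeps
    for region in config.sweep_regions:
        targets = pop_names if region.population == "all" else [region.population]
        for pop in targets:
            i = pop_names.index(pop)
            pop_freq[i] = implant_sweep(
                pop_freq[i], scaffolds, positions, region, region.fixation_level, rng
            )

    # 6: differentiation regions
    for region in config.diff_regions:
        if n_pops < 2:
            raise ConfigError("diff_regions require at least two populations")
        _implant_diff(pop_freq, scaffolds, positions, region, rng)

    # 7: genotypes under Hardy-Weinberg within each population
    samples: list[str] = []
    population_of: dict[str, str] = {}
    blocks = []
    for (pop, n_ind) in config.populations:
        i = pop_names.index(pop)
        blocks.append(rng.binomial(2, pop_freq[i], size=(n_ind, m)).astype(np.int8))
        for j in range(n_ind):
            sid = f"{pop}_{j:03d}"
            samples.append(sid)
            population_of[sid] = pop
    dosage = np.vstack(blocks)

    # 8: missingness
    if config.missing_rate > 0:
        mask = rng.random(dosage.shape) < config.missing_rate
        dosage[mask] = MISSING

    # 9: INFO annotations for "clean" sites, drawn from passing ranges
    qd = rng.uniform(5.0, 30.0, size=m)
    fs = rng.uniform(0.0, 10.0, size=m)
    mq = rng.uniform(50.0, 60.0, size=m)
    mqrs = rng.uniform(-2.0, 2.0, size=m)
    rprs = rng.uniform(-2.0, 2.0, size=m)
    dp = rng.integers(15, 26, size=m)
    qual = rng.uniform(50.0, 1000.0, size=m)

    # 10: filter-violating sites
    filter_names = list(FILTER_VIOLATION_VALUES)
    k = int(round(config.info_fail_fraction * m))
    fail_idx = np.sort(rng.choice(m, size=k, replace=False)) if k else np.empty(0, int)
    fail_rows = []
    for rank, i in enumerate(fail_idx):
        name = filter_names[rank % len(filter_names)]
        value = FILTER_VIOLATION_VALUES[name]
        if name == "QD":
            qd[i] = value
        elif name == "FS":
            fs[i] = value
        elif name == "MQ":
            mq[i] = value
        elif name == "QUAL":
            qual[i] = value
        elif name == "MQRankSum":
            mqrs[i] = value
        elif name == "ReadPosRankSum":
            rprs[i] = value
        fail_rows.append({"scaffold": scaffolds[i], "pos": int(positions[i]), "filter": name})

    # 11: synthetic non-overlapping gene features
    gene_rows = []
    for name, length in config.scaffolds:
        cursor = int(rng.integers(1_000, 10_000))
        g = 0
        while True:
            gene_len = int(rng.integers(5_000, 30_000))
            gap = int(rng.integers(2_000, 20_000))
            strand = "+" if rng.random() < 0.5 else "-"
            end = cursor + gene_len
            if end > length:
                break
            gene_rows.append(
                {
                    "scaffold": name,
                    "start": cursor,
                    "end": end,
                    "strand": strand,
                    "gene_id": f"gene_{name}_{g:04d}",
                }
            )
            cursor = end + gap
            g += 1
    genes = pd.DataFrame(gene_rows, columns=["scaffold", "start", "end", "strand", "gene_id"])

    # assemble records and matrix
    records: list[VariantRecord] = []
    for i in range(m):
        genotypes = []
        for d in dosage[:, i]:
            if d == MISSING:
                genotypes.append((None, None))
            elif d == 0:
                genotypes.append((0, 0))
            elif d == 1:
                genotypes.append((0, 1))
            else:
                genotypes.append((1, 1))
        records.append(
            VariantRecord(
                scaffold=str(scaffolds[i]),
                pos=int(positions[i]),
                ref=str(refs[i]),
                alts=(str(alts[i]),),
                qual=float(qual[i]),
                info={
                    "QD": float(qd[i]),
                    "FS": float(fs[i]),
                    "MQ": float(mq[i]),
                    "MQRankSum": float(mqrs[i]),
                    "ReadPosRankSum": float(rprs[i]),
                    "DP": int(dp[i]),
                },
                genotypes=tuple(genotypes),
            )
        )
    sites = pd.DataFrame(
        {"scaffold": scaffolds, "pos": positions, "ref": refs, "alt": alts}
    )
    matrix = GenotypeMatrix(samples, sites.copy(), dosage, population_of)
    truth = SimTruth(
        sweep_intervals=list(config.sweep_regions),
        diff_intervals=list(config.diff_regions),
        ancestral_freq=p_anc,
        pop_freq=pop_freq,
        failing_sites=pd.DataFrame(fail_rows, columns=["scaffold", "pos", "filter"]),
        populations=pop_names,
    )
    return SimCohort(config, samples, population_of, sites, records, matrix, truth, genes)


# ----------------------------------------------------------------------
def write_gff3(path, genes: pd.DataFrame) -> None:
    """Write gene features as GFF3 (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples(index=False):
            fh.write(
                f"{row.scaffold}\tsweepscan\tgene\t{row.start + 1}\t{row.end}\t.\t"
                f"{row.strand}\t.\tID={row.gene_id};Name={row.gene_id}\n"
            )


def generate_cohort(config: SimulationConfig, outdir) -> tuple[SimCohort, dict[str, Path]]:
    """Simulate and write every output file under ``outdir``.

    Returns the in-memory cohort plus a manifest of written paths.
    """
    cohort = simulate_cohort(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "cohort.vcf",
        "sample_map": outdir / "samples.tsv",
        "genes": outdir / "genes.gff3",
        "scaffolds": outdir / "scaffolds.tsv",
        "truth_sweeps": outdir / "truth_sweeps.bed",
        "truth_diff": outdir / "truth_diff.bed",
        "truth_filters": outdir / "truth_failing_sites.tsv",
    }
    vcfio.write_vcf(
        paths["vcf"], cohort.samples, cohort.records, contigs=dict(config.scaffolds)
    )
    vcfio.write_sample_map(paths["sample_map"], cohort.population_of)
    write_gff3(paths["genes"], cohort.genes)
    vcfio.write_scaffold_lengths(paths["scaffolds"], dict(config.scaffolds))
    vcfio.write_bed(
        paths["truth_sweeps"],
        [
            (r.scaffold, r.start, r.end, f"{r.population};fixation={r.fixation_level}")
            for r in cohort.truth.sweep_intervals
        ],
    )
    vcfio.write_bed(
        paths["truth_diff"],
        [
            (r.scaffold, r.start, r.end, f"delta={r.delta_freq}")
            for r in cohort.truth.diff_intervals
        ],
    )
    cohort.truth.failing_sites.to_csv(paths["truth_filters"], sep="\t", index=False)
    return cohort, paths
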