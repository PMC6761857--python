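"""Site-level VCF filtering: hard filters, depth filters, site restriction, Ts/Tv.

All stages are record-local except the depth filter, which fixes the DP
mean/SD over the whole input in a first pass before removing anything.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

#: Default removal thresholds: a record is removed when the named annotation
#: is present and the comparison holds. "QUAL" reads the record QUAL column.
DEFAULT_HARD_FILTERS: dict[str, tuple[str, float]] = {
    "QD": ("<", 2.0),
    "FS": (">", 60.0),
    "MQ": ("<", 40.0),
    "QUAL": ("<", 30.0),
    "MQRankSum": ("<", -12.5),
    "ReadPosRankSum": ("<", -8.0),
}

DEFAULT_EXCLUDED_SCAFFOLDS = frozenset({"NC_009849.1"})


class VariantParseError(ValueError):
    """Malformed INFO value, carrying scaffold:pos context."""


class TsTvUndefinedError(ZeroDivisionError):
    """Raised when a Ts/Tv ratio is undefined; carries both counts."""

    def __init__(self, transitions: int, transversions: int):
        self.transitions = transitions
        self.transversions = transversions
        super().__init__(
            f"Ts/Tv undefined: {transitions} transitions, {transversions} transversions"
        )


@dataclass
class VariantRecord:
    """One VCF site with the annotations the filtering cascade consumes."""

    scaffold: str
    pos: int  # 1-based
    ref: str
    alts: tuple[str, ...]
    qual: Optional[float] = None
    info: dict = field(default_factory=dict)
    genotypes: tuple[tuple[Optional[int], Optional[int]], ...] = ()
    id: str = "."

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref:
            raise ValueError("ref allele must be non-empty")
        self.alts = tuple(self.alts)
        n_alleles = 1 + len(self.alts)
        for gt in self.genotypes:
            for a in gt:
                if a is not None and not (0 <= a < n_alleles):
                    raise ValueError(
                        f"{self.scaffold}:{self.pos}: genotype allele index {a} "
                        f"out of range for {n_alleles} alleles"
                    )

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and all(len(a) == 1 for a in self.alts)

    @property
    def is_biallelic(self) -> bool:
        return len(self.alts) == 1

    def info_float(self, key: str) -> Optional[float]:
        """Numeric INFO value, or None if absent.

        Raises :class:`VariantParseError` on a non-numeric value.
        """
        if key == "QUAL":
            return self.qual
        value = self.info.get(key)
        if value is None:
            return None
        try:
            return float(value)
        except (TypeError, ValueError) as exc:
            raise VariantParseError(
                f"{self.scaffold}:{self.pos}: INFO field {key}={value!r} is not numeric"
            ) from exc


@dataclass
class FilterStage:
    name: str
    n_input: int
    n_removed: int

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_removed


@dataclass
class FilterReport:
    """Per-stage input/removed/retained accounting plus Ts/Tv before/after."""

    stages: list[FilterStage] = field(default_factory=list)
    tstv_before: Optional[float] = None
    tstv_after: Optional[float] = None
    #: (scaffold, pos) -> list of removal reasons, filled by each stage.
    reasons: dict[tuple[str, int], list[str]] = field(default_factory=dict)

    def add_stage(self, name: str, n_input: int, n_removed: int) -> FilterStage:
        if n_removed < 0 or n_removed > n_input:
            raise ValueError("stage counts must satisfy 0 <= removed <= input")
        stage = FilterStage(name, n_input, n_removed)
        self.stages.append(stage)
        return stage

    def record_reason(self, record: VariantRecord, reason: str) -> None:
        self.reasons.setdefault((record.scaffold, record.pos), []).append(reason)

    def extend(self, other: "FilterReport") -> None:
        self.stages.extend(other.stages)
        for key, why in other.reasons.items():
            self.reasons.setdefault(key, []).extend(why)

    def to_rows(self) -> list[dict]:
        return [
            {
                "stage": s.name,
                "n_input": s.n_input,
                "n_removed": s.n_removed,
                "n_retained": s.n_retained,
            }
            for s in self.stages
        ]

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("stage\tn_input\tn_removed\tn_retained\n")
            for row in self.to_rows():
                fh.write(
                    f"{row['stage']}\t{row['n_input']}\t{row['n_removed']}\t{row['n_retained']}\n"
                )
            if self.tstv_before is not None:
                fh.write(f"# tstv_before\t{self.tstv_before:.4f}\n")
            if self.tstv_after is not None:
                fh.write(f"# tstv_after\t{self.tstv_after:.4f}\n")


def _violates(value: float, op: str, threshold: float) -> bool:
    if op == "<":
        return value < threshold
    if op == ">":
        return value > threshold
    if op == "<=":
        return value <= threshold
    if op == ">=":
        return value >= threshold
    raise ValueError(f"unsupported comparison operator {op!r}")


def apply_hard_filters(
    records: Iterable[VariantRecord],
    thresholds: Mapping[str, tuple[str, float]] | None = None,
    report: FilterReport | None = None,
) -> tuple[list[VariantRecord], FilterReport]:
    """Remove records where any *present* annotation violates its threshold.

    Missing annotations never cause removal. Removal reasons are recorded in
    the report keyed by (scaffold, pos).
    """
    thresholds = dict(DEFAULT_HARD_FILTERS if thresholds is None else thresholds)
    report = report if report is not None else FilterReport()
    retained: list[VariantRecord] = []
    n_in = n_removed = 0
    for record in records:
        n_in += 1
        failed = []
        for key, (op, cut) in thresholds.items():
            value = record.info_float(key)
            if value is not None and _violates(value, op, cut):
                failed.append(key)
        if failed:
            n_removed += 1
            for key in failed:
                report.record_reason(record, f"hard_filter:{key}")
        else:
            retained.append(record)
    report.add_stage("hard_filters", n_in, n_removed)
    return retained, report


def apply_depth_filters(
    records: Sequence[VariantRecord],
    min_dp: float = 5.0,
    sd_mult: float = 3.0,
    report: FilterReport | None = None,
    use_mean_sample_dp: bool = False,
) -> tuple[list[VariantRecord], FilterReport]:
    """Depth filter: DP >= ``min_dp`` and within ``sd_mult`` SDs of the mean.

    Two-pass contract: mean and sample SD (n-1 denominator) of DP are computed
    over all input records before any removal. ``use_mean_sample_dp`` switches
    the DP source from site INFO DP to the mean of per-sample depths stored in
    INFO key ``sample_DP`` (alternative reading; off by default).
    """
    records = list(records)
    report = report if report is not None else FilterReport()
    key = "sample_DP_mean" if use_mean_sample_dp else "DP"

    depths = []
    for record in records:
        value = record.info_float(key)
        depths.append(np.nan if value is None else value)
    depths_arr = np.asarray(depths, dtype=float)
    present = ~np.isnan(depths_arr)
    if present.sum() >= 2:
        mean = float(np.mean(depths_arr[present]))
        sd = float(np.std(depths_arr[present], ddof=1))
    elif present.sum() == 1:
        mean, sd = float(depths_arr[present][0]), 0.0
    else:
        mean, sd = 0.0, 0.0
    lo, hi = mean - sd_mult * sd, mean + sd_mult * sd

    retained: list[VariantRecord] = []
    n_removed = 0
    for record, dp, ok in zip(records, depths_arr, present):
        if not ok:
            n_removed += 1
            report.record_reason(record, "DP-missing")
            logger.warning("%s:%d lacks DP; removed", record.scaffold, record.pos)
            continue
        if dp < min_dp:
            n_removed += 1
            report.record_reason(record, "DP-min")
        elif not (lo <= dp <= hi):
            n_removed += 1
            report.record_reason(record, "DP-outlier")
        else:
            retained.append(record)
    report.add_stage("depth_filters", len(records), n_removed)
    return retained, report


def restrict_sites(
    records: Iterable[VariantRecord],
    excluded_scaffolds: frozenset[str] | set[str] = DEFAULT_EXCLUDED_SCAFFOLDS,
    report: FilterReport | None = None,
) -> tuple[list[VariantRecord], FilterReport]:
    """Keep bi-allelic single-nucleotide sites off the excluded scaffolds."""
    excluded = set(excluded_scaffolds)
    report = report if report is not None else FilterReport()
    retained: list[VariantRecord] = []
    n_in = n_removed = 0
    for record in records:
        n_in += 1
        reasons = []
        if record.scaffold in excluded:
            reasons.append("excluded-scaffold")
        if not record.is_biallelic:
            reasons.append("multi-allelic")
        if not record.is_snp:
            reasons.append("indel")
        if reasons:
            n_removed += 1
            for why in reasons:
                report.record_reason(record, why)
        else:
            retained.append(record)
    report.add_stage("restrict_sites", n_in, n_removed)
    return retained, report


def classify_substitution(ref: str, alt: str) -> str:
    """Classify a single-base substitution as ``"ts"`` or ``"tv"``."""
    ref, alt = ref.upper(), alt.upper()
    if len(ref) != 1 or len(alt) != 1 or ref == alt:
        raise ValueError(f"not a substitution: {ref}/{alt}")
    if {ref, alt} <= PURINES or {ref, alt} <= PYRIMIDINES:
        return "ts"
    return "tv"


def compute_tstv(records: Iterable[VariantRecord]) -> float:
    """Transition/transversion ratio over bi-allelic SNP records."""
    ts = tv = 0
    for record in records:
        if not (record.is_snp and record.is_biallelic):
            continue
        if classify_substitution(record.ref, record.alts[0]) == "ts":
            ts += 1
        else:
            tv += 1
    if tv == 0:
        raise TsTvUndefinedError(ts, tv)
    return ts / tv


def intersect_callers(
    primary: Iterable[VariantRecord],
    secondary: Iterable[VariantRecord],
    report: FilterReport | None = None,
) -> tuple[list[VariantRecord], FilterReport]:
    """Set-intersect two call sets on (scaffold, pos, ref, alt) keys.

    Genotypes (and QUAL/INFO) are taken from the *secondary* records.
    """
    report = report if report is not None else FilterReport()
    keys = {(r.scaffold, r.pos, r.ref, r.alts) for r in primary}
    secondary = list(secondary)
    retained = [r for r in secondary if (r.scaffold, r.pos, r.ref, r.alts) in keys]
    report.add_stage("caller_intersection", len(secondary), len(secondary) - len(retained))
    return retained, report
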