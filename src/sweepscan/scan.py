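"""Windowed selection scans.

Two statistics over half-open sliding windows on each scaffold:

* pooled heterozygosity Hp = 2 * sum(n_MAJ) * sum(n_MIN) / (sum(n_MAJ) +
  sum(n_MIN))^2 per window, Z-transformed with median centering and sample SD;
* weighted two-population Fst, combining Weir-Cockerham per-site variance
  components as sum(a) / sum(a + b + c) within each window.

Windows supported by fewer than two SNPs are discarded; significance is an
empirical-tail quantile; overlapping significant windows merge into regions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from sweepscan.matrix import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_SIZE = 50_000
DEFAULT_WINDOW_STEP = 25_000
DEFAULT_TAIL_FRACTION = 0.001


class DegenerateDistributionError(ValueError):
    """Raised when a Z-transform is requested for a zero-variance sample."""


@dataclass(frozen=True, order=True)
class GenomicWindow:
    """Half-open interval [start, end) on a scaffold, 0-based."""

    scaffold: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid window [{self.start}, {self.end})")

    def overlaps(self, other: "GenomicWindow") -> bool:
        return (
            self.scaffold == other.scaffold
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class WindowStat:
    window: GenomicWindow
    n_snps: int
    sum_nmaj: int = 0
    sum_nmin: int = 0
    hp: Optional[float] = None
    zhp: Optional[float] = None
    sum_a: Optional[float] = None
    sum_abc: Optional[float] = None
    fst_weighted: Optional[float] = None

    @property
    def value(self) -> float:
        """The scanned statistic: ZHp if present, else weighted Fst."""
        if self.zhp is not None:
            return self.zhp
        if self.fst_weighted is not None:
            return self.fst_weighted
        raise ValueError("window statistic not yet computed")


@dataclass
class Region:
    scaffold: str
    start: int
    end: int
    windows: list[WindowStat] = field(default_factory=list)
    extreme: float = float("nan")

    @property
    def n_windows(self) -> int:
        return len(self.windows)


@dataclass(frozen=True)
class FstSiteComponents:
    a: float
    b: float
    c: float

    @property
    def theta(self) -> float:
        denom = self.a + self.b + self.c
        if denom == 0:
            return float("nan")
        return self.a / denom


# ----------------------------------------------------------------------
def make_windows(
    scaffold_lengths: Mapping[str, int],
    size: int = DEFAULT_WINDOW_SIZE,
    step: int = DEFAULT_WINDOW_STEP,
) -> list[GenomicWindow]:
    """Sliding windows anchored at 0; the trailing window is truncated."""
    if not (size >= step > 0):
        raise ValueError(f"need size >= step > 0, got size={size}, step={step}")
    windows: list[GenomicWindow] = []
    for scaffold, length in scaffold_lengths.items():
        if length <= 0:
            raise ValueError(f"scaffold {scaffold} has non-positive length {length}")
        for start in range(0, length, step):
            if start >= length:
                break
            windows.append(GenomicWindow(scaffold, start, min(start + size, length)))
    return windows


def _site_major_minor(matrix: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Observed major/minor allele counts per site over non-missing calls."""
    called = matrix.called
    n_called = called.sum(axis=0)
    n_alt = np.where(called, matrix.dosage, 0).sum(axis=0)
    n_ref = 2 * n_called - n_alt
    return np.maximum(n_ref, n_alt), np.minimum(n_ref, n_alt)


def _window_site_index(
    matrix: GenotypeMatrix, windows: Sequence[GenomicWindow]
) -> list[np.ndarray]:
    """Site indices per window; a site belongs to every window containing it.

    VCF positions are 1-based: position p lies in [start, end) iff
    start <= p - 1 < end.
    """
    scaffolds = matrix.sites["scaffold"].to_numpy()
    pos0 = matrix.sites["pos"].to_numpy() - 1
    by_scaffold: dict[str, np.ndarray] = {
        s: np.flatnonzero(scaffolds == s) for s in dict.fromkeys(scaffolds)
    }
    out = []
    for w in windows:
        idx = by_scaffold.get(w.scaffold)
        if idx is None:
            out.append(np.empty(0, dtype=int))
            continue
        p = pos0[idx]
        lo = np.searchsorted(p, w.start, side="left")
        hi = np.searchsorted(p, w.end, side="left")
        out.append(idx[lo:hi])
    return out


def window_hp(
    matrix: GenotypeMatrix, windows: Sequence[GenomicWindow]
) -> list[WindowStat]:
    """Pooled heterozygosity per window; windows with < 2 SNPs are discarded."""
    nmaj, nmin = _site_major_minor(matrix)
    stats: list[WindowStat] = []
    for w, idx in zip(windows, _window_site_index(matrix, windows)):
        if len(idx) < 2:
            continue
        s_maj = int(nmaj[idx].sum())
        s_min = int(nmin[idx].sum())
        total = s_maj + s_min
        hp = 2.0 * s_maj * s_min / (total * total) if total > 0 else 0.0
        stats.append(
            WindowStat(window=w, n_snps=len(idx), sum_nmaj=s_maj, sum_nmin=s_min, hp=hp)
        )
    return stats


def z_transform(values: Sequence[float]) -> np.ndarray:
    """(value - median) / sample SD (n-1 denominator) over all values."""
    arr = np.asarray(values, dtype=float)
    if len(arr) < 2:
        raise ValueError("need >=2 values to Z-transform")
    sd = float(np.std(arr, ddof=1))
    if sd == 0.0:
        raise DegenerateDistributionError("zero variance; Z-transform undefined")
    return (arr - float(np.median(arr))) / sd


def attach_zhp(stats: list[WindowStat]) -> list[WindowStat]:
    z = z_transform([s.hp for s in stats])
    for s, v in zip(stats, z):
        s.zhp = float(v)
    return stats


def empirical_threshold(
    values: Sequence[float], tail_fraction: float = DEFAULT_TAIL_FRACTION,
    side: str = "lower",
) -> float:
    """Empirical-tail cutoff via the linear-interpolation quantile
    (order-statistic index h = q*(n-1) + 1).

    Significance is value <= threshold for ``side="lower"`` and
    value >= threshold for ``side="upper"``.
    """
    if not (0.0 < tail_fraction < 0.5):
        raise ValueError("tail_fraction must be in (0, 0.5)")
    if side not in {"lower", "upper"}:
        raise ValueError("side must be 'lower' or 'upper'")
    arr = np.asarray(values, dtype=float)
    if len(arr) == 0:
        raise ValueError("empty sample")
    if len(arr) < 1.0 / tail_fraction:
        warnings.warn(
            f"{len(arr)} values at tail {tail_fraction}: fewer than one value "
            "expected in the tail",
            stacklevel=2,
        )
    q = tail_fraction if side == "lower" else 1.0 - tail_fraction
    return float(np.quantile(arr, q, method="linear"))


def significant_windows(
    stats: Sequence[WindowStat], tail_fraction: float = DEFAULT_TAIL_FRACTION,
    side: str = "lower",
) -> tuple[list[WindowStat], float]:
    values = [s.value for s in stats]
    cutoff = empirical_threshold(values, tail_fraction, side)
    if side == "lower":
        hits = [s for s in stats if s.value <= cutoff]
    else:
        hits = [s for s in stats if s.value >= cutoff]
    return hits, cutoff


# ----------------------------------------------------------------------
def fst_site_components(
    n1: int, p1: float, h1: float, n2: int, p2: float, h2: float
) -> FstSiteComponents:
    """Weir-Cockerham variance components for one bi-allelic site, two
    populations of ``n1``/``n2`` called diploids with allele frequencies
    ``p1``/``p2`` and observed heterozygote fractions ``h1``/``h2``.

    A site monomorphic across both populations returns (0, 0, 0).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need >=2 called diploids in each population")
    if p1 == p2 and p1 in (0.0, 1.0) and h1 == 0.0 and h2 == 0.0:
        return FstSiteComponents(0.0, 0.0, 0.0)
    r = 2
    n_sum = n1 + n2
    n_bar = n_sum / r
    n_c = n_sum - (n1 * n1 + n2 * n2) / n_sum
    p_bar = (n1 * p1 + n2 * p2) / n_sum
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
    h_bar = (n1 * h1 + n2 * h2) / n_sum

    a = (n_bar / n_c) * (
        s2
        - (1.0 / (n_bar - 1))
        * (p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - h_bar / 4.0)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar)
        - ((r - 1) / r) * s2
        - ((2 * n_bar - 1) / (4 * n_bar)) * h_bar
    )
    c = h_bar / 2.0
    return FstSiteComponents(a, b, c)


def _cohort_site_summaries(matrix: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(n called diploids, alt frequency, het fraction) per site."""
    called = matrix.called
    n = called.sum(axis=0)
    alt = np.where(called, matrix.dosage, 0).sum(axis=0)
    het = ((matrix.dosage == 1) & called).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / (2.0 * n), np.nan)
        h = np.where(n > 0, het / n, np.nan)
    return n, p, h


def window_fst(
    matrix: GenotypeMatrix,
    pop_a: str,
    pop_b: str,
    windows: Sequence[GenomicWindow],
    min_called: int = 2,
) -> list[WindowStat]:
    """Weighted Fst per window between two cohorts.

    Per-site components come from :func:`fst_site_components`; sites with
    fewer than ``min_called`` called diploids in either cohort, or monomorphic
    across both, contribute nothing. Windows with < 2 contributing SNPs are
    discarded; a window whose component denominator sums to 0 is dropped with
    a warning. Negative window values are reported as computed.
    """
    sub_a = matrix.for_populations([pop_a])
    sub_b = matrix.for_populations([pop_b])
    n1, p1, h1 = _cohort_site_summaries(sub_a)
    n2, p2, h2 = _cohort_site_summaries(sub_b)

    m = matrix.n_sites
    a_arr = np.zeros(m)
    b_arr = np.zeros(m)
    c_arr = np.zeros(m)
    usable = np.zeros(m, dtype=bool)
    for i in range(m):
        if n1[i] < min_called or n2[i] < min_called:
            continue
        comp = fst_site_components(
            int(n1[i]), float(p1[i]), float(h1[i]), int(n2[i]), float(p2[i]), float(h2[i])
        )
        if comp.a == comp.b == comp.c == 0.0:
            continue
        a_arr[i], b_arr[i], c_arr[i] = comp.a, comp.b, comp.c
        usable[i] = True

    stats: list[WindowStat] = []
    for w, idx in zip(windows, _window_site_index(matrix, windows)):
        idx = idx[usable[idx]]
        if len(idx) < 2:
            continue
        s_a = float(a_arr[idx].sum())
        s_abc = float(a_arr[idx].sum() + b_arr[idx].sum() + c_arr[idx].sum())
        if s_abc == 0.0:
            logger.warning(
                "window %s:[%d,%d) has zero Fst denominator; dropped",
                w.scaffold, w.start, w.end,
            )
            continue
        stats.append(
            WindowStat(
                window=w,
                n_snps=len(idx),
                sum_a=s_a,
                sum_abc=s_abc,
                fst_weighted=s_a / s_abc,
            )
        )
    return stats


def genomewide_weighted_fst(matrix: GenotypeMatrix, pop_a: str, pop_b: str,
                            min_called: int = 2) -> float:
    """Ratio-of-sums Fst over all usable sites (no windowing)."""
    window = [
        GenomicWindow(s, 0, int(matrix.sites.loc[matrix.sites.scaffold == s, "pos"].max()))
        for s in dict.fromkeys(matrix.sites["scaffold"])
    ]
    stats = window_fst(matrix, pop_a, pop_b, window, min_called=min_called)
    s_a = sum(s.sum_a for s in stats)
    s_abc = sum(s.sum_abc for s in stats)
    if s_abc == 0:
        raise ValueError("zero Fst denominator genome-wide")
    return s_a / s_abc


# ----------------------------------------------------------------------
def merge_significant(stats: Iterable[WindowStat], mode: str = "min") -> list[Region]:
    """Merge overlapping significant windows into maximal regions.

    Abutting half-open windows (end == start) are NOT merged. Each region
    carries the extreme member statistic: ``mode="min"`` for ZHp scans,
    ``mode="max"`` for Fst scans.
    """
    if mode not in {"min", "max"}:
        raise ValueError("mode must be 'min' or 'max'")
    pick = min if mode == "min" else max
    ordered = sorted(stats, key=lambda s: (s.window.scaffold, s.window.start, s.window.end))
    regions: list[Region] = []
    for s in ordered:
        w = s.window
        if (
            regions
            and regions[-1].scaffold == w.scaffold
            and w.start < regions[-1].end
        ):
            region = regions[-1]
            region.end = max(region.end, w.end)
            region.windows.append(s)
            region.extreme = pick(region.extreme, s.value)
        else:
            regions.append(Region(w.scaffold, w.start, w.end, [s], s.value))
    return regions
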