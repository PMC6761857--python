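"""Marker- and sample-level genotype QC.

Implements MAF / call-rate site filtering with three-bucket accounting
(maf-only, callrate-only, both), PLINK-style greedy LD pruning over sliding
SNP windows, and per-sample call-rate / identity-by-state checks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from sweepscan.matrix import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


class UndefinedSiteStatsError(ValueError):
    """Raised for a site with zero called genotypes."""


class EmptyMatrixError(ValueError):
    """Raised when QC would leave no sites to analyze."""


@dataclass
class QcReport:
    n_sites_in: int = 0
    n_sites_out: int = 0
    removed_maf: int = 0
    removed_callrate: int = 0
    removed_both: int = 0
    removed_ld: int = 0
    failed_samples: list[tuple[str, str]] = field(default_factory=list)

    def validate(self) -> None:
        expected = self.n_sites_in - (
            self.removed_maf + self.removed_callrate + self.removed_both + self.removed_ld
        )
        if expected != self.n_sites_out:
            raise AssertionError(
                f"QcReport inconsistent: {self.n_sites_in} in, "
                f"{self.n_sites_out} out, buckets do not reconcile"
            )

    def to_rows(self) -> list[dict]:
        return [
            {"item": "sites_in", "count": self.n_sites_in},
            {"item": "removed_maf_only", "count": self.removed_maf},
            {"item": "removed_callrate_only", "count": self.removed_callrate},
            {"item": "removed_both", "count": self.removed_both},
            {"item": "removed_ld", "count": self.removed_ld},
            {"item": "sites_out", "count": self.n_sites_out},
        ]

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("item\tcount\n")
            for row in self.to_rows():
                fh.write(f"{row['item']}\t{row['count']}\n")
            for sample, reason in self.failed_samples:
                fh.write(f"# failed_sample\t{sample}\t{reason}\n")


def site_stats(matrix: GenotypeMatrix, site: int) -> tuple[float, float]:
    """(minor-allele frequency, call rate) for one site index."""
    col = matrix.dosage[:, site]
    called = col != MISSING
    n_called = int(called.sum())
    if n_called == 0:
        scaffold = matrix.sites.iloc[site]["scaffold"]
        pos = matrix.sites.iloc[site]["pos"]
        raise UndefinedSiteStatsError(f"site {scaffold}:{pos} has no called genotypes")
    call_rate = n_called / matrix.n_samples
    p = float(col[called].sum()) / (2.0 * n_called)
    return min(p, 1.0 - p), call_rate


def _site_maf_callrate(matrix: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    call_rate = matrix.site_call_rates()
    p = matrix.alt_freqs()
    maf = np.minimum(p, 1.0 - p)
    return maf, call_rate


def filter_snps(
    matrix: GenotypeMatrix,
    maf_min: float = 0.05,
    call_rate_min: float = 0.95,
    apply_maf: bool = True,
    report: QcReport | None = None,
) -> tuple[GenotypeMatrix, QcReport]:
    """Remove sites with MAF < ``maf_min`` (if ``apply_maf``) or call rate
    below ``call_rate_min``; both comparisons are strict, matching removal
    rules phrased as "less than".

    Sites with zero called genotypes always fail the call-rate rule.
    """
    report = report if report is not None else QcReport()
    maf, call_rate = _site_maf_callrate(matrix)
    fail_cr = call_rate < call_rate_min
    if apply_maf:
        # an all-missing site has nan maf; it necessarily fails call rate
        fail_maf = (~np.isnan(maf)) & (maf < maf_min)
    else:
        fail_maf = np.zeros(len(maf), dtype=bool)
    keep = ~(fail_cr | fail_maf)

    report.n_sites_in += matrix.n_sites
    report.removed_maf += int((fail_maf & ~fail_cr).sum())
    report.removed_callrate += int((fail_cr & ~fail_maf).sum())
    report.removed_both += int((fail_cr & fail_maf).sum())
    report.n_sites_out = int(keep.sum())
    if report.n_sites_out == 0:
        raise EmptyMatrixError("no sites survive MAF/call-rate filtering")
    out = matrix.subset_sites(np.flatnonzero(keep))
    report.validate()
    return out, report


def pairwise_r2(d1: np.ndarray, d2: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors over jointly
    non-missing samples (composite genotypic LD).

    Returns ``nan`` when either vector has zero variance over the joint set
    or fewer than 2 joint calls; callers treat ``nan`` as "not in LD".
    """
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    joint = (d1 != MISSING) & (d2 != MISSING)
    if joint.sum() < 2:
        return float("nan")
    x, y = d1[joint], d2[joint]
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        return float("nan")
    r = float(np.corrcoef(x, y)[0, 1])
    return r * r


def _window_r2(dosage: np.ndarray) -> np.ndarray:
    """Pairwise r^2 matrix for the sites (columns) of a window.

    Fast path via corrcoef when no calls are missing; otherwise falls back to
    pairwise-complete computation.
    """
    m = dosage.shape[1]
    if (dosage != MISSING).all():
        with np.errstate(invalid="ignore"):
            c = np.corrcoef(dosage.astype(float), rowvar=False)
        r2 = c * c
    else:
        r2 = np.full((m, m), np.nan)
        for a in range(m):
            for b in range(a + 1, m):
                r2[a, b] = r2[b, a] = pairwise_r2(dosage[:, a], dosage[:, b])
    np.fill_diagonal(r2, np.nan)
    return r2


def ld_prune(
    matrix: GenotypeMatrix,
    window_snps: int = 50,
    step_snps: int = 10,
    r2_max: float = 0.1,
) -> tuple[np.ndarray, int]:
    """Greedy sliding-window LD pruning (indep-pairwise semantics).

    Within each window of ``window_snps`` consecutive *surviving* sites
    (advanced by ``step_snps``, never crossing scaffolds), while any surviving
    pair has r^2 > ``r2_max`` the member with the lower MAF is removed (tie:
    the later position). Passes repeat until a fixed point, so the audited
    post-condition — no surviving within-window pair above the threshold —
    holds for the window grid laid over the kept sites. Returns (kept site
    indices, number removed).
    """
    maf, _ = _site_maf_callrate(matrix)
    removed = np.zeros(matrix.n_sites, dtype=bool)
    scaffolds = matrix.sites["scaffold"].to_numpy()
    scaffold_idx = {s: np.flatnonzero(scaffolds == s) for s in dict.fromkeys(scaffolds)}

    changed = True
    while changed:
        changed = False
        for idx in scaffold_idx.values():
            alive_idx = idx[~removed[idx]]
            n = len(alive_idx)
            for start in range(0, max(n - 1, 1), step_snps):
                win = alive_idx[start : start + window_snps]
                win = win[~removed[win]]
                if len(win) < 2:
                    continue
                r2 = _window_r2(matrix.dosage[:, win])
                alive = np.ones(len(win), dtype=bool)
                while True:
                    sub = np.where(np.outer(alive, alive), r2, np.nan)
                    with np.errstate(invalid="ignore"):
                        offenders = np.argwhere(sub > r2_max)
                    if len(offenders) == 0:
                        break
                    a, b = offenders[0]
                    ia, ib = win[a], win[b]
                    # victim: lower MAF; tie -> later position (higher index)
                    if maf[ia] < maf[ib]:
                        victim = a
                    elif maf[ib] < maf[ia]:
                        victim = b
                    else:
                        victim = max(a, b)
                    alive[victim] = False
                if not alive.all():
                    removed[win[~alive]] = True
                    changed = True
    kept = np.flatnonzero(~removed)
    return kept, int(removed.sum())


def ibs_pair(x_j: np.ndarray, x_k: np.ndarray) -> float:
    """Identity-by-state similarity over jointly called sites.

    IBS = 1 - sum(|x_j - x_k|) / (2 * L) with L the joint call count.
    Returns ``nan`` when L = 0.
    """
    joint = (x_j != MISSING) & (x_k != MISSING)
    L = int(joint.sum())
    if L == 0:
        return float("nan")
    diff = np.abs(x_j[joint].astype(int) - x_k[joint].astype(int)).sum()
    return 1.0 - diff / (2.0 * L)


def sample_qc(
    matrix: GenotypeMatrix,
    call_rate_min: float = 0.95,
    ibs_max: float = 0.90,
) -> list[tuple[str, str]]:
    """Flag samples failing call rate or belonging to a high-IBS pair.

    For a flagged pair the member with the lower call rate is listed for
    removal (tie: the later sample). Returns (sample, reason) tuples.
    """
    if matrix.n_samples < 2:
        raise ValueError("sample_qc requires at least 2 samples")
    failed: list[tuple[str, str]] = []
    call_rates = matrix.sample_call_rates()
    for sample, cr in zip(matrix.samples, call_rates):
        if cr < call_rate_min:
            failed.append((sample, f"call_rate<{call_rate_min}"))
    for j in range(matrix.n_samples):
        for k in range(j + 1, matrix.n_samples):
            ibs = ibs_pair(matrix.dosage[j], matrix.dosage[k])
            if np.isnan(ibs):
                logger.warning(
                    "samples %s/%s share no called sites; IBS skipped",
                    matrix.samples[j],
                    matrix.samples[k],
                )
                continue
            if ibs >= ibs_max:
                victim = j if call_rates[j] < call_rates[k] else k
                if call_rates[j] == call_rates[k]:
                    victim = k
                failed.append(
                    (
                        matrix.samples[victim],
                        f"IBS>={ibs_max} with {matrix.samples[j + k - victim]}",
                    )
                )
    return failed


def audit_ld(matrix: GenotypeMatrix, kept: np.ndarray, window_snps: int = 50,
             step_snps: int = 10, r2_max: float = 0.1) -> bool:
    """Exhaustively recheck the ld_prune post-condition on ``kept`` sites."""
    sub = matrix.subset_sites(kept)
    scaffolds = sub.sites["scaffold"].to_numpy()
    for scaffold in dict.fromkeys(scaffolds):
        idx = np.flatnonzero(scaffolds == scaffold)
        n = len(idx)
        for start in range(0, max(n - 1, 1), step_snps):
            win = idx[start : start + window_snps]
            if len(win) < 2:
                continue
            r2 = _window_r2(sub.dosage[:, win])
            with np.errstate(invalid="ignore"):
                if np.any(r2 > r2_max):
                    return False
    return True
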