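"""Per-individual diversity, SNP-based relatedness, and cluster-number scoring.

Observed heterozygosity and the moment inbreeding estimate follow the
observed-vs-expected homozygosity construction; relatedness is the unadjusted
A_jk genomic-relationship estimator; the cluster-number table is the
second-order rate of change of replicate log-likelihoods across K.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from sweepscan.matrix import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

RELATEDNESS_THRESHOLD = 0.025


@dataclass
class DiversityResult:
    per_sample: pd.DataFrame  # columns: sample, population, observed_het, f_hat
    per_population: pd.DataFrame  # mean/sd of both per population

    def write_tsv(self, path) -> None:
        self.per_sample.to_csv(path, sep="\t", index=False, float_format="%.6f")


@dataclass
class RelatednessMatrix:
    samples: list[str]
    values: np.ndarray  # symmetric, nan where undefined
    threshold: float = RELATEDNESS_THRESHOLD

    def related_pairs(self) -> list[tuple[str, str, float]]:
        out = []
        n = len(self.samples)
        for j in range(n):
            for k in range(j + 1, n):
                v = self.values[j, k]
                if not np.isnan(v) and v > self.threshold:
                    out.append((self.samples[j], self.samples[k], float(v)))
        return out

    def write_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.samples, columns=self.samples).to_csv(
            path, sep="\t", float_format="%.6f"
        )


def observed_heterozygosity(matrix: GenotypeMatrix) -> np.ndarray:
    """Fraction of called sites that are heterozygous, per sample."""
    called = matrix.called
    n_called = called.sum(axis=1)
    if (n_called == 0).any():
        bad = [s for s, n in zip(matrix.samples, n_called) if n == 0]
        raise ValueError(f"samples with no called sites: {bad}")
    het = ((matrix.dosage == 1) & called).sum(axis=1)
    return het / n_called


def inbreeding_f(
    matrix: GenotypeMatrix, freqs: np.ndarray | None = None
) -> np.ndarray:
    """Moment inbreeding estimate per sample.

    F_hat_j = (O_hom_j - E_hom_j) / (L_j - E_hom_j), where O_hom_j counts
    observed homozygous calls, E_hom_j = sum over called sites of
    (1 - 2 p_i (1 - p_i)), and L_j is the called-site count. ``freqs``
    defaults to pooled alternate-allele frequencies of the matrix.

    Samples with a zero denominator yield ``nan`` (reported via log).
    """
    p = matrix.alt_freqs() if freqs is None else np.asarray(freqs, dtype=float)
    called = matrix.called
    e_hom_site = 1.0 - 2.0 * p * (1.0 - p)
    e_hom = np.where(called, e_hom_site[None, :], 0.0).sum(axis=1)
    o_hom = (((matrix.dosage == 0) | (matrix.dosage == 2)) & called).sum(axis=1)
    L = called.sum(axis=1)
    denom = L - e_hom
    with np.errstate(invalid="ignore", divide="ignore"):
        f_hat = np.where(denom != 0, (o_hom - e_hom) / denom, np.nan)
    if np.isnan(f_hat).any():
        bad = [s for s, v in zip(matrix.samples, f_hat) if np.isnan(v)]
        logger.warning("inbreeding undefined (denominator 0) for samples %s", bad)
    return f_hat


def diversity_summary(matrix: GenotypeMatrix) -> DiversityResult:
    het = observed_heterozygosity(matrix)
    f_hat = inbreeding_f(matrix)
    per_sample = pd.DataFrame(
        {
            "sample": matrix.samples,
            "population": [matrix.population_of.get(s, "") for s in matrix.samples],
            "observed_het": het,
            "f_hat": f_hat,
        }
    )
    per_population = (
        per_sample.groupby("population", sort=True)[["observed_het", "f_hat"]]
        .agg(["mean", "std"])
        .reset_index()
    )
    per_population.columns = ["_".join(c).rstrip("_") for c in per_population.columns]
    return DiversityResult(per_sample, per_population)


def relatedness_ajk(
    matrix: GenotypeMatrix, threshold: float = RELATEDNESS_THRESHOLD
) -> RelatednessMatrix:
    """Unadjusted A_jk relatedness over polymorphic sites.

    Off-diagonal: mean over jointly called sites of
    (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i)).
    Diagonal: 1 + mean of (x_ij^2 - (1 + 2 p_i) x_ij + 2 p_i^2) / (2 p_i (1 - p_i)).
    Sites with p in {0, 1} are excluded. Pairs with no contributing sites get nan.
    """
    p = matrix.alt_freqs()
    poly = (~np.isnan(p)) & (p > 0.0) & (p < 1.0)
    if not poly.any():
        raise ValueError("no polymorphic sites for relatedness")
    X = matrix.dosage[:, poly].astype(float)
    pp = p[poly]
    called = X != MISSING
    denom_site = 2.0 * pp * (1.0 - pp)

    Z = np.where(called, (X - 2.0 * pp[None, :]) / np.sqrt(denom_site)[None, :], 0.0)
    N = called.astype(np.int64) @ called.astype(np.int64).T
    num = Z @ Z.T
    with np.errstate(invalid="ignore", divide="ignore"):
        A = np.where(N > 0, num / N, np.nan)

    diag_site = (X * X - (1.0 + 2.0 * pp[None, :]) * X + 2.0 * pp[None, :] ** 2) / denom_site[
        None, :
    ]
    diag_sum = np.where(called, diag_site, 0.0).sum(axis=1)
    n_diag = called.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        diag = np.where(n_diag > 0, 1.0 + diag_sum / n_diag, np.nan)
    np.fill_diagonal(A, diag)
    if np.isnan(A).any():
        logger.warning("relatedness undefined for %d pairs", int(np.isnan(A).sum()))
    return RelatednessMatrix(list(matrix.samples), A, threshold)


def evanno_delta_k(likelihoods: Mapping[int, Sequence[float]]) -> pd.DataFrame:
    """Second-order rate-of-change table from replicate log-likelihoods per K.

    Columns: K, mean_l, sd_l, l_prime, l_double_prime_abs, delta_k. delta_k is
    defined only for interior K (needs K-1 and K+1); where sd_l is zero the
    entry is nan and logged.
    """
    ks = sorted(likelihoods)
    if len(ks) < 3:
        raise ValueError("need >=3 consecutive K values")
    if ks != list(range(ks[0], ks[0] + len(ks))):
        raise ValueError(f"K values must be consecutive, got {ks}")
    mean_l = np.array([np.mean(likelihoods[k]) for k in ks], dtype=float)
    sd_l = np.array(
        [np.std(likelihoods[k], ddof=1) if len(likelihoods[k]) > 1 else np.nan for k in ks]
    )
    n = len(ks)
    l_prime = np.full(n, np.nan)
    l_prime[1:] = mean_l[1:] - mean_l[:-1]
    l_pp = np.full(n, np.nan)
    l_pp[1:-1] = np.abs(l_prime[2:] - l_prime[1:-1])
    with np.errstate(invalid="ignore", divide="ignore"):
        delta_k = np.where((sd_l > 0) & ~np.isnan(l_pp), l_pp / sd_l, np.nan)
    if np.any((sd_l == 0) & ~np.isnan(l_pp)):
        logger.warning("delta-K undefined where replicate sd is 0")
    return pd.DataFrame(
        {
            "K": ks,
            "mean_l": mean_l,
            "sd_l": sd_l,
            "l_prime": l_prime,
            "l_double_prime_abs": l_pp,
            "delta_k": delta_k,
        }
    )


def optimal_k(table: pd.DataFrame) -> int:
    """argmax of delta_k over interior K."""
    interior = table.dropna(subset=["delta_k"])
    if interior.empty:
        raise ValueError("no K with a defined delta_k")
    return int(interior.loc[interior["delta_k"].idxmax(), "K"])
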