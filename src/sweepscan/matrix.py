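"""Samples x sites alternate-allele dosage matrix with site/sample metadata."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = -1

SITE_COLUMNS = ["scaffold", "pos", "ref", "alt"]


@dataclass
class GenotypeMatrix:
    """Diploid genotype dosage matrix.

    Parameters
    ----------
    samples
        Ordered sample identifiers (rows of ``dosage``).
    sites
        DataFrame with columns ``scaffold, pos, ref, alt`` (columns of
        ``dosage``); ``pos`` is 1-based as in VCF.
    dosage
        ``(n_samples, n_sites)`` int8 array of alternate-allele counts in
        ``{0, 1, 2}``, with ``-1`` marking a missing call.
    population_of
        Sample id -> population name.
    """

    samples: list[str]
    sites: pd.DataFrame
    dosage: np.ndarray
    population_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )
        bad = ~np.isin(self.dosage, [MISSING, 0, 1, 2])
        if bad.any():
            raise ValueError("dosage values must be in {0,1,2} or -1 (missing)")
        self.sites = self.sites.reset_index(drop=True)
        # keep site order sorted by (scaffold, pos)
        order = np.lexsort((self.sites["pos"].to_numpy(), self.sites["scaffold"].to_numpy()))
        if not np.array_equal(order, np.arange(len(self.sites))):
            self.sites = self.sites.iloc[order].reset_index(drop=True)
            self.dosage = self.dosage[:, order]

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def called(self) -> np.ndarray:
        """Boolean mask of non-missing calls, same shape as ``dosage``."""
        return self.dosage != MISSING

    def site_call_rates(self) -> np.ndarray:
        """Fraction of samples with a called genotype at each site."""
        return self.called.mean(axis=0)

    def sample_call_rates(self) -> np.ndarray:
        return self.called.mean(axis=1)

    def alt_freqs(self) -> np.ndarray:
        """Alternate-allele frequency per site over non-missing calls.

        Sites with zero called samples yield ``nan``.
        """
        called = self.called
        n_called = called.sum(axis=0)
        alt = np.where(called, self.dosage, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_called > 0, alt / (2.0 * n_called), np.nan)

    # ------------------------------------------------------------------
    def subset_sites(self, index: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            samples=list(self.samples),
            sites=self.sites.iloc[index].reset_index(drop=True),
            dosage=self.dosage[:, index],
            population_of=dict(self.population_of),
        )

    def subset_samples(self, names: Iterable[str]) -> "GenotypeMatrix":
        names = list(names)
        lookup = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in names if s not in lookup]
        if missing:
            raise KeyError(f"unknown samples: {missing}")
        idx = [lookup[s] for s in names]
        return GenotypeMatrix(
            samples=names,
            sites=self.sites.copy(),
            dosage=self.dosage[idx, :],
            population_of={s: self.population_of.get(s, "") for s in names},
        )

    def for_populations(self, populations: Iterable[str]) -> "GenotypeMatrix":
        pops = set(populations)
        names = [s for s in self.samples if self.population_of.get(s) in pops]
        if not names:
            raise KeyError(f"no samples belong to populations {sorted(pops)}")
        return self.subset_samples(names)

    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.population_of.get(s, ""), None)
        return list(seen)

    @classmethod
    def from_arrays(
        cls,
        samples: Sequence[str],
        scaffold: Sequence[str],
        pos: Sequence[int],
        ref: Sequence[str],
        alt: Sequence[str],
        dosage: np.ndarray,
        population_of: Mapping[str, str] | None = None,
    ) -> "GenotypeMatrix":
        sites = pd.DataFrame(
            {"scaffold": list(scaffold), "pos": list(pos), "ref": list(ref), "alt": list(alt)}
        )
        return cls(list(samples), sites, dosage, dict(population_of or {}))
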