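"""Candidate-region gene annotation.

Genes are loaded from GFF3 (converted to 0-based half-open coordinates) or
BED, intersected with candidate regions and with the full set of tested
windows (the background). Overlap requires at least one shared base under
half-open semantics. An optional hypergeometric over-representation test
against the background set is provided as a plain stand-in for external
enrichment services.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from gffutils.feature import feature_from_line
from scipy.stats import hypergeom

from sweepscan.scan import GenomicWindow, Region


@dataclass(frozen=True, order=True)
class GeneFeature:
    """Gene interval in internal 0-based half-open coordinates."""

    scaffold: str
    start: int
    end: int
    gene_id: str
    strand: str = "."
    name: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id}: invalid interval [{self.start}, {self.end})"
            )


class AnnotationParseError(ValueError):
    pass


def _load_gff3(path: Path, gene_types: frozenset[str]) -> list[GeneFeature]:
    genes: list[GeneFeature] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feature = feature_from_line(line)
            except Exception as exc:
                raise AnnotationParseError(f"{path}:{line_no}: {exc}") from exc
            if feature.featuretype not in gene_types:
                continue
            attrs = feature.attributes
            gene_id = (
                (attrs.get("ID") or attrs.get("gene_id") or attrs.get("Name") or [None])[0]
            )
            if gene_id is None:
                raise AnnotationParseError(
                    f"{path}:{line_no}: gene feature lacks ID/gene_id/Name"
                )
            name = (attrs.get("Name") or [""])[0]
            start0 = feature.start - 1  # GFF3 is 1-based inclusive
            if feature.end <= start0:
                raise AnnotationParseError(
                    f"{path}:{line_no}: end {feature.end} <= start {feature.start}"
                )
            genes.append(
                GeneFeature(feature.seqid, start0, feature.end, gene_id, feature.strand, name)
            )
    return genes


def _load_bed(path: Path) -> list[GeneFeature]:
    genes: list[GeneFeature] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise AnnotationParseError(
                    f"{path}:{line_no}: BED line needs >=3 columns"
                )
            scaffold, start, end = parts[0], int(parts[1]), int(parts[2])
            gene_id = parts[3] if len(parts) > 3 else f"feature_{line_no}"
            strand = parts[5] if len(parts) > 5 else "."
            if end <= start:
                raise AnnotationParseError(f"{path}:{line_no}: end {end} <= start {start}")
            genes.append(GeneFeature(scaffold, start, end, gene_id, strand, gene_id))
    return genes


def load_genes(path, gene_types: Iterable[str] = ("gene",)) -> list[GeneFeature]:
    """Load gene features from GFF3 or BED, sorted, with unique gene ids."""
    path = Path(path)
    if path.suffix.lower() in {".gff", ".gff3"}:
        genes = _load_gff3(path, frozenset(gene_types))
    else:
        genes = _load_bed(path)
    if not genes:
        warnings.warn(f"no gene features loaded from {path}", stacklevel=2)
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise AnnotationParseError(f"duplicate gene_id {g.gene_id!r} in {path}")
        seen.add(g.gene_id)
    return sorted(genes)


def _overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start < b_end and b_start < a_end


@dataclass
class IntersectionResult:
    per_region: list[tuple[Region, list[GeneFeature]]]
    unique_genes: list[GeneFeature]
    n_regions_with_genes: int
    #: gene_id -> number of regions it overlaps (a gene spanning several
    #: regions counts once in ``unique_genes`` but several times here)
    region_counts: dict[str, int]


def intersect_regions_genes(
    regions: Sequence[Region], genes: Sequence[GeneFeature]
) -> IntersectionResult:
    """Report every gene overlapping (>=1 bp) each candidate region."""
    per_region: list[tuple[Region, list[GeneFeature]]] = []
    region_counts: dict[str, int] = {}
    unique: dict[str, GeneFeature] = {}
    for region in regions:
        hits = [
            g
            for g in genes
            if g.scaffold == region.scaffold
            and _overlaps(region.start, region.end, g.start, g.end)
        ]
        per_region.append((region, hits))
        for g in hits:
            region_counts[g.gene_id] = region_counts.get(g.gene_id, 0) + 1
            unique.setdefault(g.gene_id, g)
    return IntersectionResult(
        per_region=per_region,
        unique_genes=sorted(unique.values()),
        n_regions_with_genes=sum(1 for _, hits in per_region if hits),
        region_counts=region_counts,
    )


def background_genes(
    windows: Sequence[GenomicWindow], genes: Sequence[GeneFeature]
) -> set[str]:
    """Unique gene ids overlapping at least one tested window."""
    out: set[str] = set()
    by_scaffold: dict[str, list[GenomicWindow]] = {}
    for w in windows:
        by_scaffold.setdefault(w.scaffold, []).append(w)
    for g in genes:
        for w in by_scaffold.get(g.scaffold, ()):
            if _overlaps(w.start, w.end, g.start, g.end):
                out.add(g.gene_id)
                break
    return out


def hypergeometric_enrichment(
    significant: set[str], background: set[str], gene_sets: dict[str, set[str]]
) -> list[dict]:
    """Plain hypergeometric over-representation with Benjamini-Hochberg FDR.

    A stand-in for external enrichment services: tests each named gene set
    for over-representation of ``significant`` genes relative to
    ``background`` (which must contain the significant set).
    """
    if not significant <= background:
        raise ValueError("significant gene set must be a subset of the background")
    N, n = len(background), len(significant)
    rows = []
    for name, members in gene_sets.items():
        K = len(members & background)
        k = len(members & significant)
        p = float(hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append({"gene_set": name, "n_background": K, "n_significant": k, "p_value": p})
    rows.sort(key=lambda r: r["p_value"])
    m = len(rows)
    q_min = 1.0
    for i in range(m - 1, -1, -1):
        q = rows[i]["p_value"] * m / (i + 1)
        q_min = min(q_min, q)
        rows[i]["q_value"] = q_min
    return rows
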