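"""Reading and writing the plain-text formats the pipeline exchanges.

VCF parsing is delegated to cyvcf2; writing is done directly so that output
bytes are fully determined by the in-memory records (a requirement for the
simulator's reproducibility contract).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from sweepscan.filtering import VariantRecord
from sweepscan.matrix import MISSING, GenotypeMatrix

INFO_KEYS = ("QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum", "DP")

_VCF_HEADER_INFO = [
    '##INFO=<ID=QD,Number=1,Type=Float,Description="Variant quality by depth">',
    '##INFO=<ID=FS,Number=1,Type=Float,Description="Phred-scaled strand bias">',
    '##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">',
    '##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="Mapping quality rank sum">',
    '##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="Read position rank sum">',
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="Site depth">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
]


def read_vcf(path) -> tuple[list[str], list[VariantRecord]]:
    """Parse a VCF into (samples, records)."""
    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    records: list[VariantRecord] = []
    for v in vcf:
        info = {}
        for key, value in v.INFO:
            info[key] = value
        genotypes = []
        for gt in v.genotypes:
            a1, a2 = gt[0], gt[1]
            genotypes.append(
                (None if a1 < 0 else int(a1), None if a2 < 0 else int(a2))
            )
        records.append(
            VariantRecord(
                scaffold=v.CHROM,
                pos=v.POS,
                ref=v.REF,
                alts=tuple(v.ALT),
                qual=None if v.QUAL is None else float(v.QUAL),
                info=info,
                genotypes=tuple(genotypes),
                id=v.ID or ".",
            )
        )
    vcf.close()
    return samples, records


def _format_info(info: Mapping) -> str:
    if not info:
        return "."
    parts = []
    for key, value in info.items():
        if value is None or value is True:
            parts.append(str(key))
        elif isinstance(value, float):
            parts.append(f"{key}={value:.2f}")
        else:
            parts.append(f"{key}={value}")
    return ";".join(parts)


def _format_gt(gt: tuple[Optional[int], Optional[int]]) -> str:
    a1, a2 = gt
    if a1 is None or a2 is None:
        return "./."
    return f"{a1}/{a2}"


def write_vcf(
    path,
    samples: Sequence[str],
    records: Iterable[VariantRecord],
    contigs: Mapping[str, int] | None = None,
    source: str = "sweepscan",
) -> None:
    """Write VCF v4.2 with GT-only FORMAT. Deterministic byte output."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source={source}\n")
        for name, length in (contigs or {}).items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        for line in _VCF_HEADER_INFO:
            fh.write(line + "\n")
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        fh.write("\t".join(cols + list(samples)) + "\n")
        for r in records:
            qual = "." if r.qual is None else f"{r.qual:.2f}"
            row = [
                r.scaffold,
                str(r.pos),
                r.id,
                r.ref,
                ",".join(r.alts) if r.alts else ".",
                qual,
                ".",
                _format_info(r.info),
                "GT",
            ]
            row.extend(_format_gt(gt) for gt in r.genotypes)
            fh.write("\t".join(row) + "\n")


def records_to_matrix(
    samples: Sequence[str],
    records: Sequence[VariantRecord],
    population_of: Mapping[str, str] | None = None,
) -> GenotypeMatrix:
    """Build a dosage matrix from bi-allelic SNP records."""
    keep = [r for r in records if r.is_biallelic]
    n, m = len(samples), len(keep)
    dosage = np.full((n, m), MISSING, dtype=np.int8)
    for j, r in enumerate(keep):
        for i, (a1, a2) in enumerate(r.genotypes):
            if a1 is not None and a2 is not None:
                dosage[i, j] = a1 + a2
    sites = pd.DataFrame(
        {
            "scaffold": [r.scaffold for r in keep],
            "pos": [r.pos for r in keep],
            "ref": [r.ref for r in keep],
            "alt": [r.alts[0] if r.alts else "." for r in keep],
        }
    )
    return GenotypeMatrix(list(samples), sites, dosage, dict(population_of or {}))


def load_matrix(vcf_path, sample_map_path=None) -> GenotypeMatrix:
    samples, records = read_vcf(vcf_path)
    population_of = read_sample_map(sample_map_path) if sample_map_path else {}
    return records_to_matrix(samples, records, population_of)


def read_sample_map(path) -> dict[str, str]:
    """TSV with columns sample_id, population (header optional)."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{line_no}: expected 2 tab-separated columns")
            if line_no == 1 and parts[0].lower() in {"sample", "sample_id"}:
                continue
            out[parts[0]] = parts[1]
    return out


def write_sample_map(path, population_of: Mapping[str, str]) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tpopulation\n")
        for sample, pop in population_of.items():
            fh.write(f"{sample}\t{pop}\n")


def read_scaffold_lengths(path) -> dict[str, int]:
    """TSV of scaffold name and length (first two columns, fai-style)."""
    out: dict[str, int] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{line_no}: expected >=2 tab-separated columns")
            if line_no == 1 and parts[0].lower() in {"scaffold", "name", "chrom"}:
                continue
            out[parts[0]] = int(parts[1])
    return out


def write_scaffold_lengths(path, lengths: Mapping[str, int]) -> None:
    with open(path, "w") as fh:
        for name, length in lengths.items():
            fh.write(f"{name}\t{length}\n")


def read_bed_intervals(path) -> list[tuple[str, int, int]]:
    """(scaffold, start, end) triples from a BED file; extra columns ignored."""
    out: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{line_no}: BED line needs >=3 columns")
            out.append((parts[0], int(parts[1]), int(parts[2])))
    return out


def write_bed(path, intervals: Iterable[tuple], header: str | None = None) -> None:
    """Write (scaffold, start, end[, name, score...]) rows as BED."""
    with open(path, "w") as fh:
        if header:
            fh.write(f"#{header}\n")
        for row in intervals:
            fh.write("\t".join(str(x) for x in row) + "\n")
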