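"""Per-gene leader-relative TSS-Seq 5'-end read profiles.

TSS-Seq (and PEAT-style paired-end TSS mapping) reports transcript 5' ends as
single-nucleotide position/count pileups.  This module ingests such pileups,
projects them onto a gene's oriented leader model, and applies the
low-coverage site filter: any site supported by fewer than ``min_site_reads``
reads (default 10) is dropped from both the site list and the retained read
total R before scoring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .annotation_io import LeaderModel

__all__ = [
    "TssEndRecord",
    "TssProfile",
    "TssParseError",
    "read_tss_ends",
    "build_profile",
    "build_profiles",
    "filter_low_coverage_sites",
    "write_profiles_tsv",
    "read_profiles_tsv",
]

logger = logging.getLogger(__name__)


class TssParseError(ValueError):
    pass


@dataclass(frozen=True)
class TssEndRecord:
    """One aggregated transcript 5' end: genomic position, strand, read count."""

    chrom: str
    pos: int  # 0-based genomic position of the 5'-most base
    strand: str
    count: int

    def __post_init__(self):
        if self.count < 1:
            raise ValueError(f"count must be >= 1, got {self.count}")
        if self.pos < 0:
            raise ValueError(f"pos must be >= 0, got {self.pos}")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be + or -, got {self.strand!r}")


@dataclass
class TssProfile:
    """Leader-relative 5'-end counts for one gene.

    ``total_reads`` (R) is always the sum of ``site_counts`` values; after
    filtering it is the retained-read total that normalizes the TOPscore.
    """

    gene_id: str
    site_counts: dict[int, int] = field(default_factory=dict)

    def __post_init__(self):
        for idx, count in self.site_counts.items():
            if count < 1:
                raise ValueError(
                    f"{self.gene_id}: site {idx} has non-positive count {count}"
                )

    @property
    def total_reads(self) -> int:
        return sum(self.site_counts.values())

    @property
    def n_sites(self) -> int:
        return len(self.site_counts)


def _parse_count(raw: str, where: str) -> int:
    try:
        value = float(raw)
    except ValueError:
        raise TssParseError(f"{where}: non-numeric count {raw!r}") from None
    if value <= 0 or value != int(value):
        raise TssParseError(f"{where}: count must be a positive integer, got {raw!r}")
    return int(value)


def _read_bed6(path: Path, agg: dict) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 6:
                raise TssParseError(
                    f"{path}:{lineno}: expected 6 BED columns, got {len(fields)}"
                )
            chrom, start_s, end_s, _name, score, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise TssParseError(f"{path}:{lineno}: non-integer coordinates") from None
            if strand not in {"+", "-"}:
                raise TssParseError(f"{path}:{lineno}: bad strand {strand!r}")
            if end - start != 1:
                raise TssParseError(
                    f"{path}:{lineno}: 5'-end records must be single-base intervals"
                )
            count = _parse_count(score, f"{path}:{lineno}")
            agg[(chrom, start, strand)] = agg.get((chrom, start, strand), 0) + count


def _read_bedgraph(path: Path, strand: str, agg: dict) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) != 4:
                raise TssParseError(
                    f"{path}:{lineno}: expected 4 bedGraph columns, got {len(fields)}"
                )
            chrom, start_s, end_s, value = fields
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise TssParseError(f"{path}:{lineno}: non-integer coordinates") from None
            count = _parse_count(value, f"{path}:{lineno}")
            for pos in range(start, end):
                agg[(chrom, pos, strand)] = agg.get((chrom, pos, strand), 0) + count


def read_tss_ends(
    path: str | Path,
    dialect: str = "bed6",
    minus_path: str | Path | None = None,
) -> list[TssEndRecord]:
    """Read TSS 5'-end pileups; one record per (chrom, pos, strand) with
    aggregated count.

    ``dialect='bed6'``: single-base BED6 with the read count in the score
    column.  ``dialect='bedgraph'``: ``path`` holds plus-strand coverage and
    ``minus_path`` the minus strand.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"TSS file not found: {path}")
    agg: dict[tuple[str, int, str], int] = {}
    if dialect == "bed6":
        _read_bed6(path, agg)
    elif dialect == "bedgraph":
        if minus_path is None:
            raise ValueError("bedgraph dialect requires minus_path")
        _read_bedgraph(path, "+", agg)
        _read_bedgraph(Path(minus_path), "-", agg)
    else:
        raise ValueError(f"unknown TSS dialect {dialect!r}")
    return [
        TssEndRecord(chrom, pos, strand, count)
        for (chrom, pos, strand), count in sorted(agg.items())
    ]


def build_profile(
    records: Iterable[TssEndRecord], model: LeaderModel
) -> TssProfile:
    """Project 5'-end records onto one leader.

    Only records on the model's strand/chromosome whose 5' end falls inside an
    annotated leader block contribute; everything else (upstream TSS
    heterogeneity, CDS reads, opposite strand) is excluded and counted in a
    debug log line.
    """
    site_counts: dict[int, int] = {}
    excluded = 0
    for rec in records:
        if rec.chrom != model.chrom or rec.strand != model.strand:
            excluded += 1
            continue
        idx = model.genomic_to_leader(rec.pos)
        if idx is None:
            excluded += 1
            continue
        site_counts[idx] = site_counts.get(idx, 0) + rec.count
    if excluded:
        logger.debug("%s: excluded %d non-leader records", model.gene_id, excluded)
    return TssProfile(gene_id=model.gene_id, site_counts=site_counts)


def build_profiles(
    records: Iterable[TssEndRecord], models: Mapping[str, LeaderModel]
) -> dict[str, TssProfile]:
    """Project one record stream onto many leaders (indexed by chrom/strand)."""
    by_loc: dict[tuple[str, str], list[TssEndRecord]] = {}
    for rec in records:
        by_loc.setdefault((rec.chrom, rec.strand), []).append(rec)
    profiles = {}
    for gene_id, model in models.items():
        recs = by_loc.get((model.chrom, model.strand), ())
        profiles[gene_id] = build_profile(recs, model)
    return profiles


def filter_low_coverage_sites(
    profile: TssProfile, min_site_reads: int = 10
) -> TssProfile:
    """Drop sites supported by fewer than ``min_site_reads`` reads.

    R and n_sites are recomputed over the retained sites only, so the filter
    removes low-coverage sites from both the numerator and denominator of the
    TOPscore.
    """
    if min_site_reads < 1:
        raise ValueError(f"min_site_reads must be >= 1, got {min_site_reads}")
    kept = {
        idx: count
        for idx, count in profile.site_counts.items()
        if count >= min_site_reads
    }
    return TssProfile(gene_id=profile.gene_id, site_counts=kept)


def write_profiles_tsv(profiles: Mapping[str, TssProfile], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tleader_index\tcount\n")
        for gene_id in sorted(profiles):
            prof = profiles[gene_id]
            for idx in sorted(prof.site_counts):
                fh.write(f"{gene_id}\t{idx}\t{prof.site_counts[idx]}\n")


def read_profiles_tsv(path: str | Path) -> dict[str, TssProfile]:
    profiles: dict[str, dict[int, int]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["gene_id", "leader_index", "count"]:
            raise TssParseError(f"{path}: unexpected profiles header {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            gene_id, idx_s, count_s = line.split("\t")
            profiles.setdefault(gene_id, {})[int(idx_s)] = _parse_count(
                count_s, f"{path}:{lineno}"
            )
    return {g: TssProfile(gene_id=g, site_counts=c) for g, c in profiles.items()}
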