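"""Strand-aware 5' leader models from genome FASTA plus BED/GFF3 annotations.

A "leader" here is the 5' untranslated region of an mRNA, modelled as an
oriented sequence: index 0 is the annotated-TSS-proximal (cap-proximal) base,
index L-1 abuts the start codon.  All genomic intervals are held internally in
BED convention (0-based, half-open); GFF3 input (1-based, closed) is converted
on read.  On the minus strand the leader sequence is the reverse complement of
the genomic blocks read in descending coordinate order, so leader index 0 maps
to the highest genomic coordinate.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "GenomeSequences",
    "LeaderAnnotation",
    "LeaderModel",
    "AnnotationError",
    "read_leader_annotations",
    "extract_leader_sequence",
    "map_genomic_to_leader",
    "build_leader_models",
    "write_leaders_fasta",
    "read_leaders_fasta",
]

_VALID = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class AnnotationError(ValueError):
    """Malformed annotation input (carries file/line context in the message)."""


def _clean_sequence(seq: str) -> str:
    """Uppercase and map every non-ACGT character (soft-masked, IUPAC ambiguity)
    to N so that masking cannot alter downstream scoring."""
    seq = seq.upper()
    if set(seq) <= _VALID:
        return seq
    return re.sub(r"[^ACGTN]", "N", seq)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeSequences:
    """Name -> uppercase sequence map over the alphabet {A, C, G, T, N}."""

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs: dict[str, str] = {}
        for name, seq in sequences.items():
            if not seq:
                raise ValueError(f"sequence {name!r} is empty")
            self._seqs[name] = _clean_sequence(str(seq))

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeSequences":
        records = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        if not records:
            raise ValueError(f"no FASTA records found in {path}")
        return cls(records)

    def __getitem__(self, name: str) -> str:
        try:
            return self._seqs[name]
        except KeyError:
            raise KeyError(f"sequence {name!r} not present in genome") from None

    def __contains__(self, name: str) -> bool:
        return name in self._seqs

    def __iter__(self):
        return iter(self._seqs)

    def __len__(self) -> int:
        return len(self._seqs)

    def items(self):
        return self._seqs.items()


@dataclass(frozen=True)
class LeaderAnnotation:
    """A gene's annotated 5' leader as sorted, non-overlapping genomic blocks."""

    gene_id: str
    chrom: str
    strand: str
    blocks: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if self.strand not in {"+", "-"}:
            raise AnnotationError(f"{self.gene_id}: strand must be + or -, got {self.strand!r}")
        if not self.blocks:
            raise AnnotationError(f"{self.gene_id}: annotation has no blocks")
        prev_end = -1
        for start, end in self.blocks:
            if start < 0 or start >= end:
                raise AnnotationError(
                    f"{self.gene_id}: invalid interval [{start}, {end})"
                )
            if start < prev_end:
                raise AnnotationError(f"{self.gene_id}: blocks overlap or are unsorted")
            prev_end = end

    @property
    def length(self) -> int:
        return sum(end - start for start, end in self.blocks)


@dataclass
class LeaderModel:
    """Oriented leader sequence with a genomic<->leader coordinate map."""

    gene_id: str
    chrom: str
    strand: str
    sequence: str
    genomic_positions: tuple[int, ...]  # leader index -> genomic position
    _pos_to_index: dict[int, int] = field(repr=False, default_factory=dict)

    def __post_init__(self):
        if len(self.sequence) != len(self.genomic_positions):
            raise ValueError("sequence and coordinate map lengths differ")
        if not self.sequence:
            raise ValueError(f"{self.gene_id}: empty leader")
        if not self._pos_to_index:
            self._pos_to_index = {
                pos: i for i, pos in enumerate(self.genomic_positions)
            }

    def __len__(self) -> int:
        return len(self.sequence)

    def genomic_to_leader(self, chrom_pos: int) -> int | None:
        """Leader index of the base at a genomic position, or None if the
        position falls outside every annotated block."""
        return self._pos_to_index.get(chrom_pos)

    def leader_to_genomic(self, index: int) -> int:
        return self.genomic_positions[index]


def _merge_blocks(blocks: list[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    """Union of intervals, sorted by start; touching/overlapping blocks fuse."""
    merged: list[list[int]] = []
    for start, end in sorted(blocks):
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return tuple((s, e) for s, e in merged)


def _parse_bed(path: Path) -> dict[str, dict]:
    per_gene: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 6:
                raise AnnotationError(
                    f"{path}:{lineno}: expected >= 6 BED columns, got {len(fields)}"
                )
            chrom, start_s, end_s, name, _score, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise AnnotationError(
                    f"{path}:{lineno}: non-integer coordinates {start_s!r}/{end_s!r}"
                ) from None
            if start >= end:
                raise AnnotationError(f"{path}:{lineno}: start {start} >= end {end}")
            if strand not in {"+", "-"}:
                raise AnnotationError(f"{path}:{lineno}: bad strand {strand!r}")
            blocks: list[tuple[int, int]] = []
            if len(fields) >= 12:  # BED12: explicit sub-blocks
                n_blocks = int(fields[9])
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                starts = [int(x) for x in fields[11].rstrip(",").split(",")]
                if len(sizes) != n_blocks or len(starts) != n_blocks:
                    raise AnnotationError(f"{path}:{lineno}: inconsistent BED12 blocks")
                for off, size in zip(starts, sizes):
                    blocks.append((start + off, start + off + size))
            else:
                blocks.append((start, end))
            entry = per_gene.setdefault(
                name, {"chrom": chrom, "strand": strand, "blocks": []}
            )
            if entry["chrom"] != chrom or entry["strand"] != strand:
                raise AnnotationError(
                    f"{path}:{lineno}: gene {name!r} spans multiple chromosomes/strands"
                )
            entry["blocks"].extend(blocks)
    return per_gene


_GFF_UTR_TYPES = {"five_prime_UTR", "five_prime_utr", "5'UTR"}


def _gff_gene_id(feature, transcript_to_gene: Mapping[str, str] | None) -> tuple[str, str]:
    """Resolve (gene_id, transcript_id) for a five_prime_UTR feature.

    Preference order for the gene: explicit gene_id/locus attribute, supplied
    transcript->gene map, else the Parent with an Araport-style ``.N`` isoform
    suffix stripped.
    """
    attrs = feature.attributes
    parent = attrs.get("Parent", [None])[0] or attrs.get("ID", [feature.id])[0]
    transcript = parent or feature.id
    for key in ("gene_id", "locus", "gene"):
        if key in attrs and attrs[key]:
            return attrs[key][0], transcript
    if transcript_to_gene and transcript in transcript_to_gene:
        return transcript_to_gene[transcript], transcript
    gene = re.sub(r"\.\d+$", "", transcript)
    return gene, transcript


def _parse_gff3(
    path: Path, transcript_to_gene: Mapping[str, str] | None
) -> dict[str, dict]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        keep_order=True,
        merge_strategy="create_unique",
    )
    # transcript -> {gene, chrom, strand, blocks}; one leader per isoform
    per_tx: dict[str, dict] = {}
    for ftype in _GFF_UTR_TYPES:
        try:
            features = list(db.features_of_type(ftype))
        except Exception:
            features = []
        for feat in features:
            if feat.start > feat.end:
                raise AnnotationError(f"{path}: feature {feat.id} has start > end")
            gene, tx = _gff_gene_id(feat, transcript_to_gene)
            entry = per_tx.setdefault(
                tx,
                {"gene": gene, "chrom": feat.seqid, "strand": feat.strand, "blocks": []},
            )
            # GFF3 1-based closed -> 0-based half-open
            entry["blocks"].append((feat.start - 1, feat.end))
    if not per_tx:
        raise AnnotationError(f"{path}: no five_prime_UTR features found")
    # collapse isoforms: keep the longest annotated 5'UTR per gene
    per_gene: dict[str, dict] = {}
    for tx in sorted(per_tx):
        entry = per_tx[tx]
        merged = _merge_blocks(entry["blocks"])
        total = sum(e - s for s, e in merged)
        current = per_gene.get(entry["gene"])
        if current is None or total > current["length"]:
            per_gene[entry["gene"]] = {
                "chrom": entry["chrom"],
                "strand": entry["strand"],
                "blocks": list(merged),
                "length": total,
            }
    return per_gene


def read_leader_annotations(
    path: str | Path,
    dialect: str = "auto",
    transcript_to_gene: Mapping[str, str] | None = None,
) -> list[LeaderAnnotation]:
    """Parse 5' leader annotations from BED6/BED12 or GFF3.

    BED: the name column is the gene id; multiple lines for one gene are merged
    into sorted blocks.  GFF3: five_prime_UTR features are grouped per
    transcript and the longest isoform leader per gene is kept (override the
    transcript->gene resolution with ``transcript_to_gene``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"annotation file not found: {path}")
    if dialect == "auto":
        dialect = "gff3" if path.suffix.lower() in {".gff", ".gff3", ".gtf"} else "bed"
    dialect = dialect.lower()
    if dialect == "bed":
        per_gene = _parse_bed(path)
    elif dialect == "gff3":
        per_gene = _parse_gff3(path, transcript_to_gene)
    else:
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    annotations = []
    for gene_id in sorted(per_gene):
        entry = per_gene[gene_id]
        annotations.append(
            LeaderAnnotation(
                gene_id=gene_id,
                chrom=entry["chrom"],
                strand=entry["strand"],
                blocks=_merge_blocks(list(entry["blocks"])),
            )
        )
    return annotations


def extract_leader_sequence(
    genome: GenomeSequences, ann: LeaderAnnotation
) -> LeaderModel:
    """Build the oriented leader model for one annotation.

    Plus strand: concatenate block substrings in ascending genomic order.
    Minus strand: reverse complement, read in descending genomic order, so the
    cap-proximal base (leader index 0) is the highest genomic coordinate.
    """
    chrom_seq = genome[ann.chrom]
    for start, end in ann.blocks:
        if end > len(chrom_seq):
            raise AnnotationError(
                f"{ann.gene_id}: block [{start}, {end}) exceeds {ann.chrom} "
                f"length {len(chrom_seq)}"
            )
    forward = "".join(chrom_seq[s:e] for s, e in ann.blocks)
    positions = [p for s, e in ann.blocks for p in range(s, e)]
    if ann.strand == "+":
        sequence = forward
    else:
        sequence = reverse_complement(forward)
        positions = positions[::-1]
    return LeaderModel(
        gene_id=ann.gene_id,
        chrom=ann.chrom,
        strand=ann.strand,
        sequence=sequence,
        genomic_positions=tuple(positions),
    )


def map_genomic_to_leader(model: LeaderModel, chrom_pos: int) -> int | None:
    """Leader index of a genomic position, or None when outside the leader."""
    return model.genomic_to_leader(chrom_pos)


def build_leader_models(
    genome: GenomeSequences, annotations: Iterable[LeaderAnnotation]
) -> dict[str, LeaderModel]:
    return {
        ann.gene_id: extract_leader_sequence(genome, ann) for ann in annotations
    }


def write_leaders_fasta(models: Mapping[str, LeaderModel], path: str | Path) -> None:
    """Write leader sequences as FASTA with gene ids as record names."""
    records = []
    from Bio.SeqRecord import SeqRecord

    for gene_id in sorted(models):
        m = models[gene_id]
        records.append(
            SeqRecord(Seq(m.sequence), id=gene_id, description=f"{m.chrom}:{m.strand}")
        )
    SeqIO.write(records, str(path), "fasta")


def read_leaders_fasta(path: str | Path) -> dict[str, LeaderModel]:
    """Read pre-extracted leaders: record ids are gene ids and the coordinate
    map is the identity on a plus-strand pseudo-contig named after the gene."""
    models = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = _clean_sequence(str(rec.seq))
        models[rec.id] = LeaderModel(
            gene_id=rec.id,
            chrom=rec.id,
            strand="+",
            sequence=seq,
            genomic_positions=tuple(range(len(seq))),
        )
    if not models:
        raise ValueError(f"no FASTA records found in {path}")
    return models
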