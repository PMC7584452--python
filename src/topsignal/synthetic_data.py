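"""Synthetic TSS-Seq / Ribo-Seq / RNA-Seq study with planted 5'TOP structure.

The generator emulates the study design the pipeline targets: per-gene TSS
5'-end pileups concentrated at an annotated TSS over leaders of controlled
pyrimidine composition, and negative-binomial RNA/Ribo count tables for a
{WT, larp1} x {mock, torin2} x replicate design.  A TE-repression effect is
planted only in (5'TOP gene, WT, torin2) cells; ``larp1_effect_fold`` (default
1, i.e. no effect) encodes full LARP1 dependence of the repression.

TOP genes carry a leader starting with C followed by planted_run_length - 1
pyrimidines and then a purine; non-TOP genes start with a purine.  Counts are
negative binomial with gene-level log-normal means — the standard bulk
RNA-Seq noise model; dispersion defaults reflect pooled-seedling replicates.
Everything is deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .annotation_io import (
    GenomeSequences,
    LeaderAnnotation,
    LeaderModel,
    build_leader_models,
    reverse_complement,
    write_leaders_fasta,
)
from .top_classifier import TopClassification
from .tss_profiles import TssEndRecord

__all__ = [
    "SimConfig",
    "SimulatedStudy",
    "RecoveryMetrics",
    "simulate_leaders",
    "simulate_tss_reads",
    "simulate_counts",
    "simulate_study",
    "evaluate_recovery",
    "write_bundle",
]

GENOTYPES = ("WT", "larp1")
TREATMENTS = ("mock", "torin2")
_FLANK = 20  # bp of random genomic context on each side of a planted leader

_TRUTH_MULT_COLS = [f"mult_{g}_{t}" for g in GENOTYPES for t in TREATMENTS]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the simulator; defaults are the standard scenario
    used throughout the test suite (600 genes, 15% TOP, 2.5-fold WT-only
    repression, ~300 TSS reads/gene, 3 replicates)."""

    n_genes: int = 600
    fraction_top: float = 0.15
    leader_length_range: tuple[int, int] = (30, 300)
    top_run_length_range: tuple[int, int] = (5, 15)
    background_pyrimidine_prob: float = 0.5
    primary_tss_mass: float = 0.8
    tss_scatter_window: int = 10
    reads_per_gene_mean: float = 300.0
    reads_per_gene_dispersion: float = 5.0  # NB size parameter
    rna_mean_log_mean: float = math.log(300.0)
    rna_mean_log_sd: float = 1.0
    nb_dispersion: float = 50.0  # count NB size (1/alpha); pooled-replicate bulk
    te_base_log_mean: float = 0.0
    te_base_log_sd: float = 0.25
    gene_length_kb_range: tuple[float, float] = (0.5, 3.0)
    wt_torin2_top_repression_fold: float = 2.5
    larp1_effect_fold: float = 1.0
    replicates: int = 3
    seed: int = 0

    def __post_init__(self):
        positives = {
            "background_pyrimidine_prob": self.background_pyrimidine_prob,
            "primary_tss_mass": self.primary_tss_mass,
            "reads_per_gene_mean": self.reads_per_gene_mean,
            "reads_per_gene_dispersion": self.reads_per_gene_dispersion,
            "nb_dispersion": self.nb_dispersion,
            "wt_torin2_top_repression_fold": self.wt_torin2_top_repression_fold,
            "larp1_effect_fold": self.larp1_effect_fold,
        }
        for name, value in positives.items():
            if value <= 0:
                raise ValueError(f"{name} must be > 0, got {value}")
        if not 0 <= self.fraction_top < 1:
            raise ValueError("fraction_top must be in [0, 1)")
        if not 0 < self.primary_tss_mass <= 1:
            raise ValueError("primary_tss_mass must be in (0, 1]")
        # fraction_top = 0 is the explicit no-TOP null; otherwise plant >= 1 gene
        if self.fraction_top > 0 and self.fraction_top * self.n_genes < 1:
            raise ValueError("fraction_top * n_genes must be >= 1")
        if self.wt_torin2_top_repression_fold < 1:
            raise ValueError("wt_torin2_top_repression_fold must be >= 1")
        if self.larp1_effect_fold < 1:
            raise ValueError("larp1_effect_fold must be >= 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        lo, hi = self.top_run_length_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid top_run_length_range")
        lo, hi = self.leader_length_range
        if lo < max(self.top_run_length_range[1] + 1, self.tss_scatter_window + 1):
            raise ValueError(
                "leaders must be longer than the planted run and scatter window"
            )


@dataclass
class RecoveryMetrics:
    precision: float | None
    recall: float
    f1: float | None
    tp: int
    fp: int
    fn: int


@dataclass
class SimulatedStudy:
    config: SimConfig
    genome: GenomeSequences
    annotations: list[LeaderAnnotation]
    models: dict[str, LeaderModel]
    truth: pd.DataFrame
    tss_records: list[TssEndRecord]
    counts: "CountMatrix"  # noqa: F821 - forward ref to translation_efficiency


def _random_bases(rng: np.random.Generator, n: int, pyr_prob: float) -> str:
    pyr = rng.random(n) < pyr_prob
    pyr_choice = rng.integers(0, 2, size=n)
    out = np.where(
        pyr,
        np.where(pyr_choice == 0, "C", "T"),
        np.where(pyr_choice == 0, "A", "G"),
    )
    return "".join(out)


def _multiplier(is_top: bool, genotype: str, treatment: str, config: SimConfig) -> float:
    if not is_top or treatment != "torin2":
        return 1.0
    if genotype == "WT":
        return 1.0 / config.wt_torin2_top_repression_fold
    return 1.0 / config.larp1_effect_fold


def _simulate_leader_space(
    config: SimConfig, rng: np.random.Generator
) -> tuple[GenomeSequences, list[LeaderAnnotation], dict[str, LeaderModel], pd.DataFrame]:
    n = config.n_genes
    width = len(str(n))
    gene_ids = [f"g{i + 1:0{width}d}" for i in range(n)]
    n_top = int(round(config.fraction_top * n))
    is_top = np.zeros(n, dtype=bool)
    top_idx = rng.choice(n, size=n_top, replace=False)
    is_top[top_idx] = True

    lengths = rng.integers(
        config.leader_length_range[0], config.leader_length_range[1] + 1, size=n
    )
    runs = np.zeros(n, dtype=int)
    runs[is_top] = rng.integers(
        config.top_run_length_range[0], config.top_run_length_range[1] + 1,
        size=n_top,
    )
    strands = np.where(rng.random(n) < 0.5, "+", "-")

    contigs: dict[str, str] = {}
    annotations: list[LeaderAnnotation] = []
    rows = []
    for i, gene in enumerate(gene_ids):
        length = int(lengths[i])
        if is_top[i]:
            run = int(min(runs[i], length - 1))
            head = "C" + "".join(
                "CT"[b] for b in rng.integers(0, 2, size=run - 1)
            )
            purine = "AG"[int(rng.integers(0, 2))]
            tail = _random_bases(
                rng, length - run - 1, config.background_pyrimidine_prob
            )
            leader = head + purine + tail
            runs[i] = run
        else:
            purine = "AG"[int(rng.integers(0, 2))]
            leader = purine + _random_bases(
                rng, length - 1, config.background_pyrimidine_prob
            )
        strand = strands[i]
        flank5 = _random_bases(rng, _FLANK, 0.5)
        flank3 = _random_bases(rng, _FLANK, 0.5)
        embedded = leader if strand == "+" else reverse_complement(leader)
        chrom = f"chr_{gene}"
        contigs[chrom] = flank5 + embedded + flank3
        annotations.append(
            LeaderAnnotation(
                gene_id=gene,
                chrom=chrom,
                strand=strand,
                blocks=((_FLANK, _FLANK + length),),
            )
        )
        rows.append(
            {
                "gene_id": gene,
                "is_top": bool(is_top[i]),
                "planted_run_length": int(runs[i]),
                **{
                    f"mult_{g}_{t}": _multiplier(bool(is_top[i]), g, t, config)
                    for g in GENOTYPES
                    for t in TREATMENTS
                },
            }
        )
    genome = GenomeSequences(contigs)
    models = build_leader_models(genome, annotations)
    truth = pd.DataFrame(rows).set_index("gene_id")
    return genome, annotations, models, truth


def simulate_leaders(
    config: SimConfig, rng: np.random.Generator
) -> tuple[dict[str, LeaderModel], pd.DataFrame]:
    """Leader models plus the planted ground truth table."""
    _, _, models, truth = _simulate_leader_space(config, rng)
    return models, truth


def _nb_draw(
    rng: np.random.Generator, mean, size_param: float, shape=None
) -> np.ndarray:
    """Negative binomial with mean/size (dispersion alpha = 1/size)."""
    mean = np.asarray(mean, dtype=float)
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p, size=shape)


def simulate_tss_reads(
    models: Mapping[str, LeaderModel],
    truth: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator,
) -> list[TssEndRecord]:
    """PEAT-style 5'-end pileups: a fraction ``primary_tss_mass`` of each
    gene's reads at the annotated TSS (leader index 0), the rest uniform over
    indices 1..tss_scatter_window.  All reads stay inside the leader."""
    records: list[TssEndRecord] = []
    for gene in truth.index:
        model = models[gene]
        n_reads = int(_nb_draw(
            rng, config.reads_per_gene_mean, config.reads_per_gene_dispersion
        ))
        if n_reads < 1:
            continue
        at_tss = int(rng.binomial(n_reads, config.primary_tss_mass))
        window = min(config.tss_scatter_window, len(model) - 1)
        counts: dict[int, int] = {}
        if at_tss:
            counts[0] = at_tss
        scattered = n_reads - at_tss
        if scattered and window >= 1:
            idx, idx_counts = np.unique(
                rng.integers(1, window + 1, size=scattered), return_counts=True
            )
            for i, c in zip(idx, idx_counts):
                counts[int(i)] = counts.get(int(i), 0) + int(c)
        elif scattered:
            counts[0] = counts.get(0, 0) + scattered
        for leader_idx, count in sorted(counts.items()):
            records.append(
                TssEndRecord(
                    chrom=model.chrom,
                    pos=model.leader_to_genomic(leader_idx),
                    strand=model.strand,
                    count=count,
                )
            )
    return records


def simulate_counts(
    truth: pd.DataFrame, config: SimConfig, rng: np.random.Generator
) -> "CountMatrix":
    """RNA and Ribo count tables over the full genotype x treatment x replicate
    design, with the planted TE multipliers applied to ribo means only."""
    from .translation_efficiency import CountMatrix

    genes = list(truth.index)
    n = len(genes)
    rna_mean = rng.lognormal(config.rna_mean_log_mean, config.rna_mean_log_sd, n)
    te_base = rng.lognormal(config.te_base_log_mean, config.te_base_log_sd, n)
    lengths = rng.uniform(*config.gene_length_kb_range, size=n)

    sample_rows = []
    columns = {}
    for assay in ("rna", "ribo"):
        for genotype in GENOTYPES:
            for treatment in TREATMENTS:
                mult = truth[f"mult_{genotype}_{treatment}"].to_numpy()
                mu = rna_mean if assay == "rna" else rna_mean * te_base * mult
                for rep in range(1, config.replicates + 1):
                    sid = f"{assay}_{genotype}_{treatment}_r{rep}"
                    columns[sid] = _nb_draw(rng, mu, config.nb_dispersion, shape=n)
                    sample_rows.append(
                        {
                            "sample_id": sid,
                            "assay": assay,
                            "genotype": genotype,
                            "treatment": treatment,
                            "replicate": rep,
                        }
                    )
    counts = pd.DataFrame(columns, index=genes)
    samples = pd.DataFrame(sample_rows).set_index("sample_id")
    lengths_kb = pd.Series(lengths, index=genes, name="length_kb")
    return CountMatrix(counts=counts, lengths_kb=lengths_kb, samples=samples)


def simulate_study(config: SimConfig) -> SimulatedStudy:
    """Full deterministic study bundle from one seed."""
    rng = np.random.default_rng(config.seed)
    genome, annotations, models, truth = _simulate_leader_space(config, rng)
    tss_records = simulate_tss_reads(models, truth, config, rng)
    counts = simulate_counts(truth, config, rng)
    return SimulatedStudy(
        config=config,
        genome=genome,
        annotations=annotations,
        models=models,
        truth=truth,
        tss_records=tss_records,
        counts=counts,
    )


def evaluate_recovery(
    calls: Sequence[TopClassification], truth: pd.DataFrame
) -> RecoveryMetrics:
    """Precision/recall/F1 of high-confidence calls against planted is_top.

    Genes in the truth table that received no call count as negatives.
    Precision (and F1) are None when there are no positive calls.
    """
    called_genes = {c.gene_id for c in calls}
    unknown = called_genes - set(truth.index)
    if unknown:
        raise ValueError(
            f"calls contain genes absent from the truth table: {sorted(unknown)[:5]}"
        )
    positives = {c.gene_id for c in calls if c.high_confidence}
    top_genes = set(truth.index[truth["is_top"]])
    tp = len(positives & top_genes)
    fp = len(positives - top_genes)
    fn = len(top_genes - positives)
    precision = tp / (tp + fp) if (tp + fp) else None
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    if precision is None or (precision + recall) == 0:
        f1 = None if precision is None else 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return RecoveryMetrics(precision=precision, recall=recall, f1=f1, tp=tp, fp=fp, fn=fn)


def write_bundle(study: SimulatedStudy, out_dir: str | Path) -> dict[str, Path]:
    """Write a self-contained plain-text bundle the pipeline can consume."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {name: out / fname for name, fname in [
        ("genome", "genome.fa"),
        ("annotation", "leaders.bed"),
        ("leaders", "leaders.fa"),
        ("tss", "tss.bed"),
        ("counts", "counts.tsv"),
        ("samples", "samples.tsv"),
        ("lengths", "lengths.tsv"),
        ("truth", "truth.tsv"),
        ("config", "config.yaml"),
    ]}
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    SeqIO.write(
        [SeqRecord(Seq(seq), id=name, description="") for name, seq in study.genome.items()],
        str(paths["genome"]),
        "fasta",
    )
    with open(paths["annotation"], "w") as fh:
        for ann in study.annotations:
            start, end = ann.blocks[0][0], ann.blocks[-1][1]
            fh.write(f"{ann.chrom}\t{start}\t{end}\t{ann.gene_id}\t0\t{ann.strand}\n")
    write_leaders_fasta(study.models, paths["leaders"])
    with open(paths["tss"], "w") as fh:
        for rec in study.tss_records:
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t{rec.pos + 1}\t.\t{rec.count}\t{rec.strand}\n"
            )
    study.counts.counts.rename_axis("gene_id").to_csv(paths["counts"], sep="\t")
    study.counts.samples.reset_index().to_csv(paths["samples"], sep="\t", index=False)
    study.counts.lengths_kb.rename_axis("gene_id").to_frame().to_csv(
        paths["lengths"], sep="\t"
    )
    study.truth.rename_axis("gene_id").to_csv(paths["truth"], sep="\t")
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(dataclasses.asdict(study.config), fh, sort_keys=True)
    return paths
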