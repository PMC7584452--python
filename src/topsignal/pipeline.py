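"""End-to-end orchestration: leaders -> profiles -> TOPscore -> TE ->
classification -> category statistics, with a JSON run report.

All outputs are single-header TSV files with floats printed to 6 significant
digits, so repeated runs on unchanged inputs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .annotation_io import (
    GenomeSequences,
    build_leader_models,
    read_leader_annotations,
    read_leaders_fasta,
    write_leaders_fasta,
)
from .category_stats import (
    category_topscore_analysis,
    read_category_map_tsv,
    write_category_results_tsv,
)
from .top_classifier import ClassifierConfig, classify, write_calls_tsv
from .topscore import compute_topscores, rank_percentiles, write_topscores_tsv
from .translation_efficiency import (
    CountMatrix,
    compute_fpkm,
    compute_te,
    filter_expressed,
    read_counts_tsv,
    read_lengths_tsv,
    read_samples_tsv,
    write_te_tsv,
)
from .tss_profiles import (
    build_profiles,
    filter_low_coverage_sites,
    read_tss_ends,
    write_profiles_tsv,
)

__all__ = ["PipelineConfig", "RunReport", "StageError", "run_end_to_end"]

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    out_dir: str = "topsignal_out"
    # leader inputs: either a pre-extracted leaders FASTA, or genome + annotation
    leaders_fasta: str | None = None
    genome: str | None = None
    annotation: str | None = None
    annotation_dialect: str = "auto"
    # TSS inputs
    tss: str | None = None
    tss_dialect: str = "bed6"
    tss_minus: str | None = None
    # expression inputs
    counts: str | None = None
    samples: str | None = None
    lengths: str | None = None
    categories: str | None = None
    # thresholds
    min_site_reads: int = 10
    min_total_reads: int = 10
    min_rpkm: float = 10.0
    fold_threshold: float = 2.0
    topscore_percentile_min: float = 0.80
    wt_repression_fold_min: float = 1.5
    larp1_repression_fold_max: float = 1.2
    wt_genotype: str = "WT"
    mutant_genotype: str = "larp1"
    control_treatment: str = "mock"
    treated_treatment: str = "torin2"
    category_min_size: int = 5
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def classifier_config(self) -> ClassifierConfig:
        return ClassifierConfig(
            topscore_percentile_min=self.topscore_percentile_min,
            wt_repression_fold_min=self.wt_repression_fold_min,
            larp1_repression_fold_max=self.larp1_repression_fold_max,
            min_rpkm=self.min_rpkm,
            wt_genotype=self.wt_genotype,
            mutant_genotype=self.mutant_genotype,
        )


@dataclass
class RunReport:
    version: str
    config: dict
    stages: list[str] = field(default_factory=list)
    counts: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _require(config: PipelineConfig, *names: str) -> None:
    for name in names:
        value = getattr(config, name)
        if value is None:
            raise FileNotFoundError(f"required input {name!r} not configured")
        if not Path(value).exists():
            raise FileNotFoundError(f"{name} file not found: {value}")


def run_end_to_end(config: PipelineConfig) -> RunReport:
    """Execute every configured stage; deterministic given inputs.

    Raises :class:`StageError` naming the failing stage; missing input files
    raise :class:`FileNotFoundError` before any stage runs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(version=__version__, config=dataclasses.asdict(config))

    if config.leaders_fasta is not None:
        _require(config, "leaders_fasta")
    else:
        _require(config, "genome", "annotation")
    _require(config, "tss", "counts", "samples", "lengths")
    if config.categories is not None:
        _require(config, "categories")

    stage = "leaders"
    try:
        if config.leaders_fasta is not None:
            models = read_leaders_fasta(config.leaders_fasta)
        else:
            genome = GenomeSequences.from_fasta(config.genome)
            annotations = read_leader_annotations(
                config.annotation, dialect=config.annotation_dialect
            )
            models = build_leader_models(genome, annotations)
        write_leaders_fasta(models, out / "leaders.fa")
        report.stages.append(stage)
        report.counts["annotated"] = len(models)

        stage = "profiles"
        records = read_tss_ends(
            config.tss, dialect=config.tss_dialect, minus_path=config.tss_minus
        )
        profiles = build_profiles(records, models)
        profiles = {
            g: filter_low_coverage_sites(p, config.min_site_reads)
            for g, p in profiles.items()
        }
        profiles = {g: p for g, p in profiles.items() if p.n_sites > 0}
        write_profiles_tsv(profiles, out / "profiles.tsv")
        report.stages.append(stage)
        report.counts["profiled"] = len(profiles)

        stage = "topscore"
        scored = compute_topscores(
            profiles, models, min_total_reads=config.min_total_reads
        )
        scored = rank_percentiles(scored) if scored else []
        write_topscores_tsv(scored, out / "topscores.tsv")
        report.stages.append(stage)
        report.counts["scored"] = len(scored)

        stage = "te"
        matrix = CountMatrix(
            counts=read_counts_tsv(config.counts),
            lengths_kb=read_lengths_tsv(config.lengths),
            samples=read_samples_tsv(config.samples),
        )
        fpkm = compute_fpkm(matrix)
        te = compute_te(
            fpkm,
            matrix.samples,
            control_treatment=config.control_treatment,
            treated_treatment=config.treated_treatment,
        )
        write_te_tsv(te, out / "te.tsv")
        expressed = filter_expressed(fpkm, matrix.samples, min_rpkm=config.min_rpkm)
        report.stages.append(stage)
        fold_cols = [c for c in te.columns if c[0] == "fold_change"]
        report.counts["te_defined"] = int(te[fold_cols].notna().all(axis=1).sum())

        stage = "classify"
        calls = classify(scored, te, expressed, config.classifier_config())
        write_calls_tsv(calls, out / "calls.tsv")
        report.stages.append(stage)
        report.counts["classified"] = len(calls)
        report.counts["high_confidence"] = sum(c.high_confidence for c in calls)

        if config.categories is not None:
            stage = "categorize"
            cat_map = read_category_map_tsv(config.categories)
            results = category_topscore_analysis(
                cat_map, scored, min_size=config.category_min_size
            )
            write_category_results_tsv(results, out / "categories.tsv")
            report.stages.append(stage)
            report.counts["categories_tested"] = len(results)
    except FileNotFoundError:
        raise
    except Exception as exc:  # surface the failing stage
        raise StageError(stage, exc) from exc

    report.to_json(out / "report.json")
    return report
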