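"""TOPscore: read-weighted mean pyrimidine-run length over TSS 5' ends.

A 5' terminal oligopyrimidine (5'TOP) motif is an uninterrupted run of
pyrimidines (C/T) starting at the transcript's cap-proximal base.  Each
TSS-Seq 5' end in a gene's annotated leader is scored by the length of the
maximal pyrimidine run starting at that base (0 for a purine or N); the
gene's TOPscore is the read-count-weighted mean of these per-site scores:

    TOPscore = sum_i count_i * run_length_i / R

with R the retained-read total after low-coverage site filtering.  This is
identical to the mean per-read score when every read is enumerated
individually.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from .annotation_io import LeaderModel
from .tss_profiles import TssProfile

__all__ = [
    "ScoredSite",
    "TopScoreRecord",
    "UnscorableGeneError",
    "pyrimidine_run_length",
    "run_length_table",
    "score_sites",
    "compute_topscore",
    "compute_topscores",
    "rank_percentiles",
    "write_topscores_tsv",
    "read_topscores_tsv",
]

_PYRIMIDINES = frozenset("CT")


class UnscorableGeneError(ValueError):
    """Raised when a gene has no retained TSS sites and hence no TOPscore.

    Distinct from a TOPscore of 0, which means reads are present but none
    start a pyrimidine run.
    """


@dataclass(frozen=True)
class ScoredSite:
    leader_index: int
    count: int
    run_length: int


@dataclass(frozen=True)
class TopScoreRecord:
    gene_id: str
    topscore: float
    total_reads: int  # R
    n_sites: int
    percentile: float | None = None  # set by rank_percentiles


def pyrimidine_run_length(leader_sequence: str, index: int) -> int:
    """Length of the maximal pyrimidine (C/T) run starting at ``index``.

    0 when the base there is a purine or N; the run is truncated at the
    leader's 3' end and terminated by any non-pyrimidine (N included).
    """
    if not 0 <= index < len(leader_sequence):
        raise IndexError(
            f"index {index} out of range for leader of length {len(leader_sequence)}"
        )
    run = 0
    for base in leader_sequence[index:]:
        if base not in _PYRIMIDINES:
            break
        run += 1
    return run


def run_length_table(leader_sequence: str) -> np.ndarray:
    """Pyrimidine-run length at every leader position, via a single 3'->5' pass."""
    length = len(leader_sequence)
    runs = np.zeros(length, dtype=np.int64)
    nxt = 0
    for i in range(length - 1, -1, -1):
        nxt = nxt + 1 if leader_sequence[i] in _PYRIMIDINES else 0
        runs[i] = nxt
    return runs


def score_sites(profile: TssProfile, model: LeaderModel) -> list[ScoredSite]:
    runs = run_length_table(model.sequence)
    sites = []
    for idx in sorted(profile.site_counts):
        if not 0 <= idx < len(model):
            raise IndexError(
                f"{profile.gene_id}: site index {idx} outside leader [0, {len(model)})"
            )
        sites.append(
            ScoredSite(
                leader_index=idx,
                count=profile.site_counts[idx],
                run_length=int(runs[idx]),
            )
        )
    return sites


def compute_topscore(profile: TssProfile, model: LeaderModel) -> TopScoreRecord:
    """TOPscore of one filtered profile.

    Raises :class:`UnscorableGeneError` on an empty profile (R = 0), keeping
    "no score" distinct from a true score of 0.
    """
    sites = score_sites(profile, model)
    total = sum(s.count for s in sites)
    if total < 1:
        raise UnscorableGeneError(f"{profile.gene_id}: no retained TSS sites")
    weighted = sum(s.count * s.run_length for s in sites)  # exact integer sum
    return TopScoreRecord(
        gene_id=profile.gene_id,
        topscore=weighted / total,
        total_reads=total,
        n_sites=len(sites),
    )


def compute_topscores(
    profiles: Mapping[str, TssProfile],
    models: Mapping[str, LeaderModel],
    min_total_reads: int = 10,
) -> list[TopScoreRecord]:
    """Score every gene with a retained-read total R >= ``min_total_reads``.

    Genes below the minimum (or with no retained sites at all) are reported as
    unscored, i.e. simply absent from the output.
    """
    records = []
    for gene_id in sorted(profiles):
        if gene_id not in models:
            continue
        profile = profiles[gene_id]
        if profile.total_reads < max(min_total_reads, 1):
            continue
        records.append(compute_topscore(profile, models[gene_id]))
    return records


def rank_percentiles(records: Sequence[TopScoreRecord]) -> list[TopScoreRecord]:
    """Attach weak-inequality percentile ranks.

    percentile(g) = #(scored genes with topscore <= topscore(g)) / #scored.
    Ties share the same percentile; the top gene gets exactly 1.0.
    """
    if not records:
        raise ValueError("rank_percentiles requires at least one scored gene")
    scores = np.array([r.topscore for r in records], dtype=float)
    ranks = rankdata(scores, method="max")  # count of values <= score
    n = len(records)
    return [
        replace(rec, percentile=float(rank) / n)
        for rec, rank in zip(records, ranks)
    ]


def write_topscores_tsv(records: Iterable[TopScoreRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\ttopscore\tR\tn_sites\tpercentile\n")
        for rec in sorted(records, key=lambda r: r.gene_id):
            pct = "NA" if rec.percentile is None else f"{rec.percentile:.6g}"
            fh.write(
                f"{rec.gene_id}\t{rec.topscore:.6g}\t{rec.total_reads}\t"
                f"{rec.n_sites}\t{pct}\n"
            )


def read_topscores_tsv(path: str | Path) -> list[TopScoreRecord]:
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["gene_id", "topscore", "R", "n_sites", "percentile"]:
            raise ValueError(f"{path}: unexpected topscores header {header}")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            gene_id, score, r, n_sites, pct = line.split("\t")
            records.append(
                TopScoreRecord(
                    gene_id=gene_id,
                    topscore=float(score),
                    total_reads=int(r),
                    n_sites=int(n_sites),
                    percentile=None if pct == "NA" else float(pct),
                )
            )
    return records
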