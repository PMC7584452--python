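"""Three-criterion classification of high-confidence 5'TOP mRNAs.

A gene is called a high-confidence 5'TOP mRNA when it satisfies all of:

  (i)   TOPscore percentile in the top fifth of scored genes
        (percentile >= 0.80, inclusive);
  (ii)  TE repressed by TOR inhibition in the wild type
        (WT treated/control TE fold change <= 1/wt_repression_fold_min);
  (iii) little or no TE repression by TOR inhibition in the larp1 mutant
        (larp1 fold change >= 1/larp1_repression_fold_max; TE increases
        always qualify).

The numeric cutoffs for (ii) and (iii) are package defaults reverse-engineered
from the qualitative description of the criteria and the exemplar pattern of a
gene repressed 1.7-fold in WT and unchanged (+1.2-fold) in larp1; they are
deliberately configurable because only criterion (i) has a stated threshold.
Genes lacking a TOPscore, a defined TE fold change in either genotype, or
falling below the expression floor are never called.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .topscore import TopScoreRecord

__all__ = ["ClassifierConfig", "TopClassification", "classify", "write_calls_tsv"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClassifierConfig:
    topscore_percentile_min: float = 0.80
    wt_repression_fold_min: float = 1.5
    larp1_repression_fold_max: float = 1.2
    min_rpkm: float = 10.0
    wt_genotype: str = "WT"
    mutant_genotype: str = "larp1"

    def __post_init__(self):
        if not 0 < self.topscore_percentile_min <= 1:
            raise ValueError("topscore_percentile_min must be in (0, 1]")
        if self.wt_repression_fold_min <= 1:
            raise ValueError("wt_repression_fold_min must be > 1")
        if self.larp1_repression_fold_max < 1:
            raise ValueError("larp1_repression_fold_max must be >= 1")


@dataclass(frozen=True)
class TopClassification:
    gene_id: str
    percentile: float
    wt_fold: float
    larp1_fold: float
    c1_top_percentile: bool
    c2_wt_repressed: bool
    c3_larp1_insensitive: bool

    @property
    def high_confidence(self) -> bool:
        return (
            self.c1_top_percentile
            and self.c2_wt_repressed
            and self.c3_larp1_insensitive
        )


def classify(
    topscores: Sequence[TopScoreRecord],
    te: pd.DataFrame,
    expressed: Iterable[str] | None = None,
    config: ClassifierConfig | None = None,
) -> list[TopClassification]:
    """Apply the three 5'TOP criteria to every eligible gene.

    Eligible = scored (with a percentile set), both genotype TE fold changes
    defined, and — when ``expressed`` is given — passing the expression
    filter.  Ineligible genes get no call and are logged with a reason.
    """
    config = config or ClassifierConfig()
    expressed_set = None if expressed is None else set(expressed)
    wt_col = ("fold_change", config.wt_genotype, "")
    mut_col = ("fold_change", config.mutant_genotype, "")
    for col in (wt_col, mut_col):
        if col not in te.columns:
            raise ValueError(f"TE table lacks fold-change column for {col[1]!r}")
    calls = []
    for rec in topscores:
        if rec.percentile is None:
            logger.debug("%s: no percentile rank; skipped", rec.gene_id)
            continue
        if expressed_set is not None and rec.gene_id not in expressed_set:
            logger.debug("%s: below expression floor; skipped", rec.gene_id)
            continue
        if rec.gene_id not in te.index:
            logger.debug("%s: absent from TE table; skipped", rec.gene_id)
            continue
        wt_fold = te.at[rec.gene_id, wt_col]
        mut_fold = te.at[rec.gene_id, mut_col]
        if pd.isna(wt_fold) or pd.isna(mut_fold):
            logger.debug("%s: undefined TE fold change; skipped", rec.gene_id)
            continue
        wt_fold, mut_fold = float(wt_fold), float(mut_fold)
        calls.append(
            TopClassification(
                gene_id=rec.gene_id,
                percentile=rec.percentile,
                wt_fold=wt_fold,
                larp1_fold=mut_fold,
                c1_top_percentile=rec.percentile >= config.topscore_percentile_min,
                c2_wt_repressed=wt_fold <= 1.0 / config.wt_repression_fold_min,
                c3_larp1_insensitive=mut_fold >= 1.0 / config.larp1_repression_fold_max,
            )
        )
    return calls


def write_calls_tsv(calls: Iterable[TopClassification], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "gene_id\tpercentile\twt_fold\tlarp1_fold\tc1\tc2\tc3\thigh_confidence\n"
        )
        for call in sorted(calls, key=lambda c: c.gene_id):
            fh.write(
                f"{call.gene_id}\t{call.percentile:.6g}\t{call.wt_fold:.6g}\t"
                f"{call.larp1_fold:.6g}\t{int(call.c1_top_percentile)}\t"
                f"{int(call.c2_wt_repressed)}\t{int(call.c3_larp1_insensitive)}\t"
                f"{int(call.high_confidence)}\n"
            )
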