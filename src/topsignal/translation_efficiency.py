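"""Translation efficiency from paired Ribo-Seq / RNA-Seq count tables.

TE of a gene in one design cell (genotype x treatment) is the ratio of its
mean Ribo-Seq FPKM to its mean RNA-Seq FPKM over replicates; the treated/
control TE ratio per genotype quantifies translational repression or
induction.  FPKM and RPKM are treated as the same gene-level quantity:
count / (length_kb * library_size / 1e6).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "ASSAYS",
    "CountMatrix",
    "DesignError",
    "compute_fpkm",
    "compute_te",
    "flag_te_changes",
    "filter_expressed",
    "read_counts_tsv",
    "read_samples_tsv",
    "read_lengths_tsv",
]

ASSAYS = ("rna", "ribo")
_SAMPLE_COLUMNS = ["assay", "genotype", "treatment", "replicate"]


class DesignError(ValueError):
    pass


@dataclass
class CountMatrix:
    """Gene x sample raw counts with per-gene lengths and sample metadata.

    ``counts``: non-negative integer DataFrame, genes as index, sample ids as
    columns.  ``lengths_kb``: per-gene length in kilobases (> 0).
    ``samples``: DataFrame indexed by sample_id with columns assay
    ('rna'/'ribo'), genotype, treatment, replicate.
    """

    counts: pd.DataFrame
    lengths_kb: pd.Series
    samples: pd.DataFrame

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise ValueError("counts contain negative entries")
        totals = self.counts.sum(axis=0)
        if (totals < 1).any():
            empty = list(totals.index[totals < 1])
            raise ValueError(f"sample columns with zero total count: {empty}")
        missing = self.counts.index.difference(self.lengths_kb.index)
        if len(missing):
            raise ValueError(f"genes missing lengths: {list(missing[:5])}...")
        if (self.lengths_kb.loc[self.counts.index] <= 0).any():
            raise ValueError("gene lengths must be > 0 kb")
        extra = self.counts.columns.difference(self.samples.index)
        if len(extra):
            raise ValueError(f"samples missing metadata: {list(extra)}")
        meta = self.samples.loc[self.counts.columns]
        bad_assay = set(meta["assay"]) - set(ASSAYS)
        if bad_assay:
            raise DesignError(f"unknown assay values: {sorted(bad_assay)}")
        dup = meta.duplicated(subset=_SAMPLE_COLUMNS)
        if dup.any():
            raise DesignError(
                f"duplicate (assay, genotype, treatment, replicate): "
                f"{list(meta.index[dup])}"
            )

    @property
    def genes(self) -> pd.Index:
        return self.counts.index


def compute_fpkm(counts: CountMatrix) -> pd.DataFrame:
    """FPKM(g, s) = count(g, s) / (length_kb(g) * total_count(s) / 1e6)."""
    totals = counts.counts.sum(axis=0).astype(float)
    lengths = counts.lengths_kb.loc[counts.genes].astype(float)
    return counts.counts.div(totals / 1e6, axis=1).div(lengths, axis=0)


def _cell_means(
    fpkm: pd.DataFrame, samples: pd.DataFrame, assay: str
) -> pd.DataFrame:
    """Per-gene mean FPKM over replicates for each (genotype, treatment) cell."""
    meta = samples.loc[fpkm.columns]
    cols = meta.index[meta["assay"] == assay]
    if not len(cols):
        raise DesignError(f"no {assay} samples in design")
    groups = meta.loc[cols].groupby(["genotype", "treatment"], sort=True)
    out = {}
    for (genotype, treatment), sub in groups:
        out[(genotype, treatment)] = fpkm[sub.index].mean(axis=1)
    result = pd.DataFrame(out)
    result.columns = pd.MultiIndex.from_tuples(
        result.columns, names=["genotype", "treatment"]
    )
    return result


def compute_te(
    fpkm: pd.DataFrame,
    samples: pd.DataFrame,
    control_treatment: str = "mock",
    treated_treatment: str = "torin2",
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """Per-gene TE and treated/control fold changes.

    Returns a DataFrame indexed by gene with MultiIndex columns:
    ('te', genotype, treatment), ('fold_change', genotype, ''), and
    ('log2fc', genotype, '').  TE is NaN where the rna mean is 0 (no
    pseudocount by default); fold changes are defined only when both TE
    values are.
    """
    rna = _cell_means(fpkm, samples, "rna")
    ribo = _cell_means(fpkm, samples, "ribo")
    cells = sorted(set(rna.columns) | set(ribo.columns))
    for cell in cells:
        for assay, table in (("rna", rna), ("ribo", ribo)):
            if cell not in table.columns:
                raise DesignError(
                    f"design cell genotype={cell[0]!r}, treatment={cell[1]!r} "
                    f"has no {assay} samples"
                )
    rna = rna + pseudocount
    ribo = ribo + pseudocount
    te = ribo / rna.where(rna > 0)  # NaN where rna mean is 0
    blocks = {("te", g, t): te[(g, t)] for g, t in te.columns}
    genotypes = sorted({g for g, _ in te.columns})
    for genotype in genotypes:
        treated = (genotype, treated_treatment)
        control = (genotype, control_treatment)
        if treated not in te.columns or control not in te.columns:
            raise DesignError(
                f"genotype {genotype!r} lacks treatment "
                f"{control_treatment!r}/{treated_treatment!r} cells"
            )
        fold = te[treated] / te[control].where(te[control] > 0)
        blocks[("fold_change", genotype, "")] = fold
        blocks[("log2fc", genotype, "")] = np.log2(fold)
    out = pd.DataFrame(blocks)
    out.columns = pd.MultiIndex.from_tuples(out.columns)
    return out


def flag_te_changes(
    te: pd.DataFrame, genotype: str, fold_threshold: float = 2.0
) -> tuple[set, set]:
    """(repressed, induced) gene sets for one genotype.

    Boundaries are inclusive: repressed means fold_change <= 1/threshold,
    induced means fold_change >= threshold.  Genes with undefined fold
    changes belong to neither set.
    """
    if fold_threshold <= 1:
        raise ValueError(f"fold_threshold must be > 1, got {fold_threshold}")
    fold = te[("fold_change", genotype, "")].dropna()
    repressed = set(fold.index[fold <= 1.0 / fold_threshold])
    induced = set(fold.index[fold >= fold_threshold])
    return repressed, induced


def filter_expressed(
    fpkm: pd.DataFrame, samples: pd.DataFrame, min_rpkm: float = 10.0
) -> set:
    """Genes whose mean Ribo-Seq FPKM across all ribo samples is >= min_rpkm
    (inclusive boundary)."""
    if min_rpkm < 0:
        raise ValueError(f"min_rpkm must be >= 0, got {min_rpkm}")
    meta = samples.loc[fpkm.columns]
    ribo_cols = meta.index[meta["assay"] == "ribo"]
    if not len(ribo_cols):
        raise DesignError("no ribo samples in design")
    mean_ribo = fpkm[ribo_cols].mean(axis=1)
    return set(mean_ribo.index[mean_ribo >= min_rpkm])


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    counts = pd.read_csv(path, sep="\t", index_col=0)
    return counts.astype(np.int64)


def read_samples_tsv(path: str | Path) -> pd.DataFrame:
    samples = pd.read_csv(path, sep="\t", index_col="sample_id", dtype=str)
    missing = [c for c in _SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise DesignError(f"{path}: sample sheet missing columns {missing}")
    samples["replicate"] = samples["replicate"].astype(int)
    return samples


def read_lengths_tsv(path: str | Path) -> pd.Series:
    lengths = pd.read_csv(path, sep="\t", index_col="gene_id")["length_kb"]
    return lengths.astype(float)


def write_te_tsv(te: pd.DataFrame, path: str | Path) -> None:
    """Flatten the TE table to one header line for golden-file stability."""
    flat = te.copy()
    flat.columns = [
        f"{a}_{g}_{t}" if t else f"{a}_{g}" for a, g, t in te.columns
    ]
    flat.index.name = "gene_id"
    with open(path, "w") as fh:
        fh.write("gene_id\t" + "\t".join(flat.columns) + "\n")
        for gene, row in flat.iterrows():
            vals = "\t".join(
                "NA" if pd.isna(v) else f"{v:.6g}" for v in row.values
            )
            fh.write(f"{gene}\t{vals}\n")


def read_te_tsv(path: str | Path) -> pd.DataFrame:
    flat = pd.read_csv(path, sep="\t", index_col="gene_id", na_values="NA")
    tuples = []
    for col in flat.columns:
        parts = col.split("_")
        if parts[0] == "te":
            tuples.append(("te", "_".join(parts[1:-1]), parts[-1]))
        else:
            # fold_change_<genotype> / log2fc_<genotype>
            if col.startswith("fold_change_"):
                tuples.append(("fold_change", col[len("fold_change_"):], ""))
            elif col.startswith("log2fc_"):
                tuples.append(("log2fc", col[len("log2fc_"):], ""))
            else:
                raise ValueError(f"{path}: unrecognized TE column {col!r}")
    flat.columns = pd.MultiIndex.from_tuples(tuples)
    return flat


__all__ += ["write_te_tsv", "read_te_tsv"]
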