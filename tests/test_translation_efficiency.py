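"""FPKM, translation efficiency, fold-change flags, and expression filter."""

import numpy as np
import pandas as pd
import pytest

from topsignal.translation_efficiency import (
    CountMatrix,
    DesignError,
    compute_fpkm,
    compute_te,
    filter_expressed,
    flag_te_changes,
    read_te_tsv,
    write_te_tsv,
)


def design(genotypes=("WT",), treatments=("mock", "torin2"), replicates=1):
    rows = []
    for assay in ("rna", "ribo"):
        for g in genotypes:
            for t in treatments:
                for r in range(1, replicates + 1):
                    rows.append(
                        {"sample_id": f"{assay}_{g}_{t}_r{r}", "assay": assay,
                         "genotype": g, "treatment": t, "replicate": r}
                    )
    return pd.DataFrame(rows).set_index("sample_id")


def matrix_from(counts: dict, lengths: dict, samples: pd.DataFrame) -> CountMatrix:
    return CountMatrix(
        counts=pd.DataFrame(counts),
        lengths_kb=pd.Series(lengths, name="length_kb"),
        samples=samples,
    )


class TestFpkm:
    def test_forced_arithmetic(self):
        samples = design(treatments=("mock",))
        counts = {
            "rna_WT_mock_r1": {"gA": 100, "pad": 999_900},
            "ribo_WT_mock_r1": {"gA": 100, "pad": 999_900},
        }
        # compute_te requires both treatments; here only FPKM is exercised
        samples = samples.loc[list(counts)]
        m = matrix_from(counts, {"gA": 2.0, "pad": 1.0}, samples)
        fpkm = compute_fpkm(m)
        assert fpkm.at["gA", "rna_WT_mock_r1"] == pytest.approx(50.0)

    def test_column_scaling_identity(self):
        samples = design(treatments=("mock",))
        base = {"rna_WT_mock_r1": {"gA": 10, "gB": 30},
                "ribo_WT_mock_r1": {"gA": 10, "gB": 30}}
        doubled = {k: {g: 2 * v for g, v in col.items()} for k, col in base.items()}
        lengths = {"gA": 1.0, "gB": 2.0}
        samples = samples.loc[list(base)]
        f1 = compute_fpkm(matrix_from(base, lengths, samples))
        f2 = compute_fpkm(matrix_from(doubled, lengths, samples))
        pd.testing.assert_frame_equal(f1, f2)

    def test_zero_count_gives_zero_fpkm(self):
        samples = design(treatments=("mock",))
        counts = {"rna_WT_mock_r1": {"gA": 0, "gB": 5},
                  "ribo_WT_mock_r1": {"gA": 1, "gB": 5}}
        samples = samples.loc[list(counts)]
        fpkm = compute_fpkm(matrix_from(counts, {"gA": 1.0, "gB": 1.0}, samples))
        assert fpkm.at["gA", "rna_WT_mock_r1"] == 0.0

    def test_zero_gene_length_is_error(self):
        samples = design(treatments=("mock",))
        counts = {"rna_WT_mock_r1": {"gA": 1}, "ribo_WT_mock_r1": {"gA": 1}}
        with pytest.raises(ValueError, match="length"):
            matrix_from(counts, {"gA": 0.0}, samples.loc[list(counts)])


class TestComputeTe:
    def test_replicate_means_before_ratio(self):
        samples = design(replicates=2)
        fpkm = pd.DataFrame(
            {
                "rna_WT_mock_r1": {"gA": 4.0}, "rna_WT_mock_r2": {"gA": 6.0},
                "ribo_WT_mock_r1": {"gA": 10.0}, "ribo_WT_mock_r2": {"gA": 10.0},
                "rna_WT_torin2_r1": {"gA": 5.0}, "rna_WT_torin2_r2": {"gA": 5.0},
                "ribo_WT_torin2_r1": {"gA": 5.0}, "ribo_WT_torin2_r2": {"gA": 5.0},
            }
        )
        te = compute_te(fpkm, samples)
        assert te.at["gA", ("te", "WT", "mock")] == pytest.approx(2.0)
        assert te.at["gA", ("te", "WT", "torin2")] == pytest.approx(1.0)
        assert te.at["gA", ("fold_change", "WT", "")] == pytest.approx(0.5)
        assert te.at["gA", ("log2fc", "WT", "")] == pytest.approx(-1.0)

    def test_zero_rna_mean_gives_undefined_te(self):
        samples = design()
        fpkm = pd.DataFrame(
            {
                "rna_WT_mock_r1": {"gA": 0.0}, "ribo_WT_mock_r1": {"gA": 3.0},
                "rna_WT_torin2_r1": {"gA": 2.0}, "ribo_WT_torin2_r1": {"gA": 3.0},
            }
        )
        te = compute_te(fpkm, samples)
        assert np.isnan(te.at["gA", ("te", "WT", "mock")])
        assert np.isnan(te.at["gA", ("fold_change", "WT", "")])

    def test_missing_design_cell_names_the_cell(self):
        samples = design()
        fpkm = pd.DataFrame(
            {
                "rna_WT_mock_r1": {"gA": 1.0}, "ribo_WT_mock_r1": {"gA": 1.0},
                "rna_WT_torin2_r1": {"gA": 1.0},
            }
        )
        with pytest.raises(DesignError, match="torin2"):
            compute_te(fpkm, samples.loc[list(fpkm.columns)])

    def test_te_invariant_under_uniform_library_scaling(self):
        samples = design(replicates=2)
        rng = np.random.default_rng(7)
        genes = [f"g{i}" for i in range(20)]
        counts = {
            s: dict(zip(genes, rng.integers(1, 500, len(genes))))
            for s in samples.index
        }
        lengths = {g: 1.0 + i / 10 for i, g in enumerate(genes)}
        m1 = matrix_from(counts, lengths, samples)
        scaled = {
            s: ({g: 3 * v for g, v in col.items()}
                if s.startswith("ribo") else dict(col))
            for s, col in counts.items()
        }
        m2 = matrix_from(scaled, lengths, samples)
        te1 = compute_te(compute_fpkm(m1), samples)
        te2 = compute_te(compute_fpkm(m2), samples)
        pd.testing.assert_frame_equal(te1, te2)

    def test_single_gene_ribo_scaling_approaches_factor_at_depth(self):
        # library 1e6; tripling one small gene's ribo counts scales its TE
        # by ~3 (within 1%) because the library total barely moves
        samples = design(treatments=("mock", "torin2"))
        genes = {"gA": 100, "pad": 1_000_000}
        counts = {s: dict(genes) for s in samples.index}
        bumped = {
            s: ({**col, "gA": col["gA"] * 3} if s.startswith("ribo") else dict(col))
            for s, col in counts.items()
        }
        lengths = {"gA": 1.0, "pad": 1.0}
        te1 = compute_te(compute_fpkm(matrix_from(counts, lengths, samples)), samples)
        te2 = compute_te(compute_fpkm(matrix_from(bumped, lengths, samples)), samples)
        ratio = (te2.at["gA", ("te", "WT", "mock")] /
                 te1.at["gA", ("te", "WT", "mock")])
        assert ratio == pytest.approx(3.0, rel=0.01)


class TestFlagsAndFilter:
    def te_table(self, folds):
        idx = list(folds)
        cols = pd.MultiIndex.from_tuples([("fold_change", "WT", "")])
        return pd.DataFrame({cols[0]: pd.Series(folds)}, index=idx)

    def test_flagging_boundaries(self):
        te = self.te_table({"rep": 0.45, "flat": 1.0, "ind": 2.0, "edge": 0.5})
        repressed, induced = flag_te_changes(te, "WT", 2.0)
        assert repressed == {"rep", "edge"}  # boundary inclusive
        assert induced == {"ind"}

    def test_repressed_and_induced_disjoint(self, rng):
        folds = {f"g{i}": float(f) for i, f in enumerate(rng.lognormal(0, 1, 200))}
        for threshold in (1.2, 2.0, 4.0):
            repressed, induced = flag_te_changes(self.te_table(folds), "WT", threshold)
            assert not repressed & induced

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            flag_te_changes(self.te_table({"g": 1.0}), "WT", 1.0)

    def test_expression_filter_inclusive_boundary(self):
        samples = design(treatments=("mock",))
        fpkm = pd.DataFrame(
            {
                "rna_WT_mock_r1": {"gA": 0.0, "gB": 0.0, "gC": 0.0},
                "ribo_WT_mock_r1": {"gA": 10.0, "gB": 9.9, "gC": 0.0},
            }
        )
        samples = samples.loc[list(fpkm.columns)]
        assert filter_expressed(fpkm, samples, 10.0) == {"gA"}
        assert filter_expressed(fpkm, samples, 0.0) == {"gA", "gB", "gC"}


def test_te_tsv_roundtrip(tmp_path):
    samples = design()
    fpkm = pd.DataFrame(
        {
            "rna_WT_mock_r1": {"gA": 4.0}, "ribo_WT_mock_r1": {"gA": 8.0},
            "rna_WT_torin2_r1": {"gA": 4.0}, "ribo_WT_torin2_r1": {"gA": 2.0},
        }
    )
    te = compute_te(fpkm, samples)
    path = tmp_path / "te.tsv"
    write_te_tsv(te, path)
    loaded = read_te_tsv(path)
    assert loaded.at["gA", ("fold_change", "WT", "")] == pytest.approx(0.25)
    assert loaded.at["gA", ("te", "WT", "mock")] == pytest.approx(2.0)
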