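"""Normalization, filtering and imputation contracts."""

import numpy as np
import pandas as pd
import pytest

from tmtboot import (
    AbundanceMatrix,
    ProteinAnnotation,
    Scale,
    filter_contaminants,
    filter_detection,
    impute,
    inject_block_missingness,
    mask_and_score,
    normalize_total,
    to_reference_ratios,
)
from tmtboot.types import Block, BlockDesign, Group, Plex, SampleMeta


def _tiny_design():
    plexes = [Plex("A", Group.case, "131"), Plex("B", Group.control, "131")]
    blocks = [Block("B1", "A", "B")]
    meta = []
    for grp, plex, subj in ((Group.case, "A", "c1"), (Group.control, "B", "k1")):
        for i, tp in enumerate(("T0", "T15m", "T24h")):
            meta.append(SampleMeta(f"{subj}_{tp}", subj, grp, tp, plex, str(126 + i)))
    return BlockDesign(plexes, blocks), meta


class TestNormalizeTotal:
    def test_equal_totals_unchanged(self):
        df = pd.DataFrame({"s1": [1.0, 3.0], "s2": [2.0, 2.0]}, index=["P1", "P2"])
        m = normalize_total(AbundanceMatrix(df, Scale.raw_sn))
        pd.testing.assert_frame_equal(m.data, df)

    def test_double_total_halved(self):
        df = pd.DataFrame({"s1": [2.0, 2.0], "s2": [4.0, 4.0]}, index=["P1", "P2"])
        m = normalize_total(AbundanceMatrix(df, Scale.raw_sn))
        # mean total = 6; s2 (total 8) scaled by 6/8
        assert np.allclose(m.data["s2"], [3.0, 3.0])

    def test_totals_equal_after(self, rng):
        vals = rng.lognormal(size=(30, 6))
        vals[rng.random((30, 6)) < 0.1] = np.nan
        df = pd.DataFrame(vals, index=[f"P{i}" for i in range(30)],
                          columns=[f"s{j}" for j in range(6)])
        m = normalize_total(AbundanceMatrix(df, Scale.raw_sn))
        totals = m.data.sum(axis=0, skipna=True)
        assert np.allclose(totals, totals.iloc[0], rtol=1e-9)

    def test_all_missing_column_errors(self):
        df = pd.DataFrame({"s1": [1.0, 2.0], "s2": [np.nan, np.nan]}, index=["P1", "P2"])
        with pytest.raises(ValueError, match="s2"):
            normalize_total(AbundanceMatrix(df, Scale.raw_sn))


class TestReferenceRatios:
    def _matrix(self, design, meta, ref_vals=(2.0, 4.0)):
        cols = {m.sample_id: [2.0, 4.0] for m in meta}
        cols["A_ref"] = list(ref_vals)
        cols["B_ref"] = list(ref_vals)
        return AbundanceMatrix(pd.DataFrame(cols, index=["P1", "P2"]), Scale.raw_sn)

    def test_equal_to_reference_gives_one(self):
        design, meta = _tiny_design()
        m = to_reference_ratios(self._matrix(design, meta), design, meta)
        assert np.allclose(m.data.to_numpy(), 1.0)
        assert m.scale is Scale.ref_ratio
        assert "A_ref" not in m.data.columns

    def test_double_reference_gives_two(self):
        design, meta = _tiny_design()
        m = to_reference_ratios(self._matrix(design, meta, ref_vals=(1.0, 2.0)),
                                design, meta)
        assert np.allclose(m.data.to_numpy(), 2.0)

    def test_missing_reference_propagates(self):
        design, meta = _tiny_design()
        mat = self._matrix(design, meta)
        mat.data.loc["P1", "A_ref"] = np.nan
        m = to_reference_ratios(mat, design, meta)
        a_cols = [s.sample_id for s in meta if s.plex_id == "A"]
        assert m.data.loc["P1", a_cols].isna().all()
        assert m.data.loc["P2"].notna().all()

    def test_zero_reference_errors(self):
        design, meta = _tiny_design()
        mat = self._matrix(design, meta)
        mat.data.loc["P1", "A_ref"] = 0.0
        with pytest.raises(ValueError, match="P1"):
            to_reference_ratios(mat, design, meta)


class TestContaminantFilter:
    def test_removal_counts(self, small_cohort):
        matrix, *_ = small_cohort
        ann = [
            ProteinAnnotation(p, p, "keratin" if i < 2
                              else ("lipoprotein" if i == 2 else "none"))
            for i, p in enumerate(matrix.protein_ids)
        ]
        out, report = filter_contaminants(matrix, ann)
        assert report.n_removed_contaminant == 3
        assert len(out.protein_ids) == len(matrix.protein_ids) - 3
        assert report.n_input == report.n_retained + 3

    def test_no_contaminants_identity(self, small_cohort):
        matrix, *_ = small_cohort
        ann = [ProteinAnnotation(p, p) for p in matrix.protein_ids]
        out, report = filter_contaminants(matrix, ann)
        pd.testing.assert_frame_equal(out.data, matrix.data)
        assert report.n_removed_contaminant == 0

    def test_unannotated_protein_errors(self, small_cohort):
        matrix, *_ = small_cohort
        with pytest.raises(ValueError, match="unannotated"):
            filter_contaminants(matrix, [])


class TestDetectionFilter:
    def test_threshold_boundaries(self, small_cohort):
        matrix, meta, design, _, _ = small_cohort
        data = matrix.data.copy()
        samples_of = {}
        for m in meta:
            samples_of.setdefault(m.plex_id, []).append(m.sample_id)
        b1 = samples_of["P1c"] + samples_of["P1k"]
        b2 = samples_of["P2c"] + samples_of["P2k"]
        # PROT0001: missing in 2 of 4 blocks -> removed by block rule
        data.loc["PROT0001", b1 + b2] = np.nan
        # PROT0002: detected in all blocks but only ~70% of samples
        p2_missing = data.columns[: int(0.31 * len(data.columns))]
        data.loc["PROT0002", p2_missing] = np.nan
        # PROT0003: missing exactly one 2:3 block (3/4 blocks = 0.75 passes;
        # 51/66 samples = 77% also passes)
        b4 = samples_of["P4c"] + samples_of["P4k"]
        data.loc["PROT0003", b4] = np.nan
        m2 = AbundanceMatrix(data, matrix.scale)
        out, report = filter_detection(m2, meta, design)
        assert "PROT0001" not in out.protein_ids
        assert "PROT0002" not in out.protein_ids
        assert "PROT0003" in out.protein_ids
        assert report.n_removed_block_frac == 1
        assert report.n_removed_sample_frac == 1
        assert report.n_input == report.n_retained + 2

    def test_complete_matrix_fully_retained(self, small_cohort):
        matrix, meta, design, _, _ = small_cohort
        out, report = filter_detection(matrix, meta, design)
        assert out.protein_ids == matrix.protein_ids

    def test_filter_order_safe(self, small_cohort):
        # contaminants-then-detection equals detection restricted to
        # non-contaminants
        matrix, meta, design, _, _ = small_cohort
        data = matrix.data.copy()
        data.iloc[: 10, : 40] = np.nan
        m = AbundanceMatrix(data, matrix.scale)
        ann = [ProteinAnnotation(p, p, "keratin" if i % 7 == 0 else "none")
               for i, p in enumerate(m.protein_ids)]
        a1, _ = filter_contaminants(m, ann)
        a2, _ = filter_detection(a1, meta, design)
        b1, _ = filter_detection(m, meta, design)
        b2, _ = filter_contaminants(b1, ann)
        assert a2.protein_ids == b2.protein_ids


class TestImpute:
    def test_no_missing_identity_all_methods(self, small_cohort):
        matrix, meta, design, _, _ = small_cohort
        for method in ("forest", "knn", "column_median"):
            out = impute(matrix, meta, design, method=method, seed=1,
                         n_estimators=5, max_iter=2)
            pd.testing.assert_frame_equal(out.data, matrix.data)

    def test_column_median_fill(self):
        design, meta = _tiny_design()
        cols = {m.sample_id: [float(i + 1) for i in range(3)] for m in meta}
        df = pd.DataFrame(cols, index=["P1", "P2", "P3"])
        df.loc["P2", "c1_T0"] = np.nan
        out = impute(AbundanceMatrix(df, Scale.ref_ratio), meta, design,
                     method="column_median")
        # per-protein median of observed values (log2 scale -> geometric)
        assert out.data.loc["P2", "c1_T0"] == pytest.approx(2.0)

    def test_observed_values_bitwise_preserved(self, small_cohort):
        matrix, meta, design, _, truth = small_cohort
        holed = inject_block_missingness(matrix, meta, design, 0.15, 0.05, seed=2)
        for method in ("forest", "knn", "column_median"):
            out = impute(holed, meta, design, method=method, seed=3,
                         n_estimators=5, max_iter=2)
            a, b = holed.data.to_numpy(), out.data.to_numpy()
            obs = ~np.isnan(a)
            assert np.array_equal(a[obs], b[obs])
            assert not np.isnan(b).any()

    def test_all_missing_protein_errors(self, small_cohort):
        matrix, meta, design, _, _ = small_cohort
        data = matrix.data.copy()
        data.loc["PROT0001"] = np.nan
        with pytest.raises(ValueError, match="PROT0001"):
            impute(AbundanceMatrix(data, matrix.scale), meta, design,
                   method="column_median")


class TestMaskAndScore:
    def _correlated_matrix(self, meta, rho=0.9, n_proteins=25, seed=2):
        rng = np.random.default_rng(seed)
        n_s = len(meta)
        f = rng.normal(size=n_s)
        X = np.sqrt(rho) * f[:, None] + np.sqrt(1 - rho) * rng.normal(size=(n_s, n_proteins))
        df = pd.DataFrame(np.exp2(X.T), index=[f"P{i}" for i in range(n_proteins)],
                          columns=[m.sample_id for m in meta])
        return AbundanceMatrix(df, Scale.ref_ratio)

    def test_median_imputer_nrmse_near_one_on_iid(self, small_cohort, rng):
        _, meta, design, _, _ = small_cohort
        vals = rng.standard_normal((160, 66))
        df = pd.DataFrame(vals, index=[f"P{i}" for i in range(160)],
                          columns=[m.sample_id for m in meta])
        m = AbundanceMatrix(df, Scale.log2_ref_ratio)
        nrmse = mask_and_score(m, meta, design, frac=0.1, method="column_median",
                               seed=4)
        assert nrmse == pytest.approx(1.0, abs=0.1)

    def test_forest_beats_median_on_correlated_data(self, small_cohort):
        _, meta, design, _, _ = small_cohort
        m = self._correlated_matrix(meta)
        nf = mask_and_score(m, meta, design, 0.1, "forest", seed=1,
                            n_estimators=10, max_iter=3)
        nm = mask_and_score(m, meta, design, 0.1, "column_median", seed=1)
        assert nf < 1.0
        assert nf <= nm

    def test_invalid_fraction_rejected(self, small_cohort):
        matrix, meta, design, _, _ = small_cohort
        with pytest.raises(ValueError, match="frac"):
            mask_and_score(matrix, meta, design, 0.0, "column_median")
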