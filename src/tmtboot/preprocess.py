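"""Normalization, contaminant and detection filtering, and imputation.

The preprocessing chain for a raw multi-plex TMT dataset is

    normalize_total -> to_reference_ratios -> filter_contaminants
        -> filter_detection -> impute

Reference-ratio inputs (e.g. from the synthetic cohort) enter the chain at
the filtering stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd

from .types import (
    AbundanceMatrix,
    BlockDesign,
    ContaminantClass,
    ProteinAnnotation,
    SampleMeta,
    Scale,
)

__all__ = [
    "FilterReport",
    "normalize_total",
    "to_reference_ratios",
    "filter_contaminants",
    "filter_detection",
    "impute",
    "mask_and_score",
]


@dataclass
class FilterReport:
    n_input: int = 0
    n_removed_contaminant: int = 0
    n_removed_block_frac: int = 0
    n_removed_sample_frac: int = 0
    retained: list[str] = field(default_factory=list)
    #: per-protein (blocks detected, samples detected) counts
    detection_counts: dict[str, tuple[int, int]] = field(default_factory=dict)
    removed_contaminants: list[str] = field(default_factory=list)

    @property
    def n_retained(self) -> int:
        return len(self.retained)


def normalize_total(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Scale each sample so its non-missing total equals the mean total.

    The loading normalization for raw signal-to-noise data: differences in
    total peptide amount between channels are removed by equalizing column
    sums. The missing mask is untouched.
    """
    if matrix.scale is not Scale.raw_sn:
        raise ValueError(f"normalize_total expects raw_sn input, got {matrix.scale.value}")
    totals = matrix.data.sum(axis=0, skipna=True)
    empty = matrix.data.isna().all(axis=0)
    if empty.any():
        raise ValueError(
            f"sample(s) with no observed values: {list(matrix.data.columns[empty])}"
        )
    factors = totals.mean() / totals
    return AbundanceMatrix(matrix.data * factors, Scale.raw_sn)


def to_reference_ratios(matrix: AbundanceMatrix, design: BlockDesign,
                        meta: Sequence[SampleMeta]) -> AbundanceMatrix:
    """Divide each subject sample by its plex's pooled-reference column.

    The reference channel carries a mixture of all samples, so expressing
    each channel as a ratio to it puts all plexes on a comparable scale
    ("bridging"). Reference columns are dropped from the result; a ratio is
    missing whenever either operand is missing.
    """
    if matrix.scale is not Scale.raw_sn:
        raise ValueError(f"to_reference_ratios expects raw_sn input, got {matrix.scale.value}")
    ref_sample: dict[str, str] = {}
    for p in design.plexes:
        # the reference column is named "<plex>_ref" by convention, or found
        # via a metadata row occupying the reference channel
        cand = f"{p.plex_id}_ref"
        if cand in matrix.data.columns:
            ref_sample[p.plex_id] = cand
        else:
            raise ValueError(f"reference column for plex {p.plex_id!r} not found "
                             f"(expected {cand!r})")
    out = {}
    for m in meta:
        if m.sample_id not in matrix.data.columns:
            continue
        ref = matrix.data[ref_sample[m.plex_id]]
        num = matrix.data[m.sample_id]
        zero_ref = (ref == 0) & num.notna()
        if zero_ref.any():
            bad = matrix.data.index[zero_ref][0]
            raise ValueError(
                f"reference value 0 for detected protein {bad!r} in plex {m.plex_id!r}"
            )
        out[m.sample_id] = num / ref
    return AbundanceMatrix(pd.DataFrame(out, index=matrix.data.index), Scale.ref_ratio)


def filter_contaminants(
    matrix: AbundanceMatrix, annotations: Sequence[ProteinAnnotation]
) -> tuple[AbundanceMatrix, FilterReport]:
    """Drop lipoproteins and keratins — the standard EV-proteomics contaminants."""
    ann = {a.protein_id: a for a in annotations}
    missing = [p for p in matrix.protein_ids if p not in ann]
    if missing:
        raise ValueError(f"unannotated protein(s): {missing[:5]}")
    keep, removed = [], []
    for p in matrix.protein_ids:
        if ann[p].contaminant_class is ContaminantClass.none:
            keep.append(p)
        else:
            removed.append(p)
    report = FilterReport(
        n_input=len(matrix.protein_ids),
        n_removed_contaminant=len(removed),
        retained=keep,
        removed_contaminants=removed,
    )
    return AbundanceMatrix(matrix.data.loc[keep], matrix.scale), report


def filter_detection(
    matrix: AbundanceMatrix,
    meta: Sequence[SampleMeta],
    design: BlockDesign,
    min_block_frac: float = 0.75,
    min_sample_frac: float = 0.75,
) -> tuple[AbundanceMatrix, FilterReport]:
    """Keep proteins detected in >= 75% of TMT experiments and >= 75% of samples.

    A protein is "detected in an experiment" if at least one sample of that
    block observes it. Both fractions are compared with >= on exact rationals,
    so 3 of 4 blocks passes a 0.75 threshold exactly.
    """
    plex_to_block = {}
    for b in design.blocks:
        plex_to_block[b.case_plex_id] = b.block_id
        plex_to_block[b.control_plex_id] = b.block_id
    block_cols: dict[str, list[str]] = {b.block_id: [] for b in design.blocks}
    sample_cols = []
    for m in meta:
        if m.sample_id in matrix.data.columns and m.plex_id in plex_to_block:
            block_cols[plex_to_block[m.plex_id]].append(m.sample_id)
            sample_cols.append(m.sample_id)

    n_blocks = len(design.blocks)
    n_samples = len(sample_cols)
    present = matrix.data[sample_cols].notna()
    min_bf = Fraction(min_block_frac).limit_denominator(10**6)
    min_sf = Fraction(min_sample_frac).limit_denominator(10**6)

    report = FilterReport(n_input=len(matrix.protein_ids))
    keep = []
    for p in matrix.protein_ids:
        blocks_det = sum(
            1 for bid, cols in block_cols.items() if cols and present.loc[p, cols].any()
        )
        samples_det = int(present.loc[p].sum())
        report.detection_counts[p] = (blocks_det, samples_det)
        if Fraction(blocks_det, n_blocks) < min_bf:
            report.n_removed_block_frac += 1
        elif Fraction(samples_det, n_samples) < min_sf:
            report.n_removed_sample_frac += 1
        else:
            keep.append(p)
    report.retained = keep
    return AbundanceMatrix(matrix.data.loc[keep], matrix.scale), report


def _design_covariates(
    columns: Sequence[str], meta: Sequence[SampleMeta], design: BlockDesign
) -> pd.DataFrame:
    """One-hot group/timepoint/block covariates per sample (no missing values)."""
    plex_to_block = {}
    for b in design.blocks:
        plex_to_block[b.case_plex_id] = b.block_id
        plex_to_block[b.control_plex_id] = b.block_id
    bym = {m.sample_id: m for m in meta}
    rows = []
    for sid in columns:
        m = bym[sid]
        rows.append({
            "group": m.group.value,
            "timepoint": m.timepoint.value,
            "block": plex_to_block[m.plex_id],
        })
    cat = pd.DataFrame(rows, index=list(columns))
    return pd.get_dummies(cat, dtype=float)


def impute(
    matrix: AbundanceMatrix,
    meta: Sequence[SampleMeta],
    design: BlockDesign,
    method: str = "forest",
    seed: int = 0,
    max_iter: int = 10,
    n_estimators: int = 30,
) -> AbundanceMatrix:
    """Fill missing values; observed entries are never altered.

    ``forest`` runs iterative ensemble regression: samples are rows, each
    protein is regressed on all other proteins plus the group, time-point and
    block indicator covariates, sweeping until the change in imputed values
    stops decreasing (missForest-style stopping). ``knn`` and
    ``column_median`` are deterministic baselines.
    """
    if method not in ("forest", "knn", "column_median"):
        raise ValueError(f"unknown imputation method {method!r}")
    data = matrix.data
    never = data.isna().all(axis=1)
    if never.any():
        raise ValueError(
            f"protein(s) with zero observed values: {list(data.index[never])[:5]}"
        )
    if not data.isna().any().any():
        return matrix.copy()

    # work on log2 scale for ratio-like data so errors are symmetric
    log_scale = matrix.scale is not Scale.log2_ref_ratio
    X = np.log2(data.to_numpy(dtype=float).T) if log_scale else data.to_numpy(dtype=float).T
    # X: samples x proteins
    obs_mask = ~np.isnan(X)

    if method == "column_median":
        med = np.nanmedian(X, axis=0)
        filled = np.where(obs_mask, X, med[None, :])
    elif method == "knn":
        from sklearn.impute import KNNImputer

        filled = KNNImputer(n_neighbors=min(5, X.shape[0] - 1)).fit_transform(X)
    else:
        from sklearn.ensemble import ExtraTreesRegressor
        from sklearn.experimental import enable_iterative_imputer  # noqa: F401
        from sklearn.impute import IterativeImputer

        cov = _design_covariates(list(data.columns), meta, design).to_numpy()
        est = ExtraTreesRegressor(
            n_estimators=n_estimators,
            random_state=np.random.RandomState(seed % (2**31)), n_jobs=1,
        )
        imp = IterativeImputer(
            estimator=est, max_iter=max_iter, sample_posterior=False,
            initial_strategy="median", imputation_order="ascending",
            random_state=seed % (2**31), tol=1e-3, skip_complete=True,
        )
        full = np.hstack([X, cov])
        import warnings
        from sklearn.exceptions import ConvergenceWarning

        with warnings.catch_warnings():
            # the sweep is stopped by max_iter when the error plateaus; that
            # is the intended missForest-style behaviour, not a failure
            warnings.simplefilter("ignore", ConvergenceWarning)
            filled_full = imp.fit_transform(full)
        filled = filled_full[:, : X.shape[1]]

    filled = np.where(obs_mask, X, filled)  # observed values bit-identical
    out = np.exp2(filled).T if log_scale else filled.T
    out_df = pd.DataFrame(out, index=data.index, columns=data.columns)
    # restore observed cells exactly (avoid log/exp round-trip error)
    out_df = out_df.where(data.isna(), data)
    return AbundanceMatrix(out_df, matrix.scale)


def mask_and_score(
    matrix: AbundanceMatrix,
    meta: Sequence[SampleMeta],
    design: BlockDesign,
    frac: float,
    method: str = "forest",
    seed: int = 0,
    **impute_kwargs,
) -> float:
    """Mask a fraction of cells, impute, and return the NRMSE on masked cells.

    NRMSE = RMSE(imputed, true) / SD(true masked values), computed on the
    log2 scale for ratio-like data. A value near 0 means near-perfect
    recovery; 1 is the level of a constant (mean-type) imputer on
    structureless data.
    """
    if not (0 < frac < 1):
        raise ValueError(f"frac must be in (0, 1), got {frac}")
    if matrix.data.isna().any().any():
        raise ValueError("mask_and_score requires a complete matrix")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5C03]))
    data = matrix.data.to_numpy()
    mask = rng.random(data.shape) < frac
    # never mask an entire protein row
    for i in np.where(mask.all(axis=1))[0]:
        mask[i, rng.integers(data.shape[1])] = False
    holed = matrix.data.mask(pd.DataFrame(mask, index=matrix.data.index,
                                          columns=matrix.data.columns))
    imputed = impute(AbundanceMatrix(holed, matrix.scale), meta, design,
                     method=method, seed=seed, **impute_kwargs)
    log_scale = matrix.scale is not Scale.log2_ref_ratio
    truth = np.log2(data) if log_scale else data
    est = imputed.data.to_numpy()
    est = np.log2(est) if log_scale else est
    err = est[mask] - truth[mask]
    sd = truth[mask].std(ddof=0)
    if sd == 0:
        return 0.0 if np.allclose(err, 0) else float("inf")
    return float(np.sqrt(np.mean(err**2)) / sd)
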