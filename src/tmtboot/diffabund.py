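"""Between-group bootstrapped-median fold-change inference.

The comparability constraint of bridged multi-plex TMT — case and control
samples can only be compared within a block — shapes the whole procedure:

1. For a contrast (a time point, or a within-subject ratio of two time
   points), form every case x control pair difference of log2 quantities
   within each block (9 pairs for a 3:3 block, 6 for 2:3).
2. Bootstrap: per replicate, draw with replacement ``n_case(b)`` pair values
   from each block b (3 from 9, 2 from 6 in the default design), pool the
   draws across blocks, and record the pooled median; repeat B times
   (default 10,000).
3. The point estimate is the median of the bootstrap medians; a 95%
   nearest-rank percentile interval gives the nominal CI.
4. False-coverage-rate adjustment (the Benjamini-Yekutieli CI analogue of
   FDR): with R proteins whose nominal CI excludes 0 out of m tested, all
   CIs are re-cut at level 1 - R*q/m; a protein is differentially abundant
   if its adjusted CI still excludes 0.

Within-group change over time needs no bootstrap (all three time points of a
subject share one plex): the subject-level log2 fold changes are tested
against 0 with a one-sample t-test and BH adjustment.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import (
    AbundanceMatrix,
    BlockDesign,
    Group,
    SampleMeta,
    Scale,
    Timepoint,
)

__all__ = [
    "PairFoldChanges",
    "BootstrapCIResult",
    "WithinGroupTestResult",
    "timepoint_log2",
    "within_subject_log2fc",
    "between_group_pairs",
    "bootstrap_medians",
    "percentile_ci",
    "bootstrap_ci_table",
    "fcr_adjust",
    "within_group_mean_test",
    "bh_adjust",
    "by_adjust",
    "protein_rng",
]


@dataclass
class PairFoldChanges:
    """All case-control pair differences (log2) per block, for one protein."""

    protein_id: str
    contrast: str
    by_block: dict[str, np.ndarray]  # block_id -> pair differences
    k_by_block: dict[str, int]       # draws per block = n_case(block)

    @property
    def all_values(self) -> np.ndarray:
        return np.concatenate([self.by_block[b] for b in self.by_block])


@dataclass
class BootstrapCIResult:
    protein_id: str
    contrast: str
    median_log2fc: float
    ci_nominal: tuple[float, float]
    ci_adjusted: tuple[float, float]
    significant: bool
    B: int
    ci_level: float
    fcr_q: float
    boot_medians: np.ndarray | None = None


@dataclass
class WithinGroupTestResult:
    protein_id: str
    group: str
    contrast: str
    mean_log2fc: float
    t_stat: float
    p: float
    q_bh: float = float("nan")
    degenerate: bool = False


def protein_rng(seed: int, protein_id: str, stream: int = 0) -> np.random.Generator:
    """Per-protein RNG substream, independent of protein ordering.

    The substream key hashes the protein id (CRC-32), so adding, removing or
    reordering proteins never perturbs another protein's draws.
    """
    key = zlib.crc32(protein_id.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key, int(stream)]))


def _sample_of(meta: Sequence[SampleMeta]) -> dict[tuple[str, str], str]:
    return {(m.subject_id, m.timepoint.value): m.sample_id for m in meta}


def timepoint_log2(
    matrix: AbundanceMatrix, meta: Sequence[SampleMeta], timepoint: Timepoint | str
) -> pd.DataFrame:
    """Per-subject log2 reference ratio at one time point (proteins x subjects)."""
    tp = Timepoint(timepoint).value
    if matrix.scale is not Scale.ref_ratio:
        raise ValueError("expected ref_ratio scale")
    sample_of = _sample_of(meta)
    subjects = list(dict.fromkeys(m.subject_id for m in meta))
    cols = {}
    for s in subjects:
        sid = sample_of.get((s, tp))
        if sid is None or sid not in matrix.data.columns:
            raise ValueError(f"subject {s!r} has no sample at {tp}")
        cols[s] = np.log2(matrix.data[sid].to_numpy())
    return pd.DataFrame(cols, index=matrix.data.index)


def within_subject_log2fc(
    matrix: AbundanceMatrix,
    meta: Sequence[SampleMeta],
    t_num: Timepoint | str,
    t_den: Timepoint | str,
) -> pd.DataFrame:
    """log2(value at t_num / value at t_den) per subject (proteins x subjects).

    Both samples of a subject sit in the same plex, so the plex reference
    cancels exactly and no bridging is involved.
    """
    a = timepoint_log2(matrix, meta, t_num)
    b = timepoint_log2(matrix, meta, t_den)
    out = a - b
    if out.isna().any().any():
        bad = out.columns[out.isna().any(axis=0)][0]
        raise ValueError(f"missing values in fold change for subject {bad!r}; impute first")
    return out


def between_group_pairs(
    values_by_subject: pd.Series | dict[str, float],
    meta: Sequence[SampleMeta],
    design: BlockDesign,
    protein_id: str = "",
    contrast: str = "",
) -> PairFoldChanges:
    """All case-minus-control differences within each block.

    ``values_by_subject`` maps subject id to a log2 quantity (a reference
    ratio at one time point, or a within-subject log2 fold change). A 3:3
    block yields 9 values, a 2:3 block 6.
    """
    v = pd.Series(values_by_subject, dtype=float)
    groups = design.subjects_by_block(meta)
    by_block: dict[str, np.ndarray] = {}
    k: dict[str, int] = {}
    for bid, g in groups.items():
        cases = [s for s in g[Group.case] if s in v.index]
        ctrls = [s for s in g[Group.control] if s in v.index]
        if not cases or not ctrls:
            raise ValueError(f"block {bid!r} has no case or no control subjects")
        # order pairs by the unordered subject-id pair so the pair list keeps
        # its physical identity if case/control roles are exchanged
        pairs = sorted(
            ((tuple(sorted((c, k))), v[c] - v[k]) for c in cases for k in ctrls),
            key=lambda t: t[0],
        )
        diffs = np.array([d for _, d in pairs], dtype=float)
        if not np.all(np.isfinite(diffs)):
            raise ValueError(f"non-finite fold change in block {bid!r}")
        by_block[bid] = diffs
        k[bid] = len(cases)
    return PairFoldChanges(protein_id, contrast, by_block, k)


def bootstrap_medians(
    pairs: PairFoldChanges, B: int, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """B bootstrap medians of block-wise resampled pair fold changes.

    Per replicate: draw with replacement k_b values from each block's pair
    list (k_b = number of case subjects in that block), pool across blocks,
    take the median.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = (seed if isinstance(seed, np.random.Generator)
           else protein_rng(seed, pairs.protein_id))
    draws = []
    for bid, vals in pairs.by_block.items():
        k = pairs.k_by_block[bid]
        idx = rng.integers(0, len(vals), size=(B, k))
        draws.append(vals[idx])
    pooled = np.concatenate(draws, axis=1)
    return np.median(pooled, axis=1)


def percentile_ci(samples: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Nearest-rank percentile interval.

    With B sorted samples and alpha = 1 - level, the bounds are the order
    statistics at 1-based ranks ceil((alpha/2)*B) and ceil((1-alpha/2)*B).
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("empty sample vector")
    if not (0 < level < 1):
        raise ValueError(f"level must be in (0, 1), got {level}")
    s = np.sort(samples)
    B = s.size
    alpha = 1.0 - level
    # epsilon-guarded ceil so e.g. 0.025*1000 -> rank 25, not 26
    def _rank(q: float) -> int:
        return min(B, max(1, int(np.ceil(q * B - 1e-9))))
    lo_rank = _rank(alpha / 2)
    hi_rank = _rank(1 - alpha / 2)
    return float(s[lo_rank - 1]), float(s[hi_rank - 1])


def bootstrap_ci_table(
    pairs_by_protein: Sequence[PairFoldChanges],
    B: int = 10_000,
    ci_level: float = 0.95,
    fcr_q: float = 0.1,
    seed: int = 0,
    keep_boot: bool = False,
) -> list[BootstrapCIResult]:
    """Bootstrap every protein, cut nominal CIs, then FCR-adjust jointly."""
    results = []
    boots = []
    for pairs in pairs_by_protein:
        med = bootstrap_medians(pairs, B, seed=protein_rng(seed, pairs.protein_id))
        lo, hi = percentile_ci(med, ci_level)
        results.append(
            BootstrapCIResult(
                protein_id=pairs.protein_id, contrast=pairs.contrast,
                median_log2fc=float(np.median(med)),
                ci_nominal=(lo, hi), ci_adjusted=(lo, hi),
                significant=False, B=B, ci_level=ci_level, fcr_q=fcr_q,
                boot_medians=med,
            )
        )
        boots.append(med)
    results = fcr_adjust(results, q=fcr_q)
    if not keep_boot:
        for r in results:
            r.boot_medians = None
    return results


def fcr_adjust(results: list[BootstrapCIResult], q: float = 0.1) -> list[BootstrapCIResult]:
    """False-coverage-rate adjustment of the percentile CIs.

    Selection rule: the nominal CI excludes 0. With R selected of m tested,
    every CI is re-computed at level 1 - R*q/m (>= the nominal level, so
    adjusted CIs contain nominal ones); significance then requires the
    adjusted CI to exclude 0. R = 0 leaves all CIs nominal and nothing
    significant.
    """
    if not (0 < q < 1):
        raise ValueError(f"q must be in (0, 1), got {q}")
    m = len(results)
    if m == 0:
        return results
    R = sum(1 for r in results if r.ci_nominal[0] > 0 or r.ci_nominal[1] < 0)
    if R == 0:
        for r in results:
            r.ci_adjusted = r.ci_nominal
            r.significant = False
        return results
    adj_level = 1.0 - R * q / m
    for r in results:
        if r.boot_medians is None:
            raise ValueError("fcr_adjust needs the bootstrap samples (keep_boot)")
        r.ci_adjusted = percentile_ci(r.boot_medians, adj_level)
        r.significant = r.ci_adjusted[0] > 0 or r.ci_adjusted[1] < 0
    return results


def within_group_mean_test(
    fcs: pd.DataFrame,
    meta: Sequence[SampleMeta],
    group: Group | str,
    contrast: str = "",
) -> list[WithinGroupTestResult]:
    """One-sample t-test of subject log2 fold changes against 0, per protein.

    Log2 of a ratio of 1 is 0, so testing the mean log2 fold change against 0
    is the symmetric form of testing the mean ratio against 1. Zero-variance
    proteins are flagged degenerate (p = 1 when the mean is also 0, else
    p = 0).
    """
    group = Group(group)
    subjects = [s for s in fcs.columns
                if any(m.subject_id == s and m.group is group for m in meta)]
    if len(subjects) < 2:
        raise ValueError(f"need >= 2 subjects in group {group.value}")
    sub = fcs[subjects]
    results = []
    for p in sub.index:
        x = sub.loc[p].to_numpy(dtype=float)
        mean = float(x.mean())
        sd = float(x.std(ddof=1))
        if sd == 0.0:
            degenerate = True
            if mean == 0.0:
                t, pval = float("nan"), 1.0
            else:
                t, pval = float("inf") if mean > 0 else float("-inf"), 0.0
        else:
            degenerate = False
            t, pval = stats.ttest_1samp(x, 0.0)
            t, pval = float(t), float(pval)
        results.append(
            WithinGroupTestResult(
                protein_id=p, group=group.value, contrast=contrast,
                mean_log2fc=mean, t_stat=t, p=pval, degenerate=degenerate,
            )
        )
    qs = bh_adjust(np.array([r.p for r in results]))
    for r, qv in zip(results, qs):
        r.q_bh = float(qv)
    return results


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in input order."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def by_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Yekutieli q-values: BH times the harmonic penalty c(m)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    c_m = np.sum(1.0 / np.arange(1, m + 1))
    return np.minimum(bh_adjust(p) * c_m, 1.0)


def results_frame(results: Sequence[BootstrapCIResult]) -> pd.DataFrame:
    """Flatten bootstrap CI results to a tidy table."""
    return pd.DataFrame(
        [
            {
                "protein_id": r.protein_id, "contrast": r.contrast,
                "median_log2fc": r.median_log2fc,
                "ci_lo": r.ci_nominal[0], "ci_hi": r.ci_nominal[1],
                "ci_adj_lo": r.ci_adjusted[0], "ci_adj_hi": r.ci_adjusted[1],
                "significant": r.significant,
            }
            for r in results
        ]
    )


def within_results_frame(results: Sequence[WithinGroupTestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "protein_id": r.protein_id, "group": r.group, "contrast": r.contrast,
                "mean_log2fc": r.mean_log2fc, "t_stat": r.t_stat,
                "p": r.p, "q_bh": r.q_bh, "degenerate": r.degenerate,
            }
            for r in results
        ]
    )
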