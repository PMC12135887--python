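"""Clinical association screening and cohort summary tests.

* :func:`screen_correlations` — per group, Spearman correlation of each
  protein's within-subject fold change against each clinical parameter, with
  2000-resample percentile bootstrap CIs, tail-count p-values, BH adjustment
  within each parameter, and the |rho| > 0.8 & q < 0.1 "significant and
  strong" rule.
* :func:`delta_sss` — symptom-score change, 24 h minus 0 h post-exercise
  (positive = worse; the post-exertional-malaise readout).
* :func:`welch_t_from_summary` — Welch's t-test from printed mean/SD/n
  summaries (the cohort-table comparisons).
* :func:`rank_tests` — Wilcoxon rank-sum / signed-rank for the particle
  size and concentration comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .diffabund import bh_adjust, percentile_ci, protein_rng
from .types import AnalysisConfig, Group, SSS_SYMPTOMS

__all__ = [
    "CorrelationResult",
    "RankTestResult",
    "delta_sss",
    "spearman_rho",
    "spearman_bootstrap",
    "screen_correlations",
    "welch_t_from_summary",
    "rank_tests",
]


@dataclass
class CorrelationResult:
    protein_id: str
    contrast: str
    parameter: str
    group: str
    rho: float
    ci: tuple[float, float]
    p_boot: float
    q_bh: float = float("nan")
    n: int = 0
    passes_rule: bool = False


@dataclass
class RankTestResult:
    p: float
    statistic: float
    degenerate: bool = False


def delta_sss(clinical: pd.DataFrame) -> pd.DataFrame:
    """Per-subject symptom-score change: 24 h minus 0 h, one column per symptom.

    Negative deltas mean the symptom improved after exercise; positive means
    it worsened (post-exertional malaise). Subjects missing either score for
    a symptom get NaN there, with a warning.
    """
    out = pd.DataFrame({"subject_id": clinical["subject_id"]})
    for sym in SSS_SYMPTOMS:
        c0, c24 = f"sss_0h_{sym}", f"sss_24h_{sym}"
        if c0 not in clinical.columns or c24 not in clinical.columns:
            continue
        d = clinical[c24] - clinical[c0]
        if d.isna().any():
            bad = clinical.loc[d.isna(), "subject_id"].tolist()
            warnings.warn(f"missing SSS scores for {sym}: subjects {bad}", stacklevel=2)
        out[f"delta_{sym}"] = d
    return out.set_index("subject_id")


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (average ranks for ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if rx.std() == 0 or ry.std() == 0:
        raise ValueError("zero rank variance: correlation undefined")
    return float(np.corrcoef(rx, ry)[0, 1])


def _rho_rows(xb: np.ndarray, yb: np.ndarray) -> np.ndarray:
    """Row-wise Spearman over resample matrices; NaN where degenerate."""
    rx = stats.rankdata(xb, axis=1)
    ry = stats.rankdata(yb, axis=1)
    rx = rx - rx.mean(axis=1, keepdims=True)
    ry = ry - ry.mean(axis=1, keepdims=True)
    sx = np.sqrt((rx**2).sum(axis=1))
    sy = np.sqrt((ry**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.clip((rx * ry).sum(axis=1) / (sx * sy), -1.0, 1.0)
    # identical rank patterns are exactly +/-1; snap float-summation residue
    rho[np.abs(rho) > 1 - 1e-12] = np.sign(rho[np.abs(rho) > 1 - 1e-12])
    rho[(sx == 0) | (sy == 0)] = np.nan
    return rho


def spearman_bootstrap(
    x: Sequence[float],
    y: Sequence[float],
    B: int = 2000,
    seed: int | np.random.Generator = 0,
    ci_level: float = 0.95,
) -> tuple[float, tuple[float, float], float]:
    """Pairs bootstrap of the Spearman coefficient.

    Resamples (x_i, y_i) pairs with replacement B times (degenerate
    replicates with zero rank variance are redrawn), cuts a nearest-rank
    percentile CI, and computes a two-sided tail-count p-value for rho = 0
    with add-one smoothing. Returns (rho, (lo, hi), p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 5:
        raise ValueError(f"need n >= 5 for the bootstrap, got {n}")
    rho = spearman_rho(x, y)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = np.empty(0)
    while out.size < B:
        need = B - out.size
        idx = rng.integers(0, n, size=(max(need, 64), n))
        rb = _rho_rows(x[idx], y[idx])
        out = np.concatenate([out, rb[~np.isnan(rb)][:need]])
    ci = percentile_ci(out, ci_level)
    n_le = int(np.sum(out <= 0))
    n_ge = int(np.sum(out >= 0))
    p = min(1.0, 2.0 * (1 + min(n_le, n_ge)) / (B + 1))
    return rho, ci, p


def screen_correlations(
    fc: pd.DataFrame,
    clinical: pd.DataFrame,
    group: Group | str,
    config: AnalysisConfig | None = None,
    parameters: Sequence[str] | None = None,
    contrast: str = "",
) -> list[CorrelationResult]:
    """Bootstrap-Spearman screen of protein fold changes vs clinical parameters.

    ``fc`` is proteins x subjects (log2 fold changes of one contrast);
    ``clinical`` must carry ``subject_id`` and ``group`` columns. Run
    separately per group. BH adjustment is within each parameter across
    proteins; ``passes_rule`` marks |rho| > r_min and q < corr_q.
    Parameters constant across the group's subjects are excluded with a
    warning.
    """
    config = config or AnalysisConfig()
    group = Group(group)
    clin = clinical.loc[clinical["group"] == group.value]
    subjects = [s for s in fc.columns if s in set(clin["subject_id"])]
    if len(subjects) < 5:
        raise ValueError(f"group {group.value}: need >= 5 subjects, have {len(subjects)}")
    clin = clin.set_index("subject_id").loc[subjects]
    if parameters is None:
        parameters = [
            c for c in clin.columns
            if c != "group" and pd.api.types.is_numeric_dtype(clin[c])
        ]

    results: list[CorrelationResult] = []
    for param in parameters:
        yv = clin[param].to_numpy(dtype=float)
        if np.isnan(yv).any():
            warnings.warn(f"parameter {param!r}: missing values, skipped", stacklevel=2)
            continue
        if np.unique(yv).size < 2:
            warnings.warn(f"parameter {param!r} constant in group {group.value}; "
                          "excluded", stacklevel=2)
            continue
        block: list[CorrelationResult] = []
        for pid in fc.index:
            xv = fc.loc[pid, subjects].to_numpy(dtype=float)
            rng = protein_rng(config.seed, f"{pid}|{param}|{contrast}", stream=2)
            rho, ci, p = spearman_bootstrap(xv, yv, B=config.B_corr, seed=rng,
                                            ci_level=config.ci_level)
            block.append(
                CorrelationResult(
                    protein_id=pid, contrast=contrast, parameter=param,
                    group=group.value, rho=rho, ci=ci, p_boot=p, n=len(subjects),
                )
            )
        qs = bh_adjust(np.array([r.p_boot for r in block]))
        for r, q in zip(block, qs):
            r.q_bh = float(q)
            r.passes_rule = abs(r.rho) > config.r_min and r.q_bh < config.corr_q
        results.extend(block)
    return results


def correlations_frame(results: Sequence[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"protein_id": r.protein_id, "contrast": r.contrast,
             "parameter": r.parameter, "group": r.group, "rho": r.rho,
             "ci_lo": r.ci[0], "ci_hi": r.ci[1], "p_boot": r.p_boot,
             "q_bh": r.q_bh, "n": r.n, "passes_rule": r.passes_rule}
            for r in results
        ]
    )


def welch_t_from_summary(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test from summary statistics.

    Returns (t, Welch-Satterthwaite df, two-sided p).
    """
    if s1 <= 0 or s2 <= 0:
        raise ValueError("standard deviations must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    v1, v2 = s1**2 / n1, s2**2 / n2
    t = (m1 - m2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def rank_tests(x: Sequence[float], y: Sequence[float], paired: bool) -> RankTestResult:
    """Wilcoxon rank-sum (unpaired) or signed-rank (paired) two-sided test.

    Uses the exact null distribution for small samples (combined n <= 25, no
    ties) and the tie-corrected normal approximation otherwise. Paired mode
    drops zero differences; all-zero differences give p = 1 with a flag.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired:
        if x.size != y.size:
            raise ValueError("paired test needs equal-length samples")
        d = x - y
        nz = d[d != 0]
        if nz.size == 0:
            return RankTestResult(p=1.0, statistic=0.0, degenerate=True)
        method = "exact" if (nz.size <= 25 and np.unique(np.abs(nz)).size == nz.size) \
            else "approx"
        res = stats.wilcoxon(x, y, zero_method="wilcox", correction=False,
                             alternative="two-sided", method=method)
        return RankTestResult(p=float(res.pvalue), statistic=float(res.statistic))
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    exact = (x.size + y.size <= 25) and np.unique(pooled).size == pooled.size
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="exact" if exact else "asymptotic",
                             use_continuity=False)
    return RankTestResult(p=float(res.pvalue), statistic=float(res.statistic))
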