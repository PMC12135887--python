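"""Synthetic cohort generator.

Emulates the study's exact multi-plex design: four TMT experiments (blocks),
each bridging one case plex and one control plex through a pooled-reference
channel, with case:control compositions 3:3, 3:3, 2:3, 2:3 (10 cases, 12
controls), three time points per subject (pre-exercise, 15 min and 24 h
post-exercise), log-normal abundances with subject random effects, optional
group-by-time effects on chosen proteins, block-structured missingness, and
clinical covariates rank-linked to chosen protein fold changes.

The generative model on the log2 scale is

    y[p, s, t] = mu_p + u_s + delta[p, g(s), t] + eps[p, s, t]

with ``u_s ~ N(0, subject_sd^2)`` and ``eps ~ N(0, residual_sd^2)``. The
reference channel of a plex carries, per protein, the mean of the plex's
baseline generative means (mu_p + u_s), so dividing by it cancels subject
and baseline structure exactly and a noise-free cohort returns planted
effects without bias. Output values are sample/reference ratios (linear
scale, ``ref_ratio``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import (
    AbundanceMatrix,
    Block,
    BlockDesign,
    Group,
    Plex,
    SampleMeta,
    Scale,
    Timepoint,
    TIMEPOINT_ORDER,
    SSS_SYMPTOMS,
)

__all__ = [
    "SimulationConfig",
    "Effect",
    "ClinicalLink",
    "SimulationTruth",
    "simulate_cohort",
    "inject_block_missingness",
    "link_clinical_covariates",
]

#: Default block compositions: (n_case, n_control) per TMT experiment.
DEFAULT_BLOCKS: tuple[tuple[int, int], ...] = ((3, 3), (3, 3), (2, 3), (2, 3))

CONTRASTS = ("T0", "T15m", "T24h", "T15m/T0", "T24h/T0", "T24h/T15m")


@dataclass(frozen=True)
class Effect:
    """A planted group-by-time effect.

    ``contrast`` is either a time point (cases shifted by ``delta`` log2 units
    at that time point) or a ratio like ``"T15m/T0"`` (cases shifted at the
    numerator time point, so the within-subject ratio changes by ``delta``).
    """

    protein_id: str
    contrast: str
    delta: float

    def __post_init__(self) -> None:
        if self.contrast not in CONTRASTS:
            raise ValueError(f"unknown contrast {self.contrast!r}")


@dataclass(frozen=True)
class ClinicalLink:
    """Rank-correlate a clinical covariate with a protein's fold change."""

    covariate: str
    protein_id: str
    contrast: str  # ratio contrast, e.g. "T24h/T0"
    target_rho: float
    group: Group = Group.case

    def __post_init__(self) -> None:
        if abs(self.target_rho) > 1:
            raise ValueError(f"|target_rho| must be <= 1, got {self.target_rho}")
        if self.contrast not in CONTRASTS:
            raise ValueError(f"unknown contrast {self.contrast!r}")
        object.__setattr__(self, "group", Group(self.group))


@dataclass
class SimulationConfig:
    """Cohort-level generative parameters (log2 scale throughout)."""

    n_proteins: int = 500
    blocks: tuple[tuple[int, int], ...] = DEFAULT_BLOCKS
    baseline_mean: float = 7.0   # grand mean log2 abundance
    baseline_sd: float = 1.5     # protein-to-protein spread of mu_p
    subject_sd: float = 0.25     # subject random effect SD
    residual_sd: float = 0.3     # within-subject residual SD
    effects: tuple[Effect, ...] = ()
    links: tuple[ClinicalLink, ...] = ()

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        for i, (nc, nk) in enumerate(self.blocks):
            if nc < 1 or nk < 1:
                raise ValueError(f"block {i}: needs >= 1 case and >= 1 control subject")
        for sd in (self.baseline_sd, self.subject_sd, self.residual_sd):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")
        self.effects = tuple(self.effects)
        self.links = tuple(self.links)


@dataclass
class SimulationTruth:
    """Ground truth of a simulated cohort, for recovery tests."""

    baseline: pd.Series                 # mu_p per protein
    subject_effects: pd.Series          # u_s per subject
    subject_sd: float
    residual_sd: float
    effects: tuple[Effect, ...]
    case_offsets: pd.DataFrame          # protein x timepoint log2 offsets for cases
    links: tuple[ClinicalLink, ...]
    block_missing: pd.DataFrame | None = None  # protein x block_id boolean
    cell_missing: pd.DataFrame | None = None   # protein x sample boolean

    def planted_proteins(self) -> list[str]:
        return sorted({e.protein_id for e in self.effects})


def _case_offsets(config: SimulationConfig, protein_ids: Sequence[str]) -> pd.DataFrame:
    off = pd.DataFrame(
        0.0, index=list(protein_ids), columns=[t.value for t in TIMEPOINT_ORDER]
    )
    for e in config.effects:
        if e.protein_id not in off.index:
            raise ValueError(f"effect names unknown protein {e.protein_id!r}")
        tp = e.contrast.split("/")[0]  # ratio effects act on the numerator time point
        off.loc[e.protein_id, tp] += e.delta
    return off


def _build_layout(config: SimulationConfig) -> tuple[list[SampleMeta], BlockDesign]:
    meta: list[SampleMeta] = []
    plexes: list[Plex] = []
    blocks: list[Block] = []
    case_i = ctrl_i = 0
    # 10-plex channel names; last channel is the pooled reference
    channels = ["126", "127N", "127C", "128N", "128C", "129N", "129C", "130N", "130C"]
    ref_channel = "131"
    for b, (n_case, n_ctrl) in enumerate(config.blocks, start=1):
        bid = f"B{b}"
        for group, n in ((Group.case, n_case), (Group.control, n_ctrl)):
            tag = "case" if group is Group.case else "ctrl"
            plex_id = f"P{b}{'c' if group is Group.case else 'k'}"
            plexes.append(Plex(plex_id, group, ref_channel))
            ch = iter(channels)
            for _ in range(n):
                if group is Group.case:
                    case_i += 1
                    subj = f"case{case_i:02d}"
                else:
                    ctrl_i += 1
                    subj = f"ctrl{ctrl_i:02d}"
                for t in TIMEPOINT_ORDER:
                    meta.append(
                        SampleMeta(
                            sample_id=f"{subj}_{t.value}",
                            subject_id=subj,
                            group=group,
                            timepoint=t,
                            plex_id=plex_id,
                            channel=next(ch),
                        )
                    )
        blocks.append(Block(bid, f"P{b}c", f"P{b}k"))
    return meta, BlockDesign(plexes, blocks)


def simulate_cohort(
    config: SimulationConfig | None = None,
    seed: int = 0,
) -> tuple[AbundanceMatrix, list[SampleMeta], BlockDesign, pd.DataFrame, SimulationTruth]:
    """Generate one synthetic cohort.

    Returns the reference-ratio abundance matrix, the sample metadata, the
    block design, a clinical table (one row per subject) and the ground
    truth. Identical ``config`` and ``seed`` give bit-identical outputs.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EED]))

    meta, design = _build_layout(config)
    protein_ids = [f"PROT{i:04d}" for i in range(1, config.n_proteins + 1)]
    subjects = list(dict.fromkeys(m.subject_id for m in meta))

    mu = pd.Series(
        rng.normal(config.baseline_mean, config.baseline_sd, config.n_proteins),
        index=protein_ids, name="baseline",
    )
    u = pd.Series(
        rng.normal(0.0, config.subject_sd, len(subjects)), index=subjects, name="u"
    )
    offsets = _case_offsets(config, protein_ids)

    # per-plex reference: mean over the plex's subjects of (mu_p + u_s)
    subj_plex = {m.subject_id: m.plex_id for m in meta}
    plex_subjects: dict[str, list[str]] = {}
    for s in subjects:
        plex_subjects.setdefault(subj_plex[s], []).append(s)
    ref_log2 = {
        pid: mu.to_numpy() + np.mean([u[s] for s in ss])
        for pid, ss in plex_subjects.items()
    }

    cols = {}
    for m in meta:
        y = mu.to_numpy() + u[m.subject_id]
        if m.group is Group.case:
            y = y + offsets[m.timepoint.value].to_numpy()
        y = y + rng.normal(0.0, config.residual_sd, config.n_proteins)
        cols[m.sample_id] = np.exp2(y - ref_log2[m.plex_id])
    matrix = AbundanceMatrix(
        pd.DataFrame(cols, index=protein_ids), Scale.ref_ratio
    )

    truth = SimulationTruth(
        baseline=mu, subject_effects=u, subject_sd=config.subject_sd,
        residual_sd=config.residual_sd, effects=config.effects,
        case_offsets=offsets, links=config.links,
    )
    clinical = _clinical_shell(meta, rng)
    if config.links:
        clinical = link_clinical_covariates(
            matrix, meta, truth, clinical, seed=int(rng.integers(2**31))
        )
    return matrix, meta, design, clinical, truth


# marginal distributions of the unlinked clinical covariates; location/scale
# follow the cohort's published summary table, ranges are clipped to the
# instrument's bounds
_CLIN_NORMALS = {
    # covariate: (case_mean, case_sd, ctrl_mean, ctrl_sd, lo, hi)
    "bell_scale": (38.7, 16.7, 94.2, 6.7, 10, 100),
    "sf36_pcs": (28.7, 7.3, 55.9, 6.1, 11, 64),
    "sf36_mcs": (45.7, 6.5, 55.6, 5.9, 11, 64),
    "sf36_gh": (35.0, 9.0, 70.0, 9.0, 0, 100),
    "vo2peak": (22.6, 4.9, 24.6, 5.6, 5, 60),
    "vat": (10.8, 2.9, 13.2, 3.4, 3, 40),
    "age": (46.4, 7.7, 44.5, 12.8, 18, 80),
    "bmi": (29.7, 3.6, 27.0, 3.7, 15, 50),
}


def _clinical_shell(meta: Sequence[SampleMeta], rng: np.random.Generator) -> pd.DataFrame:
    subjects: dict[str, Group] = {}
    for m in meta:
        subjects.setdefault(m.subject_id, m.group)
    rows = []
    for subj, grp in subjects.items():
        is_case = grp is Group.case
        row: dict = {"subject_id": subj, "group": grp.value}
        for cov, (cm, cs, km, ks, lo, hi) in _CLIN_NORMALS.items():
            mean, sd = (cm, cs) if is_case else (km, ks)
            row[cov] = float(np.clip(rng.normal(mean, sd), lo, hi))
        row["pct_time_reclined"] = float(
            np.clip(rng.normal(0.45 if is_case else 0.10, 0.15), 0, 1)
        )
        row["mfi_total"] = (
            float(np.clip(rng.normal(78.9, 10.1), 20, 100)) if is_case else np.nan
        )
        row["illness_duration"] = (
            float(np.clip(rng.gamma(2.0, 8.0), 3, 36)) if is_case else np.nan
        )
        for sym in SSS_SYMPTOMS:
            base = int(np.clip(rng.poisson(4 if is_case else 1), 0, 10))
            worsen = int(rng.poisson(2)) if is_case else int(rng.poisson(0.3))
            row[f"sss_0h_{sym}"] = base
            row[f"sss_24h_{sym}"] = int(np.clip(base + worsen, 0, 10))
        rows.append(row)
    return pd.DataFrame(rows)


def inject_block_missingness(
    matrix: AbundanceMatrix,
    meta: Sequence[SampleMeta],
    design: BlockDesign,
    p_block_missing: float,
    p_cell_missing: float = 0.0,
    seed: int = 0,
    truth: SimulationTruth | None = None,
) -> AbundanceMatrix:
    """Mask whole protein-by-block stripes, plus independent cell dropout.

    With probability ``p_block_missing`` a protein is masked in *all* samples
    of a block (the protein was never identified in that TMT run — the
    dominant missingness pattern in multi-plex TMT). Independently, each
    remaining cell is masked with probability ``p_cell_missing``.
    """
    for p, name in ((p_block_missing, "p_block_missing"), (p_cell_missing, "p_cell_missing")):
        if not (0 <= p <= 1):
            raise ValueError(f"{name} must be in [0, 1], got {p}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xB10C]))
    data = matrix.data.copy()

    block_samples: dict[str, list[str]] = {b.block_id: [] for b in design.blocks}
    plex_to_block = {}
    for b in design.blocks:
        plex_to_block[b.case_plex_id] = b.block_id
        plex_to_block[b.control_plex_id] = b.block_id
    for m in meta:
        if m.plex_id in plex_to_block and m.sample_id in data.columns:
            block_samples[plex_to_block[m.plex_id]].append(m.sample_id)

    block_ids = [b.block_id for b in design.blocks]
    block_mask = pd.DataFrame(
        rng.random((len(data.index), len(block_ids))) < p_block_missing,
        index=data.index, columns=block_ids,
    )
    for bid in block_ids:
        cols = block_samples[bid]
        if cols:
            data.loc[block_mask[bid], cols] = np.nan

    cell_mask = pd.DataFrame(
        rng.random(data.shape) < p_cell_missing,
        index=data.index, columns=data.columns,
    )
    data[cell_mask] = np.nan

    if truth is not None:
        truth.block_missing = block_mask
        truth.cell_missing = cell_mask
    return AbundanceMatrix(data, matrix.scale)


def link_clinical_covariates(
    matrix: AbundanceMatrix,
    meta: Sequence[SampleMeta],
    truth: SimulationTruth,
    clinical: pd.DataFrame,
    seed: int = 0,
) -> pd.DataFrame:
    """Regenerate linked covariates with a Gaussian copula against realized FCs.

    For each link, the linked group's covariate is drawn so that the
    population Spearman correlation with the subject-level realized log2
    fold change equals ``target_rho`` (latent Pearson ``2 sin(pi*rho/6)``).
    A monotone marginal transform then maps the latent normal onto the
    covariate's scale, so the rank correlation is preserved; symptom-score
    covariates are binned to integers 0-10, which introduces realistic ties.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC114]))
    clinical = clinical.copy()
    sample_of = {(m.subject_id, m.timepoint.value): m.sample_id for m in meta}
    group_of = {m.subject_id: m.group for m in meta}

    for link in truth.links:
        subjects = [s for s in clinical["subject_id"] if group_of[s] is link.group]
        if "/" in link.contrast:
            t_num, t_den = link.contrast.split("/")
            f = np.array([
                np.log2(matrix.data.loc[link.protein_id, sample_of[(s, t_num)]])
                - np.log2(matrix.data.loc[link.protein_id, sample_of[(s, t_den)]])
                for s in subjects
            ])
        else:
            f = np.array([
                np.log2(matrix.data.loc[link.protein_id, sample_of[(s, link.contrast)]])
                for s in subjects
            ])
        n = len(f)
        # latent normal scores of the realized fold changes (rank-preserving)
        ranks = stats.rankdata(f, method="average")
        z = stats.norm.ppf((ranks - 0.5) / n)
        r_lat = 2.0 * np.sin(np.pi * link.target_rho / 6.0)
        w = r_lat * z + np.sqrt(max(0.0, 1.0 - r_lat**2)) * rng.standard_normal(n)
        uq = stats.norm.cdf(w)
        values = _marginal_transform(link.covariate, uq, link.group)
        idx = clinical["subject_id"].isin(subjects)
        order = {s: i for i, s in enumerate(subjects)}
        clinical.loc[idx, link.covariate] = [
            values[order[s]] for s in clinical.loc[idx, "subject_id"]
        ]
    return clinical


def _marginal_transform(covariate: str, uq: np.ndarray, group: Group) -> np.ndarray:
    """Map copula uniforms onto a covariate's marginal scale (monotone)."""
    if covariate.startswith("sss_"):
        return np.clip(np.floor(uq * 11).astype(int), 0, 10)
    if covariate in _CLIN_NORMALS:
        cm, cs, km, ks, lo, hi = _CLIN_NORMALS[covariate]
        mean, sd = (cm, cs) if group is Group.case else (km, ks)
        return np.clip(stats.norm.ppf(uq, loc=mean, scale=sd), lo, hi)
    if covariate == "pct_time_reclined":
        return uq
    if covariate == "mfi_total":
        return np.clip(stats.norm.ppf(uq, loc=78.9, scale=10.1), 20, 100)
    if covariate == "illness_duration":
        return np.clip(stats.gamma.ppf(uq, a=2.0, scale=8.0), 3, 36)
    raise ValueError(f"unknown covariate {covariate!r}")
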