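"""Domain types shared by every analysis stage.

The central objects are thin, validated wrappers around pandas structures:

* :class:`AbundanceMatrix` — proteins x samples quantitation with an explicit
  missing mask (NaN) and a declared scale (``raw_sn``, ``ref_ratio`` or
  ``log2_ref_ratio``).
* :class:`SampleMeta` / :class:`BlockDesign` — the multi-plex layout: which
  subject/timepoint sits in which TMT plex, and which case plex is bridged to
  which control plex through the pooled reference channel.
* :class:`ClinicalTable` columns — per-subject phenotype and exercise data.
* :class:`GeneSetCollection` — named gene sets (GMT semantics).
* :class:`AnalysisConfig` — every statistical knob of the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Group",
    "Timepoint",
    "Scale",
    "SampleMeta",
    "Plex",
    "Block",
    "BlockDesign",
    "AbundanceMatrix",
    "ProteinAnnotation",
    "ContaminantClass",
    "GeneSet",
    "GeneSetCollection",
    "AnalysisConfig",
    "CLINICAL_COLUMNS",
    "SSS_SYMPTOMS",
]


class Group(str, Enum):
    case = "case"
    control = "control"


class Timepoint(str, Enum):
    """Sampling times around the maximal exercise challenge."""

    T0 = "T0"      # pre-exercise baseline
    T15m = "T15m"  # 15 minutes post-exercise
    T24h = "T24h"  # 24 hours post-exercise


TIMEPOINT_ORDER = (Timepoint.T0, Timepoint.T15m, Timepoint.T24h)

#: The six default contrasts: per-timepoint group comparisons and
#: within-subject ratios over time.
RATIO_CONTRASTS = (
    (Timepoint.T15m, Timepoint.T0),
    (Timepoint.T24h, Timepoint.T0),
    (Timepoint.T24h, Timepoint.T15m),
)


class Scale(str, Enum):
    raw_sn = "raw_sn"                  # reporter-ion signal-to-noise
    ref_ratio = "ref_ratio"            # sample / pooled-reference ratio
    log2_ref_ratio = "log2_ref_ratio"  # log2 of the above


class ContaminantClass(str, Enum):
    none = "none"
    lipoprotein = "lipoprotein"
    keratin = "keratin"


@dataclass(frozen=True)
class SampleMeta:
    """One physical sample: a subject at a time point in a TMT channel."""

    sample_id: str
    subject_id: str
    group: Group
    timepoint: Timepoint
    plex_id: str
    channel: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "group", Group(self.group))
        object.__setattr__(self, "timepoint", Timepoint(self.timepoint))


def meta_frame(meta: Sequence[SampleMeta]) -> pd.DataFrame:
    """Tabular view of a sample-metadata list (one row per sample)."""
    return pd.DataFrame(
        [
            {
                "sample_id": m.sample_id,
                "subject_id": m.subject_id,
                "group": m.group.value,
                "timepoint": m.timepoint.value,
                "plex_id": m.plex_id,
                "channel": m.channel,
            }
            for m in meta
        ]
    )


@dataclass(frozen=True)
class Plex:
    plex_id: str
    group: Group
    reference_channel: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "group", Group(self.group))


@dataclass(frozen=True)
class Block:
    """A case plex bridged to a control plex via the pooled reference.

    All case:control fold changes are formed within a block; nothing is ever
    compared across blocks except through the bootstrap pooling.
    """

    block_id: str
    case_plex_id: str
    control_plex_id: str


@dataclass
class BlockDesign:
    plexes: list[Plex]
    blocks: list[Block]

    def __post_init__(self) -> None:
        ids = [p.plex_id for p in self.plexes]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate plex_id in design")
        bids = [b.block_id for b in self.blocks]
        if len(bids) != len(set(bids)):
            raise ValueError("duplicate block_id in design")
        used: list[str] = []
        for b in self.blocks:
            used.extend([b.case_plex_id, b.control_plex_id])
        if len(used) != len(set(used)):
            raise ValueError("a plex is assigned to more than one block")
        known = set(ids)
        for b in self.blocks:
            for pid in (b.case_plex_id, b.control_plex_id):
                if pid not in known:
                    raise ValueError(f"block {b.block_id} references unknown plex {pid!r}")

    def plex(self, plex_id: str) -> Plex:
        for p in self.plexes:
            if p.plex_id == plex_id:
                return p
        raise KeyError(plex_id)

    def block_of_plex(self, plex_id: str) -> Block:
        for b in self.blocks:
            if plex_id in (b.case_plex_id, b.control_plex_id):
                return b
        raise KeyError(f"plex {plex_id!r} is not in any block")

    def subjects_by_block(
        self, meta: Sequence[SampleMeta]
    ) -> dict[str, dict[Group, list[str]]]:
        """Subjects per block, split into case/control, in first-seen order."""
        out: dict[str, dict[Group, list[str]]] = {
            b.block_id: {Group.case: [], Group.control: []} for b in self.blocks
        }
        plex_to_block = {}
        for b in self.blocks:
            plex_to_block[b.case_plex_id] = (b.block_id, Group.case)
            plex_to_block[b.control_plex_id] = (b.block_id, Group.control)
        for m in meta:
            if m.plex_id not in plex_to_block:
                continue
            bid, grp = plex_to_block[m.plex_id]
            if m.subject_id not in out[bid][grp]:
                out[bid][grp].append(m.subject_id)
        return out


@dataclass
class AbundanceMatrix:
    """Protein x sample quantitation with explicit missingness.

    ``data`` holds floats with NaN marking *not detected*; a value is never
    silently coerced to zero. ``scale`` declares the unit so downstream
    operations can refuse inputs they are not defined for.
    """

    data: pd.DataFrame
    scale: Scale

    def __post_init__(self) -> None:
        self.scale = Scale(self.scale)
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate protein ids: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        self.data = self.data.astype(float)
        if self.scale in (Scale.raw_sn, Scale.ref_ratio):
            vals = self.data.to_numpy()
            if np.any(vals[np.isfinite(vals)] < 0):
                raise ValueError(f"negative values are not valid on scale {self.scale.value}")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean frame, True where the value is missing."""
        return self.data.isna()

    @property
    def n_missing(self) -> int:
        return int(self.data.isna().to_numpy().sum())

    def copy(self) -> "AbundanceMatrix":
        return AbundanceMatrix(self.data.copy(), self.scale)


@dataclass(frozen=True)
class ProteinAnnotation:
    protein_id: str
    gene_symbol: str
    contaminant_class: ContaminantClass = ContaminantClass.none

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "contaminant_class", ContaminantClass(self.contaminant_class)
        )


#: Nine exercise-responsive symptoms scored 0-10 at 0 h and 24 h post-CPET.
SSS_SYMPTOMS = (
    "fatigue",
    "impaired_memory",
    "sore_throat",
    "lymph_node_tenderness",
    "myalgia",
    "arthralgia",
    "headache",
    "unrefreshing_sleep",
    "pem",
)

#: Required / recognised columns of a clinical table (subject_id is the key).
CLINICAL_COLUMNS = (
    ["subject_id", "group", "bell_scale", "sf36_pcs", "sf36_mcs", "sf36_gh",
     "pct_time_reclined", "mfi_total", "vo2peak", "vat", "age", "bmi",
     "illness_duration"]
    + [f"sss_0h_{s}" for s in SSS_SYMPTOMS]
    + [f"sss_24h_{s}" for s in SSS_SYMPTOMS]
)


@dataclass
class GeneSet:
    name: str
    description: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.members) == 0:
            raise ValueError(f"gene set {self.name!r} has no members")
        self.members = tuple(self.members)


@dataclass
class GeneSetCollection:
    sets: dict[str, GeneSet] = field(default_factory=dict)

    def add(self, gs: GeneSet) -> None:
        if gs.name in self.sets:
            raise ValueError(f"duplicate gene set name {gs.name!r}")
        self.sets[gs.name] = gs

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class AnalysisConfig:
    """Statistical parameters of the full pipeline.

    Defaults mirror the study design: 10,000 bootstrap replicates for the
    median fold-change CIs, 95% percentile intervals with false-coverage-rate
    adjustment at q = 0.1, gene-set permutation GSEA with 10,000 permutations
    and set sizes 5-500, 2000 correlation bootstrap resamples with the
    |rho| > 0.8 and q < 0.1 screening rule, and 75%/75% detection filtering.
    """

    B_diff: int = 10_000
    ci_level: float = 0.95
    fcr_q: float = 0.1
    bh_q_within: float = 0.1
    gsea_nperm: int = 10_000
    gsea_min_size: int = 5
    gsea_max_size: int = 500
    ora_q: float = 0.05
    B_corr: int = 2000
    r_min: float = 0.8
    corr_q: float = 0.1
    min_block_frac: float = 0.75
    min_sample_frac: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ci_level", "fcr_q", "bh_q_within", "ora_q", "corr_q",
                     "min_block_frac", "min_sample_frac"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        for name in ("B_diff", "gsea_nperm", "gsea_min_size", "gsea_max_size", "B_corr"):
            v = getattr(self, name)
            if v < 1:
                raise ValueError(f"{name} must be positive, got {v}")
        if not (0 < self.r_min <= 1):
            raise ValueError("r_min must be in (0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "AnalysisConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(d))
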