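"""Readers, writers and design validation.

All tabular I/O is plain delimited text (TSV by default). Missing values are
written as empty cells and read back as NaN; the missing mask round-trips
exactly. Gene sets use the standard GMT format
(``name<TAB>description<TAB>member...``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .types import (
    AbundanceMatrix,
    AnalysisConfig,
    Block,
    BlockDesign,
    ContaminantClass,
    GeneSet,
    GeneSetCollection,
    Group,
    Plex,
    ProteinAnnotation,
    SampleMeta,
    Scale,
    Timepoint,
    meta_frame,
)

__all__ = [
    "read_abundance_table",
    "write_abundance_table",
    "read_gmt",
    "write_gmt",
    "read_sample_meta",
    "write_sample_meta",
    "read_block_design",
    "write_block_design",
    "read_annotations",
    "write_annotations",
    "read_clinical_table",
    "write_clinical_table",
    "read_config",
    "write_config",
    "validate_design",
    "ValidationReport",
    "ParseError",
]


class ParseError(ValueError):
    """Malformed input file; the message names the offending row/column."""


def _sep(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_abundance_table(path: str | Path, scale: Scale | str) -> AbundanceMatrix:
    """Read a protein x sample table; first column = protein id, header = sample ids.

    Empty cells and ``NA`` denote missing values. Duplicate protein ids and
    non-numeric cells are rejected with an error naming the culprit.
    """
    path = Path(path)
    df = pd.read_csv(
        path, sep=_sep(path), index_col=0, na_values=["NA", ""],
        keep_default_na=False, dtype=str,
    )
    if df.index.name is None or df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        if dups:
            raise ParseError(f"{path}: duplicate sample columns {dups}")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate protein id(s) {dups}")
    numeric = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad][0]
            raise ParseError(
                f"{path}: non-numeric value {df.loc[row, col]!r} "
                f"at protein {row!r}, sample {col!r}"
            )
        numeric[col] = converted
    return AbundanceMatrix(numeric, Scale(scale))


def write_abundance_table(matrix: AbundanceMatrix, path: str | Path) -> None:
    path = Path(path)
    matrix.data.to_csv(path, sep=_sep(path), na_rep="", index_label="protein_id")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT gene-set file, preserving line order."""
    coll = GeneSetCollection()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f">=1 member (got {len(parts)} fields)"
                )
            name, desc, *members = parts
            members = [m for m in members if m]
            if not members:
                raise ParseError(f"{path}:{lineno}: gene set {name!r} has no members")
            if name in coll.sets:
                raise ParseError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            coll.add(GeneSet(name, desc, tuple(members)))
    return coll


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in coll:
            fh.write("\t".join([gs.name, gs.description, *gs.members]) + "\n")


def read_sample_meta(path: str | Path) -> list[SampleMeta]:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path), dtype=str)
    required = {"sample_id", "subject_id", "group", "timepoint", "plex_id", "channel"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return [
        SampleMeta(
            sample_id=r.sample_id, subject_id=r.subject_id, group=Group(r.group),
            timepoint=Timepoint(r.timepoint), plex_id=r.plex_id, channel=r.channel,
        )
        for r in df.itertuples()
    ]


def write_sample_meta(meta: Sequence[SampleMeta], path: str | Path) -> None:
    path = Path(path)
    meta_frame(meta).to_csv(path, sep=_sep(path), index=False)


def read_block_design(path: str | Path) -> BlockDesign:
    """Read a block design from JSON ({"plexes": [...], "blocks": [...]})."""
    with open(path, encoding="utf-8") as fh:
        d = json.load(fh)
    return BlockDesign(
        plexes=[Plex(p["plex_id"], Group(p["group"]), p["reference_channel"])
                for p in d["plexes"]],
        blocks=[Block(b["block_id"], b["case_plex_id"], b["control_plex_id"])
                for b in d["blocks"]],
    )


def write_block_design(design: BlockDesign, path: str | Path) -> None:
    d = {
        "plexes": [
            {"plex_id": p.plex_id, "group": p.group.value,
             "reference_channel": p.reference_channel}
            for p in design.plexes
        ],
        "blocks": [
            {"block_id": b.block_id, "case_plex_id": b.case_plex_id,
             "control_plex_id": b.control_plex_id}
            for b in design.blocks
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(d, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_annotations(path: str | Path) -> list[ProteinAnnotation]:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path), dtype=str)
    required = {"protein_id", "gene_symbol", "contaminant_class"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return [
        ProteinAnnotation(r.protein_id, r.gene_symbol,
                          ContaminantClass(r.contaminant_class))
        for r in df.itertuples()
    ]


def write_annotations(annotations: Sequence[ProteinAnnotation], path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame(
        [
            {"protein_id": a.protein_id, "gene_symbol": a.gene_symbol,
             "contaminant_class": a.contaminant_class.value}
            for a in annotations
        ]
    ).to_csv(path, sep=_sep(path), index=False)


def read_clinical_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path), na_values=["NA", ""], keep_default_na=False)
    if "subject_id" not in df.columns:
        raise ParseError(f"{path}: clinical table needs a subject_id column")
    if df["subject_id"].duplicated().any():
        dups = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ParseError(f"{path}: duplicate subject_id(s) {dups}")
    return df


def write_clinical_table(clinical: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    clinical.to_csv(path, sep=_sep(path), na_rep="", index=False)


def read_config(path: str | Path) -> AnalysisConfig:
    with open(path, encoding="utf-8") as fh:
        return AnalysisConfig.from_dict(yaml.safe_load(fh) or {})


def write_config(config: AnalysisConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


@dataclass
class ValidationReport:
    """Outcome of design validation; callers decide whether to abort."""

    n_subjects: int = 0
    n_samples: int = 0
    n_blocks: int = 0
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_design(
    matrix: AbundanceMatrix,
    meta: Sequence[SampleMeta],
    design: BlockDesign,
) -> ValidationReport:
    """Check that samples, subjects and plexes form a coherent block design.

    Group comparisons are only meaningful within a block (a bridged case plex /
    control plex pair), so every sample must map to a plex in exactly one
    block, every subject must be complete over the three time points, and all
    of a subject's samples must sit in one plex.
    """
    report = ValidationReport(n_blocks=len(design.blocks))
    ids = [m.sample_id for m in meta]
    if len(ids) != len(set(ids)):
        report.violations.append("duplicate sample_id in metadata")

    plex_group = {p.plex_id: p.group for p in design.plexes}
    plexes_in_blocks = set()
    for b in design.blocks:
        plexes_in_blocks.update([b.case_plex_id, b.control_plex_id])
        if plex_group.get(b.case_plex_id) != Group.case:
            report.violations.append(
                f"block {b.block_id}: case_plex {b.case_plex_id!r} is not a case plex"
            )
        if plex_group.get(b.control_plex_id) != Group.control:
            report.violations.append(
                f"block {b.block_id}: control_plex {b.control_plex_id!r} is not a control plex"
            )
    for p in design.plexes:
        if p.plex_id not in plexes_in_blocks:
            report.violations.append(f"plex {p.plex_id!r} is in no block")

    meta_by_sample = {m.sample_id: m for m in meta}
    for sid in matrix.sample_ids:
        if sid not in meta_by_sample:
            report.violations.append(f"matrix sample {sid!r} has no metadata")

    subjects: dict[str, list[SampleMeta]] = {}
    for m in meta:
        subjects.setdefault(m.subject_id, []).append(m)
        if m.plex_id not in plex_group:
            report.violations.append(
                f"sample {m.sample_id!r} assigned to unknown plex {m.plex_id!r}"
            )
        elif plex_group[m.plex_id] != m.group:
            report.violations.append(
                f"sample {m.sample_id!r}: group {m.group.value} does not match "
                f"plex {m.plex_id!r} ({plex_group[m.plex_id].value})"
            )
        ref = {p.plex_id: p.reference_channel for p in design.plexes}.get(m.plex_id)
        if ref is not None and m.channel == ref:
            report.violations.append(
                f"sample {m.sample_id!r} occupies the reference channel of plex {m.plex_id!r}"
            )

    for subj, mm in subjects.items():
        tps = sorted(m.timepoint.value for m in mm)
        if tps != sorted(t.value for t in Timepoint):
            report.violations.append(
                f"subject {subj!r} does not have exactly one sample per time point (has {tps})"
            )
        if len({m.plex_id for m in mm}) != 1:
            report.violations.append(f"subject {subj!r} spans multiple plexes")
        if len({m.group for m in mm}) != 1:
            report.violations.append(f"subject {subj!r} has inconsistent group labels")

    report.n_subjects = len(subjects)
    report.n_samples = len(meta)
    return report
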