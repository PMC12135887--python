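"""End-to-end orchestration: simulate/load -> preprocess -> inference ->
enrichment -> clinical screening, with a run manifest.

Every stage output is a pure function of (inputs, config, seed); re-running
with the same seed reproduces identical result files (the manifest's wall
times are the only thing that differs between runs).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .clinical import correlations_frame, screen_correlations
from .diffabund import (
    between_group_pairs,
    bootstrap_ci_table,
    results_frame,
    timepoint_log2,
    within_group_mean_test,
    within_results_frame,
    within_subject_log2fc,
)
from .enrichment import fisher_ora, gsea_preranked, gsea_frame, ora_frame
from .io import (
    validate_design,
    write_abundance_table,
    write_block_design,
    write_clinical_table,
    write_gmt,
    write_sample_meta,
)
from .preprocess import filter_contaminants, filter_detection, impute
from .simulate import SimulationConfig, simulate_cohort
from .types import (
    AbundanceMatrix,
    AnalysisConfig,
    BlockDesign,
    GeneSet,
    GeneSetCollection,
    Group,
    ProteinAnnotation,
    SampleMeta,
    Scale,
    TIMEPOINT_ORDER,
    RATIO_CONTRASTS,
)

__all__ = ["RunManifest", "run_pipeline", "synthetic_gene_sets"]

TIMEPOINT_CONTRASTS = tuple(t.value for t in TIMEPOINT_ORDER)
RATIO_CONTRAST_NAMES = tuple(f"{a.value}/{b.value}" for a, b in RATIO_CONTRASTS)
ALL_CONTRASTS = TIMEPOINT_CONTRASTS + RATIO_CONTRAST_NAMES


@dataclass
class RunManifest:
    config: dict
    seed: int
    software_version: str = __version__
    input_digests: dict = field(default_factory=dict)
    stage_timings: dict = field(default_factory=dict)
    stage_counts: dict = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)

    def write(self, path: Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def synthetic_gene_sets(
    protein_ids: Sequence[str],
    n_sets: int = 20,
    size_range: tuple[int, int] = (8, 40),
    seed: int = 0,
) -> GeneSetCollection:
    """Random gene sets over the protein universe, for synthetic runs.

    With gene symbol == protein id in the synthetic cohort, these play the
    role of pathway collections so the enrichment stages always have input.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x65E7]))
    ids = list(protein_ids)
    coll = GeneSetCollection()
    for i in range(1, n_sets + 1):
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        size = min(size, len(ids))
        members = list(rng.choice(ids, size=size, replace=False))
        coll.add(GeneSet(f"SET{i:03d}", f"synthetic set {i}", tuple(sorted(members))))
    return coll


def run_pipeline(
    config: AnalysisConfig,
    out_dir: str | Path,
    matrix: AbundanceMatrix | None = None,
    meta: Sequence[SampleMeta] | None = None,
    design: BlockDesign | None = None,
    clinical: pd.DataFrame | None = None,
    annotations: Sequence[ProteinAnnotation] | None = None,
    gene_sets: GeneSetCollection | None = None,
    sim_config: SimulationConfig | None = None,
    simulate: bool = False,
    contrasts: Sequence[str] = ALL_CONTRASTS,
    clinical_parameters: Sequence[str] | None = None,
) -> RunManifest:
    """Run every analysis stage and write TSV/JSON results under ``out_dir``.

    With ``simulate=True`` a synthetic cohort is generated first (and written
    alongside the results); otherwise ``matrix``, ``meta`` and ``design``
    must be supplied, with ``clinical`` optional.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict(), seed=config.seed)

    def timed(stage):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()
            def __exit__(self, *exc):
                manifest.stage_timings[stage] = round(time.perf_counter() - self.t0, 3)
        return _T()

    if simulate:
        with timed("simulate"):
            sim_config = sim_config or SimulationConfig()
            matrix, meta, design, clinical, truth = simulate_cohort(
                sim_config, seed=config.seed
            )
            write_abundance_table(matrix, out / "abundance.tsv")
            write_sample_meta(meta, out / "sample_meta.tsv")
            write_block_design(design, out / "block_design.json")
            write_clinical_table(clinical, out / "clinical.tsv")
            with open(out / "truth.json", "w", encoding="utf-8") as fh:
                json.dump(
                    {
                        "effects": [
                            {"protein_id": e.protein_id, "contrast": e.contrast,
                             "delta": e.delta} for e in truth.effects
                        ],
                        "links": [
                            {"covariate": l.covariate, "protein_id": l.protein_id,
                             "contrast": l.contrast, "target_rho": l.target_rho,
                             "group": l.group.value} for l in truth.links
                        ],
                    },
                    fh, indent=2,
                )
                fh.write("\n")
    if matrix is None or meta is None or design is None:
        raise ValueError("matrix, meta and design are required unless simulate=True")

    report = validate_design(matrix, meta, design)
    if not report.ok:
        raise ValueError("design validation failed: " + "; ".join(report.violations))
    manifest.stage_counts["subjects"] = report.n_subjects
    manifest.stage_counts["samples"] = report.n_samples
    manifest.stage_counts["proteins_in"] = len(matrix.protein_ids)

    with timed("preprocess"):
        if annotations is not None:
            matrix, crep = filter_contaminants(matrix, annotations)
            manifest.stage_counts["removed_contaminant"] = crep.n_removed_contaminant
        matrix, drep = filter_detection(
            matrix, meta, design, config.min_block_frac, config.min_sample_frac
        )
        manifest.stage_counts["removed_detection"] = (
            drep.n_removed_block_frac + drep.n_removed_sample_frac
        )
        if matrix.n_missing:
            matrix = impute(matrix, meta, design, method="forest", seed=config.seed)
        manifest.stage_counts["proteins_analyzed"] = len(matrix.protein_ids)
        write_abundance_table(matrix, out / "abundance_processed.tsv")

    gene_of = (
        {a.protein_id: a.gene_symbol for a in annotations}
        if annotations is not None
        else {p: p for p in matrix.protein_ids}
    )
    if gene_sets is None and simulate:
        gene_sets = synthetic_gene_sets(matrix.protein_ids, seed=config.seed)
        write_gmt(gene_sets, out / "gene_sets.gmt")

    universe = [gene_of[p] for p in matrix.protein_ids]
    for contrast in contrasts:
        with timed(f"diffabund[{contrast}]"):
            if "/" in contrast:
                t_num, t_den = contrast.split("/")
                fc = within_subject_log2fc(matrix, meta, t_num, t_den)
                values = fc
                for grp in (Group.case, Group.control):
                    wres = within_group_mean_test(fc, meta, grp, contrast=contrast)
                    within_results_frame(wres).to_csv(
                        out / f"within_{grp.value}_{contrast.replace('/', '_vs_')}.tsv",
                        sep="\t", index=False,
                    )
            else:
                values = timepoint_log2(matrix, meta, contrast)
            pairs = [
                between_group_pairs(values.loc[p], meta, design,
                                    protein_id=p, contrast=contrast)
                for p in values.index
            ]
            res = bootstrap_ci_table(
                pairs, B=config.B_diff, ci_level=config.ci_level,
                fcr_q=config.fcr_q, seed=config.seed,
            )
            tab = results_frame(res)
            fname = contrast.replace("/", "_vs_")
            tab.to_csv(out / f"diffabund_{fname}.tsv", sep="\t", index=False)
            manifest.stage_counts[f"daps[{contrast}]"] = int(tab["significant"].sum())

        if gene_sets is not None and len(gene_sets):
            with timed(f"enrich[{contrast}]"):
                ranked_genes = [gene_of[p] for p in tab["protein_id"]]
                gres = gsea_preranked(
                    ranked_genes, tab["median_log2fc"].to_numpy(), gene_sets,
                    nperm=config.gsea_nperm, min_size=config.gsea_min_size,
                    max_size=config.gsea_max_size, seed=config.seed,
                )
                gsea_frame(gres).to_csv(out / f"gsea_{fname}.tsv", sep="\t", index=False)
                hits = [gene_of[p] for p in tab.loc[tab["significant"], "protein_id"]]
                if hits:
                    ores = fisher_ora(hits, universe, gene_sets, config.ora_q)
                    ora_frame(ores).to_csv(out / f"ora_{fname}.tsv", sep="\t", index=False)

    if clinical is not None:
        for contrast in [c for c in contrasts if "/" in c]:
            fc = within_subject_log2fc(matrix, meta, *contrast.split("/"))
            fname = contrast.replace("/", "_vs_")
            for grp in (Group.case, Group.control):
                with timed(f"correlate[{contrast},{grp.value}]"):
                    cres = screen_correlations(
                        fc, clinical, grp, config,
                        parameters=clinical_parameters, contrast=contrast,
                    )
                    cf = correlations_frame(cres)
                    cf.to_csv(out / f"correlations_{grp.value}_{fname}.tsv",
                              sep="\t", index=False)
                    cf[cf["passes_rule"]].to_csv(
                        out / f"correlations_strong_{grp.value}_{fname}.tsv",
                        sep="\t", index=False,
                    )

    manifest.outputs = sorted(p.name for p in out.iterdir() if p.name != "manifest.json")
    manifest.input_digests = {
        name: _digest(out / name)
        for name in ("abundance.tsv", "sample_meta.tsv", "block_design.json")
        if (out / name).exists()
    }
    manifest.write(out / "manifest.json")
    return manifest
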