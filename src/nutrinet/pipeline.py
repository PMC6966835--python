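"""End-to-end contrast analysis: normalisation through module-trait tables.

Stage order: TMM normalisation -> CPM -> per-gene outlier capping ->
expressed-gene filter -> differential expression (exact NB test, BH) and
differential dispersion (LRT, BY) -> PCIT co-expression network over
expressed miRNAs and DE mRNAs -> 7mer-m8 seed validation of miRNA->mRNA
edges -> RIF regulator scoring -> mRNA hub scores -> signed weighted
modules and phenotype association.

Count-model stages (DE, DD) run on raw counts with TMM-effective library
sizes; correlation-based stages (network, RIF, modules) run on capped
log2 CPM.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import de as de_mod
from . import dispersion as dd_mod
from .matrix import ExpressionMatrix
from .modules import ModuleSet, module_trait_analysis
from .pcit import extract_edges, hub_scores, pcit_mask, pearson_matrix
from .preprocess import (cap_outliers_frame, cpm, filter_expressed,
                         read_count_matrix, tmm_factors)
from .rif import build_profile, rif_table
from .seeds import seed_filter_edges

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All inputs and thresholds of one contrast run; YAML round-trippable."""

    counts: str = "counts.tsv"
    biotypes: str = "biotypes.tsv"
    groups: str = "groups.tsv"
    utr_fasta: str = "utrs.fa"
    mirna_fasta: str = "mirna_mature.fa"
    phenotypes: str = "phenotypes.csv"
    group1: str = "fasted"
    group2: str = "fed"
    min_cpm: float = 1.0
    min_fraction: float = 0.5
    fc: float = 1.5
    fc_relaxed: float = 1.2
    q: float = 0.05
    mirna_r_max: float = -0.5
    mrna_abs_r_min: float = 0.7
    beta: float = 16.0
    min_module_size: int = 30
    merge_height: float = 0.25
    seed: int = 42
    outdir: str = "results"

    def __post_init__(self) -> None:
        if not 0 <= self.min_fraction <= 1:
            raise ValueError("min_fraction must lie in [0, 1]")
        if self.fc < 1 or self.fc_relaxed < 1:
            raise ValueError("fold-change thresholds must be >= 1")
        if not 0 < self.q <= 1:
            raise ValueError("q threshold must lie in (0, 1]")
        if self.mirna_r_max >= 0:
            raise ValueError("mirna_r_max must be negative (repressor assumption)")
        if not 0 < self.mrna_abs_r_min < 1:
            raise ValueError("mrna_abs_r_min must lie in (0, 1)")

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class ContrastResult:
    """Every stage table of one contrast run plus the run manifest."""

    expressed: pd.Index
    capped_cpm: pd.DataFrame
    de_table: pd.DataFrame
    dd_table: pd.DataFrame
    edges: pd.DataFrame
    hubs: pd.DataFrame | None
    rif: pd.DataFrame | None
    module_set: ModuleSet | None
    manifest: dict = field(default_factory=dict)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def run_contrast(
    config: PipelineConfig,
    matrix: ExpressionMatrix | None = None,
    phenotypes: pd.DataFrame | None = None,
    write: bool = True,
) -> ContrastResult:
    """Run the whole contrast pipeline from files or in-memory inputs."""
    manifest: dict = {
        "seed": config.seed,
        "thresholds": {
            k: getattr(config, k)
            for k in ("min_cpm", "min_fraction", "fc", "fc_relaxed", "q",
                      "mirna_r_max", "mrna_abs_r_min", "beta",
                      "min_module_size", "merge_height")
        },
        "stages": {},
    }

    def log_stage(name: str, n_in: int, n_out: int) -> None:
        manifest["stages"][name] = {"input_n": n_in, "output_n": n_out}
        logger.info("%s: %d -> %d", name, n_in, n_out)

    if matrix is None:
        try:
            matrix = read_count_matrix(config.counts, config.biotypes, config.groups)
        except Exception as exc:  # noqa: BLE001 - abort with stage name
            raise StageError("read_counts", str(exc)) from exc
    if phenotypes is None and Path(config.phenotypes).exists():
        phenotypes = pd.read_csv(config.phenotypes, index_col=0)

    samples = matrix.samples_of(config.group1) + matrix.samples_of(config.group2)
    if not matrix.samples_of(config.group1) or not matrix.samples_of(config.group2):
        raise StageError("contrast", f"missing group in {config.group1}/{config.group2}")
    matrix = matrix.subset_samples(samples)

    factors = tmm_factors(matrix)
    cpm_mat = cpm(matrix, factors)
    capped = cap_outliers_frame(cpm_mat)
    log_stage("normalise_cap", matrix.n_genes, matrix.n_genes)

    expressed = filter_expressed(capped, matrix.biotype,
                                 min_cpm=config.min_cpm,
                                 min_fraction=config.min_fraction)
    log_stage("filter_expressed", matrix.n_genes, len(expressed))
    capped = capped.loc[expressed]

    eff = factors.effective_library_size
    de_table = de_mod.contrast_table(
        matrix.counts.loc[expressed], matrix.group,
        config.group1, config.group2, eff_lib=eff,
    )
    de_table = de_mod.classify_de(de_table, config.fc, config.q)
    relaxed = de_mod.classify_de(de_table, config.fc_relaxed, config.q)
    de_table["de_flag_relaxed"] = relaxed["de_flag"]
    de_table["biotype"] = matrix.biotype.loc[de_table.index]
    log_stage("diff_expression", len(expressed), int(de_table["de_flag"].sum()))

    dd_table = dd_mod.dispersion_table(
        matrix.counts.loc[expressed], matrix.group,
        config.group1, config.group2, eff_lib=eff,
    )
    dd_table = dd_mod.classify_dd(dd_table, config.fc, config.q)
    dd_table["biotype"] = matrix.biotype.loc[dd_table.index]
    log_stage("diff_dispersion", len(expressed), int(dd_table["dd_flag"].sum()))

    bio = matrix.biotype
    mirna_ids = [g for g in expressed if bio[g] == "miRNA"]
    de_mrna_ids = [g for g in de_table.index[de_table["de_flag"]]
                   if bio[g] == "mRNA"]
    edges = pd.DataFrame(columns=["source", "target", "r", "edge_type",
                                  "pcit_significant", "seed_validated"])
    hubs = None
    rif = None
    if mirna_ids and len(de_mrna_ids) >= 1 and len(mirna_ids) + len(de_mrna_ids) >= 3:
        nodes = mirna_ids + de_mrna_ids
        log_node_expr = np.log2(capped.loc[nodes] + 0.25)
        corr = pearson_matrix(log_node_expr)
        mask = pcit_mask(corr)
        edges = extract_edges(corr, mask, mirna_ids, de_mrna_ids,
                              mirna_r_max=config.mirna_r_max,
                              mrna_abs_r_min=config.mrna_abs_r_min)
        n_candidates = len(edges)
        if not Path(config.utr_fasta).exists():
            raise StageError("seed_matching", f"UTR FASTA not found: {config.utr_fasta}")
        if not Path(config.mirna_fasta).exists():
            raise StageError("seed_matching", f"mature miRNA FASTA not found: "
                                              f"{config.mirna_fasta}")
        edges = seed_filter_edges(edges, config.utr_fasta, config.mirna_fasta)
        log_stage("network_edges", n_candidates, len(edges))

        if (edges["edge_type"] == "mRNA-mRNA").any():
            hubs = hub_scores(edges, node_ids=de_mrna_ids)
        samples1 = matrix.samples_of(config.group1)
        samples2 = matrix.samples_of(config.group2)
        profile = build_profile(capped, samples1, samples2, mirna_ids, de_mrna_ids)
        rif = rif_table(profile)

    module_set = None
    if phenotypes is not None:
        wgcna_genes = [g for g in expressed if bio[g] in ("mRNA", "miRNA")]
        if len(wgcna_genes) >= config.min_module_size:
            module_set = module_trait_analysis(
                np.log2(capped.loc[wgcna_genes] + 0.25), bio,
                phenotypes.loc[samples],
                beta=config.beta, min_module_size=config.min_module_size,
                merge_height=config.merge_height,
            )
            n_mod = len([m for m in module_set.labels.unique() if m != "unassigned"])
            log_stage("modules", len(wgcna_genes), n_mod)

    result = ContrastResult(expressed, capped, de_table, dd_table, edges,
                            hubs, rif, module_set, manifest)
    if write:
        _write_results(config, result)
    return result


def _write_results(config: PipelineConfig, result: ContrastResult) -> None:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.de_table.rename_axis("gene_id").to_csv(out / "de_table.tsv", sep="\t")
    result.dd_table.rename_axis("gene_id").to_csv(out / "dd_table.tsv", sep="\t")
    result.edges.to_csv(out / "edges.tsv", sep="\t", index=False)
    if result.hubs is not None:
        result.hubs.to_csv(out / "hub_scores.tsv", sep="\t")
    if result.rif is not None:
        result.rif.to_csv(out / "rif_scores.tsv", sep="\t")
    if result.module_set is not None:
        ms = result.module_set
        ms.labels.rename_axis("gene_id").to_frame().to_csv(
            out / "module_labels.tsv", sep="\t")
        ms.eigengenes.rename_axis("module").to_csv(out / "eigengenes.tsv", sep="\t")
        ms.module_trait_r.rename_axis("module").to_csv(out / "module_trait_r.csv")
        ms.module_trait_p.rename_axis("module").to_csv(out / "module_trait_p.csv")
        ms.gene_significance_r.rename_axis("gene_id").to_csv(
            out / "gene_significance_r.csv")
        ms.gene_significance_p.rename_axis("gene_id").to_csv(
            out / "gene_significance_p.csv")
        ms.kleinberg_hub.rename_axis("gene_id").to_frame().to_csv(
            out / "kleinberg_hub.tsv", sep="\t")
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
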