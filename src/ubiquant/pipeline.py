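"""End-to-end orchestration: config -> result tables + run manifest.

Stage order: read (or simulate) -> flag removal -> log2 transform ->
presence filter -> imputation -> one-tailed double-control gating ->
two-tailed condition contrasts -> robust-change clustering -> replicate and
enrichment QC -> write tables and manifest. One master seed spawns
independent per-stage child seeds, so e.g. changing the permutation count
does not perturb the imputation draws. Any stage failure aborts with the
stage name attached.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import SampleDesign
from .diffstats import combine_gates, condition_contrast, control_gate, permutation_qvalues
from .io_tables import (
    PeptideTable,
    ProteinTable,
    read_peptide_table,
    read_protein_groups,
    write_results,
)
from .preprocess import AnalysisConfig, filter_min_valid, impute_lowshift, to_log_matrix
from .profile_qc import (
    DEFAULT_UBIQUITIN_GENES,
    replicate_qc,
    robust_change_set,
    ubiquitin_fraction,
    zscore_hcluster,
)
from .simulate import SimulationConfig, simulate_dataset

__all__ = ["RunManifest", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


_STAGE_SEEDS = {"impute": 0, "gate": 1, "contrast": 2}


def _stage_seed(master: int, stage: str) -> int:
    ss = np.random.SeedSequence(master)
    children = ss.spawn(len(_STAGE_SEEDS))
    return int(children[_STAGE_SEEDS[stage]].generate_state(1)[0] % (2**31))


@dataclass
class RunManifest:
    """Audit trail of a pipeline run: config echo, seed, version, and
    per-stage row counts (non-increasing along the filtering stages)."""

    config: dict
    seed: int
    version: str = __version__
    counts: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "version": self.version,
                "seed": self.seed,
                "config": self.config,
                "counts": self.counts,
            },
            indent=2,
            sort_keys=True,
        )


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def run_pipeline(config, out_dir=None, seed: int | None = None) -> tuple[RunManifest, dict[str, pd.DataFrame]]:
    """Run the full analysis described by ``config`` (mapping or YAML path).

    Config keys: ``inputs`` (protein_groups/evidence/design paths) *or*
    ``simulate`` (SimulationConfig fields); ``parameters`` (AnalysisConfig
    fields); ``contrasts`` (list of [group_a, group_b]); ``cluster_groups``;
    ``n_clusters``; ``seed``; ``out_dir``. Returns the manifest and the
    result tables; writes both when an output directory is given.
    """
    cfg = _load_config(config)
    seed = seed if seed is not None else int(cfg.get("seed", 0))
    out_dir = out_dir or cfg.get("out_dir")
    params = AnalysisConfig(**cfg.get("parameters", {}))
    counts: dict[str, int] = {}
    tables: dict[str, pd.DataFrame] = {}

    # -- input ------------------------------------------------------------
    stage = "read"
    try:
        if "simulate" in cfg:
            sim_cfg = SimulationConfig(**{**cfg["simulate"], "seed": seed})
            table, peptides, design, truth = simulate_dataset(sim_cfg)
            tables["truth_effects"] = truth.effects
        elif "inputs" in cfg:
            inputs = cfg["inputs"]
            design = SampleDesign.from_yaml(inputs["design"])
            table = read_protein_groups(inputs["protein_groups"], design)
            peptides = (
                read_peptide_table(inputs["evidence"], design)
                if inputs.get("evidence")
                else None
            )
            truth = None
        else:
            raise ValueError("config needs an 'inputs' or 'simulate' section")
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001 - re-raise with stage context
        raise PipelineError(stage, str(e)) from e
    counts["proteins_in"] = len(table)

    try:
        stage = "flag_removal"
        if cfg.get("remove_flagged", True):
            table = table.remove_flagged()
        counts["after_flag_removal"] = len(table)

        stage = "log2_transform"
        m = to_log_matrix(table, design)

        stage = "presence_filter"
        m = filter_min_valid(m, params)
        counts["after_presence_filter"] = len(m.values)

        stage = "impute"
        m = impute_lowshift(m, params.with_seed(_stage_seed(seed, "impute")))

        stage = "control_gate"
        background = design.background_group
        blocked = design.blocked_group
        if background and blocked and design.target_groups:
            gate_seed = _stage_seed(seed, "gate")
            per_group = {}
            for g in design.target_groups:
                vs_bg = permutation_qvalues(
                    m,
                    design.samples_of(g),
                    design.samples_of(background),
                    params.with_seed(gate_seed),
                    tail="greater",
                )
                vs_bl = permutation_qvalues(
                    m,
                    design.samples_of(g),
                    design.samples_of(blocked),
                    params.with_seed(gate_seed),
                    tail="greater",
                )
                per_group[g] = control_gate(vs_bg, vs_bl, params)
                tables[f"gate_{g}_vs_background"] = vs_bg
                tables[f"gate_{g}_vs_blocked"] = vs_bl
            gate = combine_gates(per_group, scope=params.gate_scope)
            tables["enrichment_calls"] = gate
            counts["gated"] = int(gate["gated"].sum())
        else:
            gate = None

        stage = "contrasts"
        contrast_seed = _stage_seed(seed, "contrast")
        contrasts = cfg.get("contrasts")
        if contrasts is None and len(design.target_groups) >= 2:
            ref = design.target_groups[0]
            contrasts = [[g, ref] for g in design.target_groups[1:]]
        for ga, gb in contrasts or []:
            res = condition_contrast(m, design, ga, gb, params.with_seed(contrast_seed))
            tables[f"contrast_{ga}_vs_{gb}"] = res
            counts[f"significant_{ga}_vs_{gb}"] = int(res["significant"].sum())

        stage = "robust_clustering"
        cluster_groups = cfg.get("cluster_groups") or list(design.target_groups) or list(design.groups)
        if len(cluster_groups) >= 2:
            robust = robust_change_set(m, design, cluster_groups)
            counts["robust_set"] = len(robust)
            if robust:
                cols = [s for g in cluster_groups for s in design.samples_of(g)]
                cluster = zscore_hcluster(
                    m.values[cols], subset=robust, n_clusters=cfg.get("n_clusters")
                )
                zt = cluster.ordered.copy()
                zt["cluster"] = cluster.cluster_labels.reindex(zt.index)
                tables["robust_clusters"] = zt

        stage = "qc"
        qc = replicate_qc(m, design)
        tables["qc_pearson"] = qc.pearson
        tables["qc_cv_group_medians"] = qc.cv_group_medians.to_frame("median_cv_pct")
        tables["qc_pca_scores"] = qc.pca_scores
        if peptides is not None and len(peptides):
            ub_acc = set(cfg.get("ubiquitin_accessions", []))
            if not ub_acc:
                genes = table.gene_names.str.lower()
                ub_acc = set(table.ids[genes.isin(DEFAULT_UBIQUITIN_GENES)])
            if ub_acc:
                pct, per_group_pct = ubiquitin_fraction(peptides, ub_acc, design)
                tables["qc_ubiquitin_pct"] = pct.to_frame()
                tables["qc_ubiquitin_pct_by_group"] = per_group_pct
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, str(e)) from e

    manifest = RunManifest(config=cfg, seed=seed, counts=counts)

    if out_dir is not None:
        stage = "write"
        try:
            paths = write_results(tables, out_dir, config=cfg, seed=seed)
            Path(out_dir, "manifest.json").write_text(manifest.to_json() + "\n")
        except Exception as e:  # noqa: BLE001
            raise PipelineError(stage, str(e)) from e
    return manifest, tables
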