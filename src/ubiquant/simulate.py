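"""Synthetic ubiquitin-pulldown datasets with known ground truth.

The generator emulates the statistical structure of a label-free
ubiquitin-enrichment experiment: per-protein log2 abundances drawn from a
Normal(base_mean, base_sd^2) prior (so linear intensities span orders of
magnitude), small replicate noise, a fraction of "regulated" proteins whose
ubiquitylation responds to a stimulus with stated log2 effect sizes,
globally attenuated recovery of regulated proteins in the background and
conjugation-blocked control groups, and missing-not-at-random dropout:
each cell is censored with probability logistic in its true log2 intensity
(lower intensity -> more likely missing), matching the left-censored
assumption behind downshifted-Gaussian imputation.

Ubiquitin itself is simulated at the peptide level only: designated
ubiquitin peptide rows sum to a configured fraction of total peptide
intensity per group, and the protein-level ubiquitin entry is derived by
summation — exactly how the enrichment-efficiency QC consumes real
evidence-level data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .design import SampleDesign, make_design
from .io_tables import PeptideTable, ProteinTable

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_dataset",
    "evaluate_calls",
    "five_group_config",
    "six_group_triplicate_config",
    "two_group_config",
    "UBIQUITIN_ACCESSION",
]

UBIQUITIN_ACCESSION = "SYNUB0"  # synthetic ubiquitin protein-group accession


@dataclass
class SimulationConfig:
    """Parameters of the synthetic dataset.

    groups : (name, n_replicates, role) triples; role is ``target``,
        ``background`` (untagged-ubiquitin control) or ``blocked``
        (E1-inhibited control).
    affected_groups : target groups in which regulated proteins receive
        their log2 effect (the stimulus groups).
    effect_low/effect_high : regulated effects are drawn uniformly from
        this range (log2 units).
    base_mean/base_sd : location/scale of true log2 abundances.
    rep_sd : replicate noise SD (log2). The default 0.3 yields
        between-replicate Pearson correlations around 0.98 for
        base_sd = 2, inside the 0.94-0.99 range typical of replicate
        pulldowns.
    missing_rate : target overall fraction of censored cells; 0 disables
        censoring.
    censor_midpoint : log2 intensity at which the censoring probability is
        0.5; ``None`` auto-calibrates it so the realized rate matches
        ``missing_rate``.
    censor_slope : logistic steepness per log2 unit (probability of
        dropout decreases with intensity).
    control_attenuation : log2 units by which regulated proteins are
        depleted in control groups (they are not enriched without
        conjugated ubiquitin).
    ubiquitin_fraction_per_role : target fraction of summed peptide
        intensity contributed by ubiquitin peptides, per group role;
        ``None`` disables ubiquitin peptide rows entirely.
    peptides_per_protein : non-ubiquitin peptide rows generated per
        protein per sample.
    """

    n_proteins: int = 1000
    n_regulated: int = 50
    groups: tuple[tuple[str, int, str], ...] = (
        ("no_DNA", 4, "target"),
        ("DNA", 4, "target"),
        ("DSB", 4, "target"),
        ("no_His", 4, "background"),
        ("Ub_E1i", 4, "blocked"),
    )
    affected_groups: tuple[str, ...] = ("DSB",)
    effect_low: float = 1.0
    effect_high: float = 4.0
    base_mean: float = 30.0
    base_sd: float = 2.0
    rep_sd: float = 0.3
    missing_rate: float = 0.1
    censor_midpoint: float | None = None
    censor_slope: float = 1.5
    control_attenuation: float = 3.0
    ubiquitin_fraction_per_role: Mapping[str, float] | None = field(
        default_factory=lambda: {"target": 0.40, "blocked": 0.20, "background": 0.04}
    )
    peptides_per_protein: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins <= 0:
            raise ValueError("n_proteins must be positive")
        if not (0 <= self.n_regulated <= self.n_proteins):
            raise ValueError("n_regulated must be in [0, n_proteins]")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        roles = {r for _, _, r in self.groups}
        if not roles <= {"target", "background", "blocked"}:
            raise ValueError(f"unknown group role in {roles}")
        if self.ubiquitin_fraction_per_role is not None:
            for role, f in self.ubiquitin_fraction_per_role.items():
                if not (0 <= f < 1):
                    raise ValueError(f"infeasible ubiquitin fraction {f} for role {role!r}")
        target_names = {g for g, _, r in self.groups if r == "target"}
        if not set(self.affected_groups) <= target_names:
            raise ValueError("affected_groups must be target groups")

    def to_design(self) -> SampleDesign:
        background = next((g for g, _, r in self.groups if r == "background"), None)
        blocked = next((g for g, _, r in self.groups if r == "blocked"), None)
        return make_design(
            [(g, n) for g, n, _ in self.groups],
            background=background,
            blocked=blocked,
            target_groups=[g for g, _, r in self.groups if r == "target"],
        )


def five_group_config(**kw) -> SimulationConfig:
    """Default layout: 5 groups x 4 replicates (three DNA-stimulus target
    groups plus the two controls)."""
    return SimulationConfig(**kw)


def six_group_triplicate_config(**kw) -> SimulationConfig:
    """Alternative layout: 6 groups x 3 replicates (two DNA-lesion stimuli
    and an extra undamaged-DNA comparison, with both controls)."""
    kw.setdefault(
        "groups",
        (
            ("no_DNA", 3, "target"),
            ("DNA", 3, "target"),
            ("ssDNA_DPC", 3, "target"),
            ("SSB_DPC", 3, "target"),
            ("no_His", 3, "background"),
            ("Ub_E1i", 3, "blocked"),
        ),
    )
    kw.setdefault("affected_groups", ("ssDNA_DPC", "SSB_DPC"))
    return SimulationConfig(**kw)


def two_group_config(
    n_proteins: int = 1000,
    n_regulated: int = 100,
    effect_low: float = 2.0,
    effect_high: float = 4.0,
    **kw,
) -> SimulationConfig:
    """Minimal spike-in benchmark: 4 control vs 4 stimulus replicates, no
    ubiquitin peptide rows, effects applied in the stimulus group only."""
    kw.setdefault("groups", (("ctrl", 4, "target"), ("stim", 4, "target")))
    kw.setdefault("affected_groups", ("stim",))
    kw.setdefault("ubiquitin_fraction_per_role", None)
    return SimulationConfig(
        n_proteins=n_proteins,
        n_regulated=n_regulated,
        effect_low=effect_low,
        effect_high=effect_high,
        **kw,
    )


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated dataset.

    ``effects`` is proteins x groups (log2 additive shifts relative to
    baseline); unregulated proteins have all-zero rows. ``censored`` marks
    the cells dropped by the detection-limit model.
    """

    baseline: pd.Series
    effects: pd.DataFrame
    regulated: pd.Series
    effect_size: pd.Series  # signed log2 effect in the affected groups (0 if unregulated)
    censored: pd.DataFrame
    config: SimulationConfig

    @property
    def ids(self) -> pd.Index:
        return self.baseline.index

    def regulated_between(self, group_a: str, group_b: str) -> pd.Series:
        """True where a protein's expected abundance differs between the
        two groups (the truth set for that contrast)."""
        return self.effects[group_a] != self.effects[group_b]


def _calibrate_midpoint(x: np.ndarray, slope: float, rate: float) -> float:
    """Midpoint of the logistic censoring curve such that the mean dropout
    probability over the realized true intensities equals ``rate``."""

    def mean_rate(mid: float) -> float:
        return float(expit(-(x - mid) * slope).mean())

    lo, hi = x.min() - 50.0, x.max() + 50.0
    return brentq(lambda m: mean_rate(m) - rate, lo, hi, xtol=1e-8)


def simulate_dataset(
    config: SimulationConfig, seed: int | None = None
) -> tuple[ProteinTable, PeptideTable, SampleDesign, SyntheticTruth]:
    """Generate a protein-groups table, peptide table, design, and truth.

    Deterministic under a fixed seed (``seed`` overrides ``config.seed``).
    """
    if seed is None:
        seed = config.seed
    ss = np.random.SeedSequence(seed)
    rng_base, rng_fx, rng_noise, rng_cens, rng_pep = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )
    design = config.to_design()
    ids = pd.Index([f"P{i:05d}" for i in range(config.n_proteins)], name="protein")
    groups = design.groups
    role_of = {g: r for g, _, r in config.groups}

    baseline = pd.Series(
        rng_base.normal(config.base_mean, config.base_sd, config.n_proteins), index=ids
    )

    regulated_idx = rng_fx.choice(config.n_proteins, size=config.n_regulated, replace=False)
    regulated = pd.Series(False, index=ids)
    regulated.iloc[regulated_idx] = True
    magnitudes = rng_fx.uniform(config.effect_low, config.effect_high, config.n_regulated)
    effect_size = pd.Series(0.0, index=ids)
    effect_size.iloc[regulated_idx] = magnitudes

    effects = pd.DataFrame(0.0, index=ids, columns=list(groups))
    for g in groups:
        if g in config.affected_groups:
            effects.loc[regulated, g] = effect_size[regulated]
        elif role_of[g] in ("background", "blocked"):
            effects.loc[regulated, g] = -config.control_attenuation

    # true per-cell log2 intensity = baseline + group effect + replicate noise
    samples = list(design.samples)
    group_effect_cols = np.column_stack([effects[design.group_of[s]].to_numpy() for s in samples])
    true_log2 = (
        baseline.to_numpy()[:, None]
        + group_effect_cols
        + rng_noise.normal(0.0, config.rep_sd, (config.n_proteins, len(samples)))
    )

    if config.missing_rate > 0:
        mid = (
            config.censor_midpoint
            if config.censor_midpoint is not None
            else _calibrate_midpoint(true_log2.ravel(), config.censor_slope, config.missing_rate)
        )
        p_cens = expit(-(true_log2 - mid) * config.censor_slope)
        censored = rng_cens.random(true_log2.shape) < p_cens
    else:
        censored = np.zeros(true_log2.shape, dtype=bool)

    lfq = np.where(censored, 0.0, np.exp2(true_log2))
    lfq_df = pd.DataFrame(lfq, index=ids, columns=samples)

    # iBAQ: LFQ divided by a per-protein count of theoretically observable
    # peptides, widening the apparent absolute-abundance dynamic range.
    n_theoretical = rng_base.integers(1, 60, size=config.n_proteins)
    ibaq_df = lfq_df.div(n_theoretical, axis=0)

    # peptide-level table: split each protein's intensity over a few
    # peptide rows, then add designated ubiquitin peptides per sample.
    pep_frames: list[pd.DataFrame] = []
    k = config.peptides_per_protein
    if k > 0:
        shares = rng_pep.dirichlet(np.ones(k), size=config.n_proteins)  # per protein
        pep_seqs = [f"PEP{i:05d}X{j}" for i in range(config.n_proteins) for j in range(k)]
        prot_of_pep = np.repeat(ids.to_numpy(), k)
        for s_i, s in enumerate(samples):
            inten = (lfq[:, s_i][:, None] * shares).ravel()
            pep_frames.append(
                pd.DataFrame(
                    {
                        "peptide_sequence": pep_seqs,
                        "protein_ids": prot_of_pep,
                        "sample": s,
                        "intensity": inten,
                    }
                )
            )
    ub_lfq = None
    if config.ubiquitin_fraction_per_role is not None:
        n_ub_peps = 4
        ub_shares = rng_pep.dirichlet(np.ones(n_ub_peps))
        ub_totals = []
        for s_i, s in enumerate(samples):
            role = role_of[design.group_of[s]]
            frac = config.ubiquitin_fraction_per_role.get(role, 0.0)
            total_nonub = float(lfq[:, s_i].sum())
            # f = ub / (ub + nonub)  =>  ub = nonub * f / (1 - f)
            ub_total = total_nonub * frac / (1.0 - frac)
            ub_totals.append(ub_total)
            if ub_total > 0:
                pep_frames.append(
                    pd.DataFrame(
                        {
                            "peptide_sequence": [f"UBPEP{j}" for j in range(n_ub_peps)],
                            "protein_ids": UBIQUITIN_ACCESSION,
                            "sample": s,
                            "intensity": ub_total * ub_shares,
                        }
                    )
                )
        ub_lfq = pd.Series(ub_totals, index=samples)

    peptides = PeptideTable(
        df=pd.concat(pep_frames, ignore_index=True)
        if pep_frames
        else pd.DataFrame(columns=["peptide_sequence", "protein_ids", "sample", "intensity"]),
        design=design,
    )

    # assemble protein table; the ubiquitin protein-group row is derived by
    # summing its peptides and sits outside the simulated truth set.
    if ub_lfq is not None:
        lfq_df = pd.concat(
            [lfq_df, pd.DataFrame([ub_lfq.to_numpy()], index=[UBIQUITIN_ACCESSION], columns=samples)]
        )
        lfq_df.index.name = "protein"
        ibaq_df = pd.concat(
            [ibaq_df, pd.DataFrame([ub_lfq.to_numpy() / 10.0], index=[UBIQUITIN_ACCESSION], columns=samples)]
        )
        ibaq_df.index.name = "protein"
    all_ids = lfq_df.index
    gene_names = pd.Series(
        [f"gene{i}" for i in range(config.n_proteins)]
        + (["ubb"] if ub_lfq is not None else []),
        index=all_ids,
    )
    flags = pd.DataFrame(
        {"reverse": False, "contaminant": False, "site_only": False}, index=all_ids
    )
    table = ProteinTable(
        protein_ids=pd.Series(all_ids.to_numpy(), index=all_ids),
        gene_names=gene_names,
        flags=flags,
        lfq=lfq_df,
        ibaq=ibaq_df,
        design=design,
    )
    truth = SyntheticTruth(
        baseline=baseline,
        effects=effects,
        regulated=regulated,
        effect_size=effect_size,
        censored=pd.DataFrame(censored, index=ids, columns=samples),
        config=config,
    )
    return table, peptides, design, truth


def evaluate_calls(calls: pd.Series, truth: SyntheticTruth, positive: pd.Series | None = None) -> dict:
    """Confusion summary of significance calls against simulated truth.

    ``calls`` is a boolean Series indexed exactly by the truth's protein
    identifiers. ``positive`` overrides the truth set (e.g.
    ``truth.regulated_between(a, b)`` for a specific contrast); default is
    the global regulated flag.

    Returns tp, fp, fn, realized_fdp = fp / max(1, tp + fp) and
    sensitivity = tp / max(1, tp + fn).
    """
    if set(calls.index) != set(truth.ids):
        raise ValueError("calls are not indexed by the truth's protein identifiers")
    calls = calls.reindex(truth.ids).astype(bool)
    pos = (positive if positive is not None else truth.regulated).reindex(truth.ids).astype(bool)
    tp = int((calls & pos).sum())
    fp = int((calls & ~pos).sum())
    fn = int((~calls & pos).sum())
    return {
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "realized_fdp": fp / max(1, tp + fp),
        "sensitivity": tp / max(1, tp + fn),
    }
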