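"""Log2 transform, presence filtering, and left-censored imputation.

Label-free intensities are missing not at random: values drop out
preferentially below the detection limit. The standard remedy, applied
here, is (i) require a protein to be fully observed in at least one sample
group before testing, and (ii) replace remaining missing cells with draws
from a Gaussian placed *below* the bulk of observed values — centred
``downshift`` global standard deviations under the global observed mean,
with width a fraction of the global SD (defaults 1.8 and 0.3, the
convention of mainstream proteomics analysis software).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

from .design import SampleDesign

__all__ = [
    "OBSERVED",
    "MISSING",
    "IMPUTED",
    "LogMatrix",
    "AnalysisConfig",
    "to_log_matrix",
    "filter_min_valid",
    "impute_lowshift",
]

OBSERVED = "observed"
MISSING = "missing"
IMPUTED = "imputed"


@dataclass
class AnalysisConfig:
    """Tunable parameters of the quantitative analysis.

    min_valid_fraction : fraction of replicates that must be observed within
        some group for a protein to be retained (1.0 = all replicates of at
        least one group).
    downshift, width : location shift and scale of the imputation Gaussian,
        in units of the global observed SD (log2 space).
    s0 : moderation constant added to the denominator of the two-sample
        statistic, damping significance of tiny fold changes.
    n_perm : number of sample relabellings for the permutation FDR.
    fdr : control level for significance calls.
    impute_mode : "global" uses matrix-wide mean/SD (the default,
        matching a global detection limit); "per_column" recomputes them
        per sample for sensitivity analysis.
    gate_scope : "any" calls a protein enriched if it passes the double
        control gate in at least one target group; "all" requires every
        target group.
    """

    min_valid_fraction: float = 1.0
    downshift: float = 1.8
    width: float = 0.3
    s0: float = 0.1
    n_perm: int = 2500
    fdr: float = 0.05
    seed: int = 0
    impute_mode: Literal["global", "per_column"] = "global"
    gate_scope: Literal["any", "all"] = "any"

    def __post_init__(self) -> None:
        if not (0 < self.min_valid_fraction <= 1):
            raise ValueError("min_valid_fraction must be in (0, 1]")
        if self.width <= 0:
            raise ValueError("width must be > 0")
        if self.s0 < 0:
            raise ValueError("s0 must be >= 0")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not (0 < self.fdr < 1):
            raise ValueError("fdr must be in (0, 1)")
        if self.impute_mode not in ("global", "per_column"):
            raise ValueError("impute_mode must be 'global' or 'per_column'")
        if self.gate_scope not in ("any", "all"):
            raise ValueError("gate_scope must be 'any' or 'all'")

    def with_seed(self, seed: int) -> "AnalysisConfig":
        return replace(self, seed=seed)


@dataclass
class LogMatrix:
    """Proteins x samples log2 intensities with per-cell provenance.

    ``values`` holds log2 intensities (NaN where missing); ``mask`` holds one
    of ``observed`` / ``missing`` / ``imputed`` per cell. Observed cells are
    never altered by imputation.
    """

    values: pd.DataFrame
    mask: pd.DataFrame
    design: SampleDesign

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.mask.index) or not self.values.columns.equals(
            self.mask.columns
        ):
            raise ValueError("values and mask must share index and columns")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate row labels")
        if list(self.values.columns) != list(self.design.samples):
            raise ValueError("matrix columns do not match design samples")
        bad = ~self.mask.isin([OBSERVED, MISSING, IMPUTED]).to_numpy()
        if bad.any():
            raise ValueError("mask contains invalid provenance codes")
        nan_but_not_missing = self.values.isna().to_numpy() & (
            self.mask != MISSING
        ).to_numpy()
        if nan_but_not_missing.any():
            raise ValueError("NaN value in a cell not marked missing")

    @property
    def observed(self) -> pd.DataFrame:
        return self.mask == OBSERVED

    @property
    def n_missing(self) -> int:
        return int((self.mask == MISSING).to_numpy().sum())

    @property
    def is_complete(self) -> bool:
        return self.n_missing == 0

    def require_complete(self, context: str = "operation") -> None:
        if not self.is_complete:
            raise ValueError(
                f"{context} requires a complete (imputed) matrix; "
                f"{self.n_missing} missing cells remain"
            )

    def subset_rows(self, ids) -> "LogMatrix":
        return LogMatrix(self.values.loc[ids], self.mask.loc[ids], self.design)

    def copy(self) -> "LogMatrix":
        return LogMatrix(self.values.copy(), self.mask.copy(), self.design)


def to_log_matrix(table, design: SampleDesign | None = None) -> LogMatrix:
    """log2-transform LFQ intensities; zeros become explicit missing cells.

    Accepts a :class:`~ubiquant.io_tables.ProteinTable` or a raw linear-scale
    DataFrame (then ``design`` is required).
    """
    if design is None:
        design = table.design
    lfq = table if isinstance(table, pd.DataFrame) else table.lfq
    arr = lfq[list(design.samples)].to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("negative intensity")
    with np.errstate(divide="ignore"):
        vals = np.where(arr > 0, np.log2(np.where(arr > 0, arr, 1.0)), np.nan)
    values = pd.DataFrame(vals, index=lfq.index, columns=list(design.samples))
    mask = pd.DataFrame(
        np.where(arr > 0, OBSERVED, MISSING), index=lfq.index, columns=list(design.samples)
    )
    return LogMatrix(values=values, mask=mask, design=design)


def filter_min_valid(m: LogMatrix, cfg: AnalysisConfig) -> LogMatrix:
    """Keep rows observed in >= ceil(min_valid_fraction * n_g) replicates of
    at least one group (default: all replicates of some group)."""
    if not m.design.groups:
        raise ValueError("design has no groups")
    obs = m.observed
    keep = pd.Series(False, index=m.values.index)
    for g in m.design.groups:
        cols = list(m.design.samples_of(g))
        need = math.ceil(cfg.min_valid_fraction * len(cols))
        keep |= obs[cols].sum(axis=1) >= need
    if not keep.any():
        warnings.warn("presence filter removed every row", stacklevel=2)
    return LogMatrix(m.values[keep], m.mask[keep], m.design)


def impute_lowshift(m: LogMatrix, cfg: AnalysisConfig) -> LogMatrix:
    """Replace missing cells with downshifted-Gaussian draws.

    With global statistics mu, sigma over all observed log2 values, each
    missing cell is drawn independently from
    Normal(mu - downshift * sigma, (width * sigma)^2). Observed cells are
    returned bit-identically; the mask records which cells were imputed.
    Reproducible under a fixed ``cfg.seed``.
    """
    obs_mask = m.observed.to_numpy()
    if obs_mask.sum() < 2:
        raise ValueError("need at least 2 observed cells to impute")
    values = m.values.to_numpy(dtype=float).copy()
    missing = (m.mask == MISSING).to_numpy()
    rng = np.random.default_rng(cfg.seed)
    if cfg.impute_mode == "global":
        obs_vals = values[obs_mask]
        mu = float(obs_vals.mean())
        sigma = float(obs_vals.std(ddof=0))
        if sigma == 0:
            raise ValueError("degenerate matrix: zero variance among observed values")
        draws = rng.normal(mu - cfg.downshift * sigma, cfg.width * sigma, size=int(missing.sum()))
        values[missing] = draws
    else:  # per-column detection limit
        for j in range(values.shape[1]):
            col_obs = values[obs_mask[:, j], j]
            col_missing = missing[:, j]
            if not col_missing.any():
                continue
            if col_obs.size < 2 or col_obs.std(ddof=0) == 0:
                raise ValueError(f"degenerate column {m.values.columns[j]!r} for imputation")
            mu = float(col_obs.mean())
            sigma = float(col_obs.std(ddof=0))
            values[col_missing, j] = rng.normal(
                mu - cfg.downshift * sigma, cfg.width * sigma, size=int(col_missing.sum())
            )
    new_mask = m.mask.where(~pd.DataFrame(missing, index=m.mask.index, columns=m.mask.columns), IMPUTED)
    return LogMatrix(
        values=pd.DataFrame(values, index=m.values.index, columns=m.values.columns),
        mask=new_mask,
        design=m.design,
    )
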