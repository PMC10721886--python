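"""Moderated two-sample statistics with permutation-based FDR control.

The statistic is the SAM-style construction: for group means a-bar, b-bar
and pooled standard error s,

    d = (a-bar - b-bar) / (s + s0),

where ``s0`` is a small positive constant that damps the significance of
tiny fold changes measured with tiny variance. Significance is assessed by
recomputing d under random relabellings of the samples: for a threshold t,
the estimated FDR is the mean number of permuted statistics at least as
extreme as t divided by the number of observed statistics at least as
extreme, capped at 1. Per-protein q-values are the running minimum of this
estimate from the most extreme observed statistic downwards, so q is
monotone non-decreasing as |d| decreases. When the number of distinct
relabellings does not exceed the requested permutation count, all of them
(including the identity) are enumerated exactly once; otherwise distinct
non-identity relabellings are sampled uniformly without replacement. No
null-proportion (pi0) estimate is applied; the estimator is deliberately
conservative.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .design import SampleDesign
from .preprocess import AnalysisConfig, LogMatrix

__all__ = [
    "moderated_d",
    "permutation_qvalues",
    "control_gate",
    "combine_gates",
    "condition_contrast",
]

Tail = Literal["two_sided", "greater"]


def _pooled_se(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pooled standard error of a difference in means, rows = proteins."""
    nA, nB = a.shape[1], b.shape[1]
    ssa = ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ssb = ((b - b.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    pooled_var = (ssa + ssb) / (nA + nB - 2)
    return np.sqrt((1.0 / nA + 1.0 / nB) * pooled_var)


def _d_stat(a: np.ndarray, b: np.ndarray, s0: float) -> tuple[np.ndarray, np.ndarray]:
    diff = a.mean(axis=1) - b.mean(axis=1)
    denom = _pooled_se(a, b) + s0
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(denom > 0, diff / np.where(denom > 0, denom, 1.0), np.where(diff == 0, 0.0, np.inf * np.sign(diff)))
    return diff, d


def moderated_d(a: Sequence[float], b: Sequence[float], s0: float) -> tuple[float, float]:
    """Difference of means and s0-moderated statistic for one protein.

    Returns ``(diff, d)`` with ``diff = mean(a) - mean(b)`` and
    ``d = diff / (s + s0)`` where s is the pooled standard error. With
    ``s0 = 0`` this is the two-sample Student t statistic; with zero
    within-group variance it reduces to ``diff / s0``.
    """
    a_arr = np.asarray(a, dtype=float)
    b_arr = np.asarray(b, dtype=float)
    if a_arr.ndim != 1 or b_arr.ndim != 1:
        raise ValueError("a and b must be 1-D")
    if a_arr.size < 2 or b_arr.size < 2:
        raise ValueError("each group needs at least 2 values")
    if np.isnan(a_arr).any() or np.isnan(b_arr).any():
        raise ValueError("missing values must be imputed before testing")
    diff, d = _d_stat(a_arr[None, :], b_arr[None, :], s0)
    return float(diff[0]), float(d[0])


def _relabellings(
    n: int, nA: int, n_perm: int, rng: np.random.Generator
) -> list[tuple[int, ...]]:
    """Index sets assigned to group A under the null.

    Enumerates all C(n, nA) assignments (identity included) when that count
    is <= n_perm; otherwise samples n_perm distinct non-identity assignments
    uniformly without replacement.
    """
    total = comb(n, nA)
    if total < 2:
        raise ValueError("fewer than 2 distinct relabellings; cannot permute")
    if total <= n_perm:
        return [tuple(c) for c in combinations(range(n), nA)]
    identity = tuple(range(nA))
    chosen: set[tuple[int, ...]] = set()
    while len(chosen) < n_perm:
        perm = rng.permutation(n)
        cand = tuple(sorted(perm[:nA].tolist()))
        if cand != identity:
            chosen.add(cand)
    return sorted(chosen)


def _tail_stat(d: np.ndarray, tail: Tail) -> np.ndarray:
    return np.abs(d) if tail == "two_sided" else d


def permutation_qvalues(
    m: LogMatrix | pd.DataFrame,
    samples_a: Sequence[str],
    samples_b: Sequence[str],
    cfg: AnalysisConfig,
    tail: Tail = "two_sided",
) -> pd.DataFrame:
    """Per-protein moderated statistics with permutation-FDR q-values.

    Parameters
    ----------
    m
        Complete (imputed) log2 matrix, or a plain DataFrame of values.
    samples_a, samples_b
        Column names of the two groups; ``diff`` is A minus B.
    tail
        ``two_sided`` ranks proteins by |d|; ``greater`` by signed d
        (one-tailed enrichment of A over B).

    Returns
    -------
    DataFrame indexed by protein with columns ``diff``, ``d``, ``p_perm``,
    ``q``, ``direction``, ``significant``.
    """
    if isinstance(m, LogMatrix):
        m.require_complete("permutation testing")
        values = m.values
    else:
        values = m
        if values.isna().to_numpy().any():
            raise ValueError("matrix contains missing values; impute first")
    samples_a = list(samples_a)
    samples_b = list(samples_b)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    X = values[samples_a + samples_b].to_numpy(dtype=float)
    nA = len(samples_a)
    n = X.shape[1]

    rng = np.random.default_rng(cfg.seed)
    assignments = _relabellings(n, nA, cfg.n_perm, rng)
    B = len(assignments)

    diff_obs, d_obs = _d_stat(X[:, :nA], X[:, nA:], cfg.s0)
    s_obs = _tail_stat(d_obs, tail)

    all_idx = np.arange(n)
    perm_stats = np.empty((X.shape[0], B))
    for k, a_idx in enumerate(assignments):
        a_cols = np.asarray(a_idx)
        b_cols = np.setdiff1d(all_idx, a_cols, assume_unique=True)
        _, d_perm = _d_stat(X[:, a_cols], X[:, b_cols], cfg.s0)
        perm_stats[:, k] = _tail_stat(d_perm, tail)

    # Per-protein tail probability against its own permutation distribution.
    exceed_own = (perm_stats >= s_obs[:, None]).sum(axis=1)
    p_perm = exceed_own / B

    # Pooled FDR estimate at each observed threshold (ties share one
    # threshold and are counted together).
    thresholds = np.unique(s_obs)[::-1]  # descending: most extreme first
    pooled = np.sort(perm_stats.ravel())
    obs_sorted = np.sort(s_obs)
    n_obs_beyond = len(s_obs) - np.searchsorted(obs_sorted, thresholds, side="left")
    n_perm_beyond = pooled.size - np.searchsorted(pooled, thresholds, side="left")
    mean_perm_beyond = n_perm_beyond / B
    fdr_t = np.minimum(1.0, mean_perm_beyond / n_obs_beyond)

    # q per protein: the smallest estimated FDR over all thresholds at which
    # the protein would be called (t <= its own statistic), i.e. a running
    # minimum taken from the least extreme threshold backwards. This is the
    # monotone enforcement that keeps q non-decreasing as |d| decreases.
    q_t = np.minimum.accumulate(fdr_t[::-1])[::-1]
    order = np.searchsorted(-thresholds, -s_obs)  # position of each protein's threshold
    q = q_t[order]

    diff_sign = np.sign(diff_obs)
    direction = np.where(diff_sign >= 0, "up", "down")
    significant = q <= cfg.fdr

    return pd.DataFrame(
        {
            "diff": diff_obs,
            "d": d_obs,
            "p_perm": p_perm,
            "q": q,
            "direction": direction,
            "significant": significant,
        },
        index=values.index,
    )


def control_gate(
    vs_background: pd.DataFrame,
    vs_blocked: pd.DataFrame,
    cfg: AnalysisConfig,
) -> pd.DataFrame:
    """Double-control enrichment gate for one target group.

    Both inputs must be one-tailed (``greater``) test results over the same
    protein set: enrichment of the target group over the background pulldown
    control and over the conjugation-blocked control, respectively. A
    protein passes the gate only when significantly enriched (q <= fdr with
    positive difference) over *both* controls.
    """
    if not vs_background.index.equals(vs_blocked.index):
        raise ValueError("control gate inputs cover different protein sets")
    enriched_bg = (vs_background["q"] <= cfg.fdr) & (vs_background["diff"] > 0)
    enriched_bl = (vs_blocked["q"] <= cfg.fdr) & (vs_blocked["diff"] > 0)
    return pd.DataFrame(
        {
            "enriched_over_background": enriched_bg,
            "enriched_over_blocked": enriched_bl,
            "gated": enriched_bg & enriched_bl,
        },
        index=vs_background.index,
    )


def combine_gates(per_group: dict[str, pd.DataFrame], scope: Literal["any", "all"] = "any") -> pd.DataFrame:
    """Combine per-target-group gate tables into an overall call.

    ``any`` (default): a protein enriched in at least one target group is
    considered a ubiquitylation target overall; ``all`` requires every group.
    Adds a ``supporting_groups`` column listing the passing groups.
    """
    if not per_group:
        raise ValueError("no gate tables given")
    frames = list(per_group.values())
    idx = frames[0].index
    for f in frames[1:]:
        if not f.index.equals(idx):
            raise ValueError("gate tables cover different protein sets")
    gated = pd.DataFrame({g: t["gated"] for g, t in per_group.items()})
    overall = gated.any(axis=1) if scope == "any" else gated.all(axis=1)
    supporting = gated.apply(lambda row: ";".join(g for g in gated.columns[row]), axis=1)
    return pd.DataFrame({"gated": overall, "supporting_groups": supporting}, index=idx)


def condition_contrast(
    m: LogMatrix,
    design: SampleDesign,
    group_a: str,
    group_b: str,
    cfg: AnalysisConfig,
    tail: Tail = "two_sided",
) -> pd.DataFrame:
    """Two-group contrast (volcano table) between conditions.

    Runs :func:`permutation_qvalues` on the two groups' samples and adds the
    volcano coordinates: ``diff`` (x-axis) and ``neg_log10_p`` (y-axis,
    clipped at the permutation resolution), plus an ``enriched`` /
    ``depleted`` / ``ns`` label at the configured FDR.
    """
    res = permutation_qvalues(
        m, design.samples_of(group_a), design.samples_of(group_b), cfg, tail=tail
    )
    # p_perm can be 0 when no permuted statistic reaches the observed one;
    # clip at one pooled-count unit so -log10 stays finite.
    floor = 1.0 / (len(res) * max(cfg.n_perm, 1))
    res["neg_log10_p"] = -np.log10(np.maximum(res["p_perm"], floor))
    label = np.where(
        res["significant"] & (res["diff"] > 0),
        "enriched",
        np.where(res["significant"] & (res["diff"] < 0), "depleted", "ns"),
    )
    res["label"] = label
    res.attrs["contrast"] = (group_a, group_b)
    return res
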