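"""Rank statistics for cohort-level association analyses.

Spearman correlations with permutation p-values are the workhorse: the
p-value comes from the exact permutation distribution when the sample is
small enough to enumerate (n <= 9) and from seeded Monte-Carlo permutation
otherwise.  Partial Spearman correlation controls an association for a
third variable by correlating rank residuals.  Multiple testing across
drug-response compounds is handled with Benjamini-Hochberg FDR, and a
cohort-level empirical p-value is obtained by shuffling the response data
and re-measuring the fraction of significant compounds.

Ties receive mid-ranks throughout.  All Monte-Carlo paths are
deterministic given their seed, and empirical p-values use the add-one
estimator so they are never exactly zero.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AssociationResult",
    "ResponseAssociationSummary",
    "spearman_exact",
    "partial_spearman",
    "bh_fdr",
    "response_association",
]

EXACT_N_MAX = 9
MC_DRAWS = 100_000
_EPS = 1e-12


@dataclass
class AssociationResult:
    rho: float
    p: float
    n: int
    method: str  # "exact" | "montecarlo"
    sidedness: str  # "two-sided" | "greater" | "less"
    undefined: bool = False


@dataclass
class ResponseAssociationSummary:
    per_compound: pd.DataFrame  # compound, rho, p, p_adj, significant, sign
    fraction_significant: float
    fraction_positive_of_significant: float
    empirical_p: float
    n_shuffles: int
    growth_screen: Optional[pd.DataFrame] = None
    measure_specific_compounds: List[str] = field(default_factory=list)


def _midranks(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def _rho_of_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        return math.nan
    return float(np.corrcoef(rx, ry)[0, 1])


def _perm_pvalue(rho_obs: float, rho_perm: np.ndarray, sidedness: str, exact: bool) -> float:
    if sidedness == "two-sided":
        hits = np.sum(np.abs(rho_perm) >= abs(rho_obs) - _EPS)
    elif sidedness == "greater":
        hits = np.sum(rho_perm >= rho_obs - _EPS)
    elif sidedness == "less":
        hits = np.sum(rho_perm <= rho_obs + _EPS)
    else:
        raise ValueError(f"unknown sidedness {sidedness!r}")
    if exact:
        return float(hits) / len(rho_perm)
    return (1.0 + float(hits)) / (1.0 + len(rho_perm))


def spearman_exact(
    x: Sequence[float],
    y: Sequence[float],
    sidedness: str = "two-sided",
    seed: int = 0,
    n_draws: int = MC_DRAWS,
) -> AssociationResult:
    """Spearman rho with a permutation p-value.

    Exhaustive over all n! orderings for n <= 9; otherwise seeded
    Monte-Carlo with ``n_draws`` permutations (add-one estimator).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    rx, ry = _midranks(x), _midranks(y)
    rho = _rho_of_ranks(rx, ry)
    if math.isnan(rho):
        return AssociationResult(math.nan, math.nan, n, "exact", sidedness, undefined=True)
    rxc = (rx - rx.mean()) / (rx.std() * n)
    ryc = ry - ry.mean()
    if n <= EXACT_N_MAX:
        perms = np.array(list(itertools.permutations(range(n))))
        rho_perm = (ryc[perms] @ rxc) / ry.std()
        return AssociationResult(rho, _perm_pvalue(rho, rho_perm, sidedness, exact=True), n, "exact", sidedness)
    rng = np.random.default_rng(seed)
    idx = np.argsort(rng.random((n_draws, n)), axis=1)
    rho_perm = (ryc[idx] @ rxc) / ry.std()
    return AssociationResult(rho, _perm_pvalue(rho, rho_perm, sidedness, exact=False), n, "montecarlo", sidedness)


def _rank_residuals(r: np.ndarray, rz: np.ndarray) -> np.ndarray:
    zc = rz - rz.mean()
    denom = float(zc @ zc)
    if denom == 0:
        return r - r.mean()
    beta = float((r - r.mean()) @ zc) / denom
    return (r - r.mean()) - beta * zc


def partial_spearman(
    x: Sequence[float],
    y: Sequence[float],
    z: Sequence[float],
    sidedness: str = "two-sided",
    seed: int = 0,
    n_draws: int = MC_DRAWS,
) -> AssociationResult:
    """Partial Spearman correlation of x and y given z.

    Ranks of x and y are each regressed on the ranks of z and the
    residuals correlated.  The permutation p-value permutes x's ranks,
    breaking the x-(y,z) link while preserving the y-z relation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if not (x.shape == y.shape == z.shape) or x.ndim != 1:
        raise ValueError("x, y, z must be equal-length 1-d vectors")
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 observations")
    rx, ry, rz = _midranks(x), _midranks(y), _midranks(z)
    if rx.std() == 0 or ry.std() == 0:
        return AssociationResult(math.nan, math.nan, n, "exact", sidedness, undefined=True)
    ey = _rank_residuals(ry, rz)
    ex = _rank_residuals(rx, rz)
    if ex.std() == 0 or ey.std() == 0:
        # a variable fully explained by the control leaves nothing to correlate
        return AssociationResult(0.0, 1.0, n, "exact", sidedness)
    rho = float(np.corrcoef(ex, ey)[0, 1])

    def stat(perm_rx: np.ndarray) -> float:
        e = _rank_residuals(perm_rx, rz)
        s = e.std()
        if s == 0:
            return 0.0
        return float(np.corrcoef(e, ey)[0, 1])

    if n <= EXACT_N_MAX:
        rho_perm = np.array([stat(rx[list(p)]) for p in itertools.permutations(range(n))])
        return AssociationResult(rho, _perm_pvalue(rho, rho_perm, sidedness, exact=True), n, "exact", sidedness)
    rng = np.random.default_rng(seed)
    rho_perm = np.empty(n_draws)
    for i in range(n_draws):
        rho_perm[i] = stat(rx[rng.permutation(n)])
    return AssociationResult(rho, _perm_pvalue(rho, rho_perm, sidedness, exact=False), n, "montecarlo", sidedness)


def bh_fdr(pvalues: Sequence[float], alpha: float = 0.05):
    """Benjamini-Hochberg step-up: (significance mask, adjusted p-values)."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    mask, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return mask, p_adj


def _fast_spearman_pvalues(measure: np.ndarray, responses: np.ndarray) -> np.ndarray:
    """Analytic (t-approximation) two-sided Spearman p per response row,
    vectorised over rows for use inside the shuffle loop."""
    n = len(measure)
    rm = sps.rankdata(measure)
    rm = (rm - rm.mean()) / (rm.std() * n)
    rr = sps.rankdata(responses, axis=1)
    sd = rr.std(axis=1)
    sd[sd == 0] = np.inf
    rho = ((rr - rr.mean(axis=1, keepdims=True)) @ rm) / sd
    rho = np.clip(rho, -1.0 + 1e-15, 1.0 - 1e-15)
    t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
    return np.clip(p, np.nextafter(0, 1), 1.0)


def _wilcoxon_split_pvalues(measure: np.ndarray, responses: np.ndarray) -> np.ndarray:
    """Rank-sum p per compound between high- and low-measure line groups."""
    order = np.argsort(measure)
    half = len(measure) // 2
    lo, hi = order[:half], order[half:]
    out = np.empty(len(responses))
    for i, row in enumerate(responses):
        out[i] = sps.mannwhitneyu(row[hi], row[lo], alternative="two-sided").pvalue
    return np.clip(out, np.nextafter(0, 1), 1.0)


def response_association(
    measure: pd.Series,
    responses: pd.DataFrame,
    growth: Optional[pd.Series] = None,
    n_shuffles: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    shuffle_statistic: str = "spearman",
    n_draws: int = 10_000,
) -> ResponseAssociationSummary:
    """Associate a per-line measure with a compounds x lines response matrix.

    Per compound: Spearman rho with a permutation p-value, BH-FDR at
    ``alpha``; the summary reports the significant fraction and its sign
    split.  The cohort-level empirical p-value shuffles each compound's
    responses across lines ``n_shuffles`` times and counts shuffled
    cohorts whose significant fraction reaches the observed one, using a
    fast per-compound statistic (``spearman`` analytic p or ``wilcoxon``
    median-split rank-sum) inside the shuffle loop.

    When ``growth`` is given, compounds significantly associated with the
    measure but not with growth (raw p >= alpha) are listed as
    measure-specific.
    """
    lines = list(responses.columns)
    if list(measure.index) != lines:
        measure = measure.reindex(lines)
        if measure.isna().any():
            raise ValueError("measure and response matrix line ids are misaligned")
    if len(responses) < 2:
        raise ValueError("need at least 2 compounds")

    rows = []
    for comp, row in responses.iterrows():
        res = spearman_exact(measure.to_numpy(), row.to_numpy(), seed=seed, n_draws=n_draws)
        rows.append({"compound": comp, "rho": res.rho, "p": res.p, "method": res.method})
    per = pd.DataFrame(rows).set_index("compound")
    mask, p_adj = bh_fdr(per["p"].to_numpy(), alpha=alpha)
    per["p_adj"] = p_adj
    per["significant"] = mask
    per["sign"] = np.sign(per["rho"])
    frac = float(mask.mean())
    pos = float((per.loc[per["significant"], "sign"] > 0).mean()) if mask.any() else math.nan

    # cohort-level empirical p via shuffles with a fast statistic
    stat_fn = _fast_spearman_pvalues if shuffle_statistic == "spearman" else _wilcoxon_split_pvalues
    mvec = measure.to_numpy()
    R = responses.to_numpy()
    obs_fast = stat_fn(mvec, R)
    obs_frac_fast = float(bh_fdr(obs_fast, alpha=alpha)[0].mean())
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_shuffles):
        shuffled = np.take_along_axis(R, np.argsort(rng.random(R.shape), axis=1), axis=1)
        frac_s = float(bh_fdr(stat_fn(mvec, shuffled), alpha=alpha)[0].mean())
        if frac_s >= obs_frac_fast - _EPS:
            hits += 1
    empirical_p = (1.0 + hits) / (1.0 + n_shuffles)

    growth_frame = None
    specific: List[str] = []
    if growth is not None:
        growth = growth.reindex(lines)
        grows = []
        for comp, row in responses.iterrows():
            res = spearman_exact(growth.to_numpy(), row.to_numpy(), seed=seed, n_draws=n_draws)
            grows.append({"compound": comp, "rho_growth": res.rho, "p_growth": res.p})
        growth_frame = pd.DataFrame(grows).set_index("compound")
        specific = list(per.index[(per["significant"]) & (growth_frame["p_growth"] >= alpha)])

    return ResponseAssociationSummary(
        per_compound=per.reset_index(),
        fraction_significant=frac,
        fraction_positive_of_significant=pos,
        empirical_p=empirical_p,
        n_shuffles=n_shuffles,
        growth_screen=None if growth_frame is None else growth_frame.reset_index(),
        measure_specific_compounds=specific,
    )
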