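"""Three-stage anti-migratory knockout screen.

Every candidate reaction is knocked out in every cell-line model and
filtered in three stages:

1. **Lactate abolition** - the knockout drives the minimal lactate
   secretion at maximal growth to (numerical) zero in all lines: the
   Warburg phenotype is no longer forced.
2. **Growth sparing** - knockout growth stays above 10% of the wild-type
   optimum (strict inequality), so the perturbation is anti-Warburg
   rather than cytotoxic.
3. **AFR reduction** - the sampled glycolytic-to-oxidative ATP flux ratio
   falls below 60% of its wild-type level (strict), i.e. the bioenergetic
   balance genuinely shifts away from aerobic glycolysis.

Optionally a normal-proliferating cohort must also keep > 10% growth
under the knockout (normal-cohort sparing).  Survivors are mapped to the
genes of their catalysing enzymes, annotated by whether a single-gene
knockdown suffices to close the reaction (no isoenzyme backup).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .metrics import MetricConfig, compute_metrics, forced_lactate
from .model import InfeasibleModelError, StoichiometricModel, knockout_reaction, solve_fba
from .sampling import sample_optimal_face
from .tailoring import CellLineModel, ExpressionProfile

__all__ = [
    "ScreenConfig",
    "ScreenRecord",
    "run_screen",
    "screen_summary",
    "map_targets_to_genes",
    "target_expression_test",
]


@dataclass
class ScreenConfig:
    growth_fraction_threshold: float = 0.10
    afr_fraction_threshold: float = 0.60
    lactate_zero_tolerance: float = 1e-6
    require_all_lines: bool = True  # growth sparing in every line (vs mean)
    include_exchanges: bool = False
    afr_mean_mode: bool = True  # stage 3 on the mean AFR fraction across lines
    n_samples: int = 1000
    seed: int = 0
    burn_in: int = 1000
    thinning: int = 100

    def __post_init__(self):
        if not 0 < self.growth_fraction_threshold <= 1:
            raise ValueError("growth threshold must lie in (0, 1]")
        if not 0 < self.afr_fraction_threshold < 1:
            raise ValueError("AFR threshold must lie in (0, 1)")


@dataclass
class ScreenRecord:
    """Per-knockout outcome across the cohort, with the full verdict trail."""

    reaction_id: str
    per_line: pd.DataFrame  # line, wt_growth, ko_growth, growth_fraction, ko_min_lactate, wt_afr, ko_afr, afr_fraction
    lactate_abolished: bool
    growth_spared: bool
    afr_reduced: Optional[bool]  # None when stage 3 was not reached
    normal_spared: Optional[bool]
    mapped_genes: frozenset = frozenset()

    @property
    def survives(self) -> bool:
        return bool(
            self.lactate_abolished
            and self.growth_spared
            and self.afr_reduced
            and (self.normal_spared is not False)
        )


def _ko_growth_and_lactate(
    model: StoichiometricModel, rid: str, lactate: str, tol: float
):
    ko = knockout_reaction(model, rid)
    sol = solve_fba(ko)
    if not sol.optimal or sol.objective_value <= tol:
        return ko, 0.0, 0.0  # lethal or infeasible: recorded, not skipped
    mu, lac = forced_lactate(ko, lactate)
    return ko, mu, lac


def run_screen(
    cohort: Sequence[CellLineModel],
    config: ScreenConfig,
    metric_config: MetricConfig,
    reactions: Optional[Sequence[str]] = None,
    normal_cohort: Optional[Sequence[CellLineModel]] = None,
) -> List[ScreenRecord]:
    """Run the three-stage screen over a cohort of cell-line models.

    ``reactions`` defaults to every internal (non-exchange) reaction with
    the biomass export excluded; exchanges are included only when the
    config says so.  The sampled AFR (stage 3) is evaluated only for
    knockouts that pass stages 1-2, as in the screening procedure the
    thresholds come from.
    """
    if not cohort:
        raise ValueError("empty cohort")
    ref = cohort[0].model
    if reactions is None:
        reactions = [
            r.id
            for r in ref.reactions
            if r.id != ref.objective_reaction and (config.include_exchanges or not r.is_exchange)
        ]
    else:
        reactions = [rid for rid in reactions if rid != ref.objective_reaction]

    lactate = metric_config.lactate_exchange
    tol = config.lactate_zero_tolerance

    # wild-type state per line
    wt_growth: Dict[str, float] = {}
    wt_afr: Dict[str, float] = {}
    for cm in cohort:
        mu, lac = forced_lactate(cm.model, lactate)
        if mu <= 0 or lac <= tol:
            raise ValueError(
                f"line {cm.line_id}: screen requires positive wild-type growth and forced lactate"
            )
        wt_growth[cm.line_id] = mu
        ss = sample_optimal_face(
            cm.model, n=config.n_samples, seed=config.seed,
            burn_in=config.burn_in, thinning=config.thinning, line_id=cm.line_id,
        )
        m = compute_metrics(ss, metric_config, cm.model)
        if m.afr is None or m.afr <= 0:
            raise ValueError(f"line {cm.line_id}: wild-type AFR undefined or zero")
        wt_afr[cm.line_id] = m.afr

    records: List[ScreenRecord] = []
    for rid in reactions:
        rows = []
        ko_models = {}
        for cm in cohort:
            ko, mu_ko, lac_ko = _ko_growth_and_lactate(cm.model, rid, lactate, tol)
            ko_models[cm.line_id] = ko
            rows.append(
                {
                    "line": cm.line_id,
                    "wt_growth": wt_growth[cm.line_id],
                    "ko_growth": mu_ko,
                    "growth_fraction": mu_ko / wt_growth[cm.line_id],
                    "ko_min_lactate": lac_ko,
                    "wt_afr": wt_afr[cm.line_id],
                    "ko_afr": math.nan,
                    "afr_fraction": math.nan,
                }
            )
        per_line = pd.DataFrame(rows)
        lactate_ok = bool((per_line["ko_min_lactate"] <= tol).all())
        fractions = per_line["growth_fraction"]
        growth_ok = bool(
            (fractions > config.growth_fraction_threshold).all()
            if config.require_all_lines
            else fractions.mean() > config.growth_fraction_threshold
        )
        afr_ok: Optional[bool] = None
        if lactate_ok and growth_ok:
            for i, cm in enumerate(cohort):
                ss = sample_optimal_face(
                    ko_models[cm.line_id], n=config.n_samples, seed=config.seed,
                    burn_in=config.burn_in, thinning=config.thinning, line_id=cm.line_id,
                )
                mk = compute_metrics(ss, metric_config, ko_models[cm.line_id])
                ko_afr = mk.afr if mk.afr is not None else 0.0
                per_line.loc[i, "ko_afr"] = ko_afr
                per_line.loc[i, "afr_fraction"] = ko_afr / wt_afr[cm.line_id]
            if config.afr_mean_mode:
                afr_ok = bool(per_line["afr_fraction"].mean() < config.afr_fraction_threshold)
            else:
                afr_ok = bool((per_line["afr_fraction"] < config.afr_fraction_threshold).all())
        normal_ok: Optional[bool] = None
        if normal_cohort is not None and lactate_ok and growth_ok and afr_ok:
            ok = []
            for cm in normal_cohort:
                mu_n = solve_fba(cm.model).objective_value or 0.0
                ko = knockout_reaction(cm.model, rid) if cm.model.has_reaction(rid) else cm.model
                sol = solve_fba(ko)
                mu_k = sol.objective_value if sol.optimal else 0.0
                ok.append(mu_n > 0 and (mu_k / mu_n) > config.growth_fraction_threshold)
            normal_ok = bool(all(ok))
        genes = ref.get_reaction(rid).gene_rule.genes if ref.has_reaction(rid) else frozenset()
        records.append(
            ScreenRecord(
                reaction_id=rid,
                per_line=per_line,
                lactate_abolished=lactate_ok,
                growth_spared=growth_ok,
                afr_reduced=afr_ok,
                normal_spared=normal_ok,
                mapped_genes=genes,
            )
        )
    return records


def screen_summary(records: Sequence[ScreenRecord]) -> pd.DataFrame:
    """One row per tested reaction with stage verdicts and key numbers."""
    rows = []
    for rec in records:
        rows.append(
            {
                "reaction": rec.reaction_id,
                "lactate_abolished": rec.lactate_abolished,
                "growth_spared": rec.growth_spared,
                "afr_reduced": rec.afr_reduced,
                "normal_spared": rec.normal_spared,
                "survives": rec.survives,
                "min_growth_fraction": rec.per_line["growth_fraction"].min(),
                "max_ko_min_lactate": rec.per_line["ko_min_lactate"].max(),
                "mean_afr_fraction": rec.per_line["afr_fraction"].mean(),
                "genes": ";".join(sorted(rec.mapped_genes)),
            }
        )
    return pd.DataFrame(rows)


def map_targets_to_genes(
    model: StoichiometricModel, surviving_reactions: Sequence[str]
) -> pd.DataFrame:
    """Gene table for the surviving reactions.

    A gene is *knockdown sufficient* for a reaction when deleting it alone
    closes the reaction (it sits in an AND position with no OR sibling);
    isoenzyme backups make single knockdowns insufficient.
    """
    import warnings

    per_gene: Dict[str, Dict[str, bool]] = {}
    for rid in surviving_reactions:
        rule = model.get_reaction(rid).gene_rule
        if rule.is_empty:
            warnings.warn(f"surviving reaction {rid} has no gene rule", stacklevel=2)
            continue
        for g in rule.genes:
            per_gene.setdefault(g, {})[rid] = rule.knockdown_sufficient(g)
    rows = [
        {
            "gene": g,
            "reactions": ";".join(sorted(rxns)),
            "n_reactions": len(rxns),
            "knockdown_sufficient_any": any(rxns.values()),
            "knockdown_sufficient_for": ";".join(sorted(r for r, s in rxns.items() if s)),
        }
        for g, rxns in per_gene.items()
    ]
    return (
        pd.DataFrame(rows, columns=["gene", "reactions", "n_reactions",
                                    "knockdown_sufficient_any", "knockdown_sufficient_for"])
        .sort_values(["n_reactions", "gene"], ascending=[False, True])
        .reset_index(drop=True)
    )


def target_expression_test(
    profile: ExpressionProfile,
    target_genes: Sequence[str],
    background_genes: Sequence[str],
) -> float:
    """One-sided Wilcoxon rank-sum p-value: targets expressed above background.

    Each gene contributes its mean expression across the cohort; the test
    asks whether target genes rank higher than background genes.
    """
    targets, background = set(target_genes), set(background_genes)
    if not targets or not background:
        raise ValueError("both gene sets must be non-empty")
    if targets & background:
        raise ValueError(f"gene sets overlap: {sorted(targets & background)}")
    x = profile.matrix.loc[sorted(targets)].mean(axis=1).to_numpy()
    y = profile.matrix.loc[sorted(background)].mean(axis=1).to_numpy()
    method = "exact" if (len(x) <= 20 and len(y) <= 20) else "asymptotic"
    return float(sps.mannwhitneyu(x, y, alternative="greater", method=method).pvalue)
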