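"""End-to-end assembly of the cohort analysis.

Ties the stages together the way the analysis scripts and the CLI use
them: tailor cell-line models from expression (cancer and normal cohorts
are normalised jointly, so the systematic glycolytic shift between the
two populations survives the cross-line min-max scaling), apply the
simulated normoxic environment, sample each line's optimal face and
compute its Warburg metrics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .metrics import MetricConfig, WarburgMetrics, compute_metrics, forced_lactate
from .model import StoichiometricModel
from .sampling import FluxSampleSet, sample_optimal_face
from .synthetic import (
    SyntheticCohort,
    TOY_CORE_COHORT_O2,
    TOY_CORE_METRICS,
    TOY_CORE_TAILOR_TARGETS,
    build_toy_core,
)
from .tailoring import CellLineModel, ExpressionProfile, TailoringConfig, tailor_cohort

__all__ = ["build_cohort_models", "cohort_metrics", "forced_lactate_table"]


def build_cohort_models(
    cohorts: Sequence[SyntheticCohort],
    generic: Optional[StoichiometricModel] = None,
    config: Optional[TailoringConfig] = None,
    o2_bound: float = TOY_CORE_COHORT_O2,
) -> Dict[str, List[CellLineModel]]:
    """Tailor models for one or more cohorts against a shared normalisation.

    The expression matrices of all given cohorts are concatenated before
    tailoring, then the resulting models are split back per cohort mode.
    The environmental oxygen cap is applied to every tailored model.
    """
    generic = generic if generic is not None else build_toy_core()
    config = config or TailoringConfig(target_reactions=TOY_CORE_TAILOR_TARGETS)
    combined = pd.concat([c.expression.matrix for c in cohorts], axis=1)
    profile = ExpressionProfile(combined)
    tailored = tailor_cohort(generic, profile, config)
    by_line = {cm.line_id: cm for cm in tailored}
    out: Dict[str, List[CellLineModel]] = {}
    for cohort in cohorts:
        models = []
        for line in cohort.lines:
            cm = by_line[line]
            m = cm.model.with_reaction_bounds("EX_o2", 0.0, o2_bound)
            models.append(CellLineModel(line_id=line, model=m, tailored_bounds=cm.tailored_bounds))
        out[cohort.mode] = models
    return out


def forced_lactate_table(models: Sequence[CellLineModel], lactate: str = "EX_lac") -> pd.DataFrame:
    """Per-line maximal biomass and minimal lactate secretion at optimum."""
    rows = []
    for cm in models:
        mu, lac = forced_lactate(cm.model, lactate)
        rows.append({"line": cm.line_id, "max_biomass": mu, "min_lactate": lac, "forced": lac > 1e-6})
    return pd.DataFrame(rows).set_index("line")


def cohort_metrics(
    models: Sequence[CellLineModel],
    metric_config: MetricConfig = TOY_CORE_METRICS,
    n_samples: int = 1000,
    seed: int = 0,
    burn_in: int = 1000,
    thinning: int = 100,
) -> Tuple[pd.DataFrame, Dict[str, FluxSampleSet]]:
    """Sample every line's optimal face and compute its Warburg metrics."""
    rows = []
    sample_sets: Dict[str, FluxSampleSet] = {}
    for cm in models:
        ss = sample_optimal_face(
            cm.model, n=n_samples, seed=seed, burn_in=burn_in, thinning=thinning, line_id=cm.line_id
        )
        sample_sets[cm.line_id] = ss
        metrics = compute_metrics(ss, metric_config, cm.model)
        row = metrics.as_dict()
        row["biomass"] = ss.biomass_optimum
        rows.append(row)
    frame = pd.DataFrame(rows).set_index("line")
    # normalised ATP flux rates: per-line fluxes over their cohort maximum
    for col in ("glycolytic_atp_flux", "oxphos_atp_flux"):
        peak = frame[col].max()
        frame[col.replace("_flux", "_norm")] = frame[col] / peak if peak > 0 else float("nan")
    return frame, sample_sets
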