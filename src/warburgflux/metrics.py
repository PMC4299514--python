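"""Bioenergetic read-outs of the Warburg effect.

The central quantities, all computed over flux samples drawn on the
maximal-biomass face:

* **ECAR** - mean lactate-secretion flux (the modelling proxy for the
  extracellular acidification rate);
* **OCR**  - mean oxygen-uptake flux;
* **EOR**  - ECAR / OCR;
* **AFR**  - glycolytic-to-oxidative ATP flux ratio: summed mean ATP
  production of the declared glycolytic reactions over that of the
  declared OXPHOS reactions, each weighted by its ATP stoichiometric
  coefficient;
* **BEC**  - transcript-level proxy: expression ratio of GAPDH to the
  ATP-synthase beta subunit.

The module also provides the oxygen-calibration, forced-lactate, hypoxia
and dose-response procedures that set up the conditions under which those
quantities are measured.  A cell line is called *forced* Warburgian when
the minimal feasible lactate secretion at maximal biomass is strictly
positive: growth is then impossible without fermentation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .model import (
    FIX_RTOL,
    InfeasibleModelError,
    StoichiometricModel,
    flux_extremum,
    solve_fba,
)
from .sampling import FluxSampleSet, sample_optimal_face
from .tailoring import ExpressionProfile

__all__ = [
    "MetricConfig",
    "WarburgMetrics",
    "DoseResponseCurve",
    "calibrate_oxygen",
    "forced_lactate",
    "apply_hypoxia",
    "dose_response",
    "compute_metrics",
    "bec_index",
]

#: below this flux a minimal lactate secretion counts as "not forced"
LACTATE_ZERO_TOL = 1e-6


@dataclass
class MetricConfig:
    """Reaction identities needed to read the metrics off a sample set."""

    lactate_exchange: str = "EX_lac"
    oxygen_exchange: str = "EX_o2"
    glycolytic_atp_reactions: Sequence[str] = ()
    oxphos_atp_reactions: Sequence[str] = ()
    atp_metabolite: str = "atp"


@dataclass
class WarburgMetrics:
    line_id: str
    ecar: float
    ocr: float
    eor: Optional[float]
    afr: Optional[float]
    glycolytic_atp_flux: float
    oxphos_atp_flux: float
    flags: List[str] = field(default_factory=list)

    def as_dict(self) -> Dict:
        return {
            "line": self.line_id,
            "ECAR": self.ecar,
            "OCR": self.ocr,
            "EOR": self.eor if self.eor is not None else math.nan,
            "AFR": self.afr if self.afr is not None else math.nan,
            "glycolytic_atp_flux": self.glycolytic_atp_flux,
            "oxphos_atp_flux": self.oxphos_atp_flux,
            "flags": ";".join(self.flags),
        }


@dataclass
class DoseResponseCurve:
    """ECAR/OCR along a gradual inhibition of one reaction's capacity."""

    reaction_id: str
    levels: np.ndarray  # inhibition level, 0 (none) -> 1 (full)
    bounds: np.ndarray  # imposed upper bound at each level
    biomass: np.ndarray
    ecar: np.ndarray
    ocr: np.ndarray
    flags: List[str] = field(default_factory=list)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "level": self.levels,
                "bound": self.bounds,
                "biomass": self.biomass,
                "ECAR": self.ecar,
                "OCR": self.ocr,
            }
        )


# ---------------------------------------------------------------------------
# Conditions
# ---------------------------------------------------------------------------

def forced_lactate(
    model: StoichiometricModel, lactate_exchange: str = "EX_lac"
) -> Tuple[float, float]:
    """(maximal biomass, minimal lactate secretion at that biomass).

    A strictly positive second component identifies forced lactate
    secretion: the model cannot reach its growth optimum without
    fermenting.
    """
    sol = solve_fba(model)
    if not sol.optimal:
        raise InfeasibleModelError(f"model {model.name or '<unnamed>'} has no optimum ({sol.status})")
    mu = sol.objective_value
    if mu <= LACTATE_ZERO_TOL:
        return mu, 0.0
    lac = flux_extremum(model, lactate_exchange, "min", fixed={model.objective_reaction: (mu, FIX_RTOL)})
    return mu, max(lac, 0.0)


def calibrate_oxygen(
    model: StoichiometricModel,
    oxygen_exchange: str = "EX_o2",
    lactate_exchange: str = "EX_lac",
    resolution: float = 1e-3,
    max_bound: float = 1e6,
) -> Tuple[StoichiometricModel, float]:
    """Set the oxygen uptake cap to the largest value still forcing lactate.

    Bisects the oxygen upper bound: with too much oxygen a yield-maximising
    model respires everything and the minimal lactate secretion collapses
    to zero, so the largest bound with positive forced lactate defines the
    simulated normoxic state.  Returns ``(calibrated model copy, bound)``.
    """
    r_o2 = model.get_reaction(oxygen_exchange)

    def min_lac_at(bound: float) -> float:
        m = model.with_reaction_bounds(oxygen_exchange, r_o2.lower_bound, bound)
        return forced_lactate(m, lactate_exchange)[1]

    # find any oxygen bound at which lactate is forced (at very low oxygen
    # growth itself may be impossible, so forcing can live on an interval)
    probes = [r_o2.upper_bound] if np.isfinite(r_o2.upper_bound) and r_o2.upper_bound > 0 else []
    probes += list(2.0 ** np.arange(-6, 14))
    lo = next((b for b in probes if min_lac_at(b) > LACTATE_ZERO_TOL), None)
    if lo is None:
        raise InfeasibleModelError(
            "model never forced to ferment: no oxygen bound gives positive minimal lactate secretion"
        )
    hi = lo * 2.0
    while min_lac_at(hi) > LACTATE_ZERO_TOL:
        lo = hi
        hi *= 2.0
        if hi > max_bound:
            raise InfeasibleModelError(
                f"forced lactate persists up to oxygen bound {max_bound:g}; calibration has no upper bracket"
            )
    while (hi - lo) > resolution * max(hi, 1.0):
        mid = 0.5 * (lo + hi)
        if min_lac_at(mid) > LACTATE_ZERO_TOL:
            lo = mid
        else:
            hi = mid
    calibrated = model.with_reaction_bounds(oxygen_exchange, r_o2.lower_bound, lo)
    return calibrated, lo


def apply_hypoxia(
    model: StoichiometricModel, fraction: float = 0.5, oxygen_exchange: str = "EX_o2"
) -> StoichiometricModel:
    """Scale the oxygen uptake cap by *fraction* of its normoxic value."""
    if not 0 < fraction <= 1:
        raise ValueError("hypoxia fraction must lie in (0, 1]")
    r = model.get_reaction(oxygen_exchange)
    if not np.isfinite(r.upper_bound):
        raise ValueError("oxygen bound must be finite before applying hypoxia")
    return model.with_reaction_bounds(oxygen_exchange, r.lower_bound, r.upper_bound * fraction)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def _atp_weight(model_reaction, atp_metabolite: str) -> float:
    coeff = model_reaction.stoichiometry.get(atp_metabolite, 0.0)
    return max(coeff, 0.0)  # only production counts


def compute_metrics(
    sample_set: FluxSampleSet,
    config: MetricConfig,
    model: StoichiometricModel,
) -> WarburgMetrics:
    """ECAR/OCR/EOR/AFR from a flux sample set.

    Mean fluxes are weighted by ATP stoichiometric coefficients when
    summing ATP production; with unit coefficients this reduces to the
    plain summed mean flux.  Undefined ratios are flagged rather than
    silently zeroed.
    """
    if not config.glycolytic_atp_reactions or not config.oxphos_atp_reactions:
        raise ValueError("ATP-producing reaction sets must be declared and non-empty")
    flags: List[str] = []
    ecar = sample_set.mean(config.lactate_exchange)
    ocr = sample_set.mean(config.oxygen_exchange)
    gly = sum(
        _atp_weight(model.get_reaction(rid), config.atp_metabolite) * sample_set.mean(rid)
        for rid in config.glycolytic_atp_reactions
    )
    oxp = sum(
        _atp_weight(model.get_reaction(rid), config.atp_metabolite) * sample_set.mean(rid)
        for rid in config.oxphos_atp_reactions
    )
    if ocr > 0:
        eor = ecar / ocr
    else:
        eor, flags = None, flags + ["EOR_undefined_zero_OCR"]
    if oxp > 0:
        afr = gly / oxp
    else:
        afr, flags = None, flags + ["AFR_undefined_zero_OXPHOS"]
    if sample_set.degenerate:
        flags.append("degenerate_face")
    return WarburgMetrics(
        line_id=sample_set.line_id,
        ecar=ecar,
        ocr=ocr,
        eor=eor,
        afr=afr,
        glycolytic_atp_flux=gly,
        oxphos_atp_flux=oxp,
        flags=flags,
    )


def dose_response(
    model: StoichiometricModel,
    reaction_id: str,
    config: MetricConfig,
    n_levels: int = 21,
    n_samples: int = 1000,
    seed: int = 0,
    burn_in: int = 1000,
    thinning: int = 100,
) -> DoseResponseCurve:
    """ECAR/OCR while the target's capacity is lowered from its bound to 0.

    Level 0 imposes the reaction's current upper bound (no inhibition);
    level 1 closes it.  At each of the evenly spaced levels the biomass
    optimum is re-solved and the optimal face re-sampled with identical
    sampler settings and seed.  Infeasible or zero-growth levels record
    zero biomass, ECAR and OCR, flagged.
    """
    r = model.get_reaction(reaction_id)
    if not np.isfinite(r.upper_bound):
        raise ValueError(f"{reaction_id} needs a finite upper bound to define the inhibition grid")
    flags: List[str] = []
    wt = solve_fba(model)
    if wt.optimal and abs(wt.fluxes.get(reaction_id, 0.0)) < 1e-9:
        fixed = {model.objective_reaction: (wt.objective_value, FIX_RTOL)}
        if abs(flux_extremum(model, reaction_id, "max", fixed=fixed)) < 1e-9:
            flags.append("target_carries_no_flux_at_optimum")
    levels = np.linspace(0.0, 1.0, n_levels)
    bounds = r.upper_bound * (1.0 - levels)
    biomass = np.zeros(n_levels)
    ecar = np.zeros(n_levels)
    ocr = np.zeros(n_levels)
    for i, bnd in enumerate(bounds):
        m = model.with_reaction_bounds(reaction_id, min(r.lower_bound, bnd), bnd)
        sol = solve_fba(m)
        if not sol.optimal or sol.objective_value <= 1e-9:
            flags.append(f"level_{i}_zero_growth")
            continue
        ss = sample_optimal_face(m, n=n_samples, seed=seed, burn_in=burn_in, thinning=thinning)
        biomass[i] = sol.objective_value
        ecar[i] = ss.mean(config.lactate_exchange)
        ocr[i] = ss.mean(config.oxygen_exchange)
    return DoseResponseCurve(reaction_id, levels, bounds, biomass, ecar, ocr, flags)


def bec_index(
    profile: ExpressionProfile,
    line_id: str,
    gapdh_gene: str,
    atp_synthase_beta_gene: str,
) -> float:
    """Expression ratio GAPDH / ATP-synthase-beta for one line (NaN if 0/0)."""
    num = profile.level(gapdh_gene, line_id)
    den = profile.level(atp_synthase_beta_gene, line_id)
    if den == 0:
        return math.nan
    return num / den
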