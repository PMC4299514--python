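"""Synthetic networks and cohorts for desk-scale Warburg-effect analysis.

Three hand-solvable micro fixtures (``micro3``, ``parallel_path``,
``warburg_mini``) exercise every stage of the pipeline against closed-form
LP optima, and a richer ``toy_core`` network supplies the structural
features a genome-scale cancer model needs for the method to be
meaningful:

* forced lactate secretion at the default oxygen cap, vanishing when the
  cap is lifted;
* a second oxidizable substrate (glutamine) whose ATP-expensive
  biosynthetic by-routes make respiration rise as glycolysis is inhibited;
* a high-NADH glycolytic route with a low-NADH bypass and a capped
  glycerol-like reduced overflow;
* serine- and methionine-like biosynthetic branches with glutamine-fed
  alternatives, so that branch knockouts reroute growth while abolishing
  the forced fermentation - the planted hits of the knockout screen;
* isoenzyme (OR) and complex (AND) gene rules.

:func:`generate_cohort` plants a known glycolytic character ``w`` per cell
line into gene expression and phenotypes (growth decreasing in ``w``,
migration increasing, a fixed fraction of drug responses monotone in
``w``) so that recovery of the planted structure is testable end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .gpr import GeneRule
from .metrics import MetricConfig, forced_lactate
from .model import (
    FIX_RTOL,
    Metabolite,
    Reaction,
    StoichiometricModel,
    flux_extremum,
    knockout_reaction,
    solve_fba,
)
from .tailoring import ExpressionProfile

__all__ = [
    "build_micro3",
    "build_parallel_path",
    "build_warburg_mini",
    "build_toy_core",
    "generate_cohort",
    "SyntheticCohort",
    "FIXTURES",
    "WARBURG_MINI_REFERENCE",
    "WARBURG_MINI_METRICS",
    "TOY_CORE_METRICS",
    "TOY_CORE_TAILOR_TARGETS",
    "TOY_CORE_GENE_CLASSES",
]


def _met(mid: str, comp: str = "c") -> Metabolite:
    return Metabolite(id=mid, name=mid, compartment=comp)


def _rxn(rid, stoich, lb=0.0, ub=1000.0, rule="", exchange=False) -> Reaction:
    return Reaction(
        id=rid,
        stoichiometry=stoich,
        lower_bound=lb,
        upper_bound=ub,
        gene_rule=GeneRule(rule),
        is_exchange=exchange,
    )


# ---------------------------------------------------------------------------
# Micro fixtures
# ---------------------------------------------------------------------------

def build_micro3() -> StoichiometricModel:
    """Single linear chain A -> B with import capped at 10; optimum 10."""
    return StoichiometricModel(
        metabolites=[_met("A"), _met("B")],
        reactions=[
            _rxn("EX_A", {"A": 1}, ub=10, exchange=True),
            _rxn("AB", {"A": -1, "B": 1}),
            _rxn("EX_B", {"B": -1}, exchange=True),
        ],
        objective_reaction="EX_B",
        name="micro3",
    )


def build_parallel_path() -> StoichiometricModel:
    """Two equivalent routes A -> B sharing an import capped at 10.

    The maximal-export face is the segment ``x + y = 10`` with a free
    split; a uniform sample of the face has mean 5 on either route.
    """
    return StoichiometricModel(
        metabolites=[_met("A"), _met("B")],
        reactions=[
            _rxn("EX_A", {"A": 1}, ub=10, exchange=True),
            _rxn("PATH_X", {"A": -1, "B": 1}),
            _rxn("PATH_Y", {"A": -1, "B": 1}),
            _rxn("EX_B", {"B": -1}, exchange=True),
        ],
        objective_reaction="EX_B",
        name="parallel_path",
    )


def build_warburg_mini() -> StoichiometricModel:
    """Eight-metabolite fermentation/respiration network, fully hand-solvable.

    Glycolysis yields 2 pyruvate + 2 ATP + 2 NADH per glucose; respiration
    re-oxidises NADH at 2 ATP per NADH under an oxygen cap of 2.5; lactate
    dehydrogenase is the only other NADH sink.  With closed ATP/NADH
    cycles the maximal-biomass solution is a single point: biomass 5 with
    a forced lactate secretion of 15.  Lifting the oxygen cap removes the
    forcing entirely (biomass 110/7, minimal lactate 0).
    """
    mets = [
        _met("glc"), _met("pyr"), _met("lac"), _met("co2"), _met("o2"),
        _met("atp"), _met("adp"), _met("nad"), _met("nadh"), _met("biomass"),
    ]
    reactions = [
        _rxn("EX_glc", {"glc": 1}, ub=10, exchange=True),
        _rxn("EX_o2", {"o2": 1}, ub=2.5, exchange=True),
        _rxn("EX_lac", {"lac": -1}, exchange=True),
        _rxn("EX_co2", {"co2": -1}, exchange=True),
        _rxn("EX_biomass", {"biomass": -1}, exchange=True),
        _rxn("GLY", {"glc": -1, "adp": -2, "nad": -2, "pyr": 2, "atp": 2, "nadh": 2}, rule="gGLY"),
        _rxn("RESP", {"nadh": -1, "o2": -0.5, "adp": -2, "nad": 1, "atp": 2}, rule="gRESP"),
        _rxn("LDH", {"pyr": -1, "nadh": -1, "lac": 1, "nad": 1}, rule="gLDH1 or gLDH2"),
        _rxn("TCA", {"pyr": -1, "nad": -4, "nadh": 4, "co2": 1}, rule="gTCA"),
        _rxn("BIO", {"pyr": -1, "atp": -6, "biomass": 1, "adp": 6}),
    ]
    return StoichiometricModel(
        metabolites=mets,
        reactions=reactions,
        objective_reaction="EX_biomass",
        name="warburg_mini",
    )


#: closed-form reference values for warburg-mini, derived by hand from the
#: ATP/NADH/pyruvate balances and re-derived by the vertex-enumeration
#: oracle in the test suite.
WARBURG_MINI_REFERENCE = {
    "max_biomass": 5.0,
    "forced_lactate": 15.0,
    "oxygen_uptake": 2.5,
    "max_biomass_o2_free": 110.0 / 7.0,
    "forced_lactate_o2_free": 0.0,
    "ldh_ko_biomass": 55.0 / 26.0,
    "afr": 2.0,
    "ldh_ko_afr": 7.0 / 26.0,
    "ecar": 15.0,
    "ocr": 2.5,
    "eor": 6.0,
    "hypoxia_biomass": 2.5,
    "hypoxia_lactate": 7.5,
}

WARBURG_MINI_METRICS = MetricConfig(
    lactate_exchange="EX_lac",
    oxygen_exchange="EX_o2",
    glycolytic_atp_reactions=("GLY",),
    oxphos_atp_reactions=("RESP",),
)


# ---------------------------------------------------------------------------
# toy-core
# ---------------------------------------------------------------------------

#: gene classes used by the cohort generator and the tailoring targets
TOY_CORE_GENE_CLASSES = {
    "glycolytic": (
        "gGLUT1", "gHK1", "gHK2", "gPGI", "gPFK", "gGAPDH",
        "gENO", "gPYK", "gLDHA", "gLDHB", "gMCT4",
    ),
    "respiratory": ("gND1", "gCOX4", "gATP5B", "gCS", "gIDH"),
    "branch": ("gPHGDH", "gMAT2A"),
    "other": ("gASCT2", "gGLS", "gSPT", "gBHMT", "gGAPN", "gGPD1"),
}

#: growth-associated subset tailored in cohort analyses
TOY_CORE_TAILOR_TARGETS = (
    "GLCt", "HEX", "PGI", "PFK", "GAPDH", "PYK", "LDH", "LACt", "RESP", "TCA",
)

TOY_CORE_METRICS = MetricConfig(
    lactate_exchange="EX_lac",
    oxygen_exchange="EX_o2",
    glycolytic_atp_reactions=("GAPDH", "PYK"),
    oxphos_atp_reactions=("RESP",),
)

#: oxygen cap applied to tailored cohort models: generous enough that the
#: forcing per line is decided by the tailored respiratory capacity.
TOY_CORE_COHORT_O2 = 12.0

#: ground-truth survivor set of the three-stage knockout screen on the
#: generic toy-core at the canonical screen settings (1000 samples,
#: burn-in 1000, thinning 100, seed 0): the lactate-disposal route (LDH
#: and its export transporter) plus the glutamine-fed serine/methionine
#: branch routes and glutamine import.  The NADH-producing branch routes
#: SER1/MET1 abolish lactate and spare growth but fail the AFR filter.
TOY_CORE_PLANTED_HITS = frozenset({"GLNt", "LACt", "LDH", "SER2", "MET2"})


def build_toy_core(seed: int = 0, self_check: bool = True) -> StoichiometricModel:
    """Core-carbon network with glycolytic, respiratory, fermentative,
    glutaminolytic and biosynthetic branches (29 reactions, 23 metabolites).

    The stoichiometry is fixed by design (the ``seed`` argument is part of
    the generator interface but the construction is fully deterministic);
    the structural requirements are re-verified at build time:

    R1 - forced lactate secretion at the default oxygen cap;
    R2 - no forcing with the oxygen cap lifted;
    R3 - full inhibition of the glycolytic entry raises the attainable
         minimum oxygen consumption at the growth optimum;
    R4 - at least two biosynthetic branch reactions (serine-like and
         methionine-like) whose knockout abolishes forced lactate while
         sparing more than 10% of wild-type growth;
    R5 - at least one isoenzyme (OR) gene rule.
    """
    del seed  # deterministic construction; kept for interface uniformity
    mets = [_met(m, "e") for m in ("glc_e", "gln_e", "lac_e", "o2_e", "co2_e", "glyc_e")] + [
        _met(m)
        for m in (
            "glc", "g6p", "f6p", "g3p", "pg3", "pyr", "lac", "ser", "mth",
            "gln", "o2", "co2", "glyc", "atp", "adp", "nad", "nadh", "bm",
        )
    ]
    rx = [
        _rxn("EX_glc", {"glc_e": 1}, ub=16, exchange=True),
        _rxn("EX_gln", {"gln_e": 1}, ub=9, exchange=True),
        _rxn("EX_o2", {"o2_e": 1}, ub=6, exchange=True),
        _rxn("EX_lac", {"lac_e": -1}, exchange=True),
        _rxn("EX_co2", {"co2_e": -1}, exchange=True),
        _rxn("EX_glyc", {"glyc_e": -1}, exchange=True),
        _rxn("EX_biomass", {"bm": -1}, exchange=True),
        _rxn("GLCt", {"glc_e": -1, "glc": 1}, rule="gGLUT1"),
        _rxn("GLNt", {"gln_e": -1, "gln": 1}, rule="gASCT2"),
        _rxn("O2t", {"o2_e": -1, "o2": 1}),
        _rxn("LACt", {"lac": -1, "lac_e": 1}, rule="gMCT4"),
        _rxn("CO2t", {"co2": -1, "co2_e": 1}),
        _rxn("GLYCt", {"glyc": -1, "glyc_e": 1}),
        _rxn("HEX", {"glc": -1, "atp": -1, "g6p": 1, "adp": 1}, ub=16, rule="gHK1 or gHK2"),
        _rxn("PGI", {"g6p": -1, "f6p": 1}, rule="gPGI"),
        _rxn("PFK", {"f6p": -1, "atp": -1, "g3p": 2, "adp": 1}, rule="gPFK"),
        _rxn("GAPDH", {"g3p": -1, "nad": -1, "adp": -1, "pg3": 1, "nadh": 1, "atp": 1}, rule="gGAPDH"),
        _rxn("BYP", {"g3p": -1, "pg3": 1}, ub=3, rule="gGAPN"),
        _rxn("GPD", {"g3p": -1, "nadh": -1, "glyc": 1, "nad": 1}, ub=3, rule="gGPD1"),
        _rxn("PYK", {"pg3": -1, "adp": -1, "pyr": 1, "atp": 1}, rule="gENO and gPYK"),
        _rxn("LDH", {"pyr": -1, "nadh": -1, "lac": 1, "nad": 1}, rule="gLDHA or gLDHB"),
        _rxn("TCA", {"pyr": -1, "nad": -4, "nadh": 4, "co2": 3}, rule="gCS and gIDH"),
        _rxn("RESP", {"nadh": -1, "o2": -0.5, "adp": -2, "nad": 1, "atp": 2}, rule="gND1 and gCOX4 and gATP5B"),
        _rxn("GLNOX", {"gln": -1, "nad": -1, "adp": -1, "pyr": 1, "atp": 1, "nadh": 1, "co2": 2}, rule="gGLS"),
        _rxn("SER1", {"pg3": -1, "nad": -1, "ser": 1, "nadh": 1}, ub=2, rule="gPHGDH"),
        _rxn("SER2", {"gln": -1, "atp": -5.5, "ser": 1, "adp": 5.5, "co2": 2}, ub=2, rule="gSPT"),
        _rxn("MET1", {"pg3": -1, "nad": -2, "mth": 1, "nadh": 2}, ub=1, rule="gMAT2A"),
        _rxn("MET2", {"gln": -1, "atp": -5, "mth": 1, "adp": 5, "co2": 2}, ub=1, rule="gBHMT"),
        _rxn("BIO", {"pyr": -1, "ser": -0.5, "mth": -0.25, "atp": -3.5, "bm": 1, "adp": 3.5}),
    ]
    model = StoichiometricModel(
        metabolites=mets, reactions=rx, objective_reaction="EX_biomass", name="toy_core"
    )
    if self_check:
        _toy_core_self_check(model)
    return model


class ToyCoreCheckError(AssertionError):
    """A structural requirement of the toy-core fixture failed."""


def _toy_core_self_check(model: StoichiometricModel) -> None:
    mu, lac = forced_lactate(model)
    if not (mu > 0 and lac > 1e-6):
        raise ToyCoreCheckError(f"R1 violated: biomass {mu}, forced lactate {lac}")
    free = model.with_reaction_bounds("EX_o2", 0, 1e6)
    _, lac_free = forced_lactate(free)
    if lac_free > 1e-6:
        raise ToyCoreCheckError(f"R2 violated: forced lactate {lac_free} with unbounded oxygen")
    # R3: attainable minimum oxygen uptake at the optimum rises under full
    # glycolytic inhibition (sampling-free criterion: face interval shifts up)
    fixed = {"EX_biomass": (mu, FIX_RTOL)}
    o2_lo_wt = flux_extremum(model, "EX_o2", "min", fixed=fixed)
    inhibited = model.with_reaction_bounds("HEX", 0, 0)
    mu0 = solve_fba(inhibited).objective_value
    o2_lo_inh = flux_extremum(inhibited, "EX_o2", "min", fixed={"EX_biomass": (mu0, FIX_RTOL)})
    if not (mu0 > 0 and o2_lo_inh > o2_lo_wt + 1e-6):
        raise ToyCoreCheckError(
            f"R3 violated: min oxygen {o2_lo_inh} under inhibition vs {o2_lo_wt} at wild type"
        )
    hits = 0
    for rid in ("SER1", "MET1"):
        ko = knockout_reaction(model, rid)
        mu_ko, lac_ko = forced_lactate(ko)
        if lac_ko <= 1e-6 and mu_ko / mu > 0.10:
            hits += 1
    if hits < 2:
        raise ToyCoreCheckError("R4 violated: fewer than 2 reroutable branch hits")
    if not any(" or " in r.gene_rule.text.lower() for r in model.reactions):
        raise ToyCoreCheckError("R5 violated: no isoenzyme (OR) rule present")


FIXTURES = {
    "micro3": build_micro3,
    "parallel_path": build_parallel_path,
    "warburg_mini": build_warburg_mini,
    "toy_core": build_toy_core,
}


# ---------------------------------------------------------------------------
# Synthetic cohorts
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    """Expression + phenotypes with a planted glycolytic character ``w``.

    ``mode`` is ``"cancer"`` (w ~ U(0,1); glycolytic genes overexpressed,
    respiratory genes repressed, in proportion to w) or ``"normal"``
    (w concentrated near 0.5; glycolytic expression low and respiratory
    expression high overall, emulating normal proliferating cells that do
    not run aerobic glycolysis).
    """

    expression: ExpressionProfile
    w: pd.Series
    phenotypes: pd.DataFrame  # index line; columns growth, migration
    drug_response: pd.DataFrame  # compounds x lines
    planted_compounds: List[str]
    seed: int
    mode: str
    params: Dict = field(default_factory=dict)

    @property
    def lines(self) -> List[str]:
        return list(self.w.index)


def _expression_level(gene: str, w: float, mode: str) -> float:
    classes = TOY_CORE_GENE_CLASSES
    if gene in classes["glycolytic"]:
        return 100.0 * (1.5 + w) if mode == "cancer" else 100.0 * 0.5
    if gene in classes["respiratory"]:
        return 100.0 * (1.2 - w) if mode == "cancer" else 100.0 * 2.4
    if gene in classes["branch"]:
        return 100.0 * (0.8 + 0.4 * w) if mode == "cancer" else 100.0
    return 100.0


def generate_cohort(
    n_lines: int = 20,
    seed: int = 0,
    mode: str = "cancer",
    expression_sigma: float = 0.1,
    growth_sigma: float = 0.03,
    migration_sigma: float = 1.0,
    n_compounds: int = 100,
    planted_fraction: float = 0.3,
    drug_sigma: float = 0.25,
    w_values: Optional[Sequence[float]] = None,
) -> SyntheticCohort:
    """Generate a cohort of synthetic cell lines over the toy-core gene set.

    Per line a glycolytic character ``w`` is drawn (U(0,1) in cancer mode;
    N(0.5, 0.05) clipped in normal mode) and mapped to gene expression
    with multiplicative log-normal noise.  Phenotypes: growth decreases
    and migration increases linearly in ``w`` plus Gaussian noise; a
    planted fraction of drug-response compounds is monotone increasing in
    ``w`` (more glycolytic lines need higher doses), the rest pure noise.
    Deterministic given the seed.
    """
    if n_lines < 4:
        raise ValueError("need at least 4 cell lines")
    if mode not in ("cancer", "normal"):
        raise ValueError(f"unknown mode {mode!r}")
    if not 0 <= planted_fraction <= 1:
        raise ValueError("planted_fraction must lie in [0, 1]")
    for name, val in [("expression_sigma", expression_sigma), ("growth_sigma", growth_sigma),
                      ("migration_sigma", migration_sigma), ("drug_sigma", drug_sigma)]:
        if val < 0:
            raise ValueError(f"{name} must be non-negative")
    rng = np.random.default_rng(seed)
    prefix = "C" if mode == "cancer" else "N"
    lines = [f"{prefix}{i + 1:02d}" for i in range(n_lines)]
    if w_values is not None:
        if len(w_values) != n_lines:
            raise ValueError("w_values must have one entry per line")
        w = np.asarray(w_values, dtype=float)
    elif mode == "cancer":
        w = rng.uniform(0.0, 1.0, n_lines)
    else:
        w = np.clip(rng.normal(0.5, 0.05, n_lines), 0.0, 1.0)
    w = pd.Series(w, index=lines, name="w")

    genes = [g for cls in TOY_CORE_GENE_CLASSES.values() for g in cls]
    base = np.array([[_expression_level(g, wi, mode) for wi in w] for g in genes])
    noise = np.exp(rng.normal(0.0, expression_sigma, base.shape)) if expression_sigma else 1.0
    expression = ExpressionProfile(pd.DataFrame(base * noise, index=genes, columns=lines))

    growth = 1.0 - 0.5 * w + rng.normal(0.0, growth_sigma, n_lines)
    migration = 10.0 + 20.0 * w + rng.normal(0.0, migration_sigma, n_lines)
    phenotypes = pd.DataFrame({"growth": growth, "migration": migration}, index=lines)

    n_planted = int(round(planted_fraction * n_compounds))
    compounds = [f"D{i + 1:03d}" for i in range(n_compounds)]
    planted = compounds[:n_planted]
    resp = np.empty((n_compounds, n_lines))
    for i in range(n_compounds):
        if i < n_planted:
            resp[i] = w.to_numpy() + rng.normal(0.0, drug_sigma, n_lines)
        else:
            resp[i] = rng.normal(0.0, 1.0, n_lines)
    drug = pd.DataFrame(resp, index=compounds, columns=lines)

    return SyntheticCohort(
        expression=expression,
        w=w,
        phenotypes=phenotypes,
        drug_response=drug,
        planted_compounds=planted,
        seed=seed,
        mode=mode,
        params={
            "n_lines": n_lines,
            "expression_sigma": expression_sigma,
            "growth_sigma": growth_sigma,
            "migration_sigma": migration_sigma,
            "n_compounds": n_compounds,
            "planted_fraction": planted_fraction,
            "drug_sigma": drug_sigma,
        },
    )
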