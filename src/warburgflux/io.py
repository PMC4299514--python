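"""Readers and writers for the pipeline's interchange formats.

Native model format: a directory of three TSV tables —
``metabolites.tsv`` (id, name, compartment), ``reactions.tsv`` (id, name,
stoichiometry as ``met:coeff;met:coeff`` strings, bounds, gene rule,
exchange flag) and ``medium.tsv`` (exchange reaction, maximal uptake) —
plus a small ``model.json`` sidecar holding the model name, objective and
flux units.  TSVs are tab-separated UTF-8 with a header row, chosen so
that every artefact of a run is diff-able.

SBML Level 3 + FBC import/export goes through cobra/libsbml; cobra is
used strictly for format interchange, never for solving.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import pandas as pd

from .gpr import GeneRule
from .model import Metabolite, Reaction, StoichiometricModel

__all__ = ["write_model_tsv", "read_model_tsv", "write_sbml", "read_sbml"]

_MET_COLS = ["id", "name", "compartment"]
_RXN_COLS = ["id", "name", "stoichiometry", "lower_bound", "upper_bound", "gene_rule", "is_exchange"]


def _stoich_to_str(stoich) -> str:
    return ";".join(f"{met}:{coeff:g}" for met, coeff in sorted(stoich.items()))


def _stoich_from_str(text: str):
    out = {}
    for part in str(text).split(";"):
        met, _, coeff = part.rpartition(":")
        if not met:
            raise ValueError(f"malformed stoichiometry entry {part!r}")
        out[met] = float(coeff)
    return out


def write_model_tsv(model: StoichiometricModel, directory: Union[str, Path]) -> Path:
    """Serialise a model into the native three-table TSV directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [{"id": m.id, "name": m.name, "compartment": m.compartment} for m in model.metabolites],
        columns=_MET_COLS,
    ).to_csv(directory / "metabolites.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": _stoich_to_str(r.stoichiometry),
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gene_rule": r.gene_rule.text,
                "is_exchange": int(r.is_exchange),
            }
            for r in model.reactions
        ],
        columns=_RXN_COLS,
    ).to_csv(directory / "reactions.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"exchange": k, "max_uptake": v} for k, v in sorted(model.medium.items())],
        columns=["exchange", "max_uptake"],
    ).to_csv(directory / "medium.tsv", sep="\t", index=False)
    (directory / "model.json").write_text(
        json.dumps(
            {
                "name": model.name,
                "objective_reaction": model.objective_reaction,
                "flux_units": model.flux_units,
            },
            indent=1,
        )
    )
    return directory


def read_model_tsv(directory: Union[str, Path]) -> StoichiometricModel:
    """Load a model from the native TSV directory."""
    directory = Path(directory)
    for required in ("metabolites.tsv", "reactions.tsv", "model.json"):
        if not (directory / required).exists():
            raise FileNotFoundError(f"{directory}: missing {required}")
    meta = json.loads((directory / "model.json").read_text())
    mets_df = pd.read_csv(directory / "metabolites.tsv", sep="\t", keep_default_na=False)
    rxns_df = pd.read_csv(directory / "reactions.tsv", sep="\t", keep_default_na=False)
    medium_path = directory / "medium.tsv"
    medium = {}
    if medium_path.exists():
        mdf = pd.read_csv(medium_path, sep="\t")
        medium = dict(zip(mdf["exchange"], mdf["max_uptake"]))
    metabolites = [
        Metabolite(id=row["id"], name=str(row["name"]), compartment=str(row["compartment"]))
        for _, row in mets_df.iterrows()
    ]
    reactions = [
        Reaction(
            id=row["id"],
            name=str(row["name"]),
            stoichiometry=_stoich_from_str(row["stoichiometry"]),
            lower_bound=float(row["lower_bound"]),
            upper_bound=float(row["upper_bound"]),
            gene_rule=GeneRule(str(row["gene_rule"])),
            is_exchange=bool(int(row["is_exchange"])),
        )
        for _, row in rxns_df.iterrows()
    ]
    return StoichiometricModel(
        metabolites=metabolites,
        reactions=reactions,
        objective_reaction=meta["objective_reaction"],
        medium=medium,
        name=meta.get("name", ""),
        flux_units=meta.get("flux_units", "mmol/gDW/h"),
    )


def write_sbml(model: StoichiometricModel, path: Union[str, Path]) -> Path:
    """Export to SBML L3 + FBC (via cobra)."""
    import cobra

    cm = cobra.Model(model.name or "model")
    comp_map = {c: c for c in model.compartments}
    cm.compartments = comp_map
    mets = {}
    for m in model.metabolites:
        cmet = cobra.Metabolite(m.id, name=m.name, compartment=m.compartment)
        mets[m.id] = cmet
    cm.add_metabolites(list(mets.values()))
    rxns = []
    for r in model.reactions:
        cr = cobra.Reaction(r.id, name=r.name, lower_bound=r.lower_bound, upper_bound=r.upper_bound)
        rxns.append(cr)
    cm.add_reactions(rxns)
    for r in model.reactions:
        cr = cm.reactions.get_by_id(r.id)
        cr.add_metabolites({mets[k]: v for k, v in r.stoichiometry.items()})
        if not r.gene_rule.is_empty:
            cr.gene_reaction_rule = r.gene_rule.text
    cm.objective = model.objective_reaction
    cobra.io.write_sbml_model(cm, str(path))
    return Path(path)


def read_sbml(path: Union[str, Path], objective: str = "") -> StoichiometricModel:
    """Import an SBML L3 + FBC model (via cobra).

    The exchange flag is taken from cobra's boundary detection; the
    objective defaults to the SBML-declared objective reaction.
    """
    import cobra

    cm = cobra.io.read_sbml_model(str(path))
    metabolites = [
        Metabolite(id=m.id, name=m.name or m.id, compartment=m.compartment or "c")
        for m in cm.metabolites
    ]
    boundary = {r.id for r in cm.boundary}
    reactions = [
        Reaction(
            id=r.id,
            name=r.name or "",
            stoichiometry={m.id: coeff for m, coeff in r.metabolites.items()},
            lower_bound=r.lower_bound,
            upper_bound=r.upper_bound,
            gene_rule=GeneRule(r.gene_reaction_rule or ""),
            is_exchange=r.id in boundary,
        )
        for r in cm.reactions
    ]
    if not objective:
        objectives = [r.id for r in cm.reactions if r.objective_coefficient]
        if len(objectives) != 1:
            raise ValueError(f"{path}: cannot infer a unique objective reaction; pass one explicitly")
        objective = objectives[0]
    return StoichiometricModel(
        metabolites=metabolites, reactions=reactions, objective_reaction=objective,
        name=cm.id or Path(path).stem,
    )
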