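"""Expression-tailored cell-line models.

Each cell line's model is derived from a generic network by capping the
maximal flux of a designated set of enzyme-catalysed ("growth-associated")
reactions in proportion to the expression of the catalysing genes in that
line.  Per-reaction expression is aggregated over the gene rule (OR = sum
of isoenzymes, AND = limiting subunit), min-max normalised across the
cohort, and mapped linearly onto ``[floor_fraction, 1] * base_bound``:

    ub(r, line) = base_bound * (eps + (1 - eps) * x_hat(r, line))

The floor ``eps`` keeps every tailored reaction marginally open, so
tailoring modulates capacity rather than deleting reactions.  A reaction
whose aggregated expression has zero spread across the cohort is left
untailored at ``base_bound`` (no penalty).  Tailoring never touches lower
bounds and is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .model import StoichiometricModel

__all__ = ["ExpressionProfile", "TailoringConfig", "CellLineModel", "reaction_expression", "tailor_cohort"]

logger = logging.getLogger(__name__)


class ExpressionProfile:
    """Gene x cell-line expression matrix (non-negative, one platform)."""

    def __init__(self, matrix: pd.DataFrame):
        if (matrix.to_numpy() < 0).any():
            raise ValueError("expression levels must be non-negative")
        if matrix.columns.duplicated().any():
            raise ValueError("duplicate cell-line ids")
        if matrix.index.duplicated().any():
            raise ValueError("duplicate gene ids")
        self.matrix = matrix.astype(float)

    @property
    def genes(self) -> List[str]:
        return list(self.matrix.index)

    @property
    def lines(self) -> List[str]:
        return list(self.matrix.columns)

    def levels(self, line_id: str) -> Dict[str, float]:
        return self.matrix[line_id].to_dict()

    def level(self, gene: str, line_id: str) -> float:
        return float(self.matrix.at[gene, line_id])

    @classmethod
    def from_tsv(cls, path) -> "ExpressionProfile":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def to_tsv(self, path) -> None:
        self.matrix.to_csv(path, sep="\t", index_label="gene")


@dataclass
class TailoringConfig:
    """Which reactions to tailor and how hard.

    ``floor_fraction`` is the retained capacity fraction for the least
    expressed line; ``base_bound`` the cap applied before scaling, in the
    model's flux units.
    """

    target_reactions: Optional[Sequence[str]] = None  # None -> all with a gene rule
    floor_fraction: float = 0.1
    base_bound: float = 24.0

    def __post_init__(self):
        if not 0 < self.floor_fraction < 1:
            raise ValueError("floor_fraction must lie in (0, 1)")
        if self.base_bound <= 0:
            raise ValueError("base_bound must be positive")


@dataclass
class CellLineModel:
    """A tailored model plus its tailoring record (reaction -> applied ub)."""

    line_id: str
    model: StoichiometricModel
    tailored_bounds: Dict[str, float] = field(default_factory=dict)


def reaction_expression(
    model: StoichiometricModel, profile: ExpressionProfile, line_id: str
) -> Dict[str, float]:
    """Aggregate gene expression onto reactions for one cell line.

    Reactions with an empty rule, or none of whose genes are measured,
    are absent from the result.
    """
    levels = profile.levels(line_id)
    out = {}
    for r in model.reactions:
        if r.gene_rule.is_empty:
            continue
        val = r.gene_rule.aggregate_expression(levels)
        if val is not None:
            out[r.id] = float(val)
    return out


def tailor_cohort(
    generic: StoichiometricModel,
    profile: ExpressionProfile,
    config: Optional[TailoringConfig] = None,
) -> List[CellLineModel]:
    """Build one capacity-tailored model per cell line in the profile.

    Requires at least two lines: the normalisation is cross-line min-max
    per reaction, so ranks of tailored bounds match ranks of aggregated
    expression.
    """
    config = config or TailoringConfig()
    lines = profile.lines
    if len(lines) < 2:
        raise ValueError("tailoring needs a cohort of at least 2 cell lines")

    if config.target_reactions is None:
        targets = [r.id for r in generic.reactions if not r.gene_rule.is_empty and not r.is_exchange]
    else:
        targets = list(config.target_reactions)
        for rid in targets:
            if generic.get_reaction(rid).gene_rule.is_empty:
                raise ValueError(f"target reaction {rid} has no gene rule")

    # reaction x line aggregated expression
    expr = pd.DataFrame(
        {line: reaction_expression(generic, profile, line) for line in lines}
    ).reindex(targets)

    eps = config.floor_fraction
    base = config.base_bound
    cohort: List[CellLineModel] = []
    for line in lines:
        m = generic.copy(name=f"{generic.name}[{line}]")
        record: Dict[str, float] = {}
        for rid in targets:
            row = expr.loc[rid]
            if row.isna().all():
                logger.info("reaction %s has no measured gene; left untailored", rid)
                continue
            lo, hi = float(row.min()), float(row.max())
            if hi - lo <= 0:
                x_hat = 1.0  # zero cross-line spread: no penalty
                logger.info("reaction %s has zero expression spread; no penalty applied", rid)
            else:
                x_hat = (float(row[line]) - lo) / (hi - lo)
            bound = base * (eps + (1 - eps) * x_hat)
            r = m.get_reaction(rid)
            m = m.with_reaction_bounds(rid, r.lower_bound, min(r.upper_bound, bound))
            record[rid] = bound
        cohort.append(CellLineModel(line_id=line, model=m, tailored_bounds=record))
    return cohort


def tailoring_record_frame(cohort: Sequence[CellLineModel]) -> pd.DataFrame:
    """Long-format table (reaction, line, bound) of all applied caps."""
    rows = [
        {"reaction": rid, "line": cm.line_id, "bound": b}
        for cm in cohort
        for rid, b in cm.tailored_bounds.items()
    ]
    return pd.DataFrame(rows, columns=["reaction", "line", "bound"])
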