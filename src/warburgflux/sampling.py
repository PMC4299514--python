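"""Uniform-ish sampling of the maximal-biomass flux polytope.

All bioenergetic read-outs of the pipeline (ECAR, OCR, EOR, AFR) are means
over feasible flux distributions drawn from the *optimal face*: the
sub-polytope of steady-state flux vectors that achieve the maximal biomass
objective.  The face is explored with a hit-and-run random walk started
from the centroid of flux-variability extreme points, after restricting
the walk to the affine subspace ``{v : S v = 0, v_bio = opt}``.

Hit-and-run is uniform only asymptotically; uniformity is never treated
as contractual.  What is contractual, and asserted row by row, is
feasibility: mass balance, bounds, and exact biomass fixing.  Degenerate
(single-point) faces are detected via flux variability and returned as
replicated points, flagged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy.linalg import null_space

from .model import (
    FIX_RTOL,
    InfeasibleModelError,
    StoichiometricModel,
    flux_extremum,
    solve_fba,
)

__all__ = ["FluxSampleSet", "sample_optimal_face", "mean_flux"]

#: relative width below which a reaction's flux range on the face counts as
#: pinned (the biomass-fixing band alone gives the face a ~1e-9 relative
#: numerical thickness)
DEGENERACY_TOL = 1e-6


@dataclass
class FluxSampleSet:
    """Feasible flux distributions on the maximal-biomass face."""

    samples: pd.DataFrame  # n_samples x n_reactions
    line_id: str
    biomass_optimum: float
    seed: int
    settings: Dict = field(default_factory=dict)
    degenerate: bool = False

    @property
    def n(self) -> int:
        return len(self.samples)

    def mean(self, reaction_id: str) -> float:
        return float(self.samples[reaction_id].mean())

    def std(self, reaction_id: str) -> float:
        return float(self.samples[reaction_id].std(ddof=1)) if self.n > 1 else 0.0

    def to_tsv(self, path) -> None:
        """Write samples as TSV with a JSON sidecar of settings."""
        path = Path(path)
        self.samples.to_csv(path, sep="\t", index=False)
        meta = {
            "line_id": self.line_id,
            "biomass_optimum": self.biomass_optimum,
            "seed": self.seed,
            "degenerate": self.degenerate,
            **self.settings,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def mean_flux(sample_set: FluxSampleSet, reaction_id: str) -> float:
    """Arithmetic mean flux of one reaction over all samples."""
    return sample_set.mean(reaction_id)


def _face_variability(model: StoichiometricModel, optimum: float) -> pd.DataFrame:
    fixed = {model.objective_reaction: (optimum, FIX_RTOL)}
    rows = {}
    for rid in model.reaction_ids:
        lo = flux_extremum(model, rid, "min", fixed=fixed)
        hi = flux_extremum(model, rid, "max", fixed=fixed)
        rows[rid] = (lo, hi)
    return pd.DataFrame(rows, index=["min", "max"]).T


def sample_optimal_face(
    model: StoichiometricModel,
    n: int = 1000,
    seed: int = 0,
    burn_in: int = 1000,
    thinning: int = 100,
    line_id: Optional[str] = None,
) -> FluxSampleSet:
    """Draw *n* feasible flux vectors with biomass fixed at its optimum.

    Deterministic for a given seed.  Raises :class:`InfeasibleModelError`
    on an infeasible model.
    """
    sol = solve_fba(model)
    if sol.status == "infeasible":
        raise InfeasibleModelError(f"model {model.name or '<unnamed>'} is infeasible")
    if sol.status == "unbounded":
        raise InfeasibleModelError("biomass objective is unbounded; cannot fix the optimal face")
    optimum = sol.objective_value
    line = line_id if line_id is not None else (model.name or "model")
    settings = {"n": n, "burn_in": burn_in, "thinning": thinning}

    rids = model.reaction_ids
    fva = _face_variability(model, optimum)
    scale = pd.concat([fva["min"].abs(), fva["max"].abs()], axis=1).max(axis=1).clip(lower=1.0)
    widths = (fva["max"] - fva["min"]) / scale
    # the FVA box bounds the face but its endpoints carry LP tolerance;
    # clip to the model's own bounds so emitted rows satisfy them exactly
    model_lb, model_ub = model.bounds_arrays()
    lb = np.maximum(fva["min"].to_numpy(), model_lb)
    ub = np.minimum(fva["max"].to_numpy(), model_ub)
    swap = lb > ub
    if swap.any():
        mid = np.clip(0.5 * (lb + ub), model_lb, model_ub)
        lb[swap] = mid[swap]
        ub[swap] = mid[swap]

    if float(widths.max()) <= DEGENERACY_TOL:
        point = 0.5 * (lb + ub)
        samples = pd.DataFrame(np.tile(point, (n, 1)), columns=rids)
        return FluxSampleSet(samples, line, optimum, seed, settings, degenerate=True)

    # Affine subspace: S v = 0, biomass pinned at the optimum, and every
    # bound-pinned coordinate (face width ~ 0) treated as an equality so
    # the walk never pushes against a zero-width box dimension.
    S = model.stoichiometric_matrix()
    j_bio = model.reaction_index(model.objective_reaction)
    e_bio = np.zeros(len(rids))
    e_bio[j_bio] = 1.0
    pinned = np.flatnonzero(widths.to_numpy() <= DEGENERACY_TOL)
    pin_rows = np.zeros((len(pinned), len(rids)))
    pin_vals = np.empty(len(pinned))
    for i, j in enumerate(pinned):
        pin_rows[i, j] = 1.0
        pin_vals[i] = 0.5 * (lb[j] + ub[j])
        lb[j] = ub[j] = pin_vals[i]
    A = np.vstack([S, e_bio, pin_rows])
    b = np.concatenate([np.zeros(S.shape[0]), [optimum], pin_vals])
    N = null_space(A)
    if N.shape[1] == 0:  # numerically a point despite FVA widths; replicate
        point = 0.5 * (lb + ub)
        samples = pd.DataFrame(np.tile(point, (n, 1)), columns=rids)
        return FluxSampleSet(samples, line, optimum, seed, settings, degenerate=True)

    # Warm-up: centroid of the FVA vertex solutions projected on the face.
    fixed = {model.objective_reaction: (optimum, FIX_RTOL)}
    warm = []
    rng = np.random.default_rng(seed)
    probe = [rid for rid in rids if widths[rid] > DEGENERACY_TOL]
    for rid in probe:
        for sense in ("min", "max"):
            from .model import _with_fixed  # local import to avoid cycle at module load

            s = solve_fba(_with_fixed(model, fixed), rid, sense)
            if s.optimal:
                warm.append([s.fluxes[r] for r in rids])
    v0 = np.mean(np.array(warm), axis=0)
    # project the centroid onto the equality manifold, then snap into the
    # box (the snap perturbs the equalities by at most the LP tolerance)
    v0 = v0 - np.linalg.pinv(A) @ (A @ v0 - b)
    v0 = np.clip(v0, lb, ub)

    k = N.shape[1]
    out = np.empty((n, len(rids)))
    v = v0.copy()
    total = burn_in + n * thinning
    taken = 0
    for step in range(total):
        d = N @ rng.standard_normal(k)
        norm = np.linalg.norm(d)
        if norm < 1e-14:
            continue
        d /= norm
        with np.errstate(divide="ignore", invalid="ignore"):
            t_lo = np.where(d > 1e-12, (lb - v) / d, np.where(d < -1e-12, (ub - v) / d, -np.inf))
            t_hi = np.where(d > 1e-12, (ub - v) / d, np.where(d < -1e-12, (lb - v) / d, np.inf))
        tmin = float(np.max(t_lo))
        tmax = float(np.min(t_hi))
        if not np.isfinite(tmin) or not np.isfinite(tmax) or tmax <= tmin:
            continue
        v = v + (tmin + rng.uniform(0.0, 1.0) * (tmax - tmin)) * d
        v = np.clip(v, lb, ub)
        if step >= burn_in and (step - burn_in) % thinning == thinning - 1:
            out[taken] = v
            taken += 1
            if taken == n:
                break
    if taken < n:  # pathological mixing; pad with the last state
        out[taken:] = v
    samples = pd.DataFrame(out, columns=rids)
    return FluxSampleSet(samples, line, optimum, seed, settings, degenerate=False)
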