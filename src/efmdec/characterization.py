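"""Characterizing optimal metabolic behavior over a fixed set of modes.

Once a handful of elementary flux modes has been extracted, the question
becomes: how much of the network's optimal behavior do these modes
explain?  Writing the modes as columns of a matrix ``P`` and restricting
flux distributions to nonnegative combinations ``v = P w`` turns the FBA
problem into a small LP over the weights:

    maximize  f @ (P w)   subject to   a <= P w <= b,  w >= 0.

Steady state holds automatically since each column is a mode.  The
mode-restricted optimum can never exceed the full FBA optimum; when the
two agree, the mode set is *sufficient* to characterize the optimal
behavior.  A sufficient set can then be greedily reduced to a minimal
subset that stays sufficient across a whole family of model variants
(e.g. the same network at a range of substrate-uptake bounds), which is
what stacked mode-weight plots over an uptake sweep are built from.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .model_io import MetabolicModel

SUFFICIENCY_RTOL = 1e-6


class InsufficientModesError(ValueError):
    """The supplied mode set cannot reproduce the reference optimum."""


@dataclass
class ModeMatrix:
    """Flux modes as columns of an n x K matrix with column labels."""

    P: np.ndarray
    labels: list[str]

    def __post_init__(self):
        self.P = np.atleast_2d(np.asarray(self.P, dtype=float))
        if self.P.ndim != 2:
            raise ValueError("P must be a 2-D array")
        if len(self.labels) != self.P.shape[1]:
            raise ValueError("one label per column required")

    @property
    def K(self) -> int:
        return self.P.shape[1]

    @classmethod
    def from_modes(cls, modes, labels=None) -> "ModeMatrix":
        cols = [m.p if hasattr(m, "p") else np.asarray(m, dtype=float) for m in modes]
        if labels is None:
            labels = [f"mode_{k + 1}" for k in range(len(cols))]
        return cls(np.column_stack(cols), list(labels))

    @classmethod
    def from_decomposition(cls, d) -> "ModeMatrix":
        return cls.from_modes(d.modes)

    def subset(self, keep) -> "ModeMatrix":
        keep = list(keep)
        return ModeMatrix(self.P[:, keep], [self.labels[k] for k in keep])


@dataclass
class ModeWeightResult:
    w: np.ndarray | None
    objective: float | None
    status: str  # 'optimal' | 'infeasible' | 'unbounded'

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


def optimize_over_modes(model: MetabolicModel, P: ModeMatrix) -> ModeWeightResult:
    """Biologically optimal nonnegative weights over the given modes."""
    if P.P.shape[0] != model.n:
        raise ValueError(
            f"mode matrix has {P.P.shape[0]} rows, model has {model.n} reactions"
        )
    if P.K == 0:
        # only v = 0 is representable
        if np.all(model.a <= 0):
            return ModeWeightResult(w=np.zeros(0), objective=0.0, status="optimal")
        return ModeWeightResult(w=None, objective=None, status="infeasible")
    res = linprog(
        c=-(P.P.T @ model.f),
        A_ub=np.vstack([P.P, -P.P]),
        b_ub=np.concatenate([model.b, -model.a]),
        bounds=[(0, None)] * P.K,
        method="highs",
    )
    if res.status == 0:
        return ModeWeightResult(w=np.asarray(res.x), objective=float(-res.fun),
                                status="optimal")
    if res.status == 2:
        return ModeWeightResult(w=None, objective=None, status="infeasible")
    if res.status == 3:
        return ModeWeightResult(w=None, objective=None, status="unbounded")
    raise RuntimeError(f"LP solver failed: {res.message}")


def modes_sufficient(model: MetabolicModel, P: ModeMatrix,
                     reference_objective: float,
                     tol: float = SUFFICIENCY_RTOL) -> bool:
    """Do the modes reproduce the full-network FBA optimum?

    True iff the mode-restricted optimum agrees with
    ``reference_objective`` to relative tolerance ``tol``.  An
    infeasible restricted problem (e.g. positive lower bounds no
    nonnegative combination can reach) counts as insufficient.
    """
    res = optimize_over_modes(model, P)
    if not res.ok:
        return False
    return abs(res.objective - reference_objective) <= tol * max(
        1.0, abs(reference_objective)
    )


def minimal_supporting_subset(model_family, P: ModeMatrix,
                              tol: float = SUFFICIENCY_RTOL) -> ModeMatrix:
    """Greedily shrink a sufficient mode set, keeping it sufficient family-wide.

    ``model_family`` is a list of model variants (same reactions,
    different bounds).  Columns are attempted for removal in ascending
    order of the maximum weight they carry across the family's initial
    optima, so rarely-used modes go first; a column is dropped iff
    sufficiency holds for every variant without it.  The result is
    minimal — removing any single remaining column breaks sufficiency
    for at least one variant — but not necessarily unique.
    """
    from .fba import solve_fba

    model_family = list(model_family)
    refs = []
    for variant in model_family:
        fba = solve_fba(variant)
        if not fba.ok:
            raise InsufficientModesError(
                f"FBA on a family variant is {fba.status}; no reference objective"
            )
        refs.append(fba.objective_value)
    for variant, ref in zip(model_family, refs):
        if not modes_sufficient(variant, P, ref, tol):
            raise InsufficientModesError(
                "initial mode set is insufficient for at least one family variant"
            )

    max_used = np.zeros(P.K)
    for variant in model_family:
        res = optimize_over_modes(variant, P)
        if res.ok:
            max_used = np.maximum(max_used, res.w)
    order = np.argsort(max_used, kind="stable")

    keep = list(range(P.K))
    for k in order:
        if len(keep) == 1:
            break
        trial = [i for i in keep if i != k]
        sub = P.subset(trial)
        if all(modes_sufficient(vr, sub, ref, tol)
               for vr, ref in zip(model_family, refs)):
            keep = trial
    return P.subset(keep)


def sweep_characterization(model: MetabolicModel, sweep, P: ModeMatrix) -> pd.DataFrame:
    """Mode weights and objective across a sweep of one-reaction upper bounds.

    ``sweep`` is a list of ``(reaction_id, value)`` pairs; each point
    sets that reaction's upper bound to ``value`` and re-solves the
    mode-weight LP.  Returns a table with one row per sweep point:
    reaction id, bound value, objective, and one column per mode weight.
    Raises if the mode set is insufficient at any point, naming it.
    """
    from .fba import solve_fba

    rows = []
    for rid, value in sweep:
        variant = model.with_bound(rid, ub=value)
        fba = solve_fba(variant)
        if not fba.ok:
            raise InsufficientModesError(
                f"FBA {fba.status} at sweep point ({rid}, {value})"
            )
        res = optimize_over_modes(variant, P)
        if not res.ok or not modes_sufficient(variant, P, fba.objective_value):
            raise InsufficientModesError(
                f"mode set insufficient at sweep point ({rid}, {value})"
            )
        row = {"reaction_id": rid, "bound_value": value,
               "objective": res.objective}
        row.update({lab: w for lab, w in zip(P.labels, res.w)})
        rows.append(row)
    cols = ["reaction_id", "bound_value", "objective"] + list(P.labels)
    return pd.DataFrame(rows, columns=cols)
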