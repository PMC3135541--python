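"""Flux-balance analysis and steady-state balancing of measured fluxes.

FBA finds a biologically optimal flux distribution by solving the LP

    maximize  f @ v
    subject to  S v = 0,  a <= v <= b,

whose optimum is generally a vertex of the feasible polytope and need
not be unique; the solver's returned optimum is accepted as-is.
Measured flux tables that violate mass balance can be projected onto
the steady-state subspace (null space of S) before decomposition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg
from scipy.optimize import linprog

from .model_io import MetabolicModel

#: relative tolerance on the steady-state residual ||S v||_inf
STEADY_STATE_RTOL = 1e-8


@dataclass
class FbaResult:
    """Outcome of the flux-balance LP."""

    v: np.ndarray | None
    objective_value: float | None
    status: str  # 'optimal' | 'infeasible' | 'unbounded'

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


def solve_fba(model: MetabolicModel) -> FbaResult:
    """Maximize ``f @ v`` over the bounded steady-state flux polytope.

    Returns status faithfully: an infeasible or unbounded LP is reported
    in ``status``, never raised silently or masked with zeros.
    """
    res = linprog(
        c=-model.f,
        A_eq=model.S,
        b_eq=np.zeros(model.m),
        bounds=list(zip(model.a, model.b)),
        method="highs",
    )
    if res.status == 0:
        return FbaResult(v=np.asarray(res.x), objective_value=float(-res.fun),
                         status="optimal")
    if res.status == 2:
        return FbaResult(v=None, objective_value=None, status="infeasible")
    if res.status == 3:
        return FbaResult(v=None, objective_value=None, status="unbounded")
    raise RuntimeError(f"LP solver failed: {res.message}")


def steady_state_residual(model: MetabolicModel, v: np.ndarray) -> float:
    """||S v||_inf scaled by max(1, ||v||_inf)."""
    v = np.asarray(v, dtype=float)
    return float(np.max(np.abs(model.S @ v), initial=0.0)
                 / max(1.0, np.max(np.abs(v), initial=0.0)))


def is_steady_state(model: MetabolicModel, v: np.ndarray,
                    rtol: float = STEADY_STATE_RTOL) -> bool:
    return steady_state_residual(model, v) <= rtol


def balance_fluxes(model: MetabolicModel, v_meas: np.ndarray) -> np.ndarray:
    """Project a measured flux vector onto the steady-state subspace.

    Returns the Euclidean-least-squares projection of ``v_meas`` onto
    the null space of S.  The projection is then clipped to the model
    bounds only if clipping preserves the steady state; otherwise the
    unclipped projection is returned with a warning (fluxes outside the
    bounds are a modelling problem, breaking mass balance is worse).

    The projection is linear and idempotent, hence non-expansive in the
    Euclidean norm.  No sign preservation is guaranteed: a measured
    irreversible flux may project to a small negative value.
    """
    v_meas = np.asarray(v_meas, dtype=float)
    if v_meas.shape != (model.n,):
        raise ValueError(f"flux vector has shape {v_meas.shape}, expected ({model.n},)")
    N = linalg.null_space(model.S)
    if N.size == 0:
        v_proj = np.zeros(model.n)
    else:
        v_proj = N @ (N.T @ v_meas)
    v_clip = np.clip(v_proj, model.a, model.b)
    if np.allclose(v_clip, v_proj):
        return v_proj
    if is_steady_state(model, v_clip):
        return v_clip
    warnings.warn(
        "clipping the balanced fluxes to the model bounds would break the "
        "steady state; returning the unclipped projection",
        stacklevel=2,
    )
    return v_proj
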