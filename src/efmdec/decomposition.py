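"""Iterative elementary-flux-mode decomposition of a flux distribution.

Any steady-state flux distribution ``v`` (``S v = 0``) can be written as
a positively weighted sum of elementary flux modes (EFMs) that *conform*
to it — modes whose every active reaction carries flux of the same sign
as in ``v``.  Rather than enumerating all EFMs up front (exponential in
network size), this module extracts one conforming EFM at a time:

1. pick a pivot reaction, by default the one with the largest residual
   flux magnitude;
2. solve a minimum-support MILP for a conforming steady-state mode
   through the pivot — minimal support makes the mode elementary;
3. give the mode the largest weight that keeps the residual conforming,
   ``w = min_{j in R(p)} v_j / p_j``, which zeroes at least one residual
   entry;
4. subtract and repeat until the residual vanishes.

Because every iteration strictly shrinks the residual support, the loop
terminates after at most ``|R(v)|`` iterations.  Decompositions are not
unique; any pivot rule yields a valid one.

The MILP couples each candidate flux ``p_j`` (for ``j`` in the residual
support) to a binary activity indicator ``q_j`` through big-M bounds

    q_j <= sgn(v_j) p_j <= M q_j,

fixes ``p_j = 0`` off the support and ``q_pivot = 1``, and minimizes
``sum_j q_j`` subject to ``S p = 0``.  Active fluxes are scaled to lie
in ``[1, M]``, so M bounds the max/min flux ratio within one mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, milp

from .fba import is_steady_state, steady_state_residual
from .model_io import MetabolicModel

DEFAULT_EPS_ZERO = 1e-9
DEFAULT_BIG_M = 1e4

NORMALIZATIONS = ("max_abs_one", "pivot_one", "raw")


class DecompositionError(RuntimeError):
    """Decomposition failed; carries the partial trace for debugging."""

    def __init__(self, message: str, partial=None):
        super().__init__(message)
        self.partial = partial


class ConformingModeNotFound(DecompositionError):
    """The minimum-support MILP was infeasible for the given pivot."""


@dataclass
class FluxDistribution:
    """A flux vector with an explicit zero threshold defining its support."""

    v: np.ndarray
    eps_zero: float = DEFAULT_EPS_ZERO

    def __post_init__(self):
        self.v = np.asarray(self.v, dtype=float)

    @property
    def support_set(self) -> frozenset[int]:
        return support(self.v, self.eps_zero)


@dataclass
class FluxMode:
    """A steady-state flux vector with sign constraints on its support.

    ``pivot`` records the reaction index the mode was extracted for (or
    None for externally supplied modes); ``normalization`` states the
    scaling convention of ``p``.
    """

    p: np.ndarray
    pivot: int | None = None
    normalization: str = "raw"
    eps_zero: float = DEFAULT_EPS_ZERO

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)

    @property
    def support(self) -> frozenset[int]:
        return support(self.p, self.eps_zero)

    def normalized(self, normalization: str) -> "FluxMode":
        if normalization not in NORMALIZATIONS:
            raise ValueError(f"unknown normalization {normalization!r}")
        if normalization == "raw":
            return FluxMode(self.p.copy(), self.pivot, "raw", self.eps_zero)
        if normalization == "max_abs_one":
            scale = np.max(np.abs(self.p))
        else:  # pivot_one
            if self.pivot is None:
                raise ValueError("pivot_one normalization requires a pivot")
            scale = abs(self.p[self.pivot])
        if scale == 0:
            raise ValueError("cannot normalize the zero vector")
        return FluxMode(self.p / scale, self.pivot, normalization, self.eps_zero)


@dataclass
class MilpSolution:
    """One optimum of the minimum-support MILP."""

    p: FluxMode
    q: np.ndarray  # length-n binary indicator
    cardinality: int
    big_m_used: float


@dataclass
class Decomposition:
    """Ordered modes and weights with Σ_k w_k p^(k) = v."""

    modes: list[FluxMode]
    weights: list[float]
    residual_trace: list[int]
    pivots: list[int]

    @property
    def n_modes(self) -> int:
        return len(self.modes)

    def reconstruct(self, n: int | None = None) -> np.ndarray:
        if not self.modes:
            return np.zeros(0 if n is None else n)
        out = np.zeros_like(self.modes[0].p)
        for p, w in zip(self.modes, self.weights):
            out += w * p.p
        return out


# ---------------------------------------------------------------------
# primitive operations
# ---------------------------------------------------------------------

def support(v: np.ndarray, eps_zero: float = DEFAULT_EPS_ZERO) -> frozenset[int]:
    """Indices of reactions carrying flux of magnitude above ``eps_zero``."""
    if eps_zero < 0:
        raise ValueError("eps_zero must be nonnegative")
    v = np.asarray(v, dtype=float)
    return frozenset(np.flatnonzero(np.abs(v) > eps_zero).tolist())


def conforms(p: np.ndarray | FluxMode, v: np.ndarray | FluxDistribution,
             eps_zero: float = DEFAULT_EPS_ZERO) -> bool:
    """True iff every active flux of ``p`` has the sign of the same flux in ``v``.

    A conforming mode never runs a reaction that is silent or reversed
    in ``v``: ``p_j > 0`` requires ``v_j > 0`` and ``p_j < 0`` requires
    ``v_j < 0`` (at the ``eps_zero`` threshold).
    """
    if isinstance(p, FluxMode):
        p = p.p
    if isinstance(v, FluxDistribution):
        eps_zero = v.eps_zero
        v = v.v
    p = np.asarray(p, dtype=float)
    v = np.asarray(v, dtype=float)
    if p.shape != v.shape:
        raise ValueError(f"dimension mismatch: {p.shape} vs {v.shape}")
    pos = p > eps_zero
    neg = p < -eps_zero
    return bool(np.all(v[pos] > eps_zero) and np.all(v[neg] < -eps_zero))


def select_pivot(v: np.ndarray | FluxDistribution,
                 eps_zero: float = DEFAULT_EPS_ZERO,
                 rule: str = "max-abs") -> int:
    """Pick the next pivot reaction from the residual support.

    ``max-abs`` (default) takes the reaction of maximum flux magnitude,
    which upper-bounds the extracted mode's contribution by a large flux
    and avoids modes with negligible weights.  ``min-index`` takes the
    first reaction in the support; any rule yields a valid
    decomposition.  Ties break to the lowest reaction index.
    """
    if isinstance(v, FluxDistribution):
        eps_zero = v.eps_zero
        v = v.v
    v = np.asarray(v, dtype=float)
    supp = support(v, eps_zero)
    if not supp:
        raise ValueError("nothing to decompose: empty support")
    if rule == "max-abs":
        return int(np.argmax(np.abs(v)))
    if rule == "min-index":
        return min(supp)
    raise ValueError(f"unknown pivot rule {rule!r}")


def find_conforming_efm(model: MetabolicModel, v: np.ndarray | FluxDistribution,
                        pivot: int, big_m: float = DEFAULT_BIG_M,
                        eps_zero: float = DEFAULT_EPS_ZERO,
                        max_retries: int = 5) -> MilpSolution:
    """Minimum-support conforming steady-state mode through ``pivot``.

    Solves the big-M indicator MILP described in the module docstring
    with HiGHS.  The optimum's support is minimal among all modes that
    conform to ``v`` and contain the pivot, hence the mode is elementary
    within the conforming set.  If any active flux lands within
    ``1e-6 * M`` of the big-M bound, M is doubled and the MILP re-solved
    (a too-small M silently truncates wide-dynamic-range modes); after
    ``max_retries`` doublings a big-M error is raised.
    """
    if isinstance(v, FluxDistribution):
        eps_zero = v.eps_zero
        v = v.v
    v = np.asarray(v, dtype=float)
    supp = sorted(support(v, eps_zero))
    if pivot not in supp:
        raise ValueError(f"pivot {pivot} is not in the support of v")
    r = len(supp)
    signs = np.sign(v[supp])
    S_r = model.S[:, supp]
    piv_pos = supp.index(pivot)

    m_cur = float(big_m)
    for _attempt in range(max_retries + 1):
        # variables: x = [p_supp (r continuous), q_supp (r binary)]
        c = np.concatenate([np.zeros(r), np.ones(r)])
        integrality = np.concatenate([np.zeros(r), np.ones(r)])
        lb_p = np.where(signs > 0, 0.0, -m_cur)
        ub_p = np.where(signs > 0, m_cur, 0.0)
        lb_q = np.zeros(r)
        ub_q = np.ones(r)
        lb_q[piv_pos] = 1.0
        bounds = Bounds(np.concatenate([lb_p, lb_q]), np.concatenate([ub_p, ub_q]))

        constraints = [
            LinearConstraint(
                np.hstack([S_r, np.zeros((model.m, r))]),
                np.zeros(model.m), np.zeros(model.m),
            ),
            # sgn(v_j) p_j - q_j >= 0  (active flux at least 1)
            LinearConstraint(
                np.hstack([np.diag(signs), -np.eye(r)]), 0.0, np.inf
            ),
            # sgn(v_j) p_j - M q_j <= 0  (inactive flux forced to 0)
            LinearConstraint(
                np.hstack([np.diag(signs), -m_cur * np.eye(r)]), -np.inf, 0.0
            ),
        ]
        res = milp(c=c, constraints=constraints, integrality=integrality,
                   bounds=bounds)
        if res.status == 2:  # infeasible
            raise ConformingModeNotFound(
                f"no conforming mode through pivot {model.reaction_ids[pivot]!r}: "
                "the input may not be steady-state, eps_zero may be misconfigured, "
                "or the residual is numerically corrupted"
            )
        if not res.success:
            raise DecompositionError(f"MILP solver failed: {res.message}")
        p_r = res.x[:r]
        q_r = (res.x[r:] > 0.5).astype(int)
        # the mode's overall scale is free in [1, M]; what M truly caps is
        # the max/min active-flux ratio, so rescale before the contact check
        active = q_r > 0
        lo = np.min(np.abs(p_r[active]))
        p_r = p_r / lo
        if np.max(np.abs(p_r[active])) < m_cur * (1.0 - 1e-6):
            p = np.zeros(model.n)
            p[supp] = np.where(active, p_r, 0.0)
            q = np.zeros(model.n, dtype=int)
            q[supp] = q_r
            mode = FluxMode(p=p, pivot=pivot, normalization="raw",
                            eps_zero=eps_zero)
            return MilpSolution(p=mode, q=q, cardinality=int(q_r.sum()),
                                big_m_used=m_cur)
        m_cur *= 2.0
    raise DecompositionError(
        f"big-M retry limit exhausted (last M = {m_cur:g}): the mode's flux "
        "dynamic range exceeds every attempted M"
    )


def compute_weight(v: np.ndarray | FluxDistribution, p: np.ndarray | FluxMode,
                   eps_zero: float = DEFAULT_EPS_ZERO) -> float:
    """Largest weight keeping ``v - w p`` conforming: ``min_{j in R(p)} v_j/p_j``.

    All ratios are positive by conformance, and the minimizing entry of
    the residual becomes exactly zero, so the residual support strictly
    shrinks at every iteration.
    """
    if isinstance(v, FluxDistribution):
        eps_zero = v.eps_zero
        v = v.v
    if isinstance(p, FluxMode):
        p = p.p
    v = np.asarray(v, dtype=float)
    p = np.asarray(p, dtype=float)
    if not conforms(p, v, eps_zero):
        raise ValueError("mode does not conform to the flux distribution")
    supp = sorted(support(p, eps_zero))
    if not supp:
        raise ValueError("mode has empty support")
    ratios = v[supp] / p[supp]
    w = float(np.min(ratios))
    if w <= 0:
        raise ValueError("non-positive weight: mode does not conform numerically")
    return w


# ---------------------------------------------------------------------
# the decomposition loop
# ---------------------------------------------------------------------

def decompose(model: MetabolicModel, v: np.ndarray | FluxDistribution, *,
              eps_zero: float = DEFAULT_EPS_ZERO, big_m: float = DEFAULT_BIG_M,
              pivot_rule: str = "max-abs", normalization: str = "max_abs_one",
              max_big_m_retries: int = 5, log=None) -> Decomposition:
    """Decompose a steady-state flux distribution into conforming EFMs.

    Iterates pivot selection, minimum-support MILP, weight computation
    and subtraction until the residual support is empty.  Residual
    entries below ``eps_zero * max(1, ||v||_inf)`` are snapped to exactly
    zero after each subtraction so floating-point dust cannot spawn
    spurious iterations.  Modes are reported under ``normalization``
    with weights rescaled so that ``sum_k w_k p^(k) = v`` is preserved.

    Raises a precondition error before any MILP call if ``v`` is not
    steady-state or an irreversible reaction carries negative flux; a
    MILP failure mid-run raises :class:`DecompositionError` carrying the
    partial decomposition in ``.partial``.
    """
    if isinstance(v, FluxDistribution):
        eps_zero = v.eps_zero
        v = v.v
    v = np.asarray(v, dtype=float)
    if v.shape != (model.n,):
        raise ValueError(f"flux vector has shape {v.shape}, expected ({model.n},)")
    if not is_steady_state(model, v):
        raise ValueError(
            f"input is not steady-state: ||S v||_inf residual "
            f"{steady_state_residual(model, v):.3g} exceeds tolerance"
        )
    bad = [model.reaction_ids[j] for j in np.flatnonzero(
        model.irreversible & (v < -eps_zero))]
    if bad:
        raise ValueError(f"irreversible reactions carry negative flux: {bad}")

    scale = max(1.0, float(np.max(np.abs(v), initial=0.0)))
    snap = eps_zero * scale
    resid = v.copy()
    resid[np.abs(resid) < snap] = 0.0

    modes: list[FluxMode] = []
    weights: list[float] = []
    pivots: list[int] = []
    trace: list[int] = [len(support(resid, eps_zero))]
    max_iters = trace[0]

    while support(resid, eps_zero):
        if len(modes) >= max_iters:
            raise DecompositionError(
                "iteration bound |R(v)| exceeded without the residual vanishing",
                partial=Decomposition(modes, weights, trace, pivots),
            )
        pivot = select_pivot(resid, eps_zero, rule=pivot_rule)
        try:
            sol = find_conforming_efm(model, resid, pivot, big_m=big_m,
                                      eps_zero=eps_zero,
                                      max_retries=max_big_m_retries)
            w = compute_weight(resid, sol.p, eps_zero)
        except DecompositionError as exc:
            exc.partial = Decomposition(modes, weights, trace, pivots)
            raise
        resid = resid - w * sol.p.p
        resid[np.abs(resid) < snap] = 0.0
        modes.append(sol.p)
        weights.append(w)
        pivots.append(pivot)
        trace.append(len(support(resid, eps_zero)))
        if log is not None:
            log.info(
                "iteration %d: pivot %s, |R(p)|=%d, w=%.6g, |R(residual)|=%d",
                len(modes), model.reaction_ids[pivot], len(sol.p.support),
                w, trace[-1],
            )

    # re-express modes under the requested normalization; p' = p/s needs
    # w' = w*s to preserve sum w p = v
    out_modes, out_weights = [], []
    for p, w in zip(modes, weights):
        if normalization == "max_abs_one":
            s = float(np.max(np.abs(p.p)))
        elif normalization == "pivot_one":
            s = abs(float(p.p[p.pivot]))
        else:
            s = 1.0
        out_modes.append(p.normalized(normalization))
        out_weights.append(w * s)
    return Decomposition(modes=out_modes, weights=out_weights,
                         residual_trace=trace, pivots=pivots)


# ---------------------------------------------------------------------
# verification
# ---------------------------------------------------------------------

@dataclass
class VerificationReport:
    """Pass/fail per validity check, with numeric details."""

    checks: dict[str, bool] = field(default_factory=dict)
    details: dict[str, object] = field(default_factory=dict)

    @property
    def all_passed(self) -> bool:
        return all(self.checks.values())

    def failed(self) -> list[str]:
        return [name for name, ok in self.checks.items() if not ok]


def verify_decomposition(model: MetabolicModel, v: np.ndarray, d: Decomposition,
                         oracle_efms=None,
                         eps_zero: float = DEFAULT_EPS_ZERO) -> VerificationReport:
    """Check every guarantee a valid decomposition must satisfy.

    Asserts: the weighted modes reconstruct ``v``; each mode is
    steady-state, conforms to the *original* ``v`` (sign patterns never
    flip across iterations) and has positive weight; the mode count is
    at most ``|R(v)|``; the residual support trace is strictly
    decreasing; and, when an oracle EFM set is supplied, every mode's
    support equals the support of some enumerated EFM.
    """
    v = np.asarray(v, dtype=float)
    rep = VerificationReport()
    scale = max(1.0, float(np.max(np.abs(v), initial=0.0)))

    recon = d.reconstruct(model.n) if d.modes else np.zeros(model.n)
    resid = float(np.max(np.abs(recon - v), initial=0.0))
    rep.checks["reconstruction"] = resid <= 1e-6 * scale
    rep.details["reconstruction_residual"] = resid

    rep.checks["modes_steady_state"] = all(
        is_steady_state(model, p.p) for p in d.modes
    )
    rep.checks["modes_conform"] = all(conforms(p.p, v, eps_zero) for p in d.modes)
    rep.checks["weights_positive"] = all(w > 0 for w in d.weights)
    n_support = len(support(v, eps_zero))
    rep.checks["iteration_bound"] = d.n_modes <= n_support
    rep.details["n_modes"] = d.n_modes
    rep.details["support_size"] = n_support
    trace = d.residual_trace
    rep.checks["trace_strictly_decreasing"] = all(
        trace[i + 1] < trace[i] for i in range(len(trace) - 1)
    )

    if oracle_efms is not None:
        oracle_supports = {frozenset(s) for s in oracle_efms.supports}
        rep.checks["supports_in_oracle"] = all(
            p.support in oracle_supports for p in d.modes
        )
        rep.details["oracle_support_count"] = len(oracle_supports)
    return rep
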