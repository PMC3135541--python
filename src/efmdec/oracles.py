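"""Reference implementations: brute-force EFM enumeration and the QP baseline.

These exist to cross-check the MILP decomposition, not to compete with
it.  The enumerator walks reaction subsets in increasing cardinality and
accepts a subset as an EFM support when the stoichiometric null space
restricted to it is one-dimensional, fully active, sign-feasible for the
irreversible reactions, and not a strict superset of an already accepted
support.  Cost is exponential by design, so a hard size guard refuses
networks beyond ``max_n`` reactions.

The quadratic-programming baseline reproduces the classical two-stage
decomposition route: given *all* relevant EFMs as columns of ``P``, find
the weight vector of minimum Euclidean norm with ``P w = v, w >= 0``.
It is solved exactly by eliminating the equality constraints through the
null space of ``P`` (the minimum-norm particular solution is orthogonal
to that null space) and solving the remaining least-distance problem
with the Lawson–Hanson NNLS transformation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import linalg
from scipy.optimize import linprog, nnls

from .decomposition import (DEFAULT_EPS_ZERO, Decomposition, FluxMode,
                            conforms, support, verify_decomposition)
from .model_io import MetabolicModel

_NULLSPACE_RTOL = 1e-8


class EnumerationSizeError(ValueError):
    """Refused: brute-force enumeration above the size guard."""


class InfeasibleDecompositionError(ValueError):
    """v is not representable as a nonnegative combination of the modes."""


@dataclass
class EfmSet:
    """All elementary flux modes of a network, max-abs-one normalized.

    Reversible-only supports carry the cycle in both directions as two
    sign-opposite modes on the same support.
    """

    modes: list[FluxMode]
    supports: list[frozenset[int]]

    def __len__(self) -> int:
        return len(self.modes)

    def conforming(self, v: np.ndarray,
                   eps_zero: float = DEFAULT_EPS_ZERO) -> "EfmSet":
        """The subset of modes conforming to a flux distribution."""
        keep = [k for k, m in enumerate(self.modes)
                if conforms(m.p, v, eps_zero)]
        return EfmSet([self.modes[k] for k in keep],
                      [self.supports[k] for k in keep])


def enumerate_efms_bruteforce(model: MetabolicModel, max_n: int = 14) -> EfmSet:
    """Enumerate every EFM of a small network by subset search.

    A subset T of reactions is an EFM support iff null(S[:, T]) is
    spanned by a single direction with no zero entry on T, some sign of
    that direction satisfies irreversibility (p_j >= 0 wherever
    a_j >= 0), and no accepted support is a strict subset of T.  Subsets
    are visited in increasing cardinality so the strict-subset test
    guarantees minimality.  Supports whose restricted null space has
    dimension >= 2 are rejected: a zero can then be forced at any
    position, so a strictly smaller support mode exists.
    """
    n = model.n
    if n > max_n:
        raise EnumerationSizeError(
            f"network has {n} reactions; brute-force enumeration is guarded "
            f"at max_n={max_n} (cost is exponential)"
        )
    irrev = model.irreversible
    modes: list[FluxMode] = []
    supports: list[frozenset[int]] = []
    accepted: list[frozenset[int]] = []

    for r in range(1, n + 1):
        for T in combinations(range(n), r):
            Tset = frozenset(T)
            if any(sup < Tset for sup in accepted):
                continue
            N = linalg.null_space(model.S[:, T])
            if N.shape[1] != 1:
                continue
            d = N[:, 0]
            amax = np.max(np.abs(d))
            if np.min(np.abs(d)) <= _NULLSPACE_RTOL * amax:
                continue  # direction has an interior zero: support is smaller
            d = d / amax
            irrev_T = irrev[list(T)]
            emitted = False
            for sgn in (1.0, -1.0):
                cand = sgn * d
                if np.all(cand[irrev_T] > 0):
                    p = np.zeros(n)
                    p[list(T)] = cand
                    modes.append(FluxMode(p=p, pivot=None,
                                          normalization="max_abs_one"))
                    supports.append(Tset)
                    emitted = True
            if emitted:
                accepted.append(Tset)
    return EfmSet(modes=modes, supports=supports)


# ---------------------------------------------------------------------
# minimum-Euclidean-norm weights (classical QP baseline)
# ---------------------------------------------------------------------

def _ldp(G: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Least-distance problem min ||x|| s.t. G x >= h, via NNLS."""
    m, n = G.shape
    E = np.vstack([G.T, h[None, :]])
    f = np.zeros(n + 1)
    f[-1] = 1.0
    u, rnorm = nnls(E, f)
    r = E @ u - f
    if rnorm == 0.0 or abs(r[-1]) < 1e-12:
        raise InfeasibleDecompositionError("least-distance problem infeasible")
    return -r[:n] / r[-1]


def qp_decompose(P, v: np.ndarray, atol: float = 1e-8) -> np.ndarray:
    """Minimum-Euclidean-norm nonnegative weights with ``P w = v`` exactly.

    ``P`` is an n x K array or a ModeMatrix.  Raises
    :class:`InfeasibleDecompositionError` when ``v`` lies outside the
    cone spanned by the mode columns.
    """
    P_arr = P.P if hasattr(P, "P") else np.atleast_2d(np.asarray(P, dtype=float))
    v = np.asarray(v, dtype=float)
    n, K = P_arr.shape
    if v.shape != (n,):
        raise ValueError(f"v has shape {v.shape}, expected ({n},)")
    if K == 0:
        if np.max(np.abs(v), initial=0.0) <= atol:
            return np.zeros(0)
        raise InfeasibleDecompositionError("v not representable by given modes")

    # feasibility certificate first, so infeasibility is reported cleanly
    feas = linprog(c=np.zeros(K), A_eq=P_arr, b_eq=v,
                   bounds=[(0, None)] * K, method="highs")
    if feas.status == 2:
        raise InfeasibleDecompositionError("v not representable by given modes")
    if feas.status != 0:
        raise RuntimeError(f"feasibility LP failed: {feas.message}")

    w0, *_ = np.linalg.lstsq(P_arr, v, rcond=None)
    # lstsq returns the min-norm solution, orthogonal to null(P)
    N = linalg.null_space(P_arr)
    if N.shape[1] == 0:
        w = w0
    else:
        z = _ldp(N, -w0)
        w = w0 + N @ z
    w = np.where(np.abs(w) < 1e-12, 0.0, w)
    scale = max(1.0, float(np.max(np.abs(v), initial=0.0)))
    if np.max(np.abs(P_arr @ w - v), initial=0.0) > atol * scale or np.min(
            w, initial=0.0) < -1e-10:
        raise InfeasibleDecompositionError(
            "QP solution violates constraints beyond tolerance"
        )
    return np.maximum(w, 0.0)


def compare_decompositions(model: MetabolicModel, v: np.ndarray,
                           milp_result: Decomposition, full_efms: EfmSet,
                           eps_zero: float = DEFAULT_EPS_ZERO) -> dict:
    """Run both decomposition routes on the same v and report validity.

    The QP route uses the conforming subset of the full EFM set (the
    classical pipeline prunes zero-flux reactions before enumeration,
    which is equivalent to keeping conforming modes).  Returns a report
    with both reconstruction residuals and mode counts; both routes must
    yield valid decompositions of the same ``v``.
    """
    v = np.asarray(v, dtype=float)
    scale = max(1.0, float(np.max(np.abs(v), initial=0.0)))
    conf = full_efms.conforming(v, eps_zero)
    if len(conf) == 0 and np.max(np.abs(v), initial=0.0) <= eps_zero:
        w_qp = np.zeros(0)
        qp_resid = 0.0
        qp_count = 0
    else:
        P = np.column_stack([m.p for m in conf.modes])
        w_qp = qp_decompose(P, v)
        qp_resid = float(np.max(np.abs(P @ w_qp - v), initial=0.0))
        qp_count = int(np.sum(w_qp > 1e-9 * scale))
    milp_report = verify_decomposition(model, v, milp_result,
                                       oracle_efms=full_efms,
                                       eps_zero=eps_zero)
    return {
        "qp_weights": w_qp,
        "qp_reconstruction_residual": qp_resid,
        "qp_mode_count": qp_count,
        "qp_weights_nonnegative": bool(np.min(w_qp, initial=0.0) >= -1e-10),
        "qp_valid": qp_resid <= 1e-6 * scale,
        "milp_mode_count": milp_result.n_modes,
        "milp_report": milp_report,
        "milp_valid": milp_report.all_passed,
        "both_valid": (qp_resid <= 1e-6 * scale) and milp_report.all_passed,
    }
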