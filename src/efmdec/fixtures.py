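"""Toy networks and synthetic flux generators with known ground truth.

Every fixture ships with a hand-enumerated EFM count, and the test suite
re-derives each count with the brute-force enumerator, so the fixtures
double-check the oracle and vice versa.  Synthetic flux distributions
are built as positive combinations of enumerated EFMs, which makes them
steady-state by construction and gives decomposition tests a known
generating set to recover supports from.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

from .model_io import MetabolicModel


@dataclass
class FixtureSpec:
    name: str
    model: MetabolicModel
    known_efm_count: int
    notes: str


def _model(mets, reactions):
    """reactions: list of (id, {met: coeff}, lb, ub, obj)."""
    rxn_ids = [r[0] for r in reactions]
    S = np.zeros((len(mets), len(reactions)))
    midx = {m: i for i, m in enumerate(mets)}
    for j, (_, stoich, *_rest) in enumerate(reactions):
        for met, coeff in stoich.items():
            S[midx[met], j] = coeff
    a = np.array([r[2] for r in reactions], dtype=float)
    b = np.array([r[3] for r in reactions], dtype=float)
    f = np.array([r[4] for r in reactions], dtype=float)
    return MetabolicModel(list(mets), rxn_ids, S, a, b, f)


def chain_model() -> MetabolicModel:
    """Uptake -> M1 -> excretion; the smallest nontrivial network (1 EFM)."""
    return _model(["M1"], [
        ("R1", {"M1": 1}, 0, 10, 0),
        ("R2", {"M1": -1}, 0, 10, 1),
    ])


def diamond_model() -> MetabolicModel:
    """Two parallel branches A -> B with capped capacity 4 each (2 EFMs)."""
    return _model(["A", "B"], [
        ("R1", {"A": 1}, 0, 10, 0),
        ("R2", {"A": -1, "B": 1}, 0, 4, 0),
        ("R3", {"A": -1, "B": 1}, 0, 4, 0),
        ("R4", {"B": -1}, 0, 10, 1),
    ])


def reversible_cycle_model() -> MetabolicModel:
    """A <-> B <-> C <-> A, all reversible, no exchanges (2 EFMs: each direction)."""
    return _model(["A", "B", "C"], [
        ("R1", {"A": -1, "B": 1}, -10, 10, 0),
        ("R2", {"B": -1, "C": 1}, -10, 10, 0),
        ("R3", {"C": -1, "A": 1}, -10, 10, 0),
    ])


def reversible_branch_model() -> MetabolicModel:
    """Uptake of B, reversible A<->B conversion, excretion of A (1 EFM).

    The only mode runs the conversion backwards (B -> A), so it carries
    negative flux on R2 and exercises negative-sign conformance.
    """
    return _model(["A", "B"], [
        ("R1", {"B": 1}, 0, 10, 0),
        ("R2", {"A": -1, "B": 1}, -10, 10, 0),
        ("R3", {"A": -1}, 0, 10, 1),
    ])


def dual_demand_model() -> MetabolicModel:
    """One substrate feeding two obligatory sinks (2 EFMs).

    Positive lower bounds on both demand reactions — a growth demand and
    a maintenance demand, mirroring the biomass/NGAM structure of
    genome-scale models — mean no single EFM is a feasible flux
    distribution on its own: any valid behavior needs both modes, so the
    chosen modes must complement each other.
    """
    return _model(["A", "B", "C"], [
        ("R1", {"A": 1}, 0, 10, 0),
        ("R2", {"A": -1, "B": 1}, 0, 10, 0),
        ("R3", {"A": -1, "C": 1}, 0, 10, 0),
        ("R4", {"B": -1}, 0.5, 10, 1),   # growth demand
        ("R5", {"C": -1}, 1.0, 10, 0),   # maintenance demand
    ])


def builtin_fixtures() -> list[FixtureSpec]:
    """The fixture library; every count is hand-enumerated and oracle-checked."""
    return [
        FixtureSpec("chain", chain_model(), 1,
                    "single path, null space of [[1,-1]] is span{(1,1)}"),
        FixtureSpec("diamond", diamond_model(), 2,
                    "branches give supports {R1,R2,R4} and {R1,R3,R4}"),
        FixtureSpec("rev_cycle", reversible_cycle_model(), 2,
                    "1-D null space (1,1,1); both directions valid"),
        FixtureSpec("rev_branch", reversible_branch_model(), 1,
                    "unique mode (1,-1,1): conversion must run B->A"),
        FixtureSpec("dual_demand", dual_demand_model(), 2,
                    "fork to two sinks: {R1,R2,R4} and {R1,R3,R5}"),
    ]


def fixture(name: str) -> FixtureSpec:
    for spec in builtin_fixtures():
        if spec.name == name:
            return spec
    raise KeyError(f"no builtin fixture named {name!r}")


# ---------------------------------------------------------------------
# synthetic flux distributions
# ---------------------------------------------------------------------

def random_flux_from_efms(efms, k: int, seed: int, *, max_retries: int = 200):
    """Synthesize v = sum_i c_i e_i from k sign-compatible oracle EFMs.

    Weights are Uniform(0.5, 2.0) — ratios benign relative to the
    default big-M.  Mode pairs carrying some reaction with opposite
    signs are rejected and resampled, so v conforms with each of its
    generators and the generating combination is itself a valid
    decomposition.  Returns ``(v, [(mode_index, weight), ...])``.
    """
    if k > len(efms):
        raise ValueError(f"cannot sample {k} distinct modes from {len(efms)}")
    rng = np.random.default_rng(seed)
    eps = 1e-9
    for _ in range(max_retries):
        idx = rng.choice(len(efms), size=k, replace=False)
        vecs = [efms.modes[i].p for i in idx]
        compatible = True
        for i in range(k):
            for j in range(i + 1, k):
                if np.any((vecs[i] > eps) & (vecs[j] < -eps)) or np.any(
                        (vecs[i] < -eps) & (vecs[j] > eps)):
                    compatible = False
        if not compatible:
            continue
        weights = rng.uniform(0.5, 2.0, size=k)
        v = np.zeros_like(vecs[0])
        for c, e in zip(weights, vecs):
            v += c * e
        return v, list(zip(idx.tolist(), weights.tolist()))
    raise RuntimeError(
        f"no sign-compatible sample of {k} modes found in {max_retries} tries"
    )


def max_sign_compatible_k(efms, k_max: int = 3, *, probe_seed: int = 0) -> int:
    """Largest k <= k_max for which a sign-compatible k-mode sample exists.

    Sign-opposite mode pairs (e.g. a reversible cycle run in both
    directions) cannot be combined, so some networks only admit k=1.
    """
    eps = 1e-9
    vecs = [m.p for m in efms.modes]
    best = 1 if vecs else 0
    # greedy growth from each start suffices at fixture scale
    for start in range(len(vecs)):
        chosen = [start]
        for j in range(len(vecs)):
            if j in chosen or len(chosen) >= k_max:
                continue
            ok = all(
                not (np.any((vecs[i] > eps) & (vecs[j] < -eps))
                     or np.any((vecs[i] < -eps) & (vecs[j] > eps)))
                for i in chosen
            )
            if ok:
                chosen.append(j)
        best = max(best, len(chosen))
    return min(best, k_max)


def random_network(n_mets: int, n_rxns: int, density: float = 0.2,
                   seed: int = 0, *, max_retries: int = 500) -> MetabolicModel:
    """A small random stoichiometric network with a nonempty flux cone.

    One uptake exchange feeds the first metabolite and one excretion
    exchange drains the last; internal reactions convert a random
    substrate into a random product with integer coefficients in
    {-2..2}, occasionally (probability ``density``) touching a third
    metabolite.  Internal reactions are reversible with probability
    0.25.  Candidates whose steady-state cone cannot carry flux through
    the excretion exchange are discarded and regenerated, so every
    returned model admits a nonzero steady-state flux vector (hence at
    least one EFM).  Fully reproducible from ``seed``.
    """
    if n_rxns < 3:
        raise ValueError("need at least 3 reactions (two exchanges + one internal)")
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        S = np.zeros((n_mets, n_rxns))
        S[0, 0] = 1.0                      # uptake
        S[n_mets - 1, n_rxns - 1] = -1.0   # excretion
        a = np.zeros(n_rxns)
        b = np.full(n_rxns, 10.0)
        for j in range(1, n_rxns - 1):
            s_met, t_met = rng.choice(n_mets, size=2, replace=False)
            S[s_met, j] = -float(rng.integers(1, 3))
            S[t_met, j] = float(rng.integers(1, 3))
            if rng.random() < density and n_mets > 2:
                extra = rng.choice([m for m in range(n_mets)
                                    if m not in (s_met, t_met)])
                S[extra, j] = float(rng.choice([-2, -1, 1, 2]))
            if rng.random() < 0.25:
                a[j] = -10.0
        f = np.zeros(n_rxns)
        f[n_rxns - 1] = 1.0
        res = linprog(c=-f, A_eq=S, b_eq=np.zeros(n_mets),
                      bounds=list(zip(a, b)), method="highs")
        if res.status == 0 and -res.fun > 1e-6:
            mets = [f"M{i + 1}" for i in range(n_mets)]
            rxns = [f"R{j + 1}" for j in range(n_rxns)]
            return MetabolicModel(mets, rxns, S, a, b, f)
    raise RuntimeError(
        f"failed to generate a flux-carrying network in {max_retries} tries"
    )
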