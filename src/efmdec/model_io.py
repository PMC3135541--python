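"""Reading, validating and writing metabolic models and flux tables.

A metabolic network is carried as a :class:`MetabolicModel`: an m x n
stoichiometric matrix ``S`` over ``m`` metabolites and ``n`` reactions,
flux bounds ``a <= v <= b`` and a linear objective vector ``f``.  Two
on-disk formats are supported for models: SBML Level 3 with the FBC v2
package (the format genome-scale reconstructions are distributed in) and
a flat JSON dialect designed so that toy networks are human-writable and
diff-able.  Flux distributions travel as two-column TSV tables
(``reaction_id``, ``flux``); reactions absent from a table carry flux 0.

Reaction order is authoritative from the file: every vector in the
package (fluxes, modes, bounds) is aligned to the model's declared
reaction order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


class ModelFormatError(ValueError):
    """The input file could not be parsed in the declared format."""


class ModelValidationError(ValueError):
    """A parsed model violates a structural invariant (bounds, duplicates)."""


class FluxTableError(ValueError):
    """A flux table references unknown or duplicated reaction ids."""


@dataclass
class MetabolicModel:
    """A bounded stoichiometric network with a linear objective.

    Parameters
    ----------
    metabolite_ids : unique metabolite identifiers (length m).
    reaction_ids : unique reaction identifiers (length n).
    S : m x n stoichiometric matrix; ``S[i, j]`` is the coefficient of
        metabolite i in reaction j (negative = consumed).
    a, b : length-n lower/upper flux bounds.  A reaction is irreversible
        iff ``a[j] >= 0``.  Every upper bound must be positive and
        ``a[j] <= b[j]``.
    f : length-n objective weights; flux-balance analysis maximizes
        ``f @ v``.
    """

    metabolite_ids: list[str]
    reaction_ids: list[str]
    S: np.ndarray
    a: np.ndarray
    b: np.ndarray
    f: np.ndarray

    def __post_init__(self) -> None:
        self.metabolite_ids = list(self.metabolite_ids)
        self.reaction_ids = list(self.reaction_ids)
        self.S = np.asarray(self.S, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        self.validate()

    # -- basic shape --------------------------------------------------
    @property
    def m(self) -> int:
        return len(self.metabolite_ids)

    @property
    def n(self) -> int:
        return len(self.reaction_ids)

    @property
    def irreversible(self) -> np.ndarray:
        """Boolean mask: reaction j is irreversible iff a[j] >= 0."""
        return self.a >= 0

    def reaction_index(self, reaction_id: str) -> int:
        try:
            return self.reaction_ids.index(reaction_id)
        except ValueError:
            raise KeyError(f"unknown reaction id {reaction_id!r}") from None

    def validate(self) -> None:
        m, n = self.m, self.n
        if m < 1 or n < 1:
            raise ModelValidationError("model must have >= 1 metabolite and >= 1 reaction")
        if self.S.shape != (m, n):
            raise ModelValidationError(
                f"S has shape {self.S.shape}, expected ({m}, {n})"
            )
        for name, vec in (("a", self.a), ("b", self.b), ("f", self.f)):
            if vec.shape != (n,):
                raise ModelValidationError(f"{name} has shape {vec.shape}, expected ({n},)")
        if len(set(self.metabolite_ids)) != m:
            raise ModelValidationError("duplicate metabolite identifiers")
        if len(set(self.reaction_ids)) != n:
            raise ModelValidationError("duplicate reaction identifiers")
        bad_ub = [rid for rid, ub in zip(self.reaction_ids, self.b) if not ub > 0]
        if bad_ub:
            raise ModelValidationError(f"non-positive upper bounds for reactions: {bad_ub}")
        bad_pair = [
            rid for rid, lb, ub in zip(self.reaction_ids, self.a, self.b) if lb > ub
        ]
        if bad_pair:
            raise ModelValidationError(
                f"lower bound exceeds upper bound for reactions: {bad_pair}"
            )

    def with_bound(self, reaction_id: str, *, lb: float | None = None,
                   ub: float | None = None) -> "MetabolicModel":
        """Return a copy with one reaction's bounds replaced."""
        j = self.reaction_index(reaction_id)
        a, b = self.a.copy(), self.b.copy()
        if lb is not None:
            a[j] = lb
        if ub is not None:
            b[j] = ub
        return MetabolicModel(self.metabolite_ids, self.reaction_ids,
                              self.S.copy(), a, b, self.f.copy())


@dataclass
class FluxTable:
    """A sparse reaction-id -> flux mapping tied to a model's namespace."""

    entries: dict[str, float]
    model_ref: MetabolicModel

    def to_vector(self) -> np.ndarray:
        v = np.zeros(self.model_ref.n)
        for rid, flux in self.entries.items():
            v[self.model_ref.reaction_index(rid)] = flux
        return v


# ---------------------------------------------------------------------
# model reading / writing
# ---------------------------------------------------------------------

def _infer_format(path: str | Path) -> str:
    suffix = Path(path).suffix.lower()
    if suffix in {".xml", ".sbml"}:
        return "sbml"
    if suffix == ".json":
        return "flat_json"
    raise ModelFormatError(f"cannot infer model format from suffix {suffix!r}")


def load_model(path: str | Path, format: str | None = None) -> MetabolicModel:
    """Load a metabolic model from SBML (L3 + FBC v2) or flat JSON.

    Reaction order is taken from the file's declaration order.  An SBML
    model without an active FBC objective gets ``f = 0``.
    """
    fmt = format or _infer_format(path)
    if fmt == "sbml":
        return _load_sbml(path)
    if fmt == "flat_json":
        return _load_flat_json(path)
    raise ModelFormatError(f"unknown model format {fmt!r}")


def _load_flat_json(path: str | Path) -> MetabolicModel:
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"invalid JSON in {path}: {exc}") from exc
    try:
        met_ids = list(doc["metabolites"])
        reactions = doc["reactions"]
    except (KeyError, TypeError) as exc:
        raise ModelFormatError(
            f"flat JSON model must have 'metabolites' and 'reactions' keys ({path})"
        ) from exc
    rxn_ids, a, b, f = [], [], [], []
    met_index = {mid: i for i, mid in enumerate(met_ids)}
    S = np.zeros((len(met_ids), len(reactions)))
    for j, rxn in enumerate(reactions):
        try:
            rxn_ids.append(rxn["id"])
            for mid, coeff in rxn["stoich"].items():
                if mid not in met_index:
                    raise ModelFormatError(
                        f"reaction {rxn['id']!r} references unknown metabolite {mid!r}"
                    )
                S[met_index[mid], j] = float(coeff)
            a.append(float(rxn["lb"]))
            b.append(float(rxn["ub"]))
            f.append(float(rxn.get("obj", 0.0)))
        except (KeyError, TypeError) as exc:
            raise ModelFormatError(f"malformed reaction entry #{j} in {path}") from exc
    return MetabolicModel(met_ids, rxn_ids, S, np.array(a), np.array(b), np.array(f))


def write_model(model: MetabolicModel, path: str | Path) -> None:
    """Write a model in the flat JSON dialect (lossless round trip)."""
    reactions = []
    for j, rid in enumerate(model.reaction_ids):
        stoich = {
            model.metabolite_ids[i]: model.S[i, j]
            for i in range(model.m)
            if model.S[i, j] != 0
        }
        reactions.append({
            "id": rid,
            "stoich": stoich,
            "lb": model.a[j],
            "ub": model.b[j],
            "obj": model.f[j],
        })
    with open(path, "w") as fh:
        json.dump({"metabolites": model.metabolite_ids, "reactions": reactions},
                  fh, indent=1)


def _load_sbml(path: str | Path) -> MetabolicModel:
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors() > 0:
        for i in range(doc.getNumErrors()):
            err = doc.getError(i)
            if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
                raise ModelFormatError(
                    f"SBML parse error in {path}: {err.getMessage().strip()}"
                )
    if doc.getLevel() != 3:
        raise ModelFormatError(
            f"unsupported SBML level {doc.getLevel()} (only Level 3 + FBC v2 is read)"
        )
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelFormatError(f"no <model> element in {path}")
    fbc = sbml_model.getPlugin("fbc")
    if fbc is None:
        raise ModelFormatError("SBML model lacks the FBC package (flux bounds required)")

    params = {
        sbml_model.getParameter(i).getId(): sbml_model.getParameter(i).getValue()
        for i in range(sbml_model.getNumParameters())
    }
    # boundary-condition species are external pools, not balanced rows
    met_ids = []
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        if not sp.getBoundaryCondition():
            met_ids.append(sp.getId())
    met_index = {mid: i for i, mid in enumerate(met_ids)}

    n = sbml_model.getNumReactions()
    rxn_ids, a, b = [], [], []
    S = np.zeros((len(met_ids), n))
    for j in range(n):
        rxn = sbml_model.getReaction(j)
        rxn_ids.append(rxn.getId())
        rfbc = rxn.getPlugin("fbc")
        if rfbc is None or not rfbc.isSetLowerFluxBound() or not rfbc.isSetUpperFluxBound():
            raise ModelFormatError(
                f"reaction {rxn.getId()!r} lacks FBC flux bounds"
            )
        a.append(params[rfbc.getLowerFluxBound()])
        b.append(params[rfbc.getUpperFluxBound()])
        for k in range(rxn.getNumReactants()):
            ref = rxn.getReactant(k)
            if ref.getSpecies() in met_index:
                S[met_index[ref.getSpecies()], j] -= ref.getStoichiometry()
        for k in range(rxn.getNumProducts()):
            ref = rxn.getProduct(k)
            if ref.getSpecies() in met_index:
                S[met_index[ref.getSpecies()], j] += ref.getStoichiometry()

    f = np.zeros(n)
    objective = fbc.getActiveObjective()
    if objective is not None:
        sense = 1.0
        if objective.isSetType() and objective.getType() == "minimize":
            sense = -1.0
        for k in range(objective.getNumFluxObjectives()):
            fo = objective.getFluxObjective(k)
            f[rxn_ids.index(fo.getReaction())] = sense * fo.getCoefficient()

    return MetabolicModel(met_ids, rxn_ids, S, np.array(a), np.array(b), f)


# ---------------------------------------------------------------------
# flux tables
# ---------------------------------------------------------------------

def load_fluxes(path: str | Path, model: MetabolicModel) -> np.ndarray:
    """Read a reaction_id/flux TSV into a vector aligned to the model.

    Unlisted reactions are flux 0; unknown or duplicated ids are errors.
    """
    table = pd.read_csv(path, sep="\t")
    missing_cols = {"reaction_id", "flux"} - set(table.columns)
    if missing_cols:
        raise FluxTableError(f"flux table {path} lacks columns {sorted(missing_cols)}")
    ids = table["reaction_id"].astype(str)
    dupes = sorted(ids[ids.duplicated()].unique())
    if dupes:
        raise FluxTableError(f"duplicate reaction ids in flux table: {dupes}")
    known = set(model.reaction_ids)
    unknown = sorted(set(ids) - known)
    if unknown:
        raise FluxTableError(f"unknown reaction ids in flux table: {unknown}")
    v = np.zeros(model.n)
    for rid, flux in zip(ids, table["flux"].astype(float)):
        v[model.reaction_index(rid)] = flux
    return v


def write_fluxes(v: Sequence[float], model: MetabolicModel, path: str | Path,
                 *, keep_zeros: bool = False) -> None:
    v = np.asarray(v, dtype=float)
    rows = [
        (rid, flux)
        for rid, flux in zip(model.reaction_ids, v)
        if keep_zeros or flux != 0
    ]
    pd.DataFrame(rows, columns=["reaction_id", "flux"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------
# decomposition output
# ---------------------------------------------------------------------

def write_decomposition(d, model: MetabolicModel, path: str | Path,
                        format: str = "json") -> None:
    """Persist a decomposition as JSON (sparse, annotated) or TSV (dense matrix).

    JSON carries, per mode: weight, normalized flux vector as a sparse
    reaction -> value map, support size and pivot reaction id, plus the
    residual support-size trace.  TSV is a reaction x mode matrix whose
    first row holds the mode weights.
    """
    if format == "json":
        payload = {
            "normalization": d.modes[0].normalization if d.modes else "raw",
            "residual_trace": list(d.residual_trace),
            "modes": [
                {
                    "weight": w,
                    "pivot": model.reaction_ids[p.pivot] if p.pivot is not None else None,
                    "support_size": len(p.support),
                    "flux": {
                        model.reaction_ids[j]: p.p[j] for j in sorted(p.support)
                    },
                }
                for p, w in zip(d.modes, d.weights)
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
    elif format == "tsv":
        cols = {"reaction_id": ["__weight__"] + model.reaction_ids}
        for k, (p, w) in enumerate(zip(d.modes, d.weights)):
            cols[f"mode_{k + 1}"] = [w] + list(p.p)
        pd.DataFrame(cols).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown decomposition format {format!r}")


def read_decomposition(path: str | Path, model: MetabolicModel):
    """Read back a JSON decomposition written by :func:`write_decomposition`."""
    from .decomposition import Decomposition, FluxMode

    with open(path) as fh:
        payload = json.load(fh)
    modes, weights = [], []
    for entry in payload["modes"]:
        p = np.zeros(model.n)
        for rid, val in entry["flux"].items():
            p[model.reaction_index(rid)] = val
        pivot = (model.reaction_index(entry["pivot"])
                 if entry.get("pivot") is not None else None)
        modes.append(FluxMode(p=p, pivot=pivot,
                              normalization=payload.get("normalization", "raw")))
        weights.append(float(entry["weight"]))
    return Decomposition(modes=modes, weights=weights,
                         residual_trace=list(payload.get("residual_trace", [])),
                         pivots=[m.pivot for m in modes])
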