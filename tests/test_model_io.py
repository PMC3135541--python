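"""Model/flux table I/O: formats, validation, round trips."""

import json

import numpy as np
import pytest

from efmdec import (decompose, load_fluxes, load_model, read_decomposition,
                    write_decomposition, write_fluxes, write_model)
from efmdec.model_io import (FluxTableError, MetabolicModel, ModelFormatError,
                             ModelValidationError)

CHAIN_JSON = {
    "metabolites": ["M1"],
    "reactions": [
        {"id": "R1", "stoich": {"M1": 1}, "lb": 0, "ub": 10, "obj": 0},
        {"id": "R2", "stoich": {"M1": -1}, "lb": 0, "ub": 10, "obj": 1},
    ],
}


@pytest.fixture
def chain_path(tmp_path):
    path = tmp_path / "chain.json"
    path.write_text(json.dumps(CHAIN_JSON))
    return path


class TestFlatJson:
    def test_chain_coefficients_read_back(self, chain_path):
        model = load_model(chain_path, format="flat_json")
        assert model.reaction_ids == ["R1", "R2"]
        np.testing.assert_array_equal(model.S, [[1.0, -1.0]])
        np.testing.assert_array_equal(model.a, [0, 0])
        np.testing.assert_array_equal(model.b, [10, 10])
        np.testing.assert_array_equal(model.f, [0, 1])

    def test_round_trip_is_identity(self, chain_path, tmp_path):
        model = load_model(chain_path)
        out = tmp_path / "rt.json"
        write_model(model, out)
        again = load_model(out)
        assert again.metabolite_ids == model.metabolite_ids
        assert again.reaction_ids == model.reaction_ids
        for attr in ("S", "a", "b", "f"):
            np.testing.assert_allclose(getattr(again, attr),
                                       getattr(model, attr), rtol=1e-12)

    def test_bad_json_is_format_error(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text("{not json")
        with pytest.raises(ModelFormatError):
            load_model(path, format="flat_json")

    def test_unknown_metabolite_is_format_error(self, tmp_path):
        doc = {"metabolites": ["M1"],
               "reactions": [{"id": "R1", "stoich": {"MX": 1}, "lb": 0, "ub": 1}]}
        path = tmp_path / "m.json"
        path.write_text(json.dumps(doc))
        with pytest.raises(ModelFormatError, match="MX"):
            load_model(path)


class TestValidation:
    def _reactions(self, **over):
        rxn = {"id": "R1", "stoich": {"M1": 1}, "lb": 0, "ub": 10}
        rxn.update(over)
        return {"metabolites": ["M1"], "reactions": [rxn]}

    def test_lower_bound_above_upper_names_reaction(self, tmp_path):
        path = tmp_path / "m.json"
        path.write_text(json.dumps(self._reactions(lb=5, ub=2)))
        with pytest.raises(ModelValidationError, match="R1"):
            load_model(path)

    def test_nonpositive_upper_bound_rejected(self, tmp_path):
        path = tmp_path / "m.json"
        path.write_text(json.dumps(self._reactions(ub=0)))
        with pytest.raises(ModelValidationError, match="R1"):
            load_model(path)

    def test_duplicate_reaction_ids_rejected(self):
        with pytest.raises(ModelValidationError, match="duplicate"):
            MetabolicModel(["M1"], ["R1", "R1"], [[1, -1]],
                           [0, 0], [1, 1], [0, 0])

    def test_valid_model_accepted(self, chain_path):
        load_model(chain_path)  # must not raise


class TestSbml:
    @staticmethod
    def _write_chain_sbml(path, lb2=0.0, ub2=10.0):
        import libsbml

        ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
        doc = libsbml.SBMLDocument(ns)
        doc.setPackageRequired("fbc", False)
        model = doc.createModel("chain")
        mplug = model.getPlugin("fbc")
        mplug.setStrict(True)
        comp = model.createCompartment()
        comp.setId("c")
        comp.setConstant(True)
        sp = model.createSpecies()
        sp.setId("M1")
        sp.setCompartment("c")
        sp.setConstant(False)
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        for pid, value in [("lb0", 0.0), ("ub10", 10.0),
                           ("lb2", lb2), ("ub2", ub2)]:
            par = model.createParameter()
            par.setId(pid)
            par.setValue(value)
            par.setConstant(True)
        r1 = model.createReaction()
        r1.setId("R1")
        r1.setReversible(False)
        r1.setFast(False)
        prod = r1.createProduct()
        prod.setSpecies("M1")
        prod.setStoichiometry(1.0)
        prod.setConstant(True)
        r1p = r1.getPlugin("fbc")
        r1p.setLowerFluxBound("lb0")
        r1p.setUpperFluxBound("ub10")
        r2 = model.createReaction()
        r2.setId("R2")
        r2.setReversible(False)
        r2.setFast(False)
        react = r2.createReactant()
        react.setSpecies("M1")
        react.setStoichiometry(1.0)
        react.setConstant(True)
        r2p = r2.getPlugin("fbc")
        r2p.setLowerFluxBound("lb2")
        r2p.setUpperFluxBound("ub2")
        obj = mplug.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        mplug.setActiveObjectiveId("obj")
        fo = obj.createFluxObjective()
        fo.setReaction("R2")
        fo.setCoefficient(1.0)
        libsbml.writeSBMLToFile(doc, str(path))

    def test_l3_fbc_model_reads_to_same_network(self, tmp_path, chain_path):
        sbml_path = tmp_path / "chain.xml"
        self._write_chain_sbml(sbml_path)
        model = load_model(sbml_path, format="sbml")
        ref = load_model(chain_path)
        assert model.reaction_ids == ref.reaction_ids
        np.testing.assert_allclose(model.S, ref.S)
        np.testing.assert_allclose(model.a, ref.a)
        np.testing.assert_allclose(model.b, ref.b)
        np.testing.assert_allclose(model.f, ref.f)

    def test_inverted_bounds_name_the_reaction(self, tmp_path):
        sbml_path = tmp_path / "bad.xml"
        self._write_chain_sbml(sbml_path, lb2=5.0, ub2=2.0)
        with pytest.raises(ModelValidationError, match="R2"):
            load_model(sbml_path)

    def test_non_level3_is_unsupported(self, tmp_path):
        import libsbml

        doc = libsbml.SBMLDocument(2, 4)
        model = doc.createModel("old")
        comp = model.createCompartment()
        comp.setId("c")
        path = tmp_path / "l2.xml"
        libsbml.writeSBMLToFile(doc, str(path))
        with pytest.raises(ModelFormatError, match="[Ll]evel"):
            load_model(path, format="sbml")


class TestFluxTables:
    def test_rows_align_to_model_order(self, tmp_path, chain):
        path = tmp_path / "v.tsv"
        path.write_text("reaction_id\tflux\nR1\t2.0\nR2\t2.0\n")
        np.testing.assert_array_equal(load_fluxes(path, chain), [2.0, 2.0])

    def test_empty_table_is_zero_vector(self, tmp_path, chain):
        path = tmp_path / "v.tsv"
        path.write_text("reaction_id\tflux\n")
        np.testing.assert_array_equal(load_fluxes(path, chain), [0.0, 0.0])

    def test_unknown_reaction_is_listed(self, tmp_path, chain):
        path = tmp_path / "v.tsv"
        path.write_text("reaction_id\tflux\nR9\t1.0\n")
        with pytest.raises(FluxTableError, match="R9"):
            load_fluxes(path, chain)

    def test_duplicate_reaction_rejected(self, tmp_path, chain):
        path = tmp_path / "v.tsv"
        path.write_text("reaction_id\tflux\nR1\t1.0\nR1\t2.0\n")
        with pytest.raises(FluxTableError, match="R1"):
            load_fluxes(path, chain)

    def test_flux_round_trip(self, tmp_path, diamond):
        v = np.array([3.0, 2.0, 1.0, 3.0])
        path = tmp_path / "v.tsv"
        write_fluxes(v, diamond, path)
        np.testing.assert_allclose(load_fluxes(path, diamond), v, rtol=1e-12)


class TestDecompositionIO:
    def test_single_mode_chain_json(self, tmp_path, chain):
        d = decompose(chain, np.array([2.0, 2.0]))
        path = tmp_path / "d.json"
        write_decomposition(d, chain, path, format="json")
        payload = json.loads(path.read_text())
        assert len(payload["modes"]) == 1
        entry = payload["modes"][0]
        assert entry["weight"] == pytest.approx(2.0)
        assert entry["flux"] == {"R1": 1.0, "R2": 1.0}

    def test_json_round_trip_reconstructs_v(self, tmp_path, diamond):
        v = np.array([3.0, 2.0, 1.0, 3.0])
        d = decompose(diamond, v)
        path = tmp_path / "d.json"
        write_decomposition(d, diamond, path)
        again = read_decomposition(path, diamond)
        np.testing.assert_allclose(again.reconstruct(diamond.n), v, atol=1e-9)

    def test_empty_decomposition_writes_valid_files(self, tmp_path, chain):
        d = decompose(chain, np.zeros(2))
        jpath, tpath = tmp_path / "d.json", tmp_path / "d.tsv"
        write_decomposition(d, chain, jpath, format="json")
        write_decomposition(d, chain, tpath, format="tsv")
        assert json.loads(jpath.read_text())["modes"] == []
        header = tpath.read_text().splitlines()[0]
        assert header.startswith("reaction_id")

    def test_tsv_has_weight_row_and_mode_columns(self, tmp_path, diamond):
        v = np.array([3.0, 2.0, 1.0, 3.0])
        d = decompose(diamond, v)
        path = tmp_path / "d.tsv"
        write_decomposition(d, diamond, path, format="tsv")
        import pandas as pd

        table = pd.read_csv(path, sep="\t")
        assert table["reaction_id"].iloc[0] == "__weight__"
        weights = table.iloc[0, 1:].astype(float).to_numpy()
        P = table.iloc[1:, 1:].astype(float).to_numpy()
        np.testing.assert_allclose(P @ weights, v, atol=1e-9)
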