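"""End-to-end screening workflow: TTC inversion, capping, batch behavior."""

import pytest

from odorsafe import (
    ChemicalRecord,
    ConfigurationError,
    HeadspaceScenario,
    headspace_mass,
    max_solution_concentration,
    screen_batch,
    screen_chemical,
)


class TestMaxSolutionConcentration:
    def test_reference_ratio(self):
        """TTC 540 over exposure 546 -> 98.9 % within 0.1 percentage point."""
        assert max_solution_concentration(540.0, 546.0) == pytest.approx(98.9, abs=0.1)

    def test_caps_at_100_when_exposure_below_ttc(self):
        assert max_solution_concentration(1800.0, 10.0) == 100.0

    @pytest.mark.parametrize("ttc,exposure,expected", [
        (90.0, 9000.0, 1.0),
        (540.0, 5400.0, 10.0),
        (540.0, 5460.0, 9.89),
    ])
    def test_direct_division(self, ttc, exposure, expected):
        assert max_solution_concentration(ttc, exposure) == pytest.approx(expected, rel=1e-3)

    def test_nonpositive_ttc_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            max_solution_concentration(0.0, 100.0)


class TestScreenChemical:
    def test_rose_oxide_complete_row(self, rose_oxide, default_scenario):
        res = screen_chemical(rose_oxide, default_scenario)
        assert res.hazard.cramer_class == "II"
        assert res.hazard.mutagen_alerts == []
        assert res.hazard.hazard_label == "cramer_II"
        assert res.hazard.ttc_ug_per_day == 540.0
        assert res.neat_headspace_mass_ug == pytest.approx(546, rel=0.005)
        assert res.exposure_ug_per_day == pytest.approx(546, rel=0.005)
        assert res.max_conc_pct_ww == pytest.approx(98.9, abs=0.1)
        assert not res.capped and not res.out_of_domain

    def test_nonvolatile_chemical_caps(self, default_scenario):
        rec = ChemicalRecord(id="nv", name="nonvolatile", smiles="CCCCO", vp_mmHg=0.0)
        res = screen_chemical(rec, default_scenario)
        assert res.max_conc_pct_ww == 100.0
        assert res.capped

    def test_composition_identity(self, rose_oxide, default_scenario):
        """screen_chemical equals the hand-composition of its components."""
        from odorsafe import assign_ttc, classify

        res = screen_chemical(rose_oxide, default_scenario)
        hz = classify(rose_oxide.smiles)
        mass = headspace_mass(rose_oxide.vp_mmHg, rose_oxide.mw, default_scenario)
        conc = max_solution_concentration(assign_ttc(hz.hazard_label), mass)
        assert res.max_conc_pct_ww == pytest.approx(conc, rel=1e-12)
        assert res.neat_headspace_mass_ug == pytest.approx(mass, rel=1e-12)

    def test_out_of_domain_flag_surfaces(self, default_scenario):
        rec = ChemicalRecord(id="ndma", name="NDMA", smiles="O=NN(C)C", vp_mmHg=1.0)
        res = screen_chemical(rec, default_scenario)
        assert res.out_of_domain
        assert res.hazard.coc_flags == ["COC_NITROSAMINE"]

    def test_exposures_per_day_multiplier(self, rose_oxide, default_scenario):
        once = screen_chemical(rose_oxide, default_scenario)
        thrice = screen_chemical(rose_oxide, default_scenario, exposures_per_day=3.0)
        assert thrice.exposure_ug_per_day == pytest.approx(3 * once.exposure_ug_per_day)
        assert thrice.max_conc_pct_ww == pytest.approx(once.max_conc_pct_ww / 3, rel=1e-9)

    def test_override_label_replaces_structure_classification(self, rose_oxide):
        res = screen_chemical(rose_oxide, override_label="cramer_III")
        assert res.hazard.hazard_label == "cramer_III"
        assert res.hazard.ttc_ug_per_day == 90.0

    def test_audit_trail_records_configuration(self, rose_oxide, default_scenario):
        res = screen_chemical(rose_oxide, default_scenario)
        steps = {a["step"] for a in res.audit}
        assert {"hazard", "ttc", "headspace", "concentration"} <= steps
        hs = next(a for a in res.audit if a["step"] == "headspace")
        assert hs["constants_mode"] == "paper_printed"
        assert hs["volume_L"] == 0.1


class TestScreenBatch:
    def test_empty_batch(self):
        results, report = screen_batch([])
        assert results == [] and report.n_total == 0 and report.errors == []

    def test_single_record_matches_screen_chemical(self, rose_oxide, default_scenario):
        results, report = screen_batch([rose_oxide], default_scenario)
        solo = screen_chemical(rose_oxide, default_scenario)
        assert len(results) == 1 and report.n_ok == 1
        assert results[0].max_conc_pct_ww == solo.max_conc_pct_ww

    def test_errors_do_not_abort_batch(self, rose_oxide, default_scenario):
        bad = ChemicalRecord.__new__(ChemicalRecord)  # bypass validation
        bad.id, bad.name, bad.cas = "bad", "organometallic", None
        bad.smiles, bad.mw, bad.vp_mmHg = "C[Si](C)(C)C", 88.2, 1.0
        bad.vp_source, bad.mw_source, bad.mw_mismatch = "predicted", "supplied", False
        results, report = screen_batch([rose_oxide, bad, rose_oxide], default_scenario)
        assert len(results) == 2
        assert len(report.errors) == 1
        assert report.errors[0]["id"] == "bad"

    def test_order_preserved_and_counts(self, default_scenario):
        recs = [
            ChemicalRecord(id="a", name="butanol", smiles="CCCCO", vp_mmHg=7.0),
            ChemicalRecord(id="b", name="pyridine", smiles="c1ccncc1", vp_mmHg=20.0),
            ChemicalRecord(id="c", name="nonvolatile", smiles="CCCCO", vp_mmHg=0.0),
        ]
        results, report = screen_batch(recs, default_scenario)
        assert [r.record.id for r in results] == ["a", "b", "c"]
        assert report.hazard_counts == {"cramer_I": 2, "cramer_III": 1}
        assert report.n_capped >= 1
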