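"""NOAEC -> NOAEL conversion, safety margins and per-solvent summaries."""

import math

import pytest

from odorsafe import (
    ChemicalRecord,
    InputError,
    SafetyMarginRecord,
    ToxRecord,
    noaec_to_noael,
    run_validation,
    safety_margin,
    screen_chemical,
    summarize_margins,
)


class TestNoaecToNoael:
    @pytest.mark.parametrize("noaec,expected", [(1.0, 72.0), (0.0, 0.0), (100.0, 7200.0)])
    def test_default_factors(self, noaec, expected):
        """0.2 L/min x 360 min/day = 72 L/day; mg/m3 x L/day -> ug/day."""
        assert noaec_to_noael(ToxRecord("x", noaec)) == pytest.approx(expected)

    def test_custom_breathing_parameters(self):
        t = ToxRecord("x", 10.0, breathing_rate_L_min=0.5, exposure_min_per_day=60.0)
        assert noaec_to_noael(t) == pytest.approx(300.0)

    def test_negative_noaec_rejected(self):
        with pytest.raises(InputError):
            ToxRecord("x", -1.0)


class TestSafetyMargin:
    def test_ratio_identity(self, rose_oxide, default_scenario):
        from odorsafe import adjusted_headspace_mass

        res = screen_chemical(rose_oxide, default_scenario)
        adjusted = adjusted_headspace_mass(
            res.max_conc_pct_ww, rose_oxide, "water", default_scenario)
        m = safety_margin(adjusted, res, "water", default_scenario)
        assert m.margin == pytest.approx(1.0, rel=1e-9)
        # rose oxide is uncapped, so the adjusted exposure is below neat
        assert m.adjusted_exposure_ug_per_day < res.exposure_ug_per_day

    def test_capped_chemical_uses_neat_mass_any_solvent(self, default_scenario):
        rec = ChemicalRecord(id="c", name="capped", smiles="CCCCO", vp_mmHg=1e-4)
        res = screen_chemical(rec, default_scenario)
        assert res.capped
        margins = [
            safety_margin(7200.0, res, solvent, default_scenario).margin
            for solvent in ("water", "propylene_glycol", "ethanol_water_50_50")
        ]
        assert margins[0] == pytest.approx(margins[1]) == pytest.approx(margins[2])
        assert margins[0] == pytest.approx(7200.0 / res.neat_headspace_mass_ug)

    def test_margin_100_from_fixture_numbers(self, default_scenario):
        rec = ChemicalRecord(id="f", name="fix", smiles="CCCCO", vp_mmHg=1e-4)
        res = screen_chemical(rec, default_scenario)
        m = safety_margin(100.0 * res.exposure_ug_per_day, res, "water", default_scenario)
        assert m.margin == pytest.approx(100.0)

    def test_zero_exposure_reports_infinite_margin(self, default_scenario):
        rec = ChemicalRecord(id="z", name="zero vp", smiles="CCCCO", vp_mmHg=0.0)
        res = screen_chemical(rec, default_scenario)
        m = safety_margin(72.0, res, "water", default_scenario)
        assert m.infinite and math.isinf(m.margin)


class TestSummarizeMargins:
    @staticmethod
    def _recs(margins, solvent="water"):
        return [
            SafetyMarginRecord(f"c{i}", solvent, 1.0, 1.0, m, infinite=math.isinf(m))
            for i, m in enumerate(margins)
        ]

    def test_singleton(self):
        s = summarize_margins(self._recs([100.0]))["water"]
        assert s.geometric_mean == pytest.approx(100.0)
        assert (s.n_below_1, s.n_below_10) == (0, 0)

    def test_geometric_mean_two_values(self):
        s = summarize_margins(self._recs([10.0, 1000.0]))["water"]
        assert s.geometric_mean == pytest.approx(100.0)

    def test_cube_root_and_strict_counts(self):
        s = summarize_margins(self._recs([0.5, 5.0, 50.0]))["water"]
        assert s.geometric_mean == pytest.approx(5.0)
        assert (s.n_below_1, s.n_below_10, s.n_total) == (1, 2, 3)

    def test_below10_includes_below1(self):
        s = summarize_margins(self._recs([0.5, 0.9, 20.0]))["water"]
        assert s.n_below_1 == 2 and s.n_below_10 == 2

    def test_infinite_margins_excluded_from_geomean_but_counted(self):
        s = summarize_margins(self._recs([10.0, 1000.0, math.inf]))["water"]
        assert s.geometric_mean == pytest.approx(100.0)
        assert s.n_infinite == 1 and s.n_total == 3

    def test_empty_input_is_error(self):
        with pytest.raises(InputError):
            summarize_margins(self._recs([math.inf]))

    def test_percent_representations(self):
        # 1 of 10 below 1, 2 of 10 below 10
        s = summarize_margins(self._recs([0.5, 5.0] + [100.0] * 8))["water"]
        assert s.pct_above_1 == pytest.approx(90.0)
        assert s.pct_above_10 == pytest.approx(80.0)

    def test_scale_equivariance(self):
        base = summarize_margins(self._recs([0.5, 5.0, 50.0]))["water"]
        doubled = summarize_margins(self._recs([1.0, 10.0, 100.0]))["water"]
        assert doubled.geometric_mean == pytest.approx(2 * base.geometric_mean)


class TestRunValidation:
    def test_multi_solvent_grouping(self, rose_oxide, default_scenario):
        res = screen_chemical(rose_oxide, default_scenario)
        tox = {"rose_oxide": ToxRecord("rose_oxide", 100.0)}
        margins, summaries = run_validation(
            [res], tox, ["water", "propylene_glycol"], default_scenario)
        assert {m.solvent for m in margins} == {"water", "propylene_glycol"}
        assert set(summaries) == {"water", "propylene_glycol"}
        for s in summaries.values():
            assert s.n_total == 1

    def test_chemicals_without_tox_are_skipped(self, rose_oxide, default_scenario):
        res = screen_chemical(rose_oxide, default_scenario)
        other = ToxRecord("someone_else", 10.0)
        with pytest.raises(InputError):
            run_validation([res], {"someone_else": other}, ["water"], default_scenario)
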