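import numpy as np
import pytest

from pathcombo import (
    STANDARD_GRID,
    ComboExperiment,
    DoseResponse,
    ValidationError,
    bliss_score,
    classify_bliss,
    compare_predicted_vs_random,
    fit_ic,
    viability_from_od,
)
from pathcombo.errors import ComputationError
from pathcombo.synergy_lab import four_pl, read_dose_table, write_dose_table
from pathcombo.synthetic_data import DoseSpec, GeneratorSpec, generate_dose_response


class TestViabilityFromOd:
    def test_direct_arithmetic(self):
        assert viability_from_od([0.6], [1.1], [0.1])[0] == pytest.approx(0.5)

    def test_treated_equal_control_is_one(self):
        assert viability_from_od([1.1], [1.1], [0.1])[0] == pytest.approx(1.0)

    def test_treated_equal_blank_is_zero(self):
        assert viability_from_od([0.1], [1.1], [0.1])[0] == pytest.approx(0.0)

    def test_blank_shift_cancels(self):
        a = viability_from_od([0.6, 0.7], [1.1, 1.2], [0.1])
        b = viability_from_od([1.6, 1.7], [2.1, 2.2], [1.1])
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_dead_control_is_assay_failure(self):
        with pytest.raises(ValidationError, match="assay failure"):
            viability_from_od([0.5], [0.1], [0.2])


def curve(viab, conc=None, drug="D", cell="SKOV-3"):
    conc = np.array(STANDARD_GRID if conc is None else conc, dtype=float)
    return DoseResponse(drug, cell, conc, np.asarray(viab, dtype=float))


class TestFitIc:
    def test_noiseless_4pl_inverted_exactly(self):
        grid = np.array(STANDARD_GRID)
        viab = four_pl(grid, 1.0, 0.0, 9.6, 1.5)
        est = fit_ic(curve(viab[:, None]), level=0.5)
        assert est.method == "4pl"
        assert est.concentration == pytest.approx(9.6, abs=1e-6)

    def test_ic20_of_noiseless_curve(self):
        grid = np.array(STANDARD_GRID)
        viab = four_pl(grid, 1.0, 0.0, 9.6, 1.5)
        est = fit_ic(curve(viab[:, None]), level=0.2)
        assert est.concentration == pytest.approx(9.6 * 0.25 ** (1 / 1.5), rel=1e-6)

    def test_flat_curve_reports_right_censored_sentinel(self):
        est = fit_ic(curve(np.ones((8, 4))), level=0.5)
        assert est.censored
        assert str(est) == ">=50"

    def test_two_point_interpolation_closed_form(self):
        dr = curve([[1.0], [0.9], [0.7]], conc=[0.0, 1.0, 10.0])
        est = fit_ic(dr, level=0.2, method="interp")
        assert est.method == "interpolation"
        assert est.concentration == pytest.approx(10 ** 0.5, rel=1e-12)

    def test_level_must_be_a_fraction(self):
        with pytest.raises(ValidationError):
            fit_ic(curve(np.ones((8, 1))), level=1.5)


def make_combo(y1, y2, observed_inhibition, conc=(0.0, 1.0)):
    """Single-dose combination with exact inhibitions (no noise)."""
    alone = curve([[1.0], [1.0 - y1]], conc=conc)
    v_renorm = (1.0 - observed_inhibition) / (1.0 - y2)
    combo = curve([[1.0], [v_renorm]], conc=conc)
    return ComboExperiment(combo, "PARTNER", y2, alone)


class TestBlissScore:
    def test_exact_bliss_null_scores_zero(self):
        grid = np.array(STANDARD_GRID)
        v1 = four_pl(grid, 1.0, 0.0, 9.6, 1.5)
        y2 = 0.2
        alone = curve(v1[:, None])
        combo_renorm = v1[:, None].copy()  # (1-y1)(1-y2)/(1-y2) = viability alone
        combo_renorm[0] = 1.0
        combo = ComboExperiment(curve(combo_renorm), "P", y2, alone)
        res = bliss_score(combo)
        assert res.bliss_score == pytest.approx(0.0, abs=1e-12)
        assert res.klass == "additive"

    def test_synergistic_excess(self):
        res = bliss_score(make_combo(0.3, 0.4, 0.70))
        assert res.bliss_score == pytest.approx(12.0, abs=1e-9)
        assert res.klass == "synergistic"
        assert res.per_dose_excess[0] == pytest.approx(0.12)

    def test_antagonistic_shortfall(self):
        res = bliss_score(make_combo(0.3, 0.4, 0.50))
        assert res.bliss_score == pytest.approx(-8.0, abs=1e-9)
        assert res.klass == "antagonistic"

    def test_boundary_scores(self):
        # ±0.05 excess lands on the classification boundary (up to FP
        # round-trip noise); the strict-inequality contract itself is
        # checked on exact values below.
        res = bliss_score(make_combo(0.3, 0.4, 0.63))
        assert res.bliss_score == pytest.approx(5.0, abs=1e-9)
        res = bliss_score(make_combo(0.3, 0.4, 0.53))
        assert res.bliss_score == pytest.approx(-5.0, abs=1e-9)

    @pytest.mark.parametrize(
        "score, expected",
        [(5.0, "additive"), (5.001, "synergistic"), (-5.0, "additive"),
         (-5.001, "antagonistic"), (0.0, "additive")],
    )
    def test_classification_inequalities_are_strict(self, score, expected):
        assert classify_bliss(score) == expected

    def test_misaligned_grids_rejected(self):
        alone = curve([[1.0], [0.7]], conc=[0.0, 1.0])
        combo = curve([[1.0], [0.7]], conc=[0.0, 2.0])
        with pytest.raises(ValidationError, match="grids differ"):
            ComboExperiment(combo, "P", 0.2, alone)

    def test_partner_inhibition_must_be_fraction(self):
        alone = curve([[1.0], [0.7]], conc=[0.0, 1.0])
        with pytest.raises(ValidationError, match="partner inhibition"):
            ComboExperiment(alone, "P", 1.0, alone)


class TestWelch:
    def test_identical_groups(self):
        rep = compare_predicted_vs_random([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert rep.pvalue == pytest.approx(1.0)
        assert rep.mean_predicted == rep.mean_random

    def test_near_degenerate_separation(self):
        rng = np.random.default_rng(0)
        a = 10 + rng.normal(0, 1e-6, 4)
        b = 0 + rng.normal(0, 1e-6, 4)
        assert compare_predicted_vs_random(a, b).pvalue < 1e-6

    def test_groups_need_two_scores(self):
        with pytest.raises(ValidationError):
            compare_predicted_vs_random([1.0], [1.0, 2.0])


class TestDoseTableRoundTrip:
    def test_plate_io_preserves_curves_and_synergy(self, tmp_path):
        spec = GeneratorSpec(
            seed=9, noise_cv=0.0, injected_bliss_excess=0.10,
            dose_specs={"A": DoseSpec(ic50=9.6, hill=1.5),
                        "B": DoseSpec(ic50=17.0, hill=1.2)},
            drug="A",
        )
        singles = {
            ("SKOV-3", d): generate_dose_response(spec, d) for d in ("A", "B")
        }
        combo = generate_dose_response(spec, "A", partner="B")
        path = tmp_path / "plate.tsv"
        write_dose_table(path, singles, {("SKOV-3", "A", "B"): combo})
        singles2, combos2 = read_dose_table(path)
        np.testing.assert_allclose(
            singles2[("SKOV-3", "A")].mean_viability,
            singles[("SKOV-3", "A")].mean_viability,
            atol=1e-9,
        )
        back = combos2[("SKOV-3", "A", "B")]
        assert back.partner_inhibition == pytest.approx(0.2, abs=1e-9)
        direct = bliss_score(combo).bliss_score
        via_table = bliss_score(back).bliss_score
        assert via_table == pytest.approx(direct, abs=1e-6)
        assert via_table == pytest.approx(10.0, abs=1.0)

    def test_combo_without_single_agent_rejected(self, tmp_path):
        spec = GeneratorSpec(seed=9, noise_cv=0.0, drug="A",
                             dose_specs={"A": DoseSpec(ic50=9.6),
                                         "B": DoseSpec(ic50=17.0)})
        combo = generate_dose_response(spec, "A", partner="B")
        path = tmp_path / "plate.tsv"
        write_dose_table(path, {}, {("SKOV-3", "A", "B"): combo})
        with pytest.raises(ValidationError, match="matching single-agent"):
            read_dose_table(path)
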