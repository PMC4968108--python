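"""Quantitation rules: charge merging, relative levels, absolute amounts,
reference-panel selection and the terminal-degradation screen."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qapk.quantitation import (
    DegenerateCurveError,
    absolute_concentration,
    fit_standard_curve,
    merge_charge_states,
    relative_percent,
    select_reference_peptides,
    terminal_degradation_screen,
    total_concentration,
)


def _raw(rows):
    return pd.DataFrame(
        rows, columns=["subject", "time_days", "peptide_id", "mod_form", "charge",
                       "light_area", "heavy_area"]
    )


class TestMergeChargeStates:
    def test_areas_sum_over_charges(self):
        raw = _raw([("S1", 1.0, "P1", "none", 2, 100.0, 10.0),
                    ("S1", 1.0, "P1", "none", 3, 50.0, 5.0)])
        merged = merge_charge_states(raw)
        assert len(merged) == 1
        assert merged.loc[0, "light_area"] == 150.0
        assert merged.loc[0, "heavy_area"] == 15.0

    def test_single_charge_is_identity(self):
        raw = _raw([("S1", 1.0, "P1", "none", 2, 100.0, 10.0)])
        merged = merge_charge_states(raw)
        assert merged.loc[0, "light_area"] == 100.0

    def test_row_order_does_not_matter(self):
        rows = [("S1", 1.0, "P1", "none", 2, 100.0, 10.0),
                ("S1", 1.0, "P1", "deam", 2, 30.0, 0.0),
                ("S1", 2.0, "P2", "none", 3, 70.0, 7.0),
                ("S1", 1.0, "P1", "none", 3, 55.0, 5.0)]
        reference = merge_charge_states(_raw(rows))
        for perm in itertools.permutations(rows):
            pd.testing.assert_frame_equal(merge_charge_states(_raw(list(perm))), reference)

    def test_conflicting_duplicates_rejected(self):
        raw = _raw([("S1", 1.0, "P1", "none", 2, 100.0, 10.0),
                    ("S1", 1.0, "P1", "none", 2, 90.0, 10.0)])
        with pytest.raises(ValueError, match="duplicate"):
            merge_charge_states(raw)


def _table(rows):
    return pd.DataFrame(
        rows, columns=["subject", "time_days", "peptide_id", "mod_form",
                       "light_area", "heavy_area"]
    )


class TestRelativePercent:
    def test_direct_ratio(self):
        t = _table([("S1", 1.0, "P1", "deam", 35.0, 0.0),
                    ("S1", 1.0, "P1", "none", 65.0, 10.0)])
        out = relative_percent(t, "P1", "deam")
        assert out.loc[0, "value"] == pytest.approx(0.35)

    def test_three_forms_sum_to_one(self):
        t = _table([("S1", 1.0, "P1", "a", 20.0, 0.0),
                    ("S1", 1.0, "P1", "b", 30.0, 0.0),
                    ("S1", 1.0, "P1", "none", 50.0, 10.0)])
        total = sum(relative_percent(t, "P1", form).loc[0, "value"] for form in ("a", "b", "none"))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_denominator_is_missing_not_zero(self):
        t = _table([("S1", 0.0, "P1", "deam", 0.0, 0.0),
                    ("S1", 0.0, "P1", "none", 0.0, 10.0),
                    ("S1", 1.0, "P1", "deam", 10.0, 0.0),
                    ("S1", 1.0, "P1", "none", 90.0, 10.0)])
        out = relative_percent(t, "P1", "deam").set_index("time_days")["value"]
        assert np.isnan(out.loc[0.0])
        assert out.loc[1.0] == pytest.approx(0.10)

    def test_noise_free_roundtrip_recovers_generator_truth(
        self, noise_free_study, noise_free_quant
    ):
        for name, truth in noise_free_study.fractions.items():
            got = noise_free_quant["fractions"][name]
            got = got[(got["subject"] == "S1") & (got["time_days"] > 0)]
            want = truth.set_index("time_days")["fraction"].loc[got["time_days"]]
            np.testing.assert_allclose(got["value"].to_numpy(), want.to_numpy(), rtol=1e-9)

    @settings(max_examples=40, derandomize=True)
    @given(areas=st.lists(st.floats(0.1, 1e6), min_size=2, max_size=6))
    def test_form_percentages_always_sum_to_100(self, areas):
        rows = [("S1", 1.0, "P1", f"form{i}", a, 0.0) for i, a in enumerate(areas)]
        t = _table(rows)
        total = sum(
            relative_percent(t, "P1", f"form{i}").loc[0, "value"] for i in range(len(areas))
        )
        assert total * 100 == pytest.approx(100.0, abs=1e-9)


class TestAbsoluteConcentration:
    def test_methods_stated_amounts_give_200_ug_per_ml(self):
        t = _table([("S1", 1.0, "P1", "none", 10.0, 10.0)])
        out = absolute_concentration(t, "P1", calibrant_amount=2.5, serum_volume=12.5)
        assert out.loc[0, "value"] == pytest.approx(200.0)

    def test_zero_ratio_pre_bleed_is_zero_not_missing(self):
        t = _table([("S1", 0.0, "P1", "none", 0.0, 10.0)])
        out = absolute_concentration(t, "P1")
        assert out.loc[0, "value"] == 0.0

    def test_linear_in_light_inverse_in_heavy(self):
        t = _table([("S1", 1.0, "P1", "none", 5.0, 10.0)])
        base = absolute_concentration(t, "P1").loc[0, "value"]
        assert base == pytest.approx(100.0)
        t2 = _table([("S1", 1.0, "P1", "none", 10.0, 10.0)])
        assert absolute_concentration(t2, "P1").loc[0, "value"] == pytest.approx(2 * base)
        t3 = _table([("S1", 1.0, "P1", "none", 5.0, 20.0)])
        assert absolute_concentration(t3, "P1").loc[0, "value"] == pytest.approx(base / 2)

    def test_zero_heavy_area_flagged_missing(self):
        t = _table([("S1", 1.0, "P1", "none", 5.0, 0.0)])
        assert np.isnan(absolute_concentration(t, "P1").loc[0, "value"])

    def test_sub_lloq_ratio_flagged_missing(self):
        t = _table([("S1", 1.0, "P1", "none", 1e-6, 100.0)])
        assert np.isnan(absolute_concentration(t, "P1").loc[0, "value"])


class TestStandardCurve:
    def test_exact_linear_data(self):
        curve = pd.DataFrame({"concentration": [1.0, 2.0, 4.0, 8.0],
                              "light_area": [10.0, 20.0, 40.0, 80.0],
                              "heavy_area": [100.0] * 4})
        fit = fit_standard_curve(curve)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.slope == pytest.approx(0.1 / 100 * 1000 / 10)  # ratio per unit conc

    def test_constant_ratios_degenerate(self):
        curve = pd.DataFrame({"concentration": [1.0, 2.0, 4.0],
                              "light_area": [10.0, 10.0, 10.0],
                              "heavy_area": [100.0] * 3})
        with pytest.raises(DegenerateCurveError):
            fit_standard_curve(curve)

    def test_too_few_levels(self):
        curve = pd.DataFrame({"concentration": [1.0, 2.0],
                              "light_area": [10.0, 20.0], "heavy_area": [100.0] * 2})
        with pytest.raises(ValueError, match=">= 3"):
            fit_standard_curve(curve)

    def test_noisy_slope_within_5pct_of_generator(self):
        from qapk.synthetic import default_config, generate_standard_curve

        cfg = default_config(seed=9, noise_cv=0.05)
        curve = generate_standard_curve([12.5, 25, 50, 100, 200, 400, 800, 1600], cfg)
        fit = fit_standard_curve(curve)
        # generator slope: ratio = level / calibrant-equivalent concentration
        assert fit.slope == pytest.approx(1.0 / cfg.calibrant_concentration, rel=0.05)


def _panel_table(medians, modified=(), carryover=()):
    """Panel where each peptide's light areas are constant = its median."""
    rows = []
    for pid, level in medians.items():
        for t in (0.0, 1.0, 2.0):
            light = level if (t > 0 or pid in carryover) else 0.0
            rows.append(("S1", t, pid, "none", light, 10.0))
        if pid in modified:
            rows.append(("S1", 1.0, pid, "mod", 1.0, 0.0))
    return _table(rows)


class TestSelectReferencePeptides:
    def test_matches_brute_force_ranking(self):
        rng = np.random.default_rng(0)
        medians = {f"P{i:02d}": float(rng.uniform(1, 100)) for i in range(30)}
        modified = {"P03", "P11", "P17", "P22", "P28"}
        table = _panel_table(medians, modified=modified)
        got = select_reference_peptides(table, k=20)
        # oracle: eligible peptides sorted by (-median over all samples, id)
        eligible = [p for p in medians if p not in modified]
        med = {p: float(np.median([0.0, medians[p], medians[p]])) for p in eligible}
        want = sorted(eligible, key=lambda p: (-med[p], p))[:20]
        assert got == want

    def test_k1_returns_single_highest(self):
        table = _panel_table({"A": 5.0, "B": 50.0, "C": 20.0})
        assert select_reference_peptides(table, k=1) == ["B"]

    def test_carryover_excluded_regardless_of_intensity(self):
        table = _panel_table({"A": 5.0, "HOT": 500.0}, carryover={"HOT"})
        assert select_reference_peptides(table, k=1) == ["A"]

    def test_fewer_than_k_warns_and_returns_all(self):
        table = _panel_table({"A": 5.0, "B": 50.0})
        with pytest.warns(UserWarning, match="eligible"):
            got = select_reference_peptides(table, k=20)
        assert got == ["B", "A"]

    def test_deterministic_under_input_permutation(self):
        medians = {f"P{i}": float(v) for i, v in enumerate([7, 7, 3, 9, 1])}
        table = _panel_table(medians)
        shuffled = table.sample(frac=1.0, random_state=4).reset_index(drop=True)
        assert select_reference_peptides(table, k=3) == select_reference_peptides(shuffled, k=3)


class TestTotalConcentration:
    def test_noise_free_roundtrip_recovers_generator_total(
        self, noise_free_study, noise_free_quant
    ):
        truth = noise_free_study.total_concentration.set_index("time_days")["value"]
        tot = noise_free_quant["total_concentration"]
        tot = tot[tot["time_days"] > 0]
        want = truth.loc[tot["time_days"]].to_numpy()
        np.testing.assert_allclose(tot["value"].to_numpy(), want, rtol=1e-9)

    def test_identical_series_mean_is_that_series(self):
        rows = [("S1", t, pid, "none", 10.0 * t, 10.0)
                for pid in ("A", "B", "C") for t in (1.0, 2.0)]
        out = total_concentration(_table(rows), ["A", "B", "C"])
        single = absolute_concentration(_table(rows), "A")
        np.testing.assert_allclose(out["value"], single["value"])

    def test_missing_peptide_at_one_point_uses_remaining(self):
        rows = [("S1", 1.0, "A", "none", 10.0, 10.0),
                ("S1", 1.0, "B", "none", 10.0, 0.0),  # heavy lost -> missing
                ("S1", 1.0, "C", "none", 10.0, 10.0)]
        out = total_concentration(_table(rows), ["A", "B", "C"])
        assert out.loc[0, "n_peptides"] == 2
        assert out.loc[0, "value"] == pytest.approx(200.0)
        assert not out.loc[0, "flagged"]

    def test_majority_missing_point_flagged(self):
        rows = [("S1", 1.0, "A", "none", 10.0, 10.0),
                ("S1", 1.0, "B", "none", 10.0, 0.0),
                ("S1", 1.0, "C", "none", 10.0, 0.0)]
        out = total_concentration(_table(rows), ["A", "B", "C"])
        assert out.loc[0, "flagged"].item() is True

    def test_empty_reference_list_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            total_concentration(_table([("S1", 1.0, "A", "none", 1.0, 1.0)]), [])


def _series(values, subject="S1"):
    return pd.DataFrame({"subject": subject, "time_days": np.arange(1.0, 1.0 + len(values)),
                         "value": values})


class TestTerminalDegradationScreen:
    def test_peptide_equal_to_total_not_flagged(self):
        total = _series([100.0, 80.0, 60.0, 40.0])
        report = terminal_degradation_screen(total.copy(), total)
        assert report.loc[0, "log_ratio_slope"] == pytest.approx(0.0, abs=1e-12)
        assert not report.loc[0, "flagged"]

    def test_injected_extra_decay_recovered_and_flagged(self):
        t = np.array([1.0, 4.0, 7.0, 14.0, 21.0, 42.0])
        total = pd.DataFrame({"subject": "S1", "time_days": t,
                              "value": 100 * np.exp(-0.03 * t)})
        pep = total.assign(value=total["value"] * np.exp(-0.05 * t))
        report = terminal_degradation_screen(pep, total)
        assert report.loc[0, "log_ratio_slope"] == pytest.approx(-0.05, abs=1e-9)
        assert report.loc[0, "flagged"].item() is True

    def test_increasing_ratio_never_flagged(self):
        t = np.array([1.0, 4.0, 7.0, 14.0])
        total = pd.DataFrame({"subject": "S1", "time_days": t, "value": np.full(4, 50.0)})
        pep = total.assign(value=50.0 * np.exp(+0.05 * t))
        report = terminal_degradation_screen(pep, total)
        assert not report.loc[0, "flagged"]

    def test_too_few_shared_points_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            terminal_degradation_screen(_series([1.0, 2.0]), _series([1.0, 2.0]))
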