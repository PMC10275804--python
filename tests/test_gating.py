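import dataclasses

import numpy as np
import pytest
from scipy import stats

from cnvflow import (
    CalibrationError,
    GatingModel,
    GatingTemplate,
    apply_template,
    calibrate_per_timepoint,
    fit_cells_gate,
    fit_copy_gates,
    fit_singlet_gate,
    sample_events,
)
from cnvflow.io import DEBRIS_LABEL, DOUBLET_LABEL
from conftest import make_control, make_controls


class TestCellsGate:
    def test_excludes_debris_keeps_cells(self, fast_config):
        config = dataclasses.replace(fast_config, debris_frac=0.1,
                                     events_per_sample=10_000)
        table = sample_events(np.array([0.0, 1.0, 0.0]), config, seed=2)
        gate = fit_cells_gate([table], q_debris=0.1)
        from cnvflow.transforms import transform_scatter
        inside = gate.contains(transform_scatter(table["FSC-A"]),
                               transform_scatter(table["SSC-A"]))
        labels = table.true_class
        cells = labels >= 0
        debris = labels == DEBRIS_LABEL
        assert inside[cells].mean() >= 0.99
        assert inside[debris].mean() <= 0.05

    def test_without_debris_keeps_quantile_fraction(self, fast_config):
        config = dataclasses.replace(fast_config, debris_frac=0.0)
        table = sample_events(np.array([0.0, 1.0, 0.0]), config, seed=3)
        gate = fit_cells_gate([table], q_debris=0.05)
        from cnvflow.transforms import transform_scatter
        inside = gate.contains(transform_scatter(table["FSC-A"]),
                               transform_scatter(table["SSC-A"]))
        assert inside.mean() >= 0.95

    def test_control_fitted_gate_transfers_to_experimental(self, fast_config,
                                                           fitted_model):
        table = sample_events(np.array([0.0, 0.8, 0.2]), fast_config, seed=4)
        labels = fitted_model.predict(table)
        cells = table.true_class >= 0
        assert (labels[cells] != "outside_cells").mean() >= 0.90

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            fit_cells_gate([])


class TestSingletGate:
    def test_singlets_pass_without_doublets(self, fast_config, fitted_model):
        config = dataclasses.replace(fast_config, doublet_frac=0.0)
        table = sample_events(np.array([0.0, 1.0, 0.0]), config, seed=5)
        labels = fitted_model.predict(table)
        singlets = table.true_class >= 0
        passed = np.isin(labels, ["Copy0", "Copy1", "Copy2plus"])
        assert passed[singlets].mean() >= 0.99

    def test_doublets_mostly_excluded(self, fast_config, fitted_model):
        config = dataclasses.replace(fast_config, doublet_frac=0.1,
                                     events_per_sample=10_000)
        table = sample_events(np.array([0.0, 1.0, 0.0]), config, seed=6)
        labels = fitted_model.predict(table)
        doublets = table.true_class == DOUBLET_LABEL
        passed = np.isin(labels, ["Copy0", "Copy1", "Copy2plus"])
        assert passed[doublets].mean() <= 0.20

    def test_zero_width_band_is_exact_equality(self, controls):
        gate = fit_singlet_gate(list(controls.values()),
                                fit_cells_gate(controls.values()),
                                width=0.0)
        x = np.array([1.0, 1.0, 2.0])
        h = np.array([1.0, 1.0000001, 2.0])
        np.testing.assert_array_equal(gate.contains(x, h),
                                      [True, False, True])

    def test_insufficient_calibration_events(self, fast_config):
        config = dataclasses.replace(fast_config, events_per_sample=50)
        table = make_control(config, 1, seed=1)
        with pytest.raises(CalibrationError, match="100"):
            fit_singlet_gate([table], fit_cells_gate([table]))


class TestCopyGates:
    def test_each_control_median_in_own_gate(self, controls, fitted_model):
        for role, gate_name in [("control_0", "Copy0"), ("control_1", "Copy1"),
                                ("control_2", "Copy2plus")]:
            counts = fitted_model.transform(controls[role])
            assert counts.proportions[gate_name] > 0.5

    def test_identical_controls_fail_ordering_check(self, controls):
        cells = fit_cells_gate(controls.values())
        singlets = fit_singlet_gate(controls.values(), cells)
        with pytest.raises(CalibrationError, match="ordered"):
            fit_copy_gates(controls["control_0"], controls["control_1"],
                           controls["control_1"], cells, singlets)

    def test_paper_like_overlap_regime_still_contains(self, fast_config):
        """At a noise level giving ~6% one-/two-copy overlap, containment
        still clears 0.85. The noise level is found by bisection."""

        def overlap(fluor_cv):
            config = dataclasses.replace(fast_config, fluor_cv=fluor_cv,
                                         seed=31)
            ctrls = make_controls(config, seed_base=300)
            model = GatingModel().fit(ctrls)
            c1 = model.transform(ctrls["control_1"]).proportions
            c2 = model.transform(ctrls["control_2"]).proportions
            return 0.5 * ((1 - c1["Copy1"]) + (1 - c2["Copy2plus"])), model, ctrls

        lo, hi = 0.1, 0.5
        for _ in range(12):
            mid = 0.5 * (lo + hi)
            ov, model, ctrls = overlap(mid)
            if ov < 0.06:
                lo = mid
            else:
                hi = mid
        ov, model, ctrls = overlap(0.5 * (lo + hi))
        assert 0.03 < ov < 0.10
        report = model.assess(ctrls.values())
        assert report.per_strain["control_1"] > 0.85
        assert report.per_strain["control_2"] > 0.85


class TestAssessTemplate:
    def test_calibration_controls_nearly_fully_contained(self, fitted_model,
                                                         controls):
        report = fitted_model.assess(controls.values())
        assert report.passed
        assert min(report.per_strain.values()) >= 0.95

    def test_threshold_one_always_fails(self, fitted_model, controls):
        report = fitted_model.assess(controls.values(), threshold=1.0)
        assert not report.passed

    def test_drifting_control_lowers_containment_monotonically(
            self, fast_config, fitted_model):
        fractions = []
        for drift in (0.0, 0.2, 0.4, 0.6):
            table = make_control(fast_config, 1, seed=77, generation=10)
            data = table.data.copy()
            data["FLUOR"] *= 1.0 + drift
            drifted = dataclasses.replace(table, data=data)
            report = fitted_model.assess([drifted])
            fractions.append(report.per_strain["control_1"])
        assert all(a >= b for a, b in zip(fractions, fractions[1:]))
        assert fractions[-1] < fractions[0]

    def test_unknown_role_rejected(self, fitted_model, controls):
        bad = dataclasses.replace(controls["control_1"], role="experimental")
        with pytest.raises(ValueError, match="role"):
            fitted_model.assess([bad])


class TestApplyTemplate:
    def test_pure_one_copy_sample(self, fast_config, fitted_model):
        table = make_control(fast_config, 1, seed=55)
        counts = fitted_model.transform(table)
        assert counts.proportions["Copy1"] > 0.95
        assert counts.proportions["Copy0"] < 0.03
        assert counts.proportions["Copy2plus"] < 0.05

    def test_copy_gates_partition(self, fast_config, fitted_model):
        """Gates span the full fluorescence range: proportions sum to 1."""
        table = sample_events(np.array([0.1, 0.6, 0.3]), fast_config, seed=56)
        counts = fitted_model.transform(table)
        total = sum(counts.proportions.values())
        assert total == pytest.approx(1.0, abs=1e-12)
        assert sum(counts.counts.values()) == counts.n_singlets

    def test_mixture_proportion_matches_truth_labels(self, fast_config,
                                                     fitted_model):
        config = dataclasses.replace(fast_config, events_per_sample=10_000)
        table = sample_events(np.array([0.0, 0.8, 0.2]), config, seed=57)
        labels = fitted_model.predict(table)
        singlet_mask = np.isin(labels, ["Copy0", "Copy1", "Copy2plus"])
        truth_cnv = (table.true_class == 2) & singlet_mask
        n, k = int(singlet_mask.sum()), int((labels == "Copy2plus").sum())
        lo, hi = stats.binom.ppf([0.005, 0.995], n, truth_cnv.sum() / n)
        assert lo <= k <= hi

    def test_empty_sample_flagged_not_raised(self, fast_config, fitted_model):
        table = sample_events(
            np.array([1.0]), dataclasses.replace(fast_config, events_per_sample=0),
            seed=1, copy_numbers=(1,),
        )
        counts = fitted_model.transform(table)
        assert counts.n_events == 0 and counts.undefined
        assert np.isnan(counts.proportions["Copy1"])

    def test_determinism(self, fast_config, fitted_model):
        table = sample_events(np.array([0.0, 0.5, 0.5]), fast_config, seed=58)
        assert fitted_model.transform(table).counts == \
            fitted_model.transform(table).counts


class TestTemplateLifecycle:
    def test_json_round_trip_preserves_gating(self, fast_config, fitted_model,
                                              tmp_path):
        path = tmp_path / "template.json"
        fitted_model.template_.to_json(path)
        back = GatingTemplate.from_json(path)
        table = sample_events(np.array([0.0, 0.5, 0.5]), fast_config, seed=59)
        assert apply_template(back, table).counts == \
            apply_template(fitted_model.template_, table).counts

    def test_sklearn_params_clone(self):
        from sklearn.base import clone
        model = GatingModel(q_debris=0.1, shear=0.0)
        cloned = clone(model)
        assert cloned.get_params()["q_debris"] == 0.1
        assert cloned.get_params()["shear"] == 0.0

    def test_per_timepoint_templates_pass_own_controls(self, fast_config):
        tables = []
        for gen in (0, 10, 20):
            for c in (0, 1, 2):
                tables.append(make_control(fast_config, c, seed=900 + 10 * gen + c,
                                           generation=gen))
        models = calibrate_per_timepoint(tables)
        assert sorted(models) == [0, 10, 20]
        for gen, model in models.items():
            own = [t for t in tables if t.generation == gen]
            assert model.assess(own).passed

    def test_rectangle_mode_via_zero_shear(self, controls):
        """shear=0 reduces copy gates to horizontal boundaries."""
        model = GatingModel(shear=0.0).fit(controls)
        assert model.shear_ == 0.0
        assert all(g.shear == 0.0 for g in model.copy_gates_)
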