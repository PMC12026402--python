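"""Gating cascade: individual gates against generator truth, report logic."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mkflow.gating import (
    STAGES,
    GateConfig,
    gate_cd41_dump,
    gate_exclude_lymphocytes,
    gate_focus,
    gate_live_nucleated,
    gate_stable_flow,
    gate_unsaturated,
    run_cascade,
)
from mkflow.synthgen import SyntheticConfig, generate_event_set


class TestStableFlow:
    def test_uniform_times_all_retained(self):
        rng = np.random.default_rng(0)
        feats = pd.DataFrame({"time_s": rng.uniform(0, 300, 400)})
        assert len(gate_stable_flow(feats, GateConfig())) == 400

    def test_explicit_window_is_definitional(self):
        feats = pd.DataFrame({"time_s": np.arange(0.0, 30.0)})
        kept = gate_stable_flow(feats, GateConfig(stable_flow=(10.0, 20.0)))
        assert sorted(feats.loc[kept, "time_s"]) == list(np.arange(10.0, 21.0))

    def test_unstable_burst_removed_from_generator_truth(self):
        cfg = SyntheticConfig(n_events=500, seed=1, flow_instability=0.1)
        events, truth = generate_event_set(cfg)
        feats = pd.DataFrame(
            {"time_s": [e.time for e in events]}, index=events.object_ids
        )
        kept = set(gate_stable_flow(feats, GateConfig()))
        unstable = truth.index[~truth["is_stable"]]
        removed = sum(1 for i in unstable if i not in kept)
        assert removed >= 0.9 * len(unstable)

    def test_too_few_bins_keeps_all_with_warning(self):
        feats = pd.DataFrame({"time_s": [0.0, 1.0, 2.0]})
        with pytest.warns(UserWarning, match="time bins"):
            kept = gate_stable_flow(feats, GateConfig(time_bin_s=10.0))
        assert len(kept) == 3


class TestSaturationGate:
    def _features(self, values):
        return pd.DataFrame({"raw_max_pixel_cd41": values, "raw_max_pixel_bf": 100})

    def test_boundary_below_4030_kept(self):
        feats = self._features([4029])
        assert len(gate_unsaturated(feats, GateConfig())) == 1

    def test_exactly_4030_removed(self):
        feats = self._features([4030])
        assert len(gate_unsaturated(feats, GateConfig())) == 0

    def test_all_zero_images_kept(self):
        feats = self._features([0, 0])
        assert len(gate_unsaturated(feats, GateConfig())) == 2

    def test_any_single_channel_saturation_removes(self):
        feats = pd.DataFrame(
            {"raw_max_pixel_cd41": [100, 100], "raw_max_pixel_bf": [100, 4095]}
        )
        kept = gate_unsaturated(feats, GateConfig())
        assert list(kept) == [0]


class TestLiveNucleated:
    def test_dead_cells_all_removed(self, default200):
        _, truth, features = default200
        kept = set(gate_live_nucleated(features, GateConfig()))
        dead = truth.index[truth["label"] == "dead"]
        assert sum(1 for i in dead if i in kept) == 0

    def test_anucleate_events_removed(self, default200):
        _, truth, features = default200
        kept = set(gate_live_nucleated(features, GateConfig()))
        anuc = truth.index[truth["label"] == "anucleate"]
        assert sum(1 for i in anuc if i in kept) == 0

    def test_all_mk_fixture_fully_retained(self, mk_only):
        _, _, features = mk_only
        assert len(gate_live_nucleated(features, GateConfig())) == len(features)

    def test_degenerate_constant_column_demands_explicit_threshold(self):
        feats = pd.DataFrame(
            {"intensity_viability": [5.0] * 20, "intensity_dna": [7.0] * 20}
        )
        with pytest.raises(ValueError, match="explicit threshold"):
            gate_live_nucleated(feats, GateConfig())


class TestLymphocyteExclusion:
    def test_removes_lymphocytes_keeps_mks(self, lymph30_features):
        truth, features = lymph30_features
        kept = set(gate_exclude_lymphocytes(features, GateConfig()))
        lymph = truth.index[truth["label"] == "lymphocyte"]
        mks = truth.index[truth["label"] == "mk"]
        lymph_removed = sum(1 for i in lymph if i not in kept)
        mk_removed = sum(1 for i in mks if i not in kept)
        assert lymph_removed >= 0.9 * len(lymph)
        assert mk_removed <= 0.1 * len(mks)

    def test_no_lymphocytes_keeps_mks(self, mk_only):
        _, _, features = mk_only
        kept = gate_exclude_lymphocytes(features, GateConfig())
        assert len(kept) >= 0.95 * len(features)

    def test_impossible_region_removes_nothing(self, lymph30_features):
        _, features = lymph30_features
        cfg = GateConfig(cd45_min=np.inf, ssc_max=-np.inf)
        assert len(gate_exclude_lymphocytes(features, cfg)) == len(features)


class TestCd41Dump:
    def test_mks_pass(self, default200):
        _, truth, features = default200
        kept = set(gate_cd41_dump(features, GateConfig()))
        mks = truth.index[truth["label"].isin(["mk", "micro_mk"])]
        assert sum(1 for i in mks if i in kept) >= 0.95 * len(mks)

    def test_dump_positive_events_removed(self, cascade_fixture):
        _, truth, features = cascade_fixture
        kept = set(gate_cd41_dump(features, GateConfig()))
        dump_pos = truth.index[~truth["dump_negative"]]
        assert sum(1 for i in dump_pos if i in kept) == 0

    def test_permissive_thresholds_keep_all_cd41_bright(self, mk_only):
        _, _, features = mk_only
        cfg = GateConfig(cd41_min=0.0, dump_max=np.inf)
        assert len(gate_cd41_dump(features, cfg)) == len(features)


class TestFocusGate:
    def test_defocused_events_removed_at_default_threshold(self, default200):
        _, truth, features = default200
        kept = set(gate_focus(features, GateConfig()))
        blurred = truth.index[~truth["is_in_focus"]]
        removed = sum(1 for i in blurred if i not in kept)
        assert removed >= 0.9 * len(blurred)

    def test_constant_image_removed(self):
        feats = pd.DataFrame({"gradient_rms_bf": [0.0, np.nan, 60.0]})
        kept = gate_focus(feats, GateConfig())
        assert list(kept) == [2]

    def test_zero_threshold_keeps_all_textured(self, default200):
        _, _, features = default200
        cfg = GateConfig(focus_min_gradient_rms=0.0)
        textured = features["gradient_rms_bf"] > 0
        assert len(gate_focus(features, cfg)) == int(textured.sum())


class TestCascade:
    def test_oracle_fixture_survivor_counts_exact(self, cascade_fixture):
        events, truth, features = cascade_fixture
        report = run_cascade(events, features=features, truth=truth, oracle=True)
        assert [s["n_out"] for s in report.stages] == [90, 80, 70, 60, 45, 35, 25, 15, 5]
        assert report.terminal_ids == list(range(95, 100))

    def test_monotone_attrition_and_exact_fractions(self, cascade_fixture):
        events, truth, features = cascade_fixture
        report = run_cascade(events, features=features, truth=truth, oracle=True)
        outs = [s["n_out"] for s in report.stages]
        assert all(a >= b for a, b in zip(outs, outs[1:]))
        prod = 1.0
        for s in report.stages:
            assert s["fraction"] == s["n_out"] / s["n_in"]
            prod *= s["fraction"]
        assert prod == pytest.approx(report.terminal_fraction, rel=1e-12)

    def test_terminal_is_intersection_of_pass_vectors(self, cascade_fixture):
        """Independent gates commute: the cascade is a pure intersection."""
        events, truth, features = cascade_fixture
        report = run_cascade(events, features=features, truth=truth, oracle=True)
        alive = report.pass_table.all(axis=1)
        assert sorted(report.pass_table.index[alive]) == sorted(report.terminal_ids)

    def test_empty_input_reports_zeros(self):
        feats = pd.DataFrame(
            columns=["time_s", "raw_max_pixel_bf"], index=pd.Index([], name="object_id")
        )
        report = run_cascade(None, features=feats, stages=("unsaturated",))
        assert report.stages == [
            {"name": "unsaturated", "n_in": 0, "n_out": 0, "fraction": 0.0}
        ]
        assert report.terminal_ids == []

    def test_disabling_every_gate_is_identity(self, cascade_fixture):
        events, truth, features = cascade_fixture
        report = run_cascade(events, features=features, stages=())
        assert sorted(report.terminal_ids) == sorted(features.index)

    def test_missing_singlet_classifier_is_an_error(self, cascade_fixture):
        events, truth, features = cascade_fixture
        with pytest.raises(ValueError, match="classifier"):
            run_cascade(events, features=features, stages=("singlet",))

    def test_unknown_stage_rejected(self, cascade_fixture):
        events, truth, features = cascade_fixture
        with pytest.raises(ValueError, match="unknown stages"):
            run_cascade(events, features=features, stages=("warp",))

    def test_feature_mode_cascade_without_classifiers(self, default200):
        """Feature-driven gates reproduce the oracle decisions closely on
        well-separated synthetic data (no singlet/CNN stages)."""
        events, truth, features = default200
        stages = tuple(s for s in STAGES if s not in ("singlet", "cnn"))
        report = run_cascade(events, features=features, stages=stages)
        oracle = run_cascade(
            events, features=features, truth=truth, oracle=True, stages=stages
        )
        got = {s["name"]: s["n_out"] for s in report.stages}
        want = {s["name"]: s["n_out"] for s in oracle.stages}
        for name in got:
            assert got[name] == pytest.approx(want[name], abs=0.05 * len(features) + 1)

    def test_report_json_round_trip(self, cascade_fixture, tmp_path):
        import json

        events, truth, features = cascade_fixture
        report = run_cascade(events, features=features, truth=truth, oracle=True)
        report.to_json(tmp_path / "r.json")
        back = json.loads((tmp_path / "r.json").read_text())
        assert back["terminal_ids"] == report.terminal_ids
        assert back["stages"] == report.stages
        assert sum(back["diameter_histogram"]["counts"]) == 5
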