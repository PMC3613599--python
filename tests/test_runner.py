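"""Tests for protocol execution and the summary metrics."""

import numpy as np
import pytest

from amygsim import (CircuitParameters, ConfigurationError, NumericalError,
                     NOT_REACHED, build_preset, discrimination_check,
                     generalization_index, run_protocol, savings_index,
                     trials_to_criterion)


class TestRunProtocol:
    def test_four_phase_responding(self, normal_result):
        """Fear is acquired, extinguished, retrieved and re-extinguished,
        for both conditioned stimuli."""
        for cs in ("CS1", "CS2"):
            assert normal_result.epoch_records(
                "acquisition", cs)[-1].responded
            assert not normal_result.epoch_records(
                "extinction", cs)[-1].responded
            assert normal_result.epoch_records(
                "retrieval", cs)[-1].responded
            assert not normal_result.epoch_records(
                "extinction_retrieval", cs)[-1].responded

    def test_naive_network_does_not_respond(self, normal_result):
        assert not normal_result.records[0].responded
        assert normal_result.records[0].cr_cem < 1e-6

    def test_determinism(self, normal_result):
        again = run_protocol(build_preset("normal"))
        assert normal_result.to_frame().equals(again.to_frame())

    def test_record_count_matches_protocol(self, normal_result):
        assert len(normal_result.records) == \
            normal_result.protocol.n_trials

    def test_responded_consistent_with_threshold(self, normal_result):
        theta = normal_result.params.theta_response
        for r in normal_result.records:
            assert r.responded == (r.cr_cem > theta)

    def test_divergence_reports_trial_index(self):
        p = CircuitParameters(dt=0.9, g_ba_cem=500.0, g_la_itcd=50.0)
        with pytest.raises(NumericalError) as err:
            run_protocol(build_preset("normal", trials_per_epoch=2),
                         params=p)
        assert err.value.trial_index is not None


class TestTrialsToCriterion:
    def test_immediately_extinguished_epoch(self, normal_result):
        # after successful extinction, the extinction_retrieval epoch may
        # start already below threshold on trial 1 or cross early
        ttc = trials_to_criterion(normal_result, "extinction_retrieval",
                                  "extinguish")
        assert 1 <= ttc <= 3

    def test_cautious_never_extinguishes(self, preset_results):
        res = preset_results("cautious")
        assert trials_to_criterion(res, "extinction", "extinguish") \
            == NOT_REACHED

    def test_rapid_switch_faster_than_normal(self, preset_results,
                                             normal_result):
        rapid = trials_to_criterion(preset_results("rapid_switch"),
                                    "extinction", "extinguish")
        normal = trials_to_criterion(normal_result, "extinction",
                                     "extinguish")
        assert rapid < normal

    def test_unknown_direction_rejected(self, normal_result):
        with pytest.raises(ConfigurationError):
            trials_to_criterion(normal_result, "extinction", "sideways")


class TestSavings:
    def test_reacquisition_faster_than_acquisition(self, normal_result):
        assert savings_index(normal_result) < 1.0

    def test_metrics_ignore_trace_flag(self, normal_result,
                                       preset_results):
        traced = preset_results("normal", record_trace=True)
        assert savings_index(traced) == savings_index(normal_result)

    def test_undefined_without_acquisition(self):
        # a single acquisition trial leaves the naive network below
        # threshold, so the criterion is never reached
        res = run_protocol(build_preset("normal", trials_per_epoch=1))
        with pytest.raises(ConfigurationError):
            savings_index(res)


class TestGeneralizationIndex:
    def test_untrained_network_zero(self, params):
        res = run_protocol(build_preset("normal", trials_per_epoch=2))
        # inspect initial snapshot: first trial of a naive network has
        # essentially untouched w_cl outside the CS bands
        idx = generalization_index(res, range(2, 18))
        assert idx < 0.05

    def test_low_attention_spreads_associations(self, preset_results,
                                                normal_result):
        gen = generalization_index(preset_results("generalization"),
                                   range(4, 16))
        nrm = generalization_index(normal_result, range(4, 16))
        assert gen >= 2 * nrm
        assert nrm <= 0.1

    def test_full_coverage_rejected(self, normal_result):
        with pytest.raises(ConfigurationError):
            generalization_index(normal_result, range(20))


class TestDiscrimination:
    def test_table_structure(self, normal_result):
        d = discrimination_check(normal_result)
        assert set(d.epoch) == {"acquisition", "extinction", "retrieval",
                                "extinction_retrieval"}
        assert set(d.cs) == {"CS1", "CS2"}
        assert len(d) == 8

    def test_confusing_mode_discriminates(self, preset_results):
        d = discrimination_check(preset_results("confusing"))
        ext = d[d.epoch == "extinction"]
        assert not bool(ext[ext.cs == "CS1"].responded.iloc[0])
        assert bool(ext[ext.cs == "CS2"].responded.iloc[0])

    def test_frozen_itcv_blocks_single_cs_extinction(self,
                                                     preset_results):
        d = discrimination_check(preset_results("confusing_lesion_itcv"))
        ext = d[d.epoch == "extinction"]
        assert bool(ext[ext.cs == "CS1"].responded.iloc[0])


class TestOutputs:
    def test_summary_frame_shape(self, normal_result):
        df = normal_result.to_frame()
        assert len(df) == 60
        assert {"trial", "epoch", "cs", "cr_cem", "peak_cem",
                "responded"} <= set(df.columns)

    def test_csv_round_trip(self, normal_result, tmp_path):
        import pandas as pd
        path = tmp_path / "summary.csv"
        normal_result.write_csv(path)
        back = pd.read_csv(path)
        assert len(back) == 60
        assert back.cr_cem.max() == pytest.approx(
            normal_result.to_frame().cr_cem.max())

    def test_metadata_sidecar(self, normal_result, tmp_path):
        import json
        path = tmp_path / "meta.json"
        normal_result.write_metadata(path)
        meta = json.loads(path.read_text())
        assert meta["preset"] == "normal"
        assert meta["params"]["n_channels"] == 20
        assert "seed" in meta and "version" in meta
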