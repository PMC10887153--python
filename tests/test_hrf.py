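"""HRF kernel shape and ideal-response construction."""

import numpy as np
import pytest
from scipy.stats import gamma as gamma_dist

from trialfc import (HemodynamicModel, StimulusParadigm, default_paradigm,
                     hrf_kernel, ideal_response, trial_template)
from trialfc.hrf import read_paradigm, write_paradigm


class TestKernel:
    def test_peak_sits_at_peak_delay(self, model):
        k = hrf_kernel(model)
        assert np.argmax(k) * model.dt == pytest.approx(model.peak_delay,
                                                        abs=model.dt)
        assert k.max() == pytest.approx(1.0)

    def test_positive_lobe_then_smaller_undershoot(self, model):
        k = hrf_kernel(model)
        assert k.min() < 0  # undershoot exists
        assert abs(k.min()) < 0.5 * k.max()
        assert abs(k[-1]) < 0.05  # returns toward zero by kernel_length

    def test_disabled_undershoot_is_nonnegative(self, model):
        k = hrf_kernel(HemodynamicModel(undershoot_ratio=0.0))
        assert (k >= 0).all()

    def test_matches_direct_two_gamma_evaluation(self, model):
        # independent closed-form evaluation at t = 2.5, 5.0, 7.5 s:
        # unit-peak gamma lobes with mode at the stated delays
        k = hrf_kernel(model)
        t_grid = np.arange(0, model.kernel_length + model.dt / 2, model.dt)

        def lobe(tv, delay, disp):
            a = 1.0 + delay / disp
            peak = gamma_dist.pdf(delay, a, scale=disp)
            return gamma_dist.pdf(tv, a, scale=disp) / peak

        expect_unnorm = lobe(t_grid, 6.0, 1.0) - lobe(t_grid, 16.0, 1.0) / 6.0
        expect = expect_unnorm / np.abs(expect_unnorm).max()
        for t_probe in (2.5, 5.0, 7.5):
            i = int(round(t_probe / model.dt))
            assert k[i] == pytest.approx(expect[i], abs=1e-12)

    @pytest.mark.parametrize("bad", [
        dict(peak_delay=-1), dict(dt=0), dict(kernel_length=5.0),
        dict(peak_dispersion=0),
    ])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            HemodynamicModel(**bad)


class TestIdealResponse:
    def test_single_trial_spans_12_volumes(self, single_trial_paradigm):
        ir = ideal_response(single_trial_paradigm)
        assert len(ir.samples) == 12
        assert np.abs(ir.samples).max() == pytest.approx(1.0)

    def test_empty_boxcar_gives_zero_response(self):
        p = StimulusParadigm(trial_onsets=(0.0,), trial_labels=("FT",),
                             task_duration=0.0, rest_duration=30.0,
                             run_length=30.0, tr=2.5)
        assert (ideal_response(p).samples == 0).all()

    def test_matches_bruteforce_convolution(self, single_trial_paradigm,
                                            model):
        ir = ideal_response(single_trial_paradigm, model)
        # explicit double loop over boxcar x kernel on the fine grid
        dt = model.dt
        n_fine = int(round(single_trial_paradigm.run_length / dt))
        box = np.zeros(n_fine)
        box[: int(round(single_trial_paradigm.task_duration / dt))] = 1.0
        kernel = hrf_kernel(model)
        conv = np.zeros(n_fine)
        for i in range(n_fine):
            for j in range(len(kernel)):
                if 0 <= i - j < n_fine:
                    conv[i] += box[i - j] * kernel[j] * dt
        expect = conv[[int(round(k * 2.5 / dt)) for k in range(12)]]
        expect /= np.abs(expect).max()
        np.testing.assert_allclose(ir.samples, expect, atol=1e-12)

    def test_run_too_short_rejected(self):
        with pytest.raises(ValueError, match="run too short"):
            StimulusParadigm(trial_onsets=(0.0, 20.0), trial_labels=("a", "b"),
                             task_duration=6.0, rest_duration=24.0,
                             run_length=50.0, tr=2.5)

    def test_linearity_over_disjoint_trials(self, model):
        def para(onsets, labels):
            return StimulusParadigm(trial_onsets=onsets, trial_labels=labels,
                                    task_duration=6.0, rest_duration=24.0,
                                    run_length=120.0, tr=2.5)

        both = ideal_response(para((0.0, 60.0), ("a", "b")), model).samples
        r1 = ideal_response(para((0.0,), ("a",)), model).samples
        r2 = ideal_response(para((60.0,), ("b",)), model).samples
        total = r1 + r2  # equal peak scales by time invariance
        np.testing.assert_allclose(both, total / np.abs(total).max(),
                                   atol=1e-12)

    def test_time_invariance_under_tr_shift(self, model):
        def para(onset):
            return StimulusParadigm(trial_onsets=(onset,), trial_labels=("a",),
                                    task_duration=6.0, rest_duration=24.0,
                                    run_length=120.0, tr=2.5)

        base = ideal_response(para(0.0), model).samples
        shifted = ideal_response(para(25.0), model).samples  # 10 volumes
        np.testing.assert_allclose(shifted[10:], base[:-10], atol=1e-12)
        np.testing.assert_allclose(shifted[:10], 0.0, atol=1e-12)


class TestTrialTemplate:
    def test_identity_segmentation_of_single_trial(self, single_trial_paradigm):
        ir = ideal_response(single_trial_paradigm)
        np.testing.assert_array_equal(trial_template(ir, 0.0, 12), ir.samples)

    def test_window_exceeding_run_rejected(self, single_trial_paradigm):
        ir = ideal_response(single_trial_paradigm)
        with pytest.raises(ValueError):
            trial_template(ir, 5.0, 12)

    def test_window_covers_30_seconds(self, paradigm):
        assert 12 * paradigm.tr == 30.0
        assert paradigm.volumes_per_trial == 12

    def test_all_24_segments_match_canonical_template(self, paradigm, model):
        # carryover from the preceding trial is negligible under the
        # 6 s / 24 s design: every segment correlates > 0.99 with the
        # isolated single-trial response
        ir = ideal_response(paradigm, model)
        single = StimulusParadigm(trial_onsets=(0.0,), trial_labels=("FT",),
                                  task_duration=6.0, rest_duration=24.0,
                                  run_length=paradigm.run_length, tr=2.5)
        canonical = ideal_response(single, model).samples[:12]
        for onset in paradigm.trial_onsets:
            seg = trial_template(ir, onset, 12)
            assert np.corrcoef(seg, canonical)[0, 1] > 0.99


def test_paradigm_file_round_trip(tmp_path, paradigm):
    path = tmp_path / "paradigm.txt"
    write_paradigm(paradigm, path)
    back = read_paradigm(path)
    assert back == paradigm
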