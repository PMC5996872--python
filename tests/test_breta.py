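"""Alignment-procedure tests: pattern registration, the three BReTA stages,
maintenance under drift, and the randomized realignment benchmark."""

import numpy as np
import pytest

from cchm import breta
from cchm.breta import (
    BretaParams,
    PatternNotFoundError,
    SignalMeter,
    advanced_alignment,
    axial_align,
    benchmark_realignment,
    default_pattern_template,
    detect_pattern_centers,
    initial_alignment,
    lateral_hillclimb,
    lateral_raster_align,
    maintenance_run,
    maintenance_step,
)
from cchm.holo_sim import DriftProcess, NoiseModel, VirtualMicroscope
from cchm.signal_model import MisalignmentState, SourceModel, signal_map


@pytest.fixture
def meter():
    return SignalMeter()


def hidden(mic) -> MisalignmentState:
    return mic.ground_truth()


# ---------------------------------------------------------------------------
# sighting-pattern registration


class TestDetectPatternCenters:
    def test_unshifted_arms_give_zero_offset(self, make_mic, optics_small):
        mic = make_mic()
        mic.insert_pattern()
        tmpl = default_pattern_template(optics_small)
        img_o = breta._single_arm(mic, "obj")
        img_r = breta._single_arm(mic, "ref")
        obs = detect_pattern_centers(img_o, img_r, tmpl, optics_small)
        assert obs.qf_mag_um < 0.02

    def test_offset_arithmetic_follows_magnification(self, make_mic, optics_small):
        # a 12-px reference-arm shift maps to 12*pitch output-plane um and
        # divides by M for the object-plane offset
        shift_px = 12
        shift_um = shift_px * optics_small.dx_object_um
        mic = make_mic(MisalignmentState(shift_um, 0.0, 0.0))
        mic.insert_pattern()
        tmpl = default_pattern_template(optics_small)
        img_o = breta._single_arm(mic, "obj")
        img_r = breta._single_arm(mic, "ref")
        obs = detect_pattern_centers(img_o, img_r, tmpl, optics_small)
        expected_prime = shift_px * optics_small.pixel_pitch_um
        assert obs.qf_prime_um[0] == pytest.approx(expected_prime, abs=0.1 * optics_small.pixel_pitch_um)
        assert obs.qf_um[0] == pytest.approx(
            obs.qf_prime_um[0] / optics_small.magnification, abs=1e-12
        )

    def test_subpixel_shift_recovered(self, make_mic, optics_small):
        shift_um = 0.3 * optics_small.dx_object_um  # 0.3 px
        mic = make_mic(MisalignmentState(shift_um, 0.0, 0.0))
        mic.insert_pattern()
        tmpl = default_pattern_template(optics_small)
        img_o = breta._single_arm(mic, "obj")
        img_r = breta._single_arm(mic, "ref")
        obs = detect_pattern_centers(img_o, img_r, tmpl, optics_small)
        err_px = abs(obs.qf_um[0] - shift_um) / optics_small.dx_object_um
        assert err_px < 0.05

    def test_missing_pattern_raises(self, make_mic, optics_small):
        mic = make_mic()  # pattern never inserted: uniform arms
        tmpl = default_pattern_template(optics_small)
        img = breta._single_arm(mic, "obj")
        with pytest.raises(PatternNotFoundError):
            detect_pattern_centers(img, img, tmpl, optics_small)


# ---------------------------------------------------------------------------
# initial alignment


class TestInitialAlignment:
    def test_large_lateral_offset_nulled_in_few_iterations(self, make_mic, optics_wide):
        mic = make_mic(MisalignmentState(40.0, -25.0, 0.0), optics=optics_wide,
                       noise_frac=0.01, seed=2)
        tr = initial_alignment(mic)
        n_pattern = sum(1 for r in tr.records if r.phase == "pattern")
        assert tr.status == "success"
        assert n_pattern <= 3
        assert hidden(mic).qf_mag <= BretaParams().pattern_tolerance_um

    def test_dl_walk_descends_toward_zero_from_beyond_first_lobe(self, make_mic, optics_wide):
        mic = make_mic(MisalignmentState(5.0, 0.0, 60.0), optics=optics_wide,
                       noise_frac=0.01, seed=3)
        tr = initial_alignment(mic)
        assert tr.status == "success"
        assert abs(hidden(mic).dl) < 60.0

    def test_stall_on_distant_side_lobe_recovers(self, make_mic, optics_wide):
        # |dl| = 100 um starts near a side-lobe summit where a naive uphill
        # walk has no ascent direction
        mic = make_mic(MisalignmentState(10.0, 10.0, 100.0), optics=optics_wide,
                       noise_frac=0.01, seed=4)
        tr = initial_alignment(mic)
        assert tr.status == "success"
        assert abs(hidden(mic).dl) < 45.0  # on the main lobe

    def test_gaussian_spectrum_uses_noise_floor_threshold(self, make_mic, src_gauss):
        mic = make_mic(MisalignmentState(0.2, 0.1, 2.0), source=src_gauss)
        tr = initial_alignment(mic)
        assert tr.status == "success"

    def test_aligned_start_passes_immediately(self, make_mic):
        tr = initial_alignment(make_mic())
        walk = [r for r in tr.records if r.phase == "dl-walk"]
        assert tr.status == "success" and len(walk) == 1


# ---------------------------------------------------------------------------
# advanced alignment


class TestLateralRaster:
    def test_converges_to_nearest_grid_node(self, make_mic, meter):
        mic = make_mic(MisalignmentState(0.7, -0.4, 0.0))
        lateral_raster_align(mic, 5, 0.5, meter)
        assert hidden(mic).qf_mag <= 0.5 * np.sqrt(2.0) / 2.0 + 0.08

    def test_aligned_start_stays_at_center(self, make_mic, meter):
        mic = make_mic()
        offset, _ = lateral_raster_align(mic, 5, 0.5, meter)
        assert offset == (0.0, 0.0)
        assert hidden(mic).qf_mag == 0.0

    def test_noise_free_choice_matches_theory_argmax(self, make_mic, src_rect, meter):
        start = MisalignmentState(0.6, -0.3, 0.0)
        mic = make_mic(start)
        offset, _ = lateral_raster_align(mic, 5, 0.5, meter)
        # exhaustive oracle: theoretical |w| on the same lattice
        grid = [(i * 0.5, j * 0.5) for i in range(-2, 3) for j in range(-2, 3)]
        vals = [
            abs(
                np.hypot(start.xf + gx, start.yf + gy)
            )
            for gx, gy in grid
        ]
        m = signal_map(np.array(vals), [0.0], src_rect).values[:, 0]
        best = grid[int(np.argmax(m))]
        assert offset == pytest.approx(best, abs=1e-9)

    def test_even_grid_rejected(self, make_mic, meter):
        with pytest.raises(ValueError):
            lateral_raster_align(make_mic(), 4, 0.5, meter)


class TestLateralHillclimb:
    def test_beats_or_matches_raster_on_same_lattice(self, make_mic, meter):
        start = MisalignmentState(1.5, -1.0, 0.0)
        mic_h = make_mic(start)
        lateral_hillclimb(mic_h, 0.5, meter=meter)
        w_h = meter(mic_h)
        mic_r = make_mic(start)
        lateral_raster_align(mic_r, 5, 0.5, meter)
        w_r = meter(mic_r)
        assert w_h >= w_r - 1e-6

    def test_start_at_optimum_moves_at_most_one_step(self, make_mic, meter):
        mic = make_mic()
        lateral_hillclimb(mic, 0.5, meter=meter)
        assert hidden(mic).qf_mag <= 0.5 + 1e-9

    def test_final_position_is_best_visited(self, make_mic, meter):
        mic = make_mic(MisalignmentState(1.2, 0.7, 0.0))
        _, trace = lateral_hillclimb(mic, 0.5, meter=meter)
        ws = [r.wd for r in trace.records if r.phase == "hillclimb"]
        assert ws[-1] == pytest.approx(max(ws), rel=1e-12)

    def test_noise_robustness_on_matched_seeds(self, make_mic, meter):
        finals = []
        for frac in (0.0, 0.01):
            mic = make_mic(MisalignmentState(1.5, -1.0, 0.0), noise_frac=frac, seed=6)
            lateral_hillclimb(mic, 0.5, meter=meter)
            gt = hidden(mic)
            finals.append(np.array([gt.xf, gt.yf]))
        assert np.hypot(*(finals[0] - finals[1])) <= 2 * 0.5 + 1e-9


class TestAxialAlign:
    def test_coarse_plus_fine_reaches_one_micron(self, make_mic, meter):
        mic = make_mic(MisalignmentState(0.0, 0.0, 37.0), source=SourceModel())
        axial_align(mic, 10.0, 1.0, meter)
        assert abs(hidden(mic).dl) <= 1.0 + 1e-9

    def test_aligned_start_moves_at_most_fine_step(self, make_mic, meter):
        mic = make_mic()
        axial_align(mic, 10.0, 1.0, meter)
        assert abs(hidden(mic).dl) <= 1.0 + 1e-9

    def test_final_value_is_best_sampled(self, make_mic, meter):
        mic = make_mic(MisalignmentState(0.0, 0.0, 23.0))
        _, trace = axial_align(mic, 10.0, 1.0, meter)
        ws = [r.wd for r in trace.records if r.phase == "axial"]
        assert ws[-1] == pytest.approx(max(ws), rel=1e-12)


class TestAdvancedAlignment:
    def test_reaches_acceptable_misalignment_box(self, make_mic):
        # from the outer slope of the peak down to the ~90%-signal region:
        # |qf| <= 0.5 um, |dl| <= 10 um
        mic = make_mic(MisalignmentState(1.06, 1.06, 25.0), noise_frac=0.01, seed=8)
        tr = advanced_alignment(mic)
        gt = hidden(mic)
        assert tr.status == "success"
        assert gt.qf_mag <= 0.5
        assert abs(gt.dl) <= 10.0

    def test_axial_first_order_lands_in_same_place(self, make_mic, meter):
        start = MisalignmentState(1.0, -0.5, 20.0)
        mic_a = make_mic(start)
        advanced_alignment(mic_a)
        mic_b = make_mic(start)
        axial_align(mic_b, 10.0, 1.0, meter)
        lateral_raster_align(mic_b, 5, 0.5, meter)
        ga, gb = hidden(mic_a), hidden(mic_b)
        assert np.hypot(ga.xf - gb.xf, ga.yf - gb.yf) <= 0.5 + 1e-9
        assert abs(ga.dl - gb.dl) <= 1.0 + 1e-9

    def test_aligned_start_barely_moves(self, make_mic):
        mic = make_mic()
        advanced_alignment(mic)
        gt = hidden(mic)
        assert gt.qf_mag <= 0.5 and abs(gt.dl) <= 1.0


# ---------------------------------------------------------------------------
# maintenance


class TestMaintenance:
    def test_stationary_aligned_microscope_not_moved(self, make_mic, meter):
        mic = make_mic()
        decisions = maintenance_step(mic, meter=meter)
        assert decisions == {"x": 0.0, "y": 0.0, "dl": 0.0}
        gt = hidden(mic)
        assert (gt.xf, gt.yf, gt.dl) == (0.0, 0.0, 0.0)

    def test_perturbation_corrected_downhill(self, make_mic, meter):
        mic = make_mic(MisalignmentState(0.15, 0.0, 0.0))
        decisions = maintenance_step(mic, meter=meter)
        assert decisions["x"] == pytest.approx(-0.1)

    def test_tracking_beats_drift(self, make_mic, meter):
        drift = DriftProcess(ramp_um_per_tick=(0.05, 0.0, 0.15),
                             walk_std_um=(0.01, 0.01, 0.02), seed=7)
        df = maintenance_run(make_mic(noise_frac=0.01, seed=12), drift, 30, meter=meter)
        drift_ctrl = DriftProcess(ramp_um_per_tick=(0.05, 0.0, 0.15),
                                  walk_std_um=(0.01, 0.01, 0.02), seed=7)
        ctrl = maintenance_run(make_mic(noise_frac=0.01, seed=12), drift_ctrl, 30,
                               meter=meter, maintain=False)
        assert df["wD_bar_rel"].median() >= 95.0
        assert ctrl["wD_bar_rel"].min() < 80.0


# ---------------------------------------------------------------------------
# benchmark


class TestBenchmark:
    @staticmethod
    def factory_builder(optics, source, noise_frac=0.01):
        def factory(state, trial):
            return VirtualMicroscope(
                source, optics, state, noise=NoiseModel(noise_frac), seed=50 + trial
            )

        return factory

    def test_zero_misalignment_reports_full_signal(self, optics_small, src_rect):
        res = benchmark_realignment(
            self.factory_builder(optics_small, src_rect),
            n_trials=2, misalign_magnitude_um=0.0, seed=1,
        )
        assert (res.trials["status"] == "success").all()
        assert (res.trials["wD_s"] > 98.0).all()

    def test_seeded_determinism(self, optics_small, src_rect):
        runs = [
            benchmark_realignment(
                self.factory_builder(optics_small, src_rect),
                n_trials=2, misalign_magnitude_um=5.0, seed=9,
            )
            for _ in range(2)
        ]
        assert runs[0].trials.equals(runs[1].trials)
        assert runs[0].histogram.equals(runs[1].histogram)

    def test_moderate_misalignment_realigned(self, optics_wide, src_rect):
        res = benchmark_realignment(
            self.factory_builder(optics_wide, src_rect),
            n_trials=2, misalign_magnitude_um=40.0, seed=3,
        )
        assert (res.trials["status"] == "success").all()
        assert (res.trials["wD_s"] >= 90.0).all()
        assert res.histogram["count"].sum() == 2


# ---------------------------------------------------------------------------
# interface audit


class _PublicMicProxy:
    """Expose only the instrument's public surface; anything else is a breach."""

    _ALLOWED = {
        "acquire", "acquire_hologram", "set_shutter", "insert_pattern",
        "remove_pattern", "move_o2", "move_m2", "optics", "source",
        "shutters", "pattern_inserted",
    }

    def __init__(self, mic):
        object.__setattr__(self, "_mic", mic)

    def __getattr__(self, name):
        if name not in self._ALLOWED:
            raise AssertionError(f"alignment code touched non-public attribute {name!r}")
        return getattr(object.__getattribute__(self, "_mic"), name)


class TestInterfaceAudit:
    def test_procedures_use_only_images_and_commands(self, make_mic, optics_wide):
        mic = make_mic(MisalignmentState(20.0, -15.0, 30.0), optics=optics_wide,
                       noise_frac=0.01, seed=5)
        proxy = _PublicMicProxy(mic)
        tr1 = initial_alignment(proxy)
        tr2 = advanced_alignment(proxy)
        assert tr1.status == "success" and tr2.status == "success"
        gt = mic.ground_truth()
        assert gt.qf_mag <= 0.5 and abs(gt.dl) <= 10.0


class TestTraceInvariants:
    def test_step_indices_monotone(self, make_mic):
        tr = initial_alignment(make_mic(MisalignmentState(2.0, 1.0, 15.0)))
        steps = [r.step for r in tr.records]
        assert steps == sorted(steps) == list(range(len(steps)))

    def test_params_validation(self):
        with pytest.raises(ValueError):
            BretaParams(k=0.9)
        with pytest.raises(ValueError):
            BretaParams(raster_n=4)
        with pytest.raises(ValueError):
            BretaParams(axial_fine_um=20.0, axial_coarse_um=10.0)
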