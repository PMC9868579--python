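import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage.measure import regionprops

from purinesim.imaging import (
    ImageStack,
    SynthSpec,
    detect_cells,
    ensemble_summary,
    extract_traces,
    measure_displacement,
    moving_stats,
    synth_stack,
)


@pytest.fixture(scope="module")
def noisy_stack():
    """12 Gaussian-blob cells with Poisson + read noise, SNR ~ 7."""
    spec = SynthSpec(n_cells=12, gaussian_sigma=80.0, poisson=True, seed=3)
    return spec, *synth_stack(spec)


class TestSynthStack:
    def test_reproducible_from_seed(self):
        spec = SynthSpec(n_cells=4, poisson=True, gaussian_sigma=20.0, seed=9)
        s1, _ = synth_stack(spec)
        s2, _ = synth_stack(spec)
        assert np.array_equal(s1.data, s2.data)

    def test_out_of_frame_cells_rejected(self):
        spec = SynthSpec(n_cells=1, shape=(32, 32), radius=6.0,
                         centers=[(2, 2)])
        with pytest.raises(ValueError):
            synth_stack(spec)

    def test_stack_invariants(self):
        with pytest.raises(ValueError):
            ImageStack(np.zeros((1, 8, 8)))
        with pytest.raises(ValueError):
            ImageStack(np.full((4, 8, 8), -1.0))


class TestDetectCells:
    def test_uniform_stack_detects_nothing_with_warning(self):
        stack = ImageStack(np.full((5, 32, 32), 100, np.uint16))
        with pytest.warns(UserWarning):
            labels = detect_cells(stack)
        assert labels.max() == 0

    def test_recovers_cell_count_and_centroids(self, noisy_stack):
        spec, stack, truth = noisy_stack
        labels = detect_cells(stack)
        assert labels.max() == spec.n_cells
        props = regionprops(labels)
        for cy, cx in truth.centers:
            err = min(np.hypot(p.centroid[0] - cy, p.centroid[1] - cx)
                      for p in props)
            assert err < 2.0

    def test_touching_blobs_merge_into_one_label(self):
        spec = SynthSpec(n_cells=2, shape=(64, 64), radius=6.0,
                         centers=[(32, 28), (32, 36)])
        stack, _ = synth_stack(spec)
        labels = detect_cells(stack)
        assert labels.max() == 1   # documented: no watershed splitting

    def test_translation_equivariance(self):
        spec = SynthSpec(n_cells=4, shape=(96, 96), seed=5)
        stack, _ = synth_stack(spec)
        base = detect_cells(stack)
        shifted = ImageStack(np.roll(stack.data, (7, -5), axis=(1, 2)))
        labels2 = detect_cells(shifted)
        assert np.array_equal(np.roll(base > 0, (7, -5), axis=(0, 1)),
                              labels2 > 0)


class TestExtractTraces:
    def test_constant_trace_divide_mode_is_unity(self):
        spec = SynthSpec(n_cells=1, shape=(48, 48), transient_amplitude=0.0)
        stack, truth = synth_stack(spec)
        ts = extract_traces(stack, truth.labels, (0, 40), mode="divide")
        assert np.allclose(ts.normalized, 1.0, atol=1e-3)

    def test_constant_trace_subtract_mode_is_zero(self):
        spec = SynthSpec(n_cells=1, shape=(48, 48), transient_amplitude=0.0)
        stack, truth = synth_stack(spec)
        ts = extract_traces(stack, truth.labels, (0, 40), mode="subtract")
        assert np.allclose(ts.normalized, 0.0, atol=1.0)

    def test_injected_amplitude_recovered_exactly_without_noise(self):
        """Zero background: normalized peak = (baseline+amplitude)/baseline."""
        spec = SynthSpec(n_cells=1, shape=(48, 48), background=0.0,
                         baseline=1000.0, transient_amplitude=500.0)
        stack, truth = synth_stack(spec)
        ts = extract_traces(stack, truth.labels, (0, spec.transient_onset_frame
                                                  * spec.frame_interval))
        assert ts.normalized.max() == pytest.approx(1.5, rel=0.01)

    def test_empty_control_window_rejected(self, noisy_stack):
        _, stack, truth = noisy_stack
        with pytest.raises(ValueError):
            extract_traces(stack, truth.labels, (50.0, 50.0))

    def test_invalid_mode_rejected(self, noisy_stack):
        _, stack, truth = noisy_stack
        with pytest.raises(ValueError):
            extract_traces(stack, truth.labels, (0, 40), mode="log")

    def test_end_to_end_recovery_at_moderate_noise(self, noisy_stack):
        """Detect + extract recovers the injected transients: exact cell
        count, per-cell correlation >= 0.95, onset within one frame."""
        spec, stack, truth = noisy_stack
        labels = detect_cells(stack)
        assert labels.max() == spec.n_cells
        ts = extract_traces(stack, labels, (0, 60))
        for k in range(1, labels.max() + 1):
            overlap = [np.sum((labels == k) & (truth.labels == j + 1))
                       for j in range(spec.n_cells)]
            mate = int(np.argmax(overlap))
            r = np.corrcoef(ts.raw[k - 1], truth.traces[mate])[0, 1]
            assert r >= 0.95
            # onset: first frame where the normalized trace exceeds half the
            # peak elevation
            tr = ts.normalized[k - 1]
            thresh = 1.0 + 0.5 * (tr.max() - 1.0)
            onset = int(np.argmax(tr >= thresh))
            assert abs(onset - spec.transient_onset_frame) <= 1


class TestMovingStats:
    def test_window_one_is_identity(self):
        x = np.random.default_rng(0).normal(size=50)
        mean, var = moving_stats(x, 1)
        assert np.allclose(mean, x)
        assert np.allclose(var, 0.0)

    def test_window_longer_than_trace_rejected(self):
        with pytest.raises(ValueError):
            moving_stats(np.arange(5.0), 6)

    def test_linear_ramp_preserved_away_from_edges(self):
        x = np.arange(100.0)
        mean, _ = moving_stats(x, 9)   # odd window: exactly centered
        assert np.allclose(mean[10:-10], x[10:-10])
        mean8, _ = moving_stats(x, 8)  # even window: half-sample offset
        assert np.max(np.abs(mean8[10:-10] - x[10:-10])) <= 0.5

    def test_white_noise_running_variance_near_population_variance(self):
        rng = np.random.default_rng(42)
        x = rng.normal(0.0, 2.0, 600)
        _, var = moving_stats(x, 8)
        assert abs(var[4:-4].mean() - 4.0) < 0.8   # within 20%

    def test_ensemble_summary_smooths_the_mean_trace(self):
        traces = np.vstack([np.arange(100.0)] * 3)
        mean, var = ensemble_summary(traces, window=8)
        assert np.max(np.abs(mean[10:-10] - np.arange(100.0)[10:-10])) <= 0.5
        assert np.all(var >= 0)


class TestDisplacement:
    def test_identical_points_give_zero(self):
        assert measure_displacement((5, 5), (5, 5)) == 0.0

    def test_three_four_five_triangle(self):
        assert measure_displacement((0, 0), (3, 4)) == pytest.approx(8.0)

    def test_axis_displacement_matches_reported_scale(self):
        assert measure_displacement((0, 0), (10, 0)) == pytest.approx(16.0)

    @given(dy=st.floats(-50, 50), dx=st.floats(-50, 50))
    @settings(deadline=None, max_examples=40)
    def test_symmetry_and_nonnegativity(self, dy, dx):
        d = measure_displacement((0, 0), (dy, dx))
        assert d >= 0
        assert d == pytest.approx(measure_displacement((dy, dx), (0, 0)))
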