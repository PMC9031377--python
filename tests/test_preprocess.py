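import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from resosharp import (
    NoiseModel,
    ReturnLossTrace,
    SyntheticModel,
    TimeSignal,
    alpha_band,
    average_traces,
    beta_support,
    flatten_and_debias,
    idtft,
    simulate_acquisitions,
    synth_return_loss,
    unwrap_phase,
)
from resosharp.errors import (
    DegenerateSignalError,
    EndpointOrderError,
    IncompatibleTracesError,
    InvalidInputError,
)

GHZ = 1e9


def make_trace(values, fmin=2e9, fmax=3e9):
    values = np.asarray(values, dtype=float)
    return ReturnLossTrace(np.linspace(fmin, fmax, values.size), values)


@pytest.fixture(scope="module")
def mirrored_example(example_trace):
    """The 101-point example curve, mirrored so RL(fmin) < RL(fMAX)."""
    return example_trace.mirrored()


class TestAverageTraces:
    def test_mean_of_one(self, example_trace):
        out = average_traces([example_trace])
        np.testing.assert_array_equal(out.values, example_trace.values)

    def test_symmetric_cancellation(self):
        v = np.array([1.0, -2.0, 3.0, 1.0])
        a = make_trace(v + 5)
        b = make_trace(-v + 5)
        out = average_traces([a, b])
        np.testing.assert_allclose(out.values, 5.0)

    def test_noise_suppression_bound(self, example_trace):
        # Monte Carlo bound computed once with this seed and frozen:
        # 200 sweeps at 0.5 dB give max |mean - clean| ~ 0.11 dB.
        sweeps = simulate_acquisitions(
            example_trace, NoiseModel(sigma_noise=0.5, m=200, seed=11)
        )
        out = average_traces(sweeps)
        assert np.max(np.abs(out.values - example_trace.values)) < 0.2

    def test_mismatched_grids_rejected(self, example_trace):
        other = synth_return_loss(SyntheticModel(f_true=2.25 * GHZ), 99)
        with pytest.raises(IncompatibleTracesError):
            average_traces([example_trace, other])

    def test_empty_rejected(self):
        with pytest.raises(InvalidInputError):
            average_traces([])


class TestFlattenAndDebias:
    def test_endpoints_exactly_zero(self, mirrored_example):
        bar = flatten_and_debias(mirrored_example)
        assert bar.values[0] == 0.0
        assert bar.values[-1] == 0.0
        # peak of the example curve is amplitude + offset - RL(fMAX) ~ 18 dB
        assert bar.values.max() == pytest.approx(
            20.0 - mirrored_example.values[-1], abs=1e-9
        )
        assert bar.values.max() == pytest.approx(18.0, abs=0.05)

    def test_left_plateau_constant(self, mirrored_example):
        bar = flatten_and_debias(mirrored_example)
        peak = int(np.argmax(bar.values))
        first_nonzero = np.nonzero(bar.values[:peak])[0]
        assert first_nonzero.size  # plateau then rise
        plateau = bar.values[: first_nonzero[0]]
        np.testing.assert_array_equal(plateau, 0.0)

    def test_already_flat_left_only_debiased(self):
        v = np.array([3.0, 3.0, 3.0, 8.0, 12.0, 7.0, 3.0])
        bar = flatten_and_debias(make_trace(v))
        np.testing.assert_allclose(bar.values, v - 3.0)

    def test_wrong_endpoint_order_raises(self, example_trace):
        with pytest.raises(EndpointOrderError, match="mirror"):
            flatten_and_debias(example_trace)

    def test_symmetric_model_crossing_mirrors_fmax(self):
        # For equal sigmas the level RL(fMAX) is crossed at the mirror
        # image of fMAX about the peak (Gaussian symmetry); the flatten
        # plateau must end within one grid step of that point.
        model = SyntheticModel(
            f_true=2.6 * GHZ, sigma_left=0.15 * GHZ, sigma_right=0.15 * GHZ,
            band=(2.0 * GHZ, 3.0 * GHZ),
        )
        tr = synth_return_loss(model, 501)
        bar = flatten_and_debias(tr)
        mirror_of_fmax = 2 * 2.6 * GHZ - 3.0 * GHZ  # 2.2 GHz, on the grid
        plateau_end = int(np.nonzero(bar.values > 0)[0][0]) - 1
        assert abs(tr.frequencies[plateau_end] - mirror_of_fmax) <= tr.step


class TestAlphaBand:
    def test_analytic_crossings_on_dense_grid(self, paper_model):
        # Oracle: invert the Gaussian at level alpha*max of the debiased
        # curve analytically, accounting for the mirrored baseline.
        nf = 2001
        tr = synth_return_loss(paper_model, nf).mirrored()
        bar = flatten_and_debias(tr)
        band = alpha_band(bar, alpha=0.1)
        level = 2.030587028579948  # RL at the original fmin = debias level
        g = (0.1 * (20.0 - level) - 2.0 + level) / 18.0
        xl = 0.07 * GHZ * np.sqrt(2 * np.log(1 / g))
        xr = 0.10 * GHZ * np.sqrt(2 * np.log(1 / g))
        step = tr.step
        # mirrored trace: the analytic left crossing maps to the right edge
        assert abs(band.f_tilde_max - (tr.band[0] + tr.band[1] - (2.25 * GHZ - xl))) <= step
        assert abs(band.f_tilde_min - (tr.band[0] + tr.band[1] - (2.25 * GHZ + xr))) <= step
        # and both sit near the nominal analytic values (baseline shift < 1 MHz-scale)
        assert 2.25 * GHZ - xl == pytest.approx(2.0998 * GHZ, abs=5e6)
        assert 2.25 * GHZ + xr == pytest.approx(2.4646 * GHZ, abs=5e6)

    def test_alpha_near_one_collapses_to_neighbours(self, mirrored_example):
        bar = flatten_and_debias(mirrored_example)
        band = alpha_band(bar, alpha=0.999999)
        peak = int(np.argmax(bar.values))
        assert band.i_lo == peak - 1
        assert band.i_hi == peak + 1

    def test_symmetric_band_about_peak(self):
        model = SyntheticModel(
            f_true=2.5 * GHZ, sigma_left=0.1 * GHZ, sigma_right=0.1 * GHZ
        )
        tr = synth_return_loss(model, 201)
        bar = flatten_and_debias(tr)
        band = alpha_band(bar, alpha=0.3)
        step = tr.step
        assert abs((2.5 * GHZ - band.f_tilde_min) - (band.f_tilde_max - 2.5 * GHZ)) <= step

    def test_monotone_in_alpha(self, mirrored_example):
        bar = flatten_and_debias(mirrored_example)
        widths = [alpha_band(bar, a).width for a in (0.05, 0.2, 0.5, 0.8, 0.95)]
        assert all(w1 >= w2 for w1, w2 in zip(widths, widths[1:]))

    def test_band_strictly_inside(self, mirrored_example):
        bar = flatten_and_debias(mirrored_example)
        band = alpha_band(bar, 0.1)
        assert bar.band[0] < band.f_tilde_min < band.f_tilde_max < bar.band[1]

    def test_invalid_alpha(self, mirrored_example):
        bar = flatten_and_debias(mirrored_example)
        for bad in (0.0, 1.0, -0.5, 1.5):
            with pytest.raises(InvalidInputError):
                alpha_band(bar, bad)


class TestIdtft:
    def test_rectangle_gives_sinc_peak_at_zero(self):
        bar = make_trace(np.ones(51))
        sig = idtft(bar, 257)
        assert sig.times[0] == pytest.approx(-0.5 / bar.step)
        assert sig.times[-1] == pytest.approx(0.5 / bar.step)
        assert int(np.argmax(sig.magnitude)) == 128  # t = 0

    def test_shift_theorem_phase_slope(self, symmetric_model):
        # A symmetric bump centred at f0 has phase 2*pi*f0*t on the main
        # lobe: recover the slope by a linear fit over the inner half.
        # Nt must keep the phase increment below pi per sample (f0 * dt
        # < 1/2) or unwrapping aliases.
        tr = synth_return_loss(symmetric_model, 101)
        bar = flatten_and_debias(tr)
        sig = idtft(bar, 1001)
        mag = sig.magnitude
        peak = int(np.argmax(mag))
        lobe = np.nonzero(mag > 0.5 * mag[peak])[0]
        inner = lobe[(lobe > lobe[0] + lobe.size // 4) & (lobe < lobe[-1] - lobe.size // 4)]
        slope = np.polyfit(sig.times[inner], sig.phase_unwrapped[inner], 1)[0]
        f0 = slope / (2 * np.pi)
        assert abs(f0 - symmetric_model.f_true) / symmetric_model.f_true < 1e-3

    def test_modulation_property(self, symmetric_model):
        # shifting the bump centre by delta adds 2*pi*delta*t to the phase
        delta = 0.05 * GHZ
        tr1 = synth_return_loss(symmetric_model, 101)
        shifted = SyntheticModel(
            f_true=symmetric_model.f_true + delta,
            sigma_left=symmetric_model.sigma_left,
            sigma_right=symmetric_model.sigma_right,
        )
        tr2 = synth_return_loss(shifted, 101)
        sig1 = idtft(flatten_and_debias(tr1), 1025)
        sig2 = idtft(flatten_and_debias(tr2), 1025)
        mag = sig1.magnitude
        lobe = np.nonzero(mag > 0.5 * mag.max())[0]
        dphi = sig2.phase_unwrapped[lobe] - sig1.phase_unwrapped[lobe]
        dphi -= dphi[lobe.size // 2] - 2 * np.pi * delta * sig1.times[lobe][lobe.size // 2]
        np.testing.assert_allclose(
            dphi, 2 * np.pi * delta * sig1.times[lobe], rtol=0, atol=0.06
        )

    def test_grid_decoupling(self, mirrored_example):
        # the transform is pointwise in t: values at shared time points
        # agree regardless of Nt
        bar = flatten_and_debias(mirrored_example)
        coarse = idtft(bar, 129)
        fine = idtft(bar, 257)  # shares every other time point
        scale = np.max(np.abs(coarse.values))
        np.testing.assert_allclose(
            fine.values[::2], coarse.values, rtol=0, atol=1e-8 * scale
        )

    def test_rejects_nonuniform_and_small_nt(self):
        bad = ReturnLossTrace(np.array([1.0, 2.0, 4.0]), np.zeros(3))
        with pytest.raises(InvalidInputError):
            idtft(bad, 64)
        with pytest.raises(InvalidInputError):
            idtft(make_trace(np.ones(11)), 4)


class TestUnwrapPhase:
    def test_continuous_phase_unchanged(self):
        t = np.linspace(-1, 1, 101)
        phase = 0.4 * t  # small slope, no wrapping
        sig = unwrap_phase(TimeSignal(t, np.exp(1j * phase)))
        np.testing.assert_allclose(sig.phase_unwrapped, phase, atol=1e-12)

    def test_cisoid_exact_line(self):
        dt = 1.0
        t = np.arange(64) * dt
        f0 = 0.3  # cycles per sample
        sig = unwrap_phase(TimeSignal(t, np.exp(2j * np.pi * f0 * t)))
        slope = np.diff(sig.phase_unwrapped)
        np.testing.assert_allclose(slope, 2 * np.pi * f0, rtol=1e-9)

    def test_no_large_jumps(self, mirrored_example):
        sig = idtft(flatten_and_debias(mirrored_example), 512)
        assert np.max(np.abs(np.diff(sig.phase_unwrapped))) < np.pi

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_round_trip(self, seed):
        rng = np.random.default_rng(seed)
        steps = rng.uniform(-3.0, 3.0, size=100)
        x = np.cumsum(np.clip(steps, -np.pi + 1e-6, np.pi - 1e-6))
        sig = TimeSignal(np.arange(100.0), np.exp(1j * x))
        recovered = sig.phase_unwrapped
        offset = recovered[0] - x[0]
        assert offset == pytest.approx(round(offset / (2 * np.pi)) * 2 * np.pi, abs=1e-9)
        np.testing.assert_allclose(recovered - offset, x, atol=1e-9)


class TestBetaSupport:
    def test_rectangle_half_power_width(self):
        # brute-force oracle: scan the transform magnitude directly
        bar = make_trace(np.ones(41))
        sig = idtft(bar, 2001)
        sup = beta_support(sig, beta=0.5)
        norm = sig.magnitude / sig.magnitude.max()
        peak = int(np.argmax(norm))
        i = peak
        while norm[i - 1] > 0.5:
            i -= 1
        j = peak
        while norm[j + 1] > 0.5:
            j += 1
        assert sup.i_lo == i - 1
        assert sup.i_hi == j + 1

    def test_beta_near_one_collapses(self):
        # a sharply peaked magnitude: both neighbours sit below beta*max
        t = np.linspace(-1.0, 1.0, 9)
        mag = np.array([0.1, 0.1, 0.2, 0.5, 1.0, 0.5, 0.2, 0.1, 0.1])
        sup = beta_support(TimeSignal(t, mag.astype(complex)), beta=0.999)
        assert (sup.i_lo, sup.i_hi) == (3, 5)
        assert sup.n_tilde_t == 3

    def test_small_beta_extends_to_window(self):
        t = np.linspace(-1, 1, 101)
        sig = TimeSignal(t, np.exp(2j * np.pi * 3 * t))  # constant magnitude
        sup = beta_support(sig, beta=0.5)
        assert (sup.i_lo, sup.i_hi) == (0, 100)
        assert sup.covers_window
        assert sup.n_tilde_t == 101

    def test_monotone_in_beta(self, mirrored_example):
        sig = idtft(flatten_and_debias(mirrored_example), 512)
        widths = [
            beta_support(sig, b).t_tilde_max - beta_support(sig, b).t_tilde_min
            for b in (0.05, 0.15, 0.3, 0.6, 0.9)
        ]
        assert all(w1 >= w2 for w1, w2 in zip(widths, widths[1:]))

    def test_zero_signal_rejected(self):
        sig = TimeSignal(np.linspace(-1, 1, 16), np.zeros(16, dtype=complex))
        with pytest.raises(DegenerateSignalError):
            beta_support(sig, 0.5)


class TestTimeWindowInvariant:
    def test_symmetric_window(self, mirrored_example):
        bar = flatten_and_debias(mirrored_example)
        sig = idtft(bar, 256)
        assert sig.times[0] == pytest.approx(-0.5 / bar.step)
        assert sig.times[0] == pytest.approx(-sig.times[-1])
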