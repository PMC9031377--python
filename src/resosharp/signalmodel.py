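"""Core domain types and the synthetic return-loss generator.

The central object is :class:`ReturnLossTrace`, a sampled return-loss
curve ``RL(f)`` in dB on a strictly increasing frequency grid.  Synthetic
single-resonance curves are produced by :func:`synth_return_loss` from an
asymmetric-Gaussian :class:`SyntheticModel` (different widths left and
right of the peak, plus a constant dB offset), and a simple acquisition
model (:class:`NoiseModel`, :func:`simulate_acquisitions`) emulates ``M``
noisy instrument sweeps to be averaged by the preprocessing chain.

All frequencies are stored in Hz internally; convenience constructors on
the CLI accept GHz and convert on ingest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError

__all__ = [
    "ReturnLossTrace",
    "TimeSignal",
    "SyntheticModel",
    "NoiseModel",
    "rl_from_gamma",
    "synth_return_loss",
    "simulate_acquisitions",
]

#: Relative tolerance on grid-spacing deviation below which a trace is
#: considered uniformly sampled.
UNIFORM_RTOL = 1e-9


@dataclass(frozen=True)
class ReturnLossTrace:
    """A sampled return-loss curve RL(f).

    Parameters
    ----------
    frequencies
        Strictly increasing frequency grid in Hz, length ``nf >= 3``.
    values
        Return loss in dB, same length as ``frequencies``.
    """

    frequencies: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        freqs = np.asarray(self.frequencies, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if freqs.ndim != 1 or vals.ndim != 1:
            raise InvalidInputError("frequencies and values must be 1-D arrays")
        if freqs.size != vals.size:
            raise InvalidInputError(
                f"length mismatch: {freqs.size} frequencies vs {vals.size} values"
            )
        if freqs.size < 3:
            raise InvalidInputError("a trace needs at least 3 samples")
        if not np.all(np.diff(freqs) > 0):
            raise InvalidInputError("frequencies must be strictly increasing")
        object.__setattr__(self, "frequencies", freqs)
        object.__setattr__(self, "values", vals)

    @property
    def nf(self) -> int:
        return self.frequencies.size

    @property
    def band(self) -> tuple[float, float]:
        """(fmin, fMAX) in Hz."""
        return float(self.frequencies[0]), float(self.frequencies[-1])

    @property
    def uniform(self) -> bool:
        spacings = np.diff(self.frequencies)
        step = (self.band[1] - self.band[0]) / (self.nf - 1)
        return bool(np.max(np.abs(spacings - step)) <= UNIFORM_RTOL * step)

    @property
    def step(self) -> float:
        """Grid step Δf in Hz; defined only for uniform traces."""
        if not self.uniform:
            raise InvalidInputError("step is defined only for uniform traces")
        return (self.band[1] - self.band[0]) / (self.nf - 1)

    def mirrored(self) -> "ReturnLossTrace":
        """Frequency-mirror about the band centre: f -> fmin + fMAX - f."""
        fmin, fmax = self.band
        return ReturnLossTrace(
            frequencies=(fmin + fmax) - self.frequencies[::-1],
            values=self.values[::-1].copy(),
        )


@dataclass(frozen=True)
class TimeSignal:
    """Complex-valued rl(t) on a symmetric time grid.

    ``times`` spans ``[-tMAX, +tMAX]`` with ``tMAX = 0.5/Δf`` of the
    originating trace; ``values`` holds the complex samples.
    """

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        vals = np.asarray(self.values, dtype=complex)
        if times.shape != vals.shape or times.ndim != 1:
            raise InvalidInputError("times and values must be matching 1-D arrays")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", vals)

    @property
    def nt(self) -> int:
        return self.times.size

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.values)

    @property
    def phase(self) -> np.ndarray:
        """Principal-value phase in (-pi, pi]."""
        return np.angle(self.values)

    @property
    def phase_unwrapped(self) -> np.ndarray:
        return np.unwrap(np.angle(self.values))


@dataclass(frozen=True)
class SyntheticModel:
    """Asymmetric-Gaussian single-resonance return-loss model.

    ``amplitude * exp(-(f - f_true)^2 / (2 sigma^2)) + offset`` with
    ``sigma = sigma_left`` below the peak and ``sigma_right`` above it;
    continuous at ``f_true`` with peak value ``amplitude + offset``.
    """

    f_true: float
    amplitude: float = 18.0
    offset: float = 2.0
    sigma_left: float = 0.07e9
    sigma_right: float = 0.10e9
    band: tuple[float, float] = (2.0e9, 3.0e9)

    def __post_init__(self):
        fmin, fmax = self.band
        if not fmin < self.f_true < fmax:
            raise InvalidInputError(
                f"f_true={self.f_true} must lie strictly inside the band "
                f"({fmin}, {fmax})"
            )
        if self.sigma_left <= 0 or self.sigma_right <= 0:
            raise InvalidInputError("sigma_left and sigma_right must be positive")
        if self.amplitude <= 0:
            raise InvalidInputError("amplitude must be positive")

    def __call__(self, f: np.ndarray) -> np.ndarray:
        """Evaluate the model at frequencies ``f`` (Hz)."""
        f = np.asarray(f, dtype=float)
        sigma = np.where(f <= self.f_true, self.sigma_left, self.sigma_right)
        return self.amplitude * np.exp(
            -((f - self.f_true) ** 2) / (2.0 * sigma**2)
        ) + self.offset


@dataclass(frozen=True)
class NoiseModel:
    """Additive i.i.d. Gaussian perturbation (in dB) per acquisition sweep."""

    sigma_noise: float = 0.0
    m: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.sigma_noise < 0:
            raise InvalidInputError("sigma_noise must be non-negative")
        if self.m < 1:
            raise InvalidInputError("m must be at least 1")


def rl_from_gamma(gamma_magnitude: np.ndarray, frequencies: np.ndarray) -> ReturnLossTrace:
    """Return loss from reflection-coefficient magnitude: RL = -20 log10|Γ|.

    ``|Γ| = 1`` maps to 0 dB.  Magnitudes must lie in (0, 1]; a
    non-positive or >1 entry raises naming the offending index.
    """
    gamma = np.asarray(gamma_magnitude, dtype=float)
    bad = np.nonzero(gamma <= 0)[0]
    if bad.size:
        raise InvalidInputError(
            f"reflection magnitude must be positive; first offending index {bad[0]} "
            f"(value {gamma[bad[0]]!r})"
        )
    above = np.nonzero(gamma > 1.0)[0]
    if above.size:
        raise InvalidInputError(
            f"reflection magnitude must be <= 1; first offending index {above[0]} "
            f"(value {gamma[above[0]]!r}); clamp before conversion if this is "
            "calibration noise"
        )
    return ReturnLossTrace(frequencies=frequencies, values=-20.0 * np.log10(gamma))


def synth_return_loss(model: SyntheticModel, nf: int) -> ReturnLossTrace:
    """Sample the synthetic model on a uniform ``nf``-point grid over its band."""
    if nf < 3:
        raise InvalidInputError("nf must be at least 3")
    freqs = np.linspace(model.band[0], model.band[1], int(nf))
    return ReturnLossTrace(frequencies=freqs, values=model(freqs))


def simulate_acquisitions(trace: ReturnLossTrace, noise: NoiseModel) -> list[ReturnLossTrace]:
    """Simulate ``noise.m`` instrument sweeps of ``trace``.

    Each sweep adds independent zero-mean Gaussian perturbations of
    standard deviation ``noise.sigma_noise`` (dB) per sample.  Seeded and
    reproducible: the same :class:`NoiseModel` always yields bit-identical
    sweeps.
    """
    rng = np.random.default_rng(noise.seed)
    sweeps = []
    for _ in range(noise.m):
        perturbation = (
            rng.normal(0.0, noise.sigma_noise, size=trace.nf)
            if noise.sigma_noise > 0
            else np.zeros(trace.nf)
        )
        sweeps.append(
            ReturnLossTrace(
                frequencies=trace.frequencies, values=trace.values + perturbation
            )
        )
    return sweeps
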