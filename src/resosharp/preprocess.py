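"""Shared preprocessing chain for the sharpening algorithms.

The chain turns a raw return-loss trace into the time-domain signal whose
phase encodes the resonance position:

1. average repeated acquisitions (:func:`average_traces`);
2. flatten the curve left of the peak at the right-endpoint level and
   subtract that level so both band edges sit exactly at 0 dB
   (:func:`flatten_and_debias`);
3. locate the frequency band where the normalised debiased curve exceeds
   ``alpha`` (:func:`alpha_band`);
4. inverse discrete-time Fourier transform onto a symmetric time window
   (:func:`idtft`), with phase unwrapping (:func:`unwrap_phase`);
5. locate the time support where the normalised transform magnitude
   exceeds ``beta`` (:func:`beta_support`).

All threshold crossings are resolved to grid samples walking outward from
the relevant peak — no interpolation — so every step is deterministic and
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dtft import dtft_uniform
from .errors import (
    DegenerateSignalError,
    EndpointOrderError,
    IncompatibleTracesError,
    InvalidInputError,
)
from .signalmodel import ReturnLossTrace, TimeSignal

__all__ = [
    "AlphaBand",
    "BetaSupport",
    "average_traces",
    "flatten_and_debias",
    "alpha_band",
    "idtft",
    "unwrap_phase",
    "beta_support",
]


@dataclass(frozen=True)
class AlphaBand:
    """Frequency interval where the normalised debiased curve exceeds alpha."""

    f_tilde_min: float
    f_tilde_max: float
    alpha: float
    i_lo: int
    i_hi: int

    @property
    def width(self) -> float:
        return self.f_tilde_max - self.f_tilde_min


@dataclass(frozen=True)
class BetaSupport:
    """Time interval where the normalised |rl(t)| exceeds beta.

    ``covers_window`` is True when the normalised magnitude never drops
    to ``beta`` anywhere in the time window — the iterative algorithm's
    stopping condition.
    """

    t_tilde_min: float
    t_tilde_max: float
    beta: float
    n_tilde_t: int
    i_lo: int
    i_hi: int
    covers_window: bool = False


def average_traces(traces: list[ReturnLossTrace]) -> ReturnLossTrace:
    """Pointwise arithmetic mean of traces sharing one frequency grid."""
    if not traces:
        raise InvalidInputError("need at least one trace to average")
    ref = traces[0]
    for k, tr in enumerate(traces[1:], start=1):
        if tr.nf != ref.nf or not np.array_equal(tr.frequencies, ref.frequencies):
            raise IncompatibleTracesError(
                f"trace {k} has a different frequency grid from trace 0"
            )
    mean_vals = np.mean([tr.values for tr in traces], axis=0)
    return ReturnLossTrace(frequencies=ref.frequencies, values=mean_vals)


def _peak_index(values: np.ndarray) -> int:
    # np.argmax returns the lowest index on ties, which is the convention.
    return int(np.argmax(values))


def flatten_and_debias(trace: ReturnLossTrace) -> ReturnLossTrace:
    """Flatten the curve left of the peak and remove the endpoint level.

    Walks left from the peak to the sample nearest the level RL(fMAX),
    replaces everything at or left of it with that level, then subtracts
    the level.  The result is >= 0 with value exactly 0 at both band
    endpoints.

    Raises
    ------
    EndpointOrderError
        If RL(fmin) > RL(fMAX); mirror the trace first (``estimate``
        handles this automatically).
    """
    vals = trace.values
    level = float(vals[-1])
    if vals[0] > level:
        raise EndpointOrderError(
            "RL(fmin) > RL(fMAX): frequency-mirror the trace, process it, "
            "and un-mirror the estimate"
        )
    peak = _peak_index(vals)
    if peak == 0:
        raise DegenerateSignalError("peak sits at the left band edge")
    # First sample at or below the endpoint level, walking left from the peak.
    below = np.nonzero(vals[:peak] <= level)[0]
    if below.size == 0:
        # RL(fmin) == level exactly and noise keeps everything above it.
        i_cross = 0
    else:
        i_cross = int(below[-1])
        # Nearest-sample resolution: the crossing lies between i_cross and
        # i_cross + 1; keep whichever value is closer to the level.
        if i_cross + 1 < peak and abs(vals[i_cross + 1] - level) < abs(
            vals[i_cross] - level
        ):
            i_cross += 1
    new_vals = vals.astype(float).copy()
    # The grid sample only approximately sits at the level, so the plateau
    # is pinned to the level itself: after the subtraction both endpoints
    # are exactly 0 and the curve never goes negative there.
    new_vals[: i_cross + 1] = level
    new_vals -= level
    return ReturnLossTrace(frequencies=trace.frequencies, values=new_vals)


def alpha_band(trace_bar: ReturnLossTrace, alpha: float) -> AlphaBand:
    """Band edges where the normalised debiased curve falls to ``alpha``.

    Each edge is the outermost grid sample (walking outward from the
    peak) whose normalised value is still >= ``alpha``; if the sample
    just beside the peak is already below, the edge collapses onto it so
    the band always contains at least three samples.
    """
    if not 0.0 < alpha < 1.0:
        raise InvalidInputError("alpha must lie in (0, 1)")
    vals = trace_bar.values
    peak = _peak_index(vals)
    vmax = vals[peak]
    if vmax <= 0:
        raise DegenerateSignalError("debiased curve has no positive peak")
    if peak == 0 or peak == vals.size - 1:
        raise DegenerateSignalError("peak sits on a band edge after debias")
    norm = vals / vmax

    i_lo = peak
    while i_lo > 0 and norm[i_lo - 1] >= alpha:
        i_lo -= 1
    i_hi = peak
    while i_hi < norm.size - 1 and norm[i_hi + 1] >= alpha:
        i_hi += 1
    # alpha close to 1 collapses the band to the peak's neighbours.
    if i_lo == peak:
        i_lo = peak - 1
    if i_hi == peak:
        i_hi = peak + 1
    return AlphaBand(
        f_tilde_min=float(trace_bar.frequencies[i_lo]),
        f_tilde_max=float(trace_bar.frequencies[i_hi]),
        alpha=float(alpha),
        i_lo=i_lo,
        i_hi=i_hi,
    )


def idtft(trace_bar: ReturnLossTrace, nt: int) -> TimeSignal:
    """Inverse discrete-time Fourier transform of |RL̄(f)| onto the time window.

    Evaluates ``rl(t_k) = Δf · Σ_n |RL̄(f_n)| exp(+j 2π t_k f_n)`` at
    ``nt`` uniform times on the closed window ``[-0.5/Δf, +0.5/Δf]``.
    The number of time samples is independent of the frequency grid: an
    explicit DTFT sum is used instead of an FFT, so the two grids are
    fully decoupled.
    """
    if nt < 8:
        raise InvalidInputError("nt must be at least 8")
    if not trace_bar.uniform:
        raise InvalidInputError("idtft requires a uniformly sampled trace")
    df = trace_bar.step
    tmax = 0.5 / df
    times = np.linspace(-tmax, tmax, int(nt))
    absvals = np.abs(trace_bar.values)
    values = df * dtft_uniform(
        absvals,
        in_start=trace_bar.band[0],
        in_step=df,
        out_start=times[0],
        out_step=times[1] - times[0],
        n_out=int(nt),
        sign=+1,
    )
    return TimeSignal(times=times, values=values)


def unwrap_phase(signal: TimeSignal) -> TimeSignal:
    """Expose the unwrapped phase of ``signal``.

    The returned signal's ``phase_unwrapped`` differs from the principal
    phase by integer multiples of 2π per sample and has no adjacent jump
    of π or more.  (``TimeSignal`` computes the unwrapped phase lazily;
    this operation exists as the named preprocessing step.)
    """
    return TimeSignal(times=signal.times, values=signal.values)


def beta_support(signal: TimeSignal, beta: float) -> BetaSupport:
    """Time support where the normalised |rl(t)| exceeds ``beta``.

    Walking outward from the magnitude peak, each support edge is the
    first sample whose normalised magnitude drops to <= ``beta``; a side
    that never drops extends to the window edge.  When neither side
    drops anywhere the support covers the whole window
    (``covers_window=True``), which is the iterative algorithm's
    stopping condition.
    """
    if not 0.0 < beta < 1.0:
        raise InvalidInputError("beta must lie in (0, 1)")
    mag = signal.magnitude
    mmax = mag.max()
    if mmax == 0.0:
        raise DegenerateSignalError("signal magnitude is identically zero")
    norm = mag / mmax
    peak = _peak_index(mag)

    i_lo = peak
    while i_lo > 0 and norm[i_lo - 1] > beta:
        i_lo -= 1
    if i_lo > 0:
        i_lo -= 1  # first sample at or below beta
    i_hi = peak
    while i_hi < norm.size - 1 and norm[i_hi + 1] > beta:
        i_hi += 1
    if i_hi < norm.size - 1:
        i_hi += 1

    n_tilde = i_hi - i_lo + 1
    if n_tilde < 2:
        raise DegenerateSignalError("beta support degenerated to a single sample")
    return BetaSupport(
        t_tilde_min=float(signal.times[i_lo]),
        t_tilde_max=float(signal.times[i_hi]),
        beta=float(beta),
        n_tilde_t=n_tilde,
        i_lo=i_lo,
        i_hi=i_hi,
        covers_window=bool(np.all(norm >= beta)),
    )
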