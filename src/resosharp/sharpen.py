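"""The three resonance-frequency estimators.

All three start from the same preprocessed time signal and its beta
support, then diverge:

- **single_step** — one discrete-time Fourier transform of the
  unit-modulus phase term ``exp(jφ(t))`` over the beta support, sampled
  densely on the alpha band; the peak of its magnitude is the estimate.
- **iterative** — alternates that transform with an inverse transform of
  its square back to the time window, re-deriving the beta support each
  pass, until the normalised time-domain magnitude stays above beta over
  the whole window (or a pass cap is hit); the final estimate comes from
  one last forward transform.
- **music** — builds the rank-1 correlation matrix of the unit-modulus
  phase vector on the beta support, eigendecomposes it, and scans the
  MUSIC pseudospectrum (steering-vector projection onto the noise
  subspace) over the alpha band.

Traces whose left band edge sits above the right one are frequency-
mirrored before processing and the estimate is mirrored back, so callers
never need to care about the orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .dtft import dtft_uniform
from .errors import ConfigurationError, DegenerateSupportError, InvalidInputError
from .preprocess import (
    AlphaBand,
    BetaSupport,
    alpha_band,
    beta_support,
    flatten_and_debias,
    idtft,
)
from .signalmodel import ReturnLossTrace, TimeSignal

__all__ = [
    "ALGORITHMS",
    "SharpenParams",
    "EstimationResult",
    "MusicDecomposition",
    "sharpen_single_step",
    "sharpen_iterative",
    "music_correlation",
    "music_pseudospectrum",
    "estimate",
]

ALGORITHMS = ("single_step", "iterative", "music")

#: Denominator floor for the MUSIC pseudospectrum, relative to the
#: numerator; grid points below it are clamped (peak location unaffected).
_MUSIC_DEN_FLOOR = np.finfo(float).eps


@dataclass(frozen=True)
class SharpenParams:
    """The quintuple (alpha, beta, Nt, N̂f) plus algorithm selection."""

    alpha: float = 0.1
    beta: float = 0.05
    nt: int = 512
    n_hat_f: int = 512
    max_iterations: int = 50
    algorithm: str = "single_step"

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise InvalidInputError("alpha must lie in (0, 1)")
        if not 0.0 < self.beta < 1.0:
            raise InvalidInputError("beta must lie in (0, 1)")
        if self.nt < 8:
            raise InvalidInputError("nt must be at least 8")
        if self.n_hat_f < 8:
            raise InvalidInputError("n_hat_f must be at least 8")
        if self.max_iterations < 1:
            raise InvalidInputError("max_iterations must be at least 1")
        if self.algorithm not in ALGORITHMS:
            raise ConfigurationError(
                f"unknown algorithm {self.algorithm!r}; expected one of {ALGORITHMS}"
            )


@dataclass(frozen=True)
class EstimationResult:
    """Estimate plus the sharpened curve and per-algorithm diagnostics.

    ``final_curve`` holds RL̂(f) for the Fourier algorithms and the
    pseudospectrum P(f) for MUSIC, sampled at ``frequencies`` (uniform,
    ``n_hat_f`` points spanning the alpha band).
    """

    f_est: float
    frequencies: np.ndarray
    final_curve: np.ndarray
    iterations_used: int
    alpha_band: AlphaBand
    beta_support: BetaSupport
    delta_hat_f: float
    algorithm: str
    converged: bool = True
    mirrored: bool = False
    clamped_points: int = 0


@dataclass(frozen=True)
class MusicDecomposition:
    """Rank-1 correlation matrix of the phase vector and its eigenstructure.

    ``eigenvalues`` are sorted descending; the single nonzero one equals
    the number of support samples.  ``noise_subspace`` stacks the
    eigenvectors of the remaining (zero) eigenvalues as columns.
    """

    correlation: np.ndarray
    eigenvalues: np.ndarray
    signal_vector: np.ndarray
    noise_subspace: np.ndarray
    times: np.ndarray
    delta_t: float


# ---------------------------------------------------------------------------
# shared pipeline


@dataclass(frozen=True)
class _Preprocessed:
    trace_bar: ReturnLossTrace
    band: AlphaBand
    signal: TimeSignal
    support: BetaSupport
    mirrored: bool
    orig_band: tuple[float, float]


def _preprocess(trace: ReturnLossTrace, params: SharpenParams) -> _Preprocessed:
    mirrored = bool(trace.values[0] > trace.values[-1])
    work = trace.mirrored() if mirrored else trace
    bar = flatten_and_debias(work)
    band = alpha_band(bar, params.alpha)
    signal = idtft(bar, params.nt)
    support = beta_support(signal, params.beta)
    return _Preprocessed(
        trace_bar=bar,
        band=band,
        signal=signal,
        support=support,
        mirrored=mirrored,
        orig_band=trace.band,
    )


def _phase_dtft(
    signal: TimeSignal, support: BetaSupport, f_grid: np.ndarray
) -> np.ndarray:
    """|DTFT of exp(jφ(t)) over the support samples|, evaluated on f_grid."""
    if support.n_tilde_t < 2:
        raise DegenerateSupportError("beta support has fewer than two samples")
    t = signal.times[support.i_lo : support.i_hi + 1]
    u = np.exp(1j * np.angle(signal.values[support.i_lo : support.i_hi + 1]))
    dt = t[1] - t[0]
    spectrum = dtft_uniform(
        u,
        in_start=t[0],
        in_step=dt,
        out_start=f_grid[0],
        out_step=(f_grid[-1] - f_grid[0]) / (f_grid.size - 1),
        n_out=f_grid.size,
        sign=-1,
    )
    return np.abs(dt * spectrum)


def _f_grid(band: AlphaBand, n_hat_f: int) -> np.ndarray:
    return np.linspace(band.f_tilde_min, band.f_tilde_max, int(n_hat_f))


def _finalize(
    pre: _Preprocessed,
    f_grid: np.ndarray,
    curve: np.ndarray,
    support: BetaSupport,
    params: SharpenParams,
    iterations: int,
    converged: bool = True,
    clamped: int = 0,
) -> EstimationResult:
    i_max = int(np.argmax(curve))  # lowest index on ties
    f_est = float(f_grid[i_max])
    band = pre.band
    if pre.mirrored:
        fmin, fmax = pre.orig_band
        f_est = fmin + fmax - f_est
        f_grid = (fmin + fmax) - f_grid[::-1]
        curve = curve[::-1].copy()
        band = replace(
            band,
            f_tilde_min=fmin + fmax - pre.band.f_tilde_max,
            f_tilde_max=fmin + fmax - pre.band.f_tilde_min,
        )
    return EstimationResult(
        f_est=f_est,
        frequencies=f_grid,
        final_curve=curve,
        iterations_used=iterations,
        alpha_band=band,
        beta_support=support,
        delta_hat_f=float((f_grid[-1] - f_grid[0]) / (f_grid.size - 1)),
        algorithm=params.algorithm,
        converged=converged,
        mirrored=pre.mirrored,
        clamped_points=clamped,
    )


# ---------------------------------------------------------------------------
# single-step


def sharpen_single_step(
    trace: ReturnLossTrace, params: SharpenParams
) -> EstimationResult:
    """One Fourier-pair pass: sharpened curve and its peak frequency."""
    params = replace(params, algorithm="single_step")
    pre = _preprocess(trace, params)
    f_grid = _f_grid(pre.band, params.n_hat_f)
    curve = _phase_dtft(pre.signal, pre.support, f_grid)
    return _finalize(pre, f_grid, curve, pre.support, params, iterations=1)


# ---------------------------------------------------------------------------
# iterative


def sharpen_iterative(
    trace: ReturnLossTrace, params: SharpenParams
) -> EstimationResult:
    """Iterated Fourier pairs until the time magnitude flattens above beta.

    Each pass transforms the current phase term over the current beta
    support onto the alpha band, squares the result, and inverse
    transforms it back onto the full time window.  Passes repeat while
    the normalised time magnitude dips below beta anywhere; the final
    curve is one forward transform of the terminal signal's phase.  If
    ``max_iterations`` passes do not converge the result is returned with
    ``converged=False`` rather than raising.
    """
    params = replace(params, algorithm="iterative")
    pre = _preprocess(trace, params)
    f_grid = _f_grid(pre.band, params.n_hat_f)
    d_hat_f = (f_grid[-1] - f_grid[0]) / (f_grid.size - 1)
    times = pre.signal.times

    signal = pre.signal
    norm = signal.magnitude / signal.magnitude.max()
    converged = bool(np.all(norm >= params.beta))
    iterations = 0
    dt_step = times[1] - times[0]

    while not converged and iterations < params.max_iterations:
        support = beta_support(signal, params.beta)
        rl_hat = _phase_dtft(signal, support, f_grid)
        values = d_hat_f * dtft_uniform(
            rl_hat**2,
            in_start=f_grid[0],
            in_step=d_hat_f,
            out_start=times[0],
            out_step=dt_step,
            n_out=times.size,
            sign=+1,
        )
        signal = TimeSignal(times=times, values=values)
        iterations += 1
        mag = signal.magnitude
        converged = bool(np.all(mag >= params.beta * mag.max()))

    final_support = beta_support(signal, params.beta)
    curve = _phase_dtft(signal, final_support, f_grid)
    return _finalize(
        pre, f_grid, curve, final_support, params, iterations, converged=converged
    )


# ---------------------------------------------------------------------------
# MUSIC


def music_correlation(
    signal: TimeSignal, support: BetaSupport
) -> MusicDecomposition:
    """Rank-1 correlation of the unit-modulus phase vector on the support.

    The correlation matrix is the outer product of ``exp(jφ(t))`` on the
    support samples with its conjugate transpose; a Hermitian
    eigendecomposition (eigenvalues descending) splits it into a
    one-dimensional signal subspace and its orthogonal complement, the
    noise subspace.  No decorrelation step is needed: there is a single
    spectral line.
    """
    if support.n_tilde_t < 2:
        raise DegenerateSupportError("beta support has fewer than two samples")
    t = signal.times[support.i_lo : support.i_hi + 1]
    rl_tilde = np.exp(1j * np.angle(signal.values[support.i_lo : support.i_hi + 1]))
    correlation = np.outer(rl_tilde, rl_tilde.conj())
    eigvals, eigvecs = np.linalg.eigh(correlation)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    return MusicDecomposition(
        correlation=correlation,
        eigenvalues=eigvals,
        signal_vector=eigvecs[:, 0],
        noise_subspace=eigvecs[:, 1:],
        times=t,
        delta_t=float(t[1] - t[0]),
    )


def music_pseudospectrum(
    decomp: MusicDecomposition,
    band: AlphaBand,
    n_hat_f: int,
) -> tuple[np.ndarray, np.ndarray, int]:
    """MUSIC pseudospectrum P(f) on the alpha band.

    ``P(f) = (aᴴa) / (aᴴ Ṽ Ṽᴴ a)`` with the steering vector
    ``a(f) = exp(j 2π f t_k)`` on the support time grid.  Because the
    eigenbasis is orthonormal, ``Ṽ Ṽᴴ = I − v₁v₁ᴴ`` exactly, so the
    denominator is evaluated as ``aᴴa − |v₁ᴴ a|²`` — algebraically
    identical to the noise-subspace projection and linear rather than
    quadratic in the support length.  Denominators below a machine floor
    are clamped (the peak location is unaffected) and counted.

    Returns ``(f_grid, pseudospectrum, n_clamped)``.
    """
    f_grid = _f_grid(band, n_hat_f)
    n_tilde = decomp.times.size
    numerator = float(n_tilde)  # aᴴa: unit-modulus entries
    # v₁ᴴ a(f) is itself a DTFT of conj(v₁) over the support time grid.
    proj = dtft_uniform(
        decomp.signal_vector.conj(),
        in_start=float(decomp.times[0]),
        in_step=decomp.delta_t,
        out_start=float(f_grid[0]),
        out_step=(f_grid[-1] - f_grid[0]) / (f_grid.size - 1),
        n_out=f_grid.size,
        sign=+1,
    )
    signal_proj = np.abs(proj) ** 2
    denominator = numerator - signal_proj
    floor = numerator * _MUSIC_DEN_FLOOR
    clamped = int(np.count_nonzero(denominator < floor))
    pseudo = numerator / np.maximum(denominator, floor)
    return f_grid, pseudo, clamped


def sharpen_music(trace: ReturnLossTrace, params: SharpenParams) -> EstimationResult:
    """MUSIC pseudospectrum estimate over the alpha band."""
    params = replace(params, algorithm="music")
    pre = _preprocess(trace, params)
    decomp = music_correlation(pre.signal, pre.support)
    f_grid, pseudo, clamped = music_pseudospectrum(decomp, pre.band, params.n_hat_f)
    return _finalize(
        pre, f_grid, pseudo, pre.support, params, iterations=1, clamped=clamped
    )


# ---------------------------------------------------------------------------
# front door


_DISPATCH = {
    "single_step": sharpen_single_step,
    "iterative": sharpen_iterative,
    "music": sharpen_music,
}


def estimate(trace: ReturnLossTrace, params: SharpenParams) -> EstimationResult:
    """Run the selected algorithm on a raw trace.

    Performs the shared preprocessing and dispatches on
    ``params.algorithm``; deterministic — two calls with the same inputs
    return bit-identical results.
    """
    try:
        fn = _DISPATCH[params.algorithm]
    except KeyError:
        raise ConfigurationError(
            f"unknown algorithm {params.algorithm!r}; expected one of {ALGORITHMS}"
        ) from None
    return fn(trace, params)
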