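"""Monte Carlo benchmarking of the estimators.

The benchmark draws random parameter quintuples (alpha, beta, Nf, Nt,
N̂f) plus a random true resonance frequency, synthesizes a return-loss
curve per draw, runs the selected estimators on it, and accumulates the
percentage error of each estimate.  A blind variant runs the same sweep
on a single fixed trace (measured or synthetic) and characterises the
dispersion of the estimated frequency instead.

Conventions (stated so the acceptance checks are well-posed):

- the reported percentage error is the absolute value; the signed value
  is retained per repetition;
- continuous parameters are uniform on their interval, integer ones
  uniform over the inclusive integer interval;
- percentiles use linear interpolation between closest order statistics
  (numpy's default);
- one random stream per report, advanced in the fixed per-rep order
  (f_true, alpha, beta, Nf, Nt, N̂f) whether or not a parameter is
  pinned, so pinning never shifts the other draws;
- the same draws feed every selected algorithm (paired comparison);
- repetitions that fail with a degenerate-support/signal error are
  recorded and excluded from the statistics, never silently dropped.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidInputError, ResosharpError
from .sharpen import ALGORITHMS, SharpenParams, estimate
from .signalmodel import ReturnLossTrace, SyntheticModel, synth_return_loss

__all__ = [
    "DEFAULT_RANGES",
    "MonteCarloConfig",
    "MonteCarloReport",
    "EmpiricalCDF",
    "percentage_error",
    "signed_percentage_error",
    "run_monte_carlo",
    "blind_characterize",
    "empirical_cdf",
]

#: Parameter ranges of the benchmark protocol (frequencies in Hz).
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "f_true": (2.25e9, 2.75e9),
    "alpha": (0.1, 0.9),
    "beta": (0.05, 0.45),
    "nf": (100, 900),
    "nt": (512, 4608),
    "n_hat_f": (512, 4608),
}

_INT_PARAMS = ("nf", "nt", "n_hat_f")
_DRAW_ORDER = ("f_true", "alpha", "beta", "nf", "nt", "n_hat_f")


def percentage_error(f_true: float, f_est: float) -> float:
    """|f_true - f_est| / f_true × 100."""
    return abs(signed_percentage_error(f_true, f_est))


def signed_percentage_error(f_true: float, f_est: float) -> float:
    """(f_true - f_est) / f_true × 100 — sign retained."""
    if f_true <= 0:
        raise InvalidInputError("f_true must be positive")
    return (f_true - f_est) / f_true * 100.0


class EmpiricalCDF:
    """Right-continuous empirical CDF of a finite sample.

    Percentiles use linear interpolation between closest order
    statistics.
    """

    def __init__(self, samples):
        samples = np.asarray(samples, dtype=float)
        if samples.size == 0 or not np.all(np.isfinite(samples)):
            raise InvalidInputError("need at least one finite sample")
        self.samples = np.sort(samples)

    @property
    def n(self) -> int:
        return self.samples.size

    def __call__(self, x) -> np.ndarray | float:
        x = np.asarray(x, dtype=float)
        out = np.searchsorted(self.samples, x, side="right") / self.n
        return float(out) if out.ndim == 0 else out

    def percentile(self, q: float) -> float:
        return float(np.percentile(self.samples, q))


def empirical_cdf(samples) -> EmpiricalCDF:
    """Build the empirical CDF of ``samples`` (percent or Hz)."""
    return EmpiricalCDF(samples)


@dataclass(frozen=True)
class MonteCarloConfig:
    """Configuration of one Monte Carlo benchmark.

    ``fixed`` pins any of the parameters (by the keys of ``ranges``) to a
    constant; the underlying draws still advance so results stay paired
    with the unpinned experiment.
    """

    n_reps: int = 500
    ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RANGES)
    )
    fixed: dict[str, float] = field(default_factory=dict)
    seed: int = 0
    algorithms: tuple[str, ...] = ALGORITHMS
    max_iterations: int = 50

    def __post_init__(self):
        if self.n_reps < 1:
            raise InvalidInputError("n_reps must be at least 1")
        ranges = dict(DEFAULT_RANGES)
        ranges.update(self.ranges)
        for name, (lo, hi) in ranges.items():
            if lo > hi:
                raise InvalidInputError(f"range for {name!r} has low > high")
        object.__setattr__(self, "ranges", ranges)
        unknown = set(self.fixed) - set(ranges)
        if unknown:
            raise InvalidInputError(f"fixed refers to unknown parameters {unknown}")
        for alg in self.algorithms:
            if alg not in ALGORITHMS:
                raise InvalidInputError(f"unknown algorithm {alg!r}")


@dataclass(frozen=True)
class MonteCarloReport:
    """Per-repetition records plus per-algorithm summary statistics.

    ``records`` holds one row per (repetition, algorithm) with the drawn
    parameters, the estimate, the signed and absolute percentage errors
    (NaN in blind mode), iteration counts and failure markers.
    """

    records: pd.DataFrame
    config: MonteCarloConfig
    blind: bool = False

    @property
    def metric(self) -> str:
        return "f_est" if self.blind else "pe"

    def values(self, algorithm: str) -> np.ndarray:
        """Successful-rep metric values (PE in %, or f_est in Hz when blind)."""
        rows = self.records[
            (self.records["algorithm"] == algorithm) & (~self.records["failed"])
        ]
        return rows[self.metric].to_numpy(dtype=float)

    def cdf(self, algorithm: str) -> EmpiricalCDF:
        return empirical_cdf(self.values(algorithm))

    def summary(self) -> dict[str, dict[str, float]]:
        out: dict[str, dict[str, float]] = {}
        for alg in self.config.algorithms:
            rows = self.records[self.records["algorithm"] == alg]
            vals = self.values(alg)
            stats: dict[str, float] = {
                "n_attempted": int(len(rows)),
                "n_succeeded": int(vals.size),
                "n_failed": int(rows["failed"].sum()),
            }
            if vals.size:
                stats.update(
                    mean=float(np.mean(vals)),
                    std=float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0,
                    median=float(np.median(vals)),
                    p5=float(np.percentile(vals, 5)),
                    p95=float(np.percentile(vals, 95)),
                    max=float(np.max(vals)),
                )
            out[alg] = stats
        return out

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    def summary_json(self, path) -> None:
        payload = {
            "blind": self.blind,
            "metric": self.metric,
            "seed": self.config.seed,
            "n_reps": self.config.n_reps,
            "fixed": dict(self.config.fixed),
            "summary": self.summary(),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _draw(rng: np.random.Generator, config: MonteCarloConfig) -> dict[str, float]:
    draws: dict[str, float] = {}
    for name in _DRAW_ORDER:
        lo, hi = config.ranges[name]
        if name in _INT_PARAMS:
            value = int(rng.integers(int(lo), int(hi) + 1))
        else:
            value = float(rng.uniform(lo, hi))
        draws[name] = value
    for name, value in config.fixed.items():
        draws[name] = int(value) if name in _INT_PARAMS else float(value)
    return draws


def _run_reps(
    config: MonteCarloConfig,
    trace_for,
    blind: bool,
) -> MonteCarloReport:
    rng = np.random.default_rng(config.seed)
    rows = []
    for rep in range(config.n_reps):
        draws = _draw(rng, config)
        try:
            trace, f_true = trace_for(draws)
        except ResosharpError as exc:  # synthesis failure hits every algorithm
            for alg in config.algorithms:
                rows.append(_failure_row(rep, alg, draws, exc))
            continue
        for alg in config.algorithms:
            params = SharpenParams(
                alpha=draws["alpha"],
                beta=draws["beta"],
                nt=int(draws["nt"]),
                n_hat_f=int(draws["n_hat_f"]),
                max_iterations=config.max_iterations,
                algorithm=alg,
            )
            try:
                result = estimate(trace, params)
            except ResosharpError as exc:
                rows.append(_failure_row(rep, alg, draws, exc))
                continue
            pe_signed = (
                signed_percentage_error(f_true, result.f_est)
                if f_true is not None
                else np.nan
            )
            rows.append(
                {
                    "rep": rep,
                    "algorithm": alg,
                    **draws,
                    "f_est": result.f_est,
                    "pe": abs(pe_signed),
                    "pe_signed": pe_signed,
                    "iterations": result.iterations_used,
                    "converged": result.converged,
                    "failed": False,
                    "error": "",
                }
            )
    records = pd.DataFrame(rows)
    return MonteCarloReport(records=records, config=config, blind=blind)


def _failure_row(rep, alg, draws, exc) -> dict:
    return {
        "rep": rep,
        "algorithm": alg,
        **draws,
        "f_est": np.nan,
        "pe": np.nan,
        "pe_signed": np.nan,
        "iterations": 0,
        "converged": False,
        "failed": True,
        "error": f"{type(exc).__name__}: {exc}",
    }


def run_monte_carlo(
    config: MonteCarloConfig, model_template: SyntheticModel
) -> MonteCarloReport:
    """Benchmark the estimators on random synthetic curves.

    ``model_template`` supplies the non-random curve constants (amplitude,
    offset, widths, band); each repetition re-centres it on the drawn
    ``f_true`` and samples it with the drawn ``Nf``.
    """

    def trace_for(draws):
        model = dataclasses.replace(model_template, f_true=draws["f_true"])
        return synth_return_loss(model, int(draws["nf"])), draws["f_true"]

    return _run_reps(config, trace_for, blind=False)


def blind_characterize(
    trace: ReturnLossTrace, config: MonteCarloConfig
) -> MonteCarloReport:
    """Dispersion of the estimate on one fixed trace, true frequency unknown.

    Runs the estimators on the same trace under random (alpha, Nt, N̂f)
    draws (pin beta and Nf through ``config.fixed`` to follow the
    benchmark protocol) and reports the statistics of ``f_est`` itself:
    mean, standard deviation, median, 5th and 95th percentiles per
    algorithm.
    """

    def trace_for(draws):
        return trace, None

    return _run_reps(config, trace_for, blind=True)
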