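"""Performance factors for capnometry signal quantification.

Six factors characterize how well (and how fast) the pipeline recovers a
blood capnia transition: per-phase settled means, relative performance (%),
RMSE after cross-correlation alignment, a global signal-to-noise ratio (dB),
the 10–90 % rise time, and cross-correlation delays for the direct path
(input → measurement cell), the inverse path (measurement → estimate) and
the global path (input → estimate).

Phase means follow a 90 % settling rule: the mean is taken only after the
signal has covered 90 % of the gap between its level at phase start and its
equilibrium level (estimated from the final tenth of the phase window).
Quantities that cannot be computed on a given window (settling never
reached, flat signal, thresholds not crossed) are flagged undefined and
returned as NaN with a warning.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Union

import numpy as np
from scipy.signal import correlate

__all__ = [
    "PhaseDefinition",
    "MetricsReport",
    "UndefinedMetricWarning",
    "UndefinedMetricError",
    "settled_phase_mean",
    "perf_rel",
    "aligned_rmse",
    "rsb_global",
    "rise_time",
    "delay_by_xcorr",
]


class UndefinedMetricWarning(UserWarning):
    """The metric is undefined on the given window; NaN returned."""


class UndefinedMetricError(ValueError):
    """The metric is mathematically undefined for these inputs."""


@dataclass(frozen=True)
class PhaseDefinition:
    """One capnia phase of a chronogram."""

    label: str
    start: float        # s
    duration: float     # s
    level: float        # nominal blood concentration, mol·m-3

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise UndefinedMetricError(f"phase {self.label!r}: duration must be > 0")

    @property
    def stop(self) -> float:
        return self.start + self.duration


@dataclass
class MetricsReport:
    """Aggregated performance factors for one scenario run."""

    mu: dict                 # per-phase settled means of the true input
    mu_hat: dict             # per-phase settled means of the estimate
    perf_rel_pct: dict       # per-phase relative performance, %
    rise_times_s: dict       # per-phase transition times (rise or fall)
    rmse_aligned: float      # mol·m-3
    rsb_global_db: float     # dB
    td_dir_s: float
    td_inv_s: float
    td_global_s: float
    provenance: dict | None = None

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, default=float))

    def to_csv_row(self) -> str:
        """Flat CSV row (scenario aggregation across noise levels / φ values)."""
        cells = []
        for d in (self.mu, self.mu_hat, self.perf_rel_pct, self.rise_times_s):
            cells.extend(f"{v:.6g}" for v in d.values())
        cells.extend(
            f"{v:.6g}"
            for v in (self.rmse_aligned, self.rsb_global_db,
                      self.td_dir_s, self.td_inv_s, self.td_global_s)
        )
        return ",".join(cells)


def _phase_window(times: np.ndarray, phase: PhaseDefinition) -> np.ndarray:
    mask = (times >= phase.start) & (times < phase.stop)
    if not mask.any():
        raise UndefinedMetricError(
            f"phase {phase.label!r} [{phase.start}, {phase.stop}) s "
            "lies outside the signal support"
        )
    return mask


def settled_phase_mean(
    times: np.ndarray,
    signal: np.ndarray,
    phase: PhaseDefinition,
    settle_fraction: float = 0.9,
    equilibrium: float | None = None,
) -> float:
    """Mean of ``signal`` over the settled part of a phase.

    The equilibrium level defaults to the mean of the final 10 % of the
    phase window (so short phases yield an under-estimated settled mean
    rather than an error); a nominal equilibrium may be supplied instead,
    in which case settling can genuinely fail.  Settling occurs when the
    distance covered from the phase-start level first reaches
    ``settle_fraction`` of the start-to-equilibrium gap; if it never does,
    the metric is flagged undefined and NaN is returned.
    """
    mask = _phase_window(times, phase)
    x = np.asarray(signal)[mask]
    initial = x[0]
    if equilibrium is None:
        n_tail = max(1, int(round(0.1 * len(x))))
        equilibrium = float(np.mean(x[-n_tail:]))
    gap = equilibrium - initial
    scale = max(abs(initial), abs(equilibrium), float(np.ptp(x)))
    if abs(gap) <= 1e-9 * max(scale, 1e-300):
        return float(np.mean(x))  # already settled at phase start
    covered = (x - initial) / gap
    settled = np.nonzero(covered >= settle_fraction)[0]
    if len(settled) == 0:
        warnings.warn(
            f"phase {phase.label!r}: {settle_fraction:.0%} settling never reached",
            UndefinedMetricWarning, stacklevel=2,
        )
        return float("nan")
    return float(np.mean(x[settled[0]:]))


def perf_rel(mu: float, mu_hat: float) -> float:
    """Relative performance 100·(μ − μ̂)/μ in %, signed."""
    if mu == 0.0:
        raise UndefinedMetricError("perf_rel undefined for zero reference mean")
    return 100.0 * (mu - mu_hat) / mu


def delay_by_xcorr(reference: np.ndarray, signal: np.ndarray, dt: float = 1.0) -> float:
    """Lag (s) maximizing the cross-correlation of mean-removed signals.

    Positive when ``signal`` lags ``reference``; always an integer multiple
    of δt.  td_dir = delay(input, observation), td_inv = delay(observation,
    estimate), td_global = delay(input, estimate).
    """
    r = np.asarray(reference, float)
    s = np.asarray(signal, float)
    if len(r) != len(s):
        raise UndefinedMetricError("signals must share the sampling grid")
    r = r - r.mean()
    s = s - s.mean()
    if not (r.any() and s.any()):
        warnings.warn("flat signal: cross-correlation delay undefined",
                      UndefinedMetricWarning, stacklevel=2)
        return float("nan")
    xc = correlate(s, r, mode="full")
    lag = int(np.argmax(xc)) - (len(r) - 1)
    return lag * dt


def aligned_rmse(truth: np.ndarray, estimate: np.ndarray, dt: float = 1.0) -> float:
    """RMSE after shifting ``estimate`` onto ``truth`` at the best xcorr lag.

    The error is taken over the overlapping support, which must cover at
    least half of the window.
    """
    t = np.asarray(truth, float)
    e = np.asarray(estimate, float)
    lag_s = delay_by_xcorr(t, e, dt)
    k = 0 if np.isnan(lag_s) else int(round(lag_s / dt))
    if k >= 0:
        t_ov, e_ov = t[: len(t) - k], e[k:]
    else:
        t_ov, e_ov = t[-k:], e[: len(e) + k]
    if len(t_ov) == 0:
        raise UndefinedMetricError("empty overlap after alignment")
    if len(t_ov) < 0.5 * len(t):
        raise UndefinedMetricError(
            f"aligned overlap {len(t_ov)}/{len(t)} is below half the window"
        )
    return float(np.sqrt(np.mean((t_ov - e_ov) ** 2)))


def rsb_global(truth: np.ndarray, rmse: float) -> float:
    """Global signal-to-noise ratio 20·log10(rms(truth)/rmse) in dB."""
    if rmse < 0:
        raise UndefinedMetricError("rmse must be non-negative")
    rms = float(np.sqrt(np.mean(np.asarray(truth, float) ** 2)))
    if rmse == 0.0:
        return float("inf")
    return 20.0 * np.log10(rms / rmse)


def rise_time(
    times: np.ndarray,
    signal: np.ndarray,
    level_before: float,
    level_after: float,
) -> float:
    """10–90 % transition time, with sub-sample linear interpolation.

    Fall transitions (level_after < level_before) are handled symmetrically;
    the returned duration is always the 10 %-to-90 % span of the monotone
    threshold crossings.  NaN (with a warning) if a threshold is never
    crossed.
    """
    t = np.asarray(times, float)
    x = np.asarray(signal, float)
    delta = level_after - level_before
    if delta == 0.0:
        warnings.warn("degenerate transition: levels equal", UndefinedMetricWarning,
                      stacklevel=2)
        return float("nan")
    # normalize so the transition always goes 0 -> 1
    z = (x - level_before) / delta

    def first_crossing(threshold: float, start: int) -> tuple[float, int] | None:
        idx = np.nonzero(z[start:] >= threshold)[0]
        if len(idx) == 0:
            return None
        j = start + int(idx[0])
        if j == 0 or z[j - 1] >= threshold:
            return t[j], j
        frac = (threshold - z[j - 1]) / (z[j] - z[j - 1])
        return t[j - 1] + frac * (t[j] - t[j - 1]), j

    c10 = first_crossing(0.1, 0)
    if c10 is None:
        warnings.warn("10% threshold never crossed", UndefinedMetricWarning,
                      stacklevel=2)
        return float("nan")
    c90 = first_crossing(0.9, c10[1])
    if c90 is None:
        warnings.warn("90% threshold never crossed", UndefinedMetricWarning,
                      stacklevel=2)
        return float("nan")
    return float(c90[0] - c10[0])
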