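"""Corridor + cross-correlation (CORA-style) signal biofidelity rating.

Rates the agreement of a simulation signal against an experimental
reference in [0, 1].  Two sub-instruments are combined:

* corridor rating — per-sample score 1 inside the inner corridor
  (half-width a0 * max|ref|), 0 outside the outer corridor (b0 * max|ref|),
  linear in between; averaged over samples.  Corridor widths are constant
  and derived from the reference peak.
* cross-correlation ratings — the test signal is shifted within
  +/- d_max * T (T = overlap window length) to maximize the Pearson
  correlation rho; shape = max(0, rho*), size is the ratio of squared-signal
  integrals min/max over the aligned window, and phase = 1 - |shift|/(d_max*T).

total = w_corridor * corridor + w_cross * (w_shape*shape + w_size*size
+ w_phase*phase); defaults 0.5/0.5 and 0.5/0.25/0.25.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import Signal

__all__ = [
    "CoraConfig",
    "CoraScore",
    "resample_common_grid",
    "corridor_rating",
    "cross_correlation_rating",
    "cora_score",
]


@dataclass(frozen=True)
class CoraConfig:
    a0: float = 0.05          # inner corridor half-width, fraction of peak
    b0: float = 0.5           # outer corridor half-width, fraction of peak
    d_max: float = 0.12       # max phase shift, fraction of the window
    w_corridor: float = 0.5
    w_cross: float = 0.5
    w_shape: float = 0.5
    w_size: float = 0.25
    w_phase: float = 0.25
    n_resample: int = 1000

    def __post_init__(self) -> None:
        if not 0 < self.a0 < self.b0:
            raise ValueError("corridor fractions must satisfy 0 < a0 < b0")
        if abs(self.w_corridor + self.w_cross - 1) > 1e-12:
            raise ValueError("corridor/cross weights must sum to 1")
        if abs(self.w_shape + self.w_size + self.w_phase - 1) > 1e-12:
            raise ValueError("shape/size/phase weights must sum to 1")
        if not 0 <= self.d_max < 1:
            raise ValueError("d_max must be in [0, 1)")


@dataclass(frozen=True)
class CoraScore:
    corridor: float
    shape: float
    size: float
    phase: float
    total: float

    def as_dict(self) -> dict[str, float]:
        return {"corridor": self.corridor, "shape": self.shape,
                "size": self.size, "phase": self.phase, "total": self.total}


def resample_common_grid(
    ref: Signal, test: Signal, n: int = 1000
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Linearly interpolate both signals onto n uniform points over their
    overlapping time window.  Returns (times, ref_values, test_values)."""
    t0 = max(ref.times[0], test.times[0])
    t1 = min(ref.times[-1], test.times[-1])
    if t1 <= t0:
        raise ValueError("signals have no overlapping time support")
    grid = np.linspace(t0, t1, n)
    return (grid,
            np.interp(grid, ref.times, ref.values),
            np.interp(grid, test.times, test.values))


def corridor_rating(ref: np.ndarray, test: np.ndarray,
                    a0: float = 0.05, b0: float = 0.5) -> float:
    """Mean per-sample corridor score on a paired uniform grid."""
    ref = np.asarray(ref, dtype=float)
    test = np.asarray(test, dtype=float)
    peak = np.abs(ref).max()
    if peak == 0:
        raise ValueError("all-zero reference: corridor undefined")
    inner, outer = a0 * peak, b0 * peak
    delta = np.abs(test - ref)
    score = np.clip((outer - delta) / (outer - inner), 0.0, 1.0)
    return float(score.mean())


def cross_correlation_rating(
    ref: np.ndarray, test: np.ndarray, d_max: float = 0.12,
    dt: float = 1.0,
) -> tuple[float, float, float]:
    """(shape, size, phase) sub-ratings on a paired uniform grid.

    The shift search runs on the sample grid over +/- d_max * T where
    T = (n - 1) * dt is the window length; ties in the correlation prefer
    the smaller absolute shift.
    """
    ref = np.asarray(ref, dtype=float)
    test = np.asarray(test, dtype=float)
    n = len(ref)
    T = (n - 1) * dt
    max_shift = int(round(d_max * (n - 1)))
    shifts = np.arange(-max_shift, max_shift + 1)
    if ref.std() == 0 or test.std() == 0:
        warnings.warn("zero-variance series: shape rating degenerate", UserWarning)
        ir, it = float((ref ** 2).sum() * dt), float((test ** 2).sum() * dt)
        size = 1.0 if max(ir, it) == 0 else min(ir, it) / max(ir, it)
        return 0.0, size, 1.0

    best_rho, best_shift = -np.inf, 0
    for m in shifts[np.argsort(np.abs(shifts), kind="stable")]:
        # positive m: test delayed by m samples relative to ref
        if m >= 0:
            r, s = ref[m:], test[: n - m]
        else:
            r, s = ref[:n + m], test[-m:]
        if len(r) < 2 or r.std() == 0 or s.std() == 0:
            continue
        rho = float(np.corrcoef(r, s)[0, 1])
        if rho > best_rho + 1e-15:
            best_rho, best_shift = rho, int(m)
    shape = max(0.0, best_rho)
    m = best_shift
    if m >= 0:
        r, s = ref[m:], test[: n - m]
    else:
        r, s = ref[:n + m], test[-m:]
    ir, it = float((r ** 2).sum() * dt), float((s ** 2).sum() * dt)
    size = 1.0 if max(ir, it) == 0 else min(ir, it) / max(ir, it)
    phase = 1.0 if d_max == 0 else float(np.clip(1.0 - abs(m) * dt / (d_max * T), 0.0, 1.0))
    return shape, size, phase


def cora_score(ref: Signal, test: Signal, config: CoraConfig | None = None) -> CoraScore:
    """Full rating of a test signal against a reference signal."""
    cfg = config or CoraConfig()
    grid, r, s = resample_common_grid(ref, test, cfg.n_resample)
    dt = grid[1] - grid[0]
    corridor = corridor_rating(r, s, cfg.a0, cfg.b0)
    shape, size, phase = cross_correlation_rating(r, s, cfg.d_max, dt)
    total = cfg.w_corridor * corridor + cfg.w_cross * (
        cfg.w_shape * shape + cfg.w_size * size + cfg.w_phase * phase
    )
    return CoraScore(corridor=corridor, shape=shape, size=size,
                     phase=phase, total=float(total))
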