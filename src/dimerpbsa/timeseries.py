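"""Energy time-series utilities: mean-centering, moving-average smoothing,
stage segmentation by joint MM/solvation extrema, and replica selection."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StageBoundaries",
    "normalize_series",
    "moving_average",
    "segment_stages",
    "select_replica",
]

_ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X"]


@dataclass(frozen=True)
class StageBoundaries:
    """Frame indices delimiting stages; the series start/end are implicit
    outer delimiters, so ``k`` boundaries yield ``k + 1`` stages."""

    boundaries: tuple[int, ...]
    n_frames: int
    stage_means: pd.DataFrame | None = None

    def __post_init__(self):
        b = self.boundaries
        if any(b[i] >= b[i + 1] for i in range(len(b) - 1)):
            raise ValueError("boundaries must be strictly increasing")
        if b and (b[0] <= 0 or b[-1] >= self.n_frames - 1):
            raise ValueError("boundaries must be interior to the series")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(_ROMAN[: len(self.boundaries) + 1])

    def stage_slices(self) -> list[slice]:
        edges = [0, *self.boundaries, self.n_frames]
        return [slice(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]


def normalize_series(x) -> np.ndarray:
    """Mean-center a series (the variance is untouched)."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("cannot normalize an empty series")
    return x - x.mean()


def moving_average(x, window: int) -> np.ndarray:
    """Centered moving average; edges use shrinking windows so the output
    has the same length as the input."""
    x = np.asarray(x, dtype=float)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if not 1 <= window <= x.size:
        raise ValueError("window must be between 1 and the series length")
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(x)])
    n = x.size
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, n - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def _smoothed_noise_scale(x: np.ndarray, window: int) -> float:
    """Residual noise sd of a boxcar-smoothed series.

    For a width-``window`` boxcar over white noise of sd sigma, successive
    outputs differ by sigma*sqrt(2)/window while the output level noise is
    sigma/sqrt(window); the ratio is sqrt(window/2).  The successive
    difference is estimated robustly (median absolute value / 0.6745) so
    slopes of genuine features, which occupy a minority of frames, drop out.
    """
    if x.size < 2:
        return 0.0
    sigma_diff = float(np.median(np.abs(np.diff(x)))) / 0.6745
    return sigma_diff * math.sqrt(window / 2.0)


def _local_extrema(
    x: np.ndarray, window: int, kind: str, min_prominence: float = 0.0
) -> list[int]:
    """Indices that are the extremum of their ±window neighborhood.

    Plateaus keep the earliest frame; the edge regions (< window from either
    end) are ignored so shrinking-window smoothing artefacts cannot register.
    An extremum only counts when it protrudes from its neighborhood's
    opposite extreme by at least ``min_prominence``.
    """
    n = x.size
    out = []
    for i in range(window, n - window):
        seg = x[i - window: i + window + 1]
        if kind == "min":
            if x[i] == seg.min() and x[i] < x[i - 1] \
                    and seg.max() - x[i] >= min_prominence:
                out.append(i)
        else:
            if x[i] == seg.max() and x[i] > x[i - 1] \
                    and x[i] - seg.min() >= min_prominence:
                out.append(i)
    return out


def segment_stages(
    de_mm,
    de_sol,
    window: int = 101,
    match_tol: int | None = None,
    components: pd.DataFrame | None = None,
    min_prominence: float | str | None = "auto",
) -> StageBoundaries:
    """Stage delimiters: frames where a local minimum of the (smoothed,
    centered) MM binding-energy series coincides — within ``match_tol``
    frames — with a local maximum of the solvation series.

    Both inputs are expected already normalized and smoothed; ``window``
    defines the ±neighborhood over which an extremum must dominate.
    ``min_prominence`` suppresses shallow noise extrema: an extremum must
    protrude from its neighborhood's opposite extreme by at least this much
    (same units as the series).  The default ``"auto"`` uses five times the
    residual noise scale of each smoothed series, estimated robustly from the
    median absolute successive difference (flat stretches dominate the
    median, so genuine wells do not inflate it) and scaled by sqrt(window/2),
    the boxcar relation between successive-difference and level noise.
    Noise wiggles protrude by ~3 noise scales, genuine stage wells by an
    order of magnitude more.  Pass ``None`` or ``0`` for unfiltered extrema,
    or an explicit value when the smoothing window differs strongly from
    ``window``.
    Per-stage means of any supplied ``components`` table are attached.
    """
    de_mm = np.asarray(de_mm, dtype=float)
    de_sol = np.asarray(de_sol, dtype=float)
    if de_mm.shape != de_sol.shape:
        raise ValueError("series must have equal length")
    n = de_mm.size
    if n < 2 * window:
        raise ValueError("series shorter than twice the extremum window")
    if match_tol is None:
        match_tol = window // 2
    if min_prominence is None:
        prom_mm = prom_sol = 0.0
    elif min_prominence == "auto":
        prom_mm = 5.0 * _smoothed_noise_scale(de_mm, window)
        prom_sol = 5.0 * _smoothed_noise_scale(de_sol, window)
    else:
        prom_mm = prom_sol = float(min_prominence)

    minima = _local_extrema(de_mm, window, "min", prom_mm)
    maxima = np.array(_local_extrema(de_sol, window, "max", prom_sol), dtype=int)
    boundaries = []
    for m in minima:
        if maxima.size and np.min(np.abs(maxima - m)) <= match_tol:
            boundaries.append(m)
    boundaries = sorted(set(boundaries))

    stage_means = None
    sb = StageBoundaries(boundaries=tuple(boundaries), n_frames=n)
    if components is not None:
        rows = {
            label: components.iloc[sl].mean()
            for label, sl in zip(sb.labels, sb.stage_slices())
        }
        stage_means = pd.DataFrame(rows).T
        sb = StageBoundaries(
            boundaries=tuple(boundaries), n_frames=n, stage_means=stage_means
        )
    return sb


def select_replica(
    replica_matrices,
    tail: float = 2.0,
    most_favorable: bool = True,
) -> int:
    """Index of the representative replica.

    For each replica energy matrix, the per-frame inter-monomer interaction
    energy dE_ele + dE_vdw + dE_sol is averaged over the final ``tail`` ns;
    the replica with the most favorable (lowest) mean wins, ties going to the
    lowest index.  Set ``most_favorable=False`` for the literal maximum.
    """
    matrices = list(replica_matrices)
    if not matrices:
        raise ValueError("no replica matrices supplied")
    scores = []
    for m in matrices:
        t = m["time_ps"].to_numpy()
        span = t[-1] - t[0]
        if tail * 1000.0 > span + 1e-9 + (t[1] - t[0] if len(t) > 1 else 0.0):
            raise ValueError(
                f"tail window {tail} ns exceeds replica span {span / 1000.0} ns"
            )
        mask = t >= t[-1] - tail * 1000.0 + 1e-9
        de_ele = m["E_ele_C"] - m["E_ele_A"] - m["E_ele_B"]
        de_vdw = m["E_vdw_C"] - m["E_vdw_A"] - m["E_vdw_B"]
        inter = (de_ele + de_vdw + m["dE_sol"]).to_numpy()[mask]
        scores.append(float(inter.mean()))
    scores = np.array(scores)
    return int(np.argmin(scores) if most_favorable else np.argmax(scores))
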