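"""Box-counting (Minkowski) fractal dimension of a sampled waveform.

The box dimension of a planar set F is the limit of
``log N_delta(F) / log(1/delta)`` as the grid size delta shrinks, where
``N_delta`` is the number of delta x delta boxes needed to cover F. For a
sampled signal the limit is estimated over a finite range of dyadic scales
``delta_i = 2**(i-1) * delta_t`` (delta_t = one sample interval) by least-
squares fitting log N against log(1/delta); the slope is the estimate.

Conventions (they fix the estimator completely):

* time is mapped to [0, 1] and amplitude is affinely mapped to [0, 1]
  (a flat signal maps to the constant 1/2), so boxes are square in
  normalized coordinates and the estimate is invariant to affine amplitude
  transforms and bounded in [0, 2];
* the covered set is the polyline through consecutive samples, not the
  isolated sample points (isolated points undercount at coarse scales);
* the grid is anchored at the origin of the unit square and tiles it with
  an integer number NB = round(1/delta) of exactly square cells per axis
  (effective scale 1/NB, used in the fit); a value on an interior box edge
  belongs to the upper box, values on the top edge to the last box. An
  exact tiling keeps the count symmetric under amplitude flips and time
  reversal, which a ragged partial last row/column would break.

Within one time column the polyline's extremes occur either at samples or
at the column edges, so each column contributes
``row(colmax) - row(colmin) + 1`` boxes exactly, no rasterization needed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_io import HeartSoundRecord


@dataclass(frozen=True)
class BoxCountCurve:
    """Box counts across dyadic scales and the fitted log-log line."""

    scales: np.ndarray        # grid sizes delta_i (normalized units)
    counts: np.ndarray        # N_delta at each scale
    log_points: np.ndarray    # (log(1/delta), log N) pairs, one row per scale
    slope: float              # fitted box dimension D_B
    intercept: float
    r_squared: float


def _normalize(samples: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = samples.size
    t = np.arange(n) / (n - 1)
    lo, hi = samples.min(), samples.max()
    if hi - lo <= 0:
        y = np.full(n, 0.5)
    else:
        y = (samples - lo) / (hi - lo)
    return t, y


def _grid_size(delta: float) -> int:
    if not (0.0 < delta <= 1.0):
        raise ValueError("delta must lie in (0, 1] (normalized units)")
    return max(1, int(round(1.0 / delta)))


def _index(values: np.ndarray, n_boxes: int) -> np.ndarray:
    idx = np.floor(values * n_boxes).astype(int)
    return np.clip(idx, 0, n_boxes - 1)


def count_boxes(record: HeartSoundRecord, delta: float) -> int:
    """Number of boxes of an NB x NB grid (NB = round(1/delta)) covering
    the normalized waveform polyline."""
    samples = record.samples
    if samples.size < 2:
        raise ValueError("need at least 2 samples to count boxes")
    n_boxes = _grid_size(delta)
    t, y = _normalize(samples)

    # amplitude extremes per column: interior samples plus the linearly
    # interpolated values at both column edges
    edges = np.arange(n_boxes + 1) / n_boxes
    v_edge = np.interp(edges, t, y)
    col_of = _index(t, n_boxes)
    cmin = np.full(n_boxes, np.inf)
    cmax = np.full(n_boxes, -np.inf)
    np.minimum.at(cmin, col_of, y)
    np.maximum.at(cmax, col_of, y)
    cmin = np.minimum(cmin, np.minimum(v_edge[:-1], v_edge[1:]))
    cmax = np.maximum(cmax, np.maximum(v_edge[:-1], v_edge[1:]))

    rows_lo = _index(cmin, n_boxes)
    rows_hi = _index(cmax, n_boxes)
    return int(np.sum(rows_hi - rows_lo + 1))


def box_dimension(record: HeartSoundRecord, i_max: int | None = None) -> BoxCountCurve:
    """Estimate the box dimension over dyadic scales delta_i = 2**(i-1)*delta_t.

    ``i_max`` defaults to ``floor(log2(n)) - 4`` so the coarsest column still
    spans >= 16 samples; the grid scale cannot shrink below the sampling
    interval, which bounds the usable range from below.
    """
    n = record.samples.size
    if n < 2:
        raise ValueError("need at least 2 samples")
    if i_max is None:
        i_max = int(np.floor(np.log2(n))) - 4
    if i_max < 3:
        raise ValueError("i_max must be >= 3 (a 2-point fit is not a regression)")
    if n < 2 ** i_max:
        raise ValueError(f"record length {n} < 2**i_max = {2 ** i_max}")

    delta_t = 1.0 / (n - 1)
    nominal = [2.0 ** (i - 1) * delta_t for i in range(1, i_max + 1)]
    # effective scale of the exact integer tiling nearest each dyadic scale
    scales = np.array([1.0 / _grid_size(d) for d in nominal])
    counts = np.array([count_boxes(record, d) for d in scales])

    log_inv = np.log(1.0 / scales)
    log_n = np.log(counts)
    slope, intercept = np.polyfit(log_inv, log_n, 1)
    fitted = slope * log_inv + intercept
    ss_res = float(np.sum((log_n - fitted) ** 2))
    ss_tot = float(np.sum((log_n - log_n.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return BoxCountCurve(
        scales=scales,
        counts=counts,
        log_points=np.column_stack([log_inv, log_n]),
        slope=float(slope),
        intercept=float(intercept),
        r_squared=r2,
    )
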