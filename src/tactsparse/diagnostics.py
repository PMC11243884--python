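"""Secondary analyses around the survey.

Covers: compactness (phase-transition) curves from top-k coefficient
reconstruction, per-sensor/per-frame error decomposition of a
reconstruction, the grand-average temporal interaction across trials, the
filter-size-versus-sparsity trend, and the similarity of wavelet scaling
functions to the average interaction shape.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DegenerateInputError, ValidationError
from .io import TactileRecording
from .sparsifier import nmse, psnr
from .survey import SurveyTable
from .transforms import (
    CoefficientSet,
    WaveletSpec,
    forward,
    get_wavelet,
    inverse,
    scaling_function,
)


def keep_top_k(coeffs: CoefficientSet, k: int) -> CoefficientSet:
    """Keep the k largest-magnitude coefficients, zero the rest.

    Ties are broken by position in the fixed subband order (earlier kept),
    so the curve is bit-for-bit reproducible.
    """
    vec = coeffs.vector()
    n = vec.size
    if not 0 <= k <= n:
        raise ValidationError(f"k: must lie in [0, {n}], got {k}")
    keep = np.zeros(n, dtype=bool)
    if k > 0:
        # stable sort on (-|c|, position): earlier positions win ties
        order = np.argsort(-np.abs(vec), kind="stable")
        keep[order[:k]] = True
    # scatter the mask back through the subbands in the same fixed order
    out = []
    pos = 0

    def _mask(arr):
        nonlocal pos
        m = keep[pos: pos + arr.size].reshape(arr.shape)
        pos += arr.size
        return np.where(m, arr, 0.0)

    if coeffs.kind == "dct":
        out = [_mask(coeffs.coeffs[0])]
    else:
        out.append(_mask(coeffs.coeffs[0]))
        for det in coeffs.coeffs[1:]:
            out.append({key: _mask(det[key]) for key in sorted(det.keys())})
    return CoefficientSet(
        coeffs=out, kind=coeffs.kind, dimensionality=coeffs.dimensionality,
        level=coeffs.level, original_shape=coeffs.original_shape,
        axes=coeffs.axes, extension_mode=coeffs.extension_mode,
        wavelet_name=coeffs.wavelet_name,
    )


def topk_reconstruction_curve(
    data: np.ndarray,
    transform: WaveletSpec | str,
    dimensionality: int,
    k_values,
    peak: float | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Reconstruction error versus number of retained coefficients.

    Returns a (k, nmse, psnr) DataFrame and the sorted coefficient
    magnitudes (descending).  ``peak`` defaults to the data maximum.
    """
    data = np.asarray(data, dtype=float)
    coeffs = forward(data, transform, dimensionality)
    vec = coeffs.vector()
    k_values = [int(k) for k in k_values]
    if not k_values:
        raise ValidationError("k_values: must be non-empty")
    if peak is None:
        peak = float(np.max(np.abs(data)))
    rows = []
    for k in k_values:
        recon = inverse(keep_top_k(coeffs, k))
        rows.append({
            "k": k,
            "nmse": nmse(data, recon),
            "psnr": psnr(data, recon, peak),
        })
    magnitudes = np.sort(np.abs(vec))[::-1]
    return pd.DataFrame(rows), magnitudes


def spatiotemporal_error_profile(
    original: TactileRecording,
    reconstructed: TactileRecording | np.ndarray,
) -> dict:
    """Per-sensor temporal NMSE and per-frame spatial NMSE.

    The temporal profile has one value per masked-in sensor (NMSE of that
    sensor's time series); the spatial profile has one value per time point
    (NMSE of that frame over masked-in taxels).  Slices with zero mean are
    degenerate for the NMSE definition and enter the profiles as NaN; the
    summary statistics ignore them (and report how many were dropped).
    """
    y = original.frames.astype(float)
    yh = (reconstructed.frames if isinstance(reconstructed, TactileRecording)
          else np.asarray(reconstructed)).astype(float)
    if y.shape != yh.shape:
        raise ValidationError(f"shape mismatch: {y.shape} vs {yh.shape}")
    mask = original.sensor_mask
    rs, cs = np.nonzero(mask)

    def _slice_nmse(a, b):
        m = float(np.mean(a))
        if m == 0.0:
            return np.nan
        return float(np.mean((a - b) ** 2)) / m

    temporal = np.array([_slice_nmse(y[:, r, c], yh[:, r, c]) for r, c in zip(rs, cs)])
    spatial = np.array([_slice_nmse(y[t][mask], yh[t][mask]) for t in range(y.shape[0])])
    return {
        "temporal_nmse": temporal,
        "spatial_nmse": spatial,
        "temporal_mean": float(np.nanmean(temporal)),
        "temporal_std": float(np.nanstd(temporal)),
        "spatial_mean": float(np.nanmean(spatial)),
        "spatial_std": float(np.nanstd(spatial)),
        "n_degenerate_sensors": int(np.isnan(temporal).sum()),
        "n_degenerate_frames": int(np.isnan(spatial).sum()),
    }


def grand_average_interaction(
    dataset: list[TactileRecording],
    onset_fraction: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Average temporal interaction profile across trials.

    Each trial is summarized by its total masked activity per frame and
    aligned at onset (first frame whose activity exceeds ``onset_fraction``
    of the trial peak).  Aligned segments are cropped to their common length
    — cropping rather than per-trial stretching, so onset jitter does not
    dilate trials differently — and averaged at native frame resolution.
    Returns (template, per-frame standard deviation).  Trials with no
    supra-threshold activity are excluded.
    """
    if len(dataset) < 2:
        raise ValidationError("dataset: need at least 2 recordings to average")
    segments = []
    for rec in dataset:
        activity = rec.frames.astype(float)[:, rec.sensor_mask].sum(axis=1)
        peak = activity.max()
        if peak <= 0:
            continue
        above = np.nonzero(activity >= onset_fraction * peak)[0]
        if above.size == 0:
            continue
        segment = activity[above[0]:]
        if segment.size >= 2:
            segments.append(segment)
    if len(segments) < 2:
        raise ValidationError(
            "dataset: fewer than 2 recordings with supra-threshold activity"
        )
    length = min(s.size for s in segments)
    stack = np.vstack([s[:length] for s in segments])
    return stack.mean(axis=0), stack.std(axis=0)


@dataclass(frozen=True)
class TrendFit:
    """OLS fit of sparsity on wavelet support length."""

    slope: float
    intercept: float
    slope_ci_low: float
    slope_ci_high: float
    n: int


def filter_length_vs_sparsity(
    table: SurveyTable, dimensionality: int, target: float,
) -> TrendFit:
    """Linear trend of sparsity versus filter support length, with the 95%
    confidence interval of the slope."""
    cells = [
        c for c in table.converged
        if c.dimensionality == dimensionality and c.transform == "dwt"
        and np.isclose(c.target_nmse, target)
    ]
    points = [
        (get_wavelet(c.wavelet_name).support_length, c.result.sparsity)
        for c in cells
        if get_wavelet(c.wavelet_name).support_length is not None
    ]
    return fit_sparsity_trend(points)


def fit_sparsity_trend(points) -> TrendFit:
    """OLS of sparsity on support length for (length, sparsity) pairs."""
    points = list(points)
    if len(points) < 3:
        raise ValidationError(
            f"need at least 3 converged results for a trend fit, got {len(points)}"
        )
    x = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    if np.ptp(x) == 0:
        raise DegenerateInputError("all filter lengths equal: trend is undefined")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    ci = model.conf_int(alpha=0.05)
    return TrendFit(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        slope_ci_low=float(ci[1][0]),
        slope_ci_high=float(ci[1][1]),
        n=len(points),
    )


def scaling_similarity(
    wavelet: WaveletSpec | str,
    template: np.ndarray,
    iterations: int = 5,
    n_points: int = 256,
) -> float:
    """Signed similarity between a wavelet's scaling function and a template.

    Both are mean-removed, resampled to ``n_points`` samples and unit-
    normalized over their full support (matched-filter convention, so
    partial overlaps are naturally discounted), and the signed cross-
    correlation value at the shift of maximum magnitude is returned.  The
    sign is informative: an inverted template reports -1, not +1, and a
    plateau-like template can legitimately anti-match a peaked scaling
    function.  This is a descriptive shape statistic, not a test statistic.
    """
    template = np.asarray(template, dtype=float)
    if template.ndim != 1 or template.size < 2:
        raise ValidationError("template: need a 1D array with >= 2 samples")
    if np.ptp(template) == 0:
        raise DegenerateInputError("template: constant templates have no shape to correlate")
    _, phi = scaling_function(wavelet, iterations=iterations)

    def _prepare(v):
        v = np.interp(np.linspace(0.0, 1.0, n_points),
                      np.linspace(0.0, 1.0, v.size), v)
        v = v - v.mean()
        norm = np.linalg.norm(v)
        if norm == 0:
            raise DegenerateInputError("constant signal has no shape to correlate")
        return v / norm

    a = _prepare(template)
    b = _prepare(phi)
    c = np.correlate(a, b, mode="full")
    return float(c[np.argmax(np.abs(c))])
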