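"""Pupillometry: preprocessing, standardisation, per-fixation responses,
and early/late temporal decomposition.

The pupil trace is cleaned (plausible-range filter, dilation-speed outlier
rejection by a median-absolute-deviation rule, short-gap interpolation and a
light median smooth), standardised by the participant's mean diameter so a
value of 1 means "at the participant's average pupil size", and aggregated
per fixation with a forward temporal shift that accounts for pupillary
response latency.  Responses across the 0-5000 ms scene window are then
decomposed by PCA with varimax rotation into an early-weighted (PR1) and a
late-weighted (PR2) component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "PupilTrace",
    "ComponentModel",
    "preprocess_pupil",
    "standardize_pupil",
    "fixation_pupil_response",
    "fit_time_components",
    "weight_response",
    "varimax",
]


@dataclass
class PupilTrace:
    """A cleaned pupil trace with timestamps (ms) and validity."""

    t_ms: np.ndarray
    pupil_mm: np.ndarray
    valid: np.ndarray
    participant_mean_mm: float
    usable: bool = True


@dataclass
class ComponentModel:
    """Varimax-rotated two-component temporal loading model.

    ``loadings`` has shape ``(n_bins, 2)``: column 0 is the early-weighted
    component (PR1), column 1 the late-weighted one (PR2).  The rotated
    loading vectors are orthonormal (rotation of orthonormal principal
    directions); explained-variance shares are carried separately.
    """

    bin_edges_ms: np.ndarray
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray
    rotation: str = "varimax"

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges_ms) - 1

    def bin_of(self, t_scene_ms: float) -> int:
        if not (self.bin_edges_ms[0] <= t_scene_ms <= self.bin_edges_ms[-1]):
            raise ValueError(
                f"time {t_scene_ms} ms outside the modelled window "
                f"[{self.bin_edges_ms[0]}, {self.bin_edges_ms[-1]}] ms"
            )
        idx = int(np.searchsorted(self.bin_edges_ms, t_scene_ms, side="right") - 1)
        return min(idx, self.n_bins - 1)

    def loading_centroids_ms(self) -> np.ndarray:
        """Loading-weighted mean bin time per component (squared weights)."""
        centers = 0.5 * (self.bin_edges_ms[:-1] + self.bin_edges_ms[1:])
        w = self.loadings**2
        return (centers[:, None] * w).sum(axis=0) / w.sum(axis=0)


def preprocess_pupil(
    t_ms: np.ndarray,
    pupil_mm: np.ndarray,
    valid: np.ndarray | None = None,
    plausible_range_mm: tuple[float, float] = (1.0, 9.0),
    mad_multiplier: float = 16.0,
    max_gap_ms: float = 250.0,
    median_window: int = 3,
    unusable_fraction: float = 0.9,
) -> PupilTrace:
    """Clean a raw pupil trace.

    Steps: drop implausible diameters (outside ``plausible_range_mm``),
    reject dilation-speed outliers where the absolute sample-to-sample speed
    exceeds ``median + mad_multiplier * MAD`` of the speeds, linearly
    interpolate gaps up to ``max_gap_ms``, then apply a ``median_window``
    running-median smooth.  If more than ``unusable_fraction`` of the samples
    end up invalid, the trace is flagged unusable.
    """
    t = np.asarray(t_ms, dtype=float)
    p = np.asarray(pupil_mm, dtype=float).copy()
    ok = np.isfinite(p)
    if valid is not None:
        ok &= np.asarray(valid).astype(bool)
    lo, hi = plausible_range_mm
    ok &= (p >= lo) & (p <= hi)
    p[~ok] = np.nan

    # dilation-speed outliers: speed toward either neighbour
    with np.errstate(invalid="ignore", divide="ignore"):
        dt = np.diff(t)
        speed = np.abs(np.diff(p)) / dt  # mm/ms between consecutive samples
    spd = np.full(len(p), np.nan)
    spd[1:] = speed
    spd[:-1] = np.fmax(spd[:-1], speed)
    finite = np.isfinite(spd)
    if finite.sum() >= 3:
        med = np.nanmedian(spd[finite])
        mad = np.nanmedian(np.abs(spd[finite] - med))
        if mad > 0:
            bad = finite & (spd > med + mad_multiplier * mad)
            p[bad] = np.nan

    # interpolate short gaps
    good = np.isfinite(p)
    if good.sum() >= 2:
        idx_good = np.flatnonzero(good)
        for a, b in zip(idx_good[:-1], idx_good[1:]):
            if b - a > 1 and (t[b] - t[a]) <= max_gap_ms:
                frac = (t[a + 1 : b] - t[a]) / (t[b] - t[a])
                p[a + 1 : b] = p[a] + frac * (p[b] - p[a])

    # light smoothing: running median, valid samples only
    good = np.isfinite(p)
    if median_window > 1 and good.sum() >= median_window:
        sm = p.copy()
        filt = ndimage.median_filter(
            np.where(good, p, 0.0), size=median_window, mode="nearest"
        )
        # only keep the filter output where the whole window was valid
        allgood = (
            ndimage.uniform_filter(good.astype(float), size=median_window, mode="nearest")
            > 1 - 1e-9
        )
        sm[allgood] = filt[allgood]
        p = sm

    good = np.isfinite(p)
    usable = good.sum() >= (1 - unusable_fraction) * len(p) and good.sum() > 0
    mean = float(np.nanmean(p)) if good.any() else float("nan")
    return PupilTrace(t_ms=t, pupil_mm=p, valid=good, participant_mean_mm=mean, usable=usable)


def standardize_pupil(trace: PupilTrace) -> PupilTrace:
    """Divide the trace by the participant's mean pupil diameter.

    The standardised trace is dimensionless with mean exactly 1 over valid
    samples; a value of 1.1 is a 10% dilation relative to the participant's
    average.
    """
    if not np.isfinite(trace.participant_mean_mm) or trace.participant_mean_mm <= 0:
        raise ValueError("participant mean pupil size must be positive")
    return PupilTrace(
        t_ms=trace.t_ms,
        pupil_mm=trace.pupil_mm / trace.participant_mean_mm,
        valid=trace.valid,
        participant_mean_mm=1.0,
        usable=trace.usable,
    )


def fixation_pupil_response(
    trace: PupilTrace,
    onset_ms: float,
    offset_ms: float,
    shift_window_ms: tuple[float, float] = (200.0, 400.0),
    fixed_lag_ms: float | None = None,
) -> float:
    """Mean standardised pupil over the latency-shifted fixation span.

    The response window is ``[onset + shift[0], offset + shift[1]]`` ms
    (or ``[onset + lag, offset + lag]`` when ``fixed_lag_ms`` is given),
    accounting for the delay of the pupillary response to fixated content.
    Returns NaN when no valid sample falls inside the window.
    """
    if fixed_lag_ms is not None:
        lo, hi = onset_ms + fixed_lag_ms, offset_ms + fixed_lag_ms
    else:
        lo, hi = onset_ms + shift_window_ms[0], offset_ms + shift_window_ms[1]
    sel = (trace.t_ms >= lo) & (trace.t_ms <= hi) & trace.valid
    if not sel.any():
        return float("nan")
    return float(np.nanmean(trace.pupil_mm[sel]))


def varimax(loadings: np.ndarray, max_iter: int = 200, tol: float = 1e-10) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation (Kaiser) of a loading matrix; returns (rotated, R)."""
    L = np.asarray(loadings, dtype=float)
    p, k = L.shape
    R = np.eye(k)
    var_old = 0.0
    for _ in range(max_iter):
        rotated = L @ R
        u, s, vt = np.linalg.svd(
            L.T @ (rotated**3 - (rotated * (rotated**2).sum(axis=0)) / p)
        )
        R = u @ vt
        var_new = s.sum()
        if var_new - var_old < tol:
            break
        var_old = var_new
    return L @ R, R


def fit_time_components(
    records: pd.DataFrame,
    n_bins: int = 20,
    window_ms: float = 5000.0,
    time_col: str = "t_scene_ms",
    response_col: str = "pupil_response",
    unit_cols: tuple[str, str] = ("participant", "scene"),
) -> ComponentModel:
    """Two-component temporal decomposition of pupillary responses.

    Responses are binned by time-in-scene over ``[0, window_ms]``
    (``n_bins`` equal bins); observations are participant x scene mean
    response profiles, with missing bins mean-imputed for the decomposition
    only.  PCA retains the first two principal directions, which are varimax
    rotated; the component whose loading centroid is earlier is labelled PR1
    (early), the other PR2 (late).  Loading signs are normalised so each
    component's mean loading is positive.
    """
    if n_bins < 3:
        raise ValueError("need at least 3 time bins")
    edges = np.linspace(0.0, window_ms, n_bins + 1)
    t = records[time_col].to_numpy(dtype=float)
    r = records[response_col].to_numpy(dtype=float)
    keep = np.isfinite(t) & np.isfinite(r) & (t >= 0) & (t <= window_ms)
    df = records.loc[keep, list(unit_cols)].copy()
    df["_bin"] = np.clip(np.searchsorted(edges, t[keep], side="right") - 1, 0, n_bins - 1)
    df["_resp"] = r[keep]
    mat = (
        df.groupby([*unit_cols, "_bin"])["_resp"]
        .mean()
        .unstack("_bin")
        .reindex(columns=range(n_bins))
    )
    if len(mat) < 3:
        raise ValueError("not enough participant x scene profiles for PCA")
    col_means = mat.mean(axis=0)
    filled = mat.fillna(col_means).fillna(0.0).to_numpy()
    centered = filled - filled.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    var_ratio = (s**2) / (s**2).sum()
    directions = vt[:2].T  # (n_bins, 2), orthonormal
    rotated, _ = varimax(directions)
    # sign convention: mean loading positive
    rotated *= np.where(rotated.sum(axis=0) >= 0, 1.0, -1.0)
    model = ComponentModel(
        bin_edges_ms=edges,
        loadings=rotated,
        explained_variance_ratio=var_ratio[:2],
    )
    # order components early -> late by loading centroid
    cent = model.loading_centroids_ms()
    if cent[0] > cent[1]:
        model.loadings = model.loadings[:, ::-1].copy()
        model.explained_variance_ratio = model.explained_variance_ratio[::-1].copy()
    return model


def weight_response(
    response: float, t_scene_ms: float, model: ComponentModel
) -> tuple[float, float]:
    """Early/late weighted responses: response times the component loading
    at the fixation's time bin.  Returns ``(PR1, PR2)``."""
    b = model.bin_of(t_scene_ms)
    return (
        float(response * model.loadings[b, 0]),
        float(response * model.loadings[b, 1]),
    )


def add_weighted_responses(records: pd.DataFrame, model: ComponentModel) -> pd.DataFrame:
    """Append PR1/PR2 columns to a record table with responses and times."""
    out = records.copy()
    pr1 = np.full(len(out), np.nan)
    pr2 = np.full(len(out), np.nan)
    t = out["t_scene_ms"].to_numpy(dtype=float)
    r = out["pupil_response"].to_numpy(dtype=float)
    for i in range(len(out)):
        if np.isfinite(t[i]) and np.isfinite(r[i]):
            pr1[i], pr2[i] = weight_response(r[i], t[i], model)
    out["pr1"] = pr1
    out["pr2"] = pr2
    return out
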