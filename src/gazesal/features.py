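"""Per-frame physical salience, motion salience, and luminance maps.

Physical salience uses the spectral-residual method: non-redundant spectral
information of the log-amplitude spectrum back-projected with the original
phase.  Motion salience uses per-pixel Gaussian-mixture background
subtraction (adaptive mixture of K Gaussians, learning rate alpha = 0.002).
Luminance is Rec.709 relative luminance of the gamma-linearised RGB channels,
optionally blurred to a local-luminance map.

All maps share the frame's spatial shape and are normalised to [0, 1];
constant (information-free) frames map to all zeros by convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.transform import resize

__all__ = [
    "FrameFeatureMaps",
    "MotionModelState",
    "spectral_residual_salience",
    "motion_salience_update",
    "luminance_map",
    "scene_salience_summary",
    "srgb_linearize",
    "compute_scene_features",
]


@dataclass
class FrameFeatureMaps:
    """Per-frame feature grids, spatially aligned with the source frame."""

    frame_index: int
    physical_salience: np.ndarray
    motion_salience: np.ndarray
    luminance: np.ndarray
    global_luminance: float


def _to_gray(frame: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame, dtype=float)
    if frame.ndim == 3:
        return frame.mean(axis=2)
    if frame.ndim == 2:
        return frame
    raise ValueError("frame must be 2-D grayscale or 3-D RGB")


def _minmax(m: np.ndarray) -> np.ndarray:
    lo = float(m.min())
    hi = float(m.max())
    if hi - lo < 1e-12:
        return np.zeros_like(m)
    return (m - lo) / (hi - lo)


def spectral_residual_salience(
    frame: np.ndarray,
    downscale_width: int = 64,
    smooth_sigma: float = 2.5,
) -> np.ndarray:
    """Spectral-residual salience map of one frame, in [0, 1].

    Pipeline: downscale to ``downscale_width`` -> 2-D FFT -> log-amplitude ->
    subtract 3x3 local mean of the log-amplitude (the spectral residual) ->
    inverse FFT with the original phase -> squared magnitude -> Gaussian
    smooth -> upscale to the frame size -> min-max normalise.  A constant
    frame has no non-redundant information and maps to all zeros.
    """
    gray = _to_gray(frame)
    h, w = gray.shape
    if np.ptp(gray) < 1e-12:
        return np.zeros((h, w))
    scale = downscale_width / w
    small = resize(
        gray,
        (max(1, round(h * scale)), downscale_width),
        order=1,
        mode="reflect",
        anti_aliasing=False,
        preserve_range=True,
    )
    spectrum = np.fft.fft2(small)
    amplitude = np.abs(spectrum)
    phase = np.angle(spectrum)
    # log(1 + A) rather than log A: synthetic frames can have exact spectral
    # zeros (e.g. box functions) whose log would explode the residual
    log_amp = np.log1p(amplitude)
    residual = log_amp - ndimage.uniform_filter(log_amp, size=3, mode="wrap")
    recon = np.fft.ifft2(np.exp(residual + 1j * phase))
    sal = np.abs(recon) ** 2
    sal = ndimage.gaussian_filter(sal, sigma=smooth_sigma, mode="reflect")
    sal = resize(
        sal, (h, w), order=1, mode="reflect", anti_aliasing=False, preserve_range=True
    )
    return _minmax(sal)


@dataclass
class MotionModelState:
    """Per-pixel adaptive mixture-of-Gaussians background model.

    Arrays have shape ``(H, W, K)``; per-pixel weights sum to one.  The
    learning rate alpha controls how quickly the background absorbs change.
    """

    means: np.ndarray
    variances: np.ndarray
    weights: np.ndarray
    alpha: float = 0.002
    match_sd: float = 2.5
    background_fraction: float = 0.9
    initial_variance: float = 15.0
    frame_count: int = 0
    shape: tuple = field(default=(0, 0))

    @classmethod
    def initialize(
        cls,
        frame: np.ndarray,
        n_components: int = 5,
        alpha: float = 0.002,
        match_sd: float = 2.5,
        background_fraction: float = 0.9,
        initial_variance: float = 15.0,
    ) -> "MotionModelState":
        gray = _to_gray(frame)
        h, w = gray.shape
        means = np.zeros((h, w, n_components))
        means[..., 0] = gray
        # unused components parked far away with negligible weight
        means[..., 1:] = -1000.0
        variances = np.full((h, w, n_components), initial_variance)
        weights = np.full((h, w, n_components), 1e-6)
        weights[..., 0] = 1.0
        weights /= weights.sum(axis=2, keepdims=True)
        return cls(
            means=means,
            variances=variances,
            weights=weights,
            alpha=alpha,
            match_sd=match_sd,
            background_fraction=background_fraction,
            initial_variance=initial_variance,
            frame_count=1,
            shape=(h, w),
        )


def motion_salience_update(
    state: MotionModelState, frame: np.ndarray
) -> tuple[MotionModelState, np.ndarray]:
    """Update the background model with one frame; return foreground salience.

    Foreground evidence per pixel is the mismatch to the background portion of
    the mixture (minimum normalised distance to the background Gaussians,
    clipped at the match threshold), scaled to [0, 1].  The state is updated
    in place with learning rate ``alpha``; a matched component absorbs the
    pixel, otherwise the weakest component is reinitialised at it.
    """
    gray = _to_gray(frame)
    if gray.shape != state.shape:
        raise ValueError(
            f"frame shape {gray.shape} does not match model shape {state.shape}"
        )
    mu, var, w = state.means, state.variances, state.weights
    a = state.alpha
    sd = np.sqrt(var)
    dist = np.abs(gray[..., None] - mu) / sd  # normalised distance, (H,W,K)

    # --- foreground evidence from the *current* background model -----------
    order = np.argsort(-(w / sd), axis=2)
    w_sorted = np.take_along_axis(w, order, axis=2)
    cum = np.cumsum(w_sorted, axis=2)
    # background components: the strongest ones whose cumulative weight first
    # exceeds the background fraction
    nbg = (cum < state.background_fraction).sum(axis=2) + 1
    rank = np.empty_like(order)
    np.put_along_axis(rank, order, np.arange(order.shape[2])[None, None, :], axis=2)
    is_bg = rank < nbg[..., None]
    dist_bg = np.where(is_bg, dist, np.inf).min(axis=2)
    evidence = np.clip(dist_bg / state.match_sd, 0.0, 1.0)

    # --- model update -------------------------------------------------------
    matched = dist < state.match_sd
    # winner: matched component with the highest weight, if any
    w_masked = np.where(matched, w, -1.0)
    winner = np.argmax(w_masked, axis=2)
    any_match = matched.any(axis=2)
    kidx = np.arange(mu.shape[2])[None, None, :]
    is_winner = (kidx == winner[..., None]) & any_match[..., None]

    if a > 0:
        w_new = (1 - a) * w + a * is_winner
        delta = gray[..., None] - mu
        mu_new = np.where(is_winner, mu + a * delta, mu)
        var_new = np.where(is_winner, (1 - a) * var + a * delta**2, var)
        var_new = np.maximum(var_new, 1.0)
        # unmatched pixel: reinitialise the weakest component there
        weakest = np.argmin(w_new, axis=2)
        reinit = (kidx == weakest[..., None]) & (~any_match[..., None])
        mu_new = np.where(reinit, gray[..., None], mu_new)
        var_new = np.where(reinit, state.initial_variance, var_new)
        w_new = np.where(reinit, 0.05, w_new)
        w_new /= w_new.sum(axis=2, keepdims=True)
        state.means, state.variances, state.weights = mu_new, var_new, w_new
    state.frame_count += 1
    return state, evidence


def srgb_linearize(channel: np.ndarray) -> np.ndarray:
    """Piecewise sRGB gamma expansion of values in [0, 1]."""
    c = np.asarray(channel, dtype=float)
    return np.where(c <= 0.04045, c / 12.92, ((c + 0.055) / 1.055) ** 2.4)


def luminance_map(
    frame: np.ndarray,
    blur_sigma: float = 10.0,
    kernel_frac: float = 0.10,
    linearize: bool = True,
) -> tuple[np.ndarray, float]:
    """Rec.709 relative luminance with a Gaussian local-luminance blur.

    Per pixel, ``L = 0.2126 R + 0.7152 G + 0.0722 B`` on linear-light
    channels (sRGB linearisation applied unless ``linearize=False``, for
    frames already in linear light).  The local map is a Gaussian blur with
    ``sigma = blur_sigma`` pixels and kernel extent ``kernel_frac`` of the
    frame size per axis; the returned global luminance is the unblurred
    spatial mean.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 3 or frame.shape[2] != 3:
        raise ValueError("luminance requires an RGB frame (H, W, 3)")
    if frame.max() > 1.0:
        frame = frame / 255.0
    rgb = srgb_linearize(frame) if linearize else frame
    lum = 0.2126 * rgb[..., 0] + 0.7152 * rgb[..., 1] + 0.0722 * rgb[..., 2]
    h, w = lum.shape
    # kernel extent as truncation radius: kernel_frac of each axis, i.e.
    # radius = kernel_frac * size / 2
    rad_y = max(1.0, kernel_frac * h / 2.0)
    rad_x = max(1.0, kernel_frac * w / 2.0)
    local = ndimage.gaussian_filter(
        lum,
        sigma=blur_sigma,
        truncate=min(rad_y, rad_x) / blur_sigma,
        mode="reflect",
    )
    return local, float(lum.mean())


def scene_salience_summary(maps: list[np.ndarray]) -> np.ndarray:
    """Per-frame mean grid value as a percentage of the maximum possible.

    With maps normalised to [0, 1], the summary for one frame is simply
    ``100 * mean(map)``.
    """
    return np.array([100.0 * float(np.mean(m)) for m in maps])


def compute_scene_features(
    frames: np.ndarray,
    alpha: float = 0.002,
    downscale_width: int = 64,
    blur_sigma: float = 10.0,
    kernel_frac: float = 0.10,
) -> list[FrameFeatureMaps]:
    """Feature maps for one scene's ordered frame stack ``(T, H, W, 3)``.

    The motion model is initialised from the scene's first frame (it is reset
    at every scene cut so motion evidence never leaks across scenes).
    """
    frames = np.asarray(frames)
    if frames.ndim != 4:
        raise ValueError("expected frame stack (T, H, W, 3)")
    out: list[FrameFeatureMaps] = []
    state = MotionModelState.initialize(frames[0], alpha=alpha)
    for i, frame in enumerate(frames):
        phys = spectral_residual_salience(frame, downscale_width=downscale_width)
        state, motion = motion_salience_update(state, frame)
        local_lum, global_lum = luminance_map(
            frame, blur_sigma=blur_sigma, kernel_frac=kernel_frac
        )
        out.append(
            FrameFeatureMaps(
                frame_index=i,
                physical_salience=phys,
                motion_salience=motion,
                luminance=local_lum,
                global_luminance=global_lum,
            )
        )
    return out
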