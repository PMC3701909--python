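"""Synthetic single-molecule imaging data with known ground truth.

Emulates the live-cell supported-lipid-bilayer experiment: ligands diffusing
freely in the bilayer (D ~ 0.44 um^2/s), stochastic binding to receptors that
move slowly and directedly toward the cell center, exponential photobleaching,
stepwise fluorophore intensity traces, rendered camera frames with
motion blur, and fiducial bead fields for two-channel registration.

Every generator takes an integer seed and is bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import erf

from .core import (
    BLEACH, BLEACHED, BOUND, FREE, MOVIE_END, UNBIND,
    AcquisitionMeta, BoundInterval, DwellSample, GroundTruth, IntensityTrace,
    Track, TrackSet,
)
from .registration import ChannelMap

logger = logging.getLogger(__name__)

__all__ = [
    "SimKineticParams", "CameraNoise", "FrameStack",
    "simulate_free_tracks", "simulate_two_state_tracks",
    "simulate_intensity_trace", "simulate_bleaching_survival",
    "render_frames", "simulate_bead_field",
]


@dataclass(frozen=True)
class SimKineticParams:
    """Kinetic and mobility parameters of the two-state ligand model.

    The model is the Markov scheme free <-> bound -> bleached: a ligand
    diffuses freely (``d_free``), binds a receptor at rate ``k_bind``,
    and while bound diffuses residually (``d_bound``), is transported at
    ``v_radial`` toward a center point, unbinds at ``k_off`` and
    photobleaches at ``k_bl``.

    Defaults for the transport speed (0.05 um/s, the order of magnitude of
    receptor-microcluster centripetal flow) and bound residual diffusivity
    (0.005 um^2/s, small enough that the two mobility modes separate at a
    500 ms lag) are package choices; neither is directly measured.
    """

    d_free: float = 0.44
    d_bound: float = 0.005
    v_radial: float = 0.05
    k_bind: float = 0.5
    k_off: float = 1 / 5.2
    k_bl: float = 1 / 30.0

    def __post_init__(self) -> None:
        for name in ("d_free", "d_bound", "v_radial", "k_bind", "k_off", "k_bl"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.d_free > self.d_bound:
            raise ValueError("d_free must exceed d_bound")


@dataclass(frozen=True)
class CameraNoise:
    """Additive camera model: constant offset + Gaussian read noise,
    optional Poisson shot noise on the photon signal."""

    offset: float = 100.0
    read_sd: float = 2.0
    shot: bool = False


@dataclass
class FrameStack:
    """A rendered movie: (n_frames, height, width) float counts."""

    data: np.ndarray
    meta: AcquisitionMeta
    noise: CameraNoise

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("FrameStack data must be (n_frames, h, w)")

    def __len__(self) -> int:
        return self.data.shape[0]


def _uniform_positions(rng: np.random.Generator, n: int,
                       meta: AcquisitionMeta) -> np.ndarray:
    h_um, w_um = meta.field_um
    return rng.uniform([0.0, 0.0], [w_um, h_um], size=(n, 2))


def simulate_free_tracks(d_coeff: float, meta: AcquisitionMeta,
                         n_tracks: int, seed: int) -> TrackSet:
    """Pure 2D Brownian trajectories sampled at the frame interval.

    Each axis increment is Gaussian with variance ``2 * d_coeff *
    frame_interval``; this is the free-ligand mobility observed in the
    bilayer away from cells.
    """
    if d_coeff < 0:
        raise ValueError("d_coeff must be >= 0")
    if n_tracks < 1:
        raise ValueError("n_tracks must be >= 1")
    rng = np.random.default_rng(seed)
    dt = meta.frame_interval
    sd = np.sqrt(2.0 * d_coeff * dt)
    start = _uniform_positions(rng, n_tracks, meta)
    steps = rng.normal(0.0, sd, size=(n_tracks, meta.n_frames - 1, 2))
    pos = np.concatenate([start[:, None, :],
                          start[:, None, :] + np.cumsum(steps, axis=1)], axis=1)
    t = meta.times
    frames = np.arange(meta.n_frames)
    tracks = [Track(i, frames, t, pos[i, :, 0], pos[i, :, 1])
              for i in range(n_tracks)]
    return TrackSet(tracks, meta)


def _simulate_state_path(params: SimKineticParams, t_end: float,
                         rng: np.random.Generator,
                         bleach_free: bool) -> list[tuple[str, float, float]]:
    """Continuous-time state path [(state, t0, t1), ...] up to t_end.

    Ends early (path shorter than t_end) if the molecule bleaches.
    """
    segs: list[tuple[str, float, float]] = []
    t, state = 0.0, FREE
    while t < t_end:
        if state == FREE:
            rates = {BOUND: params.k_bind}
            if bleach_free:
                rates[BLEACHED] = params.k_bl
        else:
            rates = {FREE: params.k_off, BLEACHED: params.k_bl}
        total = sum(rates.values())
        dt = rng.exponential(1.0 / total) if total > 0 else np.inf
        t1 = min(t + dt, t_end)
        segs.append((state, t, t1))
        if t1 >= t_end:
            break
        # choose which transition fired
        u = rng.uniform(0, total)
        acc = 0.0
        for nxt, r in rates.items():
            acc += r
            if u <= acc:
                state = nxt
                break
        t = t1
        if state == BLEACHED:
            break
    return segs


def simulate_two_state_tracks(params: SimKineticParams, meta: AcquisitionMeta,
                              n_tracks: int, center: tuple[float, float],
                              seed: int, bleach_free: bool = False
                              ) -> tuple[TrackSet, GroundTruth]:
    """Ligands alternating between free diffusion and receptor-bound motion.

    While bound, motion is slow diffusion (``d_bound``) plus drift of
    magnitude ``v_radial`` toward ``center`` (micrometers) — the directed
    centripetal transport of engaged complexes. Photobleaching (rate
    ``k_bl``) terminates visibility; by default only bound molecules
    bleach, since only the bound state sits in the evanescent field long
    enough at the long exposures used for dwell imaging.

    Returns the visible trajectories and a :class:`GroundTruth` holding
    per-frame state labels and every bound interval with its end cause.
    """
    if n_tracks < 1:
        raise ValueError("n_tracks must be >= 1")
    h_um, w_um = meta.field_um
    cx, cy = center
    if not (0 <= cx <= w_um and 0 <= cy <= h_um):
        raise ValueError("center must lie inside the field")
    rng = np.random.default_rng(seed)
    dt = meta.frame_interval
    t_end = (meta.n_frames - 1) * dt if meta.n_frames > 1 else dt
    truth = GroundTruth()
    tracks = []
    for tid in range(n_tracks):
        segs = _simulate_state_path(params, t_end, rng, bleach_free)
        # ground-truth bound intervals; the cause is whatever followed at t1
        for si, (state, t0, t1) in enumerate(segs):
            if state != BOUND:
                continue
            if t1 >= t_end - 1e-15:
                cause = MOVIE_END
            elif si + 1 < len(segs):
                cause = UNBIND    # next segment exists, so it reverted to FREE
            else:
                cause = BLEACH    # path terminated early: photobleached
            truth.intervals.append(BoundInterval(tid, t0, t1, cause))
        bleach_t = segs[-1][2] if segs and segs[-1][2] < t_end - 1e-15 else np.inf
        # per-frame labels and positions
        pos = np.empty((meta.n_frames, 2))
        pos[0] = _uniform_positions(rng, 1, meta)[0]
        labels = np.empty(meta.n_frames, dtype=object)
        seg_i = 0
        for k in range(meta.n_frames):
            tk = k * dt
            if tk >= bleach_t - 1e-15:
                labels[k] = BLEACHED
            else:
                while seg_i + 1 < len(segs) and segs[seg_i][2] <= tk + 1e-15:
                    seg_i += 1
                labels[k] = segs[seg_i][0]
            if k == 0:
                continue
            # advance position over [tk - dt, tk], split by state segments
            x, y = pos[k - 1]
            a = tk - dt
            for state, s0, s1 in segs:
                lo, hi = max(s0, a), min(s1, tk)
                if hi <= lo:
                    continue
                h = hi - lo
                if state == FREE:
                    x += rng.normal(0, np.sqrt(2 * params.d_free * h))
                    y += rng.normal(0, np.sqrt(2 * params.d_free * h))
                elif state == BOUND:
                    dx, dy = cx - x, cy - y
                    dist = np.hypot(dx, dy)
                    step = min(params.v_radial * h, dist)
                    if dist > 0:
                        x += step * dx / dist
                        y += step * dy / dist
                    x += rng.normal(0, np.sqrt(2 * params.d_bound * h))
                    y += rng.normal(0, np.sqrt(2 * params.d_bound * h))
            pos[k] = (x, y)
        truth.labels[tid] = labels
        visible = labels != BLEACHED
        frames = np.nonzero(visible)[0]
        tracks.append(Track(tid, frames, frames * dt,
                            pos[visible, 0], pos[visible, 1],
                            state=labels[visible].copy()))
    return TrackSet(tracks, meta), truth


def simulate_intensity_trace(segment_levels, segment_durations, noise_sd: float,
                             meta: AcquisitionMeta, seed: int
                             ) -> tuple[IntensityTrace, GroundTruth]:
    """Piecewise-constant intensity (a bleach staircase or stepwise binding
    trace) plus additive Gaussian camera noise.

    ``segment_levels`` are mean counts per frame; ``segment_durations`` are
    seconds and are quantized to whole frames at the frame interval.
    """
    levels = np.asarray(segment_levels, dtype=float)
    durs = np.asarray(segment_durations, dtype=float)
    if levels.size == 0:
        raise ValueError("segment list must be non-empty")
    if levels.shape != durs.shape:
        raise ValueError("levels and durations must have equal length")
    if np.any(durs <= 0):
        raise ValueError("durations must be positive")
    rng = np.random.default_rng(seed)
    dt = meta.frame_interval
    n_per = np.maximum(1, np.round(durs / dt).astype(int))
    mean = np.repeat(levels, n_per)
    counts = mean + (rng.normal(0, noise_sd, size=mean.size) if noise_sd > 0
                     else 0.0)
    times = np.arange(mean.size) * dt
    change_frames = np.cumsum(n_per)[:-1]
    truth = GroundTruth(change_times=change_frames * dt, change_levels=levels)
    return IntensityTrace(times, counts, background_sd=noise_sd), truth


def simulate_bleaching_survival(tau_bl: float, n: int, t_max: float,
                                seed: int) -> DwellSample:
    """Exponential photobleaching lifetimes, right-censored at ``t_max``.

    Emulates the bilayer bleaching standard: fluorophores imaged without
    cells whose disappearance times calibrate tau_bl.
    """
    if tau_bl <= 0:
        raise ValueError("tau_bl must be positive")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    life = rng.exponential(tau_bl, size=n)
    censored = life > t_max
    return DwellSample(np.minimum(life, t_max), censored, source="bleach_sim")


def _deposit_gaussian(img: np.ndarray, x_px: float, y_px: float,
                      sigma_px: float, photons: float) -> None:
    """Add a pixel-integrated 2D Gaussian (total = photons) to img in place."""
    h, w = img.shape
    r = int(np.ceil(4 * sigma_px)) + 1
    x0, x1 = int(np.floor(x_px)) - r, int(np.floor(x_px)) + r + 1
    y0, y1 = int(np.floor(y_px)) - r, int(np.floor(y_px)) + r + 1
    x0, x1 = max(x0, 0), min(x1, w)
    y0, y1 = max(y0, 0), min(y1, h)
    if x0 >= x1 or y0 >= y1:
        return
    # pixel i spans [i-0.5, i+0.5] (origin at pixel center)
    xe = np.arange(x0, x1 + 1) - 0.5
    ye = np.arange(y0, y1 + 1) - 0.5
    s = sigma_px * np.sqrt(2.0)
    fx = 0.5 * (erf((xe[1:] - x_px) / s) - erf((xe[:-1] - x_px) / s))
    fy = 0.5 * (erf((ye[1:] - y_px) / s) - erf((ye[:-1] - y_px) / s))
    img[y0:y1, x0:x1] += photons * np.outer(fy, fx)


def render_frames(tracks: TrackSet, truth: GroundTruth | None,
                  psf_sigma: float = 0.084, photons_per_frame: float = 500.0,
                  substeps: int = 25, noise: CameraNoise | None = None,
                  seed: int = 0) -> FrameStack:
    """Render trajectories into camera frames with motion blur.

    Each visible emitter deposits its point-spread function (Gaussian of
    width ``psf_sigma`` micrometers) at ``substeps`` intra-exposure
    positions interpolated with a Brownian bridge between consecutive frame
    positions, so fast diffusers smear into background at long exposure
    (the "hardware filtering" that isolates slow, receptor-bound
    molecules) while total photons per frame are conserved. Bridge
    diffusivity is taken from the track's own local increment, so no
    separate mobility parameter is needed.

    Camera model: ``offset + read noise`` Gaussian, optional Poisson shot
    noise. Emitters outside the field are clipped and logged.
    """
    if psf_sigma <= 0:
        raise ValueError("psf_sigma must be positive")
    if substeps < 1:
        raise ValueError("substeps must be >= 1")
    noise = noise or CameraNoise()
    meta = tracks.meta
    rng = np.random.default_rng(seed)
    h, w = meta.field_size
    px = meta.pixel_size
    sigma_px = psf_sigma / px
    signal = np.zeros((meta.n_frames, h, w))
    exp_frac = meta.exposure_time / meta.frame_interval
    n_clipped = 0
    for tr in tracks:
        idx = {f: i for i, f in enumerate(tr.frame)}
        for i, f in enumerate(tr.frame):
            if tr.state is not None and tr.state[i] == BLEACHED:
                continue
            x0, y0 = tr.x_um[i], tr.y_um[i]
            j = idx.get(f + 1)
            if j is None or substeps == 1:
                xs = np.full(substeps, x0)
                ys = np.full(substeps, y0)
            else:
                x1, y1 = tr.x_um[j], tr.y_um[j]
                # fractions of the inter-frame interval covered by exposure
                s = (np.arange(substeps) + 0.5) / substeps * exp_frac
                dloc = ((x1 - x0) ** 2 + (y1 - y0) ** 2) / (4 * meta.frame_interval)
                bridge_sd = np.sqrt(
                    np.maximum(2 * dloc * meta.frame_interval * s * (1 - s), 0))
                xs = x0 + s * (x1 - x0) + rng.normal(0, 1, substeps) * bridge_sd
                ys = y0 + s * (y1 - y0) + rng.normal(0, 1, substeps) * bridge_sd
            per = photons_per_frame / substeps
            for xsub, ysub in zip(xs, ys):
                xp, yp = xsub / px, ysub / px
                if not (-0.5 <= xp < w - 0.5 and -0.5 <= yp < h - 0.5):
                    n_clipped += 1
                _deposit_gaussian(signal[f], xp, yp, sigma_px, per)
    if n_clipped:
        logger.warning("render_frames: %d emitter substeps outside the field "
                       "were clipped", n_clipped)
    if noise.shot:
        signal = rng.poisson(signal).astype(float)
    data = signal + noise.offset
    if noise.read_sd > 0:
        data = data + rng.normal(0, noise.read_sd, size=data.shape)
    return FrameStack(data, meta, noise)


def simulate_bead_field(n_beads: int, transform: ChannelMap, loc_noise: float,
                        field: tuple[float, float], seed: int
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Fiducial bead pairs for channel registration.

    Source positions are uniform over ``field`` (width, height in um);
    destinations are the mapped positions plus isotropic Gaussian
    localization noise of SD ``loc_noise`` um.
    """
    n_coef = transform.n_coefficients
    if n_beads < n_coef:
        raise ValueError(
            f"n_beads={n_beads} underdetermines an order-{transform.order} "
            f"map ({2 * n_coef} coefficients)")
    rng = np.random.default_rng(seed)
    src = rng.uniform([0, 0], list(field), size=(n_beads, 2))
    dst = transform.apply(src)
    if loc_noise > 0:
        dst = dst + rng.normal(0, loc_noise, size=dst.shape)
    return src, dst
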