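"""Spot detection, track linking, and two-state mobility analysis.

Diffraction-limited emitters are detected with a difference-of-Gaussians
bandpass filter plus intensity-weighted sub-pixel centroids, linked into
trajectories by per-frame optimal assignment, and their pooled step-size
distribution is fit with a one- or two-component Rayleigh mixture. Under a
T cell the distribution is bimodal — fast, freely diffusing ligand plus a
slow receptor-bound component — and the mixture crossover r* classifies
each trajectory sample as FREE or BOUND; maximal BOUND runs become dwell
events for kinetic analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.optimize import linear_sum_assignment

from .core import (BOUND, FREE, UNKNOWN, AcquisitionMeta, DwellSample, Track,
                   TrackSet)
from .sim import FrameStack

logger = logging.getLogger(__name__)

__all__ = ["Localization", "StepSample", "MobilityFit",
           "detect_spots", "detect_stack", "link_tracks",
           "step_size_distribution", "fit_mobility_mixture",
           "classify_bound_segments"]


@dataclass
class Localization:
    frame: int
    x_px: float
    y_px: float
    x_um: float
    y_um: float
    intensity: float          # integrated bandpass counts
    diameter_px: float        # 2x RMS radius of the bandpass support


@dataclass
class StepSample:
    """Pooled displacement magnitudes at one frame lag."""

    lag: int
    dr: np.ndarray
    dx: np.ndarray
    dy: np.ndarray

    def __post_init__(self) -> None:
        self.dr = np.asarray(self.dr, dtype=float)
        self.dx = np.asarray(self.dx, dtype=float)
        self.dy = np.asarray(self.dy, dtype=float)

    def __len__(self) -> int:
        return len(self.dr)


@dataclass
class MobilityFit:
    """Rayleigh-mixture fit of a step-size distribution.

    For isotropic Brownian motion the displacement magnitude at lag time
    dt is Rayleigh: p(r) = r/(2 D dt) * exp(-r^2 / (4 D dt)); a mixture of
    two such components models coexisting bound (slow) and free (fast)
    populations. ``r_star`` is the magnitude at which the two component
    posteriors are equal, used as the classification threshold.
    """

    n_components: int
    f_slow: float
    f_fast: float
    d_slow: float
    d_fast: float
    dt_lag: float
    log_likelihood: float
    r_star: float

    def __post_init__(self) -> None:
        if not np.isclose(self.f_slow + self.f_fast, 1.0):
            raise ValueError("fractions must sum to 1")
        if self.n_components == 2 and not self.d_fast > self.d_slow:
            raise ValueError("d_fast must exceed d_slow")


# ---------------------------------------------------------------- detection

def detect_spots(frame: np.ndarray, band_low: float = 0.8,
                 band_high: float = 2.0, intensity_min: float = 50.0,
                 size_max: float = 6.0, pixel_size: float = 0.105,
                 frame_index: int = 0) -> list[Localization]:
    """Detect diffraction-limited spots in one image.

    Difference-of-Gaussians bandpass (sigmas ``band_low`` < ``band_high``
    pixels) removes background and shot structure; local maxima above the
    intensity threshold are refined to sub-pixel positions by an
    intensity-weighted centroid over the bandpass support. Candidates are
    filtered uniformly on integrated intensity and apparent size.
    """
    if not band_low < band_high:
        raise ValueError("band_low must be < band_high")
    img = np.asarray(frame, dtype=float)
    if img.max() >= 65535:
        logger.warning("frame %d contains saturated pixels", frame_index)
    bp = ndimage.gaussian_filter(img, band_low) \
        - ndimage.gaussian_filter(img, band_high)
    # local maxima on the bandpass image
    fp = ndimage.maximum_filter(bp, size=3)
    # floor: reject maxima indistinguishable from filtered noise
    noise = 1.4826 * np.median(np.abs(bp - np.median(bp)))
    cand = (bp == fp) & (bp > max(4 * noise, 1e-12))
    ys, xs = np.nonzero(cand)
    h, w = img.shape
    r = int(np.ceil(2 * band_high))
    out: list[Localization] = []
    for y0, x0 in zip(ys, xs):
        yl, yh = max(y0 - r, 0), min(y0 + r + 1, h)
        xl, xh = max(x0 - r, 0), min(x0 + r + 1, w)
        patch = np.clip(bp[yl:yh, xl:xh], 0, None)
        total = patch.sum()
        if total < intensity_min:
            continue
        yy, xx = np.mgrid[yl:yh, xl:xh]
        cx = float((patch * xx).sum() / total)
        cy = float((patch * yy).sum() / total)
        var = ((patch * ((xx - cx) ** 2 + (yy - cy) ** 2)).sum() / total)
        diam = 2.0 * np.sqrt(max(var / 2.0, 0.0))   # 2x per-axis RMS radius
        if diam > size_max:
            continue
        out.append(Localization(frame_index, cx, cy, cx * pixel_size,
                                cy * pixel_size, float(total), diam))
    return out


def detect_stack(stack: FrameStack, **kwargs) -> list[list[Localization]]:
    """Run :func:`detect_spots` over every frame of a movie."""
    px = stack.meta.pixel_size
    return [detect_spots(stack.data[k], pixel_size=px, frame_index=k, **kwargs)
            for k in range(len(stack))]


# ------------------------------------------------------------------ linking

def link_tracks(locs_per_frame: list[list[Localization]], meta: AcquisitionMeta,
                max_disp: float = 0.5, max_gap: int = 1) -> TrackSet:
    """Link per-frame localizations into trajectories.

    Per frame, open tracks (those whose last detection is at most
    ``max_gap + 1`` frames old) are matched to new localizations by optimal
    assignment minimizing total squared displacement, with no match allowed
    beyond ``max_disp`` micrometers; unmatched localizations start new
    tracks. Optimal (Hungarian) assignment removes any dependence on input
    order, so linking is deterministic.
    """
    BIG = 1e12
    open_tracks: list[dict] = []   # {'id', 'frames', 'x', 'y', 'i', 'last'}
    done: list[dict] = []
    next_id = 0
    for f, locs in enumerate(locs_per_frame):
        # retire stale tracks
        still = []
        for tr in open_tracks:
            (still if f - tr["frames"][-1] <= max_gap + 1 else done).append(tr)
        open_tracks = still
        if locs:
            if open_tracks:
                cost = np.full((len(open_tracks), len(locs)), BIG)
                for i, tr in enumerate(open_tracks):
                    dx = np.array([L.x_um - tr["x"][-1] for L in locs])
                    dy = np.array([L.y_um - tr["y"][-1] for L in locs])
                    d2 = dx * dx + dy * dy
                    ok = d2 <= max_disp * max_disp
                    cost[i, ok] = d2[ok]
                ri, ci = linear_sum_assignment(cost)
                matched_locs = set()
                for i, j in zip(ri, ci):
                    if cost[i, j] >= BIG:
                        continue
                    tr = open_tracks[i]
                    L = locs[j]
                    tr["frames"].append(f)
                    tr["x"].append(L.x_um)
                    tr["y"].append(L.y_um)
                    tr["ints"].append(L.intensity)
                    matched_locs.add(j)
            else:
                matched_locs = set()
            for j, L in enumerate(locs):
                if j in matched_locs:
                    continue
                open_tracks.append({"id": next_id, "frames": [f],
                                    "x": [L.x_um], "y": [L.y_um],
                                    "ints": [L.intensity]})
                next_id += 1
    done.extend(open_tracks)
    done.sort(key=lambda tr: tr["id"])
    dt = meta.frame_interval
    tracks = [Track(tr["id"], np.array(tr["frames"]),
                    np.array(tr["frames"]) * dt,
                    np.array(tr["x"]), np.array(tr["y"]),
                    intensity=np.array(tr["ints"]))
              for tr in done]
    return TrackSet(tracks, meta)


# ------------------------------------------------------- step-size analysis

def step_size_distribution(tracks: TrackSet, lag: int = 1) -> StepSample:
    """Pool displacement magnitudes at frame lag ``lag`` across all tracks."""
    if lag < 1:
        raise ValueError("lag must be >= 1")
    dxs, dys = [], []
    for tr in tracks:
        pos = {f: i for i, f in enumerate(tr.frame)}
        for f, i in pos.items():
            j = pos.get(f + lag)
            if j is not None:
                dxs.append(tr.x_um[j] - tr.x_um[i])
                dys.append(tr.y_um[j] - tr.y_um[i])
    dx = np.array(dxs)
    dy = np.array(dys)
    return StepSample(lag, np.hypot(dx, dy), dx, dy)


def _exp_mix_em(u: np.ndarray, tol: float = 1e-10, max_iter: int = 2000
                ) -> tuple[float, float, float, float]:
    """EM for a two-component exponential mixture on u = r^2.

    Returns (f1, m1, f2, m2) with m1 <= m2 (means of the components).
    """
    med = np.median(u)
    lo, hi = u[u <= med], u[u > med]
    m1 = max(lo.mean(), 1e-12)
    m2 = max(hi.mean(), m1 * 1.01)
    f1 = 0.5
    ll_old = -np.inf
    for _ in range(max_iter):
        l1 = np.log(f1 / m1) - u / m1
        l2 = np.log((1 - f1) / m2) - u / m2
        m = np.maximum(l1, l2)
        lse = m + np.log(np.exp(l1 - m) + np.exp(l2 - m))
        g1 = np.exp(l1 - lse)
        f1 = g1.mean()
        f1 = min(max(f1, 1e-12), 1 - 1e-12)
        m1 = max((g1 * u).sum() / g1.sum(), 1e-15)
        m2 = max(((1 - g1) * u).sum() / (1 - g1).sum(), 1e-15)
        ll = lse.sum()
        if abs(ll - ll_old) < tol * (1 + abs(ll)):
            break
        ll_old = ll
    if m1 > m2:
        m1, m2, f1 = m2, m1, 1 - f1
    return f1, m1, 1 - f1, m2


def fit_mobility_mixture(steps: StepSample, dt_lag: float) -> MobilityFit:
    """Maximum-likelihood Rayleigh mixture fit of a step-size sample.

    Works on squared magnitudes, which are exponential with mean 4*D*dt per
    component, fit by EM. A single-component model is returned instead when
    it wins on BIC — the expected outcome for ligand in a bare bilayer
    before cells are added. Requires at least 50 displacements.
    """
    r = steps.dr
    if len(r) < 50:
        raise ValueError("need >= 50 displacements to fit a mixture")
    u = r.astype(float) ** 2
    if np.all(u == 0):
        raise ValueError("degenerate sample: all displacements are zero")
    n = len(u)
    # one-component exponential MLE
    m0 = u.mean()
    ll1 = float(np.sum(-np.log(m0) - u / m0))
    f1, m1, f2, m2 = _exp_mix_em(u)
    l1 = np.log(f1 / m1) - u / m1
    l2 = np.log(f2 / m2) - u / m2
    mx = np.maximum(l1, l2)
    ll2 = float(np.sum(mx + np.log(np.exp(l1 - mx) + np.exp(l2 - mx))))
    bic1 = -2 * ll1 + 1 * np.log(n)
    bic2 = -2 * ll2 + 3 * np.log(n)
    if bic1 <= bic2 or np.isclose(m1, m2, rtol=1e-3):
        d = m0 / (4 * dt_lag)
        return MobilityFit(1, 0.0, 1.0, 0.0, d, dt_lag, ll1, r_star=0.0)
    d_slow, d_fast = m1 / (4 * dt_lag), m2 / (4 * dt_lag)
    # posterior equality on the u scale: f1/m1 e^{-u/m1} = f2/m2 e^{-u/m2}
    u_star = np.log((f1 * m2) / (f2 * m1)) / (1 / m1 - 1 / m2)
    r_star = float(np.sqrt(max(u_star, 0.0)))
    return MobilityFit(2, f1, f2, d_slow, d_fast, dt_lag, ll2, r_star)


# ------------------------------------------------------ mobility classification

def classify_bound_segments(tracks: TrackSet, fit: MobilityFit,
                            window: int = 3) -> tuple[TrackSet, DwellSample]:
    """Label track samples FREE/BOUND and extract bound dwell events.

    Each sample's windowed mean consecutive-step magnitude is compared to
    the mixture crossover ``fit.r_star``: below means BOUND, at or above
    means FREE (ties break to FREE, the conservative choice for dwell
    times). Tracks shorter than ``window + 1`` samples are labeled UNKNOWN
    and excluded. Maximal BOUND runs become dwell events; an event is
    right/left-censored when it touches the movie boundary, and uncensored
    when it ends by reversion to FREE or by track disappearance
    (disappearance is unbinding-or-bleaching, resolved downstream by the
    photobleach correction).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if fit.n_components != 2:
        raise ValueError("classification needs a two-component mobility fit")
    meta = tracks.meta
    last_frame = meta.n_frames - 1
    durations, censored = [], []
    labeled = []
    for tr in tracks:
        n = len(tr)
        if n < window + 1:
            labels = np.array([UNKNOWN] * n, dtype=object)
            labeled.append(Track(tr.track_id, tr.frame, tr.t_s, tr.x_um,
                                 tr.y_um, tr.intensity, labels))
            continue
        step = np.hypot(np.diff(tr.x_um), np.diff(tr.y_um))
        # scale steps across gaps back to a one-frame equivalent
        gap = np.diff(tr.frame).astype(float)
        step = step / np.sqrt(gap)
        k = min(window, len(step))
        kern = np.ones(k) / k
        # trailing window (steps before sample i) and leading window (steps
        # after): a sample is BOUND when either side looks slow, so state
        # boundaries do not erode into whichever state the window straddles
        csum = np.concatenate([[0.0], np.cumsum(step)])
        n_steps = len(step)
        trail = np.empty(n)
        lead = np.empty(n)
        for i in range(n):
            a, b = max(i - k, 0), min(i, n_steps)
            trail[i] = (csum[b] - csum[a]) / (b - a) if b > a else np.inf
            a, b = min(i, n_steps), min(i + k, n_steps)
            lead[i] = (csum[b] - csum[a]) / (b - a) if b > a else np.inf
        lbl_step = np.minimum(trail, lead)
        labels = np.where(lbl_step < fit.r_star, BOUND, FREE).astype(object)
        labeled.append(Track(tr.track_id, tr.frame, tr.t_s, tr.x_um,
                             tr.y_um, tr.intensity, labels))
        # maximal BOUND runs -> dwell events
        is_b = labels == BOUND
        i = 0
        while i < n:
            if not is_b[i]:
                i += 1
                continue
            j = i
            while j + 1 < n and is_b[j + 1]:
                j += 1
            run_frames = tr.frame[j] - tr.frame[i] + 1
            durations.append(run_frames * meta.frame_interval)
            touches_start = tr.frame[i] == 0 and i == 0
            touches_end = tr.frame[j] == last_frame and j == n - 1
            censored.append(bool(touches_start or touches_end))
            i = j + 1
    dwells = DwellSample(np.array(durations), np.array(censored, dtype=bool),
                         source="classified")
    return TrackSet(labeled, meta), dwells
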