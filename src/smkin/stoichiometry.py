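"""Fluorophore-counting stoichiometry of kinase recruitment.

At each receptor-bound ligand position (the anchor, tracked in channel 1)
the intensity in the second channel — ZAP70-EGFP recruited to the
triggered receptor — is integrated over a fixed 315 nm (3 pixel) square
window, background-subtracted with a per-frame annulus median. Dividing
the mean feature intensity by the single-fluorophore unit intensity
(calibrated from one-step-bleaching traces in the same cell) gives the
number of visible fluorophores; dividing by the labeled fraction (EGFP
fusion expressed ~1:1 with the endogenous kinase, so 0.5 by default)
gives the total molecule count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .changepoint import ChangePointSet, count_photobleach_steps
from .core import IntensityTrace, TrackSet
from .registration import ChannelMap
from .sim import FrameStack

logger = logging.getLogger(__name__)

__all__ = ["StoichiometryResult", "integrate_local_intensity",
           "calibrate_single_molecule_intensity", "estimate_stoichiometry",
           "round_sig"]

# each receptor complex carries 10 ITAM sites, each able to bind one ZAP70;
# reported alongside results as context for the counts
ITAMS_PER_TCR = 10


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (reporting precision)."""
    if x == 0:
        return 0.0
    from math import floor, log10
    return round(x, -int(floor(log10(abs(x)))) + (sig - 1))


@dataclass
class StoichiometryResult:
    unit_intensity: float          # counts per molecule
    unit_sem: float
    feature_intensity: float       # mean feature counts
    feature_sem: float
    n_visible: float               # feature / unit
    n_visible_sem: float
    labeled_fraction: float
    n_total: float                 # n_visible / labeled_fraction
    n_total_sem: float

    def __post_init__(self) -> None:
        if self.unit_intensity <= 0:
            raise ValueError("unit_intensity must be positive")
        if not 0 < self.labeled_fraction <= 1:
            raise ValueError("labeled_fraction must be in (0, 1]")

    @property
    def n_visible_rounded(self) -> float:
        return round_sig(self.n_visible, 2)

    @property
    def n_total_rounded(self) -> float:
        return round_sig(self.n_total, 2)

    def to_dict(self) -> dict:
        d = {k: float(v) for k, v in self.__dict__.items()}
        d["n_visible_rounded"] = self.n_visible_rounded
        d["n_total_rounded"] = self.n_total_rounded
        d["itams_per_tcr"] = ITAMS_PER_TCR
        return d


def integrate_local_intensity(stack_ch2: FrameStack, anchors: TrackSet,
                              cmap: ChannelMap | None = None,
                              window_um: float = 0.315,
                              annulus_px: tuple[int, int] = (3, 6)
                              ) -> list[IntensityTrace]:
    """Integrate channel-2 intensity in a fixed window along each anchor.

    ``window_um`` must correspond to an odd pixel span (0.315 um = 3 px at
    105 nm). Anchor coordinates are mapped into the channel-2 frame with
    ``cmap`` (identity if None). Background per frame is the median of an
    annulus (inner/outer radius ``annulus_px``) around the window center
    and is subtracted per pixel. Frames missing from an anchor track
    yield NaN; anchors whose window ever clips the field edge are
    marked ``partial``.
    """
    meta = stack_ch2.meta
    px = meta.pixel_size
    wpx = int(round(window_um / px))
    if wpx % 2 == 0 or wpx < 1:
        raise ValueError(
            f"window_um={window_um} um spans {wpx} px at {px} um/px; "
            "an odd pixel span is required")
    half = wpx // 2
    r_in, r_out = annulus_px
    h, w = meta.field_size
    yy, xx = np.mgrid[-r_out:r_out + 1, -r_out:r_out + 1]
    ann = (np.hypot(xx, yy) >= r_in) & (np.hypot(xx, yy) <= r_out)
    traces = []
    for tr in anchors:
        coords = np.column_stack([tr.x_um, tr.y_um])
        mapped = cmap.apply(coords) if cmap is not None else coords
        f0, f1 = tr.frame[0], tr.frame[-1]
        frames = np.arange(f0, f1 + 1)
        vals = np.full(len(frames), np.nan)
        partial = False
        fidx = {f: i for i, f in enumerate(tr.frame)}
        for k, f in enumerate(frames):
            i = fidx.get(f)
            if i is None or f >= len(stack_ch2):
                continue
            cx = int(round(mapped[i, 0] / px))
            cy = int(round(mapped[i, 1] / px))
            if (cx - half < 0 or cx + half >= w or
                    cy - half < 0 or cy + half >= h):
                partial = True
                continue
            img = stack_ch2.data[f]
            ax0, ax1 = cx - r_out, cx + r_out + 1
            ay0, ay1 = cy - r_out, cy + r_out + 1
            m = ann
            if ax0 < 0 or ay0 < 0 or ax1 > w or ay1 > h:
                # clip the annulus, keep the window
                mx0, my0 = max(0, -ax0), max(0, -ay0)
                mx1 = m.shape[1] - max(0, ax1 - w)
                my1 = m.shape[0] - max(0, ay1 - h)
                m = m[my0:my1, mx0:mx1]
                ax0, ay0 = max(ax0, 0), max(ay0, 0)
                ax1, ay1 = min(ax1, w), min(ay1, h)
            bg = float(np.median(img[ay0:ay1, ax0:ax1][m]))
            win = img[cy - half:cy + half + 1, cx - half:cx + half + 1]
            vals[k] = float(np.sum(win - bg))
        traces.append(IntensityTrace(frames * meta.frame_interval, vals,
                                     partial=partial))
    return traces


def calibrate_single_molecule_intensity(traces: list[IntensityTrace],
                                        cps: list[ChangePointSet],
                                        background_level: float = 0.0
                                        ) -> tuple[float, float, int]:
    """Unit intensity from verified single-molecule bleach traces.

    A trace qualifies when its change points show exactly one downward
    step to background and no upward steps (single fluorophore); the unit
    is the mean pre-bleach level across qualifying traces, with SEM across
    traces. Multi-step (dimer) traces are rejected and logged.
    """
    if len(traces) != len(cps):
        raise ValueError("traces and change-point sets must pair up")
    levels = []
    for i, (trace, c) in enumerate(zip(traces, cps)):
        _, single = count_photobleach_steps(c, background_level)
        if not single:
            logger.info("calibration trace %d rejected: not single-step "
                        "(%d changes)", i, c.n_changes)
            continue
        levels.append(c.levels[0])
    if not levels:
        raise ValueError("no verified single-molecule traces for calibration")
    levels = np.asarray(levels, dtype=float)
    n = len(levels)
    sem = float(levels.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return float(levels.mean()), sem, n


def estimate_stoichiometry(feature_intensity_mean: float, unit: float,
                           labeled_fraction: float = 0.5,
                           feature_sem: float = 0.0,
                           unit_sem: float = 0.0) -> StoichiometryResult:
    """Convert feature intensity to molecule counts.

    n_visible = feature / unit; n_total = n_visible / labeled_fraction.
    SEMs propagate by the delta method (relative errors add in
    quadrature). The ratio is invariant to a global camera gain change,
    since feature and unit scale together.
    """
    if unit <= 0:
        raise ValueError("unit intensity must be positive")
    n_vis = feature_intensity_mean / unit
    rel = 0.0
    if feature_intensity_mean > 0:
        rel = np.sqrt((feature_sem / feature_intensity_mean) ** 2
                      + (unit_sem / unit) ** 2)
    n_vis_sem = abs(n_vis) * rel
    n_tot = n_vis / labeled_fraction
    return StoichiometryResult(unit, unit_sem, feature_intensity_mean,
                               feature_sem, n_vis, n_vis_sem,
                               labeled_fraction, n_tot,
                               n_vis_sem / labeled_fraction)
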