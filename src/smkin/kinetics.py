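"""Photobleach-corrected single-molecule dwell-time kinetics.

In a fluorescence tracking experiment a bound-state dwell ends either by
true unbinding (rate k_off = 1/tau_off) or by photobleaching of the label
(rate k_bl = 1/tau_bl); the two are indistinguishable frame by frame. For a
memoryless (Markov) binding model the observed dwell time is therefore the
minimum of two exponentials and is itself exponential:

    f(t) = (1/tau_bl + 1/tau_off) * exp(-t * (1/tau_bl + 1/tau_off))

with mean  <tau_obs> = (1/tau_off + 1/tau_bl)^-1.  Measuring the bleach
time on a bilayer standard (same fluorophore, no cells) lets the molecular
off time be recovered:

    1/tau_off = 1/tau_obs - 1/tau_bl,

valid as long as tau_obs < tau_bl. This module implements that observation
model, the exponential fits on both sides, and first-order (delta-method)
uncertainty propagation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import DwellSample

__all__ = ["KineticEstimate", "fit_exponential_mean", "fit_bleach_rate",
           "correct_dwell_time", "dwell_pdf", "estimate_kinetics",
           "BleachingDominatedError"]


class BleachingDominatedError(ValueError):
    """tau_obs >= tau_bl: the data are photobleaching-limited and the
    molecular off time is not identifiable."""


@dataclass
class KineticEstimate:
    """Dwell-time analysis summary: observed, bleach, and corrected scales."""

    tau_obs_mean: float
    tau_obs_sem: float
    tau_bl: float
    tau_bl_sem: float
    tau_off: float
    tau_off_sem: float
    n_events: int

    def to_dict(self) -> dict:
        return {k: (int(v) if k == "n_events" else float(v))
                for k, v in self.__dict__.items()}


def fit_exponential_mean(sample: DwellSample,
                         censor_policy: str = "exclude",
                         min_duration: float = 0.0,
                         n_bootstrap: int = 0,
                         seed: int = 0) -> tuple[float, float, int]:
    """Maximum-likelihood exponential mean of a dwell sample.

    censor_policy:
      - ``exclude``: drop censored events; MLE is the sample mean of the
        completed dwells, SEM = mean/sqrt(n) (exact for an exponential).
      - ``survival_mle``: Kaplan-Meier-free closed form for right-censored
        exponential data, MLE = (sum of all durations) / (# uncensored).

    ``min_duration`` discards events shorter than the detection floor (the
    shortest dwell the frame rate and classifier can resolve; spurious
    sub-resolution events otherwise bias the mean down). By the
    memorylessness of the exponential, the mean of events above a cutoff c
    is c + the true mean, so the estimator subtracts c — the truncation is
    bias-free for exponential dwells. Applies to the ``exclude`` policy.

    With ``n_bootstrap`` > 0 the SEM is replaced by the SD of bootstrap
    resample means (useful at small n).
    """
    if censor_policy not in ("exclude", "survival_mle"):
        raise ValueError(f"unknown censor_policy {censor_policy!r}")
    if censor_policy == "exclude":
        durs = sample.uncensored
        if min_duration > 0:
            durs = durs[durs >= min_duration]
        if durs.size == 0:
            raise ValueError("no uncensored events under policy 'exclude'")
        n_eff = durs.size
        mean = float(np.mean(durs)) - min_duration
        if mean <= 0:
            raise ValueError("all retained dwells at the detection floor; "
                             "mean is not estimable")
    else:
        if len(sample) == 0:
            raise ValueError("empty dwell sample")
        n_eff = int(np.sum(~sample.censored))
        if n_eff == 0:
            raise ValueError("survival MLE undefined with zero complete events")
        mean = float(np.sum(sample.durations) / n_eff)
    sem = mean / np.sqrt(n_eff)
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        durs = sample.uncensored if censor_policy == "exclude" else None
        boots = np.empty(n_bootstrap)
        for b in range(n_bootstrap):
            idx = rng.integers(0, len(sample), size=len(sample))
            d = sample.durations[idx]
            c = sample.censored[idx]
            if censor_policy == "exclude":
                dd = d[~c]
                dd = dd[dd >= min_duration]
                boots[b] = dd.mean() - min_duration if dd.size else np.nan
            else:
                k = np.sum(~c)
                boots[b] = d.sum() / k if k else np.nan
        sem = float(np.nanstd(boots, ddof=1))
    return mean, float(sem), n_eff


def fit_bleach_rate(bleach_sample: DwellSample | None = None,
                    decay_curve: tuple[np.ndarray, np.ndarray] | None = None
                    ) -> tuple[float, float]:
    """Photobleach rate from either lifetimes or a decay curve.

    - ``bleach_sample``: per-molecule disappearance times; MLE as in
      :func:`fit_exponential_mean` (survival form, so censoring at the
      movie end is handled).
    - ``decay_curve``: (t, f) samples of a background-subtracted ensemble
      bleaching curve; fit A*exp(-k_bl*t) by log-linear least squares.

    Returns ``(k_bl, tau_bl)`` with ``tau_bl = 1/k_bl``.
    """
    if (bleach_sample is None) == (decay_curve is None):
        raise ValueError("provide exactly one of bleach_sample or decay_curve")
    if bleach_sample is not None:
        mean, _, _ = fit_exponential_mean(bleach_sample, "survival_mle")
        return 1.0 / mean, mean
    t, f = (np.asarray(a, dtype=float) for a in decay_curve)
    if t.size < 2:
        raise ValueError("decay curve needs >= 2 points")
    if np.any(f <= 0):
        raise ValueError("decay curve must be positive for an exponential fit")
    slope, _ = np.polyfit(t, np.log(f), 1)
    k_bl = -slope
    if k_bl <= 0:
        raise ValueError("curve does not decay: bleach rate fit failed")
    return float(k_bl), float(1.0 / k_bl)


def correct_dwell_time(tau_obs: float, tau_obs_sem: float,
                       tau_bl: float, tau_bl_sem: float
                       ) -> tuple[float, float]:
    """Recover the molecular off time from the observed dwell mean.

    tau_off = (1/tau_obs - 1/tau_bl)^-1, with SEM by first-order error
    propagation over both inputs:

        d(tau_off)/d(tau_obs) = (tau_off/tau_obs)^2
        d(tau_off)/d(tau_bl)  = -(tau_off/tau_bl)^2

    ``tau_bl = inf`` is accepted and returns tau_obs unchanged (the
    no-bleaching limit). Raises :class:`BleachingDominatedError` when
    tau_obs >= tau_bl, where the correction diverges.
    """
    if tau_obs <= 0:
        raise ValueError("tau_obs must be positive")
    if np.isinf(tau_bl):
        return float(tau_obs), float(tau_obs_sem)
    if tau_bl <= 0:
        raise ValueError("tau_bl must be positive")
    if tau_obs >= tau_bl:
        raise BleachingDominatedError(
            f"tau_obs={tau_obs:g} >= tau_bl={tau_bl:g}: dwell times are "
            "bleaching-limited and tau_off is undefined")
    tau_off = 1.0 / (1.0 / tau_obs - 1.0 / tau_bl)
    var = ((tau_off / tau_obs) ** 2 * tau_obs_sem) ** 2 \
        + ((tau_off / tau_bl) ** 2 * tau_bl_sem) ** 2
    return float(tau_off), float(np.sqrt(var))


def dwell_pdf(t, tau_off: float, tau_bl: float):
    """Observed dwell-time density under competing unbinding and bleaching."""
    if tau_off <= 0 or tau_bl <= 0:
        raise ValueError("both time scales must be positive")
    rate = 1.0 / tau_off + (0.0 if np.isinf(tau_bl) else 1.0 / tau_bl)
    t = np.asarray(t, dtype=float)
    return rate * np.exp(-rate * t)


def estimate_kinetics(sample: DwellSample, tau_bl: float,
                      tau_bl_sem: float = 0.0,
                      censor_policy: str = "exclude",
                      min_duration: float = 0.0) -> KineticEstimate:
    """One-call pipeline: observed mean -> bleach correction -> estimate."""
    tau_obs, sem, n = fit_exponential_mean(sample, censor_policy,
                                           min_duration)
    tau_off, tau_off_sem = correct_dwell_time(tau_obs, sem, tau_bl, tau_bl_sem)
    return KineticEstimate(tau_obs, sem, tau_bl, tau_bl_sem,
                           tau_off, tau_off_sem, n)
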