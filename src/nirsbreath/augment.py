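"""Training-set augmentation: amplitude scaling, DC offset and horizontal flip.

The three operators keep the breathing *period* intact while diversifying the
amplitude, baseline and shape of training windows — the properties observed to
vary across participants. Their parameter ranges are not free knobs: they are
derived from extrema of the training dataset, so augmented windows stay inside
the envelope of signals the dataset actually contains.

For a training dataset ``D`` of windows ``d`` and a window ``I``:

* DC offset:       ``I + beta``, ``beta ~ U[min_D min(d) - min(I),
  max_D max(d) - max(I)]`` — the shifted window's extrema remain inside the
  dataset's global extrema.
* amplitude scale: ``I * gamma``, ``gamma ~ U[min_D ptp(d), max_D ptp(d)]``
  (literal mode, the printed formula) or ``gamma ~ U[min_D ptp(d)/ptp(I),
  max_D ptp(d)/ptp(I)]`` (ratio mode, which keeps the scaled window's
  peak-to-peak inside the dataset's observed range).
* horizontal flip: time reversal of all channels jointly, with probability 0.5.

The composite operator applies scale, then offset (with beta sampled from the
*scaled* window, matching the nesting of the composition), then flip.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .nirs_io import WindowedSample

__all__ = [
    "AugmentStats",
    "AugmentConfig",
    "compute_aug_stats",
    "sample_beta",
    "sample_gamma",
    "dc_offset",
    "amplitude_scale",
    "horizontal_flip",
    "augment",
    "augment_batch",
]

logger = logging.getLogger(__name__)


@dataclass
class AugmentStats:
    """Dataset-level extrema parameterizing the offset/scale sampling ranges.

    Each field is a scalar (pooled over channels) or a length-C vector
    (per-channel statistics). ``ptp`` is peak-to-peak amplitude, max - min.
    """

    min_of_min: np.ndarray
    max_of_min: np.ndarray
    min_of_max: np.ndarray
    max_of_max: np.ndarray
    min_ptp: np.ndarray
    max_ptp: np.ndarray
    per_channel: bool = True

    def __post_init__(self) -> None:
        for lo, hi in (
            (self.min_of_min, self.max_of_min),
            (self.min_of_max, self.max_of_max),
            (self.min_ptp, self.max_ptp),
        ):
            if np.any(np.asarray(lo) > np.asarray(hi)):
                raise ValueError("inverted extremum interval in AugmentStats")
        if np.any(np.asarray(self.min_ptp) < 0):
            raise ValueError("peak-to-peak amplitudes must be non-negative")


@dataclass
class AugmentConfig:
    flip_probability: float = 0.5
    per_channel: bool = True
    gamma_mode: str = "literal"  # or "ratio"

    def __post_init__(self) -> None:
        if not 0.0 <= self.flip_probability <= 1.0:
            raise ValueError("flip_probability must be in [0, 1]")
        if self.gamma_mode not in ("literal", "ratio"):
            raise ValueError("gamma_mode must be 'literal' or 'ratio'")


def compute_aug_stats(
    train: Sequence[WindowedSample],
    per_channel: bool = True,
    forbid_participants: set[str] | None = None,
) -> AugmentStats:
    """Compute dataset extrema over the training split.

    ``forbid_participants`` is a leakage guard: pass the held-out participant
    ids and the call raises if any of their windows slipped into ``train``.
    """
    if not train:
        raise ValueError("cannot compute augmentation statistics of an empty dataset")
    if forbid_participants:
        leaked = {s.participant_id for s in train} & set(forbid_participants)
        if leaked:
            raise ValueError(
                f"augmentation statistics would leak held-out participants {sorted(leaked)}"
            )
    X = np.stack([s.data for s in train])  # (N, C, L)
    axis = 2 if per_channel else (1, 2)
    mins = X.min(axis=axis)  # (N, C) or (N,)
    maxs = X.max(axis=axis)
    ptps = maxs - mins
    return AugmentStats(
        min_of_min=mins.min(axis=0),
        max_of_min=mins.max(axis=0),
        min_of_max=maxs.min(axis=0),
        max_of_max=maxs.max(axis=0),
        min_ptp=ptps.min(axis=0),
        max_ptp=ptps.max(axis=0),
        per_channel=per_channel,
    )


def _window_minmax(data: np.ndarray, per_channel: bool) -> tuple[np.ndarray, np.ndarray]:
    if per_channel:
        return data.min(axis=1), data.max(axis=1)
    return np.asarray(data.min()), np.asarray(data.max())


def sample_beta(
    stats: AugmentStats,
    window: WindowedSample | np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw a DC offset uniformly from the dataset-envelope interval.

    The interval is ``[min_of_min - min(I), max_of_max - max(I)]``; any drawn
    beta therefore keeps the shifted window inside the dataset's global
    extrema. For a window whose own range spans the dataset envelope the
    interval can invert; it is then clamped to {0} (identity) with a log note.
    """
    data = window.data if isinstance(window, WindowedSample) else np.asarray(window)
    wmin, wmax = _window_minmax(data, stats.per_channel)
    lo = np.asarray(stats.min_of_min - wmin, dtype=float)
    hi = np.asarray(stats.max_of_max - wmax, dtype=float)
    beta = np.where(lo <= hi, rng.uniform(np.minimum(lo, hi), np.maximum(lo, hi)), 0.0)
    if np.any(lo > hi):
        logger.debug("inverted beta interval clamped to 0 for extreme-range window")
    return beta


def sample_gamma(
    stats: AugmentStats,
    rng: np.random.Generator,
    mode: str = "literal",
    window: WindowedSample | np.ndarray | None = None,
) -> np.ndarray:
    """Draw an amplitude scale uniformly from the dataset peak-to-peak range.

    ``literal`` draws gamma directly from ``[min_ptp, max_ptp]``. ``ratio``
    divides that interval by the window's own peak-to-peak so the *scaled*
    window's amplitude lands inside the dataset range; it requires ``window``.
    An all-constant dataset (zero peak-to-peak everywhere) degenerates to
    gamma = 1 with a warning.
    """
    lo = np.asarray(stats.min_ptp, dtype=float)
    hi = np.asarray(stats.max_ptp, dtype=float)
    if np.all(hi == 0):
        logger.warning("all-constant dataset: amplitude scale fixed to 1")
        return np.ones_like(lo)
    if mode == "ratio":
        if window is None:
            raise ValueError("ratio mode requires the window being augmented")
        data = window.data if isinstance(window, WindowedSample) else np.asarray(window)
        wmin, wmax = _window_minmax(data, stats.per_channel)
        ptp = np.asarray(wmax - wmin, dtype=float)
        safe = np.where(ptp > 0, ptp, 1.0)
        lo, hi = lo / safe, hi / safe
    elif mode != "literal":
        raise ValueError("mode must be 'literal' or 'ratio'")
    return rng.uniform(lo, hi)


def _broadcast(param: np.ndarray | float, data: np.ndarray) -> np.ndarray:
    p = np.asarray(param, dtype=float)
    if p.ndim == 1:
        return p[:, None]
    return p


def dc_offset(window: WindowedSample, beta: np.ndarray | float) -> WindowedSample:
    """Add a constant baseline shift (scalar or per-channel) to every sample."""
    return WindowedSample(
        data=window.data + _broadcast(beta, window.data),
        label=window.label,
        participant_id=window.participant_id,
        start_index=window.start_index,
    )


def amplitude_scale(window: WindowedSample, gamma: np.ndarray | float) -> WindowedSample:
    """Multiply the window elementwise by a scalar or per-channel scale."""
    return WindowedSample(
        data=window.data * _broadcast(gamma, window.data),
        label=window.label,
        participant_id=window.participant_id,
        start_index=window.start_index,
    )


def horizontal_flip(
    window: WindowedSample,
    rng: np.random.Generator | None = None,
    p: float = 0.5,
    force: bool | None = None,
) -> WindowedSample:
    """Reverse the temporal order of all channels jointly with probability p."""
    if force is None:
        if rng is None:
            raise ValueError("provide rng or force")
        do_flip = rng.random() < p
    else:
        do_flip = force
    data = window.data[:, ::-1].copy() if do_flip else window.data.copy()
    return WindowedSample(
        data=data,
        label=window.label,
        participant_id=window.participant_id,
        start_index=window.start_index,
    )


def augment_batch(
    X: np.ndarray,
    stats: AugmentStats,
    cfg: AugmentConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized composite operator on a stacked batch ``(N, C, L)``.

    Applies the same scale -> offset -> flip composition as :func:`augment`,
    with independent draws per window (and per channel when the statistics are
    per-channel). Used by the training loop; algebraically equivalent to
    applying the per-window operators sample by sample.
    """
    X = np.asarray(X, dtype=float)
    N, C, _ = X.shape
    shape = (N, C) if stats.per_channel else (N,)

    lo_g = np.broadcast_to(np.asarray(stats.min_ptp, dtype=float), shape)
    hi_g = np.broadcast_to(np.asarray(stats.max_ptp, dtype=float), shape)
    if np.all(hi_g == 0):
        gamma = np.ones(shape)
    elif cfg.gamma_mode == "ratio":
        axis = 2 if stats.per_channel else (1, 2)
        ptp = X.max(axis=axis) - X.min(axis=axis)
        safe = np.where(ptp > 0, ptp, 1.0)
        gamma = rng.uniform(lo_g / safe, hi_g / safe)
    else:
        gamma = rng.uniform(lo_g, hi_g)
    out = X * (gamma[:, :, None] if stats.per_channel else gamma[:, None, None])

    axis = 2 if stats.per_channel else (1, 2)
    smin = out.min(axis=axis)
    smax = out.max(axis=axis)
    lo_b = np.asarray(stats.min_of_min, dtype=float) - smin
    hi_b = np.asarray(stats.max_of_max, dtype=float) - smax
    beta = np.where(
        lo_b <= hi_b,
        rng.uniform(np.minimum(lo_b, hi_b), np.maximum(lo_b, hi_b)),
        0.0,
    )
    out = out + (beta[:, :, None] if stats.per_channel else beta[:, None, None])

    flip = rng.random(N) < cfg.flip_probability
    out[flip] = out[flip, :, ::-1]
    return out


def augment(
    window: WindowedSample,
    stats: AugmentStats,
    cfg: AugmentConfig,
    rng: np.random.Generator,
) -> WindowedSample:
    """Composite operator: scale, then DC offset, then flip.

    The offset is sampled against the *scaled* window, per the nesting of the
    composition — each inner operator's output is the outer operator's input.
    """
    gamma = sample_gamma(stats, rng, mode=cfg.gamma_mode, window=window)
    out = amplitude_scale(window, gamma)
    beta = sample_beta(stats, out, rng)
    out = dc_offset(out, beta)
    out = horizontal_flip(out, rng, p=cfg.flip_probability)
    return out
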