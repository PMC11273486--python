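"""Impulse-noise removal for NIRS recordings.

Wearable NIRS electronics produce occasional voltage-transient spikes. These
are detected per channel from the first derivative of the signal: a sample is
flagged as impulse noise when its forward difference deviates from the mean
difference by more than the two-sided normal quantile of the configured
confidence level (1.6449 standard deviations at 90%). Flagged samples are
either deleted or replaced by linear interpolation from the nearest clean
neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .nirs_io import NIRSRecording

__all__ = ["ImpulseFilterConfig", "remove_impulse_noise", "flag_impulse_samples"]


@dataclass
class ImpulseFilterConfig:
    """Configuration of the derivative confidence-interval rule.

    confidence : two-sided coverage of the acceptance interval, in (0, 1).
    mode : ``"delete"`` removes flagged samples (shortening the series);
        ``"interpolate"`` replaces them, preserving length, which windowing
        prefers because it keeps the time base gap-free.
    """

    confidence: float = 0.90
    mode: str = "delete"

    def __post_init__(self) -> None:
        if not 0.0 < self.confidence < 1.0:
            raise ValueError("confidence must be in (0, 1)")
        if self.mode not in ("delete", "interpolate"):
            raise ValueError("mode must be 'delete' or 'interpolate'")

    @property
    def z(self) -> float:
        """Two-sided normal quantile for the configured coverage."""
        return float(stats.norm.ppf(0.5 + self.confidence / 2.0))


def flag_impulse_samples(x: np.ndarray, confidence: float = 0.90) -> np.ndarray:
    """Return indices of samples flagged as impulse noise in a 1D signal.

    The forward difference ``d[t] = x[t+1] - x[t]`` is computed once; its mean
    and standard deviation define the acceptance interval. The *later* sample
    ``x[t+1]`` bounding an outlying difference is flagged, since an impulse
    onset manifests in the forward difference into the corrupted sample.
    A zero-variance derivative (e.g. a constant signal) flags nothing.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1D signal")
    if x.size < 3:
        raise ValueError("signal too short for derivative statistics (need >= 3)")
    d = np.diff(x)
    mu = d.mean()
    sigma = d.std()  # population STD over all derivative values
    if sigma == 0.0:
        return np.empty(0, dtype=int)
    z = float(stats.norm.ppf(0.5 + confidence / 2.0))
    out = np.flatnonzero(np.abs(d - mu) > z * sigma) + 1
    return out


def remove_impulse_noise(
    rec: NIRSRecording, cfg: ImpulseFilterConfig | None = None
) -> tuple[NIRSRecording, dict[str, np.ndarray]]:
    """Apply the derivative confidence-interval rule per channel.

    Returns the cleaned recording and a mapping channel name -> flagged sample
    indices (indices into the *input* recording).

    In ``delete`` mode the union of flagged indices across channels is removed
    from every channel so that channels stay time-aligned. In ``interpolate``
    mode each channel's flagged samples are replaced by linear interpolation
    from its own nearest unflagged neighbours and length is preserved.
    """
    cfg = cfg or ImpulseFilterConfig()
    if rec.n_samples < 3:
        raise ValueError("recording too short for impulse filtering (need >= 3)")

    flagged: dict[str, np.ndarray] = {}
    for name, x in zip(rec.channels, rec.values):
        flagged[name] = flag_impulse_samples(x, cfg.confidence)

    n = rec.n_samples
    if cfg.mode == "delete":
        union = np.unique(np.concatenate(list(flagged.values()))) if flagged else []
        union = np.asarray(union, dtype=int)
        if union.size >= n:
            raise ValueError("all samples flagged as noise: pathological input")
        keep = np.setdiff1d(np.arange(n), union)
        values = rec.values[:, keep]
    else:
        values = rec.values.copy()
        t = np.arange(n)
        for i, name in enumerate(rec.channels):
            idx = flagged[name]
            if idx.size == 0:
                continue
            if idx.size >= n:
                raise ValueError("all samples flagged as noise: pathological input")
            good = np.setdiff1d(t, idx)
            values[i, idx] = np.interp(idx, good, values[i, good])

    cleaned = NIRSRecording(
        values=values,
        channels=rec.channels,
        sampling_rate=rec.sampling_rate,
        participant_id=rec.participant_id,
        task_label=rec.task_label,
    )
    return cleaned, flagged
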