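"""Raw-EMG conditioning: band-pass, rectify, low-pass, normalize.

The processing chain follows the standard gait-lab recipe: zero-phase
second-order Butterworth band-pass (30-450 Hz), full-wave rectification,
zero-phase second-order Butterworth low-pass (6 Hz), then per-subject-muscle
normalization to the maximum processed value over all recorded trials.  The
normalized envelope is the *excitation* driving activation dynamics and must
lie in [0, 1].

"Second-order" refers to the designed filter; zero-phase forward-backward
application doubles the effective order.  Edges are handled by reflective
padding so short stance records do not carry start/end transients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import butter, filtfilt

__all__ = ["Envelope", "process_raw_emg", "normalize_envelopes"]

BAND_EDGES_HZ = (30.0, 450.0)
LOWPASS_HZ = 6.0
FILTER_ORDER = 2


@dataclass
class Envelope:
    """Processed EMG envelope for one muscle in one trial."""

    values: np.ndarray
    rate: float
    #: across-trial maximum used for normalization (1.0 once normalized)
    reference: float | None = None
    muscle: str = ""
    meta: dict = field(default_factory=dict)


def _padlen(b: np.ndarray, a: np.ndarray) -> int:
    return 3 * max(len(a), len(b))


def process_raw_emg(
    raw: np.ndarray,
    rate: float,
    *,
    band: tuple[float, float] = BAND_EDGES_HZ,
    lowpass: float = LOWPASS_HZ,
    order: int = FILTER_ORDER,
) -> np.ndarray:
    """Band-pass, full-wave rectify and low-pass a raw EMG record.

    Parameters
    ----------
    raw : array
        Raw EMG samples (any units; the chain is linear up to rectification).
    rate : float
        Sampling rate in Hz.  Must exceed twice the band-pass upper edge.

    Returns
    -------
    array
        Unnormalized envelope, same length as the input, clipped at 0
        (low-pass undershoot would otherwise produce small negative values).
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 1:
        raise ValueError("raw EMG must be a 1-D series")
    if rate <= 2.0 * band[1]:
        raise ValueError(
            f"sampling rate {rate} Hz too low for a {band[1]} Hz band edge "
            f"(need rate > {2.0 * band[1]} Hz)"
        )

    b_bp, a_bp = butter(order, band, btype="bandpass", fs=rate)
    b_lp, a_lp = butter(order, lowpass, btype="lowpass", fs=rate)
    min_len = max(_padlen(b_bp, a_bp), _padlen(b_lp, a_lp)) + 1
    if raw.size < min_len:
        raise ValueError(
            f"signal of {raw.size} samples is shorter than the filter "
            f"warm-up requirement ({min_len} samples)"
        )

    banded = filtfilt(b_bp, a_bp, raw, padtype="even", padlen=min_len - 1)
    rect = np.abs(banded)
    env = filtfilt(b_lp, a_lp, rect, padtype="even", padlen=min_len - 1)
    return np.clip(env, 0.0, None)


def normalize_envelopes(envelopes: Sequence[np.ndarray]) -> tuple[list[np.ndarray], float]:
    """Normalize a subject-muscle collection of envelopes by its global maximum.

    Every trial is divided by the single maximum processed value across all
    trials, so outputs lie in [0, 1] and at least one sample somewhere in the
    collection equals exactly 1.

    Returns the normalized envelopes and the reference maximum.

    Raises
    ------
    ValueError
        If the collection is empty or its global maximum is not strictly
        positive (division by zero is reported, never silently propagated
        as NaN).
    """
    if len(envelopes) == 0:
        raise ValueError("no envelopes to normalize")
    arrays = [np.asarray(e, dtype=float) for e in envelopes]
    reference = max(float(a.max()) for a in arrays)
    if not reference > 0.0:
        raise ValueError(
            "cannot normalize: maximum processed value over the collection "
            "is not strictly positive"
        )
    return [a / reference for a in arrays], reference
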