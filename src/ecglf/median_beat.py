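"""Median-beat derivation, standardisation, alignment, filtering and splits.

The processing chain mirrors the preprocessing applied before latent-factor
modelling: 8-lead selection (lead III and the augmented limb leads are
linear combinations of I and II and are dropped), per-lead elementwise
median over R-aligned beat windows, cropping/zero-padding to 0.8 s at
500 Hz, cross-correlation alignment against a reference, exclusion of
records with extreme voltages outside +/- 8 mV, and a subject-disjoint
random train/validation/test split.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from ecglf.containers import (
    BEAT_SAMPLES,
    LEAD_NAMES,
    SAMPLING_RATE,
    VOLTAGE_LIMIT_MV,
    MedianBeatSet,
    RawECGSet,
)

__all__ = [
    "select_leads",
    "detect_r_peaks",
    "derive_median_beat",
    "standardise_length",
    "align_by_crosscorr",
    "filter_extreme_voltage",
    "split_dataset",
    "SignalQualityError",
]

#: sample index of the R peak in the standard 400-sample window
R_WINDOW_OFFSET = 150


class SignalQualityError(ValueError):
    """Raised when a raw signal does not support median-beat derivation."""


def select_leads(record: dict | pd.DataFrame) -> np.ndarray:
    """Reduce a (>= 8)-lead record to the canonical [I, II, V1..V6] order.

    Parameters
    ----------
    record : mapping of lead name -> 1-D trace, or DataFrame with lead columns.

    Returns
    -------
    ndarray, shape (8, n_samples)
    """
    if isinstance(record, pd.DataFrame):
        record = {c: record[c].to_numpy() for c in record.columns}
    traces = []
    for lead in LEAD_NAMES:
        if lead not in record:
            raise ValueError(f"missing lead {lead}")
        traces.append(np.asarray(record[lead], dtype=float))
    lengths = {t.shape[0] for t in traces}
    if len(lengths) != 1:
        raise ValueError("leads have unequal lengths")
    return np.stack(traces)


def detect_r_peaks(signal: np.ndarray, fs: int = SAMPLING_RATE) -> np.ndarray:
    """Derivative-plus-threshold R-peak detector.

    Operates on lead II of an (8, n) array (fallback: the max-amplitude
    lead when lead II is flat).  Samples where the absolute derivative
    exceeds half its maximum gate candidate QRS regions; the local absolute
    maximum of each gated region is the R peak.  Peaks closer than 200 ms
    are merged.
    """
    signal = np.atleast_2d(np.asarray(signal, dtype=float))
    lead = signal[1] if signal.shape[0] > 1 else signal[0]
    if np.ptp(lead) == 0:
        amps = np.ptp(signal, axis=1)
        if amps.max() == 0:
            raise SignalQualityError("flat signal: no beats detectable")
        lead = signal[int(np.argmax(amps))]
    deriv = np.abs(np.gradient(lead))
    gate = deriv > 0.5 * deriv.max()
    if not gate.any():
        raise SignalQualityError("no QRS-like activity found")
    min_dist = int(0.2 * fs)
    env = np.abs(lead) * gate
    peaks, _ = find_peaks(env, height=0.4 * np.abs(lead).max(), distance=min_dist)
    if peaks.size == 0:
        raise SignalQualityError("no QRS-like activity found")
    # refine each gated candidate to the local |lead| maximum
    refined = []
    half = int(0.05 * fs)
    for p in peaks:
        lo, hi = max(p - half, 0), min(p + half + 1, lead.size)
        refined.append(lo + int(np.argmax(np.abs(lead[lo:hi]))))
    return np.unique(refined)


def derive_median_beat(
    raw: np.ndarray,
    fs: int = SAMPLING_RATE,
    window: int = BEAT_SAMPLES,
    r_offset: int = R_WINDOW_OFFSET,
) -> np.ndarray:
    """Per-sample median of R-aligned beat windows of one raw record.

    Parameters
    ----------
    raw : ndarray, shape (8, n_samples)
    window, r_offset : extracted window length and the R-peak position in it.

    Returns
    -------
    ndarray, shape (8, window)

    Raises
    ------
    SignalQualityError
        If fewer than three full beat windows can be extracted.
    """
    raw = np.asarray(raw, dtype=float)
    peaks = detect_r_peaks(raw, fs=fs)
    segments = []
    for p in peaks:
        start = p - r_offset
        if start < 0 or start + window > raw.shape[1]:
            continue
        segments.append(raw[:, start:start + window])
    if len(segments) < 3:
        raise SignalQualityError(
            f"only {len(segments)} complete beats detected; at least 3 required"
        )
    return np.median(np.stack(segments), axis=0)


def standardise_length(beat: np.ndarray, r_index: int | None = None,
                       target: int = BEAT_SAMPLES) -> np.ndarray:
    """Crop or zero-pad a beat to exactly ``target`` samples.

    Longer beats are cropped symmetrically about the R peak (detected as the
    maximum of the cross-lead RMS when ``r_index`` is not given), keeping
    the R-peak sample inside the window.  Shorter beats are zero-padded on
    both ends; an odd deficit puts the extra zero at the end.
    """
    beat = np.atleast_2d(np.asarray(beat, dtype=float))
    n = beat.shape[1]
    if n == 0:
        raise ValueError("empty beat")
    if n == target:
        return beat
    if n > target:
        if r_index is None:
            r_index = int(np.argmax(np.sqrt((beat**2).mean(axis=0))))
        start = int(np.clip(r_index - target // 2, 0, n - target))
        return beat[:, start:start + target]
    deficit = target - n
    front = deficit // 2
    back = deficit - front
    return np.pad(beat, ((0, 0), (front, back)))


def _alignment_trace(beats: np.ndarray) -> np.ndarray:
    """Summed absolute voltage across leads — the signal driving alignment."""
    return np.abs(beats).sum(axis=-2)


def best_circular_lag(trace: np.ndarray, reference: np.ndarray) -> int:
    """Lag in [-n/2, n/2) maximising circular cross-correlation; ties break
    toward the smallest absolute lag."""
    n = trace.shape[-1]
    corr = np.fft.irfft(np.fft.rfft(reference) * np.conj(np.fft.rfft(trace)), n=n)
    # corr[k] = sum_t reference[t] * trace[t - k]: shifting trace by +k aligns it
    lags = np.where(np.arange(n) < n - n // 2, np.arange(n), np.arange(n) - n)
    scale = np.max(np.abs(corr))
    key = np.round(corr / scale, 9) if scale > 0 else corr
    order = np.lexsort((np.abs(lags), -key))
    return int(lags[order[0]])


def align_by_crosscorr(beats: MedianBeatSet, reference: np.ndarray) -> MedianBeatSet:
    """Circularly shift every record to maximise cross-correlation with a
    reference beat.

    The correlation is computed between the summed-absolute-lead trace of
    each record and that of the reference; ties break toward the smallest
    absolute lag.  Circular shifts preserve the 400-sample length.
    """
    reference = np.atleast_2d(np.asarray(reference, dtype=float))
    if reference.shape != beats.beats.shape[1:]:
        raise ValueError("reference must match the beat shape (8, 400)")
    ref_trace = _alignment_trace(reference)
    aligned = np.empty_like(beats.beats)
    for i in range(beats.n):
        lag = best_circular_lag(_alignment_trace(beats.beats[i]), ref_trace)
        aligned[i] = np.roll(beats.beats[i], lag, axis=-1)
    return MedianBeatSet(aligned, beats.subject_ids, beats.sampling_rate, beats.lead_names)


def filter_extreme_voltage(
    beats: MedianBeatSet, limit: float = VOLTAGE_LIMIT_MV
) -> tuple[MedianBeatSet, pd.DataFrame]:
    """Drop records with any sample strictly outside [-limit, +limit] mV.

    Returns the retained set and an exclusion report listing, per excluded
    record, the first offending lead/sample and its voltage.  Samples at
    exactly the bound are retained (the bounds are strict).
    """
    bad = (beats.beats < -limit) | (beats.beats > limit)
    keep = ~bad.any(axis=(1, 2))
    rows = []
    for i in np.flatnonzero(~keep):
        lead_idx, sample_idx = np.argwhere(bad[i])[0]
        rows.append(
            {
                "subject_id": beats.subject_ids[i],
                "lead": beats.lead_names[lead_idx],
                "sample": int(sample_idx),
                "voltage_mv": float(beats.beats[i, lead_idx, sample_idx]),
            }
        )
    report = pd.DataFrame(rows, columns=["subject_id", "lead", "sample", "voltage_mv"])
    return beats.subset(keep), report


def split_dataset(
    subject_ids: np.ndarray | MedianBeatSet,
    fractions: tuple[float, float, float] = (0.9, 0.05, 0.05),
    seed: int = 0,
) -> pd.Series:
    """Random subject-disjoint train/val/test assignment.

    All records of a subject share a partition.  Subject counts match the
    requested fractions to within one subject (largest-remainder rounding).

    Returns
    -------
    Series mapping subject_id -> partition in {"train", "val", "test"}.
    """
    if isinstance(subject_ids, MedianBeatSet):
        subject_ids = subject_ids.subject_ids
    fractions = np.asarray(fractions, dtype=float)
    if (fractions < 0).any():
        raise ValueError("fractions must be nonnegative")
    if not np.isclose(fractions.sum(), 1.0):
        raise ValueError("fractions must sum to 1")
    subjects = np.unique(np.asarray(subject_ids))
    rng = np.random.default_rng(seed)
    rng.shuffle(subjects)
    n = subjects.size
    raw = fractions * n
    counts = np.floor(raw).astype(int)
    for k in np.argsort(-(raw - counts)):
        if counts.sum() == n:
            break
        counts[k] += 1
    labels = np.repeat(["train", "val", "test"], counts)
    return pd.Series(labels, index=subjects, name="partition")
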