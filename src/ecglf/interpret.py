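"""Model interpretation: latent traversals, correlation heatmaps,
conventional ECG parameter measurement and group-stratified reconstructions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ecglf.containers import BEAT_SAMPLES, LatentRepresentation, MedianBeatSet
from ecglf.vae import BetaVAE

__all__ = [
    "TraversalGrid",
    "latent_traversal",
    "lf_correlation_matrix",
    "measure_conventional_params",
    "stratified_reconstruction",
    "plot_traversal",
]

MS_PER_SAMPLE = 2.0

#: fiducial detector constants: the activity threshold sits this many
#: median absolute deviations above the baseline (median) of the composite;
#: segments closer than the merge gap coalesce, shorter ones are discarded
FIDUCIAL_MAD_MULT = 3.0
FIDUCIAL_MIN_THRESHOLD = 1e-9
SEGMENT_MERGE_MS = 10.0
SEGMENT_MIN_MS = 20.0


@dataclass
class TraversalGrid:
    """Decoded beats obtained by sweeping one latent factor.

    ``beats[i]`` is the decode of the population-mean latent vector with
    dimension ``lf_index`` displaced by ``offsets[i]`` standard deviations.
    """

    lf_index: int
    offsets: np.ndarray
    beats: np.ndarray          # (n_offsets, 8, 400)
    baseline: np.ndarray       # population-mean latent vector


def latent_traversal(
    model: BetaVAE,
    latents: LatentRepresentation | np.ndarray,
    lf_index: int,
    offsets=tuple(range(-3, 4)),
) -> TraversalGrid:
    """Decode the mean latent vector while sweeping one dimension.

    ``offsets`` are in units of the across-subject SD of that latent
    (default -3..+3).  Sweeping an inactive latent emits a warning but the
    grid is still produced.
    """
    mu = latents.mu if isinstance(latents, LatentRepresentation) else np.asarray(latents)
    offsets = np.asarray(list(offsets), dtype=float)
    if 0.0 not in offsets:
        raise ValueError("offsets must include 0 (the baseline)")
    if not (0 <= lf_index < mu.shape[1]):
        raise ValueError(f"lf_index {lf_index} out of range")
    if isinstance(latents, LatentRepresentation) and latents.active_set.size:
        if lf_index not in latents.active_set:
            warnings.warn(f"latent {lf_index} is inactive; traversal may be flat")
    baseline = mu.mean(axis=0)
    sd = mu[:, lf_index].std()
    grid = np.tile(baseline, (offsets.size, 1))
    grid[:, lf_index] = baseline[lf_index] + offsets * sd
    return TraversalGrid(lf_index, offsets, model.inverse_transform(grid), baseline)


def lf_correlation_matrix(
    latents: LatentRepresentation | pd.DataFrame,
    other_traits: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Pairwise Pearson correlations between latent factors (and optional
    additional traits), with pairwise-complete observation handling.

    Zero-variance columns produce NaN entries and a warning.  The LF x LF
    block is symmetric with unit diagonal.
    """
    if isinstance(latents, LatentRepresentation):
        df = latents.to_frame().drop(columns="subject_id")
    else:
        df = latents.drop(columns="subject_id", errors="ignore").copy()
    if other_traits is not None:
        other = other_traits.drop(columns="subject_id", errors="ignore").reset_index(drop=True)
        df = pd.concat([df.reset_index(drop=True), other], axis=1)
    degenerate = [c for c in df.columns if df[c].std(skipna=True) == 0]
    if degenerate:
        warnings.warn(f"zero-variance columns give undefined correlations: {degenerate}")
    n_complete = df.notna().to_numpy().astype(int)
    if (n_complete.T @ n_complete < 3).any():
        warnings.warn("some pairs have fewer than 3 complete observations")
    return df.corr(method="pearson", min_periods=3)


def plot_traversal(grid: TraversalGrid, lead: int = 0, path=None):
    """Plot one lead of a traversal grid: red for negative offsets, blue
    for positive, black for the baseline.  Saves to ``path`` when given and
    returns the matplotlib figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3))
    t = np.arange(grid.beats.shape[-1]) * MS_PER_SAMPLE
    max_off = max(np.abs(grid.offsets).max(), 1.0)
    for k, off in enumerate(grid.offsets):
        if off == 0:
            colour, alpha = "black", 1.0
        elif off < 0:
            colour, alpha = "tab:red", abs(off) / max_off
        else:
            colour, alpha = "tab:blue", off / max_off
        ax.plot(t, grid.beats[k, lead], color=colour, alpha=0.3 + 0.7 * alpha, lw=1)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("voltage (mV)")
    ax.set_title(f"latent factor {grid.lf_index + 1}")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig


# ---------------------------------------------------------------------------
# conventional ECG parameters
# ---------------------------------------------------------------------------

def _wave_segments(composite: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous supra-threshold segments of the composite trace.

    The threshold adapts to the baseline: the median composite amplitude
    plus a multiple of its median absolute deviation (both zero on
    noiseless compact-support beats, so segment edges then coincide with
    the true wave onsets/offsets).
    """
    med = float(np.median(composite))
    mad = float(np.median(np.abs(composite - med)))
    threshold = max(FIDUCIAL_MIN_THRESHOLD, med + FIDUCIAL_MAD_MULT * mad)
    active = composite > threshold
    if not active.any():
        return []
    edges = np.diff(active.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if active[0]:
        starts.insert(0, 0)
    if active[-1]:
        ends.append(active.size)
    segments = list(zip(starts, ends))
    # merge fragments split by noise, then drop blips
    merged = [segments[0]]
    gap = SEGMENT_MERGE_MS / MS_PER_SAMPLE
    for s, e in segments[1:]:
        if s - merged[-1][1] <= gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    min_len = SEGMENT_MIN_MS / MS_PER_SAMPLE
    return [(s, e) for s, e in merged if e - s >= min_len]


def measure_conventional_params(
    beats: MedianBeatSet | np.ndarray,
    rr_ms: np.ndarray | float | None = None,
) -> pd.DataFrame:
    """Measure PR, QRS and QT intervals (and QTc when RR is supplied).

    Fiducials are located on the root-mean-square composite of the 8 leads:
    supra-threshold segments are classified as P wave (last segment before
    the QRS), QRS complex (segment containing the R peak) and T wave (first
    segment after).  PR = P onset to QRS onset, QRS = QRS onset to offset,
    QT = QRS onset to T offset; QTc uses the Bazett correction
    QT / sqrt(RR in s).  Undetectable waves yield missing values with a
    warning, never an exception.
    """
    arr = beats.beats if isinstance(beats, MedianBeatSet) else np.asarray(beats, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    n = arr.shape[0]
    if rr_ms is not None:
        rr_ms = np.broadcast_to(np.asarray(rr_ms, dtype=float), (n,))
    rows = []
    n_missing = 0
    for i in range(n):
        composite = np.sqrt((arr[i] ** 2).mean(axis=0))
        row = {k: np.nan for k in ("pr_ms", "qrs_ms", "qt_ms", "qtc_ms",
                                   "p_amp_mv", "r_amp_mv", "t_amp_mv")}
        segments = _wave_segments(composite)
        if segments:
            r_idx = int(np.argmax(composite))
            qrs = next(((s, e) for s, e in segments if s <= r_idx < e), None)
            if qrs is not None:
                before = [seg for seg in segments if seg[1] <= qrs[0]]
                after = [seg for seg in segments if seg[0] >= qrs[1]]
                row["qrs_ms"] = (qrs[1] - qrs[0]) * MS_PER_SAMPLE
                row["r_amp_mv"] = float(composite[r_idx])
                if before:
                    p = before[-1]
                    row["pr_ms"] = (qrs[0] - p[0]) * MS_PER_SAMPLE
                    row["p_amp_mv"] = float(composite[p[0]:p[1]].max())
                if after:
                    t = after[0]
                    row["qt_ms"] = (t[1] - qrs[0]) * MS_PER_SAMPLE
                    row["t_amp_mv"] = float(composite[t[0]:t[1]].max())
                    if rr_ms is not None and np.isfinite(rr_ms[i]) and rr_ms[i] > 0:
                        row["qtc_ms"] = row["qt_ms"] / np.sqrt(rr_ms[i] / 1000.0)
        if np.isnan(row["qrs_ms"]):
            n_missing += 1
        rows.append(row)
    if n_missing:
        warnings.warn(f"{n_missing} of {n} records had undetectable waves")
    out = pd.DataFrame(rows)
    if isinstance(beats, MedianBeatSet):
        out.insert(0, "subject_id", beats.subject_ids)
    if rr_ms is not None:
        out["rr_ms"] = rr_ms
        out["heart_rate_bpm"] = 60000.0 / out["rr_ms"]
    return out


def stratified_reconstruction(
    model: BetaVAE,
    latents: LatentRepresentation | np.ndarray,
    group_labels,
    band_sd: float = 0.5,
) -> dict:
    """Decode the per-group mean latent vector with a spread band.

    For every group with at least two members, returns the decode of the
    group-mean latent vector plus lower/upper beats decoded at
    mean -/+ ``band_sd`` per-dimension SDs (0.5 SD is the figure
    convention).  Empty or singleton groups are skipped with a warning.
    """
    mu = latents.mu if isinstance(latents, LatentRepresentation) else np.asarray(latents)
    labels = np.asarray(group_labels)
    if labels.shape[0] != mu.shape[0]:
        raise ValueError("group_labels length must match number of subjects")
    out = {}
    for group in pd.unique(labels):
        members = mu[labels == group]
        if members.shape[0] < 2:
            warnings.warn(f"group {group!r} has fewer than 2 members; skipped")
            continue
        centre = members.mean(axis=0)
        sd = members.std(axis=0)
        decoded = model.inverse_transform(
            np.stack([centre, centre - band_sd * sd, centre + band_sd * sd])
        )
        out[group] = {"mean": decoded[0], "lower": decoded[1], "upper": decoded[2]}
    if len(out) < 2:
        warnings.warn("fewer than 2 usable groups in stratified reconstruction")
    return out
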