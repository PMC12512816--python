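"""Core in-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical 8-lead order: limb leads I and II plus the six chest leads.
#: Lead III and the augmented limb leads are linear combinations of I and II
#: and carry no additional information.
LEAD_NAMES: tuple[str, ...] = ("I", "II", "V1", "V2", "V3", "V4", "V5", "V6")

#: Median-beat sampling rate (Hz) and window length (samples; 0.8 s).
SAMPLING_RATE = 500
BEAT_SAMPLES = 400

#: Voltage bound (mV): samples strictly outside +/- 8 mV mark a record as
#: artefactual (pacing spikes, excessive noise) and exclude it.
VOLTAGE_LIMIT_MV = 8.0


@dataclass
class MedianBeatSet:
    """A stack of 8-lead median beats, one per record.

    Attributes
    ----------
    beats : ndarray, shape (n, 8, 400)
        Median-beat voltage in mV sampled at 500 Hz.
    subject_ids : ndarray of str, shape (n,)
        One id per record; several records may share a subject.
    """

    beats: np.ndarray
    subject_ids: np.ndarray
    sampling_rate: int = SAMPLING_RATE
    lead_names: tuple[str, ...] = LEAD_NAMES

    def __post_init__(self) -> None:
        self.beats = np.asarray(self.beats, dtype=np.float64)
        self.subject_ids = np.asarray(self.subject_ids)
        if self.beats.ndim != 3 or self.beats.shape[1:] != (len(self.lead_names), BEAT_SAMPLES):
            raise ValueError(
                f"beats must have shape (n, {len(self.lead_names)}, {BEAT_SAMPLES}), "
                f"got {self.beats.shape}"
            )
        if self.subject_ids.shape[0] != self.beats.shape[0]:
            raise ValueError("subject_ids length must match number of beats")
        if not np.isfinite(self.beats).all():
            raise ValueError("beats contain non-finite values")

    @property
    def n(self) -> int:
        return self.beats.shape[0]

    def subset(self, index: np.ndarray) -> "MedianBeatSet":
        return MedianBeatSet(self.beats[index], self.subject_ids[index],
                             self.sampling_rate, self.lead_names)


@dataclass
class RawECGSet:
    """Raw multi-beat ECG records (10 s at 500 Hz, 8 leads)."""

    signals: np.ndarray  # (n, 8, 5000) mV
    subject_ids: np.ndarray
    sampling_rate: int = SAMPLING_RATE
    lead_names: tuple[str, ...] = LEAD_NAMES

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=np.float64)
        self.subject_ids = np.asarray(self.subject_ids)
        if self.signals.ndim != 3 or self.signals.shape[1] != len(self.lead_names):
            raise ValueError("signals must have shape (n, 8, samples)")

    @property
    def n(self) -> int:
        return self.signals.shape[0]


@dataclass
class LatentRepresentation:
    """Posterior mean/log-variance per subject plus the active-latent set."""

    mu: np.ndarray       # (n, latent_dim)
    logvar: np.ndarray   # (n, latent_dim)
    subject_ids: np.ndarray
    active_set: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=np.float64)
        self.logvar = np.asarray(self.logvar, dtype=np.float64)
        if self.mu.shape != self.logvar.shape:
            raise ValueError("mu and logvar must have identical shapes")
        if not (np.isfinite(self.mu).all() and np.isfinite(self.logvar).all()):
            raise ValueError("latent representation contains non-finite values")
        self.active_set = np.asarray(self.active_set, dtype=int)

    @property
    def latent_dim(self) -> int:
        return self.mu.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = {f"lf{d + 1}": self.mu[:, d] for d in range(self.latent_dim)}
        return pd.DataFrame({"subject_id": self.subject_ids, **cols})


@dataclass
class GenotypeMatrix:
    """Hard-call dosages plus per-variant metadata.

    ``variants`` columns: chrom, pos (1-based), ref, alt, af, is_lof,
    deleterious_all5 and (optionally) gene.
    """

    dosages: np.ndarray  # (n_subjects, n_variants) values in {0, 1, 2}
    variants: pd.DataFrame
    subject_ids: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        self.subject_ids = np.asarray(self.subject_ids)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (subjects x variants)")
        if len(self.variants) != self.dosages.shape[1]:
            raise ValueError("variant table length must match dosage columns")
        if self.subject_ids.shape[0] != self.dosages.shape[0]:
            raise ValueError("subject_ids length must match dosage rows")
        required = {"chrom", "pos", "ref", "alt", "af"}
        missing = required - set(self.variants.columns)
        if missing:
            raise ValueError(f"variant table missing columns: {sorted(missing)}")
        # positions must be sorted within each chromosome (VCF convention)
        for _, grp in self.variants.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing:
                raise ValueError("variant positions must be sorted within chromosome")

    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]


@dataclass
class AssocResult:
    """Per-variant association results for one trait.

    ``table`` columns: chrom, pos, variant_id, beta, se, p, n.  Monomorphic
    variants carry NaN statistics.  ``lambda_gc`` is the genomic-control
    inflation factor median(chi2) / 0.4549.
    """

    trait: str
    table: pd.DataFrame
    lambda_gc: float


@dataclass
class Locus:
    """A merged genomic region of associated variants (1-based inclusive)."""

    chrom: str
    start: int
    end: int
    member_variants: list
    lead_variant: str
    traits: list

    def overlaps(self, other: "Locus") -> bool:
        return self.chrom == other.chrom and self.start <= other.end and other.start <= self.end
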