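"""Synthetic ground-truth data: median beats, raw ECGs, genotypes, phenotypes.

The beat model places five compact-support wavelets (P, Q, R, S, T) on a
0.8-s grid according to per-subject interval factors, draws a 3-D cardiac
dipole trajectory, and projects it to the 8 analysed leads through a fixed
Dower-style full-rank mixing matrix.  Each wavelet is a truncated Gaussian
bump that is exactly zero outside its onset/offset, so fiducial points
(P onset, QRS onset/offset, T offset) are well defined on the noiseless
waveform and agree with the configured interval durations by construction.

Genotypes follow a Balding–Nichols two-population model when ``fst > 0``;
phenotypes combine planted SNP effects (scaled to a target heritability),
covariate effects and Gaussian noise, with binary traits obtained by
thresholding a standard-normal liability at the configured prevalence.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ecglf.containers import (
    BEAT_SAMPLES,
    LEAD_NAMES,
    SAMPLING_RATE,
    GenotypeMatrix,
    MedianBeatSet,
    RawECGSet,
)

__all__ = [
    "SimConfig",
    "DOWER_MATRIX",
    "simulate_median_beats",
    "simulate_raw_ecg",
    "simulate_genotypes",
    "simulate_phenotypes",
    "beat_from_factors",
]

#: Dower-style forward lead matrix: rows are lead vectors for
#: [I, II, V1..V6], columns the (x, y, z) dipole axes.  Full rank (3), so
#: the projection induces realistic cross-lead correlation.
DOWER_MATRIX = np.array(
    [
        [0.632, -0.235, 0.059],   # I
        [0.235, 1.066, -0.132],   # II
        [-0.515, 0.157, -0.917],  # V1
        [0.044, 0.164, -1.387],   # V2
        [0.882, 0.098, -1.277],   # V3
        [1.213, 0.127, -0.601],   # V4
        [1.125, 0.127, -0.086],   # V5
        [0.831, 0.076, 0.230],    # V6
    ]
)


def _unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


# dipole directions per wave; Q and S oppose the R axis
_DIR = {
    "P": _unit([0.50, 0.80, 0.33]),
    "R": _unit([0.70, 0.60, -0.40]),
    "T": _unit([0.60, 0.50, -0.30]),
}
_DIR["Q"] = -_DIR["R"]
_DIR["S"] = -_DIR["R"]

#: R peak is fixed at sample 150 (300 ms) of the 400-sample window.
R_PEAK_SAMPLE = 150
#: fixed wave durations (ms); intervals are carried by the factors instead
P_DURATION_MS = 90.0
T_DURATION_MS = 170.0
#: truncation half-width of the Gaussian bumps, in units of sigma
_TRUNC = 2.5

MS_PER_SAMPLE = 1000.0 / SAMPLING_RATE


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is invalid."""


@dataclass
class SimConfig:
    """Configuration of the synthetic study.

    Parameters
    ----------
    n_subjects : int
        Number of subjects (one median beat each).
    noise_sd : float
        Additive iid Gaussian noise on each beat sample (mV).
    artefact_rate : float
        Probability that a record contains an extreme-voltage sample
        (|v| > 8 mV), emulating pacing spikes.
    n_variants : int
        Number of simulated bi-allelic variants.
    maf_range : (float, float)
        Uniform range of ancestral minor-allele frequencies, within (0, 0.5].
    fst : float
        Balding–Nichols differentiation between two equal subpopulations;
        0 disables structure.
    causal_map : list of (variant_index, trait_name, effect_size)
        Planted per-allele effects on quantitative traits.
    h2_map : dict trait_name -> float
        Target narrow-sense heritability of each quantitative trait.
    seed : int
        Seed for all randomness; identical seeds give identical output.
    """

    n_subjects: int = 200
    noise_sd: float = 0.02
    artefact_rate: float = 0.0
    n_variants: int = 100
    maf_range: tuple[float, float] = (0.05, 0.5)
    fst: float = 0.0
    causal_map: list = field(default_factory=list)
    h2_map: dict = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects <= 0:
            raise ConfigurationError("n_subjects must be positive")
        if not (0.0 <= self.artefact_rate <= 1.0):
            raise ConfigurationError("artefact_rate must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be nonnegative")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must satisfy 0 < low <= high <= 0.5")
        if not (0.0 <= self.fst < 1.0):
            raise ConfigurationError("fst must lie in [0, 1)")
        for trait, h2 in self.h2_map.items():
            if not (0.0 <= h2 < 1.0):
                raise ConfigurationError(f"h2 for {trait!r} must lie in [0, 1)")

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


# ---------------------------------------------------------------------------
# factors and beat geometry
# ---------------------------------------------------------------------------

_FACTOR_SPECS = {
    # name: (mean, sd, low, high)
    "pr_ms": (165.0, 18.0, 115.0, 240.0),
    "qrs_ms": (95.0, 10.0, 70.0, 130.0),
    "qt_ms": (400.0, 25.0, 345.0, 470.0),
    "amp_p": (0.22, 0.05, 0.08, 0.45),
    "amp_r": (1.40, 0.25, 0.60, 2.60),
    "amp_t": (0.45, 0.10, 0.15, 0.90),
    "t_asym": (0.20, 0.25, -0.80, 0.80),
    # RR floor of 820 ms keeps consecutive beats' wave content disjoint
    # within the 0.8-s extraction window (worst case PR + QRS/2 + 500 ms)
    "rr_ms": (950.0, 90.0, 820.0, 1300.0),
}


def _draw_factors(rng: np.random.Generator, n: int) -> pd.DataFrame:
    cols = {"subject_id": np.array([f"S{i:05d}" for i in range(n)])}
    for name, (mean, sd, lo, hi) in _FACTOR_SPECS.items():
        cols[name] = np.clip(rng.normal(mean, sd, size=n), lo, hi)
    return pd.DataFrame(cols)


def _bump(t_ms: np.ndarray, onset: float, offset: float, peak: float, amp: float) -> np.ndarray:
    """Truncated Gaussian bump: zero outside [onset, offset], ``amp`` at ``peak``."""
    sig_l = max((peak - onset) / _TRUNC, 1e-9)
    sig_r = max((offset - peak) / _TRUNC, 1e-9)
    u = np.where(t_ms < peak, (t_ms - peak) / sig_l, (t_ms - peak) / sig_r)
    base = np.exp(-0.5 * _TRUNC**2)
    val = (np.exp(-0.5 * u**2) - base) / (1.0 - base)
    val[(t_ms < onset) | (t_ms > offset)] = 0.0
    return amp * val


def beat_fiducials(factors: pd.Series) -> dict:
    """Analytic fiducial times (ms) implied by one subject's factors."""
    t_r = R_PEAK_SAMPLE * MS_PER_SAMPLE
    qrs_on = t_r - factors["qrs_ms"] / 2.0
    qrs_off = t_r + factors["qrs_ms"] / 2.0
    p_on = qrs_on - factors["pr_ms"]
    t_off = qrs_on + factors["qt_ms"]
    return {
        "p_onset": p_on,
        "p_offset": p_on + P_DURATION_MS,
        "qrs_onset": qrs_on,
        "r_peak": t_r,
        "qrs_offset": qrs_off,
        "t_onset": t_off - T_DURATION_MS,
        "t_offset": t_off,
    }


def beat_from_factors(factors: pd.Series) -> np.ndarray:
    """Render one noiseless 8 x 400 median beat from a factor row."""
    fid = beat_fiducials(factors)
    if fid["p_onset"] < 0:
        raise ConfigurationError("PR interval too long: P wave precedes the window")
    if fid["t_offset"] > BEAT_SAMPLES * MS_PER_SAMPLE:
        raise ConfigurationError("QT interval too long: T wave exceeds the window")
    if fid["t_onset"] < fid["qrs_offset"]:
        raise ConfigurationError("QT too short for the configured QRS duration")

    t_ms = np.arange(BEAT_SAMPLES) * MS_PER_SAMPLE
    qrs = factors["qrs_ms"]
    t_peak_frac = float(np.clip(0.5 + 0.12 * factors["t_asym"], 0.2, 0.8))

    waves = {
        "P": (fid["p_onset"], fid["p_offset"],
              fid["p_onset"] + P_DURATION_MS / 2.0, factors["amp_p"]),
        "Q": (fid["qrs_onset"], fid["qrs_onset"] + 0.30 * qrs,
              fid["qrs_onset"] + 0.15 * qrs, 0.08 * factors["amp_r"]),
        "R": (fid["r_peak"] - 0.35 * qrs, fid["r_peak"] + 0.35 * qrs,
              fid["r_peak"], factors["amp_r"]),
        "S": (fid["qrs_offset"] - 0.30 * qrs, fid["qrs_offset"],
              fid["qrs_offset"] - 0.15 * qrs, 0.15 * factors["amp_r"]),
        "T": (fid["t_onset"], fid["t_offset"],
              fid["t_onset"] + t_peak_frac * T_DURATION_MS, factors["amp_t"]),
    }
    dipole = np.zeros((3, BEAT_SAMPLES))
    for name, (on, off, peak, amp) in waves.items():
        dipole += np.outer(_DIR[name], _bump(t_ms, on, off, peak, amp))
    return DOWER_MATRIX @ dipole


def simulate_median_beats(config: SimConfig) -> tuple[MedianBeatSet, pd.DataFrame]:
    """Generate one median beat per subject plus the true-factor table.

    Returns
    -------
    beats : MedianBeatSet
    factors : DataFrame
        One row per subject with the latent physiological factors.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    factors = _draw_factors(rng, config.n_subjects)
    beats = np.stack([beat_from_factors(row) for _, row in factors.iterrows()])
    if config.noise_sd > 0:
        beats = beats + rng.normal(0.0, config.noise_sd, size=beats.shape)
    if config.artefact_rate > 0:
        hit = rng.random(config.n_subjects) < config.artefact_rate
        for i in np.flatnonzero(hit):
            lead = rng.integers(0, len(LEAD_NAMES))
            sample = rng.integers(0, BEAT_SAMPLES)
            sign = 1.0 if rng.random() < 0.5 else -1.0
            beats[i, lead, sample] = sign * (8.5 + 3.5 * rng.random())
    return MedianBeatSet(beats, factors["subject_id"].to_numpy()), factors


def simulate_raw_ecg(
    config: SimConfig,
    beats_per_record: int | None = None,
    jitter_sd_ms: float = 8.0,
    duration_s: float = 10.0,
) -> tuple[RawECGSet, pd.DataFrame]:
    """Generate raw multi-beat records by repeating each subject's beat.

    Beats are placed at intervals of the subject's mean RR plus iid timing
    jitter; the template is the noiseless beat, with record-level noise
    added afterwards.  Returns the records and the true-factor table.
    """
    config.validate()
    if beats_per_record is not None and beats_per_record < 3:
        raise ConfigurationError("beats_per_record must be at least 3")
    rng = np.random.default_rng(config.seed)
    factors = _draw_factors(rng, config.n_subjects)
    n_samples = int(round(duration_s * SAMPLING_RATE))
    signals = np.zeros((config.n_subjects, len(LEAD_NAMES), n_samples))

    for i, (_, row) in enumerate(factors.iterrows()):
        rr = row["rr_ms"]
        n_beats = beats_per_record
        if n_beats is None:
            n_beats = int(duration_s * 1000.0 // rr)
        elif rr * n_beats > duration_s * 1000.0:
            raise ConfigurationError(
                f"{n_beats} beats at RR {rr:.0f} ms exceed the {duration_s:.0f}-s record"
            )
        template = beat_from_factors(row)
        jitter = rng.normal(0.0, jitter_sd_ms, size=n_beats) if jitter_sd_ms > 0 else np.zeros(n_beats)
        for k in range(n_beats):
            r_ms = rr / 2.0 + k * rr + jitter[k]
            r_idx = int(round(r_ms / MS_PER_SAMPLE))
            start = r_idx - R_PEAK_SAMPLE
            lo, hi = max(start, 0), min(start + BEAT_SAMPLES, n_samples)
            if hi <= lo:
                continue
            signals[i, :, lo:hi] += template[:, lo - start:hi - start]
    if config.noise_sd > 0:
        signals += rng.normal(0.0, config.noise_sd, size=signals.shape)
    return RawECGSet(signals, factors["subject_id"].to_numpy()), factors


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(
    config: SimConfig,
    n_genes: int = 10,
    rare_fraction: float = 0.0,
    rare_af: float = 5e-4,
    chrom: str = "1",
) -> GenotypeMatrix:
    """Draw hard-call dosages under Hardy–Weinberg sampling.

    With ``fst > 0`` subjects split into two equal subpopulations whose
    allele frequencies are Balding–Nichols perturbations of the ancestral
    frequency.  A trailing ``rare_fraction`` of variants is redrawn at
    frequency ``rare_af`` and flagged loss-of-function / deleterious-by-all-
    five to exercise the burden masks; variants are assigned to ``n_genes``
    contiguous genes.
    """
    config.validate()
    if config.n_variants < 1:
        raise ConfigurationError("n_variants must be at least 1")
    rng = np.random.default_rng(config.seed + 1)
    n, m = config.n_subjects, config.n_variants
    lo, hi = config.maf_range
    anc = rng.uniform(lo, hi, size=m)

    n_rare = int(round(rare_fraction * m))
    is_rare = np.zeros(m, dtype=bool)
    if n_rare:
        is_rare[-n_rare:] = True
        anc[is_rare] = rare_af

    if config.fst > 0:
        a = anc * (1.0 - config.fst) / config.fst
        b = (1.0 - anc) * (1.0 - config.fst) / config.fst
        pop_freq = np.stack([rng.beta(a, b), rng.beta(a, b)])  # (2, m)
        pop_freq = np.clip(pop_freq, 1e-6, 1 - 1e-6)
        pop = (np.arange(n) >= n // 2).astype(int)
        freq = pop_freq[pop]  # (n, m)
    else:
        freq = np.broadcast_to(anc, (n, m))
    dosages = rng.binomial(2, freq).astype(np.int8)

    pos = np.sort(rng.choice(np.arange(1, 250_000_001), size=m, replace=False))
    bases = np.array(list("ACGT"))
    ref_idx = rng.integers(0, 4, size=m)
    ref = bases[ref_idx]
    alt = bases[(ref_idx + rng.integers(1, 4, size=m)) % 4]
    af = dosages.mean(axis=0) / 2.0
    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "variant_id": [f"{chrom}:{p}" for p in pos],
            "ref": ref,
            "alt": alt,
            "af": af,
            "is_lof": is_rare & (rng.random(m) < 0.6),
            "deleterious_all5": is_rare & (rng.random(m) < 0.5),
            "gene": [f"GENE{1 + (i * n_genes) // m}" for i in range(m)],
        }
    )
    return GenotypeMatrix(dosages, variants, np.array([f"S{i:05d}" for i in range(n)]))


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

#: default additive covariate effects on each quantitative trait (per SD of
#: the standardised covariate); small relative to the unit residual scale
_DEFAULT_COVAR_EFFECTS = {"age": 0.10, "age2": 0.03, "sex": 0.15, "height": 0.05, "bmi": 0.05}


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    factors: pd.DataFrame | None,
    config: SimConfig,
    binary_prevalence: dict | None = None,
    covariate_effects: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate quantitative and liability-threshold binary phenotypes.

    For each trait in ``config.h2_map`` the genetic value is the dosage-
    weighted sum of the planted effects from ``config.causal_map`` (or an
    infinitesimal contribution of every variant when no effect is planted
    but h2 > 0).  Genetic value and residual are standardised in-sample so
    the realised genetic variance fraction of the non-covariate part equals
    the target h2; covariate effects are then added on top.  Binary traits
    threshold an independent standard-normal liability at the configured
    prevalence.

    Returns
    -------
    phenotypes : DataFrame  (subject_id + one column per trait)
    covariates : DataFrame  (subject_id, age, age2, sex, height, bmi, pop)
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 2)
    n = genotypes.n_subjects
    for idx, trait, _ in config.causal_map:
        if not (0 <= idx < genotypes.n_variants):
            raise ConfigurationError(f"causal variant index {idx} out of range")
        if trait not in config.h2_map:
            raise ConfigurationError(f"causal trait {trait!r} missing from h2_map")

    age = rng.uniform(40.0, 70.0, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    height = rng.normal(170.0, 9.0, size=n) + 6.0 * sex
    bmi = rng.normal(27.0, 4.0, size=n)
    pop = (np.arange(n) >= n // 2).astype(int) if config.fst > 0 else np.zeros(n, dtype=int)
    covars = pd.DataFrame(
        {
            "subject_id": genotypes.subject_ids,
            "age": age,
            "age2": age**2,
            "sex": sex,
            "height": height,
            "bmi": bmi,
            "pop": pop,
        }
    )

    eff = dict(_DEFAULT_COVAR_EFFECTS)
    if covariate_effects is not None:
        eff.update(covariate_effects)

    def _std(x):
        s = x.std()
        return (x - x.mean()) / s if s > 0 else np.zeros_like(x)

    covar_part = (
        eff.get("age", 0) * _std(age)
        + eff.get("age2", 0) * _std(age**2)
        + eff.get("sex", 0) * _std(sex)
        + eff.get("height", 0) * _std(height)
        + eff.get("bmi", 0) * _std(bmi)
    )

    pheno = {"subject_id": genotypes.subject_ids}
    dos = genotypes.dosages.astype(float)
    for trait, h2 in config.h2_map.items():
        planted = [(i, e) for i, t, e in config.causal_map if t == trait]
        if planted:
            g = np.zeros(n)
            for i, e in planted:
                g += e * dos[:, i]
        elif h2 > 0:
            u = rng.normal(0.0, 1.0, size=genotypes.n_variants)
            col_sd = dos.std(axis=0)
            ok = col_sd > 0
            z = (dos[:, ok] - dos[:, ok].mean(axis=0)) / col_sd[ok]
            g = z @ u[ok] / np.sqrt(ok.sum())
        else:
            g = np.zeros(n)
        e_noise = rng.normal(0.0, 1.0, size=n)
        if h2 > 0 and g.std() > 0:
            y = np.sqrt(h2) * _std(g) + np.sqrt(1.0 - h2) * _std(e_noise)
        else:
            y = _std(e_noise)
        pheno[trait] = y + covar_part

    if binary_prevalence:
        for name, prev in binary_prevalence.items():
            if not (0.0 < prev < 1.0):
                raise ConfigurationError(f"prevalence for {name!r} must lie in (0, 1)")
            liability = rng.normal(0.0, 1.0, size=n)
            from scipy.stats import norm

            pheno[name] = (liability > norm.ppf(1.0 - prev)).astype(int)

    # quantitative traits linked to true beat factors (for phenome tests)
    if factors is not None:
        f = factors.set_index("subject_id").reindex(genotypes.subject_ids)
        for col in ("pr_ms", "qt_ms", "amp_t"):
            if col in f:
                pheno[f"factor_{col}"] = f[col].to_numpy()

    return pd.DataFrame(pheno), covars
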