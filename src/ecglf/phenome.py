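"""Phenome-wide comparison of latent-factor and ECG-parameter predictors.

For every phenotype two least-squares prediction models are fitted on the
training split — one with all latent factors as predictors, one with the
conventional ECG parameters — both with age, age^2 and sex as covariates.
Test-split predictions are correlated with the actual values (Pearson for
continuous phenotypes, point-biserial for 0/1-coded binary phenotypes;
the two coincide algebraically on a 0/1 coding).  Significant correlations
(Bonferroni-corrected p < 0.05 per model family) are classified into
LF-only / ECG-only / both-LF-higher / both-ECG-higher / neither, and the
per-category normalised mean absolute coefficients summarise which
features drive each model family.

Binary phenotypes are fitted by ordinary least squares (a linear
probability model): the downstream point-biserial evaluation requires a
continuous prediction, which a linear fit provides directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "PhenoCorrRecord",
    "PhenotypePredictor",
    "apply_exclusions",
    "fit_prediction_model",
    "correlate_predictions",
    "compare_models",
    "coefficient_heatmap",
    "overlap_summary",
]


def _is_binary(series: pd.Series) -> bool:
    vals = set(pd.unique(series.dropna()))
    return len(vals) > 0 and vals <= {0, 1, 0.0, 1.0}


def apply_exclusions(
    table: pd.DataFrame,
    train_ids,
    max_missing: float = 0.9,
    min_cases: int = 100,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop phenotypes failing the training-set quality rules.

    A phenotype is excluded when its missingness in the training subset
    exceeds ``max_missing`` (strictly), or — for binary phenotypes — when
    its training-set positive count is below ``min_cases``.  Returns the
    filtered table and a report of drops with reasons.
    """
    if "subject_id" not in table.columns:
        raise ValueError("phenotype table needs a subject_id column")
    train_ids = set(np.asarray(train_ids))
    unknown = train_ids - set(table["subject_id"])
    if unknown:
        raise ValueError(f"{len(unknown)} train ids absent from the phenotype table")
    train = table[table["subject_id"].isin(train_ids)]
    drops = []
    for col in table.columns:
        if col == "subject_id":
            continue
        missing_frac = train[col].isna().mean()
        if missing_frac > max_missing:
            drops.append({"phenotype": col, "reason": "missingness",
                          "value": float(missing_frac)})
            continue
        if _is_binary(table[col]):
            cases = int(train[col].fillna(0).sum())
            if cases < min_cases:
                drops.append({"phenotype": col, "reason": "case_count", "value": cases})
    report = pd.DataFrame(drops, columns=["phenotype", "reason", "value"])
    return table.drop(columns=list(report["phenotype"])), report


class PhenotypePredictor(RegressorMixin, BaseEstimator):
    """Ordinary least-squares phenotype prediction model.

    Fits ``phenotype ~ features + covariates`` with an intercept; a
    rank-deficient design raises an error naming the collinear columns.
    ``coef_`` holds the coefficients in column order, ``feature_names_in_``
    the matching names; feature (non-covariate) coefficients feed the
    category coefficient heatmaps.
    """

    def __init__(self, n_features: int | None = None):
        self.n_features = n_features

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            x = X.to_numpy(dtype=float)
        else:
            x = np.asarray(X, dtype=float)
            names = [f"x{i}" for i in range(x.shape[1])]
        y = np.asarray(y, dtype=float)
        design = np.column_stack([np.ones(x.shape[0]), x])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            _, r = np.linalg.qr(design)
            diag = np.abs(np.diag(r))
            bad = diag < 1e-8 * diag.max()
            cols = [(["intercept"] + names)[i] for i in np.flatnonzero(bad)]
            raise ValueError(f"rank-deficient design; collinear columns: {cols}")
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        self.intercept_ = float(coef[0])
        self.coef_ = coef[1:]
        self.feature_names_in_ = np.asarray(names)
        self.n_features_in_ = x.shape[1]
        return self

    def predict(self, X):
        x = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
        return self.intercept_ + x @ self.coef_

    def feature_coefficients(self) -> pd.Series:
        """Coefficients of the leading ``n_features`` (non-covariate) columns."""
        k = self.n_features if self.n_features is not None else self.n_features_in_
        return pd.Series(self.coef_[:k], index=self.feature_names_in_[:k])


def _build_design(features: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    cov = pd.DataFrame(index=covariates.index)
    cov["age"] = covariates["age"].astype(float)
    cov["age2"] = cov["age"] ** 2
    cov["sex"] = covariates["sex"].astype(float)
    return pd.concat([features, cov], axis=1)


def fit_prediction_model(
    features: pd.DataFrame,
    phenotype: pd.Series,
    covariates: pd.DataFrame,
    train_ids,
    seed: int = 0,
) -> PhenotypePredictor:
    """Fit one prediction model on the training subjects.

    ``features``, ``phenotype`` and ``covariates`` (with age and sex
    columns) are indexed by subject id.  When a subject carries several
    records, a single random one is kept (seeded).  Rows with a missing
    phenotype are dropped.  The fitted model remembers the training
    subjects so evaluation can enforce train/test disjointness.
    """
    train_ids = pd.Index(np.asarray(train_ids)).unique()
    if features.index.has_duplicates:
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(features))
        features = features.iloc[order].groupby(level=0).head(1)
    x = _build_design(features.loc[features.index.intersection(train_ids)],
                      covariates.loc[features.index.intersection(train_ids)])
    y = phenotype.loc[x.index]
    keep = y.notna() & x.notna().all(axis=1)
    model = PhenotypePredictor(n_features=features.shape[1]).fit(x[keep], y[keep])
    model.train_ids_ = set(x.index[keep])
    return model


@dataclass
class PhenoCorrRecord:
    """Prediction-vs-actual correlation for one phenotype under one model."""

    phenotype: str
    model: str
    r: float
    p: float
    n: int


def correlate_predictions(
    model: PhenotypePredictor,
    features: pd.DataFrame,
    covariates: pd.DataFrame,
    phenotype: pd.Series,
    phenotype_name: str = "phenotype",
    model_name: str = "LF",
) -> PhenoCorrRecord:
    """Correlate held-out predictions with the actual phenotype.

    Pearson correlation for continuous phenotypes; for 0/1-coded binary
    phenotypes the same computation is the point-biserial coefficient.
    Constant predictions or outcomes give a missing correlation.  Raises if
    any evaluation subject was part of the training set.
    """
    if hasattr(model, "train_ids_"):
        leaked = set(features.index) & model.train_ids_
        if leaked:
            raise ValueError(f"train/test leakage: {len(leaked)} overlapping subjects")
    x = _build_design(features, covariates.loc[features.index])
    y = phenotype.loc[x.index]
    keep = y.notna() & x.notna().all(axis=1)
    pred = model.predict(x[keep])
    actual = y[keep].to_numpy(dtype=float)
    n = int(keep.sum())
    if n < 3 or np.std(pred) == 0 or np.std(actual) == 0:
        return PhenoCorrRecord(phenotype_name, model_name, np.nan, np.nan, n)
    r, p = stats.pearsonr(pred, actual)
    return PhenoCorrRecord(phenotype_name, model_name, float(r), float(p), n)


def _records_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return pd.DataFrame([vars(r) for r in records])


def compare_models(
    lf_records,
    ecg_records,
    alpha: float = 0.05,
    n_tests: int | None = None,
) -> dict:
    """Classify phenotypes by which model family predicts them.

    Significance is Bonferroni-corrected: p < alpha / n_tests within each
    model family (``n_tests`` defaults to the number of phenotypes).
    Categories: LF-only, ECG-only, both-LF-higher, both-ECG-higher (by
    comparing correlation coefficients; exact ties count toward LF) and
    neither.  Returns per-phenotype classifications, category counts and
    integer percentages of the both-significant set won by each family.
    """
    lf = _records_frame(lf_records).set_index("phenotype")
    ecg = _records_frame(ecg_records).set_index("phenotype")
    if set(lf.index) != set(ecg.index):
        raise ValueError("LF and ECG record sets cover different phenotypes")
    ecg = ecg.loc[lf.index]
    m = n_tests if n_tests is not None else len(lf)
    cut = alpha / m
    sig_lf = (lf["p"] < cut).fillna(False)
    sig_ecg = (ecg["p"] < cut).fillna(False)

    category = pd.Series("neither", index=lf.index)
    category[sig_lf & ~sig_ecg] = "LF-only"
    category[~sig_lf & sig_ecg] = "ECG-only"
    both = sig_lf & sig_ecg
    category[both & (lf["r"].abs() >= ecg["r"].abs())] = "both-LF-higher"
    category[both & (lf["r"].abs() < ecg["r"].abs())] = "both-ECG-higher"

    table = pd.DataFrame(
        {
            "r_lf": lf["r"],
            "r_ecg": ecg["r"],
            "delta_r": lf["r"].abs() - ecg["r"].abs(),
            "category": category,
        }
    )
    counts = category.value_counts().to_dict()
    n_both = int(both.sum())
    lf_higher = counts.get("both-LF-higher", 0)
    summary = {
        "counts": counts,
        "n_significant_any": int((sig_lf | sig_ecg).sum()),
        "n_both": n_both,
        "pct_lf_higher_of_both": round(100.0 * lf_higher / n_both) if n_both else np.nan,
        "pct_ecg_higher_of_both": round(100.0 * (n_both - lf_higher) / n_both) if n_both else np.nan,
        "table": table,
    }
    return summary


def coefficient_heatmap(models: dict, category_map: dict) -> pd.DataFrame:
    """Category-mean normalised absolute feature coefficients.

    For each phenotype category, the mean absolute coefficient of every
    feature across that category's fitted models, divided by the sum over
    features — each row sums to 1.  Empty categories are skipped.
    """
    rows = {}
    categories = {}
    for phenotype, model in models.items():
        cat = category_map.get(phenotype)
        if cat is None:
            continue
        categories.setdefault(cat, []).append(model.feature_coefficients().abs())
    for cat, coefs in categories.items():
        mean_abs = pd.concat(coefs, axis=1).mean(axis=1)
        total = mean_abs.sum()
        if total > 0:
            rows[cat] = mean_abs / total
    return pd.DataFrame(rows).T


def _as_intervals(items):
    out = []
    for it in items:
        if hasattr(it, "chrom") and hasattr(it, "start"):
            out.append((str(it.chrom), int(it.start), int(it.end)))
        elif isinstance(it, tuple) and len(it) == 3:
            out.append((str(it[0]), int(it[1]), int(it[2])))
        else:
            return None
    return out


def overlap_summary(hits_a, hits_b, labels: tuple = ("A", "B")) -> dict:
    """Exclusive/shared counts between two hit or locus sets.

    Accepts sets of hashable keys, or lists of loci/intervals in which case
    genomic overlap (same chromosome, intersecting 1-based inclusive
    spans) counts as shared.  Percentages of each exclusive set are
    relative to that set's own total, rounded to integer percent.
    """
    ia, ib = _as_intervals(hits_a), _as_intervals(hits_b)
    if ia is not None and ib is not None:
        def _overlaps(x, y):
            return x[0] == y[0] and x[1] <= y[2] and y[1] <= x[2]

        a_shared = sum(any(_overlaps(x, y) for y in ib) for x in ia)
        b_shared = sum(any(_overlaps(y, x) for x in ia) for y in ib)
        n_a, n_b = len(ia), len(ib)
        a_only, b_only = n_a - a_shared, n_b - b_shared
    else:
        sa, sb = set(hits_a), set(hits_b)
        n_a, n_b = len(sa), len(sb)
        a_only, b_only = len(sa - sb), len(sb - sa)
    la, lb = labels
    return {
        f"n_{la}": n_a,
        f"n_{lb}": n_b,
        f"{la}_only": a_only,
        f"{lb}_only": b_only,
        f"pct_{la}_only": round(100.0 * a_only / n_a) if n_a else np.nan,
        f"pct_{lb}_only": round(100.0 * b_only / n_b) if n_b else np.nan,
    }
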