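"""Untargeted LC-MS metabolomics processing: drift correction, feature
filtering, imputation and probabilistic quotient normalization.

The pipeline order is fixed — drift correction on pooled-QC injections,
feature quality filtering (QC relative standard deviation and dispersion
ratio), missing-value imputation, then probabilistic quotient
normalization (PQN) — matching how pooled-QC-based workflows process
batches before any differential analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PeakAreaMatrix",
    "drift_correct",
    "filter_features",
    "impute_missing",
    "pqn_normalize",
    "process_batch",
]


@dataclass
class PeakAreaMatrix:
    """Samples x features raw areas with injection metadata.

    ``classes`` labels each row ``"qc"`` (pooled quality control) or
    ``"sample"`` (biological); ``injection`` is 0-based injection order.
    """

    areas: pd.DataFrame
    injection: np.ndarray
    classes: np.ndarray

    def __post_init__(self):
        self.injection = np.asarray(self.injection)
        self.classes = np.asarray(self.classes)
        if len(self.areas) != self.injection.size or len(self.areas) != self.classes.size:
            raise ValueError("metadata length does not match the area matrix")
        vals = self.areas.to_numpy(dtype=float)
        if np.any(vals[np.isfinite(vals)] < 0):
            raise ValueError("peak areas must be nonnegative (or missing)")

    @classmethod
    def from_batch(cls, batch: pd.DataFrame) -> "PeakAreaMatrix":
        """Build from the generator's batch layout (injection, class columns)."""
        meta = batch[["injection", "class"]]
        areas = batch.drop(columns=["injection", "class"])
        return cls(areas, meta["injection"].to_numpy(), meta["class"].to_numpy())

    @property
    def qc_mask(self) -> np.ndarray:
        return self.classes == "qc"


def _qc_spline(x_qc, y_qc, x_all):
    """Cubic smoothing spline of QC areas vs injection order (GCV-chosen
    stiffness); linear fallback below the spline minimum."""
    from scipy.interpolate import make_smoothing_spline

    if x_qc.size >= 5:
        spl = make_smoothing_spline(x_qc, y_qc)
        return spl(x_all)
    warnings.warn("fewer than 5 QC injections; falling back to a linear drift model",
                  stacklevel=3)
    slope, intercept = np.polyfit(x_qc, y_qc, 1)
    return slope * x_all + intercept


def drift_correct(m: PeakAreaMatrix) -> PeakAreaMatrix:
    """Remove injection-order instrument drift using the pooled QCs.

    Per feature, a cubic smoothing spline is fit to QC area versus
    injection order; every observation is divided by the spline prediction
    at its own injection and rescaled to the median QC level, so constant
    QC series leave the matrix unchanged.
    """
    qc = m.qc_mask
    if qc.sum() < 3:
        raise ValueError("drift correction needs at least 3 QC injections")
    x_qc = m.injection[qc].astype(float)
    corrected = m.areas.copy()
    for col in m.areas.columns:
        y = m.areas[col].to_numpy(dtype=float)
        y_qc = y[qc]
        ok = np.isfinite(y_qc)
        if ok.sum() < 3:
            continue  # too few observed QCs; leave the feature untouched
        trend = _qc_spline(x_qc[ok], y_qc[ok], m.injection.astype(float))
        trend = np.where(trend > 0, trend, np.nan)
        scale = np.nanmedian(y_qc[ok])
        corrected[col] = y / trend * scale
    return PeakAreaMatrix(corrected, m.injection.copy(), m.classes.copy())


def filter_features(
    m: PeakAreaMatrix, rsd_max: float = 0.2, dratio_max: float = 0.4,
    robust: bool = False,
) -> tuple[pd.DataFrame, PeakAreaMatrix]:
    """Drop low-quality features by QC statistics.

    A feature is removed when its relative standard deviation across QC
    injections exceeds ``rsd_max`` or its dispersion ratio — QC variability
    over biological-sample variability — exceeds ``dratio_max``.  With
    ``robust=True`` both statistics use MAD-based estimates.  Values of
    retained features are never altered.
    """
    qc = m.qc_mask
    rows = []
    keep_cols = []
    for col in m.areas.columns:
        y = m.areas[col].to_numpy(dtype=float)
        y_qc, y_bio = y[qc], y[~qc]
        y_qc = y_qc[np.isfinite(y_qc)]
        y_bio = y_bio[np.isfinite(y_bio)]
        if robust:
            sd_qc = 1.4826 * np.median(np.abs(y_qc - np.median(y_qc))) if y_qc.size else np.nan
            sd_bio = 1.4826 * np.median(np.abs(y_bio - np.median(y_bio))) if y_bio.size else np.nan
            center = np.median(y_qc) if y_qc.size else 0.0
        else:
            sd_qc = np.std(y_qc, ddof=1) if y_qc.size > 1 else np.nan
            sd_bio = np.std(y_bio, ddof=1) if y_bio.size > 1 else np.nan
            center = np.mean(y_qc) if y_qc.size else 0.0
        reason = ""
        if center == 0 or not np.isfinite(center):
            rsd = np.nan
            reason = "zero-mean QC"
        else:
            rsd = sd_qc / center
        dratio = sd_qc / sd_bio if sd_bio and np.isfinite(sd_bio) and sd_bio > 0 else np.inf
        if sd_qc == 0:
            dratio = 0.0
        if not reason:
            if np.isfinite(rsd) and rsd > rsd_max:
                reason = f"QC RSD {rsd:.3f} > {rsd_max}"
            elif dratio > dratio_max:
                reason = f"D-ratio {dratio:.3f} > {dratio_max}"
        retained = reason == ""
        rows.append(
            {"feature": col, "rsd": rsd, "d_ratio": dratio, "retained": retained,
             "reason": reason}
        )
        if retained:
            keep_cols.append(col)
    report = pd.DataFrame(rows).set_index("feature")
    out = PeakAreaMatrix(m.areas[keep_cols].copy(), m.injection.copy(), m.classes.copy())
    return report, out


def impute_missing(
    m: PeakAreaMatrix, strategy: str = "forest", seed: int = 0,
) -> PeakAreaMatrix:
    """Fill missing areas; deterministic for a given seed.

    Strategies: ``"forest"`` (iterative imputer with extremely randomized
    trees, the default), ``"knn"`` (k-nearest-neighbour), ``"halfmin"``
    (half the feature minimum, the classic left-censoring fallback).
    """
    vals = m.areas.to_numpy(dtype=float)
    if not np.isnan(vals).any():
        return m
    col_missing = np.isnan(vals).mean(axis=0)
    if np.any(col_missing >= 0.5):
        bad = list(m.areas.columns[col_missing >= 0.5])
        raise ValueError(f"features missing in >=50% of injections: {bad}")
    if strategy == "halfmin":
        fill = np.nanmin(vals, axis=0) / 2.0
        out = np.where(np.isnan(vals), fill, vals)
    elif strategy == "knn":
        from sklearn.impute import KNNImputer

        out = KNNImputer(n_neighbors=min(5, len(vals) - 1)).fit_transform(vals)
    elif strategy == "forest":
        from sklearn.ensemble import ExtraTreesRegressor
        from sklearn.experimental import enable_iterative_imputer  # noqa: F401
        from sklearn.impute import IterativeImputer

        est = ExtraTreesRegressor(n_estimators=30, random_state=seed)
        imp = IterativeImputer(
            estimator=est, random_state=seed, max_iter=5, sample_posterior=False
        )
        out = imp.fit_transform(vals)
    else:
        raise ValueError(f"unknown imputation strategy {strategy!r}")
    areas = pd.DataFrame(out, index=m.areas.index, columns=m.areas.columns)
    return PeakAreaMatrix(areas.clip(lower=0.0), m.injection.copy(), m.classes.copy())


def pqn_normalize(
    m: PeakAreaMatrix | pd.DataFrame, reference: str = "median-qc"
) -> tuple[pd.DataFrame, pd.Series]:
    """Probabilistic quotient normalization.

    Each sample is divided by the median, over features, of its ratios to
    a reference spectrum (the feature-wise median of the QC injections by
    default, or of all samples when no QCs exist).  Returns the normalized
    matrix and the per-sample quotients.  Non-positive reference entries
    are excluded from the quotient with a warning.
    """
    if isinstance(m, PeakAreaMatrix):
        areas, qc = m.areas, m.qc_mask
    else:
        areas, qc = m, np.zeros(len(m), dtype=bool)
    vals = areas.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError("PQN requires a complete matrix; impute first")
    if reference == "median-qc" and qc.any():
        ref = np.median(vals[qc], axis=0)
    else:
        ref = np.median(vals, axis=0)
    usable = ref > 0
    if not usable.all():
        warnings.warn(
            f"{int((~usable).sum())} non-positive reference features excluded from PQN",
            stacklevel=2,
        )
    if not usable.any():
        raise ValueError("no positive reference features for PQN")
    quot = np.median(vals[:, usable] / ref[usable], axis=1)
    normalized = pd.DataFrame(
        vals / quot[:, None], index=areas.index, columns=areas.columns
    )
    return normalized, pd.Series(quot, index=areas.index, name="quotient")


def process_batch(
    m: PeakAreaMatrix,
    rsd_max: float = 0.2,
    dratio_max: float = 0.4,
    impute_strategy: str = "forest",
    seed: int = 0,
) -> dict:
    """Full chain: drift -> filter -> impute -> normalize (fixed order)."""
    drifted = drift_correct(m)
    report, filtered = filter_features(drifted, rsd_max, dratio_max)
    complete = impute_missing(filtered, strategy=impute_strategy, seed=seed)
    normalized, quotients = pqn_normalize(complete)
    return {
        "matrix": normalized,
        "quotients": quotients,
        "qc_report": report,
        "classes": complete.classes,
        "injection": complete.injection,
    }
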