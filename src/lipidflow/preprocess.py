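"""Filtering and normalization of aligned feature tables.

Stages, in the default pipeline order: blank filter, QC-CV filter, LOESS
signal-drift correction against pooled-QC response, protein (or TIC)
normalization, isomer summation, implausible-lipid exclusion, class-level
aggregation, and CV-profile evaluation.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

from .core_model import (
    ClassSummary,
    FeatureTable,
    ROLE_BLANK,
    ROLE_QC,
    ROLE_SAMPLE,
    class_display_label,
)

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# filters
# --------------------------------------------------------------------------


def blank_filter(ft: FeatureTable, min_fold: float = 10.0) -> FeatureTable:
    """Keep features whose mean sample signal exceeds ``min_fold`` times the
    mean blank signal (strict >).  Features absent from blanks (blank mean 0)
    are kept."""
    blanks = ft.blank_indices
    samples = ft.sample_indices
    if blanks.size == 0:
        raise ValueError(
            "no blank injections present; skip the blank-filter stage explicitly"
        )
    if samples.size == 0:
        raise ValueError("no sample injections present")
    blank_mean = ft.intensities[:, blanks].mean(axis=1)
    sample_mean = ft.intensities[:, samples].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(blank_mean > 0, sample_mean / blank_mean, np.inf)
    keep = ratio > min_fold
    logger.info("blank_filter removed %d/%d features", int((~keep).sum()), ft.n_features)
    return ft.subset_features(keep)


def qc_cv_filter(ft: FeatureTable, max_cv: float = 30.0) -> FeatureTable:
    """Exclude features whose CV%% over QC injections is >= ``max_cv`` or whose
    QC mean is zero.  CV uses the sample (n-1) standard deviation."""
    qcs = ft.qc_indices
    if qcs.size < 3:
        raise ValueError(f"qc_cv_filter requires >=3 QC injections, found {qcs.size}")
    q = ft.intensities[:, qcs]
    mean = q.mean(axis=1)
    sd = q.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, 100.0 * sd / mean, np.inf)
    keep = cv < max_cv
    logger.info("qc_cv_filter removed %d/%d features", int((~keep).sum()), ft.n_features)
    return ft.subset_features(keep)


def exclude_implausible(ft: FeatureTable, max_db: int = 12,
                        drop_odd: bool = True) -> FeatureTable:
    """Drop annotated features with too many double bonds or (optionally) odd
    total carbon counts; unannotated features are untouched."""
    keep = np.ones(ft.n_features, dtype=bool)
    for i, ann in enumerate(ft.annotations):
        if not ann.is_annotated:
            continue
        if ann.total_double_bonds > max_db:
            keep[i] = False
        elif drop_odd and ann.odd_chain:
            keep[i] = False
    logger.info("exclude_implausible removed %d/%d features",
                int((~keep).sum()), ft.n_features)
    return ft.subset_features(keep)


# --------------------------------------------------------------------------
# drift correction
# --------------------------------------------------------------------------


@dataclasses.dataclass
class DriftModel:
    """Per-feature smoothed QC response evaluated at every injection order."""

    span: float
    orders: np.ndarray           # all injection orders
    fitted: np.ndarray           # (n_features, n_injections) positive fit values
    corrected_mask: np.ndarray   # features actually corrected


def _interp_extrap(x: np.ndarray, xp: np.ndarray, fp: np.ndarray) -> np.ndarray:
    """Linear interpolation with linear extrapolation beyond the endpoints."""
    y = np.interp(x, xp, fp)
    if len(xp) >= 2:
        left = x < xp[0]
        if left.any():
            slope = (fp[1] - fp[0]) / (xp[1] - xp[0])
            y[left] = fp[0] + slope * (x[left] - xp[0])
        right = x > xp[-1]
        if right.any():
            slope = (fp[-1] - fp[-2]) / (xp[-1] - xp[-2])
            y[right] = fp[-1] + slope * (x[right] - xp[-1])
    return y


def lowess_drift_correct(ft: FeatureTable, span: float = 0.5,
                         robust_iters: int = 2) -> tuple[FeatureTable, DriftModel]:
    """Correct injection-order signal drift using a LOESS fit to QC response.

    Per feature: fit a locally weighted regression of QC intensity against
    injection order, evaluate it at every injection's order (linear
    inter/extrapolation between QC orders), and divide each intensity by the
    fit scaled to its mean over QCs.  Features whose fit goes non-positive
    are left uncorrected (logged).
    """
    if not (0 < span <= 1):
        raise ValueError("span must be in (0, 1]")
    qcs = ft.qc_indices
    if qcs.size < 5:
        raise ValueError(
            f"lowess_drift_correct requires >=5 QC injections, found {qcs.size}"
        )
    orders = ft.injections["order"].to_numpy(dtype=float)
    qc_orders = orders[qcs]
    sort = np.argsort(qc_orders)
    qc_orders = qc_orders[sort]

    corrected = ft.intensities.copy()
    fitted_all = np.ones_like(corrected)
    corrected_mask = np.zeros(ft.n_features, dtype=bool)
    n_fallback = 0
    for i in range(ft.n_features):
        y = ft.intensities[i, qcs][sort]
        fit_qc = sm_lowess(y, qc_orders, frac=span, it=robust_iters,
                           return_sorted=False)
        if np.any(fit_qc <= 0) or np.any(~np.isfinite(fit_qc)):
            n_fallback += 1
            continue
        fit_all = _interp_extrap(orders, qc_orders, fit_qc)
        if np.any(fit_all <= 0):
            n_fallback += 1
            continue
        factor = fit_all / fit_qc.mean()
        corrected[i] = ft.intensities[i] / factor
        fitted_all[i] = fit_all
        corrected_mask[i] = True
    if n_fallback:
        logger.info("lowess_drift_correct: %d features left uncorrected", n_fallback)

    out = ft.with_state("drift_corrected")
    out.intensities = corrected
    model = DriftModel(span=span, orders=orders, fitted=fitted_all,
                       corrected_mask=corrected_mask)
    return out, model


# --------------------------------------------------------------------------
# normalization
# --------------------------------------------------------------------------


def protein_normalize(ft: FeatureTable) -> FeatureTable:
    """Divide each sample column by its injected protein amount (ug).

    QC and blank columns have no protein amount and are left unscaled; they
    are dropped before statistics downstream.
    """
    if ft.normalization_state not in ("raw", "drift_corrected"):
        raise ValueError(
            f"protein_normalize expects raw or drift_corrected state, "
            f"got {ft.normalization_state}"
        )
    samples = ft.sample_indices
    prot = pd.to_numeric(
        ft.injections["protein_ug"].iloc[samples], errors="coerce"
    ).to_numpy(dtype=float)
    if np.any(~np.isfinite(prot)) or np.any(prot <= 0):
        raise ValueError("protein_ug missing or non-positive for some samples")
    out = ft.with_state("protein_normalized")
    out.intensities[:, samples] = ft.intensities[:, samples] / prot[None, :]
    return out


def tic_normalize(ft: FeatureTable) -> FeatureTable:
    """Scale every injection column to the mean total ion count."""
    if ft.normalization_state not in ("raw", "drift_corrected"):
        raise ValueError(
            f"tic_normalize expects raw or drift_corrected state, "
            f"got {ft.normalization_state}"
        )
    sums = ft.intensities.sum(axis=0)
    zero = np.flatnonzero(sums == 0)
    if zero.size:
        ids = ft.injections["injection_id"].iloc[zero].tolist()
        raise ValueError(f"zero total ion count in injections: {ids}")
    out = ft.with_state("tic_normalized")
    out.intensities = ft.intensities / sums[None, :] * sums.mean()
    return out


# --------------------------------------------------------------------------
# isomer summation
# --------------------------------------------------------------------------


def sum_isomers(ft: FeatureTable) -> FeatureTable:
    """Merge features sharing an identical sum-composition annotation by
    summing their intensity rows; m/z and rt of the most intense member are
    retained.  Unannotated features are never merged."""
    keys = [ann.sum_composition_key() for ann in ft.annotations]
    groups: dict[tuple, list[int]] = {}
    for i, key in enumerate(keys):
        if key is None:
            continue
        groups.setdefault(key, []).append(i)

    drop = np.zeros(ft.n_features, dtype=bool)
    intensities = ft.intensities.copy()
    features = ft.features.copy()
    n_merged = 0
    for key, idx in groups.items():
        if len(idx) < 2:
            continue
        total = intensities[idx].sum(axis=0)
        winner = idx[int(np.argmax(intensities[idx].sum(axis=1)))]
        intensities[winner] = total
        for i in idx:
            if i != winner:
                drop[i] = True
        n_merged += len(idx) - 1
    if n_merged:
        logger.info("sum_isomers merged %d duplicate rows", n_merged)
    out = FeatureTable(
        features=features.loc[~drop].reset_index(drop=True),
        injections=ft.injections.copy(),
        intensities=intensities[~drop],
        normalization_state=ft.normalization_state,
    )
    return out


# --------------------------------------------------------------------------
# class aggregation
# --------------------------------------------------------------------------


def class_totals(ft: FeatureTable, case_group: str, control_group: str,
                 equal_var: bool = False) -> list[ClassSummary]:
    """Per-class summed amounts with group means, fold change, and a
    two-tailed unpaired t-test (Welch by default).

    Only annotated features contribute.  Classes are reported under their
    display label (Hex2Cer -> LacCer).
    """
    if ft.normalization_state not in ("protein_normalized", "tic_normalized"):
        raise ValueError("class_totals requires a normalized table")
    case_idx = ft.group_indices(case_group)
    ctrl_idx = ft.group_indices(control_group)
    if case_idx.size == 0 or ctrl_idx.size == 0:
        raise ValueError("both groups must have at least one sample")

    by_class: dict[str, list[int]] = {}
    for i, ann in enumerate(ft.annotations):
        if ann.is_annotated:
            by_class.setdefault(ann.lipid_class, []).append(i)

    summaries: list[ClassSummary] = []
    for cls in sorted(by_class):
        idx = by_class[cls]
        per_injection = ft.intensities[idx].sum(axis=0)
        case_vals = per_injection[case_idx]
        ctrl_vals = per_injection[ctrl_idx]
        amount_case = float(case_vals.mean())
        amount_control = float(ctrl_vals.mean())
        fc = amount_case / amount_control if amount_control > 0 else np.nan
        if case_vals.size >= 2 and ctrl_vals.size >= 2:
            if np.ptp(case_vals) == 0 and np.ptp(ctrl_vals) == 0:
                p = 1.0 if amount_case == amount_control else 0.0
            else:
                p = float(sps.ttest_ind(case_vals, ctrl_vals,
                                        equal_var=equal_var).pvalue)
        else:
            p = np.nan
        summaries.append(ClassSummary(
            lipid_class=class_display_label(cls),
            n_features=len(idx),
            amount_case=amount_case,
            amount_control=amount_control,
            class_fold_change=float(fc),
            t_p_value=p,
        ))
    return summaries


# --------------------------------------------------------------------------
# CV profile
# --------------------------------------------------------------------------


@dataclasses.dataclass
class CvProfile:
    """Per-feature CV%% over a stratum of injections + acceptable fraction."""

    group_label: str
    cv_values: np.ndarray
    threshold: float = 30.0

    @property
    def pct_acceptable(self) -> float:
        defined = self.cv_values[np.isfinite(self.cv_values)]
        if defined.size == 0:
            return float("nan")
        return 100.0 * float((defined < self.threshold).sum()) / defined.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cv_percent": self.cv_values})


def cv_profile(ft: FeatureTable, role: str | None = None,
               group: str | None = None, threshold: float = 30.0) -> CvProfile:
    """CV%% distribution over the injections of one role or sample group.

    Features with zero mean in the stratum have undefined CV and are
    excluded from ``pct_acceptable``.
    """
    if (role is None) == (group is None):
        raise ValueError("specify exactly one of role or group")
    if role is not None:
        idx = ft.role_indices(role)
        label = role
    else:
        idx = ft.group_indices(group)
        label = group
    if idx.size < 3:
        raise ValueError(f"stratum {label!r} has {idx.size} injections; need >=3")
    x = ft.intensities[:, idx]
    mean = x.mean(axis=1)
    sd = x.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, 100.0 * sd / mean, np.nan)
    return CvProfile(group_label=label, cv_values=cv, threshold=threshold)
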