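"""Biomarker discovery statistics.

Covers the univariate route (IQR filter, glog + autoscaling, Welch t-tests
with Benjamini-Hochberg correction, volcano selection), the multivariate
route (NIPALS PLS-DA, VIP scores, leave-one-out cross-validation), and their
combination into the impact factor IF = |log2 FC| * (-log10 p) * VIP, with
class-level discrimination against a distribution-free median confidence
cutoff.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .core_model import (
    ClassSummary,
    FeatureStats,
    FeatureTable,
    class_display_label,
)

logger = logging.getLogger(__name__)

_TINY_P = float(np.finfo(float).tiny)


@dataclasses.dataclass
class SelectionThresholds:
    """Cutoffs for volcano + VIP biomarker selection."""

    fc_min: float = 2.0
    q_max: float = 0.05
    vip_min: float = 1.0

    def __post_init__(self):
        if not (self.fc_min > 0 and self.q_max > 0 and self.vip_min > 0):
            raise ValueError("all selection thresholds must be strictly positive")


# --------------------------------------------------------------------------
# matrix preparation
# --------------------------------------------------------------------------


def amounts_matrix(ft: FeatureTable, case_group: str,
                   control_group: str) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Extract the samples x features amount matrix and 0/1 group coding.

    QC and blank columns are dropped; ``y`` codes control as 0 and case as 1.
    """
    case_idx = ft.group_indices(case_group)
    ctrl_idx = ft.group_indices(control_group)
    if case_idx.size == 0 or ctrl_idx.size == 0:
        raise ValueError(
            f"groups {case_group!r}/{control_group!r} not found among samples"
        )
    cols = np.concatenate([ctrl_idx, case_idx])
    X = ft.intensities[:, cols].T.copy()
    y = np.concatenate([np.zeros(ctrl_idx.size), np.ones(case_idx.size)])
    return X, y, list(ft.features["feature_id"])


def iqr_filter(X: np.ndarray, keep_fraction: float = 0.75,
               min_features: int = 250) -> tuple[np.ndarray, np.ndarray]:
    """Drop the lowest-IQR features, keeping ``keep_fraction`` of them.

    No-op when the matrix has at most ``min_features`` features.  Returns the
    filtered matrix and the boolean keep mask.
    """
    if not (0 < keep_fraction <= 1):
        raise ValueError("keep_fraction must be in (0, 1]")
    if X.shape[0] < 4:
        raise ValueError("iqr_filter requires >=4 samples")
    n = X.shape[1]
    if keep_fraction == 1 or n <= min_features:
        return X, np.ones(n, dtype=bool)
    iqr = sps.iqr(X, axis=0)
    n_keep = max(1, int(math.ceil(keep_fraction * n)))
    # stable selection: rank by IQR descending, ties by original position
    order = np.lexsort((np.arange(n), -iqr))
    keep = np.zeros(n, dtype=bool)
    keep[order[:n_keep]] = True
    logger.info("iqr_filter kept %d/%d features", n_keep, n)
    return X[:, keep], keep


def glog(x: np.ndarray, a: float) -> np.ndarray:
    """Generalized logarithm: log2((x + sqrt(x^2 + a^2)) / 2), finite at 0."""
    x = np.asarray(x, dtype=float)
    return np.log2((x + np.sqrt(x * x + a * a)) / 2.0)


def glog_autoscale(X: np.ndarray, a: float | None = None) -> tuple[np.ndarray, float]:
    """glog-transform then autoscale (per-feature mean 0, unit sample sd).

    The glog offset ``a`` defaults to the smallest positive amount in the
    matrix.  Features constant after glog are scaled to all zeros (logged).
    """
    X = np.asarray(X, dtype=float)
    if np.any(X < 0):
        raise ValueError("amounts must be non-negative")
    if a is None:
        positive = X[X > 0]
        a = float(positive.min()) if positive.size else 1.0
    Z = glog(X, a)
    mean = Z.mean(axis=0)
    sd = Z.std(axis=0, ddof=1)
    constant = sd <= 1e-12 * np.maximum(1.0, np.abs(mean))
    if constant.any():
        logger.info("glog_autoscale: %d constant features scaled to zero",
                    int(constant.sum()))
    sd_safe = np.where(constant, 1.0, sd)
    Z = (Z - mean) / sd_safe
    Z[:, constant] = 0.0
    return Z, a


# --------------------------------------------------------------------------
# univariate statistics
# --------------------------------------------------------------------------


def differential_test(X: np.ndarray, Z: np.ndarray, y: np.ndarray,
                      equal_var: bool = False) -> pd.DataFrame:
    """Per-feature fold change + two-tailed t-test with BH correction.

    Fold changes come from the untransformed amounts ``X`` (mean case /
    mean control); p-values from t-tests on the transformed matrix ``Z``.
    Features with zero control mean get an undefined fold change and are
    excluded from volcano selection downstream.
    """
    y = np.asarray(y)
    case, ctrl = y == 1, y == 0
    if case.sum() < 2 or ctrl.sum() < 2:
        raise ValueError("each group requires n >= 2")

    mean_case = X[case].mean(axis=0)
    mean_ctrl = X[ctrl].mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(mean_ctrl > 0, mean_case / mean_ctrl, np.nan)
        log2_fc = np.log2(fc)
    n_undef = int(np.isnan(fc).sum())
    if n_undef:
        logger.info("differential_test: %d features with zero control mean", n_undef)

    res = sps.ttest_ind(Z[case], Z[ctrl], axis=0, equal_var=equal_var)
    p = np.asarray(res.pvalue, dtype=float)
    # zero within-group variance in both groups: identical -> p 1, else p -> 0
    var0 = (Z[case].std(axis=0) == 0) & (Z[ctrl].std(axis=0) == 0)
    same = np.isclose(Z[case].mean(axis=0), Z[ctrl].mean(axis=0))
    p = np.where(var0 & same, 1.0, p)
    p = np.where(var0 & ~same, _TINY_P, p)
    p = np.clip(np.nan_to_num(p, nan=1.0), _TINY_P, 1.0)
    q = multipletests(p, method="fdr_bh")[1]

    return pd.DataFrame({
        "mean_case": mean_case,
        "mean_control": mean_ctrl,
        "fold_change": fc,
        "log2_fc": log2_fc,
        "p_raw": p,
        "q_fdr": q,
    })


def volcano_select(stats: pd.DataFrame,
                   thresholds: SelectionThresholds | None = None
                   ) -> tuple[np.ndarray, int, int]:
    """Volcano selection: q < q_max and FC strictly beyond fc_min either way.

    Returns (selected mask, n_up, n_down); features with undefined fold
    change are never selected.
    """
    thresholds = thresholds or SelectionThresholds()
    fc = stats["fold_change"].to_numpy()
    q = stats["q_fdr"].to_numpy()
    defined = np.isfinite(fc)
    up = defined & (fc > thresholds.fc_min)
    down = defined & (fc < 1.0 / thresholds.fc_min)
    selected = (q < thresholds.q_max) & (up | down)
    n_up = int((selected & up).sum())
    n_down = int((selected & down).sum())
    return selected, n_up, n_down


# --------------------------------------------------------------------------
# PLS-DA (NIPALS PLS1)
# --------------------------------------------------------------------------


@dataclasses.dataclass
class PlsdaModel:
    """NIPALS PLS1 model on a {0,1}-coded response.

    ``weights`` (p x A) are unit-norm per component; ``explained_y`` holds
    the fraction of centered-Y sum of squares captured by each component.
    """

    n_components: int
    weights: np.ndarray      # W, p x A
    loadings: np.ndarray     # P, p x A
    scores: np.ndarray       # T, n x A
    y_loadings: np.ndarray   # q, A
    explained_y: np.ndarray  # fraction of SS_Y per component
    y_mean: float
    x_mean: np.ndarray
    coef_: np.ndarray        # regression vector for prediction

    def predict(self, Z: np.ndarray) -> np.ndarray:
        return (np.asarray(Z) - self.x_mean) @ self.coef_ + self.y_mean


def plsda_fit(Z: np.ndarray, y: np.ndarray, n_components: int = 2) -> PlsdaModel:
    """Fit PLS1 discriminant model by NIPALS on centered {0,1} labels.

    ``Z`` is assumed already transformed (glog + autoscale).  Deterministic
    given input order; components that explain no residual variance end the
    deflation early.
    """
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = Z.shape
    if len(np.unique(y)) != 2:
        raise ValueError("y must contain exactly two groups")
    if n_components > min(n - 1, p):
        raise ValueError(
            f"n_components={n_components} exceeds min(n_samples-1, n_features)"
        )
    y_mean = float(y.mean())
    yc = y - y_mean
    ss_y = float(yc @ yc)
    if ss_y == 0:
        raise ValueError("response has zero variance")

    x_mean = Z.mean(axis=0)
    Xd = Z - x_mean
    yd = yc.copy()
    W, P, T, Q, ssy = [], [], [], [], []
    for _ in range(n_components):
        w = Xd.T @ yd
        norm = np.linalg.norm(w)
        if norm == 0:
            break
        w /= norm
        t = Xd @ w
        tt = float(t @ t)
        if tt <= 1e-12:
            break
        pvec = Xd.T @ t / tt
        qa = float(yd @ t) / tt
        Xd -= np.outer(t, pvec)
        yd = yd - qa * t
        W.append(w)
        P.append(pvec)
        T.append(t)
        Q.append(qa)
        ssy.append(qa * qa * tt)
    if not W:
        raise ValueError("no informative PLS components could be extracted")
    W = np.column_stack(W)
    P = np.column_stack(P)
    T = np.column_stack(T)
    Q = np.asarray(Q)
    ssy = np.asarray(ssy)
    # B = W (P'W)^-1 q
    coef = W @ np.linalg.solve(P.T @ W, Q)
    return PlsdaModel(
        n_components=W.shape[1],
        weights=W,
        loadings=P,
        scores=T,
        y_loadings=Q,
        explained_y=ssy / ss_y,
        y_mean=y_mean,
        x_mean=x_mean,
        coef_=coef,
    )


def vip_scores(model: PlsdaModel) -> np.ndarray:
    """Variable Importance in Projection.

    VIP_j = sqrt( p * sum_a SSY_a w_ja^2 / sum_a SSY_a ) with unit-norm
    weights, so mean(VIP^2) = 1 exactly.
    """
    ssy = model.explained_y
    total = ssy.sum()
    if total <= 0:
        raise ValueError("model explains no Y variance")
    p = model.weights.shape[0]
    contrib = (model.weights ** 2) @ ssy
    return np.sqrt(p * contrib / total)


def crossvalidate(Z: np.ndarray, y: np.ndarray, n_components: int = 2,
                  q2_warn: float = 0.8) -> tuple[float, float]:
    """Training R^2 and leave-one-out Q^2 of the PLS-DA model.

    Q^2 = 1 - PRESS/SS_tot with PRESS accumulated over leave-one-out refits.
    Emits a warning when Q^2 falls below ``q2_warn``.
    """
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("crossvalidate requires n >= 3 samples")
    ss_tot = float(((y - y.mean()) ** 2).sum())
    model = plsda_fit(Z, y, n_components)
    resid = y - model.predict(Z)
    r2 = 1.0 - float(resid @ resid) / ss_tot

    press = 0.0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        if len(np.unique(y[mask])) < 2:
            press += (y[i] - y[mask].mean()) ** 2
            continue
        a = min(n_components, mask.sum() - 1)
        sub = plsda_fit(Z[mask], y[mask], a)
        press += float((y[i] - sub.predict(Z[i][None, :])[0]) ** 2)
    q2 = 1.0 - press / ss_tot
    if q2 < q2_warn:
        logger.warning("Q^2 = %.3f below %.2f: possible overfit or weak model",
                       q2, q2_warn)
    return r2, q2


# --------------------------------------------------------------------------
# impact factor + combined selection
# --------------------------------------------------------------------------


def impact_factor(log2_fc, p, vip):
    """IF = |log2 FC| * (-log10 p) * VIP, elementwise; p = 0 clipped to the
    smallest positive float (logged)."""
    log2_fc = np.asarray(log2_fc, dtype=float)
    p = np.asarray(p, dtype=float)
    vip = np.asarray(vip, dtype=float)
    if np.any(p == 0):
        logger.info("impact_factor: clipping %d zero p-values", int((p == 0).sum()))
    p = np.clip(p, _TINY_P, 1.0)
    return np.abs(log2_fc) * (-np.log10(p)) * vip


def ranking_order(stats: pd.DataFrame) -> np.ndarray:
    """Deterministic ranking: IF descending, ties by |log2FC| then feature_id."""
    frame = stats.copy()
    frame["_abs_fc"] = np.abs(frame["log2_fc"].to_numpy())
    frame = frame.sort_values(
        by=["impact_factor", "_abs_fc", "feature_id"],
        ascending=[False, False, True],
        kind="mergesort",
    )
    return frame.index.to_numpy()


def combined_select(stats: pd.DataFrame,
                    thresholds: SelectionThresholds | None = None) -> np.ndarray:
    """Intersection of volcano selection and VIP > vip_min, as a boolean mask."""
    thresholds = thresholds or SelectionThresholds()
    return (
        stats["selected_volcano"].to_numpy(dtype=bool)
        & (stats["vip"].to_numpy() > thresholds.vip_min)
    )


def top_discriminants(stats: pd.DataFrame, n: int = 100) -> pd.DataFrame:
    """Top ``n`` features by impact factor (deterministic tie rule)."""
    order = ranking_order(stats)
    if len(order) < n:
        logger.info("top_discriminants: only %d features available (< %d)",
                    len(order), n)
    return stats.loc[order[:n]]


# --------------------------------------------------------------------------
# median confidence cutoff + class discrimination
# --------------------------------------------------------------------------


def median_lower_cl(values, confidence: float = 0.95,
                    method: str = "order", n_boot: int = 2000,
                    seed: int = 0) -> float:
    """Lower confidence limit of the median.

    ``order``: distribution-free binomial order-statistic bound — the k-th
    smallest value with k the largest integer such that
    P(Binomial(n, 1/2) < k) <= (1-confidence)/2.  ``bootstrap``: percentile
    bootstrap of the median.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n == 0:
        raise ValueError("empty sample")
    alpha = (1.0 - confidence) / 2.0
    if method == "order":
        # largest k >= 1 with P(B < k) = cdf(k-1) <= alpha; fall back to minimum
        k = 1
        for cand in range(1, n + 1):
            if sps.binom.cdf(cand - 1, n, 0.5) <= alpha:
                k = cand
            else:
                break
        return float(x[k - 1])
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        medians = np.median(
            x[rng.integers(0, n, size=(n_boot, n))], axis=1
        )
        return float(np.quantile(medians, alpha))
    raise ValueError(f"unknown method {method!r}")


def class_if_discrimination(stats: pd.DataFrame, classes: pd.Series,
                            confidence: float = 0.95,
                            method: str = "order") -> tuple[list[ClassSummary], float]:
    """Median impact factor per lipid class among combined-selected features,
    compared against the lower confidence limit of the median IF over all
    selected features.

    ``classes`` maps feature_id -> lipid class (annotated features only).
    Classes with fewer than 3 selected members are flagged ``low_n``.
    """
    sel = stats.loc[stats["selected_combined"].astype(bool)].copy()
    sel = sel[sel["feature_id"].isin(classes.index)]
    if sel.empty:
        raise ValueError("no selected annotated features")
    sel["lipid_class"] = classes.loc[sel["feature_id"]].to_numpy()
    cutoff = median_lower_cl(sel["impact_factor"].to_numpy(),
                             confidence=confidence, method=method)
    summaries: list[ClassSummary] = []
    for cls, grp in sel.groupby("lipid_class", sort=True):
        med = float(grp["impact_factor"].median())
        summaries.append(ClassSummary(
            lipid_class=class_display_label(str(cls)),
            n_features=len(grp),
            median_if=med,
            passes_cutoff=med > cutoff,
            low_n=len(grp) < 3,
        ))
    return summaries, cutoff


# --------------------------------------------------------------------------
# high-level orchestration
# --------------------------------------------------------------------------


@dataclasses.dataclass
class DiscoverConfig:
    thresholds: SelectionThresholds = dataclasses.field(
        default_factory=SelectionThresholds)
    iqr_keep_fraction: float = 0.75
    iqr_min_features: int = 250
    n_components: int = 2
    use_q_for_if: bool = True
    equal_var: bool = False
    glog_a: float | None = None
    median_cl_method: str = "order"
    top_n: int = 100


@dataclasses.dataclass
class DiscoveryResult:
    stats: pd.DataFrame          # per-feature table incl. selection flags
    model: PlsdaModel
    r2: float
    q2: float
    class_summaries: list[ClassSummary]
    class_cutoff: float
    n_up: int
    n_down: int
    glog_a: float
    iqr_mask: np.ndarray

    def feature_stats(self) -> list[FeatureStats]:
        out = []
        for row in self.stats.itertuples(index=False):
            out.append(FeatureStats(
                feature_id=row.feature_id,
                mean_case=row.mean_case,
                mean_control=row.mean_control,
                fold_change=row.fold_change,
                log2_fc=row.log2_fc,
                p_raw=row.p_raw,
                q_fdr=row.q_fdr,
                vip=row.vip,
                impact_factor=row.impact_factor,
                selected_volcano=bool(row.selected_volcano),
                selected_vip=bool(row.selected_vip),
                selected_combined=bool(row.selected_combined),
            ))
        return out


def analyze(ft: FeatureTable, case_group: str, control_group: str,
            config: DiscoverConfig | None = None) -> DiscoveryResult:
    """Run the full discovery chain on a normalized feature table."""
    cfg = config or DiscoverConfig()
    X, y, feature_ids = amounts_matrix(ft, case_group, control_group)
    X, keep = iqr_filter(X, cfg.iqr_keep_fraction, cfg.iqr_min_features)
    feature_ids = [fid for fid, k in zip(feature_ids, keep) if k]

    Z, a = glog_autoscale(X, cfg.glog_a)
    stats = differential_test(X, Z, y, equal_var=cfg.equal_var)
    stats.insert(0, "feature_id", feature_ids)

    selected, n_up, n_down = volcano_select(stats, cfg.thresholds)
    stats["selected_volcano"] = selected

    n_comp = min(cfg.n_components, len(y) - 1, Z.shape[1])
    model = plsda_fit(Z, y, n_comp)
    vip = vip_scores(model)
    stats["vip"] = vip
    stats["selected_vip"] = vip > cfg.thresholds.vip_min
    r2, q2 = crossvalidate(Z, y, n_comp)

    p_for_if = stats["q_fdr"] if cfg.use_q_for_if else stats["p_raw"]
    stats["impact_factor"] = impact_factor(
        stats["log2_fc"].to_numpy(), p_for_if.to_numpy(), vip)
    stats["selected_combined"] = combined_select(stats, cfg.thresholds)

    classes = pd.Series(
        {
            fid: ann.lipid_class
            for fid, ann in zip(ft.features["feature_id"], ft.annotations)
            if ann.is_annotated
        }
    )
    try:
        class_summaries, cutoff = class_if_discrimination(
            stats, classes, method=cfg.median_cl_method)
    except ValueError:
        logger.warning("no selected annotated features; class discrimination skipped")
        class_summaries, cutoff = [], float("nan")

    return DiscoveryResult(
        stats=stats,
        model=model,
        r2=r2,
        q2=q2,
        class_summaries=class_summaries,
        class_cutoff=cutoff,
        n_up=n_up,
        n_down=n_down,
        glog_a=a,
        iqr_mask=keep,
    )
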