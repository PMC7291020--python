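"""Synthetic batch generator with ground truth.

Emulates a two-group untargeted-lipidomics batch: lognormal feature
intensities organized by lipid class, chosen per-feature fold changes,
pooled-QC injections interleaved every few samples, blank injections,
smooth injection-order drift, per-sample protein amounts multiplied into
the raw signal, and optional isomeric duplicate annotations.  Every batch
carries a manifest that, together with the seed, fully determines it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .core_model import (
    FeatureTable,
    GLYCEROPHOSPHOLIPID_CLASSES,
    ROLE_BLANK,
    ROLE_QC,
    ROLE_SAMPLE,
    parse_lipid_name,
)

logger = logging.getLogger(__name__)

DEFAULT_CLASS_MIX = {
    "PC": 30, "PE": 20, "SM": 15, "TG": 15, "Cer": 10,
    "HexCer": 5, "CE": 5, "LPC": 5, "PI": 5, "DG": 5, "Hex2Cer": 3, "GM3": 2,
}

# plausible total-carbon ranges per class (both chains summed)
_CARBON_RANGE = {
    "LPC": (14, 22), "LPE": (14, 22), "FA": (12, 24), "CAR": (12, 24),
    "TG": (44, 58), "CE": (14, 24), "DG": (30, 40),
}


@dataclasses.dataclass
class SimConfig:
    """Batch design parameters; all randomness flows from ``seed``."""

    n_features_per_class: dict[str, int] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    n_case: int = 3
    n_control: int = 3
    case_label: str = "CF"
    control_label: str = "H"
    n_blanks: int = 2
    qc_interval: int = 4
    n_lead_qcs: int = 2
    drift: str = "none"              # none | linear | sinusoidal
    drift_magnitude: float = 2.0     # end/start fold for linear; peak amp factor
    noise_cv: float = 0.16
    spikes: list[tuple[str, float]] = dataclasses.field(default_factory=list)
    n_random_spikes: int = 0
    random_spike_fc: float = 4.0
    blank_fraction: float = 0.01
    carryover_fraction: float = 0.0
    carryover_level: float = 0.5
    isomer_fraction: float = 0.0
    protein_ug_range: tuple[float, float] = (8.0, 12.0)
    id_score_range: tuple[float, float] = (70.0, 99.0)
    seed: int = 0

    def __post_init__(self):
        if self.qc_interval < 1:
            raise ValueError("qc_interval must be >= 1")
        if not self.noise_cv > 0:
            raise ValueError("noise_cv must be > 0")
        for sel, fc in self.spikes:
            if not fc > 0:
                raise ValueError(f"fold change for {sel!r} must be > 0")
        if self.drift not in ("none", "linear", "sinusoidal"):
            raise ValueError(f"unknown drift model {self.drift!r}")


@dataclasses.dataclass
class BatchManifest:
    """Ground truth of a generated batch."""

    seed: int
    feature_ids: list[str]
    lipid_class: dict[str, str]
    base_intensity: dict[str, float]
    true_fold_change: dict[str, float]
    spiked: list[str]
    drift: str
    drift_magnitude: float
    noise_cv: float

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "BatchManifest":
        return cls(**json.loads(Path(path).read_text()))


def _drift_factor(cfg: SimConfig, order: np.ndarray, n_total: int) -> np.ndarray:
    t = (order - 1) / max(n_total - 1, 1)
    if cfg.drift == "linear":
        return 1.0 + (cfg.drift_magnitude - 1.0) * t
    if cfg.drift == "sinusoidal":
        return 1.0 + 0.5 * (cfg.drift_magnitude - 1.0) * np.sin(2 * np.pi * t)
    return np.ones_like(t)


def _make_name(cls: str, rng: np.random.Generator) -> str:
    lo, hi = _CARBON_RANGE.get(cls, (30, 44))
    carbons = int(rng.integers(lo // 2, hi // 2 + 1)) * 2
    db = int(rng.integers(0, 7))
    db = min(db, carbons - 1)
    if cls in GLYCEROPHOSPHOLIPID_CLASSES and rng.random() < 0.2:
        prefix = "O-" if rng.random() < 0.5 else "P-"
        return f"{cls} {prefix}{carbons}:{db}"
    return f"{cls} {carbons}:{db}"


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with unit mean and the given CV."""
    sigma = float(np.sqrt(np.log1p(cv * cv)))
    return rng.lognormal(mean=-sigma * sigma / 2.0, sigma=sigma, size=size)


def generate_batch(cfg: SimConfig) -> tuple[FeatureTable, BatchManifest]:
    """Generate a deterministic synthetic batch and its ground-truth manifest."""
    rng = np.random.default_rng(cfg.seed)

    # ---- features ---------------------------------------------------------
    classes, names = [], []
    for cls, n in cfg.n_features_per_class.items():
        for _ in range(n):
            classes.append(cls)
            names.append(_make_name(cls, rng))
    n_feat = len(classes)
    if n_feat == 0:
        raise ValueError("empty class mix")
    feature_ids = [f"F{i + 1:05d}" for i in range(n_feat)]

    class_mu = {cls: rng.uniform(np.log(1e4), np.log(1e6))
                for cls in cfg.n_features_per_class}
    base = np.exp(np.array([class_mu[c] for c in classes])
                  + rng.normal(0, 0.8, n_feat))

    # ---- spikes -----------------------------------------------------------
    true_fc = np.ones(n_feat)
    for selector, fc in cfg.spikes:
        hits = [
            i for i in range(n_feat)
            if classes[i] == selector or feature_ids[i] == selector
        ]
        if not hits:
            raise ValueError(f"spike selector {selector!r} matches no feature")
        true_fc[hits] = fc
    if cfg.n_random_spikes:
        unspiked = np.flatnonzero(true_fc == 1.0)
        if cfg.n_random_spikes > unspiked.size:
            raise ValueError("n_random_spikes exceeds available features")
        chosen = rng.choice(unspiked, size=cfg.n_random_spikes, replace=False)
        true_fc[chosen] = cfg.random_spike_fc
    spiked = [feature_ids[i] for i in np.flatnonzero(true_fc != 1.0)]

    carryover = rng.random(n_feat) < cfg.carryover_fraction

    # ---- injection layout -------------------------------------------------
    n_samples = cfg.n_case + cfg.n_control
    group_of = ([cfg.case_label] * cfg.n_case
                + [cfg.control_label] * cfg.n_control)
    sample_perm = rng.permutation(n_samples)  # randomized run order

    layout: list[tuple[str, str, float | None]] = []  # (role, group, protein)
    protein = rng.uniform(*cfg.protein_ug_range, size=n_samples)
    for b in range(cfg.n_blanks):
        layout.append((ROLE_BLANK, "", None))
    for _ in range(cfg.n_lead_qcs):
        layout.append((ROLE_QC, "", None))
    for k, s in enumerate(sample_perm):
        layout.append((ROLE_SAMPLE, group_of[s], float(protein[s])))
        if (k + 1) % cfg.qc_interval == 0 and k + 1 < n_samples:
            layout.append((ROLE_QC, "", None))
    layout.append((ROLE_QC, "", None))

    n_inj = len(layout)
    orders = np.arange(1, n_inj + 1, dtype=float)
    drift = _drift_factor(cfg, orders, n_inj)

    # ---- intensities ------------------------------------------------------
    mean_ctrl = base
    mean_case = base * true_fc
    pooled = 0.5 * (mean_ctrl + mean_case)  # QC = mix of all samples

    intensities = np.zeros((n_feat, n_inj))
    for j, (role, group, prot) in enumerate(layout):
        noise = _lognormal_noise(rng, cfg.noise_cv, n_feat)
        if role == ROLE_SAMPLE:
            mu = mean_case if group == cfg.case_label else mean_ctrl
            intensities[:, j] = mu * prot * drift[j] * noise
        elif role == ROLE_QC:
            intensities[:, j] = pooled * np.mean(protein) * drift[j] * noise
        else:  # blank
            level = np.where(carryover, cfg.carryover_level, cfg.blank_fraction)
            intensities[:, j] = (base * np.mean(protein) * level
                                 * drift[j] * noise)

    # ---- isomer duplicates ------------------------------------------------
    if cfg.isomer_fraction > 0:
        dup_idx = np.flatnonzero(rng.random(n_feat) < cfg.isomer_fraction)
        for i in dup_idx:
            feature_ids.append(f"F{len(feature_ids) + 1:05d}")
            classes.append(classes[i])
            names.append(names[i])
            split = rng.uniform(0.3, 0.7)
            dup_row = intensities[i] * (1 - split)
            intensities[i] = intensities[i] * split
            intensities = np.vstack([intensities, dup_row[None, :]])
            base = np.append(base, base[i])
            true_fc = np.append(true_fc, true_fc[i])
        n_feat = len(feature_ids)

    # ---- assemble ---------------------------------------------------------
    features = pd.DataFrame({
        "feature_id": feature_ids,
        "mz": np.round(rng.uniform(400.0, 1100.0, n_feat), 4),
        "rt": np.round(rng.uniform(0.5, 20.0, n_feat), 3),
        "name": names,
        "id_score": np.round(rng.uniform(*cfg.id_score_range, n_feat), 1),
    })
    features["annotation"] = [parse_lipid_name(n) for n in features["name"]]

    injections = pd.DataFrame({
        "injection_id": [
            f"{role}{j + 1:03d}" for j, (role, _, _) in enumerate(layout)
        ],
        "role": [role for role, _, _ in layout],
        "group": [group for _, group, _ in layout],
        "order": np.arange(1, n_inj + 1),
        "protein_ug": [prot for _, _, prot in layout],
    })

    ft = FeatureTable(
        features=features,
        injections=injections,
        intensities=intensities,
        normalization_state="raw",
    )
    manifest = BatchManifest(
        seed=cfg.seed,
        feature_ids=list(feature_ids),
        lipid_class=dict(zip(feature_ids, classes)),
        base_intensity={fid: float(b) for fid, b in zip(feature_ids, base)},
        true_fold_change={fid: float(f) for fid, f in zip(feature_ids, true_fc)},
        spiked=spiked,
        drift=cfg.drift,
        drift_magnitude=cfg.drift_magnitude,
        noise_cv=cfg.noise_cv,
    )
    return ft, manifest


# --------------------------------------------------------------------------
# recovery evaluation
# --------------------------------------------------------------------------


def evaluate_recovery(stats: pd.DataFrame, manifest: BatchManifest,
                      q_max: float = 0.05, ks: tuple[int, ...] = (20, 50)
                      ) -> dict:
    """Precision/recall of the true spiked features under several rankings.

    ``stats`` must contain feature_id, q_fdr, impact_factor, vip.  Returns
    recall of spikes at q < q_max plus precision@k for rankings by IF,
    by q (ascending), and by VIP.
    """
    known = set(manifest.feature_ids)
    present = stats["feature_id"].isin(known)
    if not present.any():
        raise ValueError("stats and manifest share no feature ids")
    spiked = set(manifest.spiked)
    if not spiked:
        raise ValueError("manifest contains no spiked features")

    frame = stats.loc[present].copy()
    frame["is_spike"] = frame["feature_id"].isin(spiked)

    sig = frame["q_fdr"] < q_max
    recall_q = float((sig & frame["is_spike"]).sum()) / len(spiked)

    rankings = {
        "if": frame.sort_values(["impact_factor", "feature_id"],
                                ascending=[False, True], kind="mergesort"),
        "q": frame.sort_values(["q_fdr", "feature_id"],
                               ascending=[True, True], kind="mergesort"),
        "vip": frame.sort_values(["vip", "feature_id"],
                                 ascending=[False, True], kind="mergesort"),
    }
    out = {"recall_q": recall_q, "n_spiked": len(spiked)}
    for name, ranked in rankings.items():
        hits = ranked["is_spike"].to_numpy()
        for k in ks:
            kk = min(k, len(ranked))
            out[f"precision_at_{k}_{name}"] = float(hits[:kk].mean())
        out[f"average_precision_{name}"] = _average_precision(hits)
    return out


def _average_precision(hits: np.ndarray) -> float:
    """Average precision of a binary relevance ranking."""
    hits = np.asarray(hits, dtype=bool)
    if hits.sum() == 0:
        return 0.0
    cum = np.cumsum(hits)
    prec = cum / (np.arange(len(hits)) + 1)
    return float(prec[hits].sum() / hits.sum())
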