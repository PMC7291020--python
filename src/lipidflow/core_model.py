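"""Domain types, lipid shorthand-name parsing, and feature-table I/O.

The central object is :class:`FeatureTable`: a dense feature x injection
intensity matrix carrying per-feature lipid annotations and per-injection
metadata (role, group, injection order, protein amount).  Every pipeline
stage consumes and returns a ``FeatureTable``, advancing its
``normalization_state`` monotonically from ``raw`` toward
``protein_normalized`` / ``tic_normalized``.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import re
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# --------------------------------------------------------------------------
# lipid class vocabulary
# --------------------------------------------------------------------------

GLYCEROPHOSPHOLIPID_CLASSES = frozenset(
    {
        "PC", "PE", "PS", "PI", "PG", "PA",
        "LPC", "LPE", "LPS", "LPI", "LPG", "LPA",
        "CL", "BMP",
    }
)
SPHINGOLIPID_CLASSES = frozenset(
    {"Cer", "CerP", "DhCer", "HexCer", "Hex2Cer", "Hex3Cer", "GM3", "SM",
     "Sph", "SL", "SHexCer"}
)
NEUTRAL_LIPID_CLASSES = frozenset(
    {"TG", "DG", "MG", "CE", "ChE", "FA", "CAR", "ST", "Cho"}
)
KNOWN_CLASSES = GLYCEROPHOSPHOLIPID_CLASSES | SPHINGOLIPID_CLASSES | NEUTRAL_LIPID_CLASSES

#: Display-name substitutions used in class-level summaries.
CLASS_DISPLAY_LABELS = {"Hex2Cer": "LacCer"}

ETHER_NONE = "none"
ETHER_O = "O"  # plasmanyl
ETHER_P = "P"  # plasmenyl

ROLE_SAMPLE = "sample"
ROLE_QC = "qc"
ROLE_BLANK = "blank"
VALID_ROLES = (ROLE_SAMPLE, ROLE_QC, ROLE_BLANK)

#: Forward-only ordering of normalization states.
_STATE_ORDER = {
    "raw": 0,
    "drift_corrected": 1,
    "protein_normalized": 2,
    "tic_normalized": 2,
}


def class_display_label(lipid_class: str) -> str:
    """Label used when reporting a class in summaries (e.g. Hex2Cer -> LacCer)."""
    return CLASS_DISPLAY_LABELS.get(lipid_class, lipid_class)


# --------------------------------------------------------------------------
# LipidAnnotation + parser
# --------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class LipidAnnotation:
    """Parsed lipid shorthand name at sum-composition resolution.

    ``lipid_class`` is ``None`` for features whose name could not be
    interpreted; such features stay in the table but are excluded from
    class-level aggregation and composition profiling.
    """

    raw_name: str
    lipid_class: str | None = None
    total_carbons: int = 0
    total_double_bonds: int = 0
    ether_linkage: str = ETHER_NONE
    odd_chain: bool = False

    @property
    def is_annotated(self) -> bool:
        return self.lipid_class is not None

    @property
    def is_glycerophospholipid(self) -> bool:
        return self.lipid_class in GLYCEROPHOSPHOLIPID_CLASSES

    @property
    def is_ether(self) -> bool:
        return self.ether_linkage != ETHER_NONE

    def sum_composition_key(self) -> tuple | None:
        """Key identifying isomeric species: class + carbons + double bonds + ether."""
        if not self.is_annotated:
            return None
        return (self.lipid_class, self.total_carbons, self.total_double_bonds,
                self.ether_linkage)

    @classmethod
    def unannotated(cls, raw_name: str) -> "LipidAnnotation":
        return cls(raw_name=raw_name)


# One acyl/sphingoid chain token, e.g. "16:0", "d18:1", "O-16:0", "18:1;2O",
# "34:2e".  The ";..." tail carries hydroxylation counts and is ignored at
# sum-composition level; a trailing lowercase e/p marks an ether linkage in
# the older suffix dialect.
_CHAIN_RE = re.compile(
    r"^(?:[dtm])?"          # sphingoid base prefix (d18:1 etc.)
    r"(?:(O|P)-)?"          # ether prefix dialect
    r"(\d+):(\d+)"          # carbons:double bonds
    r"(?:;[0-9A-Za-z()]+)?"  # hydroxyl / oxygen annotation, e.g. ";2O"
    r"([ep])?$"             # ether suffix dialect
)

_NAME_RE = re.compile(
    r"^(?P<cls>[A-Za-z][A-Za-z0-9]*?)"
    r"(?:[ (](?P<body>[^()]*)\)?)?$"
)


def _parse_chain(token: str) -> tuple[int, int, str] | None:
    m = _CHAIN_RE.match(token.strip())
    if m is None:
        return None
    prefix, carbons, dbs, suffix = m.groups()
    ether = ETHER_NONE
    if prefix == "O" or suffix == "e":
        ether = ETHER_O
    if prefix == "P" or suffix == "p":
        ether = ETHER_P
    return int(carbons), int(dbs), ether


def parse_lipid_name(name: str) -> LipidAnnotation:
    """Parse a lipid shorthand name into a sum-composition annotation.

    Accepts sum-composition names ("PC 34:2"), chain-resolved names
    ("PC 16:0_18:2", "Cer 18:1;2O/16:0") and both ether dialects
    ("PC O-34:2" and "PC 34:2e").  Total never raises: anything that does
    not parse against the known class vocabulary comes back as an
    unannotated marker.
    """
    raw = name if isinstance(name, str) else ""
    text = raw.strip()
    if not text:
        return LipidAnnotation.unannotated(raw)

    m = _NAME_RE.match(text)
    if m is None:
        logger.debug("unparseable lipid name: %r", raw)
        return LipidAnnotation.unannotated(raw)
    cls, body = m.group("cls"), m.group("body")
    if cls not in KNOWN_CLASSES:
        # try greedy class token (Hex2Cer has digits inside)
        candidates = [c for c in KNOWN_CLASSES if text.startswith(c)]
        if candidates:
            cls = max(candidates, key=len)
            body = text[len(cls):].lstrip(" (").rstrip(")")
        else:
            logger.debug("unknown lipid class in %r", raw)
            return LipidAnnotation.unannotated(raw)
    if not body:
        return LipidAnnotation.unannotated(raw)

    carbons = dbs = 0
    ether = ETHER_NONE
    for token in re.split(r"[/_]", body):
        parsed = _parse_chain(token)
        if parsed is None:
            logger.debug("unparseable chain %r in %r", token, raw)
            return LipidAnnotation.unannotated(raw)
        c, d, e = parsed
        carbons += c
        dbs += d
        if e != ETHER_NONE:
            ether = e
    if carbons < dbs or carbons == 0:
        logger.debug("implausible composition in %r", raw)
        return LipidAnnotation.unannotated(raw)
    if ether != ETHER_NONE and cls not in GLYCEROPHOSPHOLIPID_CLASSES:
        logger.debug("ether linkage on non-glycerophospholipid %r", raw)
        return LipidAnnotation.unannotated(raw)
    return LipidAnnotation(
        raw_name=raw,
        lipid_class=cls,
        total_carbons=carbons,
        total_double_bonds=dbs,
        ether_linkage=ether,
        odd_chain=carbons % 2 == 1,
    )


# --------------------------------------------------------------------------
# Injection metadata + feature table
# --------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class InjectionMeta:
    injection_id: str
    role: str
    group: str = ""
    order: int = 0
    protein_ug: float | None = None

    def __post_init__(self):
        if self.role not in VALID_ROLES:
            raise ValueError(f"invalid role {self.role!r} for {self.injection_id}")
        if self.role != ROLE_SAMPLE and self.group:
            raise ValueError(
                f"{self.injection_id}: group must be empty for role {self.role}"
            )
        if self.role == ROLE_SAMPLE and (self.protein_ug is None or not self.protein_ug > 0):
            raise ValueError(f"{self.injection_id}: sample requires protein_ug > 0")
        if self.order <= 0:
            raise ValueError(f"{self.injection_id}: order must be positive")


FEATURE_COLUMNS = ["feature_id", "mz", "rt", "name", "id_score"]
META_COLUMNS = ["injection_id", "role", "group", "order", "protein_ug"]


@dataclasses.dataclass
class FeatureTable:
    """Feature x injection intensity matrix with metadata and annotations.

    ``features`` holds one row per feature (feature_id, mz, rt, name,
    id_score, annotation); ``injections`` one row per injection
    (injection_id, role, group, order, protein_ug); ``intensities`` is the
    dense non-negative matrix aligned to both.
    """

    features: pd.DataFrame
    injections: pd.DataFrame
    intensities: np.ndarray
    normalization_state: str = "raw"

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        if self.normalization_state not in _STATE_ORDER:
            raise ValueError(f"unknown normalization_state {self.normalization_state!r}")
        nf, ni = len(self.features), len(self.injections)
        if self.intensities.shape != (nf, ni):
            raise ValueError(
                f"intensity matrix shape {self.intensities.shape} does not match "
                f"{nf} features x {ni} injections"
            )
        if np.any(self.intensities < 0):
            raise ValueError("negative intensities")
        orders = self.injections["order"].to_numpy()
        if len(np.unique(orders)) != ni:
            raise ValueError("duplicate injection order")
        if (orders <= 0).any():
            raise ValueError("injection orders must be positive")
        bad_roles = set(self.injections["role"]) - set(VALID_ROLES)
        if bad_roles:
            raise ValueError(f"invalid roles: {sorted(bad_roles)}")
        samp = self.injections["role"] == ROLE_SAMPLE
        prot = pd.to_numeric(self.injections.loc[samp, "protein_ug"], errors="coerce")
        if prot.isna().any() or (prot <= 0).any():
            raise ValueError("every sample injection requires protein_ug > 0")
        if self.features["feature_id"].duplicated().any():
            raise ValueError("duplicate feature_id")

    # -- convenience --------------------------------------------------------

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def n_injections(self) -> int:
        return len(self.injections)

    @property
    def annotations(self) -> list[LipidAnnotation]:
        return list(self.features["annotation"])

    def role_indices(self, role: str) -> np.ndarray:
        return np.flatnonzero((self.injections["role"] == role).to_numpy())

    @property
    def sample_indices(self) -> np.ndarray:
        return self.role_indices(ROLE_SAMPLE)

    @property
    def qc_indices(self) -> np.ndarray:
        return self.role_indices(ROLE_QC)

    @property
    def blank_indices(self) -> np.ndarray:
        return self.role_indices(ROLE_BLANK)

    def sample_groups(self) -> pd.Series:
        """Group label per sample column (index = column position)."""
        idx = self.sample_indices
        return pd.Series(
            self.injections["group"].to_numpy()[idx], index=idx, name="group"
        )

    def group_indices(self, group: str) -> np.ndarray:
        mask = (self.injections["role"] == ROLE_SAMPLE) & (
            self.injections["group"] == group
        )
        return np.flatnonzero(mask.to_numpy())

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            features=self.features.copy(),
            injections=self.injections.copy(),
            intensities=self.intensities.copy(),
            normalization_state=self.normalization_state,
        )

    def subset_features(self, mask: np.ndarray) -> "FeatureTable":
        mask = np.asarray(mask, dtype=bool)
        return FeatureTable(
            features=self.features.loc[mask].reset_index(drop=True),
            injections=self.injections.copy(),
            intensities=self.intensities[mask],
            normalization_state=self.normalization_state,
        )

    def with_state(self, new_state: str) -> "FeatureTable":
        """Return a shallow copy advanced to ``new_state`` (forward-only)."""
        if _STATE_ORDER[new_state] < _STATE_ORDER[self.normalization_state]:
            raise ValueError(
                f"cannot move normalization_state backward: "
                f"{self.normalization_state} -> {new_state}"
            )
        out = self.copy()
        out.normalization_state = new_state
        return out


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------


def _read_delimited(path: str | Path) -> pd.DataFrame:
    """Read a tab- or comma-delimited text file, auto-detecting the delimiter."""
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= header.count(",") else ","
    return pd.read_csv(path, sep=sep, float_precision="round_trip")


def read_metadata(meta_path: str | Path) -> pd.DataFrame:
    meta = _read_delimited(meta_path)
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata file missing columns: {missing}")
    meta = meta[META_COLUMNS].copy()
    meta["injection_id"] = meta["injection_id"].astype(str)
    meta["group"] = meta["group"].fillna("").astype(str)
    meta["order"] = pd.to_numeric(meta["order"], errors="raise").astype(int)
    meta["protein_ug"] = pd.to_numeric(meta["protein_ug"], errors="coerce")
    # construct InjectionMeta for per-row validation
    for row in meta.itertuples(index=False):
        InjectionMeta(
            injection_id=row.injection_id,
            role=row.role,
            group=row.group,
            order=row.order,
            protein_ug=None if pd.isna(row.protein_ug) else float(row.protein_ug),
        )
    return meta.reset_index(drop=True)


def read_feature_table(table_path: str | Path, meta_path: str | Path) -> FeatureTable:
    """Read an aligned feature table + injection metadata into a FeatureTable.

    The table must contain ``feature_id, mz, rt, name, id_score`` followed by
    one intensity column per injection_id in the metadata.  Columns present
    in one file but not the other are an error; missing intensity cells are
    read as 0 with a logged count.
    """
    table = _read_delimited(table_path)
    meta = read_metadata(meta_path)

    missing = [c for c in FEATURE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")

    intensity_cols = [c for c in table.columns if c not in FEATURE_COLUMNS]
    meta_ids = list(meta["injection_id"])
    extra = sorted(set(intensity_cols) - set(meta_ids))
    if extra:
        raise ValueError(f"intensity columns absent from metadata: {extra}")
    absent = sorted(set(meta_ids) - set(intensity_cols))
    if absent:
        raise ValueError(f"metadata injections absent from feature table: {absent}")

    mat = table[meta_ids].apply(pd.to_numeric, errors="raise")
    n_missing = int(mat.isna().to_numpy().sum())
    if n_missing:
        logger.info("read %d missing intensity cells as 0", n_missing)
        mat = mat.fillna(0.0)

    features = table[FEATURE_COLUMNS].copy()
    features["feature_id"] = features["feature_id"].astype(str)
    features["name"] = features["name"].fillna("").astype(str)
    features["annotation"] = [parse_lipid_name(n) for n in features["name"]]
    n_unannot = sum(not a.is_annotated for a in features["annotation"])
    if n_unannot:
        logger.info("%d/%d features unannotated after parsing", n_unannot, len(features))

    return FeatureTable(
        features=features.reset_index(drop=True),
        injections=meta,
        intensities=mat.to_numpy(dtype=float),
        normalization_state="raw",
    )


def write_feature_table(ft: FeatureTable, table_path: str | Path,
                        meta_path: str | Path) -> None:
    """Write a FeatureTable back to TSV (full float precision)."""
    out = ft.features[FEATURE_COLUMNS].copy()
    for j, inj in enumerate(ft.injections["injection_id"]):
        out[inj] = ft.intensities[:, j]
    out.to_csv(table_path, sep="\t", index=False)
    ft.injections.to_csv(meta_path, sep="\t", index=False)


# --------------------------------------------------------------------------
# Result records
# --------------------------------------------------------------------------


@dataclasses.dataclass
class FeatureStats:
    """Per-feature differential statistics and the combined impact factor."""

    feature_id: str
    mean_case: float = math.nan
    mean_control: float = math.nan
    fold_change: float = math.nan
    log2_fc: float = math.nan
    p_raw: float = math.nan
    q_fdr: float = math.nan
    vip: float = math.nan
    impact_factor: float = math.nan
    selected_volcano: bool = False
    selected_vip: bool = False
    selected_combined: bool = False


@dataclasses.dataclass
class ClassSummary:
    """Per-class aggregate amounts, fold change, and median impact factor."""

    lipid_class: str
    n_features: int
    amount_case: float = math.nan
    amount_control: float = math.nan
    class_fold_change: float = math.nan
    t_p_value: float = math.nan
    median_if: float = math.nan
    passes_cutoff: bool = False
    low_n: bool = False


FEATURE_STATS_COLUMNS = [
    "feature_id", "mean_case", "mean_control", "fold_change", "log2_fc",
    "p_raw", "q_fdr", "vip", "impact_factor",
    "selected_volcano", "selected_vip", "selected_combined",
]
CLASS_SUMMARY_COLUMNS = [
    "lipid_class", "n_features", "amount_case", "amount_control",
    "class_fold_change", "t_p_value", "median_if", "passes_cutoff", "low_n",
]


def stats_to_frame(stats: Sequence[FeatureStats]) -> pd.DataFrame:
    return pd.DataFrame(
        [dataclasses.asdict(s) for s in stats], columns=FEATURE_STATS_COLUMNS
    )


def summaries_to_frame(summaries: Sequence[ClassSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [dataclasses.asdict(s) for s in summaries], columns=CLASS_SUMMARY_COLUMNS
    )


def write_results(stats: Sequence[FeatureStats], summaries: Sequence[ClassSummary],
                  out_dir: str | Path) -> tuple[Path, Path]:
    """Write features.tsv and classes.tsv with stable column order."""
    if not stats:
        raise ValueError("stats must be non-empty")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fpath = out_dir / "features.tsv"
    cpath = out_dir / "classes.tsv"
    stats_to_frame(stats).to_csv(fpath, sep="\t", index=False, float_format="%.17g")
    summaries_to_frame(summaries).to_csv(cpath, sep="\t", index=False,
                                         float_format="%.17g")
    return fpath, cpath


def read_results(out_dir: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    out_dir = Path(out_dir)
    return (
        pd.read_csv(out_dir / "features.tsv", sep="\t"),
        pd.read_csv(out_dir / "classes.tsv", sep="\t"),
    )
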