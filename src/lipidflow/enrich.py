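"""Ranked term enrichment and acyl-chain composition profiling.

The enrichment engine is generic over a user-supplied term -> lipid mapping
(class codes or shorthand globs); a tiny built-in demo mapping ships for
tests.  Composition profiling buckets annotated lipids into SFA/MUFA/PUFA
saturation classes and, among glycerophospholipids, ether vs. ester
linkage, with chi-square / exact binomial comparisons between subsets.
"""

from __future__ import annotations

import dataclasses
import fnmatch
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .core_model import ETHER_NONE, KNOWN_CLASSES, LipidAnnotation

logger = logging.getLogger(__name__)

TERM_CATEGORIES = (
    "lipid function",
    "cellular component",
    "physical-chemical properties",
    "lipid class",
)

SATURATION_BUCKETS = ("SFA", "MUFA", "PUFA")


@dataclasses.dataclass
class TermMapping:
    """One ontology-style term with a membership pattern.

    ``member_pattern`` is either a lipid class code (matches every lipid of
    that class) or a shell-style glob matched against the shorthand name.
    """

    term_id: str
    term_label: str
    category: str
    member_pattern: str

    def resolve(self, annotations: dict[str, LipidAnnotation]) -> list[str]:
        """Feature ids whose annotation matches this term."""
        if self.member_pattern in KNOWN_CLASSES:
            return [
                fid for fid, ann in annotations.items()
                if ann.lipid_class == self.member_pattern
            ]
        return [
            fid for fid, ann in annotations.items()
            if fnmatch.fnmatch(ann.raw_name, self.member_pattern)
        ]


@dataclasses.dataclass
class EnrichmentResult:
    term_id: str
    term_label: str
    category: str
    n_members: int
    statistic: float
    p: float
    q_fdr: float = float("nan")

    @property
    def enriched(self) -> bool:
        return self.q_fdr < 0.05


def read_term_mapping(path: str | Path) -> list[TermMapping]:
    """Read a TSV with columns term_id, label, category, member_pattern."""
    frame = pd.read_csv(path, sep="\t")
    required = ["term_id", "label", "category", "member_pattern"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"term mapping missing columns: {missing}")
    return [
        TermMapping(str(r.term_id), str(r.label), str(r.category),
                    str(r.member_pattern))
        for r in frame.itertuples(index=False)
    ]


def builtin_demo_mapping() -> list[TermMapping]:
    """Small demonstration mapping from lipid classes to membrane/organelle
    style terms, for tests and examples."""
    rows = [
        ("DEMO:0001", "plasma membrane component", "cellular component", "PC"),
        ("DEMO:0002", "plasma membrane component (SM)", "cellular component", "SM"),
        ("DEMO:0003", "endoplasmic reticulum component", "cellular component", "PE"),
        ("DEMO:0004", "mitochondrion component", "cellular component", "CL"),
        ("DEMO:0005", "lipid storage", "lipid function", "TG"),
        ("DEMO:0006", "lipid storage (CE)", "lipid function", "CE"),
        ("DEMO:0007", "membrane signalling sphingolipid", "lipid function", "Cer"),
        ("DEMO:0008", "glycosphingolipid", "lipid class", "HexCer"),
        ("DEMO:0009", "ether-linked PC", "physical-chemical properties", "PC O-*"),
        ("DEMO:0010", "lysophospholipid", "lipid class", "LPC"),
    ]
    return [TermMapping(*row) for row in rows]


# --------------------------------------------------------------------------
# ranked enrichment
# --------------------------------------------------------------------------


def ranked_enrichment(ranking: pd.Series,
                      mapping: list[TermMapping],
                      annotations: dict[str, LipidAnnotation],
                      min_members: int = 3) -> list[EnrichmentResult]:
    """Ranked enrichment with a one-tailed Welch two-sample t-test per term.

    ``ranking`` maps feature_id -> ranking statistic (higher = more
    case-associated).  Per term, members are tested against non-members with
    alternative "members greater"; q-values are BH-corrected across terms and
    results are sorted by ascending q.
    """
    ranking = ranking.dropna()
    if len(ranking) < 10:
        raise ValueError("ranking must cover at least 10 lipids")
    results: list[EnrichmentResult] = []
    for term in mapping:
        members = [fid for fid in term.resolve(annotations) if fid in ranking.index]
        if len(members) < min_members:
            logger.warning("term %s dropped: %d resolvable members < %d",
                           term.term_id, len(members), min_members)
            continue
        member_vals = ranking.loc[members].to_numpy()
        other_vals = ranking.drop(index=members).to_numpy()
        if other_vals.size < 2:
            logger.warning("term %s dropped: too few non-members", term.term_id)
            continue
        res = sps.ttest_ind(member_vals, other_vals, equal_var=False,
                            alternative="greater")
        results.append(EnrichmentResult(
            term_id=term.term_id,
            term_label=term.term_label,
            category=term.category,
            n_members=len(members),
            statistic=float(res.statistic),
            p=float(np.clip(res.pvalue, np.finfo(float).tiny, 1.0)),
        ))
    if not results:
        raise ValueError("no terms with resolvable members")
    q = multipletests([r.p for r in results], method="fdr_bh")[1]
    for r, qv in zip(results, q):
        r.q_fdr = float(qv)
    results.sort(key=lambda r: (r.q_fdr, r.p, r.term_id))
    return results


def enrichment_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "term_id": r.term_id,
            "label": r.term_label,
            "category": r.category,
            "n_members": r.n_members,
            "statistic": r.statistic,
            "p": r.p,
            "q_fdr": r.q_fdr,
            "enriched": r.enriched,
        }
        for r in results
    ])


# --------------------------------------------------------------------------
# composition profiles
# --------------------------------------------------------------------------


@dataclasses.dataclass
class CompositionProfile:
    """Saturation and (phospholipid) linkage composition of a lipid subset."""

    label: str
    saturation_counts: dict[str, int]     # SFA / MUFA / PUFA
    ether_count: int
    ester_count: int

    @property
    def n(self) -> int:
        return sum(self.saturation_counts.values())

    @property
    def n_phospholipids(self) -> int:
        return self.ether_count + self.ester_count

    @property
    def saturation_percent(self) -> dict[str, float]:
        n = self.n
        return {
            k: (100.0 * v / n if n else float("nan"))
            for k, v in self.saturation_counts.items()
        }

    @property
    def ether_percent(self) -> float:
        npl = self.n_phospholipids
        return 100.0 * self.ether_count / npl if npl else float("nan")


def saturation_bucket(annotation: LipidAnnotation) -> str:
    db = annotation.total_double_bonds
    if db == 0:
        return "SFA"
    if db == 1:
        return "MUFA"
    return "PUFA"


def composition_profile(annotations: list[LipidAnnotation],
                        label: str = "") -> CompositionProfile:
    """Bucket annotated lipids by saturation; among glycerophospholipids,
    count ether vs. ester linkage."""
    annotated = [a for a in annotations if a.is_annotated]
    if not annotated:
        raise ValueError("empty or fully unannotated subset")
    sat = {k: 0 for k in SATURATION_BUCKETS}
    ether = ester = 0
    for ann in annotated:
        sat[saturation_bucket(ann)] += 1
        if ann.is_glycerophospholipid:
            if ann.ether_linkage != ETHER_NONE:
                ether += 1
            else:
                ester += 1
    return CompositionProfile(label=label, saturation_counts=sat,
                              ether_count=ether, ester_count=ester)


def composition_to_frame(*profiles: CompositionProfile) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row = {"subset": p.label, "n": p.n}
        for k in SATURATION_BUCKETS:
            row[f"{k}_count"] = p.saturation_counts[k]
            row[f"{k}_percent"] = p.saturation_percent[k]
        row.update(
            ether_count=p.ether_count,
            ester_count=p.ester_count,
            ether_percent=p.ether_percent,
        )
        rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# composition tests
# --------------------------------------------------------------------------


def _montecarlo_gof(observed: np.ndarray, expected_prop: np.ndarray,
                    n_sim: int = 20000, seed: int = 0) -> float:
    """Exact-style Monte-Carlo multinomial goodness-of-fit (likelihood ratio)."""
    rng = np.random.default_rng(seed)
    n = int(observed.sum())

    def g_stat(obs):
        exp = n * expected_prop
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(obs > 0, obs * np.log(obs / exp), 0.0)
        return np.inf if np.any((obs > 0) & (exp == 0)) else 2.0 * terms.sum()

    g_obs = g_stat(observed)
    sims = rng.multinomial(n, expected_prop / expected_prop.sum(), size=n_sim)
    g_sim = np.array([g_stat(s) for s in sims])
    return float((1 + (g_sim >= g_obs).sum()) / (1 + n_sim))


def composition_tests(profile_a: CompositionProfile,
                      profile_b: CompositionProfile,
                      seed: int = 0) -> tuple[float, float]:
    """Compare subset A against subset B's composition.

    Saturation: chi-square goodness-of-fit of A's SFA/MUFA/PUFA counts
    against B's proportions (Monte-Carlo exact fallback when expected counts
    drop below 5 or an expected proportion is zero, logged).  Linkage:
    exact binomial test of A's ether count against B's ether proportion.
    Returns (chi-square p, binomial p).
    """
    obs = np.array([profile_a.saturation_counts[k] for k in SATURATION_BUCKETS],
                   dtype=float)
    prop_b = np.array(
        [profile_b.saturation_counts[k] for k in SATURATION_BUCKETS], dtype=float
    )
    if prop_b.sum() == 0:
        raise ValueError("subset B has no annotated lipids")
    prop_b = prop_b / prop_b.sum()
    expected = obs.sum() * prop_b
    nonzero = prop_b > 0
    if np.any(~nonzero & (obs > 0)) or np.any(expected[nonzero] < 5):
        logger.info("composition_tests: falling back to Monte-Carlo exact test")
        chi_p = _montecarlo_gof(obs, prop_b, seed=seed)
    else:
        chi_p = float(
            sps.chisquare(obs[nonzero], expected[nonzero]).pvalue
        )

    npl = profile_a.n_phospholipids
    if npl == 0 or profile_b.n_phospholipids == 0:
        binom_p = float("nan")
    else:
        p_ether_b = profile_b.ether_count / profile_b.n_phospholipids
        p_ether_b = min(max(p_ether_b, 1e-12), 1 - 1e-12)
        binom_p = float(
            sps.binomtest(profile_a.ether_count, npl, p_ether_b,
                          alternative="two-sided").pvalue
        )
    return chi_p, binom_p
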