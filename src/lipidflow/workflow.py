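"""End-to-end pipeline orchestration with configuration and a run report.

``run_workflow`` executes preprocess -> discover -> enrich on a feature
table, recording the number of features surviving each stage (the funnel),
the thresholds used, and full provenance so a run can be re-executed from
its report alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .core_model import (
    FeatureTable,
    read_feature_table,
    stats_to_frame,
    summaries_to_frame,
    write_results,
)
from .discover import DiscoverConfig, SelectionThresholds, analyze, top_discriminants
from .enrich import (
    builtin_demo_mapping,
    composition_profile,
    composition_tests,
    composition_to_frame,
    enrichment_to_frame,
    ranked_enrichment,
    read_term_mapping,
)
from .preprocess import (
    blank_filter,
    class_totals,
    cv_profile,
    exclude_implausible,
    lowess_drift_correct,
    protein_normalize,
    qc_cv_filter,
    sum_isomers,
    tic_normalize,
)

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PreprocessConfig:
    blank_min_fold: float = 10.0
    qc_max_cv: float = 30.0
    lowess_span: float = 0.5
    normalization: str = "protein"   # protein | tic | none
    max_double_bonds: int = 12
    drop_odd_chain: bool = True
    skip_blank_filter: bool = False
    skip_qc_cv_filter: bool = False
    skip_drift_correction: bool = False

    def __post_init__(self):
        if self.normalization not in ("protein", "tic", "none"):
            raise ValueError(f"unknown normalization {self.normalization!r}")


@dataclasses.dataclass
class RunConfig:
    """Validated configuration for a full workflow run."""

    case_group: str = "CF"
    control_group: str = "H"
    preprocess: PreprocessConfig = dataclasses.field(
        default_factory=PreprocessConfig)
    discover: DiscoverConfig = dataclasses.field(default_factory=DiscoverConfig)
    run_enrichment: bool = True
    term_mapping_path: str | None = None
    seed: int = 0

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data or {})
        pre = PreprocessConfig(**data.pop("preprocess", {}))
        disc_raw = dict(data.pop("discover", {}))
        thr = SelectionThresholds(**disc_raw.pop("thresholds", {}))
        disc = DiscoverConfig(thresholds=thr, **disc_raw)
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(preprocess=pre, discover=disc, **data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def preprocess_table(ft: FeatureTable, cfg: PreprocessConfig
                     ) -> tuple[FeatureTable, list[tuple[str, int]]]:
    """Run the preprocessing chain, returning the table and the stage funnel."""
    funnel = [("input", ft.n_features)]
    if not cfg.skip_blank_filter:
        ft = blank_filter(ft, cfg.blank_min_fold)
        funnel.append(("blank_filter", ft.n_features))
    if not cfg.skip_qc_cv_filter:
        ft = qc_cv_filter(ft, cfg.qc_max_cv)
        funnel.append(("qc_cv_filter", ft.n_features))
    if not cfg.skip_drift_correction:
        ft, _ = lowess_drift_correct(ft, cfg.lowess_span)
        funnel.append(("lowess_drift_correct", ft.n_features))
    if cfg.normalization == "protein":
        ft = protein_normalize(ft)
    elif cfg.normalization == "tic":
        ft = tic_normalize(ft)
    funnel.append((f"normalize_{cfg.normalization}", ft.n_features))
    ft = sum_isomers(ft)
    funnel.append(("sum_isomers", ft.n_features))
    ft = exclude_implausible(ft, cfg.max_double_bonds, cfg.drop_odd_chain)
    funnel.append(("exclude_implausible", ft.n_features))
    return ft, funnel


def run_workflow(table_path: str | Path, meta_path: str | Path,
                 config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the full pipeline; write result files and the run report.

    Outputs under ``out_dir``: features.tsv, classes.tsv, volcano.tsv,
    model.json, top_discriminants.tsv, cv_profile.tsv, composition.tsv and
    enrichment.tsv (unless enrichment is skipped), report.json, report.txt.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    stage = "read"
    try:
        ft = read_feature_table(table_path, meta_path)
        stage = "preprocess"
        processed, funnel = preprocess_table(ft, config.preprocess)

        stage = "discover"
        result = analyze(processed, config.case_group, config.control_group,
                         config.discover)
        funnel.append(("iqr_filter", int(result.iqr_mask.sum())))
        funnel.append(("volcano_selected",
                       int(result.stats["selected_volcano"].sum())))
        funnel.append(("combined_selected",
                       int(result.stats["selected_combined"].sum())))

        class_sums = class_totals(processed, config.case_group,
                                  config.control_group,
                                  equal_var=config.discover.equal_var)
        write_results(result.feature_stats(), class_sums, out_dir)
        summaries_to_frame(result.class_summaries).to_csv(
            out_dir / "class_if.tsv", sep="\t", index=False)

        volcano = result.stats[
            ["feature_id", "fold_change", "log2_fc", "p_raw", "q_fdr",
             "selected_volcano"]
        ]
        volcano.to_csv(out_dir / "volcano.tsv", sep="\t", index=False)
        top = top_discriminants(result.stats, config.discover.top_n)
        top.to_csv(out_dir / "top_discriminants.tsv", sep="\t", index=False)

        model_info = {
            "n_components": result.model.n_components,
            "r2": result.r2,
            "q2": result.q2,
            "explained_y": result.model.explained_y.tolist(),
            "class_if_cutoff": result.class_cutoff,
            "n_up": result.n_up,
            "n_down": result.n_down,
        }
        (out_dir / "model.json").write_text(json.dumps(model_info, indent=1))

        qc_prof = cv_profile(processed, role="qc") \
            if processed.qc_indices.size >= 3 else None
        if qc_prof is not None:
            prof_frame = processed.features[["feature_id"]].copy()
            prof_frame["cv_percent"] = qc_prof.cv_values
            prof_frame.to_csv(out_dir / "cv_profile.tsv", sep="\t", index=False)

        enrichment_done = False
        if config.run_enrichment:
            stage = "enrich"
            annotations = {
                fid: ann
                for fid, ann in zip(processed.features["feature_id"],
                                    processed.annotations)
                if ann.is_annotated
            }
            mapping = (read_term_mapping(config.term_mapping_path)
                       if config.term_mapping_path else builtin_demo_mapping())
            ranking = result.stats.set_index("feature_id")["impact_factor"]
            ranking = ranking[ranking.index.isin(annotations)]
            try:
                enr = ranked_enrichment(ranking, mapping, annotations)
                enrichment_to_frame(enr).to_csv(
                    out_dir / "enrichment.tsv", sep="\t", index=False)
                enrichment_done = True
            except ValueError as exc:
                logger.warning("enrichment skipped: %s", exc)

            top_ids = set(top["feature_id"])
            top_anns = [annotations[f] for f in top_ids if f in annotations]
            all_anns = list(annotations.values())
            if top_anns and all_anns:
                prof_top = composition_profile(top_anns, label="top")
                prof_all = composition_profile(all_anns, label="all")
                chi_p, binom_p = composition_tests(prof_top, prof_all,
                                                   seed=config.seed)
                comp = composition_to_frame(prof_top, prof_all)
                comp["chi_square_p"] = [chi_p, ""]
                comp["binomial_p"] = [binom_p, ""]
                comp.to_csv(out_dir / "composition.tsv", sep="\t", index=False)
    except Exception as exc:
        raise RuntimeError(f"workflow failed at stage {stage!r}: {exc}") from exc

    report = {
        "package_version": __version__,
        "table_path": str(table_path),
        "meta_path": str(meta_path),
        "config": config.to_dict(),
        "seed": config.seed,
        "stage_counts": [{"stage": s, "n_features": n} for s, n in funnel],
        "model": model_info,
        "enrichment_written": enrichment_done,
    }
    (out_dir / "report.json").write_text(json.dumps(report, indent=1))
    lines = [f"lipidflow {__version__} run report", ""]
    lines.append(f"{'stage':<24}{'features':>10}")
    for s, n in funnel:
        lines.append(f"{s:<24}{n:>10}")
    lines += ["",
              f"R2 = {result.r2:.4f}  Q2 = {result.q2:.4f}",
              f"volcano: {result.n_up} up / {result.n_down} down",
              f"class IF cutoff = {result.class_cutoff:.4g}"]
    (out_dir / "report.txt").write_text("\n".join(lines) + "\n")
    return report
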