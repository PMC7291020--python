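# lipidflow

Post-acquisition processing for untargeted lipidomics feature tables:
from an aligned feature × injection intensity matrix through blank and
QC-CV filtering, QC-based LOESS signal-drift correction, protein or TIC
normalization, lipid-class aggregation, univariate + PLS-DA statistics,
a combined fold-change/p-value/VIP biomarker index ("impact factor"),
class-level discrimination, and lipid-class enrichment / acyl-chain
composition profiling. A synthetic batch simulator provides ground truth
for every stage.

## Input formats

- **Feature table** (TSV or CSV): columns `feature_id, mz, rt, name,
  id_score`, then one intensity column per injection id. Lipid names use
  shorthand nomenclature — both sum-composition (`PC 34:2`,
  `PC O-34:2`) and chain-resolved (`PC 16:0_18:2`, `Cer 18:1;2O/16:0`)
  forms parse; unknown names are kept as unannotated features.
- **Injection metadata**: columns `injection_id, role, group, order,
  protein_ug` with `role ∈ {sample, qc, blank}`; `group` empty for
  QC/blank rows, `protein_ug` required for samples.
- **Term mapping** (optional, for enrichment): TSV with `term_id, label,
  category, member_pattern` where the pattern is a lipid class code or a
  shorthand glob (`PC O-*`).

## CLI

```bash
# generate a synthetic batch with ground-truth manifest
lipidflow simulate --out batch/ --seed 1

# filters + normalization only
lipidflow preprocess --table batch/features.tsv --meta batch/meta.tsv --out pre/

# preprocessing + statistics (features.tsv, classes.tsv, volcano.tsv, model.json)
lipidflow discover --table batch/features.tsv --meta batch/meta.tsv --out results/

# full pipeline incl. enrichment + run report with stage-survival funnel
lipidflow run --table batch/features.tsv --meta batch/meta.tsv --out results/

# enrichment over an existing stats table
lipidflow enrich --stats results/features.tsv --table batch/features.tsv --out enr/
```

All commands accept `--config config.yml` (keys mirror
`lipidflow.workflow.RunConfig`: `preprocess.blank_min_fold`,
`preprocess.qc_max_cv`, `preprocess.lowess_span`,
`preprocess.normalization`, `discover.thresholds.{fc_min,q_max,vip_min}`,
`discover.n_components`, ...) and `--seed`.

## Python API

```python
import lipidflow as lf

ft, manifest = lf.generate_batch(lf.SimConfig(seed=1, n_random_spikes=20))
ft = lf.protein_normalize(ft)
result = lf.analyze(ft, case_group="CF", control_group="H")
result.stats.head()          # fold change, p/q, VIP, impact factor, selections
result.r2, result.q2         # PLS-DA training R2 and leave-one-out Q2
lf.evaluate_recovery(result.stats, manifest)
```

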