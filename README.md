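# oleomics

Annotation and quantification pipeline for LC-MS profiling of olive-based
dietary supplements: pseudo-spectrum grouping of co-eluting features,
adduct/isotope/in-source-fragment role inference against a curated adduct
registry, molecular-formula enumeration, diagnostic-fragment class rules with
Metabolomics-Standards-Initiative confidence levels, calibration-based
quantification with LDR/LOQ handling, and product-level daily-dose assessment
against the EFSA 5 mg/day hydroxytyrosol criterion.

The package ships versioned, checksummed text fixtures with the reference
data it operates on: 202 annotated compounds (ids, formulas, retention times,
printed ion lists, confidence levels), published calibration-curve
parameters, per-product concentration ranges for 26 quantified compounds
across 14 commercial products, and product metadata including the suppliers'
recommended daily doses.

## Layout

| module                  | role |
|-------------------------|------|
| `oleomics.chemcalc`     | formula arithmetic; adduct / isotope / neutral-loss m/z calculus; ion-label grammar |
| `oleomics.feature_io`   | feature tables (CSV), MS2 spectra (MGF), packaged fixtures with SHA-256 verification |
| `oleomics.grouping`     | RT + intensity-correlation clustering into pseudo-spectra |
| `oleomics.relationships`| ion-role inference relative to a neutral mass; cross-polarity reconciliation |
| `oleomics.annotate`     | formula enumeration, MS2 merging, class rules, level assignment |
| `oleomics.quant`        | OLS calibration, LDR/LOQ, back-calculation to mg/g, RSD validation |
| `oleomics.assess`       | product totals, daily intake, 5 mg/day claim evaluation, composition summaries |
| `oleomics.stats`        | log + Pareto preprocessing, PCA, Kruskal-Wallis + Benjamini-Hochberg, heat-map ordering |
| `oleomics.synthdata`    | seeded synthetic feature tables, MS2 spectra and calibration series with ground truth |
| `oleomics.cli`          | `oleomics` command-line entry point |

## CLI

```sh
oleomics fixtures --verify                 # checksum + row-count check
oleomics simulate --out-dir sim/           # synthetic data with ground truth
oleomics annotate --neg sim/features_neg.csv --pos sim/features_pos.csv \
    --out annotations.tsv
oleomics quantify --responses resp.csv --calibration cal.csv --out quant.tsv
oleomics assess --out doses.tsv            # dose / claim report
```

Tolerances (ppm, RT window, correlation threshold, seed, alpha, claim
threshold) live in a single YAML config passed as `oleomics --config cfg.yaml
<command>`. Exit codes: 0 success, 2 validation failure, 3 fixture-integrity
failure.

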