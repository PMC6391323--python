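# metastrat

Benchmarking framework for multi-experiment LC-MS metabolomics: given two
experiments ("batches") measuring the same case/control contrast, it runs and
compares four analytical strategies —

- **SiE1 / SiE2** — analyze each experiment alone;
- **ReIn** (results integration) — analyze each experiment alone, then
  integrate marker lists, models and metrics;
- **DiMe** (direct merge) — match features across experiments by m/z
  tolerance, merge into one table, analyze jointly —

and scores each by three independent criteria:

1. **Classification capacity** — stratified train/test/independent split,
   t-test feature selection, RBF-SVM, evaluated on the independent split
   with SEN/SPE/ACC/MCC and rank-based ROC AUC.
2. **Marker robustness** — ten stratified half-samplings, t-test marker
   lists, all 45 pairwise Dice overlaps, co-identification profile.
3. **False-discovery control** — PLS-DA (VIP > 1 ∧ p < 0.05) markers,
   annotation against a reference library at 20 ppm, and the enrichment
   factor (EF) of true-marker recovery versus random selection.

A synthetic dual-experiment generator (log-normal intensities, consistent
planted effects, batch location/scale shifts, m/z jitter, MNAR/MCAR
missingness, decoy-bearing reference library) supplies fully reproducible
test data with ground truth, so the entire pipeline runs offline.

## Test

```bash
python -m pytest -q tests/
```

## CLI

```bash
# generate a synthetic experiment pair with ground truth
metastrat simulate --seed 5 --out sim/

# individual stages
metastrat pretreat --in sim/exp1.csv --meta sim/metadata.csv --k 10 --out pre1.csv
metastrat merge --a sim/exp1.csv --b sim/exp2.csv --meta sim/metadata.csv \
    --tol 0.05 --tol-unit Da --out merged.csv --map matches.tsv
metastrat markers --in pre1.csv --meta sim/metadata.csv --method plsda \
    --lib sim/library.tsv --out markers.json
metastrat classify --in pre1.csv --meta sim/metadata.csv --split 0.6,0.2,0.2 \
    --seed 7 --out metrics.json
metastrat robustness --in pre1.csv --meta sim/metadata.csv --iters 10 \
    --seed 7 --out overlap.json
metastrat ef --in pre1.csv --meta sim/metadata.csv --lib sim/library.tsv \
    --truth sim/truth_ids.txt --out ef.json

# all four strategies, side-by-side report + figures
metastrat run --pair sim/exp1.csv sim/exp2.csv --meta sim/metadata.csv \
    --lib sim/library.tsv --truth sim/truth_ids.txt --seed 1 --out report/
```

Peak tables are CSV/TSV with header `mz,rt,<sample1>,...` (features as rows,
empty cells or `NA` for missing); metadata is CSV with
`sample_id,group,experiment` (`group` ∈ {case, control}); libraries are TSV
with `metabolite_id,name,neutral_mass`. Omitting `--truth` falls back to the
packaged 12-marker serum panel.

## Layout

- `src/metastrat/io_formats.py` — peak-table/library/true-marker I/O and types
- `src/metastrat/synthetic_data.py` — dual-experiment generator + ground truth
- `src/metastrat/preprocessing.py` — KNN imputation, MSTUS normalization
- `src/metastrat/merging.py` — m/z-tolerance feature matching, table merging
- `src/metastrat/markers.py` — t-test and PLS-DA/VIP markers, annotation
- `src/metastrat/classification.py` — splits, SVM, SEN/SPE/ACC/MCC/AUC
- `src/metastrat/stability_fdr.py` — half-sampling overlaps, enrichment factor
- `src/metastrat/strategies.py` — SiE/ReIn/DiMe orchestration and comparison
- `src/metastrat/cli.py` — the `metastrat` command
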