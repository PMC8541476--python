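# soilice

Interspecies correlation estimation (ICE) models for soil invertebrates:
a tested pipeline from raw single-chemical soil toxicity records to
surrogate-based toxicity predictions with quantified accuracy.

Ecological risk assessment of soils needs toxicity values for many species,
but single-chemical soil tests exist mostly for a few earthworms, with
scattered data for springtails, nematodes, potworms, and woodlice.  ICE
models fill these gaps: when two species have been tested against the same
chemicals, their log-scale sensitivities are strongly linearly related, so a
measured value in a well-tested surrogate species can predict the value in a
data-poor species.  This package is for ecotoxicologists and risk assessors
who want to build, screen, and validate such models from tabular toxicity
exports (e.g. from the ECOTOX or Standartox knowledgebases).

## The model

For a surrogate species with species mean acute value (SMAV) `x` and a
predicted species with SMAV `y` for the same chemical (both mg/kg soil), an
ICE model is the least-squares fit of

```
log10(y) = a · log10(x) + b
```

over all chemicals with SMAVs for both species.  The pipeline stages are:

1. **Ingestion & normalization** — parse the record CSV schema, convert
   concentrations to mg/kg soil (refusing aqueous units), normalize CAS
   numbers and binomials.
2. **Curation** — keep standard acute test durations (1 d nematodes, 14 d
   earthworms/springtails; configurable), LC50 and mortality-LOEC endpoints,
   and species with data for ≥ 3 chemicals; collapse replicate records to
   SMAVs by geometric mean per species × chemical × endpoint.
3. **Model building** — for every species pair sharing ≥ 3 chemicals at an
   endpoint, fit both directed regressions (each species takes a turn as the
   surrogate) with R², residual mean square (MSE = SSE/(n−2)), and the
   two-sided slope-t p-value on n−2 df.  Forward and reverse fits share R²
   and p exactly, and `a_fwd · a_rev = R²` — identities the tests enforce.
4. **Validation** — significant models (p < 0.05) with ≥ 4 points get
   leave-one-out cross-validation; each hold-out is scored by the fold
   difference `max(pred/actual, actual/pred)` on the mg/kg scale, and the
   percentage within 5-fold (inclusive) is the model's prediction success
   rate, averaged per within-taxa (same order) and across-taxa (different
   phyla) group.
5. **Synthetic data** — a seeded generator draws chemical potencies from a
   shared latent factor and species responses `alpha + beta·potency + noise`,
   so every stage is testable against known ground truth.

## Worked example

`examples/loocv_accuracy.py` fits a six-chemical model between two
earthworm species and cross-validates it:

```
full model: slope=0.750  R^2=0.926  p=0.00212  n=6  significant=True
chemical       actual  predicted    fold  within 5-fold
chem-0           24.6       46.9    1.91  True
chem-1           97.4       91.3    1.07  True
chem-2         1294.5     5215.9    4.03  True
chem-3          525.7      354.6    1.48  True
chem-4            5.8       10.1    1.74  True
chem-5          308.7      103.0    3.00  True
success rate: 100.00% of hold-outs within 5-fold
```

Each row holds one chemical out, refits the regression on the other five,
and predicts the held-out SMAV in mg/kg; a fold difference of 1 is a perfect
prediction and 5-fold is roughly interlaboratory variation, so this model
predicts every chemical within the accepted band.  The other scripts in
`examples/` show single-model fitting and prediction
(`fit_ice_model.py`) and a full synthetic multi-species study
(`synthetic_study.py`).

The same pipeline runs from the shell:

```
soil-ice simulate --seed 3 --n-chemicals 12 --out records.csv
soil-ice run --input records.csv --out-dir out/
soil-ice predict --models out/models.csv --surrogate "Eisenia fetida" \
    --predicted "Eisenia andrei" --endpoint LC50 --value 100
```

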