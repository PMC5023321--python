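# normap

Gaussian-process **normative modelling** for mass-univariate biological
data — growth-chart-style reference models for cohorts, with
subject-level deviation maps and extreme-value outlier statistics.

Case–control comparisons assume clinical groups are homogeneous; in
practice, cohorts are heterogeneous mixtures. Normative modelling turns
the question around: instead of comparing group means, it charts the
*expected value and expected variation* of a biological response (e.g.,
task-evoked brain activity at each of thousands of locations) as a
function of clinically relevant covariates (e.g., trait impulsivity
scores) across a reference cohort, then asks, for each individual, *where
and how far* they deviate from that chart. Symptoms can then be
dissociated into those arising at the extreme of a normal spectrum of
functioning and those arising from idiosyncratic deviations from the
normal pattern. The toolkit is for researchers in clinical neuroimaging,
biostatistics, and epidemiological modelling who want calibrated
single-subject inference without clustering or case–control designs.

## The model

For each response location *j* (voxel, vertex, region — any column of a
subjects × locations matrix), the response is modelled by Gaussian-process
regression on the covariates **x**:

    y = f(x) + ε,   f ~ GP(0, k_ARD),   ε ~ N(0, σ²_nj)

with a squared-exponential ARD kernel (one length-scale per covariate, so
covariate relevance is learned) and type-II maximum-likelihood
hyperparameters. Under grouped k-fold cross-validation (families never
straddle a split), each subject *i* gets a held-out prediction ŷ_ij with
noise-free predictive variance σ²_ij, and a deviation Z-score

    z_ij = (y_ij − ŷ_ij) / √(σ²_ij + σ²_nj)

The matrix of z_ij is the subject's **normative probability map** (NPM).
Each subject's NPM is summarized by block-maxima extreme-value
statistics — a 90% trimmed mean of the top 1% of Z (positive, negative,
and absolute variants) — and a generalized extreme value distribution
fitted to the cohort's summaries converts each subject's deviance into a
tail probability (an outlier p-value). Deviating locations are localized
per subject with two-sided Benjamini–Hochberg FDR maps, and deviance is
related to symptom scores via Pearson correlations within the top 1–20%
most-deviant subsets ("tail correlations"). See `docs/methods.md` for
the full account.

## Worked example

The package ships a synthetic-cohort generator that emulates the data the
method targets: bounded skewed trait covariates, family structure, smooth
nonlinear covariate–response surfaces at a subset of locations, and
planted outlier subjects with sparse idiosyncratic deviations whose
symptoms track the injected deviation (`symptom_model: mixture` also
includes high-symptom subjects at the extreme of the normal covariate
spectrum). The pipeline mirrors the method's four stages:

```sh
cat > cohort.yaml <<EOF
n_subjects: 120
n_locations: 110
outlier_fraction: 0.05
outlier_n_locations: 5
outlier_magnitude: 4.0
outlier_sign: negative
symptom_model: mixture
seed: 7
EOF

normap simulate --spec cohort.yaml --out fx
cat > run.yaml <<EOF
covariates: fx/covariates.tsv
responses: fx/responses.tsv
groups: fx/groups.tsv
k_folds: 5
seed: 1
gp: {restarts: 2}
output: bundle
EOF
normap fit --config run.yaml                       # ~40 s on one core
normap npm --model bundle --covariates fx/covariates.tsv \
           --responses fx/responses.tsv --out npm.tsv
normap deviance --npm npm.tsv --symptoms fx/symptoms.tsv \
                --out dev --fractions 0.05,0.1,0.2
normap report --deviance-dir dev
```

which prints:

```
subjects: 120
positive: EVD gev (loc=2.330, scale=0.381, shape=-0.264), outliers: 9
negative: EVD gev (loc=2.303, scale=0.396, shape=0.167), outliers: 4
absolute: EVD gev (loc=2.607, scale=0.328, shape=0.201), outliers: 4
tail corr [positive] top 5%: r=0.826, p=0.04263, n=6
tail corr [positive] top 10%: r=0.391, p=0.2087, n=12
tail corr [positive] top 20%: r=-0.093, p=0.666, n=24
tail corr [negative] top 5%: r=0.913, p=0.01113, n=6
tail corr [negative] top 10%: r=0.912, p=3.574e-05, n=12
tail corr [negative] top 20%: r=0.889, p=6.428e-09, n=24
tail corr [absolute] top 5%: r=0.925, p=0.008138, n=6
tail corr [absolute] top 10%: r=0.912, p=3.537e-05, n=12
tail corr [absolute] top 20%: r=0.887, p=8.034e-09, n=24
```

Reading the output: the GEV fitted to the cohort's negative/absolute
deviance summaries flags 4 subjects at p < .05 — exactly the 4 planted
outliers whose injected deviations were large (the generator's truth file
`fx/truth.json` lists 6 planted subjects; the two missed ones drew small
injected magnitudes and are genuinely near-normal). Their FDR maps
(`dev/fdr_masks.tsv`) localize 5–6 deviating locations each, matching the
5 planted locations per subject. The negative-deviance tail correlations
with the symptom score are strong and positive from the extreme tail
(r = 0.91 in the top 5%) through the bulk (r = 0.89 at 20%), while the
positive-deviance correlations fade to chance — the planted mechanism
links symptoms to *under*-expression only. `dev/deviance.tsv` holds the
per-subject scores and p-values; `dev/overlap.tsv` counts deviating
subjects per location.

The same stages run on real data: covariates/groups/symptoms as TSV with
a `subject_id` column, responses either as a wide TSV matrix or as a 4D
NIfTI plus mask (`normap npm --mask ...` writes Z maps back into the
input geometry). A fitted bundle can score new cohorts with
`normap npm --transfer`.

The library API mirrors the CLI one-to-one
(`normap.fit_gp`, `grouped_kfold`, `estimate_normative`, `compute_npm`,
`summarize_deviance`, `fit_evd`, `fdr_map`, `tail_correlation`,
`centile_surface`, `generate_cohort`, …).

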