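# trajclust

Unsupervised exposure categories from longitudinal behaviour data, with
prospective predictive validation.

Cohort studies often record a binary behaviour (here: condomless anal
intercourse with non-steady partners, **nsCAI**, or any sex with non-steady
partners, **nsP**) at semiannual follow-up visits over many years. A single
"last value" or "ever" summary throws away the shape of a participant's
history. `trajclust` instead

1. maps each participant's dated questionnaire answers onto a calendar grid
   of half-year bins, giving a binary trajectory with missing bins;
2. computes pairwise **Jaccard distances** between trajectories — over bins
   observed in both, the proportion of discordant bins among bins where at
   least one participant reports the behaviour;
3. clusters participants by **agglomerative hierarchical clustering with
   Ward linkage** (Lance–Williams recurrence, ward.D2 by default), cuts the
   dendrogram into *k* clusters, and appends participants who *never*
   reported the behaviour as a reserved **baseline cluster 0**;
4. asks whether these cluster labels improve *prospective* prediction:
   outcomes (behaviour at first follow-up, nurse/physician-reported STIs,
   laboratory-confirmed incident syphilis) are measured strictly **after** a
   cut-off date, clusters are inferred strictly **before** it, and nested
   GLMs (logistic for binary outcomes, Poisson for counts) with and without
   the cluster covariate are compared by likelihood-ratio test, AIC, BIC,
   auROC and seeded 5-fold cross-validation, against simple trajectory
   summaries (last, last two, ever, mean) as comparators;
5. sweeps the number of clusters *k* and reports the BIC-optimal choice.

Incident syphilis is classified from serial serology: a treponemal
seroconversion (negative → positive), or a VDRL titer above 1:8 that is also
more than a four-fold rise over the most recent prior titer.

Because visit-level cohort data of this kind are access-restricted, the
package ships a first-class synthetic-cohort generator
(`trajclust.synthetic`) that plants known cluster structure (latent
subgroups with distinct probability curves, a large never-reporter stratum,
missing visits) and known outcome-model coefficients, so every stage is
testable end to end with ground truth.

## Worked example

Simulate a 600-participant cohort with three planted behaviour subgroups
plus a ~30% never-reporter stratum, then run the full analysis:

```sh
cat > sim.yaml <<EOF
n_participants: 600
seed: 1
EOF
cat > run.yaml <<EOF
k: 3
seed: 1
k_range: [1, 2, 3, 4, 5, 6]
EOF
trajclust simulate --config sim.yaml --out data/
trajclust run --visits data/visits.csv --labs data/labs.csv \
    --sti data/sti.csv --participants data/participants.csv \
    --config run.yaml --out results/
```

which prints

```
wrote synthetic cohort (600 participants) to data
included participants: 600
cluster sizes: 0:205, 1:131, 2:146, 3:118
BIC-optimal k per outcome: {'first_nsCAI': 3, 'any_sti': 3, 'any_syphilis': None, 'sti_count': 3, 'syphilis_count': 3}
outputs written to results
```

Cluster 0 holds the 205 participants who never reported the behaviour
before the cut-off; clusters 1–3 are the hierarchical clusters, numbered by
ascending mean trajectory positivity. The cluster-number sweep recovers
k = 3 (the planted number) as BIC-optimal for most outcomes; for the rarest
outcome (laboratory-confirmed syphilis) no k beats the cluster-free model
on BIC — exactly the behaviour one expects when events are too sparse to
repay k extra parameters.

`results/comparison_table.csv` starts:

```
outcome,comparator,family,p_lrt,p_lrt_null,aic_without,aic_with,bic_without,bic_with,auroc_without,auroc_with
first_nsCAI,cluster,binary,1.856055357e-11,1.89860579e-19,769.0976721,722.1227322,786.6853907,752.9012398,0.6390738499,0.7297855746
first_nsCAI,last_two,binary,0.03496591364,2.743632884e-09,769.0976721,766.6508332,786.6853907,788.6354815,0.6390738499,0.6624371391
```

Reading the first row: adding the cluster covariate to the conventional
model (age + last pre-cut-off flag + prior syphilis) improves the fit for
predicting the next reported behaviour (p_LRT ≈ 2·10⁻¹¹), lowers BIC from
787 to 753 and raises in-sample auROC from 0.64 to 0.73. Other outputs:
`sweep.csv` (per-k criteria), `trends.csv`/`trends.png` (per-cluster
behaviour prevalence over calendar time), `bic_bars.png`, `assignment.csv`,
`dendrogram.csv`/`.nwk`, `cv_report.json` and `run_metadata.json` (seed,
config hash, version). Re-running with the same config and inputs
reproduces every CSV byte for byte.

The same operations are available as a library (`trajclust.simulate_study`,
`trajclust.run_analysis`, and the per-stage functions they compose).

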