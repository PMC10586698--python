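# vodscore

Continuous disease-progression scoring from multivariate physiological time
series, with pre-onset risk prediction from mixed-type patient attributes.

The pipeline, per retrospective patient:

1. **Graph posterior** (`vodscore.graphical_model`) — from the patient's
   time-series matrix, compute partial correlations, the closed-form
   posterior probability of each edge of a soft graph over the parameters
   (a Normal observation model for |r| with its variance marginalised over
   a U[0,1] prior), and a chain of sampled graphs with log posteriors.
2. **Inter-patient distances** (`vodscore.graph_distance`) — the discretised
   Hellinger distance: the RMS difference of two patients' max-scaled
   log-posterior traces, paired by iteration (common random numbers across
   patients by default, so identical records give exactly zero distance).
3. **Score learning** (`vodscore.score_inference`) — Metropolis–Hastings on
   all scores relative to a reference patient pinned at 1, with Normal
   likelihoods for the reference distances and case-based pairwise
   consistency priors; multi-cohort alignment via inter-reference distances
   signed by the clinician severity ordering; status classification by the
   mean-score (0.11) and upper-HPD (0.31) cutoffs.
4. **Score prediction for a new patient** (`vodscore.gp_score_model`) — a
   vector-variate GP: the stacked pre-transplant vectors are matrix-normal
   with a squared-exponential kernel over scores as the inter-patient
   covariance; a prospective patient's score is learnt jointly with the
   kernel hyperparameters by MCMC after augmenting the data with their
   attribute vector (uniform or elicited Normal prior on the score).
5. **Risk-factor ranking** (`vodscore.variable_ranking`) — leave-one-
   variable-out change in the matrix-normal log-likelihood.

`vodscore.synthetic_cohort` generates cohorts with a latent severity that
deforms the inter-parameter correlation structure and drives the attributes,
so the full pipeline is testable end to end without any patient data.

## CLI

```sh
vodscore simulate --seed 1 --out cohort/          # synthetic cohort directory
vodscore graphs cohort/ --out graphs/             # per-patient graphical models
vodscore distances cohort/ --out dist.json        # cohort distance matrix
vodscore scores dist.json --reference C1-P1 --out scores.csv
vodscore align scores_A.csv scores_B.csv --universal-cohort scores_A \
    --alignment "scores_B:refB:1.17:less" --out aligned.csv
vodscore train cohort/ scores.csv --out hyper.json
vodscore predict cohort/ scores.csv test_patient.json --out pred.json
vodscore rank cohort/ scores.csv --a 1.0 --ell 0.5 --out ranking.csv
```

## Notes

- The inter-variable covariance of the matrix-normal model defaults to the
  GLS estimator given the current patient covariance
  (`GPMcmcConfig.sigma_y_mode="gls"`). The plain sample covariance
  (`"empirical"`) is also available but is biased when patients are strongly
  kernel-correlated, and near-singular when the attribute count approaches
  the cohort size; see the docstrings in `vodscore.gp_score_model`.
- Scores are identified only up to reflection about the reference value;
  supply `side` hints to `learn_scores` (clinician-style ordering
  information) or an `init` policy to select a branch.
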