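# metaipm

An integrated metapopulation model (IMM) for a declining Arctic-nesting
migratory goose population wintering at discrete sites in Great Britain and
Ireland.  The package is for population ecologists who need to ask not just
*"is this subpopulation declining?"* but *"which demographic process — local
recruitment, survival, or movement from neighbouring wintering groups — is
driving the change, and which groups are sources or sinks?"*

Three data streams are combined in one hierarchical Bayesian model across
four wintering subpopulation groups (Wexford, Islay, Loch Ken, and a pooled
"Elsewhere") over 39 winters:

- **site counts** `y[i,t] ~ logNormal(log Ntot[i,t], τ_y)`,
- **juvenile counts** (from observed juvenile:adult age ratios)
  `Jobs[i,t] ~ Poisson(J[i,t])`,
- **multistate mark–resighting histories**, summarized as an m-array with a
  multinomial likelihood per release cohort,

linked by a stage-structured process model

    Ntot = J + A,   A = N1 + Nad + I
    J[i,t]   ~ Poisson(A[i,t] · γ[i,t])
    N1[i,t]  ~ Binomial(J[i,t−1],  φJ · (1 − Σψ J))
    Nad[i,t] ~ Binomial(A[i,t−1],  φA · (1 − Σψ A))
    I[i,t]   ~ Poisson( Σ_s φ ψ[s→i] · abundance[s, t−1] )

with fecundity γ regressed on growing degree days (wintering, staging,
breeding) and breeding-ground snowfall, and survival φ on migration storm
days and hunting-protection periods, with Laplace shrinkage of those effects
toward among-group means.  Post-fit analyses decompose the temporal variance
of realised growth rates λ = Ntot'/Ntot into demographic contributions
(transient LTRE), compute net adult immigration rates per group pair, and
project each group under four movement scenarios (emigration only,
immigration only, none, both).

A synthetic-data generator (`metaipm.synthetic`) reproduces exactly the
statistical structure the model assumes, at the study's magnitudes, so every
stage is testable without field data.  See `docs/methods.md` for the full
model, priors, sampler and design choices.

## Worked example

The `analysis/` scripts run the whole study on synthetic data (the numbers
below are their actual output at seed 1):

```sh
python analysis/01_simulate_study.py     # counts, age ratios, covariates,
                                         # 6,840 marked birds, 24,587 resightings
python analysis/02_fit_posterior.py      # 3 chains x 3,000 iterations
python analysis/03_model_checks.py
python analysis/04_growth_decomposition.py
python analysis/05_source_sink_projections.py
```

Step 02 reports posterior medians with 90% credible intervals, e.g. adult
survival at Wexford 0.802 (0.790–0.813) and Elsewhere resighting probability
0.276 (0.251–0.302) against generating values of 0.79 and 0.28 — the
Elsewhere group is observed through a much sparser resighting process, and
the model still pins it down.  Step 03 prints Bayesian posterior-predictive
p-values; values near 0.5 (counts combined: 0.51, juveniles: 0.46) mean the
fitted model replicates the data's discrepancies, with the weakest check the
Elsewhere m-array cells (p = 0.12).  Step 04 attributes realised
growth-rate variance: at Wexford, fecundity fluctuations explain 50.8%
(90% CRI 40.9–63.7%) of Var(λ) in this simulated study and are the dominant
driver of year-to-year growth changes in 41.7% of years.  Step 05
classifies Wexford as a sink (net adult immigration rate 0.046,
90% CRI 0.036–0.051) and Elsewhere as a source, and shows what movement is
worth: Wexford's among-year growth is 0.997 with immigration only, 0.951
with both flows, 0.904 with no movement, 0.869 with emigration only.

The same pipeline is available as a CLI over one YAML config:

```sh
metaipm simulate --config run.yaml
metaipm fit      --config run.yaml
metaipm all      --config run.yaml     # simulate → fit → diagnose → ltre → project
```

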