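# Methods

## The design problem

A two-arm parallel cluster RCT with a continuous outcome randomises `c`
clusters of `m` individuals with allocation ratio `lam` between arms. The
outcome model is the two-level random-intercept linear mixed model

    Y_ij = mu_arm(j) + u_j + e_ij,   u_j ~ N(0, sigma_b2),  e_ij ~ N(0, sigma_w2),

so the ICC is `rho = sigma_b2 / (sigma_b2 + sigma_w2)` and the total
variance is `sigma2 = sigma_b2 + sigma_w2`. Sample size for an
individually randomised trial,

    n = (1 + lam)^2 (xi_{alpha/2} + xi_beta)^2 sigma2 / ((1 - w) lam delta^2),

is inflated by the design effect; with uniform individual-level attrition
`w` the attrition-adjusted equal-size design effect is
`1 + (m (1 - w) - 1) rho`. Power uses the normal approximation
`Phi(sqrt(gamma) - xi_{alpha/2})` with

    gamma = m (1 - w) c lam delta^2 / ((1 + lam)^2 sigma2 DE).

`gamma` is monotone in each driver: increasing in `c`, `m` and `delta^2`,
decreasing in `rho` (for `m > 1`) and in `w`, and maximised over the
allocation ratio at `lam = 1` (`lam / (1 + lam)^2` peaks there).

## Post-merge algebra

When `k` pairs of equal-size-`m` clusters merge, the trial is left with
`c - k` clusters: `k` of size `2m` and `c - 2k` of size `m`. The mean size
is `m_tilde = c m / (c - k)` (individuals are conserved) and the sample
variance of sizes collapses to

    s_c2 = m^2 k (c - 2k) / ((c - k)(c - k - 1)),

zero at `k = 0` and `k = c/2` with an interior maximum. Size variability
enters power through the variable-size design effect
`1 + ((s_c2 / m_bar^2 + 1) m_bar - 1) rho`. Unequal merging between arms
shifts the cluster allocation ratio to `(c0 - k0) / (c1 - k1)`.

The post-merge power operation composes these pieces — `c - k` clusters,
`m_tilde`, `s_c2`, the shifted ratio, and the variable-size design effect —
into one updated `gamma`. Each piece is also public. Algebraically
`m_tilde (c - k) = m c`, so the only changes to `gamma` are the larger
design effect and any allocation imbalance; merging therefore never
increases analytic power. Attrition is applied uniformly, which scales
every cluster by `1 - w` and leaves the squared coefficient of variation
`s_c2 / m_tilde^2` unchanged; the implementation uses exactly that
invariance.

Rounding conventions (the closed forms are silent on them): sample sizes
round up; the cluster count rounds each arm up separately, so a balanced
design gets the next even total. Power is returned unrounded. With `m = 1`
the cluster formula matches the individual formula up to this parity
rounding — the package treats the ±1 cluster as the price of a realisable
allocation rather than reporting a fractional cluster.

## The simulator

`generate_trial` draws one cluster effect per cluster and one error per
individual; arms are blocks of clusters (control first), every cluster has
exactly `m` members, and the defaults are the reference design used
throughout: `c = 80`, `m = 20`, `rho = 0.05`, `sigma2 = 1`, `mu0 = 0`,
`mu1 = 0.2`, two-sided `alpha = 0.05` — a design with ~82% analytic power
for the effect 0.2. Alternative configurations (60 clusters of 40, 48 of
100) run through the same code by changing `c` and `m`.

Merge scenarios:

* **S1 (homogeneous, all completed)** — `k0`/`k1` same-arm pairs sampled
  uniformly without replacement among never-merged clusters; pure
  relabelling, outcomes bit-identical.
* **S2 (homogeneous, partial completion)** — as S1, but only a
  `completer_fraction` (default 0.5) of each source cluster keeps its
  outcome; the remaining members' outcomes are redrawn as
  `mu_arm + u_new + e_new` with **one** new cluster effect shared by all
  non-completers of the merged cluster.
* **S3 (heterogeneous, all completed)** — `k` cross-arm pairs; outcomes
  unchanged, so a merged cluster's expected mean is `(mu0 + mu1) / 2`.
* **S4 (heterogeneous, partial completion)** — non-completers are redrawn
  with the treatment mean of the merged cluster's post-merge arm
  (`mu0` under control assignment, `mu1` under intervention assignment)
  plus a new shared cluster effect. When the analysis will discard those
  records (dropped clusters, completers-only), the pre-merge arm's mean is
  used so the record stream is identical across strategies sharing a seed.

Design choices made where the scenario definitions were open:

* Completers are the first `floor(fraction * m)` members of each source
  cluster by within-cluster index. Individuals are exchangeable within a
  cluster, so deterministic selection is equivalent in distribution to
  random selection and exactly reproducible.
* S4 mirrors S2's "new shared cluster-level effect for non-completers"
  convention; the merged cluster keeps the parents' effects only through
  completers' retained outcomes.
* A merged cluster always receives a fresh label recording both parents,
  never reusing a parent label, so the completers-only analysis can return
  to original assignments.

Analysis strategies (`build_analysis_set`) relabel rather than resample:
`as_one_cluster` (homogeneous only — rejected for cross-arm merges),
`assign_control` / `assign_intervention` (whole merged cluster analysed in
one arm), `drop_merged` (merged clusters excluded) and `completers_only`
(non-completers excluded, completers analysed under original cluster and
arm).

What the generator does *not* emulate: baseline cluster-size variation,
differential or informative attrition, merges with clusters outside the
trial, merges of more than two clusters, cluster fragmentation, membership
churn, and binary outcomes. Passing tests therefore speak to the idealised
equal-size, equal-allocation trial; real trials add size variability that
the design-effect formula handles but the simulator does not generate.

## Model fitting

The analysis model is the same random-intercept model, estimated by REML.
The implementation profiles the likelihood over the variance ratio
`r = sigma_b2 / sigma_w2`: for fixed `r`, GLS estimates, the residual
scale and the REML criterion have closed forms in per-cluster sufficient
statistics (the Woodbury identity reduces every cluster's inverse to a
rank-one correction), leaving a bounded one-dimensional minimisation over
`log r` (tolerance 1e-8, ratio searched within `e^-16 .. e^8`, the
boundary `sigma_b2 = 0` checked explicitly and allowed). This makes a fit
O(number of clusters) per criterion evaluation — roughly a millisecond for
an 80-cluster trial — which is what keeps full-size Monte Carlo tables
cheap. Tests verify the estimates against the balanced-design ANOVA closed
forms (`sigma_w2 = MSW`, `sigma_b2 = (MSB - MSW)/m`, an identity that
holds at interior solutions) and against an independent mixed-model
implementation on unbalanced post-merge data.

Inference on the treatment effect uses the Wald z test (two-sided), not a
t or Satterthwaite correction, matching the normal-approximation framing
of the power formula; with 40-80 clusters the z test is very slightly
liberal, which the type-I-error test brackets rather than hides.
"Significant" means `p < alpha` strictly.

## Monte Carlo harness

`run_cell` replicates simulate → merge → analysis set → fit and aggregates
Monte Carlo means with normal 95% intervals (`mean ± 1.96 sd / sqrt(n)`),
the empirical power at `alpha = 0.05`, and the mean post-merge
cluster-size variance. Replicate `r` of a cell seeds its generator with
`(master_seed, scenario, strategy, k0, k1, k, r)`, so cells are mutually
independent and individually reproducible regardless of execution order.
Non-convergent fits are counted and excluded (none occur in practice at
these sizes); `n_reps` counts attempted replicates.

Replicate counts: the harness default is 1000 replicates per cell. The
acceptance suite measures table cells at 4000 replicates — the Monte Carlo
SE of an empirical power near 80% is then ~0.6 percentage points, small
against the ~1.2-point SE carried by any reference 1000-replicate value — while the headline significant-result count keeps its defining
1000 replicates. Pattern tests in the unit suite run at 150-300 replicates
with correspondingly generous bands.

## Known limitations

* The normal-approximation power formula ignores the finite number of
  clusters; with few clusters it is optimistic, consistently with the
  Wald-z analysis choice.
* REML profiling assumes a single variance ratio; it does not model the
  extra within-cluster heterogeneity that partial-completion merges
  actually induce (two sub-populations share one fitted intercept). That
  misspecification is the phenomenon under study, not an estimation target.
* Empirical power comparisons against any fixed reference inherit that
  reference's own Monte Carlo noise; differences under ~2.5 percentage
  points are not distinguishable from it at 1000 replicates.
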