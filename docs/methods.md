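# Methods

## Model

A CpG dyad is modelled as a discrete-time Markov chain X(t) on
S = {u, m, h}², one step per cell division, with the canonical state order
(uu, um, mu, uh, hu, mm, mh, hm, hh) used for every vector and matrix
index. Each division applies three events in a fixed order, with no
interleaving:

1. **Replication** `D`. The newly synthesised strand carries no
   modifications; averaging over the two daughter cells, the replaced
   strand is the upper or lower one with probability ½ each, so state
   (s₁, s₂) moves to (s₁, u) or (u, s₂). `D` is parameter-free and
   time-invariant.
2. **Methylation** `M(μ_m, μ_d, p)`. On (uu), each strand is de novo
   methylated independently with probability μ_d. On a hemimethylated
   dyad, maintenance runs first (μ_m) and, on failure, de novo (μ_d),
   giving total efficiency λ = μ_m + μ_d − μ_m·μ_d. On (uh)/(hu), a
   recognition coin hides the dyad from maintenance with probability p, so
   the unmodified strand is methylated with probability
   p·μ_d + (1−p)·λ. Dyads without an unmodified cytosine — (mm), (mh),
   (hm), (hh) — are fixed points of `M`: the methyltransferases neither
   remove marks nor act on hydroxyl groups.
3. **Hydroxylation** `H(η)`. Each methylated strand independently becomes
   hydroxylated with probability η. Placing `H` after `M` lets a cytosine
   go u → m → h within a single cycle.

The per-division transition matrix is `P(t) = D·M(t)·H(t)` and the hidden
distribution evolves as π(t) = π(0)·P(1)⋯P(t). All three matrices are
row-stochastic and commute with the strand-swap permutation (entry(i→j) =
entry(swap i → swap j)); both properties are enforced by tests, as is
agreement of every row of `P` with a matrix-free event-level simulator.
A consequence used as an exact identity test: with η = 0, p = 1 and
μ_d = 0, the mean number of hydroxylated strands per dyad halves at every
division (the per-strand 5hmC functional is an eigenvector of `P` with
eigenvalue ½), reproducing passive dilution of 5hmC.

Efficiencies are linear in the division index, f(t) = β₀ + β₁·t, evaluated
at integer t ≥ 1, where f(t) governs the t-th cycle (the cycle ending at
day t under the default one-division-per-24 h regime; the day-to-division
ratio is configurable). The parameter vector is
v = (μ_m: β₀, β₁; μ_d: β₀, β₁; η: β₀, β₁; p), seven in total.

## Observation model

Each strand is read through an independent two-outcome conversion channel.
Under BS: u → T with probability c, m → C with d, h → C with e. Under
oxBS: u → T with c, m → C with d, h → T with f. The 9×4 emission matrices
over (TT, TC, CT, CC) are outer products of the per-strand channels; with
c = d = e = f = 1 they reduce to the ideal arrows (BS merges {m, h} → C,
oxBS merges {u, h} → T). Conversion probabilities are estimated per locus,
treatment and day from hairpin-linker control counts as one minus the
failed/total ratio; a pooled profile per treatment-day is assumed (no
per-molecule filtering).

## Estimation

Two-stage maximum likelihood, mirroring the experimental design:

* **Stage 1.** π(0) maximises the day-0 likelihood
  L1 = ∏_j π_bs(j,0)^n_bs(j,0) · π_ox(j,0)^n_ox(j,0) over the 9-simplex.
* **Stage 2.** With π(0) fixed, v maximises
  L2 = ∏_{t>0} ∏_j π_bs(j,t)^n_bs · π_ox(j,t)^n_ox over the post-day-0
  observation days, treated as independent (distinct small samples from a
  large pool).

Both stages minimise the negative log-likelihood with multi-start SLSQP
(default 20 starts drawn uniformly from the feasible region, seeded;
convergence tolerance 1e-9 on the objective; ties broken by objective,
then lexicographic parameter order). Feasibility of each efficiency over
the fitted division range, β₀ + β₁·t ∈ [0, 1], is imposed as linear
constraints at t = 1 and t = t_max (sufficient by linearity); p has box
bounds [0, 1]. Inside the optimiser the predicted probabilities are
floored and efficiencies clipped to keep gradients finite at the slightly
infeasible points an SQP line search may probe; the public likelihood
functions return +inf exactly when a zero-probability observable carries a
positive count. Optimum-vs-start dominance and the monotone benefit of
additional starts are tested; five starts were observed to mis-converge in
roughly one replicate in twenty on constant-efficiency data, so replicate
studies use ten to twenty.

**Uncertainty.** The observed Fisher information is the central-difference
Hessian of the stage-two negative log-likelihood at the optimum, over the
free parameters; its inverse gives standard deviations and
normal-approximation confidence intervals (default 95%). A singular
information matrix falls back to the pseudo-inverse and marks the result
unreliable; parameters pinned at a box boundary are flagged and the CI of
p is truncated to [0, 1]. These intervals are conditional on the fitted
π(0) (the information matrix covers v only), which the calibration studies
respect by conditioning on the generating π(0).

**Tests.** Each efficiency slope gets a two-sided Wald test of β₁ = 0 at
the 1% level. The joint constancy test for λ(t) notes that the t and t²
coefficients of λ (namely a₁+b₁−a₀b₁−a₁b₀ and −a₁b₁) vanish exactly when
both methylation slopes do, and runs the full-rank joint Wald χ²(2) on the
two slopes; the naive delta method on the λ coefficients has a
rank-deficient Jacobian under the null (the first-order variance of −a₁b₁
vanishes), which measurably inflates its type-I error, so it is not used.

**Model comparison.** Leave-one-timepoint-out cross-validation holds out
each post-day-0 day in turn (timepoints are the only exchangeable blocks),
refits the linear and the constant (slopes = 0) model on the remaining
days with π(0) fixed from day 0, and scores the held-out empirical
read-pair distributions with KL(empirical ‖ predicted) (predicted floored
at 1e-12) and the Bhattacharyya distance, summed over treatments. When a
fold extrapolates beyond its training divisions, efficiencies are clamped
into [0, 1]. Reported per fold, with relative improvement
(constant − linear)/constant.

## Synthetic data

The generator draws i.i.d. dyads from π(0) (no lineage correlation,
consistent with sampling few cells from a large pool), propagates each by
categorical sampling from the `P(k)` rows, and pushes every strand through
its conversion channel; BS and oxBS pools are disjoint samples of the same
hidden distribution, mirroring the split of the hairpin-ligated DNA.
Defaults define the study conditions: observation days (0, 1, 3, 6) with
one division per day; coverage 10⁴ molecules per day and treatment;
ground-truth efficiencies μ_m = 0.8, μ_d = 0.3 − 0.02 t, η = 0.05 + 0.03 t,
p = 1; a serum/LIF-like symmetric baseline π(0) with 56% fully methylated,
16% hemimethylated and 6% total 5hmC (5hmC is scarce before the 2i shift);
and conversion probabilities c = 0.995, d = 0.98, e = 0.90, f = 0.92 —
near-complete C conversion, slight 5mC over-conversion, partial 5hmC loss
under plain BS and slightly incomplete 5hmC oxidation, all typical of
hairpin (ox)BS chemistry. A separate event-level simulator plays out the
molecular rules per dyad without ever forming a matrix and serves as an
independent oracle for the transition algebra. What the generator does not
emulate: lineage correlation between sampled molecules, PCR duplicates and
amplification bias, sequencing miscalls beyond the conversion channels,
CpG-to-CpG heterogeneity within a locus, and active (replication-
independent) demethylation via 5fC/5caC — so passing tests certify the
inference machinery under the model's own assumptions, not robustness to
these real-data features.

## Identifiability

Two structural facts, established analytically and verified numerically,
shape the tests:

* **π(0) ridge.** Day-0 observables carry 6 degrees of freedom (3 per
  treatment) against 8 free parameters of the 9-simplex, so stage 1 has an
  exactly flat optimum set; under the optional strand-symmetry tie
  (um = mu, uh = hu, mh = hm) one flat direction remains, approximately
  +um +hh −uh −mh. The estimator therefore reports the spread of
  multi-start optima as a diagnostic. Entrywise recovery of π(0) is
  guaranteed only when the ridge is pinched at the simplex boundary (e.g.
  a 5hmC-free baseline); in general only the emission image of π(0) is
  identified, and the small day-0 5hmC mass of the default baseline keeps
  the ridge — and the resulting bias in downstream efficiency estimates —
  short.
* **Fully methylated loci.** When unmethylated dyads are essentially
  absent, the data constrain only λ(t) (equivalently (1−μ_m)(1−μ_d)), not
  μ_m and μ_d separately; a stable imprinted-gene-like locus is therefore
  tested through λ(t) ≈ 1.

## Numerical choices and problem sizes

Replicate studies in the test suite use 50 replicates for CI coverage
(each parameter within its 95% CI in ≥ 90% of replicates; every efficiency
recovered within 0.05 at each observed division), 300 replicates for Wald
type-I error (rate ≤ 3% per slope at the 1% level; 300 rather than 100 so
the rate estimate's standard error is small against the bound), and 20
replicates per arm for the LOOCV comparison (positive mean improvement
under a drifting η; improvement within two standard errors of zero under
constant truth). The event-level oracle uses 10⁵ draws per transition row
and five random parameter settings against a total-variation bound of
0.01. Probability validation clamps values within 1e-9 of [0, 1] to absorb
optimiser round-off; boundary proximity below 1e-6 triggers the boundary
flag.

## Limitations

The Wald machinery is asymptotic; with truth on the p = 1 boundary the
slope tests are mildly anticonservative (measured ≈ 2% at nominal 1% with
coverage 10⁴), which the 3% test bound accommodates. The FIM intervals
ignore π(0) uncertainty by construction. The model excludes 5fC/5caC and
active demethylation, assumes one pooled conversion profile per
treatment-day, and treats neighbouring CpGs as independent (per-CpG mode
simply runs the pipeline per position; aggregation sums counts).
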