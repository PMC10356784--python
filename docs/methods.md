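# Methods

This note records the models, conventions, numerical choices and known
limitations behind `covrecon`. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## Model and assumptions

A metabolic network with concentrations M ∈ ℝⁿ evolves as dM/dt = F(M).
Near a Hurwitz-stable steady state M\*, small stochastic fluctuations
with noise covariance D produce a stationary concentration covariance C
satisfying the continuous Lyapunov equation J·C + C·Jᵀ = −2D, with
J = ∂F/∂M at M\*. The package treats two experimental conditions, h and
d, each with its own (J, C, D), and targets the differential Jacobian
DJ = J_d ⊘ J_h elementwise (DJ = 1 where J_h = 0). The working
assumptions are:

- both conditions are near their (possibly different) steady states;
- noise sources act independently per metabolite, so D is diagonal —
  the classical assumption in this line of work (the L-p baseline
  optionally relaxes it to diagonal-dominant D);
- the Jacobian sparsity pattern is known (from network reduction or from
  the generating model) and shared by both conditions;
- between conditions only a small number of Jacobian entries change —
  the method ranks candidate positions, it does not reconstruct J
  quantitatively.

## Vectorization conventions

The symmetric Lyapunov equation carries m = n(n+1)/2 scalar constraints.
Rows are ordered as vech pairs (i, j), i ≤ j, row-major; columns (free
Jacobian entries q) as the row-major scan of the mask. The coefficient
of J(a, b) in constraint (i, j) is [i=a]·C(b, j) + [j=a]·C(i, b), and
b(i, j) = −2·D(i, j). These orderings are defined once in
`covrecon.lyapunov` and used by every module. With L = |mask| ≤ m the
system A q = b is overdetermined; L > m triggers an underdetermination
warning.

Least squares is solved by SVD (LAPACK `gelsd`), never by the normal
equations: the closed form (AᵀA)⁻¹Aᵀb defines the same minimizer on
full-rank problems but squares the condition number. The residual of the
fit is 1-Lipschitz in b regardless of cond(A) — verified over 1000
random instances with condition numbers up to 10¹⁰ — which is the
property the whole inverse method rests on.

## The regression-loss scan

For a candidate position p, the two conditions' systems are stacked into
a combined system Ac(p) that shares every column except p, which splits
into an h-copy and a d-copy. Structurally, every Ac(p) spans the column
space V of the fully shared (no-split) stacked system plus exactly one
extra direction u_p (the component of the h-copy column orthogonal to
V). The implementation uses this: one SVD of the shared stack, then one
projection per position; the brute-force per-position least-squares
route is retained as a test oracle and agrees to 1e-8.

The unknown fluctuation matrices are handled by sampling: per sample,
one diagonal D with entries uniform on (0, 1), used for both conditions
(b_s = [−2·vech D; −2·vech D]). Sharing the sample between conditions —
rather than drawing two independent matrices — is a deliberate choice
with two consequences we consider decisive:

- for identical conditions (C_h = C_d) every split position attains
  algebraically the same loss, so the scan correctly reports "no
  signal" (relevance ≡ 0) instead of ranking noise;
- the sampled right-hand sides concentrate on the subspace where the
  between-condition difference lives, which is what the scan
  discriminates on.

The per-sample loss for position p is the least-squares residual of
Ac(p) normalized by the residual of the *no-split* system on the same
sample — the fraction of the between-condition misfit that the single
split fails to explain. This normalization is scale-free (invariant to
rescaling C or b) and removes a bias that raw ‖b_s‖ normalization
introduces: positions whose extra direction happens to align with
typical random samples would otherwise look good regardless of the
data. The reported raw loss is the minimum over samples; relevance is
the min–max inversion over masked positions (all-equal losses map to
relevance 0). Low loss ⇒ high relevance: the split that explains the
between-condition difference fits best. Both matrices are emitted.

Default n_samples = 100: on models of roughly ten species the Top-1
ranking is already stable at this sample count, and the replicability
benchmarks below run at exactly this setting.

## L-p baseline

The older approach optimizes the diagonal entries of D_h and D_d
(bounded in (0, 1]; the diagonal-dominant variant adds off-diagonals
bounded by half the geometric mean of the corresponding diagonals) to
minimize Σ |DJ(i,j) − 1|^p over the mask, p = 0.5 by default, with
multi-start Powell over 20 seeded restarts. Two implementation points:

- the bare objective over least-squares Jacobians is degenerate:
  ill-fitting D values yield arbitrary fitted Jacobians whose sparsity
  cost can undercut the truth. The objective therefore adds a
  consistency penalty (weight 100 on the sum of the two conditions'
  relative residuals), enforcing the "the linear systems are solved,
  not merely fitted" assumption of the original method. The bare
  sparsity cost and the misfit are exposed separately
  (`sparsity_cost_`, `misfit_`).
- even with exact covariances the per-condition inverse problem is
  non-unique whenever L + n > m (the consistent diagonal-D family has
  positive dimension), and the L-p optimum may legitimately sit at an
  alternative sparse explanation. On a 3-species chain (L = 5, m = 6)
  the baseline attributes a 6-fold change at one entry to a smaller
  change at a neighboring entry. This is a limitation of the baseline,
  not of the implementation; the regression-loss scan resolves the same
  instance correctly because its combined system constrains both
  conditions jointly. Baseline tests therefore use identifiable
  configurations (L + n ≤ m, unique up to a common scale that leaves DJ
  fixed).

## Network reduction

Edge weights: forward substrate→product steps cost 1; reverse steps of
reversible reactions cost `reverse_weight` (default 2), plus log₁₀(ΔG)
when ModelSEED reports ΔG > 100 kcal/mol (the logarithm base is our
choice; the magnitude-penalty idea follows the pathway-search
literature). Co-substrates are linked both ways at the forward weight,
co-products of reversible reactions at the reverse weight, because each
reactant perturbs the shared rate law. Currency metabolites are removed
before edge construction; the shipped default list (water, protons,
common cofactors, by compartment-stripped base id) is an editable
substitute for curated lists in the pathway-search literature. Parallel
edges collapse to the minimum weight with merged provenance, so
superpathway reports list all contributing reactions.

Shortest paths use Dijkstra with full-path lexicographic tie-breaking
(deterministic, validated against exhaustive enumeration on small
graphs). A route is kept iff its cost is ≤ the threshold (default 3;
equality kept) and no interior node is itself a measured metabolite; a
kept route j → i marks Jacobian entry (i, j). One-step co-reactant
links count as routes of length 1 for pruning. Expression trimming
(GIMME-style role) removes a reaction only when *all* its associated
genes are expressed below threshold and none lacks data; gene rules are
tokenized to plain gene sets (OR semantics) — boolean rule evaluation
and LP-based expression integration are out of scope.

## Synthetic harness

`generate_mass_action_model` draws an open chain (zeroth-order inflow,
first-order conversions, a first-order degradation sink per species)
plus random extra uni-/bi-molecular conversions, rejecting candidates
until the steady state is positive and the Jacobian Hurwitz. Rate
constants: inflow 1, chain U(0.8, 1.5), degradation U(0.3, 0.8), extras
U(0.1, 0.5) (uni) / U(0.05, 0.2) (bi) — dimensionless time, O(1)
concentrations. The packaged fixture models (sizes 5, 6, 12, 13, 27,
31, 33 — matching the species counts of the published evaluation-model
suite) are uni-molecular, so their Jacobians are
concentration-independent and a rate-constant perturbation changes an
exactly known entry set.

Benchmark condition pairs perturb one degradation rate constant by a
factor of 8 — a strong enzyme up/down-regulation, and the only
mass-action perturbation that changes exactly one Jacobian entry
(|DJ−1| ≈ 1.3–3 on the fixtures, since a diagonal entry aggregates
several first-order outflows). The method targets *major* changed
components; perturbations that move an entry by only a few tens of
percent sit near its detectability floor and are not claimed to be
recoverable (see Limitations).

Covariance generation, two routes matching the two evaluation modes:

- exact: D diagonal with entries U(1 − ε_D, 1 + ε_D) (ε_D = 0 ⇒ D = I),
  C from the Lyapunov solver (`scipy.linalg.solve_continuous_lyapunov`,
  post-symmetrized, residual-checked at 1e-8);
- empirical: Euler–Maruyama integration of dM = F(M) dt + σ dW from M\*
  (dt = 0.01, σ = 0.05, burn-in 2000 steps, thinning 50 steps, floors
  at 0), sample covariance over n recorded states. The integrator is
  deliberately the simplest consistent one — only the stationary
  covariance matters downstream, and it converges to the Lyapunov
  solution with D = (σ²/2)·I (6.7% relative Frobenius error at n =
  10 000 on the 5-species fixture, seed 1). Higher-order stochastic
  integrators are pluggable but unnecessary at these step sizes.

Conserved-moiety removal computes the left null space of the
stoichiometric matrix exactly (sympy), removes the highest-index
participating species per independent relation (and species appearing
in no reaction), and re-expresses removed species through the conserved
totals at the reference state; the reduced system is what steady-state
and Jacobian analysis sees.

## Evaluation metrics

Top-k replicability: per repeat, fresh randomized D at amplitude ε_D per
condition, exact covariances, full scan, then comparison of the scan's
top-k (ties by row-major position) against the truth's top-k by
|DJ − 1|. "Hit" means exact set equality — the strictest reading; mean
per-element overlap is reported alongside, since weaker readings exist.
With a single truly changed entry, k > 1 reference sets are padded by
(unchanged) positions with tie-broken order, which makes exact k > 1
equality essentially unattainable by construction — the overlap metric
is the informative one there. Measured at 100 repeats, the fixtures
give Top-1 accuracy 1.00 (n = 5, 12, 27) at ε_D = 0.2, degrading
monotonically with ε_D (e.g. 0.98 → 0.67 on the 5-species fixture from
ε_D 0.2 → 0.5, seed 1); Spearman correlation of Top-1 accuracy against
ε_D is ≤ 0.

The differential correlation matrix (corr(C_d) − corr(C_h)) is computed
as a negative control — it is invariant to per-metabolite unit
rescaling, but it does not recover differential-Jacobian structure and
no recovery threshold is asserted for it. Relevance from the scan is
*not* claimed unit-invariant: rescaling a single metabolite changes the
admissible-system geometry. Variable importance for real datasets is
−log₁₀(P) from Welch's two-sample t-test per metabolite.

Circular plots place nodes in label order on a circle; edge width scales
with off-diagonal relevance, node size with the importance vector or the
diagonal relevance; per-edge enzyme/gene annotations go to a sidecar CSV
rather than into the figure.

## Degenerate inputs and numerical edges

- Unstable J (any eigenvalue real part ≥ 0): forward solve refuses —
  no stationary covariance exists.
- C_h = C_d: all scan losses coincide; relevance is identically 0
  (a 1e-9 relative tolerance absorbs float noise between algebraically
  equal losses).
- No-split residual numerically zero for a sample (data explained
  without any change): that sample's losses are set to 1 (no evidence).
- Split column already in the shared span (u_p ≈ 0): loss 1 for that
  position.
- Truth with no changed entry: Top-k hit is counted as a miss, with a
  warning.
- Zero variance metabolites: differential correlation raises, naming
  the metabolite; t-tests on doubly constant columns score 0 with a
  warning.

## Problem sizes

The shipped benchmarks run on one CPU: consistency suite (50 systems,
n ≤ 12), stability suite (1000 instances, 12×5), recovery (3 fixtures ×
100 repeats), replicability grid (2 fixtures × 4 noise levels × 100
repeats), SDE agreement (5 species × 10⁴ snapshots). These sizes give
binomial standard errors ≤ 0.05 on accuracy estimates and keep the whole
evaluation in the tens of seconds; all generators are bitwise
reproducible under fixed seeds.

## Known limitations

- Weak perturbations (entry changes ≲ 30%) are frequently not Top-1
  recoverable even from exact covariances; the scan ranks *major*
  components.
- The scan assumes a single differing entry per hypothesis; when several
  entries change, neighboring positions share relevance and the
  per-entry attribution blurs (the Top-1 position remains the dominant
  change in our benchmarks).
- Fixture models are uni-molecular and well-conditioned (vectorized
  system condition numbers around 10¹ rather than the 10⁴–10¹⁰ of
  curated kinetic models); the stability suite exercises the
  ill-conditioned regime synthetically, but end-to-end recovery on
  stiff curated models requires importing those models (SBML loader
  provided, mass-action kinetic laws only).
- Enzyme-level regulation (allosteric activation/inhibition) is not in
  the reaction databases the reduction uses, so Jacobian entries caused
  by it are structurally invisible to the workflow.
- Passing the synthetic benchmarks shows correctness of the machinery
  under the stated noise model (diagonal D, stationarity); real
  metabolomics adds measurement error, non-stationarity and
  compositionality that the generator does not emulate.
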