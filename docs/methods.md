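# Methods

## Scope and model

`gembench` benchmarks algorithms that extract a *context-specific*
subnetwork from a genome-scale metabolic model (GEM). A GEM is a
stoichiometric matrix `S` (metabolites x reactions) with per-reaction
flux bounds `lb <= v <= ub` and gene-protein-reaction (GPR) boolean
rules. A context-specific extraction algorithm consumes evidence —
discretized gene expression, or directly asserted present/absent
reaction sets — and returns the subset of reactions presumed active in
one tissue or condition.

Because no measured tissue network is a usable gold standard, the
benchmark manufactures its own: synthetic global networks whose
flux-consistent target submodels are known exactly, evidence sampled
from those targets at controlled completeness, and two families of
statistics — *consistency testing* (robustness to partial evidence,
resolution power, cross-validation) and *comparison-based testing*
(confusion metrics against the known target, confidence enrichment,
LP-based functionality tests with a random-network size baseline).

## Flux consistency

A reaction is flux-consistent when some steady-state distribution
(`S v = 0` within bounds) carries at least `eps` absolute flux through
it. The per-reaction oracle solves two LPs (maximize, then for
reversible reactions minimize, `v_r`). The fast set-level algorithm is
contractually identical to the oracle and layers three exact stages:

1. **Dead-end elimination.** If no remaining reaction can produce (or
   none can consume) a metabolite, every term of its steady-state row
   is one-signed, so all adjacent reactions are provably blocked;
   iterated to a fixpoint. No LP is solved.
2. **Batched certification.** One LP maximizes auxiliaries
   `t_i <= v_i`, `0 <= t_i <= eps` over the undecided reactions; every
   reaction reaching `eps` flux in the optimum is consistent.
   Reversible reactions get a mirrored pass.
3. **Per-reaction settlement.** Remaining reactions are decided by the
   oracle on the dead-end-free subnetwork; each maximizing LP's flux
   vector also certifies any other undecided reaction it pushes past
   `eps`. Negatives are never declared heuristically.

`eps` defaults to `1e-4` (the convention of the fast consistency
literature; the threshold must exceed the solver feasibility tolerance
by at least 10x, enforced). Infinite bounds are capped at `+-10000`,
matching the cap used in the task LP. All LPs go through SciPy's HiGHS
interface; HiGHS is deterministic, so all benchmark results are pure
functions of their seeds.

Because "can carry eps flux" is judged against the surrounding network,
one pruning pass is not idempotent in corner cases; generators that emit
*standalone* ground-truth networks iterate pruning to a fixpoint
(`consistent_fixpoint`), so every emitted target equals the consistent
part of its own induced subnetwork.

## Reference extractors

Four reference algorithms span the two families the benchmark contrasts:

* **`fastcore`** (exclusive): returns a small flux-consistent superset
  of a trusted-active core. The covering loop alternates (A) certifying
  core reactions *within the already-included subnetwork* — one LP per
  direction maximizing how many uncovered core reactions reach `eps`
  flux, with stalls settled one reaction at a time — and (B) forcing
  stragglers on the full network while minimizing the L1 flux norm of
  not-yet-included reactions (blocks forced jointly, bisected on
  infeasibility). Additions happen only in phase B, so a core that is
  already self-consistent is returned exactly; this is what makes the
  perfect-information recovery property exact rather than approximate.
  Supports are read off LP solutions at `1e-6` absolute flux; genuine
  path members of an eps-forced mode carry at least `eps` divided by the
  largest stoichiometric ratio (about `1e-5` here), well above that
  threshold, while sub-tolerance solver residue sits below it.
* **`exclusive`** (FASTCORMICS-style): removes trusted-inactive
  reactions first, re-prunes, drops (with a warning) core reactions that
  the removal made unsupportable, then runs the covering extractor on
  the survivors. It is the exclusive-family representative in the
  error-profile comparison because it consumes both halves of the
  evidence.
* **`inclusive`** (absence-removal): deletes trusted-inactive reactions
  and keeps everything still able to carry flux; active evidence is
  ignored — anything not ruled out is presumed present.
* **`gimme`** (objective-driven inclusive): maximizes flux through a
  designated objective reaction, then, holding the objective at a
  configurable fraction of its optimum (default 0.9), minimizes
  `sum (cutoff - score_r) |v_r|` over reactions scoring below the
  cutoff. Output: unpenalized reactions plus penalized ones carrying
  `>= eps` flux, pruned to the consistent subnetwork containing the
  objective. The historical "biomass objective coefficient 1e-4" COBRA
  setting does not map to a unique mathematical role; the required
  objective fraction is exposed directly and the historical value kept
  as a named preset.

Discretization follows the Barcode-style convention: a gene is called
expressed (+1) when >90%-threshold of samples exceed 5 z-scores,
unexpressed (-1) when the same fraction fall below 0, else 0; calls map
to reactions through the GPR with AND=min, OR=max (the dominant field
convention, and monotone — raising a gene score never lowers a reaction
score). The same ordered algebra drives proteomic confidence mapping
(OR=best, AND=worst category).

Third-party algorithms register by name
(`register_extractor(name, fn)`); drivers enforce the output-contract
(`ExtractionResult`, reactions a subset of the network) and isolate
per-extractor crashes so one failing plugin cannot corrupt the others'
tables.

## Synthetic data

The generator emulates the structure the benchmark needs, not real
biochemistry:

* **Global networks** mix internal conversions (1-2 substrates -> 1-2
  products, coefficients mostly 1, occasionally 2), reversible boundary
  exchanges for ~15% of metabolites, random GPRs (Poisson-sized gene
  sets joined by and/or, occasionally nested), subsystem labels, and a
  designated biomass-like objective consuming importable precursors.
  Defaults (120 metabolites, 330 reactions pre-pruning) yield ~300
  consistent reactions — large enough for non-trivial extraction, small
  enough that every benchmark arm runs in minutes on one CPU; larger
  configurations are reachable through `GlobalNetConfig`.
* **Targets** repeat {remove a random reaction subset; keep the
  consistent fixpoint} until the result lands within a tolerance of the
  requested size. The removal count is adapted between attempts
  (secant-style step toward the requested size, with jitter) so the
  attempt stream reaches each size band quickly; the first model within
  tolerance is accepted. The objective reaction and its sink are
  protected from removal so objective-driven extractors run on every
  target.
* **Evidence** at information fraction `f`: a uniform sample of
  `floor(f |T|)` target reactions (present) and `floor(f |U\T|)`
  complement reactions (absent); one seed per evidence draw, shared
  across all algorithms under comparison.
* **Expression profiles**: genes of target reactions draw per-sample
  z-scores from `Normal(8, 1.5)`, all others from `Normal(0, 1)` —
  means and spreads chosen so the 5/0 thresholds separate the
  populations with realistic overlap; optional dropout replaces an
  expressed gene's sample with an unexpressed draw. With the 90%-rule
  over n samples, an expressed gene survives dropout rate `d` with
  probability `BinomCDF(floor(0.1 n); n, d)` — a closed form the tests
  check against.

What the generator does **not** emulate: real compartment structure,
realistic GPR complexity distributions, correlated expression noise,
probe effects, or curated biochemistry. Passing benchmarks on this
fixture demonstrates algorithmic properties (recovery, robustness,
resolution, bias direction), not performance on real tissues.

## Statistics

Model similarity is the Jaccard index `|A n B| / |A u B|` on reaction
sets (two empty sets count as identical); matrices are clustered by
Euclidean distance between rows with average linkage (configurable).
Resolution power is the matrix of mean pairwise Jaccard between runs
for each target pair — the diagonal (within-target) reads as
robustness, the off-diagonal (between-target) as inverse specificity.
Confusion metrics use `sensitivity = TP/(TP+FN)`,
`specificity = TN/(TN+FP)`, `FDR = FP/(TP+FP)` with 0/0 (empty output)
defined as 0. The hypergeometric upper tail `P(X >= k)` comes from
SciPy's log-space survival function and is verified against exhaustive
enumeration; the two-sample KS test uses the asymptotic p-value and is
verified against a direct ECDF sweep.

Cross-validation holds out 20% of the active core per repetition
(default 100 repetitions) and counts held-out reactions re-entering the
output. The enrichment test is parameterized as: population
= reactions outside the reduced core, successes = validation set, draws
= non-core reactions the extractor added, observed = recovered; this
reading measures whether held-out reactions re-enter more often than
chance, and is recorded per repetition so alternative parameterizations
can be compared.

## Functionality (task) testing

A metabolic task asks whether a network can produce or consume stated
objective metabolites given importable/exportable metabolites, with all
explicit exchange reactions closed. With split fluxes
`v' = [v+; v-] >= 0` and `S' = [S, -S]`, accumulation `S' v'` is boxed
per metabolite: imported `[-10000, 0]` (or `[-10000, 10000]` if also
exported), exported `[0, 10000]`, produced objectives pinned to one
unit, consumed objectives to minus one, all others `[0, 0]`; exchange
columns satisfy `v+ - v- = 0`; the LP minimizes `sum(v+ + v-)`. A task
passes when the LP is feasible with nonzero accumulation on every
objective metabolite; tasks naming metabolites the network lacks return
a distinct `unresolvable` status (a subnetwork legitimately loses
metabolites) instead of raising.

Two sign conventions are implemented because the historical printed
bound table pins "produced objectives(+)" at -1 and "consumed
objectives(-)" at +1 — opposite to the convention that positive `S v`
is net production. The default `accumulation` mode follows the (+)/(-)
annotations (+1 produced, -1 consumed); `literal` reproduces the
printed numbers. They differ only by the sign of the objective rows,
and both are covered by tests.

Feasible solutions extend by zeros when reactions are added, so a task
passing on a subnetwork passes on every supernetwork — the mechanism
behind the size-score correlation that the random-network baseline
quantifies (`size_score_baseline`: random consistent subnetworks,
tasks-passed regressed on size by OLS). A bundled generator
(`generate_task_suite`) builds random import->produce / import->consume
probes verified feasible on the full network, standing in for curated
physiological task collections, which are external data; its `network`
vs `physiological` kind labels only group reporting.

## Problem sizes and numerical choices

Default benchmark scale, chosen so the complete two-arm benchmark plus
its test suite runs in well under half an hour on a single CPU: one
~300-reaction global network; five targets equally spaced between 30%
and 80% of it (tolerance +-10 reactions); information fractions
{0.5, 0.6, 0.7, 0.8, 0.9} with 20 evidence repetitions shared across
algorithms; resolution analysis at 0.9; cross-validation at 20% holdout
x 100 repetitions; functionality baseline over 100 random subnetworks
(up to 150 removals) with a 40-task suite. The protocol itself scales
to paper-sized networks (thousands of reactions, hundreds of
repetitions) by configuration only.

Numerical notes: `eps = 1e-4` with solver tolerance `1e-9`; support
threshold `1e-6` (see above); the covering LP's coverage/penalty weight
ratio is fixed at 100x `eps` so coverage strictly dominates the L1
tie-break at every magnitude the solver resolves. Alternative LP optima
can differ between solvers; contracts are therefore set-theoretic only
where the optimum is forced, and the benchmark asserts distributional
patterns, not exact reaction sets, wherever alternative optima exist.

## Known limitations

* Steady-state flux consistency only; no thermodynamic/loopless
  analysis. Directed stoichiometric cycles count as consistent, which
  also means a network with no boundary exchange can still carry flux
  around loops.
* The covering extractor is heuristically small, not minimal — exact
  minimality is NP-hard and no contract claims it.
* The GIMME-style extractor requires its objective to be operable in
  every target; the generator protects the objective during target
  construction, which real tissue data does not guarantee.
* The synthetic expression model draws genes independently; correlated
  noise (batch effects, probe cross-hybridization) is out of scope.
* Algorithms beyond the four references (iMAT-, INIT-, MBA-style, etc.)
  participate only through the plugin registry; none are bundled.
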