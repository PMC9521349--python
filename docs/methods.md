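# Methods

This note documents the statistical machinery behind `cosegnet`: the models
and algorithms, the tunable parameters and their defaults, what the
synthetic-cohort generator does and does not emulate, and the numerical and
design choices that were genuinely open.

## Data model

The unit of analysis is a binary **mutation matrix** X ∈ {0,1}^(n×m):
patient *i* is "mutation-positive" in gene *j* iff at least one retained
pathogenic alteration was called. When the input is a long alteration-call
table, two filtering rules produce the retained set: variants of unknown
significance and benign calls are excluded, while frameshift and nonsense
calls count as pathogenic regardless of their annotated significance.
Copy-number amplifications and fusions are excluded from mutation-positive
status by default (`include_copy_number=True` reverses this): gene-level
"mutation" conventions for panel reports differ, and treating structural
events separately is the conservative default. If a date column is mapped,
only each patient's earliest test is kept (first-available-result rule);
without dates, all rows for a patient are treated as one test. Gene symbols
are upper-cased and whitespace-stripped; no alias resolution is attempted —
symbol harmonisation against a reference would add silent failure modes
this package cannot verify.

## Pairwise screening

For anchor *a* and candidate *g* the 2×2 table (a⁺g⁺, a⁺g⁻, a⁻g⁺, a⁻g⁻) is
tested with the two-sided Fisher exact test under the minimum-likelihood
convention: p = Σ P(T) over all tables T with the observed margins whose
point probability is ≤ that of the observed table, with relative tie
tolerance 1e-7. Degenerate margins give p = 1. The odds ratio is reported
as the raw cross-product ratio (∞ when b·c = 0 and a·d > 0) with no
continuity correction, so the exact test stays exact.

Adjustment is Benjamini–Hochberg across exactly the candidate family of
one anchor (anchors are assessed independently; two anchors mean two
families). Significance is p_adj ≤ α with α = 0.05 default. Note that BH
is *not* idempotent in general: re-adjusting an adjusted sequence rescales
ranks (only special fixed points such as constant plateaus are preserved).

A one-sample two-cell chi-squared test (`prevalence_chi_squared`) compares
an observed prevalence against a user-supplied published reference
proportion; reference proportions are inputs, not package constants.

## Structure learning

Scores are decomposable over node families. The default is **BDeu** with
equivalent sample size 1 and a uniform structure prior:

score(v | Π) = Σ_j [ lnΓ(α_j) − lnΓ(α_j + N_j) ] +
Σ_{j,k} [ lnΓ(α_jk + N_jk) − lnΓ(α_jk) ],  α_j = ess/q, α_jk = ess/(2q),

with q = 2^|Π| parent configurations. BDeu gives Markov-equivalent DAGs
identical scores (verified to 1e-9 in tests). **BIC** (log-likelihood −
(ln n / 2)·q) is available by flag. `max_parents` defaults to 4, bounding
the scored-parent-set table at C(m−1, ≤4) entries per node.

*Approximate stage.* Greedy hill-climbing over DAGs with add, delete and
reverse moves, first-improvement-free (the single best strictly improving
move is applied each step), 10 restarts (restart 0 from the empty graph,
others from seeded random DAGs), up to 500 moves per restart, family
scores memoised. The candidate neighbor set is the union of the anchors'
Markov blankets in the best-scoring DAG; if it exceeds k (default 15,
anchors excluded), the k genes with the largest single-edge score
improvement towards an anchor are kept, and the returned list is ranked by
that improvement.

*Exact stage.* A\* over the order lattice: states are subsets S of nodes,
a transition places node v with bestScore(v, parents ⊆ S), precomputed by
a superset-max transform over the scored parent sets. The heuristic
h(S) = Σ_{v∉S} bestScore(v, any parents) is admissible and consistent, so
the first expansion of the full set is a global optimum for the given
score table (verified against exhaustive enumeration of all 25 / 543
labeled DAGs on 3 / 4 nodes). Ties in f-value expand in ascending
subset-mask order; among equal-score parent sets the smallest, then
lexicographically first, is kept — outputs are deterministic. A guard
rejects exact search above 25 nodes; the intended regime is the ≤ ~17-node
candidate sets produced by the approximate stage.

`enumerate_all_dags` (≤ 5 nodes) exists purely as a test oracle.

## Parameter fitting and inference

CPTs are Dirichlet-smoothed conditional frequencies,
P(v=1 | config) = (N₁ + c) / (N + 2c), unseen configurations = 0.5. The
default pseudo-count is **c = 0.1**, chosen on a bias argument: smoothing
biases a rare conditional by ≈ c(1−2p)/(Np) relatively, and the pipeline's
headline mutual-exclusivity query conditions on a cell with only a couple
of expected events even at n ≈ 7,700 (P(BRCA1⁺∧BRCA2⁺) ≈ 2.7·10⁻⁴), where
c = 1 would inflate the estimate by ~50%. c = 0.1 keeps every factor
strictly inside (0,1) — required for belief propagation — at ≈ 5% worst-case
relative bias. Pass `pseudo_count=0` for plain maximum likelihood or larger
values for stronger regularisation.

Exact queries use sum-product **variable elimination** in min-degree order
on the ancestral closure of the involved genes (barren nodes are dropped).
**Loopy belief propagation** is sum-product message passing on the factor
graph with a synchronous flooding schedule, damping 0.5, tolerance 1e-8 on
the largest message change, and at most 200 sweeps; evidence enters as
unary indicator factors, which are exempt from damping so that impossible
evidence produces an exact zero factor mass and a hard error naming the
factor. BP is exact on polytrees (equal to variable elimination to 1e-8 in
tests); on loopy graphs it is an approximation — see "what the tests show"
below. Relative-risk queries prefer exact elimination whenever the relevant
subnetwork has ≤ 20 nodes and fall back to BP (with a logged notice and a
chain-rule decomposition for multi-gene numerators) above that.

Both conditioning directions of the relative risk are first-class
(`anchor_given_genes`, the default, and `genes_given_anchor`), because the
field's verbal definitions of "risk of co-segregation" are used both ways
and the two ratios differ for multi-gene condition sets; every report row
carries its direction. `empirical_relative_risk` computes the same ratio
from raw cohort counts, with a (k+0.5)/(n+1) continuity correction and a
`degenerate` flag when any stratum or event count is zero.

## Synthetic cohorts

`default_cohort_model` is a 20-gene Bayesian network over binary mutation
indicators emulating a large prostate-cancer cfDNA cohort: n = 7,707
patients; BRCA1 marginal 4.6%; BRCA2 a child of BRCA1 with its CPT solved
in closed form so the BRCA2 marginal is exactly 7.97% and the model-implied
RR(BRCA2 | BRCA1) exactly 0.07; six partner genes as children of BRCA1; and
twelve independent background genes (TP53 0.40, AR 0.30, MYC 0.12, PIK3CA
0.10, PTEN 0.08, APC 0.07, ATM 0.06, CDK12 0.05, RB1 0.04, CTNNB1 0.035,
KRAS 0.03, BRAF 0.025 — typical panel ranges; no per-gene frequencies are
published for the real cohort, so these are this package's choices).

Partner CPTs (P(g=1|BRCA1=0), P(g=1|BRCA1=1)): ERBB2 (0.055, 0.16), NOTCH1
(0.07, 0.155), AKT1 (0.06, 0.14), MTOR (0.06, 0.145), ARID1A (0.045, 0.12),
EGFR (0.075, 0.165). By enumeration these give single-gene RRs vs BRCA1 of
2.99, 2.30, 2.39, 2.48, 2.68 and 2.30 respectively, and RR ≈ 11.5 for the
three-gene condition {NOTCH1, ARID1A, MTOR}. The effect strengths are
calibrated so that the planted structure is actually recoverable at the
cohort scale — each planted association has detection z ≥ 5.6, so the
Fisher/FDR screen and the BDeu edge criterion (which is stricter than the
screen) each recover all six partners in ≥ 90% of seeded cohorts. Under
weaker settings of the same RRs the weakest partners sat at z ≈ 4.5 and
dropped out of the learned graph in ~10–15% of cohorts.

Sampling is ancestral, vectorised per gene in topological order, with one
Philox (counter-based) uniform per (patient, gene) cell keyed by the seed:
realizations are bitwise reproducible and independent of gene iteration
order. Ground-truth RRs attached to a realization come from exact
enumeration of the model joint (on the query's ancestral closure), never
from the sample.

The generator emulates gene-level co-occurrence structure only. It does
not simulate read-level sequencing, variant allele fractions, assay
sensitivity, tumour fraction, clonal hematopoiesis, germline/somatic
origin, or panel versioning — so passing tests demonstrate correct
recovery of *planted gene-level dependence under ideal calling*, not
robustness to the measurement artefacts of real cfDNA assays.

## Evaluation design and what the tests show

*Relative-risk recovery* is assessed by the Monte-Carlo mean of the
estimator across 200 replicate cohorts, compared with the generator's
exact value (±15%). Per-cohort assessment is not meaningful for the
mutual-exclusivity query: its numerator rests on ~2 expected joint events
per cohort (coefficient of variation ≈ 70%), so single-realization
estimates scatter far outside any reasonable tolerance no matter the
estimator; the aggregate mean isolates estimator bias from sampling noise.
Each replicate runs the pipeline's own path — screen-selected candidates
plus anchors, exact structure search, smoothed CPT fit, exact RR query.

*Loopy-BP accuracy* is assessed per belief: on random polytrees BP must
match variable elimination to 1e-8; on loopy benchmark networks (random
polytree plus one loop-forming edge, CPTs shaped like fitted panel tables —
base rates 2–30%, multiplicative parent effects ×0.5–3) at least 95% of
converged node marginals must lie within 1e-3 of the exact values. The CPT
regime matters and is deliberate: BP's loop-induced bias is intrinsic and
grows with coupling strength — with generic strong potentials
(CPTs ~ U(0.05, 0.95)) typical worst-node errors are 1e-3 to 1e-1 and no
ensemble we measured puts 95% of *networks* under 1e-3. The benchmark
therefore certifies BP in the weak-to-moderate-coupling regime the
package's fitted networks occupy, not as a universally 1e-3-accurate
method; exact elimination remains the default for the sizes that matter
here.

*False-discovery control* is checked on cohorts where anchors are
independent of every candidate: the empirical false-discovery proportion
of the screen over 400 anchor-families stays below α plus two Monte-Carlo
standard errors (discreteness of the Fisher test makes it conservative in
practice, ~0.02–0.04 at α = 0.05).

## Numerical choices and degenerate inputs

- Fisher ties: relative tolerance 1e-7 on the point-probability comparison
  (matching the enumeration oracle used in tests to 1e-12).
- Hill-climbing accepts a move only if it improves the score by > 1e-12;
  equal-score moves are never taken, keeping runs deterministic.
- A zero RR denominator yields rr = ∞ with a `degenerate` flag rather than
  an exception; an impossible conditioning *event* (probability 0) raises.
- Empty matrices, unknown genes/anchors, p-values outside [0,1], CPT rows
  outside (0,1), cyclic parent structures, and >25-node exact searches are
  hard errors with the offending item named.
- `landscape` orders retained genes by descending frequency, ties broken
  alphabetically; retention uses ≥ min_freq (so 31/614 = 0.0505 is kept at
  the 5% threshold and 30/614 = 0.0488 is not).

## Known limitations

- Gene-level binarisation discards allele counts, zygosity and variant
  identity; two different pathogenic variants in one gene are one "1".
- The screen and the network model both assume exchangeable patients; no
  covariates (disease state, prior therapy, assay version) are modelled.
- Edge directions within a Markov-equivalence class are not identified
  from observational data; only the dependence structure (the moralised
  skeleton) and the implied joint are interpretable.
- BDeu with ess = 1 is a conventional default; edge inclusion near the
  detection boundary is sensitive to ess, and no attempt is made to tune
  it per dataset.
- The exact-search guard (25 nodes) reflects memory growth of the
  order-lattice tables (O(m·2^m)); larger panels must go through the
  approximate stage first.
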