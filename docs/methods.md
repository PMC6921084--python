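# Methods

`bnsurvey` estimates the association structure of a set of dichotomized
survey variables, separately within each stratum of a multi-country
survey (one stratum per country × sex), and aggregates the per-stratum
graphs into a cross-country summary. This note records the model, the
algorithmic choices, and what the synthetic-data experiments do and do
not demonstrate.

## Model and assumptions

Within a stratum the p binary variables are modelled as a Bayesian
network: a DAG in which an edge means the two variables are dependent
given every subset of the remaining ones. Under the assumptions of
faithfulness and no unmeasured confounders, the skeleton and the
v-structures of the DAG are identifiable from observational data, but
individual edge directions generally are not; the estimand is therefore
the CPDAG — the representative of the Markov equivalence class in which
compelled edges are directed and reversible edges left undirected.

Sampling weights are design metadata: they enter the analysis only
through weighted bootstrap resampling, never as regression or test
weights. All tests and odds ratios are computed on unweighted rows.

## Conditional-independence testing

The learner uses the G² likelihood-ratio test on stratified 2×2 tables:
for x ⊥ y | z, one 2×2 table per observed joint level of z, with
G² = 2·ΣO·ln(O/E) summed over all tables and one degree of freedom per
nonempty stratum. Pearson's X² is available as a config switch
(`LearnConfig.test="chi2"`). Choices worth recording:

* **α = 0.05** is the default rejection level — the conventional default
  in constraint-based learners.
* **Zero-margin cells** contribute nothing to the statistic (E = 0
  forces O = 0); strata with zero total are dropped from the degrees of
  freedom.
* **Small-sample guard**: when n < 5 × (number of nonempty strata) the
  test declares independence outright (`LearnConfig.guard`, settable to
  0). In bootstrap replicates, heavily conditioned tests on near-empty
  tables otherwise produce spurious rejections; the guard is the
  standard heuristic remedy.
* **Constant variables** (possible in bootstrap replicates) are declared
  independent of everything, so they become isolated nodes.

Calibration is verified empirically: at n = 1000 with conditioning sets
of size 0–2, the measured type-I error at α = 0.05 lies in [0.04, 0.06]
(see `tests/test_acceptance.py`).

## Structure learning

Per stratum the CPDAG is estimated constraint-based:

1. **IAMB Markov blankets** for every node: grow by repeatedly adding
   the candidate with the largest test statistic given the current
   blanket while it rejects at α (ties broken by smallest column index),
   then shrink by removing members independent of the target given the
   rest.
2. **AND-rule symmetrization**: x–y survives only if x ∈ MB(y) and
   y ∈ MB(x).
3. **Neighbour resolution**: x and y are adjacent iff no subset of the
   smaller of MB(x)\{y}, MB(y)\{x} separates them; subsets are searched
   in order of increasing size, and the first separating set is
   recorded.
4. **Collider orientation**: for each nonadjacent pair with a common
   neighbour z, orient x → z ← y iff z is outside the recorded
   separating set (pairs that never entered the subset search use the
   Markov blanket itself as their separating set). Conflicting collider
   decisions are resolved first-found over a fixed node ordering.
5. **Meek rules R1–R3** to closure. R4 cannot fire without background
   knowledge and is omitted. In pathological replicates contradictory
   collider evidence can direct a cycle; a safeguard then un-directs
   edges of the cycle until the directed part is acyclic.

With a d-separation oracle in place of the data-driven test the
procedure reproduces `dag_to_cpdag` exactly on hundreds of random DAGs —
the algorithmic half of the learner is exact; all estimation error comes
from the CI test.

On data, single-run recovery is limited by the test's type-I error: a
spurious adjacency that happens to survive every separation attempt does
not vanish as n grows, so even at n = 50,000 a minority of runs on the
reference network carry one or two extra edges. This is intrinsic to
constraint-based learning at a fixed α and is precisely the instability
the bootstrap-consensus step removes; the unit suite asserts the honest
single-run property (majority exact recovery over eight seeded runs at
n = 50,000), and stability claims rest on the consensus, not on single
runs.

## Weighted bootstrap consensus

Each stratum is resampled `n_boot` times (default 10,000; the test suite
and the acceptance script use 100–200), drawing n rows with replacement
with probability proportional to the sampling weight, and a CPDAG is
learned per replicate. An edge enters the consensus graph when present
in ≥ 90% of replicate CPDAGs; it is oriented a → b when that direction
occurs in ≥ 70% of replicates (directed occurrences count toward both
presence and direction; undirected ones toward presence only). Both
thresholds compare at ≥ with a 1e-12 float tolerance so an exact 90.0%
is included. The direction denominator is all replicates by default;
"replicates containing the edge" is a config switch
(`direction_denominator="present"`).

Resample size equals the original n (the standard bootstrap convention).
Replicate r uses `SeedSequence([seed, r])` (with the stratum index
prepended in multi-stratum runs), so runs are bit-for-bit reproducible,
replicates are independent of chunking, and parallel workers cannot
change the result — integer tallies add commutatively.

Per-edge signs are computed once on the original (un-resampled) stratum:
the crude odds ratio (ad/bc, with the Haldane–Anscombe +0.5 on every
cell when any cell is zero) and the Cochran–Mantel–Haenszel pooled odds
ratio Σ(aᵢdᵢ/nᵢ)/Σ(bᵢcᵢ/nᵢ) conditioned on all remaining variables. An
association is negative if both are below 1, positive if both are above
1, and indeterminate otherwise (disagreement, a ratio exactly 1, or an
undefined estimate — the CMH is undefined when its denominator
vanishes). The CMH estimator is left uncorrected: it tolerates zero
cells unless the whole denominator vanishes.

## Cross-country summary

Per sex, an edge enters the summary graph when present in at least
`min_countries` consensus graphs (default 6; 5 when the HIV-status
variable is among the columns). It is oriented when the count of
countries orienting it one way exceeds the opposite count by at least
`orientation_margin` (same defaults; countries with the edge undirected
count to neither side). The sign class is positive/negative only when
every including country agrees; a single disagreeing — or, by default,
indeterminate — country makes it mixed (`ignore_indeterminate=True`
drops indeterminate countries from the vote instead). The two thresholds
are independent settings even though the standard profiles use the same
number for both.

## Synthetic data

`reference_network` is the reference generator: a 12-node DAG (13 with
an HIV-status node) over the codebook's variables with two hub nodes —
rural residence and literacy, each of degree 6 — and logistic CPTs in
which every parent contributes ±`effect_strength` (default 1.5) on the
log-odds scale, centred so each node stays near a realistic prevalence.
The `seed` jitters base prevalences by ±0.3 logits, giving
country-specific CPTs on a shared topology. Effect 0 produces mutual
independence. Records are drawn ancestrally in topological order — exact
for a dozen binaries. Default weights are lognormal(σ = 0.5) normalized
to mean 1, mimicking heterogeneous design weights without claiming
realism; weights never alter the record-generating law.

Two faithfulness guards are deliberate (see the comment in
`synthetic.py`): adjacent parents sharing a child act on it with the
same sign, and the nonadjacent co-parent pair has a consistent
effect-sign product across its shared children. Without them,
explaining-away terms cancel direct effects nearly exactly and the
corresponding edges become undetectable at any sample size — a useful
reminder that near-unfaithful parameterizations are easy to construct.

What the synthetic experiments do **not** show: performance under survey
design features the generator omits (household clustering, informative
missingness, measurement error), behaviour when the true structure
violates faithfulness or contains unmeasured confounders, and anything
about effect sizes weaker than the generator's. Passing tests certify
the machinery and its statistical calibration, not the substantive
correctness of any real-data analysis.

## Problem sizes in the checks

The acceptance-style checks run at: 200 random DAGs for oracle
equivalence; 5000 CI-test replicates per conditioning-set size for
calibration; 20 studies of n = 5000 with 200 bootstrap replicates for
consensus recovery; and an 8-country × 2-sex study (n = 3000 per
stratum, 100 replicates) for the end-to-end metrics in
`scripts/acceptance.py`. The bootstrap default of 10,000 replicates is
used when the pipeline is run for analysis, not in the checks.

## Known limitations

* Only binary variables; multi-category handling is a codebook
  non-goal.
* No latent-variable or selection-bias modelling; the no-unmeasured-
  confounders assumption is untestable from the data.
* The country-count rules of the summary are procedural, not
  inferential: no p-values attach to summary edges.
* The dense joint-table fast path covers up to 16 variables; beyond
  that the learner falls back to per-test row scans.
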