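# Methods

## The procedure

`regenpath` implements a two-stage "reverse" pathway analysis for the
five-group neonatal infarction design (CTL-P1, CTL-P7, CTL-P28, MI-P7,
MI-P28; MI is induced at P1, so there is no MI-P1 expression group).  Genes
are first classified by explicit filtering rules applied to normalized
count summaries; pathway-level conclusions are then drawn by graph
traversal over curated pathway topologies rather than by enrichment
statistics.  The method's premise is that a pathway drives a phenotype only
when signal can flow from its initiating master regulators to its terminal
effectors, so the unit of evidence is a complete upregulated chain, not a
gene-set overlap score.

## Normalization and summaries

Size factors are the median-of-ratios estimator: for sample *j*, the median
over reference genes *g* of `count(g, j) / geomean_samples(count(g, ·))`,
with the reference set restricted to genes detected (count > 0) in every
sample.  The factors are rescaled to geometric mean 1, which removes the
overall scale indeterminacy and makes small worked examples exact.  An
empty reference set (no universally detected gene) is an error rather than
a silent fallback.

One consequence of any global rescaling convention is that multiplying one
sample's counts by *c* changes all normalized values by the common constant
c^(1/n) while raising that sample's factor *c*-fold relative to the others;
every ratio-based quantity — group-mean ratios, fold changes, error-bar
comparisons, and hence all classifications — is invariant, and the tests
assert exactly that form of the invariance.

Group summaries are arithmetic means of normalized counts with SEM
(sample SD / √n) as the error-bar half-width.  The source figures do not
define their error bars; SEM is the default convention for
biological-replicate bar charts and makes the "strictly higher error bars"
criterion testable.  Single-replicate groups get SEM 0, under which the
strict-separation rule degenerates to a strict mean inequality (the design
has three replicates; the code must not crash on fewer).

Fold changes are pseudocount-adjusted, `(mean_MI + c) / (mean_CTL + c)`
with c = 0.5 by default, keeping ratios finite for genes silent in
controls.  The boundary is inclusive: a pseudocount-adjusted ratio of
exactly 2.0 passes the two-fold rule.

## Gene classification rules

With defaults (`ClassifierConfig`):

* **abundance** — ≥ 200 raw counts summed over *all* samples, boundary
  inclusive; applied to early, late and down calls alike.
* **early_up (P7)** — abundance, fold ≥ 2, strict error-bar separation
  (`mean_MI − SEM_MI > mean_CTL + SEM_CTL`), and control non-increase
  (`mean_CTL_P7 ≤ mean_CTL_P1`, zero tolerance; a config knob could relax
  it but none of the shipped analyses do).
* **late_up (P28)** — abundance and fold ≥ 2 only.  The source criteria
  can be read as nesting late within early; the figures nevertheless mark
  late-only genes, so early and late are classified independently by
  default and `late_requires_early=True` restores the nested reading.  An
  optional strict mode adds P28 bar separation.
* **late_down (P28)** — the mirrored rule, `mean_CTL ≥ 2 × mean_MI`
  (pseudocount-adjusted).  No downregulation criterion is stated in the
  source; the symmetric rule is this package's choice.
* **persistent** — early_up and late_up.

Genes with a missing required group get the dependent flags false and the
group recorded as insufficient data; all-zero genes classify as all-false
without special-casing.

## Concordance p-values

For two replicate groups, direction is concordant when `min(A) > max(B)`
(or symmetrically); any cross-group tie makes the configuration mixed
rather than raising.  Two p-values are attached:

* `p_paper = 0.5^(n_a · n_b)` when concordant — the probability of the
  observed complete ordering if each pairwise comparison were an
  independent fair coin.  For 3 vs 3 this is 0.5⁹ ≈ 0.00195, printed as
  0.002.  The nine pairwise events are *not* independent, so this
  understates the exchangeability-exact probability; it is retained as the
  primary statistic because it is the one the filtering procedure this
  package reproduces actually uses.
* `p_rank` — the exact one-sided probability, under exchangeability of the
  pooled sample, of a split at least as extreme, by enumeration of all
  `C(n_a + n_b, n_a)` rank assignments (Mann-Whitney U with ties counting
  ½).  For a concordant 3-vs-3 split, 1/20 = 0.05 — 25× larger than
  `p_paper`, a discrepancy the tests assert rather than hide.

No general-case approximation is attempted for non-concordant inputs
(`p_paper` is simply not applicable there): the source's reference for
"other cases" is not interpretable, and guessing a method would
misrepresent it.  Human-readable output rounds to three decimals; machine
output keeps full precision.

## Pathway model and chain calls

Pathway graphs are small curated digraphs in a JSON dialect: nodes with a
role (initiator / intermediate / effector) and a non-empty gene-family
member list (OR semantics), directed edges, and named subpathways.  The
packaged fixtures for MAPK, Hippo, cAMP, JAK-STAT and Ras encode the
chains exactly as enumerated in the source narrative — not re-derived from
KEGG, whose full topologies differ and include nodes never analyzed.
Slash-named families ("SOS1/2", "CCND1/2/3") are expanded via a checked-in
table (`data/symbol_expansions.json`), which also records normalized
spellings (the gamma PKC isoform as PRKCG; "NKF1B" taken as NFKB1).  The
20-entry catalog follows the enumerated candidate list; the source counts
candidates variously as 11 or 20, a discrepancy recorded in the catalog's
metadata rather than resolved.  Catalog entries without a detailed graph
are reported as "not called", never "not upregulated".

A pathway is **comprehensively upregulated** iff at least one complete
initiator→effector chain consists of satisfied nodes, where a node is
satisfied when any member gene is upregulated at P7 and/or P28 ("any"
mode).  The one-complete-chain reading is interpretive but forced by the
data it reproduces: Hippo is called comprehensive although its core-kinase
chain ends at an unchanged YAP1/WWTR1 node, because the parallel TGFB-SMAD
branch is fully upregulated — an all-nodes reading would contradict that
call.  Downregulated nodes (CREB in the cAMP fixture) are annotated but
never satisfy nor break a chain.  Satisfied chains are simple paths
(cycles therefore terminate), listed in lexicographic node-id order with a
configurable cap (default 100) for reproducible output.  Persistence flags
report whether every initiator (resp. effector) on at least one satisfied
chain is also satisfied in late mode, matching the focus on initial and
terminal components that stay elevated at P28.

The packaged worked example (`data/worked_example_statuses.json`)
transcribes the published early/late/down gene calls; feeding it to the
caller yields 5 comprehensive of 20 catalog entries.

## Synthetic data

Counts are negative-binomial with mean μ and size *k* (variance
μ + μ²/k), the standard overdispersed RNA-seq model; defaults are
per-gene log-normal baselines with location 5.5 and scale 1.0 on the log
scale (median ≈ 245 counts), size 10, three replicates per group, and
per-sample library-size multipliers drawn log-uniformly from [0.5, 2] so
that normalization is genuinely exercised (switchable off, and always off
in noise-free mode).

Planted positive genes get a declining control profile (CTL-P1 = 2× the
P7/P28 baseline) — the early-postnatal developmental decline the control
non-increase rule expects — and an MI effect of fold 4 by default at P7
(and P28 when persistent).  Each decoy kind violates exactly one criterion
in expectation: `low_abundance` uses baseline 3 (expected total ≈ 80 raw
counts, far under the 200 floor) with an otherwise valid 4-fold effect;
`overlapping_bars` keeps the 4-fold effect but inflates dispersion
(size 0.3) so SEM intervals overlap with high probability;
`control_drift` doubles control expression from P1 to P7 under a robust
8-fold MI-P7 mean; `subthreshold_fold` uses fold 1.5.  Decoys other than
the drift kind share the declining control profile so the control rule is
not a second, accidental point of failure.

Ground truth is mode-dependent.  In stochastic mode, truth is the
*intended* construction (planted ⇒ early; decoy/background ⇒ not), and
tests assert aggregate sensitivity and specificity rather than per-gene
equality, since sampling noise makes per-gene truth probabilistic.  In
noise-free mode (counts = rounded exact means, multipliers off), truth is
computed by applying the filtering rules in closed form to the emitted
values, and recovery must be exact — the pipeline's end-to-end smoke test.
Pathway-scenario truth is always computed from the fixture topology: the
expected call is reachability over nodes with at least one planted member,
so a broken node yields whatever the remaining topology implies.

Scenario planting walks the lexicographically first initiator→effector
chain (or the first chain through the break node), planting the first
member of each node not already planted by an earlier scenario; all five
fixtures can therefore be planted together without duplicating shared
genes such as CSF1.

What the generator does *not* emulate: batch effects beyond library size,
gene-gene correlation, length/GC biases, isoform structure, or the shape
of real count distributions beyond NB(mean, size).  Passing recovery tests
shows the pipeline implements its stated rules and that those rules
separate the planted signal classes at the simulated noise level — not
that the rules are biologically optimal, nor how they behave under
violations the generator does not model.

## Problem sizes and tolerances

The shipped analyses use: rank enumeration up to pooled size 20 (tests
verify against the closed form up to 12); noise-free end-to-end runs at
300 genes; stochastic recovery at 1000 genes × 20 seeds in the test suite
(pooled sensitivity/specificity threshold 0.95, fixed from a pilot run of
the generator before being frozen into the test) and 10 seeds in the
acceptance script; empirical mean calibration at 200 replicates within 5%.
Floating-point comparisons in scale-invariance tests use relative
tolerance 1e-9.  Strict inequalities (error-bar separation, concordance)
are exact comparisons on float64 values; ties break conservatively
(separation fails, direction becomes mixed).

## Known limitations

* The pipeline starts at the count matrix; read QC, alignment and counting
  are out of scope, as is the negative-binomial GLM itself (only the
  median-of-ratios normalization and fold-change summaries are used).
* The five pathway fixtures are transcriptions of a published narrative,
  not a general KEGG importer; topology edits require editing JSON.
* `p_paper` is reported for fidelity even though it is anti-conservative
  relative to the exchangeability-exact `p_rank`; users testing ordering
  significance should prefer `p_rank`.
* No multiple-testing correction is applied to per-gene statistics,
  mirroring the procedure implemented.
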