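# Methods

`tepop` analyses two kinds of evidence about transposable-element (TE)
activity in structured plant populations: binary insertion-site matrices
from transposon display (TD), and real-time qPCR threshold cycles used for
relative and absolute copy-number estimation. This note records the models,
the numerical conventions, and the limits of what the synthetic tests
establish.

## Marker matrices

A TD gel band corresponds to one insertion locus; each accession is scored
1 (full site) or 0 (empty site). The format deliberately has no missing
value: the assay cannot distinguish "band absent" from "lane failed", so a
hard call must be made upstream. A full matrix must show every locus in at
least one accession (an unobserved band cannot be scored); row subsets are
explicit *views* that relax this invariant, because a band can legitimately
vanish within one population.

Per-population site codes for a locus are 0 (no carrier), 1 (some
carriers), 2 (all carriers). Locus classes are disjoint with precedence
unique > specific > polymorphic > monomorphic:

* **population-unique** — carriers in exactly one population;
* **population-specific** — at least one population with no carrier and at
  least two populations with carriers (the unique class is excluded so the
  two tallies can be reported side by side);
* **polymorphic** — absent somewhere, but from no whole population;
* **monomorphic** — carried by every accession.

Polymorphism level for a family is `100 * polymorphic / total`. Within a
population, `total` counts only bands observed in that population and
`polymorphic` those additionally absent in at least one of its accessions;
this is forced by survey tables in which per-population totals fall below
the pooled total. The pooled ("overall") level uses all accessions
together, not an average of per-population levels. Percentages are
presented to one decimal, rounding half away from zero. A single-accession
population has level 0 by construction — nothing can be absent in at least
one accession of it.

## Resemblance, clustering, SIMPROF

Similarity between accessions is Bray-Curtis on a 0–100 scale, computed via
`scipy.spatial.distance.pdist`; on binary data it reduces to the Sørensen
coefficient `100 * 2a / (2a + b + c)` (a = shared presences, b, c = private
presences), and the test suite verifies that identity exhaustively for up
to 10 loci. A pair of all-empty profiles has no defined similarity and is
rejected.

Clustering is group-average (UPGMA) agglomeration on similarities,
maintained exactly through the size-weighted update. The linkage is not
dictated by the data source, so the package fixes it to the common default
for resemblance dendrograms. Ties are broken toward the pair whose sorted
member-index tuples compare lexicographically smallest; this makes output
deterministic and is part of the contract (a brute-force oracle in the
tests re-derives every merge from the original matrix).

SIMPROF asks whether a group of samples contains multivariate structure
beyond exchangeability. The observed profile is the sorted list of within-
group pairwise similarities. Permutations shuffle each locus independently
across the group's samples — loci are never permuted against each other —
and the expected profile is the rank-wise mean over `n_perm_mean = 999`
permutations. The statistic is `pi = sum_ranks |observed − expected|`; 999
fresh permutations give null deviations against the same expected profile,
and the p-value uses the add-one estimator `(1 + #{null >= pi}) / (1 +
999)`, so it is never 0 and at 999 permutations never below 0.001.
Defaults follow the long-standing convention of the resemblance-analysis
software family; the counts are configurable.

Two numerical conventions: (i) inside permutations a pair whose combined
presence count is zero is assigned similarity 0 (the observed data is
screened beforehand); (ii) ties between null deviations and the observed pi
are counted in favour of the null (conservative). Groups of one or two
samples are untestable — one similarity is not a profile — and are treated
as non-significant.

The tree traversal is top-down: the root is tested first; a significant
node (p < alpha, default 0.05) is opened and its children tested; a
non-significant node closes its whole subtree untested. This reproduces the
black/red line semantics of significance-annotated dendrograms, and the
pruned subtrees induce the partition used for structure-recovery checks.
Every node's rows are canonicalized by sample id and its RNG is keyed on
(seed, member ids), so results are independent of input row order and of
traversal order; identical seeds give bit-identical trees.

Newick export encodes depth as `(100 − merge similarity)/100` and carries
`[&pi=..,p=..,significant=..]` comments on internal nodes; standard parsers
read the topology and ignore the comments.

## qPCR quantification

The comparative Ct method: `ddCt = (Ct_target − Ct_ref-gene)_sample −
(Ct_target − Ct_ref-gene)_reference-sample`, on triplicate-mean Cts, and
`RQ = (2E)^(−ddCt)` with efficiency E as a fraction of 1. The `2E` base is
taken literally as the default (at E = 1 it is the familiar `2^(−ddCt)`);
the conventional `(1 + E)` base is available as `mode="conventional"`. The
two coincide only at 100% efficiency, which is also the default when no
standard curve is supplied. Efficiency from a standard-curve slope is
`E = 10^(−1/slope) − 1`; values outside [0.8, 1.1] are flagged. Replicate
Ct spread above 0.5 cycles triggers a QC warning (a lab convention, not a
hard rule).

Absolute copy numbers calibrate RQ against a genome with a known per-family
count. RQ measures target per reference-gene (VRN1) copy, so each genome's
total is RQ × its VRN1 dose — 2 in a tetraploid sample, 3 in the hexaploid
calibrator:

    cn = (RQ_sample × 2) / (RQ_calibrator × 3) × cn_calibrator

The direction of this ploidy normalization is genuinely underdetermined by
its verbal description; it is isolated in `absolute_copy_number` with the
dose arguments explicit, so the alternative reading is a one-line change.
The hexaploid self-calibration identity `cn(r, r, c, 3, 3) = c` holds by
construction.

## Population comparison

One-way fixed-effects ANOVA (sums of squares computed here, p from the F
distribution), gated post hoc: only when ANOVA is significant at alpha =
0.05 are all-pairs comparisons run, using the Tukey-Kramer harmonic form
`q = |m_i − m_j| / sqrt(MSW/2 (1/n_i + 1/n_j))` with p from scipy's
studentized-range distribution. The compact letter display uses
insert-and-absorb: one all-inclusive letter column is split on every
significant pair and subset columns are absorbed; the resulting columns are
exactly the maximal cliques of the non-significance graph (verified by
enumeration for up to five groups), so sharing a letter is equivalent to
pairwise non-significance. Letters are assigned in descending order of
group means. Comparisons default to the raw RQ/copy-number scale; a log
transform is the caller's choice upstream.

## Synthetic data

The generator emulates the design of a five-population, ten-accessions-each
TD and qPCR survey of six MITE families with 70–116 loci per family. Three
locus strata per family reproduce the three phenomena the analysis targets:
near-fixed ancestral insertions (presence probability 0.998 everywhere) set
the monomorphic fraction; shared loci drift per population via
`q ~ Beta(kappa p0, kappa (1 − p0))` around an ancestral `p0 = 0.5`
(default concentration kappa = 5; small kappa = strong differentiation);
private loci exist only in their owning population (presence 0.8),
yielding population-unique insertions. Default stratum sizes were derived
once from the target survey's per-family band arithmetic (total and
polymorphic counts) and are not tuned against test outcomes; with them the
default 557-locus matrix lands within a few percent of the target's
per-family polymorphism levels and its ~7% unique fraction. Loci observed
nowhere are dropped. Excision and non-inheritance are not distinguished —
the assay cannot tell them apart either.

The Ct model writes the reference gene at `Normal(20, sigma)` cycles and
each target at `20 − log_base(cn / cn_reference-sample)` plus noise, base
`2 × efficiency`, three replicates per reaction, default `sigma = 0.1`
cycles. At `sigma = 0` the ddCt pipeline inverts the generator exactly.
True copy numbers are constant within a (family, population) cell; real
accessions vary within populations, so the generator understates biological
dispersion and a green comparison test shows estimator correctness, not
field realism. Likewise the marker model draws loci independently — no
linkage, no gel co-migration artefacts — so clustering recovery results
certify the algorithmic chain, not robustness to correlated noise.

A known calibration limit, measured rather than hidden: with per-replicate
Ct noise sigma = 0.1, sd(ddCt) = 2 sigma / sqrt(3) ≈ 0.115 cycles, so the
probability that an accession's RQ falls within 10% of its true ratio is
about 0.79 (and the reference-sample terms shift whole runs coherently).
The recovery test that demands 90% of accessions within 10% at this noise
level therefore fails by design of the stated noise model; reaching 90%
would need sigma ≈ 0.07 or more replicates. The test is kept at its stated
threshold rather than loosened.

## Known limitations

* SIMPROF p-values are permutation-count limited (min 1/1000 at defaults).
* The UPGMA tie-break is index-based; relabeling samples can change the
  topology of exactly-tied merges (heights and tested p-values are
  unaffected for tie-free inputs).
* Per-population polymorphism levels in the synthetic default are more
  homogeneous across populations than real surveys, where collection-site
  history drives larger spreads.
* The CLI's `all` chain clusters a single family by default; per-family
  trees are one `--family` flag each.
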