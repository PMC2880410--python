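# Methods

## The grammar model

A promoter window of fixed length 601 nt (the [-500, +100] window around
a TSS) is reduced to the ordered chain of motif occurrences found by PWM
scanning. Chain position 1 is the hit whose **end coordinate** lies
nearest the window's downstream (right) end; indices increase moving
upstream. Measuring from the end rather than the start keeps the
ordering consistent across motif widths. Overlapping hits are first
resolved to one hit per locus — highest score wins, ties broken by
earlier start, then lexicographic motif id — and the chain is truncated
at 8 positions (configurable), keeping the 8 nearest the TSS.

Each position contributes a motif identity M_i and strand S_i; each
adjacent pair contributes L_(i+1)_i, the nt gap between the upstream
motif's end and the downstream motif's start, clamped at 0 and
discretized into bins [0,20), [20,50), [50,100), [100,200), [200,inf).
The bins are configurable; the default keeps conditional probability
tables small enough to estimate from ~136 training rows. Windows whose
resolved chain holds fewer than 3 motifs are not admitted to training or
classification.

## Network, EM, and missing data

The classifier is a fixed-structure tree-augmented naive Bayes network:
a two-state Class node parents all 23 feature nodes (8 M + 8 S + 7 L at
8 positions); augmenting edges add M_i -> M_(i+1) (a site depends on the
preceding site), M_i -> S_i, and M_(i+1) -> L_(i+1)_i. Each feature node
has at most one augmenting parent, so given the class the feature graph
is a chain of M nodes with S/L leaves.

The spacer's augmenting parent could equally be M_i; the outer motif
M_(i+1) is the default because the spacer is realized when that motif is
placed, and a switch (`l_parent_outer=False`) selects the inner one.

MISSING slots are **latent**: they are marginalized both in fitting and
in scoring, never treated as an observed "absent" state (a switch,
`missing_as_state=True`, provides the alternative, which makes fitting a
single closed-form pass at the cost of letting chain length itself carry
class information). Because the per-class graph is a tree, the E-step is
exact: a scaled forward-backward pass over the M chain with evidence
from the observed S/L leaves folded into the node potentials, vectorized
over all rows sharing a missingness pattern. A fully unobserved subtree
marginalizes to exactly 1, so tails of short chains cost nothing.

The M-step applies symmetric-Dirichlet smoothing with concentration
alpha = 1 per state: theta = (count + alpha) / (total + alpha * K). This
is the posterior-mean (Laplace) update; the objective it monotonically
improves is the observed-data log-likelihood plus alpha * sum(log theta)
over all table entries — a Dirichlet(alpha + 1) log-posterior up to an
additive constant — and the implementation's convergence criterion is
the improvement of exactly that objective (tolerance 1e-6, cap 100
iterations). On complete data the first iteration already lands on the
closed-form smoothed frequencies. EM is initialized from observed-data
smoothed counts, so fitting is deterministic; the `seed` argument exists
only for interface symmetry.

Posteriors are computed in log space; P(histone|v) + P(background|v) = 1
by construction, an all-MISSING vector scores at the class prior, and a
posterior exactly at the cutoff is conservatively called background.

## PWM scoring and the anchored scan

Window scores are min-max-normalized additive log-odds against a uniform
background: s = (S - S_min) / (S_max - S_min) with S the sum of
log(freq/0.25) after pseudocount regularization p' = (p + c)/(1 + 4c),
c = 0.01. The consensus scores 1.0, the per-position-worst window 0.0,
and an N base contributes its position's minimum. Normalized scores make
cutoffs comparable across motifs; `calibrate_threshold` implements the
90%-recall rule (the largest threshold keeping at least 90% of known
sites) when curated site lists exist.

The genome scan anchors on one designated PWM (the CAAT-box role, which
in histone promoters sits ~75 nt upstream of the TSS). For a plus-strand
anchor hit starting at p the extracted segment is the inclusive window
[p - 425, p + 175] — 601 nt, so that an anchor at -75 reproduces the
[-500, +100] training geometry exactly. Minus-strand anchors get the
mirrored window [p - 175, p + 425] with the sequence
reverse-complemented, making the grammar strand-agnostic. Windows
crossing a chromosome end are dropped (not truncated), as are segments
whose GC fraction is not strictly above 0.37 (N bases excluded from both
numerator and denominator). Segments are scanned with the full PWM set
on both strands, admitted at >= 3 chain motifs, and classified in
batches; chromosomes stream one at a time so memory stays bounded.

Histone-called segments overlapping by >= 1 nt on a chromosome merge
into single-linkage clusters (strand-agnostic, spans unioned).
Annotation categories follow a precedence that makes the accounting
mutually exclusive: overlap_TSS (the segment contains a gene's TSS on
the same strand) beats within_transcript (any-strand intersection with a
transcript span) beats intergenic; intergenic predictions carry the
unsigned distance from segment edge to the nearest transcript edge (0 if
touching, NA on gene-free chromosomes). Strand is deliberately only
enforced for the TSS category, matching how intronic hits are usually
reported without a strand condition.

## Coexpression validation

Preprocessing follows the exact order: average technical replicates per
tissue on the raw scale, log2 (values below 1 clipped to 1 — the
microarray convention for "log-transformed" when the floor is unstated),
subtract each array's median, scale each array to unit sum of squares.
All-constant arrays become zero vectors and are flagged rather than
divided by zero.

maxCC is the maximum centered (standard mean-subtracted) Pearson
correlation of a probe's tissue profile against a reference block,
self-comparisons excluded; zero-variance profiles give NA. Group
comparison uses Welch's t with the sign convention
t = (mean_other - mean_predicted)/SE, so a more-coexpressed predicted
group yields negative t; 95% CIs are normal-approximation. The empirical
null draws `n_groups` groups of `group_size` probes without replacement,
treats one as the test probe and the rest as the reference block, and
records its maxCC; p-values use the add-one estimator
(1 + #{bg >= x}) / (1 + |bg|), so they are never exactly 0, and are
FDR-controlled by Benjamini-Hochberg step-up (statsmodels' fdr_bh).

In the assembled `coexpression_analysis` the null groups are drawn from
the same non-histone population the p-values are assigned to, rather
than from all probes: with the synthetic generator's block fractions
(~13% of probes correlated, versus ~4% on a real chip), a null
contaminated by the reference block itself has so heavy a tail that no
probe can reach the BH threshold, while a population-matched null is the
statistically cleaner comparison. The standalone `empirical_null` takes
a `probes=` argument, so chip-style sampling over everything remains one
call away. Enrichment of the FDR passers in the predicted set is an
upper-tail hypergeometric test via log-gamma arithmetic (exact at
p ~ 1e-55 and far below), Bonferroni-corrected by the population size.

## Synthetic data: what it emulates, what it does not

Generators are pure functions of (parameters, seed). Training sequences
are i.i.d. background at a configurable GC fraction (default 0.45,
comfortably above the 37% filter for 601-nt windows) with the grammar
chain written in: position-1 motif at `anchor_offset` from the right end
(default 175, i.e. the anchor at -75 of a [-500, +100] window), then
upstream motifs at sampled gaps, per-slot strand probabilities, optional
per-slot dropout (`insertion_noise`), and planted instances that are
consensus strings by default (`motif_fidelity=1.0`) so "noiseless"
grammars are recovered deterministically. Toy genomes plant whole
promoter windows (reverse-complemented on minus strands) at
non-overlapping positions and give a configurable fraction of them a
downstream gene whose TSS sits at the window's TSS-equivalent position;
the rest stay intergenic.

Expression matrices are latent-factor Gaussian: one standard-normal
tissue profile z drives the histone block (loading sqrt(rho_histone), so
within-block correlation is rho_histone) and the predicted block
(loading rho_predicted); background probes are independent. Per-probe
baseline offsets and technical replicate noise are both scaled by
`noise_sd` (default 0.1, chosen so that the realized mean within-histone
correlation measured on replicate-averaged log2 data sits within 0.05 of
the target at 79 tissues; the later per-array median-centering and
normalization attenuate it a further ~0.05 because an unrealistically
large share of the synthetic population is correlated). In the
`noise_sd = 0, rho_histone = 1` limit block members are exactly
identical, so their pairwise correlations survive any column-wise
transformation at exactly 1.

The generators do **not** imitate real promoter base composition, CpG
islands, curated PWM content, chip normalization pipelines, or
probe-to-gene mapping. Passing tests therefore demonstrate that the
algorithms are correct and that the pipeline detects the structures it
is told to detect under controlled conditions — not that any particular
biological discovery would replicate.

`generate_rotating_grammar_set` deserves a note: positives whose chain
starts at a random point of a fixed motif cycle, with the spacer ahead
of each motif a deterministic function of that motif. Slot marginals are
then uniform — useless to a naive Bayes model — while adjacent-pair
statistics are sharp, which is the regime where the augmenting edges
demonstrably help. With a single deterministic chain, by contrast, slot
marginals carry the whole signal and naive Bayes matches or beats the
augmented structure, which pays a variance price for its extra
parameters on small tables.

## Numerical and design choices

* Chain inference runs in linear space with per-step rescaling; class
  posteriors combine log-likelihoods with `logaddexp`.
* All CPT entries are strictly positive by construction (alpha > 0), so
  no zero-probability guards are needed downstream.
* Confusion-matrix ratios with zero denominators are reported as NA,
  never 0; reported percentages round to one decimal; the spread across
  background sets is the sample standard deviation.
* LOOCV classifies at a fixed 0.5 posterior cutoff but emits the full
  posterior column so other operating points can be analyzed.
* Problem sizes in the test and acceptance runs — 8 toy PWMs, 68 + 68
  training sequences, 3 x 100 kb genomes with 20 planted promoters,
  2,293-probe expression matrices, 10,000 null groups — are desk-scale
  stand-ins chosen to exercise every code path with stable statistics;
  the streaming scan design keeps real chromosome-scale inputs feasible.

## Known limitations

* The chain model has no alignment latent variable: spurious hits
  downstream of the anchor shift every position index, which smears the
  learned grammar in hit-dense regimes. Real workflows mitigate this
  with curated PWMs and calibrated cutoffs.
* Parameter recovery of augmented CPTs from small samples is limited by
  multinomial noise (each parent-conditional row sees only a fraction of
  the data); at 2,000 rows the naive parameterization recovers entries
  to 0.05 absolute, the augmented one to about 0.1.
* The minus-strand anchored window is mirrored around the hit start, so
  a minus-strand planted segment is recovered shifted by up to W-1 nt;
  features are position-free, so classification is unaffected, and
  recovery is assessed by interval overlap.
* Empirical-null p-values are bounded below by 1/(n_groups + 1); with
  10,000 groups the smallest achievable BH threshold limits detection to
  roughly the top 5% of a 2,200-probe population.
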