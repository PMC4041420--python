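# Methods

This note documents the models behind `trnadyn`, the choices made where the
design was genuinely open, and what the synthetic data do and do not
establish.

## Genetic code and wobble rules

Codons and anticodons are handled in the RNA alphabet, anticodons written
5′→3′ so the wobble base N34 is the first letter and pairs codon position 3.
The sense-codon table is the standard bacterial code; the three anticodons
whose reverse complement is a stop codon (UUA, CUA, UCA) are rejected,
leaving 61 valid species. The default rule set encodes the commonly
occurring bacterial interactions: G34 reads C (Watson–Crick) and U (wobble);
C34 reads only G; U34 reads A (Watson–Crick) and G (modification-dependent
wobble), plus U and C by superwobbling; A34 is treated as inosine-modified
and reads U, C and A. Superwobble edges count only inside four-codon family
boxes by default, because the broad U34 specificity is tolerable only where
all four codons are synonymous. A decoded codon must translate to the same
amino acid as the species' cognate codon; mis-reading is never counted as
decoding.

Classification: all U34 species are mandatory except U34A35U36-Ile
(special — in nature a modified C34A35U36 does this job) and U34C35G36-Arg;
G34 species are mandatory in 2-/3-fold boxes and auxiliary in family boxes;
C34A35U36-Met and C34C35A36-Trp are sole decoders and mandatory, the
remaining C34 species auxiliary; A34 species are avoided except
A34C35G36-Arg. The Arg N34-C35-G36 quartet is a context-dependent special
case: since inosine does not read the G-ending codon, ACG is classified
mandatory here and the four box members carry an `arg_box` flag. The
resulting partition of 61 species is 23 mandatory / 22 auxiliary /
15 avoided / 1 special, with exactly two single-codon mandatory species
(Met, Trp).

Limitation: decoding-completeness reports treat the A-ending Ile codon like
any other, so repertoires lacking U34A35U36 are flagged even though real
bacteria decode that codon with a modified C34A35U36 that is out of scope.

## Codon-bias statistics

ENC uses Wright's estimator: per synonymous family of size m with n codons,
the homozygosity F = (nΣp̂ᵢ² − 1)/(n − 1); class means F̄ₘ over families of
equal size enter ENC = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆, clamped at 61.
Families with n < 2 or non-positive F are excluded from their class mean; a
missing F̄₃ (Ile is its only member) is imputed as (F̄₂ + F̄₄)/2 when both
neighbours exist, and any other missing class mean as the average of the
observed class means.

ENC′ replaces F by the chi-square homozygosity
F = (X² + n − m)/(m(n − 1)) with X² = nΣ(p̂ᵢ − eᵢ)²/eᵢ, where the expected
within-family frequencies eᵢ are proportional to the product of the gene's
background nucleotide frequencies over the codon's positions, normalized
within the family. For 2- and 4-fold families this reduces exactly to
third-position background; for the 6-fold families (Leu, Ser, Arg) it
weights the 2-fold and 4-fold subfamilies by the background composition of
their differing positions as well — the standard subfamily treatment
expressed in one rule. When usage equals expectation X² = 0 and the clamped
value is exactly 61; at maximal bias with uniform background the statistic
coincides with plain ENC (verified algebraically and by test). Background
composition is taken from the same gene throughout.

ENC′_diff = (mean ENC′ of all genes − mean ENC′ of ribosomal genes) / mean
of all genes. Traits are z-normalized with the sample (n − 1) standard
deviation so regression coefficients are effect sizes.

Other conventions: percentiles use the nearest-rank (ceil(p·n)-th order
statistic) rule; the Mann–Whitney test is two-sided, exact when the smaller
group has ≤ 8 observations and tie-corrected normal otherwise; Hamming
clustering uses average linkage on profile-difference counts, with organisms
displayed in GC order.

## Phylogenetic regression

The response (including a 0/1 presence profile, treated as continuous — the
classical approach this pipeline follows, not a logistic model) is
multivariate normal with mean Xβ and covariance σ²·V(λ), where V is the
Brownian tree covariance (entries = shared root-to-MRCA path length) and λ
multiplies the off-diagonal entries. At fixed λ, β and σ² have GLS closed
forms; λ is profiled on [0, 1] over a 21-point grid followed by bounded
scalar refinement between the best grid knots. The dense grid matters: with
a coarse grid the full model of a nested pair can occasionally land in a
worse λ-basin than the restricted model, producing a negative likelihood
ratio (treated as an optimization failure and raised). On ultrametric trees
V(λ) shares V's eigenvectors, so the workspace eigendecomposes once and
each λ evaluation costs O(np); non-ultrametric trees fall back to a Cholesky
per evaluation.

Standard errors use σ̂² = RSS_GLS/(n − p) with t-based intervals; R² is the
squared Pearson correlation between GLS-fitted and observed values (a
reporting convention, chosen because alternatives disagree for GLS).
Likelihood-ratio tests compare 2ΔlnL to χ² with df = difference in free
mean parameters (1 throughout the screen). The association screen fits, per
sufficiently variable species (≥ 4 organisms discordant from the majority),
the intercept-only model, each single trait and each trait pair; a trait is
called significant-and-independent when adding it over each other single
trait survives one Benjamini–Hochberg correction pooled over *all* tests of
the screen at level q. Polytomies are resolved with zero-length branches;
constant responses are rejected.

## Gain/loss reconstruction

Each species evolves independently under a two-state chain with gain rate g
(0→1) and loss rate l (1→0) per unit branch length; the root prior defaults
to the stationary distribution l/(g+l), g/(g+l) (a uniform prior is a flag);
optional K = 4 discrete-gamma branch-rate multipliers (mean-normalized) can
be layered on. The likelihood is computed by pruning with per-node scaling;
rates are fitted by bounded L-BFGS-B over (log g, log l) from two starts;
constant columns are flagged and skipped. Node posteriors come from the
standard inside–outside pass and reproduce tip observations exactly.

Branch event probabilities are defined as P(≥ 1 gain) and P(≥ 1 loss) on the
branch — probabilities of at least one event, not expected counts (the
expectation variant would be a small extension). The default estimator is
stochastic mapping: joint ancestral states are sampled top-down from the
conditioned chain, then endpoint-conditioned paths on each branch are drawn
by uniformization (Poisson number of candidate jumps given the endpoints,
then a discrete bridge over the jump chain), with 1000 maps and seed 17 by
default. For the two-state chain the quantity also has a closed form —
P(no gain | endpoints) follows from an absorbing-state argument — and
`branch_event_probs_exact` combines it with the joint endpoint posteriors.
The closed form serves as the independent oracle for the Monte-Carlo
estimator in the tests and is available as `method="exact"`.

Events are called where the branch probability is ≥ 0.8 (inclusive) and are
attributed to the branch's child node. A known identifiability limit of this
model class: when a history is loss-only from a present ancestor, the
stationary root prior couples the root state to the rate estimates, and for
species whose gains left only one or two extant descendants the ML loss rate
can inflate, diluting gain posteriors across the root path. Interpretation
of per-branch calls for such species should be cautious; the synthetic
generator avoids placing recovery probes there.

## Co-event statistics

The permutation null reassigns each species' gain (loss) events to branches
uniformly at random without replacement, preserving per-species counts;
gains and losses are permuted independently; a branch-length-weighted
variant (Gumbel top-k sampling) is available and the scheme is recorded in
every result. The reported p-value is (1 + #{null ≥ observed})/(1 + N), so an
overlap never reached in 10⁴ permutations reports p < 10⁻⁴. Because the
co-event count is discrete, this estimator is super-uniform by construction;
each result therefore also carries `pvalue_randomized`, the tie-broken
probability integral transform, which is exactly uniform under the null and
is the quantity to use in calibration diagnostics (the conservative p-value
is the one to report). Under the uniform scheme the null overlap of two
species with k₁ and k₂ events on B branches is hypergeometric, which gives
the exact enumeration mode for small problems. Sequential order counts
(gain of X strictly ancestral to gain of Y) are descriptive only.

## Origin inference

An MRGE is a called gain with no further called gain of the same species
below it. Each gene descending from an MRGE is compared against the full
gene set by local alignment: match +1, mismatch −3, gap −5 for the first
position and −2 thereafter, both strands scanned. At typical tRNA length
(~76 nt) the inclusive 80%-of-self-score cutoff then tolerates 3 mismatches
(64 ≥ 60.8) but not 4 (60 < 60.8), and one or two short gaps — the intended
calibration of the rule. Raw scores are thresholded (not bit scores).
Per query, the best hit is kept in the vertical category (same anticodon,
same MRGE descent) and in the non-vertical category, ties broken by
lexicographic subject id. Non-vertical hits are classified: same anticodon →
horizontal transfer of the species; different anticodon in the same organism
→ duplication + anticodon mutation; different anticodon in a distant
organism (patristic distance above the 90th percentile of all tip pairs, a
stand-in for "different taxonomic family" when no taxonomy is supplied) →
transfer + mutation; otherwise ortholog mutation in close relatives.
Flanking-sequence identity can support duplication calls when flanks are
supplied; calls stand without it.

## The synthetic generator

The generator's job is to produce inputs with the statistical structure the
pipeline assumes, together with ground truth that is *identifiable* — a
recovery test against truth that no method could attribute at branch
resolution would measure nothing. Defaults (the study conditions of the
end-to-end tests): a 300-tip Yule tree scaled to unit root-to-tip depth; a
Brownian GC-like trait with variance 1 and λ = 1 (internal node values
retained); 12 tRNA species of which 4 are GC-coupled; per genome 30 coding
genes of 200 codons with 6 ribosomal genes whose within-family usage is
concentrated by a bias factor of 4 (composition-matched usage otherwise, so
ENC′_diff is positive by construction); 76-nt tRNA genes evolving with
per-site substitution rate 0.02 per unit depth, anticodon protected;
20% of operon annotations withheld. The master seed fans out to component
generators as `default_rng([seed, counter])`, making identical
configurations byte-identical.

Uncoupled species follow the homogeneous two-state chain with g = 0.12 and
l = 0.3 per unit depth — loss-dominated 3:1, about ten well-separated events
per species, the regime in which per-branch reconstruction is reliable.

GC-coupled species use the sharp-selection limit of a GC-coupled loss
process: present at the ancestor and lost, irreversibly, on the first branch
whose GC value crosses below a species-specific threshold. This is the
generator's rendering of the usage-shift phenomenon (species absent below a
characteristic GC, "once lost, not regained"). The exponential-link CTMC
coupling is also implemented (`simulate_presence` with `coupling`), but its
histories are not branch-identifiable: weak coupling gives no detectable
association, while strong coupling concentrates events along the GC isocline
where a homogeneous reconstruction either collapses parallel losses into
single ancestral events or mirror-codes whole regions (one deep loss plus
regains). The threshold automaton avoids this by construction — one loss per
maximal below-threshold clade — and two further generator-side measures keep
every recorded event attributable: adjacent losses (within three tree edges)
are merged onto their common ancestral branch, and each species' threshold
is calibrated deterministically to yield a polymorphic column with 3–12
separated loss clades whose true history is strictly cheaper than its
mirror explanation; when the shared trait admits no such threshold the
species receives a partly private Brownian component (30% of variance)
before re-calibration. Origin-probe injections (6 transfers, 3
transfer+mutation, 2–3 duplication+mutation by default; placed where hosts
qualify) are restricted to single-tip, first-presence gains on
above-median-length branches in hosts without pathological loss-rate fits;
donors must differ from every other gene of their species by ≥ 2 sites;
anticodon-mutation scenarios use species one anticodon position apart
(matching the single wobble-position mutations seen in nature); injected
substitutions avoid sequence ends so local alignment cannot trim them.

What passing the end-to-end tests shows, and what it does not: the pipeline
detects strong, threshold-like GC associations under phylogenetic control,
reconstructs sparse and well-separated histories at branch precision, and
traces recent gene origins when the sequence signal is a handful of
substitutions. Real data add everything the generator deliberately omits —
rate variation the model does not capture, parallel losses on sibling
branches (which merge into ancestral calls), saturated sequence divergence,
copy-number dynamics, incomplete and erroneous annotations — so measured
recovery rates here are upper bounds on real-data performance, not
estimates of it.

## Problem sizes and numerical settings

Simulation-based checks use the sizes at which their targets are stable:
slope-coverage at 100 replicates of 300 tips, rate recovery at 20 replicates
of 500 tips, λ recovery at 50 replicates of 300 tips per generating value,
null calibration at 200 replicates (100-tip trees for the LRT; 150-tip
trees, 20–60 events per species, 2000 permutations per pair for the
permutation test), and the end-to-end fixture at its 300-tip default.
Optimizer tolerances: λ profile xatol 10⁻⁶; rate fits bounded in
[10⁻³, 200] per unit depth; LRT statistics more negative than −10⁻⁴ raise.
Uniformization truncates the jump distribution at the 1 − 10⁻¹² Poisson
quantile. Degenerate inputs (constant columns, singular designs, empty
groups, zero-length sequences) raise or return undefined results explicitly
rather than silently.
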