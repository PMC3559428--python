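# Methods

`piezocomp` re-implements, as a tested library, the comparative analysis
used to characterise amino-acid-level adaptation in a piezophilic
(high-pressure-adapted) sulfate-reducing bacterium against its closest
non-piezophilic marine relative: one-to-one ortholog detection between two
proteomes, a directional amino-acid substitution census with a per-pair
asymmetry test, composition-based clustering of organisms, genome
composition descriptors, a COG-category outlier rule, and a gel-spot
differential-abundance filter. This note records the models, the defaults
and why, the numerical choices, and what the synthetic data do and do not
establish.

## Orthology and alignment

Orthologs are called by the reciprocal-best-hit (RBH) rule: gene pairs
(g_a, g_b) are retained iff each is the other's unique top-scoring match
across the two proteomes. Match scores are exact optimal global-alignment
scores (Needleman–Wunsch with affine gaps) rather than heuristic search
scores: at the scale this package targets (10^2–10^4 proteins) the exact
all-vs-all score matrix is affordable, and it removes both the dependence
on an external search engine and the search E-value as a hidden parameter.
An optional raw-score floor stands in for a search significance cutoff.

Scoring defaults are BLOSUM62 with gap open 11 and gap extend 1, the de
facto standard for protein comparison; a gap of length L costs
`open + extend * L`, end gaps included. Retained pairs must additionally
pass identity >= 30% and coverage >= 70% — and coverage is required of
*both* sequences, the stricter of the possible readings. Identity is
computed over ungapped alignment columns only, matching the downstream
census, which also ignores gapped columns. Genes whose best hit is tied in
score are excluded from RBH entirely (a tie means the data cannot
distinguish the candidates; excluding beats guessing) and logged.
Tracebacks take the alignment engine's canonical first optimum, so reruns
are bit-identical. In lenient mode the ambiguity letter X is accepted,
scores 0 against everything, and its columns are excluded from all counts.

## Directional substitution census and asymmetry test

Over every ungapped, fully canonical column of every aligned ortholog pair,
the 20x20 matrix M counts columns by (reference-organism state a,
comparison-organism state b); the diagonal holds conserved sites. For each
unordered residue pair {a, b} the two directed counts x = M[a][b] and
y = M[b][a] are compared to the 50:50 split expected when neither direction
is favoured, with the one-degree-of-freedom goodness-of-fit statistic

    chi2 = (x - y)^2 / (x + y),  p = upper tail of chi2_1.

The test unit is the unordered pair (190 tests), reported with the
direction of net gain; the default threshold alpha = 0.0005 is applied per
pair with no multiple-testing correction, mirroring how such censuses are
conventionally reported; Bonferroni and Benjamini–Hochberg corrections are
available as options. No continuity correction is applied.

An exact binomial alternative is provided both as an option and as the test
oracle. Two conventions are implemented: the conventional minimum-likelihood
two-sided test, and the **mid-p** variant (half weight on the observed
outcome). The uncorrected chi-square is the large-sample equivalent of the
mid-p test, not of the minimum-likelihood test — on count tables of this
size the minimum-likelihood p can exceed the chi-square p by more than 0.1
for pairs with a few dozen events, while the mid-p agrees to well under
0.01. The package therefore uses mid-p as the agreement oracle and exposes
both.

The replacement summary reports, per residue, its row off-diagonal total
("times replaced"), column off-diagonal total ("times gained"), net excess
and net excess as a percentage of the residue's full row total (conserved
sites included). The percentage denominator is a package definition: no
published formula reproduces the percentages printed alongside such
censuses, so the package states its own and asserts only rank-level facts
(which residues lose most, which gain in the most significant pairs) in its
tests. "Preferred acceptors" are residues that are the significant gaining
direction in at least k pairs (default k = 3).

## Composition descriptors and clustering

Amino-acid frequency vectors are computed over all residues of all
sequences. Pairwise dissimilarity is the Pearson correlation distance
d = 1 - r (not (1 - r)/2; the choice is configurable), which is invariant
to positive affine transforms and ranges over [0, 2]. Trees are built with
neighbor joining (Saitou–Nei agglomeration, Studier–Keppler Q criterion);
ties in Q are broken by the lowest pair of node indices in insertion order,
so join order is deterministic. Negative branch-length estimates are
clamped to zero with the deficit moved to the sister branch, preserving the
joined nodes' path length — the standard practical remedy. On exactly
additive matrices NJ provably returns the generating tree; the test suite
checks this by rebuilding the path-length matrix and by Robinson–Foulds
comparison against an independent implementation.

GC is the G+C fraction over all bases; GC3 pools every third codon
position across CDSs, excluding a terminal stop codon by default (stop
codons encode no amino acid). Isoelectric points solve Q(pH) = 0 where Q
sums Henderson–Hasselbalch terms over the two termini and the seven
ionisable side chains with the EMBOSS pKa set (configurable); bisection on
[0, 14] runs to a pH interval of 1e-7 and verifies |Q| < 1e-4. The
COG-category rule converts counts to within-organism proportions and flags
a category when the focal organism lies outside mean ± 2 SD (sample SD,
n−1) of the reference organisms; with zero reference variance any deviation
is flagged. Genomic signatures are the 256-vector of overlapping
tetranucleotide frequencies (single-strand by default, reverse-complement
combination optional) and relative synonymous codon usage
(RSCU = count × family size / family total, stop codons excluded).

## Differential abundance

Spot volumes are normalised per gel to relative volumes (sum 1), replicates
averaged per condition, and DA = larger/smaller relative volume computed
per spot. Significance is DA >= 1.5 *inclusive*: published spot tables
list entries at exactly 1.5, so a strict inequality would contradict them
(strictness is a flag). Because DA is a ratio of normalised volumes, ties
at the threshold are resolved within 1e-9 relative tolerance to avoid
float round-off artefacts. A spot quantified in only one condition is a
qualitative presence/absence difference: DA is undefined and the spot is
flagged significant. Replicate aggregation (mean of per-gel relative
volumes) is a package choice.

## Synthetic data: what it emulates and what it does not

The ortholog-pair generator draws ancestral proteins from a stated
composition (default: average Swiss-Prot residue frequencies; uniform
optional) and produces one descendant proteome by independent per-site,
single-hit substitution — no back substitutions, no rate heterogeneity
across sites, no multi-taxon genealogy. Single-hit is deliberate: the
census counts site *states*, not histories, so a second hit at a site
would only blur the recorded truth.

The base exchange process is an equal-input model in detailed balance with
the ancestral composition: a site in state a substitutes with probability
proportional to (1 − pi_a) and picks target b with probability
proportional to pi_b. Detailed balance makes the *expected* directed count
matrix symmetric, which is the property the type-I-error analysis needs; a
uniform-target process would not have it (directed counts would scale with
the source residue's frequency, producing real asymmetries between
abundant and rare residues). The nominal `sub_rate` is the
composition-averaged per-site substitution probability; its default 0.2
yields roughly 20% substituted ungapped positions, a mid-range divergence
for congeneric bacterial proteome pairs. Directional bias multiplies the
target weight of the listed ordered pairs, breaking symmetry exactly
there; the power analyses size the bias and the number of sites
analytically from this model (formulas in the test helpers and acceptance
script).

Indels are single-residue insertions/deletions in the descendant at a
per-site rate: the downstream census discards gapped columns, so indel
geometry only needs to exercise gap handling. Paralogs are duplicated
descendant genes diverged at three times the substitution rate (to exercise
best-hit uniqueness), orphans are unrelated genes added to both proteomes.

The CDS generator emits ATG-initiated, stop-free codon sequences whose
third positions are G/C with the target probability; the fixed initiator's
G shifts realised GC3 toward 100 by at most 1/length, which matters only at
the extreme targets (the degenerate-target tests therefore assert on
post-initiator codons). The spot-table generator applies planted folds to
raw volumes of the first condition with multiplicative log-normal noise of
unit mean; note that sum-normalisation shifts a planted spot's *relative*
ratio by the (small) ratio of gel totals, so planted folds are exact on raw
volumes and approximate after normalisation — the tests check both
readings.

Passing tests on these data establish that the machinery is correct and
well calibrated under a known-truth model; they do not establish anything
about real genomes, which add alignment error, domain shuffling, shared
ancestry between sites, composition heterogeneity along the chromosome and
annotation noise that the generators deliberately omit.

## Problem sizes used in validation

The validation suites run at desk scale, chosen to give tight Monte-Carlo
bounds while keeping the full suite fast: 50 bias-free replicates of 100
proteins x 300 residues for the type-I error bound; 100 replicates of
~8,200 proteins x 300 residues for power at the published K/R effect size
(x+y ≈ 4,000, x/y ≈ 1.37); 200 random short sequence pairs against the
exhaustive alignment oracle; 100 random 4–8-taxon additive matrices for NJ;
100 runs of 8 organisms x 50 proteins x 200 residues for composition
clustering (group compositions differ by a ±15% relative shift on A,R,H,T
vs D,E,K,N — the same order as the real piezophile shift, whose largest
per-residue net excess is ~12% of a residue's sites); 3 x 60,000 codons
for GC3 fidelity.

## Known limitations

* All-vs-all exact scoring is quadratic in proteome size; beyond ~10^4
  proteins a k-mer prefilter or external search tool would be needed.
* The asymmetry test treats ortholog columns as independent observations,
  as the original analysis does; phylogenetic correlation between sites of
  the same protein family is not modelled.
* The substitution census has no outgroup, so "direction" means net excess
  between the two extant organisms, not a polarised ancestral inference.
* pI values depend on the pKa set; only sequence-intrinsic charge is
  modelled (no structural pKa shifts, no post-translational modification).
* The NJ implementation targets tens of taxa (dense O(n^3) updates), which
  is ample for composition trees of selected genomes.
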