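# Methods

## Scope and data model

The package analyses in-frame coding alignments (multi-FASTA, length a
multiple of 3, no internal stop codons; a terminal stop shared by all
members is trimmed). All distance and model stages operate after *complete
deletion*: every codon column containing a gap or ambiguity character in
any member is removed. Ambiguity codes are treated as deletable, the
conservative convention of classical distance software. Site numbers in
reports are 1-based amino-acid positions on a reference sequence
(configurable; default the first member of the alignment).

## Pairwise synonymous and nonsynonymous rates (NG86)

For each codon, the fraction of single-nucleotide changes at each position
that are synonymous defines its synonymous site count; changes into stop
codons are excluded from the denominator. Site counts are averaged between
the two sequences. For codon pairs differing at 2–3 positions, synonymous
and nonsynonymous differences are the unweighted mean over all orderings of
the minimal mutational pathway, excluding pathways that pass through a stop
codon (falling back to all pathways only when every pathway is blocked).
Proportions p_S = S_d/S and p_N = N_d/N are corrected for multiple hits
with the Jukes–Cantor formula d = −(3/4) ln(1 − 4p/3). If p ≥ 3/4 the
correction is undefined; the estimate is flagged inapplicable rather than
clamped, and inapplicable values are excluded from averages with a warning.

Standard errors are nonparametric bootstrap over codon columns (default
B = 1000, seeded). An analytic variance is not implemented.

Known limitation: unweighted pathway averaging attributes fractional
nonsynonymous counts to some purely synonymous histories. When two
synonymous substitutions hit one codon at different positions inside the
leucine or arginine families (e.g. TTA↔CTC), one of the two minimal
pathways passes through a nonsynonymous intermediate and N_d for that pair
is positive even though no nonsynonymous substitution occurred. This is a
property of the published estimator, not of the implementation, and the
test suite records it (one acceptance-level check of "N_d = 0 under ω = 0"
fails for exactly this reason; the exact statement that does hold — the
protein sequence never changes under ω = 0 — is asserted separately).
NG86 site counting also ignores the transition/transversion bias, so with
κ > 1 dS is mildly overestimated and dN/dS underestimated (≈8% at κ = 2 in
our simulations); the neutrality consistency check therefore simulates with
κ = 1, where the estimator's assumptions hold exactly.

## Nucleotide distances and distance trees

p-distance (mismatch proportion) and Kimura two-parameter distance
d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q), with P and Q the transition and
transversion proportions; a non-positive log argument flags the estimate
inapplicable, and tree building aborts on inapplicable entries rather than
imputing.

Neighbor joining follows Saitou–Nei: join the pair minimising
Q(i,j) = (n−2) d(i,j) − r_i − r_j, branch lengths from the two-point
formulas, negative estimates clamped to zero with the deficit moved to the
sister branch. Ties are broken lexicographically by sorted label pair, so
output is deterministic. The unrooted result is stored with a trifurcating
root. UPGMA is average-linkage with the same tie-break. Bootstrap support
resamples alignment columns (codon or nucleotide) with replacement,
rebuilds the tree per replicate, and reports for each internal bipartition
of the point tree the percentage of replicates containing it; replicates
whose rebuild fails are skipped and counted, and more than 5% skips is an
error. Minimum-evolution search is out of scope.

## Molecular-clock dating

Averaged dS for a group of pairs is the arithmetic mean of the pair values,
and its error is the arithmetic mean of the member standard errors — not
the standard error of the mean. This convention is what published tables of
this kind print, and it keeps the averaged error on the same scale as the
member errors.

Calibration: k = dS / 2t from a split of known age t (here 60 MY for the
rice/wheat divergence). Dating: T = dS / 2k, se(T) = se(dS) / 2k, so the
relative error of T equals that of dS exactly. By default dating uses the
rate rounded to 2 significant figures — the rounded rate is the quantity
such analyses print and then reuse, and reproducing printed tables requires
it — with the unrounded rate available via a flag. Output precision: times
to 0.1 MY, rates to 2 significant figures, dS to 4 decimals.

## Codon substitution models

GY94 over the 61 sense codons: q_ij = π_j κ^[transition] ω^[nonsynonymous]
for single-position neighbours, 0 otherwise, diagonal from row sums, and
each class's matrix rescaled to one expected substitution per codon per
unit branch length (−Σ π_i q_ii = 1). The chain is reversible, so
P(t) = exp(Qt) is computed from the eigendecomposition of the symmetrized
matrix; entries more negative than −1e−8 raise, smaller negatives are
clamped and rows renormalized. Codon frequencies: F3x4 (position-specific
nucleotide frequencies) by default, with F1x4 and equal-frequency options;
zero cells are floored at 1e−10 to keep the chain irreducible.

Likelihoods use Felsenstein pruning over compressed site patterns with
per-node max-rescaling against underflow. Site models are finite ω
mixtures: M0 (one ratio), M1a (ω₀ < 1, ω₁ = 1), M2a (adds ω₂ ≥ 1), M3 with
k free classes, M7 (ω ~ Beta(p, q), discretized into 10 equal-probability
categories at their slice medians), and M8 (beta plus a point mass
ω_s ≥ 1). The two-ratio branch model instead assigns a foreground clade —
every branch whose descendant leaves all lie inside a named leaf set — its
own ω.

Fitting maximizes lnL by bounded L-BFGS-B in transformed coordinates
(log for rates and branch lengths, stick-breaking for proportions; bounds
κ ∈ [0.1, 30], ω ≤ 50, beta shapes ∈ [0.005, 99]). Branch lengths are
estimated once under M0 and held fixed for all other models — the standard
protocol, which also keeps the scan at desk scale; joint estimation is
available by not passing fixed lengths. Multi-start (default 5, seeded,
stratified over the bounds) with the convergence flag requiring the best
two starts to agree within 0.01 lnL. Alternatives are additionally
warm-started from their nested null's MLE embedded in the alternative's
coordinates (p₂ → 0 for M2a, the extra mass → 0 for M8), which guarantees
the nesting inequalities up to optimizer tolerance. Free-parameter counts
for LRT bookkeeping count the ω-distribution parameters (M0: 1, two-ratio:
2, M1a: 2, M2a: 4, M3: 2k−1, M7: 2, M8: 4); κ and branch lengths are
shared. LRT: 2Δl clamped at zero against χ² with the stated df; an
alternative falling below its null by more than 0.02 lnL raises an
optimization-failure error instead of reporting a negative statistic.

NEB: class posteriors at the MLEs, P(c|x_h) ∝ p_c f(x_h|ω_c); sites whose
summed posterior over ω > 1 classes exceeds 0.5 are reported, starred at
0.95/0.99. BEB (M2a and M8) integrates the class posteriors over a uniform
grid prior on the ω-distribution parameters (10 points per dimension;
proportions via a stick-breaking grid over the simplex, ω₀ over (0,1), the
positive-selection ω over (1,11), beta shapes over (0,2]), with κ and
branch lengths fixed at their MLEs and site likelihoods cached per distinct
ω. With long alignments the integration concentrates and BEB approaches
NEB up to grid discretization; with weak data it shrinks posteriors, so it
flags fewer sites — its design intent.

A 2-taxon M0 fit also yields an ML dS: with ρ_S the synonymous share of the
substitution flux at the MLEs and c_S the same share at ω = 1 (the
mutational opportunity), dS = t ρ_S / (3 c_S).

The universal genetic code is wired throughout (plant nuclear genes);
the code table is pluggable but untested elsewhere. Branch-site models,
empirical exchangeabilities, and ancestral reconstruction are out of scope.

Known numerical inconsistency faithfully carried from the published
analysis this workflow mirrors: the published two-ratio LRT prints
2Δl = 0.4223 while the printed log-likelihoods (−1433.52 vs −1433.09)
imply 0.86. The analytic p-value reproduction uses the printed statistic
and df; the package takes no position on which printed number is the typo.

## Simulator

Sequences evolve by exact transition-matrix sampling: a root codon per site
from π, then each child state drawn from P(t) of its branch — marginally
exact, with no event-level (Gillespie) simulation, since latent
substitution paths are not needed. Per site an ω class is drawn from the
model's mixture (or, for the two-ratio mode, per-branch ω by clade
membership); true class labels and the true tree are always returned so
recovery tests never reverse-engineer them. Runs are bit-reproducible under
the mandatory seed.

The duplicated-family fixture emulates the study design: 11 taxa × 249
codons; an outgroup ortholog (rice-like, split 60 MY), a second outgroup
(Brachypodium-like, 40 MY), a duplication at 18 MY splitting PMM-1-like and
PMM-2-like clades, species splits within clades at 11/4/2.5/0.5 MY;
background ω = 0.155, κ = 2, uniform codon frequencies. Branch lengths are
back-calculated from the target synonymous divergences (outgroup path
dS ≈ 0.44, paralog pairs dS ≈ 0.14) through the model's synonymous flux and
the mean NG86 site count, so the fixture lands on the intended dS scale up
to sampling noise and the estimator's κ bias (realized outgroup dS is
typically 0.44–0.50). What the fixture does **not** emulate: codon usage
bias (frequencies are uniform), rate variation among sites or lineages
beyond the single background ω, indels (alignments are gap-free unless a
pseudogene stop is injected), and intron evolution. Passing tests on the
fixture therefore demonstrate correctness of the machinery under the
model's own assumptions, not robustness to real-data violations of them.

## Problem sizes and test design

The test suite simulates at sizes chosen to make the statistical checks
sharp while staying desk-scale: parameter recovery at 8 taxa × 500 codons
(20 replicates), nesting inequalities at 4 taxa × 50 codons (20 datasets),
BEB/NEB agreement at 2000 codons, neutrality of NG86 at 2 taxa × 500
codons (50 replicates), NJ exactness over 100 random additive matrices of
4–12 taxa, and the full pipeline on the 11 × 249 fixture with 500
bootstrap replicates. Multi-start counts are reduced (1–2) where the
likelihood surface is known to be well-behaved (M0, warm-started nested
alternatives).

## Multiple testing

No correction is applied across the LRT battery; raw p-values are
reported, matching the workflow this package mirrors, and interpretation
is left to the user.
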