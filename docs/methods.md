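# Methods

This note documents the statistical models, the numerical choices, and the
design decisions behind `paleokin`, in the order data flows through the
package.

## Data model

Genotypes live in EIGENSTRAT text trios (`.geno`/`.snp`/`.ind`).  A `.geno`
character counts copies of the first-listed allele in the `.snp` file; on
reading, diploid values become alt-allele dosage (`2 − v`) and haploid values
alt calls (`1 − v`), with `9` mapped to the internal missing value (−1).
Haploid matrices are written in the same container with a `.ploidy` sidecar
rather than a separate format.  Genetic positions are Morgans in `.snp`
files and centimorgans in memory; a stored value of 0 is read as "no map".
Positions are 1-based; chromosome labels are verbatim strings, with labels
1–22 treated as autosomes.

Pseudo-haploid calling draws one allele per site per individual, uniformly
from the two alleles of a diploid genotype or from the reads covering the
site; zero-depth sites are missing.  Base/mapping-quality filtering is
assumed upstream.  Genetic sex is assigned from X/autosome and Y/autosome
coverage ratios (XX iff X ≥ 0.8 and Y ≤ 0.1; XY iff X ≤ 0.6 and Y ≥ 0.3;
otherwise unassigned).  The literature reports such ratios graphically
without numeric cutoffs, so these defaults are conventional choices exposed
as parameters; the assignment is invariant to uniform depth scaling.

## Pairwise mismatch rate (PMR)

For a pair of pseudo-haploid genomes, PMR = mismatches / overlapping called
sites (autosomal by default).  If the sampled alleles are identical by
descent they match; otherwise they mismatch with the population rate *b*, so

    E[PMR] = (1 − κ) · b,   κ = kinship coefficient.

*b* is the median pairwise PMR of a reference panel — the median because it
is robust to a few undetected relatives; whether to normalize by mean or
median is not fixed by convention, and the median is the safer default.  A
dispersion check reports panel pairs falling below the second-degree
boundary (0.90625 × median) as likely relatives; optionally, a supplied
expected heterozygosity (mean 2p(1−p) from external frequencies) guards
against a panel that is *mostly* relatives, which the internal check — being
relative to the panel's own median — cannot detect.  A two-individual panel
of duplicated genotypes is the extreme case: its single pair PMR *is* the
median, so only the external comparison can flag it.

Degrees are assigned from normalized PMR (PMR / b) by nearest expected value
(0.5, 0.75, 0.875, 0.9375, 1.0 for identical/1st/2nd/3rd/unrelated), i.e.
class boundaries at the midpoints 0.625, 0.8125, 0.90625, 0.96875.  An
exactly-boundary value goes to the more distant degree — conservative
against over-claiming kinship.  Pairs with fewer than 10,000 overlapping
SNPs (well below the ~66k minimum seen in practice for 1240K-captured
samples) are classified but flagged low-confidence.

### The κ = 1/32 boundary

Fourth-degree relatives have expected normalized PMR 1 − 1/32 = 0.96875 —
*exactly* the 3rd/unrelated midpoint.  This is not an implementation
artifact: midpoints between consecutive degree expectations coincide with
the next degree's expectation, because kinship halves per meiosis.  In the
jar-coffin pedigree the third-degree relative of the father is necessarily
fourth-degree to the father's children (one extra meiosis; the mother is
unrelated to him), so those two pair calls are coin flips between "third"
and "unrelated" under any SNP count, coverage, or seed: sampling noise is
symmetric around the boundary and more data only narrows the distribution
around it.  Across 100 simulated seeds the classifier reports the exact
6/2/1 first/second/third pattern in roughly a third of replicates, with the
remainder differing only in those two calls.  Tests of the classifier
therefore assert exact recovery for pairs with κ ≥ 1/16 and accept either
label at κ = 1/32; what passing shows is that every *resolvable* degree is
recovered, and that the unresolvable calls fail only in the predicted way.

## Genotype likelihoods and IBD coefficients

With per-read error ε, the alt-read probability given genotype g ∈ {0, 1, 2}
is e_g ∈ {ε, ½, 1 − ε}, so L(g) ∝ e_g^alt (1 − e_g)^ref, normalized to sum
to one; zero-depth sites are uniform (1/3, 1/3, 1/3) and drop out of the
likelihood.

For a pair, the site likelihood marginalizes over the latent IBD state m:

    P(data_s) = Σ_m k_m Σ_{g_i, g_j} GL_i(g_i) GL_j(g_j) P(g_i, g_j | m, p_s)

with P(· | m=0) the product of Hardy-Weinberg genotype probabilities,
P(· | m=2) Hardy-Weinberg on the diagonal, and P(· | m=1) conditioning on
one allele shared IBD (chosen uniformly from the first individual's
genotype) with the remaining allele drawn from the population — a table that
is already symmetric in the two individuals, so the two sharing directions
coincide.  (k0, k1, k2) is maximized by EM on the simplex: convergence when
the log-likelihood gains < 1e-6, at most 1000 iterations, non-convergence
flagged with the last iterate returned.  EM is started from the
best-scoring of the canonical relationship points (uniform, unrelated,
parent-offspring, full-sibling, second-degree, identical): from the uniform
start alone, boundary truths such as parent-offspring approach k0 = 0
sublinearly and can retain k0 of a few percent at the iteration cap, while
the multi-start converges within it.  Reference allele frequencies come
from a user-chosen panel (pooled panel frequencies by default, clipped away
from 0/1); which population's frequencies to use is exposed as
configuration rather than fixed.

First-degree pairs are split by rule: parent-offspring if k0 < 0.05 and
k2 < 0.1; full siblings if k0 ≥ 0.1 and k2 ≥ 0.1; otherwise undetermined.
Age classes are carried as advisory context and never override genetics.

Relative pruning for group analyses removes one member of every pair related
at second degree or closer, by exact maximum independent set (groups are
small); ties among maximum sets are broken by higher total site coverage,
then lexicographic ids.

## Pedigrees

Expected coefficients use the standard recursion for outbred pedigrees:
φ(a,a) = ½, φ(a,b) = ½ Σ over parents of the deeper node, and for a ≠ b

    k2 = φ(f_a, f_b) φ(m_a, m_b) + φ(f_a, m_b) φ(m_a, f_b),
    k1 = 4κ − 2 k2,   k0 = 1 − k1 − k2.

Inbreeding loops are detected (parents with φ > 0) and rejected — the target
assemblages show no offspring of close relatives, and the closed forms above
assume outbreeding.  A node may record 0, 1, or 2 parents; a single
recorded parent means the other parent exists but is unrelated to everyone
modelled (all φ-terms through it vanish).

`enumerate_pedigrees` searches exhaustively within bounds: at most
`max_latent` unsampled connectors (default 4) and `max_generations` depth
levels (default 3).  The search enumerates generation-depth labellings
(founders at depth 0, each non-founder one deeper than its deepest parent —
a canonical labelling, so each structure is generated once), then assigns
parent sets in depth order while maintaining the φ table incrementally, so
every observed-pair constraint is checked at the earliest possible node and
the branch pruned on mismatch.  Hard constraints: expected degree equals the
observed call for every observed pair (degrees beyond 3rd count as
"unrelated", matching the classifier's resolution, with the κ = 1/32 tie
going to unrelated); pairs typed parent-offspring must be a parent edge,
full siblings must share both parents; couples must be opposite-sexed and
unrelated.  Latent nodes must be genuine connectors (at least one child; a
parentless latent with a single child is removable without changing any
kinship and is pruned, which keeps representations minimal), same-sex
latents are interchangeable and deduplicated by canonical relabelling.  If
no pedigree satisfies every degree, the search relaxes to 1, then 2
mismatches and returns the best near-misses with violations listed.

Survivors are ranked by a constraint-satisfaction score: +1 for every
observed pair in the same mtDNA (mother-line) or Y (father-son line) clan
with equal observed labels, +1 for every observed parent-child edge that is
age-consistent; label conflicts within a clan and subadult-parent-of-adult
edges count as violations.  Pairs sharing a haplogroup across *different*
clans neither score nor violate — sharing by chance is possible.  All
co-maximal pedigrees are returned; for the jar-coffin pattern this is what
keeps both mother-son and father-daughter readings of the GUC004–GUC005
pair while ranking mother-son first (it explains the mtDNA shared between
GUC005 and the children).  Ranking is a count, not a likelihood —
deliberately mirroring qualitative reasoning with uniparental markers; a
likelihood over pedigrees is out of scope.

## Synthetic data

The generator emulates the statistical structure the estimators assume:
founder genotypes Binomial(2, p) under Hardy-Weinberg, Mendelian
transmission of one uniformly chosen allele per parent per SNP, mt labels
following the maternal line and Y labels the paternal line; read counts with
Poisson depth, per-read error, an optional contaminant frequency profile
(so a contamination artifact can be reproduced as a small spurious
admixture component), and extra forced site dropout, independent per
individual; and population frequencies evolving on a graph by Brownian
drift with per-SNP variance d·p(1−p) truncated to [0, 1]
(Balding-Nichols-style), with admixture as frequency mixing
α·p₁ + (1−α)·p₂.

Defaults are chosen to resemble a well-preserved 1240K-captured sample:
mean depth 1.0 (captured ancient samples typically cover 15–65% of panel
sites at least once), base error 0.001 (Q30-filtered bases), contamination
0 (the motivating samples show ≤ 2% and the artifact is studied explicitly
through the contaminant profile instead), allele frequencies Beta(1, 1).
SNPs are unlinked — sufficient for mismatch-rate and k-coefficient moments —
so IBD *segments*, runs of homozygosity, linkage disequilibrium, and
post-mortem damage gradients are explicitly not simulated; conclusions
requiring them (e.g. ROH-based inbreeding) are out of scope.  Jackknife
blocks use synthetic genetic positions: SNPs evenly spaced at 0.01 cM on 22
pseudo-chromosomes, giving ~200 five-cM blocks at 100k SNPs.  All
randomness derives from one master seed via `SeedSequence` spawning.

What passing on synthetic data does *not* show: robustness to reference
bias, damage-driven genotype error structure, linked missingness along the
genome, or population structure within the reference panel.  Those effects
are real in ancient data and are the reason the pipeline reports
low-confidence flags, baseline dispersion checks and co-maximal pedigree
alternatives instead of single answers.

## f-statistics

f3(O; A, B) = mean per-SNP (o−a)(o−b) and f4(A, B; C, D) = mean (a−b)(c−d),
over SNPs where *every* involved population has data (strict intersection;
per-statistic SNP counts are always reported).  No small-sample
heterozygosity corrections are applied — a documented divergence from
qp3Pop's corrected mode, appropriate for pseudo-haploid data and
ranking/testing use.  Because sample-frequency noise inflates products in
which a population repeats, identities such as the f4-ratio
f4(A,B;adm,B)/f4(A,B;A,B) = α hold on population frequency vectors and are
tested there; qpAdm never repeats a population within a statistic.

Standard errors use the weighted delete-one-block jackknife with block
weights proportional to SNP counts: with n SNPs in g blocks of sizes m_j and
h_j = n/m_j,

    θ*_j = h_j θ̂ − (h_j − 1) θ̂_(j),
    θ̂_J = g θ̂ − Σ_j (1 − m_j/n) θ̂_(j),
    Var  = (1/g) Σ_j (θ*_j − θ̂_J)² / (h_j − 1),

which reduces to the classic delete-one jackknife for equal blocks.  Blocks
are contiguous ≥ 5 cM windows per chromosome, falling back to 5 Mb physical
windows (with a warning) when genetic positions are absent.

qpWave builds F[i,j] = f4(l₀, l_i; r₀, r_j), estimates the covariance of
vec(F) by the jackknife above, and tests rank r via the minimized quadratic
form (alternating generalized least squares over rank-r factorizations, SVD
initialization), referred to χ² with (|L|−1−r)(|R|−1−r) degrees of freedom.
Near-singular covariances (condition number > 1e12) receive a relative
ridge (1e-9 × mean diagonal) with a warning.

qpAdm parametrizes the last source as base: with d_j = f4-profile of
(target − s_K) against the right pairs and D the profiles of (s_i − s_K),
the weights solve a generalized least squares problem in two steps (first
with the covariance of d, then re-estimated at the fitted weights).  Weight
standard errors come from delete-one-block refits fed through the same
weighted-jackknife variance; the model p-value is the χ² tail of the
residual quadratic form with (|R|−1) − (K−1) degrees of freedom.  Weights
may be negative — reported with `feasible=False` rather than clamped, since
small negative components are themselves diagnostic (e.g. a ~1%
contamination artifact appears as a mirrored ±1% component in reciprocal
models).  The first-listed right population is the implicit base r₀;
results are invariant to permuting the remaining rights (tested).  Model
reduction re-fits all single-source-removed submodels and accepts the
best-fitting one while its rank-test p exceeds 0.05, repeating until no
source can be dropped; the 0.05 convention is this package's choice.

A calibration caveat: "estimate within 2 jackknife s.e. of truth" has
nominal coverage ≈ 95.4%, so a 100-replicate study clears a ≥ 95% bar only
about two times in three even though the standard error is calibrated (a
block bootstrap on a fixed dataset reproduces it to within 1%).  The
calibration studies in `paleokin.validation` report the raw fractions.

## Skeletal MNI

Per element and age class, MNI = max(left, right, unsided); midline bones
(frontal, occipital) are carried in the unsided column, which the max
handles uniformly.  The assemblage estimate takes the maximum over elements
per age class and sums age classes — the maxima may come from different
elements, so the total can exceed every single row's value.  Exclusion of
ribs, vertebrae and phalanges (unreliable siding) is the data preparer's
responsibility; visual pair-matching and osteometric sorting are not
computable from counts and are out of scope.

## Problem sizes

The test suite and acceptance script use: 100,000 SNPs and 100 seeds for
the degree-pattern study (102-member reference panel, 50% dropout); one
100,000-SNP replicate at 2× depth for the read-level first-degree study;
50,000 SNPs × 100 replicates for the f4 null; 100,000 × 100 for qpAdm
recovery; 50,000 × 200 for the qpWave null; 30,000 SNPs for pipeline-level
tests.  These sizes give standard errors comfortably inside the asserted
bands while keeping a full run to a few minutes on one CPU.

## Known limitations

Unlinked-SNP simulation only (no ROH/IBD segments); outbred pedigrees only;
pedigree ranking is constraint-counting, not likelihood; qpAdm assumes the
rights are unadmixed with the left set (the user's modelling
responsibility); no PCA, admixture-graph fitting, or rotating-outgroup
protocols; BAM/FASTQ processing, contamination estimation and haplogroup
calling are upstream of this package and consumed as inputs.
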