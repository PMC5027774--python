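# Methods

## Scope and data model

`barcodekit` operates on two inputs: an equal-length nucleotide alignment
(FASTA) joined to a specimen metadata table (specimen_id, species, marker),
and a per-specimen morphology table (CSV) of meristic counts, raw
measurements in mm, standard length and yes/no qualitative characters.
Sequences are case-normalized and validated against the IUPAC alphabet plus
`-`; ambiguity codes are stored as-is and interpreted by each stage.
Specimens without a species label are stored as `"unknown"`; they stay in
trees and OTU clustering (the identify-a-query use case) but are excluded
from every species-wise statistic.

## Distances

p-distance is the proportion of differing sites among jointly resolved
sites; the Kimura-2-parameter distance corrects it using the observed
transition proportion P and transversion proportion Q:

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q).

Pairwise deletion: a site counts for a pair only when both sequences carry
A, C, G or T there. Partial IUPAC ambiguities (R, Y, ...) are treated as
missing, matching the default behaviour of the mainstream barcoding
software this mirrors. When a pair shares no comparable site or the log
arguments are non-positive (saturation), the distance is *undefined*: it is
stored as NaN, listed in `DistanceMatrix.undefined_pairs`, and downstream
stages either skip (gap summaries) or refuse (trees, OTUs) such pairs.
Nothing is clamped or silently dropped. Reports print percentages rounded
half-up to two decimals; full precision is retained internally and
available via `--full-precision`.

## Neighbour joining and bootstrap

The tree builder is the canonical Saitou–Nei agglomeration: minimize
Q_ij = (n-2)d_ij - r_i - r_j, join, update distances by Studier–Keppler.
Two numerical choices matter:

- **Tie-break.** The minimum Q is taken at the lowest (row, column) index
  pair in the current label ordering, so rebuilds (and bootstrap
  replicates) are exactly reproducible.
- **Negative branch lengths** are clamped to zero; the total clamped
  deficit is recorded on the tree and written to the run log. Lengths are
  reported, not used for inference, so display-style clamping is safe.

Bootstrap support resamples alignment columns with replacement, rebuilds
the NJ tree per replicate with the same distance engine (pairwise deletion
applies inside each replicate), and scores each internal edge of the
full-data tree by the percentage of replicates containing the identical
leaf bipartition. Bipartitions are canonicalized by the side not containing
the alphabetically first leaf, so the mapping is by split identity, not
node identity. A replicate whose resampled columns leave some pair with an
undefined distance is skipped and counted; support percentages are over
completed replicates, and more than 50% skipped aborts with an error. The
default is 10,000 replicates (the conventional deep setting); tests and the
acceptance script use 30–100, which saturates for the planted-signal
fixtures they measure.

## Barcode gap

For each named species: intraspecific statistics (mean, sample SD with
n-1 denominator, min, max) over all unordered within-species pairs — over
pairs, not specimens, the convention of distance-summary tools. The nearest
neighbour is the species containing the specimen at minimum interspecific
distance; exact ties report all tied species joined alphabetically with
" & ". The barcode gap is `nn_distance - max_intra` and only a strictly
positive value counts as a gap — equality or overlap is flagged "no gap",
because identification by distance needs the interspecific range to clear
the intraspecific one. Singleton species have undefined (not zero) intra
statistics and therefore an undefined gap. Genus/family-level summaries
pool interspecific distances into within-genus-between-species and
between-genera classes (genus defaults to the first word of the binomial).

## OTU clustering

Single linkage at a percent threshold: specimens share an OTU iff connected
by a chain of distances ≤ threshold (connected components of the threshold
graph). The 2.2% default is the seed threshold of BOLD's RESL procedure;
the Markov-clustering refinement RESL applies afterwards is deliberately
not reproduced (it is BOLD-internal), so these OTUs approximate BINs.
Cluster ids are their smallest member specimen_id, which makes output
stable. A cluster is concordant when it contains at most one named species
("unknown" ignored).

## Diagnostic nucleotides

A column is diagnostic for species *s* iff (a) every sequence of *s*
carries the same unambiguous base *b* there and (b) no sequence of any
other species carries *b* or an ambiguity whose base set contains *b*. The
ambiguity rule is deliberately conservative: a site is never claimed
diagnostic when an ambiguous read elsewhere could contradict it. Columns
with a gap, ambiguity or polymorphism inside *s* are ineligible for *s*.
The variable-site table lists a column iff at least two distinct
unambiguous species-consensus states occur there; positions are 1-based on
the (primer-trimmed) alignment. Only pure single-state diagnostics are
flagged; partial/private polymorphism categories are out of scope. A
species with no diagnostic site may still be identifiable by its
consensus-state vector across all variable sites
(`combination_signature`), flagged non-identifiable when another species
shares the vector.

## Morphology

Measurements are standardized to percent of standard length
(value × 100 / SL) before all statistics. Summaries report range,
mean ± sample SD and n per species × character, with missing values
excluded per character.

**Variable selection for DFA.** Composite counts (total gill rakers =
upper + lower; total vertebrae = precaudal + caudal) are excluded because
they are linear in their parts; zero-variance columns (e.g. the invariant
principal caudal-fin ray count) and qualitative characters are excluded as
well. Meristic counts enter as continuous variables — faithful to how such
analyses are run in practice. Specimens missing any selected value are
dropped (complete-case) and counted.

**Discriminant analysis.** With pooled within-group scatter W and
between-group scatter B (group sizes weighting the mean deviations), the
functions are eigenvectors of the generalized symmetric problem
B v = λ W v, at most min(g-1, p) of them. Standardized coefficients scale
raw coefficients by the pooled within-group SD, sqrt(diag(W)/(N-g)).
Eigenvector signs are fixed by making the variable with the largest
|standardized coefficient| positive per function — signs are otherwise
arbitrary. Wilks' Λ = Π 1/(1+λₖ) is tested with Bartlett's
χ² = -(N-1-(p+g)/2) ln Λ on p(g-1) df; Box's M uses the standard χ²
approximation, excludes n=1 groups with a warning, and is reported as
undefined (NaN, with a warning) when any group covariance is singular —
common when a group has fewer specimens than variables. Classification is
nearest centroid in discriminant space with equal priors (an
identification tool should not prejudge group frequencies; priors are a
documented deviation point for unequal-n use). Leave-one-out
reclassification refits the DFA per fold; a variable whose variance
collapses to zero within a fold is dropped for that fold so W stays
invertible. 95% group ellipses for score plots are computed from per-group
score covariance at the χ²₂(0.95) radius and exported as data only.

**Identification key.** Genus is decided first from premaxilla
protrusibility (PCP), vomerine teeth / prevomer hooks (VTP), the dermal
plicae count envelope and pectoral-fin length in %SL; species within a
genus from the discriminating qualitative states (snout spot; belly-scale
chevrons; caudal-base and predorsal scales) and count ranges. Each
candidate is scored matched/evaluated over the characters present; the
best fraction wins, and ties or empty evidence yield "indeterminate" (or
"genus-only") with the conflict listed. A reference state recorded as
"unknown" (the belly-scale character is not clearly detectable in
*H. lanceolatus*) is never scored against that species. The default key
configuration derives from the published reference character table and is
fully overridable.

## Synthetic data

The sequence generator draws a uniform random root, applies each species'
planted substitutions to form its consensus, then mutates each specimen
per site with probability `intraspecific_rate`. A mutation is a transition
with probability bias/(bias+1) (default bias 2, so 2:1
transition:transversion — enough to exercise the P/Q asymmetry of K2P);
the two transversions split the remainder equally. Planted columns are
immune when `protect_planted_sites` is set, making the planted sites the
exact ground-truth diagnostics and the planted divergence exactly k/L in
p-distance at rate 0. The model is deliberately minimal: site-independent,
no indels, no rate heterogeneity, no coalescent genealogy. Consequently,
passing tests show the *analysis machinery* is correct on data with the
assumed structure; they do not show robustness to alignment error,
heterotachy or recombination in real data.

Default configurations encode the study conditions: a 464-site nuclear
fragment with three variable sites (82/433/460), species sizes 27/7/30/8
and zero intraspecific variation; and a 652-site barcode-like locus with
70 specimens in which two species are one substitution apart (~0.15%) and
the other two share part of their planted divergence so their mutual
distance (~3.5%) is below their distance to the first pair — the
nearest-neighbour structure of the study data.

The morphology generator draws SL and each %SL measurement from
independent normals (the reference table publishes marginal moments only,
so no correlations are simulated — real morphometric characters are
strongly correlated with body size, which the %SL standardization partly
absorbs), converts measurements back to mm (rounded to 0.01 mm), rounds
meristic draws to the nearest integer half-away-from-zero and clamps them
to the published range, derives composite counts from their parts, and
copies qualitative states verbatim. Both generators are byte-deterministic
per seed.

## Problem sizes and determinism

Tests and the acceptance script run at desk scale by design: 70-specimen
alignments, 100 bootstrap replicates, 20 specimens per species for the
morphology simulations, 100 random instances for the oracle property
suites. All randomness flows through `numpy.random.default_rng` seeded
from the single `--seed` argument or per-test constants; reruns are
byte-identical.

## Known limitations

- OTUs approximate BINs only up to the missing RESL refinement step.
- Box's M is undefined for groups with singular covariance rather than
  approximated further.
- The K2P engine implements no other substitution models (JC, TN93, GTR)
  and no rate heterogeneity.
- The identification key encodes the four northeast Atlantic species;
  other taxa require a user-supplied `key_config`.
- Standardized DFA coefficients use within-group scaling; packages that
  standardize by total covariance will print different (proportional)
  coefficients for the same functions.
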