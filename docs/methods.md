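# Methods

`molechron` implements a pseudogene chronology pipeline for eye-specific
genes in subterranean mammals: it tabulates gene-inactivating mutations in
curated coding-sequence alignments, estimates branch-category dN/dS under a
codon substitution model, converts the mixed selection signal on a
*transitional* branch into a calendar date for the onset of relaxed
selection, and maps individual lesions onto species trees by parsimony.
This note documents the models, their assumptions, the numerical choices,
and what the synthetic-data tests do and do not demonstrate.

## Lesion detection and tabulation

Inputs are exon-annotated CDS alignments (aligned FASTA over `ACGTN-`) with
a designated reference taxon. Columns where the reference carries a gap are
*insertion columns*; all coordinates are 1-based closed intervals in
alignment space including insertion columns, which makes the labels of
curated mutation tables (e.g. `1478–1575D (E13)`, `In6Do (AT)`)
reproducible verbatim.

The scanner emits records in a fixed vocabulary: frameshift insertions and
deletions (maximal indel runs with length not divisible by 3 — in-frame
indels are recorded as metadata but are not inactivating lesions),
premature stop codons, start/termination-codon mutations, non-canonical
splice-site dinucleotides (donor outside {GT, GC}, acceptor ≠ AG;
dinucleotides containing N or gap are not called), intron–exon boundary
deletions (an exon-edge deletion run combined with a nonzero flanking
intronic deletion extent, which is supplied as data because the alignments
are CDS-level), and disrupted opsin functional sites from a configurable
site table. Transmembrane-domain entries in a site table are positional
annotations only; the lesion vocabulary has no code for them and they
produce no records.

The premature-stop screen follows the masking rule used in manual curation:
frameshift insertions are deleted and frameshift deletions are N-filled, so
the masked sequence is exactly the reference CDS length and stays in the
reference reading frame. Codons containing N are never called as stops. A
stop within two codons of the canonical stop is recorded but flagged as
possibly tolerated.

Tallies are per-entry: each record counts once for each pair member that
carries it (shared records count for both; individual-specific records for
one), absence evidence (no BLAST result / no mapped reads) counts one entry
per row, and six pleiotropic control genes (*CNGB1*, *CRYAB*, *GNB1*,
*GNB3*, *RHO*, *SLC24A2*) are excluded from eye-specific totals. The
bundled tables under `src/molechron/data/` are a transcription of published
curated mutation tables for the two *Notoryctes typhlops* individuals and
the two golden-mole species; one printed interval with start > end
(`638–630D`) was normalized to `630–638`.

## Codon substitution model

Selection analyses use a Goldman–Yang-style reversible 61-state codon
model. For codons *i*, *j* differing at exactly one position,

    q(i→j) = π_j · κ^[transition] · ω^[nonsynonymous],

zero otherwise, with the generator rescaled to one expected substitution
per codon per unit branch length. Codon frequencies π come from observed
nucleotide composition, either pooled across codon positions (CF1, the
F1X4 convention) or position-specific (CF2, F3X4); N and gap symbols are
excluded from the counts. Zero entries in π are an error (the chain must
be ergodic).

Each branch of the rooted input tree carries a selection category —
*background* (functional), *transitional:k* (the branch on which a gene
group's first inactivating mutation arose), or *pseudogenic:k* (branches
postdating inactivation) — validated so that a transitional branch
subtends only its own pseudogenic category. Likelihoods are computed by
Felsenstein pruning over site patterns; codons containing N or gap are
partial ambiguities (sums over compatible states), so the NNN masking of
premature stops cannot bias the likelihood toward any sense codon.
Transition probabilities come from the symmetrized eigendecomposition of
the reversible generator (π^{1/2}-similarity transform), with per-node
rescaling of partial likelihoods against underflow.

Fitting maximizes lnL jointly over κ, one free ω per category (pseudogenic
categories can be fixed at 1.0, the neutral expectation), and all branch
lengths, using bounded L-BFGS-B on log-transformed parameters with a
deterministic multi-start over ω ∈ {0.1, 0.5, 1.0} by default
(convergence |ΔlnL| below ~1e-6; heavier simulation studies use a single
start at 0.5, which on this model family reaches the same optimum in
practice). Branch lengths are free parameters — the dated input tree
contributes only topology, categories, and node ages. Input branch lengths
(or ages × a nominal rate) seed the optimizer.

Per-category synonymous and nonsynonymous expectations are obtained by
decomposing the generator's equilibrium flux into synonymous and
nonsynonymous parts at the MLEs; per-site normalization uses the
mutational-opportunity fractions of the same decomposition at ω = 1, under
which the reported per-category dN/dS equals ω̂ identically. The
synonymous rate of a category, s = (synonymous substitutions per
synonymous site over the category's branches) / (summed branch durations
in MY), requires node ages.

Nested models are compared by likelihood-ratio test, p = P(χ²_df ≥
2ΔlnL), with negative statistics clamped to zero.

## Inactivation dating

The transitional branch spans [T_lower, T_upper] MYA and mixes a
functional portion (duration t_f, ratio ω_f) with a pseudogenic portion
(t_p, ω_p), its overall ratio being the synonymous-substitution-weighted
average of the two regimes. With one synonymous rate the weights are
durations:

    t_p = T · (ω_t − ω_f) / (ω_p − ω_f),  T = T_upper − T_lower;

with separate functional/pseudogenic synonymous rates s_f, s_p:

    t_p = s_f·T·(ω_t − ω_f) / [ s_p·(ω_p − ω_t) + s_f·(ω_t − ω_f) ].

The two-rate form reduces to the one-rate form whenever s_f = s_p, t_p is
continuous and nondecreasing in ω_t, and the limits are exact (ω_t = ω_f ⇒
t_p = 0; ω_t = ω_p ⇒ t_p = T). These formulas are normative for this
package: they are the unique solutions of the stated mixture identity, and
they behave correctly in every limit. Estimates of ω̂_t outside [ω_f, ω_p]
(possible with few substitutions) clamp t_p to the nearest endpoint and
set a diagnostic flag rather than erroring; ω_p ≤ ω_f is an
unidentifiable mixture and is an error.

Because inactivation is irreversible, the pseudogenic portion abuts the
descendant node, so the inactivation date is T_i = T_lower + t_p. A full
analysis runs the 2×2×2 grid {CF1, CF2} × {ω_p estimated, ω_p fixed at
1.0} × {one-rate, two-rate} and reports the unweighted arithmetic mean of
the eight T_i values, retaining every per-combination record. The fixed
mode uses 1.0 both in the fit and in the dating equation; the estimated
mode uses the crown-category MLE in both. No per-combination uncertainty
is propagated.

A separate clock-proportionality estimate dates the split between two
conspecific individuals: T_split = T_ref × (mean terminal branch length) /
(mean stem+crown path length), with branch lengths in substitutions/site
from a concatenation tree. With the published inputs (63.39 MYA,
0.000727, 0.072027) this gives 0.64 MYA.

## Parsimony mapping

Lesion presence/absence characters (0/1/?) are optimized by unordered
Fitch parsimony and resolved by delayed transformation: each node keeps
its parent's state whenever that is compatible with a minimal
reconstruction, pushing changes as far from the root as possible. Root
ties break to 0 (gene intact), the plesiomorphic state given functional
outgroups. Missing states are compatible with either assignment. The
implementation is checked against exhaustive enumeration of all
reconstructions on trees of up to six tips.

## Synthetic data: what it emulates and what it does not

The simulator evolves codon alignments along a dated tree under the same
GY94 family, with one crucial difference in scaling: all category
generators are divided by the *neutral* (ω = 1) flux, so one unit of
branch length is one expected neutral substitution per codon and the
synonymous rate is identical across selection regimes — the
molecular-clock-on-silent-sites assumption under which the one-rate dating
equation is exact. A designated branch switches from the background ω to
the pseudogenic ω at a known date, giving every simulated dataset a true
T_i. Child states are drawn exactly from the eigendecomposed transition
matrices (endpoint sampling; realized substitution paths are never
needed). Defaults — κ = 3, ω_background = 0.15, ω_pseudogenic = 1.0, 300
codons, neutral rate 0.006 substitutions/codon/MY (≈2×10⁻³ per site per
MY, a typical mammalian neutral rate), slightly AT-rich F1X4 composition —
define the study conditions used in all recovery tests. The default study
tree has 10 taxa with a crown 'mole' pair of age 12.04 MY whose stem
descends from 68.21 MY, mirroring the golden-mole/tenrec calibration pair.

The lesion injector plants frameshift indels, premature stops,
start/termination-codon mutations, splice-site changes, and boundary
deletions at uniformly drawn legal positions (never overlapping; one-codon
buffers) in otherwise clean gene alignments, and emits truth records in
the scanner's own coordinate system, so scanner output can be compared to
truth exactly.

What passing these tests shows: the likelihood machinery agrees with
brute-force enumeration; the estimator recovers ω and switch dates under
the model's own assumptions; the scanner is exact against known lesions.
What they do not show: robustness to alignment error, assembly artifacts,
indel evolution, rate variation across sites or lineages, or violations of
the silent-site clock — real-data phenomena the generator deliberately
does not model (read-level validation and alignment construction are
outside this package's scope).

## Numerical and study-size choices

- Optimization bounds: κ ∈ [0.01, 100], ω ∈ [1e-4, 50], branch lengths ∈
  [1e-7, 20] substitutions/codon, all on log scale.
- Site patterns are compressed before pruning; eigendecompositions are
  cached per (κ, ω) within a fit.
- The end-to-end dating recovery study uses 20 replicates of 10 taxa × 300
  codons with the switch at 26.03 MYA and requires the grand-mean estimate
  within 15% of the transitional branch's 56.17 MY duration.
- The likelihood-ratio type-I-error study uses 500 null simulations of 4
  taxa × 300 codons. Alignment length matters here: the χ²(1) reference is
  asymptotic, and substantially shorter alignments (e.g. 60 codons) show
  the well-documented finite-sample inflation of LRT rejection rates, which
  would measure small-sample behavior rather than the test itself.
- Degenerate inputs: an all-gap row yields a single whole-gene deletion
  record plus a warning; an empty alignment, non-positive path lengths,
  zero-duration rate categories, and incomplete combination grids raise
  structured errors.

## Known limitations

- Site-homogeneous model: no among-site rate variation or site/branch-site
  selection models.
- The two-rate equation assumes the category synonymous rates estimated
  from background and crown-pseudogenic branches transfer to the two
  portions of the transitional branch.
- Dating propagates no uncertainty; the eight-combination spread is the
  only dispersion reported.
- NBR/NMR (absence) evidence cannot be derived from alignments and enters
  only through curated tables.
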