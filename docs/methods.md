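# Methods

This note documents the statistical model behind `slimcons`, the choices
made where the design was genuinely open, and what the synthetic-data
tests do and do not demonstrate about real data.

## Motif model and scanning

A motif is an ordered list of residue classes over the 20 amino acids
(`[YF]xFP` = {Y,F}, wildcard, {F}, {P}). Scanning is exhaustive and
window-by-window: every window whose residues satisfy the classes is
reported, including overlaps, because density statistics need every
occurrence and no biologically motivated collapse rule exists for
overlapping degenerate matches. An `X` (unknown residue) satisfies only
wildcard positions: an unobserved residue cannot confirm a constraint.
Internally all coordinates are 0-based half-open; serialized tables are
1-based inclusive. Built-in patterns: `docking` `[YF]xFP`, `consensus`
`Hx[RK]xx[ST]` (the default used in the proteome-wide analyses),
`consensus_hxr` `HxRxx[ST]`, and `docking_basic` `[YF][KR]FP`. Scans can
be restricted to masked intervals (e.g. predicted disordered segments);
whether to mask is left to the user because motif biology concentrates in
disordered sequence but the unmasked scan is the more conservative
default.

## Conservation score

For a motif instance in the reference protein of an ortholog group, each
non-reference species either **retains** the match — its residues at the
reference-aligned columns still satisfy the pattern, any gap breaking it —
or not. The null model says retention without selection is exactly as
probable as the local background makes it:

- `I_s`: local reference-vs-species identity over a window of `W = 15`
  alignment columns centered on the match, **excluding the match's own
  columns**. Including them would let a retained motif inflate its own
  background and discount itself (an ascertainment artifact we measured
  directly in simulation). Fewer than 5 comparable columns triggers a
  fallback to whole-alignment identity.
- `k`: number of constrained pattern positions (3 for both built-in
  motifs).
- `r_s = max(I_s, q_s^(1/k))^k`: the per-species neutral retention
  probability, floored at `q_s`, the probability that a random window of
  that species' composition matches the pattern (`q_s = Π_j Σ_{a∈class_j}
  f_s(a)`, residue frequencies pseudocounted by 0.5).
- `p_s = r_s` if retained, else 1. A motif in a nearly invariant region
  has `r_s → 1` and contributes nothing — the "high background
  conservation ⇒ low score" discount — while retention across diverged
  backgrounds is surprising and contributes strongly.

The per-match score is `S = Σ_s −ln p_s`; a protein's score for a motif
class is the maximum `S` over its matches (ties broken toward the
smallest start coordinate). `S = 0` exactly when no species retains the
match or every `r_s = 1`.

### Significance of S: a joint retention null on the species tree

`p_s` is two-valued, so the textbook chi-square tail of Fisher's
combination (still provided as `combine_fisher` and reported as
`combined_p_chisq`) is far too conservative as a significance measure:
under the null `E[−2Σ ln p_s] ≤ 2n/e`, far below the chi-square mean of
`2n`, and the rejection rate at any useful α is essentially zero. The
primary `combined_p` is instead the tail probability of `S` under the
fitted retention null, with the mid-p convention for discreteness.

Species are not independent: two species whose paths to the reference
share most of their length retain jointly far more often than the product
of their marginals. Treating them as independent inflated the neutral
rejection rate at α = 0.05 to ≈ 0.08 in simulation (a star phylogeny,
which has no shared paths, gave ≈ 0.04). When the species tree is
available the null therefore draws the retention indicators jointly: per
constrained column, class membership evolves as a lumped two-state
(in-class / out-of-class) Markov chain along the reference-rooted tree —
on an edge of length `u` a substitution occurs with probability
`1 − e^{−u}` and the replacement lands in the class with its composition
mass — conditioned on the reference being in class **and on the tree's
root being in class**. The root condition encodes what "retention" means:
the null hypothesis is that the motif was present in the common ancestor
and has merely persisted neutrally, which is also exactly what the σ = 0
calibration protocol simulates. The joint probability of every retention
pattern is computed exactly by peeling over subsets plus Möbius
inversion (exact up to 14 species; beyond that, and for groups with
species missing from the tree, the independent-Bernoulli null is the
fallback).

The chain needs a family-specific rate scale. It is fitted by regressing
the path costs implied by the **whole-alignment** reference-vs-species
identities on the tree's path lengths: the local `W`-column identity that
drives the discount weights is far too noisy (sd ≈ 0.15) for this, and
its convex log-inversion biased the fitted rate upward. One scalar per
family suffices because the tree fixes relative branch lengths; trees
without branch lengths get unit lengths, the scale absorbing the units.

Calibrated behavior (measured, not assumed): on 8 × 1,000 neutral
(σ = 0) root-planted families under the default simulator settings the
rejection rate at α = 0.05 was 0.051 ± 0.003, with each batch inside the
95% binomial band.

### Density statistic

As a secondary, alignment-free statistic, `density_pvalue` compares each
species' total match count `T_s` in its ungapped sequence with
`μ_s = λ_s + Σ_j r_s(j)` (de-novo expectation plus neutral retention of
each reference match) via the Poisson upper tail `P(X ≥ T_s)`, combined
across species with Fisher's method. Matches that moved within the
protein count here even though they break alignment-anchored retention.

## Enrichment statistics

Contingency tables cross protein classes (conserved-docking versus rest)
with outcomes (consensus match among the top-k most conserved, or
annotated as phosphorylated). Fisher's exact test reports the one-sided
upper tail of the top-left cell and the standard minimum-likelihood
two-sided p; sample odds ratios get the Haldane–Anscombe 0.5 correction
when a cell is zero. Both sidedness conventions are always reported
because neither is canonical for these comparisons. Density comparisons
treat residues as Bernoulli trials (each position a potential motif
start) and are reported per 1,000 amino acids; callers wanting the
window-count correction pass `Σ(L_i − w + 1)` as the residue totals. The
acceptor of a consensus match is its `[ST]` position — the last pattern
position, i.e. `end_1based` in serialized coordinates. Top-k
classification breaks boundary ties toward the lexicographically smaller
protein id and logs the tie, so runs are reproducible.

## Acquisition order

Presence of a motif class in a species is a raw scan hit anywhere in that
species' ortholog (conservation scores are deliberately not reused here:
presence, not selective maintenance, is the character). Missing orthologs
are missing data, not absence — they neither pull gains deeper nor count
as losses. Each class's gain is placed by Dollo parsimony: one gain at
the MRCA of the presence leaves, with the minimal number of loss edges
below it. Dollo is the right parsimony flavor for short degenerate
motifs, which are far easier to lose than to gain twice independently.
Losses can only shrink the presence set, so the inferred gain is always
within the true gain's subtree — never more ancestral than the evidence
and never in a different clade. The ordering call compares the two gain
nodes: an ancestor relation gives phospho-first or dock-first, identity
gives simultaneous, incomparable nodes give undetermined, and a motif
absent everywhere gives no-call. Resolution is per-branch by
construction; "simultaneous" means "on the same branch", not "at the same
instant".

## Synthetic data

The generator emulates families of half a dozen budding-yeast-like
orthologs: a root sequence drawn from a background composition (uniform
by default; a disorder-biased table is provided) evolves down the species
tree, each site substituting with probability `1 − e^{−b}` per branch and
resampling from the composition. Planted motifs are written at a gain
node (root by default) and maintained below it by selection of strength
σ: a substitution that would leave a constrained position's class is
rejected with probability σ, so σ = 1 is class-preserving and σ = 0 fully
neutral. There are no indels by default — rows stack into an exact
alignment, isolating scoring behavior from aligner artifacts — and an
optional deletion mode (geometric-length, inherited gap runs) exercises
gap handling. Everything is driven by one integer seed and is
byte-identical across runs.

Default study conditions, chosen once: the six-taxon tree
`(((Scer:0.10,Sbay:0.12):0.08,Cgla:0.26):0.10,((Klac:0.22,Agos:0.24):0.09,Kwal:0.27):0.13)`
with Scer as reference — branch lengths representative of post-WGD and
related budding yeasts; protein lengths uniform on [200, 500]; planted
consensus acceptors annotated "phosphorylated" at a true-positive rate of
0.8 with false positives on other S/T residues at 0.01, emulating partial
phosphoproteomics coverage. Power and ancestry experiments scale the tree
(`tree_scale` 2–3) so the root-to-leaf depth exceeds 1 substitution/site,
the regime in which neutral retention of background matches becomes rare
enough for discovery to be informative.

Experiment protocols:

- **Calibration** (`calibration_run`): families carry a root-planted
  docking motif with σ = 0; whenever the reference still matches at the
  planted window the match is scored, and families whose reference lost
  it are redrawn until the requested count is reached. The reported
  number is the fraction of scored families with `combined_p ≤ α`.
- **Power** (`power_run`): 50 of 5,000 proteins carry σ = 1 docking
  plants (6 of them also consensus plants); recovery is the fraction of
  planted proteins inside the top-50 docking score list, plus the count
  of dual plants flagged by the dual top-k scatter rule.
- **Ancestry recovery** (`ancestry_recovery_run`): one docking motif
  planted per family at a random tree node with σ = 1 (no losses
  possible); families in which a species *outside* the gain clade carries
  a chance background match are redrawn, because the experiment tests
  gain placement given the presence calls — chance occurrence would make
  100% recovery impossible for any method, and scanner false positives
  are already covered by the calibration experiment. A σ < 1 variant
  verifies that with losses the inferred gain stays within the true
  gain's subtree.

## What the synthetic tests do not show

The simulator draws sites independently with a single rate, uniform
composition, and no indels by default: real proteomes have rate
heterogeneity, domain structure, composition biases, and alignment error,
all of which the ConDens-style discount only partially absorbs. The
joint null's single per-family rate scale assumes the input tree's
relative branch lengths hold for the family; lineage-specific rate shifts
degrade calibration gracefully but measurably. Passing the synthetic
criteria therefore demonstrates correctness of the machinery under its
own model assumptions, not field accuracy on any particular proteome.
Phylogenetic non-independence is handled inside the retention null, but
species still enter the score `S` symmetrically, unweighted by the tree.

## Numerical choices

Composition pseudocount 0.5 (so single-sequence estimates never yield a
zero class mass); identity-window width `W = 15` columns with a
5-comparable-column fallback; retention floored at `q_s` so `p_s` never
drops below the chance of a de-novo match; p-values clamped into
(1e-300, 1]; the exact-null atom lattice merges atoms equal to 9 decimal
places and caps exact enumeration at 14 species; score ties broken by
start coordinate; top-k ties by protein id. Newick input is taken as
rooted exactly as written (branch lengths optional). All Fisher
chi-square tails use the even-degrees-of-freedom closed form evaluated in
log space and are cross-checked against numerical integration in the test
suite.
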