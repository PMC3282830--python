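# Methods

This note documents the models, definitions and design choices behind
compspectra: what each statistic computes, what the simulator emulates, and
where the open design decisions were resolved.

## Problem setting

Compositional heterogeneity — lineages drifting toward different base
compositions — can mislead tree reconstruction. The subtle variant this
package targets is the *symplesiomorphy trap*: the biased lineages
themselves stay correctly placed, but by eroding shared derived states they
make the *unbiased* lineages' retained ancestral states look like
synapomorphies, so a paraphyletic assemblage of unbiased taxa is recovered
as a clade. Detecting the trap therefore needs per-taxon compositional
diagnostics (who is biased?), split-support accounting at the character
level (what kind of positions support each competing grouping?), and a
generative model in which the trap can be produced on demand with known
truth.

## Compositional statistics

Let `mu_Xi` be the frequency of state `X` in taxon `i`, computed over that
taxon's **counted** sites only, and `mu~_X` the unweighted mean of the
per-taxon frequencies across the `n` taxa. Counted means unambiguous,
non-gap, non-missing: gaps (`-`), missing (`?`) and IUPAC ambiguity codes
are excluded from both numerator and denominator. They are
non-observations, not states; this matters because OTU concatenation leaves
large missing blocks, and a pooled-count mean would weight taxa by
coverage. `mu~_X` is the *unweighted* mean of per-taxon frequency vectors
for the same reason — the two definitions differ exactly when coverage
varies.

**RCFV** (relative composition frequency variability):

    RCFV = sum_{i=1..n} sum_X |mu_Xi - mu~_X| / n

The `i`-th summand divided by `n` is the taxon-specific contribution, so
the total is exactly the sum of the per-taxon values (same summation
order). RCFV is zero iff all per-taxon frequency vectors coincide, is
invariant under column permutation and duplication (scale-free), and
applies verbatim to amino-acid alphabets (only the state set changes).

**RCV**, the count-based precursor, is provided for comparison: the same
double sum over absolute state counts `c_Xi`, normalized by `n * Lbar`
with `Lbar` the mean number of counted sites per taxon. The original
normalization is not uniquely fixed by its description; ours is chosen so
that on gap-free, equal-length alignments RCV equals RCFV exactly (the
counts are then `mu * L`), which makes the measure's length-confounding
visible as the *only* difference between the two on real data. The
normalization is stated in all output metadata.

**Class deviations** bin the four nucleotides into two classes (AT/GC, or
purines R = A+G vs pyrimidines Y = C+T) and report binned frequencies and
absolute deviations from the across-taxon mean. With two classes the
deviations of the pair are identical per taxon, so one value is reported.
IUPAC codes that resolve wholly within one class are counted for that
class (`R`, `Y` for the R/Y scheme; `W`, `S` for AT/GC): this makes the
R/Y table equal, per taxon and exactly, to the RCFV-style deviations of
the RY-recoded alignment — a cross-module identity the test suite asserts
to 1e-12.

**Skews** measure directional bias inside a pair:

    skew(X, Y) = (mu_X - mu_Y) / (mu_X + mu_Y)

for the classical strand-asymmetry pairs A-T and G-C and additionally for
the within-purine (A-G) and within-pyrimidine (C-T) pairs, which target
the deamination-driven biases typical of mitochondrial genomes. A zero
denominator yields NaN, an explicit "undefined" marker — never an
exception and never 0, because 0 is the meaningful "balanced" value.
Defined skews lie in [-1, 1] and negate under swapping the pair.

**Codon usage** tabulates 64-codon counts per taxon over frame-annotated
charset blocks. Codon positions are defined relative to each block's
frame, not global coordinates; a trailing partial codon is dropped with a
warning, and codons containing any uncounted symbol are skipped.

## Recoding and masking

RY recoding maps A,G to R and C,T to Y. Ambiguity codes resolving within
one class keep the class; codes spanning both (W, S, K, M, B, D, H, V, N)
become `?` rather than being deleted, so alignment length — and every
coordinate map — stays valid. The operation is idempotent. Masking removes
named blocks and/or per-block codon positions (e.g. saturated third
positions) and returns a new-to-original 1-based coordinate map.

## Split-support spectra

A column supports a directed bipartition (ingroup vs outgroup, both sides
of every split evaluated as ingroup in turn) in one of three mutually
exclusive quality categories: **binary** (both sides monomorphic,
different states), **noisy_outgroup** (ingroup monomorphic, outgroup
polymorphic with a strict-majority state different from the ingroup's) and
**noisy_both** (both sides polymorphic with distinct strict-majority
states). Strict majority means > 50% of the counted states on that side;
ties yield no majority and no support. Taxa with uncounted symbols at a
column are removed before evaluation, and each side must keep at least
`min_side` (default 2) counted taxa.

Because "every subset of taxa" is not a workable candidate space, the
candidate rule is explicit and testable:

* without a group mapping, a candidate ingroup must be **state-class
  complete** — every state present in the ingroup occurs nowhere in the
  outgroup. Monomorphic candidates are thus exactly the state classes;
  polymorphic (category-3) candidates are unions of whole state classes
  possessing a strict-majority state. With four nucleotide states this is
  at most a few dozen candidates per column.
* with a group mapping active, category-3 candidates are instead unions of
  whole taxon groups (restricted to the column's counted taxa), which is
  how named multi-family clades are read off a spectrum.

An `exclusive` flag additionally requires the ingroup's majority state to
be absent from the outgroup; under the class-complete rule this is
automatic, so the flag only bites for group-generated candidates. The test
suite checks the fast implementation against an exhaustive enumeration of
all subsets under the same predicate, for both candidate modes.

`filter_focal` retains splits whose ingroup lies inside the focal taxon
set (2 <= |ingroup| <= |focal| - 1) and, when groups are mapped, only
group-complete ingroups, labelling them with the sorted group names.
`label_hypotheses` reports the per-category counts of the split matching
each named hypothesis exactly — the bar-chart decomposition used to compare
competing sister-group hypotheses.

## Non-stationary simulator

Each branch carries an HKY-style model (transition/transversion ratio
`kappa`, optionally 6 GTR exchangeabilities) with its own equilibrium
composition `pi_b`; `q_ij = r_ij * pi_j`, rows summing to zero, scaled so
the expected rate is 1 at the branch's own stationary vector. Scaling at
`pi_b` keeps branch lengths in expected-substitutions-per-site units during
composition shifts; it is an approximation in that the process enters a
branch away from that branch's equilibrium. The root sequence is drawn
i.i.d. from a root composition; each branch applies `expm(Q_b * l_b)`
site-independently. There is no among-site rate variation in v1 (the
diagnostics under test are composition-based, not rate-based); a gamma
model is the natural extension hook.

Per-branch RNG streams are derived from the master seed and the branch's
descendant-tip signature, so adding a taxon does not reshuffle draws on
unrelated branches. Identical inputs give byte-identical alignments. The
implementation's matrix exponential route is cross-checked in the tests
against independently coded closed-form HKY transition probabilities
(agreement to 1e-12) and against simulated substitution fractions at
L = 1e5 (within 3 binomial SE).

## The trap scenario and its defaults

The preset scenario builds the topology `(P,(T,(Tr,(Am,Al))))` with two
tips per clade: an outgroup analogue P and a four-clade ingroup in which
Am and Al are true sisters and Tr is their true closest relative (so the
true sister-group hypothesis is "TriAA" = {Tr, Am, Al}; the trap's wrong
alternative is "TriTer" = {Tr, T}).

Default study conditions, chosen once on biological grounds:

* `L = 50,000` sites; `delta = 0.15`: the Am stem and subtree shift
  composition by +delta toward thymine and -delta away from cytosine, the
  Al lineage the opposite way — opposite pyrimidine biases of equal
  magnitude.
* `pi0 = (A 0.30, C 0.24, G 0.16, T 0.30)`: guanine rarest, as is typical
  of the coding strand of animal mitochondrial genomes.
* `kappa = 3`, a moderate mitochondrial transition bias.
* branch lengths: 0.02 expected substitutions/site on all conserved
  branches (backbone and P/T/Tr tips) and 0.2 on the biased Am/Al stems
  and tips. The asymmetry is the trap mechanism itself: ancestral states
  survive in the conserved lineages while the long biased branches erode
  them.

With `delta = 0` the scenario degenerates to a stationary simulation, and
the median ingroup taxon-specific RCFV decays toward zero as L grows
(pure multinomial sampling noise, ~1/sqrt(L)).

## What the synthetic data does and does not show

The simulator reproduces the compositional signature of the trap robustly:
opposite C-T skews in the Am- and Al-analogues, and taxon-specific RCFV
contributions that single out exactly the biased tips, in 20/20 seeds at
the default conditions. In the split spectrum, binary support concentrates
on the true clade (~230 positions vs ~10 for either alternative per run),
and the wrong sister-pairing {Tr, T} is the only hypothesis with a
substantial noisy_outgroup excess (~50 positions vs ~0-1 for {T, Am, Al})
— precisely the symplesiomorphy signature: ingroup-monomorphic positions
whose outgroup polymorphism is generated by the biased lineages.

Two features of real data are deliberately not emulated, and they shape
what passing tests can claim. First, sites are i.i.d. with no rate
variation, so *every* candidate split accumulates a uniform noisy_both
background, and erosion occasionally runs all the way back: an apomorphy
that arises on the backbone and survives in T and Tr while both biased
clades revert to the ancestral state produces a genuinely binary pattern
for the wrong pairing (order 10 per 50,000 sites; the ratio of
wrong-to-true binary support tends to a small constant as branch lengths
shrink, so it cannot be eliminated by any realistic parameter choice —
with only four states, eroded lineages are likely to land on a state
already present elsewhere). In rate-heterogeneous real data, conserved
sites are conserved across all taxa, which is why empirical spectra can
show literally zero binary support for wrong groupings. The tests
therefore assert dominance (true-clade binary > 5x either alternative;
wrong-pairing noisy_outgroup > its binary and > 10x the other
alternative's), margins fixed from this mechanism analysis. Second, the
simulator is a generic realization of branch-specific compositional
vectors, not a replica of any particular inference program's
parameterization.

## Numerical and degenerate-input conventions

* `?` and `-` are distinct on input, both uncounted downstream.
* `U` is silently normalized to `T` for nucleotide alphabets (rRNA data).
* A taxon with zero counted sites in the selected columns raises an error
  naming the taxon; callers drop taxa explicitly, never silently.
* Frequency vectors sum to 1 within 1e-12 whenever a taxon has a counted
  site; all oracle comparisons in the tests run at 1e-12.
* Undefined skews are NaN; JSON output preserves them as null.
* Masking that would remove every column is an error, as is a focal set
  smaller than 3 taxa.
* User-facing coordinates are 1-based inclusive everywhere (reports echo
  1-based even though the internal representation is 0-based).

## Known limitations

* The spectrum's candidate rule is a documented reconstruction of a
  split-support method whose exact tie-breaking is not published; both the
  default and the `exclusive` variant are implemented so empirical counts
  can be attempted under each.
* RCV's historical normalization is not uniquely determined; ours is
  labelled in output.
* No amino-acid recoding schemes beyond the nucleotide RY map.
* The published 17-taxon matrices this toolkit's dataset-level numbers
  refer to are not redistributable here; the external comparison in the
  test suite activates only when a user supplies them under
  `data/external/`.
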