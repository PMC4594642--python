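# Methods

## Data model

A karyotype is an ordered block composition per chromosome: each syntenic
block carries the outgroup chromosome label, an optional arm (`p`/`q`) and
an optional fission-segment tag (`a`/`b`/`x`/`y`), concatenated for display
(`2q`, `16a`). Block triples are unique genome-wide within a karyotype's
autosomes. Positions and indices are 0-based; a centromere is located at a
junction index between blocks (0 = before the first block), with a
within-block flag when paint resolution cannot place it at a junction.
Sex chromosomes are parsed and carried along but excluded from association
characters and event counts: Y-chromosome paints are typically unavailable
in this kind of dataset and the X is conserved, so including them would mix
evidence of different quality.

Syntenic associations — adjacencies of two blocks on one chromosome — are
unordered and orientation-blind (`"12+2q"`, smaller label first), because
painting carries no reliable orientation signal. Inversion annotations are
chromosome-level notes, not characters.

Dated trees are rooted Newick plus a separate `label → (age, age_se)`
table (Newick has no standard slot for ages or their errors). Internodal
time of a branch is `parent.age − child.age`, required strictly positive.

## Ancestral reconstruction

Associations are unordered binary characters optimised independently with
two-pass Fitch parsimony; gains and losses weigh equally. Polarity comes
entirely from the outgroup: when the top-down pass leaves the root
ambiguous, the outgroup's observed state is chosen, making assignments
deterministic (no ACCTRAN/DELTRAN choice arises for binary characters once
the root is pinned). The per-character score is the minimum number of state
changes; a score above 1 flags homoplasy. Leaves without data are treated
as missing ({0,1}). Branch lengths play no role in parsimony; ages are
consumed downstream by the rates module.

The module reports association sets per node and deliberately does not
assemble whole ancestral chromosomes: when two characters sharing a block
conflict, no published rule resolves them, so assembly is left to the user.

## Event counting

The derived karyotype is decomposed into maximal fragments — runs of blocks
contiguous (adjacent in either order) on a single ancestral chromosome.
Fusions = Σ over derived chromosomes (fragments − 1); fissions = Σ over
ancestral chromosomes (fragments it was split into − 1), with ancestral
chromosomes entirely missing from the derived map (paint censoring)
contributing nothing. When every ancestral block is represented, the
balance `n_derived = n_ancestral + fissions − fusions` is an identity.
Derived segment tags are matched to the untagged ancestral block, so a
block split across two chromosomes counts as one fission. Orientation-blind
adjacency can under-count inversions; inversions and centromeric shifts are
out of scope of the rate counting by design. Translocations are not modeled
as atomic events — a reciprocal translocation appears as one fission plus
one fusion, so totals are fusion+fission equivalents and may overstate the
number of mutational events when translocations are common.

On histories *without* breakpoint reuse these counts equal the true event
number (each event leaves a permanent adjacency trace); with reuse they are
a lower bound. Both properties are exercised against the generator's
ground-truth logs.

Fusion junctions are classified from centromere annotations: Robertsonian
when both joined fragment ends carry their ancestral centromeric junctions
and the derived chromosome is biarmed; telomeric/tandem when both ends are
non-centromeric ancestral termini; otherwise unspecified (missing
annotation degrades the call, never errors). Single-block fragments have
orientation-ambiguous ends; classification accepts either junction, which
is exact for the canonical centric-fusion case and conservative elsewhere.

## Rates

`R = n_changes / t` in changes per myr, with bounds `n/(t ± SE)`. The t−SE
bound is reported as-is — negative or infinite when SE ≥ t — with a
`nonphysical` flag rather than clamped, so published tables of this kind
can be reproduced verbatim. Display rounding is round-half-even to 4
decimals; published tables of this kind mix rounding and truncation, so
comparisons should use the printed precision, not exact string equality.

Branch-time SEs: node age SEs are combined in quadrature
(`sqrt(se_parent² + se_child²)`), the standard error of a difference of
independent estimates. Published per-branch SEs whose derivation from node
CIs is not stated can instead be supplied directly (the CLI `rates`
subcommand accepts explicit `time`/`time_se` columns, which take
precedence over tree-derived values).

"Stasis"/"Evolution" labels are narrative annotations, not analysis:
Stasis when n ≤ 1, Evolution when the central rate exceeds 2 changes/myr
(both configurable), "variable" otherwise.

`per_generation_rate(R, g) = R × 10⁻⁶ × g` converts to fixations per
species per generation. Generation length is a sensitivity input spanning
2–10 years by default — the plausible range for small bats — because no
single authoritative value is printed with the source data.

## Underdominant fixation and Nₑ inversion

Fixation probability of a rearrangement with symmetric heterozygote
disadvantage s (fitnesses 1 : 1−s : 1), from initial frequency p₀:

    P(Nₑ, s, p₀) = ∫₀^p₀ ψ(x) dx / ∫₀¹ ψ(x) dx,   ψ(x) = exp(4 Nₑ s x(1−x))

computed by adaptive quadrature (relative tolerance 1e-10) on the shifted
integrand `exp(−4 Nₑ s (x−1/2)²)` — the same ratio after factoring out the
integrand's maximum, which keeps the evaluation overflow-free at any Nₑs.
At extreme Nₑs (> ~700) the ratio underflows to 0.0, the correct
double-precision limit, and the solver handles it transparently. The
neutral limit s = 0 returns p₀ exactly.

Rate equation: `R_gen(Nₑ) = 2 N u P(Nₑ, s, 1/(2N))` with census N = Nₑ by
default (an Nₑ/N ratio parameter exists, default 1 — no published ratio
accompanies the data this targets); p₀ = 1/(2N) is a single new mutant.
`solve_ne` inverts it on Nₑ ∈ [2, 10⁷] by Brent's bracketed method on
log Nₑ (monotonicity checked at the bracket ends; solved residual enforced
≤ 10⁻⁶ relative). Targets at or above the rate at Nₑ = 2 return
`supra_neutral_no_solution` (underdominance cannot reach the neutral
rate); targets below the rate at the bracket ceiling return
`below_minimum`. The primary computation is the exact quadrature, not the
Laplace/erf closed form `2u √(Nₑs/π) e^(−Nₑs) / erf(√(Nₑs))`: that form
holds only in the joint limit s → 0 with Nₑs large — at fixed s it omits a
factor `(e^{2s}−1)/(2s)` (≈ 1.11 at s = 0.1) — and the sensitivity grids
include small-Nₑs cells near the neutral bound where it fails entirely.
It is retained as a cross-check inside its validity regime.

## Wright–Fisher oracle

One generation: deterministic viability selection on Hardy–Weinberg
genotype frequencies, post-selection allele frequency
`p' = (p² + pq(1−s)) / (1 − 2spq)`, then binomial sampling of the 2N
allele copies. Replicates advance in lockstep on one seeded generator
(bit-reproducible per seed); fixation fractions get Clopper–Pearson 95%
intervals. The simulator is validated against the exact absorbing-chain
fixation probabilities of the same finite Markov chain.

The diffusion formula is exact only in the scaling limit: against the
finite chain it overestimates fixation probability with an O(1/N) bias
that grows with s (ratio ≈ 1.12 at N = 20, s = 0.1 and ≈ 1.32 at N = 50,
s = 0.1). At 2×10⁵ replicates this bias is resolvable — about 4 and 1.7
Monte-Carlo SEs respectively — so simulation-vs-diffusion comparisons at
s = 0.1 sit at the edge of a 3-SE band by the physics of the
approximation, not by implementation error. For the Nₑ inversion this bias
is conservative: the diffusion slightly overstates fixation at a given Nₑ,
so inverted population sizes are, if anything, slight overestimates, and
upper-bound conclusions ("Nₑ below N") are unaffected.

`deme_fixation_experiment` is an exploratory, deliberately minimal
individual-based model of very small demes: monogamous random pairs,
Poisson offspring, viability selection against heterozygotes, hard cap at
the founding size, extinction below two adults. Demes that lose the
rearrangement under supercritical demography (≥ 2 offspring per mating)
are scored as surviving without further simulation; under subcritical
demography they are followed to their near-certain extinction. It checks
directions (fixation needs small founder numbers, weak underdominance and
high fecundity; single-offspring demes below ~10 founders collapse), not
any published simulation's numbers.

## Synthetic histories

The generator evolves a root karyotype down a dated tree with independent
Poisson(rate × branch time) fusion and fission counts per branch, applied
sequentially in shuffled order. The root has one outgroup "colour" per
chromosome, split into 1–4 uniquely tagged blocks (`a,b,x,y`) — one colour
per ancestral chromosome is what makes paint emulation meaningful
downstream. Fusions join two uniformly chosen chromosomes at uniformly
chosen ends; fissions split a uniform chromosome at a uniform junction,
falling back to splitting an untagged block into `a`/`b` halves when no
junction is available; an inapplicable event is a logged skip, never an
error. Deeper sub-segment labels are not generated (the field's `a/b/x/y`
naming bounds resolution at 4 blocks per ancestral chromosome).

With breakpoint reuse disallowed (the default), fissions only break
ancestral adjacencies and fusions never (re)create one, so every event is
permanently countable and the counting module recovers per-branch truth
exactly; with reuse allowed, counted ≤ true. Every branch log replays from
the parent karyotype to the child exactly — the invariant the tests sweep
over 100 seeds. Regime presets ship as flat config files
(`presets/stasis.cfg` ≈ 0.02 events/myr, `presets/burst.cfg` ≈ 6
events/myr) mirroring the observed extremes.

`emulate_painting` censors a map the way limited probe resolution does:
maximal same-colour runs (paint segments) shorter than the detection
threshold are absorbed into their larger neighbour and their blocks vanish.
A single-run chromosome is returned unchanged (there is no neighbour), so
a same-colour multi-block run — already one paint segment — is not
collapsed further. Because fragments never span colours when each
ancestral chromosome is one colour, censoring removes whole fragments and
event counts can only decrease: painted data under-report rearrangements,
never over-report them.

## What the synthetic data do and do not show

The generator reproduces the structural features the pipeline depends on —
block uniqueness, adjacency characters, burst-vs-stasis rate regimes
(branches with 0 to tens of events), fission-segment labelling, paint
censoring. It does not emulate inversions or centromeric shifts (excluded
from counting anyway), chromosome-size constraints, meiotic-drive biases in
which fusions fix, or hybridisation noise in block boundary placement.
Green tests therefore certify the algorithms and their contracts on
clean painting-like data, not the wet-lab error model of real
hybridisations.

## Problem sizes in the test suite

Default runs use 2×10⁵ Wright–Fisher replicates per comparison cell, 500
random parsimony instances (≤ 6 leaves) against exhaustive enumeration,
1000 synthetic ancestral/derived pairs for the balance identity, 40-seed
recovery sweeps, and the full 162-cell Nₑ sensitivity grid per lineage —
sizes chosen so the whole suite completes in well under a minute on one
CPU while keeping Monte-Carlo standard errors small relative to every
tolerance tested.

## Known limitations

* Counting is parsimony-style and orientation-blind: minimal event numbers,
  lower bounds under breakpoint reuse, translocations counted as
  fission+fusion pairs.
* The Nₑ model assumes a homogeneous fixation process along a branch; the
  burst-then-stasis pattern that motivates the analysis violates that
  assumption, so inverted Nₑ values are long-term effective sizes under the
  model, not literal census history.
* Fusion classification requires junction-level centromere annotations;
  within-block centromeres degrade calls to "unspecified".
* The homology-table dialect is this package's own (painting supplements
  are rarely machine-readable); it is deliberately trivial TSV.
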