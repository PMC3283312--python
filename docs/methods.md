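# Methods

## Model and assumptions

The data model is a pair of binary sequences (G, H) indexed by a finite
interval [0, N), with the invariant g(i) + h(i) ≥ 1: both members of a
duplicate pair are never deleted. The homogeneous process on the integers
is approximated by a large interval (default N = 100,000; tests also use
300,000 to confirm edge effects are negligible). Positions are 0-based.

A deletion event draws an anchor uniformly over currently eligible
positions (one-sided: g(i) = 1; two-sided: positions still duplicated), a
target homeolog with probability φ (two-sided only), and an excision
length a from the geometric law γ(a) = (1/µ)(1 − 1/µ)^(a−1). The scan
converts 1s to 0s rightward from the anchor, skipping positions already 0
in the target (excised DNA is invisible), and in the two-sided model stops
— truncating the event — at the first position that is single copy on the
other homeolog. Events are applied sequentially; no continuous-time clock
is modelled, since event rates cancel out of every observable considered
here. The discrete-event embedding of a constant per-site rate is exactly
the uniform-over-eligible anchor choice, implemented by rejection
sampling, which leaves the conditional law unchanged.

Draw order per event is fixed (anchor attempts, then target, then length)
from a single `random.Random(seed)` stream, so a configuration and seed
reproduce the event log exactly.

## Run statistics

The consolidated sequence G + H alternates single-copy runs (value 1) and
duplicated runs (value 2). Every event's deleted and skipped positions
form one contiguous single-copy block, so each event belongs to exactly
one final run; r per run is obtained by counting events whose first
deleted position falls inside it (both homeologs' events, in the two-sided
model). By default the two runs touching the interval boundary, and runs
containing a boundary-truncated event, are excluded from distributions so
that finite-interval statistics estimate the boundary-free process; the
flag can be disabled to check the (negligible) difference.

Empirical means of single-copy and duplicated runs are reported as plain
means over included runs. Because the two run counts on an interval differ
by at most one, the conservation identity
mean_single = (1 − θ)/θ · mean_duplicated holds to O(1/R); the test suite
checks it at 5% pooled over 20 replicates per (µ, θ) condition.

The negative-binomial mixture Σ_r π(r)·NB(l; r, 1/µ) (NB on support
l ≥ r, the sum of r geometrics, mean rµ) is provided as the independence
approximation to the single-copy run-length law. It is deliberately tested
as an approximation: simulated runs conditioned on r deviate from it
(short events are over-represented in r = 1 runs), because the events
composing a run are not independent draws.

## Recurrence for π(r)

For the one-sided model only. Undeleted run lengths ρ are taken geometric
with mean E_ρ = θN/R (each event drops a uniformly placed demarcation
among surviving loci, so gaps between demarcations are geometric); this is
a modelling assumption of the recurrence, not an extra approximation layer
— with it, the five event-type probabilities reduce to closed forms in
E_ρ and µ (derivation in `recurrence.py`; a brute-force truncated triple
sum over run length, anchor offset and excision length serves as an
independent oracle in the tests). No series cutoff is therefore needed for
the probabilities themselves.

Bookkeeping per event: type A adds a run with r = 1; B and C move a
π-distributed run from r to r + 1; D and E draw two runs independently
from π and replace them by one with r + s + 1. Mergers of three or more
runs ("other") are tracked as accumulated probability mass but not fed
back, so the recurrence is accurate for moderate θ and drifts once
multi-run mergers become common (θ below roughly 0.3); tests assert
agreement with simulation (within 0.07 absolute on p_A, p_B + p_C,
p_D + p_E for µ = 2) only for θ ≥ 0.4.

Numerical choices: π is carried on support r = 1..r_max (default 200) and
renormalized; mass pushed past r_max is accumulated and warned about above
1e-6. Each step applies Λ events with the same probabilities; θ decreases
by Λµ/N (the expected excision per interior one-sided event) and
E_ρ' = θ'N/R', which re-satisfies the conservation identity after every
step. The default Λ deletes 0.1% of the remaining undeleted mass per step,
favouring accuracy over speed (halving it changes the final π by < 1e-3
total variation in the tested regime); a step driving any π mass or the
run count negative raises instead of clipping. Initialisation starts from
a short burn-in (10 runs of r = 1 just below θ = 1) because the
probabilities are degenerate at exactly θ = 1.

## Inference

θ from gene counts: with n genes and m single-copy genes, pairs
P = (n − m)/2, ancestral loci L = P + m, θ = P/L. The packaged 15-genome
survey table reproduces its printed 1 − θ values from (n, m) at printed
precision for 14 of 15 rows; the N. castelli row prints 0.88 where its own
counts give 0.8748, a one-ulp inconsistency in the printed table that the
regression tests document rather than hide. The table's final column is
the observed mean AU run length ū, the quantity the rearrangement
correction consumes; the rearrangement distance d is always user input.

The response surface maps a (µ, θ) grid to the simulated mean single-copy
run length with Monte-Carlo standard errors; mean run length is strictly
increasing in µ at fixed θ, so linear interpolation in θ followed by
monotone inversion in µ at an observed ū yields µ̂. The ±1 SE interval is
propagated through the same inversion and labelled heuristic — no formal
inferential procedure is attached to run statistics here. Observed run
lengths at or beyond the grid's extreme curves return flagged boundary
estimates (e.g. "µ ≤ smallest grid value"), which is also how the method
expresses that a data set carries no evidence of µ much greater than 1.

Rearrangement correction: assuming the observed AU length law is geometric
with mean ū and an AU of length u survives rearrangement with probability
(1 − αD)^(u+1) (u + 1 internal adjacencies), dividing out the survival
leaves a geometric with ratio z = (1 − 1/ū)/(1 − αD) and mean
ν = 1/(1 − z) ≥ ū. The default α = 0.5 is exposed as a flag; the validity
bound αD < 1/ū is enforced with an explicit divergence error because the
procedure is very sensitive to α near that bound.

## Synthetic descendants and AU scanning

The generator runs the two-sided simulator, lays the survivors of G and H
on two chromosomes with deleted genes removed and survivors re-indexed
(gap-free: excision is invisible), assigns two-member families to
surviving pairs, and applies a chosen number of random segment inversions
(uniform endpoints on a uniformly chosen chromosome, orientations
flipped). Inversions are the only rearrangement type generated — breaking
adjacencies is all the survival correction models, and translocations or
transpositions would add nothing the correction distinguishes.

The AU scanner takes paralogy (family_id) as given. Anchors are members of
exactly-two-member families; a candidate segment lies between consecutive
anchors on a chromosome, requires the two flanking anchors to share
orientation (per chromosome, as the definition states; relative
orientation between chromosomes is unconstrained), and is rejected if any
interior gene belongs to a family of size ≥ 2 (its paralog necessarily
lies outside the unit). Two segments bounded by the same family pair and
jointly using all four family members form one AU, reported maximal, with
u = s1 + s2; the two regions may lie on one chromosome (flagged). AUs with
u = 0 (adjacent duplicate pairs) are reported but excluded from the
geometric fit of the length distribution.

What passing tests show — and what they do not: the generator emulates
two-sided fractionation over two chromosomes plus inversions with
uniformly chosen breakpoints. Real genomes add unequal chromosome numbers,
translocations, tandem duplications, annotation noise in family
assignments, and rate heterogeneity along the genome; recovery results on
synthetic data therefore validate the machinery and the correction's
internal consistency, not the realism of the null model for any particular
lineage.

## Problem sizes and defaults

Simulation-based tests use the model's stated study conditions: interval
100,000 (300,000 for the edge-effect control), 20 replicates per
condition, µ ∈ {2, 3, 6, 11} (plus µ = 1 for closed-form checks) and
θ ∈ {0.5, 0.3, 0.1}. Response surfaces use 3 replicates per grid point
(2 for the two-sided surface at N = 50,000 used in the end-to-end
recovery check); the synthetic-descendant recovery uses 20,000 ancestral
loci and 600 inversions, keeping the measured per-adjacency disruption
probability safely below the correction's divergence bound.

## Known limitations

- The recurrence neglects ≥ 3-run mergers and is one-sided only; its
  divergence from simulation at small θ is expected and asserted as such.
- ρ is modelled as geometric inside the recurrence; simulated ρ passes a
  pooled goodness-of-fit test in the tested regimes, but this is an
  assumption, not a theorem, near percolation.
- The µ estimator's interval is heuristic (propagated surface SEs), and
  the rearrangement correction inherits the arbitrariness of α.
- Fractionation bias (φ ≠ 0.5) is a simulation knob only; no inference
  about bias, and no hypothesis tests of geometric-versus-gene-by-gene
  deletion, are implemented.
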