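# Methods

## Problem and scope

`fragspec` addresses three desk-scale tasks in small-molecule tandem mass
spectrometry (ESI-MS/MS): predicting the [M+H]+ / [M−H]− product-ion
spectrum of a neutral structure at low (10 V), medium (20 V) and high
(40 V) collision energies; annotating the peaks of observed spectra with
enumerated fragment structures; and ranking a list of candidate
structures against observed spectra. All three are built on the same two
components: a combinatorial fragment enumerator and a trainable
probabilistic model of competing fragmentation events. The package ships
no pre-trained weights for real instruments — parameters are learned
from (molecule, spectrum) pairs by EM, and a fixed set of synthetic
reference parameters drives the test benchmark.

## Fragment enumeration

The precursor is the intact molecule; ion m/z is neutral-fragment mass
± the proton mass (1.00727646 Da, electron mass folded in, so the
[M+H]+/[M−H]− gap is exactly two proton masses). Enumeration proceeds
breadth-first to a configurable depth (default 2):

- every acyclic heavy-atom bond is broken once; rings are opened by
  jointly cleaving each pair of bonds within the same smallest ring
  (no triple cleavages);
- both sides of a disconnection are tried as the charge-retaining
  fragment;
- each side is emitted at net hydrogen offsets {−1, 0, +1} relative to
  homolytic cleavage, and only even-electron species are kept. The
  even-electron test is a parity rule: with per-atom valences frozen
  from the precursor, a fragment survives iff its free-valence deficit
  is even and its hydrogen count fits the available slots. Under this
  rule single-bond homolysis survives only at offsets ±1 and two-bond
  ring opening only at offset 0.

Fragment identity is the pair (canonical heavy-atom skeleton SMILES,
total hydrogen count). Hydrogen *placement* after a rearrangement is
chemically ambiguous, so fragments differing only in where the migrated
hydrogen sits are merged into one node; ion masses always come from the
exact tracked elemental formula, never from the skeleton SMILES. This is
deliberately a combinatorial enumeration, not mechanistic chemistry: it
overgenerates (e.g. bare-heteroatom fragments) and relies on the
probabilistic model to decide which events matter.

Node numbering is deterministic (BFS level order, ties by ascending ion
mass then canonical key), graphs are capped at 10 000 nodes with a hard
error, and two builds of the same input serialize byte-identically.

## Transition model

Fragmentation is a d-step Markov chain on the graph (default d = 2,
per energy). From node *i* the ion either stays put, with score equal to
a scalar bias θ_b, or takes transition *e*, with score θ_f · Φ(e); the
move distribution is the softmax of these scores. Φ is a 14-dimensional
cleavage feature vector: broken-bond order, aromatic-bond flag,
ring-cleavage flag, net H offset, indicator flags for common neutral
losses (H2O, CO, CO2, NH3, CH4, CH2, HCOOH, other), neutral-loss mass
scaled by 1/100 Da, and the heteroatom count of the charge-retaining
side. The marginal occupancy after d steps is the predicted peak
intensity distribution. Three independent single-energy models are kept
(low/medium/high); no parameters are shared across energies.

### EM training

Each unit of normalized observed peak intensity is treated as the
observation "the terminal chain state lies in the set of graph nodes
within mass tolerance of this peak". The E-step soft-assigns that
intensity to matched nodes in proportion to the current marginals —
which is the exact posterior for this observation model — and computes
expected stay/transition counts by a forward–backward pass over the
d-step chain. The M-step maximizes the expected complete-data
log-likelihood over θ (an L2-penalized weighted softmax regression) by
full-batch gradient ascent: counts normalized to total 1 so the step
size is scale-free, learning rate 0.1, 50 inner steps, halving
backtracking if the inner objective would decrease, penalty λ = 0.01.
The reported trace is the penalized observed-data log-likelihood, which
EM makes non-decreasing up to numerical slack; convergence is declared
when the gain drops below 1e−4. Peaks matching no node are skipped with
a warning (or raise, per configuration). The λ = 0 configuration
recovers the closed-form Bernoulli MLE exactly in the one-transition
case; with λ > 0 estimates shrink slightly toward zero, which is
intended.

Standard errors in `SingleEnergyResults.bse` come from a central-difference
numerical Hessian of the penalized observed log-likelihood; they are
reported as NaN where the Hessian is not negative definite (common when a
feature does not vary in the training graphs).

## Prediction, selection, adducts

Per energy: probability-prune the graph (nodes with terminal marginal
below 0.001 are dropped, root paths kept — the threshold is a
reimplementation choice, documented as such), recompute marginals on the
pruned graph, pool probability mass of nodes whose enumerated masses
coincide within 1e−5 Da (computed masses, so only exact collisions
merge), and rescale to base peak 100. Display selection keeps the
smallest descending-intensity prefix holding ≥ 80% of the total
intensity, then clamps the count into [5, 30] (never more than
available); intensity ties break by ascending m/z. Note the 80% rule is
relative to the current total, so re-selecting an already-selected
spectrum can shrink it further — selection is a display step, not a
projection.

Non-protonation adducts ([M+Na]+, [M+K]+, [M+NH4]+, [M+Cl]−,
[M+FA−H]−; table extensible via config) add a single extra peak at the
adduct precursor mass, carrying the protonated/deprotonated precursor's
intensity (the model cannot score adduct ions); adducts never propagate
to daughter ions, and in annotation only the precursor node may match at
the adduct mass.

## Annotation and identification

A peak matches a node when |Δm| ≤ max(abs, ppm·mz·1e−6); defaults
0.01 Da / 10 ppm (Q-TOF-like accuracy; both configurable). Candidates
for a peak are ordered by marginal probability and scored by
explained intensity — the peak intensity split across candidates in
proportion to their marginals, so per-peak scores sum to the peak
intensity. The pruned graph reported with annotations is induced by the
union of matched node ids plus root paths.

Identification filters candidates by precursor mass (±Da or ±ppm,
over the selected adducts), predicts the selection-truncated spectra of
each candidate at each provided energy, and averages a set Jaccard score
over energies: peaks paired greedily, closest mass difference first,
each peak used once; score = matches / (union size). Intensities are
ignored by the default score; an intensity-weighted variant is available
behind a flag. Ties rank by ascending reference id; at most 100
candidates per run; unparsable candidates score 0 with a warning.

## Synthetic benchmark

The generator builds random heavy-atom trees (elements drawn with C
weighted 3:1 over N and O, 3–8 heavy atoms) with one extra ring bond in
30% of molecules, hydrogen-filled to valence, deduplicated by canonical
SMILES. Reference "true" parameters share one chemically plausible
feature-weight vector (water/ammonia losses favored, heavy losses
penalized) with a survival bias falling from +3 (low) to −1 (high
energy), so precursors survive gentle collisions and shatter at 40 V.
Observed spectra are the predicted spectra plus noise: 5% peak dropout
(never the precursor), Gaussian m/z jitter of 0.002 Da, and one spurious
uniform peak in 10% of spectra.

The benchmark (30 molecules, EM from zeros, 15 iterations) supports two
end-to-end properties: spectra predicted under the re-trained parameters
match those under the generating parameters (mean energy-averaged
Jaccard ≥ 0.8), and identification against the full library ranks the
true molecule first in ≥ 80% of noisy queries. What this does *not*
show: the generator samples from the same model family that is being
fitted, uses clean single-charge, single-isotope peaks, and small
molecules only — so passing says the machinery is self-consistent and
numerically sound, not that it reproduces real CID chemistry or
instrument intensity statistics.

## Numerical and design notes

- All randomness flows through explicit seeds; reruns of any CLI
  subcommand are byte-identical (fixed-precision writers: m/z 5 dp,
  intensity 2 dp, scores 4 dp, UTF-8, Unix newlines).
- Softmaxes are computed with max-subtraction; marginal vectors sum to 1
  to ≤ 1e−9 and are validated against dense kernel powers in tests.
- Probability pruning is implemented as an exhaustive-marginal filter
  plus root-path closure, equivalent at depth 2 to pruning during
  expansion; the on-the-fly variant is an optimization left out at this
  scale.
- Charged input structures are rejected (the precursor must be neutral);
  disconnected structures are parseable (mass arithmetic is additive)
  but rejected as precursors.
- Supported elements: C, H, N, O, P, S, F, Cl, Br, I (+ Na, K for
  adduct arithmetic); anything else errors loudly by element name.
- Known limitations: no isotope patterns, no stereochemistry-aware
  identity, no tautomers, no mechanistic bond-energy filtering, ring
  opening limited to bond pairs within one smallest ring, hydrogen
  rearrangement limited to ±1.
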