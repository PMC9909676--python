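# Methods

## Problem setting and model

EI–MS spectra of small molecules are modelled as observations of a latent
probability distribution over molecular fragments.  Writing a molecule as a
graph *M* = (*V*, *E*) with *N_A* atoms (hydrogens always explicit), a
fragment is represented at one of two abstraction levels:

* a **chemical subformula** — a count vector over the element universe
  (H, C, O, N, F, S, P, Cl), componentwise ≤ the molecular formula; or
* an **atom subset** — a subset of the molecule's vertices (bond
  connectivity inside the subset is deliberately ignored; the observable
  mass peaks of a fragment depend only on which atoms it contains).

Either representation determines the fragment's mass-peak distribution
exactly, so a probability distribution *p* over fragments maps to a
spectrum through a fixed, exact observation model:

    spectrum = L2-normalize( Σ_i p_i · bin( isotope_distribution(formula_i) ) )

The learning problem is to predict *p* from the molecular graph.  Because
*p* lives on enumerable candidates with known exact masses, the same model
renders spectra at any resolution by changing only the binning.

### Candidate enumeration

**Subformulae** are enumerated by the Cartesian product of the per-element
count ranges 0..c_e; a formula with counts (c_1, …, c_8) has ∏(c_e + 1)
subformulae (C6H12O6: 7·13·7 = 637).  The empty formula is retained so the
product identity holds exactly; it has no observable peaks.  Enumeration is
deliberately structure-blind — no valence or connectivity feasibility is
imposed.

**Atom subsets** come from breaking every unordered combination of up to
*d* bonds simultaneously and collecting the connected components (default
*d* = 3; two removals are needed to open a ring, which combination
enumeration handles exactly).  Unordered combinations avoid the factorial
growth of ordered break sequences without losing any subset.  "Exhaustive
hydrogen rearrangement" is operationalised as emitting, for each subset,
every variant obtained by adding up to `max_h_transfer` hydrogens from
outside and/or removing up to `max_h_transfer` hydrogens inside (default
2, covering single and double H transfer; each concrete hydrogen choice is
a distinct mask).  All bonds including X–H are breakable by default, with
a heavy-bonds-only switch.  Lone-hydrogen subsets are kept by default.
Deduplication is by atom mask; if the deduplicated pool exceeds
`max_subsets` (default 12288, matching the dataset filter) a seeded uniform
subsample is drawn that always retains the full-molecule subset.  Ring
*rearrangements* (e.g. the tropylium pathway of toluene) are not generated
— a known recall limitation of subset enumeration; the formula lattice
still contains such fragments' formulas.

### Observation model

Isotope masses and natural abundances for the 8 elements are pinned as
literals (standard IUPAC/CODATA values) so results are bit-stable across
chemistry-toolkit versions.  A formula's peak distribution is the iterated
convolution of per-element single-atom distributions (binary
exponentiation per element), merging peaks whose masses agree within
1e-9 Da (merged mass = probability-weighted mean).  Peaks below
`prune_below` (default 1e-6) are dropped **without renormalization**, so a
conservation check (total retained probability ≈ 1) can detect
over-pruning; tests and conservation checks use `prune_below = 0`, where
total probability is exact.

Binning assigns each peak to the nearest bin center k·resolution; a mass
exactly half-way between centers goes to the higher bin (implemented with
a 1e-9 relative nudge that also absorbs float fuzz).  Binning conserves
total intensity exactly.  Singly charged fragments are assumed throughout
(m/z = mass); the electron mass is neglected.

### Networks

The backbone is a relational message-passing GNN: per layer, one weight
matrix per bond-order channel (1, 1.5, 2, 3) plus a self weight, sum
aggregation over neighbours, ReLU, residual connections once widths match.
Input features per atom: element one-hot (8), heavy-degree one-hot (0–4),
attached-H count, aromatic flag, ring flag, formal-charge slot (17 total).
Full-size defaults are 8 layers × width 256; the desk-scale experiments in
the tests use 4 × 64.

*Formula head.*  Candidates are run-length ("N-hot") encodings: per
element a block of `maxelem` bits whose first `count` bits are set
(default `maxelem` 48 = the atom-count filter cap; the desk-scale
experiments use 24, enough for any element count in ≤ 8-heavy-atom
molecules).  Encodings act as queries in a single-head scaled dot-product
attention over atom embeddings (atoms provide keys and values), giving one
attended atom summary per formula.  [summary, encoding] feeds an MLP with
two hidden layers (width `mlp_hidden`, then half that); scores are
softmaxed over the candidate axis.  The softmax output is then multiplied
by a positive per-formula gate — softplus of a linear map of the attended
summary — and renormalized.  A strictly per-molecule scalar gate would
cancel under the renormalization, so the per-formula reading is the only
one with effect; the gate lets the model rescale scored probabilities
without routing everything through the softmax logits.

*Subset head.*  A subset's embedding is the mean of its member atoms' rows
of *X_d* (indicator-matrix product); [embedding, formula encoding] feeds
the same two-hidden-layer MLP, softmaxed over subsets.

Output layers (scores and gates) are zero-initialised, so an untrained
model emits the uniform distribution over candidates — a useful anchor for
tests and a neutral starting point for the softmax.

### Training

Loss: Σ_bins (I_pred^w − I_obs^w)² on the union bin grid, with both
spectra L2-normalized and default power w = 0.5 (< 1 damps dominant
peaks).  Inside the autodiff graph the power is computed as (x + 1e-12)^w
to keep the w < 1 gradient finite at empty bins.  Optimisation is Adam
over seeded, shuffled minibatches (default lr 5e-3, batch 32); per-example
gradients accumulate within a minibatch before each step.  Per-molecule
candidate sets, encodings, and binned fragment-spectrum matrices are
precomputed once, so a training forward pass is a handful of small dense
matmuls.  Training is deterministic given the config seeds
(single-threaded numpy).

The gradients come from a compact reverse-mode autodiff engine written
over numpy arrays (`autodiff.py`), verified against central finite
differences in the test suite.

## Synthetic data: what it emulates and what it does not

`synth.py` grows random valence-respecting molecules over {C, O, N}
(+ hydrogens), ≤ 10 heavy atoms (kept small so exhaustive oracles are
feasible), with occasional double bonds and ring closures, deduplicated by
canonical SMILES and filtered by the dataset admission rules (≤ 48 atoms,
≤ 4096 subformulae, ≤ 12288 subsets).

The *planted model* scores each fragment formula reachable by subset
enumeration with a fixed random linear function of cheap descriptors
(normalized element counts, fragment size, H-count parity) and softmaxes
at a temperature; the spectrum is the exact observation-model rendering of
that distribution.  Two deliberate choices make recovery well-posed for
both heads: descriptors use only formula-level information, and the
support is the subset-reachable formula set (the subset head cannot place
mass on formulas its subsets never produce, while the formula head's
candidate lattice is a superset).  Consequently the planted target is
exactly realizable by both heads and the loss at the planted distribution
is identically zero.

Replicate noise is multiplicative log-normal intensity jitter plus
Bernoulli peak dropout (base peak always kept), then L2 renormalization —
a stand-in for run-to-run and apparatus-to-apparatus variability.

What passing on this data shows: the enumeration, observation model,
differentiable training loop, metrics, and matching protocol are correct
and can recover a distribution that genuinely generated the spectra.  What
it does not show: performance on real EI–MS fragmentation chemistry.  Real
fragment propensities are not linear functions of formula descriptors,
real spectra contain rearrangement products outside the subset space, and
real libraries are orders of magnitude larger and more diverse.

## Metrics and matching conventions

* Weighted dot product: cosine of m^a·I^b vectors on the union grid; mass
  power a = 0 defines 0^0 = 1 (plain cosine).  Scale-invariant, in [0, 1].
* WP / WFPR: a truth bin is "present" if its L1-normalized intensity is
  ≥ i_min = 1e-4; WP + WFPR = 1 exactly.  Top-K ties break toward lower
  m/z.
* Library matching: candidates filtered to base peak (max-intensity bin)
  within ±5 Da of the query's — base-peak keying is the default because
  candidate molecular weight need not be known for predicted spectra;
  SDP-descending ranking with stable tie-break by molecule id; recall@K
  counts filter-excluded truths as misses.  Bootstrap error bars draw a
  20 % fraction of queries without replacement.

## Problem sizes used in the bundled experiments

The recovery experiment in the acceptance tests uses 500 planted
molecules (≤ 8 heavy atoms, seed 0), split 400/100, heads at 4 GNN layers
× width 64, maxelem 24, ≤ 200 epochs of Adam (lr 5e-3, batch 32), with
evaluation every 10 epochs and early stop once held-out mean SDP reaches
0.95.  The subset head trains with a 2048-subset cap — the same random
subset capping used at full scale to bound the indicator matrix.  The
overfit-one sanity check uses the planted molecule with the smallest
candidate set and a longer single-example schedule (formula: lr 2e-3,
3000 epochs; subset: lr 5e-3, 2000 epochs), since one example yields one
gradient step per epoch.  The library-matching check uses a 50-molecule
augmented library with replicate queries at jitter 0.1 / dropout 0.02.

## Numerical choices and degenerate inputs

* Isotope-peak merge tolerance 1e-9 Da; tie masses bin upward.
* All-zero spectra raise `DegenerateSpectrumError`; empty candidate
  batches and zero-atom subsets raise `DegenerateInputError`; enumeration
  past the hard ceiling raises overflow errors rather than silently
  capping.
* Fold assignment: canonical-SMILES Morgan fingerprint (radius 2,
  2048 bits) packed to bytes in bit order, CRC32, last decimal digit.
  Identical molecules land in the same fold regardless of input spelling.
* The run-length `maxelem` is shared across elements (per-element
  capacities would also work; shared is simpler and the filter caps make
  one bound valid for all elements).

## Known limitations

* Training at large learning rates on hard single examples can transiently
  produce non-finite values through the sqrt-power loss (the engine has no
  gradient clipping); the documented schedules are stable, but aggressive
  custom schedules may need care.
* The subset sampler caps uniformly; importance-aware capping (e.g. by
  fragment mass coverage) would likely lose less signal, mirroring the
  observed performance dip when deep-break subset pools are subsampled
  hard.
* Neutral, stereochemistry-free molecules only; no multiply charged ions,
  instrument peak shapes, or retention-time simulation.
* `passes_filters` counts subsets with the same enumeration used for
  modelling, so its cost grows with bond count; for very large molecules
  the atom/formula checks short-circuit first.
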