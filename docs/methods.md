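# Methods

## Network model

The core object is a fully connected recurrent network of N bipolar units
split into K contiguous partitions (slots).  Unit activations take values
+1 (active), −1 (inactive) or 0 (blank).  Blank is a genuine third state:
a blank unit exerts no drive on any other unit, so a blanked slot is empty
rather than "all inactive", and the all-blank network is a fixed point.
Rasters and exported traces render +1 as 1/white, −1 as 0/black, and blank
as `-`.

Weights are trained once with the Hopfield outer-product rule over the L
vocabulary patterns, `w_ij = (1/N) Σ_l ξ_i^l ξ_j^l` with `w_ii = 0`.  The
matrix is symmetric to machine precision by construction, which is what
licenses the energy arguments below.  Training warns when L exceeds one
tenth of the smallest partition — see *Load and stability*.

Dynamics threshold the gated net input: a unit becomes the sign of
`Σ_j (g·w)_ij x_j`; exactly zero net input keeps the previous value (so
undriven blank units stay blank).  The default update is synchronous, which
makes runs cheap and reproducible.  Synchronous Hopfield dynamics can enter
a period-2 limit cycle; the settler detects this and stops on the
lower-energy state of the pair, flagged as non-converged.  A seeded
asynchronous mode (random unit order, one sweep per step) is also provided;
with any symmetric effective weight matrix it makes the total energy
`E = −½ Σ_i Σ_{j≠i} w_ij x_i x_j` non-increasing at every single-unit
update, and the test suite checks exactly that.

Gating is a K×K boolean matrix over directed synapse *blocks*: entry
(k, k′) multiplies every weight from partition k onto partition k′ by 0 or
1 at evaluation time.  Stored weights are never modified.  With only the
diagonal on, each slot is an isolated attractor network (a buffer); opening
off-diagonal blocks reconstitutes parts of the original network.

## Vocabulary

Symbols are seeded random bipolar patterns; each unit is +1 with
probability equal to the coding level (default 0.5, the standard dense
regime for the outer-product rule).  Patterns must be pairwise distinct on
every partition; colliding patterns are resampled up to 100 times before
construction fails, which in practice only triggers when a partition is far
too small for the vocabulary.

## Transfer

`transfer(k → k′)` blanks the target slot, clamps the source, opens the
directed block k→k′ (target's within-slot block on), and settles for a step
budget (default 40 synchronous steps).  The first update writes
`sign(W_{k′k} ξ_k^l)` into the blank target, which is already close to the
target piece of the source's global attractor; within-slot recurrence then
sharpens it.  Afterwards the cross block is gated off and the target's
within-slot gate left on, holding the result.  Transfer therefore moves the
*symbol*, not the bit pattern — the defining property checked exhaustively
in the tests (all source/target/symbol combinations decode correctly).

## Equality detection and calibration

The cross energy between two slots,
`E_kk′ = −Σ_{i∈k,j∈k′} w_ij x_i x_j − Σ_{j∈k,i∈k′} w_ij x_i x_j`
(both directed blocks, no ½ factor), concentrates around
`−2·N_k·N_k′/N` when the slots hold pieces of the same stored pattern and
around 0 when they hold different ones or a blank.  An equality neuron per
unordered pair fires when `E_kk′` falls below a threshold.  No principled
closed-form threshold exists for finite networks, so thresholds are
*calibrated*: for each pair, the mean matched-symbol and mean
mismatched-symbol cross energies over the whole vocabulary are computed and
the threshold placed at their midpoint.  Calibration fails loudly if the two
populations do not separate.  At the scales used here the margin is large
(matched ≈ −28 vs. mismatched ≈ 0 for 100-unit slots in a 700-unit
network), which is why equality readout stays exact even when slot contents
drift by a few bits.

## Readout thresholds

Three overlap thresholds appear, all normalized to slot size:

- `decode_slot` default 0.8 — general-purpose decoding; tolerant of ~10%
  flipped units.
- symbol detectors 0.9 — production conditions; slots normally sit on (or
  very near) exact attractor pieces when rules are evaluated.
- trace readout 0.5 — the symbolic interpretation written into event logs
  reports the nearest symbol whenever its overlap is clearly above chance
  (distinct random pieces overlap near 0).  This floor exists because a held
  piece can transiently drift below 0.8 at high load (next section) while
  the network still behaves, verifiably, as if the symbol were present.

## Load and stability

A piece `P_k^l` is a fixed point of its isolated slot exactly when every
unit's crosstalk stays below its signal; the signal-to-noise ratio is
`sqrt((N_k − 1)/(L − 1))`.  For the binding demo (4 symbols on 100-unit
slots) this is ≈ 5.7 and every piece is exactly stable across seeds — the
partition-retention property test asserts 100% retention at that load.  The
Count Model's 11 symbols on 100-unit slots give SNR ≈ 3.2: a few percent of
pieces are not exact fixed points of their isolated slot, and with the small
slot size a drifting piece occasionally cascades to a spurious state (worst
observed overlap ≈ 0.5).  The *full* 700-unit network is far below capacity
(SNR ≈ 8.4), so all 11 global patterns are stable attractors — the quantity
the acceptance script verifies.

Consequences at the Count Model scale, measured over 40 seeds: the run is
symbolically perfect for roughly seven seeds in eight; in the remainder a
piece the run depends on degrades enough that a symbol detector misses and
the run stalls or miscounts.  This is an inherent finite-size property of
the outer-product rule at this load, not of the architecture: larger slots
or fewer symbols eliminate it.  Tests and demos therefore pin their seeds;
the seed sensitivity is the main caveat when extrapolating from passing
tests to arbitrary configurations.

## Production system

Rules are single thresholded neurons with ±1 synapses from equality and
symbol-detection neurons.  Negative weights are vetoes by construction —
rule validation rejects wirings whose positive inputs cannot reach the
threshold alone.  Conflict resolution picks the highest net input, ties
broken by definition order (no graded utilities are modeled).  A fired
rule's actions run sets first, then transfers in listed order; this
ordering matters when a set and a transfer touch related slots in one rule,
as in the Count Model's start production.

A retrieval request names the DM slots to be filled (blanked before
retrieval); when unspecified, slots decoding to no symbol are blanked.  The
explicit form mirrors how a production's retrieval request distinguishes
cue slots from requested slots, and is required for repeated retrievals
where the requested slot still holds the previous answer.  Declarative
retrieval scores each stored chunk by the mean per-slot normalized overlap
against the non-blank DM slots (slot-count invariant) and completes the
blank slots from the best match, earliest stored on ties.  The default
store is an explicit lookup table.

## Cycle schedule

Per cycle: 10 settle steps before matching, 40 steps per transfer, 5 steps
holding blanked retrieval slots, 5 steps after retrieval.  All budgets are
configurable through `CycleSchedule`.  The pre-match settle runs every
cycle; re-evaluating directly after the post-retrieval settle would also be
defensible and changes none of the cycle counts or firings at the scales
tested.

## Scales used in the test suite

Property tests use a 3-slot / 6-symbol network at 100-unit slots
(exhaustive transfer and equality sweeps over 5–10 seeds), tiny random
networks (N ≤ 20) for brute-force double-loop oracle comparisons of the
training rule and both energy functions (tolerance 1e−9), and the full
7×100 Count Model for end-to-end runs, including all 21 (start, end) pairs
over 5 seeds with a shared trained network per seed.  The whole suite runs
in well under a minute on one CPU.

## Known limitations

- Seed sensitivity at the Count Model load, as described above.
- No learning of equality neurons, detectors or productions; thresholds are
  calibrated or declared, not trained.
- No continuous-time or biologically detailed dynamics; no ACT-R
  sub-symbolic machinery (utilities, latencies, partial matching).
- The attractor-based DM backend (a second outer-product weight matrix over
  the DM partitions, completed by clamped sign dynamics) works only for
  weakly correlated chunk sets; the count-order facts all share the same
  IsA piece and retrieval then fails for some chunks, so the lookup table
  is the supported and default backend.
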