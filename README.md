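# dpaan

Dynamically partitionable autoassociative networks: Hopfield slot buffers
with gateable synapse blocks, energy-based equality detection, slot-to-slot
symbol transfer, and a small production-system runtime built on top.

## The problem

Connectionist models struggle with *variable binding*: representing "red
circle and blue square" without the colors and shapes blurring together, and
doing it so that whatever the system has learned about "red" applies no
matter which neural population currently represents it (role–filler
independence).  Assigning each role its own pool of neurons solves the
superposition problem but seems to break transfer and comparison between
pools — associations trained on one pool don't exist for another, and there
is no wiring that tells the brain two different activation patterns "mean
the same thing".

This package implements a resolution: train **one** fully connected
autoassociative network over all the pools at once, then partition it
dynamically.

## The model

A network of N neurons is split into K contiguous partitions ("slots") of
sizes N₁…N_K.  It is trained with the Hopfield outer-product rule on L
random bipolar global patterns P¹…P^L — the symbol vocabulary:

    w_ij = (1/N) Σ_l ξ_i^l ξ_j^l,   w_ii = 0

Slot k "contains symbol l" when its activation equals P_k^l, the piece of
global attractor l on that slot.  Because every piece belongs to one global
attractor, three operations come for free:

- **Buffering** — zero out (gate off) all between-slot synapse blocks and
  each slot is an independent attractor network holding its symbol.
- **Transfer** — blank slot k′, clamp slot k, momentarily gate on the block
  k→k′: attractor completion pulls k′ onto the *same* global pattern,
  whatever symbol k holds.  Assignment, implemented by pattern completion.
- **Equality detection** — the Hopfield energy restricted to the synapses
  between slots k and k′,

      E_kk′ = −Σ_{i∈k, j∈k′} w_ij x_i x_j − Σ_{j∈k, i∈k′} w_ij x_i x_j,

  is strongly negative exactly when the two slots hold pieces of the same
  stored pattern; thresholding it gives one equality neuron per slot pair.

On top of this sit symbol-detection perceptrons, production rules (single
thresholded neurons with ±1 synapses from equality/symbol-detection neurons,
negative weights acting as vetoes), a declarative memory that completes
blanked slots from stored chunks by nearest match, and a match–execute cycle
runtime — enough to run a classic ACT-R model entirely in attractor-network
operations.

## Worked example

```pycon
>>> from dpaan import run_binding_demo, run_count_demo
>>> _, report = run_binding_demo(seed=0)
>>> report["initial_eq_active"]
[[1, 3]]
>>> report["final_eq_active"]
[[1, 3], [1, 5], [3, 5]]
>>> report["final_slots"]
{1: 'red', 2: 'circle', 3: 'red', 4: 'square', 5: 'red'}
```

Five 100-neuron slots hold (red, circle, red, square, blank).  Initially
only equality neuron (1,3) fires: slots 1 and 3 both contain "red", even
though their activation vectors are unrelated bit patterns.  Opening the
single synapse block 1→5 transfers "red" into the vocalization slot, after
which (1,5) and (3,5) fire too.

```pycon
>>> _, report = run_count_demo("two", "seven", seed=1)
>>> report["fired"]
['start', 'increment', 'increment', 'increment', 'increment', 'increment', 'stop']
>>> report["count_sequence"]
['two', 'three', 'four', 'five', 'six', 'seven']
```

The Count Model counts from two to seven: the start production fires once,
increment fires five times (each cycle transferring the retrieved successor
into the count slot and requesting the next count-order fact from
declarative memory), and stop halts the run when the count equals the end
slot — 7 match–execute cycles in all.

The same demos are available from the shell:

```bash
dpaan binding --seed 0 --out trace/
dpaan jealousy --scenario mutual
dpaan count --start two --end seven
```

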