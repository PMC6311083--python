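# brnest

Logical-parameter estimation for qualitative biological regulatory
networks (BRNs), for systems biologists who model gene/protein regulation
in the discrete (René Thomas) formalism and want to know **which logical
parameters are consistent with their wet-lab observations**.

## The problem and the method

A BRN is a signed, thresholded directed graph: entities (genes, proteins)
carry discrete expression levels `0..ℓ`, and an interaction `x →(τ,σ) y`
influences `y` once `x` reaches threshold `τ` (σ = `+` activation, `-`
inhibition). In a state `s`, the *resources* of `v` are its currently
helping regulators

&nbsp;&nbsp;`W_v(s) = { x regulator of v : (s_x ≥ τ and σ=+) or (s_x < τ and σ=-) }`,

and a *logical parameter* `K_v(W)` gives the level toward which `v`
evolves when its resource set is `W`, one unit per step:

&nbsp;&nbsp;`s_v △ K = s_v + 1` if `s_v < K`, `s_v − 1` if `s_v > K`, else `s_v`.

Under asynchronous updating (one entity per transition) a complete
assignment of `K` values — a *parametrization* — induces a state graph
over the `∏ (ℓ_v + 1)` qualitative states; its deadlocks are stable
steady states and its cycles are homeostatic oscillations. The `K` values
are rarely measurable, but observations *about the dynamics* are: written
as CTL formulas over level atoms `v=n`, they can be model-checked on each
candidate state graph. brnest sweeps the whole parametrization space
(`∏ (ℓ_v + 1)^(2^|regulators(v)|)` candidates, optionally restricted by a
PARA section), accepts exactly the parametrizations whose state graph
satisfies every observation in every state, and reduces the results to a
single deterministic file. The CTL decision procedure is a built-in
explicit-state fixpoint labeling engine; the sweep is embarrassingly
parallel and is block-partitioned over worker processes, with a result
that is identical for every worker count.

## Worked example

The classic two-entity mucus-production switch of *Pseudomonas
aeruginosa* ships with the package: `x` (the sigma factor ALGU, levels
0..2, self-activating at threshold 2) and `y` (its inhibitor, levels 0..1),
with observations "from the resting state, `x` never over-expresses" and
"the over-expressed state (2,1) is stable":

```sh
$ brnest count --input src/brnest/models/pseudomonas.smb
states: 6
parametrizations: 324

$ brnest estimate --input src/brnest/models/pseudomonas.smb --workers 4 --output results.txt
accepted 37 of 324 parametrizations
```

Of the 324 candidate models (3⁴ choices of `K_x` × 2² of `K_y`), 37
satisfy both observations. `results.txt` lists each accepted model's six
`K` values; model 93, for example, is the textbook parametrization
`K_x({})=0, K_x({x})=2, K_x({y})=1, K_x({x,y})=2, K_y({})=0, K_y({x})=1`.
Its dynamics:

```sh
$ brnest stategraph --input src/brnest/models/pseudomonas.smb --param-index 93 --format dot --output graph.dot
6 states, 5 transitions, 1 deadlock(s)
```

The exported graph contains the homeostasis cycle
`(0,0) → (1,0) → (1,1) → (0,1) → (0,0)` — sustained oscillation of the
healthy response — and the deadlock `(2,1)`: the stable pathogenic state
in which ALGU stays over-expressed and mucus production persists.
`brnest check --input … --params-file results.txt` re-verifies a results
file model by model.

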