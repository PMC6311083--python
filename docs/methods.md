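# Methods

## Model semantics

brnest implements the discrete (Thomas-style) formalism for biological
regulatory networks. An entity `v` holds a level in `{0..ℓ_v}` (`ℓ_v ≥ 1`,
declared in the VAR section). An interaction `x →(τ,σ) y` requires
`1 ≤ τ ≤ ℓ_x`; at most one interaction is allowed per ordered entity
pair. The resources `W_v(s)` of `v` in state `s` are its present
activators plus its absent inhibitors; the logical parameter `K_v(W)`
(one per entity and regulator subset, in `[0, ℓ_v]`) is the attractor
level of `v` under resource set `W`. Transitions are asynchronous: a
state `s` has one successor per entity whose level differs from its `K`
target, moving that entity by exactly one unit toward the target. The
state graph is built over the full cartesian product of level ranges; a
state where every entity sits on its target has no successor and is
recorded as a deadlock (a stable steady state).

Two conventions deserve note:

* **Declared ranges are authoritative.** The classical definition ties
  `ℓ_v` to the entity's out-degree, but published models routinely
  declare ranges that differ from it. brnest treats the declared VAR
  range as the truth and logs an advisory warning on a mismatch rather
  than rejecting the model. The random-network generator suppresses this
  warning, since random topologies do not follow the convention by
  construction.
* **No self-loops in the raw graph.** The transition relation never
  contains `s → s`; deadlock self-loops exist only inside the CTL
  engine's totalization step and are never serialized or exported.

## CTL engine

Observations are CTL formulas over equality atoms `v=n` (no `≥`/`≤`
atoms; a level set must be written as a disjunction of equalities),
boolean connectives and the eight temporal forms EX/AX/EF/AF/EG/AG and
E[· U ·]/A[· U ·]. The grammar accepts `,` as a synonym for `&` because
published observation strings are printed with commas, and reads a bare
`X` as AX. Precedence is `!` > `&` > `|` > `->` with `->`
right-associative.

Deciding a formula uses the standard explicit-state labeling: atoms by
scanning, EX as a pre-image, E[p U q] as a least fixpoint computed with a
backward worklist, EG p as a greatest fixpoint computed by repeatedly
pruning states with no successor inside the candidate set, and the
universal forms via the dualities AX = ¬EX¬, EF p = E[⊤ U p],
AF p = ¬EG¬p, AG p = ¬EF¬p, A[p U q] = ¬(E[¬q U (¬p∧¬q)] ∨ EG¬q).
Because CTL path quantifiers range over infinite paths, the relation is
totalized first by adding a self-loop at every deadlock; this is what
makes `AG(x=2)` hold at a stable over-expressed state, matching the
biological reading that a deadlock cannot recover.

**Acceptance convention.** A parametrization is accepted iff the
conjunction of all observations holds in *every* state of the totalized
graph. Observations are customarily written as implication-guarded
formulas (`guard -> temporal claim`), which are vacuously true outside
their guard states, so the all-states convention is equivalent to
checking from unconstrained initial states — the behavior of standard
symbolic checkers when no initial state is declared. Whether the original
estimation tools instead used a designated initial state is not
documented; the all-states choice is recorded here as this package's
convention. Rejected models can be inspected with `violating_states`
(a diagnostic listing; no counter-example traces are produced).

## Parameter space, indexing, partitioning

Slots (one per entity × regulator subset) are ordered by entity
declaration order, then by subset bitmask over declaration-ordered
regulators (empty set first). Each slot's allowed values default to
`0..ℓ` and can be restricted by PARA lines (`K_v:{r1,r2} = lo..hi`, a
single value, or a comma list — both range and enumeration syntaxes are
accepted since the original tool's grammar is unpublished). The global
index of a parametrization is its mixed-radix encoding with the **last
slot varying fastest**; the map is bijective, so accepted-model indices
are stable across runs and worker counts. No observability/Snoussi-style
constraints are imposed on K values; PARA ranges are the only restriction
mechanism.

`block_partition(total, parts)` splits `[0, total)` into contiguous
blocks whose sizes differ by at most one, remainder to the earliest
blocks — a fixed deterministic choice. Workers are stateless: each
evaluates its block independently (build graph, check formulas), and the
reduction concatenates accepted lists in index order; its cost is linear
in the number of accepted models. Worker processes come from the standard
library process pool; the partition/reduce contract is the whole
interface, so a distributed transport could be substituted without
changing any result. The conjunction of observations is evaluated with
short-circuiting; per-formula failure counts are recorded only in
diagnostics mode, where every formula is evaluated on every model.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `state_cap` | 10⁶ states | guard on explicit-state graph construction; exceeding it raises `CapacityError`. Protects against accidentally materializing multi-million-state graphs (e.g. a 23-entity Boolean network, 8.4×10⁶ states), which this explicit-state engine is not meant for. Override per call/flag. |
| `workers` | 1 | number of block-partition worker processes; never affects results. |
| `edge_density` (random networks) | 0.3 | per ordered pair probability of an interaction; 0.25–0.8 used in tests to vary branching. |
| `diagnostics` | off | per-formula failure counts (disables short-circuiting). |

## What the fixtures emulate — and what they do not

* **Pseudomonas (shipped, 2 entities).** Thresholds and the two
  observation texts are reconstructions from the published network
  diagram's caption prose; they are not printed as machine-readable data
  anywhere. All downstream checks therefore assert *structural* facts —
  the sweep accepts a non-empty set, some accepted model shows both the
  homeostasis cycle and the stable state (2,1) — never specific K values.
* **HBP-like (shipped, 9 Boolean entities).** The entity order matches
  the published state notation `(NFkB,P21,FoXM1,PI3K,P53,MDM2,OGT,OGA,CMyc)`
  and the topology contains the text-attested motifs (P53–MDM2 negative
  feedback, CMyc→OGT, OGA⊣OGT, the OGT–CMyc loop), but the full
  interaction map is a documented synthetic stand-in. It supports
  structural tests (512-state graphs, deadlock queries) and does **not**
  reproduce the deposited model's accepted-set counts (28/4) or its 2304
  transitions; reproducing those requires the original model file, which
  is not redistributed here.
* **Random networks** (`random_brn`) are seeded and platform-stable
  (stdlib Mersenne Twister); they emulate topology and sign/threshold
  diversity, not biological realism. Passing tests on them demonstrates
  correctness of the algebra and the CTL engine, not fidelity to any
  real pathway.

## Verification strategy

The fixpoint engine is checked against a naive reference evaluator
(`tests/naive_ctl.py`) that computes semantics by explicit graph search —
EF by reachability closure, EG by restriction and SCC-or-self-loop
detection, E[· U ·] by per-state DFS — over networkx primitives, sharing
no code with the worklist implementation. The estimation driver is
checked against direct enumeration of all K assignments with
`itertools.product`, bypassing the indexing and partitioning machinery
entirely. Problem sizes are chosen for desk-scale determinism: random
CTL graphs stay at or below 64 states, oracle sweeps use 100 graphs, and
the end-to-end sweep uses the 324-parametrization Pseudomonas space.

## Known limitations

* Explicit-state only: no BDD/symbolic representation, no on-the-fly
  graph construction; the state cap is the honest boundary.
* Asynchronous updating only; synchronous semantics are out of scope.
* The model-file dialect is defined by this package; files written for
  other tools parse only via the best-effort `compat=True` mode, which
  reports unrecognized statements instead of guessing.
* Acceptance is all-states; per-initial-state checking is not offered.
* No fairness constraints, LTL, or counter-example witness traces.
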