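# srnav

**Composite egocentric + allocentric successor-representation agents for
continual gridworld navigation.**

Animals (and robots) can describe space in two reference frames: an
*allocentric* one fixed to the world ("the goal is in the north-east
corner") and an *egocentric* one fixed to the self ("there is a barrier
directly ahead").  Computational accounts of navigation have focused
almost exclusively on allocentric predictive maps; `srnav` is a research
codebase for studying what an *egocentric* predictive map adds.  It is
aimed at computational-neuroscience and RL researchers who want a small,
fully deterministic, fully inspectable testbed for composing maps across
reference frames.

## The model

The agent lives in a walled 20x20 gridworld with opaque U-shaped
barriers that re-arrange (together with the reward) every block of
episodes.  It acts egocentrically (go-forward, turn-90-cw, turn-180,
turn-90-ccw) and maintains **two state-action successor representations
(SRs)**:

- an allocentric SR `M_A[. | s_A, a_A]` over interior cells `s_A` and
  compass actions `a_A` — expected discounted future cell occupancy;
- an egocentric SR `M_E[. | s_E, a_E]` over *views* `s_E` (the occluded
  (H+1) x (2H+1) window the agent sees; many poses alias to one view)
  and egocentric actions.

Action values are linear in the concatenation of the two SR rows,

    Q(s, a) = w . [ M_A[. | s_A, R_d^{-1}(a)],  M_E[. | s_E, a] ],

where `R_d` is the heading-dependent bijection between compass
directions and egocentric actions (facing East, "North" is a
counter-clockwise turn).  Both SRs are initialised at their
uniform-policy fixed points `M_s = T (I - gamma T)^{-1}`,
`M_a = T_a (I + gamma M_s)` and then track behaviour by TD learning;
`w` learns by semi-gradient Q-learning with ADAM.  Because Q is linear,
the greedy value splits exactly, `V(x,y,d) = V_a(x,y) + V_e(x,y,d)`:
a smooth allocentric gradient to the reward plus local, heading-dependent
egocentric corrections that *transfer* across worlds sharing local
structure.

Lesion variants (`ALLO_ONLY`, `EGO_ONLY`, `EGO_QLEARNER`, `NO_ADAM`)
remove or replace one ingredient each; paired comparisons on
bit-identical world/start/exploration sequences quantify what each
contributes.  See `docs/methods.md` for the full model description,
hyperparameters and limitations.

## Worked example

`examples/03_lesion_comparison.py` runs the paired comparison at a small
scale (2 task seeds x 5 worlds x 200 episodes):

```text
$ python examples/03_lesion_comparison.py
FULL       post-switch counted steps (first 100 episodes, worlds 2-5):  153.8   hole time:  38.8
ALLO_ONLY  post-switch counted steps (first 100 episodes, worlds 2-5):  200.1   hole time:  56.9
```

"Counted steps" counts only go-forward selections (turns are free, so
composite and lesioned agents are scored on the same currency); lower is
better, and the optimal path from a random start is ~18 steps.  "Hole
time" is primitive steps spent inside a U-barrier cavity.  The composite
agent relearns a re-arranged world markedly faster than its
allocentric-only lesion and spends about a third less time trapped —
the egocentric SR has learned, in a view-indexed and therefore
world-independent way, what barriers look like and how to skirt them.

The other examples generate and render worlds (`01`), show occluded
views and aliasing (`02`), decompose a trained value function into its
two frame components (`04`), and fit the two behavioural GLMs —
per-world mean steps vs barrier load (Poisson), and
which-agent-produced-this-episode vs occupancy profile (logistic)
(`05`).  Each prints what it computes and what the numbers mean.

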