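# Methods

`srnav` implements a reinforcement-learning agent that navigates
re-arranging gridworlds by combining two successor representations (SRs)
defined in different reference frames, and the experimental and
analytical machinery around it: world generators, lesioned agent
variants, paired comparisons, value decomposition and behavioural GLMs.

## Task and environment

The environment is a `width x height` grid (default 20x20) whose
boundary ring carries a distinct wall label per side, leaving an 18x18
traversable interior; corner cells take the horizontal wall's label as a
fixed tie-break.  A world contains U-shaped opaque barriers (or, in the
unstructured paradigm, scattered single-cell obstacles) and one rewarded
cell.  Episodes start from a uniformly random traversable pose (cell +
heading, reward cell excluded) and end when the agent enters the reward
cell (reward 1, otherwise 0) or after an episode cap of primitive steps
(default 10,000; the reduced protocol uses 2,000).

Actions are egocentric: go-forward, turn-90-clockwise, turn-180,
turn-90-anticlockwise.  A blocked go-forward is a no-op that still
consumes a time step and still triggers learning.  Performance is
reported as *counted steps*: go-forward selections only, so an
allocentric "move North" realised as turn-then-advance costs one counted
step, keeping composite and lesioned agents comparable.

The egocentric observation is an (H+1) x (2H+1) window of cell labels
in front of and beside the agent, aligned to its heading (H = horizon,
default 2).  Opaque cells (barriers, walls) occlude: a pixel whose
line-of-sight segment from the agent's cell centre crosses the interior
of an opaque cell strictly between the endpoints is replaced by a
distinct OCCLUDED sentinel; the window is categorical and never summed,
so the sentinel serves only view identity.  Visibility uses an exact
integer supercover traversal; a cell grazed exactly at a corner does not
block.  Cells beyond the grid are OUTSIDE.  The reward is deliberately
invisible in the view (a config flag could render it): reward
localisation is forced through the allocentric pathway, which is what
makes the frame separation interpretable.  Views are aliased — many
poses share one view — and a codebook maps each distinct view to a dense
integer index; the egocentric state count N_E is the number of distinct
views actually enumerated over the task's worlds.  (The closed-form
pixel-count bound 2(H+1)(2H+1)-1 is recorded as metadata only; the
categorical view count is the operative dimension.)

## World generators

Five paradigms, all pure functions of (parameters, seed):

- **MAIN** (default): per world, 20 independent attempts to place a
  4x4-outer U barrier at a uniformly sampled anchor; a placement succeeds
  only if the footprint plus a one-cell buffer overlaps no wall, barrier
  or reward.  In the first world all barriers share one orientation
  (opening away from the reward corner's side, so barriers trap
  reward-bound travel); later worlds orient each barrier at random.
- **ALIGNED_FIXED / ALIGNED_VARSIZE**: every world aligned-to-obstruct;
  VARSIZE samples outer sizes uniformly from 3-6.
- **RANDOM_ORIENT_VARSIZE**: varied sizes, uniformly random orientation.
- **FULLY_RANDOM**: single-cell obstacles added one at a time until
  obstacle density reaches 0.2; each candidate is rejected unless
  breadth-first search from the corner opposite the reward still reaches
  every non-obstacle cell.

A task is 5 worlds with the reward alternating between the top-right and
bottom-right interior corners (TR first by default).  All generated
worlds are verified connected with the reward reachable (with a one-cell
buffer a U barrier cannot disconnect space, but the check is cheap).
Worlds serialise to JSON with a single-character cell code, round-trip
exact.

## Successor representations

Both frames keep a state-state table `M_s[s] ~ E[sum_t gamma^t
1(s_t = .)]` bootstrapped on the *next* state, and a state-action table
`M[a, s]` conditioning on the first action.  The online rules are

    M_s[s]    += alpha * (onehot(s') + gamma * M_s[s'] - M_s[s])
    M[a, s]   += alpha * (onehot(s') + gamma * M_s[s'] - M[a, s])

applied concurrently (state-state first); on the terminal transition the
bootstrap term is dropped.  Their fixed points under a one-step matrix T
are `M_s = T (I - gamma T)^-1` and `M_a = T_a (I + gamma M_s)`, which is
how tables are initialised:

- **Allocentric** (states = interior cells, actions = compass moves,
  blocked moves self-loop): uniform-random compass actions on the
  *empty* world.
- **Egocentric** (states = views, actions = ego actions): every pose of
  every task world is enumerated; an aliased view's transition row is the
  mean of its pose-wise rows; per-world matrices are averaged across the
  task's worlds (a view absent from a world contributes nothing to that
  row's average), so the agent starts with the task family's mean local
  structure.  A single-sample-world initialisation is available as a
  config switch.

During behaviour the allocentric SR is updated with the *compass* action
the chosen ego action realises at the pre-step heading; a turn is an
allocentric self-transition ("I chose North and did not move North
yet").  Views not yet in the codebook (possible only outside the
preparing task) extend the tables with the table-mean row and
zero-initialised weights.

## Composite linear Q-learning

Action values are linear in the concatenation of the two state-action SR
rows,

    Q(s, a) = w . [ M_A[. | s_A, R_d^-1(a)],  M_E[. | s_E, a] ] ,

where `R_d` is the heading-dependent bijection between compass directions
and ego actions.  Selection is epsilon-softmax (uniform with probability
epsilon, else softmax at temperature tau, max-subtracted).  Weights learn
by semi-gradient Q-learning with an ADAM step; the two SR bases have very
different row magnitudes (the egocentric graph is small and dense, the
allocentric one large and sparse), which a single global learning rate
handles poorly — this is the rationale for the adaptive step, and the
NO_ADAM ablation (plain SGD at the same eta) demonstrates it.  The ADAM
update uses the standard `eta * m_hat / (sqrt(v_hat) + eps_adam)` step;
a config switch `adam_no_sqrt` runs the dimensionally unstable
`m_hat / v_hat` variant for comparison.  Moments decay on every step for
every coordinate; the step counter increments exactly once per
transition.  The TD target bootstraps off the freshly TD-updated SR
features of the post-step state and is dropped at terminals; truncation
at the episode cap is not treated as terminal.

### Lesion variants

- **FULL** — both feature blocks, both SRs learned.
- **ALLO_ONLY** — egocentric block removed from features and learning.
- **EGO_ONLY** — allocentric block removed (the agent cannot localise the
  reward; it performs worst and serves as a floor).
- **EGO_QLEARNER** — the egocentric SR row is replaced by a one-hot of
  the view index inside the same shared weight vector.  Because the
  one-hot does not depend on the action, this term cannot change action
  ranking; it behaves like a learned state-value bias, and empirically
  the variant tracks the allocentric-only agent.
- **NO_ADAM** — full features, plain SGD weight step.

### Hyperparameter defaults and how they were set

Reference hyperparameter values were not available, so defaults were
calibrated once, following the same protocol the study design
prescribes: shared parameters were chosen to maximise the *lesioned*
(allocentric-only) agent's post-switch performance on three pilot task
seeds, then the egocentric parameters were chosen for the full agent;
everything is config-exposed.

| parameter | default | role |
| --- | --- | --- |
| gamma_A, gamma_Q | 0.95 | allocentric SR / Q discount |
| gamma_E | 0.9 | egocentric SR discount (local predictions transfer best) |
| alpha_A, alpha_E | 0.05 | SR TD learning rates |
| eta | 1e-3 | ADAM step size |
| beta1, beta2 | 0.9, 0.999 | ADAM moment decays |
| eps_adam | 1e-2 | ADAM denominator floor |
| epsilon | 0.1 | uniform exploration probability |
| tau | 0.01 | softmax temperature |
| H | 2 | view horizon |

`eps_adam` is deliberately large.  With terminal-only reward the raw
gradient is sparse and tiny almost everywhere, and with a conventional
1e-8 floor the ratio `m_hat / sqrt(v_hat)` saturates at +/-1 for every
coordinate, so weights random-walk at rate eta and the noise swamps the
exponentially small distal Q differences; a 1e-2 floor restores
magnitude sensitivity for near-zero gradients while leaving genuinely
active coordinates adaptive.  Exploration parameters are constant
(no annealing).

## Experiments

`run_task` takes one agent through a task's worlds in order; nothing is
reset at a switch — SRs, codebook, weights and optimizer state all carry
over (continual learning).  Start poses and episode seeds are pure
functions of (master seed, world index, episode index), so paired
variants of a comparison see bit-identical worlds, starts and
exploration draws.  The per-step loop runs as a numba-compiled kernel
that mirrors the composable reference functions; a replay-equivalence
test holds the two paths to the same trajectories and
numerically identical tables.

Reported metrics per episode: counted steps, primitive steps, *hole
time* (primitive steps whose pre-step cell lies in a U cavity), time
near walls (first interior ring, Chebyshev distance 1 from the
boundary), and time on current/previous worlds' barrier sites (cavity
cells plus traversable cells adjacent to a barrier footprint); the
radii are configurable conventions.

**Reduced protocol.**  The full study scale (30 task seeds, 1000
episodes per world) is reduced by default to 5 task seeds x 5 worlds x
200 episodes with a 2,000-step cap for the lesion battery, and 10 seeds
for the horizon sweep (H in {2, 3, 4}; the allocentric-only agent is run
once per seed since its behaviour is H-invariant).  At this scale the
qualitative contrasts (full < lesioned post-switch steps and hole time;
ego-only worst; no-ADAM degraded) are stable across seeds; the horizon
advantage falls sharply from H=2, while the H=3 vs H=4 difference sits
within seed noise at this scale.  Per-episode aggregation uses means
across seeds.
Comparisons use one-sided paired sign tests across task seeds.

## Analyses

- **Value decomposition.**  Because Q is linear in the concatenated
  features, the greedy value splits exactly:
  `V(x,y,d) = V_a(x,y,d) + V_e(x,y,d)`, both blocks read at the total-Q
  argmax action (ties broken by fixed action order).  The
  head-direction mean of V_e and the direction-resolved residuals are
  exported separately; inaccessible cells are NaN, with a helper that
  renders them at the mean of accessible cells.
- **Egocentric SR visualisation.**  A view's SR row is binned into 5
  equal-width occupancy bins on its positive support, and the top 3 bins
  (the top 60% of the occupancy range) are returned in descending order;
  membership is invariant to positive rescaling.  Equal-count (quantile)
  binning was the alternative reading; equal-width is the default
  convention here.  The allocentric rendering maps each pose's view
  occupancy onto four direction-indexed heat maps; aliased poses form
  constant-valued blocks.
- **Barrier GLM.**  Per task seed, a log-link Poisson regression of
  per-world mean counted steps on the world's barrier pixel count
  (statsmodels IRLS); coefficients aggregate across seeds as mean +/- sd.
- **Occupancy GLM.**  A logistic regression predicting which agent
  (lesioned = 1) produced an episode from its occupancy proportions
  (near walls, current barrier sites, each previous world's sites),
  fitted separately per consecutive chunk of 25 episodes; perfect
  separation raises rather than being silently dropped.  Both fitters
  are validated by simulate-and-refit recovery within three standard
  errors.

## What the synthetic worlds do and do not capture

All inputs are minted by the package's own generators, which *are* the
study's stimulus distribution — there is no external data.  The worlds
deliberately share local egocentric structure (identical barrier pieces,
walls) while global structure changes; the contrasts measured here
quantify exactly that transfer.  Consequences: results say nothing about
environments without shared local structure beyond the FULLY_RANDOM
paradigm; observations are noiseless and dynamics deterministic, so
robustness to sensor noise is untested; and the linear-in-SR value
model is the object of study, not a claim about richer function classes.

## Numerical choices and edge cases

- SR fixed points solve `(I - gamma T)^T X^T = T^T` by LAPACK rather
  than explicit inversion; gamma < 1 and row-stochastic T guarantee
  non-singularity.
- The definitional SR includes the t=0 self-occupancy, but the *printed
  update rules* bootstrap on the next-state indicator; the updates are
  what the agent runs, so tables are initialised at the updates' fixed
  points (rows sum to gamma-geometric 1/(1-gamma), not 1 + ...).
- Softmax uses max-subtraction; selection consumes exactly two uniforms
  per step so compiled and reference paths stay in lock step.
- Ties in argmax resolve to the lowest action index everywhere.
- Episode truncation bootstraps normally (only true reward entry is
  terminal for learning).
- Degenerate inputs (all-zero SR row in binning, constant Poisson
  regressor, single-class logistic labels, untraversable start) raise
  `ValueError` with a field-specific message.

## Known limitations

- The egocentric table is dense over views; beyond H ~ 5 the quadratic
  memory in N_E becomes the binding constraint.
- EGO_QLEARNER's action-independent one-hot block is a deliberate
  design choice (it keeps the shared weight-vector shape), but it means
  that variant tests only value-bias effects, not tabular egocentric
  control.
- The sign tests at 5 seeds have a minimum attainable p of 1/32; the
  reduced protocol is adequate for the large observed contrasts but not
  for subtle ones.
- Hyperparameters were calibrated on the MAIN paradigm; other paradigms
  reuse them unchanged.
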