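# Methods note

This package implements a generative-model account of how an agent can
represent, infer, and transfer abstract knowledge about the *structure* of a
task — the connectivity rule of the graph its experience is drawn from —
separately from the particular stimuli it observes. It also implements a
family of associative baselines (successor representations) that learn
stimulus-stimulus predictions without any abstract structural layer, so the
two accounts can be compared on exactly the same synthetic data.

## Generative model

A task is modelled as a hidden Markov model. The hidden states are the nodes
of an abstract graph whose transition matrix `A` is fixed by two discrete
choices: a **structural form** (translationally invariant hexagonal lattice,
or a ring of densely connected communities) and a **size**. The emission
matrix `B` maps each abstract state to sensory symbols; it is the only part
learnt from data. Observations are either uniform random walks on the graph
or independently presented adjacent pairs.

Both graph families are six-regular, so degree carries no information about
form:

- **Hexagonal**: a triangular-lattice torus; node `(i, j)` connects to the
  six offsets `(0, ±1), (±1, 0), (1, −1), (−1, 1)` with periodic boundaries.
  The canonical size is 6×6 = 36 nodes; candidate sizes are 25, 36, 49.
- **Community ring**: communities of 7 nodes, all-to-all within a community
  except that its two designated *connecting nodes* are not adjacent to each
  other; connecting node 1 of community `c` links to connecting node 0 of
  community `c+1`, closing a ring. The canonical size is 5×7 = 35 nodes;
  candidate sizes are 28, 35, 42.

## Basis sets

Each form is represented compactly by a basis `U` with weights `S` such that
`f(U S Uᵀ)` approximates the form's transition matrix at any candidate size,
where `f` rectifies negative entries, discards off-diagonal entries below
half of their row's maximum, zeroes the diagonal, and row-normalizes.

- **Hexagonal basis**: the 12 eigenvectors of largest absolute eigenvalue
  (excluding the constant mode) of the random-walk kernel of a large native
  10×10 torus. These are periodic lattice waves, the graph analogue of
  grid-cell firing maps. They are *resized* to each candidate lattice by
  spline interpolation with periodic boundary handling followed by QR
  re-orthonormalization. The thresholded reconstruction recovers the true
  six-neighbour kernel exactly at all three candidate sizes (verified in
  tests), which is what makes one basis transferable across sizes.
- **Community basis**: built directly at each candidate size from one binary
  membership vector per community plus one link vector per ring edge. A link
  vector carries a Gaussian profile over candidate connector *slots* on each
  side (peaked at the outgoing slot of one community and the incoming slot of
  the next), encoding that later slots are less likely to be the connector.
  The profile width is σ = 0.5 with amplitude 1.2 relative to membership
  vectors. This was calibrated analytically, before any inference experiment
  was run: wider profiles (σ = 1.0) provably cannot pass the shared
  half-row-max threshold with both within-community edges and the
  cross-community link intact — the two inequalities conflict — whereas the
  chosen values reproduce the true degree-6 adjacency with no missing edge
  and a single spurious edge per community (between its two connecting
  nodes), an approximation the inference tolerates.

## Inference

Given observations, the agent fits `B` for every (form, size) hypothesis by
expectation-maximization with the M-step restricted to emissions (`A` is
never updated — structure is selected, not learnt edge by edge). Walks are
scored as one long sequence with a scaled forward-backward E-step (a
numba-compiled kernel with a pure-numpy twin kept for verification); pairs
are scored as independent two-observation segments, which vectorizes in
closed form. Because fitting many states to limited data is prone to local
optima, EM uses a screening strategy: many random Dirichlet initializations
(plus a warm start from the previous block, since evidence accumulates) are
run for a few iterations each, and only the best few are run to convergence.

Each hypothesis is scored by a BIC approximation of the model evidence,
`log L − (N/2)·log k` with `N` the state count and `k` the observation
count, and combined with categorical priors (uniform over forms, uniform
over sizes within a form). The MAP form maximizes the size-marginalized
posterior; the MAP size is the conditional MAP within that form.

## From model to behaviour

The inferred `A` is thresholded back into an adjacency matrix and
breadth-first search yields the abstract link-count matrix `D`. The Bayesian
inversion of the emission matrix under the uniform state prior, `B̃`
(columns of `B̂` normalized over states), maps observations to states, and
the observation-level distance estimate is the bilinear form
`D̃ = B̃ᵀ D B̃` with states indexing the rows of `B̃` — an orientation pinned
by a hand-computed three-state test. "Which of two symbols is closer to a
target?" is answered by the smaller `D̃` entry, with exact ties resolved by
a seeded fair coin.

On community graphs, connector identification is scored through the
emission matrix: `fc` is the average probability mass the inferred
connector states place on the true connector symbols, and `fIc` the mass
all other states place there (both divided by the number of inferred
connecting nodes), so `fc → 1` with `fIc → 0` means the agent knows which
stimuli sit at community boundaries.

## Baselines

The successor representation `M = (I − γA)⁻¹` (γ = 0.8) holds discounted
expected future occupancies; on these regular graphs occupancy decays with
link distance, so `M(option, target)` answers closeness questions.

- **SR-online**: temporal-difference learning (α = 0.1) on observed
  transitions; presented pairs trigger one update in each direction with no
  cross-pair bootstrapping. Answers use the symmetrized matrix.
- **SR-A / DA**: the closed-form SR of the row-normalized transition-count
  estimate. The discounted-association baseline (DA) answers through the
  same implied occupancy, so the two coincide numerically by construction;
  both labels are kept for the five-model results layout.
- **SRreg**: the symmetrized TD-SR reconstructed from its m = 7
  largest-eigenvalue components (verified equivalent to the best rank-m
  reconstruction). Spectral truncation smooths occupancy across gaps in
  experience, which is what lets this baseline generalize over never-seen
  edges.

## Packaged experiments

**fig4 (missing-link inference).** The complete graph is the 36-node
hexagonal torus; eight *key* links are withheld from experience: the
vertical and diagonal links crossing one lattice row boundary over four
contiguous columns (a partial cut; the frozen set is
`graphs.FIXTURE_HEX_OMITTED_EDGES`). Agents observe 7 blocks of 150
adjacent-pair presentations from the incomplete graph; after each block they
answer 40 questions whose two options are exactly tied in link counts on the
observed graph but differ on the complete graph, so only inference about the
withheld links can beat chance. Ten simulations; per-simulation mean
accuracy is compared with 0.5 by a one-tailed one-sample t-test.

The cut is structured deliberately. With scattered random omissions, even
the SR of the *observed* graph answers the tied questions far above chance
asymptotically — the resolvent still tracks complete-graph proximity — so
the task would not dissociate structural inference from raw association.
Across the partial cut, the observed-graph SR is systematically misleading
(exact-SR accuracy ≈ 0.04–0.36, below chance) while the low-rank-filtered
SR and the structural agent recover the missing links (≈ 0.86 and ≈ 1.0
asymptotically). The choice was made from these asymptotic (infinite-data)
model properties, not by iterating on test outcomes.

**fig6a (connector identification).** The complete 35-node community graph
is observed through 7 blocks of 180 random-walk steps (no omitted edges, no
distance questions). The agent carries a community-form prior over the three
candidate sizes. Per block we record the MAP size and fc/fIc. Twenty
simulations; the acceptance property is that the modal inferred number of
communities is five and that fc rises toward 1 while fIc stays near 0.
Stronger EM search settings are used here (more restarts, longer screening)
because the 35- and 42-state hypotheses are separated by only tens of nats
of evidence and the 42-state model is the easier optimization target; with
default settings the size posterior is noisy even though connector
identification already works.

## What the synthetic results do and do not show

All results here are model-side: they show that the implemented basis-set
agent and the regularized SR can recover withheld structure from the
packaged synthetic tasks, and that unfiltered associative baselines cannot.
They say nothing about human behaviour; no behavioural data ships with the
package, and numbers that would require participant data are out of scope.
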