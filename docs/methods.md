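# Methods

## The two-graph model

A protein–ligand complex is treated as a single graph over its heavy atoms
with two edge sets that are never mixed. The covalent adjacency `A_C` is
the disjoint union of the two molecular graphs: it carries real chemical
bonds and is zero between molecules, because the complexes modeled here
bind noncovalently. The noncovalent adjacency `A_NC` connects every
ligand–protein pair and nothing else; it encodes *candidate* interactions,
leaving it to the learned convolution to decide which pairs matter. Both
matrices are data: binary, symmetric, without self-loops, not normalized,
and untouched by training. Self-information reaches each atom through the
residual term of every convolution, `X + ReLU(A·X·W)`, rather than through
diagonal entries.

Distance information enters the model in exactly one place: the pocket
crop. A protein atom survives iff its minimum distance to any ligand atom
is at most the range cutoff (inclusive; atoms are removed only when they
*exceed* it). After cropping, `A_NC` is distance-blind by design — the
burden of sorting real from spurious candidate contacts falls on the
features and the training signal. The default cutoff is 5 Å; the sweep
harness covers 3–6 Å, over which mean pocket size grows monotonically.

Atom features are configurable blocks: element one-hot over
(C, N, O, S, P, F, Cl, Br, I, other), degree one-hot (0–5, computed on the
cropped complex), aromaticity, ring membership, formal charge,
hybridization one-hot (SP/SP2/SP3/other) and a ligand/protein role bit —
F = 24 with everything enabled. Chemistry annotations are captured from the
source files' perception (RDKit) at load time, so featurization is a pure
function of the in-memory structure.

## Training

The target is pKd = −log₁₀ Kd. Optimization is Adam on MSE with the
schedule: initial learning rate 1.5·10⁻⁴, multiplied by 0.75 whenever the
best validation loss has not improved for 200 consecutive epochs, and
termination after 400 epochs without improvement; gradients are clipped by
global L2 norm at 0.5; the returned parameters are those of the best
validation epoch. Cross-validation uses repeated random sub-sampling:
independent random 8:1:1 partitions per fold (20 by default), not disjoint
folds.

Gradients are exact reverse-mode derivatives of the forward pass, written
by hand in NumPy and verified against central finite differences in the
test suite. Minibatches accumulate per-graph gradients; because sum
pooling acts within a graph, this is value-identical to block-diagonal
batching of the adjacencies. All randomness (initialization, shuffling,
splits) derives from explicit seeds, and training histories are bitwise
reproducible on one machine.

Initialization is Glorot-uniform with one deliberate exception: the output
layer starts with zero weights and bias +1. The prediction is clamped
nonnegative by its outer ReLU, and with a randomly initialized final layer
the pre-activation is a large-magnitude sum of pooled activations whose
sign is a coin flip — about half of all seeds start, and then permanently
stay, in the dead regime where no gradient flows. Starting the output at a
small positive constant keeps the unit active; its weights receive
gradient from the first step.

Two optimization quirks are worth knowing. First, the running epoch loss
averages minibatch losses computed *before* each update, so an
early-stopping criterion on a target training loss re-evaluates the full
training set with the final parameters before stopping. Second, under the
fixed schedule the network approaches but does not exactly reach the
constant predictor on constant labels within a few thousand epochs (a slow
plateau near MSE 0.1 on toy data); tests assert convergence toward the
constant, not attainment.

## Relevance propagation

Explanations seed the output relevance with the prediction ŷ and propagate
it backward. For a linear layer with inputs `a_j`, weights `w_jk` and
pre-activation `z_k` (bias included as a virtual input with a₀ = 1,
w₀ₖ = b_k):

* LRP-0: `R_j = Σ_k (a_j w_jk / z_k) R_k` — used on the output layer;
* LRP-ε: denominator `z_k + ε·sign(z_k)` with ε = 0.25 — used on the
  remaining dense head layer; the signed stabilizer is the standard
  formulation and the only one that damps near-zero *negative*
  denominators;
* LRP-γ: `w_jk → w_jk + γ·max(w_jk, 0)` in numerator and denominator with
  γ = 100 — used on every graph convolution.

Sum pooling distributes each pooled feature's relevance over atoms in
proportion to their activations; a feature whose column sums to zero
contributed nothing and receives nothing (no uniform fallback). The
residual convolution splits each output entry's relevance between the
identity branch (`X_in`) and the convolution branch (`ReLU(A·X·W)`) in
proportion to those two nonnegative contributions — the standard LRP
treatment of sums; the branch share then propagates through the composite
linear operator with effective weights `A[k,i]·W[f,f']` (A is binary, so
its positive part is `A[k,i]·max(W,0)[f,f']`). Bias relevance is absorbed,
so totals are conserved exactly only when biases vanish; with zero biases
and ε = γ = 0 the per-atom contributions sum to ŷ to machine precision.
Denominators within 10⁻¹² of zero short-circuit to zero flow, preventing
sign-flip blowups. The node-embedding layers are skipped: they are
row-local, so they redistribute relevance between one atom's features and
cannot change per-atom totals. Contributions are the per-atom feature sums
of the relevance at the embedded representation.

## Knowledge-based interaction profiling

Structures are heavy-atom only, so hydrogen-bond detection uses a
donor–acceptor heavy-atom distance window (2.5–3.5 Å) between N/O atoms on
opposite sides of the interface, with no angle term; with hydrogens
stripped, donor and acceptor roles cannot be assigned reliably, so both
are typed permissively by element (sulfur optional, off by default).
Hydrophobic contacts pair apolar carbons (no bonded N/O) across the
interface at ≤ 4.0 Å and are de-duplicated to one contact per
(ligand atom, protein residue), matching residue-level reporting
conventions. All thresholds are configuration, not constants.

The comparison between an interaction profile and an LRP explanation
reports, per ligand atom, interaction membership and contribution
sign/rank, the fraction of hydrogen-bond ligand atoms with positive
contribution, and a one-sided permutation p-value for whether interacting
atoms out-rank the rest (mean rank against random same-size subsets).

## The synthetic generator

The toy complexes exist so that every stage is testable without downloads.
A ligand is a bonded chain (1.5 Å spacing) with an oxygen at each engaged
hydrogen-bond site; the protein is a set of short bonded chains (3–5
atoms). Planted hydrogen bonds place a nitrogen anchor 2.8–3.2 Å from a
ligand oxygen (the first one in 2.8–3.0 Å, so a 3 Å crop is never empty);
planted hydrophobic contacts place a carbon anchor 3.75–3.9 Å beneath an
apolar ligand carbon, jittered only perpendicular to the chain axis so the
neighboring carbons stay outside the 4.0 Å threshold; all remaining
residues sit at 5.5–8 Å from every ligand atom. Non-bonded atoms are kept
≥ 2.3 Å apart so that distance-based bond perception on the exported PDB
recovers exactly the intended bonds, and the global minimum interatomic
distance of 1.2 Å clears the sanity filter. By construction, the default
interaction rules detect exactly the planted contacts — the generator is
the profiler's oracle, and this is verified at generation time.

Labels follow pKd = 0.5·(planted contacts) + 4.0 + N(0, 0.3²), spanning a
realistic 4–9 range. Datasets vary the planted counts (1–3 hydrogen bonds,
0–2 hydrophobic contacts) and the ligand size (9–15 atoms), as real
ligands vary; a constant ligand would be perfectly collinear with the bias
and would absorb an arbitrary share of the baseline in any relevance
decomposition.

What the toys do *not* emulate: conformational flexibility, sterics beyond
a hard distance floor, aromaticity, rings, charges, realistic residue
chemistry, or any geometry of hydrogen bonding beyond a distance window.
Passing tests on them demonstrates the correctness of the machinery and
the recoverability of planted signal — not predictive performance on real
complexes, which requires training on a real affinity-labeled corpus.

## Explainability experiment design

The recovery experiment trains the two-graph variant (hidden width 128,
one convolution of each type) on 136 toy complexes, selects on 14, and
explains 20 held-out complexes; enrichment of the planted contact atoms
(both sides of every planted pair) is tested at p < 0.05 with 10⁴
permutations. Toy complexes are featurized with element and role only. The
other default blocks are constant or role-determined on these acyclic,
neutral, sp³ structures; carrying such uninformative but role-asymmetric
features lets the optimizer distribute the (collinear) count signal across
redundant channels in ways that relevance then faithfully reports — a
general caution for LRP on redundant featurizations, not a property of the
planted chemistry. With the chemistry-bearing features, positive
contributions concentrate on the planted contact atoms on both sides of
the interface.

The capacity check fits 32 noiseless complexes with minibatches of 8:
under the fixed learning-rate schedule with a capped epoch budget, the
number of optimizer updates per epoch is what controls convergence speed,
and full-batch training converges needlessly slowly.

Problem sizes throughout (hundreds of complexes of ~15–25 pocket atoms,
single folds for the variant comparison) were chosen to make the whole
suite and the acceptance script run in minutes on one CPU while leaving
every measured effect far from its decision threshold.

## Known limitations

* The all-ones noncovalent adjacency cannot distinguish an engaged from an
  unengaged polar ligand atom when the rest of the pocket is identical;
  after cropping, interaction geometry is invisible to the network. On the
  toys this is mitigated by coupling ligand composition to the planted
  bonds; on real data the richness of pockets plays that role.
* The dense head on a sum-pooled representation means relevance
  conservation is exact only without biases; with trained biases a
  fraction of ŷ is absorbed en route and the contribution total is
  correspondingly smaller.
* Hydrogen-bond detection without hydrogens over-counts relative to
  angle-aware tools; printed counts from structure viewers will match only
  under compatible thresholds.
* Adjacencies are stored dense; pockets beyond ~10³ atoms would need the
  sparse path (not implemented — 5 Å pockets stay far below that).
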