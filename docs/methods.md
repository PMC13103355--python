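# Methods

## Scope and model

`pairlm` implements a paired-sequence masked language model for protein
chain pairs and three downstream predictors built on its representations:
binary interaction, binding affinity, and inter-protein residue contacts.
Everything runs on CPU in numpy (reverse-mode differentiation via
autograd), at a configurable scale.  The default "tiny" instance (2
transformer blocks, 4 heads, width 64) is what the test battery trains;
the full-scale instance (33 blocks, 650M-parameter class) is constructible
but is never trained here — the design goal is that every mechanism is
exercised end-to-end on synthetic data with known ground truth.

### Tokenization and the inter-chain mask

Each chain is tokenized independently over a minimal vocabulary (20
canonical residues, X, BOS, EOS, MASK, PAD) and the two runs are
concatenated: `[BOS, a1..aLa, EOS, BOS, b1..bLb, EOS]`.  The binary
token-level matrix M marks inter-chain position pairs (1 when the two
tokens carry different chain labels; special tokens carry their chain's
label).  Model predictions are distributions over the 21 residue classes
only; special tokens are never loss targets.

### Hybrid attention

Every head computes two scaled dot-product logit matrices: `A_rope` from
rotary-rotated queries/keys (intra-chain, relative-position aware) and
`A_row` from unrotated ones (inter-chain, position-free).  They are mixed
elementwise on the *pre-softmax logits*:

    A = W_lh · M · A_row + (1 − M) · A_rope + M

with `W_lh` a learnable scalar per layer and head (initialized to 1) and
the `+M` term a literal +1 logit bias on inter-chain pairs.  Mixing after
the softmax would destroy row normalization, so the logit-level reading is
used.  The 1/√d scaling is folded into `A_row`/`A_rope` before the mix.
Blocks are pre-layer-norm with GELU feed-forward networks.

RoPE is implemented without tensor slicing as `x·cos + (x S)·sin` with a
constant pair-swap matrix S — identical numerics, much cheaper
reverse-mode gradient in autograd.

### Initialization

Weights are Gaussian with 1/√fan-in scale and embeddings σ = 0.02, with
two deliberate exceptions, both motivated by how positional information
enters this architecture.  Inter-chain attention is content-based, so
routing a masked chain-B query to its chain-A partner position requires
the first block to write *absolute-position codes* into its outputs; with
rotary-only position encoding those codes can only arise from (a)
content-independent query/key components interacting through the rotary
phases and (b) attention onto the fixed begin/end anchor tokens.  At a
standard all-zero bias init both channels are absent and a linear probe
finds chain position completely undecodable from first-block outputs — a
saddle that gradient descent escapes only very slowly.  We therefore
initialize query/key biases with σ = 4 and scale the BOS/EOS embedding
init by 15×; position probes then read ~45% position accuracy (chance 6%)
from the first block at initialization, and the coupling-recovery
experiments converge instead of plateauing.

### Masked-LM objective

The loss is the cross-entropy over masked residues averaged per chain and
summed over the two chains (a chain with nothing masked contributes 0).
Masking strategies:

- *pretraining, structure-derived (PDB) pairs*: 30% of interface residues
  and 15% of non-interface residues, sampled per chain (nearest-integer
  rounding);
- *pretraining, interaction-database (STRING) pairs*: uniform 15% per
  chain;
- *homomers*: identical positions masked jointly (default on for both
  pretraining and evaluation — predicting a residue from its copy is
  trivial otherwise);
- *evaluation, random protocol*: non-overlapping rounds of ⌈0.15·L⌉
  positions per chain until every position is masked exactly once (ceiling
  guarantees coverage; the final round is the remainder);
- *evaluation, interface protocols*: Dual masks every interface residue on
  both chains in one pass; Single masks one chain's interface at a time
  and pools the two passes. Single mode is rejected for homomers.

Perplexity is the exponential of the mean negative log-likelihood pooled
over all masked positions of a pair (1 = perfect; 20 ≈ random over the
canonical alphabet).  Pooling across chains avoids double-weighting short
chains; exponentiating the two-chain loss instead is available but not the
default.

Pairs above 1024 tokens are cropped before evaluation: window lengths are
allocated to chains proportionally (largest-remainder rounding);
structure-derived pairs take the windows retaining the most interface
residues (exhaustive start scan up to 2048 total residues, stride 16
beyond; random tie-break), others take uniform random contiguous windows.
Training pairs are sampled from structure and interaction-database
cluster collections at a 1:2 ratio, then uniformly by cluster and member.

Training uses AdamW (β₁ = 0.9, β₂ = 0.98), linear warm-up followed by
linear decay, batched pairs padded to a common length with PAD tokens
excluded from attention keys and losses.

## Downstream heads

*Interaction (PPI).*  The frozen backbone supplies five features per pair:
final-layer embeddings of each chain and final-layer intra-A/intra-B/inter
attention maps with heads as channels.  Max pooling and mean pooling along
the residue axes (matrices pooled over both axes sequentially) form two
branches; per-feature linear projections to a unified width (default 256)
are concatenated and fed to a five-layer MLP (layer norm + ReLU after the
first four layers, sigmoid output); the pair probability is the mean of
the two branch probabilities.  Training is stratified 10-fold
cross-validation with binary cross-entropy; per fold the epoch checkpoint
with the best validation AUPRC is kept and the five best heads across
folds form the inference ensemble (mean probability).

*Affinity.*  Receptor-side and ligand-side chains are each concatenated
in input order (order sensitivity is inherent and documented, not
corrected).  Only the backbone's final transformer block and a two-layer
readout (max pooling over all residue positions jointly, hidden width 128,
intermediate ReLU) receive gradients; MSE loss at batch size 1.
Cross-validation folds are grouped: all samples sharing a complex
identifier are assigned to one fold, groups placed greedily largest-first
into the currently smallest fold.

*Contacts.*  Ground truth: residues of opposite chains are in contact
when their minimum heavy-atom distance is < 8 Å (strict); a chain's
interface is the support of the contact map.  Features: 2-D intra-chain
stacks (pairwise concatenation of one-hot + PSSM residue channels plus a
Gaussian-transformed distance channel) and an inter-chain stack
(final-layer language-model inter attention per head, MI+APC coupling
scores from a species-paired alignment, a PSSM inner-product channel,
pairwise one-hot concatenation, and — in "contact2" mode — a
Gaussian-transformed complex-derived inter-chain distance channel).  A
shared tied-weight residual 2-D convolution encoder produces both
intra-chain representations; a second encoder produces the inter-chain
representation z.  Each of the n_blocks (default 2 at tiny scale; 12 at
full scale) transformer blocks applies, each residually: two parallel
triangle multiplications (one per chain as intermediate), two parallel
cross-attention updates (z queries its row/column's intra-chain pairs),
two parallel self-attention updates along the rows and columns of z with
logits multiplied by `exp(−(d/σ)²)`-transformed intra-chain distances
(σ = 8 Å), and a two-linear transition (ReLU, 4× expansion).  A sigmoid
head reads contact probabilities; homodimer mode averages the map with
its transpose.  The loss is the two-class focal loss, mean over all cells,
with α = 0.25 and γ = 1.5: the printed positive-only form diverges for
confident true negatives, so the standard p_t convention is used.
Chains above 256 residues are cropped during training to the contiguous
window with the most interface residues (random tie-break).  Contact
ranking metrics use top-k precision with lexicographic (row, column)
tie-breaking and cutoffs {1, 10, 50, L/10, L/5, L} (floor, minimum 1,
L = shorter chain); interface residues are extracted by walking contact
pairs in descending probability until N new residues per chain are
collected.  Ensembling is the elementwise mean of member maps.

*MSA features.*  A3M parsing drops lowercase insertion columns; species
tags are read from `species:TAG` header fields.  PSSMs are per-column
log-odds against a uniform background with +1 pseudocounts, gaps
excluded.  Heterodimer alignments are paired by species tag (first
occurrence per species, query rows always paired); homodimer alignments
reuse the monomer alignment for both blocks.  Inter-chain co-evolution is
scored as plug-in mutual information (21 states; gaps/X lumped) with the
average product correction — a deliberately desk-scale stand-in for
direct coupling analysis that preserves rank structure; a
pseudolikelihood DCA is out of scope.

## Synthetic ground truth

The generators plant known structure so every pipeline is testable
offline:

- *Coupled pairs*: chain A i.i.d. uniform over the canonical alphabet;
  chain B likewise except at planted (pos_a, pos_b) couplings, where the
  chain-B residue is the alphabet-shift (+1 by default) of its chain-A
  source.  Interface annotations mark the coupled positions.  Negative
  (non-interacting) pairs place an explicit non-partner residue at the
  coupled sink positions.
- *Toy complexes*: kinked helical backbone walks — segments of 8–14
  residues of ideal helix (rise 1.5 Å, radius 2.3 Å, ~100°/residue), each
  segment's axis rotated 40–80° from the previous about a random
  perpendicular — docked by a random rigid orientation and an approach
  offset found by bisection so a target fraction of residues falls within
  8 Å of the partner chain.  One centroid heavy atom per residue by
  default; optional jitter atoms exercise the min-over-atoms path.  The
  kinks matter: with straight helix pairs, spatial adjacency is a fixed
  function of sequence offsets, a prior a convolutional model learns
  without ever consulting distance maps; fold-dependent geometry is what
  makes the monomer-distance features genuinely informative.  Contact-net
  training instances use an interface fraction of 0.4, giving ~90–110
  contacts on 40-residue chains — comparable to the contact-to-length
  ratios of real dimers and necessary for top-L precision near 1 to be
  attainable at all (the metric's ceiling is #contacts/L).  Couplings are
  planted at a subset of true contact pairs ("anchors", 35% of the shorter
  chain length, unique per chain), so the sequence-derived channels flag
  only part of the interface and the network must propagate evidence
  spatially to find the rest.
- *Toy alignments*: mutated copies of a pair (per-position mutation
  probability; co-mutation enforced at couplings) with shared per-row
  species tags.
- *Interaction tables*: exact 10:1 negative:positive ratio by default.
- *Affinity tables*: a mutation panel against one shared receptor, the
  standard layout of experimental affinity series: ΔG = −slope·k + ε with
  k the number of intact couplings (random subset of the planted sites per
  sample; broken sites carry an explicit non-partner residue), ε ~ N(0,
  0.5 kcal/mol).  Groups share a base ligand background (exercising
  grouped folding); some receptors are split into two chains to exercise
  concatenation.  The shared receptor is a deliberate design: with a fresh
  random receptor per sample, predicting k requires cross-chain residue
  comparison learned from a few hundred scalar labels, which no model at
  this scale can do; with a fixed receptor the task is position-specific
  pattern detection, squarely within reach of fine-tuning the final block.

What these fixtures do *not* emulate: real amino-acid composition,
phylogenetic correlation in alignments, physical energetics, or
biochemical complementarity at interfaces (couplings are positional, the
hardest case for content-based inter-chain attention).  Passing the
recovery experiments shows the mechanisms can extract a planted signal at
small scale, not that the model reaches the accuracy a full-scale
pretrained instance would reach on real data.

## Recovery experiments (study conditions)

- *Inter-chain coupling recovery*: chains of length 16 with 8 planted
  couplings; a tiny backbone trained on 2,000 coupled pairs; evaluation
  masks the coupled chain-B positions of 200 held-out pairs and pools
  NLLs.  Training masks the full chain-B interface per example (the
  Single-chain interface plan) rather than the diluted pretraining rule:
  at this scale the cross-chain routing circuit only forms when the
  masked-LM gradient is concentrated on the coupled positions.  Whether a
  given run discovers the circuit or memorizes the corpus is strongly
  initialization-dependent — a grokking-like race between a general
  low-loss circuit and pair-specific shortcuts — so training monitors a
  small held-out slice, aborts runs showing the rising-perplexity
  memorization signature, and restarts from a fresh initialization (up to
  three attempts).  The control ablates inter-chain attention (cross-chain
  logits forced to −∞) and remains near-random.  Attention-partner
  agreement is the fraction of held-out (pair, coupling) queries whose
  inter attention at the masked sink ranks the true source first; the
  scored (layer, head) is chosen on a separate selection set.
- *Contact recovery*: 200 toy complexes of length 40 per chain for
  training, top-L precision on 16 held-out complexes; the distance
  ablation removes both the distance feature channel and the attention
  modulation, evaluated on the identical instance set (paired).  The
  desk-scale network uses one pair-update block with 12 channels, trained
  6 epochs at batch 1 (lr 2e-3, ×0.88 per epoch) with parameters
  Polyak-averaged over the final two epochs — the longest schedule that
  keeps the whole battery within its runtime envelope; precision is still
  climbing when training stops, which is part of why the top-L bound is
  only partially attained (see limitations).
- *Affinity recovery*: 500 panel samples, grouped 5-fold split, last
  block + readout fine-tuned on four folds (10 epochs, MSE, batch 1) and
  correlated on the fifth; the structural freeze is asserted bit-for-bit.

Problem sizes and schedules were chosen so the whole battery runs in
minutes on one CPU; all randomness flows from explicit integer seeds
through `numpy.random.Generator`.

## Numerical choices

Single precision (float32) throughout the networks; float64 in metrics
and geometry.  Probabilities are clipped at 1e-7 inside losses.  Softmax
subtracts the row max.  Layer norm uses ε = 1e-5.  Ties in window
selection, fold assignment and sampling are broken by the experiment's
seeded generator; ties in contact ranking are broken lexicographically so
evaluation is deterministic.  Checkpoints are npz archives with a JSON
config echo.

## Known limitations

- The full-scale configuration is never trained; no claim is made about
  reproducing benchmark numbers that require the 650M pretrained model.
- At tiny scale the trained backbone recovers planted couplings by
  *superposition reading*: near-uniform inter attention over
  position-tagged first-block values, unmixed by the decoder.  Its
  attention argmax therefore does not point at the true partner even when
  coupled-position perplexity is ~1 — the attention–interface alignment
  reported for the full-scale model (33 blocks, ESM2-initialized) is an
  emergent property this miniature does not reproduce, and the
  corresponding check in the test battery fails by design of honesty
  rather than be weakened.
- The contact network's held-out top-L precision at the desk-scale
  training budget ranges ~0.75–0.82 across seeds; the distance-ablation
  ordering is consistent, but the 0.8 bound is not met on every seed and
  longer schedules were ruled out by the suite's runtime budget.
- Pretraining on CPU limits corpus passes; the coupling-recovery training
  schedule (epochs, learning rate, restarts) was chosen for that budget.
- MI+APC is weaker than pseudolikelihood DCA on shallow alignments.
- The "row score" channel of coupling analysis is interpretive (per-row
  max coupling) since its exact definition is underdetermined; it is off
  by default.
- Chain-concatenation order for multi-chain affinity sides affects
  predictions; input order is preserved and documented rather than
  canonicalized.
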