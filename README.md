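# pairlm

Paired-sequence protein language modeling for protein–protein
interaction (PPI) analysis, on CPU.

Most protein language models encode one chain at a time and cannot
represent dependencies *between* interacting proteins.  `pairlm` encodes a
pair of chains jointly: the two sequences are tokenized independently,
concatenated with begin/end markers, and passed through transformer blocks
whose attention treats within-chain and cross-chain token pairs
differently.  With M the binary inter-chain indicator and W_lh a learnable
scalar per layer l and head h, each head's pre-softmax attention logits are

    A_lhij = W_lh · M_ij · A_row_lhij + (1 − M_ij) · A_rope_lhij + M_ij

where A_rope uses rotary positional embeddings (relative-position-aware,
for residues of the same chain) and A_row uses no positional encoding
(content-based, for residues of different chains).  Training is a masked
language model: the loss is the cross-entropy over masked residues,
averaged within each chain and summed over the two chains.  Model quality
is reported as perplexity — exp of the mean negative log-likelihood over
masked positions — where 1 is perfect and ~20 is random over the amino
acid alphabet.

On top of the backbone the package provides the three standard PPI tasks:

- **interaction** (`pairlm.ppi`): pooled embeddings + attention maps →
  dual max/mean-pooling branches → five-layer MLPs → averaged probability,
  trained with stratified 10-fold cross-validation and a top-5 ensemble;
- **binding affinity** (`pairlm.affinity`): fine-tunes only the last
  transformer block, max-pools residue embeddings, two fully connected
  layers, MSE loss, group-aware cross-validation folds;
- **inter-protein contacts** (`pairlm.contact`): residual-convolution
  feature encoders and pair-representation transformer blocks (triangle
  multiplication, cross-attention, distance-modulated self-attention,
  transition), trained with focal loss (α=0.25, γ=1.5) against the 8 Å
  heavy-atom contact definition, evaluated by top-k precision.

Everything is trainable and testable offline: `pairlm.synthetic` generates
sequence pairs with planted inter-chain residue couplings, toy helical
two-chain complexes with derivable contact maps, co-varying alignments,
and labeled interaction/affinity tables.  See `docs/methods.md` for the
model details and design choices.

## Worked example

Train a tiny backbone on pairs with planted couplings and evaluate
perplexity with the three protocols:

```python
import numpy as np
from pairlm import (ModelConfig, PairLanguageModel, TrainConfig, train_mlm,
                    evaluate_perplexity_random)
from pairlm.synthetic import default_coupling_spec, gen_coupled_corpus
from pairlm.data import Source

rng = np.random.default_rng(0)
spec = default_coupling_spec(12, 12, 4, rng)        # 4 planted couplings
corpus = gen_coupled_corpus(500, 12, 12, spec, rng, source=Source.PDB)
model, trace = train_mlm(corpus, ModelConfig(),
                         TrainConfig(epochs=3, batch_size=50), rng=0)
held_out = gen_coupled_corpus(5, 12, 12, spec, np.random.default_rng(1))
ppl = np.mean([evaluate_perplexity_random(model, p, 0.15, rng=i)
               for i, p in enumerate(held_out)])
print(f"loss {trace[0]:.2f} -> {trace[-1]:.2f}; held-out perplexity {ppl:.2f}")
```

prints (seed 0):

```
loss 7.02 -> 5.99; held-out perplexity 20.62
```

The loss falls from its random-start value to the ~ln 20 + ln 20
two-chain floor while held-out perplexity still sits at the random anchor
of ~20: synthetic chains are uniformly random except at the planted
couplings, so after this short demonstration run nothing generalizable
has been learned yet.  The full recovery experiment
(`pairlm.experiments.coupling_recovery_experiment`, 2,000 pairs and a
longer restart-guarded schedule) drives perplexity at the coupled
positions to ~1.2-1.5 while an inter-attention-ablated control stays
near 20.

The same pipeline is available from the shell:

```bash
pairlm make-fixtures --out-dir fixtures --n-pairs 100 --seed 0
pairlm pretrain --pairs fixtures/pairs.tsv --fasta fixtures/chains.fasta \
       --out model.npz --epochs 5
pairlm eval-ppl --checkpoint model.npz --pairs fixtures/pairs.tsv \
       --fasta fixtures/chains.fasta --strategy random
```

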