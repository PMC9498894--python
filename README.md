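# multiconv

Multinomial-convolution neural networks for DNA sequence-activity regression
with streamlined, database-interoperable motif discovery.

First-layer convolution kernels are constrained to be multinomial
distributions over A, C, G, T: an unconstrained weight matrix `X` is passed
through a per-row temperature softmax `T[i,j] = exp(a·X[i,j]) / Σ_j' exp(a·X[i,j'])`,
and each length-`L` window `s` of a one-hot encoded sequence is scored by the
background-corrected log-likelihood ratio `Σ_ij ln(T[i,j]/B[j])·s[i,j]`.
Because each kernel is row-stochastic, a trained filter *is* a position
weight matrix — no post hoc interpretation pipeline is needed — and can be
exported to MEME minimal format for use with external tools (e.g. Tomtom).

Both the forward strand and the reverse complement are scored with shared
kernels and pooled jointly, so predictions are invariant under reverse
complementation. The default architecture is 512 filters of length 12 with
ReLU activation, max pooling, dropout 0.4, and a single dense output node; a
conventional five-layer CNN baseline builder is included for benchmarking.
The networks are implemented directly in NumPy with hand-written reverse-mode
gradients (verified against finite differences in the test suite) and an
Adam optimizer — no deep-learning framework required.

## Layout

| module | contents |
|---|---|
| `multiconv.core` | one-hot encoding, reverse complement, multinomial transform, LLR scoring and scanning |
| `multiconv.model` | network builders (multinomial + conventional baseline), training, prediction, JSON checkpoints |
| `multiconv.cv` | fold construction (10/9/81 test/validation/train), Spearman metric, cross-validation, grid search |
| `multiconv.motifs` | motif extraction, information content per position (ICP), Welch ICP comparison, MEME minimal read/write |
| `multiconv.simulate` | synthetic activity data with planted activator/repressor motifs, recovery scoring |
| `multiconv.data` / `multiconv.io` | activity tables (TSV/CSV) and FASTA |
| `multiconv.cli` | `multiconv` command-line entry point |

## CLI

```sh
# generate a synthetic dataset from a YAML spec
multiconv simulate --spec spec.yaml --out sim/ --seed 1

# train on an id/sequence/activity table; writes checkpoint.json + history
multiconv train --config model.yaml --data sim/activity.tsv --out run/ --seed 1

# 10-fold cross-validation report
multiconv cv --config model.yaml --data sim/activity.tsv --out cv/ --k 10 --seed 1

# motifs (MEME file, ICP values, activator/repressor roles) from a checkpoint
multiconv extract --checkpoint run/checkpoint.json --out motifs/

# best LLR hit per motif per sequence
multiconv scan --meme motifs/motifs.meme --fasta queries.fa --out hits/
```

A model config file is a flat YAML mapping of `ModelConfig` fields
(`n_filters`, `filter_length`, `alpha`, `activation`, `pooling`,
`dropout_rate`, `l2_factor`, `batch_size`, `learning_rate`, `max_epochs`,
`early_stopping_patience`, `seed`, ...). A simulation spec lists planted
motifs as consensus strings with weights; see `multiconv.config` docstrings.

## Library example

```python
import numpy as np
from multiconv import (ModelConfig, build_multinomial_cnn, train, predict,
                       extract_motifs, write_meme, read_activity_table)

data = read_activity_table("activity.tsv")
idx = np.random.default_rng(0).permutation(len(data))
model = train(build_multinomial_cnn(ModelConfig(seed=0)),
              data.subset(idx[200:]), data.subset(idx[:200]))
motifs = extract_motifs(model)       # one PWM + dense weight per filter
write_meme(motifs, "motifs.meme")    # ready for Tomtom
```

## Background distribution

All LLR and ICP computations default to the human genomic background
A 0.295, C 0.205, G 0.205, T 0.295 (`multiconv.DEFAULT_BACKGROUND`); any
`BackgroundDistribution` can be substituted.
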