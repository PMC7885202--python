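# splicenas

Differentiable neural architecture search for splice-site classification on
raw DNA sequences — a pure scientific-Python implementation (numpy +
[autograd](https://github.com/HIPS/autograd) + numba, no deep-learning
framework required).

Labelled DNA windows are one-hot encoded (channel order A, T, C, G) into
`(n_d x 4)` matrices and fed to a stack of convolutional *cells*.  During the
search stage every cell edge carries a softmax-weighted mixture over eight
candidate operations (separable 3x3/5x5/7x7 convolutions, dilated 3x3
separable convolution, a 7x1-then-1x7 convolution, 3x3 max/average pooling,
and a zero op); the mixture coefficients `alpha` and the operation weights
`omega` are optimized in an alternating bilevel loop (Adam on the validation
loss for `alpha`, momentum SGD with cosine-annealed learning rate on the
training loss for `omega`).  The best-validation-accuracy epoch's mixture is
discretized into a *genotype* (two strongest incoming edges per node, argmax
non-zero operation per edge), which is retrained from scratch as a fixed
network and evaluated with accuracy / sensitivity / specificity / F-score /
AUC plus ROC and precision–recall curves.  A planted-motif simulator
generates balanced, provably separable datasets so the entire pipeline runs
offline on one CPU.

## Layout

| module                    | contents                                                                  |
| ------------------------- | ------------------------------------------------------------------------- |
| `splicenas.seqdata`       | FASTA/TSV readers, one-hot encode/decode, seeded 0.8/0.1/0.1 split        |
| `splicenas.search_space`  | primitive operation set, ReLU–Conv–BN blocks, softmax mixed edge          |
| `splicenas.cell_network`  | cell DAGs, genotype JSON format, stacked network, parameter counting      |
| `splicenas.engine`        | bilevel optimization, genotype derivation, the search loop                |
| `splicenas.evaluation`    | fixed-network training, metric suite, transfer trimming                   |
| `splicenas.synthetic`     | planted-dimer dataset generator with tunable difficulty                   |
| `splicenas.cli`           | `splicenas` command-line entry point                                      |
| `splicenas.nnops`         | autograd primitives with hand-written gradients (+ traced references)     |

## CLI

```sh
splicenas simulate --n 2000 --length 141 --decoy-rate 0 --seed 1 --out data.tsv
splicenas encode   --in data.tsv --out report.json
splicenas search   --in data.tsv --epochs 50 --seed 1 \
                   --out-genotype cell.json --out-history history.tsv
splicenas train    --in data.tsv --genotype cell.json --epochs 70 \
                   --seed 1 --out-prefix model
splicenas eval     --in data.tsv --weights model --seed 1 --out-prefix results
```

Datasets are two-column TSV (`sequence<TAB>label`, no header) or FASTA with a
`label=<0|1>` token in each header.  Hyperparameters can also be supplied via
an INI config file (sections `data`, `search`, `network`, `train`, `eval`)
passed with `--config`; explicit flags win.  Every command writes a
`*.manifest.json` recording the fully resolved configuration and seed.

## Notes

* Batch normalization always uses current-batch statistics (search and
  evaluation both operate on mini-batches); scoring therefore proceeds in
  fixed-order batches.
* Determinism: every source of randomness (simulation, splitting, parameter
  initialization, shuffling) derives from the seed passed to the respective
  config; single-threaded runs are bit-reproducible.
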