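# rbpadda

Adversarial domain adaptation for RNA-binding-protein (RBP) affinity
regression.

RBP binding preferences are measured by two kinds of experiment that
disagree in systematic ways: in vitro assays (RNAcompete-style probe
intensities) have a high signal-to-noise ratio, while in vivo assays
(eCLIP-style peak enrichments) are noisier, cell-type dependent and
confounded by other trans-acting factors.  Models trained on one kind
of data often transfer poorly to the other — a classic *domain shift*.
This package trains a per-RBP affinity regressor jointly from both
domains with an adversarial discriminative domain-adaptation (ADDA)
strategy, and interprets the trained model with integrated gradients.

It is aimed at computational biologists who want to model sequence
intensities from paired in vitro ("source") and in vivo ("target")
tables, and at methods developers who want a small, fully-tested,
numpy-only reference implementation of the three-step adversarial
training loop.

## The model

Four parameterized functions are trained: a source encoder *Mₛ*, a
target encoder *Mₜ* (same CNN architecture: two convolution layers of
32 filters, sizes 4×4 and 4×1, each followed by ReLU and max-pooling,
then fully connected layers of 128 and 64 units), a task predictor *T*
(64 → 32 → 1, linear head) and a domain discriminator *D* (64 units,
sigmoid head).  Sequences are one-hot encoded (A, C, G, U; `N` and
padding are zero rows) at a fixed length of 41 nt; intensities are
min–max scaled to [−1, 1] on the training split.

Training proceeds in three steps:

1. **Pre-training** — minimize the source squared error
   `L₁ = mean (T(Mₛ(xₛ)) − yₛ)²`.
2. **Domain adaptation** — initialize *Mₜ* from *Mₛ*, then alternate a
   least-squares discriminator update
   `L₂ = ½[(D(Mₛ(Xₛ)) − 1)² + (D(Mₜ(Xₜ)) − 0)²]`
   with a target-network update
   `L₃ = (D(Mₜ(Xₜ)) − 1)² + (T(Mₜ(Xₜ)) − Yₜ)²`
   (fool the discriminator while fitting the target labels); *Mₛ* and
   *T* stay frozen.
3. **Fine-tuning** — update only *T*, at a much smaller learning rate,
   on both domains simultaneously:
   `L₄ = (T(Mₛ(Xₛ)) − Yₛ)² + (T(Mₜ(Xₜ)) − Yₜ)²`.

Predictions route by domain — `T(Mₜ(x))` for target sequences,
`T(Mₛ(x))` for source sequences — and performance is reported as the
Pearson correlation between predicted and observed intensities on
held-out data.  A `without_adda` ablation skips step 2 entirely and a
`reversed` mode swaps the two domains.  Training-time sequence
augmentation (Replacement / Swap / Gap operators) and an integrated-
gradients interpretation layer (per-nucleotide attributions, consensus
5-mer extraction, PWM/logo export) round out the pipeline.

There is no deep-learning framework underneath: the forward and
backward passes of all four networks are written directly on numpy
arrays and verified against finite differences in the test suite.

## Worked example

Simulate a domain-shifted dataset pair (a planted `UGUGU` motif drives
the intensity; the target domain has 3× noise, fewer sequences and a
CA-rich confounder), train, and interpret:

```bash
rbp-adda simulate --n-source 2000 --n-target 800 --seed 7 --out fixture

cat > config.yaml <<'YAML'
data:
  source: fixture/source.tsv
  target: fixture/target.tsv
training:
  n1: 350
  n2: 300
  n3: 150
  early_stop_patience: 5
  seed: 7
YAML

rbp-adda run --config config.yaml --out run
```

which prints the held-out Pearson correlation per step and domain:

```
pretrain	source	pearson=0.5521
pretrain	target	pearson=0.3969
adapt	source	pearson=0.5521
adapt	target	pearson=0.3969
finetune	source	pearson=0.5333
finetune	target	pearson=0.3836
```

Source-domain performance is higher than target-domain performance, as
expected from the signal-to-noise gap.  On this replicate the
adaptation step was not retained (the `adapt` row repeats the
`pretrain` value): the validation-based do-no-harm rule only keeps the
adapted target encoder when it confirms a real improvement, which with
800 noisy target sequences is frequently not the case.

Interpretation of the trained model:

```bash
rbp-adda attribute --checkpoint run/checkpoint.npz \
    --input fixture/source.tsv --domain source --out attr
```

```
top1	source:1304	pred=0.837	top-5-mer=GCUUA@26
top2	source:1222	pred=0.755	top-5-mer=GAAUU@11
...
consensus	UGUGU
```

The five sequences with the highest predictions (all above the 0.5
threshold) are attributed with integrated gradients, and pooling the
5-mer window attributions across them recovers the planted motif
`UGUGU` as the consensus; `attr/` contains per-sequence attribution
tables and logos plus the consensus PWM.

Other verbs: `encode` (one-hot arrays to `.npz`), `predict`
(checkpoint → per-sequence predictions), `augment-preview` (show the
augmentation operators), `grid` (the hyper-parameter grid runner).
Input tables are two-column TSV (`sequence<TAB>intensity`) or FASTA
with `score=<float>` in the header; `T` is transliterated to `U` on
read, and CLIP peaks outside the 26–41 nt band are padded or split
into 10-nt-overlap windows automatically.

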