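# agsam

Agent-guided automatic prompting for a frozen promptable segmentation model,
aimed at few-shot medical image segmentation.

## The problem

Promptable foundation segmenters (SAM-style: a large image encoder, a prompt
encoder, and a mask decoder) segment almost anything — but only when a human
supplies point or box prompts.  In clinical few-shot settings (1–20 labelled
images of cardiac ultrasound or retinal fundus photographs) there is too
little data to fine-tune such a model, yet its pre-trained encoder *and*
decoder carry exactly the generic segmentation skill the task needs.

This package implements an agent-guided architecture that makes the frozen
foundation pair fully automatic.  A small trainable **agent** segmentation
network (FCN-, DeepLabV3-, or tiny conv-style) is trained on the few labelled
images; its prediction and features replace the human prompts:

- dual-path encoding: `f_SAM = M_SAM_enc(I)` (frozen), `f_Agent = M_agent_enc(I)`;
- a **confusion module** fuses them:
  `f_Fused = Conv1x1(f_Agent ⊕ resize(Conv3x3(f_SAM)))`;
- the agent decoder predicts `Mask_agent` from `f_Fused`;
- two prompt-generation paths (average pooling, seven **FACM** blocks of
  which the first three have stride 2, a 1×1 conv; total downsampling 1/16)
  turn `Mask_agent` into **sparse** per-class prompt tokens and `f_Fused`
  into a **dense** spatial prompt embedding;
- the frozen mask decoder produces `Mask_SAM = M_SAM_dec(p_sparse, p_dense)`;
- the final prediction is the convex mask fusion
  `Mask_pred = (1 − α)·Mask_SAM + α·Mask_agent`;
- training minimises the dual Dice loss `L_all = L_Agent + L_pred`,
  back-propagating *through* the frozen decoder (frozen ≠ detached).

The **FACM** (feature augmentation convolution module) is a 3×3 convolution
whose output, during training, is randomly linearly suppressed:
`x_aug = α·x + β` with `α ~ U(0.25, 1)` and `β ~ U(−10, 10)`, or zeroed with
small probability.  At inference it is exactly a single convolution.

Everything runs on one CPU: the package ships a **seeded surrogate
foundation pair** (pre-trainable on synthetic phantoms in seconds, then
frozen) and a **phantom generator** that emulates the nested anatomy of the
two target domains — endocardium / epicardium / left-atrium wall for
cardiac ultrasound, optic disc / cup for fundus photographs.  A full-scale
profile (256-px inputs, ResNet-50-shaped agent trunk, ViT-b-shaped frozen
encoder, 256×16×16 embeddings) and a mini profile (64-px, CPU-trainable)
share one code path.  The neural-network machinery itself — reverse-mode
autodiff over numpy arrays, conv/attention layers, AdamW — is part of the
package (`agsam.autodiff`, `agsam.nn`).

## Worked example

```bash
python examples/02_few_shot_training.py
```

trains the full guided model and an identically budgeted agent-only
baseline on **two** labelled cardiac phantoms and evaluates on eight
held-out ones:

```
full guided model: held-out mean foreground Dice = 0.876 (best epoch 4)
agent-only baseline: held-out mean foreground Dice = 0.544 (best epoch 7)
```

The gap is the value of the frozen pre-trained encoder/decoder when
training data are scarce.  Other examples cover phantom generation
(`01`), the evaluation metrics (`03`), the FE/MD/FACM module ablation
(`04`), and the full-scale tensor contracts (`05`).

The same workflows are available from a thin CLI:

```bash
agsam synth --n 30 --out phantoms/ --seed 0
agsam demo --out demo/ --seed 0          # synth → few-shot train → evaluate → ablate
agsam validate-config cfg.yaml
```

## Layout

```
src/agsam/
  autodiff.py    reverse-mode autodiff core (conv, attention, resize, ...)
  nn.py          layers, parameter management, AdamW
  profiles.py    full / mini scale profiles
  phantom.py     synthetic cardiac & fundus phantoms
  data.py        manifests, pre-processing, augmentation, few-shot splits
  backbone.py    agent encoder variants (fcn / deeplab / tiny) + decoder
  foundation.py  frozen foundation contract + seeded surrogate
  prompts.py     confusion module, FACM, sparse/dense prompt paths
  core.py        model assembly, dual Dice loss, training loop, ablations
  metrics.py     Dice, Hausdorff, sensitivity/specificity/AUC/AUPR, t-tests
  experiments.py packaged few-shot comparison protocol
  cli.py         click CLI (synth/train/predict/evaluate/ablate/demo/...)
```

See `docs/methods.md` for the modelling choices, parameter defaults and
known limitations.
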