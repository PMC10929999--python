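# selfseg

Semi-supervised **self-annotation** for multi-organ segmentation of
anisotropic 3D images.

Expert contours for organs-at-risk (OARs) in pelvic imaging — bladder,
femoral heads, rectum, small intestine — are expensive, while unlabeled
volumes accumulate freely. `selfseg` implements the self-training recipe
for exactly this situation: train a small ensemble of U-Nets on the few
labeled cases via k-fold cross-validation, pseudo-label the unlabeled
volumes by **average voting** over the ensemble's softmax probabilities,
repair the pseudo-labels morphologically (fill cavities, drop spurious
fragments), and retrain a single model on the enlarged set. The package is
aimed at researchers studying annotation-efficient medical segmentation
who want a complete, CPU-runnable, deterministic reference pipeline —
including a synthetic phantom generator so every stage is testable without
clinical data.

## The method in brief

Training minimizes a composite loss

```
L = a · (1 − softDice(p, y)) + (1 − a) · CE(p, y),        a = 0.5
```

with per-organ soft Dice `(2Σpy + s)/(Σp + Σy + s)` and 5-class
categorical cross-entropy over the softmax output `p` and one-hot
reference `y`. The 2D/3D U-Nets use convolution → instance norm → leaky
ReLU blocks, strided convolutions down, transposed convolutions up; the
3D variant down-samples z only twice (thick slices) while halving the
in-plane axes six times (256 → 4). Given k fold-models `m_1..m_k`, a
pseudo-label is

```
ŷ(v) = argmax_c  (1/k) Σ_i  softmax(m_i(v))_c
```

followed by per-class hole filling, largest-component retention (bladder
1, femoral heads 2, rectum 1, intestine unlimited) and optional closing.
Evaluation reports DSC = 2|P∩G|/(|P|+|G|) plus the spacing-aware surface
distances HD, HD95 and ASD in mm, a six-bin expert revision score, and the
composite accuracy `Σ_organ (DSC + score/5)`.

Everything — network, backprop, Adam — is implemented in NumPy with an
im2col convolution engine, so the full pipeline runs on one CPU with
bit-reproducible results under fixed seeds. See `docs/methods.md` for the
complete model description, conventions and limitations.

## Worked example

Generate a phantom cohort and run both arms of the label-budget study
(10 labeled + 30 unlabeled cases, 10 held-out test cases):

```python
from selfseg import PhantomConfig, NetworkConfig, TrainConfig
from selfseg.cli import ExperimentConfig, run_supervised, run_semisupervised
from selfseg.metrics import summarize_report

cfg = ExperimentConfig(
    out_dir="runs/demo",
    phantom=PhantomConfig(grid_shape=(16, 48, 48),
                          spacing_mm=(6.5, 2.656, 2.656), seed=45),
    n_labeled=10, n_unlabeled=30, n_test=10,
    net=NetworkConfig.preset("2d_test"),
    train=TrainConfig(epochs=10, batch_size=4, learning_rate=0.01,
                      patch_size=(1, 48, 48), foreground_fraction=0.5),
    seed=3,
)
supervised = run_supervised(cfg)
semi = run_semisupervised(cfg)          # writes runs/demo/... artifacts
print(summarize_report(semi).to_string(index=False))
print(f"supervised mean DSC:      {supervised['dsc'].mean():.4f}")
print(f"semi-supervised mean DSC: {semi['dsc'].mean():.4f}")
```

which prints (this exact run, ~5 min on one CPU):

```
 organ_class           organ      dsc     hd_mm   hd95_mm   asd_mm
           1         bladder 0.971678  4.126970  1.446800 0.294956
           2   femoral_heads 0.876328  5.823645  3.624795 0.790954
           3          rectum 0.723289 14.874135 13.046277 3.731243
           4 small_intestine 0.935378  4.275515  2.185167 0.393351
supervised mean DSC:      0.8624
semi-supervised mean DSC: 0.8767
```

The summary rows are per-organ means over the 10 held-out test cases:
overlap (DSC, 1 = perfect) and surface disagreement in millimetres (HD,
HD95, ASD; 0 = perfect). The thin, low-contrast rectum is the hardest
structure. The retrained semi-supervised model beats the 10-label
supervised baseline (0.8767 vs 0.8624 mean DSC) by exploiting the 30
unlabeled cases — the package's central reproducible effect. Every run
writes a `run_manifest.json` (config hash, seeds, artifact paths)
sufficient to replay it; rerunning with the same config reproduces the
report.

A command-line interface mirrors the library:

```bash
selfseg generate-cohort runs/cohort --n-labeled 10 --n-unlabeled 30 --n-test 10
selfseg run-semisupervised --config experiment.yaml --seed 1
selfseg evaluate runs/pred runs/ref runs/report.csv
selfseg compare runs/a/report.csv runs/b/report.csv
```

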