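# dstan — dual-stream spatiotemporal attention network for micro-expression recognition

Micro-expressions are involuntary facial movements lasting under a fifth of a
second, with motion amplitudes of a pixel or two — too subtle and too brief
for ordinary expression classifiers, and the labelled corpora that exist
(SMIC, CASME, CASME II) are small and subject-structured. `dstan` implements
a dual-stream spatiotemporal attention network for this regime, end to end:

* **STAN-A** (appearance stream) consumes the raw frame sequence, normalised
  to a fixed length *t* and frame size;
* **STMN-A** (motion stream) consumes the dense optical-flow sequence between
  adjacent frames;
* both streams share a lightweight backbone of five [3×3 conv → batch norm →
  ReLU → 2×2 max-pool] blocks, refined by three attention mechanisms:
  - **multiscale-kernel spatial attention** on a low-level map *F*ˡ:
    *S*ₘ = Convₘ(*F*ˡ) for 1×1 / 3×3 / 5×5 kernels,
    *SA* = σ(Conv⁴(concat(*S*₁, *S*₂, *S*₃))), *F_S* = *SA* ⊗ *F*ˡ;
  - **global dual-pool channel attention** on the high-level map *F*ʰ:
    *C_b* = *w*₂ δ(*w*₁ pool(*F*ʰ) + *b*₁) + *b*₂ for GAP and GMP pooling
    with shared weights, *CA* = σ(*C*₁ ⊕ *C*₂), *F_C* = *CA* ⊗ *F*ʰ;
  - **temporal attention** per frame: *r*ᵢ = σ(*u*·*S*ᵢ + *b*), *S*ᵢ′ = *S*ᵢ *r*ᵢ;
* the appearance stream fuses low-level texture and high-level semantic
  descriptors (LHFN: 1×1 conv + global average pooling on each, concatenated);
* per-frame features pass through a single-layer LSTM and **temporal average
  pooling**, *f* = (1/*t*) Σᵢ *v*ᵢ, then an affine classifier + softmax;
* the two streams are integrated by **feature concatenation + linear SVM**
  (DSTAN-SVM), with unweighted probability averaging (DSTAN-Average) as the
  baseline;
* evaluation is **leave-one-subject-out cross-validation** (LOSOCV) with
  accuracy, macro precision/recall/F1 and confusion matrices.

The network layers (convolution, batch norm, pooling, LSTM, the three
attention blocks, Adam, cross-entropy) are implemented in NumPy with explicit
backpropagation (`dstan.nn`), with optional numba-compiled inner loops; no
deep-learning framework is required. Optical flow uses scikit-image
(iterative Lucas–Kanade by default, TV-L1 available, or any callable you
plug in), and the fusion SVM is scikit-learn's linear-kernel SVC.

Because the real corpora are access-restricted, the package ships a
first-class **synthetic micro-expression generator** (`dstan.synthetic`):
per-subject face-like templates with localized, Gaussian-windowed
onset–apex–offset deformations, per-class motion direction or brightness
cues, nuisance drift and noise. Every pipeline stage is tested against it.

## Worked example

```python
from dstan.benchmark import run_benchmark

result = run_benchmark(master_seed=0)   # 8 subjects x 3 classes x 6 sequences
for method, report in result.reports.items():
    print(f"{method}: acc={report.accuracy:.3f} f1={report.f1:.3f}")
```

This generates the 144-sequence synthetic corpus (9 frames, 64×64), computes
flow, trains both streams from scratch inside each of the 8
leave-one-subject-out folds, fuses them, and pools the test predictions.
Output from the run above:

```
stan: acc=0.708 f1=0.698
stmn: acc=0.847 f1=0.849
dstan_svm: acc=0.993 f1=0.993
dstan_average: acc=0.903 f1=0.903
```

Read: the appearance stream alone reaches 70.8% pooled accuracy, the motion
stream 84.7%, and the fused DSTAN-SVM 99.3% — the two streams carry
complementary cues by construction (motion direction vs. apex brightness),
so fusion recovers what either stream alone misses. A zero-amplitude control
corpus (no class signal) under the identical pipeline stays at chance
(~1/3), confirming the benchmark is not leaking identity or structure.

The same pipeline is scriptable from the shell:

```bash
dstan synth --out data/ --seed 0          # corpus on disk + labels.csv
dstan preprocess --config config.yaml     # cached frames + flows (content-hashed)
dstan train-eval --config config.yaml     # reports, confusions, predictions.csv
dstan report --predictions runs/out/predictions.csv   # metric audit
```

Real data drops in the same way: frame directories (or videos) plus a
`labels.csv` with `sample_id, subject_id, label, path`; faces are expected
pre-cropped and aligned (an alignment hook is exposed, detection itself is
out of scope).

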