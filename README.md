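# wmdecode

Decoding item-specific working-memory content from delay-period fMRI in a
retro-cue orientation task.

In the emulated paradigm, an observer studies two orientation gratings in
sequence, a retrospective cue indicates which one to retain, and after a
5-TR delay the cued orientation is reproduced continuously. The scientific
question is whether multi-voxel activity patterns recorded during the delay
carry information about the cued item (and not the uncued one), and whether
the quality of that neural information predicts recall precision.
`wmdecode` implements the complete analysis pipeline for this question —
plus a synthetic-data generator that emulates the task — so every stage can
be validated end-to-end without access to scanner data.

## What the pipeline computes

**Inverted encoding model (IEM).** Voxel patterns are modeled as weighted
sums of k = 9 idealized orientation channels (half-wave rectified
sinusoids, `max(0, cos(πΔθ/180))^p`, centered on the 9 stimulus
orientations):

    B = W C + N,           W = B₁C₁ᵀ(C₁C₁ᵀ)⁻¹

Decoding uses per-channel optimal linear filters that account for
correlated voxel noise. For channel i, the residual εᵢ = B₁ − WᵢC₁ᵢ gives a
noise covariance Σᵢ = εᵢεᵢᵀ/(n₁−1), regularized by analytic
(Ledoit–Wolf-style) shrinkage toward a scaled identity, and

    Vᵢ = Σᵢ⁻¹Wᵢ / (WᵢᵀΣᵢ⁻¹Wᵢ),       C₂ = VᵀB₂

so each filter has unit gain on its own channel. A leave-one-block-out
routine decodes every trial exactly once; reconstructions are interpolated
to a 1° grid, circularly aligned to the trial's orientation label, and
reduced to the information metric

    z = (1/k) Σₖ Cₖ e^{2iψₖ},        R = |z| cos(arg z) = Re(z)

which is 0 for flat reconstructions and positive when response mass
concentrates at the aligned center.

**Stimulus-based RSA.** Trial-pair cosine similarity of delay patterns is
rank-correlated (Spearman, Fisher-z transformed) with a stimulus similarity
model, 180° minus the circular orientation distance between trial labels.

**Behavior linkage.** Recall errors are signed circular differences in
[−90°, 90°). Trials are split into small (<20°) and larger (20° to 3·SD of
the pooled error distribution, or a fixed 45° cut-off) error categories;
small-error reconstructions are balanced to the larger-error trial count by
5000-fold subset resampling before the within-subject contrast.

**Group statistics.** Paired t-tests with Cohen's d, 1000-iteration
subject-level bootstrap p values, Bonferroni correction, and the 2×2
cue-by-region interaction (one-sample test on the per-subject
difference-of-differences; F(1, n−1) = t²).

## Worked example

```python
import numpy as np
import wmdecode as wd
from wmdecode.delay import extract_delay_patterns

cfg = wd.SimConfig(n_voxels=24, seed=1)          # 10 blocks x 18 trials
basis = wd.ChannelBasis()                        # 9 channels, p = 8
cued, uncued = [], []
for sub_seed in wd.subject_seeds(cfg):           # 16 subjects
    trials, runs, _ = wd.simulate_subject(cfg, sub_seed)
    pat = extract_delay_patterns(runs)           # z-score + TENT (0,1,2,1,0)
    cued.append(wd.lobo_cv(pat, trials, basis, "cued").mean_R)
    uncued.append(wd.lobo_cv(pat, trials, basis, "uncued").mean_R)
res = wd.paired_test(cued, uncued)
print(f"cued R = {np.mean(cued):.3f}, uncued R = {np.mean(uncued):.3f}, "
      f"t({res.df}) = {res.t:.2f}")
```

prints

```
cued R = 0.177, uncued R = 0.032, t(15) = 68.12
```

i.e. delay-period patterns reconstruct the cued orientation far above
chance, while the uncued item carries only the marginal information implied
by the task's item-separation constraint. (Simulated subjects share the
same signal-to-noise level, so t values are much larger than any real
between-subject study would give.)

The same pipeline is scriptable from the shell:

```bash
wmdecode simulate --out-dir out/sim
wmdecode extract  --in-dir out/sim --out-dir out/pat
wmdecode iem      --sim-dir out/sim --pattern-dir out/pat --out-dir out/iem
wmdecode report   --iem-dir out/iem --out-dir out/report
```

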