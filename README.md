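# spinemorph

Quantitative lumbar spine morphometry from labeled mid-sagittal segmentation
masks, for researchers who have vertebral-body and disc segmentations (from
annotators or an automated model) and need reproducible disc-health metrics
and inter-rater agreement statistics.

Given a 2D label mask covering the vertebral bodies L1–S1 and the
intervertebral discs L1/2–L5/S1, the package measures per-structure heights
along each level's local axis and computes the **Disc Height Index**

```
DHI = 2 · IVD height / (cranial VB height + caudal VB height)
```

a dimensionless, scanner-independent measure of disc health. Around that
core it provides:

- **mask I/O** — single-channel PNG and NIfTI-1 label masks with physical
  pixel spacing and a configurable JSON label scheme (default: L1..S1 → 1..6,
  L1/2..L5/S1 → 7..11); 3D NIfTI volumes yield their mid-sagittal slice;
- **agreement** — per-structure Dice (DSC) and IoU, Bland-Altman analysis of
  paired DHI series (bias, SD, 1.96·SD limits of agreement, paired t-test),
  and squared-Pearson R² with percentile-bootstrap 95% CIs (1000 resamples),
  pooled or per level;
- **preprocessing** — percentile histogram clipping (0.5th/99.5th by
  default), square median filtering (kernel 11), and physical-extent-preserving
  geometric scaling, plus a seeded augmentation sampler;
- **synthetic phantoms** — parametric sagittal spine phantoms with analytic
  ground-truth heights/DHI and a rater-style boundary-perturbation model, so
  the whole pipeline is testable without patient data;
- **CLI** — batch DHI reports and two-rater agreement summaries over
  directories of masks.

## Worked example

```python
from spinemorph import (SpinePhantomSpec, RaterPerturbSpec, generate_phantom,
                        perturb_mask, compute_all_dhi, overlap_report,
                        PairedSeries, bland_altman, bootstrap_r2)

# a random spine phantom with known geometry
spec = SpinePhantomSpec.sample(seed=42)
mask, truth = generate_phantom(spec)
for rec in compute_all_dhi(mask):
    print(f"{rec.level:6s} ivd={rec.ivd_height_mm:5.2f} mm  "
          f"cr={rec.cranial_vb_height_mm:5.2f}  ca={rec.caudal_vb_height_mm:5.2f}  "
          f"DHI={rec.dhi:.3f}  (truth {truth.dhi[rec.level]:.3f})")

# simulate a second annotator and run the agreement suite
rater_b = perturb_mask(mask, RaterPerturbSpec(boundary_sd_px=1.0, seed=7))
print(overlap_report(mask, rater_b, "dsc"))
a = [r.dhi for r in compute_all_dhi(mask)]
b = [r.dhi for r in compute_all_dhi(rater_b)]
labels = tuple(("subj0", r.level) for r in compute_all_dhi(mask))
series = PairedSeries(labels, a, b)
ba = bland_altman(series)
print(f"bias={ba.mean_diff:+.4f}  sd={ba.sd_diff:.4f}  "
      f"LoA=[{ba.loa_low:+.4f}, {ba.loa_high:+.4f}]  p={ba.p_two_sided:.3f}")
ci = bootstrap_r2(series, seed=1)
print(f"R2={ci.r2:.3f}  95% CI=[{ci.ci_low:.3f}, {ci.ci_high:.3f}]")
```

Output:

```
L1/2   ivd= 9.61 mm  cr=30.50  ca=27.49  DHI=0.331  (truth 0.343)
L2/3   ivd=10.86 mm  cr=27.49  ca=30.89  DHI=0.372  (truth 0.373)
L3/4   ivd= 8.65 mm  cr=30.88  ca=29.56  DHI=0.286  (truth 0.288)
L4/5   ivd= 7.42 mm  cr=29.57  ca=24.81  DHI=0.273  (truth 0.272)
L5/S1  ivd= 9.26 mm  cr=24.80  ca=31.79  DHI=0.327  (truth 0.329)
DSC 0.9884 ± 0.0020
bias=+0.0048  sd=0.0055  LoA=[-0.0060, +0.0156]  p=0.122
R2=0.981  95% CI=[0.931, 1.000]
```

Measured DHI tracks the phantom's analytic ground truth to within 0.02 at
0.5 mm resolution; the simulated 1 px annotator jitter costs about one DSC
point and produces a small DHI bias between "raters" that the Bland-Altman
summary exposes.

## Command line

```
spinemorph dhi     --input masks/ --out report/            # per-subject DHI CSV
spinemorph agree   --a raterA/ --b raterB/ --seed 1 --out agree/
spinemorph phantom --n 30 --seed 1 --out phantoms/
```

`dhi` writes `dhi_report.csv` (one row per subject and level, incomplete
levels flagged rather than dropped) and `report.json` (run metadata and
error rows — a corrupt file never aborts the batch). `agree` pairs masks by
filename and writes per-structure overlap scores, the pooled Bland-Altman
summary of DHI, and per-level bootstrap R² CIs. `--scheme FILE` overrides
the label coding with a JSON mapping.

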