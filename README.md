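# fgsquant

Quantitative image analysis for comparing fluorescence-guided-surgery
(FGS) contrast agents — e.g. a near-infrared (NIR) protease-activated
probe against the clinical standard 5-ALA/PPIX — in orthotopic brain-tumor
models, with a synthetic phantom generator so the whole pipeline is
testable without any animal or patient data.

The package is aimed at preclinical imaging groups who quantify coronal
brain sections, tissue homogenates, and ex-vivo fragment assays, and want
those readouts reproducible and validated against known ground truth.

## What it computes

* **TNR** (tumor-to-normal-brain ratio): the tumor ROI is segmented from
  the nuclear-dye channel (Otsu threshold, opening, largest component),
  mirrored across the hemispheric midline to obtain a matched
  contralateral normal-brain ROI, and transferred into the co-registered
  fluorescence channel; TNR = mean(tumor) / mean(normal).
* **Discriminative RGB→gray projection** for PPIX blue-light images: each
  pixel is mapped to v·(R,G,B), where the unit vector
  v = (m_T − m_N)/‖m_T − m_N‖ maximizes the separation of the median
  tumor and normal colors; cohort images are converted with the mean of
  the per-sample vectors, and the projected image feeds the same TNR
  computation.
* **Supporting readouts**: per-pixel normalization to the contralateral
  mean, between-section coefficient of variation, weight-normalized
  homogenate TNR, stained/unstained MFI ratio, reference-normalized
  ex-vivo fragment activation and group fold differences.
* **Statistics**: Mann-Whitney U, Wilcoxon signed-rank and paired t,
  with exact enumeration-based p-values at the small sample sizes these
  studies use.
* **Phantoms**: elliptical-tumor multi-channel sections with configurable
  true contrast ρ, noise, infiltrating margin and PPIX-like colors, plus
  homogenate and ex-vivo table generators — all pure functions of
  (parameters, seed).

## Worked example

```python
import fgsquant as fq

spec = fq.PhantomSpec()          # 192x192 section, true NIR contrast 30
sec = fq.generate_section(spec, seed=1)

tumor = fq.segment_tumor(sec.nuclear)
normal = fq.mirror_roi(tumor, sec.midline_col)
res = fq.compute_tnr(sec.nir, tumor, normal, agent="6QC-ICG")
print(f"tumor mean {res.tumor_mean:.3f} AU over {res.tumor_pixels} px")
print(f"normal mean {res.normal_mean:.3f} AU over {res.normal_pixels} px")
print(f"TNR = {res.tnr:.2f}  (true contrast 30)")

v = fq.optimal_projection(fq.median_color(sec.rgb, tumor),
                          fq.median_color(sec.rgb, normal))
print("projection vector:", v.v.round(4))
print(f"projected PPIX TNR = {fq.ppix_tnr(sec.rgb, tumor, normal, v).tnr:.2f}")
```

prints

```
tumor mean 29.998 AU over 1625 px
normal mean 1.001 AU over 1625 px
TNR = 29.96  (true contrast 30)
projection vector: [ 0.9434 -0.0029 -0.3317]
projected PPIX TNR = 17.55
```

The estimated TNR (29.96) recovers the phantom's true contrast (30) to
0.1% despite 5% additive noise, because segmentation, mirroring and the
ratio of means are each unbiased under the generative model.  The fitted
projection vector weights red positively and blue negatively — exactly
the red-pink-over-blue contrast PPIX produces — and yields a projected
contrast of ~17.6 where a plain luminance conversion would see far less.

The end-to-end comparison (simulate cohort → segment → TNR for both the
NIR agent and the projected PPIX image → paired test) runs from one
config:

```python
from fgsquant.pipeline import PipelineConfig, run_pipeline
result = run_pipeline(PipelineConfig(out_dir="run", seed=1))
t = result.test_result
print(f"wilcoxon W={t.statistic} p={t.p_value:.4g} n={t.n} ({t.method})")
# wilcoxon W=54.0 p=0.003906 n=10 (exact)
```

and writes `sections.csv`, `animals.csv`, `vectors.yaml`, `stats.yaml`
plus the fully resolved `config.yaml`, byte-identical across reruns with
the same seed.  The same workflow is scriptable from the shell:

```
fgsquant simulate cohort --n-animals 10 --seed 1 --out sections/
fgsquant run --seed 1 --out run/
fgsquant compare --table run/animals.csv --agents 6QC-ICG,5-ALA --test wilcoxon
```

See `docs/methods.md` for the models, defaults, and the design decisions
behind the segmentation, projection and statistics.

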