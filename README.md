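# mixqmri

Desk-scale simulation and analysis of **interleaved prep-module turbo
spin-echo (MIXTURE) quantitative knee MRI**.

MIXTURE-style sequences interleave TSE blocks with different
magnetization preparation inside one repetition time, yielding
co-registered morphologic images *and* voxel-wise quantitative maps from
a single scan: a PD-weighted fat-saturated variant with T2 mapping
("MIX1": T2-prep TE 0/50 ms at TR 1200 ms) and a T1-weighted variant
with T1ρ mapping ("MIX2": spin-lock TSL 0/25/50 ms at 500 Hz, TR
600 ms). This package provides everything needed to study such
acquisitions quantitatively without a scanner:

* **phantom** — synthetic sagittal knee slabs (femoral/tibial cartilage
  with depth-dependent zonal T2/T1ρ, synovial fluid, fat pad, marrow,
  menisci, muscle) carrying known ground-truth relaxation maps;
* **acquisition** — steady-state two-compartment signal simulation per
  TSE block, `S_c = PD·(1−e^{−TR/T1})·e^{−TE_equiv/T2}·P_c` with prep
  factor `P_c ∈ {1, e^{−TE_prep/T2}, e^{−TSL/T1ρ}}` and a multiplicative
  fat-saturation residual, plus Rician magnitude noise; presets for
  MIX1, MIX2, and the 2D/3D TSE reference sequences;
* **relaxometry** — voxel-wise mono-exponential mapping (closed-form
  two-point fit, log-linear fit for ≥3 points) with validity
  diagnostics that reproduce the "no meaningful values in fat" behavior
  of fat-saturated prep acquisitions;
* **quality** — ROI-based image-quality surrogates: Weber contrast
  `(SI_t − SI_r)/SI_r`, CNR `(SI_a − SI_b)/√(σ_a²+σ_b²)`, CV `σ/μ`;
* **reader_stats** — the reader-study statistics: paired sample-size
  estimation, 5-point Likert score simulation, cumulative link mixed
  models (proportional odds, Laplace approximation, crossed random
  intercepts for specimen/reader/structure), latent-scale EMMs with
  Tukey-adjusted contrasts, and repeated-measures ANOVA with
  Tukey–Kramer tests.

Intended users: MR physicists and methods researchers prototyping
prep-module quantitative sequences, and statisticians designing or
auditing ordinal reader studies.

## Worked example

```python
import numpy as np
from mixqmri import (build_knee_phantom, load_sequence_presets,
                     simulate_stack, reconstruct_map, summarize_region,
                     compare_sequences, min_sample_size)

phantom = build_knee_phantom()                  # 160 x 160 x 7 voxels
presets = load_sequence_presets()

# noiseless MIX1 -> T2 map reproduces the ground truth exactly
stack = simulate_stack(phantom, presets["MIX1"], noise_sigma=0.0)
t2map = reconstruct_map(stack, "T2", floor=0.0)
fem, tib = summarize_region(t2map, phantom.labels, [1, 2],
                            ["femoral cartilage", "tibial cartilage"])
print(f"{fem.region}: {fem.mean_ms:.1f} ± {fem.sd_ms:.1f} ms "
      f"({fem.n_voxels} voxels)")
print(f"{tib.region}: {tib.mean_ms:.1f} ± {tib.sd_ms:.1f} ms")

# contrast comparison across the PD-w FS sequences at sigma = 0.3
stacks = [simulate_stack(phantom, presets[n], noise_sigma=0.3, seed=i)
          for i, n in enumerate(["MIX1", "2D TSE PD-w FS", "3D TSE PD-w FS"])]
for row in compare_sequences(stacks, phantom, "PD-w FS"):
    print(f"{row.sequence:18s} Weber {row.weber:+.3f}  CV {row.cv:.4f}")

print("minimum specimens:", min_sample_size(0.5, 0.4, 0.8, 0.01))
```

Output:

```
femoral cartilage: 48.0 ± 11.2 ms (3136 voxels)
tibial cartilage: 36.0 ± 11.2 ms
MIX1               Weber -0.210  CV 0.0133
2D TSE PD-w FS     Weber -0.365  CV 0.0064
3D TSE PD-w FS     Weber -0.186  CV 0.0100
minimum specimens: 8
```

The segmented plate means (48/36 ms) reflect the configured zonal
profiles (cartilage T2 decreasing from the articular surface toward
bone). Weber contrast is negative on all PD-w FS sequences — cartilage
is darker than the bright synovial fluid — and most negative for the
long-TR 2D TSE, which recovers the long-T1 fluid signal most. The
sample-size line is the paired two-sided normal approximation for a
0.5-point score difference with SD 0.4 at power 0.8 and α = 0.01.

A `mixqmri` CLI wraps the same pipeline
(`phantom`, `simulate`, `map`, `metrics`, `reader-sim`, `run`,
`presets`); `mixqmri run` executes phantom → stacks → maps → metrics and
writes NIfTI volumes, CSV tables, and a hash-stamped JSON manifest that
is bit-identical across reruns of the same config.

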