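# netfalff

Network-level fALFF analysis of resting-state fMRI, with a synthetic
cohort generator that makes every stage testable against known ground
truth.

## The problem

Resting-state BOLD signals fluctuate slowly; the **fractional amplitude of
low-frequency fluctuations (fALFF)** quantifies how much of a signal's
spectral power sits in the 0.01–0.1 Hz band:

```
fALFF = Σ_{0.01 ≤ f ≤ 0.1 Hz} |X(f)|²  /  Σ_{f > 0} |X(f)|²
```

Cross-sectional studies of mind–body practice (e.g. experienced Tai Chi
Chuan practitioners vs matched controls) ask whether this index differs at
the level of whole **intrinsic connectivity networks** (ICNs) — default
mode, frontoparietal control, and friends — and whether it tracks practice
exposure and cognitive-control performance.  Answering that requires a
chain of machinery: temporal preprocessing of vertex-sampled time series,
a way to derive group ICN templates by aligning per-subject spatial ICA
components across people (normalized-mutual-information matching with
permutation-tested inter-subject consistency), spatial regression to get
one representative time series per network, the filtered-to-original power
ratio itself, and a covariate-adjusted inference layer.

`netfalff` implements that chain end to end for researchers who want a
tested, seeded, fully reproducible reference implementation — and, because
the original scans of such studies are rarely shareable, it ships a
**synthetic cohort generator** whose network time courses are built in the
Fourier domain so the planted fALFF of every network is exact by
construction.  Every pipeline property (identities, calibration, power) is
demonstrated on that generator.

## Worked example

```python
import numpy as np
from netfalff import generate_subject_scan, generate_templates, network_falff
from netfalff.preprocess import bandpass_fft

templates = generate_templates(n_vertices=1000, n_networks=4, seed=4)
planted = np.array([0.2, 0.45, 0.7, 0.9])
raw, _ = generate_subject_scan(templates, planted, noise_sd=0.0, seed=0)
print(network_falff(raw, bandpass_fft(raw), templates))
```

prints

```
  subject_id network  falff
0    subject   ICN01   0.20
1    subject   ICN02   0.45
2    subject   ICN03   0.70
3    subject   ICN04   0.90
```

— the recovered network fALFF equals the planted in-band power fraction
exactly on noise-free data (with unit Gaussian vertex noise the worst
error in this configuration is about 0.003).  The scripts in `examples/`
walk through each capability one at a time: cohort synthesis, temporal
preprocessing and motion QC, cross-subject ICA alignment, network fALFF,
and group inference; e.g. `examples/05_group_inference.py` ends with

```
two-sample t from printed education summaries: t=0.434, p=0.667
```

the pooled two-sample t recomputed from group mean/SD/n summaries alone.

## Command line

A thin CLI wraps the same library:

```bash
netfalff simulate   --out run --seed 7 --n-tcc 22 --n-ctr 18
netfalff preprocess --out run --seed 7
netfalff align      --out run --seed 7            # or --templates fixed.tsv
netfalff falff      --out run --seed 7 --band 0.01 0.1
netfalff stats      --out run --seed 7 --covariates age,sex,education
# or: netfalff run-all --config pipeline.yaml
```

Each stage writes TSV/JSON into its own subdirectory of the run folder;
reruns with the same config and seed are byte-identical, and completed
stages are skipped via config-hash markers.

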