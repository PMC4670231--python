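# grayripley

Grayscale Ripley K-function statistics for quantifying aggregation in 2-D
images.

## The problem

Fluorescence microscopy of aggregation-prone proteins (and of condensed
chromatin) produces grayscale images in which a bright punctate signal sits
on top of a variable diffuse pool.  Segmenting such images reliably is often
impossible at low signal-to-background ratios, so an *abstract* clustering
index — one that needs no segmentation — is the practical alternative.
Classic spatial statistics such as Ripley's K-function assume distinct,
non-overlapping point events; pixel data violate that assumption as soon as
more than one "event" falls on a pixel.

`grayripley` treats every intensity unit of an 8-bit image as one particle
(saturation 255 particles/pixel) and computes the grayscale extension of
Ripley's K:

```
K(r, n) = |Ω| / (n (n − 1)) · Σ_x c_x · P_x · (P_x − 1 + Σ_{y≠x, d_xy≤r} P_y)
```

where `P_x` is the intensity at pixel x, `n = Σ P_x` the total particle
count over the study region Ω, and `c_x` a Besag-style edge-correction
factor.  Under complete spatial randomness (CSR), `E[K(r)] = πr²`, so the
standardized statistic

```
K̃(r, n) = (K(r, n) − πr²) / sqrt(var{K(r, n)})
```

is approximately standard normal at CSR: values above the CSR 99th
percentile indicate aggregation, below the 1st percentile dispersion.

The package's central methodological point is the **full-field edge
correction** `c_x = πr² / A_xr` applied to *every* pixel (`A_xr` = area of
the disc around x clipped to Ω).  Border-only corrections leave the
pixelated-disc bias uncorrected and make K̃ drift by tens of standard
deviations at high particle densities; the full-field factor makes
`E[K] = πr²` exact for any mask geometry.  The variance and the 1%/99%
critical quantiles of K̃ are estimated by Monte-Carlo CSR simulation matched
in mask, particle count, radius and correction method, with first-order
Cornish-Fisher approximants as a cheap analytic alternative.

Beyond the abstract index, the package ships the generators used to
validate it (CSR fields, circular-cluster fields with controlled
aggregate-to-diffuse ratio ADR and signal-to-background ratio SBR,
confocal-style PSF + Poisson degradation, decimated study regions) and
concrete aggregate characterization: granulometry (pattern spectrum),
a background-subtract / max-entropy / close segmentation pipeline, the
TET/TEE bivariate similarity index, three-class Otsu preprocessing and
ensemble averaging of K̃ profiles.

## Worked example

```python
import numpy as np
from grayripley import (simulate_csr, simulate_clusters, ClusterSpec,
                        csr_reference, ktilde, make_disc_kernel)

kernel = make_disc_kernel(5)
mask = np.ones((256, 256), dtype=bool)

csr = simulate_csr((256, 256), density=4.0, seed=1)
clustered, truth = simulate_clusters(
    ClusterSpec(n_clusters=12, cluster_radius=8, sbr=3.0, background_density=4.0),
    seed=1,
)

for name, field in [("CSR", csr), ("clustered", clustered)]:
    ref = csr_reference(mask, field.n, kernel, "full_field",
                        replicates=1000, seed=42)
    value = ktilde(field, kernel, "full_field", ref)
    print(f"{name:9s}  n={field.n:7d}  K~(r=5) = {value:8.2f}   "
          f"CSR 1%/99% quantiles: [{ref.q01_empirical:.2f}, {ref.q99_empirical:.2f}]")
```

prints

```
CSR        n= 262144  K~(r=5) =    -0.37   CSR 1%/99% quantiles: [-2.20, 2.28]
clustered  n= 290512  K~(r=5) =  1124.68   CSR 1%/99% quantiles: [-2.22, 2.26]
```

The CSR field sits well inside its null band, while twelve radius-8
clusters holding ~10% of the particles push K̃ three orders of magnitude
past the 99% critical quantile — the statistic separates the two regimes
without segmenting anything.

A command-line interface mirrors the library
(`grayripley simulate-csr`, `simulate-clusters`, `decimate`, `k`,
`reference`, `profile`, `granulometry`, `segment`, `similarity`,
`ensemble`); every run writes a `<out>.config.json` sidecar with its
resolved parameters so outputs are reproducible byte-for-byte from
(config, seed).

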