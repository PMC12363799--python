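# alffkit

Amplitude of low-frequency fluctuations (ALFF) and fractional ALFF (fALFF)
are standard resting-state fMRI summaries of how much a voxel's BOLD signal
oscillates inside a band of interest, conventionally 0.01–0.08 Hz. The
literature conflates two distinct constructs — toolboxes variously average
the amplitude spectrum or root-mean-square it — and some pipelines z-score
the BOLD signal first, which silently changes the answer. `alffkit`
computes both variants of both metrics explicitly, in the frequency domain
and (for the quadratic-mean forms) directly in the time domain, with the
subject-level normalization and mean-BOLD-intensity (MBI) diagnostics
needed to use them correctly.

For a demeaned voxel series s(n), n = 0..N−1, with one-sided amplitude
spectrum S(k) = |FFT(s)| and band bins B = [k_fl, k_fh]:

- **amALFF** = (1/|B|) Σ_B 2S(k)/N — arithmetic mean of in-band amplitudes
- **qmALFF** = sqrt((1/|B|) Σ_B (2S(k)/N)²) — quadratic mean; by Parseval,
  equivalently sqrt(2/|B|)·RMS of the bandpassed series, no FFT needed
- **amfALFF** = Σ_B S(k) / Σ_{1..k_fc} S(k) — in-band fraction of amplitude
  up to the preprocessing low-pass cutoff f_c (0.2 Hz by default)
- **qmfALFF** = sqrt(Σ_B S² / Σ_{1..k_fc} S²) — in time domain, the RMS
  ratio of the bandpassed to the f_c-low-passed series

Key structural facts the package computes, tests, and exposes: qmALFF ≥
amALFF voxelwise; both fALFF variants are invariant under rescaling and
z-scoring of the series while the ALFF variants are not; dividing a map by
its mask mean cancels multiplicative MBI effects exactly; and z-scoring
before ALFF reshuffles the normalized maps unless the temporal standard
deviation is constant across voxels.

Intended users are neuroimaging methods researchers and pipeline builders
who need a precisely specified, testable (f)ALFF implementation. The
package reads 4D BOLD + 3D mask NIfTI volumes, works on masked
voxel-by-time matrices, and writes metric maps back into volume space.
Preprocessing (registration, motion/confound correction) is out of scope
and assumed done upstream.

## Worked example

```python
import numpy as np
from alffkit import *

# synthetic subject: baseline 500, one in-band cosine (0.04 Hz, A=1),
# one out-of-band cosine (0.15 Hz, A=0.5), white noise sd 0.2
spec = SyntheticSpec(seed=7, n_subjects=1, n_voxels=3, noise_sd=0.2,
                     components=[(0.04, 1.0, 0.0), (0.15, 0.5, 0.7)])
subjects, truth = make_dataset(spec)
series = demean(subjects[0])
band = BandSpec()              # 0.01-0.08 Hz within a 0.2 Hz range
idx = band_indices(band, series.n_timepoints, series.tr)
spectrum = amplitude_spectrum(series)

print("MBI          ", mbi_subject(series))
print("amALFF       ", am_alff(spectrum, idx).values)
print("qmALFF (freq)", qm_alff_freq(spectrum, idx).values)
print("qmALFF (time)", qm_alff_time(series, band).values)
print("qmfALFF      ", qm_falff_freq(spectrum, idx).values)
print("qmALFF_norm  ", normalize_map(qm_alff_freq(spectrum, idx)).values)
```

```
MBI           499.99785874586786
amALFF        [0.05136276 0.0549898  0.05241253]
qmALFF (freq) [0.17107948 0.17352414 0.17263082]
qmALFF (time) [0.17914585 0.18597959 0.18316719]
qmfALFF       [0.88554376 0.88562893 0.86959005]
qmALFF_norm   [0.9922743  1.00645353 1.00127217]
```

MBI recovers the 500 baseline. qmALFF exceeds amALFF because the in-band
energy is concentrated at one bin (for a single bin qmALFF = amALFF·√|B|);
the time-domain qmALFF (zero-lag order-4 Butterworth) tracks the
frequency-domain value within a few percent, the residual being filter
roll-off and edge transients. qmfALFF ≈ 0.89 reflects the true in-band
power share: the 0.15 Hz component and the noise below 0.2 Hz hold the
ratio below 1. The normalized map averages exactly 1 by construction.

The same pipeline is available from the shell:

```bash
alffkit synth --spec spec.json --out data/        # fixture dataset
alffkit compute --bold data/sub-000_bold.nii.gz --mask data/mask.nii.gz \
    --out out/                                    # qmALFF_norm + qmfALFF
alffkit group --tables table.csv --out group/     # correlation matrices
```

`compute` defaults to the time-domain quadratic-mean path (band 0.01–0.08
Hz, cutoff 0.2 Hz, zero-lag order-4 Butterworth) and writes a JSON sidecar
with every parameter, so outputs are bit-reproducible from their sidecar;
`--domain frequency --metrics all` produces all four metrics plus their
normalized forms, and `--zscore-diagnostic` adds the z-then-normalized
maps.

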