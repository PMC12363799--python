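# Methods

## The quantities

For a voxel's demeaned BOLD series s(n), n = 0..N−1, sampled every TR
seconds, write S(k) = |FFT(s)| for the one-sided spectrum at bins
k = 0..N/2, with resolution Δf = 1/(N·TR). The per-bin **amplitude of
oscillation** is a(k) = 2·S(k)/N for interior bins; the DC bin and (for even
N) the unpaired Nyquist bin are scaled 1/N instead, because they have no
conjugate mirror. Over a band of bins B = [k_fl, k_fh] (the images of the
band edges f_l, f_h on the FFT grid) the package computes

- **amALFF** = mean over B of a(k) — the arithmetic mean of the in-band
  amplitudes;
- **qmALFF** = sqrt(mean over B of a(k)²) — the quadratic (RMS) mean;
- **amfALFF** = Σ_B S(k) / Σ_{k=1..k_fc} S(k) — the in-band fraction of
  total amplitude up to the preprocessing low-pass cutoff f_c;
- **qmfALFF** = sqrt(Σ_B S(k)² / Σ_{k=1..k_fc} S(k)²) — the square root of
  the in-band fraction of power.

Defaults are f_l = 0.01 Hz, f_h = 0.08 Hz, f_c = 0.2 Hz, the conventional
resting-state band and low-pass cutoff. By the power-mean inequality
qmALFF ≥ amALFF voxelwise, with equality exactly when all in-band
amplitudes coincide; no such ordering holds between the fractional
variants. Both fractional metrics lie in [0, 1] and are invariant under
positive rescaling of the series; the unscaled metrics are homogeneous of
degree one.

The fractional denominators start at k = 1 although the defining ratio
nominally includes k = 0: the series is demeaned, so the DC term is
analytically zero and including it would only admit floating-point dust.
This is a deliberate, documented divergence from the literal formula.

## Time-domain forms

Parseval's identity links the band power to the RMS of an ideally
band-limited series: for a brick-wall selection of the bins in B
(no Nyquist bin in the band),

    qmALFF = sqrt(2 / |B|) · RMS(s_bp),    |B| = k_fh − k_fl + 1.

The constant sqrt(2/|B|) is fixed by requiring the brick-wall path to equal
the frequency-domain estimator exactly; the test suite verifies the
identity to 1e-9 relative on random series. The practical band selector is
a **zero-lag fourth-order Butterworth** filter: design order 4, applied
forward and backward (`scipy.signal.sosfiltfilt`), which cancels the phase
response and squares the magnitude response. Users who read "fourth order"
as the effective two-pass response can pass design order 2. Edge
transients are tamed with odd-symmetric reflection padding of length
3·(2·order+1) samples; series must exceed that length.

The fractional time-domain form needs no constant:
qmfALFF = RMS(bandpassed) / RMS(low-passed at f_c). Preprocessed BOLD data
normally arrives already low-passed at f_c, in which case the caller flags
`lowpass_applied=True` and the denominator is the series itself; by default
the operation applies the f_c low-pass internally. The two differ for
spectral content near the cutoff: the order-4 response already sheds ~9% of
the power of a component at 0.75·f_c, which biases the internally-low-passed
ratio upward. Filter ripple and edge transients can push the ratio
marginally above 1 on band-dominated inputs; such values are clipped back
to 1 with a warning stating the excess.

Expected accuracy of the Butterworth path against the frequency-domain
estimator, measured on band-dominated synthetic voxels (in-band sinusoids
at 0.02–0.07 Hz plus weak white noise, 240 timepoints at TR = 2 s): median
relative error around 2%. Components at the band edges are attenuated to
half power by construction and are not "band-dominated" in the filter's
sense; short records inflate the error through edge transients, which decay
in proportion to record length.

## Mean BOLD intensity and normalization

MBI is the temporal mean of the raw (pre-demeaning, pre-filtering) signal —
demeaning would destroy exactly the scanner/physiology scale information
MBI is meant to capture — averaged over voxels (subject level) or over
subjects per voxel (voxel level). Because the spectrum is homogeneous in
the signal scale, a subject's multiplicative intensity factor moves amALFF
and qmALFF proportionally; dividing each map by its mask mean
(`normalize_map`, making the mean exactly 1) cancels any such factor.
Normalization is idempotent (a map whose mean is already within 1e-12 of 1
is returned unchanged, making repeated application bit-stable).

## z-scoring

z-scoring a voxel's series divides its whole amplitude spectrum by the
temporal standard deviation σ(m). Both fractional metrics are therefore
invariant; amALFF and qmALFF are divided by σ(m) voxelwise, which reshuffles
the *normalized* maps unless σ is constant across voxels. The composite
`znorm_map` (divide by σ, renormalize to mean 1) equals plain normalization
iff σ(1) = ... = σ(M); the package uses the **population** σ convention
(divide by N) so z-scored rows have RMS exactly 1, with sample σ (N−1)
available as an option. The shared variance (squared Pearson r) between the
normalized and z-then-normalized qmALFF maps decreases as the dispersion of
σ across voxels grows — the diagnostic behind treating z-scored ALFF as
inappropriate.

## Synthetic data

The generator emulates a voxel as baseline + sinusoids + white noise:

    s(t) = mbi_base·g_j + g_j·Σ_i A_i cos(2π f_i t + φ_i) + ε(t)

with one subject gain g_j per subject (the MBI mechanism), optional
snapping of each f_i to the FFT grid so amplitudes are exactly recoverable,
and ε either gain-independent (default) or scaled by g_j
(`noise_gain_scaled`, the receiver-gain model under which fractional
metrics carry no gain information — without it, gain raises in-band SNR and
fALFF tracks MBI, a property of the noise model rather than of the
estimators). Every (subject, voxel) pair draws from its own stream spawned
from the master seed, so datasets are bit-reproducible and can be
regenerated in part. Defaults: 6×6×6 grid, 100-voxel mask, 240 timepoints
at TR = 2 s (Δf = 1/480 Hz, safely below the 0.01 Hz band edge), baseline
500.

The generator deliberately omits hemodynamic response shapes, 1/f spectral
background, spatial autocorrelation, and structured physiological noise.
Passing tests certify the estimators' numerics and algebraic structure —
oracle agreement, Parseval consistency, scale (co)variance, normalization
and z-scoring behavior — not robustness to realistic BOLD structure or to
preprocessing choices, which are upstream of this package.

## Numerical and design choices

- **Band-edge bin mapping**: each edge f maps to the integer k minimizing
  |k·Δf − f|; exact ties round toward the larger k; k_fl is clamped to ≥ 1
  so the DC bin can never enter a band; k_fc is clamped to the last
  one-sided bin.
- **Odd N**: accepted; the one-sided range is 0..(N−1)/2 with no Nyquist
  bin and all k ≥ 1 doubled. Verified against the brute-force DFT oracle.
- **Degenerate voxels**: in-mask voxels with zero temporal variance are
  dropped at read time with a logged count — every downstream formula
  divides by a spectral or RMS quantity that would vanish — rather than
  producing NaN maps. Zero denominators elsewhere yield NaN plus a warning.
- **Voxel order**: sorted flattened index in C order, making reads and all
  derived maps bit-reproducible.
- **Output maps**: float32 by neuroimaging convention, float64 under a
  flag; out-of-mask voxels NaN (or 0 under a flag); affine carried
  unchanged.
- **Correlations**: Pearson r with two-sided p-values, no multiple-testing
  correction; constant columns give NaN with a warning. The 1-D k-means
  used for MBI strata seeds centers at mid-quantiles and orders labels by
  cluster mean, so labels are deterministic.
- **Problem sizes in tests**: oracle checks use ≤ 256 timepoints and ≤ 1000
  voxels; filter steady-state checks use 1200-timepoint records so edge
  transients (which scale as 1/record length in RMS share) sit well below
  the measured attenuation. Cohort fixtures use 50–1000 subjects of 10–20
  voxels — collinearity claims need few subjects, independence claims need
  many (the null SD of r is ~1/√n).
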