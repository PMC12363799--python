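"""Independent brute-force oracles the fast paths are checked against.

Everything here is deliberately naive — O(n^2) DFT sums and literal
band-metric formulas on the raw one-sided spectrum — and shares no code
with the package implementation.
"""

import numpy as np


def naive_dft_amplitude(x):
    """One-sided |DFT| by direct O(n^2) summation."""
    x = np.asarray(x, dtype=float)
    n = x.size
    n_bins = n // 2 + 1
    out = np.empty(n_bins)
    idx = np.arange(n)
    for k in range(n_bins):
        w = np.exp(-2j * np.pi * k * idx / n)
        out[k] = np.abs(np.sum(x * w))
    return out


def one_sided_scale_ref(n):
    s = np.full(n // 2 + 1, 2.0 / n)
    s[0] = 1.0 / n
    if n % 2 == 0:
        s[-1] = 1.0 / n
    return s


def am_alff_ref(amp, n, k_fl, k_fh):
    a = amp * one_sided_scale_ref(n)
    return np.mean(a[k_fl : k_fh + 1])


def qm_alff_ref(amp, n, k_fl, k_fh):
    a = amp * one_sided_scale_ref(n)
    return np.sqrt(np.mean(a[k_fl : k_fh + 1] ** 2))


def am_falff_ref(amp, k_fl, k_fh, k_fc):
    return np.sum(amp[k_fl : k_fh + 1]) / np.sum(amp[1 : k_fc + 1])


def qm_falff_ref(amp, k_fl, k_fh, k_fc):
    return np.sqrt(
        np.sum(amp[k_fl : k_fh + 1] ** 2) / np.sum(amp[1 : k_fc + 1] ** 2)
    )


def nearest_bin_ref(f, n, tr):
    """Exhaustive argmin over k of |k/(n*tr) - f|, ties toward larger k."""
    ks = np.arange(n // 2 + 1)
    d = np.abs(ks / (n * tr) - f)
    best = np.flatnonzero(d == d.min()).max()
    return int(best)
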