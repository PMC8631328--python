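"""Independent reference implementations used only to check the package.

These deliberately use different algorithms / formulas than the library:
loop-based sums of squares, the element-wise Greenhouse-Geisser formula,
and periodogram band powers.  They are slow and simple on purpose.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps
from scipy.stats import f as fdist


def naive_rm_anova_oneway(data: np.ndarray):
    """Loop-based one-way within-subject ANOVA.

    Returns (F, epsilon_gg, p_gg).  Epsilon uses the classic element-wise
    covariance formula rather than orthonormal contrasts.
    """
    data = np.asarray(data, dtype=float)
    n, k = data.shape
    grand = data.mean()
    ss_cond = 0.0
    for j in range(k):
        ss_cond += n * (data[:, j].mean() - grand) ** 2
    ss_subj = 0.0
    for i in range(n):
        ss_subj += k * (data[i].mean() - grand) ** 2
    ss_tot = 0.0
    for i in range(n):
        for j in range(k):
            ss_tot += (data[i, j] - grand) ** 2
    ss_err = ss_tot - ss_cond - ss_subj
    df1, df2 = k - 1, (n - 1) * (k - 1)
    F = (ss_cond / df1) / (ss_err / df2)

    s = np.cov(data, rowvar=False)
    mean_all = s.mean()
    row_means = s.mean(axis=1)
    mean_diag = np.trace(s) / k
    num = (k * (mean_diag - mean_all)) ** 2
    den = (k - 1) * (
        (s**2).sum() - 2 * k * (row_means**2).sum() + k**2 * mean_all**2
    )
    eps = num / den
    eps = min(1.0, max(1.0 / (k - 1), eps))
    p = fdist.sf(F, eps * df1, eps * df2)
    return F, eps, p


def naive_rm_anova_twoway(data: np.ndarray):
    """Loop-based two-way within-subject F statistics.

    Returns dict of effect -> (F, df1, df2) with effects 'a', 'b', 'ab'.
    """
    data = np.asarray(data, dtype=float)
    n, a, b = data.shape
    grand = data.mean()
    m_i = data.mean(axis=(1, 2))
    m_a = data.mean(axis=(0, 2))
    m_b = data.mean(axis=(0, 1))
    m_ia = data.mean(axis=2)
    m_ib = data.mean(axis=1)
    m_ab = data.mean(axis=0)

    ss_a = sum(n * b * (m_a[p] - grand) ** 2 for p in range(a))
    ss_b = sum(n * a * (m_b[q] - grand) ** 2 for q in range(b))
    ss_ab = 0.0
    for p in range(a):
        for q in range(b):
            ss_ab += n * (m_ab[p, q] - m_a[p] - m_b[q] + grand) ** 2
    ss_as = 0.0
    for i in range(n):
        for p in range(a):
            ss_as += b * (m_ia[i, p] - m_i[i] - m_a[p] + grand) ** 2
    ss_bs = 0.0
    for i in range(n):
        for q in range(b):
            ss_bs += a * (m_ib[i, q] - m_i[i] - m_b[q] + grand) ** 2
    ss_abs = 0.0
    for i in range(n):
        for p in range(a):
            for q in range(b):
                ss_abs += (
                    data[i, p, q]
                    - m_ia[i, p]
                    - m_ib[i, q]
                    - m_ab[p, q]
                    + m_i[i]
                    + m_a[p]
                    + m_b[q]
                    - grand
                ) ** 2

    out = {}
    for name, ss_eff, df1, ss_err in [
        ("a", ss_a, a - 1, ss_as),
        ("b", ss_b, b - 1, ss_bs),
        ("ab", ss_ab, (a - 1) * (b - 1), ss_abs),
    ]:
        df2 = df1 * (n - 1)
        out[name] = ((ss_eff / df1) / (ss_err / df2), df1, df2)
    return out


def periodogram_band_fractions(
    x: np.ndarray, fs: float, bands: list[tuple[float, float]]
) -> np.ndarray:
    """Relative power in each frequency band, estimated by Welch PSD."""
    freqs, psd = sps.welch(x, fs=fs, nperseg=min(len(x), 4096))
    powers = []
    for low, high in bands:
        mask = (freqs >= low) & (freqs < high)
        powers.append(np.trapezoid(psd[mask], freqs[mask]))
    powers = np.asarray(powers)
    return powers / powers.sum()


def fft_gain(x_in: np.ndarray, x_out: np.ndarray, trim: int) -> float:
    """RMS gain of a filter for a sinusoidal input, edges trimmed."""
    a = x_in[trim:-trim]
    b = x_out[trim:-trim]
    return float(np.sqrt(np.mean(b**2) / np.mean(a**2)))
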