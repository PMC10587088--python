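"""HS-WSFE: order-2 Haar/Symlet wavelet scattering for 1-D sensor windows.

The cascade alternates band-pass convolution, modulus and low-pass averaging:

    S0        = x * eta
    U1[j]     = |x * psi_j|                     j = 1..J
    S1[j]     = U1[j] * eta
    U2[j1,j2] = |U1[j1] * psi_j2|               j2 > j1
    S2[j1,j2] = U2[j1,j2] * eta

with psi_j a dyadically dilated Haar wavelet (length 2**j, zero mean) and eta
a Symlet-4 scaling filter cascaded (a-trous) to the target support, unit sum.
All convolutions are circular, so a global time-average of each S path is
exactly invariant to circular shifts of the window; those averages form the
feature vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

from .records import WindowSet

__all__ = [
    "FilterBank",
    "ScatteringCoefficients",
    "ScatteringFeatureMatrix",
    "build_filter_bank",
    "scatter_window",
    "extract_features",
    "circular_convolve",
]


def circular_convolve(x: np.ndarray, h: np.ndarray, method: str = "fft") -> np.ndarray:
    """Circular convolution y[n] = sum_k h[k] x[(n - k) mod N].

    ``method='direct'`` is the O(N^2) reference path used as a numerical
    oracle in the tests; ``'fft'`` is the default fast path.  Filters longer
    than the signal are wrapped modulo N first (both paths agree).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    hw = np.zeros(n)
    np.add.at(hw, np.arange(len(h)) % n, h)
    if method == "direct":
        y = np.empty(n)
        for i in range(n):
            y[i] = sum(hw[k] * x[(i - k) % n] for k in range(n))
        return y
    if method == "fft":
        return np.fft.irfft(np.fft.rfft(x) * np.fft.rfft(hw), n=n)
    raise ValueError(f"unknown convolution method {method!r}")


@dataclass
class FilterBank:
    """Haar band-pass filters at dyadic scales plus a Symlet-4 low-pass."""

    band_pass: list[np.ndarray]       # psi_j, j = 1..J, length 2**j
    low_pass: np.ndarray              # eta, unit tap-sum
    J: int
    window_len: int
    boundary: str = "circular"
    normalized: bool = False


def _haar_filter(j: int) -> np.ndarray:
    half = 2 ** (j - 1)
    return np.concatenate([np.ones(half), -np.ones(half)]) * 2.0 ** (-j / 2)


def _symlet_lowpass(J: int, window_len: int) -> np.ndarray:
    """Symlet-4 scaling filter cascaded a-trous toward support 2**J.

    Cascade depth is the smallest m whose support (2**m - 1)*(L-1) + 1
    reaches 2**J, reduced if necessary so the support stays within the
    window.  Taps are normalized to unit sum so constants pass unchanged.
    """
    base = np.asarray(pywt.Wavelet("sym4").dec_lo, dtype=float)
    L = len(base)
    target = 2 ** J

    def support(m: int) -> int:
        return (2 ** m - 1) * (L - 1) + 1

    m = 1
    while support(m) < target:
        m += 1
    while m > 1 and support(m) > window_len:
        m -= 1
    h = base.copy()
    for level in range(1, m):
        up = np.zeros((len(base) - 1) * 2 ** level + 1)
        up[:: 2 ** level] = base
        h = np.convolve(h, up)
    return h / h.sum()


def build_filter_bank(J: int, window_len: int, normalize: bool = False) -> FilterBank:
    """Build the scattering filter bank for windows of ``window_len`` samples.

    ``normalize=True`` rescales each band-pass filter to unit operator norm
    (max circular-DFT magnitude 1 at this window length), which makes every
    stage of the cascade non-expansive.
    """
    if 2 ** J > window_len:
        j_max = int(np.log2(window_len))
        raise ValueError(
            f"2**J = {2 ** J} exceeds window_len {window_len}; max feasible J is {j_max}"
        )
    band = [_haar_filter(j) for j in range(1, J + 1)]
    if normalize:
        scaled = []
        for h in band:
            hw = np.zeros(window_len)
            hw[: len(h)] = h
            g = np.abs(np.fft.fft(hw)).max()
            scaled.append(h / g)
        band = scaled
    low = _symlet_lowpass(J, window_len)
    return FilterBank(band_pass=band, low_pass=low, J=J, window_len=window_len,
                      normalized=normalize)


@dataclass
class ScatteringCoefficients:
    """All S/U signals for one window/channel, keyed by scale path."""

    S0: np.ndarray
    S1: dict[int, np.ndarray]
    S2: dict[tuple[int, int], np.ndarray]
    U1: dict[int, np.ndarray]
    U2: dict[tuple[int, int], np.ndarray]

    def pooled(self) -> np.ndarray:
        """Global time-average per path: [S0, S1 by j, S2 by (j1, j2)]."""
        parts = [self.S0.mean()]
        parts += [self.S1[j].mean() for j in sorted(self.S1)]
        parts += [self.S2[p].mean() for p in sorted(self.S2)]
        return np.asarray(parts)


def scatter_window(
    x: np.ndarray, bank: FilterBank, method: str = "fft"
) -> ScatteringCoefficients:
    """Run the order-2 scattering cascade on one single-channel window."""
    x = np.asarray(x, dtype=float)
    if len(x) != bank.window_len:
        raise ValueError(f"window length {len(x)} != bank window_len {bank.window_len}")
    conv = lambda s, h: circular_convolve(s, h, method=method)
    eta = bank.low_pass
    S0 = conv(x, eta)
    U1, S1, U2, S2 = {}, {}, {}, {}
    for j1, psi1 in enumerate(bank.band_pass, start=1):
        u1 = np.abs(conv(x, psi1))
        U1[j1] = u1
        S1[j1] = conv(u1, eta)
        for j2 in range(j1 + 1, bank.J + 1):
            u2 = np.abs(conv(u1, bank.band_pass[j2 - 1]))
            U2[(j1, j2)] = u2
            S2[(j1, j2)] = conv(u2, eta)
    return ScatteringCoefficients(S0=S0, S1=S1, S2=S2, U1=U1, U2=U2)


@dataclass
class ScatteringFeatureMatrix:
    """Per-window scattering feature vectors with path/channel names."""

    features: np.ndarray              # (n_windows, M)
    feature_names: list[str]
    labels: np.ndarray | None = None

    @property
    def n_features(self) -> int:
        return self.features.shape[1]


def n_paths(J: int) -> int:
    """Feature count per channel: 1 + J + J(J-1)/2."""
    return 1 + J + J * (J - 1) // 2


def path_names(J: int, channel: str) -> list[str]:
    names = [f"{channel}:S0"]
    names += [f"{channel}:S1:j{j}" for j in range(1, J + 1)]
    names += [
        f"{channel}:S2:j{j1}-j{j2}"
        for j1 in range(1, J + 1)
        for j2 in range(j1 + 1, J + 1)
    ]
    return names


def extract_features(
    windows: WindowSet, bank: FilterBank, method: str = "fft"
) -> ScatteringFeatureMatrix:
    """Scatter every window/channel and pool to a feature matrix.

    The vector per window is the concatenation over channels of the pooled
    path averages, M = n_channels * (1 + J + J(J-1)/2) features in total.
    """
    n, c, L = windows.windows.shape
    if L != bank.window_len:
        raise ValueError("window length does not match the filter bank")
    per_ch = n_paths(bank.J)
    feats = np.empty((n, c * per_ch))
    for i in range(n):
        for ch in range(c):
            coeffs = scatter_window(windows.windows[i, ch], bank, method=method)
            feats[i, ch * per_ch : (ch + 1) * per_ch] = coeffs.pooled()
    names = []
    for ch_name in windows.channel_names:
        names += path_names(bank.J, ch_name)
    return ScatteringFeatureMatrix(features=feats, feature_names=names, labels=windows.labels)
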