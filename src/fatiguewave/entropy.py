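"""Wavelet Rényi entropy — the fatigue marker.

Each 8-s epoch is decomposed with a 4-level Daubechies-4 discrete wavelet
transform.  At the 62.5 Hz analysis rate the detail levels 1–4 cover
≈ 15.6–31.2, 7.8–15.6, 3.9–7.8 and 2.0–3.9 Hz, i.e. approximately the β,
α, θ and δ EEG bands.  Per level, coefficients whose magnitude exceeds
``mean(|w|) + 2·std(|w|)`` are halved (in-band denoising), the band energy
is ``E_j = Σ_k w_j(k)²``, relative energies ``p_j = E_j / Σ E_j`` form a
probability-like band profile over the four detail bands, and the order-q
Rényi entropy

    RE = (1 / (1 - q)) · ln Σ_j p_j^q,          q = 2 by default,

normalized by ``ln 4`` so that a flat band profile maps to 1, is the
epoch's marker value.  The session value is the mean across epochs.

A flatter band profile — less dominance of any single rhythm — yields a
higher entropy; across the study's sessions the profile flattens as mental
fatigue accumulates, so the session entropy rises.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

from .errors import DegenerateProfileError
from .preprocess import EpochSet

#: Detail levels 1..4 at the 62.5 Hz analysis rate map onto these bands.
BAND_NAMES: tuple[str, ...] = ("beta", "alpha", "theta", "delta")

DEFAULT_WAVELET = "db4"
DEFAULT_LEVELS = 4
#: Periodized boundary handling keeps the transform orthonormal, so the
#: coefficient energy equals the signal energy exactly on dyadic lengths.
DEFAULT_BOUNDARY = "periodization"


@dataclass
class WaveletDecomposition:
    """DWT coefficients of one epoch.

    ``details[0]`` is level 1 (highest frequency band), ``details[-1]`` is
    level ``levels``; ``approx`` holds the level-``levels`` approximation.
    """

    details: list[np.ndarray]
    approx: np.ndarray
    wavelet_name: str = DEFAULT_WAVELET
    levels: int = DEFAULT_LEVELS
    boundary_mode: str = DEFAULT_BOUNDARY

    def __post_init__(self) -> None:
        if len(self.details) != self.levels:
            raise ValueError(
                f"{len(self.details)} detail series for {self.levels} levels"
            )


@dataclass
class BandEnergyProfile:
    """Per-band wavelet energies and relative energies for one epoch."""

    energies: np.ndarray
    relative: np.ndarray
    band_names: tuple[str, ...] = BAND_NAMES


@dataclass
class EntropyResult:
    """Per-epoch and aggregate entropy for one channel of one session."""

    per_epoch: np.ndarray
    session_value: float
    q: float = 2.0
    normalized: bool = True
    log_base: str = "e"


def dwt_decompose(
    epoch: np.ndarray,
    wavelet: str = DEFAULT_WAVELET,
    levels: int = DEFAULT_LEVELS,
    mode: str = DEFAULT_BOUNDARY,
) -> WaveletDecomposition:
    """Multi-level discrete wavelet analysis of one epoch."""
    x = np.asarray(epoch, dtype=float).ravel()
    if x.size < 2**levels:
        raise ValueError(
            f"epoch of {x.size} samples too short for {levels} levels "
            f"(needs >= {2**levels})"
        )
    coeffs = pywt.wavedec(x, wavelet, mode=mode, level=levels)
    approx = coeffs[0]
    details = list(coeffs[1:][::-1])  # reorder so index 0 is level 1
    return WaveletDecomposition(
        details=details, approx=approx, wavelet_name=wavelet,
        levels=levels, boundary_mode=mode,
    )


def reconstruct(decomp: WaveletDecomposition) -> np.ndarray:
    """Inverse transform; within 1e-8 of the analysed epoch."""
    coeffs = [decomp.approx] + list(decomp.details[::-1])
    return pywt.waverec(coeffs, decomp.wavelet_name, mode=decomp.boundary_mode)


def denoise_inband(decomp: WaveletDecomposition) -> WaveletDecomposition:
    """Halve outlying detail coefficients, level by level.

    The per-level threshold is ``T_j = mean(|w_j|) + 2·std(|w_j|)`` with the
    population standard deviation; coefficients with ``|w| > T_j`` (strict)
    are replaced by ``w / 2`` with sign preserved.  Approximation
    coefficients are untouched.  For a level of identical magnitudes the
    threshold equals that magnitude and nothing changes.
    """
    new_details = []
    for w in decomp.details:
        a = np.abs(w)
        t = a.mean() + 2.0 * a.std()
        new_details.append(np.where(a > t, w / 2.0, w))
    return WaveletDecomposition(
        details=new_details,
        approx=decomp.approx.copy(),
        wavelet_name=decomp.wavelet_name,
        levels=decomp.levels,
        boundary_mode=decomp.boundary_mode,
    )


def band_energies(decomp: WaveletDecomposition) -> BandEnergyProfile:
    """Energies ``E_j = Σ w_j²`` and relative energies over the detail bands.

    The approximation band is excluded: the four detail levels carry the
    β/α/θ/δ mapping and the 3 Hz high-pass empties the sub-2 Hz residual.
    """
    energies = np.array([float(np.sum(w * w)) for w in decomp.details])
    total = energies.sum()
    if total <= 0.0:
        raise DegenerateProfileError("all detail bands have zero energy")
    names = BAND_NAMES if decomp.levels == len(BAND_NAMES) else tuple(
        f"level{j + 1}" for j in range(decomp.levels)
    )
    return BandEnergyProfile(energies=energies, relative=energies / total,
                             band_names=names)


def renyi_entropy(
    relative: np.ndarray, q: float = 2.0, normalized: bool = True
) -> float:
    """Order-q Rényi entropy of a band-probability vector.

    ``RE = ln(Σ p^q) / (1 - q)`` in nats; with ``normalized`` the value is
    divided by ``ln(n)`` so the uniform vector maps to 1 and a one-hot
    vector to 0.
    """
    p = np.asarray(relative, dtype=float).ravel()
    if q == 1.0:
        raise ValueError("q = 1 is the Shannon limit and is not supported")
    if np.any(p < 0):
        raise ValueError("relative energies must be non-negative")
    total = p.sum()
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ValueError(f"relative energies sum to {total}, expected 1")
    value = float(np.log(np.sum(p**q)) / (1.0 - q))
    if normalized:
        value /= float(np.log(p.size))
    return value


def epoch_entropy(
    epoch: np.ndarray,
    wavelet: str = DEFAULT_WAVELET,
    levels: int = DEFAULT_LEVELS,
    q: float = 2.0,
    normalized: bool = True,
    denoise: bool = True,
) -> float:
    """Marker value of a single epoch: DWT → denoise → energies → entropy."""
    decomp = dwt_decompose(epoch, wavelet=wavelet, levels=levels)
    if denoise:
        decomp = denoise_inband(decomp)
    profile = band_energies(decomp)
    return renyi_entropy(profile.relative, q=q, normalized=normalized)


def session_entropy(
    epochs: EpochSet,
    wavelet: str = DEFAULT_WAVELET,
    levels: int = DEFAULT_LEVELS,
    q: float = 2.0,
    normalized: bool = True,
    denoise: bool = True,
) -> EntropyResult:
    """Aggregate the marker over an epoch set (arithmetic mean of epochs)."""
    if epochs.n_epochs < 1:
        raise ValueError("epoch set is empty")
    values = np.empty(epochs.n_epochs)
    for i, ep in enumerate(epochs.epochs):
        try:
            values[i] = epoch_entropy(
                ep, wavelet=wavelet, levels=levels, q=q,
                normalized=normalized, denoise=denoise,
            )
        except DegenerateProfileError as err:
            raise DegenerateProfileError(f"epoch {i}: {err}") from err
    return EntropyResult(
        per_epoch=values,
        session_value=float(values.mean()),
        q=q,
        normalized=normalized,
    )
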