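"""Synthetic cohort generator emulating the 9-subject, 6-session study.

Generates resting-state prefrontal EEG, oddball event logs and per-session
metadata with the statistical structure the analysis assumes, so every
downstream stage is testable without any recorded data.

EEG model
---------
Each channel is the sum of

* four band-limited oscillatory components (filtered white noise, one per
  β/α/θ/δ dyadic band, clipped to the 3–30 Hz analysis passband), whose
  relative powers after 3–30 Hz filtering follow the session's programmed
  band-power profile, and
* ``1/f^a`` background noise contributing a fixed fraction (default 30 %)
  of the total in-band power.

Filtered noise rather than pure sinusoids is used deliberately: the band
profile of a tone is degenerate across windows, whereas noise carriers
give every epoch an independent realization.

Session trajectories are parameterized by target normalized order-2 Rényi
entropies; a session's band profile is found by mixing an alpha-dominant
resting profile toward the uniform profile until the target entropy is
met.  Between-subject offsets and within-subject jitter act on the
entropy scale and reshape each cell's profile along a power-sharpening
path, so a custom trajectory keeps its shape.

Every generator is a pure function of the master seed and its arguments:
per-(subject, session, channel) substreams are derived with counter-based
``SeedSequence`` spawn keys, so adding or removing one subject never
perturbs any other subject's data.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats as sp_stats

from . import preprocess as pp
from .behavioral import OddballLog
from .entropy import BAND_NAMES, renyi_entropy
from .preprocess import DEFAULT_CHANNELS, EEGRecording

logger = logging.getLogger(__name__)

#: Ordered session labels: three daily assessments, then the
#: sleep-deprivation phase with two extra rounds on day four.
DEFAULT_SESSIONS: tuple[str, ...] = (
    "Day1", "Day2", "Day3", "Day4A", "Day4B", "Day5",
)

#: Session-mean normalized entropy levels used as the default trajectory.
DEFAULT_SESSION_ENTROPY: tuple[float, ...] = (0.657, 0.684, 0.661, 0.737, 0.761, 0.841)

#: Alpha-dominant resting band profile (β, α, θ, δ) used as the
#: low-entropy anchor of the trajectory parameterization.
BASE_PROFILE = np.array([0.15, 0.70, 0.10, 0.05])

# substream tags for counter-based seed derivation
_TAG_SUBJECT_OFFSET = 0
_TAG_CELL = 1
_TAG_SIGNAL = 2
_TAG_ODDBALL = 3
_TAG_TABLE = 4


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Independent substream for a (tag, subject, session, channel, ...) key."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


@dataclass(frozen=True)
class BandSpec:
    """One EEG band: name, half-open frequency range [low, high) Hz, and
    its relative power fraction."""

    band_name: str
    freq_range: tuple[float, float]
    relative_power: float

    def __post_init__(self) -> None:
        if self.band_name not in BAND_NAMES:
            raise ValueError(f"band_name must be one of {BAND_NAMES}")
        low, high = self.freq_range
        if not 0 <= low < high:
            raise ValueError(f"bad frequency range {self.freq_range}")
        if self.relative_power < 0:
            raise ValueError("relative_power must be >= 0")


def dyadic_bands(
    analysis_fs: float = 62.5,
    powers: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
) -> tuple[BandSpec, ...]:
    """The four dyadic detail bands of a 4-level DWT at ``analysis_fs``.

    At 62.5 Hz: β 15.6–31.25, α 7.8–15.6, θ 3.9–7.8, δ 2.0–3.9 Hz.
    Ranges are disjoint and ordered; relative powers must sum to 1.
    """
    if abs(sum(powers) - 1.0) > 1e-9:
        raise ValueError(f"relative powers sum to {sum(powers)}, expected 1")
    high = analysis_fs / 2.0
    bands = []
    for name, p in zip(BAND_NAMES, powers):
        bands.append(BandSpec(name, (high / 2.0, high), float(p)))
        high /= 2.0
    return tuple(bands)


def profile_for_entropy(
    target: float, base: np.ndarray = BASE_PROFILE, tol: float = 1e-10
) -> np.ndarray:
    """Band profile with the requested normalized order-2 Rényi entropy.

    Mixes ``base`` linearly toward the uniform profile; entropy is strictly
    increasing along that path, so bisection converges.  Targets outside
    the attainable range are clipped to it.
    """
    base = np.asarray(base, dtype=float)
    uniform = np.full_like(base, 1.0 / base.size)
    lo_h = renyi_entropy(base)
    target = float(np.clip(target, lo_h, 1.0))
    lo, hi = 0.0, 1.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if renyi_entropy((1 - mid) * base + mid * uniform) < target:
            lo = mid
        else:
            hi = mid
    t = 0.5 * (lo + hi)
    return (1 - t) * base + t * uniform


def _sharpened(profile: np.ndarray, gamma: float) -> np.ndarray:
    q = np.power(np.clip(profile, 0.0, None), gamma)
    return q / q.sum()


def perturb_profile_entropy(
    profile: np.ndarray, target: float, tol: float = 1e-9
) -> np.ndarray:
    """Reshape ``profile`` along the power-sharpening path p^γ / Σp^γ so
    its normalized order-2 entropy equals ``target`` (clipped to the
    attainable range).  γ < 1 flattens (raises entropy), γ > 1 sharpens."""
    profile = np.asarray(profile, dtype=float)
    if np.allclose(profile, profile[0]):
        return profile / profile.sum()  # uniform is a fixed point of the path
    g_lo, g_hi = 1e-3, 32.0
    h_hi = renyi_entropy(_sharpened(profile, g_lo))
    h_lo = renyi_entropy(_sharpened(profile, g_hi))
    target = float(np.clip(target, h_lo, h_hi))
    # entropy decreases as gamma grows
    lo, hi = g_lo, g_hi
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if renyi_entropy(_sharpened(profile, mid)) > target:
            lo = mid
        else:
            hi = mid
    return _sharpened(profile, 0.5 * (lo + hi))


def trajectory_from_entropy(
    session_labels: Sequence[str],
    targets: Sequence[float],
    base: np.ndarray = BASE_PROFILE,
) -> dict[str, np.ndarray]:
    """Map session labels to band profiles realizing the entropy targets."""
    if len(session_labels) != len(targets):
        raise ValueError("one entropy target per session required")
    return {
        s: profile_for_entropy(t, base) for s, t in zip(session_labels, targets)
    }


def monotone_entropy_targets(
    start: float = 0.65, stop: float = 0.84, n_sessions: int = 6
) -> np.ndarray:
    """Linearly rising entropy targets for marker-validity studies."""
    return np.linspace(start, stop, n_sessions)


@dataclass
class CohortSpec:
    """Study design of the synthetic cohort.

    Defaults reproduce the study conditions: nine subjects, six assessment
    sessions (Day1–Day3, then Day4A/Day4B/Day5 under sleep deprivation),
    4-channel forehead EEG at 250 Hz for 5 minutes per session, session
    band profiles whose normalized entropy follows
    :data:`DEFAULT_SESSION_ENTROPY`, between-subject entropy sd 0.15 and
    within-subject (session-to-session) jitter sd 0.03.
    """

    n_subjects: int = 9
    session_labels: tuple[str, ...] = DEFAULT_SESSIONS
    band_trajectory: Mapping[str, np.ndarray] | None = None
    between_subject_sd: float = 0.15
    within_subject_sd: float = 0.03
    noise_exponent: float = 1.0
    background_fraction: float = 0.3
    duration_s: float = 300.0
    fs: float = 250.0
    n_channels: int = 4
    channel_labels: tuple[str, ...] = DEFAULT_CHANNELS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        n = self.duration_s * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration_s * fs must be an integer sample count")
        if not 0.0 <= self.background_fraction < 1.0:
            raise ValueError("background_fraction must be in [0, 1)")
        self.session_labels = tuple(self.session_labels)
        self.channel_labels = tuple(self.channel_labels[: self.n_channels])
        if len(self.channel_labels) != self.n_channels:
            raise ValueError("one label per channel required")
        if self.band_trajectory is None:
            self.band_trajectory = trajectory_from_entropy(
                self.session_labels, DEFAULT_SESSION_ENTROPY[: len(self.session_labels)]
            )
        traj = {}
        for s in self.session_labels:
            if s not in self.band_trajectory:
                raise ValueError(f"trajectory missing session {s!r}")
            p = np.asarray(self.band_trajectory[s], dtype=float)
            if p.size != len(BAND_NAMES) or abs(p.sum() - 1.0) > 1e-9 or np.any(p < 0):
                raise ValueError(f"session {s!r}: band powers must be >= 0 and sum to 1")
            traj[s] = p
        self.band_trajectory = traj

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))


@dataclass
class OddballSpec:
    """Timing and response model of one oddball run.

    Defaults follow the study protocol: 4-minute runs, 1000 ms
    inter-stimulus interval, 50 ms stimulus duration, 20 % deviants.
    ``rt_mean_s``/``rt_sd_s`` parameterize the truncated-normal response
    latency inside ``response_window_s``.
    """

    modality: str = "audio"
    p_deviant: float = 0.2
    isi_ms: float = 1000.0
    stim_dur_ms: float = 50.0
    total_duration_s: float = 240.0
    rt_mean_s: float = 0.35
    rt_sd_s: float = 0.08
    miss_rate: float = 0.05
    response_window_s: tuple[float, float] = (0.1, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.modality not in ("audio", "visual"):
            raise ValueError("modality must be 'audio' or 'visual'")
        if not 0.0 <= self.p_deviant <= 1.0:
            raise ValueError(f"p_deviant {self.p_deviant} outside [0, 1]")
        if not 0.0 <= self.miss_rate <= 1.0:
            raise ValueError(f"miss_rate {self.miss_rate} outside [0, 1]")
        if self.isi_ms <= 0 or self.stim_dur_ms <= 0:
            raise ValueError("isi_ms and stim_dur_ms must be positive")
        lo, hi = self.response_window_s
        if not lo < self.rt_mean_s < hi:
            raise ValueError(
                f"rt_mean_s {self.rt_mean_s} outside response window {self.response_window_s}"
            )
        period = (self.isi_ms + self.stim_dur_ms) / 1000.0
        if self.total_duration_s <= period:
            raise ValueError("total_duration_s must exceed one stimulus period")

    @property
    def period_s(self) -> float:
        return (self.isi_ms + self.stim_dur_ms) / 1000.0

    @property
    def n_stimuli(self) -> int:
        return int(self.total_duration_s / self.period_s)


def session_entropy_target(
    spec: CohortSpec, subject: int, session: str
) -> float:
    """Latent entropy target of one subject × session cell.

    Session trajectory value + a per-subject offset (constant across
    sessions, sd ``between_subject_sd``) + i.i.d. session jitter
    (sd ``within_subject_sd``), clipped to the attainable entropy range.
    """
    s_idx = spec.session_labels.index(session)
    base_h = renyi_entropy(spec.band_trajectory[session])
    offset = float(
        _rng(spec.seed, _TAG_SUBJECT_OFFSET, subject).normal(0.0, spec.between_subject_sd)
    )
    jitter = float(
        _rng(spec.seed, _TAG_CELL, subject, s_idx).normal(0.0, spec.within_subject_sd)
    )
    return float(np.clip(base_h + offset + jitter, 0.02, 0.998))


def cell_profile(spec: CohortSpec, subject: int, session: str) -> np.ndarray:
    """Programmed band profile of one subject × session cell."""
    target = session_entropy_target(spec, subject, session)
    return perturb_profile_entropy(spec.band_trajectory[session], target)


@lru_cache(maxsize=8)
def _bp_mag2(n: int, fs: float, low: float, high: float) -> np.ndarray:
    """|H(f)|² of the zero-phase analysis band-pass at the rfft frequencies.

    ``sosfiltfilt`` applies the filter forward and backward, so its
    effective transfer function is the squared magnitude response.
    """
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    sos = pp._bandpass_sos(low, high, fs)
    _, h = sps.sosfreqz(sos, worN=freqs, fs=fs)
    return np.abs(h) ** 2


def _one_over_f(rng: np.random.Generator, n: int, exponent: float) -> np.ndarray:
    """Gaussian noise with a 1/f^exponent power spectrum."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    return np.fft.irfft(spec * shape, n)


def _unit_inband_noise(
    rng: np.random.Generator, n: int, low: float, high: float, fs: float
) -> np.ndarray:
    """Band-limited white noise with unit power after 3–30 Hz filtering.

    Synthesized spectrally (white noise restricted to [low, high) Hz) and
    scaled so that passing it through the zero-phase analysis band-pass
    would leave unit variance.
    """
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec = np.fft.rfft(rng.standard_normal(n))
    spec[(freqs < low) | (freqs >= high)] = 0.0
    comp = np.fft.irfft(spec, n)
    ref = np.fft.irfft(spec * _bp_mag2(n, fs, *pp.DEFAULT_BAND), n)
    return comp / ref.std()


def _unit_inband_background(
    rng: np.random.Generator, n: int, exponent: float, fs: float
) -> np.ndarray:
    """1/f^exponent noise with unit power after 3–30 Hz filtering."""
    bg = _one_over_f(rng, n, exponent)
    spec = np.fft.rfft(bg)
    ref = np.fft.irfft(spec * _bp_mag2(n, fs, *pp.DEFAULT_BAND), n)
    return bg / ref.std()


def generate_eeg(spec: CohortSpec, subject: int, session: str) -> EEGRecording:
    """Synthesize one multi-channel resting-state recording.

    The four oscillatory components are individually normalized to unit
    power *after* the 3–30 Hz analysis band-pass, so the in-band relative
    powers of the sum match the cell's programmed profile; background
    ``1/f^a`` noise contributes ``background_fraction`` of the in-band
    power.  Deterministic given (seed, subject, session).
    """
    if not 0 <= subject < spec.n_subjects:
        raise ValueError(f"subject {subject} outside 0..{spec.n_subjects - 1}")
    if session not in spec.session_labels:
        raise ValueError(
            f"unknown session {session!r}; expected one of {spec.session_labels}"
        )
    if spec.duration_s <= 0:
        raise ValueError("duration_s must be positive")
    s_idx = spec.session_labels.index(session)
    profile = cell_profile(spec, subject, session)
    n = spec.n_samples
    lo_hz, hi_hz = pp.DEFAULT_BAND
    bands = dyadic_bands(spec.fs / pp.DEFAULT_DECIMATION, profile)

    data = np.empty((spec.n_channels, n))
    for ch in range(spec.n_channels):
        rng = _rng(spec.seed, _TAG_SIGNAL, subject, s_idx, ch)
        osc = np.zeros(n)
        for band in bands:
            b_lo = max(band.freq_range[0], lo_hz)
            b_hi = min(band.freq_range[1], hi_hz)
            comp = _unit_inband_noise(rng, n, b_lo, b_hi, spec.fs)
            osc += np.sqrt(band.relative_power) * comp
        bg = _unit_inband_background(rng, n, spec.noise_exponent, spec.fs)
        f = spec.background_fraction
        x = np.sqrt(1.0 - f) * osc + np.sqrt(f) * bg
        data[ch] = 20.0 * x / x.std()  # ~20 µV RMS, realistic forehead EEG scale

    return EEGRecording(
        data=data,
        fs=spec.fs,
        channel_labels=spec.channel_labels,
        subject=subject,
        session=session,
    )


def generate_oddball_log(
    spec: OddballSpec, subject: int | str | None = None, session: str | None = None
) -> OddballLog:
    """Simulate one oddball run as an ordered event log.

    Stimulus onsets lie on a fixed grid of period ``isi + duration``; each
    stimulus is independently deviant with ``p_deviant``; each non-missed
    deviant is followed by a press at onset + a truncated-normal latency
    inside the valid-response window.  Deterministic given ``spec.seed``.
    """
    rng = _rng(spec.seed, _TAG_ODDBALL)
    n = spec.n_stimuli
    onsets = np.arange(n) * spec.period_s
    deviant = rng.random(n) < spec.p_deviant
    missed = rng.random(n) < spec.miss_rate
    lo, hi = spec.response_window_s
    a = (lo - spec.rt_mean_s) / spec.rt_sd_s
    b = (hi - spec.rt_mean_s) / spec.rt_sd_s
    lats = sp_stats.truncnorm.rvs(
        a, b, loc=spec.rt_mean_s, scale=spec.rt_sd_s, size=n, random_state=rng
    )

    rows = [
        {"time_s": float(t), "kind": "deviant" if d else "standard",
         "modality": spec.modality}
        for t, d in zip(onsets, deviant)
    ]
    for t, d, m, lat in zip(onsets, deviant, missed, lats):
        if d and not m:
            rows.append(
                {"time_s": float(t + lat), "kind": "press", "modality": spec.modality}
            )
    events = pd.DataFrame(rows, columns=["time_s", "kind", "modality"])
    events = events.sort_values("time_s", kind="stable").reset_index(drop=True)
    return OddballLog(events=events, subject=subject, session=session)


@dataclass
class CohortEffects:
    """Programmed session trends of the non-EEG instruments.

    Defaults follow the study's descriptive statistics: sleepiness scores
    rising toward the sleep-deprivation sessions, reaction times slowly
    lengthening, and pre-assessment sleep collapsing to near zero.  All
    values per session, in instrument units.
    """

    sss_session_means: tuple[float, ...] = (2.333, 1.778, 2.444, 2.556, 3.222, 4.222)
    sss_between_sd: float = 0.5
    sss_within_sd: float = 0.6
    rt_audio_session_means: tuple[float, ...] = (0.328, 0.320, 0.331, 0.353, 0.374, 0.398)
    rt_visual_session_means: tuple[float, ...] = (0.338, 0.334, 0.360, 0.351, 0.366, 0.404)
    rt_between_sd: float = 0.03
    sleep_session_means: tuple[float, ...] = (375.5, 419.4, 243.0, 232.2, 15.5, 2.2)
    sleep_within_sd: float = 40.0


@dataclass
class Cohort:
    """All artifacts of one simulated study."""

    recordings: dict[tuple[int, str], EEGRecording]
    logs: dict[tuple[int, str, str], OddballLog]
    session_table: pd.DataFrame
    clamp_log: list[str] = field(default_factory=list)


def generate_cohort(
    spec: CohortSpec,
    oddball: OddballSpec | None = None,
    effects: CohortEffects | None = None,
    with_signals: bool = True,
) -> Cohort:
    """Simulate the full cohort: EEG, oddball logs and session metadata.

    One multi-channel recording per subject × session, one audio and one
    visual oddball log per subject × session, and a session table with SSS
    scores (latent-normal, rounded and clamped to 1..7), sleep durations
    (clamped at 0) per subject × session.  Latent values clamped out of
    range are recorded in ``clamp_log``.  Fully reproducible from
    ``spec.seed``; ``with_signals=False`` skips EEG synthesis when only
    logs and metadata are needed.
    """
    oddball = oddball if oddball is not None else OddballSpec(seed=spec.seed)
    effects = effects if effects is not None else CohortEffects()
    n_sess = len(spec.session_labels)
    for name in ("sss_session_means", "rt_audio_session_means",
                 "rt_visual_session_means", "sleep_session_means"):
        if len(getattr(effects, name)) != n_sess:
            raise ValueError(f"{name} must have {n_sess} entries")

    recordings: dict[tuple[int, str], EEGRecording] = {}
    logs: dict[tuple[int, str, str], OddballLog] = {}
    rows = []
    clamp_log: list[str] = []
    rt_means = {"audio": effects.rt_audio_session_means,
                "visual": effects.rt_visual_session_means}

    for subj in range(spec.n_subjects):
        subj_rng = _rng(spec.seed, _TAG_TABLE, subj)
        sss_offset = subj_rng.normal(0.0, effects.sss_between_sd)
        rt_offset = subj_rng.normal(0.0, effects.rt_between_sd)
        for s_idx, session in enumerate(spec.session_labels):
            cell_rng = _rng(spec.seed, _TAG_TABLE, subj, s_idx)
            latent_sss = (
                effects.sss_session_means[s_idx]
                + sss_offset
                + cell_rng.normal(0.0, effects.sss_within_sd)
            )
            sss = int(round(latent_sss))
            if not 1 <= sss <= 7:
                clamp_log.append(
                    f"subject {subj} {session}: latent SSS {latent_sss:.2f} clamped"
                )
                logger.warning(clamp_log[-1])
                sss = min(7, max(1, sss))
            sleep = effects.sleep_session_means[s_idx] + cell_rng.normal(
                0.0, effects.sleep_within_sd
            )
            sleep = max(0.0, sleep)
            rows.append(
                {"subject": subj, "session": session, "sss": sss,
                 "sleep_min": round(sleep, 1)}
            )
            if with_signals:
                recordings[(subj, session)] = generate_eeg(spec, subj, session)
            lo, hi = oddball.response_window_s
            for modality in ("audio", "visual"):
                rt_mean = float(
                    np.clip(
                        rt_means[modality][s_idx]
                        + rt_offset
                        + cell_rng.normal(0.0, 0.01),
                        lo + 0.05,
                        hi - 0.05,
                    )
                )
                sub_seed = int(
                    _rng(spec.seed, _TAG_ODDBALL, subj, s_idx,
                         0 if modality == "audio" else 1).integers(2**31)
                )
                mod_spec = dataclasses.replace(
                    oddball, modality=modality, rt_mean_s=rt_mean, seed=sub_seed
                )
                logs[(subj, session, modality)] = generate_oddball_log(
                    mod_spec, subject=subj, session=session
                )

    table = pd.DataFrame(rows, columns=["subject", "session", "sss", "sleep_min"])
    return Cohort(
        recordings=recordings, logs=logs, session_table=table, clamp_log=clamp_log
    )
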