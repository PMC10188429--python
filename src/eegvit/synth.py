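"""Synthetic EEG cohorts with band-structured class differences.

The clinical recordings this pipeline was designed for are 8-channel
limited-lead EEG sampled every 4 ms, labelled delirium+/- by bedside
CAM-ICU assessment.  Delirium is associated with spectral "slowing":
elevated delta/theta power and suppressed alpha.  This module builds
cohorts with exactly that structure so every downstream stage (filtering,
slicing, imaging, the transformer) can be exercised and tested without
access to patient data.

Each channel is a sum of narrowband components — either fixed sinusoids
(frequencies drawn uniformly inside each canonical band, random phases;
easy to verify spectrally) or band-limited Gaussian noise with the
stochastic envelopes real rhythms have — plus an aperiodic 1/f^2
background, white broadband noise and, optionally, mains line noise and
short high-frequency muscle bursts.  Cohorts add subject-level
heterogeneity in overall gain, per-band amplitude, and background levels.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np

N_CHANNELS = 8
DEFAULT_SAMPLING_INTERVAL = 0.004  # seconds; 250 Hz

#: Canonical EEG band edges in Hz.  The gamma band is open-ended (> 30 Hz)
#: physiologically; 60 Hz is used as the synthesis upper edge.
BAND_EDGES = {
    "delta": (0.5, 3.0),
    "theta": (4.0, 7.0),
    "alpha": (8.0, 12.0),
    "beta": (15.0, 30.0),
    "gamma": (30.0, 60.0),
}

#: Per-sinusoid count used when synthesising one band.
_COMPONENTS_PER_BAND = 3


@dataclass(frozen=True)
class BandSpec:
    """One canonical EEG band with a synthesis amplitude (µV-like units)."""

    name: str
    low_hz: float
    high_hz: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.name not in BAND_EDGES:
            raise ValueError(f"unknown band {self.name!r}; expected one of {sorted(BAND_EDGES)}")
        if not (0 < self.low_hz < self.high_hz):
            raise ValueError(f"band {self.name}: need 0 < low_hz < high_hz, got ({self.low_hz}, {self.high_hz})")
        if self.amplitude < 0:
            raise ValueError(f"band {self.name}: amplitude must be >= 0, got {self.amplitude}")


def default_bands(**amplitudes: float) -> list[BandSpec]:
    """Build the five canonical bands with the given amplitudes.

    Keywords are band names; unspecified bands get amplitude 0.

    >>> default_bands(alpha=20.0)[2]
    BandSpec(name='alpha', low_hz=8.0, high_hz=12.0, amplitude=20.0)
    """
    unknown = set(amplitudes) - set(BAND_EDGES)
    if unknown:
        raise ValueError(f"unknown band name(s): {sorted(unknown)}")
    return [
        BandSpec(name, lo, hi, float(amplitudes.get(name, 0.0)))
        for name, (lo, hi) in BAND_EDGES.items()
    ]


@dataclass(frozen=True)
class ArtifactConfig:
    """Optional artifact contamination: mains line noise and muscle bursts."""

    line_noise_hz: float = 60.0  # US mains
    line_noise_amplitude: float = 0.0
    muscle_rate_hz: float = 0.0        # expected bursts per second per channel
    muscle_amplitude: float = 0.0
    muscle_duration_s: float = 0.1


@dataclass(frozen=True)
class SubjectProfile:
    """Class-conditional generative parameters for one subject.

    ``gain`` is a subject-level multiplicative factor on the whole signal
    (electrode contact / skull thickness proxy); ``noise_sd`` is the
    standard deviation of additive broadband Gaussian noise.
    """

    subject_id: str
    label: int  # 1 = delirium, 0 = control
    bands: list[BandSpec]
    gain: float = 1.0
    noise_sd: float = 0.0
    pink_sd: float = 0.0       # sd of the aperiodic 1/f background
    pink_exponent: float = 2.0  # PSD ~ 1/f**exponent
    synthesis: str = "sinusoid"  # or "filtered_noise" (stochastic band envelopes)
    artifacts: ArtifactConfig | None = None

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 (control) or 1 (delirium), got {self.label}")
        if self.gain <= 0:
            raise ValueError(f"gain must be > 0, got {self.gain}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.pink_sd < 0:
            raise ValueError(f"pink_sd must be >= 0, got {self.pink_sd}")
        if self.synthesis not in ("sinusoid", "filtered_noise"):
            raise ValueError(f"synthesis must be 'sinusoid' or 'filtered_noise', got {self.synthesis!r}")
        names = [b.name for b in self.bands]
        if len(names) != len(set(names)):
            raise ValueError(f"duplicate band specs: {names}")


@dataclass
class Recording:
    """One subject-session: an 8 x N sample array plus its delirium label."""

    subject_id: str
    label: int
    data: np.ndarray  # shape (8, N), channels x time
    sampling_interval: float = DEFAULT_SAMPLING_INTERVAL

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2 or self.data.shape[0] != N_CHANNELS:
            raise ValueError(
                f"recording {self.subject_id}: data must be {N_CHANNELS} x N, got shape {self.data.shape}"
            )
        if self.data.shape[1] < 1:
            raise ValueError(f"recording {self.subject_id}: need at least one sample")
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"recording {self.subject_id}: data contains non-finite samples")
        if self.sampling_interval <= 0:
            raise ValueError(f"sampling_interval must be > 0, got {self.sampling_interval}")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples * self.sampling_interval

    @property
    def sfreq(self) -> float:
        return 1.0 / self.sampling_interval


# --------------------------------------------------------------------------
# Default cohort profiles.
#
# Control amplitudes are in a realistic scalp-EEG µV range for drowsy,
# sedated older ICU patients (prominent diffuse theta); the delirium
# template applies the classic slowing signature (delta and theta doubled,
# alpha halved).  noise_sd of 5 µV is broadband instrument noise and the
# 20 µV pink component is the aperiodic background.  These are the cohort
# conditions used throughout the tests.
# --------------------------------------------------------------------------

CONTROL_AMPLITUDES = {"delta": 20.0, "theta": 30.0, "alpha": 20.0, "beta": 5.0, "gamma": 2.0}
DELIRIUM_AMPLITUDES = {"delta": 40.0, "theta": 60.0, "alpha": 10.0, "beta": 5.0, "gamma": 2.0}
DEFAULT_NOISE_SD = 5.0
DEFAULT_PINK_SD = 20.0


def control_profile(
    subject_id: str = "control-template",
    noise_sd: float = DEFAULT_NOISE_SD,
    pink_sd: float = DEFAULT_PINK_SD,
    synthesis: str = "filtered_noise",
) -> SubjectProfile:
    return SubjectProfile(subject_id, 0, default_bands(**CONTROL_AMPLITUDES),
                          noise_sd=noise_sd, pink_sd=pink_sd, synthesis=synthesis)


def delirium_profile(
    subject_id: str = "delirium-template",
    noise_sd: float = DEFAULT_NOISE_SD,
    pink_sd: float = DEFAULT_PINK_SD,
    synthesis: str = "filtered_noise",
) -> SubjectProfile:
    return SubjectProfile(subject_id, 1, default_bands(**DELIRIUM_AMPLITUDES),
                          noise_sd=noise_sd, pink_sd=pink_sd, synthesis=synthesis)


def delta_contrast_profiles(
    noise_sd: float = DEFAULT_NOISE_SD,
    pink_sd: float = DEFAULT_PINK_SD,
    synthesis: str = "filtered_noise",
) -> tuple[SubjectProfile, SubjectProfile]:
    """Template pair whose classes differ *only* in delta amplitude (2x).

    This is the cohort used to demonstrate the minimum-detectable-frequency
    mechanism: the class difference lives entirely below 3 Hz, so a slice
    shorter than one delta cycle cannot carry it.
    """
    amps = dict(CONTROL_AMPLITUDES)
    delirium = SubjectProfile(
        "delirium-template", 1,
        default_bands(**{**amps, "delta": 2 * amps["delta"]}),
        noise_sd=noise_sd, pink_sd=pink_sd, synthesis=synthesis,
    )
    control = SubjectProfile("control-template", 0, default_bands(**amps),
                             noise_sd=noise_sd, pink_sd=pink_sd, synthesis=synthesis)
    return delirium, control


def generate_recording(
    profile: SubjectProfile,
    duration: float,
    seed: int,
    sampling_interval: float = DEFAULT_SAMPLING_INTERVAL,
) -> Recording:
    """Synthesise one 8-channel recording from a subject profile.

    Each channel independently receives, per band, ``_COMPONENTS_PER_BAND``
    sinusoids with frequencies drawn uniformly inside the band and phases
    uniform on [0, 2pi); sinusoid amplitudes are scaled so the band's total
    power matches a single sinusoid at ``BandSpec.amplitude``.  Broadband
    Gaussian noise and configured artifacts are added, and the whole signal
    is multiplied by the subject gain.  Deterministic given ``seed``.
    """
    if duration <= 0:
        raise ValueError(f"duration must be > 0 seconds, got {duration}")
    if sampling_interval <= 0:
        raise ValueError(f"sampling_interval must be > 0, got {sampling_interval}")
    rng = np.random.default_rng(seed)
    n = int(round(duration / sampling_interval))
    t = np.arange(n) * sampling_interval
    data = np.zeros((N_CHANNELS, n))
    for band in profile.bands:
        if band.amplitude == 0:
            continue
        if profile.synthesis == "sinusoid":
            k = _COMPONENTS_PER_BAND
            # equal power split: k sinusoids at a/sqrt(k) have the power of one at a
            amp = band.amplitude / np.sqrt(k)
            freqs = rng.uniform(band.low_hz, band.high_hz, size=(N_CHANNELS, k))
            phases = rng.uniform(0, 2 * np.pi, size=(N_CHANNELS, k))
            data += (amp * np.sin(2 * np.pi * freqs[..., None] * t + phases[..., None])).sum(axis=1)
        else:
            data += _filtered_noise_band(band, (N_CHANNELS, n), sampling_interval, rng)
    if profile.noise_sd > 0:
        data += rng.normal(0, profile.noise_sd, size=data.shape)
    if profile.pink_sd > 0:
        data += _pink_noise(profile.pink_sd, profile.pink_exponent, data.shape, sampling_interval, rng)
    if profile.artifacts is not None:
        data += _render_artifacts(profile.artifacts, t, rng)
    data *= profile.gain
    return Recording(profile.subject_id, profile.label, data, sampling_interval)


def _filtered_noise_band(
    band: BandSpec, shape: tuple[int, int], dt: float, rng: np.random.Generator
) -> np.ndarray:
    """Narrowband activity as band-limited Gaussian noise.

    Unlike fixed sinusoids, this gives each band the stochastic,
    waxing-and-waning envelope real rhythms have (envelope decorrelation
    time ~ 1/bandwidth), so band power estimated from a short window is a
    noisy random variable while a long window averages it out.  Synthesis
    is spectral: complex Gaussian coefficients on the in-band DFT bins,
    zero elsewhere; per-channel output is rescaled to the power of one
    sinusoid at ``band.amplitude`` (RMS = amplitude / sqrt(2)).
    """
    n = shape[1]
    freqs = np.fft.rfftfreq(n, dt)
    mask = (freqs >= band.low_hz) & (freqs <= band.high_hz)
    if not mask.any():  # recording too short to hold the band: nearest bin
        mask[np.argmin(np.abs(freqs - (band.low_hz + band.high_hz) / 2))] = True
    gain = np.zeros_like(freqs)
    gain[mask] = 1.0
    coeff = rng.normal(0, 1.0, (shape[0], freqs.size)) + 1j * rng.normal(0, 1.0, (shape[0], freqs.size))
    noise = np.fft.irfft(coeff * gain, n=n, axis=1)
    rms = noise.std(axis=1, keepdims=True)
    rms[rms == 0] = 1.0
    return noise * (band.amplitude / np.sqrt(2)) / rms


def _pink_noise(
    sd: float, exponent: float, shape: tuple[int, int], dt: float, rng: np.random.Generator
) -> np.ndarray:
    """Aperiodic 1/f background: white noise spectrally shaped to PSD ~ f^-exponent.

    Scalp EEG is dominated by this aperiodic component (reported exponents
    roughly 1-2); it is what makes very short windows look like random
    ramps in both classes.  Shaping is flat below 0.3 Hz to keep variance
    finite; output is rescaled to standard deviation ``sd`` per channel.
    """
    n = shape[1]
    freqs = np.fft.rfftfreq(n, dt)
    gain = np.ones_like(freqs)
    nonzero = freqs > 0
    gain[nonzero] = np.maximum(freqs[nonzero], 0.3) ** (-exponent / 2)
    gain[0] = 0.0  # no DC offset
    spectrum = np.fft.rfft(rng.normal(0, 1.0, size=shape), axis=1) * gain
    noise = np.fft.irfft(spectrum, n=n, axis=1)
    scale = noise.std(axis=1, keepdims=True)
    scale[scale == 0] = 1.0
    return sd * noise / scale


def _render_artifacts(cfg: ArtifactConfig, t: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = np.zeros((N_CHANNELS, t.size))
    if cfg.line_noise_amplitude > 0:
        # mains pickup is coherent across channels up to phase
        phase = rng.uniform(0, 2 * np.pi)
        out += cfg.line_noise_amplitude * np.sin(2 * np.pi * cfg.line_noise_hz * t + phase)
    if cfg.muscle_rate_hz > 0 and cfg.muscle_amplitude > 0:
        dt = t[1] - t[0] if t.size > 1 else 1.0
        width = max(2, int(round(cfg.muscle_duration_s / dt)))
        window = np.hanning(width)
        duration = t.size * dt
        for ch in range(N_CHANNELS):
            n_bursts = rng.poisson(cfg.muscle_rate_hz * duration)
            for _ in range(n_bursts):
                start = rng.integers(0, max(1, t.size - width))
                burst = cfg.muscle_amplitude * window * rng.normal(0, 1, size=width)
                out[ch, start:start + width] += burst[: t.size - start]
    return out


def generate_cohort(
    n_subjects: int,
    fraction_delirium: float,
    profile_templates: tuple[SubjectProfile, SubjectProfile],
    duration: float,
    seed: int,
    gain_spread: float = 0.1,
    band_spread: float = 0.1,
    noise_spread: float = 0.45,
    sampling_interval: float = DEFAULT_SAMPLING_INTERVAL,
) -> list[Recording]:
    """Generate a cohort of recordings from a (delirium, control) template pair.

    Label counts follow the rounded fraction.  Subject-level heterogeneity
    is drawn log-normally around the template values: overall gain with
    log-sd ``gain_spread``, each band's amplitude with log-sd
    ``band_spread`` (one factor per band, shared by all channels — spectral
    profiles differ between people), and the broadband noise levels
    (``noise_sd`` and ``pink_sd``) with log-sd ``noise_spread`` (electrode
    impedance and background artifact levels vary widely).  Subject ids are
    ``S01``, ``S02``, ... with labels shuffled across them.  Reproducible
    given ``seed``.
    """
    if n_subjects < 2:
        raise ValueError(f"need at least 2 subjects, got {n_subjects}")
    if not (0 < fraction_delirium < 1):
        raise ValueError(f"fraction_delirium must be in (0, 1), got {fraction_delirium}")
    delirium_t, control_t = profile_templates
    if delirium_t.label != 1 or control_t.label != 0:
        raise ValueError("profile_templates must be (delirium template, control template)")
    n_pos = int(round(n_subjects * fraction_delirium))
    if n_pos == 0 or n_pos == n_subjects:
        raise ValueError(
            f"fraction_delirium={fraction_delirium} leaves a class empty at n_subjects={n_subjects}"
        )
    rng = np.random.default_rng(seed)
    labels = np.array([1] * n_pos + [0] * (n_subjects - n_pos))
    rng.shuffle(labels)
    cohort = []
    for i, label in enumerate(labels):
        template = delirium_t if label == 1 else control_t
        gain = template.gain * float(np.exp(rng.normal(0, gain_spread)))
        bands = [
            replace(b, amplitude=b.amplitude * float(np.exp(rng.normal(0, band_spread))))
            for b in template.bands
        ]
        noise_factor = float(np.exp(rng.normal(0, noise_spread)))
        pink_factor = float(np.exp(rng.normal(0, noise_spread)))
        profile = replace(
            template, subject_id=f"S{i + 1:02d}", gain=gain, bands=bands,
            noise_sd=template.noise_sd * noise_factor,
            pink_sd=template.pink_sd * pink_factor,
        )
        rec_seed = int(rng.integers(0, 2**31 - 1))
        cohort.append(generate_recording(profile, duration, rec_seed, sampling_interval))
    return cohort


def band_power(rec: Recording, low_hz: float, high_hz: float) -> float:
    """Mean per-channel periodogram power of ``rec`` inside [low_hz, high_hz]."""
    from scipy.signal import periodogram

    freqs, pxx = periodogram(rec.data, fs=rec.sfreq, axis=1)
    mask = (freqs >= low_hz) & (freqs <= high_hz)
    return float(pxx[:, mask].sum(axis=1).mean())
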