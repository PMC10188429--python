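"""EEG cleaning chain: band-pass filter, common-average reference, epoching,
and ICA-based artifact rejection.

The cleaning pipeline is filter -> rereference -> (epoch) -> ica_clean.
The "uncleaned" analysis arm skips only the ICA stage; filtering and
re-referencing always apply.  Defaults: 4th-order zero-phase Butterworth
band-pass at 0.1-40 Hz, common-average reference, component rejection by
plain kurtosis > 10 or > 50% of spectral power above 30 Hz.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps
from scipy import stats

from .synth import Recording

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocessConfig:
    highpass_hz: float = 0.1
    lowpass_hz: float = 40.0
    filter_order: int = 4
    reference: str = "common_average"  # or "none"
    epoch_length: float = 10.0  # seconds
    ica_enabled: bool = True
    ica_kurtosis_threshold: float = 10.0       # plain (Pearson) kurtosis; Gaussian = 3
    ica_highfreq_power_threshold: float = 0.5  # fraction of component power above 30 Hz
    ica_max_iter: int = 500
    ica_tol: float = 1e-4  # fixed-point convergence tolerance

    def __post_init__(self) -> None:
        if not (0 <= self.highpass_hz < self.lowpass_hz):
            raise ValueError(f"need 0 <= highpass < lowpass, got ({self.highpass_hz}, {self.lowpass_hz})")
        if self.epoch_length <= 0:
            raise ValueError(f"epoch_length must be > 0, got {self.epoch_length}")
        if self.ica_kurtosis_threshold < 0 or self.ica_highfreq_power_threshold < 0:
            raise ValueError("ICA rejection thresholds must be >= 0")
        if self.reference not in ("common_average", "none"):
            raise ValueError(f"reference must be 'common_average' or 'none', got {self.reference!r}")


def bandpass_filter(rec: Recording, cfg: PreprocessConfig = PreprocessConfig()) -> Recording:
    """Zero-phase Butterworth band-pass, applied independently per channel.

    Forward-backward filtering (``sosfiltfilt``) doubles the effective order
    and cancels phase distortion, so band-limited EEG features keep their
    latencies.
    """
    nyquist = rec.sfreq / 2
    if cfg.lowpass_hz >= nyquist:
        raise ValueError(
            f"lowpass {cfg.lowpass_hz} Hz is at or above Nyquist ({nyquist} Hz) "
            f"for recording {rec.subject_id}"
        )
    sos = sps.butter(
        cfg.filter_order, [cfg.highpass_hz, cfg.lowpass_hz], btype="bandpass",
        fs=rec.sfreq, output="sos",
    )
    filtered = sps.sosfiltfilt(sos, rec.data, axis=1)
    return replace(rec, data=filtered)


def rereference(rec: Recording) -> Recording:
    """Common-average reference: subtract the cross-channel mean per sample."""
    if rec.data.shape[0] < 2:
        raise ValueError(f"re-referencing needs >= 2 channels, got {rec.data.shape[0]}")
    return replace(rec, data=rec.data - rec.data.mean(axis=0, keepdims=True))


def epoch(rec: Recording, cfg: PreprocessConfig = PreprocessConfig()) -> list[Recording]:
    """Split into consecutive non-overlapping epochs; the remainder is dropped."""
    samples = int(round(cfg.epoch_length / rec.sampling_interval))
    if samples > rec.n_samples:
        raise ValueError(
            f"epoch_length {cfg.epoch_length}s exceeds recording {rec.subject_id} "
            f"duration {rec.duration}s"
        )
    n_epochs = rec.n_samples // samples
    return [
        replace(rec, data=rec.data[:, i * samples:(i + 1) * samples])
        for i in range(n_epochs)
    ]


MIN_ICA_SECONDS = 10.0


def ica_clean(
    rec: Recording,
    cfg: PreprocessConfig = PreprocessConfig(),
    seed: int = 0,
) -> Recording:
    """Remove artifact components found by FastICA.

    The recording is unmixed into 8 independent components (negentropy
    maximising fixed-point algorithm).  A component is rejected when its
    plain kurtosis exceeds ``ica_kurtosis_threshold`` (spiky transients such
    as muscle bursts or electrode pops) or when more than
    ``ica_highfreq_power_threshold`` of its spectral power lies above 30 Hz
    (EMG-like activity).  Rejected components are zeroed and the signal is
    rebuilt from the rest.  With ``ica_enabled`` False this is an identity.

    On convergence failure the recording is returned unmodified with a
    logged warning.
    """
    if not cfg.ica_enabled:
        return rec
    if rec.duration < MIN_ICA_SECONDS:
        raise ValueError(
            f"recording {rec.subject_id} is {rec.duration:.1f}s; ICA needs >= "
            f"{MIN_ICA_SECONDS:.0f}s for a stable unmixing"
        )
    import warnings

    from sklearn.decomposition import FastICA
    from sklearn.exceptions import ConvergenceWarning

    n_channels = rec.data.shape[0]
    ica = FastICA(
        n_components=n_channels, whiten="unit-variance", max_iter=cfg.ica_max_iter,
        tol=cfg.ica_tol, random_state=seed,
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        sources = ica.fit_transform(rec.data.T)  # (n_samples, n_components)
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            logger.warning(
                "FastICA did not converge in %d iterations for recording %s; "
                "returning it unmodified", cfg.ica_max_iter, rec.subject_id,
            )
            return rec

    keep = np.ones(n_channels, dtype=bool)
    kurt = stats.kurtosis(sources, axis=0, fisher=False)
    highfreq = _highfreq_power_fraction(sources.T, rec.sfreq)
    keep &= kurt <= cfg.ica_kurtosis_threshold
    keep &= highfreq <= cfg.ica_highfreq_power_threshold
    logger.info(
        "ICA on %s (seed=%d): rejecting %d/%d components (kurtosis=%s, highfreq=%s)",
        rec.subject_id, seed, int((~keep).sum()), n_channels,
        np.array2string(kurt, precision=1), np.array2string(highfreq, precision=2),
    )
    sources[:, ~keep] = 0.0
    cleaned = sources @ ica.mixing_.T + ica.mean_
    return replace(rec, data=cleaned.T)


def _highfreq_power_fraction(sources: np.ndarray, sfreq: float, cutoff_hz: float = 30.0) -> np.ndarray:
    freqs, pxx = sps.periodogram(sources, fs=sfreq, axis=1)
    total = pxx.sum(axis=1)
    total[total == 0] = 1.0
    return pxx[:, freqs > cutoff_hz].sum(axis=1) / total


def preprocess_recording(
    rec: Recording,
    cfg: PreprocessConfig = PreprocessConfig(),
    seed: int = 0,
    ica: bool | None = None,
) -> Recording:
    """Full cleaning chain on one recording: filter -> rereference -> ica.

    ``ica=False`` selects the "uncleaned" arm (still filtered and
    re-referenced).  Epoching is a separate, optional step because the
    slicing stage cuts its own windows.
    """
    out = bandpass_filter(rec, cfg)
    if cfg.reference == "common_average":
        out = rereference(out)
    use_ica = cfg.ica_enabled if ica is None else ica
    if use_ica:
        out = ica_clean(out, replace(cfg, ica_enabled=True), seed=seed)
    return out
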