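"""Signal conditioning: windowing, session-baseline artifact rejection, filtering.

Order of operations is fixed: split each ~2 s trial into two consecutive
1 s windows -> compute the session baseline from *unfiltered* window
amplitudes -> reject trials whose window amplitude deviates more than
3 SD from the baseline -> band-pass (0.1-123.75 Hz, 4th-order Butterworth,
zero phase) and 60 Hz notch the surviving windows.  Rejection deliberately
precedes filtering so that broadband transients are judged at full amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import signal

from .montage import SAMPLING_RATE, RawTrial, ValidationError

WINDOW_SAMPLES = 250  # 1 s at 250 Hz

#: Band-pass corners.  The upper corner is clipped below Nyquist (125 Hz at
#: 250 Hz sampling) because a corner at Nyquist is unrealizable.
BAND_LOW_HZ = 0.1
BAND_HIGH_HZ = 123.75
NOTCH_HZ = 60.0
NOTCH_Q = 30.0
REJECTION_SD = 3.0


@dataclass
class WindowPair:
    """A trial split into its two 1 s analysis windows."""

    participant: int
    session: int
    phoneme_id: int
    trial_index: int
    window1: np.ndarray | None
    window2: np.ndarray | None
    rejected: bool = False
    rejection_reason: str = ""

    @property
    def windows(self) -> tuple[np.ndarray, ...]:
        return tuple(w for w in (self.window1, self.window2) if w is not None)


@dataclass(frozen=True)
class SessionBaseline:
    """Mean and SD of the per-window amplitude statistic over one session.

    Computed over *all* windows of the session before any rejection.
    """

    participant: int
    session: int
    mean_amplitude: float
    sd_amplitude: float


def window_amplitude(window: np.ndarray) -> float:
    """The amplitude statistic: mean absolute amplitude over channels and samples."""
    return float(np.mean(np.abs(window)))


def split_windows(trial: RawTrial) -> WindowPair:
    """Split a trial into two consecutive 1 s windows; excess samples are dropped."""
    samples = np.asarray(trial.samples, dtype=float)
    meta = dict(
        participant=trial.participant,
        session=trial.session,
        phoneme_id=trial.phoneme_id,
        trial_index=trial.trial_index,
    )
    if samples.shape[1] < 2 * WINDOW_SAMPLES:
        return WindowPair(**meta, window1=None, window2=None,
                          rejected=True, rejection_reason="short")
    return WindowPair(
        **meta,
        window1=samples[:, :WINDOW_SAMPLES].copy(),
        window2=samples[:, WINDOW_SAMPLES : 2 * WINDOW_SAMPLES].copy(),
    )


def compute_baseline(pairs: Sequence[WindowPair]) -> SessionBaseline:
    """Session baseline: mean and SD (population, ddof=0) of window amplitudes."""
    if not pairs:
        raise ValidationError("cannot compute a baseline from an empty session")
    participant = pairs[0].participant
    session = pairs[0].session
    stats = [window_amplitude(w) for p in pairs for w in p.windows]
    if not stats:
        raise ValidationError("session has no intact windows")
    return SessionBaseline(
        participant=participant,
        session=session,
        mean_amplitude=float(np.mean(stats)),
        sd_amplitude=float(np.std(stats)),
    )


def reject_artifacts(pair: WindowPair, baseline: SessionBaseline) -> WindowPair:
    """Mark the trial rejected if either window deviates > 3 SD from baseline."""
    if pair.rejected:
        return pair
    threshold = REJECTION_SD * baseline.sd_amplitude
    for window in pair.windows:
        if abs(window_amplitude(window) - baseline.mean_amplitude) > threshold:
            return replace(pair, rejected=True, rejection_reason="artifact")
    return pair


_gain_cache: dict[tuple[int, float], np.ndarray] = {}


def _zero_phase_gain(n_samples: int, sampling_rate: float) -> np.ndarray:
    """|H(f)|^2 of the band-pass + notch chain on the window's rFFT grid.

    Forward-backward application of a filter has transfer function |H(f)|^2
    (zero phase).  On 1 s windows the 0.1 Hz Butterworth corner's impulse
    response is far longer than the window, so time-domain filtfilt is
    dominated by edge transients; applying the squared magnitude response
    multiplicatively in the frequency domain realizes the same zero-phase
    response exactly, with no transients.
    """
    key = (n_samples, sampling_rate)
    if key not in _gain_cache:
        nyquist = sampling_rate / 2.0
        high = min(BAND_HIGH_HZ, 0.99 * nyquist)
        freqs = np.fft.rfftfreq(n_samples, d=1.0 / sampling_rate)
        sos = signal.butter(4, [BAND_LOW_HZ, high], btype="bandpass",
                            fs=sampling_rate, output="sos")
        _, h_bp = signal.sosfreqz(sos, worN=freqs, fs=sampling_rate)
        b_notch, a_notch = signal.iirnotch(NOTCH_HZ, NOTCH_Q, fs=sampling_rate)
        _, h_notch = signal.freqz(b_notch, a_notch, worN=freqs, fs=sampling_rate)
        _gain_cache[key] = (np.abs(h_bp) * np.abs(h_notch)) ** 2
    return _gain_cache[key]


def filter_window(window: np.ndarray, sampling_rate: float = SAMPLING_RATE) -> np.ndarray:
    """Zero-phase band-pass (0.1-123.75 Hz, 4th-order Butterworth) + 60 Hz notch (Q=30)."""
    window = np.asarray(window, dtype=float)
    if not np.all(np.isfinite(window)):
        raise ValidationError("window contains non-finite samples")
    n = window.shape[-1]
    gain = _zero_phase_gain(n, sampling_rate)
    return np.fft.irfft(np.fft.rfft(window, axis=-1) * gain, n=n, axis=-1)


def preprocess_session(trials: Sequence[RawTrial]) -> tuple[list[WindowPair], SessionBaseline]:
    """Run split -> baseline -> reject -> filter over one session's trials.

    Returns the processed pairs (filtered windows for retained trials,
    rejection flags for the rest) and the session baseline.
    """
    pairs = [split_windows(t) for t in trials]
    baseline = compute_baseline(pairs)
    out: list[WindowPair] = []
    for pair in pairs:
        pair = reject_artifacts(pair, baseline)
        if not pair.rejected:
            pair = replace(
                pair,
                window1=filter_window(pair.window1),
                window2=filter_window(pair.window2),
            )
        out.append(pair)
    return out, baseline
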