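"""Synthetic imagined-speech EEG datasets with known ground truth.

Each trial is 2 s of 16-channel, 250 Hz EEG emulating the study conditions:
per-channel 1/f colored-noise background, 60 Hz mains contamination,
phoneme-specific gamma-band power signatures concentrated on F3/F7 (the
left-frontal sites over speech-forming cortex), and occasional
high-amplitude movement-like transients.

The class signature model: every phoneme receives a fixed total tone-power
budget, split by a seeded Dirichlet draw across four slots —
(F3, F7) x (low-gamma, high-gamma) — with seeded per-slot tone frequencies.
Separability therefore lives in the gamma sub-band *structure* on F3/F7
rather than in gross amplitude, and ``effect_size = 0`` yields exchangeable
classes (a proper null).  Generation is a pure function of the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .montage import (
    CHANNELS,
    SAMPLING_RATE,
    NOMINAL_SAMPLES,
    DatasetManifest,
    RawTrial,
    ValidationError,
    build_manifest,
    write_trial,
)

#: Gamma sub-band tone frequency ranges (Hz): low gamma 30-65, high gamma 65-100,
#: with margins so Hann leakage stays inside the sub-band.
_LOW_GAMMA_TONE_RANGE = (33.0, 62.0)
_HIGH_GAMMA_TONE_RANGE = (68.0, 97.0)

_ARTIFACT_DURATION_S = 0.2
_ARTIFACT_GAIN = 6.0  # peak amplitude as a multiple of background RMS


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters for the synthetic dataset.

    Defaults reproduce the acquisition structure: 3 sessions x 44 phonemes x
    5 trials per participant (660 trials), 2 s trials at 250 Hz.
    ``effect_size`` is the dimensionless amplitude of the class-specific
    gamma signature relative to background RMS (0 disables it);
    ``background_rms`` is in microvolts.
    """

    n_participants: int = 1
    n_sessions: int = 3
    trials_per_phoneme: int = 5
    effect_channels: tuple[str, ...] = ("F3", "F7")
    effect_size: float = 1.0
    background_rms: float = 10.0
    background_exponent: float = 1.0
    line_noise_amplitude: float = 2.0
    artifact_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not set(self.effect_channels) <= set(CHANNELS):
            raise ValidationError("effect_channels must be montage labels")
        if self.effect_size < 0:
            raise ValidationError("effect_size must be >= 0")
        if not (0.0 <= self.artifact_rate <= 1.0):
            raise ValidationError("artifact_rate must be in [0, 1]")
        if self.n_participants < 1 or self.n_sessions < 1 or self.trials_per_phoneme < 1:
            raise ValidationError("counts must be positive")
        if self.background_rms <= 0:
            raise ValidationError("background_rms must be positive")


#: Per-class level grades for the primary slot's share of the power budget.
_PRIMARY_SHARES = (0.55, 0.625, 0.70, 0.775, 0.85)


@dataclass(frozen=True)
class SlotTone:
    """One gamma tone: where it lives and how strong it is in each window."""

    window: int        # 1 or 2 (first / second 1 s of the trial)
    channel: str       # F3 or F7
    sub_band: str      # "low" (30-65 Hz) or "high" (65-100 Hz)
    frequency: float   # Hz
    amplitude: float   # uV, within its window; zero in the other window


@dataclass(frozen=True)
class ClassSignature:
    """Ground-truth gamma signature of one phoneme class.

    Each class concentrates the fixed tone-power budget on a *primary* and
    a *secondary* slot among the 8 (window x channel x gamma sub-band)
    slots, with a graded primary share.  Sparse slot ownership gives every
    class a strongly mean-shifted marginal feature — the structure a
    univariate effect-size ranking like ADEN can recover.
    """

    phoneme_id: int
    tones: tuple[SlotTone, ...]

    def expected_band_power(
        self, channel: str, lo: float, hi: float, window: int | None = None
    ) -> float:
        """Expected added power (uV^2) in [lo, hi) on ``channel``.

        With ``window=None`` the trial-average over the two windows is
        returned; otherwise the named window's power.
        """
        power = 0.0
        for tone in self.tones:
            if tone.channel != channel or not (lo <= tone.frequency < hi):
                continue
            p = tone.amplitude**2 / 2.0
            if window is None:
                power += p / 2.0  # tone occupies one of the two windows
            elif tone.window == window:
                power += p
        return power


def class_signatures(config: SimulationConfig) -> dict[int, ClassSignature]:
    """Deterministic per-phoneme gamma signatures implied by ``config``.

    Every class has the same total trial-average tone power,
    (effect_size * background_rms)^2 / 2, split between an ordered pair of
    distinct slots (primary share from :data:`_PRIMARY_SHARES`, remainder to
    the secondary).  The pair assignment and the tone frequencies are a
    pure function of ``config.seed``; ``effect_size = 0`` zeroes every tone.
    """
    config.validate()
    total_power = (config.effect_size * config.background_rms) ** 2 / 2.0
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(1,)))
    slots = [
        (window, channel, sub)
        for window in (1, 2)
        for channel in config.effect_channels
        for sub in ("low", "high")
    ]
    pairs = [(i, j) for i in range(len(slots)) for j in range(len(slots)) if i != j]
    order = rng.permutation(len(pairs))
    out: dict[int, ClassSignature] = {}
    for phoneme_id in range(1, 45):
        i, j = pairs[order[(phoneme_id - 1) % len(pairs)]]
        share = _PRIMARY_SHARES[(phoneme_id - 1) % len(_PRIMARY_SHARES)]
        tones = []
        for slot_idx, slot_power in ((i, share * total_power),
                                     (j, (1.0 - share) * total_power)):
            window, channel, sub = slots[slot_idx]
            band = _LOW_GAMMA_TONE_RANGE if sub == "low" else _HIGH_GAMMA_TONE_RANGE
            # The slot's tone is confined to one window, so its in-window
            # power is twice its trial-average contribution.
            tones.append(
                SlotTone(
                    window=window,
                    channel=channel,
                    sub_band=sub,
                    frequency=float(rng.uniform(*band)),
                    amplitude=math.sqrt(2.0 * 2.0 * slot_power),
                )
            )
        out[phoneme_id] = ClassSignature(phoneme_id, tuple(tones))
    return out


def _colored_noise(rng: np.random.Generator, n: int, exponent: float, rms: float) -> np.ndarray:
    """1/f^exponent Gaussian noise of length n, scaled to the target RMS."""
    freqs = np.fft.rfftfreq(n, d=1.0 / SAMPLING_RATE)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    spectrum = shape * (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size))
    x = np.fft.irfft(spectrum, n=n)
    sd = x.std()
    if sd > 0:
        x *= rms / sd
    return x


def simulate_trial(
    config: SimulationConfig,
    participant: int,
    session: int,
    phoneme_id: int,
    trial_index: int,
    signatures: dict[int, ClassSignature] | None = None,
) -> RawTrial:
    """Generate one trial deterministically from (config.seed, identity)."""
    config.validate()
    if signatures is None:
        signatures = class_signatures(config)
    rng = np.random.default_rng(
        np.random.SeedSequence(
            config.seed, spawn_key=(2, participant, session, phoneme_id, trial_index)
        )
    )
    n = NOMINAL_SAMPLES
    t = np.arange(n) / SAMPLING_RATE
    samples = np.empty((len(CHANNELS), n))
    for c in range(len(CHANNELS)):
        samples[c] = _colored_noise(rng, n, config.background_exponent, config.background_rms)
    # Mains contamination, common phase across channels within a trial.
    phase = rng.uniform(0, 2 * np.pi)
    samples += config.line_noise_amplitude * np.sin(2 * np.pi * 60.0 * t + phase)
    # Class-specific gamma tones, each confined to its window.
    signature = signatures[phoneme_id]
    half = n // 2
    for tone in signature.tones:
        row = CHANNELS.index(tone.channel)
        sl = slice(0, half) if tone.window == 1 else slice(half, n)
        samples[row, sl] += tone.amplitude * np.sin(
            2 * np.pi * tone.frequency * t[sl] + rng.uniform(0, 2 * np.pi)
        )
    # Occasional high-amplitude transient across all channels.
    if rng.random() < config.artifact_rate:
        width = int(_ARTIFACT_DURATION_S * SAMPLING_RATE)
        start = rng.integers(0, n - width)
        bump = 0.5 * (1.0 - np.cos(2 * np.pi * np.arange(width) / width))
        samples[:, start : start + width] += _ARTIFACT_GAIN * config.background_rms * bump
    return RawTrial(
        participant=participant,
        session=session,
        phoneme_id=phoneme_id,
        trial_index=trial_index,
        samples=samples,
    )


def iter_trials(config: SimulationConfig):
    """Yield every trial of the simulated dataset, in deterministic order."""
    signatures = class_signatures(config)
    for participant in range(1, config.n_participants + 1):
        for session in range(1, config.n_sessions + 1):
            for phoneme_id in range(1, 45):
                for trial_index in range(1, config.trials_per_phoneme + 1):
                    yield simulate_trial(
                        config, participant, session, phoneme_id, trial_index, signatures
                    )


def simulate_dataset(config: SimulationConfig, directory: str | Path) -> DatasetManifest:
    """Write a full synthetic dataset as per-trial CSV files and return its manifest."""
    config.validate()
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for trial in iter_trials(config):
        write_trial(trial, directory)
    return build_manifest(directory)


def oracle_band_power(
    samples: np.ndarray, lo: float, hi: float, sampling_rate: float = SAMPLING_RATE
) -> float:
    """Band power by direct FFT periodogram summation (test oracle).

    Independent of the Welch implementation used for features: a single
    un-tapered periodogram of the full record, one-sided, summed over bins
    with centers in [lo, hi).  Units uV^2 for input in uV.
    """
    if not (0.0 <= lo < hi <= sampling_rate / 2.0):
        raise ValidationError(f"band [{lo}, {hi}) outside (0, Nyquist]")
    x = np.asarray(samples, dtype=float)
    n = x.shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate)
    spectrum = np.fft.rfft(x)
    # One-sided PSD: 2|X|^2 / (fs * n), no doubling at DC/Nyquist.
    psd = (np.abs(spectrum) ** 2) / (sampling_rate * n)
    psd[..., 1:] *= 2.0
    if n % 2 == 0:
        psd[..., -1] /= 2.0
    df = freqs[1] - freqs[0]
    mask = (freqs >= lo) & (freqs < hi)
    return float(np.sum(psd[..., mask], axis=-1) * df)
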