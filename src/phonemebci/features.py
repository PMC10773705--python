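"""Per-window band-power feature extraction and feature-matrix assembly.

Each 1 s channel window yields 35 features:

====  =========================================  ==================
pos   feature                                     kind
====  =========================================  ==================
1     temporal mean                               amplitude
2     99.95th percentile of |amplitude|           amplitude
3     RMS amplitude                               amplitude
4     peak-to-peak amplitude                      amplitude
5     total power 1-100 Hz                        absolute power
6-10  band powers (delta..gamma)                  absolute power
11-20 sub-band powers (low/high per band)         absolute power
21-25 relative band powers (band/total)           relative power
26-35 relative sub-band powers                    relative power
====  =========================================  ==================

Per trial: 35 features x 16 channels x 2 windows = 1,120 values, ordered
window-major, then channel in montage order, then inventory order.
Spectra come from Welch's method (125-sample Hann segments, 50% overlap,
2 Hz resolution); band power is the rectangle-rule integral of the density
over bins whose centers fall in [lo, hi).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .montage import (
    CHANNELS,
    SAMPLING_RATE,
    DatasetManifest,
    ValidationError,
)
from .preprocess import WINDOW_SAMPLES, WindowPair, preprocess_session

logger = logging.getLogger(__name__)

#: Canonical EEG bands (Hz).  Sub-bands split each at its arithmetic
#: midpoint (so alpha-low is 8-10 Hz).
BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (5.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 100.0),
}

TOTAL_BAND = (1.0, 100.0)

WELCH_NPERSEG = 125
WELCH_NOVERLAP = 62

N_FEATURES_PER_CHANNEL = 35
N_FEATURES_PER_WINDOW = 35 * 16
N_FEATURES_PER_TRIAL = 2 * N_FEATURES_PER_WINDOW


def sub_bands() -> dict[str, tuple[float, float]]:
    """The 10 sub-bands: each band split at its arithmetic midpoint."""
    out: dict[str, tuple[float, float]] = {}
    for name, (lo, hi) in BANDS.items():
        mid = (lo + hi) / 2.0
        out[f"{name}_low"] = (lo, mid)
        out[f"{name}_high"] = (mid, hi)
    return out


@dataclass(frozen=True)
class FeatureDef:
    name: str
    kind: str  # amplitude | absolute-power | relative-power
    band: tuple[float, float] | None = None
    band_name: str | None = None  # base band for (sub-)band features


def feature_inventory() -> list[FeatureDef]:
    """The ordered 35-entry per-channel feature inventory."""
    inv: list[FeatureDef] = [
        FeatureDef("mean", "amplitude"),
        FeatureDef("p99_95", "amplitude"),
        FeatureDef("rms", "amplitude"),
        FeatureDef("ptp", "amplitude"),
        FeatureDef("total_power", "absolute-power", TOTAL_BAND),
    ]
    subs = sub_bands()
    for name, band in BANDS.items():
        inv.append(FeatureDef(f"pow_{name}", "absolute-power", band, name))
    for name, band in subs.items():
        inv.append(FeatureDef(f"pow_{name}", "absolute-power", band, name.split("_")[0]))
    for name, band in BANDS.items():
        inv.append(FeatureDef(f"rel_{name}", "relative-power", band, name))
    for name, band in subs.items():
        inv.append(FeatureDef(f"rel_{name}", "relative-power", band, name.split("_")[0]))
    assert len(inv) == N_FEATURES_PER_CHANNEL
    return inv


FEATURE_INVENTORY = feature_inventory()
FEATURE_NAMES = [f.name for f in FEATURE_INVENTORY]


def feature_index() -> pd.DataFrame:
    """Column metadata for the 1,120-element trial vector.

    One row per position: window (1|2), channel label, feature name, kind,
    and the base band name for spectral features.
    """
    rows = []
    for window in (1, 2):
        for channel in CHANNELS:
            for fdef in FEATURE_INVENTORY:
                rows.append(
                    {
                        "window": window,
                        "channel": channel,
                        "feature": fdef.name,
                        "kind": fdef.kind,
                        "band": fdef.band_name or "",
                    }
                )
    frame = pd.DataFrame(rows)
    frame.index.name = "column"
    return frame


def welch_psd(window: np.ndarray, sampling_rate: float = SAMPLING_RATE):
    """Welch PSD of a 1 s window (125-sample Hann segments, 50% overlap).

    Accepts a 1D (samples,) or 2D (channels, samples) array; density in
    uV^2/Hz over 0..Nyquist.
    """
    window = np.asarray(window, dtype=float)
    if not np.all(np.isfinite(window)):
        raise ValidationError("non-finite input to welch_psd")
    freqs, density = signal.welch(
        window,
        fs=sampling_rate,
        window="hann",
        nperseg=WELCH_NPERSEG,
        noverlap=WELCH_NOVERLAP,
        detrend=False,
        axis=-1,
    )
    return freqs, density


_warned_empty_bands: set[tuple[float, float]] = set()


def band_power(freqs: np.ndarray, density: np.ndarray, band: tuple[float, float]) -> float:
    """Integrate a PSD over bins with centers in [lo, hi); units uV^2."""
    lo, hi = band
    mask = (freqs >= lo) & (freqs < hi)
    if not np.any(mask):
        if (lo, hi) not in _warned_empty_bands:
            _warned_empty_bands.add((lo, hi))
            logger.warning(
                "band [%g, %g) contains no frequency bins at this resolution; "
                "its power is 0", lo, hi,
            )
        return 0.0
    df = float(freqs[1] - freqs[0])
    return float(np.sum(density[..., mask], axis=-1) * df)


def extract_channel_features(
    window: np.ndarray, sampling_rate: float = SAMPLING_RATE
) -> np.ndarray:
    """The 35 features for one channel's filtered 1 s window, inventory order."""
    x = np.asarray(window, dtype=float)
    if x.ndim != 1 or x.size != WINDOW_SAMPLES:
        raise ValidationError(f"expected a {WINDOW_SAMPLES}-sample channel window")
    freqs, density = welch_psd(x, sampling_rate)
    total = band_power(freqs, density, TOTAL_BAND)
    subs = sub_bands()
    abs_bands = [band_power(freqs, density, BANDS[b]) for b in BANDS]
    abs_subs = [band_power(freqs, density, subs[s]) for s in subs]

    def rel(p: float) -> float:
        return p / total if total > 0 else 0.0

    values = [
        float(np.mean(x)),
        float(np.percentile(np.abs(x), 99.95)),
        float(np.sqrt(np.mean(x**2))),
        float(np.ptp(x)),
        total,
        *abs_bands,
        *abs_subs,
        *[rel(p) for p in abs_bands],
        *[rel(p) for p in abs_subs],
    ]
    return np.asarray(values)


@dataclass
class TrialFeatures:
    """One trial's 1,120-element feature vector plus identity."""

    participant: int
    session: int
    phoneme_id: int
    trial_index: int
    vector: np.ndarray


def assemble_trial_vector(pair: WindowPair) -> TrialFeatures:
    """Concatenate per-channel features: 16x35 = 560 per window, w1 || w2 = 1,120."""
    if pair.rejected:
        raise ValidationError("cannot extract features from a rejected trial")
    blocks = []
    for window in (pair.window1, pair.window2):
        for c in range(len(CHANNELS)):
            blocks.append(extract_channel_features(window[c]))
    vector = np.concatenate(blocks)
    assert vector.size == N_FEATURES_PER_TRIAL
    return TrialFeatures(
        participant=pair.participant,
        session=pair.session,
        phoneme_id=pair.phoneme_id,
        trial_index=pair.trial_index,
        vector=vector,
    )


@dataclass
class FeatureMatrix:
    """Stacked trial feature vectors with labels and participant groups."""

    X: np.ndarray                  # (n_trials, 1120)
    labels: np.ndarray             # phoneme id per row, 1..44
    participants: np.ndarray       # participant id per row
    sessions: np.ndarray = None    # session per row
    index: pd.DataFrame = None     # column metadata (feature_index())
    rejections: pd.DataFrame = None

    def __post_init__(self) -> None:
        if self.index is None:
            self.index = feature_index()
        if self.X.ndim != 2 or self.X.shape[1] != N_FEATURES_PER_TRIAL:
            raise ValidationError(
                f"feature matrix must have {N_FEATURES_PER_TRIAL} columns"
            )

    @property
    def n_trials(self) -> int:
        return self.X.shape[0]

    def to_frame(self) -> pd.DataFrame:
        cols = [
            f"w{r.window}_{r.channel}_{r.feature}" for r in self.index.itertuples()
        ]
        frame = pd.DataFrame(self.X, columns=cols)
        frame.insert(0, "participant", self.participants)
        frame.insert(1, "phoneme", self.labels)
        return frame

    def export(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def build_feature_matrix(
    manifest: DatasetManifest,
    mode: str = "intersubject",
    participant: int | None = None,
) -> FeatureMatrix:
    """Preprocess and extract features for every retained trial in a manifest.

    ``mode='intrasubject'`` restricts to one participant (required argument);
    ``mode='intersubject'`` pools all participants.  Trials rejected as
    artifacts (or too short) shrink the row count; the rejection log is
    attached to the returned matrix.
    """
    if mode == "intrasubject":
        if participant is None:
            raise ValidationError("intrasubject mode requires a participant id")
        records = [r for r in manifest.trials if r.participant == participant]
    elif mode == "intersubject":
        records = list(manifest.trials)
    else:
        raise ValidationError(f"unknown mode {mode!r}")
    if not records:
        raise ValidationError("no retained trials to featurize")

    by_session: dict[tuple[int, int], list] = {}
    for record in records:
        by_session.setdefault((record.participant, record.session), []).append(record)

    rows, labels, participants, sessions, rejection_rows = [], [], [], [], []
    for (pid, sid), session_records in sorted(by_session.items()):
        from .montage import read_trial

        trials = [read_trial(r.path) for r in session_records]
        pairs, _ = preprocess_session(trials)
        for pair in pairs:
            if pair.rejected:
                rejection_rows.append(
                    {
                        "participant": pair.participant,
                        "session": pair.session,
                        "phoneme": pair.phoneme_id,
                        "trial": pair.trial_index,
                        "reason": pair.rejection_reason,
                    }
                )
                continue
            tf = assemble_trial_vector(pair)
            rows.append(tf.vector)
            labels.append(tf.phoneme_id)
            participants.append(tf.participant)
            sessions.append(tf.session)
    if not rows:
        raise ValidationError("every trial was rejected; nothing to featurize")
    logger.info(
        "feature matrix: %d trials kept, %d rejected", len(rows), len(rejection_rows)
    )
    return FeatureMatrix(
        X=np.vstack(rows),
        labels=np.asarray(labels),
        participants=np.asarray(participants),
        sessions=np.asarray(sessions),
        rejections=pd.DataFrame(
            rejection_rows,
            columns=["participant", "session", "phoneme", "trial", "reason"],
        ),
    )
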