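"""Electrode montage, phoneme inventory, per-trial file I/O and dataset manifest.

Trials are 16-channel, 250 Hz recordings of ~2 s, one CSV file per trial,
with participant/session/phoneme/trial encoded in the filename::

    P{participant:02d}_S{session}_PH{phoneme:02d}_T{trial}.csv

The CSV has a header row of channel labels (10-20 system) and one row per
sample, values in microvolts.  A sidecar file with the same stem and the
suffix ``.failed`` marks a trial whose acquisition timestamp failed; such
trials are excluded from the manifest.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: 10-20 channel labels in fixed montage order.  Feature-vector positions
#: depend on this order; it must never change between writing and reading.
CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "F4", "F8", "T3", "C3",
    "C4", "T4", "T5", "T6", "P3", "P4", "O1", "O2",
)

SAMPLING_RATE: float = 250.0

#: Nominal trial length (2 s at 250 Hz) and the accepted range (±10%).
NOMINAL_SAMPLES: int = 500
MIN_SAMPLES: int = 450
MAX_SAMPLES: int = 550

_FILENAME_RE = re.compile(
    r"^P(?P<participant>\d{2,})_S(?P<session>\d)_PH(?P<phoneme>\d{2})_T(?P<trial>\d)\.csv$"
)


class ValidationError(ValueError):
    """A trial or file violates a structural invariant."""


@dataclass(frozen=True)
class Montage:
    """The fixed 16-channel 10-20 montage at 250 Hz."""

    channels: tuple[str, ...] = CHANNELS
    sampling_rate: float = SAMPLING_RATE

    def __post_init__(self) -> None:
        if len(self.channels) != 16 or len(set(self.channels)) != 16:
            raise ValidationError("montage requires exactly 16 distinct channel labels")

    def index(self, label: str) -> int:
        return self.channels.index(label)


DEFAULT_MONTAGE = Montage()


@dataclass(frozen=True)
class Phoneme:
    id: int
    symbol: str
    example: str


# The 44-phoneme English inventory (24 consonants + 20 vowels/diphthongs),
# ARPAbet-style symbols.  Any fixed 44-symbol inventory is interchangeable
# for classification; this one ships as the packaged default.
_PHONEME_TABLE: tuple[tuple[str, str], ...] = (
    # consonants (24)
    ("P", "pan"), ("B", "ban"), ("T", "tan"), ("D", "dan"),
    ("K", "can"), ("G", "gap"), ("CH", "chat"), ("JH", "jam"),
    ("F", "fan"), ("V", "van"), ("TH", "thin"), ("DH", "then"),
    ("S", "sip"), ("Z", "zip"), ("SH", "ship"), ("ZH", "measure"),
    ("HH", "hat"), ("M", "man"), ("N", "nap"), ("NG", "sing"),
    ("L", "lap"), ("R", "ran"), ("W", "wet"), ("Y", "yes"),
    # monophthongs (12)
    ("IY", "fleece"), ("IH", "kit"), ("UH", "foot"), ("UW", "goose"),
    ("EH", "dress"), ("AX", "about"), ("ER", "nurse"), ("AO", "thought"),
    ("AE", "trap"), ("AH", "strut"), ("AA", "palm"), ("OH", "lot"),
    # diphthongs (8)
    ("EY", "face"), ("AY", "price"), ("OY", "choice"), ("OW", "goat"),
    ("AW", "mouth"), ("IA", "near"), ("EA", "square"), ("UA", "cure"),
)


@dataclass(frozen=True)
class PhonemeInventory:
    """Ordered inventory of the 44 English phonemes, ids 1..44."""

    entries: tuple[Phoneme, ...] = tuple(
        Phoneme(i + 1, sym, word) for i, (sym, word) in enumerate(_PHONEME_TABLE)
    )

    def __post_init__(self) -> None:
        ids = [p.id for p in self.entries]
        symbols = [p.symbol for p in self.entries]
        if len(self.entries) != 44 or ids != list(range(1, 45)):
            raise ValidationError("phoneme inventory must have ids 1..44 with no gaps")
        if len(set(symbols)) != 44:
            raise ValidationError("phoneme symbols must be unique")

    def __len__(self) -> int:
        return 44

    def symbol(self, phoneme_id: int) -> str:
        return self.entries[phoneme_id - 1].symbol


DEFAULT_INVENTORY = PhonemeInventory()


@dataclass
class RawTrial:
    """One trial's multichannel time series plus identity metadata.

    ``samples`` is a (16, n_samples) float array in microvolts, rows in
    :data:`CHANNELS` order.
    """

    participant: int
    session: int
    phoneme_id: int
    trial_index: int
    samples: np.ndarray
    timestamp_ok: bool = True

    def validate(self) -> None:
        if not (1 <= self.session <= 3):
            raise ValidationError(f"session {self.session} not in 1..3")
        if not (1 <= self.phoneme_id <= 44):
            raise ValidationError(f"phoneme_id {self.phoneme_id} not in 1..44")
        if not (1 <= self.trial_index <= 5):
            raise ValidationError(f"trial_index {self.trial_index} not in 1..5")
        if self.participant < 1:
            raise ValidationError("participant id must be >= 1")
        samples = np.asarray(self.samples)
        if samples.ndim != 2 or samples.shape[0] != 16:
            raise ValidationError(
                f"samples must be 16 x time, got shape {samples.shape}"
            )
        if not (MIN_SAMPLES <= samples.shape[1] <= MAX_SAMPLES):
            raise ValidationError(
                f"trial length {samples.shape[1]} outside accepted "
                f"[{MIN_SAMPLES}, {MAX_SAMPLES}]"
            )

    @property
    def n_samples(self) -> int:
        return int(np.asarray(self.samples).shape[1])

    def filename(self) -> str:
        return trial_filename(
            self.participant, self.session, self.phoneme_id, self.trial_index
        )


def trial_filename(
    participant: int, session: int, phoneme_id: int, trial_index: int
) -> str:
    return f"P{participant:02d}_S{session}_PH{phoneme_id:02d}_T{trial_index}.csv"


def parse_trial_filename(name: str) -> dict[str, int]:
    m = _FILENAME_RE.match(name)
    if m is None:
        raise ValidationError(f"filename {name!r} does not match trial naming rule")
    return {
        "participant": int(m.group("participant")),
        "session": int(m.group("session")),
        "phoneme_id": int(m.group("phoneme")),
        "trial_index": int(m.group("trial")),
    }


def write_trial(trial: RawTrial, directory: str | Path) -> Path:
    """Write one trial as a CSV file; returns the written path.

    The header row carries channel labels; each subsequent row is one sample
    across channels, in microvolts.  Full float repr is written so a
    write/read round trip is exact.
    """
    trial.validate()
    directory = Path(directory)
    path = directory / trial.filename()
    frame = pd.DataFrame(np.asarray(trial.samples, dtype=float).T, columns=CHANNELS)
    # 17 significant digits: float64 values survive the text round trip exactly
    frame.to_csv(path, index=False, float_format="%.17g")
    if not trial.timestamp_ok:
        path.with_suffix(".failed").touch()
    return path


def read_trial(path: str | Path) -> RawTrial:
    """Read one trial CSV, re-ordering columns to montage order if needed."""
    path = Path(path)
    meta = parse_trial_filename(path.name)
    frame = pd.read_csv(path, float_precision="round_trip")
    if set(frame.columns) != set(CHANNELS):
        raise ValidationError(
            f"{path.name}: header must contain exactly the 16 montage labels"
        )
    frame = frame[list(CHANNELS)]
    samples = frame.to_numpy(dtype=float).T
    trial = RawTrial(
        participant=meta["participant"],
        session=meta["session"],
        phoneme_id=meta["phoneme_id"],
        trial_index=meta["trial_index"],
        samples=samples,
        timestamp_ok=not path.with_suffix(".failed").exists(),
    )
    trial.validate()
    return trial


@dataclass
class TrialRecord:
    """Manifest entry: one scanned trial file and its retention outcome."""

    path: Path
    participant: int
    session: int
    phoneme_id: int
    trial_index: int
    n_samples: int
    retained: bool
    reason: str = ""


@dataclass
class DatasetManifest:
    """All scanned trial files with retention decisions.

    ``trials`` lists only retained trials (timestamped, valid length, and the
    participant passed the >=2-trials-per-phoneme rule); ``records`` keeps
    every scanned file with its reason for exclusion.
    """

    records: list[TrialRecord] = field(default_factory=list)

    @property
    def trials(self) -> list[TrialRecord]:
        return [r for r in self.records if r.retained]

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def participants(self) -> list[int]:
        return sorted({r.participant for r in self.trials})

    def counts_by_phoneme(self) -> pd.DataFrame:
        """Per-participant retained-trial counts by phoneme."""
        rows = [(r.participant, r.phoneme_id) for r in self.trials]
        frame = pd.DataFrame(rows, columns=["participant", "phoneme_id"])
        return frame.groupby(["participant", "phoneme_id"]).size().rename("n_trials").reset_index()

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "path": str(r.path),
                    "participant": r.participant,
                    "session": r.session,
                    "phoneme": r.phoneme_id,
                    "trial": r.trial_index,
                    "n_samples": r.n_samples,
                    "retained": r.retained,
                    "reason": r.reason,
                }
                for r in self.records
            ]
        )

    def export(self, path: str | Path) -> None:
        self.to_table().to_csv(path, sep="\t", index=False)

    def iter_trials(self) -> Iterable[RawTrial]:
        for record in self.trials:
            yield read_trial(record.path)


def build_manifest(
    directory: str | Path, min_trials_per_phoneme: int = 2
) -> DatasetManifest:
    """Scan a directory of trial files and apply the retention rules.

    Exclusions, each logged with its reason:

    * files that fail to parse (name, header, or values) are skipped;
    * trials whose timestamp failed (``.failed`` sidecar) are excluded;
    * trials with out-of-range length are excluded;
    * participants lacking ``min_trials_per_phoneme`` retained trials for
      every one of the 44 phonemes are excluded entirely.
    """
    directory = Path(directory)
    records: list[TrialRecord] = []
    for path in sorted(directory.glob("*.csv")):
        try:
            meta = parse_trial_filename(path.name)
        except ValidationError:
            logger.warning("skipping %s: unparseable filename", path.name)
            continue
        try:
            trial = read_trial(path)
        except (ValidationError, ValueError, pd.errors.ParserError) as exc:
            logger.warning("excluding %s: %s", path.name, exc)
            records.append(
                TrialRecord(path, meta["participant"], meta["session"],
                            meta["phoneme_id"], meta["trial_index"], 0,
                            retained=False, reason=f"invalid: {exc}")
            )
            continue
        if not trial.timestamp_ok:
            logger.info("excluding %s: timestamp failed", path.name)
            records.append(
                TrialRecord(path, trial.participant, trial.session,
                            trial.phoneme_id, trial.trial_index, trial.n_samples,
                            retained=False, reason="timestamp")
            )
            continue
        records.append(
            TrialRecord(path, trial.participant, trial.session,
                        trial.phoneme_id, trial.trial_index, trial.n_samples,
                        retained=True)
        )

    # Participant-level retention: >=2 timestamped trials for every phoneme.
    counts: dict[int, dict[int, int]] = {}
    for r in records:
        if r.retained:
            counts.setdefault(r.participant, {}).setdefault(r.phoneme_id, 0)
            counts[r.participant][r.phoneme_id] += 1
    dropped = {
        pid
        for pid, by_ph in counts.items()
        if any(by_ph.get(ph, 0) < min_trials_per_phoneme for ph in range(1, 45))
    }
    for r in records:
        if r.retained and r.participant in dropped:
            r.retained = False
            r.reason = "participant-excluded"
    for pid in sorted(dropped):
        logger.info("participant %d excluded: <%d trials for some phoneme",
                    pid, min_trials_per_phoneme)
    return DatasetManifest(records=records)
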