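"""Recording I/O and the standard preprocessing rules for overnight PSG.

Preprocessing order is fixed: relabel (R&K -> AASM) -> trim excess wake ->
epoch extraction.  Relabeling merges N4 into N3 and excludes MOVEMENT and
UNKNOWN epochs; wake trimming drops continuous leading/trailing wake beyond
30 minutes outside the sleep period, leaving interior wake untouched.  No
waveform filtering is applied anywhere.

EDF reading goes through :mod:`mne`; a minimal EDF writer is provided for
exporting synthetic recordings (16-bit EDF, one data record per second), and
the mne reader doubles as its round-trip check.  Epochs are stored in a
versioned ``.npz`` container with per-modality arrays, labels and rates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np

from .signals import STAGES, EpochRecord

__all__ = [
    "HypnogramSequence",
    "RecordEntry",
    "RK_LABELS",
    "read_hypnogram_csv",
    "write_hypnogram_csv",
    "relabel_aasm",
    "trim_wake",
    "harmonize_rates",
    "read_recording",
    "write_edf",
    "extract_epochs",
    "epoch_store_write",
    "epoch_store_read",
    "assign_folds",
]

RK_LABELS = ("W", "N1", "N2", "N3", "N4", "REM", "MOVEMENT", "UNKNOWN")

STORE_VERSION = 1


@dataclass
class HypnogramSequence:
    labels: list[str]
    epoch_duration: float = 30.0

    def __post_init__(self):
        if not self.labels:
            raise ValueError("hypnogram is empty")
        for lab in self.labels:
            if lab not in RK_LABELS:
                raise ValueError(f"unknown hypnogram label {lab!r}")


@dataclass
class RecordEntry:
    """One manifest entry: file paths plus modality -> EDF channel mapping."""

    psg_path: str
    hypnogram_path: str
    channel_map: dict[str, str]
    subject_id: str = ""
    fold: int | None = None


def read_hypnogram_csv(path) -> HypnogramSequence:
    """Two-column CSV ``epoch_index,label`` (header optional)."""
    labels = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.lower().startswith("epoch"):
            continue
        _, lab = line.split(",")
        labels.append(lab.strip())
    return HypnogramSequence(labels)


def write_hypnogram_csv(path, h: HypnogramSequence) -> None:
    lines = ["epoch_index,label"]
    lines += [f"{i},{lab}" for i, lab in enumerate(h.labels)]
    Path(path).write_text("\n".join(lines) + "\n")


def relabel_aasm(h: HypnogramSequence) -> tuple[HypnogramSequence, np.ndarray]:
    """Merge N4 into N3; flag MOVEMENT/UNKNOWN for exclusion."""
    out, keep = [], []
    for lab in h.labels:
        if lab == "N4":
            out.append("N3")
            keep.append(True)
        elif lab in ("MOVEMENT", "UNKNOWN"):
            out.append(lab)
            keep.append(False)
        else:
            out.append(lab)
            keep.append(True)
    return (
        HypnogramSequence(out, h.epoch_duration),
        np.array(keep, dtype=bool),
    )


def trim_wake(h: HypnogramSequence, max_lead_min: float = 30.0) -> np.ndarray:
    """Keep-mask truncating leading/trailing continuous wake to 30 minutes.

    Only wake outside the sleep period (before the first / after the last
    non-W epoch) is trimmed; interior wake bouts are untouched.  An all-wake
    record keeps its final 30-minute run, with a warning.
    """
    if (max_lead_min * 60) % h.epoch_duration != 0:
        raise ValueError("epoch duration must divide the wake allowance")
    limit = int(max_lead_min * 60 / h.epoch_duration)
    labels = h.labels
    n = len(labels)
    keep = np.ones(n, dtype=bool)
    non_wake = [i for i, lab in enumerate(labels) if lab != "W"]
    if not non_wake:
        warnings.warn("all-wake record: keeping only the final 30-minute run")
        keep[: max(0, n - limit)] = False
        return keep
    first, last = non_wake[0], non_wake[-1]
    if first > limit:
        keep[: first - limit] = False
    trailing = n - 1 - last
    if trailing > limit:
        keep[last + limit + 1:] = False
    return keep


def harmonize_rates(waveforms: dict[str, tuple[np.ndarray, float]],
                    target_rate: float) -> dict[str, np.ndarray]:
    """Polyphase-resample every modality to one common rate."""
    from scipy.signal import resample_poly

    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    out = {}
    for mod, (wav, rate) in waveforms.items():
        if rate == target_rate:
            out[mod] = np.asarray(wav, dtype=float)
            continue
        frac = Fraction(target_rate / rate).limit_denominator(1000)
        out[mod] = resample_poly(np.asarray(wav, dtype=float),
                                 frac.numerator, frac.denominator)
    return out


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def read_recording(edf_path, entry: RecordEntry):
    """Read the mapped channels of an EDF recording via mne.

    Returns ``{modality: (waveform, sampling_rate)}`` plus the raw info
    object (header metadata).  Amplitudes follow mne's convention (SI units:
    a channel recorded in microvolts comes back in volts).
    """
    import mne

    raw = mne.io.read_raw_edf(str(edf_path), preload=True, verbose="error")
    available = list(raw.ch_names)
    out = {}
    for mod, ch in entry.channel_map.items():
        if ch not in available:
            raise ValueError(
                f"channel {ch!r} for modality {mod} not in EDF; "
                f"available: {available}"
            )
        idx = available.index(ch)
        data = raw.get_data(picks=[idx])[0]
        out[mod] = (data, float(raw.info["sfreq"]))
    return out, raw.info


def _pad_ascii(s: str, width: int) -> bytes:
    b = s.encode("ascii")[:width]
    return b + b" " * (width - len(b))


def write_edf(path, signals: dict[str, tuple[np.ndarray, float]],
              patient: str = "X", recording: str = "synthetic") -> None:
    """Write a minimal EDF file (16-bit, one data record per second).

    Sampling rates must be positive integers and all signals must span the
    same whole number of seconds.
    """
    names = list(signals)
    rates = []
    durations = set()
    for mod in names:
        wav, fs = signals[mod]
        if fs <= 0 or fs != int(fs):
            raise ValueError(f"{mod}: sampling rate must be a positive integer")
        if len(wav) % int(fs) != 0:
            raise ValueError(f"{mod}: length not a whole number of seconds")
        rates.append(int(fs))
        durations.add(len(wav) // int(fs))
    if len(durations) != 1:
        raise ValueError("signals span different durations")
    n_records = durations.pop()
    ns = len(names)
    header_bytes = 256 + 256 * ns

    phys = {}
    for mod in names:
        wav = np.asarray(signals[mod][0], dtype=float)
        lo, hi = float(wav.min()), float(wav.max())
        if lo == hi:
            lo, hi = lo - 1.0, hi + 1.0
        phys[mod] = (lo, hi)

    with open(path, "wb") as f:
        f.write(_pad_ascii("0", 8))
        f.write(_pad_ascii(patient, 80))
        f.write(_pad_ascii(recording, 80))
        f.write(_pad_ascii("01.01.00", 8))
        f.write(_pad_ascii("00.00.00", 8))
        f.write(_pad_ascii(str(header_bytes), 8))
        f.write(_pad_ascii("", 44))
        f.write(_pad_ascii(str(n_records), 8))
        f.write(_pad_ascii("1", 8))
        f.write(_pad_ascii(str(ns), 4))
        for field_fn, width in (
            (lambda m: m, 16),                      # label
            (lambda m: "", 80),                     # transducer
            (lambda m: "uV", 8),                    # physical dimension
            (lambda m: f"{phys[m][0]:.6g}", 8),
            (lambda m: f"{phys[m][1]:.6g}", 8),
            (lambda m: "-32768", 8),
            (lambda m: "32767", 8),
            (lambda m: "", 80),                     # prefiltering
            (lambda m: str(int(signals[m][1])), 8),  # samples per record
            (lambda m: "", 32),
        ):
            for mod in names:
                f.write(_pad_ascii(field_fn(mod), width))
        # digitise
        digital = {}
        for mod in names:
            wav = np.asarray(signals[mod][0], dtype=float)
            lo, hi = phys[mod]
            scaled = (wav - lo) / (hi - lo) * 65535.0 - 32768.0
            digital[mod] = np.clip(np.round(scaled), -32768, 32767).astype("<i2")
        for rec in range(n_records):
            for mod, fs in zip(names, rates):
                chunk = digital[mod][rec * fs:(rec + 1) * fs]
                f.write(chunk.tobytes())


# ---------------------------------------------------------------------------
# epoching and the epoch store
# ---------------------------------------------------------------------------

def extract_epochs(waveforms: dict[str, np.ndarray], rate: float,
                   h: HypnogramSequence, keep: np.ndarray,
                   subject_id: str = "") -> list[EpochRecord]:
    """Cut kept 30-s epochs from hypnogram boundaries (0-based, half-open)."""
    spe = int(round(h.epoch_duration * rate))
    records = []
    for i, (lab, k) in enumerate(zip(h.labels, keep)):
        if not k:
            continue
        if lab not in STAGES:
            raise ValueError(f"epoch {i}: label {lab!r} not AASM (relabel first)")
        sig = {}
        for mod, wav in waveforms.items():
            seg = wav[i * spe:(i + 1) * spe]
            if len(seg) < spe:
                break  # recording ends mid-epoch; drop the partial epoch
            sig[mod] = np.asarray(seg, dtype=float)
        else:
            records.append(
                EpochRecord(
                    signals=sig,
                    sampling_rates={m: rate for m in waveforms},
                    duration=h.epoch_duration,
                    label=lab,
                    difficulty_tier="eeg_separable",
                    subject_id=subject_id,
                )
            )
    return records


def epoch_store_write(path, records: list[EpochRecord]) -> None:
    """Versioned npz container: per-modality arrays + labels + metadata."""
    if not records:
        raise ValueError("no records to write")
    mods = list(records[0].signals)
    arrays = {
        f"signal_{m}": np.stack([r.signals[m] for r in records]) for m in mods
    }
    np.savez(
        path,
        version=np.array(STORE_VERSION),
        modalities=np.array(mods),
        labels=np.array([r.label for r in records]),
        tiers=np.array([r.difficulty_tier for r in records]),
        subjects=np.array([r.subject_id for r in records]),
        rates=np.array([records[0].sampling_rates[m] for m in mods]),
        duration=np.array(records[0].duration),
        **arrays,
    )


def epoch_store_read(path) -> list[EpochRecord]:
    try:
        z = np.load(path, allow_pickle=False)
    except Exception as e:
        raise ValueError(f"unreadable epoch store {path}: {e}") from e
    with z:
        if "version" not in z.files or int(z["version"]) != STORE_VERSION:
            raise ValueError(
                f"epoch store version mismatch (expected {STORE_VERSION})"
            )
        mods = [str(m) for m in z["modalities"]]
        rates = {m: float(r) for m, r in zip(mods, z["rates"])}
        duration = float(z["duration"])
        signals = {m: z[f"signal_{m}"] for m in mods}
        labels = [str(x) for x in z["labels"]]
        tiers = [str(x) for x in z["tiers"]]
        subjects = [str(x) for x in z["subjects"]]
    return [
        EpochRecord(
            signals={m: signals[m][i] for m in mods},
            sampling_rates=rates,
            duration=duration,
            label=labels[i],
            difficulty_tier=tiers[i],
            subject_id=subjects[i],
        )
        for i in range(len(labels))
    ]


def assign_folds(entries: list[RecordEntry], k: int = 10,
                 subject_wise: bool = True, seed: int = 0) -> list[RecordEntry]:
    """Assign k-fold split indices; subject-wise by default (no subject in
    both train and test)."""
    rng = np.random.default_rng(seed)
    if subject_wise:
        subjects = sorted({e.subject_id for e in entries})
        order = rng.permutation(len(subjects))
        fold_of = {subjects[i]: int(order[i] % k) for i in range(len(subjects))}
        for e in entries:
            e.fold = fold_of[e.subject_id]
    else:
        order = rng.permutation(len(entries))
        for i, e in enumerate(entries):
            e.fold = int(order[i] % k)
    return entries
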