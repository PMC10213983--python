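"""Synthetic polysomnography epochs with stage-specific spectral structure.

Real overnight PSG is scored in 30-s epochs into the five AASM stages
(W, N1, N2, N3, REM), and each stage has a characteristic electrophysiology:
slow delta (0.5-4 Hz) waves dominate N3, alpha (8-13 Hz) marks relaxed
wakefulness, theta (4-8 Hz) marks N1/REM, eye movements (EOG) are frequent
in W and REM, and chin muscle tone (EMG) is high in W and nearly absent in
REM.  The generator here reproduces exactly that *statistical* structure —
band-limited sinusoids with stage-specific weights, EOG deflection events at
stage-specific rates, EMG activity bursts at rates tied to muscle tone —
without attempting physiological realism (no spindles, K-complexes or
artifacts).

A second axis, the *difficulty tier*, controls which modalities carry the
discriminative information.  This emulates the empirical premise of
multi-exit sleep staging: most epochs are classifiable from EEG alone, while
a minority need EOG or EMG.

- ``eeg_separable``: every modality is drawn from the true stage template.
- ``eog_required``: the EEG spectrum is the average of the true stage and its
  confusable partner (W<->N1, N2<->N3, REM->N1), so EEG alone cannot resolve
  the pair; EOG (and EMG) keep the true stage's parameters.
- ``emg_required``: the EEG spectrum is the all-stage average and the EOG
  event rate is the all-stage average, so only the EMG burst rate identifies
  the stage.

All randomness flows from explicit integer seeds; identical arguments give
bit-identical epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "STAGES",
    "BANDS",
    "TIERS",
    "CONFUSABLE_PARTNER",
    "StageTemplate",
    "EpochRecord",
    "SyntheticDatasetConfig",
    "stage_template",
    "synthesize_epoch",
    "synthesize_dataset",
    "apportion",
    "band_power_fraction",
]

STAGES = ("W", "N1", "N2", "N3", "REM")

#: frequency bands (Hz) used by the stage templates
BANDS = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}

TIERS = ("eeg_separable", "eog_required", "emg_required")

#: stage pairs whose EEG spectra are blended in the harder tiers
CONFUSABLE_PARTNER = {"W": "N1", "N1": "W", "N2": "N3", "N3": "N2", "REM": "N1"}


@dataclass(frozen=True)
class StageTemplate:
    """Spectral/behavioural signature of one AASM stage.

    ``band_weights`` are relative oscillation amplitudes per band (unitless),
    ``eog_event_rate`` is expected EOG deflections per 30-s epoch, and
    ``emg_tone`` is relative muscle tone in [0, 1] which sets the EMG
    activity-burst rate.
    """

    stage: str
    band_weights: dict[str, float]
    eog_event_rate: float
    emg_tone: float

    def __post_init__(self):
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage label {self.stage!r}")
        if sum(self.band_weights.values()) <= 0:
            raise ValueError("band weights must have positive sum")
        if self.eog_event_rate < 0 or self.emg_tone < 0:
            raise ValueError("rates must be nonnegative")


_TEMPLATES = {
    # delta dominates N3 (strict max); alpha > delta in wake; theta marks
    # N1/REM.  EOG: frequent blinks in W, rapid eye movements in REM.
    # EMG: tone highest in W, atonia in REM.
    "W": StageTemplate("W", {"delta": 0.10, "theta": 0.15, "alpha": 0.50, "beta": 0.25}, 10.0, 1.00),
    "N1": StageTemplate("N1", {"delta": 0.20, "theta": 0.50, "alpha": 0.20, "beta": 0.10}, 3.0, 0.55),
    "N2": StageTemplate("N2", {"delta": 0.35, "theta": 0.40, "alpha": 0.15, "beta": 0.10}, 1.5, 0.35),
    "N3": StageTemplate("N3", {"delta": 0.65, "theta": 0.20, "alpha": 0.10, "beta": 0.05}, 0.2, 0.15),
    "REM": StageTemplate("REM", {"delta": 0.25, "theta": 0.40, "alpha": 0.20, "beta": 0.15}, 8.0, 0.03),
}


def stage_template(stage: str) -> StageTemplate:
    """Return the fixed template for an AASM stage (deterministic)."""
    try:
        return _TEMPLATES[stage]
    except KeyError:
        raise ValueError(f"unknown stage label {stage!r}") from None


@dataclass
class EpochRecord:
    """One labeled 30-s multimodal sample."""

    signals: dict[str, np.ndarray]
    sampling_rates: dict[str, float]
    duration: float
    label: str
    difficulty_tier: str
    subject_id: str = "synthetic"

    def __post_init__(self):
        if self.label not in STAGES:
            raise ValueError(f"label {self.label!r} not an AASM class")
        for mod, wav in self.signals.items():
            expect = int(round(self.duration * self.sampling_rates[mod]))
            if len(wav) != expect:
                raise ValueError(
                    f"{mod}: waveform length {len(wav)} != "
                    f"duration x rate = {expect}"
                )


# Table-1-style stage proportions of the 20-subject Sleep-EDF cohort
SLEEP_EDF_20_PROPORTIONS = (0.193, 0.069, 0.414, 0.142, 0.182)


@dataclass
class SyntheticDatasetConfig:
    n_epochs: int = 1000
    class_proportions: tuple[float, ...] = SLEEP_EDF_20_PROPORTIONS
    tier_proportions: tuple[float, ...] = (0.5, 0.3, 0.2)
    sampling_rates: dict[str, float] = field(
        default_factory=lambda: {"EEG": 100.0, "EOG": 100.0, "EMG": 100.0}
    )
    duration: float = 30.0
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if abs(sum(self.tier_proportions) - 1.0) > 1e-9:
            raise ValueError("tier proportions must sum to 1")
        if any(r <= 0 for r in self.sampling_rates.values()):
            raise ValueError("sampling rates must be positive")


def _effective_template(stage: str, tier: str) -> StageTemplate:
    """Stage template as seen through a difficulty tier (EEG/EOG ambiguity)."""
    t = stage_template(stage)
    if tier == "eeg_separable":
        return t
    if tier == "eog_required":
        partner = stage_template(CONFUSABLE_PARTNER[stage])
        bw = {b: 0.5 * (t.band_weights[b] + partner.band_weights[b]) for b in BANDS}
        return replace(t, band_weights=bw)
    if tier == "emg_required":
        bw = {
            b: float(np.mean([_TEMPLATES[s].band_weights[b] for s in STAGES]))
            for b in BANDS
        }
        rate = float(np.mean([_TEMPLATES[s].eog_event_rate for s in STAGES]))
        return replace(t, band_weights=bw, eog_event_rate=rate)
    raise ValueError(f"unknown difficulty tier {tier!r}")


_OSC_PER_BAND = 3  # a band is broadband: several oscillators, not a pure tone


def _band_oscillations(rng, weights: dict[str, float], t: np.ndarray) -> np.ndarray:
    out = np.zeros_like(t)
    scale = 1.0 / np.sqrt(_OSC_PER_BAND)  # keep band power ~ weight^2
    for band, w in weights.items():
        lo, hi = BANDS[band]
        for _ in range(_OSC_PER_BAND):
            f = rng.uniform(lo, hi)
            phase = rng.uniform(0, 2 * np.pi)
            out += w * scale * np.sin(2 * np.pi * f * t + phase)
    return out


def _event_train(rng, n_samples: int, rate: float, width_s: float,
                 amp: float, fs: float) -> np.ndarray:
    """Sum of half-sine deflections at ``rate`` expected events per epoch."""
    out = np.zeros(n_samples)
    n_events = rng.poisson(rate)
    width = max(2, int(round(width_s * fs)))
    pulse = amp * np.sin(np.pi * np.arange(width) / width)
    for _ in range(n_events):
        start = rng.integers(0, max(1, n_samples - width))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        out[start:start + width] += sign * pulse
    return out


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


def synthesize_epoch(
    stage: str,
    tier: str,
    config: SyntheticDatasetConfig,
    seed: int,
    subject_id: str = "synthetic",
) -> EpochRecord:
    """Generate one 30-s multimodal epoch; bit-identical under identical args."""
    eff = _effective_template(stage, tier)
    true = stage_template(stage)
    rng = np.random.default_rng(seed)
    signals: dict[str, np.ndarray] = {}
    for mod, fs in config.sampling_rates.items():
        n = int(round(config.duration * fs))
        t = np.arange(n) / fs
        if mod == "EEG":
            wav = _band_oscillations(rng, eff.band_weights, t)
        elif mod == "EOG":
            # slow (~0.7 s) large deflections; rate distinguishes stages
            wav = 0.15 * _band_oscillations(rng, eff.band_weights, t)
            wav += _event_train(rng, n, eff.eog_event_rate, 0.7, 3.0, fs)
        elif mod == "EMG":
            # muscle tone encoded as activity-burst *rate* so the cue
            # survives per-channel amplitude normalisation
            wav = 0.2 * rng.standard_normal(n)
            burst = _event_train(rng, n, true.emg_tone * 15.0, 0.25, 1.0, fs)
            wav += burst * rng.standard_normal(n)
        else:
            wav = _band_oscillations(rng, eff.band_weights, t)
        wav = wav + config.noise_sd * rng.standard_normal(n)
        signals[mod] = _zscore(wav)
    return EpochRecord(
        signals=signals,
        sampling_rates=dict(config.sampling_rates),
        duration=config.duration,
        label=stage,
        difficulty_tier=tier,
        subject_id=subject_id,
    )


def apportion(n: int, proportions) -> list[int]:
    """Largest-remainder apportionment of ``n`` items to the proportions."""
    quotas = np.asarray(proportions, dtype=float) * n
    counts = np.floor(quotas).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(quotas - counts), kind="stable")
    for i in range(remainder):
        counts[order[i]] += 1
    return counts.tolist()


def synthesize_dataset(config: SyntheticDatasetConfig) -> list[EpochRecord]:
    """Generate a shuffled labeled dataset matching the configured mix."""
    active = sum(1 for p in config.class_proportions if p > 0)
    if config.n_epochs < active:
        raise ValueError(
            f"n_epochs={config.n_epochs} < {active} classes with nonzero proportion"
        )
    rng = np.random.default_rng(config.seed)
    class_counts = apportion(config.n_epochs, config.class_proportions)
    tier_counts = apportion(config.n_epochs, config.tier_proportions)
    labels = [s for s, c in zip(STAGES, class_counts) for _ in range(c)]
    tiers = [t for t, c in zip(TIERS, tier_counts) for _ in range(c)]
    rng.shuffle(tiers)  # tiers independent of class
    order = rng.permutation(config.n_epochs)
    records = []
    for i in order:
        seed = int(rng.integers(0, 2**31 - 1))
        records.append(
            synthesize_epoch(
                labels[i], tiers[i], config, seed,
                subject_id=f"synth-{i % 8:02d}",
            )
        )
    return records


def band_power_fraction(wav: np.ndarray, fs: float, band: tuple[float, float]) -> float:
    """Fraction of total periodogram power inside ``band`` (scipy-based)."""
    from scipy.signal import periodogram

    f, pxx = periodogram(wav, fs=fs)
    total = pxx.sum()
    if total == 0:
        return 0.0
    lo, hi = band
    return float(pxx[(f >= lo) & (f <= hi)].sum() / total)
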