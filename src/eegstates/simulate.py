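"""Synthetic multi-channel EEG with controlled spectral structure.

The generator provides ground truth for every downstream stage of the
pipeline.  Each cognitive state is a :class:`StateProfile`: a set of
relative band weights (Theta/Alpha/L-Beta/H-Beta/Gamma), a 1/f^β background
exponent and a broadband-noise scale.  Per channel, the signal is a sum of
random-phase band-limited Gaussian oscillations (independent complex
spectral coefficients, so band bins fill realistically rather than as pure
tones), a pink 1/f^β background and white noise.

The six bundled profiles emulate the study conditions: meditation (MED) is
narrowly alpha-dominant with a regional alpha boost over occipital/parietal
sites and the largest overall amplitude (high total power); video watching
(VDO) is the broadest low-amplitude mixture; the remaining four task states
interpolate so that expected spectral spread ranks
MED < SENT < {WORDS, MM} < IMG < VDO.

Cohorts follow the study design: 11 meditators and 9 non-meditators, each
measured in all six modalities, with meditators carrying a multiplicative
group effect (stronger alpha, less broadband noise).  Sub-seeds derive from
the master seed through ``SeedSequence((seed, participant_idx, modality_idx))``
so any single recording is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .layout import SensorLayout, default_layout
from .preprocess import MODALITIES, Event, Recording

__all__ = [
    "StateProfile",
    "ExperimentSchedule",
    "CohortSpec",
    "state_profile",
    "experiment_schedule",
    "mm_digit_reduce",
    "simulate_recording",
    "simulate_cohort",
]

_BAND_EDGES = {
    "Theta": (4.0, 8.0),
    "Alpha": (8.0, 13.0),
    "L-Beta": (13.0, 20.0),
    "H-Beta": (20.0, 30.0),
    "Gamma": (30.0, 48.0),
}


@dataclass(frozen=True)
class StateProfile:
    """Spectral recipe of one cognitive state."""

    name: str
    band_weights: dict[str, float]
    one_over_f_exponent: float = 1.0
    noise_scale: float = 0.5
    amplitude: float = 1.0
    region_modulation: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = self.band_weights
        if any(v < 0 for v in w.values()) or not any(v > 0 for v in w.values()):
            raise ValueError("band weights must be non-negative, not all zero")
        if not 0 <= self.one_over_f_exponent <= 2:
            raise ValueError("1/f exponent must lie in [0, 2]")


# Frozen study-condition profiles.  Amplitudes decrease with engagement so
# total power is highest in MED; band mixtures broaden in the same order.
_PROFILES: dict[str, StateProfile] = {
    "MED": StateProfile(
        "MED",
        {"Theta": 0.5, "Alpha": 3.0, "L-Beta": 0.3, "H-Beta": 0.2, "Gamma": 0.1},
        noise_scale=0.30,
        amplitude=1.6,
        region_modulation={"occipital": 1.5, "parietal": 1.3},
    ),
    "SENT": StateProfile(
        "SENT",
        {"Theta": 0.8, "Alpha": 2.0, "L-Beta": 0.6, "H-Beta": 0.4, "Gamma": 0.25},
        noise_scale=0.45,
        amplitude=1.3,
    ),
    "WORDS": StateProfile(
        "WORDS",
        {"Theta": 0.9, "Alpha": 1.6, "L-Beta": 0.8, "H-Beta": 0.6, "Gamma": 0.4},
        noise_scale=0.50,
        amplitude=1.15,
    ),
    "MM": StateProfile(
        "MM",
        {"Theta": 1.0, "Alpha": 1.5, "L-Beta": 0.9, "H-Beta": 0.7, "Gamma": 0.45},
        noise_scale=0.50,
        amplitude=1.1,
    ),
    "IMG": StateProfile(
        "IMG",
        {"Theta": 1.0, "Alpha": 1.2, "L-Beta": 1.0, "H-Beta": 0.9, "Gamma": 0.6},
        noise_scale=0.55,
        amplitude=0.95,
    ),
    "VDO": StateProfile(
        "VDO",
        {"Theta": 1.0, "Alpha": 1.0, "L-Beta": 1.0, "H-Beta": 0.95, "Gamma": 0.8},
        noise_scale=0.60,
        amplitude=0.85,
    ),
}


def state_profile(name: str) -> StateProfile:
    """The frozen spectral profile of one of the six modalities."""
    try:
        return _PROFILES[name]
    except KeyError:
        raise ValueError(f"unknown state {name!r}; expected one of {MODALITIES}") from None


@dataclass(frozen=True)
class ExperimentSchedule:
    """Stimulus schedule of one modality: duration plus trial list."""

    modality: str
    duration_ms: float
    trials: tuple[tuple[str, float, object], ...]  # (descriptor, onset_ms, expected)

    def __post_init__(self) -> None:
        onsets = [t[1] for t in self.trials]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("trial onsets must be strictly increasing")
        if any(not 0 <= t < self.duration_ms for t in onsets):
            raise ValueError("trial onset outside experiment duration")


def mm_digit_reduce(a: int, b: int) -> int:
    """Digit-sum reduction of a product to a single digit (digital root).

    E.g. 7 x 7 = 49 -> 4 + 9 = 13 -> 1 + 3 = 4.
    """
    if a < 1 or b < 1:
        raise ValueError("operands must be positive integers")
    n = a * b
    while n >= 10:
        n = sum(int(d) for d in str(n))
    return n


# per-trial presentation slots (stimulus + response window), ms
_TRIAL_SLOT_MS = {"WORDS": 5000.0, "IMG": 10000.0, "MM": 8000.0, "SENT": 6000.0}


def experiment_schedule(modality: str) -> ExperimentSchedule:
    """Protocol schedule for one modality.

    Trial counts follow the study protocol: 20 scrambled words, 12 ambiguous
    images, 28 mental-arithmetic items, 20 sentences; meditation runs 7 min
    and the video about 2 min, both without discrete trials.
    """
    if modality == "MED":
        return ExperimentSchedule("MED", 420_000.0, ())
    if modality == "VDO":
        return ExperimentSchedule("VDO", 120_000.0, ())
    if modality == "WORDS":
        trials = tuple(
            (f"word_{i + 1:02d}", i * _TRIAL_SLOT_MS["WORDS"],
             "value" if i % 2 == 0 else "object")
            for i in range(20)
        )
        return ExperimentSchedule("WORDS", 20 * _TRIAL_SLOT_MS["WORDS"], trials)
    if modality == "IMG":
        trials = tuple(
            (f"image_{i + 1:02d}", i * _TRIAL_SLOT_MS["IMG"], (i % 3) + 1)
            for i in range(12)
        )
        return ExperimentSchedule("IMG", 12 * _TRIAL_SLOT_MS["IMG"], trials)
    if modality == "MM":
        # deterministic operand cycle; expected response is the digital root
        trials = []
        for i in range(28):
            a, b = (i % 9) + 1, ((i * 3) % 9) + 1
            trials.append(
                (f"{a}x{b}", i * _TRIAL_SLOT_MS["MM"], mm_digit_reduce(a, b))
            )
        return ExperimentSchedule("MM", 28 * _TRIAL_SLOT_MS["MM"], tuple(trials))
    if modality == "SENT":
        kinds = ("meaningless", "meaningful", "pleasant")
        trials = tuple(
            (f"sentence_{i + 1:02d}", i * _TRIAL_SLOT_MS["SENT"], kinds[i % 3])
            for i in range(20)
        )
        return ExperimentSchedule("SENT", 20 * _TRIAL_SLOT_MS["SENT"], trials)
    raise ValueError(f"unknown modality {modality!r}")


# ---------------------------------------------------------------------------
# signal synthesis


def _complex_gauss(rng: np.random.Generator, shape) -> np.ndarray:
    """Unit-variance circular complex Gaussians (random phase)."""
    return (rng.standard_normal(shape) + 1j * rng.standard_normal(shape)) / np.sqrt(2.0)


def _synthesize(
    rng: np.random.Generator,
    n_ch: int,
    n: int,
    fs: float,
    band_gains: dict[str, np.ndarray],
    beta: float,
    pink_scale: float,
) -> np.ndarray:
    """Sum of random-phase band-limited oscillations plus 1/f^beta background.

    Components are drawn directly in the frequency domain (independent
    complex-Gaussian coefficients per bin) and returned through a single
    inverse FFT.  Each component's coefficients are scaled so its expected
    RMS equals its gain; disjoint bands are therefore independent processes.
    """
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec = np.zeros((n_ch, freqs.size), dtype=complex)
    for band, gain in band_gains.items():
        lo, hi = _BAND_EDGES[band]
        bins = np.nonzero((freqs >= lo) & (freqs < hi))[0]
        if bins.size == 0:
            continue
        # |Z|^2 summed over m bins -> RMS^2 = 2 m sigma^2 / n^2 (Parseval)
        sigma = n / np.sqrt(2.0 * bins.size)
        z = _complex_gauss(rng, (n_ch, bins.size))
        spec[:, bins] += np.asarray(gain).reshape(-1, 1) * sigma * z
    if pink_scale > 0:
        shaping = np.zeros_like(freqs)
        shaping[1:] = freqs[1:] ** (-beta / 2.0)
        sigma = n / np.sqrt(2.0 * (shaping**2).sum())
        z = _complex_gauss(rng, (n_ch, freqs.size))
        spec += pink_scale * sigma * shaping * z
    return np.fft.irfft(spec, n=n, axis=-1)


def simulate_recording(
    profile: StateProfile,
    layout: SensorLayout | None = None,
    duration_ms: float = 60_000.0,
    fs: float = 1000.0,
    seed: int | np.random.SeedSequence = 0,
    participant_id: str = "",
    group: str = "",
    events: tuple[Event, ...] = (),
) -> Recording:
    """Generate one multi-channel recording for a state profile.

    Per channel the signal (in arbitrary microvolt-scale units) is
    ``amplitude * Σ_b w_b(ch) * bandnoise_b + noise_scale * (pink + 0.5 white)``
    where the alpha weight of channels in a boosted region is multiplied by
    the profile's region modulation.  Deterministic given ``seed``.
    """
    if duration_ms < 1000:
        raise ValueError("duration must be at least 1000 ms")
    layout = layout or default_layout()
    n_ch = layout.n_channels
    n = int(round(duration_ms * fs / 1000.0))
    rng = np.random.default_rng(seed)

    # per-channel alpha modulation from scalp region
    alpha_gain = np.ones(n_ch)
    if profile.region_modulation:
        for idx, ch in enumerate(layout.channels):
            mult = profile.region_modulation.get(layout.region_of(ch))
            if mult is not None:
                alpha_gain[idx] = mult

    band_gains = {
        band: profile.amplitude
        * weight
        * (alpha_gain if band == "Alpha" else np.ones(n_ch))
        for band, weight in profile.band_weights.items()
        if weight > 0
    }
    x = _synthesize(
        rng, n_ch, n, fs, band_gains,
        beta=profile.one_over_f_exponent, pink_scale=profile.noise_scale,
    )
    x += profile.noise_scale * 0.5 * rng.standard_normal((n_ch, n))
    x *= 10.0  # microvolt-ish scale

    return Recording(
        signal=x,
        fs=fs,
        channels=layout.channels,
        events=events,
        participant_id=participant_id,
        modality=profile.name if profile.name in MODALITIES else "",
        group=group,
        meta={"profile": profile.name, "synthetic": True},
    )


@dataclass(frozen=True)
class CohortSpec:
    """Study-design parameters of a simulated cohort."""

    n_meditators: int = 11
    n_nonmeditators: int = 9
    group_effect: float = 1.3  # meditators: alpha x effect, noise / effect
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_meditators < 2 or self.n_nonmeditators < 2:
            raise ValueError("need at least 2 participants per group")


def _apply_group_effect(profile: StateProfile, effect: float) -> StateProfile:
    if effect == 1.0:
        return profile
    weights = dict(profile.band_weights)
    weights["Alpha"] = weights.get("Alpha", 0.0) * effect
    return replace(profile, band_weights=weights,
                   noise_scale=profile.noise_scale / effect)


def simulate_cohort(
    spec: CohortSpec,
    layout: SensorLayout | None = None,
    modalities: tuple[str, ...] = MODALITIES,
    duration_ms: float | None = None,
    fs: float = 1000.0,
    profiles: dict[str, StateProfile] | None = None,
) -> tuple[list[Recording], pd.DataFrame]:
    """Simulate a full cohort: every participant in every modality.

    ``duration_ms`` overrides the protocol durations with one common length
    (useful for scaled-down experiments); ``profiles`` overrides the state
    profiles (e.g. identical profiles for a null calibration).  Returns the
    recordings plus a ground-truth manifest frame.
    """
    layout = layout or default_layout()
    profiles = profiles or {m: state_profile(m) for m in modalities}
    participants = [(f"M{i + 1:02d}", "Meditator") for i in range(spec.n_meditators)]
    participants += [(f"N{i + 1:02d}", "Non-Meditator") for i in range(spec.n_nonmeditators)]

    recordings: list[Recording] = []
    manifest_rows = []
    for p_idx, (pid, group) in enumerate(participants):
        for m_idx, modality in enumerate(modalities):
            prof = profiles[modality]
            if group == "Meditator":
                prof = _apply_group_effect(prof, spec.group_effect)
            sched = experiment_schedule(modality)
            if duration_ms is None:
                dur = sched.duration_ms
                events = tuple(Event(desc, onset) for desc, onset, _ in sched.trials)
            else:
                dur = duration_ms
                events = ()
            sub_seed = np.random.SeedSequence((spec.seed, p_idx, m_idx))
            rec = simulate_recording(
                prof, layout, duration_ms=dur, fs=fs, seed=sub_seed,
                participant_id=pid, group=group, events=events,
            )
            rec.modality = modality
            recordings.append(rec)
            manifest_rows.append(
                {
                    "participant": pid,
                    "group": group,
                    "modality": modality,
                    "profile": profiles[modality].name,
                    "duration_ms": dur,
                    "seed": (spec.seed, p_idx, m_idx),
                }
            )
    return recordings, pd.DataFrame(manifest_rows)
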