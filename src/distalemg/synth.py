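"""Seeded synthetic generator for target-muscle and distal ankle EMG.

The generator emulates the statistical structure the estimation method
assumes: six lower-leg muscles drive band-limited stochastic EMG carriers
amplitude-modulated by cyclic activation envelopes (one bump per gait
cycle); the five distal channels around the ankle observe a nonlinearly
saturated, attenuated mixture of those sources plus powerline
interference, low-frequency motion artifact and sensor noise.

Everything is deterministic given (config, seed): the same pair always
reproduces bit-identical arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import signal as sps

from .signals import (
    DISTAL_LABELS,
    MUSCLE_LABELS,
    ParameterError,
    SignalRecord,
)

# Plausible gait-phase offsets (fraction of cycle) and ON-duty fractions
# for L1..L6: dorsiflexor active around heel strike / swing, plantar
# flexors through stance, peroneus through mid/late stance.
DEFAULT_PHASES = (0.60, 0.25, 0.25, 0.30, 0.30, 0.45)
DEFAULT_DUTIES = (0.35, 0.30, 0.30, 0.35, 0.35, 0.40)

# Per-muscle carrier bands (Hz).  Surface-EMG spectra differ between
# muscles (fibre composition, depth) and are reshaped along the
# propagation path; distinct spectral signatures per source are part of
# the structure the estimation method assumes.
DEFAULT_CARRIER_BANDS = (
    (35.0, 450.0),  # tibialis anterior
    (25.0, 350.0),  # gastrocnemius lateral
    (20.0, 300.0),  # gastrocnemius medial
    (20.0, 240.0),  # soleus lateral
    (25.0, 280.0),  # soleus medial
    (45.0, 400.0),  # peroneus
)


@dataclass
class MuscleActivationProfile:
    """Per-muscle activation level over time (arbitrary units, >= 0)."""

    muscle_label: str
    envelope: np.ndarray
    cycle_period: float

    def __post_init__(self) -> None:
        self.envelope = np.asarray(self.envelope, dtype=float)
        if np.any(self.envelope < 0):
            raise ParameterError("activation envelope must be nonnegative")


def _tukey_bump(u: np.ndarray, alpha: float) -> np.ndarray:
    """Tapered-cosine bump on u in [0, 1): flat top, raised-cosine ramps."""
    y = np.ones_like(u)
    half = alpha / 2.0
    lo = u < half
    hi = u > 1.0 - half
    y[lo] = 0.5 * (1.0 - np.cos(np.pi * u[lo] / half))
    y[hi] = 0.5 * (1.0 - np.cos(np.pi * (1.0 - u[hi]) / half))
    return y


def generate_activation_envelopes(
    n_samples: int,
    sampling_rate: float,
    cycle_period: float,
    duty_fractions=DEFAULT_DUTIES,
    *,
    phases=DEFAULT_PHASES,
    peak: float = 1.0,
    baseline: float = 0.05,
    taper: float = 0.5,
    amplitude_jitter: float = 0.0,
    seed: int | None = 0,
) -> list[MuscleActivationProfile]:
    """Periodic smooth activation bumps, one per muscle.

    Each envelope is ``baseline + peak * bump(phase)`` where the bump is a
    tapered cosine (Tukey) of width ``duty_fraction`` of the cycle, placed
    at the muscle's phase offset.  ``amplitude_jitter`` scales each cycle's
    bump by an independent lognormal factor (sigma = jitter), seeded.
    With ``duty_fraction >= 1`` the envelope is constant at
    ``baseline + peak`` (the bump covers the whole cycle).

    One cycle of the noiseless bump integrates to exactly
    ``peak * duty * period * (1 - taper/2) + baseline * period``.
    """
    if n_samples <= 0:
        raise ParameterError("n_samples must be positive")
    if cycle_period <= 0 or sampling_rate <= 0:
        raise ParameterError("cycle_period and sampling_rate must be positive")
    duties = np.broadcast_to(np.asarray(duty_fractions, float), (len(MUSCLE_LABELS),))
    if np.any(duties <= 0):
        raise ParameterError("duty fractions must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(n_samples) / sampling_rate
    n_cycles = int(np.ceil(t[-1] / cycle_period)) + 1
    profiles = []
    for label, duty, phase in zip(MUSCLE_LABELS, duties, phases):
        u = (t / cycle_period - phase) % 1.0
        if duty >= 1.0:
            bump = np.ones_like(u)
        else:
            bump = np.where(u < duty, _tukey_bump(np.minimum(u / duty, 1.0), taper), 0.0)
        if amplitude_jitter > 0:
            gains = np.exp(amplitude_jitter * rng.standard_normal(n_cycles))
            cyc = np.floor(t / cycle_period - phase).astype(int) + 1
            bump = bump * gains[np.clip(cyc, 0, n_cycles - 1)]
        env = baseline + peak * bump
        profiles.append(MuscleActivationProfile(label, env, cycle_period))
    return profiles


def bandlimited_noise(
    n: int, sampling_rate: float, low_hz: float, high_hz: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance Gaussian noise with spectral support confined to a band.

    Built in the frequency domain (white spectrum, out-of-band bins zeroed)
    so the confinement is exact up to the modulation applied afterwards.
    """
    if not (0 < low_hz < high_hz <= sampling_rate / 2):
        raise ParameterError(
            f"carrier band ({low_hz}, {high_hz}) must lie inside (0, Nyquist={sampling_rate / 2}]"
        )
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1.0 / sampling_rate)
    spec[(freqs < low_hz) | (freqs > high_hz)] = 0.0
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def synthesize_target_emg(
    profiles: list[MuscleActivationProfile],
    carrier_band=DEFAULT_CARRIER_BANDS,
    sampling_rate: float = 2000.0,
    *,
    powerline_hz: float = 50.0,
    powerline_amplitude: float = 0.0,
    seed: int | None = 0,
) -> SignalRecord:
    """Amplitude-modulate independent band-limited carriers by the envelopes.

    Each channel is ``envelope * carrier`` (zero-mean), optionally plus a
    small powerline sinusoid so the notch stage has something to remove.
    ``carrier_band`` is either one (low, high) pair shared by all muscles
    or one pair per profile (the default gives each muscle its own band).
    """
    rng = np.random.default_rng(seed)
    n = len(profiles[0].envelope)
    t = np.arange(n) / sampling_rate
    bands = np.asarray(carrier_band, dtype=float)
    if bands.ndim == 1:
        bands = np.tile(bands, (len(profiles), 1))
    if bands.shape != (len(profiles), 2):
        raise ParameterError("carrier_band must be one (low, high) pair or one per muscle")
    rows = []
    for prof, band in zip(profiles, bands):
        carrier = bandlimited_noise(n, sampling_rate, *band, rng)
        chan = prof.envelope * carrier
        if powerline_amplitude > 0:
            chan = chan + powerline_amplitude * np.sin(
                2 * np.pi * powerline_hz * t + rng.uniform(0, 2 * np.pi)
            )
        rows.append(chan)
    return SignalRecord(np.vstack(rows), sampling_rate, [p.muscle_label for p in profiles])


def _default_gain_matrix() -> np.ndarray:
    # rows A1..A5, cols L1..L6; dominant paths reflect electrode geometry
    # (A1 at the tibialis anterior tendon, A3/A4 flanking the Achilles
    # tendon near gastrocnemius/soleus, A2/A5 intermediate).
    return np.array(
        [
            [0.90, 0.10, 0.10, 0.10, 0.10, 0.30],
            [0.40, 0.30, 0.10, 0.30, 0.10, 0.70],
            [0.10, 0.80, 0.30, 0.60, 0.20, 0.30],
            [0.10, 0.30, 0.80, 0.20, 0.60, 0.10],
            [0.50, 0.10, 0.30, 0.10, 0.40, 0.40],
        ]
    )


@dataclass
class MixingModel:
    """How six muscle sources appear in five ankle channels.

    ``gains[j, i]`` scales muscle i in channel j.  Each propagation path
    applies a first-order low-pass (cutoff ``attenuation_hz[j, i]``,
    ``inf`` disables it) emulating the spectral shaping of tissue
    propagation; the channel sum then passes through a saturating
    nonlinearity ``s * tanh(x / s)`` (identity when ``saturation`` is
    ``inf``), and powerline, sub-20 Hz motion artifact and white sensor
    noise are added.
    """

    gains: np.ndarray = field(default_factory=_default_gain_matrix)
    attenuation_hz: np.ndarray | None = None
    saturation: float = 2.0
    powerline_hz: float = 50.0
    powerline_amplitude: float = 0.05
    motion_amplitude: float = 0.10
    noise_std: float = 0.05

    def __post_init__(self) -> None:
        self.gains = np.asarray(self.gains, dtype=float)
        if np.any(self.gains < 0):
            raise ParameterError("mixing gains must be nonnegative")
        if self.attenuation_hz is None:
            # stronger path = shorter distance = milder low-pass
            self.attenuation_hz = 120.0 + 300.0 * self.gains
        self.attenuation_hz = np.asarray(self.attenuation_hz, dtype=float)
        if self.attenuation_hz.shape != self.gains.shape:
            raise ParameterError("attenuation_hz shape must match gains")

    def nonlinearity(self, x: np.ndarray) -> np.ndarray:
        s = self.saturation
        if not np.isfinite(s):
            return x
        return s * np.tanh(x / s)


def _attenuate(x: np.ndarray, cutoff_hz: float, sampling_rate: float) -> np.ndarray:
    """Single-pole low-pass along a propagation path (causal)."""
    if not np.isfinite(cutoff_hz):
        return x
    b, a = sps.butter(1, cutoff_hz, btype="low", fs=sampling_rate)
    return sps.lfilter(b, a, x)


def synthesize_distal_channels(
    target: SignalRecord, mixing: MixingModel, seed: int | None = 0
) -> SignalRecord:
    """Mix target-muscle EMGs into the five distal ankle channels."""
    if mixing.gains.shape != (len(DISTAL_LABELS), target.n_channels):
        raise ParameterError(
            f"gain matrix {mixing.gains.shape} does not match "
            f"({len(DISTAL_LABELS)}, {target.n_channels})"
        )
    rng = np.random.default_rng(seed)
    n = target.n_samples
    fs = target.sampling_rate
    t = np.arange(n) / fs
    rows = []
    for j in range(len(DISTAL_LABELS)):
        mixed = np.zeros(n)
        for i in range(target.n_channels):
            g = mixing.gains[j, i]
            if g == 0:
                continue
            mixed += g * _attenuate(target.samples[i], mixing.attenuation_hz[j, i], fs)
        chan = mixing.nonlinearity(mixed)
        if mixing.powerline_amplitude > 0:
            chan = chan + mixing.powerline_amplitude * np.sin(
                2 * np.pi * mixing.powerline_hz * t + rng.uniform(0, 2 * np.pi)
            )
        if mixing.motion_amplitude > 0 and n > 1:
            chan = chan + mixing.motion_amplitude * bandlimited_noise(n, fs, 0.2, 15.0, rng)
        if mixing.noise_std > 0:
            chan = chan + mixing.noise_std * rng.standard_normal(n)
        rows.append(chan)
    return SignalRecord(np.vstack(rows), fs, list(DISTAL_LABELS))


@dataclass
class SynthConfig:
    """Study conditions for one synthetic calibration recording."""

    sampling_rate: float = 2000.0
    duration_s: float = 30.0
    cycle_period: float = 1.1
    duty_fractions: tuple = DEFAULT_DUTIES
    phases: tuple = DEFAULT_PHASES
    carrier_bands: tuple = DEFAULT_CARRIER_BANDS
    envelope_peak: float = 1.0
    envelope_baseline: float = 0.05
    amplitude_jitter: float = 0.10
    target_powerline_amplitude: float = 0.02
    mixing: MixingModel = field(default_factory=MixingModel)

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.sampling_rate <= 0:
            raise ParameterError("duration and sampling rate must be positive")
        bands = np.atleast_2d(np.asarray(self.carrier_bands, dtype=float))
        for low, high in bands:
            if not (0 < low < high <= self.sampling_rate / 2):
                raise ParameterError("carrier bands must lie inside (0, Nyquist]")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sampling_rate))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mixing"]["gains"] = self.mixing.gains.tolist()
        d["mixing"]["attenuation_hz"] = self.mixing.attenuation_hz.tolist()
        return d


@dataclass
class SyntheticRecording:
    """Target + distal records with the ground-truth envelopes that drove them."""

    target: SignalRecord
    distal: SignalRecord
    envelopes: np.ndarray  # (6, n) ground-truth activation levels
    seed: int | None
    sampling_rate: float


def generate_recording(config: SynthConfig, seed: int | None = 0) -> SyntheticRecording:
    """Run the full generator: envelopes -> target EMG -> distal channels."""
    ss = np.random.SeedSequence(seed)
    s_env, s_tgt, s_mix = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(3))
    profiles = generate_activation_envelopes(
        config.n_samples,
        config.sampling_rate,
        config.cycle_period,
        config.duty_fractions,
        phases=config.phases,
        peak=config.envelope_peak,
        baseline=config.envelope_baseline,
        amplitude_jitter=config.amplitude_jitter,
        seed=s_env,
    )
    target = synthesize_target_emg(
        profiles,
        config.carrier_bands,
        config.sampling_rate,
        powerline_hz=config.mixing.powerline_hz,
        powerline_amplitude=config.target_powerline_amplitude,
        seed=s_tgt,
    )
    distal = synthesize_distal_channels(target, config.mixing, seed=s_mix)
    return SyntheticRecording(
        target=target,
        distal=distal,
        envelopes=np.vstack([p.envelope for p in profiles]),
        seed=seed,
        sampling_rate=config.sampling_rate,
    )
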