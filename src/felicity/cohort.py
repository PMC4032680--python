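"""Synthetic three-epoch psychophysiological cohorts.

The measurement model compares a candidate "happiness" epoch against two
ground-truth epochs (relax, stress) recorded on the same subject.  No public
recordings exist for this protocol, so this module generates them: per-channel
signal generators with controllable ground truth (NN-interval series with
LF/HF spectral modulation, tonic+phasic skin conductance, burst-modulated
facial EMG, sinusoidal respiration, band-limited bilateral EEG, pupil traces
with blink dropouts), assembled into multi-channel recordings whose per-epoch
targets follow configurable scenario patterns (happiness-true, stress-only,
null).

Every generator takes an explicit seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

# ---------------------------------------------------------------------------
# Constants: epoch labels, channel inventory, sampling conventions
# ---------------------------------------------------------------------------

EPOCH_LABELS = ("relax", "happiness", "stress")

#: default export sampling rate, Hz (one sample every 3.90625 ms)
DEFAULT_FS = 256.0
#: EMG needs a higher rate to represent broadband muscle activity
EMG_FS = 1024.0
#: default epoch length, seconds (5-minute recording blocks)
DEFAULT_EPOCH_S = 300.0

#: generative carrier frequencies for the HRV modulations (band centres of
#: LF 0.04-0.15 Hz and HF 0.15-0.5 Hz)
LF_GEN_HZ = 0.10
HF_GEN_HZ = 0.30

SAMPLED_CHANNELS = (
    "gsr", "emg_zyg", "emg_corr", "emg_orb", "rsp",
    "eeg_left", "eeg_right", "pupil",
)
CHANNEL_NAMES = ("ecg_nn",) + SAMPLED_CHANNELS

#: the 14 measures of the index table, grouped by model dimension
MEASURES = (
    "HR", "SC", "beta_power", "pupil_size", "rsp_depth",
    "emg_zyg", "emg_corr", "startle", "alpha_asym",
    "lf_hf", "lf_power", "hf_power", "nn50", "rmssd",
)


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EpochPlan:
    """A labelled recording segment: [start_s, start_s + duration_s)."""

    label: str
    start_s: float
    duration_s: float = DEFAULT_EPOCH_S

    def __post_init__(self) -> None:
        if self.label not in EPOCH_LABELS:
            raise ValueError(f"unknown epoch label {self.label!r}; "
                             f"expected one of {EPOCH_LABELS}")
        if self.start_s < 0:
            raise ValueError(f"start_s must be >= 0, got {self.start_s}")
        if self.duration_s <= 0:
            raise ValueError(f"duration_s must be > 0, got {self.duration_s}")

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s


def default_epochs(duration_s: float = DEFAULT_EPOCH_S) -> list[EpochPlan]:
    """Three contiguous epochs in relax -> happiness -> stress order."""
    return [EpochPlan(lab, i * duration_s, duration_s)
            for i, lab in enumerate(EPOCH_LABELS)]


def validate_epochs(epochs: list[EpochPlan]) -> list[EpochPlan]:
    """Check all three labels present exactly once and non-overlapping."""
    labels = [e.label for e in epochs]
    for lab in EPOCH_LABELS:
        if labels.count(lab) != 1:
            raise ValueError(f"epoch label {lab!r} must appear exactly once, "
                             f"got labels {labels}")
    ordered = sorted(epochs, key=lambda e: e.start_s)
    for a, b in zip(ordered, ordered[1:]):
        if a.end_s > b.start_s + 1e-9:
            raise ValueError(f"epochs {a.label!r} and {b.label!r} overlap")
    return ordered


@dataclass
class ChannelTrace:
    """A uniformly sampled channel: value per sample at rate ``fs``."""

    name: str
    fs: float
    samples: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"fs must be > 0, got {self.fs} for {self.name}")
        self.samples = np.asarray(self.samples, dtype=float)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs

    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.fs

    def segment(self, start_s: float, end_s: float) -> "ChannelTrace":
        i0 = int(round(start_s * self.fs))
        i1 = int(round(end_s * self.fs))
        return ChannelTrace(self.name, self.fs, self.samples[i0:i1], self.units)


@dataclass
class NNSeries:
    """Normal-to-normal heartbeat intervals with their beat timestamps.

    ``nn_ms[i]`` is the interval between ``beat_times_s[i]`` and
    ``beat_times_s[i+1]`` in milliseconds (so ``len(nn_ms) == beats - 1``).
    """

    beat_times_s: np.ndarray
    nn_ms: np.ndarray

    def __post_init__(self) -> None:
        self.beat_times_s = np.asarray(self.beat_times_s, dtype=float)
        self.nn_ms = np.asarray(self.nn_ms, dtype=float)
        if len(self.nn_ms) != len(self.beat_times_s) - 1:
            raise ValueError("nn_ms must have one element fewer than beat_times_s")
        if np.any(self.nn_ms <= 0):
            raise ValueError("NN intervals must be strictly positive")
        if np.any(np.diff(self.beat_times_s) <= 0):
            raise ValueError("beat times must be strictly increasing")

    def segment(self, start_s: float, end_s: float) -> "NNSeries":
        """Beats (and the intervals between them) inside [start_s, end_s)."""
        keep = (self.beat_times_s >= start_s) & (self.beat_times_s < end_s)
        times = self.beat_times_s[keep]
        if len(times) < 2:
            raise ValueError("fewer than 2 beats in requested segment")
        return NNSeries(times, np.diff(times) * 1000.0)


#: per-epoch generator parameters for one subject
@dataclass
class EpochParams:
    mean_hr: float = 65.0          # beats/min
    lf_mod_amp: float = 40.0       # ms, 0.10 Hz NN modulation amplitude
    hf_mod_amp: float = 25.0       # ms, 0.30 Hz NN modulation amplitude
    nn_jitter_sd: float = 20.0     # ms
    scl_tonic: float = 4.0         # microsiemens
    scl_drift_per_min: float = 0.05  # microsiemens/min
    scr_rate: float = 4.0          # events/min
    emg_zyg_amp: float = 8.0       # microvolts (burst RMS)
    emg_corr_amp: float = 3.0
    emg_orb_amp: float = 2.5
    emg_noise_floor: float = 1.0   # microvolts
    resp_rate: float = 12.0        # breaths/min
    resp_depth: float = 2.4        # peak-to-trough amplitude units
    alpha_power_left: float = 1.0  # band-power targets (units^2)
    alpha_power_right: float = 1.49
    beta_power: float = 1.0
    pupil_mean: float = 3.4        # mm
    blink_rate: float = 15.0       # events/min

    def __post_init__(self) -> None:
        if not (30.0 <= self.mean_hr <= 220.0):
            raise ValueError(f"mean_hr must be in [30, 220], got {self.mean_hr}")
        for name in ("lf_mod_amp", "hf_mod_amp", "nn_jitter_sd", "scl_tonic",
                     "scr_rate", "emg_zyg_amp", "emg_corr_amp", "emg_orb_amp",
                     "emg_noise_floor", "resp_rate", "resp_depth",
                     "alpha_power_left", "alpha_power_right", "beta_power",
                     "pupil_mean", "blink_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")


@dataclass
class SubjectProfile:
    """Per-epoch ground-truth generator targets for one subject."""

    epochs: dict[str, EpochParams]

    def __post_init__(self) -> None:
        missing = set(EPOCH_LABELS) - set(self.epochs)
        if missing:
            raise ValueError(f"profile missing epoch(s): {sorted(missing)}")

    def to_dict(self) -> dict:
        return {lab: asdict(p) for lab, p in self.epochs.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "SubjectProfile":
        return cls({lab: EpochParams(**p) for lab, p in d.items()})


@dataclass
class Recording:
    """One subject's multi-channel recording over the three epochs."""

    subject_id: str
    nn: NNSeries
    channels: dict[str, ChannelTrace]
    epochs: list[EpochPlan]
    seed: int
    profile: Optional[SubjectProfile] = None

    def __post_init__(self) -> None:
        self.epochs = validate_epochs(self.epochs)
        total = self.epochs[-1].end_s
        for name, tr in self.channels.items():
            if tr.duration_s + 1e-6 < total:
                raise ValueError(f"channel {name!r} does not cover the epochs "
                                 f"({tr.duration_s:.2f}s < {total:.2f}s)")

    def epoch(self, label: str) -> EpochPlan:
        for e in self.epochs:
            if e.label == label:
                return e
        raise KeyError(label)


# ---------------------------------------------------------------------------
# Per-channel generators
# ---------------------------------------------------------------------------

def generate_nn_series(mean_hr: float, lf_mod_amp: float = 0.0,
                       hf_mod_amp: float = 0.0, nn_jitter_sd: float = 0.0,
                       duration_s: float = DEFAULT_EPOCH_S,
                       seed: int = 0) -> NNSeries:
    """Generate an NN-interval series (tachogram) beat by beat.

    The mean interval is 60000/mean_hr ms; sinusoidal modulations at the LF
    (0.10 Hz) and HF (0.30 Hz) carrier frequencies with the stated amplitudes
    are superposed, plus white Gaussian jitter.  Indexes operate on NN
    intervals directly, so the series is produced as an event series rather
    than as a waveform.
    """
    if mean_hr <= 0:
        raise ValueError(f"mean_hr must be positive, got {mean_hr}")
    if duration_s < 60:
        raise ValueError(f"duration_s must be >= 60, got {duration_s}")
    for name, v in (("lf_mod_amp", lf_mod_amp), ("hf_mod_amp", hf_mod_amp),
                    ("nn_jitter_sd", nn_jitter_sd)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")
    rng = np.random.default_rng(seed)
    base_ms = 60000.0 / mean_hr
    times = [0.0]
    nn = []
    t = 0.0
    while True:
        interval = (base_ms
                    + lf_mod_amp * np.sin(2 * np.pi * LF_GEN_HZ * t)
                    + hf_mod_amp * np.sin(2 * np.pi * HF_GEN_HZ * t))
        if nn_jitter_sd > 0:
            interval += rng.normal(0.0, nn_jitter_sd)
        interval = max(interval, 250.0)  # physiological floor
        t_next = t + interval / 1000.0
        if t_next > duration_s:
            break
        nn.append(interval)
        times.append(t_next)
        t = t_next
    return NNSeries(np.array(times), np.array(nn))


def _scr_kernel(fs: float, rise_s: float = 1.0, decay_s: float = 4.0) -> np.ndarray:
    # 1 s exponential rise, 4 s decay, normalized to unit peak
    tau = np.arange(0, rise_s + 6 * decay_s, 1.0 / fs)
    h = (1.0 - np.exp(-tau / (rise_s / 3.0))) * np.exp(-tau / decay_s)
    return h / h.max()


def generate_scl(scl_tonic: float, drift_per_min: float = 0.0,
                 scr_rate: float = 0.0, fs: float = DEFAULT_FS,
                 duration_s: float = DEFAULT_EPOCH_S, seed: int = 0,
                 scr_amp: float = 0.3) -> ChannelTrace:
    """Skin conductance: tonic level + linear drift + phasic responses.

    Phasic events occur at Poisson times (scr_rate events/min) with an
    exponential rise/decay shape; the trace is clipped at zero.
    """
    if fs <= 0:
        raise ValueError(f"fs must be > 0, got {fs}")
    if scl_tonic < 0:
        raise ValueError(f"scl_tonic must be >= 0, got {scl_tonic}")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    x = scl_tonic + drift_per_min * t / 60.0
    if scr_rate > 0:
        n_events = rng.poisson(scr_rate * duration_s / 60.0)
        onsets = np.sort(rng.uniform(0.0, duration_s, n_events))
        kern = _scr_kernel(fs)
        amps = scr_amp * rng.lognormal(0.0, 0.3, n_events)
        for t0, a in zip(onsets, amps):
            i0 = int(t0 * fs)
            seg = min(len(kern), n - i0)
            x[i0:i0 + seg] += a * kern[:seg]
    return ChannelTrace("gsr", fs, np.maximum(x, 0.0), "uS")


def generate_emg(burst_amp: float, burst_rate: float = 0.0,
                 noise_floor: float = 0.0, fs: float = EMG_FS,
                 duration_s: float = DEFAULT_EPOCH_S, seed: int = 0,
                 burst_duration_s: float = 0.5) -> ChannelTrace:
    """Surface EMG: zero-mean broadband noise under an amplitude envelope.

    The envelope sits at ``noise_floor`` and rises to ``burst_amp`` during
    Poisson-timed burst windows (burst_rate events/min), so the RMS during a
    burst approximates ``burst_amp`` microvolts.  ``burst_rate=inf`` (or any
    rate whose windows tile the trace) yields a continuously active muscle.
    """
    if fs <= 0:
        raise ValueError(f"fs must be > 0, got {fs}")
    if burst_amp < 0 or noise_floor < 0:
        raise ValueError("burst_amp and noise_floor must be >= 0")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    envelope = np.full(n, float(noise_floor))
    if np.isinf(burst_rate):
        envelope[:] = burst_amp
    elif burst_rate > 0:
        n_events = rng.poisson(burst_rate * duration_s / 60.0)
        onsets = rng.uniform(0.0, duration_s, n_events)
        w = int(burst_duration_s * fs)
        for t0 in onsets:
            i0 = int(t0 * fs)
            envelope[i0:i0 + w] = burst_amp
    samples = envelope * rng.standard_normal(n) if (burst_amp > 0 or noise_floor > 0) \
        else np.zeros(n)
    return ChannelTrace("emg", fs, samples, "uV")


def generate_respiration(resp_rate: float, resp_depth: float,
                         fs: float = DEFAULT_FS,
                         duration_s: float = DEFAULT_EPOCH_S, seed: int = 0,
                         noise_sd: float = 0.0) -> ChannelTrace:
    """Respiration belt signal: sinusoid at resp_rate/60 Hz whose
    peak-to-trough excursion equals ``resp_depth``."""
    if not (4.0 < resp_rate < 60.0):
        raise ValueError(f"resp_rate must be in (4, 60) breaths/min, got {resp_rate}")
    if resp_depth < 0:
        raise ValueError(f"resp_depth must be >= 0, got {resp_depth}")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    x = 0.5 * resp_depth * np.sin(2 * np.pi * resp_rate / 60.0 * t)
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, n)
    return ChannelTrace("rsp", fs, x, "au")


def _bandlimited_noise(rng: np.random.Generator, n: int, fs: float,
                       lo_hz: float, hi_hz: float, power: float) -> np.ndarray:
    """White Gaussian noise confined to (lo_hz, hi_hz), rescaled so its
    realized variance (== band power) equals ``power`` exactly."""
    if power <= 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    spec[(freqs < lo_hz) | (freqs > hi_hz)] = 0.0
    x = np.fft.irfft(spec, n)
    var = x.var()
    if var <= 0:
        raise ValueError("band is empty at this length/sampling rate")
    return x * np.sqrt(power / var)


def generate_eeg(alpha_power_left: float, alpha_power_right: float,
                 beta_power: float, fs: float = DEFAULT_FS,
                 duration_s: float = DEFAULT_EPOCH_S,
                 seed: int = 0) -> tuple[ChannelTrace, ChannelTrace]:
    """Bilateral frontal EEG as sums of band-limited noise components.

    The alpha component is synthesized inside 8-12 Hz and the beta component
    inside 14-28 Hz (strict interiors of the analysis bands, so leakage does
    not bleed across band edges); each component's realized variance is scaled
    to the requested band-power target.  Left and right differ only in alpha
    power.
    """
    for name, v in (("alpha_power_left", alpha_power_left),
                    ("alpha_power_right", alpha_power_right),
                    ("beta_power", beta_power)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    left = (_bandlimited_noise(rng, n, fs, 8.0, 12.0, alpha_power_left)
            + _bandlimited_noise(rng, n, fs, 14.0, 28.0, beta_power))
    right = (_bandlimited_noise(rng, n, fs, 8.0, 12.0, alpha_power_right)
             + _bandlimited_noise(rng, n, fs, 14.0, 28.0, beta_power))
    return (ChannelTrace("eeg_left", fs, left, "uV"),
            ChannelTrace("eeg_right", fs, right, "uV"))


def generate_pupil(pupil_mean: float, blink_rate: float = 0.0,
                   fs: float = DEFAULT_FS, duration_s: float = DEFAULT_EPOCH_S,
                   seed: int = 0, noise_sd: float = 0.0,
                   blink_duration_s: float = 0.2) -> ChannelTrace:
    """Pupil diameter trace (mm) with blink dropouts forced to zero."""
    if pupil_mean < 0:
        raise ValueError(f"pupil_mean must be >= 0, got {pupil_mean}")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    x = np.full(n, float(pupil_mean))
    if noise_sd > 0:
        x += rng.normal(0.0, noise_sd, n)
    if blink_rate > 0:
        n_events = rng.poisson(blink_rate * duration_s / 60.0)
        onsets = rng.uniform(0.0, duration_s, n_events)
        w = int(blink_duration_s * fs)
        for t0 in onsets:
            i0 = int(t0 * fs)
            x[i0:i0 + w] = 0.0
    return ChannelTrace("pupil", fs, x, "mm")


def render_ecg(nn: NNSeries, fs: float = DEFAULT_FS,
               duration_s: Optional[float] = None,
               pad_s: float = 0.5) -> ChannelTrace:
    """Render a template waveform ECG from a known NN series.

    Only exists to exercise R-peak detection: each beat is a narrow Gaussian
    R-wave (with small flanking Q/S deflections) on a flat baseline.  A
    ``pad_s`` lead-in/out keeps every beat clear of filter edge effects.
    """
    if duration_s is None:
        duration_s = float(nn.beat_times_s[-1]) + 2 * pad_s
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs - pad_s
    x = np.zeros(n)
    for bt in nn.beat_times_s:
        x += 1.0 * np.exp(-0.5 * ((t - bt) / 0.012) ** 2)          # R
        x -= 0.15 * np.exp(-0.5 * ((t - bt + 0.040) / 0.015) ** 2)  # Q
        x -= 0.20 * np.exp(-0.5 * ((t - bt - 0.040) / 0.015) ** 2)  # S
    return ChannelTrace("ecg", fs, x, "mV")


# ---------------------------------------------------------------------------
# Scenario patterns
# ---------------------------------------------------------------------------
# Relax-epoch baseline and the epoch deviations realizing the hypothesized
# sign patterns: arousal indexes low in relax and equally elevated in the
# candidate and stress epochs; valence indexes positive in relax and the
# candidate, negative in stress; vagally driven satisfaction indexes peaked in
# the candidate epoch with relax and stress at a common lower level.

_RELAX = EpochParams()

_HAPPINESS = EpochParams(
    mean_hr=74.0, lf_mod_amp=22.0, hf_mod_amp=50.0, nn_jitter_sd=40.0,
    scl_tonic=6.5, scr_rate=8.0,
    emg_zyg_amp=8.0, emg_corr_amp=3.0, emg_orb_amp=2.5,
    resp_rate=15.0, resp_depth=1.6,
    alpha_power_left=1.0, alpha_power_right=1.49, beta_power=1.6,
    pupil_mean=4.2,
)

_STRESS = EpochParams(
    mean_hr=74.0, lf_mod_amp=40.0, hf_mod_amp=25.0, nn_jitter_sd=20.0,
    scl_tonic=6.5, scr_rate=8.0,
    emg_zyg_amp=3.0, emg_corr_amp=8.0, emg_orb_amp=7.0,
    resp_rate=15.0, resp_depth=1.6,
    alpha_power_left=1.0, alpha_power_right=0.819, beta_power=1.6,
    pupil_mean=4.2,
)

SCENARIOS = ("happiness_true", "stress_only", "null")

#: numeric generator-parameter fields subject to scenario scaling and
#: between-subject variation
_SCALED_FIELDS = tuple(f for f in asdict(_RELAX))


def _scenario_epoch_params(scenario: str) -> dict[str, EpochParams]:
    if scenario == "happiness_true":
        return {"relax": _RELAX, "happiness": _HAPPINESS, "stress": _STRESS}
    if scenario == "stress_only":
        # the candidate epoch is a full stress replica: arousal elevated, but
        # the valence / satisfaction signatures of happiness absent
        return {"relax": _RELAX, "happiness": _STRESS, "stress": _STRESS}
    if scenario == "null":
        return {"relax": _RELAX, "happiness": _RELAX, "stress": _RELAX}
    raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")


def _scale_params(params: EpochParams, baseline: EpochParams,
                  effect_scale: float) -> dict[str, float]:
    """Shrink/stretch epoch deviations from the relax baseline."""
    base = asdict(baseline)
    tgt = asdict(params)
    return {k: base[k] + effect_scale * (tgt[k] - base[k]) for k in _SCALED_FIELDS}


#: between-subject and subject-by-epoch variability: multiplicative lognormal
#: factors with ~10% coefficient of variation
SUBJECT_CV = 0.10
EPOCH_CV = 0.10

#: fields that must not be randomized (physiological/config constants)
_FIXED_FIELDS = ("emg_noise_floor", "scl_drift_per_min", "blink_rate")


def make_subject_profile(scenario: str, effect_scale: float = 1.0,
                         seed: int = 0) -> SubjectProfile:
    """Draw one subject's per-epoch targets under a scenario.

    A single lognormal factor per parameter (sd ~10% of the mean) models
    stable between-subject differences; an independent lognormal factor per
    (parameter, epoch) models within-subject fluctuation between sessions, so
    the repeated-measures correlation is ~0.5, matching the planning
    assumption of the power analysis.
    """
    rng = np.random.default_rng(seed)
    pattern = _scenario_epoch_params(scenario)
    sig_s = np.sqrt(np.log(1 + SUBJECT_CV ** 2))
    sig_e = np.sqrt(np.log(1 + EPOCH_CV ** 2))
    subj_factor = {f: rng.lognormal(-sig_s ** 2 / 2, sig_s) for f in _SCALED_FIELDS}
    epochs = {}
    for lab in EPOCH_LABELS:
        vals = _scale_params(pattern[lab], _RELAX, effect_scale)
        out = {}
        for f, v in vals.items():
            if f in _FIXED_FIELDS:
                out[f] = v
            else:
                out[f] = v * subj_factor[f] * rng.lognormal(-sig_e ** 2 / 2, sig_e)
        out["mean_hr"] = float(np.clip(out["mean_hr"], 30.0, 220.0))
        epochs[lab] = EpochParams(**out)
    return SubjectProfile(epochs)


# ---------------------------------------------------------------------------
# Recording assembly
# ---------------------------------------------------------------------------

def synthesize_recording(profile: SubjectProfile,
                         epochs: Optional[list[EpochPlan]] = None,
                         seed: int = 0,
                         subject_id: str = "s00") -> Recording:
    """Concatenate per-epoch generator outputs into one recording.

    Epochs must tile the recording contiguously (the writer records the
    markers exactly); each channel is generated epoch by epoch with that
    epoch's parameters and concatenated.
    """
    if epochs is None:
        epochs = default_epochs()
    epochs = validate_epochs(epochs)
    t0 = epochs[0].start_s
    for a, b in zip(epochs, epochs[1:]):
        if abs(a.end_s - b.start_s) > 1e-9:
            raise ValueError("epochs must be contiguous")
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    keys = ("nn", "gsr", "emg_zyg", "emg_corr", "emg_orb", "rsp", "eeg", "pupil")
    child = {k: s for k, s in zip(keys, ss.spawn(len(keys)))}

    def epoch_seeds(key: str) -> list[np.random.SeedSequence]:
        return child[key].spawn(len(epochs))

    # NN event series: generate per epoch, then shift beat times
    beat_times: list[np.ndarray] = []
    for ep, s in zip(epochs, epoch_seeds("nn")):
        p = profile.epochs[ep.label]
        nn = generate_nn_series(p.mean_hr, p.lf_mod_amp, p.hf_mod_amp,
                                p.nn_jitter_sd, ep.duration_s,
                                seed=s)
        beat_times.append(nn.beat_times_s + ep.start_s)
    all_times = np.concatenate(beat_times)
    all_times = np.unique(all_times)
    nn_series = NNSeries(all_times - t0 + t0, np.diff(all_times) * 1000.0)

    channels: dict[str, ChannelTrace] = {}

    def build(name: str, fs: float, units: str, gen) -> None:
        segs = [gen(ep, profile.epochs[ep.label], s)
                for ep, s in zip(epochs, child[name if name in child else "eeg"]
                                 .spawn(len(epochs)))]
        channels[name] = ChannelTrace(name, fs, np.concatenate(segs), units)

    build("gsr", DEFAULT_FS, "uS",
          lambda ep, p, s: generate_scl(p.scl_tonic, p.scl_drift_per_min,
                                        p.scr_rate, DEFAULT_FS, ep.duration_s,
                                        seed=s).samples)
    for ch, amp_field in (("emg_zyg", "emg_zyg_amp"),
                          ("emg_corr", "emg_corr_amp"),
                          ("emg_orb", "emg_orb_amp")):
        build(ch, EMG_FS, "uV",
              lambda ep, p, s, f=amp_field: generate_emg(
                  getattr(p, f), burst_rate=np.inf,
                  noise_floor=p.emg_noise_floor, fs=EMG_FS,
                  duration_s=ep.duration_s, seed=s).samples)
    build("rsp", DEFAULT_FS, "au",
          lambda ep, p, s: generate_respiration(p.resp_rate, p.resp_depth,
                                                DEFAULT_FS, ep.duration_s,
                                                seed=s).samples)
    build("pupil", DEFAULT_FS, "mm",
          lambda ep, p, s: generate_pupil(p.pupil_mean, p.blink_rate,
                                          DEFAULT_FS, ep.duration_s,
                                          seed=s).samples)
    eeg_l, eeg_r = [], []
    for ep, s in zip(epochs, epoch_seeds("eeg")):
        p = profile.epochs[ep.label]
        l, r = generate_eeg(p.alpha_power_left, p.alpha_power_right,
                            p.beta_power, DEFAULT_FS, ep.duration_s, seed=s)
        eeg_l.append(l.samples)
        eeg_r.append(r.samples)
    channels["eeg_left"] = ChannelTrace("eeg_left", DEFAULT_FS,
                                        np.concatenate(eeg_l), "uV")
    channels["eeg_right"] = ChannelTrace("eeg_right", DEFAULT_FS,
                                         np.concatenate(eeg_r), "uV")

    seed_int = seed if isinstance(seed, int) \
        else int(ss.generate_state(1)[0] % (2 ** 31))
    return Recording(subject_id=subject_id, nn=nn_series, channels=channels,
                     epochs=epochs, seed=seed_int, profile=profile)


def synthesize_cohort(n: int, scenario: str = "happiness_true",
                      effect_scale: float = 1.0, seed: int = 0,
                      epoch_duration_s: float = DEFAULT_EPOCH_S) -> list[Recording]:
    """Generate ``n`` subjects' recordings under one scenario.

    ``effect_scale`` shrinks (or stretches) every epoch deviation from the
    relax baseline; 1.0 encodes physiologically typical contrast magnitudes
    (per-measure Cohen's f roughly 0.8-1.5), ~0.2 reproduces the conservative
    f = 0.25 planning value of the power analysis.
    """
    if n < 2:
        raise ValueError(f"cohort size must be >= 2, got {n}")
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    ss = np.random.SeedSequence(seed)
    recs = []
    epochs = default_epochs(epoch_duration_s)
    for i, child in enumerate(ss.spawn(n)):
        prof_seed, rec_seed = child.spawn(2)
        prof = make_subject_profile(scenario, effect_scale, seed=prof_seed)
        recs.append(synthesize_recording(prof, list(epochs), seed=rec_seed,
                                         subject_id=f"s{i:02d}"))
    return recs


# ---------------------------------------------------------------------------
# Index-level scenario sampler
# ---------------------------------------------------------------------------
# Expected index values implied by the scenario generator parameters; used to
# draw subject x epoch x measure tables directly when a study needs hundreds
# of replicate cohorts (the signal -> extraction path is tied to these same
# targets by the round-trip tests).

INDEX_TARGETS: dict[str, dict[str, float]] = {
    #            relax   happiness  stress
    "HR":         dict(relax=65.0, happiness=74.0, stress=74.0),
    "SC":         dict(relax=4.0, happiness=6.5, stress=6.5),
    "beta_power": dict(relax=1.0, happiness=1.6, stress=1.6),
    "pupil_size": dict(relax=3.4, happiness=4.2, stress=4.2),
    "rsp_depth":  dict(relax=2.4, happiness=1.6, stress=1.6),
    "emg_zyg":    dict(relax=8.0, happiness=8.0, stress=3.0),
    "emg_corr":   dict(relax=3.0, happiness=3.0, stress=8.0),
    "startle":    dict(relax=2.5, happiness=2.5, stress=7.0),
    "alpha_asym": dict(relax=0.4, happiness=0.4, stress=-0.2),
    "lf_hf":      dict(relax=2.56, happiness=0.19, stress=2.56),
    "lf_power":   dict(relax=800.0, happiness=242.0, stress=800.0),
    "hf_power":   dict(relax=312.0, happiness=1250.0, stress=312.0),
    "nn50":       dict(relax=24.0, happiness=120.0, stress=24.0),
    "rmssd":      dict(relax=30.0, happiness=62.0, stress=30.0),
}

#: alpha_asym is a signed log-ratio; its noise is additive on a fixed scale
_ADDITIVE_MEASURES = {"alpha_asym": 0.4}


def sample_index_table(n: int, scenario: str = "happiness_true",
                       effect_scale: float = 1.0, seed: int = 0):
    """Draw a subject x epoch x measure index table under a scenario.

    Distributional surrogate for synthesize -> extract: each cell is the
    scenario's expected index value perturbed by a per-subject lognormal
    factor (between-subject, sd ~10%) and an independent per-(subject, epoch)
    lognormal factor (session noise, sd ~10%); the signed alpha-asymmetry
    index instead gets additive Gaussian noise on its natural scale.  Returns
    a long-format pandas DataFrame (subject, epoch, 14 measure columns).
    """
    import pandas as pd

    if n < 2:
        raise ValueError(f"cohort size must be >= 2, got {n}")
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    rng = np.random.default_rng(seed)
    sig_s = np.sqrt(np.log(1 + SUBJECT_CV ** 2))
    sig_e = np.sqrt(np.log(1 + EPOCH_CV ** 2))

    def epoch_mean(measure: str, lab: str) -> float:
        tgt = INDEX_TARGETS[measure]
        if scenario == "null":
            return tgt["relax"]
        if scenario == "stress_only" and lab == "happiness":
            raw = tgt["stress"]
        else:
            raw = tgt[lab]
        return tgt["relax"] + effect_scale * (raw - tgt["relax"])

    rows = []
    for i in range(n):
        subj = f"s{i:02d}"
        subj_f = {m: rng.lognormal(-sig_s ** 2 / 2, sig_s) for m in MEASURES}
        subj_o = {m: rng.normal(0.0, SUBJECT_CV * s)
                  for m, s in _ADDITIVE_MEASURES.items()}
        for lab in EPOCH_LABELS:
            row = {"subject": subj, "epoch": lab}
            for m in MEASURES:
                mu = epoch_mean(m, lab)
                if m in _ADDITIVE_MEASURES:
                    scale = _ADDITIVE_MEASURES[m]
                    row[m] = mu + subj_o[m] + rng.normal(0.0, EPOCH_CV * scale)
                else:
                    row[m] = (mu * subj_f[m]
                              * rng.lognormal(-sig_e ** 2 / 2, sig_e))
            rows.append(row)
    return pd.DataFrame(rows)
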