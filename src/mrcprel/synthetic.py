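"""Synthetic MRCP epochs, continuous recordings and simulated raters.

No real EEG ships with this package; this module generates data with the
statistical structure the reliability analysis assumes and a known ground
truth:

* **Waveform** — a piecewise cosine-ramp template per dataset: baseline at
  zero, a smooth monotone negative ramp from a pre-cue onset to the peak
  negativity (PN), then a smooth recovery toward baseline. This matches the
  slow (~0.5 Hz) character of the MRCP while keeping the planted PN latency
  and amplitude exact.
* **Epoch-to-epoch variability** — per-epoch amplitude scaling, latency
  jitter, and additive background noise (a white + 1/f "pink" mixture), plus
  occasional large low-frequency blink-like artefact transients that are
  flagged in the ground truth.
* **Conditions** — three calibrated parameter sets (healthy voluntary,
  healthy imagined, stroke voluntary) whose default noise levels reproduce
  the reported condition-wise mean cosine similarity (~0.39 / 0.27 / 0.41):
  imagined movement has smaller, less defined negativities; stroke has
  longer latencies and smaller amplitudes than healthy voluntary movement.
* **Raters** — accept/reject decisions are Bernoulli draws whose log-odds
  are linear in the epoch's cosine similarity (the generative inverse of the
  logistic trend model fitted downstream), independent across sessions given
  similarity; PN labels are the automated PN of the average plus a
  rater-specific bias and zero-mean Gaussian noise, so the implied ICC is
  sigma2_dataset / (sigma2_dataset + sigma2_bias + sigma2_noise).

Reproducibility: every stochastic operation takes (or derives) a
``numpy.random.Generator``. Streams are derived from the single config seed
by hashing a role key (condition, participant, rater, session), so e.g.
adding raters never perturbs the dataset noise.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .epoch_metrics import AverageMRCP, label_pn
from .preprocessing import ContinuousRecording, EpochSet

__all__ = [
    "HEALTHY_VOLUNTARY",
    "HEALTHY_IMAGINED",
    "STROKE_VOLUNTARY",
    "CONDITIONS",
    "ConditionParams",
    "MRCPTemplate",
    "RaterProfile",
    "SimulationConfig",
    "SimulatedDataset",
    "default_condition_params",
    "default_rater_profiles",
    "child_rng",
    "make_template",
    "simulate_epoch",
    "simulate_dataset",
    "simulate_study",
    "simulate_continuous",
    "simulate_rater_decisions",
    "simulate_rater_label",
]

HEALTHY_VOLUNTARY = "healthy_voluntary"
HEALTHY_IMAGINED = "healthy_imagined"
STROKE_VOLUNTARY = "stroke_voluntary"
CONDITIONS = (HEALTHY_VOLUNTARY, HEALTHY_IMAGINED, STROKE_VOLUNTARY)

#: Channels of the sparse 10-20 montage emulated in continuous mode.
MONTAGE = ("FP1", "F3", "Fz", "F4", "C3", "Cz", "C4", "P3", "Pz", "P4")
#: Spatial attenuation of the injected MRCP relative to Cz per channel group.
_SPREAD = {"Cz": 1.0, "C3": 0.25, "C4": 0.25, "Fz": 0.25, "Pz": 0.25,
           "F3": 0.1, "F4": 0.1, "P3": 0.1, "P4": 0.1, "FP1": 0.0}


@dataclass(frozen=True)
class ConditionParams:
    """Generative parameters of one movement condition.

    Amplitudes in uV (PN amplitude negative), times in ms relative to the cue
    (ramp onset negative = pre-cue). ``pn_latency_jitter_sd_ms`` is the
    epoch-to-epoch latency jitter; ``pn_latency_dataset_sd_ms`` the
    between-dataset (between-participant) latency spread that carries the
    "true" variance the ICC compares rater error against.
    """

    condition_id: str
    pn_amplitude_mean: float
    pn_amplitude_sd: float
    ramp_onset_ms: float
    pn_latency_mean_ms: float
    pn_latency_jitter_sd_ms: float
    background_noise_sd: float
    pink_noise_fraction: float = 0.5
    artefact_prob: float = 0.05
    artefact_amplitude: float = 60.0
    pn_latency_dataset_sd_ms: float = 120.0
    epoch_scale_sd: float = 0.25
    recovery_ms: float = 1000.0

    def __post_init__(self) -> None:
        if self.pn_amplitude_mean >= 0:
            raise ValueError("pn_amplitude_mean must be negative (uV)")
        if not 0.0 <= self.artefact_prob <= 1.0:
            raise ValueError("artefact_prob must lie in [0, 1]")
        if not 0.0 <= self.pink_noise_fraction <= 1.0:
            raise ValueError("pink_noise_fraction must lie in [0, 1]")
        if self.pn_latency_jitter_sd_ms < 0:
            raise ValueError("pn_latency_jitter_sd_ms must be >= 0")
        if self.ramp_onset_ms >= self.pn_latency_mean_ms:
            raise ValueError("ramp onset must precede the PN latency")


def default_condition_params() -> dict[str, ConditionParams]:
    """Calibrated per-condition defaults.

    Background-noise levels were fixed once by scripts/calibrate_similarity.py
    so that the condition-wise grand mean cosine similarity lands on
    0.39 (healthy voluntary), 0.27 (healthy imagined) and 0.41 (stroke
    voluntary). Morphology contrasts: imagined movement has roughly half the
    voluntary amplitude and more latency jitter; stroke has smaller
    amplitudes and ~200 ms longer latencies than healthy voluntary movement.
    """
    return {
        HEALTHY_VOLUNTARY: ConditionParams(
            condition_id=HEALTHY_VOLUNTARY,
            pn_amplitude_mean=-15.0,
            pn_amplitude_sd=4.0,
            ramp_onset_ms=-1750.0,
            pn_latency_mean_ms=100.0,
            pn_latency_jitter_sd_ms=80.0,
            background_noise_sd=16.47,
            pn_latency_dataset_sd_ms=120.0,
            epoch_scale_sd=0.25,
        ),
        HEALTHY_IMAGINED: ConditionParams(
            condition_id=HEALTHY_IMAGINED,
            pn_amplitude_mean=-8.0,
            pn_amplitude_sd=2.5,
            ramp_onset_ms=-1500.0,
            pn_latency_mean_ms=150.0,
            pn_latency_jitter_sd_ms=200.0,
            background_noise_sd=13.40,
            pn_latency_dataset_sd_ms=150.0,
            epoch_scale_sd=0.35,
        ),
        STROKE_VOLUNTARY: ConditionParams(
            condition_id=STROKE_VOLUNTARY,
            pn_amplitude_mean=-12.0,
            pn_amplitude_sd=3.0,
            ramp_onset_ms=-1600.0,
            pn_latency_mean_ms=300.0,
            pn_latency_jitter_sd_ms=120.0,
            background_noise_sd=12.21,
            pn_latency_dataset_sd_ms=160.0,
            epoch_scale_sd=0.30,
        ),
    }


@dataclass
class MRCPTemplate:
    """Noise-free dataset-level MRCP waveform with its planted ground truth."""

    samples: np.ndarray
    fs: float
    cue_index: int
    true_pn_index: int
    true_pn_amplitude: float

    @property
    def true_pn_latency_ms(self) -> float:
        return (self.true_pn_index - self.cue_index) * 1000.0 / self.fs


@dataclass(frozen=True)
class RaterProfile:
    """Generative parameters of one simulated rater.

    ``accept_cs_slope`` may be a single log-odds-per-unit-similarity value or
    a mapping condition -> slope. ``pn_bias_ms`` is a fixed rater-specific
    offset of the PN label; ``pn_noise_sd_ms`` the per-label noise SD.
    """

    rater_id: str
    experience_years: float
    accept_intercept: float
    accept_cs_slope: float | Mapping[str, float]
    pn_bias_ms: float = 0.0
    pn_noise_sd_ms: float = 40.0

    def __post_init__(self) -> None:
        if self.pn_noise_sd_ms < 0:
            raise ValueError("pn_noise_sd_ms must be >= 0")

    def slope_for(self, condition: str) -> float:
        if isinstance(self.accept_cs_slope, Mapping):
            return float(self.accept_cs_slope[condition])
        return float(self.accept_cs_slope)


def default_rater_profiles() -> list[RaterProfile]:
    """Five simulated raters, mean experience 4.7 years (range 1.5--8).

    Acceptance slopes are steeper for the morphologically cleaner voluntary
    conditions: low-similarity epochs are rejected more decisively there.
    """
    slopes = {HEALTHY_VOLUNTARY: 6.0, HEALTHY_IMAGINED: 2.0, STROKE_VOLUNTARY: 3.5}
    spec = [
        ("E1", 1.5, -0.8, 0.0, 45.0),
        ("E2", 3.0, -1.0, 8.0, 40.0),
        ("E3", 5.0, -0.9, -6.0, 35.0),
        ("E4", 6.0, -1.2, 12.0, 30.0),
        ("E5", 8.0, -1.1, -10.0, 25.0),
    ]
    return [
        RaterProfile(
            rater_id=rid,
            experience_years=exp,
            accept_intercept=b0,
            accept_cs_slope=slopes,
            pn_bias_ms=bias,
            pn_noise_sd_ms=noise,
        )
        for rid, exp, b0, bias, noise in spec
    ]


@dataclass
class SimulationConfig:
    """Full study-generation configuration (defaults mirror the study design:
    10 datasets per condition, 50 epochs of 4.5 s at 500 Hz, 5 raters,
    3 evaluation sessions)."""

    n_datasets_per_condition: int = 10
    n_epochs: int = 50
    fs: float = 500.0
    pre_s: float = 3.0
    post_s: float = 1.5
    n_raters: int = 5
    n_sessions: int = 3
    seed: int = 0
    condition_params: dict[str, ConditionParams] = field(
        default_factory=default_condition_params
    )
    rater_profiles: list[RaterProfile] = field(default_factory=default_rater_profiles)

    def __post_init__(self) -> None:
        if self.n_epochs < 1 or self.n_datasets_per_condition < 1:
            raise ValueError("counts must be positive")
        self.rater_profiles = list(self.rater_profiles)[: self.n_raters]

    @property
    def n_samples(self) -> int:
        return int(round((self.pre_s + self.post_s) * self.fs))

    @property
    def cue_index(self) -> int:
        return int(round(self.pre_s * self.fs))


@dataclass
class SimulatedDataset:
    """One simulated dataset plus its generative ground truth."""

    epochs: EpochSet
    true_pn_index: int
    true_pn_latency_ms: float
    true_pn_amplitude: float
    artefact_flags: np.ndarray


# ---------------------------------------------------------------------------
# RNG stream derivation
# ---------------------------------------------------------------------------

def child_rng(seed: int, *key) -> np.random.Generator:
    """Derive an independent, reproducible sub-stream for a role key.

    Each key component (e.g. "dataset", condition name, participant index,
    rater id, session) is hashed to a 64-bit word; the words seed a
    ``SeedSequence`` together with the master seed. Streams for distinct keys
    are statistically independent, and adding entities under one key never
    perturbs streams under another.
    """
    words = [int(seed) & 0xFFFFFFFF]
    for part in key:
        digest = hashlib.sha256(str(part).encode()).digest()
        words.append(int.from_bytes(digest[:8], "little"))
    return np.random.default_rng(np.random.SeedSequence(words))


# ---------------------------------------------------------------------------
# Waveform generation
# ---------------------------------------------------------------------------

def _truncnorm(rng: np.random.Generator, mean: float, sd: float, nsd: float = 2.0) -> float:
    """Normal draw clipped to mean +/- nsd * sd (guards against rogue tails)."""
    return float(np.clip(rng.normal(mean, sd), mean - nsd * sd, mean + nsd * sd))


def make_template(
    params: ConditionParams,
    fs: float,
    pre_s: float,
    post_s: float,
    rng: np.random.Generator,
) -> MRCPTemplate:
    """Draw a dataset-level MRCP template.

    Amplitude ~ N(pn_amplitude_mean, pn_amplitude_sd) and latency ~
    N(pn_latency_mean_ms, pn_latency_dataset_sd_ms), both truncated at 2 SD;
    the latency is snapped to the sample grid so the planted minimum is exact.
    The waveform is zero before the ramp onset, follows a half-cosine ramp
    down to the PN, and a half-cosine recovery toward baseline afterwards.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    if pre_s * 1000.0 < abs(params.ramp_onset_ms):
        raise ValueError("pre-cue window shorter than the ramp onset")
    n = int(round((pre_s + post_s) * fs))
    cue_index = int(round(pre_s * fs))

    amp = _truncnorm(rng, params.pn_amplitude_mean, params.pn_amplitude_sd)
    amp = min(amp, -0.5)  # keep a genuinely negative peak
    lat_ms = _truncnorm(rng, params.pn_latency_mean_ms, params.pn_latency_dataset_sd_ms)
    pn_index = cue_index + int(round(lat_ms * fs / 1000.0))
    if not 0 <= pn_index < n:
        raise ValueError(f"PN latency {lat_ms:.1f} ms falls outside the epoch window")
    lat_ms = (pn_index - cue_index) * 1000.0 / fs  # grid-snapped
    if lat_ms <= params.ramp_onset_ms:
        raise ValueError("drawn PN latency precedes the ramp onset")

    t_ms = (np.arange(n) - cue_index) * 1000.0 / fs
    samples = np.zeros(n)
    ramp = (t_ms >= params.ramp_onset_ms) & (t_ms <= lat_ms)
    phase = (t_ms[ramp] - params.ramp_onset_ms) / (lat_ms - params.ramp_onset_ms)
    samples[ramp] = amp * (1.0 - np.cos(np.pi * phase)) / 2.0
    rec = t_ms > lat_ms
    phase_r = np.minimum((t_ms[rec] - lat_ms) / params.recovery_ms, 1.0)
    samples[rec] = amp * (1.0 + np.cos(np.pi * phase_r)) / 2.0

    return MRCPTemplate(
        samples=samples,
        fs=fs,
        cue_index=cue_index,
        true_pn_index=pn_index,
        true_pn_amplitude=amp,
    )


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f noise via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]  # avoid the DC singularity
    spec /= np.sqrt(f)
    pink = np.fft.irfft(spec, n)
    pink -= pink.mean()
    sd = pink.std()
    return pink / sd if sd > 0 else pink


def _shift(x: np.ndarray, k: int) -> np.ndarray:
    """Shift right by k samples (left if negative), zero-padding the edge."""
    if k == 0:
        return x.copy()
    out = np.zeros_like(x)
    if k > 0:
        out[k:] = x[:-k]
    else:
        out[:k] = x[-k:]
    return out


def simulate_epoch(
    template: MRCPTemplate,
    params: ConditionParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, bool]:
    """One epoch: scaled, jittered template + background noise (+ artefact).

    Returns ``(epoch, is_artefact)``; the artefact flag is ground truth only
    and never exposed to the simulated raters. With all variability
    parameters at zero the epoch equals the template exactly.
    """
    n = template.samples.size
    scale = 1.0 + (
        _truncnorm(rng, 0.0, params.epoch_scale_sd) if params.epoch_scale_sd > 0 else 0.0
    )
    scale = max(scale, 0.1)
    jitter_ms = rng.normal(0.0, params.pn_latency_jitter_sd_ms) if params.pn_latency_jitter_sd_ms > 0 else 0.0
    shift = int(round(jitter_ms * template.fs / 1000.0))
    epoch = scale * _shift(template.samples, shift)

    if params.background_noise_sd > 0:
        pf = params.pink_noise_fraction
        noise = np.sqrt(1.0 - pf) * rng.standard_normal(n)
        if pf > 0:
            noise += np.sqrt(pf) * _pink_noise(n, rng)
        # cortical signal and background EEG share the same volume-conduction
        # attenuation, so the noise floor scales with the dataset's drawn
        # amplitude: per-participant SNR is far more stable than raw amplitude
        atten = template.true_pn_amplitude / params.pn_amplitude_mean
        epoch = epoch + params.background_noise_sd * atten * noise

    is_artefact = bool(rng.random() < params.artefact_prob)
    if is_artefact:
        # blink-like low-frequency bump, large enough to survive a 0.05-5 Hz
        # band-pass and dominate the template
        amp = max(params.artefact_amplitude, 3.0 * abs(template.true_pn_amplitude))
        centre = rng.uniform(0, n)
        width = rng.uniform(0.2, 0.4) * template.fs  # 200-400 ms SD
        idx = np.arange(n)
        epoch = epoch + amp * np.exp(-0.5 * ((idx - centre) / width) ** 2)
    return epoch, is_artefact


def simulate_dataset(
    condition: str,
    participant_id: int,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> SimulatedDataset:
    """Simulate one dataset (default 50 epochs) with ground truth.

    The RNG stream is derived from ``(config.seed, "dataset", condition,
    participant_id)`` unless an explicit generator is passed.
    """
    if condition not in config.condition_params:
        raise ValueError(f"no parameters configured for condition {condition!r}")
    params = config.condition_params[condition]
    if rng is None:
        rng = child_rng(config.seed, "dataset", condition, participant_id)
    template = make_template(params, config.fs, config.pre_s, config.post_s, rng)
    epochs = np.empty((config.n_epochs, template.samples.size))
    flags = np.zeros(config.n_epochs, dtype=bool)
    for i in range(config.n_epochs):
        epochs[i], flags[i] = simulate_epoch(template, params, rng)
    es = EpochSet(
        dataset_id=f"{condition}-{participant_id:02d}",
        condition=condition,
        epochs=epochs,
        fs=config.fs,
        cue_index=template.cue_index,
    )
    return SimulatedDataset(
        epochs=es,
        true_pn_index=template.true_pn_index,
        true_pn_latency_ms=template.true_pn_latency_ms,
        true_pn_amplitude=template.true_pn_amplitude,
        artefact_flags=flags,
    )


def simulate_study(
    config: SimulationConfig, conditions: Sequence[str] = CONDITIONS
) -> list[SimulatedDataset]:
    """All datasets of the study design (default 3 conditions x 10 datasets)."""
    return [
        simulate_dataset(cond, pid, config)
        for cond in conditions
        for pid in range(config.n_datasets_per_condition)
    ]


def simulate_continuous(
    condition: str,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    participant_id: int = 0,
) -> tuple[ContinuousRecording, np.ndarray]:
    """Thin multi-channel continuous recording for pipeline testing.

    MRCP activity is injected around each cue, full amplitude at Cz and
    attenuated on surrounding channels, so the Cz-centred Laplacian recovers
    the waveform. Consecutive cues are separated by a focus interval (2-3 s)
    plus a ~1 s movement hold plus a rest interval (6-8 s). Returns the
    recording and the cue times in seconds (strictly increasing, one per
    epoch).
    """
    if config.n_epochs < 1:
        raise ValueError("need at least one epoch")
    params = config.condition_params[condition]
    if rng is None:
        rng = child_rng(config.seed, "continuous", condition, participant_id)
    template = make_template(params, config.fs, config.pre_s, config.post_s, rng)

    cues = [config.pre_s + 1.0]
    for _ in range(config.n_epochs - 1):
        focus = rng.uniform(2.0, 3.0)
        rest = rng.uniform(6.0, 8.0)
        cues.append(cues[-1] + focus + 1.0 + rest)
    cue_times = np.asarray(cues)
    n_total = int(round((cue_times[-1] + config.post_s + 1.0) * config.fs))

    data = np.zeros((len(MONTAGE), n_total))
    pre_n = template.cue_index
    for cue in cue_times:
        c = int(np.floor(cue * config.fs + 0.5))
        start = c - pre_n
        stop = start + template.samples.size
        epoch, _ = simulate_epoch(
            template, replace(params, artefact_prob=0.0, background_noise_sd=0.0), rng
        )
        for ci, name in enumerate(MONTAGE):
            data[ci, start:stop] += _SPREAD[name] * epoch
    if params.background_noise_sd > 0:
        pf = params.pink_noise_fraction
        for ci in range(len(MONTAGE)):
            noise = np.sqrt(1.0 - pf) * rng.standard_normal(n_total)
            if pf > 0:
                noise += np.sqrt(pf) * _pink_noise(n_total, rng)
            data[ci] += params.background_noise_sd * noise
    rec = ContinuousRecording(channel_names=list(MONTAGE), data=data, fs=config.fs)
    return rec, cue_times


# ---------------------------------------------------------------------------
# Simulated raters
# ---------------------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_rater_decisions(
    epochs: EpochSet,
    cs: Sequence[float],
    profile: RaterProfile,
    session: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Accept/reject decisions for one rater at one session.

    accept ~ Bernoulli(sigmoid(intercept + slope * cosine_similarity)),
    independent across sessions given the similarity (no rater memory).
    Returns a long DataFrame: dataset_id, rater_id, session, epoch_index,
    accept.
    """
    cs = np.asarray(cs, dtype=float)
    if cs.size != epochs.n_epochs:
        raise ValueError("need one cosine-similarity value per epoch")
    slope = profile.slope_for(epochs.condition)
    p = _sigmoid(profile.accept_intercept + slope * cs)
    accept = rng.random(cs.size) < p
    return pd.DataFrame(
        {
            "dataset_id": epochs.dataset_id,
            "rater_id": profile.rater_id,
            "session": int(session),
            "epoch_index": np.arange(cs.size),
            "accept": accept,
        }
    )


def simulate_rater_label(
    avg: AverageMRCP,
    profile: RaterProfile,
    rng: np.random.Generator,
    window_ms: tuple[float, float] | None = None,
) -> float:
    """A rater's PN latency label (ms relative to cue) for an average MRCP.

    label = automated PN latency + rater bias + N(0, pn_noise_sd_ms). The
    implied two-way ICC across raters is
    sigma2_dataset / (sigma2_dataset + sigma2_bias + sigma2_noise).
    Raises on a degenerate (constant) average, like the automated labeller.
    """
    kwargs = {} if window_ms is None else {"window_ms": window_ms}
    auto = label_pn(avg, **kwargs)
    noise = rng.normal(0.0, profile.pn_noise_sd_ms) if profile.pn_noise_sd_ms > 0 else 0.0
    return float(auto.pn_ms + profile.pn_bias_ms + noise)
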