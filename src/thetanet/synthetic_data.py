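"""Ground-truth LFP simulator: shared theta sources, state schedules, 1/f noise.

Each brain region's signal is a linear mixture of a small number of
phase-diffusion theta oscillators plus independent pink (1/f) background:

    x_r(t) = sum_s w_rs * A_s(t) * cos(2*pi*f_s*t + phi_s(t - d_rs)) + n_r(t)

The oscillator phase performs a Brownian walk (variance ``phase_diffusion``
rad^2 per second), which gives a Lorentzian spectral line of controllable
width around the center frequency — narrow ~8 Hz peaks for the social
("high theta") regime, ~5 Hz for the fear-recall ("low theta") regime.
Amplitude envelopes A_s(t) follow the behavioral paradigm: a linear onset
ramp when a stimulus appears, novelty-scaled plateaus across repeated
encounters, and exponential persistence after stimulus removal.

The default topology encodes two independent theta generators: a
"bulb" source feeding the olfactory bulb channels (MOB, AOB) and a "limbic"
source feeding the amygdala/septal/piriform channels (MeA, LS, Pir).
Fear-recall sessions add a network-wide low-theta "fear" source.

Because the mixture is linear with independent noise, expected PSD peaks and
expected coherence have closed forms; those analytic values are stored in a
GroundTruth sidecar so every downstream estimator can be checked by
parameter recovery.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
from scipy.fft import rfft, irfft

from .signal_io import Period, Session, ValidationError
from .spectral import make_dpss_window

DEFAULT_REGIONS = ("MOB", "AOB", "MeA", "LS", "Pir")

#: default mixing weights of the two-generator topology
DEFAULT_WEIGHTS: dict[str, dict[str, float]] = {
    "MOB": {"bulb": 1.0},
    "AOB": {"bulb": 0.9},
    "MeA": {"limbic": 1.0},
    "LS": {"limbic": 0.9},
    "Pir": {"limbic": 0.7},
    "NAcc": {"limbic": 0.5},
}


def _child_rng(seed: int, name: str) -> np.random.Generator:
    """Independent, name-keyed RNG stream.

    Streams are keyed by (seed, crc32(name)) so adding a region or source
    never perturbs the noise of existing ones.
    """
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])
    )


# ---------------------------------------------------------------------------
# Primitive generators
# ---------------------------------------------------------------------------

def pink_noise(n: int, fs: float, level: float = 1.0, alpha: float = 1.0,
               rng: np.random.Generator | None = None) -> np.ndarray:
    """Gaussian background with one-sided PSD ``level^2 / max(f, 1)^alpha`` uV^2/Hz.

    Shaped in the frequency domain; the density flattens below 1 Hz so the
    spectrum integrates.  ``level`` is thus the amplitude density (uV/sqrt(Hz))
    at 1 Hz.  alpha=0 is white noise above DC.
    """
    if n < 2:
        raise ValidationError("pink_noise needs n >= 2 samples")
    if alpha < 0:
        raise ValidationError(f"spectral exponent alpha must be >= 0, got {alpha}")
    rng = rng or np.random.default_rng()
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    density = level ** 2 / np.maximum(freqs, 1.0) ** alpha      # one-sided, uV^2/Hz
    sigma = np.sqrt(density * fs * n / 2.0)                      # E|X_k|^2 target
    z = sigma * (rng.standard_normal(len(freqs))
                 + 1j * rng.standard_normal(len(freqs))) / np.sqrt(2.0)
    z[0] = 0.0
    if n % 2 == 0:
        z[-1] = z[-1].real * np.sqrt(2.0)
    return irfft(z, n=n)


@dataclass(frozen=True)
class ThetaSource:
    """A phase-diffusion oscillator: center frequency, linewidth control, amplitude."""

    name: str
    center_freq_hz: float = 8.0
    phase_diffusion: float = 5.0   # rad^2/s; Lorentzian HWHM = D / (4*pi) Hz
    base_amp: float = 5.0          # uV at multiplier 1

    def __post_init__(self) -> None:
        if self.center_freq_hz <= 0:
            raise ValidationError("center_freq_hz must be positive")
        if self.phase_diffusion < 0:
            raise ValidationError("phase_diffusion must be >= 0")


@dataclass
class StateSchedule:
    """Per-period amplitude multipliers with ramped onsets and decaying offsets.

    ``multipliers`` maps period names to target amplitude multipliers; periods
    without an entry hold the running level.  Periods whose names start with a
    ``ramp_prefixes`` entry approach their target linearly over
    ``onset_ramp_s``; periods starting with a ``decay_prefixes`` entry relax
    exponentially toward their target with time constant ``post_decay_tau_s``
    (``None`` means an immediate jump — no persistence).
    """

    multipliers: dict[str, float] = field(default_factory=dict)
    onset_ramp_s: float = 15.0
    post_decay_tau_s: float | None = 60.0
    initial_multiplier: float = 1.0
    ramp_prefixes: tuple[str, ...] = ("Enc", "Tone")
    decay_prefixes: tuple[str, ...] = ("Post",)

    def __post_init__(self) -> None:
        if self.onset_ramp_s < 0:
            raise ValidationError("onset_ramp_s must be >= 0")
        if any(m < 0 for m in self.multipliers.values()):
            raise ValidationError("amplitude multipliers must be >= 0")


def build_envelope(schedule: StateSchedule, timeline: Sequence[Period],
                   fs: float, total_s: float) -> np.ndarray:
    """Amplitude-multiplier time course over [0, total_s) at sampling rate fs."""
    n = int(round(total_s * fs))
    env = np.full(n, schedule.initial_multiplier, dtype=float)
    level = schedule.initial_multiplier
    for p in sorted(timeline, key=lambda q: q.start_s):
        if p.name not in schedule.multipliers:
            continue
        target = schedule.multipliers[p.name]
        i0 = int(round(p.start_s * fs))
        i1 = min(int(round(p.end_s * fs)), n)
        if i1 <= i0:
            continue
        t = np.arange(i1 - i0) / fs
        if p.name.startswith(schedule.ramp_prefixes) and schedule.onset_ramp_s > 0:
            ramp = np.clip(t / schedule.onset_ramp_s, 0.0, 1.0)
            seg = level + (target - level) * ramp
        elif p.name.startswith(schedule.decay_prefixes) and schedule.post_decay_tau_s:
            seg = target + (level - target) * np.exp(-t / schedule.post_decay_tau_s)
        else:
            seg = np.full(i1 - i0, target)
        env[i0:i1] = seg
        env[i1:] = seg[-1]          # hold until the next scheduled period
        level = seg[-1]
    return env


def render_source(src: ThetaSource, schedule: StateSchedule,
                  timeline: Sequence[Period], fs: float, total_s: float,
                  rng: np.random.Generator) -> np.ndarray:
    """s(t) = base_amp * A(t) * cos(2*pi*f0*t + phi(t)), phi a Brownian walk."""
    _check_no_overlap([p for p in timeline if p.name in schedule.multipliers])
    n = int(round(total_s * fs))
    t = np.arange(n) / fs
    if src.phase_diffusion > 0:
        dphi = rng.standard_normal(n) * np.sqrt(src.phase_diffusion / fs)
        phi = np.cumsum(dphi)
    else:
        phi = 0.0
    env = build_envelope(schedule, timeline, fs, total_s)
    return src.base_amp * env * np.cos(2 * np.pi * src.center_freq_hz * t + phi)


def _check_no_overlap(periods: Sequence[Period]) -> None:
    ordered = sorted(periods, key=lambda p: p.start_s)
    for a, b in zip(ordered, ordered[1:]):
        if b.start_s < a.end_s - 1e-12:
            raise ValidationError(
                f"scheduled periods {a.name!r} and {b.name!r} overlap"
            )


# ---------------------------------------------------------------------------
# Mixing and analytic oracles
# ---------------------------------------------------------------------------

@dataclass
class RegionMixing:
    """Linear source->region weights plus independent pink background per region."""

    weights: dict[str, dict[str, float]]                  # region -> {source: w}
    noise_level: float | dict[str, float] = 1.0           # uV/sqrt(Hz) at 1 Hz
    noise_exponent: float = 1.0
    delays_s: dict[tuple[str, str], float] = field(default_factory=dict)

    def weight(self, region: str, source: str) -> float:
        return self.weights.get(region, {}).get(source, 0.0)

    def level(self, region: str) -> float:
        if isinstance(self.noise_level, Mapping):
            return float(self.noise_level[region])
        return float(self.noise_level)

    def noise_density(self, region: str, freq_hz: float) -> float:
        """One-sided background density (uV^2/Hz) at freq_hz."""
        return self.level(region) ** 2 / max(freq_hz, 1.0) ** self.noise_exponent


def lorentzian_density(freq_hz: np.ndarray | float, src: ThetaSource,
                       amp_mult: float = 1.0) -> np.ndarray | float:
    """One-sided PSD (uV^2/Hz) of the phase-diffusion oscillator.

    The autocovariance is ``(A^2/2) exp(-D|tau|/2) cos(2 pi f0 tau)``, so the
    spectrum is a pair of Lorentzians of half-width-at-half-maximum
    ``D / (4 pi)`` Hz centered at +-f0.
    """
    a = src.phase_diffusion / 2.0
    amp = src.base_amp * amp_mult
    f = np.asarray(freq_hz, dtype=float)
    if a == 0:
        raise ValidationError("zero-diffusion line has no finite density; use D > 0")
    def l2(off):                     # two-sided Lorentzian, unit area over f in Hz
        return 2 * a / (a ** 2 + (2 * np.pi * off) ** 2)
    s2 = (amp ** 2 / 4.0) * (l2(f - src.center_freq_hz) + l2(f + src.center_freq_hz))
    return 2.0 * s2


def expected_welch_peak_density(src: ThetaSource, amp_mult: float, fs: float,
                                window_s: float = 1.0, nw: float = 3.0,
                                n_grid: int = 1 << 15) -> float:
    """Expected Welch-PSD value at the source center frequency (uV^2/Hz).

    The Welch estimator's expectation is the true two-sided spectrum
    convolved with the taper's spectral window.  For lines narrower than the
    window bandwidth the measured peak is window-limited; for broad lines it
    approaches the Lorentzian peak.  Computed by direct numerical convolution
    (an expectation formula — independent of the estimator implementation).
    """
    taper = make_dpss_window(window_s, fs, nw, 0)
    m = len(taper)
    nfft = max(n_grid, 4 * m)
    w = np.fft.fft(taper, nfft)
    kernel = np.abs(w) ** 2                         # |W(nu)|^2 on the fft grid
    nu = np.fft.fftfreq(nfft, d=1.0 / fs)
    a = src.phase_diffusion / 2.0
    amp = src.base_amp * amp_mult
    f0 = src.center_freq_hz
    s2 = (amp ** 2 / 4.0) * (
        2 * a / (a ** 2 + (2 * np.pi * (nu - f0)) ** 2)
        + 2 * a / (a ** 2 + (2 * np.pi * (nu + f0)) ** 2)
    )
    dnu = fs / nfft
    # E[S_hat(f0)] one-sided = (2/fs) * integral S2(nu) |W(nu - f0)|^2 dnu
    shift = int(round(f0 / dnu))
    return float((2.0 / fs) * np.sum(s2 * np.roll(kernel, shift)) * dnu)


def effective_source_density(src: ThetaSource, amp_mult: float,
                             half_bw_hz: float) -> float:
    """Band-averaged source density over +-half_bw_hz around the center (uV^2/Hz).

    This is what a multitaper estimator of bandwidth W sees at the line
    center: the fraction ``(2/pi) atan(2 pi W / a)`` of the line's power,
    spread over 2W.
    """
    if half_bw_hz <= 0:
        raise ValidationError("half_bw_hz must be positive")
    a = src.phase_diffusion / 2.0
    amp = src.base_amp * amp_mult
    total = amp ** 2 / 2.0
    frac = 1.0 if a == 0 else (2.0 / np.pi) * np.arctan(2 * np.pi * half_bw_hz / a)
    return total * frac / (2.0 * half_bw_hz)


def analytic_coherence(mix: RegionMixing, src_densities: Mapping[str, float],
                       pair: tuple[str, str], freq_hz: float) -> float:
    """Expected magnitude coherence of a region pair under linear mixing.

    ``Coh_ij = |sum_s w_is w_js S_s| / sqrt((sum_s w_is^2 S_s + N_i)(sum_s w_js^2 S_s + N_j))``
    with S_s the per-source densities at the evaluation frequency and N the
    independent background densities.
    """
    ri, rj = pair
    cross = sum(mix.weight(ri, s) * mix.weight(rj, s) * d
                for s, d in src_densities.items())
    auto_i = sum(mix.weight(ri, s) ** 2 * d for s, d in src_densities.items())
    auto_j = sum(mix.weight(rj, s) ** 2 * d for s, d in src_densities.items())
    auto_i += mix.noise_density(ri, freq_hz)
    auto_j += mix.noise_density(rj, freq_hz)
    if auto_i == 0 or auto_j == 0:
        return 0.0
    return float(abs(cross) / np.sqrt(auto_i * auto_j))


# ---------------------------------------------------------------------------
# Paradigm sessions
# ---------------------------------------------------------------------------

@dataclass
class SrmConfig:
    """Habituation-dishabituation (SRM) session: regions, sources, schedule.

    Defaults follow the behavioral paradigm: a 5-min no-stimulus baseline,
    then five trials of 15-s stimulus transfer + 5-min encounter + 5-min
    post period; encounter amplitudes scale with stimulus novelty
    (habituation across Enc1-4, dishabituation rebound at Enc5).  The social
    stimulus drives both theta generators with post-encounter persistence;
    the object stimulus drives only the bulb generator, weakly and without
    persistence.
    """

    stimulus: str = "social"                       # "social" | "object"
    regions: tuple[str, ...] = DEFAULT_REGIONS
    fs: float = 1000.0
    base_s: float = 300.0
    enc_s: float = 300.0
    post_s: float = 300.0
    transfer_s: float = 15.0
    n_trials: int = 5
    novelty: tuple[float, ...] = (1.0, 0.8, 0.65, 0.5, 1.0)
    bulb_gain: float | None = None                 # resolved from stimulus type
    limbic_gain: float | None = None
    onset_ramp_s: float = 15.0
    post_decay_tau_s: float | None = 60.0
    high_freq_hz: float = 8.0
    phase_diffusion: float = 5.0
    source_amp: float = 5.0
    noise_level: float = 1.0
    noise_exponent: float = 1.0
    weights: dict[str, dict[str, float]] | None = None
    delays_s: dict[tuple[str, str], float] = field(default_factory=dict)
    subject_gain: float = 1.0                      # per-subject effect-size factor
    annotate_it: bool = True                       # investigation-time meta
    anticipatory_onset: bool = False               # ramp during the 15-s transfer

    def __post_init__(self) -> None:
        if self.stimulus not in ("social", "object"):
            raise ValidationError(f"unknown stimulus type {self.stimulus!r}")
        if len(self.novelty) < self.n_trials:
            raise ValidationError("need one novelty multiplier per trial")
        if self.bulb_gain is None:
            self.bulb_gain = 1.05 if self.stimulus == "social" else 0.3
        if self.limbic_gain is None:
            self.limbic_gain = 0.7 if self.stimulus == "social" else 0.0
        if self.stimulus == "object":
            self.post_decay_tau_s = None           # no persistence after objects
        if self.weights is None:
            self.weights = {r: dict(DEFAULT_WEIGHTS.get(r, {})) for r in self.regions}

    def mixing(self) -> RegionMixing:
        return RegionMixing(self.weights, self.noise_level, self.noise_exponent,
                            dict(self.delays_s))

    def sources(self) -> dict[str, ThetaSource]:
        return {
            "bulb": ThetaSource("bulb", self.high_freq_hz, self.phase_diffusion,
                                self.source_amp),
            "limbic": ThetaSource("limbic", self.high_freq_hz, self.phase_diffusion,
                                  self.source_amp),
        }

    def timeline(self) -> list[Period]:
        periods = [Period("Base", 0.0, self.base_s)]
        t = self.base_s
        for k in range(1, self.n_trials + 1):
            periods.append(Period(f"Transfer{k}", t, t + self.transfer_s))
            t += self.transfer_s
            periods.append(Period(f"Enc{k}", t, t + self.enc_s))
            if k == 1:
                periods.append(Period("Stimulus", t, t + 15.0))
            t += self.enc_s
            periods.append(Period(f"Post{k}", t, t + self.post_s))
            t += self.post_s
        return periods

    def total_s(self) -> float:
        return self.base_s + self.n_trials * (self.transfer_s + self.enc_s + self.post_s)

    def schedules(self) -> dict[str, StateSchedule]:
        gains = {"bulb": self.bulb_gain, "limbic": self.limbic_gain}
        out = {}
        for name, gain in gains.items():
            mult = {"Base": 1.0}
            for k in range(1, self.n_trials + 1):
                target = 1.0 + gain * self.novelty[k - 1] * self.subject_gain
                mult[f"Enc{k}"] = target
                mult[f"Post{k}"] = 1.0
                if self.anticipatory_onset:
                    # arousal rises in anticipation, while the stimulus is
                    # being transferred into the arena
                    mult[f"Transfer{k}"] = target
            ramps = ("Enc", "Tone", "Transfer") if self.anticipatory_onset \
                else ("Enc", "Tone")
            out[name] = StateSchedule(mult, self.onset_ramp_s,
                                      self.post_decay_tau_s, ramp_prefixes=ramps)
        return out


@dataclass
class GroundTruth:
    """Generator parameters plus analytic expectations for recovery tests."""

    kind: str
    seed: int
    params: dict
    analytic_tp_db: dict[str, dict[str, float]]            # region -> period -> dB/Hz
    analytic_coherence: dict[str, dict[str, float]]        # "R1-R2" -> period -> coh

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True, default=str)


def _steady_multiplier(schedule: StateSchedule, period: str) -> float:
    return schedule.multipliers.get(period, schedule.initial_multiplier)


def _session_ground_truth(kind: str, seed: int, cfg, sources: dict[str, ThetaSource],
                          schedules: dict[str, StateSchedule], mix: RegionMixing,
                          regions: Sequence[str], periods: Sequence[str],
                          eval_freq: float, half_bw_hz: float = 1.5) -> GroundTruth:
    tp: dict[str, dict[str, float]] = {}
    for r in regions:
        tp[r] = {}
        for p in periods:
            dens = mix.noise_density(r, eval_freq)
            for s_name, src in sources.items():
                w = mix.weight(r, s_name)
                if w == 0.0:
                    continue
                m = _steady_multiplier(schedules[s_name], p)
                dens += w ** 2 * expected_welch_peak_density(src, m, cfg.fs)
            tp[r][p] = float(10 * np.log10(max(dens, 1e-30)))
    coh: dict[str, dict[str, float]] = {}
    for i, ri in enumerate(regions):
        for rj in regions[i + 1:]:
            key = f"{ri}-{rj}"
            coh[key] = {}
            for p in periods:
                dens = {}
                for s, src in sources.items():
                    m = _steady_multiplier(schedules[s], p)
                    if abs(src.center_freq_hz - eval_freq) <= half_bw_hz:
                        dens[s] = effective_source_density(src, m, half_bw_hz)
                    else:  # off-band source: only its Lorentzian tail contributes
                        dens[s] = float(lorentzian_density(eval_freq, src, m))
                coh[key][p] = analytic_coherence(mix, dens, (ri, rj), eval_freq)
    params = {k: v for k, v in asdict(cfg).items() if k != "delays_s"}
    params["delays_s"] = {f"{r}:{s}": d for (r, s), d in cfg.delays_s.items()}
    return GroundTruth(kind, seed, params, tp, coh)


def _render_session(regions: Sequence[str], sources: dict[str, ThetaSource],
                    schedules: dict[str, StateSchedule], mix: RegionMixing,
                    timeline: Sequence[Period], fs: float, total_s: float,
                    seed: int) -> np.ndarray:
    n = int(round(total_s * fs))
    rendered = {
        name: render_source(src, schedules[name], timeline, fs, total_s,
                            _child_rng(seed, f"source:{name}"))
        for name, src in sources.items()
    }
    signals = np.zeros((len(regions), n))
    for i, r in enumerate(regions):
        x = pink_noise(n, fs, mix.level(r), mix.noise_exponent,
                       _child_rng(seed, f"noise:{r}"))
        for s_name in sources:
            w = mix.weight(r, s_name)
            if w == 0.0:
                continue
            src_sig = rendered[s_name]
            d = int(round(mix.delays_s.get((r, s_name), 0.0) * fs))
            if d != 0:
                # region sees the source d samples late (positive delay)
                shifted = np.zeros_like(src_sig)
                if d > 0:
                    shifted[d:] = src_sig[:-d]
                else:
                    shifted[:d] = src_sig[-d:]
                src_sig = shifted
            x = x + w * src_sig
        signals[i] = x
    return signals


def synthesize_srm_session(config: SrmConfig | None = None,
                           seed: int = 0) -> tuple[Session, GroundTruth]:
    """Render a full habituation-dishabituation session with ground truth."""
    cfg = config or SrmConfig()
    timeline = cfg.timeline()
    sources = cfg.sources()
    schedules = cfg.schedules()
    mix = cfg.mixing()
    signals = _render_session(cfg.regions, sources, schedules, mix, timeline,
                              cfg.fs, cfg.total_s(), seed)
    meta: dict = {"paradigm": f"SRM-{cfg.stimulus}", "seed": seed}
    if cfg.annotate_it:
        # investigation time tracks novelty (~40 s of a 300-s encounter at peak)
        meta["investigation_time_s"] = {
            f"Enc{k}": round(40.0 * cfg.novelty[k - 1], 1)
            for k in range(1, cfg.n_trials + 1)
        }
    session = Session(signals, cfg.fs, list(cfg.regions), timeline, meta)
    period_names = ["Base"] + [f"Enc{k}" for k in range(1, cfg.n_trials + 1)] + \
        [f"Post{k}" for k in range(1, cfg.n_trials + 1)]
    gt = _session_ground_truth(f"srm-{cfg.stimulus}", seed, cfg, sources, schedules,
                               mix, cfg.regions, period_names, cfg.high_freq_hz)
    return session, gt


@dataclass
class FcConfig:
    """Fear-recall session: tone periods activate a network-wide low-theta source.

    Baseline 5 min, then ``n_tones`` conditioned-tone presentations (40 s each,
    180-s inter-trial interval), so tones start at 300, 520, 740, ... s.  The
    first 15 s of each tone is its Stimulus analysis window.  The fear source
    (~5 Hz) ramps in quickly (fear onset is fast compared to the 15-s social
    transfer) and switches off after each tone.
    """

    regions: tuple[str, ...] = DEFAULT_REGIONS + ("NAcc",)
    fs: float = 1000.0
    base_s: float = 300.0
    tone_s: float = 40.0
    iti_s: float = 180.0
    n_tones: int = 5
    fear_freq_hz: float = 5.0
    fear_gain: float = 4.0                      # tone amplitude multiplier = 1 + gain
    fear_amp: float = 1.5                       # uV at multiplier 1 (weak at rest)
    fear_weight: float = 1.0                    # network-wide mixing weight
    onset_ramp_s: float = 2.0
    high_freq_hz: float = 8.0
    phase_diffusion: float = 5.0
    source_amp: float = 5.0
    noise_level: float = 1.0
    noise_exponent: float = 1.0
    weights: dict[str, dict[str, float]] | None = None
    delays_s: dict[tuple[str, str], float] = field(default_factory=dict)
    subject_gain: float = 1.0

    def __post_init__(self) -> None:
        if self.weights is None:
            self.weights = {r: dict(DEFAULT_WEIGHTS.get(r, {})) for r in self.regions}
            for r in self.regions:
                self.weights[r]["fear"] = self.fear_weight

    def mixing(self) -> RegionMixing:
        return RegionMixing(self.weights, self.noise_level, self.noise_exponent,
                            dict(self.delays_s))

    def sources(self) -> dict[str, ThetaSource]:
        return {
            "bulb": ThetaSource("bulb", self.high_freq_hz, self.phase_diffusion,
                                self.source_amp),
            "limbic": ThetaSource("limbic", self.high_freq_hz, self.phase_diffusion,
                                  self.source_amp),
            "fear": ThetaSource("fear", self.fear_freq_hz, self.phase_diffusion,
                                self.fear_amp),
        }

    def timeline(self) -> list[Period]:
        periods = [Period("Base", 0.0, self.base_s)]
        for k in range(1, self.n_tones + 1):
            t0 = self.base_s + (k - 1) * (self.tone_s + self.iti_s)
            periods.append(Period(f"Tone{k}", t0, t0 + self.tone_s))
            periods.append(Period(f"Stim{k}", t0, t0 + 15.0))
        return periods

    def total_s(self) -> float:
        return self.base_s + self.n_tones * (self.tone_s + self.iti_s)

    def schedules(self) -> dict[str, StateSchedule]:
        fear_mult = {"Base": 1.0}
        for k in range(1, self.n_tones + 1):
            fear_mult[f"Tone{k}"] = 1.0 + self.fear_gain * self.subject_gain
        flat = StateSchedule({"Base": 1.0}, self.onset_ramp_s, None)
        return {
            "bulb": flat,
            "limbic": StateSchedule({"Base": 1.0}, self.onset_ramp_s, None),
            "fear": StateSchedule(fear_mult, self.onset_ramp_s, None),
        }


def synthesize_fc_session(config: FcConfig | None = None,
                          seed: int = 0) -> tuple[Session, GroundTruth]:
    """Render a fear-memory-recall session with ground truth."""
    cfg = config or FcConfig()
    timeline = cfg.timeline()
    sources = cfg.sources()
    schedules = cfg.schedules()
    mix = cfg.mixing()
    # Tone/Stim windows overlap by construction; overlap checking applies to
    # the scheduled (multiplier-bearing) periods only, which are disjoint.
    signals = _render_session(cfg.regions, sources, schedules, mix, timeline,
                              cfg.fs, cfg.total_s(), seed)
    session = Session(signals, cfg.fs, list(cfg.regions), timeline,
                      {"paradigm": "FC-recall", "seed": seed})
    period_names = ["Base"] + [f"Tone{k}" for k in range(1, cfg.n_tones + 1)]
    gt = _session_ground_truth("fc-recall", seed, cfg, sources, schedules, mix,
                               cfg.regions, period_names, cfg.fear_freq_hz)
    return session, gt


def subject_gains(n_subjects: int, seed: int, sd: float = 0.15,
                  floor: float = 0.2) -> np.ndarray:
    """Per-subject multiplicative effect-size factors (between-animal variability)."""
    rng = _child_rng(seed, "subject-gains")
    return np.maximum(floor, 1.0 + sd * rng.standard_normal(n_subjects))


# ---------------------------------------------------------------------------
# Recovery fits for state dynamics
# ---------------------------------------------------------------------------

def fit_onset_ramp(times_s: np.ndarray, dtp_db: np.ndarray,
                   max_ramp_s: float = 60.0, grid_step_s: float = 0.25) -> float:
    """Estimate the onset ramp duration (s) from an instantaneous-TP series.

    The series is assumed to start at the stimulus onset with unit relative
    amplitude (ΔTP reference = mean Base).  Converts TP change to linear
    amplitude and least-squares fits ``a(t) = 1 + (hi - 1) min(t/T, 1)`` over
    a grid of ramp durations T; the plateau ``hi`` is the median of the last
    30% of the series.
    """
    t = np.asarray(times_s, dtype=float)
    a = 10.0 ** (np.asarray(dtp_db, dtype=float) / 20.0)
    hi = np.median(a[-max(3, int(0.3 * len(a))):])
    if hi <= 1.0:
        raise ValidationError("no rising step found in the series")
    grid = np.arange(grid_step_s, min(max_ramp_s, t[-1]) + grid_step_s, grid_step_s)
    sse = [np.sum((a - (1.0 + (hi - 1.0) * np.minimum(t / T, 1.0))) ** 2)
           for T in grid]
    return float(grid[int(np.argmin(sse))])


def fit_exp_decay_tau(times_s: np.ndarray, dtp_db: np.ndarray) -> float:
    """Recover the persistence time constant tau (s) from a decaying TP series.

    Nonlinear least squares of ``a(t) = 1 + c exp(-t/tau)`` on the linear
    amplitude series (fitting in the amplitude domain keeps the late, noisy
    near-baseline samples from dominating as they would on a log scale).
    """
    from scipy.optimize import curve_fit

    t = np.asarray(times_s, dtype=float)
    a = 10.0 ** (np.asarray(dtp_db, dtype=float) / 20.0)
    c0 = np.median(a[: max(3, len(a) // 20)]) - 1.0
    if c0 <= 0:
        raise ValidationError("series does not start above the baseline level")

    def model(tt, c, tau):
        return 1.0 + c * np.exp(-tt / tau)

    try:
        popt, _ = curve_fit(model, t, a, p0=(c0, max(t[-1] / 3.0, 1.0)),
                            bounds=([0.0, 0.1], [np.inf, 10.0 * t[-1]]),
                            maxfev=10000)
    except RuntimeError as exc:
        raise ValidationError(f"decay fit did not converge: {exc}") from None
    return float(popt[1])
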