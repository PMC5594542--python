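"""Synthetic EEG + EMG generator for the five-session force-load protocol.

The generator produces recordings with the statistical structure the
decoding analysis assumes:

* 1/f background noise on every channel;
* mu (8-13 Hz) and beta (14-30 Hz) band-limited oscillations radiating
  from a left sensorimotor focus (C3) with a weaker mirror source on the
  contralateral side (C4), their channel weights decaying exponentially
  with layout-distance rank;
* event-related desynchronization: during motor-execution and
  motor-imagery segments the oscillatory sources are attenuated
  multiplicatively by ``1 - depth``, where the depth is graded by the
  imagined force load (high > low > relaxed = 0) and ramps over 300 ms at
  segment edges;
* trial-to-trial variability: a lognormal per-trial oscillation gain and a
  lognormal per-segment jitter of the ERD depth, so that class-conditional
  band-power distributions overlap the way real motor-imagery data do;
* one EMG channel containing band-limited bursts only inside
  motor-execution segments, with burst amplitude scaled by load.

Session plans follow the experimental timeline: sessions 1-3 have two
blocks of ten trials (five 'high', five 'low', randomly ordered), each
trial being cue 2 s, motor execution 6 s, rest 4 s, motor imagery 6 s,
rest 4 s; session 4 has thirty 'relaxed' trials; session 5 has four blocks
of twelve trials (four per class, randomly ordered). Sessions 4 and 5 have
no motor-execution segment (cue 2 s, imagery 6 s, rest 4 s).

All randomness flows from explicit integer seeds; identical (plan, config,
seed) yield bit-identical sample arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import fft, signal

from . import montage
from .containers import EVENT_COLUMNS, Recording
from .errors import ConfigError

#: Trial timelines (segment name, duration in seconds).
SEGMENTS_EXEC: tuple[tuple[str, float], ...] = (
    ("cue", 2.0), ("ME", 6.0), ("rest", 4.0), ("MI", 6.0), ("rest", 4.0),
)
SEGMENTS_IMAGERY: tuple[tuple[str, float], ...] = (
    ("cue", 2.0), ("MI", 6.0), ("rest", 4.0),
)

LOADS = ("high", "low", "relaxed")


@dataclass(frozen=True)
class GeneratorConfig:
    """Free parameters of the synthetic recording generator.

    Amplitudes are standard deviations in microvolts. ``erd_depth_*`` are
    fractional amplitude attenuations in [0, 1] applied to the oscillatory
    sources during task segments. ``erd_depth_jitter`` is the sigma of a
    multiplicative lognormal jitter applied to the depth independently per
    task segment (so a zero depth stays exactly zero). ``amp_jitter`` is
    the sigma of a lognormal per-trial gain on the oscillation amplitude.
    """

    montage: tuple[str, ...] = montage.FULL_64
    include_emg: bool = True
    fs: float = 1000.0
    erd_depth_high: float = 0.5
    erd_depth_low: float = 0.25
    erd_depth_jitter: float = 0.2
    amp_jitter: float = 0.1
    erd_focus: str = "C3"
    spatial_decay: float = 3.0
    mirror_focus: str | None = "C4"
    mirror_gain: float = 0.3
    mu_band: tuple[float, float] = (8.0, 13.0)
    beta_band: tuple[float, float] = (14.0, 30.0)
    osc_amplitude: float = 3.0
    beta_gain: float = 0.5
    beta_depth_ratio: float = 1.2
    noise_amplitude: float = 1.0
    noise_exponent: float = 1.0
    line_freq: float = 50.0
    line_amplitude: float = 0.5
    apply_notch: bool = True
    emg_burst_amplitude: float = 40.0
    emg_low_scale: float = 0.6
    emg_noise_amplitude: float = 2.0
    emg_band: tuple[float, float] = (20.0, 450.0)
    ramp_s: float = 0.3
    lead_in_s: float = 2.0
    lead_out_s: float = 2.0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "montage", tuple(self.montage))
        if not 0.0 <= self.erd_depth_low <= self.erd_depth_high <= 1.0:
            raise ConfigError("require 0 <= erd_depth_low <= erd_depth_high <= 1")
        for name in ("mu_band", "beta_band"):
            lo, hi = getattr(self, name)
            if not 0.0 < lo < hi < self.fs / 2:
                raise ConfigError(f"{name} must lie inside (0, fs/2)")
        if self.erd_focus not in self.montage:
            raise ConfigError(f"erd_focus {self.erd_focus!r} not in montage")
        if self.mirror_focus is not None and self.mirror_gain > 0 \
                and self.mirror_focus not in self.montage:
            raise ConfigError(f"mirror_focus {self.mirror_focus!r} not in montage")
        if self.fs <= 0:
            raise ConfigError("fs must be positive")

    def depth(self, load: str) -> float:
        """Base ERD depth for a task load."""
        if load == "high":
            return self.erd_depth_high
        if load == "low":
            return self.erd_depth_low
        if load == "relaxed":
            return 0.0
        raise ConfigError(f"unknown load {load!r}")


@dataclass(frozen=True)
class TrialPlan:
    """Ordered trial labels and the per-trial segment timeline of a session."""

    session_id: int
    blocks: tuple[tuple[str, ...], ...]
    timeline: tuple[tuple[str, float], ...]

    def __post_init__(self):
        object.__setattr__(self, "blocks",
                           tuple(tuple(b) for b in self.blocks))
        object.__setattr__(self, "timeline",
                           tuple((s, float(d)) for s, d in self.timeline))
        bad = {lb for b in self.blocks for lb in b} - set(LOADS)
        if bad:
            raise ConfigError(f"unknown trial labels {sorted(bad)}")

    @property
    def trial_duration(self) -> float:
        return sum(d for _, d in self.timeline)

    @property
    def n_trials(self) -> int:
        return sum(len(b) for b in self.blocks)

    @property
    def trials(self) -> list[tuple[int, int, str]]:
        """Flat list of (block, trial_index_in_session, label)."""
        out, k = [], 0
        for bi, block in enumerate(self.blocks):
            for lb in block:
                out.append((bi, k, lb))
                k += 1
        return out


def plan_sessions(seed: int) -> list[TrialPlan]:
    """Reproducible trial plans for the five sessions of the protocol."""
    if seed < 0:
        raise ConfigError("seed must be a nonnegative integer")
    rng = np.random.default_rng(seed)
    plans: list[TrialPlan] = []
    for sid in (1, 2, 3):
        blocks = tuple(
            tuple(rng.permutation(["high"] * 5 + ["low"] * 5))
            for _ in range(2)
        )
        plans.append(TrialPlan(sid, blocks, SEGMENTS_EXEC))
    plans.append(TrialPlan(4, (("relaxed",) * 30,), SEGMENTS_IMAGERY))
    blocks5 = tuple(
        tuple(rng.permutation(["high"] * 4 + ["low"] * 4 + ["relaxed"] * 4))
        for _ in range(4)
    )
    plans.append(TrialPlan(5, blocks5, SEGMENTS_IMAGERY))
    return plans


def _pink_noise(rng: np.random.Generator, n_ch: int, n: int,
                exponent: float) -> np.ndarray:
    """Unit-variance 1/f^exponent noise, one independent row per channel.

    Synthesized by spectrally shaping white noise; the FFT runs at the
    next fast transform length and the result is truncated to ``n``.
    """
    if exponent == 0:
        return rng.standard_normal((n_ch, n), dtype=np.float32)
    # draw the spectrum directly: white noise is i.i.d. complex Gaussian in
    # the frequency domain, so one inverse FFT suffices. The scale is fixed
    # analytically (not from the realized std) so that every session draws
    # from exactly the same distribution -- an empirical per-session
    # normalization would imprint a session-level amplitude fingerprint
    # that a classifier could exploit.
    nf = fft.next_fast_len(n)
    m = nf // 2 + 1
    spec = (rng.standard_normal((n_ch, m), dtype=np.float32)
            + 1j * rng.standard_normal((n_ch, m), dtype=np.float32))
    f = np.fft.rfftfreq(nf)
    shaping = np.zeros(f.shape, dtype=np.float32)
    shaping[1:] = f[1:] ** np.float32(-exponent / 2.0)
    sigma = 2.0 * np.sqrt(np.sum(shaping.astype(np.float64) ** 2)) / nf
    x = fft.irfft(spec * shaping, n=nf, axis=1)[:, :n]
    x /= np.float32(sigma)
    return x


def _band_noise(rng: np.random.Generator, n: int, band: tuple[float, float],
                fs: float) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to ``band``.

    Normalized by the analytic output variance of the zero-phase filter
    (mean of |H|^4 over frequency), not the realized std, so all sessions
    share one amplitude scale.
    """
    lo, hi = band
    hi = min(hi, 0.49 * fs)
    sos = signal.butter(4, (lo, hi), btype="bandpass", fs=fs, output="sos")
    _, h = signal.sosfreqz(sos, worN=4096)
    sigma = np.sqrt(np.mean(np.abs(h) ** 4))
    return signal.sosfiltfilt(sos, rng.standard_normal(n)) / sigma


def _apply_attenuation(env: np.ndarray, i0: int, i1: int, depth: float,
                       n_ramp: int) -> None:
    """Multiply env[i0:i1] by an attenuation profile with edge ramps."""
    m = i1 - i0
    prof = np.full(m, 1.0 - depth)
    k = min(n_ramp, m // 2)
    if k > 0:
        prof[:k] = np.linspace(1.0, 1.0 - depth, k)
        prof[m - k:] = np.linspace(1.0 - depth, 1.0, k)
    env[i0:i1] *= prof


def synthesize_recording(plan: TrialPlan, cfg: GeneratorConfig,
                         seed: int | None = None) -> Recording:
    """Generate one continuous session recording from a trial plan.

    The stream used for the session's random draws is derived from
    ``(seed, plan.session_id)``, so different sessions of the same subject
    are independent while the whole subject is reproducible from one seed.
    """
    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng([int(seed), int(plan.session_id)])
    fs = cfg.fs
    n_trials = plan.n_trials
    total_s = cfg.lead_in_s + n_trials * plan.trial_duration + cfg.lead_out_s
    n = int(round(total_s * fs))
    eeg_labels = list(cfg.montage)
    n_eeg = len(eeg_labels)
    n_ramp = int(round(cfg.ramp_s * fs))

    # --- event table and modulation envelopes -------------------------------
    events = []
    atten = {"mu": np.ones(n), "beta": np.ones(n)}
    gain = np.ones(n)
    emg_spans = []  # (i0, i1, load)
    t_cursor = cfg.lead_in_s
    for block, trial, label in plan.trials:
        tr0 = int(round(t_cursor * fs))
        tr1 = int(round((t_cursor + plan.trial_duration) * fs))
        g = float(np.exp(rng.normal(0.0, cfg.amp_jitter)))
        gain[tr0:tr1] *= g
        seg_t = t_cursor
        for seg, dur in plan.timeline:
            events.append((seg_t, dur, seg, label,
                           plan.session_id, block, trial))
            i0 = int(round(seg_t * fs))
            i1 = int(round((seg_t + dur) * fs))
            if seg in ("ME", "MI"):
                base = cfg.depth(label)
                d = 0.0
                if base > 0:
                    d = min(1.0, base * float(np.exp(
                        rng.normal(0.0, cfg.erd_depth_jitter))))
                _apply_attenuation(atten["mu"], i0, i1, d, n_ramp)
                d_beta = min(1.0, d * cfg.beta_depth_ratio)
                _apply_attenuation(atten["beta"], i0, i1, d_beta, n_ramp)
                if seg == "ME":
                    emg_spans.append((i0, i1, label))
            seg_t += dur
        t_cursor += plan.trial_duration
    events = pd.DataFrame(events, columns=list(EVENT_COLUMNS))

    # --- EEG: 1/f background + focal oscillatory sources --------------------
    data = _pink_noise(rng, n_eeg, n, cfg.noise_exponent) * cfg.noise_amplitude

    sources = [(cfg.erd_focus, 1.0)]
    if cfg.mirror_focus is not None and cfg.mirror_gain > 0:
        sources.append((cfg.mirror_focus, cfg.mirror_gain))
    bands = [("mu", cfg.mu_band, cfg.osc_amplitude),
             ("beta", cfg.beta_band, cfg.osc_amplitude * cfg.beta_gain)]
    for focus, src_gain in sources:
        ranks = montage.rank_distance(eeg_labels, focus)
        weights = src_gain * np.exp(-ranks / cfg.spatial_decay)
        for name, band, amp in bands:
            series = (_band_noise(rng, n, band, fs)
                      * atten[name] * gain).astype(np.float32)
            data += np.outer((weights * amp).astype(np.float32), series)
    data = data.astype(np.float64)

    # --- EMG channel ---------------------------------------------------------
    if cfg.include_emg:
        lo, hi = cfg.emg_band
        emg = _band_noise(rng, n, (lo, hi), fs) * cfg.emg_noise_amplitude
        for i0, i1, label in emg_spans:
            scale = 1.0 if label == "high" else cfg.emg_low_scale
            m = i1 - i0
            burst = _band_noise(rng, m, (lo, hi), fs)
            env = np.ones(m)
            k = min(n_ramp, m // 2)
            if k > 0:
                env[:k] = np.linspace(0.0, 1.0, k)
                env[m - k:] = np.linspace(1.0, 0.0, k)
            emg[i0:i1] += burst * env * cfg.emg_burst_amplitude * scale
        data = np.vstack([data, emg[None, :]])
        labels = tuple(eeg_labels) + (montage.EMG_LABEL,)
    else:
        labels = tuple(eeg_labels)

    # --- acquisition-stage line interference and hardware notch -------------
    if cfg.line_amplitude > 0:
        phases = rng.uniform(0, 2 * np.pi, size=data.shape[0])
        period = fs / cfg.line_freq
        if abs(period - round(period)) < 1e-9:
            # integer samples per cycle: tile one period per channel
            p = int(round(period))
            k = np.arange(p)
            cycle = cfg.line_amplitude * np.sin(
                2 * np.pi * cfg.line_freq * k[None, :] / fs
                + phases[:, None])
            reps = int(np.ceil(n / p))
            data += np.tile(cycle, reps)[:, :n]
        else:
            t = np.arange(n) / fs
            data += cfg.line_amplitude * np.sin(
                2 * np.pi * cfg.line_freq * t[None, :] + phases[:, None])
    if cfg.apply_notch and 0 < cfg.line_freq < fs / 2:
        # forward-backward notch via lfilter (fast path; the lead-in
        # segment absorbs the unpadded edge transient)
        b, a = signal.iirnotch(cfg.line_freq, Q=30.0, fs=fs)
        data = signal.lfilter(b, a, data, axis=1)
        data = signal.lfilter(b, a, data[:, ::-1], axis=1)[:, ::-1]

    meta = {"session": plan.session_id, "seed": int(seed),
            "generator": "mfload.simulate"}
    return Recording(data, fs, labels, events, meta)


def simulate_subject(cfg: GeneratorConfig,
                     seed: int | None = None,
                     sessions: tuple[int, ...] = (1, 2, 3, 4, 5),
                     ) -> dict[int, Recording]:
    """All five sessions of one simulated subject, keyed by session id."""
    if seed is None:
        seed = cfg.seed
    plans = {p.session_id: p for p in plan_sessions(seed)}
    return {sid: synthesize_recording(plans[sid], cfg, seed)
            for sid in sessions}


def jittered_config(cfg: GeneratorConfig, seed: int,
                    depth_jitter_sd: float) -> GeneratorConfig:
    """Per-subject variant of ``cfg`` with ERD depths perturbed.

    Emulates between-subject variability in a simulated cohort: each
    subject's class depths are the defaults plus a seed-determined Gaussian
    offset, clipped so the high > low > relaxed ordering is preserved.
    """
    if depth_jitter_sd <= 0:
        return cfg
    rng = np.random.default_rng([int(seed), 97])
    dh, dl = rng.normal([cfg.erd_depth_high, cfg.erd_depth_low],
                        depth_jitter_sd)
    dl = float(np.clip(dl, 0.0, 1.0))
    dh = float(np.clip(dh, dl, 1.0))
    return replace(cfg, erd_depth_high=dh, erd_depth_low=dl)
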