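"""Seeded synthetic cohorts of annotated extracellular recordings.

The generator produces recordings with the statistical structure the
downstream analysis assumes, so that every injected effect is a
recoverable effect:

* power-law (``1/f``-like) background spectra whose lowest analysis band
  dominates the analysis range,
* a behavior schedule built as an alternating renewal process
  (round-robin over behaviors, log-normal episode lengths, exponential
  gaps),
* multiplicative band-power effects per (group, week, behavior),
* episode-length-coupled band power (negative for grooming, positive
  for sniffing),
* per-rat log-power intercepts shared across weeks (repeated-measures
  structure),
* mains interference at the base frequency plus harmonics, and
* excursion / saturation artifacts that trip both exclusion rules.

Seeding: one master seed in :class:`CohortDesign`.  Every session draws
from ``numpy.random.SeedSequence([master_seed, stable_rat_key, week])``
and the per-rat intercept from ``SeedSequence([master_seed, 1, stable_rat_key])``,
so any single session is independently reproducible.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Iterator, Mapping, NamedTuple

import numpy as np
from scipy import fft as _fft
from scipy import signal as _sig

from .core import (
    BEHAVIORS,
    GROUPS,
    STRUCTURES,
    ArtifactEvent,
    BehaviorSchedule,
    Episode,
    RecordingSession,
)

__all__ = [
    "CohortDesign",
    "EpisodeParams",
    "generate_powerlaw_noise",
    "schedule_behaviors",
    "generate_session",
    "generate_cohort",
    "reduced_design",
    "default_band_gain",
    "default_duration_params",
    "powerlaw_band_fraction",
]


class EpisodeParams(NamedTuple):
    """Episode-length distribution for one behavior: log-normal with the
    given median (s) and log-SD, plus an expected episode count per
    scheduling round."""

    median_s: float
    log_sd: float
    rate: float = 1.0


# Baseline episode-length medians (s) at protocol scale.  Chosen so that a
# 500-800 s session yields >= 5 episodes of >= 5 s for every behavior with
# probability >= 0.99 (validated by simulation in the test suite).
_BASE_MEDIANS = {
    "resting": 14.0,
    "grooming": 9.0,
    "locomotion": 10.0,
    "rearing": 9.0,
    "sniffing": 9.0,
}
_BASE_LOG_SD = 0.35

# Log-length shifts for the experimental group in week 1 (hypokinesia:
# longer resting, shorter grooming / rearing / sniffing).
_W1_SHIFTS = {
    "resting": 0.40,
    "grooming": -0.35,
    "rearing": -0.35,
    "sniffing": -0.15,
}


def default_duration_params(
    medians: Mapping[str, float] | None = None,
    log_sd: float = _BASE_LOG_SD,
    w1_shifts: Mapping[str, float] | None = None,
) -> dict[tuple[str, str], EpisodeParams]:
    """Build the duration-parameter table keyed by ``(condition, behavior)``.

    ``condition`` is ``"base"`` for every cell except the experimental
    week-1 cells that carry the injected hypokinesia effect, which live
    under ``"experimental_w1"``.
    """
    medians = dict(_BASE_MEDIANS if medians is None else medians)
    w1_shifts = dict(_W1_SHIFTS if w1_shifts is None else w1_shifts)
    table: dict[tuple[str, str], EpisodeParams] = {}
    for b, m in medians.items():
        table[("base", b)] = EpisodeParams(m, log_sd)
        shifted = m * math.exp(w1_shifts.get(b, 0.0))
        table[("experimental_w1", b)] = EpisodeParams(shifted, log_sd)
    return table


def default_band_gain(
    gain: float = 1.8,
    weeks: tuple[int, ...] = (1, 2),
    behaviors: tuple[str, ...] = ("grooming", "locomotion", "rearing", "sniffing"),
) -> dict[tuple[str, int, str], float]:
    """Default band-power gain table: experimental hyperactivity in the
    early weeks for the active behaviors; 1.0 everywhere else."""
    return {("experimental", w, b): gain for w in weeks for b in behaviors}


def _default_coupling() -> dict[str, float]:
    return {"grooming": -0.12, "sniffing": 0.12}


@dataclass(frozen=True)
class CohortDesign:
    """Full parameterization of a synthetic cohort.

    Defaults mirror the recording protocol: 12 + 12 rats, four weekly
    sessions of 500-800 s sampled at 10 kHz, five annotated behaviors,
    a power-law background with exponent 3.2 normalized to
    ``base_power`` uV^2 inside ``total_band``, and effect tables for
    band gain, episode durations and duration-power coupling.
    """

    n_control: int = 12
    n_experimental: int = 12
    weeks: int = 4
    fs: float = 10_000.0
    session_duration: tuple[float, float] = (500.0, 800.0)
    behaviors: tuple[str, ...] = BEHAVIORS
    spectral_exponent: float = 3.2
    base_power: float = 1.0  # uV^2 within total_band
    total_band: tuple[float, float] = (300.0, 3000.0)
    effect_band: tuple[float, float] = (300.0, 500.0)
    acquisition_band: tuple[float, float] = (100.0, 6000.0)
    band_gain: dict[tuple[str, int, str], float] = field(default_factory=default_band_gain)
    duration_params: dict[tuple[str, str], EpisodeParams] = field(
        default_factory=default_duration_params
    )
    duration_coupling: dict[str, float] = field(default_factory=_default_coupling)
    gap_mean: float = 0.5
    mains_amp: float = 0.5  # uV at the mains base frequency
    mains_base: float = 60.0
    artifact_rate: float = 3.0  # expected artifacts per session and channel
    rail: float = 500.0  # uV saturation level of the virtual acquisition chain
    rat_sd: float = 0.2  # SD of the per-rat log-power intercept
    seed: int = 0
    enforce_protocol_duration: bool = True

    def __post_init__(self) -> None:
        if self.n_control <= 0 or self.n_experimental <= 0 or self.weeks <= 0:
            raise ValueError("all cohort counts must be positive")
        if self.fs <= 0 or self.base_power <= 0:
            raise ValueError("fs and base_power must be positive")
        if self.spectral_exponent < 0:
            raise ValueError("spectral_exponent must be >= 0")
        lo, hi = self.session_duration
        if not 0 < lo <= hi:
            raise ValueError("session_duration bounds must satisfy 0 < lo <= hi")
        if self.enforce_protocol_duration and not (500.0 <= lo and hi <= 800.0):
            raise ValueError(
                "protocol sessions must lie within [500, 800] s; "
                "pass enforce_protocol_duration=False for reduced fixtures"
            )
        if set(self.behaviors) != set(BEHAVIORS):
            raise ValueError(f"behaviors must be exactly {sorted(BEHAVIORS)}")
        if any(g <= 0 for g in self.band_gain.values()):
            raise ValueError("band gains must be positive")
        if self.rat_sd < 0 or self.artifact_rate < 0 or self.mains_amp < 0:
            raise ValueError("rat_sd, artifact_rate and mains_amp must be >= 0")

    # -- effect-table lookups -------------------------------------------------

    def gain(self, group: str, week: int, behavior: str) -> float:
        return self.band_gain.get((group, week, behavior), 1.0)

    def episode_params(self, group: str, week: int, behavior: str) -> EpisodeParams:
        if group == "experimental" and week == 1 and ("experimental_w1", behavior) in self.duration_params:
            return self.duration_params[("experimental_w1", behavior)]
        return self.duration_params[("base", behavior)]

    def coupling(self, behavior: str) -> float:
        return self.duration_coupling.get(behavior, 0.0)

    def rat_ids(self) -> list[tuple[str, str]]:
        """All (rat_id, group) pairs of the cohort, controls first."""
        out = [(f"C{i + 1:02d}", "control") for i in range(self.n_control)]
        out += [(f"E{i + 1:02d}", "experimental") for i in range(self.n_experimental)]
        return out


def reduced_design(**overrides) -> CohortDesign:
    """Desk-scale variant for calibration runs: 2 kHz sampling, bands
    scaled by 1/5 (analysis range 60-600 Hz), 80-120 s sessions, short
    episodes, no mains and no artifacts.  Statistical structure (groups,
    weeks, effect tables) is unchanged unless overridden."""
    medians = {"resting": 7.0, "grooming": 4.0, "locomotion": 4.5, "rearing": 4.0, "sniffing": 4.0}
    base = dict(
        fs=2000.0,
        session_duration=(80.0, 120.0),
        total_band=(60.0, 600.0),
        effect_band=(60.0, 100.0),
        acquisition_band=(20.0, 900.0),
        duration_params=default_duration_params(
            medians=medians,
            log_sd=0.45,
            w1_shifts={"resting": 0.40, "grooming": -0.35, "rearing": -0.35, "sniffing": -0.08},
        ),
        duration_coupling={"grooming": -0.45, "sniffing": 0.45},
        gap_mean=0.3,
        mains_amp=0.0,
        artifact_rate=0.0,
        enforce_protocol_duration=False,
    )
    base.update(overrides)
    return CohortDesign(**base)


# ---------------------------------------------------------------------------
# Power-law background noise
# ---------------------------------------------------------------------------


def powerlaw_band_fraction(
    alpha: float,
    band: tuple[float, float],
    total: tuple[float, float],
) -> float:
    """Closed-form fraction of ``f**-alpha`` power in ``band`` relative to
    ``total`` (continuous integral; the oracle for the generator)."""
    f1, f2 = band
    t1, t2 = total
    if alpha == 1.0:
        return math.log(f2 / f1) / math.log(t2 / t1)
    a = alpha - 1.0
    return (f1**-a - f2**-a) / (t1**-a - t2**-a)


def generate_powerlaw_noise(
    n_samples: int,
    fs: float,
    alpha: float,
    total_power: float,
    seed: int | np.random.Generator,
    band: tuple[float, float] = (300.0, 3000.0),
) -> np.ndarray:
    """Gaussian noise with expected one-sided PSD proportional to ``f**-alpha``.

    Spectral shaping is applied in the frequency domain as
    ``|f|**(-alpha/2)`` amplitude scaling with the DC bin excluded, and
    the overall scale is chosen so that the *expected* power falling in
    ``band`` (inclusive of both edges on the DFT grid) equals
    ``total_power``.

    Parameters
    ----------
    n_samples : int
        Signal length; must be > 1.
    fs : float
        Sample rate (Hz).
    alpha : float
        Spectral exponent (>= 0; 0 gives white noise).
    total_power : float
        Target expected power (uV^2) inside ``band``.
    seed : int or numpy.random.Generator
        Source of randomness; the same seed yields a bit-identical signal.
    band : (float, float)
        Normalization band in Hz.

    Returns
    -------
    numpy.ndarray
        Real zero-mean signal of length ``n_samples`` (uV).
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if total_power <= 0:
        raise ValueError("total_power must be positive")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    # Synthesize at the next fast FFT length and truncate: the process is
    # stationary, so truncation leaves the expected PSD unchanged while
    # keeping the inverse transform fast for arbitrary session lengths.
    n_fft = int(_fft.next_fast_len(n_samples, real=True))
    freqs = np.fft.rfftfreq(n_fft, 1.0 / fs)
    n_bins = len(freqs)
    # Target expected power per rfft bin: K * f**-alpha, DC excluded.
    shape = np.zeros(n_bins)
    shape[1:] = freqs[1:] ** (-alpha)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    band_sum = shape[in_band].sum()
    if band_sum <= 0:
        raise ValueError(f"normalization band {band} contains no DFT bins")
    p = shape * (total_power / band_sum)

    # Draw unit-power complex coefficients and scale so each bin contributes
    # its target expected power to the signal variance.
    z = rng.standard_normal(n_bins) + 1j * rng.standard_normal(n_bins)
    amp = np.zeros(n_bins)
    interior = slice(1, n_bins - 1) if n_fft % 2 == 0 else slice(1, n_bins)
    amp[interior] = n_fft * np.sqrt(p[interior] / 4.0)
    if n_fft % 2 == 0:  # real Nyquist bin
        amp[-1] = n_fft * np.sqrt(p[-1] / 2.0)
        z[-1] = z[-1].real
    x = _fft.irfft(z * amp, n=n_fft)
    return x[:n_samples]


# ---------------------------------------------------------------------------
# Behavior scheduling
# ---------------------------------------------------------------------------


def schedule_behaviors(
    duration: float,
    params: Mapping[str, EpisodeParams],
    seed: int | np.random.Generator,
    gap_mean: float = 0.5,
) -> BehaviorSchedule:
    """Alternating-renewal behavior schedule.

    Behaviors are scheduled in shuffled round-robin rounds: within each
    round every behavior receives (on average) ``rate`` episodes in random
    order, with log-normal episode lengths and exponential inter-episode
    gaps.  The final episode is truncated at the session end.  Episodes
    never overlap by construction.

    Raises
    ------
    ValueError
        If ``duration <= 0`` or any rate/length parameter is non-positive.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if gap_mean < 0:
        raise ValueError("gap_mean must be >= 0")
    for b, p in params.items():
        if p.median_s <= 0 or p.log_sd <= 0 or p.rate <= 0:
            raise ValueError(f"non-positive episode parameters for {b!r}: {p}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    behaviors = list(params)
    episodes: list[Episode] = []
    t = 0.0
    while t < duration:
        # One round: each behavior appears floor(rate) + Bernoulli(frac) times.
        round_items: list[str] = []
        for b in behaviors:
            r = params[b].rate
            k = int(r) + (1 if rng.random() < r - int(r) else 0)
            round_items.extend([b] * k)
        rng.shuffle(round_items)
        if not round_items:
            raise ValueError("all episode rates rounded to zero")
        for b in round_items:
            if gap_mean > 0:
                t += rng.exponential(gap_mean)
            if t >= duration:
                break
            p = params[b]
            length = rng.lognormal(mean=math.log(p.median_s), sigma=p.log_sd)
            end = min(t + length, duration)
            if end > t:
                episodes.append(Episode(b, t, end))
            t = end

    sched = BehaviorSchedule(episodes)
    sched.validate(duration=duration)
    return sched


# ---------------------------------------------------------------------------
# Session synthesis
# ---------------------------------------------------------------------------


def _stable_key(rat_id: str) -> int:
    """Stable 48-bit integer key for a rat id (independent of PYTHONHASHSEED)."""
    return int.from_bytes(hashlib.blake2s(rat_id.encode(), digest_size=6).digest(), "big")


def _session_seed(design: CohortDesign, rat_id: str, week: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([design.seed, _stable_key(rat_id), week])


def rat_intercept(design: CohortDesign, rat_id: str) -> float:
    """Per-rat multiplicative power intercept, log-normal with SD ``rat_sd``;
    shared by all of the rat's sessions."""
    if design.rat_sd == 0:
        return 1.0
    ss = np.random.SeedSequence([design.seed, 1, _stable_key(rat_id)])
    z = np.random.default_rng(ss).standard_normal()
    return float(np.exp(design.rat_sd * z))


@lru_cache(maxsize=32)
def _bandpass_sos(band: tuple[float, float], fs: float, order: int = 4) -> np.ndarray:
    lo, hi = band
    hi = min(hi, 0.999 * fs / 2.0)
    return _sig.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")


def _crossfade_envelope(
    n: int, fs: float, schedule: BehaviorSchedule, scale: Mapping[int, float], fade_s: float = 0.05
) -> np.ndarray:
    """Per-sample amplitude envelope: ``scale[i]`` inside episode ``i``,
    1.0 elsewhere, with linear cross-fades of ``fade_s`` at episode edges."""
    env = np.ones(n)
    for i, ep in enumerate(schedule):
        s = scale.get(i, 1.0)
        if s == 1.0:
            continue
        i0 = int(round(ep.onset_s * fs))
        i1 = min(int(round(ep.offset_s * fs)), n)
        if i1 <= i0:
            continue
        fade = min(int(round(fade_s * fs)), (i1 - i0) // 2)
        env[i0:i1] = s
        if fade > 0:
            ramp = np.linspace(0.0, 1.0, fade, endpoint=False)
            env[i0 : i0 + fade] = 1.0 + (s - 1.0) * ramp
            env[i1 - fade : i1] = s + (1.0 - s) * ramp
    return env


def generate_session(
    design: CohortDesign,
    rat_id: str,
    group: str,
    week: int,
    seed: np.random.SeedSequence | None = None,
) -> RecordingSession:
    """Synthesize one rat x week recording session.

    The three structure channels share a single behavior schedule.  For
    each channel the power-law background is band-limited to the
    acquisition band, split into its effect-band component and the
    complement, and the effect-band component is rescaled inside each
    episode of behavior ``b`` by::

        gain(group, week, b) * exp(kappa_b * episode_length) * rat_intercept

    (a power factor; amplitudes are scaled by its square root) with 50 ms
    linear cross-fades at episode edges.  Mains interference and
    artifacts are injected last, and the channel is clipped at the rail.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    if not 1 <= week <= design.weeks:
        raise ValueError(f"week must be in 1..{design.weeks}, got {week}")

    ss = seed if seed is not None else _session_seed(design, rat_id, week)
    streams = ss.spawn(2 + len(STRUCTURES))
    rng = np.random.default_rng(streams[0])

    duration = float(rng.uniform(*design.session_duration))
    n = int(round(duration * design.fs))
    duration = n / design.fs  # align the schedule horizon to the sample grid
    schedule = schedule_behaviors(
        duration,
        {b: design.episode_params(group, week, b) for b in design.behaviors},
        np.random.default_rng(streams[1]),
        gap_mean=design.gap_mean,
    )
    intercept = rat_intercept(design, rat_id)

    acq_sos = _bandpass_sos(design.acquisition_band, design.fs)
    eff_sos = _bandpass_sos(design.effect_band, design.fs)
    sd_ref = math.sqrt(design.base_power)  # amplitude scale of in-band background

    # Power scale per episode index.  The duration coupling is centered on
    # the behavior's median episode length so that kappa sets a per-second
    # log-power *slope* without shifting the mean band gain away from g.
    def _scale(ep: Episode) -> float:
        kappa = design.coupling(ep.behavior)
        center = design.episode_params(group, week, ep.behavior).median_s
        return math.sqrt(
            design.gain(group, week, ep.behavior)
            * math.exp(kappa * (ep.duration - center))
            * intercept
        )

    scale = {i: _scale(ep) for i, ep in enumerate(schedule)}
    envelope = _crossfade_envelope(n, design.fs, schedule, scale)

    t = np.arange(n) / design.fs
    channels: dict[str, np.ndarray] = {}
    artifacts: list[ArtifactEvent] = []
    for structure, stream in zip(STRUCTURES, streams[2:]):
        ch_rng = np.random.default_rng(stream)
        bg = generate_powerlaw_noise(
            n, design.fs, design.spectral_exponent, design.base_power, ch_rng, band=design.total_band
        )
        bg = _sig.sosfiltfilt(acq_sos, bg)
        band_comp = _sig.sosfiltfilt(eff_sos, bg)
        x = (bg - band_comp) + band_comp * envelope

        if design.mains_amp > 0:
            k_max = int(min(design.acquisition_band[1], 0.999 * design.fs / 2) // design.mains_base)
            for k in range(1, k_max + 1):
                phase = ch_rng.uniform(0, 2 * np.pi)
                x += (design.mains_amp / k) * np.sin(2 * np.pi * design.mains_base * k * t + phase)

        if design.artifact_rate > 0:
            n_art = ch_rng.poisson(design.artifact_rate)
            for _ in range(n_art):
                t0 = ch_rng.uniform(0, duration)
                if ch_rng.random() < 0.5:
                    # Excursion: short in-band tone burst, 12-20 reference SDs.
                    # The carrier is cosine-phased at the burst center, where the
                    # taper peaks, so the nominal amplitude is actually reached.
                    dur = ch_rng.uniform(1e-3, 10e-3)
                    amp = ch_rng.uniform(12.0, 20.0) * sd_ref
                    m = max(int(round(dur * design.fs)) | 1, 5)  # odd, >= 5 samples
                    i0 = min(int(t0 * design.fs), n - m)  # keep the burst whole
                    i1 = i0 + m
                    carrier = math.sqrt(design.total_band[0] * design.total_band[1])
                    k = np.arange(m) - (m - 1) / 2.0
                    burst = amp * np.hanning(m) * np.cos(2 * np.pi * carrier * k / design.fs)
                    x[i0:i1] += burst
                    artifacts.append(ArtifactEvent(structure, "excursion", i0 / design.fs, i1 / design.fs))
                else:
                    # Saturation: clip a run of >= 5 samples at +-rail.
                    run = int(ch_rng.integers(5, 51))
                    i0 = int(t0 * design.fs)
                    i1 = min(i0 + run, n)
                    if i1 - i0 < 5:
                        i0 = max(0, i1 - 5)
                    x[i0:i1] = design.rail if ch_rng.random() < 0.5 else -design.rail
                    artifacts.append(ArtifactEvent(structure, "saturation", i0 / design.fs, i1 / design.fs))

        if np.isfinite(design.rail):
            np.clip(x, -design.rail, design.rail, out=x)
        channels[structure] = x

    return RecordingSession(
        rat_id=rat_id,
        group=group,
        week=week,
        fs=design.fs,
        channels=channels,
        episodes=schedule,
        rail=design.rail if np.isfinite(design.rail) else None,
        seed=design.seed,
        artifacts=artifacts,
    )


def generate_cohort(
    design: CohortDesign,
    groups: tuple[str, ...] = GROUPS,
    weeks: tuple[int, ...] | None = None,
) -> Iterator[RecordingSession]:
    """Yield every session of the cohort, deterministically ordered by
    (group, rat, week).  ``groups``/``weeks`` restrict generation (e.g.
    experimental-only calibration runs)."""
    weeks = tuple(range(1, design.weeks + 1)) if weeks is None else weeks
    for rat_id, group in design.rat_ids():
        if group not in groups:
            continue
        for week in weeks:
            yield generate_session(design, rat_id, group, week)
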