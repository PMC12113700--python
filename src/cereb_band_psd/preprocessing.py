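"""Signal conditioning, behavior-aligned trace extraction and artifact QC.

Filtering is zero-phase (forward-backward), so behavior-aligned windows
are not phase-delayed; the effective roll-off therefore doubles the
nominal filter order.  Filters are applied per channel over the whole
session before windowing, which keeps edge transients out of the
extracted traces (reflection padding of up to 1 s at the session edges).

Trace windows are tiled from each episode onset without overlap, ordered
by start time across the session, and the earliest windows surviving QC
are kept -- a deterministic, auditable selection rule.

QC applies two exclusion rules, saturation first:

* saturation -- a run of at least 5 consecutive samples pinned at the
  known rail (or, when the rail is unknown, tied at the channel's
  maximum absolute value), checked on the *raw* trace because rail
  contact is a property of the acquired values, not of filter output;
* excursion -- any filtered sample deviating more than 10 standard
  deviations from the filtered session mean, with the SD computed on the
  full filtered session channel so a fully saturated trace cannot mask
  itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
from scipy import signal as _sig

from .core import (
    BEHAVIORS,
    QC_EXCURSION,
    QC_OK,
    QC_SATURATION,
    BehaviorSchedule,
    RecordingSession,
)

__all__ = [
    "Trace",
    "bandpass_filter",
    "notch_filter",
    "tile_windows",
    "flag_artifacts",
    "extract_traces",
    "preprocess_channels",
    "ChannelState",
]

DEFAULT_TRACE_LEN = 5.0
DEFAULT_MAX_TRACES = 5
EXCURSION_N_SD = 10.0
SATURATION_MIN_RUN = 5


@dataclass
class Trace:
    """A fixed-length behavior-labeled window cut from one channel."""

    rat_id: str
    group: str
    week: int
    structure: str
    behavior: str
    samples: np.ndarray  # filtered signal, uV
    window: tuple[float, float]  # (start_s, end_s) within the session
    fs: float
    qc: str = QC_OK
    raw: np.ndarray | None = field(default=None, repr=False)

    @property
    def start_s(self) -> float:
        return self.window[0]

    @property
    def duration(self) -> float:
        return self.window[1] - self.window[0]


def bandpass_filter(
    x: np.ndarray,
    fs: float,
    low: float = 300.0,
    high: float = 3000.0,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass.

    ``order`` is the design order of the band-pass prototype; the
    forward-backward application squares the magnitude response.  Gain at
    the geometric mid-band is within 1% of unity.
    """
    if not 0 < low < high:
        raise ValueError(f"need 0 < low < high, got ({low}, {high})")
    if high >= fs / 2:
        raise ValueError(f"high corner {high} Hz must be below Nyquist ({fs / 2} Hz)")
    x = np.asarray(x, dtype=np.float64)
    if x.size == 0:
        return x
    sos = _sig.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    padlen = min(x.size - 1, int(round(fs)))  # up to 1 s reflection padding
    return _sig.sosfiltfilt(sos, x, padlen=padlen)


def notch_filter(
    x: np.ndarray,
    fs: float,
    base: float = 60.0,
    max_freq: float = 3000.0,
    q: float = 35.0,
) -> np.ndarray:
    """Zero-phase cascade of IIR notches at every harmonic of ``base``.

    Notches are placed at ``base * k`` for all ``k`` with
    ``base * k <= max_freq`` (and below Nyquist).  ``q`` is the quality
    factor of the base notch; every harmonic notch keeps the same
    *absolute* rejection bandwidth ``base / q`` (i.e. quality ``q * k``),
    so high harmonics are not smeared.  Each notch has a true zero at its
    center (attenuation >> 30 dB); 5 Hz or more away from every center
    the cascade gain stays within 5% of unity at the default Q.
    """
    if base <= 0:
        raise ValueError("base frequency must be positive")
    if q <= 0:
        raise ValueError("q must be positive")
    x = np.asarray(x, dtype=np.float64)
    nyq = fs / 2.0
    k_max = int(min(max_freq, 0.999 * nyq) // base)
    if k_max < 1:
        return x.copy()
    sections = []
    for k in range(1, k_max + 1):
        b, a = _sig.iirnotch(base * k, q * k, fs=fs)
        sections.append(_sig.tf2sos(b, a))
    sos = np.vstack(sections)
    padlen = min(x.size - 1, int(round(fs)))
    return _sig.sosfiltfilt(sos, x, padlen=padlen)


def notch_centers(base: float, max_freq: float, fs: float) -> list[float]:
    """Notch center frequencies used by :func:`notch_filter`."""
    nyq = fs / 2.0
    k_max = int(min(max_freq, 0.999 * nyq) // base)
    return [base * k for k in range(1, k_max + 1)]


class Window(NamedTuple):
    start_s: float
    end_s: float
    behavior: str


def tile_windows(
    schedule: BehaviorSchedule, behavior: str, trace_len: float = DEFAULT_TRACE_LEN
) -> list[Window]:
    """Non-overlapping ``trace_len`` windows tiled from each episode onset,
    ordered by start time across the session."""
    if trace_len <= 0:
        raise ValueError("trace_len must be positive")
    windows = []
    for ep in schedule.for_behavior(behavior):
        n_fit = int((ep.duration + 1e-9) // trace_len)
        for i in range(n_fit):
            s = ep.onset_s + i * trace_len
            windows.append(Window(s, s + trace_len, behavior))
    windows.sort(key=lambda w: w.start_s)
    return windows


def _has_run(mask: np.ndarray, min_run: int) -> bool:
    if not mask.any():
        return False
    # Longest run of True values.
    padded = np.concatenate(([0], mask.view(np.int8), [0]))
    edges = np.flatnonzero(np.diff(padded))
    runs = edges[1::2] - edges[::2]
    return bool(runs.max() >= min_run)


def flag_artifacts(
    trace: Trace | np.ndarray,
    session_sd: float,
    rail: float | None = None,
    session_mean: float = 0.0,
    raw: np.ndarray | None = None,
    n_sd: float = EXCURSION_N_SD,
    min_run: int = SATURATION_MIN_RUN,
) -> str:
    """Classify one trace as ``ok`` / ``excluded_saturation`` / ``excluded_excursion``.

    Saturation is checked first, on the raw samples when available.
    ``session_sd``/``session_mean`` are the statistics of the full
    filtered session channel.
    """
    if session_sd <= 0:
        raise ValueError("session_sd must be positive")
    if isinstance(trace, Trace):
        filtered = np.asarray(trace.samples, dtype=np.float64)
        raw_samples = trace.raw if trace.raw is not None else None
    else:
        filtered = np.asarray(trace, dtype=np.float64)
        raw_samples = raw
    sat_source = np.asarray(raw_samples if raw_samples is not None else filtered, dtype=np.float64)

    if rail is not None and np.isfinite(rail):
        pinned = np.isclose(np.abs(sat_source), rail, rtol=1e-6, atol=0.0)
    else:
        peak = np.abs(sat_source).max() if sat_source.size else 0.0
        pinned = np.abs(sat_source) == peak if peak > 0 else np.zeros(sat_source.shape, bool)
    if _has_run(pinned, min_run):
        return QC_SATURATION

    if np.any(np.abs(filtered - session_mean) > n_sd * session_sd):
        return QC_EXCURSION
    return QC_OK


@dataclass
class ChannelState:
    """One filtered session channel plus the statistics QC needs.

    ``mean``/``sd`` are robust location/scale estimates (median and
    1.4826 * MAD) of the full filtered channel: equal to the moments for
    clean Gaussian signal, but immune to the very artifacts the 10-SD
    rule is meant to catch (a saturated stretch must not inflate the
    threshold that would flag it).
    """

    filtered: np.ndarray
    raw: np.ndarray
    mean: float
    sd: float


def preprocess_channels(
    session: RecordingSession,
    low: float = 300.0,
    high: float = 3000.0,
    order: int = 4,
    notch_base: float | None = 60.0,
    notch_q: float = 35.0,
) -> dict[str, ChannelState]:
    """Band-pass (and optionally notch) every channel of a session and
    compute the full-session mean/SD used by the exclusion rules."""
    out: dict[str, ChannelState] = {}
    for label, raw in session.channels.items():
        y = bandpass_filter(raw, session.fs, low=low, high=high, order=order)
        if notch_base is not None and notch_base > 0:
            y = notch_filter(y, session.fs, base=notch_base, max_freq=high, q=notch_q)
        center = float(np.median(y))
        mad_sd = 1.4826 * float(np.median(np.abs(y - center)))
        out[label] = ChannelState(
            filtered=y, raw=np.asarray(raw, dtype=np.float64), mean=center, sd=mad_sd
        )
    return out


def extract_traces(
    session: RecordingSession,
    behavior: str,
    trace_len: float = DEFAULT_TRACE_LEN,
    max_traces: int = DEFAULT_MAX_TRACES,
    structures: Sequence[str] | None = None,
    channels: Mapping[str, ChannelState] | None = None,
    qc: bool = True,
    include_flagged: bool = False,
    **filter_kwargs,
) -> list[Trace]:
    """Extract up to ``max_traces`` QC-passing traces of one behavior.

    Candidate windows are tiled from episode onsets (see
    :func:`tile_windows`) and are shared across structures; QC is applied
    per structure, earliest candidates first, and selection stops once
    ``max_traces`` traces pass.  A warning is emitted when a structure
    cannot supply ``max_traces`` traces.

    Pass a precomputed ``channels`` mapping (from
    :func:`preprocess_channels`) to avoid re-filtering; otherwise the
    session is filtered with ``filter_kwargs``.
    """
    if behavior not in BEHAVIORS and behavior not in session.episodes.behaviors:
        raise ValueError(f"unknown behavior {behavior!r}")
    if max_traces < 1:
        raise ValueError("max_traces must be >= 1")
    if channels is None:
        channels = preprocess_channels(session, **filter_kwargs)
    structures = list(channels) if structures is None else list(structures)

    windows = tile_windows(session.episodes, behavior, trace_len)
    n_len = int(round(trace_len * session.fs))
    out: list[Trace] = []
    for structure in structures:
        state = channels[structure]
        kept = 0
        for w in windows:
            if kept >= max_traces:
                break
            i0 = int(round(w.start_s * session.fs))
            i1 = i0 + n_len
            if i1 > len(state.filtered):
                continue
            tr = Trace(
                rat_id=session.rat_id,
                group=session.group,
                week=session.week,
                structure=structure,
                behavior=behavior,
                samples=state.filtered[i0:i1],
                window=(w.start_s, w.start_s + trace_len),
                fs=session.fs,
                raw=state.raw[i0:i1],
            )
            if qc and state.sd > 0:
                tr.qc = flag_artifacts(tr, session_sd=state.sd, rail=session.rail, session_mean=state.mean)
            if tr.qc == QC_OK:
                kept += 1
                out.append(tr)
            elif include_flagged:
                out.append(tr)
        if kept < max_traces:
            warnings.warn(
                f"{session.rat_id} w{session.week} {structure}/{behavior}: "
                f"only {kept} of {max_traces} traces available",
                UserWarning,
                stacklevel=2,
            )
    return out
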