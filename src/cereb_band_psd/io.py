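"""On-disk representation of annotated recording sessions.

Layout of a session directory::

    manifest.json               # metadata + file references
    episodes.csv                # behavior,onset_s,offset_s (6-decimal seconds)
    <rat>_w<week>_<structure>.f32   # little-endian float32 signal, one per channel

Signals are stored in microvolts.  Serialization is deterministic:
writing the same session twice produces byte-identical files.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import BEHAVIORS, RARE_BEHAVIORS, BehaviorSchedule, Episode, RecordingSession

MANIFEST_NAME = "manifest.json"
EPISODES_NAME = "episodes.csv"
_KNOWN_BEHAVIORS = set(BEHAVIORS) | set(RARE_BEHAVIORS)


class SessionIOError(RuntimeError):
    """Raised on malformed or inconsistent session files."""


@dataclass
class SessionManifest:
    """Parsed manifest of a stored session."""

    path: Path
    rat_id: str
    group: str
    week: int
    fs: float
    units: str
    rail: float | None
    seed: int | None
    channels: dict[str, dict]  # label -> {"file": str, "n_samples": int}
    episodes_file: str

    @property
    def directory(self) -> Path:
        return self.path.parent

    def validate(self) -> None:
        """Check that referenced files exist and sizes match the manifest."""
        n_set = {info["n_samples"] for info in self.channels.values()}
        if len(n_set) > 1:
            raise SessionIOError(f"{self.path}: channels differ in n_samples: {n_set}")
        for label, info in self.channels.items():
            f = self.directory / info["file"]
            if not f.exists():
                raise SessionIOError(f"{self.path}: missing signal file {f}")
            expected = 4 * info["n_samples"]
            actual = f.stat().st_size
            if actual != expected:
                raise SessionIOError(
                    f"{f}: file length {actual} B does not match manifest "
                    f"({info['n_samples']} float32 samples = {expected} B) for channel {label!r}"
                )
        if not (self.directory / self.episodes_file).exists():
            raise SessionIOError(f"{self.path}: missing episodes file {self.episodes_file}")


def write_session(session: RecordingSession, directory: str | Path) -> SessionManifest:
    """Write a session to ``directory`` and return its manifest.

    Signals are written as little-endian float32, episodes as CSV with
    6-decimal second timestamps, the manifest as sorted-key JSON.
    """
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
        channels = {}
        for label in sorted(session.channels):
            fname = f"{session.rat_id}_w{session.week}_{label}.f32"
            arr = np.ascontiguousarray(session.channels[label], dtype="<f4")
            arr.tofile(directory / fname)
            channels[label] = {"file": fname, "n_samples": int(arr.size), "dtype": "<f4"}

        with open(directory / EPISODES_NAME, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["behavior", "onset_s", "offset_s"])
            for ep in session.episodes:
                w.writerow([ep.behavior, f"{ep.onset_s:.6f}", f"{ep.offset_s:.6f}"])

        doc = {
            "format_version": 1,
            "rat_id": session.rat_id,
            "group": session.group,
            "week": session.week,
            "fs": session.fs,
            "units": "uV",
            "rail": session.rail,
            "seed": session.seed,
            "channels": channels,
            "episodes_file": EPISODES_NAME,
        }
        path = directory / MANIFEST_NAME
        path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    except OSError as exc:
        raise SessionIOError(f"failed writing session to {directory}: {exc}") from exc

    return SessionManifest(
        path=path,
        rat_id=session.rat_id,
        group=session.group,
        week=session.week,
        fs=session.fs,
        units="uV",
        rail=session.rail,
        seed=session.seed,
        channels=channels,
        episodes_file=EPISODES_NAME,
    )


def read_manifest(manifest_path: str | Path) -> SessionManifest:
    path = Path(manifest_path)
    if path.is_dir():
        path = path / MANIFEST_NAME
    try:
        doc = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise SessionIOError(f"cannot parse manifest {path}: {exc}") from exc
    try:
        return SessionManifest(
            path=path,
            rat_id=doc["rat_id"],
            group=doc["group"],
            week=int(doc["week"]),
            fs=float(doc["fs"]),
            units=doc.get("units", "uV"),
            rail=doc.get("rail"),
            seed=doc.get("seed"),
            channels=doc["channels"],
            episodes_file=doc.get("episodes_file", EPISODES_NAME),
        )
    except KeyError as exc:
        raise SessionIOError(f"manifest {path} missing required key {exc}") from exc


def _read_episodes(path: Path) -> BehaviorSchedule:
    episodes: list[Episode] = []
    problems: list[str] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"behavior", "onset_s", "offset_s"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise SessionIOError(f"{path}: episode CSV must have columns {sorted(required)}")
        for row_no, row in enumerate(reader, start=2):  # header is line 1
            try:
                onset, offset = float(row["onset_s"]), float(row["offset_s"])
            except ValueError:
                problems.append(f"row {row_no}: non-numeric onset/offset")
                continue
            behavior = row["behavior"].strip()
            if onset >= offset:
                problems.append(f"row {row_no}: onset {onset} >= offset {offset}")
                continue
            if behavior not in _KNOWN_BEHAVIORS:
                warnings.warn(
                    f"{path} row {row_no}: unrecognized behavior label {behavior!r} (kept)",
                    UserWarning,
                    stacklevel=3,
                )
            episodes.append(Episode(behavior, onset, offset))
    if problems:
        raise SessionIOError(f"{path}: invalid episode rows: " + "; ".join(problems))

    # Overlap check with row context (rows are 1-based data rows + header).
    order = sorted(range(len(episodes)), key=lambda i: episodes[i].onset_s)
    overlaps = [
        (a + 2, b + 2)
        for a, b in zip(order, order[1:])
        if episodes[b].onset_s < episodes[a].offset_s - 1e-5
    ]
    if overlaps:
        raise SessionIOError(f"{path}: overlapping episodes at CSV line pairs {overlaps}")
    return BehaviorSchedule(episodes)


def read_session(manifest_path: str | Path) -> RecordingSession:
    """Load a session from its manifest, enforcing all invariants."""
    manifest = read_manifest(manifest_path)
    manifest.validate()
    channels = {
        label: np.fromfile(manifest.directory / info["file"], dtype="<f4").astype(np.float64)
        for label, info in manifest.channels.items()
    }
    schedule = _read_episodes(manifest.directory / manifest.episodes_file)
    session = RecordingSession(
        rat_id=manifest.rat_id,
        group=manifest.group,
        week=manifest.week,
        fs=manifest.fs,
        channels=channels,
        episodes=schedule,
        rail=manifest.rail,
        seed=manifest.seed,
    )
    session.validate()
    return session
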