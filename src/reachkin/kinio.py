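"""Readers and writers for marker trajectories and cohort manifests.

The package's interchange format is a plain-text trial CSV: metadata in
``# key: value`` header comments, a ``frame`` column, and one ``<MARKER>_X/_Y/_Z``
column triple per marker, coordinates in millimetres.  Missing marker samples
(optoelectronic dropouts) are serialized as empty cells and tracked in a
per-marker validity mask.  C3D files can be read when the optional ``ezc3d``
dependency is installed.

Coordinate convention (all modules assume it): ISB-style laboratory axes with
X anterior, Y vertical (up), Z pointing to the subject's right.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ManifestError, MissingDependencyError

#: Canonical marker names: suprasternal notch, 7th cervical vertebra,
#: 8th thoracic vertebra, acromion, lateral/medial humeral epicondyles,
#: radial/ulnar styloids.
MARKER_NAMES: tuple[str, ...] = ("IJ", "C7", "T8", "ACR", "LE", "ME", "RS", "US")

GROUPS = ("AOT", "CTRL")
PHASES = ("PRE", "POST")
MOVEMENTS = ("A-Low", "A-High", "L-Low")
HANDEDNESS = ("right", "left")

_META_FIELDS = ("subject_id", "group", "handedness", "phase", "movement",
                "trial_index", "rate")


@dataclass
class TrialRecording:
    """Labeled 3D marker trajectories for one subject/phase/movement/trial.

    ``markers`` maps each canonical marker name to a ``(n_frames, 3)`` float
    array in millimetres; ``validity`` maps it to a boolean mask that is False
    where the sample is missing.
    """

    subject_id: str
    group: str
    handedness: str
    phase: str
    movement: str
    trial_index: int
    rate: float
    markers: dict[str, np.ndarray]
    validity: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [m for m in MARKER_NAMES if m not in self.markers]
        if missing:
            raise FormatError(f"missing canonical marker(s): {', '.join(missing)}")
        lengths = set()
        for name in MARKER_NAMES:
            arr = np.asarray(self.markers[name], dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise FormatError(f"marker {name}: expected (n, 3) array, got {arr.shape}")
            self.markers[name] = arr
            lengths.add(arr.shape[0])
        if len(lengths) != 1:
            raise FormatError(f"markers have unequal frame counts: {sorted(lengths)}")
        if self.rate <= 0:
            raise FormatError(f"sampling rate must be positive, got {self.rate}")
        n = lengths.pop()
        for name in MARKER_NAMES:
            mask = self.validity.get(name)
            if mask is None:
                mask = np.all(np.isfinite(self.markers[name]), axis=1)
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != (n,):
                raise FormatError(f"validity mask for {name}: expected ({n},), got {mask.shape}")
            self.validity[name] = mask

    @property
    def n_frames(self) -> int:
        return self.markers[MARKER_NAMES[0]].shape[0]

    @property
    def key(self) -> tuple[str, str, str, int]:
        return (self.subject_id, self.phase, self.movement, self.trial_index)

    def copy(self) -> "TrialRecording":
        return TrialRecording(
            subject_id=self.subject_id, group=self.group,
            handedness=self.handedness, phase=self.phase,
            movement=self.movement, trial_index=self.trial_index,
            rate=self.rate,
            markers={k: v.copy() for k, v in self.markers.items()},
            validity={k: v.copy() for k, v in self.validity.items()},
        )


@dataclass
class CohortDataset:
    """A collection of trial recordings with manifest rows and keyed lookup."""

    recordings: list[TrialRecording]
    manifest: pd.DataFrame

    def __post_init__(self) -> None:
        index: dict[tuple, TrialRecording] = {}
        subject_group: dict[str, str] = {}
        for rec in self.recordings:
            if rec.key in index:
                raise ManifestError(f"duplicate trial key {rec.key}")
            index[rec.key] = rec
            prev = subject_group.setdefault(rec.subject_id, rec.group)
            if prev != rec.group:
                raise ManifestError(
                    f"subject {rec.subject_id} assigned to both {prev} and {rec.group}")
        self._index = index

    def __len__(self) -> int:
        return len(self.recordings)

    def __iter__(self):
        return iter(self.recordings)

    def get(self, subject_id: str, phase: str, movement: str,
            trial_index: int) -> TrialRecording:
        return self._index[(subject_id, phase, movement, trial_index)]

    @property
    def subjects(self) -> list[str]:
        seen: dict[str, None] = {}
        for rec in self.recordings:
            seen.setdefault(rec.subject_id, None)
        return list(seen)


def _csv_columns() -> list[str]:
    cols = ["frame"]
    for name in MARKER_NAMES:
        cols += [f"{name}_X", f"{name}_Y", f"{name}_Z"]
    return cols


def write_trial_csv(recording: TrialRecording, path: str | Path) -> None:
    """Serialize a recording to the trial CSV dialect.

    Metadata goes into ``# key: value`` header comments, gaps become empty
    cells, coordinates are written in millimetres with 4 decimal places.
    """
    if recording.n_frames == 0:
        raise FormatError("cannot write a recording with zero frames")
    path = Path(path)
    n = recording.n_frames
    data = {"frame": np.arange(n)}
    for name in MARKER_NAMES:
        xyz = recording.markers[name].astype(float).copy()
        xyz[~recording.validity[name]] = np.nan
        for j, ax in enumerate("XYZ"):
            data[f"{name}_{ax}"] = xyz[:, j]
    frame = pd.DataFrame(data, columns=_csv_columns())
    with open(path, "w", newline="") as fh:
        for key in _META_FIELDS:
            fh.write(f"# {key}: {getattr(recording, key)}\n")
        frame.to_csv(fh, index=False, float_format="%.4f", na_rep="")


def read_trial_csv(path: str | Path, metadata: dict | None = None) -> TrialRecording:
    """Read a trial CSV.  Metadata comes from header comments unless an
    explicit ``metadata`` dict (e.g. a manifest row) overrides it."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"trial file not found: {path}")
    meta: dict[str, str] = {}
    header_lines = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip()] = value.strip()
    try:
        table = pd.read_csv(path, skiprows=header_lines)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: malformed CSV ({exc})") from exc
    for name in MARKER_NAMES:
        for ax in "XYZ":
            if f"{name}_{ax}" not in table.columns:
                raise FormatError(f"{path}: missing column for canonical marker {name}")
    if metadata:
        meta.update({k: str(v) for k, v in metadata.items()})
    missing_meta = [k for k in _META_FIELDS if k not in meta]
    if missing_meta:
        raise FormatError(f"{path}: missing metadata fields {missing_meta}")
    markers: dict[str, np.ndarray] = {}
    validity: dict[str, np.ndarray] = {}
    for name in MARKER_NAMES:
        xyz = table[[f"{name}_{ax}" for ax in "XYZ"]].to_numpy(dtype=float)
        valid = np.all(np.isfinite(xyz), axis=1)
        markers[name] = xyz
        validity[name] = valid
    return TrialRecording(
        subject_id=meta["subject_id"], group=meta["group"],
        handedness=meta["handedness"], phase=meta["phase"],
        movement=meta["movement"], trial_index=int(meta["trial_index"]),
        rate=float(meta["rate"]), markers=markers, validity=validity,
    )


def read_c3d(path: str | Path, alias_table: dict[str, str] | None = None,
             metadata: dict | None = None) -> TrialRecording:
    """Read a C3D motion-capture file (requires the optional ``ezc3d`` extra).

    ``alias_table`` maps vendor point labels to the canonical marker names,
    e.g. ``{"STRN": "IJ"}``.  Units are converted to millimetres and points
    with negative residuals are masked as invalid.  The file's own frame rate
    is kept (no resampling at the I/O layer).
    """
    try:
        import ezc3d
    except ImportError as exc:  # pragma: no cover - exercised when extra absent
        raise MissingDependencyError(
            "reading C3D files requires the optional dependency 'ezc3d' "
            "(pip install reachkin[c3d]); alternatively convert to the trial "
            "CSV dialect") from exc
    c3d = ezc3d.c3d(str(path))
    labels = [lab.strip() for lab in
              c3d["parameters"]["POINT"]["LABELS"]["value"]]
    alias = dict(alias_table or {})
    name_for = {lab: alias.get(lab, lab) for lab in labels}
    unmapped = [m for m in MARKER_NAMES if m not in name_for.values()]
    if unmapped:
        raise FormatError(
            f"{path}: cannot map C3D labels to canonical markers {unmapped}; "
            f"available labels: {labels}")
    unit = "mm"
    try:
        unit = c3d["parameters"]["POINT"]["UNITS"]["value"][0].strip().lower()
    except (KeyError, IndexError):
        pass
    scale = {"mm": 1.0, "cm": 10.0, "m": 1000.0}.get(unit, 1.0)
    rate = float(c3d["parameters"]["POINT"]["RATE"]["value"][0])
    points = c3d["data"]["points"]          # (4, n_markers, n_frames)
    residuals = c3d["data"]["meta_points"]["residuals"][0]
    markers: dict[str, np.ndarray] = {}
    validity: dict[str, np.ndarray] = {}
    for i, lab in enumerate(labels):
        canon = name_for[lab]
        if canon not in MARKER_NAMES:
            continue
        xyz = points[:3, i, :].T * scale
        valid = residuals[i, :] >= 0
        xyz = xyz.copy()
        xyz[~valid] = np.nan
        markers[canon] = xyz
        validity[canon] = np.asarray(valid, dtype=bool)
    meta = dict(metadata or {})
    return TrialRecording(
        subject_id=str(meta.get("subject_id", "unknown")),
        group=str(meta.get("group", "CTRL")),
        handedness=str(meta.get("handedness", "right")),
        phase=str(meta.get("phase", "PRE")),
        movement=str(meta.get("movement", "A-Low")),
        trial_index=int(meta.get("trial_index", 1)),
        rate=rate, markers=markers, validity=validity,
    )


MANIFEST_COLUMNS = ("subject_id", "group", "handedness", "phase", "movement",
                    "trial_index", "file")


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ManifestError(f"manifest missing columns {missing}")
    manifest.loc[:, list(MANIFEST_COLUMNS)].to_csv(path, index=False)


def load_cohort(manifest_path: str | Path) -> CohortDataset:
    """Load a cohort from a manifest CSV.

    Trial files referenced by the manifest are resolved relative to the
    manifest's directory.  Missing files are tolerated (the pipeline must
    survive dropped recordings): they are reported with a warning and the
    manifest row is kept with ``loaded = False``.
    """
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    missing_cols = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing_cols:
        raise ManifestError(f"{manifest_path}: missing columns {missing_cols}")
    keys = manifest[["subject_id", "phase", "movement", "trial_index"]].apply(tuple, axis=1)
    dup = keys[keys.duplicated()]
    if len(dup):
        raise ManifestError(f"{manifest_path}: duplicate trial keys {sorted(set(dup))}")
    root = manifest_path.parent
    recordings: list[TrialRecording] = []
    loaded_flags = []
    for row in manifest.to_dict("records"):
        fpath = root / str(row["file"])
        if not fpath.exists():
            warnings.warn(f"trial file missing, skipped: {fpath}")
            loaded_flags.append(False)
            continue
        meta = {k: row[k] for k in _META_FIELDS if k in row}
        recordings.append(read_trial_csv(fpath, metadata=meta))
        loaded_flags.append(True)
    manifest = manifest.assign(loaded=loaded_flags)
    return CohortDataset(recordings=recordings, manifest=manifest)
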