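"""Reading and writing the PCG dataset dialect.

A dataset directory holds, per auscultation recording, a 16-bit PCM mono WAV
file named ``<patient>_<SITE>.wav`` (sites AV, PV, TV, MV; anything else maps
to OTHER), plus per patient a ``<patient>.txt`` metadata file of ``key: value``
lines (the ``Murmur:`` key is mandatory) and optionally per recording a
``<patient>_<SITE>.tsv`` segmentation table with three tab-separated columns:
start seconds, end seconds, integer segment code (0 unlabeled, 1 S1,
2 systole, 3 S2, 4 diastole).

Time coordinates are seconds, 0-based, half-open ``[start, end)``; the sample
index of a time t is ``floor(t * rate)``.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.io import wavfile

__all__ = [
    "SITES",
    "MURMUR_LABELS",
    "SEGMENT_CODES",
    "SEGMENT_LABELS",
    "FormatError",
    "PcgRecording",
    "PatientRecord",
    "Segment",
    "SegmentTable",
    "SplitSpec",
    "read_wav",
    "write_wav",
    "read_patient_metadata",
    "write_patient_metadata",
    "read_segment_tsv",
    "write_segment_tsv",
    "stratified_split",
    "load_manifest",
]

SITES = ("AV", "PV", "TV", "MV", "OTHER")
MURMUR_LABELS = ("Present", "Unknown", "Absent")

SEGMENT_CODES = {0: "unlabeled", 1: "S1", 2: "systole", 3: "S2", 4: "diastole"}
SEGMENT_LABELS = {v: k for k, v in SEGMENT_CODES.items()}

_SITE_RE = re.compile(r"^(?P<patient>.+)_(?P<site>AV|PV|TV|MV)$")


class FormatError(ValueError):
    """A file does not follow the expected dialect."""


@dataclass
class PcgRecording:
    """One auscultation recording: samples, sampling rate, site label."""

    samples: np.ndarray
    rate: int
    site: str = "OTHER"
    recording_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if int(self.rate) <= 0:
            raise ValueError(f"rate must be positive, got {self.rate}")
        self.rate = int(self.rate)
        if self.site not in SITES:
            raise ValueError(f"site must be one of {SITES}, got {self.site!r}")

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate


@dataclass
class PatientRecord:
    """A patient: murmur label, recordings, pass-through demographics."""

    patient_id: str
    murmur: str
    recordings: list[PcgRecording] = field(default_factory=list)
    demographics: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.murmur not in MURMUR_LABELS:
            raise ValueError(
                f"murmur must be one of {MURMUR_LABELS}, got {self.murmur!r}"
            )


@dataclass(frozen=True)
class Segment:
    start: float
    end: float
    label: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.start < self.end:
            raise ValueError(f"need 0 <= start < end, got [{self.start}, {self.end})")
        if self.label not in SEGMENT_LABELS:
            raise ValueError(f"unknown segment label {self.label!r}")


@dataclass
class SegmentTable:
    """Sorted, non-overlapping labeled time segments of one recording."""

    rows: list[Segment] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.rows = sorted(self.rows, key=lambda r: r.start)
        for a, b in zip(self.rows, self.rows[1:]):
            if b.start < a.end - 1e-12:
                raise ValueError(
                    f"overlapping segments [{a.start}, {a.end}) and [{b.start}, {b.end})"
                )

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def select(self, *labels: str) -> list[Segment]:
        return [r for r in self.rows if r.label in labels]

    def sample_mask(self, rate: int, n_samples: int, *labels: str) -> np.ndarray:
        """Boolean per-sample mask of the union of segments with the labels."""
        mask = np.zeros(n_samples, dtype=bool)
        for r in self.select(*labels):
            lo = min(n_samples, int(math.floor(r.start * rate)))
            hi = min(n_samples, int(math.floor(r.end * rate)))
            mask[lo:hi] = True
        return mask


@dataclass(frozen=True)
class SplitSpec:
    """Patient-level stratified split specification."""

    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


# ---------------------------------------------------------------------------
# WAV


def site_from_filename(path: str | Path) -> str:
    m = _SITE_RE.match(Path(path).stem)
    return m.group("site") if m else "OTHER"


def read_wav(path: str | Path) -> PcgRecording:
    """Read a 16-bit PCM mono WAV file; amplitudes are mapped to [-1, 1)."""
    path = Path(path)
    try:
        rate, data = wavfile.read(path)
    except Exception as exc:  # noqa: BLE001 - rewrap with the offending path
        raise FormatError(f"unreadable WAV file {path}: {exc}") from exc
    if data.ndim != 1:
        raise FormatError(f"{path}: expected mono audio, got {data.shape[1]} channels")
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / 32768.0
    elif np.issubdtype(data.dtype, np.floating):
        samples = data.astype(np.float64)
    else:
        raise FormatError(f"{path}: unsupported sample format {data.dtype}")
    return PcgRecording(
        samples=samples,
        rate=int(rate),
        site=site_from_filename(path),
        recording_id=path.stem,
    )


def write_wav(path: str | Path, recording: PcgRecording) -> None:
    """Write a recording as 16-bit PCM mono; amplitudes clipped to [-1, 1)."""
    q = np.clip(recording.samples, -1.0, 32767.0 / 32768.0)
    wavfile.write(Path(path), recording.rate, np.round(q * 32768.0).astype(np.int16))


# ---------------------------------------------------------------------------
# Patient metadata


def read_patient_metadata(path: str | Path) -> PatientRecord:
    """Parse ``key: value`` metadata lines; requires a valid ``Murmur:`` key.

    The murmur label is matched case-insensitively; every other key is kept
    verbatim in the demographics map. The patient id is taken from a
    ``Patient:`` key when present, else from the file stem.
    """
    path = Path(path)
    murmur: str | None = None
    patient_id = path.stem
    demographics: dict[str, str] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        if ":" not in line:
            raise FormatError(f"{path}:{lineno}: expected 'key: value', got {line!r}")
        key, _, value = line.partition(":")
        key, value = key.strip(), value.strip()
        if key.lower() == "murmur":
            matches = [m for m in MURMUR_LABELS if m.lower() == value.lower()]
            if not matches:
                raise FormatError(
                    f"{path}:{lineno}: murmur label must be one of "
                    f"{MURMUR_LABELS}, got {value!r}"
                )
            murmur = matches[0]
        elif key.lower() == "patient":
            patient_id = value
        else:
            demographics[key] = value
    if murmur is None:
        raise FormatError(f"{path}: missing required 'Murmur:' key")
    return PatientRecord(patient_id=patient_id, murmur=murmur, demographics=demographics)


def write_patient_metadata(path: str | Path, patient: PatientRecord) -> None:
    lines = [f"Patient: {patient.patient_id}", f"Murmur: {patient.murmur}"]
    lines += [f"{k}: {v}" for k, v in patient.demographics.items()]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Segmentation TSV


def read_segment_tsv(path: str | Path) -> SegmentTable:
    """Read a 3-column segmentation table (start, end, integer code)."""
    path = Path(path)
    rows: list[Segment] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise FormatError(f"{path}:{lineno}: expected 3 tab-separated columns")
        try:
            start, end = float(fields[0]), float(fields[1])
            code = int(fields[2])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric field: {exc}") from exc
        if code not in SEGMENT_CODES:
            raise FormatError(f"{path}:{lineno}: unknown segment code {code}")
        if not 0.0 <= start < end:
            raise FormatError(
                f"{path}:{lineno}: need 0 <= start < end, got {start} .. {end}"
            )
        rows.append(Segment(start, end, SEGMENT_CODES[code]))
    try:
        return SegmentTable(rows)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_segment_tsv(path: str | Path, table: SegmentTable) -> None:
    lines = [
        f"{r.start:.6f}\t{r.end:.6f}\t{SEGMENT_LABELS[r.label]}" for r in table.rows
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# Stratified split


def stratified_split(
    patients: list[PatientRecord], spec: SplitSpec = SplitSpec()
) -> tuple[list[PatientRecord], list[PatientRecord]]:
    """Patient-level stratified train/validation split.

    All recordings of a patient stay on the same side. Per-class train counts
    follow the largest-remainder method against a total of
    ``round(train_fraction * n_patients)``, so each class lands within one
    patient of ``train_fraction`` times its size; remainder ties break by
    class label order, and the within-class assignment is a seeded
    permutation of patients sorted by id, hence fully deterministic.
    """
    if not patients:
        raise ValueError("cannot split an empty patient list")
    by_class: dict[str, list[PatientRecord]] = {}
    for p in patients:
        by_class.setdefault(p.murmur, []).append(p)

    n_total = len(patients)
    n_train_total = int(round(spec.train_fraction * n_total))
    labels = sorted(by_class)  # deterministic class order
    quotas = {c: spec.train_fraction * len(by_class[c]) for c in labels}
    counts = {c: int(math.floor(quotas[c])) for c in labels}
    leftover = n_train_total - sum(counts.values())
    for c in sorted(labels, key=lambda c: (-(quotas[c] - counts[c]), c)):
        if leftover <= 0:
            break
        if counts[c] < len(by_class[c]):
            counts[c] += 1
            leftover -= 1

    rng = np.random.default_rng(spec.seed)
    train: list[PatientRecord] = []
    val: list[PatientRecord] = []
    for c in labels:
        members = sorted(by_class[c], key=lambda p: p.patient_id)
        order = rng.permutation(len(members))
        chosen = set(order[: counts[c]].tolist())
        for i, p in enumerate(members):
            (train if i in chosen else val).append(p)
    return train, val


# ---------------------------------------------------------------------------
# Dataset manifests


def load_manifest(path: str | Path, with_audio: bool = True) -> list[PatientRecord]:
    """Load a cohort from a ``manifest.json`` written by the simulator/CLI.

    The manifest maps patient ids to ``{"metadata": file, "recordings":
    [wav files], "murmur": label}``; paths are relative to the manifest.
    """
    path = Path(path)
    manifest = json.loads(path.read_text())
    root = path.parent
    patients: list[PatientRecord] = []
    for pid in sorted(manifest):
        entry = manifest[pid]
        patient = read_patient_metadata(root / entry["metadata"])
        if with_audio:
            patient.recordings = [read_wav(root / w) for w in entry["recordings"]]
        patients.append(patient)
    return patients
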