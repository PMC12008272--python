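"""Domain types and I/O for transcripts, NFS items and evaluation reports.

The atomic unit of every stage is a :class:`Transcript`: one free-speech
recording from one patient in one medication state, optionally annotated
with the 0-60 neuropsychiatric state score.  The Neuropsychiatric
Fluctuations Scale (NFS) is a 20-item self-report instrument, 10 items
describing typical ON-medication symptoms and 10 typical OFF-medication
symptoms; the packaged default item file
(``data/nfs_items_synthetic.csv``) contains the handful of item texts
quoted in the clinical literature plus theme-consistent synthetic
stand-ins for the remainder (``source`` column distinguishes them).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Any, Iterable, Iterator, Sequence

from .errors import SchemaError, ValidationError

SCORE_MIN = 0.0
SCORE_MAX = 60.0

REPORT_SCHEMA_VERSION = "1"

_REQUIRED_COLUMNS = ("patient_id", "recording_id", "med_state", "text")


class MedState(str, Enum):
    """Dopaminergic medication state of a recording."""

    ON = "ON"
    OFF = "OFF"
    UNKNOWN = "UNKNOWN"

    @classmethod
    def parse(cls, value: str) -> "MedState":
        v = str(value).strip().upper()
        if v in ("ON", "OFF", "UNKNOWN"):
            return cls(v)
        raise ValidationError(f"unrecognized med_state {value!r} (expected ON/OFF/UNKNOWN)")


@dataclass(frozen=True)
class Transcript:
    """One recording's text with its clinical annotations.

    ``score`` is the neuropsychiatric state score in [0, 60] (0 = very
    low mood, 60 = very high mood), absent when not assessed.
    """

    patient_id: str
    recording_id: str
    med_state: MedState
    text: str
    score: float | None = None
    language: str = "en"
    duration_s: float | None = None

    def __post_init__(self) -> None:
        if not self.text or not self.text.strip():
            raise ValidationError(
                f"transcript {self.patient_id}/{self.recording_id}: text is empty"
            )
        if self.score is not None and not (SCORE_MIN <= self.score <= SCORE_MAX):
            raise ValidationError(
                f"transcript {self.patient_id}/{self.recording_id}: score "
                f"{self.score} outside [{SCORE_MIN:g}, {SCORE_MAX:g}]"
            )
        if self.duration_s is not None and self.duration_s < 0:
            raise ValidationError(
                f"transcript {self.patient_id}/{self.recording_id}: negative duration"
            )


@dataclass(frozen=True)
class NFSItem:
    """One NFS scale item with its medication-state polarity."""

    item_id: int
    text: str
    polarity: MedState

    def __post_init__(self) -> None:
        if not 1 <= self.item_id <= 20:
            raise ValidationError(f"item_id {self.item_id} outside 1..20")
        if self.polarity not in (MedState.ON, MedState.OFF):
            raise ValidationError(f"item {self.item_id}: polarity must be ON or OFF")


@dataclass
class Dataset:
    """An ordered collection of transcripts plus provenance metadata."""

    transcripts: list[Transcript]
    provenance: str = ""
    repeat_trial: bool = False

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        per_patient_state: dict[tuple[str, MedState], int] = {}
        for t in self.transcripts:
            key = (t.patient_id, t.recording_id)
            if key in seen:
                raise ValidationError(f"duplicate (patient_id, recording_id) = {key}")
            seen.add(key)
            per_patient_state[(t.patient_id, t.med_state)] = (
                per_patient_state.get((t.patient_id, t.med_state), 0) + 1
            )
        if not self.repeat_trial:
            for (pid, state), n in per_patient_state.items():
                if n > 1:
                    raise ValidationError(
                        f"patient {pid} has {n} recordings in state {state.value}; "
                        "set repeat_trial=True for repeat-trial datasets"
                    )

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self) -> Iterator[Transcript]:
        return iter(self.transcripts)

    @property
    def patient_ids(self) -> list[str]:
        """Distinct patient ids in first-appearance order."""
        out: list[str] = []
        seen: set[str] = set()
        for t in self.transcripts:
            if t.patient_id not in seen:
                seen.add(t.patient_id)
                out.append(t.patient_id)
        return out


def _row_to_transcript(row: dict[str, Any], where: str) -> Transcript:
    for col in _REQUIRED_COLUMNS:
        if col not in row or row[col] is None or str(row[col]).strip() == "":
            raise SchemaError(f"{where}: missing required field {col!r}")
    score_raw = row.get("score")
    score = None
    if score_raw is not None and str(score_raw).strip() != "":
        try:
            score = float(score_raw)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"{where}: score {score_raw!r} is not numeric") from exc
        if not (SCORE_MIN <= score <= SCORE_MAX):
            raise ValidationError(
                f"{where}: score {score:g} outside [{SCORE_MIN:g}, {SCORE_MAX:g}]"
            )
    dur_raw = row.get("duration_s")
    dur = None
    if dur_raw is not None and str(dur_raw).strip() != "":
        dur = float(dur_raw)
    return Transcript(
        patient_id=str(row["patient_id"]).strip(),
        recording_id=str(row["recording_id"]).strip(),
        med_state=MedState.parse(str(row["med_state"])),
        text=str(row["text"]),
        score=score,
        language=str(row.get("language") or "en"),
        duration_s=dur,
    )


def load_transcripts(path: str | Path, fmt: str | None = None) -> Dataset:
    """Load a transcript table from CSV or JSON-lines.

    ``fmt`` is ``"csv"`` or ``"jsonl"``; inferred from the suffix when
    omitted.  Any malformed row raises with its line number — files load
    fully or not at all, rows are never silently dropped.
    """
    path = Path(path)
    if fmt is None:
        fmt = "jsonl" if path.suffix.lower() in (".jsonl", ".ndjson", ".json") else "csv"
    if fmt not in ("csv", "jsonl"):
        raise ValueError(f"unknown transcript format {fmt!r}")
    transcripts: list[Transcript] = []
    if fmt == "csv":
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                raise SchemaError(f"{path}: empty file, no header row")
            missing = [c for c in _REQUIRED_COLUMNS if c not in reader.fieldnames]
            if missing:
                raise SchemaError(f"{path}: missing required column(s) {missing}")
            for i, row in enumerate(reader, start=2):  # header is line 1
                transcripts.append(_row_to_transcript(row, f"{path}:line {i}"))
    else:
        with open(path, encoding="utf-8") as fh:
            for i, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    row = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise SchemaError(f"{path}:line {i}: invalid JSON") from exc
                transcripts.append(_row_to_transcript(row, f"{path}:line {i}"))
    return Dataset(transcripts=transcripts, provenance=f"file:{path}")


def write_transcripts(dataset: Dataset, path: str | Path) -> None:
    """Write a dataset as the canonical CSV (UTF-8, header row)."""
    path = Path(path)
    cols = ["patient_id", "recording_id", "med_state", "text", "score", "language", "duration_s"]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(cols)
        for t in dataset:
            writer.writerow(
                [
                    t.patient_id,
                    t.recording_id,
                    t.med_state.value,
                    t.text,
                    "" if t.score is None else repr(float(t.score)),
                    t.language,
                    "" if t.duration_s is None else repr(float(t.duration_s)),
                ]
            )


def default_nfs_items_path() -> Path:
    """Path of the packaged (partly synthetic) NFS item file."""
    return Path(str(resources.files("nfspeech").joinpath("data/nfs_items_synthetic.csv")))


def load_nfs_items(path: str | Path | None = None) -> list[NFSItem]:
    """Load the 20 NFS items, enforcing the 10 ON / 10 OFF balance."""
    path = default_nfs_items_path() if path is None else Path(path)
    items: list[NFSItem] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for col in ("item_id", "polarity", "text"):
            if reader.fieldnames is None or col not in reader.fieldnames:
                raise SchemaError(f"{path}: missing required column {col!r}")
        for i, row in enumerate(reader, start=2):
            items.append(
                NFSItem(
                    item_id=int(row["item_id"]),
                    text=row["text"],
                    polarity=MedState.parse(row["polarity"]),
                )
            )
    if len(items) != 20:
        raise ValidationError(f"{path}: expected 20 NFS items, found {len(items)}")
    n_on = sum(1 for it in items if it.polarity is MedState.ON)
    if n_on != 10:
        raise ValidationError(
            f"{path}: polarity imbalance — {n_on} ON / {20 - n_on} OFF (expected 10/10)"
        )
    if len({it.item_id for it in items}) != 20:
        raise ValidationError(f"{path}: duplicate item_id")
    return sorted(items, key=lambda it: it.item_id)


def write_report(report: Any, path: str | Path) -> None:
    """Serialize an evaluation report (or any dict-able object) to JSON.

    Output is key-sorted with a top-level ``schema_version`` so repeated
    runs with identical inputs produce byte-identical files.
    """
    payload = report.to_dict() if hasattr(report, "to_dict") else dict(report)
    payload.setdefault("schema_version", REPORT_SCHEMA_VERSION)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, allow_nan=False)
        fh.write("\n")


def read_report(path: str | Path) -> dict[str, Any]:
    """Load a report written by :func:`write_report`."""
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
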