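"""Reading and writing session files.

Native format is JSONL — one session object per line — because sessions are
ragged. A flat CSV dialect (one utterance per row, ``session_id`` column)
and an AnnoMI-style transcript CSV dialect are also read; the AnnoMI column
names are supplied via a configurable mapping since annotated-transcript
exports vary.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import pandas as pd

from .data import Category, Quality, Session, SessionSet, Speaker, Utterance
from .errors import FormatError, ValidationError

CSV_COLUMNS = ["session_id", "quality", "index", "speaker", "text", "category", "score"]

#: Default column mapping for the AnnoMI transcript dialect.
ANNOMI_COLUMNS = {
    "session_id": "transcript_id",
    "quality": "mi_quality",
    "speaker": "interlocutor",
    "text": "utterance_text",
    "category": "client_talk_type",
}

_CATEGORY_ALIASES = {
    "change": Category.CHANGE,
    "neutral": Category.NEUTRAL,
    "sustain": Category.SUSTAIN,
}


def _utterance_from_fields(session_id, index, speaker, text, category, score) -> Utterance:
    try:
        return Utterance(
            index=index,
            speaker=Speaker(speaker),
            text=text,
            category=Category(category) if category is not None else None,
            score=score,
        )
    except ValidationError as exc:
        raise ValidationError(f"session {session_id!r}: {exc}") from exc
    except ValueError as exc:
        raise FormatError(f"session {session_id!r}, index {index}: {exc}") from exc


def read_sessions(path, format: str = "jsonl", column_map: dict | None = None) -> SessionSet:
    """Read a session file in the named dialect.

    ``format`` is one of ``jsonl``, ``csv``, ``annomi_csv``. For
    ``annomi_csv``, ``column_map`` overrides :data:`ANNOMI_COLUMNS` entries.
    """
    path = Path(path)
    if format == "jsonl":
        return _read_jsonl(path)
    if format == "csv":
        return _read_csv(path)
    if format == "annomi_csv":
        return _read_annomi_csv(path, column_map)
    raise FormatError(f"unknown session file format {format!r}")


def _read_jsonl(path: Path) -> SessionSet:
    sessions = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise FormatError(f"{path}:{lineno}: invalid JSON: {exc}") from exc
            for col in ("session_id", "quality", "utterances"):
                if col not in rec:
                    raise FormatError(f"{path}:{lineno}: missing required field {col!r}")
            utts = []
            for i, u in enumerate(rec["utterances"]):
                if "speaker" not in u:
                    raise FormatError(
                        f"{path}:{lineno}: utterance {i} missing required field 'speaker'"
                    )
                utts.append(
                    _utterance_from_fields(
                        rec["session_id"],
                        u.get("index", i),
                        u["speaker"],
                        u.get("text"),
                        u.get("category"),
                        u.get("score"),
                    )
                )
            sessions.append(Session(rec["session_id"], Quality(rec["quality"]), tuple(utts)))
    return SessionSet(sessions, provenance="file")


def _opt_str(value):
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    value = str(value)
    return value if value != "" else None


def _opt_int(value, what: str):
    value = _opt_str(value)
    if value is None:
        return None
    try:
        return int(float(value))
    except ValueError as exc:
        raise FormatError(f"non-integer {what}: {value!r}") from exc


def _read_csv(path: Path) -> SessionSet:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in CSV_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    sessions = []
    for sid, grp in df.groupby("session_id", sort=False):
        quality = Quality(grp["quality"].iloc[0])
        utts = tuple(
            _utterance_from_fields(
                sid,
                _opt_int(row["index"], "index"),
                row["speaker"],
                _opt_str(row["text"]),
                _opt_str(row["category"]),
                _opt_int(row["score"], "score"),
            )
            for _, row in grp.iterrows()
        )
        sessions.append(Session(str(sid), quality, utts))
    return SessionSet(sessions, provenance="file")


def _read_annomi_csv(path: Path, column_map: dict | None) -> SessionSet:
    cols = dict(ANNOMI_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for role, col in cols.items():
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r} (maps to {role})")
    sessions = []
    for sid, grp in df.groupby(cols["session_id"], sort=False):
        quality = Quality(str(grp[cols["quality"]].iloc[0]).strip().lower())
        utts = []
        for i, (_, row) in enumerate(grp.iterrows()):
            speaker = str(row[cols["speaker"]]).strip().lower()
            raw_cat = _opt_str(row[cols["category"]])
            category = None
            if raw_cat is not None:
                category = _CATEGORY_ALIASES.get(raw_cat.strip().lower())
            utts.append(
                _utterance_from_fields(
                    sid, i, speaker, _opt_str(row[cols["text"]]), category, None
                )
            )
        sessions.append(Session(str(sid), quality, tuple(utts)))
    return SessionSet(sessions, provenance="file")


def write_sessions(sset: SessionSet, path, format: str = "jsonl") -> None:
    """Write sessions so that ``read_sessions`` round-trips field-for-field.

    Absent text/category/score fields are preserved as nulls (JSONL) or
    empty cells (CSV), never coerced to ``""`` / 0.
    """
    path = Path(path)
    if format == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for s in sset.sessions:
                rec = {
                    "session_id": s.session_id,
                    "quality": s.quality.value,
                    "utterances": [
                        {
                            "index": u.index,
                            "speaker": u.speaker.value,
                            "text": u.text,
                            "category": u.category.value if u.category else None,
                            "score": u.score,
                        }
                        for u in s.utterances
                    ],
                }
                fh.write(json.dumps(rec, sort_keys=True) + "\n")
    elif format == "csv":
        rows = [
            {
                "session_id": s.session_id,
                "quality": s.quality.value,
                "index": u.index,
                "speaker": u.speaker.value,
                "text": "" if u.text is None else u.text,
                "category": "" if u.category is None else u.category.value,
                "score": "" if u.score is None else u.score,
            }
            for s in sset.sessions
            for u in s.utterances
        ]
        pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)
    else:
        raise FormatError(f"unknown session file format {format!r}")
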