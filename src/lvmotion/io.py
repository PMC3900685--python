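"""Readers and writers for the coordinate, metadata and event-time formats.

Coordinate frames travel as a plain CSV matrix with one row per frame and
``3k`` columns ordered ``x1,y1,z1,...,xk,yk,zk`` (the layout of deposited
341 x 7782 LV datasets).  Subject affiliation, status and acquisition
times live in a metadata JSON; electromechanical event times in a JSON or
CSV file with six labeled times (ms) per subject.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .shape_core import LandmarkConfiguration, ShapeSequence
from .trajectory import EVENT_NAMES, EventTimes


def write_coords_csv(path, frames_matrix: np.ndarray) -> None:
    """Write a frames x (3k) coordinate matrix as headerless CSV."""
    pd.DataFrame(np.asarray(frames_matrix, dtype=float)).to_csv(
        path, header=False, index=False)


def read_coords_csv(path) -> np.ndarray:
    """Read a headerless coordinate CSV; columns must divide by 3 and be finite."""
    mat = pd.read_csv(path, header=None).to_numpy(dtype=float)
    if mat.shape[1] % 3:
        raise ValueError(f"column count {mat.shape[1]} is not divisible by 3")
    if not np.all(np.isfinite(mat)):
        raise ValueError("coordinate matrix contains non-finite values")
    return mat


def write_metadata_json(path, sequences: list[ShapeSequence],
                        landmark_metadata: dict | None = None) -> None:
    meta = {
        "subjects": [
            {
                "id": s.subject_id,
                "status": s.status,
                "n_frames": s.n_frames,
                "times_ms": s.times_ms.tolist(),
            }
            for s in sequences
        ]
    }
    if landmark_metadata:
        meta["landmarks"] = landmark_metadata
    Path(path).write_text(json.dumps(meta, indent=1))


def write_events_json(path, events: dict[str, EventTimes]) -> None:
    payload = {
        sid: {name: getattr(ev, name) for name in EVENT_NAMES}
        for sid, ev in events.items()
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_events(path) -> dict[str, EventTimes]:
    """Read per-subject event times from JSON or CSV (six labeled times, ms)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        return {sid: EventTimes(**{n: float(v[n]) for n in EVENT_NAMES})
                for sid, v in payload.items()}
    df = pd.read_csv(path)
    missing = set(EVENT_NAMES) - set(df.columns)
    if missing or "subject_id" not in df.columns:
        raise ValueError(f"events CSV needs columns subject_id + {list(EVENT_NAMES)}")
    return {
        str(row["subject_id"]): EventTimes(**{n: float(row[n]) for n in EVENT_NAMES})
        for _, row in df.iterrows()
    }


def read_dataset(coords_csv, metadata_json, events_path=None):
    """Assemble typed per-subject sequences from the on-disk formats.

    Validates that the row count equals the sum of per-subject frame
    counts, that the landmark count is constant (homology contract), and
    that acquisition times are strictly increasing.

    Returns ``(sequences, events)`` where ``events`` is None when no event
    file is given.
    """
    mat = read_coords_csv(coords_csv)
    meta = json.loads(Path(metadata_json).read_text())
    subjects = meta["subjects"]
    total = sum(s["n_frames"] for s in subjects)
    if total != mat.shape[0]:
        raise ValueError(
            f"metadata declares {total} frames but the matrix has {mat.shape[0]} rows")
    k = mat.shape[1] // 3
    if k < 4:
        raise ValueError("LV datasets need at least 4 landmarks")

    lm_meta = meta.get("landmarks", {})
    surface_labels = lm_meta.get("surface_labels")
    if surface_labels is not None:
        surface_labels = np.asarray(surface_labels, dtype=object)

    sequences = []
    row = 0
    for s in subjects:
        n = s["n_frames"]
        frames = [
            LandmarkConfiguration(coords=mat[row + j].reshape(k, 3),
                                  surface_labels=surface_labels)
            for j in range(n)
        ]
        sequences.append(ShapeSequence(
            subject_id=str(s["id"]), status=s["status"],
            frames=frames, times_ms=np.asarray(s["times_ms"], dtype=float)))
        row += n

    events = read_events(events_path) if events_path is not None else None
    return sequences, events


def write_dataset(outdir, sequences: list[ShapeSequence],
                  events: dict[str, EventTimes] | None = None) -> dict[str, Path]:
    """Write a cohort in the package's standard on-disk layout."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = [f.coords.ravel() for s in sequences for f in s.frames]
    paths = {"coords": outdir / "coords.csv", "metadata": outdir / "metadata.json"}
    write_coords_csv(paths["coords"], np.vstack(rows))
    lm = None
    first = sequences[0].frames[0]
    if first.surface_labels is not None:
        lm = {"surface_labels": first.surface_labels.tolist()}
    write_metadata_json(paths["metadata"], sequences, lm)
    if events is not None:
        paths["events"] = outdir / "events.json"
        write_events_json(paths["events"], events)
    return paths
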