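"""File formats: PNG stimuli, CSV tables, JSON configs and manifests."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .psychophysics import ResponseRecord, TaskCondition

__all__ = [
    "save_png",
    "load_png",
    "stimulus_path",
    "responses_to_frame",
    "frame_to_responses",
    "write_responses",
    "read_responses",
    "write_json",
    "read_json",
    "file_sha256",
]

RESPONSE_COLUMNS = [
    "observer_id",
    "environment",
    "task",
    "illumination_condition",
    "object",
    "difficulty",
    "m",
    "chosen_index",
    "correct",
]


def save_png(image: np.ndarray, path: Path) -> None:
    if image.dtype != np.uint8:
        raise ValueError("images are written as 8-bit sRGB")
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(image, mode="RGB").save(path, format="PNG")


def load_png(path: Path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


def stimulus_path(
    root: Path, task: str, illum: int, obj: int, value: float, pose_deg: int
) -> Path:
    """Directory layout mirroring the public dataset's organization."""
    return (
        Path(root)
        / f"task_{task}"
        / f"illum_{illum}"
        / f"object_{obj}"
        / f"param_{value:g}"
        / f"pose_{pose_deg}.png"
    )


def responses_to_frame(records: list[ResponseRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        c = r.condition
        rows.append(
            {
                "observer_id": r.observer_id,
                "environment": r.environment,
                "task": c.dimension,
                "illumination_condition": c.illumination,
                "object": c.object_id,
                "difficulty": c.difficulty,
                "m": 4 if c.illumination == 1 else 3,
                "chosen_index": r.chosen_index,
                "correct": int(r.correct),
            }
        )
    return pd.DataFrame(rows, columns=RESPONSE_COLUMNS)


def frame_to_responses(df: pd.DataFrame) -> list[ResponseRecord]:
    missing = set(RESPONSE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"response table missing columns: {sorted(missing)}")
    records = []
    for i, row in df.iterrows():
        try:
            cond = TaskCondition(
                dimension=str(row["task"]),
                object_id=int(row["object"]),
                illumination=int(row["illumination_condition"]),
                difficulty=float(row["difficulty"]),
            )
            records.append(
                ResponseRecord(
                    observer_id=str(row["observer_id"]),
                    environment=str(row["environment"]),
                    condition=cond,
                    chosen_index=int(row["chosen_index"]),
                    correct=bool(int(row["correct"])),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"malformed response row {i}: {exc}") from exc
    return records


def write_responses(records: list[ResponseRecord], path: Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    responses_to_frame(records).to_csv(path, index=False)


def read_responses(path: Path) -> list[ResponseRecord]:
    return frame_to_responses(pd.read_csv(path))


def write_json(obj, path: Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: Path):
    return json.loads(Path(path).read_text())


def file_sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
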