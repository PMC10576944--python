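"""File I/O: images, class maps, score tables, and YAML configuration."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .classify import ClassifierParams
from .scoring import PositivityFractions, SampleRecord

SCORES_COLUMNS = [
    "sample_id",
    "tissue_type",
    "t_stage",
    "n_stage",
    "m_stage",
    "n_analyzed",
    "f_negative",
    "f_weak",
    "f_medium",
    "f_strong",
    "h_score",
]


def read_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit RGB image (PNG or TIFF) as an H x W x 3 uint8 array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"), dtype=np.uint8)


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Write an H x W x 3 uint8 array as an 8-bit RGB image."""
    Image.fromarray(np.asarray(image, dtype=np.uint8), mode="RGB").save(path)


def write_class_map(path: str | Path, class_map: np.ndarray) -> None:
    """Write a class map as a single-channel PNG with the integer codes."""
    Image.fromarray(np.asarray(class_map, dtype=np.uint8), mode="L").save(path)


def read_class_map(path: str | Path) -> np.ndarray:
    """Read a single-channel class-map PNG back to a uint8 array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("L"), dtype=np.uint8)


def records_to_frame(records: Sequence[SampleRecord]) -> pd.DataFrame:
    rows = [
        {
            "sample_id": r.sample_id,
            "tissue_type": r.tissue_type,
            "t_stage": r.t_stage,
            "n_stage": r.n_stage,
            "m_stage": r.m_stage,
            "n_analyzed": r.n_analyzed,
            "f_negative": r.fractions.f_negative,
            "f_weak": r.fractions.f_weak,
            "f_medium": r.fractions.f_medium,
            "f_strong": r.fractions.f_strong,
            "h_score": r.h_score,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=SCORES_COLUMNS)


def write_scores(records: Sequence[SampleRecord], path: str | Path) -> Path:
    """Write per-sample scores to CSV in the standard column order."""
    path = Path(path)
    records_to_frame(records).to_csv(path, index=False)
    return path


def read_scores(path: str | Path) -> list[SampleRecord]:
    """Read a scores CSV back into sample records."""
    df = pd.read_csv(path, dtype={"t_stage": str, "n_stage": str, "m_stage": str})
    records = []
    for _, row in df.iterrows():
        records.append(
            SampleRecord(
                sample_id=str(row["sample_id"]),
                tissue_type=str(row["tissue_type"]),
                t_stage=str(row["t_stage"]),
                n_stage=str(row["n_stage"]),
                m_stage=str(row["m_stage"]),
                n_analyzed=int(row["n_analyzed"]),
                fractions=PositivityFractions(
                    f_negative=float(row["f_negative"]),
                    f_weak=float(row["f_weak"]),
                    f_medium=float(row["f_medium"]),
                    f_strong=float(row["f_strong"]),
                ),
                h_score=float(row["h_score"]),
            )
        )
    return records


def load_config(path: str | Path) -> dict:
    """Load a YAML configuration file to a dict ({} for an empty file)."""
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def classifier_params_from_config(config: dict) -> ClassifierParams:
    """Build classifier params from a config dict's ``classifier:`` section."""
    section = config.get("classifier", {}) or {}
    params = ClassifierParams(**section)
    params.validate()
    return params
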