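import csv
from pathlib import Path

import pytest

from padpref.pad_core import DEFAULT_NORMS, PADVector

DATA_DIR = Path(__file__).parent / "data"

#: Column order of the proximity fixtures ("Digust" is the transcribed
#: spelling of Disgust and is normalized at load time).
PROX_COLUMNS = (
    "Joyful",
    "Relaxed",
    "Surprise",
    "Dependent",
    "Boring",
    "Fear",
    "Contempt",
    "Digust",
)


def _normalize_label(label: str) -> str:
    return "Disgust" if label == "Digust" else label


def load_pad_table(name: str):
    """Rows: dicts with group, stimulus, pad (or None if masked), emotion."""
    rows = []
    with (DATA_DIR / name).open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            complete = all(row[c] != "" for c in ("P", "A", "D"))
            rows.append(
                {
                    "group": row["group"],
                    "stimulus": row["stimulus"],
                    "pad": PADVector(float(row["P"]), float(row["A"]), float(row["D"]))
                    if complete
                    else None,
                    "emotion": _normalize_label(row["emotion"]) if row["emotion"] else None,
                }
            )
    return rows


def load_prox_table(name: str):
    """Rows: dicts with group, stimulus, and label -> printed distance."""
    rows = []
    with (DATA_DIR / name).open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            cells = {
                _normalize_label(c): float(row[c]) for c in PROX_COLUMNS if row[c] != ""
            }
            rows.append(
                {"group": row["group"], "stimulus": row["stimulus"], "cells": cells}
            )
    return rows


@pytest.fixture(scope="session")
def painting_pad():
    return load_pad_table("painting_pad.csv")


@pytest.fixture(scope="session")
def interior_pad():
    return load_pad_table("interior_pad.csv")


@pytest.fixture(scope="session")
def painting_prox():
    return load_prox_table("painting_proximity.csv")


@pytest.fixture(scope="session")
def interior_prox():
    return load_prox_table("interior_proximity.csv")


@pytest.fixture(scope="session")
def norm_by_label():
    return {n.label: n for n in DEFAULT_NORMS}
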