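"""Readers/writers for ratings, norms, preference reports, and epoch sets.

File formats
------------
ratings CSV
    UTF-8, header ``participant_id,group,sex,age_group,stimulus_id,v1,...,v12``
    (``sex`` and ``age_group`` are optional metadata columns and may be
    absent); one record per row.
norms CSV
    header ``label,PN,AN,DN``; the package ships its normative inventory
    as the built-in default, so this file is only needed to override it.
results CSV
    tidy, one row per group × stimulus, mirroring
    :class:`~padpref.pad_core.PreferenceResult`; floats printed half-up at
    4 decimals (PAD, proximities); missing cells rendered empty, never 0.
epoch container
    ``<stem>.dat`` — whitespace-separated text matrix with
    n_trials × n_channels rows of n_samples voltages (μV) — plus a JSON
    sidecar ``<stem>.json`` holding fs, t0_ms, channel names, per-trial
    condition labels, and the array shape.
"""

from __future__ import annotations

import csv
import json
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from padpref.erp_pipeline import EpochSet, PeakTable
from padpref.pad_core import (
    DEFAULT_NORMS,
    EmotionNorm,
    PreferenceResult,
    RatingRecord,
    ValidationError,
)

__all__ = [
    "read_ratings",
    "write_ratings",
    "read_norms",
    "write_norms",
    "write_report",
    "write_text_report",
    "read_epochs",
    "write_epochs",
    "round_half_up",
    "fmt",
]

RATINGS_REQUIRED = ("participant_id", "group", "stimulus_id") + tuple(
    f"v{i}" for i in range(1, 13)
)


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal half-up rounding (the convention used in printed tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def fmt(x: float | None, ndigits: int = 4) -> str:
    """Render a float at fixed decimals, or an empty cell for missing."""
    if x is None:
        return ""
    return f"{round_half_up(x, ndigits):.{ndigits}f}"


def read_ratings(path: str | Path) -> list[RatingRecord]:
    """Read and validate a ratings CSV; errors name the row and field."""
    path = Path(path)
    records: list[RatingRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in RATINGS_REQUIRED if c not in header]
        if missing:
            raise ValidationError(
                f"{path.name}: header missing required columns {missing}"
            )
        for lineno, row in enumerate(reader, start=2):
            items = []
            for i in range(1, 13):
                cell = (row.get(f"v{i}") or "").strip()
                if cell == "":
                    raise ValidationError(
                        f"{path.name} row {lineno}: missing value in column v{i}"
                    )
                try:
                    items.append(float(cell))
                except ValueError:
                    raise ValidationError(
                        f"{path.name} row {lineno}: non-numeric value "
                        f"{cell!r} in column v{i}"
                    ) from None
            try:
                records.append(
                    RatingRecord(
                        participant_id=row["participant_id"],
                        group=row["group"],
                        stimulus_id=row["stimulus_id"],
                        items=tuple(items),
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"{path.name} row {lineno}: {exc}") from None
    return records


_GROUP_META = {
    "young": ("", "young"),
    "young-man": ("male", "young"),
    "young-woman": ("female", "young"),
    "elderly": ("", "elderly"),
}


def write_ratings(records: Iterable[RatingRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["participant_id", "group", "sex", "age_group", "stimulus_id"]
            + [f"v{i}" for i in range(1, 13)]
        )
        for rec in records:
            sex, age = _GROUP_META[rec.group]
            writer.writerow(
                [rec.participant_id, rec.group, sex, age, rec.stimulus_id]
                + [repr(v) for v in rec.items]
            )


def read_norms(path: str | Path) -> list[EmotionNorm]:
    path = Path(path)
    norms: list[EmotionNorm] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for col in ("label", "PN", "AN", "DN"):
            if col not in (reader.fieldnames or []):
                raise ValidationError(f"{path.name}: header missing column {col!r}")
        for lineno, row in enumerate(reader, start=2):
            try:
                norms.append(
                    EmotionNorm(
                        label=row["label"].strip(),
                        PN=float(row["PN"]),
                        AN=float(row["AN"]),
                        DN=float(row["DN"]),
                    )
                )
            except ValueError:
                raise ValidationError(
                    f"{path.name} row {lineno}: non-numeric norm value"
                ) from None
    if not norms:
        raise ValidationError(f"{path.name}: no norm rows")
    return norms


def write_norms(norms: Iterable[EmotionNorm], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["label", "PN", "AN", "DN"])
        for n in norms:
            writer.writerow([n.label, f"{n.PN:g}", f"{n.AN:g}", f"{n.DN:g}"])


def write_report(
    results: Sequence[PreferenceResult],
    path: str | Path,
    norms: Sequence[EmotionNorm] = DEFAULT_NORMS,
) -> None:
    """Write the tidy results CSV with deterministic column order."""
    path = Path(path)
    labels = [n.label for n in norms]
    header = (
        ["group", "stimulus_id", "n", "P", "A", "D", "octant", "zero_flag"]
        + [f"prox_{lbl}" for lbl in labels]
        + ["nearest_emotion", "nearest_distance", "tie_flag", "pleasure_band"]
    )
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for res in results:
            writer.writerow(
                [
                    res.group,
                    res.stimulus_id,
                    res.n_records or "",
                    fmt(res.pad.P),
                    fmt(res.pad.A),
                    fmt(res.pad.D),
                    res.octant.label,
                    int(res.octant.zero_flag),
                ]
                + [fmt(res.proximities.get(lbl)) for lbl in labels]
                + [
                    res.nearest_emotion,
                    fmt(res.nearest_distance),
                    int(res.tie_flag),
                    res.pleasure_band,
                ]
            )


def write_text_report(
    results: Sequence[PreferenceResult],
    path: str | Path,
    peaks: dict[str, PeakTable] | None = None,
) -> None:
    """Human-readable companion to the tidy CSV."""
    path = Path(path)
    lines = ["Preference report", "=" * 17, ""]
    for res in results:
        lines.append(
            f"{res.group:12s} {res.stimulus_id:24s} "
            f"PAD=({fmt(res.pad.P)}, {fmt(res.pad.A)}, {fmt(res.pad.D)}) "
            f"octant={res.octant.label:10s} "
            f"nearest={res.nearest_emotion} ({fmt(res.nearest_distance)}) "
            f"band={res.pleasure_band}"
        )
    if peaks:
        lines += ["", "Peak amplitudes (uV)", "-" * 20]
        for cond, table in peaks.items():
            cells = ", ".join(f"{ch}={fmt(v, 3)}" for ch, v in table.peaks.items())
            lines.append(f"{cond:8s} {cells}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_epochs(epochs: EpochSet, stem: str | Path) -> tuple[Path, Path]:
    """Write the text epoch container (``<stem>.dat`` + ``<stem>.json``)."""
    stem = Path(stem)
    dat = stem.with_suffix(".dat")
    hdr = stem.with_suffix(".json")
    n_trials, n_channels, n_samples = epochs.data.shape
    np.savetxt(dat, epochs.data.reshape(n_trials * n_channels, n_samples))
    hdr.write_text(
        json.dumps(
            {
                "fs": epochs.fs,
                "t0_ms": epochs.t0_ms,
                "channels": list(epochs.channels),
                "conditions": list(epochs.conditions),
                "shape": [n_trials, n_channels, n_samples],
            },
            indent=2,
        )
        + "\n",
        encoding="utf-8",
    )
    return dat, hdr


def read_epochs(stem: str | Path) -> EpochSet:
    """Read an epoch container written by :func:`write_epochs`."""
    stem = Path(stem)
    meta = json.loads(stem.with_suffix(".json").read_text(encoding="utf-8"))
    n_trials, n_channels, n_samples = meta["shape"]
    flat = np.loadtxt(stem.with_suffix(".dat"), ndmin=2)
    data = flat.reshape(n_trials, n_channels, n_samples)
    return EpochSet(
        data=data,
        fs=float(meta["fs"]),
        t0_ms=float(meta["t0_ms"]),
        channels=tuple(meta["channels"]),
        conditions=tuple(meta["conditions"]),
    )
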