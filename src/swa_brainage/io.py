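"""Delimited-text and JSON interchange formats.

* SWA matrix: CSV with header ``mouse_id,age_months,exercise,h01,...,h12``;
  exercise encoded ``yes``/``no``.
* Epoch series: CSV, one row per 4-s epoch:
  ``mouse_id,epoch_index,offset_s,state,artifact,p_0.50,...,p_25.00``.
* Cohort spec: JSON mirroring :class:`~swa_brainage.cohort.CohortSpec`.
* Centroids: CSV ``group,x,y,z``; distance matrix: labelled TSV.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Union

import numpy as np
import pandas as pd

from .cohort import (
    EPOCH_SECONDS,
    FREQUENCY_GRID,
    N_HOURS,
    ClassLabel,
    CohortSpec,
    EpochSpectrumSeries,
    SWAProfile,
)
from .clustering import CentroidDistanceMatrix

PathLike = Union[str, Path]

HOUR_COLUMNS = [f"h{h:02d}" for h in range(1, N_HOURS + 1)]
SWA_HEADER = ["mouse_id", "age_months", "exercise", *HOUR_COLUMNS]
POWER_COLUMNS = [f"p_{f:.2f}" for f in FREQUENCY_GRID]
EPOCH_HEADER = ["mouse_id", "epoch_index", "offset_s", "state", "artifact", *POWER_COLUMNS]


# --- SWA matrices ------------------------------------------------------------

def write_swa_csv(profiles: Sequence[SWAProfile], path: PathLike) -> None:
    rows = [
        {
            "mouse_id": p.mouse_id,
            "age_months": p.label.age_months,
            "exercise": "yes" if p.label.exercise else "no",
            **{col: float(v) for col, v in zip(HOUR_COLUMNS, p.values)},
        }
        for p in profiles
    ]
    pd.DataFrame(rows, columns=SWA_HEADER).to_csv(path, index=False)


def read_swa_csv(path: PathLike) -> List[SWAProfile]:
    df = pd.read_csv(path)
    missing = [c for c in SWA_HEADER if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    out = []
    for _, row in df.iterrows():
        exercise = str(row["exercise"]).strip().lower()
        if exercise not in ("yes", "no"):
            raise ValueError(f"{path}: exercise must be yes/no, got {row['exercise']!r}")
        label = ClassLabel(int(row["age_months"]), exercise == "yes")
        out.append(SWAProfile(str(row["mouse_id"]), label, row[HOUR_COLUMNS].to_numpy(float)))
    return out


@dataclass(frozen=True)
class Finding:
    """One machine-readable validation finding (row is 1-based, 0 = header)."""

    code: str
    row: int
    message: str


def validate_swa_file(path: PathLike) -> List[Finding]:
    """Validate an SWA matrix file without raising on content errors.

    Checks the header, the label vocabulary (ages 6/18/24, exercise yes/no),
    twelve complete positive finite hourly values per row, and duplicate
    mouse ids.  Returns an empty list for a well-formed file.
    """
    findings: List[Finding] = []
    seen_ids: Dict[str, int] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            return [Finding("EMPTY_FILE", 0, "file has no header row")]
        if [h.strip() for h in header] != SWA_HEADER:
            findings.append(Finding("BAD_HEADER", 0, f"expected header {','.join(SWA_HEADER)}"))
        for lineno, row in enumerate(reader, start=1):
            if len(row) < len(SWA_HEADER):
                findings.append(Finding("MISSING_HOUR", lineno,
                                        f"row has {len(row)} fields, expected {len(SWA_HEADER)}"))
                continue
            if len(row) > len(SWA_HEADER):
                findings.append(Finding("EXTRA_FIELD", lineno,
                                        f"row has {len(row)} fields, expected {len(SWA_HEADER)}"))
                continue
            mouse_id, age, exercise, *hours = [f.strip() for f in row]
            if mouse_id in seen_ids:
                findings.append(Finding("DUPLICATE_ID", lineno,
                                        f"mouse_id {mouse_id!r} already seen at row {seen_ids[mouse_id]}"))
            else:
                seen_ids[mouse_id] = lineno
            if age not in ("6", "18", "24"):
                findings.append(Finding("BAD_LABEL", lineno, f"age_months must be 6/18/24, got {age!r}"))
            if exercise.lower() not in ("yes", "no"):
                findings.append(Finding("BAD_LABEL", lineno, f"exercise must be yes/no, got {exercise!r}"))
            for col, val in zip(HOUR_COLUMNS, hours):
                try:
                    x = float(val)
                except ValueError:
                    findings.append(Finding("BAD_VALUE", lineno, f"{col}: not a number ({val!r})"))
                    continue
                if not math.isfinite(x) or x <= 0:
                    findings.append(Finding("BAD_VALUE", lineno, f"{col}: must be finite and > 0"))
    return findings


# --- epoch series ------------------------------------------------------------

def write_epochs_csv(series_iter: Iterable[EpochSpectrumSeries], path: PathLike) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(EPOCH_HEADER)
        for series in series_iter:
            for i in range(len(series.offsets)):
                writer.writerow([
                    series.mouse_id, i, int(series.offsets[i]), series.states[i],
                    int(series.artifact[i]),
                    *(repr(float(v)) for v in series.power[i]),
                ])


def read_epochs_csv(path: PathLike) -> List[EpochSpectrumSeries]:
    df = pd.read_csv(path)
    missing = [c for c in EPOCH_HEADER if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    out = []
    for mouse_id, grp in df.groupby("mouse_id", sort=False):
        grp = grp.sort_values("epoch_index")
        out.append(EpochSpectrumSeries(
            mouse_id=str(mouse_id),
            label=None,  # epoch files carry no class label
            freqs=FREQUENCY_GRID.copy(),
            power=grp[POWER_COLUMNS].to_numpy(float),
            states=grp["state"].to_numpy(str),
            artifact=grp["artifact"].to_numpy(bool),
            offsets=grp["offset_s"].to_numpy(int),
        ))
    return out


# --- cohort specs ------------------------------------------------------------

def cohort_spec_to_json(spec: CohortSpec, path: PathLike) -> None:
    doc = {
        "seed": spec.seed,
        "floor": spec.floor,
        "classes": {
            lab.short: {
                "count": int(spec.counts[lab]),
                "mean": [float(v) for v in spec.means[lab]],
                "covariance": [[float(v) for v in row] for row in spec.covariances[lab]],
            }
            for lab in spec.labels
        },
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def cohort_spec_from_json(path: PathLike) -> CohortSpec:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    counts, means, covs = {}, {}, {}
    for short, entry in doc["classes"].items():
        lab = ClassLabel.parse(short)
        counts[lab] = int(entry["count"])
        means[lab] = np.asarray(entry["mean"], dtype=float)
        covs[lab] = np.asarray(entry["covariance"], dtype=float)
    return CohortSpec(counts=counts, means=means, covariances=covs,
                      seed=int(doc.get("seed", 0)), floor=float(doc.get("floor", 1.0)))


# --- centroids and distance matrices -----------------------------------------

def write_centroids_csv(centroids: Dict[str, np.ndarray], path: PathLike) -> None:
    dims = len(next(iter(centroids.values())))
    cols = ["group", *("xyz"[i] if dims <= 3 else f"c{i + 1}" for i in range(dims))]
    rows = [[lab, *(repr(float(v)) for v in coords)] for lab, coords in centroids.items()]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(cols)
        writer.writerows(rows)


def read_centroids_csv(path: PathLike) -> Dict[str, np.ndarray]:
    df = pd.read_csv(path)
    if "group" not in df.columns or df.shape[1] < 2:
        raise ValueError(f"{path}: expected header group,<coordinate columns>")
    coord_cols = [c for c in df.columns if c != "group"]
    return {str(r["group"]): r[coord_cols].to_numpy(float) for _, r in df.iterrows()}


def write_distance_matrix(matrix: CentroidDistanceMatrix, path: PathLike, decimals: int = 2) -> None:
    rounded = matrix.rounded(decimals)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["group", *matrix.labels])
        for lab, row in zip(matrix.labels, rounded):
            writer.writerow([lab, *(f"{v:.{decimals}f}" for v in row)])
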