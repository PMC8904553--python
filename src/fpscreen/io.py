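"""Readers and writers for the on-disk formats the pipeline touches.

Spectra are stored the way an optical spectrum analyzer exports them: plain
two-column delimited text, wavelength [nm] then optical power, one file per
measurement, ``#``-prefixed comment lines allowed, whitespace or comma
delimited (auto-detected).  A CSV manifest ties the files to their liquid
label index, replicate number and seed.  Feature tables, fold plans and the
flat results table are CSV; the full evaluation report is JSON.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import EvaluationReport
from .data import FoldPlan, LabeledDataset
from .exceptions import FPScreenError
from .features import FEATURE_NAMES
from .sim import Interferogram

__all__ = [
    "write_spectrum",
    "read_spectrum",
    "write_study",
    "read_manifest",
    "write_feature_table",
    "read_feature_table",
    "write_fold_plan",
    "read_fold_plan",
    "write_report",
]

MANIFEST_NAME = "manifest.csv"


def write_spectrum(igram: Interferogram, path: str | Path) -> None:
    """Write one spectrum as two-column text (wavelength nm, power)."""
    path = Path(path)
    header = "# wavelength_nm\tpower"
    np.savetxt(path, np.column_stack([igram.wavelength, igram.power]),
               fmt="%.8g", delimiter="\t", header=header, comments="")


def read_spectrum(path: str | Path) -> Interferogram:
    """Read a two-column delimited spectrum file.

    Comment lines starting with '#' are skipped; the delimiter (whitespace
    or comma) is auto-detected from the first data line.
    """
    path = Path(path)
    lines = [
        ln.strip() for ln in path.read_text().splitlines()
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if not lines:
        raise FPScreenError(f"no data lines in spectrum file {path}")
    delimiter = "," if "," in lines[0] else None  # None -> any whitespace
    rows = []
    for ln in lines:
        parts = ln.split(delimiter)
        if len(parts) < 2:
            raise FPScreenError(f"malformed line in {path}: {ln!r}")
        rows.append((float(parts[0]), float(parts[1])))
    arr = np.array(rows, dtype=float)
    order = np.argsort(arr[:, 0])
    return Interferogram(wavelength=arr[order, 0], power=arr[order, 1],
                         metadata={"source": str(path)})


def write_study(spectra: list[Interferogram], out_dir: str | Path, seed: int) -> Path:
    """Write a study's spectra plus its manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = out_dir / MANIFEST_NAME
    with open(manifest_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["file", "label_index", "operating_index", "replicate", "seed"])
        for igram in spectra:
            md = igram.metadata
            name = f"spectrum_{md.get('spectrum_id', 0):04d}.txt"
            write_spectrum(igram, out_dir / name)
            writer.writerow(
                [name, md.get("label_index", ""), md.get("operating_index", ""),
                 md.get("replicate", ""), seed]
            )
    return manifest_path


def read_manifest(manifest_path: str | Path) -> list[Interferogram]:
    """Load every spectrum listed in a manifest, restoring its metadata."""
    manifest_path = Path(manifest_path)
    table = pd.read_csv(manifest_path)
    if len(table) == 0:
        raise FPScreenError(f"manifest {manifest_path} lists no spectra")
    spectra = []
    for i, row in table.iterrows():
        igram = read_spectrum(manifest_path.parent / row["file"])
        igram.metadata.update(
            label_index=float(row["label_index"]),
            operating_index=float(row.get("operating_index", row["label_index"])),
            replicate=int(row.get("replicate", 0)),
            spectrum_id=int(i),
        )
        spectra.append(igram)
    return spectra


def write_feature_table(ds: LabeledDataset, path: str | Path) -> None:
    """Feature table as CSV: F1..F18 first, provenance columns after."""
    cols = list(FEATURE_NAMES) + [c for c in ds.frame.columns if c not in FEATURE_NAMES]
    ds.frame[cols].to_csv(path, index_label="row_id")


def read_feature_table(path: str | Path) -> LabeledDataset:
    frame = pd.read_csv(path, index_col="row_id")
    return LabeledDataset(frame)


def write_fold_plan(plan: FoldPlan, path: str | Path) -> None:
    """Fold plan as a CSV of (row_id, role, fold); validation rows have no fold."""
    rows = [
        {"row_id": int(idx), "role": "train", "fold": int(f)}
        for idx, f in zip(plan.train_indices, plan.folds)
    ]
    rows += [
        {"row_id": int(idx), "role": "validation", "fold": ""}
        for idx in plan.validation_indices
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_fold_plan(path: str | Path) -> FoldPlan:
    table = pd.read_csv(path)
    tr = table[table["role"] == "train"]
    va = table[table["role"] == "validation"]
    return FoldPlan(
        k=int(tr["fold"].max()) + 1,
        train_indices=tr["row_id"].to_numpy(dtype=int),
        folds=tr["fold"].to_numpy(dtype=int),
        validation_indices=va["row_id"].to_numpy(dtype=int),
    )


def write_report(report: EvaluationReport, out_dir: str | Path) -> None:
    """JSON report, flat CSV table and per-classifier confusion matrices."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "report.json").write_text(report.to_json())
    report.to_table().to_csv(out_dir / "report.csv", index=False)
    for c in report.classifiers:
        if c.validation_cm is None:
            continue
        cm = c.validation_cm
        # 2x2 layout: rows = actual (cancer, healthy), cols = predicted
        frame = pd.DataFrame(
            [[cm.tp, cm.fn], [cm.fp, cm.tn]],
            index=["actual_cancer", "actual_healthy"],
            columns=["pred_cancer", "pred_healthy"],
        )
        frame.to_csv(out_dir / f"confusion_validation_{c.family}.csv")
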