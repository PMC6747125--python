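"""File I/O for descriptor tables, measurements, models and predictions.

Dialects: CSV is comma-separated UTF-8 with a mandatory header row and
"." decimals; predictions and evaluation tables are written as TSV;
models and search reports as JSON.  Complex ids are free text matched
exactly (the en-dash convention of the experimental table is preserved
verbatim).  All writers are deterministic: no timestamps in artifacts.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .evaluate import EvaluationRow, evaluation_frame
from .models import (
    AffinityPrediction,
    DescriptorMatrix,
    DescriptorRecord,
    LinearAffinityModel,
)
from .search import AffinityMeasurement, SearchResult
from .thermo import AffinityRange

__all__ = [
    "read_descriptor_table",
    "write_descriptor_table",
    "read_measurements",
    "write_measurements",
    "read_model",
    "write_model",
    "read_predictions",
    "write_predictions",
    "write_evaluation_table",
    "write_search_report",
]


def read_descriptor_table(
    path: str | Path, classes: dict[str, str] | None = None
) -> DescriptorMatrix | list[DescriptorRecord]:
    """Read a descriptor CSV: first column ``complex``, numeric columns after.

    Header names are normalised for surrounding whitespace only.  With a
    ``classes`` mapping (descriptor name -> class label) the result is a
    :class:`DescriptorMatrix`; without one, a list of
    :class:`DescriptorRecord` (class labels are configuration, not data,
    so the file itself never carries them).
    """
    frame = pd.read_csv(path)
    if frame.columns.empty or frame.columns[0].strip() != "complex":
        raise ValueError(f"{path}: first column must be 'complex', got {list(frame.columns)[:1]}")
    frame.columns = [str(c).strip() for c in frame.columns]
    if len(set(frame.columns)) != len(frame.columns):
        raise ValueError(f"{path}: duplicate descriptor names after whitespace normalisation")
    frame = frame.set_index("complex")
    frame.index.name = None
    if frame.index.has_duplicates:
        dupes = sorted(set(frame.index[frame.index.duplicated()]))
        raise ValueError(f"{path}: duplicate complex ids: {dupes}")
    for col in frame.columns:
        numeric = pd.to_numeric(frame[col], errors="coerce")
        if numeric.isna().any():
            rows = frame.index[numeric.isna()].tolist()
            raise ValueError(f"{path}: non-numeric cell(s) in column {col!r}, rows {rows}")
        frame[col] = numeric.astype(float)
    records = [
        DescriptorRecord(complex_id=str(idx), values=row.to_dict())
        for idx, row in frame.iterrows()
    ]
    if classes is None:
        return records
    return DescriptorMatrix(data=frame, classes=classes)


def write_descriptor_table(matrix: DescriptorMatrix, path: str | Path) -> None:
    matrix.data.rename_axis("complex").to_csv(path)


def read_measurements(path: str | Path) -> list[AffinityMeasurement]:
    """Read a measurement CSV: complex, kd_nM, optional kd_err_nM, set."""
    frame = pd.read_csv(path)
    frame.columns = [str(c).strip() for c in frame.columns]
    required = {"complex", "kd_nM", "set"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    has_err = "kd_err_nM" in frame.columns
    out = []
    for i, row in frame.iterrows():
        err = None
        if has_err and pd.notna(row["kd_err_nM"]):
            err = float(row["kd_err_nM"])
        try:
            out.append(
                AffinityMeasurement(
                    complex_id=str(row["complex"]),
                    kd_nm=float(row["kd_nM"]),
                    kd_err_nm=err,
                    set_label=str(row["set"]).strip(),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: row {i + 2}: {exc}") from exc
    return out


def write_measurements(measurements: Sequence[AffinityMeasurement], path: str | Path) -> None:
    pd.DataFrame(
        {
            "complex": [m.complex_id for m in measurements],
            "kd_nM": [m.kd_nm for m in measurements],
            "kd_err_nM": [m.kd_err_nm for m in measurements],
            "set": [m.set_label for m in measurements],
        }
    ).to_csv(path, index=False)


def read_model(path: str | Path) -> LinearAffinityModel:
    return LinearAffinityModel.from_json(Path(path).read_text(encoding="utf-8"))


def write_model(model: LinearAffinityModel, path: str | Path) -> None:
    Path(path).write_text(model.to_json(indent=2) + "\n", encoding="utf-8")


def write_predictions(predictions: Sequence[AffinityPrediction], path: str | Path) -> None:
    """Prediction TSV: complex_id, delta_G_kcal_mol, Kd_nM, range."""
    pd.DataFrame(
        {
            "complex_id": [p.complex_id for p in predictions],
            "delta_G_kcal_mol": [p.dg_kcal_mol for p in predictions],
            "Kd_nM": [p.kd_nm for p in predictions],
            "range": [p.range_class.symbol for p in predictions],
        }
    ).to_csv(path, sep="\t", index=False)


def read_predictions(path: str | Path) -> list[AffinityPrediction]:
    frame = pd.read_csv(path, sep="\t")
    required = {"complex_id", "delta_G_kcal_mol", "Kd_nM", "range"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing prediction columns {sorted(missing)}")
    return [
        AffinityPrediction(
            complex_id=str(row["complex_id"]),
            dg_kcal_mol=float(row["delta_G_kcal_mol"]),
            kd_nm=float(row["Kd_nM"]),
            range_class=AffinityRange.from_symbol(str(row["range"])),
        )
        for _, row in frame.iterrows()
    ]


def write_evaluation_table(rows: Sequence[EvaluationRow], path: str | Path) -> None:
    evaluation_frame(rows).to_csv(path, sep="\t", index=False)


def write_search_report(result: SearchResult, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(result.to_dict(), indent=2) + "\n", encoding="utf-8"
    )
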