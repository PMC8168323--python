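"""File input/output, axis calibration for digitized pixels, and reports.

Coordinate files are CSV or TSV with an optional header and one of three
layouts: two numeric columns (time, survival) for a single arm; three
columns with an arm label in the third; or four columns holding two
(time, survival) pairs side by side (the two-arm template layout, where
the arms may have different numbers of points and short columns are
padded with blanks).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import CalibrationError, InvalidInputError
from .preprocess import CurvePoints, RiskTable

__all__ = [
    "AxisCalibration",
    "calibrate_pixels",
    "read_points",
    "read_risk_table",
    "parse_risk_args",
    "read_ipd",
    "write_ipd",
    "write_report",
]


@dataclass
class AxisCalibration:
    """Pixel positions of the axis reference points and their data labels.

    ``px_x1``/``px_x2`` are the pixel x of the points labelled ``x1``/``x2``
    on the time axis; ``px_y1``/``px_y2`` the pixel y of the points
    labelled ``y1``/``y2`` on the survival axis (screen y grows downward,
    which the affine map handles automatically).
    """

    px_x1: float
    px_x2: float
    px_y1: float
    px_y2: float
    x1: float
    x2: float
    y1: float
    y2: float

    def __post_init__(self):
        if self.px_x1 == self.px_x2 or self.px_y1 == self.px_y2:
            raise CalibrationError("axis reference pixels coincide; cannot calibrate")
        if self.x1 == self.x2 or self.y1 == self.y2:
            raise CalibrationError("axis reference labels coincide; cannot calibrate")


def calibrate_pixels(cal: AxisCalibration, pixel_points) -> CurvePoints:
    """Map clicked pixel coordinates to data coordinates.

    Applies the per-axis affine map defined by the two reference points of
    each axis to every (pixel_x, pixel_y) pair.
    """
    P = np.asarray(pixel_points, dtype=float)
    if P.ndim != 2 or P.shape[1] != 2:
        raise InvalidInputError("pixel_points must be an (N, 2) array")
    t = cal.x1 + (P[:, 0] - cal.px_x1) * (cal.x2 - cal.x1) / (cal.px_x2 - cal.px_x1)
    s = cal.y1 + (P[:, 1] - cal.px_y1) * (cal.y2 - cal.y1) / (cal.px_y2 - cal.px_y1)
    return CurvePoints(t, s)


def _sniff_rows(path) -> list[list[str]]:
    text = Path(path).read_text()
    delim = "\t" if text.count("\t") >= text.count(",") and "\t" in text else ","
    rows = [row for row in csv.reader(text.splitlines(), delimiter=delim)]
    return [r for r in rows if any(cell.strip() for cell in r)]


def _is_number(cell: str) -> bool:
    try:
        float(cell)
        return True
    except ValueError:
        return False


def read_points(path) -> dict[str, CurvePoints]:
    """Read digitized coordinates; returns ``{arm_label: CurvePoints}``.

    Handles comma- or tab-separated files, an optional header row, and the
    three column layouts described in the module docstring.  Non-numeric
    cells are reported with their line number.
    """
    rows = _sniff_rows(path)
    if not rows:
        raise InvalidInputError(f"{path}: file is empty")
    header = None
    start = 0
    if not all(_is_number(c) for c in rows[0][:2]):
        header = [c.strip() for c in rows[0]]
        start = 1
    if start >= len(rows):
        raise InvalidInputError(f"{path}: no data rows")
    ncol = max(len(r) for r in rows[start:])

    def num(cell: str, line: int, col: int) -> float:
        cell = cell.strip()
        if cell == "":
            return np.nan
        if not _is_number(cell):
            raise InvalidInputError(
                f"{path}: non-numeric value {cell!r} at line {line}, column {col + 1}"
            )
        return float(cell)

    if ncol >= 4:
        # two side-by-side (time, survival) pairs, possibly ragged
        pairs: list[list[tuple[float, float]]] = [[], []]
        for off, r in enumerate(rows[start:]):
            line = start + off + 1
            for a in range(2):
                t = num(r[2 * a], line, 2 * a) if len(r) > 2 * a else np.nan
                s = num(r[2 * a + 1], line, 2 * a + 1) if len(r) > 2 * a + 1 else np.nan
                if not (np.isnan(t) or np.isnan(s)):
                    pairs[a].append((t, s))
        labels = ["arm1", "arm2"]
        if header and len(header) >= 4:
            labels = [header[0], header[2]]
        return {
            labels[a]: CurvePoints(*map(np.array, zip(*pairs[a]))) for a in range(2)
        }

    if ncol == 3:
        out: dict[str, list[tuple[float, float]]] = {}
        for off, r in enumerate(rows[start:]):
            line = start + off + 1
            t = num(r[0], line, 0)
            s = num(r[1], line, 1)
            label = r[2].strip() if len(r) > 2 else ""
            out.setdefault(label or "arm1", []).append((t, s))
        return {
            lab: CurvePoints(*map(np.array, zip(*pts))) for lab, pts in out.items()
        }

    pts = []
    for off, r in enumerate(rows[start:]):
        line = start + off + 1
        if len(r) < 2:
            raise InvalidInputError(f"{path}: line {line} has fewer than 2 columns")
        pts.append((num(r[0], line, 0), num(r[1], line, 1)))
    return {"arm1": CurvePoints(*map(np.array, zip(*pts)))}


def read_risk_table(path) -> RiskTable:
    """Read a two-column (trisk, nrisk) CSV/TSV, header optional."""
    rows = _sniff_rows(path)
    start = 0 if rows and _is_number(rows[0][0]) else 1
    trisk, nrisk = [], []
    for off, r in enumerate(rows[start:]):
        if len(r) < 2:
            raise InvalidInputError(f"{path}: line {start + off + 1} has fewer than 2 columns")
        trisk.append(float(r[0]))
        nrisk.append(int(float(r[1])))
    return RiskTable(np.array(trisk), np.array(nrisk))


def parse_risk_args(trisk: str, nrisk: str) -> RiskTable:
    """Build a risk table from comma-separated CLI strings."""
    return RiskTable(
        np.array([float(x) for x in trisk.split(",")]),
        np.array([int(x) for x in nrisk.split(",")]),
    )


def read_ipd(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"time", "status"} - set(df.columns)
    if missing:
        raise InvalidInputError(f"{path}: missing column(s) {sorted(missing)}")
    if "arm" not in df.columns:
        df["arm"] = 0
    return df


def write_ipd(ipd: pd.DataFrame, path) -> None:
    ipd.to_csv(path, index=False)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def write_report(report: dict, json_path, text_path=None, text: str | None = None) -> None:
    """Write the combined JSON report (schema v1) and an optional text twin."""
    payload = {"schema": "kmipd-report/1", **report}
    Path(json_path).write_text(json.dumps(payload, indent=2, cls=_NumpyEncoder) + "\n")
    if text_path is not None and text is not None:
        Path(text_path).write_text(text + "\n")
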