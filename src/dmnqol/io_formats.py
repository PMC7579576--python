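"""Reading and writing every table the pipeline touches.

All tabular artifacts are tab-separated text with a header row; commas are
accepted on read by delimiter sniffing.  Time-series files carry one column
per ROI (header = ROI labels) and one row per volume; in memory the
orientation is ROIs x time.  Displayed p-values follow a truncation (floor)
convention at three decimals, with full precision retained in machine-readable
fields.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import LengthError, ParseError, SchemaError

__all__ = [
    "QOL_DIMENSIONS",
    "ROITimeSeriesSet",
    "ReportBundle",
    "format_p",
    "load_dmn_roi_scheme",
    "load_study_mean_ranks",
    "read_qol",
    "read_timeseries",
    "write_qol",
    "write_report",
    "read_report",
    "write_timeseries",
]

#: Canonical order of the eight quality-of-life dimensions
#: (Schalock–Verdugo model, as operationalised by the Personal Outcomes Scale).
QOL_DIMENSIONS = (
    "personal_development",
    "self_determination",
    "interpersonal_relations",
    "social_inclusion",
    "rights",
    "emotional_well_being",
    "physical_well_being",
    "material_well_being",
)


@dataclass
class ROITimeSeriesSet:
    """One subject's ROI-by-time matrix of BOLD-like signal.

    Parameters
    ----------
    subject_id : str
        Unique subject identifier.
    values : ndarray, shape (n_rois, n_timepoints)
        Signal values; rows follow ``roi_labels``.
    tr_seconds : float
        Sampling interval (repetition time) in seconds.
    roi_labels : list of str
        ROI names, one per row of ``values``.
    """

    subject_id: str
    values: np.ndarray
    tr_seconds: float = 2.0
    roi_labels: Sequence[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D ROI x time matrix")
        if not self.roi_labels:
            self.roi_labels = [f"ROI{i}" for i in range(self.values.shape[0])]
        self.roi_labels = list(self.roi_labels)
        if len(self.roi_labels) != self.values.shape[0]:
            raise SchemaError(
                f"{len(self.roi_labels)} ROI labels for "
                f"{self.values.shape[0]} rows"
            )
        if self.values.shape[1] < 2:
            raise LengthError("a time series needs at least 2 time points")
        if not np.isfinite(self.values).all():
            raise ParseError("time series contains missing/non-finite values")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


def _read_delimited(path: str | Path) -> pd.DataFrame:
    """Read a TSV (or, by sniffing, CSV) table with a header row."""
    return pd.read_csv(path, sep=None, engine="python")


def read_timeseries(
    path: str | Path,
    discard_initial: int = 0,
    keep_volumes: int | None = None,
    subject_id: str | None = None,
    tr_seconds: float = 2.0,
) -> ROITimeSeriesSet:
    """Read an ROI time-series table, dropping saturation volumes.

    The file has one column per ROI (header row = ROI labels) and one row
    per volume.  The first ``discard_initial`` volumes are dropped — in the
    original acquisition 10 volumes were discarded against magnetic
    saturation — then the series is truncated to ``keep_volumes`` if given
    (the study kept the first 220 volumes so both groups were comparable).
    """
    if discard_initial < 0:
        raise ValueError("discard_initial must be nonnegative")
    raw = pd.read_csv(path, sep=None, engine="python", dtype=str)
    labels = [str(c) for c in raw.columns]
    columns = []
    for j, label in enumerate(labels):
        cells = raw.iloc[:, j].to_numpy()
        try:
            # float() is correctly rounded; pd.to_numeric is not always
            columns.append(np.array([float(c) for c in cells]))
        except (TypeError, ValueError):
            for i, cell in enumerate(cells):
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ParseError(
                        f"non-numeric cell at data row {i}, column "
                        f"{label!r} in {path}"
                    ) from None
            raise
    values = np.vstack(columns)  # -> ROIs x time (one column per ROI)
    if values.shape[1] < discard_initial + 2:
        raise LengthError(
            f"{values.shape[1]} volumes is too few after discarding "
            f"{discard_initial}"
        )
    values = values[:, discard_initial:]
    if keep_volumes is not None:
        if keep_volumes <= 0:
            raise ValueError("keep_volumes must be positive")
        values = values[:, :keep_volumes]
    sid = subject_id if subject_id is not None else Path(path).stem
    return ROITimeSeriesSet(
        subject_id=sid, values=values, tr_seconds=tr_seconds, roi_labels=labels
    )


def write_timeseries(ts: ROITimeSeriesSet, path: str | Path) -> None:
    """Write a time-series set as TSV (columns = ROIs, rows = volumes)."""
    frame = pd.DataFrame(ts.values.T, columns=ts.roi_labels)
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")


def load_dmn_roi_scheme() -> pd.DataFrame:
    """Return the bundled 24-ROI default-mode-network scheme.

    Columns: ``roi_index`` (AAL90 region number), ``region_name`` (exact AAL
    name, case-sensitive) and ``subnetwork`` (``DMN``, ``DMN-anterior`` or
    ``DMN-ventral``; sizes 6, 6 and 12).  A fresh copy is returned on every
    call so callers cannot mutate the bundled fixture.
    """
    with resources.files("dmnqol.data").joinpath("dmn_rois.tsv").open() as fh:
        scheme = pd.read_csv(fh, sep="\t")
    return scheme


def load_study_mean_ranks() -> pd.DataFrame:
    """Return the published DS-vs-control group summary (mean ranks).

    One row per complexity indicator with group sizes, group mean ranks and
    the printed one-sided significance.  These printed summaries are
    sufficient to reconstruct the Mann–Whitney test exactly (see
    :func:`dmnqol.stats.mann_whitney_from_ranks`).
    """
    with resources.files("dmnqol.data").joinpath(
        "study_mean_ranks.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")


def _canon_dimension(name: str) -> str:
    key = "".join(ch for ch in str(name).lower() if ch.isalnum())
    for canonical in QOL_DIMENSIONS:
        if key == "".join(ch for ch in canonical if ch.isalnum()):
            return canonical
    return str(name)


def read_qol(path: str | Path) -> pd.DataFrame:
    """Read a per-subject quality-of-life table.

    The file needs a ``subject_id`` column plus the eight dimension columns
    (order-insensitive; names matched case/punctuation-insensitively).  The
    result is indexed by subject id with columns in canonical order.
    """
    raw = _read_delimited(path)
    raw.columns = [_canon_dimension(c) if c != "subject_id" else c
                   for c in raw.columns]
    if "subject_id" not in raw.columns:
        raise SchemaError("QoL table is missing a 'subject_id' column")
    missing = [d for d in QOL_DIMENSIONS if d not in raw.columns]
    if missing:
        raise SchemaError(f"QoL table is missing dimensions: {missing}")
    table = raw.set_index("subject_id")[list(QOL_DIMENSIONS)].astype(float)
    if table.index.duplicated().any():
        raise SchemaError("duplicate subject ids in QoL table")
    return table


def write_qol(qol: pd.DataFrame, path: str | Path) -> None:
    qol.to_csv(
        path, sep="\t", index=True, index_label="subject_id",
        float_format="%.17g",
    )


def format_p(p: float) -> str:
    """Format a p-value by the display convention: floor at 3 decimals.

    Values below 0.001 print as ``<0.001``.  Truncation (not rounding) is
    the convention used throughout the reported comparison tables.
    """
    if not np.isfinite(p):
        return "NA"
    if p < 0.001:
        return "<0.001"
    return f"{math.floor(p * 1000 + 1e-9) / 1000:.3f}"


def _frame_to_payload(frame: pd.DataFrame | None) -> dict | None:
    if frame is None:
        return None
    return json.loads(frame.to_json(orient="split", double_precision=15))


def _frame_from_payload(payload: dict | None) -> pd.DataFrame | None:
    if payload is None:
        return None
    return pd.DataFrame(
        payload["data"], columns=payload["columns"], index=payload["index"]
    )


@dataclass
class ReportBundle:
    """Everything one pipeline run reports.

    ``comparison_table`` mirrors the group-comparison layout (indicator,
    group, n, mean, mean rank, SD, significance); ``correlation_table`` the
    flagged correlation matrix; ``models_table`` the stepwise-model summary
    (indicator rows x QoL-dimension columns).  ``metadata`` records the seed
    and configuration so a run can be repeated exactly.
    """

    comparison_table: pd.DataFrame | None = None
    correlation_table: pd.DataFrame | None = None
    models_table: pd.DataFrame | None = None
    metadata: dict = field(default_factory=dict)


def write_report(bundle: ReportBundle, path: str | Path) -> None:
    """Serialize a report bundle to JSON.

    p-value columns gain display twins formatted by :func:`format_p`; the
    full-precision numbers stay in the machine-readable fields.
    """
    comp = bundle.comparison_table
    if comp is not None:
        comp = comp.copy()
        for col in comp.columns:
            if str(col).startswith("p_"):
                comp[f"display_{col}"] = [
                    format_p(v) if pd.notna(v) else ""
                    for v in comp[col]
                ]
    payload = {
        "comparison_table": _frame_to_payload(comp),
        "correlation_table": _frame_to_payload(bundle.correlation_table),
        "models_table": _frame_to_payload(bundle.models_table),
        "metadata": bundle.metadata,
    }
    Path(path).write_text(json.dumps(payload, indent=1, allow_nan=True))


def read_report(path: str | Path) -> ReportBundle:
    payload = json.loads(Path(path).read_text())
    comp = _frame_from_payload(payload["comparison_table"])
    if comp is not None:
        comp = comp[[c for c in comp.columns
                     if not str(c).startswith("display_")]]
    return ReportBundle(
        comparison_table=comp,
        correlation_table=_frame_from_payload(payload["correlation_table"]),
        models_table=_frame_from_payload(payload["models_table"]),
        metadata=payload.get("metadata", {}),
    )
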