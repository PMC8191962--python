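"""Waveform and cohort I/O for segmental longitudinal-strain recordings.

A *view waveform file* stores the six segmental strain curves of one apical
echocardiographic view (4ch, 3ch or 2ch) as delimited text::

    # view: 4ch
    # t_qrs_s: 0.0
    # t_avc_s: 0.40
    # sampling_hz: 100
    time_s,BS,MS,AS,BL,ML,AL
    0.000,0.0,0.0,0.0,0.0,0.0,0.0
    ...

Strain is in percent (negative = shortening), time in seconds.  On read,
the time axis is re-zeroed at the declared QRS onset (``t_qrs_s``) so that
``t = 0`` is the QRS reference for every downstream computation; ``t_avc_s``
is expressed relative to the same reference after the shift.

A *cohort manifest* is a CSV with columns ``patient_id, file_4ch, file_3ch,
file_2ch, qrs_ms, lvef_pct, esv_baseline_ml, esv_followup_ml``; view-file
paths are resolved relative to the manifest's directory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Segment labels per view, anatomical wall side first (septal-type wall,
#: then the opposing wall), basal -> mid -> apical within each wall.
VIEW_SEGMENTS: dict[str, tuple[str, ...]] = {
    "4ch": ("BS", "MS", "AS", "BL", "ML", "AL"),
    "3ch": ("BAs", "MAs", "AAs", "BP", "MP", "AP"),
    "2ch": ("BI", "MI", "AI", "BA", "MA", "AA"),
}

#: Opposing wall ("side") membership and naming per view, in the order the
#: side difference is taken (first minus second).
VIEW_SIDES: dict[str, tuple[tuple[str, tuple[str, ...]], tuple[str, tuple[str, ...]]]] = {
    "4ch": (("S", ("BS", "MS", "AS")), ("L", ("BL", "ML", "AL"))),
    "2ch": (("I", ("BI", "MI", "AI")), ("A", ("BA", "MA", "AA"))),
    "3ch": (("As", ("BAs", "MAs", "AAs")), ("P", ("BP", "MP", "AP"))),
}

VIEWS: tuple[str, ...] = ("4ch", "3ch", "2ch")


class FormatError(ValueError):
    """A waveform or manifest file violates the expected dialect."""


@dataclass
class StrainTrace:
    """One segment's longitudinal strain time series.

    Parameters
    ----------
    segment_id
        Segment label (e.g. ``BS`` for basal septal in the 4ch view).
    time
        Seconds from QRS onset; strictly increasing, ``time[0] == 0``.
    strain
        Percent shortening (negative during contraction), same length.
    """

    segment_id: str
    time: np.ndarray
    strain: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.strain = np.asarray(self.strain, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.strain.shape:
            raise FormatError(f"segment {self.segment_id}: time/strain shape mismatch")
        if self.time.size < 2:
            raise FormatError(f"segment {self.segment_id}: needs at least 2 samples")
        if not np.all(np.diff(self.time) > 0):
            raise FormatError(f"segment {self.segment_id}: time not strictly increasing")
        if abs(self.time[0]) > 1e-12:
            raise FormatError(f"segment {self.segment_id}: time[0] must be 0 (QRS onset)")
        if not np.all(np.isfinite(self.strain)):
            raise FormatError(f"segment {self.segment_id}: non-finite strain values")


@dataclass
class ViewRecording:
    """Six segmental strain traces of one apical view plus its AVC instant."""

    view: str
    traces: list[StrainTrace]
    t_avc: float

    def __post_init__(self) -> None:
        if self.view not in VIEW_SEGMENTS:
            raise FormatError(f"unknown view {self.view!r}")
        expected = VIEW_SEGMENTS[self.view]
        got = [tr.segment_id for tr in self.traces]
        missing = [s for s in expected if s not in got]
        if missing:
            raise FormatError(f"missing segment {missing[0]} in {self.view} recording")
        if len(got) != 6 or set(got) != set(expected):
            raise FormatError(f"{self.view} recording must have exactly segments {expected}")
        # canonical ordering
        order = {s: i for i, s in enumerate(expected)}
        self.traces = sorted(self.traces, key=lambda tr: order[tr.segment_id])
        if not self.t_avc > 0:
            raise FormatError(f"t_avc must be positive, got {self.t_avc}")
        for tr in self.traces:
            if self.t_avc > tr.time[-1] + 1e-12:
                raise FormatError(
                    f"t_avc={self.t_avc} beyond end of segment {tr.segment_id} trace"
                )

    def trace(self, segment_id: str) -> StrainTrace:
        for tr in self.traces:
            if tr.segment_id == segment_id:
                return tr
        raise KeyError(segment_id)


@dataclass
class PatientRecord:
    """All strain recordings and clinical metadata of one patient."""

    patient_id: str
    views: dict[str, ViewRecording]
    qrs_duration: float  # ms
    lvef: float  # percent
    esv_baseline: float | None = None  # mL
    esv_followup: float | None = None  # mL
    response: str = "unknown"  # responder | non-responder | unknown

    def __post_init__(self) -> None:
        for vw in VIEWS:
            if vw not in self.views:
                raise FormatError(f"patient {self.patient_id}: missing view {vw}")
        if not self.qrs_duration > 0:
            raise FormatError(f"patient {self.patient_id}: qrs_duration must be > 0")
        if not 0 < self.lvef < 100:
            raise FormatError(f"patient {self.patient_id}: lvef out of (0, 100)")
        if self.response not in ("responder", "non-responder", "unknown"):
            raise FormatError(f"patient {self.patient_id}: bad response label {self.response!r}")


def read_view_file(path: str | Path, view: str | None = None) -> ViewRecording:
    """Read one view waveform file and return a validated :class:`ViewRecording`.

    The time axis is shifted so the declared QRS onset maps to ``t = 0`` and
    ``t_avc`` is expressed on the shifted axis.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if not line.startswith("#"):
                break
            key, _, value = line[1:].partition(":")
            meta[key.strip()] = value.strip()
            pos = fh.tell()
        fh.seek(pos)
        body = pd.read_csv(fh)
    for key in ("view", "t_qrs_s", "t_avc_s"):
        if key not in meta:
            raise FormatError(f"{path}: missing metadata field {key}")
    file_view = meta["view"]
    if view is not None and file_view != view:
        raise FormatError(f"{path}: file declares view {file_view!r}, expected {view!r}")
    if file_view not in VIEW_SEGMENTS:
        raise FormatError(f"{path}: unknown view {file_view!r}")
    if "time_s" not in body.columns:
        raise FormatError(f"{path}: missing column time_s")
    t_qrs = float(meta["t_qrs_s"])
    t_avc = float(meta["t_avc_s"]) - t_qrs
    time = body["time_s"].to_numpy(dtype=float) - t_qrs
    traces = []
    for seg in VIEW_SEGMENTS[file_view]:
        if seg not in body.columns:
            raise FormatError(f"{path}: missing segment {seg}")
        traces.append(StrainTrace(seg, time, body[seg].to_numpy(dtype=float)))
    return ViewRecording(view=file_view, traces=traces, t_avc=t_avc)


def write_view_file(rec: ViewRecording, path: str | Path, sampling_hz: float | None = None) -> Path:
    """Write a :class:`ViewRecording` to the text dialect read by :func:`read_view_file`.

    Round trips to 1e-9 on every numeric field (``%.12g`` formatting).
    """
    path = Path(path)
    if not rec.traces or rec.traces[0].time.size == 0:
        raise FormatError("cannot write a recording with empty traces")
    time = rec.traces[0].time
    for tr in rec.traces:
        if tr.time.shape != time.shape or not np.allclose(tr.time, time, atol=0, rtol=0):
            raise FormatError("all traces of one view must share a common time axis")
    if sampling_hz is None:
        sampling_hz = 1.0 / float(np.median(np.diff(time)))
    segs = [tr.segment_id for tr in rec.traces]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# view: {rec.view}\n")
        fh.write("# t_qrs_s: 0\n")
        fh.write(f"# t_avc_s: {rec.t_avc:.12g}\n")
        fh.write(f"# sampling_hz: {sampling_hz:.12g}\n")
        fh.write("time_s," + ",".join(segs) + "\n")
        cols = [time] + [tr.strain for tr in rec.traces]
        for row in zip(*cols):
            fh.write(",".join(f"{v:.12g}" for v in row) + "\n")
    return path


MANIFEST_COLUMNS = (
    "patient_id",
    "file_4ch",
    "file_3ch",
    "file_2ch",
    "qrs_ms",
    "lvef_pct",
    "esv_baseline_ml",
    "esv_followup_ml",
)


def load_cohort(manifest: str | Path) -> list[PatientRecord]:
    """Load every readable patient listed in a cohort manifest.

    Patients whose files are missing or fail validation are skipped with a
    logged reason (mirroring clinical withdrawal of poor-quality recordings);
    an unreadable manifest is fatal.
    """
    from .features import classify_response  # deferred: avoids import cycle

    manifest = Path(manifest)
    table = pd.read_csv(manifest, comment="#")
    for col in ("patient_id", "file_4ch", "file_3ch", "file_2ch", "qrs_ms", "lvef_pct"):
        if col not in table.columns:
            raise FormatError(f"{manifest}: manifest missing column {col}")
    if table.empty:
        logger.warning("%s: empty manifest, no patients loaded", manifest)
        return []
    records: list[PatientRecord] = []
    base = manifest.parent
    for _, row in table.iterrows():
        pid = str(row["patient_id"])
        try:
            views = {
                vw: read_view_file(base / str(row[f"file_{vw}"]), vw) for vw in VIEWS
            }
            esv_b = row.get("esv_baseline_ml")
            esv_f = row.get("esv_followup_ml")
            esv_b = None if pd.isna(esv_b) else float(esv_b)
            esv_f = None if pd.isna(esv_f) else float(esv_f)
            response = (
                classify_response(esv_b, esv_f) if esv_b is not None and esv_f is not None
                else "unknown"
            )
            records.append(
                PatientRecord(
                    patient_id=pid,
                    views=views,
                    qrs_duration=float(row["qrs_ms"]),
                    lvef=float(row["lvef_pct"]),
                    esv_baseline=esv_b,
                    esv_followup=esv_f,
                    response=response,
                )
            )
        except (OSError, FormatError, ValueError) as exc:
            logger.warning("skipping patient %s: %s", pid, exc)
    return records


def write_manifest(rows: Iterable[dict], path: str | Path, header_comment: str | None = None) -> Path:
    """Write a cohort manifest CSV (optionally with a leading ``#`` comment)."""
    path = Path(path)
    frame = pd.DataFrame(list(rows), columns=list(MANIFEST_COLUMNS))
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        frame.to_csv(fh, index=False)
    return path


def write_feature_table(table: pd.DataFrame, path: str | Path, header_comment: str | None = None) -> Path:
    """Write the per-patient feature table (patient_id, response, 158 features)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        table.to_csv(fh, index=False, float_format="%.12g")
    return path


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a feature table written by :func:`write_feature_table`."""
    return pd.read_csv(path, comment="#")
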