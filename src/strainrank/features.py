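"""Extraction of the 158 longitudinal-strain features.

The feature set quantifies left-ventricular contraction amplitude, timing
and cumulative deformation per apical view (4ch, 3ch, 2ch; six segments
each), with all timings referenced to QRS onset (``t = 0``):

* ``Tavc_<vw>`` — aortic-valve-closure instant of the view (s).
* ``P_<vw>_<sg>`` — peak contraction magnitude of a segment, i.e. the
  maximum percent shortening (reported positive); per-view mean and std.
* ``Tpeak_<vw>_<sg>`` — time of the peak (s); per-view mean and std over
  segments with a defined peak.
* ``dP_<vw>``, ``dTpeak_<vw>`` — max−min of peaks and peak times across
  the six segments (contraction heterogeneity and dyssynchrony markers).
* ``Iavc_<vw>_<sg>`` — integral of contraction strain magnitude from QRS
  onset to AVC (%·s): the cumulative shortening that ejects blood.
* ``Ipeak_<vw>_<sg>`` — same integral up to the segment's strain peak:
  the total cumulative shortening the segment deploys.
* ``E_<vw>_<sg> = Ipeak − Iavc`` — mechanical-efficiency marker; positive
  values are shortening wasted after valve closure.
* For each integral family: per-view mean, std, the two wall ("side")
  sums and their difference (septal−lateral, inferior−anterior,
  anteroseptal−posterior).
* ``QRS`` (ms) and ``LVEF`` (%), copied from the clinical record.

Strain values inside the ±5% dead zone are ignored by every integral and
by peak-time qualification: only samples below −5% count as contraction.
Curves are resampled to 500 Hz before feature computation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import VIEWS, VIEW_SEGMENTS, VIEW_SIDES, PatientRecord, StrainTrace, ViewRecording

logger = logging.getLogger(__name__)

DEAD_ZONE = 5.0  # percent; |strain| <= 5 ignored everywhere
RESAMPLE_HZ = 500.0


class LowQualityViewError(ValueError):
    """No segment of the view ever exceeds the contraction dead zone."""


# ---------------------------------------------------------------------------
# feature-name registry

def _view_feature_names(vw: str) -> list[str]:
    segs = VIEW_SEGMENTS[vw]
    (sd1, _), (sd2, _) = VIEW_SIDES[vw]
    names = [f"Tavc_{vw}"]
    names += [f"P_{vw}_{s}" for s in segs] + [f"P_{vw}_mean", f"P_{vw}_std"]
    names += [f"Tpeak_{vw}_{s}" for s in segs] + [f"Tpeak_{vw}_mean", f"Tpeak_{vw}_std"]
    names += [f"dP_{vw}", f"dTpeak_{vw}"]
    for fam in ("Iavc", "Ipeak", "E"):
        names += [f"{fam}_{vw}_{s}" for s in segs]
        names += [f"{fam}_{vw}_mean", f"{fam}_{vw}_std"]
        names += [f"{fam}_{vw}_{sd1}", f"{fam}_{vw}_{sd2}", f"{fam}_{vw}_{sd1}-{sd2}"]
    return names


def feature_names() -> list[str]:
    """The canonical ordered list of the 158 feature names.

    Views in order 4ch, 3ch, 2ch (52 features each), then QRS and LVEF.
    """
    names: list[str] = []
    for vw in VIEWS:
        names += _view_feature_names(vw)
    names += ["QRS", "LVEF"]
    return names


FEATURE_NAMES: tuple[str, ...] = tuple(feature_names())
N_FEATURES = len(FEATURE_NAMES)  # 158


def feature_view(name: str) -> str | None:
    """View a feature belongs to (``'4ch'|'3ch'|'2ch'``) or None for QRS/LVEF."""
    parts = name.split("_")
    if len(parts) >= 2 and parts[1] in VIEW_SEGMENTS:
        return parts[1]
    return None


# ---------------------------------------------------------------------------
# per-trace primitives

def resample_trace(trace: StrainTrace, rate: float = RESAMPLE_HZ) -> StrainTrace:
    """Linearly resample a trace onto a uniform grid from 0 to its last time."""
    if trace.time.size < 2:
        raise ValueError("resampling needs at least 2 samples")
    t_end = float(trace.time[-1])
    n = max(1, round(t_end * rate))
    grid = np.linspace(0.0, t_end, n + 1)
    values = np.interp(grid, trace.time, trace.strain)
    return StrainTrace(trace.segment_id, grid, values)


def dead_zone_mask(trace: StrainTrace) -> np.ndarray:
    """Boolean mask of samples contributing to contraction integrals.

    True exactly where strain < −5%; the ±5% band and all positive strain
    are excluded.
    """
    return trace.strain < -DEAD_ZONE


def peak_features(trace: StrainTrace) -> tuple[float, float | None]:
    """Peak contraction magnitude P and its time.

    P is the maximum percent contraction, ``max(-strain)`` clipped below at
    zero.  The peak time is the first global strain minimum, and is defined
    only when the peak exceeds the dead zone (P > 5%); otherwise ``None``.
    """
    p = max(0.0, float(-np.min(trace.strain)))
    if p <= DEAD_ZONE:
        return p, None
    idx = int(np.argmin(trace.strain))  # argmin returns the first minimum
    return p, float(trace.time[idx])


def _masked_linear_integral(time: np.ndarray, strain: np.ndarray) -> float:
    """Exact integral of |strain| where strain < −5 for the piecewise-linear curve.

    Each sampling interval is split at its crossing of the −5% threshold, so
    the result is exact for the linear interpolant rather than depending on
    where the grid falls relative to the dead-zone boundary.
    """
    thr = -DEAD_ZONE
    s0, s1 = strain[:-1], strain[1:]
    t0, t1 = time[:-1], time[1:]
    dt = t1 - t0
    ds = s1 - s0
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(ds != 0, (thr - s0) / ds, 0.0)
    frac = np.clip(frac, 0.0, 1.0)
    both = (s0 < thr) & (s1 < thr)
    enter = (s0 >= thr) & (s1 < thr)  # crossing downward into contraction
    leave = (s0 < thr) & (s1 >= thr)  # crossing back out
    area = np.zeros_like(dt)
    area[both] = 0.5 * (-s0[both] - s1[both]) * dt[both]
    # sub-interval from the crossing (value exactly thr) to the inside endpoint
    area[enter] = 0.5 * (DEAD_ZONE + -s1[enter]) * dt[enter] * (1.0 - frac[enter])
    area[leave] = 0.5 * (-s0[leave] + DEAD_ZONE) * dt[leave] * frac[leave]
    return float(area.sum())


def strain_integral(trace: StrainTrace, t_end: float) -> float:
    """Integral of contraction strain magnitude over [0, t_end] (%·s).

    Integrates |strain| restricted to samples below the −5% dead zone of the
    piecewise-linear curve; non-negative and non-decreasing in ``t_end``.
    """
    if not 0 < t_end <= trace.time[-1] + 1e-9:
        raise ValueError(f"t_end={t_end} outside trace span (0, {trace.time[-1]}]")
    t_end = min(t_end, float(trace.time[-1]))
    cut = int(np.searchsorted(trace.time, t_end, side="left"))
    if cut < trace.time.size and trace.time[cut] == t_end:
        time = trace.time[: cut + 1]
        strain = trace.strain[: cut + 1]
    else:
        # split the final interval exactly at t_end
        time = np.append(trace.time[:cut], t_end)
        strain = np.append(trace.strain[:cut], np.interp(t_end, trace.time, trace.strain))
    if time.size < 2:
        return 0.0
    return _masked_linear_integral(time, strain)


@dataclass
class SegmentFeatures:
    """Scalar features of one segment: peak, its timing, and the three integrals."""

    P: float
    T_peak: float | None
    I_avc: float
    I_peak: float
    E: float


def segment_features(trace: StrainTrace, t_avc: float) -> SegmentFeatures:
    """Peak and integral features of one (resampled) segment trace.

    ``E = I_peak − I_avc``: negative when the segment peaks before valve
    closure (efficient shortening), positive when qualifying contraction
    continues past AVC up to a later peak (wasted shortening).  A segment
    that never leaves the dead zone has no peak time; its I_peak is 0 and
    E = −I_avc.
    """
    p, t_peak = peak_features(trace)
    i_avc = strain_integral(trace, t_avc)
    i_peak = strain_integral(trace, t_peak) if t_peak is not None else 0.0
    return SegmentFeatures(P=p, T_peak=t_peak, I_avc=i_avc, I_peak=i_peak, E=i_peak - i_avc)


# ---------------------------------------------------------------------------
# per-view and per-patient aggregation

def view_features(rec: ViewRecording, rate: float = RESAMPLE_HZ) -> dict[str, float]:
    """All 52 features of one view, keyed by canonical feature name.

    Segments with an undefined peak time are excluded from the Tpeak
    mean/std and dTpeak statistics (their count is logged); if no segment
    has a defined peak the view is flagged low-quality.
    """
    vw = rec.view
    segs = VIEW_SEGMENTS[vw]
    per_seg = {
        seg: segment_features(resample_trace(rec.trace(seg), rate), rec.t_avc)
        for seg in segs
    }
    n_undef = sum(1 for sf in per_seg.values() if sf.T_peak is None)
    if n_undef == 6:
        raise LowQualityViewError(f"{vw}: no segment exceeds the contraction dead zone")
    if n_undef:
        logger.info("%s view: %d segment(s) without a defined peak time", vw, n_undef)

    out: dict[str, float] = {f"Tavc_{vw}": rec.t_avc}
    p_vals = np.array([per_seg[s].P for s in segs])
    for s in segs:
        out[f"P_{vw}_{s}"] = per_seg[s].P
    out[f"P_{vw}_mean"] = float(p_vals.mean())
    out[f"P_{vw}_std"] = float(p_vals.std(ddof=1))
    t_vals = np.array([per_seg[s].T_peak for s in segs if per_seg[s].T_peak is not None])
    for s in segs:
        tp = per_seg[s].T_peak
        out[f"Tpeak_{vw}_{s}"] = math.nan if tp is None else tp
    out[f"Tpeak_{vw}_mean"] = float(t_vals.mean())
    out[f"Tpeak_{vw}_std"] = float(t_vals.std(ddof=1)) if t_vals.size > 1 else 0.0
    out[f"dP_{vw}"] = float(p_vals.max() - p_vals.min())
    out[f"dTpeak_{vw}"] = float(t_vals.max() - t_vals.min())

    (sd1, segs1), (sd2, segs2) = VIEW_SIDES[vw]
    for fam, attr in (("Iavc", "I_avc"), ("Ipeak", "I_peak"), ("E", "E")):
        vals = np.array([getattr(per_seg[s], attr) for s in segs])
        for s in segs:
            out[f"{fam}_{vw}_{s}"] = getattr(per_seg[s], attr)
        out[f"{fam}_{vw}_mean"] = float(vals.mean())
        out[f"{fam}_{vw}_std"] = float(vals.std(ddof=1))
        sum1 = float(sum(getattr(per_seg[s], attr) for s in segs1))
        sum2 = float(sum(getattr(per_seg[s], attr) for s in segs2))
        out[f"{fam}_{vw}_{sd1}"] = sum1
        out[f"{fam}_{vw}_{sd2}"] = sum2
        out[f"{fam}_{vw}_{sd1}-{sd2}"] = sum1 - sum2
    return out


def extract_patient_features(p: PatientRecord, rate: float = RESAMPLE_HZ) -> dict[str, float]:
    """The full ordered 158-feature vector of one patient."""
    out: dict[str, float] = {}
    for vw in VIEWS:
        if vw not in p.views:
            raise ValueError(f"patient {p.patient_id}: missing view {vw}")
        out.update(view_features(p.views[vw], rate))
    out["QRS"] = p.qrs_duration
    out["LVEF"] = p.lvef
    ordered = {name: out[name] for name in FEATURE_NAMES}
    assert len(ordered) == N_FEATURES
    return ordered


def extract_cohort_features(records: list[PatientRecord], rate: float = RESAMPLE_HZ) -> pd.DataFrame:
    """Feature table for a cohort: patient_id, response, then the 158 features.

    Patients with a low-quality view are skipped with a logged reason.
    """
    rows = []
    for rec in records:
        try:
            row = {"patient_id": rec.patient_id, "response": rec.response}
            row.update(extract_patient_features(rec, rate))
            rows.append(row)
        except LowQualityViewError as exc:
            logger.warning("skipping patient %s: %s", rec.patient_id, exc)
    return pd.DataFrame(rows, columns=["patient_id", "response", *FEATURE_NAMES])


def classify_response(esv_baseline: float, esv_followup: float) -> str:
    """Responder label from the end-systolic volume pair.

    Responder iff the relative ESV decrease at follow-up strictly exceeds
    15%; a decrease of exactly 15% is a non-responder.
    """
    if not (esv_baseline > 0 and esv_followup > 0):
        raise ValueError("end-systolic volumes must be positive")
    decrease = (esv_baseline - esv_followup) / esv_baseline
    return "responder" if decrease > 0.15 else "non-responder"
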