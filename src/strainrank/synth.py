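"""Synthetic cohorts of segmental strain curves with LBBB-like mechanics.

Each segment curve is a sum of two raised-cosine lobes: a negative systolic
lobe (depth = ``amplitude``, centred at ``t_peak``, support ``width``) and,
optionally, a positive post-peak rebound lobe (relative height
``rebound_fraction``) modelling the stretch a prematurely activated septum
undergoes while the opposing wall contracts.  The family is smooth with
closed-form extrema and analytically integrable, so every downstream
feature has an independent closed-form oracle.

The cohort generator emulates a CRT candidate population with left bundle
branch block.  Septal-type segments follow the LBBB pattern: early
systolic shortening, rebound stretch, then post-systolic shortening that
peaks after aortic valve closure — so septal efficiency (E) is positive,
i.e. part of the septal work is wasted.  Lateral segments contract once,
peaking after AVC.  *Responders* additionally carry the group effects the
clinical literature associates with reverse remodelling: a deeper septal
post-systolic lobe (more wasted septal work, moving the septal ``E_4ch``
features) and a stronger, later-peaking lateral wall (more lateral
cumulative strain, moving ``Iavc_4ch_L`` / ``Ipeak_4ch_L``).  The group
effects are expressed in the 4-chamber view, which images the
septal–lateral axis along which LBBB dyssynchrony is maximal.

End-systolic volume pairs are drawn conditionally on the label so that the
strict >15%-decrease responder rule reproduces the assigned labels exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import VIEWS, VIEW_SEGMENTS, VIEW_SIDES, PatientRecord, StrainTrace, ViewRecording

#: Features that carry the planted responder effect most directly, in the
#: canonical grammar: the septal-efficiency effect is read out by the
#: three septal segment E features and their wall sum; the lateral
#: cumulative-strain effect by the lateral Ipeak wall sum.
PLANTED_FEATURES: tuple[str, ...] = (
    "E_4ch_BS",
    "E_4ch_MS",
    "E_4ch_AS",
    "E_4ch_S",
    "Ipeak_4ch_L",
)

#: Septal efficiency features expected to dominate group separation when
#: only the septal effect is planted.
SEPTAL_E_FEATURES: tuple[str, ...] = (
    "E_4ch_BS", "E_4ch_MS", "E_4ch_AS",
    "E_4ch_S", "E_4ch_S-L", "E_4ch_mean", "E_4ch_std",
)


@dataclass
class SegmentParams:
    """Parameters of one synthetic segment curve."""

    amplitude: float  # percent, depth of peak shortening (> 0)
    t_peak: float  # s, centre of the systolic lobe
    width: float  # s, full support of the systolic lobe
    rebound_fraction: float = 0.0  # in [0, 1), height of rebound lobe / amplitude
    noise_sd: float = 0.0  # percent, additive white noise

    def validate(self, cycle_length: float) -> None:
        if not self.amplitude > 0:
            raise ValueError("amplitude must be > 0")
        if not 0 < self.t_peak < cycle_length:
            raise ValueError("t_peak must lie inside the cycle")
        if not self.width > 0:
            raise ValueError("width must be > 0")
        if self.t_peak + self.width / 2 > cycle_length:
            raise ValueError("systolic lobe extends past the end of the cycle")
        if self.t_peak - self.width / 2 < 0:
            raise ValueError("systolic lobe must start at or after QRS onset")
        if not 0 <= self.rebound_fraction < 1:
            raise ValueError("rebound_fraction must be in [0, 1)")


@dataclass
class EffectMap:
    """Additive responder-group offsets on the 4ch wall parameters.

    The septal-efficiency effect acts on the post-systolic lobe through
    three co-directional routes: ``septal_e_pct`` deepens it,
    ``septal_t_peak_s`` delays it and ``septal_width_s`` broadens it —
    all three increase the wasted septal shortening after valve closure
    and hence the septal ``E_4ch`` features.  The lateral offsets
    strengthen and further delay the lateral peak (more lateral
    cumulative strain).  ``septal_amplitude_pct`` deepens the early
    septal lobe; zero under the standard study conditions.
    """

    septal_e_pct: float = 3.0
    septal_t_peak_s: float = 0.03
    septal_width_s: float = 0.08
    septal_amplitude_pct: float = 0.0
    lateral_amplitude_pct: float = 4.0
    lateral_t_peak_s: float = 0.05

    def is_null(self) -> bool:
        return all(
            v == 0
            for v in (
                self.septal_e_pct,
                self.septal_t_peak_s,
                self.septal_width_s,
                self.septal_amplitude_pct,
                self.lateral_amplitude_pct,
                self.lateral_t_peak_s,
            )
        )


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort."""

    n_patients: int = 130
    responder_fraction: float = 0.64
    cycle_length_s: float = 1.0
    rate_hz: float = 100.0  # export sampling rate; upsampled to 500 Hz downstream
    t_avc_s: dict[str, float] = field(
        default_factory=lambda: {"4ch": 0.40, "3ch": 0.41, "2ch": 0.39}
    )
    effect: EffectMap = field(default_factory=EffectMap)
    noise_sd: float = 1.0  # percent
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if not 0 <= self.responder_fraction <= 1:
            raise ValueError("responder_fraction must be in [0, 1]")
        for vw, t in self.t_avc_s.items():
            if not 0 < t < self.cycle_length_s:
                raise ValueError(f"t_avc for {vw} must be inside the cycle")


# baseline (non-responder) population parameters: mean, sd of per-patient draws
_WALL_TIMING = {
    # single-lobe wall types -> (t_peak mean s, t_peak sd s)
    "lateral": (0.48, 0.03),
    "other": (0.42, 0.035),
}
_AMP_MEAN, _AMP_SD = 12.0, 2.5  # percent; HF cohort, depressed strain
_WIDTH_MEAN, _WIDTH_SD = 0.55, 0.05  # s
# septal (LBBB) pattern: early systolic lobe, rebound stretch, post-systolic lobe
_SEPT_EARLY_AMP_MEAN, _SEPT_EARLY_AMP_SD = 10.0, 2.5  # percent
_SEPT_EARLY_TPEAK_MEAN, _SEPT_EARLY_TPEAK_SD = 0.25, 0.02  # s
_SEPT_LOBE_WIDTH_MEAN, _SEPT_LOBE_WIDTH_SD = 0.30, 0.02  # s
_SEPT_PSS_LIFT_MEAN, _SEPT_PSS_LIFT_SD = 2.5, 1.5  # percent above early amp
_SEPT_PSS_TPEAK_MEAN, _SEPT_PSS_TPEAK_SD = 0.58, 0.025  # s


def _wall_type(view: str, segment: str) -> str:
    if view == "4ch":
        (sd1, segs1), (sd2, segs2) = VIEW_SIDES["4ch"]
        if segment in segs1:
            return "septal"
        return "lateral"
    if view == "3ch":
        (sd1, segs1), _ = VIEW_SIDES["3ch"]
        # anteroseptal wall shares the septum's premature activation
        return "septal" if segment in segs1 else "other"
    return "other"


def make_segment_curve(
    p: SegmentParams,
    cycle_length: float,
    rate: float,
    rng: np.random.Generator | None = None,
) -> StrainTrace:
    """Evaluate the two-lobe curve on a uniform grid of length ``cycle_length``.

    The rebound lobe has width ``width/2`` and starts exactly where the
    systolic lobe ends, so its maximum equals ``rebound_fraction x amplitude``
    whenever it fits inside the cycle.
    """
    p.validate(cycle_length)
    n = max(1, round(cycle_length * rate))
    t = np.linspace(0.0, cycle_length, n + 1)
    s = np.zeros_like(t)
    half = p.width / 2
    in_lobe = np.abs(t - p.t_peak) <= half
    s[in_lobe] = -p.amplitude * 0.5 * (1 + np.cos(2 * np.pi * (t[in_lobe] - p.t_peak) / p.width))
    if p.rebound_fraction > 0:
        w_r = p.width / 2
        c_r = p.t_peak + half + w_r / 2
        in_reb = np.abs(t - c_r) <= w_r / 2
        s[in_reb] += (
            p.rebound_fraction
            * p.amplitude
            * 0.5
            * (1 + np.cos(2 * np.pi * (t[in_reb] - c_r) / w_r))
        )
    if p.noise_sd > 0:
        if rng is None:
            raise ValueError("noise_sd > 0 requires an rng")
        s = s + rng.normal(0.0, p.noise_sd, size=s.shape)
    return StrainTrace("synthetic", t, s)


def _draw_segment_components(
    rng: np.random.Generator, cfg: CohortConfig, view: str, segment: str, responder: bool
) -> list[SegmentParams]:
    """Noiseless curve components of one segment, conditioned on the label.

    Septal-type walls get the LBBB pattern — an early systolic lobe with a
    rebound-stretch lobe, plus a deeper post-systolic lobe after AVC —
    so their global strain peak falls late and their efficiency marker E
    is positive.  Lateral and other walls get a single systolic lobe.
    Responder offsets apply to the 4ch view only.
    """
    wall = _wall_type(view, segment)
    eff = cfg.effect
    apply = responder and view == "4ch"
    if wall == "septal":
        early_amp = _SEPT_EARLY_AMP_MEAN + (eff.septal_amplitude_pct if apply else 0.0)
        early_tp = _SEPT_EARLY_TPEAK_MEAN
        amplitude = float(np.clip(rng.normal(early_amp, _SEPT_EARLY_AMP_SD), 5.5, 20.0))
        t_peak = float(np.clip(rng.normal(early_tp, _SEPT_EARLY_TPEAK_SD), 0.18, 0.33))
        width = float(np.clip(rng.normal(_SEPT_LOBE_WIDTH_MEAN, _SEPT_LOBE_WIDTH_SD), 0.24, 0.36))
        width = min(width, 2 * t_peak)
        rebound = float(rng.uniform(0.15, 0.35))
        early = SegmentParams(amplitude, t_peak, width, rebound_fraction=rebound)
        # post-systolic lobe: wasted shortening after valve closure
        lift = max(0.5, rng.normal(_SEPT_PSS_LIFT_MEAN, _SEPT_PSS_LIFT_SD))
        pss_amp = amplitude + lift + (eff.septal_e_pct if apply else 0.0)
        pss_mu = _SEPT_PSS_TPEAK_MEAN + (eff.septal_t_peak_s if apply else 0.0)
        pss_tp = float(np.clip(rng.normal(pss_mu, _SEPT_PSS_TPEAK_SD), 0.50, 0.70))
        pss_w_mu = _SEPT_LOBE_WIDTH_MEAN + (eff.septal_width_s if apply else 0.0)
        pss_width = float(np.clip(rng.normal(pss_w_mu, _SEPT_LOBE_WIDTH_SD), 0.24, 0.46))
        late = SegmentParams(pss_amp, pss_tp, pss_width)
        return [early, late]
    t_mean, t_sd = _WALL_TIMING[wall]
    amp_mean = _AMP_MEAN
    if apply and wall == "lateral":
        t_mean = t_mean + eff.lateral_t_peak_s
        amp_mean = amp_mean + eff.lateral_amplitude_pct
    amplitude = float(np.clip(rng.normal(amp_mean, _AMP_SD), 6.0, 25.0))
    t_peak = float(np.clip(rng.normal(t_mean, t_sd), 0.30, 0.62))
    width = float(np.clip(rng.normal(_WIDTH_MEAN, _WIDTH_SD), 0.40, 0.66))
    width = min(width, 2 * t_peak, 2 * (cfg.cycle_length_s - t_peak))
    return [SegmentParams(amplitude, t_peak, width)]


def _compose_segment(
    components: list[SegmentParams],
    segment_id: str,
    cfg: CohortConfig,
    rng: np.random.Generator,
) -> StrainTrace:
    """Sum the noiseless component curves and add one measurement-noise draw."""
    total = None
    time = None
    for p in components:
        tr = make_segment_curve(p, cfg.cycle_length_s, cfg.rate_hz)
        time = tr.time
        total = tr.strain if total is None else total + tr.strain
    if cfg.noise_sd > 0:
        total = total + rng.normal(0.0, cfg.noise_sd, size=total.shape)
    return StrainTrace(segment_id, time, total)


def generate_cohort(cfg: CohortConfig) -> tuple[list[PatientRecord], np.ndarray]:
    """Generate a cohort of patient records and their binary labels.

    Labels are drawn first (responder count = ``round(fraction x n)``,
    order shuffled), then every curve parameter is drawn conditionally on
    the label.  Fully reproducible from ``cfg.seed``.

    Returns the records and an int array (1 = responder, 0 = non-responder).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patients
    n_resp = round(cfg.responder_fraction * n)
    labels = np.zeros(n, dtype=int)
    labels[:n_resp] = 1
    rng.shuffle(labels)

    records: list[PatientRecord] = []
    for i in range(n):
        responder = bool(labels[i])
        views: dict[str, ViewRecording] = {}
        for vw in VIEWS:
            traces = []
            for seg in VIEW_SEGMENTS[vw]:
                comps = _draw_segment_components(rng, cfg, vw, seg, responder)
                traces.append(_compose_segment(comps, seg, cfg, rng))
            views[vw] = ViewRecording(view=vw, traces=traces, t_avc=cfg.t_avc_s[vw])
        esv_b = float(np.clip(rng.normal(180.0, 45.0), 90.0, 320.0))
        frac = rng.uniform(0.20, 0.45) if responder else rng.uniform(-0.08, 0.10)
        esv_f = esv_b * (1 - frac)
        qrs = float(np.clip(rng.normal(168.4 if responder else 165.4, 19.2 if responder else 22.0), 120.0, 220.0))
        lvef = float(np.clip(rng.normal(29.3 if responder else 28.4, 7.2 if responder else 9.7), 10.0, 45.0))
        records.append(
            PatientRecord(
                patient_id=f"P{i + 1:03d}",
                views=views,
                qrs_duration=qrs,
                lvef=lvef,
                esv_baseline=esv_b,
                esv_followup=esv_f,
                response="responder" if responder else "non-responder",
            )
        )
    return records, labels


def write_cohort(records: list[PatientRecord], out_dir, header_comment: str | None = None):
    """Write a cohort as view waveform files plus a manifest; returns the manifest path."""
    from pathlib import Path

    from .io import write_manifest, write_view_file

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        row = {"patient_id": rec.patient_id, "qrs_ms": rec.qrs_duration, "lvef_pct": rec.lvef,
               "esv_baseline_ml": rec.esv_baseline, "esv_followup_ml": rec.esv_followup}
        for vw in VIEWS:
            fname = f"{rec.patient_id}_{vw}.csv"
            write_view_file(rec.views[vw], out_dir / fname)
            row[f"file_{vw}"] = fname
        rows.append(row)
    return write_manifest(rows, out_dir / "manifest.csv", header_comment=header_comment)
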