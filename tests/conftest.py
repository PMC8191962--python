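"""Shared fixtures: small synthetic cohorts and analytic test pulses."""

from __future__ import annotations

import numpy as np
import pytest

from strainrank.io import VIEW_SEGMENTS, StrainTrace, ViewRecording
from strainrank.synth import CohortConfig, generate_cohort


def triangular_pulse(
    depth: float = 20.0,
    t_peak: float = 0.3,
    t_end_pulse: float = 0.6,
    duration: float = 1.0,
    rate: float = 100.0,
    segment_id: str = "BS",
) -> StrainTrace:
    """Triangle 0 -> -depth at t_peak -> 0 at t_end_pulse, flat afterwards.

    Piecewise linear with vertices on the sampling grid, so linear
    resampling and the piecewise-linear integral are exact.
    """
    t = np.round(np.arange(0, duration * rate + 1) / rate, 12)
    down = -t / t_peak * depth
    up = -depth + (t - t_peak) / (t_end_pulse - t_peak) * depth
    s = np.where(t <= t_peak, down, np.where(t <= t_end_pulse, up, 0.0))
    return StrainTrace(segment_id, t, s)


def identical_view(view: str = "4ch", trace: StrainTrace | None = None, t_avc: float = 0.45) -> ViewRecording:
    """A view whose six segments all carry the same curve."""
    base = trace or triangular_pulse()
    traces = [StrainTrace(seg, base.time, base.strain) for seg in VIEW_SEGMENTS[view]]
    return ViewRecording(view=view, traces=traces, t_avc=t_avc)


@pytest.fixture(scope="session")
def small_cohort():
    """12-patient synthetic cohort with the default effect structure."""
    cfg = CohortConfig(n_patients=12, seed=42)
    records, labels = generate_cohort(cfg)
    return records, labels


@pytest.fixture(scope="session")
def cohort_features(small_cohort):
    from strainrank.features import extract_cohort_features

    records, labels = small_cohort
    return extract_cohort_features(records), labels
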