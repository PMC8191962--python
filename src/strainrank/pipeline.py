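"""End-to-end pipeline: synthesize -> extract -> rank -> report.

One run-level integer seed fans out deterministically to the generator and
to the random-forest stage via :class:`numpy.random.SeedSequence`, so each
stage is independently reproducible.  Every output file carries a comment
header with the seed and a hash of the configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import importance as imp
from .features import extract_cohort_features
from .importance import RFConfig
from .io import load_cohort, read_feature_table, write_feature_table
from .synth import CohortConfig, EffectMap, generate_cohort, write_cohort

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Full configuration of one pipeline run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    rf: RFConfig = field(default_factory=RFConfig)
    top_k: int = 20
    min_methods: int = 3
    relief_k: int = 10
    corr_threshold: float = 0.5
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        cohort = d.pop("cohort", {})
        effect = cohort.pop("effect", {}) if isinstance(cohort, dict) else {}
        rf = d.pop("rf", {})
        cfg = cls(
            cohort=CohortConfig(**{**cohort, "effect": EffectMap(**effect)})
            if isinstance(cohort, dict)
            else cohort,
            rf=RFConfig(**rf) if isinstance(rf, dict) else rf,
            **d,
        )
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> Path:
        path = Path(path)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
        return path

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def stage_seeds(self) -> dict[str, int]:
        """Derive per-stage seeds (< 2**31) from the run seed."""
        ss = np.random.SeedSequence(self.seed)
        synth_ss, rf_ss = ss.spawn(2)
        return {
            "synth": int(synth_ss.generate_state(1, np.uint32)[0] % (2**31)),
            "rf": int(rf_ss.generate_state(1, np.uint32)[0] % (2**31)),
        }

    def header(self) -> str:
        return f"strainrank run seed={self.seed} config_hash={self.config_hash()}"


def run_synth(cfg: RunConfig, out_dir) -> Path:
    """Generate a cohort and write it as view files + manifest."""
    seeds = cfg.stage_seeds()
    cohort_cfg = CohortConfig(**{**asdict(cfg.cohort), "effect": cfg.cohort.effect,
                                 "seed": seeds["synth"]})
    records, labels = generate_cohort(cohort_cfg)
    manifest = write_cohort(records, out_dir, header_comment=cfg.header())
    n_resp = int(labels.sum())
    logger.info(
        "synthesized %d patients: %d responders / %d non-responders",
        len(records), n_resp, len(records) - n_resp,
    )
    return manifest


def run_extract(manifest, out_path, header: str | None = None) -> Path:
    """Load a cohort from files and write its 158-feature table."""
    records = load_cohort(manifest)
    table = extract_cohort_features(records)
    return write_feature_table(table, out_path, header_comment=header)


def run_rank(feature_table, cfg: RunConfig, out_dir) -> dict:
    """Run every importance method on a feature table and write all outputs.

    Writes one ranking CSV per method, the CWF table, the correlation edge
    list for the OOB top-20, and a plain-text report with the view census
    and the OOB/CWF overlap.  Returns the rankings and summaries.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if isinstance(feature_table, (str, Path)):
        feature_table = read_feature_table(feature_table)
    X = feature_table.drop(columns=["patient_id", "response"], errors="ignore")
    y = (feature_table["response"] == "responder").astype(int).to_numpy()
    X = imp.impute_median(X)

    seeds = cfg.stage_seeds()
    rf_cfg = RFConfig(**{**asdict(cfg.rf), "seed": seeds["rf"]})
    oob = imp.oob_importance(X, y, rf_cfg)
    fw = imp.run_filter_wrapper_rankings(X, y)
    cwf = imp.cwf_combine(fw, top_k=cfg.top_k, min_methods=cfg.min_methods)

    header = cfg.header()
    for rk in [oob, *fw, cwf]:
        path = out_dir / f"ranking_{rk.method}.csv"
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# {header}\n")
            rk.to_frame().to_csv(fh, index=False, float_format="%.8g")

    graph = imp.correlation_graph(X, features=oob.top(cfg.top_k), threshold=cfg.corr_threshold)
    with open(out_dir / "correlation_edges.csv", "w", encoding="utf-8") as fh:
        fh.write(f"# {header}\na,b,abs_r,thickness\n")
        for a, b, data in sorted(graph.edges(data=True)):
            fh.write(f"{a},{b},{data['abs_r']:.6f},{data['thickness']:.6f}\n")

    census = imp.view_census(oob.top(cfg.top_k))
    overlap = imp.ranking_overlap(oob, cwf, top_k=cfg.top_k)
    report = [f"# {header}", ""]
    report.append(f"OOB top-{cfg.top_k} view census: "
                  + ", ".join(f"{v}: {census[v]}" for v in ("4ch", "3ch", "2ch", "none")))
    report.append(f"overlap(OOB, CWF) top-{cfg.top_k}: {overlap}")
    report.append("")
    for rk in [oob, *fw, cwf]:
        report.append(f"[{rk.method}] top-{cfg.top_k}:")
        for pos, (name, score) in enumerate(rk.entries[: cfg.top_k], start=1):
            report.append(f"  {pos:2d}. {name}  ({score:.4g})")
        report.append("")
    (out_dir / "report.txt").write_text("\n".join(report), encoding="utf-8")

    return {
        "oob": oob,
        "filter_wrapper": fw,
        "cwf": cwf,
        "graph": graph,
        "census": census,
        "overlap": overlap,
    }
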