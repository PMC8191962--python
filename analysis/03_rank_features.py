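"""Rank the 158 features by every importance method and summarize.

Runs the OOB random-forest importance (700 gini trees, 10 random features
per tree), the five filter/wrapper rankers and their CWF consensus on the
extracted feature table; writes the per-method rankings, the correlation
edge list of the OOB top-20 and a plain-text report under results/rankings/.
Prints the view census of the OOB top-20 and the OOB/CWF overlap, next to
the corresponding published clinical-cohort values.
"""

from pathlib import Path

from strainrank.importance import ranking_overlap, view_census
from strainrank.pipeline import RunConfig, run_rank
from strainrank.published import PUBLISHED_CWF_TOP20, PUBLISHED_OOB_TOP20
from strainrank.synth import PLANTED_FEATURES

ROOT = Path(__file__).resolve().parents[1]
SEED = 7


def main() -> None:
    cfg = RunConfig(seed=SEED)
    features = ROOT / "scratch" / "analysis" / "features.csv"
    if not features.exists():
        raise SystemExit("run analysis/02_extract_features.py first")
    out = ROOT / "results" / "rankings"
    result = run_rank(features, cfg, out)

    census = result["census"]
    print("synthetic OOB top-20 view census:",
          {k: v for k, v in census.items()})
    print("published clinical-cohort census:",
          view_census(list(PUBLISHED_OOB_TOP20)))
    print(f"\nsynthetic overlap(OOB, CWF): {result['overlap']} / 20")
    pub_overlap = ranking_overlap(list(PUBLISHED_OOB_TOP20), list(PUBLISHED_CWF_TOP20))
    print(f"published overlap(OOB, CWF): {pub_overlap} / 20")

    top20 = set(result["oob"].top(20))
    recovered = [f for f in PLANTED_FEATURES if f in top20]
    print(f"\nplanted effect carriers recovered in OOB top-20: "
          f"{len(recovered)}/{len(PLANTED_FEATURES)} {recovered}")
    print(f"\nfull report: {out / 'report.txt'}")


if __name__ == "__main__":
    main()
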