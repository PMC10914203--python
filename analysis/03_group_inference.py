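#!/usr/bin/env python
"""Cohort-level inference over the detected responses.

Reads the per-arousal calls and stable-sleep samples produced by
02_detect_responses.py and rebuilds the report tables: per-cause response and
recovery proportions with pairwise relative risks, magnitude and delay
medians with iterated one-sided signed-rank p-values, before/after levels
against the stable-sleep baseline, and the magnitude-delay correlations.
"""
import pathlib

import pandas as pd

from ppgarousal import stats

SEED = 11
RESULTS = pathlib.Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    calls = pd.read_csv(RESULTS / "pipeline" / "calls.csv")
    stable = pd.read_csv(RESULTS / "pipeline" / "stable.csv")
    tables = stats.build_report(calls, stable, stats.ReportConfig(seed=SEED))
    for name, table in tables.items():
        table.to_csv(RESULTS / f"report_{name}.csv", index=False)

    props = tables["proportions"]
    print("response proportions by cause:")
    print(props.pivot(index="cause", columns="kind", values="prop_response").round(3).to_string())
    mags = tables["magnitude_comparisons"]
    sig = mags[mags["significant"]]
    print(f"\nmagnitude comparisons: {len(sig)} of {len(mags)} significant at p < 0.01")
    print(mags[["kind", "cause_a", "cause_b", "median_a", "median_b", "median_p"]]
          .round(4).to_string(index=False))
    corr = tables["magnitude_delay_correlation"]
    print("\nmagnitude-delay correlations:")
    print(corr.round(4).to_string(index=False))


if __name__ == "__main__":
    main()
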