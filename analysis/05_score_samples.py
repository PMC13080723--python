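#!/usr/bin/env python
"""Score every sample: delta expression against its condition's day-0
baseline, then effector and memory scores as inner products with the
signature weights; summarize as a per-condition time course.

The expected planted picture: the effector score pulses at day 7 in every
condition; the memory score rises monotonically over days 0 -> 7 -> 14 only
in the BATF3 condition. Writes per-sample scores and the time-course table
under results/.
"""

from pathlib import Path

import pandas as pd

from chromsig import compute_scores, delta_expression, read_sample_sheet, \
    score_timecourse
from chromsig.signatures import SignatureVectors
from chromsig.io import write_table

ROOT = Path(__file__).resolve().parents[1]
FIXTURE = ROOT / "scratch" / "fixture"


def main() -> None:
    if not (ROOT / "scratch" / "signatures.tsv").exists():
        raise SystemExit("run analysis/04_build_signatures.py first")
    activity = pd.read_csv(
        ROOT / "scratch" / "gene_activity.tsv", sep="\t", index_col=0
    )
    samples = read_sample_sheet(FIXTURE / "samples.tsv")
    weights = pd.read_csv(
        ROOT / "scratch" / "signatures.tsv", sep="\t", index_col=0
    )

    delta = delta_expression(activity, samples, policy="per_condition_day0")
    scores = compute_scores(delta, SignatureVectors(weights))
    tc = score_timecourse(scores)
    write_table(scores, ROOT / "results" / "sample_scores.tsv")
    write_table(tc, ROOT / "results" / "score_timecourse.tsv")

    print(tc.round(1).to_string(index=False))
    wide = tc.set_index(["condition", "day"])["memory_mean"]
    for cond in samples["condition"].unique():
        m = [wide.loc[(cond, d)] for d in (0, 7, 14)]
        trend = "monotone increase" if m[0] < m[1] < m[2] else "no monotone increase"
        print(f"memory score in {cond}: {trend}")


if __name__ == "__main__":
    main()
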