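#!/usr/bin/env python
"""Good/bad response classification of the MEGs, checked against the truth.

A MEG whose monotone direction opposes its differential-expression direction
drifts back toward control levels (good response); matching directions mean
it drifts further away (bad response). Writes megs_classified.tsv and
run_report.json, and verifies direction agreement with the planted trends.
"""

import argparse
from pathlib import Path

from megscreen.io import read_table
from megscreen.pipeline import PipelineConfig, stage_classify
from megscreen.simulate import truth_from_frame


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--outdir", type=Path, default=Path("results/study"))
    args = parser.parse_args()

    cfg = PipelineConfig(outdir=args.outdir, seed=args.seed)
    counts = stage_classify(cfg)
    for group, c in counts.items():
        print(f"{group}: {c['megs']} MEGs -> {c['good']} good response, {c['bad']} bad response.")

    truth = truth_from_frame(read_table(args.outdir / "truth.tsv").fillna(""))
    classified = read_table(args.outdir / "megs_classified.tsv")
    agree = total = 0
    for row in classified.itertuples():
        up = truth.monotone_up.get(row.group, frozenset())
        down = truth.monotone_down.get(row.group, frozenset())
        if row.gene in up or row.gene in down:
            total += 1
            agree += row.meg_direction == ("up" if row.gene in up else "down")
    if total:
        print(f"Direction agreement with planted trends: {agree}/{total} ({100 * agree / total:.0f}%).")


if __name__ == "__main__":
    main()
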