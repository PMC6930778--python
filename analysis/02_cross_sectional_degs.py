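#!/usr/bin/env python
"""Cross-sectional differential expression: moderated t, BH, DEG selection.

Reads the study written by 01_simulate_study.py, writes de_results.tsv and
degs.tsv next to it, and reports the DEG funnel against the planted truth.
"""

import argparse
from pathlib import Path

from megscreen.io import read_table
from megscreen.pipeline import PipelineConfig, stage_degs
from megscreen.simulate import truth_from_frame


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--outdir", type=Path, default=Path("results/study"))
    parser.add_argument("--deg-alpha", type=float, default=0.1)
    args = parser.parse_args()

    cfg = PipelineConfig(outdir=args.outdir, seed=args.seed, deg_alpha=args.deg_alpha)
    counts = stage_degs(cfg)
    print(
        f"Moderated t on {counts['n_genes']} genes: {counts['n_degs']} DEGs at "
        f"adjusted p < {args.deg_alpha} ({counts['n_up']} up, {counts['n_down']} down)."
    )

    truth = truth_from_frame(read_table(args.outdir / "truth.tsv").fillna(""))
    degs = set(read_table(args.outdir / "degs.tsv", index_col="gene_id").index)
    planted = truth.de_up | truth.de_down
    tp = len(degs & planted)
    print(
        f"Against the planted truth: {tp}/{len(planted)} planted genes recovered, "
        f"{len(degs - planted)} false discoveries (FDR target 0.1)."
    )


if __name__ == "__main__":
    main()
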