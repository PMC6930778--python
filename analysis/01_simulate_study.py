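#!/usr/bin/env python
"""Generate the synthetic two-cohort study used by the downstream stages.

Writes the interaction network, the cross-sectional case/control matrix,
the longitudinal two-group matrix and the planted truth into
results/study/, then prints what was planted.
"""

import argparse
from pathlib import Path

from megscreen.pipeline import PipelineConfig, stage_simulate
from megscreen.simulate import SimulationConfig


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--outdir", type=Path, default=Path("results/study"))
    args = parser.parse_args()

    sim = SimulationConfig(seed=args.seed)
    cfg = PipelineConfig(outdir=args.outdir, simulation=sim, seed=args.seed)
    info = stage_simulate(cfg)

    n_de = round(sim.de_fraction * sim.n_genes)
    print(f"Wrote synthetic study to {args.outdir} (seed {args.seed}).")
    print(
        f"{info['n_genes']} genes, {info['n_edges']} interactions; "
        f"{sim.n_cases} cases vs {sim.n_controls} controls; "
        f"2 response groups x {sim.n_patients_per_group} patients x {sim.n_timepoints} time points."
    )
    print(
        f"Planted: {n_de} DE genes (log2 shift {sim.de_effect}), monotone trends of "
        f"{sim.trend_step}/time point on the DE genes in each group, noise sd {sim.noise_sd}."
    )


if __name__ == "__main__":
    main()
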