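#!/usr/bin/env python
"""Generate the default synthetic germ-cell-tumour cohort and write it out.

The cohort has four subtype groups of 12 tumours (EC-like and TE-like
bimodal, SE-like with an intermediate upper mode, SS-like globally
hypomethylated), 20,000 probes over chromosomes 1-3 and X (TE-like is
female, so its X is hemi-methylated), three imprinting control regions,
and three planted 8-probe differentially methylated blocks (ΔM = 3,
hypermethylated in EC-like vs SE-like).

Writes results/cohort/ (manifest, beta, detection p, samples, imprinting
resources, exclusion lists, gene model, truth.json).
"""

import argparse
from pathlib import Path

from gctmethyl.io import write_cohort
from gctmethyl.synthetic import SyntheticSpec, generate_cohort

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out-dir", type=Path, default=ROOT / "results" / "cohort")
    args = parser.parse_args()

    cohort = generate_cohort(SyntheticSpec(), seed=args.seed)
    write_cohort(cohort, args.out_dir)

    n_planted = sum(len(b["probe_ids"]) for b in cohort.truth.planted)
    print(f"cohort: {len(cohort.probes)} probes x {len(cohort.matrix.sample_ids)} samples")
    print(f"planted: {len(cohort.truth.planted)} blocks, {n_planted} probes")
    print(f"ICRs: {cohort.imprint.n_icrs} (covered: {cohort.imprint.icr_coverage(cohort.probes)})")
    print(f"wrote {args.out_dir}")


if __name__ == "__main__":
    main()
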