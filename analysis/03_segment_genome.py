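#!/usr/bin/env python
"""Segment the genome with the Gaussian-emission HMM.

Reads results/cohort/, trains the HMM on per-probe M-value vectors over
all tumour samples (no subtype labels), reports the likelihood curve over
a small state grid, and writes the fitted k = 6 model plus the Viterbi
run-length segments.  Six states cover this cohort's pattern vocabulary
(shared low/high domains, the female X, imprinting control regions and
the planted blocks); the study-scale default of twenty is configurable.
"""

import argparse
from pathlib import Path

from gctmethyl.hmm import fit_hmm, segments_to_frame, select_k, viterbi_segment
from gctmethyl.io import read_cohort
from gctmethyl.preprocess import filter_probes

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--k", type=int, default=6)
    parser.add_argument("--k-grid", type=int, nargs="*", default=[2, 4, 6, 8])
    parser.add_argument("--data-dir", type=Path, default=ROOT / "results" / "cohort")
    parser.add_argument("--out-dir", type=Path, default=ROOT / "results" / "segmentation")
    args = parser.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    cohort = read_cohort(args.data_dir)
    valid, _ = filter_probes(cohort.matrix, crosshyb=cohort.crosshyb, snps=cohort.snps)
    m = valid.m[valid.tumor_samples()]
    bounds = valid.probes.chrom_bounds()

    if args.k_grid:
        k_sel, curve = select_k(
            m, bounds, args.k_grid, seed=args.seed, n_restarts=1, max_iter=100
        )
        print("loglik curve:", {k: round(ll) for k, ll in zip(args.k_grid, curve)})
        print(f"likelihood saturates at k = {k_sel}")

    model = fit_hmm(m, bounds, k=args.k, seed=args.seed)
    segments = viterbi_segment(model, m, valid.probes)
    model.to_json(args.out_dir / "model.json")
    segments_to_frame(segments).to_csv(args.out_dir / "segments.tsv", sep="\t", index=False)
    sizes = [s.n_probes for s in segments]
    print(
        f"k={args.k}: {len(segments)} segments "
        f"(median {sorted(sizes)[len(sizes)//2]} probes), loglik {model.train_loglik:.0f}"
    )


if __name__ == "__main__":
    main()
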