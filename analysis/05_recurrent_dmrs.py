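#!/usr/bin/env python
"""Recurrent DMR genes across pairwise subtype comparisons.

Runs two further comparisons against the globally hypomethylated SS-like
group (EC-like vs SS-like and SE-like vs SS-like) sharing the HMM from
03, annotates all DMR lists with flanked gene overlaps, and tallies genes
occurring in more than one DMR within or between comparisons.
"""

import argparse
from pathlib import Path

from gctmethyl.dmr import dmrs_to_frame, recurrent_genes
from gctmethyl.hmm import HmmModel, viterbi_segment
from gctmethyl.io import read_cohort
from gctmethyl.pipeline import ComparisonConfig, run_comparison
from gctmethyl.preprocess import filter_probes

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--k", type=int, default=6)
    parser.add_argument("--data-dir", type=Path, default=ROOT / "results" / "cohort")
    parser.add_argument("--model", type=Path, default=ROOT / "results" / "segmentation" / "model.json")
    parser.add_argument("--out-dir", type=Path, default=ROOT / "results" / "differential")
    args = parser.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    cohort = read_cohort(args.data_dir)
    model = segments = None
    if args.model.exists():
        model = HmmModel.from_json(args.model)
        valid, _ = filter_probes(cohort.matrix, crosshyb=cohort.crosshyb, snps=cohort.snps)
        segments = viterbi_segment(model, valid.m[valid.tumor_samples()], valid.probes)

    dmr_lists = {}
    for a, b in [("EC_like", "SS_like"), ("SE_like", "SS_like")]:
        config = ComparisonConfig(group_a=a, group_b=b, k=args.k, seed=args.seed)
        res = run_comparison(
            cohort.matrix,
            config,
            imprint=cohort.imprint,
            gene_model=cohort.genes,
            crosshyb=cohort.crosshyb,
            snps=cohort.snps,
            model=model,
            segments=segments,
        )
        label = f"{a}_vs_{b}"
        dmr_lists[label] = res.dmrs
        dmrs_to_frame(res.dmrs).to_csv(args.out_dir / f"dmrs_{label}.tsv", sep="\t", index=False)
        print(
            f"{label}: {len(res.dmps.hyper_a)}+{len(res.dmps.hyper_b)} DMPs, "
            f"{len(res.dmrs)} DMRs"
        )

    rec = recurrent_genes(dmr_lists)
    rec.to_csv(args.out_dir / "recurrent_genes.tsv", sep="\t", index_label="gene")
    n_rec = int(rec["recurrent"].sum())
    print(f"recurrent genes (in >1 DMR within or between comparisons): {n_rec}")
    if n_rec:
        print(rec[rec["recurrent"]].head(10))


if __name__ == "__main__":
    main()
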