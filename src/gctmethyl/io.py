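"""Plain-text readers and writers for cohort artifacts.

All tables are TSV.  The β and detection-p matrices have probes as rows
(index column ``probe_id``) and samples as columns; sample metadata is
(sample_id, subtype, sex, site, is_cell_line); ICRs are
(chrom, start, end, allele) and imprinted TSSs
(gene, chrom, tss, strand, allele), all 1-based inclusive.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .annotation import (
    IcrInterval,
    ImprintedTss,
    ImprintResource,
    ProbeTable,
    load_manifest,
    write_manifest,
)
from .preprocess import MethylationMatrix, SnpRecord
from .synthetic import Cohort, SyntheticTruth


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="probe_id")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="probe_id")


def write_samples(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


def read_samples(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def write_imprint(imprint: ImprintResource, icr_path, tss_path) -> None:
    pd.DataFrame(
        [(i.chrom, i.start, i.end, i.allele) for i in imprint.icr_intervals],
        columns=["chrom", "start", "end", "allele"],
    ).to_csv(icr_path, sep="\t", index=False)
    pd.DataFrame(
        [(t.gene, t.chrom, t.tss_pos, t.strand, t.allele) for t in imprint.imprinted_tss],
        columns=["gene", "chrom", "tss", "strand", "allele"],
    ).to_csv(tss_path, sep="\t", index=False)


def read_imprint(icr_path, tss_path=None) -> ImprintResource:
    icrs = pd.read_csv(icr_path, sep="\t")
    resource = ImprintResource(
        icr_intervals=[
            IcrInterval(str(r.chrom), int(r.start), int(r.end), str(r.allele))
            for r in icrs.itertuples()
        ]
    )
    if tss_path is not None and Path(tss_path).exists():
        tss = pd.read_csv(tss_path, sep="\t")
        resource.imprinted_tss = [
            ImprintedTss(str(r.gene), str(r.chrom), int(r.tss), str(r.strand), str(r.allele))
            for r in tss.itertuples()
        ]
    return resource


def write_snps(snps: list[SnpRecord], path) -> None:
    pd.DataFrame(
        [(s.probe_id, s.distance_bp, s.allele_freq) for s in snps],
        columns=["probe_id", "distance_bp", "allele_freq"],
    ).to_csv(path, sep="\t", index=False)


def read_snps(path) -> list[SnpRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        SnpRecord(str(r.probe_id), int(r.distance_bp), float(r.allele_freq))
        for r in df.itertuples()
    ]


def write_cohort(cohort: Cohort, out_dir) -> None:
    """Write a generated cohort as manifest/beta/detection/sample/resource TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_manifest(cohort.probes, out / "manifest.tsv")
    write_matrix(cohort.matrix.beta, out / "beta.tsv")
    if cohort.matrix.detection_p is not None:
        write_matrix(cohort.matrix.detection_p, out / "detection_p.tsv")
    write_samples(cohort.matrix.sample_meta, out / "samples.tsv")
    write_imprint(cohort.imprint, out / "icrs.tsv", out / "imprinted_tss.tsv")
    with open(out / "crosshyb.txt", "w") as fh:
        fh.write("\n".join(sorted(cohort.crosshyb)) + "\n")
    write_snps(cohort.snps, out / "snps.tsv")
    cohort.genes.to_csv(out / "genes.tsv", sep="\t", index=False)
    truth = {
        "planted": cohort.truth.planted,
        "icr_states": cohort.truth.icr_states,
        "female_groups": cohort.truth.female_groups,
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)


def read_cohort(data_dir) -> Cohort:
    """Reload a cohort written by :func:`write_cohort`."""
    d = Path(data_dir)
    probes = load_manifest(d / "manifest.tsv")
    beta = read_matrix(d / "beta.tsv")
    det_path = d / "detection_p.tsv"
    detection = read_matrix(det_path) if det_path.exists() else None
    meta = read_samples(d / "samples.tsv")
    matrix = MethylationMatrix(
        probes=probes,
        beta=beta.loc[probes.probe_ids],
        sample_meta=meta,
        detection_p=detection.loc[probes.probe_ids] if detection is not None else None,
    )
    imprint = read_imprint(d / "icrs.tsv", d / "imprinted_tss.tsv")
    crosshyb = set()
    ch_path = d / "crosshyb.txt"
    if ch_path.exists():
        crosshyb = {line.strip() for line in ch_path.read_text().splitlines() if line.strip()}
    snps = read_snps(d / "snps.tsv") if (d / "snps.tsv").exists() else []
    genes_path = d / "genes.tsv"
    genes = pd.read_csv(genes_path, sep="\t") if genes_path.exists() else pd.DataFrame()
    truth = SyntheticTruth(modes=pd.DataFrame(), archetype=pd.Series(dtype=object))
    truth_path = d / "truth.json"
    if truth_path.exists():
        with open(truth_path) as fh:
            t = json.load(fh)
        truth.planted = t.get("planted", [])
        truth.icr_states = t.get("icr_states", {})
        truth.female_groups = t.get("female_groups", [])
    return Cohort(
        probes=probes,
        matrix=matrix,
        imprint=imprint,
        truth=truth,
        crosshyb=crosshyb,
        snps=snps,
        genes=genes,
    )
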