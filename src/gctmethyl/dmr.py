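"""Differentially methylated regions: chaining adjacent DMPs.

A DMR is a maximal chain of >= 5 DMPs of one direction on one chromosome
in which consecutive DMPs (in genomic order) are at most 1 kb apart.
Intervening non-DMP array probes do not break a chain: only the inter-DMP
distance matters.  Regions are annotated with the gene symbols overlapping
the region extended by flanks of 20% of its length on each side, and genes
recurring across DMRs (within or between comparisons) are tallied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import ProbeTable
from .differential import DmpSet


@dataclass
class DmRecord:
    """One differentially methylated region (1-based inclusive span)."""

    comparison: tuple[str, str]
    direction: str  # hyperA | hyperB
    chrom: str
    start_pos: int
    end_pos: int
    probe_ids: list[str]
    genes: list[str] = field(default_factory=list)
    flank_bp: int = 0

    @property
    def n_dmps(self) -> int:
        return len(self.probe_ids)

    @property
    def length_bp(self) -> int:
        return self.end_pos - self.start_pos + 1


def call_dmrs(
    dmps: DmpSet,
    probe_table: ProbeTable,
    min_probes: int = 5,
    max_gap_bp: int = 1000,
) -> list[DmRecord]:
    """Chain adjacent same-direction DMPs into regions.

    Per chromosome and direction, DMPs sorted by position are chained while
    successive positions are <= ``max_gap_bp`` apart (boundary included);
    maximal chains with >= ``min_probes`` members become records.  The
    result is independent of the order in which DMPs are supplied.
    """
    records: list[DmRecord] = []
    for direction, ids in (("hyperA", dmps.hyper_a), ("hyperB", dmps.hyper_b)):
        if not ids:
            continue
        loc = probe_table.positions_of(sorted(ids))
        for chrom, sub in loc.groupby("chrom", sort=False):
            sub = sub.sort_values("pos")
            pos = sub["pos"].to_numpy()
            pid = sub["probe_id"].to_numpy()
            breaks = np.flatnonzero(np.diff(pos) > max_gap_bp) + 1
            for chunk in np.split(np.arange(len(pos)), breaks):
                if len(chunk) >= min_probes:
                    records.append(
                        DmRecord(
                            comparison=dmps.comparison,
                            direction=direction,
                            chrom=str(chrom),
                            start_pos=int(pos[chunk[0]]),
                            end_pos=int(pos[chunk[-1]]),
                            probe_ids=list(pid[chunk]),
                        )
                    )
    records.sort(key=lambda r: (r.chrom, r.start_pos, r.direction))
    return records


def annotate_dmrs(
    dmrs: list[DmRecord],
    gene_model: pd.DataFrame,
    flank_frac: float = 0.2,
) -> list[DmRecord]:
    """Attach gene symbols overlapping each region extended by its flanks.

    ``gene_model`` columns: symbol, chrom, start, end (1-based inclusive).
    flank_bp = round(flank_frac * region length); the flanked interval is
    clipped at position 1.
    """
    for r in dmrs:
        flank = int(round(flank_frac * r.length_bp))
        lo = max(1, r.start_pos - flank)
        hi = r.end_pos + flank
        sub = gene_model[gene_model["chrom"].astype(str) == r.chrom]
        hit = sub[(sub["start"] <= hi) & (sub["end"] >= lo)]
        r.genes = sorted(hit["symbol"].unique())
        r.flank_bp = flank
    return dmrs


def recurrent_genes(dmr_lists: dict[str, list[DmRecord]]) -> pd.DataFrame:
    """Tally gene occurrences within and between comparison DMR lists.

    ``dmr_lists`` maps a comparison label to its annotated DMRs.  Returns a
    frame indexed by gene with n_total_occurrences (DMRs mentioning the
    gene), n_dmr_lists (distinct comparisons) and recurrent (total > 1).
    """
    total: dict[str, int] = {}
    lists: dict[str, set[str]] = {}
    for label, dmrs in dmr_lists.items():
        for r in dmrs:
            for g in r.genes:
                total[g] = total.get(g, 0) + 1
                lists.setdefault(g, set()).add(label)
    out = pd.DataFrame(
        {
            "n_total_occurrences": pd.Series(total, dtype=int),
            "n_dmr_lists": pd.Series({g: len(s) for g, s in lists.items()}, dtype=int),
        }
    ).sort_index()
    out["recurrent"] = out["n_total_occurrences"] > 1
    return out


def dmrs_to_frame(dmrs: list[DmRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "comparison": [f"{r.comparison[0]}:{r.comparison[1]}" for r in dmrs],
            "direction": [r.direction for r in dmrs],
            "chrom": [r.chrom for r in dmrs],
            "start": [r.start_pos for r in dmrs],
            "end": [r.end_pos for r in dmrs],
            "n_dmps": [r.n_dmps for r in dmrs],
            "genes": [";".join(r.genes) for r in dmrs],
            "flank_bp": [r.flank_bp for r in dmrs],
        }
    )


def dmrs_to_bed(dmrs: list[DmRecord]) -> pd.DataFrame:
    """BED representation (0-based half-open) of called regions."""
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in dmrs],
            "start": [r.start_pos - 1 for r in dmrs],
            "end": [r.end_pos for r in dmrs],
            "name": [
                f"{r.comparison[0]}:{r.comparison[1]}:{r.direction}:{','.join(r.genes) or '.'}"
                for r in dmrs
            ],
        }
    )
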