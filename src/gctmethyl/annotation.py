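"""Extended probe annotation for 450K-style methylation arrays.

A probe manifest records, for every CpG probe, its genomic location and a
set of precomputed functional attributes (TSS distance class, gene-region
classes, CpG-island membership, repeat class, small-RNA association).  This
module loads such manifests, merges literature-derived imprinting control
regions (ICRs), and derives the functional probe categories used throughout
the analysis: transcription-regulation classes, repeat/small-RNA classes,
imprinting-associated classes (ICR overlap and proximity to imprinted-gene
TSSs, split by expressed allele) and the X chromosome.

Coordinates are 1-based inclusive throughout, following the Illumina
manifest convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical chromosome sort order (1..22, X, Y)
CHROMOSOMES = [str(c) for c in range(1, 23)] + ["X", "Y"]

REGION_CLASSES = {"5'UTR", "EXON1", "GENE.BODY", "3'UTR"}
TSS_CLASSES = {"none", "TSS200", "TSS1500"}
REPEAT_CLASSES = {"none", "LINE", "SINE"}

MANIFEST_COLUMNS = [
    "probe_id",
    "chrom",
    "pos",
    "strand",
    "gene_symbols",
    "tss_distance_class",
    "region_classes",
    "island",
    "repeat_class",
    "mir",
    "snrna",
]

#: default functional category names (X_CHROM is kept separate from the
#: functional set when counting tests for the Bonferroni threshold)
DEFAULT_CATEGORIES = [
    "TSS200",
    "TSSAssociated",
    "5'UTR",
    "EXON1",
    "GENE.BODY",
    "3'UTR",
    "ISLAND",
    "LINE",
    "SINE",
    "MIR",
    "snRNA",
    "ICR_P",
    "ICR_M",
    "IMPR_P200",
    "IMPR_P1500",
    "IMPR_M200",
    "IMPR_M1500",
]


class ManifestFormatError(ValueError):
    """Raised when a probe manifest violates the documented format."""


def normalize_chrom(chrom) -> str:
    """Strip an optional ``chr`` prefix and return the bare chromosome name."""
    c = str(chrom).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    return c


def chrom_sort_key(chrom: str) -> int:
    c = normalize_chrom(chrom)
    try:
        return CHROMOSOMES.index(c)
    except ValueError:
        return len(CHROMOSOMES)


@dataclass(frozen=True)
class IcrInterval:
    """A literature-validated imprinting control region, 1-based inclusive."""

    chrom: str
    start: int
    end: int
    allele: str  # 'P', 'M' or 'unknown'

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"ICR start > end: {self}")
        if self.allele not in {"P", "M", "unknown"}:
            raise ValueError(f"unknown expressed_allele {self.allele!r}")


@dataclass(frozen=True)
class ImprintedTss:
    """TSS of an imprinted gene with its expressed allele."""

    gene: str
    chrom: str
    tss_pos: int
    strand: str
    allele: str  # 'P' or 'M'

    def __post_init__(self):
        if self.allele not in {"P", "M"}:
            raise ValueError(f"unknown expressed_allele {self.allele!r}")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass
class ImprintResource:
    """Imprinting annotation: merged ICR intervals plus imprinted-gene TSSs."""

    imprinted_tss: list[ImprintedTss] = field(default_factory=list)
    icr_intervals: list[IcrInterval] = field(default_factory=list)
    n_merged_from: int = 0

    @property
    def n_icrs(self) -> int:
        return len(self.icr_intervals)

    def icr_coverage(self, probes: "ProbeTable") -> int:
        """Number of merged ICRs containing at least one probe."""
        covered = 0
        for icr in self.icr_intervals:
            sub = probes.df[probes.df["chrom"] == icr.chrom]
            if ((sub["pos"] >= icr.start) & (sub["pos"] <= icr.end)).any():
                covered += 1
        return covered


class ProbeTable:
    """Ordered genomic probe annotation backed by a pandas DataFrame.

    Rows are sorted by (chromosome, position); probe ids are unique.
    """

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        df = df.copy()
        df["chrom"] = df["chrom"].map(normalize_chrom)
        df["pos"] = df["pos"].astype(np.int64)
        if validate:
            if df["probe_id"].duplicated().any():
                dups = df.loc[df["probe_id"].duplicated(), "probe_id"].head().tolist()
                raise ManifestFormatError(f"duplicated probe_id(s): {dups}")
            if (df["pos"] < 1).any():
                raise ManifestFormatError("probe positions must be >= 1 (1-based)")
        chrom_code = df["chrom"].map(chrom_sort_key).to_numpy()
        order = np.lexsort((df["pos"].to_numpy(), chrom_code))
        self.df = df.iloc[order].reset_index(drop=True)
        self._index = pd.Index(self.df["probe_id"])

    def __len__(self) -> int:
        return len(self.df)

    @property
    def probe_ids(self) -> np.ndarray:
        return self.df["probe_id"].to_numpy()

    @property
    def chroms(self) -> list[str]:
        seen: list[str] = []
        for c in self.df["chrom"]:
            if not seen or seen[-1] != c:
                seen.append(c)
        return seen

    def chrom_bounds(self) -> list[tuple[int, int]]:
        """Half-open [start, stop) row ranges of each chromosome block."""
        bounds = []
        chroms = self.df["chrom"].to_numpy()
        start = 0
        for i in range(1, len(chroms) + 1):
            if i == len(chroms) or chroms[i] != chroms[start]:
                bounds.append((start, i))
                start = i
        return bounds

    def positions_of(self, probe_ids: Iterable[str]) -> pd.DataFrame:
        idx = self._index.get_indexer(list(probe_ids))
        if (idx < 0).any():
            missing = [p for p, i in zip(probe_ids, idx) if i < 0]
            raise KeyError(f"probe ids not in table: {missing[:5]}")
        return self.df.iloc[idx][["probe_id", "chrom", "pos"]].reset_index(drop=True)


@dataclass
class FunctionalCategories:
    """Mapping from functional category name to the set of member probe ids."""

    category_map: dict[str, set[str]]

    def __getitem__(self, name: str) -> set[str]:
        return self.category_map[name]

    def __contains__(self, name: str) -> bool:
        return name in self.category_map

    @property
    def names(self) -> list[str]:
        return list(self.category_map)

    def n_functional(self, exclude: Sequence[str] = ("X_CHROM",)) -> int:
        return len([n for n in self.category_map if n not in exclude])


def _split_multi(value) -> list[str]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return []
    s = str(value).strip()
    if not s or s.lower() in {"none", "nan"}:
        return []
    return [t for t in s.split(";") if t]


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    return str(value).strip().lower() in {"1", "true", "yes", "y"}


def load_manifest(path) -> ProbeTable:
    """Load a probe manifest (TSV or CSV) into a sorted :class:`ProbeTable`.

    Required columns: probe_id, chrom, pos, strand, gene_symbols,
    tss_distance_class, region_classes, island, repeat_class, mir, snrna.
    gene_symbols and region_classes are ';'-separated.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str)
    for col in MANIFEST_COLUMNS:
        if col not in df.columns:
            raise ManifestFormatError(f"manifest is missing required column {col!r}")
    pos_numeric = pd.to_numeric(df["pos"], errors="coerce")
    if pos_numeric.isna().any():
        bad = int(np.flatnonzero(pos_numeric.isna().to_numpy())[0])
        # +2 converts the 0-based data row index to a 1-based file line number
        raise ManifestFormatError(
            f"non-numeric position {df['pos'].iloc[bad]!r} at line {bad + 2}"
        )
    df["pos"] = pos_numeric.astype(np.int64)
    df["island"] = df["island"].map(_parse_bool)
    df["mir"] = df["mir"].map(_parse_bool)
    df["snrna"] = df["snrna"].map(_parse_bool)
    df["repeat_class"] = df["repeat_class"].fillna("none")
    df["tss_distance_class"] = df["tss_distance_class"].fillna("none")
    return ProbeTable(df)


def write_manifest(probes: ProbeTable, path) -> None:
    """Write a ProbeTable back to TSV in the documented column layout."""
    out = probes.df[MANIFEST_COLUMNS].copy()
    out.to_csv(path, sep="\t", index=False)


def merge_icrs(raw: Iterable[IcrInterval | tuple]) -> ImprintResource:
    """Merge overlapping or book-ended ICR intervals of the same allele.

    Overlapping intervals with conflicting alleles are flagged and kept
    separate (a warning is logged).  The merge is invariant to input order.
    Returns an :class:`ImprintResource` whose ``icr_intervals`` hold the
    merged list (imprinted_tss left empty; fill in separately).
    """
    intervals = [i if isinstance(i, IcrInterval) else IcrInterval(*i) for i in raw]
    n_input = len(intervals)
    merged: list[IcrInterval] = []
    # merge within (chrom, allele); book-ended (end + 1 == start) counts as touching
    by_key: dict[tuple[str, str], list[IcrInterval]] = {}
    for iv in intervals:
        by_key.setdefault((normalize_chrom(iv.chrom), iv.allele), []).append(iv)
    for (chrom, allele), ivs in sorted(by_key.items()):
        ivs = sorted(ivs, key=lambda i: (i.start, i.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end + 1:
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(IcrInterval(chrom, cur_start, cur_end, allele))
                cur_start, cur_end = iv.start, iv.end
        merged.append(IcrInterval(chrom, cur_start, cur_end, allele))
    # flag conflicting-allele overlaps
    for i, a in enumerate(merged):
        for b in merged[i + 1 :]:
            if (
                normalize_chrom(a.chrom) == normalize_chrom(b.chrom)
                and a.allele != b.allele
                and a.start <= b.end
                and b.start <= a.end
            ):
                logger.warning(
                    "ICRs with conflicting alleles overlap and are kept separate: %s / %s",
                    a,
                    b,
                )
    merged.sort(key=lambda i: (chrom_sort_key(i.chrom), i.start, i.allele))
    return ImprintResource(icr_intervals=merged, n_merged_from=n_input)


def _in_any_interval(chrom: np.ndarray, pos: np.ndarray, intervals: list[IcrInterval]) -> np.ndarray:
    hit = np.zeros(len(pos), dtype=bool)
    for iv in intervals:
        hit |= (chrom == normalize_chrom(iv.chrom)) & (pos >= iv.start) & (pos <= iv.end)
    return hit


def classify_probes(
    probes: ProbeTable,
    imprint: ImprintResource | None = None,
    categories: Sequence[str] | None = None,
) -> FunctionalCategories:
    """Derive the functional category membership of every probe.

    Imprinting classes follow the "not mutually exclusive" rule: a probe is
    IMPR_{P,M}{200,1500} if it lies within 200/1500 bp upstream of an
    imprinted-gene TSS on the annotated strand (distance 0, at the TSS,
    counts) *or* inside an ICR of that allele.  ICR_P/ICR_M require interval
    overlap.  X_CHROM collects all probes on chromosome X.
    """
    imprint = imprint or ImprintResource()
    df = probes.df
    pid = df["probe_id"].to_numpy()
    chrom = df["chrom"].to_numpy()
    pos = df["pos"].to_numpy()

    cats: dict[str, np.ndarray] = {}
    tss_cls = df["tss_distance_class"].to_numpy()
    cats["TSS200"] = tss_cls == "TSS200"
    cats["TSSAssociated"] = (tss_cls == "TSS200") | (tss_cls == "TSS1500")
    region_sets = df["region_classes"].map(_split_multi)
    for rc in sorted(REGION_CLASSES):
        cats[rc] = region_sets.map(lambda s, rc=rc: rc in s).to_numpy()
    cats["ISLAND"] = df["island"].to_numpy(dtype=bool)
    rep = df["repeat_class"].to_numpy()
    cats["LINE"] = rep == "LINE"
    cats["SINE"] = rep == "SINE"
    cats["MIR"] = df["mir"].to_numpy(dtype=bool)
    cats["snRNA"] = df["snrna"].to_numpy(dtype=bool)

    for allele in ("P", "M"):
        icrs = [iv for iv in imprint.icr_intervals if iv.allele == allele]
        in_icr = _in_any_interval(chrom, pos, icrs)
        cats[f"ICR_{allele}"] = in_icr
        for window in (200, 1500):
            near = np.zeros(len(pos), dtype=bool)
            for g in imprint.imprinted_tss:
                if g.allele != allele:
                    continue
                on_chrom = chrom == normalize_chrom(g.chrom)
                if g.strand == "+":
                    w = (pos >= g.tss_pos - window) & (pos <= g.tss_pos)
                else:
                    w = (pos >= g.tss_pos) & (pos <= g.tss_pos + window)
                near |= on_chrom & w
            cats[f"IMPR_{allele}{window}"] = near | in_icr
    cats["X_CHROM"] = chrom == "X"

    wanted = list(categories) if categories is not None else DEFAULT_CATEGORIES + ["X_CHROM"]
    category_map = {name: set(pid[cats[name]]) for name in wanted if name in cats}
    return FunctionalCategories(category_map)
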