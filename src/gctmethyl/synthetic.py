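"""Self-contained synthetic 450K-style cohorts with known planted truth.

The generator emulates the statistical structure the downstream analysis
assumes for germ-cell-tumour subtypes:

* bimodal β distributions (modes near 0.1 and 0.9) for EC/mNS/TE/DC-like
  groups, a single low mode with a thin upper tail for SS-like groups, and
  a 0.1 / ~0.55 profile for SE/DG-like groups;
* methylation *domains*: archetypes (low / high / partially methylated
  baseline) are assigned in contiguous runs along each chromosome, so
  that genome segmentation has structure to find; hypomethylated groups
  retain methylation in a shared subset of the methylated domains;
* imprinting control regions whose methylation state per group is somatic
  (≈0.5), erased (≈0.05) or uniparental (≈0.95);
* hemi-methylation (β ≈ 0.5) of the X chromosome in female groups;
* planted differentially methylated blocks with known member probes: a
  contiguous run of high-archetype probes, flanked by low-archetype
  probes, on which the affected group's M values are shifted upward by a
  known ΔM.

β noise is Beta-distributed around each mode (parameterized by mode and
concentration), so generated values are natively bounded in [0, 1];
planted shifts are applied in M space through the logit transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

from .annotation import (
    IcrInterval,
    ImprintedTss,
    ImprintResource,
    ProbeTable,
    merge_icrs,
)
from .preprocess import MethylationMatrix, SnpRecord, beta_to_m, m_to_beta

Profile = Literal["bimodal", "hypomethylated", "intermediate"]
IcrState = Literal["somatic", "erased", "uniparental"]

#: β modes used by the group profiles
MODE_LOW = 0.1
MODE_HIGH = 0.9
MODE_INTERMEDIATE = 0.55
MODE_HEMI = 0.5
#: partially methylated domains share one intermediate mode in every group
MODE_PMD = 0.45
ICR_MODES = {"somatic": 0.5, "erased": 0.05, "uniparental": 0.95}


@dataclass(frozen=True)
class GroupSpec:
    name: str
    n_samples: int = 12
    sex: str = "M"
    global_profile: Profile = "bimodal"
    icr_p_state: IcrState = "somatic"
    icr_m_state: IcrState = "somatic"


@dataclass(frozen=True)
class PlantedDmr:
    """A planted differentially methylated block.

    The block occupies ``n_probes`` consecutive probes on ``chrom`` at
    ``spacing_bp`` intervals; the affected group (A for hyperA, B for
    hyperB) has its M values shifted up by ``delta_m`` on those probes.
    """

    group_a: str
    group_b: str
    direction: Literal["hyperA", "hyperB"] = "hyperA"
    chrom: str = "1"
    n_probes: int = 8
    spacing_bp: int = 400
    delta_m: float = 3.0

    @property
    def affected_group(self) -> str:
        return self.group_a if self.direction == "hyperA" else self.group_b


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of a synthetic cohort; deterministic given ``seed``."""

    groups: tuple[GroupSpec, ...] = (
        GroupSpec("EC_like", 12, "M", "bimodal", "somatic", "somatic"),
        GroupSpec("SE_like", 12, "M", "intermediate", "somatic", "somatic"),
        GroupSpec("TE_like", 12, "F", "bimodal", "somatic", "somatic"),
        GroupSpec("SS_like", 12, "M", "hypomethylated", "erased", "uniparental"),
    )
    n_probes_per_chrom: tuple[tuple[str, int], ...] = (
        ("1", 6000),
        ("2", 5000),
        ("3", 5000),
        ("X", 4000),
    )
    median_gap_bp: int = 3000
    gap_log_sigma: float = 0.8
    planted_dmrs: tuple[PlantedDmr, ...] = (
        PlantedDmr("EC_like", "SE_like", "hyperA", "1"),
        PlantedDmr("EC_like", "SE_like", "hyperA", "2"),
        PlantedDmr("EC_like", "SE_like", "hyperA", "3"),
    )
    beta_concentration: float = 60.0
    archetype_high_frac: float = 0.45
    #: fraction of domains that are partially methylated (mode ~0.45) in all groups
    archetype_mid_frac: float = 0.12
    archetype_mean_run: float = 10.0
    #: fraction of methylated domains where hypomethylated groups retain methylation
    hypo_retained_frac: float = 0.15
    #: fraction of domains given a randomly chosen group-specific flipped mode
    group_specific_frac: float = 0.0
    hypo_tail_frac: float = 0.02
    detection_fail_rate: float = 0.004
    n_crosshyb: int = 60
    n_snp: int = 60
    seed: int = 0

    def __post_init__(self):
        names = [g.name for g in self.groups]
        if len(set(names)) != len(names):
            raise ValueError("group names must be unique")
        known = set(names)
        for p in self.planted_dmrs:
            if p.group_a not in known or p.group_b not in known:
                raise ValueError(f"planted DMR references unknown group: {p}")


@dataclass
class SyntheticTruth:
    """Planted truth of a generated cohort, for recovery testing."""

    modes: pd.DataFrame  # probes × groups: the β mode each value was drawn around
    archetype: pd.Series  # 'low' | 'high' per probe
    planted: list[dict] = field(default_factory=list)
    icr_states: dict[str, dict[str, str]] = field(default_factory=dict)
    female_groups: list[str] = field(default_factory=list)

    def planted_probe_ids(self, comparison: tuple[str, str] | None = None) -> set[str]:
        out: set[str] = set()
        for blk in self.planted:
            if comparison is None or {blk["group_a"], blk["group_b"]} == set(comparison):
                out.update(blk["probe_ids"])
        return out


@dataclass
class Cohort:
    """Everything a pipeline run needs, bundled."""

    probes: ProbeTable
    matrix: MethylationMatrix
    imprint: ImprintResource
    truth: SyntheticTruth
    crosshyb: set[str]
    snps: list[SnpRecord]
    genes: pd.DataFrame  # symbol, chrom, start, end


def _beta_params(mode: np.ndarray, concentration: float) -> tuple[np.ndarray, np.ndarray]:
    """Beta(a, b) with the requested mode: a = m(c-2)+1, b = (1-m)(c-2)+1."""
    if concentration <= 2:
        raise ValueError("beta concentration must exceed 2")
    a = mode * (concentration - 2.0) + 1.0
    b = (1.0 - mode) * (concentration - 2.0) + 1.0
    return a, b


def _draw_archetypes(
    rng: np.random.Generator, n: int, p_high: float, p_mid: float, mean_run: float
) -> np.ndarray:
    """Markov-chain archetype sequence: contiguous low/high/mid domains."""
    switch = 1.0 / mean_run
    kinds = np.array(["low", "high", "mid"])
    probs = np.array([1.0 - p_high - p_mid, p_high, p_mid])
    out = np.empty(n, dtype="<U4")
    cur = rng.choice(kinds, p=probs)
    for i in range(n):
        out[i] = cur
        if rng.random() < switch:
            cur = rng.choice(kinds, p=probs)
    return out


def generate_cohort(spec: SyntheticSpec, seed: int | None = None) -> Cohort:
    """Generate a full synthetic cohort with planted truth.

    Deterministic given ``spec`` and ``seed`` (defaults to ``spec.seed``).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    groups = list(spec.groups)
    group_names = [g.name for g in groups]

    # --- probe coordinates ----------------------------------------------
    chroms, positions, gaps_all = [], [], []
    for chrom, n in spec.n_probes_per_chrom:
        gaps = np.exp(rng.normal(np.log(spec.median_gap_bp), spec.gap_log_sigma, size=n))
        gaps = np.maximum(gaps.astype(np.int64), 2)
        pos = 1000 + np.cumsum(gaps)
        chroms.extend([chrom] * n)
        positions.append(pos)
        gaps_all.append(gaps)
    n_total = len(chroms)
    chrom_arr = np.asarray(chroms)

    # --- archetype domains ----------------------------------------------
    archetype = np.concatenate(
        [
            _draw_archetypes(
                rng, n, spec.archetype_high_frac, spec.archetype_mid_frac, spec.archetype_mean_run
            )
            for _, n in spec.n_probes_per_chrom
        ]
    )

    # --- plant blocks: force archetypes and tight spacing ----------------
    chrom_offsets: dict[str, int] = {}
    off = 0
    for chrom, n in spec.n_probes_per_chrom:
        chrom_offsets[chrom] = off
        off += n
    chrom_sizes = dict(spec.n_probes_per_chrom)

    reserved = np.zeros(n_total, dtype=bool)
    planted_slices: list[tuple[PlantedDmr, slice]] = []
    flank = 4  # low-archetype probes forced on each side of a block
    for blk in spec.planted_dmrs:
        if blk.chrom not in chrom_sizes:
            raise ValueError(f"planted DMR on unknown chromosome {blk.chrom!r}")
        n_chrom = chrom_sizes[blk.chrom]
        need = blk.n_probes + 2 * flank
        if n_chrom < need + 20:
            raise ValueError(f"chromosome {blk.chrom} has too few probes for planted DMR")
        base = chrom_offsets[blk.chrom]
        for _ in range(1000):
            start = int(rng.integers(10, n_chrom - need - 10))
            sl = slice(base + start, base + start + blk.n_probes)
            guard = slice(max(base, sl.start - flank - 2), min(base + n_chrom, sl.stop + flank + 2))
            if not reserved[guard].any():
                break
        else:  # pragma: no cover - would need a pathological spec
            raise ValueError("could not place planted DMR without overlap")
        reserved[guard] = True
        archetype[sl] = "high"
        archetype[sl.start - flank : sl.start] = "low"
        archetype[sl.stop : sl.stop + flank] = "low"
        # tighten intra-block spacing so the block is callable as a DMR
        ci = [i for i, (c, _) in enumerate(spec.n_probes_per_chrom) if c == blk.chrom][0]
        local = slice(sl.start - base, sl.stop - base)
        g = gaps_all[ci]
        g[local.start + 1 : local.stop] = blk.spacing_bp
        planted_slices.append((blk, sl))
    # recompute positions after gap adjustment
    positions = [1000 + np.cumsum(g) for g in gaps_all]
    pos_arr = np.concatenate(positions)

    probe_ids = np.array([f"cg{i:08d}" for i in range(n_total)])

    # --- ICR intervals and imprinted TSSs --------------------------------
    icr_raw: list[IcrInterval] = []
    imprinted: list[ImprintedTss] = []
    icr_probe_mask = {"P": np.zeros(n_total, dtype=bool), "M": np.zeros(n_total, dtype=bool)}
    icr_hosts = [c for c, n in spec.n_probes_per_chrom if n >= 60 and c not in {"X", "Y"}]
    if not icr_hosts:
        icr_hosts = [c for c, n in spec.n_probes_per_chrom if n >= 60]
    icr_plan = [
        (icr_hosts[i % len(icr_hosts)], allele, gene)
        for i, (allele, gene) in enumerate([("P", "IMPG1"), ("P", "IMPG2"), ("M", "IMPG3")])
    ]
    for chrom, allele, gene in icr_plan:
        base = chrom_offsets[chrom]
        n_chrom = chrom_sizes[chrom]
        for _ in range(1000):
            start = int(rng.integers(10, n_chrom - 30))
            sl = slice(base + start, base + start + 8)
            if not reserved[max(0, sl.start - 2) : sl.stop + 2].any():
                break
        else:  # pragma: no cover
            raise ValueError("could not place ICR")
        reserved[sl] = True
        icr_probe_mask[allele][sl] = True
        iv = IcrInterval(chrom, int(pos_arr[sl.start] - 100), int(pos_arr[sl.stop - 1] + 100), allele)
        icr_raw.append(iv)
        imprinted.append(ImprintedTss(gene, chrom, iv.start, "+", allele))
    imprint = merge_icrs(icr_raw)
    imprint.imprinted_tss = imprinted

    # --- per-probe, per-group β modes ------------------------------------
    modes = pd.DataFrame(index=probe_ids, columns=group_names, dtype=float)
    high = archetype == "high"
    mid = archetype == "mid"
    # hypomethylated groups retain methylation in a shared subset of the
    # methylated domains (residual methylation), decided per domain
    domain_starts = np.flatnonzero(
        np.r_[True, (archetype[1:] != archetype[:-1]) | (chrom_arr[1:] != chrom_arr[:-1])]
    )
    domain_bounds = np.r_[domain_starts, n_total]
    retained = np.zeros(n_total, dtype=bool)
    for d in range(len(domain_starts)):
        sl = slice(domain_bounds[d], domain_bounds[d + 1])
        if archetype[sl.start] == "high" and not reserved[sl].any():
            if rng.random() < spec.hypo_retained_frac:
                retained[sl] = True
    for g in groups:
        if g.global_profile == "bimodal":
            m = np.where(high, MODE_HIGH, MODE_LOW)
        elif g.global_profile == "intermediate":
            m = np.where(high, MODE_INTERMEDIATE, MODE_LOW)
        elif g.global_profile == "hypomethylated":
            m = np.where(high & retained, MODE_HIGH, MODE_LOW)
        else:  # pragma: no cover
            raise ValueError(f"unknown profile {g.global_profile}")
        m = np.where(mid, MODE_PMD, m)
        m = m.astype(float)
        m[icr_probe_mask["P"]] = ICR_MODES[g.icr_p_state]
        m[icr_probe_mask["M"]] = ICR_MODES[g.icr_m_state]
        if g.sex == "F":
            m[(chrom_arr == "X") & ~icr_probe_mask["P"] & ~icr_probe_mask["M"]] = MODE_HEMI
        modes[g.name] = m

    # optional group-specific domains (subtype-private methylation)
    if spec.group_specific_frac > 0:
        domain_starts = np.flatnonzero(
            np.r_[True, (archetype[1:] != archetype[:-1]) | (chrom_arr[1:] != chrom_arr[:-1])]
        )
        domain_bounds = np.r_[domain_starts, n_total]
        for d in range(len(domain_starts)):
            sl = slice(domain_bounds[d], domain_bounds[d + 1])
            if reserved[sl].any() or (chrom_arr[sl.start] == "X"):
                continue
            if rng.random() < spec.group_specific_frac:
                gname = group_names[int(rng.integers(len(group_names)))]
                col = modes[gname].to_numpy()
                col[sl] = MODE_HIGH if col[sl.start] < 0.5 else MODE_LOW
                modes[gname] = col

    # --- draw β values ----------------------------------------------------
    sample_ids: list[str] = []
    meta_rows = []
    beta_cols = []
    for g in groups:
        mode_vec = modes[g.name].to_numpy()
        a, b = _beta_params(mode_vec, spec.beta_concentration)
        draw = rng.beta(a[:, None], b[:, None], size=(n_total, g.n_samples))
        if g.global_profile == "hypomethylated" and spec.hypo_tail_frac > 0:
            # thin upper tail: occasional partially methylated observations
            tail = rng.random(draw.shape) < spec.hypo_tail_frac
            ta, tb = _beta_params(np.full(int(tail.sum()), MODE_HEMI), 10.0)
            draw[tail] = rng.beta(ta, tb)
        beta_cols.append(draw)
        for i in range(g.n_samples):
            sid = f"{g.name}_{i:02d}"
            sample_ids.append(sid)
            meta_rows.append(
                {"sample_id": sid, "subtype": g.name, "sex": g.sex, "site": "NA", "is_cell_line": False}
            )
    beta = np.concatenate(beta_cols, axis=1)

    # --- planted shifts (M space) ----------------------------------------
    col_of = {s: j for j, s in enumerate(sample_ids)}
    planted_records = []
    for blk, sl in planted_slices:
        cols = [col_of[s] for s in sample_ids if s.startswith(blk.affected_group + "_")]
        sub = beta[sl, :][:, cols]
        beta[np.ix_(range(sl.start, sl.stop), cols)] = m_to_beta(beta_to_m(sub) + blk.delta_m)
        planted_records.append(
            {
                "group_a": blk.group_a,
                "group_b": blk.group_b,
                "direction": blk.direction,
                "chrom": blk.chrom,
                "delta_m": blk.delta_m,
                "probe_ids": list(probe_ids[sl]),
                "start": int(pos_arr[sl.start]),
                "end": int(pos_arr[sl.stop - 1]),
            }
        )

    # --- detection p-values ----------------------------------------------
    detection = rng.uniform(0.0, 0.005, size=beta.shape)
    available = ~reserved
    n_fail = int(round(spec.detection_fail_rate * n_total))
    fail_idx = rng.choice(np.flatnonzero(available), size=n_fail, replace=False)
    detection[fail_idx, :] = rng.uniform(0.02, 1.0, size=(n_fail, beta.shape[1]))
    available[fail_idx] = False

    # --- exclusion lists --------------------------------------------------
    ch_idx = rng.choice(np.flatnonzero(available), size=spec.n_crosshyb, replace=False)
    available[ch_idx] = False
    crosshyb = set(probe_ids[ch_idx])
    snp_idx = rng.choice(np.flatnonzero(available), size=spec.n_snp, replace=False)
    snps = [
        SnpRecord(probe_ids[i], int(rng.integers(0, 11)), float(rng.uniform(0.05, 0.5)))
        for i in snp_idx
    ]
    # decoys below the distance / frequency thresholds (must be retained)
    decoy_idx = rng.choice(np.flatnonzero(available), size=20, replace=False)
    for i in decoy_idx[:10]:
        snps.append(SnpRecord(probe_ids[i], int(rng.integers(11, 100)), 0.3))
    for i in decoy_idx[10:]:
        snps.append(SnpRecord(probe_ids[i], 0, float(rng.uniform(0.0, 0.049))))

    # --- gene model and manifest annotation -------------------------------
    gene_rows = []
    gene_symbols = np.empty(n_total, dtype=object)
    tss_class = np.full(n_total, "none", dtype=object)
    region = np.empty(n_total, dtype=object)
    gene_no = 0
    for chrom, n in spec.n_probes_per_chrom:
        base = chrom_offsets[chrom]
        i = 0
        while i < n:
            span = int(rng.integers(20, 40))
            sl = slice(base + i, base + min(i + span, n))
            symbol = f"GENE{gene_no:04d}"
            gene_no += 1
            gene_rows.append(
                {
                    "symbol": symbol,
                    "chrom": chrom,
                    "start": int(pos_arr[sl.start]),
                    "end": int(pos_arr[sl.stop - 1]),
                }
            )
            k = sl.stop - sl.start
            gene_symbols[sl] = symbol
            tss_class[sl.start] = "TSS200"
            if k > 1:
                tss_class[sl.start + 1] = "TSS1500"
            for j in range(sl.start, sl.stop):
                if j == sl.start:
                    region[j] = "EXON1"
                elif j == sl.stop - 1:
                    region[j] = "3'UTR"
                elif j == sl.start + 1:
                    region[j] = "5'UTR;GENE.BODY"
                else:
                    region[j] = "GENE.BODY"
            i += span
    genes = pd.DataFrame(gene_rows)
    # islands concentrate at unmethylated domains, repeats at methylated ones
    island = (archetype == "low") & (rng.random(n_total) < 0.5)
    repeat = np.full(n_total, "none", dtype=object)
    rep_draw = rng.random(n_total)
    repeat[(archetype == "high") & (rep_draw < 0.15)] = "LINE"
    repeat[(archetype == "high") & (rep_draw >= 0.15) & (rep_draw < 0.25)] = "SINE"
    mir = rng.random(n_total) < 0.01
    snrna = rng.random(n_total) < 0.005

    manifest = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "chrom": chrom_arr,
            "pos": pos_arr,
            "strand": np.where(rng.random(n_total) < 0.5, "+", "-"),
            "gene_symbols": gene_symbols,
            "tss_distance_class": tss_class,
            "region_classes": region,
            "island": island,
            "repeat_class": repeat,
            "mir": mir,
            "snrna": snrna,
        }
    )
    probes = ProbeTable(manifest)
    # generation already emits rows in (chrom, pos) order; keep matrices aligned
    assert np.array_equal(probes.probe_ids, probe_ids)

    sample_meta = pd.DataFrame(meta_rows).set_index("sample_id")
    matrix = MethylationMatrix(
        probes=probes,
        beta=pd.DataFrame(beta, index=probe_ids, columns=sample_ids),
        sample_meta=sample_meta,
        detection_p=pd.DataFrame(detection, index=probe_ids, columns=sample_ids),
    )
    truth = SyntheticTruth(
        modes=modes,
        archetype=pd.Series(archetype, index=probe_ids),
        planted=planted_records,
        icr_states={
            g.name: {"ICR_P": g.icr_p_state, "ICR_M": g.icr_m_state} for g in groups
        },
        female_groups=[g.name for g in groups if g.sex == "F"],
    )
    return Cohort(
        probes=probes,
        matrix=matrix,
        imprint=imprint,
        truth=truth,
        crosshyb=crosshyb,
        snps=snps,
        genes=genes,
    )


def null_spec(spec: SyntheticSpec | None = None) -> SyntheticSpec:
    """Derive a fully null spec: identical generating distribution per group.

    All groups become male bimodal with somatic imprinting and no planted
    effects, so any downstream differential call is a false positive.
    """
    spec = spec or SyntheticSpec()
    groups = tuple(
        replace(g, sex="M", global_profile="bimodal", icr_p_state="somatic", icr_m_state="somatic")
        for g in spec.groups
    )
    return replace(spec, groups=groups, planted_dmrs=(), group_specific_frac=0.0)


def null_cohort(spec: SyntheticSpec | None = None, seed: int | None = None) -> Cohort:
    """Generate a cohort in which all groups share one distribution."""
    base = null_spec(spec)
    if len(base.groups) < 2:
        raise ValueError("null cohort needs at least two groups")
    return generate_cohort(base, seed=seed)
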