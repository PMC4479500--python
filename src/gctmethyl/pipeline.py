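"""End-to-end comparison workflow: filter → segment → routes → DMRs → enrichment.

`run_comparison` wires the stages together for one pairwise subtype
comparison (groups may be merged sets of subtype labels, e.g. SE+DG).
Every protocol constant is a configurable field of
:class:`ComparisonConfig`; stage outputs are pure functions of
(inputs, config, seed) and a machine-readable run manifest records
thresholds, seeds and per-stage counts for reproducibility.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import CHROMOSOMES, FunctionalCategories, ImprintResource, classify_probes
from .differential import (
    DEFAULT_DM_MIN,
    DmpSet,
    delta_median,
    intersect_dmps,
    lasso_state_selection,
    evaluate_features,
)
from .dmr import DmRecord, annotate_dmrs, call_dmrs
from .hmm import HmmModel, Segment, fit_hmm, segment_medians, state_medians, viterbi_segment
from .preprocess import FilterReport, MethylationMatrix, filter_probes, variability_filter
from .summaries import enrichment_to_frame, fisher_enrichment

logger = logging.getLogger(__name__)


@dataclass
class ComparisonConfig:
    """All thresholds of the comparison protocol, with their defaults."""

    group_a: str | Sequence[str] = "A"
    group_b: str | Sequence[str] = "B"
    alpha: float = 0.05
    dm_min: float = DEFAULT_DM_MIN  # 0.9
    sigma_probe: float = 0.8
    sigma_segment: float = 0.6
    n_boot: int = 100
    support_min: float = 0.95
    k: int = 20
    n_restarts: int = 3
    min_probes: int = 5
    max_gap_bp: int = 1000
    flank_frac: float = 0.2
    detect_p_thresh: float = 0.01
    detect_frac: float = 0.95
    boot_adjust: str = "bh"
    lasso_positive_only: bool = False
    seed: int = 0

    def __post_init__(self):
        for name in (
            "alpha",
            "dm_min",
            "sigma_probe",
            "sigma_segment",
            "support_min",
            "flank_frac",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_boot < 1 or self.k < 1 or self.min_probes < 1 or self.max_gap_bp < 1:
            raise ValueError("counts and thresholds must be positive")

    @property
    def groups_a(self) -> list[str]:
        return [self.group_a] if isinstance(self.group_a, str) else list(self.group_a)

    @property
    def groups_b(self) -> list[str]:
        return [self.group_b] if isinstance(self.group_b, str) else list(self.group_b)

    @property
    def label(self) -> tuple[str, str]:
        return ("+".join(self.groups_a), "+".join(self.groups_b))

    @classmethod
    def from_yaml(cls, path) -> "ComparisonConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ComparisonResult:
    config: ComparisonConfig
    filter_report: FilterReport
    matrix: MethylationMatrix  # valid probes only
    model: HmmModel
    segments: list[Segment]
    probe_route: pd.DataFrame
    segment_route: pd.DataFrame
    selected_states: list
    state_coefs: pd.Series
    dmps: DmpSet
    dmrs: list[DmRecord]
    enrichment: dict[str, pd.DataFrame] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def _routes_to_probe_sets(
    probe_route: pd.DataFrame,
    segment_route: pd.DataFrame,
    segments: list[Segment],
    selected_states: list,
    valid: MethylationMatrix,
    cols_a: list[str],
    cols_b: list[str],
    dm_min: float,
) -> tuple[dict[str, set[str]], dict[str, set[str]], dict[str, set[str]]]:
    """Expand the three routes into per-direction probe-id sets."""
    probe_sets = {
        d: set(probe_route.index[(probe_route["passes"]) & (probe_route["direction"] == d)])
        for d in ("hyperA", "hyperB")
    }
    seg_sets: dict[str, set[str]] = {"hyperA": set(), "hyperB": set()}
    for seg_idx, row in segment_route[segment_route["passes"]].iterrows():
        seg_sets[row["direction"]].update(segments[seg_idx].probe_ids)
    # state route: member probes of selected states, with the per-probe ΔM filter
    state_probe_rows: list[int] = []
    for seg in segments:
        if seg.state in selected_states:
            state_probe_rows.extend(range(seg.row_slice.start, seg.row_slice.stop))
    state_sets: dict[str, set[str]] = {"hyperA": set(), "hyperB": set()}
    if state_probe_rows:
        sub = valid.m.iloc[state_probe_rows]
        dm = delta_median(sub, cols_a, cols_b)
        state_sets["hyperA"] = set(dm.index[dm > dm_min])
        state_sets["hyperB"] = set(dm.index[dm < -dm_min])
    return state_sets, seg_sets, probe_sets


def run_comparison(
    matrix: MethylationMatrix,
    config: ComparisonConfig,
    imprint: ImprintResource | None = None,
    gene_model: pd.DataFrame | None = None,
    crosshyb: set[str] | None = None,
    snps: list | None = None,
    model: HmmModel | None = None,
    segments: list[Segment] | None = None,
) -> ComparisonResult:
    """Run the full pairwise comparison workflow on a β matrix.

    A precomputed HMM (``model`` + ``segments``, e.g. shared across several
    comparisons) can be supplied; otherwise one is trained here on the
    tumour samples.  Returns all intermediate and final artifacts.
    """
    t0 = time.time()
    timings: dict[str, float] = {}

    valid, report = filter_probes(
        matrix,
        crosshyb=crosshyb,
        snps=snps,
        detect_p_thresh=config.detect_p_thresh,
        detect_frac=config.detect_frac,
    )
    timings["filter"] = time.time() - t0
    logger.info(
        "probe filter: %d input, %d valid (detection %d, crosshyb %d, snp %d)",
        report.n_input,
        report.n_valid,
        report.n_excluded_detection,
        report.n_excluded_crosshyb,
        report.n_excluded_snp,
    )

    tumor_cols = valid.tumor_samples()
    cols_a = valid.samples_of(config.groups_a)
    cols_b = valid.samples_of(config.groups_b)
    if not cols_a or not cols_b:
        raise ValueError(f"comparison groups {config.label} not found in sample metadata")

    m_tumor = valid.m[tumor_cols]
    t = time.time()
    if model is None:
        model = fit_hmm(
            m_tumor,
            valid.probes.chrom_bounds(),
            k=config.k,
            seed=config.seed,
            n_restarts=config.n_restarts,
        )
    if segments is None:
        segments = viterbi_segment(model, m_tumor, valid.probes)
    timings["segment"] = time.time() - t
    logger.info("HMM k=%d: %d segments", model.k, len(segments))

    # --- probe route -----------------------------------------------------
    t = time.time()
    keep_probe = variability_filter(valid.m[tumor_cols], config.sigma_probe)
    probe_route = evaluate_features(
        valid.m.loc[keep_probe],
        cols_a,
        cols_b,
        alpha=config.alpha,
        n_boot=config.n_boot,
        support_min=config.support_min,
        dm_min=config.dm_min,
        seed=config.seed,
        boot_adjust=config.boot_adjust,  # type: ignore[arg-type]
    )
    timings["probe_route"] = time.time() - t

    # --- segment route ---------------------------------------------------
    t = time.time()
    seg_med = pd.DataFrame(segment_medians(segments, valid.m[tumor_cols]), columns=tumor_cols)
    keep_seg = variability_filter(seg_med, config.sigma_segment)
    segment_route = evaluate_features(
        seg_med.loc[keep_seg],
        cols_a,
        cols_b,
        alpha=config.alpha,
        n_boot=config.n_boot,
        support_min=config.support_min,
        dm_min=config.dm_min,
        seed=config.seed,
        boot_adjust=config.boot_adjust,  # type: ignore[arg-type]
    )
    timings["segment_route"] = time.time() - t

    # --- state route (LASSO) ----------------------------------------------
    t = time.time()
    st_med = state_medians(segments, valid.m[tumor_cols])
    st_med.columns = tumor_cols
    selected_states, state_coefs = lasso_state_selection(
        st_med,
        cols_a,
        cols_b,
        seed=config.seed,
        positive_only=config.lasso_positive_only,
    )
    timings["state_route"] = time.time() - t
    logger.info("LASSO selected states: %s", selected_states)

    state_sets, seg_sets, probe_sets = _routes_to_probe_sets(
        probe_route,
        segment_route,
        segments,
        selected_states,
        valid,
        cols_a,
        cols_b,
        config.dm_min,
    )
    dmps = intersect_dmps(
        state_sets,
        seg_sets,
        probe_sets,
        comparison=config.label,
        universe=set(valid.probe_ids),
    )
    logger.info("DMPs: %d hyperA, %d hyperB", len(dmps.hyper_a), len(dmps.hyper_b))

    # --- DMRs --------------------------------------------------------------
    t = time.time()
    dmrs = call_dmrs(dmps, valid.probes, min_probes=config.min_probes, max_gap_bp=config.max_gap_bp)
    if gene_model is not None:
        dmrs = annotate_dmrs(dmrs, gene_model, flank_frac=config.flank_frac)
    timings["dmr"] = time.time() - t

    # --- enrichment ---------------------------------------------------------
    t = time.time()
    enrichment: dict[str, pd.DataFrame] = {}
    if dmps.n_total == 0:
        logger.info("no DMPs; enrichment skipped")
    else:
        functional = classify_probes(valid.probes, imprint)
        n_functional = functional.n_functional()
        chrom_sets = {
            f"chr{c}": set(valid.probes.df.loc[valid.probes.df["chrom"] == c, "probe_id"])
            for c in CHROMOSOMES
        }
        chrom_sets = {k: v for k, v in chrom_sets.items() if v}
        state_sets_all: dict[str, set[str]] = {}
        for seg in segments:
            state_sets_all.setdefault(f"state{seg.state}", set()).update(seg.probe_ids)
        alpha_bonf = config.alpha / (n_functional + len(chrom_sets) + model.k)
        universe = set(valid.probe_ids)
        all_cats = {**functional.category_map, **chrom_sets, **state_sets_all}
        for direction, ids in (("hyperA", dmps.hyper_a), ("hyperB", dmps.hyper_b)):
            if ids:
                enrichment[direction] = enrichment_to_frame(
                    fisher_enrichment(ids, universe, all_cats, alpha_bonf)
                )
    timings["enrichment"] = time.time() - t

    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "counts": {
            "n_input_probes": report.n_input,
            "n_valid_probes": report.n_valid,
            "n_segments": len(segments),
            "n_states": model.k,
            "n_probe_candidates": int(keep_probe.sum()),
            "n_segment_candidates": int(keep_seg.sum()),
            "n_selected_states": len(selected_states),
            "n_dmp_hyper_a": len(dmps.hyper_a),
            "n_dmp_hyper_b": len(dmps.hyper_b),
            "n_dmrs": len(dmrs),
        },
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
    }
    return ComparisonResult(
        config=config,
        filter_report=report,
        matrix=valid,
        model=model,
        segments=segments,
        probe_route=probe_route,
        segment_route=segment_route,
        selected_states=selected_states,
        state_coefs=state_coefs,
        dmps=dmps,
        dmrs=dmrs,
        enrichment=enrichment,
        manifest=manifest,
    )
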