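"""β/M conversion, probe exclusion and the low-variability feature filter.

Array methylation at a CpG is quantified either as the methylation fraction
β ∈ [0, 1] or as the M-value, M = log2(β / (1 − β)).  M-values have more
homogeneous variance across the β range and are used for all statistics;
β is retained for interpretation (percent methylation).

Probe exclusion mirrors standard 450K practice: probes that fail detection,
cross-hybridizing probes, and probes with a common SNP at or near the
target CpG are removed before analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .annotation import ProbeTable

logger = logging.getLogger(__name__)

#: default clamp bound for the logit transform, keeps M finite at β ∈ {0, 1}
DEFAULT_EPSILON = 1e-6


def beta_to_m(beta, epsilon: float = DEFAULT_EPSILON):
    """logit2 transform: M = log2(b / (1 − b)) with b clamped to [ε, 1 − ε].

    Accepts scalars or arrays.  β outside [0, 1] raises a ValueError.
    """
    if not 0 < epsilon < 0.5:
        raise ValueError("epsilon must be in (0, 0.5)")
    b = np.asarray(beta, dtype=float)
    if np.any((b < 0) | (b > 1)):
        raise ValueError("beta values must lie in [0, 1]")
    b = np.clip(b, epsilon, 1.0 - epsilon)
    m = np.log2(b / (1.0 - b))
    return m if m.ndim else float(m)


def m_to_beta(m):
    """Inverse logit2: β = 2^M / (1 + 2^M)."""
    m_arr = np.asarray(m, dtype=float)
    if not np.all(np.isfinite(m_arr)):
        raise ValueError("M values must be finite")
    # expit formulation avoids overflow for large |M|
    b = np.where(m_arr >= 0, 1.0 / (1.0 + 2.0 ** (-m_arr)), 2.0**m_arr / (1.0 + 2.0**m_arr))
    return b if b.ndim else float(b)


@dataclass
class SnpRecord:
    """A SNP near a probe's target CpG."""

    probe_id: str
    distance_bp: int
    allele_freq: float

    def __post_init__(self):
        if self.distance_bp < 0:
            raise ValueError("SNP distance must be >= 0")
        if not 0 <= self.allele_freq <= 1:
            raise ValueError("allele frequency must be in [0, 1]")


@dataclass
class FilterReport:
    """Reconciliation of the probe-exclusion step."""

    n_input: int
    n_excluded_detection: int
    n_excluded_crosshyb: int
    n_excluded_snp: int
    n_valid: int
    excluded_ids: dict[str, set[str]] = field(default_factory=dict)

    def check(self) -> None:
        union = set().union(*self.excluded_ids.values()) if self.excluded_ids else set()
        assert self.n_valid + len(union) == self.n_input, "filter report does not reconcile"


@dataclass
class MethylationMatrix:
    """Probes × samples β matrix with sample metadata, aligned to a ProbeTable.

    ``sample_meta`` is indexed by sample id with at least the columns
    subtype, sex, site, is_cell_line.  ``detection_p`` is optional.
    """

    probes: ProbeTable
    beta: pd.DataFrame
    sample_meta: pd.DataFrame
    detection_p: pd.DataFrame | None = None
    epsilon: float = DEFAULT_EPSILON

    def __post_init__(self):
        if not np.array_equal(self.beta.index.to_numpy(), self.probes.probe_ids):
            raise ValueError("beta row order must equal ProbeTable order")
        vals = self.beta.to_numpy()
        if np.any((vals < 0) | (vals > 1)) or not np.all(np.isfinite(vals)):
            raise ValueError("beta values must lie in [0, 1]")
        missing = set(self.beta.columns) - set(self.sample_meta.index)
        if missing:
            raise ValueError(f"samples missing from metadata: {sorted(missing)[:5]}")
        self._m: pd.DataFrame | None = None

    @property
    def sample_ids(self) -> list[str]:
        return list(self.beta.columns)

    @property
    def probe_ids(self) -> np.ndarray:
        return self.probes.probe_ids

    @property
    def m(self) -> pd.DataFrame:
        """M-value matrix, computed lazily from β."""
        if self._m is None:
            self._m = pd.DataFrame(
                beta_to_m(self.beta.to_numpy(), self.epsilon),
                index=self.beta.index,
                columns=self.beta.columns,
            )
        return self._m

    def samples_of(self, subtype: str | Iterable[str], tumors_only: bool = True) -> list[str]:
        names = {subtype} if isinstance(subtype, str) else set(subtype)
        meta = self.sample_meta.loc[self.sample_ids]
        mask = meta["subtype"].isin(names)
        if tumors_only and "is_cell_line" in meta:
            mask &= ~meta["is_cell_line"].astype(bool)
        return list(meta.index[mask])

    def tumor_samples(self) -> list[str]:
        meta = self.sample_meta.loc[self.sample_ids]
        if "is_cell_line" in meta:
            return list(meta.index[~meta["is_cell_line"].astype(bool)])
        return self.sample_ids

    def subset_probes(self, probe_ids: np.ndarray | list[str]) -> "MethylationMatrix":
        keep = self.probes.df["probe_id"].isin(set(probe_ids)).to_numpy()
        probes = ProbeTable(self.probes.df.loc[keep], validate=False)
        det = self.detection_p.loc[keep] if self.detection_p is not None else None
        return MethylationMatrix(
            probes=probes,
            beta=self.beta.loc[keep],
            sample_meta=self.sample_meta,
            detection_p=det,
            epsilon=self.epsilon,
        )


def filter_probes(
    mat: MethylationMatrix,
    crosshyb: set[str] | None = None,
    snps: Iterable[SnpRecord | tuple] | None = None,
    detect_p_thresh: float = 0.01,
    detect_frac: float = 0.95,
    snp_max_distance: int = 10,
    snp_min_freq: float = 0.05,
) -> tuple[MethylationMatrix, FilterReport]:
    """Apply the probe-exclusion rules and return the valid-probe matrix.

    Excluded are (a) probes not detected (detection p < ``detect_p_thresh``)
    in at least ``detect_frac`` of samples, (b) cross-hybridizing probes,
    (c) probes with a SNP within ``snp_max_distance`` bp of the target CpG
    at allele frequency >= ``snp_min_freq``.  Exclusion reasons may overlap;
    the report reconciles counts against the union.
    """
    crosshyb = crosshyb or set()
    snp_records = [s if isinstance(s, SnpRecord) else SnpRecord(*s) for s in (snps or [])]
    probe_ids = mat.probe_ids
    known = set(probe_ids)

    excl_det: set[str] = set()
    if mat.detection_p is not None:
        detected = (mat.detection_p.to_numpy() < detect_p_thresh).mean(axis=1)
        excl_det = set(probe_ids[detected < detect_frac])
    else:
        logger.info("no detection p-values supplied; detection filter skipped")

    excl_ch = crosshyb & known
    n_unknown = len(crosshyb - known)

    snp_hit = {
        s.probe_id
        for s in snp_records
        if s.distance_bp <= snp_max_distance and s.allele_freq >= snp_min_freq
    }
    excl_snp = snp_hit & known
    n_unknown += len(snp_hit - known)
    if n_unknown:
        logger.info("%d exclusion-list probe ids absent from matrix (ignored)", n_unknown)

    excluded = excl_det | excl_ch | excl_snp
    keep = [p for p in probe_ids if p not in excluded]
    report = FilterReport(
        n_input=len(probe_ids),
        n_excluded_detection=len(excl_det),
        n_excluded_crosshyb=len(excl_ch),
        n_excluded_snp=len(excl_snp),
        n_valid=len(keep),
        excluded_ids={"detection": excl_det, "crosshyb": excl_ch, "snp": excl_snp},
    )
    report.check()
    return mat.subset_probes(keep), report


def variability_filter(m_values: pd.DataFrame | np.ndarray, sigma_min: float) -> np.ndarray:
    """Retain features whose sample standard deviation (ddof=1) is >= sigma_min.

    ``m_values`` is features × samples.  Returns a boolean retain mask in row
    order.  Exclusion is strict (<), so a feature at exactly ``sigma_min``
    is retained.
    """
    arr = np.asarray(m_values, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("variability filter needs a 2-D matrix with >= 2 samples")
    sigma = arr.std(axis=1, ddof=1)
    return ~(sigma < sigma_min)
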