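"""Gaussian-emission HMM segmentation of genomically ordered probes.

Each probe contributes one observation: its vector of M values across the
tumour samples.  A k-state HMM with diagonal-covariance Gaussian emissions
is trained by Baum-Welch on the per-chromosome observation sequences
(chromosomes are independent chains sharing one parameter set), without
using subtype labels.  Maximal runs of identical Viterbi states become
*segments*; the median M (or β) of a segment's or state's member probes is
used as a methylation proxy downstream.

Numerics are delegated to hmmlearn (log-space forward/backward/Viterbi);
initialization, restarts, the variance floor and the relative-likelihood
convergence rule are defined here.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from hmmlearn.base import ConvergenceMonitor
from hmmlearn.hmm import GaussianHMM
from sklearn.cluster import KMeans

from .annotation import ProbeTable

logger = logging.getLogger(__name__)

DEFAULT_VAR_FLOOR = 1e-3


@dataclass
class HmmModel:
    """Trained k-state diagonal-Gaussian HMM."""

    k: int
    pi: np.ndarray  # (k,)
    transmat: np.ndarray  # (k, k)
    means: np.ndarray  # (k, n_samples)
    variances: np.ndarray  # (k, n_samples)
    train_loglik: float
    seed: int
    loglik_history: list[float] = field(default_factory=list)
    var_floor: float = DEFAULT_VAR_FLOOR

    def __post_init__(self):
        np.testing.assert_allclose(self.pi.sum(), 1.0, atol=1e-9)
        np.testing.assert_allclose(self.transmat.sum(axis=1), 1.0, atol=1e-9)
        if np.any(self.variances < self.var_floor * (1 - 1e-12)):
            raise ValueError("state variances fell below the variance floor")

    @property
    def n_samples(self) -> int:
        return self.means.shape[1]

    def to_json(self, path) -> None:
        payload = {
            "k": self.k,
            "pi": self.pi.tolist(),
            "transmat": self.transmat.tolist(),
            "means": self.means.tolist(),
            "variances": self.variances.tolist(),
            "train_loglik": self.train_loglik,
            "seed": self.seed,
            "var_floor": self.var_floor,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "HmmModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            k=d["k"],
            pi=np.asarray(d["pi"]),
            transmat=np.asarray(d["transmat"]),
            means=np.asarray(d["means"]),
            variances=np.asarray(d["variances"]),
            train_loglik=d["train_loglik"],
            seed=d["seed"],
            var_floor=d.get("var_floor", DEFAULT_VAR_FLOOR),
        )


@dataclass
class Segment:
    """Maximal run of consecutive probes sharing one Viterbi state."""

    chrom: str
    start_pos: int
    end_pos: int
    probe_ids: list[str]
    state: int
    row_slice: slice  # rows of the M matrix covered by this segment

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)


class _RelativeMonitor(ConvergenceMonitor):
    """Convergence on relative log-likelihood change; records the full curve."""

    def __init__(self, tol: float, n_iter: int):
        super().__init__(tol, n_iter, verbose=False)
        self.full_history: list[float] = []

    def report(self, log_prob: float) -> None:
        self.full_history.append(log_prob)
        super().report(log_prob)

    @property
    def converged(self) -> bool:
        if self.iter == self.n_iter:
            return True
        if len(self.history) >= 2:
            prev, cur = self.history[-2], self.history[-1]
            return (cur - prev) < self.tol * max(1.0, abs(prev))
        return False


class _FlooredGaussianHMM(GaussianHMM):
    """Diagonal-Gaussian HMM with a hard per-dimension variance floor."""

    def __init__(self, *args, var_floor: float = DEFAULT_VAR_FLOOR, **kwargs):
        super().__init__(*args, **kwargs)
        self.var_floor = var_floor

    def _do_mstep(self, stats):
        super()._do_mstep(stats)
        self._covars_ = np.maximum(self._covars_, self.var_floor)


def _as_lengths(chrom_bounds: list[tuple[int, int]], n: int) -> list[int]:
    lengths = [stop - start for start, stop in chrom_bounds]
    if sum(lengths) != n or any(l <= 0 for l in lengths):
        raise ValueError("chrom_bounds must partition the probe rows")
    return lengths


def _to_hmmlearn(model: HmmModel) -> _FlooredGaussianHMM:
    h = _FlooredGaussianHMM(
        n_components=model.k, covariance_type="diag", init_params="", var_floor=model.var_floor
    )
    h.startprob_ = model.pi.copy()
    h.transmat_ = model.transmat.copy()
    h.means_ = model.means.copy()
    h.covars_ = model.variances.copy()
    h.n_features = model.n_samples
    return h


def _m_array(m_matrix) -> np.ndarray:
    X = np.asarray(m_matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("M matrix must be 2-D (probes x samples)")
    if not np.all(np.isfinite(X)):
        raise ValueError("M matrix contains non-finite values")
    return X


def fit_hmm(
    m_matrix,
    chrom_bounds: list[tuple[int, int]],
    k: int,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
    n_restarts: int = 3,
    var_floor: float = DEFAULT_VAR_FLOOR,
) -> HmmModel:
    """Baum-Welch fit of a k-state diagonal-Gaussian HMM.

    Initialization per restart: emission means from a seeded k-means over
    probe M vectors, per-cluster variances (floored), uniform initial
    distribution, and a 0.9 self-loop transition matrix.  The best of
    ``n_restarts`` fits by final log-likelihood is returned; the whole
    procedure is deterministic given ``seed``.
    """
    X = _m_array(m_matrix)
    n, d = X.shape
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    lengths = _as_lengths(chrom_bounds, n)

    best: tuple[float, HmmModel] | None = None
    for r in range(n_restarts):
        rs = int(seed) + 1000 * r
        if k == 1:
            means = X.mean(axis=0, keepdims=True)
            variances = np.maximum(X.var(axis=0, keepdims=True), var_floor)
            trans = np.ones((1, 1))
        else:
            km = KMeans(n_clusters=k, n_init=1, random_state=rs).fit(X)
            means = km.cluster_centers_.copy()
            variances = np.empty((k, d))
            for s in range(k):
                member = X[km.labels_ == s]
                v = member.var(axis=0) if len(member) > 1 else np.full(d, 1.0)
                variances[s] = np.maximum(v, var_floor)
            trans = np.full((k, k), 0.1 / (k - 1))
            np.fill_diagonal(trans, 0.9)

        h = _FlooredGaussianHMM(
            n_components=k,
            covariance_type="diag",
            init_params="",
            params="stmc",
            n_iter=max_iter,
            tol=tol,
            random_state=rs,
            var_floor=var_floor,
        )
        h.startprob_ = np.full(k, 1.0 / k)
        h.transmat_ = trans
        h.means_ = means
        h.covars_ = variances
        h.monitor_ = _RelativeMonitor(tol, max_iter)
        # hmmlearn warns on likelihood dips beyond ~1.5e-8 absolute, which at
        # genome-scale |log L| is pure roundoff; silence it during the fit
        hl_logger = logging.getLogger("hmmlearn.base")
        level = hl_logger.level
        hl_logger.setLevel(logging.ERROR)
        try:
            h.fit(X, lengths)
        finally:
            hl_logger.setLevel(level)
        ll = float(h.score(X, lengths))
        model = HmmModel(
            k=k,
            pi=h.startprob_.copy(),
            transmat=h.transmat_.copy(),
            means=h.means_.copy(),
            variances=np.asarray([np.diag(c) for c in h.covars_]),
            train_loglik=ll,
            seed=int(seed),
            loglik_history=list(h.monitor_.full_history),
            var_floor=var_floor,
        )
        if best is None or ll > best[0]:
            best = (ll, model)
    assert best is not None
    return best[1]


def forward_loglik(model: HmmModel, m_matrix, chrom_bounds: list[tuple[int, int]]) -> float:
    """Forward-algorithm log-likelihood of the data under ``model``."""
    X = _m_array(m_matrix)
    lengths = _as_lengths(chrom_bounds, X.shape[0])
    return float(_to_hmmlearn(model).score(X, lengths))


def select_k(
    m_matrix,
    chrom_bounds: list[tuple[int, int]],
    k_grid: list[int],
    seed: int = 0,
    saturation_frac: float = 0.01,
    **fit_kwargs,
) -> tuple[int, list[float]]:
    """Pick the state count at which the likelihood saturates.

    Fits the HMM for every k in the ascending ``k_grid`` and returns the
    last k before the log-likelihood improvement drops below
    ``saturation_frac`` of the total gain accumulated over the grid so far
    (plus the full curve).  If the curve never saturates, the largest k is
    returned.
    """
    if not k_grid:
        raise ValueError("k_grid must be non-empty")
    if sorted(k_grid) != list(k_grid):
        raise ValueError("k_grid must be ascending")
    curve = [
        fit_hmm(m_matrix, chrom_bounds, k, seed=seed, **fit_kwargs).train_loglik for k in k_grid
    ]
    selected = k_grid[-1]
    for i in range(1, len(k_grid)):
        total_gain = curve[i] - curve[0]
        step_gain = curve[i] - curve[i - 1]
        if total_gain <= 0 or step_gain < saturation_frac * total_gain:
            selected = k_grid[i - 1]
            break
    return selected, curve


def viterbi_segment(model: HmmModel, m_matrix, probes: ProbeTable) -> list[Segment]:
    """Decode the maximum-probability state path and emit run-length segments.

    Each chromosome is decoded as an independent sequence; every probe
    belongs to exactly one segment.
    """
    X = _m_array(m_matrix)
    if X.shape[0] != len(probes):
        raise ValueError("M matrix rows must match the probe table")
    if X.shape[1] != model.n_samples:
        raise ValueError(
            f"model was trained on {model.n_samples} samples, matrix has {X.shape[1]}"
        )
    bounds = probes.chrom_bounds()
    h = _to_hmmlearn(model)
    states = h.predict(X, _as_lengths(bounds, X.shape[0]))

    df = probes.df
    segments: list[Segment] = []
    for start, stop in bounds:
        run_start = start
        for i in range(start + 1, stop + 1):
            if i == stop or states[i] != states[run_start]:
                segments.append(
                    Segment(
                        chrom=df.at[run_start, "chrom"],
                        start_pos=int(df.at[run_start, "pos"]),
                        end_pos=int(df.at[i - 1, "pos"]),
                        probe_ids=list(df["probe_id"].iloc[run_start:i]),
                        state=int(states[run_start]),
                        row_slice=slice(run_start, i),
                    )
                )
                run_start = i
    return segments


def segment_medians(segments: list[Segment], m_matrix) -> np.ndarray:
    """Per-segment median M vector across samples (segments × samples)."""
    X = _m_array(m_matrix)
    return np.vstack([np.median(X[s.row_slice], axis=0) for s in segments])


def state_medians(segments: list[Segment], m_matrix) -> pd.DataFrame:
    """Per-state median over all member probes, one value per sample.

    States without any assigned probe are excluded (with a warning); the
    returned frame is indexed by the states that do occur.
    """
    X = _m_array(m_matrix)
    by_state: dict[int, list[slice]] = {}
    for seg in segments:
        by_state.setdefault(seg.state, []).append(seg.row_slice)
    all_states = set(range(max(by_state) + 1)) if by_state else set()
    missing = all_states - set(by_state)
    if missing:
        logger.warning("states with no probes excluded from medians: %s", sorted(missing))
    rows = {
        s: np.median(np.concatenate([X[sl] for sl in slices], axis=0), axis=0)
        for s, slices in sorted(by_state.items())
    }
    return pd.DataFrame.from_dict(rows, orient="index")


def segments_to_frame(segments: list[Segment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [s.chrom for s in segments],
            "start": [s.start_pos for s in segments],
            "end": [s.end_pos for s in segments],
            "n_probes": [s.n_probes for s in segments],
            "state": [s.state for s in segments],
        }
    )
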