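"""Cluster-size population state vectors, time averages and system differences.

For a frame with N ions partitioned into clusters, let c_i be the number of
clusters of size i and n_i = c_i / N. The state vector holds the components
i * n_i — the fraction of ions residing in size-i clusters — so that
n_1 + 2 n_2 + 3 n_3 + ... = 1 identically. Sizes beyond the reporting cap
S_max are accumulated in an overflow term, never dropped, so the
normalisation stays exact. Clusters of equal size but different charge
composition are merged into one cluster class; a charge-resolved tally is
retained for sensitivity reporting.

Time averages carry a conservative "maximum error": the trajectory is cut
into contiguous equal-length blocks (default 5, remainder folded into the
last) and the uncertainty of a component is the largest deviation of a block
mean from the global mean. Differences between two systems propagate these
as a plain sum, and a component is flagged significant when the magnitude of
its difference exceeds that combined uncertainty.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cluster import ClusterPartition
from .errors import IntegrityError

__all__ = [
    "StateVector",
    "PopulationSummary",
    "PopulationDifference",
    "state_vector",
    "summarize",
    "population_difference",
]


@dataclass(frozen=True)
class StateVector:
    """Per-frame populations: components[i-1] = i * n_i for sizes 1..S_max.

    ``overflow`` is the total ion fraction sitting in clusters larger than
    S_max, so components.sum() + overflow == 1 exactly.
    ``charge_tally`` maps (n_cations, n_anions) -> number of such clusters.
    """

    frame_index: int
    components: np.ndarray
    overflow: float = 0.0
    charge_tally: dict = field(default_factory=dict)

    def __post_init__(self):
        comp = np.asarray(self.components, dtype=float).reshape(-1)
        object.__setattr__(self, "components", comp)
        if np.any(comp < -1e-15):
            raise IntegrityError("state-vector components must be non-negative")

    @property
    def s_max(self) -> int:
        return self.components.shape[0]

    @property
    def normalization(self) -> float:
        return float(self.components.sum() + self.overflow)


def state_vector(p: ClusterPartition, n_ions: int, s_max: int) -> StateVector:
    """Build the normalised population vector of one partition.

    Raises :class:`IntegrityError` when the partition does not cover exactly
    ``n_ions`` ions.
    """
    if s_max < 1:
        raise ValueError(f"s_max must be >= 1, got {s_max}")
    if p.n_ions != n_ions:
        raise IntegrityError(
            f"partition covers {p.n_ions} ions but n_ions={n_ions}"
        )
    comp = np.zeros(s_max)
    overflow = 0.0
    tally: dict = {}
    for c in p.clusters:
        tally[c.charge_composition] = tally.get(c.charge_composition, 0) + 1
        if c.size <= s_max:
            comp[c.size - 1] += c.size / n_ions
        else:
            overflow += c.size / n_ions
    return StateVector(
        frame_index=p.frame_index, components=comp, overflow=overflow,
        charge_tally=tally,
    )


@dataclass(frozen=True)
class PopulationSummary:
    """Time-averaged populations with per-component maximum errors."""

    mean: np.ndarray
    max_error: np.ndarray
    mean_overflow: float
    max_error_overflow: float
    n_ions: int
    n_frames: int
    n_blocks: int

    @property
    def s_max(self) -> int:
        return self.mean.shape[0]

    @property
    def counts(self) -> np.ndarray:
        """Mean number of ions in each size class: N_ions * i * <n_i>."""
        return self.n_ions * self.mean

    @property
    def counts_max_error(self) -> np.ndarray:
        return self.n_ions * self.max_error

    def to_dict(self) -> dict:
        return {
            "mean": self.mean.tolist(),
            "max_error": self.max_error.tolist(),
            "mean_overflow": self.mean_overflow,
            "max_error_overflow": self.max_error_overflow,
            "n_ions": self.n_ions,
            "n_frames": self.n_frames,
            "n_blocks": self.n_blocks,
            "counts": self.counts.tolist(),
            "counts_max_error": self.counts_max_error.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationSummary":
        return cls(
            mean=np.asarray(d["mean"], float),
            max_error=np.asarray(d["max_error"], float),
            mean_overflow=float(d["mean_overflow"]),
            max_error_overflow=float(d["max_error_overflow"]),
            n_ions=int(d["n_ions"]),
            n_frames=int(d["n_frames"]),
            n_blocks=int(d["n_blocks"]),
        )


def _block_slices(n_frames: int, n_blocks: int) -> list[slice]:
    L = n_frames // n_blocks
    slices = [slice(k * L, (k + 1) * L) for k in range(n_blocks - 1)]
    slices.append(slice((n_blocks - 1) * L, n_frames))  # remainder folds into last
    return slices


def summarize(series, n_blocks: int = 5, *, n_ions: int | None = None) -> PopulationSummary:
    """Average a state-vector time series with block maximum-error bars.

    ``n_ions`` defaults to the value implied by nothing in the vectors
    themselves, so callers that want the ion-count view must pass it; the
    fractional views are always available.
    """
    series = list(series)
    if not series:
        raise ValueError("cannot summarize an empty series")
    if n_blocks < 2:
        raise ValueError(f"n_blocks must be >= 2, got {n_blocks}")
    if len(series) < n_blocks:
        raise ValueError(
            f"need at least n_blocks={n_blocks} frames, got {len(series)}"
        )
    s_max = series[0].s_max
    if any(sv.s_max != s_max for sv in series):
        raise ValueError("state vectors in a series must share S_max")
    X = np.array([sv.components for sv in series])  # (n_frames, s_max)
    ov = np.array([sv.overflow for sv in series])
    mean = X.mean(axis=0)
    mean_ov = float(ov.mean())
    max_err = np.zeros(s_max)
    max_err_ov = 0.0
    for sl in _block_slices(len(series), n_blocks):
        max_err = np.maximum(max_err, np.abs(X[sl].mean(axis=0) - mean))
        max_err_ov = max(max_err_ov, abs(float(ov[sl].mean()) - mean_ov))
    return PopulationSummary(
        mean=mean,
        max_error=max_err,
        mean_overflow=mean_ov,
        max_error_overflow=max_err_ov,
        n_ions=int(n_ions) if n_ions is not None else 0,
        n_frames=len(series),
        n_blocks=n_blocks,
    )


@dataclass(frozen=True)
class PopulationDifference:
    """Componentwise difference a - b with conservative combined uncertainties."""

    delta: np.ndarray  # fraction units
    uncertainty: np.ndarray
    delta_counts: np.ndarray  # ion-count units
    uncertainty_counts: np.ndarray
    significant: np.ndarray  # |delta| > uncertainty, per component
    delta_overflow: float
    uncertainty_overflow: float

    def to_dict(self) -> dict:
        return {
            "delta": self.delta.tolist(),
            "uncertainty": self.uncertainty.tolist(),
            "delta_counts": self.delta_counts.tolist(),
            "uncertainty_counts": self.uncertainty_counts.tolist(),
            "significant": [bool(x) for x in self.significant],
            "delta_overflow": self.delta_overflow,
            "uncertainty_overflow": self.uncertainty_overflow,
        }


def population_difference(a: PopulationSummary, b: PopulationSummary) -> PopulationDifference:
    """Difference of two population summaries (a - b).

    Uncertainties add (consistent with maximum-error semantics); the
    ion-count view requires both summaries to describe systems with the same
    number of ions.
    """
    if a.s_max != b.s_max:
        raise ValueError(f"mismatched S_max: {a.s_max} vs {b.s_max}")
    if a.n_ions != b.n_ions:
        raise ValueError(
            f"mismatched ion counts: {a.n_ions} vs {b.n_ions}; "
            "the count view is only meaningful for equal systems"
        )
    delta = a.mean - b.mean
    unc = a.max_error + b.max_error
    return PopulationDifference(
        delta=delta,
        uncertainty=unc,
        delta_counts=a.n_ions * delta,
        uncertainty_counts=a.n_ions * unc,
        significant=np.abs(delta) > unc,
        delta_overflow=a.mean_overflow - b.mean_overflow,
        uncertainty_overflow=a.max_error_overflow + b.max_error_overflow,
    )
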