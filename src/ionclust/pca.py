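"""Principal component analysis of cluster-population fluctuations.

The covariance of the state-vector components i*n_i over trajectory frames,

    C_ij = (1/N_frames) * sum_k (i n_i,k - <i n_i>) (j n_j,k - <j n_j>),

is diagonalised; the eigenvectors are the principal modes of population
fluctuation (e.g. monomer/dimer exchange) and the eigenvalue fractions say
how much of the total variance each mode carries.

Conventions: vectors are truncated to S_max (default 4) *before* centring
and are not renormalised — larger clusters are treated as negligible, not
redistributed; the divisor is N_frames, not N_frames - 1; each eigenvector's
largest-magnitude component is made positive so reports are reproducible
across linear-algebra backends. When the series has no overflow the
deviation vectors sum to zero, so C annihilates the all-ones vector and one
eigenvalue is exactly zero.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["PCAResult", "ModeReport", "covariance", "decompose", "pca", "mode_report"]


@dataclass(frozen=True)
class PCAResult:
    covariance: np.ndarray  # (S_max, S_max)
    eigenvalues: np.ndarray  # descending
    eigenvectors: np.ndarray  # orthonormal columns, sign-fixed
    variance_fractions: np.ndarray  # eigenvalue / trace (zeros if trace is 0)
    n_frames: int | None = None

    @property
    def s_max(self) -> int:
        return self.covariance.shape[0]

    def to_dict(self) -> dict:
        return {
            "covariance": self.covariance.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "eigenvectors": self.eigenvectors.tolist(),
            "variance_fractions": self.variance_fractions.tolist(),
            "n_frames": self.n_frames,
        }


def covariance(series, s_max: int = 4) -> np.ndarray:
    """Population covariance of the components i*n_i, divisor N_frames.

    Vectors longer than ``s_max`` are truncated first (no renormalisation);
    at least 2 frames are required.
    """
    X = np.array([np.asarray(sv.components, float)[:s_max] for sv in series])
    if X.shape[0] < 2:
        raise ValueError(f"need at least 2 frames, got {X.shape[0]}")
    if X.shape[1] != s_max:
        raise ValueError(
            f"state vectors have only {X.shape[1]} components, need s_max={s_max}"
        )
    Xc = X - X.mean(axis=0)
    return Xc.T @ Xc / X.shape[0]


def decompose(C: np.ndarray, *, n_frames: int | None = None,
              sym_tol: float = 1e-8) -> PCAResult:
    """Symmetric eigen-decomposition with descending eigenvalues and fixed signs."""
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError(f"covariance must be square, got shape {C.shape}")
    if np.max(np.abs(C - C.T)) > sym_tol:
        raise ValueError("covariance matrix is not symmetric within tolerance")
    C = 0.5 * (C + C.T)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    for i in range(evecs.shape[1]):
        j = np.argmax(np.abs(evecs[:, i]))
        if evecs[j, i] < 0:
            evecs[:, i] = -evecs[:, i]
    trace = float(np.trace(C))
    fractions = evals / trace if trace > 0 else np.zeros_like(evals)
    return PCAResult(
        covariance=C,
        eigenvalues=evals,
        eigenvectors=evecs,
        variance_fractions=fractions,
        n_frames=n_frames,
    )


def pca(series, s_max: int = 4) -> PCAResult:
    """Convenience: covariance + decomposition of a state-vector series."""
    series = list(series)
    return decompose(covariance(series, s_max), n_frames=len(series))


@dataclass(frozen=True)
class ModeReport:
    """First k fluctuation modes: signed per-size contributions and summaries."""

    components: np.ndarray  # (k, S_max) signed eigenvector entries
    variance_fractions: np.ndarray  # (k,)
    cumulative_variance: float
    classifications: list[str]

    def to_dict(self) -> dict:
        return {
            "components": self.components.tolist(),
            "variance_fractions": self.variance_fractions.tolist(),
            "cumulative_variance": self.cumulative_variance,
            "classifications": list(self.classifications),
        }


def classify_mode(vector: np.ndarray, rel_tol: float = 0.2) -> str:
    """Describe the sign pattern of a fluctuation mode over cluster sizes.

    Components smaller than ``rel_tol`` times the largest magnitude are
    treated as negligible. Recognises the two canonical patterns — monomer vs
    dimer exchange, and (monomer+dimer) vs (trimer+tetramer) redistribution —
    and falls back to an explicit sign-group description.
    """
    v = np.asarray(vector, dtype=float)
    amax = np.max(np.abs(v))
    if amax == 0:
        return "null mode"
    signs = np.where(np.abs(v) >= rel_tol * amax, np.sign(v), 0.0)
    pos = {int(i) + 1 for i in np.flatnonzero(signs > 0)}
    neg = {int(i) + 1 for i in np.flatnonzero(signs < 0)}
    if (pos, neg) in (({1}, {2}), ({2}, {1})):
        return "monomer-dimer anticorrelation"
    if (pos, neg) in (({1, 2}, {3, 4}), ({3, 4}, {1, 2})):
        return "monomer-dimer vs trimer-tetramer anticorrelation"
    if not neg:
        return f"correlated fluctuation of sizes {sorted(pos)}"
    return f"sizes {sorted(pos)} anticorrelated with sizes {sorted(neg)}"


def mode_report(r: PCAResult, k: int) -> ModeReport:
    """Report the first ``k`` modes of a :class:`PCAResult`."""
    if not 1 <= k <= r.s_max:
        raise ValueError(f"k must be in 1..{r.s_max}, got {k}")
    comps = r.eigenvectors[:, :k].T.copy()
    fracs = r.variance_fractions[:k].copy()
    return ModeReport(
        components=comps,
        variance_fractions=fracs,
        cumulative_variance=float(fracs.sum()),
        classifications=[classify_mode(comps[i]) for i in range(k)],
    )
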