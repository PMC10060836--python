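"""Structural connectivity probabilities from tractography summaries.

Stages, applied in order: voxel-level percentile rule → symmetrization →
zero-inflated Poisson (ZIP) distance-bias fit → distance adjustment →
second-order (one-intermediate) connections.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, special

from .cohort_io import LabeledMatrix, VoxelCountTable
from .errors import ComputationError, DegenerateDataError, ValidationError

log = logging.getLogger(__name__)

ADJUST_MODES = ("median-distance", "zero-distance", "none")
SYMMETRIZE_MODES = ("mean", "max")


# ---------------------------------------------------------------------------
# Probability rule and symmetrization
# ---------------------------------------------------------------------------


def sc_probability(
    counts: VoxelCountTable,
    percentile: float = 90.0,
    *,
    quantile_method: str = "linear",
) -> dict[tuple[str, str], float]:
    """Directed connection probability per ordered ROI pair.

    For pair (i, j): the ``percentile`` of the voxel-level counts in the
    target ROI j, divided by the total number of streamlines leaving the
    source ROI i, clipped to [0, 1]. The default quantile convention is
    linear interpolation between order statistics (type 7).
    """
    if not 0 < percentile <= 100:
        raise ValidationError(f"percentile must be in (0, 100], got {percentile}")
    out: dict[tuple[str, str], float] = {}
    for (i, j), vec in counts.counts.items():
        if vec.size == 0:
            raise ValidationError(f"empty voxel vector for pair ({i}, {j})")
        if i not in counts.total_leaving:
            raise ValidationError(f"total_leaving missing for source ROI {i!r}")
        total = counts.total_leaving[i]
        if total == 0:
            log.warning("total_leaving[%s] = 0; probability set to 0", i)
            out[(i, j)] = 0.0
            continue
        q = float(np.percentile(vec, percentile, method=quantile_method))
        out[(i, j)] = float(min(1.0, max(0.0, q / total)))
    return out


@dataclass
class SCProbMatrix:
    """Symmetric structural-connectivity probabilities with provenance.

    ``provenance`` is 'direct' everywhere until :func:`second_order` marks
    the pairs where an indirect (max-product) path won.
    """

    matrix: LabeledMatrix
    provenance: np.ndarray  # dtype '<U8', entries in {'direct', 'indirect'}

    def __post_init__(self) -> None:
        if self.matrix.kind != "sc_prob":
            raise ValidationError("SCProbMatrix requires kind='sc_prob'")
        if self.provenance.shape != self.matrix.values.shape:
            raise ValidationError("provenance shape mismatch")

    @property
    def labels(self) -> list[str]:
        return self.matrix.labels

    @property
    def values(self) -> np.ndarray:
        return self.matrix.values


def symmetrize(
    directed: Mapping[tuple[str, str], float],
    labels: Sequence[str],
    mode: str = "mean",
) -> SCProbMatrix:
    """Fold directed probabilities into a symmetric matrix; diagonal = 1."""
    if mode not in SYMMETRIZE_MODES:
        raise ValidationError(f"symmetrize mode must be one of {SYMMETRIZE_MODES}")
    labels = list(labels)
    n = len(labels)
    vals = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            i, j = labels[a], labels[b]
            if (i, j) not in directed or (j, i) not in directed:
                raise ValidationError(f"missing reverse pair for ({i}, {j})")
            p, q = directed[(i, j)], directed[(j, i)]
            vals[a, b] = vals[b, a] = (p + q) / 2.0 if mode == "mean" else max(p, q)
    np.fill_diagonal(vals, 1.0)
    m = LabeledMatrix(labels=labels, values=vals, kind="sc_prob")
    return SCProbMatrix(matrix=m, provenance=np.full((n, n), "direct", dtype="<U8"))


# ---------------------------------------------------------------------------
# Zero-inflated Poisson distance model
# ---------------------------------------------------------------------------


@dataclass
class ZipFit:
    """Fitted zero-inflation weight and log-linear Poisson coefficients."""

    alpha0: float
    alpha1: float
    omega: float
    converged: bool
    n_pairs: int
    loglik: float

    def mu(self, g: np.ndarray | float) -> np.ndarray | float:
        return np.exp(self.alpha0 + self.alpha1 * np.asarray(g, dtype=float))

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2)
            fh.write("\n")


def zip_loglik(
    alpha0: float, alpha1: float, omega: float, counts: np.ndarray, distances: np.ndarray
) -> float:
    """Log-likelihood of the ZIP model with log mean alpha0 + alpha1·g.

    P(0) = ω + (1−ω)e^{−μ};  P(k>0) = (1−ω)e^{−μ}μ^k / k!.
    """
    counts = np.asarray(counts, dtype=float)
    g = np.asarray(distances, dtype=float)
    if not 0 <= omega < 1:
        return -np.inf
    eta = alpha0 + alpha1 * g
    mu = np.exp(eta)
    zero = counts == 0
    ll = 0.0
    if zero.any():
        # log(ω + (1−ω)e^{−μ}) computed stably
        with np.errstate(divide="ignore"):
            terms = np.logaddexp(
                np.log(omega) if omega > 0 else -np.inf,
                np.log1p(-omega) - mu[zero],
            )
        ll += float(terms.sum())
    pos = ~zero
    if pos.any():
        k = counts[pos]
        ll += float(
            np.sum(np.log1p(-omega) - mu[pos] + k * eta[pos] - special.gammaln(k + 1))
        )
    return ll


def fit_zip(
    totals: np.ndarray | Sequence[float],
    distances: np.ndarray | Sequence[float],
    *,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> ZipFit:
    """Maximum-likelihood ZIP fit of pair totals against inter-ROI distance.

    Starts from method-of-moments (excess zeros → ω, log-linear fit on
    positive counts → α) and refines with bounded quasi-Newton on
    (α0, α1, logit ω). Non-convergence returns the best iterate with
    ``converged=False`` rather than raising.
    """
    s = np.asarray(totals, dtype=float).ravel()
    g = np.asarray(distances, dtype=float).ravel()
    if s.shape != g.shape:
        raise ValidationError("totals and distances must have equal length")
    if s.size < 6:
        raise ValidationError(f"need at least 6 pairs to fit, got {s.size}")
    if not np.all(np.isfinite(g)) or (g < 0).any():
        raise ValidationError("distances must be finite and non-negative")
    if (s < 0).any() or not np.all(s == np.floor(s)):
        raise ValidationError("totals must be non-negative integers")
    if not s.any():
        raise DegenerateDataError("all pair totals are zero; ZIP fit is degenerate")

    # method-of-moments start
    pos = s > 0
    if pos.sum() >= 2 and np.ptp(g[pos]) > 0:
        b = np.polyfit(g[pos], np.log(s[pos]), 1)
        a0_0, a1_0 = float(b[1]), float(b[0])
    else:
        a0_0, a1_0 = float(np.log(max(s[pos].mean(), 1e-8))), 0.0
    mu0 = np.exp(np.clip(a0_0 + a1_0 * g, -30, 30))
    expected_zero = float(np.mean(np.exp(-mu0)))
    observed_zero = float(np.mean(~pos))
    w0 = (observed_zero - expected_zero) / max(1e-12, 1.0 - expected_zero)
    w0 = float(np.clip(w0, 1e-4, 1 - 1e-4))

    def unpack(x: np.ndarray) -> tuple[float, float, float]:
        return float(x[0]), float(x[1]), float(special.expit(x[2]))

    def nll(x: np.ndarray) -> float:
        a0, a1, w = unpack(x)
        return -zip_loglik(a0, a1, w, s, g)

    x0 = np.array([a0_0, a1_0, special.logit(w0)])
    res = optimize.minimize(
        nll,
        x0,
        method="L-BFGS-B",
        bounds=[(-20, 20), (-2, 2), (-15, 15)],
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-10},
    )
    a0, a1, w = unpack(res.x)
    return ZipFit(
        alpha0=a0,
        alpha1=a1,
        omega=w,
        converged=bool(res.success),
        n_pairs=int(s.size),
        loglik=float(-res.fun),
    )


def fit_zip_from_matrices(
    pair_totals: LabeledMatrix, distances: LabeledMatrix, **kwargs
) -> ZipFit:
    """Fit over all ordered off-diagonal pairs of labeled matrices.

    Pair totals are directed (one observation per ordered pair), so both
    triangles contribute; the distance matrix is symmetric.
    """
    if pair_totals.labels != distances.labels:
        raise ValidationError("pair_totals and distances have different labels")
    off = ~np.eye(len(pair_totals.labels), dtype=bool)
    return fit_zip(pair_totals.values[off], distances.values[off], **kwargs)


# ---------------------------------------------------------------------------
# Distance adjustment and second-order connections
# ---------------------------------------------------------------------------


def distance_adjust(
    pi: SCProbMatrix,
    fit: ZipFit,
    distances: LabeledMatrix,
    *,
    mode: str = "median-distance",
    force: bool = False,
) -> SCProbMatrix:
    """Remove the fitted exponential distance trend from SC probabilities.

    ``median-distance`` rescales each pair by μ̂(g_med)/μ̂(g) — unit factor at
    the cohort-median distance; ``zero-distance`` references g = 0 instead;
    ``none`` is the identity. Values are clipped to [0, 1]; the diagonal is
    untouched.
    """
    if mode not in ADJUST_MODES:
        raise ValidationError(f"adjust mode must be one of {ADJUST_MODES}")
    if mode == "none":
        return pi
    if not fit.converged and not force:
        raise ComputationError(
            "ZIP fit did not converge; pass force=True to adjust anyway"
        )
    if pi.labels != distances.labels:
        raise ValidationError("probability and distance matrices have different labels")
    g = distances.values
    iu = np.triu_indices(len(pi.labels), k=1)
    g_ref = float(np.median(g[iu])) if mode == "median-distance" else 0.0
    factor = np.exp(-fit.alpha1 * (g - g_ref))
    if not np.all(np.isfinite(factor)):
        raise ComputationError("non-finite distance rescale factor")
    vals = np.minimum(1.0, pi.values * factor)
    np.fill_diagonal(vals, np.diag(pi.values))
    m = LabeledMatrix(labels=pi.labels, values=vals, kind="sc_prob")
    return SCProbMatrix(matrix=m, provenance=pi.provenance.copy())


def second_order(pi: SCProbMatrix) -> SCProbMatrix:
    """Incorporate indirect connections through one intermediate region.

    For every pair (i, j), output = max(π_ij, max over m∉{i,j} of
    π_im·π_mj), evaluated entirely on the input matrix (a single pass; no
    propagation beyond second order). Pairs where the product wins are
    flagged 'indirect'.
    """
    p = pi.values
    n = p.shape[0]
    best = np.full((n, n), -np.inf)
    for m in range(n):
        prod = np.outer(p[:, m], p[m, :])
        prod[m, :] = -np.inf  # exclude m == i
        prod[:, m] = -np.inf  # exclude m == j
        best = np.maximum(best, prod)
    out = p.copy()
    prov = pi.provenance.copy()
    off = ~np.eye(n, dtype=bool)
    win = off & (best > p)
    out[win] = best[win]
    prov[win] = "indirect"
    m_out = LabeledMatrix(labels=pi.labels, values=out, kind="sc_prob")
    return SCProbMatrix(matrix=m_out, provenance=prov)


def process_subject_sc(
    counts: VoxelCountTable,
    distances: LabeledMatrix,
    *,
    percentile: float = 90.0,
    symmetrization: str = "mean",
    adjust: str = "median-distance",
    apply_second_order: bool = True,
    zip_fit: ZipFit | None = None,
    force_adjust: bool = True,
) -> tuple[SCProbMatrix, ZipFit | None]:
    """Full SC stage for one subject, in the documented order."""
    directed = sc_probability(counts, percentile=percentile)
    pi = symmetrize(directed, distances.labels, mode=symmetrization)
    fit = zip_fit
    if adjust != "none":
        if fit is None:
            totals = counts.pair_totals_matrix(distances.labels)
            fit = fit_zip_from_matrices(totals, distances)
        pi = distance_adjust(pi, fit, distances, mode=adjust, force=force_adjust)
    if apply_second_order:
        pi = second_order(pi)
    return pi, fit
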