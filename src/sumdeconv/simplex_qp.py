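"""Simplex-constrained least squares for ancestry mixing proportions.

Given a target vector b (the cohort's PC projection, or its raw frequency
vector) and a basis matrix A whose columns represent the K reference
populations in the same space, the mixing proportions solve

    minimize  || b - A @ alpha ||^2   subject to  alpha >= 0,  sum(alpha) = 1.

This is a small convex quadratic program on the probability simplex.  It is
solved exactly by a primal active-set method on the equivalent QP
``minimize 1/2 alpha' Q alpha - c' alpha`` with ``Q = A'A``, ``c = A'b``:
starting from the uniform vector, the equality-constrained subproblem on
the current working set is solved through its KKT system, bound constraints
are added when a step would leave the simplex and released at the most
negative Lagrange multiplier, until all multipliers are non-negative.

:func:`grid_oracle` brute-forces the same problem on a simplex lattice and
serves as an independent correctness reference in the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .pca_projection import ProjectedPoint
from .sumstats_match import SumdeconvError

logger = logging.getLogger("sumdeconv")

#: pre-clipping tolerance on constraint violation
FEASIBILITY_TOL = 1e-10
#: KKT multiplier threshold for optimality
KKT_TOL = 1e-12


@dataclass
class DeconvolutionProblem:
    """Least-squares deconvolution instance: target b, basis A, group names."""

    target: np.ndarray
    basis: np.ndarray
    groups: list[str]

    def __post_init__(self) -> None:
        self.target = np.asarray(self.target, dtype=float)
        self.basis = np.asarray(self.basis, dtype=float)
        if self.target.ndim != 1 or self.basis.ndim != 2:
            raise ValueError("target must be a vector and basis a matrix")
        d, k = self.basis.shape
        if d < 1 or k < 1:
            raise ValueError("problem must have D >= 1 and K >= 1")
        if self.target.shape != (d,):
            raise ValueError(f"target length {self.target.shape[0]} != basis rows {d}")
        if len(self.groups) != k:
            raise ValueError("one group name per basis column required")
        if not (np.all(np.isfinite(self.target)) and np.all(np.isfinite(self.basis))):
            raise SumdeconvError("non-finite entries in deconvolution problem")

    @property
    def n_groups(self) -> int:
        return self.basis.shape[1]


@dataclass
class AncestryProportions:
    """Fitted mixing proportions on the K-simplex with the achieved residual."""

    alpha: np.ndarray
    groups: list[str]
    objective: float
    mode: str

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.alpha.shape != (len(self.groups),):
            raise ValueError("alpha and groups must be parallel")
        if np.any(self.alpha < 0):
            raise ValueError("alpha must be non-negative")
        if abs(self.alpha.sum() - 1.0) > 1e-9:
            raise ValueError("alpha must sum to 1")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.groups, self.alpha.tolist()))


def _objective(problem: DeconvolutionProblem, alpha: np.ndarray) -> float:
    r = problem.target - problem.basis @ alpha
    return float(r @ r)


def _finalize_alpha(alpha: np.ndarray) -> np.ndarray:
    """Clip tiny negatives and renormalize so the sum is exactly 1."""
    if alpha.min() < -FEASIBILITY_TOL:
        raise SumdeconvError(
            f"solver produced infeasible alpha (min {alpha.min():.3e})"
        )
    alpha = np.clip(alpha, 0.0, None)
    return alpha / alpha.sum()


def _collapse_duplicate_columns(basis: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Move mass between exactly-identical basis columns onto the lowest index.

    Duplicated columns (merged-twin populations) make the optimum a face of
    the simplex; any point on it is optimal, and the deterministic
    convention here is the vertex with the lowest group index.
    """
    k = basis.shape[1]
    scale = max(float(np.abs(basis).max()), 1.0)
    taken = np.zeros(k, dtype=bool)
    out = alpha.copy()
    for i in range(k):
        if taken[i]:
            continue
        for j in range(i + 1, k):
            if not taken[j] and np.max(np.abs(basis[:, i] - basis[:, j])) <= 1e-12 * scale:
                out[i] += out[j]
                out[j] = 0.0
                taken[j] = True
    return out


def solve_simplex_ls(problem: DeconvolutionProblem) -> AncestryProportions:
    """Globally minimize ||b - A alpha||^2 over the probability simplex.

    Primal active-set method; exact for this convex QP.  Raises on
    non-finite input or failure to converge within ``100 * K`` iterations.
    """
    a_mat, b = problem.basis, problem.target
    k = problem.n_groups
    q = a_mat.T @ a_mat
    c = a_mat.T @ b

    alpha = np.full(k, 1.0 / k)
    free = np.ones(k, dtype=bool)
    max_iter = 100 * k
    ones = np.ones(k)

    for _ in range(max_iter):
        f_idx = np.flatnonzero(free)
        nf = len(f_idx)
        # KKT system of the equality-constrained subproblem on the free set
        kkt = np.zeros((nf + 1, nf + 1))
        kkt[:nf, :nf] = q[np.ix_(f_idx, f_idx)]
        kkt[:nf, nf] = 1.0
        kkt[nf, :nf] = 1.0
        rhs = np.concatenate([c[f_idx], [1.0]])
        try:
            sol = np.linalg.solve(kkt, rhs)
        except np.linalg.LinAlgError:
            sol = np.linalg.lstsq(kkt, rhs, rcond=None)[0]
        target_f = sol[:nf]
        lam = sol[nf]

        step = target_f - alpha[f_idx]
        if np.min(target_f) >= -FEASIBILITY_TOL:
            # full step feasible: candidate optimum on this working set
            alpha = np.zeros(k)
            alpha[f_idx] = target_f
            grad = q @ alpha - c
            mu = grad - (-lam)  # multipliers of the active bounds
            mu_active = np.where(free, np.inf, mu)
            worst = int(np.argmin(mu_active))
            if mu_active[worst] >= -KKT_TOL:
                alpha = _finalize_alpha(alpha)
                alpha = _collapse_duplicate_columns(a_mat, alpha)
                return AncestryProportions(
                    alpha=alpha,
                    groups=list(problem.groups),
                    objective=_objective(problem, alpha),
                    mode="unspecified",
                )
            free[worst] = True
            continue
        # partial step: find the blocking bound (lowest index on ties)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(step < 0, -alpha[f_idx] / step, np.inf)
        t_max = float(np.min(t))
        block = f_idx[int(np.argmin(t))]
        alpha[f_idx] = alpha[f_idx] + min(t_max, 1.0) * step
        alpha[block] = 0.0
        free[block] = False
        if not free.any():  # numerical safeguard; cannot happen with sum = 1
            free[block] = True

    cond = np.linalg.cond(q)
    raise SumdeconvError(
        f"active-set solver failed to converge in {max_iter} iterations "
        f"(K={k}, cond(A'A)={cond:.3e})"
    )


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------

_lattice_cache: dict[tuple[int, int], np.ndarray] = {}


def _simplex_lattice(k: int, m: int) -> np.ndarray:
    """All length-k integer compositions of m, as an (n_points, k) array."""
    key = (k, m)
    if key in _lattice_cache:
        return _lattice_cache[key]
    if k == 1:
        out = np.array([[m]], dtype=np.int64)
    else:
        parts = []
        for first in range(m + 1):
            rest = _simplex_lattice(k - 1, m - first)
            block = np.empty((len(rest), k), dtype=np.int64)
            block[:, 0] = first
            block[:, 1:] = rest
            parts.append(block)
        out = np.concatenate(parts, axis=0)
    _lattice_cache[key] = out
    return out


def grid_oracle(problem: DeconvolutionProblem, resolution: float) -> AncestryProportions:
    """Exhaustive search on the simplex lattice of the given resolution.

    Evaluates the objective at every point with coordinates that are
    multiples of ``resolution`` summing to 1, and returns the best lattice
    point (first in lexicographic order on ties).  Restricted to K <= 5.
    """
    k = problem.n_groups
    if k > 5:
        raise SumdeconvError(f"grid_oracle is combinatorial; refusing K={k} > 5")
    m = int(round(1.0 / resolution))
    lattice = _simplex_lattice(k, m)
    alphas = lattice.astype(float) / m
    best_obj = np.inf
    best_idx = 0
    block = 200_000
    at = problem.basis.T
    for start in range(0, len(alphas), block):
        chunk = alphas[start : start + block]
        resid = chunk @ at - problem.target
        obj = np.einsum("ij,ij->i", resid, resid)
        i = int(np.argmin(obj))
        if obj[i] < best_obj:
            best_obj = float(obj[i])
            best_idx = start + i
    alpha = _finalize_alpha(alphas[best_idx])
    return AncestryProportions(
        alpha=alpha,
        groups=list(problem.groups),
        objective=_objective(problem, alpha),
        mode="unspecified",
    )


# ---------------------------------------------------------------------------
# problem construction
# ---------------------------------------------------------------------------

def build_problem_pc(
    cohort: ProjectedPoint,
    panel_points: np.ndarray,
    groups: Sequence[str],
) -> DeconvolutionProblem:
    """Assemble the PC-space problem: b = cohort projection, A = L x K panel points."""
    basis = np.asarray(panel_points, dtype=float)
    if basis.ndim != 2:
        raise SumdeconvError("panel_points must be an L x K matrix")
    if len(cohort.coords) == 0:
        raise SumdeconvError("empty PC coordinate list")
    if basis.shape[0] != len(cohort.coords):
        raise SumdeconvError(
            f"cohort has {len(cohort.coords)} PCs but panel points have {basis.shape[0]}"
        )
    _warn_collinear(basis, list(groups))
    return DeconvolutionProblem(target=cohort.coords, basis=basis, groups=list(groups))


def build_problem_freq(
    cohort_freq: np.ndarray,
    panel_freqs: np.ndarray,
    groups: Sequence[str],
) -> DeconvolutionProblem:
    """Assemble the frequency-space (Summix-style) problem: b = f0, A = M x K panel."""
    basis = np.asarray(panel_freqs, dtype=float)
    target = np.asarray(cohort_freq, dtype=float)
    if basis.ndim != 2 or basis.shape[0] != target.shape[0]:
        raise SumdeconvError("cohort frequencies and panel matrix must share variant rows")
    _warn_collinear(basis, list(groups))
    return DeconvolutionProblem(target=target, basis=basis, groups=list(groups))


def _warn_collinear(basis: np.ndarray, groups: list[str]) -> None:
    scale = max(float(np.abs(basis).max()), 1.0)
    k = basis.shape[1]
    for i in range(k):
        for j in range(i + 1, k):
            if np.max(np.abs(basis[:, i] - basis[:, j])) <= 1e-12 * scale:
                logger.warning(
                    "collinear basis: groups %r and %r have identical representations",
                    groups[i],
                    groups[j],
                )
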