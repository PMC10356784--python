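"""Inverse differential-Jacobian inference from two conditions' covariances.

Given covariance matrices ``Ch`` and ``Cd`` measured under two conditions
("h"/healthy and "d"/disease), and the Jacobian sparsity structure from
network reduction, the scan ranks each admissible Jacobian position by
how well the hypothesis "only this entry differs between the two
conditions" explains the data.  For a candidate position the two
vectorized Lyapunov systems are stacked into one combined system that
shares every Jacobian entry except the candidate, which is split into an
h-copy and a d-copy.  Positions that truly changed leave a small
least-squares residual; the residual — not the solution — is the ranking
statistic, because the residual of a least-squares fit is insensitive to
the conditioning of the system matrix while the solution is not.

The unknown fluctuation matrices are handled by sampling diagonal
matrices with entries uniform on (0, 1) — one matrix per sample, shared
between the two conditions — and taking, per position, the minimum
relative loss over samples.  The per-sample loss is normalized by the
residual of the fully shared (no-split) system, so it measures the
fraction of the between-condition misfit that the candidate split fails
to explain; this normalization is scale-free and removes the bias that
raw right-hand-side norms introduce between samples.

An L-p optimization baseline (the older approach in this line of work)
is provided for comparison: it optimizes the fluctuation diagonals so
that the implied differential Jacobian is as close to all-ones as an
L-p (p < 1, sparsity-promoting) cost can make it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from .lyapunov import (
    CovarianceMatrix,
    Jacobian,
    LyapunovSystem,
    build_b,
    regression_solve,
    vectorize,
)

__all__ = [
    "DifferentialJacobian",
    "RelevanceMatrix",
    "CombinedSystem",
    "differential_jacobian",
    "build_combined_system",
    "DifferentialJacobianScanner",
    "regression_loss_scan",
    "LpDifferentialJacobian",
    "lp_optimize",
    "rank_components",
]


@dataclass
class DifferentialJacobian:
    """Elementwise ratio Jd/Jh with DJ = 1 wherever Jh is zero."""

    values: np.ndarray

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class RelevanceMatrix:
    """Per-position minimum relative regression loss and its min-max inversion.

    ``raw_loss`` holds the minimum (over fluctuation samples) relative
    residual for each masked position; small loss means the
    single-difference hypothesis at that position fits well.
    ``relevance`` inverts and rescales the loss to [0, 1] so that large
    means relevant; it is 0 outside the mask and identically 0 when all
    losses coincide.
    """

    raw_loss: np.ndarray
    relevance: np.ndarray
    mask: np.ndarray
    labels: list[str]
    n_samples: int
    seed: int | None


@dataclass
class CombinedSystem:
    """Stacked two-condition system in which one position is split.

    Columns 0..L-2 are shared between conditions (in index-map order with
    the split position removed); the last two columns are the h-copy and
    d-copy of the split position.
    """

    Ac: np.ndarray
    split_position: tuple[int, int]
    column_map: list[tuple[int, int] | str]


def differential_jacobian(Jh: Jacobian | np.ndarray, Jd: Jacobian | np.ndarray) -> DifferentialJacobian:
    """DJ(i,j) = Jd(i,j) / Jh(i,j), with DJ(i,j) = 1 where Jh(i,j) = 0."""
    Jhv = Jh.values if isinstance(Jh, Jacobian) else np.asarray(Jh, dtype=float)
    Jdv = Jd.values if isinstance(Jd, Jacobian) else np.asarray(Jd, dtype=float)
    if Jhv.shape != Jdv.shape:
        raise ValueError(f"shape mismatch: {Jhv.shape} vs {Jdv.shape}")
    out = np.ones_like(Jhv)
    nz = Jhv != 0.0
    out[nz] = Jdv[nz] / Jhv[nz]
    return DifferentialJacobian(values=out)


def build_combined_system(Ah: LyapunovSystem, Ad: LyapunovSystem,
                          position: tuple[int, int]) -> CombinedSystem:
    """Stack Ah over Ad, splitting one Jacobian position into two columns."""
    if Ah.index_map != Ad.index_map:
        raise ValueError("the two systems index different Jacobian positions")
    position = tuple(position)
    if position not in Ah.index_map:
        raise ValueError(f"position {position} not in the Jacobian mask")
    k = Ah.index_map.index(position)
    m = Ah.m
    shared = [c for c in range(Ah.L) if c != k]
    Ac = np.zeros((2 * m, len(shared) + 2))
    Ac[:m, : len(shared)] = Ah.A[:, shared]
    Ac[m:, : len(shared)] = Ad.A[:, shared]
    Ac[:m, -2] = Ah.A[:, k]
    Ac[m:, -1] = Ad.A[:, k]
    column_map: list = [Ah.index_map[c] for c in shared] + ["h_split", "d_split"]
    return CombinedSystem(Ac=Ac, split_position=position, column_map=column_map)


def _sample_b_matrix(n: int, n_samples: int, rng: np.random.Generator) -> np.ndarray:
    """Stacked right-hand sides for sampled diagonal fluctuation matrices.

    Column s is [b(D_s); b(D_s)] with one diagonal D_s ~ U(0, 1)^n shared
    between the two conditions.  Sharing keeps the identical-conditions
    case exactly symmetric (every split position then attains the same
    loss) and concentrates the sampling on the subspace where the
    between-condition signal lives.
    """
    m = n * (n + 1) // 2
    B = np.zeros((2 * m, n_samples))
    # vech rows with i == j sit at offsets 0, n, n + (n-1), ...
    diag_rows = np.concatenate([[0], np.cumsum(np.arange(n, 1, -1))]).astype(int)
    for s in range(n_samples):
        d = rng.uniform(0.0, 1.0, size=n)
        B[diag_rows, s] = -2.0 * d
        B[m + diag_rows, s] = -2.0 * d
    return B


class DifferentialJacobianScanner(BaseEstimator):
    """Regression-loss scan over Jacobian positions (sklearn-style estimator).

    Parameters
    ----------
    structure : JacobianStructure
        Sparsity pattern (boolean mask plus labels) of the Jacobian.
    n_samples : int, default 100
        Number of sampled fluctuation-matrix pairs; around 100 suffices
        for networks of roughly ten variables.
    random_state : int or numpy Generator, optional
        Seed for the fluctuation sampling; fixed seeds are bitwise
        reproducible.

    Attributes
    ----------
    raw_loss_ : (n, n) ndarray — minimum relative loss per masked position.
    relevance_ : (n, n) ndarray — min-max-inverted loss in [0, 1].
    result_ : RelevanceMatrix with both matrices and run metadata.
    """

    def __init__(self, structure=None, n_samples: int = 100, random_state=None):
        self.structure = structure
        self.n_samples = n_samples
        self.random_state = random_state

    def fit(self, cov_h: CovarianceMatrix | np.ndarray, cov_d: CovarianceMatrix | np.ndarray):
        if self.structure is None:
            raise ValueError("a JacobianStructure is required")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        mask = np.asarray(self.structure.mask, dtype=bool)
        n = mask.shape[0]
        if not mask.any():
            raise ValueError("structure has no admissible Jacobian positions")
        labels = list(getattr(self.structure, "labels", [])) or [f"x{i}" for i in range(n)]

        Ch = cov_h if isinstance(cov_h, CovarianceMatrix) else CovarianceMatrix(np.asarray(cov_h, float))
        Cd = cov_d if isinstance(cov_d, CovarianceMatrix) else CovarianceMatrix(np.asarray(cov_d, float))
        if Ch.n != n or Cd.n != n:
            raise ValueError("covariance size does not match structure")

        Ah = vectorize(Ch, self.structure)
        Ad = vectorize(Cd, self.structure)
        m, L = Ah.m, Ah.L
        if m < L:
            warnings.warn(
                f"underdetermined scan: {L} free Jacobian entries but only {m} "
                "independent covariance constraints", stacklevel=2)

        seed = self.random_state
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        B = _sample_b_matrix(n, self.n_samples, rng)          # (2m, S), shared across positions

        # Every split system shares the column space V of the fully shared
        # (no-split) stacked system [Ah; Ad]; splitting position p adds the
        # single direction u_p = component of [Ah_p; 0] orthogonal to V.
        # Hence resid_p(b)^2 = ||P_V^perp b||^2 - <P_V^perp b, u_p>^2, which
        # turns the scan into one SVD plus one projection per position.
        A0 = np.vstack([Ah.A, Ad.A])
        U, s, _ = sla.svd(A0, full_matrices=False)
        rank = int(np.sum(s > max(A0.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)))
        U = U[:, :rank]
        W = B - U @ (U.T @ B)                                 # unexplained misfit per sample
        wnorm2 = np.sum(W * W, axis=0)
        base = np.sqrt(wnorm2)
        degenerate = base <= 1e-12 * np.linalg.norm(B, axis=0)

        raw = np.full((n, n), np.nan)
        for k, pos in enumerate(Ah.index_map):
            col = np.concatenate([Ah.A[:, k], np.zeros(m)])
            u = col - U @ (U.T @ col)
            nu = np.linalg.norm(u)
            if nu <= 1e-12 * max(np.linalg.norm(col), 1.0):
                raw[pos] = 1.0                                # split adds no freedom
                continue
            proj = (u / nu) @ W
            resid = np.sqrt(np.maximum(wnorm2 - proj ** 2, 0.0))
            # relative loss: fraction of the no-split misfit the single
            # split cannot explain (scale-free, comparable across samples)
            rel = np.where(degenerate, 1.0, resid / np.where(degenerate, 1.0, base))
            raw[pos] = float(rel.min())

        losses = raw[mask]
        lo, hi = losses.min(), losses.max()
        relevance = np.zeros((n, n))
        # all-equal losses (e.g. identical conditions) carry no signal; the
        # tolerance absorbs float noise between algebraically equal losses
        if hi - lo > 1e-9 * max(hi, 1e-300):
            relevance[mask] = (hi - raw[mask]) / (hi - lo)
        raw_out = np.where(mask, raw, 0.0)

        self.raw_loss_ = raw_out
        self.relevance_ = relevance
        self.labels_ = labels
        self.result_ = RelevanceMatrix(
            raw_loss=raw_out, relevance=relevance, mask=mask, labels=labels,
            n_samples=self.n_samples,
            seed=seed if isinstance(seed, (int, np.integer)) else None,
        )
        return self


def regression_loss_scan(Ch, Cd, structure, n_samples: int = 100, seed=None) -> RelevanceMatrix:
    """Functional wrapper over :class:`DifferentialJacobianScanner`."""
    scanner = DifferentialJacobianScanner(structure=structure, n_samples=n_samples,
                                          random_state=seed)
    return scanner.fit(Ch, Cd).result_


class LpDifferentialJacobian(BaseEstimator):
    """L-p fluctuation-matrix optimization baseline.

    Optimizes the diagonal entries of Dh and Dd (plus bounded
    off-diagonals in the diagonal-dominant variant) so that the
    differential Jacobian implied by the per-condition least-squares
    solutions is as close to all-ones as possible under the
    sparsity-promoting cost sum |DJ - 1|^p.

    Attributes
    ----------
    dj_ : DifferentialJacobian estimate at the best optimum found.
    objective_ : float — best L-p cost.
    converged_ : bool — False when no restart converged (best values kept).
    """

    def __init__(self, structure=None, p: float = 0.5, restarts: int = 20,
                 random_state=None, d_form: str = "diagonal",
                 consistency_weight: float = 100.0):
        self.structure = structure
        self.p = p
        self.restarts = restarts
        self.random_state = random_state
        self.d_form = d_form
        self.consistency_weight = consistency_weight

    def _dj_from_x(self, x, Ah, Ad, mask, tri):
        return self._evaluate(x, Ah, Ad, mask, tri)[0]

    def _evaluate(self, x, Ah, Ad, mask, tri):
        n = mask.shape[0]
        if self.d_form == "diagonal":
            Dh = np.diag(x[:n])
            Dd = np.diag(x[n:])
        else:
            k = n + tri.shape[0] if tri.size else n
            Dh = self._dd_matrix(x[:k], n, tri)
            Dd = self._dd_matrix(x[k:], n, tri)
        rh = regression_solve(Ah.A, build_b(Dh))
        rd = regression_solve(Ad.A, build_b(Dd))
        Jh = np.zeros((n, n))
        Jd = np.zeros((n, n))
        for k_, (i, j) in enumerate(Ah.index_map):
            Jh[i, j] = rh.q_star[k_]
            Jd[i, j] = rd.q_star[k_]
        misfit = rh.relative_residual + rd.relative_residual
        return differential_jacobian(Jh, Jd), misfit

    def _objective(self, x, Ah, Ad, mask, tri):
        """L-p sparsity cost plus a consistency penalty.

        The fitted Jacobians are only meaningful for fluctuation matrices
        under which the per-condition Lyapunov systems are (near-)
        consistent — the classical methods assume the linear systems are
        solved, not merely fitted.  The penalty keeps the search on that
        manifold; without it the unconstrained minimum exploits
        ill-fitting D values whose least-squares Jacobians are arbitrary.
        """
        dj, misfit = self._evaluate(x, Ah, Ad, mask, tri)
        dev = np.abs(dj.values[mask] - 1.0)
        return float(np.sum(dev ** self.p) + self.consistency_weight * misfit)

    @staticmethod
    def _dd_matrix(x, n, tri):
        # diagonal entries first, then scaled off-diagonal factors in (-1, 1);
        # off-diagonal (i, j) bounded by half the geometric mean of the diagonals
        D = np.diag(x[:n])
        for t, (i, j) in enumerate(tri):
            bound = 0.5 * np.sqrt(max(x[i], 0.0) * max(x[j], 0.0))
            D[i, j] = D[j, i] = x[n + t] * bound
        return D

    def fit(self, cov_h, cov_d):
        if self.structure is None:
            raise ValueError("a JacobianStructure is required")
        if not (0 < self.p <= 2):
            raise ValueError("p must lie in (0, 2]")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        if self.d_form not in ("diagonal", "diagonal_dominant"):
            raise ValueError(f"unknown d_form {self.d_form!r}")
        mask = np.asarray(self.structure.mask, dtype=bool)
        n = mask.shape[0]
        Ch = cov_h if isinstance(cov_h, CovarianceMatrix) else CovarianceMatrix(np.asarray(cov_h, float))
        Cd = cov_d if isinstance(cov_d, CovarianceMatrix) else CovarianceMatrix(np.asarray(cov_d, float))
        Ah = vectorize(Ch, self.structure)
        Ad = vectorize(Cd, self.structure)

        tri = np.array([(i, j) for i in range(n) for j in range(i + 1, n)], dtype=int)
        if self.d_form == "diagonal":
            dim = 2 * n
            bounds = [(1e-6, 1.0)] * dim
        else:
            per = n + tri.shape[0]
            dim = 2 * per
            bounds = ([(1e-6, 1.0)] * n + [(-1.0, 1.0)] * tri.shape[0]) * 2

        def objective(x):
            return self._objective(x, Ah, Ad, mask, tri)

        rng = (self.random_state if isinstance(self.random_state, np.random.Generator)
               else np.random.default_rng(self.random_state))
        best_x, best_f, any_ok = None, np.inf, False
        for _ in range(self.restarts):
            x0 = np.array([rng.uniform(lo if np.isfinite(lo) else -1, hi) for lo, hi in bounds])
            f0 = objective(x0)
            res = minimize(objective, x0, method="Powell", bounds=bounds,
                           options={"maxiter": 5000, "xtol": 1e-8, "ftol": 1e-10})
            fbest = min(res.fun, f0)           # descent: never worse than the start
            xbest = res.x if res.fun <= f0 else x0
            any_ok = any_ok or res.success
            if fbest < best_f:
                best_f, best_x = fbest, xbest
        if not any_ok:
            warnings.warn("L-p optimizer failed to converge on every restart; "
                          "returning best values found", stacklevel=2)
        dj, misfit = self._evaluate(best_x, Ah, Ad, mask, tri)
        self.dj_ = dj
        self.objective_ = best_f
        self.sparsity_cost_ = float(np.sum(np.abs(dj.values[mask] - 1.0) ** self.p))
        self.misfit_ = misfit
        self.converged_ = any_ok
        return self


def lp_optimize(Ch, Cd, structure, p: float = 0.5, restarts: int = 20,
                seed=None, d_form: str = "diagonal") -> tuple[DifferentialJacobian, float]:
    """Functional wrapper over :class:`LpDifferentialJacobian`."""
    est = LpDifferentialJacobian(structure=structure, p=p, restarts=restarts,
                                 random_state=seed, d_form=d_form).fit(Ch, Cd)
    return est.dj_, est.objective_


def rank_components(R: RelevanceMatrix, k: int) -> list[tuple[int, int]]:
    """Top-k masked positions by relevance; ties broken by (row, column)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    positions = [(i, j) for i, j in np.argwhere(R.mask)]
    if k > len(positions):
        warnings.warn(f"k={k} exceeds the {len(positions)} masked positions; truncating",
                      stacklevel=2)
        k = len(positions)
    positions.sort(key=lambda p: (-R.relevance[p[0], p[1]], p[0], p[1]))
    return [tuple(p) for p in positions[:k]]
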