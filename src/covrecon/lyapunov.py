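"""Lyapunov-equation machinery linking Jacobian, covariance and fluctuation matrices.

Near a stable steady state, the concentration covariance ``C`` of a
stochastically perturbed network with Jacobian ``J`` and noise covariance
``D`` obeys the continuous Lyapunov equation

    J C + C J^T = -2 D.

Because both sides are symmetric, the equation carries ``m = n(n+1)/2``
independent scalar constraints.  When the Jacobian sparsity pattern leaves
``L <= m`` free entries, stacking the upper triangle turns the equation
into an overdetermined linear system ``A q = b`` in the free Jacobian
entries ``q``; this module builds that system and solves it by stable
least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla

__all__ = [
    "Jacobian",
    "CovarianceMatrix",
    "FluctuationMatrix",
    "LyapunovSystem",
    "RegressionResult",
    "solve_forward_lyapunov",
    "vectorize",
    "build_b",
    "regression_solve",
    "condition_diagnostics",
    "read_covariance_csv",
    "write_covariance_csv",
]

_SYM_TOL = 1e-10
_PSD_TOL = 1e-8


@dataclass
class Jacobian:
    """Dense Jacobian with an optional sparsity structure.

    When a structure is attached, entries outside its mask must be exactly
    zero; ``__post_init__`` enforces this.
    """

    values: np.ndarray
    structure: "object | None" = None  # JacobianStructure, avoided circular import

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("Jacobian must be square")
        if self.structure is not None:
            mask = np.asarray(self.structure.mask, dtype=bool)
            if mask.shape != self.values.shape:
                raise ValueError("structure mask shape does not match values")
            if np.any(self.values[~mask] != 0.0):
                raise ValueError("nonzero Jacobian entries outside structure mask")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def is_stable(self) -> bool:
        return bool(np.max(np.linalg.eigvals(self.values).real) < 0)


@dataclass
class CovarianceMatrix:
    """Symmetric PSD covariance with metabolite labels."""

    values: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.ndim != 2 or self.values.shape[1] != n:
            raise ValueError("covariance must be square")
        if not self.labels:
            self.labels = [f"x{i}" for i in range(n)]
        if len(self.labels) != n:
            raise ValueError("label count does not match matrix size")
        scale = max(np.abs(self.values).max(), 1.0)
        if np.abs(self.values - self.values.T).max() > _SYM_TOL * scale:
            raise ValueError("covariance matrix is not symmetric")
        self.values = 0.5 * (self.values + self.values.T)
        tr = np.trace(self.values)
        lam_min = np.linalg.eigvalsh(self.values)[0]
        if lam_min < -_PSD_TOL * max(tr, 1.0):
            raise ValueError(f"covariance not PSD (min eigenvalue {lam_min:g})")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class FluctuationMatrix:
    """Noise-source covariance D; diagonal in all classical treatments."""

    values: np.ndarray
    diagonal_only: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = np.diag(self.values)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("fluctuation matrix must be square")
        if self.diagonal_only and np.any(self.values - np.diag(np.diag(self.values))):
            raise ValueError("off-diagonal entries present in diagonal-only D")
        lam_min = np.linalg.eigvalsh(0.5 * (self.values + self.values.T))[0]
        if lam_min < -_PSD_TOL * max(np.trace(self.values), 1.0):
            raise ValueError("fluctuation matrix not PSD")

    @property
    def n(self) -> int:
        return self.values.shape[0]


def vech_rows(n: int) -> list[tuple[int, int]]:
    """Row order of the stacked system: (i, j) with i <= j, row-major.

    Single source of truth for every module that touches ``A`` or ``b``.
    """
    return [(i, j) for i in range(n) for j in range(i, n)]


def mask_positions(mask: np.ndarray) -> list[tuple[int, int]]:
    """Column order of q: row-major scan of the boolean mask."""
    mask = np.asarray(mask, dtype=bool)
    return [(i, j) for i in range(mask.shape[0]) for j in range(mask.shape[1]) if mask[i, j]]


@dataclass
class LyapunovSystem:
    """Vectorized Lyapunov constraints ``A q = b`` for a masked Jacobian."""

    A: np.ndarray
    index_map: list[tuple[int, int]]  # column k -> Jacobian position (i, j)
    row_map: list[tuple[int, int]]    # row -> unordered pair (i, j), i <= j

    @property
    def m(self) -> int:
        return self.A.shape[0]

    @property
    def L(self) -> int:
        return self.A.shape[1]

    def q_of(self, J: np.ndarray) -> np.ndarray:
        J = np.asarray(J, dtype=float)
        return np.array([J[i, j] for i, j in self.index_map])


@dataclass
class RegressionResult:
    q_star: np.ndarray
    residual_norm: float
    relative_residual: float


def solve_forward_lyapunov(J: Jacobian | np.ndarray, D: FluctuationMatrix | np.ndarray,
                           labels: list[str] | None = None) -> CovarianceMatrix:
    """Solve J C + C J^T = -2 D for the stationary covariance C.

    Raises if J is not Hurwitz-stable, since no stationary covariance
    exists then.  The result is symmetrized and checked against the
    residual bound ||J C + C J^T + 2 D||_F <= 1e-8 ||D||_F.
    """
    Jv = J.values if isinstance(J, Jacobian) else np.asarray(J, dtype=float)
    Dv = D.values if isinstance(D, FluctuationMatrix) else np.asarray(D, dtype=float)
    if Dv.ndim == 1:
        Dv = np.diag(Dv)
    max_re = float(np.max(np.linalg.eigvals(Jv).real))
    if max_re >= 0:
        raise ValueError(f"Jacobian is not Hurwitz-stable (max eigenvalue real part {max_re:g})")
    C = sla.solve_continuous_lyapunov(Jv, -2.0 * Dv)
    C = 0.5 * (C + C.T)
    resid = np.linalg.norm(Jv @ C + C @ Jv.T + 2.0 * Dv, "fro")
    dnorm = np.linalg.norm(Dv, "fro")
    if dnorm > 0 and resid > 1e-8 * dnorm:
        raise ArithmeticError(f"Lyapunov residual {resid:g} exceeds tolerance")
    return CovarianceMatrix(C, labels=list(labels) if labels else [])


def vectorize(C: CovarianceMatrix | np.ndarray, structure) -> LyapunovSystem:
    """Build the m x L coefficient matrix of the vectorized Lyapunov equation.

    Row (i, j) (i <= j) of ``A`` collects the coefficient of each free
    Jacobian entry J(a, b) in (J C + C J^T)(i, j):

        coeff = [i == a] * C(b, j) + [j == a] * C(i, b).
    """
    Cv = C.values if isinstance(C, CovarianceMatrix) else np.asarray(C, dtype=float)
    mask = np.asarray(structure.mask, dtype=bool)
    n = mask.shape[0]
    if Cv.shape != (n, n):
        raise ValueError(f"covariance is {Cv.shape} but structure is {mask.shape}")
    rows = vech_rows(n)
    cols = mask_positions(mask)
    ri = np.array([r[0] for r in rows])[:, None]
    rj = np.array([r[1] for r in rows])[:, None]
    ca = np.array([c[0] for c in cols])[None, :]
    cb = np.array([c[1] for c in cols])[None, :]
    A = (ri == ca) * Cv[cb, rj] + (rj == ca) * Cv[ri, cb]
    return LyapunovSystem(A=np.ascontiguousarray(A, dtype=float), index_map=cols, row_map=rows)


def build_b(D: FluctuationMatrix | np.ndarray) -> np.ndarray:
    """Right-hand side b(row (i,j)) = -2 D(i,j), in vech row order."""
    Dv = D.values if isinstance(D, FluctuationMatrix) else np.asarray(D, dtype=float)
    if Dv.ndim == 1:
        Dv = np.diag(Dv)
    n = Dv.shape[0]
    return np.array([-2.0 * Dv[i, j] for i, j in vech_rows(n)])


def regression_solve(A: np.ndarray, b: np.ndarray) -> RegressionResult:
    """Minimum-norm least squares by SVD (LAPACK gelsd), never normal equations.

    The textbook closed form (A^T A)^{-1} A^T b defines the same minimizer
    on full-rank problems but squares the condition number; the SVD route
    is the numerically faithful implementation of that definition.
    """
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float).ravel()
    if A.ndim != 2 or A.shape[1] < 1:
        raise ValueError("A must be 2-D with at least one column")
    if not (np.all(np.isfinite(A)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite entries in regression inputs")
    q, *_ = sla.lstsq(A, b, lapack_driver="gelsd")
    r = b - A @ q
    rnorm = float(np.linalg.norm(r))
    bnorm = float(np.linalg.norm(b))
    return RegressionResult(q_star=q, residual_norm=rnorm,
                            relative_residual=rnorm / bnorm if bnorm > 0 else 0.0)


def condition_diagnostics(A: np.ndarray) -> dict:
    """2-norm condition number and numerical rank of the system matrix."""
    A = np.asarray(A, dtype=float)
    if not np.all(np.isfinite(A)):
        raise ValueError("non-finite entries in A")
    s = sla.svdvals(A)
    smax = s[0] if s.size else 0.0
    tol = max(A.shape) * np.finfo(float).eps * smax
    rank = int(np.sum(s > tol))
    smin = s[-1] if s.size else 0.0
    cond = float(smax / smin) if smin > tol else np.inf
    return {"condition_number": cond, "rank": rank}


def read_covariance_csv(path) -> CovarianceMatrix:
    """Labeled square CSV (header row and index column are the labels)."""
    import pandas as pd

    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError("covariance CSV row and column labels differ")
    return CovarianceMatrix(df.to_numpy(dtype=float), labels=[str(c) for c in df.columns])


def write_covariance_csv(C: CovarianceMatrix, path) -> None:
    import pandas as pd

    pd.DataFrame(C.values, index=C.labels, columns=C.labels).to_csv(path)
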