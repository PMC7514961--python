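"""Twin support vector machine (TWSVM) with Gaussian kernel.

Unlike a standard SVM, which separates two classes with a single maximum-
margin hyperplane, a TWSVM fits *two nonparallel* hyperplanes in the
kernel-expanded space,

    K(x, C')u1 + b1 = 0   and   K(x, C')u2 + b2 = 0,

where C stacks all m training samples. Each plane is pulled close to its
own class and pushed at least unit distance from the other, by one convex
quadratic program per plane:

    (plane 1, close to the positive class A, far from B)
        min_{u1,b1,zeta}  1/2 ||K(A,C')u1 + e1 b1||^2 + c1 e2' zeta
        s.t.  -(K(B,C')u1 + e2 b1) + zeta >= e2,  zeta >= 0

    (plane 2, symmetric with A and B exchanged and the inequality reversed)

Each QP involves only one class in its constraints, so the two problems are
roughly a quarter the size of the single SVM QP. A new point is assigned to
the class whose plane is nearer in perpendicular (kernel-metric) distance.

The QPs are solved through their duals. With H = [K(A,C') e1] and
G = [K(B,C') e2], the dual of the first problem is the box-constrained QP

    max_alpha  e2' alpha - 1/2 alpha' G (H'H + eps I)^{-1} G' alpha,
    0 <= alpha <= c1,

with primal recovery [u1; b1] = -(H'H + eps I)^{-1} G' alpha; the second
plane is symmetric (recovery with a plus sign). The Tikhonov ridge eps
keeps the normal-equations matrix invertible (H'H is rank-deficient
whenever m1 + 1 < m). The box QP is solved by projected L-BFGS-B followed
by an exact Newton polish on the free (strictly interior) coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import joblib
import numpy as np
from scipy.optimize import minimize

SERIAL_VERSION = 1


@dataclass(frozen=True)
class TrainingSet:
    """Feature matrix with +1/-1 labels (+1 = abnormal, the positive class)."""

    X: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be m x n with one label per row")
        if not np.all(np.isfinite(X)):
            raise ValueError("X must be finite")
        if not set(np.unique(y)) <= {-1, 1}:
            raise ValueError("labels must be in {+1, -1}")
        if not ((y == 1).any() and (y == -1).any()):
            raise ValueError("both classes must be non-empty")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y.astype(int))

    @property
    def A(self) -> np.ndarray:
        """Positive-class (abnormal) rows."""
        return self.X[self.y == 1]

    @property
    def B(self) -> np.ndarray:
        """Negative-class (normal) rows."""
        return self.X[self.y == -1]

    @property
    def C(self) -> np.ndarray:
        """All training rows."""
        return self.X


@dataclass(frozen=True)
class SlackDuals:
    """Slack variables and dual multipliers of the two QPs, for diagnostics."""

    zeta: np.ndarray   # plane-1 slacks (one per negative sample)
    eta: np.ndarray    # plane-2 slacks (one per positive sample)
    alpha: np.ndarray  # plane-1 duals, 0 <= alpha <= c1
    gamma: np.ndarray  # plane-2 duals, 0 <= gamma <= c2


def gaussian_kernel(X: np.ndarray, Y: np.ndarray, sigma: float) -> np.ndarray:
    """RBF Gram matrix K[i, j] = exp(-||x_i - y_j||^2 / (2 sigma^2))."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[1] != Y.shape[1]:
        raise ValueError("X and Y must have the same number of columns")
    sq = (
        np.sum(X * X, axis=1)[:, None]
        + np.sum(Y * Y, axis=1)[None, :]
        - 2.0 * X @ Y.T
    )
    np.maximum(sq, 0.0, out=sq)
    return np.exp(-sq / (2.0 * sigma**2))


def _solve_box_qp(Q: np.ndarray, c: float, tol: float = 1e-12) -> np.ndarray:
    """Minimize 1/2 a'Qa - e'a subject to 0 <= a <= c (Q PSD).

    Projected L-BFGS-B for the bulk of the work, then an active-set polish:
    coordinates strictly inside the box are re-solved exactly from the KKT
    linear system, which removes the first-order solver's residual error.
    """
    m = Q.shape[0]
    e = np.ones(m)

    def fun(a):
        Qa = Q @ a
        return 0.5 * a @ Qa - a.sum(), Qa - e

    res = minimize(
        fun,
        x0=np.zeros(m),
        jac=True,
        method="L-BFGS-B",
        bounds=[(0.0, c)] * m,
        options={"maxiter": 2000, "ftol": 1e-16, "gtol": 1e-12},
    )
    if res.success or res.status == 1:
        a = np.clip(res.x, 0.0, c)
    else:
        # ill-conditioned Q can defeat L-BFGS-B's line search; fall back to
        # accelerated projected gradient with a spectral step, which only
        # needs matrix-vector products and cannot diverge
        lip = float(np.linalg.norm(Q, 2)) + 1e-12
        a = np.clip(np.zeros(m), 0.0, c)
        z, t_mom = a.copy(), 1.0
        for _ in range(5000):
            g = Q @ z - e
            a_new = np.clip(z - g / lip, 0.0, c)
            t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_mom**2))
            z = a_new + ((t_mom - 1.0) / t_new) * (a_new - a)
            if np.max(np.abs(a_new - a)) < 1e-14 * max(c, 1.0):
                a = a_new
                break
            a, t_mom = a_new, t_new

    edge = 1e-8 * max(c, 1.0)
    for _ in range(3):
        free = (a > edge) & (a < c - edge)
        if not free.any():
            break
        fixed = ~free
        rhs = e[free] - Q[np.ix_(free, fixed)] @ a[fixed]
        Qff = Q[np.ix_(free, free)]
        try:
            a_free = np.linalg.solve(Qff + tol * np.eye(free.sum()), rhs)
        except np.linalg.LinAlgError:
            break
        if np.all(a_free > -edge) and np.all(a_free < c + edge):
            cand = a.copy()
            cand[free] = np.clip(a_free, 0.0, c)
            if fun(cand)[0] <= fun(a)[0] + 1e-15:
                a = cand
                continue
        break
    return a


class TwinSVM:
    """Two-class twin SVM with Gaussian (or linear) kernel.

    Parameters
    ----------
    c1, c2 : float
        Penalty weights on the slack of planes 1 and 2. Default 3.5.
    sigma1, sigma2 : float
        Gaussian kernel widths used when building planes 1 and 2.
        Default 3.5. Ignored for the linear kernel.
    kernel : {"rbf", "linear"}
        "linear" uses K(x, y) = x . y (useful for validation against
        closed-form geometry); "rbf" is the default.
    standardize : bool
        Z-score the features with training-set statistics inside fit and
        predict. On by default: the raw features mix scales (norms of order
        tens, entropy of order one) and an RBF kernel would otherwise be
        dominated by the largest-scale block.
    ridge : float
        Tikhonov term added to H'H / G'G before inversion.
    """

    def __init__(self, c1: float = 3.5, c2: float = 3.5, sigma1: float = 3.5,
                 sigma2: float = 3.5, kernel: str = "rbf",
                 standardize: bool = True, ridge: float = 1e-6):
        if c1 <= 0 or c2 <= 0:
            raise ValueError("penalty parameters must be positive")
        if kernel == "rbf" and (sigma1 <= 0 or sigma2 <= 0):
            raise ValueError("kernel widths must be positive")
        if kernel not in ("rbf", "linear"):
            raise ValueError("kernel must be 'rbf' or 'linear'")
        self.c1, self.c2 = float(c1), float(c2)
        self.sigma1, self.sigma2 = float(sigma1), float(sigma2)
        self.kernel = kernel
        self.standardize = standardize
        self.ridge = float(ridge)

    # -- kernel and scaling -------------------------------------------------

    def _kernel(self, X: np.ndarray, Y: np.ndarray, sigma: float) -> np.ndarray:
        if self.kernel == "linear":
            return np.atleast_2d(X) @ np.atleast_2d(Y).T
        return gaussian_kernel(X, Y, sigma)

    def _scale(self, X: np.ndarray) -> np.ndarray:
        if not self.standardize:
            return np.asarray(X, dtype=float)
        return (np.asarray(X, dtype=float) - self.mean_) / self.scale_

    # -- fitting ------------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray) -> "TwinSVM":
        train = X if isinstance(X, TrainingSet) else TrainingSet(X, y)
        Xraw = train.X
        self.mean_ = Xraw.mean(axis=0)
        scale = Xraw.std(axis=0)
        scale[scale == 0.0] = 1.0
        self.scale_ = scale
        Xs = self._scale(Xraw)
        self.C_train_ = Xs
        self.y_train_ = train.y
        A = Xs[train.y == 1]
        B = Xs[train.y == -1]
        m = Xs.shape[0]

        # plane 1: close to A, pushed from B
        H1 = np.column_stack([self._kernel(A, Xs, self.sigma1), np.ones(len(A))])
        G1 = np.column_stack([self._kernel(B, Xs, self.sigma1), np.ones(len(B))])
        M1 = np.linalg.inv(H1.T @ H1 + self.ridge * np.eye(m + 1))
        alpha = _solve_box_qp(G1 @ M1 @ G1.T, self.c1)
        v1 = -M1 @ (G1.T @ alpha)
        self.u1_, self.b1_ = v1[:-1], float(v1[-1])

        # plane 2: close to B, pushed from A
        G2 = np.column_stack([self._kernel(B, Xs, self.sigma2), np.ones(len(B))])
        H2 = np.column_stack([self._kernel(A, Xs, self.sigma2), np.ones(len(A))])
        M2 = np.linalg.inv(G2.T @ G2 + self.ridge * np.eye(m + 1))
        gamma = _solve_box_qp(H2 @ M2 @ H2.T, self.c2)
        v2 = M2 @ (H2.T @ gamma)
        self.u2_, self.b2_ = v2[:-1], float(v2[-1])

        zeta = np.maximum(0.0, 1.0 + (G1[:, :-1] @ self.u1_ + self.b1_))
        eta = np.maximum(0.0, 1.0 - (H2[:, :-1] @ self.u2_ + self.b2_))
        self.slack_duals_ = SlackDuals(zeta=zeta, eta=eta, alpha=alpha, gamma=gamma)

        K11 = self._kernel(Xs, Xs, self.sigma1)
        K22 = K11 if self.sigma1 == self.sigma2 else self._kernel(Xs, Xs, self.sigma2)
        n1 = float(self.u1_ @ K11 @ self.u1_)
        n2 = float(self.u2_ @ K22 @ self.u2_)
        if n1 <= 1e-12 or n2 <= 1e-12:
            raise RuntimeError("degenerate hyperplane: u'Ku is not positive")
        self.denom1_ = float(np.sqrt(n1))
        self.denom2_ = float(np.sqrt(n2))
        return self

    # -- prediction ---------------------------------------------------------

    def decision_distances(self, X: np.ndarray) -> np.ndarray:
        """Perpendicular kernel-metric distances (d1, d2) to the two planes."""
        Xs = np.atleast_2d(self._scale(X))
        if Xs.shape[1] != self.C_train_.shape[1]:
            raise ValueError("feature dimensionality does not match training data")
        f1 = self._kernel(Xs, self.C_train_, self.sigma1) @ self.u1_ + self.b1_
        f2 = self._kernel(Xs, self.C_train_, self.sigma2) @ self.u2_ + self.b2_
        return np.column_stack([np.abs(f1) / self.denom1_,
                                np.abs(f2) / self.denom2_])

    def predict(self, X: np.ndarray) -> np.ndarray:
        """+1 (abnormal) where the positive plane is strictly nearer, else -1."""
        d = self.decision_distances(X)
        return np.where(d[:, 0] < d[:, 1], 1, -1)

    # -- diagnostics --------------------------------------------------------

    def primal_objectives(self) -> tuple[float, float]:
        """Objective values of the two primal QPs at the fitted solution."""
        A = self.C_train_[self.y_train_ == 1]
        B = self.C_train_[self.y_train_ == -1]
        sd = self.slack_duals_
        r1 = self._kernel(A, self.C_train_, self.sigma1) @ self.u1_ + self.b1_
        j1 = 0.5 * float(r1 @ r1) + self.c1 * float(sd.zeta.sum())
        r2 = self._kernel(B, self.C_train_, self.sigma2) @ self.u2_ + self.b2_
        j2 = 0.5 * float(r2 @ r2) + self.c2 * float(sd.eta.sum())
        return j1, j2

    # -- serialization ------------------------------------------------------

    def save(self, path) -> None:
        payload = {
            "format": "twinpcg-twsvm",
            "version": SERIAL_VERSION,
            "params": {
                "c1": self.c1, "c2": self.c2,
                "sigma1": self.sigma1, "sigma2": self.sigma2,
                "kernel": self.kernel, "standardize": self.standardize,
                "ridge": self.ridge,
            },
            "state": {
                "u1": self.u1_, "b1": self.b1_,
                "u2": self.u2_, "b2": self.b2_,
                "denom1": self.denom1_, "denom2": self.denom2_,
                "mean": self.mean_, "scale": self.scale_,
                "C_train": self.C_train_, "y_train": self.y_train_,
            },
        }
        joblib.dump(payload, path)

    @classmethod
    def load(cls, path) -> "TwinSVM":
        payload = joblib.load(path)
        if payload.get("format") != "twinpcg-twsvm":
            raise ValueError("not a twinpcg TWSVM model file")
        model = cls(**payload["params"])
        st = payload["state"]
        model.u1_, model.b1_ = st["u1"], st["b1"]
        model.u2_, model.b2_ = st["u2"], st["b2"]
        model.denom1_, model.denom2_ = st["denom1"], st["denom2"]
        model.mean_, model.scale_ = st["mean"], st["scale"]
        model.C_train_, model.y_train_ = st["C_train"], st["y_train"]
        return model
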