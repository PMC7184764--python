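"""Sparse linear discriminant feature selection per subband.

For each subband n the H x D matrix M_n stacks the 8-entropy vectors of
every (channel, segment) pair; C_n is the two-column focal/non-focal
indicator.  The sparse optimal-scoring criterion

    min_{theta, beta} ||C theta - M beta||^2 + delta ||beta||^2
                       + delta1 ||beta||_1,
    s.t. (1/H) theta^T C^T C theta = 1

is solved with the elastic-net (LARS-EN) path on ridge-augmented data,
stopping when G = |delta1| coefficients are active — the "desired
number of variables" reading of the sparsity control.  The selected
index sets I_n subset each subband's columns; concatenating the
selected columns across the N subbands yields the classifier input
V* of length sum_n G_n.

With two classes a single discriminative direction exists: the score
vector theta that satisfies the normalization constraint and is
orthogonal (in the C^T C metric) to the constant scoring is unique up
to sign, so no theta/beta alternation is needed — one deflation +
normalization step from the all-ones initialization fixes it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import lars_path

__all__ = ["SldaSolution", "fit_slda", "select_features", "weight_map"]


@dataclass
class SldaSolution:
    """Fitted per-subband sparse discriminant direction.

    beta : coefficient vector (length D), zeros outside the selection
    theta : class-score vector (focal, nonfocal)
    index_set : sorted 0-based indices of the non-zero coefficients
    delta : ridge weight; implied_l1 : L1 weight at the path knot used
    mean / scale : training-column statistics when standardized
    """

    beta: np.ndarray
    theta: np.ndarray
    index_set: np.ndarray
    delta: float
    implied_l1: float
    subband: int | None = None
    mean: np.ndarray | None = None
    scale: np.ndarray | None = None


def _score_vector(focal: np.ndarray) -> np.ndarray:
    """Two-class optimal-scoring theta satisfying (1/H) theta' C'C theta = 1
    and orthogonality to the constant score, focal class positive."""
    h1 = int(focal.sum())
    h2 = int((~focal).sum())
    if h1 == 0 or h2 == 0:
        raise ValueError("need at least one focal and one non-focal row")
    return np.array([h2, -h1]) / np.sqrt(h1 * h2)


def fit_slda(
    M: np.ndarray,
    focal: np.ndarray,
    delta: float = 3.0,
    g: int | None = None,
    delta1: float | None = None,
    standardize: bool = True,
    subband: int | None = None,
) -> SldaSolution:
    """Fit the sparse discriminant direction for one subband.

    Parameters
    ----------
    M
        H x D feature matrix (rows: channel-segment pairs).
    focal
        Boolean row labels (True = focal/SOZ).
    delta
        Ridge weight (default 3).
    g, delta1
        Sparsity: keep exactly ``g`` features; alternatively pass the
        negative ``delta1`` convention where g = \\|delta1\\|.  ``g`` of
        ``None`` (or g >= D) keeps all columns — the solution is then
        the ridge closed form (M'M + delta I)^{-1} M' C theta.
    standardize
        Z-score columns with the (training) rows seen here; selection
        indices always refer to the original columns.
    """
    M = np.asarray(M, dtype=float)
    focal = np.asarray(focal, dtype=bool)
    if M.ndim != 2 or M.shape[0] != focal.shape[0]:
        raise ValueError("M must be H x D with one label per row")
    H, D = M.shape
    if g is None and delta1 is not None:
        g = int(round(abs(delta1)))
    if g is not None and (g < 1 or g > D):
        raise ValueError(f"g must be in 1..{D}, got {g}")

    theta = _score_vector(focal)
    y = np.where(focal, theta[0], theta[1])

    mean = scale = None
    X = M
    if standardize:
        mean = M.mean(axis=0)
        scale = M.std(axis=0)
        scale = np.where(scale == 0, 1.0, scale)
        X = (M - mean) / scale

    if g is None or g == D:
        beta = np.linalg.solve(X.T @ X + delta * np.eye(D), X.T @ y)
        implied_l1 = 0.0
    else:
        # elastic net as lasso on ridge-augmented data (LARS-EN)
        X_aug = np.vstack([X, np.sqrt(delta) * np.eye(D)])
        y_aug = np.concatenate([y, np.zeros(D)])
        alphas, _, coefs = lars_path(X_aug, y_aug, method="lasso")
        n_active = (coefs != 0).sum(axis=0)
        hits = np.nonzero(n_active == g)[0]
        if len(hits) == 0:
            # path skipped G (drop/add in one step); take the last knot
            # with at most G active variables
            hits = np.nonzero(n_active <= g)[0][-1:]
        knot = hits[0]
        beta = coefs[:, knot]
        # lars_path minimizes (1/(2n))||y - Xb||^2 + alpha ||b||_1
        implied_l1 = float(2 * len(y_aug) * alphas[knot])

    index_set = np.nonzero(beta)[0]
    return SldaSolution(
        beta=beta,
        theta=theta,
        index_set=index_set,
        delta=delta,
        implied_l1=implied_l1,
        subband=subband,
        mean=mean,
        scale=scale,
    )


def slda_objective(
    sol: SldaSolution, M: np.ndarray, focal: np.ndarray, beta: np.ndarray | None = None
) -> float:
    """Evaluate the penalized criterion at ``beta`` (default: the fit),
    using the fit's standardization and implied L1 weight."""
    beta = sol.beta if beta is None else np.asarray(beta, dtype=float)
    X = np.asarray(M, dtype=float)
    if sol.mean is not None:
        X = (X - sol.mean) / sol.scale
    y = np.where(np.asarray(focal, bool), sol.theta[0], sol.theta[1])
    resid = y - X @ beta
    return float(
        resid @ resid
        + sol.delta * beta @ beta
        + sol.implied_l1 * np.abs(beta).sum()
    )


def select_features(
    matrices: dict[int, np.ndarray], solutions: dict[int, SldaSolution]
) -> np.ndarray:
    """Assemble V*: per-subband column subsetting, then concatenation.

    ``matrices`` maps subband index -> rows x D matrix (training or
    test rows, in the same row order for every subband); ``solutions``
    maps the same keys to fitted selections.  Returns the rows x
    sum_n G_n selected feature matrix.
    """
    if set(matrices) != set(solutions):
        raise ValueError("matrices and solutions must cover the same subbands")
    blocks = []
    for n in sorted(matrices):
        sol = solutions[n]
        if len(sol.index_set) == 0:
            raise ValueError(f"empty selection in subband {n}")
        blocks.append(np.asarray(matrices[n], dtype=float)[:, sol.index_set])
    return np.hstack(blocks)


def weight_map(solutions: dict[int, SldaSolution], n_features: int = 8) -> np.ndarray:
    """N x D matrix of |beta| across subbands (zeros where unselected),
    the substrate of the weights-vs-entropy colormap."""
    ns = sorted(solutions)
    out = np.zeros((len(ns), n_features))
    for row, n in enumerate(ns):
        out[row] = np.abs(solutions[n].beta)
    return out
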