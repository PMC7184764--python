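"""ADASYN oversampling of the focal (minority) class.

Focal segments are a small fraction of the training rows (few SOZ
channels among many).  ADASYN generates synthetic minority vectors
adaptively: each minority seed i receives a share Gamma_i of the
total synthetic budget proportional to the fraction Theta_i / K of
majority samples among its K nearest neighbors in the full training
set, so seeds near the class boundary generate the most.  Each
synthetic point is a convex combination of its seed and a randomly
chosen minority neighbor (the SMOTE interpolation step).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

__all__ = ["BalancedTrainingSet", "adasyn_balance"]


@dataclass
class BalancedTrainingSet:
    """Result of ADASYN balancing.

    X / focal : balanced design matrix and labels (originals first,
        synthetics appended)
    synthetic : the generated minority vectors (n_synthetic x dim)
    gamma : per-seed generation ratios (sums to 1; all zero when no
        synthesis was needed)
    theta : per-seed majority-neighbor counts among the K-NN
    g : per-seed synthetic counts (sums to n_synthetic exactly)
    """

    X: np.ndarray
    focal: np.ndarray
    synthetic: np.ndarray
    gamma: np.ndarray
    theta: np.ndarray
    g: np.ndarray
    beta: float
    k: int


def _largest_remainder(target: int, weights: np.ndarray) -> np.ndarray:
    """Integer apportionment of ``target`` by ``weights`` (sum to 1)."""
    raw = weights * target
    base = np.floor(raw).astype(int)
    short = target - base.sum()
    if short > 0:
        order = np.argsort(-(raw - base), kind="stable")
        base[order[:short]] += 1
    return base


def adasyn_balance(
    X: np.ndarray,
    focal: np.ndarray,
    beta: float = 1.0,
    k: int = 5,
    seed: int | np.random.Generator | None = None,
) -> BalancedTrainingSet:
    """Balance a focal/non-focal training set by adaptive synthesis.

    Parameters
    ----------
    X, focal
        Training matrix (rows = channel-segment feature vectors V*)
        and boolean minority labels.
    beta
        Balance level in [0, 1]; 1 generates (J - I) synthetics so the
        classes end up equal in count.
    k
        Neighborhood size for both the adaptivity ratio and the SMOTE
        interpolation draw.  Reduced (with a warning) when the minority
        class has fewer than k + 1 members.
    seed
        Seed or Generator; output is bit-identical for a fixed seed.
    """
    X = np.asarray(X, dtype=float)
    focal = np.asarray(focal, dtype=bool)
    if X.ndim != 2 or X.shape[0] != focal.shape[0]:
        raise ValueError("X must be 2-D with one label per row")
    if not 0 <= beta <= 1:
        raise ValueError("beta must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    minority = X[focal]
    i_in, j_in = len(minority), int((~focal).sum())
    if i_in == 0:
        raise ValueError("no focal (minority) rows to oversample")
    dim = X.shape[1]
    empty = BalancedTrainingSet(
        X=X, focal=focal, synthetic=np.empty((0, dim)),
        gamma=np.zeros(i_in), theta=np.zeros(i_in, dtype=int),
        g=np.zeros(i_in, dtype=int), beta=beta, k=k,
    )
    n_syn = int(round((j_in - i_in) * beta))
    if n_syn <= 0:
        return empty

    if i_in <= k:
        warnings.warn(
            f"minority class has {i_in} members; reducing k from {k} to {i_in - 1}"
        )
        k = i_in - 1
    if k < 1:
        raise ValueError("need at least 2 minority samples to interpolate")

    # adaptivity: majority fraction among K-NN in the FULL training set
    nn_all = NearestNeighbors(n_neighbors=k + 1).fit(X)
    idx = nn_all.kneighbors(minority, return_distance=False)[:, 1:]  # drop self
    theta = (~focal[idx]).sum(axis=1)
    if theta.sum() == 0:
        # every seed sits in a pure-minority neighborhood: nothing to adapt
        warnings.warn("all minority neighborhoods are pure; no synthesis")
        return empty
    gamma = (theta / k) / (theta / k).sum()
    g = _largest_remainder(n_syn, gamma)

    # SMOTE step: interpolate toward one of the K nearest minority neighbors
    nn_min = NearestNeighbors(n_neighbors=min(k, i_in - 1) + 1).fit(minority)
    min_idx = nn_min.kneighbors(minority, return_distance=False)[:, 1:]
    synth = np.empty((n_syn, dim))
    pos = 0
    for i in range(i_in):
        for _ in range(g[i]):
            nb = minority[rng.choice(min_idx[i])]
            delta = rng.uniform()
            synth[pos] = minority[i] + (nb - minority[i]) * delta
            pos += 1

    X_out = np.vstack([X, synth])
    focal_out = np.concatenate([focal, np.ones(n_syn, dtype=bool)])
    return BalancedTrainingSet(
        X=X_out, focal=focal_out, synthetic=synth,
        gamma=gamma, theta=theta, g=g, beta=beta, k=k,
    )
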