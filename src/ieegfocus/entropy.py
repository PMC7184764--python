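"""Entropy features of a narrowband iEEG segment.

Eight complexity measures are computed per subband signal:

* approximate entropy (APE) and sample entropy (Sp): template-matching
  regularity statistics on delay embeddings with Chebyshev distance and
  tolerance r = 0.2 x SD of the signal;
* permutation entropy (PE): Shannon entropy (base 2) of ordinal-pattern
  frequencies, embedding d = 3, lag 1;
* spectral entropies Shannon (Sh), Renyi (Ren, order 2) and Tsallis
  (Ts, index 2) of the normalized one-sided power spectrum;
* phase entropies S1 and S2: entropies of the normalized bispectral
  magnitude (and squared magnitude) over the principal domain.

The eight values form the per-subband feature vector in the fixed order
(APE, PE, Sh, Sp, Ts, S2, S1, Ren).

APE and Sp are O(L^2); for production-length segments (L = 40,000 at
2 kHz x 20 s) they are evaluated on a strided subsample capped at
``max_samples`` points (default 4,000).  The exact path is used
automatically whenever the signal is short enough, so oracle-scale
inputs are always computed exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "EntropyParams",
    "ENTROPY_NAMES",
    "approximate_entropy",
    "sample_entropy",
    "permutation_entropy",
    "power_spectrum_probs",
    "shannon_spectral",
    "renyi_spectral",
    "tsallis_spectral",
    "Bispectrum",
    "bispectrum",
    "phase_entropies",
    "entropy_vector",
    "UndefinedEntropyError",
]

#: Fixed feature order of the per-subband entropy vector (D = 8).
ENTROPY_NAMES = ("ape", "pe", "sh", "sp", "ts", "s2", "s1", "ren")


class UndefinedEntropyError(ValueError):
    """An estimator is undefined for this input (e.g. no template matches,
    zero spectral power).  Callers record a missing value rather than
    silently imputing."""


@dataclass(frozen=True)
class EntropyParams:
    """Estimator parameters.

    d_embed : embedding dimension for APE/Sp (2) ; pe_d for PE (3)
    r_factor : tolerance multiplier, r = r_factor x SD of the signal
    tau : PE time lag
    alpha : Renyi order ; q : Tsallis index (both != 1)
    bispec_epochs / bispec_nfft : direct-FFT bispectrum estimator config
    max_samples : cap on APE/Sp input length (strided subsample above it)
    metric : 'chebyshev' (standard) or 'euclidean' template distance
    """

    d_embed: int = 2
    r_factor: float = 0.2
    pe_d: int = 3
    tau: int = 1
    alpha: float = 2.0
    q: float = 2.0
    bispec_epochs: int = 31
    bispec_nfft: int = 1024
    max_samples: int = 4000
    metric: str = "chebyshev"

    def __post_init__(self) -> None:
        if self.d_embed < 2:
            raise ValueError("d_embed must be >= 2")
        if self.r_factor <= 0:
            raise ValueError("r_factor must be positive")
        if self.tau < 1:
            raise ValueError("tau must be >= 1")
        if self.alpha == 1 or self.q == 1:
            raise ValueError("alpha and q must differ from 1")
        if self.metric not in ("chebyshev", "euclidean"):
            raise ValueError("metric must be 'chebyshev' or 'euclidean'")


# ---------------------------------------------------------------- APE / Sp

@njit(cache=True)
def _template_counts(x, d, n_templates, r, chebyshev):
    """counts[i] = #{j : dist(X(i), X(j)) <= r}, templates X(k)=x[k:k+d],
    i, j in [0, n_templates).  Includes the self-match j == i."""
    counts = np.ones(n_templates, dtype=np.int64)  # self-matches
    r2 = r * r
    for i in range(n_templates):
        for j in range(i + 1, n_templates):
            if chebyshev:
                ok = True
                for k in range(d):
                    if abs(x[i + k] - x[j + k]) > r:
                        ok = False
                        break
                if ok:
                    counts[i] += 1
                    counts[j] += 1
            else:
                s = 0.0
                for k in range(d):
                    diff = x[i + k] - x[j + k]
                    s += diff * diff
                if s <= r2:
                    counts[i] += 1
                    counts[j] += 1
    return counts


def _prepare(x: np.ndarray, max_samples: int | None) -> np.ndarray:
    x = np.ascontiguousarray(np.asarray(x, dtype=float))
    if x.ndim != 1:
        raise ValueError("expected a 1-D signal")
    if max_samples is not None and len(x) > max_samples:
        stride = int(np.ceil(len(x) / max_samples))
        x = np.ascontiguousarray(x[::stride])
    return x


def _tolerance(x: np.ndarray, r: float | None, r_factor: float) -> float:
    if r is None:
        r = r_factor * float(np.std(x))
    if r < 0:
        raise ValueError("tolerance r must be >= 0")
    return float(r)


def approximate_entropy(
    x: np.ndarray,
    d: int = 2,
    r: float | None = None,
    r_factor: float = 0.2,
    metric: str = "chebyshev",
    max_samples: int | None = None,
) -> float:
    """Approximate entropy APE(d, r, L).

    Phi_m = mean_i ln C_i^m(r) with C_i^m the fraction of the L-m+1
    length-m templates within tolerance r of template i (self-match
    included); APE = Phi_d - Phi_{d+1}.  By default r = 0.2 x SD(x).
    A constant signal gives 0.
    """
    x = _prepare(x, max_samples)
    L = len(x)
    if L <= d + 1:
        raise ValueError(f"signal length {L} too short for embedding d={d}")
    r = _tolerance(x, r, r_factor)
    cheb = metric == "chebyshev"
    phis = []
    for m in (d, d + 1):
        nt = L - m + 1
        counts = _template_counts(x, m, nt, r, cheb)
        phis.append(np.mean(np.log(counts / nt)))
    return float(phis[0] - phis[1])


def sample_entropy(
    x: np.ndarray,
    d: int = 2,
    r: float | None = None,
    r_factor: float = 0.2,
    metric: str = "chebyshev",
    max_samples: int | None = None,
) -> float:
    """Sample entropy Sp(d, r, L) = -ln(A^d(r) / B^d(r)).

    B counts length-d template pairs within r, A counts length-(d+1)
    pairs, both over the first L-d templates and excluding self-matches.
    Raises :class:`UndefinedEntropyError` when no (d+1)-matches exist.
    """
    x = _prepare(x, max_samples)
    L = len(x)
    if L <= d + 1:
        raise ValueError(f"signal length {L} too short for embedding d={d}")
    r = _tolerance(x, r, r_factor)
    cheb = metric == "chebyshev"
    nt = L - d
    # counts include the self-match; subtract it for the Richman-Moorman sums
    b = _template_counts(x, d, nt, r, cheb).sum() - nt
    a = _template_counts(x, d + 1, nt, r, cheb).sum() - nt
    if b == 0:
        raise UndefinedEntropyError("sample entropy undefined: no d-template matches")
    if a == 0:
        raise UndefinedEntropyError(
            "sample entropy undefined: no (d+1)-template matches"
        )
    return float(-np.log(a / b))


def _ape_sp_fused(
    x: np.ndarray, d: int, r: float, chebyshev: bool
) -> tuple[float, float]:
    """APE and Sp from shared template counts (x already prepared).

    The d-template counts over all L-d+1 templates give APE's Phi_d
    directly and, after removing the last template's matches and the
    self-matches, Sp's B sum; the (d+1)-counts over L-d templates give
    both Phi_{d+1} and Sp's A sum.  Matches the standalone estimators
    exactly.  Sp is NaN when no (d+1)-template matches exist.
    """
    L = len(x)
    nt1, nt2 = L - d + 1, L - d
    counts_d = _template_counts(x, d, nt1, r, chebyshev)
    counts_d1 = _template_counts(x, d + 1, nt2, r, chebyshev)
    ape = float(
        np.mean(np.log(counts_d / nt1)) - np.mean(np.log(counts_d1 / nt2))
    )
    b = counts_d[:nt2].sum() - (counts_d[nt2] - 1) - nt2
    a = counts_d1.sum() - nt2
    sp = float(-np.log(a / b)) if (a > 0 and b > 0) else float("nan")
    return ape, sp


# ------------------------------------------------------------------- PE

def permutation_entropy(x: np.ndarray, d: int = 3, tau: int = 1) -> float:
    """Permutation entropy, base-2, of ordinal patterns of length ``d``.

    Patterns are ranked with stable ordering (ties broken by position,
    the Bandt-Pompe convention); probabilities are pattern counts over
    the L-(d-1)tau embedding windows.  Bounded by log2(d!); a monotone
    ramp gives 0.
    """
    x = np.asarray(x, dtype=float)
    L = len(x)
    n_vec = L - (d - 1) * tau
    if n_vec < 2:
        raise ValueError(f"signal length {L} too short for d={d}, tau={tau}")
    idx = np.arange(n_vec)[:, None] + tau * np.arange(d)[None, :]
    patterns = np.argsort(x[idx], axis=1, kind="stable")
    # encode each pattern as an integer in base d
    codes = (patterns * d ** np.arange(d)[None, :]).sum(axis=1)
    _, counts = np.unique(codes, return_counts=True)
    p = counts / n_vec
    return float(-(p * np.log2(p)).sum())


# ------------------------------------------------------------- spectral

def power_spectrum_probs(x: np.ndarray) -> np.ndarray:
    """Normalized one-sided power spectrum p_f = P_f / sum(P_f).

    Rectangular window periodogram, DC bin excluded.  Raises
    :class:`UndefinedEntropyError` on zero spectral power.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("expected a 1-D signal of length >= 2")
    P = np.abs(np.fft.rfft(x)[1:]) ** 2
    total = P.sum()
    if total == 0:
        raise UndefinedEntropyError("zero spectral power")
    return P / total


def _check_probs(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or np.any(p < -1e-12) or abs(p.sum() - 1.0) > 1e-8:
        raise ValueError("expected a probability vector summing to 1")
    return np.clip(p, 0.0, None)


def shannon_spectral(p: np.ndarray) -> float:
    """Shannon spectral entropy -sum p_f ln p_f (natural log; 0 ln 0 = 0)."""
    p = _check_probs(p)
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def renyi_spectral(p: np.ndarray, alpha: float = 2.0, literal_form: bool = False) -> float:
    """Renyi spectral entropy of order ``alpha`` (default 2).

    Standard form (1/(1-alpha)) ln sum p_f^alpha, which is nonnegative
    and bounded above by the Shannon entropy for alpha > 1.  With
    ``literal_form=True`` the non-standard variant
    (1/(1-alpha)) sum ln p_f^2 is returned instead (it diverges to +inf
    whenever any bin is empty); it is kept only for comparison.
    """
    if alpha == 1:
        raise ValueError("alpha = 1 is the Shannon limit; use shannon_spectral")
    p = _check_probs(p)
    if literal_form:
        with np.errstate(divide="ignore"):
            return float(np.sum(np.log(p**2)) / (1.0 - alpha))
    return float(np.log(np.sum(p**alpha)) / (1.0 - alpha))


def tsallis_spectral(p: np.ndarray, q: float = 2.0) -> float:
    """Tsallis spectral entropy (1 - sum p_f^q)/(q - 1); in [0, 1-1/F] for q=2."""
    if q == 1:
        raise ValueError("q = 1 is the Shannon limit; use shannon_spectral")
    p = _check_probs(p)
    return float((1.0 - np.sum(p**q)) / (q - 1.0))


# ----------------------------------------------------------- bispectrum

@dataclass
class Bispectrum:
    """Direct-FFT bispectrum estimate over the principal domain.

    ``values[f1, f2]`` holds B(f1, f2) on the grid of nonnegative
    frequency bins; ``mask`` marks the principal triangular domain
    f1 >= f2 >= 0 (DC excluded), f1 + f2 <= Nyquist bin.
    """

    values: np.ndarray
    mask: np.ndarray
    nfft: int
    n_epochs: int

    @property
    def magnitudes(self) -> np.ndarray:
        """|B| over the principal domain, flattened."""
        return np.abs(self.values[self.mask])


def bispectrum(x: np.ndarray, epochs: int = 31, nfft: int = 1024) -> Bispectrum:
    """Estimate B(f1,f2) = E[F(f1) F(f2) F*(f1+f2)] by epoch averaging.

    The signal is split into ``epochs`` non-overlapping windows of
    ``nfft`` samples (demeaned, rectangular window); the triple product
    is averaged across epochs.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < epochs * nfft:
        raise ValueError(
            f"signal length {len(x)} < epochs*nfft = {epochs * nfft}"
        )
    half = nfft // 2
    f1, f2 = np.meshgrid(np.arange(half + 1), np.arange(half + 1), indexing="ij")
    mask = (f1 >= f2) & (f2 >= 1) & (f1 + f2 <= half)
    i1, i2 = np.nonzero(mask)
    i3 = i1 + i2
    # epoch-wise FFTs at once; accumulate only over the principal domain
    segs = x[: epochs * nfft].reshape(epochs, nfft)
    F = np.fft.fft(segs - segs.mean(axis=1, keepdims=True), axis=1)
    flat = (F[:, i1] * F[:, i2] * np.conj(F[:, i3])).mean(axis=0)
    acc = np.zeros((half + 1, half + 1), dtype=complex)
    acc[i1, i2] = flat
    return Bispectrum(values=acc, mask=mask, nfft=nfft, n_epochs=epochs)


def phase_entropies(b: Bispectrum) -> tuple[float, float]:
    """Phase entropies (S1, S2) of the normalized bispectral magnitude.

    S1 uses p_k = |B_k| / sum|B|, S2 uses q_k = |B_k|^2 / sum|B|^2 over
    the principal domain; S2 <= S1 since squaring sharpens the
    distribution.  Raises on zero bispectral mass.
    """
    mag = b.magnitudes
    tot = mag.sum()
    if tot == 0:
        raise UndefinedEntropyError("zero bispectral power")
    p = mag / tot
    q = mag**2 / (mag**2).sum()
    s1 = -(p[p > 0] * np.log(p[p > 0])).sum()
    s2 = -(q[q > 0] * np.log(q[q > 0])).sum()
    return float(s1), float(s2)


# ------------------------------------------------------------ assembly

def entropy_vector(
    x: np.ndarray,
    params: EntropyParams = EntropyParams(),
) -> np.ndarray:
    """The 8-entropy feature vector of one subband signal.

    Order: (APE, PE, Sh, Sp, Ts, S2, S1, Ren).  Estimators that are
    undefined for the input (constant signal, no template matches)
    yield NaN with a warning; downstream feature assembly drops such
    rows rather than imputing.
    """
    x = np.asarray(x, dtype=float)
    out = np.full(len(ENTROPY_NAMES), np.nan)
    sd = float(np.std(x))
    if sd == 0.0:
        # constant signal: regularity entropies are 0 by definition,
        # spectral/bispectral ones are undefined
        out[ENTROPY_NAMES.index("ape")] = 0.0
        out[ENTROPY_NAMES.index("sp")] = 0.0
        out[ENTROPY_NAMES.index("pe")] = 0.0
        warnings.warn("constant subband: spectral entropies undefined", stacklevel=2)
        return out

    xs = _prepare(x, params.max_samples)
    r = _tolerance(xs, None, params.r_factor)
    ape, sp = _ape_sp_fused(xs, params.d_embed, r, params.metric == "chebyshev")
    if np.isnan(sp):
        warnings.warn("sample entropy undefined: no template matches", stacklevel=2)
    out[ENTROPY_NAMES.index("ape")] = ape
    out[ENTROPY_NAMES.index("sp")] = sp
    out[ENTROPY_NAMES.index("pe")] = permutation_entropy(x, d=params.pe_d, tau=params.tau)

    try:
        p = power_spectrum_probs(x)
    except UndefinedEntropyError as err:
        warnings.warn(f"spectral entropies undefined: {err}", stacklevel=2)
    else:
        out[ENTROPY_NAMES.index("sh")] = shannon_spectral(p)
        out[ENTROPY_NAMES.index("ren")] = renyi_spectral(p, alpha=params.alpha)
        out[ENTROPY_NAMES.index("ts")] = tsallis_spectral(p, q=params.q)

    def _phase() -> tuple[float, float]:
        # fit the epoch count to the segment, up to the configured maximum
        epochs = min(params.bispec_epochs, len(x) // params.bispec_nfft)
        if epochs < 1:
            raise UndefinedEntropyError(
                f"segment of {len(x)} samples shorter than one "
                f"{params.bispec_nfft}-sample bispectrum epoch"
            )
        b = bispectrum(x, epochs=epochs, nfft=params.bispec_nfft)
        return phase_entropies(b)

    try:
        s1, s2 = _phase()
    except (UndefinedEntropyError, ValueError) as err:
        warnings.warn(f"phase entropies undefined: {err}", stacklevel=2)
    else:
        out[ENTROPY_NAMES.index("s1")] = s1
        out[ENTROPY_NAMES.index("s2")] = s2
    return out
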