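"""The JTT amino-acid substitution model.

Implements the Jones-Taylor-Thornton (1992) empirical model as a normalised
reversible rate matrix: transition probabilities P(t) = expm(Q t), expected
proportion of different sites at divergence time t, and maximum-likelihood
pairwise distances (the "JTT matrix-based" distances used for the domain
phylogeny).  Time is measured in expected substitutions per site.

The exchangeability constants and equilibrium frequencies are the published
jones.dat values (residue order ARNDCQEGHILKMFPSTWYV).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .alphabet import N_AA

# Lower triangle (row 2..20, PAML layout) of the JTT exchangeability matrix.
_JTT_LOWER = [
    58, 54, 81, 56, 57, 105, 179, 27, 36, 30, 35, 54, 15, 194, 378, 475, 9,
    11, 298, 45, 16, 113, 310, 29, 137, 328, 22, 38, 646, 44, 5, 74, 101, 64,
    126, 20, 17, 528, 34, 86, 58, 81, 391, 47, 12, 263, 30, 10, 15, 503, 232,
    8, 70, 16, 10, 49, 767, 130, 112, 11, 7, 26, 15, 4, 15, 59, 38, 4, 46,
    31, 9, 5, 59, 69, 17, 23, 7, 31, 78, 14, 223, 42, 115, 209, 62, 323, 26,
    597, 9, 72, 292, 43, 4, 164, 53, 51, 18, 24, 20, 119, 26, 12, 9, 181, 18,
    5, 18, 30, 32, 10, 7, 45, 23, 6, 6, 27, 14, 5, 24, 201, 33, 55, 8, 47,
    16, 56, 45, 33, 40, 115, 73, 46, 8, 573, 11, 229, 21, 479, 89, 10, 40,
    245, 9, 32, 961, 14, 388, 248, 102, 59, 25, 52, 24, 180, 65, 4, 21, 47,
    103, 10, 8, 14, 43, 16, 29, 226, 24, 18, 323, 17, 92, 12, 53, 536, 62,
    285, 118, 6, 10, 23, 477, 35, 63, 38, 12, 21, 112, 71, 25, 16,
]

JTT_FREQUENCIES = np.array(
    [
        0.076748, 0.051691, 0.042645, 0.051544, 0.019803,
        0.040752, 0.061830, 0.073152, 0.022944, 0.053761,
        0.091904, 0.058676, 0.023826, 0.040126, 0.050901,
        0.068765, 0.058565, 0.014261, 0.032102, 0.066005,
    ]
)
JTT_FREQUENCIES = JTT_FREQUENCIES / JTT_FREQUENCIES.sum()

MAX_DISTANCE = 10.0  # saturation cap, substitutions per site


class SaturatedDistance(Warning):
    pass


def _exchangeabilities() -> np.ndarray:
    s = np.zeros((N_AA, N_AA))
    k = 0
    for i in range(1, N_AA):
        for j in range(i):
            s[i, j] = s[j, i] = _JTT_LOWER[k]
            k += 1
    return s


@lru_cache(maxsize=1)
def _spectral():
    """Eigendecomposition of the normalised JTT rate matrix.

    Returns (eigenvalues, left, right) such that
    ``P(t) = right @ diag(exp(lam * t)) @ left``.
    """
    pi = JTT_FREQUENCIES
    s = _exchangeabilities()
    q = s * pi[None, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    # normalise to one expected substitution per site per unit time
    rate = -(pi * np.diag(q)).sum()
    q /= rate
    sqrt_pi = np.sqrt(pi)
    b = (q * sqrt_pi[:, None]) / sqrt_pi[None, :]
    b = 0.5 * (b + b.T)  # symmetrise against round-off
    lam, u = np.linalg.eigh(b)
    right = u / sqrt_pi[:, None]
    left = (u * sqrt_pi[:, None]).T
    return lam, left, right


def rate_matrix() -> np.ndarray:
    lam, left, right = _spectral()
    return (right * lam[None, :]) @ left


def transition_probabilities(t: float) -> np.ndarray:
    """P(t): row i -> probability distribution of the residue after time t."""
    if t < 0:
        raise ValueError("time must be non-negative")
    lam, left, right = _spectral()
    p = (right * np.exp(lam * t)[None, :]) @ left
    np.clip(p, 0.0, None, out=p)
    return p / p.sum(axis=1, keepdims=True)


def expected_pdistance(t: float) -> float:
    """Expected fraction of differing sites between two ends of a branch of
    length ``t`` when the ancestor is at equilibrium."""
    p = transition_probabilities(t)
    return float(1.0 - (JTT_FREQUENCIES * np.diag(p)).sum())


def time_for_pdistance(d: float) -> float:
    """Invert ``expected_pdistance`` (d must be below the saturation plateau)."""
    if not 0.0 <= d < 1.0:
        raise ValueError("target p-distance must lie in [0, 1)")
    if d == 0.0:
        return 0.0
    plateau = expected_pdistance(500.0)
    if d >= plateau - 1e-9:
        raise ValueError(f"p-distance {d} unreachable (saturation at {plateau:.3f})")
    return brentq(lambda t: expected_pdistance(t) - d, 1e-9, 500.0, xtol=1e-10)


def time_for_mixture_pdistance(d: float, rates) -> float:
    """Global time T such that the mean over sites of the expected
    p-distance at per-site times ``T * rates[i]`` equals ``d``.

    Used to plant domains whose overall divergence is ``d`` while slow
    (structurally conserved) sites diverge proportionally less.
    """
    rates = np.asarray(rates, dtype=float)
    if np.any(rates <= 0):
        raise ValueError("site rates must be positive")
    if not 0.0 <= d < 1.0:
        raise ValueError("target p-distance must lie in [0, 1)")
    if d == 0.0:
        return 0.0
    uniq, counts = np.unique(rates, return_counts=True)
    w = counts / counts.sum()

    def mean_p(t):
        return float(sum(wi * expected_pdistance(t * r) for wi, r in zip(w, uniq)))

    hi = 500.0 / uniq.max()
    if d >= mean_p(hi) - 1e-9:
        raise ValueError(f"p-distance {d} unreachable under the given rates")
    return brentq(lambda t: mean_p(t) - d, 1e-9, hi, xtol=1e-10)


def ml_distance(counts: np.ndarray, max_distance: float = MAX_DISTANCE):
    """Maximum-likelihood JTT distance from a 20x20 pair-count matrix.

    Maximises ``sum_ab N[a,b] * log(pi_a * P_ab(t))`` over the branch length
    ``t``.  Returns ``(distance, saturated_flag)``; distances beyond
    ``max_distance`` are capped and flagged.
    """
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("no residue pairs to estimate a distance from")
    identical = np.trace(counts)
    if identical == total:
        return 0.0, False

    log_pi = np.log(JTT_FREQUENCIES)

    def nll(t):
        p = transition_probabilities(t)
        with np.errstate(divide="ignore"):
            logp = np.log(p)
        ll = counts * (log_pi[:, None] + logp)
        # zero-count cells may be log(0); they contribute nothing
        return -np.sum(ll[counts > 0])

    res = minimize_scalar(nll, bounds=(1e-8, max_distance), method="bounded",
                          options={"xatol": 1e-10})
    t = float(res.x)
    if t >= max_distance - 1e-4 and nll(max_distance) <= nll(max_distance - 1e-3):
        return max_distance, True
    return (0.0 if t < 1e-6 else t), False
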