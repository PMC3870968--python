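"""Local-alignment scoring engine for profile HMMs.

Scores are log2 odds ("bits") against the profile's background null model.
A local alignment path enters at any match state (uniform entry probability
1/K), threads match/insert/delete states in order, and exits freely from any
match state; the unaligned flanks of the target contribute odds 1 and are
therefore ignored.  Viterbi returns the single best path (with deterministic
M > D > I tie-breaking); Forward the log2 of the summed odds of all paths.

E-values come from a Gumbel law fitted to Viterbi scores of random
background-sampled sequences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .alphabet import encode
from .hmm import ProfileHMM

NEG = -np.inf
_TIE_TOL = 1e-9


class EngineInputError(ValueError):
    pass


class CalibrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class ScoredAlignmentPath:
    """Best local alignment of a profile on a target sequence.

    ``env_start``/``env_end`` are 1-based inclusive residue coordinates of
    the emitted envelope; ``coverage`` counts match states visited on the
    path; ``state_path`` lists state labels like ``"M3"``.
    """

    bit_score: float
    env_start: int
    env_end: int
    coverage: int
    state_path: tuple


def _log_params(profile: ProfileHMM):
    with np.errstate(divide="ignore"):
        esc = np.log2(profile.match_emissions / profile.background[None, :])
        k = profile.n_match
        if k > 1:
            isc = np.log2(profile.insert_emissions / profile.background[None, :])
            tr = {n: np.log2(profile.transitions[n]) for n in profile.transitions}
        else:
            isc = np.zeros((0, profile.background.size))
            tr = {n: np.zeros(0) for n in ("mm", "mi", "md", "im", "ii", "dm", "dd")}
    entry = -np.log2(k)
    return esc, isc, tr, entry


def _dp(profile: ProfileHMM, seq: str, allowed: np.ndarray | None, viterbi: bool):
    """Fill the three DP matrices; returns (VM, VI, VD, esc, isc, tr, entry).

    Matrices have shape (L+1, K+1) with 1-based indexing; row/column 0 is
    the -inf boundary.  Delete-chain recursions use running (max / logsum)
    scans so the inner loop is vectorised over states.
    """
    if not seq:
        raise EngineInputError("empty sequence")
    x = encode(seq)
    esc, isc, tr, entry = _log_params(profile)
    big_k = profile.n_match
    length = len(x)

    vm = np.full((length + 1, big_k + 1), NEG)
    vi = np.full((length + 1, big_k + 1), NEG)
    vd = np.full((length + 1, big_k + 1), NEG)

    if big_k > 1:
        cum_dd = np.concatenate(([0.0], np.cumsum(tr["dd"])))  # cum_dd[m] = sum_{u<=m} tDD[u]
    comb = np.maximum if viterbi else np.logaddexp2
    accum = comb.accumulate

    for i in range(1, length + 1):
        e_row = esc[:, x[i - 1]].copy()
        if allowed is not None and not allowed[i - 1]:
            e_row[:] = NEG
        # M: from entry, M_{k-1}, I_{k-1}, D_{k-1} at i-1
        prev_m = vm[i - 1, 1:big_k]
        prev_i = vi[i - 1, 1:big_k]
        prev_d = vd[i - 1, 1:big_k]
        best = np.full(big_k, entry)
        if big_k > 1:
            cand = comb(
                comb(prev_m + tr["mm"], prev_i + tr["im"]),
                prev_d + tr["dm"],
            )
            best[1:] = comb(best[1:], cand)
        vm[i, 1:] = e_row + best
        if big_k > 1:
            # I states 1..K-1
            i_row = isc[:, x[i - 1]].copy()
            if allowed is not None and not allowed[i - 1]:
                i_row[:] = NEG
            vi[i, 1:big_k] = i_row + comb(
                vm[i - 1, 1:big_k] + tr["mi"], vi[i - 1, 1:big_k] + tr["ii"]
            )
            # D states 2..K from M_j at same i via delete chain:
            # VD[i,k] = cum_dd[k-1] + best over j<k of (VM[i,j]+tMD[j]-cum_dd[j])
            a = vm[i, 1:big_k] + tr["md"] - cum_dd[1:]
            vd[i, 2:] = cum_dd[1:] + accum(a)
    return vm, vi, vd, esc, isc, tr, entry, x


def score_forward(profile: ProfileHMM, seq: str) -> float:
    """Forward bit score: log2 of summed odds over all local paths."""
    vm, *_ = _dp(profile, seq, None, viterbi=False)
    ends = vm[1:, 1:]
    finite = ends[np.isfinite(ends)]
    if finite.size == 0:
        return NEG
    return float(np.logaddexp2.reduce(np.sort(finite)))


def viterbi_score(profile: ProfileHMM, seq: str, allowed=None) -> float:
    vm, *_ = _dp(profile, seq, allowed, viterbi=True)
    return float(vm[1:, 1:].max())


def score_viterbi(profile: ProfileHMM, seq: str, allowed=None) -> ScoredAlignmentPath:
    """Best local alignment path (deterministic M > D > I tie-breaking)."""
    vm, vi, vd, esc, isc, tr, entry, x = _dp(profile, seq, allowed, viterbi=True)
    big_k = profile.n_match
    flat = np.argmax(vm[1:, 1:])
    i = int(flat // big_k) + 1
    k = int(flat % big_k) + 1
    score = float(vm[i, k])
    if not np.isfinite(score):
        return ScoredAlignmentPath(NEG, 0, 0, 0, ())

    path = []
    env_end = i
    state = "M"
    while True:
        path.append(f"{state}{k}")
        if state == "M":
            target = vm[i, k] - esc[k - 1, x[i - 1]]
            cands = []
            if k > 1:
                cands = [
                    ("M", vm[i - 1, k - 1] + tr["mm"][k - 2]),
                    ("D", vd[i - 1, k - 1] + tr["dm"][k - 2]),
                    ("I", vi[i - 1, k - 1] + tr["im"][k - 2]),
                ]
            cands.append(("B", entry))
            choice = _pick(cands, target)
            if choice == "B":
                env_start = i
                break
            i, k, state = i - 1, k - 1, choice
        elif state == "D":
            target = vd[i, k]
            choice = _pick(
                [
                    ("M", vm[i, k - 1] + tr["md"][k - 2]),
                    ("D", vd[i, k - 1] + tr["dd"][k - 2]),
                ],
                target,
            )
            k, state = k - 1, choice
        else:  # insert
            target = vi[i, k] - isc[k - 1, x[i - 1]]
            choice = _pick(
                [
                    ("M", vm[i - 1, k] + tr["mi"][k - 1]),
                    ("I", vi[i - 1, k] + tr["ii"][k - 1]),
                ],
                target,
            )
            i, state = i - 1, choice
    path.reverse()
    coverage = sum(1 for s in path if s[0] == "M")
    return ScoredAlignmentPath(score, env_start, env_end, coverage, tuple(path))


def _pick(cands, target):
    best = max(v for _, v in cands)
    ref = max(best, target)
    for name, v in cands:
        if v >= ref - max(_TIE_TOL, abs(ref) * 1e-12):
            return name
    return max(cands, key=lambda nv: nv[1])[0]


def calibrate_evalues(
    profile: ProfileHMM, n_random: int = 1000, length: int = 400, seed: int = 0
):
    """Fit Gumbel (mu, lambda) to Viterbi scores of random background
    sequences; deterministic given ``seed``."""
    if n_random < 100:
        raise CalibrationError("need at least 100 random sequences to calibrate")
    rng = np.random.default_rng(seed)
    bg = profile.background
    scores = np.empty(n_random)
    for r in range(n_random):
        codes = rng.choice(bg.size, size=length, p=bg)
        seq = "".join("ARNDCQEGHILKMFPSTWYV"[c] for c in codes)
        scores[r] = viterbi_score(profile, seq)
    return fit_gumbel(scores)


def fit_gumbel(scores) -> tuple:
    """(mu, lambda) of a Gumbel law fitted to a score sample."""
    scores = np.asarray(scores, dtype=float)
    if np.std(scores) < 1e-9:
        raise CalibrationError("degenerate score variance; cannot fit Gumbel")
    loc, scale = stats.gumbel_r.fit(scores)
    return float(loc), float(1.0 / scale)


def pvalue(score: float, mu: float, lam: float) -> float:
    """P(S >= score) under the fitted Gumbel score law."""
    return float(-np.expm1(-np.exp(-lam * (score - mu))))
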