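"""Profile hidden Markov models built from masked seed alignments.

The model is a Plan7-like local-alignment profile: match states M_1..M_K
anchored on the masked alignment columns, insert states I_1..I_{K-1} for the
inter-match (kept-indel) regions, delete states D_1..D_K, uniform local
entry over match states and free exit from any match state.  Emissions are
estimated from weighted residue counts mixed with ``pseudocount_weight``
times the background; transitions from the observed match/insert/delete
paths of each seed row through the mask, with Laplace pseudocounts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .alphabet import AA_INDEX, GAP, N_AA, ROBINSON_FREQUENCIES, decode
from .seed import SeedAlignment

PROFILE_SCHEMA_VERSION = 1
_TRANSITION_NAMES = ("mm", "mi", "md", "im", "ii", "dm", "dd")


class ProfileBuildError(ValueError):
    pass


@dataclass
class ProfileHMM:
    """A local-alignment profile HMM with log-odds scoring support.

    All probabilities are stored in natural scale and strictly positive.
    ``transitions[name][k]`` is the probability of the transition out of
    state ``k+1`` (0-based arrays of length ``n_match - 1``).
    ``match_columns`` records the 1-based seed-alignment column each match
    state came from (when built from a seed).  ``key_columns`` optionally
    names annotated match states (1-based), e.g. the catalytic Asp/Lys.
    """

    name: str
    match_emissions: np.ndarray
    insert_emissions: np.ndarray
    transitions: dict
    background: np.ndarray = field(default_factory=lambda: ROBINSON_FREQUENCIES.copy())
    calibration: tuple | None = None  # (mu, lambda) of the Gumbel score law
    match_columns: tuple | None = None
    key_columns: dict = field(default_factory=dict)

    def __post_init__(self):
        self.match_emissions = np.asarray(self.match_emissions, dtype=float)
        self.insert_emissions = np.asarray(self.insert_emissions, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        self.validate()

    @property
    def n_match(self) -> int:
        return self.match_emissions.shape[0]

    def validate(self) -> None:
        k = self.n_match
        if k < 1:
            raise ProfileBuildError("profile needs at least one match state")
        dists = [self.match_emissions, self.background[None, :]]
        if k > 1:
            dists.append(self.insert_emissions)
            for name in _TRANSITION_NAMES:
                arr = np.asarray(self.transitions[name], dtype=float)
                if arr.shape != (k - 1,):
                    raise ProfileBuildError(f"transition array {name} has wrong length")
                self.transitions[name] = arr
            for tri in (("mm", "mi", "md"), ("im", "ii"), ("dm", "dd")):
                s = sum(self.transitions[n] for n in tri)
                if np.any(np.abs(s - 1.0) > 1e-9):
                    raise ProfileBuildError(f"transitions {tri} do not sum to 1")
                if any(np.any(self.transitions[n] <= 0) for n in tri):
                    raise ProfileBuildError("non-positive transition probability")
        for d in dists:
            if np.any(np.abs(d.sum(axis=1) - 1.0) > 1e-9):
                raise ProfileBuildError("emission distribution does not sum to 1")
            if np.any(d <= 0):
                raise ProfileBuildError("non-positive emission probability")

    def consensus(self) -> str:
        """Match-state argmax sequence (ties: first residue in ARND... order)."""
        return decode(np.argmax(self.match_emissions, axis=1))

    # -- serialization ----------------------------------------------------
    def to_json(self, path=None) -> str:
        doc = {
            "schema_version": PROFILE_SCHEMA_VERSION,
            "name": self.name,
            "n_match": self.n_match,
            "match_emissions": self.match_emissions.tolist(),
            "insert_emissions": self.insert_emissions.tolist(),
            "transitions": {n: np.asarray(v).tolist() for n, v in self.transitions.items()},
            "background": self.background.tolist(),
            "calibration": list(self.calibration) if self.calibration else None,
            "match_columns": list(self.match_columns) if self.match_columns else None,
            "key_columns": self.key_columns,
        }
        text = json.dumps(doc)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "ProfileHMM":
        if isinstance(source, (str, bytes)) and not str(source).lstrip().startswith("{"):
            with open(source) as fh:
                doc = json.load(fh)
        elif isinstance(source, (str, bytes)):
            doc = json.loads(source)
        else:
            doc = json.load(source)
        if doc.get("schema_version") != PROFILE_SCHEMA_VERSION:
            raise ProfileBuildError("unsupported profile schema version")
        return cls(
            name=doc["name"],
            match_emissions=np.array(doc["match_emissions"]),
            insert_emissions=np.array(doc["insert_emissions"]).reshape(-1, N_AA),
            transitions={n: np.array(v) for n, v in doc["transitions"].items()},
            background=np.array(doc["background"]),
            calibration=tuple(doc["calibration"]) if doc.get("calibration") else None,
            match_columns=tuple(doc["match_columns"]) if doc.get("match_columns") else None,
            key_columns=doc.get("key_columns") or {},
        )


def _row_events(aligned: str, mask: np.ndarray):
    """Yield the (state, index) events of one seed row through the mask.

    Match columns emit ('M', k) or delete ('D', k); residues in unmasked
    columns between match anchors k and k+1 are insert events ('I', k).
    Flanking insert residues (before M_1 / after M_K) belong to the free
    flanks of the local model and yield no event.
    """
    n_match = int(mask.sum())
    k = 0
    for j, c in enumerate(aligned):
        if mask[j]:
            k += 1
            yield ("D" if c == GAP else "M", k)
        elif c != GAP and 1 <= k <= n_match - 1:
            yield ("I", k)


def build_profile(
    aln: SeedAlignment,
    mask: np.ndarray,
    pseudocount_weight: float = 1.0,
    background: np.ndarray | None = None,
    name: str = "profile",
) -> ProfileHMM:
    """Estimate a profile HMM from a seed alignment and a match-column mask.

    Rows carry uniform weight.  Emission estimates are
    ``(counts + pseudocount_weight * background)`` normalised; transition
    estimates are Laplace-smoothed counts of the per-row state paths.
    Transitions without a Plan7 counterpart (I->D, D->I) are dropped from
    the counts.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (aln.n_columns,):
        raise ProfileBuildError("mask length differs from alignment width")
    if pseudocount_weight <= 0:
        raise ProfileBuildError("pseudocount_weight must be positive")
    k = int(mask.sum())
    if k == 0:
        raise ProfileBuildError("mask selects no match columns")
    bg = ROBINSON_FREQUENCIES if background is None else np.asarray(background, float)
    bg = bg / bg.sum()

    m_counts = np.zeros((k, N_AA))
    i_counts = np.zeros((max(k - 1, 1), N_AA))
    t_counts = {n: np.zeros(max(k - 1, 1)) for n in _TRANSITION_NAMES}

    for _, aligned in aln.rows:
        events = list(_row_events(aligned, mask))
        for (s1, k1), (s2, _k2) in zip(events, events[1:]):
            name_ = s1.lower() + s2.lower()
            if name_ in t_counts:
                # transitions are indexed by source anchor k1 (1-based)
                t_counts[name_][k1 - 1] += 1

    # column-wise emission counts
    match_cols = np.flatnonzero(mask)
    cols = [aln.column(j + 1) for j in range(aln.n_columns)]
    for state_i, j in enumerate(match_cols):
        for c in cols[j]:
            if c != GAP:
                m_counts[state_i, AA_INDEX[c]] += 1
    if k > 1:
        anchor = np.cumsum(mask) - mask  # n matches strictly before each column
        for j in range(aln.n_columns):
            if mask[j]:
                continue
            a = int(anchor[j])
            if 1 <= a <= k - 1:
                for c in cols[j]:
                    if c != GAP:
                        i_counts[a - 1, AA_INDEX[c]] += 1

    match_em = m_counts + pseudocount_weight * bg[None, :]
    match_em /= match_em.sum(axis=1, keepdims=True)
    if k > 1:
        ins_em = i_counts + pseudocount_weight * bg[None, :]
        ins_em /= ins_em.sum(axis=1, keepdims=True)
        trans = {}
        for tri in (("mm", "mi", "md"), ("im", "ii"), ("dm", "dd")):
            tot = sum(t_counts[n] for n in tri) + len(tri)  # Laplace: +1 per category
            for n in tri:
                trans[n] = (t_counts[n] + 1.0) / tot
    else:
        ins_em = np.zeros((0, N_AA))
        trans = {n: np.zeros(0) for n in _TRANSITION_NAMES}

    return ProfileHMM(
        name=name,
        match_emissions=match_em,
        insert_emissions=ins_em,
        transitions=trans,
        background=bg,
        match_columns=tuple(int(j) + 1 for j in match_cols),
    )


def profile_from_aligned_rows(
    rows, pseudocount_weight: float = 1.0, background=None, name: str = "profile",
    key_columns: dict | None = None,
) -> ProfileHMM:
    """Build a profile from already match-aligned rows (every column a match
    state; rows may contain gaps, treated as deletions)."""
    aln = SeedAlignment(rows=tuple(rows))
    mask = np.ones(aln.n_columns, dtype=bool)
    prof = build_profile(aln, mask, pseudocount_weight, background, name=name)
    if key_columns:
        prof.key_columns = dict(key_columns)
    return prof
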