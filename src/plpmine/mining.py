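"""The two-pass database search and filter cascade.

Mirrors the discovery procedure for fold type I PLP domains embedded in
NRPS/PKS assembly lines: (1) scan a protein database with the fold type I
search profile and keep hits in sequences longer than 1000 residues whose
alignment covers at least 110 profile match states; (2) annotate domains
with the packaged mini-profile library and keep sequences where a carrier
protein (phosphopantetheine-binding, CP) domain co-occurs with the PLP hit;
(3) excise the PLP domains and re-estimate a profile specialised for the
embedded domains; (4) rescan, now keeping sequences longer than 500
residues, again with coverage >= 110 and CP co-occurrence.

Boundary semantics follow the stated rules literally: length thresholds are
strict (>), the coverage threshold is inclusive (>=).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json

import numpy as np
from Bio import SeqIO

from .alphabet import encode
from .engine import (
    ScoredAlignmentPath,
    pvalue,
    score_viterbi,
    viterbi_score,
)
from .hmm import ProfileHMM, _TRANSITION_NAMES
from .alphabet import N_AA, AA_INDEX

PLP_LABEL = "PLP_typeI"
CP_LABEL = "CP"
FAMILY_NUMBER = {
    "Aminotran_3": "1",
    "Aminotran_1_2": "2",
    "Beta_elim_lyase": "3",
    "Pyridoxal_deC": "4",
}
ARCH_SEP = "–"  # en dash, as in the published architecture strings


class ConfigurationError(ValueError):
    pass


class DataError(ValueError):
    pass


class SpecializationError(ValueError):
    pass


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    residues: str
    description: str = ""

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class MiningConfig:
    """Thresholds of the filter cascade (defaults are the published ones)."""

    min_len_pass1: int = 1000   # strict >
    min_coverage: int = 110     # inclusive >=
    min_len_pass2: int = 500    # strict >
    evalue_max: float | None = 0.01
    rng_seed: int = 0

    def __post_init__(self):
        if min(self.min_len_pass1, self.min_coverage, self.min_len_pass2) <= 0:
            raise ConfigurationError("all thresholds must be positive")
        if self.min_len_pass2 > self.min_len_pass1:
            raise ConfigurationError("min_len_pass2 must not exceed min_len_pass1")


@dataclass(frozen=True)
class DomainCall:
    domain_label: str
    env_start: int
    env_end: int
    bit_score: float
    coverage: int
    source_profile: str = ""


def read_fasta(path) -> list:
    """Read a protein FASTA database; duplicate ids are a hard error."""
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise DataError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        encode(seq)  # validates the alphabet
        records.append(SequenceRecord(id=rec.id, residues=seq, description=rec.description))
    return records


def write_fasta(records, path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), 70):
                fh.write(rec.residues[i : i + 70] + "\n")


def scan_database(profile: ProfileHMM, db, config: MiningConfig):
    """One best-scoring hit per sequence passing the E-value threshold,
    ordered by descending bit score (ties by id)."""
    if config.evalue_max is not None and profile.calibration is None:
        raise ConfigurationError("profile must be calibrated for E-value filtering")
    hits = []
    for rec in db:
        path = score_viterbi(profile, rec.residues)
        if not np.isfinite(path.bit_score):
            continue
        if config.evalue_max is not None:
            mu, lam = profile.calibration
            if pvalue(path.bit_score, mu, lam) > config.evalue_max:
                continue
        hits.append((rec, path))
    hits.sort(key=lambda h: (-h[1].bit_score, h[0].id))
    return hits


def filter_pass1(hits, config: MiningConfig):
    """Keep hits in sequences longer than ``min_len_pass1`` residues whose
    path covers at least ``min_coverage`` match states."""
    return [
        (rec, path)
        for rec, path in hits
        if rec.length > config.min_len_pass1 and path.coverage >= config.min_coverage
    ]


def annotate_domains(
    seq: SequenceRecord,
    library,
    evalue_max: float = 0.01,
    overlap_tolerance: int = 10,
    max_hits_per_profile: int = 8,
    min_coverage_fraction: float = 0.5,
):
    """Locate known domains on a sequence with a profile library.

    ``library`` maps domain labels to calibrated profiles.  Candidate hits
    are collected per profile by iterated Viterbi with envelope masking; a
    hit must cover at least ``min_coverage_fraction`` of its profile's
    match states (suppresses leftover fragments of an already-called
    domain).  Final calls are a greedy non-overlapping assignment: highest
    bit score first, a new call may overlap accepted calls by at most
    ``overlap_tolerance`` residues.  Calls are returned sorted by env_start.
    """
    if not library:
        raise ConfigurationError("empty profile library")
    candidates = []
    n = seq.length
    for label, prof in library.items():
        if prof.calibration is None:
            raise ConfigurationError(f"profile for {label!r} is not calibrated")
        mu, lam = prof.calibration
        allowed = np.ones(n, dtype=bool)
        for _ in range(max_hits_per_profile):
            path = score_viterbi(prof, seq.residues, allowed=allowed)
            if not np.isfinite(path.bit_score):
                break
            if pvalue(path.bit_score, mu, lam) > evalue_max:
                break
            if path.coverage >= min_coverage_fraction * prof.n_match:
                candidates.append(
                    DomainCall(
                        domain_label=label,
                        env_start=path.env_start,
                        env_end=path.env_end,
                        bit_score=path.bit_score,
                        coverage=path.coverage,
                        source_profile=prof.name,
                    )
                )
            allowed[path.env_start - 1 : path.env_end] = False
            if not allowed.any():
                break
    candidates.sort(key=lambda c: (-c.bit_score, c.env_start, c.domain_label))
    accepted = []
    for cand in candidates:
        if all(_overlap(cand, acc) <= overlap_tolerance for acc in accepted):
            accepted.append(cand)
    accepted.sort(key=lambda c: (c.env_start, c.env_end))
    return accepted


def _overlap(a: DomainCall, b: DomainCall) -> int:
    return max(0, min(a.env_end, b.env_end) - max(a.env_start, b.env_start) + 1)


def require_cp_cooccurrence(calls) -> bool:
    """True iff at least one CP call and one PLP type I call are present."""
    labels = {c.domain_label for c in calls}
    return CP_LABEL in labels and PLP_LABEL in labels


def excise_domain(seq: SequenceRecord, call: DomainCall) -> SequenceRecord:
    """Subsequence env_start..env_end (1-based inclusive), id parent/start-end."""
    if not (1 <= call.env_start <= call.env_end <= seq.length):
        raise DataError(
            f"call {call.env_start}-{call.env_end} outside sequence {seq.id} "
            f"of length {seq.length}"
        )
    return SequenceRecord(
        id=f"{seq.id}/{call.env_start}-{call.env_end}",
        residues=seq.residues[call.env_start - 1 : call.env_end],
        description=f"excised from {seq.id}",
    )


def specialize_profile(excised, base_profile: ProfileHMM, pseudocount_weight: float = 1.0):
    """Re-estimate a profile specific for embedded domains.

    Each excised sequence is aligned to ``base_profile`` by Viterbi; the
    implied match/insert/delete paths are stacked and a profile with the
    same number of match states is re-estimated (emissions and transitions,
    with pseudocounts).  If the re-estimate does not improve the mean
    training self-score the base profile is kept, so specialisation never
    degrades recognition of its own training set.
    """
    excised = list(excised)
    if len(excised) < 2:
        raise SpecializationError("need at least 2 excised sequences to specialize")
    k = base_profile.n_match
    bg = base_profile.background
    m_counts = np.zeros((k, N_AA))
    i_counts = np.zeros((max(k - 1, 1), N_AA))
    t_counts = {n: np.zeros(max(k - 1, 1)) for n in _TRANSITION_NAMES}
    base_scores = []
    for rec in excised:
        path = score_viterbi(base_profile, rec.residues)
        base_scores.append(path.bit_score)
        events = []
        pos = path.env_start
        for label in path.state_path:
            state, idx = label[0], int(label[1:])
            events.append((state, idx))
            if state == "M":
                m_counts[idx - 1, AA_INDEX[rec.residues[pos - 1]]] += 1
                pos += 1
            elif state == "I":
                i_counts[idx - 1, AA_INDEX[rec.residues[pos - 1]]] += 1
                pos += 1
        for (s1, k1), (s2, _k2) in zip(events, events[1:]):
            name = s1.lower() + s2.lower()
            if name in t_counts:
                t_counts[name][k1 - 1] += 1

    match_em = m_counts + pseudocount_weight * bg[None, :]
    match_em /= match_em.sum(axis=1, keepdims=True)
    if k > 1:
        ins_em = i_counts + pseudocount_weight * bg[None, :]
        ins_em /= ins_em.sum(axis=1, keepdims=True)
        trans = {}
        for tri in (("mm", "mi", "md"), ("im", "ii"), ("dm", "dd")):
            tot = sum(t_counts[nn] for nn in tri) + len(tri)
            for nn in tri:
                trans[nn] = (t_counts[nn] + 1.0) / tot
    else:
        ins_em = np.zeros((0, N_AA))
        trans = {n: np.zeros(0) for n in _TRANSITION_NAMES}
    specialized = ProfileHMM(
        name=base_profile.name + "_specialized",
        match_emissions=match_em,
        insert_emissions=ins_em,
        transitions=trans,
        background=bg,
        match_columns=base_profile.match_columns,
        key_columns=dict(base_profile.key_columns),
    )
    new_scores = [viterbi_score(specialized, rec.residues) for rec in excised]
    if np.mean(new_scores) >= np.mean(base_scores):
        return specialized
    return base_profile


def filter_pass2(hits, calls_by_id, config: MiningConfig):
    """Final retention rule: length > min_len_pass2, coverage >= min_coverage
    and CP/PLP co-occurrence among the sequence's domain calls."""
    kept = []
    for rec, path in hits:
        if rec.length <= config.min_len_pass2:
            continue
        if path.coverage < config.min_coverage:
            continue
        if not require_cp_cooccurrence(calls_by_id.get(rec.id, [])):
            continue
        kept.append((rec, path))
    return kept


def render_architecture(calls, family_labels=None) -> str:
    """Domain layout string, e.g. ``KS–CP–PLP1``.

    PLP type I calls render as PLP1..PLP4 according to their family
    (Aminotran_3, Aminotran_1_2, Beta_elim_lyase, Pyridoxal_deC) or ``PLP?``
    when unassigned; ``family_labels`` maps the index of each PLP call
    (0-based among PLP calls, in order) to a family name.
    """
    starts = [c.env_start for c in calls]
    if starts != sorted(starts):
        raise DataError("calls must be sorted by env_start")
    family_labels = family_labels or {}
    parts = []
    plp_i = 0
    for call in calls:
        if call.domain_label == PLP_LABEL:
            fam = family_labels.get(plp_i)
            parts.append("PLP" + FAMILY_NUMBER.get(fam, "?"))
            plp_i += 1
        else:
            parts.append(call.domain_label)
    return ARCH_SEP.join(parts)


@dataclass
class MiningReport:
    """Per-sequence outcome of the cascade plus the excised domains."""

    sequences: dict = field(default_factory=dict)
    excised: list = field(default_factory=list)

    def add(self, seq_id, calls=(), pass1_kept=False, cp_cooccurrence=False, pass2_kept=False):
        if pass2_kept and not cp_cooccurrence:
            raise DataError("pass2_kept requires cp_cooccurrence")
        self.sequences[seq_id] = {
            "calls": [asdict(c) for c in calls],
            "pass1_kept": bool(pass1_kept),
            "cp_cooccurrence": bool(cp_cooccurrence),
            "pass2_kept": bool(pass2_kept),
        }

    def to_json(self, path=None) -> str:
        doc = {"sequences": self.sequences, "excised": self.excised}
        text = json.dumps(doc, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "MiningReport":
        if isinstance(source, str) and not source.lstrip().startswith("{"):
            with open(source) as fh:
                doc = json.load(fh)
        else:
            doc = json.loads(source)
        return cls(sequences=doc["sequences"], excised=doc["excised"])
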