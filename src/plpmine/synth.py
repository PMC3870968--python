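"""Seeded synthetic megasynthetase assemblies, decoys and ground truth.

Emulates the study's target proteins: multidomain NRPS/PKS assembly lines
(roughly 800-4000 aa) whose ordered domains are joined by short
low-complexity linkers, with a fold type I PLP domain planted at a
controlled sequence divergence.  Divergence is parameterised as the target
expected p-distance and realised through JTT conditional distributions, the
same evolutionary model the classifier assumes.  Three decoy classes
accompany the positives: stand-alone ~400 aa PLP enzymes, multidomain
proteins lacking any carrier protein, and non-PLP multidomain proteins.

Every operation is deterministic for a fixed seed; generator output is
byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import jtt
from .alphabet import AMINO_ACIDS, N_AA, ROBINSON_FREQUENCIES, decode, encode
from .mining import SequenceRecord

FAMILIES = ("Aminotran_3", "Aminotran_1_2", "Beta_elim_lyase", "Pyridoxal_deC")
PLP = "PLP_typeI"

TRUTH_COLUMNS = ("id", "class", "family", "plp_start", "plp_end", "divergence", "expected_verdict")


class GrammarError(ValueError):
    pass


@dataclass(frozen=True)
class ArchitectureGrammar:
    """Domain vocabulary with length ranges and allowed layouts.

    Length ranges are amino-acid counts typical for each assembly-line
    domain; linkers are 10-40 aa, biased toward A/G/P/S/T.
    """

    vocabulary: dict = field(
        default_factory=lambda: {
            "CP": (70, 90),
            "KS": (400, 440),
            "AT": (290, 320),
            "C": (430, 460),
            "A": (480, 520),
            "KR": (170, 190),
            "TE": (220, 260),
            PLP: (380, 440),
        }
    )
    linker_range: tuple = (10, 40)
    # layouts observed on the published non-redundant assemblies (positives),
    # plus decoy layouts for each decoy class
    positive_layouts: tuple = (
        ("KS", "CP", PLP),
        ("A", "CP", PLP),
        ("CP", PLP, "C"),
        ("KS", "AT", "CP", PLP),
        ("A", "CP", "KS", "AT", "CP", PLP),
        ("A", "CP", "C", PLP),
        ("KR", "CP", PLP),
        ("CP", PLP, "C", "A", "CP"),
    )
    nocp_layouts: tuple = (
        ("KS", "AT", PLP),
        ("A", "C", PLP),
        ("KS", "KR", PLP, "TE"),
    )
    noplp_layouts: tuple = (
        ("KS", "AT", "CP", "C", "A"),
        ("A", "CP", "C", "TE"),
        ("KS", "AT", "CP", "KR", "TE"),
    )

    def min_total_length(self, layout) -> int:
        try:
            body = sum(self.vocabulary[lab][0] for lab in layout)
        except KeyError as exc:
            raise GrammarError(f"unknown domain label {exc.args[0]!r}") from exc
        return body + (len(layout) - 1) * self.linker_range[0]


@dataclass(frozen=True)
class EmbeddingSpec:
    """How the planted PLP domain is diverged from its family consensus."""

    family: str = "Aminotran_3"
    divergence: float = 0.2
    indel_rate: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.divergence < 1.0:
            raise ValueError("divergence must lie in [0, 1)")
        if not 0.0 <= self.indel_rate <= 0.05:
            raise ValueError("indel_rate must lie in [0, 0.05]")
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")


@dataclass(frozen=True)
class TruthRecord:
    id: str
    cls: str  # positive | decoy_standalone | decoy_noCP | decoy_noPLP
    family: str | None
    plp_start: int | None  # 1-based inclusive
    plp_end: int | None
    divergence: float | None
    expected_verdict: str  # pass2_keep | reject


# low-complexity linker composition: A/G/P/S/T-rich
_LINKER_AAS = "AGPST"
_LINKER_P = np.full(N_AA, 0.3 / 15)
for _a in _LINKER_AAS:
    _LINKER_P[AMINO_ACIDS.index(_a)] = 0.7 / 5
_LINKER_P /= _LINKER_P.sum()


def mutate_domain(consensus: str, spec: EmbeddingSpec, frozen=(), site_rates=None) -> str:
    """Diverge a consensus by JTT conditional substitutions and rare indels.

    Substitutions are sampled per position from the JTT transition rows at
    the time whose expected p-distance equals ``spec.divergence``; indels
    (single-residue deletions / 1-3 residue background insertions) occur at
    ``spec.indel_rate`` per position.  Positions in ``frozen`` (0-based) are
    left untouched.  ``site_rates`` optionally scales per-site times (slow
    structurally conserved sites); the overall expected p-distance still
    equals ``spec.divergence``.  Deterministic given ``spec.seed``.
    """
    if not consensus:
        raise ValueError("empty consensus")
    rng = np.random.default_rng(spec.seed)
    codes = encode(consensus)
    frozen = set(frozen)
    if spec.divergence > 0:
        if site_rates is None:
            rates = np.ones(codes.size)
            t = jtt.time_for_pdistance(spec.divergence)
        else:
            rates = np.asarray(site_rates, dtype=float)
            if rates.size != codes.size:
                raise ValueError("site_rates length differs from consensus length")
            t = jtt.time_for_mixture_pdistance(spec.divergence, rates)
        cums = {
            r: np.cumsum(jtt.transition_probabilities(t * r), axis=1)
            for r in np.unique(rates)
        }
        u = rng.random(codes.size)
        new = np.array(
            [
                min(int(np.searchsorted(cums[r][c], ui)), N_AA - 1)
                for c, ui, r in zip(codes, u, rates)
            ]
        )
        keep = np.array([i in frozen for i in range(codes.size)])
        codes = np.where(keep, codes, new)
    out = []
    for i, c in enumerate(codes):
        if spec.indel_rate > 0 and i not in frozen:
            r = rng.random()
            if r < spec.indel_rate / 2:
                continue  # deletion
            out.append(int(c))
            if r >= 1.0 - spec.indel_rate / 2:
                ins_len = int(rng.integers(1, 4))
                out.extend(rng.choice(N_AA, size=ins_len, p=ROBINSON_FREQUENCIES))
        else:
            out.append(int(c))
    return decode(out)


def _consensus_map():
    from . import fixtures  # local import: fixtures loads packaged data only

    cons = {lab: fixtures.domain_consensus(lab) for lab in ("CP", "KS", "AT", "C", "A", "KR", "TE")}
    for fam in FAMILIES:
        cons[fam] = fixtures.family_consensus(fam)
    return cons


def _plp_rates(length: int):
    from . import fixtures

    rates = fixtures.plp_site_rates()
    return rates if rates.size == length else None


def _classify_layout(layout) -> str:
    has_plp = PLP in layout
    has_cp = "CP" in layout
    if has_plp and has_cp:
        return "positive"
    if has_plp and len(layout) == 1:
        return "decoy_standalone"
    if has_plp:
        return "decoy_noCP"
    return "decoy_noPLP"


def generate_assembly(
    layout,
    grammar: ArchitectureGrammar,
    plp_spec: EmbeddingSpec,
    seed: int,
    seq_id: str = "synthetic",
    consensus_map=None,
    aux_divergence: float = 0.2,
):
    """One multidomain record: mutated domain copies joined by linkers.

    The planted PLP domain follows ``plp_spec``; auxiliary domains are
    diverged at ``aux_divergence``.  Returns ``(SequenceRecord,
    TruthRecord)`` with exact 1-based planted-domain coordinates.
    """
    for lab in layout:
        if lab not in grammar.vocabulary:
            raise GrammarError(f"unknown domain label {lab!r}")
    cons = consensus_map if consensus_map is not None else _consensus_map()
    rng = np.random.default_rng(seed)
    pieces = []
    pos = 0
    plp_start = plp_end = None
    for i, lab in enumerate(layout):
        if i > 0:
            lo, hi = grammar.linker_range
            linker_len = int(rng.integers(lo, hi + 1))
            linker = decode(rng.choice(N_AA, size=linker_len, p=_LINKER_P))
            pieces.append(linker)
            pos += linker_len
        sub_seed = int(rng.integers(0, 2**31 - 1))
        if lab == PLP:
            spec = EmbeddingSpec(
                family=plp_spec.family,
                divergence=plp_spec.divergence,
                indel_rate=plp_spec.indel_rate,
                seed=sub_seed if plp_spec.seed == 0 else plp_spec.seed,
            )
            dom = mutate_domain(
                cons[plp_spec.family], spec, site_rates=_plp_rates(len(cons[plp_spec.family]))
            )
            plp_start = pos + 1
            plp_end = pos + len(dom)
        else:
            spec = EmbeddingSpec(family="Aminotran_3", divergence=aux_divergence,
                                 indel_rate=0.01, seed=sub_seed)
            dom = mutate_domain(cons[lab], spec)
        pieces.append(dom)
        pos += len(dom)
    residues = "".join(pieces)
    cls = _classify_layout(layout)
    truth = TruthRecord(
        id=seq_id,
        cls=cls,
        family=plp_spec.family if PLP in layout else None,
        plp_start=plp_start,
        plp_end=plp_end,
        divergence=plp_spec.divergence if PLP in layout else None,
        expected_verdict="pass2_keep" if cls == "positive" else "reject",
    )
    rec = SequenceRecord(id=seq_id, residues=residues, description=f"synthetic {cls}")
    return rec, truth


def generate_benchmark(
    n_per_class: int,
    divergence_grid,
    seed: int,
    grammar: ArchitectureGrammar | None = None,
    indel_rate: float = 0.01,
):
    """The full seeded benchmark: positives across the divergence grid plus
    the three decoy classes in equal number.

    Returns ``(records, truth_frame)``; ``truth_frame`` is a DataFrame with
    the fixed columns id / class / family / plp_start / plp_end /
    divergence / expected_verdict.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    grammar = grammar or ArchitectureGrammar()
    rng = np.random.default_rng(seed)
    records, rows = [], []

    def emit(layout, plp_spec, seq_id):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        rec, truth = generate_assembly(layout, grammar, plp_spec, sub_seed, seq_id=seq_id)
        records.append(rec)
        rows.append(
            {
                "id": truth.id,
                "class": truth.cls,
                "family": truth.family or "",
                "plp_start": truth.plp_start or 0,
                "plp_end": truth.plp_end or 0,
                "divergence": truth.divergence if truth.divergence is not None else np.nan,
                "expected_verdict": truth.expected_verdict,
            }
        )

    for gi, div in enumerate(divergence_grid):
        for i in range(n_per_class):
            layout = grammar.positive_layouts[i % len(grammar.positive_layouts)]
            fam = FAMILIES[i % len(FAMILIES)]
            spec = EmbeddingSpec(family=fam, divergence=float(div), indel_rate=indel_rate)
            emit(layout, spec, f"POS_d{int(round(div * 100)):02d}_{i:03d}")
    for i in range(n_per_class):
        fam = FAMILIES[i % len(FAMILIES)]
        div = float(divergence_grid[i % len(divergence_grid)])
        emit(("PLP_typeI",), EmbeddingSpec(family=fam, divergence=div, indel_rate=indel_rate),
             f"DEC_standalone_{i:03d}")
    for i in range(n_per_class):
        fam = FAMILIES[i % len(FAMILIES)]
        div = float(divergence_grid[i % len(divergence_grid)])
        layout = grammar.nocp_layouts[i % len(grammar.nocp_layouts)]
        emit(layout, EmbeddingSpec(family=fam, divergence=div, indel_rate=indel_rate),
             f"DEC_noCP_{i:03d}")
    for i in range(n_per_class):
        layout = grammar.noplp_layouts[i % len(grammar.noplp_layouts)]
        emit(layout, EmbeddingSpec(divergence=0.2, indel_rate=indel_rate), f"DEC_noPLP_{i:03d}")

    truth = pd.DataFrame(rows, columns=list(TRUTH_COLUMNS))
    return records, truth


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False, float_format="%.4f")


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"family": str}, keep_default_na=False,
                       na_values=[""])
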