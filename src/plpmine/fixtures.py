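"""Loaders for the packaged seed alignments and mini-profiles.

The packaged seed alignment is a synthetic reconstruction honoring the
published structure of the fold type I structure-based alignment: 31 rows
(labelled by the source PDB entries), 13 SCR blocks whose widths sum to 108
columns, long inter-SCR indel regions kept, and an invariant catalytic Asp
at SCR position 69 / Schiff-base Lys at SCR position 85.  The auxiliary
domain seeds (CP, KS, AT, C, A, KR, TE) and the four family seeds are
likewise synthetic; the CP seed carries the conserved-serine
phosphopantetheine attachment motif (GGDSL).  Real seed alignments /
Pfam-derived profiles can be substituted through the same file formats.

All loaders cache; profiles are returned uncalibrated.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources

import numpy as np

from .hmm import ProfileHMM, build_profile
from .seed import (
    SCRAnnotation,
    SeedAlignment,
    define_match_columns,
    read_scr_annotation,
    read_seed_alignment,
    search_column_mask,
)

AUX_LABELS = ("CP", "KS", "AT", "C", "A", "KR", "TE")
FAMILIES = ("Aminotran_3", "Aminotran_1_2", "Beta_elim_lyase", "Pyridoxal_deC")


def _data_path(*parts):
    path = resources.files("plpmine").joinpath("data")
    for part in parts:
        path = path.joinpath(part)
    return path


@lru_cache(maxsize=1)
def _meta() -> dict:
    with _data_path("meta.json").open() as fh:
        return json.load(fh)


@lru_cache(maxsize=1)
def seed_alignment() -> SeedAlignment:
    return read_seed_alignment(str(_data_path("seed_plp_type1.synthetic.afa")))


@lru_cache(maxsize=1)
def scr_annotation() -> SCRAnnotation:
    return read_scr_annotation(str(_data_path("seed_plp_type1.synthetic.scr.tsv")))


def _key_columns_for_mask(mask: np.ndarray) -> dict:
    """Match-state indices (1-based) of the catalytic Asp/Lys columns."""
    meta = _meta()
    cols = np.flatnonzero(mask) + 1
    out = {}
    for key in ("asp", "lys"):
        col = meta[f"{key}_col"]
        where = np.nonzero(cols == col)[0]
        if where.size:
            out[key] = int(where[0]) + 1
    return out


@lru_cache(maxsize=1)
def scr_profile() -> ProfileHMM:
    """The strict SCR-masked profile: one match state per SCR column (108)."""
    aln, scrs = seed_alignment(), scr_annotation()
    mask = define_match_columns(aln, scrs)
    prof = build_profile(aln, mask, name="PLP_domain_scr")
    prof.key_columns = _key_columns_for_mask(mask)
    return prof


@lru_cache(maxsize=1)
def search_profile() -> ProfileHMM:
    """The database-search profile: SCR columns plus low-gap inter-SCR
    columns (gap fraction <= 0.5), as a profile estimated from the
    indel-kept alignment would have."""
    aln, scrs = seed_alignment(), scr_annotation()
    mask = search_column_mask(aln, scrs)
    prof = build_profile(aln, mask, name="PLP_domain")
    prof.key_columns = _key_columns_for_mask(mask)
    return prof


@lru_cache(maxsize=None)
def aux_seed(label: str) -> SeedAlignment:
    if label not in AUX_LABELS:
        raise KeyError(f"unknown auxiliary domain {label!r}")
    return read_seed_alignment(str(_data_path("aux", f"{label}.synthetic.afa")))


@lru_cache(maxsize=None)
def aux_profile(label: str) -> ProfileHMM:
    aln = aux_seed(label)
    mask = np.ones(aln.n_columns, dtype=bool)
    return build_profile(aln, mask, name=label)


@lru_cache(maxsize=None)
def family_seed(family: str) -> SeedAlignment:
    if family not in FAMILIES:
        raise KeyError(f"unknown family {family!r}")
    return read_seed_alignment(str(_data_path("families", f"{family}.synthetic.afa")))


@lru_cache(maxsize=None)
def family_profile(family: str) -> ProfileHMM:
    aln = family_seed(family)
    mask = np.ones(aln.n_columns, dtype=bool)
    prof = build_profile(aln, mask, name=family)
    meta = _meta()
    prof.key_columns = {"asp": meta["asp_col"], "lys": meta["lys_col"]}
    return prof


@lru_cache(maxsize=None)
def family_consensus(family: str) -> str:
    return family_profile(family).consensus()


@lru_cache(maxsize=None)
def domain_consensus(label: str) -> str:
    """Ungapped consensus used by the synthetic generator to plant domains."""
    return aux_profile(label).consensus()


@lru_cache(maxsize=1)
def plp_site_rates() -> np.ndarray:
    """Per-column relative evolutionary rates of the fold type I domain
    (slow SCR core, intermediate flanking core, fast variable regions)."""
    meta = _meta()
    by_kind = meta["rate_by_kind"]
    return np.array([by_kind[k] for k in meta["column_kinds"]])


@lru_cache(maxsize=1)
def reference_sequences():
    """Labelled family reference sequences: list of (id, family, residues)."""
    labels = {}
    with _data_path("families", "references.labels.tsv").open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("id"):
                continue
            rid, fam = line.split("\t")
            labels[rid] = fam
    aln = read_seed_alignment(str(_data_path("families", "references.synthetic.fasta")))
    return [(rid, labels[rid], seq.replace("-", "")) for rid, seq in aln.rows]
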