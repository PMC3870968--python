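"""Seed alignments and structurally conserved region (SCR) annotations.

A seed alignment is a gapped multiple alignment of reference fold type I
sequences; the SCR annotation marks the alignment blocks that correspond to
the structurally conserved core shared by all superposed structures.  Match
states of the profile HMM are anchored on these blocks (optionally extended
by low-gap inter-block columns, see :func:`match_column_mask`).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
from Bio import SeqIO

from .alphabet import GAP, validate_gapped


class AlignmentFormatError(ValueError):
    """Malformed alignment input (ragged rows, duplicate ids, bad blocks)."""


@dataclass(frozen=True)
class SeedAlignment:
    """A multiple protein alignment with row identifiers.

    ``rows`` is an ordered list of ``(sequence_id, aligned_sequence)``; all
    aligned sequences share the same number of columns.
    """

    rows: tuple = ()
    n_columns: int = 0

    def __post_init__(self):
        if not self.rows:
            raise AlignmentFormatError("alignment has no rows")
        lengths = {len(s) for _, s in self.rows}
        if len(lengths) != 1:
            raise AlignmentFormatError(f"ragged alignment rows: lengths {sorted(lengths)}")
        ids = [i for i, _ in self.rows]
        if len(set(ids)) != len(ids):
            raise AlignmentFormatError("duplicate sequence ids in alignment")
        object.__setattr__(self, "n_columns", lengths.pop())

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def column(self, j: int) -> str:
        """1-based column as a string of residues/gaps."""
        return "".join(s[j - 1] for _, s in self.rows)

    def gap_fraction(self) -> np.ndarray:
        mat = np.array([list(s) for _, s in self.rows])
        return (mat == GAP).mean(axis=0)


@dataclass(frozen=True)
class SCRAnnotation:
    """Ordered, non-overlapping 1-based inclusive column blocks."""

    blocks: tuple = ()

    def __post_init__(self):
        prev_end = 0
        for idx, (num, start, end) in enumerate(self.blocks, start=1):
            if num != idx:
                raise AlignmentFormatError("SCR blocks must be numbered 1..n in order")
            if not (1 <= start <= end):
                raise AlignmentFormatError(f"bad SCR block ({num},{start},{end})")
            if start <= prev_end:
                raise AlignmentFormatError("SCR blocks overlap or are out of order")
            prev_end = end

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def total_width(self) -> int:
        return sum(e - s + 1 for _, s, e in self.blocks)

    def columns(self):
        for _, s, e in self.blocks:
            yield from range(s, e + 1)


def read_seed_alignment(path, format: str = "afa") -> SeedAlignment:
    """Read a seed alignment.

    ``format`` is ``"afa"`` (aligned FASTA) or ``"stockholm"`` (a
    Stockholm-like block format whose ``#=GC SCR`` line carries the SCR mask;
    use :func:`read_stockholm` to recover the annotation too).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format == "afa":
        rows = tuple(
            (rec.id, validate_gapped(str(rec.seq))) for rec in SeqIO.parse(str(path), "fasta")
        )
        return SeedAlignment(rows=rows)
    if format == "stockholm":
        aln, _ = read_stockholm(path)
        return aln
    raise ValueError(f"unknown alignment format {format!r}")


def read_stockholm(path):
    """Read the Stockholm-like format: ``name  gappedseq`` lines, optional
    ``#=GC SCR`` annotation line marking SCR columns with ``x``.

    Returns ``(SeedAlignment, SCRAnnotation or None)``.
    """
    names: list = []
    seqs: dict = {}
    scr_line: list = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("# STOCKHOLM", "//")):
                continue
            if line.startswith("#=GC"):
                parts = line.split()
                if len(parts) >= 3 and parts[1] == "SCR":
                    scr_line.append(parts[2])
                continue
            if line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise AlignmentFormatError(f"unparseable line: {line!r}")
            name, chunk = parts
            if name not in seqs:
                names.append(name)
                seqs[name] = []
            seqs[name].append(validate_gapped(chunk))
    rows = tuple((n, "".join(seqs[n])) for n in names)
    aln = SeedAlignment(rows=rows)
    scrs = None
    if scr_line:
        mask_str = "".join(scr_line)
        if len(mask_str) != aln.n_columns:
            raise AlignmentFormatError("SCR annotation length differs from alignment")
        scrs = scr_from_mask(np.array([c == "x" for c in mask_str]))
    return aln, scrs


def read_scr_annotation(path) -> SCRAnnotation:
    """Read SCR blocks from a TSV with columns index, start_col, end_col."""
    blocks = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("index"):
                continue
            num, start, end = (int(x) for x in line.split("\t"))
            blocks.append((num, start, end))
    return SCRAnnotation(blocks=tuple(blocks))


def write_scr_annotation(scrs: SCRAnnotation, path) -> None:
    with open(path, "w") as fh:
        fh.write("index\tstart_col\tend_col\n")
        for num, s, e in scrs.blocks:
            fh.write(f"{num}\t{s}\t{e}\n")


def write_seed_alignment(aln: SeedAlignment, path) -> None:
    with open(path, "w") as fh:
        for name, seq in aln.rows:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def scr_from_mask(mask: np.ndarray) -> SCRAnnotation:
    """Convert a boolean column mask into numbered contiguous blocks."""
    blocks = []
    j = 0
    n = len(mask)
    while j < n:
        if mask[j]:
            start = j
            while j < n and mask[j]:
                j += 1
            blocks.append((len(blocks) + 1, start + 1, j))
        else:
            j += 1
    return SCRAnnotation(blocks=tuple(blocks))


def define_match_columns(aln: SeedAlignment, scrs: SCRAnnotation) -> np.ndarray:
    """Boolean per-column mask: True exactly on columns inside SCR blocks.

    Columns outside the mask are treated as insert regions when a profile is
    built.  Blocks must lie within the alignment.
    """
    for num, s, e in scrs.blocks:
        if e > aln.n_columns:
            raise AlignmentFormatError(
                f"SCR block {num} ({s}-{e}) outside alignment of {aln.n_columns} columns"
            )
    mask = np.zeros(aln.n_columns, dtype=bool)
    for col in scrs.columns():
        mask[col - 1] = True
    return mask


def search_column_mask(
    aln: SeedAlignment, scrs: SCRAnnotation, max_gap_fraction: float = 0.5
) -> np.ndarray:
    """Match-column mask for database searching.

    The SCR columns plus every inter-block column whose gap fraction is at
    most ``max_gap_fraction`` — the same rule HMMER applies when a profile is
    estimated from an alignment in which long indels were kept.  The
    resulting profile is longer than the SCR-only one, so a coverage
    threshold above the SCR width remains satisfiable while still implying
    that the conserved core was matched.
    """
    mask = define_match_columns(aln, scrs)
    return mask | (aln.gap_fraction() <= max_gap_fraction)
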