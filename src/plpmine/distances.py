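"""Pairwise identity, redundancy pruning and JTT evolutionary distances.

Identity follows the EMBOSS convention: one optimal global alignment
(BLOSUM62, affine gaps), identical pairs divided by the full alignment
length including gap columns.  Redundancy pruning removes sequences sharing
more than a threshold identity (default 70%), discarding the shorter member
of each offending pair.  Evolutionary distances are maximum-likelihood
scalings of the JTT model after complete deletion of gapped columns.
"""

from __future__ import annotations

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from skbio import DistanceMatrix

from . import jtt
from .alphabet import AA_INDEX, GAP


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def pairwise_identity(a: str, b: str, aligner: Align.PairwiseAligner | None = None) -> float:
    """Percent identity over one optimal global alignment (full alignment
    length as denominator, gap columns included)."""
    if not a or not b:
        raise ValueError("empty sequence")
    aligner = aligner or _aligner()
    aln = aligner.align(a, b)[0]
    s1, s2 = str(aln[0]), str(aln[1])
    same = sum(1 for x, y in zip(s1, s2) if x == y and x != GAP)
    return 100.0 * same / len(s1)


def remove_redundant(seqs, threshold_percent: float = 70.0):
    """Greedy redundancy pruning of ``(id, sequence)`` pairs.

    Pairs above the identity threshold are processed in input order and the
    shorter member discarded (on equal length, the later one).  The retained
    subset contains no pair above the threshold; deterministic for a fixed
    input order.
    """
    if not 0 < threshold_percent <= 100:
        raise ValueError("threshold must lie in (0, 100]")
    seqs = list(seqs)
    aligner = _aligner()
    alive = [True] * len(seqs)
    for i in range(len(seqs)):
        if not alive[i]:
            continue
        for j in range(i + 1, len(seqs)):
            if not (alive[i] and alive[j]):
                continue
            ident = pairwise_identity(seqs[i][1], seqs[j][1], aligner)
            if ident > threshold_percent:
                drop = j if len(seqs[j][1]) <= len(seqs[i][1]) else i
                alive[drop] = False
        if not alive[i]:
            continue
    return [sq for sq, a in zip(seqs, alive) if a]


class GapDeletionError(ValueError):
    pass


def complete_deletion(rows: list) -> np.ndarray:
    """Drop every column containing a gap in any row; returns an int-coded
    (n_rows, n_kept_columns) matrix."""
    mat = np.array([list(s) for s in rows])
    keep = ~np.any(mat == GAP, axis=0)
    if not keep.any():
        raise GapDeletionError("complete gap deletion removed all columns")
    coded = np.vectorize(AA_INDEX.get)(mat[:, keep])
    return coded.astype(np.int64)


def jtt_distance(msa) -> DistanceMatrix:
    """JTT maximum-likelihood distance matrix from ``(id, gapped_row)``
    pairs, after complete deletion of gap-containing columns.

    Saturated pairs are capped at :data:`plpmine.jtt.MAX_DISTANCE`; capped
    pairs are recorded on the returned matrix as ``saturated_pairs``.
    """
    msa = list(msa)
    if len(msa) < 2:
        raise ValueError("need at least two rows")
    ids = [i for i, _ in msa]
    coded = complete_deletion([s for _, s in msa])
    n = len(ids)
    d = np.zeros((n, n))
    saturated = []
    for i in range(n):
        for j in range(i + 1, n):
            counts = np.zeros((20, 20))
            np.add.at(counts, (coded[i], coded[j]), 1.0)
            counts = 0.5 * (counts + counts.T)  # reversible model: symmetrise
            dist, flagged = jtt.ml_distance(counts)
            d[i, j] = d[j, i] = dist
            if flagged:
                saturated.append((ids[i], ids[j]))
    dm = DistanceMatrix(d, ids=ids)
    dm.saturated_pairs = saturated
    return dm


def write_phylip(dm: DistanceMatrix, path) -> None:
    """Write a distance matrix in PHYLIP square format."""
    with open(path, "w") as fh:
        fh.write(f"{len(dm.ids)}\n")
        for i, name in enumerate(dm.ids):
            row = " ".join(f"{dm.data[i, j]:.6f}" for j in range(len(dm.ids)))
            fh.write(f"{name:<10s} {row}\n")


def p_distance_matrix(msa) -> DistanceMatrix:
    """Plain proportion-of-differences matrix after complete deletion
    (used as the lower bound / sanity companion of the JTT distances)."""
    msa = list(msa)
    ids = [i for i, _ in msa]
    coded = complete_deletion([s for _, s in msa])
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = float(np.mean(coded[i] != coded[j]))
    return DistanceMatrix(d, ids=ids)
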