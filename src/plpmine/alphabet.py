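"""Amino-acid alphabet, encoding helpers and background frequencies.

The canonical residue order used throughout the package is the one
substitution-matrix literature uses (``ARNDCQEGHILKMFPSTWYV``).  Gaps are
``-`` (``.`` is accepted on input and normalised to ``-``).
"""

from __future__ import annotations

import numpy as np

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
GAP = "-"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
N_AA = 20

# Robinson & Robinson (1991) amino-acid background frequencies, the default
# null model for log-odds scoring (overridable wherever a background is taken).
ROBINSON_FREQUENCIES = np.array(
    [
        0.07805, 0.05129, 0.04487, 0.05364, 0.01925,
        0.04264, 0.06295, 0.07377, 0.02199, 0.05142,
        0.09019, 0.05744, 0.02243, 0.03856, 0.05203,
        0.07120, 0.05841, 0.01330, 0.03216, 0.06441,
    ]
)
ROBINSON_FREQUENCIES = ROBINSON_FREQUENCIES / ROBINSON_FREQUENCIES.sum()


class AlphabetError(ValueError):
    """A sequence or alignment contains a character outside the alphabet."""


def encode(seq: str) -> np.ndarray:
    """Encode a residue string as an int array (0..19).

    Raises
    ------
    AlphabetError
        If ``seq`` contains anything other than the 20 standard residues.
    """
    try:
        return np.array([AA_INDEX[c] for c in seq.upper()], dtype=np.int64)
    except KeyError as exc:
        raise AlphabetError(f"illegal residue character {exc.args[0]!r}") from exc


def decode(codes) -> str:
    return "".join(AMINO_ACIDS[int(c)] for c in codes)


def validate_gapped(row: str) -> str:
    """Normalise and validate one gapped alignment row ('.' -> '-')."""
    row = row.upper().replace(".", GAP)
    for c in row:
        if c != GAP and c not in AA_INDEX:
            raise AlphabetError(f"illegal residue character {c!r}")
    return row
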