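"""Family assignment of excised PLP type I domains and catalytic-residue checks.

The four families are the Pfam-named groups the embedded domains partition
into: Aminotran_3, Aminotran_1_2, Beta_elim_lyase and Pyridoxal_deC.
Assignment runs either by profile competition (best Forward bit score among
the four family profiles, unassigned on a sub-1-bit margin) or by clade
membership (the family of the references sharing the smallest surrounding
clade in the JTT/minimum-evolution tree, unassigned when that clade mixes
families).

Every fold type I domain carries a catalytic aspartate (contacts the
cofactor pyridine nitrogen) and the Schiff-base lysine; the key-residue
check reports what a domain aligns to those profile columns.
"""

from __future__ import annotations

from dataclasses import dataclass

from .distances import jtt_distance
from .engine import score_forward, score_viterbi
from .hmm import ProfileHMM
from .tree import PhyloTree, me_tree

FAMILIES = ("Aminotran_3", "Aminotran_1_2", "Beta_elim_lyase", "Pyridoxal_deC")


class FamilyConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class FamilyAssignment:
    domain_id: str
    family: str | None  # None = explicitly unassigned
    method: str  # "clade" | "profile_competition"
    support: float


@dataclass(frozen=True)
class KeyResidueReport:
    domain_id: str
    asp_residue: str  # residue aligned to the catalytic Asp column, or "-"
    schiff_lys: str   # residue aligned to the Schiff-base Lys column, or "-"
    flagged: bool     # a catalytic column was deleted / outside the envelope

    @property
    def asp_conserved(self) -> bool:
        return self.asp_residue == "D"


def profile_align_rows(base_profile: ProfileHMM, seqs):
    """Implicit multiple alignment: Viterbi-align each ``(id, residues)``
    to the profile and stack the match-column residues (the hmmalign
    equivalent used before distance computation)."""
    rows = []
    k = base_profile.n_match
    for sid, residues in seqs:
        path = score_viterbi(base_profile, residues)
        row = ["-"] * k
        pos = path.env_start
        for label in path.state_path:
            state, idx = label[0], int(label[1:])
            if state == "M":
                row[idx - 1] = residues[pos - 1]
                pos += 1
            elif state == "I":
                pos += 1
        rows.append((sid, "".join(row)))
    return rows


def assign_family(
    domains,
    references,
    mode: str = "profile_competition",
    family_profiles: dict | None = None,
    base_profile: ProfileHMM | None = None,
    tree: PhyloTree | None = None,
    margin_bits: float = 1.0,
):
    """Assign each ``(id, residues)`` domain to one of the four families.

    ``references`` is a list of ``(id, family, residues)``; all four
    families must be represented.  In ``profile_competition`` mode the
    domain goes to the family profile with the best Forward bit score
    (support = margin over the runner-up; ties within ``margin_bits`` are
    unassigned).  In ``clade`` mode the domain takes the family of the
    reference(s) in its smallest surrounding clade of ``tree`` (built from
    ``base_profile``-aligned rows when not supplied); a clade mixing
    families yields an explicit unassigned verdict.
    """
    ref_families = {fam for _, fam, _ in references}
    missing = set(FAMILIES) - ref_families
    if missing:
        raise FamilyConfigurationError(f"references missing families: {sorted(missing)}")
    ref_family_of = {rid: fam for rid, fam, _ in references}

    out = []
    if mode == "profile_competition":
        if not family_profiles or set(family_profiles) != set(FAMILIES):
            raise FamilyConfigurationError("need one profile per family")
        for did, residues in domains:
            if did in ref_family_of:
                out.append(FamilyAssignment(did, ref_family_of[did], mode, 100.0))
                continue
            scores = {
                fam: score_forward(family_profiles[fam], residues) for fam in FAMILIES
            }
            ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
            margin = ranked[0][1] - ranked[1][1]
            fam = ranked[0][0] if margin >= margin_bits else None
            out.append(FamilyAssignment(did, fam, mode, float(margin)))
        return out

    if mode != "clade":
        raise FamilyConfigurationError(f"unknown assignment mode {mode!r}")

    if tree is None:
        if base_profile is None:
            raise FamilyConfigurationError("clade mode needs a tree or a base profile")
        rows = profile_align_rows(
            base_profile,
            list(domains) + [(rid, res) for rid, _f, res in references],
        )
        tree = me_tree(jtt_distance(rows))

    taxa = frozenset(tree.taxa)
    all_splits = tree.splits(include_trivial=True)
    for did, _residues in domains:
        if did in ref_family_of:
            out.append(FamilyAssignment(did, ref_family_of[did], mode, 100.0))
            continue
        # nested clades around the domain, smallest first
        sides = []
        for split in all_splits:
            for side in (split, taxa - split):
                if did in side:
                    sides.append(side)
        sides.sort(key=lambda s: (len(s), sorted(s)))
        fam, support = None, 0.0
        for side in sides:
            fams = {ref_family_of[t] for t in side if t in ref_family_of}
            if not fams:
                continue
            if len(fams) == 1:
                fam = fams.pop()
                inner = side if min(taxa) not in side else taxa - side
                support = float(tree.supports.get(inner, 100.0))
            break  # smallest clade containing any reference decides
        out.append(FamilyAssignment(did, fam, mode, support))
    return out


def check_key_residues(domain_id: str, residues: str, family_profile: ProfileHMM) -> KeyResidueReport:
    """Report the residues a domain aligns to the catalytic Asp and
    Schiff-base Lys match columns of a family profile."""
    keys = family_profile.key_columns
    if "asp" not in keys or "lys" not in keys:
        raise FamilyConfigurationError("profile lacks annotated asp/lys columns")
    path = score_viterbi(family_profile, residues)
    aligned = {}
    pos = path.env_start
    for label in path.state_path:
        state, idx = label[0], int(label[1:])
        if state == "M":
            aligned[idx] = residues[pos - 1]
            pos += 1
        elif state == "I":
            pos += 1
    asp = aligned.get(keys["asp"], "-")
    lys = aligned.get(keys["lys"], "-")
    return KeyResidueReport(
        domain_id=domain_id,
        asp_residue=asp,
        schiff_lys=lys,
        flagged=(asp == "-" or lys == "-"),
    )
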