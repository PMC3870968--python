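"""Regenerate the packaged synthetic seed data (deterministic).

Writes, under src/plpmine/data/:
  seed_plp_type1.synthetic.afa / .scr.tsv   the fold type I seed alignment:
      31 rows named after the source PDB entries, 13 SCR blocks of total
      width 108, kept inter-SCR indel regions, invariant Asp (SCR pos 69)
      and Lys (SCR pos 85)
  families/<family>.synthetic.afa           four family seed alignments
  families/references.synthetic.fasta/.labels.tsv  labelled references
  aux/<label>.synthetic.afa                 mini seeds for CP/KS/AT/C/A/KR/TE
  meta.json                                 key-column bookkeeping

Run from the repository root:  python scripts/build_fixtures.py
"""

import json
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from plpmine import jtt
from plpmine.alphabet import AMINO_ACIDS, N_AA, ROBINSON_FREQUENCIES, decode
from plpmine.seed import SCRAnnotation, SeedAlignment, write_scr_annotation, write_seed_alignment

DATA = Path(__file__).resolve().parents[1] / "src" / "plpmine" / "data"

MASTER_SEED = 20130101

SCR_WIDTHS = [10, 9, 8, 7, 9, 8, 6, 10, 9, 7, 8, 9, 8]          # sum 108
CORE_WIDTHS = [3, 4, 3, 2, 4, 3, 3, 4, 3, 4, 4, 3]              # sum 40
VAR_WIDTHS = [15, 20, 15, 12, 25, 18, 12, 25, 20, 15, 25, 18]   # sum 220
N_FLANK, C_FLANK = 20, 40

ROW_NAMES = [
    "1AX4", "1B9H", "1BJ4", "1BJN", "1BJW", "1BS0", "1C7N", "1CL1", "1D2F",
    "1DGD", "1DTY", "1ECX", "1ELQ", "1FG3", "1H0C", "1IAX", "1JS6", "1LK9",
    "1MDX", "1OAT", "1QGN", "1SF2", "1WKG", "2BWP", "2FM1", "2GSA", "2JG2",
    "2NMP", "3BWO", "3EI7", "3FZ8",
]

FAMILIES = ("Aminotran_3", "Aminotran_1_2", "Beta_elim_lyase", "Pyridoxal_deC")
AUX_LENGTHS = {"CP": 80, "KS": 420, "AT": 300, "C": 445, "A": 500, "KR": 180, "TE": 240}
CP_MOTIF, CP_MOTIF_AT = "GGDSL", 30  # phosphopantetheine attachment serine motif

SEED_ROW_DIV = 0.5     # seed-row divergence from the master (before rates)
FAMILY_DIV = 0.35      # family masters from the overall master
FAMILY_SEED_DIV = 0.25
REFERENCE_DIV = 0.20
AUX_SEED_DIV = 0.20
CORE_PRESENT = 0.85
VAR_PRESENT = 0.35

# Site-rate heterogeneity: structurally conserved columns evolve slower
# (that is what makes a superfamily profile informative).  Multipliers on
# the JTT time implied by the nominal divergence.  Chosen so that the
# reconstructed profile, like the published one, still recovers embedded
# domains down to ~25-40% overall identity to the references.
RATE_BY_KIND = {"scr": 0.3, "core": 0.6, "var": 1.0}


def column_layout():
    """Return (kinds, scr_blocks): per-column kind in {scr, core, var} and the
    1-based SCR blocks."""
    kinds = ["var"] * N_FLANK
    blocks = []
    for i, w in enumerate(SCR_WIDTHS):
        start = len(kinds) + 1
        kinds += ["scr"] * w
        blocks.append((i + 1, start, start + w - 1))
        if i < 12:
            kinds += ["core"] * CORE_WIDTHS[i]
            kinds += ["var"] * VAR_WIDTHS[i]
    kinds += ["var"] * C_FLANK
    return kinds, blocks


def jtt_mutate(rng, codes, pdist, frozen, rates=None):
    """Mutate ``codes`` by JTT conditionals at the time implied by ``pdist``,
    optionally scaled per-position by ``rates``; ``frozen`` positions kept."""
    if pdist == 0:
        return codes.copy()
    t = jtt.time_for_pdistance(pdist)
    if rates is None:
        rates = np.ones(codes.size)
    cums = {r: np.cumsum(jtt.transition_probabilities(t * r), axis=1)
            for r in sorted(set(rates.tolist()))}
    u = rng.random(codes.size)
    out = codes.copy()
    for i in range(codes.size):
        if i in frozen:
            continue
        out[i] = min(int(np.searchsorted(cums[rates[i]][codes[i]], u[i])), N_AA - 1)
    return out


def main():
    rng = np.random.default_rng(MASTER_SEED)
    kinds, blocks = column_layout()
    n_cols = len(kinds)
    scr_positions = [j for j, kind in enumerate(kinds) if kind == "scr"]
    asp_col = scr_positions[69 - 1] + 1   # 1-based column of SCR position 69
    lys_col = scr_positions[85 - 1] + 1   # 1-based column of SCR position 85

    master = rng.choice(N_AA, size=n_cols, p=jtt.JTT_FREQUENCIES)
    master[asp_col - 1] = AMINO_ACIDS.index("D")
    master[lys_col - 1] = AMINO_ACIDS.index("K")
    frozen_master = {asp_col - 1, lys_col - 1}
    rates = np.array([RATE_BY_KIND[k] for k in kinds])

    # --- seed alignment rows -------------------------------------------
    rows = []
    for name in ROW_NAMES:
        mutated = jtt_mutate(rng, master, SEED_ROW_DIV, frozen_master, rates)
        chars = []
        for j, kind in enumerate(kinds):
            if kind == "scr":
                chars.append(AMINO_ACIDS[mutated[j]])
            elif kind == "core":
                if rng.random() < CORE_PRESENT:
                    chars.append(AMINO_ACIDS[mutated[j]])
                else:
                    chars.append("-")
            else:  # var: unrelated indel content
                if rng.random() < VAR_PRESENT:
                    chars.append(AMINO_ACIDS[rng.choice(N_AA, p=ROBINSON_FREQUENCIES)])
                else:
                    chars.append("-")
        rows.append((name, "".join(chars)))
    aln = SeedAlignment(rows=tuple(rows))
    scrs = SCRAnnotation(blocks=tuple(blocks))
    DATA.mkdir(parents=True, exist_ok=True)
    write_seed_alignment(aln, DATA / "seed_plp_type1.synthetic.afa")
    write_scr_annotation(scrs, DATA / "seed_plp_type1.synthetic.scr.tsv")

    # --- family masters, seeds and references --------------------------
    (DATA / "families").mkdir(exist_ok=True)
    fam_masters = {}
    for fam in FAMILIES:
        fam_masters[fam] = jtt_mutate(rng, master, FAMILY_DIV, frozen_master, rates)
    for fam in FAMILIES:
        fam_rows = [
            (f"{fam}_seed{i+1}",
             decode(jtt_mutate(rng, fam_masters[fam], FAMILY_SEED_DIV, frozen_master, rates)))
            for i in range(6)
        ]
        write_seed_alignment(SeedAlignment(rows=tuple(fam_rows)), DATA / "families" / f"{fam}.synthetic.afa")
    ref_rows, ref_labels = [], []
    for fam in FAMILIES:
        for i in range(2):
            rid = f"{fam}_ref{i+1}"
            ref_rows.append(
                (rid, decode(jtt_mutate(rng, fam_masters[fam], REFERENCE_DIV, frozen_master, rates)))
            )
            ref_labels.append((rid, fam))
    write_seed_alignment(SeedAlignment(rows=tuple(ref_rows)), DATA / "families" / "references.synthetic.fasta")
    with open(DATA / "families" / "references.labels.tsv", "w") as fh:
        fh.write("id\tfamily\n")
        for rid, fam in ref_labels:
            fh.write(f"{rid}\t{fam}\n")

    # --- auxiliary domain seeds ----------------------------------------
    (DATA / "aux").mkdir(exist_ok=True)
    for label, length in AUX_LENGTHS.items():
        m = rng.choice(N_AA, size=length, p=ROBINSON_FREQUENCIES)
        frozen = set()
        if label == "CP":
            for k, c in enumerate(CP_MOTIF):
                m[CP_MOTIF_AT + k] = AMINO_ACIDS.index(c)
                frozen.add(CP_MOTIF_AT + k)
        aux_rows = [
            (f"{label}_seed{i+1}", decode(jtt_mutate(rng, m, AUX_SEED_DIV, frozen)))
            for i in range(6)
        ]
        write_seed_alignment(SeedAlignment(rows=tuple(aux_rows)), DATA / "aux" / f"{label}.synthetic.afa")

    with open(DATA / "meta.json", "w") as fh:
        json.dump(
            {
                "asp_col": asp_col,
                "lys_col": lys_col,
                "n_columns": n_cols,
                "generator_seed": MASTER_SEED,
                "column_kinds": "".join(k[0] for k in kinds),  # s/c/v per column
                "rate_by_kind": {k[0]: RATE_BY_KIND[k] for k in RATE_BY_KIND},
            },
            fh,
            indent=1,
        )
    print(f"wrote fixtures: {n_cols} columns, asp_col={asp_col}, lys_col={lys_col}")


if __name__ == "__main__":
    main()
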