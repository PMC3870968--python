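"""End-to-end orchestration: scan, filter cascade, specialisation,
classification, architecture rendering and benchmark evaluation.

``run_pipeline`` executes the full discovery procedure on a FASTA database
and writes every intermediate artifact (hit tables, domain calls, excised
domains, the non-redundant subset, family assignments, key-residue report,
architecture strings, an optional bootstrap tree and a summary JSON).
Stage counts are logged and weakly decreasing along the cascade; runs are
deterministic for a fixed configuration and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import fixtures
from .distances import remove_redundant
from .engine import calibrate_evalues
from .families import (
    FAMILIES,
    assign_family,
    check_key_residues,
    profile_align_rows,
)
from .hmm import ProfileHMM
from .mining import (
    PLP_LABEL,
    ConfigurationError,
    DataError,
    MiningConfig,
    MiningReport,
    annotate_domains,
    excise_domain,
    filter_pass1,
    filter_pass2,
    read_fasta,
    render_architecture,
    require_cp_cooccurrence,
    scan_database,
    specialize_profile,
    write_fasta,
)
from .tree import bootstrap_consensus

log = logging.getLogger("plpmine")


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    ``db_path`` may be None when ``records`` are handed in directly (the
    benchmark path).  Packaged profiles are used unless explicit profile
    JSON paths are given.
    """

    db_path: str | None = None
    out_dir: str | None = None
    mining: MiningConfig = field(default_factory=MiningConfig)
    profile_path: str | None = None
    classify_mode: str = "profile_competition"  # or "clade"
    bootstrap_replicates: int = 0  # 0: skip the bootstrap tree
    redundancy_threshold: float = 70.0
    calibration_n: int = 1000
    calibration_length: int = 400
    seed: int = 0
    truth_path: str | None = None


@dataclass
class SummaryReport:
    """Stage counts, family tally, architectures and benchmark metrics."""

    counts: dict = field(default_factory=dict)
    family_tally: dict = field(default_factory=dict)
    architectures: dict = field(default_factory=dict)
    assignments: dict = field(default_factory=dict)
    metrics: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "SummaryReport":
        doc = json.loads(Path(source).read_text()) if Path(str(source)).exists() else json.loads(source)
        return cls(**doc)


def _calibrated_library(config: RunConfig, search_profile: ProfileHMM) -> dict:
    """The annotation library: the PLP search profile plus the auxiliary
    mini-profiles, all Gumbel-calibrated with seeds derived from the run seed."""
    rng = np.random.default_rng(config.seed)
    library = {PLP_LABEL: search_profile}
    for label in fixtures.AUX_LABELS:
        library[label] = fixtures.aux_profile(label)
    for label in sorted(library):
        prof = library[label]
        if prof.calibration is None:
            prof.calibration = calibrate_evalues(
                prof, config.calibration_n, config.calibration_length,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            log.info("calibrated %s: mu=%.2f lambda=%.3f", label, *prof.calibration)
    return library


def run_pipeline(config: RunConfig, records=None) -> SummaryReport:
    """Execute scan -> pass1 -> annotate -> CP co-occurrence -> excise ->
    specialize -> rescan -> pass2 -> redundancy -> classify -> render."""
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    if records is None:
        if config.db_path is None:
            raise ConfigurationError("either db_path or records must be given")
        records = read_fasta(config.db_path)
    records = list(records)

    if config.profile_path:
        search_profile = ProfileHMM.from_json(config.profile_path)
    else:
        search_profile = fixtures.search_profile()
    library = _calibrated_library(config, search_profile)
    rng = np.random.default_rng(config.seed + 1)

    counts = {"scanned": len(records)}
    report = MiningReport()
    annotation_cache: dict = {}

    def annotate(rec):
        if rec.id not in annotation_cache:
            annotation_cache[rec.id] = annotate_domains(
                rec, library, evalue_max=config.mining.evalue_max or 0.01
            )
        return annotation_cache[rec.id]

    # pass 1: scan with the seed-derived search profile
    hits1 = scan_database(search_profile, records, config.mining)
    counts["hits"] = len(hits1)
    kept1 = filter_pass1(hits1, config.mining)
    counts["pass1"] = len(kept1)
    log.info("scan: %d sequences, %d hits, %d pass the length/coverage filter",
             counts["scanned"], counts["hits"], counts["pass1"])

    # CP co-occurrence on pass-1 survivors; excise their PLP domains
    excised_train = []
    cp_ok_ids = set()
    for rec, _path in kept1:
        calls = annotate(rec)
        if require_cp_cooccurrence(calls):
            cp_ok_ids.add(rec.id)
            for call in calls:
                if call.domain_label == PLP_LABEL:
                    excised_train.append(excise_domain(rec, call))
    counts["cp_cooccur"] = len(cp_ok_ids)
    log.info("CP co-occurrence: %d of %d pass-1 sequences", counts["cp_cooccur"], counts["pass1"])

    # specialisation (falls back to the search profile when too few domains)
    if len(excised_train) >= 2:
        specialized = specialize_profile(excised_train, search_profile)
    else:
        specialized = search_profile
        log.info("too few excised domains (%d); rescanning with the base profile",
                 len(excised_train))
    if specialized.calibration is None:
        specialized.calibration = calibrate_evalues(
            specialized, config.calibration_n, config.calibration_length,
            seed=int(rng.integers(0, 2**31 - 1)),
        )

    # pass 2: rescan everything with the specialised profile
    hits2 = scan_database(specialized, records, config.mining)
    calls_by_id = {}
    for rec, path in hits2:
        if rec.length > config.mining.min_len_pass2 and path.coverage >= config.mining.min_coverage:
            calls_by_id[rec.id] = annotate(rec)
    kept2 = filter_pass2(hits2, calls_by_id, config.mining)
    counts["pass2"] = len(kept2)
    log.info("pass 2: %d hits, %d retained", len(hits2), counts["pass2"])

    # mining report + final excised domains
    kept2_ids = {rec.id for rec, _ in kept2}
    final_excised = []
    plp_call_by_excised = {}
    for rec, _path in hits2:
        calls = annotation_cache.get(rec.id, [])
        cp_flag = require_cp_cooccurrence(calls)
        report.add(
            rec.id,
            calls=calls,
            pass1_kept=any(r.id == rec.id for r, _ in kept1),
            cp_cooccurrence=cp_flag,
            pass2_kept=rec.id in kept2_ids,
        )
        if rec.id in kept2_ids:
            for call in calls:
                if call.domain_label == PLP_LABEL:
                    sub = excise_domain(rec, call)
                    final_excised.append(sub)
                    plp_call_by_excised[sub.id] = (rec.id, call)
    report.excised = [
        {"parent_id": plp_call_by_excised[s.id][0], "start": plp_call_by_excised[s.id][1].env_start,
         "end": plp_call_by_excised[s.id][1].env_end, "id": s.id}
        for s in final_excised
    ]
    counts["excised"] = len(final_excised)

    # redundancy pruning (for the tree / representative set)
    nonredundant = remove_redundant(
        [(s.id, s.residues) for s in final_excised], config.redundancy_threshold
    )
    counts["non_redundant"] = len(nonredundant)
    log.info("redundancy pruning: %d -> %d", counts["excised"], counts["non_redundant"])

    # family classification of every final excised domain
    references = fixtures.reference_sequences()
    family_profiles = {f: fixtures.family_profile(f) for f in FAMILIES}
    assignments = []
    if final_excised:
        assignments = assign_family(
            [(s.id, s.residues) for s in final_excised],
            references,
            mode=config.classify_mode,
            family_profiles=family_profiles,
            base_profile=search_profile,
        )
    tally = {f: 0 for f in FAMILIES}
    tally["unassigned"] = 0
    for a in assignments:
        tally[a.family or "unassigned"] += 1

    # key residues
    key_reports = []
    fam_of = {a.domain_id: a.family for a in assignments}
    for s in final_excised:
        fam = fam_of.get(s.id)
        if fam:
            key_reports.append(check_key_residues(s.id, s.residues, family_profiles[fam]))

    # architectures of retained parents
    architectures = {}
    for rec, _path in kept2:
        calls = annotation_cache[rec.id]
        fam_by_plp_index = {}
        plp_i = 0
        for call in calls:
            if call.domain_label == PLP_LABEL:
                sid = f"{rec.id}/{call.env_start}-{call.env_end}"
                if fam_of.get(sid):
                    fam_by_plp_index[plp_i] = fam_of[sid]
                plp_i += 1
        architectures[rec.id] = render_architecture(calls, fam_by_plp_index)

    # optional bootstrap tree on the non-redundant set plus references
    tree_newick = None
    if config.bootstrap_replicates > 0 and len(nonredundant) + len(references) >= 3:
        rows = profile_align_rows(
            search_profile,
            list(nonredundant) + [(rid, res) for rid, _f, res in references],
        )
        tree = bootstrap_consensus(
            rows, config.bootstrap_replicates, seed=int(rng.integers(0, 2**31 - 1))
        )
        tree_newick = tree.newick(support_min=50.0)

    summary = SummaryReport(
        counts=counts,
        family_tally=tally,
        architectures=architectures,
        assignments={a.domain_id: {"family": a.family, "method": a.method, "support": a.support}
                     for a in assignments},
    )

    # benchmark metrics when a truth table is available
    if config.truth_path:
        from .synth import read_truth

        truth = read_truth(config.truth_path)
        summary.metrics = evaluate_against_truth(report, assignments, truth,
                                                 {r.id for r in records})

    if out_dir:
        _write_artifacts(out_dir, hits1, kept1, hits2, kept2, report, final_excised,
                         nonredundant, assignments, key_reports, architectures,
                         tree_newick, summary, specialized)
    return summary


def _write_artifacts(out_dir, hits1, kept1, hits2, kept2, report, final_excised,
                     nonredundant, assignments, key_reports, architectures,
                     tree_newick, summary, specialized):
    def hit_frame(hits, kept):
        kept_ids = {rec.id for rec, _ in kept}
        rows = []
        for rec, path in hits:
            rows.append({
                "id": rec.id, "length": rec.length, "bit_score": round(path.bit_score, 2),
                "env_start": path.env_start, "env_end": path.env_end,
                "coverage": path.coverage, "kept": rec.id in kept_ids,
            })
        return pd.DataFrame(rows)

    hit_frame(hits1, kept1).to_csv(out_dir / "hits_pass1.tsv", sep="\t", index=False)
    hit_frame(hits2, kept2).to_csv(out_dir / "hits_pass2.tsv", sep="\t", index=False)
    report.to_json(out_dir / "mining_report.json")
    write_fasta(final_excised, out_dir / "excised_domains.fasta")
    with open(out_dir / "excised_nonredundant.fasta", "w") as fh:
        for sid, seq in nonredundant:
            fh.write(f">{sid}\n{seq}\n")
    pd.DataFrame(
        [{"domain_id": a.domain_id, "family": a.family or "?", "method": a.method,
          "support": round(a.support, 2)} for a in assignments]
    ).to_csv(out_dir / "family_assignments.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"domain_id": r.domain_id, "asp": r.asp_residue, "asp_conserved": r.asp_conserved,
          "schiff_lys": r.schiff_lys, "flagged": r.flagged} for r in key_reports]
    ).to_csv(out_dir / "key_residues.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"id": k, "architecture": v} for k, v in sorted(architectures.items())]
    ).to_csv(out_dir / "architectures.tsv", sep="\t", index=False)
    if tree_newick:
        (out_dir / "tree.nwk").write_text(tree_newick + "\n")
    specialized.to_json(out_dir / "specialized_profile.json")
    summary.to_json(out_dir / "summary.json")


def evaluate_against_truth(report: MiningReport, assignments, truth: pd.DataFrame,
                           known_ids=None) -> dict:
    """Benchmark metrics against a generator truth table.

    A positive is recovered iff its sequence is pass2-kept, some PLP call
    overlaps the planted interval by at least half the planted length, and
    the assigned family (when assigned) matches the planted one.  Decoys
    count as false positives when pass2-kept.
    """
    if known_ids is not None:
        unknown = set(truth["id"]) - set(known_ids)
        if unknown:
            raise DataError(f"truth table contains unknown ids: {sorted(unknown)[:5]}")
    fam_of_domain = {a.domain_id: a.family for a in assignments}
    per_class: dict = {}
    recovered_flags = {}
    for row in truth.to_dict("records"):
        entry = report.sequences.get(row["id"], {})
        kept = bool(entry.get("pass2_kept"))
        cls = row["class"]
        if cls == "positive":
            ok = False
            if kept:
                tlen = row["plp_end"] - row["plp_start"] + 1
                for call in entry.get("calls", []):
                    if call["domain_label"] != PLP_LABEL:
                        continue
                    ov = (min(call["env_end"], row["plp_end"])
                          - max(call["env_start"], row["plp_start"]) + 1)
                    if ov < 0.5 * tlen:
                        continue
                    did = f"{row['id']}/{call['env_start']}-{call['env_end']}"
                    fam = fam_of_domain.get(did)
                    if fam is None or fam == row["family"]:
                        ok = True
                        break
            recovered_flags[row["id"]] = ok
        per_class.setdefault(cls, {"n": 0, "kept": 0})
        per_class[cls]["n"] += 1
        per_class[cls]["kept"] += int(kept)

    pos = truth[truth["class"] == "positive"]
    metrics: dict = {"per_class": per_class}
    if len(pos):
        rec_overall = float(np.mean([recovered_flags[i] for i in pos["id"]]))
        metrics["recall"] = rec_overall
        by_div = {}
        for div, grp in pos.groupby("divergence"):
            by_div[f"{float(div):.2f}"] = float(np.mean([recovered_flags[i] for i in grp["id"]]))
        metrics["recall_by_divergence"] = by_div
        # family accuracy among recovered positives with an assigned family
        fam_ok = fam_tot = 0
        fam_ok_low = fam_tot_low = 0
        for row in pos.to_dict("records"):
            entry = report.sequences.get(row["id"], {})
            for call in entry.get("calls", []):
                if call["domain_label"] != PLP_LABEL:
                    continue
                did = f"{row['id']}/{call['env_start']}-{call['env_end']}"
                fam = fam_of_domain.get(did)
                if fam is not None:
                    fam_tot += 1
                    fam_ok += int(fam == row["family"])
                    if row["divergence"] <= 0.30 + 1e-9:
                        fam_tot_low += 1
                        fam_ok_low += int(fam == row["family"])
        metrics["family_accuracy"] = fam_ok / fam_tot if fam_tot else None
        metrics["family_accuracy_low_divergence"] = (
            fam_ok_low / fam_tot_low if fam_tot_low else None
        )
    decoys = truth[truth["class"] != "positive"]
    n_fp = sum(per_class.get(c, {}).get("kept", 0) for c in
               ("decoy_standalone", "decoy_noCP", "decoy_noPLP"))
    metrics["decoys_accepted"] = int(n_fp)
    n_accepted_total = n_fp + (int(sum(recovered_flags.values())) if len(pos) else 0)
    metrics["precision"] = (
        (n_accepted_total - n_fp) / n_accepted_total if n_accepted_total else None
    )
    metrics["n_decoys"] = int(len(decoys))
    return metrics
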