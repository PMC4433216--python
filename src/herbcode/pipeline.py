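"""End-to-end orchestration: simulate -> align -> identify -> gap -> authenticate.

The pipeline composes the library modules into one reproducible run over a
synthetic market survey (or persisted FASTA/TSV inputs): reference sets are
star-aligned per marker, queries are projected into each reference frame,
similarity assignments are made per marker and per marker combination and
consolidated, within-genus calls are refined by the genus barcode gap, and
molecular verdicts are fused with the chemistry assays into authentication
records and study-level summaries.  Every run is deterministic given the
configuration seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import chem as chem_mod
from .chem import (
    AssayResult,
    AuthenticationRecord,
    ChemicalSpec,
    MolecularCall,
    StudySummary,
    authenticate_sample,
    summarize_study,
)
from .distances import DistanceMatrix, distance_matrix, k2p_distance
from .gap import GapAnalysis, classify_by_gap, detect_gap, split_distances
from .identify import (
    ReferenceLibrary,
    TaxonAssignment,
    assign_rank,
    best_hits,
    combine_markers,
)
from .phylo import bootstrap_support, nj_tree, write_newick
from .seqstore import (
    AlignedSet,
    MarkerSequence,
    build_aligned_set,
    concatenate,
    project_to_anchor,
    quality_filter,
    read_fasta,
    subset,
    write_fasta,
)
from .simulate import (
    QuerySimulation,
    ReferenceSimulation,
    SimulationConfig,
    default_chem_specs,
    simulate_chemistry,
    simulate_queries,
    simulate_reference_library,
)

logger = logging.getLogger(__name__)

COMBOS: tuple[tuple[str, ...], ...] = (("matK", "rbcL"), ("matK", "rbcL", "ITS2"))
# preference order when choosing the frame for barcode-gap classification
_FRAME_PRIORITY: tuple[tuple[str, ...], ...] = (
    ("matK", "rbcL", "ITS2"),
    ("matK", "rbcL"),
    ("matK",),
    ("rbcL",),
    ("ITS2",),
)


@dataclass
class AnalysisParams:
    cutoff: float = 98.0
    tie_tol: float = 0.2
    qv_min: int = 15
    bin_width: float = 0.001
    mode: str = "resolved"  # barcode-gap classification mode
    rounding: str = "half_up"
    n_bootstrap: int = 0  # 0 skips bootstrap trees in reports
    markers: tuple[str, ...] = ("matK", "rbcL", "ITS2")


@dataclass
class StudyResult:
    library: ReferenceLibrary
    truth: pd.DataFrame | None
    assay: pd.DataFrame
    assignments: list[TaxonAssignment]  # per marker and per combination
    consolidated: dict[str, TaxonAssignment]
    calls: dict[str, MolecularCall]
    gaps: dict[tuple[str, str], GapAnalysis]  # (genus, frame name) -> analysis
    records: list[AuthenticationRecord]
    summary: StudySummary


def build_reference_library(
    refs: Mapping[str, Sequence[MarkerSequence]],
    taxonomy: Mapping[str, tuple[str, str]],
    target_species: Sequence[str],
) -> ReferenceLibrary:
    aligned = {m: build_aligned_set(list(seqs)) for m, seqs in refs.items()}
    return ReferenceLibrary(aligned, dict(taxonomy), list(target_species))


def _combo_name(combo: Sequence[str]) -> str:
    return "+".join(combo)


class _Frames:
    """Reference frames (per marker and per combination) plus query projections."""

    def __init__(self, library: ReferenceLibrary, markers: Sequence[str]):
        self.library = library
        self.markers = [m for m in markers if m in library.aligned]
        self.ref_sets: dict[str, AlignedSet] = {m: library.aligned[m] for m in self.markers}
        self.combo_excluded: dict[str, list[str]] = {}
        for combo in COMBOS:
            if all(m in self.markers for m in combo):
                res = concatenate([library.aligned[m] for m in combo])
                self.ref_sets[_combo_name(combo)] = res.aligned
                self.combo_excluded[_combo_name(combo)] = res.excluded
        self.query_rows: dict[tuple[str, str], np.ndarray] = {}

    def project_query(self, seq: MarkerSequence) -> None:
        ref = self.ref_sets[seq.marker]
        self.query_rows[(seq.sample_id, seq.marker)] = project_to_anchor(seq, ref.anchor_bases)

    def query_row(self, sample_id: str, frame: str) -> np.ndarray | None:
        if "+" in frame:
            parts = frame.split("+")
            rows = []
            for m in parts:
                row = self.query_rows.get((sample_id, m))
                if row is None:
                    return None
                rows.append(row[self.library.aligned[m].mask])
            return np.concatenate(rows)
        row = self.query_rows.get((sample_id, frame))
        return row

    def available_frames(self, sample_id: str) -> list[str]:
        present = {m for (sid, m) in self.query_rows if sid == sample_id}
        out = []
        for combo in _FRAME_PRIORITY:
            name = _combo_name(combo)
            if name in self.ref_sets and all(m in present for m in combo):
                out.append(name)
        return out


def compute_gap_analyses(
    library: ReferenceLibrary,
    frames: _Frames,
    bin_width: float = 0.001,
) -> dict[tuple[str, str], GapAnalysis]:
    """Barcode-gap analysis for every target genus in every reference frame."""
    gaps: dict[tuple[str, str], GapAnalysis] = {}
    by_genus: dict[str, list[str]] = {}
    for sp in library.taxonomy:
        by_genus.setdefault(library.taxonomy[sp][0], []).append(sp)
    for frame, ref_set in frames.ref_sets.items():
        for genus in sorted(library.target_genera):
            labels = [l for l in ref_set.labels
                      if library.taxonomy.get(ref_set.species.get(l, ""), (None,))[0] == genus]
            if len(labels) < 2:
                gaps[(genus, frame)] = detect_gap(genus, frame, [], [], bin_width)
                continue
            sub = subset(ref_set, labels)
            dm = distance_matrix(sub, model="K2P")
            intra, inter = split_distances(dm, sub.species)
            gaps[(genus, frame)] = detect_gap(genus, frame, intra, inter, bin_width)
    return gaps


def _query_species_distance(
    frames: _Frames, sample_id: str, frame: str, species: str
) -> float | None:
    """Minimum K2P distance from a query to any voucher of ``species``."""
    row = frames.query_row(sample_id, frame)
    ref_set = frames.ref_sets[frame]
    if row is None:
        return None
    qrow = row[ref_set.mask] if "+" not in frame else row
    best = None
    for label, sp in ref_set.species.items():
        if sp != species:
            continue
        ref_row = ref_set.masked_matrix()[ref_set.labels.index(label)]
        try:
            res = k2p_distance(qrow, ref_row)
        except ValueError:
            continue
        if res.defined and (best is None or res.value < best):
            best = res.value
    return best


def identify_all(
    library: ReferenceLibrary,
    frames: _Frames,
    query_ids: Sequence[str],
    params: AnalysisParams,
) -> tuple[list[TaxonAssignment], dict[str, TaxonAssignment]]:
    assignments: list[TaxonAssignment] = []
    consolidated: dict[str, TaxonAssignment] = {}
    for sid in query_ids:
        per_sample: list[TaxonAssignment] = []
        for frame, ref_set in frames.ref_sets.items():
            row = frames.query_row(sid, frame)
            if row is None:
                per_sample.append(TaxonAssignment(sid, frame, "no_sequence", None, None))
                continue
            qrow = row  # best_hits applies the mask for single markers
            hits = best_hits(qrow, ref_set, cutoff=params.cutoff, tie_tol=params.tie_tol)
            per_sample.append(assign_rank(sid, frame, hits, library, ref_set))
        assignments.extend(per_sample)
        consolidated[sid] = combine_markers(per_sample, library)
    return assignments, consolidated


def molecular_call(
    consolidated: TaxonAssignment,
    labelled_species: str,
    library: ReferenceLibrary,
    frames: _Frames,
    gaps: Mapping[tuple[str, str], GapAnalysis],
    mode: str = "resolved",
) -> MolecularCall:
    """Derive the molecular verdict, refining within-genus cases by the gap.

    Out-of-genus assignments (including family-level assignments outside the
    labelled species' family) are prompt substitutions.  Within the expected
    genus the query's distance to the labelled species' vouchers is compared
    with that genus' maximum intraspecific divergence in the widest marker
    frame the query covers.
    """
    sid = consolidated.sample_id
    exp_genus, exp_family = library.taxonomy[labelled_species]
    rank, taxon = consolidated.rank, consolidated.taxon
    if rank == "no_sequence":
        return MolecularCall(sid, labelled_species, "no_sequence", None, rank)
    if rank == "unidentified":
        return MolecularCall(sid, labelled_species, "unidentified", None, rank)
    if rank == "family":
        verdict = "inconclusive" if taxon == exp_family else "substitute"
        return MolecularCall(sid, labelled_species, verdict, taxon, rank)
    genus = library.taxonomy[taxon][0] if rank == "species" else taxon
    if genus != exp_genus:
        return MolecularCall(sid, labelled_species, "substitute", taxon, rank)
    if rank == "species":
        verdict = "authentic" if taxon == labelled_species else "substitute"
        return MolecularCall(sid, labelled_species, verdict, taxon, rank)
    # genus-level within the expected genus: barcode-gap refinement
    for frame in frames.available_frames(sid):
        gap = gaps.get((exp_genus, frame))
        if gap is None:
            continue
        dist = _query_species_distance(frames, sid, frame, labelled_species)
        if dist is None:
            continue
        if gap.gap_exists == "not_applicable" and gap.max_intra is None:
            continue
        call = classify_by_gap(dist, gap, mode=mode)
        verdict = {"substitution": "substitute", "authentic": "authentic",
                   "inconclusive": "inconclusive"}[call]
        return MolecularCall(sid, labelled_species, verdict, taxon, rank)
    return MolecularCall(sid, labelled_species, "inconclusive", taxon, rank)


def run_synthetic_study(
    config: SimulationConfig, params: AnalysisParams | None = None
) -> StudyResult:
    """Simulate a market survey and run the full authentication pipeline."""
    params = params or AnalysisParams()
    ref_sim = simulate_reference_library(config)
    queries = simulate_queries(config, ref_sim)
    specs = default_chem_specs(ref_sim)
    assay = simulate_chemistry(queries.truth, specs, config)
    library = build_reference_library(
        {m: ref_sim.sequences[m] for m in params.markers if m in ref_sim.sequences},
        ref_sim.taxonomy,
        ref_sim.target_species,
    )
    return analyze(
        library,
        {m: queries.sequences[m] for m in params.markers if m in queries.sequences},
        queries.truth[["sample_id", "labelled_species"]],
        assay,
        specs,
        params,
        truth=queries.truth,
    )


def analyze(
    library: ReferenceLibrary,
    query_seqs: Mapping[str, Sequence[MarkerSequence]],
    labels: pd.DataFrame,  # sample_id, labelled_species
    assay: pd.DataFrame,  # sample_id, tlc, concentration, unit
    specs: Mapping[str, ChemicalSpec],
    params: AnalysisParams | None = None,
    truth: pd.DataFrame | None = None,
) -> StudyResult:
    params = params or AnalysisParams()
    frames = _Frames(library, params.markers)
    for marker, seqs in query_seqs.items():
        for seq in seqs:
            filtered = quality_filter(seq, qv_min=params.qv_min) if seq.quality is not None else None
            record = filtered.record if filtered is not None else seq
            if record is None:
                continue  # discarded: propagates as no_sequence
            frames.project_query(record)
    query_ids = list(labels.sample_id)
    assignments, consolidated = identify_all(library, frames, query_ids, params)
    gaps = compute_gap_analyses(library, frames, bin_width=params.bin_width)
    labelled = dict(zip(labels.sample_id, labels.labelled_species))
    calls = {
        sid: molecular_call(consolidated[sid], labelled[sid], library, frames, gaps,
                            mode=params.mode)
        for sid in query_ids
    }
    assay_by_id = {row.sample_id: row for row in assay.itertuples()}
    records = []
    for sid in query_ids:
        arow = assay_by_id.get(sid)
        if arow is None:
            records.append(authenticate_sample(calls[sid], None, None))
            continue
        conc = None if pd.isna(arow.concentration) else float(arow.concentration)
        result = AssayResult(sid, arow.tlc, conc, arow.unit)
        records.append(authenticate_sample(calls[sid], result, specs[labelled[sid]]))
    summary = summarize_study(records, convention=params.rounding)
    return StudyResult(
        library=library,
        truth=truth,
        assay=assay,
        assignments=assignments,
        consolidated=consolidated,
        calls=calls,
        gaps=gaps,
        records=records,
        summary=summary,
    )


# ---------------------------------------------------------------------------
# persistence: dataset simulation to disk, report writing, full runs


def simulate_dataset(config: SimulationConfig, outdir: str | Path) -> Path:
    """Write a synthetic dataset (FASTAs, truth table, assays, config echo)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ref_sim = simulate_reference_library(config)
    queries = simulate_queries(config, ref_sim)
    specs = default_chem_specs(ref_sim)
    assay = simulate_chemistry(queries.truth, specs, config)
    for marker, seqs in ref_sim.sequences.items():
        write_fasta(seqs, outdir / f"refs_{marker}.fasta")
    for marker, seqs in queries.sequences.items():
        write_fasta(seqs, outdir / f"queries_{marker}.fasta")
    truth = queries.truth.merge(
        assay[["sample_id", "chem_marker_present", "concentration"]], on="sample_id"
    ).rename(columns={"chem_marker_present": "chem_present"})
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    assay.drop(columns=["chem_marker_present"]).to_csv(
        outdir / "assay.tsv", sep="\t", index=False
    )
    taxonomy = pd.DataFrame(
        [{"species": sp, "genus": g, "family": f} for sp, (g, f) in sorted(ref_sim.taxonomy.items())]
    )
    taxonomy.to_csv(outdir / "taxonomy.tsv", sep="\t", index=False)
    (outdir / "target_species.txt").write_text("\n".join(ref_sim.target_species) + "\n")
    (outdir / "config.json").write_text(config.to_json() + "\n")
    return outdir


def load_dataset(datadir: str | Path, markers: Sequence[str] = ("matK", "rbcL", "ITS2")):
    """Load a dataset directory written by :func:`simulate_dataset`."""
    datadir = Path(datadir)
    refs = {}
    queries = {}
    for marker in markers:
        rp = datadir / f"refs_{marker}.fasta"
        if rp.exists():
            refs[marker] = read_fasta(rp, marker)
        qp = datadir / f"queries_{marker}.fasta"
        if qp.exists():
            queries[marker] = read_fasta(qp, marker)
    if not refs:
        raise FileNotFoundError(f"no reference FASTAs found under {datadir}")
    taxonomy_df = pd.read_csv(datadir / "taxonomy.tsv", sep="\t")
    taxonomy = {r.species: (r.genus, r.family) for r in taxonomy_df.itertuples()}
    target_species = (datadir / "target_species.txt").read_text().splitlines()
    target_species = [line.strip() for line in target_species if line.strip()]
    truth = pd.read_csv(datadir / "truth.tsv", sep="\t")
    assay = pd.read_csv(datadir / "assay.tsv", sep="\t")
    return refs, queries, taxonomy, target_species, truth, assay


def write_reports(result: StudyResult, outdir: str | Path, params: AnalysisParams,
                  seed: int | None = None) -> None:
    """Write assignment, gap, authentication and summary tables plus a run log."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "sample_id": a.sample_id,
            "marker": a.marker,
            "rank": a.rank,
            "taxon": a.taxon if a.taxon else "",
            "best_similarity": "" if a.best_similarity is None else f"{a.best_similarity:.2f}",
            "out_of_target_genus": a.out_of_target_genus,
            "conflict": a.conflict,
        }
        for a in result.assignments
    ).to_csv(outdir / "assignment.tsv", sep="\t", index=False)

    frame_order = sorted({frame for (_, frame) in result.gaps})
    genera = sorted({genus for (genus, _) in result.gaps})
    rows = []
    for genus in genera:
        row = {"genus": genus}
        for frame in frame_order:
            gap = result.gaps.get((genus, frame))
            if gap is None or gap.gap_exists == "not_applicable":
                row[frame] = "not applicable"
            elif gap.gap_exists == "no":
                row[frame] = "X"
            else:
                row[frame] = f"{gap.max_intra:.5f}"
        rows.append(row)
    pd.DataFrame(rows).to_csv(outdir / "gap_report.tsv", sep="\t", index=False)

    pd.DataFrame(
        {
            "sample_id": r.sample_id,
            "labelled_species": r.labelled_species,
            "molecular_verdict": r.molecular_verdict,
            "assigned_taxon": r.assigned_taxon or "",
            "chemical_presence": "" if r.chemical_presence is None else r.chemical_presence,
            "meets_minimum": "" if r.meets_minimum is None else r.meets_minimum,
            "concordance": r.concordance,
            "hazard_flags": ";".join(r.hazard_flags),
        }
        for r in result.records
    ).to_csv(outdir / "authentication.tsv", sep="\t", index=False)

    s = result.summary
    overall = pd.DataFrame([{k: getattr(s, k) for k in (
        "n_total", "n_no_sequence", "n_sequenced", "n_inconclusive", "n_conclusive",
        "n_substitute", "n_authentic", "inconclusive_pct", "substitute_pct", "authentic_pct",
    )}])
    overall.to_csv(outdir / "summary_overall.tsv", sep="\t", index=False)
    s.per_species.to_csv(outdir / "summary_per_species.tsv", sep="\t", index=False)

    if params.n_bootstrap > 0:
        treedir = outdir / "trees"
        treedir.mkdir(exist_ok=True)
        for marker, aset in result.library.aligned.items():
            boot = bootstrap_support(aset, n_reps=params.n_bootstrap, seed=seed)
            (treedir / f"refs_{marker}.nwk").write_text(write_newick(boot.tree))

    log = {
        "seed": seed,
        "params": asdict(params),
        "n_queries": len(result.records),
        "similarity_definition": "100*(1 - p-distance) on pairwise-comparable masked sites",
    }
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: SimulationConfig, outdir: str | Path,
                 params: AnalysisParams | None = None) -> StudyResult:
    """Full reproducible run: simulate, analyze, and write every report."""
    params = params or AnalysisParams()
    result = run_synthetic_study(config, params)
    write_reports(result, outdir, params, seed=config.seed)
    return result


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
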