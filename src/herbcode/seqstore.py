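"""Sequence storage: FASTA I/O, quality filtering, anchor alignment, concatenation.

Sequences are held per marker (matK, rbcL, ITS2) as :class:`MarkerSequence`
records and assembled into :class:`AlignedSet` matrices in the coordinate
frame of an anchor sequence.  Distance computation downstream uses the
complete-deletion mask: every column that carries a gap or an ambiguous base
in *any* row is removed, matching the convention of distance-based barcoding
workflows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

MARKERS = ("matK", "rbcL", "ITS2")

# Integer base codes used throughout: A,G are purines, C,T pyrimidines, so the
# code//2 test separates the two classes; 4 = gap, 5 = N/ambiguous.
_CODE = {"A": 0, "G": 1, "C": 2, "T": 3, "-": 4}
_DECODE = np.array(list("AGCT-N"))
GAP_CODE = 4
N_CODE = 5

IUPAC_CHARS = set("ACGTURYSWKMBDHVN-")


class DuplicateIdentifierError(ValueError):
    pass


class MalformedHeaderError(ValueError):
    pass


def encode_bases(bases: str) -> np.ndarray:
    """Encode an IUPAC nucleotide string to uint8 codes (ambiguity -> N)."""
    out = np.full(len(bases), N_CODE, dtype=np.uint8)
    arr = np.frombuffer(bases.upper().encode(), dtype="S1")
    for ch, code in _CODE.items():
        out[arr == ch.encode()] = code
    out[arr == b"U"] = 3
    return out


def decode_bases(codes: np.ndarray) -> str:
    return "".join(_DECODE[codes])


@dataclass
class MarkerSequence:
    """One nucleotide sequence for one sample at one marker."""

    sample_id: str
    marker: str
    bases: str
    quality: Sequence[int] | None = None
    role: str = "query"  # "reference" | "query"
    species_label: str | None = None

    def __post_init__(self) -> None:
        if self.marker not in MARKERS:
            raise ValueError(f"unknown marker {self.marker!r}; expected one of {MARKERS}")
        if not self.bases:
            raise ValueError(f"{self.sample_id}: empty sequence")
        bad = set(self.bases.upper()) - IUPAC_CHARS
        if bad:
            raise ValueError(f"{self.sample_id}: non-IUPAC characters {sorted(bad)}")
        if self.quality is not None and len(self.quality) != len(self.bases):
            raise ValueError(f"{self.sample_id}: quality length != sequence length")

    @property
    def codes(self) -> np.ndarray:
        return encode_bases(self.bases)

    def n_unambiguous(self) -> int:
        return int((self.codes < GAP_CODE).sum())


def _parse_header(header: str, role: str | None) -> tuple[str, str, str | None]:
    """Return (sample_id, role, species_label) from a FASTA header.

    Reference headers look like ``SP|Genus_species|voucher``; query headers
    ``Q|sample_id``.  Headers without the prefix fall back to the caller's
    ``role`` with the first whitespace token as the id.
    """
    token = header.split()[0]
    if token.startswith("SP|"):
        parts = token.split("|")
        if len(parts) != 3 or not parts[1] or not parts[2]:
            raise MalformedHeaderError(f"malformed reference header {header!r}")
        return parts[2], "reference", parts[1].replace("_", " ")
    if token.startswith("Q|"):
        parts = token.split("|")
        if len(parts) != 2 or not parts[1]:
            raise MalformedHeaderError(f"malformed query header {header!r}")
        return parts[1], "query", None
    if role is None:
        raise MalformedHeaderError(
            f"header {header!r} has no SP|/Q| prefix and no role was given"
        )
    return token, role, None


def read_fasta(path: str | Path, marker: str, role: str | None = None) -> list[MarkerSequence]:
    """Read one marker's FASTA file into :class:`MarkerSequence` records.

    Headers following the ``SP|Genus_species|voucher`` / ``Q|sample_id``
    convention are parsed for role and species label; duplicate sample ids
    within the file are rejected.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: empty FASTA file")
    out: list[MarkerSequence] = []
    seen: set[str] = set()
    for rec in records:
        sample_id, rec_role, species = _parse_header(rec.description, role)
        if sample_id in seen:
            raise DuplicateIdentifierError(f"{path}: duplicate sample id {sample_id!r}")
        seen.add(sample_id)
        out.append(
            MarkerSequence(
                sample_id=sample_id,
                marker=marker,
                bases=str(rec.seq).upper(),
                role=rec_role,
                species_label=species,
            )
        )
    return out


def write_fasta(seqs: Iterable[MarkerSequence], path: str | Path) -> None:
    records = []
    for s in seqs:
        if s.role == "reference":
            header = f"SP|{(s.species_label or 'unknown').replace(' ', '_')}|{s.sample_id}"
        else:
            header = f"Q|{s.sample_id}"
        records.append(SeqRecord(Seq(s.bases), id=header, description=""))
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta-2line")


@dataclass
class FilterResult:
    record: MarkerSequence | None
    discarded: bool
    n_low: int


def quality_filter(
    seq: MarkerSequence, qv_min: int = 15, max_low_fraction: float = 0.5
) -> FilterResult:
    """Apply the per-base quality rule used for trace-derived sequences.

    Bases with quality value below ``qv_min`` (QV 15 corresponds to a 3.2%
    error probability) are replaced by N.  If the low-quality fraction exceeds
    ``max_low_fraction`` — the sequence is mostly unreliable — the whole
    record is discarded and the sample propagates downstream as having no
    sequence at this marker.  Records without quality values (e.g. database
    references) pass through unchanged with a warning.
    """
    if seq.quality is None:
        logger.warning("%s/%s: no quality values; passing through", seq.sample_id, seq.marker)
        return FilterResult(seq, False, 0)
    qv = np.asarray(seq.quality)
    low = qv < qv_min
    n_low = int(low.sum())
    if n_low / len(qv) > max_low_fraction:
        return FilterResult(None, True, n_low)
    if n_low == 0:
        return FilterResult(seq, False, 0)
    bases = np.frombuffer(seq.bases.encode(), dtype="S1").copy()
    bases[low] = b"N"
    edited = MarkerSequence(
        sample_id=seq.sample_id,
        marker=seq.marker,
        bases=bases.tobytes().decode(),
        quality=list(qv),
        role=seq.role,
        species_label=seq.species_label,
    )
    return FilterResult(edited, False, n_low)


@dataclass
class AlignedSet:
    """Equal-length sequence rows in an anchor coordinate frame.

    ``matrix`` holds uint8 base codes, one row per label, with as many columns
    as the anchor has bases.  ``mask`` lists the columns retained by complete
    deletion: no gap and no ambiguous base in any row.
    """

    marker: str
    labels: list[str]
    matrix: np.ndarray
    mask: np.ndarray
    anchor_bases: str
    species: dict[str, str] = field(default_factory=dict)

    def masked_matrix(self) -> np.ndarray:
        return self.matrix[:, self.mask]

    def row(self, label: str) -> np.ndarray:
        return self.matrix[self.labels.index(label)]

    @property
    def n_sites(self) -> int:
        return len(self.mask)


def complete_deletion_mask(matrix: np.ndarray) -> np.ndarray:
    """Columns free of gaps and ambiguous bases in every row (order-invariant)."""
    ok = (matrix < GAP_CODE).all(axis=0)
    return np.flatnonzero(ok)


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    # terminal gaps free: truncated fragments should align at no cost
    if hasattr(aligner, "end_insertion_score"):
        aligner.end_insertion_score = 0
        aligner.end_deletion_score = 0
    else:  # older attribute names
        aligner.target_end_gap_score = 0
        aligner.query_end_gap_score = 0
    return aligner


_ALIGNER = _make_aligner()


def project_to_anchor(seq: MarkerSequence, anchor_bases: str) -> np.ndarray:
    """Globally align ``seq`` to the anchor and express it in anchor columns.

    Scoring is match +1 / mismatch -1 / gap -2 with free terminal gaps.
    Columns of the anchor not covered by the sequence become gaps; bases the
    sequence inserts relative to the anchor have no column and are dropped
    (the markers are nearly indel-free, so this loses essentially nothing).
    Sequences already the anchor's length are taken as positionally
    homologous (the markers are near-indel-free coding regions, so
    equal-length sequences are in frame); only length differences trigger
    the aligner.
    """
    if seq.n_unambiguous() < 20:
        raise ValueError(f"{seq.sample_id}: fewer than 20 unambiguous bases")
    qbases = seq.bases.upper().replace("-", "")
    if len(qbases) == len(anchor_bases):
        return encode_bases(qbases)
    alignment = _ALIGNER.align(anchor_bases.upper(), qbases)[0]
    row = np.full(len(anchor_bases), GAP_CODE, dtype=np.uint8)
    qcodes = encode_bases(qbases)
    tblocks, qblocks = alignment.aligned
    for (ts, te), (qs, qe) in zip(tblocks, qblocks):
        row[ts:te] = qcodes[qs:qe]
    return row


def build_aligned_set(
    seqs: Sequence[MarkerSequence], anchor: MarkerSequence | None = None
) -> AlignedSet:
    """Star-align sequences to an anchor and compute the complete-deletion mask."""
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    markers = {s.marker for s in seqs}
    if len(markers) != 1:
        raise ValueError(f"mixed markers in one set: {sorted(markers)}")
    if anchor is None:
        anchor = seqs[0]
    anchor_bases = anchor.bases.upper().replace("-", "")
    rows = np.vstack([project_to_anchor(s, anchor_bases) for s in seqs])
    labels = [s.sample_id for s in seqs]
    if len(set(labels)) != len(labels):
        raise DuplicateIdentifierError("duplicate sample ids in aligned set")
    species = {s.sample_id: s.species_label for s in seqs if s.species_label}
    return AlignedSet(
        marker=seqs[0].marker,
        labels=labels,
        matrix=rows,
        mask=complete_deletion_mask(rows),
        anchor_bases=anchor_bases,
        species=species,
    )


@dataclass
class ConcatenationResult:
    aligned: AlignedSet
    excluded: list[str]


_MARKER_ORDER = {m: i for i, m in enumerate(MARKERS)}


def concatenate(
    sets: Sequence[AlignedSet], sample_ids: Sequence[str] | None = None
) -> ConcatenationResult:
    """Row-wise concatenation of masked columns in matK, rbcL, ITS2 order.

    Samples missing from any input set are excluded and reported; the result
    carries a combination marker name such as ``matK+rbcL`` and an all-columns
    mask (inputs are already gap- and N-free after complete deletion).
    """
    if not sets:
        raise ValueError("no sets to concatenate")
    ordered = sorted(sets, key=lambda s: _MARKER_ORDER.get(s.marker, 99))
    universe = sample_ids if sample_ids is not None else ordered[0].labels
    common = [sid for sid in universe if all(sid in s.labels for s in ordered)]
    excluded = [sid for sid in universe if sid not in common]
    if not common:
        raise ValueError("no sample is present in every marker set")
    blocks = []
    for s in ordered:
        idx = [s.labels.index(sid) for sid in common]
        blocks.append(s.masked_matrix()[idx])
    matrix = np.hstack(blocks)
    species: dict[str, str] = {}
    for s in ordered:
        species.update({k: v for k, v in s.species.items() if k in common})
    combo = AlignedSet(
        marker="+".join(s.marker for s in ordered),
        labels=list(common),
        matrix=matrix,
        mask=np.arange(matrix.shape[1]),
        anchor_bases=decode_bases(matrix[0]),
        species=species,
    )
    return ConcatenationResult(combo, excluded)


def subset(aligned: AlignedSet, labels: Sequence[str]) -> AlignedSet:
    idx = [aligned.labels.index(l) for l in labels]
    matrix = aligned.matrix[idx]
    return AlignedSet(
        marker=aligned.marker,
        labels=list(labels),
        matrix=matrix,
        mask=complete_deletion_mask(matrix),
        anchor_bases=aligned.anchor_bases,
        species={l: aligned.species[l] for l in labels if l in aligned.species},
    )
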