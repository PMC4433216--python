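"""Similarity-based taxonomic assignment of query sequences.

A query is compared against a reference library at each marker; references
within the similarity cutoff (default 98%) and within a small tie tolerance
of the best hit form the hit set, and the taxonomic resolution of that set
determines the assigned rank:

* one species                     -> species
* several species, one genus     -> genus
* several genera, one family     -> family
* several families, or no hit    -> unidentified
* marker missing                 -> no_sequence

Queries whose assignment falls outside the target genera (the marketed
medicinal genera under study) are flagged as out-of-target substitutions.
Per-marker and marker-combination assignments are consolidated by letting
the finest rank win, backing off to the deepest common ancestor on
conflicts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .seqstore import AlignedSet, GAP_CODE

RANKS = ("species", "genus", "family", "unidentified", "no_sequence")
_RANK_DEPTH = {r: i for i, r in enumerate(RANKS)}


@dataclass
class ReferenceLibrary:
    """Per-marker reference alignments plus the taxonomy that resolves them."""

    aligned: dict[str, AlignedSet]
    taxonomy: dict[str, tuple[str, str]]  # species -> (genus, family)
    target_species: list[str]

    def __post_init__(self) -> None:
        for marker, aset in self.aligned.items():
            missing = [s for s in aset.species.values() if s not in self.taxonomy]
            if missing:
                raise ValueError(f"{marker}: species without taxonomy: {sorted(set(missing))[:5]}")
        for sp in self.target_species:
            if sp not in self.taxonomy:
                raise ValueError(f"target species {sp!r} not in taxonomy")

    @property
    def target_genera(self) -> set[str]:
        return {self.taxonomy[s][0] for s in self.target_species}

    def genus_of(self, species: str) -> str:
        return self.taxonomy[species][0]

    def family_of_genus(self, genus: str) -> str:
        for g, f in self.taxonomy.values():
            if g == genus:
                return f
        raise KeyError(genus)


@dataclass
class TaxonAssignment:
    sample_id: str
    marker: str
    rank: str
    taxon: str | None
    best_similarity: float | None
    hit_species: set[str] = field(default_factory=set)
    out_of_target_genus: bool = False
    conflict: bool = False

    def __post_init__(self) -> None:
        if self.rank not in RANKS:
            raise ValueError(f"unknown rank {self.rank!r}")


@dataclass
class HitResult:
    labels: list[str]
    similarities: dict[str, float]
    best_similarity: float | None


def best_hits(
    query_row: np.ndarray,
    refs: AlignedSet,
    cutoff: float = 98.0,
    tie_tol: float = 0.2,
) -> HitResult:
    """References with similarity >= cutoff and within tie_tol of the best.

    Similarity is percent identity over the mutually unambiguous sites of the
    complete-deletion mask; it is computed pairwise, so a short query is
    scored on the columns it actually covers.  The best similarity is
    reported even when below the cutoff.
    """
    if not refs.labels:
        raise ValueError("empty reference set")
    q = query_row[refs.mask]
    R = refs.masked_matrix()
    valid = (R < GAP_CODE) & (q[None, :] < GAP_CODE)
    n = valid.sum(axis=1)
    mism = ((R != q[None, :]) & valid).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        sims = np.where(n > 0, 100.0 * (1.0 - mism / np.maximum(n, 1)), np.nan)
    if np.all(np.isnan(sims)):
        return HitResult([], {}, None)
    best = float(np.nanmax(sims))
    keep = np.flatnonzero((sims >= cutoff) & (sims >= best - tie_tol))
    labels = [refs.labels[i] for i in keep]
    return HitResult(labels, {refs.labels[i]: float(sims[i]) for i in keep}, best)


def assign_rank(
    sample_id: str,
    marker: str,
    hits: HitResult,
    library: ReferenceLibrary,
    refs: AlignedSet,
) -> TaxonAssignment:
    """Map a hit set to a rank per the resolution rules in the module docstring."""
    species = {refs.species[l] for l in hits.labels if l in refs.species}
    for sp in species:
        if sp not in library.taxonomy:
            raise KeyError(f"species {sp!r} absent from taxonomy")
    if not species:
        return TaxonAssignment(sample_id, marker, "unidentified", None, hits.best_similarity)
    genera = {library.taxonomy[sp][0] for sp in species}
    families = {library.taxonomy[sp][1] for sp in species}
    if len(species) == 1:
        (taxon,) = species
        rank = "species"
        genus = library.taxonomy[taxon][0]
    elif len(genera) == 1:
        (taxon,) = genera
        rank = "genus"
        genus = taxon
    elif len(families) == 1:
        (taxon,) = families
        rank = "family"
        genus = None
    else:
        return TaxonAssignment(
            sample_id, marker, "unidentified", None, hits.best_similarity,
            hit_species=species, conflict=True,
        )
    oot = genus is not None and genus not in library.target_genera
    return TaxonAssignment(
        sample_id, marker, rank, taxon, hits.best_similarity,
        hit_species=species, out_of_target_genus=oot,
    )


def _genus_of_assignment(a: TaxonAssignment, library: ReferenceLibrary) -> str | None:
    if a.rank == "species":
        return library.taxonomy[a.taxon][0]
    if a.rank == "genus":
        return a.taxon
    return None


def _family_of_assignment(a: TaxonAssignment, library: ReferenceLibrary) -> str | None:
    if a.rank == "species":
        return library.taxonomy[a.taxon][1]
    if a.rank == "genus":
        return library.family_of_genus(a.taxon)
    if a.rank == "family":
        return a.taxon
    return None


def combine_markers(
    assignments: Sequence[TaxonAssignment], library: ReferenceLibrary
) -> TaxonAssignment:
    """Consolidate per-marker and combination assignments for one sample.

    The finest-rank assignment wins.  When several assignments share the
    finest rank but name different taxa, the call backs off to their deepest
    common ancestor rank (genus, then family, then unidentified) and the
    conflict flag is set.  A consolidated genus outside the target genera is
    a prompt substitution signal carried by ``out_of_target_genus``.
    """
    if not assignments:
        raise ValueError("no assignments to consolidate")
    sample_id = assignments[0].sample_id
    informative = [a for a in assignments if a.rank != "no_sequence"]
    if not informative:
        return TaxonAssignment(sample_id, "consolidated", "no_sequence", None, None)
    sims = [a.best_similarity for a in informative if a.best_similarity is not None]
    best_sim = max(sims) if sims else None
    ranked = [a for a in informative if a.rank != "unidentified"]
    if not ranked:
        return TaxonAssignment(sample_id, "consolidated", "unidentified", None, best_sim)
    finest = min(_RANK_DEPTH[a.rank] for a in ranked)
    top = [a for a in ranked if _RANK_DEPTH[a.rank] == finest]
    taxa = {a.taxon for a in top}
    hit_species = set().union(*(a.hit_species for a in top))
    if len(taxa) == 1:
        a0 = top[0]
        return TaxonAssignment(
            sample_id, "consolidated", a0.rank, a0.taxon, best_sim,
            hit_species=hit_species, out_of_target_genus=a0.out_of_target_genus,
        )
    # same rank, different taxa: back off to the deepest common ancestor
    genera = {_genus_of_assignment(a, library) for a in top}
    families = {_family_of_assignment(a, library) for a in top}
    if None not in genera and len(genera) == 1:
        (genus,) = genera
        return TaxonAssignment(
            sample_id, "consolidated", "genus", genus, best_sim,
            hit_species=hit_species, conflict=True,
            out_of_target_genus=genus not in library.target_genera,
        )
    if None not in families and len(families) == 1:
        (fam,) = families
        return TaxonAssignment(
            sample_id, "consolidated", "family", fam, best_sim,
            hit_species=hit_species, conflict=True,
        )
    return TaxonAssignment(
        sample_id, "consolidated", "unidentified", None, best_sim,
        hit_species=hit_species, conflict=True,
    )
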