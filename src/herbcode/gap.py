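"""Per-genus barcode-gap analysis.

For one genus' reference set, pairwise distances are decomposed into
intraspecific (same species label) and interspecific (different species)
multisets.  A barcode gap exists when the two classes separate strictly:
max(intraspecific) < min(interspecific).  The maximum intraspecific
divergence then serves as the species-discrimination threshold: a query
further than the threshold from every conspecific voucher is a
substitution, while a query within it is the correct species when a gap
exists ("resolved" mode) and inconclusive otherwise.  A frequency histogram
over shared bin edges is materialized for reporting; the gap decision uses
the max/min statistics, not the bins.  Monotypic genera have no
interspecific class and the gap is not applicable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .distances import DistanceMatrix


@dataclass
class GapHistogram:
    bin_edges: np.ndarray
    intra_counts: np.ndarray
    inter_counts: np.ndarray


@dataclass
class GapAnalysis:
    genus: str
    marker: str
    intra_distances: list[float]
    inter_distances: list[float]
    max_intra: float | None
    min_inter: float | None
    gap_exists: str  # "yes" | "no" | "not_applicable"
    histogram: GapHistogram | None = None


def split_distances(
    dm: DistanceMatrix, species_by_label: Mapping[str, str]
) -> tuple[list[float], list[float]]:
    """Class each unordered pair as intra- or interspecific by species label."""
    n = len(dm.labels)
    if n < 2:
        raise ValueError("need at least two sequences")
    intra: list[float] = []
    inter: list[float] = []
    for i in range(n):
        for j in range(i + 1, n):
            d = float(dm.values[i, j])
            if species_by_label[dm.labels[i]] == species_by_label[dm.labels[j]]:
                intra.append(d)
            else:
                inter.append(d)
    return intra, inter


def detect_gap(
    genus: str,
    marker: str,
    intra: Sequence[float],
    inter: Sequence[float],
    bin_width: float = 0.001,
) -> GapAnalysis:
    """Decide gap existence by strict separation and build the histogram."""
    intra = [float(x) for x in intra]
    inter = [float(x) for x in inter]
    if not intra or not inter:
        return GapAnalysis(
            genus, marker, intra, inter,
            max_intra=max(intra) if intra else None,
            min_inter=min(inter) if inter else None,
            gap_exists="not_applicable",
        )
    max_intra = max(intra)
    min_inter = min(inter)
    gap = "yes" if max_intra < min_inter else "no"
    hi = max(max(intra), max(inter))
    edges = np.arange(0.0, hi + 2 * bin_width, bin_width)
    intra_counts, _ = np.histogram(intra, bins=edges)
    inter_counts, _ = np.histogram(inter, bins=edges)
    return GapAnalysis(
        genus, marker, intra, inter, max_intra, min_inter, gap,
        histogram=GapHistogram(edges, intra_counts, inter_counts),
    )


class MissingThresholdError(ValueError):
    pass


def classify_by_gap(
    query_distance: float, gap: GapAnalysis, mode: str = "resolved"
) -> str:
    """Classify a within-genus query by its distance to the expected species.

    ``query_distance`` is the minimum distance to any conspecific voucher.
    Above the maximum intraspecific divergence the sample is a substitution.
    At or below it, "resolved" mode calls the sample authentic when a gap
    exists; "strict" mode (and any case without a gap) leaves the sample
    inconclusive.
    """
    if mode not in ("strict", "resolved"):
        raise ValueError(f"unknown mode {mode!r}")
    if gap.gap_exists == "not_applicable":
        return "inconclusive"
    if gap.max_intra is None:
        raise MissingThresholdError(f"{gap.genus}/{gap.marker}: no intraspecific distances")
    if query_distance > gap.max_intra:
        return "substitution"
    if mode == "resolved" and gap.gap_exists == "yes":
        return "authentic"
    return "inconclusive"
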