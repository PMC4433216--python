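"""Pairwise nucleotide distances: p-distance and Kimura 2-parameter (K2P).

The K2P model corrects separately for transitions (A<->G, C<->T) and
transversions.  With P the observed transition proportion and Q the observed
transversion proportion over the mutually unambiguous sites,

    d = -1/2 * ln[(1 - 2P - Q) * sqrt(1 - 2Q)]

The estimator is undefined (saturated) when 1-2P-Q <= 0 or 1-2Q <= 0; such
pairs are flagged, never silently returned as infinities.  Note that K2P
distances need not satisfy the triangle inequality; nothing downstream
assumes it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .seqstore import AlignedSet, GAP_CODE, encode_bases


class ZeroComparableSitesError(ValueError):
    pass


def _as_codes(x) -> np.ndarray:
    if isinstance(x, str):
        return encode_bases(x)
    return np.asarray(x, dtype=np.uint8)


def site_counts(a, b) -> tuple[int, int, int]:
    """(comparable sites, transitions, transversions) between two rows.

    Sites where either base is a gap or ambiguous are excluded pairwise.
    """
    a = _as_codes(a)
    b = _as_codes(b)
    if a.shape != b.shape:
        raise ValueError("sequences have different lengths")
    valid = (a < GAP_CODE) & (b < GAP_CODE)
    n = int(valid.sum())
    diff = valid & (a != b)
    ts = int((diff & ((a >> 1) == (b >> 1))).sum())  # same purine/pyrimidine class
    tv = int(diff.sum()) - ts
    return n, ts, tv


def p_distance(a, b) -> tuple[float, int]:
    """Proportion of mismatches over mutually unambiguous sites, with the count."""
    n, ts, tv = site_counts(a, b)
    if n == 0:
        raise ZeroComparableSitesError("no mutually unambiguous sites")
    return (ts + tv) / n, n


def similarity(a, b) -> float:
    """Percent identity, 100 * (1 - p-distance)."""
    p, _ = p_distance(a, b)
    return 100.0 * (1.0 - p)


@dataclass
class K2PDistance:
    value: float  # nan when undefined
    transitions: float  # P
    transversions: float  # Q
    n_sites: int
    defined: bool


def k2p_from_proportions(P: float, Q: float) -> tuple[float, bool]:
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return math.nan, False
    return -0.5 * math.log(w1 * math.sqrt(w2)), True


def k2p_distance(a, b) -> K2PDistance:
    n, ts, tv = site_counts(a, b)
    if n == 0:
        raise ZeroComparableSitesError("no mutually unambiguous sites")
    P, Q = ts / n, tv / n
    d, defined = k2p_from_proportions(P, Q)
    return K2PDistance(d, P, Q, n, defined)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix over labelled sequences."""

    labels: list[str]
    values: np.ndarray
    model: str  # "p" | "K2P"
    n_sites: int
    undefined_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        finite = np.nan_to_num(v)
        if not np.allclose(finite, finite.T):
            raise ValueError("matrix is not symmetric")
        if not np.allclose(np.diag(finite), 0.0):
            raise ValueError("diagonal is not zero")

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def submatrix(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        vals = self.values[np.ix_(idx, idx)]
        keep = set(labels)
        und = [p for p in self.undefined_pairs if p[0] in keep and p[1] in keep]
        return DistanceMatrix(list(labels), vals, self.model, self.n_sites, und)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_phylip(self) -> str:
        lines = [f" {len(self.labels)}"]
        for label, row in zip(self.labels, self.values):
            cells = " ".join(f"{x:.6f}" for x in row)
            lines.append(f"{label[:10]:<10}  {cells}")
        return "\n".join(lines) + "\n"

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t")


def matrix_from_codes(
    codes: np.ndarray, labels: Sequence[str], model: str = "K2P"
) -> DistanceMatrix:
    """All-pairs distances over rows of a (pre-masked) code matrix."""
    n = len(labels)
    if n < 2:
        raise ValueError("need at least two rows")
    values = np.zeros((n, n))
    undefined: list[tuple[str, str]] = []
    for i in range(n):
        for j in range(i + 1, n):
            if model == "p":
                d, _ = p_distance(codes[i], codes[j])
            elif model == "K2P":
                res = k2p_distance(codes[i], codes[j])
                d = res.value
                if not res.defined:
                    undefined.append((labels[i], labels[j]))
            else:
                raise ValueError(f"unknown model {model!r}")
            values[i, j] = values[j, i] = d
    return DistanceMatrix(list(labels), values, model, codes.shape[1], undefined)


def distance_matrix(aligned: AlignedSet, model: str = "K2P") -> DistanceMatrix:
    """Distance matrix over an aligned set, on its complete-deletion mask."""
    return matrix_from_codes(aligned.masked_matrix(), aligned.labels, model)
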