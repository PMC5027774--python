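"""Pairwise p- and Kimura-2-parameter distances under pairwise deletion.

A site contributes to a pair's comparison only when both sequences carry an
unambiguous base (A, C, G or T) there; gaps and IUPAC ambiguity codes are
excluded for that pair alone, matching the pairwise-deletion treatment of
standard barcoding software. The K2P model corrects the observed transition
(P) and transversion (Q) proportions::

    d = -1/2 * ln(1 - 2P - Q) - 1/4 * ln(1 - 2Q)

When a pair shares no comparable site, or the log arguments are non-positive
(saturation), the distance is *undefined*: it is stored as NaN and recorded
in :attr:`DistanceMatrix.undefined_pairs` rather than clamped or dropped
silently. Distances are stored as proportions; report writers convert to
percentages rounded half-up to 2 decimals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .seqio import Alignment

__all__ = [
    "SiteComparison",
    "DistanceMatrix",
    "compare_sites",
    "k2p_distance",
    "p_distance",
    "distance_matrix",
    "encode_alignment",
    "matrix_from_encoded",
    "round_half_up",
]

# Base encoding: purines {A:0, G:1}, pyrimidines {C:2, T:3}; anything else
# (gap, N, partial ambiguity) is missing (-1). A pair of equal-group bases
# that differ is a transition; different-group differing bases a transversion.
_CODE = np.full(256, -1, dtype=np.int8)
for _b, _c in (("A", 0), ("G", 1), ("C", 2), ("T", 3)):
    _CODE[ord(_b)] = _c


@dataclass(frozen=True)
class SiteComparison:
    """Counts over the jointly resolved sites of one sequence pair."""

    n_compared: int
    n_transitions: int
    n_transversions: int

    def __post_init__(self) -> None:
        if self.n_transitions + self.n_transversions > self.n_compared:
            raise ValueError("more differences than compared sites")


def encode_alignment(aln: Alignment) -> np.ndarray:
    """Encode an alignment as an (n_records, length) int8 matrix."""
    buf = np.frombuffer(
        "".join(r.sequence for r in aln.records).encode("ascii"), dtype=np.uint8
    )
    return _CODE[buf].reshape(len(aln), aln.length)


def _encode_seq(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]


def compare_sites(seq_a: str, seq_b: str) -> SiteComparison:
    """Count compared sites, transitions and transversions for one pair."""
    if len(seq_a) != len(seq_b):
        raise ValueError(
            f"sequence lengths differ: {len(seq_a)} vs {len(seq_b)}"
        )
    a, b = _encode_seq(seq_a), _encode_seq(seq_b)
    return _compare_encoded(a, b)


def _compare_encoded(a: np.ndarray, b: np.ndarray) -> SiteComparison:
    both = (a >= 0) & (b >= 0)
    n = int(both.sum())
    diff = both & (a != b)
    # same purine/pyrimidine group (codes 0-1 vs 2-3) => transition
    ts = int((diff & ((a < 2) == (b < 2))).sum())
    tv = int(diff.sum()) - ts
    return SiteComparison(n, ts, tv)


def k2p_distance(sc: SiteComparison) -> float:
    """Kimura-2-parameter distance; NaN when undefined (no overlap/saturated)."""
    if sc.n_compared == 0:
        return math.nan
    p = sc.n_transitions / sc.n_compared
    q = sc.n_transversions / sc.n_compared
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        return math.nan
    return -0.5 * math.log(w1) - 0.25 * math.log(w2) + 0.0  # avoid -0.0


def p_distance(sc: SiteComparison) -> float:
    """Proportion of differing sites; NaN when no sites are comparable."""
    if sc.n_compared == 0:
        return math.nan
    return (sc.n_transitions + sc.n_transversions) / sc.n_compared


_MODELS = {"k2p": k2p_distance, "p": p_distance}


@dataclass
class DistanceMatrix:
    """Labelled symmetric distance matrix with per-pair site counts.

    ``values`` holds proportions (NaN = undefined); ``comparable_sites``
    the per-pair count of jointly resolved sites.
    """

    labels: list[str]
    values: np.ndarray
    comparable_sites: np.ndarray
    model: str = "k2p"

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("values shape must match labels")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("diagonal must be zero")
        defined = ~np.isnan(self.values)
        if not np.array_equal(defined, defined.T) or not np.allclose(
            np.nan_to_num(self.values), np.nan_to_num(self.values.T)
        ):
            raise ValueError("matrix must be symmetric")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    @property
    def undefined_pairs(self) -> list[tuple[str, str]]:
        """Label pairs (i < j) whose distance could not be computed."""
        out = []
        nan = np.isnan(self.values)
        for i in range(len(self.labels)):
            for j in range(i + 1, len(self.labels)):
                if nan[i, j]:
                    out.append((self.labels[i], self.labels[j]))
        return out

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def matrix_from_encoded(
    enc: np.ndarray, labels: list[str], model: str = "k2p"
) -> DistanceMatrix:
    """Distance matrix from an encoded alignment (fast path for bootstrap)."""
    dist_fn = _MODELS[model.lower()]
    n = enc.shape[0]
    values = np.zeros((n, n))
    sites = np.zeros((n, n), dtype=np.int64)
    np.fill_diagonal(sites, enc.shape[1])
    for i in range(n):
        for j in range(i + 1, n):
            sc = _compare_encoded(enc[i], enc[j])
            d = dist_fn(sc)
            values[i, j] = values[j, i] = d
            sites[i, j] = sites[j, i] = sc.n_compared
    return DistanceMatrix(list(labels), values, sites, model=model.lower())


def distance_matrix(aln: Alignment, model: str = "k2p") -> DistanceMatrix:
    """All-pairs distances for an alignment under the chosen model.

    Undefined pairs are kept as NaN and listed in ``undefined_pairs``.
    """
    if model.lower() not in _MODELS:
        raise ValueError(f"unknown model {model!r}; use 'k2p' or 'p'")
    return matrix_from_encoded(
        encode_alignment(aln), aln.specimen_ids, model=model
    )


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, the convention of the printed reports."""
    if math.isnan(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
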