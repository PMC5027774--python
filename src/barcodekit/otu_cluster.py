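"""Threshold single-linkage clustering of barcodes into OTUs.

Two specimens share an OTU iff they are connected by a chain of pairwise
distances at or below the threshold (single linkage = connected components
of the threshold graph). The default threshold of 2.2% is the seed value
BOLD's RESL algorithm uses for its initial single-linkage pass; the
Markov-clustering refinement BOLD applies afterwards is intentionally not
reproduced here, so these OTUs approximate BINs rather than replicate them.

A cluster is *concordant* when it contains exactly one species label
(specimens labelled "unknown" are ignored), *discordant* otherwise —
mirroring BIN discordance reporting.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .distances import DistanceMatrix
from .seqio import UNKNOWN_SPECIES

__all__ = ["OTUPartition", "single_linkage_otus", "concordance_report",
           "DEFAULT_THRESHOLD_PCT"]

DEFAULT_THRESHOLD_PCT = 2.2


@dataclass
class OTUPartition:
    """A partition of specimens into OTUs at one distance threshold.

    Clusters are sorted by (and identified by) their smallest member id.
    """

    clusters: list[frozenset]
    threshold: float  # percent

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def cluster_of(self, specimen_id: str) -> frozenset:
        for c in self.clusters:
            if specimen_id in c:
                return c
        raise KeyError(specimen_id)


def single_linkage_otus(
    dm: DistanceMatrix, threshold: float = DEFAULT_THRESHOLD_PCT
) -> OTUPartition:
    """Cluster specimens at a percent distance threshold (single linkage)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive (percent)")
    if dm.undefined_pairs:
        raise ValueError(
            f"undefined distances prevent clustering: {dm.undefined_pairs}"
        )
    adj = (dm.values * 100.0 <= threshold).astype(np.int8)
    _, comp = connected_components(csr_matrix(adj), directed=False)
    members: dict[int, set] = {}
    for label, c in zip(dm.labels, comp):
        members.setdefault(int(c), set()).add(label)
    clusters = sorted((frozenset(m) for m in members.values()), key=min)
    return OTUPartition(clusters=clusters, threshold=threshold)


def concordance_report(
    partition: OTUPartition, species_map: dict[str, str]
) -> list[dict]:
    """Per-cluster rows: id, size, species tally, concordance flag."""
    rows = []
    for cluster in partition.clusters:
        tally = Counter(
            species_map.get(sid, UNKNOWN_SPECIES)
            for sid in cluster
            if species_map.get(sid, UNKNOWN_SPECIES) != UNKNOWN_SPECIES
        )
        rows.append(
            {
                "cluster_id": min(cluster),
                "size": len(cluster),
                "species_tally": "; ".join(
                    f"{sp} ({n})" for sp, n in sorted(tally.items())
                ),
                "n_species": len(tally),
                "concordant": len(tally) <= 1,
            }
        )
    return rows
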