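"""Per-species distance summaries and the barcode-gap statistic.

For each named species the intraspecific K2P (or p) distances over all
unordered within-species specimen pairs are summarised (mean, sample SD,
min, max), the nearest-neighbour species — the other species containing the
specimen at minimum distance — is located, and the barcode gap is the excess
of that nearest-neighbour distance over the maximum intraspecific distance.
A species has a usable gap only when this excess is strictly positive;
otherwise intra- and interspecific variation overlap and distance-based
identification fails ("no gap"). Specimens labelled "unknown" are excluded
from all species-wise statistics.

All summary fields are percentages (distance matrices store proportions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .distances import DistanceMatrix
from .seqio import UNKNOWN_SPECIES

__all__ = [
    "SpeciesGapSummary",
    "LevelDistanceSummary",
    "compute_gap",
    "species_summaries",
    "level_summaries",
]

#: Separator for tied nearest-neighbour species names (joined alphabetically).
NN_TIE_SEP = " & "


def compute_gap(max_intra_pct: float, nn_distance_pct: float) -> float | None:
    """Barcode gap in percent, or None when there is no positive gap."""
    gap = nn_distance_pct - max_intra_pct
    return gap if gap > 0 else None


@dataclass
class SpeciesGapSummary:
    """One species' row of the distance-summary report.

    Intra fields are None for singleton species (undefined, not zero);
    ``barcode_gap`` is None when absent or not computable.
    """

    species: str
    n_specimens: int
    mean_intra: float | None
    sd_intra: float | None
    min_intra: float | None
    max_intra: float | None
    nearest_neighbor: str
    nn_distance: float
    barcode_gap: float | None

    @property
    def has_gap(self) -> bool | None:
        if self.max_intra is None:
            return None
        return self.barcode_gap is not None


@dataclass(frozen=True)
class LevelDistanceSummary:
    level: str  # "within-genus-between-species" | "between-genera"
    n_pairs: int
    min: float
    mean: float
    max: float


def _species_indices(
    dm: DistanceMatrix, species_map: dict[str, str]
) -> dict[str, list[int]]:
    groups: dict[str, list[int]] = {}
    for i, label in enumerate(dm.labels):
        sp = species_map.get(label, UNKNOWN_SPECIES)
        if sp != UNKNOWN_SPECIES:
            groups.setdefault(sp, []).append(i)
    return groups


def species_summaries(
    dm: DistanceMatrix, species_map: dict[str, str]
) -> list[SpeciesGapSummary]:
    """Distance summary rows for every named species, sorted by name.

    Undefined (NaN) pairs are skipped. Nearest-neighbour ties at the exact
    minimum distance are reported as all tied species joined alphabetically.
    """
    groups = _species_indices(dm, species_map)
    if len(groups) < 2:
        raise ValueError(
            "nearest-neighbour statistics need at least 2 named species"
        )
    v = dm.values * 100.0  # report scale
    out: list[SpeciesGapSummary] = []
    for sp in sorted(groups):
        idx = groups[sp]
        intra = [
            v[i, j]
            for a, i in enumerate(idx)
            for j in idx[a + 1:]
            if not math.isnan(v[i, j])
        ]
        if intra:
            mean = float(np.mean(intra))
            sd = float(np.std(intra, ddof=1)) if len(intra) > 1 else 0.0
            lo, hi = float(min(intra)), float(max(intra))
        else:
            mean = sd = lo = hi = None

        nn_dist = math.inf
        nn_species: set[str] = set()
        for other, oidx in groups.items():
            if other == sp:
                continue
            block = v[np.ix_(idx, oidx)]
            if np.all(np.isnan(block)):
                continue
            m = float(np.nanmin(block))
            if m < nn_dist - 1e-12:
                nn_dist, nn_species = m, {other}
            elif abs(m - nn_dist) <= 1e-12:
                nn_species.add(other)
        if not nn_species:
            raise ValueError(f"no defined interspecific distance for {sp}")

        gap = compute_gap(hi, nn_dist) if hi is not None else None
        out.append(
            SpeciesGapSummary(
                species=sp,
                n_specimens=len(idx),
                mean_intra=mean,
                sd_intra=sd,
                min_intra=lo,
                max_intra=hi,
                nearest_neighbor=NN_TIE_SEP.join(sorted(nn_species)),
                nn_distance=nn_dist,
                barcode_gap=gap,
            )
        )
    return out


def level_summaries(
    dm: DistanceMatrix,
    species_map: dict[str, str],
    genus_map: dict[str, str] | None = None,
) -> list[LevelDistanceSummary]:
    """Pooled interspecific distances at genus and family level.

    Pairs are classed as within-genus-between-species or between-genera;
    ``genus_map`` maps species to genus and defaults to the first word of
    the binomial. Empty classes are omitted.
    """
    groups = _species_indices(dm, species_map)
    if genus_map is None:
        genus_map = {sp: sp.split()[0] for sp in groups}
    v = dm.values * 100.0
    pools: dict[str, list[float]] = {
        "within-genus-between-species": [],
        "between-genera": [],
    }
    species_list = sorted(groups)
    for a, sp_a in enumerate(species_list):
        for sp_b in species_list[a + 1:]:
            block = v[np.ix_(groups[sp_a], groups[sp_b])]
            vals = block[~np.isnan(block)].ravel().tolist()
            level = (
                "within-genus-between-species"
                if genus_map[sp_a] == genus_map[sp_b]
                else "between-genera"
            )
            pools[level].extend(vals)
    out = []
    for level in ("within-genus-between-species", "between-genera"):
        vals = pools[level]
        if not vals:
            continue
        out.append(
            LevelDistanceSummary(
                level=level,
                n_pairs=len(vals),
                min=float(min(vals)),
                mean=float(np.mean(vals)),
                max=float(max(vals)),
            )
        )
    return out
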