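"""Species-level marker sets and species-specific marker selection.

A marker is *present* in a species when at least one of its samples scores 1
(the any-sample rule; relevant where a species contributes several
accessions, e.g. two bread-wheat cultivars). *Absence* is judged under a
missing-call policy:

* ``lenient`` (default) — missing calls count as absent: a species is
  "absent" for a marker when no sample scores 1;
* ``strict`` — a missing call disqualifies the absence judgement: a marker
  with any missing call in a species can never be declared absent there.

A *species-specific* marker is present in the focal species and absent in
every background species. With the all-vs-one background convention the
specific sets of different species are pairwise disjoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd

from .io import MarkerMatrix, SamplePanel

MISSING_POLICIES = ("lenient", "strict")


def round_half_up(value: float, ndigits: int) -> float:
    """Decimal round-half-up (0.005 -> 0.01 at 2 digits), as in printed tables."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass
class SpeciesMarkerSet:
    """Markers judged present in (or specific to) one species.

    ``markers`` preserves the matrix's marker order. ``provenance`` records
    the samples aggregated and the missing-call policy, so that downstream
    tables can state how the set was derived.
    """

    species: str
    markers: pd.Index
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.markers)

    def as_set(self) -> set:
        return set(self.markers)


def _check_policy(missing_policy: str) -> None:
    if missing_policy not in MISSING_POLICIES:
        raise ValueError(
            f"missing_policy must be one of {MISSING_POLICIES}, got {missing_policy!r}"
        )


def presence_mask(matrix: MarkerMatrix, panel: SamplePanel, species: str) -> np.ndarray:
    """Boolean per-marker vector: any sample of ``species`` scores 1."""
    sub = matrix.scores[panel.samples_of(species)].to_numpy(dtype=float)
    return np.nansum(sub == 1.0, axis=1) > 0


def absence_mask(
    matrix: MarkerMatrix, panel: SamplePanel, species: str, missing_policy: str = "lenient"
) -> np.ndarray:
    """Boolean per-marker vector: ``species`` judged absent for the marker."""
    _check_policy(missing_policy)
    sub = matrix.scores[panel.samples_of(species)].to_numpy(dtype=float)
    no_presence = ~(np.nansum(sub == 1.0, axis=1) > 0)
    if missing_policy == "lenient":
        return no_presence
    return no_presence & ~np.isnan(sub).any(axis=1)


def species_presence(
    matrix: MarkerMatrix,
    panel: SamplePanel,
    species: str,
    missing_policy: str = "lenient",
) -> SpeciesMarkerSet:
    """Aggregate a species' samples into its presence marker set."""
    _check_policy(missing_policy)
    mask = presence_mask(matrix, panel, species)
    return SpeciesMarkerSet(
        species=species,
        markers=matrix.marker_ids[mask],
        provenance={
            "samples": panel.samples_of(species),
            "missing_policy": missing_policy,
            "rule": "present if any sample scores 1",
        },
    )


def select_species_specific(
    matrix: MarkerMatrix,
    panel: SamplePanel,
    focal_species: str,
    background_species: Sequence[str],
    missing_policy: str = "lenient",
) -> SpeciesMarkerSet:
    """Markers present in the focal species and absent in every background species."""
    _check_policy(missing_policy)
    background = list(background_species)
    if not background:
        raise ValueError("background species list must be non-empty")
    if focal_species in background:
        raise ValueError(
            f"focal species {focal_species!r} must not appear in the background list"
        )
    mask = presence_mask(matrix, panel, focal_species)
    for other in background:
        mask &= absence_mask(matrix, panel, other, missing_policy)
    return SpeciesMarkerSet(
        species=focal_species,
        markers=matrix.marker_ids[mask],
        provenance={
            "samples": panel.samples_of(focal_species),
            "background": background,
            "missing_policy": missing_policy,
        },
    )


def specificity_report(
    matrix: MarkerMatrix,
    panel: SamplePanel,
    species_list: Sequence[str],
    missing_policy: str = "lenient",
) -> pd.DataFrame:
    """Per-species marker totals, specific counts, and specific percentages.

    For each species in ``species_list`` the background is the rest of the
    list (all-vs-one), so the specific sets are pairwise disjoint. The
    percentage is 100 x specific / total, rounded half-up to 2 decimals;
    a species with an empty presence set reports 0.00.
    """
    species_list = list(species_list)
    if len(species_list) < 2:
        raise ValueError("specificity_report needs at least 2 species")
    rows = []
    for species in species_list:
        total = len(species_presence(matrix, panel, species, missing_policy))
        background = [s for s in species_list if s != species]
        specific = len(
            select_species_specific(matrix, panel, species, background, missing_policy)
        )
        pct = round_half_up(100.0 * specific / total, 2) if total else 0.0
        rows.append({"species": species, "total": total, "specific": specific,
                     "specific_pct": pct})
    return pd.DataFrame(rows).set_index("species")
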