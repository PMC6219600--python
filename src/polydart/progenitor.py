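"""Diploid-to-polyploid marker retention and progenitor inference.

The genome-analysis logic works on presence/absence (SilicoDArT) marker
sets. A diploid *analyzer*'s markers — usually its species-specific set —
are intersected with a polyploid target's presence set; the proportion
retained (diploid–polyploid monomorphism) measures how much of the
analyzer's genome survives in the polyploid. Analyzers whose retention
stands clearly above the rest are called as putative subgenome progenitors;
near-ties among related analyzers are reported as unresolved slots (an
ancestral or extinct donor) rather than forced to a single species.

Analyzers for bread-wheat-related polyploids are themselves pre-selected by
*homoeology*: the share of a diploid's markers whose reference-aligned
chromosome labels fall on each bread-wheat subgenome (A, B, D), expressed
as a percentage of the reference subgenome's own marker total. Species
reaching at least 10% on any subgenome qualify.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .filters import (
    SpeciesMarkerSet,
    round_half_up,
    select_species_specific,
    species_presence,
    specificity_report,
)
from .io import SUBGENOME_LETTERS, UNASSIGNED, MarkerMatrix, SamplePanel, SnpMatrix

DEFAULT_HOMOEOLOGY_THRESHOLD = 10.0  # percent
DEFAULT_MARGIN = 0.10  # absolute retention margin for "considerably higher"
DEFAULT_N_MIN = 20  # markers per chromosome bucket before a cell is trusted


class EmptyAnalyzerSetError(ValueError):
    """Retention against an empty analyzer set is undefined (never 0/0)."""


def subgenome_of(chromosome: str) -> str | None:
    """Subgenome letter of a canonical chromosome label, None if unassigned."""
    if chromosome == UNASSIGNED:
        return None
    return chromosome[-1]


# ---------------------------------------------------------------------------
# Retention
# ---------------------------------------------------------------------------

def retention(analyzer_markers: Sequence[str] | set, target_presence: set) -> float:
    """Proportion of the analyzer's markers present in the target.

    |analyzer ∩ target| / |analyzer|; raises on an empty analyzer set.
    """
    analyzer = set(analyzer_markers)
    if not analyzer:
        raise EmptyAnalyzerSetError("retention is undefined for an empty analyzer set")
    return len(analyzer & set(target_presence)) / len(analyzer)


@dataclass
class RetentionTable:
    """Retention of each analyzer's marker set in each polyploid target.

    ``values``: rows = analyzers, columns = targets, cells in [0, 1]; a cell
    whose analyzer set was empty is NaN and listed in ``undefined_cells``.
    ``marker_basis`` records whether analyzer sets were species-specific or
    all-marker presence sets.
    """

    values: pd.DataFrame
    marker_basis: str
    analyzer_set_sizes: pd.Series
    undefined_cells: list = field(default_factory=list)

    def column(self, target: str) -> pd.Series:
        return self.values[target]

    def to_csv(self, path: str | Path) -> None:
        self.values.rename_axis("analyzer").to_csv(path)


def retention_table(
    matrix: MarkerMatrix,
    panel: SamplePanel,
    analyzers: Sequence[str],
    targets: Sequence[str],
    use_specific: bool = True,
    missing_policy: str = "lenient",
) -> RetentionTable:
    """Build the analyzer x target retention table.

    Analyzer sets are species-specific markers (background = the other
    analyzers) when ``use_specific`` is true, otherwise full presence sets.
    """
    analyzers = list(analyzers)
    targets = list(targets)
    analyzer_sets: dict[str, set] = {}
    for species in analyzers:
        if use_specific:
            background = [s for s in analyzers if s != species]
            mset = select_species_specific(matrix, panel, species, background, missing_policy)
        else:
            mset = species_presence(matrix, panel, species, missing_policy)
        analyzer_sets[species] = mset.as_set()
    target_sets = {
        t: species_presence(matrix, panel, t, missing_policy).as_set() for t in targets
    }
    values = pd.DataFrame(index=pd.Index(analyzers, name="analyzer"), columns=targets,
                          dtype=float)
    undefined = []
    for a in analyzers:
        for t in targets:
            if not analyzer_sets[a]:
                values.loc[a, t] = np.nan
                undefined.append((a, t))
            else:
                values.loc[a, t] = retention(analyzer_sets[a], target_sets[t])
    return RetentionTable(
        values=values,
        marker_basis="species-specific" if use_specific else "all-markers",
        analyzer_set_sizes=pd.Series({a: len(s) for a, s in analyzer_sets.items()}),
        undefined_cells=undefined,
    )


# ---------------------------------------------------------------------------
# Homoeology to the reference subgenomes
# ---------------------------------------------------------------------------

@dataclass
class HomoeologyTable:
    """Per (diploid x reference subgenome) marker homoeology counts.

    ``counts`` has a (subgenome, statistic) column MultiIndex with
    statistics ``shared``, ``specific`` and ``total`` (shared + specific =
    total, asserted); ``percentages`` is 100 x total / reference-subgenome
    total, rounded half-up to 1 decimal; ``reference_totals`` holds the
    reference species' own per-subgenome marker counts.
    """

    counts: pd.DataFrame
    percentages: pd.DataFrame
    reference_totals: pd.Series
    shared_definition: str = "present in >=1 other screened diploid"

    def __post_init__(self) -> None:
        for g in self.percentages.columns:
            mismatch = (
                self.counts[(g, "shared")] + self.counts[(g, "specific")]
                != self.counts[(g, "total")]
            )
            if mismatch.any():
                bad = list(self.counts.index[mismatch])
                raise AssertionError(f"shared+specific != total for {bad} on {g}")

    def to_csv(self, path: str | Path) -> None:
        flat = self.counts.copy()
        flat.columns = [f"{g}_{stat}" for g, stat in flat.columns]
        for g in self.percentages.columns:
            flat[f"{g}_pct"] = self.percentages[g]
        flat.rename_axis("species").to_csv(path)


def homoeology_percentage(total: int, reference_total: int) -> float:
    """Percentage of a reference subgenome's marker total, half-up to 1 dp."""
    if reference_total <= 0:
        raise ValueError("reference subgenome has no markers")
    return round_half_up(100.0 * total / reference_total, 1)


def homoeology_table(
    matrix: MarkerMatrix,
    panel: SamplePanel,
    diploid_species: Sequence[str],
    reference_species: str,
    missing_policy: str = "lenient",
    subgenomes: Sequence[str] = SUBGENOME_LETTERS,
) -> HomoeologyTable:
    """Assign each screened diploid's markers to reference subgenomes.

    A marker's subgenome comes solely from its chromosome label (e.g. 3B ->
    B); unassigned markers are excluded. ``shared`` counts markers also
    present in at least one other screened diploid, ``specific`` the rest;
    the percentage uses the total only, relative to the reference species'
    own marker count on that subgenome.
    """
    diploids = list(diploid_species)
    presence = {s: species_presence(matrix, panel, s, missing_policy).as_set()
                for s in diploids}
    ref_set = species_presence(matrix, panel, reference_species, missing_policy).as_set()
    marker_subgenome = matrix.chromosome.map(subgenome_of)

    ref_totals = {}
    for g in subgenomes:
        on_g = set(matrix.marker_ids[(marker_subgenome == g).to_numpy()])
        ref_totals[g] = len(ref_set & on_g)
        if ref_totals[g] == 0:
            raise ValueError(f"reference species has no markers on subgenome {g}")

    columns = pd.MultiIndex.from_product([subgenomes, ("shared", "specific", "total")])
    counts = pd.DataFrame(0, index=pd.Index(diploids, name="species"), columns=columns)
    pct = pd.DataFrame(0.0, index=counts.index, columns=pd.Index(subgenomes))
    for g in subgenomes:
        on_g = set(matrix.marker_ids[(marker_subgenome == g).to_numpy()])
        for s in diploids:
            mine = presence[s] & on_g
            others = set().union(*(presence[o] for o in diploids if o != s)) if len(diploids) > 1 else set()
            shared = len(mine & others)
            counts.loc[s, (g, "shared")] = shared
            counts.loc[s, (g, "specific")] = len(mine) - shared
            counts.loc[s, (g, "total")] = len(mine)
            pct.loc[s, g] = homoeology_percentage(len(mine), ref_totals[g])
    return HomoeologyTable(
        counts=counts,
        percentages=pct,
        reference_totals=pd.Series(ref_totals, name="reference_total"),
    )


@dataclass
class AnalyzerSelection:
    """Species passing the homoeology threshold, per subgenome and pooled."""

    per_subgenome: dict[str, list[str]]
    union: list[str]
    threshold_percent: float


def select_analyzers(
    percentages: pd.DataFrame | HomoeologyTable,
    threshold_percent: float = DEFAULT_HOMOEOLOGY_THRESHOLD,
) -> AnalyzerSelection:
    """Select analyzers: homoeology percentage >= threshold on any subgenome.

    The comparison is inclusive ("at least 10%"). Accepts either a
    HomoeologyTable or a plain species x subgenome percentage frame, so the
    selection can also be run on published percentage tables.
    """
    if threshold_percent <= 0:
        raise ValueError("threshold_percent must be > 0")
    pct = percentages.percentages if isinstance(percentages, HomoeologyTable) else percentages
    per_subgenome = {
        g: list(pct.index[pct[g] >= threshold_percent]) for g in pct.columns
    }
    union = [s for s in pct.index if any(s in lst for lst in per_subgenome.values())]
    return AnalyzerSelection(per_subgenome=per_subgenome, union=union,
                             threshold_percent=threshold_percent)


# ---------------------------------------------------------------------------
# Polyploid differentiation
# ---------------------------------------------------------------------------

def polyploid_specific_markers(
    matrix: MarkerMatrix,
    panel: SamplePanel,
    polyploid_list: Sequence[str],
    missing_policy: str = "lenient",
) -> pd.DataFrame:
    """Species-specific marker report with the polyploid panel as its own
    background universe (the diploid machinery applied unchanged)."""
    return specificity_report(matrix, panel, polyploid_list, missing_policy)


# ---------------------------------------------------------------------------
# Per-chromosome retention profiles
# ---------------------------------------------------------------------------

@dataclass
class ChromosomeProfile:
    """Retention of an analyzer's markers per chromosome of one subgenome.

    ``retention`` and ``marker_counts`` are indexed by chromosome number
    1..7; buckets with fewer than ``n_min`` markers are flagged
    ``low_support`` (reported, never silently dropped)."""

    analyzer: str
    target: str
    genome_letter: str
    retention: pd.Series
    marker_counts: pd.Series
    low_support: pd.Series
    n_min: int


def chromosome_profile(
    matrix: MarkerMatrix,
    panel: SamplePanel,
    analyzer_set: SpeciesMarkerSet,
    target_species: str,
    genome_letter: str,
    n_min: int = DEFAULT_N_MIN,
    missing_policy: str = "lenient",
) -> ChromosomeProfile:
    """Bucket the analyzer's markers by chromosome 1..7 of ``genome_letter``
    and compute retention in the target per bucket."""
    target_set = species_presence(matrix, panel, target_species, missing_policy).as_set()
    chrom = matrix.chromosome.reindex(analyzer_set.markers)
    wanted = {f"{i}{genome_letter}": i for i in range(1, 8)}
    buckets: dict[int, set] = {i: set() for i in range(1, 8)}
    for marker, label in chrom.items():
        if label in wanted:
            buckets[wanted[label]].add(marker)
    if not any(buckets.values()):
        raise ValueError(
            f"no markers of analyzer {analyzer_set.species!r} map to subgenome "
            f"{genome_letter!r} chromosomes"
        )
    idx = pd.Index(range(1, 8), name="chromosome")
    ret = pd.Series(
        [retention(buckets[i], target_set) if buckets[i] else np.nan for i in idx],
        index=idx,
    )
    counts = pd.Series([len(buckets[i]) for i in idx], index=idx)
    return ChromosomeProfile(
        analyzer=analyzer_set.species,
        target=target_species,
        genome_letter=genome_letter,
        retention=ret,
        marker_counts=counts,
        low_support=counts < n_min,
        n_min=n_min,
    )


# ---------------------------------------------------------------------------
# Progenitor calling
# ---------------------------------------------------------------------------

@dataclass
class ProgenitorSlot:
    """One subgenome slot of a polyploid: a selected species or an
    unresolved tie among candidates (an ancestral/unknown donor)."""

    status: str  # "selected" | "unresolved"
    species: str | None
    candidates: list[str]
    retention: dict[str, float]


@dataclass
class ProgenitorCall:
    """Ranked progenitor call for one polyploid target."""

    target: str
    ploidy: int
    margin: float
    ranking: pd.Series  # analyzers sorted by retention, descending
    slots: list[ProgenitorSlot]

    @property
    def selected(self) -> list[str]:
        return [s.species for s in self.slots if s.status == "selected"]

    @property
    def unresolved(self) -> list[list[str]]:
        return [s.candidates for s in self.slots if s.status == "unresolved"]

    def to_record(self) -> dict:
        return {
            "target": self.target,
            "ploidy": self.ploidy,
            "margin": self.margin,
            "ranking": {a: float(r) for a, r in self.ranking.items()},
            "slots": [
                {
                    "status": s.status,
                    "species": s.species,
                    "candidates": s.candidates,
                    "retention": {a: float(r) for a, r in s.retention.items()},
                }
                for s in self.slots
            ],
        }


def call_progenitors(
    retention_column: pd.Series,
    ploidy: int,
    margin: float = DEFAULT_MARGIN,
    target: str = "",
) -> ProgenitorCall:
    """Call putative progenitors for one polyploid from analyzer retentions.

    Analyzers are ranked by retention (descending; label tie-break). The top
    ploidy/2 fill the subgenome slots. The last slot's candidate is tested
    for near-ties: analyzers ranked below it whose retention is within
    ``margin`` of it compete for that one slot, so the slot is reported
    unresolved with the tied candidate set instead of forcing a choice —
    the behaviour wanted when several related diploids (or none, because
    the true donor is extinct) trace a subgenome. Near-tied analyzers that
    all fit within the available slots are each selected; ``margin=0``
    degenerates to a pure argmax fill.
    """
    if retention_column.isna().any():
        bad = list(retention_column.index[retention_column.isna()])
        raise ValueError(f"retention column incomplete (NaN) for analyzers: {bad}")
    if ploidy < 4 or ploidy % 2:
        raise ValueError(f"target must be polyploid with even ploidy >= 4, got {ploidy}")
    n_slots = ploidy // 2
    if len(retention_column) < n_slots:
        raise ValueError(
            f"{len(retention_column)} analyzers cannot fill {n_slots} subgenome slots"
        )
    ranking = retention_column.sort_values(ascending=False, kind="mergesort")
    # stable secondary sort on label for deterministic ties
    ranking = ranking.iloc[
        sorted(range(len(ranking)), key=lambda i: (-ranking.iloc[i], str(ranking.index[i])))
    ]
    slots: list[ProgenitorSlot] = []
    for k in range(n_slots):
        candidate = ranking.index[k]
        r_cand = float(ranking.iloc[k])
        if k == n_slots - 1:
            followers = ranking.iloc[k + 1:]
            tied = [a for a, r in followers.items() if r_cand - float(r) < margin]
            if tied:
                members = [candidate] + tied
                slots.append(
                    ProgenitorSlot(
                        status="unresolved",
                        species=None,
                        candidates=members,
                        retention={a: float(ranking[a]) for a in members},
                    )
                )
                continue
        slots.append(
            ProgenitorSlot(
                status="selected",
                species=candidate,
                candidates=[candidate],
                retention={candidate: r_cand},
            )
        )
    return ProgenitorCall(target=target, ploidy=ploidy, margin=margin,
                          ranking=ranking, slots=slots)


def write_progenitor_calls(calls: Sequence[ProgenitorCall], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps([c.to_record() for c in calls], indent=2) + "\n"
    )


# ---------------------------------------------------------------------------
# Cross-genome SNP monomorphism
# ---------------------------------------------------------------------------

def cross_genome_monomorphism(
    snp_matrix: SnpMatrix,
    subgenome_partition: Mapping[str, Sequence[str]],
    sample_groups: Mapping[str, Sequence[str]],
    collapse_het: bool = False,
) -> pd.DataFrame:
    """Percentage of SNPs identically scored across each sample group.

    For each (group, partition) pair, the denominator is the partition's
    markers consistently called (non-missing) in every group member; the
    numerator those with identical scores across all members. With
    ``collapse_het`` heterozygous calls (2) are collapsed with the
    alternate homozygote (1) before comparison.
    """
    rows = []
    for part_name, marker_ids in subgenome_partition.items():
        idx = pd.Index(marker_ids)
        if not len(idx):
            raise ValueError(f"empty subgenome partition {part_name!r}")
        block_all = snp_matrix.scores.loc[idx]
        for group_name, samples in sample_groups.items():
            block = block_all[list(samples)].to_numpy(dtype=float)
            if collapse_het:
                block = np.where(block == 2.0, 1.0, block)
            called = ~np.isnan(block).any(axis=1)
            n = int(called.sum())
            if n == 0:
                pct = np.nan
            else:
                sub = block[called]
                identical = (sub == sub[:, [0]]).all(axis=1)
                pct = 100.0 * identical.sum() / n
            rows.append({"group": group_name, "partition": part_name,
                         "n_markers": n, "monomorphic_pct": pct})
    return pd.DataFrame(rows).set_index(["group", "partition"])
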