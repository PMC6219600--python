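"""Synthetic DArT-style marker panels with known allopolyploid ancestry.

The generator stands in for undeposited genotyping data. It evolves a pool
of presence/absence markers down a user-supplied ultrametric species tree
— per-branch Bernoulli loss per marker plus a fixed count of new private
markers gained per branch — and then forms allopolyploids as unions of
their parents' marker sets with independent per-marker post-merger loss
(probability ``loss_rate``, emulating genomic adjustment after
polyploidization) and private marker gain. SNP markers (0/1 homozygote scores) evolve by per-branch
state flips at a clock-like rate; a polyploid's SNP score is the parents'
shared score where they agree and heterozygous (2) where they differ.
Missing calls are injected independently at a fixed rate at emission time.

Chromosome labels (the 21-chromosome 1A..7D reference) are drawn per
marker; markers gained on a terminal branch are biased toward the species'
*subgenome affinity* so that reference-based homoeology screens see the
structure they assume. All bookkeeping (true per-species marker sets,
private markers, polyploid parents and lost markers) is returned as a
:class:`SimTruth`, the ground truth for pipeline tests.

A preset panel — 11 diploids in 5 sections plus one *hidden* diploid
pruned before emission, and 12 polyploids of which 5 descend from the
hidden donor — exercises the unresolved-progenitor behaviour expected
when a subgenome's true donor is extinct.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .io import CHROMOSOMES, MarkerMatrix, SamplePanel, SnpMatrix


@dataclass
class PolyploidEvent:
    """One allopolyploidization: parents, post-merger loss, private gain."""

    name: str
    parents: tuple[str, ...]
    loss_rate: float = 0.2  # per-marker post-polyploidization loss probability
    gain: int = 300  # private markers gained after the merger
    chrom_loss: Mapping[str, float] | None = None  # per-chromosome loss override
    role: str = "polyploid_target"

    @property
    def ploidy(self) -> int:
        return 2 * len(self.parents)


@dataclass
class SimConfig:
    """Generator parameters; a fixed seed yields bit-identical output."""

    seed: int
    species_tree: str  # Newick with branch lengths; leaf labels = diploid species
    ancestral_pool_size: int = 8000
    branch_loss_rate: float = 0.05  # per-marker loss probability per branch
    branch_gain: int = 500  # private markers gained per branch
    polyploids: tuple[PolyploidEvent, ...] = ()
    missing_rate: float = 0.02  # per-cell missing-call probability at emission
    snp_count: int = 5000
    snp_substitution_rate: float = 0.1  # flip probability per unit branch length
    chromosomes: tuple[str, ...] = CHROMOSOMES
    affinity: Mapping[str, str] = field(default_factory=dict)  # species -> subgenome letter
    affinity_bias: float = 0.8  # share of gained markers placed on the affinity subgenome
    hidden_species: tuple[str, ...] = ()  # leaves pruned from all emitted matrices

    def __post_init__(self) -> None:
        for rate in (self.branch_loss_rate, self.missing_rate, self.snp_substitution_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rates must lie in [0, 1], got {rate}")
        for event in self.polyploids:
            if not 0.0 <= event.loss_rate <= 1.0:
                raise ValueError(f"loss_rate must lie in [0, 1], got {event.loss_rate}")


@dataclass
class SimTruth:
    """Generator bookkeeping consumed by oracle tests.

    Marker sets are the *true* presence sets, recorded before missing-call
    injection; ``private_markers`` is relative to the emitted diploid panel.
    """

    species_markers: dict[str, set]
    private_markers: dict[str, set]
    polyploids: dict[str, dict]
    hidden_species: list[str]
    tree_newick: str  # emitted diploid topology (hidden leaves pruned)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "species_markers": {s: sorted(m) for s, m in self.species_markers.items()},
            "private_markers": {s: sorted(m) for s, m in self.private_markers.items()},
            "polyploids": {
                name: {**rec, "lost": sorted(rec["lost"]), "gained": sorted(rec["gained"])}
                for name, rec in self.polyploids.items()
            },
            "hidden_species": self.hidden_species,
            "tree_newick": self.tree_newick,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            species_markers={s: set(m) for s, m in payload["species_markers"].items()},
            private_markers={s: set(m) for s, m in payload["private_markers"].items()},
            polyploids={
                name: {**rec, "lost": set(rec["lost"]), "gained": set(rec["gained"])}
                for name, rec in payload["polyploids"].items()
            },
            hidden_species=list(payload["hidden_species"]),
            tree_newick=payload["tree_newick"],
        )


@dataclass
class SimResult:
    """Emitted matrices, panel and ground truth of one simulation."""

    markers: MarkerMatrix
    snps: SnpMatrix
    panel: SamplePanel
    truth: SimTruth

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "silicodart": outdir / "silicodart.csv",
            "snp": outdir / "snp.csv",
            "panel": outdir / "panel.csv",
            "truth": outdir / "truth.json",
        }
        self.markers.to_csv(paths["silicodart"])
        self.snps.to_csv(paths["snp"])
        self.panel.to_csv(paths["panel"])
        self.truth.to_json(paths["truth"])
        return paths


class Simulator:
    """Stateful simulation: diploids down the tree, then polyploid events."""

    def __init__(self, config: SimConfig):
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self.tree = dendropy.Tree.get(data=config.species_tree, schema="newick")
        leaves = [lf.taxon.label for lf in self.tree.leaf_node_iter()]
        if len(leaves) != len(set(leaves)):
            raise ValueError("species tree has duplicate leaf labels")
        if len(leaves) < 2 and config.polyploids:
            raise ValueError("a single-leaf species tree cannot host polyploid events")
        unknown_hidden = set(config.hidden_species) - set(leaves)
        if unknown_hidden:
            raise ValueError(f"hidden species not in tree: {sorted(unknown_hidden)}")
        self.diploids = leaves
        self._marker_chrom: list[str] = []
        self._species_sets: dict[str, set[int]] = {}
        self._snp_vectors: dict[str, np.ndarray] = {}
        self._polyploid_records: dict[str, dict] = {}
        self._polyploid_order: list[str] = []
        self._run_diploids()

    # -- marker bookkeeping -------------------------------------------------

    def _new_markers(self, count: int, affinity: str | None) -> set[int]:
        chroms = np.asarray(self.config.chromosomes)
        if affinity is not None and self.config.affinity_bias > 0:
            on_aff = np.array([c.endswith(affinity) for c in chroms])
            if not on_aff.any():
                raise ValueError(f"no chromosomes for affinity letter {affinity!r}")
            p = np.where(on_aff, self.config.affinity_bias / on_aff.sum(),
                         (1 - self.config.affinity_bias) / (~on_aff).sum())
        else:
            p = np.full(len(chroms), 1.0 / len(chroms))
        drawn = self.rng.choice(len(chroms), size=count, p=p)
        start = len(self._marker_chrom)
        self._marker_chrom.extend(chroms[i] for i in drawn)
        return set(range(start, start + count))

    def _run_diploids(self) -> None:
        cfg = self.config
        pool = self._new_markers(cfg.ancestral_pool_size, None)
        snp_root = self.rng.integers(0, 2, size=cfg.snp_count).astype(float)
        state: dict[int, tuple[set[int], np.ndarray]] = {
            id(self.tree.seed_node): (pool, snp_root)
        }
        for node in self.tree.preorder_node_iter():
            if node is self.tree.seed_node:
                continue
            parent_set, parent_snp = state[id(node.parent_node)]
            markers = set(parent_set)
            if cfg.branch_loss_rate > 0 and markers:
                arr = np.fromiter(markers, dtype=int)
                lost = arr[self.rng.random(len(arr)) < cfg.branch_loss_rate]
                markers -= set(lost.tolist())
            is_leaf = node.is_leaf()
            affinity = (
                cfg.affinity.get(node.taxon.label) if is_leaf else None
            )
            if cfg.branch_gain > 0:
                markers |= self._new_markers(cfg.branch_gain, affinity)
            length = node.edge.length if node.edge.length is not None else 1.0
            flip_p = min(1.0, cfg.snp_substitution_rate * length)
            snp = parent_snp.copy()
            flips = self.rng.random(len(snp)) < flip_p
            snp[flips] = 1.0 - snp[flips]
            if is_leaf:
                self._species_sets[node.taxon.label] = markers
                self._snp_vectors[node.taxon.label] = snp
            else:
                state[id(node)] = (markers, snp)

    # -- polyploid events ---------------------------------------------------

    def add_polyploid(self, event: PolyploidEvent) -> None:
        """Form an allopolyploid as the parents' union with per-marker loss."""
        if len(set(event.parents)) != len(event.parents):
            raise ValueError(f"{event.name}: duplicate parent in {event.parents}")
        if len(event.parents) < 2:
            raise ValueError(f"{event.name}: an allopolyploid needs >= 2 parents")
        unknown = [p for p in event.parents if p not in self._species_sets]
        if unknown:
            raise ValueError(f"{event.name}: unknown parents {unknown}")
        if event.name in self._species_sets:
            raise ValueError(f"species {event.name!r} already exists")
        union = set().union(*(self._species_sets[p] for p in event.parents))
        arr = np.fromiter(sorted(union), dtype=int)
        p_loss = np.full(len(arr), event.loss_rate)
        if event.chrom_loss:
            chrom = np.array([self._marker_chrom[i] for i in arr])
            for label, rate in event.chrom_loss.items():
                p_loss[chrom == label] = rate
        lost = set(arr[self.rng.random(len(arr)) < p_loss].tolist())
        gained = self._new_markers(event.gain, None) if event.gain else set()
        self._species_sets[event.name] = (union - lost) | gained
        # SNP score: parents' consensus where they agree, heterozygous otherwise
        snp_stack = np.stack([self._snp_vectors[p] for p in event.parents])
        agree = (snp_stack == snp_stack[0]).all(axis=0)
        self._snp_vectors[event.name] = np.where(agree, snp_stack[0], 2.0)
        self._polyploid_records[event.name] = {
            "parents": list(event.parents),
            "ploidy": event.ploidy,
            "loss_rate": event.loss_rate,
            "lost": lost,
            "gained": gained,
            "role": event.role,
        }
        self._polyploid_order.append(event.name)

    # -- emission -----------------------------------------------------------

    def emit(self) -> SimResult:
        cfg = self.config
        hidden = set(cfg.hidden_species)
        visible_diploids = [s for s in self.diploids if s not in hidden]
        species = visible_diploids + self._polyploid_order
        marker_ids = {i: f"SD{i:06d}" for i in range(len(self._marker_chrom))}

        observed = sorted(set().union(*(self._species_sets[s] for s in species)))
        index = pd.Index([marker_ids[i] for i in observed], name="marker_id")
        presence = np.zeros((len(observed), len(species)))
        pos = {m: k for k, m in enumerate(observed)}
        for col, s in enumerate(species):
            for m in self._species_sets[s]:
                if m in pos:
                    presence[pos[m], col] = 1.0
        scores = pd.DataFrame(presence, index=index, columns=species)
        if cfg.missing_rate > 0:
            mask = self.rng.random(scores.shape) < cfg.missing_rate
            scores = scores.mask(mask)
        chrom = pd.Series([self._marker_chrom[m] for m in observed], index=index)
        markers = MarkerMatrix(scores, chrom)

        snp_index = pd.Index([f"SNP{i:05d}" for i in range(cfg.snp_count)],
                             name="marker_id")
        snp_scores = pd.DataFrame(
            {s: self._snp_vectors[s] for s in species}, index=snp_index, dtype=float
        )
        if cfg.missing_rate > 0:
            mask = self.rng.random(snp_scores.shape) < cfg.missing_rate
            snp_scores = snp_scores.mask(mask)
        snp_chrom = pd.Series(
            self.rng.choice(list(cfg.chromosomes), size=cfg.snp_count), index=snp_index
        )
        snps = SnpMatrix(snp_scores, snp_chrom)

        rows = []
        for s in visible_diploids:
            rows.append({"sample_id": s, "species": s, "ploidy": 2,
                         "genome_formula": cfg.affinity.get(s, "?"),
                         "role": "diploid_analyzer"})
        for s in self._polyploid_order:
            rec = self._polyploid_records[s]
            formula = "".join(cfg.affinity.get(p, "?") for p in rec["parents"])
            rows.append({"sample_id": s, "species": s, "ploidy": rec["ploidy"],
                         "genome_formula": formula, "role": rec["role"]})
        panel = SamplePanel(pd.DataFrame(rows).set_index("sample_id"))

        named_sets = {
            s: {marker_ids[m] for m in self._species_sets[s] if m in pos}
            for s in species + sorted(hidden)
        }
        diploid_sets = [named_sets[s] for s in visible_diploids]
        private = {}
        for k, s in enumerate(visible_diploids):
            others = set().union(*(d for j, d in enumerate(diploid_sets) if j != k))
            private[s] = named_sets[s] - others
        truth = SimTruth(
            species_markers=named_sets,
            private_markers=private,
            polyploids={
                name: {**rec,
                       "lost": {marker_ids[m] for m in rec["lost"] if m in pos},
                       "gained": {marker_ids[m] for m in rec["gained"] if m in pos}}
                for name, rec in self._polyploid_records.items()
            },
            hidden_species=sorted(hidden),
            tree_newick=self._visible_tree_newick(),
        )
        return SimResult(markers=markers, snps=snps, panel=panel, truth=truth)

    def _visible_tree_newick(self) -> str:
        tree = dendropy.Tree.get(data=self.config.species_tree, schema="newick")
        if self.config.hidden_species:
            keep = [t for t in tree.taxon_namespace
                    if t.label not in set(self.config.hidden_species)]
            tree.retain_taxa(keep)
        return tree.as_string(schema="newick", suppress_rooting=True).strip()


# ---------------------------------------------------------------------------
# Spec-level operations
# ---------------------------------------------------------------------------

def simulate_diploids(config: SimConfig) -> SimResult:
    """Diploid panel only: markers and SNPs evolved down the species tree."""
    return Simulator(replace(config, polyploids=())).emit()


def simulate_panel(config: SimConfig) -> SimResult:
    """Full panel: diploids plus every configured polyploidization event."""
    sim = Simulator(config)
    for event in config.polyploids:
        sim.add_polyploid(event)
    return sim.emit()


def simulate_polyploid(
    sim: Simulator,
    name: str,
    parents: Sequence[str],
    loss_rate: float,
    gain: int = 0,
    chrom_loss: Mapping[str, float] | None = None,
) -> Simulator:
    """Add one polyploid to a running simulation (union of parents, loss)."""
    sim.add_polyploid(PolyploidEvent(name=name, parents=tuple(parents),
                                     loss_rate=loss_rate, gain=gain,
                                     chrom_loss=chrom_loss))
    return sim


# ---------------------------------------------------------------------------
# Preset panel
# ---------------------------------------------------------------------------

#: Ultrametric species tree: 12 diploid leaves in 5 sections; leaf H is the
#: hidden ancestral donor (pruned before emission). H hangs off a polytomy
#: inside the S-section radiation, so it is equidistant from S1, S2 and S3
#: and no single extant species monopolizes marker sharing with it — the
#: configuration under which a subgenome donated by H cannot be pinned to
#: one extant analyzer and must surface as an unresolved slot.
PRESET_TREE = (
    "(((A1:0.3,A2:0.3):0.6,(B1:0.55,"
    "(S1:0.2,(S2:0.15,S3:0.15):0.05,H:0.2):0.35):0.35):0.1,"
    "((D1:0.3,D2:0.3):0.5,(U1:0.25,(U2:0.2,U3:0.2):0.05):0.55):0.2);"
)

PRESET_AFFINITY = {
    "A1": "A", "A2": "A",
    "B1": "B", "H": "B",
    "S1": "B", "S2": "B", "S3": "B",
    "D1": "D", "D2": "D",
    "U1": "A", "U2": "A", "U3": "A",
}


def preset_polyploids(loss_rate: float = 0.2, gain: int = 300) -> tuple[PolyploidEvent, ...]:
    """12 polyploids: 7 with emitted diploid parents (one hexaploid doubling
    as the homoeology reference) and 5 descending from the hidden donor H."""
    ev = lambda name, parents, role="polyploid_target": PolyploidEvent(
        name=name, parents=parents, loss_rate=loss_rate, gain=gain, role=role)
    return (
        ev("T01", ("D1", "U1")),
        ev("T02", ("D2", "U1")),
        ev("T03", ("S1", "U2")),
        ev("T04", ("S2", "U2")),
        ev("T05", ("A2", "U3")),
        ev("T06", ("B1", "D2")),
        ev("R01", ("A1", "B1", "D1"), role="reference"),
        ev("X01", ("H", "U1")),
        ev("X02", ("H", "D1")),
        ev("X03", ("H", "D2", "U2")),
        ev("X04", ("H", "U3")),
        ev("X05", ("H", "S3", "U1")),
    )


def triticeae_like_config(seed: int, loss_rate: float = 0.2,
                          missing_rate: float = 0.02, **overrides) -> SimConfig:
    """The shipped preset: 11 visible diploids in 5 sections, 12 polyploids,
    one hidden ancestral donor, Table-1-like marker magnitudes."""
    params = dict(
        seed=seed,
        species_tree=PRESET_TREE,
        ancestral_pool_size=8000,
        branch_loss_rate=0.05,
        branch_gain=500,
        polyploids=preset_polyploids(loss_rate=loss_rate),
        missing_rate=missing_rate,
        snp_count=5000,
        snp_substitution_rate=0.1,
        affinity=PRESET_AFFINITY,
        hidden_species=("H",),
    )
    params.update(overrides)
    return SimConfig(**params)
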