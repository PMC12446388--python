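"""Clade-structured protein sequence simulator.

Sequences evolve along a tree under a reversible substitution model.  Sites
are partitioned by a domain map; branches whose descendant leaves all belong
to one clade group can carry per-region rate multipliers, which is how the
"elevated sensor-region rate in an aquatic clade" scenario is generated.  A
diagnostic column can be planted per clade after simulation.

Alignments are generated gap-free; gap handling elsewhere is exercised by
synthetic gap injection, not by indel simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import dendropy
import numpy as np

from .errors import ValidationError
from .io import (
    Alignment,
    CladeGroupEntry,
    CladeGroupTable,
    DomainMap,
    SequenceRecord,
    ThermalAnnotation,
    write_alignment,
    write_newick,
)
from .substitution import N_STATES, SubstitutionModel


@dataclass
class SimulationConfig:
    tree: dendropy.Tree
    seq_length: int
    domain_map: DomainMap
    clade_groups: CladeGroupTable
    seed: int
    # (group_id, region_name) -> rate multiplier; default 1 everywhere
    rate_multipliers: Mapping[tuple[int, str], float] = field(default_factory=dict)
    # reference position -> {group_id: residue}
    planted_column: tuple[int, Mapping[int, str]] | None = None

    def __post_init__(self) -> None:
        for key, mult in self.rate_multipliers.items():
            if mult <= 0:
                raise ValidationError(f"rate multiplier for {key} must be > 0")
        if self.planted_column is not None:
            pos, _ = self.planted_column
            if not (1 <= pos <= self.seq_length):
                raise ValidationError(
                    f"planted position {pos} outside sequence length {self.seq_length}"
                )
        if self.seq_length < self.domain_map.reference_length:
            raise ValidationError("seq_length shorter than domain-map reference length")


@dataclass
class SimulatedDataset:
    alignment: Alignment
    tree: dendropy.Tree
    clade_groups: CladeGroupTable
    domain_map: DomainMap
    truth: dict
    seed: int
    thermal: ThermalAnnotation | None = None

    def write(self, directory: str | Path) -> None:
        """Write alignment, tree and annotation tables as plain text."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        tagged = Alignment(
            [
                SequenceRecord(r.taxon_id, r.residues, f"seed={self.seed}")
                for r in self.alignment.rows
            ]
        )
        write_alignment(tagged, directory / "alignment.fasta")
        write_newick(self.tree, directory / "tree.nwk")
        with open(directory / "clade_groups.tsv", "w") as fh:
            fh.write(f"# seed={self.seed}\n")
            fh.write("taxon_id\tgroup_id\tgroup_name\tsuperorder\n")
            for taxon, e in sorted(self.clade_groups.entries.items()):
                fh.write(f"{taxon}\t{e.group_id}\t{e.group_name}\t{e.superorder}\n")
        with open(directory / "truth.tsv", "w") as fh:
            fh.write(f"# seed={self.seed}\n")
            fh.write("key\tvalue\n")
            for k, v in sorted(self.truth.items(), key=lambda kv: str(kv[0])):
                fh.write(f"{k}\t{v}\n")


# ---------------------------------------------------------------------------
# core simulation
# ---------------------------------------------------------------------------

def _site_regions(config: SimulationConfig) -> dict[str, np.ndarray]:
    """Boolean site masks for every region named in a rate-multiplier key."""
    masks: dict[str, np.ndarray] = {}
    for (_, region) in config.rate_multipliers:
        if region in masks:
            continue
        mask = np.zeros(config.seq_length, dtype=bool)
        for pos in config.domain_map.region_positions(region):
            mask[pos - 1] = True
        masks[region] = mask
    return masks


def _edge_group(node: dendropy.Node, clade_groups: CladeGroupTable) -> int | None:
    """Group id if every leaf below the node is in one group, else None."""
    gids = {
        clade_groups.group_of(leaf.taxon.label) for leaf in node.leaf_iter()
    }
    return gids.pop() if len(gids) == 1 else None


def simulate_alignment(
    config: SimulationConfig, model: SubstitutionModel
) -> SimulatedDataset:
    """Simulate one alignment; bit-identical for identical config and seed.

    The root sequence is drawn from the model's equilibrium frequencies; each
    branch applies P(r*t) sitewise, with r the multiplier configured for the
    branch's clade group and the site's region (default 1).  The planted
    column, if any, is overwritten last.
    """
    rng = np.random.default_rng(config.seed)
    tree = config.tree
    L = config.seq_length
    masks = _site_regions(config)

    root_states = rng.choice(N_STATES, size=L, p=model.pi)
    states: dict[int, np.ndarray] = {id(tree.seed_node): root_states}

    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        t = float(node.edge.length or 0.0)
        parent_states = states[id(node.parent_node)]
        if t == 0.0:
            states[id(node)] = parent_states.copy()
            continue
        rates = np.ones(L)
        gid = _edge_group(node, config.clade_groups)
        if gid is not None:
            for (g, region), mult in config.rate_multipliers.items():
                if g == gid:
                    rates[masks[region]] = mult
        child = np.empty(L, dtype=np.int64)
        for r in np.unique(rates):
            P = model.transition_matrix(r * t)
            cum = P.cumsum(axis=1)
            sel = rates == r
            u = rng.random(sel.sum())
            child[sel] = (cum[parent_states[sel]] < u[:, None]).sum(axis=1)
        states[id(node)] = child

    alphabet = model.alphabet
    truth: dict = {
        f"multiplier:{gid}:{region}": mult
        for (gid, region), mult in config.rate_multipliers.items()
    }
    rows = []
    leaves = sorted(tree.leaf_node_iter(), key=lambda nd: nd.taxon.label)
    planted = config.planted_column
    for leaf in leaves:
        seq = states[id(leaf)]
        residues = "".join(alphabet[s] for s in seq)
        if planted is not None:
            pos, per_group = planted
            gid = config.clade_groups.group_of(leaf.taxon.label)
            if gid in per_group:
                residues = residues[: pos - 1] + per_group[gid] + residues[pos:]
                truth[f"planted:{leaf.taxon.label}"] = per_group[gid]
        rows.append(SequenceRecord(leaf.taxon.label, residues))
    if planted is not None:
        truth["planted_position"] = planted[0]
    return SimulatedDataset(
        Alignment(rows), tree, config.clade_groups, config.domain_map, truth, config.seed
    )


# ---------------------------------------------------------------------------
# random clade-structured trees
# ---------------------------------------------------------------------------

def _random_subtree(
    taxa: list[str],
    namespace: dendropy.TaxonNamespace,
    rng: np.random.Generator,
    length_range: tuple[float, float],
) -> dendropy.Node:
    """Random binary subtree over the taxa (random sequential joins)."""
    lo, hi = length_range
    nodes = []
    for name in taxa:
        nd = dendropy.Node()
        nd.taxon = namespace.get_taxon(name)
        nd.edge.length = float(rng.uniform(lo, hi))
        nodes.append(nd)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        parent.edge.length = float(rng.uniform(lo, hi))
        nodes = [nd for k, nd in enumerate(nodes) if k not in (i, j)] + [parent]
    return nodes[0]


def clade_structured_tree(
    clade_taxa: Mapping[int, list[str]],
    seed: int,
    length_range: tuple[float, float] = (0.02, 0.3),
) -> dendropy.Tree:
    """Random tree in which each clade group is monophyletic.

    Clade subtrees hang off a random backbone (Yule-like sequential joins);
    branch lengths are uniform draws from ``length_range``.
    """
    rng = np.random.default_rng(seed)
    all_taxa = [t for taxa in clade_taxa.values() for t in taxa]
    namespace = dendropy.TaxonNamespace(all_taxa)
    subtrees = [
        _random_subtree(taxa, namespace, rng, length_range)
        for _, taxa in sorted(clade_taxa.items())
    ]
    while len(subtrees) > 1:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        parent = dendropy.Node()
        parent.add_child(subtrees[i])
        parent.add_child(subtrees[j])
        parent.edge.length = float(rng.uniform(*length_range))
        subtrees = [nd for k, nd in enumerate(subtrees) if k not in (i, j)] + [parent]
    tree = dendropy.Tree(taxon_namespace=namespace)
    tree.seed_node = subtrees[0]
    tree.seed_node.edge.length = None
    tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# packaged fixtures
# ---------------------------------------------------------------------------

def _fixture_clade_table(groups: Mapping[int, tuple[str, str, int]]) -> tuple[CladeGroupTable, dict[int, list[str]]]:
    """groups: group_id -> (group_name, superorder, n_taxa)."""
    entries: dict[str, CladeGroupEntry] = {}
    clade_taxa: dict[int, list[str]] = {}
    for gid, (name, superorder, n) in sorted(groups.items()):
        taxa = [f"g{gid}_t{k + 1}" for k in range(n)]
        clade_taxa[gid] = taxa
        for t in taxa:
            entries[t] = CladeGroupEntry(gid, name, superorder)
    return CladeGroupTable(entries), clade_taxa


def marine_domain_map(region_length: int = 400, reference_taxon: str = "g14_t1") -> DomainMap:
    """Three equal-length analysis regions on a gap-free reference."""
    L = 3 * region_length
    return DomainMap(
        reference_taxon,
        L,
        {
            "ARD1_9": [(1, region_length)],
            "ARD10_16_linker": [(region_length + 1, 2 * region_length)],
            "S1_S6_COOH": [(2 * region_length + 1, L)],
        },
    )


def make_marine_fixture(
    seed: int,
    model: SubstitutionModel,
    n_per_group: int = 3,
    region_length: int = 400,
    sensor_multiplier: float = 3.0,
) -> SimulatedDataset:
    """Four clade groups mimicking an aquatic/terrestrial contrast.

    Group 14 plays the aquatic clade: its ARD1_9 ("sensor") region evolves at
    ``sensor_multiplier`` times the base rate; everything else at 1.  Setting
    the multiplier to 1 yields the null (homogeneous) dataset.
    """
    table, clade_taxa = _fixture_clade_table(
        {
            14: ("aquatic_A", "cladeI", n_per_group),
            15: ("terrestrial_B", "cladeI", n_per_group),
            16: ("terrestrial_C", "cladeI", n_per_group),
            17: ("terrestrial_D", "cladeII", n_per_group),
        }
    )
    tree = clade_structured_tree(clade_taxa, seed)
    domain_map = marine_domain_map(region_length)
    multipliers = {(14, "ARD1_9"): float(sensor_multiplier)}
    config = SimulationConfig(
        tree=tree,
        seq_length=domain_map.reference_length,
        domain_map=domain_map,
        clade_groups=table,
        seed=seed,
        rate_multipliers=multipliers,
    )
    dataset = simulate_alignment(config, model)
    dataset.truth["aquatic_group"] = 14
    dataset.truth["sensor_region"] = "ARD1_9"
    return dataset


def residue_domain_map(reference_taxon: str = "g26_t1") -> DomainMap:
    """Short map with an S5 display window around the diagnostic position."""
    return DomainMap(
        reference_taxon,
        900,
        {
            "ARD1_9": [(1, 300)],
            "ARD10_16_linker": [(301, 600)],
            "S1_S6_COOH": [(601, 900)],
            "S5": [(854, 890)],
        },
    )


def make_residue_fixture(
    seed: int,
    model: SubstitutionModel,
    n_per_group: int = 4,
    position: int = 878,
) -> SimulatedDataset:
    """Three clade groups with a planted diagnostic column.

    The myomorph-like group (25, thermal label ``cold``) carries G at the
    diagnostic position; the lagomorph-like (24) and primate-like (26) groups
    (both ``insensitive``) carry V.  Background columns vary with the seed;
    the planted column never does.
    """
    table, clade_taxa = _fixture_clade_table(
        {
            24: ("lagomorph_like", "euarchontoglires", n_per_group),
            25: ("myomorph_like", "euarchontoglires", n_per_group),
            26: ("primate_like", "euarchontoglires", n_per_group),
        }
    )
    tree = clade_structured_tree(clade_taxa, seed)
    domain_map = residue_domain_map()
    config = SimulationConfig(
        tree=tree,
        seq_length=domain_map.reference_length,
        domain_map=domain_map,
        clade_groups=table,
        seed=seed,
        planted_column=(position, {24: "V", 25: "G", 26: "V"}),
    )
    dataset = simulate_alignment(config, model)
    dataset.thermal = ThermalAnnotation({24: "insensitive", 25: "cold", 26: "insensitive"})
    dataset.truth["expected_calls"] = {24: "V", 25: "G", 26: "V"}
    return dataset
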