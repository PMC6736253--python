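"""Synthetic data with planted ground truth.

The generator emulates the statistical structure the analysis assumes on
real data: a rooted binary species tree partitioned into monophyletic
supergroups on both sides of the root; domain families gained at the
root (ancestral domains) and lost independently on branches; and
per-species detection failures — genes present in the genome but missing
from the predicted proteome ("unpredicted"), and pseudogenes whose
genomic copy carries an in-frame stop codon.  Concrete genome and
proteome FASTA fixtures are emitted with a manifest recording every
planted segment, so detector recall/precision and the downstream
correction can be scored against exact ground truth.

Sequence realism is deliberately limited: detection is by planted
consensus motif, not by divergent homology, and there are no introns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .io import DomainModel
from .tree import Node, SpeciesTree

__all__ = [
    "SimParams",
    "DomainEvents",
    "generate_species_tree",
    "simulate_dollo_evolution",
    "inject_detection_failures",
    "make_domain_models",
    "emit_sequences",
]

# ground-truth statuses per (domain, species)
PREDICTED_PRESENT = "predicted_present"
UNPREDICTED = "unpredicted"
PSEUDOGENE = "pseudogene"
LOST = "lost"
PRE_GAIN = "pre_gain"

_AA = "ACDEFGHIKLMNPQRSTVWY"
_NT = "ACGT"


@dataclass
class SimParams:
    """Study-condition knobs for one synthetic dataset.

    Defaults describe a mid-sized eukaryote-wide survey: 50 species in 6
    supergroups, 400 root-gained (ancestral) domain families, a 5%
    per-branch loss probability, a 10% chance for a present gene to be
    missing from the predicted proteome and a 2% chance for it to be a
    pseudogene.
    """

    n_species: int = 50
    n_supergroups: int = 6
    n_domains: int = 400
    p_loss_per_branch: float = 0.05
    p_unpredicted: float = 0.10
    p_pseudogene: float = 0.02
    peptide_length_range: tuple[int, int] = (20, 40)
    spacer_length_range: tuple[int, int] = (30, 120)
    codon_table: int = 1
    seed: int = 0

    def __post_init__(self):
        for name in ("p_loss_per_branch", "p_unpredicted", "p_pseudogene"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.p_unpredicted + self.p_pseudogene > 1.0:
            raise ValueError("p_unpredicted + p_pseudogene must be <= 1")
        if self.n_supergroups < 3:
            raise ValueError("n_supergroups must be >= 3 so ancestral-content criteria are satisfiable")


@dataclass
class DomainEvents:
    """Planted evolutionary history of one domain family."""

    domain_id: str
    gain_node: str
    loss_branches: list[str] = field(default_factory=list)


def _random_binary_join(nodes: list[Node], rng: np.random.Generator, prefix: str, counter: list[int]) -> Node:
    """Join subtrees into a random binary tree by repeated pair merging."""
    nodes = list(nodes)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        counter[0] += 1
        parent = Node(id=f"{prefix}{counter[0]}")
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent.children = [a, b]
        a.parent = parent
        b.parent = parent
        nodes.append(parent)
    return nodes[0]


def generate_species_tree(n_species: int, n_supergroups: int = 6, seed: int = 0) -> SpeciesTree:
    """Random rooted binary species tree with monophyletic supergroups.

    Species are partitioned into ``n_supergroups`` contiguous clades and
    the supergroup clades are distributed over both sides of the root.
    Deterministic for a given seed.
    """
    if n_species < 4:
        raise ValueError("n_species must be >= 4")
    if n_supergroups < 2:
        raise ValueError("n_supergroups must be >= 2")
    if n_supergroups > n_species:
        raise ValueError("cannot have more supergroups than species")
    rng = np.random.default_rng(seed)
    # sizes: at least 1 species per supergroup, remainder spread randomly
    sizes = np.ones(n_supergroups, dtype=int)
    for _ in range(n_species - n_supergroups):
        sizes[rng.integers(n_supergroups)] += 1
    counter = [0]
    sg_roots = []
    sp = 0
    for g in range(n_supergroups):
        label = f"SG{g + 1}"
        leaves = []
        for _ in range(sizes[g]):
            sp += 1
            sid = f"sp{sp:03d}"
            leaves.append(Node(id=sid, species_id=sid, supergroup=label))
        sg_roots.append(_random_binary_join(leaves, rng, "n", counter))
    # split supergroup clades over the two root sides, both non-empty
    order = rng.permutation(n_supergroups)
    n_left = int(rng.integers(1, n_supergroups))
    left = [sg_roots[i] for i in order[:n_left]]
    right = [sg_roots[i] for i in order[n_left:]]
    left_root = _random_binary_join(left, rng, "n", counter)
    right_root = _random_binary_join(right, rng, "n", counter)
    root = Node(id="root")
    root.children = [left_root, right_root]
    left_root.parent = root
    right_root.parent = root
    return SpeciesTree(root)


def simulate_dollo_evolution(
    tree: SpeciesTree,
    n_domains: int,
    p_loss_per_branch: float,
    seed: int = 0,
    gain_at_root: bool = True,
) -> tuple[pd.DataFrame, dict[str, DomainEvents]]:
    """Evolve domains under the single-gain model the reconstruction assumes.

    Each domain is gained once (at the root by default, matching an
    ancestral-repertoire analysis; optionally at a random node to
    exercise pre-gain handling) and lost independently on each branch
    below the gain with probability ``p_loss_per_branch``; once lost on
    a lineage it is never regained.

    Returns the true leaf presence matrix (domains x species) and the
    per-domain event log.
    """
    if not (0.0 <= p_loss_per_branch <= 1.0):
        raise ValueError("p_loss_per_branch must be in [0, 1]")
    rng = np.random.default_rng(seed)
    species = tree.species_ids
    internal = [n for n in tree.nodes if not n.is_leaf]
    matrix = pd.DataFrame(0, index=pd.Index([f"D{i + 1:04d}" for i in range(n_domains)], name="domain_id"),
                          columns=species, dtype="int8")
    events: dict[str, DomainEvents] = {}
    for domain_id in matrix.index:
        gain = tree.root if gain_at_root else internal[rng.integers(len(internal))]
        ev = DomainEvents(domain_id=domain_id, gain_node=gain.id)

        def descend(node: Node, present: bool) -> None:
            if node.is_leaf:
                if present:
                    matrix.at[domain_id, node.species_id] = 1
                return
            for child in node.children:
                child_present = present
                if present and rng.random() < p_loss_per_branch:
                    child_present = False
                    ev.loss_branches.append(child.id)
                descend(child, child_present)

        descend(gain, True)
        events[domain_id] = ev
    return matrix, events


def inject_detection_failures(
    truth_matrix: pd.DataFrame,
    p_unpredicted: float,
    p_pseudogene: float,
    seed: int = 0,
    events: Mapping[str, DomainEvents] | None = None,
    tree: SpeciesTree | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Overlay gene-prediction failures on the true presence matrix.

    For every truly-present cell a single uniform draw decides its fate:
    pseudogene with probability ``p_pseudogene``, unpredicted with
    probability ``p_unpredicted``, otherwise predicted as present — so
    the two failure modes are mutually exclusive and each occurs at its
    nominal marginal rate.  Truly-absent cells are labelled ``lost``, or
    ``pre_gain`` when the species lies outside the domain's gain subtree
    (requires the event log and tree).

    Returns the observed proteome presence matrix and the status matrix.
    """
    if p_unpredicted + p_pseudogene > 1.0:
        raise ValueError("p_unpredicted + p_pseudogene must be <= 1")
    rng = np.random.default_rng(seed)
    observed = truth_matrix.copy()
    statuses = pd.DataFrame(LOST, index=truth_matrix.index, columns=truth_matrix.columns, dtype=object)
    pre_gain_species: dict[str, set[str]] = {}
    if events is not None and tree is not None:
        for domain_id, ev in events.items():
            gain = tree.node(ev.gain_node)
            inside = {l.species_id for l in gain.leaves()}
            outside = set(tree.species_ids) - inside
            if outside:
                pre_gain_species[domain_id] = outside
    for domain_id in truth_matrix.index:
        outside = pre_gain_species.get(domain_id, ())
        row = truth_matrix.loc[domain_id]
        for species_id in truth_matrix.columns:
            if row[species_id]:
                u = rng.random()
                if u < p_pseudogene:
                    statuses.at[domain_id, species_id] = PSEUDOGENE
                    observed.at[domain_id, species_id] = 0
                elif u < p_pseudogene + p_unpredicted:
                    statuses.at[domain_id, species_id] = UNPREDICTED
                    observed.at[domain_id, species_id] = 0
                else:
                    statuses.at[domain_id, species_id] = PREDICTED_PRESENT
            elif species_id in outside:
                statuses.at[domain_id, species_id] = PRE_GAIN
    return observed, statuses


def make_domain_models(
    n_domains: int,
    seed: int = 0,
    length_range: tuple[int, int] = (20, 40),
    domain_ids: list[str] | None = None,
) -> dict[str, DomainModel]:
    """Random consensus peptides, one per domain family.

    The score cutoff is set to the peptide length: an exact occurrence
    scores exactly the length, so cutoff filtering keeps perfect matches
    (including stop-tolerated pseudogene copies) and drops degraded ones.
    """
    rng = np.random.default_rng(seed)
    if domain_ids is None:
        domain_ids = [f"D{i + 1:04d}" for i in range(n_domains)]
    models = {}
    for domain_id in domain_ids:
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        pep = "".join(rng.choice(list(_AA), size=length))
        models[domain_id] = DomainModel(
            domain_id=domain_id, model_length=length, score_cutoff=float(length), consensus_peptide=pep
        )
    return models


def _codon_maps(table_id: int) -> tuple[dict[str, list[str]], list[str]]:
    table = CodonTable.unambiguous_dna_by_id[table_id]
    by_aa: dict[str, list[str]] = {}
    for codon, aa in sorted(table.forward_table.items()):
        by_aa.setdefault(aa, []).append(codon)
    return by_aa, sorted(table.stop_codons)


def back_translate(peptide: str, rng: np.random.Generator, table_id: int = 1) -> str:
    """Back-translate with uniformly random synonymous codons (never stops)."""
    by_aa, _stops = _codon_maps(table_id)
    return "".join(by_aa[aa][rng.integers(len(by_aa[aa]))] for aa in peptide)


def _rc(dna: str) -> str:
    return dna.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def emit_sequences(
    statuses: pd.DataFrame,
    models: Mapping[str, DomainModel],
    params: SimParams,
) -> tuple[dict[str, str], dict[str, dict[str, str]], pd.DataFrame]:
    """Emit per-species genome and proteome sequences plus a manifest.

    Every domain with a genomic copy in a species (statuses
    ``predicted_present``, ``unpredicted`` or ``pseudogene``) is
    back-translated and embedded in that species' single contig at a
    random strand and frame, separated by random background spacers so
    planted segments never overlap.  Pseudogene copies get exactly one
    strictly internal codon replaced by a stop codon of the active
    table.  Predicted-present domains additionally appear as proteins
    in the proteome.

    Returns ``(genomes, proteomes, manifest)`` where genomes maps
    species_id -> contig sequence, proteomes maps species_id ->
    {protein_id: peptide} and the manifest records one row per embedded
    segment: domain, species, contig, interval, strand, frame, status.
    """
    rng = np.random.default_rng(params.seed + 101)
    _by_aa, stops = _codon_maps(params.codon_table)
    genomes: dict[str, str] = {}
    proteomes: dict[str, dict[str, str]] = {}
    manifest_rows = []
    lo_sp, hi_sp = params.spacer_length_range
    for species_id in statuses.columns:
        parts: list[str] = []
        pos = 0
        pending = []  # (start, end, strand, domain_id, status)
        proteome: dict[str, str] = {}
        p_idx = 0
        for domain_id in statuses.index:
            status = statuses.at[domain_id, species_id]
            if status not in (PREDICTED_PRESENT, UNPREDICTED, PSEUDOGENE):
                continue
            pep = models[domain_id].consensus_peptide
            nt = back_translate(pep, rng, params.codon_table)
            if status == PSEUDOGENE:
                if len(pep) < 3:
                    raise ValueError("peptide too short to plant an internal stop")
                k = int(rng.integers(1, len(pep) - 1))  # strictly internal codon
                stop = stops[rng.integers(len(stops))]
                nt = nt[: 3 * k] + stop + nt[3 * (k + 1):]
            strand = "+" if rng.random() < 0.5 else "-"
            segment = nt if strand == "+" else _rc(nt)
            spacer_len = int(rng.integers(lo_sp, hi_sp + 1))
            spacer = "".join(rng.choice(list(_NT), size=spacer_len))
            parts.append(spacer)
            pos += spacer_len
            start = pos
            parts.append(segment)
            pos += len(segment)
            pending.append((start, pos, strand, domain_id, status))
            if status == PREDICTED_PRESENT:
                p_idx += 1
                proteome[f"{species_id}_p{p_idx}"] = pep
        tail = "".join(rng.choice(list(_NT), size=int(rng.integers(lo_sp, hi_sp + 1))))
        parts.append(tail)
        genome = "".join(parts)
        contig_id = f"{species_id}_chr1"
        genomes[species_id] = genome
        proteomes[species_id] = proteome
        L = len(genome)
        for start, end, strand, domain_id, status in pending:
            if strand == "+":
                frame = (start % 3) + 1
            else:
                frame = -(((L - end) % 3) + 1)
            manifest_rows.append(
                {
                    "domain_id": domain_id,
                    "species_id": species_id,
                    "contig_id": contig_id,
                    "start": start,
                    "end": end,
                    "strand": strand,
                    "frame": frame,
                    "status": status,
                }
            )
    manifest = pd.DataFrame(
        manifest_rows,
        columns=["domain_id", "species_id", "contig_id", "start", "end", "strand", "frame", "status"],
    )
    return genomes, proteomes, manifest
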