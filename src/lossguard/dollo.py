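"""Dollo-parsimony ancestral content reconstruction and absence classes.

Under the Dollo model a domain family is gained exactly once on the tree
and can only be lost afterwards; the reconstruction minimising losses
places the gain at the most recent common ancestor (MRCA) of the
present-day carriers and marks an internal node present iff at least one
of its descendant leaves is present.  Losses are the present-to-absent
transitions, attributed to the child node of the transition branch.

Absent leaves inside the gain subtree fall into two categories:

* **species-specific** — the parent node is reconstructed present, i.e.
  the loss happened on the terminal branch and no sister taxon supports
  the absence;
* **clade-specific** — the parent node is reconstructed absent, i.e. the
  absence is shared with neighbouring species through an ancestral loss.

Species-specific absences are the biologically suspicious class: an
absence seen in a single species amidst a carrying clade is a prime
candidate for a gene-prediction artifact rather than a real loss.

Ancestral (LECA) membership additionally requires a phylogenetic spread
criterion — presence in at least three supergroups and on both sides of
the root — and, in the strict variant, survival of a horizontal-transfer
screen (see :mod:`lossguard.hgt`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .tree import Node, SpeciesTree

__all__ = [
    "DolloReconstruction",
    "AbsenceRecord",
    "LossSummary",
    "reconstruct",
    "count_losses",
    "leca_filter",
    "classify_absences",
]

PRESENT = "present"
ABSENT = "absent"
PRE_GAIN = "pre_gain"

SPECIES_SPECIFIC = "species_specific"
CLADE_SPECIFIC = "clade_specific"


@dataclass
class DolloReconstruction:
    """Minimal-loss single-gain history of one domain on a species tree."""

    domain_id: str
    gain_node: str
    node_states: dict[str, str]  # node id -> present | absent | pre_gain
    loss_branches: list[str]  # child-node ids of present->absent branches

    @property
    def n_losses(self) -> int:
        return len(self.loss_branches)


@dataclass(frozen=True)
class AbsenceRecord:
    """One absence call for a leaf inside the gain subtree."""

    domain_id: str
    species_id: str
    category: str  # species_specific | clade_specific
    found_in_genome: bool = False
    pseudogene_only: bool = False


@dataclass
class LossSummary:
    per_domain: dict[str, int]
    total: int
    median: float
    distribution: dict[int, int]  # loss count -> number of domains


def reconstruct(tree: SpeciesTree, presence: Mapping[str, int], domain_id: str = "") -> DolloReconstruction:
    """Reconstruct the minimal-loss single-gain history of one domain.

    Parameters
    ----------
    tree:
        The species tree.
    presence:
        species_id -> 0/1 for every leaf of the tree.

    Raises
    ------
    ValueError
        If no leaf is present (the gain is unplaceable) or the profile
        does not cover the leaf set.
    """
    missing = set(tree.species_ids) - set(presence)
    if missing:
        raise ValueError(f"profile missing species: {sorted(missing)[:5]}")
    present_leaves = [sid for sid in tree.species_ids if presence[sid]]
    if not present_leaves:
        raise ValueError(f"all-absent profile for domain {domain_id!r}: no gain node placeable")

    gain = tree.mrca(present_leaves)
    states: dict[str, str] = {}

    def fill(node: Node) -> bool:
        """Post-order: present iff >= 1 descendant leaf present."""
        if node.is_leaf:
            state = bool(presence[node.species_id])
        else:
            left = fill(node.children[0])
            right = fill(node.children[1])
            state = left or right
        states[node.id] = PRESENT if state else ABSENT
        return state

    fill(gain)
    for node in tree.root.postorder():
        if node.id not in states:
            states[node.id] = PRE_GAIN

    losses = [
        node.id
        for node in gain.preorder()
        if node is not gain and states[node.parent.id] == PRESENT and states[node.id] == ABSENT
    ]
    return DolloReconstruction(
        domain_id=domain_id, gain_node=gain.id, node_states=states, loss_branches=losses
    )


def count_losses(reconstructions: Iterable[DolloReconstruction]) -> LossSummary:
    """Total, per-domain, median and distribution of loss counts."""
    per_domain = {rec.domain_id: rec.n_losses for rec in reconstructions}
    counts = np.array(list(per_domain.values()), dtype=int)
    distribution: dict[int, int] = {}
    for c in counts:
        distribution[int(c)] = distribution.get(int(c), 0) + 1
    return LossSummary(
        per_domain=per_domain,
        total=int(counts.sum()) if counts.size else 0,
        median=float(np.median(counts)) if counts.size else float("nan"),
        distribution=dict(sorted(distribution.items())),
    )


def leca_filter(
    tree: SpeciesTree,
    matrix: pd.DataFrame,
    min_supergroups: int = 3,
    require_both_sides: bool = True,
    hgt_flags: Mapping[str, bool] | None = None,
) -> pd.DataFrame:
    """Classify each domain's ancestral (LECA) membership.

    Non-strict membership requires presence in at least
    ``min_supergroups`` supergroups and (by default) on both sides of
    the root; strict membership additionally requires the domain not to
    be flagged as a horizontal transfer.

    Returns a DataFrame indexed by domain with columns
    ``n_supergroups_present, both_sides_of_root, hgt_flagged,
    in_leca_nonstrict, in_leca_strict``.
    """
    if list(matrix.columns) != tree.species_ids and set(matrix.columns) != set(tree.species_ids):
        raise ValueError("matrix species do not match tree leaves")
    hgt_flags = hgt_flags or {}
    sg = pd.Series(tree.supergroups)
    side = pd.Series(tree.root_sides)
    rows = []
    for domain_id, row in matrix.iterrows():
        present = row[row == 1].index
        n_sg = sg.loc[present].nunique()
        sides = set(side.loc[present])
        both = {"left", "right"} <= sides
        nonstrict = n_sg >= min_supergroups and (both or not require_both_sides)
        flagged = bool(hgt_flags.get(domain_id, False))
        rows.append(
            {
                "domain_id": domain_id,
                "n_supergroups_present": int(n_sg),
                "both_sides_of_root": both,
                "hgt_flagged": flagged,
                "in_leca_nonstrict": nonstrict,
                "in_leca_strict": nonstrict and not flagged,
            }
        )
    return pd.DataFrame(rows).set_index("domain_id")


def classify_absences(tree: SpeciesTree, rec: DolloReconstruction) -> list[AbsenceRecord]:
    """Categorise every absent leaf inside the gain subtree.

    Parent reconstructed present -> species-specific (a terminal-branch
    loss, unsupported by sister taxa); parent reconstructed absent ->
    clade-specific (shared with the neighbouring species through an
    ancestral loss).  Leaves outside the gain subtree (pre-gain) yield
    no record.
    """
    records = []
    gain = tree.node(rec.gain_node)
    for leaf in gain.leaves():
        if rec.node_states[leaf.id] != ABSENT:
            continue
        if leaf is gain:  # gain at a leaf: cannot be absent (gain requires a present leaf)
            continue
        parent_state = rec.node_states[leaf.parent.id]
        category = SPECIES_SPECIFIC if parent_state == PRESENT else CLADE_SPECIFIC
        records.append(AbsenceRecord(domain_id=rec.domain_id, species_id=leaf.species_id, category=category))
    return records
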