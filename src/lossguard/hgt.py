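"""Horizontal-gene-transfer screening of ancestral-content candidates.

Naive single-gain reconstruction is fooled by horizontal transfers from
prokaryotes: independent acquisitions on both sides of the eukaryotic
root look exactly like ancestral presence plus massive loss.  The screen
works on externally inferred per-domain gene trees containing both
prokaryotic and eukaryotic sequences:

1. The eukaryotic sequence set is first reduced to cross-root
   bidirectional best hits (BBHs) — mutual best-scoring pairs between
   the two sides of the eukaryotic root — before tree inference
   (tree inference itself is an external step; trees are inputs here).
2. In each gene tree, every *maximal* monophyletic all-eukaryote clade
   is tested: it must contain species from both sides of the eukaryotic
   root, and the mean over five supergroup presence percentages
   (distinct species with a homolog in the clade, including unsampled
   sequences assigned to their best representative in the tree, divided
   by the supergroup's total species count) must reach the threshold
   (default 15%).  Such a clade is an ancestral ("LECA") clade.
3. A domain with at least one ancestral clade is accepted; otherwise it
   is flagged as a likely transfer and removed from the strict
   ancestral set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy

__all__ = [
    "LeafMeta",
    "LecaCladeCall",
    "cross_root_bbh",
    "assign_unsampled",
    "annotate_leca_clades",
    "toy_similarity_scores",
]

SUPERGROUPS5 = (
    "Excavata",
    "SAR+Haptista",
    "Archaeplastida+Cryptista",
    "Amoebozoa",
    "Opisthokonta+Apusozoa",
)


@dataclass(frozen=True)
class LeafMeta:
    """Metadata for one gene-tree leaf (a sequence)."""

    kind: str  # "prokaryote" | "eukaryote"
    species_id: str = ""
    root_side: str = ""  # "left" | "right" (eukaryotes)
    supergroup5: str = ""  # five-supergroup scheme (eukaryotes)


@dataclass
class LecaCladeCall:
    """Verdict for one maximal monophyletic eukaryotic clade."""

    clade_leaves: tuple[str, ...]
    has_both_root_sides: bool
    supergroup_percentages: dict[str, float]  # percent, 0..100
    mean_percentage: float
    is_leca_clade: bool


def _best_partner(
    candidates: Sequence[str], score_of: Mapping[str, float]
) -> str:
    """Highest score, ties broken lexicographically by id."""
    return min(candidates, key=lambda c: (-score_of[c], c))


def cross_root_bbh(
    scores: Mapping[tuple[str, str], float],
    left_ids: Sequence[str],
    right_ids: Sequence[str],
) -> list[tuple[str, str]]:
    """Bidirectional best hits between the two sides of the root.

    ``scores`` maps (left_id, right_id) -> similarity (higher is
    better); missing pairs are treated as unscored and never selected.
    A pair (l, r) is selected iff r is l's best-scoring partner on the
    right AND l is r's best on the left, with lexicographic tie-breaks.
    """
    if not left_ids or not right_ids:
        raise ValueError("both root sides must be non-empty")
    best_right: dict[str, str] = {}
    for l in left_ids:
        cands = [r for r in right_ids if (l, r) in scores]
        if cands:
            best_right[l] = _best_partner(cands, {r: scores[(l, r)] for r in cands})
    best_left: dict[str, str] = {}
    for r in right_ids:
        cands = [l for l in left_ids if (l, r) in scores]
        if cands:
            best_left[r] = _best_partner(cands, {l: scores[(l, r)] for l in cands})
    pairs = [
        (l, r)
        for l, r in best_right.items()
        if best_left.get(r) == l
    ]
    return sorted(pairs)


def assign_unsampled(
    scores: Mapping[str, Mapping[str, float]],
) -> dict[str, str]:
    """Assign each unsampled sequence to its best-scoring tree leaf.

    ``scores`` maps unsampled sequence id -> {leaf label: score}.  Ties
    break lexicographically.  Raises on a sequence with no scores.
    """
    assignment = {}
    for seq_id, leaf_scores in scores.items():
        if not leaf_scores:
            raise ValueError(f"sequence {seq_id!r} has no scored tree leaves")
        assignment[seq_id] = _best_partner(list(leaf_scores), leaf_scores)
    return assignment


def _maximal_eukaryote_clades(
    tree: dendropy.Tree, meta: Mapping[str, LeafMeta]
) -> list[list[str]]:
    """Maximal clades whose leaves are all eukaryotic (preorder scan;
    once a clade qualifies, its subclades are not enumerated)."""

    def leaf_labels(node) -> list[str]:
        return [l.taxon.label for l in node.leaf_iter()]

    clades = []
    stack = [tree.seed_node]
    while stack:
        node = stack.pop()
        labels = leaf_labels(node)
        for lab in labels:
            if lab not in meta:
                raise KeyError(f"gene-tree leaf {lab!r} has no metadata")
        if all(meta[lab].kind == "eukaryote" for lab in labels):
            clades.append(labels)
        else:
            stack.extend(node.child_nodes())
    return clades


def annotate_leca_clades(
    gene_tree: dendropy.Tree,
    meta: Mapping[str, LeafMeta],
    supergroup_totals: Mapping[str, int],
    threshold: float = 0.15,
    unsampled_meta: Mapping[str, LeafMeta] | None = None,
    assignments: Mapping[str, str] | None = None,
) -> tuple[list[LecaCladeCall], bool]:
    """Annotate ancestral clades in one gene tree and give the verdict.

    Parameters
    ----------
    gene_tree:
        The per-domain tree (dendropy) with sequence-labelled leaves.
    meta:
        leaf label -> :class:`LeafMeta`.
    supergroup_totals:
        supergroup -> total number of species of that supergroup in the
        dataset (denominator of the presence percentages).
    threshold:
        Minimum mean supergroup presence fraction (default 0.15, i.e.
        a mean of at least 15% — the comparison is inclusive).
    unsampled_meta, assignments:
        Sequences left out of the tree by the BBH reduction, with the
        leaf each was assigned to; their species augment the clade's
        species sets.

    Returns
    -------
    (clade calls, is_leca) where ``is_leca`` is True iff at least one
    clade qualifies; a domain with ``is_leca`` False is HGT-flagged.
    """
    for sg, total in supergroup_totals.items():
        if total <= 0:
            raise ValueError(f"supergroup {sg!r} has non-positive species total")
    assignments = assignments or {}
    unsampled_meta = unsampled_meta or {}
    # unsampled sequences grouped by the leaf they were assigned to
    extra_by_leaf: dict[str, list[LeafMeta]] = {}
    for seq_id, leaf in assignments.items():
        if seq_id not in unsampled_meta:
            raise KeyError(f"assigned sequence {seq_id!r} has no metadata")
        extra_by_leaf.setdefault(leaf, []).append(unsampled_meta[seq_id])

    calls = []
    for labels in _maximal_eukaryote_clades(gene_tree, meta):
        members = [meta[lab] for lab in labels]
        for lab in labels:
            members.extend(extra_by_leaf.get(lab, []))
        sides = {m.root_side for m in members if m.root_side}
        both = {"left", "right"} <= sides
        percentages = {}
        for sg, total in supergroup_totals.items():
            species = {m.species_id for m in members if m.supergroup5 == sg}
            percentages[sg] = 100.0 * len(species) / total
        mean_pct = sum(percentages.values()) / len(percentages) if percentages else 0.0
        calls.append(
            LecaCladeCall(
                clade_leaves=tuple(sorted(labels)),
                has_both_root_sides=both,
                supergroup_percentages=percentages,
                mean_percentage=mean_pct,
                is_leca_clade=both and mean_pct >= 100.0 * threshold,
            )
        )
    return calls, any(c.is_leca_clade for c in calls)


def toy_similarity_scores(seqs_a: Mapping[str, str], seqs_b: Mapping[str, str], k: int = 3) -> dict[tuple[str, str], float]:
    """Shared k-mer count similarity — a fixture-grade stand-in for BLAST
    bitscores when exercising the BBH reduction."""
    def kmers(s: str) -> set[str]:
        return {s[i : i + k] for i in range(len(s) - k + 1)}

    cache_a = {i: kmers(s) for i, s in seqs_a.items()}
    cache_b = {i: kmers(s) for i, s in seqs_b.items()}
    return {
        (a, b): float(len(cache_a[a] & cache_b[b]))
        for a in seqs_a
        for b in seqs_b
    }
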