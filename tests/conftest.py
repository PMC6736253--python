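import itertools

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from lossguard import simulate
from lossguard.tree import SpeciesTree, read_newick_string

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def quartet_sidecar() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "species_id": ["A", "B", "C", "D"],
            "supergroup": ["SG1", "SG1", "SG2", "SG2"],
            "phylum": ["p1", "p1", "p2", "p2"],
            "root_side": ["left", "left", "right", "right"],
        }
    )


@pytest.fixture
def quartet_tree(quartet_sidecar) -> SpeciesTree:
    """((A,B),(C,D)); two supergroups, one per root side."""
    return read_newick_string("((A,B),(C,D));", sidecar=quartet_sidecar)


def random_small_tree(n_leaves: int, seed: int) -> SpeciesTree:
    """Random rooted binary tree with 4-7 leaves for oracle tests."""
    return simulate.generate_species_tree(n_leaves, n_supergroups=2, seed=seed)


def brute_force_dollo_losses(tree: SpeciesTree, profile: dict) -> int:
    """Minimum losses over all single-gain histories, by exhaustive
    enumeration of gain nodes and internal-node state assignments.

    A history places the gain at node g (one absent->present transition
    on the branch above g), keeps everything outside g absent, forbids
    any further absent->present transition, and counts present->absent
    branches.  Independent of the reconstruction code under test.
    """
    present = {s for s, v in profile.items() if v}
    assert present, "profile must have a present leaf"
    best = None
    for gain in tree.root.postorder():
        under = {l.species_id for l in gain.leaves()}
        if not present <= under:
            continue
        if gain.is_leaf:
            losses = 0 if profile[gain.species_id] else None
            if losses is not None and (best is None or losses < best):
                best = losses
            continue
        internal = [n for n in gain.preorder() if not n.is_leaf]
        for bits in itertools.product((0, 1), repeat=len(internal)):
            states = {n.id: b for n, b in zip(internal, bits)}
            if states[gain.id] == 0:
                continue  # gain node itself must be present

            def state(node):
                return profile[node.species_id] if node.is_leaf else states[node.id]

            losses, valid = 0, True
            for node in gain.preorder():
                if node is gain:
                    continue
                ps, cs = state(node.parent), state(node)
                if ps == 0 and cs == 1:
                    valid = False  # second gain: not a Dollo history
                    break
                if ps == 1 and cs == 0:
                    losses += 1
            if valid and (best is None or losses < best):
                best = losses
    return best
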