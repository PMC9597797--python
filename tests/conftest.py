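import numpy as np
import pytest

from dloopkin.io_formats import SequenceRecord
from dloopkin.synthetic_data import BreedSpec, SimConfig


@pytest.fixture
def small_records():
    return [
        SequenceRecord(id="b1", sequence="ACGTACGT", breed="BRKI"),
        SequenceRecord(id="b2", sequence="ACGTACGT", breed="BRKI"),
        SequenceRecord(id="b3", sequence="ACGTACGA", breed="BRKI"),
        SequenceRecord(id="f1", sequence="ACGTACGT", breed="FALL"),
    ]


@pytest.fixture
def three_breed_config():
    """Two breeds sharing recent ancestry and one distant breed.

    The shallow split depth leaves most within-breed lineages uncoalesced
    when they enter the shared haplogroup pools, so the two related breeds'
    genealogies genuinely interleave; the third breed lives in different
    haplogroups entirely.
    """
    w_ab = (0.5, 0.5, 0.0, 0.0, 0.0)
    w_c = (0.0, 0.0, 0.0, 0.5, 0.5)
    return SimConfig(
        breeds=[
            BreedSpec("AAAA", 15, w_ab, region="Egypt"),
            BreedSpec("BBBB", 15, w_ab, region="Egypt"),
            BreedSpec("CCCC", 15, w_c, region="Eastern Asia"),
        ],
        theta=5.0,
        split_depth=0.05,
        seed=11,
    )


def leaf_distances(tree):
    """Patristic tip-tip distances computed by direct root-path traversal
    (test-side oracle, independent of library helpers)."""
    depth = {}
    paths = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        d = (depth[parent] if parent else 0.0) + (node.edge.length or 0.0)
        depth[node] = d
        paths[node] = (paths[parent] if parent else ()) + (node,)
    tips = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
    out = {}
    for a in tips:
        for b in tips:
            if a >= b:
                continue
            pa, pb = paths[tips[a]], paths[tips[b]]
            common = 0
            for x, y in zip(pa, pb):
                if x is y:
                    common += 1
                else:
                    break
            mrca = pa[common - 1]
            out[(a, b)] = depth[tips[a]] + depth[tips[b]] - 2 * depth[mrca]
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
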