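import numpy as np
import pandas as pd
import pytest

from phylou import (Phylogeny, RegimePainting, read_tree,
                    scale_to_unit_height, paint_from_node_states)


@pytest.fixture
def three_tip_tree():
    return scale_to_unit_height(read_tree("((A:0.5,B:0.5):0.5,C:1);"))


@pytest.fixture
def five_tip_tree():
    # balanced-ish ultrametric fixture, height 1
    return read_tree(
        "(((A:0.25,B:0.25):0.25,C:0.5):0.5,(D:0.6,E:0.6):0.4);")


@pytest.fixture
def five_tip_painting(five_tip_tree):
    """One internal shift: the (A,B) clade and its stem are in regime S,
    everything else in regime F (child-state convention)."""
    t = five_tip_tree
    states = {}
    ab = t.mrca(["A", "B"])
    in_s = {ab.index} | {c.index for c in ab.children}
    for n in t.nodes:
        states[n.index] = "S" if n.index in in_s else "F"
    return paint_from_node_states(t, states)


@pytest.fixture
def constant_painting():
    def make(tree, regime="F"):
        return paint_from_node_states(
            tree, {n.index: regime for n in tree.nodes})
    return make


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
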