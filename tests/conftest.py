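"""Shared fixtures: synthetic structures with known ground truth."""

from __future__ import annotations

import numpy as np
import pytest

from aquadefect.structure import Atom, Residue, Structure, TopologyAnnotation
from aquadefect.synthetic import (ChannelSpec, make_bundle_channel,
                                  make_channel_wall, make_ideal_helix,
                                  make_interface_tetramer, make_tailed_bundle)


@pytest.fixture(scope="session")
def helix18():
    return make_ideal_helix(18)


@pytest.fixture(scope="session")
def cylinder_wall():
    """Cylindrical channel wall R=4.0, atom vdw 1.5 -> pore radius 2.5."""
    return make_channel_wall(ChannelSpec(wall_radius_fn=lambda z: 4.0,
                                         z_range=(-10.0, 10.0)))


@pytest.fixture(scope="session")
def cone_wall():
    """Conical wall R(z) = 4 + 0.1 z -> pore radius 2.5 + 0.1 z."""
    return make_channel_wall(ChannelSpec(wall_radius_fn=lambda z: 4.0 + 0.1 * z,
                                         z_range=(-10.0, 10.0)))


@pytest.fixture(scope="session")
def bundle6():
    return make_bundle_channel(6, 9.0, 18)


@pytest.fixture(scope="session")
def bundle_annotation():
    return TopologyAnnotation(
        helix_ranges={f"H{h + 1}": (h * 100 + 1, h * 100 + 18) for h in range(6)})


@pytest.fixture(scope="session")
def interface_tetramer():
    return make_interface_tetramer()


@pytest.fixture(scope="session")
def tailed_bundle():
    return make_tailed_bundle()


@pytest.fixture(scope="session")
def tail_annotation():
    return TopologyAnnotation(
        helix_ranges={f"H{h + 1}": (h * 100 + 1, h * 100 + 18) for h in range(6)},
        c_tail_start=690, phosphosites=[706])


def single_atom_structure(coords, vdw=1.7, chain="A"):
    """Structure of one-atom pseudo-residues at the given coordinates."""
    residues = [
        Residue(aa="X", number=i + 1,
                atoms=[Atom("C", "C", np.asarray(xyz, float), vdw, False)],
                chain=chain, resname="UNK")
        for i, xyz in enumerate(coords)
    ]
    return Structure({chain: residues})


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def salt_bridge_pair(separation: float = 3.0):
    """Two helix fragments: an Arg and a Glu with guanidinium-carboxylate
    nitrogen-oxygen distance set to *separation* Å."""
    h_arg = make_ideal_helix(7, "AAARAAA", start_number=701)
    h_glu = make_ideal_helix(7, "AAAEAAA", start_number=721)
    nh1 = h_arg.residue("A", 704).atom("NH1").xyz
    oe1 = h_glu.residue("A", 724).atom("OE1").xyz
    # move the Glu helix so OE1 sits `separation` from NH1 along x
    target = nh1 + np.array([separation, 0.0, 0.0])
    h_glu.transform(np.eye(3), target - oe1)
    residues = list(h_arg.chains["A"]) + list(h_glu.chains["A"])
    return Structure({"A": residues})
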