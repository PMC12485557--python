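import numpy as np
import pytest

from qgrn import (
    build_transition_map,
    find_attractors,
    parse_boolnet,
)

SWAP_TEXT = "targets, factors\nA, B\nB, A\n"


@pytest.fixture
def swap_net():
    """Two genes copying each other: fixed points 00 and 11 plus the
    2-cycle (01, 10)."""
    return parse_boolnet(SWAP_TEXT)


@pytest.fixture
def swap_tmap(swap_net):
    return build_transition_map(swap_net)


@pytest.fixture
def swap_attractors(swap_tmap):
    return find_attractors(swap_tmap)
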