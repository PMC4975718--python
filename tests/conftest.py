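import numpy as np
import pytest

from streamnet.network import NetworkPointSet, Segment, StreamNetwork, generate_network


@pytest.fixture(scope="session")
def small_net():
    """Three unit-length segments: outlet 1 with headwaters 2 and 3."""
    return StreamNetwork([
        Segment(1, None, 1.0, 2.0, 0.0, 0.0, 0.0, 1.0),
        Segment(2, 1, 1.0, 1.0, 0.0, 1.0, -0.6, 1.8),
        Segment(3, 1, 1.0, 1.0, 0.0, 1.0, 0.6, 1.8),
    ])


@pytest.fixture(scope="session")
def rand_net():
    """A 25-segment random dendritic network."""
    return generate_network(25, seed=42)


@pytest.fixture(scope="session")
def rand_points(rand_net):
    return rand_net.sample_points(40, seed=7)


def walk_to_outlet(net: StreamNetwork, seg_id: int) -> list[int]:
    """Segment ids on the path from seg_id down to the outlet (inclusive)."""
    path = [seg_id]
    while net.segments[path[-1]].downstream_id is not None:
        path.append(net.segments[path[-1]].downstream_id)
    return path


def oracle_pair(net: StreamNetwork, p, q):
    """Path-enumeration oracle: (connected, stream distance, pi weight).

    Walks explicit downstream paths, finds the junction by path
    intersection, and accumulates confluence weights segment by segment —
    independent of the vectorized Euler-tour/cumulative-weight machinery.
    """
    path_p = walk_to_outlet(net, p.segment_id)
    path_q = walk_to_outlet(net, q.segment_id)
    if p.segment_id in path_q or q.segment_id in path_p:
        # flow-connected: pi accumulates over confluences strictly between
        if p.segment_id in path_q:
            down, up_path = p.segment_id, path_q
        else:
            down, up_path = q.segment_id, path_p
        pi = 1.0
        for seg in up_path[:up_path.index(down)]:
            child = net.segments[seg]
            pi *= child.flow / net.segments[child.downstream_id].flow
        return True, abs(p.updist - q.updist), pi
    common = next(s for s in path_p if s in set(path_q))
    junction = net.base_updist[common - 1] + net.segments[common].length
    return False, p.updist + q.updist - 2.0 * junction, 0.0
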