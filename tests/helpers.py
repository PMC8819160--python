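"""Shared test utilities: independent oracles."""

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree


def dense_graph_oracle(mesh, speed, src_point, blocked_fn, radius=3.5):
    """Dijkstra on the subdivided edge graph of the mesh (independent oracle).

    Nodes are the mesh nodes plus all element-edge midpoints; edges connect
    every pair within ``radius`` mm unless a sample point along the segment
    is blocked.
    """
    edges = set()
    for el in mesh.elements:
        for i in range(len(el)):
            for j in range(i + 1, len(el)):
                edges.add((min(el[i], el[j]), max(el[i], el[j])))
    edges = np.array(sorted(edges))
    midpoints = 0.5 * (mesh.nodes[edges[:, 0]] + mesh.nodes[edges[:, 1]])
    cloud = np.concatenate([mesh.nodes, midpoints], axis=0)
    tree = cKDTree(cloud)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    pa, pb = cloud[pairs[:, 0]], cloud[pairs[:, 1]]
    good = np.ones(len(pairs), dtype=bool)
    length = np.linalg.norm(pb - pa, axis=1)
    for f in np.linspace(0.08, 0.92, 8):
        good &= ~blocked_fn(pa + f * (pb - pa))
    w = length[good] / speed
    G = sp.csr_matrix((w, (pairs[good, 0], pairs[good, 1])),
                      shape=(len(cloud), len(cloud)))
    isrc = int(np.argmin(np.linalg.norm(cloud - src_point, axis=1)))
    d = dijkstra(G, directed=False, indices=isrc)
    return d[: mesh.n_nodes]
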