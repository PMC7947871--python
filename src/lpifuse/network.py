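"""Bipartite network topology features for lncRNA-protein pairs.

For a pair (l_i, p_j) the topology feature concatenates the lncRNA's edge
row over all proteins except p_j with the protein's edge column over all
lncRNAs except l_i. The pair's own edge e_ij never appears in its feature
vector, so the feature carries the neighbourhood, not the label. The vector
length is (M-1) + (N-1) = N + M - 2 for an N x M network.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .io import InteractionNetwork, ValidationError

TOPOLOGY_BLOCK_NAME = "LDNet"


class PairIndex(NamedTuple):
    """0-based (lncRNA, protein) position in the network's node orderings."""

    i: int
    j: int


@dataclass
class FeatureBlock:
    """A named feature matrix whose rows align with an ordered pair list."""

    name: str
    pair_list: list[PairIndex]
    matrix: np.ndarray
    dim: int

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.pair_list), self.dim):
            raise ValidationError(
                f"block {self.name!r}: matrix shape {self.matrix.shape} does not "
                f"match {len(self.pair_list)} pairs x dim {self.dim}"
            )
        if not np.all(np.isfinite(self.matrix)):
            raise ValidationError(f"block {self.name!r}: non-finite values")

    @property
    def n_pairs(self) -> int:
        return len(self.pair_list)

    def feature_names(self) -> list[str]:
        return [f"{self.name}:{k}" for k in range(self.dim)]


def _check_pair(net: InteractionNetwork, pair: PairIndex) -> None:
    if not (0 <= pair.i < net.n_lncrna and 0 <= pair.j < net.n_protein):
        raise ValidationError(f"pair {pair} out of range for {net.n_lncrna}x{net.n_protein} network")


def topology_feature(net: InteractionNetwork, pair: PairIndex) -> np.ndarray:
    """Topology feature vector for one pair: L_ij then P_ji, length N+M-2.

    L_ij is l_i's edge indicator to every protein but p_j (in protein order);
    P_ji is p_j's edge indicator to every lncRNA but l_i (in lncRNA order).
    """
    _check_pair(net, pair)
    adj = net.adjacency
    l_half = np.delete(adj[pair.i, :], pair.j)
    p_half = np.delete(adj[:, pair.j], pair.i)
    return np.concatenate([l_half, p_half]).astype(float)


def topology_dim(net: InteractionNetwork) -> int:
    return net.n_lncrna + net.n_protein - 2


def build_topology_block(
    net: InteractionNetwork,
    pairs: Sequence[PairIndex],
    masked_edges: Sequence[PairIndex] = (),
) -> FeatureBlock:
    """Build the topology feature block for a list of pairs.

    ``masked_edges`` are zeroed in a copy of the adjacency before any
    feature is computed. During cross-validation the held-out fold's
    positive edges are masked so that no feature cell of any row (train or
    test) is derived from a held-out label.
    """
    for p in pairs:
        _check_pair(net, PairIndex(*p))
    adj = net.adjacency.copy()
    for e in masked_edges:
        _check_pair(net, PairIndex(*e))
        adj[e[0], e[1]] = 0
    masked_net = InteractionNetwork(net.lncrna_ids, net.protein_ids, adj)
    dim = topology_dim(net)
    mat = np.empty((len(pairs), dim))
    for row, p in enumerate(pairs):
        mat[row] = topology_feature(masked_net, PairIndex(*p))
    return FeatureBlock(TOPOLOGY_BLOCK_NAME, [PairIndex(*p) for p in pairs], mat, dim)
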