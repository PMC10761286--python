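"""Multi-strain complex contagion of knowledge (threshold model with memory).

Twenty independent pieces of knowledge spread over the same contact layers
as the disease.  Each piece starts on a single random node.  A node
acquires a piece only after accumulating K interactions with nodes that
already hold it (threshold with memory); once acquired, knowledge is never
lost (multi-strain SI).  Exposure counters advance on every 2-hour contact
layer, but acquisitions — and with them the eligibility to pass a piece on —
take effect only at the daily (24 h) knowledge update, so a node never
spreads a piece the same day it reached the threshold.  Confined nodes
(isolated or quarantined) neither give nor receive exposures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .netgen import Layer

__all__ = [
    "KnowledgeParams",
    "KnowledgeState",
    "seed_knowledge",
    "exposure_step",
    "daily_update",
    "mean_knowledge",
]


@dataclass(frozen=True)
class KnowledgeParams:
    """Number of circulating knowledge pieces and the exposure threshold K."""

    n_pieces: int = 20
    K: int = 8

    def __post_init__(self) -> None:
        if self.n_pieces < 0:
            raise ValueError("n_pieces must be >= 0")
        if self.K < 1:
            raise ValueError("K must be >= 1")


@dataclass
class KnowledgeState:
    """Node x piece exposure counters and acquisition flags.

    ``acquired`` reflects all acquisitions up to the last daily update;
    ``eligible`` is the snapshot used for spreading during the current day
    (identical to ``acquired`` right after a daily update).
    """

    exposures: np.ndarray   # (N, n_pieces) uint32
    acquired: np.ndarray    # (N, n_pieces) bool
    eligible: np.ndarray    # (N, n_pieces) bool — holders as of last daily update

    @property
    def n_nodes(self) -> int:
        return self.acquired.shape[0]

    @property
    def n_pieces(self) -> int:
        return self.acquired.shape[1]


def seed_knowledge(
    n_nodes: int, params: KnowledgeParams, rng: np.random.Generator
) -> KnowledgeState:
    """Give each piece to one uniformly chosen node (draws independent per
    piece, so a node may by chance hold several pieces)."""
    exposures = np.zeros((n_nodes, params.n_pieces), dtype=np.uint32)
    acquired = np.zeros((n_nodes, params.n_pieces), dtype=bool)
    for k in range(params.n_pieces):
        acquired[int(rng.integers(n_nodes)), k] = True
    return KnowledgeState(exposures, acquired, acquired.copy())


def exposure_step(
    state: KnowledgeState,
    layer: Layer | np.ndarray,
    confined_mask: np.ndarray | None,
    params: KnowledgeParams,
) -> None:
    """Accumulate exposures along one contact layer (both directions).

    For a contact (i, j) with neither node confined, i gains one exposure
    to every piece j held at the last daily update and i has not yet
    acquired, and vice versa.  Repeated contacts with the same holder in
    different layers each count.
    """
    edges = layer.edges if isinstance(layer, Layer) else layer
    if edges.shape[0] == 0 or params.n_pieces == 0:
        return
    if confined_mask is not None:
        keep = ~confined_mask[edges[:, 0]] & ~confined_mask[edges[:, 1]]
        edges = edges[keep]
        if edges.shape[0] == 0:
            return
    a, b = edges[:, 0], edges[:, 1]
    inc_a = state.eligible[b] & ~state.acquired[a]
    inc_b = state.eligible[a] & ~state.acquired[b]
    np.add.at(state.exposures, a, inc_a.astype(np.uint32))
    np.add.at(state.exposures, b, inc_b.astype(np.uint32))


def daily_update(state: KnowledgeState, params: KnowledgeParams) -> int:
    """Activate pending acquisitions and refresh spreading eligibility.

    Returns the number of node-piece acquisitions that became active.
    """
    pending = (state.exposures >= params.K) & ~state.acquired
    n_new = int(pending.sum())
    if n_new:
        state.acquired |= pending
    np.copyto(state.eligible, state.acquired)
    return n_new


def mean_knowledge(state: KnowledgeState) -> float:
    """Mean number of acquired pieces per node, in [0, n_pieces]."""
    return float(state.acquired.sum()) / state.n_nodes
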