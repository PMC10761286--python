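"""Synthetic modular temporal contact networks under a fixed link budget.

A temporal network is a sequence of independent static contact layers, one
per epidemic time step (2 h by default).  Each layer is a draw from a
stochastic block model over ``N`` nodes partitioned into contiguous
clusters ("social bubbles"): any within-cluster node pair is linked with
probability ``p_intra`` and any between-cluster pair with probability
``p_inter``.  The two probabilities are not free: they are tied by a fixed
expected number of links per layer,

    L = sum_i n_i (n_i - 1) / 2 * p_intra  +  sum_i n_i (N - n_i) / 2 * p_inter,

so the modularity ratio ``p = p_intra / p_inter`` can be tuned without
changing the average contact volume.  The default configuration (680 nodes,
10 bubbles of 68, 400 expected links per 2-hour layer) mimics the density
of the Copenhagen Network Study proximity data.

The module also implements *temporal clustering*: a round-robin schedule
that, for ``d`` days at a time, concentrates all inter-bubble contacts onto
matched bubble pairs, rotating the matching until every pair of bubbles
has met.  The matched-pair link probability is boosted so that the expected
numbers of intra- and inter-bubble links per layer are unchanged.
"""

from __future__ import annotations

import csv
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

Matching = tuple[tuple[int, int], ...]

__all__ = [
    "NetworkConfig",
    "Layer",
    "TemporalNetwork",
    "PairingSchedule",
    "pair_counts",
    "expected_links",
    "solve_p_inter",
    "solve_probabilities",
    "matched_pair_probability",
    "round_robin_schedule",
    "sample_layer",
    "build_temporal_network",
    "write_temporal_network",
    "read_temporal_network",
]


# ---------------------------------------------------------------------------
# Link-budget arithmetic
# ---------------------------------------------------------------------------

def pair_counts(cluster_sizes: Sequence[int]) -> tuple[float, float]:
    """Number of intra-cluster and inter-cluster node pairs.

    Returns ``(A, B)`` with ``A = sum_i n_i(n_i-1)/2`` and
    ``B = sum_i n_i(N-n_i)/2`` (each unordered inter pair counted once).
    """
    sizes = np.asarray(cluster_sizes, dtype=float)
    n = sizes.sum()
    intra = float((sizes * (sizes - 1) / 2).sum())
    inter = float((sizes * (n - sizes) / 2).sum())
    return intra, inter


def expected_links(
    N: int,
    cluster_sizes: Sequence[int],
    p_intra: float,
    p_inter: float,
) -> tuple[float, float]:
    """Expected intra- and inter-cluster link counts of one layer."""
    if sum(cluster_sizes) != N:
        raise ValueError("cluster sizes must sum to N")
    if not (0.0 <= p_intra <= 1.0 and 0.0 <= p_inter <= 1.0):
        raise ValueError("probabilities must lie in [0, 1]")
    intra_pairs, inter_pairs = pair_counts(cluster_sizes)
    return intra_pairs * p_intra, inter_pairs * p_inter


def solve_p_inter(
    N: int,
    cluster_sizes: Sequence[int],
    L: float,
    p_intra: float,
) -> float:
    """Solve the link-budget constraint for ``p_inter`` given ``p_intra``.

    Inverts ``L = A p_intra + B p_inter`` (with A, B the intra/inter pair
    counts); raises if the resulting probability leaves [0, 1].
    """
    if sum(cluster_sizes) != N:
        raise ValueError("cluster sizes must sum to N")
    if not 0.0 <= p_intra <= 1.0:
        raise ValueError("p_intra must lie in [0, 1]")
    if L <= 0:
        raise ValueError("L must be positive")
    intra_pairs, inter_pairs = pair_counts(cluster_sizes)
    if inter_pairs == 0:
        raise ValueError("need at least two clusters to place inter links")
    p_inter = (L - intra_pairs * p_intra) / inter_pairs
    if not 0.0 <= p_inter <= 1.0:
        raise ValueError(
            f"no admissible p_inter for p_intra={p_intra}: got {p_inter:.6g}"
        )
    return p_inter


def solve_probabilities(
    cluster_sizes: Sequence[int],
    L: float,
    p: float,
) -> tuple[float, float]:
    """(p_intra, p_inter) for a modularity ratio ``p`` under the budget ``L``.

    Substituting ``p_intra = p * p_inter`` into the budget gives
    ``p_inter = L / (A p + B)``.
    """
    if p < 0:
        raise ValueError("modularity ratio must be non-negative")
    intra_pairs, inter_pairs = pair_counts(cluster_sizes)
    p_inter = L / (intra_pairs * p + inter_pairs)
    p_intra = p * p_inter
    if p_intra > 1.0 or p_inter > 1.0:
        raise ValueError("link budget not attainable with probabilities <= 1")
    return p_intra, p_inter


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class NetworkConfig:
    """Structural parameters of the temporal-network generator.

    ``cluster_sizes`` are the bubble sizes n_i (contiguous node blocks: the
    first n_1 node indices form bubble 0, the next n_2 bubble 1, ...).
    ``L`` is the expected number of links per layer; ``p_intra``/``p_inter``
    must satisfy the link budget.  ``pairing_period_d = 0`` disables
    temporal clustering; a positive value is the number of days each
    round-robin bubble matching stays in force.
    """

    cluster_sizes: tuple[int, ...]
    L: float
    p_intra: float
    p_inter: float
    pairing_period_d: int = 0
    steps_per_day: int = 12
    _sampler: Optional["_LayerSampler"] = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.cluster_sizes = tuple(int(s) for s in self.cluster_sizes)
        if any(s < 2 for s in self.cluster_sizes):
            raise ValueError("every cluster needs at least 2 nodes")
        if not (0.0 <= self.p_intra <= 1.0 and 0.0 <= self.p_inter <= 1.0):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.steps_per_day < 1:
            raise ValueError("steps_per_day must be >= 1")
        if self.pairing_period_d < 0:
            raise ValueError("pairing_period_d must be >= 0")
        li, le = expected_links(self.N, self.cluster_sizes, self.p_intra, self.p_inter)
        if abs((li + le) - self.L) > 1e-9 * max(1.0, abs(self.L)):
            raise ValueError(
                f"(p_intra, p_inter) violate the link budget: "
                f"expected {li + le:.6f} links, declared L={self.L}"
            )

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_modularity(
        cls,
        n_nodes: int,
        n_bubbles: int,
        links: float,
        p: float,
        pairing_period_d: int = 0,
        steps_per_day: int = 12,
    ) -> "NetworkConfig":
        """Equal-size bubbles at modularity ratio ``p = p_intra/p_inter``."""
        if n_nodes % n_bubbles:
            raise ValueError("n_nodes must be divisible by n_bubbles")
        sizes = (n_nodes // n_bubbles,) * n_bubbles
        p_intra, p_inter = solve_probabilities(sizes, links, p)
        return cls(sizes, links, p_intra, p_inter, pairing_period_d, steps_per_day)

    @classmethod
    def from_p_intra(
        cls,
        cluster_sizes: Sequence[int],
        links: float,
        p_intra: float,
        pairing_period_d: int = 0,
        steps_per_day: int = 12,
    ) -> "NetworkConfig":
        sizes = tuple(int(s) for s in cluster_sizes)
        p_inter = solve_p_inter(sum(sizes), sizes, links, p_intra)
        return cls(sizes, links, p_intra, p_inter, pairing_period_d, steps_per_day)

    @classmethod
    def from_probabilities(
        cls,
        cluster_sizes: Sequence[int],
        p_intra: float,
        p_inter: float,
        pairing_period_d: int = 0,
        steps_per_day: int = 12,
    ) -> "NetworkConfig":
        """Config with the budget L implied by the given probabilities."""
        sizes = tuple(int(s) for s in cluster_sizes)
        li, le = expected_links(sum(sizes), sizes, p_intra, p_inter)
        return cls(sizes, li + le, p_intra, p_inter, pairing_period_d, steps_per_day)

    # -- derived quantities -------------------------------------------------

    @property
    def N(self) -> int:
        return sum(self.cluster_sizes)

    @property
    def N_c(self) -> int:
        return len(self.cluster_sizes)

    @property
    def p(self) -> float:
        """Modularity ratio p_intra / p_inter (inf when p_inter == 0)."""
        if self.p_inter == 0.0:
            return float("inf") if self.p_intra > 0 else float("nan")
        return self.p_intra / self.p_inter

    @property
    def offsets(self) -> np.ndarray:
        return np.concatenate(([0], np.cumsum(self.cluster_sizes)))[:-1]

    @property
    def membership(self) -> np.ndarray:
        """node -> cluster index (contiguous blocks)."""
        return np.repeat(np.arange(self.N_c), self.cluster_sizes)

    def sampler(self) -> "_LayerSampler":
        if self._sampler is None:
            self._sampler = _LayerSampler(self)
        return self._sampler


# ---------------------------------------------------------------------------
# Layers and temporal networks
# ---------------------------------------------------------------------------

@dataclass
class Layer:
    """One static contact layer: undirected node pairs with i < j."""

    edges: np.ndarray  # shape (m, 2), int64, i < j, no duplicates

    @property
    def pairs(self) -> set[tuple[int, int]]:
        return {(int(i), int(j)) for i, j in self.edges}

    @property
    def n_links(self) -> int:
        return int(self.edges.shape[0])


@dataclass
class TemporalNetwork:
    """Ordered sequence of contact layers plus the node->cluster map."""

    layers: list[Layer]
    membership: np.ndarray

    def __len__(self) -> int:
        return len(self.layers)


@dataclass
class PairingSchedule:
    """Round-robin tournament of bubble pairings (temporal clustering).

    ``rounds[r]`` is a perfect matching of cluster indices (with a bye
    cluster left unmatched when the cluster count is odd).  The matching in
    force at a given epidemic step cycles through the rounds every
    ``round_length_steps`` steps.
    """

    rounds: tuple[Matching, ...]
    round_length_steps: int

    def matching_at_step(self, step: int) -> Matching:
        r = (step // self.round_length_steps) % len(self.rounds)
        return self.rounds[r]


def round_robin_schedule(
    N_c: int, d_days: int, steps_per_day: int = 12
) -> PairingSchedule:
    """Circle-method round robin: every bubble pair meets exactly once.

    For even ``N_c`` there are ``N_c - 1`` rounds of ``N_c/2`` pairs; for
    odd ``N_c`` a dummy opponent is added and the bubble drawn against it
    sits the round out (no inter-bubble links for that bubble).
    """
    if N_c < 2:
        raise ValueError("need at least two clusters to pair")
    if d_days < 1:
        raise ValueError("d_days must be >= 1")
    teams = list(range(N_c))
    if N_c % 2:
        teams.append(-1)  # bye marker
    n = len(teams)
    rounds: list[Matching] = []
    for _ in range(n - 1):
        pairs = []
        for i in range(n // 2):
            a, b = teams[i], teams[n - 1 - i]
            if a != -1 and b != -1:
                pairs.append((min(a, b), max(a, b)))
        rounds.append(tuple(sorted(pairs)))
        teams = [teams[0]] + [teams[-1]] + teams[1:-1]  # rotate, fix first
    return PairingSchedule(tuple(rounds), d_days * steps_per_day)


def matched_pair_probability(config: NetworkConfig, a: int, b: int) -> float:
    """Boosted link probability for a matched bubble pair.

    Chosen so the pair's expected link count equals the two bubbles'
    combined share of the unmatched inter-cluster budget,
    ``n_a n_b p_pair = [n_a (N - n_a) + n_b (N - n_b)] / 2 * p_inter``.
    For equal bubble sizes this is ``p_inter * (N - n_c) / n_c``.  With a
    full matching the total expected inter-link count is exactly preserved.
    """
    sizes = config.cluster_sizes
    n_a, n_b, N = sizes[a], sizes[b], config.N
    p_pair = config.p_inter * (n_a * (N - n_a) + n_b * (N - n_b)) / (2 * n_a * n_b)
    if p_pair > 1.0:
        raise ValueError(
            f"matched-pair probability {p_pair:.4g} exceeds 1 for bubbles "
            f"({a}, {b}); reduce p_inter or use larger bubbles"
        )
    return p_pair


# ---------------------------------------------------------------------------
# Layer sampling
# ---------------------------------------------------------------------------

def _sample_distinct(rng: np.random.Generator, n: int, m: int) -> np.ndarray:
    """m distinct uniform integers from range(n) (sequential rejection)."""
    if m <= 0:
        return np.empty(0, dtype=np.int64)
    if m >= n:
        return np.arange(n, dtype=np.int64)
    if 3 * m > n:
        return rng.permutation(n)[:m].astype(np.int64)
    draws = rng.integers(0, n, size=m + m // 8 + 8)
    while np.unique(draws).size < m:
        draws = np.concatenate([draws, rng.integers(0, n, size=m // 4 + 8)])
    vals, first = np.unique(draws, return_index=True)
    return vals[np.argsort(first)][:m]


class _LayerSampler:
    """Precomputed index tables for fast SBM layer draws.

    Every intra-cluster node pair is assigned a global index in
    ``[0, A)`` and every inter-cluster pair one in ``[0, B)``; a layer is
    then a binomial count plus a without-replacement draw of indices,
    decoded through lookup tables.  This realizes the exact G(n, p)
    distribution per pair type.
    """

    def __init__(self, config: NetworkConfig):
        self.config = config
        sizes = np.asarray(config.cluster_sizes)
        offsets = config.offsets
        # intra table
        rows, cols = [], []
        for off, n_i in zip(offsets, sizes):
            r, c = np.triu_indices(n_i, k=1)
            rows.append(off + r)
            cols.append(off + c)
        self.intra_i = np.concatenate(rows).astype(np.int64)
        self.intra_j = np.concatenate(cols).astype(np.int64)
        self.n_intra_pairs = self.intra_i.size
        # inter table (all unordered cluster pairs a < b)
        ii, jj = [], []
        for a in range(len(sizes)):
            for b in range(a + 1, len(sizes)):
                va = np.repeat(np.arange(sizes[a]), sizes[b]) + offsets[a]
                vb = np.tile(np.arange(sizes[b]), sizes[a]) + offsets[b]
                ii.append(va)
                jj.append(vb)
        if ii:
            self.inter_i = np.concatenate(ii).astype(np.int64)
            self.inter_j = np.concatenate(jj).astype(np.int64)
        else:
            self.inter_i = np.empty(0, dtype=np.int64)
            self.inter_j = np.empty(0, dtype=np.int64)
        self.n_inter_pairs = self.inter_i.size
        self._offsets = offsets
        self._sizes = sizes

    def sample_edges(
        self, rng: np.random.Generator, matching: Optional[Matching] = None
    ) -> np.ndarray:
        cfg = self.config
        parts = []
        if cfg.p_intra > 0 and self.n_intra_pairs:
            m = rng.binomial(self.n_intra_pairs, cfg.p_intra)
            ks = _sample_distinct(rng, self.n_intra_pairs, m)
            parts.append(np.column_stack((self.intra_i[ks], self.intra_j[ks])))
        if matching is None:
            if cfg.p_inter > 0 and self.n_inter_pairs:
                m = rng.binomial(self.n_inter_pairs, cfg.p_inter)
                ks = _sample_distinct(rng, self.n_inter_pairs, m)
                parts.append(np.column_stack((self.inter_i[ks], self.inter_j[ks])))
        else:
            for a, b in matching:
                p_pair = matched_pair_probability(cfg, a, b)
                if p_pair == 0.0:
                    continue
                n_a, n_b = self._sizes[a], self._sizes[b]
                m = rng.binomial(n_a * n_b, p_pair)
                ks = _sample_distinct(rng, n_a * n_b, m)
                i = self._offsets[a] + ks // n_b
                j = self._offsets[b] + ks % n_b
                parts.append(np.column_stack((i, j)))
        if not parts:
            return np.empty((0, 2), dtype=np.int64)
        return np.concatenate(parts, axis=0)


def sample_layer(
    config: NetworkConfig,
    matching: Optional[Matching],
    rng: np.random.Generator,
) -> Layer:
    """Draw one SBM contact layer.

    With ``matching`` given, inter-bubble links occur only between matched
    bubbles, at the boosted probability that keeps the expected inter-link
    count unchanged (see :func:`matched_pair_probability`).
    """
    if matching is not None:
        seen: set[int] = set()
        for a, b in matching:
            if a == b or a in seen or b in seen:
                raise ValueError("matching must pair distinct clusters at most once")
            seen.update((a, b))
    return Layer(config.sampler().sample_edges(rng, matching))


def build_temporal_network(
    config: NetworkConfig,
    horizon_steps: int,
    rng: np.random.Generator,
) -> TemporalNetwork:
    """Sample ``horizon_steps`` i.i.d. layers (with pairing if configured)."""
    schedule = None
    if config.pairing_period_d > 0:
        schedule = round_robin_schedule(
            config.N_c, config.pairing_period_d, config.steps_per_day
        )
    layers = []
    for t in range(horizon_steps):
        matching = schedule.matching_at_step(t) if schedule else None
        layers.append(sample_layer(config, matching, rng))
    return TemporalNetwork(layers, config.membership)


# ---------------------------------------------------------------------------
# Plain-text I/O
# ---------------------------------------------------------------------------

def write_temporal_network(
    network: TemporalNetwork,
    edges_path: str | Path,
    membership_path: str | Path,
) -> None:
    """Write a timestamped edge list (`step,i,j`) and a membership sidecar."""
    with open(edges_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["step", "i", "j"])
        for step, layer in enumerate(network.layers):
            for i, j in layer.edges:
                writer.writerow([step, int(i), int(j)])
    with open(membership_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["node", "cluster"])
        for node, cluster in enumerate(network.membership):
            writer.writerow([node, int(cluster)])


def read_temporal_network(
    edges_path: str | Path,
    membership_path: str | Path,
    n_steps: Optional[int] = None,
) -> TemporalNetwork:
    """Read a temporal network written by :func:`write_temporal_network`."""
    membership_rows = []
    with open(membership_path, newline="") as fh:
        for row in csv.DictReader(fh):
            membership_rows.append((int(row["node"]), int(row["cluster"])))
    membership_rows.sort()
    membership = np.array([c for _, c in membership_rows], dtype=np.int64)

    by_step: dict[int, list[tuple[int, int]]] = defaultdict(list)
    max_step = -1
    with open(edges_path, newline="") as fh:
        for row in csv.DictReader(fh):
            step = int(row["step"])
            by_step[step].append((int(row["i"]), int(row["j"])))
            max_step = max(max_step, step)
    if n_steps is None:
        n_steps = max_step + 1
    layers = []
    for step in range(n_steps):
        pairs = by_step.get(step, [])
        edges = (
            np.array(pairs, dtype=np.int64)
            if pairs
            else np.empty((0, 2), dtype=np.int64)
        )
        layers.append(Layer(edges))
    return TemporalNetwork(layers, membership)
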