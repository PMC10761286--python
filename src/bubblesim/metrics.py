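"""Scalar indicators and diagnostics of co-simulation ensembles.

The headline indicators mirror the scenario comparison of the study design:

* peak simultaneous infected — the maximum over time of the ensemble-mean
  count of active infected + isolated + true-positive quarantined nodes
  (every currently infected individual, whatever its confinement state);
* knowledge milestone times — the first day the ensemble-mean knowledge
  reaches n_pieces/N_c pieces (the amount initially present in one
  bubble), 50% and 80% of all pieces;
* collateral confinement — the average fraction of nodes confined at least
  once during a run without ever being infected;
* realized modularity — the per-window realized intra/inter link-density
  ratio, a diagnostic that the generated (and confinement-thinned)
  networks actually carry the configured modularity ratio p.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .netgen import TemporalNetwork

__all__ = [
    "Indicators",
    "simultaneous_infected_series",
    "knowledge_milestones",
    "collateral_confinement",
    "realized_modularity",
    "compute_indicators",
]


def simultaneous_infected_series(obj) -> np.ndarray:
    """Pointwise sum of active infected, isolated and true-positive
    quarantined counts.

    Accepts a RunResult, an EnsembleResult (whose mean curves are used), or
    any object with ``I_active``, ``isolated`` and
    ``quarantined_true_positive`` array attributes.
    """
    return (
        np.asarray(obj.I_active, dtype=float)
        + np.asarray(obj.isolated, dtype=float)
        + np.asarray(obj.quarantined_true_positive, dtype=float)
    )


def knowledge_milestones(
    knowledge_series: Sequence[float],
    n_pieces: int,
    N_c: int,
) -> tuple[Optional[int], Optional[int], Optional[int]]:
    """First crossing days of the three knowledge thresholds.

    Thresholds are ``n_pieces / N_c`` (one bubble's initial endowment),
    ``0.5 * n_pieces`` and ``0.8 * n_pieces``.  The series is daily, entry
    d being the mean knowledge at the end of day d (entry 0 = initial).
    A threshold never reached within the horizon is reported as None.
    """
    series = np.asarray(knowledge_series, dtype=float)
    out = []
    for threshold in (n_pieces / N_c, 0.5 * n_pieces, 0.8 * n_pieces):
        crossed = np.flatnonzero(series >= threshold)
        out.append(int(crossed[0]) if crossed.size else None)
    return tuple(out)


def collateral_confinement(runs) -> float:
    """Average % of nodes confined at least once while never infected."""
    fracs = [
        float((run.ever_confined & ~run.ever_infected).sum()) / run.ever_confined.size
        for run in runs
    ]
    return 100.0 * float(np.mean(fracs))


def realized_modularity(
    network: TemporalNetwork,
    free_masks: Optional[Sequence[np.ndarray]] = None,
    window_steps: int = 12,
) -> np.ndarray:
    """Windowed realized (intra density)/(inter density) ratio.

    Edges touching confined nodes (``free_masks``, one boolean mask per
    layer) are removed, as are the confined nodes themselves when counting
    the possible intra/inter pairs.  Windows with zero realized inter-links
    (or no possible pairs of either kind) yield NaN, never infinity.
    """
    membership = network.membership
    n_layers = len(network.layers)
    n_windows = (n_layers + window_steps - 1) // window_steps
    out = np.full(n_windows, np.nan)
    n_clusters = int(membership.max()) + 1 if membership.size else 0
    for w in range(n_windows):
        lo, hi = w * window_steps, min((w + 1) * window_steps, n_layers)
        intra = inter = 0
        poss_intra = poss_inter = 0.0
        for t in range(lo, hi):
            edges = network.layers[t].edges
            if free_masks is not None:
                free = free_masks[t]
                if edges.shape[0]:
                    edges = edges[free[edges[:, 0]] & free[edges[:, 1]]]
                counts = np.bincount(
                    membership[free], minlength=n_clusters
                ).astype(float)
            else:
                counts = np.bincount(membership, minlength=n_clusters).astype(float)
            if edges.shape[0]:
                same = membership[edges[:, 0]] == membership[edges[:, 1]]
                intra += int(same.sum())
                inter += int((~same).sum())
            total = counts.sum()
            poss_intra += float((counts * (counts - 1) / 2).sum())
            poss_inter += float((counts * (total - counts) / 2).sum())
        if inter > 0 and poss_intra > 0 and poss_inter > 0:
            out[w] = (intra / poss_intra) / (inter / poss_inter)
    return out


@dataclass
class Indicators:
    """Scalar ensemble summary with 95% bootstrap confidence intervals."""

    peak_simultaneous_infected: float
    peak_simultaneous_infected_pct: float
    peak_ci_pct: tuple[float, float]
    per_run_peaks: np.ndarray
    t_bubble_knowledge: Optional[int]
    t_50: Optional[int]
    t_80: Optional[int]
    collateral_confinement_pct: float
    collateral_ci_pct: tuple[float, float]
    realized_p_ratio: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "peak_simultaneous_infected": self.peak_simultaneous_infected,
            "peak_simultaneous_infected_pct": self.peak_simultaneous_infected_pct,
            "peak_ci_pct": list(self.peak_ci_pct),
            "per_run_peaks_mean": float(np.mean(self.per_run_peaks)),
            "t_bubble_knowledge": self.t_bubble_knowledge,
            "t_50": self.t_50,
            "t_80": self.t_80,
            "collateral_confinement_pct": self.collateral_confinement_pct,
            "collateral_ci_pct": list(self.collateral_ci_pct),
            "realized_p_ratio": self.realized_p_ratio,
        }


def compute_indicators(
    runs,
    n_nodes: int,
    N_c: int,
    n_pieces: int,
    n_boot: int = 200,
    boot_seed: int = 12345,
) -> Indicators:
    """Ensemble indicators from padded, same-length run series.

    The peak is taken on the ensemble-mean simultaneous-infected curve,
    not as the mean of per-run peaks; per-run peaks are also reported for
    dispersion.  Confidence intervals are percentile bootstrap over runs.
    """
    sim = np.stack([simultaneous_infected_series(r) for r in runs])
    mean_curve = sim.mean(axis=0)
    peak = float(mean_curve.max())
    know = np.stack([np.asarray(r.knowledge_mean, dtype=float) for r in runs])
    mean_know = know.mean(axis=0)
    tb, t50, t80 = knowledge_milestones(mean_know, n_pieces, N_c)
    collat = np.array(
        [
            100.0
            * float((r.ever_confined & ~r.ever_infected).sum())
            / r.ever_confined.size
            for r in runs
        ]
    )
    rng = np.random.default_rng(boot_seed)
    n_runs = len(runs)
    boot_peaks = np.empty(n_boot)
    boot_coll = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n_runs, n_runs)
        boot_peaks[b] = sim[idx].mean(axis=0).max()
        boot_coll[b] = collat[idx].mean()
    pct = 100.0 / n_nodes
    return Indicators(
        peak_simultaneous_infected=peak,
        peak_simultaneous_infected_pct=peak * pct,
        peak_ci_pct=(
            float(np.percentile(boot_peaks, 2.5) * pct),
            float(np.percentile(boot_peaks, 97.5) * pct),
        ),
        per_run_peaks=sim.max(axis=1),
        t_bubble_knowledge=tb,
        t_50=t50,
        t_80=t80,
        collateral_confinement_pct=float(collat.mean()),
        collateral_ci_pct=(
            float(np.percentile(boot_coll, 2.5)),
            float(np.percentile(boot_coll, 97.5)),
        ),
    )
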