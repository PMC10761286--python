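"""Coupled disease/knowledge co-simulation on temporal bubble networks.

Each 2-hour epidemic step: sample the contact layer for the current bubble
matching (if temporal clustering is active), cut all edges touching
confined nodes, run disease transmission, advance disease progression
(isolations trigger 7-day contact tracing), and accumulate knowledge
exposures on the same thinned layer.  At every 24-hour boundary the
knowledge acquisitions pending from the day's exposures are activated.
Both processes are seeded at step 0: one infected individual with a
uniform initial infection age, and one holder per knowledge piece.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import metrics
from .epi import (
    FREE,
    INFECTED,
    EpiParams,
    EpiState,
    InfectivityCurve,
    default_infectivity_curve,
    progression_step,
    seed_infection,
    trace_and_quarantine,
    transmission_step,
)
from .knowledge import (
    KnowledgeParams,
    daily_update,
    exposure_step,
    mean_knowledge,
    seed_knowledge,
)
from .netgen import NetworkConfig, round_robin_schedule

__all__ = ["Scenario", "RunResult", "EnsembleResult", "run_once", "run_ensemble", "sweep"]

EPI_COLUMNS = (
    "S",
    "I_active",
    "isolated",
    "quarantined_total",
    "quarantined_true_positive",
    "R",
)


@dataclass
class Scenario:
    """A fully specified simulation setting."""

    network: NetworkConfig
    epi: EpiParams = field(default_factory=EpiParams)
    knowledge: KnowledgeParams = field(default_factory=KnowledgeParams)
    horizon_days: int = 150
    n_runs: int = 50
    master_seed: int = 0
    early_stop: bool = True        # stop once epidemic over AND knowledge >= 80%
    curve: Optional[InfectivityCurve] = None

    def __post_init__(self) -> None:
        if self.horizon_days < 1 or self.n_runs < 1:
            raise ValueError("horizon_days and n_runs must be >= 1")
        if self.curve is None:
            self.curve = default_infectivity_curve(
                infectious_period_days=self.epi.infectious_period_days
            )


@dataclass
class RunResult:
    """Per-step compartment counts, daily knowledge, per-node histories."""

    S: np.ndarray
    I_active: np.ndarray
    isolated: np.ndarray
    quarantined_total: np.ndarray
    quarantined_true_positive: np.ndarray
    R: np.ndarray
    knowledge_mean: np.ndarray      # entry d = mean knowledge at end of day d; entry 0 initial
    ever_infected: np.ndarray
    ever_confined: np.ndarray
    seed_node: int
    steps_per_day: int

    @property
    def n_steps(self) -> int:
        return self.S.size

    def epi_frame(self) -> pd.DataFrame:
        """Tidy per-step time series (`step,day,S,...,R`)."""
        steps = np.arange(self.n_steps)
        data = {"step": steps, "day": (steps + 1) / self.steps_per_day}
        for col in EPI_COLUMNS:
            data[col] = getattr(self, col)
        return pd.DataFrame(data)

    def knowledge_frame(self) -> pd.DataFrame:
        days = np.arange(self.knowledge_mean.size)
        return pd.DataFrame({"day": days, "mean_knowledge": self.knowledge_mean})

    def padded(self, n_steps: int, n_days: int) -> "RunResult":
        """Extend series to a common length by repeating final values.

        Used to align early-terminated runs in an ensemble; the epidemic is
        over at termination so the padded compartment counts are exact,
        while padded knowledge is a lower bound past the stop day (the stop
        rule requires >= 80% knowledge, so milestones are unaffected).
        """
        if self.n_steps >= n_steps and self.knowledge_mean.size >= n_days + 1:
            return self

        def pad(arr, size):
            if arr.size >= size:
                return arr
            return np.concatenate([arr, np.full(size - arr.size, arr[-1], arr.dtype)])

        kwargs = {col: pad(getattr(self, col), n_steps) for col in EPI_COLUMNS}
        return RunResult(
            knowledge_mean=pad(self.knowledge_mean, n_days + 1),
            ever_infected=self.ever_infected,
            ever_confined=self.ever_confined,
            seed_node=self.seed_node,
            steps_per_day=self.steps_per_day,
            **kwargs,
        )


@dataclass
class EnsembleResult:
    """Runs plus pointwise ensemble-mean curves and scalar indicators."""

    scenario: Scenario
    runs: list[RunResult]
    I_active: np.ndarray
    isolated: np.ndarray
    quarantined_total: np.ndarray
    quarantined_true_positive: np.ndarray
    S: np.ndarray
    R: np.ndarray
    knowledge_mean: np.ndarray
    indicators: metrics.Indicators

    def mean_frame(self) -> pd.DataFrame:
        steps = np.arange(self.S.size)
        data = {
            "step": steps,
            "day": (steps + 1) / self.scenario.network.steps_per_day,
        }
        for col in EPI_COLUMNS:
            data[col] = getattr(self, col)
        data["simultaneous_infected"] = metrics.simultaneous_infected_series(self)
        return pd.DataFrame(data)


def run_once(scenario: Scenario, rng: Optional[np.random.Generator] = None) -> RunResult:
    """One seeded realization of the coupled dynamics."""
    if rng is None:
        rng = np.random.default_rng(scenario.master_seed)
    cfg = scenario.network
    params = scenario.epi
    kparams = scenario.knowledge
    curve = scenario.curve
    spd = cfg.steps_per_day
    step_days = 1.0 / spd
    horizon_steps = scenario.horizon_days * spd

    schedule = None
    if cfg.pairing_period_d > 0:
        schedule = round_robin_schedule(cfg.N_c, cfg.pairing_period_d, spd)
    sampler = cfg.sampler()

    state = EpiState.fresh(cfg.N, params.tracing_window_days * spd)
    seed_node = seed_infection(state, rng, params)
    kstate = seed_knowledge(cfg.N, kparams, rng)

    series = {col: np.zeros(horizon_steps, dtype=np.int32) for col in EPI_COLUMNS}
    kseries = np.zeros(scenario.horizon_days + 1)
    kseries[0] = mean_knowledge(kstate)

    n_steps_done = 0
    day = 0
    for t in range(horizon_steps):
        matching = schedule.matching_at_step(t) if schedule else None
        edges = sampler.sample_edges(rng, matching)
        free = state.free
        edges = edges[free[edges[:, 0]] & free[edges[:, 1]]]
        state.contact_log.append(edges)

        transmission_step(state, edges, params, curve, rng)
        newly_isolated = progression_step(state, params, curve, step_days, t, rng)
        for node in newly_isolated:
            trace_and_quarantine(state, int(node), params, rng, t)
        exposure_step(kstate, edges, None, kparams)

        counts = state.counts()
        for col in EPI_COLUMNS:
            series[col][t] = counts[col]
        n_steps_done = t + 1

        if (t + 1) % spd == 0:
            daily_update(kstate, kparams)
            day += 1
            kseries[day] = mean_knowledge(kstate)
            if (
                scenario.early_stop
                and counts["I_active"] == 0
                and counts["isolated"] == 0
                and counts["quarantined_true_positive"] == 0
                and kseries[day] >= 0.8 * kparams.n_pieces
            ):
                break

    return RunResult(
        **{col: series[col][:n_steps_done] for col in EPI_COLUMNS},
        knowledge_mean=kseries[: day + 1],
        ever_infected=state.ever_infected,
        ever_confined=state.ever_confined,
        seed_node=seed_node,
        steps_per_day=spd,
    )


def run_ensemble(scenario: Scenario) -> EnsembleResult:
    """Monte-Carlo ensemble with independent per-run RNG streams.

    Streams are spawned from ``master_seed`` via numpy's SeedSequence, so
    the full ensemble is reproducible and runs are statistically
    independent.
    """
    children = np.random.SeedSequence(scenario.master_seed).spawn(scenario.n_runs)
    runs = [run_once(scenario, np.random.default_rng(c)) for c in children]
    n_steps = max(r.n_steps for r in runs)
    n_days = max(r.knowledge_mean.size for r in runs) - 1
    runs = [r.padded(n_steps, n_days) for r in runs]

    means = {
        col: np.stack([getattr(r, col) for r in runs]).mean(axis=0)
        for col in EPI_COLUMNS
    }
    know = np.stack([r.knowledge_mean for r in runs]).mean(axis=0)
    cfg = scenario.network
    ind = metrics.compute_indicators(
        runs, cfg.N, cfg.N_c, scenario.knowledge.n_pieces
    )
    return EnsembleResult(
        scenario=scenario,
        runs=runs,
        knowledge_mean=know,
        indicators=ind,
        **means,
    )


def sweep(scenarios: list[Scenario]) -> pd.DataFrame:
    """Run an ensemble per scenario and tabulate indicators.

    Returns a tidy table with one row per scenario: the varied parameters
    (modularity ratio p, eps_I, eps_T, pairing period d) and the scalar
    indicators.
    """
    rows = []
    for sc in scenarios:
        ens = run_ensemble(sc)
        ind = ens.indicators
        rows.append(
            {
                "p": sc.network.p,
                "eps_I": sc.epi.eps_I,
                "eps_T": sc.epi.eps_T,
                "pairing_period_d": sc.network.pairing_period_d,
                "n_runs": sc.n_runs,
                "peak_simultaneous_infected": ind.peak_simultaneous_infected,
                "peak_pct": ind.peak_simultaneous_infected_pct,
                "t_bubble_knowledge": ind.t_bubble_knowledge,
                "t_50": ind.t_50,
                "t_80": ind.t_80,
                "collateral_confinement_pct": ind.collateral_confinement_pct,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "p",
            "eps_I",
            "eps_T",
            "pairing_period_d",
            "n_runs",
            "peak_simultaneous_infected",
            "peak_pct",
            "t_bubble_knowledge",
            "t_50",
            "t_80",
            "collateral_confinement_pct",
        ],
    )
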