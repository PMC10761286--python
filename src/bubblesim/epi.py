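"""Non-Markovian SIR disease dynamics with isolation, tracing and quarantine.

The transmission probability of an infected node depends on its infection
age tau (days since its own contagion) through an infectivity profile
omega(tau) peaking around day 5 and vanishing at day 10, when untreated
individuals recover.  80% of infections are symptomatic; symptom onset
follows a log-normal incubation-time distribution.  Once symptomatic, a
node is detected and isolated with probability eps_I per update step (the
detection process runs at the 2-hour contact cadence); on isolation
its contacts of the last 7 days are traced and each is preventively
quarantined with probability eps_T.  Confined nodes (isolated or
quarantined) make no contacts at all, so they spread neither disease nor
knowledge.  Isolation and quarantine both last 10 days; isolated nodes are
recovered on release, quarantined nodes that turn symptomatic are promoted
to isolation (triggering their own tracing).

The overall transmission scale ``beta`` multiplies omega(tau).  Its default
is calibrated (bisection on :func:`estimate_R0`) so that the index case
generates on average R0 = 1.64 secondary infections on the baseline
network (680 nodes, 10 bubbles, 400 links/layer, modularity ratio 5,
eps_I = 0.1, eps_T = 0).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np
from scipy.special import ndtr

from .netgen import Layer, NetworkConfig, round_robin_schedule

__all__ = [
    "SUSCEPTIBLE",
    "INFECTED",
    "RECOVERED",
    "FREE",
    "ISOLATED",
    "QUARANTINED",
    "DEFAULT_BETA",
    "EpiParams",
    "InfectivityCurve",
    "default_infectivity_curve",
    "EpiState",
    "seed_infection",
    "transmission_step",
    "progression_step",
    "trace_and_quarantine",
    "estimate_R0",
    "calibrate_beta",
]

# status codes
SUSCEPTIBLE, INFECTED, RECOVERED = 0, 1, 2
# confinement codes
FREE, ISOLATED, QUARANTINED = 0, 1, 2

#: Transmission scale calibrated so estimate_R0 ~= 1.64 on the baseline
#: network (p=5, eps_I=0.1, eps_T=0) with the default infectivity profile.
DEFAULT_BETA = 0.05346


@dataclass(frozen=True)
class EpiParams:
    """Disease-model parameters.  Probabilities are per day where noted."""

    eps_I: float = 0.1            # per-step isolation probability once symptomatic
    eps_T: float = 0.0            # per-contact quarantine probability on tracing
    symptomatic_fraction: float = 0.80
    infectious_period_days: int = 10
    isolation_days: int = 10
    quarantine_days: int = 10
    tracing_window_days: int = 7
    beta: float = DEFAULT_BETA    # transmission scale multiplying omega(tau)
    seed_tau_max_days: float = 10.0

    def __post_init__(self) -> None:
        for name in ("eps_I", "eps_T", "symptomatic_fraction", "beta"):
            v = getattr(self, name)
            if name != "beta" and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in (
            "infectious_period_days",
            "isolation_days",
            "quarantine_days",
            "tracing_window_days",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class InfectivityCurve:
    """Infection-age profiles: relative infectiousness and symptom onset.

    ``omega(tau)`` is the relative transmission probability at infection
    age tau (days), non-negative, peaking near day 5 and zero from the end
    of the infectious period on.  ``s(tau)`` is the cumulative probability
    that a symptomatic-course individual has shown symptoms by age tau
    (non-decreasing, s(0) = 0).
    """

    omega: Callable[[np.ndarray], np.ndarray]
    s: Callable[[np.ndarray], np.ndarray]


def default_infectivity_curve(
    infectious_period_days: float = 10.0,
    omega_mode_days: float = 5.0,
    omega_shape: float = 6.0,
    incubation_median_days: float = 5.5,
    incubation_sigma: float = 0.42,
) -> InfectivityCurve:
    """Gamma-shaped infectiousness + log-normal incubation CDF.

    omega is a gamma density with mode at ``omega_mode_days`` (shape k,
    scale mode/(k-1)), normalized to peak 1 and truncated to zero at the
    end of the infectious period.  s is the log-normal CDF with the given
    median and log-scale sigma (values in line with the COVID-19
    incubation-period literature).
    """
    k = omega_shape
    scale = omega_mode_days / (k - 1.0)
    log_med = np.log(incubation_median_days)

    def omega(tau: np.ndarray) -> np.ndarray:
        tau = np.asarray(tau, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.where(
                (tau > 0) & (tau < infectious_period_days),
                (tau / omega_mode_days) ** (k - 1.0)
                * np.exp((omega_mode_days - tau) / scale),
                0.0,
            )
        return rel

    def s(tau: np.ndarray) -> np.ndarray:
        tau = np.asarray(tau, dtype=float)
        out = np.zeros_like(tau)
        pos = tau > 0
        out[pos] = ndtr((np.log(tau[pos]) - log_med) / incubation_sigma)
        return out

    return InfectivityCurve(omega=omega, s=s)


# ---------------------------------------------------------------------------
# State
# ---------------------------------------------------------------------------

@dataclass
class EpiState:
    """Per-node epidemiological state, stored as flat arrays."""

    status: np.ndarray          # int8: S/I/R
    conf: np.ndarray            # int8: free/isolated/quarantined
    conf_end: np.ndarray        # int64: step at which confinement expires
    tau: np.ndarray             # float: infection age in days (0 if not infected)
    will_symptomatic: np.ndarray
    symptomatic: np.ndarray
    ever_infected: np.ndarray
    ever_confined: np.ndarray
    contact_log: deque          # of (m, 2) edge arrays, trailing tracing window

    @classmethod
    def fresh(cls, n_nodes: int, tracing_window_steps: int) -> "EpiState":
        return cls(
            status=np.zeros(n_nodes, dtype=np.int8),
            conf=np.zeros(n_nodes, dtype=np.int8),
            conf_end=np.zeros(n_nodes, dtype=np.int64),
            tau=np.zeros(n_nodes, dtype=float),
            will_symptomatic=np.zeros(n_nodes, dtype=bool),
            symptomatic=np.zeros(n_nodes, dtype=bool),
            ever_infected=np.zeros(n_nodes, dtype=bool),
            ever_confined=np.zeros(n_nodes, dtype=bool),
            contact_log=deque(maxlen=tracing_window_steps),
        )

    @property
    def n_nodes(self) -> int:
        return self.status.size

    @property
    def free(self) -> np.ndarray:
        return self.conf == FREE

    def counts(self) -> dict[str, int]:
        status, conf = self.status, self.conf
        infected = status == INFECTED
        return {
            "S": int((status == SUSCEPTIBLE).sum()),
            "I_active": int((infected & (conf == FREE)).sum()),
            "isolated": int((conf == ISOLATED).sum()),
            "quarantined_total": int((conf == QUARANTINED).sum()),
            "quarantined_true_positive": int(
                ((conf == QUARANTINED) & infected).sum()
            ),
            "R": int((status == RECOVERED).sum()),
        }


def seed_infection(
    state: EpiState, rng: np.random.Generator, params: EpiParams
) -> int:
    """Infect one uniformly chosen node with tau ~ U[0, seed_tau_max_days].

    Returns the seed node index.  Raises if the population is not fully
    susceptible.
    """
    if (state.status != SUSCEPTIBLE).any():
        raise ValueError("seed_infection requires a fully susceptible population")
    node = int(rng.integers(state.n_nodes))
    state.status[node] = INFECTED
    state.tau[node] = float(rng.uniform(0.0, params.seed_tau_max_days))
    state.will_symptomatic[node] = rng.random() < params.symptomatic_fraction
    state.ever_infected[node] = True
    return node


# ---------------------------------------------------------------------------
# Dynamics
# ---------------------------------------------------------------------------

def transmission_step(
    state: EpiState,
    layer: Layer | np.ndarray,
    params: EpiParams,
    curve: InfectivityCurve,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One contact layer of disease transmission.

    For every contact between a free infected node i and a free susceptible
    node j, j is infected independently with probability
    ``beta * omega(tau_i)``.  Returns ``(newly_infected, infectors)``; when
    a node has several successful infectious contacts in the same layer its
    infector is chosen uniformly among them.
    """
    edges = layer.edges if isinstance(layer, Layer) else layer
    empty = np.empty(0, dtype=np.int64)
    if edges.shape[0] == 0:
        return empty, empty
    free = state.free
    both_free = free[edges[:, 0]] & free[edges[:, 1]]
    edges = edges[both_free]
    if edges.shape[0] == 0:
        return empty, empty
    status = state.status
    a, b = edges[:, 0], edges[:, 1]
    fwd = (status[a] == INFECTED) & (status[b] == SUSCEPTIBLE)
    bwd = (status[b] == INFECTED) & (status[a] == SUSCEPTIBLE)
    sources = np.concatenate((a[fwd], b[bwd]))
    targets = np.concatenate((b[fwd], a[bwd]))
    if sources.size == 0:
        return empty, empty
    prob = params.beta * curve.omega(state.tau[sources])
    hit = rng.random(sources.size) < prob
    if not hit.any():
        return empty, empty
    sources, targets = sources[hit], targets[hit]
    perm = rng.permutation(sources.size)
    newly, first = np.unique(targets[perm], return_index=True)
    infectors = sources[perm][first]
    state.status[newly] = INFECTED
    state.tau[newly] = 0.0
    state.will_symptomatic[newly] = (
        rng.random(newly.size) < params.symptomatic_fraction
    )
    state.symptomatic[newly] = False
    state.ever_infected[newly] = True
    return newly, infectors


def progression_step(
    state: EpiState,
    params: EpiParams,
    curve: InfectivityCurve,
    step_days: float,
    step_index: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Advance infection ages, symptoms, confinements and recoveries.

    Order within the step: expire confinements (isolated -> recovered,
    quarantined -> free), advance tau, draw symptom onsets via the
    incremental hazard of s, draw isolations of symptomatic non-isolated
    nodes with probability eps_I per step, then apply
    natural recovery of non-isolated infected nodes at tau >=
    infectious_period_days.  Returns the indices of newly isolated nodes
    (the caller triggers contact tracing for them).
    """
    status, conf = state.status, state.conf
    spd = int(round(1.0 / step_days))

    # confinement expirations
    expired = (conf != FREE) & (state.conf_end <= step_index)
    iso_done = expired & (conf == ISOLATED)
    if iso_done.any():
        status[iso_done] = RECOVERED
    conf[expired] = FREE

    # infection-age advance
    infected = status == INFECTED
    state.tau[infected] += step_days

    # symptom onset via incremental hazard of s(tau)
    cand = infected & state.will_symptomatic & ~state.symptomatic
    if cand.any():
        idx = np.flatnonzero(cand)
        t1 = state.tau[idx]
        t0 = t1 - step_days
        s0, s1 = curve.s(t0), curve.s(t1)
        hazard = (s1 - s0) / np.maximum(1.0 - s0, 1e-12)
        onset = rng.random(idx.size) < hazard
        state.symptomatic[idx[onset]] = True

    # isolation of symptomatic infected nodes (free or quarantined);
    # eps_I is a per-update-step detection probability
    newly_isolated = np.empty(0, dtype=np.int64)
    if params.eps_I > 0:
        elig = state.symptomatic & (status == INFECTED) & (conf != ISOLATED)
        if elig.any():
            idx = np.flatnonzero(elig)
            fire = rng.random(idx.size) < params.eps_I
            newly_isolated = idx[fire]
            conf[newly_isolated] = ISOLATED
            state.conf_end[newly_isolated] = (
                step_index + params.isolation_days * spd
            )
            state.ever_confined[newly_isolated] = True

    # natural recovery (free or quarantined; isolated recover on release)
    recov = (
        (status == INFECTED)
        & (conf != ISOLATED)
        & (state.tau >= params.infectious_period_days)
    )
    status[recov] = RECOVERED

    return newly_isolated


def trace_and_quarantine(
    state: EpiState,
    isolated_node: int,
    params: EpiParams,
    rng: np.random.Generator,
    step_index: int,
) -> np.ndarray:
    """Quarantine recent contacts of a newly isolated node.

    Every distinct partner appearing in the node's trailing 7-day contact
    log is quarantined independently with probability eps_T, unless already
    recovered, isolated, or currently quarantined.  Returns the quarantined
    node indices.
    """
    if params.eps_T <= 0 or not state.contact_log:
        return np.empty(0, dtype=np.int64)
    all_edges = np.concatenate(list(state.contact_log), axis=0)
    if all_edges.shape[0] == 0:
        return np.empty(0, dtype=np.int64)
    partners = np.concatenate(
        (
            all_edges[all_edges[:, 0] == isolated_node, 1],
            all_edges[all_edges[:, 1] == isolated_node, 0],
        )
    )
    partners = np.unique(partners)
    if partners.size == 0:
        return partners
    elig = (state.status[partners] != RECOVERED) & (state.conf[partners] == FREE)
    partners = partners[elig]
    fire = rng.random(partners.size) < params.eps_T
    quarantined = partners[fire]
    spd = state.contact_log.maxlen // (params.tracing_window_days or 1)
    state.conf[quarantined] = QUARANTINED
    state.conf_end[quarantined] = step_index + params.quarantine_days * spd
    state.ever_confined[quarantined] = True
    return quarantined


# ---------------------------------------------------------------------------
# Reproduction number
# ---------------------------------------------------------------------------

def estimate_R0(
    config: NetworkConfig,
    params: EpiParams,
    curve: InfectivityCurve,
    n_runs: int,
    rng: np.random.Generator,
) -> float:
    """Mean number of secondary infections caused directly by the index case.

    Each run seeds one infection on a fresh network realization and counts
    the infections attributed to the seed until the seed stops being an
    active spreader (recovery or confinement — confinement lasts at least
    as long as the seed's remaining infectious period, so no further
    offspring are possible after it).
    """
    spd = config.steps_per_day
    step_days = 1.0 / spd
    window_steps = params.tracing_window_days * spd
    max_steps = (params.infectious_period_days + params.isolation_days + 1) * spd
    schedule = None
    if config.pairing_period_d > 0:
        schedule = round_robin_schedule(config.N_c, config.pairing_period_d, spd)
    sampler = config.sampler()

    total_offspring = 0
    for _ in range(n_runs):
        state = EpiState.fresh(config.N, window_steps)
        seed = seed_infection(state, rng, params)
        for t in range(max_steps):
            if state.status[seed] != INFECTED or state.conf[seed] != FREE:
                break
            matching = schedule.matching_at_step(t) if schedule else None
            edges = sampler.sample_edges(rng, matching)
            free = state.free
            edges = edges[free[edges[:, 0]] & free[edges[:, 1]]]
            state.contact_log.append(edges)
            _, infectors = transmission_step(state, edges, params, curve, rng)
            total_offspring += int((infectors == seed).sum())
            newly_iso = progression_step(state, params, curve, step_days, t, rng)
            for node in newly_iso:
                trace_and_quarantine(state, int(node), params, rng, t)
    return total_offspring / n_runs


def calibrate_beta(
    config: NetworkConfig,
    params: EpiParams,
    curve: InfectivityCurve,
    target_r0: float = 1.64,
    n_runs: int = 2000,
    n_iter: int = 12,
    beta_lo: float = 0.0,
    beta_hi: float = 0.3,
    seed: int = 0,
) -> float:
    """Bisection on ``estimate_R0`` for the transmission scale beta.

    Common random numbers (the same seed per evaluation) keep the
    simulated R0 monotone in beta up to Monte-Carlo noise.
    """
    lo, hi = beta_lo, beta_hi
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        r0 = estimate_R0(
            config,
            replace(params, beta=mid),
            curve,
            n_runs,
            np.random.default_rng(seed),
        )
        if r0 < target_r0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
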