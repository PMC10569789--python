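"""Markov model of the CFTR gating cycle.

Phosphorylated CFTR gates by a unidirectional conformational cycle: a long
interburst closed state (IB, inward-facing, ~1 s) opens into a prehydrolytic
bursting state (B1, outward-facing, NBD-dimerized), which is terminated either
by ATP hydrolysis (rate ``k_1``, via the short-lived posthydrolytic state B2)
or by non-hydrolytic NBD-dimer dissociation (rate ``k_minus1``).  Within a
burst the pore flickers between an open (O) and a brief flickery-closed (C_f)
conformation without disrupting the NBD dimer.  Catalytic-site mutants with
``k_1 = 0`` gate at equilibrium between IB and B1 only.

The state space used throughout the package is::

    IB  <--k_minus1--  B1_O <-> B1_Cf   --k_1-->  B2_O <-> B2_Cf  --k_2--> IB
        --k_open-->    (flickers k_OC/k_CO)       (flickers k_OC/k_CO)

Burst-terminating rates fire identically from the O and C_f substates: the
flicker gate is a local pore motion independent of the NBD gate, which keeps
the aggregate burst lifetime exactly exponential with rate ``k_1 + k_minus1``
and makes the closed-form summary quantities below exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "STATES",
    "RateScheme",
    "GenotypePreset",
    "StateTrajectory",
    "CycleSummary",
    "mean_burst_duration",
    "coupling_ratio",
    "intraburst_equilibrium",
    "cycle_summary",
    "stationary_distribution",
    "simulate_trajectory",
    "simulate_with_atp_removal",
]

#: State labels; order fixes the integer codes used in trajectories.
STATES: tuple[str, ...] = ("IB", "B1_O", "B1_Cf", "B2_O", "B2_Cf")
IB, B1_O, B1_CF, B2_O, B2_CF = range(5)

#: States in which the pore conducts.
OPEN_STATES: frozenset[int] = frozenset({B1_O, B2_O})
#: States belonging to a burst (NBD dimer formed).
BURST_STATES: frozenset[int] = frozenset({B1_O, B1_CF, B2_O, B2_CF})


@dataclass(frozen=True)
class RateScheme:
    """Microscopic rate constants (1/s) of one genotype/condition.

    Parameters
    ----------
    k_open : IB -> B1 opening rate; ATP dependent, 0 after ATP removal.
    k_1 : B1 -> B2 hydrolysis rate; 0 in non-hydrolytic mutants.
    k_minus1 : B1 -> IB non-hydrolytic closing rate.
    k_2 : B2 -> IB post-hydrolytic closing rate.
    k_OC, k_CO : intraburst O -> C_f and C_f -> O flicker rates.
    temperature : absolute temperature in kelvin.
    """

    k_open: float
    k_1: float
    k_minus1: float
    k_2: float
    k_OC: float = 9.9
    k_CO: float = 100.0
    temperature: float = 298.15

    def __post_init__(self) -> None:
        for name in ("k_open", "k_1", "k_minus1", "k_2", "k_OC", "k_CO"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.k_OC > 0 and self.k_CO <= 0:
            raise ValueError("k_CO must be > 0 whenever k_OC > 0 "
                             "(flickery closures must be able to reopen)")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (kelvin)")

    def with_atp_removed(self) -> "RateScheme":
        """Scheme after ATP washout: opening is abolished, all else unchanged."""
        return replace(self, k_open=0.0)

    def transition_matrix(self) -> np.ndarray:
        """Generator entries as a dense (5, 5) rate matrix Q, rows = from-state."""
        q = np.zeros((5, 5))
        q[IB, B1_O] = self.k_open
        for o, c in ((B1_O, B1_CF), (B2_O, B2_CF)):
            q[o, c] = self.k_OC
            q[c, o] = self.k_CO
        for s in (B1_O, B1_CF):
            q[s, IB] = self.k_minus1
            q[s, s + 2] = self.k_1  # B1_x -> B2_x preserves the flicker substate
        for s in (B2_O, B2_CF):
            q[s, IB] = self.k_2
        np.fill_diagonal(q, -q.sum(axis=1))
        return q


@dataclass(frozen=True)
class GenotypePreset:
    """A named rate scheme plus the provenance of each rate.

    ``provenance`` maps rate name -> a short string tagged ``measured``
    (printed experimental value), ``derived`` (computed from printed
    relations, e.g. fold-changes), or ``assumed`` (package design choice).
    """

    name: str
    scheme: RateScheme
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [k for k in ("k_open", "k_1", "k_minus1", "k_2", "k_OC", "k_CO")
                   if k not in self.provenance]
        if missing:
            raise ValueError(f"preset {self.name!r} lacks provenance for {missing}")


@dataclass
class StateTrajectory:
    """Piecewise-constant path through the gating scheme.

    Dwells are contiguous and non-overlapping; ``states`` holds integer codes
    into :data:`STATES`.
    """

    states: np.ndarray
    entry_times: np.ndarray
    durations: np.ndarray
    scheme: RateScheme
    seed: int | None = None
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int64)
        self.entry_times = np.asarray(self.entry_times, dtype=float)
        self.durations = np.asarray(self.durations, dtype=float)
        if not (len(self.states) == len(self.entry_times) == len(self.durations)):
            raise ValueError("states, entry_times and durations must align")
        if np.any(self.durations <= 0):
            raise ValueError("dwell durations must be positive")

    @property
    def duration(self) -> float:
        """Total simulated time (s)."""
        if len(self.durations) == 0:
            return 0.0
        return float(self.entry_times[-1] + self.durations[-1] - self.t0)

    @property
    def end_time(self) -> float:
        return self.t0 + self.duration

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "state": [STATES[s] for s in self.states],
            "entry_time_s": self.entry_times,
            "duration_s": self.durations,
        })

    def state_at(self, times: np.ndarray) -> np.ndarray:
        """State codes at arbitrary times (clamped to the trajectory span)."""
        idx = np.searchsorted(self.entry_times, times, side="right") - 1
        return self.states[np.clip(idx, 0, len(self.states) - 1)]

    def open_fraction(self) -> float:
        """Time-weighted fraction spent in conducting states."""
        mask = np.isin(self.states, list(OPEN_STATES))
        return float(self.durations[mask].sum() / self.durations.sum())

    def bursts(self) -> pd.DataFrame:
        """Aggregate contiguous non-IB dwells into bursts.

        Returns a frame with burst start, duration, and the terminating path
        (``hydrolytic`` if the burst left via B2, ``nonhydrolytic`` via B1,
        ``censored`` if the trajectory ends mid-burst).
        """
        in_burst = np.isin(self.states, list(BURST_STATES))
        starts, durs, terms = [], [], []
        i = 0
        n = len(self.states)
        while i < n:
            if not in_burst[i]:
                i += 1
                continue
            j = i
            while j < n and in_burst[j]:
                j += 1
            starts.append(self.entry_times[i])
            durs.append(self.entry_times[j - 1] + self.durations[j - 1]
                        - self.entry_times[i])
            if j == n:
                terms.append("censored")
            elif self.states[j - 1] in (B2_O, B2_CF):
                terms.append("hydrolytic")
            else:
                terms.append("nonhydrolytic")
            i = j
        return pd.DataFrame({"start_s": starts, "duration_s": durs,
                             "terminated": terms})


@dataclass(frozen=True)
class CycleSummary:
    """Closed-form summary quantities of a scheme."""

    tau_b: float          # mean burst duration (s)
    CR: float             # coupling ratio, fraction of bursts ending via hydrolysis
    P_oB: float           # intraburst open probability
    K_eqB: float          # intraburst equilibrium constant (inf if no flickers)
    tau_ib: float         # mean interburst duration (s); inf if k_open == 0


def mean_burst_duration(scheme: RateScheme) -> float:
    """Mean burst duration tau_b (s).

    The burst lifetime is the B1 lifetime ``1/(k_1 + k_minus1)`` plus, for the
    fraction of bursts that proceed through hydrolysis, the B2 lifetime
    ``1/k_2``.  With ``k_1 = 0`` this reduces exactly to ``1/k_minus1``.
    """
    ktot = scheme.k_1 + scheme.k_minus1
    if ktot == 0:
        raise ValueError("k_1 + k_minus1 = 0: burst never terminates")
    if scheme.k_1 == 0:
        return 1.0 / scheme.k_minus1
    if scheme.k_2 == 0:
        raise ValueError("k_1 > 0 requires k_2 > 0 (B2 must be able to close)")
    return 1.0 / ktot + (scheme.k_1 / ktot) / scheme.k_2


def coupling_ratio(scheme: RateScheme) -> float:
    """Fraction of initiated bursts terminated by ATP hydrolysis,
    ``CR = k_1 / (k_1 + k_minus1)``."""
    ktot = scheme.k_1 + scheme.k_minus1
    if ktot == 0:
        raise ValueError("k_1 + k_minus1 = 0: coupling ratio undefined")
    return scheme.k_1 / ktot


def intraburst_equilibrium(scheme: RateScheme) -> tuple[float, float]:
    """Intraburst open probability and equilibrium constant ``(P_oB, K_eqB)``.

    ``P_oB = k_CO / (k_CO + k_OC)`` and ``K_eqB = k_CO / k_OC``; the identity
    ``K_eqB = P_oB / (1 - P_oB)`` holds.  With ``k_OC = 0`` the pore never
    flickers: returns ``(1.0, inf)``.
    """
    if scheme.k_OC == 0:
        return 1.0, math.inf
    if scheme.k_CO <= 0:
        raise ValueError("k_CO must be > 0 when k_OC > 0")
    p = scheme.k_CO / (scheme.k_CO + scheme.k_OC)
    return p, scheme.k_CO / scheme.k_OC


def cycle_summary(scheme: RateScheme) -> CycleSummary:
    p, k = intraburst_equilibrium(scheme)
    return CycleSummary(
        tau_b=mean_burst_duration(scheme),
        CR=coupling_ratio(scheme),
        P_oB=p,
        K_eqB=k,
        tau_ib=(1.0 / scheme.k_open) if scheme.k_open > 0 else math.inf,
    )


def stationary_distribution(scheme: RateScheme) -> np.ndarray:
    """Stationary occupancy over :data:`STATES` with ATP present.

    Derived from mean cycle times: one full cycle spends ``1/k_open`` in IB,
    ``1/(k_1+k_minus1)`` in B1 and ``CR/k_2`` in B2; occupancy within B1/B2 is
    split by the flicker equilibrium.  With ``k_open = 0`` all mass is in IB.
    """
    if scheme.k_open == 0:
        return np.array([1.0, 0, 0, 0, 0])
    t_ib = 1.0 / scheme.k_open
    ktot = scheme.k_1 + scheme.k_minus1
    if ktot == 0:
        raise ValueError("k_1 + k_minus1 = 0: no stationary cycle")
    t_b1 = 1.0 / ktot
    cr = scheme.k_1 / ktot
    t_b2 = cr / scheme.k_2 if scheme.k_1 > 0 else 0.0
    p_o, _ = intraburst_equilibrium(scheme)
    pi = np.array([t_ib,
                   t_b1 * p_o, t_b1 * (1 - p_o),
                   t_b2 * p_o, t_b2 * (1 - p_o)])
    return pi / pi.sum()


def bursting_fraction(scheme: RateScheme) -> float:
    """Stationary probability that a channel is in a burst (ATP present)."""
    return float(stationary_distribution(scheme)[1:].sum())


# ---------------------------------------------------------------------------
# Stochastic simulation (Gillespie direct method)
# ---------------------------------------------------------------------------

def _exit_tables(scheme: RateScheme):
    """Per-state (targets, cumulative probabilities, total exit rate)."""
    q = scheme.transition_matrix()
    tables = []
    for s in range(5):
        rates = q[s].copy()
        rates[s] = 0.0
        total = rates.sum()
        targets = np.nonzero(rates)[0]
        if total > 0:
            cum = np.cumsum(rates[targets]) / total
        else:
            cum = np.array([])
        tables.append((targets, cum, total))
    return tables


def simulate_trajectory(
    scheme: RateScheme,
    *,
    duration: float | None = None,
    n_bursts: int | None = None,
    absorb: bool = False,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    start: int | str = "stationary",
    t0: float = 0.0,
) -> StateTrajectory:
    """Exact stochastic realization of the gating scheme.

    Exactly one of the stopping rules applies: a fixed ``duration`` (the final
    dwell is truncated), a number of completed ``n_bursts``, or ``absorb``
    (stop at the first entry into IB — the natural rule after ATP removal).
    Identical seeds give identical trajectories.

    ``start`` is a state code, a state name, or ``"stationary"`` to draw the
    initial state from the stationary distribution with ATP present.
    """
    if sum(x is not None for x in (duration, n_bursts)) + int(absorb) != 1:
        raise ValueError("specify exactly one of duration, n_bursts, absorb")
    if rng is None:
        rng = np.random.default_rng(seed)

    if isinstance(start, str):
        if start == "stationary":
            state = int(rng.choice(5, p=stationary_distribution(scheme)))
        else:
            state = STATES.index(start)
    else:
        state = int(start)

    tables = _exit_tables(scheme)
    states: list[int] = []
    entries: list[float] = []
    durs: list[float] = []
    t = t0
    completed = 0
    t_end = (t0 + duration) if duration is not None else math.inf

    while True:
        targets, cum, total = tables[state]
        if total == 0.0:
            if duration is not None:
                if t_end > t:
                    states.append(state)
                    entries.append(t)
                    durs.append(t_end - t)
                break
            raise ValueError(
                f"state {STATES[state]} has no exits; trajectory cannot "
                "satisfy the requested stopping rule")
        dt = rng.exponential(1.0 / total)
        nxt = int(targets[np.searchsorted(cum, rng.random(), side="right")])
        if t + dt >= t_end:
            states.append(state)
            entries.append(t)
            durs.append(t_end - t)
            break
        states.append(state)
        entries.append(t)
        durs.append(dt)
        t += dt
        if nxt == IB and state != IB:
            completed += 1
            if absorb:
                break
            if n_bursts is not None and completed >= n_bursts:
                break
        state = nxt

    return StateTrajectory(np.array(states), np.array(entries), np.array(durs),
                           scheme=scheme, seed=seed, t0=t0)


def simulate_with_atp_removal(
    scheme: RateScheme,
    t_atp_off: float,
    t_end: float,
    *,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    start: int | str = "stationary",
) -> StateTrajectory:
    """One channel through the ATP-removal protocol.

    Gates with ATP (full scheme) on ``[0, t_atp_off)``, then with
    ``k_open = 0`` until ``t_end``; after the terminal entry into IB the
    channel stays closed for the remainder of the record.
    """
    if not 0 <= t_atp_off < t_end:
        raise ValueError("need 0 <= t_atp_off < t_end")
    if rng is None:
        rng = np.random.default_rng(seed)
    if t_atp_off > 0:
        pre = simulate_trajectory(scheme, duration=t_atp_off, rng=rng,
                                  start=start, t0=0.0)
        last_state = int(pre.states[-1])
        states = list(pre.states)
        entries = list(pre.entry_times)
        durs = list(pre.durations)
    else:
        if start == "stationary":
            last_state = int(rng.choice(5, p=stationary_distribution(scheme)))
        elif isinstance(start, str):
            last_state = STATES.index(start)
        else:
            last_state = int(start)
        states, entries, durs = [], [], []
    post = simulate_trajectory(scheme.with_atp_removed(),
                               duration=t_end - t_atp_off, rng=rng,
                               start=last_state, t0=t_atp_off)
    # fuse the dwell straddling the removal time if the state is unchanged
    if states and len(post.states) and post.states[0] == states[-1]:
        durs[-1] += post.durations[0]
        states += list(post.states[1:])
        entries += list(post.entry_times[1:])
        durs += list(post.durations[1:])
    else:
        states += list(post.states)
        entries += list(post.entry_times)
        durs += list(post.durations)
    return StateTrajectory(np.array(states), np.array(entries), np.array(durs),
                           scheme=scheme, seed=seed, t0=0.0)
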