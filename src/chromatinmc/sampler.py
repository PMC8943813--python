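"""Metropolis Monte Carlo with replica exchange, annealing and diagnostics.

Move set: single-segment twist about the local u axis, crankshaft
rotations of short interior sub-chains about the chord between two
joints, and pivot rotations of a random head or tail about a random
axis.  All moves are rigid rotations (segment lengths are conserved) with
symmetric proposals, so Metropolis acceptance min(1, exp(-dE/T))
satisfies detailed balance.  One "MC step" is one attempted elementary
move; a sweep is one attempted move per segment on average.

Replica exchange follows the standard scheme: M replicas at a ladder of
dimensionless temperatures, with adjacent-pair temperature swaps
attempted every ``swap_interval`` steps at probability
min[1, exp(-(beta_i - beta_i+1)(E_i+1 - E_i))].  The ladder can be
feedback-optimized from measured replica flow.  Equilibration detection,
integrated autocorrelation times and thinning turn raw runs into
uncorrelated samples.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from .chain import ChainTopology, Configuration
from .forcefield import EnergyBreakdown, EnergyModel, ForceField

__all__ = [
    "TemperatureLadder",
    "RunControl",
    "Trajectory",
    "MCState",
    "metropolis_sweep",
    "swap_probability",
    "replica_exchange_run",
    "metropolis_run",
    "optimize_ladder",
    "simulated_annealing",
    "autocorrelation_time",
    "equilibration_cut",
    "thin",
]


@dataclass
class TemperatureLadder:
    """Strictly increasing dimensionless temperature multipliers."""

    temperatures: np.ndarray

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, float)
        if self.temperatures.size < 1:
            raise ValueError("ladder needs at least one temperature")
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("temperatures must be strictly increasing")

    def __len__(self) -> int:
        return int(self.temperatures.size)

    @property
    def betas(self) -> np.ndarray:
        return 1.0 / self.temperatures

    @classmethod
    def geometric(cls, t_min: float = 1.0, t_max: float = 2.5, n: int = 16):
        if n == 1:
            return cls(np.array([t_min]))
        return cls(np.geomspace(t_min, t_max, n))


@dataclass
class RunControl:
    """Run lengths and bookkeeping for a (replica-exchange) MC run."""

    n_steps: int = 200_000          # attempted moves per replica
    swap_interval: int = 5_000      # steps between swap attempts
    record_interval: int = 500      # steps between recorded samples
    seed: int = 0
    annealing_from: float = 3.0     # start temperature of the pre-relaxation
    annealing_stages: int = 8
    annealing_moves_per_stage: int | None = None
    thin_tau: float | None = None   # fixed thinning; None = estimate
    equilibration_cut: int | None = None  # manual override of the auto cut

    def __post_init__(self) -> None:
        for name in ("n_steps", "swap_interval", "record_interval"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive integer")


@dataclass
class Trajectory:
    """Recorded samples of one temperature's chain during a run."""

    temperature: float
    steps: np.ndarray
    positions: list                    # list of (n+1, 3) arrays
    energies: np.ndarray               # (n_samples, 6) per-term kT
    end_to_end: np.ndarray
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return int(self.steps.size)

    @property
    def energy_total(self) -> np.ndarray:
        return self.energies.sum(axis=1)

    def breakdown(self, i: int) -> EnergyBreakdown:
        return EnergyBreakdown.from_array(self.energies[i])

    def select(self, idx) -> "Trajectory":
        idx = np.asarray(idx)
        return Trajectory(
            self.temperature,
            self.steps[idx],
            [self.positions[int(i)] for i in idx],
            self.energies[idx],
            self.end_to_end[idx],
            dict(self.meta),
        )

    def save(self, path) -> None:
        np.savez(
            path,
            steps=self.steps,
            positions=np.array(self.positions),
            energies=self.energies,
            end_to_end=self.end_to_end,
            temperature=self.temperature,
            meta=json.dumps(self.meta),
        )

    @classmethod
    def load(cls, path) -> "Trajectory":
        z = np.load(path, allow_pickle=False)
        return cls(
            float(z["temperature"]),
            z["steps"],
            list(z["positions"]),
            z["energies"],
            z["end_to_end"],
            json.loads(str(z["meta"])),
        )


# ---------------------------------------------------------------------------
# Elementary sampling
# ---------------------------------------------------------------------------

@dataclass
class MoveSet:
    """Move amplitudes (radians) and mixture; frozen during production."""

    amp_twist: float = 1.0
    amp_crank: float = 0.8
    amp_pivot: float = 0.5
    p_twist: float = 0.2
    p_crank: float = 0.5
    crank_max: int = 12

    def scaled(self, factor: float) -> None:
        cap = math.pi
        self.amp_twist = min(max(self.amp_twist * factor, 1e-3), cap)
        self.amp_crank = min(max(self.amp_crank * factor, 1e-3), cap)
        self.amp_pivot = min(max(self.amp_pivot * factor, 1e-3), cap)


class MCState:
    """A chain configuration plus its running energy, ready for MC kernels."""

    def __init__(
        self,
        topology: ChainTopology,
        ff: ForceField,
        config: Configuration,
        seed=0,
        moveset: MoveSet | None = None,
        model: EnergyModel | None = None,
    ):
        self.topology = topology
        self.model = model if model is not None else EnergyModel(topology, ff)
        self.config = config
        self.rng = np.random.default_rng(seed)
        self.moveset = moveset if moveset is not None else MoveSet()
        self.eterms = self.model.energy_array(config)
        self.moves = 0
        self.accepted = 0
        self.last_drift = 0.0

    @property
    def energy(self) -> EnergyBreakdown:
        return EnergyBreakdown.from_array(self.eterms)

    def run(self, n_moves: int, T: float = 1.0, refresh: bool = True) -> int:
        """Attempt *n_moves* Metropolis moves at temperature T.

        With ``refresh`` the frames are re-orthonormalized afterwards and
        the running energy is replaced by a full recomputation; the
        incremental-vs-full discrepancy is kept in :attr:`last_drift`.
        """
        m = self.model
        ms = self.moveset
        seed = int(self.rng.integers(2**31))
        acc = K.run_mc(
            self.config.pos, self.config.frames, m.l0, m.kstretch, m.is_stem,
            m.seg_nuc, m.q, m.kbend, m.theta0, m.ktwist, m.stem_seg,
            m.nuc_off, m.nuc_axis, m.params, float(T), int(n_moves), seed,
            ms.amp_twist, ms.amp_crank, ms.amp_pivot, ms.p_twist, ms.p_crank,
            int(ms.crank_max), self.eterms,
        )
        self.moves += n_moves
        self.accepted += acc
        if refresh:
            self.config.orthonormalize()
            full = m.energy_array(self.config)
            self.last_drift = float(np.max(np.abs(full - self.eterms)))
            self.eterms = full
        return int(acc)

    @property
    def acceptance(self) -> float:
        return self.accepted / self.moves if self.moves else 0.0


def metropolis_sweep(
    config: Configuration,
    topology: ChainTopology,
    ff: ForceField,
    T: float = 1.0,
    moveset: MoveSet | None = None,
    seed=0,
    state: MCState | None = None,
) -> dict:
    """One sweep (one attempted move per segment on average) at temperature T.

    Mutates *config* in place and returns acceptance statistics.  For
    repeated sweeps build an :class:`MCState` once and call ``run``.
    """
    if state is None:
        state = MCState(topology, ff, config, seed=seed, moveset=moveset)
    acc = state.run(topology.n_segments, T)
    return {
        "attempted": topology.n_segments,
        "accepted": acc,
        "acceptance": acc / topology.n_segments,
        "energy": state.energy,
    }


def swap_probability(e_i: float, e_i1: float, beta_i: float, beta_i1: float) -> float:
    """Replica-exchange acceptance min[1, exp(-(b_i - b_i+1)(E_i+1 - E_i))]."""
    if beta_i <= 0 or beta_i1 <= 0:
        raise ValueError("betas must be > 0")
    arg = -(beta_i - beta_i1) * (e_i1 - e_i)
    if arg >= 0:
        return 1.0
    return math.exp(arg)


# ---------------------------------------------------------------------------
# Annealing and production runs
# ---------------------------------------------------------------------------

def simulated_annealing(
    config: Configuration,
    topology: ChainTopology,
    ff: ForceField,
    schedule: np.ndarray | None = None,
    moves_per_stage: int | None = None,
    seed=0,
    tune_amplitudes: bool = True,
    target_acceptance: float = 0.4,
    model: EnergyModel | None = None,
) -> tuple[Configuration, MoveSet]:
    """Pre-relax a configuration by cooling through a temperature schedule.

    Move amplitudes are auto-tuned toward *target_acceptance* during the
    schedule and returned frozen for production (fixed amplitudes keep
    detailed balance during production sampling).
    """
    if schedule is None:
        schedule = np.geomspace(3.0, 1.0, 8)
    schedule = np.asarray(schedule, float)
    if schedule.size > 1 and np.any(np.diff(schedule) > 0):
        raise ValueError("annealing schedule must be non-increasing")
    if moves_per_stage is None:
        moves_per_stage = 20 * topology.n_segments
    state = MCState(topology, ff, config, seed=seed, model=model)
    for T in schedule:
        before = state.accepted
        state.run(moves_per_stage, float(T))
        if tune_amplitudes:
            rate = (state.accepted - before) / moves_per_stage
            factor = min(max((rate + 0.02) / target_acceptance, 0.5), 2.0)
            state.moveset.scaled(factor)
    return state.config, state.moveset


def metropolis_run(
    topology: ChainTopology,
    ff: ForceField,
    control: RunControl,
    T: float = 1.0,
    initial: Configuration | None = None,
    moveset: MoveSet | None = None,
) -> Trajectory:
    """Plain single-temperature Metropolis production run."""
    ladder = TemperatureLadder(np.array([T]))
    return replica_exchange_run(topology, ff, ladder, control, initial, moveset)[0]


def replica_exchange_run(
    topology: ChainTopology,
    ff: ForceField,
    ladder: TemperatureLadder,
    control: RunControl,
    initial: Configuration | None = None,
    moveset: MoveSet | None = None,
    _flow: dict | None = None,
) -> list[Trajectory]:
    """Replica-exchange production run; one Trajectory per ladder temperature.

    Every replica evolves under its own RNG substream (spawned from the
    control seed, so results are reproducible and independent of replica
    count bookkeeping); adjacent temperatures attempt swaps every
    ``swap_interval`` steps with Eq.-style probability.  A single-entry
    ladder degenerates to a plain Metropolis run.
    """
    from .chain import initial_configuration

    n_rep = len(ladder)
    temps = ladder.temperatures
    model = EnergyModel(topology, ff)
    seeds = np.random.SeedSequence(control.seed).spawn(n_rep + 1)
    swap_rng = np.random.default_rng(seeds[-1])

    if initial is None:
        initial = initial_configuration(topology, "straight")
    states = []
    for r in range(n_rep):
        ms = MoveSet(**vars(moveset)) if moveset is not None else MoveSet()
        states.append(
            MCState(topology, ff, initial.copy(), seed=seeds[r], moveset=ms, model=model)
        )

    replica_at_temp = list(range(n_rep))   # temperature index -> replica
    temp_of_replica = list(range(n_rep))
    labels = [None] * n_rep                # "up" (seen bottom) / "down" (seen top)
    flow_up = np.zeros(n_rep)
    flow_dn = np.zeros(n_rep)
    round_trips = 0

    samples: list[list] = [[] for _ in range(n_rep)]
    chunk = min(control.record_interval, control.swap_interval)
    n_rounds = max(control.n_steps // control.swap_interval, 1)
    step = 0
    parity = 0
    for rnd in range(n_rounds):
        done = 0
        while done < control.swap_interval:
            todo = min(chunk, control.swap_interval - done)
            for r in range(n_rep):
                states[r].run(todo, float(temps[temp_of_replica[r]]))
            done += todo
            step += todo
            if step % control.record_interval == 0:
                for t in range(n_rep):
                    st = states[replica_at_temp[t]]
                    samples[t].append(
                        (step, st.config.pos.copy(), st.eterms.copy(),
                         st.config.end_to_end)
                    )
        # flow labels for ladder feedback
        labels[replica_at_temp[0]] = "up"
        if n_rep > 1:
            top = replica_at_temp[-1]
            if labels[top] == "up":
                round_trips += 1
            labels[top] = "down"
        for t in range(n_rep):
            lab = labels[replica_at_temp[t]]
            if lab == "up":
                flow_up[t] += 1
            elif lab == "down":
                flow_dn[t] += 1
        # adjacent swaps, alternating parity
        for t in range(parity, n_rep - 1, 2):
            ri, rj = replica_at_temp[t], replica_at_temp[t + 1]
            p = swap_probability(
                float(states[ri].eterms.sum()), float(states[rj].eterms.sum()),
                1.0 / temps[t], 1.0 / temps[t + 1],
            )
            if swap_rng.random() < p:
                replica_at_temp[t], replica_at_temp[t + 1] = rj, ri
                temp_of_replica[ri], temp_of_replica[rj] = t + 1, t
        parity ^= 1

    if _flow is not None:
        _flow["up"] = flow_up
        _flow["down"] = flow_dn
        _flow["round_trips"] = round_trips

    out = []
    for t in range(n_rep):
        if samples[t]:
            steps_arr = np.array([s[0] for s in samples[t]])
            pos_list = [s[1] for s in samples[t]]
            e_arr = np.stack([s[2] for s in samples[t]])
            ee = np.array([s[3] for s in samples[t]])
        else:
            steps_arr = np.zeros(0, int)
            pos_list = []
            e_arr = np.zeros((0, 6))
            ee = np.zeros(0)
        out.append(
            Trajectory(
                float(temps[t]), steps_arr, pos_list, e_arr, ee,
                meta={
                    "ladder": temps.tolist(),
                    "n_steps": control.n_steps,
                    "swap_interval": control.swap_interval,
                    "seed": int(control.seed),
                },
            )
        )
    return out


def optimize_ladder(
    topology: ChainTopology,
    ff: ForceField,
    ladder: TemperatureLadder,
    pilot: RunControl,
    max_iters: int = 3,
    initial: Configuration | None = None,
) -> TemperatureLadder:
    """Feedback-optimized temperature ladder.

    Pilot runs measure the fraction of "down-moving" replicas at each
    temperature (replicas labeled by the last ladder endpoint they
    visited); temperatures are re-placed so that this flow fraction
    becomes linear in the ladder index, which maximizes the round-trip
    diffusion of replicas.  Endpoints stay fixed and monotonicity is
    preserved; iteration stops when the measured round-trip rate stops
    improving.  With no measurable flow a geometric ladder is returned
    with a warning.
    """
    n = len(ladder)
    if n < 3:
        return ladder
    best = ladder
    best_rate = -1.0
    current = ladder
    for it in range(max_iters):
        flow: dict = {}
        replica_exchange_run(
            topology, ff, current, pilot, initial=initial, _flow=flow
        )
        tot = flow["up"] + flow["down"]
        if np.all(tot[1:-1] == 0):
            warnings.warn(
                "no replica flow measured; falling back to geometric spacing"
            )
            return TemperatureLadder.geometric(
                float(current.temperatures[0]), float(current.temperatures[-1]), n
            )
        rate = flow["round_trips"] / max(pilot.n_steps // pilot.swap_interval, 1)
        if rate > best_rate:
            best, best_rate = current, rate
        elif it > 0:
            break
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(tot > 0, flow["down"] / np.maximum(tot, 1), np.nan)
        f[0], f[-1] = 0.0, 1.0
        idx = ~np.isnan(f)
        f = np.interp(np.arange(n), np.nonzero(idx)[0], f[idx])
        f = np.maximum.accumulate(f)
        f[-1] = 1.0
        # strictly increasing support for inversion
        eps = 1e-6
        for i in range(1, n):
            if f[i] <= f[i - 1]:
                f[i] = f[i - 1] + eps
        targets = np.linspace(f[0], f[-1], n)
        new_t = np.interp(targets, f, current.temperatures)
        new_t[0] = current.temperatures[0]
        new_t[-1] = current.temperatures[-1]
        for i in range(1, n):   # enforce strict monotonicity
            if new_t[i] <= new_t[i - 1]:
                new_t[i] = new_t[i - 1] * (1 + 1e-9)
        current = TemperatureLadder(new_t)
    return best


# ---------------------------------------------------------------------------
# Convergence diagnostics
# ---------------------------------------------------------------------------

def autocorrelation_time(series, c: float = 5.0) -> float:
    """Integrated autocorrelation time with Sokal's adaptive window.

    tau = 1 + 2 sum rho(k), truncated at the smallest window M with
    M >= c*tau(M).  Raises if the series is constant or too short for a
    reliable estimate (fewer than ~50 tau samples).
    """
    x = np.asarray(series, float)
    n = x.size
    if n < 16:
        raise ValueError("series too short for autocorrelation analysis")
    x = x - x.mean()
    var = float(np.mean(x * x))
    if var == 0:
        raise ValueError("constant series: autocorrelation time undefined")
    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, nfft)
    acf = np.fft.irfft(f * np.conjugate(f))[:n].real
    acf /= acf[0]
    taus = 2.0 * np.cumsum(acf) - 1.0
    window = np.arange(n)
    ok = window >= c * taus
    ok[0] = False
    if not np.any(ok):
        raise ValueError("no autocorrelation window found; series too short")
    m = int(np.argmax(ok))
    tau = max(float(taus[m]), 1.0)
    if n < 50 * tau:
        raise ValueError(
            f"series of length {n} shorter than 50*tau = {50 * tau:.0f}; run longer"
        )
    return tau


def equilibration_cut(
    energy_series,
    end_to_end_series,
    tol: float = 0.8,
    override: int | None = None,
) -> int:
    """First index after which both series look stationary.

    Candidate cut points are log-spaced; a cut is accepted when, for both
    series, the means of the two halves of the remaining samples agree
    within *tol* standard deviations of the remaining samples.  An
    explicit *override* is returned verbatim.
    """
    if override is not None:
        return int(override)
    e = np.asarray(energy_series, float)
    r = np.asarray(end_to_end_series, float)
    if e.size != r.size or e.size < 4:
        raise ValueError("need two aligned series with >= 4 samples")
    n = e.size
    cuts = sorted({0} | {n // d for d in (64, 32, 16, 8, 4, 3, 2)})
    for k in cuts:
        if n - k < 4:
            continue
        good = True
        for s in (e, r):
            rest = s[k:]
            half = rest.size // 2
            a, b = rest[:half], rest[half:]
            # scale by the late-half spread so a decaying transient in the
            # first half cannot inflate its own acceptance threshold
            sd = b.std()
            if abs(a.mean() - b.mean()) > tol * sd:
                good = False
                break
        if good:
            return k
    raise ValueError("no stationary window found; run longer or set an override")


def thin(trajectory: Trajectory, tau: float) -> Trajectory:
    """Keep every ceil(tau)-th sample (post-equilibration thinning)."""
    if tau < 1:
        raise ValueError("tau must be >= 1")
    stride = int(math.ceil(tau))
    return trajectory.select(np.arange(0, len(trajectory), stride))
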