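"""Energy minimization and (NM)MD time integration.

Unit system: length in Å, energy in ε (mapped to kcal/mol only for the
temperature conversion, k_B = 0.0019872041 ε/K), bead mass 1 reduced
mass unit.  The nominal time unit is labelled ps to match common MD
practice; with unit bead masses the absolute time scale is conventional
and only relative durations matter.

Normal-mode MD (NMMD) augments Cartesian molecular dynamics with the
amplitudes of a set of (non-rigid-body) normal modes as extra dynamical
variables.  Each amplitude q_m carries its own inertia (``nm_mass``)
and time step (``nm_dt``) and feels the generalized force
f_m = u_mᵀ F, the projection of the Cartesian forces onto mode m.  The
mode displacement increment Σ_m Δq_m u_m is added to the coordinates
every step, which boosts motion along the most collective directions.
Both parts are integrated with Velocity Verlet; with a positive target
temperature a Langevin thermostat (BAOAB splitting) acts on the
Cartesian and mode velocities.

An empty mode list reduces NMMD to plain MD exactly (bit-for-bit at a
fixed seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .go_model import GoTopology, go_energy_forces
from .structure_io import AtomicModel, rmsd

__all__ = [
    "KB", "SimulationParams", "SimulationState", "TrajectoryRecord",
    "mdspace_preset", "mdtomo_preset", "minimize", "md_step", "nmmd_step",
    "run_simulation", "simulated_duration", "initial_state",
]

#: Boltzmann constant in reduced energy units (ε ≡ 1 kcal/mol) per kelvin
KB = 0.0019872041


@dataclass
class SimulationParams:
    """Parameters of a minimization / MD / NMMD run."""

    sim_type: str = "nmmd"            # minimization | md | nmmd
    dt: float = 0.002                 # ps
    n_steps: int = 20_000
    temperature: float = 300.0        # K; 0 disables the thermostat
    friction: float = 1.0             # ps⁻¹
    nm_dt: float | None = None        # defaults to dt
    nm_mass: float = 5.0              # mode inertia, dimensionless
    mode_indices: tuple[int, ...] = tuple(range(7, 17))
    seed: int = 0
    k_bias: float = 3000.0            # weight of the −k·CC biasing potential
    sigma_gauss: float = 2.0          # Å, Gaussian width of simulated density
    report_interval: int = 100

    def __post_init__(self) -> None:
        if self.sim_type not in ("minimization", "md", "nmmd"):
            raise ValueError(f"unknown sim_type {self.sim_type!r}")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_steps < 0:
            raise ValueError("n_steps must be ≥ 0")
        if self.nm_mass <= 0:
            raise ValueError("nm_mass must be positive")
        if any(m <= 6 for m in self.mode_indices):
            raise ValueError("mode_indices must exclude rigid-body modes 1–6")
        if self.nm_dt is None:
            self.nm_dt = self.dt
        ratio = self.nm_dt / self.dt
        if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
            raise ValueError(
                "nm_dt must equal dt or be an integer multiple of dt "
                f"(got nm_dt={self.nm_dt}, dt={self.dt})")

    @property
    def nm_subcycle(self) -> int:
        """Number of MD steps between normal-mode updates."""
        return int(round(self.nm_dt / self.dt))


def mdspace_preset(**overrides) -> SimulationParams:
    """Workflow preset for single-particle image fitting."""
    base = dict(sim_type="nmmd", n_steps=20_000, dt=0.002, nm_mass=5.0,
                k_bias=3000.0, temperature=300.0)
    base.update(overrides)
    return SimulationParams(**base)


def mdtomo_preset(**overrides) -> SimulationParams:
    """Workflow preset for subtomogram fitting (slower, gentler bias)."""
    base = dict(sim_type="nmmd", n_steps=50_000, dt=0.002, nm_mass=10.0,
                k_bias=1000.0, temperature=300.0)
    base.update(overrides)
    return SimulationParams(**base)


@dataclass
class SimulationState:
    """Instantaneous dynamical state of a simulation."""

    coords: np.ndarray                   # (N, 3) Å
    velocities: np.ndarray               # (N, 3) Å/ps
    q: np.ndarray                        # mode amplitudes
    q_dot: np.ndarray                    # mode amplitude velocities
    time: float = 0.0
    step: int = 0
    forces: np.ndarray | None = None     # cached forces at `coords`

    def copy(self) -> "SimulationState":
        return SimulationState(
            self.coords.copy(), self.velocities.copy(), self.q.copy(),
            self.q_dot.copy(), self.time, self.step,
            None if self.forces is None else self.forces.copy())


def initial_state(model: AtomicModel, n_modes: int = 0) -> SimulationState:
    """State at rest at the model's coordinates."""
    return SimulationState(
        coords=model.coords.copy(),
        velocities=np.zeros_like(model.coords),
        q=np.zeros(n_modes),
        q_dot=np.zeros(n_modes),
    )


class TrajectoryRecord:
    """Per-reporting-interval diagnostics of a run."""

    def __init__(self) -> None:
        self.time: list[float] = []
        self.potential: list[float] = []
        self.kinetic: list[float] = []
        self.cc: list[float] = []
        self.rmsd: list[float] = []
        self.q: list[np.ndarray] = []

    def append(self, time, potential, kinetic, cc, rmsd_val, q) -> None:
        self.time.append(float(time))
        self.potential.append(float(potential))
        self.kinetic.append(float(kinetic))
        self.cc.append(float(cc) if cc is not None else math.nan)
        self.rmsd.append(float(rmsd_val))
        self.q.append(np.array(q, dtype=float))

    def __len__(self) -> int:
        return len(self.time)

    def as_dataframe(self):
        import pandas as pd

        df = pd.DataFrame({
            "time": self.time, "potential": self.potential,
            "kinetic": self.kinetic, "cc": self.cc, "rmsd": self.rmsd,
        })
        if self.q and len(self.q[0]):
            qarr = np.vstack(self.q)
            for k in range(qarr.shape[1]):
                df[f"q{k + 1}"] = qarr[:, k]
        return df


def simulated_duration(params: SimulationParams) -> float:
    """Physical length of the simulation, ps (n_steps × dt)."""
    return params.n_steps * params.dt


def minimize(
    top: GoTopology,
    model: AtomicModel,
    n_steps: int = 500,
    step_size: float = 1e-3,
) -> tuple[AtomicModel, TrajectoryRecord]:
    """Steepest-descent energy minimization with backtracking.

    The step along the force direction is halved whenever it would
    increase the energy and gently re-grown after accepted moves, so the
    recorded energy sequence is non-increasing.
    """
    if step_size <= 0:
        raise ValueError("step_size must be positive")
    x = model.coords.copy()
    report, forces = go_energy_forces(top, x)
    energy = report.total
    if not np.isfinite(energy):
        raise ValueError("non-finite energy at minimization input")
    record = TrajectoryRecord()
    record.append(0.0, energy, 0.0, None, 0.0, [])
    step = step_size
    for it in range(n_steps):
        fmax = np.max(np.abs(forces))
        if fmax < 1e-10:
            break
        trial = x + step * forces
        trial_report, trial_forces = go_energy_forces(top, trial)
        if trial_report.total <= energy:
            x, forces, energy = trial, trial_forces, trial_report.total
            step *= 1.2
        else:
            step *= 0.5
            if step < 1e-14:
                break
        record.append(float(it + 1), energy, 0.0, None,
                      rmsd(x, model.coords), [])
    return model.with_coords(x), record


def nmmd_step(
    state: SimulationState,
    params: SimulationParams,
    basis: np.ndarray | None,
    force_fn,
    masses: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> SimulationState:
    """One joint Velocity Verlet update of coordinates and amplitudes.

    ``basis`` is a ``(n_modes, 3N)`` array of displacement directions
    (rows unit-normalized); ``force_fn(coords) -> (potential, forces)``.
    With ``basis`` empty or ``None`` the update is exactly a plain MD
    step.  When ``nm_dt`` is an integer multiple of ``dt``, mode updates
    are sub-cycled: they fire only on steps where ``step % ratio == 0``.
    """
    n = state.coords.shape[0]
    if masses is None:
        masses = np.ones(n)
    nm = 0 if basis is None else basis.shape[0]
    if nm != len(state.q):
        raise ValueError("basis size does not match state.q")
    s = state.copy()
    if s.forces is None:
        _, s.forces = force_fn(s.coords)
    if not np.all(np.isfinite(s.forces)):
        raise FloatingPointError(f"non-finite force at step {s.step}")
    dt = params.dt
    mode_active = nm > 0 and (s.step % params.nm_subcycle == 0)
    nm_dt = params.nm_dt

    # B: half kick
    s.velocities += 0.5 * dt * s.forces / masses[:, None]
    if mode_active:
        f_m = basis @ s.forces.ravel()
        s.q_dot += 0.5 * nm_dt * f_m / params.nm_mass

    # A: half drift
    s.coords += 0.5 * dt * s.velocities
    if mode_active:
        dq = 0.5 * nm_dt * s.q_dot
        s.q += dq
        s.coords += (dq @ basis).reshape(n, 3)

    # O: thermostat (Cartesian first, then modes — fixed draw order)
    if params.temperature > 0 and rng is not None:
        c1 = math.exp(-params.friction * dt)
        kt = KB * params.temperature
        s.velocities = c1 * s.velocities + np.sqrt(
            kt * (1 - c1 * c1) / masses)[:, None] * rng.standard_normal((n, 3))
        if mode_active:
            s.q_dot = c1 * s.q_dot + math.sqrt(
                kt * (1 - c1 * c1) / params.nm_mass
            ) * rng.standard_normal(nm)

    # A: half drift
    s.coords += 0.5 * dt * s.velocities
    if mode_active:
        dq = 0.5 * nm_dt * s.q_dot
        s.q += dq
        s.coords += (dq @ basis).reshape(n, 3)

    # B: half kick with new forces
    _, s.forces = force_fn(s.coords)
    if not np.all(np.isfinite(s.forces)):
        raise FloatingPointError(f"non-finite force at step {s.step + 1}")
    s.velocities += 0.5 * dt * s.forces / masses[:, None]
    if mode_active:
        f_m = basis @ s.forces.ravel()
        s.q_dot += 0.5 * nm_dt * f_m / params.nm_mass

    s.time += dt
    s.step += 1
    return s


def md_step(
    state: SimulationState,
    params: SimulationParams,
    force_fn,
    masses: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> SimulationState:
    """One Velocity Verlet (optionally Langevin BAOAB) MD step."""
    return nmmd_step(state, params, None, force_fn, masses=masses, rng=rng)


def kinetic_energy(state: SimulationState, params: SimulationParams,
                   masses: np.ndarray | None = None) -> float:
    """Total kinetic energy: Cartesian plus mode-amplitude part."""
    if masses is None:
        masses = np.ones(state.coords.shape[0])
    ke = 0.5 * float(np.sum(masses[:, None] * state.velocities**2))
    ke += 0.5 * params.nm_mass * float(np.sum(state.q_dot**2))
    return ke


def run_simulation(
    model: AtomicModel,
    params: SimulationParams,
    force_fn,
    basis: np.ndarray | None = None,
    cc_fn=None,
    state: SimulationState | None = None,
) -> tuple[SimulationState, TrajectoryRecord]:
    """Integrate ``n_steps`` steps, recording diagnostics periodically.

    ``force_fn(coords) -> (potential, forces)`` supplies the full force
    field (physical plus any biasing term); ``cc_fn(coords) -> float``
    optionally reports the data correlation at recording time.  RMSD is
    measured against the starting coordinates.
    """
    masses = model.mass
    nm = 0 if basis is None else basis.shape[0]
    if state is None:
        state = initial_state(model, nm)
    rng = np.random.default_rng(params.seed)
    record = TrajectoryRecord()

    def report(s: SimulationState) -> None:
        pot, _ = force_fn(s.coords)
        record.append(
            s.time, pot, kinetic_energy(s, params, masses),
            cc_fn(s.coords) if cc_fn is not None else None,
            rmsd(s.coords, model.coords), s.q)

    report(state)
    for _ in range(params.n_steps):
        state = nmmd_step(state, params, basis, force_fn,
                          masses=masses, rng=rng)
        if state.step % params.report_interval == 0:
            report(state)
    if params.n_steps % params.report_interval != 0:
        report(state)
    return state, record
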