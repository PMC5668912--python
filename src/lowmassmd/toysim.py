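"""Minimal classical MD engine for toy systems.

Velocity-Verlet integration with optional SHAKE bond-length constraints
and a Berendsen weak-coupling thermostat, in AMBER-compatible units:
lengths in Å, times in fs, masses in amu, energies in kcal/mol.  The
single unit-bridging constant is

    ``ACCEL = 4.184e-4``  Å/fs² per (kcal/mol/Å)/amu,

i.e. acceleration = force / mass × ACCEL.  Potential terms are the
standard harmonic bond/angle, cosine torsion, and 12-6 Lennard-Jones
forms:

    V_bond    = ½ k_b (r − r0)²
    V_angle   = ½ k_a (θ − θ0)²
    V_torsion = (barrier/2) (1 + cos(n φ − phase))
    V_LJ      = 4 ε ((σ/r)¹² − (σ/r)⁶)

No periodic boundaries, no barostat, no long-range electrostatics:
toy systems are finite clusters and chains, which is all that is needed
to exercise mass scaling and folding-style kinetics at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import (
    ConfigurationError,
    DegenerateStateError,
    ShakeConvergenceError,
)

#: Acceleration per unit (force/mass): Å/fs² per (kcal/mol/Å)/amu.
ACCEL = 4.184e-4

#: Boltzmann constant, kcal/mol/K.
KB = 0.0019872


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ToySystem:
    """Point particles with masses, coordinates, and velocities.

    Parameters
    ----------
    masses : (n,) array, amu — strictly positive.
    positions : (n, 3) array, Å.
    velocities : (n, 3) array, Å/fs.
    labels : per-particle atom-name strings (e.g. ``"CA"``, ``"CB"``).
    residue_ids : 1-based residue numbers, one per particle.
    """

    masses: np.ndarray
    positions: np.ndarray
    velocities: np.ndarray
    labels: list[str] = field(default_factory=list)
    residue_ids: np.ndarray | None = None

    def __post_init__(self):
        self.masses = np.asarray(self.masses, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.velocities = np.asarray(self.velocities, dtype=float)
        n = self.masses.shape[0]
        if np.any(self.masses <= 0):
            raise ConfigurationError("all masses must be strictly positive")
        if self.positions.shape != (n, 3):
            raise ConfigurationError(
                f"positions must have shape ({n}, 3), got {self.positions.shape}"
            )
        if self.velocities.shape != self.positions.shape:
            raise ConfigurationError(
                "positions and velocities must have identical shapes"
            )
        if not self.labels:
            self.labels = [f"X{i + 1}" for i in range(n)]
        if self.residue_ids is None:
            self.residue_ids = np.arange(1, n + 1)
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)

    @property
    def n_particles(self) -> int:
        return self.masses.shape[0]

    def copy(self) -> "ToySystem":
        return ToySystem(
            self.masses.copy(),
            self.positions.copy(),
            self.velocities.copy(),
            list(self.labels),
            self.residue_ids.copy(),
        )


@dataclass
class ForceField:
    """Bonded and nonbonded interaction terms.

    ``bonds``: (i, j, k_b kcal/mol/Å², r0 Å);
    ``angles``: (i, j, k, k_a kcal/mol/rad², θ0 rad), j is the vertex;
    ``torsions``: (i, j, k, l, barrier kcal/mol, periodicity, phase rad);
    ``lj_pairs``: (i, j, ε kcal/mol, σ Å).
    """

    bonds: Sequence[tuple] = field(default_factory=list)
    angles: Sequence[tuple] = field(default_factory=list)
    torsions: Sequence[tuple] = field(default_factory=list)
    lj_pairs: Sequence[tuple] = field(default_factory=list)

    def validate(self, n_particles: int) -> None:
        for (i, j, kb, r0) in self.bonds:
            if i == j:
                raise ConfigurationError("bond with identical endpoints")
            if not (0 <= i < n_particles and 0 <= j < n_particles):
                raise ConfigurationError(f"bond index out of range: ({i}, {j})")
            if kb < 0:
                raise ConfigurationError("negative bond force constant")
        for (i, j, k, ka, _) in self.angles:
            if len({i, j, k}) != 3:
                raise ConfigurationError("angle with repeated indices")
            if max(i, j, k) >= n_particles or min(i, j, k) < 0:
                raise ConfigurationError("angle index out of range")
            if ka < 0:
                raise ConfigurationError("negative angle force constant")
        for (i, j, k, l, *_rest) in self.torsions:
            if max(i, j, k, l) >= n_particles or min(i, j, k, l) < 0:
                raise ConfigurationError("torsion index out of range")
        for (i, j, eps, _) in self.lj_pairs:
            if max(i, j) >= n_particles or min(i, j) < 0:
                raise ConfigurationError("LJ index out of range")
            if eps < 0:
                raise ConfigurationError("negative LJ epsilon")


@dataclass
class ConstraintSet:
    """Holonomic pair-distance constraints solved by SHAKE.

    ``pairs``: (i, j, target length Å); ``tolerance`` is relative on the
    pair distance; ``max_iterations`` bounds the SHAKE sweep count, and
    exceeding it raises rather than silently passing — so the known
    failure mode of too-long time steps is observable.
    """

    pairs: Sequence[tuple]
    tolerance: float = 1e-8
    max_iterations: int = 500

    def __post_init__(self):
        if self.tolerance <= 0:
            raise ConfigurationError("constraint tolerance must be > 0")
        for (i, j, d) in self.pairs:
            if i == j:
                raise ConfigurationError("constraint with identical endpoints")
            if d <= 0:
                raise ConfigurationError("constraint target length must be > 0")

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class Thermostat:
    """Berendsen weak-coupling parameters: target T (K), τ_T (fs)."""

    target_T: float
    tau_T: float

    def __post_init__(self):
        if self.target_T <= 0 or self.tau_T <= 0:
            raise ConfigurationError("thermostat T and tau_T must be > 0")


@dataclass
class IntegratorConfig:
    """Run parameters.

    ``dt`` is the integration step in fs of standard-mass time;
    frames are saved every ``save_interval`` steps (the initial
    conformation is not saved).  ``seed`` feeds the Maxwell–Boltzmann
    velocity draw when ``initialize_velocities`` is set.
    """

    dt: float
    n_steps: int
    save_interval: int
    thermostat: Thermostat | None = None
    seed: int = 0
    initialize_velocities: bool = False

    def __post_init__(self):
        if self.dt <= 0:
            raise ConfigurationError("dt must be > 0")
        if self.save_interval <= 0:
            raise ConfigurationError("save_interval must be > 0")
        if self.n_steps < self.save_interval:
            raise ConfigurationError("n_steps must be >= save_interval")


@dataclass
class Trajectory:
    """Saved frames with their step indices and time axes.

    ``dt`` is the integration step; ``effective_dt`` the standard-mass
    time credited per step (equal to ``dt`` unless the run used scaled
    masses).  Energies, when recorded, are per saved frame in kcal/mol.
    """

    frames: np.ndarray          # (n_frames, n_particles, 3)
    step_indices: np.ndarray    # (n_frames,)
    dt: float
    effective_dt: float | None = None
    potential: np.ndarray | None = None
    kinetic: np.ndarray | None = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        self.step_indices = np.asarray(self.step_indices, dtype=np.int64)
        if len(self.frames) != len(self.step_indices):
            raise ConfigurationError("frames and step_indices length mismatch")
        if len(self.step_indices) > 1 and np.any(np.diff(self.step_indices) <= 0):
            raise ConfigurationError("step_indices must be strictly increasing")
        if self.effective_dt is None:
            self.effective_dt = self.dt

    @property
    def n_frames(self) -> int:
        return len(self.step_indices)

    def times_fs(self) -> np.ndarray:
        """Effective (standard-mass) time of each frame, fs."""
        return self.step_indices * self.effective_dt


# ---------------------------------------------------------------------------
# Forces and energies
# ---------------------------------------------------------------------------

def _scatter(n: int, *blocks) -> np.ndarray:
    """Incidence matrix turning per-term contributions into per-particle
    sums via one dense matmul — much faster than ``np.add.at`` on the
    tiny systems this engine targets.  Each block is a list of
    (index array, sign) entries sharing one column range."""
    mats = []
    for block in blocks:
        width = len(block[0][0])
        m = np.zeros((n, width))
        for idx, sign in block:
            np.add.at(m, (idx, np.arange(width)), sign)
        mats.append(m)
    return np.hstack(mats) if mats else np.zeros((n, 0))


def _prepared(ff: ForceField, n_particles: int):
    """Pack forcefield terms into index/parameter/scatter arrays once."""
    n = n_particles
    b = np.array([t[:2] for t in ff.bonds], dtype=int).reshape(-1, 2)
    bp = np.array([t[2:] for t in ff.bonds], dtype=float).reshape(-1, 2)
    a = np.array([t[:3] for t in ff.angles], dtype=int).reshape(-1, 3)
    ap = np.array([t[3:] for t in ff.angles], dtype=float).reshape(-1, 2)
    d = np.array([t[:4] for t in ff.torsions], dtype=int).reshape(-1, 4)
    dp = np.array([t[4:] for t in ff.torsions], dtype=float).reshape(-1, 3)
    lj = np.array([t[:2] for t in ff.lj_pairs], dtype=int).reshape(-1, 2)
    ljp = np.array([t[2:] for t in ff.lj_pairs], dtype=float).reshape(-1, 2)
    sb = _scatter(n, [(b[:, 0], 1.0), (b[:, 1], -1.0)])
    sa = _scatter(n, [(a[:, 0], 1.0)], [(a[:, 2], 1.0)], [(a[:, 1], 1.0)])
    sd = _scatter(
        n, [(d[:, 0], 1.0)], [(d[:, 1], 1.0)], [(d[:, 2], 1.0)], [(d[:, 3], 1.0)]
    )
    slj = _scatter(n, [(lj[:, 0], 1.0), (lj[:, 1], -1.0)])
    return b, bp, a, ap, d, dp, lj, ljp, sb, sa, sd, slj


def potential_energy(system: ToySystem, ff: ForceField) -> float:
    """Total potential energy, kcal/mol."""
    _, energy = compute_forces(system, ff, return_energy=True)
    return energy


def kinetic_energy(system: ToySystem) -> float:
    """Total kinetic energy, kcal/mol."""
    return _kinetic(system.masses, system.velocities)


def _kinetic(masses: np.ndarray, velocities: np.ndarray) -> float:
    return 0.5 * float(np.sum(masses * np.sum(velocities**2, axis=1))) / ACCEL


def instantaneous_temperature(
    system: ToySystem, n_constraints: int = 0
) -> float:
    """2·KE / (N_dof·k_B) with N_dof = 3·n − n_constraints, in K."""
    ndof = 3 * system.n_particles - n_constraints
    return 2.0 * kinetic_energy(system) / (ndof * KB)


def compute_forces(
    system: ToySystem, ff: ForceField, return_energy: bool = False
):
    """Per-particle forces (kcal/mol/Å) as −∇V of the total potential."""
    ff.validate(system.n_particles)
    prep = _prepared(ff, system.n_particles)
    f, e = _forces_raw(system.positions, prep)
    return (f, e) if return_energy else f


def _dots(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    return (u * v).sum(axis=-1)


def _cross(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Cross product on the last axis; avoids np.cross's axis plumbing,
    which dominates the per-step cost on tiny systems."""
    out = np.empty(np.broadcast_shapes(u.shape, v.shape))
    out[..., 0] = u[..., 1] * v[..., 2] - u[..., 2] * v[..., 1]
    out[..., 1] = u[..., 2] * v[..., 0] - u[..., 0] * v[..., 2]
    out[..., 2] = u[..., 0] * v[..., 1] - u[..., 1] * v[..., 0]
    return out


def _forces_raw(x: np.ndarray, prep) -> tuple[np.ndarray, np.ndarray]:
    """Forces and potential energy; ``x`` may be a single configuration
    (n, 3) or a batch (..., n, 3) of replicas sharing one topology.

    Energy comes back as a scalar (or an array of batch shape).
    """
    b, bp, a, ap, d, dp, lj, ljp, sb, sa, sd, slj = prep
    forces = np.zeros_like(x)
    energy = np.zeros(x.shape[:-2])

    if len(b):
        rij = x[..., b[:, 0], :] - x[..., b[:, 1], :]
        r = np.sqrt(_dots(rij, rij))
        dr = r - bp[:, 1]
        energy = energy + 0.5 * (bp[:, 0] * dr**2).sum(axis=-1)
        # F_i = -k (r - r0) r̂_ij, scattered +i / −j
        fvec = (-bp[:, 0] * dr / r)[..., None] * rij
        forces += sb @ fvec

    if len(a):
        u = x[..., a[:, 0], :] - x[..., a[:, 1], :]
        v = x[..., a[:, 2], :] - x[..., a[:, 1], :]
        nu = np.sqrt(_dots(u, u))
        nv = np.sqrt(_dots(v, v))
        c = np.clip(_dots(u, v) / (nu * nv), -1.0, 1.0)
        theta = np.arccos(c)
        s = np.sqrt(np.maximum(1.0 - c**2, 1e-14))
        dtheta = theta - ap[:, 1]
        dVdtheta = ap[:, 0] * dtheta
        energy = energy + 0.5 * (ap[:, 0] * dtheta**2).sum(axis=-1)
        # dθ/dr_i = (c û − v̂) / (|u| s);  symmetric for k
        uh = u / nu[..., None]
        vh = v / nv[..., None]
        fi = -dVdtheta[..., None] * (c[..., None] * uh - vh) / (nu * s)[..., None]
        fk = -dVdtheta[..., None] * (c[..., None] * vh - uh) / (nv * s)[..., None]
        forces += sa @ np.concatenate([fi, fk, -(fi + fk)], axis=-2)

    if len(d):
        b1 = x[..., d[:, 1], :] - x[..., d[:, 0], :]
        b2 = x[..., d[:, 2], :] - x[..., d[:, 1], :]
        b3 = x[..., d[:, 3], :] - x[..., d[:, 2], :]
        n1 = _cross(b1, b2)
        n2 = _cross(b2, b3)
        nb2 = np.sqrt(_dots(b2, b2))
        phi = np.arctan2(_dots(_cross(n1, n2), b2) / nb2, _dots(n1, n2))
        barrier, period, phase = dp[:, 0], dp[:, 1], dp[:, 2]
        energy = energy + (0.5 * barrier * (1.0 + np.cos(period * phi - phase))).sum(
            axis=-1
        )
        dVdphi = -0.5 * barrier * period * np.sin(period * phi - phase)
        dphi_i = (-nb2 / _dots(n1, n1))[..., None] * n1
        dphi_l = (nb2 / _dots(n2, n2))[..., None] * n2
        c12 = (_dots(b1, b2) / nb2**2)[..., None]
        c32 = (_dots(b3, b2) / nb2**2)[..., None]
        dphi_j = -(1.0 + c12) * dphi_i + c32 * dphi_l
        dphi_k = c12 * dphi_i - (1.0 + c32) * dphi_l
        g = -dVdphi[..., None]
        forces += sd @ np.concatenate(
            [g * dphi_i, g * dphi_j, g * dphi_k, g * dphi_l], axis=-2
        )

    if len(lj):
        rij = x[..., lj[:, 0], :] - x[..., lj[:, 1], :]
        r2 = _dots(rij, rij)
        sr6 = (ljp[:, 1] ** 2 / r2) ** 3
        sr12 = sr6**2
        energy = energy + (4.0 * ljp[:, 0] * (sr12 - sr6)).sum(axis=-1)
        # F_i = 24 ε (2 (σ/r)¹² − (σ/r)⁶) r_ij / r²
        fvec = (24.0 * ljp[:, 0] * (2.0 * sr12 - sr6) / r2)[..., None] * rij
        forces += slj @ fvec

    return forces, energy if energy.ndim else float(energy)


# ---------------------------------------------------------------------------
# SHAKE / RATTLE
# ---------------------------------------------------------------------------

def shake_project(
    positions: np.ndarray,
    reference_positions: np.ndarray,
    constraints: ConstraintSet,
    masses: np.ndarray,
    step: int | None = None,
) -> np.ndarray:
    """Project positions onto the constraint manifold (SHAKE).

    Corrections are applied along the *reference* (pre-drift) bond
    vectors, mass-weighted, and iterated until every constrained pair
    distance is within the relative tolerance of its target.  Raises
    :class:`ShakeConvergenceError` when ``max_iterations`` sweeps do not
    converge — the signature of a too-long time step.
    """
    x = np.array(positions, dtype=float)
    ref = np.asarray(reference_positions, dtype=float)
    idx = np.array([p[:2] for p in constraints.pairs], dtype=int)
    targets = np.array([p[2] for p in constraints.pairs], dtype=float)
    invm = 1.0 / np.asarray(masses, dtype=float)
    tol = constraints.tolerance

    for _ in range(constraints.max_iterations):
        done = True
        for m, (i, j) in enumerate(idx):
            r = x[i] - x[j]
            d2 = targets[m] ** 2
            diff = r @ r - d2
            if abs(diff) > 2.0 * tol * d2:
                done = False
                s = ref[i] - ref[j]
                denom = 2.0 * (invm[i] + invm[j]) * (s @ r)
                if abs(denom) < 1e-14:
                    raise ShakeConvergenceError(
                        "SHAKE: constraint and reference bond orthogonal",
                        step=step,
                    )
                g = diff / denom
                x[i] -= g * invm[i] * s
                x[j] += g * invm[j] * s
        if done:
            return x
    raise ShakeConvergenceError(
        f"SHAKE did not converge in {constraints.max_iterations} iterations",
        step=step,
    )


def rattle_velocities(
    velocities: np.ndarray,
    positions: np.ndarray,
    constraints: ConstraintSet,
    masses: np.ndarray,
    sweeps: int = 50,
) -> np.ndarray:
    """Remove velocity components along constrained bonds (RATTLE).

    After this projection the relative velocity of each constrained pair
    has no component along the bond, keeping the kinetic energy (and
    hence the thermostat's temperature estimate) consistent with the
    reduced number of degrees of freedom.
    """
    v = np.array(velocities, dtype=float)
    idx = np.array([p[:2] for p in constraints.pairs], dtype=int)
    invm = 1.0 / np.asarray(masses, dtype=float)
    for _ in range(sweeps):
        worst = 0.0
        for (i, j) in idx:
            r = positions[i] - positions[j]
            r2 = r @ r
            proj = r @ (v[i] - v[j])
            worst = max(worst, abs(proj))
            k = proj / (r2 * (invm[i] + invm[j]))
            v[i] -= k * invm[i] * r
            v[j] += k * invm[j] * r
        if worst < 1e-12:
            break
    return v


# ---------------------------------------------------------------------------
# Thermostat
# ---------------------------------------------------------------------------

def berendsen_scale_factor(
    T_inst: float, T_target: float, tau_T: float, dt: float
) -> float:
    """Berendsen velocity scaling factor sqrt(1 + (dt/τ_T)(T_target/T_inst − 1))."""
    if T_inst <= 0:
        raise DegenerateStateError(
            "instantaneous temperature must be positive for Berendsen coupling"
        )
    return float(np.sqrt(1.0 + (dt / tau_T) * (T_target / T_inst - 1.0)))


def maxwell_boltzmann_velocities(
    masses: np.ndarray, T: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw velocities (Å/fs) from the Maxwell–Boltzmann distribution at T."""
    m = np.asarray(masses, dtype=float)
    sigma = np.sqrt(KB * T * ACCEL / m)
    return rng.normal(size=(len(m), 3)) * sigma[:, None]


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

def velocity_verlet_step(
    system: ToySystem,
    ff: ForceField,
    dt: float,
    constraints: ConstraintSet | None = None,
) -> ToySystem:
    """One full velocity-Verlet update; returns a new system.

    Half-kick, drift, force recompute, half-kick; if constraints are
    given the drifted positions are SHAKE-projected and velocities are
    RATTLE-corrected along the constraints.
    """
    if dt <= 0:
        raise ConfigurationError("dt must be > 0")
    new = system.copy()
    ff.validate(system.n_particles)
    prep = _prepared(ff, system.n_particles)
    forces, _ = _forces_raw(new.positions, prep)
    _step_inplace(
        new.positions, new.velocities, new.masses, forces, prep, dt, constraints
    )
    return new


def _step_inplace(x, v, masses, forces, prep, dt, constraints):
    """Advance (x, v, forces) by one velocity-Verlet step, in place.

    Returns the updated forces array (for reuse next step).
    """
    c = ACCEL * dt / masses[:, None]
    v += 0.5 * c * forces
    if constraints is None:
        x += v * dt
    else:
        ref = x.copy()
        x += v * dt
        x[:] = shake_project(x, ref, constraints, masses)
        # fold the constraint displacement back into the velocities
        v[:] = (x - ref) / dt
    forces, energy = _forces_raw(x, prep)
    v += 0.5 * c * forces
    if constraints is not None:
        v[:] = rattle_velocities(v, x, constraints, masses)
    return forces, energy


def run_simulation(
    system: ToySystem,
    ff: ForceField,
    config: IntegratorConfig,
    constraints: ConstraintSet | None = None,
    effective_dt: float | None = None,
    monitor: Callable[[np.ndarray, int], bool] | None = None,
    monitor_interval: int = 1000,
) -> Trajectory:
    """Run a fixed-length simulation, saving frames periodically.

    Frames are saved at steps ``save_interval, 2·save_interval, …``; the
    initial conformation is not a saved frame.  Deterministic for a
    given (system, config): all randomness comes from ``config.seed``.

    ``monitor(positions, step)``, checked every ``monitor_interval``
    steps, may return True to stop the run early (frames saved so far
    are returned); used for first-passage studies.

    Raises :class:`ShakeConvergenceError` (with the failing step index)
    if constraint projection fails.
    """
    ff.validate(system.n_particles)
    prep = _prepared(ff, system.n_particles)
    work = system.copy()
    x, v, masses = work.positions, work.velocities, work.masses

    if config.initialize_velocities:
        if config.thermostat is None:
            raise ConfigurationError(
                "velocity initialization requires a thermostat target T"
            )
        rng = np.random.default_rng(config.seed)
        v[:] = maxwell_boltzmann_velocities(masses, config.thermostat.target_T, rng)
        if constraints is not None:
            v[:] = rattle_velocities(v, x, constraints, masses)

    n_con = len(constraints) if constraints is not None else 0
    ndof = 3 * len(masses) - n_con
    thermo = config.thermostat
    dt = config.dt

    n_frames = config.n_steps // config.save_interval
    frames = np.empty((n_frames, len(masses), 3))
    steps_out = np.empty(n_frames, dtype=np.int64)
    epot = np.empty(n_frames)
    ekin = np.empty(n_frames)

    forces, _ = _forces_raw(x, prep)
    saved = 0
    for step in range(1, config.n_steps + 1):
        try:
            forces, energy = _step_inplace(
                x, v, masses, forces, prep, dt, constraints
            )
        except ShakeConvergenceError as err:
            raise ShakeConvergenceError(str(err), step=step) from None
        if thermo is not None:
            ke = _kinetic(masses, v)
            t_inst = 2.0 * ke / (ndof * KB)
            v *= berendsen_scale_factor(t_inst, thermo.target_T, thermo.tau_T, dt)
        if step % config.save_interval == 0:
            frames[saved] = x
            steps_out[saved] = step
            epot[saved] = energy
            ekin[saved] = _kinetic(masses, v)
            saved += 1
        if monitor is not None and step % monitor_interval == 0:
            if monitor(x, step):
                break

    return Trajectory(
        frames[:saved],
        steps_out[:saved],
        dt=dt,
        effective_dt=effective_dt if effective_dt is not None else dt,
        potential=epot[:saved],
        kinetic=ekin[:saved],
    )
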