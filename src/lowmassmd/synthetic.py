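"""Synthetic data generators and packaged benchmark tables.

Three independent sources of test data, so every analysis stage can be
exercised without any download:

* :func:`simulate_two_state` — a continuous-time two-state Markov
  folding simulator (D ⇌ N with exact exponential waiting times) that
  emits per-frame pseudo-RMSD series plus the exact ground-truth
  first-passage times, so estimator bias from frame spacing is
  measurable rather than hidden;
* :func:`build_double_well` — a four-bead chain whose torsion angle has
  two basins separated by a tunable barrier: a desk-scale stand-in for
  a β-hairpin folding landscape that feeds the metrics/kinetics
  pipeline unchanged through a pseudo-RMSD reaction coordinate;
* :func:`reference_tables` — transcriptions of the published
  aggregated-population / folding-time tables for CLN025 and chignolin
  20-run NTP MD folding studies (conditions FF14SBlm, FF14SB,
  FF12MC, FF12MCstdm at time steps 1.00/2.00/3.16 fs), stored as CSV
  data files with checksums so any future correction is a data change,
  not a code change.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegenerateInputError, FormatError
from .kinetics import FoldingRecord, TwoStateModel
from .metrics import NATIVE_CUTOFF
from .toysim import (
    ACCEL,
    KB,
    ConstraintSet,
    ForceField,
    ToySystem,
    _forces_raw,
    _prepared,
)

# ---------------------------------------------------------------------------
# Two-state Markov folding simulator
# ---------------------------------------------------------------------------

#: Default emission ranges (Å): folded conformations sit well below the
#: 1.96 Å native cutoff (observed folded-state pseudo-RMSDs ~1.5 Å),
#: unfolded ones well above, so classification is unambiguous.
NATIVE_RMSD_RANGE = (1.0, 1.9)
NONNATIVE_RMSD_RANGE = (2.5, 8.0)


@dataclass
class TwoStateSimSpec:
    """Parameters of a synthetic two-state folding experiment.

    ``n_sims`` replicate simulations of ``n_steps`` steps, frames saved
    every ``save_interval`` steps, each step credited ``effective_dt``
    fs of standard-mass time.  Rates in ``model`` are ns⁻¹.  The
    emission ranges must keep a ≥0.05 Å margin on each side of the
    native cutoff so boundary classification is never ambiguous.
    """

    model: TwoStateModel
    n_sims: int = 20
    n_steps: int = 500_000_000
    save_interval: int = 100_000
    effective_dt: float = 3.1622776601683795
    seed: int = 0
    native_rmsd_range: tuple[float, float] = NATIVE_RMSD_RANGE
    nonnative_rmsd_range: tuple[float, float] = NONNATIVE_RMSD_RANGE
    cutoff: float = NATIVE_CUTOFF

    def __post_init__(self):
        if self.model.k_f == 0 and self.model.k_u == 0:
            raise DegenerateInputError("at least one rate must be positive")
        lo, hi = self.native_rmsd_range
        if not (lo < hi and hi <= self.cutoff - 0.05):
            raise ConfigurationError(
                "native emission range must lie >= 0.05 A below the cutoff"
            )
        lo, hi = self.nonnative_rmsd_range
        if not (lo < hi and lo >= self.cutoff + 0.05):
            raise ConfigurationError(
                "nonnative emission range must lie >= 0.05 A above the cutoff"
            )

    @property
    def n_frames(self) -> int:
        return self.n_steps // self.save_interval

    @property
    def frame_dt_ns(self) -> float:
        return self.save_interval * self.effective_dt * 1e-6

    @property
    def duration_ns(self) -> float:
        return self.n_steps * self.effective_dt * 1e-6


def simulate_two_state(
    spec: TwoStateSimSpec,
) -> tuple[np.ndarray, list[FoldingRecord]]:
    """Simulate D ⇌ N folding trajectories with exact waiting times.

    Each replicate starts in the nonnative state D; state dwell times
    are drawn exponentially with rates k_f (D→N) and k_u (N→D).  The
    returned RMSD matrix (n_sims × n_frames) emits one value per saved
    frame, uniform over the current state's range; the returned records
    are the *exact* ground-truth first D→N transition times (ns), with a
    replicate that never folds within the run right-censored at the full
    duration.
    """
    rng = np.random.default_rng(spec.seed)
    frame_times = (np.arange(spec.n_frames) + 1) * spec.frame_dt_ns
    rmsd = np.empty((spec.n_sims, spec.n_frames))
    records: list[FoldingRecord] = []
    k = (spec.model.k_f, spec.model.k_u)
    for s in range(spec.n_sims):
        state = 0  # 0 = D, 1 = N
        t = 0.0
        first_fold = None
        # state at each frame time
        frame_state = np.zeros(spec.n_frames, dtype=np.int8)
        ptr = 0
        while ptr < spec.n_frames:
            rate = k[state]
            dwell = np.inf if rate == 0 else rng.exponential(1.0 / rate)
            t_next = t + dwell
            if state == 0 and first_fold is None and t_next <= spec.duration_ns:
                first_fold = t_next
            if t_next >= spec.duration_ns:
                frame_state[ptr:] = state
                break
            upto = np.searchsorted(frame_times, t_next, "left")
            frame_state[ptr:upto] = state
            ptr = upto
            state = 1 - state
            t = t_next
        lo_n, hi_n = spec.native_rmsd_range
        lo_d, hi_d = spec.nonnative_rmsd_range
        u = rng.uniform(size=spec.n_frames)
        rmsd[s] = np.where(
            frame_state == 1, lo_n + u * (hi_n - lo_n), lo_d + u * (hi_d - lo_d)
        )
        if first_fold is not None:
            records.append(FoldingRecord(time=first_fold, event=True))
        else:
            records.append(FoldingRecord(time=spec.duration_ns, event=False))
    return rmsd, records


# ---------------------------------------------------------------------------
# Double-well toy folder
# ---------------------------------------------------------------------------

@dataclass
class DoubleWell:
    """A four-bead chain whose torsion angle φ has two basins.

    The torsion potential (barrier/2)(1 + cos 2φ) has equal minima at
    φ = ±π/2 separated by the stated barrier.  φ = +π/2 is tagged the
    *folded* basin; :meth:`pseudo_rmsd` maps the angular distance from
    it onto [0, ``separation``] Å so the metrics/kinetics pipeline can
    classify frames with an ordinary cutoff.
    """

    system: ToySystem
    forcefield: ForceField
    constraints: ConstraintSet | None
    barrier: float
    separation: float
    folded_phi: float = np.pi / 2

    def torsion_angle(self, positions: np.ndarray):
        """Torsion angle φ (rad); accepts one frame (4, 3) or a batch."""
        x = np.asarray(positions, dtype=float)
        b1 = x[..., 1, :] - x[..., 0, :]
        b2 = x[..., 2, :] - x[..., 1, :]
        b3 = x[..., 3, :] - x[..., 2, :]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        nb2 = np.sqrt((b2 * b2).sum(axis=-1))
        phi = np.arctan2(
            (np.cross(n1, n2) * b2).sum(axis=-1) / nb2, (n1 * n2).sum(axis=-1)
        )
        return float(phi) if phi.ndim == 0 else phi

    def pseudo_rmsd(self, positions: np.ndarray):
        """Distance of the reaction coordinate from the folded minimum, Å."""
        dphi = self.torsion_angle(positions) - self.folded_phi
        dphi = (dphi + np.pi) % (2 * np.pi) - np.pi
        return np.abs(dphi) / np.pi * self.separation


def build_double_well(
    barrier: float = 2.0,
    separation: float = 8.0,
    mass: float = 12.0,
    start: str = "extended",
) -> DoubleWell:
    """Construct the double-well bead chain.

    ``barrier`` (kcal/mol) is the torsion barrier between the folded
    (φ = +π/2) and extended (φ = −π/2) basins; ``separation`` (Å) is
    the pseudo-RMSD assigned to the extended minimum; ``mass`` (amu)
    per bead.  Bond and angle force constants are deliberately unequal:
    a symmetric chain has nearly decoupled normal modes and the torsion
    then thermalizes too slowly to cross the barrier on test timescales.
    """
    if barrier <= 0:
        raise ConfigurationError("barrier must be > 0")
    r0 = 1.53
    theta0 = np.deg2rad(109.5)
    phi0 = np.pi / 2 if start == "folded" else -np.pi / 2
    positions = _chain_positions(r0, theta0, phi0)
    system = ToySystem(
        masses=np.full(4, float(mass)),
        positions=positions,
        velocities=np.zeros((4, 3)),
        labels=["C1", "C2", "C3", "C4"],
        residue_ids=np.array([1, 1, 1, 1]),
    )
    ff = ForceField(
        bonds=[(0, 1, 45.0, r0), (1, 2, 50.0, r0), (2, 3, 55.0, r0)],
        angles=[(0, 1, 2, 25.0, theta0), (1, 2, 3, 35.0, theta0)],
        torsions=[(0, 1, 2, 3, barrier, 2.0, 0.0)],
    )
    return DoubleWell(
        system=system,
        forcefield=ff,
        constraints=None,
        barrier=barrier,
        separation=separation,
    )


#: Bath temperature (K) for double-well crossing studies, calibrated by
#: pilot ensembles so that most replicas cross within ~10⁴ steps at
#: standard mass: with Berendsen weak coupling on a four-bead chain the
#: canonical fluctuations of the torsion are suppressed, so the bath
#: must run hotter (k_B·T ≈ barrier) than a Langevin intuition would
#: suggest.
CROSSING_TEMPERATURE = 900.0


def _chain_positions(r0: float, theta0: float, phi: float) -> np.ndarray:
    """Four beads with bond length r0, bond angles theta0, torsion phi."""
    p0 = np.array([0.0, 0.0, 0.0])
    p1 = np.array([r0, 0.0, 0.0])
    # p2 in the xy-plane making the bond angle at p1
    d = np.array([np.cos(np.pi - theta0), np.sin(np.pi - theta0), 0.0])
    p2 = p1 + r0 * d
    # p3 placed to realize the torsion angle phi about the p1-p2 axis
    b2 = p2 - p1
    b2h = b2 / np.linalg.norm(b2)
    # frame at p2: u in the 0-1-2 plane perpendicular to b2, w out of plane
    u = -(p1 - p0) + np.dot(p1 - p0, b2h) * b2h
    u /= np.linalg.norm(u)
    w = np.cross(b2h, u)
    dir3 = (
        -np.cos(theta0) * b2h
        + np.sin(theta0) * (np.cos(phi) * u + np.sin(phi) * w)
    )
    p3 = p2 + r0 * dir3
    return np.vstack([p0, p1, p2, p3])


def ensemble_first_crossing(
    well: DoubleWell,
    temperature: float,
    lam: float = 1.0,
    n_replicas: int = 20,
    seed: int = 0,
    tau_T: float = 50.0,
    dt: float = 1.0,
    max_steps: int = 100_000,
    cutoff: float = NATIVE_CUTOFF,
    check_interval: int = 25,
) -> np.ndarray:
    """First-passage step counts for a thermostatted double-well ensemble.

    Integrates ``n_replicas`` independent replicas (Maxwell–Boltzmann
    velocities at ``temperature``, Berendsen coupling, masses scaled by
    ``lam``) in one vectorized batch and records, per replica, the first
    step at which the pseudo-RMSD reaches the cutoff, resolved to
    ``check_interval`` steps.  Replicas that never cross within
    ``max_steps`` get ``np.inf``.

    This is the headline sampling-enhancement measurement at toy scale:
    at equal ``dt``, λ = 0.1 replicas cross in fewer steps than λ = 1
    because each step advances √(1/λ) times more effective time.
    """
    base = well.system
    ff = well.forcefield
    n = base.n_particles
    masses = base.masses * lam
    prep = _prepared(ff, n)
    rng = np.random.default_rng(seed)

    x = np.repeat(base.positions[None], n_replicas, axis=0)
    sigma = np.sqrt(KB * temperature * ACCEL / masses)
    v = rng.normal(size=(n_replicas, n, 3)) * sigma[None, :, None]
    f, _ = _forces_raw(x, prep)

    crossing = np.full(n_replicas, np.inf)
    active = np.arange(n_replicas)
    ndof = 3 * n
    c = ACCEL * dt / masses[:, None]
    for step in range(1, max_steps + 1):
        v += 0.5 * c * f
        x += v * dt
        f, _ = _forces_raw(x, prep)
        v += 0.5 * c * f
        ke = 0.5 * (masses[None, :, None] * v**2).sum(axis=(1, 2)) / ACCEL
        t_inst = 2.0 * ke / (ndof * KB)
        factor = np.sqrt(1.0 + (dt / tau_T) * (temperature / t_inst - 1.0))
        v *= factor[:, None, None]
        if step % check_interval == 0:
            hit = well.pseudo_rmsd(x) <= cutoff
            if hit.any():
                crossing[active[hit]] = step
                keep = ~hit
                if not keep.any():
                    break
                active = active[keep]
                x, v, f = x[keep], v[keep], f[keep]
    return crossing


# ---------------------------------------------------------------------------
# Packaged benchmark tables
# ---------------------------------------------------------------------------

#: Table code → (data file, sha256).  Codes 1 / 2A / 2B / 2C follow the
#: source study's numbering: 1 = CLN025 (four conditions), 2A = chignolin
#: FF12MC Δt=1.00, 2B = chignolin FF12MCstdm Δt=3.16, 2C = chignolin
#: FF12MCstdm Δt=2.00.
_TABLE_FILES = {
    "1": (
        "cln025_populations.csv",
        "39decb2f2aa79b13ba21d804972ea7067a0ba9f682f1f4d5183a6f396a4432f5",
    ),
    "2A": (
        "chignolin_ff12mc_dt100.csv",
        "3084c013dc753ef79747fe38e783f2c10e626e7510443bb8ab5909e46f035cc7",
    ),
    "2B": (
        "chignolin_ff12mcstdm_dt316.csv",
        "6dfbbc1b2274ca7d1e5a7c9f69ccf97f53c57f118cf125041d2e9c287a8becff",
    ),
    "2C": (
        "chignolin_ff12mcstdm_dt200.csv",
        "cd675061116ac3d493d15bc29b428f286b1951cc4ca8bcd5019aa70f72fff3a3",
    ),
}


def load_reference_table(which: str) -> pd.DataFrame:
    """Load one transcribed benchmark table by code (1, 2A, 2B, 2C).

    The stored checksum is verified on every load, so a corrupted or
    silently edited transcription fails loudly.
    """
    key = str(which).upper()
    if key not in _TABLE_FILES:
        raise FormatError(f"unknown table code {which!r}; expected 1, 2A, 2B, 2C")
    fname, digest = _TABLE_FILES[key]
    raw = resources.files("lowmassmd.data").joinpath(fname).read_bytes()
    if hashlib.sha256(raw).hexdigest() != digest:
        raise FormatError(f"checksum mismatch for packaged table {key} ({fname})")
    import io

    return pd.read_csv(io.BytesIO(raw))


def reference_tables() -> dict[str, pd.DataFrame]:
    """All four transcribed benchmark tables, keyed by code.

    Row counts and the row-wise SE ≤ SD invariant are asserted on load.
    """
    tables = {k: load_reference_table(k) for k in _TABLE_FILES}
    conditions = tables["1"].groupby(["condition", "timestep_fs"])
    if any(len(g) != 10 for _, g in conditions):
        raise FormatError("CLN025 table must have 10 rows per condition")
    for key in ("2A", "2B", "2C"):
        if len(tables[key]) != 22:
            raise FormatError(f"table {key} must have 22 rows")
    for key, df in tables.items():
        if (df["se_pct"] > df["sd_pct"]).any():
            raise FormatError(f"table {key}: SE exceeds SD in some row")
    return tables


def cln025_mean_curve(condition: str, timestep_fs: float) -> np.ndarray:
    """The 10-point aggregated-population mean curve for one CLN025 condition."""
    df = load_reference_table("1")
    sel = df[
        (df["condition"] == condition)
        & (np.isclose(df["timestep_fs"], timestep_fs))
    ]
    if len(sel) != 10:
        raise FormatError(
            f"no 10-row CLN025 condition ({condition!r}, dt={timestep_fs})"
        )
    return sel["mean_pct"].to_numpy(dtype=float)
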