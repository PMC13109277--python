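"""Coulomb-explosion engine: Monte Carlo photoionization + classical dynamics.

The model follows the standard desk-scale treatment of X-ray-induced
Coulomb explosion of gas-phase biomolecules:

* Photoabsorption events are drawn per atom as an inhomogeneous Poisson
  process whose rate is the (charge-state-dependent) photoabsorption cross
  section times the instantaneous fluence rate of a Gaussian pulse.  The
  cross section saturates with the remaining-electron fraction,
  sigma_eff = sigma_neutral * (Z - q) / Z.
* Optionally, each inner-shell (K) photoabsorption adds one secondary
  (Auger) ionization, instantly or with an exponential delay.
* Ejected electrons are removed from the system and not tracked.
* The ions are propagated with velocity-Verlet under pairwise Coulomb
  forces plus a steep soft-core repulsion A/r^12 that prevents overlap
  singularities; atoms start at rest and charges switch on at their
  ionization event times.  Two-phase time stepping (fine during the pulse,
  coarse afterwards) carries the system to 300 fs, when the ions travel
  essentially ballistically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from ._elements import ACC_CONV, ATOMIC_NUMBER, COULOMB_EV_NM, K_EDGE_EV, KE_CONV
from .synthetic_structures import MolecularStructure
from .xray_optics import AtomicDataTable, FELPulse, gaussian_profile, peak_fluence

__all__ = [
    "ChargedSystem",
    "IonizationEventLog",
    "ExplosionResult",
    "FragmentPartition",
    "sample_ionizations",
    "propagate",
    "detect_fragments",
    "run_explosion",
    "atomization_scan",
    "atomization_threshold",
    "SOFTCORE_A",
]

logger = logging.getLogger(__name__)

#: Soft-core amplitude (eV nm^12): equals unit-charge Coulomb repulsion at
#: the 0.05 nm minimum contact distance, negligible beyond ~0.1 nm.
SOFTCORE_A = COULOMB_EV_NM * 0.05**11

DEFAULT_DT_FS = 0.05
DEFAULT_DT_FAR_FS = 0.5
DEFAULT_T_END_FS = 300.0
DEFAULT_BOND_CUTOFF_NM = 0.25
PULSE_WINDOW_SIGMAS = 4.0


@dataclass
class ChargedSystem:
    """Snapshot of the exploding system (positions nm, velocities nm/fs)."""

    elements: np.ndarray
    positions: np.ndarray
    velocities: np.ndarray
    charges: np.ndarray  # integer e, 0 <= q <= Z
    masses: np.ndarray  # u

    def __post_init__(self) -> None:
        n = len(self.elements)
        self.charges = np.asarray(self.charges, dtype=int)
        if np.any(self.charges < 0):
            raise ValueError("negative charge")
        z = np.array([ATOMIC_NUMBER[el] for el in self.elements])
        if np.any(self.charges > z):
            raise ValueError("charge exceeds atomic number")
        for arr, shape in ((self.positions, (n, 3)), (self.velocities, (n, 3))):
            if arr.shape != shape or not np.all(np.isfinite(arr)):
                raise ValueError("bad positions/velocities")

    @property
    def kinetic_energies_ev(self) -> np.ndarray:
        v2 = np.einsum("ij,ij->i", self.velocities, self.velocities)
        return 0.5 * self.masses * v2 * KE_CONV


@dataclass
class IonizationEventLog:
    """Ionization events: parallel arrays of time (fs), atom index, increment."""

    times: np.ndarray
    atom_indices: np.ndarray
    increments: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.atom_indices = np.asarray(self.atom_indices, dtype=int)
        self.increments = np.asarray(self.increments, dtype=int)
        if not (len(self.times) == len(self.atom_indices) == len(self.increments)):
            raise ValueError("mismatched event arrays")
        if len(self.times) and np.any(self.increments < 1):
            raise ValueError("increments must be >= 1")

    def __len__(self) -> int:
        return len(self.times)

    def final_charges(self, n_atoms: int) -> np.ndarray:
        q = np.zeros(n_atoms, dtype=int)
        np.add.at(q, self.atom_indices, self.increments)
        return q


@dataclass
class ExplosionResult:
    """End state of one explosion plus bookkeeping for audits."""

    system: ChargedSystem
    events: IonizationEventLog
    t_end: float
    audit: dict = field(default_factory=dict)

    @property
    def kinetic_energies_ev(self) -> np.ndarray:
        return self.system.kinetic_energies_ev


@dataclass
class FragmentPartition:
    """Partition of atoms into bound fragments."""

    labels: np.ndarray

    @property
    def n_fragments(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels)

    @property
    def is_atomized(self) -> bool:
        """True when every fragment contains exactly one atom."""
        return bool(np.all(self.sizes == 1))


# ---------------------------------------------------------------------------
# Monte Carlo photoionization

def sample_ionizations(
    structure: MolecularStructure,
    pulse: FELPulse,
    table: AtomicDataTable,
    auger_mode: str = "off",
    seed: int = 0,
    dt_sample_fs: float = 0.1,
    auger_tau_fs: float = 10.0,
) -> IonizationEventLog:
    """Draw per-atom photoionization events under the Gaussian pulse.

    Returns an event log on the time axis [0, T] with the pulse peak at
    T/2, T = 2 * PULSE_WINDOW_SIGMAS * sigma.  ``auger_mode``:

    - ``"off"``: primary photoionization only (default; see docs/methods.md),
    - ``"instant"``: each K-shell absorption adds one simultaneous
      secondary ionization,
    - ``"delayed"``: the secondary is delayed by Exp(auger_tau_fs).
    """
    if auger_mode not in ("off", "instant", "delayed"):
        raise ValueError(f"unknown auger_mode {auger_mode!r}")
    energy = pulse.photon_energy_ev
    present = sorted(set(structure.elements.tolist()))
    sigma0 = {el: table.sigma(el, energy) for el in present}  # raises out of range
    z_of = {el: ATOMIC_NUMBER[el] for el in present}
    k_accessible = {
        el: (K_EDGE_EV[el] is not None and energy >= K_EDGE_EV[el]) for el in present
    }

    rng = np.random.default_rng(seed)
    n = structure.n_atoms
    fluence = peak_fluence(pulse)  # photons / cm^2, sigma in cm^2
    sigma_fwhm = pulse.fwhm_fs / 2.3548200450309493
    half_window = PULSE_WINDOW_SIGMAS * sigma_fwhm
    t_grid = np.arange(0.0, 2.0 * half_window, dt_sample_fs)

    sig_neutral = np.array([sigma0[el] for el in structure.elements])
    z = np.array([z_of[el] for el in structure.elements], dtype=float)
    k_shell = np.array([k_accessible[el] for el in structure.elements])
    charges = np.zeros(n)

    times, atoms, incs = [], [], []
    for t in t_grid:
        rate = sig_neutral * (1.0 - charges / z) * fluence
        p = rate * gaussian_profile(t - half_window, pulse.fwhm_fs) * dt_sample_fs
        hits = np.flatnonzero(rng.random(n) < p)
        for i in hits:
            if charges[i] >= z[i]:
                continue
            charges[i] += 1
            times.append(t)
            atoms.append(i)
            incs.append(1)
            if k_shell[i] and auger_mode != "off" and charges[i] < z[i]:
                charges[i] += 1
                delay = 0.0 if auger_mode == "instant" else rng.exponential(auger_tau_fs)
                times.append(t + delay)
                atoms.append(i)
                incs.append(1)

    order = np.argsort(np.array(times, dtype=float), kind="stable") if times else []
    return IonizationEventLog(
        np.array(times, dtype=float)[order] if len(times) else np.empty(0),
        np.array(atoms, dtype=int)[order] if len(times) else np.empty(0, dtype=int),
        np.array(incs, dtype=int)[order] if len(times) else np.empty(0, dtype=int),
    )


# ---------------------------------------------------------------------------
# classical propagation

try:  # numba accelerates the O(n^2) force loop; numpy path is equivalent
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def wrap(fn):
            return fn

        return wrap


@_njit(cache=False)
def _pair_kernel(pos, charges, softcore_a, k_coulomb):  # pragma: no cover
    n = pos.shape[0]
    forces = np.zeros((n, 3))
    pot = 0.0
    for i in range(n - 1):
        qi = charges[i]
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            inv_r2 = 1.0 / r2
            inv_r = np.sqrt(inv_r2)
            qq = qi * charges[j]
            f_over_r = k_coulomb * qq * inv_r2 * inv_r
            pot += k_coulomb * qq * inv_r
            if qi + charges[j] > 0.0:
                inv_r12 = inv_r2 * inv_r2 * inv_r2
                inv_r12 *= inv_r12
                f_over_r += 12.0 * softcore_a * inv_r12 * inv_r2
                pot += softcore_a * inv_r12
            fx = f_over_r * dx
            fy = f_over_r * dy
            fz = f_over_r * dz
            forces[i, 0] += fx
            forces[i, 1] += fy
            forces[i, 2] += fz
            forces[j, 0] -= fx
            forces[j, 1] -= fy
            forces[j, 2] -= fz
    return forces, pot


def _pair_numpy(pos, charges, softcore_a):
    diff = pos[:, None, :] - pos[None, :, :]
    r2 = np.einsum("ijk,ijk->ij", diff, diff)
    np.fill_diagonal(r2, np.inf)
    inv_r = 1.0 / np.sqrt(r2)
    qq = np.outer(charges, charges).astype(float)
    any_charged = (charges[:, None] + charges[None, :]) > 0
    inv_r2 = inv_r * inv_r
    coul = COULOMB_EV_NM * qq * inv_r2 * inv_r
    soft = 12.0 * softcore_a * inv_r2**7 * any_charged
    forces = np.einsum("ij,ijk->ik", coul + soft, diff)
    pot = 0.5 * np.sum(COULOMB_EV_NM * qq * inv_r + softcore_a * inv_r2**6 * any_charged)
    return forces, float(pot)


def _forces_and_potential(pos, charges, softcore_a):
    """Pairwise Coulomb + soft-core forces (eV/nm) and potential (eV).

    The soft-core term acts only on pairs with at least one ion; neutral
    pairs are force-free (no bonded terms in this model).  Raises on
    non-finite forces, naming the offending pair.
    """
    if _HAVE_NUMBA:
        forces, pot = _pair_kernel(pos, charges.astype(float), softcore_a, COULOMB_EV_NM)
    else:
        forces, pot = _pair_numpy(pos, charges, softcore_a)
    if not np.all(np.isfinite(forces)):
        diff = pos[:, None, :] - pos[None, :, :]
        r2 = np.einsum("ijk,ijk->ij", diff, diff)
        np.fill_diagonal(r2, np.inf)
        i, j = np.unravel_index(np.argmin(r2), r2.shape)
        raise FloatingPointError(f"non-finite force for atom pair ({i}, {j})")
    return forces, float(pot)


def _delta_u_event(pos, charges, i, dq, softcore_a):
    """Potential-energy change from raising charge of atom i by dq (O(n))."""
    diff = pos - pos[i]
    r = np.linalg.norm(diff, axis=1)
    r[i] = np.inf
    d_coul = COULOMB_EV_NM * dq * np.sum(charges / r)
    if charges[i] == 0 and dq > 0:
        newly_active = charges == 0
        d_soft = softcore_a * np.sum(1.0 / r[newly_active] ** 12)
    else:
        d_soft = 0.0
    return float(d_coul + d_soft)


def propagate(
    structure: MolecularStructure,
    events: IonizationEventLog,
    dt: float = DEFAULT_DT_FS,
    t_end: float = DEFAULT_T_END_FS,
    dt_far: float | None = DEFAULT_DT_FAR_FS,
    t_switch: float | None = None,
    softcore_a: float = SOFTCORE_A,
) -> ExplosionResult:
    """Velocity-Verlet propagation of the charged system from rest.

    Charges switch on at their event times; ``dt`` is used until
    ``t_switch`` (default: the last event time, i.e. the end of the pulse),
    then ``dt_far``.  Raises on unstable ``dt`` (> 0.2 fs) and on
    non-finite forces.
    """
    if dt > 0.2:
        raise ValueError(f"dt = {dt} fs too large for stability (need <= 0.2 fs)")
    last_event = float(events.times.max()) if len(events) else 0.0
    if t_end < last_event:
        raise ValueError("t_end must cover the ionization window")
    if t_switch is None:
        t_switch = last_event
    if dt_far is None:
        dt_far = dt

    pos = structure.positions.copy()
    vel = np.zeros_like(pos)
    charges = np.zeros(structure.n_atoms, dtype=int)
    masses = structure.masses

    ev_t, ev_i, ev_dq = events.times, events.atom_indices, events.increments
    next_ev = 0
    injected = 0.0

    def apply_events(t_now):
        nonlocal next_ev, injected
        while next_ev < len(ev_t) and ev_t[next_ev] <= t_now:
            i, dq = ev_i[next_ev], ev_dq[next_ev]
            injected += _delta_u_event(pos, charges, i, dq, softcore_a)
            charges[i] += dq
            next_ev += 1

    apply_events(0.0)
    u0 = _forces_and_potential(pos, np.zeros_like(charges), softcore_a)[1]  # == 0
    forces, _ = _forces_and_potential(pos, charges, softcore_a)

    t = 0.0
    while t < t_end - 1e-9:
        step = dt if t < t_switch - 1e-9 else dt_far
        step = min(step, t_end - t)
        acc = forces / masses[:, None] * ACC_CONV
        vel += 0.5 * step * acc
        pos += step * vel
        t += step
        apply_events(t)
        forces, pot = _forces_and_potential(pos, charges, softcore_a)
        vel += 0.5 * step * (forces / masses[:, None] * ACC_CONV)

    system = ChargedSystem(structure.elements.copy(), pos, vel, charges, masses)
    ke = float(system.kinetic_energies_ev.sum())
    e_ref = u0 + injected
    drift = abs((ke + pot) - e_ref) / max(abs(e_ref), ke, 1e-12)
    momentum = (masses[:, None] * vel).sum(axis=0)
    p_scale = np.abs(masses[:, None] * vel).sum() or 1.0
    audit = {
        "energy_injected_ev": injected,
        "final_kinetic_ev": ke,
        "final_potential_ev": pot,
        "energy_drift_rel": drift,
        "momentum_rel": float(np.linalg.norm(momentum) / p_scale),
    }
    return ExplosionResult(system, events, t_end, audit)


# ---------------------------------------------------------------------------
# fragment detection

def detect_fragments(
    result: ExplosionResult,
    bond_cutoff: float = DEFAULT_BOND_CUTOFF_NM,
    softcore_a: float = SOFTCORE_A,
) -> FragmentPartition:
    """Single-linkage fragments of the final configuration.

    Atom pairs within ``bond_cutoff`` are linked only when their relative
    kinetic energy is below their pair potential at that separation (pairs
    escaping each other are not bound).  The pair potential here includes
    the soft-core term for *all* pairs, so an un-ionized structure at rest
    is a single intact fragment.
    """
    if bond_cutoff <= 0:
        raise ValueError("bond_cutoff must be > 0")
    sys_ = result.system
    n = sys_.positions.shape[0]
    pairs = cKDTree(sys_.positions).query_pairs(bond_cutoff, output_type="ndarray")
    rows, cols = [], []
    for i, j in pairs:
        r = np.linalg.norm(sys_.positions[i] - sys_.positions[j])
        r = max(r, 1e-6)
        u_pair = (
            COULOMB_EV_NM * sys_.charges[i] * sys_.charges[j] / r
            + softcore_a / r**12
        )
        mu = sys_.masses[i] * sys_.masses[j] / (sys_.masses[i] + sys_.masses[j])
        v_rel2 = float(np.sum((sys_.velocities[i] - sys_.velocities[j]) ** 2))
        ke_rel = 0.5 * mu * v_rel2 * KE_CONV
        if ke_rel < u_pair:
            rows.append(i)
            cols.append(j)
    adj = sparse.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    _, labels = connected_components(adj, directed=False)
    return FragmentPartition(labels)


def atomization_scan(
    structure: MolecularStructure,
    pulse: FELPulse,
    table: AtomicDataTable,
    intensity_scales=(1.0, 10.0, 100.0, 500.0, 1000.0, 2000.0, 4000.0, 8000.0),
    seeds=(0, 1, 2, 3, 4),
    dt: float = DEFAULT_DT_FS,
    t_end: float = DEFAULT_T_END_FS,
    auger_mode: str = "off",
    bond_cutoff: float = DEFAULT_BOND_CUTOFF_NM,
) -> list:
    """Scan pulse intensity and record mean charge and atomization per run.

    Returns one record per (scale, seed): a dict with ``scale``, ``seed``,
    ``mean_charge`` (e/atom) and ``atomized``.  The atomization threshold
    is the smallest mean charge among scales where every seed atomized
    (see ``atomization_threshold``).
    """
    records = []
    for scale in intensity_scales:
        scaled = FELPulse(
            pulse.photons_per_pulse * scale,
            pulse.wavelength_nm,
            pulse.focus_diameter_nm,
            pulse.fwhm_fs,
        )
        for seed in seeds:
            result = run_explosion(
                structure, scaled, table, dt=dt, t_end=t_end, seed=seed,
                auger_mode=auger_mode,
            )
            frag = detect_fragments(result, bond_cutoff=bond_cutoff)
            records.append(
                {
                    "scale": scale,
                    "seed": seed,
                    "mean_charge": float(result.system.charges.mean()),
                    "atomized": frag.is_atomized,
                }
            )
            logger.info(
                "scan scale %g seed %d: %.3f e/atom atomized=%s",
                scale, seed, records[-1]["mean_charge"], frag.is_atomized,
            )
    return records


def atomization_threshold(records) -> float:
    """Smallest mean charge/atom among scales where all seeds atomized.

    Returns NaN when no scan point atomized on every seed.
    """
    by_scale: dict = {}
    for rec in records:
        by_scale.setdefault(rec["scale"], []).append(rec)
    candidates = [
        float(np.mean([r["mean_charge"] for r in recs]))
        for recs in by_scale.values()
        if all(r["atomized"] for r in recs)
    ]
    return min(candidates) if candidates else float("nan")


def run_explosion(
    structure: MolecularStructure,
    pulse: FELPulse,
    table: AtomicDataTable,
    dt: float = DEFAULT_DT_FS,
    t_end: float = DEFAULT_T_END_FS,
    seed: int = 0,
    auger_mode: str = "off",
    dt_far: float | None = DEFAULT_DT_FAR_FS,
    softcore_a: float = SOFTCORE_A,
) -> ExplosionResult:
    """One end-to-end seeded explosion: ionize, then propagate to t_end."""
    events = sample_ionizations(structure, pulse, table, auger_mode=auger_mode, seed=seed)
    return propagate(
        structure, events, dt=dt, t_end=t_end, dt_far=dt_far, softcore_a=softcore_a
    )
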