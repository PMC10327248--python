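"""Coarse-grained Langevin dynamic fitting against an AFM topograph.

A minimal native-centric structure potential (harmonic bonded terms along
the bead chain, 12-10 Go wells for native contacts, harmonic wells for
listed base pairs and stacks, soft-core excluded volume and Debye-screened
phosphate electrostatics) is combined with the AFM pseudo-potential and the
stage potential, and integrated with the BAOAB Langevin splitting.  This is
deliberately not a full biomolecular force field: the point of the engine
is the topographic bias and the ten per-frame energy features it emits, not
force-field fidelity.

Reduced units throughout: kB*T = 1 at the reference temperature, unit bead
masses, lengths in Angstrom.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .energy_model import (
    StageParams,
    ThetaConfig,
    b_stage,
    b_stage_force,
)
from .afm_topography import TipModel
from .io_formats import AFMSurface, CoarseModel, EnergyRecord, SecondaryStructure
from .structure_metrics import Trajectory

__all__ = [
    "StructurePotential",
    "FitConfig",
    "build_structure_potential",
    "run_fitting",
    "theta_scan",
]



def _scatter_add(f: np.ndarray, idx: np.ndarray, contrib: np.ndarray) -> None:
    # bincount-based scatter-add; much faster than np.add.at for small arrays
    n = f.shape[0]
    for d in range(3):
        f[:, d] += np.bincount(idx, weights=contrib[:, d], minlength=n)

@dataclass
class StructurePotential:
    """Native-centric potential terms, all reference values measured from
    the native model.  Index arrays refer to bead order in the model."""

    bonds: np.ndarray          # (nb, 2) int
    bond_r0: np.ndarray
    bond_k: float
    angles: np.ndarray         # (na, 3) int
    angle_t0: np.ndarray
    angle_k: float
    dihedrals: np.ndarray      # (nd, 4) int
    dihedral_p0: np.ndarray
    dihedral_k: float
    go_pairs: np.ndarray       # (ng, 2) int
    go_r0: np.ndarray
    go_eps: float
    pair_terms: np.ndarray     # (np_, 2) int, base beads of paired residues
    pair_r0: np.ndarray
    pair_k: float
    stack_terms: np.ndarray
    stack_r0: np.ndarray
    stack_k: float
    ev_pairs: np.ndarray       # (ne, 2) int
    ev_sigma: float
    ev_eps: float
    elec_pairs: np.ndarray     # (nq, 2) int, phosphate beads
    elec_k: float
    elec_lambda: float

    # ---- energies -------------------------------------------------------

    def _dists(self, coords: np.ndarray, pairs: np.ndarray) -> np.ndarray:
        if len(pairs) == 0:
            return np.empty(0)
        d = coords[pairs[:, 0]] - coords[pairs[:, 1]]
        return np.sqrt(np.sum(d * d, axis=1))

    def energy_components(self, coords: np.ndarray) -> dict[str, float]:
        """Raw (unweighted) energy components at the given coordinates."""
        comp = {}
        e_local = 0.0
        r = self._dists(coords, self.bonds)
        e_local += 0.5 * self.bond_k * np.sum((r - self.bond_r0) ** 2)
        if len(self.angles):
            t = _angles(coords, self.angles)
            e_local += 0.5 * self.angle_k * np.sum((t - self.angle_t0) ** 2)
        if len(self.dihedrals):
            p = _dihedrals(coords, self.dihedrals)
            e_local += self.dihedral_k * np.sum(1.0 - np.cos(p - self.dihedral_p0))
        comp["e_local"] = float(e_local)

        r = self._dists(coords, self.go_pairs)
        if len(r):
            s = self.go_r0 / r
            comp["e_go"] = float(self.go_eps * np.sum(5.0 * s**12 - 6.0 * s**10))
        else:
            comp["e_go"] = 0.0

        r = self._dists(coords, self.pair_terms)
        comp["e_pairing"] = float(0.5 * self.pair_k * np.sum((r - self.pair_r0) ** 2))
        r = self._dists(coords, self.stack_terms)
        comp["e_stacking"] = float(0.5 * self.stack_k * np.sum((r - self.stack_r0) ** 2))

        r = self._dists(coords, self.ev_pairs)
        if len(r):
            inside = r < self.ev_sigma
            s6 = (self.ev_sigma / np.maximum(r[inside], 0.2 * self.ev_sigma)) ** 6
            comp["e_repulsive"] = float(self.ev_eps * np.sum(s6 * s6 - 1.0))
        else:
            comp["e_repulsive"] = 0.0

        r = self._dists(coords, self.elec_pairs)
        if len(r):
            comp["e_electrostatic"] = float(
                self.elec_k * np.sum(np.exp(-r / self.elec_lambda) / r))
        else:
            comp["e_electrostatic"] = 0.0
        return comp

    # ---- forces ---------------------------------------------------------

    def forces(self, coords: np.ndarray, theta: ThetaConfig) -> np.ndarray:
        """Theta-weighted structure force, shape (n, 3)."""
        f = np.zeros_like(coords)

        def add_pair_force(pairs, fmag_over_r):
            # fmag_over_r: magnitude/r along (ri - rj); positive = repulsive
            d = coords[pairs[:, 0]] - coords[pairs[:, 1]]
            fv = d * fmag_over_r[:, None]
            _scatter_add(f, pairs[:, 0], fv)
            _scatter_add(f, pairs[:, 1], -fv)

        if len(self.bonds):
            d = coords[self.bonds[:, 0]] - coords[self.bonds[:, 1]]
            r = np.sqrt(np.sum(d * d, axis=1))
            add_pair_force(self.bonds,
                           -theta.theta_c * self.bond_k * (r - self.bond_r0) / r)
        if len(self.angles):
            _add_angle_forces(f, coords, self.angles, self.angle_t0,
                              theta.theta_c * self.angle_k)
        if len(self.dihedrals):
            _add_dihedral_forces(f, coords, self.dihedrals, self.dihedral_p0,
                                 theta.theta_c * self.dihedral_k)
        if len(self.go_pairs):
            d = coords[self.go_pairs[:, 0]] - coords[self.go_pairs[:, 1]]
            r = np.sqrt(np.sum(d * d, axis=1))
            s = self.go_r0 / r
            mag = theta.theta_contact * self.go_eps * 60.0 * (s**12 - s**10) / (r * r)
            add_pair_force(self.go_pairs, mag)
        if len(self.pair_terms):
            d = coords[self.pair_terms[:, 0]] - coords[self.pair_terms[:, 1]]
            r = np.sqrt(np.sum(d * d, axis=1))
            add_pair_force(self.pair_terms,
                           -theta.theta_pairing * self.pair_k * (r - self.pair_r0) / r)
        if len(self.stack_terms):
            d = coords[self.stack_terms[:, 0]] - coords[self.stack_terms[:, 1]]
            r = np.sqrt(np.sum(d * d, axis=1))
            add_pair_force(self.stack_terms,
                           -theta.theta_stacking * self.stack_k * (r - self.stack_r0) / r)
        if len(self.ev_pairs):
            d = coords[self.ev_pairs[:, 0]] - coords[self.ev_pairs[:, 1]]
            r = np.sqrt(np.sum(d * d, axis=1))
            rc = np.maximum(r, 0.2 * self.ev_sigma)
            s6 = (self.ev_sigma / rc) ** 6
            mag = 12.0 * self.ev_eps * s6 * s6 / (rc * rc)
            mag[r >= self.ev_sigma] = 0.0
            add_pair_force(self.ev_pairs, mag)
        if len(self.elec_pairs):
            d = coords[self.elec_pairs[:, 0]] - coords[self.elec_pairs[:, 1]]
            r = np.sqrt(np.sum(d * d, axis=1))
            x = np.exp(-r / self.elec_lambda)
            mag = self.elec_k * x * (1.0 / (r * r) + 1.0 / (self.elec_lambda * r)) / r
            add_pair_force(self.elec_pairs, mag)
        return f

    def forces_fast(self, coords: np.ndarray, theta: ThetaConfig) -> np.ndarray:
        """Compiled equivalent of :meth:`forces` (used by the integrator)."""
        from ._kernels import structure_forces
        return structure_forces(
            coords,
            self.bonds, self.bond_r0, self.bond_k,
            self.angles, self.angle_t0, self.angle_k,
            self.dihedrals, self.dihedral_p0, self.dihedral_k,
            self.go_pairs, self.go_r0, self.go_eps,
            self.pair_terms, self.pair_r0, self.pair_k,
            self.stack_terms, self.stack_r0, self.stack_k,
            self.ev_pairs, self.ev_sigma, self.ev_eps,
            self.elec_pairs, self.elec_k, self.elec_lambda,
            theta.theta_c, theta.theta_stacking, theta.theta_pairing,
            theta.theta_contact,
        )


# ---------------------------------------------------------------------------
# geometry helpers (angles / dihedrals and their gradients)
# ---------------------------------------------------------------------------

def _angles(coords, idx):
    u = coords[idx[:, 0]] - coords[idx[:, 1]]
    v = coords[idx[:, 2]] - coords[idx[:, 1]]
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    cos = np.clip(np.sum(u * v, axis=1) / (nu * nv), -1.0, 1.0)
    return np.arccos(cos)


def _add_angle_forces(f, coords, idx, t0, k):
    u = coords[idx[:, 0]] - coords[idx[:, 1]]
    v = coords[idx[:, 2]] - coords[idx[:, 1]]
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    uh = u / nu[:, None]
    vh = v / nv[:, None]
    cos = np.clip(np.sum(uh * vh, axis=1), -1.0, 1.0)
    sin = np.sqrt(np.maximum(1.0 - cos * cos, 1e-12))
    t = np.arccos(cos)
    dEdt = k * (t - t0)
    dti = (cos[:, None] * uh - vh) / (nu * sin)[:, None]
    dtk = (cos[:, None] * vh - uh) / (nv * sin)[:, None]
    _scatter_add(f, idx[:, 0], -dEdt[:, None] * dti)
    _scatter_add(f, idx[:, 2], -dEdt[:, None] * dtk)
    _scatter_add(f, idx[:, 1], dEdt[:, None] * (dti + dtk))


def _dihedrals(coords, idx):
    b1 = coords[idx[:, 1]] - coords[idx[:, 0]]
    b2 = coords[idx[:, 2]] - coords[idx[:, 1]]
    b3 = coords[idx[:, 3]] - coords[idx[:, 2]]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2, axis=1)
    y = np.sum(np.cross(n1, n2) * (b2 / nb2[:, None]), axis=1)
    x = np.sum(n1 * n2, axis=1)
    return np.arctan2(y, x)


def _add_dihedral_forces(f, coords, idx, p0, k):
    b1 = coords[idx[:, 1]] - coords[idx[:, 0]]
    b2 = coords[idx[:, 2]] - coords[idx[:, 1]]
    b3 = coords[idx[:, 3]] - coords[idx[:, 2]]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2, axis=1)
    sn1 = np.sum(n1 * n1, axis=1)
    sn2 = np.sum(n2 * n2, axis=1)
    y = np.sum(np.cross(n1, n2) * (b2 / nb2[:, None]), axis=1)
    x = np.sum(n1 * n2, axis=1)
    phi = np.arctan2(y, x)
    dEdp = k * np.sin(phi - p0)
    dpi = -(nb2 / np.maximum(sn1, 1e-12))[:, None] * n1
    dpl = (nb2 / np.maximum(sn2, 1e-12))[:, None] * n2
    c12 = (np.sum(b1 * b2, axis=1) / (nb2 * nb2))[:, None]
    c32 = (np.sum(b3 * b2, axis=1) / (nb2 * nb2))[:, None]
    dpj = -(1.0 + c12) * dpi + c32 * dpl
    dpk = -dpi - dpj - dpl
    _scatter_add(f, idx[:, 0], -dEdp[:, None] * dpi)
    _scatter_add(f, idx[:, 1], -dEdp[:, None] * dpj)
    _scatter_add(f, idx[:, 2], -dEdp[:, None] * dpk)
    _scatter_add(f, idx[:, 3], -dEdp[:, None] * dpl)


# ---------------------------------------------------------------------------
# potential construction
# ---------------------------------------------------------------------------

def build_structure_potential(
    native: CoarseModel,
    ss: SecondaryStructure | None = None,
    go_cutoff: float = 12.0,
    bond_k: float = 20.0,
    angle_k: float = 10.0,
    dihedral_k: float = 1.0,
    go_eps: float = 0.4,
    pair_k: float = 2.0,
    stack_k: float = 2.0,
    ev_sigma: float = 4.0,
    ev_eps: float = 0.5,
    elec_k: float = 0.5,
    elec_lambda: float = 10.0,
) -> StructurePotential:
    """Measure a native-centric potential from a reference model.

    Bonds, angles and dihedrals run along the backbone chain
    (P1?, S1, P2, S2, ...) with sugar-base branches; reference values are
    the native ones.  Native bead pairs within ``go_cutoff`` (excluding
    bonded or angle-sharing pairs and intra-residue pairs) become 12-10 Go
    wells; listed base pairs and stacks become harmonic wells between base
    beads; everything else gets soft-core repulsion, plus Debye-screened
    phosphate-phosphate electrostatics.
    """
    ss = ss or SecondaryStructure()
    coords = native.coords
    n = native.n_beads
    res_ids = native.residue_indices
    ss.validate_indices(len(res_ids))

    # bead index lookup per residue
    by_res: dict[int, dict[str, int]] = {}
    for i, b in enumerate(native.beads):
        by_res.setdefault(b.residue_index, {})[b.kind] = i

    backbone: list[int] = []
    for ridx in res_ids:
        slot = by_res[ridx]
        if "phosphate" in slot:
            backbone.append(slot["phosphate"])
        backbone.append(slot["sugar"])

    bonds = [(backbone[i], backbone[i + 1]) for i in range(len(backbone) - 1)]
    for ridx in res_ids:
        slot = by_res[ridx]
        bonds.append((slot["sugar"], slot["base"]))

    angles = [(backbone[i], backbone[i + 1], backbone[i + 2])
              for i in range(len(backbone) - 2)]
    for pos, ridx in enumerate(res_ids):
        slot = by_res[ridx]
        s = slot["sugar"]
        bb_pos = backbone.index(s)
        nb = backbone[bb_pos + 1] if bb_pos + 1 < len(backbone) else backbone[bb_pos - 1]
        angles.append((slot["base"], s, nb))

    dihedrals = [(backbone[i], backbone[i + 1], backbone[i + 2], backbone[i + 3])
                 for i in range(len(backbone) - 3)]

    bonded = set()
    for i, j in bonds:
        bonded.add((min(i, j), max(i, j)))
    angle_13 = set()
    for a in angles:
        angle_13.add((min(a[0], a[2]), max(a[0], a[2])))
    excluded = bonded | angle_13

    # residue index per bead for intra-residue exclusion
    res_of = native.residue_of_bead()

    pair_idx = []
    for ridx_i, ridx_j in ss.pairs:
        pair_idx.append((by_res[res_ids[ridx_i - 1]]["base"],
                         by_res[res_ids[ridx_j - 1]]["base"]))
    stack_idx = []
    for ridx_i, ridx_j in ss.stacks:
        stack_idx.append((by_res[res_ids[ridx_i - 1]]["base"],
                          by_res[res_ids[ridx_j - 1]]["base"]))
    harmonic = {(min(i, j), max(i, j)) for i, j in pair_idx + stack_idx}

    # native Go contacts
    go = []
    if go_cutoff > 0:
        d = np.sqrt(np.sum((coords[:, None, :] - coords[None, :, :]) ** 2, axis=2))
        for i in range(n):
            for j in range(i + 1, n):
                if (i, j) in excluded or (i, j) in harmonic:
                    continue
                if res_of[i] == res_of[j]:
                    continue
                if d[i, j] <= go_cutoff:
                    go.append((i, j))
    go_set = set(go)

    ev = []
    for i in range(n):
        for j in range(i + 1, n):
            key = (i, j)
            if key in excluded or key in harmonic or key in go_set:
                continue
            if res_of[i] == res_of[j]:
                continue
            ev.append(key)

    phos = [i for i, b in enumerate(native.beads) if b.kind == "phosphate"]
    elec = [(i, j) for ii, i in enumerate(phos) for j in phos[ii + 1:]
            if (min(i, j), max(i, j)) not in excluded]

    def arr(lst, w):
        return np.array(lst, dtype=int).reshape(-1, w)

    bonds_a = arr(bonds, 2)
    angles_a = arr(angles, 3)
    dihedrals_a = arr(dihedrals, 4)
    go_a = arr(go, 2)
    pair_a = arr(pair_idx, 2)
    stack_a = arr(stack_idx, 2)

    def dists(pairs):
        if len(pairs) == 0:
            return np.empty(0)
        dd = coords[pairs[:, 0]] - coords[pairs[:, 1]]
        return np.sqrt(np.sum(dd * dd, axis=1))

    return StructurePotential(
        bonds=bonds_a, bond_r0=dists(bonds_a), bond_k=bond_k,
        angles=angles_a, angle_t0=_angles(coords, angles_a) if len(angles_a) else np.empty(0),
        angle_k=angle_k,
        dihedrals=dihedrals_a,
        dihedral_p0=_dihedrals(coords, dihedrals_a) if len(dihedrals_a) else np.empty(0),
        dihedral_k=dihedral_k,
        go_pairs=go_a, go_r0=dists(go_a), go_eps=go_eps,
        pair_terms=pair_a, pair_r0=dists(pair_a), pair_k=pair_k,
        stack_terms=stack_a, stack_r0=dists(stack_a), stack_k=stack_k,
        ev_pairs=arr(ev, 2), ev_sigma=ev_sigma, ev_eps=ev_eps,
        elec_pairs=arr(elec, 2), elec_k=elec_k, elec_lambda=elec_lambda,
    )


# ---------------------------------------------------------------------------
# Langevin integration
# ---------------------------------------------------------------------------

@dataclass
class FitConfig:
    """Langevin dynamic-fitting configuration (reduced units)."""

    n_steps: int = 50_000
    save_every: int | None = None       # default n_steps // 1000
    timestep: float = 0.02
    friction: float = 0.5
    temperature: float = 0.3
    seed: int = 0
    theta: ThetaConfig = field(default_factory=ThetaConfig)
    stage: StageParams = field(default_factory=StageParams)
    tip: TipModel = field(default_factory=TipModel)
    kT_ref: float = 1.0                 # kB*T in the AFM pseudo-potential
    afm_every: int = 1                  # image/force recomputation cadence
    soft_temperature: float = 1.0       # smoothing of the dilation max, A

    def __post_init__(self):
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.save_every is None:
            self.save_every = max(1, self.n_steps // 1000)
        if self.save_every < 1:
            raise ValueError("save_every must be >= 1")


def run_fitting(start: CoarseModel, target: AFMSurface,
                pot: StructurePotential, cfg: FitConfig) -> Trajectory:
    """BAOAB Langevin dynamics under structure + stage + AFM potentials.

    ``start`` must already be placed in the image frame (see
    :func:`afmfit.energy_model.register_rigid`).  Every ``save_every``
    steps a frame and a full 10-feature energy record are emitted.  The
    run is reproducible bitwise for a fixed configuration and seed.
    """
    rng = np.random.default_rng(cfg.seed)
    coords = start.coords
    if coords[:, 2].min() <= 0:          # defensive drop onto the stage
        coords[:, 2] -= coords[:, 2].min() - cfg.tip.bead_radius
    n = coords.shape[0]
    dt = cfg.timestep
    vel = rng.normal(0.0, np.sqrt(max(cfg.temperature, 0.0)), size=(n, 3))
    c1 = np.exp(-cfg.friction * dt)
    c2 = np.sqrt(max(cfg.temperature, 0.0) * (1.0 - c1 * c1))

    afm_on = cfg.theta.theta_afm > 0
    f_afm = np.zeros_like(coords)
    cc = 0.0
    from ._kernels import afm_cc_grad
    pref = cfg.theta.theta_afm * n * cfg.kT_ref
    R = cfg.tip.contact_radius

    def total_force(x, step):
        nonlocal f_afm, cc
        f = pot.forces_fast(x, cfg.theta)
        f[:, 2] += b_stage_force(x[:, 2], cfg.stage)
        if afm_on and step % cfg.afm_every == 0:
            cc, grad_cc, _ = afm_cc_grad(
                x, target.heights, target.origin[0], target.origin[1],
                target.pixel_size, cfg.tip.radius, R, cfg.soft_temperature, True)
            if cc <= -1.5:
                raise RuntimeError(
                    f"degenerate simulated image at step {step}")
            f_afm = pref * grad_cc
        if afm_on:
            f = f + f_afm
        return f

    frames: list[CoarseModel] = []
    records: list[EnergyRecord] = []

    def save(step, x):
        comp = pot.energy_components(x)
        from .energy_model import v_afm, total_energy
        cc_now, _, _ = afm_cc_grad(
            x, target.heights, target.origin[0], target.origin[1],
            target.pixel_size, cfg.tip.radius, R, cfg.soft_temperature, False)
        cc_now = max(float(cc_now), 0.0)
        comp["cc_afm"] = cc_now
        comp["v_afm"] = v_afm(cc_now, cfg.theta.theta_afm, n, cfg.kT_ref)
        comp["b_stage"] = b_stage(np.maximum(x[:, 2], 1e-6), cfg.stage)
        records.append(total_energy(comp, cfg.theta, frame=step))
        frames.append(start.with_coords(x.copy()))

    force = total_force(coords, 0)
    for step in range(1, cfg.n_steps + 1):
        vel += 0.5 * dt * force
        coords += 0.5 * dt * vel
        vel = c1 * vel + c2 * rng.normal(size=(n, 3))
        coords += 0.5 * dt * vel
        force = total_force(coords, step)
        vel += 0.5 * dt * force
        if np.max(np.abs(coords)) > 1e6:
            raise RuntimeError(f"numerical blow-up at step {step}")
        if step % cfg.save_every == 0:
            save(step, coords)
    if not frames:
        save(cfg.n_steps, coords)
    return Trajectory(frames=frames, records=records)


def theta_scan(start: CoarseModel, target: AFMSurface, pot: StructurePotential,
               cfg: FitConfig,
               thetas: Sequence[float] = (2.0, 5.0, 10.0, 20.0, 50.0),
               ) -> dict[float, Trajectory]:
    """Independent seeded runs over a theta_AFM scan list (default touches
    the scanned range endpoints 2 and 50)."""
    if not thetas:
        raise ValueError("theta list must be non-empty")
    out = {}
    for i, th in enumerate(thetas):
        c = copy.deepcopy(cfg)
        c.theta = replace(cfg.theta, theta_afm=float(th))
        c.seed = cfg.seed + 7919 * i
        out[float(th)] = run_fitting(start, target, pot, c)
    return out
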