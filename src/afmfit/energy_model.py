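"""AFM scoring and biasing machinery.

The agreement between an experimental topograph ``I_exp`` and a
back-calculated one ``I_sim`` is the non-centered cosine similarity

    CC = sum(I_exp * I_sim) / sqrt(sum(I_exp^2) * sum(I_sim^2)),

which lies in [0, 1] for non-negative height maps (note: deliberately not
mean-centered — the centered form is reserved for the resolution ACV).
The corresponding pseudo-potential is

    V_AFM = theta_AFM * N * kB*T * (1 - CC),

with N the total bead count; it vanishes exactly at perfect correlation.
A Lennard-Jones-form stage potential keeps the molecule's backside on the
support plane.  Energies are in reduced units with kB*T = 1 at the
reference temperature.

The AFM force is the exact analytic gradient of V_AFM computed through the
smooth (softplus + log-sum-exp) image synthesis, so it matches finite
differences of the same potential.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .afm_topography import TipModel, synthesize_surface, synthesize_surface_soft
from .io_formats import AFMSurface, CoarseModel, EnergyRecord

__all__ = [
    "ThetaConfig",
    "StageParams",
    "cc_afm",
    "v_afm",
    "v_afm_soft",
    "b_stage",
    "b_stage_force",
    "total_energy",
    "afm_force",
    "register_rigid",
]


@dataclass
class ThetaConfig:
    """Empirical weights balancing image agreement against structure
    integrity.  Defaults follow the optimized values: covalent 5,
    stacking 9, pairing 9, contact 1; theta_afm is scanned (2-50)."""

    theta_afm: float = 10.0
    theta_c: float = 5.0
    theta_stacking: float = 9.0
    theta_pairing: float = 9.0
    theta_contact: float = 1.0

    def __post_init__(self):
        for name in ("theta_afm", "theta_c", "theta_stacking",
                     "theta_pairing", "theta_contact"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class StageParams:
    """Stage (mica) interaction: 12-6 Lennard-Jones per bead with well depth
    ``epsilon`` and contact distance ``d`` (defaults to the bead radius)."""

    epsilon: float = 1.0
    d: float = 4.0

    def __post_init__(self):
        if self.epsilon <= 0 or self.d <= 0:
            raise ValueError("epsilon and d must be positive")


def cc_afm(exp: AFMSurface, sim: AFMSurface) -> float:
    """Non-centered normalized cross-correlation of two height grids."""
    a = exp.heights.ravel()
    b = sim.heights.ravel()
    if a.shape != b.shape:
        raise ValueError("surfaces must share shape")
    na = np.sum(a * a)
    nb = np.sum(b * b)
    if na == 0 or nb == 0:
        raise ValueError("all-zero image: cross-correlation undefined")
    return float(np.sum(a * b) / np.sqrt(na * nb))


def v_afm(cc: float, theta_afm: float, n_beads: int, kT: float = 1.0) -> float:
    """Pseudo-potential theta_AFM * N * kB*T * (1 - CC)."""
    if theta_afm < 0:
        raise ValueError("theta_afm must be >= 0")
    return theta_afm * n_beads * kT * (1.0 - cc)


def _cc_soft(coords: np.ndarray, exp: AFMSurface, tip: TipModel,
             temperature: float, return_parts: bool = False):
    h = synthesize_surface_soft(coords, exp, tip, temperature)
    e = exp.heights
    B = np.sum(e * e)
    C = np.sum(h * h)
    if B == 0:
        raise ValueError("all-zero experimental image")
    if C < 1e-20:
        raise ValueError("degenerate (all-zero) simulated image")
    A = np.sum(e * h)
    cc = A / np.sqrt(B * C)
    if return_parts:
        return cc, h, A, B, C
    return cc


def v_afm_soft(model: CoarseModel, exp: AFMSurface, tip: TipModel,
               theta: ThetaConfig, kT: float = 1.0,
               temperature: float = 1.0) -> tuple[float, float]:
    """(CC, V_AFM) evaluated through the smooth synthesis path.

    This is the differentiable potential whose exact gradient
    :func:`afm_force` returns; finite differences of this function match
    the force.
    """
    cc = _cc_soft(model.coords, exp, tip, temperature)
    return float(cc), v_afm(float(cc), theta.theta_afm, model.n_beads, kT)


def afm_force(model: CoarseModel, exp: AFMSurface, tip: TipModel,
              theta: ThetaConfig, kT: float = 1.0,
              temperature: float = 1.0) -> np.ndarray:
    """-grad V_AFM with respect to bead positions, shape (n_beads, 3)."""
    coords = model.coords
    f, _ = _afm_force_coords(coords, exp, tip, theta, kT, temperature)
    return f


def _afm_force_coords(coords, exp, tip, theta, kT=1.0, temperature=1.0):
    """Force and (cc, v_afm) from raw coordinates; used by the integrator."""
    h, (p, dx, dy, dc_dq) = synthesize_surface_soft(
        coords, exp, tip, temperature, return_grad=True
    )
    e = exp.heights
    B = np.sum(e * e)
    C = np.sum(h * h)
    if B == 0:
        raise ValueError("all-zero experimental image")
    if C < 1e-20:
        raise ValueError("degenerate (all-zero) simulated image")
    A = np.sum(e * h)
    cc = A / np.sqrt(B * C)
    n = coords.shape[0]
    pref = theta.theta_afm * n * kT
    if pref == 0.0:
        return np.zeros_like(coords), (float(cc), 0.0)
    # dCC/dh_p, then chain through the soft synthesis
    g = e / np.sqrt(B * C) - cc * h / C            # (ny, nx)
    gp = g[None] * p                                # (n_beads, ny, nx)
    # c_i = z_i - r_t + root(q_i);  dq/dx_i = 2*dx (dx = x_pixel - x_i)
    common = gp * dc_dq * 2.0
    dcc_dx = np.sum(common * dx, axis=(1, 2))
    dcc_dy = np.sum(common * dy, axis=(1, 2))
    dcc_dz = np.sum(gp, axis=(1, 2))
    grad_cc = np.stack([dcc_dx, dcc_dy, dcc_dz], axis=1)
    force = pref * grad_cc                          # -dV/dr = +pref * dCC/dr
    return force, (float(cc), pref * (1.0 - float(cc)))


def b_stage(model_or_z, params: StageParams, floor_frac: float = 0.25) -> float:
    """Stage potential: sum over beads of 4 eps [(d/z)^12 - (d/z)^6].

    ``z`` is the bead height above the stage plane.  Heights below
    ``floor_frac * d`` are clamped to that floor (the wall is already
    enormous there); a non-positive height after clamping is an error.
    """
    z = model_or_z.coords[:, 2] if isinstance(model_or_z, CoarseModel) else np.asarray(model_or_z, float)
    if np.any(z <= 0):
        raise ValueError("bead height at or below the stage plane")
    zc = np.maximum(z, floor_frac * params.d)
    s6 = (params.d / zc) ** 6
    return float(np.sum(4.0 * params.epsilon * (s6 * s6 - s6)))


def b_stage_force(z: np.ndarray, params: StageParams,
                  floor_frac: float = 0.25) -> np.ndarray:
    """-d b_stage / d z per bead.

    Below the clamping floor the force is held at its (already enormous,
    upward) floor value so a penetrating bead is always pushed back out.
    """
    z = np.asarray(z, dtype=float)
    zc = np.maximum(z, floor_frac * params.d)
    s6 = (params.d / zc) ** 6
    return 24.0 * params.epsilon * (2.0 * s6 * s6 - s6) / zc


_RAW_COMPONENTS = ("e_go", "e_local", "e_stacking", "e_pairing",
                   "e_repulsive", "e_electrostatic", "b_stage",
                   "v_afm", "cc_afm")


def total_energy(components: Mapping[str, float], theta: ThetaConfig,
                 frame: int = 0) -> EnergyRecord:
    """Assemble the theta-weighted total energy from raw components.

    E_total = V_AFM + theta_c*E_local + theta_stacking*E_stacking
            + theta_pairing*E_pairing + theta_contact*E_go
            + E_repulsive + E_electrostatic + B_stage.

    The returned record stores the *weighted* components (matching what a
    trajectory energy table reports), plus the pass-through CC score.
    """
    missing = [k for k in _RAW_COMPONENTS if k not in components]
    if missing:
        raise ValueError(f"missing energy component(s): {', '.join(missing)}")
    w = {
        "e_go": theta.theta_contact * components["e_go"],
        "e_local": theta.theta_c * components["e_local"],
        "e_stacking": theta.theta_stacking * components["e_stacking"],
        "e_pairing": theta.theta_pairing * components["e_pairing"],
        "e_repulsive": components["e_repulsive"],
        "e_electrostatic": components["e_electrostatic"],
        "b_stage": components["b_stage"],
        "v_afm": components["v_afm"],
    }
    e_total = sum(w.values())
    return EnergyRecord(frame=frame, e_total=e_total,
                        cc_afm=components["cc_afm"], **w)


def register_rigid(
    model: CoarseModel,
    exp: AFMSurface,
    tip: TipModel | None = None,
    rotation_step_deg: float = 15.0,
    max_shift_px: int = 4,
) -> tuple[CoarseModel, float]:
    """Initial rigid placement of a model in the image frame.

    Deterministic grid search over in-plane rotations (about the molecule
    centroid, default 15-degree steps) and integer-pixel translations,
    maximizing CC of the hard-synthesized image against the experimental
    one.  Returns the transformed model and its CC.
    """
    tip = tip or TipModel()
    coords0 = model.coords
    centroid = coords0.mean(axis=0)
    img_center = np.array([
        exp.origin[0] + 0.5 * exp.pixel_size * (exp.shape[1] - 1),
        exp.origin[1] + 0.5 * exp.pixel_size * (exp.shape[0] - 1),
    ])
    best = (-2.0, None)
    angles = np.deg2rad(np.arange(0.0, 360.0, rotation_step_deg))
    shifts = exp.pixel_size * np.arange(-max_shift_px, max_shift_px + 1)
    for ang in angles:
        ca, sa = np.cos(ang), np.sin(ang)
        rot = np.array([[ca, -sa, 0.0], [sa, ca, 0.0], [0.0, 0.0, 1.0]])
        base = (coords0 - centroid) @ rot.T
        base[:, 0] += img_center[0]
        base[:, 1] += img_center[1]
        for sx in shifts:
            for sy in shifts:
                c = base.copy()
                c[:, 0] += sx
                c[:, 1] += sy
                cand = model.with_coords(c)
                sim = synthesize_surface(cand, tip=tip, grid_like=exp)
                if sim.heights.max() == 0:
                    continue
                cc = cc_afm(exp, sim)
                if cc > best[0]:
                    best = (cc, c)
    if best[1] is None:
        raise ValueError("registration failed: model never touches the grid")
    placed = model.with_coords(best[1])
    # drop onto the stage plane
    coords = placed.coords
    coords[:, 2] -= coords[:, 2].min() - tip.bead_radius
    return placed.with_coords(coords), best[0]
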