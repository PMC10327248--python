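"""Synthetic generators: toy RNAs on idealized A-form geometry, controlled
perturbations with a known RMSD, ground-truth surfaces with benchmark noise
levels, and planted trajectories with a known energy-RMSD structure.

The toy builders place phosphate/sugar/base beads on ideal helical tracks
(rise 2.8 A per residue, twist 32.7 degrees per residue) so duplex width
and pitch land in the ~25 / ~30 A envelope of an A-form duplex.  Planted
trajectories emulate the working assumption behind trajectory model
selection: that frames close to the true structure have low energies and
high image cross-correlation.  Every generator is deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .afm_topography import (
    BENCHMARK_NOISE_LEVELS,
    TipModel,
    add_gaussian_noise,
    synthesize_surface,
)
from .io_formats import AFMSurface, Bead, CoarseModel, EnergyRecord, SecondaryStructure
from .structure_metrics import rmsd

__all__ = [
    "SyntheticSpec",
    "PlantedTrajectorySpec",
    "build_toy_rna",
    "perturb_known_rmsd",
    "make_benchmark",
    "planted_trajectory",
]

HELIX_RISE = 2.8          # A per residue
HELIX_TWIST = 32.7        # degrees per residue
P_RADIUS = 10.5           # phosphate track radius -> ~21 A track separation
S_RADIUS = 9.2
B_RADIUS = 6.0
STRAND_PHASE = 150.0      # degrees between paired strands


@dataclass
class SyntheticSpec:
    n_residues: int = 20
    topology: str = "hairpin"     # hairpin | two_helix_junction | three_way
    helix_rise: float = HELIX_RISE
    helix_twist: float = HELIX_TWIST
    seed: int = 0

    def __post_init__(self):
        if self.n_residues < 8:
            raise ValueError("need at least 8 residues")
        if self.topology not in ("hairpin", "two_helix_junction", "three_way"):
            raise ValueError(f"unknown topology {self.topology!r}")


@dataclass
class PlantedTrajectorySpec:
    """Planted linear energy-RMSD relation with Gaussian noise.

    Each energy component is ``intercept + slope * RMSD + noise`` and the
    CC score follows a monotone-decreasing map of RMSD.  Defaults give a
    clearly learnable but noisy relation, emulating a trajectory in which
    good models are simultaneously low-energy and high-correlation.
    """

    n_frames: int = 6000
    rmsd_range: tuple[float, float] = (2.0, 25.0)
    energy_slopes: dict[str, float] = field(default_factory=lambda: {
        "e_total": 40.0, "e_go": 8.0, "e_local": 12.0, "e_stacking": 6.0,
        "e_pairing": 6.0, "e_repulsive": 3.0, "e_electrostatic": 1.0,
        "b_stage": 2.0, "v_afm": 10.0,
    })
    energy_intercepts: dict[str, float] = field(default_factory=lambda: {
        "e_total": -800.0, "e_go": -200.0, "e_local": 150.0, "e_stacking": -90.0,
        "e_pairing": -90.0, "e_repulsive": 20.0, "e_electrostatic": 5.0,
        "b_stage": -40.0, "v_afm": 30.0,
    })
    noise_sd: dict[str, float] = field(default_factory=lambda: {
        "e_total": 60.0, "e_go": 15.0, "e_local": 20.0, "e_stacking": 10.0,
        "e_pairing": 10.0, "e_repulsive": 6.0, "e_electrostatic": 2.0,
        "b_stage": 4.0, "v_afm": 15.0,
    })
    cc_map: Callable[[np.ndarray], np.ndarray] = field(
        default_factory=lambda: (lambda r: 0.97 - 0.018 * r))
    cc_noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.rmsd_range
        if not (0 < lo < hi):
            raise ValueError("rmsd_range must be positive with min < max")


# ---------------------------------------------------------------------------
# toy RNA construction
# ---------------------------------------------------------------------------

def _helix_arm(n_pairs: int, rise: float, twist: float, start_res: int,
               loop_len: int = 4):
    """A hairpin arm: duplex of n_pairs + terminal loop, axis along +x.

    Returns (positions dict residue -> {kind: xyz}, pairs, stacks,
    n_residues_used).  Residues run 5'->3' down strand 1, through the
    loop, and back along strand 2; residue i pairs with (total + 1 - i).
    """
    tw = np.deg2rad(twist)
    ph = np.deg2rad(STRAND_PHASE)
    total = 2 * n_pairs + loop_len
    res: dict[int, dict[str, np.ndarray]] = {}

    def place(residue, angle, axial):
        res[residue] = {
            "phosphate": np.array([axial, P_RADIUS * np.cos(angle),
                                   P_RADIUS * np.sin(angle)]),
            "sugar": np.array([axial, S_RADIUS * np.cos(angle - 0.25),
                               S_RADIUS * np.sin(angle - 0.25)]),
            "base": np.array([axial, B_RADIUS * np.cos(angle - 0.5),
                              B_RADIUS * np.sin(angle - 0.5)]),
        }

    for t in range(n_pairs):
        place(start_res + t, t * tw, t * rise)                       # strand 1
        place(start_res + total - 1 - t, t * tw + ph, t * rise)      # strand 2
    # loop: semicircular arc past the helix end
    end_ax = (n_pairs - 1) * rise
    a1 = (n_pairs - 1) * tw
    a2 = a1 + ph
    for k in range(loop_len):
        frac = (k + 1) / (loop_len + 1)
        ang = a1 + frac * (a2 - a1)
        ax = end_ax + 6.0 * np.sin(np.pi * frac)
        rad = P_RADIUS
        res[start_res + n_pairs + k] = {
            "phosphate": np.array([ax, rad * np.cos(ang), rad * np.sin(ang)]),
            "sugar": np.array([ax, (rad - 1.3) * np.cos(ang), (rad - 1.3) * np.sin(ang)]),
            "base": np.array([ax, (rad - 4.5) * np.cos(ang), (rad - 4.5) * np.sin(ang)]),
        }
    pairs = [(start_res + t, start_res + total - 1 - t) for t in range(n_pairs)]
    stacks = [(start_res + i, start_res + i + 1) for i in range(total - 1)]
    return res, pairs, stacks, total


def _assemble(parts) -> tuple[CoarseModel, SecondaryStructure]:
    beads: list[Bead] = []
    pairs, stacks = [], []
    nts = "ACGU"
    for res, p, s in parts:
        pairs += p
        stacks += s
        for ridx in sorted(res):
            nt = nts[ridx % 4]
            if ridx > 1:
                beads.append(Bead(ridx, "phosphate", res[ridx]["phosphate"], nt))
            beads.append(Bead(ridx, "sugar", res[ridx]["sugar"], nt))
            beads.append(Bead(ridx, "base", res[ridx]["base"], nt))
    beads.sort(key=lambda b: (b.residue_index, ("phosphate", "sugar", "base").index(b.kind)))
    model = CoarseModel(beads)
    ss = SecondaryStructure(pairs=pairs, stacks=stacks)
    ss.validate_indices(model.n_residues)
    return model, ss


def _rot(axis: str, deg: float) -> np.ndarray:
    a = np.deg2rad(deg)
    c, s = np.cos(a), np.sin(a)
    if axis == "z":
        return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
    if axis == "y":
        return np.array([[c, 0, s], [0, 1.0, 0], [-s, 0, c]])
    return np.array([[1.0, 0, 0], [0, c, -s], [0, s, c]])


def _transform_part(res, rot, shift):
    return {r: {k: rot @ v + shift for k, v in slots.items()}
            for r, slots in res.items()}


def build_toy_rna(spec: SyntheticSpec) -> tuple[CoarseModel, SecondaryStructure]:
    """Idealized toy RNA lying flat (helix axes in the xy plane)."""
    loop = 4
    if spec.topology == "hairpin":
        n_pairs = (spec.n_residues - loop) // 2
        if n_pairs < 2:
            raise ValueError("too few residues for a hairpin")
        res, pairs, stacks, total = _helix_arm(
            n_pairs, spec.helix_rise, spec.helix_twist, 1, loop)
        return _assemble([(res, pairs, stacks)])

    if spec.topology == "two_helix_junction":
        per_arm = (spec.n_residues - 2) // 2
        n_pairs = (per_arm - loop) // 2
        if n_pairs < 2:
            raise ValueError("too few residues for a two-helix junction")
        r1, p1, s1, t1 = _helix_arm(n_pairs, spec.helix_rise, spec.helix_twist, 1, loop)
        r2, p2, s2, t2 = _helix_arm(n_pairs, spec.helix_rise, spec.helix_twist,
                                    t1 + 3, loop)
        r2 = _transform_part(r2, _rot("z", 120.0), np.array([-8.0, 14.0, 0.0]))
        # 2-residue single-strand linker between the arms
        end1 = r1[t1]["sugar"]
        start2 = r2[t1 + 3]["sugar"]
        linker = {}
        for k in range(2):
            frac = (k + 1) / 3
            pos = end1 + frac * (start2 - end1)
            linker[t1 + 1 + k] = {
                "phosphate": pos + np.array([0.0, 0.0, 1.5]),
                "sugar": pos,
                "base": pos + np.array([0.0, 0.0, -1.5]),
            }
        return _assemble([(r1, p1, s1), (linker, [], []), (r2, p2, s2)])

    # three_way
    per_arm = (spec.n_residues - 4) // 3
    n_pairs = (per_arm - loop) // 2
    if n_pairs < 2:
        raise ValueError("too few residues for a three-way junction")
    parts = []
    next_res = 1
    prev_end = None
    for arm, ang in enumerate((0.0, 120.0, 240.0)):
        r, p, s, t = _helix_arm(n_pairs, spec.helix_rise, spec.helix_twist,
                                next_res, loop)
        r = _transform_part(r, _rot("z", ang),
                            18.0 * np.array([np.cos(np.deg2rad(ang + 60)),
                                             np.sin(np.deg2rad(ang + 60)), 0.0]))
        parts.append((r, p, s))
        last = next_res + t - 1
        next_res = last + 1
        if arm < 2:
            nxt = {next_res: {
                "phosphate": r[last]["sugar"] + np.array([2.0, 2.0, 1.5]),
                "sugar": r[last]["sugar"] + np.array([3.0, 3.0, 0.0]),
                "base": r[last]["sugar"] + np.array([3.0, 3.0, -1.5]),
            }}
            parts.append((nxt, [], []))
            next_res += 1
    return _assemble(parts)


# ---------------------------------------------------------------------------
# perturbations with known RMSD
# ---------------------------------------------------------------------------

def perturb_known_rmsd(model: CoarseModel, target_rmsd: float,
                       mode: str = "jitter", seed: int = 0,
                       tol: float = 0.005,
                       ss: SecondaryStructure | None = None) -> CoarseModel:
    """Perturb a model so its Kabsch RMSD to the input hits the target.

    ``jitter`` adds a smooth random displacement field (correlated along
    the chain so the perturbation is not pure white noise); ``hinge``
    rotates the second half of the beads rigidly about a hinge at the
    middle bead.  The perturbation magnitude is scaled in a closed loop
    until the superposed RMSD is within ``tol`` (relative) of the target.
    """
    if target_rmsd <= 0:
        raise ValueError("target RMSD must be positive")
    rng = np.random.default_rng(seed)
    coords0 = model.coords
    n = model.n_beads

    if mode == "jitter":
        raw = rng.normal(size=(n, 3))
        # smooth along the bead chain: moving average window 7
        kernel = np.ones(7) / 7.0
        disp = np.stack([np.convolve(raw[:, d], kernel, mode="same")
                         for d in range(3)], axis=1)
        disp /= np.sqrt(np.mean(np.sum(disp**2, axis=1)))

        def apply(scale):
            return model.with_coords(coords0 + scale * disp)

        scale = target_rmsd
        for _ in range(100):
            cand = apply(scale)
            got = rmsd(cand, model)
            if abs(got - target_rmsd) <= tol * target_rmsd:
                return cand
            if got <= 1e-9:
                scale *= 2.0
                continue
            scale *= target_rmsd / got
        raise RuntimeError("perturbation scaling did not converge")

    if mode == "hinge":
        hinge = n // 2
        pivot = coords0[hinge]
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)

        def apply(angle):
            K = np.array([[0, -axis[2], axis[1]],
                          [axis[2], 0, -axis[0]],
                          [-axis[1], axis[0], 0]])
            R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
            c = coords0.copy()
            c[hinge:] = (c[hinge:] - pivot) @ R.T + pivot
            return model.with_coords(c)

        hi = np.pi
        if rmsd(apply(hi), model) < target_rmsd:
            raise ValueError(
                f"target {target_rmsd} A unreachable by hinge rotation")
        lo = 0.0
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            cand = apply(mid)
            got = rmsd(cand, model)
            if abs(got - target_rmsd) <= tol * target_rmsd:
                return cand
            if got < target_rmsd:
                lo = mid
            else:
                hi = mid
        raise RuntimeError("hinge bisection did not converge")

    raise ValueError(f"unknown perturbation mode {mode!r}")


# ---------------------------------------------------------------------------
# benchmark surfaces and planted trajectories
# ---------------------------------------------------------------------------

def make_benchmark(model: CoarseModel,
                   noise_levels: Sequence[float] = BENCHMARK_NOISE_LEVELS,
                   pixel_size: float = 5.0,
                   tip: TipModel | None = None,
                   seed: int = 0,
                   margin: float = 20.0) -> tuple[AFMSurface, dict[float, AFMSurface]]:
    """Ground-truth pseudo-topograph plus one noisy variant per level
    (defaults: 5-50% of the maximum height)."""
    tip = tip or TipModel()
    gt = synthesize_surface(model, pixel_size=pixel_size, tip=tip, margin=margin)
    noisy = {float(lv): add_gaussian_noise(gt, lv, seed=seed + i)
             for i, lv in enumerate(noise_levels)}
    return gt, noisy


def planted_trajectory(spec: PlantedTrajectorySpec | None = None,
                       ) -> tuple[list[EnergyRecord], np.ndarray]:
    """Synthetic (records, true-RMSD-labels) with a planted linear
    energy-RMSD relation; all ten record fields populated."""
    spec = spec or PlantedTrajectorySpec()
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.rmsd_range
    labels = rng.uniform(lo, hi, size=spec.n_frames)
    comps = {}
    for name, slope in spec.energy_slopes.items():
        noise = spec.noise_sd.get(name, 0.0)
        comps[name] = (spec.energy_intercepts.get(name, 0.0)
                       + slope * labels
                       + (rng.normal(0.0, noise, size=spec.n_frames)
                          if noise > 0 else 0.0))
    cc = spec.cc_map(labels)
    if spec.cc_noise_sd > 0:
        cc = cc + rng.normal(0.0, spec.cc_noise_sd, size=spec.n_frames)
    cc = np.clip(cc, 0.0, 1.0)
    records = [
        EnergyRecord(frame=i + 1, cc_afm=float(cc[i]),
                     **{k: float(v[i]) for k, v in comps.items()})
        for i in range(spec.n_frames)
    ]
    return records, labels
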