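"""Geometry analytics for coarse-grained RNA models.

Kabsch least-squares superposition, RMSD, per-residue RMSF profiles, radius
of gyration and residue dynamic cross-correlation maps (DCCM).  RMSD is
computed over all beads by default; a ``kind`` selection restricts it to a
single bead type (e.g. phosphates), and a residue mask can exclude residues
(useful when a reference structure has unmodelled regions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio.SVDSuperimposer import SVDSuperimposer

from .io_formats import CoarseModel, EnergyRecord

__all__ = [
    "Trajectory",
    "superpose_kabsch",
    "rmsd",
    "rmsf_per_residue",
    "radius_of_gyration",
    "dccm",
]


@dataclass
class Trajectory:
    """Ordered frames (CoarseModel snapshots) with parallel energy records."""

    frames: list[CoarseModel]
    records: list[EnergyRecord] = field(default_factory=list)

    def __post_init__(self):
        if self.frames:
            n = self.frames[0].n_beads
            if any(f.n_beads != n for f in self.frames):
                raise ValueError("all frames must share bead topology")
        if self.records and len(self.records) != len(self.frames):
            raise ValueError("records and frames must be parallel lists")

    def __len__(self) -> int:
        return len(self.frames)

    def coords(self) -> np.ndarray:
        """(n_frames, n_beads, 3) coordinate stack."""
        return np.stack([f.coords for f in self.frames])


def _check_topology(a: CoarseModel, b: CoarseModel) -> None:
    if a.n_beads != b.n_beads:
        raise ValueError("models differ in bead count")
    for ba, bb in zip(a.beads, b.beads):
        if ba.kind != bb.kind or ba.residue_index != bb.residue_index:
            raise ValueError("models differ in bead topology/ordering")


def _selection_mask(model: CoarseModel, kind: str | None,
                    residue_mask: Sequence[int] | None) -> np.ndarray:
    mask = np.ones(model.n_beads, dtype=bool)
    if kind is not None:
        mask &= model.bead_selection(kind)
    if residue_mask is not None:
        keep = set(residue_mask)
        mask &= np.array([b.residue_index in keep for b in model.beads])
    if mask.sum() < 3:
        raise ValueError("need at least 3 beads for superposition")
    return mask


def superpose_kabsch(
    mobile: CoarseModel,
    reference: CoarseModel,
    kind: str | None = None,
    residue_mask: Sequence[int] | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal least-squares superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile.coords @ rotation + translation`` minimises the RMS deviation.
    """
    _check_topology(mobile, reference)
    mask = _selection_mask(mobile, kind, residue_mask)
    sup = SVDSuperimposer()
    sup.set(reference.coords[mask], mobile.coords[mask])
    sup.run()
    rot, tran = sup.get_rotran()
    return rot, tran, float(sup.get_rms())


def rmsd(a: CoarseModel, b: CoarseModel, superpose: bool = True,
         kind: str | None = None,
         residue_mask: Sequence[int] | None = None) -> float:
    """RMSD between two models, after optimal superposition by default."""
    if superpose:
        return superpose_kabsch(a, b, kind=kind, residue_mask=residue_mask)[2]
    _check_topology(a, b)
    mask = _selection_mask(a, kind, residue_mask)
    d = a.coords[mask] - b.coords[mask]
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))


def apply_transform(model: CoarseModel, rotation: np.ndarray,
                    translation: np.ndarray) -> CoarseModel:
    return model.with_coords(model.coords @ rotation + translation)


def rmsf_per_residue(model_a: CoarseModel, model_b: CoarseModel,
                     superpose: bool = False) -> np.ndarray:
    """Per-residue RMS displacement between two models.

    One value per residue: the root-mean-square over that residue's beads of
    the inter-model displacement.  Set ``superpose=True`` to remove the
    optimal rigid transform of ``model_a`` onto ``model_b`` first.
    """
    _check_topology(model_a, model_b)
    if superpose:
        rot, tran, _ = superpose_kabsch(model_a, model_b)
        model_a = apply_transform(model_a, rot, tran)
    d2 = np.sum((model_a.coords - model_b.coords) ** 2, axis=1)
    res = model_a.residue_of_bead()
    out = np.empty(len(model_a.residue_indices))
    for k, idx in enumerate(model_a.residue_indices):
        out[k] = np.sqrt(np.mean(d2[res == idx]))
    return out


def radius_of_gyration(model: CoarseModel, weights: np.ndarray | None = None) -> float:
    """Rg = sqrt(sum w_i |r_i - rbar|^2 / sum w_i); uniform weights by default."""
    coords = model.coords
    if coords.shape[0] == 0:
        raise ValueError("empty model")
    w = np.ones(coords.shape[0]) if weights is None else np.asarray(weights, float)
    if w.shape[0] != coords.shape[0] or np.any(w < 0) or w.sum() <= 0:
        raise ValueError("invalid weights")
    center = np.average(coords, axis=0, weights=w)
    d2 = np.sum((coords - center) ** 2, axis=1)
    return float(np.sqrt(np.average(d2, weights=w)))


def dccm(trajectory: Trajectory) -> np.ndarray:
    """Residue dynamic cross-correlation map over a trajectory.

    C_ij = <dr_i . dr_j> / sqrt(<|dr_i|^2><|dr_j|^2>) over frames, using the
    sugar bead of each residue as the residue representative.  Frames are
    assumed pre-superposed to a common reference.  Zero-variance residues
    yield 0 entries with a warning; the diagonal is set to 1 where variance
    is positive.
    """
    if len(trajectory) < 2:
        raise ValueError("need at least 2 frames")
    first = trajectory.frames[0]
    sugar = first.bead_selection("sugar")
    X = trajectory.coords()[:, sugar, :]          # (m, n_res, 3)
    dX = X - X.mean(axis=0, keepdims=True)
    cov = np.einsum("mik,mjk->ij", dX, dX) / X.shape[0]
    var = np.diag(cov).copy()
    zero = var <= 1e-30
    if np.any(zero):
        warnings.warn(f"{int(zero.sum())} residue(s) with zero variance in DCCM",
                      stacklevel=2)
    denom = np.sqrt(np.outer(var, var))
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0), 0.0)
    np.fill_diagonal(c, np.where(zero, 0.0, 1.0))
    return np.clip(c, -1.0, 1.0)
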