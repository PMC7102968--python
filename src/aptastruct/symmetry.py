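"""Homodimer dyad extraction and nucleic-acid self-correspondence.

The dyad test: a homodimer bound to a monomeric nucleic acid cannot be
globally two-fold symmetric.  To quantify how far the nucleic component is
from respecting the protein dyad, the dimer's two-fold axis is derived from
the protomer-onto-protomer superposition, the nucleic phosphorus atoms are
rotated 180° about that axis, and each rotated phosphorus is matched to its
nearest original counterpart (mutual-nearest filtering).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import StructureModel
from .superpose import protomer_rmsd

__all__ = ["SymmetryAxis", "CorrespondenceRow", "dimer_dyad_axis", "rna_self_correspondence"]


@dataclass
class SymmetryAxis:
    point: np.ndarray        # a point on the axis, Å
    direction: np.ndarray    # unit vector
    angle: float             # degrees, rotation relating the protomers
    screw_translation: float # Å along the axis (0 for a pure rotation)

    def rotate_180(self, coords: np.ndarray) -> np.ndarray:
        """Rotate coordinates 180° about the axis (pure rotation, no screw)."""
        coords = np.asarray(coords, float)
        u = self.direction
        rel = coords - self.point
        # Rodrigues at theta = 180°: R v = 2 u (u.v) - v
        rotated = 2.0 * np.outer(rel @ u, u) - rel
        return rotated + self.point


@dataclass
class CorrespondenceRow:
    nucleotide: tuple[str, int]          # (chain, author number)
    counterpart: tuple[str, int] | None  # mutual-nearest partner, or None
    distance: float | None               # P-P distance after rotation, Å


def dimer_dyad_axis(model: StructureModel, chain_a: str, chain_b: str) -> SymmetryAxis:
    """Two-fold axis from the rotation that superposes one protomer onto the
    other (axis-angle decomposition of the Kabsch rotation).

    The axis point comes from the screw decomposition: the component of the
    superposition translation perpendicular to the axis fixes a point, the
    parallel component is reported as ``screw_translation`` (non-zero for
    real, imperfect dimers).
    """
    fit = protomer_rmsd(model, chain_a, chain_b)
    rot, trans = fit.rotation, fit.translation

    cos_theta = (np.trace(rot) - 1.0) / 2.0
    theta = float(np.degrees(np.arccos(np.clip(cos_theta, -1.0, 1.0))))
    if theta < 90.0:
        raise ValueError(
            f"chains {chain_a}/{chain_b} not related by an approximate dyad "
            f"(rotation angle {theta:.1f}°)"
        )

    # Rotation axis: eigenvector of R for eigenvalue +1.  Near 180° the
    # antisymmetric part vanishes, so use the symmetric construction.
    w, v = np.linalg.eig(rot)
    axis = np.real(v[:, np.argmin(np.abs(w - 1.0))])
    axis /= np.linalg.norm(axis)

    # Screw decomposition: t = t_par + t_perp; a point p on the axis solves
    # (I - R) p = t_perp.
    t_par = float(trans @ axis)
    t_perp = trans - t_par * axis
    point, *_ = np.linalg.lstsq(np.eye(3) - rot, t_perp, rcond=None)

    # Orient the axis deterministically (largest-magnitude component positive).
    lead = np.argmax(np.abs(axis))
    if axis[lead] < 0:
        axis = -axis
        t_par = -t_par
    return SymmetryAxis(point=point, direction=axis, angle=theta, screw_translation=t_par)


def rna_self_correspondence(
    model: StructureModel,
    nucleic_chain: str | Sequence[str],
    axis: SymmetryAxis,
) -> dict:
    """Rotate the nucleic chain's phosphorus atoms 180° about the dyad and map
    each onto its nearest original phosphorus.

    Returns the per-nucleotide correspondence table (sorted by residue
    number), the overall r.m.s.d. over mutual-nearest pairs, and the count of
    mutual pairs.  Distances grow where the nucleic fold departs from the
    protein's two-fold symmetry.
    """
    chain_ids = [nucleic_chain] if isinstance(nucleic_chain, str) else list(nucleic_chain)
    numbers, coords = [], []
    for cid in chain_ids:
        for res in model.chain(cid).residues:
            pos = res.position("P")
            if res.kind == "nucleotide" and pos is not None:
                numbers.append((cid, res.number))
                coords.append(pos)
    if not coords:
        raise ValueError(f"chains {chain_ids} have no phosphorus atoms")
    coords = np.array(coords)
    rotated = axis.rotate_180(coords)

    dmat = np.linalg.norm(rotated[:, None, :] - coords[None, :, :], axis=2)
    nearest = np.argmin(dmat, axis=1)
    nearest_back = np.argmin(dmat, axis=0)

    rows: list[CorrespondenceRow] = []
    mutual_d: list[float] = []
    for i, key in enumerate(numbers):
        j = int(nearest[i])
        d = float(dmat[i, j])
        if int(nearest_back[j]) == i:
            rows.append(CorrespondenceRow(key, numbers[j], d))
            mutual_d.append(d)
        else:
            rows.append(CorrespondenceRow(key, None, d))
    rows.sort(key=lambda r: r.nucleotide)
    rmsd = float(np.sqrt(np.mean(np.square(mutual_d)))) if mutual_d else float("nan")
    return {
        "rows": rows,
        "rmsd": rmsd,
        "n_mutual": len(mutual_d),
        "axis": axis,
    }
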