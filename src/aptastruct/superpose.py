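"""Rigid-body superposition and the domain-anchored r.m.s.d. protocol.

The comparison protocol used throughout: superpose two homodimer models on
the Cα atoms of a conformationally invariant anchor domain (the
effector-binding domains, both protomers pooled), then measure the r.m.s.d.
of a probe domain (the DNA/RNA-reading domains) under that same transform
*without* refitting.  A small anchor r.m.s.d. with a large probe r.m.s.d.
therefore isolates genuine inter-domain rearrangement from global motion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import StructureModel, select_atoms

__all__ = [
    "DomainDefinition", "SuperpositionResult", "RigidTransform",
    "kabsch_superpose", "anchored_domain_rmsd", "inter_residue_distance",
    "protomer_rmsd", "EBD_SEGMENTS", "NBD_SEGMENTS",
]

# Conformationally invariant effector-binding-domain anchor segments of the
# TetR dimer (author numbering, identical in both protomers).
EBD_SEGMENTS: tuple[tuple[int, int], ...] = (
    (48, 66), (73, 103), (108, 129), (131, 137),
    (139, 151), (166, 173), (179, 180), (183, 202),
)

# DNA/RNA-reading domain: everything N-terminal of the first anchor segment
# (helices α1-α3).
NBD_SEGMENTS: tuple[tuple[int, int], ...] = ((2, 47),)


@dataclass(frozen=True)
class DomainDefinition:
    """Named set of inclusive residue-number segments, per protomer."""

    name: str
    segments: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        prev_end = None
        for start, end in self.segments:
            if end < start:
                raise ValueError(f"domain {self.name}: segment {start}-{end} reversed")
            if prev_end is not None and start <= prev_end:
                raise ValueError(f"domain {self.name}: segments overlap or not ascending")
            prev_end = end


EBD = DomainDefinition("EBD", EBD_SEGMENTS)
NBD = DomainDefinition("NBD", NBD_SEGMENTS)


@dataclass
class RigidTransform:
    rotation: np.ndarray      # 3x3, det +1
    translation: np.ndarray   # 3-vector

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


@dataclass
class SuperpositionResult:
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_pairs: int
    per_pair_distances: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def transform(self) -> RigidTransform:
        return RigidTransform(self.rotation, self.translation)


def _check_point_set(x: np.ndarray, label: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3:
        raise ValueError(f"{label}: expected an (n, 3) coordinate array")
    if x.shape[0] < 3:
        raise ValueError(f"{label}: need at least 3 points, got {x.shape[0]}")
    # Degeneracy: all points collinear (or coincident) leaves the rotation
    # underdetermined about the line.
    centered = x - x.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] < 1e-8 * max(s[0], 1.0):
        raise ValueError(f"{label}: degenerate (collinear or coincident) point set")
    return x


def kabsch_superpose(moving: np.ndarray, fixed: np.ndarray) -> SuperpositionResult:
    """Least-squares optimal proper rotation + translation of ``moving`` onto ``fixed``."""
    moving = _check_point_set(moving, "moving")
    fixed = _check_point_set(fixed, "fixed")
    if moving.shape != fixed.shape:
        raise ValueError(f"length mismatch: {moving.shape[0]} vs {fixed.shape[0]} points")

    mc, fc = moving.mean(axis=0), fixed.mean(axis=0)
    h = (moving - mc).T @ (fixed - fc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = fc - rot @ mc
    moved = moving @ rot.T + trans
    dists = np.linalg.norm(moved - fixed, axis=1)
    return SuperpositionResult(
        rotation=rot,
        translation=trans,
        rmsd=float(np.sqrt(np.mean(dists**2))),
        n_pairs=moving.shape[0],
        per_pair_distances=dists,
    )


# ---------------------------------------------------------------------------
# Model-level helpers
# ---------------------------------------------------------------------------

def _domain_pairs(
    model_a: StructureModel,
    model_b: StructureModel,
    chains_a: Sequence[str],
    chains_b: Sequence[str],
    domain: DomainDefinition,
    atom_name: str,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Pooled coordinates of domain atoms modeled in BOTH structures.

    ``chains_a[i]`` is paired with ``chains_b[i]``.  A residue contributes a
    pair only when the requested atom is present in both models (gap
    skipping); the pair count is returned alongside.
    """
    xa, xb = [], []
    for ca, cb in zip(chains_a, chains_b):
        chain_a = model_a.chain(ca)
        chain_b = model_b.chain(cb)
        for start, end in domain.segments:
            for num in range(start, end + 1):
                ra = chain_a.residue(num)
                rb = chain_b.residue(num)
                if ra is None or rb is None:
                    continue
                pa, pb = ra.position(atom_name), rb.position(atom_name)
                if pa is None or pb is None:
                    continue
                xa.append(pa)
                xb.append(pb)
    return np.array(xa), np.array(xb), len(xa)


def _dimer_chain_orders(chains: Sequence[str]) -> list[tuple[str, ...]]:
    if len(chains) == 2:
        return [tuple(chains), (chains[1], chains[0])]
    return [tuple(chains)]


def anchored_domain_rmsd(
    model_a: StructureModel,
    model_b: StructureModel,
    anchor: DomainDefinition = EBD,
    probe: DomainDefinition = NBD,
    chains_a: Sequence[str] = ("A", "B"),
    chains_b: Sequence[str] = ("A", "B"),
    atom_name: str = "CA",
) -> dict:
    """Superpose on the anchor domain, evaluate the probe under that transform.

    Both protomers are pooled for fitting.  For dimers, the chain
    correspondence (parallel vs swapped) minimizing the anchor r.m.s.d. is
    chosen automatically.  The probe r.m.s.d. is computed with NO refit.
    """
    best = None
    for order in _dimer_chain_orders(chains_b):
        xa, xb, n_anchor = _domain_pairs(model_a, model_b, chains_a, order, anchor, atom_name)
        if n_anchor < 3:
            continue
        fit = kabsch_superpose(xa, xb)
        if best is None or fit.rmsd < best[0].rmsd:
            best = (fit, order, n_anchor)
    if best is None:
        raise ValueError("fewer than 3 anchor atom pairs resolvable in both models")
    fit, order, n_anchor = best

    pa, pb, n_probe = _domain_pairs(model_a, model_b, chains_a, order, probe, atom_name)
    if n_probe == 0:
        raise ValueError("probe selection empty in one of the models")
    moved = fit.transform.apply(pa)
    probe_rmsd = float(np.sqrt(np.mean(np.sum((moved - pb) ** 2, axis=1))))
    return {
        "anchor_rmsd": fit.rmsd,
        "probe_rmsd": probe_rmsd,
        "n_anchor_pairs": n_anchor,
        "n_probe_pairs": n_probe,
        "transform": fit.transform,
        "chain_pairing": dict(zip(chains_a, order)),
    }


def inter_residue_distance(
    model_a: StructureModel,
    model_b: StructureModel,
    transform: RigidTransform,
    residue_number: int,
    chains_a: Sequence[str] = ("A", "B"),
    chains_b: Sequence[str] = ("A", "B"),
    atom_name: str = "CA",
) -> float:
    """Distance between the same residue in two superposed models, averaged
    over the two protomer copies of the dimer."""
    dists = []
    for ca, cb in zip(chains_a, chains_b):
        ra = model_a.chain(ca).residue(residue_number)
        rb = model_b.chain(cb).residue(residue_number)
        for res, label in ((ra, f"{ca} of first model"), (rb, f"{cb} of second model")):
            if res is None or res.position(atom_name) is None:
                raise ValueError(
                    f"residue {residue_number} ({atom_name}) missing in chain {label}"
                )
        moved = transform.apply(ra.position(atom_name)[None, :])[0]
        dists.append(float(np.linalg.norm(moved - rb.position(atom_name))))
    return float(np.mean(dists))


def protomer_rmsd(
    model: StructureModel,
    chain_a: str,
    chain_b: str,
    atom_name: str = "CA",
) -> SuperpositionResult:
    """Full Kabsch r.m.s.d. between the two protomers of a homodimer, over
    residues modeled (with the requested atom) in BOTH chains."""
    ca = model.chain(chain_a)
    cb = model.chain(chain_b)
    xa, xb = [], []
    numbers_b = {r.number: r for r in cb.residues}
    for ra in ca.residues:
        rb = numbers_b.get(ra.number)
        if rb is None:
            continue
        pa, pb = ra.position(atom_name), rb.position(atom_name)
        if pa is None or pb is None:
            continue
        xa.append(pa)
        xb.append(pb)
    if len(xa) < 3:
        raise ValueError(
            f"chains {chain_a}/{chain_b} share fewer than 3 residues with {atom_name}"
        )
    return kabsch_superpose(np.array(xa), np.array(xb))
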