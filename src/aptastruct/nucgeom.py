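"""Nucleic-acid geometry annotation.

Backbone torsions (α through ζ), glycosidic conformation (χ, syn/anti),
base-pair detection with Leontis-Westhof edge/orientation classification,
stacking runs with flipped-out base flags, and categorical helix-form calls
from successive base-pair frames.

Edge assignment uses a fixed per-base atom-to-edge table.  Atoms lying on an
edge boundary (e.g. guanine O6, shared by the Watson-Crick and Hoogsteen
edges) carry fractional weight to each family; a pair's edge on each side is
the weighted majority over its hydrogen-bonding atoms, with ties resolved
toward the Watson-Crick edge.  The cis/trans orientation is the sign of the
N(glycosidic)-C1'-C1'-N(glycosidic) pseudo-torsion: within ±90° is cis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import chemistry as chem
from .geometry import dihedral, interplanar_angle, ring_frame
from .interface import (
    DEFAULT_HBOND_MAX_DIST,
    DEFAULT_STACK_MAX_ANGLE,
    DEFAULT_STACK_MAX_DIST,
)
from .model import Chain, Residue, StructureModel

__all__ = [
    "NucleotideGeometry", "BasePair", "StackingRun",
    "backbone_torsions", "glycosidic_classification", "detect_base_pairs",
    "stacking_runs_and_flips", "helix_form", "bases_stack",
]

TORSION_NAMES = ("alpha", "beta", "gamma", "delta", "epsilon", "zeta", "chi")


@dataclass
class NucleotideGeometry:
    chain_id: str
    number: int
    name: str
    alpha: float | None = None
    beta: float | None = None
    gamma: float | None = None
    delta: float | None = None
    epsilon: float | None = None
    zeta: float | None = None
    chi: float | None = None

    @property
    def glycosidic_class(self) -> str:
        if self.chi is None:
            return "unclassified"
        return "syn" if -90.0 <= self.chi <= 90.0 else "anti"


@dataclass
class BasePair:
    chain_i: str
    number_i: int
    name_i: str
    chain_j: str
    number_j: int
    name_j: str
    edge_i: str
    edge_j: str
    orientation: str            # "cis" | "trans"
    n_hbonds: int
    hbond_atoms: list[tuple[str, str]]   # (atom on i, atom on j)
    interplanar_angle: float

    @property
    def canonical(self) -> bool:
        if self.edge_i != chem.WC or self.edge_j != chem.WC or self.orientation != "cis":
            return False
        bi, bj = chem.base_letter(self.name_i), chem.base_letter(self.name_j)
        return bj in chem.WC_COMPLEMENT.get(bi, set()) and not self.wobble

    @property
    def wobble(self) -> bool:
        pair = {chem.base_letter(self.name_i), chem.base_letter(self.name_j)}
        return pair == {"G", "U"} or pair == {"G", "T"}

    @property
    def label(self) -> str:
        ori = self.orientation
        return f"{self.name_i}{self.number_i}:{self.name_j}{self.number_j} {ori} {self.edge_i}/{self.edge_j}"


@dataclass
class StackingRun:
    chain_id: str
    numbers: list[int]

    def __len__(self) -> int:
        return len(self.numbers)


# ---------------------------------------------------------------------------
# Torsions
# ---------------------------------------------------------------------------

def _nucleotides(chain: Chain) -> list[Residue]:
    return [r for r in chain.residues if r.kind == "nucleotide"]


def _tors(*positions) -> float | None:
    if any(p is None for p in positions):
        return None
    return dihedral(*positions)


def backbone_torsions(chain: Chain) -> list[NucleotideGeometry]:
    """Standard α/β/γ/δ/ε/ζ/χ torsions per nucleotide of one chain.

    A torsion is ``None`` when any defining atom is missing, including the
    case where the 5'- or 3'-neighbor nucleotide (by author number ± 1) is
    not modeled.
    """
    residues = _nucleotides(chain)
    by_number = {r.number: r for r in residues}
    out: list[NucleotideGeometry] = []
    for res in residues:
        prev = by_number.get(res.number - 1)
        nxt = by_number.get(res.number + 1)
        p = res.position
        o3_prev = prev.position("O3'") if prev is not None else None
        p_next = nxt.position("P") if nxt is not None else None
        o5_next = nxt.position("O5'") if nxt is not None else None

        base = chem.base_letter(res.name)
        n_gly = p(chem.GLYCOSIDIC_N[base])
        chi_base = p(chem.CHI_BASE_ATOM[base])

        out.append(NucleotideGeometry(
            chain_id=res.chain_id, number=res.number, name=res.name,
            alpha=_tors(o3_prev, p("P"), p("O5'"), p("C5'")),
            beta=_tors(p("P"), p("O5'"), p("C5'"), p("C4'")),
            gamma=_tors(p("O5'"), p("C5'"), p("C4'"), p("C3'")),
            delta=_tors(p("C5'"), p("C4'"), p("C3'"), p("O3'")),
            epsilon=_tors(p("C4'"), p("C3'"), p("O3'"), p_next),
            zeta=_tors(p("C3'"), p("O3'"), p_next, o5_next),
            chi=_tors(p("O4'"), p("C1'"), n_gly, chi_base),
        ))
    return out


def glycosidic_classification(chain: Chain) -> dict[int, str]:
    """anti/syn/unclassified per nucleotide (syn for χ in [-90°, +90°])."""
    return {g.number: g.glycosidic_class for g in backbone_torsions(chain)}


# ---------------------------------------------------------------------------
# Base pairs
# ---------------------------------------------------------------------------

def _edge_atoms(res: Residue) -> dict[str, tuple[str, ...]]:
    table = chem.EDGE_MEMBERSHIP[chem.base_letter(res.name)]
    if res.name.upper() in chem.DEOXYNUCLEOTIDES:   # no 2'-hydroxyl
        table = {k: v for k, v in table.items() if k != "O2'"}
    return table


def _inter_base_hbonds(
    ri: Residue, rj: Residue, max_dist: float
) -> list[tuple[str, str, float]]:
    """Donor-acceptor contacts between the edge atoms of two nucleotides."""
    donors_i, acceptors_i = chem.donor_map(ri.name), chem.acceptor_set(ri.name)
    donors_j, acceptors_j = chem.donor_map(rj.name), chem.acceptor_set(rj.name)
    edges_i, edges_j = _edge_atoms(ri), _edge_atoms(rj)
    hits: list[tuple[str, str, float]] = []
    for ai in edges_i:
        pi = ri.position(ai)
        if pi is None:
            continue
        for aj in edges_j:
            pj = rj.position(aj)
            if pj is None:
                continue
            donor_ok = (ai in donors_i and aj in acceptors_j) or \
                       (aj in donors_j and ai in acceptors_i)
            if not donor_ok:
                continue
            d = float(np.linalg.norm(pi - pj))
            if 2.0 <= d <= max_dist:
                hits.append((ai, aj, d))
    return hits


def _edge_vote(base: str, atoms: Sequence[str]) -> str:
    weights = {chem.WC: 0.0, chem.HOOGSTEEN: 0.0, chem.SUGAR: 0.0}
    table = chem.EDGE_MEMBERSHIP[base]
    for a in atoms:
        memberships = table.get(a)
        if not memberships:
            continue
        w = 1.0 / len(memberships)
        for e in memberships:
            weights[e] += w
    # ties resolved toward the Watson-Crick edge, then Hoogsteen
    order = (chem.WC, chem.HOOGSTEEN, chem.SUGAR)
    return max(order, key=lambda e: (weights[e], -order.index(e)))


def _pair_orientation(ri: Residue, rj: Residue) -> str | None:
    bi, bj = chem.base_letter(ri.name), chem.base_letter(rj.name)
    ni = ri.position(chem.GLYCOSIDIC_N[bi])
    nj = rj.position(chem.GLYCOSIDIC_N[bj])
    c1i, c1j = ri.position("C1'"), rj.position("C1'")
    if any(x is None for x in (ni, nj, c1i, c1j)):
        return None
    tau = dihedral(ni, c1i, c1j, nj)
    return "cis" if abs(tau) <= 90.0 else "trans"


def _base_frame(res: Residue) -> tuple[np.ndarray, np.ndarray] | None:
    names = chem.BASE_ATOMS[chem.base_letter(res.name)]
    coords = [res.position(n) for n in names]
    coords = [c for c in coords if c is not None]
    if len(coords) < 4:
        return None
    return ring_frame(np.array(coords))


def detect_base_pairs(
    model: StructureModel,
    chains: Sequence[str],
    max_hbond_dist: float = DEFAULT_HBOND_MAX_DIST,
    max_plane_angle: float = 45.0,
) -> list[BasePair]:
    """Base pairs across (and within) the given nucleic chains.

    Candidates need >= 2 inter-base hydrogen bonds and base interplanar angle
    <= ``max_plane_angle``; every nucleotide joins at most one pair (best
    candidate first).  Pairs are reported once, lower (chain, number) first.
    """
    residues: list[Residue] = []
    for cid in chains:
        residues.extend(_nucleotides(model.chain(cid)))

    candidates = []
    for idx_i in range(len(residues)):
        for idx_j in range(idx_i + 1, len(residues)):
            ri, rj = residues[idx_i], residues[idx_j]
            if ri.chain_id == rj.chain_id and abs(ri.number - rj.number) < 2:
                continue
            fi, fj = _base_frame(ri), _base_frame(rj)
            if fi is None or fj is None:
                continue
            if float(np.linalg.norm(fi[0] - fj[0])) > 12.0:
                continue
            plane_ang = interplanar_angle(fi[1], fj[1])
            if plane_ang > max_plane_angle:
                continue
            hbonds = _inter_base_hbonds(ri, rj, max_hbond_dist)
            if len(hbonds) < 2:
                continue
            orientation = _pair_orientation(ri, rj)
            if orientation is None:
                continue
            mean_d = float(np.mean([d for _, _, d in hbonds]))
            candidates.append((len(hbonds), -mean_d, idx_i, idx_j, hbonds, plane_ang, orientation))

    candidates.sort(key=lambda c: (-c[0], -c[1], c[2], c[3]))
    used: set[int] = set()
    pairs: list[BasePair] = []
    for _, _, idx_i, idx_j, hbonds, plane_ang, orientation in candidates:
        if idx_i in used or idx_j in used:
            continue
        used.update((idx_i, idx_j))
        ri, rj = residues[idx_i], residues[idx_j]
        pairs.append(BasePair(
            chain_i=ri.chain_id, number_i=ri.number, name_i=ri.name,
            chain_j=rj.chain_id, number_j=rj.number, name_j=rj.name,
            edge_i=_edge_vote(chem.base_letter(ri.name), [a for a, _, _ in hbonds]),
            edge_j=_edge_vote(chem.base_letter(rj.name), [a for _, a, _ in hbonds]),
            orientation=orientation,
            n_hbonds=len(hbonds),
            hbond_atoms=[(a, b) for a, b, _ in hbonds],
            interplanar_angle=plane_ang,
        ))
    pairs.sort(key=lambda p: (p.chain_i, p.number_i))
    return pairs


# ---------------------------------------------------------------------------
# Stacking
# ---------------------------------------------------------------------------

def _base_rings(res: Residue) -> list[tuple[np.ndarray, np.ndarray]]:
    rings = []
    for names in chem.BASE_RINGS[chem.base_letter(res.name)]:
        coords = res.positions(names)
        if coords is not None:
            rings.append(ring_frame(coords))
    return rings


def bases_stack(
    ri: Residue,
    rj: Residue,
    max_dist: float = DEFAULT_STACK_MAX_DIST,
    max_angle: float = DEFAULT_STACK_MAX_ANGLE,
) -> bool:
    """Stacking gate: any ring pair with centroid distance and interplanar
    angle inside the thresholds."""
    for ci, ni in _base_rings(ri):
        for cj, nj in _base_rings(rj):
            if (np.linalg.norm(ci - cj) <= max_dist
                    and interplanar_angle(ni, nj) <= max_angle):
                return True
    return False


def stacking_runs_and_flips(
    chain: Chain,
    max_dist: float = DEFAULT_STACK_MAX_DIST,
    max_angle: float = DEFAULT_STACK_MAX_ANGLE,
) -> tuple[list[StackingRun], dict[int, bool]]:
    """Maximal runs of sequentially stacked nucleotides, plus flipped-out flags.

    A nucleotide is flipped out when both sequential neighbors (author number
    ± 1) are modeled yet it stacks with neither.
    """
    residues = _nucleotides(chain)
    by_number = {r.number: r for r in residues}
    numbers = sorted(by_number)

    stacked_next: dict[int, bool] = {}
    for num in numbers:
        nxt = by_number.get(num + 1)
        if nxt is not None:
            stacked_next[num] = bases_stack(by_number[num], nxt, max_dist, max_angle)

    runs: list[StackingRun] = []
    current: list[int] = []
    for num in numbers:
        if not current:
            current = [num]
        if stacked_next.get(num) and (num + 1) in by_number:
            current.append(num + 1)
        else:
            if len(current) >= 2:
                runs.append(StackingRun(chain.chain_id, current))
            current = []

    flipped: dict[int, bool] = {}
    for num in numbers:
        has_prev = (num - 1) in by_number
        has_next = (num + 1) in by_number
        if not (has_prev and has_next):
            flipped[num] = False
            continue
        flipped[num] = not stacked_next.get(num - 1, False) and not stacked_next.get(num, False)
    return runs, flipped


# ---------------------------------------------------------------------------
# Helix form
# ---------------------------------------------------------------------------

A_FORM_RISE = (2.3, 3.1)
A_FORM_TWIST = (30.0, 34.0)
B_FORM_RISE = (3.1, 3.6)
B_FORM_TWIST = (34.0, 38.0)


def _pair_frame(model: StructureModel, pair: BasePair) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(origin, x-axis, normal) of a base-pair frame: origin at the C1'-C1'
    midpoint, x along C1'(i) -> C1'(j), normal the mean base-plane normal."""
    ri = model.chain(pair.chain_i).residue(pair.number_i)
    rj = model.chain(pair.chain_j).residue(pair.number_j)
    c1i, c1j = ri.position("C1'"), rj.position("C1'")
    if c1i is None or c1j is None:
        raise ValueError(f"pair {pair.label}: C1' atoms missing")
    fi, fj = _base_frame(ri), _base_frame(rj)
    ni, nj = fi[1], fj[1]
    if ni @ nj < 0:
        nj = -nj
    normal = ni + nj
    normal /= np.linalg.norm(normal)
    x = c1j - c1i
    x /= np.linalg.norm(x)
    return (c1i + c1j) / 2.0, x, normal


def helix_form(model: StructureModel, pairs: Sequence[BasePair]) -> dict:
    """Categorical A/B/irregular call from mean rise and twist of successive
    base-pair frames.  Needs >= 3 consecutive pairs in stem order."""
    if len(pairs) < 3:
        raise ValueError("helix form needs at least 3 consecutive base pairs")
    frames = [_pair_frame(model, p) for p in pairs]
    rises, twists = [], []
    for (o1, x1, n1), (o2, x2, n2) in zip(frames, frames[1:]):
        if n1 @ n2 < 0:
            n2 = -n2
        z = n1 + n2
        z /= np.linalg.norm(z)
        rises.append(abs(float((o2 - o1) @ z)))
        a1 = x1 - (x1 @ z) * z
        a2 = x2 - (x2 @ z) * z
        a1 /= np.linalg.norm(a1)
        a2 /= np.linalg.norm(a2)
        tw = np.degrees(np.arctan2(float(np.cross(a1, a2) @ z), float(a1 @ a2)))
        twists.append(abs(float(tw)))
    rise, twist = float(np.mean(rises)), float(np.mean(twists))
    if A_FORM_RISE[0] <= rise <= A_FORM_RISE[1] and A_FORM_TWIST[0] <= twist <= A_FORM_TWIST[1]:
        form = "A"
    elif B_FORM_RISE[0] <= rise <= B_FORM_RISE[1] and B_FORM_TWIST[0] <= twist <= B_FORM_TWIST[1]:
        form = "B"
    else:
        form = "irregular"
    return {"form": form, "mean_rise": rise, "mean_twist": twist, "n_steps": len(rises)}
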