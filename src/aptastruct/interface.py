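"""Protein-nucleic-acid interface census and typing.

Four layers, each independently configurable:

* distance-cutoff contact census (default 3.7 Å, heavy atoms);
* buried solvent-accessible surface area, decomposed per protein domain
  (Shrake-Rupley numerical SASA, Bondi radii, deterministic sphere points);
* heavy-atom hydrogen-bond detection (donor-acceptor <= 3.5 Å, antecedent
  angle >= 90° where the antecedent is modeled);
* ring interactions: π-π stacking (ring-centroid distance <= 4.5 Å,
  interplanar angle <= 30°) and cation-π (cation centroid <= 6.0 Å from the
  ring centroid and within 45° of the ring normal).

The hydrogen-bond and ring thresholds are permissive literature values for
hydrogen-free crystallographic models; every hit carries its raw geometric
parameters so results can be re-gated without recomputation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from . import chemistry as chem
from .geometry import angle, interplanar_angle, ring_frame
from .model import Residue, StructureModel

__all__ = [
    "Contact", "ContactCensus", "HydrogenBond", "RingInteraction",
    "InterfaceSummary", "find_contact_residues", "shrake_rupley_sasa",
    "solvent_accessible_area", "buried_area_decomposition",
    "detect_hydrogen_bonds", "detect_ring_interactions", "analyze_interface",
]

DEFAULT_CONTACT_CUTOFF = 3.7     # Å
DEFAULT_HBOND_MAX_DIST = 3.5     # Å, donor-acceptor heavy atoms
DEFAULT_HBOND_MIN_ANGLE = 90.0   # degrees, antecedent-donor-acceptor
DEFAULT_STACK_MAX_DIST = 4.5     # Å, ring centroid-centroid
DEFAULT_STACK_MAX_ANGLE = 30.0   # degrees, interplanar
DEFAULT_CATION_PI_MAX_DIST = 6.0   # Å, cation centroid to ring centroid
DEFAULT_CATION_PI_MAX_ANGLE = 45.0  # degrees from ring normal
DEFAULT_PROBE_RADIUS = 1.4       # Å
DEFAULT_SPHERE_POINTS = 960


AtomRef = tuple[str, int, str]   # chain, residue number, atom name


@dataclass
class Contact:
    protein_atom: AtomRef
    nucleic_atom: AtomRef
    distance: float
    type: str = "generic"


@dataclass
class ContactCensus:
    contacts: list[Contact]
    residues_per_chain: dict[str, list[int]]
    cutoff: float

    @property
    def n_residues(self) -> int:
        return sum(len(v) for v in self.residues_per_chain.values())


@dataclass
class HydrogenBond:
    donor: AtomRef
    acceptor: AtomRef
    distance: float
    antecedent_angle: float | None

    @property
    def residue_pair(self) -> tuple[tuple[str, int], tuple[str, int]]:
        return ((self.donor[0], self.donor[1]), (self.acceptor[0], self.acceptor[1]))


@dataclass
class RingInteraction:
    kind: str                    # "stacking" | "cation_pi"
    residue_a: tuple[str, int, str]   # chain, number, residue name
    residue_b: tuple[str, int, str]
    centroid_distance: float
    angle: float                 # interplanar (stacking) or off-normal (cation-pi)


@dataclass
class InterfaceSummary:
    census: ContactCensus
    per_domain_buried: dict[str, float]
    total_buried: float
    hydrogen_bonds: list[HydrogenBond]
    ring_interactions: list[RingInteraction]
    thresholds: dict = field(default_factory=dict)

    def schematic(self) -> list[dict]:
        """Nucplot-style edge list: one typed edge per residue/nucleotide link."""
        edges: dict[tuple, dict] = {}
        for hb in self.hydrogen_bonds:
            key = (hb.residue_pair, "hbond")
            e = edges.setdefault(key, {
                "protein_residue": list(hb.residue_pair[0]),
                "nucleotide": list(hb.residue_pair[1]),
                "type": "hbond", "count": 0, "min_distance": np.inf,
            })
            e["count"] += 1
            e["min_distance"] = min(e["min_distance"], hb.distance)
        hbonded = {k[0] for k in edges}
        for c in self.census.contacts:
            pair = ((c.protein_atom[0], c.protein_atom[1]),
                    (c.nucleic_atom[0], c.nucleic_atom[1]))
            if pair in hbonded:
                continue
            key = (pair, "vdw")
            e = edges.setdefault(key, {
                "protein_residue": list(pair[0]), "nucleotide": list(pair[1]),
                "type": "vdw", "count": 0, "min_distance": np.inf,
            })
            e["count"] += 1
            e["min_distance"] = min(e["min_distance"], c.distance)
        out = list(edges.values())
        for e in out:
            e["min_distance"] = round(float(e["min_distance"]), 2)
        return sorted(out, key=lambda e: (e["protein_residue"], e["nucleotide"]))


# ---------------------------------------------------------------------------
# Atom collection helpers
# ---------------------------------------------------------------------------

def _collect(
    model: StructureModel,
    chains: Sequence[str],
    include_hydrogens: bool = False,
    include_hetero: bool = False,
) -> tuple[list[tuple[Residue, int]], np.ndarray]:
    """(residue, atom-index) pairs and stacked coordinates for a chain group.

    Waters and non-polymer residues are excluded unless ``include_hetero``.
    """
    refs: list[tuple[Residue, int]] = []
    coords: list[np.ndarray] = []
    for cid in chains:
        for res in model.chain(cid).residues:
            if res.kind == "other" and not include_hetero:
                continue
            for i, atom in enumerate(res.atoms):
                if atom.element == "H" and not include_hydrogens:
                    continue
                refs.append((res, i))
                coords.append(atom.position)
    return refs, np.array(coords) if coords else np.empty((0, 3))


# ---------------------------------------------------------------------------
# Contact census
# ---------------------------------------------------------------------------

def find_contact_residues(
    model: StructureModel,
    protein_chains: Sequence[str],
    nucleic_chains: Sequence[str],
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    include_hydrogens: bool = False,
) -> ContactCensus:
    """Protein residues with ANY atom within ``cutoff`` of ANY nucleic atom.

    Returns the per-chain residue lists and the full atom-pair contact list.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    prefs, pcoords = _collect(model, protein_chains, include_hydrogens)
    nrefs, ncoords = _collect(model, nucleic_chains, include_hydrogens)
    if len(prefs) == 0 or len(nrefs) == 0:
        raise ValueError("empty protein or nucleic selection")

    tree = cKDTree(ncoords)
    pairs = tree.query_ball_point(pcoords, r=cutoff)
    contacts: list[Contact] = []
    per_chain: dict[str, set[int]] = {c: set() for c in protein_chains}
    for ip, neighbors in enumerate(pairs):
        pres, pai = prefs[ip]
        for jn in neighbors:
            nres, nai = nrefs[jn]
            d = float(np.linalg.norm(pcoords[ip] - ncoords[jn]))
            contacts.append(Contact(
                protein_atom=(pres.chain_id, pres.number, pres.atoms[pai].name),
                nucleic_atom=(nres.chain_id, nres.number, nres.atoms[nai].name),
                distance=d,
            ))
            per_chain[pres.chain_id].add(pres.number)
    return ContactCensus(
        contacts=contacts,
        residues_per_chain={c: sorted(v) for c, v in per_chain.items()},
        cutoff=cutoff,
    )


# ---------------------------------------------------------------------------
# Solvent-accessible surface area (Shrake-Rupley)
# ---------------------------------------------------------------------------

def _golden_spiral(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    return np.column_stack([
        np.cos(theta) * np.sin(phi),
        np.sin(theta) * np.sin(phi),
        np.cos(phi),
    ])


def shrake_rupley_sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_SPHERE_POINTS,
) -> np.ndarray:
    """Per-atom solvent-accessible area (Å²) by numerical sphere sampling."""
    coords = np.asarray(coords, float)
    radii = np.asarray(radii, float) + probe_radius
    n = coords.shape[0]
    sphere = _golden_spiral(n_points)
    areas = np.zeros(n)
    tree = cKDTree(coords)
    max_r = radii.max()
    for i in range(n):
        pts = coords[i] + radii[i] * sphere
        neighbors = [j for j in tree.query_ball_point(coords[i], radii[i] + max_r) if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 > radii[j] ** 2
        areas[i] = 4.0 * np.pi * radii[i] ** 2 * accessible.mean()
    return areas


def solvent_accessible_area(
    model: StructureModel,
    chains: Sequence[str] | None = None,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_SPHERE_POINTS,
    include_hydrogens: bool = False,
) -> dict[AtomRef, float]:
    """Per-atom SASA map for the selected chains (heavy atoms by default)."""
    chains = chains or model.chain_ids
    refs, coords = _collect(model, chains, include_hydrogens)
    if len(refs) == 0:
        raise ValueError("no atoms selected for SASA")
    radii = np.array([chem.vdw_radius(res.atoms[i].element) for res, i in refs])
    areas = shrake_rupley_sasa(coords, radii, probe_radius, n_points)
    return {
        (res.chain_id, res.number, res.atoms[i].name): float(a)
        for (res, i), a in zip(refs, areas)
    }


def _domain_atom_keys(
    model: StructureModel,
    domains: dict[str, tuple[str, Sequence[tuple[int, int]]]],
) -> dict[str, set[AtomRef]]:
    keyed: dict[str, set[AtomRef]] = {}
    claimed: dict[tuple[str, int], str] = {}
    for name, (chain_id, segments) in domains.items():
        atoms: set[AtomRef] = set()
        for res in model.chain(chain_id).residues:
            if any(lo <= res.number <= hi for lo, hi in segments):
                prev = claimed.get((chain_id, res.number))
                if prev is not None and prev != name:
                    raise ValueError(
                        f"domains {prev!r} and {name!r} overlap at {chain_id}:{res.number}"
                    )
                claimed[(chain_id, res.number)] = name
                atoms.update((res.chain_id, res.number, a.name) for a in res.atoms)
        keyed[name] = atoms
    return keyed


def buried_area_decomposition(
    model: StructureModel,
    protein_chains: Sequence[str],
    nucleic_chains: Sequence[str],
    domains: dict[str, tuple[str, Sequence[tuple[int, int]]]] | None = None,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_SPHERE_POINTS,
) -> dict:
    """Protein surface buried by the nucleic component, split by domain.

    Buried area of a domain = SASA of its atoms in the free protein minus
    SASA of the same atoms in the complex.  ``domains`` maps a name to
    (chain id, residue segments); default is one domain per protein chain.
    """
    if domains is None:
        domains = {f"chain_{c}": (c, [(-(10**6), 10**6)]) for c in protein_chains}
    free = solvent_accessible_area(model, protein_chains, probe_radius, n_points)
    both = solvent_accessible_area(
        model, list(protein_chains) + list(nucleic_chains), probe_radius, n_points
    )
    keyed = _domain_atom_keys(model, domains)
    per_domain = {}
    for name, keys in keyed.items():
        per_domain[name] = float(sum(free[k] - both[k] for k in keys if k in free))
    return {
        "per_domain": per_domain,
        "total": float(sum(per_domain.values())),
        "probe_radius": probe_radius,
        "n_points": n_points,
    }


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------

def _residues_of(model: StructureModel, chains: Sequence[str]) -> list[Residue]:
    out = []
    for cid in chains:
        out.extend(r for r in model.chain(cid).residues if r.kind != "other")
    return out


def _hbond_candidates(res: Residue) -> tuple[dict[str, str], set[str]]:
    return chem.donor_map(res.name), chem.acceptor_set(res.name)


def detect_hydrogen_bonds(
    model: StructureModel,
    chains_a: Sequence[str],
    chains_b: Sequence[str],
    max_distance: float = DEFAULT_HBOND_MAX_DIST,
    min_angle: float = DEFAULT_HBOND_MIN_ANGLE,
) -> list[HydrogenBond]:
    """Heavy-atom hydrogen bonds between two chain groups (both directions).

    A donor-acceptor pair is reported when the distance is <= ``max_distance``
    and, whenever the donor's antecedent atom is modeled, the
    antecedent-donor-acceptor angle is >= ``min_angle``.
    """
    group_a = _residues_of(model, chains_a)
    group_b = _residues_of(model, chains_b)
    bonds: list[HydrogenBond] = []
    for donors, acceptors in ((group_a, group_b), (group_b, group_a)):
        for dres in donors:
            dmap, _ = _hbond_candidates(dres)
            for datom_name, antecedent in dmap.items():
                dpos = dres.position(datom_name)
                if dpos is None:
                    continue
                apos_ante = dres.position(antecedent)
                for ares in acceptors:
                    _, acc = _hbond_candidates(ares)
                    for aatom_name in acc:
                        apos = ares.position(aatom_name)
                        if apos is None:
                            continue
                        d = float(np.linalg.norm(dpos - apos))
                        if d > max_distance or d < 0.5:
                            continue
                        ang = None
                        if apos_ante is not None:
                            ang = angle(apos_ante, dpos, apos)
                            if ang < min_angle:
                                continue
                        bonds.append(HydrogenBond(
                            donor=(dres.chain_id, dres.number, datom_name),
                            acceptor=(ares.chain_id, ares.number, aatom_name),
                            distance=d,
                            antecedent_angle=ang,
                        ))
    bonds.sort(key=lambda b: (b.donor, b.acceptor))
    return bonds


def group_bidentate(bonds: Iterable[HydrogenBond]) -> dict[tuple, list[HydrogenBond]]:
    """Group hydrogen bonds by (donor residue, acceptor residue) pair."""
    grouped: dict[tuple, list[HydrogenBond]] = {}
    for b in bonds:
        grouped.setdefault(b.residue_pair, []).append(b)
    return grouped


# ---------------------------------------------------------------------------
# Ring interactions
# ---------------------------------------------------------------------------

def _rings_of(res: Residue) -> list[tuple[np.ndarray, np.ndarray]]:
    """(centroid, normal) for every aromatic ring of a residue."""
    if res.kind == "amino_acid":
        defs = chem.PROTEIN_RINGS.get(res.name.upper(), [])
    elif res.kind == "nucleotide":
        defs = chem.BASE_RINGS[chem.base_letter(res.name)]
    else:
        return []
    rings = []
    for names in defs:
        coords = res.positions(names)
        if coords is not None:
            rings.append(ring_frame(coords))
    return rings


def _cations_of(res: Residue) -> list[np.ndarray]:
    names = chem.CATION_GROUPS.get(res.name.upper())
    if not names:
        return []
    coords = res.positions(names)
    return [] if coords is None else [coords.mean(axis=0)]


def detect_ring_interactions(
    model: StructureModel,
    chains_a: Sequence[str],
    chains_b: Sequence[str],
    stack_max_dist: float = DEFAULT_STACK_MAX_DIST,
    stack_max_angle: float = DEFAULT_STACK_MAX_ANGLE,
    cation_max_dist: float = DEFAULT_CATION_PI_MAX_DIST,
    cation_max_angle: float = DEFAULT_CATION_PI_MAX_ANGLE,
) -> list[RingInteraction]:
    """π-π stacking and cation-π interactions between two chain groups."""
    group_a = _residues_of(model, chains_a)
    group_b = _residues_of(model, chains_b)
    hits: list[RingInteraction] = []

    for ra in group_a:
        rings_a = _rings_of(ra)
        cations_a = _cations_of(ra)
        for rb in group_b:
            rings_b = _rings_of(rb)
            best = None
            for ca_, na in rings_a:
                for cb_, nb in rings_b:
                    d = float(np.linalg.norm(ca_ - cb_))
                    ang = interplanar_angle(na, nb)
                    if d <= stack_max_dist and ang <= stack_max_angle:
                        if best is None or d < best[0]:
                            best = (d, ang)
            if best is not None:
                hits.append(RingInteraction(
                    "stacking",
                    (ra.chain_id, ra.number, ra.name),
                    (rb.chain_id, rb.number, rb.name),
                    best[0], best[1],
                ))
            for cation_pos, (centroid, normal), (res_c, res_r) in (
                [(c, r, (ra, rb)) for c in cations_a for r in rings_b]
                + [(c, r, (rb, ra)) for c in _cations_of(rb) for r in rings_a]
            ):
                d = float(np.linalg.norm(cation_pos - centroid))
                if d > cation_max_dist or d < 0.5:
                    continue
                v = (cation_pos - centroid) / d
                off_normal = interplanar_angle(v, normal)
                # interplanar_angle returns the acute angle to the normal
                if off_normal <= cation_max_angle:
                    hits.append(RingInteraction(
                        "cation_pi",
                        (res_c.chain_id, res_c.number, res_c.name),
                        (res_r.chain_id, res_r.number, res_r.name),
                        d, off_normal,
                    ))
    # deduplicate cation-pi hits discovered twice (inner double loop)
    seen = set()
    unique = []
    for h in hits:
        key = (h.kind, h.residue_a, h.residue_b, round(h.centroid_distance, 6))
        if key not in seen:
            seen.add(key)
            unique.append(h)
    return unique


# ---------------------------------------------------------------------------
# Full interface summary
# ---------------------------------------------------------------------------

def analyze_interface(
    model: StructureModel,
    protein_chains: Sequence[str],
    nucleic_chains: Sequence[str],
    domains: dict[str, tuple[str, Sequence[tuple[int, int]]]] | None = None,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_SPHERE_POINTS,
) -> InterfaceSummary:
    census = find_contact_residues(model, protein_chains, nucleic_chains, cutoff)
    buried = buried_area_decomposition(
        model, protein_chains, nucleic_chains, domains, probe_radius, n_points
    )
    hbonds = detect_hydrogen_bonds(model, protein_chains, nucleic_chains)
    rings = detect_ring_interactions(model, protein_chains, nucleic_chains)
    return InterfaceSummary(
        census=census,
        per_domain_buried=buried["per_domain"],
        total_buried=buried["total"],
        hydrogen_bonds=hbonds,
        ring_interactions=rings,
        thresholds={
            "contact_cutoff": cutoff,
            "hbond_max_distance": DEFAULT_HBOND_MAX_DIST,
            "hbond_min_angle": DEFAULT_HBOND_MIN_ANGLE,
            "stack_max_distance": DEFAULT_STACK_MAX_DIST,
            "stack_max_angle": DEFAULT_STACK_MAX_ANGLE,
            "cation_pi_max_distance": DEFAULT_CATION_PI_MAX_DIST,
            "cation_pi_max_angle": DEFAULT_CATION_PI_MAX_ANGLE,
            "sasa_probe_radius": probe_radius,
            "sasa_points": n_points,
        },
    )
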