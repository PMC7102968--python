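"""Synthetic structure generators for testing and calibration.

Emulates, without any external coordinate files, the geometric situations the
analysis modules must handle:

* idealized A-form / B-form nucleic-acid duplexes and single strands with
  prescribed rise and twist;
* arbitrary two-base pairings built to explicit hydrogen-bond targets, for
  exercising the edge/orientation classifier on every Leontis-Westhof class;
* a C2-symmetric two-chain mini-protein bound to a nucleic component either
  symmetrically (operator-DNA-like) or asymmetrically (monomeric aptamer-like);
* seeded Gaussian coordinate noise.

Idealized nucleotide and amino-acid geometry comes from the Chemical
Component Dictionary shipped with biotite (queried at run time); base-pair
geometry is solved in-plane by least squares against 2.9 Å hydrogen-bond
targets with a soft anti-clash penalty.  All generators are deterministic
for fixed inputs.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import biotite.structure.info as bsinfo
import numpy as np
from scipy import optimize

from . import chemistry as chem
from .geometry import dihedral, plane_normal
from .model import Atom, Chain, Residue, StructureModel

__all__ = [
    "HelixSpec", "ToyComplexSpec", "build_helix", "build_base_pair",
    "build_c2_complex", "perturb", "transformed", "WC_PAIR_BONDS",
]

HELIX_DEFAULTS = {"A": (2.81, 32.7), "B": (3.38, 36.0)}   # rise Å, twist deg

COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G", "T": "A"}
DNA_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}

# Canonical Watson-Crick hydrogen-bond atom pairs (first base, second base).
WC_PAIR_BONDS = {
    ("G", "C"): [("O6", "N4"), ("N1", "N3"), ("N2", "O2")],
    ("C", "G"): [("N4", "O6"), ("N3", "N1"), ("O2", "N2")],
    ("A", "U"): [("N6", "O4"), ("N1", "N3")],
    ("U", "A"): [("O4", "N6"), ("N3", "N1")],
    ("A", "T"): [("N6", "O4"), ("N1", "N3")],
    ("T", "A"): [("O4", "N6"), ("N3", "N1")],
}

_GLYCOSIDIC_LENGTH = 1.47   # Å N-C1'
_C1_C1 = 10.4               # Å canonical C1'-C1' separation
_LAMBDA = np.radians(55.0)  # glycosidic bond angle to the C1'-C1' line
_HBOND_TARGET = 2.9         # Å


# ---------------------------------------------------------------------------
# Idealized residue templates
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _template(resname: str) -> dict[str, np.ndarray]:
    """Heavy-atom ideal coordinates for a residue type (CCD via biotite)."""
    arr = bsinfo.residue(resname)
    if arr is None:
        raise ValueError(f"unknown residue template {resname!r}")
    out = {}
    for name, element, coord in zip(arr.atom_name, arr.element, arr.coord):
        if element == "H" or name in ("OP3", "OXT"):
            continue
        out[str(name)] = np.array(coord, dtype=float)
    return out


def _nucleotide_name(base: str, nucleic_type: str) -> str:
    return base if nucleic_type == "RNA" else f"D{'T' if base == 'U' else base}"


def _local_nucleotide(resname: str) -> dict[str, np.ndarray]:
    """Template re-expressed in the base frame: glycosidic N at the origin,
    x along N -> C1', base plane in z = 0."""
    tpl = _template(resname)
    base = chem.base_letter(resname)
    n_gly = tpl[chem.GLYCOSIDIC_N[base]]
    base_coords = np.array([tpl[a] for a in chem.BASE_ATOMS[base] if a in tpl])
    z = plane_normal(base_coords)
    x = tpl["C1'"] - n_gly
    x = x - (x @ z) * z
    x /= np.linalg.norm(x)
    centroid_dir = base_coords.mean(axis=0) - n_gly
    # right-handed frame with y pointing toward the base body
    y = np.cross(z, x)
    if y @ centroid_dir < 0:
        z, y = -z, -y
    rot = np.array([x, y, z])
    local = {name: rot @ (pos - n_gly) for name, pos in tpl.items()}
    return _set_glycosidic_torsion(local, base, target_chi=-158.0)


def _set_glycosidic_torsion(local: dict[str, np.ndarray], base: str,
                            target_chi: float) -> dict[str, np.ndarray]:
    """Rotate the sugar-phosphate moiety about the glycosidic bond so the
    template adopts a standard anti conformation (CCD conformers vary)."""
    n_name = chem.GLYCOSIDIC_N[base]
    needed = {"O4'", "C1'", n_name, chem.CHI_BASE_ATOM[base]}
    if not needed <= set(local):
        return local
    axis = local["C1'"] - local[n_name]
    axis = axis / np.linalg.norm(axis)
    pivot = local[n_name]
    base_atoms = set(chem.BASE_ATOMS[base])

    def chi_of(coords: dict[str, np.ndarray]) -> float:
        return dihedral(coords["O4'"], coords["C1'"], coords[n_name],
                        coords[chem.CHI_BASE_ATOM[base]])

    def rotated(angle_deg: float) -> dict[str, np.ndarray]:
        t = np.radians(angle_deg)
        cos, sin = np.cos(t), np.sin(t)
        out = {}
        for name, pos in local.items():
            if name in base_atoms or name == "C1'":
                out[name] = pos
            else:
                rel = pos - pivot
                out[name] = (rel * cos + np.cross(axis, rel) * sin
                             + axis * (axis @ rel) * (1 - cos)) + pivot
        return out

    delta = target_chi - chi_of(local)
    for sign in (1.0, -1.0):
        cand = rotated(sign * delta)
        if abs(((chi_of(cand) - target_chi + 180) % 360) - 180) < 1e-6:
            return cand
    return local


def _place(local: dict[str, np.ndarray], x_to: np.ndarray, z_to: np.ndarray,
           origin: np.ndarray) -> dict[str, np.ndarray]:
    """Map a local-frame template so local x -> ``x_to``, z -> ``z_to``,
    origin (the glycosidic N) -> ``origin``."""
    x_to = x_to / np.linalg.norm(x_to)
    z_to = z_to - (z_to @ x_to) * x_to
    z_to /= np.linalg.norm(z_to)
    y_to = np.cross(z_to, x_to)
    m = np.column_stack([x_to, y_to, z_to])
    return {name: m @ pos + origin for name, pos in local.items()}


# ---------------------------------------------------------------------------
# Base-pair construction
# ---------------------------------------------------------------------------

def _rotz(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _pair_cost_arrays(
    bond_pi: np.ndarray, bond_pj: np.ndarray,
    clash_pi: np.ndarray, clash_pj: np.ndarray,
    clash_mask: np.ndarray,
) -> float:
    # bond-distance residuals plus a soft anti-clash penalty restricted to the
    # base moieties (the rigid template backbones are cosmetic)
    d_bonds = np.linalg.norm(bond_pi - bond_pj, axis=1)
    cost = float(np.sum((d_bonds - _HBOND_TARGET) ** 2))
    d = np.linalg.norm(clash_pi[:, None, :] - clash_pj[None, :, :], axis=2)
    viol = np.where(clash_mask & (d < 2.7), 2.7 - d, 0.0)
    return cost + 5.0 * float(np.sum(viol**2))


@lru_cache(maxsize=None)
def _pair_geometry(
    resname_i: str,
    resname_j: str,
    bonds: tuple[tuple[str, str], ...],
    orientation: str,
) -> tuple[tuple[tuple[str, tuple[float, float, float]], ...],
           tuple[tuple[str, tuple[float, float, float]], ...]]:
    """Solve the in-plane placement of base j against a fixed base i such that
    the requested hydrogen bonds reach 2.9 Å without steric clash, and the
    glycosidic pseudo-torsion has the requested cis/trans sign."""
    local_i = _local_nucleotide(resname_i)
    local_j = _local_nucleotide(resname_j)
    base_i = chem.base_letter(resname_i)
    base_j = chem.base_letter(resname_j)

    # base i fixed: C1' at (-L/2, 0, 0), glycosidic bond tilted by lambda
    c1_i = np.array([-_C1_C1 / 2.0, 0.0, 0.0])
    u_i = np.array([-np.cos(_LAMBDA), np.sin(_LAMBDA), 0.0])  # N->C1' direction
    n_i = c1_i - _GLYCOSIDIC_LENGTH * u_i
    coords_i = _place(local_i, u_i, np.array([0.0, 0.0, 1.0]), n_i)

    # base j starting guesses: mirrored placement, optionally flipped
    c1_j0 = np.array([_C1_C1 / 2.0, 0.0, 0.0])
    u_j = np.array([np.cos(_LAMBDA), np.sin(_LAMBDA), 0.0])
    n_j0 = c1_j0 - _GLYCOSIDIC_LENGTH * u_j

    clash_i = [a for a in coords_i if a in chem.BASE_ATOMS[base_i] or a in ("C1'", "O2'")]
    clash_j_names = set(chem.BASE_ATOMS[base_j]) | {"C1'", "O2'"}

    best = None
    for flip in (True, False):
        z_j = np.array([0.0, 0.0, -1.0 if flip else 1.0])
        base_coords = _place(local_j, u_j, z_j, n_j0)
        names = list(base_coords)
        clash_j = [a for a in names if a in clash_j_names]
        stack0 = np.array([base_coords[n] for n in names])
        center = stack0.mean(axis=0)

        name_idx = {n: i for i, n in enumerate(names)}
        bond_pi = np.array([coords_i[ai] for ai, _ in bonds])
        bond_j_idx = np.array([name_idx[aj] for _, aj in bonds])
        clash_pi = np.array([coords_i[a] for a in clash_i])
        clash_j_idx = np.array([name_idx[a] for a in clash_j])
        bond_pairs = {(ai, aj) for ai, aj in bonds}
        clash_mask = np.array([
            [(ai, aj) not in bond_pairs for aj in clash_j] for ai in clash_i
        ])

        def moved_stack(theta_txy: np.ndarray) -> np.ndarray:
            theta, tx, ty = theta_txy
            return (stack0 - center) @ _rotz(theta).T + center + np.array([tx, ty, 0.0])

        def cost(theta_txy: np.ndarray) -> float:
            m = moved_stack(theta_txy)
            return _pair_cost_arrays(
                bond_pi, m[bond_j_idx], clash_pi, m[clash_j_idx], clash_mask
            )

        def placed(theta_txy: np.ndarray) -> dict[str, np.ndarray]:
            return dict(zip(names, moved_stack(theta_txy)))

        # Starting points: for each in-plane rotation of base j, the two bond
        # distances fix the translation up to a two-circle intersection.
        starts: list[np.ndarray] = []
        (ai1, aj1), (ai2, aj2) = bonds[0], bonds[-1]
        for theta0 in np.radians(np.arange(0.0, 360.0, 10.0)):
            rot0 = _rotz(theta0)
            pj1 = rot0 @ (base_coords[aj1] - center) + center
            pj2 = rot0 @ (base_coords[aj2] - center) + center
            r1 = (coords_i[ai1] - pj1)[:2]
            r2 = (coords_i[ai2] - pj2)[:2]
            d12 = np.linalg.norm(r2 - r1)
            if d12 < 1e-9 or d12 > 2 * _HBOND_TARGET:
                continue
            midp = (r1 + r2) / 2.0
            h2 = _HBOND_TARGET**2 - (d12 / 2.0) ** 2
            if h2 < 0:
                continue
            perp = np.array([-(r2 - r1)[1], (r2 - r1)[0]]) / d12
            for sgn in (1.0, -1.0):
                t = midp + sgn * np.sqrt(h2) * perp
                starts.append(np.array([theta0, t[0], t[1]]))

        if not starts:   # single-bond fallback: plain rotation grid
            starts = [np.array([t, 0.0, 0.0])
                      for t in np.radians(np.arange(0.0, 360.0, 30.0))]

        def start_orientation(p: np.ndarray) -> str:
            c = placed(p)
            tau = dihedral(
                coords_i[chem.GLYCOSIDIC_N[base_i]], coords_i["C1'"],
                c["C1'"], c[chem.GLYCOSIDIC_N[base_j]],
            )
            return "cis" if abs(tau) <= 90.0 else "trans"

        # polish the most promising starts that already have the requested
        # cis/trans character (plus a few best overall, as a safety net)
        starts.sort(key=cost)
        matching = [s for s in starts if start_orientation(s) == orientation]
        for start in matching[:10] + starts[:4]:
            res = optimize.minimize(
                cost,
                x0=start,
                method="Nelder-Mead",
                options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 2000},
            )
            cand = placed(res.x)
            # orientation check via the N-C1'-C1'-N pseudo-torsion
            tau = dihedral(
                coords_i[chem.GLYCOSIDIC_N[base_i]], coords_i["C1'"],
                cand["C1'"], cand[chem.GLYCOSIDIC_N[base_j]],
            )
            ori = "cis" if abs(tau) <= 90.0 else "trans"
            if ori != orientation:
                continue
            if best is None or res.fun < best[0] - 1e-9:
                best = (res.fun, cand)
    if best is None or best[0] > 0.5:
        raise ValueError(
            f"could not build {resname_i}:{resname_j} {orientation} pair with bonds {bonds}"
        )

    # Normalize the pair frame: C1'-C1' midpoint at the origin, the C1'(i) ->
    # C1'(j) axis exactly along +x, base planes in z = 0.  This keeps stacked
    # pair frames strictly comparable regardless of sequence.
    coords_j_fit = best[1]
    c1i, c1j = coords_i["C1'"], coords_j_fit["C1'"]
    mid = (c1i + c1j) / 2.0
    x_ax = c1j - c1i
    x_ax[2] = 0.0
    x_ax /= np.linalg.norm(x_ax)
    rot = np.array([[x_ax[0], x_ax[1], 0.0], [-x_ax[1], x_ax[0], 0.0], [0.0, 0.0, 1.0]])

    def norm_frame(d: dict) -> tuple:
        return tuple((k, tuple(map(float, rot @ (v - mid)))) for k, v in d.items())

    return norm_frame(coords_i), norm_frame(coords_j_fit)


def build_base_pair(
    resname_i: str,
    resname_j: str,
    bonds: Sequence[tuple[str, str]] | None = None,
    orientation: str = "cis",
    chain_ids: tuple[str, str] = ("C", "D"),
) -> StructureModel:
    """Two-nucleotide model realizing the requested pairing geometry.

    ``bonds`` are explicit (atom on i, atom on j) hydrogen-bond targets;
    canonical Watson-Crick bonds are used when omitted.
    """
    if bonds is None:
        key = (chem.base_letter(resname_i), chem.base_letter(resname_j))
        if key not in WC_PAIR_BONDS:
            raise ValueError(f"no canonical bond set for {key}; pass bonds explicitly")
        bonds = WC_PAIR_BONDS[key]
    geo_i, geo_j = _pair_geometry(resname_i, resname_j, tuple(map(tuple, bonds)), orientation)
    chains = []
    for cid, resname, geo in ((chain_ids[0], resname_i, geo_i), (chain_ids[1], resname_j, geo_j)):
        res = Residue(chain_id=cid, number=1, name=resname)
        for name, pos in geo:
            res.atoms.append(Atom(name=name, element=name[0], position=np.array(pos)))
        chains.append(Chain(cid, [res]))
    return StructureModel(identifier=f"pair_{resname_i}_{resname_j}", chains=chains,
                          source_format="PDB")


# ---------------------------------------------------------------------------
# Helix builder
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HelixSpec:
    """Idealized duplex (or single-strand) specification.

    ``sequence`` is strand 1, 5'->3'.  Fiber-like defaults: A-form
    rise/twist (2.81 Å, 32.7°) with RNA chemistry, B-form (3.38 Å, 36.0°)
    with DNA chemistry.
    """

    sequence: str
    form: str = "A"
    duplex: bool = True
    rise: float | None = None
    twist: float | None = None
    nucleic_type: str | None = None      # "RNA" | "DNA"
    chain_ids: tuple[str, str] = ("C", "D")

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        if self.form not in HELIX_DEFAULTS:
            raise ValueError(f"unknown helix form {self.form!r}")
        bad = set(self.sequence.upper()) - set("ACGUT")
        if bad:
            raise ValueError(f"unknown base letters {sorted(bad)}")

    @property
    def params(self) -> tuple[float, float]:
        d_rise, d_twist = HELIX_DEFAULTS[self.form]
        return (self.rise if self.rise is not None else d_rise,
                self.twist if self.twist is not None else d_twist)

    @property
    def chemistry(self) -> str:
        if self.nucleic_type is not None:
            return self.nucleic_type
        return "RNA" if self.form == "A" else "DNA"


def _atoms_from(geo: dict[str, np.ndarray]) -> list[Atom]:
    return [Atom(name=n, element=n[0], position=p) for n, p in geo.items()]


def build_helix(spec: HelixSpec) -> StructureModel:
    """Deterministic idealized helix from stacked base-pair frames."""
    rise, twist = spec.params
    chemistry = spec.chemistry
    comp = COMPLEMENT if chemistry == "RNA" else DNA_COMPLEMENT
    seq = spec.sequence.upper()
    if chemistry == "DNA":
        seq = seq.replace("U", "T")
    n = len(seq)

    strand1: list[Residue] = []
    strand2: list[Residue] = []
    for k, letter in enumerate(seq):
        partner = comp[letter]
        name_i = _nucleotide_name(letter, chemistry)
        name_j = _nucleotide_name(partner, chemistry)
        bonds = WC_PAIR_BONDS[(letter if letter != "T" else "T",
                               partner if partner != "T" else "T")]
        geo_i, geo_j = _pair_geometry(name_i, name_j, tuple(map(tuple, bonds)), "cis")
        rot = _rotz(np.radians(k * twist))
        shift = np.array([0.0, 0.0, k * rise])

        def moved(geo):
            return {a: rot @ np.array(p) + shift for a, p in geo}

        res_i = Residue(chain_id=spec.chain_ids[0], number=k + 1, name=name_i,
                        atoms=_atoms_from(moved(geo_i)))
        strand1.append(res_i)
        if spec.duplex:
            res_j = Residue(chain_id=spec.chain_ids[1], number=n - k, name=name_j,
                            atoms=_atoms_from(moved(geo_j)))
            strand2.append(res_j)

    chains = [Chain(spec.chain_ids[0], strand1)]
    if spec.duplex:
        strand2.sort(key=lambda r: r.number)
        chains.append(Chain(spec.chain_ids[1], strand2))
    return StructureModel(identifier=f"{spec.form}_helix", chains=chains, source_format="PDB")


# ---------------------------------------------------------------------------
# Mini protein and C2 complex
# ---------------------------------------------------------------------------

_CA_RISE = 1.5        # Å per residue along an alpha-helix axis
_CA_TWIST = 100.0     # degrees per residue
_CA_RADIUS = 2.3      # Å


def _alpha_helix_ca(n_res: int) -> np.ndarray:
    k = np.arange(n_res)
    ang = np.radians(k * _CA_TWIST)
    return np.column_stack([
        _CA_RADIUS * np.cos(ang), _CA_RADIUS * np.sin(ang), _CA_RISE * k,
    ])


def _ala_template() -> dict[str, np.ndarray]:
    tpl = _template("ALA")
    return {k: tpl[k] for k in ("N", "CA", "C", "O", "CB")}


def _poly_ala_helix(
    chain_id: str, start_number: int, n_res: int,
    rotation: np.ndarray, translation: np.ndarray,
) -> list[Residue]:
    """Poly-alanine helix: a rigid ALA template is set on each Cα position,
    oriented by the local backbone direction (idealized internal geometry,
    approximate peptide links)."""
    from .superpose import kabsch_superpose

    ca = _alpha_helix_ca(n_res) @ rotation.T + translation
    axis = rotation @ np.array([0.0, 0.0, 1.0])
    tpl = _ala_template()
    tpl_frame = np.array([tpl["N"], tpl["CA"], tpl["C"]])
    residues = []
    for k in range(n_res):
        prev_ca = ca[k - 1] if k > 0 else ca[k] - axis * 3.8
        next_ca = ca[k + 1] if k < n_res - 1 else ca[k] + axis * 3.8
        target = np.array([
            ca[k] + 0.32 * (prev_ca - ca[k]),
            ca[k],
            ca[k] + 0.33 * (next_ca - ca[k]),
        ])
        fit = kabsch_superpose(tpl_frame, target)
        res = Residue(chain_id=chain_id, number=start_number + k, name="ALA")
        for name in ("N", "CA", "C", "CB"):
            pos = fit.transform.apply(tpl[name][None, :])[0]
            res.atoms.append(Atom(name, name[0], pos))
        residues.append(res)
    # second pass: carbonyl O from sp2 peptide geometry (opposite the
    # CA / next-N bisector), so O never collides with the next amide N
    for k, res in enumerate(residues):
        c_pos = res.position("C")
        ca_pos = res.position("CA")
        if k + 1 < n_res:
            n_next = residues[k + 1].position("N")
        else:
            n_next = c_pos + (c_pos - ca_pos)
        bisector = ((ca_pos - c_pos) / np.linalg.norm(ca_pos - c_pos)
                    + (n_next - c_pos) / max(np.linalg.norm(n_next - c_pos), 1e-9))
        norm = np.linalg.norm(bisector)
        direction = -bisector / norm if norm > 1e-9 else np.cross(
            axis, ca_pos - c_pos) / np.linalg.norm(np.cross(axis, ca_pos - c_pos))
        res.atoms.insert(3, Atom("O", "O", c_pos + 1.23 * direction))
    return residues


def _rot_about(axis: np.ndarray, degrees: float) -> np.ndarray:
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    t = np.radians(degrees)
    k = np.array([
        [0, -axis[2], axis[1]],
        [axis[2], 0, -axis[0]],
        [-axis[1], axis[0], 0],
    ])
    return np.eye(3) + np.sin(t) * k + (1 - np.cos(t)) * (k @ k)


def _build_protomer(chain_id: str) -> Chain:
    """Compact three-helix mini-domain centered near (14, 0, 0)."""
    residues: list[Residue] = []
    base = np.array([14.0, 0.0, -8.0])
    residues += _poly_ala_helix(chain_id, 1, 12, np.eye(3), base)
    residues += _poly_ala_helix(
        chain_id, 13, 12, _rot_about([1, 0, 0], 180.0), base + np.array([6.0, 1.0, 18.0]))
    residues += _poly_ala_helix(
        chain_id, 25, 12, _rot_about([0, 1, 0], 90.0), base + np.array([2.0, 6.5, 2.0]))
    return Chain(chain_id, residues)


def _rotate_chain_z180(chain: Chain, new_id: str) -> Chain:
    rot = np.diag([-1.0, -1.0, 1.0])
    new_residues = []
    for res in chain.residues:
        r2 = Residue(chain_id=new_id, number=res.number, name=res.name, icode=res.icode)
        r2.atoms = [Atom(a.name, a.element, rot @ a.position, a.occupancy, a.altloc,
                         a.b_factor) for a in res.atoms]
        new_residues.append(r2)
    return Chain(new_id, new_residues)


@dataclass(frozen=True)
class ToyComplexSpec:
    """C2 protein dimer (dyad = global z-axis) plus a nucleic component.

    ``asymmetry``: ``symmetric`` places a nucleic half and its exact dyad
    image (operator-duplex-like); ``offset`` shifts that symmetric component
    perpendicular to the dyad; ``monomeric-L`` places a single bent strand on
    one side only (aptamer-like).
    """

    asymmetry: str = "symmetric"
    nucleic_sequence: str = "GCGAUC"
    offset: float = 1.0          # Å, used by the "offset" mode
    protein_chains: tuple[str, str] = ("A", "B")
    nucleic_chains: tuple[str, str] = ("E", "F")

    def __post_init__(self) -> None:
        if self.asymmetry not in ("symmetric", "offset", "monomeric-L"):
            raise ValueError(f"unknown asymmetry mode {self.asymmetry!r}")


def _nucleic_half(spec: ToyComplexSpec) -> Chain:
    strand = build_helix(HelixSpec(sequence=spec.nucleic_sequence, form="A", duplex=False,
                                   chain_ids=(spec.nucleic_chains[0], "x")))
    chain = strand.chains[0]
    # strand axis parallel to the dyad, nestled against one protomer face
    shift = np.array([10.0, 13.0, -4.0])
    for res in chain.residues:
        for a in res.atoms:
            a.position = a.position + shift
    # keep the half strictly on the +y side of the dyad so that its 180-degree
    # image never interpenetrates it
    min_y = min(a.position[1] for res in chain.residues for a in res.atoms)
    if min_y < 1.2:
        lift = np.array([0.0, 1.2 - min_y, 0.0])
        for res in chain.residues:
            for a in res.atoms:
                a.position = a.position + lift
    return chain


def build_c2_complex(spec: ToyComplexSpec) -> StructureModel:
    chain_a = _build_protomer(spec.protein_chains[0])
    chain_b = _rotate_chain_z180(chain_a, spec.protein_chains[1])

    half = _nucleic_half(spec)
    nucleic_chains: list[Chain]
    if spec.asymmetry in ("symmetric", "offset"):
        image = _rotate_chain_z180(half, spec.nucleic_chains[1])
        nucleic_chains = [half, image]
        if spec.asymmetry == "offset":
            # shift the whole nucleic component perpendicular to the dyad
            for chain in nucleic_chains:
                for res in chain.residues:
                    for a in res.atoms:
                        a.position = a.position + np.array([0.0, spec.offset, 0.0])
    else:
        # single bent strand pushed clearly off the dyad (aptamer-like)
        residues = half.residues
        hinge_idx = len(residues) // 2
        hinge_point = residues[hinge_idx].position("C1'")
        rot = _rot_about([0, 0, 1], 90.0)
        for res in residues[hinge_idx:]:
            for a in res.atoms:
                a.position = rot @ (a.position - hinge_point) + hinge_point
        # keep the whole strand strictly on one side of the dyad so the
        # 180-degree image is unambiguously far away
        min_y = min(a.position[1] for res in residues for a in res.atoms)
        lift = np.array([0.0, max(0.0, 3.0 - min_y), 2.0])
        for res in residues:
            for a in res.atoms:
                a.position = a.position + lift
        nucleic_chains = [half]

    model = StructureModel(
        identifier=f"toy_c2_{spec.asymmetry}",
        chains=[chain_a, chain_b] + nucleic_chains,
        source_format="PDB",
    )
    # clash gate between protein and nucleic components
    prot = np.array([a.position for c in (chain_a, chain_b) for r in c.residues for a in r.atoms])
    nuc = np.array([a.position for c in nucleic_chains for r in c.residues for a in r.atoms])
    dmin = np.min(np.linalg.norm(prot[:, None, :] - nuc[None, :, :], axis=2))
    if dmin < 1.5:
        raise ValueError(f"clashing placement: minimum protein-nucleic distance {dmin:.2f} Å")
    return model


# ---------------------------------------------------------------------------
# Perturbation and rigid motion
# ---------------------------------------------------------------------------

def perturb(model: StructureModel, sigma: float, seed: int) -> StructureModel:
    """Isotropic per-atom Gaussian displacement with fixed seed; σ = 0 is the
    identity (bit-for-bit)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    new = copy.deepcopy(model)
    if sigma == 0:
        return new
    rng = np.random.default_rng(seed)
    for _, atom in new.atoms():
        atom.position = atom.position + rng.normal(0.0, sigma, size=3)
    return new


def transformed(model: StructureModel, rotation: np.ndarray,
                translation: np.ndarray) -> StructureModel:
    """Rigidly moved copy of a model."""
    new = copy.deepcopy(model)
    rotation = np.asarray(rotation, float)
    translation = np.asarray(translation, float)
    for _, atom in new.atoms():
        atom.position = rotation @ atom.position + translation
    return new
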