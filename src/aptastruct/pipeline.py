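"""End-to-end analysis workflows and report writers.

``analyze_complex`` runs the interface census, nucleic-acid geometry
annotation and dyad-symmetry test on one protein-nucleic complex and returns
a single JSON-serializable report.  ``compare_complexes`` applies the
anchored-domain r.m.s.d. protocol of a reference complex against a list of
comparison structures.  ``thermo_table`` derives the ΔG/TΔS bookkeeping and
fold changes from a table of binding parameters.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import json
import os
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from . import __version__
from .interface import analyze_interface
from .model import StructureModel, read_structure
from .nucgeom import backbone_torsions, detect_base_pairs, stacking_runs_and_flips
from .superpose import (
    EBD, NBD, DomainDefinition, anchored_domain_rmsd, inter_residue_distance,
)
from .symmetry import dimer_dyad_axis, rna_self_correspondence
from .thermo import (
    BindingParameters, DEFAULT_TEMPERATURE, derive_thermo, fold_change,
    present_fold,
)

__all__ = [
    "AnalysisConfig", "analyze_complex", "compare_complexes", "thermo_table",
    "load_binding_table",
]


@dataclass
class AnalysisConfig:
    """Chain roles and thresholds for one complex analysis.

    Defaults reproduce the standard settings: 3.7 Å contact cutoff, 1.4 Å
    SASA probe with 960 sphere points, heavy-atom hydrogen-bond and ring
    gates from :mod:`aptastruct.interface`.
    """

    structure: str | StructureModel
    protein_chains: tuple[str, str] = ("A", "B")
    nucleic_chains: tuple[str, ...] = ("C",)
    domains: dict[str, tuple[str, Sequence[tuple[int, int]]]] | None = None
    contact_cutoff: float = 3.7
    probe_radius: float = 1.4
    sasa_points: int = 960
    temperature: float = DEFAULT_TEMPERATURE
    output_dir: str | None = None


def _load(structure: str | StructureModel) -> StructureModel:
    if isinstance(structure, StructureModel):
        return structure
    return read_structure(structure)


def _resolve_chains(model: StructureModel, config: AnalysisConfig) -> None:
    known = set(model.chain_ids)
    wanted = set(config.protein_chains) | set(config.nucleic_chains)
    missing = sorted(wanted - known)
    if missing:
        raise ValueError(
            f"configuration error: chains {missing} not present in structure "
            f"{model.identifier!r} (has {sorted(known)})"
        )


def analyze_complex(config: AnalysisConfig) -> dict:
    """Interface census + nucleic geometry + dyad test for one complex."""
    model = _load(config.structure)
    _resolve_chains(model, config)
    prot = list(config.protein_chains)
    nuc = list(config.nucleic_chains)

    summary = analyze_interface(
        model, prot, nuc,
        domains=config.domains,
        cutoff=config.contact_cutoff,
        probe_radius=config.probe_radius,
        n_points=config.sasa_points,
    )

    nucleic_report = {}
    for cid in nuc:
        chain = model.chain(cid)
        torsions = backbone_torsions(chain)
        runs, flips = stacking_runs_and_flips(chain)
        nucleic_report[cid] = {
            "torsions": [dataclasses.asdict(t) | {"glycosidic_class": t.glycosidic_class}
                         for t in torsions],
            "stacking_runs": [r.numbers for r in runs],
            "flipped_out": sorted(num for num, f in flips.items() if f),
        }
    base_pairs = detect_base_pairs(model, nuc)

    symmetry_report = None
    if len(prot) == 2:
        try:
            axis = dimer_dyad_axis(model, prot[0], prot[1])
            corr = rna_self_correspondence(model, nuc, axis)
            symmetry_report = {
                "axis_direction": axis.direction.tolist(),
                "axis_point": axis.point.tolist(),
                "rotation_angle": axis.angle,
                "screw_translation": axis.screw_translation,
                "correspondence": [
                    {"nucleotide": list(r.nucleotide),
                     "counterpart": list(r.counterpart) if r.counterpart else None,
                     "distance": r.distance}
                    for r in corr["rows"]
                ],
                "match_rmsd": corr["rmsd"],
                "n_mutual": corr["n_mutual"],
            }
        except ValueError as exc:
            symmetry_report = {"error": f"symmetry stage: {exc}"}

    report = {
        "schema_version": 1,
        "package_version": __version__,
        "structure": model.identifier,
        "protein_chains": prot,
        "nucleic_chains": nuc,
        "thresholds": summary.thresholds,
        "interface": {
            "contact_residues": summary.census.residues_per_chain,
            "n_contact_residues": summary.census.n_residues,
            "n_atom_contacts": len(summary.census.contacts),
            "buried_area_per_domain": summary.per_domain_buried,
            "buried_area_total": summary.total_buried,
            "hydrogen_bonds": [
                {"donor": list(h.donor), "acceptor": list(h.acceptor),
                 "distance": round(h.distance, 3),
                 "angle": None if h.antecedent_angle is None else round(h.antecedent_angle, 1)}
                for h in summary.hydrogen_bonds
            ],
            "ring_interactions": [
                {"kind": r.kind, "residue_a": list(r.residue_a),
                 "residue_b": list(r.residue_b),
                 "distance": round(r.centroid_distance, 3), "angle": round(r.angle, 1)}
                for r in summary.ring_interactions
            ],
            "schematic": summary.schematic(),
        },
        "base_pairs": [
            {"i": [p.chain_i, p.number_i, p.name_i],
             "j": [p.chain_j, p.number_j, p.name_j],
             "edge_i": p.edge_i, "edge_j": p.edge_j,
             "orientation": p.orientation, "canonical": p.canonical,
             "wobble": p.wobble, "n_hbonds": p.n_hbonds}
            for p in base_pairs
        ],
        "nucleic_geometry": nucleic_report,
        "symmetry": symmetry_report,
    }

    if config.output_dir:
        os.makedirs(config.output_dir, exist_ok=True)
        out = os.path.join(config.output_dir, f"{model.identifier}_report.json")
        with open(out, "w") as fh:
            json.dump(report, fh, indent=1, default=float)
        _write_torsion_tsv(report, os.path.join(
            config.output_dir, f"{model.identifier}_torsions.tsv"))
    return report


def _write_torsion_tsv(report: dict, path: str) -> None:
    rows = []
    for cid, block in report["nucleic_geometry"].items():
        rows.extend(block["torsions"])
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Cross-complex comparison (anchored r.m.s.d. table)
# ---------------------------------------------------------------------------

def compare_complexes(
    reference: str | StructureModel,
    targets: Sequence[str | StructureModel],
    anchor: DomainDefinition = EBD,
    probe: DomainDefinition = NBD,
    chains: tuple[str, str] = ("A", "B"),
    marker_residues: tuple[int, ...] = (55, 12, 42),
    output_path: str | None = None,
) -> pd.DataFrame:
    """One row per target: anchor r.m.s.d., un-refit probe r.m.s.d., averaged
    marker-residue displacements and pair counts."""
    ref = _load(reference)
    rows = []
    for target in targets:
        tgt = _load(target)
        res = anchored_domain_rmsd(ref, tgt, anchor, probe, chains_a=chains,
                                   chains_b=chains)
        row = {
            "reference": ref.identifier,
            "target": tgt.identifier,
            "anchor_rmsd": round(res["anchor_rmsd"], 3),
            "probe_rmsd": round(res["probe_rmsd"], 3),
            "n_anchor_pairs": res["n_anchor_pairs"],
            "n_probe_pairs": res["n_probe_pairs"],
            "chain_pairing": "".join(res["chain_pairing"].values()),
        }
        paired = tuple(res["chain_pairing"].values())
        for num in marker_residues:
            try:
                d = inter_residue_distance(ref, tgt, res["transform"], num,
                                           chains_a=chains, chains_b=paired)
                row[f"residue_{num}_distance"] = round(d, 3)
            except ValueError:
                row[f"residue_{num}_distance"] = float("nan")
        rows.append(row)
    df = pd.DataFrame(rows)
    if output_path:
        df.to_csv(output_path, sep="\t", index=False)
    return df


# ---------------------------------------------------------------------------
# Thermodynamics table
# ---------------------------------------------------------------------------

def load_binding_table() -> pd.DataFrame:
    """Bundled reference table of measured binding parameters."""
    with importlib.resources.files("aptastruct").joinpath(
            "data/binding_table.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def thermo_table(
    table: pd.DataFrame | str | None = None,
    temperature: float = DEFAULT_TEMPERATURE,
    reference_construct: str = "TetR",
    output_path: str | None = None,
) -> pd.DataFrame:
    """Derive TΔS, ΔG, RT·ln(K_d) and fold changes for a binding table.

    Expected columns: ``complex``, ``construct``, ``kd_nm``, ``delta_h_kj_mol``,
    ``delta_s_j_mol_k`` (and optionally ``n``).  Fold changes are computed per
    ``complex`` group against ``reference_construct``.
    """
    if table is None:
        df = load_binding_table()
    elif isinstance(table, str):
        df = pd.read_csv(table, sep="\t")
    else:
        df = table.copy()
    if "kd_nm" not in df.columns and "kd_um" in df.columns:
        df["kd_nm"] = df["kd_um"] * 1000.0

    derived_rows = []
    for _, row in df.iterrows():
        params = BindingParameters(
            k_d=float(row["kd_nm"]) * 1e-9,
            delta_h=float(row["delta_h_kj_mol"]),
            n=float(row.get("n", 1.0)),
            delta_s=float(row["delta_s_j_mol_k"]),
            temperature=temperature,
        )
        d = derive_thermo(params)
        derived_rows.append({
            "t_delta_s_kj_mol": round(d.t_delta_s, 1),
            "minus_t_delta_s_kj_mol": round(d.minus_t_delta_s, 1),
            "delta_g_kj_mol": round(d.delta_g, 1),
            "delta_g_from_kd_kj_mol": round(d.delta_g_from_kd, 1),
            "consistency_residual_kj_mol": round(d.residual, 1),
        })
    out = pd.concat([df.reset_index(drop=True), pd.DataFrame(derived_rows)], axis=1)

    folds = []
    for _, row in out.iterrows():
        group = out[out["complex"] == row["complex"]]
        ref = group[group["construct"] == reference_construct]
        if ref.empty:
            raise ValueError(
                f"no reference construct {reference_construct!r} in group "
                f"{row['complex']!r}"
            )
        ratio = fold_change(float(row["kd_nm"]), float(ref.iloc[0]["kd_nm"]))
        folds.append({
            "fold_change": round(ratio, 2),
            "fold_change_presented": present_fold(ratio),
        })
    out = pd.concat([out, pd.DataFrame(folds)], axis=1)
    if output_path:
        out.to_csv(output_path, sep="\t", index=False)
    return out
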