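# aptastruct

Structural and thermodynamic characterization of how a homodimeric
transcription repressor (TetR) binds a synthetic RNA aptamer versus its
natural operator DNA.

TetR represses transcription by inserting the DNA-reading heads (NBDs,
helices α1–α3) of its two protomers into consecutive major-groove half-sites
of the palindromic *tetO* operator. A SELEX-derived 43-nt RNA aptamer
out-competes the operator despite folding into an L-shaped hairpin that looks
nothing like B-DNA. `aptastruct` implements the quantitative toolkit used to
compare the two complexes:

* **Domain-anchored superposition.** Structures are superposed with the
  Kabsch algorithm on the Cα atoms of the conformationally invariant
  effector-binding domains (EBDs, segments 48–66, 73–103, 108–129, 131–137,
  139–151, 166–173, 179–180, 183–202 in both protomers); the r.m.s.d. of the
  NBDs is then evaluated under that transform *without refitting*, isolating
  reading-head reorientation from global motion.
* **Interface census.** Contact residues at a 3.7 Å heavy-atom cutoff;
  buried solvent-accessible surface area per domain (in-package
  Shrake–Rupley, Bondi radii, deterministic golden-spiral sampling);
  hydrogen bonds (donor–acceptor ≤ 3.5 Å, antecedent angle ≥ 90°); π–π
  stacking and cation–π geometry.
* **Nucleic-acid annotation.** Backbone torsions α–ζ and χ with syn/anti
  calls, Leontis–Westhof base-pair classification (interacting edge per base
  from a fixed atom→edge table; cis/trans from the glycosidic-bond
  pseudo-torsion), stacking runs, flipped-out bases, and categorical A/B
  helix-form calls from base-pair frames.
* **Dyad pseudo-symmetry test.** The dimer two-fold axis is extracted from
  the protomer-onto-protomer rotation; nucleic phosphorus atoms are rotated
  180° about it and matched to their nearest originals — a palindromic
  operator duplex maps onto itself, a monomeric aptamer cannot.
* **Binding thermodynamics.** ΔG = ΔH − TΔS bookkeeping and RT·ln K_d
  cross-checks at T = 298 K, fold-change presentation, an exact single-site
  (Wiseman) ITC model with dilution correction for simulation and nonlinear
  refitting of (K_d, ΔH, n), and a fraction-bound isotherm fit for
  mobility-shift data.
* **Synthetic structure generators.** Idealized A/B-form helices, arbitrary
  two-base pairings built to explicit hydrogen-bond targets, a C2-symmetric
  two-chain mini-protein with symmetric or monomeric nucleic cargo, and
  seeded coordinate noise — so the whole pipeline is testable without any
  coordinate download.

## Worked example

```python
>>> import aptastruct as ap
>>> df = ap.thermo_table(temperature=298.0)
>>> print(df[["complex", "construct", "kd_nm", "minus_t_delta_s_kj_mol",
...           "delta_g_kj_mol", "fold_change_presented"]].to_string(index=False))
    complex construct   kd_nm  minus_t_delta_s_kj_mol  delta_g_kj_mol fold_change_presented
RNA_aptamer      TetR     5.6                   108.8           -47.2                1-fold
RNA_aptamer TetR-Q38A    26.2                   109.4           -43.4              4.7-fold
RNA_aptamer TetR-Y42A 13900.0                    46.8           -27.8             2500-fold
   tetO_DNA      TetR    51.1                  -100.2           -42.5                1-fold
   tetO_DNA TetR-Q38A   432.7                   -89.7           -36.3              8.5-fold
```

Reading the table: aptamer binding is enthalpy-driven (−TΔS = +108.8
kJ·mol⁻¹ is an entropic *penalty* overcome by ΔH = −156 kJ·mol⁻¹), while
operator-DNA binding is entropy-driven (−TΔS = −100.2 kJ·mol⁻¹ pays for an
endothermic ΔH = +57.7 kJ·mol⁻¹); the resulting ΔG values are nearly equal
(−47.2 vs −42.5 kJ·mol⁻¹). Removing the Tyr42 stacking platform costs
2500-fold in aptamer affinity; removing Gln38 costs 8.5-fold on DNA.

The structural pipeline works the same way on any parsed complex:

```python
>>> toy = ap.build_c2_complex(ap.ToyComplexSpec(asymmetry="monomeric-L"))
>>> report = ap.analyze_complex(ap.AnalysisConfig(
...     structure=toy, protein_chains=("A", "B"), nucleic_chains=("E",)))
>>> round(report["symmetry"]["rotation_angle"], 1), round(report["symmetry"]["match_rmsd"], 1)
(180.0, 13.4)
```

A perfect dimer dyad (180.0°) with a poor phosphorus self-match (13.4 Å
r.m.s.d.) is the signature of a monomeric nucleic ligand on a two-fold
protein — the aptamer situation; the symmetric operator-like fixture gives
a self-match of 0 Å instead.

A CLI mirrors the library: `aptastruct analyze`, `compare`, `thermo`,
`fixtures` (see `--help` on each subcommand).

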