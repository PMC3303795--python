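"""Shipped residue topologies and molecular-mechanics parameter fixtures.

All fixtures are plain text, generated deterministically (no timestamps).
Topologies are amino-acid dipeptides (acetyl / N-methyl amide caps) with
Engh–Huber-like ideal bond lengths and angles and CHARMM27-style atom types.
The parameter file is a small CHARMM27-like subset covering every shipped
topology; epsilon (kcal/mol) and rmin/2 (A) follow the published CHARMM27
values for the types used here.

TOY1 and TOY2 are minimal synthetic residues whose side chains feel a single
(respectively two independent) three-fold torsion(s) and no Lennard-Jones
interactions at all, so their rotamer wells are analytic (-60/60/180).
"""

from __future__ import annotations

import os

from .chem import MMParams, ResidueTopology, parse_params, parse_topology

__all__ = [
    "FIXTURE_TOPOLOGIES",
    "FIXTURE_PARAMS",
    "REFERENCE_LIBRARY",
    "fixture_names",
    "load_topology",
    "load_params",
    "params_for",
    "generate_fixtures",
]

# ---------------------------------------------------------------------------
# shared dipeptide backbone (acetyl cap CAY/CY/OY, N-methyl amide cap NT/CT)

_BACKBONE_ATOMS = """\
  - {name: CAY, element: C, type: CT3, refs: []}
  - {name: CY,  element: C, type: C,   refs: [CAY], length: 1.510}
  - {name: N,   element: N, type: NH1, refs: [CY, CAY], length: 1.329, angle: 116.5, backbone: true}
  - {name: CA,  element: C, type: CT1, refs: [N, CY, CAY], length: 1.458, angle: 121.7, dihedral: 180.0, backbone: true}
  - {name: OY,  element: O, type: O,   refs: [CY, N, CA], length: 1.231, angle: 123.0, dihedral: 0.0}
  - {name: H,   element: H, type: H,   refs: [N, CY, CAY], length: 0.990, angle: 119.2, dihedral: 0.0, backbone: true}
  - {name: HY1, element: H, type: HA,  refs: [CAY, CY, N], length: 1.090, angle: 109.5, dihedral: 180.0}
  - {name: HY2, element: H, type: HA,  refs: [CAY, CY, N], length: 1.090, angle: 109.5, dihedral: 60.0}
  - {name: HY3, element: H, type: HA,  refs: [CAY, CY, N], length: 1.090, angle: 109.5, dihedral: -60.0}
  - {name: C,   element: C, type: C,   refs: [CA, N, CY], length: 1.525, angle: 111.2, dihedral: phi, backbone: true}
  - {name: O,   element: O, type: O,   refs: [C, CA, N], length: 1.231, angle: 120.8, dihedral: psi+180, backbone: true}
  - {name: NT,  element: N, type: NH1, refs: [C, CA, N], length: 1.329, angle: 116.2, dihedral: psi}
  - {name: HNT, element: H, type: H,   refs: [NT, C, CA], length: 0.990, angle: 119.2, dihedral: 0.0}
  - {name: CT,  element: C, type: CT3, refs: [NT, C, CA], length: 1.449, angle: 121.7, dihedral: 180.0}
  - {name: HT1, element: H, type: HA,  refs: [CT, NT, C], length: 1.090, angle: 109.5, dihedral: 180.0}
  - {name: HT2, element: H, type: HA,  refs: [CT, NT, C], length: 1.090, angle: 109.5, dihedral: 60.0}
  - {name: HT3, element: H, type: HA,  refs: [CT, NT, C], length: 1.090, angle: 109.5, dihedral: -60.0}
"""

_HA_ATOM = """\
  - {name: HA,  element: H, type: HA,  refs: [CA, N, C], length: 1.090, angle: 108.0, dihedral: 119.0, backbone: true}
"""

_BACKBONE_BONDS = """\
  - [CAY, CY]
  - [CAY, HY1]
  - [CAY, HY2]
  - [CAY, HY3]
  - [CY, OY]
  - [CY, N]
  - [N, H]
  - [N, CA]
  - [CA, C]
  - [C, O]
  - [C, NT]
  - [NT, HNT]
  - [NT, CT]
  - [CT, HT1]
  - [CT, HT2]
  - [CT, HT3]
"""

_CAPS = """\
cap_atoms:
  acetyl: [CAY, HY1, HY2, HY3, CY, OY]
  nmethyl: [NT, HNT, CT, HT1, HT2, HT3]
"""


def _dipeptide(code, side_atoms, side_bonds, chi_atoms, chi_periods, seeds,
               with_ha=True, ha_bond=True):
    chi_lines = "".join(f"  - [{', '.join(q)}]\n" for q in chi_atoms)
    seed_lines = "".join(f"  - [{', '.join(str(s) for s in seed)}]\n" for seed in seeds)
    parts = [f"name: {code}\n", "atoms:\n", _BACKBONE_ATOMS]
    if with_ha:
        parts.append(_HA_ATOM)
    parts += [side_atoms, "bonds:\n", _BACKBONE_BONDS]
    if with_ha and ha_bond:
        parts.append("  - [CA, HA]\n")
    parts += [side_bonds, _CAPS]
    if chi_atoms:
        parts += ["chi_atoms:\n", chi_lines,
                  f"chi_periods: [{', '.join(str(p) for p in chi_periods)}]\n"]
    else:
        parts += ["chi_atoms: []\n", "chi_periods: []\n"]
    if seeds:
        parts += ["rotamer_seeds:\n", seed_lines]
    return "".join(parts)


def _product_seeds(*wells_per_chi):
    seeds = [[]]
    for wells in wells_per_chi:
        seeds = [s + [w] for s in seeds for w in wells]
    return seeds


# ---------------------------------------------------------------------------
# canonical residues

_ALA = _dipeptide(
    "ALA",
    """\
  - {name: CB,  element: C, type: CT3, refs: [CA, N, C], length: 1.521, angle: 110.4, dihedral: -120.5}
  - {name: HB1, element: H, type: HA,  refs: [CB, CA, N], length: 1.090, angle: 109.5, dihedral: 180.0}
  - {name: HB2, element: H, type: HA,  refs: [CB, CA, N], length: 1.090, angle: 109.5, dihedral: 60.0}
  - {name: HB3, element: H, type: HA,  refs: [CB, CA, N], length: 1.090, angle: 109.5, dihedral: -60.0}
""",
    """\
  - [CA, CB]
  - [CB, HB1]
  - [CB, HB2]
  - [CB, HB3]
""",
    [], [], [],
)

_VAL = _dipeptide(
    "VAL",
    """\
  - {name: CB,   element: C, type: CT1, refs: [CA, N, C], length: 1.540, angle: 111.5, dihedral: -120.5}
  - {name: CG1,  element: C, type: CT3, refs: [CB, CA, N], length: 1.521, angle: 110.5, dihedral: chi1}
  - {name: CG2,  element: C, type: CT3, refs: [CB, CA, N], length: 1.521, angle: 110.5, dihedral: chi1+122.3}
  - {name: HB,   element: H, type: HA,  refs: [CB, CA, N], length: 1.090, angle: 108.0, dihedral: chi1-118.7}
  - {name: HG11, element: H, type: HA,  refs: [CG1, CB, HB], length: 1.090, angle: 110.0, dihedral: 60.0}
  - {name: HG12, element: H, type: HA,  refs: [CG1, CB, HB], length: 1.090, angle: 110.0, dihedral: 180.0}
  - {name: HG13, element: H, type: HA,  refs: [CG1, CB, HB], length: 1.090, angle: 110.0, dihedral: -60.0}
  - {name: HG21, element: H, type: HA,  refs: [CG2, CB, HB], length: 1.090, angle: 110.0, dihedral: 60.0}
  - {name: HG22, element: H, type: HA,  refs: [CG2, CB, HB], length: 1.090, angle: 110.0, dihedral: 180.0}
  - {name: HG23, element: H, type: HA,  refs: [CG2, CB, HB], length: 1.090, angle: 110.0, dihedral: -60.0}
""",
    """\
  - [CA, CB]
  - [CB, CG1]
  - [CB, CG2]
  - [CB, HB]
  - [CG1, HG11]
  - [CG1, HG12]
  - [CG1, HG13]
  - [CG2, HG21]
  - [CG2, HG22]
  - [CG2, HG23]
""",
    [("N", "CA", "CB", "CG1")], [360],
    _product_seeds([-60, 60, 180]),
)

_LEU = _dipeptide(
    "LEU",
    """\
  - {name: CB,   element: C, type: CT2, refs: [CA, N, C], length: 1.530, angle: 110.4, dihedral: -120.5}
  - {name: CG,   element: C, type: CT1, refs: [CB, CA, N], length: 1.530, angle: 116.3, dihedral: chi1}
  - {name: HB1,  element: H, type: HA,  refs: [CB, CA, N], length: 1.090, angle: 108.0, dihedral: chi1+119.4}
  - {name: HB2,  element: H, type: HA,  refs: [CB, CA, N], length: 1.090, angle: 108.0, dihedral: chi1-119.4}
  - {name: CD1,  element: C, type: CT3, refs: [CG, CB, CA], length: 1.521, angle: 110.7, dihedral: chi2}
  - {name: CD2,  element: C, type: CT3, refs: [CG, CB, CA], length: 1.521, angle: 110.7, dihedral: chi2+122.3}
  - {name: HG,   element: H, type: HA,  refs: [CG, CB, CA], length: 1.090, angle: 107.0, dihedral: chi2-118.7}
  - {name: HD11, element: H, type: HA,  refs: [CD1, CG, HG], length: 1.090, angle: 110.0, dihedral: 60.0}
  - {name: HD12, element: H, type: HA,  refs: [CD1, CG, HG], length: 1.090, angle: 110.0, dihedral: 180.0}
  - {name: HD13, element: H, type: HA,  refs: [CD1, CG, HG], length: 1.090, angle: 110.0, dihedral: -60.0}
  - {name: HD21, element: H, type: HA,  refs: [CD2, CG, HG], length: 1.090, angle: 110.0, dihedral: 60.0}
  - {name: HD22, element: H, type: HA,  refs: [CD2, CG, HG], length: 1.090, angle: 110.0, dihedral: 180.0}
  - {name: HD23, element: H, type: HA,  refs: [CD2, CG, HG], length: 1.090, angle: 110.0, dihedral: -60.0}
""",
    """\
  - [CA, CB]
  - [CB, HB1]
  - [CB, HB2]
  - [CB, CG]
  - [CG, HG]
  - [CG, CD1]
  - [CG, CD2]
  - [CD1, HD11]
  - [CD1, HD12]
  - [CD1, HD13]
  - [CD2, HD21]
  - [CD2, HD22]
  - [CD2, HD23]
""",
    [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")], [360, 360],
    _product_seeds([-60, 60, 180], [-60, 60, 180]),
)

_HSE = _dipeptide(
    "HSE",
    """\
  - {name: CB,  element: C, type: CT2, refs: [CA, N, C], length: 1.530, angle: 110.4, dihedral: -120.5}
  - {name: CG,  element: C, type: CT2, refs: [CB, CA, N], length: 1.530, angle: 114.1, dihedral: chi1}
  - {name: HB1, element: H, type: HA,  refs: [CB, CA, N], length: 1.090, angle: 108.0, dihedral: chi1+119.4}
  - {name: HB2, element: H, type: HA,  refs: [CB, CA, N], length: 1.090, angle: 108.0, dihedral: chi1-119.4}
  - {name: OD,  element: O, type: OH1, refs: [CG, CB, CA], length: 1.417, angle: 110.8, dihedral: chi2}
  - {name: HG1, element: H, type: HA,  refs: [CG, CB, CA], length: 1.090, angle: 108.9, dihedral: chi2+120.0}
  - {name: HG2, element: H, type: HA,  refs: [CG, CB, CA], length: 1.090, angle: 108.9, dihedral: chi2-120.0}
  - {name: HD,  element: H, type: H,   refs: [OD, CG, CB], length: 0.960, angle: 108.5, dihedral: chi3}
""",
    """\
  - [CA, CB]
  - [CB, HB1]
  - [CB, HB2]
  - [CB, CG]
  - [CG, HG1]
  - [CG, HG2]
  - [CG, OD]
  - [OD, HD]
""",
    [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD"), ("CB", "CG", "OD", "HD")],
    [360, 360, 360],
    _product_seeds([-60, 60, 180], [-60, 60, 180], [-60, 60, 180]),
)

# alpha-methyl-tryptophan: tryptophan with the HA replaced by a methyl (CM)
_AMT = _dipeptide(
    "AMT",
    """\
  - {name: CM,  element: C, type: CT3, refs: [CA, N, C], length: 1.530, angle: 109.3, dihedral: 119.5}
  - {name: HM1, element: H, type: HA,  refs: [CM, CA, N], length: 1.090, angle: 109.5, dihedral: 180.0}
  - {name: HM2, element: H, type: HA,  refs: [CM, CA, N], length: 1.090, angle: 109.5, dihedral: 60.0}
  - {name: HM3, element: H, type: HA,  refs: [CM, CA, N], length: 1.090, angle: 109.5, dihedral: -60.0}
  - {name: CB,  element: C, type: CT2, refs: [CA, N, C], length: 1.535, angle: 110.5, dihedral: -120.5}
  - {name: CG,  element: C, type: CY,  refs: [CB, CA, N], length: 1.512, angle: 114.0, dihedral: chi1}
  - {name: HB1, element: H, type: HA,  refs: [CB, CA, N], length: 1.090, angle: 108.0, dihedral: chi1+119.4}
  - {name: HB2, element: H, type: HA,  refs: [CB, CA, N], length: 1.090, angle: 108.0, dihedral: chi1-119.4}
  - {name: CD1, element: C, type: CA,  refs: [CG, CB, CA], length: 1.365, angle: 126.9, dihedral: chi2}
  - {name: CD2, element: C, type: CPT, refs: [CG, CB, CA], length: 1.433, angle: 126.7, dihedral: chi2+180.0}
  - {name: NE1, element: N, type: NY,  refs: [CD1, CG, CD2], length: 1.374, angle: 110.2, dihedral: 0.0}
  - {name: HD1, element: H, type: HP,  refs: [CD1, CG, CD2], length: 1.080, angle: 124.0, dihedral: 180.0}
  - {name: CE2, element: C, type: CPT, refs: [NE1, CD1, CG], length: 1.370, angle: 109.0, dihedral: 0.0}
  - {name: HE1, element: H, type: H,   refs: [NE1, CD1, CG], length: 1.010, angle: 125.0, dihedral: 180.0}
  - {name: CE3, element: C, type: CA,  refs: [CD2, CG, CD1], length: 1.400, angle: 133.9, dihedral: 180.0}
  - {name: HE3, element: H, type: HP,  refs: [CE3, CD2, CG], length: 1.080, angle: 120.0, dihedral: 0.0}
  - {name: CZ3, element: C, type: CA,  refs: [CE3, CD2, CG], length: 1.391, angle: 118.7, dihedral: 180.0}
  - {name: HZ3, element: H, type: HP,  refs: [CZ3, CE3, CD2], length: 1.080, angle: 120.0, dihedral: 180.0}
  - {name: CZ2, element: C, type: CA,  refs: [CE2, NE1, CD1], length: 1.394, angle: 130.1, dihedral: 180.0}
  - {name: HZ2, element: H, type: HP,  refs: [CZ2, CE2, NE1], length: 1.080, angle: 120.0, dihedral: 0.0}
  - {name: CH2, element: C, type: CA,  refs: [CZ2, CE2, NE1], length: 1.368, angle: 117.5, dihedral: 180.0}
  - {name: HH2, element: H, type: HP,  refs: [CH2, CZ2, CE2], length: 1.080, angle: 120.0, dihedral: 180.0}
""",
    """\
  - [CA, CM]
  - [CM, HM1]
  - [CM, HM2]
  - [CM, HM3]
  - [CA, CB]
  - [CB, HB1]
  - [CB, HB2]
  - [CB, CG]
  - [CG, CD1]
  - [CG, CD2]
  - [CD1, NE1]
  - [CD1, HD1]
  - [NE1, HE1]
  - [NE1, CE2]
  - [CE2, CD2]
  - [CE2, CZ2]
  - [CD2, CE3]
  - [CE3, HE3]
  - [CE3, CZ3]
  - [CZ3, HZ3]
  - [CZ3, CH2]
  - [CZ2, HZ2]
  - [CZ2, CH2]
  - [CH2, HH2]
""",
    [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")], [360, 360],
    _product_seeds([-60, 60, 180], [-90, 90]),
    with_ha=False,
)


def _indanyl_glycine(code, pucker):
    """2-indanyl-glycine; ring puckers ('endo'/'exo') are distinct topologies."""
    side = f"""\
  - {{name: CB,  element: C, type: CT1, refs: [CA, N, C], length: 1.540, angle: 111.5, dihedral: -120.5}}
  - {{name: C1G, element: C, type: CT2, refs: [CB, CA, N], length: 1.545, angle: 112.0, dihedral: chi1}}
  - {{name: C3G, element: C, type: CT2, refs: [CB, CA, N], length: 1.545, angle: 112.0, dihedral: chi1+118.0}}
  - {{name: HB,  element: H, type: HA,  refs: [CB, CA, N], length: 1.090, angle: 108.0, dihedral: chi1-121.0}}
  - {{name: C7A, element: C, type: CA,  refs: [C1G, CB, C3G], length: 1.505, angle: 103.5, dihedral: {pucker:.1f}}}
  - {{name: C3A, element: C, type: CA,  refs: [C3G, CB, C1G], length: 1.505, angle: 103.5, dihedral: {-pucker:.1f}}}
  - {{name: H11, element: H, type: HA,  refs: [C1G, CB, C7A], length: 1.090, angle: 111.0, dihedral: 118.0}}
  - {{name: H12, element: H, type: HA,  refs: [C1G, CB, C7A], length: 1.090, angle: 111.0, dihedral: -122.0}}
  - {{name: H31, element: H, type: HA,  refs: [C3G, CB, C3A], length: 1.090, angle: 111.0, dihedral: 118.0}}
  - {{name: H32, element: H, type: HA,  refs: [C3G, CB, C3A], length: 1.090, angle: 111.0, dihedral: -122.0}}
  - {{name: C7G, element: C, type: CA,  refs: [C7A, C1G, CB], length: 1.390, angle: 128.5, dihedral: 175.0}}
  - {{name: C4G, element: C, type: CA,  refs: [C3A, C3G, CB], length: 1.390, angle: 128.5, dihedral: 175.0}}
  - {{name: C6G, element: C, type: CA,  refs: [C7G, C7A, C1G], length: 1.390, angle: 120.0, dihedral: -178.0}}
  - {{name: C5G, element: C, type: CA,  refs: [C4G, C3A, C3G], length: 1.390, angle: 120.0, dihedral: -178.0}}
  - {{name: H7G, element: H, type: HP,  refs: [C7G, C7A, C6G], length: 1.080, angle: 120.0, dihedral: 180.0}}
  - {{name: H4G, element: H, type: HP,  refs: [C4G, C3A, C5G], length: 1.080, angle: 120.0, dihedral: 180.0}}
  - {{name: H6G, element: H, type: HP,  refs: [C6G, C7G, C7A], length: 1.080, angle: 120.0, dihedral: 180.0}}
  - {{name: H5G, element: H, type: HP,  refs: [C5G, C4G, C3A], length: 1.080, angle: 120.0, dihedral: 180.0}}
"""
    bonds = """\
  - [CA, CB]
  - [CB, HB]
  - [CB, C1G]
  - [CB, C3G]
  - [C1G, H11]
  - [C1G, H12]
  - [C1G, C7A]
  - [C3G, H31]
  - [C3G, H32]
  - [C3G, C3A]
  - [C7A, C3A]
  - [C7A, C7G]
  - [C3A, C4G]
  - [C7G, H7G]
  - [C7G, C6G]
  - [C4G, H4G]
  - [C4G, C5G]
  - [C6G, H6G]
  - [C6G, C5G]
  - [C5G, H5G]
"""
    return _dipeptide(code, side, bonds,
                      [("N", "CA", "CB", "C1G")], [360],
                      _product_seeds([-60, 60, 180]))


_IGE = _indanyl_glycine("IGE", pucker=20.0)   # endo
_IGX = _indanyl_glycine("IGX", pucker=-20.0)  # exo

# ---------------------------------------------------------------------------
# toy residues: analytic torsion-only side chains

_TOY1 = """\
name: TOY1
atoms:
  - {name: Y1, element: C, type: TB0, refs: []}
  - {name: N,  element: N, type: TB0, refs: [Y1], length: 1.40}
  - {name: CA, element: C, type: TB0, refs: [N, Y1], length: 1.50, angle: 115.0, backbone: true}
  - {name: C,  element: C, type: TB0, refs: [CA, N, Y1], length: 1.50, angle: 112.0, dihedral: phi, backbone: true}
  - {name: NT, element: N, type: TB0, refs: [C, CA, N], length: 1.40, angle: 115.0, dihedral: psi}
  - {name: B1, element: C, type: TB1, refs: [CA, N, C], length: 1.50, angle: 110.0, dihedral: 121.0}
  - {name: B2, element: C, type: TB2, refs: [B1, CA, N], length: 1.50, angle: 110.0, dihedral: 180.0}
  - {name: B3, element: C, type: TB3, refs: [B2, B1, CA], length: 1.50, angle: 110.0, dihedral: chi1}
bonds:
  - [Y1, N]
  - [N, CA]
  - [CA, C]
  - [C, NT]
  - [CA, B1]
  - [B1, B2]
  - [B2, B3]
cap_atoms:
  acetyl: [Y1]
  nmethyl: [NT]
chi_atoms:
  - [CA, B1, B2, B3]
chi_periods: [360]
rotamer_seeds:
  - [-60]
  - [60]
  - [180]
"""

_TOY2 = """\
name: TOY2
atoms:
  - {name: Y1, element: C, type: TB0, refs: []}
  - {name: N,  element: N, type: TB0, refs: [Y1], length: 1.40}
  - {name: CA, element: C, type: TB0, refs: [N, Y1], length: 1.50, angle: 115.0, backbone: true}
  - {name: C,  element: C, type: TB0, refs: [CA, N, Y1], length: 1.50, angle: 112.0, dihedral: phi, backbone: true}
  - {name: NT, element: N, type: TB0, refs: [C, CA, N], length: 1.40, angle: 115.0, dihedral: psi}
  - {name: B1, element: C, type: TB1, refs: [CA, N, C], length: 1.50, angle: 110.0, dihedral: 121.0}
  - {name: B2, element: C, type: TB2, refs: [B1, CA, N], length: 1.50, angle: 110.0, dihedral: 180.0}
  - {name: B3, element: C, type: TB3, refs: [B2, B1, CA], length: 1.50, angle: 110.0, dihedral: chi1}
  - {name: B4, element: C, type: TB4, refs: [B3, B2, B1], length: 1.50, angle: 110.0, dihedral: chi2}
bonds:
  - [Y1, N]
  - [N, CA]
  - [CA, C]
  - [C, NT]
  - [CA, B1]
  - [B1, B2]
  - [B2, B3]
  - [B3, B4]
cap_atoms:
  acetyl: [Y1]
  nmethyl: [NT]
chi_atoms:
  - [CA, B1, B2, B3]
  - [B1, B2, B3, B4]
chi_periods: [360, 360]
rotamer_seeds:
  - [-60, -60]
  - [-60, 60]
  - [-60, 180]
  - [60, -60]
  - [60, 60]
  - [60, 180]
  - [180, -60]
  - [180, 60]
  - [180, 180]
"""

# ---------------------------------------------------------------------------
# parameter files

_MM_PARAMS = """\
* CHARMM27-like subset: epsilon (kcal/mol), rmin/2 (A); torsions K n theta
NONBONDED
C    0.1100  2.0000
O    0.1200  1.7000
NH1  0.2000  1.8500
H    0.0460  0.2245
HA   0.0220  1.3200
CT1  0.0200  2.2750
CT2  0.0560  2.0100
CT3  0.0780  2.0400
CA   0.0700  1.9924
HP   0.0300  1.3582
CY   0.0730  1.9900
CPT  0.0990  1.8600
NY   0.2000  1.8500
OH1  0.1521  1.7700
DIHEDRALS
X    C    NH1  X    2.5000  2  180.00
X    NH1  CT1  X    0.0000  3    0.00
X    CT1  C    X    0.0000  3    0.00
X    NH1  CT3  X    0.0000  3    0.00
X    C    CT3  X    0.0500  6  180.00
X    CT1  CT1  X    0.2000  3    0.00
X    CT1  CT2  X    0.2000  3    0.00
X    CT1  CT3  X    0.2000  3    0.00
X    CT2  CT2  X    0.1900  3    0.00
X    CT2  CT3  X    0.1600  3    0.00
X    CT2  OH1  X    0.1400  3    0.00
X    CT2  CY   X    0.2500  2  180.00
X    CT2  CA   X    0.2300  2  180.00
X    CA   CA   X    3.1000  2  180.00
X    CA   CPT  X    3.0000  2  180.00
X    CPT  CPT  X    2.8000  2  180.00
X    CY   CA   X    3.5000  2  180.00
X    CY   CPT  X    3.0000  2  180.00
X    CA   NY   X    2.8000  2  180.00
X    NY   CPT  X    2.8000  2  180.00
END
"""

_TOY1_PARAMS = """\
* TOY1: a single three-fold side-chain torsion, no Lennard-Jones
NONBONDED
TB0  0.0000  1.0000
TB1  0.0000  1.0000
TB2  0.0000  1.0000
TB3  0.0000  1.0000
DIHEDRALS
X    TB0  TB0  X    0.0000  1    0.00
X    TB0  TB1  X    0.0000  1    0.00
X    TB1  TB2  X    1.0000  3    0.00
END
"""

_TOY2_PARAMS = """\
* TOY2: two independent three-fold side-chain torsions, no Lennard-Jones
NONBONDED
TB0  0.0000  1.0000
TB1  0.0000  1.0000
TB2  0.0000  1.0000
TB3  0.0000  1.0000
TB4  0.0000  1.0000
DIHEDRALS
X    TB0  TB0  X    0.0000  1    0.00
X    TB0  TB1  X    0.0000  1    0.00
X    TB1  TB2  X    1.0000  3    0.00
X    TB2  TB3  X    1.0000  3    0.00
END
"""

# A tiny hand-written knowledge-based-style reference library (one residue,
# one phi/psi bin, three rotamers) used by the comparison tests.  Synthetic:
# not derived from any published library file.
REFERENCE_LIBRARY = """\
# synthetic reference rotamer library (bbdep-style dialect)
TOY1  -60  -40  120  1 0 0 0  0.7000   180.0     0.0     0.0     0.0   10.0    0.0    0.0    0.0
TOY1  -60  -40   60  1 0 0 0  0.2000   -60.0     0.0     0.0     0.0   10.0    0.0    0.0    0.0
TOY1  -60  -40   20  1 0 0 0  0.1000    60.0     0.0     0.0     0.0   10.0    0.0    0.0    0.0
"""

FIXTURE_TOPOLOGIES = {
    "ALA": _ALA,
    "VAL": _VAL,
    "LEU": _LEU,
    "HSE": _HSE,
    "AMT": _AMT,
    "IGE": _IGE,
    "IGX": _IGX,
    "TOY1": _TOY1,
    "TOY2": _TOY2,
}

FIXTURE_PARAMS = {
    "mm_params": _MM_PARAMS,
    "toy1": _TOY1_PARAMS,
    "toy2": _TOY2_PARAMS,
}

_PARAMS_FOR = {
    "ALA": "mm_params", "VAL": "mm_params", "LEU": "mm_params", "HSE": "mm_params",
    "AMT": "mm_params", "IGE": "mm_params", "IGX": "mm_params",
    "TOY1": "toy1", "TOY2": "toy2",
}


def fixture_names():
    return sorted(FIXTURE_TOPOLOGIES)


def load_topology(code: str) -> ResidueTopology:
    try:
        return parse_topology(FIXTURE_TOPOLOGIES[code.upper()])
    except KeyError:
        raise KeyError(f"no shipped topology named {code!r}; "
                       f"available: {', '.join(fixture_names())}") from None


def load_params(name: str = "mm_params") -> MMParams:
    return parse_params(FIXTURE_PARAMS[name])


def params_for(code: str) -> MMParams:
    """The shipped parameter set appropriate for a shipped topology."""
    return load_params(_PARAMS_FOR[code.upper()])


def generate_fixtures(outdir: str) -> list:
    """Write every shipped fixture file into ``outdir``; returns the paths.

    Output is byte-deterministic (fixture text embeds no timestamps).
    """
    os.makedirs(outdir, exist_ok=True)
    written = []
    for code, text in sorted(FIXTURE_TOPOLOGIES.items()):
        path = os.path.join(outdir, f"{code}.top")
        with open(path, "w") as fh:
            fh.write(text)
        written.append(path)
    for name, text in sorted(FIXTURE_PARAMS.items()):
        path = os.path.join(outdir, f"{name}.prm")
        with open(path, "w") as fh:
            fh.write(text)
        written.append(path)
    path = os.path.join(outdir, "reference.rotlib")
    with open(path, "w") as fh:
        fh.write(REFERENCE_LIBRARY)
    written.append(path)
    return written
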