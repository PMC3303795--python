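"""Residue chemistry: topologies, internal coordinates, and Cartesian building.

A residue is modelled as an amino-acid *dipeptide*: the residue itself plus an
acetyl cap on the N-terminus and an N-methyl amide cap on the C-terminus.  The
dipeptide isolates every phi/psi-dependent interaction between a side chain and
the neighbouring backbone, which is exactly what a backbone-dependent rotamer
library has to capture.

Atoms carry ideal internal coordinates (bond length, bond angle, dihedral) with
respect to three previously-built reference atoms, so a full Cartesian
conformation is generated deterministically from (phi, psi, chi_1..chi_n) by
natural-extension (NeRF-style) placement.  Bond lengths and angles are never
relaxed; the only degrees of freedom are torsions.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import yaml

__all__ = [
    "AtomRecord",
    "ResidueTopology",
    "MMParams",
    "Conformation",
    "TopologyError",
    "ParameterError",
    "GeometryError",
    "canonical_angle",
    "measure_dihedral",
    "build_conformation",
    "build_chi_coords",
    "bond_separation",
    "parse_topology",
    "parse_params",
    "write_pdb",
]


class TopologyError(ValueError):
    """Raised for malformed or inconsistent residue topologies."""


class ParameterError(KeyError):
    """Raised when an atom type or torsion quadruple has no parameters."""


class GeometryError(ValueError):
    """Raised for degenerate geometry (collinear dihedral axes etc.)."""


# ---------------------------------------------------------------------------
# angles

def canonical_angle(x):
    """Wrap angles (degrees) into the canonical interval (-180, 180]."""
    a = np.asarray(x, dtype=float)
    w = a - 360.0 * np.floor((a + 180.0) / 360.0)
    w = np.where(w <= -180.0, w + 360.0, w)
    if np.ndim(x) == 0:
        return float(w)
    return w


def fold_symmetric(x, period):
    """Fold an angle into the canonical interval for its period.

    period 360 -> (-180, 180]; period 180 -> (-90, 90] (symmetric termini).
    """
    a = np.asarray(x, dtype=float)
    half = period / 2.0
    w = a - period * np.floor((a + half) / period)
    w = np.where(w <= -half, w + period, w)
    if np.ndim(x) == 0:
        return float(w)
    return w


def measure_dihedral(p1, p2, p3, p4):
    """Signed dihedral angle p1-p2-p3-p4 in degrees, IUPAC convention.

    Accepts single points (3,) or batches (..., 3); result in (-180, 180].
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    norm1 = np.linalg.norm(n1, axis=-1)
    norm2 = np.linalg.norm(n2, axis=-1)
    if np.any(norm1 < 1e-9) or np.any(norm2 < 1e-9):
        raise GeometryError("collinear atoms: dihedral axis is undefined")
    b2n = b2 / np.linalg.norm(b2, axis=-1, keepdims=True)
    m1 = np.cross(n1, b2n)
    x = np.sum(n1 * n2, axis=-1)
    y = -np.sum(m1 * n2, axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    return canonical_angle(ang)


def measure_angle(p1, p2, p3):
    """Bond angle p1-p2-p3 in degrees."""
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    v1 = p1 - p2
    v2 = p3 - p2
    cosang = np.sum(v1 * v2, axis=-1) / (
        np.linalg.norm(v1, axis=-1) * np.linalg.norm(v2, axis=-1)
    )
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


# ---------------------------------------------------------------------------
# domain types

# dihedral spec: fixed float, or (kind, index, offset) where kind is one of
# "phi", "psi", "chi" and offset is added to the named torsion.
_DIH_RE = re.compile(r"^\s*(phi|psi|chi(\d+))\s*(?:([+-])\s*([0-9.]+))?\s*$")


def _parse_dihedral_spec(spec):
    if isinstance(spec, (int, float)):
        return ("fixed", 0, float(spec))
    m = _DIH_RE.match(str(spec))
    if not m:
        raise TopologyError(f"cannot parse dihedral spec {spec!r}")
    offset = float(m.group(4) or 0.0)
    if m.group(3) == "-":
        offset = -offset
    if m.group(2) is not None:
        return ("chi", int(m.group(2)) - 1, offset)
    return (m.group(1), 0, offset)


@dataclass(frozen=True)
class AtomRecord:
    """One atom with its ideal internal coordinates.

    ``refs`` are the bond-to, angle-to and dihedral-to atom names (all must be
    built earlier); the first three atoms of a topology seed the frame and use
    progressively fewer references.
    """

    name: str
    element: str
    mm_type: str
    refs: tuple  # up to 3 names
    ideal_bond_length: float = 0.0
    ideal_bond_angle: float = 0.0
    dihedral: tuple = ("fixed", 0, 0.0)  # (kind, chi index, offset degrees)
    is_backbone: bool = False

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() == "H"


@dataclass
class ResidueTopology:
    """Atom graph, ideal internal coordinates and chi definitions of one residue."""

    code: str
    atoms: list  # of AtomRecord, in build order
    bonds: list  # of (name, name)
    chi_atoms: list  # of 4-tuples of atom names
    chi_periods: list  # of 180 or 360
    cap_atoms: dict = field(default_factory=dict)  # {"acetyl": [...], "nmethyl": [...]}
    rotamer_seeds: list | None = None  # default K-means centroid seeds
    source_text: str | None = None

    def __post_init__(self):
        names = [a.name for a in self.atoms]
        if len(set(names)) != len(names):
            raise TopologyError(f"{self.code}: duplicate atom names")
        self._index = {n: i for i, n in enumerate(names)}
        g = nx.Graph()
        g.add_nodes_from(names)
        for a, b in self.bonds:
            if a not in self._index or b not in self._index:
                raise TopologyError(f"{self.code}: bond references unknown atom {a}-{b}")
            g.add_edge(a, b)
        if len(names) > 1 and not nx.is_connected(g):
            raise TopologyError(f"{self.code}: bond graph is not connected")
        self.graph = g
        for k, quad in enumerate(self.chi_atoms):
            if len(quad) != 4:
                raise TopologyError(f"{self.code}: chi {k + 1} needs 4 atoms")
            if not g.has_edge(quad[1], quad[2]):
                raise TopologyError(
                    f"{self.code}: chi {k + 1} middle atoms {quad[1]}-{quad[2]} not bonded"
                )
        for p in self.chi_periods:
            if p not in (180, 360):
                raise TopologyError(f"{self.code}: chi period must be 180 or 360, got {p}")
        if len(self.chi_periods) != len(self.chi_atoms):
            raise TopologyError(f"{self.code}: chi_periods/chi_atoms length mismatch")
        # validate build order and internal coordinates
        for i, a in enumerate(self.atoms):
            for r in a.refs:
                j = self._index.get(r)
                if j is None:
                    raise TopologyError(f"{self.code}: atom {a.name} references unknown {r}")
                if j >= i:
                    raise TopologyError(
                        f"{self.code}: atom {a.name} references {r} before it is built"
                    )
            if i >= 1 and not a.ideal_bond_length > 0:
                raise TopologyError(f"{self.code}: atom {a.name} needs a positive bond length")
            if i >= 2 and not (0.0 < a.ideal_bond_angle < 180.0):
                raise TopologyError(f"{self.code}: atom {a.name} bond angle out of (0, 180)")

    # -- convenience ------------------------------------------------------
    @property
    def atom_names(self):
        return [a.name for a in self.atoms]

    @property
    def n_chi(self) -> int:
        return len(self.chi_atoms)

    def index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise TopologyError(f"{self.code}: no atom named {name!r}") from None

    def chi_indices(self) -> np.ndarray:
        """(n_chi, 4) array of atom indices defining each chi."""
        return np.array(
            [[self.index(n) for n in quad] for quad in self.chi_atoms], dtype=int
        ).reshape(-1, 4)

    def backbone_indices(self):
        return [i for i, a in enumerate(self.atoms) if a.is_backbone]

    def content_hash(self) -> str:
        text = self.source_text or repr(self.atoms) + repr(self.bonds)
        return hashlib.sha256(text.encode()).hexdigest()[:12]

    def distal_atoms(self, chi_index: int):
        """Atom names on the side-chain side of the chi_index axis (moved by it)."""
        a2, a3 = self.chi_atoms[chi_index][1], self.chi_atoms[chi_index][2]
        g = self.graph.copy()
        g.remove_edge(a2, a3)
        comp = nx.node_connected_component(g, a3)
        comp.discard(a3)
        return sorted(comp | {self.chi_atoms[chi_index][3]} - {a3})


@dataclass
class MMParams:
    """CHARMM-style molecular-mechanics parameters.

    lj: atom type -> (epsilon kcal/mol, rmin/2 A).
    torsions: 4-type key -> list of (K kcal/mol, n, theta degrees); outer atoms
    of a key may be the wildcard ``X``.
    """

    lj: dict
    torsions: dict
    source_text: str | None = None

    def __post_init__(self):
        for t, (eps, rmin_half) in self.lj.items():
            if eps < 0 or rmin_half <= 0:
                raise ParameterError(f"bad LJ parameters for type {t}")
        for key, terms in self.torsions.items():
            for (k, n, theta) in terms:
                if n < 1:
                    raise ParameterError(f"torsion multiplicity must be >= 1 for {key}")

    def lj_params(self, mm_type: str):
        try:
            return self.lj[mm_type]
        except KeyError:
            raise ParameterError(f"no Lennard-Jones parameters for atom type {mm_type!r}") from None

    def torsion_terms(self, t1, t2, t3, t4):
        """CHARMM lookup order: exact quadruple (either direction), then wildcard."""
        for key in ((t1, t2, t3, t4), (t4, t3, t2, t1), ("X", t2, t3, "X"), ("X", t3, t2, "X")):
            if key in self.torsions:
                return self.torsions[key]
        raise ParameterError(
            f"no torsion parameters for atom-type quadruple {t1}-{t2}-{t3}-{t4}"
        )

    def content_hash(self) -> str:
        text = self.source_text or repr(sorted(self.lj.items()))
        return hashlib.sha256(text.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# parsing

def parse_topology(text_or_path) -> ResidueTopology:
    """Parse a residue topology from the YAML schema (path or string).

    Schema keys: ``name``, ``atoms`` (list of mappings with name/element/type/
    refs/length/angle/dihedral/backbone), ``bonds``, ``chi_atoms``,
    ``chi_periods``, optional ``cap_atoms`` and ``rotamer_seeds``.
    """
    text = _slurp(text_or_path)
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as e:
        raise TopologyError(f"topology is not valid YAML: {e}") from e
    if not isinstance(doc, dict) or "atoms" not in doc:
        raise TopologyError("topology file must be a mapping with an 'atoms' list")
    atoms = []
    for i, rec in enumerate(doc["atoms"]):
        refs = tuple(rec.get("refs") or ())
        need = min(i, 3)
        if len(refs) != need:
            raise TopologyError(
                f"atom {rec.get('name')}: expected {need} reference atoms, got {len(refs)}"
            )
        atoms.append(
            AtomRecord(
                name=str(rec["name"]),
                element=str(rec["element"]),
                mm_type=str(rec["type"]),
                refs=refs,
                ideal_bond_length=float(rec.get("length", 0.0)),
                ideal_bond_angle=float(rec.get("angle", 0.0)),
                dihedral=_parse_dihedral_spec(rec.get("dihedral", 0.0)),
                is_backbone=bool(rec.get("backbone", False)),
            )
        )
    return ResidueTopology(
        code=str(doc.get("name", "RES")),
        atoms=atoms,
        bonds=[tuple(b) for b in doc.get("bonds", [])],
        chi_atoms=[tuple(c) for c in doc.get("chi_atoms", [])],
        chi_periods=list(doc.get("chi_periods", [])),
        cap_atoms={k: list(v) for k, v in (doc.get("cap_atoms") or {}).items()},
        rotamer_seeds=doc.get("rotamer_seeds"),
        source_text=text,
    )


def parse_params(text_or_path) -> MMParams:
    """Parse the plain-text parameter dialect (NONBONDED / DIHEDRALS sections).

    NONBONDED rows: ``type epsilon rmin_half``; DIHEDRALS rows:
    ``t1 t2 t3 t4 K n theta`` where t1/t4 may be ``X``.  ``*`` or ``!`` start
    comments; ``END`` terminates.
    """
    text = _slurp(text_or_path)
    lj: dict = {}
    torsions: dict = {}
    section = None
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("!")[0].strip()
        if not line or line.startswith("*"):
            continue
        upper = line.upper()
        if upper.startswith("NONBONDED"):
            section = "nb"
            continue
        if upper.startswith("DIHEDRAL"):
            section = "dih"
            continue
        if upper == "END":
            break
        parts = line.split()
        try:
            if section == "nb":
                if len(parts) != 3:
                    raise ValueError("expected: type epsilon rmin_half")
                lj[parts[0]] = (abs(float(parts[1])), float(parts[2]))
            elif section == "dih":
                if len(parts) != 7:
                    raise ValueError("expected: t1 t2 t3 t4 K n theta")
                key = tuple(parts[:4])
                term = (float(parts[4]), int(parts[5]), float(parts[6]))
                torsions.setdefault(key, []).append(term)
            else:
                raise ValueError("data outside NONBONDED/DIHEDRALS section")
        except ValueError as e:
            raise ParameterError(f"parameter file line {lineno}: {e} ({raw!r})") from e
    return MMParams(lj=lj, torsions=torsions, source_text=text)


def _slurp(text_or_path) -> str:
    s = str(text_or_path)
    if "\n" in s:
        return s
    with open(s) as fh:
        return fh.read()


# ---------------------------------------------------------------------------
# Cartesian construction

def _place(rj, rk, rl, length, theta_deg, chi_deg):
    """NeRF placement: new atom at given distance from rj, angle (new-j-k) and
    dihedral (new-j-k-l).  All arrays broadcast over leading batch dims."""
    theta = np.radians(theta_deg)
    chi = np.radians(chi_deg)
    u = rk - rj
    u = u / np.linalg.norm(u, axis=-1, keepdims=True)
    w = rl - rk
    n = np.cross(w, u)
    nn = np.linalg.norm(n, axis=-1, keepdims=True)
    if np.any(nn < 1e-9):
        raise GeometryError("collinear reference atoms during placement")
    n = n / nn
    v = np.cross(u, n)
    ct, st = np.cos(theta), np.sin(theta)
    cc, sc = np.cos(chi), np.sin(chi)
    direction = (
        np.asarray(ct)[..., None] * u
        + np.asarray(st * cc)[..., None] * v
        + np.asarray(st * sc)[..., None] * n
    )
    return rj + length * direction


def build_chi_coords(topology: ResidueTopology, phi: float, psi: float, chis) -> np.ndarray:
    """Cartesian coordinates for one backbone bin and a batch of chi vectors.

    ``chis`` has shape (n_chi,) or (B, n_chi); returns (n_atoms, 3) or
    (B, n_atoms, 3).  The two peptide-bond omegas are fixed internally by the
    topology's own dihedral specs (180 degrees in the shipped fixtures).
    """
    chis = np.asarray(chis, dtype=float)
    single = chis.ndim <= 1
    chis = np.atleast_2d(chis)
    B = chis.shape[0]
    if chis.shape[1] != topology.n_chi:
        raise ValueError(
            f"{topology.code}: expected {topology.n_chi} chi angles, got {chis.shape[1]}"
        )
    n = len(topology.atoms)
    coords = np.empty((B, n, 3), dtype=float)
    idx = topology._index
    for i, atom in enumerate(topology.atoms):
        if i == 0:
            coords[:, i] = 0.0
        elif i == 1:
            coords[:, i] = coords[:, idx[atom.refs[0]]] + np.array(
                [atom.ideal_bond_length, 0.0, 0.0]
            )
        elif i == 2:
            rj = coords[:, idx[atom.refs[0]]]
            rk = coords[:, idx[atom.refs[1]]]
            theta = np.radians(atom.ideal_bond_angle)
            u = rk - rj
            u = u / np.linalg.norm(u, axis=-1, keepdims=True)
            # rotate u by theta in the xy-plane
            perp = np.stack([-u[..., 1], u[..., 0], np.zeros(B)], axis=-1)
            coords[:, i] = rj + atom.ideal_bond_length * (
                np.cos(theta) * u + np.sin(theta) * perp
            )
        else:
            kind, k, offset = atom.dihedral
            if kind == "fixed":
                dih = np.full(B, offset)
            elif kind == "phi":
                dih = np.full(B, phi + offset)
            elif kind == "psi":
                dih = np.full(B, psi + offset)
            else:  # chi
                if k >= topology.n_chi:
                    raise TopologyError(
                        f"{topology.code}: atom {atom.name} uses undefined chi{k + 1}"
                    )
                dih = chis[:, k] + offset
            coords[:, i] = _place(
                coords[:, idx[atom.refs[0]]],
                coords[:, idx[atom.refs[1]]],
                coords[:, idx[atom.refs[2]]],
                atom.ideal_bond_length,
                atom.ideal_bond_angle,
                dih,
            )
    return coords[0] if single else coords


@dataclass
class Conformation:
    """A built dipeptide conformation: topology plus torsions plus coordinates."""

    topology: ResidueTopology
    phi: float
    psi: float
    chis: np.ndarray
    coords: np.ndarray
    omega: float = 180.0

    def measured_chi(self, k: int) -> float:
        quad = self.topology.chi_indices()[k]
        return measure_dihedral(*(self.coords[i] for i in quad))

    def measured_chis(self) -> np.ndarray:
        return np.array([self.measured_chi(k) for k in range(self.topology.n_chi)])

    def with_chis(self, chis) -> "Conformation":
        return build_conformation(self.topology, self.phi, self.psi, chis)


def build_conformation(topology: ResidueTopology, phi: float, psi: float, chis=()) -> Conformation:
    """Build a dipeptide at the given backbone and side-chain torsions."""
    chis = np.asarray(chis, dtype=float).reshape(-1)
    if chis.size != topology.n_chi:
        raise ValueError(
            f"{topology.code}: expected {topology.n_chi} chi angles, got {chis.size}"
        )
    coords = build_chi_coords(topology, float(phi), float(psi), chis)
    return Conformation(
        topology=topology,
        phi=canonical_angle(phi),
        psi=canonical_angle(psi),
        chis=canonical_angle(chis.copy()) if chis.size else chis,
        coords=coords,
    )


# ---------------------------------------------------------------------------
# bond graph utilities

def bond_separation(topology: ResidueTopology) -> np.ndarray:
    """Matrix of bond-graph distances (number of bonds on the shortest path)."""
    if len(topology.atoms) > 1 and not nx.is_connected(topology.graph):
        raise TopologyError(f"{topology.code}: bond graph is not connected")
    n = len(topology.atoms)
    sep = np.zeros((n, n), dtype=int)
    lengths = dict(nx.all_pairs_shortest_path_length(topology.graph))
    for a, da in lengths.items():
        i = topology.index(a)
        for b, d in da.items():
            sep[i, topology.index(b)] = d
    return sep


# ---------------------------------------------------------------------------
# PDB output (write-only, for visual inspection)

def write_pdb(conf: Conformation, path_or_buf) -> None:
    """Write a Conformation as standard PDB ATOM records."""
    own = isinstance(path_or_buf, (str,))
    fh = open(path_or_buf, "w") if own else path_or_buf
    try:
        fh.write(f"REMARK   generated by rotlib: {conf.topology.code} "
                 f"phi={conf.phi:.1f} psi={conf.psi:.1f}\n")
        for i, (atom, xyz) in enumerate(zip(conf.topology.atoms, conf.coords), 1):
            name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
            code = (conf.topology.code + "   ")[:3]
            fh.write(
                f"ATOM  {i:5d} {name:<4s}{code:>4s} A   1    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {atom.element:>2s}\n"
            )
        fh.write("END\n")
    finally:
        if own:
            fh.close()


def superpose_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """RMSD of two coordinate sets after optimal rigid superposition (Kabsch)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    h = ac.T @ bc
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    diff = (ac @ rot.T) - bc
    return float(np.sqrt((diff**2).sum() / len(a)))
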