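"""Molecular-mechanics energy terms for the modified design score.

Two terms replace the knowledge-based rotamer-internal and backbone-torsion
potentials so that arbitrary side chains can be scored:

* a CHARMM-form torsion term, ``E = sum_paths sum_terms K (1 + cos(n chi - theta))``,
  evaluated over every distinct 4-atom bonded path, and
* a CHARMM-form Lennard-Jones term, ``E = eps [(rmin/d)^12 - 2 (rmin/d)^6]``,
  evaluated between atom pairs separated by three or more chemical bonds and
  split into a repulsive and an attractive branch at the pair minimum.

The weighted design score is a plain dot product of unweighted term values and
a weight set; the shipped default weights are the fitted values of the
modified energy function (torsion 0.27, intra-rep 0.32, intra-atr 0.54,
inter-rep 0.63, inter-atr 0.80, unfolded 0.90).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields

import numpy as np

from .chem import (
    Conformation,
    GeometryError,
    MMParams,
    ParameterError,
    ResidueTopology,
    bond_separation,
    build_chi_coords,
    measure_dihedral,
)

__all__ = [
    "EnergyBreakdown",
    "WeightSet",
    "EnergyTables",
    "MODIFIED_WEIGHTS",
    "torsion_energy",
    "lj_energy",
    "total_energy",
    "chi_gradient",
    "DipeptideScorer",
]

#: Fitted weights of the modified (molecular-mechanics) design score.
MODIFIED_WEIGHTS = {
    "mm_torsion": 0.27,
    "mm_lj_intra_rep": 0.32,
    "mm_lj_intra_atr": 0.54,
    "lj_inter_rep": 0.63,
    "lj_inter_atr": 0.80,
    "unfolded": 0.90,
}

CLASH_DISTANCE = 0.1  # A; below this the finite-difference gradient is unreliable


@dataclass
class EnergyBreakdown:
    """Unweighted per-term energies in kcal/mol."""

    mm_torsion: float = 0.0
    mm_lj_intra_rep: float = 0.0
    mm_lj_intra_atr: float = 0.0
    lj_inter_rep: float = 0.0
    lj_inter_atr: float = 0.0
    unfolded: float = 0.0

    TERMS = (
        "mm_torsion",
        "mm_lj_intra_rep",
        "mm_lj_intra_atr",
        "lj_inter_rep",
        "lj_inter_atr",
        "unfolded",
    )

    def __post_init__(self):
        vals = self.as_dict()
        if not all(np.isfinite(v) for v in vals.values()):
            raise ValueError("non-finite energy term")
        if self.mm_lj_intra_rep < 0 or self.mm_lj_intra_atr > 0:
            raise ValueError("LJ split must satisfy rep >= 0 and atr <= 0")

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


@dataclass
class WeightSet:
    """Term weights (dimensionless) plus per-term fixed flags used in fitting."""

    weights: dict = field(default_factory=lambda: dict(MODIFIED_WEIGHTS))
    fixed: frozenset = frozenset({"lj_inter_atr"})

    def __post_init__(self):
        if not all(np.isfinite(v) for v in self.weights.values()):
            raise ValueError("weights must be finite")
        self.fixed = frozenset(self.fixed)

    def __getitem__(self, term: str) -> float:
        return self.weights[term]

    def free_terms(self):
        return [t for t in self.weights if t not in self.fixed]


def total_energy(breakdown: EnergyBreakdown, weights: WeightSet) -> float:
    """Weighted linear combination of the unweighted term energies."""
    total = 0.0
    for term, value in breakdown.as_dict().items():
        if value == 0.0:
            continue
        try:
            w = weights[term]
        except KeyError:
            raise KeyError(f"no weight configured for nonzero term {term!r}") from None
        total += w * value
    return total


# ---------------------------------------------------------------------------
# compiled interaction tables

class EnergyTables:
    """Precompiled torsion paths and LJ pair lists for one topology.

    Compiling once makes batched evaluation over thousands of chi vectors
    cheap; all arrays are indexed into the topology's atom order.
    """

    def __init__(self, topology: ResidueTopology, params: MMParams,
                 min_bond_separation: int = 3):
        self.topology = topology
        self.params = params
        self.min_bond_separation = int(min_bond_separation)
        self._compile_torsions()
        self._compile_lj()

    def _compile_torsions(self):
        top = self.topology
        g = top.graph
        paths = set()
        for j, k in g.edges():
            for i in g.neighbors(j):
                if i == k:
                    continue
                for l in g.neighbors(k):
                    if l == j or l == i:
                        continue
                    path = (i, j, k, l)
                    if path[::-1] not in paths:
                        paths.add(path)
        path_idx, ks, ns, thetas = [], [], [], []
        types = {a.name: a.mm_type for a in top.atoms}
        for path in sorted(paths):
            terms = self.params.torsion_terms(*(types[n] for n in path))
            idx = [top.index(n) for n in path]
            for (K, n, theta) in terms:
                path_idx.append(idx)
                ks.append(K)
                ns.append(n)
                thetas.append(theta)
        self.torsion_paths = np.array(path_idx, dtype=int).reshape(-1, 4)
        self.torsion_k = np.array(ks, dtype=float)
        self.torsion_n = np.array(ns, dtype=float)
        self.torsion_theta = np.radians(np.array(thetas, dtype=float))
        self.n_torsion_paths = len(paths)

    def _compile_lj(self):
        top = self.topology
        sep = bond_separation(top)
        n = len(top.atoms)
        ii, jj = np.triu_indices(n, k=1)
        keep = sep[ii, jj] >= self.min_bond_separation
        ii, jj = ii[keep], jj[keep]
        eps = np.empty(len(top.atoms))
        rmin_half = np.empty(len(top.atoms))
        for i, a in enumerate(top.atoms):
            eps[i], rmin_half[i] = self.params.lj_params(a.mm_type)
        self.lj_pairs = np.stack([ii, jj], axis=1) if len(ii) else np.empty((0, 2), int)
        self.lj_eps = np.sqrt(eps[ii] * eps[jj])
        self.lj_rmin = rmin_half[ii] + rmin_half[jj]

    # -- evaluation -------------------------------------------------------
    def torsion_energy(self, coords: np.ndarray):
        """Torsion energy for coords of shape (..., n_atoms, 3)."""
        if self.torsion_k.size == 0:
            return np.zeros(coords.shape[:-2]) if coords.ndim > 2 else 0.0
        p = self.torsion_paths
        chi = measure_dihedral(
            coords[..., p[:, 0], :],
            coords[..., p[:, 1], :],
            coords[..., p[:, 2], :],
            coords[..., p[:, 3], :],
        )
        e = self.torsion_k * (1.0 + np.cos(self.torsion_n * np.radians(chi) - self.torsion_theta))
        out = e.sum(axis=-1)
        return float(out) if np.ndim(out) == 0 else out

    def lj_energy(self, coords: np.ndarray):
        """(repulsive, attractive) LJ energies for coords (..., n_atoms, 3)."""
        if len(self.lj_pairs) == 0:
            z = np.zeros(coords.shape[:-2])
            return (float(z), float(z)) if z.ndim == 0 else (z, z)
        d = np.linalg.norm(
            coords[..., self.lj_pairs[:, 0], :] - coords[..., self.lj_pairs[:, 1], :],
            axis=-1,
        )
        x = (self.lj_rmin / d) ** 6
        e = self.lj_eps * (x * x - 2.0 * x)
        below = d < self.lj_rmin
        rep = np.where(below, e + self.lj_eps, 0.0).sum(axis=-1)
        atr = np.where(below, -self.lj_eps, e).sum(axis=-1)
        if np.ndim(rep) == 0:
            return float(rep), float(atr)
        return rep, atr

    def min_distance(self, coords: np.ndarray):
        if len(self.lj_pairs) == 0:
            return np.inf
        d = np.linalg.norm(
            coords[..., self.lj_pairs[:, 0], :] - coords[..., self.lj_pairs[:, 1], :],
            axis=-1,
        )
        return d.min(axis=-1)


# ---------------------------------------------------------------------------
# user-facing term functions

def torsion_energy(conf: Conformation, params: MMParams) -> float:
    """CHARMM-form torsion energy summed over all distinct 4-atom bonded paths."""
    return EnergyTables(conf.topology, params).torsion_energy(conf.coords)


def lj_energy(conf: Conformation, params: MMParams, min_bond_separation: int = 3):
    """Intra-residue Lennard-Jones energy as a (repulsive, attractive) pair."""
    tables = EnergyTables(conf.topology, params, min_bond_separation)
    return tables.lj_energy(conf.coords)


# ---------------------------------------------------------------------------
# dipeptide scoring closure

class DipeptideScorer:
    """Unweighted MM energy (torsion + LJ) of one dipeptide at fixed phi/psi,
    as a function of the chi vector.  Accepts batches of chi vectors."""

    def __init__(self, topology: ResidueTopology, params: MMParams,
                 phi: float, psi: float, tables: EnergyTables | None = None):
        self.topology = topology
        self.params = params
        self.phi = float(phi)
        self.psi = float(psi)
        self.tables = tables or EnergyTables(topology, params)

    def coords(self, chis) -> np.ndarray:
        return build_chi_coords(self.topology, self.phi, self.psi, chis)

    def energy(self, chis):
        """Total unweighted energy; scalar for a chi vector, array for a batch."""
        coords = self.coords(chis)
        rep, atr = self.tables.lj_energy(coords)
        return self.tables.torsion_energy(coords) + rep + atr

    def breakdown(self, chis) -> EnergyBreakdown:
        coords = self.coords(np.asarray(chis, dtype=float).reshape(-1))
        rep, atr = self.tables.lj_energy(coords)
        return EnergyBreakdown(
            mm_torsion=self.tables.torsion_energy(coords),
            mm_lj_intra_rep=rep,
            mm_lj_intra_atr=atr,
        )

    def gradient(self, chis, step: float = 0.01):
        """Central finite-difference gradient in kcal/mol/degree.

        ``chis`` may be (n_chi,) or (B, n_chi); the gradient has the same shape.
        """
        chis = np.asarray(chis, dtype=float)
        single = chis.ndim == 1
        chis = np.atleast_2d(chis)
        if single:
            coords = self.coords(chis[0])
            dmin = self.tables.min_distance(coords)
            if dmin < CLASH_DISTANCE:
                raise GeometryError(
                    f"atom clash (d = {dmin:.3f} A < {CLASH_DISTANCE} A): "
                    "gradient is not numerically reliable"
                )
        grad = np.empty_like(chis)
        for k in range(chis.shape[1]):
            up = chis.copy()
            dn = chis.copy()
            up[:, k] += step
            dn[:, k] -= step
            grad[:, k] = (self.energy(up) - self.energy(dn)) / (2.0 * step)
        return grad[0] if single else grad


def chi_gradient(conf: Conformation, params: MMParams, step: float = 0.01) -> np.ndarray:
    """Gradient of the unweighted MM energy with respect to each chi (deg)."""
    scorer = DipeptideScorer(conf.topology, params, conf.phi, conf.psi)
    return scorer.gradient(conf.chis, step=step)
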