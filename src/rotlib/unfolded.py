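"""Explicit unfolded-state reference energies from 5-mer fragment ensembles.

The unfolded (reference) energy of a residue type is the average of its
unweighted per-term energies when placed at the center of short disordered
peptides and repacked.  Here the disordered backbone ensemble is drawn from a
Ramachandran mixture model (alpha, beta and uniform-coil components) rather
than fragments cut from crystal structures, so the package is buildable with
no external data; the sampler is pluggable, and real fragment (phi, psi)
values can be substituted wherever an ensemble array is accepted.

The weighted unfolded energy of a type is then sum_j w_j <E_j>, with the same
weights used for the folded-state score, and enters the design score with its
own (negative) contribution so that folded energies are measured relative to
the unfolded ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .chem import MMParams, ResidueTopology, canonical_angle, _place
from .energy import EnergyBreakdown, WeightSet, total_energy
from .makerotlib import RotamerLibrary
from .packer import AnnealSchedule, PackSystem, pack_rotamers, prune_rotamers

__all__ = [
    "FragmentEnsembleSpec",
    "UnfoldedEnergyTable",
    "generate_fragment_ensemble",
    "ChainConformation",
    "build_chain",
    "ChainScorer",
    "estimate_unfolded",
    "unfolded_energy",
]

#: (weight, phi mean, psi mean, sigma) for the alpha and beta components; the
#: remainder of the mass is uniform over the torus.
DEFAULT_ALPHA = (0.40, -63.0, -43.0, 10.0)
DEFAULT_BETA = (0.40, -120.0, 130.0, 15.0)


@dataclass
class FragmentEnsembleSpec:
    """Backbone sampler for the synthetic unfolded ensemble."""

    n_fragments: int = 500
    length: int = 5
    alpha: tuple = DEFAULT_ALPHA
    beta: tuple = DEFAULT_BETA
    seed: int = 0

    def __post_init__(self):
        if self.n_fragments < 1:
            raise ValueError("need at least one fragment")
        w = self.alpha[0] + self.beta[0]
        if not (0.0 <= w <= 1.0):
            raise ValueError("alpha + beta mixture weights must lie in [0, 1]")

    @property
    def uniform_weight(self) -> float:
        return 1.0 - self.alpha[0] - self.beta[0]


def generate_fragment_ensemble(spec: FragmentEnsembleSpec) -> np.ndarray:
    """Sample (n_fragments, length, 2) phi/psi arrays from the mixture.

    Each residue draws its component independently (random coil has no
    inter-residue torsion correlation in this model).
    """
    rng = np.random.default_rng(spec.seed)
    n, L = spec.n_fragments, spec.length
    comp = rng.choice(
        3, size=(n, L),
        p=[spec.alpha[0], spec.beta[0], spec.uniform_weight],
    )
    out = np.empty((n, L, 2))
    for idx, (_, pm, sm, sd) in ((0, spec.alpha), (1, spec.beta)):
        mask = comp == idx
        out[mask, 0] = rng.normal(pm, sd, size=mask.sum())
        out[mask, 1] = rng.normal(sm, sd, size=mask.sum())
    mask = comp == 2
    out[mask] = rng.uniform(-180.0, 180.0, size=(mask.sum(), 2))
    return canonical_angle(out)


# ---------------------------------------------------------------------------
# polypeptide chains from dipeptide topologies

_ACETYL = "acetyl"
_NMETHYL = "nmethyl"


@dataclass
class ChainConformation:
    """A built multi-residue chain: coordinates plus per-atom bookkeeping."""

    topologies: list
    phis: np.ndarray
    psis: np.ndarray
    chis: list
    coords: np.ndarray
    atom_residue: np.ndarray  # residue index per atom
    atom_names: list  # (residue_index, atom_name) unique keys
    mm_types: list
    graph: "nx.Graph"


def _cap_sets(top: ResidueTopology):
    ac = set(top.cap_atoms.get(_ACETYL, ()))
    nm = set(top.cap_atoms.get(_NMETHYL, ()))
    return ac, nm


def build_chain(topologies, phis, psis, chis_list) -> ChainConformation:
    """Build an N-residue chain with acetyl/N-methyl termini.

    Residue i > 0 replaces its acetyl cap with a peptide bond to residue
    i - 1 (the cap atoms play the role of the previous residue's backbone:
    CY -> C, CAY -> CA, OY -> O); omegas are fixed trans by the topologies'
    own internal coordinates.
    """
    n = len(topologies)
    phis = np.asarray(phis, dtype=float)
    psis = np.asarray(psis, dtype=float)
    if not (len(phis) == len(psis) == n and len(chis_list) == n):
        raise ValueError("need one phi, psi and chi vector per residue")
    coords: dict = {}
    placed: list = []  # (res, name, mm_type, element)
    graph = nx.Graph()

    def key(r, name):
        return (r, name)

    for r, top in enumerate(topologies):
        ac, nm = _cap_sets(top)
        alias = {}
        skip = set()
        if r > 0:
            skip |= ac
            alias = {"CY": key(r - 1, "C"), "CAY": key(r - 1, "CA"),
                     "OY": key(r - 1, "O")}
        if r < n - 1:
            skip |= nm
        chis = np.asarray(chis_list[r], dtype=float).reshape(-1)
        if chis.size != top.n_chi:
            raise ValueError(f"residue {r}: expected {top.n_chi} chis")

        def resolve(name):
            if name in alias:
                return alias[name]
            return key(r, name)

        for i, atom in enumerate(top.atoms):
            if atom.name in skip:
                continue
            k = key(r, atom.name)
            if r > 0 and atom.name == "N":
                # place via the previous residue's N-methyl nitrogen record
                prev = topologies[r - 1]
                nt_rec = next(a for a in prev.atoms if a.name == "NT")
                refs = [key(r - 1, x) for x in nt_rec.refs]
                dih = _resolve_dihedral(nt_rec.dihedral, phis[r - 1],
                                        psis[r - 1], np.zeros(0))
                coords[k] = _place(coords[refs[0]], coords[refs[1]],
                                   coords[refs[2]], nt_rec.ideal_bond_length,
                                   nt_rec.ideal_bond_angle, dih)
            elif i == 0:
                coords[k] = np.zeros(3)
            elif i == 1:
                coords[k] = coords[resolve(atom.refs[0])] + \
                    np.array([atom.ideal_bond_length, 0.0, 0.0])
            elif i == 2:
                rj = coords[resolve(atom.refs[0])]
                rk = coords[resolve(atom.refs[1])]
                u = rk - rj
                u = u / np.linalg.norm(u)
                perp = np.array([-u[1], u[0], 0.0])
                th = np.radians(atom.ideal_bond_angle)
                coords[k] = rj + atom.ideal_bond_length * (
                    np.cos(th) * u + np.sin(th) * perp)
            else:
                dih = _resolve_dihedral(atom.dihedral, phis[r], psis[r], chis)
                refs = [resolve(x) for x in atom.refs]
                coords[k] = _place(coords[refs[0]], coords[refs[1]],
                                   coords[refs[2]], atom.ideal_bond_length,
                                   atom.ideal_bond_angle, dih)
            placed.append((r, atom.name, atom.mm_type, atom.element))
            graph.add_node(k)
        for a, b in top.bonds:
            if a in skip or b in skip:
                continue
            graph.add_edge(key(r, a), key(r, b))
        if r > 0:
            graph.add_edge(key(r - 1, "C"), key(r, "N"))

    names = [(r, nm) for (r, nm, _, _) in placed]
    return ChainConformation(
        topologies=list(topologies), phis=phis, psis=psis,
        chis=[np.asarray(c, float) for c in chis_list],
        coords=np.array([coords[k] for k in names]),
        atom_residue=np.array([r for (r, _) in names], dtype=int),
        atom_names=names,
        mm_types=[t for (_, _, t, _) in placed],
        graph=graph,
    )


def _resolve_dihedral(spec, phi, psi, chis):
    kind, k, offset = spec
    if kind == "fixed":
        return offset
    if kind == "phi":
        return phi + offset
    if kind == "psi":
        return psi + offset
    if k >= len(chis):
        raise ValueError(f"chi{k + 1} referenced but only {len(chis)} supplied")
    return chis[k] + offset


# ---------------------------------------------------------------------------
# chain energies attributed per residue

class ChainScorer:
    """Torsion and LJ terms over a chain, attributable to single residues.

    Intra terms of residue r: torsion paths whose middle bond lies within r,
    and LJ pairs with both atoms in r.  Inter LJ pairs (atoms in different
    residues) contribute half to each participant, so summing residues
    reproduces the chain total.
    """

    def __init__(self, chain: ChainConformation, params: MMParams,
                 min_bond_separation: int = 3):
        self.params = params
        idx = {k: i for i, k in enumerate(chain.atom_names)}
        g = chain.graph
        # torsion paths
        paths = set()
        for j, k in g.edges():
            for i2 in g.neighbors(j):
                if i2 == k:
                    continue
                for l2 in g.neighbors(k):
                    if l2 == j or l2 == i2:
                        continue
                    if (l2, k, j, i2) not in paths:
                        paths.add((i2, j, k, l2))
        types = {k: t for k, t in zip(chain.atom_names, chain.mm_types)}
        tp, tk, tn, tt, tres = [], [], [], [], []
        for path in sorted(paths):
            terms = params.torsion_terms(*(types[a] for a in path))
            mid = path[1][0]  # residue of the middle bond's first atom
            for (K, n, theta) in terms:
                tp.append([idx[a] for a in path])
                tk.append(K)
                tn.append(n)
                tt.append(theta)
                tres.append(mid)
        self.t_paths = np.array(tp, dtype=int).reshape(-1, 4)
        self.t_k = np.array(tk)
        self.t_n = np.array(tn)
        self.t_theta = np.radians(np.array(tt))
        self.t_res = np.array(tres, dtype=int)
        # LJ pairs
        sep = dict(nx.all_pairs_shortest_path_length(g))
        eps = {}
        rmh = {}
        for k, t in types.items():
            eps[k], rmh[k] = params.lj_params(t)
        ii, jj, pe, pr = [], [], [], []
        keys = chain.atom_names
        for a in range(len(keys)):
            da = sep[keys[a]]
            for b in range(a + 1, len(keys)):
                if da.get(keys[b], 99) >= min_bond_separation:
                    ii.append(a)
                    jj.append(b)
                    pe.append(np.sqrt(eps[keys[a]] * eps[keys[b]]))
                    pr.append(rmh[keys[a]] + rmh[keys[b]])
        self.p_i = np.array(ii, dtype=int)
        self.p_j = np.array(jj, dtype=int)
        self.p_eps = np.array(pe)
        self.p_rmin = np.array(pr)
        self.atom_residue = chain.atom_residue

    def terms(self, coords):
        """Per-pair/per-path raw energies (used by the residue attribution)."""
        from .chem import measure_dihedral
        chi = measure_dihedral(
            coords[self.t_paths[:, 0]], coords[self.t_paths[:, 1]],
            coords[self.t_paths[:, 2]], coords[self.t_paths[:, 3]],
        ) if len(self.t_paths) else np.zeros(0)
        e_tor = self.t_k * (1.0 + np.cos(self.t_n * np.radians(chi) - self.t_theta))
        d = np.linalg.norm(coords[self.p_i] - coords[self.p_j], axis=-1)
        x = (self.p_rmin / d) ** 6
        e_lj = self.p_eps * (x * x - 2.0 * x)
        below = d < self.p_rmin
        rep = np.where(below, e_lj + self.p_eps, 0.0)
        atr = np.where(below, -self.p_eps, e_lj)
        return e_tor, rep, atr

    def total(self, coords) -> float:
        e_tor, rep, atr = self.terms(coords)
        return float(e_tor.sum() + rep.sum() + atr.sum())

    def residue_breakdown(self, coords, residue: int) -> EnergyBreakdown:
        e_tor, rep, atr = self.terms(coords)
        res_i = self.atom_residue[self.p_i]
        res_j = self.atom_residue[self.p_j]
        intra = (res_i == residue) & (res_j == residue)
        inter = (res_i == residue) ^ (res_j == residue)
        return EnergyBreakdown(
            mm_torsion=float(e_tor[self.t_res == residue].sum()),
            mm_lj_intra_rep=float(rep[intra].sum()),
            mm_lj_intra_atr=float(atr[intra].sum()),
            lj_inter_rep=0.5 * float(rep[inter].sum()),
            lj_inter_atr=0.5 * float(atr[inter].sum()),
        )


# ---------------------------------------------------------------------------
# the unfolded-state estimate

@dataclass
class UnfoldedEnergyTable:
    """Residue code -> term -> mean unweighted energy over the ensemble."""

    entries: dict = field(default_factory=dict)
    ensemble_size: int = 0
    seed: int = 0

    def energy(self, code: str, weights: WeightSet) -> float:
        return unfolded_energy(code, self, weights)


def estimate_unfolded(topology: ResidueTopology, ensemble: np.ndarray,
                      params: MMParams, rotlib: RotamerLibrary,
                      weights: WeightSet | None = None,
                      flank: ResidueTopology | None = None,
                      seed: int = 0) -> dict:
    """Mean unweighted per-term energies of ``topology`` at the center of
    each fragment after repacking.

    The central residue's candidates come from the rotamer library bin
    nearest each fragment's central (phi, psi) (top-95% pruned); flanking
    residues default to alanine.  Repacking runs through the packer on the
    candidate set (with rotamer-free flanks this reduces to picking the
    lowest weighted-energy candidate, which is exactly what a packer would
    return).  Returns {term: mean energy} plus a "n" entry.
    """
    if flank is None:
        from .fixtures import load_topology
        flank = load_topology("ALA")
    weights = weights or WeightSet()
    ens = np.asarray(ensemble, dtype=float)
    if ens.ndim != 3 or ens.shape[2] != 2:
        raise ValueError("ensemble must be (n_fragments, length, 2)")
    length = ens.shape[1]
    center = length // 2
    sums = {t: 0.0 for t in EnergyBreakdown.TERMS if t != "unfolded"}
    rng = np.random.default_rng(seed)
    topos = [flank] * center + [topology] + [flank] * (length - center - 1)
    chis0 = [np.zeros(t.n_chi) for t in topos]
    # interaction tables depend only on the residue sequence: compile once
    scorer = ChainScorer(build_chain(topos, ens[0][:, 0], ens[0][:, 1], chis0),
                         params)
    for frag in ens:
        phis, psis = frag[:, 0], frag[:, 1]
        bin_ = _nearest_bin(rotlib, phis[center], psis[center])
        cands = prune_rotamers(bin_)

        def context_energy(rot):
            chis = list(chis0)
            chis[center] = rot.chi_means
            chain = build_chain(topos, phis, psis, chis)
            bd = scorer.residue_breakdown(chain.coords, center)
            return total_energy(bd, weights), bd

        one_body = np.array([context_energy(r)[0] for r in cands])
        system = PackSystem.from_energies(
            [np.zeros(1)] * center + [one_body] + [np.zeros(1)] * (length - center - 1),
            labels=[None] * center + [cands] + [None] * (length - center - 1),
        )
        system, _ = pack_rotamers(
            system, AnnealSchedule.default(system, seed=int(rng.integers(2**31))))
        best = cands[system.current[center]]
        _, bd = context_energy(best)
        for t, v in bd.as_dict().items():
            if t in sums:
                sums[t] += v
    n = len(ens)
    out = {t: v / n for t, v in sums.items()}
    out["n"] = n
    return out


def _nearest_bin(rotlib: RotamerLibrary, phi: float, psi: float):
    keys = np.array(sorted(rotlib.bins))
    d = np.abs(canonical_angle(keys - np.array([phi, psi])))
    best = np.argmin((d ** 2).sum(axis=1))
    return rotlib.bins[tuple(keys[best])]


def unfolded_energy(code: str, table: UnfoldedEnergyTable,
                    weights: WeightSet) -> float:
    """Weighted unfolded energy: sum_j w_j <E_j> for one residue type."""
    try:
        entry = table.entries[code]
    except KeyError:
        raise KeyError(f"no unfolded-state entry for residue {code!r}") from None
    bd = EnergyBreakdown(**{t: entry.get(t, 0.0)
                            for t in EnergyBreakdown.TERMS if t != "unfolded"})
    return total_energy(bd, weights)
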