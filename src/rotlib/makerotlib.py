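"""Backbone-dependent rotamer library generation for arbitrary side chains.

The protocol generates a rotamer library for one residue type from nothing but
its topology and molecular-mechanics parameters:

1. lay a grid over the (phi, psi) plane (10 degree spacing -> 1296 bins);
2. in every bin, seed dipeptide conformations at all combinations of chi
   values (5 degree spacing per chi by default);
3. relax each seed with a fixed number of steepest-descent steps, moving only
   the chi angles -- each seed falls into its nearest local minimum, which is
   exactly what a rotamer is;
4. cluster the minimized chi vectors with a circular K-means (cluster count
   and centroid seeds chosen per residue, e.g. -60/60/180 per sp3 chi);
5. the rotamer of each cluster is its lowest-energy member; a per-chi
   standard deviation is read off the energy profile (the deviation at which
   the energy rises by 0.5 kcal/mol);
6. cluster-minimum energies are converted to probabilities with a Boltzmann
   factor and normalized within the bin.

Everything is deterministic given the configuration; there is no stochastic
step in the default pipeline (the recorded seed only breaks hypothetical
ties).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .chem import ResidueTopology, MMParams, canonical_angle, fold_symmetric
from .energy import DipeptideScorer, EnergyTables

__all__ = [
    "KT_ROOM",
    "RotamerRecord",
    "RotamerLibraryBin",
    "RotamerLibrary",
    "MakeRotLibConfig",
    "phi_psi_grid",
    "seed_chi_grid",
    "minimize_chi",
    "kmeans_chi",
    "select_rotamers",
    "estimate_chi_sd",
    "energies_to_probabilities",
    "probability_to_energy",
    "build_library",
    "build_bin",
    "distinct_minima_count",
]

#: kcal/mol at T = 298 K
KT_ROOM = 0.5917

#: A below which two nonbonded atoms count as interpenetrating
HARD_CORE_DISTANCE = 1.0


# ---------------------------------------------------------------------------
# domain types

@dataclass
class RotamerRecord:
    """One rotamer: chi means/spreads, its energy and its bin probability."""

    chi_means: np.ndarray
    chi_sds: np.ndarray
    energy: float
    probability: float = 0.0
    well_labels: tuple | None = None
    cluster_size: int = 1
    sd_flat: bool = False  # sigma scan hit the cap without the energy rising

    def __post_init__(self):
        self.chi_means = np.asarray(self.chi_means, dtype=float)
        self.chi_sds = np.asarray(self.chi_sds, dtype=float)
        if not (0.0 <= self.probability <= 1.0):
            raise ValueError("probability must lie in [0, 1]")
        if np.any(self.chi_sds < 0):
            raise ValueError("chi standard deviations must be positive")

    @property
    def n_chi(self) -> int:
        return len(self.chi_means)


@dataclass
class RotamerLibraryBin:
    phi: float
    psi: float
    rotamers: list
    observations: int | None = None

    def check_normalized(self, tol: float = 1e-9) -> bool:
        return abs(sum(r.probability for r in self.rotamers) - 1.0) <= tol


@dataclass
class RotamerLibrary:
    """Backbone-dependent rotamer library: (phi, psi) -> bin of rotamers."""

    code: str
    bins: dict  # (phi, psi) -> RotamerLibraryBin
    provenance: str = "generated"  # or "knowledge-based"
    meta: dict = field(default_factory=dict)

    def bin_at(self, phi: float, psi: float) -> RotamerLibraryBin:
        key = (canonical_angle(phi), canonical_angle(psi))
        try:
            return self.bins[key]
        except KeyError:
            raise KeyError(f"{self.code}: no bin at phi={key[0]}, psi={key[1]}") from None

    def n_rotamers(self) -> int:
        counts = {len(b.rotamers) for b in self.bins.values()}
        if len(counts) != 1:
            raise ValueError(f"{self.code}: unequal rotamer counts across bins: {counts}")
        return counts.pop()


@dataclass
class MakeRotLibConfig:
    """Settings of the library-generation protocol.

    chi_seed_spacing is in degrees per chi (a scalar applies to every chi);
    centroid_seeds are the K-means starting centroids (defaults come from the
    topology's rotamer_seeds); kT sets the Boltzmann conversion temperature.
    """

    phi_psi_spacing: float = 10.0
    chi_seed_spacing: float = 5.0
    centroid_seeds: list | None = None
    min_steps: int = 25
    kmeans_max_iter: int = 500
    kT: float = KT_ROOM
    sd_energy_rise: float = 0.5
    random_seed: int = 0

    def __post_init__(self):
        if self.phi_psi_spacing <= 0 or 360.0 % self.phi_psi_spacing != 0:
            raise ValueError("phi_psi_spacing must divide 360")
        if self.kT <= 0:
            raise ValueError("kT must be positive")

    @property
    def n_clusters(self) -> int:
        if self.centroid_seeds is None:
            raise ValueError("centroid seeds are not set")
        return len(self.centroid_seeds)

    def resolved_seeds(self, topology: ResidueTopology) -> np.ndarray:
        seeds = self.centroid_seeds
        if seeds is None:
            seeds = topology.rotamer_seeds
        if seeds is None:
            raise ValueError(
                f"{topology.code}: no centroid seeds in config or topology"
            )
        arr = np.asarray(seeds, dtype=float).reshape(len(seeds), -1)
        if arr.shape[1] != topology.n_chi:
            raise ValueError(
                f"{topology.code}: centroid seeds have {arr.shape[1]} chis, "
                f"topology has {topology.n_chi}"
            )
        return arr


# ---------------------------------------------------------------------------
# grids

def phi_psi_grid(spacing: float = 10.0):
    """All (phi, psi) bins of a square grid with the given spacing.

    Bins lie in the canonical interval (-180, 180]; 10 degrees -> 1296 bins.
    """
    if spacing <= 0 or 360.0 % spacing != 0:
        raise ValueError(f"spacing {spacing} does not divide 360")
    edges = canonical_angle(np.arange(-180.0, 180.0, spacing))
    return [(float(p), float(s)) for p in edges for s in edges]


def seed_chi_grid(topology: ResidueTopology, spacing=5.0) -> np.ndarray:
    """Cartesian product of per-chi seed grids, honoring each chi's period.

    Returns an array (n_seeds, n_chi); a zero-chi topology yields the single
    empty seed (the bare backbone conformation).
    """
    spacings = np.broadcast_to(np.asarray(spacing, dtype=float), (topology.n_chi,))
    axes = []
    for period, sp in zip(topology.chi_periods, spacings):
        if sp <= 0 or period % sp != 0:
            raise ValueError(f"chi seed spacing {sp} does not divide period {period}")
        axes.append(np.arange(-180.0, -180.0 + period, sp))
    if not axes:
        return np.zeros((1, 0))
    return np.array(list(itertools.product(*axes)), dtype=float)


# ---------------------------------------------------------------------------
# chi-only minimization (batched steepest descent)

def minimize_chi(scorer: DipeptideScorer, chis, steps: int = 25,
                 initial_step: float = 5.0, shrink: float = 0.5,
                 armijo_c: float = 1e-4, max_backtracks: int = 12):
    """Relax chi angles into the nearest local minimum by steepest descent.

    ``chis`` is (n_chi,) or (B, n_chi).  Each outer step takes the
    finite-difference gradient, normalizes it, and backtracks from a 5 degree
    trial step until the Armijo condition holds; the energy never increases.
    phi, psi and all non-chi internal coordinates are untouched by
    construction (only chi values move).

    Returns (chis_min, energies) with the same leading shape.
    """
    chis = np.asarray(chis, dtype=float)
    single = chis.ndim == 1
    x = np.atleast_2d(chis).copy()
    e = np.asarray(scorer.energy(x), dtype=float).reshape(-1).copy()
    for _ in range(steps):
        g = scorer.gradient(x)
        gnorm = np.linalg.norm(g, axis=1)
        active = gnorm > 1e-12
        if not np.any(active):
            break
        d = np.zeros_like(g)
        d[active] = -g[active] / gnorm[active, None]
        t = np.full(len(x), float(initial_step))
        accepted = ~active
        for _ in range(max_backtracks):
            todo = np.flatnonzero(~accepted)
            if len(todo) == 0:
                break
            trial = x[todo] + t[todo, None] * d[todo]
            e_trial = np.asarray(scorer.energy(trial), dtype=float).reshape(-1)
            ok = e_trial <= e[todo] - armijo_c * t[todo] * gnorm[todo]
            idx = todo[ok]
            if len(idx):
                x[idx] = trial[ok]
                e[idx] = e_trial[ok]
                accepted[idx] = True
            t[~accepted] *= shrink
    x = canonical_angle(x)
    if single:
        return x[0], float(e[0])
    return x, e


# ---------------------------------------------------------------------------
# circular K-means over chi vectors

def _circ_delta(a, b, periods):
    """Minimal-image differences a - b per chi, given per-chi periods."""
    d = a - b
    return d - periods * np.round(d / periods)


def chi_vector_distance(a, b, periods) -> np.ndarray:
    """Square root of the sum of squared minimal-image chi differences."""
    d = _circ_delta(np.asarray(a, float), np.asarray(b, float),
                    np.asarray(periods, float))
    return np.sqrt((d * d).sum(axis=-1))


def kmeans_chi(points, seeds, periods, energies=None, max_iter: int = 500):
    """Circular K-means over chi vectors.

    Assignment uses the chi-vector distance (minimal image per chi);
    centroids are per-chi circular means of members.  Empty clusters are
    reseeded at the point farthest from its current centroid (deterministic).
    Iterates until no point changes cluster or ``max_iter`` sweeps.

    Returns (labels, centroids, n_iter).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or len(pts) == 0:
        raise ValueError("points must be a non-empty (N, n_chi) array")
    cent = np.asarray(seeds, dtype=float).copy()
    if len(np.unique(cent.round(9), axis=0)) != len(cent):
        raise ValueError("centroid seeds must be distinct")
    periods = np.broadcast_to(np.asarray(periods, float), (pts.shape[1],))
    labels = np.full(len(pts), -1, dtype=int)
    for it in range(1, max_iter + 1):
        d = chi_vector_distance(pts[:, None, :], cent[None, :, :], periods)
        new_labels = np.argmin(d, axis=1)
        for k in range(len(cent)):
            if not np.any(new_labels == k):
                far = np.argmax(d[np.arange(len(pts)), new_labels])
                new_labels[far] = k
        if np.array_equal(new_labels, labels):
            return labels, cent, it
        labels = new_labels
        for k in range(len(cent)):
            members = pts[labels == k]
            cent[k] = _circular_mean(members, periods)
    return labels, cent, max_iter


def _circular_mean(points, periods):
    ang = points * (2.0 * np.pi / periods)
    s = np.sin(ang).mean(axis=0)
    c = np.cos(ang).mean(axis=0)
    mean = np.arctan2(s, c) * (periods / (2.0 * np.pi))
    return np.array([fold_symmetric(m, p) for m, p in zip(np.atleast_1d(mean),
                                                          np.atleast_1d(periods))])


def select_rotamers(points, energies, labels, n_clusters: int):
    """The rotamer of each cluster is its lowest-energy member.

    Ties are broken by the smallest chi1, then chi2, ...  Returns a list of
    (chi_vector, energy, cluster_size) triples, one per cluster.
    """
    pts = np.asarray(points, dtype=float)
    es = np.asarray(energies, dtype=float)
    out = []
    for k in range(n_clusters):
        idx = np.flatnonzero(labels == k)
        if len(idx) == 0:
            raise ValueError(f"cluster {k} is empty")
        sub = idx[np.argsort(es[idx], kind="stable")]
        best = es[sub[0]]
        tied = sub[np.isclose(es[sub], best, rtol=0, atol=1e-12)]
        if len(tied) > 1:
            order = np.lexsort(tuple(pts[tied, c] for c in
                                     reversed(range(pts.shape[1]))))
            winner = tied[order[0]]
        else:
            winner = sub[0]
        out.append((pts[winner].copy(), float(es[winner]), int(len(idx))))
    return out


# ---------------------------------------------------------------------------
# per-chi standard deviations

def estimate_chi_sd(scorer: DipeptideScorer, chis, rise: float = 0.5,
                    cap: float = 60.0, scan_step: float = 0.25):
    """Angular deviation per chi at which the energy first rises by ``rise``.

    Each chi is scanned alone in both directions from the rotamer; the
    reported sigma is the mean of the +/- first crossings (linear
    interpolation between scan points).  A direction that never rises within
    ``cap`` degrees contributes the cap and sets the flat flag.

    Returns (sds, flat_flag).
    """
    chis = np.asarray(chis, dtype=float).reshape(-1)
    e0 = scorer.energy(chis)
    n_chi = len(chis)
    sds = np.empty(n_chi)
    flat = False
    offsets = np.arange(scan_step, cap + scan_step, scan_step)
    for k in range(n_chi):
        crossings = []
        for sign in (+1.0, -1.0):
            trial = np.tile(chis, (len(offsets), 1))
            trial[:, k] += sign * offsets
            de = scorer.energy(trial) - e0
            above = np.flatnonzero(de >= rise)
            if len(above) == 0:
                crossings.append(cap)
                flat = True
                continue
            i = above[0]
            if i == 0:
                frac = rise / de[0] if de[0] > 0 else 1.0
                crossings.append(float(offsets[0] * frac))
            else:
                frac = (rise - de[i - 1]) / (de[i] - de[i - 1])
                crossings.append(float(offsets[i - 1] + frac * scan_step))
        sds[k] = 0.5 * (crossings[0] + crossings[1])
    return sds, flat


# ---------------------------------------------------------------------------
# probability <-> energy

def energies_to_probabilities(energies, kT: float = KT_ROOM) -> np.ndarray:
    """Boltzmann conversion P_i = exp(-E_i / kT) / sum_j exp(-E_j / kT)."""
    if kT <= 0:
        raise ValueError("kT must be positive")
    e = np.asarray(energies, dtype=float)
    w = np.exp(-(e - e.min()) / kT)
    return w / w.sum()


def probability_to_energy(p, p_ref=None, kT: float = KT_ROOM,
                          p_floor: float = 1e-16):
    """Pseudo-energy E = -kT ln(P / P_ref) (P_ref defaults to max -> best = 0)."""
    p = np.asarray(p, dtype=float)
    p = np.clip(p, p_floor, None)
    ref = float(np.max(p)) if p_ref is None else max(float(p_ref), p_floor)
    e = -kT * np.log(p / ref)
    return float(e) if np.ndim(e) == 0 else e


# ---------------------------------------------------------------------------
# the full protocol

def build_bin(topology: ResidueTopology, params: MMParams, phi: float, psi: float,
              config: MakeRotLibConfig, tables: EnergyTables | None = None
              ) -> RotamerLibraryBin:
    """Run the generation protocol for a single (phi, psi) bin."""
    scorer = DipeptideScorer(topology, params, phi, psi, tables=tables)
    seeds = seed_chi_grid(topology, config.chi_seed_spacing)
    if topology.n_chi == 0:
        e = scorer.energy(np.zeros((1, 0)))
        rec = RotamerRecord(chi_means=np.zeros(0), chi_sds=np.zeros(0),
                            energy=float(e[0]), probability=1.0)
        return RotamerLibraryBin(phi=phi, psi=psi, rotamers=[rec])
    minimized, energies = minimize_chi(scorer, seeds, steps=config.min_steps)
    centroid_seeds = config.resolved_seeds(topology)
    labels, _, _ = kmeans_chi(minimized, centroid_seeds, topology.chi_periods,
                              max_iter=config.kmeans_max_iter)
    chosen = select_rotamers(minimized, energies, labels, len(centroid_seeds))
    probs = energies_to_probabilities([e for _, e, _ in chosen], kT=config.kT)
    rotamers = []
    for (chi, e, size), p in zip(chosen, probs):
        sds, flat = estimate_chi_sd(scorer, chi, rise=config.sd_energy_rise)
        chi_fold = np.array([fold_symmetric(c, per)
                             for c, per in zip(chi, topology.chi_periods)])
        rotamers.append(RotamerRecord(
            chi_means=chi_fold, chi_sds=sds, energy=e, probability=float(p),
            cluster_size=size, sd_flat=flat,
        ))
    rotamers.sort(key=lambda r: -r.probability)
    return RotamerLibraryBin(phi=phi, psi=psi, rotamers=rotamers)


def build_library(topology: ResidueTopology, params: MMParams,
                  config: MakeRotLibConfig | None = None,
                  bins=None, progress=None) -> RotamerLibrary:
    """Generate a backbone-dependent rotamer library.

    ``bins`` restricts generation to the given (phi, psi) pairs (default:
    the full grid of the config).  Deterministic for a fixed config.
    """
    config = config or MakeRotLibConfig()
    tables = EnergyTables(topology, params)
    if bins is None:
        bins = phi_psi_grid(config.phi_psi_spacing)
    out = {}
    for i, (phi, psi) in enumerate(bins):
        key = (canonical_angle(phi), canonical_angle(psi))
        out[key] = build_bin(topology, params, key[0], key[1], config, tables=tables)
        if progress is not None:
            progress(i + 1, len(bins), key)
    lib = RotamerLibrary(code=topology.code, bins=out, provenance="generated")
    lib.meta = {
        "topology_hash": topology.content_hash(),
        "params_hash": params.content_hash(),
        "phi_psi_spacing": config.phi_psi_spacing,
        "chi_seed_spacing": config.chi_seed_spacing,
        "min_steps": config.min_steps,
        "kT": config.kT,
        "random_seed": config.random_seed,
    }
    return lib


# ---------------------------------------------------------------------------
# model-independent minima counting (acceptance instrument)

def distinct_minima_count(topology: ResidueTopology, params: MMParams,
                          phi: float, psi: float, grid_spacing: float = 5.0,
                          merge_radius: float = 30.0, steps: int = 25,
                          return_clusters: bool = False):
    """Number of distinct chi-space local minima at one backbone bin.

    Minimizes from a dense chi seed grid and merges endpoints whose
    chi-vector distance is below ``merge_radius`` (leader clustering in
    ascending energy order, so cluster representatives are true minima).
    Independent of any cluster-count configuration.
    """
    scorer = DipeptideScorer(topology, params, phi, psi)
    seeds = seed_chi_grid(topology, grid_spacing)
    if topology.n_chi == 0:
        return 1 if not return_clusters else (1, [np.zeros(0)])
    minimized, energies = minimize_chi(scorer, seeds, steps=steps)
    # keep only endpoints that are genuine local minima along every chi axis;
    # seeds that started exactly on a barrier top (zero gradient) or ran out
    # of descent steps on a slope are not rotamer wells and are discarded
    keep = _is_axis_minimum(scorer, minimized, energies)
    # endpoints with interpenetrating atoms (hard-core overlap) are geometric
    # artifacts of descent through a clash, not conformations
    coords = scorer.coords(minimized)
    keep &= np.asarray(scorer.tables.min_distance(coords)) >= HARD_CORE_DISTANCE
    minimized, energies = minimized[keep], energies[keep]
    order = np.argsort(energies, kind="stable")
    periods = np.asarray(topology.chi_periods, float)
    reps = []
    for i in order:
        x = minimized[i]
        if not any(chi_vector_distance(x, r, periods) < merge_radius for r in reps):
            reps.append(x)
    if return_clusters:
        return len(reps), reps
    return len(reps)


def _is_axis_minimum(scorer: DipeptideScorer, chis: np.ndarray,
                     energies: np.ndarray, probe: float = 1.0,
                     slack: float = 1e-9) -> np.ndarray:
    """True where no single-chi probe of +-``probe`` degrees lowers the energy."""
    ok = np.ones(len(chis), dtype=bool)
    for k in range(chis.shape[1]):
        for sign in (+1.0, -1.0):
            trial = chis.copy()
            trial[:, k] += sign * probe
            ok &= np.asarray(scorer.energy(trial)) >= energies - slack
    return ok
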