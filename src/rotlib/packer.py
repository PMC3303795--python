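"""Discrete side-chain optimization over rotamer libraries.

The packing problem is posed on precomputed energies: every position carries a
candidate rotamer list with one-body energies, and interacting position pairs
carry a two-body energy matrix.  ``pack_rotamers`` runs a simulated-annealing
Metropolis search over rotamer substitutions (best-seen state is tracked and
returned); ``rotamer_trials`` greedily re-optimizes flagged positions one at a
time in seeded random order.  ``small_move``/``shear_move`` are the standard
backbone perturbations (a single phi-or-psi rotation of up to 3 degrees, or a
compensated phi/psi(-1) pair), and ``design_peptide`` composes the primitives
into the perturb-then-design loop used for single peptides.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .makerotlib import KT_ROOM, RotamerLibraryBin
from .compare import top95_set

__all__ = [
    "PackSystem",
    "AnnealSchedule",
    "Backbone",
    "prune_rotamers",
    "pack_rotamers",
    "rotamer_trials",
    "small_move",
    "shear_move",
    "design_peptide",
]


def prune_rotamers(bin_: RotamerLibraryBin, mass: float = 0.95) -> list:
    """Top-95% probability pruning (shared with the comparison metric)."""
    return top95_set(bin_, mass=mass)


# ---------------------------------------------------------------------------
# the packing system

@dataclass
class PackSystem:
    """Positions x candidate rotamers with cached one- and two-body energies.

    ``one_body[i]`` has shape (n_rot_i,); ``pair[(i, j)]`` (i < j) has shape
    (n_rot_i, n_rot_j).  ``current`` holds the selected rotamer index per
    position.
    """

    one_body: list
    pair: dict
    current: list
    labels: list | None = None  # arbitrary per-position payloads (rotamers)

    @classmethod
    def from_energies(cls, one_body, pair=None, current=None, labels=None):
        one_body = [np.asarray(e, dtype=float) for e in one_body]
        if any(len(e) == 0 for e in one_body):
            raise ValueError("every position needs at least one candidate rotamer")
        norm_pair = {}
        for (i, j), m in (pair or {}).items():
            if i == j:
                raise ValueError("pair energies need two distinct positions")
            if i > j:
                i, j, m = j, i, np.asarray(m, dtype=float).T
            m = np.asarray(m, dtype=float)
            if m.shape != (len(one_body[i]), len(one_body[j])):
                raise ValueError(f"pair ({i},{j}) matrix has wrong shape {m.shape}")
            norm_pair[(i, j)] = m
        current = list(current) if current is not None else [0] * len(one_body)
        for i, c in enumerate(current):
            if not (0 <= c < len(one_body[i])):
                raise ValueError(f"current rotamer index {c} invalid at position {i}")
        return cls(one_body=one_body, pair=norm_pair, current=current, labels=labels)

    @property
    def n_positions(self) -> int:
        return len(self.one_body)

    def neighbors(self, i):
        for (a, b) in self.pair:
            if a == i:
                yield b
            elif b == i:
                yield a

    def pair_energy(self, i, ri, j, rj) -> float:
        if i > j:
            i, j, ri, rj = j, i, rj, ri
        m = self.pair.get((i, j))
        return float(m[ri, rj]) if m is not None else 0.0

    def total_energy(self, assignment=None) -> float:
        a = self.current if assignment is None else list(assignment)
        e = sum(float(self.one_body[i][a[i]]) for i in range(self.n_positions))
        e += sum(float(m[a[i], a[j]]) for (i, j), m in self.pair.items())
        return e

    def delta_energy(self, i, new_rot, assignment=None) -> float:
        """Energy change of substituting rotamer ``new_rot`` at position i."""
        a = self.current if assignment is None else assignment
        old = a[i]
        d = float(self.one_body[i][new_rot] - self.one_body[i][old])
        for j in self.neighbors(i):
            d += self.pair_energy(i, new_rot, j, a[j]) - \
                self.pair_energy(i, old, j, a[j])
        return d

    def position_energies(self, i, assignment=None) -> np.ndarray:
        """Context energy of every candidate at position i, neighbors fixed."""
        a = self.current if assignment is None else assignment
        e = self.one_body[i].copy()
        for j in self.neighbors(i):
            if i < j:
                e += self.pair[(i, j)][:, a[j]]
            else:
                e += self.pair[(j, i)][a[j], :]
        return e


@dataclass
class AnnealSchedule:
    """Simulated-annealing temperature ladder (kcal/mol)."""

    temperatures: np.ndarray
    moves_per_temp: int
    seed: int = 0

    def __post_init__(self):
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        if np.any(self.temperatures <= 0):
            raise ValueError("temperatures must be positive")
        if np.any(np.diff(self.temperatures) >= 0):
            raise ValueError("temperatures must be strictly decreasing")

    @classmethod
    def default(cls, system: PackSystem, kT: float = KT_ROOM, levels: int = 8,
                hot: float = 10.0, cold: float = 0.1, seed: int = 0):
        temps = kT * np.geomspace(hot, cold, levels)
        n_rot = max(len(e) for e in system.one_body)
        return cls(temperatures=temps,
                   moves_per_temp=system.n_positions * n_rot, seed=seed)


def pack_rotamers(system: PackSystem, schedule: AnnealSchedule | None = None):
    """Simulated-annealing Metropolis optimization of the rotamer assignment.

    A move substitutes a random candidate at a random position and is
    accepted per Metropolis; the best assignment ever seen is restored at the
    end.  Deterministic under the schedule seed.

    Returns (system, best_energy); the system's ``current`` holds the result.
    """
    if schedule is None:
        schedule = AnnealSchedule.default(system)
    rng = np.random.default_rng(schedule.seed)
    a = list(system.current)
    e = system.total_energy(a)
    best_a, best_e = list(a), e
    for T in schedule.temperatures:
        for _ in range(schedule.moves_per_temp):
            i = int(rng.integers(system.n_positions))
            n_cand = len(system.one_body[i])
            if n_cand == 1:
                continue
            r = int(rng.integers(n_cand))
            if r == a[i]:
                continue
            d = system.delta_energy(i, r, a)
            if d <= 0 or rng.random() < np.exp(-d / T):
                a[i] = r
                e += d
                if e < best_e - 1e-12:
                    best_a, best_e = list(a), e
    system.current = best_a
    return system, float(system.total_energy(best_a))


def rotamer_trials(system: PackSystem, increased_flags, seed: int = 0):
    """Greedy context-optimal replacement at each flagged position.

    Flagged positions are visited in seeded random order; at its visit each
    holds the argmin candidate given the current rotamers elsewhere, so the
    total energy never increases over the sweep.
    """
    flags = list(increased_flags)
    if len(flags) != system.n_positions:
        raise ValueError("one flag per position required")
    order = [i for i in range(system.n_positions) if flags[i]]
    rng = np.random.default_rng(seed)
    rng.shuffle(order)
    for i in order:
        system.current[i] = int(np.argmin(system.position_energies(i)))
    return system


# ---------------------------------------------------------------------------
# backbone moves

@dataclass
class Backbone:
    """Peptide backbone torsions (degrees) for a run of residues."""

    phis: np.ndarray
    psis: np.ndarray

    def __post_init__(self):
        self.phis = np.asarray(self.phis, dtype=float)
        self.psis = np.asarray(self.psis, dtype=float)
        if self.phis.shape != self.psis.shape or self.phis.ndim != 1:
            raise ValueError("phis and psis must be 1-D arrays of equal length")

    def __len__(self):
        return len(self.phis)


def small_move(backbone: Backbone, max_angle: float = 3.0, seed: int = 0):
    """Rotate phi or psi of one random residue by up to ``max_angle`` degrees.

    Returns (new backbone, changed residue index).
    """
    rng = np.random.default_rng(seed)
    i = int(rng.integers(len(backbone)))
    which = rng.integers(2)
    delta = rng.uniform(-max_angle, max_angle)
    phis, psis = backbone.phis.copy(), backbone.psis.copy()
    if which == 0:
        phis[i] += delta
    else:
        psis[i] += delta
    return Backbone(phis=phis, psis=psis), i


def shear_move(backbone: Backbone, max_angle: float = 3.0, seed: int = 0):
    """Rotate phi of residue i and psi of residue i-1 by opposite amounts.

    Requires at least two residues.  Returns (new backbone, residue index i).
    """
    if len(backbone) < 2:
        raise ValueError("shear move needs at least two residues")
    rng = np.random.default_rng(seed)
    i = int(rng.integers(1, len(backbone)))
    delta = rng.uniform(-max_angle, max_angle)
    phis, psis = backbone.phis.copy(), backbone.psis.copy()
    phis[i] += delta
    psis[i - 1] -= delta
    return Backbone(phis=phis, psis=psis), i


# ---------------------------------------------------------------------------
# composed design loop

def design_peptide(backbone: Backbone, system_builder, seed: int = 0,
                   iterations: int = 50, perturb_cycles: int = 100,
                   max_angle: float = 3.0):
    """Iterate backbone perturbation and rotamer design for one peptide.

    ``system_builder(backbone) -> PackSystem`` supplies the (pluggable)
    energy model.  Each iteration runs ``perturb_cycles`` perturbations (a
    small or shear move followed by rotamer trials on positions whose context
    energy increased) and one design phase (pack_rotamers).  Rigid-body moves
    and Cartesian minimization are out of scope.

    Returns (best backbone, best PackSystem, best energy).
    """
    rng = np.random.default_rng(seed)
    system = system_builder(backbone)
    system, energy = pack_rotamers(
        system, AnnealSchedule.default(system, seed=int(rng.integers(2**31))))
    best = (backbone, system, energy)
    for _ in range(iterations):
        for _ in range(perturb_cycles):
            mover = shear_move if (len(backbone) > 1 and rng.random() < 0.5) \
                else small_move
            new_backbone, _ = mover(backbone, max_angle=max_angle,
                                    seed=int(rng.integers(2**31)))
            new_system = system_builder(new_backbone)
            new_system.current = list(system.current)
            before = [system.position_energies(i)[system.current[i]]
                      for i in range(system.n_positions)]
            after = [new_system.position_energies(i)[new_system.current[i]]
                     for i in range(new_system.n_positions)]
            flags = [a > b for a, b in zip(after, before)]
            rotamer_trials(new_system, flags, seed=int(rng.integers(2**31)))
            backbone, system = new_backbone, new_system
        system, energy = pack_rotamers(
            system, AnnealSchedule.default(system, seed=int(rng.integers(2**31))))
        if energy < best[2]:
            best = (backbone, system, energy)
    return best
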