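"""Agreement metrics between two backbone-dependent rotamer libraries.

A generated library is validated against a knowledge-based reference by
asking, bin by bin: of the rotamers that make up the top 95% of the generated
library's probability mass, what fraction sits within 30 degrees (chi-vector
distance) of a rotamer in the reference's own top-95% set?  Matching is
one-to-one; bins where the reference has too few observations (<= 10) are
excluded from summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .makerotlib import RotamerLibrary, RotamerLibraryBin, chi_vector_distance

__all__ = [
    "OverlapResult",
    "OverlapSummary",
    "top95_set",
    "chi_distance",
    "percent_overlap",
    "summarize",
]


@dataclass
class OverlapResult:
    phi: float
    psi: float
    percent_overlap: float | None  # None when either top-95% set is empty
    matched_pairs: list  # (gen RotamerRecord, ref RotamerRecord, distance deg)
    reference_observations: int | None = None

    @property
    def defined(self) -> bool:
        return self.percent_overlap is not None

    def mean_distance(self) -> float:
        if not self.matched_pairs:
            return float("nan")
        return float(np.mean([d for (_, _, d) in self.matched_pairs]))


@dataclass
class OverlapSummary:
    code: str
    n_bins: int
    overlap_low: float
    overlap_high: float
    overlap_mean: float
    distance_low: float
    distance_high: float
    distance_mean: float

    def __post_init__(self):
        if not (self.overlap_low <= self.overlap_mean <= self.overlap_high):
            raise ValueError("summary ordering violated (low <= mean <= high)")


def top95_set(bin_: RotamerLibraryBin, mass: float = 0.95) -> list:
    """Minimal most-probable prefix whose cumulative probability reaches 95%.

    Rotamers are taken in descending probability; the boundary rotamer that
    reaches the threshold is included.  Ties keep the original bin order.
    """
    order = sorted(range(len(bin_.rotamers)),
                   key=lambda i: (-bin_.rotamers[i].probability, i))
    out, cum = [], 0.0
    for i in order:
        out.append(bin_.rotamers[i])
        cum += bin_.rotamers[i].probability
        if cum >= mass - 1e-12:
            break
    return out


def chi_distance(a, b, periods=None) -> float:
    """Chi-vector distance: sqrt of the sum of squared minimal-image
    differences between corresponding chi angles (degrees)."""
    ca = np.asarray(getattr(a, "chi_means", a), dtype=float)
    cb = np.asarray(getattr(b, "chi_means", b), dtype=float)
    if ca.shape != cb.shape:
        raise ValueError(f"chi count mismatch: {ca.shape} vs {cb.shape}")
    if periods is None:
        periods = np.full(ca.shape, 360.0)
    return float(chi_vector_distance(ca, cb, np.asarray(periods, dtype=float)))


def percent_overlap(gen_bin: RotamerLibraryBin, ref_bin: RotamerLibraryBin,
                    threshold: float = 30.0, periods=None) -> OverlapResult:
    """Fraction of the generated top-95% set matched one-to-one within the
    distance threshold, as a percentage of the generated set size.

    Matching is greedy by ascending distance; each reference rotamer matches
    at most once.
    """
    gen = top95_set(gen_bin)
    ref = top95_set(ref_bin)
    if not gen or not ref:
        return OverlapResult(phi=gen_bin.phi, psi=gen_bin.psi,
                             percent_overlap=None, matched_pairs=[],
                             reference_observations=ref_bin.observations)
    cand = []
    for i, g in enumerate(gen):
        for j, r in enumerate(ref):
            d = chi_distance(g, r, periods)
            if d < threshold:
                cand.append((d, i, j))
    cand.sort(key=lambda t: (t[0], t[1], t[2]))
    used_g, used_r, pairs = set(), set(), []
    for d, i, j in cand:
        if i in used_g or j in used_r:
            continue
        used_g.add(i)
        used_r.add(j)
        pairs.append((gen[i], ref[j], d))
    return OverlapResult(
        phi=gen_bin.phi, psi=gen_bin.psi,
        percent_overlap=100.0 * len(pairs) / len(gen),
        matched_pairs=pairs,
        reference_observations=ref_bin.observations,
    )


def summarize(gen_lib: RotamerLibrary, ref_lib: RotamerLibrary,
              min_observations: int = 10, threshold: float = 30.0,
              periods=None):
    """Per-residue lowest/highest/average overlap and matched-pair RMS
    distance over qualifying bins (reference observations strictly greater
    than ``min_observations``).

    Returns (OverlapSummary, per-bin OverlapResult list).
    """
    shared = sorted(set(gen_lib.bins) & set(ref_lib.bins))
    results = []
    for key in shared:
        ref_bin = ref_lib.bins[key]
        if ref_bin.observations is not None and ref_bin.observations <= min_observations:
            continue
        res = percent_overlap(gen_lib.bins[key], ref_bin, threshold, periods)
        if res.defined:
            results.append(res)
    if not results:
        raise ValueError(
            f"no qualifying bins shared by {gen_lib.code} and {ref_lib.code}"
        )
    overlaps = np.array([r.percent_overlap for r in results])
    dists = np.array([r.mean_distance() for r in results if r.matched_pairs])
    if len(dists) == 0:
        dists = np.array([float("nan")])
    summary = OverlapSummary(
        code=gen_lib.code,
        n_bins=len(results),
        overlap_low=float(overlaps.min()),
        overlap_high=float(overlaps.max()),
        overlap_mean=float(overlaps.mean()),
        distance_low=float(np.nanmin(dists)),
        distance_high=float(np.nanmax(dists)),
        distance_mean=float(np.nanmean(dists)),
    )
    return summary, results
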