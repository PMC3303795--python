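"""Reading and writing backbone-dependent rotamer libraries.

The columnar dialect follows the widely used knowledge-based (Dunbrack
2002-style) backbone-dependent library layout::

    RES  phi  psi  count  r1 r2 r3 r4  probability  chi1..chi4  sig1..sig4

with ``#`` comments, whitespace-separated columns, angles in degrees and one
row per rotamer.  Residues with fewer than four chis fill the unused chi/sigma
columns with 0, per the common published convention.  Both space- and
tab-separated files parse (any whitespace run splits columns).
"""

from __future__ import annotations

import warnings

import numpy as np

from .chem import canonical_angle
from .makerotlib import RotamerLibrary, RotamerLibraryBin, RotamerRecord

__all__ = ["DialectError", "LibraryParseError", "read_bbdep", "write_library"]

MAX_CHI = 4


class DialectError(ValueError):
    """Raised when a library cannot be represented in the file dialect."""


class LibraryParseError(ValueError):
    """Raised for malformed library files (message carries the line number)."""


_N_COLUMNS = 4 + MAX_CHI + 1 + MAX_CHI + MAX_CHI  # 17


def _round_preserving_sum(values, decimals):
    """Round to ``decimals`` places such that the rounded values keep the
    original sum (largest-remainder adjustment on the biggest entry)."""
    scale = 10 ** decimals
    rounded = [round(v * scale) for v in values]
    drift = round(sum(values) * scale) - sum(rounded)
    if drift and rounded:
        rounded[int(np.argmax(rounded))] += drift
    return [r / scale for r in rounded]


def _well_label(chi: float) -> int:
    """1/2/3 well id per the m/p/t convention (gauche-, gauche+, trans)."""
    c = canonical_angle(chi)
    if -120.0 < c <= 0.0:
        return 3  # minus (gauche-)
    if 0.0 < c <= 120.0:
        return 2  # plus (gauche+)
    return 1  # trans


def write_library(lib: RotamerLibrary, path, codes_upper: bool = True) -> None:
    """Write a rotamer library in the bbdep-style dialect.

    Row order is deterministic: phi, then psi, then descending probability.
    Header comments record provenance (topology/parameter hashes, config).
    """
    n_chi = {r.n_chi for b in lib.bins.values() for r in b.rotamers}
    if len(n_chi) != 1:
        raise DialectError("library mixes rotamers with different chi counts")
    n_chi = n_chi.pop()
    if n_chi > MAX_CHI:
        raise DialectError(
            f"dialect caps at chi{MAX_CHI}; library has {n_chi} chis"
        )
    code = lib.code.upper() if codes_upper else lib.code
    with open(path, "w") as fh:
        fh.write(f"# rotamer library for {code} ({lib.provenance})\n")
        for key in sorted(lib.meta):
            fh.write(f"# {key}: {lib.meta[key]}\n")
        for (phi, psi) in sorted(lib.bins):
            b = lib.bins[(phi, psi)]
            total = sum(r.probability for r in b.rotamers)
            if abs(total - 1.0) > 1e-6:
                raise DialectError(
                    f"bin ({phi}, {psi}) probabilities sum to {total}, not 1"
                )
            rows = sorted(b.rotamers, key=lambda r: -r.probability)
            probs = _round_preserving_sum([r.probability for r in rows], 4)
            for r, p in zip(rows, probs):
                chis = list(np.round(r.chi_means, 1)) + [0.0] * (MAX_CHI - n_chi)
                sds = list(np.round(r.chi_sds, 1)) + [0.0] * (MAX_CHI - n_chi)
                wells = [_well_label(c) for c in r.chi_means] + [0] * (MAX_CHI - n_chi)
                obs = b.observations if b.observations is not None else 0
                fh.write(
                    f"{code:<5s} {phi:6.0f} {psi:5.0f} {obs:5d}  "
                    + " ".join(str(w) for w in wells)
                    + f"  {p:8.4f} "
                    + " ".join(f"{c:7.1f}" for c in chis)
                    + "  "
                    + " ".join(f"{s:6.1f}" for s in sds)
                    + "\n"
                )


def read_bbdep(path, n_chi: int | None = None) -> RotamerLibrary:
    """Read a bbdep-style rotamer library file.

    Rows with a phi of -180 are canonicalized to +180 (duplicated boundary
    rows in some published files are dropped in favor of the canonical bin).
    Bin probabilities that sum to something other than 1 (beyond 1e-6) are
    renormalized with a warning.  ``n_chi`` truncates the chi columns; by
    default trailing all-zero chi columns are trimmed file-wide.
    """
    rows = []
    codes = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != _N_COLUMNS:
                raise LibraryParseError(
                    f"{path}: line {lineno}: expected {_N_COLUMNS} columns, "
                    f"got {len(parts)}"
                )
            try:
                code = parts[0]
                phi, psi = float(parts[1]), float(parts[2])
                obs = int(parts[3])
                prob = float(parts[8])
                chis = [float(x) for x in parts[9:13]]
                sds = [float(x) for x in parts[13:17]]
            except ValueError as e:
                raise LibraryParseError(f"{path}: line {lineno}: {e}") from e
            rows.append((code, canonical_angle(phi), canonical_angle(psi),
                         obs, prob, chis, sds))
            codes.add(code)
    if not rows:
        raise LibraryParseError(f"{path}: no data rows")
    if len(codes) > 1:
        main = rows[0][0]
        warnings.warn(
            f"{path}: multiple residue codes {sorted(codes)}; keeping {main!r}",
            stacklevel=2,
        )
        rows = [r for r in rows if r[0] == main]
    code = rows[0][0]
    if n_chi is None:
        n_chi = 0
        for r in rows:
            nz = [k for k in range(MAX_CHI) if r[5][k] != 0.0 or r[6][k] != 0.0]
            n_chi = max(n_chi, max(nz) + 1 if nz else 0)
        n_chi = max(n_chi, 1)
    bins: dict = {}
    for (_, phi, psi, obs, prob, chis, sds) in rows:
        key = (phi, psi)
        rec = RotamerRecord(
            chi_means=np.array(chis[:n_chi]),
            chi_sds=np.maximum(np.array(sds[:n_chi]), 1e-6),
            energy=0.0,
            probability=min(max(prob, 0.0), 1.0),
        )
        b = bins.setdefault(key, RotamerLibraryBin(phi=phi, psi=psi, rotamers=[],
                                                   observations=obs))
        b.rotamers.append(rec)
    for key, b in bins.items():
        total = sum(r.probability for r in b.rotamers)
        if total <= 0:
            raise LibraryParseError(f"{path}: bin {key} has zero probability mass")
        if abs(total - 1.0) > 1e-6:
            warnings.warn(
                f"{path}: bin {key} probabilities sum to {total:.6f}; renormalizing",
                stacklevel=2,
            )
        for r in b.rotamers:
            r.probability /= total
    return RotamerLibrary(code=code, bins=bins, provenance="knowledge-based")
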