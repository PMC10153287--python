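"""High-order repeat annotation and unit deduplication.

A reconstructed unit may itself be a tandem of diverged monomers — a
high-order repeat (HOR), like the ~171 bp alpha monomers whose 4-to-18-monomer
units tile human centromeres. The period detector decomposes a unit into
near-exact p-periodic blocks and applies the HOR criterion: a unit is a HOR
when some internal period repeats at least three times and the decomposition
covers at least 90% of the unit.

Greedy reconstruction can also emit near-identical variants of the same
repeat family. Two units are considered equivalent when the shorter aligns
into (a doubled copy of) the longer, over any rotation and either strand, at
under 2% edit divergence; deduplication keeps the variant of highest mean
k-mer count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple, Union

import numpy as np

from .graph import RepeatUnit
from .kmers import revcomp

#: a period qualifies as a HOR monomer only with >= 3 copies ...
HOR_MIN_COPIES = 3.0
#: ... covering >= 90% of the unit.
HOR_MIN_COVERAGE = 0.90


@dataclass
class HORAnnotation:
    """Internal structure of one unit and its HOR verdict."""

    unit_id: str
    monomer_len: int
    n_monomers: float
    coverage: float
    is_hor: bool


@dataclass
class DedupParams:
    """Units closer than ``max_divergence`` (default 2%) are merged."""

    max_divergence: float = 0.02


def _edit_distance(a: str, b: str, max_ed: int) -> int:
    """Banded global edit distance; -1 if above *max_ed*."""
    import edlib

    return edlib.align(a, b, mode="NW", task="distance", k=max_ed)["editDistance"]


def _block_coverage(seq: str, p: int, block_tol: float) -> float:
    """Fraction of *seq* assigned to near-exact p-periodic blocks.

    The unit is cut into consecutive p-blocks (plus a remainder that wraps
    circularly onto the first block); a block is covered when it matches a
    neighbouring block within a banded edit distance of ``block_tol * p`` —
    HOR monomer copies are similar but rarely identical, so exact matching
    would be too strict.
    """
    n = len(seq)
    m = n // p
    r = n - m * p
    blocks = [seq[i * p : (i + 1) * p] for i in range(m)]
    tol = max(1, int(block_tol * p))
    nxt = [
        _edit_distance(blocks[i], blocks[i + 1], tol) >= 0 for i in range(m - 1)
    ]
    covered = 0
    for i in range(m):
        if (i > 0 and nxt[i - 1]) or (i < m - 1 and nxt[i]):
            covered += p
    if r:
        rem = seq[m * p :]
        rtol = max(1, int(block_tol * r))
        if m and _edit_distance(rem, blocks[0][:r], rtol) >= 0:
            covered += r
    return covered / n


def detect_period(
    unit: Union[RepeatUnit, str],
    *,
    min_match_frac: float = 0.8,
    block_tol: float = 0.2,
    min_coverage: float = HOR_MIN_COVERAGE,
) -> List[Tuple[int, float, float]]:
    """Candidate internal periods of a unit.

    Every period ``1 <= p <= len/2`` is screened by the fraction of circular
    positions i with ``base(i) == base(i + p)``; survivors are refined by the
    block decomposition above. Returns ``(monomer_len, coverage, n_monomers)``
    tuples with coverage >= *min_coverage*, ascending in period; an aperiodic
    unit yields an empty list. Multiples of a true period typically also
    qualify, so callers wanting the minimal monomer take the first entry.
    """
    seq = unit.seq if isinstance(unit, RepeatUnit) else str(unit)
    n = len(seq)
    if n < 2:
        return []
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out: List[Tuple[int, float, float]] = []
    for p in range(1, n // 2 + 1):
        frac = float(np.mean(arr == np.roll(arr, -p)))
        if frac < min_match_frac:
            continue
        cov = _block_coverage(seq, p, block_tol)
        if cov >= min_coverage:
            out.append((p, cov, n / p))
    return out


def classify_hor(unit: Union[RepeatUnit, str], unit_id: str = "") -> HORAnnotation:
    """HOR verdict for one unit.

    Takes the smallest period with at least 3 monomer copies and >= 90%
    coverage; with no qualifying period the unit is its own monomer
    (``n_monomers = 1``, not a HOR).
    """
    seq = unit.seq if isinstance(unit, RepeatUnit) else str(unit)
    uid = unit_id or (unit.id if isinstance(unit, RepeatUnit) else "unit")
    for p, cov, nm in detect_period(unit):
        if nm >= HOR_MIN_COPIES and cov >= HOR_MIN_COVERAGE:
            return HORAnnotation(uid, monomer_len=p, n_monomers=nm, coverage=cov, is_hor=True)
    return HORAnnotation(uid, monomer_len=len(seq), n_monomers=1.0, coverage=1.0, is_hor=False)


def unit_divergence(a: Union[RepeatUnit, str], b: Union[RepeatUnit, str]) -> float:
    """Minimum edit divergence of the shorter unit against the longer one,
    over all rotations and both strands.

    Rotations are handled by aligning the shorter sequence as an infix of
    the doubled longer sequence; the result is edit distance divided by the
    shorter length. Zero iff the two units are circular/strand equivalent.
    """
    import edlib

    sa = a.seq if isinstance(a, RepeatUnit) else str(a)
    sb = b.seq if isinstance(b, RepeatUnit) else str(b)
    if len(sa) > len(sb):
        sa, sb = sb, sa
    if not sa:
        raise ValueError("cannot compare an empty unit")
    target = sb + sb
    best = None
    for q in (sa, revcomp(sa)):
        ed = edlib.align(q, target, mode="HW", task="distance")["editDistance"]
        if best is None or ed < best:
            best = ed
    return best / len(sa)


def dedup_units(
    units: Sequence[RepeatUnit],
    params: DedupParams = DedupParams(),
) -> Tuple[List[RepeatUnit], Dict[str, str]]:
    """Merge near-identical units.

    Units are considered in descending mean-count order; each is merged into
    the first already-kept unit it diverges from by less than
    ``params.max_divergence``, recorded in the merge map, else kept.
    """
    ordered = sorted(units, key=lambda u: (-u.mean_count, u.id))
    kept: List[RepeatUnit] = []
    merge_map: Dict[str, str] = {}
    for u in ordered:
        for v in kept:
            if unit_divergence(u, v) < params.max_divergence:
                merge_map[u.id] = v.id
                break
        else:
            kept.append(u)
    kept.sort(key=lambda u: u.id)
    return kept, merge_map


def write_hor_tsv(annotations: Iterable[HORAnnotation], path: str) -> None:
    with open(path, "wt") as fh:
        fh.write("unit_id\tmonomer_len\tn_monomers\tcoverage\tis_hor\n")
        for a in annotations:
            fh.write(
                f"{a.unit_id}\t{a.monomer_len}\t{a.n_monomers:.2f}\t"
                f"{a.coverage:.3f}\t{str(a.is_hor).lower()}\n"
            )
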