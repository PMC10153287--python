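"""Satellite abundance estimation from unit-to-sequence alignments.

The greedy reconstruction says nothing about how much of the input a repeat
unit explains. Abundance is measured by aligning the input sequences against
the reconstructed units (normally with minimap2 against *enlonged* units so
alignments can span the circular junction; a naive built-in scanner covers
small test inputs) and then filtering the hits:

1. hits below 90% identity are dropped (diverged scattered monomers would
   otherwise inflate the estimate);
2. same-unit hits separated by at most ``merge_gap`` bases are merged;
3. where different units claim the same bases, the highest-identity interval
   wins and lower ones are trimmed, so each input base maps to at most one
   unit;
4. intervals with fewer than 2 tandem copies in the middle of a sequence, or
   fewer than 1.5 copies when the interval reaches a sequence end, are
   dropped — this removes tandemly duplicated interspersed repeats (e.g.
   LTRs) that are not satellite arrays, at the cost of underestimating units
   longer than the reads.

The surviving intervals give per-unit total bases and the fraction of input
bases, the quantities reported in the abundance table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .graph import RepeatUnit
from .kmers import revcomp

#: minimap2 invocation recommended for real data (units enlonged first).
SUGGESTED_ALIGNER_CMD = "minimap2 -c -N1000000 -f1000 -r100,100 <input.fa> <units.enlong.fa>"

DEFAULT_ENLONG_TARGET = 20_000


@dataclass
class FilterParams:
    """Alignment filter constants.

    ``min_identity`` 0.90, tandem-copy cuts 2.0 (internal) / 1.5 (interval
    reaching a sequence end), ``merge_gap`` 100 bp (matches the small
    alignment bandwidth used with the external aligner). An interval
    "reaches an end" when it starts or ends within ``merge_gap`` of the
    sequence boundary.
    """

    min_identity: float = 0.90
    min_copies_internal: float = 2.0
    min_copies_at_end: float = 1.5
    merge_gap: int = 100


@dataclass
class AlignmentHit:
    """One unit-to-sequence alignment record with PAF semantics."""

    unit_id: str
    target_name: str
    target_len: int
    target_start: int
    target_end: int  # 0-based half-open
    strand: str  # '+' or '-'
    matches: int
    align_len: int
    query_len: int = 0
    query_start: int = 0
    query_end: int = 0
    mapq: int = 60

    @property
    def identity(self) -> float:
        return self.matches / self.align_len if self.align_len else 0.0


@dataclass
class MergedInterval:
    """A filtered, merged, per-base-unique satellite interval."""

    target_name: str
    start: int
    end: int
    unit_id: str
    mean_identity: float
    copies: float
    touches_end: bool

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class AbundanceReport:
    """Per-unit aligned bases and fraction of total input bases."""

    per_unit_bases: Dict[str, int]
    fractions: Dict[str, float]
    total_input_bases: int
    total_satellite_bases: int

    @property
    def total_fraction(self) -> float:
        if self.total_input_bases == 0:
            return 0.0
        return self.total_satellite_bases / self.total_input_bases


class PafFormatError(ValueError):
    """A PAF file is malformed; the message names the line."""


def enlong(unit, target_min_len: Optional[int] = None) -> str:
    """Concatenate a circular unit with itself so linear alignments can span
    the junction: at least two copies, and at least *target_min_len* bases
    (default: max(20 kb, twice the unit length))."""
    seq = unit.seq if isinstance(unit, RepeatUnit) else str(unit)
    if not seq:
        raise ValueError("cannot enlong an empty unit")
    if target_min_len is None:
        target_min_len = max(DEFAULT_ENLONG_TARGET, 2 * len(seq))
    if target_min_len < len(seq):
        raise ValueError("target_min_len must be >= unit length")
    copies = max(2, math.ceil(target_min_len / len(seq)))
    return seq * copies


# ---------------------------------------------------------------------------
# PAF I/O


def read_paf(path: str) -> List[AlignmentHit]:
    """Parse a PAF file into alignment hits.

    Identity is residue matches (column 10) over alignment block length
    (column 11). The query is expected to be a (possibly enlonged) repeat
    unit; its name is taken as the unit id.
    """
    hits: List[AlignmentHit] = []
    with open(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise PafFormatError(f"line {lineno}: expected >= 12 columns, got {len(f)}")
            try:
                hit = AlignmentHit(
                    unit_id=f[0],
                    query_len=int(f[1]),
                    query_start=int(f[2]),
                    query_end=int(f[3]),
                    strand=f[4],
                    target_name=f[5],
                    target_len=int(f[6]),
                    target_start=int(f[7]),
                    target_end=int(f[8]),
                    matches=int(f[9]),
                    align_len=int(f[10]),
                    mapq=int(f[11]),
                )
            except ValueError as exc:
                raise PafFormatError(f"line {lineno}: {exc}") from None
            if hit.strand not in "+-":
                raise PafFormatError(f"line {lineno}: bad strand {hit.strand!r}")
            if not (0 <= hit.target_start < hit.target_end <= hit.target_len):
                raise PafFormatError(f"line {lineno}: bad target interval")
            hits.append(hit)
    return hits


def write_paf(hits: Iterable[AlignmentHit], path: str) -> None:
    with open(path, "wt") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.unit_id,
                        h.query_len,
                        h.query_start,
                        h.query_end,
                        h.strand,
                        h.target_name,
                        h.target_len,
                        h.target_start,
                        h.target_end,
                        h.matches,
                        h.align_len,
                        h.mapq,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Naive built-in aligner (tests and small inputs only)


def naive_align(
    units: Sequence[RepeatUnit],
    targets: Iterable[Tuple[str, str]],
    *,
    max_scan_divergence: float = 0.25,
    min_pattern_len: int = 120,
) -> List[AlignmentHit]:
    """Scan targets for tandem occurrences of each unit with edlib.

    For every unit a search pattern of whole-unit copies at least
    *min_pattern_len* bp long is built, and each target is scanned left to
    right with infix alignments of the pattern (both strands). Hits are
    pattern-sized; adjacent copies merge downstream. This is an exact but
    slow substitute for a production aligner: up to one pattern length can
    be missed at array boundaries and read ends.
    """
    import edlib

    patterns = []
    for u in units:
        ul = len(u.seq)
        if ul == 0:
            continue
        reps = max(1, math.ceil(min_pattern_len / ul))
        pat = u.seq * reps
        patterns.append((u, pat, revcomp(pat)))

    hits: List[AlignmentHit] = []
    for tname, tseq in targets:
        L = len(tseq)
        for u, pat, patrc in patterns:
            plen = len(pat)
            maxk = max(1, int(max_scan_divergence * plen))
            if L < plen - maxk:
                continue
            slack = max(8, plen // 20)
            p = 0
            anchored = False  # right after a hit: take the adjacent copy,
            # not the cleanest copy anywhere in a wide window
            while p <= L - (plen - maxk):
                win = plen + slack if anchored else 2 * plen
                chunk = tseq[p : p + win]
                best_ed, best_loc, best_strand = -1, None, "+"
                for q, strand in ((pat, "+"), (patrc, "-")):
                    res = edlib.align(q, chunk, mode="HW", task="locations", k=maxk)
                    ed = res["editDistance"]
                    if ed >= 0 and (best_ed < 0 or ed < best_ed):
                        best_ed, best_loc, best_strand = ed, res["locations"][0], strand
                if best_loc is None:
                    if anchored:
                        anchored = False  # retry this position with a wide window
                        continue
                    p += max(1, plen // 2)
                    continue
                start = p + best_loc[0]
                end = p + best_loc[1] + 1
                align_len = max(plen, end - start)
                hits.append(
                    AlignmentHit(
                        unit_id=u.id,
                        target_name=tname,
                        target_len=L,
                        target_start=start,
                        target_end=end,
                        strand=best_strand,
                        matches=align_len - best_ed,
                        align_len=align_len,
                        query_len=plen,
                        query_start=0,
                        query_end=plen,
                    )
                )
                p = end if end > p else p + 1
                anchored = True
    return hits


# ---------------------------------------------------------------------------
# Filtering, merging, per-base uniqueness, copy-number cut


def _subtract(start: int, end: int, claimed: List[Tuple[int, int]]) -> List[Tuple[int, int]]:
    """Pieces of [start, end) not covered by the (sorted, disjoint) claims."""
    pieces = []
    cur = start
    for cs, ce in claimed:
        if ce <= cur:
            continue
        if cs >= end:
            break
        if cs > cur:
            pieces.append((cur, cs))
        cur = max(cur, ce)
        if cur >= end:
            break
    if cur < end:
        pieces.append((cur, end))
    return pieces


def _insert_claim(claimed: List[Tuple[int, int]], piece: Tuple[int, int]) -> None:
    claimed.append(piece)
    claimed.sort()


def filter_and_merge(
    hits: Iterable[AlignmentHit],
    params: FilterParams,
    target_lengths: Dict[str, int],
    unit_lengths: Dict[str, int],
) -> List[MergedInterval]:
    """Apply the full filter chain and return disjoint per-target intervals.

    Order: identity cut -> same-unit merge (gap <= merge_gap) -> cross-unit
    overlap resolution (identity-descending; an interval trimmed by more
    than half is dropped) -> tandem-copy-number cut with the end rule.
    """
    # 1. identity filter, grouped per (target, unit)
    grouped: Dict[Tuple[str, str], List[AlignmentHit]] = {}
    for h in hits:
        if h.identity < params.min_identity:
            continue
        if h.unit_id not in unit_lengths:
            raise ValueError(f"unknown unit length for {h.unit_id!r}")
        grouped.setdefault((h.target_name, h.unit_id), []).append(h)

    # 2. merge same-unit hits
    proto: Dict[str, List[Tuple[int, int, str, float]]] = {}  # target -> merged runs
    for (tname, uid), hs in grouped.items():
        hs.sort(key=lambda h: (h.target_start, h.target_end))
        runs = proto.setdefault(tname, [])
        cur_s, cur_e = hs[0].target_start, hs[0].target_end
        id_weight = hs[0].identity * (cur_e - cur_s)
        w = cur_e - cur_s
        for h in hs[1:]:
            if h.target_start - cur_e <= params.merge_gap:
                cur_e = max(cur_e, h.target_end)
            else:
                runs.append((cur_s, cur_e, uid, id_weight / w))
                cur_s, cur_e = h.target_start, h.target_end
                id_weight = w = 0
            hl = h.target_end - h.target_start
            id_weight += h.identity * hl
            w += hl
        runs.append((cur_s, cur_e, uid, id_weight / w))

    # 3 + 4. cross-unit resolution then copy-number filter, per target
    out: List[MergedInterval] = []
    for tname in sorted(proto):
        tlen = target_lengths.get(tname)
        if tlen is None:
            raise ValueError(f"unknown target length for {tname!r}")
        runs = proto[tname]
        # highest identity first; ties: longer first, then unit id
        runs.sort(key=lambda r: (-r[3], -(r[1] - r[0]), r[2]))
        claimed: List[Tuple[int, int]] = []
        for s, e, uid, ident in runs:
            pieces = _subtract(s, e, claimed)
            kept = sum(pe - ps for ps, pe in pieces)
            if kept * 2 < (e - s):  # trimming removed more than half
                continue
            for piece in pieces:
                _insert_claim(claimed, piece)
            ul = unit_lengths[uid]
            for ps, pe in pieces:
                copies = (pe - ps) / ul
                touches = ps <= params.merge_gap or pe >= tlen - params.merge_gap
                cut = params.min_copies_at_end if touches else params.min_copies_internal
                if copies >= cut:
                    out.append(
                        MergedInterval(
                            target_name=tname,
                            start=ps,
                            end=pe,
                            unit_id=uid,
                            mean_identity=ident,
                            copies=copies,
                            touches_end=touches,
                        )
                    )
    out.sort(key=lambda iv: (iv.target_name, iv.start))
    return out


def compute_abundance(
    intervals: Iterable[MergedInterval],
    total_input_bases: int,
    unit_ids: Optional[Iterable[str]] = None,
) -> AbundanceReport:
    """Sum interval lengths per unit and express them as input fractions."""
    per_unit: Dict[str, int] = {uid: 0 for uid in (unit_ids or [])}
    total_sat = 0
    for iv in intervals:
        n = len(iv)
        per_unit[iv.unit_id] = per_unit.get(iv.unit_id, 0) + n
        total_sat += n
    fractions = {
        uid: (b / total_input_bases if total_input_bases else 0.0)
        for uid, b in per_unit.items()
    }
    return AbundanceReport(
        per_unit_bases=per_unit,
        fractions=fractions,
        total_input_bases=total_input_bases,
        total_satellite_bases=total_sat,
    )


# ---------------------------------------------------------------------------
# Output writers


def write_bed(intervals: Iterable[MergedInterval], path: str) -> None:
    """BED: target, start, end, unit id, mean identity, copies."""
    with open(path, "wt") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.target_name}\t{iv.start}\t{iv.end}\t{iv.unit_id}\t"
                f"{iv.mean_identity:.4f}\t{iv.copies:.2f}\n"
            )


def write_abundance_tsv(report: AbundanceReport, path: str) -> None:
    with open(path, "wt") as fh:
        fh.write("unit_id\ttotal_bases\tfraction\n")
        for uid in sorted(report.per_unit_bases):
            fh.write(f"{uid}\t{report.per_unit_bases[uid]}\t{report.fractions[uid]:.6f}\n")
        fh.write(
            f"#total\t{report.total_satellite_bases}\t{report.total_fraction:.6f}\n"
        )
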