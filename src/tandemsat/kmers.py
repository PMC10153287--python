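"""Canonical k-mer counting and dump-file handling.

Satellite repeat reconstruction works on a table of canonical k-mer counts:
the bidirected de Bruijn graph traversed by :mod:`tandemsat.graph` is implicit
in this table, so counting k-mers (or importing a dump produced by an external
counter such as KMC) is the first step of every run.

A *canonical* k-mer is the lexicographic minimum of a k-mer and its reverse
complement; counting canonically makes the table strand-symmetric, which is
what prevents a repeat unit from being reported once per strand downstream.

Two counting paths are provided: a vectorised 2-bit packed path for k <= 31
(covers the desk-scale default used by the simulator-driven analyses) and a
generic string-keyed path for longer k such as the 151/171 defaults used on
real reads and assemblies. Windows containing non-ACGT bases are skipped in
both paths. Counting at 30x-human scale is out of scope; supply an external
counter's two-column dump instead.
"""

from __future__ import annotations

import gzip
import io
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Tuple

import numpy as np

# ---------------------------------------------------------------------------
# Defaults. k follows the established practice for each input type; the
# occurrence threshold defines which k-mers enter the high-abundance graph:
# a fixed floor of 20 for assemblies, 10x the average read depth for reads.
DEFAULT_K_ASSEMBLY = 171
DEFAULT_K_READS = 151
DEFAULT_K_SHORT_READS = 101
DEFAULT_MIN_COUNT_ASSEMBLY = 20
DEFAULT_DEPTH_MULTIPLIER = 10

_ACGT = frozenset("ACGT")
_COMP = str.maketrans("ACGTacgt", "TGCAtgca")

# byte -> 2-bit code; 4 flags an ambiguous base
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _CODE[_b] = _i


class InvalidAlphabetError(ValueError):
    """A k-mer contains a character outside {A, C, G, T}."""


class KmerDumpFormatError(ValueError):
    """A k-mer dump file is malformed; the message names the line."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (preserves case, maps N -> N)."""
    return seq.translate(_COMP)[::-1]


def canonical(kmer: str) -> Tuple[str, bool]:
    """Return ``(canonical_kmer, flipped)`` for *kmer*.

    The canonical form is ``min(kmer, revcomp(kmer))``; ``flipped`` is True
    iff the reverse complement was returned. ``canonical`` is a projection:
    applying it to its own output is the identity.
    """
    if not _ACGT.issuperset(kmer):
        bad = sorted(set(kmer) - _ACGT)
        raise InvalidAlphabetError(f"non-ACGT character(s) {bad} in k-mer")
    rc = kmer.translate(_COMP)[::-1]
    if rc < kmer:
        return rc, True
    return kmer, False


@dataclass
class KmerTable:
    """Counts of canonical k-mers; the de Bruijn graph is implicit in it."""

    k: int
    counts: Dict[str, int] = field(default_factory=dict)
    total_input_bases: int = 0

    def __len__(self) -> int:
        return len(self.counts)

    def __contains__(self, kmer: str) -> bool:
        return kmer in self.counts

    def get(self, kmer: str, default: int = 0) -> int:
        return self.counts.get(kmer, default)

    def max_count_kmer(self) -> Optional[str]:
        """Highest-count k-mer (ties broken lexicographically), or None."""
        if not self.counts:
            return None
        return min(self.counts, key=lambda km: (-self.counts[km], km))


@dataclass
class ThresholdPolicy:
    """How the high-abundance threshold is derived.

    ``assembly`` mode uses a fixed ``min_count`` (default 20). ``reads`` mode
    ties the threshold to sequencing depth: ``min_count = round(multiplier *
    depth)`` with a default multiplier of 10, so e.g. 40-fold coverage gives
    a threshold of 400.
    """

    mode: str
    min_count: int
    depth: float = 0.0
    multiplier: int = DEFAULT_DEPTH_MULTIPLIER

    @classmethod
    def assembly(cls, min_count: int = DEFAULT_MIN_COUNT_ASSEMBLY) -> "ThresholdPolicy":
        return cls(mode="assembly", min_count=min_count)

    @classmethod
    def reads(cls, depth: float, multiplier: int = DEFAULT_DEPTH_MULTIPLIER) -> "ThresholdPolicy":
        if depth <= 0:
            raise ValueError("reads-mode threshold needs a positive depth")
        return cls(
            mode="reads",
            min_count=int(round(multiplier * depth)),
            depth=depth,
            multiplier=multiplier,
        )


def estimate_depth(total_read_bases: int, genome_size: int) -> float:
    """Average fold coverage: total read bases over genome (or assembly) size."""
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    return total_read_bases / genome_size


# ---------------------------------------------------------------------------
# Counting


def _valid_window_mask(codes: np.ndarray, k: int) -> np.ndarray:
    n = codes.size - k + 1
    bad = np.flatnonzero(codes >= 4)
    if bad.size > codes.size // (2 * k) + 16:  # dense ambiguity: cumsum wins
        cs = np.concatenate(([0], np.cumsum((codes >= 4).astype(np.int32))))
        return (cs[k:] - cs[:-k]) == 0
    mask = np.ones(n, dtype=bool)
    for b in bad:  # ambiguous bases are sparse; invalidate windows covering b
        mask[max(0, b - k + 1) : min(n, b + 1)] = False
    return mask


def _revcomp_packed(v: np.ndarray, k: int) -> np.ndarray:
    """Reverse complement of 2-bit packed k-mers (vectorised bit reversal)."""
    x = np.bitwise_not(v)  # base complement: c ^ 3
    x &= np.uint64((1 << (2 * k)) - 1)
    for shift, mask in (
        (2, 0x3333333333333333),
        (4, 0x0F0F0F0F0F0F0F0F),
        (8, 0x00FF00FF00FF00FF),
        (16, 0x0000FFFF0000FFFF),
    ):
        s, m = np.uint64(shift), np.uint64(mask)
        hi = x & m
        hi <<= s
        x >>= s
        x &= m
        x |= hi
    hi = x << np.uint64(32)
    x >>= np.uint64(32)
    x |= hi
    x >>= np.uint64(64 - 2 * k)
    return x


def _packed_canonical_windows(seq: str, k: int) -> np.ndarray:
    """All valid canonical k-mers of *seq* as 2-bit packed uint64 (k <= 31)."""
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    c64 = codes.astype(np.uint64)
    fwd = np.zeros(n, dtype=np.uint64)
    two = np.uint64(2)
    for j in range(k):  # in-place shift-or keeps memory traffic low
        fwd <<= two
        fwd |= c64[j : j + n]
    # windows crossing an ambiguous base hold garbage codes; masked below
    canon = np.minimum(fwd, _revcomp_packed(fwd, k))
    return canon[_valid_window_mask(codes, k)]


def _decode_packed(value: int, k: int) -> str:
    chars = []
    for _ in range(k):
        chars.append("ACGT"[value & 3])
        value >>= 2
    return "".join(reversed(chars))


def _count_fast(sequences: Iterable[str], k: int, min_count: Optional[int]) -> Tuple[Dict[str, int], int]:
    total = 0
    chunks: List[np.ndarray] = []
    for seq in sequences:
        total += len(seq)
        chunks.append(_packed_canonical_windows(seq, k))
    if not chunks:
        return {}, total
    packed = np.concatenate(chunks) if len(chunks) > 1 else chunks[0]
    if packed.size == 0:
        return {}, total
    packed.sort()  # in-place; we own the buffer (avoids np.unique's copy)
    starts = np.flatnonzero(np.concatenate(([True], packed[1:] != packed[:-1])))
    cnt = np.diff(np.concatenate((starts, [packed.size])))
    uniq = packed[starts]
    if min_count is not None:
        keep = cnt >= min_count
        uniq, cnt = uniq[keep], cnt[keep]
    counts = {_decode_packed(int(v), k): int(c) for v, c in zip(uniq, cnt)}
    return counts, total


def _count_generic(sequences: Iterable[str], k: int, min_count: Optional[int]) -> Tuple[Dict[str, int], int]:
    counts: Dict[str, int] = {}
    total = 0
    for seq in sequences:
        total += len(seq)
        s = seq.upper()
        L = len(s)
        if L < k:
            continue
        codes = _CODE[np.frombuffer(s.encode("ascii"), dtype=np.uint8)]
        rc = revcomp(s)
        for i in np.flatnonzero(_valid_window_mask(codes, k)):
            w = s[i : i + k]
            wrc = rc[L - k - i : L - i]
            key = w if w <= wrc else wrc
            counts[key] = counts.get(key, 0) + 1
    if min_count is not None:
        counts = {km: c for km, c in counts.items() if c >= min_count}
    return counts, total


def count_kmers(sequences: Iterable[str], k: int, *, min_count: Optional[int] = None) -> KmerTable:
    """Count canonical k-mers over *sequences*.

    Every length-k window whose bases are all ACGT contributes one count to
    its canonical form, so forward and reverse occurrences pool together.
    ``total_input_bases`` records the summed sequence lengths (all bases,
    including ambiguous ones).

    Parameters
    ----------
    min_count:
        Optional pruning applied while the table is built. Equivalent to
        ``apply_threshold`` afterwards but avoids materialising the
        (possibly large) low-count tail; used by the pipeline on read sets.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k <= 31:
        counts, total = _count_fast(sequences, k, min_count)
    else:
        counts, total = _count_generic(sequences, k, min_count)
    return KmerTable(k=k, counts=counts, total_input_bases=total)


def apply_threshold(table: KmerTable, policy: ThresholdPolicy) -> KmerTable:
    """Keep exactly the entries with ``count >= policy.min_count``."""
    if policy.min_count < 1:
        raise ValueError("min_count must be >= 1")
    kept = {km: c for km, c in table.counts.items() if c >= policy.min_count}
    return KmerTable(k=table.k, counts=kept, total_input_bases=table.total_input_bases)


# ---------------------------------------------------------------------------
# Dump-file I/O (two-column tab-separated text, the dialect of kmc_dump)


def write_kmer_dump(table: KmerTable, path: str, count_cap: Optional[int] = None) -> None:
    """Write ``kmer<TAB>count`` lines, lexicographically sorted.

    Counts are stored uncapped internally; *count_cap* saturates them on
    output only, for compatibility with counters that cap on disk.
    """
    op = gzip.open if str(path).endswith(".gz") else open
    with op(path, "wt") as fh:
        for km in sorted(table.counts):
            c = table.counts[km]
            if count_cap is not None:
                c = min(c, count_cap)
            fh.write(f"{km}\t{c}\n")


def read_kmer_dump(path: str) -> KmerTable:
    """Read a two-column k-mer dump; k is inferred from the first record.

    Keys are canonicalised on input (counts of a k-mer and its reverse
    complement merge), so ``write(read(f))`` reproduces ``read(f)``.
    """
    counts: Dict[str, int] = {}
    k = 0
    op = gzip.open if str(path).endswith(".gz") else open
    with op(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise KmerDumpFormatError(
                    f"line {lineno}: expected 2 tab-separated columns, got {len(fields)}"
                )
            km, cnt_s = fields
            try:
                cnt = int(cnt_s)
            except ValueError:
                raise KmerDumpFormatError(f"line {lineno}: non-integer count {cnt_s!r}") from None
            if cnt < 1:
                raise KmerDumpFormatError(f"line {lineno}: count must be positive, got {cnt}")
            if k == 0:
                k = len(km)
            elif len(km) != k:
                raise KmerDumpFormatError(
                    f"line {lineno}: k-mer length {len(km)} differs from first record ({k})"
                )
            try:
                key, _ = canonical(km.upper())
            except InvalidAlphabetError as exc:
                raise KmerDumpFormatError(f"line {lineno}: {exc}") from None
            counts[key] = counts.get(key, 0) + cnt
    return KmerTable(k=k, counts=counts)


# ---------------------------------------------------------------------------
# Sequence input (FASTA/FASTQ, plain or gzipped)


def _open_text(path: str) -> io.TextIOBase:
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_sequences(path: str) -> Iterator[Tuple[str, str]]:
    """Yield ``(name, sequence)`` from a FASTA or FASTQ file (gzip ok)."""
    from Bio import SeqIO

    fh = _open_text(path)
    try:
        head = fh.read(1)
        fh.seek(0)
        if head == ">":
            fmt = "fasta"
        elif head == "@":
            fmt = "fastq"
        elif head == "":
            return
        else:
            raise ValueError(f"{path}: not FASTA or FASTQ (starts with {head!r})")
        for rec in SeqIO.parse(fh, fmt):
            yield rec.id, str(rec.seq).upper()
    finally:
        fh.close()
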