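"""Synthetic satellite genomes and reads with known ground truth.

The generator emulates what the reconstruction pipeline assumes about real
satellite DNA: an ancestral repeat unit — optionally a high-order repeat
(HOR) built from several monomers, e.g. ``ABCD`` repeated — tandemly copied
many times, each copy independently mutated from the ancestor (star
phylogeny, substitutions by default), the arrays embedded in i.i.d. uniform
random background, and accurate reads drawn uniformly from both strands at a
stated depth with optional substitution errors.

It does not emulate realistic HiFi error profiles (homopolymer-biased
errors), mutation along a copy chain, or transposon-structured backgrounds;
results on simulated data bound what the algorithm can do under its own
model, not performance on arbitrary real genomes.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from . import graph, hor, kmers

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_IDX = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _IDX[_b] = _i

RngLike = Union[int, np.random.Generator]


def _rng(seed_or_rng: RngLike) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def random_dna(n: int, seed_or_rng: RngLike) -> str:
    rng = _rng(seed_or_rng)
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode("ascii")


def mutate(seq: str, sub_rate: float, indel_rate: float, seed_or_rng: RngLike) -> str:
    """Mutate *seq*: substitutions to a uniformly chosen *different* base at
    *sub_rate* per base; insertions/deletions each at ``indel_rate / 2``."""
    rng = _rng(seed_or_rng)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    if sub_rate > 0 and arr.size:
        pos = np.flatnonzero(rng.random(arr.size) < sub_rate)
        if pos.size:
            shift = rng.integers(1, 4, size=pos.size).astype(np.uint8)
            arr[pos] = _BASES[(_IDX[arr[pos]] + shift) % 4]
    out = arr.tobytes().decode("ascii")
    if indel_rate > 0 and out:
        chars = list(out)
        result: List[str] = []
        for ch in chars:
            r = rng.random()
            if r < indel_rate / 2:
                continue  # deletion
            result.append(ch)
            if r >= indel_rate / 2 and r < indel_rate:
                result.append("ACGT"[rng.integers(0, 4)])  # insertion
        out = "".join(result)
    return out


def make_hor_monomers(length: int, n: int, divergence: float, seed_or_rng: RngLike) -> List[str]:
    """*n* monomers derived from one ancestral monomer at the given
    divergence — the 'similar but not identical' monomer alphabet of a
    natural HOR (use independent random monomers for unrelated alphabets)."""
    rng = _rng(seed_or_rng)
    base = random_dna(length, rng)
    return [mutate(base, divergence, 0.0, rng) for _ in range(n)]


@dataclass
class ArraySpec:
    """One tandem array: monomers, HOR order, copy number, mutation rates.

    ``monomers`` may be given explicitly or drawn randomly from
    ``monomer_lengths``. ``hor_order`` indexes monomers to form the HOR unit
    (default: all monomers once, in order — ``[0, 1, 2, 3]`` is 'ABCD').
    ``per_copy_divergence`` is the substitution probability per base applied
    independently to each copy of the unit.
    """

    monomers: Optional[List[str]] = None
    monomer_lengths: Optional[List[int]] = None
    hor_order: Optional[List[int]] = None
    n_units: int = 100
    per_copy_divergence: float = 0.0
    indel_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        for r in (self.per_copy_divergence, self.indel_rate):
            if not (0.0 <= r < 1.0):
                raise ValueError("rates must be in [0, 1)")
        if self.monomers is None and self.monomer_lengths is None:
            raise ValueError("give monomers or monomer_lengths")


@dataclass
class ArrayTruth:
    """The unmutated unit and the layout of one generated array."""

    unit: str
    monomers: List[str]
    n_units: int
    length: int


@dataclass
class PlantedArray:
    name: str
    seq: str
    unit: str


@dataclass
class GenomeTruth:
    """A simulated genome: sequence, array intervals, planted fraction."""

    sequence: str
    intervals: List[Tuple[int, int, str]]  # (start, end, array name)
    satellite_fraction: float
    units: Dict[str, str]  # array name -> ancestral unit


@dataclass
class ReadSpec:
    """Accurate-read model: fixed or normal read length, fold depth,
    uniform substitution errors, random strand."""

    read_len: int = 10_000
    read_len_sd: float = 0.0
    depth: float = 20.0
    error_rate: float = 0.0
    seed: int = 0


def make_array(spec: ArraySpec, seed_or_rng: RngLike) -> Tuple[str, ArrayTruth]:
    """Generate one tandem array and its truth record."""
    rng = _rng(seed_or_rng)
    if spec.monomers is not None:
        monomers = [m.upper() for m in spec.monomers]
    else:
        monomers = [random_dna(L, rng) for L in spec.monomer_lengths]
    order = spec.hor_order if spec.hor_order is not None else list(range(len(monomers)))
    unit = "".join(monomers[i] for i in order)
    copies = [
        mutate(unit, spec.per_copy_divergence, spec.indel_rate, rng)
        for _ in range(spec.n_units)
    ]
    seq = "".join(copies)
    return seq, ArrayTruth(unit=unit, monomers=monomers, n_units=spec.n_units, length=len(seq))


def embed_in_background(
    arrays: Sequence[PlantedArray],
    background_len: int,
    seed_or_rng: RngLike,
) -> GenomeTruth:
    """Place arrays non-overlapping at random positions in uniform-ACGT
    background of *background_len* total bases."""
    rng = _rng(seed_or_rng)
    bg = random_dna(background_len, rng)
    cuts = sorted(int(c) for c in rng.integers(0, background_len + 1, size=len(arrays)))
    pieces: List[str] = []
    intervals: List[Tuple[int, int, str]] = []
    prev = 0
    pos = 0
    for arr, cut in zip(arrays, cuts):
        pieces.append(bg[prev:cut])
        pos += cut - prev
        intervals.append((pos, pos + len(arr.seq), arr.name))
        pieces.append(arr.seq)
        pos += len(arr.seq)
        prev = cut
    pieces.append(bg[prev:])
    sequence = "".join(pieces)
    sat = sum(len(a.seq) for a in arrays)
    return GenomeTruth(
        sequence=sequence,
        intervals=intervals,
        satellite_fraction=sat / len(sequence) if sequence else 0.0,
        units={a.name: a.unit for a in arrays},
    )


def simulate_reads(genome: str, spec: ReadSpec) -> List[Tuple[str, str]]:
    """Draw reads uniformly from *genome*; returns ``(name, seq)`` pairs.

    Read names carry the truth: ``read<i>|<start>-<end>|<strand>``. Strand is
    random; errors are uniform substitutions at ``spec.error_rate``.
    """
    rng = np.random.default_rng(spec.seed)
    G = len(genome)
    if G == 0:
        return []
    mean_len = min(spec.read_len, G)
    n_reads = max(1, int(round(spec.depth * G / mean_len)))
    if spec.read_len_sd > 0:
        lens = rng.normal(mean_len, spec.read_len_sd, size=n_reads)
        lens = np.clip(np.round(lens), 50, G).astype(int)
    else:
        lens = np.full(n_reads, mean_len, dtype=int)
    reads: List[Tuple[str, str]] = []
    for i in range(n_reads):
        L = int(lens[i])
        start = int(rng.integers(0, G - L + 1))
        seq = genome[start : start + L]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            seq = kmers.revcomp(seq)
        if spec.error_rate > 0:
            seq = mutate(seq, spec.error_rate, 0.0, rng)
        reads.append((f"read{i:06d}|{start}-{start + L}|{strand}", seq))
    return reads


# ---------------------------------------------------------------------------
# Output writers


def write_fasta(records: Sequence[Tuple[str, str]], path: str) -> None:
    with open(path, "wt") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def write_fastq(reads: Sequence[Tuple[str, str]], path: str) -> None:
    with open(path, "wt") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_truth(truth: GenomeTruth, bed_path: str, json_path: str) -> None:
    with open(bed_path, "wt") as fh:
        for s, e, name in truth.intervals:
            fh.write(f"genome\t{s}\t{e}\t{name}\n")
    with open(json_path, "wt") as fh:
        json.dump(
            {
                "genome_len": len(truth.sequence),
                "satellite_fraction": truth.satellite_fraction,
                "units": truth.units,
                "intervals": truth.intervals,
            },
            fh,
            indent=2,
        )


# ---------------------------------------------------------------------------
# Standard recovery scenarios: the simulation grid used for end-to-end
# evaluation of the pipeline (also exercised by the acceptance script).


@dataclass
class Scenario:
    """One end-to-end simulation condition.

    ``depth`` None means assembly mode (the genome itself is the input);
    otherwise reads at that fold coverage are simulated. ``n_units`` is
    chosen so the ancestral unit's k-mers clear the abundance threshold with
    at least ~2.5x margin at the stated divergence (survival of a k-length
    window per copy is ``(1 - divergence)^k``).
    """

    name: str
    monomer_len: int
    hor_order: int
    n_units: int
    divergence: float
    genome_len: int
    depth: Optional[float] = None  # None -> assembly mode
    k: int = 31
    read_len: int = 10_000
    error_rate: float = 0.0


def default_recovery_scenarios() -> List[Scenario]:
    """The standard 20-condition grid: monomer lengths {5, 120, 171, 178},
    HOR orders 1-6, per-copy divergence 0-3%, read depth 20-40x or assembly
    input, genome sizes 200 kb - 1 Mb."""
    return [
        Scenario("s01-alpha-mono", 171, 1, 100, 0.00, 200_000, depth=20, error_rate=0.001),
        Scenario("s02-alpha-4mer", 171, 4, 150, 0.02, 400_000, depth=30),
        Scenario("s03-alpha-2mer", 171, 2, 100, 0.01, 300_000, depth=40),
        Scenario("s04-cen180", 178, 1, 200, 0.03, 250_000, depth=20),
        Scenario("s05-cen180-3mer", 178, 3, 60, 0.00, 300_000, depth=25),
        Scenario("s06-cen180-6mer-asm", 178, 6, 120, 0.01, 600_000),
        Scenario("s07-minor-asm", 120, 1, 100, 0.00, 200_000),
        Scenario("s08-minor-5mer", 120, 5, 130, 0.02, 500_000, depth=20),
        Scenario("s09-minor-2mer", 120, 2, 200, 0.03, 300_000, depth=40, error_rate=0.001),
        Scenario("s10-minor-3mer", 120, 3, 90, 0.01, 250_000, depth=30),
        Scenario("s11-penta", 5, 1, 2000, 0.00, 200_000, depth=20),
        Scenario("s12-penta-div", 5, 1, 4000, 0.02, 200_000, depth=30),
        Scenario("s13-penta-4mer", 5, 4, 1000, 0.00, 200_000, depth=25),
        Scenario("s14-alpha-6mer-asm", 171, 6, 100, 0.00, 1_000_000),
        Scenario("s15-cen180-2mer", 178, 2, 130, 0.02, 350_000, depth=35),
        Scenario("s16-minor-4mer", 120, 4, 80, 0.00, 400_000, depth=40),
        Scenario("s17-alpha-3mer", 171, 3, 200, 0.03, 450_000, depth=20),
        Scenario("s18-cen180-4mer", 178, 4, 90, 0.01, 300_000, depth=20),
        Scenario("s19-penta-2mer-asm", 5, 2, 3000, 0.01, 200_000),
        Scenario("s20-alpha-deep", 171, 1, 120, 0.02, 1_000_000, depth=40),
    ]


@dataclass
class ScenarioResult:
    scenario: Scenario
    truth: GenomeTruth
    table: "kmers.KmerTable"
    units: List["graph.RepeatUnit"]
    total_read_bases: int

    def recovered(self, max_divergence: Optional[float] = None) -> bool:
        """True when the planted unit was reconstructed: exactly up to
        rotation/strand at zero divergence, within the planted divergence
        otherwise (or within *max_divergence* if given)."""
        planted = self.truth.units["sat0"]
        tol = max_divergence if max_divergence is not None else self.scenario.divergence
        for u in self.units:
            if tol == 0.0:
                if graph.canonical_form(u.seq) == graph.canonical_form(planted):
                    return True
            elif hor.unit_divergence(u, planted) <= tol:
                return True
        return False


def _joined_chunks(reads: Sequence[Tuple[str, str]], chunk_bases: int = 4_000_000) -> List[str]:
    # Joining reads with 'N' separators lets the vectorised counter run over
    # large blocks; windows across the separator are skipped as ambiguous.
    chunks: List[str] = []
    buf: List[str] = []
    size = 0
    for _, seq in reads:
        buf.append(seq)
        size += len(seq) + 1
        if size >= chunk_bases:
            chunks.append("N".join(buf))
            buf, size = [], 0
    if buf:
        chunks.append("N".join(buf))
    return chunks


def run_scenario(sc: Scenario, seed: int) -> ScenarioResult:
    """Simulate one scenario and run the reconstruction pipeline on it."""
    rng = np.random.default_rng([seed, zlib.crc32(sc.name.encode()) % (2**31)])
    monomers = [random_dna(sc.monomer_len, rng) for _ in range(sc.hor_order)]
    spec = ArraySpec(
        monomers=monomers,
        n_units=sc.n_units,
        per_copy_divergence=sc.divergence,
    )
    arr_seq, arr_truth = make_array(spec, rng)
    bg_len = sc.genome_len - len(arr_seq)
    if bg_len <= 0:
        raise ValueError(f"{sc.name}: array longer than genome")
    truth = embed_in_background(
        [PlantedArray("sat0", arr_seq, arr_truth.unit)], bg_len, rng
    )

    if sc.depth is None:
        policy = kmers.ThresholdPolicy.assembly()
        table = kmers.count_kmers([truth.sequence], sc.k, min_count=policy.min_count)
        total_read_bases = len(truth.sequence)
    else:
        reads = simulate_reads(
            truth.sequence,
            ReadSpec(
                read_len=sc.read_len,
                depth=sc.depth,
                error_rate=sc.error_rate,
                seed=int(rng.integers(2**31)),
            ),
        )
        total_read_bases = sum(len(s) for _, s in reads)
        depth = kmers.estimate_depth(total_read_bases, len(truth.sequence))
        policy = kmers.ThresholdPolicy.reads(depth)
        table = kmers.count_kmers(_joined_chunks(reads), sc.k, min_count=policy.min_count)
        table.total_input_bases = total_read_bases

    units = graph.find_repeat_units(table)
    kept, _ = hor.dedup_units(units)
    return ScenarioResult(
        scenario=sc,
        truth=truth,
        table=table,
        units=kept,
        total_read_bases=total_read_bases,
    )
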