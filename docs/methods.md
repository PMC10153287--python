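# Methods

## Model and assumptions

A satellite array is modelled as tandem copies of an ancestral repeat unit,
each copy carrying independent random mutations. Under this model the
high-abundance part of the canonical k-mer de Bruijn graph of the array is,
with high probability, exactly the cycle spelled by the ancestral unit: an
ancestral k-mer survives unmutated in a given copy with probability
`(1 - d)^k` (d = per-copy substitution divergence), so across `n` copies its
expected count is `n (1 - d)^k` times the read depth, whereas any particular
mutated variant is typically private to one copy. The occurrence threshold
(20 for assemblies, 10× depth for reads) is what separates these two
populations; everything downstream assumes it has done so.

Consequences worth keeping in mind:

- **k must exceed the scale of monomer similarity.** In a HOR whose
  monomers are mutually similar, a k-mer shared between two monomers fuses
  the unit cycle with itself and the walk aborts (revisit). The expected
  number of such collisions is about `L_monomer · pairs · (1-d_mono)^{2k}`;
  the default long k (151/171) keeps it near zero for natural monomer
  divergences, and the same calculation should guide k for simulated data
  (tests use k = 101 for 6%-diverged 171 bp monomer alphabets, k = 31 for
  independent monomers).
- **Low-abundance or high-diversity families are missed** when
  `n (1-d)^k` falls under the threshold — the method's stated conservatism,
  not a defect; the simulation grid picks copy numbers with ≥ ~2.5× margin.

## Graph traversal

Nodes are canonical k-mers (lexicographic min of k-mer and reverse
complement); a node is visited in forward or flipped orientation, and
successors extend the (k-1)-suffix of the oriented k-mer by one base. The
walk starts at the highest-count unused k-mer in forward orientation and
always takes the highest-count successor. Termination:

- closing on the start in the same orientation → a repeat unit (one base
  emitted per cycle node);
- no successor → deadend, walk discarded;
- the chosen successor was already used (this walk, a previous walk, or the
  start in flipped orientation) → discarded likewise.

All k-mers touched by a walk, successful or not, are marked used: this keeps
runtime linear in table size and makes reported units pairwise disjoint in
k-mer content. Determinism is fixed by three conventions: count ties at
bifurcations break by extension base in A < C < G < T order; start k-mers
with equal counts are taken lexicographically; the reported unit is the
lexicographically smallest rotation over both strands. Tie-breaking can
rotate the exact output sequence relative to other implementations, but not
its length or circular identity.

## Thresholds and parameters

| parameter | default | meaning |
|---|---|---|
| k | 171 assembly / 151 HiFi / 101 short reads | window length; ≤ 31 uses the packed counter |
| min_count (assembly) | 20 | graph inclusion threshold |
| min_count (reads) | round(10 × depth) | depth = total read bases / genome size |
| min_identity | 0.90 | alignment filter (matches / block length) |
| min copies internal / at end | 2.0 / 1.5 | tandem-copy filter; "at end" = within merge_gap of a sequence boundary |
| merge_gap | 100 bp | same-unit merge distance; matches the 100 bp aligner bandwidth |
| dedup max divergence | 0.02 | rotation/strand-aware edit distance ratio |
| HOR rule | ≥ 3 copies, ≥ 90% coverage | on the smallest qualifying internal period |

## Abundance estimation

Alignments (PAF; query = enlonged unit, target = read/contig) are filtered
in a fixed order: identity cut → same-unit merge → cross-unit overlap
resolution → copy-number cut. Identity is PAF residue matches over alignment
block length. Overlap resolution realises the "each base maps to at most one
unit" guarantee: merged intervals are taken in descending identity (ties:
longer first, then unit id), each trimmed to bases not yet claimed, and an
interval losing more than half its length to trimming is dropped; surviving
pieces are re-tested against the copy cuts. The merge/resolve order and the
trimming rule are design choices of this package; abundance is monotone
non-increasing in every filter threshold under a single-unit workload, and
per-target intervals are disjoint by construction.

The built-in aligner scans each target left-to-right with edlib infix
alignments of a tandem pattern (whole unit copies, ≥ 120 bp). After a hit it
anchors the next search to the adjacent window so a mutated copy is not
skipped in favour of a cleaner one further on; up to one pattern length can
still be missed at array boundaries and read ends, a ≤ ~5% downward bias at
the test geometries. Units longer than ~2/3 of the read length cannot reach
1.5 tandem copies within a read and collapse to zero abundance — the
deliberate cost of the copy-number filter, reproduced qualitatively in the
tests.

## HOR annotation

Rather than a full tandem-repeat finder, the annotator checks every
candidate period p ≤ len/2 directly against the HOR criterion. A cheap
screen keeps p only if ≥ 80% of circular positions satisfy
`base(i) == base(i+p)`; survivors are refined by cutting the unit into
consecutive p-blocks (remainder wrapping circularly) and accepting a block
when it matches a neighbour within a banded edit distance of 0.2 p —
monomer copies are similar, rarely identical. Coverage is the accepted
fraction of the unit; the smallest period with ≥ 3 copies and ≥ 90% coverage
is reported. Multiples of the true period also qualify and are listed after
it. The 80% screen means monomer alphabets beyond ~10% mutual divergence are
not called — consistent with treating such units as non-HOR at the edit
tolerance used.

Unit deduplication aligns the shorter unit as an infix of the doubled longer
unit (both strands), which handles all rotations in one alignment; units
under 2% divergence merge, keeping the higher-mean-count representative.

## Synthetic data

The generator emulates exactly the model above: ancestral unit (optionally a
HOR unit concatenated from a monomer alphabet, either independent random
monomers or siblings of one ancestor at a set divergence), `n` copies each
independently substituted (star phylogeny — mutation along a copy chain
would make the consensus ill-defined), arrays placed without overlap in
uniform random background, reads drawn uniformly with random strand and
uniform substitution errors. Indels are supported but default to zero so
truth alignment stays trivial. All randomness flows from one seed;
identical seeds give identical bytes.

It does not model homopolymer-biased HiFi errors, copy-chain mutation
accumulation, transposon-structured background, or segmental duplications;
passing tests bound behaviour under the stated model, not on arbitrary real
genomes.

The standard evaluation grid (`simulate.default_recovery_scenarios`) spans
monomer lengths {5, 120, 171, 178}, HOR orders 1–6, per-copy divergence
0–3%, read depths 20–40× (plus assembly-mode conditions) and genomes of
200 kb–1 Mb, with copy numbers giving the ancestral k-mers ≥ ~2.5× threshold
margin at k = 31. Abundance recovery is evaluated at planted fractions of
1–10% on 600 kb genomes at 30×, sizes at which read-sampling noise is a few
percent relative; these grid sizes keep the whole suite in the tens of
seconds on one CPU.

## Numerical and degenerate-input choices

- Windows containing non-ACGT bases are skipped during counting; dump files
  are canonicalised on input and counts are stored uncapped (an optional cap
  applies on write only, for counter-format compatibility).
- Even k admits reverse-complement-palindromic k-mers, which create
  spurious bifurcations in toy examples; defaults are odd.
- Homopolymer cycles give single-base units; `min_unit_len` (default 1)
  filters only on request, since genuine short satellites such as (AAGAC)n
  are reportable.
- Empty inputs yield empty outputs (exit 0 on the CLI), not errors;
  malformed dump/PAF records fail with the line number.

## Known limitations

- One unit per k-mer neighbourhood: when two families share long similar
  stretches, the lower-abundance one is absorbed or lost (reporting multiple
  overlapping cycles is out of scope).
- No graph cleaning or bubble popping; the threshold is the only noise
  control.
- In-memory counting is not intended for deep mammalian-scale datasets;
  import an external counter's dump instead.
- The built-in aligner is for tests and small inputs; real data should be
  aligned with minimap2 as printed by the CLI.
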