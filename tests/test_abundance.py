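"""Alignment filtering, merging, and abundance estimation."""

import numpy as np
import pytest

from tandemsat import simulate
from tandemsat.abundance import (
    AlignmentHit,
    FilterParams,
    PafFormatError,
    compute_abundance,
    enlong,
    filter_and_merge,
    naive_align,
    read_paf,
    write_paf,
)
from tandemsat.graph import RepeatUnit


def make_hit(unit="u1", target="r1", tlen=10_000, start=0, end=1000,
             identity=0.95, strand="+"):
    align_len = end - start
    return AlignmentHit(
        unit_id=unit, target_name=target, target_len=tlen,
        target_start=start, target_end=end, strand=strand,
        matches=int(round(identity * align_len)), align_len=align_len,
        query_len=align_len, query_start=0, query_end=align_len,
    )


class TestEnlong:
    def test_ceil_rule(self):
        assert enlong("ACGTG", 12) == "ACGTG" * 3

    def test_at_least_twice(self):
        seq = "A" * 5000
        assert enlong(seq, 5000) == seq * 2

    def test_default_target(self):
        assert len(enlong("ACGTG")) >= 20_000

    def test_target_below_unit_rejected(self):
        with pytest.raises(ValueError):
            enlong("ACGTGACGTG", 5)

    def test_junction_spanning_reads_align(self, rng):
        """Reads drawn across the circular junction of an array align fully
        to the enlonged unit."""
        import edlib

        unit = simulate.random_dna(100, rng)
        array = unit * 10
        ref = enlong(unit, 300)
        for start in (50, 150, 250):  # reads spanning copy junctions
            read = array[start : start + 180]
            res = edlib.align(read, ref, mode="HW", task="distance")
            assert res["editDistance"] == 0


class TestPafIO:
    def test_identity_from_matches_over_block(self, tmp_path):
        p = tmp_path / "a.paf"
        p.write_text("u1\t500\t0\t100\t+\tread1\t10000\t200\t300\t90\t100\t60\n")
        hits = read_paf(p)
        assert len(hits) == 1
        assert hits[0].identity == pytest.approx(0.90)
        assert hits[0].unit_id == "u1"
        assert (hits[0].target_start, hits[0].target_end) == (200, 300)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "e.paf"
        p.write_text("")
        assert read_paf(p) == []

    @pytest.mark.parametrize(
        "line",
        [
            "u1\t500\t0\t100\t+\tread1\t10000\t200\t300\t90\t100",  # 11 cols
            "u1\t500\t0\t100\t*\tread1\t10000\t200\t300\t90\t100\t60",  # strand
            "u1\t500\t0\t100\t+\tread1\t10000\t300\t200\t90\t100\t60",  # coords
            "u1\tx\t0\t100\t+\tread1\t10000\t200\t300\t90\t100\t60",  # non-int
        ],
    )
    def test_malformed_lines_report_line_number(self, tmp_path, line):
        p = tmp_path / "bad.paf"
        p.write_text(line + "\n")
        with pytest.raises(PafFormatError, match="line 1"):
            read_paf(p)

    def test_naive_aligner_round_trip(self, tmp_path, rng):
        unit_seq = simulate.random_dna(150, rng)
        unit = RepeatUnit("unit-0001", unit_seq, 31, 1, 1, 1.0)
        read = simulate.random_dna(200, rng) + unit_seq * 5 + simulate.random_dna(200, rng)
        hits = naive_align([unit], [("read1", read)])
        assert hits
        p = tmp_path / "n.paf"
        write_paf(hits, p)
        assert read_paf(p) == hits


class TestFilterAndMerge:
    TLEN = {"r1": 10_000}
    ULEN = {"u1": 200, "u2": 100}

    def test_identity_boundary(self):
        """Hits below 90% identity are dropped; 90% exactly is kept."""
        params = FilterParams()
        lo = make_hit(start=1000, end=2000, identity=0.89)
        hi = make_hit(start=3000, end=4000, identity=0.90)
        out = filter_and_merge([lo, hi], params, self.TLEN, self.ULEN)
        assert [(iv.start, iv.end) for iv in out] == [(3000, 4000)]

    def test_copy_number_boundaries(self):
        """< 2 tandem copies mid-sequence drop; 1.6 copies at an end are
        kept, 1.4 are not."""
        params = FilterParams()
        mid_low = make_hit(start=3000, end=3380, identity=0.99)  # 1.9 copies
        mid_ok = make_hit(start=5000, end=5400, identity=0.99)  # 2.0 copies
        out = filter_and_merge([mid_low, mid_ok], params, self.TLEN, self.ULEN)
        assert [(iv.start, iv.end) for iv in out] == [(5000, 5400)]

        end_ok = make_hit(start=0, end=320, identity=0.99)  # 1.6 copies at start
        end_low = make_hit(start=9720, end=10_000, identity=0.99)  # 1.4 at end
        out = filter_and_merge([end_ok, end_low], params, self.TLEN, self.ULEN)
        assert [(iv.start, iv.end) for iv in out] == [(0, 320)]
        assert out[0].touches_end

    def test_merge_within_gap(self):
        params = FilterParams(merge_gap=100)
        a = make_hit(start=1000, end=1200, identity=0.95)
        b = make_hit(start=1290, end=1500, identity=0.97)  # gap 90 <= 100
        c = make_hit(start=1700, end=2100, identity=0.95)  # gap 200 > 100
        out = filter_and_merge([a, b, c], params, self.TLEN, self.ULEN)
        assert [(iv.start, iv.end) for iv in out] == [(1000, 1500), (1700, 2100)]

    def test_cross_unit_overlap_resolution(self):
        """The higher-identity unit keeps its span; the other is trimmed to
        the unclaimed remainder and re-tested against the copy cuts."""
        params = FilterParams(merge_gap=0)
        x = make_hit(unit="u1", start=100, end=500, identity=0.95)
        y = make_hit(unit="u2", start=300, end=700, identity=0.92)
        out = filter_and_merge([x, y], params, self.TLEN, self.ULEN)
        by_unit = {iv.unit_id: iv for iv in out}
        assert (by_unit["u1"].start, by_unit["u1"].end) == (100, 500)
        assert (by_unit["u2"].start, by_unit["u2"].end) == (500, 700)
        assert by_unit["u2"].copies == pytest.approx(2.0)

    def test_mostly_shadowed_hit_dropped(self):
        params = FilterParams(merge_gap=0)
        x = make_hit(unit="u1", start=100, end=900, identity=0.99)
        y = make_hit(unit="u2", start=200, end=800, identity=0.92)  # fully inside
        out = filter_and_merge([x, y], params, self.TLEN, self.ULEN)
        assert [iv.unit_id for iv in out] == ["u1"]

    def test_intervals_disjoint_per_target(self, rng):
        params = FilterParams(merge_gap=10)
        hits = []
        for _ in range(100):
            s = int(rng.integers(0, 9000))
            e = s + int(rng.integers(100, 1000))
            hits.append(
                make_hit(unit=str(rng.choice(["u1", "u2"])), start=s, end=min(e, 10_000),
                         identity=float(rng.uniform(0.85, 1.0)))
            )
        out = filter_and_merge(hits, params, self.TLEN, self.ULEN)
        last_end = -1
        for iv in sorted(out, key=lambda iv: iv.start):
            assert iv.start >= last_end
            last_end = iv.end

    def test_unknown_unit_length_rejected(self):
        with pytest.raises(ValueError, match="unit length"):
            filter_and_merge([make_hit(unit="zz")], FilterParams(), self.TLEN, self.ULEN)


class TestComputeAbundance:
    def test_single_interval_fraction(self):
        ivs = filter_and_merge(
            [make_hit(start=2000, end=3000, identity=0.99)],
            FilterParams(), {"r1": 10_000}, {"u1": 200},
        )
        rep = compute_abundance(ivs, 10_000)
        assert rep.fractions["u1"] == pytest.approx(0.10)
        assert rep.total_satellite_bases == 1000

    def test_empty_report(self):
        rep = compute_abundance([], 10_000, unit_ids=["u1"])
        assert rep.fractions == {"u1": 0.0}
        assert rep.total_fraction == 0.0


def _planted_fraction_run(rng, n_units, genome_len, read_seed, params=None):
    mono = simulate.random_dna(171, rng)
    arr, tr = simulate.make_array(
        simulate.ArraySpec(monomers=[mono], n_units=n_units, per_copy_divergence=0.01), rng
    )
    truth = simulate.embed_in_background(
        [simulate.PlantedArray("sat0", arr, tr.unit)], genome_len - len(arr), rng
    )
    reads = simulate.simulate_reads(
        truth.sequence, simulate.ReadSpec(read_len=8000, depth=20, error_rate=0.0, seed=read_seed)
    )
    total = sum(len(s) for _, s in reads)
    unit = RepeatUnit("unit-0001", mono, 31, 1, 1, 1.0)
    hits = naive_align([unit], reads)
    ivs = filter_and_merge(
        hits, params or FilterParams(), {n: len(s) for n, s in reads}, {"unit-0001": 171}
    )
    rep = compute_abundance(ivs, total)
    return truth.satellite_fraction, rep, hits, reads


def test_planted_fraction_recovered(rng):
    planted, rep, _, _ = _planted_fraction_run(rng, n_units=120, genome_len=250_000, read_seed=11)
    assert rep.total_fraction == pytest.approx(planted, rel=0.10)


def test_abundance_monotone_in_filters(rng):
    """Tightening identity or copy thresholds never raises a unit's estimate."""
    planted, rep, hits, reads = _planted_fraction_run(
        rng, n_units=120, genome_len=250_000, read_seed=11
    )
    tlens = {n: len(s) for n, s in reads}
    base = rep.per_unit_bases["unit-0001"]
    for params in (
        FilterParams(min_identity=0.95),
        FilterParams(min_identity=0.999),
        FilterParams(min_copies_internal=4.0, min_copies_at_end=3.0),
    ):
        ivs = filter_and_merge(hits, params, tlens, {"unit-0001": 171})
        tighter = compute_abundance(ivs, rep.total_input_bases).per_unit_bases["unit-0001"]
        assert tighter <= base


def test_long_unit_underestimate_failure_mode(rng):
    """A unit longer than ~2/3 of the read length cannot show >= 1.5 tandem
    copies inside a read, so its abundance collapses — the conservative
    copy-number filter's known cost."""
    long_unit = simulate.random_dna(900, rng)
    arr, tr = simulate.make_array(
        simulate.ArraySpec(monomers=[long_unit], n_units=30, per_copy_divergence=0.0), rng
    )
    truth = simulate.embed_in_background(
        [simulate.PlantedArray("sat0", arr, tr.unit)], 100_000, rng
    )
    reads = simulate.simulate_reads(
        truth.sequence, simulate.ReadSpec(read_len=1000, depth=15, error_rate=0.0, seed=4)
    )
    total = sum(len(s) for _, s in reads)
    unit = RepeatUnit("unit-0001", long_unit, 31, 1, 1, 1.0)
    hits = naive_align([unit], reads)
    ivs = filter_and_merge(hits, FilterParams(), {n: len(s) for n, s in reads}, {"unit-0001": 900})
    rep = compute_abundance(ivs, total)
    assert rep.total_fraction < 0.5 * truth.satellite_fraction
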