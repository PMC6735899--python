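"""Caller: quality confidence, filtering, ranking, truncation, round trips."""

import pytest

from poolscreen.align import MismatchObservation
from poolscreen.calling import (
    CallerConfig,
    call_and_rank,
    filter_mismatches,
    quality_confidence,
    read_calls,
    write_calls,
    write_vcf,
)
from poolscreen.errors import ConfigError, DataError


def obs(ref, pos, alt, quality=40, read_id=None):
    return MismatchObservation(
        orf_pos=pos, ref_base=ref.base(pos), read_base=alt,
        quality=quality, read_id=read_id or f"r{pos}.{alt}.{quality}",
    )


def alt_of(ref, pos, skip=()):
    return next(b for b in "ACGT" if b != ref.base(pos) and b not in skip)


class TestQualityConfidence:
    def test_q38_is_9998_percent(self):
        assert round(quality_confidence(38), 2) == 99.98

    @pytest.mark.parametrize("q,expected", [(0, 0.0), (10, 90.0), (20, 99.0)])
    def test_round_values(self, q, expected):
        assert quality_confidence(q) == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(ConfigError):
            quality_confidence(-1)


class TestFilter:
    def test_boundary_38_kept_37_dropped(self, toy_ref):
        cfg = CallerConfig(min_quality=38)
        kept = filter_mismatches(
            [obs(toy_ref, 4, "A", 38), obs(toy_ref, 4, "A", 37)], cfg
        )
        assert [o.quality for o in kept] == [38]

    def test_zero_threshold_is_identity_and_order_preserving(self, toy_ref):
        xs = [obs(toy_ref, p, alt_of(toy_ref, p), q) for p, q in [(9, 2), (4, 40), (7, 0)]]
        assert filter_mismatches(xs, CallerConfig(min_quality=0)) == xs

    def test_empty_in_empty_out(self):
        assert filter_mismatches([], CallerConfig()) == []


class TestCallAndRank:
    def test_supporting_read_counting_and_ranks(self, toy_ref):
        p1, p2 = 4, 22
        a1, a2 = alt_of(toy_ref, p1), alt_of(toy_ref, p2)
        observations = [
            obs(toy_ref, p1, a1, read_id="r1"),
            obs(toy_ref, p1, a1, read_id="r2"),
            obs(toy_ref, p1, a1, read_id="r3"),
            obs(toy_ref, p2, a2, read_id="r4"),
        ]
        table = call_and_rank(toy_ref, observations, CallerConfig(include_synonymous=True))
        assert [(e.rank, e.supporting_reads) for e in table.entries] == [(1, 3), (2, 1)]
        assert table.threshold_reads == 1

    def test_duplicate_observations_from_one_read_count_once(self, toy_ref):
        o = obs(toy_ref, 4, alt_of(toy_ref, 4), read_id="same")
        table = call_and_rank(toy_ref, [o, o], CallerConfig(include_synonymous=True))
        assert table.entries[0].supporting_reads == 1

    def test_tie_break_by_residue_then_alt_aa(self, toy_ref):
        # two substitutions with equal support: order by residue ascending
        p_hi, p_lo = 100, 10
        observations = [
            obs(toy_ref, p_hi, alt_of(toy_ref, p_hi), read_id="a"),
            obs(toy_ref, p_lo, alt_of(toy_ref, p_lo), read_id="b"),
        ]
        t1 = call_and_rank(toy_ref, observations, CallerConfig(include_synonymous=True))
        t2 = call_and_rank(toy_ref, observations[::-1], CallerConfig(include_synonymous=True))
        assert [e.key() for e in t1.entries] == [e.key() for e in t2.entries]
        assert t1.entries[0].residue < t1.entries[1].residue

    def test_truncation_noop_below_top_n(self, toy_ref):
        positions = range(4, 44)
        observations = [obs(toy_ref, p, alt_of(toy_ref, p)) for p in positions]
        table = call_and_rank(toy_ref, observations, CallerConfig(top_n=100, include_synonymous=True))
        assert len(table) == 40
        assert table.threshold_reads == table.entries[-1].supporting_reads

    def test_boundary_ties_reported_in_annex_not_table(self, toy_ref):
        observations = [obs(toy_ref, p, alt_of(toy_ref, p)) for p in range(4, 14)]
        table = call_and_rank(toy_ref, observations, CallerConfig(top_n=5, include_synonymous=True))
        assert len(table) == 5
        assert len(table.boundary_ties) == 5  # all tied at 1 supporting read
        assert all(e.supporting_reads == table.threshold_reads for e in table.boundary_ties)

    def test_synonymous_flagged_and_excluded_by_default(self, toy_ref):
        # find a synonymous change on the toy ORF (third codon positions)
        from poolscreen.reference import substitution_from_mismatch

        syn = next(
            (p, b)
            for p in range(3, len(toy_ref.seq) + 1, 3)
            for b in "ACGT"
            if b != toy_ref.base(p)
            and substitution_from_mismatch(toy_ref, p, b).synonymous
        )
        observations = [obs(toy_ref, syn[0], syn[1]), obs(toy_ref, 4, alt_of(toy_ref, 4))]
        default = call_and_rank(toy_ref, observations, CallerConfig())
        assert syn not in {e.key() for e in default.entries}
        included = call_and_rank(toy_ref, observations, CallerConfig(include_synonymous=True))
        assert syn in {e.key() for e in included.entries}

    def test_quality_filter_applied_internally_idempotent(self, toy_ref):
        xs = [obs(toy_ref, 4, alt_of(toy_ref, 4), 10, "low")]
        table = call_and_rank(toy_ref, xs, CallerConfig(min_quality=38))
        assert len(table) == 0
        assert table.totals["calls_passing_quality"] == 0
        assert table.totals["mismatch_reads_in"] == 1

    def test_corruption_guard_names_position(self, toy_ref):
        pos = 4
        wrong_ref = alt_of(toy_ref, pos)
        bad = MismatchObservation(
            orf_pos=pos, ref_base=wrong_ref,
            read_base=alt_of(toy_ref, pos, skip=(wrong_ref,)),
            quality=40, read_id="bad",
        )
        with pytest.raises(DataError, match=str(pos)):
            call_and_rank(toy_ref, [bad], CallerConfig())

    def test_collapse_aa_merges_degenerate_routes(self, toy_ref):
        # arginine-style degeneracy is rare on a random ORF; force one by
        # finding two nucleotide changes in a codon yielding the same AA
        from poolscreen.reference import substitution_from_mismatch

        found = None
        for pos in range(1, len(toy_ref.seq) + 1):
            for b in "ACGT":
                if b == toy_ref.base(pos):
                    continue
                s1 = substitution_from_mismatch(toy_ref, pos, b)
                if s1.synonymous:
                    continue
                for pos2 in range(3 * (s1.residue - 1) + 1, 3 * s1.residue + 1):
                    for b2 in "ACGT":
                        if b2 == toy_ref.base(pos2) or (pos2, b2) == (pos, b):
                            continue
                        s2 = substitution_from_mismatch(toy_ref, pos2, b2)
                        if s2.aa_key() == s1.aa_key():
                            found = ((pos, b), (pos2, b2))
                            break
                    if found:
                        break
                if found:
                    break
            if found:
                break
        assert found, "toy ORF unexpectedly lacks any degenerate AA route"
        (pa, ba), (pb, bb) = found
        observations = [
            obs(toy_ref, pa, ba, read_id="x1"),
            obs(toy_ref, pb, bb, read_id="x2"),
            obs(toy_ref, pb, bb, read_id="x3"),
        ]
        table = call_and_rank(toy_ref, observations, CallerConfig())
        assert len(table) == 2  # nt-level rows stay separate
        collapsed = table.collapse_aa()
        assert len(collapsed) == 1
        assert collapsed.entries[0].supporting_reads == 3


class TestRoundTrip:
    def _table(self, toy_ref):
        observations = [obs(toy_ref, p, alt_of(toy_ref, p)) for p in (4, 8, 22, 100)]
        observations += [obs(toy_ref, 4, alt_of(toy_ref, 4), read_id="extra")]
        return call_and_rank(toy_ref, observations, CallerConfig(include_synonymous=True))

    def test_write_read_lossless(self, toy_ref, tmp_path):
        table = self._table(toy_ref)
        path = tmp_path / "calls.tsv"
        write_calls(table, path)
        loaded = read_calls(path)
        assert loaded.entries == table.entries
        assert loaded.threshold_reads == table.threshold_reads
        assert loaded.totals == table.totals
        assert loaded.ref_id == table.ref_id

    def test_ranks_strictly_sequential(self, toy_ref):
        table = self._table(toy_ref)
        assert [e.rank for e in table.entries] == list(range(1, len(table) + 1))

    def test_empty_table_round_trip(self, toy_ref, tmp_path):
        table = call_and_rank(toy_ref, [], CallerConfig())
        path = tmp_path / "empty.tsv"
        write_calls(table, path)
        assert read_calls(path).entries == []

    def test_vcf_export_one_row_per_entry(self, toy_ref, tmp_path):
        table = self._table(toy_ref)
        path = tmp_path / "calls.vcf"
        write_vcf(table, toy_ref, path)
        body = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        assert len(body) == len(table)
        assert all(l.split("\t")[0] == toy_ref.id for l in body)
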