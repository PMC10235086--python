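"""Classification rules: spec'd cases, oracle agreement, tally properties."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cenrna.classify import (
    ClassificationError,
    classify_fragment,
    classify_frame,
    length_class,
    tally,
    term_class_distribution,
)
from cenrna.fragments import FragmentRecord, SampleSheet, frame_from_records
from cenrna.genome import OrfFeature, build_genome_model

from oracle import oracle_classify


def _rec(start, end, strand="+", chrom="chrT", sample="s1", name="f"):
    return FragmentRecord(chrom=chrom, start=start, end=end, strand=strand,
                          sample=sample, name=name)


class TestClassifyFragment:
    def test_cdeii_terminating_cen_fragment(self, toy_model):
        """End boundary 1050 falls in CDEII [1008,1092); 5' end upstream."""
        c = classify_fragment(_rec(900, 1050), toy_model)
        assert c.tclass == "CEN"
        assert c.term_class == "CDEII"
        assert c.initiated_in_pericen
        assert c.length_class == "SHORT"
        assert c.side == "UP"

    def test_full_core_coverage(self, toy_model):
        c = classify_fragment(_rec(990, 1200), toy_model)
        assert c.tclass == "CEN"
        assert c.term_class == "FULL_CEN"

    def test_noncoding_pericen_up_window(self, toy_model):
        c = classify_fragment(_rec(600, 840), toy_model)
        assert c.tclass == "PERICEN_NONCODING"
        assert c.side == "UP"
        assert c.term_class == "NONE" and c.length_class == "NONE"

    def test_outside_everything_is_other(self, toy_model):
        assert classify_fragment(_rec(100, 300), toy_model).tclass == "OTHER"

    def test_coding_pericen_requires_orf_overlap(self, toy_model_with_orf):
        assert classify_fragment(_rec(600, 840), toy_model_with_orf).tclass == "PERICEN_CODING"
        assert classify_fragment(_rec(850, 950), toy_model_with_orf).tclass == "PERICEN_NONCODING"

    def test_coding_strand_matched_switch(self, toy_model_with_orf):
        c = classify_fragment(_rec(600, 840, strand="-"), toy_model_with_orf,
                              coding_strand_matched=True)
        assert c.tclass == "PERICEN_NONCODING"  # ORF is '+', fragment '-'

    def test_core_overlap_beats_orf_overlap(self, toy_model_with_orf):
        """Subtraction semantics: any core overlap makes a fragment CEN."""
        c = classify_fragment(_rec(700, 1010), toy_model_with_orf)
        assert c.tclass == "CEN"

    def test_unknown_chromosome_raises(self, toy_model):
        with pytest.raises(ClassificationError, match="chrZ"):
            classify_fragment(_rec(1, 10, chrom="chrZ"), toy_model)

    def test_wholly_inside_core_uses_three_prime_boundary(self, toy_model):
        # [1010,1100) has start in CDEII, end-1=1099 in CDEIII
        assert classify_fragment(_rec(1010, 1100, "+"), toy_model).term_class == "CDEIII"
        assert classify_fragment(_rec(1010, 1100, "-"), toy_model).term_class == "CDEII"


class TestLengthClass:
    @pytest.mark.parametrize(
        "length,expected",
        [(231, "SHORT"), (4458, "LONG"), (999, "SHORT"), (1000, "LONG"), (125, "SHORT")],
    )
    def test_published_and_boundary_lengths(self, length, expected):
        assert length_class(length) == expected


class TestOracleAgreement:
    def test_exhaustive_agreement_on_tiny_chromosome(self, tiny_model):
        """Vectorised classifier == set-based oracle for every placement.

        All start/end pairs on a 200 bp chromosome with a 20 bp core,
        both strands — exhaustive, not sampled.
        """
        records = [
            _rec(s, e, strand, name=f"{s}-{e}{strand}")
            for s in range(200)
            for e in range(s + 1, 201)
            for strand in ("+", "-")
        ]
        frame = classify_frame(frame_from_records(records), tiny_model)
        for row in frame.itertuples(index=False):
            exp = oracle_classify(row.chrom, row.start, row.end, row.strand, tiny_model)
            got = {
                "tclass": row.tclass, "term_class": row.term_class,
                "length_class": row.length_class,
                "initiated_in_pericen": row.initiated_in_pericen, "side": row.side,
            }
            assert got == exp, f"[{row.start},{row.end}){row.strand}: {got} != {exp}"

    def test_scalar_and_vectorised_paths_agree(self, toy_model_with_orf):
        rng = np.random.default_rng(0)
        records = [
            _rec(int(s), int(s + w), strand, name=str(i))
            for i, (s, w, strand) in enumerate(
                zip(
                    rng.integers(0, 2500, 500),
                    rng.integers(1, 1500, 500),
                    rng.choice(["+", "-"], 500),
                )
            )
        ]
        frame = classify_frame(frame_from_records(records), toy_model_with_orf)
        for rec, row in zip(records, frame.itertuples(index=False)):
            c = classify_fragment(rec, toy_model_with_orf)
            assert (
                c.tclass, c.term_class, c.length_class, c.initiated_in_pericen, c.side,
            ) == (
                row.tclass, row.term_class, row.length_class,
                row.initiated_in_pericen, row.side,
            )

    def test_subtraction_equivalence(self, tiny_model):
        """PERICEN_* == {window-overlapping} minus {core-overlapping}.

        Mirrors the two-pass intersect/subtract extraction, checked
        exhaustively on the tiny chromosome.
        """
        core = tiny_model.cores["chrT"]
        win = tiny_model.windows["chrT"]
        core_pos = set(range(core.start, core.end))
        win_pos = set(range(*win.up)) | set(range(*win.down))
        for s in range(200):
            for e in range(s + 1, 201):
                pos = set(range(s, e))
                in_subtracted_set = bool(pos & win_pos) and not (pos & core_pos)
                c = classify_fragment(_rec(s, e), tiny_model)
                assert c.tclass.startswith("PERICEN") == in_subtracted_set

    def test_mirror_symmetry(self):
        """Reflecting coordinates and strands maps UP<->DOWN and CDEI<->CDEIII."""
        L = 10_000
        model = build_genome_model({"chrT": L}, {"chrT": (1000, 1117)})
        mirrored = build_genome_model(
            {"chrT": L}, {"chrT": (L - 1117, L - 1000)}, cde1_len=25, cde3_len=8
        )
        # mirrored CDE layout: CDEI(8bp) of the original becomes the *last*
        # 8 bp, i.e. the mirrored model's cde3 slot; swap names accordingly
        swap = {"CDEI": "CDEIII", "CDEIII": "CDEI", "CDEII": "CDEII",
                "FULL_CEN": "FULL_CEN", "NONE": "NONE"}
        side_swap = {"UP": "DOWN", "DOWN": "UP", "BOTH": "BOTH", "NONE": "NONE"}
        rng = np.random.default_rng(1)
        for _ in range(300):
            s = int(rng.integers(0, 2500))
            w = int(rng.integers(1, 1500))
            strand = str(rng.choice(["+", "-"]))
            c = classify_fragment(_rec(s, s + w, strand), model)
            m_strand = "-" if strand == "+" else "+"
            cm = classify_fragment(_rec(L - (s + w), L - s, m_strand), mirrored)
            assert cm.tclass == c.tclass
            assert cm.term_class == swap[c.term_class]
            assert cm.side == side_swap[c.side]
            assert cm.initiated_in_pericen == c.initiated_in_pericen

    def test_coding_exclusion_near_core(self):
        """With ORFs only >200 bp from the core, fragments confined to the
        200 bp surrounding the core are never PERICEN_CODING."""
        orf = OrfFeature(chrom="chrT", start=300, end=795, strand="+", id="o")
        model = build_genome_model({"chrT": 10_000}, {"chrT": (1000, 1117)}, [orf])
        for s in range(800, 1320, 7):
            for w in (5, 60, 150):
                e = min(s + w, 1317)
                if e <= s:
                    continue
                c = classify_fragment(_rec(s, e), model)
                assert c.tclass != "PERICEN_CODING"


class TestTally:
    def _sheet(self):
        return SampleSheet(
            pd.DataFrame(
                {"sample": ["s1"], "condition": ["mock"], "replicate": [1],
                 "total_fragments": [100]}
            )
        )

    def _classified(self, toy_model, records):
        return classify_frame(frame_from_records(records), toy_model)

    def test_marginals_count_all_fragments(self, toy_model):
        records = [_rec(1000, 1050, name=str(i)) for i in range(3)] + [
            _rec(600, 840, name=f"p{i}") for i in range(2)
        ]
        t = tally(self._classified(toy_model, records), self._sheet())
        by_class = t.groupby("tclass")["count"].sum()
        assert by_class["CEN"] == 3
        assert by_class["PERICEN_NONCODING"] == 2
        assert t["count"].sum() == len(records)

    def test_empty_stream_zero_tally(self, toy_model):
        t = tally(
            classify_frame(frame_from_records([]), toy_model), self._sheet()
        )
        assert t.empty

    def test_order_independence(self, toy_model):
        records = [_rec(990 + i, 1200 + 3 * i, name=str(i)) for i in range(20)]
        t1 = tally(self._classified(toy_model, records), self._sheet())
        t2 = tally(self._classified(toy_model, records[::-1]), self._sheet())
        pd.testing.assert_frame_equal(t1, t2)

    def test_unknown_sample_rejected(self, toy_model):
        cl = self._classified(toy_model, [_rec(1000, 1050, sample="ghost")])
        with pytest.raises(ClassificationError, match="ghost"):
            tally(cl, self._sheet())


class TestTermDistribution:
    def _setup(self, toy_model, records):
        sheet = SampleSheet(
            pd.DataFrame(
                {"sample": ["s1"], "condition": ["mock"], "replicate": [1],
                 "total_fragments": [100]}
            )
        )
        t = tally(classify_frame(frame_from_records(records), toy_model), sheet)
        return t, sheet

    def test_all_full_cen_distribution(self, toy_model):
        records = [_rec(990, 1200, name=str(i)) for i in range(5)]
        t, sheet = self._setup(toy_model, records)
        d = term_class_distribution(t, "mock", sheet)
        full_plus = d[(d.term_class == "FULL_CEN") & (d.strand == "+")]["fraction"]
        assert float(full_plus.iloc[0]) == 1.0
        assert d["fraction"].sum() == pytest.approx(1.0)

    def test_fractions_sum_to_one_mixed(self, toy_model):
        rng = np.random.default_rng(3)
        records = [
            _rec(int(s), int(s) + int(w), str(st_), name=str(i))
            for i, (s, w, st_) in enumerate(
                zip(rng.integers(900, 1110, 200), rng.integers(10, 600, 200),
                    rng.choice(["+", "-"], 200))
            )
        ]
        t, sheet = self._setup(toy_model, records)
        d = term_class_distribution(t, "mock", sheet)
        assert d["fraction"].sum() == pytest.approx(1.0)
        assert d["count"].sum() == (
            classify_frame(frame_from_records(records), toy_model)["tclass"] == "CEN"
        ).sum()

    def test_zero_cen_fragments_error(self, toy_model):
        t, sheet = self._setup(toy_model, [_rec(100, 200)])
        with pytest.raises(ClassificationError, match="zero CEN"):
            term_class_distribution(t, "mock", sheet)


@given(
    st.lists(
        st.tuples(st.integers(0, 2400), st.integers(1, 800), st.sampled_from(["+", "-"])),
        min_size=1, max_size=50,
    )
)
@settings(max_examples=100, derandomize=True)
def test_partition_every_fragment_gets_exactly_one_class(tuples):
    """Property: classes partition the fragment set (CEN beats PERICEN)."""
    model = build_genome_model({"chrT": 10_000}, {"chrT": (1000, 1117)})
    records = [
        _rec(s, s + w, strand, name=str(i)) for i, (s, w, strand) in enumerate(tuples)
    ]
    frame = classify_frame(frame_from_records(records), model)
    assert frame["tclass"].isin(["CEN", "PERICEN_NONCODING", "PERICEN_CODING", "OTHER"]).all()
    cen = frame[frame["tclass"] == "CEN"]
    core = model.cores["chrT"]
    # CEN iff >=1 bp core overlap, regardless of window overlap
    overlaps = (frame["start"] < core.end) & (frame["end"] > core.start)
    assert ((frame["tclass"] == "CEN") == overlaps).all()
    assert (cen["term_class"] != "NONE").all()
    assert (frame.loc[frame["tclass"] != "CEN", "term_class"] == "NONE").all()
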