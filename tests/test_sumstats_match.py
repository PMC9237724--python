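"""Variant reading, matching and harmonization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import sumdeconv as sd
from sumdeconv.sumstats_match import COMPLEMENT


def _write(path, text):
    path.write_text(text)
    return path


def _table(rows):
    """Build a FreqTable from (chrom, pos, a1, a2, freq) tuples."""
    chrom, pos, a1, a2, freq = zip(*rows)
    return sd.FreqTable(
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        a1=np.array(a1, dtype=object),
        a2=np.array(a2, dtype=object),
        freq=np.array(freq, dtype=float),
    )


def _panel(rows, k=1):
    chrom, pos, a1, a2 = zip(*rows)
    m = len(rows)
    return sd.ReferencePanel(
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        a1=np.array(a1, dtype=object),
        a2=np.array(a2, dtype=object),
        freqs=np.full((m, k), 0.5),
        groups=[f"g{i}" for i in range(k)],
        sizes=np.full(k, 10),
    )


class TestReadFreqTable:
    def test_out_of_range_frequency_dropped(self, tmp_path):
        p = _write(
            tmp_path / "t.tsv",
            "chr\tpos\ta1\ta2\tfreq\n1\t100\tA\tG\t0.3\n1\t200\tA\tG\t1.2\n1\t300\tC\tT\t0.9\n",
        )
        t = sd.read_freq_table(p)
        assert len(t) == 2
        assert list(t.pos) == [100, 300]

    def test_duplicate_key_keeps_first(self, tmp_path):
        p = _write(
            tmp_path / "t.tsv",
            "chr\tpos\ta1\ta2\tfreq\n1\t100\tA\tG\t0.3\n1\t100\tG\tA\t0.6\n",
        )
        t = sd.read_freq_table(p)
        assert len(t) == 1
        assert t.freq[0] == 0.3

    def test_well_formed_rows_kept_in_file_order(self, tmp_path):
        rows = [(f"1\t{100 * i}\tA\tG\t0.{i}") for i in range(1, 6)]
        p = _write(tmp_path / "t.tsv", "chr\tpos\ta1\ta2\tfreq\n" + "\n".join(rows) + "\n")
        t = sd.read_freq_table(p)
        assert len(t) == 5
        assert list(t.pos) == [100, 200, 300, 400, 500]

    def test_indels_and_bad_alleles_rejected(self, tmp_path):
        p = _write(
            tmp_path / "t.tsv",
            "chr\tpos\ta1\ta2\tfreq\n1\t100\tAT\tG\t0.3\n1\t200\tA\tN\t0.4\n"
            "1\t300\tA\tA\t0.2\n1\t400\tT\tC\t0.5\n",
        )
        t = sd.read_freq_table(p)
        assert len(t) == 1 and t.pos[0] == 400

    def test_chr_prefix_normalized(self, tmp_path):
        p = _write(tmp_path / "t.csv", "chr,pos,a1,a2,freq\nchr7,100,A,G,0.3\nchrX,5,C,T,0.2\n")
        t = sd.read_freq_table(p)
        assert list(t.chrom) == ["7", "X"]

    def test_column_map(self, tmp_path):
        p = _write(tmp_path / "t.tsv", "CHR\tBP\tREF\tALT\tAF\n1\t9\tA\tG\t0.25\n")
        t = sd.read_freq_table(
            p, column_map={"chrom": "CHR", "pos": "BP", "a1": "REF", "a2": "ALT", "freq": "AF"}
        )
        assert t.freq[0] == 0.25

    def test_empty_table_is_fatal(self, tmp_path):
        p = _write(tmp_path / "t.tsv", "chr\tpos\ta1\ta2\tfreq\n1\t100\tA\tG\t2.0\n")
        with pytest.raises(sd.SumdeconvError, match="empty"):
            sd.read_freq_table(p)

    def test_missing_file_is_fatal(self, tmp_path):
        with pytest.raises(sd.SumdeconvError):
            sd.read_freq_table(tmp_path / "nope.tsv")


class TestVariantKey:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(chrom="1", pos=0, a1="A", a2="G"),
            dict(chrom="1", pos=5, a1="A", a2="A"),
            dict(chrom="1", pos=5, a1="AT", a2="G"),
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            sd.VariantKey(**kwargs)

    def test_ambiguity(self):
        assert sd.VariantKey("1", 5, "A", "T").is_ambiguous
        assert not sd.VariantKey("1", 5, "A", "G").is_ambiguous


class TestMatchVariants:
    def test_allele_swap_sets_swapped(self):
        ss = _table([("1", 100, "A", "G", 0.3)])
        pn = _panel([("1", 100, "G", "A")])
        m = sd.match_variants(ss, pn)
        assert m.n_matched == 1 and m.swapped[0] and not m.strand_flipped[0]

    def test_strand_complement_sets_flip_only(self):
        ss = _table([("1", 100, "T", "C", 0.3)])
        pn = _panel([("1", 100, "A", "G")])
        m = sd.match_variants(ss, pn)
        assert m.n_matched == 1 and m.strand_flipped[0] and not m.swapped[0]

    def test_ambiguous_excluded_by_default(self):
        ss = _table([("1", 100, "A", "T", 0.3)])
        pn = _panel([("1", 100, "A", "T")])
        with pytest.raises(sd.SumdeconvError, match="no overlap"):
            sd.match_variants(ss, pn, remove_ambiguous=True)

    def test_ambiguous_kept_when_flag_off(self):
        ss = _table([("1", 100, "A", "T", 0.3)])
        pn = _panel([("1", 100, "A", "T")])
        m = sd.match_variants(ss, pn, remove_ambiguous=False)
        assert m.n_matched == 1 and not m.swapped[0]

    def test_position_mismatch_not_matched(self):
        ss = _table([("1", 100, "A", "G", 0.3), ("1", 200, "A", "G", 0.4)])
        pn = _panel([("1", 200, "A", "G"), ("2", 100, "A", "G")])
        m = sd.match_variants(ss, pn)
        assert m.n_matched == 1
        assert m.idx_sumstats[0] == 1

    def test_symmetric_match_count(self, small_bundle):
        panel = small_bundle.sim.panel
        ss = sd.simulate_cohort_sumstats(
            panel, panel.freqs, small_bundle.config.alpha_true, None, seed=3
        )
        m_fwd = sd.match_variants(ss, panel)
        # reverse direction: treat the panel as a frequency table
        rev = sd.FreqTable(
            chrom=panel.chrom, pos=panel.pos, a1=panel.a1, a2=panel.a2,
            freq=panel.freqs[:, 0],
        )
        pn_rev = sd.ReferencePanel(
            chrom=ss.chrom, pos=ss.pos, a1=ss.a1, a2=ss.a2,
            freqs=ss.freq[:, None], groups=["cohort"], sizes=np.array([1]),
        )
        m_rev = sd.match_variants(rev, pn_rev)
        assert m_fwd.n_matched == m_rev.n_matched


class TestHarmonize:
    def test_swap_complements_frequency(self):
        ss = _table([("1", 100, "A", "G", 0.3)])
        pn = _panel([("1", 100, "G", "A")])
        f0, _ = sd.harmonize(ss, pn, sd.match_variants(ss, pn))
        assert f0[0] == pytest.approx(0.7, abs=1e-15)

    def test_strand_flip_leaves_frequency(self):
        ss = _table([("1", 100, "T", "C", 0.3)])
        pn = _panel([("1", 100, "A", "G")])
        f0, _ = sd.harmonize(ss, pn, sd.match_variants(ss, pn))
        assert f0[0] == pytest.approx(0.3, abs=1e-15)

    def test_identity_passthrough(self):
        ss = _table([("1", 100, "A", "G", 0.42)])
        pn = _panel([("1", 100, "A", "G")])
        f0, _ = sd.harmonize(ss, pn, sd.match_variants(ss, pn))
        assert f0[0] == 0.42

    def test_stale_match_detected(self):
        ss = _table([("1", 100, "A", "G", 0.42)])
        pn = _panel([("1", 100, "A", "G")])
        m = sd.match_variants(ss, pn)
        tiny = _table([("1", 100, "A", "G", 0.42)])
        m.idx_panel = np.array([5])
        with pytest.raises(sd.SumdeconvError, match="stale"):
            sd.harmonize(tiny, pn, m)


class TestRoundTripProperties:
    def test_self_match_is_identity(self, small_bundle):
        panel = small_bundle.sim.panel
        ss = sd.FreqTable(
            chrom=panel.chrom, pos=panel.pos, a1=panel.a1, a2=panel.a2,
            freq=panel.freqs[:, 0],
        )
        m = sd.match_variants(ss, panel)
        assert m.n_matched == m.n_input - m.n_ambiguous_removed
        assert not m.swapped.any() and not m.strand_flipped.any()
        f0, _ = sd.harmonize(ss, panel, m)
        np.testing.assert_array_equal(f0, panel.freqs[m.idx_panel, 0])

    def test_swap_involution(self, small_bundle):
        """Swapping every allele pair flips the flag but not the harmonized values."""
        panel = small_bundle.sim.panel
        base = sd.FreqTable(
            chrom=panel.chrom, pos=panel.pos, a1=panel.a1, a2=panel.a2,
            freq=panel.freqs[:, 0],
        )
        swapped = sd.FreqTable(
            chrom=panel.chrom, pos=panel.pos, a1=panel.a2, a2=panel.a1,
            freq=1.0 - panel.freqs[:, 0],
        )
        m0 = sd.match_variants(base, panel)
        m1 = sd.match_variants(swapped, panel)
        assert m1.swapped.all()
        f0a, _ = sd.harmonize(base, panel, m0)
        f0b, _ = sd.harmonize(swapped, panel, m1)
        np.testing.assert_allclose(f0a, f0b, atol=1e-15)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(
    st.lists(
        st.tuples(
            st.integers(1, 3),
            st.integers(1, 50),
            st.sampled_from(["A", "C", "G", "T"]),
            st.sampled_from(["A", "C", "G", "T"]),
            st.floats(0, 1, allow_nan=False),
        ),
        min_size=1,
        max_size=20,
    )
)
def test_matching_flags_consistent_with_alleles(rows):
    """Whatever the table, every reported match obeys its own flags."""
    rows = [(str(c), p, a1, a2, f) for c, p, a1, a2, f in rows if a1 != a2]
    seen = set()
    uniq = []
    for r in rows:
        key = (r[0], r[1], frozenset((r[2], r[3])))
        if key not in seen:
            seen.add(key)
            uniq.append(r)
    if not uniq:
        return
    ss = _table(uniq)
    pn = _panel([(c, p, a1, a2) for c, p, a1, a2, _ in uniq])
    m = sd.match_variants(ss, pn, remove_ambiguous=False)
    for si, pi, sw, fl in zip(m.idx_sumstats, m.idx_panel, m.swapped, m.strand_flipped):
        a1, a2 = ss.a1[si], ss.a2[si]
        if sw:
            a1, a2 = a2, a1
        if fl:
            a1, a2 = COMPLEMENT[a1], COMPLEMENT[a2]
        assert (a1, a2) == (pn.a1[pi], pn.a2[pi])


def test_panel_roundtrip_through_files(small_bundle, tmp_path):
    panel = small_bundle.sim.panel
    path = tmp_path / "panel.tsv"
    sd.write_panel(panel, path)
    back = sd.read_panel(path)
    assert back.groups == panel.groups
    np.testing.assert_array_equal(back.sizes, panel.sizes)
    np.testing.assert_allclose(back.freqs, panel.freqs, atol=0)
    np.testing.assert_array_equal(back.pos, panel.pos)
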