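import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from colxlink.conservation import (
    RESIDUES,
    build_profile,
    export_logo_matrix,
    lysine_depletion_probability,
    measure_depletion_regions,
)
from colxlink.chain_io import Region
from colxlink.errors import EmptyProfileError
from colxlink.sites import CrosslinkSite

from conftest import make_chain
from oracles import entropy_information_bits

LOG2_20 = math.log2(20)


def _site(chain_id, k, cls="telo_C"):
    return CrosslinkSite(chain_id=chain_id, site_class=cls, k_pos=k, window="-" * 7, score=1.0)


class TestBuildProfile:
    def test_identical_windows_are_point_masses(self):
        chains = [make_chain("AAEKGPPAAA", f"c{i}") for i in range(2)]
        sites = [_site(c.chain_id, 3) for c in chains]
        profile = build_profile(sites, chains, flank_left=2, flank_right=4, pseudocount=0.0)
        assert profile.width == 7
        assert all(w == "AEKGPPA" for w in profile.windows)
        assert profile.info_content == pytest.approx([LOG2_20] * 7)
        # the anchor column is all K with frequency 1
        k_col = profile.frequencies[2, RESIDUES.index("K")]
        assert k_col == 1.0

    def test_mixed_column_hand_computed_entropy(self):
        # column {G, G, A}: H(2/3, 1/3) = 0.9183, info = 4.3219 - 0.9183
        seqs = ["AAKGAAA", "AAKGAAA", "AAKAAAA"]
        chains = [make_chain(s, f"c{i}") for i, s in enumerate(seqs)]
        sites = [_site(c.chain_id, 2) for c in chains]
        profile = build_profile(sites, chains, flank_left=2, flank_right=4, pseudocount=0.0)
        assert profile.info_content[3] == pytest.approx(3.4036, abs=1e-4)
        g = profile.frequencies[3, RESIDUES.index("G")]
        a = profile.frequencies[3, RESIDUES.index("A")]
        assert (g, a) == pytest.approx((2 / 3, 1 / 3))

    def test_uniform_column_has_zero_information(self):
        chains = [make_chain(f"AK{r}A", f"c{i}") for i, r in enumerate(RESIDUES)]
        sites = [_site(c.chain_id, 1) for c in chains]
        profile = build_profile(sites, chains, flank_left=0, flank_right=1, pseudocount=0.0)
        assert profile.info_content[1] == pytest.approx(0.0, abs=1e-12)

    def test_pads_and_x_excluded_from_counts(self):
        chains = [make_chain("KXA", "c0")]  # window clipped at the chain start
        profile = build_profile([_site("c0", 0)], chains, flank_left=2, flank_right=2)
        assert profile.windows == ["--KXA"]
        assert profile.counts[0].sum() == 0  # pad column
        assert profile.counts[3].sum() == 0  # X column
        assert profile.frequencies[0] == pytest.approx([1 / 20] * 20)
        assert profile.info_content[0] == 0.0

    def test_pseudocount_flattens_frequencies(self):
        chains = [make_chain("AKGA", "c0")]
        raw = build_profile([_site("c0", 1)], chains, 1, 1, pseudocount=0.0)
        smoothed = build_profile([_site("c0", 1)], chains, 1, 1, pseudocount=0.5)
        assert raw.info_content[2] == pytest.approx(LOG2_20)
        assert 0 < smoothed.info_content[2] < raw.info_content[2]
        assert smoothed.frequencies.sum(axis=1) == pytest.approx([1.0] * 3)

    def test_empty_site_list_is_an_error(self):
        with pytest.raises(EmptyProfileError):
            build_profile([], [], 2, 4)

    def test_mixed_classes_rejected(self):
        chains = [make_chain("AKGA", "c0"), make_chain("AKGA", "c1")]
        sites = [_site("c0", 1, "telo_C"), _site("c1", 1, "telo_N")]
        with pytest.raises(ValueError):
            build_profile(sites, chains, 1, 1)

    def test_information_matches_entropy_oracle(self, rng):
        # random count tables, compared column-wise at 1e-9
        for _ in range(30):
            n_chains = int(rng.integers(2, 8))
            seqs = [
                "".join(rng.choice(list("ACDEFGHILK"), size=9)) for _ in range(n_chains)
            ]
            chains = [
                make_chain(s[:4] + "K" + s[5:], f"c{i}") for i, s in enumerate(seqs)
            ]
            pseudocount = float(rng.choice([0.0, 0.5]))
            profile = build_profile(
                [_site(c.chain_id, 4) for c in chains], chains, 2, 2, pseudocount
            )
            for col in range(profile.width):
                expected = entropy_information_bits(list(profile.counts[col]), pseudocount)
                assert profile.info_content[col] == pytest.approx(expected, abs=1e-9)


class TestDepletionProbability:
    def test_lengths_summing_275(self):
        res = lysine_depletion_probability([15] * 15 + [10] * 5, f_k=0.072)
        assert res.n_total == 275
        assert res.probability == pytest.approx(0.928**275)
        assert f"{res.probability:.1e}" == "1.2e-09"

    def test_lengths_summing_176(self):
        res = lysine_depletion_probability([176], f_k=0.072)
        assert f"{res.probability:.1e}" == "1.9e-06"

    def test_empty_list_probability_one(self):
        res = lysine_depletion_probability([], f_k=0.072)
        assert res.n_total == 0
        assert res.probability == 1.0

    def test_negative_length_rejected(self):
        with pytest.raises(ValueError):
            lysine_depletion_probability([5, -1])

    def test_f_k_bounds(self):
        with pytest.raises(ValueError):
            lysine_depletion_probability([5], f_k=0.0)
        with pytest.raises(ValueError):
            lysine_depletion_probability([5], f_k=1.0)

    @settings(derandomize=True, max_examples=50)
    @given(
        n=st.integers(min_value=1, max_value=500),
        extra=st.integers(min_value=1, max_value=50),
        f_k=st.floats(min_value=0.01, max_value=0.5),
        df=st.floats(min_value=0.001, max_value=0.4),
    )
    def test_strictly_monotone_in_total_and_frequency(self, n, extra, f_k, df):
        base = lysine_depletion_probability([n], f_k).probability
        assert lysine_depletion_probability([n + extra], f_k).probability < base
        if f_k + df < 1.0:
            assert lysine_depletion_probability([n], f_k + df).probability < base


class TestMeasureDepletionRegions:
    def _annotated_chain(self, chain_id="c0"):
        # minor [30,60), main [100,300): lysine-free telopeptides around K's
        seq = ["A"] * 340
        chain = make_chain("".join(seq), chain_id)
        chain.add_region(Region(30, 60, "minor_helix"))
        chain.add_region(Region(100, 300, "main_helix"))
        return chain

    def test_c_side_length_is_direct_subtraction(self):
        chain = self._annotated_chain()
        top = {"telo_C": _site("c0", 315, "telo_C")}
        out = measure_depletion_regions([(chain, top)])
        assert out["telo_C"]["lengths"] == [15]
        assert out["telo_C"]["lysine_free"] == [True]

    def test_n_side_measured_from_minor_helix_end(self):
        chain = self._annotated_chain()
        top = {"telo_N": _site("c0", 72, "telo_N")}
        out = measure_depletion_regions([(chain, top)])
        assert out["telo_N"]["lengths"] == [12]

    def test_chain_without_site_skipped(self, caplog):
        chain = self._annotated_chain()
        with caplog.at_level("INFO"):
            out = measure_depletion_regions([(chain, {})])
        assert out["telo_C"]["lengths"] == []
        assert out["telo_N"]["lengths"] == []

    def test_lysine_in_stretch_flagged(self):
        chain = self._annotated_chain()
        seq = list(chain.sequence)
        seq[305] = "K"
        chain.sequence = "".join(seq)
        top = {"telo_C": _site("c0", 315, "telo_C")}
        out = measure_depletion_regions([(chain, top)])
        assert out["telo_C"]["lysine_free"] == [False]


class TestExportLogoMatrix:
    def test_tsv_shape_and_row_sums(self, tmp_path):
        chains = [make_chain("AAEKGPPAAA", f"c{i}") for i in range(3)]
        sites = [_site(c.chain_id, 3) for c in chains]
        profile = build_profile(sites, chains, 2, 4)
        out = tmp_path / "logo.tsv"
        export_logo_matrix(profile, out)
        df = pd.read_csv(out, sep="\t", index_col=0)
        assert df.shape == (7, 21)  # 20 residue frequencies + info_content
        freq = df[list(RESIDUES)]
        assert np.allclose(freq.sum(axis=1), 1.0, atol=1e-9)
        # anchor row: K frequency 1 at pseudocount 0
        assert df.loc[0, "K"] == pytest.approx(1.0)
        assert list(df.index) == [-2, -1, 0, 1, 2, 3, 4]
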