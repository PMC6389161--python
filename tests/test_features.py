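import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xtalfate.features import (
    GROUP_SIZES,
    TOTAL_FEATURES,
    aa_composition,
    aaindex_features,
    build_catalog,
    ctd_features,
    dipeptide_composition,
    disorder_profile,
    extract_all,
    global_physchem,
    load_property_alphabets,
    load_residue_scales,
    low_complexity_mask,
    profile_summary34,
)
from xtalfate.features.physchem import aliphatic_index, isoelectric_point, net_charge
from xtalfate.features.scales import window_means
from xtalfate.sequence_io import STANDARD_AA, ProteinRecord

sequences = st.text(alphabet=STANDARD_AA, min_size=30, max_size=120)


class TestCatalog:
    def test_group_sizes_and_total(self, catalog):
        assert len(catalog) == TOTAL_FEATURES == 1276
        for group, size in GROUP_SIZES.items():
            assert catalog.group_indices(group).size == size
        assert len(set(catalog.names)) == TOTAL_FEATURES

    def test_order_is_stable_across_constructions(self, catalog):
        build_catalog.cache_clear()
        assert build_catalog().names == catalog.names
        assert build_catalog().groups == catalog.groups

    def test_export(self, catalog, tmp_path):
        path = tmp_path / "catalog.tsv"
        catalog.to_tsv(path)
        lines = path.read_text().splitlines()
        assert len(lines) == TOTAL_FEATURES + 1
        assert lines[1].split("\t") == [catalog.names[0], catalog.groups[0]]


class TestComposition:
    def test_homopolymer(self):
        comp = aa_composition("A" * 40)
        assert comp[0] == 1.0 and comp[1:].sum() == 0.0

    def test_uniform(self):
        comp = aa_composition(STANDARD_AA * 2)
        np.testing.assert_allclose(comp, 0.05)

    def test_dipeptide_hand_enumeration(self):
        # ACACAC has 5 adjacent pairs: AC x3, CA x2
        dpc = dipeptide_composition("ACACAC")
        names = [f"{a}{b}" for a in STANDARD_AA for b in STANDARD_AA]
        table = dict(zip(names, dpc))
        assert table["AC"] == pytest.approx(3 / 5)
        assert table["CA"] == pytest.approx(2 / 5)
        assert sum(v for k, v in table.items() if k not in ("AC", "CA")) == 0.0

    def test_dipeptide_homopolymer(self):
        dpc = dipeptide_composition("A" * 35)
        assert dpc[0] == 1.0 and dpc.sum() == pytest.approx(1.0)

    @given(sequences)
    @settings(max_examples=25, deadline=None)
    def test_compositions_normalize(self, seq):
        assert aa_composition(seq).sum() == pytest.approx(1.0, abs=1e-9)
        assert dipeptide_composition(seq).sum() == pytest.approx(1.0, abs=1e-9)


class TestCTD:
    def test_output_length(self, random_record):
        assert ctd_features(random_record.sequence).size == 336

    def test_homopolymer_single_class(self):
        values = ctd_features("A" * 40)
        per_property = values.reshape(7, 48)
        for alphabet, block in zip(load_property_alphabets(), per_property):
            ci = next(i for i, cls in enumerate(alphabet.classes) if "A" in cls)
            comp, trans = block[:3], block[3:6]
            assert comp[ci] == 1.0 and comp.sum() == 1.0
            assert np.all(trans == 0.0)
            seg = block[6 + 15 :].reshape(3, 9)
            assert seg[ci][1] == 1.0  # longest run / L

    def test_charged_alternating_sequence(self):
        # K and R share the positive charge class: KRKR... is one long run
        seq = "KR" * 15
        values = ctd_features(seq)
        alphabets = load_property_alphabets()
        prop_idx = next(i for i, a in enumerate(alphabets) if a.name == "charge")
        block = values.reshape(7, 48)[prop_idx]
        ci = next(i for i, cls in enumerate(alphabets[prop_idx].classes) if "K" in cls)
        assert "R" in alphabets[prop_idx].classes[ci]
        assert block[:3][ci] == 1.0
        seg = block[6 + 15 :].reshape(3, 9)
        assert seg[ci][0] == pytest.approx(1 / 30)  # run count / L

    @given(sequences)
    @settings(max_examples=25, deadline=None)
    def test_invariants(self, seq):
        values = ctd_features(seq)
        per_property = values.reshape(7, 48)
        for block in per_property:
            assert block[:3].sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(values >= 0.0) and np.all(values <= 1.0)


class TestResidueScales:
    def test_bundled_set_has_64_tables(self):
        scales = load_residue_scales()
        assert len(scales) == 64
        assert sum(1 for s in scales if s.name.startswith("SYN")) == 48

    def test_output_length(self, random_record):
        assert aaindex_features(random_record.sequence).size == 448

    def test_homopolymer_constant_profile(self):
        values = aaindex_features("G" * 50).reshape(64, 7)
        for scale, row in zip(load_residue_scales(), values):
            g = scale.values[STANDARD_AA.index("G")]
            np.testing.assert_allclose(row, g, atol=1e-12)

    @given(sequences)
    @settings(max_examples=25, deadline=None)
    def test_window_extrema_bracket_mean(self, seq):
        # the grand mean is a convex combination of window means only when
        # disjoint windows tile the sequence, so the bracket is asserted
        # for tiling window lengths; the extrema ordering always holds
        values = aaindex_features(seq).reshape(64, 7)
        mean = values[:, 0]
        for w_idx, w in enumerate((5, 15, 31)):
            wmin, wmax = values[:, 1 + 2 * w_idx], values[:, 2 + 2 * w_idx]
            assert np.all(wmin <= wmax + 1e-12)
            if len(seq) % min(w, len(seq)) == 0:
                assert np.all(wmin <= mean + 1e-12)
                assert np.all(mean <= wmax + 1e-12)

    def test_window_means_brute_force(self, rng):
        profile = rng.standard_normal(37)
        for w in (5, 15, 31, 50):
            got = window_means(profile, w)
            weff = min(w, profile.size)
            expected = [
                profile[i : i + weff].mean()
                for i in range(profile.size - weff + 1)
            ]
            np.testing.assert_allclose(got, expected, atol=1e-12)


class TestGlobalPhyschem:
    def test_aliphatic_index_poly_a_and_poly_v(self):
        # Ikai: X(A) + 2.9 X(V) + 3.9 (X(I)+X(L)) in mole percent
        assert aliphatic_index("A" * 40) == pytest.approx(100.0)
        assert aliphatic_index("V" * 40) == pytest.approx(290.0)

    def test_poly_g_isoelectric_point_is_terminal_midpoint(self):
        # no ionizable side chains: charge curve symmetric around
        # (pKa_Nterm + pKa_Cterm) / 2 = (8.6 + 3.6) / 2
        assert isoelectric_point("G" * 40) == pytest.approx(6.1, abs=2e-3)

    def test_net_charge_signs_at_ph7(self):
        assert net_charge("K" * 40, 7.0) > 30
        assert net_charge("D" * 40, 7.0) < -30

    def test_vector_shape(self, random_record):
        assert global_physchem(random_record.sequence).shape == (4,)


class TestProfiles:
    def test_disorder_contract(self, random_record):
        signal = disorder_profile(random_record.sequence)
        assert signal.size == len(random_record.sequence)
        assert np.all((signal >= 0.0) & (signal <= 1.0))

    def test_charged_sequence_more_disordered_than_hydrophobic(self):
        poly_k = disorder_profile("K" * 50)
        poly_w = disorder_profile("W" * 50)
        assert np.all(poly_k > poly_w)

    def test_low_complexity_homopolymer_fully_masked(self):
        assert np.all(low_complexity_mask("A" * 40) == 1)

    def test_diverse_windows_unmasked(self):
        # every window of 12 holds 12 distinct residues: entropy log2(12) > 2.2
        seq = "ACDEFGHIKLMN" * 4
        assert np.all(low_complexity_mask(seq) == 0)

    def test_mask_length_and_short_sequence(self):
        seq = "ACDEFGHIK"  # shorter than the window: one clipped window
        assert low_complexity_mask(seq).size == len(seq)

    def test_summary_constant_signals(self):
        zeros = profile_summary34(np.zeros(50), 50)
        assert zeros.size == 34
        assert zeros[11] == 0.0  # fraction above 0.5
        assert np.all(zeros[12:24] == 0.0)  # run statistics
        ones = profile_summary34(np.ones(50), 50)
        # coverage at every minimum run length and longest run / L are 1
        assert ones[11] == 1.0
        for t in range(3):
            block = ones[12 + 4 * t : 16 + 4 * t]
            assert block[1] == 1.0 and block[3] == 1.0

    def test_summary_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            profile_summary34(np.zeros(10), 11)

    def test_external_score_file_injection(self, tmp_path, rng):
        from xtalfate.features.profiles import read_score_file

        scores = rng.random(40) * 1.4 - 0.2  # some values outside [0, 1]
        path = tmp_path / "disorder.txt"
        path.write_text(
            "".join(f"{i + 1}\t{s:.6f}\n" for i, s in enumerate(scores))
        )
        loaded = read_score_file(path, 40)
        np.testing.assert_allclose(loaded, np.clip(scores, 0, 1), atol=1e-6)
        with pytest.raises(ValueError):
            read_score_file(path, 41)


class TestExtractAll:
    def test_total_length_and_determinism(self, random_record, catalog):
        v1 = extract_all(random_record, catalog)
        v2 = extract_all(random_record, catalog)
        assert v1.values.size == 1276
        assert np.array_equal(v1.values, v2.values)
        assert np.all(np.isfinite(v1.values))

    def test_permutation_preserves_aac_block(self, random_record, catalog, rng):
        shuffled = "".join(rng.permutation(list(random_record.sequence)))
        v1 = extract_all(random_record, catalog).values
        v2 = extract_all(ProteinRecord("perm", shuffled), catalog).values
        np.testing.assert_allclose(v1[:20], v2[:20], atol=1e-12)

    def test_extraction_order_independence(self, catalog, rng):
        records = [
            ProteinRecord(f"r{i}", "".join(rng.choice(list(STANDARD_AA), 60)))
            for i in range(4)
        ]
        forward = {r.id: extract_all(r, catalog).values for r in records}
        backward = {r.id: extract_all(r, catalog).values for r in reversed(records)}
        for rid in forward:
            assert np.array_equal(forward[rid], backward[rid])
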