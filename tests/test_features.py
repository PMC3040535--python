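import numpy as np
import pytest
from Bio.Align import substitution_matrices
from hypothesis import given, settings, strategies as st

from phoskit import KNNConfig, aa_frequencies, knn_scores, window_similarity
from phoskit.core import CandidateSite, Dataset, Label
from phoskit.errors import MissingTrackError
from phoskit.features import (
    DEFAULT_K_FRACTIONS,
    PAD,
    SiteWindow,
    assemble_feature_vector,
    default_disorder_track,
    disorder_feature,
    encode_windows,
    extract_window,
    feature_layout,
    knn_score_matrix,
)

BLOSUM62 = substitution_matrices.load("BLOSUM62")
AA = "ACDEFGHIKLMNPQRSTVWY"


def brute_force_similarity(a: str, b: str) -> float:
    """Independent oracle: per-position dict lookup, pads contribute 0."""
    total = 0.0
    for x, y in zip(a, b):
        if x == PAD or y == PAD:
            continue
        if x in BLOSUM62.alphabet and y in BLOSUM62.alphabet:
            total += float(BLOSUM62[x, y])
    return total


def brute_force_knn(query, ref_peptides, ref_labels, k_fractions, exclude=None):
    """Independent oracle: full sort with (−similarity, index) key, count labels."""
    sims = [
        (-brute_force_similarity(query, pep), i)
        for i, pep in enumerate(ref_peptides)
        if i != exclude
    ]
    sims.sort()
    n = len(sims)
    out = []
    for f in k_fractions:
        k = max(1, round(f * n))
        top = sims[:k]
        out.append(sum(ref_labels[i] for _, i in top) / k)
    return out


def make_dataset(peptides, labels, half_width):
    sites = [
        CandidateSite("P", i + 1, pep[half_width], Label.POSITIVE if l else Label.NEGATIVE)
        for i, (pep, l) in enumerate(zip(peptides, labels))
    ]
    windows = [SiteWindow(pep, half_width) for pep in peptides]
    return Dataset(sites=sites, windows=windows, residue_types=frozenset("STY"),
                   half_width=half_width)


def random_peptides(rng, n, half_width=3):
    length = 2 * half_width + 1
    peps = []
    for _ in range(n):
        chars = [rng.choice(list(AA)) for _ in range(length)]
        left = rng.integers(0, half_width + 1)
        right = rng.integers(0, half_width + 1)
        for i in range(left):
            chars[i] = PAD
        for i in range(right):
            chars[-(i + 1)] = PAD
        peps.append("".join(chars))
    return peps


class TestExtractWindow:
    def test_symmetric_padding(self):
        assert extract_window("MSK", 2, 2).peptide == "-MSK-"

    def test_left_padding(self):
        assert extract_window("MSK", 1, 1).peptide == "-MS"

    def test_center_is_sequence_residue(self):
        for pos in range(1, 4):
            assert extract_window("MSK", pos, 5).center == "MSK"[pos - 1]

    def test_out_of_range_position(self):
        with pytest.raises(IndexError):
            extract_window("MSK", 4, 2)

    def test_window_invariants_rejected(self):
        with pytest.raises(ValueError):
            SiteWindow("--A", 1)  # wrong center? ("-" at center index 1)
        with pytest.raises(ValueError):
            SiteWindow("ABCD", 1)  # wrong length


class TestWindowSimilarity:
    def test_blosum_diagonal_sum(self):
        assert window_similarity("AC", "AC") == 13.0  # A/A=4 + C/C=9

    def test_self_similarity_is_maximal(self):
        # BLOSUM62 diagonal maximality: verified exhaustively over the matrix
        for a in AA:
            for b in AA:
                assert BLOSUM62[a, a] >= BLOSUM62[a, b]
        assert window_similarity("ACD", "ACD") >= window_similarity("ACD", "CDE")

    def test_all_pad_contributes_zero(self):
        assert window_similarity("---", "ACD") == 0.0

    def test_pad_positions_skipped(self):
        assert window_similarity("A-C", "AAC") == float(BLOSUM62["A", "A"] + BLOSUM62["C", "C"])

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            window_similarity("AC", "ACD")

    def test_matches_oracle_on_random_windows(self, rng):
        peps = random_peptides(rng, 30)
        for a in peps[:10]:
            for b in peps[10:20]:
                assert window_similarity(a, b) == brute_force_similarity(a, b)


class TestKnnScores:
    def test_all_neighbors_positive(self):
        peps = ["AASAA", "AASAA", "AASAC", "WWSWW"]
        ds = make_dataset(peps[1:], [True, True, True], half_width=2)
        scores = knn_scores(SiteWindow(peps[0], 2), ds, KNNConfig(k_fractions=(0.4, 1.0)))
        assert np.allclose(scores, 1.0)

    def test_matches_brute_force_small(self, rng):
        peps = random_peptides(rng, 10)
        labels = [bool(b) for b in rng.integers(0, 2, 10)]
        labels[0] = True  # at least one positive
        ds = make_dataset(peps, labels, half_width=3)
        config = KNNConfig(k_fractions=(0.3,), exclude_self=False)
        query = SiteWindow(random_peptides(rng, 1)[0], 3)
        expected = brute_force_knn(query.peptide, peps, labels, (0.3,))
        assert knn_scores(query, ds, config).tolist() == expected

    def test_k_from_fraction(self):
        assert KNNConfig(k_fractions=(0.3,)).k_values(10) == [3]
        assert KNNConfig().k_values(1) == [1] * len(DEFAULT_K_FRACTIONS)

    def test_exclude_self_ignores_own_window(self, rng):
        peps = random_peptides(rng, 8)
        labels = [True] + [False] * 7
        ds = make_dataset(peps, labels, half_width=3)
        config = KNNConfig(k_fractions=(0.14,))  # k=1 of effective 7
        # query identical to the only positive window, excluding it:
        scores = knn_scores(SiteWindow(peps[0], 3), ds, config, self_index=0)
        expected = brute_force_knn(peps[0], peps, labels, (0.14,), exclude=0)
        assert scores.tolist() == expected

    def test_empty_after_self_exclusion(self):
        ds = make_dataset(["ASA"], [True], half_width=1)
        with pytest.raises(ValueError):
            knn_scores(SiteWindow("ASA", 1), ds, KNNConfig(), self_index=0)

    def test_permutation_invariance_with_distinct_similarities(self, rng):
        query = SiteWindow(random_peptides(rng, 1)[0], 3)
        # pick 12 references with pairwise-distinct similarity to the query
        pool = random_peptides(rng, 300)
        peps, seen = [], set()
        for pep in pool:
            sim = brute_force_similarity(query.peptide, pep)
            if sim not in seen:
                seen.add(sim)
                peps.append(pep)
            if len(peps) == 12:
                break
        sims = [brute_force_similarity(query.peptide, p) for p in peps]
        assert len(set(sims)) == len(sims) == 12
        labels = [bool(b) for b in rng.integers(0, 2, 12)]
        config = KNNConfig(k_fractions=(0.25, 0.5), exclude_self=False)
        base = knn_scores(query, make_dataset(peps, labels, 3), config)
        perm = rng.permutation(12)
        shuffled = knn_scores(
            query,
            make_dataset([peps[i] for i in perm], [labels[i] for i in perm], 3),
            config,
        )
        assert base.tolist() == shuffled.tolist()

    def test_tie_break_by_insertion_order(self):
        # two identical reference windows with opposite labels; k=1 must pick
        # the earlier one
        peps = ["AASAA", "AASAA", "WWSWW"]
        q = SiteWindow("AASAA", 2)
        config = KNNConfig(k_fractions=(1 / 3,), exclude_self=False)
        first_pos = knn_scores(q, make_dataset(peps, [True, False, False], 2), config)
        first_neg = knn_scores(q, make_dataset(peps, [False, True, False], 2), config)
        assert first_pos.tolist() == [1.0]
        assert first_neg.tolist() == [0.0]

    def test_batch_matches_single(self, rng):
        peps = random_peptides(rng, 20)
        labels = rng.integers(0, 2, 20).astype(float)
        config = KNNConfig(k_fractions=(0.1, 0.5), exclude_self=False)
        queries = random_peptides(rng, 5)
        batch = knn_score_matrix(encode_windows(queries), encode_windows(peps), labels, config)
        ds = make_dataset(peps, [bool(b) for b in labels], 3)
        for i, q in enumerate(queries):
            single = knn_scores(SiteWindow(q, 3), ds, config)
            assert batch[i].tolist() == single.tolist()


class TestKnnConfigValidation:
    def test_fractions_must_increase(self):
        with pytest.raises(ValueError):
            KNNConfig(k_fractions=(0.5, 0.2))

    def test_fractions_in_unit_interval(self):
        with pytest.raises(ValueError):
            KNNConfig(k_fractions=(0.0, 0.5))
        with pytest.raises(ValueError):
            KNNConfig(k_fractions=(0.5, 1.5))


class TestAaFrequencies:
    def test_single_letter(self):
        freqs = aa_frequencies("AAAA")
        assert freqs[AA.index("A")] == 1.0
        assert freqs.sum() == 1.0

    def test_pads_excluded(self):
        freqs = aa_frequencies("-MS")
        assert freqs[AA.index("M")] == 0.5
        assert freqs[AA.index("S")] == 0.5

    def test_nonstandard_letters_excluded(self):
        freqs = aa_frequencies("XMSU")
        assert freqs[AA.index("M")] == 0.5
        assert freqs[AA.index("S")] == 0.5

    @settings(max_examples=50, deadline=None)
    @given(st.text(alphabet=AA + "XUBZ-", min_size=1, max_size=30))
    def test_sums_to_one_with_any_standard_residue(self, peptide):
        freqs = aa_frequencies(peptide)
        n_standard = sum(c in AA for c in peptide)
        if n_standard:
            assert abs(freqs.sum() - 1.0) < 1e-9
        else:
            assert freqs.sum() == 0.0


class TestDisorder:
    def test_track_length_and_range(self):
        seq = "MSTKWWEEPLKR" * 10
        track = default_disorder_track(seq)
        assert len(track) == len(seq)
        assert all(0.0 <= v <= 1.0 for v in track)

    def test_disorder_promoting_scores_higher(self):
        poly_e = default_disorder_track("E" * 50)
        poly_w = default_disorder_track("W" * 50)
        assert np.mean(poly_e) > np.mean(poly_w)

    def test_empty_sequence(self):
        assert default_disorder_track("") == []

    def test_constant_track_mean(self):
        assert disorder_feature([0.5] * 10, 5, 3) == 0.5

    def test_mean_against_manual_sum(self):
        track = [0.1, 0.2, 0.3, 0.4, 0.5]
        assert disorder_feature(track, 3, 1) == pytest.approx((0.2 + 0.3 + 0.4) / 3)

    def test_clipping_at_sequence_start(self):
        track = [float(i) for i in range(1, 11)]
        assert disorder_feature(track, 1, 5) == pytest.approx(sum(range(1, 7)) / 6)

    def test_missing_track_is_instructive_error(self):
        with pytest.raises(MissingTrackError, match="disorder prediction"):
            disorder_feature(None, 1, 3)


class TestAssembleFeatureVector:
    def test_default_layout_length(self, rng):
        peps = random_peptides(rng, 10, half_width=3)
        ds = make_dataset(peps, [True] * 5 + [False] * 5, 3)
        track = [0.5] * 50
        fv = assemble_feature_vector(SiteWindow(peps[0], 3), ds, KNNConfig(), track, 10)
        assert len(fv.values) == len(DEFAULT_K_FRACTIONS) + 1 + 20
        assert fv.layout == feature_layout(KNNConfig())

    def test_block_order_and_contents(self, rng):
        peps = random_peptides(rng, 10, half_width=3)
        ds = make_dataset(peps, [True] * 5 + [False] * 5, 3)
        config = KNNConfig(k_fractions=(0.5,))
        window = SiteWindow(peps[0], 3)
        fv = assemble_feature_vector(window, ds, config, [0.25] * 50, 10)
        assert fv.block("disorder")[0] == 0.25
        assert np.array_equal(fv.block("aa_freq"), aa_frequencies(window))
        assert np.array_equal(fv.block("knn"), knn_scores(window, ds, config))

    def test_deterministic(self, rng):
        peps = random_peptides(rng, 10, half_width=3)
        ds = make_dataset(peps, [True] * 5 + [False] * 5, 3)
        args = (SiteWindow(peps[0], 3), ds, KNNConfig(), [0.5] * 50, 10)
        a = assemble_feature_vector(*args)
        b = assemble_feature_vector(*args)
        assert a.values.tobytes() == b.values.tobytes()
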