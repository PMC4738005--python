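import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from coelute.profiles import ContractError, ProfileMatrix, QuantKind
from coelute.scoring import (
    PairScoreRecord,
    ScoreParams,
    co_apex,
    euclidean_similarity,
    pearson_plain,
    pearson_poisson_noise,
    read_pair_scores,
    score_experiment,
    weighted_cross_correlation,
    write_pair_scores,
)


def pearson_oracle(u, v):
    """Direct-summation Pearson, independent of numpy vector paths."""
    n = len(u)
    mu = sum(u) / n
    mv = sum(v) / n
    num = sum((a - mu) * (b - mv) for a, b in zip(u, v))
    du = math.sqrt(sum((a - mu) ** 2 for a in u))
    dv = math.sqrt(sum((b - mv) ** 2 for b in v))
    if du == 0 or dv == 0:
        return 0.0
    return num / (du * dv)


def wcc_oracle(x, y, k_max):
    """Independent direct summation over lags."""
    n = len(x)
    num = den = 0.0
    for k in range(-k_max, k_max + 1):
        if k >= 0:
            u, v = x[k:], y[: n - k]
        else:
            u, v = x[: n + k], y[-k:]
        w = 1.0 / (1.0 + abs(k))
        num += w * pearson_oracle(list(u), list(v))
        den += w
    return num / den


class TestPearsonPlain:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ([1, 2, 3], [2, 4, 6], 1.0),
            ([1, 2, 3], [3, 2, 1], -1.0),
            ([5, 5, 5], [1, 2, 3], 0.0),  # zero-variance convention
        ],
    )
    def test_reference_values(self, x, y, expected):
        assert pearson_plain(x, y) == pytest.approx(expected)

    def test_length_mismatch_raises(self):
        with pytest.raises(ContractError):
            pearson_plain([1, 2, 3], [1, 2])


class TestPearsonPoissonNoise:
    def test_r_zero_equals_plain(self, rng):
        params = ScoreParams(noise_reps=0)
        for _ in range(50):
            x = rng.poisson(2.0, size=12)
            y = rng.poisson(2.0, size=12)
            assert pearson_poisson_noise(x, y, params) == pearson_plain(x, y)

    def test_pure_noise_profiles_are_uncorrelated(self):
        params = ScoreParams(noise_reps=1000, noise_pseudocount=1.0, rng_seed=42)
        score = pearson_poisson_noise([0] * 5, [0] * 5, params, pair_key="A|B")
        assert abs(score) <= 0.1

    def test_small_noise_barely_perturbs_perfect_pair(self):
        params = ScoreParams(noise_reps=2000, noise_pseudocount=0.1, rng_seed=42)
        x = [0, 20, 80, 20, 0]
        score = pearson_poisson_noise(x, x, params, pair_key="A|B")
        assert 0.95 <= score <= 1.0

    def test_fixed_seed_is_bit_reproducible(self):
        params = ScoreParams(noise_reps=50, rng_seed=9)
        x, y = [0, 3, 9, 3, 0, 0], [0, 2, 8, 4, 1, 0]
        first = pearson_poisson_noise(x, y, params, pair_key="A|B")
        second = pearson_poisson_noise(x, y, params, pair_key="A|B")
        assert first == second

    def test_non_integer_counts_rejected(self):
        with pytest.raises(ContractError):
            pearson_poisson_noise([1.5, 2, 3], [1, 2, 3], ScoreParams())


class TestWeightedCrossCorrelation:
    def test_k_zero_reduces_to_pearson(self, rng):
        params = ScoreParams(max_lag=0)
        for _ in range(200):
            x = rng.poisson(3.0, size=10).astype(float)
            y = rng.poisson(3.0, size=10).astype(float)
            assert weighted_cross_correlation(x, y, params) == pytest.approx(
                pearson_plain(x, y), abs=1e-15
            )

    def test_shifted_spike_matches_hand_summation(self):
        x = [0, 0, 10, 0, 0, 0]
        y = [0, 0, 0, 10, 0, 0]
        got = weighted_cross_correlation(x, y, ScoreParams(max_lag=1))
        assert got == pytest.approx(wcc_oracle(x, y, 1), abs=1e-12)
        # the matching lag contributes rho = 1 at weight 1/2
        assert wcc_oracle(x, y, 1)  # sanity: oracle itself nonzero

    def test_identical_profiles_bounded_below(self, rng):
        # rho_0 = 1 and every other lag's rho >= -1 bounds WCC from below
        x = rng.permutation(np.arange(1.0, 13.0))
        got = weighted_cross_correlation(x, x, ScoreParams(max_lag=2))
        weights = [1 / (1 + abs(k)) for k in range(-2, 3)]
        w0_share = 1.0 / sum(weights)
        assert got >= w0_share - (1 - w0_share)

    def test_oracle_agreement_on_random_pairs(self, rng):
        for _ in range(50):
            n = int(rng.integers(10, 61))
            k = int(rng.integers(0, 3))
            x = rng.poisson(2.0, size=n).astype(float)
            y = rng.poisson(2.0, size=n).astype(float)
            got = weighted_cross_correlation(x, y, ScoreParams(max_lag=k))
            assert got == pytest.approx(wcc_oracle(list(x), list(y), k), abs=1e-12)

    def test_excessive_lag_raises(self):
        with pytest.raises(ContractError):
            weighted_cross_correlation([1, 2, 3, 4], [1, 2, 3, 4], ScoreParams(max_lag=2))


class TestCoApex:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ([0, 9, 1], [2, 7, 0], 1.0),           # same apex
            ([9, 0, 0, 0], [0, 0, 0, 5], 0.25),    # apex distance 3
            ([5, 5, 1], [9, 0, 0], 1.0),           # tie breaks to earliest index
        ],
    )
    def test_reference_values(self, x, y, expected):
        assert co_apex(x, y) == pytest.approx(expected)

    def test_all_zero_vector_is_missing(self):
        assert co_apex([0, 0, 0], [1, 2, 1]) is None

    @given(st.integers(min_value=1, max_value=50))
    def test_translation_robust_with_unique_apex(self, shift):
        x = [0.0, 1.0, 5.0, 2.0]
        y = [3.0, 1.0, 0.0, 0.0]
        base = co_apex(x, y)
        assert co_apex([v + shift for v in x], [v + shift for v in y]) == base


class TestEuclideanSimilarity:
    def test_identical_profiles_score_one(self):
        assert euclidean_similarity([2, 5, 1], [2, 5, 1]) == pytest.approx(1.0)

    def test_disjoint_one_hots_score_zero(self):
        assert euclidean_similarity([1, 0], [0, 1]) == pytest.approx(0.0)

    def test_closed_form_half_overlap(self):
        got = euclidean_similarity([1, 1, 0, 0], [0, 0, 1, 1])
        assert got == pytest.approx(1 - 1 / math.sqrt(2), abs=1e-12)

    def test_all_zero_vector_is_missing(self):
        assert euclidean_similarity([0, 0], [1, 2]) is None

    @given(st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariant(self, c):
        x = [1.0, 4.0, 2.0, 0.0]
        y = [0.5, 3.0, 3.0, 1.0]
        assert euclidean_similarity([c * v for v in x], y) == pytest.approx(
            euclidean_similarity(x, y), abs=1e-9
        )


def _matrix(ids, rows, kind=QuantKind.MS2_COUNTS, exp="e1"):
    return ProfileMatrix(exp, "human", kind, ids, np.asarray(rows, dtype=float))


class TestScoreExperiment:
    def test_three_overlapping_proteins_give_three_records(self):
        ms2 = _matrix(
            ("A", "B", "C"),
            [[1, 2, 3, 0, 0, 1], [2, 2, 1, 0, 1, 0], [0, 1, 1, 1, 0, 2]],
        )
        records = score_experiment(ms2, None, ScoreParams(noise_reps=0))
        assert len(records) == 3
        assert all(r.euclid_sim is None for r in records)

    def test_disjoint_profiles_are_omitted(self):
        ms2 = _matrix(("A", "B"), [[1, 1, 0, 0, 0, 0], [0, 0, 0, 0, 2, 2]])
        assert score_experiment(ms2, None, ScoreParams(noise_reps=0, min_overlap=1)) == []

    def test_record_count_matches_brute_force_enumeration(self, rng):
        values = rng.poisson(0.8, size=(20, 12)).astype(float)
        ids = tuple(f"P{i:02d}" for i in range(20))
        ms2 = _matrix(ids, values)
        params = ScoreParams(noise_reps=0, min_overlap=2)
        records = score_experiment(ms2, None, params)
        expected = 0
        for i in range(20):
            for j in range(i + 1, 20):
                overlap = int(((values[i] > 0) & (values[j] > 0)).sum())
                expected += overlap >= 2
        assert len(records) == expected

    def test_scores_symmetric_under_row_permutation(self):
        rows = {"B": [0, 3, 9, 3, 0, 1], "A": [1, 2, 8, 4, 0, 0]}
        params = ScoreParams(noise_reps=20, rng_seed=5)
        fwd = score_experiment(_matrix(("A", "B"), [rows["A"], rows["B"]]), None, params)
        rev = score_experiment(_matrix(("B", "A"), [rows["B"], rows["A"]]), None, params)
        assert fwd == rev  # exact, including the Poisson-noise feature

    def test_ms1_feature_missing_when_protein_lacks_ms1(self):
        ms2 = _matrix(
            ("A", "B", "C"),
            [[1, 2, 1, 0, 1, 0], [2, 1, 1, 1, 0, 0], [1, 1, 2, 0, 0, 1]],
        )
        ms1 = _matrix(
            ("A", "B"),
            [[1.0, 2.0, 1.0, 0.0, 0.5, 0.0], [2.0, 1.0, 0.5, 0.5, 0.0, 0.0]],
            kind=QuantKind.MS1_INTENSITY,
        )
        records = {r.pair: r for r in score_experiment(ms2, ms1, ScoreParams(noise_reps=0))}
        assert records[("A", "B")].euclid_sim is not None
        assert records[("A", "C")].euclid_sim is None

    def test_pair_scores_tsv_round_trip(self, tmp_path):
        records = [
            PairScoreRecord("A", "B", "e1", pcc_noise=0.5, wcc=0.25, coapex=1.0, euclid_sim=None),
            PairScoreRecord("A", "C", "e1", pcc_noise=-0.125, wcc=None, coapex=0.5, euclid_sim=0.75),
        ]
        path = tmp_path / "scores.tsv"
        write_pair_scores(records, path)
        assert read_pair_scores(path) == records


def test_co_complex_pairs_score_above_random_pairs(default_world):
    """Monotone separation: simulated co-complex pairs carry higher
    Poisson-noise Pearson scores than random non-complex pairs."""
    from scipy.stats import mannwhitneyu

    world = default_world
    exp = world.experiments[0]
    ids = exp.ms2.protein_ids
    omap = world.ortholog_maps[exp.species].forward_index()
    ref_of = {sp_gene: next(iter(refs)) for sp_gene, refs in omap.items()}
    positives = world.positive_pairs
    params = ScoreParams(noise_reps=20, rng_seed=1)
    rng = np.random.default_rng(0)
    pos_scores, neg_scores = [], []
    idx = {pid: i for i, pid in enumerate(ids)}
    pairs = [(a, b) for i, a in enumerate(ids) for b in ids[i + 1:]]
    rng.shuffle(pairs)
    for a, b in pairs:
        ra, rb = ref_of[a], ref_of[b]
        if ra == rb:
            continue
        x, y = exp.ms2.values[idx[a]], exp.ms2.values[idx[b]]
        if not (np.any(x > 0) and np.any(y > 0)):
            continue
        key = (min(ra, rb), max(ra, rb))
        score = pearson_poisson_noise(x, y, params, pair_key=f"{a}|{b}")
        (pos_scores if key in positives else neg_scores).append(score)
        if len(pos_scores) >= 300 and len(neg_scores) >= 1000:
            break
    assert len(pos_scores) + len(neg_scores) >= 500
    assert np.mean(pos_scores) > np.mean(neg_scores)
    p = mannwhitneyu(pos_scores, neg_scores, alternative="greater").pvalue
    assert p < 0.01
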