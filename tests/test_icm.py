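import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2

from icmhost.errors import ModelStoreError, TrainingError
from icmhost.icm import (
    IcmModel,
    ModelSet,
    conditional_probability,
    load_model_set,
    save_model_set,
    score_sequence,
    train_icm,
    train_model_set,
)
from icmhost.seq_io import SequenceRecord, reverse_complement

# ---------------------------------------------------------------------------
# independent oracles (deliberately naive, dict-based, no numpy)


def sliding_window_counts(texts, k):
    """Brute-force order-k (context, base) counts on forward strands."""
    counts = {}
    for text in texts:
        for i in range(k, len(text)):
            w = text[i - k : i]
            b = text[i]
            if "N" in w or b == "N":
                continue
            counts[(w, b)] = counts.get((w, b), 0) + 1
    return counts


def fixed_order_prob(counts_by_k, k, context, base, alpha):
    """Add-alpha conditional at a single fixed order (no interpolation)."""
    row = [counts_by_k[k].get((context, b), 0) for b in "ACGT"]
    n = sum(row)
    return (counts_by_k[k].get((context, base), 0) + alpha) / (n + 4 * alpha)


def fixed_order_position_logprobs(counts_by_k, K, text, alpha):
    """Per-position fixed-order log-probabilities with the 0->K order ramp."""
    out = []
    for i in range(len(text)):
        k = min(i, K)
        w = text[i - k : i]
        if "N" in w or text[i] == "N":
            out.append(None)
        else:
            out.append(math.log(fixed_order_prob(counts_by_k, k, w, text[i], alpha)))
    return out


# ---------------------------------------------------------------------------
# training


def test_homopolymer_order0_probability():
    m = train_icm([SequenceRecord("g", "A" * 100)], "m", K=0)
    assert m.trained_bases == 100
    assert conditional_probability(m, "", "A") == pytest.approx(101 / 104)


def test_counts_match_bruteforce_sliding_window():
    text = "ACGTACGT"
    m = train_icm([SequenceRecord("g", text)], "m", K=2)
    oracle = sliding_window_counts([text], 2)
    assert oracle[("AC", "G")] == 2
    assert oracle[("GT", "A")] == 1
    for (w, b), n in oracle.items():
        code = sum(4 ** (1 - j) * "ACGT".index(c) for j, c in enumerate(w))
        assert m.counts[2][code, "ACGT".index(b)] == n
    assert m.counts[2].sum() == sum(oracle.values())


def test_n_windows_contribute_nothing():
    m = train_icm([SequenceRecord("g", "ACNGT")], "m", K=1)
    # order-1 windows crossing the N (CN, NG) are dropped
    oracle = sliding_window_counts(["ACNGT"], 1)
    assert m.counts[1].sum() == sum(oracle.values()) == 2
    assert m.trained_bases == 4  # order-0 skips only the N itself


def test_all_n_input_is_a_training_error():
    with pytest.raises(TrainingError):
        train_icm([SequenceRecord("g", "NNNN")], "m", K=2)


def test_node_pooling_trains_one_model_per_taxon(tree):
    recs = [
        (SequenceRecord("g1", "ACGT" * 50), 14),
        (SequenceRecord("g2", "AATT" * 50), 15),
        (SequenceRecord("g3", "GGCC" * 50), 17),
    ]
    ms = train_model_set(recs, pooling="node", pool_rank="genus", tree=tree, K=2)
    assert sorted(m.label_taxid for m in ms) == [13, 16]
    pooled = ms.by_id("taxon_13")
    direct = train_icm([recs[0][0], recs[1][0]], "x", K=2)
    for k in range(3):
        assert (pooled.counts[k] == direct.counts[k]).all()


# ---------------------------------------------------------------------------
# interpolation


@pytest.fixture(scope="module")
def trained_model(rng=np.random.default_rng(11)):
    text = "".join(rng.choice(list("ACGT"), p=[0.4, 0.3, 0.2, 0.1], size=4000))
    return train_icm([SequenceRecord("g", text)], "m", K=4, C=50)


def test_conditional_distributions_sum_to_one(trained_model):
    rng = np.random.default_rng(3)
    for _ in range(200):
        k = int(rng.integers(0, trained_model.max_order + 1))
        ctx = "".join(rng.choice(list("ACGT"), size=k))
        total = sum(conditional_probability(trained_model, ctx, b) for b in "ACGT")
        assert total == pytest.approx(1.0, abs=1e-9)


def test_unseen_context_falls_back_to_lower_order():
    # trained on A/C only, so any context containing G was never observed
    m = train_icm([SequenceRecord("g", "ACAACC" * 30)], "m", K=2, C=10)
    assert m.counts[2][
        4 * "ACGT".index("A") + "ACGT".index("G")
    ].sum() == 0
    for b in "ACGT":
        assert conditional_probability(m, "AG", b) == pytest.approx(
            conditional_probability(m, "G", b), abs=1e-12
        )


def test_lambda_rule_on_toy_counts():
    """Single hand-checked case of the interpolation weight: order-1
    counts (6,2,1,1) after context A, order-0 counts (60,20,10,10)."""
    counts0 = np.array([[60, 20, 10, 10]])
    counts1 = np.zeros((4, 4), dtype=int)
    counts1[0] = [6, 2, 1, 1]
    m = IcmModel("toy", [counts0, counts1], alpha=1.0, count_threshold=400)

    # independent evaluation of the same formulas
    alpha = 1.0
    p0 = (counts0[0] + alpha) / (counts0[0].sum() + 4 * alpha)
    c = counts1[0].astype(float)
    n = c.sum()
    raw1 = (c + alpha) / (n + 4 * alpha)
    stat = (((c - n * p0) ** 2) / (n * p0)).sum()
    d = chi2(df=3).cdf(stat)
    lam = 0.0 if d < 0.5 else min(1.0, d * n / 400)
    expected = lam * raw1 + (1 - lam) * p0

    got = [conditional_probability(m, "A", b) for b in "ACGT"]
    assert got == pytest.approx(list(expected), abs=1e-12)
    # untouched context rows have lambda 0 -> order-0 fallback
    assert conditional_probability(m, "C", "A") == pytest.approx(p0[0])


def test_invalid_symbols_rejected(trained_model):
    with pytest.raises(ValueError):
        conditional_probability(trained_model, "AN", "A")
    with pytest.raises(ValueError):
        conditional_probability(trained_model, "AC", "N")


# ---------------------------------------------------------------------------
# scoring


def test_uniform_model_scores_length_times_log_quarter():
    zero = [np.zeros((4**k, 4), dtype=int) for k in range(4)]
    m = IcmModel("uniform", zero)
    rec = SequenceRecord("q", "ACGTTGCA" * 25)
    res = score_sequence(m, rec)
    assert res.log_likelihood == pytest.approx(200 * math.log(0.25))
    assert res.scored_positions == 200


def test_score_matches_bruteforce_product_saturated_order1():
    # C=1 and every 1-mer context observed => pure fixed-order behaviour
    train = "ACGTTGCAACGGTTCA" * 10
    m = train_icm([SequenceRecord("t", train)], "m", K=1, C=1)
    counts_by_k = {k: sliding_window_counts([train], k) for k in (0, 1)}
    probe = "ACGT"
    fwd = sum(fixed_order_position_logprobs(counts_by_k, 1, probe, 1.0))
    rev = sum(
        fixed_order_position_logprobs(counts_by_k, 1, reverse_complement(probe), 1.0)
    )
    res = score_sequence(m, SequenceRecord("q", probe))
    assert res.log_likelihood == pytest.approx(max(fwd, rev), abs=1e-9)


def test_interpolated_equals_fixed_order_on_saturating_text():
    """With C=1 and a training text containing every context, the
    interpolated scorer must collapse onto a brute-force fixed-order
    Markov scorer with identical add-alpha smoothing (1e-9/position)."""
    K = 3
    train = "".join("".join(p) for p in itertools.product("ACGT", repeat=K + 1))
    m = train_icm([SequenceRecord("t", train)], "m", K=K, C=1)
    counts_by_k = {k: sliding_window_counts([train], k) for k in range(K + 1)}
    rng = np.random.default_rng(5)
    probe = "".join(rng.choice(list("ACGT"), size=200))
    res = score_sequence(m, SequenceRecord("q", probe))
    best = max(
        sum(fixed_order_position_logprobs(counts_by_k, K, s, 1.0))
        for s in (probe, reverse_complement(probe))
    )
    assert res.log_likelihood == pytest.approx(best, abs=1e-9 * len(probe))


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.text(alphabet="ACGTN", min_size=1, max_size=60))
def test_scoring_is_strand_symmetric(trained_model, s):
    a = score_sequence(trained_model, SequenceRecord("q", s))
    b = score_sequence(trained_model, SequenceRecord("q", reverse_complement(s)))
    assert a.log_likelihood == pytest.approx(b.log_likelihood, abs=1e-9)
    assert a.scored_positions == b.scored_positions


def test_skip_counts_are_model_independent(trained_model):
    other = train_icm([SequenceRecord("g", "GGGGCCCC" * 40)], "o", K=4, C=50)
    rec = SequenceRecord("q", "ACGTNNACGTACGNTACG")
    r1 = score_sequence(trained_model, rec)
    r2 = score_sequence(other, rec)
    assert (r1.scored_positions, r1.skipped_positions) == (
        r2.scored_positions,
        r2.skipped_positions,
    )


def test_all_n_record_scores_zero_and_is_flagged(trained_model):
    res = score_sequence(trained_model, SequenceRecord("q", "NNNNN"))
    assert res.log_likelihood == 0.0
    assert res.scored_positions == 0
    assert res.all_skipped


def test_own_composition_scores_higher_than_disjoint():
    """Sequences sampled from a model's training composition must score
    higher, on average over 50 samples, under that model than under one
    trained on composition-disjoint text."""
    rng = np.random.default_rng(21)
    at_text = "".join(rng.choice(list("ACGT"), p=[0.45, 0.05, 0.05, 0.45], size=20000))
    gc_text = "".join(rng.choice(list("ACGT"), p=[0.05, 0.45, 0.45, 0.05], size=20000))
    m_at = train_icm([SequenceRecord("at", at_text)], "at", K=3, C=100)
    m_gc = train_icm([SequenceRecord("gc", gc_text)], "gc", K=3, C=100)
    diffs = []
    for _ in range(50):
        start = int(rng.integers(0, len(at_text) - 500))
        rec = SequenceRecord("s", at_text[start : start + 500])
        diffs.append(
            score_sequence(m_at, rec).log_likelihood
            - score_sequence(m_gc, rec).log_likelihood
        )
    assert np.mean(diffs) > 0


# ---------------------------------------------------------------------------
# persistence


@pytest.fixture
def model_set(trained_model):
    other = train_icm(
        [SequenceRecord("g2", "GGCCGGTT" * 60)], "m2", label_taxid=14, K=4, C=50
    )
    return ModelSet(models=[trained_model, other], kind="reference")


def test_store_roundtrip_preserves_scores(model_set, tmp_path):
    probe = SequenceRecord("p", "ACGTTGCAGGCC" * 10)
    save_model_set(model_set, tmp_path / "store")
    back = load_model_set(tmp_path / "store")
    assert back.kind == "reference"
    for m0, m1 in zip(model_set, back):
        assert m1.model_id == m0.model_id
        assert m1.label_taxid == m0.label_taxid
        assert m1.trained_bases == m0.trained_bases
        s0 = score_sequence(m0, probe).log_likelihood
        s1 = score_sequence(m1, probe).log_likelihood
        assert s1 == s0


def test_empty_model_set_roundtrips(tmp_path):
    save_model_set(ModelSet(models=[], kind="scaffold"), tmp_path / "empty")
    assert len(load_model_set(tmp_path / "empty")) == 0


def test_corrupt_model_file_is_a_load_error(model_set, tmp_path):
    save_model_set(model_set, tmp_path / "store")
    (tmp_path / "store" / "model_00000.npz").write_bytes(b"garbage")
    with pytest.raises(ModelStoreError, match="corrupt"):
        load_model_set(tmp_path / "store")


def test_version_mismatch_is_a_load_error(model_set, tmp_path):
    import json

    save_model_set(model_set, tmp_path / "store")
    mpath = tmp_path / "store" / "manifest.json"
    manifest = json.loads(mpath.read_text())
    manifest["format_version"] = 99
    mpath.write_text(json.dumps(manifest))
    with pytest.raises(ModelStoreError, match="99"):
        load_model_set(tmp_path / "store")


def test_model_set_rejects_mismatched_hyperparameters(trained_model):
    other = train_icm([SequenceRecord("g", "ACGT" * 100)], "x", K=2, C=50)
    with pytest.raises(ValueError, match="share"):
        ModelSet(models=[trained_model, other])
    with pytest.raises(ValueError, match="unique"):
        ModelSet(models=[trained_model, trained_model])
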