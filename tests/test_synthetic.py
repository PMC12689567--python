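"""Generator ground truth: coverage recovery, planted-corpus recovery, fixture checks."""

from fractions import Fraction

import numpy as np
import pytest
from scipy.stats import binom

from pmckit.coding import coverage_rates
from pmckit.engine import evaluate_corpus, evaluate_from_first_level
from pmckit.synthetic import (
    SyntheticCodingConfig,
    SyntheticCorpusConfig,
    generate_coding_matrix,
    generate_corpus,
)
from pmckit.textmine import cooccurrence_network, term_frequencies, tokenize


def test_all_ones_config(schema, scale):
    config = SyntheticCodingConfig(
        n_policies=4, coverage={c: 1.0 for c in schema.secondary_codes}, mode="quota"
    )
    res = evaluate_corpus(generate_coding_matrix(config, schema), schema, scale)
    assert all(c.pmc == 9 for c in res.scorecards)


def test_quota_mode_exact_counts(schema, study):
    config = SyntheticCodingConfig(
        n_policies=22, coverage={c: k / 22 for c, k in study.counts.items()},
        seed=5, mode="quota",
    )
    prof = coverage_rates(generate_coding_matrix(config, schema))
    assert prof.counts == dict(study.counts)


def test_quota_end_to_end_recovers_dimension_averages(schema, scale, study):
    """Evaluating a quota matrix at fixture coverage reproduces the fixture averages."""
    config = SyntheticCodingConfig(
        n_policies=22, coverage={c: k / 22 for c, k in study.counts.items()},
        seed=9, mode="quota",
    )
    res = evaluate_corpus(generate_coding_matrix(config, schema), schema, scale)
    ref = evaluate_from_first_level(study.scores_thirds, scale)
    assert res.dimension_averages == ref.dimension_averages
    assert res.average_pmc == ref.average_pmc


def test_stochastic_coverage_within_ci(schema):
    p = 0.45
    n = 2000
    config = SyntheticCodingConfig(
        n_policies=n, coverage={c: p for c in schema.secondary_codes}, seed=1
    )
    prof = coverage_rates(generate_coding_matrix(config, schema))
    lo, hi = binom.ppf([0.005, 0.995], n, p)
    counts = np.array(list(prof.counts.values()))
    # 27 columns, each inside the central 99% binomial interval with high probability
    assert (counts >= lo).mean() > 0.9 and (counts <= hi).mean() > 0.9


def test_stochastic_ci_coverage_over_seeds(schema):
    """Over 100 seeds at n = 500, ~99% of empirical counts fall in the 99% CI."""
    p, n = 0.45, 500
    lo, hi = binom.ppf([0.005, 0.995], n, p)
    code = schema.secondary_codes[0]
    inside = 0
    for seed in range(100):
        config = SyntheticCodingConfig(
            n_policies=n, coverage={c: p for c in schema.secondary_codes}, seed=seed
        )
        matrix = generate_coding_matrix(config, schema)
        j = matrix.indicator_codes.index(code)
        k = matrix.values[:, j].sum()
        inside += int(lo <= k <= hi)
    assert inside >= 94


def test_invalid_configs_rejected(schema):
    with pytest.raises(ValueError):
        SyntheticCodingConfig(n_policies=0, coverage={})
    with pytest.raises(ValueError):
        SyntheticCodingConfig(n_policies=2, coverage={"X1-1": 1.5})
    with pytest.raises(ValueError):
        generate_coding_matrix(
            SyntheticCodingConfig(n_policies=2, coverage={"X1-1": 0.5}), schema
        )


def test_corpus_recovery_exact():
    config = SyntheticCorpusConfig(
        term_frequencies={"alpha": 5, "beta": 4, "gamma": 2},
        planted_pairs=[("alpha", "beta", 3)],
        seed=17,
    )
    docs, ledger = generate_corpus(config)
    corpus = [tokenize(d) for d in docs]
    freqs = term_frequencies(corpus).set_index("term")["frequency"].to_dict()
    assert freqs == ledger["term_frequencies"]
    g = cooccurrence_network(corpus)
    assert g["alpha"]["beta"]["weight"] == 3
    assert set(ledger["doc_cooccurrence"]) == {("alpha", "beta")}
    assert not g.has_edge("alpha", "gamma")


def test_corpus_single_term_single_doc():
    docs, _ = generate_corpus(SyntheticCorpusConfig(term_frequencies={"t": 5}))
    corpus = [tokenize(d) for d in docs]
    assert term_frequencies(corpus)["frequency"].tolist() == [5]


def test_corpus_order_invariance():
    config = dict(term_frequencies={"a": 3, "b": 2}, planted_pairs=[("a", "b", 2)])
    t1 = term_frequencies(
        [tokenize(d) for d in generate_corpus(SyntheticCorpusConfig(**config, seed=1))[0]]
    )
    t2 = term_frequencies(
        [tokenize(d) for d in generate_corpus(SyntheticCorpusConfig(**config, seed=2))[0]]
    )
    assert t1.equals(t2)  # shuffled document order leaves global counts unchanged


def test_corpus_unrealizable_rejected():
    with pytest.raises(ValueError, match="remain"):
        generate_corpus(
            SyntheticCorpusConfig(
                term_frequencies={"a": 1, "b": 5}, planted_pairs=[("a", "b", 2)]
            )
        )
    with pytest.raises(ValueError, match="n_documents"):
        generate_corpus(
            SyntheticCorpusConfig(term_frequencies={"a": 2, "b": 2},
                                  planted_pairs=[("a", "b", 2)], n_documents=1)
        )


def test_fixture_self_checks(study):
    assert study.total_ones == 415
    assert study.average_pmc == Fraction(415, 66)
    assert study.counts["X6-1"] == 8 and study.counts["X6-2"] == 8 and study.counts["X6-3"] == 14
    # P11 row as exact thirds
    assert study.scores_thirds.loc["P11"].tolist() == [2, 3, 3, 2, 3, 2, 3, 3, 3]
    assert study.imputed == {"X8-1", "X8-2"}
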