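"""Synthetic data generators with known ground truth.

Every pipeline stage is testable without external data: coding matrices
are generated with specified per-indicator coverage (either exact quotas
or independent Bernoulli draws), and token corpora are constructed with
planted term frequencies and document co-occurrences, returned together
with the ground-truth ledger the generator guarantees.

A single integer seed governs all randomness; generated artifacts record
it so runs are reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .coding import CodingMatrix
from .schema import IndicatorSchema, default_schema
from .textmine import Document

__all__ = [
    "SyntheticCodingConfig",
    "SyntheticCorpusConfig",
    "generate_coding_matrix",
    "generate_corpus",
]


@dataclass(frozen=True)
class SyntheticCodingConfig:
    """Coverage-controlled binary coding matrix.

    ``mode='quota'`` places exactly round(p_j x n) ones per column via a
    seeded permutation of policies (coverage recovered exactly);
    ``mode='stochastic'`` draws independent Bernoulli(p_j) cells (coverage
    recovered in distribution).
    """

    n_policies: int
    coverage: Mapping[str, float]  # secondary code -> probability in [0, 1]
    seed: int = 0
    mode: str = "stochastic"

    def __post_init__(self) -> None:
        if self.n_policies < 1:
            raise ValueError("n_policies must be >= 1")
        if self.mode not in ("stochastic", "quota"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for code, p in self.coverage.items():
            if not 0.0 <= float(p) <= 1.0:
                raise ValueError(f"coverage probability for {code} outside [0, 1]: {p}")


def generate_coding_matrix(
    config: SyntheticCodingConfig, schema: IndicatorSchema | None = None
) -> CodingMatrix:
    """Generate a policies x indicators binary matrix per the config."""
    schema = schema or default_schema()
    codes = schema.secondary_codes
    missing = [c for c in codes if c not in config.coverage]
    if missing:
        raise ValueError(f"coverage missing for secondaries: {missing}")
    rng = np.random.default_rng(config.seed)
    n = config.n_policies
    values = np.zeros((n, len(codes)), dtype=np.int8)
    for j, code in enumerate(codes):
        p = float(config.coverage[code])
        if config.mode == "stochastic":
            values[:, j] = rng.random(n) < p
        else:
            k = int(round(p * n))
            rows = rng.permutation(n)[:k]
            values[rows, j] = 1
    policy_ids = tuple(f"S{i + 1}" for i in range(n))
    return CodingMatrix(policy_ids=policy_ids, indicator_codes=tuple(codes), values=values)


@dataclass(frozen=True)
class SyntheticCorpusConfig:
    """Token corpus with planted term frequencies and document co-occurrences.

    Each planted pair (a, b, c) occupies c dedicated documents containing
    one occurrence of a and one of b, so the document-level co-occurrence
    weight of (a, b) is exactly c.  Remaining frequency mass of each term
    (target frequency minus its pair placements) goes into single-term
    documents, which leave co-occurrences untouched.
    """

    term_frequencies: Mapping[str, int]
    planted_pairs: Sequence[tuple[str, str, int]] = ()
    n_documents: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for term, f in self.term_frequencies.items():
            if f < 0:
                raise ValueError(f"negative frequency for {term!r}")
        seen = set()
        for a, b, c in self.planted_pairs:
            if a == b:
                raise ValueError(f"planted pair ({a!r}, {b!r}) is not a pair")
            key = tuple(sorted((a, b)))
            if key in seen:
                raise ValueError(f"planted pair {key} listed twice")
            seen.add(key)
            if c < 1:
                raise ValueError(f"planted pair {key} needs count >= 1")


def generate_corpus(
    config: SyntheticCorpusConfig,
) -> tuple[list[Document], dict]:
    """Construct documents realising the config exactly; return the ledger.

    The ledger records the ground truth the construction guarantees:
    ``term_frequencies`` (exact raw token counts after the default
    tokenizer/filters) and ``doc_cooccurrence`` (exact document-level
    co-occurrence weight per planted pair; all other pairs are 0).
    Raises ``ValueError`` if the config is unrealizable (pair placements
    exceed a term's target frequency, or documents exceed ``n_documents``).
    """
    remaining = dict(config.term_frequencies)
    docs: list[list[str]] = []
    for a, b, c in config.planted_pairs:
        for term in (a, b):
            if remaining.get(term, 0) < c:
                raise ValueError(
                    f"term {term!r} needs {c} occurrences for pair ({a}, {b}) "
                    f"but only {remaining.get(term, 0)} remain"
                )
        for _ in range(c):
            docs.append([a, b])
        remaining[a] -= c
        remaining[b] -= c
    for term, f in remaining.items():
        if f > 0:
            docs.append([term] * f)
    if config.n_documents is not None:
        if len(docs) > config.n_documents:
            raise ValueError(
                f"config requires {len(docs)} documents but n_documents="
                f"{config.n_documents}"
            )
        docs.extend([] for _ in range(config.n_documents - len(docs)))
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(docs))
    documents = [
        Document(id=f"D{i + 1}", text=" ".join(docs[k])) for i, k in enumerate(order)
    ]
    ledger = {
        "seed": config.seed,
        "term_frequencies": {t: f for t, f in config.term_frequencies.items() if f > 0},
        "doc_cooccurrence": {
            tuple(sorted((a, b))): c for a, b, c in config.planted_pairs
        },
    }
    return documents, ledger
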