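"""Text-mining front end: tokenization, stop-word filtering, term
frequencies, co-occurrence networks, word-cloud data export.

This stage assists — it does not replace — the human content-analysis step
that produces the binary coding matrix: ranked term frequencies and the
co-occurrence ("semantic") network summarise what a policy corpus talks
about before criteria are coded.

Tokenization is pluggable.  The default plugin segments on Unicode
word boundaries (whitespace/punctuation), protects multi-word lexicon
terms from being split, and drops tokens containing digits outright.  A
Chinese word segmenter (e.g. jieba with a custom medical lexicon) can be
registered under its own plugin id::

    import jieba
    register_tokenizer("jieba", lambda text: jieba.lcut(text))
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "Document",
    "register_tokenizer",
    "tokenize",
    "load_stoplist",
    "filter_stopwords",
    "term_frequencies",
    "cooccurrence_network",
    "export_wordcloud_data",
]


@dataclass(frozen=True)
class Document:
    id: str
    text: str


_TOKENIZERS: dict[str, Callable[[str], list[str]]] = {}


def register_tokenizer(plugin_id: str, fn: Callable[[str], list[str]]) -> None:
    """Register a segmentation plugin: text -> raw token list."""
    _TOKENIZERS[plugin_id] = fn


def _unicode_segment(text: str) -> list[str]:
    return re.findall(r"\w+", text, flags=re.UNICODE)


register_tokenizer("unicode", _unicode_segment)

_HAS_DIGIT = re.compile(r"\d")


def tokenize(
    doc: Document | str,
    lexicon: Sequence[str] = (),
    tokenizer: str = "unicode",
    casefold: bool = True,
) -> list[str]:
    """Segment a document into filtered tokens.

    Protected ``lexicon`` terms (matched longest-first, case-insensitively
    when ``casefold``) are never split by the segmenter.  Punctuation and
    special characters separate tokens; any token containing a digit is
    dropped wholesale rather than stripped (partial stripping would invent
    tokens that never occurred).
    """
    try:
        segment = _TOKENIZERS[tokenizer]
    except KeyError as exc:
        raise KeyError(
            f"unknown tokenizer plugin {tokenizer!r}; registered: {sorted(_TOKENIZERS)}"
        ) from exc
    text = doc.text if isinstance(doc, Document) else doc
    flags = re.IGNORECASE if casefold else 0
    tokens: list[str] = []

    def emit(segment_text: str) -> None:
        for tok in segment(segment_text):
            if _HAS_DIGIT.search(tok):
                continue
            tokens.append(tok.casefold() if casefold else tok)

    if lexicon:
        pattern = "|".join(
            re.escape(term) for term in sorted(lexicon, key=len, reverse=True)
        )
        pos = 0
        for m in re.finditer(pattern, text, flags=flags):
            emit(text[pos : m.start()])
            term = m.group(0)
            tokens.append(term.casefold() if casefold else term)
            pos = m.end()
        emit(text[pos:])
    else:
        emit(text)
    return tokens


def load_stoplist(path: str | Path) -> set[str]:
    """Plain-text stop-word list, one word per line; blank lines ignored."""
    words = Path(path).read_text(encoding="utf-8").splitlines()
    return {w.strip() for w in words if w.strip()}


def filter_stopwords(
    tokens: Iterable[str],
    *stoplists: Iterable[str],
    casefold: bool = True,
) -> list[str]:
    """Drop tokens found in the union of the stop-word lists."""
    stop = set()
    for sl in stoplists:
        stop.update(w.casefold() if casefold else w for w in sl)
    if casefold:
        return [t for t in tokens if t.casefold() not in stop]
    return [t for t in tokens if t not in stop]


def term_frequencies(
    corpus: Sequence[Sequence[str]],
    top_k: int | None = None,
    per_document: bool = False,
) -> pd.DataFrame:
    """Ranked global term counts: columns rank, term, frequency.

    ``per_document=True`` counts each term at most once per document
    (document frequency) instead of raw token occurrences.  Ties in
    frequency are broken lexicographically so the ranking is deterministic.
    """
    if top_k is not None and top_k < 1:
        raise ValueError("top_k must be >= 1")
    counts: Counter[str] = Counter()
    for tokens in corpus:
        counts.update(set(tokens) if per_document else tokens)
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    if top_k is not None:
        ordered = ordered[:top_k]
    return pd.DataFrame(
        [
            {"rank": i, "term": term, "frequency": freq}
            for i, (term, freq) in enumerate(ordered, start=1)
        ],
        columns=["rank", "term", "frequency"],
    )


def cooccurrence_network(
    corpus: Sequence[Sequence[str]],
    window: int | str = "document",
    min_weight: int = 1,
) -> nx.Graph:
    """Undirected term co-occurrence graph.

    Edge weight = number of documents (``window='document'``) or of sliding
    token windows of the given size in which both terms appear.  Edges with
    weight below ``min_weight`` are pruned; nodes keep their total term
    frequency as attribute ``frequency``.
    """
    if isinstance(window, int) and window < 1:
        raise ValueError("window must be >= 1 or 'document'")
    node_freq: Counter[str] = Counter()
    pair_weight: Counter[tuple[str, str]] = Counter()
    for tokens in corpus:
        node_freq.update(tokens)
        if window == "document":
            groups: Iterable[Sequence[str]] = [tokens]
        else:
            groups = [tokens[i : i + window] for i in range(max(1, len(tokens) - window + 1))]
        for group in groups:
            uniq = sorted(set(group))
            for a_i, a in enumerate(uniq):
                for b in uniq[a_i + 1 :]:
                    pair_weight[(a, b)] += 1
    graph = nx.Graph()
    for term, freq in node_freq.items():
        graph.add_node(term, frequency=freq)
    for (a, b), w in pair_weight.items():
        if w >= min_weight:
            graph.add_edge(a, b, weight=w)
    return graph


def export_wordcloud_data(table: pd.DataFrame, path: str | Path) -> None:
    """Write (term, weight) CSV for external word-cloud rendering."""
    out = table.rename(columns={"frequency": "weight"})[["term", "weight"]]
    out.to_csv(path, index=False)
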