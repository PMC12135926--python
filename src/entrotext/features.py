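"""Word and POS n-gram distributions and the six Shannon-entropy features.

For a stream of L units the n-grams are the L − n + 1 contiguous windows,
taken across the whole (truncated) stream with no sentence-boundary resets
or padding. With type frequencies f(i) and total N = Σ f(i), the relative
frequencies are p(i) = f(i)/N and the plug-in (maximum-likelihood) Shannon
entropy is

    H = − Σ_i p(i) · log2 p(i)      [bits]

No bias correction is applied: documents are compared at a fixed window
length, so the estimator's downward bias is shared across classes and the
plain plug-in form keeps H interpretable as the empirical average
information content of the window.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from entrotext.annotate import (
    DEFAULT_TRUNCATE_LIMIT,
    TagStream,
    TokenStream,
    default_tagger,
    pos_tag,
    tokenize,
    truncate_stream,
)
from entrotext.corpus import Corpus

logger = logging.getLogger(__name__)

#: Fixed feature order used everywhere (tables, coefficient tie-breaks).
FEATURE_COLUMNS: tuple[str, ...] = (
    "word_h1", "word_h2", "word_h3", "pos_h1", "pos_h2", "pos_h3",
)


@dataclass
class NGramDistribution:
    """Frequency distribution of the n-grams of one stream.

    ``total`` is N = Σ f(i) = stream length − n + 1; ``n_types`` is the
    number of distinct n-gram types.
    """

    unit: str  # "word" or "pos"
    n: int
    counts: dict[tuple[str, ...], int]
    total: int

    @property
    def n_types(self) -> int:
        return len(self.counts)


@dataclass
class EntropyFeatureVector:
    """The six per-document entropies, in bits."""

    doc_id: str
    class_label: str
    word_h1: float
    word_h2: float
    word_h3: float
    pos_h1: float
    pos_h2: float
    pos_h3: float

    def as_row(self) -> dict[str, object]:
        return {
            "doc_id": self.doc_id,
            "class_label": self.class_label,
            **{name: getattr(self, name) for name in FEATURE_COLUMNS},
        }


def extract_ngrams(stream: Sequence[str], n: int, unit: str = "word") -> NGramDistribution:
    """Count the contiguous n-grams of an ordered stream.

    Rejects streams shorter than n, for which the feature is undefined.
    """
    if n < 1:
        raise ValueError(f"gram order must be >= 1, got {n}")
    length = len(stream)
    if length < n:
        raise ValueError(
            f"stream of length {length} has no {n}-grams (need length >= {n})"
        )
    counts = Counter(tuple(stream[i : i + n]) for i in range(length - n + 1))
    return NGramDistribution(unit=unit, n=n, counts=dict(counts), total=length - n + 1)


def relative_frequencies(dist: NGramDistribution) -> dict[tuple[str, ...], float]:
    """p(i) = f(i)/N for every type; the values sum to 1."""
    if dist.total < 1 or not dist.counts:
        raise ValueError("empty distribution has no relative frequencies")
    return {gram: count / dist.total for gram, count in dist.counts.items()}


def shannon_entropy(probabilities: Mapping[object, float]) -> float:
    """Plug-in Shannon entropy H = −Σ p log2 p of a normalized distribution.

    Requires Σp = 1 within 1e-9 and every p > 0; returns bits.
    """
    if not probabilities:
        raise ValueError("empty probability map")
    p = np.fromiter(probabilities.values(), dtype=float)
    if np.any(p <= 0.0):
        raise ValueError("all probabilities must be > 0")
    total = p.sum()
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"probabilities sum to {total!r}, not 1")
    return float(-(p * np.log2(p)).sum())


def stream_entropy(stream: Sequence[str], n: int, unit: str = "word") -> float:
    """Entropy of the n-gram distribution of a stream, in bits."""
    return shannon_entropy(relative_frequencies(extract_ngrams(stream, n, unit)))


def compute_features(tokens: TokenStream, tags: TagStream) -> EntropyFeatureVector:
    """All six entropies for one annotated document.

    The streams must be paired (equal length, already truncated) and long
    enough for tri-grams.
    """
    if len(tokens.tokens) != len(tags.tags):
        raise ValueError(
            f"document {tokens.doc_id!r}: unpaired streams "
            f"({len(tokens.tokens)} tokens, {len(tags.tags)} tags)"
        )
    if len(tokens.tokens) < 3:
        raise ValueError(
            f"document {tokens.doc_id!r}: length {len(tokens.tokens)} < 3, "
            "tri-gram entropy undefined"
        )
    h = {}
    for n in (1, 2, 3):
        h[f"word_h{n}"] = stream_entropy(tokens.tokens, n, "word")
        h[f"pos_h{n}"] = stream_entropy(tags.tags, n, "pos")
    return EntropyFeatureVector(doc_id=tokens.doc_id, class_label="", **h)


def build_feature_table(
    corpus: Corpus,
    tagger=None,
    truncate_limit: int = DEFAULT_TRUNCATE_LIMIT,
    drop_short: bool = False,
    on_error: str = "raise",
) -> pd.DataFrame:
    """One feature row per document of a corpus.

    Documents already carrying token/tag streams (synthetic corpora, sidecar
    tag files) are used as-is after truncation; raw-text documents are
    tokenized and tagged with ``tagger`` (default: the built-in rule-based
    tagger with the coarse tagset). ``on_error="skip"`` logs and drops
    documents whose annotation or features fail instead of raising.
    """
    if on_error not in ("raise", "skip"):
        raise ValueError(f"on_error must be 'raise' or 'skip', got {on_error!r}")
    if tagger is None:
        tagger = default_tagger(coarse=True)

    rows: list[dict[str, object]] = []
    for doc in corpus:
        try:
            if doc.tokens is not None and doc.tags is not None:
                tok = TokenStream(doc.doc_id, list(doc.tokens))
                tag = TagStream(doc.doc_id, list(doc.tags))
            else:
                tok = tokenize(doc.raw_text, doc.doc_id)
                tag = pos_tag(tok, tagger)
            tok, tag = truncate_stream(tok, tag, limit=truncate_limit)
            if drop_short and tok.short_text_flag:
                logger.info("dropping short document %s (%d tokens)",
                            doc.doc_id, len(tok.tokens))
                continue
            vec = compute_features(tok, tag)
            vec.class_label = doc.class_label
            rows.append(vec.as_row())
        except (ValueError, KeyError) as exc:
            if on_error == "raise":
                raise ValueError(f"document {doc.doc_id!r}: {exc}") from exc
            logger.warning("skipping document %s: %s", doc.doc_id, exc)
    return pd.DataFrame(rows, columns=["doc_id", "class_label", *FEATURE_COLUMNS])
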