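"""Tokenization, POS tagging, coarse tagset mapping and stream truncation.

Word tokens are case-folded and punctuation-only tokens are excluded before
any counting; hyphen- and dash-joined compounds (``china–u.s.``) stay single
tokens. Both choices are required for consistency of relative frequencies:
type counts over a 22-token sentence only come out right when ``The`` and
``the`` merge and commas are dropped.

The tagger is an injected callable ``tokens -> tags`` so that a deterministic
fixture (or a sidecar tag file) can stand in for automatic tagging. The
built-in default is :class:`RuleBasedTagger`, a lexicon-plus-suffix tagger
emitting Penn-Treebank-style tags, normally composed with the coarse
:data:`PENN_TO_COARSE` mapping.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

DEFAULT_TRUNCATE_LIMIT = 500

# A "core" is a plain alphanumeric run or an abbreviation with internal
# periods (u.s., e.g.); cores may be joined by hyphens/dashes/apostrophes
# into one compound token. Trailing sentence punctuation never attaches.
_ABBR = r"[A-Za-z0-9]+(?:\.[A-Za-z0-9]+)+\.?"
_PLAIN = r"[A-Za-z0-9]+"
_CORE = rf"(?:{_ABBR}|{_PLAIN})"
_JOIN = "[-‐‑‒–—'’]"
_TOKEN_RE = re.compile(rf"{_CORE}(?:{_JOIN}{_CORE})*")


@dataclass
class TokenStream:
    """Ordered, case-folded word tokens of one document."""

    doc_id: str
    tokens: list[str]
    short_text_flag: bool = False

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass
class TagStream:
    """Ordered POS tags paired position-by-position with a TokenStream."""

    doc_id: str
    tags: list[str]

    def __len__(self) -> int:
        return len(self.tags)


#: Default mapping from Penn-Treebank-style tags to the coarse categories
#: used throughout (Det, Num, Noun, Aux, Verb, Adj, Prep, Conj, Pron, Adv,
#: Part, Other). Any tag outside the table maps to "Other" when the mapping
#: is applied with ``strict=False`` (the default for the full Penn set).
PENN_TO_COARSE: dict[str, str] = {
    "DT": "Det", "PDT": "Det", "WDT": "Det",
    "CD": "Num",
    "NN": "Noun", "NNS": "Noun", "NNP": "Noun", "NNPS": "Noun",
    "MD": "Aux",
    "VB": "Verb", "VBD": "Verb", "VBG": "Verb", "VBN": "Verb",
    "VBP": "Verb", "VBZ": "Verb",
    "JJ": "Adj", "JJR": "Adj", "JJS": "Adj",
    "IN": "Prep",
    "CC": "Conj",
    "PRP": "Pron", "PRP$": "Pron", "WP": "Pron", "WP$": "Pron", "EX": "Pron",
    "RB": "Adv", "RBR": "Adv", "RBS": "Adv", "WRB": "Adv",
    "RP": "Part", "TO": "Part", "POS": "Part",
    "UH": "Other", "FW": "Other", "SYM": "Other", "LS": "Other",
}


def tokenize(raw_text: str, doc_id: str = "") -> TokenStream:
    """Split raw text into case-folded word tokens.

    Punctuation-only tokens are discarded; abbreviations keep their internal
    (and trailing) periods; dash/hyphen/apostrophe compounds stay joined.
    Empty input yields an empty stream. Idempotent on space-joined output.
    """
    tokens = [m.group(0).lower() for m in _TOKEN_RE.finditer(raw_text)]
    return TokenStream(doc_id=doc_id, tokens=tokens)


def pos_tag(
    tokens: TokenStream,
    tagger: Callable[[Sequence[str]], Sequence[str]],
) -> TagStream:
    """Tag a token stream with an injected deterministic tagger.

    The tagger maps the token sequence to exactly one tag per token; a
    wrong-length return is rejected rather than silently realigned.
    """
    if not tokens.tokens:
        raise ValueError(f"document {tokens.doc_id!r}: cannot tag an empty stream")
    tags = list(tagger(tokens.tokens))
    if len(tags) != len(tokens.tokens):
        raise ValueError(
            f"document {tokens.doc_id!r}: tagger returned {len(tags)} tags "
            f"for {len(tokens.tokens)} tokens"
        )
    return TagStream(doc_id=tokens.doc_id, tags=tags)


def map_to_coarse(
    tags: TagStream,
    mapping: Mapping[str, str] | None = None,
    strict: bool = True,
) -> TagStream:
    """Map fine-grained tags to coarse categories.

    With ``strict=True`` a tag outside the mapping's domain is an error that
    names the tag; with ``strict=False`` it falls back to ``"Other"``.
    """
    if mapping is None:
        mapping = PENN_TO_COARSE
    out: list[str] = []
    for tag in tags.tags:
        if tag in mapping:
            out.append(mapping[tag])
        elif strict:
            raise KeyError(f"tag {tag!r} is not in the tagset mapping")
        else:
            out.append("Other")
    return TagStream(doc_id=tags.doc_id, tags=out)


def truncate_stream(
    tokens: TokenStream,
    tags: TagStream,
    limit: int = DEFAULT_TRUNCATE_LIMIT,
) -> tuple[TokenStream, TagStream]:
    """Keep the first ``limit`` aligned positions of both streams.

    Documents shorter than the limit are kept whole with
    ``short_text_flag=True`` so callers can apply a drop-short policy.
    """
    if limit < 1:
        raise ValueError(f"truncation limit must be >= 1, got {limit}")
    if len(tokens.tokens) != len(tags.tags):
        raise ValueError(
            f"document {tokens.doc_id!r}: unpaired streams "
            f"({len(tokens.tokens)} tokens, {len(tags.tags)} tags)"
        )
    short = len(tokens.tokens) < limit
    return (
        TokenStream(tokens.doc_id, tokens.tokens[:limit], short_text_flag=short),
        TagStream(tags.doc_id, tags.tags[:limit]),
    )


# --- default tagger -------------------------------------------------------

_CLOSED_CLASS: dict[str, str] = {
    # determiners
    "the": "DT", "a": "DT", "an": "DT", "this": "DT", "that": "DT",
    "these": "DT", "those": "DT", "each": "DT", "every": "DT", "some": "DT",
    "any": "DT", "no": "DT", "all": "PDT", "both": "PDT", "which": "WDT",
    # numbers (small closed set; digits are handled by pattern)
    "one": "CD", "two": "CD", "three": "CD", "four": "CD", "five": "CD",
    "six": "CD", "seven": "CD", "eight": "CD", "nine": "CD", "ten": "CD",
    "first": "JJ", "second": "JJ", "third": "JJ",
    # modals / auxiliaries
    "will": "MD", "would": "MD", "can": "MD", "could": "MD", "may": "MD",
    "might": "MD", "shall": "MD", "should": "MD", "must": "MD",
    "is": "VBZ", "are": "VBP", "was": "VBD", "were": "VBD", "be": "VB",
    "been": "VBN", "being": "VBG", "has": "VBZ", "have": "VBP", "had": "VBD",
    "do": "VBP", "does": "VBZ", "did": "VBD",
    # prepositions / subordinators
    "of": "IN", "in": "IN", "on": "IN", "at": "IN", "by": "IN", "for": "IN",
    "with": "IN", "from": "IN", "into": "IN", "over": "IN", "under": "IN",
    "between": "IN", "through": "IN", "during": "IN", "about": "IN",
    "against": "IN", "after": "IN", "before": "IN", "as": "IN", "than": "IN",
    "if": "IN", "because": "IN", "while": "IN", "since": "IN",
    # conjunctions
    "and": "CC", "or": "CC", "but": "CC", "nor": "CC", "yet": "CC", "so": "CC",
    # pronouns
    "i": "PRP", "you": "PRP", "he": "PRP", "she": "PRP", "it": "PRP",
    "we": "PRP", "they": "PRP", "me": "PRP", "him": "PRP", "her": "PRP",
    "us": "PRP", "them": "PRP", "who": "WP", "what": "WP", "there": "EX",
    "my": "PRP$", "your": "PRP$", "his": "PRP$", "its": "PRP$",
    "our": "PRP$", "their": "PRP$",
    # particles / adverbs
    "to": "TO", "not": "RB", "also": "RB", "very": "RB", "only": "RB",
    "more": "RBR", "most": "RBS", "now": "RB", "then": "RB", "here": "RB",
    "when": "WRB", "where": "WRB", "how": "WRB", "why": "WRB",
    "other": "JJ", "various": "JJ", "such": "JJ", "many": "JJ", "few": "JJ",
    "new": "JJ", "own": "JJ", "same": "JJ",
}

_SUFFIX_RULES: tuple[tuple[str, str], ...] = (
    ("ing", "VBG"),
    ("edly", "RB"),
    ("ly", "RB"),
    ("ed", "VBD"),
    ("ies", "NNS"),
    ("es", "NNS"),
    ("ss", "NN"),
    ("s", "NNS"),
    ("ful", "JJ"),
    ("able", "JJ"),
    ("ible", "JJ"),
    ("al", "JJ"),
    ("ive", "JJ"),
    ("ous", "JJ"),
    ("ic", "JJ"),
    ("ment", "NN"),
    ("ness", "NN"),
    ("tion", "NN"),
    ("sion", "NN"),
    ("ity", "NN"),
    ("er", "NN"),
    ("or", "NN"),
)

_NUMERIC_RE = re.compile(r"^\d+([.,]\d+)*$")


@dataclass
class RuleBasedTagger:
    """Deterministic lexicon + suffix tagger emitting Penn-style tags.

    Closed-class words are looked up directly; open-class words fall through
    ordered suffix rules and default to ``NN``. Coverage is deliberately
    shallow — it provides a reproducible annotation path for English text
    when no external tagger is supplied, and any injected tagger (or sidecar
    tag file) takes precedence in the pipeline.
    """

    lexicon: dict[str, str] = field(default_factory=lambda: dict(_CLOSED_CLASS))

    def __call__(self, tokens: Sequence[str]) -> list[str]:
        return [self._tag_one(tok) for tok in tokens]

    def _tag_one(self, token: str) -> str:
        if token in self.lexicon:
            return self.lexicon[token]
        if _NUMERIC_RE.match(token):
            return "CD"
        for suffix, tag in _SUFFIX_RULES:
            if len(token) > len(suffix) + 2 and token.endswith(suffix):
                return tag
        return "NN"


def default_tagger(coarse: bool = True) -> Callable[[Sequence[str]], list[str]]:
    """The built-in tagger, optionally composed with the coarse mapping."""
    base = RuleBasedTagger()
    if not coarse:
        return base

    def tag(tokens: Sequence[str]) -> list[str]:
        return [PENN_TO_COARSE.get(t, "Other") for t in base(tokens)]

    return tag
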