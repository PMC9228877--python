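"""Automatic labelling of pathway communities from member names.

Pathway names in MSigDB-style collections encode their content as
underscore-separated tokens (e.g. ``GOBP_CARBOHYDRATE_METABOLIC_PROCESS``).
After dropping the database identifier and stop words, the most common
contiguous 3-token sequence across a community's members — supported by
at least three members — makes a good human-readable label. Ties are
broken by the average hubness of the supporting pathways (labels should
reflect the community's central members), then lexicographically for
determinism. If no 3-mer has enough support the procedure falls back to
2-mers, then 1-mers, then 1-mers without the support floor — the last
two rungs extend the chain so that even very small communities receive
a label.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

#: leading tokens recognised as database identifiers and dropped
DATABASE_IDENTIFIERS = frozenset({"kegg", "reactome", "gobp", "gomf", "go", "hallmark"})

_SPLIT = re.compile(r"[\s_]+")


@dataclass(frozen=True)
class LabelCandidate:
    """A ranked n-gram label: token tuple, member support, mean hubness."""

    tokens: tuple[str, ...]
    count: int
    mean_hubness: float

    def __str__(self) -> str:
        return " ".join(self.tokens)


def load_stopwords(path: str | Path | None = None) -> frozenset[str]:
    """Load a stop-word list (one word per line, ``#`` comments allowed).

    With no path, the package's default list is used.
    """
    if path is None:
        text = resources.files("pathcom").joinpath("data/stopwords.txt").read_text()
    else:
        text = Path(path).read_text()
    words = set()
    for line in text.splitlines():
        word = line.strip().lower()
        if word and not word.startswith("#"):
            words.add(word)
    return frozenset(words)


def tokenize_name(name: str, stopwords: Iterable[str] | None = None) -> list[str]:
    """Tokenise a pathway name: split on underscores/whitespace, lower-case,
    drop a leading database identifier, remove stop words.

    May return an empty list.
    """
    if not name:
        raise ValueError("empty pathway name")
    if stopwords is None:
        stopwords = load_stopwords()
    stop = {w.lower() for w in stopwords}
    tokens = [t.lower() for t in _SPLIT.split(name) if t]
    if tokens and tokens[0] in DATABASE_IDENTIFIERS:
        tokens = tokens[1:]
    return [t for t in tokens if t not in stop]


def _ngram_support(
    token_lists: Mapping[str, Sequence[str]], n: int
) -> dict[tuple[str, ...], list[str]]:
    """Map each contiguous n-gram to the names supporting it (once per name)."""
    support: dict[tuple[str, ...], list[str]] = {}
    for name, tokens in token_lists.items():
        seen: set[tuple[str, ...]] = set()
        for i in range(len(tokens) - n + 1):
            gram = tuple(tokens[i : i + n])
            if gram not in seen:
                seen.add(gram)
                support.setdefault(gram, []).append(name)
    return support


def label_community(
    names: Sequence[str],
    hubness_scores: Mapping[str, float] | None = None,
    min_count: int = 3,
    stopwords: Iterable[str] | None = None,
) -> list[LabelCandidate]:
    """Rank label candidates for one community from its member pathway names.

    Returns the full ranked candidate list (the top item is *the*
    label), ordered by (support count desc, mean hubness of supporting
    pathways desc, tokens lexicographically asc). Each pathway supports
    a given n-gram at most once however often it repeats in the name.
    """
    if not names:
        raise ValueError("cannot label a community with no member names")
    if hubness_scores is None:
        hubness_scores = {}
    if stopwords is None:
        stopwords = load_stopwords()
    token_lists = {name: tokenize_name(name, stopwords) for name in names}

    def rank(support: dict[tuple[str, ...], list[str]], floor: int) -> list[LabelCandidate]:
        cands = [
            LabelCandidate(
                tokens=gram,
                count=len(members),
                mean_hubness=(
                    sum(hubness_scores.get(m, 0.0) for m in members) / len(members)
                ),
            )
            for gram, members in support.items()
            if len(members) >= floor
        ]
        cands.sort(key=lambda c: (-c.count, -c.mean_hubness, c.tokens))
        return cands

    for n in (3, 2, 1):
        ranked = rank(_ngram_support(token_lists, n), min_count)
        if ranked:
            return ranked
    # no n-gram reaches the floor: fall back to unfloored 1-mers
    return rank(_ngram_support(token_lists, 1), 1)


def label_all_communities(
    members_by_community: Mapping[int, Sequence[str]],
    hubness_scores: Mapping[str, float] | None = None,
    min_count: int = 3,
    stopwords: Iterable[str] | None = None,
    top_k: int = 10,
) -> dict[int, list[LabelCandidate]]:
    """Top ``top_k`` label candidates for every community."""
    return {
        c: label_community(list(names), hubness_scores, min_count, stopwords)[:top_k]
        for c, names in members_by_community.items()
    }
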