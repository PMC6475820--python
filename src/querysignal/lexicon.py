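"""Concept lexicons and dictionary-based phrase matching.

A lexicon maps canonical concept ids (e.g. ``diarrhea``) to synonym phrases
(``loose stools``).  Matching is word-boundary phrase matching on normalized
query text: a synonym matches iff it occurs as a contiguous word sequence,
so "flu" does not fire inside "fluent".  Each concept is reported at most
once per query; when several synonyms of the same concept cover overlapping
spans, the longest phrase is recorded.

The on-disk format is TSV ``concept_id<TAB>synonym`` (one synonym per line,
``#`` comment lines ignored); every concept id is implicitly its own synonym.
The package ships small demonstration lexicons; full-scale symptom/condition
lists are supplied by the user in the same format.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from querysignal.ingest import normalize_text

__all__ = [
    "Lexicon",
    "ConceptMatch",
    "LexiconError",
    "load_lexicon",
    "match_concepts",
    "match_concept_ids_bulk",
    "packaged_lexicon_path",
]

CATEGORIES = ("symptom", "condition", "indicator", "recipe")


class LexiconError(RuntimeError):
    """Fatal problem loading a lexicon file."""


@dataclass(frozen=True)
class ConceptMatch:
    """One concept found in one query."""

    concept_id: str
    category: str
    phrase: str


@dataclass
class Lexicon:
    """Canonical concept ids with synonym phrase lists, for one category."""

    category: str
    entries: dict[str, list[str]]
    _index: dict[str, str] = field(init=False, repr=False)
    _max_words: int = field(init=False, repr=False)

    def __post_init__(self) -> None:
        index: dict[str, str] = {}
        max_words = 1
        for cid, phrases in self.entries.items():
            for phrase in phrases:
                if not phrase:
                    raise LexiconError(f"empty synonym phrase for concept {cid!r}")
                if phrase != normalize_text(phrase):
                    raise LexiconError(
                        f"synonym {phrase!r} of {cid!r} is not in normalized form"
                    )
                prev = index.get(phrase)
                if prev is not None and prev != cid:
                    raise LexiconError(
                        f"synonym {phrase!r} maps to both {prev!r} and {cid!r}"
                    )
                index[phrase] = cid
                max_words = max(max_words, phrase.count(" ") + 1)
        self._index = index
        self._max_words = max_words

    @property
    def concept_ids(self) -> list[str]:
        return sorted(self.entries)

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self.entries

    def __len__(self) -> int:
        return len(self.entries)


def load_lexicon(path: str | Path, category: str) -> Lexicon:
    """Load a ``concept_id<TAB>synonym`` TSV into a :class:`Lexicon`.

    Raises :class:`LexiconError` on an empty file or when one synonym maps
    to two different concepts.
    """
    if category not in CATEGORIES:
        raise ValueError(f"unknown lexicon category {category!r}; expected one of {CATEGORIES}")
    path = Path(path)
    entries: dict[str, list[str]] = {}
    try:
        text = path.read_text(encoding="utf-8")
    except OSError as exc:
        raise LexiconError(f"cannot read lexicon {path}: {exc}") from exc
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise LexiconError(f"{path}:{lineno}: expected 2 tab-separated columns")
        cid_raw, synonym = parts
        cid = normalize_text(cid_raw)
        if not cid:
            raise LexiconError(f"{path}:{lineno}: empty concept id")
        phrases = entries.setdefault(cid, [])
        if cid not in phrases:
            phrases.append(cid)  # a concept id is implicitly its own synonym
        phrase = normalize_text(synonym)
        if phrase and phrase not in phrases:
            phrases.append(phrase)
    if not entries:
        raise LexiconError(f"lexicon {path} contains no entries")
    return Lexicon(category=category, entries=entries)


def match_concepts(norm_text: str, lexicon: Lexicon) -> set[ConceptMatch]:
    """Match normalized query text against a lexicon.

    Scans every word n-gram of the query (up to the lexicon's longest phrase)
    and looks it up in the synonym index, which enforces the word-boundary
    rule by construction.  Returns each matching concept once, carrying the
    longest synonym that matched.
    """
    words = norm_text.split()
    if not words:
        return set()
    index = lexicon._index
    best: dict[str, str] = {}
    max_n = min(lexicon._max_words, len(words))
    for n in range(1, max_n + 1):
        for i in range(len(words) - n + 1):
            phrase = " ".join(words[i : i + n])
            cid = index.get(phrase)
            if cid is not None and (cid not in best or len(phrase) > len(best[cid])):
                best[cid] = phrase
    return {
        ConceptMatch(concept_id=cid, category=lexicon.category, phrase=phrase)
        for cid, phrase in best.items()
    }


def match_concept_ids_bulk(
    norm_texts: pd.Series,
    lexicon: Lexicon,
    cache: dict[str, frozenset[str]] | None = None,
) -> pd.Series:
    """Concept-id frozensets for a text Series, memoized over unique texts.

    Query logs repeat the same surface forms heavily, so matching each
    distinct text once is a large constant-factor saving.  Pass a ``cache``
    dict to share the memo across calls.
    """
    if cache is None:
        cache = {}
    for text in pd.unique(norm_texts):
        if text not in cache:
            cache[text] = frozenset(m.concept_id for m in match_concepts(text, lexicon))
    return norm_texts.map(cache)


def packaged_lexicon_path(name: str) -> Path:
    """Path to one of the demonstration data files shipped with the package."""
    ref = resources.files("querysignal").joinpath("data", name)
    return Path(str(ref))
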