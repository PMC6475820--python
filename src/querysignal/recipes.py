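"""Recipe-query detection, ingredient mapping, and dietary-shift ranking.

Recipe searches proxy what people actually cook, so comparing dish queries
in the 14 days before the first CRQ with the 14 days after it reveals
short-term dietary shifts (e.g. toward gluten-free baking).  A query counts
as a recipe query when a dish synonym matches at word boundaries and either
a recipe-intent cue ("recipe", "how to make", "bake", ...) is present or
the dish synonym itself has at least two words.  Dish counts propagate to
the ingredients of the matched dish, so ingredient counts are a linear
function of dish counts through the recipe→ingredient incidence structure.

The change score is the smoothed log-ratio ``log((n_after + 0.5) /
(n_before + 0.5))`` — positive for dishes queried more after the index
event, antisymmetric under swapping the windows, and finite at zero counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from querysignal.cohort import CohortMember
from querysignal.ingest import LogSpan, normalize_text
from querysignal.signal import WindowSpec, _infer_span, _user_groups

__all__ = [
    "RecipeMap",
    "RecipeMapError",
    "FoodChangeResult",
    "FoodChangeTable",
    "load_recipe_map",
    "detect_recipe_query",
    "rank_food_changes",
]

#: Single-word recipe-intent cues; "how to make" is handled as a phrase.
_INTENT_WORDS = frozenset({"recipe", "recipes", "bake", "baking", "cook", "cooking"})
_INTENT_PHRASE = "how to make"


class RecipeMapError(RuntimeError):
    """Fatal problem loading a recipe→ingredient map."""


@dataclass
class RecipeMap:
    """Dishes with synonym phrases and ingredient lists.

    ``recipes`` maps dish id → synonym phrase list (normalized; the id's own
    normalized form included); ``ingredients`` maps dish id → ingredient id
    list (every dish has at least one; ingredient ids are shared across
    dishes).
    """

    recipes: dict[str, list[str]]
    ingredients: dict[str, list[str]]
    _index: dict[str, str] = field(init=False, repr=False)
    _max_words: int = field(init=False, repr=False)

    def __post_init__(self) -> None:
        index: dict[str, str] = {}
        max_words = 1
        for rid, phrases in self.recipes.items():
            if not self.ingredients.get(rid):
                raise RecipeMapError(f"recipe {rid!r} has no ingredients")
            for phrase in phrases:
                prev = index.get(phrase)
                if prev is not None and prev != rid:
                    raise RecipeMapError(f"synonym {phrase!r} maps to both {prev!r} and {rid!r}")
                index[phrase] = rid
                max_words = max(max_words, phrase.count(" ") + 1)
        self._index = index
        self._max_words = max_words

    @property
    def recipe_ids(self) -> list[str]:
        return sorted(self.recipes)

    @property
    def ingredient_ids(self) -> list[str]:
        return sorted({i for ings in self.ingredients.values() for i in ings})


def load_recipe_map(path: str | Path) -> RecipeMap:
    """Load a recipe map from TSV.

    Each line is ``recipe_id`` TAB synonym fields TAB ``|`` TAB ingredient
    fields — a literal ``|`` field separates synonyms from ingredients.
    ``#`` comment lines are ignored.  Synonyms and ingredients are
    normalized on load.
    """
    path = Path(path)
    try:
        text = path.read_text(encoding="utf-8")
    except OSError as exc:
        raise RecipeMapError(f"cannot read recipe map {path}: {exc}") from exc
    recipes: dict[str, list[str]] = {}
    ingredients: dict[str, list[str]] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if "|" not in parts:
            raise RecipeMapError(f"{path}:{lineno}: missing '|' separator field")
        sep = parts.index("|")
        if sep < 1:
            raise RecipeMapError(f"{path}:{lineno}: missing recipe id")
        rid = parts[0].strip()
        syns = [normalize_text(p) for p in parts[1:sep] if normalize_text(p)]
        ings = [normalize_text(p) for p in parts[sep + 1 :] if normalize_text(p)]
        own = normalize_text(rid.replace("_", " "))
        if own and own not in syns:
            syns.insert(0, own)
        if not ings:
            raise RecipeMapError(f"{path}:{lineno}: recipe {rid!r} has no ingredients")
        recipes[rid] = syns
        ingredients[rid] = ings
    if not recipes:
        raise RecipeMapError(f"recipe map {path} contains no entries")
    return RecipeMap(recipes=recipes, ingredients=ingredients)


def detect_recipe_query(norm_text: str, recipes: RecipeMap) -> str | None:
    """Return the dish id a query searches a recipe for, or None.

    A dish synonym must match at word boundaries, and the query must either
    contain a recipe-intent cue or match a multi-word dish synonym.  When
    several synonyms match, the longest wins (ties by dish id).
    """
    words = norm_text.split()
    if not words:
        return None
    index = recipes._index
    candidates: list[tuple[int, str, str]] = []
    max_n = min(recipes._max_words, len(words))
    for n in range(1, max_n + 1):
        for i in range(len(words) - n + 1):
            phrase = " ".join(words[i : i + n])
            rid = index.get(phrase)
            if rid is not None:
                candidates.append((n, phrase, rid))
    if not candidates:
        return None
    has_intent = bool(_INTENT_WORDS & set(words)) or f" {_INTENT_PHRASE} " in f" {norm_text} "
    eligible = [c for c in candidates if has_intent or c[0] >= 2]
    if not eligible:
        return None
    eligible.sort(key=lambda c: (-c[0], c[2]))
    return eligible[0][2]


@dataclass(frozen=True)
class FoodChangeResult:
    """Pooled before/after counts and change score for one dish or ingredient."""

    item_id: str
    item_kind: str  # "food" or "ingredient"
    n_before: int
    n_after: int

    @property
    def change_score(self) -> float:
        return math.log((self.n_after + 0.5) / (self.n_before + 0.5))


@dataclass
class FoodChangeTable:
    """Ranked increased/decreased lists for foods and ingredients."""

    foods: list[FoodChangeResult]
    ingredients: list[FoodChangeResult]
    foods_increased: list[FoodChangeResult]
    foods_decreased: list[FoodChangeResult]
    ingredients_increased: list[FoodChangeResult]
    ingredients_decreased: list[FoodChangeResult]


def _rank(results: list[FoodChangeResult], top_k: int, descending: bool) -> list[FoodChangeResult]:
    sign = -1.0 if descending else 1.0
    ranked = sorted(
        results,
        key=lambda r: (sign * r.change_score, -(r.n_before + r.n_after), r.item_id),
    )
    return ranked[:top_k]


def rank_food_changes(
    members: list[CohortMember],
    records: pd.DataFrame,
    recipes: RecipeMap,
    window: WindowSpec = WindowSpec(),
    min_support: int = 10,
    top_k: int = 10,
    span: LogSpan | None = None,
) -> FoodChangeTable:
    """Pool dish and ingredient counts across members' windows and rank shifts.

    Uses complete-windows truncation (members whose windows spill over the
    log span are dropped).  Items with fewer than ``min_support`` total
    counts are excluded; "increased" is the top-k by change score
    descending, "decreased" the top-k ascending, ties broken by larger
    total count then lexicographic id.
    """
    if span is None and not records.empty:
        span = _infer_span(records)
    groups = _user_groups(records)
    nb_food: dict[str, int] = {}
    na_food: dict[str, int] = {}
    cache: dict[str, str | None] = {}
    for member in members:
        if span is not None and not window.is_complete(member.t0, span):
            continue
        sub = groups.get(member.user_id)
        if sub is None:
            continue
        ts = sub["timestamp"]
        t0 = member.t0
        lo, hi = t0 - window.delta, t0 + window.delta
        in_any = (ts >= lo) & (ts <= hi) & (ts != t0)
        if not in_any.any():
            continue
        win = sub.loc[in_any.to_numpy()]
        for t, text in zip(win["timestamp"], win["norm_text"]):
            if text not in cache:
                cache[text] = detect_recipe_query(text, recipes)
            rid = cache[text]
            if rid is None:
                continue
            bucket = nb_food if t < t0 else na_food
            bucket[rid] = bucket.get(rid, 0) + 1

    foods = [
        FoodChangeResult(rid, "food", nb_food.get(rid, 0), na_food.get(rid, 0))
        for rid in recipes.recipe_ids
    ]
    nb_ing: dict[str, int] = {}
    na_ing: dict[str, int] = {}
    for rid in recipes.recipe_ids:
        for ing in recipes.ingredients[rid]:
            nb_ing[ing] = nb_ing.get(ing, 0) + nb_food.get(rid, 0)
            na_ing[ing] = na_ing.get(ing, 0) + na_food.get(rid, 0)
    ingredients = [
        FoodChangeResult(ing, "ingredient", nb_ing[ing], na_ing[ing])
        for ing in recipes.ingredient_ids
    ]

    foods_kept = [r for r in foods if r.n_before + r.n_after >= min_support]
    ings_kept = [r for r in ingredients if r.n_before + r.n_after >= min_support]
    return FoodChangeTable(
        foods=foods,
        ingredients=ingredients,
        foods_increased=_rank(foods_kept, top_k, descending=True),
        foods_decreased=_rank(foods_kept, top_k, descending=False),
        ingredients_increased=_rank(ings_kept, top_k, descending=True),
        ingredients_decreased=_rank(ings_kept, top_k, descending=False),
    )
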