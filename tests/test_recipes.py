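"""Recipe detection, ingredient inheritance, and dietary-shift ranking."""

import math

import pandas as pd
import pytest

from querysignal.cohort import CohortMember
from querysignal.recipes import (
    FoodChangeResult,
    RecipeMap,
    RecipeMapError,
    detect_recipe_query,
    load_recipe_map,
    rank_food_changes,
)
from querysignal.signal import WindowSpec
from conftest import SPAN_2017, make_log


def test_demo_map_contents(recipe_map):
    for dish in ["gluten_free_pie_crust", "gluten_free_pancakes", "cucumber_salad",
                 "honey_cake", "tuna_noodle_casserole", "roasted_pumpkin_seeds",
                 "cinnamon_rolls", "pumpkin_soup", "pumpkin_muffins"]:
        assert dish in recipe_map.recipes
    for ing in ["xanthan gum", "bean flour", "all purpose flour", "dark rum",
                "serrano chile", "gelatin", "sunflower seeds", "anisette", "gin"]:
        assert ing in recipe_map.ingredient_ids
    for rid in recipe_map.recipes:
        assert recipe_map.ingredients[rid]


@pytest.mark.parametrize(
    "text,expected",
    [
        ("gluten free banana bread recipe", "gluten_free_banana_bread"),
        ("banana prices", None),
        ("how to make cucumber salad", "cucumber_salad"),
        ("cucumber salad", "cucumber_salad"),        # >= 2-word dish synonym suffices
        ("ratatouille", None),                       # 1-word dish without an intent cue
        ("ratatouille recipe", "ratatouille"),
        ("baking gluten free pancakes", "gluten_free_pancakes"),
    ],
)
def test_detect_recipe_query(text, expected, recipe_map):
    assert detect_recipe_query(text, recipe_map) == expected


def test_longest_synonym_wins():
    rmap = RecipeMap(
        recipes={"banana_bread": ["banana bread"],
                 "gluten_free_banana_bread": ["gluten free banana bread"]},
        ingredients={"banana_bread": ["flour"], "gluten_free_banana_bread": ["rice flour"]},
    )
    assert detect_recipe_query("gluten free banana bread recipe", rmap) == "gluten_free_banana_bread"


def test_recipe_without_ingredients_fatal(tmp_path):
    p = tmp_path / "r.tsv"
    p.write_text("toast\tbuttered toast\t|\t\n", encoding="utf-8")
    with pytest.raises(RecipeMapError):
        load_recipe_map(p)


def test_change_score_formula_and_signs():
    up = FoodChangeResult("x", "food", 0, 20)
    assert up.change_score == pytest.approx(math.log(20.5 / 0.5))
    flat = FoodChangeResult("y", "food", 7, 7)
    assert flat.change_score == 0.0


def _member(uid, t0):
    return CohortMember(user_id=uid, t0=pd.Timestamp(t0), interest="sustained",
                        crq_day_count=2, indicator_positive=False, self_identified=False)


def _shift_log():
    rows = [("u1", "2017-01-05T10:00:00", "history filler")]
    t0 = "2017-06-15T12:00:00"
    # before: 6x pasta salad; after: 2x pasta salad, 8x gluten-free pancakes
    for i in range(6):
        rows.append(("u1", f"2017-06-0{i+2}T10:00:00", "pasta salad recipe"))
    for i in range(2):
        rows.append(("u1", f"2017-06-2{i}T10:00:00", "pasta salad recipe"))
    for i in range(8):
        rows.append(("u1", f"2017-06-1{6 + i % 4}T1{i}:00:00", "gluten free pancakes recipe"))
    return make_log(rows), [_member("u1", t0)]


def test_rank_food_changes_counts_and_inheritance(recipe_map):
    df, members = _shift_log()
    table = rank_food_changes(members, df, recipe_map, WindowSpec(14), min_support=2,
                              top_k=5, span=SPAN_2017)
    foods = {r.item_id: r for r in table.foods}
    assert (foods["pasta_salad"].n_before, foods["pasta_salad"].n_after) == (6, 2)
    assert (foods["gluten_free_pancakes"].n_before, foods["gluten_free_pancakes"].n_after) == (0, 8)
    assert table.foods_increased[0].item_id == "gluten_free_pancakes"
    assert table.foods_decreased[0].item_id == "pasta_salad"
    # ingredient counts inherit linearly through the recipe->ingredient structure
    ings = {r.item_id: r for r in table.ingredients}
    # pasta appears in pasta_salad and tuna_noodle_casserole (0 counts)
    assert (ings["pasta"].n_before, ings["pasta"].n_after) == (6, 2)
    # xanthan gum is in every gluten-free dish; only pancakes were queried
    assert ings["xanthan gum"].n_after == 8


def test_ingredient_counts_match_bruteforce(recipe_map):
    df, members = _shift_log()
    table = rank_food_changes(members, df, recipe_map, WindowSpec(14), min_support=1,
                              top_k=10, span=SPAN_2017)
    food_nb = {r.item_id: r.n_before for r in table.foods}
    food_na = {r.item_id: r.n_after for r in table.foods}
    for ing in table.ingredients:
        nb = sum(food_nb[rid] for rid in recipe_map.recipes
                 if ing.item_id in recipe_map.ingredients[rid])
        na = sum(food_na[rid] for rid in recipe_map.recipes
                 if ing.item_id in recipe_map.ingredients[rid])
        assert (ing.n_before, ing.n_after) == (nb, na)


def test_swapping_windows_negates_scores(recipe_map):
    df, members = _shift_log()
    table = rank_food_changes(members, df, recipe_map, WindowSpec(14), min_support=1,
                              top_k=10, span=SPAN_2017)
    # swap by mirroring every timestamp around t0
    t0 = members[0].t0
    df2 = df.copy()
    df2["timestamp"] = t0 + (t0 - df2["timestamp"])
    df2 = df2.sort_values(["user_id", "timestamp"], kind="stable", ignore_index=True)
    from datetime import date
    from querysignal.ingest import LogSpan

    mirrored_span = LogSpan(date(2017, 1, 1), date(2017, 12, 31))
    table2 = rank_food_changes(members, df2, recipe_map, WindowSpec(14), min_support=1,
                               top_k=10, span=mirrored_span)
    s1 = {r.item_id: r.change_score for r in table.foods}
    s2 = {r.item_id: r.change_score for r in table2.foods}
    for rid in s1:
        assert s1[rid] == pytest.approx(-s2[rid])
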