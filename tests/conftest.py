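from datetime import date

import pandas as pd
import pytest

from querysignal.ingest import LogSpan, records_to_dataframe, QueryRecord, normalize_text
from querysignal.lexicon import load_lexicon, packaged_lexicon_path
from querysignal.recipes import load_recipe_map

SPAN_2017 = LogSpan(date(2017, 1, 1), date(2017, 10, 31))


@pytest.fixture(scope="session")
def symptom_lexicon():
    return load_lexicon(packaged_lexicon_path("symptoms.tsv"), "symptom")


@pytest.fixture(scope="session")
def condition_lexicon():
    return load_lexicon(packaged_lexicon_path("conditions.tsv"), "condition")


@pytest.fixture(scope="session")
def recipe_map():
    return load_recipe_map(packaged_lexicon_path("recipes.tsv"))


def make_log(rows):
    """Build a log frame from (user, iso_timestamp, text[, zip]) tuples."""
    records = []
    for row in rows:
        user, ts, text = row[:3]
        zip_code = row[3] if len(row) > 3 else ""
        records.append(
            QueryRecord(
                user_id=user,
                timestamp=pd.Timestamp(ts).floor("s").to_pydatetime(),
                raw_text=text,
                norm_text=normalize_text(text),
                zip_code=zip_code,
            )
        )
    return records_to_dataframe(records)
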