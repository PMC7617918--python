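"""Example mapping of a deposited survey export onto the package's schema.

Public Delphi deposits (e.g. data-service or Dryad archives) ship as wide
spreadsheets whose exact column layout varies by study.  This sketch shows
the transformation they typically need: pick out the item-rating columns,
normalise 'unsure'-style tokens, and split demographics into the metadata
CSV.  It is a documented starting point, NOT tested against any specific
archive layout — edit the column lists to match the export in hand.

Usage:
    python examples/map_archive_export.py raw_export.csv ratings.csv meta.csv
"""

import sys

import pandas as pd

RATING_PREFIX = "item_"          # columns holding Likert ratings
ID_COLUMN = "respondent_id"
META_COLUMNS = {                  # export column -> package schema column
    "sex": "gender",
    "age": "age_years",
    "profession": "role_raw",
    "experience_years": "years_experience",
    "country_of_residence": "country",
}
UNSURE_TOKENS = {"unsure", "no opinion", "don't know", "n/a", ""}


def main(raw_path: str, ratings_out: str, meta_out: str) -> None:
    raw = pd.read_csv(raw_path, dtype=str, keep_default_na=False)

    rating_cols = [c for c in raw.columns if c.startswith(RATING_PREFIX)]
    ratings = raw[[ID_COLUMN, *rating_cols]].rename(
        columns={ID_COLUMN: "participant_id"}
    )
    for col in rating_cols:  # blank out any 'unsure'-style token
        ratings[col] = ratings[col].where(
            ~ratings[col].str.strip().str.lower().isin(UNSURE_TOKENS), ""
        )
    ratings.to_csv(ratings_out, index=False)

    meta = raw[[ID_COLUMN, *META_COLUMNS]].rename(
        columns={ID_COLUMN: "participant_id", **META_COLUMNS}
    )
    meta.to_csv(meta_out, index=False)
    print(f"{len(ratings)} participants, {len(rating_cols)} items -> {ratings_out}, {meta_out}")


if __name__ == "__main__":
    main(*sys.argv[1:4])
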