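"""Country-level comparison of mapped versus reported primary-forest area.

The combined extent (documented + potential, overlaps already resolved in
favor of documented upstream) is compared against externally reported
country areas.  The combination exists only for this comparison; all
indicator computations keep the two statuses separate.

Caveat carried through to the output: the forest definitions behind the mask
and behind reported statistics differ, so differences mix real mapping gaps
with definitional mismatch.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .geodata import DOCUMENTED, POTENTIAL


def combined_area(polygon_df: pd.DataFrame) -> pd.DataFrame:
    """Documented + potential forest area (ha) per country, plus a Europe total.

    ``polygon_df`` is the overlay polygon table (one row per polygon with
    ``country``, ``status``, ``forest_area_ha``).
    """
    pivot = (
        polygon_df.groupby(["country", "status"])["forest_area_ha"].sum().unstack(fill_value=0.0)
    )
    for col in (DOCUMENTED, POTENTIAL):
        if col not in pivot:
            pivot[col] = 0.0
    out = pivot.reset_index()[["country", DOCUMENTED, POTENTIAL]]
    out.columns = ["country", "documented_ha", "potential_ha"]
    out["combined_ha"] = out["documented_ha"] + out["potential_ha"]
    total = pd.DataFrame(
        [{
            "country": "EUROPE",
            "documented_ha": out["documented_ha"].sum(),
            "potential_ha": out["potential_ha"].sum(),
            "combined_ha": out["combined_ha"].sum(),
        }]
    )
    return pd.concat([out.sort_values("country"), total], ignore_index=True)


def discrepancy(combined: pd.DataFrame, reported: pd.DataFrame) -> pd.DataFrame:
    """Difference and ratio of combined mapped area against reported area.

    ``difference_ha = combined - reported``; ``ratio_pct = 100 * combined /
    reported`` (null where reported is zero, with the row flagged).
    Countries present on only one side are kept with the other side null.
    """
    rep = reported.rename(columns={"reported_area_ha": "reported_ha"})[["country", "reported_ha"]]
    merged = combined.merge(rep, on="country", how="outer")
    merged["difference_ha"] = merged["combined_ha"] - merged["reported_ha"]
    merged["ratio_pct"] = np.where(
        merged["reported_ha"] > 0,
        100.0 * merged["combined_ha"] / merged["reported_ha"],
        np.nan,
    )
    merged["flag"] = ""
    merged.loc[merged["reported_ha"].isna(), "flag"] = "unreported"
    merged.loc[merged["combined_ha"].isna(), "flag"] = "unmapped"
    merged.loc[(merged["reported_ha"] == 0) & (merged["combined_ha"] > 0), "flag"] = "zero-reported"
    return merged
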