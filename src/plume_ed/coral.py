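"""Colony condition-score panels: scale, fate rules, exclusions, exceedance.

Tagged colonies are photographed roughly fortnightly and each photograph is
scored for the proportion of the surface covered by sediment (and, for
massive Porites, by mucous sheets) on a 7-category scale:

    1 = 0%, 2 = 1-5%, 3 = 6-33%, 4 = 34-65%, 5 = 66-95%, 6 = 96-99%, 7 = 100%

Because the printed bands are integer-valued, non-integer covers fall in the
half-open band (previous upper, upper]; e.g. 5.5% is category 3.

Fate of covered tissue follows the photographic-sequence rule: a covered
episode whose sediment is eventually washed off revealing live tissue is
'live' throughout; if the sediment stays to the end of the record, or its
removal reveals dead tissue, the tissue is 'dead' from the first covered
day of that episode.  Dislodged colonies are removed from all analyses,
including their earlier observations.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "SCORE_BANDS",
    "score_from_percent",
    "band_from_score",
    "classify_fate",
    "exclude_dislodged",
    "site_exceedance",
]

#: category -> (lower, upper] percent-cover band; category 1 is exactly 0%
SCORE_BANDS: dict[int, tuple[float, float]] = {
    1: (0.0, 0.0),
    2: (0.0, 5.0),
    3: (5.0, 33.0),
    4: (33.0, 65.0),
    5: (65.0, 95.0),
    6: (95.0, 99.0),
    7: (99.0, 100.0),
}

_UPPER_EDGES = np.array([0.0, 5.0, 33.0, 65.0, 95.0, 99.0, 100.0])


def score_from_percent(percent_cover: float) -> int:
    """Map a percent cover in [0, 100] to its 1-7 category."""
    p = float(percent_cover)
    if not 0.0 <= p <= 100.0:
        raise ValueError(f"percent cover {p} outside [0, 100]")
    if p == 0.0:
        return 1
    # half-open bands (prev_upper, upper], category 2 starts above 0
    return int(np.searchsorted(_UPPER_EDGES, p, side="left")) + 1


def band_from_score(score: int) -> tuple[float, float]:
    """The (lower, upper] percent-cover band of a category."""
    if score not in SCORE_BANDS:
        raise ValueError(f"score {score} outside 1..7")
    return SCORE_BANDS[score]


def classify_fate(surface_states: list[str] | pd.Series) -> list[str]:
    """Per-observation tissue labels {live, dead} from a colony timeline.

    ``surface_states`` is the chronological sequence of
    {clear_live, covered, clear_dead} for one colony.  Each maximal covered
    episode is labelled live throughout if it ends in ``clear_live``; it is
    labelled dead from its first covered day if it ends in ``clear_dead`` or
    if the record ends while still covered.  Once dead, tissue never
    reverts to live later in the record.
    """
    states = list(surface_states)
    valid = {"clear_live", "covered", "clear_dead"}
    bad = set(states) - valid
    if bad:
        raise ValueError(f"unknown surface states {sorted(bad)}")
    n = len(states)
    labels = ["live"] * n
    i = 0
    while i < n:
        if states[i] == "clear_dead":
            labels[i] = "dead"
            i += 1
            continue
        if states[i] == "covered":
            start = i
            while i < n and states[i] == "covered":
                i += 1
            episode_dead = i >= n or states[i] == "clear_dead"
            if episode_dead:
                for j in range(start, i):
                    labels[j] = "dead"
            continue
        i += 1
    # dead is absorbing over the record
    seen_dead = False
    for j in range(n):
        if labels[j] == "dead":
            seen_dead = True
        elif seen_dead:
            labels[j] = "dead"
    return labels


def exclude_dislodged(observations: pd.DataFrame) -> pd.DataFrame:
    """Drop every observation of any colony ever flagged dislodged.

    A colony moved by divers or storms is excluded from all further
    analyses, so the whole colony series is removed, not just the flagged
    surveys.
    """
    if "dislodged" not in observations.columns or observations.empty:
        return observations.copy()
    flagged = observations.loc[observations["dislodged"].astype(bool), "colony_id"]
    keep = ~observations["colony_id"].isin(set(flagged))
    out = observations.loc[keep].reset_index(drop=True)
    if out.empty and not observations.empty:
        warnings.warn("all colonies flagged dislodged; empty panel", stacklevel=2)
    return out


def site_exceedance(
    observations: pd.DataFrame,
    score_field: str = "sediment_score",
    threshold: int = 3,
    sites: pd.DataFrame | None = None,
    per_colony: bool = False,
) -> pd.DataFrame:
    """Per-site proportion of observations with score >= threshold.

    The default denominator is observations (colony x survey); with
    ``per_colony`` it is colonies, a colony counting once if it ever
    exceeds.  Observations with a missing score (e.g. mucous scores on
    non-Porites colonies) are excluded from both numerator and denominator.
    Sites with zero scored observations yield no row.  If a ``sites`` table
    (site_id, distance_km) is given, distances are attached.
    """
    if score_field not in observations.columns:
        raise ValueError(f"missing score column {score_field!r}")
    work = observations.dropna(subset=[score_field])
    if per_colony:
        colony = (
            work.assign(exceed=work[score_field] >= threshold)
            .groupby(["site_id", "colony_id"], sort=True)["exceed"]
            .any()
            .reset_index()
        )
        grouped = colony.groupby("site_id", sort=True)["exceed"]
    else:
        grouped = (
            work.assign(exceed=work[score_field] >= threshold)
            .groupby("site_id", sort=True)["exceed"]
        )
    out = grouped.agg(n_obs="size", proportion="mean").reset_index()
    out["n_obs"] = out["n_obs"].astype(int)
    if sites is not None:
        out = out.merge(sites[["site_id", "distance_km"]], on="site_id", how="left")
        out = out[["site_id", "distance_km", "n_obs", "proportion"]]
    return out
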