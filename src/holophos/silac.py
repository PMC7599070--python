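"""Forward/reverse SILAC dephosphorylation scoring.

Three cell lines are compared: (1) cells expressing the activated
PP1-binding cofactor, (2) cells expressing a derivative that cannot
bind PP1, and (3) empty vector, each measured in both labelling
orientations (heavy R10K8 / light R0K0).  For every phosphosite the
four control/active ratios

    2H/1L, 3H/1L, 2L/1H, 3L/1H

quantify how much the site's phosphorylation drops when the active
holoenzyme is present.  The dephosphorylation score is their geometric
mean:

    log2(score) = 0.25 * [log2(2H/1L) + log2(3H/1L)
                          + log2(2L/1H) + log2(3L/1H)]

so a score of 4 means the site is ~4-fold dephosphorylated in cells
carrying the active complex.  High-scoring sites are candidate
holoenzyme substrates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .io import SiteTable

#: RatioSet slot names, forward orientation first
RATIO_SLOTS = ("r2H1L", "r3H1L", "r2L1H", "r3L1H")
FORWARD_SLOTS = ("r2H1L", "r3H1L")
REVERSE_SLOTS = ("r2L1H", "r3L1H")


@dataclass(frozen=True)
class RatioSet:
    """The four SILAC control/active ratios for one site.

    Each ratio is ``None`` when the site was not quantified in that
    channel; present values must be strictly positive.
    """

    r2H1L: float | None = None
    r3H1L: float | None = None
    r2L1H: float | None = None
    r3L1H: float | None = None

    def __post_init__(self) -> None:
        for slot in RATIO_SLOTS:
            v = getattr(self, slot)
            if v is not None and not v > 0:
                raise ValueError(f"ratio {slot} must be strictly positive, got {v}")

    def present(self) -> dict[str, float]:
        return {s: getattr(self, s) for s in RATIO_SLOTS
                if getattr(self, s) is not None}


@dataclass
class ScoredSite:
    """A site's dephosphorylation score.

    ``score = 2**log2_score``; ``scored`` is False (and the score NaN)
    when too few ratios were available under the chosen policy.
    """

    site_id: str
    log2_score: float
    score: float
    n_ratios_used: int
    scored: bool = True


@dataclass(frozen=True)
class SilacDesign:
    """Maps quantification columns onto the four ratio slots.

    ``columns`` maps each slot name in :data:`RATIO_SLOTS` to exactly
    one column of the site table.  ``stored_orientation`` declares how
    the file stores the ratios: ``"control_over_active"`` (high value =
    dephosphorylated, used directly) or ``"active_over_control"``
    (inverted at mapping time, never downstream).
    """

    columns: Mapping[str, str]
    stored_orientation: str = "control_over_active"

    def __post_init__(self) -> None:
        missing = [s for s in RATIO_SLOTS if s not in self.columns]
        if missing:
            raise ValueError(f"design missing slots: {missing}")
        extra = [s for s in self.columns if s not in RATIO_SLOTS]
        if extra:
            raise ValueError(f"design has unknown slots: {extra}")
        if self.stored_orientation not in ("control_over_active",
                                           "active_over_control"):
            raise ValueError(
                f"unknown stored_orientation {self.stored_orientation!r}")


def compute_dephos_score(ratios: RatioSet, policy: str = "strict",
                         site_id: str = "") -> ScoredSite:
    """Score one site as the mean of the available log2 ratios.

    Policies
    --------
    ``"strict"``
        All four ratios required (the complete-case formula
        ``0.25 * sum(log2 r_i)``); otherwise the site is returned
        flagged unscored.
    ``"balanced"``
        At least two ratios, with at least one from each labelling
        orientation, guarding against label-bias artifacts.
    """
    if policy not in ("strict", "balanced"):
        raise ValueError(f"unknown policy {policy!r}")
    present = ratios.present()
    n = len(present)
    if policy == "strict":
        ok = n == 4
    else:
        n_fwd = sum(1 for s in FORWARD_SLOTS if s in present)
        n_rev = sum(1 for s in REVERSE_SLOTS if s in present)
        ok = n >= 2 and n_fwd >= 1 and n_rev >= 1
    if not ok:
        return ScoredSite(site_id, math.nan, math.nan, n, scored=False)
    log2_score = sum(math.log2(v) for v in present.values()) / n
    return ScoredSite(site_id, log2_score, 2.0 ** log2_score, n)


def score_table(table: SiteTable, design: SilacDesign,
                policy: str = "strict") -> pd.DataFrame:
    """Score every site in a table.

    Returns a DataFrame with columns ``site_id``, ``protein_id``,
    ``log2_score``, ``score``, ``n_ratios_used``, ``scored``.  Rows
    that cannot be scored under the policy are flagged, never dropped.
    """
    absent = [c for c in design.columns.values() if c not in table.df.columns]
    if absent:
        raise ValueError(f"design references absent columns: {absent}")
    invert = design.stored_orientation == "active_over_control"
    rows = []
    for _, row in table.df.iterrows():
        kwargs = {}
        for slot in RATIO_SLOTS:
            v = row[design.columns[slot]]
            if pd.isna(v):
                kwargs[slot] = None
            else:
                v = float(v)
                kwargs[slot] = 1.0 / v if invert else v
        scored = compute_dephos_score(RatioSet(**kwargs), policy,
                                      site_id=str(row["site_id"]))
        rows.append({
            "site_id": scored.site_id,
            "protein_id": row["protein_id"],
            "log2_score": scored.log2_score,
            "score": scored.score,
            "n_ratios_used": scored.n_ratios_used,
            "scored": scored.scored,
        })
    return pd.DataFrame(rows, columns=["site_id", "protein_id", "log2_score",
                                       "score", "n_ratios_used", "scored"])


def select_candidates(scored: pd.DataFrame,
                      threshold: float = 2.5) -> pd.DataFrame:
    """Candidate substrates: sites with ``score > threshold`` (strict),
    sorted descending by score with ties broken by ``site_id``.
    """
    if len(scored) == 0:
        raise ValueError("scored table is empty")
    hits = scored[scored["scored"] & (scored["score"] > threshold)].copy()
    hits = hits.sort_values(["score", "site_id"],
                            ascending=[False, True], kind="mergesort")
    return hits.reset_index(drop=True)
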