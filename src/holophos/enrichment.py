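"""Rank-based annotation enrichment of dephosphorylation scores.

Terms (e.g. GO Biological Process sets of proteins) are tested for
whether their members carry systematically higher dephosphorylation
scores than the remaining proteins, via a two-sided Mann-Whitney test
summarised by the rank-biserial enrichment score

    s = 2*U/(n1*n2) - 1 in [-1, 1],

where U counts (member, other) pairs with member > other, ties as 1/2.
p-values use exact enumeration of the permutation null (implemented as
a count-weighted dynamic program over the tie structure) for
n1*n2 <= 400, and the normal approximation with tie and continuity
correction otherwise.  FDR control is Benjamini-Hochberg step-up.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

EXACT_LIMIT = 400  # exact null up to n1*n2 of this size


def protein_scores(scored: pd.DataFrame, agg: str = "max") -> dict[str, float]:
    """Aggregate site scores to one value per protein.

    ``agg="max"`` (default: a protein is a substrate if any of its
    sites is) or ``agg="mean"``.  Unscored sites are ignored; proteins
    with no scored site are absent from the output.
    """
    if agg not in ("max", "mean"):
        raise ValueError(f"unknown aggregator {agg!r}")
    if len(scored) == 0:
        raise ValueError("scored table is empty")
    ok = scored[scored["scored"]]
    grouped = ok.groupby("protein_id")["score"]
    series = grouped.max() if agg == "max" else grouped.mean()
    return series.to_dict()


def _u_statistic(member: np.ndarray, other: np.ndarray) -> float:
    """Number of (member, other) pairs with member > other, ties as 1/2."""
    pooled = np.concatenate([member, other])
    ranks = stats.rankdata(pooled)
    r1 = ranks[:len(member)].sum()
    return r1 - len(member) * (len(member) + 1) / 2.0


def _exact_null_p(member: np.ndarray, other: np.ndarray, u_obs: float) -> float:
    """Two-sided exact p-value for U under random group assignment.

    The null distribution of U over all C(N, n1) assignments is built
    by a dynamic program over the distinct pooled values: picking
    ``a`` members from a tie group of size ``m`` with ``b`` smaller
    "other" elements already fixed adds ``a*b + a*(m-a)/2`` to U, and
    there are C(m, a) ways to do it.  Identical to brute-force
    enumeration, but polynomial time.
    """
    n1, n2 = len(member), len(other)
    pooled = np.sort(np.concatenate([member, other]))
    values, counts = np.unique(pooled, return_counts=True)
    # dist maps (k members used) -> {2U: count}; 2U keeps ties integral
    dist: list[dict[int, float]] = [dict() for _ in range(n1 + 1)]
    dist[0][0] = 1.0
    n_other_below = 0
    n_seen = 0
    for m in counts:
        m = int(m)
        new: list[dict[int, float]] = [dict() for _ in range(n1 + 1)]
        for k in range(min(n_seen, n1) + 1):
            for u2, c in dist[k].items():
                for a in range(0, min(m, n1 - k) + 1):
                    # others in this tie group once a members are chosen
                    # contribute later; smaller others so far: need count of
                    # *other-role* elements below this group = (elements seen
                    # so far) - (members chosen so far)
                    b_below = n_seen - k
                    du2 = 2 * a * b_below + a * (m - a)
                    w = c * comb(m, a)
                    tgt = new[k + a]
                    tgt[u2 + du2] = tgt.get(u2 + du2, 0.0) + w
        dist = new
        n_seen += m
    null = dist[n1]
    total = comb(n1 + n2, n1)
    mu2 = n1 * n2  # 2 * E[U]
    d_obs = abs(2.0 * u_obs - mu2)
    tail = sum(c for u2, c in null.items() if abs(u2 - mu2) >= d_obs - 1e-9)
    return min(1.0, tail / total)


def _normal_approx_p(member: np.ndarray, other: np.ndarray,
                     u_obs: float) -> float:
    """Two-sided normal-approximation p with tie and continuity correction."""
    n1, n2 = len(member), len(other)
    n = n1 + n2
    pooled = np.concatenate([member, other])
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts.astype(float) ** 3 - counts)
    mu = n1 * n2 / 2.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 1.0
    z = (abs(u_obs - mu) - 0.5) / np.sqrt(var)
    z = max(z, 0.0)
    return min(1.0, 2.0 * stats.norm.sf(z))


def enrichment_score(member_values: Sequence[float],
                     other_values: Sequence[float]) -> tuple[float, float]:
    """Rank-based enrichment score ``s`` in [-1, 1] and two-sided p.

    ``s = 2*U/(n1*n2) - 1``: +1 when every member exceeds every other,
    0 under exchangeability, -1 when every member is smaller.
    """
    member = np.asarray(member_values, dtype=float)
    other = np.asarray(other_values, dtype=float)
    if member.size == 0 or other.size == 0:
        raise ValueError("both value lists must be nonempty")
    u = _u_statistic(member, other)
    s = 2.0 * u / (member.size * other.size) - 1.0
    if member.size * other.size > EXACT_LIMIT:
        p = _normal_approx_p(member, other, u)
    else:
        p = _exact_null_p(member, other, u)
    return s, max(p, np.finfo(float).tiny)


def bh_fdr(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, order-preserving."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def read_annotation_map(path: str | Path) -> tuple[dict[str, set[str]],
                                                   dict[str, str]]:
    """Read a term->protein TSV (term_id, protein_id[, term_name]).

    Returns the annotation map and a term_id -> term_name dict (may be
    empty when no names are given).
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need at least two columns "
                         "(term_id, protein_id)")
    annotations: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    for row in df.itertuples(index=False):
        term, protein = row[0], row[1]
        annotations.setdefault(term, set()).add(protein)
        if df.shape[1] >= 3 and isinstance(row[2], str):
            names[term] = row[2]
    return annotations, names


def run_enrichment(scores: Mapping[str, float],
                   annotations: Mapping[str, set[str]],
                   min_size: int = 5,
                   term_names: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Test every annotation term against the protein score map.

    Terms with fewer than ``min_size`` scored members, or with no
    non-member proteins, are excluded.  BH adjustment is applied
    across all tested terms.  Columns: ``term_id``, ``term_name``,
    ``n_members``, ``mean_score``, ``s``, ``p``, ``q``.
    """
    all_values = dict(scores)
    rows = []
    for term_id in sorted(annotations):
        members = sorted(annotations[term_id] & all_values.keys())
        if len(members) < min_size:
            continue
        others = [pid for pid in all_values if pid not in annotations[term_id]]
        if not others:
            continue
        mvals = [all_values[pid] for pid in members]
        ovals = [all_values[pid] for pid in others]
        s, p = enrichment_score(mvals, ovals)
        rows.append({
            "term_id": term_id,
            "term_name": (term_names or {}).get(term_id, ""),
            "n_members": len(members),
            "mean_score": float(np.mean(mvals)),
            "s": s,
            "p": p,
        })
    if not rows:
        raise ValueError("no testable terms after size filtering")
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out


def significant_terms(enrichment: pd.DataFrame,
                      min_mean_score: float = 1.0,
                      max_q: float = 0.02) -> pd.DataFrame:
    """Reported view: terms with mean score and FDR passing strict cuts."""
    keep = (enrichment["mean_score"] > min_mean_score) & \
           (enrichment["q"] < max_q)
    return enrichment[keep].sort_values("q", kind="mergesort").reset_index(drop=True)
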