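"""TMT differential phosphoproteomics for neuronal actin-drug treatments.

Neurons of two genotypes (wild-type and cofactor-null) are treated
with cytochalasin D (CD, activates the holoenzyme via G-actin release)
or vehicle (DMSO); log intensities are Z-score normalised per sample,
(DMSO - CD) deltas are computed within matched blocks (replicate x
brain region x MS acquisition mode), pooled per genotype, and compared
between genotypes with Welch's t-test.  The differential Z-score
diff_z = mean(delta_WT) - mean(delta_KO) is positive for sites whose
CD-induced dephosphorylation requires the cofactor.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

GENOTYPES = ("WT", "KO")
TREATMENTS = ("DMSO", "CD", "LB")
DESIGN_FIELDS = ("genotype", "treatment", "replicate", "region", "ms_mode")
BLOCK_FIELDS = ("replicate", "region", "ms_mode")


@dataclass
class TmtDesign:
    """Sample sheet: one row per TMT channel/sample.

    ``table`` is indexed by sample id with columns genotype (WT/KO),
    treatment (DMSO/CD/LB), replicate (int), region
    (cortical/hippocampal) and ms_mode (MS2/MS3).  Each full
    combination must be unique.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in DESIGN_FIELDS if c not in self.table.columns]
        if missing:
            raise ValueError(f"design missing columns: {missing}")
        bad_g = set(self.table["genotype"]) - set(GENOTYPES)
        if bad_g:
            raise ValueError(f"unknown genotypes: {sorted(bad_g)}")
        bad_t = set(self.table["treatment"]) - set(TREATMENTS)
        if bad_t:
            raise ValueError(f"unknown treatments: {sorted(bad_t)}")
        if self.table.duplicated(subset=list(DESIGN_FIELDS)).any():
            raise ValueError("duplicate (genotype, treatment, replicate, "
                             "region, ms_mode) combination in design")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TmtDesign":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        table = pd.DataFrame.from_dict(raw, orient="index")
        table.index.name = "sample"
        return cls(table)

    def to_yaml(self, path: str | Path) -> None:
        raw = {str(k): {f: (int(v) if f == "replicate" else str(v))
                        for f, v in row.items()}
               for k, row in self.table.to_dict(orient="index").items()}
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


def zscore_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Standardise each sample column to mean 0, sd 1 (ddof=1).

    Missing entries are ignored in the statistics and preserved in the
    output.  A constant column (or one with < 2 finite values) is an
    error naming the sample.
    """
    out = matrix.copy().astype(float)
    for col in out.columns:
        vals = out[col]
        finite = vals.dropna()
        if len(finite) < 2 or finite.std(ddof=1) == 0:
            raise ValueError(f"sample {col!r}: constant or near-empty column "
                             "cannot be Z-scored")
        out[col] = (vals - finite.mean()) / finite.std(ddof=1)
    return out


def treatment_deltas(matrix: pd.DataFrame, design: TmtDesign,
                     pair: tuple[str, str] = ("DMSO", "CD")
                     ) -> tuple[dict[str, pd.DataFrame], list[str]]:
    """Per-site (pair[0] - pair[1]) deltas within matched blocks.

    A block is one (replicate, region, ms_mode) combination within a
    genotype; blocks missing either treatment are skipped with a
    warning.  Blocks are pooled (kept as columns) across region and
    ms_mode, giving per-genotype sites x blocks delta matrices.
    """
    ref, alt = pair
    warnings: list[str] = []
    deltas: dict[str, pd.DataFrame] = {}
    table = design.table
    for genotype in sorted(set(table["genotype"])):
        cols = {}
        sub = table[table["genotype"] == genotype]
        for block_key, block in sub.groupby(list(BLOCK_FIELDS)):
            ref_samples = block.index[block["treatment"] == ref]
            alt_samples = block.index[block["treatment"] == alt]
            if len(ref_samples) != 1 or len(alt_samples) != 1:
                warnings.append(
                    f"{genotype} block {block_key}: missing or duplicated "
                    f"{ref}/{alt} sample, block skipped")
                continue
            name = "_".join(str(k) for k in block_key)
            cols[name] = matrix[ref_samples[0]] - matrix[alt_samples[0]]
        deltas[genotype] = pd.DataFrame(cols)
    return deltas, warnings


@dataclass
class DifferentialRow:
    """Welch comparison of treatment deltas between genotypes."""

    site_id: str
    diff_z: float
    t_stat: float
    p: float
    significant: bool
    testable: bool = True


def differential_test(delta_wt: Sequence[float], delta_ko: Sequence[float],
                      site_id: str = "", alpha: float = 0.05,
                      equal_var: bool = False) -> DifferentialRow:
    """Two-sample t-test of WT vs KO deltas for one site.

    Welch (unequal variance) by default; ``equal_var=True`` switches to
    the pooled-variance test.  With fewer than 2 finite values in
    either group the site is returned untestable.
    """
    a = np.asarray(delta_wt, dtype=float)
    b = np.asarray(delta_ko, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        return DifferentialRow(site_id, np.nan, np.nan, np.nan,
                               significant=False, testable=False)
    diff_z = float(a.mean() - b.mean())
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        # degenerate: identical constants give t=0/p=1, else infinite t
        if diff_z == 0:
            return DifferentialRow(site_id, 0.0, 0.0, 1.0, False)
        return DifferentialRow(site_id, diff_z, np.inf * np.sign(diff_z),
                               0.0, 0.0 < alpha)
    t_stat, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return DifferentialRow(site_id, diff_z, float(t_stat), float(p),
                           significant=bool(p < alpha))


def differential_table(delta_wt: pd.DataFrame, delta_ko: pd.DataFrame,
                       alpha: float = 0.05,
                       equal_var: bool = False) -> pd.DataFrame:
    """Run :func:`differential_test` for every site (row) of the pooled
    per-genotype delta matrices; index alignment is by site id."""
    sites = delta_wt.index.intersection(delta_ko.index)
    rows = []
    for site in sites:
        r = differential_test(delta_wt.loc[site].to_numpy(),
                              delta_ko.loc[site].to_numpy(),
                              site_id=str(site), alpha=alpha,
                              equal_var=equal_var)
        rows.append(vars(r))
    return pd.DataFrame(rows, columns=["site_id", "diff_z", "t_stat", "p",
                                       "significant", "testable"])


def call_and_overlap(rows: pd.DataFrame, alpha: float,
                     silac_hits: set[str],
                     id_mapping: Mapping[str, str] | None = None
                     ) -> tuple[set[str], set[str], int]:
    """Call cofactor-dependent hits and intersect with SILAC candidates.

    Hits are testable sites with ``p < alpha`` and ``diff_z > 0``
    (CD-induced dephosphorylation present in WT only).  ``id_mapping``
    translates SILAC site ids into this experiment's ids; unmappable
    ids are counted, not fatal.  Returns (hits, overlap, n_unmapped).
    """
    ok = rows[rows["testable"] & (rows["p"] < alpha) & (rows["diff_z"] > 0)]
    hits = set(ok["site_id"])
    if id_mapping is None:
        mapped = set(silac_hits)
        n_unmapped = 0
    else:
        mapped = {id_mapping[s] for s in silac_hits if s in id_mapping}
        n_unmapped = sum(1 for s in silac_hits if s not in id_mapping)
    return hits, hits & mapped, n_unmapped
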