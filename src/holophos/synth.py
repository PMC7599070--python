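"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of its parameters and a seed, and
returns ground-truth labels alongside the data so recovery can be
checked against what was planted.  A single top-level seed fans out to
per-generator child streams by stable hashing of the generator name,
so adding a generator never perturbs the others.

The binding-fixture table encodes the reported mutant affinities of
the cofactor's PP1-binding peptide as Kd fold changes versus wild type
(Kd 10.4 nM); entries reported only as a bound carry ``bound_flag``.
Fixture on-rates are a synthetic convention (kon = 1e5 /M/s, a typical
peptide-protein on-rate) since only equilibrium constants are
reported; koff = kon * Kd.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bli import BindingParams, Sensorgram, simulate_sensorgram
from .io import SiteTable, extract_window
from .kinetics import (DilutionSeries, StandardCurve, final_concentrations,
                       mm_product)
from .silac import RATIO_SLOTS
from .tmt import TmtDesign

AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
BASIC = "RK"
ACIDIC = "DE"

#: synthetic convention for fixture kinetics (only Kd is reported)
FIXTURE_KON = 1e5  # 1/(M*s)
WT_KD = 10.4e-9    # M


@dataclass(frozen=True)
class BindingFixture:
    """One peptide construct with its dissociation constant.

    ``fold_vs_wt`` is Kd(mutant)/Kd(WT); ``bound_flag`` marks entries
    where only a lower bound on the fold change is reported (these are
    excluded from equality-style checks).
    """

    name: str
    kd: float
    fold_vs_wt: float
    bound_flag: bool = False

    def params(self, rmax: float = 1.0) -> BindingParams:
        kon = FIXTURE_KON
        return BindingParams(kon=kon, koff=kon * self.kd, rmax=rmax)


def _fixture(name: str, fold: float, bound: bool = False) -> BindingFixture:
    return BindingFixture(name=name, kd=fold * WT_KD, fold_vs_wt=fold,
                          bound_flag=bound)


BINDING_FIXTURES: dict[str, BindingFixture] = {
    f.name: f for f in [
        _fixture("WT", 1.0),
        _fixture("I520A", 4.0),
        _fixture("F522A", 650.0),
        _fixture("R536P", 300.0, bound=True),
        _fixture("Y534A", 10.0, bound=True),
        _fixture("W542A", 40.0),
        _fixture("R544A", 3.0),
        _fixture("LFL-3A", 900.0),
        _fixture("L574D", 17.0),
        _fixture("F577A", 16.0),
        _fixture("H578A", 7.0),
        _fixture("HHH-A", 50.0, bound=True),
    ]
}


def child_seed(seed: int, name: str) -> np.random.SeedSequence:
    """Stable per-generator seed stream derived from a top-level seed."""
    return np.random.SeedSequence([int(seed), zlib.crc32(name.encode())])


@dataclass
class PlantedSite:
    site_id: str
    protein_id: str
    position: int


@dataclass
class GroundTruth:
    """What the generators planted: substrate sites, the proteome they
    live in, and (after gen_silac) per-site effects."""

    proteome: dict[str, str]
    substrates: list[PlantedSite]
    halfwidth: int = 7

    @property
    def substrate_ids(self) -> set[str]:
        return {s.site_id for s in self.substrates}


def gen_proteome(n_proteins: int = 100, length: int = 60,
                 n_substrates: int = 20, seed: int = 0
                 ) -> tuple[dict[str, str], GroundTruth]:
    """Random proteome with one planted substrate motif per substrate
    protein.

    Background residues are uniform over the 20 amino acids.  Each
    planted window mimics the substrate consensus: basic residues
    N-terminal (-3..-1), a serine phosphoacceptor, acidic residues at
    +1..+3 and +6..+8, and the leucine doublet at +4/+5 — so every
    planted site matches the default motif pattern by construction.
    """
    if length < 20:
        raise ValueError("protein length must be at least 20")
    if n_substrates > n_proteins:
        raise ValueError("n_substrates cannot exceed n_proteins")
    rng = np.random.default_rng(child_seed(seed, "proteome"))
    proteome: dict[str, str] = {}
    substrates: list[PlantedSite] = []
    for i in range(n_proteins):
        pid = f"P{i + 1:04d}"
        seq = rng.choice(AA, size=length)
        if i < n_substrates:
            pos = int(rng.integers(10, length - 9))  # 1-based site position
            c = pos - 1
            seq[c - 3:c] = rng.choice(list(BASIC), size=3)
            seq[c] = "S"
            seq[c + 1:c + 4] = rng.choice(list(ACIDIC), size=3)
            seq[c + 4] = "L"
            seq[c + 5] = "L"
            seq[c + 6:c + 9] = rng.choice(list(ACIDIC), size=3)
            substrates.append(PlantedSite(site_id=f"{pid}_S{pos}",
                                          protein_id=pid, position=pos))
        proteome[pid] = "".join(seq)
    return proteome, GroundTruth(proteome=proteome, substrates=substrates)


def _background_sites(truth: GroundTruth, n_sites: int,
                      rng: np.random.Generator) -> list[PlantedSite]:
    """Sample non-substrate S/T sites from the proteome."""
    planted = {(s.protein_id, s.position) for s in truth.substrates}
    pool: list[tuple[str, int]] = []
    for pid, seq in truth.proteome.items():
        for i, res in enumerate(seq):
            if res in "ST" and (pid, i + 1) not in planted:
                pool.append((pid, i + 1))
    if len(pool) < n_sites:
        raise ValueError(f"proteome has only {len(pool)} background S/T "
                         f"sites, need {n_sites}")
    idx = rng.choice(len(pool), size=n_sites, replace=False)
    out = []
    for k in sorted(idx):
        pid, pos = pool[k]
        out.append(PlantedSite(site_id=f"{pid}_{truth.proteome[pid][pos-1]}{pos}",
                               protein_id=pid, position=pos))
    return out


def gen_silac(truth: GroundTruth, effect_log2: float = 3.0,
              noise_sd_log2: float = 0.3, n_sites: int = 500,
              seed: int = 0) -> tuple[SiteTable, pd.DataFrame]:
    """SILAC site table with four control/active ratio columns.

    Substrate sites get ratios centred at ``2**effect_log2``,
    background sites at 1, with lognormal noise per ratio
    (sd ``noise_sd_log2`` on the log2 scale).  Returns the table and a
    truth frame (site_id, is_substrate, log2_effect).
    """
    if not truth.substrates and n_sites == 0:
        raise ValueError("ground truth has no sites to generate")
    if noise_sd_log2 < 0:
        raise ValueError("noise sd cannot be negative")
    rng = np.random.default_rng(child_seed(seed, "silac"))
    n_background = n_sites - len(truth.substrates)
    if n_background < 0:
        raise ValueError("n_sites smaller than the number of substrates")
    sites = list(truth.substrates) + _background_sites(truth, n_background, rng)
    rows = []
    truth_rows = []
    for site in sites:
        is_sub = site.site_id in truth.substrate_ids
        mu = effect_log2 if is_sub else 0.0
        seq = truth.proteome[site.protein_id]
        row = {
            "site_id": site.site_id,
            "protein_id": site.protein_id,
            "position": site.position,
            "residue": seq[site.position - 1],
            "window": extract_window(seq, site.position, truth.halfwidth),
        }
        for slot in RATIO_SLOTS:
            row[slot] = float(2.0 ** (mu + rng.normal(0.0, noise_sd_log2)))
        rows.append(row)
        truth_rows.append({"site_id": site.site_id, "is_substrate": is_sub,
                           "log2_effect": mu})
    table = SiteTable(pd.DataFrame(rows))
    return table, pd.DataFrame(truth_rows)


def default_tmt_design(replicates: int = 2,
                       regions: tuple[str, ...] = ("cortical", "hippocampal"),
                       ms_modes: tuple[str, ...] = ("MS2", "MS3")
                       ) -> TmtDesign:
    """The pooled neuronal design: WT/KO x DMSO/CD x replicates x
    regions x MS modes, one sample per combination."""
    rows = {}
    for g in ("WT", "KO"):
        for t in ("DMSO", "CD"):
            for rep in range(1, replicates + 1):
                for region in regions:
                    for mode in ms_modes:
                        sample = f"{g}_{t}_r{rep}_{region}_{mode}"
                        rows[sample] = dict(genotype=g, treatment=t,
                                            replicate=rep, region=region,
                                            ms_mode=mode)
    return TmtDesign(pd.DataFrame.from_dict(rows, orient="index"))


def gen_tmt(truth: GroundTruth, design: TmtDesign | None = None,
            effect: float = 1.5, noise_sd: float = 0.5,
            n_sites: int = 2000, seed: int = 0
            ) -> tuple[pd.DataFrame, TmtDesign, set[str]]:
    """TMT log-intensity matrix with genotype x treatment structure.

    Planted (substrate) sites are dephosphorylated by CD only in WT
    samples: their WT/CD entries are lowered by ``effect`` Z-units, so
    the (DMSO - CD) delta carries the effect in WT and 0 in KO.
    Per-site baselines are standard normal; measurement noise is
    Gaussian with sd ``noise_sd``.  Returns (matrix, design,
    planted-site ids); planted ids match the SILAC generator's.
    """
    design = design or default_tmt_design()
    table = design.table
    for required in ("WT", "KO"):
        if required not in set(table["genotype"]):
            raise ValueError(f"design lacks genotype {required}")
    for required in ("DMSO", "CD"):
        if required not in set(table["treatment"]):
            raise ValueError(f"design lacks treatment {required}")
    if table["replicate"].nunique() < 2:
        raise ValueError("design needs at least 2 replicates")
    rng = np.random.default_rng(child_seed(seed, "tmt"))
    planted = sorted(truth.substrate_ids)
    n_background = n_sites - len(planted)
    if n_background < 0:
        raise ValueError("n_sites smaller than the number of planted sites")
    site_ids = planted + [f"bg{i + 1:05d}" for i in range(n_background)]
    samples = list(table.index)
    baseline = rng.normal(0.0, 1.0, size=len(site_ids))
    data = baseline[:, None] + rng.normal(0.0, noise_sd,
                                          size=(len(site_ids), len(samples)))
    is_wt_cd = ((table["genotype"] == "WT")
                & (table["treatment"] == "CD")).to_numpy()
    data[:len(planted), :][:, is_wt_cd] -= effect
    matrix = pd.DataFrame(data, index=site_ids, columns=samples)
    matrix.index.name = "site_id"
    return matrix, design, set(planted)


def gen_assay_plate(kcat_over_km: float, km: float,
                    t: float = 15.0, enzyme_units: float = 1.0,
                    series: DilutionSeries | None = None,
                    curve: StandardCurve | None = None,
                    noise_sd_abs: float = 0.0, seed: int = 0
                    ) -> pd.DataFrame:
    """One phosphatase assay plate as CSV-ready rows.

    Product follows the single-timepoint Michaelis-Menten model, is
    converted to A620 through the standard curve, and Gaussian
    absorbance noise is added.  Columns: well, substrate_conc_uM, a620.
    """
    series = series or DilutionSeries()
    curve = curve or StandardCurve(slope=0.01, intercept=0.05)
    rng = np.random.default_rng(child_seed(seed, "plate"))
    conc = final_concentrations(series)
    p = mm_product(conc, t, enzyme_units, kcat_over_km, km)
    a620 = curve.intercept + curve.slope * p
    if noise_sd_abs > 0:
        a620 = a620 + rng.normal(0.0, noise_sd_abs, size=a620.shape)
    wells = [f"{chr(ord('A') + i // 12)}{i % 12 + 1}" for i in range(len(conc))]
    return pd.DataFrame({"well": wells, "substrate_conc_uM": conc,
                         "a620": a620})


def fixture_concentration_grid(kd: float, n: int = 8,
                               span: float = 20.0) -> np.ndarray:
    """Log-spaced analyte concentrations bracketing a fixture's Kd."""
    return np.geomspace(kd / span, kd * span, n)


def gen_sensorgrams(fixture: str | BindingParams,
                    conc: np.ndarray | None = None,
                    t_assoc: float | None = None,
                    t_dissoc: float | None = None,
                    dt: float | None = None,
                    noise_sd: float = 0.0, seed: int = 0
                    ) -> list[Sensorgram]:
    """Simulate BLI traces for a named fixture or explicit parameters.

    Concentrations default to 8 log-spaced points bracketing the Kd.
    The association window defaults to ~12 dissociation half-times so
    the slowest trace approaches equilibrium (truncation error below
    1e-4 of Req).
    """
    if isinstance(fixture, str):
        if fixture not in BINDING_FIXTURES:
            raise ValueError(
                f"unknown fixture {fixture!r}; known fixtures: "
                f"{sorted(BINDING_FIXTURES)}")
        params = BINDING_FIXTURES[fixture].params()
    else:
        params = fixture
    if conc is None:
        conc = fixture_concentration_grid(params.kd)
    if t_assoc is None:
        t_assoc = 12.0 / params.koff
    if t_dissoc is None:
        t_dissoc = 3.0 / params.koff
    if dt is None:
        dt = t_assoc / 1000.0
    ss = child_seed(seed, "sensorgrams").spawn(len(conc))
    return [
        simulate_sensorgram(params, float(c), t_assoc, t_dissoc, dt,
                            noise_sd=noise_sd,
                            seed=None if noise_sd == 0 else child)
        for c, child in zip(conc, ss)
    ]
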