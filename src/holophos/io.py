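"""Core data types and file I/O shared by every pipeline stage.

Phosphorylation sites are represented with 1-based residue positions
(matching the field's "pS455" notation) and a sequence window of odd
length centred on the phosphoacceptor.  Positions beyond the protein
termini are padded with ``'_'``; pads are excluded from all downstream
frequency counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

PAD = "_"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PHOSPHO_RESIDUES = frozenset("STY")

#: columns every site table must provide
REQUIRED_COLUMNS = ("protein_id", "position", "residue")
#: recognised metadata columns; anything else is treated as quantification
META_COLUMNS = ("site_id", "protein_id", "position", "residue", "window",
                "localization_prob")


@dataclass
class PhosphoSite:
    """One localized phosphorylation site.

    Attributes
    ----------
    site_id : str
        Unique identifier within a table.
    protein_id : str
        Identifier of the parent protein (FASTA header token).
    position : int
        1-based residue index of the phosphoacceptor.
    residue : str
        One of S, T, Y.
    window : str
        Sequence window of length ``2*halfwidth + 1`` centred on the
        site, ``'_'``-padded beyond the termini.
    localization_prob : float or None
        Site localization probability in [0, 1], if available.
    """

    site_id: str
    protein_id: str
    position: int
    residue: str
    window: str = ""
    localization_prob: float | None = None

    def __post_init__(self) -> None:
        if self.residue not in PHOSPHO_RESIDUES:
            raise ValueError(
                f"site {self.site_id!r}: residue must be one of S/T/Y, "
                f"got {self.residue!r}")
        if self.position < 1:
            raise ValueError(
                f"site {self.site_id!r}: position must be >= 1 (1-based)")
        if self.window:
            h = len(self.window) // 2
            if len(self.window) % 2 != 1:
                raise ValueError(f"site {self.site_id!r}: window length must be odd")
            if self.window[h] != self.residue:
                raise ValueError(
                    f"site {self.site_id!r}: window centre {self.window[h]!r} "
                    f"does not match residue {self.residue!r}")


@dataclass
class SiteTable:
    """An ordered collection of phosphosites plus quantification columns.

    Thin wrapper over a :class:`pandas.DataFrame` whose rows are sites.
    Metadata columns are those in :data:`META_COLUMNS`; every other
    column is a quantification column keyed by experiment label.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"site table missing required columns: {missing}")
        if "site_id" not in self.df.columns:
            self.df = self.df.copy()
            self.df.insert(0, "site_id", [
                f"{p}_{r}{q}" for p, r, q in zip(
                    self.df["protein_id"], self.df["residue"], self.df["position"])
            ])
        ids = self.df["site_id"]
        if ids.duplicated().any():
            dups = sorted(ids[ids.duplicated()].unique())
            raise ValueError(f"duplicate site_id values: {dups}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def quant_columns(self) -> list[str]:
        return [c for c in self.df.columns if c not in META_COLUMNS]

    def sites(self) -> Iterable[PhosphoSite]:
        for row in self.df.itertuples(index=False):
            lp = getattr(row, "localization_prob", None)
            if lp is not None and pd.isna(lp):
                lp = None
            yield PhosphoSite(
                site_id=str(row.site_id),
                protein_id=str(row.protein_id),
                position=int(row.position),
                residue=str(row.residue),
                window=str(getattr(row, "window", "") or ""),
                localization_prob=lp,
            )


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a multi-record FASTA into ``{protein_id: sequence}``.

    The id is the first whitespace-delimited token of the header;
    sequences are uppercased; insertion order is preserved.

    Raises
    ------
    ValueError
        If the file contains no records or a duplicate id.
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ValueError(f"duplicate FASTA id: {record.id!r}")
        sequences[record.id] = str(record.seq).upper()
    if not sequences:
        raise ValueError(f"no FASTA records found in {path}")
    return sequences


def extract_window(sequence: str, position: int, halfwidth: int = 7) -> str:
    """Return the sequence window of length ``2*halfwidth + 1`` centred at
    ``position`` (1-based), padding beyond the termini with ``'_'``.

    >>> extract_window("QQGKSSSTGNLLDKDDL", 7)
    '_QQGKSSSTGNLLDK'
    """
    if not 1 <= position <= len(sequence):
        raise ValueError(
            f"position {position} out of range for sequence of "
            f"length {len(sequence)}")
    i = position - 1
    lo, hi = i - halfwidth, i + halfwidth + 1
    left_pad = PAD * max(0, -lo)
    right_pad = PAD * max(0, hi - len(sequence))
    return left_pad + sequence[max(0, lo):min(len(sequence), hi)] + right_pad


def read_site_table(path: str | Path,
                    sequences: Mapping[str, str] | None = None,
                    halfwidth: int = 7) -> SiteTable:
    """Read a tab-separated site table.

    Required columns: ``protein_id``, ``position``, ``residue``.
    Optional: ``site_id``, ``localization_prob``, ``window``; any other
    column is kept as a quantification column.  Missing numeric values
    are encoded as ``NA``.

    If ``sequences`` is given, windows are recomputed from the protein
    sequences (and positions validated); otherwise an existing
    ``window`` column is used as-is.
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "residue": str},
                     na_values=["NA"], keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns: {missing}")
    for i, res in enumerate(df["residue"]):
        if res not in PHOSPHO_RESIDUES:
            raise ValueError(
                f"{path}: row {i + 1}: residue {res!r} not one of S/T/Y")
    df["position"] = df["position"].astype(int)
    if sequences is not None:
        windows = []
        for i, (pid, pos, res) in enumerate(
                zip(df["protein_id"], df["position"], df["residue"])):
            if pid not in sequences:
                raise ValueError(f"{path}: row {i + 1}: protein {pid!r} "
                                 f"not in supplied sequences")
            seq = sequences[pid]
            w = extract_window(seq, pos, halfwidth)
            if seq[pos - 1] != res:
                raise ValueError(
                    f"{path}: row {i + 1}: residue {res!r} does not match "
                    f"sequence {seq[pos - 1]!r} at position {pos} of {pid}")
            windows.append(w)
        df["window"] = windows
    return SiteTable(df)


def write_site_table(table: SiteTable, path: str | Path) -> None:
    """Write a site table as TSV; missing numeric values become ``NA``."""
    table.df.to_csv(path, sep="\t", index=False, na_rep="NA")


def validate_site_table(table: SiteTable,
                        sequences: Mapping[str, str]) -> list[str]:
    """Cross-check a table against protein sequences.

    Returns a list of human-readable problems (empty when valid):
    unknown proteins, out-of-range positions, residue mismatches and
    window centres that disagree with the annotated residue.
    """
    problems: list[str] = []
    for site in table.sites():
        seq = sequences.get(site.protein_id)
        if seq is None:
            problems.append(f"{site.site_id}: protein {site.protein_id!r} "
                            "not in FASTA")
            continue
        if not 1 <= site.position <= len(seq):
            problems.append(f"{site.site_id}: position {site.position} out of "
                            f"range (protein length {len(seq)})")
            continue
        if seq[site.position - 1] != site.residue:
            problems.append(f"{site.site_id}: residue {site.residue} does not "
                            f"match sequence {seq[site.position - 1]}")
        if site.window:
            h = len(site.window) // 2
            expect = extract_window(seq, site.position, h)
            if site.window != expect:
                problems.append(f"{site.site_id}: window {site.window!r} "
                                f"differs from sequence-derived {expect!r}")
    return problems
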