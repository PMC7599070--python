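"""Positional amino-acid frequency contrast and the S/T-x(2-3)-phi-L scanner.

High-scoring dephosphorylation substrates share a short core motif: the
target serine/threonine, a 2-3 residue spacer, a hydrophobic residue
(phi), then leucine.  With the 3-residue spacer the hydrophobic pair
sits at +4/+5 relative to the phosphoacceptor ("canonical" register);
with the 2-residue spacer at +3/+4 ("stretched").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import AMINO_ACIDS, PAD

HYDROPHOBIC = frozenset("LIVMF")


@dataclass(frozen=True)
class MotifPattern:
    """The core dephosphorylation recognition pattern S/T-x(2-3)-phi-L.

    ``phi_set`` is the hydrophobic class accepted at the penultimate
    position; ``terminal`` the residues accepted at the distal position
    (leucine by default; pass ``relaxed=True`` to accept any phi there).
    """

    target_set: frozenset[str] = frozenset("ST")
    spacer_min: int = 2
    spacer_max: int = 3
    phi_set: frozenset[str] = HYDROPHOBIC
    terminal: frozenset[str] = frozenset("L")

    def __post_init__(self) -> None:
        if self.spacer_min > self.spacer_max:
            raise ValueError("empty spacer range")
        if not (self.target_set and self.phi_set and self.terminal):
            raise ValueError("pattern residue sets must be nonempty")

    @classmethod
    def default(cls) -> "MotifPattern":
        return cls()

    @classmethod
    def relaxed(cls) -> "MotifPattern":
        """Variant accepting any hydrophobic residue at the distal position."""
        return cls(terminal=HYDROPHOBIC)


@dataclass(frozen=True)
class MotifMatch:
    """One motif occurrence.

    ``target_position`` is 1-based.  ``match_class`` is ``"canonical"``
    for the 3-residue spacer (phi at +4, L at +5) and ``"stretched"``
    for the 2-residue spacer (phi at +3, L at +4).  When both spacers
    match at a position, the larger spacer is reported and the
    alternative spacer lengths are recorded in ``alt_spacers``.
    """

    target_position: int
    target_residue: str
    spacer_len: int
    phi_residue: str
    match_class: str
    alt_spacers: tuple[int, ...] = ()


def _classify_spacer(spacer: int) -> str:
    return "canonical" if spacer == 3 else "stretched"


def scan_motif(sequence: str,
               pattern: MotifPattern | None = None) -> list[MotifMatch]:
    """Find all motif occurrences in a protein or peptide sequence.

    For every position whose residue is in the target set, each spacer
    ``s`` in the pattern range is checked: the residue ``s+1`` after
    the target must be in ``phi_set`` and the residue ``s+2`` after it
    in ``terminal``.  Matches are ordered by position; the empty list
    means no match.
    """
    pattern = pattern or MotifPattern.default()
    matches: list[MotifMatch] = []
    n = len(sequence)
    for i, res in enumerate(sequence):
        if res not in pattern.target_set:
            continue
        hits = []
        for s in range(pattern.spacer_min, pattern.spacer_max + 1):
            j_phi, j_term = i + s + 1, i + s + 2
            if j_term < n and sequence[j_phi] in pattern.phi_set \
                    and sequence[j_term] in pattern.terminal:
                hits.append(s)
        if hits:
            primary = max(hits)
            matches.append(MotifMatch(
                target_position=i + 1,
                target_residue=res,
                spacer_len=primary,
                phi_residue=sequence[i + primary + 1],
                match_class=_classify_spacer(primary),
                alt_spacers=tuple(s for s in hits if s != primary),
            ))
    return matches


@dataclass
class FrequencyMatrix:
    """Per-position amino-acid counts and frequencies over a window set.

    ``counts`` is positions (-h..+h) x residues; ``n`` the non-pad
    count per position.  ``freq`` normalises each position by its own
    non-pad count (positions with count 0 have no frequencies).
    """

    counts: pd.DataFrame
    n: pd.Series

    @property
    def halfwidth(self) -> int:
        return int(self.counts.index.max())

    @property
    def freq(self) -> pd.DataFrame:
        denom = self.n.replace(0, np.nan)
        return self.counts.div(denom, axis=0)

    def adjusted_freq(self, pseudocount: float = 0.5) -> pd.DataFrame:
        """Frequencies with a pseudocount added on the count scale
        before normalisation (Laplace-style smoothing)."""
        k = self.counts.shape[1]
        denom = self.n + k * pseudocount
        return (self.counts + pseudocount).div(denom, axis=0)


def positional_frequency(windows: Sequence[str]) -> FrequencyMatrix:
    """Count residues at each window position, excluding ``'_'`` pads.

    All windows must share the same odd length; position 0 is the
    phosphoacceptor.
    """
    if not windows:
        raise ValueError("no windows supplied")
    lengths = {len(w) for w in windows}
    if len(lengths) != 1:
        raise ValueError(f"mixed window lengths: {sorted(lengths)}")
    (length,) = lengths
    if length % 2 != 1:
        raise ValueError("window length must be odd")
    h = length // 2
    positions = list(range(-h, h + 1))
    residues = list(AMINO_ACIDS)
    counts = pd.DataFrame(0, index=positions, columns=residues, dtype=int)
    arr = np.array([list(w) for w in windows])
    for j, pos in enumerate(positions):
        col = arr[:, j]
        vals, cnt = np.unique(col[col != PAD], return_counts=True)
        for v, c in zip(vals, cnt):
            if v not in counts.columns:
                counts[v] = 0
            counts.loc[pos, v] += int(c)
    n = counts.sum(axis=1)
    return FrequencyMatrix(counts=counts, n=n)


def frequency_contrast(foreground: FrequencyMatrix,
                       background: FrequencyMatrix,
                       pseudocount: float = 0.5) -> pd.DataFrame:
    """log2 enrichment of foreground over background per position/residue.

    Pseudocounts are applied on the count scale before normalisation,
    so residues absent from one set stay finite.
    """
    if foreground.counts.shape != background.counts.shape or \
            list(foreground.counts.index) != list(background.counts.index):
        raise ValueError("frequency matrices have mismatched dimensions")
    f = foreground.adjusted_freq(pseudocount)
    b = background.adjusted_freq(pseudocount)
    return np.log2(f / b)


def classify_candidates(candidates: pd.DataFrame,
                        pattern: MotifPattern | None = None,
                        window_column: str = "window"
                        ) -> tuple[pd.DataFrame, int]:
    """Label each candidate canonical / stretched / none by scanning its
    site-centred window.

    Returns the annotated copy (new ``motif_class`` column) and a count
    of warnings (rows whose window centre is not in the target set).
    """
    pattern = pattern or MotifPattern.default()
    out = candidates.copy()
    classes = []
    warnings = 0
    for w in out[window_column]:
        h = len(w) // 2
        if w[h] not in pattern.target_set:
            warnings += 1
            classes.append("none")
            continue
        centre_matches = [m for m in scan_motif(w, pattern)
                          if m.target_position == h + 1]
        classes.append(centre_matches[0].match_class if centre_matches
                       else "none")
    out["motif_class"] = classes
    return out, warnings
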