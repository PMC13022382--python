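"""Amino-acid frequency and enrichment analysis of NNK library reads.

Amplicon reads from saturation-mutagenesis screening rounds are matched to
the library template at fixed positions (the amplicon is a fixed-length
window around the randomized stretch, so alignment reduces to position-based
comparison with an identity gate). Codons at the randomized positions are
translated (the amber stop is kept as a 21st symbol: NNK permits TAG) and
tallied into per-position frequencies; round-over-round enrichment is the
pseudo-counted frequency ratio against the first round.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synth import AA_ALPHABET, _CODON_TABLE

__all__ = [
    "LibraryDesign",
    "EnrichmentTable",
    "extract_variable_codons",
    "aa_frequencies",
    "enrichment_ratio",
    "combine_rounds",
]

log = logging.getLogger(__name__)

#: Minimum fraction of matching non-randomized bases for a read to count.
IDENTITY_THRESHOLD = 0.90


@dataclass
class LibraryDesign:
    """Template and randomized-codon layout of one NNK library."""

    template: str
    randomized_codons: list[int]  # 0-based codon indices
    rounds: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.template = self.template.upper()
        if len(self.template) % 3 != 0:
            raise ValueError("template length must be divisible by 3")
        n = len(self.template) // 3
        if len(set(self.randomized_codons)) != len(self.randomized_codons):
            raise ValueError("randomized codon indices must be unique")
        for pos in self.randomized_codons:
            if not 0 <= pos < n:
                raise ValueError(f"randomized codon index {pos} out of range (0-{n - 1})")

    def constant_mask(self) -> np.ndarray:
        """Boolean mask of template bases outside the randomized codons."""
        mask = np.ones(len(self.template), dtype=bool)
        for pos in self.randomized_codons:
            mask[3 * pos : 3 * pos + 3] = False
        return mask


@dataclass
class EnrichmentTable:
    """Per-position amino-acid frequencies for one or more rounds.

    ``freq`` has a (position, amino acid) MultiIndex over the randomized
    codons and the 21-symbol alphabet (20 amino acids + stop); one column
    per round. ``read_counts`` maps round -> (total, used, discarded).
    """

    freq: pd.DataFrame
    read_counts: dict[str, tuple[int, int, int]]
    design: LibraryDesign


def extract_variable_codons(
    read: str, design: LibraryDesign
) -> tuple[list[str] | None, str | None]:
    """Return the codons at the randomized positions, or a discard reason.

    A read is usable when its length equals the template's and it matches
    the template at >= 90% of the non-randomized bases; an ambiguous base
    (N) inside a randomized codon discards the read as "ambiguous".
    """
    read = read.upper()
    if len(read) != len(design.template):
        return None, "length_mismatch"
    arr = np.frombuffer(read.encode(), dtype="S1")
    tmpl = np.frombuffer(design.template.encode(), dtype="S1")
    mask = design.constant_mask()
    n_const = int(mask.sum())
    if n_const > 0:
        identity = float(np.sum(arr[mask] == tmpl[mask])) / n_const
        if identity < IDENTITY_THRESHOLD:
            return None, "identity"
    codons = [read[3 * pos : 3 * pos + 3] for pos in design.randomized_codons]
    if any("N" in c for c in codons):
        return None, "ambiguous"
    return codons, None


def aa_frequencies(
    reads: list[tuple[str, str, str | None]] | list[str],
    design: LibraryDesign,
    round_label: str = "r0",
) -> EnrichmentTable:
    """Tally amino-acid frequencies at each randomized position.

    The denominator is the number of usable reads (both usable and discarded
    counts are reported). Frequencies at every position sum to 1 over the
    21-symbol alphabet.
    """
    seqs = [r if isinstance(r, str) else r[1] for r in reads]
    counts = {
        pos: {aa: 0 for aa in AA_ALPHABET} for pos in design.randomized_codons
    }
    used = 0
    discarded = 0
    for seq in seqs:
        codons, reason = extract_variable_codons(seq, design)
        if codons is None:
            discarded += 1
            continue
        aas = [_CODON_TABLE.get(c) for c in codons]
        if any(a is None for a in aas):
            discarded += 1
            continue
        for pos, aa in zip(design.randomized_codons, aas):
            counts[pos][aa] += 1
        used += 1
    if used == 0:
        raise ValueError("no usable reads")
    index = pd.MultiIndex.from_product(
        [design.randomized_codons, list(AA_ALPHABET)], names=["position", "aa"]
    )
    values = np.array(
        [counts[pos][aa] / used for pos, aa in index], dtype=float
    )
    freq = pd.DataFrame({round_label: values}, index=index)
    log.info("round %s: %d reads, %d used, %d discarded", round_label, len(seqs), used, discarded)
    return EnrichmentTable(
        freq=freq,
        read_counts={round_label: (len(seqs), used, discarded)},
        design=design,
    )


def combine_rounds(tables: list[EnrichmentTable]) -> EnrichmentTable:
    """Merge per-round tables (same design) into one multi-round table."""
    first = tables[0]
    for t in tables[1:]:
        if (
            t.design.template != first.design.template
            or t.design.randomized_codons != first.design.randomized_codons
        ):
            raise ValueError("mismatched library designs between rounds")
    freq = pd.concat([t.freq for t in tables], axis=1)
    counts: dict[str, tuple[int, int, int]] = {}
    for t in tables:
        counts.update(t.read_counts)
    return EnrichmentTable(freq=freq, read_counts=counts, design=first.design)


def enrichment_ratio(
    tables: list[EnrichmentTable] | EnrichmentTable, pseudo: float = 1e-4
) -> pd.DataFrame:
    """Round-over-round frequency enrichment against the first round.

    ratio_r = (freq_r + pseudo) / (freq_first + pseudo), computed per
    (position, amino acid); a ``last_over_first`` summary column is
    appended. Being frequency-based, the ratios are invariant to sequencing
    depth.
    """
    table = combine_rounds(tables) if isinstance(tables, list) else tables
    if table.freq.shape[1] < 2:
        raise ValueError("enrichment needs at least 2 rounds")
    base = table.freq.iloc[:, 0] + pseudo
    ratios = table.freq.add(pseudo).div(base, axis=0)
    ratios["last_over_first"] = (table.freq.iloc[:, -1] + pseudo) / base
    return ratios
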