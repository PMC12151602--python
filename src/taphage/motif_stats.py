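"""Observed, expected and relative motif frequencies per genome.

The statistic of interest is the relative frequency of a toxin recognition
site (for MazF the trinucleotide ACA) in a genome: the observed per-window
frequency divided by the frequency expected from the genome's base
composition alone.  Values below 1 indicate avoidance of the site.

Conventions
-----------
* Occurrences are counted at every start position, overlapping matches
  included, on the given strand only (the genomes of interest are
  message-sense ssRNA molecules).
* Observed frequency uses the number of windows, ``L - k + 1``, as its
  denominator; the expected count multiplies the expected frequency by the
  full genome length ``L``.  The two denominators differ by a factor
  ``L/(L-k+1)`` (< 0.06% at the genome lengths of interest); both follow the
  published convention for these statistics and reproduce published tables.
* IUPAC-degenerate motif letters match their expansion sets; ambiguity
  letters in the *genome* match nothing but still count toward length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome_io import GenomeRecord, RNA_BASES

#: IUPAC code -> set of concrete RNA bases it stands for.
IUPAC_EXPAND: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "U": "U",
    "R": "AG", "Y": "CU", "S": "CG", "W": "AU",
    "K": "GU", "M": "AC", "B": "CGU", "D": "AGU",
    "H": "ACU", "V": "ACG", "N": "ACGU",
}

_BASE_CODE = {b: i for i, b in enumerate(RNA_BASES)}
_AMBIG_CODE = len(RNA_BASES)  # any non-ACGU letter

# translation table mapping every IUPAC letter to a small integer code
_ENCODE_TABLE = np.full(128, -1, dtype=np.int8)
for _b, _i in _BASE_CODE.items():
    _ENCODE_TABLE[ord(_b)] = _i
for _c in IUPAC_EXPAND:
    if _c not in _BASE_CODE:
        _ENCODE_TABLE[ord(_c)] = _AMBIG_CODE


def encode(sequence: str) -> np.ndarray:
    """Encode a normalized sequence as int8 codes (A=0,C=1,G=2,U=3, ambig=4)."""
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    codes = _ENCODE_TABLE[raw]
    if np.any(codes < 0):
        bad = int(np.argmax(codes < 0))
        raise ValueError(
            f"invalid character {sequence[bad]!r} at position {bad + 1}"
        )
    return codes


def _motif_masks(motif: str) -> list[np.ndarray]:
    """Per-position boolean lookup tables over the 5 sequence codes."""
    masks = []
    for letter in motif:
        if letter not in IUPAC_EXPAND:
            raise ValueError(f"motif letter {letter!r} is not an IUPAC nucleotide code")
        table = np.zeros(_AMBIG_CODE + 1, dtype=bool)
        for base in IUPAC_EXPAND[letter]:
            table[_BASE_CODE[base]] = True
        # ambiguity letters in the genome never match
        masks.append(table)
    return masks


def count_motif(sequence: str | np.ndarray, motif: str) -> int:
    """Count overlapping occurrences of ``motif`` in ``sequence``.

    ``motif`` may contain IUPAC degenerate letters (e.g. ``ACD``), which match
    their expansion sets.  Ambiguity letters in the genome match nothing.
    Returns 0 when the motif is longer than the sequence.
    """
    masks = _motif_masks(motif)
    if len(motif) < 1:
        raise ValueError("motif must have length >= 1")
    codes = sequence if isinstance(sequence, np.ndarray) else encode(sequence)
    return _count_encoded(codes, masks)


def _count_encoded(codes: np.ndarray, masks: list[np.ndarray]) -> int:
    k = len(masks)
    n_windows = codes.size - k + 1
    if n_windows <= 0:
        return 0
    hit = masks[0][codes[:n_windows]]
    for j in range(1, k):
        hit &= masks[j][codes[j : j + n_windows]]
    return int(hit.sum())


@dataclass(frozen=True)
class Composition:
    """Single-nucleotide composition of one genome.

    Fractions are taken over the full length, so at positions holding
    ambiguity codes the four base fractions sum to less than one.
    """

    fraction_a: float
    fraction_c: float
    fraction_g: float
    fraction_u: float
    length: int
    n_ambiguous: int = 0

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("Composition requires length >= 1")
        total = (
            self.fraction_a + self.fraction_c + self.fraction_g + self.fraction_u
            + self.n_ambiguous / self.length
        )
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"base fractions and ambiguity must sum to 1, got {total}")

    def fraction(self, base: str) -> float:
        return {
            "A": self.fraction_a, "C": self.fraction_c,
            "G": self.fraction_g, "U": self.fraction_u,
        }[base]


def base_fractions(sequence: str | np.ndarray) -> Composition:
    """Compute base fractions over the full sequence length."""
    codes = sequence if isinstance(sequence, np.ndarray) else encode(sequence)
    if codes.size < 1:
        raise ValueError("sequence must have length >= 1")
    counts = np.bincount(codes, minlength=_AMBIG_CODE + 1)
    length = codes.size
    return Composition(
        fraction_a=counts[_BASE_CODE["A"]] / length,
        fraction_c=counts[_BASE_CODE["C"]] / length,
        fraction_g=counts[_BASE_CODE["G"]] / length,
        fraction_u=counts[_BASE_CODE["U"]] / length,
        length=length,
        n_ambiguous=int(counts[_AMBIG_CODE]),
    )


def expected_frequency(comp: Composition, motif: str) -> float:
    """Zero-order expected motif frequency from base composition.

    Product over motif positions of the summed fractions of each letter's
    expansion set; for a degenerate motif this equals the sum of the products
    over all concrete expansions.
    """
    freq = 1.0
    for letter in motif:
        if letter not in IUPAC_EXPAND:
            raise ValueError(f"motif letter {letter!r} is not an IUPAC nucleotide code")
        freq *= sum(comp.fraction(b) for b in IUPAC_EXPAND[letter])
    return freq


def expected_count(comp: Composition, motif: str) -> float:
    """Expected number of motif sites: expected frequency times genome length."""
    return expected_frequency(comp, motif) * comp.length


def round_half_away(value: float, ndigits: int = 0) -> float:
    """Round half away from zero (display convention for published tables)."""
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(value) * factor + 0.5), value) / factor


@dataclass(frozen=True)
class MotifStat:
    """Observed/expected statistics for one motif in one genome."""

    genome_id: str
    motif: str
    length: int
    observed_count: int
    observed_frequency: float
    expected_frequency: float
    expected_count: float
    relative_frequency: float  # NaN when undefined (expected and observed both 0)

    @property
    def defined(self) -> bool:
        """False when the composition admits no occurrences and none were seen."""
        return not math.isnan(self.relative_frequency)

    @property
    def expected_count_rounded(self) -> int:
        return int(round_half_away(self.expected_count))

    @property
    def relative_frequency_2dp(self) -> float:
        return round_half_away(self.relative_frequency, 2)


def relative_frequency(record: GenomeRecord | str, motif: str = "ACA") -> MotifStat:
    """Compute the full motif statistic for one genome.

    Observed frequency is ``n / (L - k + 1)``; expected frequency comes from
    :func:`expected_frequency`; their ratio is the relative frequency, the
    avoidance statistic (values below 1 indicate underrepresentation).

    Raises ``ValueError`` for the impossible case of a zero expected frequency
    with a positive observed count.
    """
    if isinstance(record, GenomeRecord):
        genome_id, sequence = record.id, record.sequence
    else:
        genome_id, sequence = "<sequence>", record
    k = len(motif)
    codes = encode(sequence)
    if codes.size <= k:
        raise ValueError(f"genome {genome_id!r} is not longer than the motif")
    observed = count_motif(codes, motif)
    comp = base_fractions(codes)
    exp_freq = expected_frequency(comp, motif)
    obs_freq = observed / (codes.size - k + 1)
    if exp_freq == 0.0:
        if observed > 0:
            raise ValueError(
                f"impossible composition for {genome_id!r}: expected frequency is 0 "
                f"but {observed} occurrences of {motif!r} were observed"
            )
        rel = math.nan
    else:
        rel = obs_freq / exp_freq
    return MotifStat(
        genome_id=genome_id,
        motif=motif,
        length=codes.size,
        observed_count=observed,
        observed_frequency=obs_freq,
        expected_frequency=exp_freq,
        expected_count=exp_freq * codes.size,
        relative_frequency=rel,
    )


def motif_table(
    records: Iterable[GenomeRecord], motifs: Sequence[str] = ("ACA",)
) -> pd.DataFrame:
    """Per-genome, per-motif statistics as a tidy table (one row each)."""
    rows = []
    for rec in records:
        for motif in motifs:
            stat = relative_frequency(rec, motif)
            rows.append(
                {
                    "genome_id": stat.genome_id,
                    "motif": stat.motif,
                    "length": stat.length,
                    "observed_count": stat.observed_count,
                    "expected_count": stat.expected_count,
                    "observed_frequency": stat.observed_frequency,
                    "expected_frequency": stat.expected_frequency,
                    "relative_frequency": stat.relative_frequency,
                }
            )
    return pd.DataFrame(rows)
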