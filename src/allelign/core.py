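"""Domain model: chromosome/allele normalization and the canonical variant index.

Every dataset row is reduced to a :class:`VariantRecord` in which ``a1`` plays
the ALT/effect-allele role and ``a2`` the REF/other-allele role.  The canonical
index ``CHR:POS:REF:ALT`` is the unified identifier used to join variants
across datasets; its reverse (REF and ALT swapped) identifies the same site
with the opposite allele orientation.

Coordinates are 1-based throughout (VCF/.pvar/.bim convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .errors import MalformedIndex, UnrecognizedChromosome

__all__ = [
    "CHROMOSOMES",
    "VALID_ALLELES",
    "VariantRecord",
    "DatasetSpec",
    "normalize_chromosome",
    "normalize_chromosome_series",
    "chromosome_sort_key",
    "is_biallelic_snp",
    "biallelic_mask",
    "is_palindromic",
    "canonical_index",
    "canonical_index_series",
    "parse_index",
    "reverse_index",
]

#: Accepted chromosome codes, in natural sort order.
CHROMOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X", "Y", "MT")

VALID_ALLELES = frozenset("ACGT")

_CHROM_RANK = {c: i for i, c in enumerate(CHROMOSOMES)}

# alias → canonical code; lookups are done on upper-cased, "CHR"-stripped labels
_CHROM_ALIASES = {c: c for c in CHROMOSOMES}
_CHROM_ALIASES.update({"M": "MT", "MT": "MT", "23": "X", "24": "Y", "25": "MT"})

# A/T and C/G pairs are their own reverse complements; strand flips at these
# sites are undetectable from alleles alone and are only counted, not fixed.
_PALINDROMIC_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


def normalize_chromosome(label: object) -> str:
    """Normalize a free-text chromosome label to one of ``1``..``22``/X/Y/MT.

    Case- and ``chr``-prefix-insensitive: ``chr7``, ``7`` and ``Chr7`` all
    yield ``"7"``; ``chrM``, ``M`` and ``MT`` all yield ``"MT"``.

    Raises
    ------
    UnrecognizedChromosome
        For anything outside the alias set (contig names, empty labels, ...).
    """
    text = str(label).strip().upper()
    if text.startswith("CHR"):
        text = text[3:]
    try:
        return _CHROM_ALIASES[text]
    except KeyError:
        raise UnrecognizedChromosome(f"unrecognized chromosome label: {label!r}") from None


def normalize_chromosome_series(labels: pd.Series) -> pd.Series:
    """Vectorized :func:`normalize_chromosome` for a pandas Series."""
    stripped = labels.astype(str).str.strip().str.upper().str.removeprefix("CHR")
    out = stripped.map(_CHROM_ALIASES)
    if out.isna().any():
        bad = labels[out.isna()].iloc[0]
        raise UnrecognizedChromosome(f"unrecognized chromosome label: {bad!r}")
    return out


def chromosome_sort_key(code: str) -> int:
    """Rank of a normalized chromosome code in natural order (1..22, X, Y, MT)."""
    return _CHROM_RANK[code]


def is_biallelic_snp(a1: object, a2: object) -> bool:
    """True iff both alleles normalize to distinct single bases in {A,C,G,T}.

    Multi-character alleles (indels), ``-``/``I``/``D``/``*``/``.`` codes and
    monomorphic pairs all fail, which disqualifies the row from the biallelic
    SNP set.
    """
    u1, u2 = str(a1).strip().upper(), str(a2).strip().upper()
    return u1 in VALID_ALLELES and u2 in VALID_ALLELES and u1 != u2


def biallelic_mask(a1: pd.Series, a2: pd.Series) -> pd.Series:
    """Vectorized :func:`is_biallelic_snp` over upper-cased allele columns."""
    ok1 = a1.isin(VALID_ALLELES)
    ok2 = a2.isin(VALID_ALLELES)
    return ok1 & ok2 & (a1 != a2)


def is_palindromic(a1: str, a2: str) -> bool:
    """True for A/T and C/G allele pairs (ambiguous under strand flips)."""
    return (a1, a2) in _PALINDROMIC_PAIRS


@dataclass(frozen=True)
class VariantRecord:
    """One dataset row: a biallelic site with its allele orientation.

    ``a1`` is the dataset's ALT / effect allele, ``a2`` the REF / other
    allele.  ``stats`` optionally carries role-keyed summary statistics
    (``effect_size``, ``effect_allele_freq``, ``p_value``, ...).
    """

    chrom: str
    pos: int
    a1: str
    a2: str
    dataset_id: str = ""
    stats: Optional[Mapping[str, float]] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be a positive 1-based coordinate, got {self.pos}")
        if self.a1 == self.a2:
            raise ValueError(f"a1 and a2 must differ, got {self.a1}/{self.a2}")

    def swapped(self) -> "VariantRecord":
        """The same site with a1 and a2 exchanged (stats untouched)."""
        return replace(self, a1=self.a2, a2=self.a1)


@dataclass
class DatasetSpec:
    """Declarative description of one input file.

    For ``format="sumstats"`` the ``columns`` map assigns column names to the
    roles ``chrom``, ``pos``, ``id``, ``effect_allele``, ``other_allele``
    (mandatory) and ``effect_size``, ``effect_allele_freq``, ``p_value``
    (optional).  ``.pvar``/``.bim`` files have fixed layouts and ignore
    ``columns``.
    """

    path: str
    format: str  # one of {"sumstats", "pvar", "bim"}
    dataset_label: str
    columns: Mapping[str, str] = field(default_factory=dict)
    effect_scale: str = "none"  # one of {"beta", "odds_ratio", "none"}
    delimiter: str = "\t"

    def __post_init__(self) -> None:
        if self.format not in {"sumstats", "pvar", "bim"}:
            raise ValueError(f"unknown format {self.format!r}")
        if self.effect_scale not in {"beta", "odds_ratio", "none"}:
            raise ValueError(f"unknown effect_scale {self.effect_scale!r}")


def canonical_index(rec: VariantRecord) -> str:
    """``CHR:POS:REF:ALT`` with REF = ``a2`` and ALT = ``a1``."""
    return f"{rec.chrom}:{rec.pos}:{rec.a2}:{rec.a1}"


def canonical_index_series(df: pd.DataFrame) -> pd.Series:
    """Canonical index strings for a frame with chrom/pos/a1/a2 columns."""
    return (
        df["chrom"].astype(str)
        + ":"
        + df["pos"].astype(np.int64).astype(str)
        + ":"
        + df["a2"]
        + ":"
        + df["a1"]
    )


def _split_index(text: str) -> tuple[str, str, str, str]:
    parts = str(text).split(":")
    if len(parts) != 4:
        raise MalformedIndex(
            f"expected CHR:POS:REF:ALT with exactly 3 colons, got {text!r}"
        )
    return parts[0], parts[1], parts[2], parts[3]


def parse_index(text: str) -> VariantRecord:
    """Parse a ``CHR:POS:REF:ALT`` string back into a :class:`VariantRecord`.

    Round-trips: ``canonical_index(parse_index(s)) == s`` for valid ``s``.
    """
    chrom, pos, ref, alt = _split_index(text)
    try:
        position = int(pos)
    except ValueError:
        raise MalformedIndex(f"non-integer position in index {text!r}") from None
    return VariantRecord(
        chrom=normalize_chromosome(chrom),
        pos=position,
        a1=alt,
        a2=ref,
        dataset_id=text,
    )


def reverse_index(idx: str) -> str:
    """Swap the REF and ALT fields of a canonical index (an involution)."""
    chrom, pos, ref, alt = _split_index(idx)
    return f"{chrom}:{pos}:{alt}:{ref}"
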