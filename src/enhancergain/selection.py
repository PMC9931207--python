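"""Direction-of-selection (DoS) statistic and derived-allele-frequency tests.

DoS = Dn/(Dn+Ds) - Pn/(Pn+Ps) contrasts the fixed-site fraction of a
foreground mutation class (e.g. essential mutations in de novo gained
enhancers) against a neutral background (mutated fourfold-degenerate
sites). Positive values indicate adaptive evolution, zero neutrality, and
negative values segregating slightly deleterious variation. Fixed versus
polymorphic status is an input column: the statistic layer does not
re-derive it from population data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from scipy import stats

from .intervals import reverse_complement

__all__ = [
    "MKTable",
    "ClassifiedSite",
    "fourfold_sites",
    "build_mk_table",
    "dos",
    "daf_compare",
    "SITE_CLASSES",
]

SITE_CLASSES = (
    "essential",
    "nonessential_gained",
    "preserved_enhancer",
    "fourfold_background",
)

# third-position fourfold-degenerate codon families of the standard code
_STANDARD_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


@dataclass(frozen=True)
class MKTable:
    """Fixed/polymorphic contingency: Dn, Ds fixed; Pn, Ps polymorphic."""

    Dn: int
    Ds: int
    Pn: int
    Ps: int

    def __post_init__(self) -> None:
        if min(self.Dn, self.Ds, self.Pn, self.Ps) < 0:
            raise ValueError("all MK counts must be nonnegative")


@dataclass(frozen=True)
class ClassifiedSite:
    site_class: str
    fixed: bool
    daf: float | None = None

    def __post_init__(self) -> None:
        if self.fixed and self.daf is not None:
            raise ValueError("fixed sites carry no derived allele frequency")
        if not self.fixed and self.daf is None:
            raise ValueError("polymorphic sites require a derived allele frequency")
        if self.daf is not None and not 0.0 <= self.daf <= 1.0:
            raise ValueError("daf must be in [0, 1]")


def fourfold_sites(
    cds_seq: str,
    frame: int = 0,
    strand: str = "+",
    genetic_code: dict | None = None,
) -> list[int]:
    """Fourfold-degenerate third-codon positions of a CDS.

    Positions are 0-based offsets in the supplied (forward-strand) sequence.
    Minus-strand CDSs are reverse complemented before codon reading and the
    positions mapped back. Internal stop codons warn but do not abort.
    """
    code = _STANDARD_TABLE if genetic_code is None else genetic_code
    seq = cds_seq.upper()[frame:]
    if len(seq) % 3 != 0:
        raise ValueError("CDS length (after frame offset) must be divisible by 3")
    read = reverse_complement(seq) if strand == "-" else seq
    positions: list[int] = []
    n = len(read)
    for start in range(0, n, 3):
        codon = read[start : start + 3]
        if any(b not in "ACGT" for b in codon):
            continue
        aa = code.get(codon)
        if aa == "*" and start + 3 < n:
            warnings.warn(f"internal stop codon at offset {start}", stacklevel=2)
        family = {code.get(codon[:2] + b) for b in "ACGT"}
        if len(family) == 1 and None not in family:
            third = start + 2
            pos = (n - 1 - third) if strand == "-" else third
            positions.append(pos + frame if strand == "+" else pos + frame)
    return sorted(positions)


def build_mk_table(
    sites: Sequence[ClassifiedSite],
    foreground_class: str,
    background_class: str = "fourfold_background",
) -> MKTable:
    """Count fixed/polymorphic sites of the two classes into an MKTable."""
    if foreground_class == background_class:
        raise ValueError("foreground and background classes must differ")
    fg = [s for s in sites if s.site_class == foreground_class]
    bg = [s for s in sites if s.site_class == background_class]
    for name, group in (("foreground", fg), ("background", bg)):
        if not group:
            raise ValueError(
                f"{name} class "
                f"{foreground_class if name == 'foreground' else background_class!r} "
                "has no sites"
            )
    return MKTable(
        Dn=sum(s.fixed for s in fg),
        Ds=sum(s.fixed for s in bg),
        Pn=sum(not s.fixed for s in fg),
        Ps=sum(not s.fixed for s in bg),
    )


def dos(table: MKTable) -> float:
    """Direction of selection: Dn/(Dn+Ds) - Pn/(Pn+Ps), in [-1, 1]."""
    d_margin = table.Dn + table.Ds
    p_margin = table.Pn + table.Ps
    if d_margin == 0 or p_margin == 0:
        raise ValueError(
            "DoS undefined: need at least one fixed and one polymorphic site"
        )
    return table.Dn / d_margin - table.Pn / p_margin


def daf_compare(
    daf_a: Sequence[float],
    daf_b: Sequence[float],
    alternative: str = "two-sided",
    exact_max_n: int = 20,
) -> tuple[float, float]:
    """Mann-Whitney comparison of two derived-allele-frequency samples.

    Exact null distribution for small samples (combined n <= ``exact_max_n``
    and no ties), normal approximation with tie correction otherwise.
    Returns (U statistic, p value).
    """
    a, b = list(daf_a), list(daf_b)
    if not a or not b:
        raise ValueError("both samples must be non-empty")
    method = "exact" if len(a) + len(b) <= exact_max_n else "asymptotic"
    try:
        res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    except ValueError:
        # exact method refuses ties; fall back to the corrected approximation
        res = stats.mannwhitneyu(a, b, alternative=alternative, method="asymptotic")
    return float(res.statistic), float(res.pvalue)
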