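"""Ortholog pairing, mutation extraction and trio-based status calls.

An enhancer is called *de novo gained* when the human sequence carries an
H3K27ac peak and scores as active while both the macaque ortholog and the
reconstructed human-macaque ancestral sequence score inactive and macaque
shows no peak; *lost* is the mirror image; *conserved* requires peaks in
both species and active scores for all three sequences. Ortholog pairs are
retained only when reciprocal and within 50 bp of each other in length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

from .intervals import GenomicInterval

__all__ = [
    "OrthologPair",
    "MutationSite",
    "StatusCall",
    "pair_orthologs",
    "extract_mutations",
    "classify_status",
    "activity_preserved",
    "MAX_LENGTH_DIFF",
]

MAX_LENGTH_DIFF = 50

_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class MutationSite:
    """A single human-macaque substitution in an aligned ortholog pair."""

    position: int
    human_allele: str
    macaque_allele: str
    ancestor_allele: str | None = None
    is_polymorphic: bool = False
    derived_allele_frequency: float | None = None

    def __post_init__(self) -> None:
        if self.human_allele == self.macaque_allele:
            raise ValueError("human and macaque alleles must differ")
        for a in (self.human_allele, self.macaque_allele):
            if a not in _BASES:
                raise ValueError(f"allele {a!r} not in ACGT")


@dataclass
class OrthologPair:
    human_interval: GenomicInterval
    macaque_interval: GenomicInterval
    human_seq: str = ""
    macaque_seq: str = ""
    ancestor_seq: str | None = None
    reciprocal: bool = True

    @property
    def length_diff(self) -> int:
        return abs(self.human_interval.width - self.macaque_interval.width)


@dataclass(frozen=True)
class StatusCall:
    status: str  # gained | lost | conserved | ambiguous | unmapped
    scores: tuple[float, float, float | None]
    peaks: tuple[bool, bool]


def _key(iv: GenomicInterval) -> tuple[str, int, int]:
    return (iv.chrom, iv.start, iv.end)


def pair_orthologs(
    forward: Sequence[tuple[GenomicInterval, GenomicInterval]],
    reverse: Sequence[tuple[GenomicInterval, GenomicInterval]],
    max_length_diff: int = MAX_LENGTH_DIFF,
) -> tuple[list[OrthologPair], list[GenomicInterval]]:
    """Keep reciprocal human/macaque pairs within the length-difference cap.

    ``forward`` maps human -> macaque intervals, ``reverse`` macaque ->
    human. A pair is reciprocal when the reverse map sends the macaque
    interval back to the same human interval. Intervals with conflicting
    duplicate mappings are dropped with a warning. Returns (pairs,
    unmapped_human_intervals).
    """
    fwd: dict[tuple, GenomicInterval] = {}
    fwd_conflicts: set[tuple] = set()
    for h, m in forward:
        k = _key(h)
        if k in fwd and _key(fwd[k]) != _key(m):
            fwd_conflicts.add(k)
        fwd[k] = m
    rev: dict[tuple, GenomicInterval] = {}
    rev_conflicts: set[tuple] = set()
    for m, h in reverse:
        k = _key(m)
        if k in rev and _key(rev[k]) != _key(h):
            rev_conflicts.add(k)
        rev[k] = h
    if fwd_conflicts or rev_conflicts:
        warnings.warn(
            f"dropped {len(fwd_conflicts)} forward and {len(rev_conflicts)} "
            "reverse conflicting duplicate mappings",
            stacklevel=2,
        )

    pairs: list[OrthologPair] = []
    unmapped: list[GenomicInterval] = []
    for h, m in forward:
        hk, mk = _key(h), _key(m)
        if hk in fwd_conflicts or mk in rev_conflicts:
            unmapped.append(h)
            continue
        back = rev.get(mk)
        if back is None or _key(back) != hk:
            unmapped.append(h)
            continue
        pair = OrthologPair(human_interval=h, macaque_interval=m)
        if pair.length_diff > max_length_diff:
            unmapped.append(h)
            continue
        pairs.append(pair)
    return pairs, unmapped


def extract_mutations(
    human_seq: str,
    macaque_seq: str,
    ancestor_seq: str | None = None,
) -> list[MutationSite]:
    """One MutationSite per substitution column of an aligned pair.

    Sequences must be equal length (alignment gaps as '-'); gap columns and
    ambiguous bases yield no site. Positions are alignment-column offsets.
    """
    if len(human_seq) != len(macaque_seq):
        raise ValueError("aligned sequences must have equal length")
    if ancestor_seq is not None and len(ancestor_seq) != len(human_seq):
        raise ValueError("ancestor sequence length must match the alignment")
    sites: list[MutationSite] = []
    for i, (h, m) in enumerate(zip(human_seq.upper(), macaque_seq.upper())):
        if h == m or h not in _BASES or m not in _BASES:
            continue
        anc = None
        if ancestor_seq is not None:
            a = ancestor_seq[i].upper()
            anc = a if a in _BASES else None
        sites.append(
            MutationSite(position=i, human_allele=h, macaque_allele=m,
                         ancestor_allele=anc)
        )
    return sites


def classify_status(
    human_peak: bool,
    macaque_peak: bool,
    s_h: float,
    s_m: float,
    s_a: float | None,
    thr,
) -> StatusCall:
    """Trio status call from peak evidence and activity scores.

    gained:    human peak + active human score, no macaque peak, inactive
               macaque and ancestor scores.
    lost:      macaque peak + active macaque and ancestor scores, no human
               peak, inactive human score.
    conserved: peaks in both species and all three scores active.
    Pairs without an ancestor score cannot be polarized -> ambiguous.
    """
    t = getattr(thr, "value", thr)
    if s_a is None:
        return StatusCall("ambiguous", (s_h, s_m, None), (human_peak, macaque_peak))
    if human_peak and s_h >= t and not macaque_peak and s_m < t and s_a < t:
        status = "gained"
    elif macaque_peak and s_m >= t and s_a >= t and not human_peak and s_h < t:
        status = "lost"
    elif human_peak and macaque_peak and min(s_h, s_m, s_a) >= t:
        status = "conserved"
    else:
        status = "ambiguous"
    return StatusCall(status, (s_h, s_m, s_a), (human_peak, macaque_peak))


def activity_preserved(h_signal: float, m_signal: float, max_ratio: float = 1.2) -> bool:
    """True when H3K27ac signal differs by at most ``max_ratio``-fold."""
    if h_signal <= 0 or m_signal <= 0:
        raise ValueError("signals must be positive")
    return max(h_signal / m_signal, m_signal / h_signal) <= max_ratio
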