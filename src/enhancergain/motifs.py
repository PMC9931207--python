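"""Position-weight-matrix scanning, threshold calibration and TF-role calls.

A PWM is scanned by log-odds (base 2) against a background base composition,
on both strands. Hit thresholds are calibrated empirically on random
background sequence so that the expected false-positive burden does not
exceed a target rate (default five hits per 10 kb, both strands counted).
TFs are classified as activators or repressors from the ratio of binding-site
gains to losses caused by essential mutations relative to the same ratio for
common SNPs (1.2-fold rule).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .intervals import reverse_complement

__all__ = [
    "PWM",
    "PWMScorer",
    "MotifHit",
    "TFRoleCall",
    "pwm_from_consensus",
    "read_meme",
    "write_meme",
    "window_scores",
    "scan",
    "calibrate_pwm_threshold",
    "motif_enrichment",
    "site_gain_loss",
    "classify_tf_role",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_PSEUDOCOUNT = 1e-3


def encode(seq: str) -> np.ndarray:
    """Integer-encode ACGT (other letters -> 4)."""
    table = np.full(128, 4, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class PWM:
    """Probabilistic motif model with a calibrated log-odds hit threshold."""

    name: str
    matrix: np.ndarray  # (width, 4) per-position base probabilities
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    threshold: float | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be (width, 4)")
        if self.width < 4:
            raise ValueError("PWM width must be >= 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM rows must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """(width, 5) base-2 log-odds; column 4 (ambiguous base) scores 0."""
        p = self.matrix + _PSEUDOCOUNT
        p /= p.sum(axis=1, keepdims=True)
        bg = self.background + _PSEUDOCOUNT
        bg /= bg.sum()
        lo = np.log2(p / bg)
        return np.hstack([lo, np.zeros((self.width, 1))])

    @property
    def max_score(self) -> float:
        return float(self.log_odds[:, :4].max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))

    def max_info_position(self) -> int:
        """Position with the highest information content (ties: leftmost)."""
        p = self.matrix + _PSEUDOCOUNT
        p /= p.sum(axis=1, keepdims=True)
        info = 2.0 + (p * np.log2(p)).sum(axis=1)
        return int(info.argmax())

    def with_threshold(self, threshold: float) -> "PWM":
        return replace(self, threshold=threshold)


@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    offset: int
    strand: str
    log_odds_score: float


@dataclass(frozen=True)
class TFRoleCall:
    tf_name: str
    gain_count_essential: int
    loss_count_essential: int
    gain_count_snp: int
    loss_count_snp: int
    role: str


@dataclass
class PWMScorer:
    """Sequence-to-activity scorer driven by a single calibrated PWM.

    The score is a logistic transform of the best window log-odds (both
    strands) centred on the PWM threshold, so score >= 0.5 holds exactly
    when the motif scan reports at least one hit. Serves as a transparent,
    independently checkable stand-in for the trained network.
    """

    pwm: PWM
    slope: float = 1.0

    def __post_init__(self) -> None:
        if self.pwm.threshold is None:
            raise ValueError("PWMScorer requires a calibrated PWM threshold")

    @property
    def activity_threshold(self) -> float:
        return 0.5

    def score(self, sequence: str) -> float:
        fwd, rev = window_scores(sequence, self.pwm)
        if fwd.size == 0:
            return 0.0
        best = float(max(fwd.max(), rev.max()))
        return float(1.0 / (1.0 + math.exp(-self.slope * (best - self.pwm.threshold))))


def pwm_from_consensus(
    name: str, consensus: str, p_major: float = 0.97,
    background: Sequence[float] | None = None,
) -> PWM:
    """Sharp PWM placing probability ``p_major`` on each consensus base."""
    consensus = consensus.upper()
    w = len(consensus)
    mat = np.full((w, 4), (1.0 - p_major) / 3.0)
    for i, b in enumerate(consensus):
        mat[i, _BASE_INDEX[b]] = p_major
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    return PWM(name, mat, bg)


def read_meme(path) -> list[PWM]:
    """Parse a minimal MEME motif file (letter-probability matrices)."""
    pwms: list[PWM] = []
    background = np.full(4, 0.25)
    with open(path) as fh:
        lines = iter(fh.read().splitlines())
    name = None
    rows: list[list[float]] = []
    expect_bg = False
    for line in lines:
        stripped = line.strip()
        if stripped.lower().startswith("background letter frequencies"):
            expect_bg = True
            continue
        if expect_bg and stripped:
            toks = stripped.split()
            freq = {toks[i]: float(toks[i + 1]) for i in range(0, len(toks) - 1, 2)}
            background = np.array([freq.get(b, 0.25) for b in BASES])
            expect_bg = False
            continue
        if stripped.startswith("MOTIF"):
            if name is not None and rows:
                pwms.append(PWM(name, np.array(rows), background))
            name = stripped.split()[1]
            rows = []
            continue
        if name is not None:
            toks = stripped.split()
            if len(toks) == 4:
                try:
                    rows.append([float(t) for t in toks])
                except ValueError:
                    pass
    if name is not None and rows:
        pwms.append(PWM(name, np.array(rows), background))
    return pwms


def write_meme(path, pwms: Iterable[PWM]) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        fh.write("Background letter frequencies\n")
        first = next(iter(pwms), None)
        bg = first.background if first is not None else np.full(4, 0.25)
        fh.write(" ".join(f"{b} {f:.5f}" for b, f in zip(BASES, bg)) + "\n\n")
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.width}\n"
            )
            for row in pwm.matrix:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


def window_scores(seq: str, pwm: PWM) -> tuple[np.ndarray, np.ndarray]:
    """Forward- and reverse-strand log-odds scores for every window.

    Both arrays are indexed by the window's 0-based offset on the forward
    sequence; the reverse score at offset i is the score of the reverse
    complement of seq[i:i+w].
    """
    codes = encode(seq)
    w = pwm.width
    n = len(codes) - w + 1
    if n <= 0:
        return np.empty(0), np.empty(0)
    lo = pwm.log_odds
    fwd = np.zeros(n)
    rev = np.zeros(n)
    # reverse-complement log-odds: position j of the RC window reads the
    # complement of forward position w-1-j
    comp = np.array([3, 2, 1, 0, 4])
    lo_rc = lo[::-1][:, comp]
    for j in range(w):
        col = codes[j : j + n]
        fwd += lo[j, col]
        rev += lo_rc[j, col]
    return fwd, rev


def scan(seq: str, pwm: PWM, sequence_id: str = "", threshold: float | None = None) -> list[MotifHit]:
    """All windows (both strands) scoring at or above the PWM threshold."""
    thr = pwm.threshold if threshold is None else threshold
    if thr is None:
        raise ValueError(f"PWM {pwm.name!r} has no calibrated threshold")
    fwd, rev = window_scores(seq, pwm)
    hits = [
        MotifHit(sequence_id, int(i), "+", float(s))
        for i, s in enumerate(fwd)
        if s >= thr
    ]
    hits += [
        MotifHit(sequence_id, int(i), "-", float(s))
        for i, s in enumerate(rev)
        if s >= thr
    ]
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def calibrate_pwm_threshold(
    pwm: PWM,
    random_seqs: Sequence[str],
    max_fp_per_10kb: float = 5.0,
) -> float:
    """Smallest log-odds cutoff with <= ``max_fp_per_10kb`` hits per 10 kb.

    Hits are counted on both strands of the supplied background sequences.
    If even the maximum observed score exceeds the budget (degenerate,
    information-free motifs), a cutoff just above the maximum achievable
    score is returned so that nothing passes.
    """
    total_bp = sum(len(s) for s in random_seqs)
    if total_bp == 0 or all(len(s) < pwm.width for s in random_seqs):
        raise ValueError("background sequences shorter than the motif")
    if total_bp < 100_000:
        warnings.warn(
            f"PWM calibration on only {total_bp} bp of background "
            "(>= 100 kb recommended)",
            stacklevel=2,
        )
    scores = []
    for s in random_seqs:
        fwd, rev = window_scores(s, pwm)
        scores.append(fwd)
        scores.append(rev)
    all_scores = np.sort(np.concatenate(scores))
    max_hits = math.floor(max_fp_per_10kb * total_bp / 10_000.0)
    n = all_scores.size
    # smallest observed score whose >=-tail (ties included) fits the budget
    for cand in np.unique(all_scores):
        count_ge = n - np.searchsorted(all_scores, cand, side="left")
        if count_ge <= max_hits:
            return float(cand)
    return float(np.nextafter(max(all_scores[-1], pwm.max_score), np.inf))


def motif_enrichment(
    fg_seqs: Sequence[str], bg_seqs: Sequence[str], pwm: PWM
) -> tuple[float, float]:
    """Region-level motif enrichment: odds ratio and Fisher exact p.

    The 2x2 table counts regions with vs without at least one hit in the
    foreground and background sets.
    """
    if not fg_seqs or not bg_seqs:
        raise ValueError("foreground and background sets must be non-empty")
    fg_hit = sum(1 for s in fg_seqs if scan(s, pwm))
    bg_hit = sum(1 for s in bg_seqs if scan(s, pwm))
    table = [
        [fg_hit, len(fg_seqs) - fg_hit],
        [bg_hit, len(bg_seqs) - bg_hit],
    ]
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)


def site_gain_loss(
    macaque_seq: str,
    position: int,
    human_allele: str,
    macaque_allele: str,
    pwm: PWM,
) -> str:
    """Classify a substitution's effect on this motif: gain, loss or neutral.

    A gain means a hit overlapping ``position`` exists with the human allele
    but not with the macaque allele; a loss is the converse.
    """
    if not 0 <= position < len(macaque_seq):
        raise IndexError("position outside sequence")
    if macaque_seq[position].upper() != macaque_allele.upper():
        raise ValueError("macaque_allele does not match the sequence")
    human_seq = macaque_seq[:position] + human_allele.upper() + macaque_seq[position + 1 :]

    def overlapping_hit(seq: str) -> bool:
        return any(
            h.offset <= position < h.offset + pwm.width for h in scan(seq, pwm)
        )

    h_hit = overlapping_hit(human_seq)
    m_hit = overlapping_hit(macaque_seq)
    if h_hit and not m_hit:
        return "gain"
    if m_hit and not h_hit:
        return "loss"
    return "neutral"


def classify_tf_role(
    tf_name: str,
    gain_essential: int,
    loss_essential: int,
    gain_snp: int,
    loss_snp: int,
    fold: float = 1.2,
    pseudocount: float = 0.5,
) -> TFRoleCall:
    """Activator/repressor call from gain:loss ratios (1.2-fold rule).

    The gain/loss ratio caused by essential mutations is compared with the
    ratio caused by common SNPs; exceeding ``fold`` times the SNP ratio in
    the gain (loss) direction marks an activator (repressor). A Haldane-
    Anscombe pseudocount keeps ratios finite at zero counts.
    """
    for c in (gain_essential, loss_essential, gain_snp, loss_snp):
        if c < 0:
            raise ValueError("counts must be nonnegative")
    ge, le = gain_essential + pseudocount, loss_essential + pseudocount
    gs, ls = gain_snp + pseudocount, loss_snp + pseudocount
    gain_ratio_e, gain_ratio_s = ge / le, gs / ls
    loss_ratio_e, loss_ratio_s = le / ge, ls / gs
    if gain_ratio_e > fold * gain_ratio_s:
        role = "activator"
    elif loss_ratio_e > fold * loss_ratio_s:
        role = "repressor"
    else:
        role = "undetermined"
    return TFRoleCall(
        tf_name, gain_essential, loss_essential, gain_snp, loss_snp, role
    )
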