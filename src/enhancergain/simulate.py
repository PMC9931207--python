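"""Ground-truthed synthetic data with the statistical structure the
analysis assumes.

The generator emulates, at desk scale, the data the comparative pipeline
consumes: human/macaque/ancestor sequence trios with ~50 substitutions per
kb whose enhancer status (gained, lost, conserved, neutral) is created or
destroyed by designated single-base *essential* substitutions at a planted
activator motif's most informative position; binomially sampled allele
read counts at heterozygous sites with a configurable imbalance ratio;
fixed/polymorphic site tables for the direction-of-selection statistic;
and TF expression matrices with positive latent correlation along planted
regulatory edges.

Every output is a pure function of ``SimConfig.seed``: each operation draws
from its own fixed substream of the seed, so regenerated files are
byte-identical.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .comparative import MutationSite
from .motifs import BASES, PWM, pwm_from_consensus, scan
from .network import RegulatoryEdge

__all__ = [
    "SimConfig",
    "TrioTruth",
    "default_activator_pwm",
    "default_repressor_pwm",
    "random_sequence",
    "simulate_trio",
    "simulate_trios",
    "simulate_het_reads",
    "simulate_mk_sites",
    "simulate_expression",
    "generate_dataset",
]

TRIO_STATUSES = ("gained", "lost", "conserved", "neutral")

# fixed substream tags: one RNG stream per operation, derived from the seed
_STREAM_TRIO = 11
_STREAM_READS = 12
_STREAM_MK = 13
_STREAM_EXPR = 14
_STREAM_SIGNAL = 15


def default_activator_pwm(threshold_frac: float = 0.8) -> PWM:
    """Sharp 10-bp activator motif with a fixed log-odds cutoff."""
    pwm = pwm_from_consensus("ACT_A", "TGACGTCATC", p_major=0.97)
    return pwm.with_threshold(threshold_frac * pwm.max_score)


def default_repressor_pwm(threshold_frac: float = 0.8) -> PWM:
    pwm = pwm_from_consensus("REP_A", "CCGGAAGTGC", p_major=0.97)
    return pwm.with_threshold(threshold_frac * pwm.max_score)


@dataclass
class SimConfig:
    """Study conditions for the synthetic data.

    ``substitution_rate`` is the mean number of human-macaque substitutions
    per kb of enhancer (the observed density in both gained and conserved
    enhancers is ~50/kb). ``read_depth`` is the mean total read count per
    heterozygous site and ``imbalance_ratio`` the human:macaque allele rate
    ratio r, reads drawn Binomial(depth, r/(1+r)).
    """

    seed: int = 0
    n_enhancers: int = 100
    enhancer_len: int = 1000
    n_background: int = 100
    substitution_rate: float = 50.0
    activator_pwms: tuple[PWM, ...] = field(
        default_factory=lambda: (default_activator_pwm(),)
    )
    repressor_pwms: tuple[PWM, ...] = field(
        default_factory=lambda: (default_repressor_pwm(),)
    )
    planted_gain_fraction: float = 0.5
    read_depth: float = 30.0
    imbalance_ratio: float = 1.0
    signal_log_sd: float = 0.5  # log-normal noise on peak signal (stand-in)

    def __post_init__(self) -> None:
        if self.substitution_rate < 0:
            raise ValueError("substitution_rate must be >= 0")
        if not 0.0 <= self.planted_gain_fraction <= 1.0:
            raise ValueError("planted_gain_fraction must be in [0, 1]")
        if self.imbalance_ratio < 1.0:
            raise ValueError("imbalance_ratio must be >= 1")
        if self.read_depth < 0:
            raise ValueError("read_depth must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        """Load study conditions from a YAML file (scalar fields only;
        PWMs keep their defaults)."""
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        allowed = {
            "seed", "n_enhancers", "enhancer_len", "n_background",
            "substitution_rate", "planted_gain_fraction", "read_depth",
            "imbalance_ratio", "signal_log_sd",
        }
        unknown = set(raw) - allowed
        if unknown:
            raise ValueError(f"unknown SimConfig fields: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class TrioTruth:
    """One simulated enhancer trio and its ground truth."""

    ancestor_seq: str
    human_seq: str
    macaque_seq: str
    mutations: list[MutationSite]
    essential_positions: frozenset[int]
    intended_status: str
    human_peak: bool
    macaque_peak: bool
    motif_window: tuple[int, int] | None = None
    human_signal: float = 0.0
    macaque_signal: float = 0.0


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(BASES))[rng.integers(0, 4, size=length)])


def _worst_base(pwm: PWM, row: int, exclude: str) -> str:
    order = np.argsort(pwm.matrix[row])
    for idx in order:
        if BASES[idx] != exclude:
            return BASES[idx]
    raise AssertionError("unreachable")


def _clear_hits(seq: str, pwm: PWM, rng: np.random.Generator, max_iter: int = 50) -> str:
    """Destroy all motif hits by mutating each hit's most informative base."""
    key = pwm.max_info_position()
    for _ in range(max_iter):
        hits = scan(seq, pwm)
        if not hits:
            return seq
        chars = list(seq)
        for h in hits:
            pos = h.offset + (key if h.strand == "+" else pwm.width - 1 - key)
            current = chars[pos]
            choices = [b for b in BASES if b != current]
            chars[pos] = choices[rng.integers(0, 3)]
        seq = "".join(chars)
    raise RuntimeError("could not clear motif hits from background sequence")


def simulate_trio(config: SimConfig, status: str, index: int = 0) -> TrioTruth:
    """Generate one ancestor/human/macaque trio with known ground truth.

    gained:    activator motif absent from ancestor and macaque, created in
               human by a single essential substitution at the motif's most
               informative position.
    lost:      motif present in ancestor and macaque, destroyed in human by
               the essential substitution.
    conserved: motif present in all three.
    neutral:   no planted motif anywhere.

    All substitutions lie on the human branch (macaque retains the
    ancestral allele), and their total count is Poisson with mean
    ``substitution_rate`` per kb. Neutral substitutions are re-drawn if
    they accidentally create or destroy motif hits, so planted ground
    truth is exact.
    """
    if status not in TRIO_STATUSES:
        raise ValueError(f"unknown status {status!r}")
    if status != "neutral" and not config.activator_pwms:
        raise ValueError("activator PWM required for non-neutral trios")
    length = config.enhancer_len
    pwm = config.activator_pwms[0] if config.activator_pwms else None
    if pwm is not None and pwm.width > length:
        raise ValueError("motif longer than the enhancer sequence")
    rng = np.random.default_rng(
        [config.seed, _STREAM_TRIO, index, TRIO_STATUSES.index(status)]
    )
    sig_rng = np.random.default_rng([config.seed, _STREAM_SIGNAL, index])

    for _attempt in range(100):
        ancestor = random_sequence(rng, length)
        if pwm is not None:
            ancestor = _clear_hits(ancestor, pwm, rng)
        essential: set[int] = set()
        motif_window = None
        if status in ("gained", "lost", "conserved"):
            offset = int(rng.integers(0, length - pwm.width + 1))
            motif_window = (offset, offset + pwm.width)
            key_local = pwm.max_info_position()
            key = offset + key_local
            consensus = pwm.consensus
            broken = _worst_base(pwm, key_local, exclude=consensus[key_local])
            chars = list(ancestor)
            chars[offset : offset + pwm.width] = list(consensus)
            if status == "gained":
                chars[key] = broken  # motif incomplete in the ancestor
            anc_planted = "".join(chars)
            anc_hits = scan(anc_planted, pwm)
            if status == "gained" and anc_hits:
                continue  # broken instance still matched; re-draw
            if status in ("lost", "conserved") and not anc_hits:
                continue
            ancestor = anc_planted
        macaque = ancestor

        n_mut = int(rng.poisson(config.substitution_rate * length / 1000.0))
        human_chars = list(ancestor)
        if status == "gained":
            human_chars[key] = pwm.consensus[key_local]
            essential = {key}
            n_neutral = max(n_mut - 1, 0)
        elif status == "lost":
            human_chars[key] = broken
            essential = {key}
            n_neutral = max(n_mut - 1, 0)
        else:
            n_neutral = n_mut

        forbidden = set(range(*motif_window)) if motif_window else set()
        candidates = np.array(
            sorted(set(range(length)) - forbidden - essential), dtype=int
        )
        ok = False
        for _retry in range(50):
            trial = list(human_chars)
            if n_neutral > 0:
                pos = rng.choice(candidates, size=min(n_neutral, candidates.size),
                                 replace=False)
                for p in pos:
                    alts = [b for b in BASES if b != ancestor[p]]
                    trial[p] = alts[rng.integers(0, 3)]
            human = "".join(trial)
            if pwm is None:
                ok = True
                break
            hits = scan(human, pwm)
            if status in ("gained", "conserved"):
                in_window = [
                    h for h in hits
                    if motif_window[0] < h.offset + pwm.width
                    and h.offset < motif_window[1]
                ]
                ok = len(in_window) >= 1 and len(in_window) == len(hits)
            else:
                ok = len(hits) == 0
            if ok:
                break
        if not ok:
            continue

        mutations = [
            MutationSite(
                position=i,
                human_allele=human[i],
                macaque_allele=macaque[i],
                ancestor_allele=ancestor[i],
            )
            for i in range(length)
            if human[i] != macaque[i]
        ]
        human_peak = status in ("gained", "conserved")
        macaque_peak = status in ("lost", "conserved")
        base_signal = 10.0
        h_sig = (
            base_signal * float(np.exp(sig_rng.normal(0.0, config.signal_log_sd)))
            if human_peak
            else 0.0
        )
        m_sig = (
            base_signal * float(np.exp(sig_rng.normal(0.0, config.signal_log_sd)))
            if macaque_peak
            else 0.0
        )
        return TrioTruth(
            ancestor_seq=ancestor,
            human_seq=human,
            macaque_seq=macaque,
            mutations=mutations,
            essential_positions=frozenset(essential),
            intended_status=status,
            human_peak=human_peak,
            macaque_peak=macaque_peak,
            motif_window=motif_window,
            human_signal=h_sig,
            macaque_signal=m_sig,
        )
    raise RuntimeError(f"failed to construct a {status} trio; check the PWM config")


def simulate_trios(
    config: SimConfig, statuses: Sequence[str] | None = None
) -> list[TrioTruth]:
    """A batch of trios; default status mix uses ``planted_gain_fraction``
    for gained and splits the remainder between conserved, lost and neutral."""
    if statuses is None:
        n = config.n_enhancers
        n_gain = int(round(config.planted_gain_fraction * n))
        rest = n - n_gain
        n_cons = rest // 3
        n_lost = rest // 3
        n_neut = rest - n_cons - n_lost
        statuses = (
            ["gained"] * n_gain
            + ["conserved"] * n_cons
            + ["lost"] * n_lost
            + ["neutral"] * n_neut
        )
    return [simulate_trio(config, s, index=i) for i, s in enumerate(statuses)]


def simulate_het_reads(
    config: SimConfig,
    n_sites: int,
    imbalanced_flags: Sequence[bool],
) -> pd.DataFrame:
    """Allele read counts at heterozygous sites.

    Flagged sites draw the human-allele count from Binomial(depth,
    r/(1+r)) with r = ``imbalance_ratio``; balanced sites use r = 1. The
    per-site depth is Poisson with mean ``read_depth``.
    """
    if config.read_depth <= 0:
        raise ValueError("read_depth must be positive to simulate reads")
    flags = np.asarray(imbalanced_flags, dtype=bool)
    if flags.size != n_sites:
        raise ValueError("imbalanced_flags must have length n_sites")
    rng = np.random.default_rng([config.seed, _STREAM_READS])
    depth = rng.poisson(config.read_depth, size=n_sites)
    r = np.where(flags, config.imbalance_ratio, 1.0)
    p = r / (1.0 + r)
    reads_h = rng.binomial(depth, p)
    return pd.DataFrame(
        {
            "site_id": [f"site_{i:06d}" for i in range(n_sites)],
            "imbalanced_truth": flags,
            "reads_h": reads_h,
            "reads_m": depth - reads_h,
        }
    )


def simulate_mk_sites(
    config: SimConfig,
    n_per_class: int | Mapping[str, int],
    fixed_fraction_per_class: Mapping[str, float],
    daf_beta: tuple[float, float] = (1.0, 3.0),
) -> pd.DataFrame:
    """Fixed/polymorphic site table per mutation class.

    Each site is fixed with its class's probability; polymorphic sites draw
    a derived allele frequency from Beta(*daf_beta*) (skewed to rare
    variants by default, as expected under drift).
    """
    for cls, frac in fixed_fraction_per_class.items():
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"fixed fraction for {cls!r} outside [0, 1]")
    rng = np.random.default_rng([config.seed, _STREAM_MK])
    rows = []
    for cls in sorted(fixed_fraction_per_class):
        n = n_per_class if isinstance(n_per_class, int) else n_per_class.get(cls, 0)
        frac = fixed_fraction_per_class[cls]
        fixed = rng.random(n) < frac
        daf = rng.beta(*daf_beta, size=n)
        for i in range(n):
            rows.append(
                {
                    "site_id": f"{cls}_{i:06d}",
                    "class": cls,
                    "fixed": bool(fixed[i]),
                    "daf": float("nan") if fixed[i] else float(daf[i]),
                }
            )
    return pd.DataFrame(rows, columns=["site_id", "class", "fixed", "daf"])


def simulate_expression(
    network: Sequence[RegulatoryEdge],
    n_samples: int,
    noise_sd: float,
    tfs: Sequence[str] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """TF-by-sample expression with positive latent correlation along edges.

    Every TF has an independent latent N(0, 1) factor; a regulated TF's
    expression is the sum of its regulators' latent factors plus its own
    factor scaled by ``noise_sd``, so linked pairs correlate positively and
    unlinked pairs stay independent. As noise_sd -> 0 the Spearman
    correlation of a regulated pair tends to 1.
    """
    if n_samples < 3:
        warnings.warn(
            "fewer than 3 samples: correlation estimates are undefined or trivial",
            stacklevel=2,
        )
    names = sorted(
        set(tfs or [])
        | {e.source_tf for e in network}
        | {e.target_tf_gene for e in network}
    )
    if not names:
        raise ValueError("no TFs specified")
    rng = np.random.default_rng([seed, _STREAM_EXPR])
    latent = {t: rng.normal(size=n_samples) for t in names}
    parents: dict[str, list[str]] = {t: [] for t in names}
    for e in network:
        parents[e.target_tf_gene].append(e.source_tf)
    data = {}
    for t in names:
        if parents[t]:
            x = noise_sd * latent[t]
            for s in parents[t]:
                x = x + latent[s]
        else:
            x = latent[t].copy()
        data[t] = x
    frame = pd.DataFrame(data).T
    frame.columns = [f"sample_{i}" for i in range(n_samples)]
    return frame


def generate_dataset(config: SimConfig, outdir: str | Path) -> dict:
    """Write a full synthetic input bundle (FASTA, TSV, JSON truth manifest).

    Returns the truth manifest. Outputs are byte-identical under a fixed
    seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    trios = simulate_trios(config)
    with open(outdir / "trios.fa", "w") as fh:
        for i, t in enumerate(trios):
            for species, seq in (
                ("human", t.human_seq),
                ("macaque", t.macaque_seq),
                ("ancestor", t.ancestor_seq),
            ):
                fh.write(f">trio_{i:05d}|{species}|{t.intended_status}\n{seq}\n")
    mut_rows = [
        {
            "trio": f"trio_{i:05d}",
            "position": m.position,
            "human_allele": m.human_allele,
            "macaque_allele": m.macaque_allele,
            "ancestor_allele": m.ancestor_allele,
            "essential": m.position in t.essential_positions,
        }
        for i, t in enumerate(trios)
        for m in t.mutations
    ]
    pd.DataFrame(
        mut_rows,
        columns=[
            "trio", "position", "human_allele", "macaque_allele",
            "ancestor_allele", "essential",
        ],
    ).to_csv(outdir / "mutations.tsv", sep="\t", index=False)

    n_sites = max(config.n_enhancers, 10)
    flags = [i < n_sites // 2 for i in range(n_sites)]
    simulate_het_reads(config, n_sites, flags).to_csv(
        outdir / "het_reads.tsv", sep="\t", index=False
    )
    simulate_mk_sites(
        config,
        n_per_class=max(config.n_enhancers, 10),
        fixed_fraction_per_class={
            "essential": 0.99,
            "nonessential_gained": 0.98,
            "preserved_enhancer": 0.98,
            "fourfold_background": 0.98,
        },
    ).to_csv(outdir / "mk_sites.tsv", sep="\t", index=False)

    manifest = {
        "seed": config.seed,
        "n_trios": len(trios),
        "statuses": [t.intended_status for t in trios],
        "essential_positions": [sorted(t.essential_positions) for t in trios],
        "human_peaks": [t.human_peak for t in trios],
        "macaque_peaks": [t.macaque_peak for t in trios],
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
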