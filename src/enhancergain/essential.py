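"""In-silico mutagenesis: essential mutations and minimal activating sets.

Each human-specific allele is introduced into the inactive macaque ortholog
and scored; a mutation whose single introduction pushes the score over the
activity threshold is *essential*. The minimal activating set search
iterates combination sizes m = 1, 2, ..., enumerating all C(n, m)
combinations when that count is at most the cap (default 10,000) and
otherwise sampling the cap's worth of distinct combinations without
replacement, reproducibly from a seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Sequence

import numpy as np

from .cnn import apply_edits
from .comparative import MutationSite

__all__ = [
    "MutationEffect",
    "MinimalSet",
    "single_mutation_effects",
    "find_minimal_activating_set",
    "deactivating_essential",
    "DEFAULT_CAP",
]

DEFAULT_CAP = 10_000


@dataclass(frozen=True)
class MutationEffect:
    site: MutationSite
    delta: float
    activates: bool


@dataclass(frozen=True)
class MinimalSet:
    """Smallest activating combination of human alleles (m absent if none).

    ``n_evaluated`` counts the combinations scored at the returned (or, when
    nothing activates, the last attempted) combination size; it never
    exceeds the sampling cap. ``evaluations_by_m`` records the count per
    attempted size.
    """

    m: int | None
    combination: tuple[MutationSite, ...]
    n_evaluated: int
    capped: bool
    delta: float | None = None
    evaluations_by_m: tuple[tuple[int, int], ...] = ()


def _threshold_value(thr) -> float:
    return float(getattr(thr, "value", thr))


def single_mutation_effects(
    scorer,
    macaque_seq: str,
    mutations: Sequence[MutationSite],
    thr,
) -> list[MutationEffect]:
    """Delta and activation call for each human allele introduced singly."""
    t = _threshold_value(thr)
    base = scorer.score(macaque_seq)
    if base >= t:
        raise ValueError(
            f"macaque sequence already active (score {base:.4f} >= {t:.4f}); "
            "essentiality is undefined"
        )
    effects = []
    for site in mutations:
        edited = apply_edits(macaque_seq, [(site.position, site.human_allele)])
        s = scorer.score(edited)
        effects.append(
            MutationEffect(site=site, delta=float(s - base), activates=s >= t)
        )
    return effects


def _unrank_combination(rank: int, n: int, m: int) -> tuple[int, ...]:
    """Combination of given colex-free rank in lexicographic order."""
    out = []
    x = 0
    r = rank
    for slot in range(m):
        for candidate in range(x, n - (m - slot) + 1):
            block = comb(n - candidate - 1, m - slot - 1)
            if r < block:
                out.append(candidate)
                x = candidate + 1
                break
            r -= block
        else:  # pragma: no cover - rank always in range
            raise ValueError("rank out of range")
    return tuple(out)


def _iter_combinations(n: int, m: int, cap: int | None, rng: np.random.Generator):
    """Index combinations: exhaustive when C(n, m) <= cap, else cap samples.

    Sampling is without replacement over combination ranks so that exactly
    ``cap`` distinct combinations are evaluated, reproducibly.
    """
    total = comb(n, m)
    if cap is None or total <= cap:
        return list(combinations(range(n), m)), False
    if total <= 8 * cap:
        ranks = np.sort(rng.permutation(total)[:cap])
    else:
        chosen: set[int] = set()
        while len(chosen) < cap:
            draw = rng.integers(0, total, size=cap - len(chosen))
            chosen.update(int(d) for d in draw)
        ranks = np.sort(np.fromiter(chosen, dtype=np.int64))
    return [_unrank_combination(int(r), n, m) for r in ranks], True


def find_minimal_activating_set(
    scorer,
    macaque_seq: str,
    mutations: Sequence[MutationSite],
    thr,
    cap: int | None = DEFAULT_CAP,
    seed: int = 0,
) -> MinimalSet:
    """Smallest set of human alleles that activates the macaque sequence.

    Iterates m = 1..n; within each m, evaluates all combinations if their
    number is at most ``cap`` (pass None to disable the cap), otherwise a
    seeded sample of ``cap`` distinct combinations. Among activating
    combinations at the minimal m, the one with the largest score delta is
    returned (ties broken by lexicographic position order).
    """
    if not mutations:
        raise ValueError("at least one mutation required")
    t = _threshold_value(thr)
    base = scorer.score(macaque_seq)
    if base >= t:
        raise ValueError("macaque sequence already active")
    rng = np.random.default_rng(seed)
    n = len(mutations)
    order = sorted(range(n), key=lambda i: mutations[i].position)
    sites = [mutations[i] for i in order]
    capped_any = False
    by_m: list[tuple[int, int]] = []
    n_eval_m = 0
    for m in range(1, n + 1):
        combos, capped = _iter_combinations(n, m, cap, rng)
        capped_any = capped_any or capped
        n_eval_m = len(combos)
        by_m.append((m, n_eval_m))
        best = None  # (delta, positions, combo)
        for combo in combos:
            edits = [(sites[i].position, sites[i].human_allele) for i in combo]
            s = scorer.score(apply_edits(macaque_seq, edits))
            if s >= t:
                delta = s - base
                key = (-delta, tuple(sites[i].position for i in combo))
                if best is None or key < best[0]:
                    best = (key, combo, delta)
        if best is not None:
            _, combo, delta = best
            return MinimalSet(
                m=m,
                combination=tuple(sites[i] for i in combo),
                n_evaluated=n_eval_m,
                capped=capped_any,
                delta=float(delta),
                evaluations_by_m=tuple(by_m),
            )
    return MinimalSet(
        m=None,
        combination=(),
        n_evaluated=n_eval_m,
        capped=capped_any,
        evaluations_by_m=tuple(by_m),
    )


def deactivating_essential(scorer, human_seq: str, variant: tuple[int, str], thr) -> bool:
    """True when a single variant drops an active human enhancer below threshold."""
    t = _threshold_value(thr)
    base = scorer.score(human_seq)
    if base < t:
        raise ValueError(
            f"human sequence not active (score {base:.4f} < {t:.4f})"
        )
    pos, allele = variant
    edited = apply_edits(human_seq, [(pos, allele)])
    return bool(scorer.score(edited) < t)
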