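"""Printed fractions, subsample-bootstrap uncertainty, exact 2x2 tests and
run manifests."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "FractionReport",
    "fraction",
    "bootstrap_fraction",
    "fisher_2x2",
    "write_manifest",
]


@dataclass(frozen=True)
class FractionReport:
    numerator: int
    denominator: int
    percent: float  # 100*n/d rounded half-away-from-zero to `decimals`
    decimals: int
    bootstrap_median: float | None = None
    bootstrap_sd: float | None = None


def fraction(numerator: int, denominator: int, decimals: int = 1) -> FractionReport:
    """Percentage with deterministic half-away-from-zero rounding."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValueError("require 0 <= numerator <= denominator")
    pct = Decimal(100 * numerator) / Decimal(denominator)
    quant = Decimal(1).scaleb(-decimals)
    rounded = float(pct.quantize(quant, rounding=ROUND_HALF_UP))
    return FractionReport(numerator, denominator, rounded, decimals)


def bootstrap_fraction(
    items: Sequence[bool],
    keep_frac: float = 0.9,
    reps: int = 50,
    seed: int = 0,
) -> tuple[float, float]:
    """Median and SD of the true-fraction over repeated 90% subsamples.

    Each replicate draws floor(keep_frac * n) items without replacement
    (subsampling, not a classical with-replacement bootstrap — matching the
    "90%" qualifier). Returns (median, sd) over replicates.
    """
    if not 0.0 < keep_frac <= 1.0:
        raise ValueError("keep_frac must be in (0, 1]")
    arr = np.asarray(items, dtype=bool)
    n = arr.size
    if n < 10:
        raise ValueError("at least 10 items required")
    k = int(np.floor(keep_frac * n))
    rng = np.random.default_rng(seed)
    fracs = np.empty(reps)
    for r in range(reps):
        idx = rng.choice(n, size=k, replace=False)
        fracs[r] = arr[idx].mean()
    return float(np.median(fracs)), float(np.std(fracs, ddof=1))


def fisher_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float, bool]:
    """Two-sided Fisher exact test on [[a, b], [c, d]].

    Returns (odds_ratio, p, adjusted); the odds ratio is ad/bc with a 0.5
    pseudocount added to every cell when any cell is zero (adjusted=True).
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("cells must be nonnegative integers")
    if a + b + c + d == 0:
        raise ValueError("all-zero table")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if min(a, b, c, d) == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        return float(odds), float(p), True
    return (a * d) / (b * c), float(p), False


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path: str | Path,
    config: Mapping,
    seed: int | None = None,
    inputs: Iterable[str | Path] = (),
    outputs: Iterable[str | Path] = (),
) -> dict:
    """Write a JSON run manifest with config hash and input checksums."""
    config_json = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "config": json.loads(config_json),
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "seed": seed,
        "inputs": {str(p): _sha256(p) for p in inputs},
        "outputs": {str(p): _sha256(p) for p in outputs},
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
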