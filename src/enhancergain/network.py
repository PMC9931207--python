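"""TF->TF-gene regulatory-network inference and hierarchy statistics.

An edge source->target is drawn when the source TF's motif-hit density
(hits per kb) in the de novo gained enhancers near the target TF gene is
enriched over its density in the conserved enhancers near the same gene
(ratio >= 1.5 and one-sided Poisson p <= 0.05 by default; both cutoffs are
configurable because no canonical rule exists for this call). Self-edges
(autoregulation) are allowed. The master regulator is the TF with the
highest out-degree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from scipy import stats

from .motifs import PWM, scan

__all__ = [
    "RegulatoryEdge",
    "motif_density",
    "build_network",
    "hierarchy",
]


@dataclass(frozen=True)
class RegulatoryEdge:
    source_tf: str
    target_tf_gene: str
    density_fg: float  # hits per kb in gained enhancers near the target
    density_bg: float  # hits per kb in conserved enhancers near the target
    enrichment_ratio: float
    p_value: float


def motif_density(seqs: Sequence[str], pwm: PWM) -> tuple[int, float]:
    """(hit count, hits per kb) of a motif over a set of sequences."""
    total_bp = sum(len(s) for s in seqs)
    if total_bp == 0:
        raise ValueError("no sequence supplied")
    hits = sum(len(scan(s, pwm)) for s in seqs)
    return hits, hits / (total_bp / 1000.0)


def build_network(
    gained_by_gene: Mapping[str, Sequence[str]],
    conserved_by_gene: Mapping[str, Sequence[str]],
    pwms: Mapping[str, PWM],
    min_ratio: float = 1.5,
    alpha: float = 0.05,
) -> list[RegulatoryEdge]:
    """Infer regulatory edges from motif-density enrichment near each gene.

    ``gained_by_gene``/``conserved_by_gene`` map a TF gene name to the
    sequences of the de novo gained / conserved enhancers assigned to it
    (nearest-TSS assignment upstream). ``pwms`` maps source TF names to
    calibrated motifs. Targets lacking enhancers on either side are skipped
    with a warning. The foreground hit count is tested against the expected
    count under the background per-kb rate (one-sided Poisson).
    """
    edges: list[RegulatoryEdge] = []
    for target in sorted(gained_by_gene):
        fg_seqs = list(gained_by_gene.get(target, ()))
        bg_seqs = list(conserved_by_gene.get(target, ()))
        if not fg_seqs or not bg_seqs:
            warnings.warn(
                f"target {target!r} lacks gained or conserved enhancers; skipped",
                stacklevel=2,
            )
            continue
        fg_kb = sum(len(s) for s in fg_seqs) / 1000.0
        bg_kb = sum(len(s) for s in bg_seqs) / 1000.0
        for source in sorted(pwms):
            pwm = pwms[source]
            fg_hits, fg_density = motif_density(fg_seqs, pwm)
            bg_hits, bg_density = motif_density(bg_seqs, pwm)
            # half-hit floor keeps the rate test defined for empty backgrounds
            bg_rate = max(bg_hits, 0.5) / bg_kb
            ratio = fg_density / bg_rate
            expected = bg_rate * fg_kb
            p = float(stats.poisson.sf(fg_hits - 1, expected)) if fg_hits > 0 else 1.0
            if ratio >= min_ratio and p <= alpha:
                edges.append(
                    RegulatoryEdge(
                        source_tf=source,
                        target_tf_gene=target,
                        density_fg=fg_density,
                        density_bg=bg_density,
                        enrichment_ratio=ratio,
                        p_value=p,
                    )
                )
    return edges


def hierarchy(edges: Sequence[RegulatoryEdge]) -> tuple[pd.DataFrame, str | None]:
    """Out-/in-degree table (rank by out-degree) and the master regulator.

    A self-edge counts toward both degrees of its TF. The master regulator
    is the TF with the maximum out-degree, ties broken lexicographically;
    None when there are no edges.
    """
    tfs = sorted(
        {e.source_tf for e in edges} | {e.target_tf_gene for e in edges}
    )
    out_deg = {t: 0 for t in tfs}
    in_deg = {t: 0 for t in tfs}
    for e in edges:
        out_deg[e.source_tf] += 1
        in_deg[e.target_tf_gene] += 1
    table = pd.DataFrame(
        {
            "tf": tfs,
            "out_degree": [out_deg[t] for t in tfs],
            "in_degree": [in_deg[t] for t in tfs],
        }
    ).sort_values(["out_degree", "tf"], ascending=[False, True], ignore_index=True)
    table["rank"] = range(1, len(table) + 1)
    master = table.iloc[0]["tf"] if len(table) else None
    return table, master
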