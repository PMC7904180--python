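"""Pathway over-representation analysis of enumerated networks.

For each network, each pathway's 2×2 contingency table (active vs pathway
membership over a common background of reactions) is tested with a one-sided
(right-tail) Fisher's exact test; p-values are Benjamini–Hochberg adjusted
across pathways within each network.  The union summary marks a pathway as
detected if it is enriched (adjusted p < α) in at least one network, which is
how solution sets are compared: a method that detects more enriched pathways
has surfaced more alternative metabolic hypotheses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .exceptions import ValidationError
from .model import MetabolicModel

__all__ = [
    "PathwayAnnotation",
    "EnrichmentResult",
    "contingency",
    "fisher_right_tail",
    "bh_adjust",
    "enrich_solution_set",
]

DEFAULT_ALPHA = 0.05


@dataclass
class PathwayAnnotation:
    """Pathway name → set of member reaction ids."""

    pathways: dict[str, set[str]] = field(default_factory=dict)

    @classmethod
    def from_model_subsystems(cls, model: MetabolicModel) -> "PathwayAnnotation":
        pathways: dict[str, set[str]] = {}
        for rxn in model.reactions:
            if rxn.subsystem:
                pathways.setdefault(rxn.subsystem, set()).add(rxn.id)
        return cls(pathways)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PathwayAnnotation":
        frame = pd.read_csv(path, sep="\t")
        name_col, rxn_col = frame.columns[:2]
        pathways: dict[str, set[str]] = {}
        for name, rid in zip(frame[name_col], frame[rxn_col]):
            pathways.setdefault(str(name), set()).add(str(rid))
        return cls(pathways)

    def validate_for(self, reaction_ids: Iterable[str]) -> None:
        universe = set(reaction_ids)
        for name, members in self.pathways.items():
            unknown = members - universe
            if unknown:
                raise ValidationError(
                    f"pathway {name!r} annotates unknown reactions: "
                    f"{sorted(unknown)[:5]}"
                )


def contingency(
    active: set[str], pathway: set[str], background: set[str]
) -> tuple[int, int, int, int]:
    """2×2 table (a, b, c, d) for over-representation of *pathway* in *active*."""
    if not pathway <= background:
        raise ValidationError("pathway set must be contained in the background")
    if not active <= background:
        raise ValidationError("active set must be contained in the background")
    a = len(active & pathway)
    b = len(active - pathway)
    c = len(pathway - active)
    d = len(background) - a - b - c
    return a, b, c, d


def fisher_right_tail(a: int, b: int, c: int, d: int) -> float:
    """One-sided Fisher's exact p-value: P(X ≥ a) with all margins fixed."""
    if min(a, b, c, d) < 0:
        raise ValueError("contingency counts must be non-negative")
    if a == 0:
        return 1.0  # P(X >= 0) is certain; also covers the empty table
    total = a + b + c + d
    # X ~ Hypergeometric(total, pathway size a+c, draws a+b)
    return float(hypergeom.sf(a - 1, total, a + c, a + b))


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values (capped at 1)."""
    pvalues = list(pvalues)
    if not pvalues:
        return []
    if any(not 0 <= p <= 1 for p in pvalues):
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(pvalues, method="fdr_bh")
    return [float(p) for p in adjusted]


@dataclass
class EnrichmentResult:
    table: pd.DataFrame  # per (network, pathway): counts, p, p_adjusted, enriched
    union: dict[str, bool]  # pathway → enriched in >= 1 network at alpha
    alpha: float

    @property
    def n_enriched_union(self) -> int:
        return sum(self.union.values())


def enrich_solution_set(
    solution_set,
    annotation: PathwayAnnotation,
    alpha: float = DEFAULT_ALPHA,
    background: set[str] | None = None,
) -> EnrichmentResult:
    """Per-network pathway over-representation with a union summary.

    The background defaults to all reactions of the generic model (the only
    universe shared by every network, keeping p-values comparable).  BH
    adjustment is applied across pathways within each network.
    """
    reaction_ids = list(solution_set.reaction_ids)
    background = set(background) if background is not None else set(reaction_ids)
    annotation.validate_for(background)
    names = sorted(annotation.pathways)
    records = []
    union = {name: False for name in names}
    for k, sol in enumerate(solution_set):
        active = {
            rid for rid, bit in zip(reaction_ids, sol.activity) if bit
        } & background
        raw = []
        counts = []
        for name in names:
            tab = contingency(active, annotation.pathways[name] & background, background)
            counts.append(tab)
            raw.append(fisher_right_tail(*tab))
        adjusted = bh_adjust(raw)
        for name, tab, p, padj in zip(names, counts, raw, adjusted):
            enriched = padj < alpha
            union[name] = union[name] or enriched
            records.append(
                {
                    "network": k,
                    "pathway": name,
                    "a": tab[0],
                    "b": tab[1],
                    "c": tab[2],
                    "d": tab[3],
                    "pvalue": p,
                    "p_adjusted": padj,
                    "enriched": enriched,
                }
            )
    table = pd.DataFrame.from_records(
        records,
        columns=[
            "network", "pathway", "a", "b", "c", "d",
            "pvalue", "p_adjusted", "enriched",
        ],
    )
    return EnrichmentResult(table=table, union=union, alpha=alpha)
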