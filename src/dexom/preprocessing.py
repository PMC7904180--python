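"""From gene expression to the R_H/R_L reaction partition.

Genes are classed by quantile thresholds on their own expression distribution
(strictly below the lower quantile → lowly expressed, strictly above the upper
→ highly expressed), then propagated to reactions through GPR rules with
AND = min / OR = max on the {−1, 0, +1} lattice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .gpr import GprNode
from .model import MetabolicModel, ReactionPartition

__all__ = [
    "ExpressionProfile",
    "GeneClassification",
    "load_expression",
    "classify_genes",
    "evaluate_gpr",
    "partition_reactions",
    "random_partition_fixture",
]

LOW, UNCLASSIFIED, HIGH = -1, 0, 1


@dataclass
class ExpressionProfile:
    """Normalized expression value per gene (platform-agnostic units)."""

    values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {g: v for g, v in self.values.items() if not np.isfinite(v)}
        if bad:
            raise ValidationError(
                f"non-finite expression values for genes {sorted(bad)[:5]}"
            )


@dataclass
class GeneClassification:
    """Gene → class in {−1 (lowly), 0 (unclassified), +1 (highly)}."""

    classes: dict[str, int] = field(default_factory=dict)


def load_expression(path: str | Path) -> ExpressionProfile:
    """Read a 2-column TSV/CSV (gene_id, value); separator is sniffed."""
    sep = "\t" if Path(path).suffix.lower() in (".tsv", ".tab", ".txt") else ","
    frame = pd.read_csv(path, sep=sep)
    gene_col, value_col = frame.columns[:2]
    return ExpressionProfile(
        dict(zip(frame[gene_col].astype(str), frame[value_col].astype(float)))
    )


def classify_genes(
    profile: ExpressionProfile | Mapping[str, float],
    q_low: float = 0.25,
    q_high: float = 0.75,
) -> GeneClassification:
    """Quantile-threshold classification over the profile's own values.

    Values strictly below the q_low quantile are lowly expressed, strictly
    above the q_high quantile highly expressed; ties with a threshold stay
    unclassified (a constant profile classifies every gene as 0).
    """
    values = profile.values if isinstance(profile, ExpressionProfile) else dict(profile)
    if not values:
        raise ValidationError("cannot classify an empty expression profile")
    if not 0 <= q_low < q_high <= 1:
        raise ValueError("quantiles must satisfy 0 <= q_low < q_high <= 1")
    arr = np.array(list(values.values()), dtype=float)
    lo = np.quantile(arr, q_low)  # linear-interpolation empirical quantile
    hi = np.quantile(arr, q_high)
    classes = {
        g: (LOW if v < lo else HIGH if v > hi else UNCLASSIFIED)
        for g, v in values.items()
    }
    return GeneClassification(classes)


def evaluate_gpr(
    gpr: GprNode | None,
    classification: GeneClassification | Mapping[str, int],
    missing: int = UNCLASSIFIED,
) -> int:
    """Aggregate gene classes through a GPR tree (AND = min, OR = max)."""
    if gpr is None:
        return UNCLASSIFIED
    classes = (
        classification.classes
        if isinstance(classification, GeneClassification)
        else classification
    )
    return gpr.evaluate_ternary(classes, missing=missing)


def partition_reactions(
    model: MetabolicModel, classification: GeneClassification
) -> ReactionPartition:
    """Reactions whose GPR evaluates to +1 go to R_H, −1 to R_L."""
    rh, rl = set(), set()
    for rxn in model.reactions:
        cls = evaluate_gpr(rxn.gpr, classification)
        if cls == HIGH:
            rh.add(rxn.id)
        elif cls == LOW:
            rl.add(rxn.id)
    return ReactionPartition(rh=rh, rl=rl)


def random_partition_fixture(
    model: MetabolicModel, n_high: int, n_low: int, seed: int = 0
) -> ReactionPartition:
    """Random disjoint R_H/R_L sets of the requested sizes (reaction ids are
    sampled directly, mirroring random-reaction benchmark setups)."""
    ids = model.reaction_ids
    if n_high < 0 or n_low < 0 or n_high + n_low > len(ids):
        raise ValueError(
            f"cannot draw {n_high}+{n_low} disjoint reactions from {len(ids)}"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(ids), size=n_high + n_low, replace=False)
    rh = {ids[i] for i in chosen[:n_high]}
    rl = {ids[i] for i in chosen[n_high:]}
    return ReactionPartition(rh=rh, rl=rl)
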