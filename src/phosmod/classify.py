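"""Fold-change pattern classification across a three-strain panel.

Phospho-peptides (or genes) are classified by the shape of their
replicate-averaged log2 fold-change profile across an ordered strain
panel (progenitor -> intermediate -> evolved):

* ``A_inc`` / ``A_dec`` -- progressive increase/decrease: each
  consecutive strain step differs by at least ``log2(fold_threshold)``.
* ``B_inc`` / ``B_dec`` -- a response unique to the evolved strain: the
  evolved strain differs from both earlier strains by at least the
  threshold while the two earlier strains are fold-equivalent.
* ``none`` -- everything else.

"1.5-fold difference in log2 changes" is interpreted as a difference of
log2 values of at least log2(1.5); applying a multiplicative factor to a
log value directly would be ill-defined near zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

CLASS_LABELS = ("A_inc", "A_dec", "B_inc", "B_dec", "none")
RESPONSIVE_LABELS = ("A_inc", "A_dec", "B_inc", "B_dec")


@dataclass(frozen=True)
class ClassificationParams:
    """Strain order and fold thresholds for profile classification.

    fold_threshold and b_equality_threshold are fold ratios (> 1); both
    are applied on the log2 scale as ``log2(threshold)``.
    """

    strain_order: tuple[str, str, str]
    fold_threshold: float = 1.5
    b_equality_threshold: float = 1.5

    def __post_init__(self) -> None:
        if len(self.strain_order) != 3:
            raise ValueError("strain_order must name exactly 3 strains")
        if self.fold_threshold <= 1 or self.b_equality_threshold <= 1:
            raise ValueError("fold thresholds must be > 1")

    @property
    def log2_step(self) -> float:
        return math.log2(self.fold_threshold)

    @property
    def log2_equality(self) -> float:
        return math.log2(self.b_equality_threshold)


@dataclass(frozen=True)
class ResponseProfile:
    """Replicate-level and replicate-averaged log2 fold-changes per strain."""

    feature_id: str
    replicates: Mapping[str, tuple[float, ...]]
    values: Mapping[str, float] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        reps = {s: tuple(float(v) for v in vals) for s, vals in self.replicates.items()}
        object.__setattr__(self, "replicates", reps)
        values = average_replicates(reps)
        if self.values is not None:
            for s, v in self.values.items():
                if abs(v - values[s]) > 1e-12:
                    raise ValueError(
                        f"{self.feature_id}: values[{s}] is not the replicate mean"
                    )
        object.__setattr__(self, "values", values)


def average_replicates(replicates: Mapping[str, Sequence[float]]) -> dict[str, float]:
    """Arithmetic mean of the replicate values for each strain."""
    out = {}
    for strain, vals in replicates.items():
        vals = list(vals)
        if not vals:
            raise ValueError(f"strain {strain} has no replicate values")
        out[strain] = sum(float(v) for v in vals) / len(vals)
    return out


def classify_progressive(profile: ResponseProfile, params: ClassificationParams) -> str:
    """Assign one of the five class labels to a three-strain profile.

    Class A (progressive) takes precedence over Class B.  Returns a
    label from :data:`CLASS_LABELS`.
    """
    missing = [s for s in params.strain_order if s not in profile.values]
    if missing:
        raise ValueError(f"{profile.feature_id}: missing strain(s) {missing}")
    v1, v2, v3 = (profile.values[s] for s in params.strain_order)
    t = params.log2_step
    eq = params.log2_equality
    if v2 - v1 >= t and v3 - v2 >= t:
        return "A_inc"
    if v1 - v2 >= t and v2 - v3 >= t:
        return "A_dec"
    if v3 - v1 >= t and v3 - v2 >= t and abs(v2 - v1) < eq:
        return "B_inc"
    if v1 - v3 >= t and v2 - v3 >= t and abs(v2 - v1) < eq:
        return "B_dec"
    return "none"


def classify_reproducible_contrast(
    replicates_a: Sequence[float],
    replicates_b: Sequence[float],
    fold_threshold: float = 1.5,
) -> str:
    """Reproducible per-replicate contrast rule: ``up``/``down``/``none``.

    Replicates are paired by index; the call is ``up`` (``down``) only if
    every per-replicate difference a-b is >= log2(fold_threshold)
    (<= -log2(fold_threshold)).
    """
    if len(replicates_a) != len(replicates_b) or not replicates_a:
        raise ValueError("replicate sequences must be paired and non-empty")
    t = math.log2(fold_threshold)
    diffs = [float(a) - float(b) for a, b in zip(replicates_a, replicates_b)]
    if all(d >= t for d in diffs):
        return "up"
    if all(d <= -t for d in diffs):
        return "down"
    return "none"


def classify_peptides(peptides, params: ClassificationParams) -> pd.DataFrame:
    """Classify a peptide collection; returns a table of labels and means.

    Peptides missing any strain in ``params.strain_order`` are labelled
    ``none`` (and logged by the caller if desired) rather than dropped.
    """
    rows = []
    for p in peptides:
        profile = ResponseProfile(p.peptide_id, p.log2fc)
        if any(s not in profile.values for s in params.strain_order):
            label = "none"
            vals = [float("nan")] * 3
        else:
            label = classify_progressive(profile, params)
            vals = [profile.values[s] for s in params.strain_order]
        rows.append((p.peptide_id, label, *vals))
    return pd.DataFrame(rows, columns=["feature_id", "class", "v1", "v2", "v3"])
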