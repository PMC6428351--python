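"""Shared-interactor and annotation-set enrichment.

A *shared interactor* (SI) of a module is a protein in the background
interaction network whose partners include more of the module's
constituent proteins than expected by chance under a hypergeometric
model.  Candidate regulators are the SIs whose directed interactions
with the module point predominantly toward module members (or are all
undirected).  The same hypergeometric machinery serves generic
annotation-set enrichment.

The hypergeometric tail is computed with exact integer combinatorics so
that desk-scale enumeration checks agree to machine precision;
Benjamini-Hochberg adjustment goes through statsmodels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from math import comb
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .io import AnnotationSets, InteractionNetwork
from .motifs import Module

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentParams:
    """FDR cut-off, minimum module overlap for a reportable SI, and the
    fraction of directed edges that must point toward the module."""

    fdr_threshold: float = 0.05
    min_overlap: int = 2
    direction_majority: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.fdr_threshold < 1:
            raise ValueError("fdr_threshold must be in (0, 1)")
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if not 0 < self.direction_majority <= 1:
            raise ValueError("direction_majority must be in (0, 1]")


@dataclass(frozen=True)
class SharedInteractor:
    """One (candidate protein, module) enrichment result."""

    protein_id: str
    module_id: str
    class_label: str
    overlap: int
    degree: int
    module_size_in_network: int
    population: int
    p_value: float
    q_value: float
    toward_fraction: float | None


def hypergeom_pvalue(population: int, successes: int, draws: int, observed: int) -> float:
    """Exact upper tail P(X >= observed), X ~ Hypergeom(population, successes, draws)."""
    if not (0 <= successes <= population and 0 <= draws <= population):
        raise ValueError("successes and draws must be between 0 and population")
    if not 0 <= observed <= min(successes, draws):
        raise ValueError("observed must be between 0 and min(successes, draws)")
    numerator = sum(
        comb(successes, k) * comb(population - successes, draws - k)
        for k in range(observed, min(successes, draws) + 1)
        if draws - k <= population - successes
    )
    return float(Fraction(numerator, comb(population, draws)))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _toward_fraction(
    network: InteractionNetwork, candidate: str, members: frozenset
) -> float | None:
    toward = sum(1 for t in network.directed_out.get(candidate, ()) if t in members)
    backward = sum(1 for s in network.directed_in.get(candidate, ()) if s in members)
    total = toward + backward
    return None if total == 0 else toward / total


def find_shared_interactors(
    network: InteractionNetwork,
    modules: Sequence[Module],
    params: EnrichmentParams,
    significant_only: bool = True,
) -> list[SharedInteractor]:
    """Significant shared interactors for each module.

    For every module and every network node outside the module with at
    least one module partner: population = |nodes| - 1 (the candidate
    cannot be its own partner), successes = module proteins present in
    the network, draws = the candidate's distinct partners.  BH
    correction is applied jointly across all tests of one response
    class; results with q below the FDR threshold and overlap >=
    ``min_overlap`` are returned (all tested pairs when
    ``significant_only`` is false, e.g. for calibration studies).
    """
    by_class: dict[str, list[Module]] = {}
    for m in modules:
        by_class.setdefault(m.class_label, []).append(m)

    results: list[SharedInteractor] = []
    population = len(network.nodes) - 1
    for class_label in sorted(by_class):
        tests: list[tuple[str, str, frozenset, int, int, int, float]] = []
        for module in sorted(by_class[class_label], key=lambda m: m.module_id):
            members = frozenset(module.protein_ids) & network.nodes
            dropped = len(module.protein_ids) - len(members)
            if dropped:
                logger.info(
                    "module %s: %d protein(s) absent from the network",
                    module.module_id,
                    dropped,
                )
            if not members:
                logger.warning("module %s has no proteins in the network; skipped",
                               module.module_id)
                continue
            for candidate in sorted(network.nodes - members):
                partners = network.partners[candidate]
                overlap = len(partners & members)
                if overlap == 0:
                    continue
                p = hypergeom_pvalue(population, len(members), len(partners), overlap)
                tests.append(
                    (candidate, module.module_id, members, overlap, len(partners),
                     len(members), p)
                )
        if not tests:
            continue
        q_values = bh_adjust([t[6] for t in tests])
        for (candidate, module_id, members, overlap, degree, mod_size, p), q in zip(
            tests, q_values
        ):
            if not significant_only or (
                q < params.fdr_threshold and overlap >= params.min_overlap
            ):
                results.append(
                    SharedInteractor(
                        protein_id=candidate,
                        module_id=module_id,
                        class_label=class_label,
                        overlap=overlap,
                        degree=degree,
                        module_size_in_network=mod_size,
                        population=population,
                        p_value=p,
                        q_value=float(q),
                        toward_fraction=_toward_fraction(network, candidate, members),
                    )
                )
    results.sort(key=lambda s: (s.class_label, s.module_id, s.p_value, s.protein_id))
    return results


def directionality_filter(
    shared: Sequence[SharedInteractor],
    regulator_set: Iterable[str],
    params: EnrichmentParams,
) -> list[SharedInteractor]:
    """Keep known regulators whose module interactions are all undirected
    or point predominantly toward module constituents."""
    regulators = set(regulator_set)
    kept = []
    for s in shared:
        if s.protein_id not in regulators:
            continue
        if s.toward_fraction is None or s.toward_fraction >= params.direction_majority:
            kept.append(s)
    return kept


def enrich_annotation(
    feature_set: Iterable[str],
    annotations: AnnotationSets,
    params: EnrichmentParams,
) -> pd.DataFrame:
    """Hypergeometric enrichment of a feature set against annotation sets.

    Returns a table (set_name, set_size, overlap, p_value, q_value),
    BH-corrected across all annotation sets.
    """
    features = frozenset(feature_set)
    stray = features - annotations.background
    if stray:
        raise ValueError(f"features outside background: {sorted(stray)[:5]}")
    population = len(annotations.background)
    draws = len(features)
    rows = []
    for name in sorted(annotations.sets):
        members = annotations.sets[name]
        overlap = len(features & members)
        p = hypergeom_pvalue(population, len(members), draws, overlap)
        rows.append((name, len(members), overlap, p))
    df = pd.DataFrame(rows, columns=["set_name", "set_size", "overlap", "p_value"])
    df["q_value"] = bh_adjust(df["p_value"]) if len(df) else []
    return df
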