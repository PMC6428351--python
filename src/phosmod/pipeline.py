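"""End-to-end orchestration: classify -> modules -> enrich -> match.

``run_pipeline`` executes the four stages in order on user-supplied
input files, writes per-stage result tables, a Cytoscape SIF of the
assembled regulator network and a JSON run manifest.  A second run with
the same configuration and seed is byte-identical.

Regulator edges in the assembled network require every line of
evidence: shared-interactor significance, directionality, and — for
kinases present in the specificity library — a passing specificity
match.  Phosphatases (regulators without a library entry) are retained
on the first two lines alone, since no spot-array specificity exists
for them.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .classify import ClassificationParams, RESPONSIVE_LABELS, classify_peptides
from .enrichment import (
    EnrichmentParams,
    SharedInteractor,
    directionality_filter,
    find_shared_interactors,
)
from .io import (
    read_kinase_intensities,
    read_network,
    read_peptide_table,
    read_proteome,
    sha256_of_file,
    write_result_tables,
    write_sif,
)
from .matching import MatchParams, MatchResult, library_to_pwms, match_kinases, pwm_from_windows
from .motifs import Module, MotifParams, background_windows, motifx_partition

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    peptides: str
    network: str
    proteome: str
    kinase_intensities: str
    regulators: str
    out_dir: str
    strain_order: tuple[str, str, str] = ("Y22-3", "Y127", "Y128")
    fold_threshold: float = 1.5
    b_equality_threshold: float = 1.5
    motif: MotifParams = field(default_factory=MotifParams)
    enrichment: EnrichmentParams = field(default_factory=EnrichmentParams)
    match: MatchParams = field(default_factory=MatchParams)
    seed: int = 0

    def __post_init__(self) -> None:
        self.strain_order = tuple(self.strain_order)
        # a single run-level seed drives the only stochastic stage
        if self.match.rng_seed != self.seed:
            self.match = MatchParams(
                pseudocount=self.match.pseudocount,
                n_shuffles=self.match.n_shuffles,
                match_fdr_threshold=self.match.match_fdr_threshold,
                rng_seed=self.seed,
                null=self.match.null,
            )

    @property
    def classification(self) -> ClassificationParams:
        return ClassificationParams(
            self.strain_order, self.fold_threshold, self.b_equality_threshold
        )

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        for key, klass in (
            ("motif", MotifParams),
            ("enrichment", EnrichmentParams),
            ("match", MatchParams),
        ):
            if key in raw and isinstance(raw[key], dict):
                if key == "motif" and "central_residues" in raw[key]:
                    raw[key]["central_residues"] = frozenset(raw[key]["central_residues"])
                raw[key] = klass(**raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["motif"]["central_residues"] = sorted(self.motif.central_residues)
        return d


@dataclass(frozen=True)
class RegulatoryNetwork:
    """Typed regulator -> module -> protein graph for export."""

    nodes: tuple  # (node_id, kind, attributes)
    edges: tuple  # (source, relation, target)


def assemble_network(
    modules: Sequence[Module],
    filtered_sis: Sequence[SharedInteractor],
    matches: Sequence[MatchResult],
    library_kinases: frozenset,
    match_fdr_threshold: float = 0.05,
) -> tuple[RegulatoryNetwork, list[SharedInteractor]]:
    """Assemble the regulator network from the three evidence layers.

    Returns the network plus the shared interactors rejected at the
    specificity-matching step (kinases with a library entry whose match
    FDR was not below threshold).
    """
    module_by_id = {m.module_id: m for m in modules}
    for s in filtered_sis:
        if s.module_id not in module_by_id:
            raise ValueError(f"shared interactor references unknown module {s.module_id}")
    match_fdr = {(m.kinase, m.module_id): m.fdr for m in matches}

    reg_edges = []
    rejected = []
    for s in filtered_sis:
        if s.protein_id in library_kinases:
            fdr = match_fdr.get((s.protein_id, s.module_id))
            if fdr is None or fdr >= match_fdr_threshold:
                rejected.append(s)
                continue
        reg_edges.append((s.protein_id, "regulates", s.module_id))

    nodes = []
    seen = set()
    for source, _, target in sorted(reg_edges):
        if source not in seen:
            seen.add(source)
            kind = "kinase" if source in library_kinases else "phosphatase"
            nodes.append((source, "regulator", {"regulator_kind": kind}))
    edges = sorted(reg_edges)
    for module in sorted(modules, key=lambda m: m.module_id):
        nodes.append(
            (
                module.module_id,
                "module",
                {"class": module.class_label, "motif": module.motif.pattern()},
            )
        )
        for protein in sorted(module.protein_ids):
            edges.append((module.module_id, "contains", protein))
            key = (module.module_id, protein)
            if key not in seen:
                seen.add(key)
                nodes.append((protein, "protein", {}))
    return RegulatoryNetwork(tuple(nodes), tuple(edges)), rejected


def build_modules(
    peptides,
    classified: pd.DataFrame,
    proteome,
    motif_params: MotifParams,
) -> list[Module]:
    """Partition each responsive class into phospho-motif modules."""
    bg = background_windows(proteome, motif_params.central_residues, motif_params.width)
    window_of = {p.peptide_id: p.window for p in peptides}
    protein_of = {p.peptide_id: p.protein_id for p in peptides}
    modules: list[Module] = []
    for label in RESPONSIVE_LABELS:
        ids = classified.loc[classified["class"] == label, "feature_id"]
        fg = [(pid, window_of[pid]) for pid in ids if pid in window_of]
        if not fg:
            continue
        mods, unassigned = motifx_partition(
            fg, bg, motif_params, class_label=label, protein_of=protein_of
        )
        logger.info(
            "class %s: %d modules, %d unassigned peptides", label, len(mods),
            len(unassigned),
        )
        modules.extend(mods)
    return modules


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all four stages and write outputs; returns the run manifest."""
    paths = {
        "peptides": config.peptides,
        "network": config.network,
        "proteome": config.proteome,
        "kinase_intensities": config.kinase_intensities,
        "regulators": config.regulators,
    }
    missing = [name for name, p in paths.items() if not Path(p).is_file()]
    if missing:
        raise FileNotFoundError(f"missing input file(s): {missing}")
    checksums = {name: sha256_of_file(p) for name, p in paths.items()}

    peptides = read_peptide_table(config.peptides, config.strain_order)
    network = read_network(config.network)
    proteome = read_proteome(config.proteome)
    library = read_kinase_intensities(config.kinase_intensities)
    with open(config.regulators) as fh:
        regulator_set = {line.strip() for line in fh if line.strip()}

    # stage 1: classification
    classified = classify_peptides(peptides, config.classification)
    logger.info(
        "classified %d peptides: %s",
        len(classified),
        classified["class"].value_counts().to_dict(),
    )

    # stage 2: motif modules
    modules = build_modules(peptides, classified, proteome, config.motif)
    logger.info("%d modules total", len(modules))

    # stage 3: shared interactors + directionality
    shared = find_shared_interactors(network, modules, config.enrichment)
    candidates = directionality_filter(shared, regulator_set, config.enrichment)
    logger.info("%d significant SIs, %d pass regulator/directionality filter",
                len(shared), len(candidates))

    # stage 4: kinase specificity matching
    window_of = {p.peptide_id: p.window for p in peptides}
    module_pwms = {
        m.module_id: pwm_from_windows(
            [window_of[pid] for pid in sorted(m.peptide_ids)],
            pseudocount=config.match.pseudocount,
        )
        for m in modules
    }
    kinase_pwms = library_to_pwms(library, config.match.pseudocount)
    cand_by_module: dict[str, set] = {}
    for s in candidates:
        if s.protein_id in kinase_pwms:
            cand_by_module.setdefault(s.module_id, set()).add(s.protein_id)
    matches = match_kinases(
        {mid: module_pwms[mid] for mid in cand_by_module},
        kinase_pwms,
        cand_by_module,
        config.match,
    )
    logger.info(
        "%d kinase matches scored, %d below FDR %.3g",
        len(matches),
        sum(m.fdr < config.match.match_fdr_threshold for m in matches),
        config.match.match_fdr_threshold,
    )

    regnet, rejected = assemble_network(
        modules,
        candidates,
        matches,
        frozenset(kinase_pwms),
        config.match.match_fdr_threshold,
    )

    # outputs
    tables = {
        "classified": classified,
        "modules": pd.DataFrame(
            [
                (m.module_id, m.class_label, m.motif.pattern(), pid, None)
                for m in modules
                for pid in sorted(m.peptide_ids)
            ],
            columns=["module_id", "class", "motif", "peptide_id", "protein_id"],
        ),
        "shared_interactors": _si_table(shared),
        "regulators": _si_table(candidates),
        "matches": pd.DataFrame(
            [
                (m.kinase, m.module_id, m.kld, m.null_size, m.fdr)
                for m in matches
            ],
            columns=["kinase", "module_id", "kld_bits", "null_size", "fdr"],
        ),
        "rejected": _si_table(rejected),
    }
    protein_of = {p.peptide_id: p.protein_id for p in peptides}
    tables["modules"]["protein_id"] = tables["modules"]["peptide_id"].map(protein_of)

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    hashed_config = config.to_dict()
    hashed_config.pop("out_dir")  # not part of the analytic configuration
    manifest = write_result_tables(
        tables,
        out_dir,
        config=hashed_config,
        seed=config.seed,
        input_checksums=checksums,
    )
    sif_path = out_dir / "network.sif"
    write_sif(list(regnet.edges), sif_path)
    manifest["outputs"][sif_path.name] = sha256_of_file(sif_path)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def _si_table(sis: Sequence[SharedInteractor]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                s.protein_id,
                s.module_id,
                s.class_label,
                s.overlap,
                s.degree,
                s.module_size_in_network,
                s.p_value,
                s.q_value,
                "" if s.toward_fraction is None else s.toward_fraction,
            )
            for s in sis
        ],
        columns=[
            "protein_id",
            "module_id",
            "class",
            "overlap",
            "degree",
            "module_size_in_network",
            "p_value",
            "q_value",
            "toward_fraction",
        ],
    )
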