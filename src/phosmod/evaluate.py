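"""Scoring pipeline output against the synthetic ground truth.

A reported regulator edge kinase -> module is *attributed* to the
kinase when at least ``attribution_threshold`` of the module's member
peptides are planted substrates of that kinase.  A planted kinase
counts as recovered when it has at least one attributed edge; a kinase
reported with an edge it cannot be attributed counts as a false
regulator call.  The default threshold of 0.25 tolerates modules that
legitimately merge substrates of kinases with overlapping specificity
while still flagging regulators foreign to a module.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .pipeline import PipelineConfig, run_pipeline
from .simulate import Scenario, SimParams, generate_scenario, write_scenario


@dataclass(frozen=True)
class RecoveryScore:
    recovered: frozenset
    false_calls: frozenset
    n_planted: int

    @property
    def n_recovered(self) -> int:
        return len(self.recovered)

    @property
    def n_false(self) -> int:
        return len(self.false_calls)


def score_regulator_recovery(
    regulates_edges: Sequence[tuple[str, str]],
    module_members: Mapping[str, Sequence[str]],
    kinase_of_peptide: Mapping[str, str | None],
    planted_kinases: Sequence[str],
    attribution_threshold: float = 0.25,
) -> RecoveryScore:
    """Score reported regulator -> module edges against the planted truth."""
    recovered = set()
    false_calls = set()
    for kinase, module_id in regulates_edges:
        members = list(module_members.get(module_id, ()))
        if not members:
            false_calls.add(kinase)
            continue
        own = sum(1 for pid in members if kinase_of_peptide.get(pid) == kinase)
        if own / len(members) >= attribution_threshold:
            if kinase in planted_kinases:
                recovered.add(kinase)
        else:
            false_calls.add(kinase)
    return RecoveryScore(
        frozenset(recovered), frozenset(false_calls), len(set(planted_kinases))
    )


def read_regulates_edges(sif_path) -> list[tuple[str, str]]:
    edges = []
    with open(sif_path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) == 3 and parts[1] == "regulates":
                edges.append((parts[0], parts[2]))
    return edges


def run_planted_benchmark(
    params: SimParams,
    pipeline_seed: int,
    workdir=None,
    attribution_threshold: float = 0.25,
) -> tuple[RecoveryScore, Scenario]:
    """Generate a scenario, run the full pipeline on its files, and score
    regulator recovery; the scenario seed lives in ``params.seed``."""
    scenario = generate_scenario(params)
    ctx = tempfile.TemporaryDirectory() if workdir is None else None
    base = Path(ctx.name if ctx else workdir)
    try:
        files = write_scenario(scenario, base / "inputs")
        config = PipelineConfig(
            peptides=files["peptides.tsv"],
            network=files["network.tsv"],
            proteome=files["proteome.fasta"],
            kinase_intensities=files["kinase_intensities.tsv"],
            regulators=files["regulators.txt"],
            out_dir=str(base / "out"),
            strain_order=params.strains,
            seed=pipeline_seed,
        )
        run_pipeline(config)
        modules_df = pd.read_csv(base / "out" / "modules.tsv", sep="\t", dtype=str)
        members = {
            mid: list(sub["peptide_id"])
            for mid, sub in modules_df.groupby("module_id")
        }
        edges = read_regulates_edges(base / "out" / "network.sif")
        score = score_regulator_recovery(
            edges,
            members,
            scenario.truth.kinase_of_peptide,
            sorted(scenario.kinase_library.entries),
            attribution_threshold,
        )
    finally:
        if ctx:
            ctx.cleanup()
    return score, scenario
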