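"""Ground-truthed synthetic scenarios for the whole pipeline.

A scenario bundles a proteome, a kinase spot-array library, a background
interaction network with planted kinase->substrate edges, and a
multi-strain phospho-peptide table, together with the ground truth used
to score recovery.  The statistical structure mirrors the data the
pipeline expects from a three-strain evolution panel profiled in
biological duplicate:

* each planted kinase has a sharp specificity PWM (symmetric Dirichlet
  columns; small concentration = sharp motif) and a set of substrate
  proteins whose phospho-site windows are sampled column-wise from it;
* decoy peptides carry uniform-random windows and a flat response;
* each kinase's substrates share one response class, so the class x
  motif module structure the pipeline looks for actually exists;
* replicate log2 fold-changes are the class mean pattern plus Gaussian
  noise;
* the network is an Erdos-Renyi background of undirected ppi edges
  plus one directed kinase_substrate edge per planted pair.

The whole bundle is a pure function of ``SimParams`` (including the
seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .classify import RESPONSIVE_LABELS
from .io import (
    AMINO_ACIDS,
    Edge,
    InteractionNetwork,
    KinaseIntensityLibrary,
    PhosphoPeptide,
    Proteome,
    write_kinase_intensities,
    write_network,
    write_peptide_table,
    write_proteome,
)
from .matching import PWM, default_flank_positions

#: protein length used for synthetic proteins; long enough that every
#: 13-mer window fits without pad characters.
_PROTEIN_LENGTH = 61
_DEFAULT_STRAINS = ("Y22-3", "Y127", "Y128")


@dataclass(frozen=True)
class SimParams:
    """Generator settings; defaults describe the benchmark scenario used
    throughout the test suite (four sharp kinases, 40 substrates each,
    400 decoys, an 800-node background network and duplicate noise of
    0.2 log2 units)."""

    n_kinases: int = 4
    substrates_per_kinase: int = 40
    n_decoy_peptides: int = 400
    n_network_nodes: int = 800
    background_edge_prob: float = 0.01
    pwm_sharpness: float = 0.05
    n_strains: int = 3
    n_replicates: int = 2
    class_effect: float = 1.0
    noise_sd: float = 0.2
    planted_class_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "A_inc": 0.25,
            "A_dec": 0.25,
            "B_inc": 0.25,
            "B_dec": 0.25,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_kinases", "substrates_per_kinase", "n_decoy_peptides",
                     "n_network_nodes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.background_edge_prob <= 1:
            raise ValueError("background_edge_prob must be in [0, 1]")
        if self.pwm_sharpness <= 0:
            raise ValueError("pwm_sharpness must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_replicates < 1 or self.n_strains < 2:
            raise ValueError("need >= 1 replicate and >= 2 strains")
        total = sum(self.planted_class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("planted_class_mix proportions must sum to 1")
        object.__setattr__(self, "planted_class_mix", dict(self.planted_class_mix))

    @property
    def strains(self) -> tuple[str, ...]:
        if self.n_strains == 3:
            return _DEFAULT_STRAINS
        return tuple(f"S{i + 1}" for i in range(self.n_strains))

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, indent=2)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimParams":
        return cls(**d)


@dataclass(frozen=True)
class GroundTruth:
    """What was planted: owning kinase and true class per peptide, plus
    the kinase->substrate edges guaranteed to be in the network."""

    kinase_of_peptide: Mapping[str, str | None]
    true_class: Mapping[str, str]
    planted_edges: frozenset


@dataclass(frozen=True)
class Scenario:
    proteome: Proteome
    kinase_library: KinaseIntensityLibrary
    network: InteractionNetwork
    peptides: tuple[PhosphoPeptide, ...]
    truth: GroundTruth
    params: SimParams


def class_pattern(label: str, class_effect: float, n_strains: int = 3) -> np.ndarray:
    """Mean log2 fold-change profile of a response class across strains.

    Progressive classes step by ``class_effect`` per strain; evolved-
    strain-specific classes are flat except for the final strain, which
    sits at the progressive endpoint (so A and B reach the same final
    amplitude and differ only in trajectory).
    """
    steps = np.arange(n_strains, dtype=float)
    if label == "A_inc":
        return class_effect * steps
    if label == "A_dec":
        return -class_effect * steps
    if label == "B_inc":
        out = np.zeros(n_strains)
        out[-1] = class_effect * (n_strains - 1)
        return out
    if label == "B_dec":
        out = np.zeros(n_strains)
        out[-1] = -class_effect * (n_strains - 1)
        return out
    if label == "none":
        return np.zeros(n_strains)
    raise ValueError(f"unknown class label {label!r}")


def sample_pwm(
    n_positions: int,
    sharpness: float,
    rng: np.random.Generator,
    positions: Sequence[int] | None = None,
) -> PWM:
    """Draw each PWM column from a symmetric Dirichlet over 20 residues.

    Smaller ``sharpness`` (the concentration parameter) gives sharper
    columns; sharpness -> infinity approaches the uniform column.
    """
    if n_positions < 1:
        raise ValueError("n_positions must be >= 1")
    if sharpness <= 0:
        raise ValueError("sharpness must be > 0")
    if positions is None:
        if n_positions % 2 == 0:
            positions = default_flank_positions(n_positions + 1)
        else:
            positions = tuple(range(1, n_positions + 1))
    matrix = rng.dirichlet(np.full(20, float(sharpness)), size=n_positions).T
    # guard against numerically degenerate draws summing slightly off 1
    matrix = matrix / matrix.sum(axis=0)
    return PWM(tuple(positions), matrix)


def generate_network(
    params: SimParams,
    truth: GroundTruth,
    rng: np.random.Generator,
    proteins: Sequence[str] = (),
) -> InteractionNetwork:
    """Erdos-Renyi ppi background plus the planted directed edges.

    Nodes are the planted kinases and substrate proteins, any extra
    ``proteins``, and anonymous filler nodes up to ``n_network_nodes``.
    """
    nodes = set(proteins)
    for e in truth.planted_edges:
        nodes.update((e.source, e.target))
    n_fill = max(0, params.n_network_nodes - len(nodes))
    nodes.update(f"N{i + 1:04d}" for i in range(n_fill))
    node_list = sorted(nodes)
    n = len(node_list)
    edges = [(e.source, e.target, e.directed, e.etype) for e in truth.planted_edges]
    if params.background_edge_prob > 0 and n > 1:
        iu, ju = np.triu_indices(n, k=1)
        mask = rng.random(iu.size) < params.background_edge_prob
        for i, j in zip(iu[mask], ju[mask]):
            edges.append((node_list[i], node_list[j], False, "ppi"))
    return InteractionNetwork.build(edges, extra_nodes=node_list)


def _sample_window(
    rng: np.random.Generator,
    pwm: PWM | None,
    width: int = 13,
) -> str:
    """A width-13 window with a random S/T centre; flanks from the PWM
    columns when one is given, otherwise uniform over the 20 residues."""
    half = width // 2
    chars = []
    aa = np.array(list(AMINO_ACIDS))
    for pos in range(-half, half + 1):
        if pos == 0:
            chars.append("S" if rng.random() < 0.5 else "T")
        elif pwm is not None and pos in pwm.positions:
            col = pwm.matrix[:, pwm.positions.index(pos)]
            chars.append(str(rng.choice(aa, p=col)))
        else:
            chars.append(str(aa[rng.integers(20)]))
    return "".join(chars)


def generate_peptide_table(
    params: SimParams,
    truth: GroundTruth,
    kinase_pwms: Mapping[str, PWM],
    rng: np.random.Generator,
) -> tuple[PhosphoPeptide, ...]:
    """Realize windows, site positions and replicate fold-changes.

    Peptide identifiers are ``<protein>_1`` (one peptide per synthetic
    protein); the protein identifier is recovered by stripping the
    suffix.  Replicate values are the class mean pattern plus
    ``Normal(0, noise_sd)`` noise.
    """
    peptides = []
    strains = params.strains
    for peptide_id in sorted(truth.true_class):
        protein_id = peptide_id.rsplit("_", 1)[0]
        kinase = truth.kinase_of_peptide.get(peptide_id)
        pwm = kinase_pwms[kinase] if kinase else None
        window = _sample_window(rng, pwm)
        site_pos = int(rng.integers(7, _PROTEIN_LENGTH - 5))
        pattern = class_pattern(
            truth.true_class[peptide_id], params.class_effect, params.n_strains
        )
        log2fc = {}
        for s, mean in zip(strains, pattern):
            noise = rng.normal(0.0, params.noise_sd, size=params.n_replicates)
            log2fc[s] = tuple(float(mean + e) for e in noise)
        peptides.append(
            PhosphoPeptide(
                peptide_id=peptide_id,
                protein_id=protein_id,
                site_pos=site_pos,
                window=window,
                log2fc=log2fc,
            )
        )
    return tuple(peptides)


def _build_proteome(
    peptides: Sequence[PhosphoPeptide], rng: np.random.Generator
) -> Proteome:
    aa = np.array(list(AMINO_ACIDS))
    sequences = {}
    for p in peptides:
        seq = list(aa[rng.integers(0, 20, size=_PROTEIN_LENGTH)])
        start = p.site_pos - 7  # 0-based start of the 13-mer
        for off, res in enumerate(p.window):
            seq[start + off] = res
        sequences[p.protein_id] = "".join(seq)
    return Proteome(sequences)


def generate_scenario(params: SimParams) -> Scenario:
    """Generate a complete, internally consistent scenario bundle."""
    ss = np.random.SeedSequence(params.seed)
    rng_pwm, rng_truth, rng_table, rng_net, rng_prot = (
        np.random.default_rng(c) for c in ss.spawn(5)
    )

    kinases = [f"K{i + 1:02d}" for i in range(params.n_kinases)]
    pwms = {k: sample_pwm(12, params.pwm_sharpness, rng_pwm) for k in kinases}

    labels = [l for l in RESPONSIVE_LABELS if params.planted_class_mix.get(l, 0) > 0]
    if kinases and not labels:
        raise ValueError("planted_class_mix gives no mass to any responsive class")
    probs = np.array([params.planted_class_mix[l] for l in labels])
    probs = probs / probs.sum()

    kinase_of_peptide: dict[str, str | None] = {}
    true_class: dict[str, str] = {}
    planted_edges = set()
    for k in kinases:
        k_class = labels[rng_truth.choice(len(labels), p=probs)]
        for j in range(params.substrates_per_kinase):
            protein = f"{k}S{j + 1:03d}"
            peptide = f"{protein}_1"
            kinase_of_peptide[peptide] = k
            true_class[peptide] = k_class
            planted_edges.add(Edge(k, protein, True, "kinase_substrate"))
    for j in range(params.n_decoy_peptides):
        peptide = f"D{j + 1:04d}_1"
        kinase_of_peptide[peptide] = None
        true_class[peptide] = "none"

    truth = GroundTruth(kinase_of_peptide, true_class, frozenset(planted_edges))
    peptides = generate_peptide_table(params, truth, pwms, rng_table)
    proteome = _build_proteome(peptides, rng_prot)
    network = generate_network(
        params, truth, rng_net, proteins=[p.protein_id for p in peptides]
    )
    # spot-array intensities on a 0-100 scale, so downstream PWM
    # normalization is exercised nontrivially
    library = KinaseIntensityLibrary(
        entries={k: pwms[k].matrix * 100.0 for k in kinases},
        position_labels={k: pwms[k].positions for k in kinases},
    )
    return Scenario(proteome, library, network, peptides, truth, params)


def write_scenario(scenario: Scenario, out_dir) -> dict[str, str]:
    """Write the scenario in the formats the pipeline reads, plus the
    ground truth, regulator list and generator config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_peptide_table(scenario.peptides, out / "peptides.tsv")
    write_network(scenario.network, out / "network.tsv")
    write_proteome(scenario.proteome, out / "proteome.fasta")
    write_kinase_intensities(scenario.kinase_library, out / "kinase_intensities.tsv")
    with open(out / "regulators.txt", "w") as fh:
        for k in sorted(scenario.kinase_library.entries):
            fh.write(k + "\n")
    with open(out / "ground_truth.tsv", "w") as fh:
        fh.write("peptide_id\tkinase\ttrue_class\n")
        for pid in sorted(scenario.truth.true_class):
            kin = scenario.truth.kinase_of_peptide.get(pid) or ""
            fh.write(f"{pid}\t{kin}\t{scenario.truth.true_class[pid]}\n")
    with open(out / "sim_config.json", "w") as fh:
        fh.write(scenario.params.to_json() + "\n")
    return {
        name: str(out / name)
        for name in (
            "peptides.tsv",
            "network.tsv",
            "proteome.fasta",
            "kinase_intensities.tsv",
            "regulators.txt",
            "ground_truth.tsv",
            "sim_config.json",
        )
    }
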