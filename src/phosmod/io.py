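"""Readers and writers for the pipeline's on-disk formats.

Phospho-peptide tables, interaction-network edge lists and kinase
spot-array intensities travel as TSV; proteomes as FASTA; network
exports as Cytoscape SIF (three tab-separated columns).  All writers
emit deterministically ordered output so that a run with a fixed seed
reproduces its files byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Canonical amino-acid row order used by every matrix in the package.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
#: Pad character used beyond protein termini in sequence windows.
PAD = "-"
CENTRAL_RESIDUES = frozenset("STY")
EDGE_TYPES = frozenset({"ppi", "kinase_substrate"})
#: Format used for every floating-point cell written to a result table.
FLOAT_FORMAT = "%.6g"


class FormatError(ValueError):
    """An input file violates its documented schema."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhosphoPeptide:
    """One localized phospho-site with its sequence context and response.

    Parameters
    ----------
    peptide_id, protein_id : str
        Identifiers for the peptide record and its parent protein.
    site_pos : int
        1-based position of the phosphorylated residue in the protein.
    window : str
        13-character sequence window (positions -6..+6 around the site),
        padded with ``-`` beyond the protein termini.  Stored uppercase;
        rendering with a lowercase centre is cosmetic only.
    log2fc : mapping
        strain -> tuple of replicate-level log2 fold-changes for the
        condition contrast defined by the run configuration.
    """

    peptide_id: str
    protein_id: str
    site_pos: int
    window: str
    log2fc: Mapping[str, tuple[float, ...]]

    def __post_init__(self) -> None:
        if len(self.window) != 13:
            raise FormatError(
                f"{self.peptide_id}: window must have length 13, got {len(self.window)}"
            )
        if self.central_residue not in CENTRAL_RESIDUES:
            raise FormatError(
                f"{self.peptide_id}: central residue {self.window[6]!r} is not S/T/Y"
            )
        if self.site_pos < 1:
            raise FormatError(f"{self.peptide_id}: site_pos must be >= 1")
        object.__setattr__(
            self,
            "log2fc",
            {s: tuple(float(v) for v in vals) for s, vals in self.log2fc.items()},
        )
        for strain, vals in self.log2fc.items():
            if len(vals) == 0:
                raise FormatError(
                    f"{self.peptide_id}: strain {strain} has no replicate values"
                )

    @property
    def central_residue(self) -> str:
        return self.window[6].upper()


@dataclass(frozen=True, order=True)
class Edge:
    """A typed, optionally directed interaction between two proteins."""

    source: str
    target: str
    directed: bool
    etype: str


def _canonical_edge(source: str, target: str, directed: bool, etype: str) -> Edge:
    if etype not in EDGE_TYPES:
        raise FormatError(f"unknown edge type {etype!r}")
    if not directed and target < source:
        source, target = target, source
    return Edge(source, target, bool(directed), etype)


@dataclass(frozen=True)
class InteractionNetwork:
    """Background protein-interaction network.

    Undirected edges are stored with lexicographically ordered endpoints;
    a directed A->B edge and an undirected {A,B} edge are distinct
    records.  Self-loops are dropped at construction time.
    """

    nodes: frozenset
    edges: frozenset

    @classmethod
    def build(
        cls,
        edges: Iterable[tuple[str, str, bool, str]],
        extra_nodes: Iterable[str] = (),
    ) -> "InteractionNetwork":
        canon: set[Edge] = set()
        n_loops = 0
        for source, target, directed, etype in edges:
            if source == target:
                n_loops += 1
                continue
            canon.add(_canonical_edge(source, target, directed, etype))
        if n_loops:
            logger.warning("dropped %d self-loop edge(s)", n_loops)
        nodes = {n for e in canon for n in (e.source, e.target)} | set(extra_nodes)
        return cls(frozenset(nodes), frozenset(canon))

    @cached_property
    def partners(self) -> dict[str, frozenset]:
        """node -> distinct interaction partners (any type or direction)."""
        adj: dict[str, set] = {n: set() for n in self.nodes}
        for e in self.edges:
            adj[e.source].add(e.target)
            adj[e.target].add(e.source)
        return {n: frozenset(p) for n, p in adj.items()}

    @cached_property
    def directed_out(self) -> dict[str, tuple[str, ...]]:
        """node -> targets of its outgoing directed edges (with multiplicity)."""
        out: dict[str, list] = {n: [] for n in self.nodes}
        for e in self.edges:
            if e.directed:
                out[e.source].append(e.target)
        return {n: tuple(sorted(t)) for n, t in out.items()}

    @cached_property
    def directed_in(self) -> dict[str, tuple[str, ...]]:
        inc: dict[str, list] = {n: [] for n in self.nodes}
        for e in self.edges:
            if e.directed:
                inc[e.target].append(e.source)
        return {n: tuple(sorted(s)) for n, s in inc.items()}


@dataclass
class KinaseIntensityLibrary:
    """Spot-array style kinase specificity matrices.

    entries maps kinase name -> non-negative (20, P) intensity matrix with
    rows in :data:`AMINO_ACIDS` order; position_labels gives the P position
    offsets (relative to the phospho-site, 0 excluded) per kinase.
    """

    entries: dict[str, np.ndarray]
    position_labels: dict[str, tuple[int, ...]]

    def __post_init__(self) -> None:
        for kinase, mat in self.entries.items():
            mat = np.asarray(mat, dtype=float)
            if mat.ndim != 2 or mat.shape[0] != 20 or mat.shape[1] < 1:
                raise FormatError(f"{kinase}: intensity matrix must be 20 x P, P >= 1")
            if (mat < 0).any():
                raise FormatError(f"{kinase}: negative intensity")
            if len(self.position_labels[kinase]) != mat.shape[1]:
                raise FormatError(f"{kinase}: position labels do not match matrix")
            self.entries[kinase] = mat


@dataclass(frozen=True)
class Proteome:
    """Uppercase amino-acid sequences keyed by protein identifier."""

    sequences: Mapping[str, str]

    def __post_init__(self) -> None:
        for pid, seq in self.sequences.items():
            if not seq:
                raise FormatError(f"empty sequence for {pid}")


@dataclass(frozen=True)
class AnnotationSets:
    """Named feature sets plus the background universe they live in."""

    sets: Mapping[str, frozenset]
    background: frozenset

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            stray = set(members) - self.background
            if stray:
                raise FormatError(
                    f"annotation set {name} has features outside the background: "
                    f"{sorted(stray)[:5]}"
                )


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_peptide_table(path, strains: Sequence[str]) -> list[PhosphoPeptide]:
    """Read a phospho-peptide TSV.

    Required columns: ``peptide_id``, ``protein_id``, ``site_pos``,
    ``window`` plus one ``<strain>_rep<k>_log2fc`` column per strain and
    replicate.  Rows whose window is malformed (length != 13 or non-S/T/Y
    centre) are rejected and counted in the log.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("peptide_id", "protein_id", "site_pos", "window"):
        if col not in df.columns:
            raise FormatError(f"peptide table is missing required column {col!r}")
    rep_cols: dict[str, list[str]] = {}
    for strain in strains:
        pat = re.compile(rf"^{re.escape(strain)}_rep(\d+)_log2fc$")
        cols = sorted(
            (c for c in df.columns if pat.match(c)),
            key=lambda c: int(pat.match(c).group(1)),
        )
        if not cols:
            raise FormatError(
                f"peptide table is missing replicate columns for strain {strain!r} "
                f"(expected pattern '{strain}_rep<k>_log2fc')"
            )
        rep_cols[strain] = cols

    peptides: list[PhosphoPeptide] = []
    n_rejected = 0
    columns = list(df.columns)
    for i, row in enumerate(df.itertuples(index=False, name=None), start=2):
        rec = dict(zip(columns, row))  # header = line 1
        window = str(rec["window"]).upper()
        if len(window) != 13 or window[6] not in CENTRAL_RESIDUES:
            n_rejected += 1
            continue
        try:
            site_pos = int(rec["site_pos"])
        except (TypeError, ValueError):
            raise FormatError(f"non-integer site_pos at line {i}") from None
        log2fc = {}
        for strain, cols in rep_cols.items():
            vals = []
            for c in cols:
                try:
                    vals.append(float(rec[c]))
                except (TypeError, ValueError):
                    raise FormatError(
                        f"non-numeric fold-change in column {c!r} at line {i}"
                    ) from None
            log2fc[strain] = tuple(vals)
        peptides.append(
            PhosphoPeptide(
                peptide_id=str(rec["peptide_id"]),
                protein_id=str(rec["protein_id"]),
                site_pos=site_pos,
                window=window,
                log2fc=log2fc,
            )
        )
    if n_rejected:
        logger.warning("rejected %d malformed peptide row(s)", n_rejected)
    if not peptides:
        logger.warning("peptide table %s produced no peptides", path)
    return peptides


def write_peptide_table(peptides: Sequence[PhosphoPeptide], path) -> None:
    strains = list(peptides[0].log2fc) if peptides else []
    rows = []
    for p in peptides:
        row = {
            "peptide_id": p.peptide_id,
            "protein_id": p.protein_id,
            "site_pos": p.site_pos,
            "window": p.window,
        }
        for s in strains:
            for k, v in enumerate(p.log2fc[s], start=1):
                row[f"{s}_rep{k}_log2fc"] = repr(v)
        rows.append(row)
    cols = ["peptide_id", "protein_id", "site_pos", "window"] + [
        f"{s}_rep{k}_log2fc"
        for s in strains
        for k in range(1, len(peptides[0].log2fc[s]) + 1)
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_network(path) -> InteractionNetwork:
    """Read a TSV edge list with columns source, target, directed (0/1), etype."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("source", "target", "directed", "etype"):
        if col not in df.columns:
            raise FormatError(f"network file is missing required column {col!r}")
    edges = []
    for row in df.itertuples(index=False):
        try:
            directed = bool(int(row.directed))
        except (TypeError, ValueError):
            raise FormatError(f"directed flag must be 0/1, got {row.directed!r}") from None
        edges.append((str(row.source), str(row.target), directed, str(row.etype)))
    return InteractionNetwork.build(edges)


def write_network(network: InteractionNetwork, path) -> None:
    rows = sorted(
        (e.source, e.target, int(e.directed), e.etype) for e in network.edges
    )
    pd.DataFrame(rows, columns=["source", "target", "directed", "etype"]).to_csv(
        path, sep="\t", index=False
    )


def read_kinase_intensities(path) -> KinaseIntensityLibrary:
    """Read a long-format TSV (kinase, position, residue, intensity)."""
    df = pd.read_csv(path, sep="\t", dtype={"kinase": str, "residue": str})
    for col in ("kinase", "position", "residue", "intensity"):
        if col not in df.columns:
            raise FormatError(f"intensity file is missing required column {col!r}")
    entries: dict[str, np.ndarray] = {}
    labels: dict[str, tuple[int, ...]] = {}
    for kinase, sub in df.groupby("kinase", sort=True):
        positions = sorted(int(p) for p in sub["position"].unique())
        mat = np.zeros((20, len(positions)), dtype=float)
        for j, pos in enumerate(positions):
            cell = sub[sub["position"] == pos]
            if cell.duplicated(subset="residue").any():
                raise FormatError(
                    f"duplicate intensity cell for kinase {kinase}, position {pos}"
                )
            residues = set(cell["residue"])
            if residues != set(AMINO_ACIDS):
                missing = sorted(set(AMINO_ACIDS) - residues)
                raise FormatError(
                    f"kinase {kinase}, position {pos}: missing residue(s) {missing}"
                )
            for res, inten in zip(cell["residue"], cell["intensity"]):
                val = float(inten)
                if val < 0:
                    raise FormatError(
                        f"negative intensity for kinase {kinase}, position {pos}"
                    )
                mat[AA_INDEX[res], j] = val
        entries[str(kinase)] = mat
        labels[str(kinase)] = tuple(positions)
    return KinaseIntensityLibrary(entries, labels)


def write_kinase_intensities(library: KinaseIntensityLibrary, path) -> None:
    rows = []
    for kinase in sorted(library.entries):
        mat = library.entries[kinase]
        for j, pos in enumerate(library.position_labels[kinase]):
            for i, res in enumerate(AMINO_ACIDS):
                rows.append((kinase, pos, res, repr(float(mat[i, j]))))
    pd.DataFrame(rows, columns=["kinase", "position", "residue", "intensity"]).to_csv(
        path, sep="\t", index=False
    )


def read_proteome(path) -> Proteome:
    """Read a FASTA proteome; identifiers are the first header token."""
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        pid = record.id
        if pid in sequences:
            raise FormatError(f"duplicate protein identifier {pid!r}")
        seq = str(record.seq).upper()
        if not seq:
            raise FormatError(f"empty record for {pid!r}")
        sequences[pid] = seq
    return Proteome(sequences)


def write_proteome(proteome: Proteome, path) -> None:
    with open(path, "w") as fh:
        for pid in sorted(proteome.sequences):
            fh.write(f">{pid}\n")
            seq = proteome.sequences[pid]
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def read_annotation_sets(path, background: Iterable[str] | None = None) -> AnnotationSets:
    """Read a TSV (set_name, feature); background defaults to the union."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("set_name", "feature"):
        if col not in df.columns:
            raise FormatError(f"annotation file is missing required column {col!r}")
    sets = {
        str(name): frozenset(sub["feature"].astype(str))
        for name, sub in df.groupby("set_name", sort=True)
    }
    if background is None:
        bg = frozenset().union(*sets.values()) if sets else frozenset()
    else:
        bg = frozenset(background)
    return AnnotationSets(sets, bg)


# ---------------------------------------------------------------------------
# Writers for pipeline outputs
# ---------------------------------------------------------------------------


def write_sif(edges: Sequence[tuple[str, str, str]], path) -> None:
    """Write (source, relation, target) triples as Cytoscape SIF."""
    lines = []
    for source, relation, target in edges:
        if not relation or any(c.isspace() for c in relation):
            raise FormatError(f"invalid SIF relation {relation!r}")
        if "\t" in source or "\t" in target:
            raise FormatError("node names must not contain tabs")
        lines.append(f"{source}\t{relation}\t{target}\n")
    with open(path, "w") as fh:
        fh.writelines(lines)


#: Preferred leading sort columns for result tables (identifier-ish first).
_SORT_PRIORITY = (
    "class",
    "module_id",
    "kinase",
    "regulator",
    "set_name",
    "protein_id",
    "peptide_id",
    "feature_id",
)


def _sorted_table(df: pd.DataFrame) -> pd.DataFrame:
    if df.empty:
        return df
    by = [c for c in _SORT_PRIORITY if c in df.columns]
    by += [c for c in df.columns if c not in by]
    return df.sort_values(by=by, kind="mergesort").reset_index(drop=True)


def sha256_of_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_result_tables(
    tables: Mapping[str, pd.DataFrame],
    out_dir,
    *,
    config: Mapping | None = None,
    seed: int | None = None,
    input_checksums: Mapping[str, str] | None = None,
) -> dict:
    """Write result tables plus a JSON run manifest; return the manifest.

    Tables are sorted deterministically and floats rendered with six
    significant digits, so identical inputs and seed yield byte-identical
    files.  The manifest records the config hash, the seed and SHA-256
    checksums of all inputs and outputs (no timestamps, by design).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    for name in sorted(tables):
        path = out_dir / f"{name}.tsv"
        _sorted_table(tables[name]).to_csv(
            path, sep="\t", index=False, float_format=FLOAT_FORMAT
        )
        outputs[path.name] = sha256_of_file(path)
    config_json = json.dumps(config or {}, sort_keys=True, default=str)
    manifest = {
        "config_hash": hashlib.sha256(config_json.encode()).hexdigest(),
        "seed": seed,
        "inputs": dict(sorted((input_checksums or {}).items())),
        "outputs": outputs,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
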