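"""Iterative greedy phospho-motif extraction (motif-x style).

Aligned 13-mer windows centred on a phospho-acceptor are partitioned
into modules of peptides sharing a motif.  The algorithm repeatedly
fixes the single (position, residue) pair with the smallest one-sided
binomial tail probability against the running background frequency,
restricts both foreground and background to matching windows, and emits
a motif when no further pair passes the occurrence and significance
thresholds.  Matched windows are removed from the foreground and
extraction restarts on the remainder.

Serine- and threonine-centred windows are processed separately; each
emitted module carries its central residue.  Pad characters beyond the
protein termini never count as residue occurrences and are excluded
from both numerator and denominator at their position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .io import AA_INDEX, AMINO_ACIDS, PAD, Proteome

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MotifParams:
    """Extraction thresholds: window width, admissible central residues,
    minimum motif occurrences and binomial significance cut-off."""

    width: int = 13
    central_residues: frozenset = frozenset({"S", "T"})
    min_occurrences: int = 10
    significance: float = 1e-6

    def __post_init__(self) -> None:
        if self.width < 3 or self.width % 2 == 0:
            raise ValueError("width must be odd and >= 3")
        if not 0 < self.significance < 1:
            raise ValueError("significance must be in (0, 1)")
        object.__setattr__(self, "central_residues", frozenset(self.central_residues))


@dataclass(frozen=True)
class Motif:
    """A set of fixed (position, residue) pairs around a central S/T/Y.

    Positions are offsets relative to the phospho-site (0 excluded).
    """

    central: str
    fixed: frozenset
    width: int = 13

    def pattern(self) -> str:
        half = self.width // 2
        chars = ["."] * self.width
        chars[half] = self.central.lower()
        for pos, res in self.fixed:
            chars[half + pos] = res
        return "".join(chars)

    def matches(self, window: str) -> bool:
        half = len(window) // 2
        if window[half].upper() != self.central:
            return False
        return all(window[half + pos].upper() == res for pos, res in self.fixed)


@dataclass(frozen=True)
class Module:
    """Peptides of one response class sharing one phospho-motif."""

    module_id: str
    class_label: str
    motif: Motif
    peptide_ids: frozenset
    protein_ids: frozenset


def extract_window(proteome: Proteome, protein_id: str, site_pos: int, width: int = 13) -> str:
    """Window of ``width`` residues centred at ``site_pos`` (1-based),
    padded with ``-`` beyond the protein termini."""
    seq = proteome.sequences[protein_id]
    if not 1 <= site_pos <= len(seq):
        raise ValueError(f"site {site_pos} out of range for {protein_id} (len {len(seq)})")
    half = width // 2
    i = site_pos - 1
    left = seq[max(0, i - half) : i]
    right = seq[i + 1 : i + 1 + half]
    return PAD * (half - len(left)) + left + seq[i] + right + PAD * (half - len(right))


def background_windows(
    proteome: Proteome, central_residues: frozenset, width: int = 13
) -> list[str]:
    """One window per occurrence of each central residue in the proteome."""
    windows = []
    for pid in sorted(proteome.sequences):
        seq = proteome.sequences[pid]
        for i, res in enumerate(seq):
            if res in central_residues:
                windows.append(extract_window(proteome, pid, i + 1, width))
    return windows


def binomial_tail(k: int, n: int, p0: float) -> float:
    """Upper tail P(X >= k) for X ~ Binomial(n, p0)."""
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 <= p0 <= 1.0:
        raise ValueError(f"p0 must be in [0, 1], got {p0}")
    if k == 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, p0))


def _encode(windows: Sequence[str], width: int) -> np.ndarray:
    table = np.full(128, -1, dtype=np.int8)
    for aa, idx in AA_INDEX.items():
        table[ord(aa)] = idx
    flat = np.frombuffer("".join(w.upper() for w in windows).encode(), dtype=np.uint8)
    return table[flat].reshape(len(windows), width)


def _counts(enc: np.ndarray, width: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-position residue counts (width, 20) and non-pad totals (width,)."""
    counts = np.zeros((width, 20), dtype=np.int64)
    for r in range(20):
        counts[:, r] = (enc == r).sum(axis=0)
    return counts, counts.sum(axis=1)


def _extract_one_motif(
    fg: np.ndarray, bg: np.ndarray, params: MotifParams
) -> tuple[list[tuple[int, str]], np.ndarray] | None:
    """Greedy fixation loop; returns (fixed pairs, member mask) or None."""
    width = params.width
    half = width // 2
    fg_mask = np.ones(len(fg), dtype=bool)
    bg_mask = np.ones(len(bg), dtype=bool)
    fixed: list[tuple[int, str]] = []
    fixed_cols: set[int] = set()
    while True:
        fg_counts, fg_n = _counts(fg[fg_mask], width)
        bg_counts, bg_n = _counts(bg[bg_mask], width)
        best = None
        for col in range(width):
            if col == half or col in fixed_cols:
                continue
            n = int(fg_n[col])
            n_bg = int(bg_n[col])
            if n == 0 or n_bg == 0:
                continue
            for r in range(20):
                k = int(fg_counts[col, r])
                if k < params.min_occurrences:
                    continue
                p0 = bg_counts[col, r] / n_bg
                p = binomial_tail(k, n, p0)
                if p > params.significance:
                    continue
                # tie-break: smaller p, larger k, smaller |offset|, then
                # position and residue lexicographically
                key = (p, -k, abs(col - half), col - half, AMINO_ACIDS[r])
                if best is None or key < best[0]:
                    best = (key, col, r)
        if best is None:
            break
        _, col, r = best
        fixed.append((col - half, AMINO_ACIDS[r]))
        fixed_cols.add(col)
        fg_mask &= fg[:, col] == r
        bg_mask &= bg[:, col] == r
    if fixed and int(fg_mask.sum()) >= params.min_occurrences:
        return fixed, fg_mask
    return None


def motifx_partition(
    foreground: Sequence[tuple[str, str]],
    background: Sequence[str],
    params: MotifParams,
    class_label: str = "",
    protein_of: Mapping[str, str] | None = None,
) -> tuple[list[Module], list[str]]:
    """Partition foreground windows into motif modules.

    Parameters
    ----------
    foreground : sequence of (peptide_id, window)
    background : sequence of windows (typically every proteome window
        centred on an admissible residue)
    class_label : response class recorded on the emitted modules; also
        prefixes the module identifiers.
    protein_of : optional peptide_id -> protein_id map used to fill in
        module protein sets.

    Returns the modules and the peptide ids left unassigned.
    """
    if not background:
        raise ValueError("background window collection is empty")
    width = params.width
    for _, w in foreground:
        if len(w) != width:
            raise ValueError(f"foreground window of width {len(w)} != {width}")
    protein_of = protein_of or {}
    half = width // 2
    modules: list[Module] = []
    unassigned: list[str] = []
    bg_enc_all = _encode(background, width)
    bg_central = np.array([w[half].upper() for w in background])
    for central in sorted(params.central_residues):
        fg_items = [(pid, w) for pid, w in foreground if w[half].upper() == central]
        if not fg_items:
            continue
        fg_enc = _encode([w for _, w in fg_items], width)
        bg_enc = bg_enc_all[bg_central == central]
        if len(bg_enc) == 0:
            logger.warning("no background windows centred on %s; skipping", central)
            unassigned.extend(pid for pid, _ in fg_items)
            continue
        remaining = np.ones(len(fg_items), dtype=bool)
        while remaining.sum() >= params.min_occurrences:
            idx = np.flatnonzero(remaining)
            result = _extract_one_motif(fg_enc[idx], bg_enc, params)
            if result is None:
                break
            fixed, member_mask = result
            members = idx[member_mask]
            motif = Motif(central=central, fixed=frozenset(fixed), width=width)
            pep_ids = frozenset(fg_items[i][0] for i in members)
            prot_ids = frozenset(protein_of.get(p, p) for p in pep_ids)
            prefix = f"{class_label}:" if class_label else ""
            modules.append(
                Module(
                    module_id=f"{prefix}{motif.pattern()}",
                    class_label=class_label,
                    motif=motif,
                    peptide_ids=pep_ids,
                    protein_ids=prot_ids,
                )
            )
            remaining[members] = False
        unassigned.extend(fg_items[i][0] for i in np.flatnonzero(remaining))
    # peptides whose centre is not an admissible residue are unassigned too
    unassigned.extend(
        pid
        for pid, w in foreground
        if w[half].upper() not in params.central_residues
    )
    return modules, unassigned
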