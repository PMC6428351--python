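"""Kinase-to-module specificity matching by Kullback-Leibler divergence.

Kinase spot-array intensity matrices and module peptide windows are both
converted to pseudocounted, column-stochastic position weight matrices
(PWMs).  A candidate kinase is scored against a module as
``D(module || kinase)`` in bits over their common positions (the fixed
central S/T carries no information and is excluded); smaller divergence
means a better match.  Significance is an empirical FDR: each kinase
PWM in the library is shuffled -- residues permuted independently within
each column, then the column order permuted -- ``n_shuffles`` times, all
shuffled matrices are scored against the module PWM to form a pooled
null, and the FDR is the fraction of null scores *smaller* (better)
than the observed score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import AA_INDEX, KinaseIntensityLibrary, PAD

logger = logging.getLogger(__name__)


def default_flank_positions(width: int = 13) -> tuple[int, ...]:
    """Offsets -(w//2)..+(w//2) excluding the central 0."""
    half = width // 2
    return tuple(p for p in range(-half, half + 1) if p != 0)


@dataclass(frozen=True)
class PWM:
    """Column-stochastic position x amino-acid matrix.

    ``matrix`` has shape (20, P), rows in :data:`phosmod.io.AMINO_ACIDS`
    order; ``positions`` labels the P columns with offsets relative to
    the phospho-site (0 excluded).
    """

    positions: tuple[int, ...]
    matrix: np.ndarray
    pseudocount_used: float = 0.0

    def __post_init__(self) -> None:
        mat = np.asarray(self.matrix, dtype=float)
        if mat.shape != (20, len(self.positions)):
            raise ValueError("PWM matrix must be 20 x len(positions)")
        if not np.allclose(mat.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("PWM columns must each sum to 1")
        if (mat < 0).any():
            raise ValueError("PWM entries must be non-negative")
        object.__setattr__(self, "matrix", mat)
        object.__setattr__(self, "positions", tuple(int(p) for p in self.positions))


@dataclass(frozen=True)
class MatchParams:
    pseudocount: float = 0.01
    n_shuffles: int = 1000
    match_fdr_threshold: float = 0.05
    rng_seed: int = 0
    null: str = "pooled"  # or "per-kinase"

    def __post_init__(self) -> None:
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        if self.n_shuffles < 1:
            raise ValueError("n_shuffles must be >= 1")
        if self.null not in ("pooled", "per-kinase"):
            raise ValueError("null must be 'pooled' or 'per-kinase'")


@dataclass(frozen=True)
class MatchResult:
    kinase: str
    module_id: str
    kld: float
    null_size: int
    n_null_smaller: int

    @property
    def fdr(self) -> float:
        return self.n_null_smaller / self.null_size


def pwm_from_intensities(
    matrix: np.ndarray,
    positions: Sequence[int],
    pseudocount: float = 0.01,
) -> PWM:
    """Normalize a (20, P) non-negative intensity matrix column-wise.

    The pseudocount is added to every cell before dividing by the column
    total, removing zeros so the PWM can serve as the reference
    distribution of a KL divergence.
    """
    mat = np.asarray(matrix, dtype=float)
    if (mat < 0).any():
        raise ValueError("intensities must be non-negative")
    mat = mat + pseudocount
    totals = mat.sum(axis=0)
    if (totals == 0).any():
        bad = [positions[j] for j in np.flatnonzero(totals == 0)]
        raise ValueError(f"all-zero column(s) at position(s) {bad} with pseudocount 0")
    return PWM(tuple(positions), mat / totals, pseudocount)


def pwm_from_windows(
    windows: Sequence[str],
    pseudocount: float = 0.01,
    positions: Sequence[int] | None = None,
) -> PWM:
    """Residue-frequency PWM from aligned sequence windows.

    Pad characters are excluded from the counts, so the effective count
    at each position is the number of non-pad windows there.
    """
    if not windows:
        raise ValueError("no windows given")
    width = len(windows[0])
    if any(len(w) != width for w in windows):
        raise ValueError("windows must share one width")
    if positions is None:
        positions = default_flank_positions(width)
    half = width // 2
    cols = []
    for pos in positions:
        counts = np.zeros(20)
        n_eff = 0
        for w in windows:
            res = w[half + pos].upper()
            if res == PAD:
                continue
            if res in AA_INDEX:
                counts[AA_INDEX[res]] += 1
                n_eff += 1
        if n_eff == 0 and pseudocount == 0:
            raise ValueError(f"every window is padded at position {pos:+d}")
        cols.append((counts + pseudocount) / (n_eff + 20 * pseudocount))
    return PWM(tuple(positions), np.column_stack(cols), pseudocount)


def kld(p: PWM, q: PWM) -> float:
    """Kullback-Leibler divergence D(p || q) in bits over common positions.

    Terms with p = 0 contribute 0; q must be strictly positive wherever
    p is positive (guaranteed when q was built with a pseudocount).
    """
    common = [pos for pos in p.positions if pos in q.positions]
    if not common:
        raise ValueError("PWMs share no positions")
    pi = [p.positions.index(c) for c in common]
    qi = [q.positions.index(c) for c in common]
    pm = p.matrix[:, pi]
    qm = q.matrix[:, qi]
    if np.any((qm <= 0) & (pm > 0)):
        raise ValueError("q has a zero where p is positive; use a pseudocount")
    mask = pm > 0
    return float(np.sum(pm[mask] * np.log2(pm[mask] / qm[mask])))


def shuffle_pwm(pwm: PWM, rng: np.random.Generator) -> PWM:
    """Permute values within each column, then permute the column order.

    Position labels stay attached to their slots, so slot i keeps label
    i while the values move; column-stochasticity is preserved exactly.
    """
    mat = pwm.matrix.copy()
    for j in range(mat.shape[1]):
        mat[:, j] = mat[rng.permutation(20), j]
    mat = mat[:, rng.permutation(mat.shape[1])]
    return PWM(pwm.positions, mat, pwm.pseudocount_used)


def _shuffled_batch(matrix: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """n shuffled copies of a (20, P) matrix, shape (n, 20, P).

    Same null as :func:`shuffle_pwm` (independent within-column
    permutations followed by a column permutation), vectorized.
    """
    n_pos = matrix.shape[1]
    row_perm = np.argsort(rng.random((n, 20, n_pos)), axis=1)
    out = np.take_along_axis(np.broadcast_to(matrix, (n, 20, n_pos)), row_perm, axis=1)
    col_perm = np.argsort(rng.random((n, n_pos)), axis=1)
    return np.take_along_axis(out, col_perm[:, None, :], axis=2)


def _batch_kld(pm: np.ndarray, q_batch: np.ndarray) -> np.ndarray:
    """D(pm || q) for each q in a batch; pm (20, P), q_batch (n, 20, P)."""
    mask = pm > 0
    ref = np.sum(pm[mask] * np.log2(pm[mask]))
    cross = np.einsum("ap,nap->n", np.where(mask, pm, 0.0), np.log2(q_batch))
    return ref - cross


def match_kinases(
    module_pwms: Mapping[str, PWM],
    kinase_library: Mapping[str, PWM],
    candidates: Mapping[str, Iterable[str]],
    params: MatchParams,
) -> list[MatchResult]:
    """Score candidate kinases against module PWMs with an empirical FDR.

    For each module a null distribution is built by shuffling every
    library PWM ``n_shuffles`` times (pooled null of size
    ``n_shuffles * len(library)``; with ``null='per-kinase'`` each
    candidate is compared only against its own kinase's shuffles).  The
    FDR of an observed score is the fraction of null scores strictly
    smaller than it; ties do not count against the match.  Results for
    all candidates are returned; callers filter on
    ``params.match_fdr_threshold``.
    """
    results: list[MatchResult] = []
    ss = np.random.SeedSequence(params.rng_seed)
    module_ids = sorted(module_pwms)
    children = ss.spawn(len(module_ids))
    lib_names = sorted(kinase_library)
    for child, module_id in zip(children, module_ids):
        rng = np.random.default_rng(child)
        module_pwm = module_pwms[module_id]
        null_scores: dict[str, np.ndarray] = {}
        for name in lib_names:
            kin = kinase_library[name]
            common = [pos for pos in module_pwm.positions if pos in kin.positions]
            if not common:
                continue
            batch = _shuffled_batch(kin.matrix, params.n_shuffles, rng)
            qi = [kin.positions.index(c) for c in common]
            pi = [module_pwm.positions.index(c) for c in common]
            null_scores[name] = _batch_kld(
                module_pwm.matrix[:, pi], batch[:, :, qi]
            )
        pooled = (
            np.concatenate([null_scores[n] for n in lib_names if n in null_scores])
            if null_scores
            else np.empty(0)
        )
        for kinase in sorted(set(candidates.get(module_id, ()))):
            if kinase not in kinase_library:
                logger.warning(
                    "candidate %s for module %s absent from kinase library",
                    kinase,
                    module_id,
                )
                continue
            observed = kld(module_pwm, kinase_library[kinase])
            null = pooled if params.null == "pooled" else null_scores.get(
                kinase, np.empty(0)
            )
            if null.size == 0:
                logger.warning("empty null for %s / %s", kinase, module_id)
                continue
            results.append(
                MatchResult(
                    kinase=kinase,
                    module_id=module_id,
                    kld=observed,
                    null_size=int(null.size),
                    n_null_smaller=int(np.sum(null < observed)),
                )
            )
    return results


def library_to_pwms(
    library: KinaseIntensityLibrary, pseudocount: float = 0.01
) -> dict[str, PWM]:
    """Convert every spot-array entry to a pseudocounted PWM."""
    return {
        name: pwm_from_intensities(
            library.entries[name], library.position_labels[name], pseudocount
        )
        for name in library.entries
    }
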