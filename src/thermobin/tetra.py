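"""Tetranucleotide-frequency PCA binning.

Reference-free recruitment of homology-unassigned sequences: every
sequence is summarised by the frequencies of the 256 overlapping
4-nucleotide words (counted on both strands, so profiles are
strand-invariant), profiles at a site are projected onto their first ten
principal components, and Pearson correlations between PC-score vectors
drive the recruitment rule.  A candidate (longer than 900 nt and not
assigned by homology) joins a homology-seeded bin when its average
correlation to the bin's members exceeds the bin's internal average
pairwise correlation, and does not exceed that average for any other
bin.  Finally, a mate-pair pass co-assigns unassigned mates of assigned
reads.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.decomposition import PCA

from .homology import TaxonAssignment
from .io import Lineage, SequenceRecord

N_COMPONENTS = 10

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMP = {0: 3, 1: 2, 2: 1, 3: 0}


def _revcomp_index(idx: int) -> int:
    """Index of the reverse complement of the 4-mer encoded by ``idx``."""
    bases = [(idx >> (2 * k)) & 3 for k in (3, 2, 1, 0)]  # left-to-right
    rc = [_COMP[b] for b in reversed(bases)]
    out = 0
    for b in rc:
        out = (out << 2) | b
    return out


REVCOMP_INDEX = np.array([_revcomp_index(i) for i in range(256)])


def tetra_freqs(sequence: str) -> tuple[np.ndarray, int]:
    """Tetranucleotide word frequencies of one sequence.

    Overlapping 4-mer windows are counted on the given strand and its
    reverse complement; windows containing non-ACGT characters are
    skipped.  Returns the length-256 frequency vector (summing to 1) and
    the number of windows counted.
    """
    if len(sequence) < 4:
        raise ValueError(f"sequence too short for tetranucleotides: {len(sequence)} nt")
    codes = np.fromiter(
        (_BASE_CODE.get(c, -1) for c in sequence.upper()), dtype=np.int16
    )
    valid = codes >= 0
    window_ok = valid[:-3] & valid[1:-2] & valid[2:-1] & valid[3:]
    idx = (
        (codes[:-3] << 6) | (codes[1:-2] << 4) | (codes[2:-1] << 2) | codes[3:]
    )[window_ok]
    if idx.size == 0:
        raise ValueError("no valid tetranucleotide windows (all contain N)")
    counts = np.bincount(idx, minlength=256).astype(float)
    counts = counts + counts[REVCOMP_INDEX]  # add reverse-complement strand
    n_windows = int(counts.sum())
    return counts / n_windows, n_windows


def profile_matrix(records: Sequence[SequenceRecord]) -> np.ndarray:
    """Stack tetranucleotide frequency vectors for a set of sequences."""
    return np.vstack([tetra_freqs(r.sequence)[0] for r in records])


def fit_pca(freqs: np.ndarray) -> np.ndarray:
    """Scores on the first ten principal components of the frequency matrix.

    PCA is mean-centred and unscaled (covariance PCA).  When the matrix
    has rank below ten the missing score columns are zero-padded.  The
    sign of each component is fixed by making its largest-magnitude
    loading positive, so scores are reproducible across runs.
    """
    freqs = np.asarray(freqs, dtype=float)
    if freqs.ndim != 2 or freqs.shape[0] < 2:
        raise ValueError("PCA needs at least two profiles")
    centered = freqs - freqs.mean(axis=0)
    if not centered.any():
        warnings.warn("all profiles identical; PCA scores are all zero")
        return np.zeros((freqs.shape[0], N_COMPONENTS))
    k = min(N_COMPONENTS, freqs.shape[0] - 1, freqs.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(freqs)
    # deterministic sign: largest-magnitude loading of each component positive
    for j in range(k):
        loading = pca.components_[j]
        if loading[np.argmax(np.abs(loading))] < 0:
            scores[:, j] = -scores[:, j]
    if k < N_COMPONENTS:
        scores = np.hstack([scores, np.zeros((freqs.shape[0], N_COMPONENTS - k))])
    return scores


def pearson_r(u: np.ndarray, v: np.ndarray) -> float:
    """Pearson correlation of two PC-score vectors.

    Zero-variance input has no defined correlation and is reported as 0
    with a warning, matching the conservative recruitment rule.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    du = u - u.mean()
    dv = v - v.mean()
    su = np.sqrt((du**2).sum())
    sv = np.sqrt((dv**2).sum())
    if su == 0.0 or sv == 0.0:
        warnings.warn("zero-variance score vector; correlation treated as 0")
        return 0.0
    return float((du * dv).sum() / (su * sv))


def _zscore_rows(scores: np.ndarray) -> np.ndarray:
    """Standardise rows so the Gram product gives pairwise Pearson r."""
    centered = scores - scores.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1, keepdims=True)
    zero = norms[:, 0] == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-variance score rows; r treated as 0")
        norms[zero] = 1.0
    z = centered / norms
    z[zero] = 0.0
    return z


def correlation_matrix(scores: np.ndarray) -> np.ndarray:
    """All-pairs Pearson correlation of PC-score rows."""
    z = _zscore_rows(np.asarray(scores, dtype=float))
    return np.clip(z @ z.T, -1.0, 1.0)


@dataclass
class BinCorrelationStats:
    """Internal cohesion of one homology-seeded bin in PC-score space."""

    bin_id: str
    member_ids: list[str]
    internal_mean_r: float


def bin_internal_stats(
    bins: Mapping[str, Sequence[str]],
    scores_by_id: Mapping[str, np.ndarray],
    min_bin_size: int = 50,
) -> dict[str, BinCorrelationStats]:
    """Mean pairwise member-to-member correlation per bin.

    Bins with fewer than ``min_bin_size`` members are dropped: they are
    analysed by homology alone and never recruit.
    """
    out: dict[str, BinCorrelationStats] = {}
    for bin_id, members in bins.items():
        members = [m for m in members if m in scores_by_id]
        n = len(members)
        if n < min_bin_size:
            continue
        z = _zscore_rows(np.vstack([scores_by_id[m] for m in members]))
        gram = z @ z.T
        mean_r = float((gram.sum() - np.trace(gram)) / (n * (n - 1)))
        out[bin_id] = BinCorrelationStats(bin_id, list(members), mean_r)
    return out


def recruit_unassigned(
    candidates: Sequence[SequenceRecord],
    bin_stats: Mapping[str, BinCorrelationStats],
    scores_by_id: Mapping[str, np.ndarray],
    bin_lineages: Mapping[str, Lineage],
    min_length: int = 900,
) -> dict[str, TaxonAssignment]:
    """Recruit homology-unassigned sequences into tetranucleotide bins.

    A candidate longer than ``min_length`` nt is assigned to bin B iff
    its mean correlation to B's members is greater than B's internal mean
    correlation and not greater than the internal mean of any other bin;
    candidates matching zero or several bins stay unassigned.
    """
    out: dict[str, TaxonAssignment] = {}
    eligible = [
        c for c in candidates if c.length > min_length and c.id in scores_by_id
    ]
    for cand in candidates:
        out[cand.id] = TaxonAssignment(sequence_id=cand.id)
    if not bin_stats or not eligible:
        return out

    bin_ids = sorted(bin_stats)
    member_z = {
        b: _zscore_rows(
            np.vstack([scores_by_id[m] for m in bin_stats[b].member_ids])
        )
        for b in bin_ids
    }
    cand_z = _zscore_rows(np.vstack([scores_by_id[c.id] for c in eligible]))
    # mean correlation of every candidate to every bin
    mean_r = np.column_stack(
        [(cand_z @ member_z[b].T).mean(axis=1) for b in bin_ids]
    )
    internal = np.array([bin_stats[b].internal_mean_r for b in bin_ids])
    exceeds = mean_r > internal  # candidate beats the bin's internal cohesion

    for i, cand in enumerate(eligible):
        hits = np.flatnonzero(exceeds[i])
        if hits.size == 1:
            b = bin_ids[hits[0]]
            out[cand.id] = TaxonAssignment(
                sequence_id=cand.id,
                lineage=bin_lineages[b],
                method="tetra",
                evidence={
                    "bin": b,
                    "mean_r": float(mean_r[i, hits[0]]),
                    "internal_mean_r": float(internal[hits[0]]),
                },
            )
        # 0 or >1 matching bins: stay unassigned (conservative ambiguity rule)
    return out


def propagate_mates(
    assignments: Mapping[str, TaxonAssignment],
    records: Sequence[SequenceRecord],
) -> tuple[dict[str, TaxonAssignment], list[tuple[str, str]]]:
    """Co-assign unassigned mates of assigned reads.

    When one read of a pair is assigned and its mate is not, the mate
    adopts the same lineage (method ``mate``).  Pairs assigned to
    different lineages are left untouched and returned as conflicts.
    """
    out = dict(assignments)
    conflicts: list[tuple[str, str]] = []
    by_id = {r.id: r for r in records}
    seen: set[tuple[str, str]] = set()
    for rec in records:
        if not rec.mate_id or rec.mate_id not in by_id:
            continue
        key = tuple(sorted((rec.id, rec.mate_id)))
        if key in seen:
            continue
        seen.add(key)
        a = out.get(rec.id, TaxonAssignment(sequence_id=rec.id))
        b = out.get(rec.mate_id, TaxonAssignment(sequence_id=rec.mate_id))
        if a.assigned and b.assigned:
            if a.lineage != b.lineage:
                conflicts.append(key)
        elif a.assigned and not b.assigned:
            out[rec.mate_id] = TaxonAssignment(
                sequence_id=rec.mate_id,
                lineage=a.lineage,
                method="mate",
                evidence={"from": rec.id},
            )
        elif b.assigned and not a.assigned:
            out[rec.id] = TaxonAssignment(
                sequence_id=rec.id,
                lineage=b.lineage,
                method="mate",
                evidence={"from": rec.mate_id},
            )
    return out, conflicts
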