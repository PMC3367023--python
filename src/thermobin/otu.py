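"""16S rRNA alignment filtering, OTU clustering and diversity indices.

The OTU stage consumes a pre-computed multiple sequence alignment: noisy
columns are removed by an entropy / gap / identity filter, pairwise
distances are computed gap-skipped, sequences are agglomerated into
operational taxonomic units by furthest-neighbour (complete-linkage)
clustering at a similarity threshold (default 97%, i.e. distance 0.03),
and community structure is summarised by the Shannon, Simpson and Pielou
indices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

GAP_CHARS = frozenset("-.")


@dataclass(frozen=True)
class AlignmentColumnStats:
    position: int
    entropy_bits: float
    gap_fraction: float
    identity_fraction: float


def _column_stats(column: Sequence[str], position: int) -> AlignmentColumnStats:
    symbols = ["-" if c in GAP_CHARS else c.upper() for c in column]
    n = len(symbols)
    counts: dict[str, int] = {}
    for s in symbols:
        counts[s] = counts.get(s, 0) + 1
    probs = np.array([c / n for c in counts.values()])
    entropy = float(-(probs * np.log2(probs)).sum())
    gap_fraction = counts.get("-", 0) / n
    identity_fraction = max(counts.values()) / n
    return AlignmentColumnStats(position, entropy, gap_fraction, identity_fraction)


def column_stats(alignment: Sequence[str]) -> list[AlignmentColumnStats]:
    """Per-column entropy (bits), gap fraction and identity fraction."""
    lengths = {len(row) for row in alignment}
    if len(lengths) > 1:
        raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")
    ncol = lengths.pop() if lengths else 0
    return [
        _column_stats([row[j] for row in alignment], j) for j in range(ncol)
    ]


def filter_alignment(
    alignment: Sequence[str],
    entropy_cutoff: float = 2.0,
    max_gap: float = 0.5,
) -> tuple[list[str], list[int]]:
    """Drop uninformative alignment columns.

    A column is removed when its Shannon entropy (bits, over the observed
    residue/gap symbols) reaches ``entropy_cutoff``, when more than
    ``max_gap`` of rows are gapped, or when all rows are identical.
    Returns the filtered rows and the kept (0-based) column positions.
    """
    stats = column_stats(alignment)
    kept = [
        s.position
        for s in stats
        if s.entropy_bits < entropy_cutoff
        and s.gap_fraction <= max_gap
        and s.identity_fraction < 1.0
    ]
    filtered = ["".join(row[j] for j in kept) for row in alignment]
    return filtered, kept


def pairwise_distance(alignment: Sequence[str]) -> np.ndarray:
    """Gap-skipped p-distance matrix.

    ``d = 1 - matches / compared`` over positions where neither sequence is
    gapped.  A pair with no comparable positions is reported at the maximum
    distance 1.0 with a warning.
    """
    lengths = {len(row) for row in alignment}
    if len(lengths) > 1:
        raise ValueError("ragged alignment")
    n = len(alignment)
    # integer codes; gaps -> -1
    codes = np.full((n, lengths.pop() if lengths else 0), -1, dtype=np.int16)
    for i, row in enumerate(alignment):
        for j, c in enumerate(row.upper()):
            if c not in GAP_CHARS:
                codes[i, j] = ord(c)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = (codes[i] >= 0) & (codes[j] >= 0)
            compared = int(both.sum())
            if compared == 0:
                warnings.warn(
                    f"no comparable positions between rows {i} and {j}; "
                    "distance reported as 1.0"
                )
                d = 1.0
            else:
                matches = int((codes[i][both] == codes[j][both]).sum())
                d = 1.0 - matches / compared
            dist[i, j] = dist[j, i] = d
    return dist


def cluster_otus_furthest_neighbor(
    dist: np.ndarray, threshold: float = 0.03
) -> list[int]:
    """Complete-linkage OTU clustering at a distance threshold.

    Every within-OTU pair of sequences is within ``threshold`` of each
    other (furthest-neighbour criterion).  Returns a cluster label per
    sequence, labelled 0..k-1 in order of first appearance.
    """
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(dist, dist.T):
        raise ValueError("distance matrix must be symmetric")
    n = dist.shape[0]
    if n == 1:
        return [0]
    z = linkage(squareform(dist, checks=False), method="complete")
    raw = fcluster(z, t=threshold, criterion="distance")
    # relabel in order of first appearance for determinism
    mapping: dict[int, int] = {}
    labels = []
    for lab in raw:
        if lab not in mapping:
            mapping[lab] = len(mapping)
        labels.append(mapping[lab])
    return labels


def diversity_indices(counts: Sequence[float]) -> dict[str, float | None]:
    """Shannon H' (nats), Simpson D = sum p^2, Pielou J and richness S.

    ``J = H'/ln S`` is undefined for a single category and reported as
    ``None`` in that case.
    """
    counts = np.asarray(counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("negative counts")
    total = counts.sum()
    if total == 0:
        raise ValueError("all-zero abundance vector")
    p = counts[counts > 0] / total
    shannon = float(-(p * np.log(p)).sum())
    simpson = float((p**2).sum())
    richness = int(p.size)
    pielou = shannon / np.log(richness) if richness > 1 else None
    return {
        "shannon_H": shannon,
        "simpson_D": simpson,
        "pielou_J": pielou,
        "richness_S": richness,
    }


def simpson_variants(simpson_d: float) -> dict[str, float]:
    """Common Simpson-index conventions derived from D = sum p^2."""
    return {
        "D": simpson_d,
        "one_minus_D": 1.0 - simpson_d,
        "inverse_D": 1.0 / simpson_d,
    }
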