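"""Per-bin EC presence calls, bin statistics and biogeochemical gene tallies.

Metabolic capacity is reconstructed per taxonomic bin (or per site) from
EC-labelled proteins.  Raw EC copy counts are normalised by the scope's
average duplication factor (total EC-labelled proteins divided by
distinct EC families) and an EC is scored present when the normalised
value exceeds a cutoff (default 0.25).  Bin statistics follow the
genome-reconstruction bookkeeping of the binning stage: assigned
megabases, percent of site sequence, sequencing depth against an
estimated genome size, and Lander-Waterman expected genome coverage
``(1 - exp(-depth)) * 100``.  Gene tallies for biogeochemical cycles
(sulfur, nitrogen, carbon fixation) are counted per site against a
configurable category map and optionally normalised to the smallest
site dataset.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd


@dataclass
class ECProfile:
    """EC presence/absence profile of one scope (site or bin)."""

    scope: str
    raw_counts: dict[str, int]
    duplication_factor: float | None = None
    normalized: dict[str, float] = field(default_factory=dict)
    present: dict[str, bool] = field(default_factory=dict)


def duplication_factor(raw_counts: Mapping[str, int]) -> float | None:
    """Total EC-labelled proteins divided by distinct EC families.

    ``None`` (undefined) when the scope contains no EC-labelled protein.
    """
    distinct = sum(1 for c in raw_counts.values() if c > 0)
    if distinct == 0:
        return None
    return sum(raw_counts.values()) / distinct


def ec_presence(
    raw_counts: Mapping[str, int], scope: str = "", cutoff: float = 0.25
) -> ECProfile:
    """Duplication-normalised presence calls for one scope.

    ``normalized(ec) = raw_count(ec) / duplication_factor``; the EC is
    present when that value exceeds ``cutoff``.
    """
    profile = ECProfile(scope=scope, raw_counts=dict(raw_counts))
    dup = duplication_factor(raw_counts)
    profile.duplication_factor = dup
    if dup is None:
        warnings.warn(f"scope {scope!r} has no EC-labelled proteins; all absent")
        return profile
    for ec, count in raw_counts.items():
        value = count / dup
        profile.normalized[ec] = value
        profile.present[ec] = value > cutoff
    return profile


@dataclass
class BinReport:
    """Genome-reconstruction statistics for one taxonomic bin."""

    bin_id: str
    site: str
    n_reads: int
    total_mb: float
    pct_of_site: float
    est_genome_mb: float
    depth: float
    coverage_pct: float
    profiled: bool  # False for bins under the small-bin threshold


def lander_waterman_coverage(depth: float) -> float:
    """Expected percent of a genome seen at a given fold-depth."""
    return (1.0 - math.exp(-depth)) * 100.0


def bin_report(
    bin_id: str,
    site: str,
    assigned_lengths_nt: Sequence[int],
    est_genome_mb: float,
    site_total_nt: float,
    small_bin_pct: float = 0.2,
) -> BinReport:
    """Statistics for one bin from its assigned sequence lengths.

    Bins holding less than ``small_bin_pct`` percent of the site's
    sequence are still reported but flagged ``profiled=False`` and are
    omitted from metabolic profiling.
    """
    if est_genome_mb <= 0:
        raise ValueError(f"estimated genome size must be positive for {bin_id}")
    total_mb = sum(assigned_lengths_nt) / 1e6
    pct = total_mb * 1e6 / site_total_nt * 100.0
    depth = total_mb / est_genome_mb
    return BinReport(
        bin_id=bin_id,
        site=site,
        n_reads=len(assigned_lengths_nt),
        total_mb=total_mb,
        pct_of_site=pct,
        est_genome_mb=est_genome_mb,
        depth=depth,
        coverage_pct=lander_waterman_coverage(depth),
        profiled=pct >= small_bin_pct,
    )


def bin_report_table(reports: Sequence[BinReport]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in reports])


def cycle_tally(
    gene_hits: pd.DataFrame,
    category_map: Mapping[str, Sequence[str]],
    normalize: bool = True,
    known_genes: set[str] | None = None,
) -> pd.DataFrame:
    """Per-site counts of genes in each biogeochemical category.

    ``gene_hits`` has columns ``site``, ``gene`` and optionally ``count``
    (default 1 per row).  Every gene id appearing in the category map
    values is tallied per site; with ``normalize`` each site's counts are
    scaled by (smallest site total gene count) / (site total gene
    count), so deeper-sequenced sites are not over-counted.  When a
    ``known_genes`` vocabulary is supplied, map entries outside it raise
    an error listing the offenders.
    """
    df = gene_hits.copy()
    if "count" not in df.columns:
        df["count"] = 1
    for cat, genes in category_map.items():
        if not genes:
            raise ValueError(f"empty gene category {cat!r}")
    if known_genes is not None:
        mapped_genes = {g for genes in category_map.values() for g in genes}
        unknown = mapped_genes - known_genes
        if unknown:
            raise ValueError(f"unknown gene identifiers in category map: {sorted(unknown)}")

    site_totals = df.groupby("site")["count"].sum()
    scale = (
        site_totals.min() / site_totals if normalize else pd.Series(1.0, index=site_totals.index)
    )
    rows = []
    for cat, genes in category_map.items():
        sub = df[df["gene"].isin(set(genes))]
        counts = sub.groupby("site")["count"].sum()
        for site in site_totals.index:
            raw = int(counts.get(site, 0))
            rows.append(
                {
                    "category": cat,
                    "site": site,
                    "raw_count": raw,
                    "normalized_count": raw * float(scale[site]),
                }
            )
    return pd.DataFrame(rows)
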