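"""Bundled data tables.

Two kinds of data ship with the package: published summary statistics of
a five-site environmental genome from the outflow channel of an alkaline
Yellowstone hot spring (per-site sequencing totals and per-bin
genome-reconstruction statistics), used to exercise the bin-statistics
arithmetic against printed values; and small synthetic fixtures (a
20-reaction energetics table and a five-site conditions transect) that
are invented but realistic, flagged ``synthetic`` in their filenames.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd
import yaml

from .energetics import ReactionEnergetics, SiteConditions


def _path(name: str):
    return resources.files("thermobin.data").joinpath(name)


def load_published_bin_stats() -> pd.DataFrame:
    """Per-bin binning and consensus-genome statistics (25 bins, 5 sites).

    Columns: read counts at three assignment stages, predicted proteins,
    assigned sequence (Mb), percent of site sequence, estimated genome
    size (Mb, nearest sequenced neighbour), depth and coverage (%).
    """
    with _path("published_bin_stats.csv").open() as fh:
        return pd.read_csv(fh)


def load_published_site_totals() -> pd.DataFrame:
    """Per-site sequencing totals: reads, mean read length, total bases."""
    with _path("published_site_totals.csv").open() as fh:
        return pd.read_csv(fh)


def load_gene_categories() -> dict[str, list[str]]:
    """Default biogeochemical gene-category map (sulfur/nitrogen/carbon)."""
    with _path("gene_categories.yaml").open() as fh:
        return yaml.safe_load(fh)


def load_synthetic_reactions() -> list[ReactionEnergetics]:
    """20-reaction synthetic energetics fixture (invented parameters)."""
    from .io import parse_reaction_table

    with resources.as_file(_path("reactions_synthetic.csv")) as p:
        return parse_reaction_table(p)


def load_synthetic_site_conditions() -> list[SiteConditions]:
    """Synthetic five-site temperature/pH transect."""
    with _path("site_conditions_synthetic.csv").open() as fh:
        df = pd.read_csv(fh, comment="#")
    return [
        SiteConditions(row.site_id, float(row.temperature_c), float(row.ph))
        for row in df.itertuples()
    ]
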