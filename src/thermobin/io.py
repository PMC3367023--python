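"""Readers and writers for the external formats the pipeline touches.

Sequences travel as FASTA, homology search results as 12-column tabular
hit files (BLAST ``-outfmt 6`` column order), reference taxonomy as a
tab-separated table of subject id plus seven rank columns, and reaction
energetics as CSV.  Parsing is strict by default: malformed rows raise
with enough context (line number, offending id) to locate the problem.
"""

from __future__ import annotations

import csv
from collections import OrderedDict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

RANKS = ("superkingdom", "phylum", "class", "order", "family", "genus", "species")

_VALID_BASES = frozenset("ACGTN")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class Lineage:
    """Taxonomic lineage over the seven major ranks.

    ``ranks`` always has length 7 (superkingdom .. species); empty strings
    mark unresolved ranks and must form a contiguous suffix, i.e. a lineage
    resolved at family level has its genus and species slots empty.
    """

    ranks: tuple[str, ...] = ("",) * 7

    def __post_init__(self) -> None:
        if len(self.ranks) != len(RANKS):
            raise ValueError(f"lineage needs {len(RANKS)} ranks, got {len(self.ranks)}")
        seen_empty = False
        for name in self.ranks:
            if name == "":
                seen_empty = True
            elif seen_empty:
                raise ValueError(f"non-contiguous lineage: {self.ranks}")

    @classmethod
    def from_names(cls, *names: str) -> "Lineage":
        names = tuple(names)
        return cls(names + ("",) * (len(RANKS) - len(names)))

    @property
    def depth(self) -> int:
        """Number of resolved ranks (0 = completely unresolved / root)."""
        return sum(1 for r in self.ranks if r)

    @property
    def deepest_rank(self) -> str:
        return RANKS[self.depth - 1] if self.depth else "unassigned"

    def truncate(self, depth: int) -> "Lineage":
        return Lineage(self.ranks[:depth] + ("",) * (len(RANKS) - depth))

    def common_depth(self, other: "Lineage") -> int:
        """Depth of the deepest rank at which both lineages agree."""
        d = 0
        for a, b in zip(self.ranks, other.ranks):
            if a and a == b:
                d += 1
            else:
                break
        return d

    def name_at(self, rank: str) -> str:
        return self.ranks[RANKS.index(rank)]

    def is_empty(self) -> bool:
        return self.depth == 0


@dataclass
class SequenceRecord:
    """One read / contig / scaffold with its site label and mate link."""

    id: str
    sequence: str
    site: str = ""
    mate_id: str | None = None

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class HitRecord:
    """One homology hit (one row of a 12-column tabular search result)."""

    query_id: str
    subject_id: str
    percent_identity: float
    aln_length: int
    e_value: float
    bit_score: float
    search_type: str = "protein"  # {protein, nucleotide}

    def __post_init__(self) -> None:
        if self.bit_score < 0 or self.e_value < 0:
            raise ValueError(f"negative score/e-value for {self.query_id}")
        if self.aln_length < 1:
            raise ValueError(f"alignment length < 1 for {self.query_id}")


def parse_fasta(
    path: str | Path,
    site: str = "",
    mate_suffixes: tuple[str, str] | None = ("/1", "/2"),
) -> list[SequenceRecord]:
    """Read FASTA into :class:`SequenceRecord` objects.

    Mate pairs are recognised from a configurable pair of header suffixes
    (default ``/1`` and ``/2``); records sharing the same stem with both
    suffixes are linked symmetrically.  Sequences are upper-cased and must
    use only A, C, G, T, N.
    """
    path = Path(path)
    records: "OrderedDict[str, SequenceRecord]" = OrderedDict()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if rec.id in records:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        for pos, base in enumerate(seq):
            if base not in _VALID_BASES:
                raise FormatError(
                    f"invalid character {base!r} at position {pos} of {rec.id!r}"
                )
        if not seq:
            raise FormatError(f"empty sequence for {rec.id!r}")
        records[rec.id] = SequenceRecord(id=rec.id, sequence=seq, site=site)
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    if mate_suffixes is not None:
        s1, s2 = mate_suffixes
        for rid, rec in records.items():
            if rid.endswith(s1):
                other = rid[: -len(s1)] + s2
                if other in records:
                    rec.mate_id = other
                    records[other].mate_id = rid
    return list(records.values())


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), 80):
                fh.write(rec.sequence[i : i + 80] + "\n")


def parse_taxonomy_table(path: str | Path) -> dict[str, Lineage]:
    """Tab-separated table: subject_id + 7 rank columns (blank allowed)."""
    taxonomy: dict[str, Lineage] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 8:
                raise FormatError(f"{path} line {lineno}: expected 8 columns")
            sid, *names = parts
            if sid in taxonomy:
                raise FormatError(f"{path} line {lineno}: duplicate subject {sid!r}")
            taxonomy[sid] = Lineage(tuple(names))
    return taxonomy


def write_taxonomy_table(taxonomy: Mapping[str, Lineage], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, lin in taxonomy.items():
            fh.write("\t".join((sid,) + lin.ranks) + "\n")


def parse_hit_table(
    path: str | Path,
    taxonomy: Mapping[str, Lineage] | None = None,
    search_type: str = "protein",
    strict: bool = True,
) -> dict[str, list[HitRecord]]:
    """Parse a 12-column tabular hit file, grouped by query.

    Column order follows BLAST ``-outfmt 6``: qseqid sseqid pident length
    mismatch gapopen qstart qend sstart send evalue bitscore.  Within each
    query group hits are sorted by descending bit score (ties by subject id
    for determinism).  With ``strict`` every subject must appear in the
    taxonomy map; otherwise unmapped subjects are kept with empty lineage.
    """
    groups: dict[str, list[HitRecord]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise FormatError(f"{path} line {lineno}: expected 12 columns")
            try:
                hit = HitRecord(
                    query_id=parts[0],
                    subject_id=parts[1],
                    percent_identity=float(parts[2]),
                    aln_length=int(parts[3]),
                    e_value=float(parts[10]),
                    bit_score=float(parts[11]),
                    search_type=search_type,
                )
            except ValueError as exc:
                raise FormatError(f"{path} line {lineno}: {exc}") from exc
            if strict and taxonomy is not None and hit.subject_id not in taxonomy:
                raise FormatError(
                    f"{path} line {lineno}: subject {hit.subject_id!r} missing "
                    "from taxonomy (use strict=False to keep it)"
                )
            groups.setdefault(hit.query_id, []).append(hit)
    for qid in groups:
        groups[qid].sort(key=lambda h: (-h.bit_score, h.subject_id))
    return groups


def write_hit_table(groups: Mapping[str, Sequence[HitRecord]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for qid in groups:
            for h in groups[qid]:
                fh.write(
                    "\t".join(
                        [
                            h.query_id,
                            h.subject_id,
                            f"{h.percent_identity:.2f}",
                            str(h.aln_length),
                            "0",
                            "0",
                            "1",
                            str(h.aln_length),
                            "1",
                            str(h.aln_length),
                            f"{h.e_value:.3g}",
                            f"{h.bit_score:.1f}",
                        ]
                    )
                    + "\n"
                )


def parse_reaction_table(path: str | Path):
    """CSV with columns id, slope, intercept, n_electrons (header required).

    Returns one :class:`~thermobin.energetics.ReactionEnergetics` per row.
    """
    from .energetics import ReactionEnergetics

    reactions = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(row for row in fh if not row.startswith("#"))
        required = {"id", "slope", "intercept", "n_electrons"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise FormatError(f"{path}: needs columns {sorted(required)}")
        for lineno, row in enumerate(reader, 2):
            rid = row["id"].strip()
            if rid in seen:
                raise FormatError(f"{path} line {lineno}: duplicate reaction {rid!r}")
            seen.add(rid)
            n_e = int(row["n_electrons"])
            if n_e <= 0:
                raise FormatError(
                    f"{path} line {lineno}: n_electrons must be positive, got {n_e}"
                )
            reactions.append(
                ReactionEnergetics(
                    reaction_id=rid,
                    slope=float(row["slope"]),
                    intercept=float(row["intercept"]),
                    n_electrons=n_e,
                    oxidant=row.get("oxidant", "") or "",
                    reductant=row.get("reductant", "") or "",
                )
            )
    return reactions
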