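"""Two-track homology assignment and the consensus rules that merge them.

Track one is an inclusive lowest-common-ancestor (LCA) assignment over
protein-level hits (min bit score 35, top-percent 10, min support 5);
track two is a conservative nucleotide best-hit assignment (bit score
strictly above 300).  A sequence enters a taxonomic bin when the two
tracks agree rank-by-rank, or under one of three override conditions:

1. the LCA track resolved the read at species level;
2. the nucleotide best hit scored above 1000 bits;
3. the tracks agree at a rank exactly two levels rootward of the deeper
   track's rank, in which case the deeper call is accepted.

Every consensus call records which rule fired so assignments are
auditable after the fact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .io import RANKS, HitRecord, Lineage


@dataclass(frozen=True)
class LcaParams:
    """Parameters of the inclusive LCA track."""

    min_score: float = 35.0
    top_percent: float = 10.0
    min_support: int = 5

    def __post_init__(self) -> None:
        if self.min_score <= 0 or self.top_percent <= 0 or self.min_support <= 0:
            raise ValueError("LCA parameters must all be positive")


@dataclass
class TaxonAssignment:
    """Per-sequence taxonomic call with its provenance.

    ``method`` is one of lca, besthit, consensus, tetra, mate;
    ``rule`` names the consensus condition that fired (agreement,
    lca_species, high_bit, two_level) where applicable.
    """

    sequence_id: str
    lineage: Lineage = field(default_factory=Lineage)
    method: str = "unassigned"
    rule: str = ""
    evidence: dict = field(default_factory=dict)

    @property
    def assigned(self) -> bool:
        return self.lineage.depth > 0

    @property
    def assigned_rank(self) -> str:
        return self.lineage.deepest_rank


def _unassigned(qid: str, method: str = "unassigned") -> TaxonAssignment:
    return TaxonAssignment(sequence_id=qid, method=method)


def lca_assign(
    hits_by_query: Mapping[str, Sequence[HitRecord]],
    taxonomy: Mapping[str, Lineage],
    params: LcaParams = LcaParams(),
) -> dict[str, TaxonAssignment]:
    """Inclusive LCA assignment over protein-level hits.

    Per query: hits below ``min_score`` bits are dropped, hits within
    ``top_percent`` percent of the best retained bit score are kept, and
    the query is placed at the lowest common ancestor of the kept
    lineages (a subject missing from the taxonomy contributes the
    uninformative root lineage).  A dataset-wide min-support pass then
    promotes reads assigned to any taxon supported by fewer than
    ``min_support`` reads up to the nearest sufficiently supported
    ancestor; reads reaching the root become unassigned.
    """
    raw: dict[str, Lineage] = {}
    for qid, hits in hits_by_query.items():
        kept = [h for h in hits if h.bit_score >= params.min_score]
        if not kept:
            raw[qid] = Lineage()
            continue
        best = max(h.bit_score for h in kept)
        floor = (1.0 - params.top_percent / 100.0) * best
        retained = [h for h in kept if h.bit_score >= floor]
        lca = taxonomy.get(retained[0].subject_id, Lineage())
        depth = lca.depth
        for h in retained[1:]:
            lin = taxonomy.get(h.subject_id, Lineage())
            depth = min(depth, lca.common_depth(lin))
            if depth == 0:
                break
        raw[qid] = lca.truncate(depth)

    promoted = _apply_min_support(raw, params.min_support)
    out: dict[str, TaxonAssignment] = {}
    for qid, lineage in promoted.items():
        if lineage.depth == 0:
            out[qid] = _unassigned(qid)
        else:
            out[qid] = TaxonAssignment(
                sequence_id=qid,
                lineage=lineage,
                method="lca",
                evidence={"raw_depth": raw[qid].depth},
            )
    return out


def _apply_min_support(
    assignments: Mapping[str, Lineage], min_support: int
) -> dict[str, Lineage]:
    """Bottom-up single-pass min-support promotion.

    A node's support counts the reads assigned exactly at it plus any
    reads promoted into it from unsupported descendants.
    """
    node_reads: dict[tuple[str, ...], list[str]] = {}
    for qid, lin in assignments.items():
        node = lin.ranks[: lin.depth]
        node_reads.setdefault(node, []).append(qid)

    for depth in range(len(RANKS), 0, -1):
        for node in sorted(n for n in node_reads if len(n) == depth):
            reads = node_reads[node]
            if len(reads) < min_support:
                parent = node[:-1]
                node_reads.setdefault(parent, []).extend(reads)
                del node_reads[node]

    out: dict[str, Lineage] = {}
    for node, reads in node_reads.items():
        lineage = Lineage(tuple(node) + ("",) * (len(RANKS) - len(node)))
        for qid in reads:
            out[qid] = lineage
    return out


def besthit_assign(
    hits_by_query: Mapping[str, Sequence[HitRecord]],
    taxonomy: Mapping[str, Lineage],
    min_bit: float = 300.0,
) -> dict[str, TaxonAssignment]:
    """Conservative nucleotide best-hit assignment.

    The query takes the lineage of its single highest-scoring hit if that
    hit scores strictly above ``min_bit`` bits; ties on the top bit score
    resolve to the LCA of the tied subjects.
    """
    out: dict[str, TaxonAssignment] = {}
    for qid, hits in hits_by_query.items():
        if not hits:
            out[qid] = _unassigned(qid)
            continue
        best_bit = max(h.bit_score for h in hits)
        if not best_bit > min_bit:
            out[qid] = _unassigned(qid)
            continue
        tied = [h for h in hits if h.bit_score == best_bit]
        lca = taxonomy.get(tied[0].subject_id, Lineage())
        depth = lca.depth
        for h in tied[1:]:
            depth = min(depth, lca.common_depth(taxonomy.get(h.subject_id, Lineage())))
        lineage = lca.truncate(depth)
        if lineage.depth == 0:
            out[qid] = _unassigned(qid)
        else:
            out[qid] = TaxonAssignment(
                sequence_id=qid,
                lineage=lineage,
                method="besthit",
                evidence={"bit_score": best_bit},
            )
    return out


def consensus_bin(
    lca: TaxonAssignment,
    besthit: TaxonAssignment,
    besthit_bit: float | None = None,
) -> TaxonAssignment:
    """Merge the two homology tracks for one sequence.

    Applies, in order: the species-level LCA override, the >1000-bit
    best-hit override, the two-level agreement override, then the base
    rank-by-rank agreement rule.  The fired rule is recorded on the
    returned assignment.
    """
    qid = lca.sequence_id or besthit.sequence_id
    if besthit_bit is None:
        besthit_bit = besthit.evidence.get("bit_score", 0.0)

    if not lca.assigned and not besthit.assigned:
        return _unassigned(qid)

    evidence = {
        "lca_rank": lca.assigned_rank,
        "besthit_rank": besthit.assigned_rank,
        "besthit_bit": besthit_bit,
    }

    # override 1: LCA resolved to species
    if lca.lineage.depth == len(RANKS):
        return TaxonAssignment(
            qid, lca.lineage, method="consensus", rule="lca_species", evidence=evidence
        )
    # override 2: very strong nucleotide hit
    if besthit.assigned and besthit_bit > 1000.0:
        return TaxonAssignment(
            qid, besthit.lineage, method="consensus", rule="high_bit", evidence=evidence
        )

    agree_depth = lca.lineage.common_depth(besthit.lineage)

    # override 3: the shallower track is unresolved past the agreement depth
    # and the deeper call reaches exactly two ranks further; accept the deeper
    # call (the shallow track agrees as far as it goes, it is not conflicting)
    if lca.assigned and besthit.assigned and agree_depth >= 1:
        deeper = lca if lca.lineage.depth >= besthit.lineage.depth else besthit
        shallower = besthit if deeper is lca else lca
        if (
            shallower.lineage.depth == agree_depth
            and deeper.lineage.depth - agree_depth == 2
        ):
            return TaxonAssignment(
                qid,
                deeper.lineage,
                method="consensus",
                rule="two_level",
                evidence=evidence,
            )

    # base rule: deepest rank of rank-by-rank agreement
    if agree_depth >= 1:
        return TaxonAssignment(
            qid,
            lca.lineage.truncate(agree_depth),
            method="consensus",
            rule="agreement",
            evidence=evidence,
        )
    return _unassigned(qid)


def consensus_assign(
    lca_assignments: Mapping[str, TaxonAssignment],
    besthit_assignments: Mapping[str, TaxonAssignment],
) -> dict[str, TaxonAssignment]:
    """Apply :func:`consensus_bin` across a dataset (union of queries)."""
    out: dict[str, TaxonAssignment] = {}
    for qid in sorted(set(lca_assignments) | set(besthit_assignments)):
        lca = lca_assignments.get(qid, _unassigned(qid))
        bh = besthit_assignments.get(qid, _unassigned(qid))
        out[qid] = consensus_bin(lca, bh)
    return out


def audit_consensus(
    call: TaxonAssignment, lca: TaxonAssignment, besthit: TaxonAssignment
) -> bool:
    """Check that a non-unassigned consensus call satisfies its recorded rule.

    Used by the test suite to verify that every consensus assignment is
    justified by one of the four stated conditions.
    """
    if not call.assigned:
        return True
    bit = besthit.evidence.get("bit_score", 0.0)
    agree = lca.lineage.common_depth(besthit.lineage)
    if call.rule == "lca_species":
        return lca.lineage.depth == len(RANKS) and call.lineage == lca.lineage
    if call.rule == "high_bit":
        return bit > 1000.0 and call.lineage == besthit.lineage
    if call.rule == "two_level":
        deeper = lca if lca.lineage.depth >= besthit.lineage.depth else besthit
        shallower = besthit if deeper is lca else lca
        return (
            agree >= 1
            and shallower.lineage.depth == agree
            and deeper.lineage.depth - agree == 2
            and call.lineage == deeper.lineage
        )
    if call.rule == "agreement":
        return agree >= 1 and call.lineage == lca.lineage.truncate(agree)
    return False
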