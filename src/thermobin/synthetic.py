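"""Synthetic hot-spring community generator with known ground truth.

Every downstream stage is exercised against mock communities built here:
source genomes are drawn from per-taxon Markov chains (order 3 by
default, so taxa differ in exactly the tetranucleotide feature space the
binner uses), error-free Sanger-scale paired reads are sampled with
skewed abundances, homology hit tables are simulated with identity and
bit score decaying with taxonomic distance to the references, and
protein families with known EC labels are planted for the clustering
stage.  All sampling is deterministic given a seed, and a truth table
maps every read to its source taxon and genome coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import HitRecord, Lineage, SequenceRecord

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class TaxonModel:
    """Generative model of one community member.

    ``transition`` holds conditional next-base probabilities given the
    previous ``markov_order`` bases (shape ``(4**order, 4)``, rows
    summing to 1).  ``reference_distance`` in [0, 1] controls how far
    this taxon sits from its simulated reference sequences: 0 means the
    reference is the organism itself.
    """

    taxon_id: str
    lineage: Lineage
    genome_length: int
    abundance: float
    transition: np.ndarray
    markov_order: int = 3
    reference_distance: float = 0.0

    def __post_init__(self) -> None:
        expected = (4**self.markov_order, 4)
        if self.transition.shape != expected:
            raise ValueError(
                f"{self.taxon_id}: transition table shape {self.transition.shape}, "
                f"expected {expected}"
            )
        rows = self.transition.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-9):
            raise ValueError(f"{self.taxon_id}: transition rows must sum to 1")


@dataclass
class TruthTable:
    """Map read id -> (source taxon, genome start, genome end)."""

    origin: dict[str, tuple[str, int, int]] = field(default_factory=dict)

    def taxon_of(self, read_id: str) -> str:
        return self.origin[read_id][0]

    def __len__(self) -> int:
        return len(self.origin)

    def __contains__(self, read_id: str) -> bool:
        return read_id in self.origin


def make_transition_table(
    rng: np.random.Generator,
    gc: float = 0.5,
    signature_sd: float = 0.35,
    markov_order: int = 3,
) -> np.ndarray:
    """Random word-usage signature around a target GC content.

    Each conditional probability is a GC-determined base weight times a
    lognormal perturbation; ``signature_sd`` sets how idiosyncratic the
    taxon's word usage is (0 collapses all taxa of equal GC onto the
    same chain).
    """
    base = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    weights = base * np.exp(rng.normal(0.0, signature_sd, size=(4**markov_order, 4)))
    return weights / weights.sum(axis=1, keepdims=True)


def generate_genome(model: TaxonModel, seed: int) -> str:
    """Draw one genome from the taxon's Markov chain, deterministically."""
    rng = np.random.default_rng(seed)
    n = model.genome_length
    order = model.markov_order
    cum = np.cumsum(model.transition, axis=1)
    cum[:, -1] = 1.0
    cum_list = cum.tolist()
    u = rng.random(n).tolist()
    out = [0] * n
    state = 0
    n_states = 4**order
    for i in range(order):  # seed context drawn uniformly
        b = int(u[i] * 4)
        out[i] = b
        state = (state * 4 + b) % n_states
    for i in range(order, n):
        row = cum_list[state]
        x = u[i]
        b = 0
        while row[b] < x:
            b += 1
        out[i] = b
        state = (state * 4 + b) % n_states
    lut = np.array(list(BASES))
    return "".join(lut[out])


def stationary_tetra_distribution(model: TaxonModel, length: int = 60000, seed: int = 0) -> np.ndarray:
    """Empirical tetranucleotide distribution of a long draw from the chain."""
    from .tetra import tetra_freqs

    return tetra_freqs(generate_genome(model, seed))[0]


def js_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen-Shannon divergence (base-2 bits) between two distributions."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    m = 0.5 * (p + q)

    def _kl(a: np.ndarray, b: np.ndarray) -> float:
        mask = a > 0
        return float((a[mask] * np.log2(a[mask] / b[mask])).sum())

    return 0.5 * _kl(p, m) + 0.5 * _kl(q, m)


def _truncated_normal_lengths(
    rng: np.random.Generator, n: int, mean: float, sd: float, minimum: int = 50
) -> np.ndarray:
    lengths = rng.normal(mean, sd, size=n)
    for _ in range(100):
        bad = lengths < minimum
        if not bad.any():
            break
        lengths[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    lengths[lengths < minimum] = minimum
    return lengths.round().astype(int)


def simulate_reads(
    community: Sequence[TaxonModel],
    n_reads: int,
    length_mean: float = 1000.0,
    length_sd: float = 150.0,
    paired: bool = False,
    seed: int = 0,
    site: str = "site1",
    fragment_mean: float = 3000.0,
    fragment_sd: float = 300.0,
) -> tuple[list[SequenceRecord], TruthTable]:
    """Sample error-free reads from a community, with known origins.

    Read counts per taxon are multinomial in abundance x genome length,
    lengths are truncated-normal (>= 50 nt), and paired reads come from
    opposite ends (opposite strands) of a fragment.  ``n_reads`` counts
    reads, so paired simulation requires an even ``n_reads``.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    if paired and n_reads % 2:
        raise ValueError("paired simulation needs an even n_reads")
    total_abundance = sum(m.abundance for m in community)
    if not math.isclose(total_abundance, 1.0, abs_tol=1e-9):
        raise ValueError(f"abundances must sum to 1, got {total_abundance}")

    root = np.random.SeedSequence(seed)
    genome_seeds, read_seed = root.spawn(2)
    genomes = {
        m.taxon_id: generate_genome(m, int(s.generate_state(1)[0] % 2**31))
        for m, s in zip(community, genome_seeds.spawn(len(community)))
    }
    rng = np.random.default_rng(read_seed)

    weights = np.array([m.abundance * m.genome_length for m in community], dtype=float)
    weights /= weights.sum()
    n_units = n_reads // 2 if paired else n_reads
    counts = rng.multinomial(n_units, weights)

    records: list[SequenceRecord] = []
    truth = TruthTable()
    unit = 0
    for model, n_taxon in zip(community, counts):
        genome = genomes[model.taxon_id]
        g = len(genome)
        for _ in range(n_taxon):
            if paired:
                l1, l2 = _truncated_normal_lengths(rng, 2, length_mean, length_sd)
                frag = None
                for _attempt in range(100):
                    f = int(round(rng.normal(fragment_mean, fragment_sd)))
                    f = max(f, l1 + l2)
                    if f <= g:
                        frag = f
                        break
                if frag is None:
                    raise ValueError(
                        f"cannot place fragment in genome of {model.taxon_id} "
                        f"({g} nt) after 100 attempts"
                    )
                start = int(rng.integers(0, g - frag + 1))
                r1 = genome[start : start + l1]
                r2 = revcomp(genome[start + frag - l2 : start + frag])
                base = f"{site}_r{unit:06d}"
                for rid, seq, s0, s1_ in (
                    (base + "/1", r1, start, start + l1),
                    (base + "/2", r2, start + frag - l2, start + frag),
                ):
                    records.append(SequenceRecord(id=rid, sequence=seq, site=site))
                    truth.origin[rid] = (model.taxon_id, s0, s1_)
                records[-2].mate_id = base + "/2"
                records[-1].mate_id = base + "/1"
            else:
                length = None
                for _attempt in range(100):
                    (cand,) = _truncated_normal_lengths(rng, 1, length_mean, length_sd)
                    if cand <= g:
                        length = int(cand)
                        break
                if length is None:
                    raise ValueError(
                        f"read length exceeds genome of {model.taxon_id} "
                        "after 100 attempts"
                    )
                start = int(rng.integers(0, g - length + 1))
                rid = f"{site}_r{unit:06d}"
                records.append(
                    SequenceRecord(id=rid, sequence=genome[start : start + length], site=site)
                )
                truth.origin[rid] = (model.taxon_id, start, start + length)
            unit += 1
    return records, truth


# --- simulated homology searches -------------------------------------------

#: bit-score model coefficients per search type: bit = k * aln_len * max(pid - p0, 0)
_BIT_MODEL = {"protein": (0.005, 30.0), "nucleotide": (0.024, 50.0)}


def identity_from_distance(distance: float) -> float:
    """Expected percent identity to a reference at a given taxonomic distance.

    Linear decay from 100% at distance 0 to 55% at distance 1; the
    monotone contract (greater distance never increases identity) is by
    construction.
    """
    if not 0.0 <= distance <= 1.0:
        raise ValueError("reference_distance must lie in [0, 1]")
    return 100.0 - 45.0 * distance


@dataclass
class HitSimParams:
    """Controls for the simulated homology search.

    ``identity[(taxon_id, ref_id)]`` is the expected percent identity of
    that taxon's reads against that reference; ``hit_prob`` the chance a
    read registers a hit against it at all.  Pairs absent from the maps
    produce no hits.  ``hit_free_ids`` forces specific reads to receive
    no hits (used to share the hit-free read set across search types).
    """

    identity: Mapping[tuple[str, str], float]
    hit_prob: Mapping[tuple[str, str], float]
    identity_sd: float = 3.0
    bit_noise_sd: float = 10.0
    aln_frac_range: tuple[float, float] = (0.6, 0.9)
    no_hit_fraction: float = 0.0
    search_type: str = "protein"
    hit_free_ids: frozenset[str] = frozenset()


def simulate_hit_table(
    reads: Sequence[SequenceRecord],
    truth: TruthTable,
    references: Mapping[str, Lineage],
    params: HitSimParams,
    seed: int = 0,
) -> dict[str, list[HitRecord]]:
    """Simulate a tabular homology search against a reference set.

    Percent identity is Gaussian around the configured expectation, the
    alignment covers a uniform fraction of the read, and the bit score is
    a deterministic linear function of identity and alignment length
    plus Gaussian noise (coefficients per search type).
    """
    k, p0 = _BIT_MODEL[params.search_type]
    rng = np.random.default_rng(seed)
    out: dict[str, list[HitRecord]] = {}
    ref_ids = sorted(references)
    for rec in reads:
        if rec.id in params.hit_free_ids:
            continue
        if params.no_hit_fraction and rng.random() < params.no_hit_fraction:
            continue
        taxon = truth.taxon_of(rec.id)
        hits: list[HitRecord] = []
        # the alignable fraction is a property of the read and is shared by
        # all of its hits (with small per-hit jitter)
        lo, hi = params.aln_frac_range
        read_frac = rng.uniform(lo, hi)
        for ref_id in ref_ids:
            p = params.hit_prob.get((taxon, ref_id), 0.0)
            if p <= 0.0 or rng.random() >= p:
                continue
            expected = params.identity[(taxon, ref_id)]
            # identity spread scales with divergence (binomial mismatch
            # noise): a self-reference aligns at exactly 100%
            sd = params.identity_sd * math.sqrt(max(100.0 - expected, 0.0) / 10.0)
            pid = float(np.clip(rng.normal(expected, sd), 30.0, 100.0))
            frac = float(np.clip(read_frac * rng.normal(1.0, 0.03), 0.05, 1.0))
            aln_len = max(1, int(rec.length * frac))
            bit = k * aln_len * max(pid - p0, 0.0) + rng.normal(0.0, params.bit_noise_sd)
            bit = max(bit, 1.0)
            e_value = min(10.0, aln_len * 2.0 ** (-bit) * 1e9)
            hits.append(
                HitRecord(
                    query_id=rec.id,
                    subject_id=ref_id,
                    percent_identity=round(pid, 2),
                    aln_length=aln_len,
                    e_value=e_value,
                    bit_score=round(bit, 1),
                    search_type=params.search_type,
                )
            )
        if hits:
            hits.sort(key=lambda h: (-h.bit_score, h.subject_id))
            out[rec.id] = hits
    return out


# --- planted protein families ----------------------------------------------


def plant_protein_families(
    n_families: int,
    family_sizes: int | Sequence[int] = 10,
    ec_labels: Mapping[int, Sequence[str]] | None = None,
    labeled_fraction: float = 0.5,
    within_score: float = 500.0,
    between_ratio: float = 0.1,
    between_prob: float = 0.1,
    between_log10_evalue: tuple[float, float] = (-50.0, -10.0),
    score_sd: float = 20.0,
    seed: int = 0,
) -> tuple[list[tuple[str, str, float, float]], dict[str, list[str]], dict[str, int]]:
    """Plant protein families as a similarity edge list with EC labels.

    Within-family edges carry strong bit scores around ``within_score``
    and vanishing e-values.  Spurious between-family similarity
    (probability ``between_prob`` per cross pair) scores
    ``between_ratio`` times the within score with e-values log-uniform
    over ``between_log10_evalue`` — most of them fall above a stringent
    e-value cutoff and are discarded at graph construction, as for real
    domain-level cross-family hits, so families are recoverable but not
    trivially disconnected.  A ``labeled_fraction`` of each family's
    members carries EC labels (the reference-database role); the rest
    are unlabelled environmental proteins.  Returns (edges, ec label
    table, true family index per protein).
    """
    if n_families < 1:
        raise ValueError("need at least one family")
    if isinstance(family_sizes, int):
        family_sizes = [family_sizes] * n_families
    if len(family_sizes) != n_families:
        raise ValueError("family_sizes length must match n_families")
    if any(s < 1 for s in family_sizes):
        raise ValueError("family size < 1")
    rng = np.random.default_rng(seed)

    members: list[list[str]] = []
    labels: dict[str, list[str]] = {}
    truth: dict[str, int] = {}
    for i, size in enumerate(family_sizes):
        fam_ecs = (
            list(ec_labels[i]) if ec_labels and i in ec_labels else [f"{i + 1}.1.1.{i + 1}"]
        )
        n_labeled = max(1, int(round(labeled_fraction * size))) if size > 1 else 1
        fam = []
        for j in range(size):
            labeled = j < n_labeled
            name = f"{'ref' if labeled else 'env'}_f{i:03d}_p{j:03d}"
            fam.append(name)
            truth[name] = i
            if labeled:
                labels[name] = fam_ecs
        members.append(fam)

    edges: list[tuple[str, str, float, float]] = []
    for i, fam in enumerate(members):
        for a_idx in range(len(fam)):
            for b_idx in range(a_idx + 1, len(fam)):
                bit = max(1.0, rng.normal(within_score, score_sd))
                edges.append((fam[a_idx], fam[b_idx], 1e-60, bit))
    for i in range(n_families):
        for j in range(i + 1, n_families):
            for a in members[i]:
                for b in members[j]:
                    if rng.random() < between_prob:
                        bit = max(
                            1.0,
                            rng.normal(within_score * between_ratio, score_sd * between_ratio),
                        )
                        e_value = 10.0 ** rng.uniform(*between_log10_evalue)
                        edges.append((a, b, e_value, bit))
    return edges, labels, truth


# --- the shipped default scenario ------------------------------------------


def default_community(
    seed: int = 0,
    genome_length: int = 200_000,
    reference_distance: float = 0.25,
    signature_sd: float = 0.35,
) -> list[TaxonModel]:
    """Three-phylum mock community of a chemotrophic hot-spring streamer biofilm.

    The taxa emulate the dominant phyla of alkaline-spring streamer
    communities (an Aquificae-like bacterium, a Thermoproteales-like
    crenarchaeon and a Thermus-like deinococcus) with skewed abundances
    (0.5 / 0.3 / 0.2), distinct GC contents and idiosyncratic word-usage
    signatures.  Genomes are drawn at a reduced length so the full
    pipeline runs at desk scale; abundance and signature structure, not
    genome size, carry the signal the binner uses.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xC0FFEE)))
    spec = [
        (
            "aquificae_sp",
            Lineage.from_names(
                "Bacteria", "Aquificae", "Aquificae_c", "Aquificales",
                "Aquificaceae", "Thermocrinis_like", "Thermocrinis_like_sp",
            ),
            0.5,
            0.42,
        ),
        (
            "thermoproteales_sp",
            Lineage.from_names(
                "Archaea", "Crenarchaeota", "Thermoprotei", "Thermoproteales",
                "Thermoproteaceae", "Pyrobaculum_like", "Pyrobaculum_like_sp",
            ),
            0.3,
            0.55,
        ),
        (
            "thermus_sp",
            Lineage.from_names(
                "Bacteria", "Deinococcus-Thermus", "Deinococci", "Thermales",
                "Thermaceae", "Thermus_like", "Thermus_like_sp",
            ),
            0.2,
            0.65,
        ),
    ]
    return [
        TaxonModel(
            taxon_id=tid,
            lineage=lineage,
            genome_length=genome_length,
            abundance=abundance,
            transition=make_transition_table(rng, gc=gc, signature_sd=signature_sd),
            reference_distance=reference_distance,
        )
        for tid, lineage, abundance, gc in spec
    ]


def default_references(community: Sequence[TaxonModel]) -> dict[str, Lineage]:
    """Reference set: one congeneric species and one confamilial genus per taxon.

    Hot-spring taxa are sparsely represented in reference databases;
    a single close (congeneric) reference plus a confamilial one is the
    typical situation the homology stage faces.
    """
    refs: dict[str, Lineage] = {}
    for model in community:
        genus = model.lineage.name_at("genus")
        family_prefix = model.lineage.ranks[:5]
        refs[f"{model.taxon_id}_refA"] = Lineage(
            family_prefix + (genus, f"{genus}_refA")
        )
        refs[f"{model.taxon_id}_refC"] = Lineage(
            family_prefix + (f"{genus}_sister", f"{genus}_sister_ref")
        )
    return refs


def default_hit_params(
    community: Sequence[TaxonModel],
    references: Mapping[str, Lineage],
    search_type: str = "protein",
    hit_free_ids: frozenset[str] = frozenset(),
) -> HitSimParams:
    """Identity/probability maps tying reference distance to hit quality.

    The congeneric reference sits at each taxon's configured
    ``reference_distance``, the confamilial reference 8 identity points
    lower with a reduced hit probability, and cross-phylum references at
    55% identity — the regime where homology binning is informative but
    imperfect: a read that happens to miss its own-family references can
    still register (and be misled by) distant matches.
    """
    identity: dict[tuple[str, str], float] = {}
    hit_prob: dict[tuple[str, str], float] = {}
    for model in community:
        d = model.reference_distance
        own = identity_from_distance(d)
        # hit probability decays with distance: a self-reference (d = 0)
        # registers every read, a distant congener misses some
        p_own = float(np.clip(1.0 - 0.4 * d, 0.75, 1.0))
        p_fam = float(np.clip(0.7 - 0.8 * d, 0.3, 0.7))
        for ref_id in references:
            if ref_id.startswith(model.taxon_id + "_"):
                if ref_id.endswith("_refC"):
                    identity[(model.taxon_id, ref_id)] = max(own - 8.0, 45.0)
                    hit_prob[(model.taxon_id, ref_id)] = p_fam
                else:
                    identity[(model.taxon_id, ref_id)] = own
                    hit_prob[(model.taxon_id, ref_id)] = p_own
            else:
                identity[(model.taxon_id, ref_id)] = 55.0
                hit_prob[(model.taxon_id, ref_id)] = 0.5
    return HitSimParams(
        identity=identity,
        hit_prob=hit_prob,
        search_type=search_type,
        hit_free_ids=hit_free_ids,
    )


def default_scenario(
    seed: int = 0,
    n_reads: int = 1800,
    hit_free_fraction: float = 0.3,
) -> dict:
    """Simulate the full shipped scenario: reads, truth, both hit tables.

    A shared 30% of reads receives no hits in either search (novel
    sequence with no database representation), which is the pool the
    tetranucleotide stage must recruit.
    """
    root = np.random.SeedSequence((seed, 0x5EED))
    s_comm, s_reads, s_free, s_prot, s_nuc = (
        int(s.generate_state(1)[0] % 2**31) for s in root.spawn(5)
    )
    community = default_community(seed=s_comm)
    reads, truth = simulate_reads(
        community, n_reads=n_reads, paired=True, seed=s_reads, site="site1"
    )
    rng = np.random.default_rng(s_free)
    hit_free = frozenset(
        rec.id for rec in reads if rng.random() < hit_free_fraction
    )
    references = default_references(community)
    protein_hits = simulate_hit_table(
        reads, truth, references,
        default_hit_params(community, references, "protein", hit_free),
        seed=s_prot,
    )
    nucleotide_hits = simulate_hit_table(
        reads, truth, references,
        default_hit_params(community, references, "nucleotide", hit_free),
        seed=s_nuc,
    )
    return {
        "community": community,
        "reads": reads,
        "truth": truth,
        "references": references,
        "hit_free_ids": hit_free,
        "protein_hits": protein_hits,
        "nucleotide_hits": nucleotide_hits,
    }
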