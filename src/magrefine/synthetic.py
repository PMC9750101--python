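"""Ground-truth communities and noisy multi-binner outputs for testing.

The generator builds a small community with known contig-to-genome truth:
each genome is a set of contigs over which its domain's single-copy
markers are scattered uniformly (real marker clustering is irrelevant to
the algorithm, which never looks at coordinates).  A configurable noise
model then caricatures a binning tool's characteristic error modes —
splitting genomes, fusing genomes, dropping contigs, and pulling foreign
contigs into bins — while keeping each simulated binset a partition, as
real binners produce.  Everything is driven by Python's integer-based
``random.Random`` so fixed seeds reproduce bit-identically across
platforms.

The three default noise models mimic the qualitative contrasts reported
for popular binners: a high-completeness/high-contamination greedy binner,
a low-contamination/low-completeness cautious one, and a balanced one.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import ContigToBinRecord, MarkerSet, RawHit, default_marker_sets
from .refine import RefinementResult


@dataclass(frozen=True)
class SyntheticTruth:
    """A community with known contig membership and marker content."""

    genomes: Mapping[str, frozenset[str]]          # genome -> contigs
    contig_markers: Mapping[str, tuple[str, ...]]  # contig -> markers (with multiplicity)
    genome_domain: Mapping[str, str]               # genome -> domain name

    @property
    def contig_genome(self) -> dict[str, str]:
        return {c: g for g, contigs in self.genomes.items() for c in contigs}

    @property
    def contigs(self) -> set[str]:
        return {c for contigs in self.genomes.values() for c in contigs}


@dataclass(frozen=True)
class NoiseModel:
    """Error modes of one simulated binning tool.

    split_prob: chance a genome is split across two bins (an even
        bisection with random membership).
    merge_prob: chance a genome is fused into another genome's bin; fusion
        partners are drawn from the same domain, as real binners fuse
        compositionally similar genomes (a cross-domain fusion would also be
        invisible to a single domain's marker score, which is not the error
        mode this models).
    dropout_rate: per-contig chance of being left unbinned.
    contamination_rate: per-slot chance a bin steals a contig from another
        bin (the donor loses it, so the binset stays a partition).
    """

    label: str
    split_prob: float = 0.0
    merge_prob: float = 0.0
    dropout_rate: float = 0.0
    contamination_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for p in (self.split_prob, self.merge_prob, self.dropout_rate, self.contamination_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("noise probabilities must be in [0, 1]")


def default_noise_models(seed: int = 0) -> list[NoiseModel]:
    """Three binner caricatures: greedy, cautious, balanced.

    Rates are fixed properties of the simulated tools; *seed* only offsets
    their random streams.
    """
    return [
        NoiseModel(label="greedy", split_prob=0.05, merge_prob=0.08,
                   dropout_rate=0.02, contamination_rate=0.08, seed=seed * 13 + 1),
        NoiseModel(label="cautious", split_prob=0.25, merge_prob=0.0,
                   dropout_rate=0.08, contamination_rate=0.0, seed=seed * 13 + 2),
        NoiseModel(label="balanced", split_prob=0.08, merge_prob=0.05,
                   dropout_rate=0.04, contamination_rate=0.03, seed=seed * 13 + 3),
    ]


def generate_truth(
    n_genomes: int,
    contigs_per_genome: int = 30,
    markers_per_genome: int | None = None,
    duplicate_marker_rate: float = 0.02,
    archaeal_fraction: float = 0.2,
    seed: int = 0,
    marker_sets: Mapping[str, MarkerSet] | None = None,
) -> SyntheticTruth:
    """Build a community with known truth.

    Each genome draws ``markers_per_genome`` markers without replacement
    from its domain's set (the whole set when ``None``) and scatters them
    uniformly over its contigs; each marker additionally gains one extra
    copy with probability ``duplicate_marker_rate``.  The first
    ``round(archaeal_fraction * n_genomes)`` genomes are archaeal.
    """
    if n_genomes < 1:
        raise ValueError("n_genomes must be >= 1")
    if marker_sets is None:
        marker_sets = default_marker_sets()
    domains = list(marker_sets)
    if markers_per_genome is not None:
        smallest = min(ms.size for ms in marker_sets.values())
        if markers_per_genome > smallest:
            raise ValueError(
                f"markers_per_genome={markers_per_genome} exceeds the smallest "
                f"marker-set size ({smallest})")

    rng = random.Random(seed)
    n_archaeal = round(archaeal_fraction * n_genomes)
    genomes: dict[str, frozenset[str]] = {}
    contig_markers: dict[str, tuple[str, ...]] = {}
    genome_domain: dict[str, str] = {}

    for i in range(n_genomes):
        gid = f"g{i + 1:03d}"
        domain = domains[-1] if i < n_archaeal and len(domains) > 1 else domains[0]
        mset = marker_sets[domain]
        contigs = [f"{gid}_c{j + 1:03d}" for j in range(contigs_per_genome)]
        pool = sorted(mset.marker_ids)
        k = markers_per_genome if markers_per_genome is not None else mset.size
        markers = rng.sample(pool, k)
        per_contig: dict[str, list[str]] = {c: [] for c in contigs}
        for m in markers:
            per_contig[rng.choice(contigs)].append(m)
            if rng.random() < duplicate_marker_rate:
                per_contig[rng.choice(contigs)].append(m)
        genomes[gid] = frozenset(contigs)
        genome_domain[gid] = domain
        for c in contigs:
            contig_markers[c] = tuple(per_contig[c])

    return SyntheticTruth(genomes=genomes, contig_markers=contig_markers,
                          genome_domain=genome_domain)


def truth_annotation_hits(truth: SyntheticTruth) -> list[RawHit]:
    """Protein-level marker hits implied by the truth.

    Protein ids follow the prodigal ``<contig>_<n>`` convention so the
    protein-to-contig mapping round-trips through the annotation parsers.
    """
    hits: list[RawHit] = []
    for contig in sorted(truth.contig_markers):
        for i, marker in enumerate(truth.contig_markers[contig], start=1):
            hits.append(RawHit(protein_id=f"{contig}_{i}", marker_id=marker,
                               evalue=1e-20, bitscore=100.0))
    return hits


def _apply_noise(truth: SyntheticTruth, model: NoiseModel) -> list[ContigToBinRecord]:
    rng = random.Random(model.seed)
    order = sorted(truth.genomes)

    # dropout: each contig unbinned independently
    kept: dict[str, list[str]] = {}
    for gid in order:
        kept[gid] = [c for c in sorted(truth.genomes[gid])
                     if rng.random() >= model.dropout_rate]

    # split / merge: one event per genome, split takes precedence; fusion
    # only with an earlier bin of the same domain
    bins: dict[str, set[str]] = {}
    merge_targets: dict[str, list[str]] = {}
    n = 0
    for gid in order:
        contigs = kept[gid]
        if not contigs:
            continue
        domain = truth.genome_domain[gid]
        targets = merge_targets.setdefault(domain, [])
        if len(contigs) >= 2 and rng.random() < model.split_prob:
            # an even bisection with random membership: split events in real
            # binners yield substantial fragments, not single contigs
            shuffled = contigs[:]
            rng.shuffle(shuffled)
            cut = len(shuffled) // 2
            for part in (shuffled[:cut], shuffled[cut:]):
                n += 1
                bins[f"{model.label}_bin{n:03d}"] = set(part)
        elif targets and rng.random() < model.merge_prob:
            bins[rng.choice(targets)].update(contigs)
        else:
            n += 1
            bid = f"{model.label}_bin{n:03d}"
            bins[bid] = set(contigs)
            targets.append(bid)

    # contamination: steal contigs from other bins, preserving the partition
    if model.contamination_rate > 0 and len(bins) > 1:
        for bid in sorted(bins):
            others = [b for b in sorted(bins) if b != bid and bins[b]]
            if not others:
                continue
            n_steal = sum(1 for _ in range(len(bins[bid]))
                          if rng.random() < model.contamination_rate)
            for _ in range(n_steal):
                donors = [b for b in others if len(bins[b]) > 1]
                if not donors:
                    break
                donor = rng.choice(donors)
                stolen = rng.choice(sorted(bins[donor]))
                bins[donor].discard(stolen)
                bins[bid].add(stolen)

    records: list[ContigToBinRecord] = []
    for bid in sorted(bins):
        for contig in sorted(bins[bid]):
            records.append(ContigToBinRecord(bin_id=bid, contig_id=contig,
                                             binset_label=model.label))
    return records


def simulate_binners(
    truth: SyntheticTruth,
    models: Sequence[NoiseModel],
) -> tuple[list[list[ContigToBinRecord]], list[RawHit]]:
    """One contig-to-bin record list per noise model, plus the shared
    protein-level annotation table.

    Every binset is a partition by construction.  With all-zero noise each
    binset equals the truth exactly (one bin per genome).
    """
    if not models:
        raise ValueError("at least one noise model is required")
    binsets = [_apply_noise(truth, model) for model in models]
    return binsets, truth_annotation_hits(truth)


def evaluate_against_truth(
    result: "RefinementResult | Mapping[str, Iterable[str]] | Iterable[ContigToBinRecord]",
    truth: SyntheticTruth,
) -> pd.DataFrame:
    """Per-genome recovery of a refinement result or a raw binset.

    Each bin is assigned to its plurality genome;
    ``true_completeness`` is the fraction of that genome's contigs the bin
    recovered and ``purity`` the fraction of the bin's contigs that belong
    to it.  Genomes claimed by several bins keep their best bin (highest
    completeness, then purity); unrecovered genomes get zeros.  Returns a
    DataFrame indexed by genome with columns ``bin_id``,
    ``true_completeness`` and ``purity``.
    """
    if isinstance(result, RefinementResult):
        bins: dict[str, set[str]] = {b.bin_id: set(b.contigs) for b, _ in result.selected}
    elif isinstance(result, Mapping):
        bins = {bid: set(contigs) for bid, contigs in result.items()}
    else:
        bins = {}
        for rec in result:
            bins.setdefault(rec.bin_id, set()).add(rec.contig_id)

    contig_genome = truth.contig_genome
    best: dict[str, tuple[float, float, str]] = {}
    for bid in sorted(bins):
        contigs = bins[bid]
        if not contigs:
            continue
        per_genome: dict[str, int] = {}
        for c in contigs:
            g = contig_genome.get(c)
            if g is not None:
                per_genome[g] = per_genome.get(g, 0) + 1
        if not per_genome:
            continue
        genome = min(per_genome, key=lambda g: (-per_genome[g], g))
        completeness = per_genome[genome] / len(truth.genomes[genome])
        purity = per_genome[genome] / len(contigs)
        cur = best.get(genome)
        if cur is None or (completeness, purity) > (cur[0], cur[1]):
            best[genome] = (completeness, purity, bid)

    rows = []
    for gid in sorted(truth.genomes):
        compl, purity, bid = best.get(gid, (0.0, 0.0, ""))
        rows.append({"genome": gid, "bin_id": bid,
                     "true_completeness": compl, "purity": purity})
    return pd.DataFrame(rows).set_index("genome")


def count_high_quality(
    table: pd.DataFrame,
    min_completeness: float = 0.9,
    min_purity: float = 0.9,
) -> int:
    """Number of genomes recovered at the given completeness/purity tier."""
    ok = (table["true_completeness"] >= min_completeness) & (table["purity"] >= min_purity)
    return int(ok.sum())


def standard_fixture(
    seed: int = 42,
    n_genomes: int = 20,
) -> tuple[SyntheticTruth, list[NoiseModel], list[list[ContigToBinRecord]], list[RawHit]]:
    """The canonical benchmark community: *n_genomes* genomes (20% archaeal,
    30 contigs each, full domain marker sets, 2% marker duplication) binned
    by the three default noise models."""
    truth = generate_truth(
        n_genomes=n_genomes, contigs_per_genome=30, markers_per_genome=None,
        duplicate_marker_rate=0.02, archaeal_fraction=0.2, seed=seed,
    )
    models = default_noise_models(seed=seed)
    binsets, hits = simulate_binners(truth, models)
    return truth, models, binsets, hits
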