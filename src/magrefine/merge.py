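"""Hybrid candidate bins from pairs of bins sharing marker genes.

Different binners often recover overlapping fragments of the same genome.
Before scoring, every bin carrying enough marker genes is compared with
every other; when the proportion of shared marker-annotated *genes* —
annotated protein instances, shared exactly when the bins share the
contigs carrying them — reaches a threshold, the union of the two contig
sets is added as a new "hybrid" candidate.  Gene-level overlap is what
makes the scan selective: near-complete genomes of the same domain carry
nearly identical marker *identifier* sets, but only bins covering the same
genome share the actual annotated genes.  The scan runs for a configurable
number of iterations (hybrids from the previous round are compared against
original bins only), letting a hybrid absorb additional fragments.
Originals are never removed: hybrids merely compete with them in the
scoring stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

from .io import ContigToBinRecord
from .profiles import MarkerProfile

HYBRID_ORIGIN = "hybrid"


@dataclass(frozen=True)
class Bin:
    """A named set of contigs with an origin label.

    ``origin`` is the producing binset's label, or ``"hybrid"`` for merged
    candidates, in which case ``parents`` names the two ancestors.
    """

    bin_id: str
    origin: str
    contigs: frozenset[str]
    parents: tuple[str, ...] = ()

    def __post_init__(self):
        if (self.origin == HYBRID_ORIGIN) != bool(self.parents):
            raise ValueError("hybrid origin requires parents and vice versa")


class BinCollection:
    """An ordered, id-unique collection of candidate bins."""

    def __init__(self, bins: Iterable[Bin] = ()):
        self._bins: dict[str, Bin] = {}
        for b in bins:
            self.add(b)

    def add(self, b: Bin) -> None:
        if b.bin_id in self._bins:
            raise ValueError(f"duplicate bin id {b.bin_id!r}")
        self._bins[b.bin_id] = b

    def __iter__(self) -> Iterator[Bin]:
        return iter(self._bins.values())

    def __len__(self) -> int:
        return len(self._bins)

    def __contains__(self, bin_id: str) -> bool:
        return bin_id in self._bins

    def __getitem__(self, bin_id: str) -> Bin:
        return self._bins[bin_id]

    def copy(self) -> "BinCollection":
        return BinCollection(self)

    @property
    def contigs(self) -> set[str]:
        out: set[str] = set()
        for b in self:
            out |= b.contigs
        return out

    def origins(self) -> list[str]:
        seen: dict[str, None] = {}
        for b in self:
            seen.setdefault(b.origin, None)
        return list(seen)

    def by_origin(self) -> dict[str, list[Bin]]:
        out: dict[str, list[Bin]] = {}
        for b in self:
            out.setdefault(b.origin, []).append(b)
        return out

    @classmethod
    def from_records(cls, records: Iterable[ContigToBinRecord]) -> "BinCollection":
        """Group contig-to-bin records into bins.

        Bin ids are qualified as ``<binset_label>.<bin_id>`` so identically
        named bins from different binners never collide.
        """
        grouped: dict[tuple[str, str], set[str]] = {}
        for rec in records:
            grouped.setdefault((rec.binset_label, rec.bin_id), set()).add(rec.contig_id)
        coll = cls()
        for (label, bin_id), contigs in sorted(grouped.items()):
            coll.add(Bin(bin_id=f"{label}.{bin_id}", origin=label, contigs=frozenset(contigs)))
        return coll


@dataclass(frozen=True)
class MergeParams:
    """Knobs of the hybrid-creation scan.

    min_markers: a bin enters the scan only with at least this many distinct
        markers (default 20) — tiny fragments produce spurious overlaps.
    overlap_threshold: shared-marker proportion required to merge
        (default 0.8).
    iterations: scan rounds (default 2); round 2+ pairs fresh hybrids with
        originals only.
    denominator: what "proportion" is relative to — the smaller profile
        (``min``, default: symmetric, catches fragment-vs-superset pairs),
        the ``union`` of both, or the ``query`` (first) profile.
    inclusive: whether the threshold itself qualifies (default: yes).
    enabled: the whole step can be switched off.
    """

    min_markers: int = 20
    overlap_threshold: float = 0.8
    iterations: int = 2
    denominator: str = "min"
    inclusive: bool = True
    enabled: bool = True

    def __post_init__(self):
        if not 0 < self.overlap_threshold <= 1:
            raise ValueError("overlap_threshold must be in (0, 1]")
        if self.iterations < 0 or self.min_markers < 0:
            raise ValueError("iterations and min_markers must be >= 0")
        if self.denominator not in ("min", "union", "query"):
            raise ValueError(f"unknown overlap denominator {self.denominator!r}")


def set_overlap(a: frozenset, b: frozenset, denominator: str = "min") -> float:
    """Shared-element proportion of two sets, in [0, 1]; 0 if either is empty.

    ``min``: ``|A ∩ B| / min(|A|, |B|)`` (symmetric; a fragment scores 1.0
    against its superset); ``union``: Jaccard; ``query``: relative to *a*.
    """
    if not a or not b:
        return 0.0
    shared = len(a & b)
    if denominator == "min":
        denom = min(len(a), len(b))
    elif denominator == "union":
        denom = len(a | b)
    elif denominator == "query":
        denom = len(a)
    else:
        raise ValueError(f"unknown overlap denominator {denominator!r}")
    return shared / denom


def marker_overlap(
    profile_a: MarkerProfile,
    profile_b: MarkerProfile,
    denominator: str = "min",
) -> float:
    """Shared-marker proportion of two profiles, in [0, 1].

    A profile-level convenience around :func:`set_overlap`.  Note the merge
    scan itself compares marker *genes* (see :func:`propose_hybrids`), not
    marker identifiers: two near-complete bins of unrelated genomes share
    almost all marker ids but none of the annotated genes.
    """
    return set_overlap(profile_a.marker_ids, profile_b.marker_ids, denominator)


def propose_hybrids(
    collection: BinCollection,
    contig_genes: Mapping[str, frozenset[str]],
    params: MergeParams = MergeParams(),
) -> BinCollection:
    """Grow the collection with hybrid bins; never removes an original.

    *contig_genes* maps each contig to the marker-annotated genes (protein
    ids) it carries, restricted to the union of the domain marker sets (see
    :func:`magrefine.profiles.contig_marker_genes`).  A bin's gene content
    is the union over its contigs; a pair merges when both carry at least
    ``min_markers`` genes and their gene-level overlap reaches the
    threshold.

    Hybrid ids are ``hybrid_<k>`` numbered in deterministic scan order
    (pairs sorted by bin id); a hybrid whose contig set duplicates any
    existing candidate is dropped.
    """
    out = collection.copy()
    if not params.enabled or params.iterations == 0:
        return out

    def genes_of(b: Bin) -> frozenset[str]:
        out_genes: set[str] = set()
        for contig in b.contigs:
            out_genes |= contig_genes.get(contig, frozenset())
        return frozenset(out_genes)

    genes: dict[str, frozenset[str]] = {b.bin_id: genes_of(b) for b in collection}
    existing_sets: set[frozenset[str]] = {b.contigs for b in collection}
    originals = sorted(collection, key=lambda b: b.bin_id)
    k = 0
    prev_hybrids: list[Bin] = []

    for iteration in range(params.iterations):
        if iteration == 0:
            pairs = ((a, b) for i, a in enumerate(originals) for b in originals[i + 1:])
        else:
            pairs = ((h, o) for h in prev_hybrids for o in originals)
        new_hybrids: list[Bin] = []
        for a, b in pairs:
            ga, gb = genes[a.bin_id], genes[b.bin_id]
            if len(ga) < params.min_markers or len(gb) < params.min_markers:
                continue
            ov = set_overlap(ga, gb, params.denominator)
            qualifies = ov >= params.overlap_threshold if params.inclusive else ov > params.overlap_threshold
            if not qualifies:
                continue
            union = a.contigs | b.contigs
            if union in existing_sets:
                continue
            k += 1
            hybrid = Bin(
                bin_id=f"hybrid_{k}",
                origin=HYBRID_ORIGIN,
                contigs=frozenset(union),
                parents=tuple(sorted((a.bin_id, b.bin_id))),
            )
            out.add(hybrid)
            existing_sets.add(hybrid.contigs)
            genes[hybrid.bin_id] = ga | gb
            new_hybrids.append(hybrid)
        if not new_hybrids:
            break
        prev_hybrids = new_hybrids
    return out
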