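"""Resolve raw marker hits to per-contig annotations and per-bin profiles.

Proteins follow the prodigal naming convention ``<contig>_<orf-number>``;
stripping the final numeric suffix maps a protein back to its contig.  One
marker is accepted per protein (best bit score), after which per-bin copy
counts of each marker in a domain set form the bin's marker profile — the
sole statistic the scoring and merging steps consume.
"""

from __future__ import annotations

import logging
import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .io import MarkerSet, RawHit

logger = logging.getLogger("magrefine")

_ORF_SUFFIX = re.compile(r"_\d+$")
_warned_no_suffix = False


def reset_warnings() -> None:
    """Re-arm the once-per-run protein-naming warning (used between CLI runs)."""
    global _warned_no_suffix
    _warned_no_suffix = False


@dataclass(frozen=True)
class MarkerAnnotation:
    """One accepted protein-to-marker assignment, resolved to its contig."""

    contig_id: str
    protein_id: str
    marker_id: str
    bitscore: float


@dataclass(frozen=True)
class MarkerProfile:
    """Copy counts of the markers of one domain set observed in one bin."""

    bin_id: str
    counts: Mapping[str, int]

    @property
    def unique_count(self) -> int:
        """Number of distinct markers present at least once."""
        return len(self.counts)

    @property
    def total_count(self) -> int:
        """Total marker copies, duplicates included."""
        return sum(self.counts.values())

    @property
    def marker_ids(self) -> frozenset[str]:
        return frozenset(self.counts)


def protein_to_contig(protein_id: str) -> str:
    """Strip the prodigal ``_<orf-number>`` suffix to recover the contig id.

    Ids without such a suffix are returned unchanged; the first occurrence
    per run triggers a warning, since it usually means the proteins were not
    named by prodigal and the contig mapping may be wrong.
    """
    global _warned_no_suffix
    stripped = _ORF_SUFFIX.sub("", protein_id)
    if stripped == protein_id or not stripped:
        if not _warned_no_suffix:
            logger.warning(
                "protein id %r has no trailing _<number> ORF suffix; "
                "using it verbatim as the contig id", protein_id)
            _warned_no_suffix = True
        return protein_id
    return stripped


def select_best_hits(hits: Iterable[RawHit], evalue_cutoff: float = 1e-5) -> list[MarkerAnnotation]:
    """Filter hits by E-value and keep one marker per protein.

    Hits with ``evalue > evalue_cutoff`` are discarded.  Among the survivors
    sharing a protein, the highest bit score wins; ties break by lowest
    E-value, then lexicographically smallest marker id, so the outcome is
    deterministic.  Kept hits are resolved to their contigs.
    """
    best: dict[str, RawHit] = {}
    for hit in hits:
        if hit.evalue > evalue_cutoff:
            continue
        cur = best.get(hit.protein_id)
        if cur is None or (-hit.bitscore, hit.evalue, hit.marker_id) < (-cur.bitscore, cur.evalue, cur.marker_id):
            best[hit.protein_id] = hit
    return [
        MarkerAnnotation(
            contig_id=protein_to_contig(pid),
            protein_id=pid,
            marker_id=h.marker_id,
            bitscore=h.bitscore,
        )
        for pid, h in sorted(best.items())
    ]


def contig_marker_counts(
    annotations: Iterable[MarkerAnnotation],
    marker_set: MarkerSet,
) -> dict[str, Counter]:
    """Per-contig copy counts of the markers belonging to *marker_set*."""
    out: dict[str, Counter] = defaultdict(Counter)
    for ann in annotations:
        if ann.marker_id in marker_set:
            out[ann.contig_id][ann.marker_id] += 1
    return dict(out)


def contig_marker_genes(
    annotations: Iterable[MarkerAnnotation],
    marker_ids: frozenset[str] | set[str],
) -> dict[str, frozenset[str]]:
    """Per-contig sets of marker-annotated genes (protein ids).

    Only annotations whose marker lies in *marker_ids* (typically the union
    of the bacterial and archaeal sets) count.  This gene-level view feeds
    the hybrid-merge overlap scan: two bins share a gene exactly when they
    share the contig carrying it.
    """
    out: dict[str, set[str]] = defaultdict(set)
    for ann in annotations:
        if ann.marker_id in marker_ids:
            out[ann.contig_id].add(ann.protein_id)
    return {contig: frozenset(genes) for contig, genes in out.items()}


def profile_from_contigs(
    bin_id: str,
    contigs: Iterable[str],
    contig_counts: Mapping[str, Counter],
) -> MarkerProfile:
    """Sum per-contig marker counts over a bin's contigs."""
    counts: Counter = Counter()
    for contig in contigs:
        hits = contig_counts.get(contig)
        if hits:
            counts.update(hits)
    return MarkerProfile(bin_id=bin_id, counts=dict(counts))


def build_profiles(
    bins,
    annotations: Iterable[MarkerAnnotation],
    marker_set: MarkerSet,
) -> dict[str, MarkerProfile]:
    """Marker profile of every bin in a collection for one domain set.

    *bins* is any iterable of objects exposing ``bin_id`` and ``contigs``
    (a :class:`~magrefine.merge.BinCollection` qualifies).  Annotations whose
    marker is outside *marker_set* are ignored; bins whose contigs carry no
    markers get an empty profile.
    """
    contig_counts = contig_marker_counts(annotations, marker_set)
    return {
        b.bin_id: profile_from_contigs(b.bin_id, b.contigs, contig_counts)
        for b in bins
    }
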