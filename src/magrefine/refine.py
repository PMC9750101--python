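"""Iterative scoring, selection and dereplication of candidate bins.

Each round the highest-scoring candidate is promoted to the output and its
contigs are deleted from every remaining candidate, so the final bins are
pairwise disjoint.  The loop stops when no candidate reaches the reporting
threshold *t*.

Two shortcuts keep the loop fast without changing its outcome under normal
inputs:

* only candidates that shared contigs with the last winner are re-scored —
  nothing else changed;
* when the winner and the previous winner come from the same input binset
  and every input binset is a verified partition, even that re-scoring is
  skipped: within a partition the winner's contigs cannot occur in another
  bin of its own set, so consecutive same-set winners were untouched by
  each other's dereplication.  The skip never applies after a hybrid wins,
  since a hybrid's contigs span several input sets at once.

Candidates whose (weighted) completeness falls below *t* are pruned: their
score is bounded above by ``a * completeness`` and completeness only drops
as contigs are removed, so they can never reach *t* again.

:func:`refine_naive` re-scores everything every round with no pruning and
serves as the correctness oracle for the optimised loop.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

from .io import ContigToBinRecord, MarkerSet
from .merge import Bin, BinCollection, HYBRID_ORIGIN
from .profiles import MarkerAnnotation, contig_marker_counts, profile_from_contigs
from .scoring import BinScore, ScoringWeights, score_bin

logger = logging.getLogger("magrefine")


@dataclass(frozen=True)
class RefinementParams:
    weights: ScoringWeights = ScoringWeights()
    threshold_t: float = 0.5
    skip_heuristic: bool = True
    #: select while score >= t (default); with False, only while score > t
    select_inclusive: bool = True


@dataclass(frozen=True)
class AuditRecord:
    iteration: int
    winner_id: str
    origin: str
    score: float
    n_rescored: int
    n_pruned: int
    skip_applied: bool


@dataclass
class RefinementResult:
    """Ordered winners, the contigs nothing claimed, and the iteration log."""

    selected: list[tuple[Bin, BinScore]]
    leftover_contigs: set[str]
    audit: list[AuditRecord]

    @property
    def selected_ids(self) -> list[str]:
        return [b.bin_id for b, _ in self.selected]

    def contig_assignments(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for b, _ in self.selected:
            for contig in b.contigs:
                out[contig] = b.bin_id
        return out


def is_partition(binset: Iterable[ContigToBinRecord]) -> bool:
    """True iff no contig is assigned to two bins of this binset."""
    seen: dict[str, str] = {}
    for rec in binset:
        prev = seen.setdefault(rec.contig_id, rec.bin_id)
        if prev != rec.bin_id:
            return False
    return True


def _origins_partitioned(collection: BinCollection) -> bool:
    """True iff within every non-hybrid origin the bins are contig-disjoint."""
    for origin, bins in collection.by_origin().items():
        if origin == HYBRID_ORIGIN:
            continue
        seen: set[str] = set()
        for b in bins:
            if seen & b.contigs:
                return False
            seen |= b.contigs
    return True


@dataclass
class _Candidate:
    bin_id: str
    origin: str
    parents: tuple[str, ...]
    contigs: set[str]
    score: BinScore | None = None

    def to_bin(self) -> Bin:
        return Bin(bin_id=self.bin_id, origin=self.origin,
                   contigs=frozenset(self.contigs), parents=self.parents)


def _score_candidate(
    cand: _Candidate,
    domain_counts: Mapping[str, Mapping[str, Counter]],
    marker_sets: Mapping[str, MarkerSet],
    weights: ScoringWeights,
) -> BinScore:
    profiles = {
        domain: profile_from_contigs(cand.bin_id, cand.contigs, counts)
        for domain, counts in domain_counts.items()
    }
    return score_bin(cand.bin_id, profiles, marker_sets, weights)


def _selection_key(c: _Candidate):
    # highest score; ties by more unique markers, fewer contigs, smallest id
    s = c.score
    assert s is not None
    return (-s.score, -s.best.unique_markers, len(c.contigs), c.bin_id)


def _prune(candidates: dict[str, _Candidate], params: RefinementParams) -> int:
    """Drop candidates whose weighted completeness cannot reach t."""
    a, t = params.weights.a, params.threshold_t
    doomed = [
        cid for cid, c in candidates.items()
        if c.score is not None
        and a * max(ds.completeness for ds in c.score.domain_scores.values()) < t
    ]
    for cid in doomed:
        del candidates[cid]
    return len(doomed)


def refine(
    collection: BinCollection,
    annotations: Iterable[MarkerAnnotation],
    marker_sets: Mapping[str, MarkerSet],
    params: RefinementParams = RefinementParams(),
) -> RefinementResult:
    """Run the optimised selection/dereplication loop.

    Returns the ordered winners with the scores they held when selected,
    the contigs no winner claimed, and a per-iteration audit trail.
    """
    annotations = list(annotations)
    domain_counts = {
        name: contig_marker_counts(annotations, mset)
        for name, mset in marker_sets.items()
    }
    input_contigs = collection.contigs

    candidates: dict[str, _Candidate] = {
        b.bin_id: _Candidate(b.bin_id, b.origin, b.parents, set(b.contigs))
        for b in collection
    }

    skip_active = params.skip_heuristic
    if skip_active and not _origins_partitioned(collection):
        logger.info("an input binset is not a partition; "
                    "disabling the consecutive-winner re-scoring skip")
        skip_active = False

    for cand in candidates.values():
        cand.score = _score_candidate(cand, domain_counts, marker_sets, params.weights)
    n_pruned_initial = _prune(candidates, params)
    if n_pruned_initial:
        logger.debug("initial pruning removed %d candidates", n_pruned_initial)

    selected: list[tuple[Bin, BinScore]] = []
    audit: list[AuditRecord] = []
    prev_origin: str | None = None
    iteration = 0

    while candidates:
        winner = min(candidates.values(), key=_selection_key)
        assert winner.score is not None
        good = (winner.score.score >= params.threshold_t if params.select_inclusive
                else winner.score.score > params.threshold_t)
        if not good:
            break
        iteration += 1
        selected.append((winner.to_bin(), winner.score))
        del candidates[winner.bin_id]

        winner_contigs = winner.contigs
        affected = [c for c in candidates.values() if c.contigs & winner_contigs]
        for c in affected:
            c.contigs -= winner_contigs
        for c in affected:
            if not c.contigs:
                del candidates[c.bin_id]
        affected = [c for c in affected if c.bin_id in candidates]

        skip = (skip_active
                and winner.origin != HYBRID_ORIGIN
                and prev_origin == winner.origin)
        n_rescored = 0
        if not skip:
            for c in affected:
                c.score = _score_candidate(c, domain_counts, marker_sets, params.weights)
            n_rescored = len(affected)
        n_pruned = _prune(candidates, params)
        prev_origin = winner.origin

        audit.append(AuditRecord(
            iteration=iteration, winner_id=winner.bin_id, origin=winner.origin,
            score=winner.score.score, n_rescored=n_rescored,
            n_pruned=n_pruned, skip_applied=skip,
        ))

    selected_contigs = {c for b, _ in selected for c in b.contigs}
    result = RefinementResult(
        selected=selected,
        leftover_contigs=input_contigs - selected_contigs,
        audit=audit,
    )
    _assert_invariants(result, input_contigs)
    return result


def refine_naive(
    collection: BinCollection,
    annotations: Iterable[MarkerAnnotation],
    marker_sets: Mapping[str, MarkerSet],
    params: RefinementParams = RefinementParams(),
) -> RefinementResult:
    """Reference implementation: full re-scoring every round, no pruning.

    Produces the same selected list (ids, order, scores) as
    :func:`refine` with the skip heuristic off; used as an oracle in tests.
    """
    annotations = list(annotations)
    domain_counts = {
        name: contig_marker_counts(annotations, mset)
        for name, mset in marker_sets.items()
    }
    input_contigs = collection.contigs
    candidates: dict[str, _Candidate] = {
        b.bin_id: _Candidate(b.bin_id, b.origin, b.parents, set(b.contigs))
        for b in collection
    }

    selected: list[tuple[Bin, BinScore]] = []
    audit: list[AuditRecord] = []
    iteration = 0
    while candidates:
        for c in candidates.values():
            c.score = _score_candidate(c, domain_counts, marker_sets, params.weights)
        winner = min(candidates.values(), key=_selection_key)
        assert winner.score is not None
        good = (winner.score.score >= params.threshold_t if params.select_inclusive
                else winner.score.score > params.threshold_t)
        if not good:
            break
        iteration += 1
        selected.append((winner.to_bin(), winner.score))
        del candidates[winner.bin_id]
        for cid in list(candidates):
            c = candidates[cid]
            c.contigs -= winner.contigs
            if not c.contigs:
                del candidates[cid]
        audit.append(AuditRecord(
            iteration=iteration, winner_id=winner.bin_id, origin=winner.origin,
            score=winner.score.score, n_rescored=len(candidates),
            n_pruned=0, skip_applied=False,
        ))

    selected_contigs = {c for b, _ in selected for c in b.contigs}
    result = RefinementResult(
        selected=selected,
        leftover_contigs=input_contigs - selected_contigs,
        audit=audit,
    )
    _assert_invariants(result, input_contigs)
    return result


def _assert_invariants(result: RefinementResult, input_contigs: set[str]) -> None:
    """Disjointness and conservation hold on every run, not just in tests."""
    seen: set[str] = set()
    for b, _score in result.selected:
        overlap = seen & b.contigs
        assert not overlap, f"selected bins share contigs: {sorted(overlap)[:5]}"
        seen |= b.contigs
    assert seen <= input_contigs, "selected contigs not drawn from the input"
    assert result.leftover_contigs == input_contigs - seen
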