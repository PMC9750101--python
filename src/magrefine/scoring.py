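"""The weighted completeness/contamination score and the domain-max rule.

A bin's score against one domain's single-copy marker set is

    score = a * completeness - b * duplicate_fraction - c * multiplicate_fraction

with

    completeness          = unique markers present / markers in set
    duplicate_fraction    = markers present in >1 copy / unique markers present
    multiplicate_fraction = copies beyond the second / markers in set
                          = (total - unique - duplicated) / set size

The three terms are disjoint: a marker contributes to completeness once,
to the duplicate term once if it has a second copy, and every copy past
the second inflates the multiplicate term.  Defaults a=1, b=0.5, c=0.5.
A bin is scored against the bacterial and the archaeal set; the higher
score wins and names the bin's domain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .io import MarkerSet
from .profiles import MarkerProfile


@dataclass(frozen=True)
class ScoringWeights:
    a: float = 1.0  # completeness weight
    b: float = 0.5  # duplicate penalty
    c: float = 0.5  # multiplicate penalty

    def __post_init__(self):
        if self.a < 0 or self.b < 0 or self.c < 0:
            raise ValueError("scoring weights must be non-negative")


@dataclass(frozen=True)
class DomainScore:
    domain: str
    completeness: float
    duplicate_fraction: float
    multiplicate_fraction: float
    score: float
    unique_markers: int


@dataclass(frozen=True)
class BinScore:
    bin_id: str
    domain_scores: Mapping[str, DomainScore]
    best_domain: str

    @property
    def best(self) -> DomainScore:
        return self.domain_scores[self.best_domain]

    @property
    def score(self) -> float:
        return self.best.score


def score_profile(
    profile: MarkerProfile,
    marker_set: MarkerSet,
    weights: ScoringWeights = ScoringWeights(),
) -> DomainScore:
    """Score one bin's marker profile against one domain set.

    Degenerate cases are defined: an empty profile has all three terms 0
    (the 0/0 duplicate ratio is taken as 0) and scores 0.
    """
    unique = profile.unique_count
    total = profile.total_count
    n_duplicated = sum(1 for v in profile.counts.values() if v > 1)
    completeness = unique / marker_set.size
    duplicate_fraction = n_duplicated / unique if unique else 0.0
    multiplicate_fraction = (total - unique - n_duplicated) / marker_set.size
    score = (weights.a * completeness
             - weights.b * duplicate_fraction
             - weights.c * multiplicate_fraction)
    return DomainScore(
        domain=marker_set.name,
        completeness=completeness,
        duplicate_fraction=duplicate_fraction,
        multiplicate_fraction=multiplicate_fraction,
        score=score,
        unique_markers=unique,
    )


def score_bin(
    bin_id: str,
    profiles: Mapping[str, MarkerProfile],
    marker_sets: Mapping[str, MarkerSet],
    weights: ScoringWeights = ScoringWeights(),
) -> BinScore:
    """Score a bin against every domain set and keep the maximum.

    *marker_sets* order fixes the tie-break: on equal scores the earlier
    domain (bacteria, in the shipped defaults) wins.
    """
    domain_scores: dict[str, DomainScore] = {}
    best_domain = None
    for name, mset in marker_sets.items():
        prof = profiles.get(name) or MarkerProfile(bin_id=bin_id, counts={})
        ds = score_profile(prof, mset, weights)
        domain_scores[name] = ds
        if best_domain is None or ds.score > domain_scores[best_domain].score:
            best_domain = name
    assert best_domain is not None, "at least one marker set required"
    return BinScore(bin_id=bin_id, domain_scores=domain_scores, best_domain=best_domain)


def checkm_style_score(completeness: float, contamination: float) -> float:
    """The reporting summary ``completeness - 0.5 * contamination``.

    Both arguments must be on the same scale (0-1 or 0-100).  Used only to
    rank or tier finished bins (e.g. high quality above 0.9); never inside
    the refinement loop.
    """
    return completeness - 0.5 * contamination
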