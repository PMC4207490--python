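"""Pairwise locus similarity from weighted pfam-set comparison.

Two loci I and J, each represented by a pfam set with per-pfam ORF distances
from the envelope, are compared through three sets: C (pfams common to
both), D_IJ (pfams only in I) and D_JI (pfams only in J).  Shared pfams
build a positive component; disjoint pfams build a negative component
down-weighted by a factor k (shared content says more about similarity than
disjoint content).  Four weights modulate each pfam's contribution:

* distance weight — 1.0 for a pfam inside the envelope, decaying linearly
  by 0.1 per intervening ORF to a floor of 0.6 at four or more ORFs; genes
  far from the envelope are less likely to serve the BMC.
* identifying weight — a configurable boost (default 2.0) for pfams known a
  priori to diagnose a locus type (signature enzymes such as propanediol
  dehydratase or the carboxysomal CsoS2).
* rarity weight R(p) — the proportion of corpus loci *lacking* p; sharing a
  rare pfam is strong evidence of similarity, while ubiquitous core enzymes
  (AldDH, AlcDH) say little.  The positive component applies a small floor
  so fully ubiquitous shared pfams still contribute.
* co-occurrence weight — a disjoint pfam frequently found in corpus loci
  that contain the pair's common set C is a secondary/peripheral pfam; its
  negative contribution is scaled by (1 - F(p | C)), where F is the
  conditional frequency of p among loci whose pfam sets contain C.

The final score is positive minus negative and is exactly symmetric.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .model import LocusPfamProfile

logger = logging.getLogger("bmclocus")

#: distance-weight table: ORF distance -> weight; distances past the last
#: key take the last value (0.6 at d >= 4)
DEFAULT_DISTANCE_WEIGHTS: dict[int, float] = {0: 1.0, 1: 0.9, 2: 0.8, 3: 0.7, 4: 0.6}

#: identifying pfams shipped by default, with the locus type each diagnoses
DEFAULT_IDENTIFYING_PFAMS: dict[str, str] = {
    "PF12288": "alpha-carboxysome",   # CsoS2
    "PF08936": "alpha-carboxysome",   # CsoSCA
    "PF00132": "beta-carboxysome",    # CcmM
    "PF06751": "EUT",                 # ethanolamine ammonia lyase, large
    "PF05985": "EUT",                 # ethanolamine ammonia lyase, small
    "PF02286": "PDU",                 # propanediol dehydratase, alpha
    "PF02287": "PDU",                 # propanediol dehydratase, beta
    "PF02288": "PDU",                 # propanediol dehydratase, gamma
    "PF00596": "PVM",                 # class II aldolase
}


@dataclass
class ScoringParams:
    """Tunable weights of the locus similarity score.

    k is the negative-component weight (0 < k <= 1); identifying_boost
    multiplies identifying pfams in both components; rare_floor keeps
    ubiquitous shared pfams minimally contributing on the positive side;
    combine_rule merges the two loci's distance weights for a shared pfam.
    """

    k: float = 0.5
    identifying_pfams: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_IDENTIFYING_PFAMS)
    )
    identifying_boost: float = 2.0
    distance_weights: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_DISTANCE_WEIGHTS)
    )
    rare_floor: float = 0.05
    combine_rule: str = "mean"  # mean | product | min
    cooccurrence_subset_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.k <= 1:
            raise ValueError("k must lie in [0, 1]")
        if self.identifying_boost < 1:
            raise ValueError("identifying_boost must be >= 1")
        weights = [self.distance_weights[d] for d in sorted(self.distance_weights)]
        if any(b > a for a, b in zip(weights, weights[1:])):
            raise ValueError("distance weights must be non-increasing in d")
        if self.combine_rule not in ("mean", "product", "min"):
            raise ValueError(f"unknown combine_rule {self.combine_rule!r}")


@dataclass
class CorpusPfamStats:
    """Corpus-level pfam occurrence statistics.

    Built over the scoring corpus (non-truncated, non-satellite loci).
    ``profiles`` retains each locus's pfam set for the co-occurrence weight.
    """

    n_loci: int
    pfam_counts: dict[str, int]
    profiles: dict[str, frozenset[str]]

    @classmethod
    def from_profiles(cls, profiles: Iterable[LocusPfamProfile]) -> "CorpusPfamStats":
        sets = {p.locus_id: p.pfam_set for p in profiles}
        counts: dict[str, int] = {}
        for pfams in sets.values():
            for p in pfams:
                counts[p] = counts.get(p, 0) + 1
        return cls(n_loci=len(sets), pfam_counts=counts, profiles=sets)


@dataclass(frozen=True)
class ScoreBreakdown:
    """Pairwise similarity with its component sets and weighted sums."""

    locus_i: str
    locus_j: str
    common: frozenset[str]
    only_i: frozenset[str]
    only_j: frozenset[str]
    positive: float
    negative: float

    @property
    def score(self) -> float:
        return self.positive - self.negative


def distance_weight(d: int, params: Optional[ScoringParams] = None) -> float:
    """Weight of a pfam at ORF distance d from the envelope.

    1.0 inside the envelope (d=0), decreasing by 0.1 per ORF, clamped to 0.6
    for d >= 4.
    """
    if d < 0:
        raise ValueError("ORF distance cannot be negative")
    table = params.distance_weights if params is not None else DEFAULT_DISTANCE_WEIGHTS
    d_max = max(table)
    return table[min(d, d_max)]


def rare_weight(pfam_acc: str, stats: CorpusPfamStats) -> float:
    """R(p): the proportion of corpus loci that do not contain pfam p.

    0 for a pfam present in every locus; approaches (never reaches) 1 for
    very rare pfams.  A pfam absent from the corpus (a novel locus scored
    against a frozen corpus) is treated as present in one locus, with a
    warning.
    """
    count = stats.pfam_counts.get(pfam_acc)
    if count is None:
        logger.warning(
            "pfam %s not in corpus statistics; treating as singleton", pfam_acc
        )
        count = 1
    return 1.0 - count / stats.n_loci


def identifying_weight(pfam_acc: str, params: ScoringParams) -> float:
    """Boost for pfams diagnosing a known locus type; 1 otherwise."""
    return params.identifying_boost if pfam_acc in params.identifying_pfams else 1.0


def cooccurrence_weight(
    pfam_acc: str,
    common: frozenset[str],
    stats: CorpusPfamStats,
    subset_fraction: float = 1.0,
) -> float:
    """F(p | C): frequency of p among corpus loci whose pfam set contains C.

    With ``subset_fraction`` q < 1 the condition relaxes to containing at
    least a q fraction of C.  With C empty every locus qualifies, so F is
    the overall corpus frequency of p.
    """
    need = subset_fraction * len(common)
    denom = 0
    numer = 0
    for pfams in stats.profiles.values():
        if len(common & pfams) >= need:
            denom += 1
            if pfam_acc in pfams:
                numer += 1
    if denom == 0:
        logger.warning(
            "no corpus locus contains the common set; co-occurrence weight of %s "
            "set to 0",
            pfam_acc,
        )
        return 0.0
    return numer / denom


def _combine(w_i: float, w_j: float, rule: str) -> float:
    if rule == "mean":
        return 0.5 * (w_i + w_j)
    if rule == "product":
        return w_i * w_j
    return min(w_i, w_j)


def pairwise_score(
    profile_i: LocusPfamProfile,
    profile_j: LocusPfamProfile,
    stats: CorpusPfamStats,
    params: Optional[ScoringParams] = None,
) -> ScoreBreakdown:
    """Similarity score between two loci with its component breakdown.

    positive = sum over shared pfams of W_id * max(R, rare_floor) *
    combine(W_dist,I, W_dist,J); negative = k * sum over each locus's
    private pfams of W_id * R * W_dist * (1 - F(p | C)).  The score is
    positive - negative and symmetric under exchange of I and J.
    """
    params = params or ScoringParams()
    set_i, set_j = profile_i.pfam_set, profile_j.pfam_set
    common = set_i & set_j
    only_i = set_i - set_j
    only_j = set_j - set_i

    positive = 0.0
    for p in sorted(common):
        w_dist = _combine(
            distance_weight(profile_i.distance(p), params),
            distance_weight(profile_j.distance(p), params),
            params.combine_rule,
        )
        rarity = max(rare_weight(p, stats), params.rare_floor)
        positive += identifying_weight(p, params) * rarity * w_dist

    def _private_sum(private: frozenset[str], profile: LocusPfamProfile) -> float:
        total = 0.0
        for p in sorted(private):
            f = cooccurrence_weight(
                p, common, stats, params.cooccurrence_subset_fraction
            )
            total += (
                identifying_weight(p, params)
                * rare_weight(p, stats)
                * distance_weight(profile.distance(p), params)
                * (1.0 - f)
            )
        return total

    negative = params.k * (
        _private_sum(only_i, profile_i) + _private_sum(only_j, profile_j)
    )
    return ScoreBreakdown(
        locus_i=profile_i.locus_id,
        locus_j=profile_j.locus_id,
        common=frozenset(common),
        only_i=frozenset(only_i),
        only_j=frozenset(only_j),
        positive=positive,
        negative=negative,
    )


def score_all_pairs(
    profiles: Sequence[LocusPfamProfile],
    params: Optional[ScoringParams] = None,
    stats: Optional[CorpusPfamStats] = None,
) -> list[ScoreBreakdown]:
    """Score every unordered locus pair, ordered by (locus_i, locus_j).

    Corpus statistics default to the given profiles themselves; pass
    ``stats`` to score against a different (e.g. frozen) corpus.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles to score pairs")
    stats = stats or CorpusPfamStats.from_profiles(profiles)
    ordered = sorted(profiles, key=lambda p: p.locus_id)
    return [
        pairwise_score(a, b, stats, params)
        for a, b in itertools.combinations(ordered, 2)
    ]
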