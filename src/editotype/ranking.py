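"""Candidate ranking and the dependence-based candidate filter.

For each PPR protein, candidate editing sites are ranked by descending
binding score (competition ranking: ties share the smallest applicable
rank, deterministic tie-break by site id).  For E+ proteins — which
require the trans-acting DYW-domain donor DYW2 for catalysis, so their
targets must lie among the DYW2-dependent sites — the candidate list can
be restricted to that dependent set, which can only improve (never
worsen) the rank of any retained site.  The converse restriction is
invalid: DYW2-dependent sites include targets of non-E+ proteins (an
E-class protein, MEF19, and a P-class protein, PPME, each have one), so
dependence cannot shrink the protein shortlist of a dependent site; only
DYW2-*independent* sites may drop E+ proteins from their shortlists.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .pprcode import PPRProtein

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CandidateSet:
    """A labelled set of candidate editing-site ids."""

    label: str  # "full" or "dyw2_dependent"
    site_ids: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "site_ids", frozenset(self.site_ids))


@dataclass(frozen=True)
class RankedPrediction:
    """One (protein, site) prediction with full and filtered ranks.

    ``rank_filtered`` is None unless the dependence filter applies and
    retains the site; when present it never exceeds ``rank_full``.
    """

    protein_id: str
    site_id: str
    score: float
    rank_full: int
    rank_filtered: int | None = None


def _competition_ranks(scored: Sequence[tuple[str, float]]) -> dict[str, int]:
    """Competition rank per site: 1 + number of strictly better scores."""
    ranks = {}
    for site_id, score in scored:
        ranks[site_id] = 1 + sum(1 for _, s in scored if s > score)
    return ranks


def rank_targets(
    protein: PPRProtein | str,
    candidates: CandidateSet | Iterable[str],
    scores: Mapping[str, float],
) -> list[RankedPrediction]:
    """Rank every candidate site of a protein by descending score.

    Output is sorted by descending score with ties broken by ascending
    site id, so identical inputs always give identical ordered output.
    """
    protein_id = protein.protein_id if isinstance(protein, PPRProtein) else protein
    ids = candidates.site_ids if isinstance(candidates, CandidateSet) else set(candidates)
    if not ids:
        raise ValueError(f"protein {protein_id}: empty candidate set")
    missing = sorted(ids - set(scores))
    if missing:
        raise ValueError(f"protein {protein_id}: no score for candidates {missing}")
    scored = sorted(((sid, scores[sid]) for sid in ids), key=lambda t: (-t[1], t[0]))
    ranks = _competition_ranks(scored)
    return [
        RankedPrediction(protein_id=protein_id, site_id=sid, score=s, rank_full=ranks[sid])
        for sid, s in scored
    ]


def apply_dependence_filter(
    protein: PPRProtein,
    full_ranking: Sequence[RankedPrediction],
    dependent_set: Iterable[str],
) -> list[RankedPrediction]:
    """Restrict an E+ protein's ranking to the dependent candidate set.

    Refuses non-E+ proteins: dependence of a site does not identify the
    subfamily of its editing factor (MEF19's and PPME's targets are
    dependent yet not E+-associated), so the filter direction is valid
    only from E+ protein to dependent sites.  Relative order is
    preserved and every retained site's filtered rank is <= its full
    rank.
    """
    if protein.subfamily != "E+":
        raise ValueError(
            f"protein {protein.protein_id} is subfamily {protein.subfamily!r}: "
            "the dependent-site filter applies only to E+ proteins — dependent "
            "sites are not exclusively E+ targets, so the restriction is "
            "one-directional"
        )
    dependent = set(dependent_set)
    extra = dependent - {r.site_id for r in full_ranking}
    if extra:
        raise ValueError(
            f"dependent set contains ids outside the full candidate set: {sorted(extra)}"
        )
    retained = [r for r in full_ranking if r.site_id in dependent]
    ranks = _competition_ranks([(r.site_id, r.score) for r in retained])
    return [
        RankedPrediction(
            protein_id=r.protein_id,
            site_id=r.site_id,
            score=r.score,
            rank_full=r.rank_full,
            rank_filtered=ranks[r.site_id],
        )
        for r in retained
    ]


def evaluate_improvement(
    pairs: Sequence[tuple[int, int]],
) -> dict[str, float]:
    """Summarize (rank_full, rank_filtered) pairs.

    Checks the monotonicity guarantee (no pair may worsen), then reports
    counts, the improvement fraction and the two median ranks.
    """
    if not pairs:
        raise ValueError("no rank pairs to evaluate")
    for full, filt in pairs:
        if full < 1 or filt < 1:
            raise ValueError(f"ranks must be >= 1, got ({full}, {filt})")
        if filt > full:
            raise ValueError(
                f"filtered rank {filt} worse than full rank {full}: "
                "candidate-set restriction cannot demote a retained site"
            )
    n = len(pairs)
    n_improved = sum(1 for full, filt in pairs if filt < full)
    return {
        "n": n,
        "n_improved": n_improved,
        "n_unchanged": n - n_improved,
        "improvement_fraction": n_improved / n,
        "median_full": float(statistics.median(full for full, _ in pairs)),
        "median_filtered": float(statistics.median(filt for _, filt in pairs)),
    }


def candidate_shortlist_for_non_eplus(
    full_candidates: Iterable[str],
    dependent_set: Iterable[str],
    ppr_panel: Sequence[PPRProtein],
) -> dict[str, list[str]]:
    """Per-site eligible-protein shortlists using the dependence split.

    Characterized DYW2-independent sites are, so far, exclusively served
    by non-E+ proteins, so for each independent site the E+ proteins are
    dropped from its shortlist.  Dependent sites keep the whole panel
    (their factor's subfamily is not pinned down by dependence alone).
    Proteins lacking a subfamily label are kept with a warning.
    """
    dependent = set(dependent_set)
    shortlists: dict[str, list[str]] = {}
    for site_id in sorted(set(full_candidates)):
        eligible = []
        for protein in ppr_panel:
            subfamily = protein.subfamily
            if not subfamily:
                logger.warning(
                    "protein %s has no subfamily label; kept in every shortlist",
                    protein.protein_id,
                )
                eligible.append(protein.protein_id)
                continue
            if site_id not in dependent and subfamily == "E+":
                continue
            eligible.append(protein.protein_id)
        shortlists[site_id] = eligible
    return shortlists
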