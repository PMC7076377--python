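"""Differential-editing statistics and dependence classification.

Compares the editotype of a mutant against the wild type site by site:
relative change of editing extent (dEE), a two-sided Fisher exact test on
the pooled edited/unedited read counts, Bonferroni adjustment over the
sites actually tested, and a dependence call — a site depends on the
mutated factor when the adjusted p-value is significant AND editing
*decreases* by more than a threshold (default 25 percentage-relative).
Editing increases, which do occur when removing one factor unmasks
another, are reported as differential but never as dependent.

Also implements the cis-element overlap analysis: each editing site's
upstream cis-element spans transcript positions -31..-4 relative to the
edited C, and sites whose window contains another editing site are
flagged, since the C/U state of the contained site can modulate the
affinity of the PPR protein reading the window.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .quantify import EditingSite

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
DEFAULT_DELTA_THRESHOLD = 25.0  # percent decrease required for dependence
CIS_WINDOW = (-31, -4)  # transcript-strand offsets of the cis-element


@dataclass(frozen=True)
class DifferentialEditingResult:
    """Per-site differential-editing summary (percent scale).

    ``delta_ee`` is the relative change 100 * (EE_mut - EE_wt) / EE_wt;
    it is NaN (``delta_defined`` False) when EE_wt is zero.  ``dependent``
    requires both Bonferroni significance and a decrease beyond the
    threshold, so ``dependent`` implies ``significant``.
    """

    site_id: str
    ee_wt: float  # percent
    ee_mut: float  # percent
    delta_ee: float  # percent change, NaN when undefined
    p_value: float
    p_adj: float
    significant: bool
    dependent: bool

    @property
    def delta_defined(self) -> bool:
        return not math.isnan(self.delta_ee)


def delta_ee(ee_wt: float, ee_mut: float) -> float:
    """Relative change of editing extent, in percent of the WT extent.

    Inputs are percentages in [0, 100].  Returns NaN when ``ee_wt`` is 0
    (the relative change is undefined, not an error).  The result is
    bounded below by -100 (attained only when ``ee_mut`` is 0).
    """
    for v, label in ((ee_wt, "ee_wt"), (ee_mut, "ee_mut")):
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"{label}={v} outside [0, 100]")
    if ee_wt == 0.0:
        return math.nan
    # clamp float rounding at the mathematical lower bound of -100
    return max(-100.0, 100.0 * (ee_mut - ee_wt) / ee_wt)


def test_site(
    counts_wt: tuple[int, int], counts_mut: tuple[int, int]
) -> float:
    """Two-sided Fisher exact p-value for one site.

    ``counts_wt`` and ``counts_mut`` are pooled (n_edited, n_unedited)
    tallies per genotype; the test conditions on the margins of the
    resulting 2x2 table.  Exactness matters because many sites have low
    informative coverage.
    """
    table = [list(counts_wt), list(counts_mut)]
    if min(min(row) for row in table) < 0:
        raise ValueError("counts must be >= 0")
    if sum(counts_wt) == 0 or sum(counts_mut) == 0:
        raise ValueError("a genotype has zero informative reads; skip this site")
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def adjust_bonferroni(p_values: Sequence[float], m: int | None = None) -> list[float]:
    """Bonferroni adjustment: p_adj = min(1, m * p).

    ``m`` defaults to the number of p-values given, i.e. the number of
    sites actually tested in the comparison.  Order-preserving: ranking
    by adjusted values equals ranking by raw values.
    """
    p_values = list(p_values)
    if m is None:
        m = len(p_values)
    if m < 0:
        raise ValueError("m must be >= 0")
    for p in p_values:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value {p} outside [0, 1]")
    return [min(1.0, m * p) for p in p_values]


def differential_editing(
    counts: pd.DataFrame,
    *,
    alpha: float = DEFAULT_ALPHA,
    delta_threshold: float = DEFAULT_DELTA_THRESHOLD,
    min_coverage: int = 1,
) -> list[DifferentialEditingResult]:
    """Full mutant-vs-WT differential analysis from a tidy counts table.

    ``counts`` carries site_id, genotype ("WT"/"mutant"), n_edited,
    n_unedited (replicates are pooled by summation).  Sites lacking
    ``min_coverage`` informative reads in either genotype are skipped
    (logged), and the Bonferroni multiplicity is the number of sites
    actually tested.
    """
    pooled = (
        counts.groupby(["site_id", "genotype"])[["n_edited", "n_unedited"]]
        .sum()
        .reset_index()
        .pivot(index="site_id", columns="genotype")
    )
    rows = []
    for site_id in pooled.index:
        try:
            wt = (
                int(pooled.loc[site_id, ("n_edited", "WT")]),
                int(pooled.loc[site_id, ("n_unedited", "WT")]),
            )
            mut = (
                int(pooled.loc[site_id, ("n_edited", "mutant")]),
                int(pooled.loc[site_id, ("n_unedited", "mutant")]),
            )
        except (KeyError, ValueError):
            logger.warning("site %s missing a genotype; skipped", site_id)
            continue
        if sum(wt) < min_coverage or sum(mut) < min_coverage or sum(wt) == 0 or sum(mut) == 0:
            logger.warning("site %s below coverage in a genotype; skipped", site_id)
            continue
        rows.append((site_id, wt, mut))

    p_raw = [test_site(wt, mut) for _, wt, mut in rows]
    p_adj = adjust_bonferroni(p_raw, m=len(rows))
    results = []
    for (site_id, wt, mut), p, padj in zip(rows, p_raw, p_adj):
        ee_wt = 100.0 * wt[0] / sum(wt)
        ee_mut = 100.0 * mut[0] / sum(mut)
        results.append(
            _classify_one(site_id, ee_wt, ee_mut, p, padj, alpha, delta_threshold)
        )
    return results


def _classify_one(
    site_id: str,
    ee_wt: float,
    ee_mut: float,
    p: float,
    padj: float,
    alpha: float,
    delta_threshold: float,
) -> DifferentialEditingResult:
    d = delta_ee(ee_wt, ee_mut)
    significant = padj < alpha
    dependent = significant and (not math.isnan(d)) and d <= -delta_threshold
    return DifferentialEditingResult(
        site_id=site_id,
        ee_wt=ee_wt,
        ee_mut=ee_mut,
        delta_ee=d,
        p_value=p,
        p_adj=padj,
        significant=significant,
        dependent=dependent,
    )


def classify_dependence(
    results: Iterable[DifferentialEditingResult],
    alpha: float = DEFAULT_ALPHA,
    delta_threshold: float = DEFAULT_DELTA_THRESHOLD,
) -> tuple[list[DifferentialEditingResult], set[str]]:
    """(Re-)label dependence and return the dependent-site id set.

    A site is dependent when ``p_adj < alpha`` and its editing extent
    decreased by at least ``delta_threshold`` percent of the WT extent
    (``delta_ee <= -delta_threshold``).  Sites with undefined dEE
    (EE_wt = 0) are never dependent.  The returned set is directly usable
    as the candidate filter in :mod:`editotype.ranking`.
    """
    labeled = [
        _classify_one(
            r.site_id, r.ee_wt, r.ee_mut, r.p_value, r.p_adj, alpha, delta_threshold
        )
        for r in results
    ]
    return labeled, {r.site_id for r in labeled if r.dependent}


def results_to_frame(results: Iterable[DifferentialEditingResult]) -> pd.DataFrame:
    """Tabular view with dEE rounded to integer percent for display."""
    df = pd.DataFrame(
        [
            (
                r.site_id,
                r.ee_wt,
                r.ee_mut,
                r.delta_ee,
                round(r.delta_ee) if r.delta_defined else math.nan,
                r.p_value,
                r.p_adj,
                r.significant,
                r.dependent,
            )
            for r in results
        ],
        columns=[
            "site_id",
            "ee_wt",
            "ee_mut",
            "delta_ee",
            "delta_ee_display",
            "p_value",
            "p_adj",
            "significant",
            "dependent",
        ],
    )
    return df


# ---------------------------------------------------------------------------
# cis-element overlap
# ---------------------------------------------------------------------------

def transcript_offset(a: EditingSite, b: EditingSite) -> float:
    """Offset of site ``b`` relative to site ``a`` in transcript coordinates.

    Negative values mean ``b`` lies upstream (5') of ``a`` on the strand
    of ``a``.  NaN when the sites are on different molecules or strands.
    """
    if a.organelle != b.organelle or a.strand != b.strand:
        return math.nan
    if a.strand == "+":
        return b.position - a.position
    return a.position - b.position


def cis_element_overlap(
    sites: Sequence[EditingSite],
    window: tuple[int, int] = CIS_WINDOW,
) -> tuple[dict[str, list[str]], int]:
    """Find editing sites contained in other sites' cis-elements.

    Site B is contained in site A's window iff B != A, both lie on the
    same molecule and strand, and B's transcript-strand offset from A
    falls in the closed interval ``window`` (default [-31, -4]).  The
    relation is asymmetric.  Returns the per-site containment map and
    the number of sites whose window holds at least one other site.
    """
    lo, hi = window
    if lo > hi:
        raise ValueError(f"window {window} must satisfy lo <= hi")
    contained: dict[str, list[str]] = {s.site_id: [] for s in sites}
    for a in sites:
        for b in sites:
            if a.site_id == b.site_id:
                continue
            off = transcript_offset(a, b)
            if not math.isnan(off) and lo <= off <= hi:
                contained[a.site_id].append(b.site_id)
    for ids in contained.values():
        ids.sort()
    n_with_overlap = sum(1 for ids in contained.values() if ids)
    return contained, n_with_overlap
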