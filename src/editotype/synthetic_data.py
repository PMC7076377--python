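"""Synthetic organellar editing fixtures.

Generates self-contained data sets with the statistical structure the
analysis stages assume: a random organelle-like genome with C-to-U
editing sites (reference C on the annotated strand, full -31..-4
upstream window available), replicate read tallies per genotype drawn
binomially around true editing extents, planted mutant knockdowns,
linked site pairs (one site inside another's cis-element window), and
PPR proteins constructed by inverting a recognition-code table so that
they prefer a chosen target window.

All randomness flows from a single seeded generator in a fixed iteration
order, so a (config, seed) pair reproduces a fixture bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .pprcode import (
    CodeTable,
    PPRMotif,
    PPRProtein,
    RNA_BASES,
    extract_window,
    protein_to_dict,
)
from .quantify import EditingSite, SiteCounts, counts_to_frame, write_sites

#: minimum 1-based position so the full -31..-4 window fits upstream
MIN_SITE_POSITION = 36
#: minimum spacing between non-linked sites (keeps windows disjoint)
SITE_SPACING = 40

GENOTYPES = ("WT", "mutant")


@dataclass(frozen=True)
class LinkedPair:
    """Place ``upstream`` inside ``downstream``'s cis-element window.

    ``offset`` is the transcript-strand offset of the upstream site from
    the downstream site's edited C, constrained to the window [-31, -4].
    Sites are referenced by their index in generation order.
    """

    upstream: int
    downstream: int
    offset: int

    def __post_init__(self) -> None:
        if not -31 <= self.offset <= -4:
            raise ValueError(f"linked-pair offset {self.offset} outside [-31, -4]")
        if self.upstream == self.downstream:
            raise ValueError("a site cannot be linked to itself")


@dataclass
class SimulationConfig:
    """Study conditions for one simulated editing experiment.

    ``ee_wt`` lists true WT editing extents, cycled over sites;
    ``knockdown_effects`` maps a site (by generation index or by
    site_id) to the multiplicative factor applied to its extent in the
    mutant (0.1 models a -90% knockdown; factors > 1 model the editing
    increases seen when one factor's loss unmasks another, clipped to
    extent 1).  ``error_rate`` is an optional per-base miscall rate
    feeding the n_other tally only.
    """

    genome_length: int = 20_000
    n_sites: int = 100
    coverage_mean: int = 500
    n_replicates: int = 3
    ee_wt: Sequence[float] = (0.9, 0.8, 0.7, 0.95)
    knockdown_effects: Mapping[int | str, float] = field(default_factory=dict)
    linked_pairs: Sequence[LinkedPair] = ()
    error_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.genome_length < 200:
            raise ValueError("genome_length must be >= 200")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.coverage_mean < 1:
            raise ValueError("coverage_mean must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not self.ee_wt:
            raise ValueError("ee_wt must be non-empty")
        for ee in self.ee_wt:
            if not 0.0 <= ee <= 1.0:
                raise ValueError(f"ee_wt value {ee} outside [0, 1]")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")
        for pair in self.linked_pairs:
            for idx in (pair.upstream, pair.downstream):
                if isinstance(idx, int) and not 0 <= idx < self.n_sites:
                    raise ValueError(f"linked-pair site index {idx} out of range")
        for factor in self.knockdown_effects.values():
            if factor < 0:
                raise ValueError("knockdown factors must be >= 0")


@dataclass
class Fixture:
    """A generated data set: genome, sites, truth, counts, PPR panel."""

    genome: str
    sites: list[EditingSite]
    truth: dict[str, dict[str, float]]  # site_id -> genotype -> true EE
    counts: pd.DataFrame | None = None
    ppr_panel: list[PPRProtein] = field(default_factory=list)
    ppr_targets: dict[str, str] = field(default_factory=dict)  # protein_id -> site_id


def _true_extents(config: SimulationConfig, index: int, site_id: str) -> dict[str, float]:
    ee_wt = float(config.ee_wt[index % len(config.ee_wt)])
    factor = config.knockdown_effects.get(index, config.knockdown_effects.get(site_id, 1.0))
    return {"WT": ee_wt, "mutant": min(1.0, max(0.0, ee_wt * float(factor)))}


def generate_genome(config: SimulationConfig) -> Fixture:
    """Build the genome and editing-site panel.

    Non-linked sites are laid out on a regular grid with >= 40 nt
    spacing and strands drawn at random; each linked pair shares a
    strand, with the upstream partner written at its configured offset
    inside the downstream partner's window.  Every site position is then
    forced to hold C on its annotated strand.  Raises when the genome is
    too short for the requested panel.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genome = rng.choice(list("ACGT"), size=config.genome_length)

    linked_upstream = {p.upstream: p for p in config.linked_pairs}
    if set(linked_upstream) & {p.downstream for p in config.linked_pairs}:
        raise ValueError("chained linked pairs are not supported")
    n_anchored = config.n_sites - len(linked_upstream)
    span_needed = MIN_SITE_POSITION + n_anchored * SITE_SPACING
    if span_needed > config.genome_length:
        raise ValueError(
            f"genome_length {config.genome_length} too short for "
            f"{config.n_sites} sites (needs >= {span_needed})"
        )

    # anchor positions for every site that is not the upstream member of
    # a linked pair; upstream members are placed relative to their partner
    anchor_positions = [
        MIN_SITE_POSITION + i * SITE_SPACING for i in range(n_anchored)
    ]
    strands = rng.choice(["+", "-"], size=config.n_sites)

    positions: dict[int, int] = {}
    site_strands: dict[int, str] = {}
    anchor_iter = iter(anchor_positions)
    for i in range(config.n_sites):
        if i in linked_upstream:
            continue
        positions[i] = next(anchor_iter)
        site_strands[i] = str(strands[i])
    for i, pair in linked_upstream.items():
        down_pos = positions[pair.downstream]
        strand = site_strands[pair.downstream]
        # transcript offset -> genomic offset depends on strand
        positions[i] = down_pos + pair.offset if strand == "+" else down_pos - pair.offset
        site_strands[i] = strand

    sites: list[EditingSite] = []
    truth: dict[str, dict[str, float]] = {}
    for i in range(config.n_sites):
        pos = positions[i]
        strand = site_strands[i]
        if not MIN_SITE_POSITION <= pos <= config.genome_length - 4:
            raise ValueError(f"site {i} placed at infeasible position {pos}")
        genome[pos - 1] = "C" if strand == "+" else "G"
        site_id = f"M{pos}"
        sites.append(
            EditingSite(
                site_id=site_id,
                organelle="mitochondrion",
                position=pos,
                strand=strand,
                name=f"synth{i}_{pos}",
            )
        )
        truth[site_id] = _true_extents(config, i, site_id)

    return Fixture(genome="".join(genome), sites=sites, truth=truth)


def simulate_counts(fixture: Fixture, config: SimulationConfig) -> pd.DataFrame:
    """Draw replicate read tallies for every site and genotype.

    Per site, replicate and genotype: informative coverage is Poisson
    with mean ``coverage_mean`` truncated at 1, edited reads are
    binomial at the genotype's true extent, and miscalls (n_other) are
    Poisson at ``coverage * error_rate`` on top.  The draw order (site,
    genotype, replicate) is fixed for reproducibility.
    """
    if not fixture.sites or not fixture.truth:
        raise ValueError("fixture lacks sites or truth; run generate_genome first")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    records: list[SiteCounts] = []
    for site in fixture.sites:
        for genotype in GENOTYPES:
            ee = fixture.truth[site.site_id][genotype]
            for rep in range(config.n_replicates):
                coverage = 0
                while coverage < 1:  # truncated Poisson, >= 1 read
                    coverage = int(rng.poisson(config.coverage_mean))
                n_edited = int(rng.binomial(coverage, ee))
                n_other = (
                    int(rng.poisson(coverage * config.error_rate))
                    if config.error_rate > 0
                    else 0
                )
                records.append(
                    SiteCounts(
                        site_id=site.site_id,
                        sample_id=f"{genotype}_rep{rep + 1}",
                        genotype=genotype,
                        n_edited=n_edited,
                        n_unedited=coverage - n_edited,
                        n_other=n_other,
                    )
                )
    fixture.counts = counts_to_frame(records)
    return fixture.counts


def plant_ppr(
    target_site: EditingSite,
    fixture: Fixture,
    code_table: CodeTable,
    n_motifs: int = 13,
    protein_id: str | None = None,
    subfamily: str = "E+",
) -> PPRProtein:
    """Construct a protein whose code residues prefer the target window.

    The window covers transcript positions -(n_motifs+3)..-4 of the
    target site.  For each window base the code table is inverted: the
    (residue pair, class) entry giving that base the highest probability
    is assigned to the corresponding motif, so the planted protein
    attains the maximum achievable score on its own window.  Raises when
    the window is truncated by the sequence edge, or when the table
    cannot be inverted for some base.
    """
    window = extract_window(target_site, fixture.genome, n_motifs)
    best_by_base: dict[str, tuple[float, tuple[str, str, str]]] = {}
    for (r6, r1p, group), dist in sorted(code_table.entries.items()):
        for base in RNA_BASES:
            if base not in best_by_base or dist[base] > best_by_base[base][0]:
                best_by_base[base] = (dist[base], (r6, r1p, group))
    for base in RNA_BASES:
        if base in best_by_base and best_by_base[base][0] <= code_table.background[base]:
            del best_by_base[base]
    missing = [b for b in set(window.sequence) if b not in best_by_base]
    if missing:
        raise ValueError(
            f"code table not invertible: no entry prefers base(s) {sorted(missing)}"
        )
    motifs = []
    for i, base in enumerate(window.sequence, start=1):
        _, (r6, r1p, group) = best_by_base[base]
        motif_class = group if group != "*" else "P"
        motifs.append(
            PPRMotif(index=i, motif_class=motif_class, residue_6=r6, residue_1prime=r1p)
        )
    protein = PPRProtein(
        protein_id=protein_id or f"SYNPPR_{target_site.site_id}",
        subfamily=subfamily,
        motifs=tuple(motifs),
    )
    fixture.ppr_panel.append(protein)
    fixture.ppr_targets[protein.protein_id] = target_site.site_id
    return protein


def generate_fixture(
    config: SimulationConfig,
    code_table: CodeTable | None = None,
    n_planted_ppr: int = 0,
    ppr_n_motifs: int = 13,
) -> Fixture:
    """Genome + sites + counts (+ optionally planted PPR proteins)."""
    fixture = generate_genome(config)
    simulate_counts(fixture, config)
    if n_planted_ppr:
        if code_table is None:
            from .pprcode import default_code_table

            code_table = default_code_table()
        if n_planted_ppr > len(fixture.sites):
            raise ValueError("more planted proteins than sites")
        for site in fixture.sites[:n_planted_ppr]:
            plant_ppr(site, fixture, code_table, n_motifs=ppr_n_motifs)
    return fixture


def write_fixture(fixture: Fixture, outdir: str | Path) -> None:
    """Write genome FASTA, site/count TSVs and truth/panel JSON."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    SeqIO.write(
        [SeqRecord(Seq(fixture.genome), id="synth_organelle", description="")],
        outdir / "genome.fa",
        "fasta",
    )
    write_sites(fixture.sites, outdir / "sites.tsv")
    if fixture.counts is not None:
        fixture.counts.to_csv(outdir / "counts.tsv", sep="\t", index=False)
    (outdir / "truth.json").write_text(json.dumps(fixture.truth, indent=1))
    (outdir / "ppr_panel.json").write_text(
        json.dumps(
            {
                "proteins": [protein_to_dict(p) for p in fixture.ppr_panel],
                "targets": fixture.ppr_targets,
            },
            indent=1,
        )
    )
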