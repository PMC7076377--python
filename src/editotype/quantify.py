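"""Editing-extent quantification from per-site base tallies.

Plant mitochondrial and plastid transcripts undergo C-to-U editing at
defined cytidines.  Given aligned RNA-seq, the editing extent (EE) of a
site is the fraction of reads supporting the edited base (T on the sense
strand) among reads supporting either the edited or the unedited base.
This module turns BAM pileups, or pre-tabulated counts, into per-site,
per-genotype EE estimates, and also provides the Sanger peak-height
estimator used to validate editing levels from chromatograms.

Coordinates are 1-based and refer to the organelle genome; a site on the
"-" strand has a genomic G at its position, and reads showing a genomic A
there support the edited transcript base.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

#: default minimum number of informative (edited + unedited) reads for an
#: EE estimate to be reported; below this the site is flagged low_coverage.
DEFAULT_MIN_COVERAGE = 5

#: default pileup quality filters (standard practice for base tallies).
DEFAULT_MIN_BASE_QUALITY = 20
DEFAULT_MIN_MAPPING_QUALITY = 1

SITE_COLUMNS = ["site_id", "organelle", "position", "strand", "name", "reference_base"]
COUNT_COLUMNS = ["site_id", "sample_id", "genotype", "n_edited", "n_unedited", "n_other"]

_COMPLEMENT = str.maketrans("ACGTUacgtu", "TGCAAtgcaa")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA/RNA string (returns DNA alphabet)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class EditingSite:
    """An annotated C-to-U editing position.

    ``site_id`` follows the organelle-position convention ("M" or "P"
    followed by the 1-based genome coordinate, e.g. "M17884"); ``name``
    is the transcript-relative label (e.g. "ccmB_551").
    """

    site_id: str
    organelle: str  # "mitochondrion" or "plastid"
    position: int  # 1-based genome coordinate of the edited C
    strand: str  # "+" or "-"
    name: str
    reference_base: str = "C"

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"site {self.site_id}: position must be >= 1")
        if self.strand not in ("+", "-"):
            raise ValueError(f"site {self.site_id}: strand must be '+' or '-'")


@dataclass(frozen=True)
class SiteCounts:
    """Read tallies at one site in one sample.

    ``n_edited`` counts reads supporting the edited (T/U) sense base,
    ``n_unedited`` reads supporting C, ``n_other`` everything else
    (sequencing errors, rare variants).
    """

    site_id: str
    sample_id: str
    genotype: str  # "WT" or "mutant"
    n_edited: int
    n_unedited: int
    n_other: int = 0

    def __post_init__(self) -> None:
        if min(self.n_edited, self.n_unedited, self.n_other) < 0:
            raise ValueError(f"site {self.site_id}: counts must be >= 0")

    @property
    def coverage(self) -> int:
        """Informative coverage (edited + unedited reads)."""
        return self.n_edited + self.n_unedited


@dataclass(frozen=True)
class EditingExtentRecord:
    """An EE estimate for one site in one genotype.

    ``ee`` is a fraction in [0, 1] (NaN when ``status == "low_coverage"``),
    ``coverage`` the number of informative reads behind it.
    """

    site_id: str
    genotype: str
    ee: float
    coverage: int
    status: str = "ok"  # "ok" or "low_coverage"

    @property
    def ee_percent(self) -> float:
        return self.ee * 100.0


# ---------------------------------------------------------------------------
# core estimators
# ---------------------------------------------------------------------------

def editing_extent(
    counts: Iterable[SiteCounts] | SiteCounts,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
) -> EditingExtentRecord:
    """Pool replicate counts of one site x genotype and estimate EE.

    Counts are summed over replicates before the ratio is taken, so a
    single EE per genotype is produced regardless of replicate structure;
    the estimate is invariant to pooling order.  ``n_other`` reads are
    excluded from the denominator so that sequencing errors do not
    deflate the estimate.  With fewer than ``min_coverage`` informative
    reads the record is flagged ``low_coverage`` and ``ee`` is NaN
    (never a division by zero).
    """
    if isinstance(counts, SiteCounts):
        counts = [counts]
    counts = list(counts)
    if not counts:
        raise ValueError("editing_extent requires at least one count record")
    site_ids = {c.site_id for c in counts}
    genotypes = {c.genotype for c in counts}
    if len(site_ids) != 1 or len(genotypes) != 1:
        raise ValueError(
            "editing_extent pools replicates of a single site and genotype; "
            f"got sites {sorted(site_ids)} and genotypes {sorted(genotypes)}"
        )
    n_edited = sum(c.n_edited for c in counts)
    n_unedited = sum(c.n_unedited for c in counts)
    informative = n_edited + n_unedited
    if informative < min_coverage or informative == 0:
        return EditingExtentRecord(
            site_id=counts[0].site_id,
            genotype=counts[0].genotype,
            ee=math.nan,
            coverage=informative,
            status="low_coverage",
        )
    return EditingExtentRecord(
        site_id=counts[0].site_id,
        genotype=counts[0].genotype,
        ee=n_edited / informative,
        coverage=informative,
    )


def editing_extent_table(
    counts: pd.DataFrame, min_coverage: int = DEFAULT_MIN_COVERAGE
) -> pd.DataFrame:
    """Per-site, per-genotype EE table from a tidy counts table.

    ``counts`` must carry the columns of :data:`COUNT_COLUMNS` (sample_id
    and n_other optional).  Returns columns site_id, genotype, n_edited,
    n_unedited, coverage, ee, ee_percent, status.
    """
    required = {"site_id", "genotype", "n_edited", "n_unedited"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"counts table missing columns: {sorted(missing)}")
    grouped = (
        counts.groupby(["site_id", "genotype"], sort=True)[["n_edited", "n_unedited"]]
        .sum()
        .reset_index()
    )
    grouped["coverage"] = grouped["n_edited"] + grouped["n_unedited"]
    low = grouped["coverage"] < min_coverage
    grouped["ee"] = grouped["n_edited"] / grouped["coverage"].where(grouped["coverage"] > 0)
    grouped.loc[low, "ee"] = math.nan
    grouped["ee_percent"] = grouped["ee"] * 100.0
    grouped["status"] = "ok"
    grouped.loc[low, "status"] = "low_coverage"
    return grouped


def sanger_extent(peak_T: float, peak_C: float) -> float:
    """Editing level from Sanger chromatogram peak heights.

    The editing level at a site is estimated as the relative height of
    the T peak among the T and C peaks: ``peak_T / (peak_T + peak_C)``.
    """
    if peak_T < 0 or peak_C < 0:
        raise ValueError("peak heights must be >= 0")
    total = peak_T + peak_C
    if total == 0:
        raise ValueError("both peak heights are zero: editing level undefined")
    return peak_T / total


# ---------------------------------------------------------------------------
# BAM pileup tallies
# ---------------------------------------------------------------------------

def count_bases_at_sites(
    alignments,
    sites: Sequence[EditingSite],
    *,
    contig: str | None = None,
    sample_id: str = "sample",
    genotype: str = "WT",
    min_base_quality: int = DEFAULT_MIN_BASE_QUALITY,
    min_mapping_quality: int = DEFAULT_MIN_MAPPING_QUALITY,
) -> list[SiteCounts]:
    """Tally edited / unedited / other reads at each site from a BAM.

    ``alignments`` is an open, indexed :class:`pysam.AlignmentFile` (or a
    path to one).  For a "+" site, reads showing T are edited and reads
    showing C unedited; for a "-" site the genomic reference is G and the
    tallies use the complement: A is edited, G unedited.  ``contig``
    names the reference sequence sites live on; with a single-contig BAM
    it may be omitted.
    """
    import pysam

    owns = False
    if isinstance(alignments, (str, Path)):
        alignments = pysam.AlignmentFile(str(alignments), "rb")
        owns = True
    try:
        if contig is None:
            if len(alignments.references) != 1:
                raise ValueError(
                    "contig must be given for a multi-contig alignment file"
                )
            contig = alignments.references[0]
        if contig not in alignments.references:
            raise ValueError(f"contig {contig!r} not found in alignment file")
        ref_len = alignments.get_reference_length(contig)
        out: list[SiteCounts] = []
        for site in sites:
            if site.position > ref_len:
                raise ValueError(
                    f"site {site.site_id} position {site.position} outside "
                    f"reference {contig} (length {ref_len})"
                )
            pos0 = site.position - 1
            edited = unedited = other = 0
            for column in alignments.pileup(
                contig,
                pos0,
                pos0 + 1,
                truncate=True,
                min_base_quality=min_base_quality,
                min_mapping_quality=min_mapping_quality,
                ignore_overlaps=False,
                stepper="samtools",
            ):
                for read in column.pileups:
                    if read.is_del or read.is_refskip or read.query_position is None:
                        continue
                    base = read.alignment.query_sequence[read.query_position].upper()
                    if site.strand == "+":
                        edited_base, unedited_base = "T", "C"
                    else:
                        edited_base, unedited_base = "A", "G"
                    if base == edited_base:
                        edited += 1
                    elif base == unedited_base:
                        unedited += 1
                    else:
                        other += 1
            out.append(
                SiteCounts(
                    site_id=site.site_id,
                    sample_id=sample_id,
                    genotype=genotype,
                    n_edited=edited,
                    n_unedited=unedited,
                    n_other=other,
                )
            )
        return out
    finally:
        if owns:
            alignments.close()


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------

def read_sites(path: str | Path) -> list[EditingSite]:
    """Read an editing-site annotation TSV (columns of SITE_COLUMNS)."""
    df = pd.read_csv(path, sep="\t", dtype={"site_id": str, "name": str})
    missing = set(SITE_COLUMNS[:5]) - set(df.columns)
    if missing:
        raise ValueError(f"site table {path} missing columns: {sorted(missing)}")
    if "reference_base" not in df.columns:
        df["reference_base"] = "C"
    return [
        EditingSite(
            site_id=row.site_id,
            organelle=row.organelle,
            position=int(row.position),
            strand=row.strand,
            name=row.name,
            reference_base=row.reference_base,
        )
        for row in df.itertuples()
    ]


def write_sites(sites: Sequence[EditingSite], path: str | Path) -> None:
    pd.DataFrame(
        [
            (s.site_id, s.organelle, s.position, s.strand, s.name, s.reference_base)
            for s in sites
        ],
        columns=SITE_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a counts TSV into a tidy DataFrame (COUNT_COLUMNS)."""
    df = pd.read_csv(path, sep="\t", dtype={"site_id": str, "sample_id": str})
    missing = {"site_id", "genotype", "n_edited", "n_unedited"} - set(df.columns)
    if missing:
        raise ValueError(f"counts table {path} missing columns: {sorted(missing)}")
    if "n_other" not in df.columns:
        df["n_other"] = 0
    if "sample_id" not in df.columns:
        df["sample_id"] = "pooled"
    return df[COUNT_COLUMNS]


def counts_to_frame(counts: Iterable[SiteCounts]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (c.site_id, c.sample_id, c.genotype, c.n_edited, c.n_unedited, c.n_other)
            for c in counts
        ],
        columns=COUNT_COLUMNS,
    )
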