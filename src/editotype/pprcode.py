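"""PPR recognition-code scoring of candidate cis-elements.

PLS-class pentatricopeptide-repeat (PPR) editing factors bind the RNA
upstream of the C they serve, one motif per base, with the C-terminal-most
PPR motif anchored on the base at position -4 relative to the edited C.
The identity of two amino acids per motif — position 6 and position 1'
(the first residue of the next motif; positions 5 and 35 in the
alternative numbering) — largely determines which nucleotide the motif
prefers.  A code table maps (residue pair, motif class) to a probability
distribution over {A, C, G, U}; a candidate window of length n_motifs is
scored as the sum over motifs of log-odds against a background
distribution, so an entirely uninformative protein scores exactly 0 on
any window.

The numeric content of the code is configuration: any table in the TSV
format accepted by :func:`load_code_table` can be used.  A small built-in
table covering the classical high-confidence pairs (TD -> G, TN/SN -> A,
ND -> U over C, NS/NN -> C-leaning) is provided for simulation and tests.
"""

from __future__ import annotations

import io
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .quantify import EditingSite, reverse_complement

logger = logging.getLogger(__name__)

RNA_BASES = ("A", "C", "G", "U")
#: distance from the edited C (position 0) to the base bound by the last motif
ANCHOR_OFFSET = -4

MOTIF_CLASSES = {"P", "L", "S", "P1", "P2", "L1", "L2", "S1", "S2", "E1", "E2"}


def _class_group(motif_class: str) -> str:
    """Collapse subvariants: P1/P2 -> P, L1/L2 -> L, S1/S2 -> S."""
    c = motif_class.upper()
    if c not in MOTIF_CLASSES:
        raise ValueError(f"unknown PPR motif class {motif_class!r}")
    return c[0] if c[0] in "PLS" else c


@dataclass(frozen=True)
class PPRMotif:
    """One PPR motif: class plus the two code residues (6, 1')."""

    index: int  # 1-based from the N-terminus
    motif_class: str
    residue_6: str
    residue_1prime: str

    def __post_init__(self) -> None:
        for r in (self.residue_6, self.residue_1prime):
            if not (len(r) == 1 and (r == "-" or r.isalpha())):
                raise ValueError(f"invalid code residue {r!r} in motif {self.index}")
        _class_group(self.motif_class)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.residue_6.upper(), self.residue_1prime.upper())


@dataclass(frozen=True)
class PPRProtein:
    """An ordered array of PPR motifs (N->C), C-terminal domains excluded.

    ``subfamily`` ("E+", "E", "DYW", "P", "other") drives eligibility for
    the dependence-based candidate filter: only E+ proteins, which need
    the trans-acting DYW-domain donor for catalysis, may use it.
    """

    protein_id: str
    subfamily: str
    motifs: tuple[PPRMotif, ...]

    def __post_init__(self) -> None:
        if len(self.motifs) < 2:
            raise ValueError(f"protein {self.protein_id}: need >= 2 motifs")
        if not self.subfamily:
            raise ValueError(f"protein {self.protein_id}: subfamily label required")

    @property
    def n_motifs(self) -> int:
        return len(self.motifs)


@dataclass(frozen=True)
class BindingWindow:
    """Candidate cis-element: the n_motifs bases ending at position -4.

    ``sequence`` is on the edited transcript's sense strand, 5'->3', RNA
    alphabet, covering transcript offsets -(n_motifs+3) .. -4 so that the
    last (C-terminal) motif pairs with the base at -4.
    """

    site_id: str
    sequence: str


class CodeTable:
    """Maps (residue_6, residue_1prime, class group) to base preferences.

    Distributions are pseudocounted and renormalized at load time so all
    four probabilities are strictly positive.  Lookups fall back from the
    motif's class group to a wildcard ('*') entry, then to the background
    distribution (uninformative: log-odds contribution 0).
    """

    def __init__(
        self,
        entries: Mapping[tuple[str, str, str], Mapping[str, float]],
        pseudocount: float = 0.01,
        background: Mapping[str, float] | None = None,
    ) -> None:
        if pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        self.pseudocount = pseudocount
        bg = dict(background) if background else {b: 0.25 for b in RNA_BASES}
        if abs(sum(bg.values()) - 1.0) > 1e-9 or min(bg.values()) <= 0:
            raise ValueError("background must be a positive distribution summing to 1")
        self.background = {b: bg[b] for b in RNA_BASES}
        self.entries: dict[tuple[str, str, str], dict[str, float]] = {}
        for key, dist in entries.items():
            r6, r1p, group = key
            probs = {b: float(dist.get(b, 0.0)) for b in RNA_BASES}
            total = sum(probs.values())
            if not math.isclose(total, 1.0, abs_tol=1e-6):
                raise ValueError(
                    f"code entry {key}: distribution sums to {total}, expected 1"
                )
            smoothed = {
                b: (probs[b] + pseudocount) / (1.0 + 4 * pseudocount)
                for b in RNA_BASES
            }
            self.entries[(r6.upper(), r1p.upper(), group.upper())] = smoothed

    def lookup(self, motif: PPRMotif) -> tuple[dict[str, float], bool]:
        """Distribution for a motif and whether it is informative.

        Returns ``(distribution, informative)``; ``informative`` is False
        when the residue pair is absent and the background was returned.
        """
        r6, r1p = motif.pair
        group = _class_group(motif.motif_class)
        for key in ((r6, r1p, group), (r6, r1p, "*")):
            if key in self.entries:
                return self.entries[key], True
        return dict(self.background), False


#: built-in code table: classical high-confidence residue pairs.
DEFAULT_CODE_TSV = """\
residue_6\tresidue_1prime\tclass_group\tpA\tpC\tpG\tpU
T\tD\t*\t0.04\t0.04\t0.88\t0.04
T\tN\t*\t0.85\t0.05\t0.05\t0.05
S\tN\t*\t0.80\t0.08\t0.04\t0.08
N\tD\t*\t0.05\t0.35\t0.05\t0.55
N\tN\t*\t0.08\t0.48\t0.04\t0.40
N\tS\t*\t0.06\t0.66\t0.04\t0.24
S\tD\t*\t0.06\t0.30\t0.14\t0.50
T\tS\t*\t0.50\t0.25\t0.05\t0.20
"""


def load_code_table(
    source: str | Path | io.TextIOBase,
    pseudocount: float = 0.01,
    background: Mapping[str, float] | None = None,
) -> CodeTable:
    """Parse a code-table TSV.

    Columns: residue_6, residue_1prime, class_group ('*' matches any
    class), pA, pC, pG, pU.  Each row's probabilities must sum to 1;
    malformed rows raise with their line number.
    """
    if isinstance(source, io.TextIOBase):
        text = source.read()
        origin = "<stream>"
    else:
        text = Path(source).read_text()
        origin = str(source)
    entries: dict[tuple[str, str, str], dict[str, float]] = {}
    lines = text.splitlines()
    if not lines:
        raise ValueError(f"{origin}: empty code table")
    header = lines[0].rstrip("\n").split("\t")
    expected = ["residue_6", "residue_1prime", "class_group", "pA", "pC", "pG", "pU"]
    if header != expected:
        raise ValueError(f"{origin}: header must be {expected}, got {header}")
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 7:
            raise ValueError(f"{origin}: line {lineno}: expected 7 fields, got {len(parts)}")
        r6, r1p, group = parts[0], parts[1], parts[2]
        try:
            probs = dict(zip(RNA_BASES, (float(x) for x in parts[3:])))
        except ValueError as exc:
            raise ValueError(f"{origin}: line {lineno}: {exc}") from exc
        if not math.isclose(sum(probs.values()), 1.0, abs_tol=1e-6):
            raise ValueError(
                f"{origin}: line {lineno}: probabilities sum to "
                f"{sum(probs.values())}, expected 1"
            )
        entries[(r6.upper(), r1p.upper(), group.upper())] = probs
    return CodeTable(entries, pseudocount=pseudocount, background=background)


def default_code_table(pseudocount: float = 0.01) -> CodeTable:
    """The built-in code table (see :data:`DEFAULT_CODE_TSV`)."""
    return load_code_table(io.StringIO(DEFAULT_CODE_TSV), pseudocount=pseudocount)


# ---------------------------------------------------------------------------
# window extraction and scoring
# ---------------------------------------------------------------------------

def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


class WindowTruncatedError(ValueError):
    """The binding window would extend past the sequence edge."""


def extract_window(
    site: EditingSite, sequence: str, n_motifs: int
) -> BindingWindow:
    """Cut the n_motifs-base window ending at transcript position -4.

    ``sequence`` is the genome (or transcript) the site's coordinates
    refer to.  For a "-" strand site the genomic segment is
    reverse-complemented so the window reads 5'->3' on the edited
    transcript.  Raises :class:`WindowTruncatedError` when the window
    would run off the sequence; such sites are excluded from candidate
    sets by callers.
    """
    if n_motifs < 1:
        raise ValueError("n_motifs must be >= 1")
    pos0 = site.position - 1  # 0-based index of the edited C
    if site.strand == "+":
        start = pos0 - (n_motifs + 3)
        end = pos0 - 3  # exclusive; last base is at offset -4
        if start < 0:
            raise WindowTruncatedError(
                f"site {site.site_id}: window needs position "
                f"{site.position - (n_motifs + 3)}, before sequence start"
            )
        segment = sequence[start:end]
    else:
        start = pos0 + 4
        end = pos0 + n_motifs + 4
        if end > len(sequence):
            raise WindowTruncatedError(
                f"site {site.site_id}: window extends past sequence end"
            )
        segment = reverse_complement(sequence[start:end])
    return BindingWindow(site_id=site.site_id, sequence=to_rna(segment))


def score_window(
    protein: PPRProtein,
    window: BindingWindow | str,
    code: CodeTable,
    class_weights: Mapping[str, float] | None = None,
) -> float:
    """Additive log-odds binding score of a protein on a window.

    Motif i (N->C) is paired with window base i (5'->3'); each motif
    contributes ``w_class * log(P_code(base | motif) / background(base))``.
    ``class_weights`` lets L motifs (often less sequence-specific) be
    down-weighted; default weight 1.0 for every class.  Higher scores
    mean better predicted binding; an all-background protein scores 0.
    """
    seq = window.sequence if isinstance(window, BindingWindow) else to_rna(window)
    if len(seq) != protein.n_motifs:
        raise ValueError(
            f"window length {len(seq)} != protein {protein.protein_id} "
            f"motif count {protein.n_motifs}"
        )
    weights = class_weights or {}
    score = 0.0
    for motif, base in zip(protein.motifs, seq):
        if base not in RNA_BASES:
            raise ValueError(f"non-RNA base {base!r} in window")
        dist, _ = code.lookup(motif)
        w = weights.get(_class_group(motif.motif_class), 1.0)
        score += w * math.log(dist[base] / code.background[base])
    return score


def scan_sites(
    protein: PPRProtein,
    sites: Sequence[EditingSite],
    sequence: str,
    code: CodeTable,
    class_weights: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """Score a protein against the cis-element of every candidate site.

    Sites whose window is truncated by the sequence edge are skipped and
    logged; they belong to no candidate set.
    """
    scores: dict[str, float] = {}
    for site in sites:
        try:
            window = extract_window(site, sequence, protein.n_motifs)
        except WindowTruncatedError:
            logger.warning(
                "site %s: window truncated, excluded from candidates", site.site_id
            )
            continue
        scores[site.site_id] = score_window(protein, window, code, class_weights)
    return scores


MAX_VARIANT_SITES = 5


def edited_window_variants(
    window: BindingWindow | str, contained_offsets: Sequence[int]
) -> list[tuple[str, tuple[bool, ...]]]:
    """Enumerate C/U states of editing sites contained in a window.

    ``contained_offsets`` are 0-based indices into the window sequence
    where other editing sites sit (each must hold a C in the unedited
    window).  Returns the 2^k (sequence, edit-status) pairs, the status
    vector marking which contained sites are in the edited (U) state.
    Guarded at k <= 5 to bound the combinatorics.
    """
    seq = window.sequence if isinstance(window, BindingWindow) else to_rna(window)
    k = len(contained_offsets)
    if k > MAX_VARIANT_SITES:
        raise ValueError(f"{k} contained sites exceed the limit of {MAX_VARIANT_SITES}")
    for off in contained_offsets:
        if not 0 <= off < len(seq):
            raise ValueError(f"contained-site offset {off} outside window")
        if seq[off] != "C":
            raise ValueError(
                f"window position {off} holds {seq[off]!r}, expected unedited C"
            )
    variants = []
    for mask in range(2 ** k):
        status = tuple(bool(mask >> i & 1) for i in range(k))
        chars = list(seq)
        for off, edited in zip(contained_offsets, status):
            if edited:
                chars[off] = "U"
        variants.append(("".join(chars), status))
    return variants


# ---------------------------------------------------------------------------
# protein I/O
# ---------------------------------------------------------------------------

def protein_to_dict(protein: PPRProtein) -> dict:
    return {
        "protein_id": protein.protein_id,
        "subfamily": protein.subfamily,
        "motifs": [
            {
                "index": m.index,
                "motif_class": m.motif_class,
                "residue_6": m.residue_6,
                "residue_1prime": m.residue_1prime,
            }
            for m in protein.motifs
        ],
    }


def protein_from_dict(d: Mapping) -> PPRProtein:
    return PPRProtein(
        protein_id=d["protein_id"],
        subfamily=d["subfamily"],
        motifs=tuple(
            PPRMotif(
                index=m["index"],
                motif_class=m["motif_class"],
                residue_6=m["residue_6"],
                residue_1prime=m["residue_1prime"],
            )
            for m in d["motifs"]
        ),
    )


def read_proteins(path: str | Path) -> list[PPRProtein]:
    """Read a protein panel from JSON (a list of motif-table dicts)."""
    data = json.loads(Path(path).read_text())
    return [protein_from_dict(d) for d in data]


def write_proteins(proteins: Iterable[PPRProtein], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps([protein_to_dict(p) for p in proteins], indent=1)
    )
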