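# Methods

## Editing-extent estimation

The editing extent (EE) of a site is the binomial proportion
`n_edited / (n_edited + n_unedited)` after pooling replicate counts of a
genotype by summation, so one EE is reported per site × genotype and the
estimate is invariant to pooling order. Reads supporting neither the
edited nor the unedited base (`n_other`) are treated as sequencing noise
and excluded from the denominator; including them would deflate EE at
high-error sites. A site needs at least `min_coverage` informative reads
(default 5) for an estimate; below that it is flagged `low_coverage` and
EE is NaN — never a division by zero. Pileup tallies are strand-aware: a
"−"-strand site has genomic G at its position, and reads showing genomic
A are counted as edited. Pileup filters default to base quality ≥ 20 and
mapping quality ≥ 1, both configurable; read mapping itself is out of
scope and the package consumes indexed BAMs or count tables. The Sanger
estimator is the plain peak-height ratio `h_T / (h_T + h_C)`.

## Differential editing and dependence

ΔEE is the *relative* change `100 × (EE_mut − EE_wt) / EE_wt`, undefined
(NaN, flagged — not an exception) when EE_wt = 0, and clamped at its
mathematical lower bound of −100 against float rounding. Full precision
is kept internally; display tables round to integer percent.

The per-site test is a two-sided Fisher exact test on the pooled
`[edited, unedited] × [WT, mutant]` table (via `scipy.stats.fisher_exact`;
the suite verifies it against exhaustive hypergeometric enumeration with
exact binomial coefficients for every table with N ≤ 30). An exact test
was chosen because informative coverage varies over orders of magnitude
across sites and can be very low; it is conservative under the null,
which the calibration test acknowledges (raw p < 0.05 at ≤ 5% + 3 Monte
Carlo SE). Multiplicity is handled by Bonferroni, `p_adj = min(1, m·p)`,
with m = the number of sites actually tested in that comparison — the
testable site set varies between samples, so a fixed genome-wide m would
be wrong in both directions.

A site is *dependent* on the mutated factor iff `p_adj < alpha` (default
0.05) **and** `ΔEE ≤ −delta_threshold` (default 25). Increases in
editing, which occur when one factor's loss unmasks another, are
therefore differential but never dependent; undefined ΔEE is never
dependent. The dependent-site set is the candidate filter for E+ protein
ranking.

Cis-element containment uses the closed transcript-strand interval
[−31, −4]: site B is contained in A's window iff both share molecule and
strand and B's transcript offset from A lies in that interval. The
relation is asymmetric by construction.

## PPR-code scoring

A protein's candidate window covers transcript positions
−(n_motifs+3)..−4, anchored so the C-terminal-most motif reads the base
at −4; windows truncated by a sequence edge exclude the site from
candidate sets (logged). Scoring is additive log-odds: motif i (N→C)
against window base i (5′→3′), each contributing
`w_class · log(P_code(base | pair, class) / background(base))` with a
uniform background by default. Log-odds was chosen over raw
log-likelihood so that uninformative motifs — unknown residue pairs fall
back to the background — contribute exactly 0 rather than a penalty, and
so that a fully uninformative protein scores 0 on any window. Per-class
weights (default 1.0 everywhere) allow down-weighting L motifs, which
are reported in the field as less sequence-specific. The code's numeric
content is configuration: any TSV table of
(residue_6, residue_1prime, class_group) → (pA, pC, pG, pU) rows is
accepted, distributions are pseudocounted (default 0.01) and
renormalized so every probability is strictly positive. The small
built-in table covers the classical high-confidence pairs (TD→G, TN/SN→A,
ND→U>C, NS/NN→C-leaning) and is intended for simulation and testing, not
as a substitute for a fitted published code; reproducing any externally
trained scoring model's parameters is a non-goal. Edited-window variants
enumerate the 2^k C/U states of editing sites contained in a window
(guarded at k ≤ 5), which is how upstream-editing-enables-binding
mechanisms are scored.

## Ranking and the dependence filter

Candidates are competition-ranked by descending score (ties share the
minimum rank) with a deterministic secondary sort by site id. The
dependence filter is strictly a candidate-set restriction — scores are
never modified — so for every retained site the filtered rank is ≤ the
full rank; `evaluate_improvement` enforces this as a data-integrity
check before summarizing. The filter's direction is asymmetric and the
API enforces it: only E+ proteins may restrict candidates to the
dependent set, because dependent sites include targets of non-E+
proteins (an E-class and a P-class factor each have one), so dependence
cannot shrink a dependent site's protein shortlist; conversely,
DYW2-independent sites may drop E+ proteins from their shortlists.

## Synthetic-data generator

The generator emulates the statistical structure of a mutant-vs-WT
editing RNA-seq comparison, not the sequencing process: per site,
genotype and replicate, informative coverage is Poisson (mean =
`coverage_mean`, truncated at ≥ 1 read) and edited reads are binomial at
the genotype's true extent — the simplest overdispersion-free model
consistent with pooled-count analysis. Mutant effects are multiplicative
on the WT extent, clipped to [0, 1], so both knockdowns (factor < 1) and
editing increases (factor > 1) can be planted. An optional per-base
miscall rate feeds `n_other` only (default 0). Sites are laid out on a
40-nt grid starting at position 36, which guarantees the full −31..−4
window exists and windows of distinct sites are disjoint, except for
linked pairs, whose upstream member is written at a configured
transcript offset in [−31, −4] inside its partner's window on the same
strand. Every site position is forced to hold C on its annotated strand.
Planted PPR proteins invert the code table: each window base is assigned
the (residue pair, class) entry that gives it maximal probability, and
because every chosen entry's modal base is the window base, the planted
protein provably attains the global maximum score on its own window —
the basis of the rank-1 recovery checks. All draws come from one seeded
generator in a fixed (site, genotype, replicate) order, so a
(config, seed) pair reproduces a fixture bit for bit.

Defaults (coverage 500, 3 replicates per genotype, 100 sites, −90%
planted knockdowns) are the recovery-study conditions used throughout
the tests. What passing these tests shows is that the statistical
machinery is correct and well calibrated under the assumed model; real
RNA-seq additionally has overdispersion between biological replicates,
alignment artifacts around splice and editing clusters, and coverage
that tracks expression — none of which the generator models, so recovery
rates here are upper bounds on real-data performance.

## Numerical and interface choices

- Coordinates are 1-based inclusive in annotation files; 0-based only
  inside pileup/window arithmetic. RNA alphabet internally {A, C, G, U};
  T accepted on input and converted.
- Residue pairs are stored as (6, 1′) following the editing-factor
  literature's numbering; this corresponds to (5, 35) in the alternative
  motif-numbering convention.
- The bundled published measurements (mutant editing-extent table, 45
  rank pairs) carry extents rounded to 0.1 percentage point; recomputed
  ΔEE values are therefore checked to the interval that printed
  precision allows, exactly where that interval pins down the integer.
- The acceptance script scales its exhaustive Fisher sweep to N ≤ 30
  (45,385 tables) and its simulations to 100 sites / 20 planted proteins,
  sizes at which every check runs in seconds while Monte Carlo error
  stays far below the asserted margins.

## Known limitations

- No replicate-level dispersion modeling (a beta-binomial extension
  would be the natural next step for real data).
- No FDR alternatives to Bonferroni; the dependence threshold treats
  partially dependent sites by the single ΔEE cutoff, adjustable by the
  user.
- RNA secondary structure, MORF cofactor effects and competition between
  RNA-binding proteins are outside the scoring model.
- De novo editing-site discovery and read mapping are out of scope; the
  pipeline starts from annotated sites and aligned reads.
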