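# Methods

## The problem

Mouse LINE-1 (L1) retrotransposons carry their promoter inside the 5'UTR,
which — unlike the human L1 5'UTR — is built from ~200-bp tandem repeats
("monomers") followed by a non-monomeric "tether" that joins the array to
ORF1. Most genomic L1 copies are 5'-truncated by incomplete reverse
transcription, so each locus retains a variable, generally fractional number
of monomers, and the truncation breakpoint clusters at reproducible
single-nucleotide positions within a monomer. `l1utr` implements the
computational side of a promoter study of this system: locating each locus's
5' start point relative to a subfamily consensus, tabulating a truncation
census per subfamily, and analysing dual-luciferase reporter plates that
measure the promoter activity of monomer/tether constructs.

## Extended query and coordinate map

A subfamily consensus is stored as an ordered monomer list (5'-most full
monomer first, the monomer adjacent to the tether last) plus the tether,
with any 5' partial monomer already removed. The *extended query* prepends
copies of the 5'-most full monomer until the array holds `total_monomers`
(default 11) monomers, then appends the tether. Domains are labelled
M11…M1, T from the 5' end, and a bisection-backed coordinate map converts
1-based query positions to `(domain, offset)` pairs and back, exactly.
Offsets are 1-based inclusive, matching the "nucleotide position 83/86"
convention used when reporting breakpoint hotspots. Monomer lengths may
differ within one model (e.g. 212-bp outer monomers over a 197-bp M1); only
the duplicated unit's length affects the prepended copies.

## Alignment

Each locus is aligned to the extended query with an exact affine-gap local
alignment (Gotoh recurrences, executed by Biopython's C pairwise engine).
Default scoring is +2 match, −3 mismatch, gap open 5, gap extend 2 — chosen
to approximate default nucleotide BLAST behaviour — and a length-L gap
costs `open + L·extend`. No identity threshold and no E-value model are
applied; selection is by raw score (bit score for hits imported from the
12-column tabular format). `N` is allowed in subjects, always scores as a
mismatch and never counts toward identity; it is rejected in queries.
Percent identity is matches over all alignment columns, gap columns
included.

Ties among co-optimal alignments are broken by smallest subject start, then
smallest query start, then longest alignment, evaluated over a bounded
prefix (32) of the deterministic co-optimal enumeration; unbounded
enumeration can be combinatorial on repetitive sequence and the bounded
scan is deterministic for a fixed input. When several hits exist per locus
(e.g. imported files), one hit per locus is kept by maximal score with the
same tie-break; this selection rule is a declared convention of this
package, since upstream tools differ in how they order co-optimal HSPs.

## Filters, bins and fractional monomer counts

A hit is accepted only when anchored at both ends of the element:

* tether-tail filter — the alignment must end within the last
  `tether_tail_window` (default 10) bases of the query, i.e.
  `qend ≥ L_q − 9`; failure means the locus's tether is 3'-truncated;
* head filter — the alignment must start within the first
  `subject_head_window` (default 10) bases of the locus, i.e.
  `sstart ≤ 10`; failure indicates a 5' end that is not monomeric promoter
  sequence (chimeric or rearranged loci).

Both windows are inclusive; shrinking either window never admits a
previously rejected hit (a tested monotonicity property). Minus-orientation
hits are rejected outright.

The query position of a passing alignment's start assigns the locus to one
of 12 bins — tether (T), monomers M1…M10, or the open-ended M11+ — and a
locus starting at offset `o` inside the `i`-th monomer (length `L_i`)
retains

    monomer_count = (i − 1) + (L_i − o + 1) / L_i

monomers. The formula is this package's explicit definition of the
"fractional 5'UTR length"; starts in T count 0, starts in the outermost
monomer domain carry more than 10 monomers. Subfamily averages exclude T
and M11+ loci (both tails are unbounded or undefined for averaging).
Cumulative "at least k intact monomers" categories are defined as
`monomer_count ≥ k` — equivalently a start in M(k+1) or beyond, or exactly
at position 1 of Mk. The ≥ reading (rather than a strict >) was adopted
because the two phrasings coexist in the source material and only ≥ makes
the per-subfamily and pooled worked examples mutually consistent.

Subfamilies with several monomer-organisation patterns (the Gf patterns,
whose tethers are 377, 313 and 250 bp for patterns I, II and IV) are run
once per pattern; a locus passing under several patterns is kept once under
the highest-precedence pattern, default II > I > IV with pattern II the
subfamily prototype. Pattern III is excluded by default because its
alignments are short and redundant with the other patterns.

Reported percentages are rounded half away from zero to one decimal, at
reporting time only; all internal values keep full precision.

## Age regression

The relationship between subfamily age (Myr) and average monomer count is
summarised by ordinary least squares. The reported `r` is the signed
Pearson correlation and `p` the two-sided slope t-test,
`t = r·sqrt(n−2)/sqrt(1−r²)` on `n−2` degrees of freedom; with `r = −0.91`
over 7 subfamilies this evaluates to `p = 0.0044`, printed as 0.004.
Exactly collinear inputs return `r = ±1` with `p = 0`; fewer than three
points, duplicated ages, or zero age variance are errors.

## Reporter normalization and statistics

Normalization is stepwise: per-well ratio Fluc/Rluc; mean ratio of the
no-promoter control construct; every well's ratio divided by that mean (so
the control averages exactly 1 and activities read as fold over assay
background); per-construct mean ± SEM, with SEM = SD/√n. Wells with
missing or non-positive Rluc are errors, never silently dropped, and no
background subtraction is applied. Because the per-well ratio cancels
transfection efficiency, scaling all Fluc or all Rluc values by a constant
leaves normalized activities unchanged (tested in both channels).

Pairwise construct comparisons use two-sided t-tests with a single pooled
standard deviation across all groups (residual df = N − k), matching the
default of the R convention the field uses, with Benjamini–Hochberg
adjustment across exactly the pairs reported in one run and a 0.05
significance level. Whether the source analysis pooled per pair or across
all groups is not stated; pooling across groups is the named function's
default and is assumed here. When the pooled variance is zero, equal means
give p = 1 and unequal means p = 0.

Two standard errors appear in the package and differ on purpose.
`ConstructSummary.sem` is the reporting convention (SD/√n of normalized
wells). The recovery analyses instead use `activity_standard_error`, the
delta-method standard error of the normalized-activity *estimator*: the
estimate is a ratio of two sample means, and every normalized value on a
plate shares the control-mean denominator, so the construct-level SEM
understates the estimator's error by about √2. Coverage statements ("within
3 standard errors of truth") are only well calibrated with the propagated
version.

Titration runs are summarised per dose (mean ± SEM of Fluc, Rluc and their
ratio), with a least-squares line through the origin fitted on a
user-chosen dose subset and each dose's relative deviation from that line
reported. No automatic plateau call is made; the deviation column is the
evidence a reader uses to pick the linear range.

## Synthetic data: what it emulates, what it does not

The locus generator draws, per clean locus, a monomer slot from a
categorical distribution (default peaked at M3 with a tail to the M11+
slot, echoing the census shape of young subfamilies) and a within-monomer
breakpoint from a mixture of single-nucleotide hotspots — defaults at
offsets 83 (weight 0.17) and 86 (weight 0.10), echoing the dominant Tf and
A breakpoints and their observed peak shares — over a uniform background.
The locus is the corresponding suffix of the extended query, mutated at a
default 1% per-base substitution rate (indels optional, geometric lengths),
roughly the divergence expected of recently active subfamily members. A
configured fraction of loci lose 11–30 bp from the tether 3' end
(guaranteed to fail the tether-tail filter) and a further fraction are
uniform-random decoys with the clean length distribution. The default
synthetic consensus has three 212-bp monomers diverged ~10% from each other
and a 205-bp tether, sized like a Tf-type promoter.

The plate generator multiplies both channels by a shared per-well
efficiency factor (log-normal, default CV 15%) and each channel by an
independent log-normal measurement noise (default CV 10%), with optional
dose scaling `d·K/(K+d)` applied to both channels; defaults put Rluc near
2.5×10⁴ RLU and the no-promoter Fluc near the ~10² RLU background scale.

Deliberately not modelled: phylogenetically realistic sequence evolution
(mutations are i.i.d.), 5'-inversions and internal rearrangements, monomer
subtype structure, CpG-biased substitution, channel crosstalk, and plate
position effects. Passing recovery tests therefore show that the pipeline
inverts its own generative model under realistic noise magnitudes — not
that it is robust to every artefact of genomic or plate data.

## Problem sizes and verification

The repository's checks run the full pipeline at sizes chosen to keep the
suite quick while leaving the statistics meaningful: 200 random pairs for
exact score agreement with an independent brute-force Gotoh oracle; 500
simulated loci at 1% substitution for recovery (observed: 100% bin
recovery, ≥98% offsets within ±1 nt; the ±1 misses come from local
alignments clipping a mutated first base); 100 loci each for the
tether-truncation and decoy rejection checks (100% rejected); and 200
seeded plates for the 3-standard-error coverage check (observed ≥96%).
`scripts/acceptance.py --seed <int> --out <path>` recomputes all of these
plus the worked-example percentages and writes them as JSON.

## Known limitations

* The genome-wide census numbers of the original study depend on a
  specific genome assembly and repeat library; this package reproduces the
  method and its worked-example arithmetic, not those database-bound
  counts.
* The built-in aligner computes one best local alignment; multi-HSP
  chaining, seeded heuristics and E-values are out of scope (import
  tabular output from an external aligner when those matter).
* Subfamily ages are inputs, not estimates; nothing here dates insertions.
* The bounded co-optimal scan makes tie-breaking deterministic but can, in
  principle, miss a co-optimal alignment with a smaller subject start on
  pathologically repetitive inputs.
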