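# Methods

This note records the models behind each analysis, the defaults and why they
were chosen, and what the synthetic data generator does and does not emulate.

## Record model and coordinates

Sequences are DNA (ACGTN) or protein (20 amino acids + X), normalized to
uppercase at construction; intervals are 0-based half-open in memory and
1-based inclusive only in GFF3-style output. ORF regions must be a multiple of
3. Reading frames are searched on the forward strand only: the inputs this
package targets are cDNAs and genes already in sense orientation.

## Reference census tables

Two TSV fixtures ship with the package: per-sequence cysteine-cluster counts
(26 CdMTs, 17 CuMTs) and per-sequence glutamine codon counts, transcribed by
hand from the published family census. Both are guarded by embedded column
checksums; `load_fixture_tables` refuses to return silently corrupted data.
Cluster-count columns are cluster counts, not residue counts: each CCC, CXCC
or CXCXC cluster contributes 3 Cys, XCCX and CXC contribute 2, XXCXX
contributes 1 — the only reading under which every row reproduces its printed
total-Cys value, which the loader verifies row by row. The printed CuMT length
column was shifted by one row in the available rendering; lengths were
restored by requiring `100 · total_cys / length` to reproduce each row's
printed Cys percentage, which succeeds for 15 of 17 rows and is corroborated
by the isoform lengths quoted in the running text (ImMTT2 167 aa, TborMTT3
and TborMTT6 158 aa, mean CuMT length 113 aa). Two rows (TtroMT2, sp1.7-MT1)
print a Cys percentage inconsistent with their counts and length; the fixture
keeps the printed values — the published CuMT mean of 28.60 % only reproduces
with them — and flags the rows (`pct_consistent = False`) rather than
guessing a correction.

## Genetic code and codon statistics

The ciliate nuclear code is NCBI translation table 6 (UAA/UAG → Gln, UGA the
sole stop), taken from Biopython; the standard code is available for contrast.
Translation excludes the terminal stop, maps N-containing codons to X, and
treats an internal stop as an error that reports the codon index. ORF finding
takes the longest ATG..stop frame, breaking ties toward the 5' end; the
default minimum is 60 nt, well below any real MT ORF, to reject spurious
micro-frames. Gln codon tallies are keyed in RNA spelling (CAA/UAA/UAG/CAG)
to match field convention; the non-canonical/canonical ratio
(UAA+UAG)/(CAA+CAG) is reported as an exact rational plus a float rounded to
two decimals, and a zero denominator yields an undefined ratio, not an error.

## Cysteine clusters

A cluster is a maximal chain of Cys in which consecutive Cys are ≤ 1 residue
apart. The type is determined by the internal C/X pattern alone — the
flanking context implied by the names XCCX/XXCXX is not required, so clusters
at sequence termini classify normally — and CCXC is folded into CXCC
(orientation-insensitive; the six-type inventory has no separate CCXC class
and the census rows only balance under this merge). Chains of more than three
Cys have no canonical type; they are decomposed into consecutive canonical
blocks, preferring the fewest blocks and then the longest leading blocks
(CCCC → CCC + isolated C), with each resulting sub-cluster flagged
`decomposed` for audit. An exhaustive partition enumerator over all
{A,C}-strings of length ≤ 12 backs this rule in the test suite.

Subfamily calling: CdMT when the Cys fraction held in CCC+CXCC+CXCXC clusters
is ≥ 0.25 (the lowest value any real CdMT attains), CuMT when the CXC
fraction is ≥ 0.50 with the triple-cluster fraction ≤ 0.05, otherwise
ambiguous. The thresholds are configurable; they are descriptive separators,
not fitted quantities.

## CdMT module grammar

Modules end in a CXCCX terminator. Candidate terminators are CXCC followed by
any non-Cys residue; a candidate is flagged *canonical* when the final
residue is K, Q, E or N (the observed distribution of sm2 C-terminal finals,
roughly 55/36/7/2 %). Requiring the canonical set outright would make a
single substitution at the final residue delete an entire module from the
segmentation; with the relaxed candidate set plus the preference order below,
module counts survive 5 % random substitution essentially always. Boundaries
are chosen by dynamic programming over candidate subsets maximizing, in
order: modules with in-range lengths (32–63 aa) and linkers (2–9 aa),
canonical terminators, module count, with leftmost boundaries on ties.
Out-of-range segments are kept and flagged, never discarded. With no
candidate at all the whole protein is returned as a single flagged module.

Submodule annotation matches, left to right within a module: sm1
(`C{2,3}X6C{1,2}X6`), sm2 (`C{2}X{6,8}` + `CXCXXC{1,2}XXC{1,2}X{1,2}`),
an sm2 C-terminal fragment, and half-sm1, with X any non-Cys residue (a Cys
at a spacer position breaks the match, preventing cluster Cys from being
absorbed as spacers). The printed sm2 consensus cannot literally end in
CXCCX — enumeration of all its C₁₋₂/X₁₋₂ choices shows the last five
residues never form that motif — yet modules are defined to end in one; both
rules are stated with exceptions. The matcher therefore accepts an optional
CXCCX tail on sm2 (and on the C-terminal fragment), and the synthetic
generator emits that form, so a canonical module satisfies the module rule
and the submodule grammar simultaneously. A module is *canonical* when it
decomposes exactly as sm1+sm1+sm2.

CuMT repeats are all windows matching C·?·C·X₂₋₅·C·X·C (? any residue, X any
non-Cys), overlapping allowed, each flagged canonical when position 2 is the
consensus Lys.

## Metal-binding capacity

Capacity assumes every Cys thiolate coordinates metal at the vertebrate
stoichiometries Cd₇(Cys)₂₀ and Cu₁₂(Cys)₂₀, i.e. 0.35 Cd or 0.6 Cu ions per
Cys. Ion counts round half away from zero — the one rule consistent with all
the worked values in the reference material (54 Cys → 19 Cd, 24 → 8, 25 → 9,
32 Cys → 19 Cu, and 48 Cys → 17 Cd matching the experimentally characterized
Cd₁₇ complex); whether the original capacities were floored or rounded is not
stated anywhere, so this choice is flagged here.

## UTR motifs

Patterns are IUPAC strings scanned on the forward strand at every position
with a per-motif mismatch budget (default 0); overlapping hits are all
counted, a deterministic convention that never undercounts and is recorded in
the summary metadata. The default set — TATA = TAATAA, MTCM1 core = TGANTCA,
polyA signals AATAAA and ATTAAA, ARE = ATTTA — is a configuration default,
not a claim of completeness: the exact MTCM1 consensus and the two
polyadenylation signals used in the original promoter work are not available
in machine-readable form, so the standard eukaryotic signals stand in and
every definition is overridable.

## Semi-complete tandem duplication

The model: a derived gene is copy1 (a 5'/3'-truncated, substitution-diverged
copy of the parent) + a short junction + copy2 (likewise truncated and
diverged). Detection proceeds in two phases.

*Coarse scan.* An affine-gap local DP (Gotoh; match +2, mismatch −3, gap open
−5, extend −2 per additional base) is filled once for derived-vs-parent and
once for both reversed. For every breakpoint pair (i ≤ j, j−i ≤ 30 nt) the
score is the best alignment *ending exactly at* i plus the best alignment
*starting exactly at* j (row maxima of the two matrices — anchoring matters,
since a plain local alignment clips a lightly diverged segment tail and
leaves the score flat over several candidates) plus ⅓ per junction base.
That last term is a null model: a random junction base matches the parent
continuation with probability ~¼, so a copy may only claim a base it
explains better than junction background; without it, breakpoints drift
whenever the junction happens to resemble the eliminated parent region.
Both segments must be ≥ 50 nt and score ≥ 40, else a "not detected" result
is returned (never an exception).

*Boundary refinement.* Copies diverge by substitution only, so within a copy
the derived/parent correspondence is a gapless diagonal. Each breakpoint is
re-estimated by anchoring 15 nt inside the copy (via the segment's local
alignment) and walking the diagonal toward the junction, accumulating the
calibrated log-odds of copy versus junction per step (match:
log((1−d)/0.25); mismatch: log(d/0.75); d = 0.06 by default). The cumulative
walk is a boundary posterior under a uniform prior; the estimator returns the
position maximizing the posterior mass within ±2 nt — the Bayes rule when any
placement inside that window counts as correct — except that when the
maximum-a-posteriori point sits at walk exhaustion (no junction observed at
all, as for an exact head-to-tail double) it is returned exactly.

Known limitation: a junction flank that chance-matches the parent
continuation is information-theoretically indistinguishable from copy
sequence. Simulating the exact change-point posterior with known truth shows
even an ideal observer places a boundary within ±2 nt only ~96/94/92 % of the
time at 4/6/8 % divergence with a 9-nt uniform-random junction; with two
boundaries per gene the per-case ceiling is ~85–93 %. The implementation
performs at that ceiling (≈ 85–90 % over mixed 4–8 % divergence cohorts), and
the corresponding cohort test documents the measured capability rather than a
wished-for one.

## Synthetic generator

The generator emulates the family's documented architecture so that every
analysis stage has recoverable ground truth: CdMT proteins are Met + 2–5
modules assembled from sm1/sm1/sm2 templates with CXCCX terminators and 2–9 aa
linkers; CuMT proteins are CKCX₂₋₅CXC repeats with Lys-flanked spacers ≥ 6 aa
(shorter spacers would let the repeat pattern match across boundaries,
breaking exact truth recovery). Spacer ("X") residues are drawn from a
Cys-free, MT-like pool (K,S,T,G,E,Q,D,N,A). sm1's leading Cys run is CCC with
probability 0.75 so that the synthetic cluster composition mirrors the real
family, where CCC is the most abundant CdMT cluster type; a uniform draw
leaves synthetic CdMTs CCC-poor enough to fall near the subfamily-classifier
boundary. Terminator finals are drawn K/Q/E/N at 0.55/0.36/0.07/0.02.

Back-translation uses the ciliate code with glutamine codons drawn from the
per-subfamily biases measured on the real census (CdMT:
CAA/UAA/UAG/CAG = 0.29/0.54/0.15/0.02; CuMT: 0.61/0.29/0.08/0.02) and
uniform synonymous choice elsewhere; the ORF is ATG…TGA. UTR backgrounds are
A+T-rich (~66 %) and rejection-sampled to contain no default motif, then the
requested motifs are planted non-overlapping and re-verified, so planted
counts are exactly recoverable — a testing convenience, not a biological
claim about real UTRs. The assembled cDNA is rebuilt until the planted CDS is
the unambiguous longest reading frame. Substitution mutations apply at
non-Cys protein positions (start Met excluded) before back-translation; there
is no indel model. A fixed spec (including seed) is byte-deterministic.

What passing the synthetic round-trips does *not* show: real MT sequences
carry the "with several exceptions" irregularities the grammar only flags
(out-of-range modules, non-canonical terminators, incomplete submodules),
real UTRs contain motif-like background the planted counts deliberately
exclude, and real duplication junctions are recombination products rather
than uniform random sequence. Tests on generated data validate the machinery,
not the biology of any particular accession.

## Problem sizes and determinism

The shipped tests and the acceptance script use 200-gene cohorts for
module-count recovery (zero and 5 % mutation), 100 seeded cases for
duplication breakpoints (divergence cycling 4/6/8 %, Fig-geometry
truncations 29/40 nt and a 9-nt junction), and 1000 genes for the codon-bias
check — sizes at which the binomial noise on each rate is well under the
margins being asserted. All randomness flows from explicit integer seeds
through `numpy.random.default_rng`; reports are byte-identical across runs
with the same inputs and seed.
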