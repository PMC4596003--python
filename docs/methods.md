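# Methods

This note documents the models behind each detector, the conventions and
tunable parameters, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was open.

## Coordinates and orientation conventions

All positions are 0-based with half-open intervals internally; 1-based
conventions exist only at I/O boundaries (VCF positions, 1-based-inclusive
CN TSV). A breakend orientation of `head` means the sequence retained
through the junction lies at coordinates ≤ pos; `tail` means ≥ pos. BEDPE
strands map `+` → head and `-` → tail, so a deletion-type junction is
(head, tail) on ordered breakends, a tandem-duplication-type junction is
(tail, head), and fold-back/inversion junctions are same-orientation —
matching the common BEDPE convention for deletions as (+, −).

## SV confidence filter

A call passes when (≥ 2 evidence classes each with ≥ 1 read, or exactly one
class with ≥ 10 reads) AND no supporting reads in the matched normal AND
breakend region coverage ≤ 1000× (a proxy for collapsed repeats). "Lines of
evidence" counts classes, not reads. The filter is a total, monotone
function: more supporting reads can never demote a call, more normal
evidence can never rescue one.

## Eight-way SV typing

Typing is a first-match-wins decision table: translocation (different
chromosomes) → deletion ((head, tail) with a loss-state segment whose two
boundaries each fall within ± 30 kb of the two breakends) → tandem
duplication ((tail, head), gain/amplified segment boundary-matched the same
way) → duplication ((tail, head), gain/amplified overlap without the
boundary match) → fold-back inversion (same orientation, span ≤ 30 kb, a CN
step within ± 30 kb of a breakend) → amplified inversion (same orientation,
both breakends inside amplified segments) → inversion (any other
same-orientation join) → intrachromosomal (everything else). Fold-back must
precede plain inversion or it is unreachable. The ± 30 kb window is applied
per breakend. The fold-back span cap reuses the 30 kb window: fold-back
junctions join nearby loci by construction, and no separate span is
established in the literature; it is configurable (`MatchParams`).

The split between fold-back and amplified inversion (CN step proximity vs
amplified-segment membership) is this package's operationalization; the two
labels are treated as one inversion family by the BFB detector, so the
boundary between them does not affect catastrophe calls.

## Copy-number states

loss: CN 0–1; neutral: CN 2 heterozygous; cnLOH: CN 2 with major allele
fraction ≥ 0.9; gain: CN 3–5; amplified: CN ≥ 6. The 0.9 cutoff for "one
parental allele" tolerates allele-fraction noise at realistic tumour
cellularity (~70 %) while separating cnLOH from heterozygous segments; it
is configurable (`CNStateThresholds.loh_min_maf`).

## Chromothripsis

Per chromosome, five criteria, all reported as individual flags:

1. **Clustered breakpoints** — one-sample Kolmogorov–Smirnov test of
   breakend positions (each breakend on the chromosome counts once;
   translocations contribute one end) against Uniform(0, length),
   *P* < 0.001. Below 5 breakends the test returns *P* = 1 with a small-n
   flag.
2. **CN oscillation** — ≥ 10 adjacent-segment switches in total CN.
3. **2–3 states** — the number of distinct total-CN levels on the
   chromosome is 2 or 3.
4. **Retained heterozygosity** — every segment at the modal higher CN level
   has major allele fraction < 0.9; lowest-level ("lost") segments are
   exempt. Missing allele-fraction data makes this flag, and therefore the
   verdict, indeterminate (None) rather than negative.
5. **Random joins** — χ² goodness-of-fit of the four join orientation-pair
   counts against equal proportions (df = 3); the criterion is met when
   *P* ≥ 0.001 (high *P* is consistent with random joining). With < 8
   intrachromosomal joins the test is indeterminate, and an indeterminate
   join test counts as criterion-not-met: the criterion demands affirmative
   evidence of random joining, and without it small clustered events (for
   example a six-join double-minute chromosome, which oscillates between
   two CN levels) would be indistinguishable from shattering.

The composite verdict is the conjunction of the flags. The χ² formulation
is the simplest faithful operationalization of join-randomness over
orientation pairs; a segment-order permutation test was considered and
rejected as under-specified for this data model. "Expected" breaks/Mb for
the 3× localization rule is the same sample's genome-wide rate. The
array-only variant uses criteria 2–4 only.

## Breakage-fusion-bridge

Positive when a terminal run of loss-state segments spans ≥ 1 Mb (p- or
q-side), an amplified segment starts within 1 Mb of that run (contiguous
amplified neighbours merged into one region), and ≥ 2 inversion-family
calls (inversion, fold-back, amplified inversion) have both breakends
inside the amplified region. The 1 Mb loss and adjacency windows are
package choices — no spans are established in the literature — and are
configurable (`BFBCriteria`). The detector requires type-level inversions
rather than literal fold-backs only, since plain inversions in the amplicon
carry the same signal.

## Kataegis

Per sample, all mutations are ordered by chromosomal position genome-wide
(one series per sample, chromosomes concatenated in genome order) and
intermutation distances taken between consecutive mutations; duplicate
positions are collapsed first, since zero distances would dominate the
log-scale segmentation. log₁₀(IMD) is segmented by exact penalized
least-squares piecewise-constant fitting with penalty γ = 25 and minimum
segment length kmin = 2. The log transform is required for γ = 25 to be
meaningful: raw IMDs span 10⁰–10⁸ and would reduce the penalty to noise.
Segmentation on the genome-wide series means a focus near a chromosome end
still has ample flanking background (from the neighbouring chromosome) for
the changepoint penalty to be paid; cross-chromosome distances on the
concatenated coordinate are so large that no qualifying focus can straddle
a boundary.

A segment qualifies as a focus when it **contains** a run of ≥ 6
consecutive mutations whose mean raw spacing is ≤ 1,000 bp; the longest
such run is reported (found in O(m log m) with prefix sums of IMD − 1000).
Applying the ≤ 1 kb mean to the contained run rather than to every spacing
in the segment matters in practice: a single background mutation landing a
few tens of kb from a genuine focus has an intermediate log-IMD that the
SSE-optimal segmentation absorbs into the focus segment, and a
whole-segment mean would then disqualify a real focus. The ≤ 1 kb test uses
arithmetic means of raw distances (the criterion is stated in bp, not in
log units). Per-sample burden: none (0 foci), occasional (1–9), numerous
(≥ 10). Focus class composition (C>T / C>G vs other, pyrimidine-
normalized) is reported per focus rather than being a calling requirement.

### PCF exactness

`pcf_segment` minimizes within-segment SSE + γ·(segments − 1) subject to
segment length ≥ kmin by dynamic programming over prefix sums (O(n²),
vectorized); it is provably optimal and is verified against brute-force
enumeration of all admissible segmentations for n ≤ 20 in the test suite.
Ties within a 10⁻⁹ relative tolerance break toward fewer segments, then
earlier boundaries. kmin > n returns a single flagged segment.

## 96-context spectra

Substitution classes are ordered C>A, C>G, C>T, T>A, T>C, T>G; bases are
ordered A, C, G, T; the class index is 16·sub + 4·idx(5′) + idx(3′).
Purine-reference substitutions are reverse-complemented (ref, alt and both
flanks) before indexing, so the 192 raw combinations collapse onto exactly
96 classes. The spectrum matrix preserves per-sample SNV counts as column
sums.

## Telomere content

A read is telomeric iff it contains three contiguous copies of the repeat
on either strand as an exact substring; a read counts at most once, N bases
break matches, and degenerate variant repeats (e.g. TGAGGG) are not
matched. Mean genome coverage is an input (from alignment metrics or
simulation truth), not estimated from the FASTQ, because unaligned reads
cannot supply genome-wide base coverage. The ratio is
(tumour count / tumour coverage) / (normal count / normal coverage); it is
invariant under proportional scaling of counts and coverage and undefined
when the normal has zero telomeric reads.

## Double-minute reconstruction

Each amplified segment is a node with two ports (left = genomic start,
right = genomic end). A head breakend (retained lower side) attaches to a
right port, a tail breakend to a left port, within ± 30 kb (the same window
as CN-boundary matching; nearest fragment wins). A valid cycle uses each
visited fragment's both ports exactly once, alternating fragment traversals
and SV edges. Cycles are enumerated by exhaustive depth-first walk with a
12-fragment cap — exact at the scale such amplicons occur (a handful of
fragments) — and deduplicated by their edge set, which uniquely determines
the cyclic order, so rotations and reflections collapse to one canonical
report (started at the smallest fragment id). All overlapping cycles are
reported; no model selection among alternatives is attempted. The search is
verified against an independent edge-subset enumeration oracle: a subset of
edges is a cycle iff every incident port has degree exactly one, both ports
of every touched fragment are used, and the touched fragments are
connected.

## Synthetic cohort generator

The generator emulates the qualitative structure of each phenomenon; no
generative model exists in the literature, so distributional choices are
package conventions, fixed once:

* **Genome** — 22 uniform 100 Mb chromosomes with 1 Mb mid-chromosome
  centromere intervals. Rates and windows scale per-Mb, so uniform lengths
  lose no generality for the detectors.
* **Chromothripsis** — a shattered region covering 10 % of the chromosome
  at a random location, partitioned into 30 fragments (1 kb resolution),
  each independently retained (higher of 2–3 CN states, heterozygous
  allele fraction) or lost (lowest state, LOH) with p = 0.5; consecutive
  retained fragments are joined with orientations uniform over the four
  head/tail pairs. The region is localized because the phenomenon is —
  whole-chromosome partitions would make breakpoints uniform and the
  clustering criterion unsatisfiable by construction. Draws are retried
  (budget 100, then a loud error) until the profile has ≥ 10 switches and
  the join orientations are not χ²-extreme (p ≥ 0.01): the generator's
  contract is a clear-margin positive, and an orientation draw in the
  extreme 1 % tail is not one.
* **BFB** — 5 Mb terminal loss (CN 1, LOH), adjacent 4 Mb amplicon at CN 8
  (matching the scale of observed BFB amplicons), 20 same-orientation
  inversions with both breakends inside the amplicon and spans < 30 kb.
* **Kataegis** — background SNVs at 1/Mb placed uniformly; foci of 8 C>T or
  C>G mutations within 4 kb (mean spacing ≈ 570 bp), redrawn when within
  1 Mb of another focus.
* **Double minutes** — 6 fragments summing to 2.5 Mb at CN 12, placed in
  disjoint zones of the host chromosome(s), cycled in random order with
  random orientations.
* **Background SVs** — 0.05/Mb uniformly per bp, 80 % intrachromosomal,
  orientations uniform; ~95 % carry filter-passing evidence and the rest
  exercise each reject path. Shattered chromosomes and the background are
  drawn jointly and redrawn together (same retry policy) until every
  shattered chromosome keeps a clear margin on the combined join set the
  detectors see — clustering at a 10× margin below the detection threshold
  and join orientations outside the extreme 1 % tail — keeping the planted
  truth unambiguous.
* **Telomere reads** — full-read tandem repeats at a set fraction (tumour
  1 %, normal 2 %, i.e. somatic shortening), rest i.i.d. uniform bases;
  coverages 74× / 39×.

Everything is deterministic given `SimulationParams` (including the seed).

**What passing tests do and do not show.** The generator produces clean
integer CN, noise-free breakpoints, exact evidence counts and
ideal-tandem telomeric reads. Truth recovery on these cohorts demonstrates
that the decision logic implements its criteria exactly and with zero false
positives under the stated conditions; it does not demonstrate robustness
to segmentation noise, subclonality, impure tumours, alignment artifacts or
degenerate telomere repeats, none of which are modelled.

## Problem sizes in the test suite

The acceptance-style checks use 50-sample cohorts per detector (22
chromosomes each), 100 kataegis SNV sets, 200 PCF series (n ≤ 20, where
exhaustive enumeration is feasible), 1,000 null chromosomes for KS
calibration and 50 random port graphs (≤ 12 fragments, where edge-subset
enumeration is feasible) — sizes chosen so every stochastic property is
measured with adequate resolution while the whole suite runs in about a
minute.

## Known limitations

* Temporal ordering of co-occurring catastrophes (BFB then chromothripsis)
  is out of scope; verdicts are per-chromosome and independent.
* "One or few chromosomes" is not quantified anywhere; the pipeline flags
  every positive chromosome and reports all of them.
* Whether a read matching both telomeric motifs should count twice is
  unspecified; here a read counts at most once.
* The breaks/Mb 3× localization rule uses breakends (a double-strand-break
  count), not events.
* Amplicon search is exhaustive and therefore capped (default 12
  fragments); graphs from whole-genome-amplified samples with hundreds of
  amplified segments would need the cap raised or the fragment set
  pre-filtered.
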