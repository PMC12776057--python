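# Methods

This note documents the models, parameter choices, and numerical conventions
behind each stage, and what the synthetic data do and do not emulate.

## The synthetic cluster model (`forge`)

A haplotype is laid out as `flank | C1 | flank | C2 | unit×N | SYT19-rest |
flank`, all coordinates 0-based half-open. The duplication unit — the
segment that tandem expansion repeats — contains a suffix fragment of the
upstream gene (C2), an intergenic gap, the expanded gene (C3), a second gap,
and a prefix fragment of the downstream gene (SYT19). Fragment and gap sizes
are fixed fractions of the unit (a = b = unit/8, gap = unit/10), so the unit
scales from the 2 kb desk default up to the real ~17.6 kb without changing
structure.

**Ecotype SNPs.** One ancestral backbone is drawn per seed; SNP columns
(default rate 0.005/bp) carry a marine (ancestral) and freshwater (derived)
base. Marine and freshwater haplotypes built from the same seed are
byte-identical except at the SNP table's positions — an invariant the tests
rely on. SNP entries inside a duplicated unit are duplicated with the unit.
SNPs are excluded from windows around unit boundaries (max(24, imperfect
microhomology + 8) bp) so junction analyses are independent of SNP noise.

**Junction microhomology.** The fusion junction of tandem expansion joins
the SYT19-prefix end of one unit to the C2-suffix start of the next. Rather
than editing each junction, the homology is planted once in the donor
genes: the k bases immediately left of the breakpoint are copied from SYT19
into C2 (the perfect core), an optional longer window with exactly one
interior mismatch forms the imperfect extension, and double-mismatch
"walls" bound both, so the detector's answer is exact, not probabilistic.
Defaults are 4 bp perfect / 8 bp imperfect. When no imperfect extension is
planted, a detector with mismatch budget m will report perfect + m, since
any window may absorb m wall bases.

**Paralog divergence.** The duplicated (new last) unit receives private
substitutions at rate 0.01/bp, placed outside junction-flank windows and off
SNP columns. This rate is not a measured quantity of the real cluster; it is
chosen to yield ~20 informative columns per 2 kb unit — enough for crossover
inference at toy scale and comparable in visual density to real
divergent-site tracks. All conclusions about the inference machinery are
conditional on substitution-only divergence: the forge plants no indels
between units, so gap-column handling is exercised only through synthetic
alignments in tests.

**Mosaic intermediates.** 5- and 6-copy haplotypes insert intermediate
units equal to `L[:x] + A[x:]` (x = crossover offset), the product unequal
crossover between a first (A) and last (L) unit would generate.
`recombine_nahr` produces the reciprocal duplication/deletion pair from two
haplotypes explicitly; total copy number is conserved, and the recorded
crossover interval is the maximal identity interval around x between the
paired donor units — the best any inference can localize.

**Read simulation.** Paired-end defaults are 76 bp reads, normal fragment
lengths 150 ± 50 bp truncated to [read length, source length], FR
orientation, 8× depth, i.i.d. substitution errors, constant base quality.
Source sequences are drawn proportional to weight × length for fragment
pools and proportional to weight alone for full-length transcript reads.
Platform error profiles, indels, PCR duplicates, and base-quality models
are deliberately out of scope: downstream stages use exact matching.

## Depth-based copy calling (`depthcnv`)

Depth is accumulated on a reference in which only one duplication unit is
retained and the rest are hard-masked, so reads from every copy pile up at a
single locus; mean depth over the unmasked gene divided by a baseline mean
is then linear in copy number. The default pileup projects the simulator's
source coordinates through the truth record (positions inside any unit map
into unit 1); this is the noise-free equivalent of realignment to the masked
reference and keeps the statistical path testable without an aligner.
SAM/BAM input is also accepted, with MAPQ ≥ 3 and primary-alignment filters.

Calibration simulates reads per assembled haplotype per copy count and
averages replicate depths (default 4 simulations per haplotype; entries
must increase strictly with copy count or the table is rejected as a
mapping/mask misconfiguration). Calls are nearest-entry with ties broken
toward the lower count — the conservative, ancestral-state-first rule.
Diploid totals use genotype expectations (mean of haplotype expectations;
depth linearity makes every decomposition of a total agree).

For depth experiments the synthetic flanks are enlarged (30 kb genes, 10 kb
flanks; ~118 kb of single-copy baseline around a 17.6 kb unit) so that the
baseline mean is nearly noise-free, as the genome-wide autosomal mean is in
real data. With a 19 kb toy baseline the normalization itself contributes
~3% noise and genotype recovery at 8× drops to ~93–96%; with the
genome-like baseline it is 99–100%.

The Mann–Kendall test reports S, the tie-corrected variance, and a z with
the conventional sign-dependent continuity correction; the one-sided
(increasing) p uses P(S ≥ s) ≈ Φc((s−1)/σ) for all s — on the lattice of S
this is the correct upper-tail correction, and it agrees with the exact
permutation p (computed for n ≤ 8 by full enumeration) to well under 0.02
at n = 6–8. Rank-sum, signed-rank, Pearson, and hypergeometric computations
delegate to scipy.stats.

## K-mer expression (`kmerquant`)

Columns of the copy-by-allele alignment are classified exclusively as
copy-discriminating (no within-copy allele difference; some pair of copies
has disjoint residue sets), allele-discriminating (some copy's alleles
differ; no cross-copy disjointness), invariant, or other (gaps or mixed
signal; such columns disqualify a window). Every qualifying 27-column
window is emitted, then reduced greedily left-to-right to non-overlapping
windows per target — the selection rule is a package choice; only the
window-qualification rules are inherited from the study design.

Screening treats matches inside the declared homologous target regions as
on-target; elsewhere, one perfect match or more than five one-mismatch
matches (both strands) removes the whole set, as does a member closer than
100 bp to a transcript end. The end rule matters in practice: end-proximal
sets collect few informative pairs, and an unweighted per-set average lets
their noisy proportions dominate (observed as a −0.065 bias in an
unscreened run).

Counting is exact substring matching; a pair increments a member at most
once. Reverse-complement search defaults on — the real libraries are
strand-specific but the orientation convention of exact-match counting is
not fixed by that — with a stranded mode available. The ASE estimate is the
unweighted mean over sets of allele1/(allele1+allele2), gated by QC (≥1
read per allele, ≥100 total, every set detected); failure is a value with a
reason, not an exception.

## Long-read attribution (`isoquant`)

The variant key consists of all columns within the spanning interval at
which ≥2 copies differ; key construction fails (naming the pair) if two
copies are indistinguishable. Unaligned reads are placed by exact anchored
search: the span consensus with wildcards at key positions must match
somewhere in the read (either orientation). A read is assigned only if it
covers the full span and matches exactly one copy's profile at every key
position; `max_key_mismatch` (default 0) can relax the per-profile match,
but mismatching reads are otherwise "conflicting" — near-misses are not
rescued by majority vote, because the error model of a single discordant
variant position is ambiguous between sequencing error and recombination.

## Mechanism inference (`mechinfer`)

Microhomology: donors are compared at matched junction-relative offsets;
the perfect length is the identity run containing the junction point, and
the imperfect length is the longest window containing that core and
spanning the junction with at most `mismatch_budget` (default 1)
mismatches, found by exhaustive O(W²) scan over the flank window (default
60 bp each side). "Imperfect microhomology" has no standard definition; the
budgeted-window formalization reproduces a 4 bp core inside an 8 bp
one-mismatch window and stays parameterizable.

Crossover windows: gap-containing columns are removed first; columns where
A ≠ L are labeled by the intermediate's base (A/L/other, "other" excluded);
a single changepoint c minimizing mismatches to "L up to c, A after" is
found by exhaustive scan. The window runs from the last informative column
of the L segment to the first of the A segment, unioned over tied optima —
ranges, not point estimates, are the honest resolution of the data.
Residual mismatches are reported as putative gene-conversion tracts, not
modeled; an HMM would smooth them away at the cost of oracle-verifiability.
All-one-state label sequences yield a flagged degenerate window; sequences
fitting the reversed A-then-L model strictly better are flagged
non-canonical. Assemblies are grouped by window overlap (connected
components); the group count is the minimum number of independent
expansion events.

## Protein divergence (`protdiv`)

"Divergent between ecotypes" is residue-set disjointness per column — the
strictest reading of "changed in all freshwater relative to marine" that
handles polymorphic groups. Domain enrichment is the exact hypergeometric
upper tail P(X ≥ k) with N = protein length, K = domain length, n =
divergent sites, k = sites in the domain; at the myosin scale (N = 1931,
K = 51, n = 18, k = 3) this gives 0.0107, i.e. 0.01 at reporting precision.
CDS integrity classifies an internal stop as nonsense truncation at that
residue, a non-multiple-of-3 length difference as frameshift truncation at
the first out-of-frame stop (sequence end if none), and a clean codon-count
deletion as in-frame.

## Problem sizes and determinism

Tests and the acceptance script run everything from seeds; identical seeds
give byte-identical outputs (gzip streams are written with a fixed mtime).
Desk-scale defaults (2 kb units, ~22–28 kb haplotypes, 1.2 kb transcripts)
keep the full suite under a minute; depth-recovery experiments use the real
17.6 kb unit at 8× with 100 replicate diploids, ASE recovery uses 100
replicates × 1,500 pairs per true proportion, and the changepoint fit is
checked against brute force on all 8,188 label strings up to length 12.
Passing on these synthetic conditions validates the machinery — exact
counting, calibration, detection, and the statistics — not the biological
values of any real population, which require the deposited sequencing data.

## Known limitations

Substitution-only divergence (no indels at junctions or between units);
no alignment step (mapping bias is emulated only through its solution —
masking and exact matching); uniform fragment start positions (no GC or
hexamer bias, so the 5' trim option is a pass-through at desk scale); the
sex-chromosome normalization mode is recorded but sex inference itself is
upstream metadata; and the k-mer screen's off-target scan is a dense
O(genome × k) comparison, adequate for desk-scale references but not a
replacement for an indexed search at whole-genome scale.
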