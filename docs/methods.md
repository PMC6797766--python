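# Methods

`srnamir` re-implements, as a tested reusable library, the computational
analysis used in small RNA sequencing studies of stress-responsive plant
miRNAs: read cleaning and accounting, conserved-miRNA calling against a
mature reference, novel-miRNA prediction from genomic hairpins with
duplex/MFEI criteria, an exact digital differential-expression test with
Bonferroni correction, hypergeometric term enrichment, and 2^-ddCt qPCR
validation. Every stage can be exercised end to end on synthetic data with
planted ground truth. This note records the models, parameter choices and
their rationale, and what the synthetic data does and does not show.

## Read QC and accounting

Raw reads are 4-line FASTQ (Phred+33). Each read receives exactly one of
five categories, tested in a fixed precedence order so that a read violating
several rules is counted once:

1. **low_quality** — mean Phred < 20, or > 10% of bases below Q13. Common
   Illumina-era conventions; the accounting scheme we reproduce does not
   define the thresholds, so they are explicit `QcParams` fields.
2. **invalid_adapter** — no 3' adapter occurrence. An occurrence is a full
   adapter match anywhere or a >= 6 nt adapter prefix at the read end.
   Trimmed inserts longer than the retained maximum (30 nt) also land here:
   such reads have no valid 3'-primer position within the retained window.
3. **poly_a** — trimmed insert >= 80% adenine.
4. **short** — trimmed insert < 18 nt. An adapter dimer (adapter at
   position 0, empty insert) is therefore "short".
5. **clean** — insert within 18-30 nt.

The retained window is a genuinely open choice (the study design we emulate
quotes both a 15-30 nt histogram axis and an 18 nt lower cutoff); we retain
18-30 nt for analysis and plot the histogram over 15-30 with an overflow
bucket. The accounting row satisfies `raw = low_quality + invalid_adapter +
poly_a + short + clean` identically (fuzz-tested), and the clean percentage
is rounded to two decimals.

## Unique tags, ncRNA discard, genome mapping

Clean inserts are collapsed to unique tags with a per-library count vector.
Tags matching an rRNA/tRNA/snRNA/snoRNA/scRNA decoy reference (exact
substring on either strand) are discarded from miRNA analysis; the class
priority rRNA > tRNA > snRNA > snoRNA > scRNA breaks multi-class ties
deterministically. The remaining tags are mapped to the genome by exact
search on both strands; minus-strand hits are reported in plus-strand
coordinates with a strand flag (external coordinates 1-based inclusive,
internal 0-based half-open, converters tested). The index is a plain
all-occurrence substring scan: at the package's intended toy-to-moderate
scale the contract (every occurrence, both strands) matters, not the data
structure. Tags with more than 20 loci are flagged repeat-like and excluded
from novel calling.

## Conserved calling

A tag is a conserved miRNA if its best ungapped overlay on any reference
mature sequence scores at most 3, where the score is the Hamming distance
within the overlap plus every overhanging base, and at most 2 nt of overhang
are allowed per side. Counting length differences against the mismatch
budget treats isomiR-like 3' heterogeneity consistently with a BLASTN-style
"no more than three mismatches" rule whose exact alignment parameters are
not recoverable. Ties are broken by fewest overhang bases, then by
reference name. Calls with summed counts across all libraries below 10 are
discarded (the threshold is applied to the total, not per library — the
stricter per-library reading would also discard genuinely expressed
miRNAs with one weak library). Families are the numeric part of the name
(bra-miR156a-3p -> MIR156); abundance ranks use summed reads-per-million.

## Folding engine

Precursor candidates are folded with an in-package dynamic program over
nested structures (Watson-Crick + G.U pairs, minimum hairpin loop 3 nt).
The energy model is deliberately compact so that it is *exhaustively
verifiable*: a pair stacked on an inner pair scores -3.3 kcal/mol (both
pairs GC), -2.1 (either AU) or -1.4 (either G.U); an unstacked pair scores
-1.0; hairpin loops cost +3.0 and bulges +2.0; interior loops and
multiloops are free; bulge/interior loops are capped at 30 unpaired nt (the
standard DP bound — irrelevant below 30 nt, where the oracle runs).
Energies are integers in tenths of kcal/mol, so co-optimal ties are exact
and the tie-break (fewer pairs, then a fixed scan order in the traceback)
is deterministic. The DP is O(n^3) (numba-compiled) with full traceback to
a dot-bracket string.

The model is *not* Turner-2004 thermodynamics, and no attempt is made to
reproduce MFE values computed by external folders on real precursors. What
is verified instead: on 200 random sequences up to 25 nt the DP minimum
equals brute-force enumeration over every nested structure scored by an
independent implementation; appending bases never raises the MFE (the old
optimum stays feasible); and the traceback structure re-scores to its
reported energy. Derived statistics follow the standard conventions:
AMFE = MFE/length x 100 and MFEI = |AMFE| / GC% (reported as a positive
magnitude; undefined at GC = 0 and returned as NaN).

## Novel-miRNA screen

For every unannotated, uniquely-mapped tag, three precursor windows are
excised around the locus (centred with 150 nt flanks, and two asymmetric
variants placing the mature near either end), capped at 320 nt and clipped
at chromosome ends; minus-strand windows are reverse-complemented. Each
window is folded and screened:

* **star placement** — the pairing-partner interval of the mature shifted
  +2 nt in precursor coordinates. Both strands' 3' ends point the same way
  along the precursor, so a single +2 shift yields the canonical Dicer
  2-nt 3' overhang on *both* duplex ends; applying the shift twice returns
  the mature interval exactly (tested). A mature with fewer than 60% of its
  bases pairing toward one arm (e.g. spanning the loop) has no star.
* **duplex criteria** — over the duplex region (each strand minus its own
  2-nt 3' overhang): mismatched mature bases < 3, asymmetric bulge runs
  (unpaired on one strand, zero opposite) <= 1, and a >= 1 nt 3' overhang
  on both strands.
* **star evidence** — the star sequence must occur among the sequenced
  tags, with up to 2 nt of 3'-end slack (shared 5' end); any library
  suffices. Matching in *all* libraries would be the stricter reading; any
  one library is what a discovery screen can honestly require at four
  libraries of this depth.
* **MFEI threshold** — folded window MFEI >= 0.8 (configurable), the lower
  edge of the band typical of plant pre-miRNAs.

The best passing window (lowest MFE) represents the locus. Each precursor
is reported once: tags are screened in descending abundance and a tag whose
loci fall inside an already-accepted precursor window — the star product of
a called miRNA, typically — is absorbed into that call. Reports are named
novel-mirNNN in genomic order with 1-based locations, the mature length
column computed from the sequence, plus GFF3 and dot-bracket outputs.

## Digital differential expression

Counts are normalized to reads per million of the library's clean total;
exact zeros become 0.01 so fold changes stay defined; miRNAs below 1 RPM in
every library are excluded. For a tag with count x in the control library
(depth N1) and y in the treatment (depth N2), the test statistic is the
conditional probability

    p(y|x) = (N2/N1)^y (x+y)! / ( x! y! (1 + N2/N1)^(x+y+1) )

— algebraically the negative-binomial NB(x+1, N1/(N1+N2)) pmf in y, which
the tests exploit as an independent cross-check via scipy. Tails
C = sum_{y' <= y} p(y'|x) and D = sum_{y' >= y} p(y'|x) both include the
observed point, so C + D = 1 + p(y|x) exactly; the implementation sums the
shorter tail directly in log-gamma space (terms beyond 40 conditional SDs
dropped, well below 1e-16 of the total) and recovers the longer tail from
the identity, keeping counts up to ~1e7 overflow-free. The two-sided
p-value is min(1, 2 min(C, D)) — the doubled smaller tail, a standard and
conservative combination for a statistic whose two tails are printed
separately. Under library exchange the tails map onto each other up to the
shared boundary term: C(x,y;N1,N2) = D(y,x;N2,N1) - p(x|y;N2,N1), asserted
to 1e-10.

Bonferroni correction multiplies by the number of tested miRNAs in the
comparison (capped at 1). Volcano calls use |log2fc| >= 1 and corrected
p < 0.05 by default; the thresholds are exposed because the analysis we
emulate reports up/down counts without printing its cutoffs. Comparisons
are each treatment timepoint against the 0 h control.

The "p(x|y)" orientation question: the equation header names p(x|y) while
the tail sums run over y given x. We implement the standard reading — the
distribution of the second library's count conditioned on the first — and
make no claim about the original authors' code.

Calibration measured by the tests: under an equal-expression Poisson null
(2000 tags, matched 1e6 depths, Poisson means 100-1000, 20 replicates) the
raw p < 0.05 fraction is 0.047 (within 0.05 +/- 0.01; the shortfall is the
usual discreteness of an exact test), and Bonferroni leaves >= 95% of
replicates without any family-wise false positive at the tested seed. The
per-replicate family-wise rate is itself a 20-draw binomial, so the
acceptance script's reported rate varies noticeably with the seed.

## Enrichment

Hypergeometric upper tail P(X >= k) for k study hits of a K-gene term in an
n-gene study set against an N-gene background (all genes of the annotation
table unless overridden), computed via scipy's log-space implementation and
verified against exhaustive subset enumeration for N <= 12. Correction is
Benjamini-Hochberg by default — the field's standard for enrichment — with
a Bonferroni option; significance is corrected p <= 0.05.

## qPCR validation

dCt = mean(Ct_target) - mean(Ct_reference) per condition, averaged over
technical replicates *before* differencing (the order is unstated in the
protocols we emulate; averaging first is the usual 2^-ddCt arithmetic);
ddCt subtracts the calibrator condition (0 h); relative expression is
2^-ddCt and the qPCR log2 fold change is -ddCt. Platform agreement is an
OLS of sequencing log2FC on qPCR log2FC with R^2 the squared Pearson
correlation. Published R^2 values on real data are not reproducible from
synthetic inputs; the simulation property (R^2 > 0.9 at 0.2-cycle Ct noise,
near 1 at zero noise) is the testable surface.

## Synthetic-data generator

The generator emulates a four-library heat-stress time course and is the
package's test bed, not a sequencing simulator:

* **Genome** — uniform-random chromosomes (default 2 x 50 kb) with 10
  planted stem-loop precursors (spans 120-320 nt, both strands, >= 400 nt
  apart; exceeding capacity is an error naming the limit).
* **Hairpins** — built arm-by-arm: GC-enriched stems (55%), an 18%
  interior-loop rate in the lower stem (long perfect helices are not
  realistic and would push MFEI above the 0.8-2.2 band typical of plant
  precursors), and two G.U wobbles inside the mature/star duplex so the
  mature maps to a single genomic locus (a perfectly complementary duplex
  would also map on the minus strand). Six hairpins are constructed to pass
  the duplex screen (0-2 mismatches, 0-1 bulges), three to fail it (3 or 4
  mismatches; two 3-nt bulges), one to pass structurally but carry no star
  reads. Because the refolded optimum occasionally absorbs a planted defect
  into an alternative pairing, each design is verified by folding at build
  time and redrawn until the measured verdict matches the intent — the
  truth table records exactly what the screen should find.
* **Reference** — 41 conserved matures in 19 MIR families (members 1-2
  substitutions apart), echoing the scale of the study design emulated.
* **Expression** — per-miRNA mean counts: conserved ~lognormal (median
  ~150, minimum 12), novel matures 40-90, star reads ~3, ncRNA decoy
  fragments and background genomic tags complete the mix; library totals
  land near 20-25k clean reads — deliberately desk-scale so the full
  pipeline, tests and acceptance script run in seconds to minutes on one
  CPU. Ten conserved and four novel miRNAs carry planted log2 fold changes
  of +/-2 (DE rows have means >= 100).
* **Counts** — dispersion 0 gives the deterministic zero-noise limit
  (rounded means), used for exact-recovery tests; dispersion > 0 draws
  NB(size = 1/dispersion) counts, default 0.05 for sensitivity runs — a
  moderate overdispersion standing in for the pooled-replicate libraries,
  whose replicate-level variability is not recoverable.
* **Reads** — clean reads are insert + 3' adapter truncated to 36 nt at
  Q40; contaminant classes are generated per the QC definitions at the
  per-library proportions of the four-library accounting table this
  package reproduces (~7-8% non-clean), deterministically rounded, with
  per-class true counts recorded.
* **Ct tables** — target Ct shifted by -log2FC around a per-miRNA baseline,
  U6-style constant reference, Gaussian noise per well.

Everything is a pure function of one integer seed (byte-identical outputs,
tested). What passing on this data does *not* show: robustness to
sequencing error profiles, RNA degradation, isomiR clouds, repeat-dense
genomes, or real-genome mapping ambiguity — none of which the generator
models.

## Numerical and engineering choices

* Integer deci-kcal energies eliminate floating-point ties in the DP.
* AC tails: shorter-tail summation ascending in magnitude via logsumexp;
  longer tail from the exact C + D identity.
* Zero-read libraries report 0.00% clean with a warning rather than NaN.
* Empty study sets, empty call lists and header-only reports round-trip.
* Problem sizes used by the test suite and acceptance script (10 planted
  hairpins, ~80k reads over four libraries, 200 oracle sequences, 40k null
  tests) were chosen so a complete run takes about a minute; they are
  generator parameters, not limits of the implementation.

## Known limitations

* The folding model ranks structures plausibly but its absolute energies
  are not comparable with Turner-parameter folders.
* The exact-match mapper is not built for genome-scale references.
* The AC test models no biological replication; with overdispersed truth
  it is anti-conservative, which is inherent to the method being
  re-implemented, not a defect of this implementation.
* Enrichment takes a user-supplied gene -> term table; no pathway-database
  access, DAG propagation or map rendering.
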