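# Methods

## The measurement model

A full-length cDNA read aligned splice-aware to the genome carries its
poly(A) tail as a terminal soft clip: the tail has no genomic template, so
the aligner clips it.  `tailscape` treats the clip at the transcript's 3′
side as the candidate tail — the 3′ clip of a + strand alignment, or the
reverse complement of the 5′ (low-coordinate) clip of a − strand alignment,
so tails always read 5′→3′ along the transcript.  Alignments carrying any
of the samtools `-F 3844` flags (unmapped, secondary, supplementary,
QC-fail, duplicate) are ignored.  U residues appear as T in cDNA; the
library computes on the DNA alphabet and prints U in user-facing labels.

### Tail classification

Genuine tails are A-rich with sparse, irregularly placed non-A residues,
whereas unaligned mRNA body in a clip is high-complexity sequence.  Two
filters separate them:

1. **HIGH_TCG** — T, C and G each constitute ≥ 0.1 of the clip.  Checked
   first.
2. **FALSE_score_12+** — the transition score (number of adjacent unequal
   residue pairs scanning 5′→3′; a homopolymer scores 0) is strictly
   greater than 12.

Everything else is **TRUE** and proceeds to annotation.  Numerical choices:
the proportions are computed over non-N bases (N is a no-call and is also
excluded from all base counts); an empty clip is a valid 0-nt tail and is
TRUE with score 0; the score is computed on the full clip, untrimmed.

### Per-read annotation

Each TRUE tail becomes a fixed 13-column record (barcode, read id, gene id,
pass count, literal `1`, counts of A/T/C/G, non-A count, literal `0`, tail
sequence, mean tail base quality).  Zero-length tails serialize with `-` as
the sequence placeholder.  *Poly(A)+* reads are those with pass count ≥ 10
and tail length ≥ 1 nt; all tail-level analyses use them.

### Residue statistics

For each base B ∈ {U, C, G} the longest consecutive run is bucketed:
U1 / U2–5 / U≥6, C1 / C2 / C≥3, G1 / G2 / G≥3.  A tail is in the *3′-end*
class for B when its terminal base is B (maximal terminal run, length ≥ 1),
scanned before the internal class; a `collapse_end3_to_internal` mode
reports every occurrence as internal, matching libraries that cannot
capture 3′-terminal non-A residues.  The *N length* of a uridylated tail is
the 0-based offset of the unique longest U run from the tail's 5′ end,
counting residues of every kind; when two or more runs tie for longest the
N length is undefined and the tail is dropped from N-length analyses.

### PAS calling and PIT/PDI classification

A read's polyadenylation site is its 3′-most aligned base in transcript
orientation (`aln_end` on +, `aln_start` on −).  Per gene, sites are called
greedily from poly(A)+ read ends: score each observed end position by the
number of read ends within ±5 nt (inclusive), call the best if its support
is ≥ 10, exclude every candidate within ±20 nt (inclusive) of a called
site, repeat.  Candidates are restricted to observed end positions (any
position with zero exact ends is dominated by a nearby observed end, and
the search stays finite).  Support ties break by larger exact-end count,
then by the 5′-most coordinate; both choices are arbitrary but make the
caller deterministic.  For genes with exactly two sites, the one nearer the
transcription start is labeled pPAS, the other dPAS.

Classification against a catalog: a read ending within ±5 nt of a site is a
**PIT** (nearest site wins; exact-distance ties go to the 5′-most site);
otherwise a read ending more than 5 nt 5′-upstream of at least one site is
a **PDI**; remaining reads, and all reads of genes without called sites,
are **UNASSIGNED** and excluded from PDI proportions (denominator =
PITs + PDIs).  PDI ends are annotated as CDS, 3′-UTR (within the terminal
exon downstream of the CDS end) or other.

**Reference catalogs.** In a sample where most reads are degradation
intermediates, self-called catalogs absorb dense degraded-end clusters as
spurious sites.  The pipeline therefore supports (and the acceptance
analysis uses) a catalog called on a low-degradation reference sample and
reused for other samples of the same genome — the appropriate design
whenever a quiescent reference stage is available.

### Summaries

Per-gene tail length is the geometric mean (exp of the mean log length)
over poly(A)+ reads, as per-gene tail lengths are lognormal-like; it is
defined only from tails of length ≥ 1.  Gene-level proportions (non-A, PDI,
average U per tail, APA isoform comparison) require ≥ 20 qualifying reads
per gene — and for the APA comparison, ≥ 20 PIT reads per isoform.
Expression uses CPM = 10⁶ · (reads assigned to gene) / (all assigned
reads), counting every read with ≥ 1 pass; tail analyses use ≥ 10 passes.

Differential expression: log₂FC = log₂((mean_B + ε)/(mean_A + ε)) with a
pseudocount ε = 1 CPM guarding zero means; P values from a Student's
(equal-variance) two-sample t-test on CPM, Welch available by flag.  The
default is **two-sided**: a one-tailed test with a fixed direction is
available (`alternative='greater'|'less'`), but choosing the direction per
gene from the observed sign would double the null type-I rate, so it is
never the default.  Genes with zero variance in both groups and equal means
get P = 1.  Flags at |log₂FC| ≥ 0.5 and P < 0.05, raw P only (no
multiple-testing correction is applied, matching the screening use).

### UMI handling and library modes

UMI-tagged libraries are deduplicated to one read per (barcode, UMI, gene):
the copy with the highest pass count wins (more passes, better consensus),
ties to the lexicographically smallest read id; reads without a UMI pass
through and are counted.  The `paiso2` mode additionally restricts to reads
whose polyadenylation site lies in the last exon of their gene, a guard
against RNA fragmentation products.  GI-tailed (FLAM-style) reads are
parsed by their trailing G-run *g* before the UMI/barcode: *g* < 7 discards
the read, 7 ≤ *g* ≤ 16 strips the whole run, *g* ≥ 17 strips exactly 17 G
and keeps the surplus as potential genuine guanylation.

## The synthetic-data generator

The generator emulates the remodeling regime of the oocyte-to-embryo
transition so every stage is testable without controlled-access data.  Per
gene (two exons, CDS ending inside the last exon, 180-nt 3′-UTR; 30% of
genes carry a second PAS 100 nt upstream used for 30% of molecules):

- **read counts** — gamma-Poisson, mean 100, dispersion 0.1;
- **tail lengths** — lognormal, median per preset, log-sd 0.45, rounded
  and clamped to ≥ 1 nt;
- **degradation** — with probability `p_pdi` the 3′ end moves upstream of
  the used PAS by a uniform offset spanning the 3′-UTR plus a 20-nt CDS
  incursion (≈ 10% of degraded ends land in the CDS).  Uniform is the
  default because degraded ends show no positional hotspots; a geometric
  alternative exists.  The minimum offset is 15 nt: visible 3′-UTR
  shortening spans tens of nucleotides, and an end within ~3× the 5-nt
  assignment window of a PAS is operationally indistinguishable from an
  intact end.  Intact ends jitter around the PAS (±2 nt, mode at 0).  The
  recorded truth category is derived from the realized geometry, so truth
  and classifier definitions always agree;
- **uridylation** — with probability `p_u` a single U run (geometric
  length, mean 4, capped at 30) is written into the tail at an N length of
  0 with probability 0.3 and otherwise short-geometric (mean 6, ≤ 15),
  with at least one trailing A so the run is internal; a `p_end3_u` option
  places the run at the 3′ terminus instead;
- **mono C/G** — per-base substitution of remaining A at rates 0.004 and
  0.003;
- **sequencing** — substitution-only errors at 0.001/base (no indels, so
  ground-truth tail length stays exact); pass counts 1 + Poisson(18) with
  an 8% low-pass fraction exercising the pass filter;
- **duplication** — optional UMI-tagged PCR duplicates (Poisson extra
  copies per molecule).  Synthetic UMIs are deterministic unique base-4
  codes per molecule rather than random k-mers, so deduplication provably
  restores pre-duplication counts at toy scale.

Stage presets bundle the regime parameters: `GV` (median 37 nt, 15% PDI,
15% uridylated), `MII` (63 nt, 15%, 30%), `1C` (33 nt, 60%, 60%),
`somatic` (70 nt, 15%, 12% with mono-dominated runs).  Presets are
conveniences, not claims of fidelity.

Reads are emitted pre-aligned (SAM constructed directly, tail as terminal
soft clip, reverse-complemented on −), which makes ground truth exact and
avoids an aligner dependency.  The same seed yields byte-identical output.

**What the generator does not model** — and hence what passing tests do not
show about real data: alignment artifacts and splice-site errors, indel
errors in tails (real CCS tails have them at low rates), 3′-end
microheterogeneity beyond ±2 nt, polyadenylation-signal sequence context,
transcription during ZGA, multi-isoform structures beyond two PAS, barcode
demultiplexing errors, and realistic base-caller error profiles.

## Verification design

Classification and PAS calling are checked against independently coded
brute-force re-implementations on thousands of random inputs; run/N-length
statistics against an exhaustive all-substrings oracle; parameter recovery
(PDI fraction, uridylated fraction, per-gene geometric-mean median) on a
200-gene × ~100-read simulation against the generator's parameters within
binomial/lognormal sampling tolerance; DE calibration on 2,000 null genes.
These problem sizes keep the whole suite in the tens of seconds while the
binomial standard errors (~0.004 on a 0.6 proportion at ~18,000 reads) are
far inside the asserted tolerances.

## Known limitations

- The greedy caller resolves sites to ±1 nt only when the surrounding
  ±(window+2) nt are free of unrelated read-end mass; a proximal site
  embedded in the degradation field of a longer isoform can be called 1–2
  nt off its true position (observed in ~1% of high-support sites at the
  1C regime).
- Self-called catalogs on high-PDI samples contain spurious sites inside
  degraded regions and bias PDI proportions downward by a few percent;
  use a reference catalog (see above).
- `HIGH_TCG` reads are dropped, never rescued; quality-aware tail
  correction is out of scope.
- The transition-score and proportion thresholds (12; 0.1) are taken as
  fixed protocol constants, not re-estimated from data.
- The toy overlap gene assigner resolves no ambiguous overlaps (returns
  none); real analyses should supply a featureCounts-style table.
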