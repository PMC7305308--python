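# Methods

## The assembly model

`cdr3kit` treats CDR3 recovery as anchored pattern matching rather than
alignment. The conserved residues that delimit the CDR3 — the last
cysteine of every functional V segment, the first phenylalanine (IGK/IGL)
or tryptophan (IGH) of every J segment — are located once in the germline
reference; each V/J amino-acid sequence is split into its pre-anchor and
post-anchor substrings (V_x/V_y, J_x/J_y, anchor excluded). Reads are
translated in all six frames (RNA-Seq libraries are assumed unstranded;
duplicate detections collapse at aggregation), scanned for C…F/W spans of
4–30 aa containing no stop codon, and a span is admitted when both ends
carry germline evidence at Levenshtein distance ≤ 1.

**Match windows.** Evidence for the V side of a span starting at read
position x is accepted through either of two windows, whichever matches
better:

* *outer flank*: the read prefix r[0, x) against the equal-length suffix
  of V_x, requiring the prefix to be longer than four residues;
* *anchored window*: the read around the anchor against
  (suffix of V_x) + C + (prefix of V_y), requiring more than four matched
  germline residues in total (anchor excluded).

The J side is symmetric with J_x inside the span and J_y after it. The
anchored window exists because the outer-flank rule alone bounds the
recoverable CDR3 at read_length − 30 nt: a junction of typical length
(~55–70 nt here) would then be unrecoverable from 75 bp reads, while the
interior margins of the CDR3 adjacent to each anchor are themselves
germline-templated and carry the same information. Both flanking
substrings of each anchor are defined by the anchor-split for exactly
this reason. One documented asymmetry: the read suffix after the F/W is
compared against the *post*-anchor string J_y, since the residues before
the F/W belong to the CDR3 (they are covered by the J_x part of the
anchored window); comparing the suffix against the pre-anchor region
would cross the anchor geometrically.

Per read, at most one span survives: the largest total matched context
wins, ties broken by lexicographically smallest CDR3. All equally-best
(minimum-distance) V genes and J genes are reported.

**Stage 2.** Reads with only one-sided evidence (a C anchored to a V but
no terminating F/W, or vice versa) are candidates for merging: V-side and
J-side reads sharing an exact suffix/prefix nucleotide overlap of ≥ 15 nt
are concatenated (greedy, longest overlap first, ties by read id, each
read used once) and re-scanned. Exactness is deliberate — allowing
mismatches in the overlap invites chimeric V/J fusions from unrelated
reads. Stage 2 defaults to on only when reads are ≤ 50 bp; at longer read
lengths single reads contain whole junctions and merging mostly adds
false positives (`--forceOverlap` / `--noOverlap` override).

**Read extraction.** Before any scanning, reads are screened for a shared
15-mer with the germline V/J nucleotide sequences (both strands). Any
read overlapping a V or J gene by ≥ 15 error-free nucleotides passes; on
transcriptome-like decoys the pass rate is the random collision rate
(~0.1% for 75 bp reads against this fixture). The screen is the
candidate-read extraction step and also what admits reads into stage-2
consideration. A quality filter (mean base quality ≥ Q20 where qualities
exist; dinucleotide Shannon entropy ≥ 1.0 bits as a cheap DUST-like
low-complexity proxy; optional exact-31-mer rRNA exclusion, off by
default since no canonical database is bundled) runs on the survivors —
the two per-read predicates commute, so ordering is a pure speed choice.

## Error correction

Distinct CDR3 amino-acid sequences within a chain form a complete graph:
node weight = supporting read count, edge affinity = 1/Levenshtein
(identical sequences have already been aggregated, so the distance is
never zero). CAST clustering repeatedly opens a partition at the
unassigned node with maximal count-weighted affinity sum (in a complete
graph plain degree is constant; the count-weighted sum is the only
discriminating notion of "max degree"), then alternately adds every
unassigned node whose count-weighted mean affinity to the partition is
≥ τ and removes every member whose mean affinity to the rest falls
below τ, until the member set stops changing. The add/remove dynamics can
enter a short cycle at the threshold boundary; a repeated-state check
closes the partition there, with a hard cap of 100 passes as a final
guard. Heavy and light chains are clustered separately — they are
distinct repertoires throughout.

The clonotype reported for a partition is the count-weighted consensus:
the length class with the largest total count is selected (ties → the
shorter length), then a per-position count-weighted majority is taken
within that class (ties → alphabetical). V/J assignments are the
weighted-majority gene sets across members; the nucleotide witness is the
most frequent core of the best-supported member, and the IGH D gene is
the one sharing the longest exact substring (≥ 5 nt; shorter matches are
noise against 10–30 nt D genes) with the witness interior, anchors
excluded, ties alphabetical.

τ defaults to 0.25: sequences within edit distance 4 of a cluster's mean
can be absorbed, which captures one- and two-error satellites of an
abundant parent while leaving genuinely distinct clonotypes (pairwise
distances ≫ 4 for random junctions) apart. Values below ~0.1 start
collapsing bona fide related-but-distinct clones; `--cast-threshold`
exposes the knob and `--no-cast` disables correction entirely.

## The simulator

The generator produces what the assembler is meant to find, plus ground
truth for scoring.

* **Synthetic germline fixture.** A miniature reference with the anchor
  anatomy of real Ig genes: per chain, V segments of ~94 aa ending in
  (last) C plus a short templated tail ("CAK"-like for IGH, longer V-coded
  CDR3 starts for the light chains), J segments with 2–4 templated
  residues before the (first) F/W and a framework-4 tail after it, and six
  IGH D genes of 11–21 nt. Frameworks are random but fixed by seed, so
  the whole test suite runs with zero downloads. Loaders also accept real
  IMGT files (gap dots stripped, pipe-delimited headers parsed,
  pseudogenes with stops before the anchor excluded).
* **Transcripts.** Uniform V(D)J choice; a total non-templated insertion
  length drawn per transcript from a truncated rounded Gaussian
  (mean 15 nt, sd 4 nt) and split binomially between the V–D and D–J
  junctions (single junction for light chains). The mean is interpreted
  as the *total* inserted material: per-junction means of 15 nt would
  push IGH CDR3s to ~23–24 aa, longer than observed repertoires, whereas
  the total reading yields ~18 aa — within the long-normal range.
  Out-of-frame draws and draws whose CDR3 contains a stop are rejected
  and redrawn (guarded against pathological rejection rates). Clone
  frequencies follow rank^(−1) (Zipf; exponent configurable, 0 = uniform).
* **Reads.** Paired-end; fragment (insert) lengths Gaussian 300 ± 50 nt,
  clipped to [read length, transcript length] — the standard Illumina
  library geometry; starts uniform; R2 reverse-complemented.
  Per-transcript fragment count = round(c · L / (2l) · w), where w is the
  clone weight (n × frequency, mean 1), so *coverage c is the expected
  per-base depth from all mates at unit clone weight*. Errors are i.i.d.
  substitutions (default 0.1%/base, matching Illumina's dominant error
  mode; indels are not modelled). All randomness derives from the seed;
  identical seeds give byte-identical FASTQ and manifests.
* **Mixtures.** Receptor reads interleaved with ratio× decoy reads drawn
  from either a user transcriptome FASTA or the built-in generator
  (random transcripts, 42% GC, 500–3000 nt), shuffled deterministically.
  The truth manifest records each receptor read's transcript, true CDR3
  and whether its interval overlaps the non-templated junction region.

**What the simulator does not emulate** — and therefore what passing
tests do not show about real data: somatic hypermutation (germline V
matching in heavily mutated clones is harder than distance ≤ 1), allelic
variants and the high mutual similarity of real IMGT gene families
(random frameworks make V/J *assignment* artificially easy; detection is
unaffected), exonucleolytic trimming of segment ends at the junction
(which erodes the templated margins the anchored window uses — any
anchor-based caller faces the same erosion), position-dependent quality
profiles, indel sequencing errors, and genomic decoys such as unspliced
Ig loci. Scoring against this generator measures the assembly machinery,
not robustness to every biological nuisance.

## Numerical and design choices

* Coordinates are 0-based half-open internally; only logs are 1-based.
* Entropy is base 2 everywhere: a spleen-like repertoire of ~1000
  equifrequent clonotypes has α ≈ 10 bits; natural-log entropy would be
  incompatible with α values above ln(n).
* β-diversity is computed on amino-acid clonotype sets (the clonotype
  definition is the CDR3 amino-acid sequence); samples with fewer than 10
  clonotypes are excluded from pairwise comparisons.
* Read pairs are treated as independent single-end reads; the assembly is
  strictly per-read and mate-aware logic would only matter for a
  fragment-level consensus this package does not attempt.
* Determinism: every tie in span selection, stage-2 pairing, CAST seeding
  and consensus has a documented deterministic break; identical inputs
  and seeds are byte-identical end to end.
* Degenerate inputs: empty read sets yield an empty repertoire (warning,
  not an error); germline segments lacking an anchor or with a stop
  before it are excluded with a warning; an error rate of 0.5 still
  produces legal FASTQ.
* Problem sizes: the validation suite and the acceptance script use 200
  simulated transcripts per grid cell over read lengths {50, 75, 100} ×
  coverages {8, 16, 32} × 3 seeds, and a 1:100 decoy mixture for the
  extraction check — large enough that the binomial noise on a recall or
  precision estimate is ~2–3 points, small enough to run in minutes on
  one CPU. Unit and property tests use 5–50 transcripts.

## Known limitations

T-cell receptors, isotype (constant-gene) calling, paired heavy/light
inference, nucleotide-level clustering and hypermutation lineage trees
are out of scope. Stage-1 sensitivity at 75 bp is intrinsically limited
for long IGH junctions (the span plus minimal context must fit in one
read); stage 2 recovers part of this at 50 bp but is disabled by default
at 75–100 bp because its precision cost outweighs the recall gain there.
The IMGT loader is version-agnostic and does not resolve allele-level
nomenclature.
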