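# Methods

This note documents the models, rules and numerical choices behind each
stage of the pipeline, what the synthetic-data generator does and does not
emulate, and the design decisions taken where several reasonable options
existed.

## Coordinate and table conventions

All sequence coordinates are 1-based inclusive, end to end; conversions to
0-based happen only inside alignment internals.  The packaged family
census uses two conventions worth naming explicitly:

- **Linker length** is `HR-A/B start − DBD end` (no −1).  This is the only
  reading that reproduces the printed linker column on the rows where the
  census is internally consistent (e.g. 163 − 134 = 29).
- **Exon coordinates** in the structure census are transcript-relative
  (exon 2 starts exactly one past exon 1's end) with intron lengths printed
  separately; `tables.gene_models_from_structure_table(space="genomic")`
  shifts downstream exons by the intron lengths to recover locus-relative
  coordinates.  Both forms are available.

Cross-table arithmetic that fails (printed linker vs coordinates for six
genes; stated DBD lengths vs coordinates for four; implied protein length
vs census length for three) is emitted by `tables.build_consistency_report`
and asserted in tests as *discrepancies* — the package never "fixes" a
published number.

## Domain detection

**DBD.**  Detection scans a position-weight model (PWM) over the query.
The packaged profile is synthetic: a 94-position PWM built
deterministically from the canonical secondary-structure layout of the Hsf
DBD (three helices, four strands, connecting loops), with the consensus
residue at probability 0.70 and same-state alternatives sharing 0.29.  It
carries no biological alignment data, which keeps the package free of
accession/licensing dependencies; users with a real alignment can supply
their own profile.  Windows are scored in log-odds against a uniform
background; terminal truncations down to 83 positions are admitted so
proteins that start or end mid-domain (the shortest census variant is 83
residues) are still annotated.  The score threshold is calibrated per
query: best-window scores of 100 composition-preserving shuffles are fit
with a Gumbel distribution (method of moments) and the 0.999 quantile is
the cutoff.  An empirical percentile of the shuffle maxima would sit at the
sample maximum and be exceeded by fresh shuffles far more often than 0.1%;
the extreme-value fit controls the false-positive rate beyond the number of
shuffles drawn.

**HR-A/B.**  A heptad block is any position i with hydrophobic residues
(L/I/V/M/F) at i, i+7 and i+14.  HR-A is the first block C-terminal of the
DBD; HR-B the first block starting at least 15 residues later.  The raw
insertion (residues strictly between the two 15-residue cores) is snapped
to the nearest class signature {0, 7, 21} when within ±2; the raw value is
always retained, and unsnappable insertions leave the protein explicitly
unclassified rather than forced into a class.

**NLS / NES / AHA.**  NLS: maximal runs of ≥3 K/R residues tolerating one
single-residue interruption, C-terminal of the DBD.  NES: the generalized
leucine-rich pattern Φ-x(1,3)-Φ-x(1,3)-Φ-x-Φ (Φ ∈ L/I/V/M/F) restricted to
the C-terminal 30% of the protein; exact matches to the class-A motif
LTEQMGLL and the class-B motif L[GR]LNLM are flagged canonical.  AHA:
12-residue windows C-terminal of HR-B scoring ≥0.6 on the fraction of
W/F/Y + L/I/V + E/D residues, requiring at least one aromatic and one
acidic residue; overlapping windows merge.  Localization prediction is the
obvious rule: NLS without NES → nucleus; NLS and NES → nucleocytoplasmic
shuttling.  A protein with no NLS at all falls outside the rule set (every
census member has one); the call defaults to shuttling with a
low-confidence flag rather than failing.

## Mining

The homology search translates each pool sequence in six frames and aligns
every reference protein locally (BLOSUM62, gap open 11 / extend 1, via
Biopython's PairwiseAligner).  Similarity is the BLAST-"Positives"
convention: positive-scoring columns over alignment columns (gap columns in
the denominator).  Significance uses the Karlin–Altschul expectation
`E = K·m·n·e^(−λS)` with the gapped BLOSUM62 constants λ = 0.267,
K = 0.041, m the reference length and n = 2·(pool-entry length) as the
six-frame amino-acid search space; the default cutoff 1e-4 treats P ≈ E at
that magnitude.  Defaults: similarity ≥ 0.60, E ≤ 1e-4.

Assembly is greedy longest-overlap-first over both orientations with
Hamming-identity overlaps (defaults: overlap ≥ 40 nt at ≥ 0.95 identity),
containment absorbed, ties broken on lexicographic contig ids so assembly
is deterministic.  This is a deliberate choice for small curated pools
(tens to hundreds of reads) where determinism and inspectability matter
more than scalability; there is no consensus polishing, so high error
rates degrade contigs (see limitations).  Full-length validation accepts a
contig only when its best ORF (longest stop-free stretch over six frames)
matches a reference below the E-value cutoff *and* carries both a
detectable DBD and an HR-A/B region.

## Duplications and gene structure

The 80/80 rule uses an end-gap-free global nucleotide alignment (match 2,
mismatch −3, gap open 5 / extend 2): coverage = both-residue columns over
the longer gene's length; similarity = identical columns over aligned
columns (the published rule does not define "similarity"; identity over
the aligned region is the declared reading).  A passing pair is *tandem*
when both genes share a chromosome with at most 5 intervening genes
(counted in a genome-wide census when supplied, otherwise among the family
loci; without any census, a 50 kb start-distance threshold stands in), and
*segmental* otherwise.

Spliced alignment chains exact anchor matches (20-mers) of the CDS along
the genomic sequence, requiring introns to start GT and end AG, with
bounded backtracking at donor sites (the maximal exact extension can
overrun a donor whose first bases coincide with the next exon).  Both
strands are tried; when no GT-AG-consistent chain exists the best
unconstrained chain is returned flagged `gtag_consistent=False`, and a CDS
that cannot be placed at all raises a structure-not-found error.  The
implementation is exact-match based: it resolves planted structures
perfectly at zero sequence divergence, which is the tested regime; truly
divergent CDS/genome pairs would need an alignment-based (mismatch
tolerant) exon chainer, which is out of scope here.

Implied protein length from a gene model is `(Σ exon lengths)/3 − 1`
(terminal stop removed); `check_length_consistency` reports pass/fail plus
the implied value and never rounds a failure away.

## Molecular evolution

Distances: p-distance with pairwise deletion (columns gapped in either
member of the pair are dropped; "complete" deletion over the whole
alignment is also available), then Poisson correction `d = −ln(1 − p)`.
p ≥ 1 is undefined under the correction; such pairs are capped at
−ln(0.001) and reported, never silently clamped.

Neighbor joining is the standard Saitou–Nei Q-criterion algorithm with two
determinism guarantees: ties in Q resolve to the lexicographically lowest
pair of cluster labels (a cluster is labeled by its smallest leaf), and
negative branch lengths are clamped to zero with a flag.  Bootstrap
support resamples alignment columns with replacement, rebuilds the NJ tree
and counts bipartitions of the full-data tree.  The implementation is
cross-checked in the test suite against scikit-bio's NJ and against
exhaustive topology enumeration with least-squares branch fitting.

Nei–Gojobori counting: per-codon synonymous site fractions (changes to
stop codons count as non-synonymous at the site level) averaged over both
sequences; observed differences classified by averaging over all shortest
mutational pathways, excluding pathways that cross a stop codon (if every
pathway crosses one — possible only in degenerate codon pairs — the
average falls back to all pathways).  Codons containing gaps or ambiguity
codes are skipped.  Pooled mutation frequencies divide total, synonymous
and non-synonymous differences by the same compared-site denominator, so
`syn + nonsyn = total` holds exactly; this shared-denominator convention is
declared in the output.

## Expression

Replicate Cts are averaged arithmetically (the standard comparative-CT
practice); relative expression is `2^−(Ct_target − Ct_reference)` with the
SD propagated from replicate SDs in quadrature via the delta method, and
fold-change is `2^−ΔΔCT` against the untreated control.  Response patterns
over (1 h heat, 2 h recovery, 4 h recovery) use declared thresholds
up = 2.0 and down = 0.5 (CLI-overridable, echoed in output):
immediate_up if fold(1h) ≥ 2; late_up if fold(1h) < 2 with a monotone rise
to ≥ 2 by 4 h; inhibited if fold(1h) ≤ 0.5 without such a rise; unchanged
otherwise.  The genotype comparison flags a gene at a developmental stage
when the WT/mutant expression ratio is ≥ 2 or ≤ 0.5.  No
amplification-efficiency correction is applied and no statistical test is
run beyond the ratio thresholds.

## The synthetic-data generator

The generator is the package's test bed: it emulates the statistical and
structural properties each stage assumes and records the generating truth.

- **Proteins**: leader (10–30 aa), DBD sampled from the packaged PWM,
  linker drawn from the class's census range (A: 12–37, B: 16–77,
  C: 10–29, in the `HR-A/B start − DBD end` convention), two planted
  heptad blocks separated by exactly 21/0/7 residues, an NLS template, and
  for class A an AHA window (9 of 12 residues from W/F/Y/L/I/V/E/D with
  forced aromatic and acidic members) plus the canonical NES.  Subclass
  identity is a shared DBD base sequence (per-subclass, derived from a
  stable hash) mutated per protein at 5% — this is what nearest-exemplar
  subclassing recovers.
- **Filler is low-complexity by design** (A/G/S/T/N/Q/P/H/E/D only: no
  K/R, no hydrophobics, no aromatics), so the planted motif set is exactly
  the detectable motif set and recovery rates are attributable.  Real
  proteins have hydrophobic, basic and aromatic residues everywhere, so
  passing tests demonstrate correctness of the rules, not real-data motif
  specificity; on real sequences the NLS/NES/AHA scanners will produce
  additional candidate hits that need curation.
- **Genomes**: CDS by uniform-synonymous reverse translation, 1 or 2
  GT..AG introns (95:5 by default, mirroring the census histogram 38:2),
  genes embedded on both strands in GC-0.35 background (plant-like,
  configurable) with 200–1000 nt intergenic gaps.  Duplicates are mutated
  prefix copies covering the requested fraction of the source at the
  requested identity, always placed inter-chromosomally; mutation placement
  is uniform, the simplest model satisfying the 80/80 detector's
  assumptions.  The tandem cluster is a block of near-identical copies at
  adjacent ranks on one chromosome.
- **ESTs**: fixed-length substrings with iid substitution errors, both
  strands; the first two reads anchor the termini so sufficient coverage
  always tiles the source (uniform sampling alone leaves terminal gaps with
  noticeable probability, which would conflate coverage statistics with
  assembler behavior).  No indel errors or quality values in v1.
- **Ortholog pairs** differ by exactly the requested number of synonymous
  and non-synonymous single-nucleotide changes, one per codon, verified
  against the standard codon table at generation time — which is why
  pathway counting must recover them exactly.
- **Ct tables**: reference gene constant at Ct 18 up to noise, target
  baselines uniform in [22, 28], planted fold trajectories per pattern
  (defaults: immediate_up 400/50/5, late_up 0.4/1.2/4, inhibited
  0.3/0.35/0.5), Gaussian replicate noise on the Ct scale.

Same seed ⇒ byte-identical outputs throughout (single `numpy` Generator
threaded through each routine).

## Problem sizes

The shipped analyses and checks run at desk scale by choice: families of
4–11 genes across 2–4 chromosomes, CDS of ~0.7–1 kb, 100-gene expression
panels, bootstrap at 50–200 replicates (the CLI default remains 1000), and
recovery experiments over tens of seeds.  These sizes exercise every code
path; all statistics scale to larger inputs linearly in pairs or columns.

## Known limitations

- The DBD profile is synthetic; absolute DBD scores are not comparable to
  scores from a biologically derived profile, though the calibration
  procedure is profile-agnostic.
- The heptad detector takes the first two blocks after the DBD; proteins
  with degenerate or extra upstream hydrophobic periodicity could shift
  the HR-A anchor.
- The assembler has no consensus polishing; it is intended for small,
  low-error pools.
- The spliced aligner requires exact anchor matches (see above).
- Subclass assignment is nearest-exemplar, a declared stand-in for clade
  membership in a full phylogeny; the evolution module's tree is available
  for cross-checking.
- pI uses a single Bjellqvist side-chain/terminal pKa set packaged as
  data; tools applying residue-context-dependent terminal pKas will differ
  in the second decimal.
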