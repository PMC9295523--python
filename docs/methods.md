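# Methods

This note documents the models, rules and numerical choices behind
`pprscout`, and what the synthetic benchmarks do and do not demonstrate.

## ORF model

ORFs are the maximal stop-to-stop codon runs in each of the six reading
frames. A run bounded upstream by a stop codon is trimmed to its first ATG
and labeled `complete` when a downstream stop exists (`3'partial`
otherwise); a run starting at the transcript edge is reported whole —
`complete`/`3'partial` when it begins with ATG, else `5'partial` or
`internal`. This is a deliberately minimal coding-region model: no Markov
coding score, no splice awareness. The default retention threshold is 31
amino acids. Coordinates are 0-based half-open on the forward strand
internally and 1-based inclusive in all reports.

Split ORFs (frameshift artifacts of de novo assembly) may be joined when
they lie on the same strand, within 90 nt (about one PPR motif — the
"structural continuity" window is not quantified in the source tooling, so
it is exposed as `max_join_gap`), and their concatenated motif arrays keep
C-terminal motifs terminal. The bridge is `ceil(gap/3)` `X` residues. Joined
products are hypothetical reconstructions: they are flagged and excluded
from final tallies. Only adjacent pairs join; no transitive chains.

## Motif filtering and array resolution

Hit scores are profile bit scores. Retention is strict: score > 0 for most
motif types, > 10 for SS, > 30 for DYW; an E-value cutoff of ≤ 1e-10 applies
only when the input table carries E-values, because hit-table producers
differ. Overlap resolution is greedy by descending score (ties: leftmost
start, then catalog order) rather than optimal weighted interval
scheduling — it is deterministic, O(n log n), and mirrors first-pass
annotation tools; the exact maximum-weight oracle is kept in the test suite
and greedy output is verified against it on instance families where greedy
is provably optimal (coincident-interval clusters).

## Classification rules

An array is discarded when it has a single non-DYW motif; when its sum
score is ≤ 40 bits (strict); when adjacent motifs are separated by more
than 50 aa (the "classic array" continuity window — about 1.4 motif
lengths of linker drift, configurable); or when it carries a truncated
E+ domain without a PG box. A standalone single DYW motif survives only
when the domain grades `full`.

Subfamily P requires every motif to be canonical P (an auxiliary SMR
domain is representable as an annotation attribute, not a motif type).
Any P1/L1/S1-family variant or E/DYW motif places the protein in PLS.
Class follows the C-terminal composition: `full` DYW domain → DYW;
`truncated_with_PG` → E+; else E2 > E1 > PLS by terminal motif content.
Classification is a pure function of (array, DYW grade).

## DYW domain model

The ~136-aa DYW domain is modeled as three conserved regions — PG box
(24 aa), active site (32 aa), C-terminal (25 aa) — each a position weight
matrix built by count-and-normalize with pseudocount
(count + c)/(n + 20c), default c = 0.5, over a uniform 1/20 background
(dataset frequencies can be supplied). Window scores are
Σ log2(P_j(a)/bg(a)) bits; p-values are exact tail probabilities of the
null score distribution computed by dynamic programming over integer
scores at scale 1000 (the FIMO construction), memoized per matrix.
Non-standard residues score 0 (background odds) with a logged warning.

Grading scans the candidate domain region — the stretch from the last
non-domain motif to the C-terminus — at p ≤ 1e-5: `full` requires all
three regions in positional order (PG < active < C-terminal; the
literature offsets ~1/68/112 are kept as hints only, because published
coordinate spans for these regions are internally inconsistent),
`truncated_with_PG` requires the PG box, else `absent`. Only sequences
whose arrays carry E/DYW-type motifs are scanned, matching the original
workflow in which domain analysis was applied to the DYW/E+ candidates.

## Ortholog selection and localization

Per query the highest bit score wins (ties: lowest E-value, then
lexicographic subject id); a query is dropped when its best hit — not its
best above-threshold hit — falls below 50% identity (non-strict boundary).
Localization: agreeing targeting predictors decide; a single confident
predictor is accepted as consensus (logged); otherwise the ortholog title
is scanned case-insensitively for "chloroplast" (substring, so
"chloroplastic" matches); else `unknown`.

## The PPR code and target search

Code-bearing motifs are the P- and S-type motifs (P, P1, P2, S1, S2, SS);
L-type and E/DYW motifs do not contact RNA and contribute no position
(configurable per run). Each motif contributes the residues at its 5th
and last positions; the packaged code table maps the canonical published
two-residue combinations to nucleotide sets, and unknown pairs degrade to
the full set [ACGU] rather than failing. Motif i binds nucleotide i,
5'→3', with no terminal offset — forced by the published pattern/target
pairs, whose lengths are equal in every row.

Patterns render in the published dialect (singleton → bare letter, subset
→ bracket group, full set → `[ACGU]`); built patterns order groups
A<C<G<U, while parsed patterns preserve their source group order so
parse/render round-trips are text-identical. The search covers annotated
gene regions only, sense strand only, reporting every ungapped matching
window with the feature type at the match midpoint (intron outranks CDS
outranks exon when features abut). Genes duplicated in the inverted
repeats are searched once and their hits flagged. Proteins with more than
60 distinct targets are flagged promiscuous and excluded from the
headline report.

## qRT-PCR quantification

Technical replicates average at the Ct level. Multiple reference genes
aggregate as the arithmetic mean of per-gene mean Cts — equivalent to a
geometric mean of linear quantities; the aggregation rule is stated here
because common practice varies. ΔCt = Ct_target − Ct_refs per tissue,
ΔΔCt against the calibrator tissue (GL), relative expression 2^-ΔΔCt
(calibrator ≡ 1 by construction). Efficiency from a standard-curve slope
is (10^(−1/slope) − 1)×100 with the conventional 90-110% acceptance band
(inclusive, with 1e-9 numerical tolerance). ANOVA/Tukey lettering is out
of scope; outputs carry group means for external statistics.

## Synthetic data: what it emulates, what it does not

Proteins concatenate fixed per-motif-type consensus blocks (internally
seeded, independent of any external profile set) with code residues
substituted at positions 5 and 35; DYW-class proteins append the full
three-region domain at the literature spacing, E+ proteins the PG box
only, and all other classes end within ~10 residues of the last motif.
Hit scores are base values per motif type plus Normal(0, σ) noise
(default σ = 2 bits; recovery benchmarks use σ = 0). The default cohort is
200 proteins with the study-like class mix P 40%, E2 20%, PLS 15%,
DYW 15%, E+ 7%, E1 3%.

The toy plastid gene set draws ~24 genes with canonical names, uniform
base composition, introns at probability 0.3 (forced for the genes whose
published targets lie in introns), exon features for tRNA/rRNA genes, and
verbatim IR duplicates of rps12, rrn23, ycf2 and trnI-GAU. Planted target
windows are overwritten with uniform draws from the planted pattern's
position sets. Ct tables plant fold changes of 4 (AL), 2 (AM) and 0.5
(GM) against the GL calibrator with Normal noise (σ = 0.2 cycles).

Every generator is a pure function of (spec, seed); fixtures regenerate
byte-identically. The generator does **not** emulate real PPR sequence
homology, codon usage, assembly artifacts, composition bias, or profile
alignment uncertainty — passing recovery benchmarks demonstrates the
correctness of the filtering/classification/search logic, not detector
sensitivity on real transcriptomes, where profile quality dominates.

## Problem sizes and tolerances

Benchmarks run at 200 synthetic proteins for classification recovery,
genes ≤ 5 kb for exhaustive search cross-checks, widths ≤ 3 for exact
p-value enumeration (widths ≤ 32 against Monte-Carlo within 3 SE), 100
replicate Ct tables for fold-change recovery, and 500
composition-preserving shuffles per published target for negative
controls — sizes at which the independent oracles are exact or their
Monte-Carlo error is well below the tested effects. Shuffle controls are
compared against the exact permutation (composition-conditional) match
probability, not the i.i.d. uniform rate, since shuffling preserves
composition.

## Known limitations

- The ORF model will differ from Markov-model coding predictors on
  transcripts with long UTR-frame runs; completeness labels are
  structural, not probabilistic.
- Greedy array resolution can in principle select a lower-total-score
  array than the optimal schedule when a long strong hit spans several
  shorter ones; in PPR hit tables this is rare because motif hits are
  near-uniform in length.
- The packaged code table is deterministic; probabilistic code weights
  (per-nucleotide affinities) are not modeled, and unknown residue pairs
  widen to full degeneracy, which inflates target counts for proteins
  with many non-canonical motifs.
- Intergenic and antisense plastid sequence is not searched.
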