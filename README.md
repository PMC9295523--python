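# pprscout

Discovery, classification and plastid RNA-target prediction for
**pentatricopeptide repeat (PPR) proteins** from transcriptome data.

PPR proteins are nucleus-encoded RNA-binding proteins built from tandem
arrays of a degenerate ~35-amino-acid helical motif; each motif contacts one
nucleotide of a single-stranded RNA. They are central post-transcriptional
regulators of chloroplast and mitochondrial gene expression, and the family
splits into the **P subfamily** (canonical P motifs only) and the **PLS
subfamily** (P1-L1-S1 triad variants), the latter subdivided by C-terminal
composition into the **PLS, E1, E2, E+ and DYW** classes. The DYW class ends
in a cytidine-deaminase-like domain associated with C-to-U RNA editing.

`pprscout` implements the full discovery pipeline for researchers annotating
PPR complements in non-model plants:

1. **ORF extraction** — six-frame scan of transcripts (minimum 31 aa),
   completeness labeling, and motif-guided joining of frameshift-split ORFs
   with `X` spacers (joined products flagged hypothetical).
2. **Motif detection** — ingestion of profile hit tables (plain TSV or HMMER
   `domtblout`), score filters (score > 0; SS > 10; DYW > 30; optional
   E-value ≤ 1e-10), and greedy resolution into non-overlapping tandem
   arrays.
3. **Family classification** — array validity (single-motif rule, sum score
   > 40, inter-motif continuity) and subfamily/class assignment with explicit
   discard reasons.
4. **DYW analysis** — the three conserved regions of the DYW domain (PG box,
   24 aa; active site, 32 aa; C-terminal, 25 aa) as position weight matrices,
   scanned with log-odds scores whose p-values are **exact** (dynamic
   programming over integer-scaled scores, the FIMO construction; cutoff
   p ≤ 1e-5), grading each protein `full` / `truncated_with_PG` / `absent`.
5. **Ortholog localization** — best-hit selection from BLAST tables
   (identity ≥ 50%), targeting-predictor consensus with a
   "chloroplast"-keyword fallback.
6. **Target prediction** — the **PPR code**: the amino acids at each motif's
   5th and last positions map to preferred nucleotides; per-protein
   specificity vectors compile into degenerate patterns (e.g.
   `UUG[CU]CGC`) searched against the sense-strand RNAs of an annotated
   plastid gene set, with feature context (CDS/intron/exon), inverted-repeat
   (IR) deduplication, and promiscuity flagging (> 60 targets).
7. **Expression quantification** — qRT-PCR relative expression by
   2^-ΔΔCt with multi-reference normalization and efficiency-from-slope
   checks (90-110% band).

A first-class **synthetic data generator** plants motif arrays, code
residues, domain regions, genome target sites, IR duplicates and fold
changes with known ground truth, so every stage is testable offline.

## Worked example

Generate a small noise-free cohort, resolve its first protein's array,
compile its binding pattern, and search a toy plastid genome carrying one
planted site:

```python
from pprscout.motif_detection import arrays_from_hits
from pprscout.synthetic_data import SyntheticSpec, gen_ppr_cohort, gen_plastid_genome
from pprscout.target_prediction import load_code_table, predict_pattern, search_targets

spec = SyntheticSpec(seed=7, n_sequences=5, score_noise_sd=0.0)
records, truth = gen_ppr_cohort(spec)
r = records[0]
array = arrays_from_hits(r["hits"])[r["seq_id"]]
print(array.motif_string, array.sum_score)     # P-P-P-P-P-P-P-P-P-P-P 275.0
pattern = predict_pattern(array, r["aa_sequence"], load_code_table())
print(pattern.render())                        # UUCACAACAUA

genes, site = gen_plastid_genome(spec, [{"ppr_id": r["seq_id"],
                                         "pattern": pattern, "gene": "rbcL"}])
for h in search_targets(pattern, genes, r["seq_id"]):
    print(h.gene_name, h.match_start, h.feature_context, h.matched_sequence)
# rbcL 317 CDS UUCACAACAUA
```

The 11-motif P-subfamily protein yields an 11-position pattern (one
nucleotide per code-bearing motif, 5'→3'); the search recovers the planted
site in the `rbcL` CDS at the planted offset (317).

The same stages are exposed as a CLI:

```bash
pprscout synth --seed 7 -o fixtures/          # ground-truthed fixtures
pprscout orfs -i transcripts.fa -o orfs/
pprscout motifs --hits hits.tsv -o arrays.tsv
pprscout classify --fasta orfs/peptides.fa --hits hits.tsv -o annotations.tsv
pprscout targets --genome cp.fa --gff cp.gff3 --patterns patterns.tsv -o targets.tsv
pprscout run -o report/                       # end-to-end synthetic run
```

The package also ships the published degenerate patterns and predicted
plastid targets for the twelve chloroplastic *Agave angustifolia* PPR
proteins (`pprscout.target_prediction.load_reference_predictions()`),
used as a verification corpus: all 23 printed (protein, target) pairs
match their patterns, and the 19 distinct target genes classify into
9 photosynthesis-related genes, 4 ribosomal proteins, 2 tRNAs, 1 rRNA,
1 PEP subunit and 2 genes of unknown function.

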