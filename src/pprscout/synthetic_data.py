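"""Ground-truthed synthetic fixtures for every pipeline stage.

Generates PPR protein cohorts with planted motif arrays, code residues and
per-class C-terminal domains; matching motif hit tables with tunable score
noise; a toy plastid genome (CDS/intron/exon features, inverted-repeat gene
duplicates) with planted target sites realized from planted patterns; and
qRT-PCR Ct tables with planted fold changes.  Every generator is a pure
function of its spec and seed: regeneration is byte-identical.

The synthetic proteins concatenate per-motif-type consensus blocks (fixed,
internally seeded, decoupled from any external profile set); they emulate
array structure and code readout, not real PPR sequence homology.
"""

from __future__ import annotations

import functools
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dyw_analysis import AA_ALPHABET, REGION_WIDTHS, build_pwm
from .motif_detection import MotifHit
from .target_prediction import (
    CodeTable,
    DegeneratePattern,
    PlastidGene,
    load_code_table,
)

NUCLEOTIDES = "ACGU"

#: Planted class proportions (study-like mix: P dominates, E1 is rare).
DEFAULT_CLASS_MIX = {"P": 0.40, "E2": 0.20, "PLS": 0.15, "DYW": 0.15, "E+": 0.07, "E1": 0.03}

#: Base hit scores in bits per motif type.
BASE_SCORES = {
    "P": 25.0, "P1": 25.0, "P2": 25.0, "L1": 20.0, "L2": 20.0,
    "S1": 20.0, "S2": 20.0, "SS": 20.0, "E1": 15.0, "E2": 15.0,
    "DYW": 60.0, "E+": 15.0,
}

_CONSENSUS_SEED = 9173  # fixed: consensus blocks never depend on the user seed


def _fixed_rng(*key):
    return np.random.default_rng(np.random.SeedSequence(list(key)))


def _random_aa(rng, n):
    return "".join(rng.choice(list(AA_ALPHABET), size=n))


def _make_consensus():
    rng = _fixed_rng(_CONSENSUS_SEED)
    motifs = {}
    for mt in ("P", "P1", "L1", "S1", "P2", "L2", "S2", "SS", "E1", "E2"):
        motifs[mt] = _random_aa(rng, 35)
    regions = {}
    for region, width in REGION_WIDTHS.items():
        regions[region] = _random_aa(rng, width)
    # give the C-terminal region its eponymous last three residues
    regions["C_terminal"] = regions["C_terminal"][:-3] + "DYW"
    return motifs, regions


MOTIF_CONSENSUS, REGION_CONSENSUS = _make_consensus()


def gen_region_blocks(n: int = 40, mutation_rate: float = 0.08, seed: int = 777) -> dict:
    """Synthetic alignment blocks for the three DYW-domain regions."""
    rng = _fixed_rng(seed, 1)
    blocks = {}
    for region, consensus in REGION_CONSENSUS.items():
        seqs = []
        for _ in range(n):
            chars = list(consensus)
            for j in range(len(chars)):
                if rng.random() < mutation_rate:
                    chars[j] = AA_ALPHABET[rng.integers(20)]
            seqs.append("".join(chars))
        blocks[region] = seqs
    return blocks


@functools.lru_cache(maxsize=4)
def default_region_pwms(pseudocount: float = 0.5) -> dict:
    """PWMs for the three DYW regions built from the synthetic blocks."""
    from .dyw_analysis import REGION_OFFSETS

    blocks = gen_region_blocks()
    return {
        region: build_pwm(
            block, pseudocount=pseudocount, region=region,
            offset_hint=REGION_OFFSETS[region],
        )
        for region, block in blocks.items()
    }


@dataclass
class GenomeSpec:
    n_genes: int = 24
    intron_probability: float = 0.3
    ir_gene_names: tuple = ("rps12", "rrn23", "ycf2", "trnI-GAU")
    spacer_length: int = 100


@dataclass
class QpcrSpec:
    fold_changes: dict = field(default_factory=lambda: {"AL": 4.0, "AM": 2.0, "GM": 0.5})
    ct_noise_sd: float = 0.2
    replicates: int = 3
    target_genes: tuple = ("AaPPR1",)
    reference_genes: tuple = ("actin", "tubulin", "18S")


@dataclass
class SyntheticSpec:
    seed: int
    n_sequences: int = 200
    class_mix: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    motif_length: int = 35
    score_noise_sd: float = 2.0
    genome: GenomeSpec = field(default_factory=GenomeSpec)
    qpcr: QpcrSpec = field(default_factory=QpcrSpec)

    def __post_init__(self):
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions must sum to 1 (got {total})")


def _motif_plan(rng, class_label):
    """Ordered motif-type list for one protein of the given class."""
    if class_label == "P":
        return ["P"] * int(rng.integers(3, 13))
    triads = ["P1", "L1", "S1"] * int(rng.integers(2, 5))
    if class_label == "PLS":
        return triads
    if class_label == "E1":
        return triads + ["E1"]
    return triads + ["E1", "E2"]  # E2, E+ and DYW share the E1-E2 tail


def _inverse_code(table: CodeTable):
    inv = {}
    for nts, pairs in table.inverse().items():
        if len(nts) == 1:
            inv[next(iter(nts))] = pairs
    missing = set(NUCLEOTIDES) - set(inv)
    if missing:
        raise ValueError(f"code table lacks singleton entries for {sorted(missing)}")
    return inv


def gen_ppr_cohort(spec: SyntheticSpec, code_table: CodeTable | None = None):
    """Generate the protein cohort.

    Returns ``(records, truth)``: ``records`` is a list of dicts with
    seq_id, aa_sequence and planted MotifHits (the noisy hit table);
    ``truth`` maps seq_id to the planted class, subfamily, motif string,
    code pairs and expected nucleotide sets.
    """
    table = code_table or load_code_table()
    inv = _inverse_code(table)
    rng = _fixed_rng(spec.seed, 1)
    classes = sorted(spec.class_mix)
    probs = np.array([spec.class_mix[c] for c in classes])
    code_bearing = {"P", "P1", "P2", "S1", "S2", "SS"}
    records, truth = [], {}
    for i in range(spec.n_sequences):
        seq_id = f"synppr{i + 1:04d}"
        class_label = classes[rng.choice(len(classes), p=probs)]
        plan = _motif_plan(rng, class_label)
        nterm = _random_aa(rng, int(rng.integers(20, 51)))
        parts = [nterm]
        pos = len(nterm)
        hits, code_pairs, code_sets = [], [], []
        for mt in plan:
            block = list(MOTIF_CONSENSUS[mt])
            if mt in code_bearing:
                nt = NUCLEOTIDES[rng.integers(4)]
                pairs = inv[nt]
                a5, alast = pairs[rng.integers(len(pairs))]
                block[4] = a5
                block[-1] = alast
                code_pairs.append((a5, alast))
                code_sets.append(nt)
            block = "".join(block)
            start = pos + 1  # 1-based
            end = pos + len(block)
            score = BASE_SCORES[mt] + rng.normal(0.0, spec.score_noise_sd)
            hits.append(MotifHit(seq_id=seq_id, motif_type=mt, aa_start=start,
                                 aa_end=end, score=round(float(score), 3)))
            parts.append(block)
            pos = end
        motif_types = list(plan)
        if class_label == "DYW":
            domain = (
                REGION_CONSENSUS["PG_box"]
                + _random_aa(rng, 43)
                + REGION_CONSENSUS["active_site"]
                + _random_aa(rng, 12)
                + REGION_CONSENSUS["C_terminal"]
            )
            start = pos + 1
            end = pos + len(domain)
            score = BASE_SCORES["DYW"] + rng.normal(0.0, spec.score_noise_sd)
            hits.append(MotifHit(seq_id=seq_id, motif_type="DYW", aa_start=start,
                                 aa_end=end, score=round(float(score), 3)))
            parts.append(domain)
            pos = end
            motif_types.append("DYW")
        elif class_label == "E+":
            domain = REGION_CONSENSUS["PG_box"]
            start = pos + 1
            end = pos + len(domain)
            score = BASE_SCORES["E+"] + rng.normal(0.0, spec.score_noise_sd)
            hits.append(MotifHit(seq_id=seq_id, motif_type="E+", aa_start=start,
                                 aa_end=end, score=round(float(score), 3)))
            parts.append(domain)
            pos = end
            motif_types.append("E+")
        # short C-terminal tail: arrays run close to the protein end
        parts.append(_random_aa(rng, int(rng.integers(3, 10))))
        aa = "".join(parts)
        records.append({"seq_id": seq_id, "aa_sequence": aa, "hits": hits})
        truth[seq_id] = {
            "class": class_label,
            "subfamily": "P" if class_label == "P" else "PLS",
            "motif_string": "-".join(motif_types),
            "code_pairs": code_pairs,
            "code_nucleotides": "".join(code_sets),
        }
    return records, truth


def cohort_fasta(records) -> str:
    return "".join(f">{r['seq_id']}\n{r['aa_sequence']}\n" for r in records)


def cohort_hit_table(records) -> pd.DataFrame:
    rows = [
        {"seq_id": h.seq_id, "motif": h.motif_type, "start": h.aa_start,
         "end": h.aa_end, "score": h.score}
        for r in records
        for h in r["hits"]
    ]
    return pd.DataFrame(rows, columns=["seq_id", "motif", "start", "end", "score"])


_GENE_ROSTER = (
    ("psbA", "protein"), ("psbC", "protein"), ("psbD", "protein"),
    ("psaA", "protein"), ("psaB", "protein"), ("petA", "protein"),
    ("petN", "protein"), ("atpA", "protein"), ("atpE", "protein"),
    ("rbcL", "protein"), ("ndhG", "protein"), ("rpoC1", "protein"),
    ("rpoB", "protein"), ("matK", "protein"), ("rps12", "protein"),
    ("rps14", "protein"), ("rps16", "protein"), ("rpl33", "protein"),
    ("ycf1", "protein"), ("ycf2", "protein"), ("trnK-UUU", "tRNA"),
    ("trnI-GAU", "tRNA"), ("rrn16", "rRNA"), ("rrn23", "rRNA"),
)
#: genes generated with an intron regardless of the intron probability
_FORCED_INTRON = {"rpoC1", "rps12", "rps16", "trnK-UUU", "trnI-GAU"}


def _random_rna(rng, n):
    return "".join(rng.choice(list(NUCLEOTIDES), size=n))


def _gene_features(rng, name, gene_type, intron_probability):
    """(rna_length, features) for one gene."""
    if gene_type == "protein":
        body = "CDS"
        n1 = int(rng.integers(150, 450)) * 2
    elif gene_type == "tRNA":
        body = "exon"
        n1 = 80
    else:
        body = "exon"
        n1 = 500
    has_intron = name in _FORCED_INTRON or rng.random() < intron_probability
    if has_intron:
        e1 = n1 // 2
        ilen = int(rng.integers(120, 400))
        length = n1 + ilen
        features = (
            (body, 1, e1),
            ("intron", e1 + 1, e1 + ilen),
            (body, e1 + ilen + 1, length),
        )
    else:
        length = n1
        features = ((body, 1, n1),)
    return length, features


def gen_plastid_genome(spec: SyntheticSpec, planted: list | None = None):
    """Generate the toy plastid gene set with planted target sites.

    ``planted`` is a list of dicts with keys ``ppr_id``, ``pattern`` (text or
    :class:`DegeneratePattern`), ``gene`` and optionally ``feature`` (a
    feature type to plant inside).  Returns ``(genes, truth)`` where genes is
    a list of :class:`PlastidGene` (IR genes appear twice, the second copy
    flagged) and truth records the planted site coordinates and sequences.
    """
    g = spec.genome
    rng = _fixed_rng(spec.seed, 2)
    roster = _GENE_ROSTER[: g.n_genes]
    genes_rna = {}
    features_by_gene = {}
    for name, gtype in roster:
        length, feats = _gene_features(rng, name, gtype, g.intron_probability)
        genes_rna[name] = _random_rna(rng, length)
        features_by_gene[name] = feats
    truth = []
    for plant in planted or []:
        name = plant["gene"]
        if name not in genes_rna:
            raise ValueError(f"cannot plant in unknown gene {name!r}")
        pattern = plant["pattern"]
        if not isinstance(pattern, DegeneratePattern):
            pattern = DegeneratePattern.parse(pattern)
        feats = features_by_gene[name]
        want = plant.get("feature")
        candidates = [f for f in feats if want is None or f[0] == want]
        if not candidates:
            raise ValueError(f"gene {name!r} has no feature of type {want!r}")
        ftype, fstart, fend = candidates[int(rng.integers(len(candidates)))]
        width = len(pattern)
        if fend - fstart + 1 < width:
            raise ValueError(f"feature {ftype} of {name!r} shorter than pattern")
        start = int(rng.integers(fstart, fend - width + 2))  # 1-based
        realized = "".join(
            sorted(s)[int(rng.integers(len(s)))] for s in pattern.positions
        )
        rna = genes_rna[name]
        genes_rna[name] = rna[: start - 1] + realized + rna[start - 1 + width:]
        truth.append(
            {"ppr_id": plant["ppr_id"], "gene": name, "start": start,
             "feature": ftype, "sequence": realized}
        )
    genes = []
    for name, gtype in roster:
        gene = PlastidGene(
            gene_name=name,
            rna_sequence=genes_rna[name],
            features=features_by_gene[name],
        )
        genes.append(gene)
        if name in g.ir_gene_names:
            genes.append(
                PlastidGene(
                    gene_name=name,
                    rna_sequence=genes_rna[name],
                    features=features_by_gene[name],
                    ir_duplicate=True,
                )
            )
    return genes, truth


def genome_to_fasta_gff(genes, spec: SyntheticSpec):
    """Assemble a single genome FASTA and GFF3 from the gene set.

    Every third gene goes on the minus strand; IR duplicates carry an
    ``ir_duplicate=true`` attribute.
    """
    spacer = spec.genome.spacer_length
    rng = _fixed_rng(spec.seed, 3)
    chunks = []
    gff = ["##gff-version 3"]
    pos = 0
    comp = str.maketrans("ACGT", "TGCA")
    for k, gene in enumerate(genes):
        chunks.append(_random_rna(rng, spacer).replace("U", "T"))
        pos += spacer
        dna = gene.rna_sequence.replace("U", "T")
        strand = "-" if k % 3 == 2 else "+"
        if strand == "-":
            dna = dna.translate(comp)[::-1]
        gstart, gend = pos + 1, pos + len(dna)
        gid = f"gene{k + 1}"
        attrs = f"ID={gid};Name={gene.gene_name}"
        if gene.ir_duplicate:
            attrs += ";ir_duplicate=true"
        gff.append(
            "\t".join(["synplastome", "pprscout", "gene", str(gstart), str(gend),
                       ".", strand, ".", attrs])
        )
        L = len(gene.rna_sequence)
        for ftype, fs, fe in gene.features:
            if strand == "+":
                a, b = gstart + fs - 1, gstart + fe - 1
            else:
                a, b = gstart + (L - fe), gstart + (L - fs)
            gff.append(
                "\t".join(["synplastome", "pprscout", ftype, str(a), str(b),
                           ".", strand, ".", f"Parent={gid}"])
            )
        chunks.append(dna)
        pos = gend
    chunks.append(_random_rna(rng, spacer).replace("U", "T"))
    genome = "".join(chunks)
    fasta = ">synplastome\n" + "\n".join(
        genome[i: i + 70] for i in range(0, len(genome), 70)
    ) + "\n"
    return fasta, "\n".join(gff) + "\n"


def gen_ct_table(spec: SyntheticSpec):
    """Ct table with planted fold changes (calibrator GL at fold 1).

    ct = base - log2(fold) + Normal(0, ct_noise_sd); reference genes are
    constant across tissues up to the same noise.
    """
    q = spec.qpcr
    rng = _fixed_rng(spec.seed, 4)
    tissues = ("GL", "GM", "AL", "AM")
    rows = []
    truth = {}
    for gene in q.target_genes:
        base = float(rng.uniform(22.0, 26.0))
        folds = {t: float(q.fold_changes.get(t, 1.0)) for t in tissues}
        folds["GL"] = 1.0
        truth[gene] = folds
        for tissue in tissues:
            for rep in range(1, q.replicates + 1):
                ct = base - np.log2(folds[tissue]) + rng.normal(0.0, q.ct_noise_sd)
                rows.append({"gene": gene, "tissue": tissue, "replicate": rep,
                             "ct": round(float(ct), 4)})
    for gene in q.reference_genes:
        base = float(rng.uniform(12.0, 22.0))
        for tissue in tissues:
            for rep in range(1, q.replicates + 1):
                ct = base + rng.normal(0.0, q.ct_noise_sd)
                rows.append({"gene": gene, "tissue": tissue, "replicate": rep,
                             "ct": round(float(ct), 4)})
    return pd.DataFrame(rows, columns=["gene", "tissue", "replicate", "ct"]), truth


def gen_ortholog_tables(spec: SyntheticSpec, seq_ids, chloro_fraction: float = 0.3):
    """Best-hit and predictor tables with planted chloroplast membership.

    Returns ``(blast_rows, predictor_rows, truth_chloro_ids)``.  Half of the
    planted chloroplastic sequences are called by the predictors, half only
    via the ortholog-title keyword (exercising both code paths).
    """
    rng = _fixed_rng(spec.seed, 5)
    species = ("Asparagus officinalis", "Elaeis guineensis",
               "Phoenix dactylifera", "Dendrobium catenatum")
    blast, predictor, chloro = [], [], set()
    for sid in seq_ids:
        identity = float(rng.uniform(30.0, 95.0))
        sp = species[int(rng.integers(len(species)))]
        is_chloro = rng.random() < chloro_fraction
        title = f"pentatricopeptide repeat-containing protein, {sp}"
        if is_chloro:
            title = f"pentatricopeptide repeat-containing protein, chloroplastic"
        blast.append({
            "qseqid": sid, "sseqid": f"XP_{rng.integers(10**8):09d}",
            "pident": round(identity, 2),
            "bitscore": round(float(rng.uniform(80, 900)), 1),
            "evalue": float(10.0 ** -rng.uniform(20, 180)),
            "stitle": title, "sspecies": sp,
        })
        if is_chloro and identity >= 50.0:
            chloro.add(sid)
        if sid in chloro and rng.random() < 0.5:
            predictor.append({"query_id": sid, "predotar": "plastid",
                              "targetp": "chloroplast"})
    return blast, predictor, chloro


def gen_de_table(spec: SyntheticSpec, seq_ids, de_fraction: float = 0.2):
    """Differential-expression flag table with planted membership."""
    rng = _fixed_rng(spec.seed, 6)
    rows, de_ids = [], set()
    for sid in seq_ids:
        sig = bool(rng.random() < de_fraction)
        rows.append({
            "seq_id": sid, "comparison": "GL_vs_AL",
            "log2fc": round(float(rng.normal(0.0, 2.0)), 3),
            "significant": sig,
        })
        if sig:
            de_ids.add(sid)
    return pd.DataFrame(rows), de_ids


def fixture_digest(*texts) -> str:
    """SHA-256 over generated text artifacts (determinism checks)."""
    h = hashlib.sha256()
    for t in texts:
        h.update(t.encode())
    return h.hexdigest()


def write_fixtures(spec: SyntheticSpec, outdir):
    """Write FASTA/TSV/GFF3/CSV fixtures plus truth.json under ``outdir``."""
    import pathlib

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    records, truth_cohort = gen_ppr_cohort(spec)
    (out / "proteins.fa").write_text(cohort_fasta(records))
    cohort_hit_table(records).to_csv(out / "hits.tsv", sep="\t", index=False)
    genes, truth_sites = gen_plastid_genome(spec)
    fasta, gff = genome_to_fasta_gff(genes, spec)
    (out / "plastome.fa").write_text(fasta)
    (out / "plastome.gff3").write_text(gff)
    ct, truth_ct = gen_ct_table(spec)
    ct.to_csv(out / "ct.csv", index=False)
    truth = {
        "cohort": truth_cohort,
        "planted_sites": truth_sites,
        "fold_changes": truth_ct,
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    return out
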