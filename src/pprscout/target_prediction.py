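"""PPR-code readout, degenerate pattern compilation, and plastid target search.

Each P/S-type motif in a tandem array reads one RNA nucleotide, specified by
the amino acids at the motif's 5th and last positions (the PPR code).  The
per-motif nucleotide sets are compiled into a degenerate pattern (one
position per code-bearing motif, 5'->3') and searched against the sense-strand
RNAs of an annotated plastid gene set.  Hits carry the feature context (CDS /
intron / exon) at the match midpoint; genes duplicated in the inverted
repeats are reported once and flagged.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from importlib import resources

import pandas as pd

logger = logging.getLogger(__name__)

NUCLEOTIDES = "ACGU"
FULL_SET = frozenset(NUCLEOTIDES)

#: Motif types whose 5th/last residues contribute a pattern position.
CODE_BEARING_MOTIFS = frozenset({"P", "P1", "P2", "S1", "S2", "SS"})

PROMISCUITY_THRESHOLD = 60

_FEATURE_PRIORITY = {"intron": 0, "CDS": 1, "exon": 2, "tRNA": 3, "rRNA": 4}


class CodeTable:
    """Lookup from (aa_5th, aa_last) to a nucleotide set; total via the
    [ACGU] default for unknown pairs."""

    def __init__(self, entries: dict):
        self.entries = {
            (a.upper(), b.upper()): frozenset(v) for (a, b), v in entries.items()
        }
        for pair, nts in self.entries.items():
            if not nts or not nts <= FULL_SET:
                raise ValueError(f"bad nucleotide set for {pair}: {nts}")

    def lookup(self, pair) -> frozenset:
        a, b = pair
        if a is None or b is None:
            return FULL_SET
        return self.entries.get((str(a).upper(), str(b).upper()), FULL_SET)

    def inverse(self) -> dict:
        """nucleotide-set -> list of pairs (used by the synthetic generator)."""
        inv: dict[frozenset, list] = {}
        for pair, nts in sorted(self.entries.items()):
            inv.setdefault(nts, []).append(pair)
        return inv


def load_code_table(path=None) -> CodeTable:
    """Load the packaged PPR code table, or a user-supplied TSV with columns
    aa_5th, aa_last, nucleotides."""
    if path is None:
        source = resources.files("pprscout.data").joinpath("ppr_code.tsv")
        with resources.as_file(source) as p:
            df = pd.read_csv(p, sep="\t", comment="#")
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
    entries = {
        (str(r.aa_5th), str(r.aa_last)): frozenset(str(r.nucleotides))
        for r in df.itertuples(index=False)
    }
    return CodeTable(entries)


@dataclass(frozen=True)
class DegeneratePattern:
    """Ordered per-position nucleotide sets with a bracket-group rendering.

    Built patterns render groups in A<C<G<U order; parsed patterns keep the
    source group order so that parse/render round-trips are text-identical.
    """

    positions: tuple  # tuple of frozensets
    groups_text: tuple = ()  # per-position source text, when parsed

    def __post_init__(self):
        for s in self.positions:
            if not s or not frozenset(s) <= FULL_SET:
                raise ValueError(f"invalid position set {s!r}")

    def __len__(self):
        return len(self.positions)

    @classmethod
    def from_sets(cls, code_sets) -> "DegeneratePattern":
        return cls(positions=tuple(frozenset(s) for s in code_sets))

    @classmethod
    def parse(cls, text: str) -> "DegeneratePattern":
        positions, groups = [], []
        i = 0
        while i < len(text):
            ch = text[i]
            if ch == "[":
                j = text.index("]", i)
                group = text[i + 1: j]
                if not group or set(group) - set(NUCLEOTIDES):
                    raise ValueError(f"bad group {group!r} in pattern")
                positions.append(frozenset(group))
                groups.append(group)
                i = j + 1
            elif ch in NUCLEOTIDES:
                positions.append(frozenset(ch))
                groups.append(ch)
                i += 1
            else:
                raise ValueError(f"bad character {ch!r} in pattern at {i}")
        return cls(positions=tuple(positions), groups_text=tuple(groups))

    def render(self) -> str:
        out = []
        for k, s in enumerate(self.positions):
            if self.groups_text and set(self.groups_text[k]) == s:
                g = self.groups_text[k]
                out.append(g if len(g) == 1 else f"[{g}]")
            elif len(s) == 1:
                out.append(next(iter(s)))
            else:
                out.append("[" + "".join(n for n in NUCLEOTIDES if n in s) + "]")
        return "".join(out)

    def matches(self, window: str) -> bool:
        return len(window) == len(self.positions) and all(
            c in s for c, s in zip(window, self.positions)
        )

    def to_regex(self) -> "re.Pattern":
        parts = []
        for s in self.positions:
            chars = "".join(n for n in NUCLEOTIDES if n in s)
            parts.append(chars if len(chars) == 1 else f"[{chars}]")
        return re.compile("(?=(" + "".join(parts) + "))")


@dataclass(frozen=True)
class PlastidGene:
    """One plastid gene: sense-strand RNA with 1-based inclusive features."""

    gene_name: str
    rna_sequence: str
    features: tuple  # of (type, start, end)
    ir_duplicate: bool = False

    def __post_init__(self):
        rna = self.rna_sequence.upper().replace("T", "U")
        object.__setattr__(self, "rna_sequence", rna)
        for ftype, start, end in self.features:
            if not (1 <= start <= end <= len(rna)):
                raise ValueError(
                    f"{self.gene_name}: feature {ftype} {start}-{end} out of bounds"
                )

    def feature_at(self, position: int) -> str | None:
        covering = [
            f for f in self.features if f[1] <= position <= f[2]
        ]
        if not covering:
            return None
        covering.sort(key=lambda f: (_FEATURE_PRIORITY.get(f[0], 9), f[1]))
        return covering[0][0]


@dataclass(frozen=True)
class TargetHit:
    ppr_id: str
    gene_name: str
    feature_context: str
    match_start: int  # 1-based on the gene RNA
    matched_sequence: str
    ir_flagged: bool = False


def extract_code_residues(array, sequences: dict, code_bearing=CODE_BEARING_MOTIFS):
    """Per code-bearing motif, the residues at the 5th and last positions.

    Motifs shorter than 5 aa yield ``(None, None)``; out-of-bounds
    coordinates raise naming the motif.
    """
    seq = sequences[array.seq_id] if isinstance(sequences, dict) else sequences
    out = []
    for idx, hit in enumerate(array.hits):
        if hit.motif_type not in code_bearing:
            continue
        if hit.aa_end > len(seq) or hit.aa_start < 1:
            raise ValueError(
                f"{array.seq_id}: motif {idx} ({hit.motif_type} "
                f"{hit.aa_start}-{hit.aa_end}) outside sequence of length {len(seq)}"
            )
        if hit.aa_end - hit.aa_start + 1 < 5:
            out.append((idx, None, None))
            continue
        out.append((idx, seq[hit.aa_start + 3], seq[hit.aa_end - 1]))
    return out


def code_lookup(pair, table: CodeTable) -> frozenset:
    return table.lookup(pair)


def build_pattern(code_sets) -> DegeneratePattern:
    sets = list(code_sets)
    if not sets:
        raise ValueError("need at least one code set")
    return DegeneratePattern.from_sets(sets)


def predict_pattern(array, sequence, table: CodeTable) -> DegeneratePattern:
    """Convenience: code residues -> nucleotide sets -> pattern (5'->3',
    motif i binds nucleotide i)."""
    residues = extract_code_residues(array, {array.seq_id: sequence})
    return build_pattern([table.lookup((a, b)) for _, a, b in residues])


def search_targets(pattern: DegeneratePattern, genes, ppr_id: str = "") -> list:
    """All ungapped sense-strand windows matching the pattern.

    IR-duplicated genes (same name, ``ir_duplicate`` on the extra copy) are
    scanned once on the primary copy and the hits flagged.  Deterministic
    order: (gene_name, match_start).
    """
    by_name: dict[str, list] = {}
    for g in genes:
        by_name.setdefault(g.gene_name, []).append(g)
    rx = pattern.to_regex()
    width = len(pattern)
    hits = []
    for name in sorted(by_name):
        copies = by_name[name]
        primary = next((g for g in copies if not g.ir_duplicate), copies[0])
        ir = len(copies) > 1 or primary.ir_duplicate
        rna = primary.rna_sequence
        for m in rx.finditer(rna):
            start = m.start() + 1
            mid = start + width // 2
            context = primary.feature_at(mid) or (
                "CDS" if any(f[0] == "CDS" for f in primary.features) else "exon"
            )
            hits.append(
                TargetHit(
                    ppr_id=ppr_id,
                    gene_name=name,
                    feature_context=context,
                    match_start=start,
                    matched_sequence=m.group(1),
                    ir_flagged=ir,
                )
            )
    hits.sort(key=lambda h: (h.gene_name, h.match_start))
    return hits


def flag_promiscuous(hits_by_ppr: dict, threshold: int = PROMISCUITY_THRESHOLD) -> set:
    """Proteins with more than ``threshold`` distinct targets; these are
    excluded from the headline target report."""
    flagged = set()
    for ppr_id, hits in hits_by_ppr.items():
        distinct = {(h.gene_name, h.match_start, h.matched_sequence) for h in hits}
        if len(distinct) > threshold:
            flagged.add(ppr_id)
    return flagged


GENE_FUNCTION_CATEGORIES = (
    "photosynthesis",
    "ribosomal_protein",
    "tRNA",
    "rRNA",
    "PEP_subunit",
    "unknown_function",
    "other",
)


def classify_gene_function(gene_name: str) -> str:
    """Functional category of a plastid gene by naming convention."""
    name = gene_name.strip()
    low = name.lower()
    if low.startswith(("psa", "psb", "pet", "atp", "ndh")) or low == "rbcl":
        return "photosynthesis"
    if low.startswith(("rps", "rpl")):
        return "ribosomal_protein"
    if low.startswith("trn"):
        return "tRNA"
    if low.startswith("rrn"):
        return "rRNA"
    if low.startswith("rpo"):
        return "PEP_subunit"
    if low.startswith("ycf"):
        return "unknown_function"
    return "other"


def load_reference_predictions() -> pd.DataFrame:
    """Packaged table of published A. angustifolia chloroplastic PPR
    patterns and predicted targets (columns: ppr_id, subfamily, pattern,
    gene, feature, target_sequence, ir)."""
    source = resources.files("pprscout.data").joinpath("aappr_targets.tsv")
    with resources.as_file(source) as p:
        return pd.read_csv(p, sep="\t", comment="#")


def target_report(hits_by_ppr: dict, threshold: int = PROMISCUITY_THRESHOLD) -> pd.DataFrame:
    """Headline target table (promiscuous proteins excluded), one row per hit
    with the IR asterisk convention."""
    flagged = flag_promiscuous(hits_by_ppr, threshold)
    rows = []
    for ppr_id in sorted(hits_by_ppr):
        if ppr_id in flagged:
            continue
        for h in hits_by_ppr[ppr_id]:
            rows.append(
                {
                    "ppr_id": ppr_id,
                    "gene": h.gene_name + ("*" if h.ir_flagged else ""),
                    "feature": h.feature_context,
                    "target_sequence": f"5'-{h.matched_sequence}-3'",
                    "position": h.match_start,
                }
            )
    return pd.DataFrame(
        rows, columns=["ppr_id", "gene", "feature", "target_sequence", "position"]
    )
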