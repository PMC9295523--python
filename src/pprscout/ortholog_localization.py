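"""Best-ortholog selection and chloroplast localization inference.

Best hits are chosen per query by bit score (ties: lowest E-value, then
lexicographic subject id) from BLAST outfmt-6-style tables; queries whose
best hit falls below 50% identity are dropped (non-strict at the boundary).
Localization comes from targeting predictors when they agree, falling back
to a case-insensitive "chloroplast" keyword scan of the ortholog title.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

MIN_IDENTITY_DEFAULT = 50.0

_COMPARTMENT_ALIASES = {
    "chloroplast": "chloroplast",
    "plastid": "chloroplast",
    "cp": "chloroplast",
    "c": "chloroplast",
    "mitochondrion": "mitochondrion",
    "mitochondria": "mitochondrion",
    "mito": "mitochondrion",
    "m": "mitochondrion",
}


@dataclass(frozen=True)
class OrthologHit:
    query_id: str
    subject_id: str
    subject_title: str = ""
    identity_pct: float = 0.0
    bitscore: float = 0.0
    evalue: float = 1.0
    subject_species: str = ""

    def __post_init__(self):
        if not 0.0 <= self.identity_pct <= 100.0:
            raise ValueError("identity_pct must be in [0, 100]")


@dataclass(frozen=True)
class LocalizationCall:
    query_id: str
    call: str  # chloroplast | mitochondrion | other | unknown
    basis: str  # predictor | keyword | none

    def __post_init__(self):
        if (self.basis == "none") != (self.call == "unknown"):
            raise ValueError("basis=none iff call=unknown")


def select_best_hits(hits, min_identity: float = MIN_IDENTITY_DEFAULT) -> dict:
    """Per query: highest bitscore wins (tie: lowest evalue, then subject id);
    queries whose best hit has identity < min_identity are dropped."""
    best: dict[str, OrthologHit] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None or (-h.bitscore, h.evalue, h.subject_id) < (
            -cur.bitscore,
            cur.evalue,
            cur.subject_id,
        ):
            best[h.query_id] = h
    return {q: h for q, h in best.items() if h.identity_pct >= min_identity}


def _normalize_compartment(value) -> str | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip().lower()
    if not s or s in {"-", "none", "nan", "na", "_", "unknown"}:
        return None
    return _COMPARTMENT_ALIASES.get(s, "other")


def infer_localization(predictor_rows, best_hits: dict):
    """One :class:`LocalizationCall` per query with a best hit.

    ``predictor_rows`` is a table with columns ``query_id``, ``predotar``,
    ``targetp`` (either may be missing/empty).  Agreeing predictors (or a
    single confident one) decide the call; otherwise the ortholog title is
    scanned for "chloroplast" (accepting "chloroplastic"); else unknown.
    """
    pred: dict[str, tuple] = {}
    if predictor_rows is not None and len(predictor_rows) > 0:
        df = pd.DataFrame(predictor_rows)
        for row in df.itertuples(index=False):
            pred[str(row.query_id)] = (
                _normalize_compartment(getattr(row, "predotar", None)),
                _normalize_compartment(getattr(row, "targetp", None)),
            )
    calls = []
    for query_id in sorted(best_hits):
        a, b = pred.get(query_id, (None, None))
        call = basis = None
        stated = [c for c in (a, b) if c is not None]
        if stated and all(c == stated[0] for c in stated):
            call, basis = stated[0], "predictor"
            if len(stated) == 1:
                logger.info("%s: single-predictor call %s", query_id, call)
        else:
            if len(stated) == 2:
                logger.info("%s: discordant predictors %s/%s", query_id, a, b)
            title = best_hits[query_id].subject_title.lower()
            if "chloroplast" in title:  # also matches "chloroplastic"
                call, basis = "chloroplast", "keyword"
        if call is None:
            call, basis = "unknown", "none"
        calls.append(LocalizationCall(query_id=query_id, call=call, basis=basis))
    return calls


def species_tally(best_hits: dict) -> pd.DataFrame:
    """Side table of best-hit species counts (no threshold applied)."""
    counts: dict[str, int] = {}
    for h in best_hits.values():
        sp = h.subject_species or "unspecified"
        counts[sp] = counts.get(sp, 0) + 1
    df = pd.DataFrame(
        sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["species", "count"],
    )
    if len(df):
        df["percent"] = 100.0 * df["count"] / df["count"].sum()
    return df


def read_blast_table(path, columns=None):
    """BLAST outfmt-6-style TSV; default columns qseqid sseqid pident bitscore
    evalue stitle [sspecies]."""
    names = columns or ["qseqid", "sseqid", "pident", "bitscore", "evalue", "stitle", "sspecies"]
    df = pd.read_csv(path, sep="\t", names=names, comment="#")
    hits = []
    for row in df.itertuples(index=False):
        hits.append(
            OrthologHit(
                query_id=str(row.qseqid),
                subject_id=str(row.sseqid),
                subject_title="" if pd.isna(row.stitle) else str(row.stitle),
                identity_pct=float(row.pident),
                bitscore=float(row.bitscore),
                evalue=float(row.evalue),
                subject_species=""
                if not hasattr(row, "sspecies") or pd.isna(row.sspecies)
                else str(row.sspecies),
            )
        )
    return hits
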