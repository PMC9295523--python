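"""Motif hit ingestion, score filtering, and tandem-array resolution.

Hit tables in plain TSV or HMMER ``domtblout`` dialect are normalized to the
PPR motif catalog.  Score filters follow the standard PPR search practice:
most motif types are kept at score > 0, SS motifs at score > 10 and DYW
domains at score > 30 (all strict).  Overlapping hits are resolved greedily
by descending score into a non-overlapping tandem array.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

#: Recognized motif types, in catalog order.
MOTIF_CATALOG = ("P", "P1", "L1", "S1", "P2", "L2", "S2", "SS", "E1", "E2", "DYW", "E+")
_CATALOG_INDEX = {m: i for i, m in enumerate(MOTIF_CATALOG)}

#: Strict per-type score thresholds (bits); types not listed use ``DEFAULT_MIN_SCORE``.
SCORE_THRESHOLDS = {"SS": 10.0, "DYW": 30.0}
DEFAULT_MIN_SCORE = 0.0

#: Profile E-value cutoff, applied only when hits carry an E-value.
EVALUE_CUTOFF = 1e-10


@dataclass(frozen=True)
class MotifHit:
    """One profile hit; protein coordinates are 1-based inclusive."""

    seq_id: str
    motif_type: str
    aa_start: int
    aa_end: int
    score: float
    source_profile: str = ""
    evalue: float | None = None

    def __post_init__(self):
        if self.motif_type not in _CATALOG_INDEX:
            raise ValueError(f"unknown motif type {self.motif_type!r}")
        if self.aa_start > self.aa_end:
            raise ValueError(f"{self.seq_id}: aa_start > aa_end")

    def overlaps(self, other: "MotifHit") -> bool:
        return not (self.aa_end < other.aa_start or other.aa_end < self.aa_start)


@dataclass(frozen=True)
class MotifArray:
    """Non-overlapping hits on one protein, sorted by start; the tandem array."""

    seq_id: str
    hits: tuple
    sum_score: float

    @property
    def motif_string(self) -> str:
        return "-".join(h.motif_type for h in self.hits)

    @property
    def motif_count(self) -> int:
        return len(self.hits)


_DEFAULT_COLUMNS = {
    "seq_id": "seq_id",
    "motif": "motif",
    "start": "start",
    "end": "end",
    "score": "score",
    "evalue": "evalue",  # optional
}


def _normalize_motif_name(name: str) -> str | None:
    name = name.strip()
    if name in _CATALOG_INDEX:
        return name
    # common profile-name prefixes, e.g. "PPR_P1" or lowercase
    stripped = name.upper().removeprefix("PPR_").removeprefix("PPR-")
    if stripped in _CATALOG_INDEX:
        return stripped
    return None


def parse_hit_table(path, columns: dict | None = None, dialect: str = "tsv"):
    """Read a per-motif hit table into :class:`MotifHit` records.

    ``dialect='tsv'`` expects named columns (remappable via ``columns``);
    ``dialect='domtblout'`` parses the fixed whitespace layout HMMER writes,
    taking the target as the protein, the query as the motif profile, the
    per-domain bit score and the alignment coordinates.  Rows naming motifs
    outside the catalog are skipped with a warning.
    """
    if dialect == "domtblout":
        rows = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                f = line.split()
                rows.append(
                    {
                        "seq_id": f[0],
                        "motif": f[3],
                        "evalue": float(f[12]),
                        "score": float(f[13]),
                        "start": int(f[17]),
                        "end": int(f[18]),
                    }
                )
        df = pd.DataFrame(rows)
    else:
        colmap = dict(_DEFAULT_COLUMNS)
        if columns:
            colmap.update(columns)
        df = pd.read_csv(path, sep="\t", comment="#")
        for key in ("seq_id", "motif", "start", "end", "score"):
            if colmap[key] not in df.columns:
                raise ValueError(f"hit table missing required column {colmap[key]!r}")
        rename = {v: k for k, v in colmap.items() if v in df.columns}
        df = df.rename(columns=rename)

    hits = []
    for row in df.itertuples(index=False):
        motif = _normalize_motif_name(str(row.motif))
        if motif is None:
            logger.warning("skipping hit with unknown motif name %r", row.motif)
            continue
        evalue = getattr(row, "evalue", None)
        if evalue is not None and pd.isna(evalue):
            evalue = None
        hits.append(
            MotifHit(
                seq_id=str(row.seq_id),
                motif_type=motif,
                aa_start=int(row.start),
                aa_end=int(row.end),
                score=float(row.score),
                evalue=None if evalue is None else float(evalue),
            )
        )
    return hits


def filter_hits(hits, thresholds: dict | None = None, evalue_cutoff: float = EVALUE_CUTOFF):
    """Apply the strict per-type score thresholds (and the E-value cutoff when
    a hit carries an E-value)."""
    th = dict(SCORE_THRESHOLDS)
    if thresholds:
        th.update(thresholds)
    kept = []
    for h in hits:
        if h.score <= th.get(h.motif_type, DEFAULT_MIN_SCORE):
            continue
        if h.evalue is not None and h.evalue > evalue_cutoff:
            continue
        kept.append(h)
    return kept


def resolve_overlaps(hits, seq_id: str | None = None) -> MotifArray:
    """Greedily select non-overlapping hits by descending score.

    Ties break to the leftmost start, then catalog order.  The result is
    sorted by start with ``sum_score`` the sum of retained scores.
    """
    if hits:
        ids = {h.seq_id for h in hits}
        if len(ids) > 1:
            raise ValueError(f"hits from multiple sequences: {sorted(ids)}")
        seq_id = hits[0].seq_id
    ordered = sorted(
        hits, key=lambda h: (-h.score, h.aa_start, _CATALOG_INDEX[h.motif_type])
    )
    selected = []
    for h in ordered:
        if not any(h.overlaps(s) for s in selected):
            selected.append(h)
    selected.sort(key=lambda h: h.aa_start)
    return MotifArray(
        seq_id=seq_id or "", hits=tuple(selected), sum_score=float(sum(h.score for h in selected))
    )


def arrays_from_hits(hits, thresholds=None):
    """Group hits by sequence, filter, and resolve each into a MotifArray."""
    by_seq: dict[str, list] = {}
    for h in filter_hits(hits, thresholds):
        by_seq.setdefault(h.seq_id, []).append(h)
    return {sid: resolve_overlaps(hs) for sid, hs in sorted(by_seq.items())}


def write_array_table(arrays, path):
    rows = [
        {
            "seq_id": a.seq_id,
            "motif_string": a.motif_string,
            "motif_count": a.motif_count,
            "sum_score": round(a.sum_score, 3),
        }
        for a in arrays.values()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
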