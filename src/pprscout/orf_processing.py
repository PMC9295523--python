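"""Six-frame ORF extraction and motif-guided joining of split ORFs.

ORFs are taken as the longest stop-to-stop stretches in each of the six
reading frames, trimmed to the first ATG when an upstream stop bounds the
stretch.  Coordinates are kept 0-based half-open on the forward strand
internally; user-facing tables are 1-based inclusive.  ORFs split across a
frameshift whose motif arrays remain a valid tandem array can be joined with
``X`` spacer residues; joined products are flagged hypothetical and excluded
from final tallies.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from Bio.Seq import Seq

logger = logging.getLogger(__name__)

_IUPAC_NT = set("ACGTURYSWKMBDHVN")

#: Default minimum retained ORF length in amino acids.
MIN_AA_DEFAULT = 31

#: Default maximum nucleotide gap bridged when joining split ORFs
#: (about one 35-aa PPR motif).
MAX_JOIN_GAP_DEFAULT = 90


@dataclass(frozen=True)
class TranscriptRecord:
    """A nucleotide transcript; sequence normalized to upper-case DNA."""

    transcript_id: str
    sequence: str

    def __post_init__(self):
        seq = self.sequence.upper().replace("U", "T")
        if not seq:
            raise ValueError(f"{self.transcript_id}: empty sequence")
        for i, ch in enumerate(seq):
            if ch not in _IUPAC_NT:
                raise ValueError(
                    f"{self.transcript_id}: non-nucleotide character "
                    f"{ch!r} at position {i + 1}"
                )
        object.__setattr__(self, "sequence", seq)


@dataclass(frozen=True)
class OrfRecord:
    """One predicted ORF on a transcript.

    ``nt_start``/``nt_end`` are 0-based half-open forward-strand coordinates
    of the coding codons (stop codon excluded); ``frame`` is the frame on the
    reading strand.
    """

    orf_id: str
    transcript_id: str
    strand: str
    frame: int
    nt_start: int
    nt_end: int
    aa_sequence: str
    completeness: str  # complete | 5'partial | 3'partial | internal


@dataclass(frozen=True)
class JoinedOrf:
    """Two ORFs bridged with X spacers; hypothetical, excluded from tallies."""

    members: tuple
    aa_sequence: str
    x_count: int
    hypothetical: bool = True


def _scan_frame(seq: str, offset: int):
    """Yield (start_codon_idx, end_codon_idx, upstream_stop, downstream_stop)
    for maximal stop-free codon runs of frame ``offset`` (codon indices)."""
    n_codons = (len(seq) - offset) // 3
    codons = [seq[offset + 3 * i: offset + 3 * i + 3] for i in range(n_codons)]
    stops = {"TAA", "TAG", "TGA"}
    run_start = 0
    upstream = False
    for i, codon in enumerate(codons + ["TAA"]):  # sentinel terminates last run
        is_stop = codon in stops and i < n_codons
        if is_stop or i == n_codons:
            yield run_start, i, upstream, is_stop
            run_start = i + 1
            upstream = True


def extract_orfs(transcript: TranscriptRecord, min_aa: int = MIN_AA_DEFAULT):
    """Scan all six frames and return retained :class:`OrfRecord` objects.

    A run bounded upstream by a stop codon is trimmed to its first ATG and is
    ``complete`` when a downstream stop exists, else ``3'partial``.  A run
    starting at the sequence edge is reported whole: ``complete``/``3'partial``
    when it begins with ATG, otherwise ``5'partial`` (with a downstream stop)
    or ``internal``.
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    seq = transcript.sequence
    length = len(seq)
    rc = str(Seq(seq).reverse_complement())
    out = []
    counter = 0
    for strand, s in (("+", seq), ("-", rc)):
        for frame in range(3):
            for run_start, run_end, upstream, downstream in _scan_frame(s, frame):
                if run_end <= run_start:
                    continue
                codon_start = run_start
                if upstream:
                    # trim to first ATG
                    atg = None
                    for c in range(run_start, run_end):
                        if s[frame + 3 * c: frame + 3 * c + 3] == "ATG":
                            atg = c
                            break
                    if atg is None:
                        continue
                    codon_start = atg
                    completeness = "complete" if downstream else "3'partial"
                elif s[frame + 3 * run_start: frame + 3 * run_start + 3] == "ATG":
                    # run begins at the sequence edge with a start codon
                    completeness = "complete" if downstream else "3'partial"
                else:
                    completeness = "5'partial" if downstream else "internal"
                aa_len = run_end - codon_start
                if aa_len < min_aa:
                    continue
                nt_a = frame + 3 * codon_start
                nt_b = frame + 3 * run_end
                aa = str(Seq(s[nt_a:nt_b]).translate())
                if strand == "+":
                    nt_start, nt_end = nt_a, nt_b
                else:
                    nt_start, nt_end = length - nt_b, length - nt_a
                counter += 1
                out.append(
                    OrfRecord(
                        orf_id=f"{transcript.transcript_id}|orf{counter}",
                        transcript_id=transcript.transcript_id,
                        strand=strand,
                        frame=frame,
                        nt_start=nt_start,
                        nt_end=nt_end,
                        aa_sequence=aa,
                        completeness=completeness,
                    )
                )
    out.sort(key=lambda o: (o.nt_start, o.nt_end, o.strand, o.frame))
    return out


def _array_order_ok(motif_types):
    """Concatenated arrays must keep C-terminal motifs terminal: no P/L/S
    motif may follow an E1/E2/E+/DYW motif."""
    rank = {"E1": 1, "E2": 2, "E+": 3, "DYW": 4}
    seen_terminal = 0
    for m in motif_types:
        r = rank.get(m, 0)
        if r == 0 and seen_terminal:
            return False
        seen_terminal = max(seen_terminal, r)
    return True


def join_orfs(orfs, arrays, max_gap_nt: int = MAX_JOIN_GAP_DEFAULT):
    """Join adjacent same-strand ORF pairs whose combined motif array is a
    valid tandem array.

    ``arrays`` maps orf_id to a :class:`~pprscout.motif_detection.MotifArray`.
    Only adjacent pairs in coordinate order are considered (no transitive
    chains).  Overlapping members refuse to join.  ``x_count`` =
    ceil(gap_nt / 3).
    """
    transcripts = {o.transcript_id for o in orfs}
    if len(transcripts) > 1:
        raise ValueError("join_orfs expects ORFs from a single transcript")
    ordered = sorted(orfs, key=lambda o: (o.nt_start, o.nt_end))
    joined = []
    used = set()
    for a, b in zip(ordered, ordered[1:]):
        if a.orf_id in used or b.orf_id in used:
            continue
        if a.strand != b.strand:
            continue
        gap = b.nt_start - a.nt_end
        if gap < 0:
            logger.warning(
                "join refused (overlap): %s / %s", a.orf_id, b.orf_id
            )
            continue
        if gap > max_gap_nt:
            continue
        arr_a, arr_b = arrays.get(a.orf_id), arrays.get(b.orf_id)
        if arr_a is None or arr_b is None:
            continue
        first, second = (a, b) if a.strand == "+" else (b, a)
        motifs = [h.motif_type for h in arrays[first.orf_id].hits] + [
            h.motif_type for h in arrays[second.orf_id].hits
        ]
        if not _array_order_ok(motifs):
            continue
        x_count = math.ceil(gap / 3)
        aa = first.aa_sequence + "X" * x_count + second.aa_sequence
        joined.append(
            JoinedOrf(members=(first.orf_id, second.orf_id), aa_sequence=aa, x_count=x_count)
        )
        used.update({a.orf_id, b.orf_id})
    return joined


def orf_table(orfs) -> "pandas.DataFrame":  # noqa: F821
    """1-based inclusive user-facing ORF table."""
    import pandas as pd

    rows = [
        {
            "orf_id": o.orf_id,
            "transcript_id": o.transcript_id,
            "strand": o.strand,
            "frame": o.frame,
            "start": o.nt_start + 1,
            "end": o.nt_end,
            "length_aa": len(o.aa_sequence),
            "completeness": o.completeness,
        }
        for o in orfs
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "orf_id",
            "transcript_id",
            "strand",
            "frame",
            "start",
            "end",
            "length_aa",
            "completeness",
        ],
    )
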