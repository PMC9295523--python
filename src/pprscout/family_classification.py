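"""Array validity filtering and P/PLS subfamily + class assignment.

P-subfamily proteins carry only canonical P motifs; PLS-subfamily proteins
carry the P1-L1-S1 triad variants and are subdivided by C-terminal
composition into the PLS, E1, E2, E+ and DYW classes.  Single-motif arrays
are discarded unless they are a complete standalone DYW domain; arrays must
clear a sum-score cutoff of > 40 bits and show no inter-motif gap larger
than the configured maximum ("classic array" continuity).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .motif_detection import MotifArray

logger = logging.getLogger(__name__)

SUM_SCORE_MIN = 40.0
MAX_INTERMOTIF_GAP = 50  # aa; ~1.4 motif lengths of linker drift

PLS_VARIANT_MOTIFS = frozenset({"P1", "L1", "S1", "P2", "L2", "S2", "SS"})
TERMINAL_MOTIFS = frozenset({"E1", "E2", "E+", "DYW"})

DISCARD_REASONS = (
    "single_motif",
    "low_sum_score",
    "no_classic_array",
    "standalone_DYW_no_PGbox",
    "E+_no_PGbox",
    "low_identity_ortholog",
    "joined_hypothetical",
    "none",
)


@dataclass
class PprAnnotation:
    """Per-sequence subfamily/class call with an explicit fate."""

    seq_id: str
    subfamily: str = "none"  # P | PLS | none
    ppr_class: str = "none"  # none | PLS | E1 | E2 | E+ | DYW
    motif_count: int = 0
    length_aa: int = 0
    fate: str = "retained"
    discard_reason: str = "none"
    motif_string: str = ""
    sum_score: float = 0.0
    aux_domains: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if (self.fate == "discarded") != (self.discard_reason != "none"):
            raise ValueError("fate and discard_reason inconsistent")


def validate_array(
    array: MotifArray,
    dyw_status: str | None = None,
    sum_score_min: float = SUM_SCORE_MIN,
    max_intermotif_gap: int = MAX_INTERMOTIF_GAP,
):
    """Return ``(ok, discard_reason)`` for a resolved array.

    A single-motif array fails unless the motif is DYW and the domain grades
    ``full`` (a complete standalone DYW functional domain).  Arrays carrying
    an E+ motif whose C-terminus lacks at least the PG box are discarded.
    """
    if array.motif_count == 0:
        return False, "no_classic_array"
    if array.motif_count == 1:
        if array.hits[0].motif_type == "DYW" and dyw_status == "full":
            return True, "none"
        if array.hits[0].motif_type == "DYW":
            return False, "standalone_DYW_no_PGbox"
        return False, "single_motif"
    if array.sum_score <= sum_score_min:
        return False, "low_sum_score"
    for prev, nxt in zip(array.hits, array.hits[1:]):
        if nxt.aa_start - prev.aa_end - 1 > max_intermotif_gap:
            return False, "no_classic_array"
    if any(h.motif_type == "E+" for h in array.hits) and dyw_status not in (
        "truncated_with_PG",
        "full",
    ):
        return False, "E+_no_PGbox"
    return True, "none"


def classify(
    array: MotifArray,
    dyw_status: str = "absent",
    length_aa: int = 0,
    aux_domains: frozenset = frozenset(),
) -> PprAnnotation:
    """Assign subfamily and class from motif composition and DYW grade.

    Subfamily P: only canonical P motifs (auxiliary SMR allowed).  Subfamily
    PLS: any P1/L1/S1-variant or E/DYW motif.  Class by C-terminal
    composition: DYW (full domain) > E+ (truncated with PG box) > E2 > E1 >
    PLS.  Pure function of ``(array, dyw_status)``.
    """
    types = [h.motif_type for h in array.hits]
    if all(t == "P" for t in types):
        subfamily, ppr_class = "P", "none"
        if dyw_status == "full":
            # a P array ending in a full DYW domain is not canonical P
            subfamily, ppr_class = "PLS", "DYW"
    else:
        subfamily = "PLS"
        if any(t not in PLS_VARIANT_MOTIFS and t not in TERMINAL_MOTIFS for t in types):
            logger.info(
                "%s: mixed P/variant array classified PLS", array.seq_id
            )
        if dyw_status == "full" or "DYW" in types:
            ppr_class = "DYW"
        elif dyw_status == "truncated_with_PG":
            ppr_class = "E+"
        elif "E2" in types:
            ppr_class = "E2"
        elif "E1" in types:
            ppr_class = "E1"
        else:
            ppr_class = "PLS"
    return PprAnnotation(
        seq_id=array.seq_id,
        subfamily=subfamily,
        ppr_class=ppr_class,
        motif_count=array.motif_count,
        length_aa=length_aa,
        motif_string=array.motif_string,
        sum_score=array.sum_score,
        aux_domains=aux_domains,
    )


def annotate(array, dyw_status="absent", length_aa=0, **validate_kw) -> PprAnnotation:
    """Validate then classify; discarded arrays keep their reason."""
    ok, reason = validate_array(array, dyw_status=dyw_status, **validate_kw)
    if not ok:
        return PprAnnotation(
            seq_id=array.seq_id,
            motif_count=array.motif_count,
            length_aa=length_aa,
            fate="discarded",
            discard_reason=reason,
            motif_string=array.motif_string,
            sum_score=array.sum_score,
        )
    return classify(array, dyw_status=dyw_status, length_aa=length_aa)


def summarize_funnel(annotations) -> dict:
    """Counts and percentages by subfamily/class plus motif-count and length
    histograms over retained sequences."""
    df = pd.DataFrame(
        [
            {
                "seq_id": a.seq_id,
                "subfamily": a.subfamily,
                "ppr_class": a.ppr_class,
                "motif_count": a.motif_count,
                "length_aa": a.length_aa,
                "fate": a.fate,
                "discard_reason": a.discard_reason,
            }
            for a in annotations
        ]
    )
    if df.empty:
        empty = pd.DataFrame()
        return {"by_group": empty, "motif_count_hist": empty, "length_hist": empty, "fates": empty}
    retained = df[df.fate == "retained"]
    by_group = (
        retained.groupby(["subfamily", "ppr_class"]).size().rename("count").reset_index()
    )
    total = max(len(retained), 1)
    by_group["percent"] = 100.0 * by_group["count"] / total
    motif_hist = (
        retained.groupby(["subfamily", "motif_count"]).size().rename("count").reset_index()
    )
    length_hist = (
        retained.assign(length_bin=(retained.length_aa // 100) * 100)
        .groupby("length_bin")
        .size()
        .rename("count")
        .reset_index()
    )
    fates = df.groupby(["fate", "discard_reason"]).size().rename("count").reset_index()
    return {
        "by_group": by_group,
        "motif_count_hist": motif_hist,
        "length_hist": length_hist,
        "fates": fates,
    }
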