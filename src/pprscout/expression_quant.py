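"""qRT-PCR relative quantification (2^-ddCt) and validation-set selection.

Technical replicates are averaged at the Ct level; multiple reference genes
are aggregated as the arithmetic mean of their per-gene mean Cts (the
geometric mean of the linear quantities).  dCt(tissue) = mean Ct_target -
mean Ct_refs; ddCt is taken against a calibrator tissue, whose relative
expression is 1.0 by construction.  Primer amplification efficiency comes
from the standard-curve slope, with the conventional 90-110% acceptance band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

TISSUES = ("GL", "GM", "AL", "AM")
CALIBRATOR_DEFAULT = "GL"
REFERENCE_GENES_DEFAULT = ("actin", "tubulin", "18S")

EFFICIENCY_RANGE = (90.0, 110.0)


@dataclass(frozen=True)
class CtRecord:
    gene: str
    tissue: str
    replicate: int
    ct: float

    def __post_init__(self):
        if not 0.0 < self.ct < 45.0:
            raise ValueError(f"Ct out of range: {self.ct}")


@dataclass(frozen=True)
class EfficiencyResult:
    primer_pair: str
    slope: float
    efficiency_pct: float
    in_range: bool


def _to_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return pd.DataFrame(
        [{"gene": r.gene, "tissue": r.tissue, "replicate": r.replicate, "ct": r.ct} for r in records]
    )


def ddct(
    records,
    target: str,
    references=REFERENCE_GENES_DEFAULT,
    calibrator: str = CALIBRATOR_DEFAULT,
) -> dict:
    """Relative expression per tissue by 2^-ddCt.

    Raises when the target or a reference gene is missing in any tissue
    where the target was measured, naming gene and tissue.
    """
    df = _to_frame(records)
    means = df.groupby(["gene", "tissue"])["ct"].mean()
    tissues = sorted(df.loc[df.gene == target, "tissue"].unique())
    if not tissues:
        raise ValueError(f"target gene {target!r} not measured")
    if calibrator not in tissues:
        raise ValueError(f"calibrator tissue {calibrator!r} not measured for {target!r}")
    dct = {}
    for tissue in tissues:
        ref_cts = []
        for ref in references:
            if (ref, tissue) not in means.index:
                raise ValueError(f"reference gene {ref!r} missing in tissue {tissue!r}")
            ref_cts.append(means[(ref, tissue)])
        dct[tissue] = means[(target, tissue)] - float(np.mean(ref_cts))
    return {t: float(2.0 ** (-(dct[t] - dct[calibrator]))) for t in tissues}


def efficiency_from_slope(slope: float, primer_pair: str = "") -> EfficiencyResult:
    """Amplification efficiency from a standard-curve slope (Ct per log10
    dilution): efficiency% = (10^(-1/slope) - 1) * 100."""
    if not slope < 0:
        raise ValueError("standard-curve slope must be negative")
    eff = (10.0 ** (-1.0 / slope) - 1.0) * 100.0
    lo, hi = EFFICIENCY_RANGE
    return EfficiencyResult(
        primer_pair=primer_pair,
        slope=float(slope),
        efficiency_pct=float(eff),
        in_range=bool(lo - 1e-9 <= eff <= hi + 1e-9),
    )


def select_for_validation(annotations, localization_calls, de_table) -> list:
    """Sequences meeting all three selection criteria: complete ORF
    structure, hypothetical chloroplast localization, and differential
    expression.

    ``annotations``: table/records with seq_id, fate and completeness (only
    retained + complete pass); ``localization_calls``: LocalizationCall
    records or a table with seq_id/call; ``de_table``: table with seq_id and
    a boolean ``significant`` column.
    """
    ann = pd.DataFrame(annotations)
    if ann.empty:
        return []
    complete = set(
        ann.loc[
            (ann.get("fate", "retained") == "retained")
            & (ann["completeness"] == "complete"),
            "seq_id",
        ]
    )
    if hasattr(localization_calls, "__iter__") and not isinstance(
        localization_calls, pd.DataFrame
    ):
        loc_rows = [
            {"seq_id": c.query_id, "call": c.call}
            if hasattr(c, "query_id")
            else dict(c)
            for c in localization_calls
        ]
        loc = pd.DataFrame(loc_rows)
    else:
        loc = pd.DataFrame(localization_calls)
    chloro = set(loc.loc[loc["call"] == "chloroplast", "seq_id"]) if len(loc) else set()
    de = pd.DataFrame(de_table)
    de_ids = (
        set(de.loc[de["significant"].astype(bool), "seq_id"]) if len(de) else set()
    )
    return sorted(complete & chloro & de_ids)


def expression_table(values_by_gene: dict) -> pd.DataFrame:
    """Long-format relative-expression table for reporting."""
    rows = [
        {"gene": gene, "tissue": tissue, "relative_expression": value}
        for gene, by_tissue in values_by_gene.items()
        for tissue, value in by_tissue.items()
    ]
    return pd.DataFrame(rows, columns=["gene", "tissue", "relative_expression"])
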