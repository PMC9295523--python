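"""Stage orchestration: hits -> arrays -> DYW grading -> annotation -> targets.

The funnel report tracks, at every filtering stage, input, retained and
discarded counts with discard reasons, so that retained + discarded = input
holds at each step.  A JSON run manifest records thresholds and seeds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import pandas as pd

from . import __version__
from .dyw_analysis import P_CUTOFF_DEFAULT, grade_dyw
from .family_classification import (
    MAX_INTERMOTIF_GAP,
    SUM_SCORE_MIN,
    annotate,
    summarize_funnel,
)
from .motif_detection import SCORE_THRESHOLDS, arrays_from_hits
from .synthetic_data import (
    SyntheticSpec,
    cohort_hit_table,
    default_region_pwms,
    gen_plastid_genome,
    gen_ppr_cohort,
)
from .target_prediction import (
    PROMISCUITY_THRESHOLD,
    load_code_table,
    predict_pattern,
    search_targets,
    target_report,
)

_DOMAIN_MOTIFS = {"E1", "E2", "E+", "DYW"}


@dataclass
class PipelineConfig:
    min_aa: int = 31
    ss_min: float = 10.0
    dyw_min: float = 30.0
    sum_score_min: float = SUM_SCORE_MIN
    identity_min: float = 50.0
    fimo_p: float = P_CUTOFF_DEFAULT
    promiscuity: int = PROMISCUITY_THRESHOLD
    max_join_gap: int = 90
    max_intermotif_gap: int = MAX_INTERMOTIF_GAP
    seed: int = 0

    def thresholds(self) -> dict:
        th = dict(SCORE_THRESHOLDS)
        th["SS"], th["DYW"] = self.ss_min, self.dyw_min
        return th


@dataclass
class PipelineResult:
    annotations: list
    arrays: dict
    funnel: pd.DataFrame
    target_hits: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)

    def funnel_conserved(self) -> bool:
        return bool(
            (self.funnel["input"] == self.funnel["retained"] + self.funnel["discarded"]).all()
        )


def dyw_candidate_region(array, sequence: str) -> str:
    """The stretch from the end of the last non-domain motif to the protein
    C-terminus — where a DYW domain (full or truncated) would sit."""
    non_domain = [h for h in array.hits if h.motif_type not in _DOMAIN_MOTIFS]
    # for a standalone DYW candidate the whole sequence is the domain region
    start = non_domain[-1].aa_end if non_domain else 0
    return sequence[start:]


def grade_sequences(arrays: dict, sequences: dict, pwms: dict | None = None,
                    p_cutoff: float = P_CUTOFF_DEFAULT) -> dict:
    """DYW grade per sequence; only arrays carrying E/DYW-type motifs are
    scanned (the domain-analysis candidates), others are ``absent``."""
    pwms = pwms or default_region_pwms()
    grades = {}
    for sid, array in arrays.items():
        if any(h.motif_type in _DOMAIN_MOTIFS for h in array.hits):
            region = dyw_candidate_region(array, sequences[sid])
            grades[sid] = grade_dyw(region, pwms, p_cutoff)
        else:
            grades[sid] = "absent"
    return grades


def annotate_cohort(sequences: dict, hits, config: PipelineConfig | None = None,
                    pwms: dict | None = None):
    """Filter hits, resolve arrays, grade DYW completeness, annotate.

    Returns ``(annotations, arrays, funnel)``; sequences with hits but no
    surviving array are annotated discarded.
    """
    config = config or PipelineConfig()
    all_ids = sorted({h.seq_id for h in hits} | set(sequences))
    arrays = arrays_from_hits(hits, thresholds=config.thresholds())
    grades = grade_sequences(
        {sid: a for sid, a in arrays.items() if a.motif_count > 0},
        sequences, pwms, config.fimo_p,
    )
    annotations = []
    for sid in all_ids:
        array = arrays.get(sid)
        if array is None or array.motif_count == 0:
            from .family_classification import PprAnnotation

            annotations.append(
                PprAnnotation(seq_id=sid, fate="discarded",
                              discard_reason="no_classic_array",
                              length_aa=len(sequences.get(sid, "")))
            )
            continue
        annotations.append(
            annotate(
                array,
                dyw_status=grades.get(sid, "absent"),
                length_aa=len(sequences.get(sid, "")),
                sum_score_min=config.sum_score_min,
                max_intermotif_gap=config.max_intermotif_gap,
            )
        )
    n = len(all_ids)
    discards = pd.Series([a.discard_reason for a in annotations])
    retained = int(sum(a.fate == "retained" for a in annotations))
    funnel_rows = [{"stage": "annotation", "input": n, "retained": retained,
                    "discarded": n - retained}]
    for reason, count in discards[discards != "none"].value_counts().items():
        funnel_rows.append({"stage": f"discard:{reason}", "input": int(count),
                            "retained": 0, "discarded": int(count)})
    funnel = pd.DataFrame(funnel_rows)
    return annotations, arrays, funnel


def predict_targets(annotations, arrays: dict, sequences: dict, genes,
                    config: PipelineConfig | None = None, code_table=None):
    """Degenerate patterns for retained sequences searched against the gene
    set; returns ``(hits_by_ppr, report, flagged)``."""
    from .target_prediction import flag_promiscuous

    config = config or PipelineConfig()
    table = code_table or load_code_table()
    hits_by_ppr = {}
    for ann in annotations:
        if ann.fate != "retained":
            continue
        array = arrays[ann.seq_id]
        pattern = predict_pattern(array, sequences[ann.seq_id], table)
        hits_by_ppr[ann.seq_id] = search_targets(pattern, genes, ppr_id=ann.seq_id)
    flagged = flag_promiscuous(hits_by_ppr, config.promiscuity)
    report = target_report(hits_by_ppr, config.promiscuity)
    return hits_by_ppr, report, flagged


def run_synthetic_pipeline(spec: SyntheticSpec, config: PipelineConfig | None = None,
                           with_targets: bool = False) -> PipelineResult:
    """End-to-end run on generated data: cohort -> arrays -> grades ->
    annotations (and optionally code patterns -> genome search)."""
    config = config or PipelineConfig(seed=spec.seed)
    records, truth = gen_ppr_cohort(spec)
    sequences = {r["seq_id"]: r["aa_sequence"] for r in records}
    hit_df = cohort_hit_table(records)
    hits = [h for r in records for h in r["hits"]]
    annotations, arrays, funnel = annotate_cohort(sequences, hits, config)
    result = PipelineResult(
        annotations=annotations,
        arrays=arrays,
        funnel=funnel,
        manifest={
            "pprscout_version": __version__,
            "seed": spec.seed,
            "n_sequences": spec.n_sequences,
            "config": asdict(config),
            "n_hits": int(len(hit_df)),
        },
    )
    if with_targets:
        genes, site_truth = gen_plastid_genome(spec)
        hits_by_ppr, report, flagged = predict_targets(
            annotations, arrays, sequences, genes, config
        )
        result.target_hits = hits_by_ppr
        result.manifest["n_target_hits"] = int(sum(len(v) for v in hits_by_ppr.values()))
        result.manifest["promiscuous"] = sorted(flagged)
    return result


def write_manifest(result: PipelineResult, path):
    with open(path, "w") as fh:
        json.dump(result.manifest, fh, indent=1, sort_keys=True)


def summary_tables(result: PipelineResult) -> dict:
    return summarize_funnel(result.annotations)
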