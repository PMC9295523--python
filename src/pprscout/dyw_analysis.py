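"""DYW-domain modeling: region PWMs, exact-p-value scanning, completeness grading.

The DYW cytidine-deaminase-like domain carries three conserved regions — the
PG box (24 residues), the active site (32) and the C-terminal region (25).
Each region is modeled as a position weight matrix built from an alignment
block.  Candidate C-termini are scanned with log-odds scores whose p-values
are computed exactly by dynamic programming over integer-scaled scores (the
FIMO approach), and the domain is graded ``full`` (all three regions present
in order), ``truncated_with_PG`` (PG box only) or ``absent``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}

REGIONS = ("PG_box", "active_site", "C_terminal")
REGION_WIDTHS = {"PG_box": 24, "active_site": 32, "C_terminal": 25}
#: Expected start residue of each region within the ~136-aa domain (soft hint;
#: only the relative order is enforced).
REGION_OFFSETS = {"PG_box": 1, "active_site": 68, "C_terminal": 112}

P_CUTOFF_DEFAULT = 1e-5
SCORE_SCALE = 1000


@dataclass(frozen=True)
class RegionPwm:
    """Probability matrix (width x 20) for one conserved region."""

    region: str
    matrix: np.ndarray
    background: np.ndarray
    offset_hint: int = 0

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def __post_init__(self):
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 20:
            raise ValueError("matrix must be width x 20")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM columns must sum to 1")
        if np.any(self.matrix <= 0):
            raise ValueError("PWM probabilities must be positive (use a pseudocount)")


@dataclass(frozen=True)
class PwmScanHit:
    seq_id: str
    region: str
    aa_start: int  # 1-based
    log_odds_score: float  # bits
    p_value: float


def uniform_background() -> np.ndarray:
    return np.full(20, 1.0 / 20)


def build_pwm(
    aligned_block,
    pseudocount: float = 0.5,
    region: str = "PG_box",
    background: np.ndarray | None = None,
    offset_hint: int = 0,
) -> RegionPwm:
    """Count-and-normalize a PWM from equal-length aligned sequences.

    Columns containing gap characters are dropped with a warning.  Column
    probabilities are ``(count + pseudocount) / (n + 20 * pseudocount)``.
    """
    block = [s.upper() for s in aligned_block]
    if len(block) < 2:
        raise ValueError("need at least 2 aligned sequences")
    widths = {len(s) for s in block}
    if len(widths) != 1:
        raise ValueError("aligned sequences must have equal length")
    width = widths.pop()
    keep = [j for j in range(width) if all(s[j] in _AA_INDEX for s in block)]
    if len(keep) < width:
        logger.warning("dropping %d gapped/non-standard columns", width - len(keep))
    n = len(block)
    mat = np.zeros((len(keep), 20))
    for col, j in enumerate(keep):
        for s in block:
            mat[col, _AA_INDEX[s[j]]] += 1.0
        mat[col] = (mat[col] + pseudocount) / (n + 20.0 * pseudocount)
    if pseudocount == 0 and np.any(mat <= 0):
        # keep the matrix usable for scanning; nudge zeros minimally
        mat = np.clip(mat, 1e-12, None)
        mat /= mat.sum(axis=1, keepdims=True)
    bg = uniform_background() if background is None else np.asarray(background, float)
    return RegionPwm(region=region, matrix=mat, background=bg, offset_hint=offset_hint)


def _int_score_matrix(pwm: RegionPwm, scale: int = SCORE_SCALE) -> np.ndarray:
    return np.round(scale * np.log2(pwm.matrix / pwm.background[None, :])).astype(np.int64)


def score_distribution(pwm: RegionPwm, scale: int = SCORE_SCALE):
    """Exact null distribution of the integer-scaled window score.

    Returns ``(min_sum, tail)`` where ``tail[s - min_sum]`` is the
    probability, under the background, that a random window scores >= s.
    The result is memoized on the PWM instance.
    """
    cache = getattr(pwm, "_dist_cache", None)
    if cache is not None and scale in cache:
        return cache[scale]
    ints = _int_score_matrix(pwm, scale)
    bg = pwm.background
    col_min = ints.min(axis=1)
    col_max = ints.max(axis=1)
    min_sum = int(col_min.sum())
    max_sum = int(col_max.sum())
    dist = np.zeros(max_sum - min_sum + 1)
    dist[0] = 1.0  # offset: current support starts at sum of processed col mins
    cur_lo = 0  # processed minimal sum relative to min_sum
    cur_len = 1
    for j in range(pwm.width):
        new_len = cur_len + int(col_max[j] - col_min[j])
        new = np.zeros(new_len)
        for a in range(20):
            shift = int(ints[j, a] - col_min[j])
            new[shift: shift + cur_len] += bg[a] * dist[:cur_len]
        dist[:new_len] = new
        cur_len = new_len
    pmf = dist[:cur_len]
    tail = np.cumsum(pmf[::-1])[::-1]
    # guard against float drift so that the minimum score has p = 1
    tail = np.minimum(tail, 1.0)
    if cache is None:
        cache = {}
        object.__setattr__(pwm, "_dist_cache", cache)
    cache[scale] = (min_sum, tail)
    return min_sum, tail


def scan_pwm(
    pwm: RegionPwm,
    sequence: str,
    p_cutoff: float = P_CUTOFF_DEFAULT,
    seq_id: str = "",
    scale: int = SCORE_SCALE,
):
    """Scan every window of ``sequence`` and return hits with p <= p_cutoff.

    Non-standard residues contribute a neutral score of 0 (background odds).
    """
    sequence = sequence.upper()
    if len(sequence) < pwm.width:
        return []
    ints = _int_score_matrix(pwm, scale)
    min_sum, tail = score_distribution(pwm, scale)
    max_sum = min_sum + len(tail) - 1
    hits = []
    warned = False
    for start in range(len(sequence) - pwm.width + 1):
        total = 0
        for j in range(pwm.width):
            aa = sequence[start + j]
            idx = _AA_INDEX.get(aa)
            if idx is None:
                if not warned:
                    logger.warning("non-standard residue %r scored neutrally", aa)
                    warned = True
                continue
            total += int(ints[j, idx])
        if total <= min_sum:
            p = 1.0
        elif total > max_sum:
            p = tail[-1]
        else:
            p = float(tail[total - min_sum])
        if p <= p_cutoff:
            hits.append(
                PwmScanHit(
                    seq_id=seq_id,
                    region=pwm.region,
                    aa_start=start + 1,
                    log_odds_score=total / scale,
                    p_value=p,
                )
            )
    return hits


def grade_dyw(cterm_sequence: str, pwms: dict, p_cutoff: float = P_CUTOFF_DEFAULT) -> str:
    """Grade DYW completeness from region scans of a candidate C-terminus.

    ``full``: all three regions hit with PG box < active site < C-terminal by
    position; ``truncated_with_PG``: the PG box hits but not all three in
    order; ``absent`` otherwise.
    """
    missing = [r for r in REGIONS if r not in pwms]
    if missing:
        raise ValueError(f"missing PWMs for regions: {missing}")
    hits = {r: scan_pwm(pwms[r], cterm_sequence, p_cutoff) for r in REGIONS}
    for pg in hits["PG_box"]:
        for act in hits["active_site"]:
            if act.aa_start <= pg.aa_start:
                continue
            for ct in hits["C_terminal"]:
                if ct.aa_start > act.aa_start:
                    return "full"
    if hits["PG_box"]:
        return "truncated_with_PG"
    return "absent"


def write_pwm(pwm: RegionPwm, path):
    """Tab-delimited position x residue probability matrix."""
    with open(path, "w") as fh:
        fh.write("# region=%s offset_hint=%d\n" % (pwm.region, pwm.offset_hint))
        fh.write("pos\t" + "\t".join(AA_ALPHABET) + "\n")
        for i, row in enumerate(pwm.matrix, start=1):
            fh.write(str(i) + "\t" + "\t".join(f"{p:.6g}" for p in row) + "\n")


def read_pwm(path, region: str | None = None) -> RegionPwm:
    offset_hint = 0
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                for tok in line[1:].split():
                    k, _, v = tok.partition("=")
                    if k == "region" and region is None:
                        region = v
                    elif k == "offset_hint":
                        offset_hint = int(v)
                continue
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "pos" or not parts[0]:
                continue
            rows.append([float(x) for x in parts[1:21]])
    mat = np.asarray(rows)
    mat /= mat.sum(axis=1, keepdims=True)
    return RegionPwm(
        region=region or "PG_box",
        matrix=np.clip(mat, 1e-12, None) / np.clip(mat, 1e-12, None).sum(axis=1, keepdims=True),
        background=uniform_background(),
        offset_hint=offset_hint,
    )
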