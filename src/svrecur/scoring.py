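"""Per-read and per-SV validation scores.

Each spanning read is compared against the original (R_o) and SV-altered
(R_a) reference window through its recurrence matrices.  Small events that
are fully encompassed by enough reads use the mean (or directed) distance of
matrix records to the diagonal; large events are assessed junction by
junction with a relative-tolerance match fraction.  Normalized per-read
scores are positive when the read fits the predicted structure better, and
the validation score of an SV is the fraction of reads with positive score.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, replace
from typing import Iterable, Optional

import pysam

from .config import RunConfig
from .genotyping import GenotypeCall, call_genotype
from .recurrence import (
    NONASSESSABLE,
    RecurrenceMatrix,
    recurrence_matrix,
    select_window_size,
)
from .sv_model import Junction, ReferencePair, SVRecord, build_reference_pair

logger = logging.getLogger(__name__)

MODE_SMALL = "SMALL"
MODE_LARGE = "LARGE"

QC_PASS = "PASS"
QC_NO_READS = "NO_READS"


@dataclass
class ReadScore:
    read_id: str
    score_o: float          # matrix score vs R_o
    score_a: float          # matrix score vs R_a
    normalized: float       # positive = supports the predicted structure
    mode: str
    used_directed: bool = False


@dataclass
class SVResult:
    sv: SVRecord
    vapor_score: Optional[float]       # fraction of reads with positive score
    max_read_score: Optional[float]
    n_reads: int
    qc: str                            # PASS / NONASSESSABLE / NO_READS
    mode: Optional[str]
    window: Optional[int]
    genotype: Optional[GenotypeCall]
    read_scores: list

    @property
    def passes(self) -> bool:
        return self.qc == QC_PASS


# ---------------------------------------------------------------------------
# Matrix statistics


def _scaled(x: float, x_scale: float, x_origin: float) -> float:
    """Read coordinate corrected for the global error-driven length expansion.

    Long-read error profiles are insertion-dominated, so raw read coordinates
    advance faster than reference coordinates by a constant factor.  Scaling
    around the extraction anchor (``x_origin``) removes that deterministic
    slope without touching SV-induced jumps.
    """
    return x_origin + (x - x_origin) * x_scale


def mean_diagonal_distance(
    matrix: RecurrenceMatrix, x_scale: float = 1.0, x_origin: float = 0.0
) -> float:
    """Mean vertical distance of records to the diagonal: sum|x - y| / m."""
    m = matrix.n_records
    if m == 0:
        raise ValueError("empty recurrence matrix has no distance score")
    return (
        sum(abs(_scaled(x, x_scale, x_origin) - y) for x, y in matrix.all_records())
        / m
    )


def directed_distance_score(
    matrix: RecurrenceMatrix, x_scale: float = 1.0, x_origin: float = 0.0
) -> float:
    """Duplication-corrected distance: |sum(x - y)| / m.

    Centrosymmetric record pairs produced by duplicated segments contribute
    opposite-sign distances that cancel, so a read that genuinely carries the
    duplication is not penalised for its intrinsic multi-matching.
    """
    m = matrix.n_records
    if m == 0:
        raise ValueError("empty recurrence matrix has no distance score")
    return (
        abs(sum(_scaled(x, x_scale, x_origin) - y for x, y in matrix.all_records()))
        / m
    )


def junction_score(
    matrix: RecurrenceMatrix,
    rel_tol: float = 0.15,
    x_scale: float = 1.0,
    x_origin: float = 0.0,
) -> float:
    """Fraction of records within a relative tolerance of the diagonal.

    A record counts as a hit when |x - y| < rel_tol * x (strict, so a record
    at x = 0 never counts).  Larger is better.
    """
    m = matrix.n_records
    if m == 0:
        raise ValueError("empty recurrence matrix has no junction score")
    hits = 0
    for x, y in matrix.all_records():
        xs = _scaled(x, x_scale, x_origin)
        if abs(xs - y) < rel_tol * xs:
            hits += 1
    return hits / m


def estimate_read_expansion(bam: pysam.AlignmentFile, max_reads: int = 300) -> float:
    """Global query-per-reference length ratio of the read set.

    Median of (aligned query length / reference span) over sampled primary
    reads.  With an insertion-dominated error profile this exceeds 1; read
    coordinates are divided by it before distances to the diagonal are
    measured.  Robust to the occasional SV-carrying read via the median.
    """
    ratios = []
    for read in bam.fetch():
        if not _usable(read) or read.reference_length < 1000:
            continue
        ratios.append(read.query_alignment_length / read.reference_length)
        if len(ratios) >= max_reads:
            break
    if not ratios:
        return 1.0
    ratios.sort()
    return ratios[len(ratios) // 2]


def normalize_small(score_o: float, score_a: float, eps_div: float = 0.5) -> float:
    """score_o / (score_a + eps_div) - 1; positive supports the SV."""
    return score_o / (score_a + eps_div) - 1.0


def normalize_large(score_o: float, score_a: float, eps_div: float) -> float:
    """score_a / (score_o + eps_div) - 1; positive supports the SV.

    Junction scores live in [0, 1], so the guard should be on the 1/m scale
    of the original-reference matrix rather than the 0.5 used for distances.
    """
    return score_a / (score_o + eps_div) - 1.0


def aggregate_vapor_score(read_scores: list) -> tuple[float, float]:
    """(validation score, max supportive score) over scored reads.

    The validation score is the fraction of reads with strictly positive
    normalized score; zero counts as non-supporting.
    """
    if not read_scores:
        raise ValueError("no scored reads to aggregate")
    vals = [rs.normalized for rs in read_scores]
    vapor = sum(1 for v in vals if v > 0) / len(vals)
    return vapor, max(vals)


# ---------------------------------------------------------------------------
# Read bookkeeping


def query_at_ref(read: pysam.AlignedSegment, anchor: int, mode: str = "first"):
    """Query index corresponding to reference coordinate ``anchor``.

    ``mode="first"`` returns the query offset when the alignment first
    reaches the anchor; ``mode="adv"`` skips any inserted query bases sitting
    at the anchor, returning the offset just before the alignment consumes
    reference past it.  Returns None when the anchor lies outside the
    alignment footprint.  Offsets index ``query_sequence`` (soft clips
    included).
    """
    if read.reference_start is None or not read.cigartuples:
        return None
    if anchor < read.reference_start or anchor > read.reference_end:
        return None
    q, r = 0, read.reference_start
    started = False
    for op, ln in read.cigartuples:
        if op in (0, 7, 8):  # M/=/X consume both
            if r == anchor:
                return q
            if r < anchor < r + ln:
                return q + (anchor - r)
            q += ln
            r += ln
            started = True
        elif op in (2, 3):  # D/N consume reference
            if r == anchor:
                return q
            if r < anchor < r + ln:
                return q  # anchor falls in a deletion: junction query index
            r += ln
            started = True
        elif op in (1, 4):  # I/S consume query
            if r == anchor and started and mode == "first":
                return q
            q += ln
    return q if r == anchor else None


def _read_key(read: pysam.AlignedSegment) -> str:
    return hashlib.md5(read.query_name.encode()).hexdigest()


def _usable(read: pysam.AlignedSegment) -> bool:
    return not (
        read.is_unmapped
        or read.is_secondary
        or read.is_supplementary
        or read.query_sequence is None
        or not read.cigartuples
    )


def collect_spanning_reads(
    bam: pysam.AlignmentFile,
    sv: SVRecord,
    pair: ReferencePair,
    flank_margin: int = 50,
    min_span_reads: int = 10,
    max_reads: int = 100,
):
    """Gather reads for an SV and decide the assessment mode.

    SMALL mode applies when more than ``min_span_reads`` primary reads fully
    cover [start - flank_margin, end + flank_margin]; those reads are
    returned (capped deterministically by read-name hash).  Otherwise LARGE
    mode returns (read, junction) pairs for reads anchored across each
    predicted junction.
    """
    reads = [
        r
        for r in bam.fetch(sv.chrom, pair.window_start, pair.window_end)
        if _usable(r)
    ]
    spanning = [
        r
        for r in reads
        if r.reference_start <= sv.start - flank_margin
        and r.reference_end >= sv.end + flank_margin
    ]
    if len(spanning) > min_span_reads:
        spanning.sort(key=_read_key)
        return MODE_SMALL, spanning[:max_reads]

    items = []
    for junction in pair.junctions:
        lo, hi = junction.ref_anchor - flank_margin, junction.ref_anchor + flank_margin
        for r in reads:
            if r.reference_start <= lo and r.reference_end >= hi:
                items.append((r, junction))
    items.sort(key=lambda t: (_read_key(t[0]), t[1].alt_pos))
    return MODE_LARGE, items[:max_reads]


# ---------------------------------------------------------------------------
# Per-read scoring


def _segment_by_ref(read, rstart: int, rend: int):
    """Read subsequence aligned to [rstart, rend) plus its window-frame offset."""
    lo = max(rstart, read.reference_start)
    hi = min(rend, read.reference_end)
    if hi <= lo:
        return "", 0
    qs = query_at_ref(read, lo, "first")
    qe = query_at_ref(read, hi, "first")
    if qs is None or qe is None or qe <= qs:
        return "", 0
    return read.query_sequence[qs:qe], lo - rstart


def score_read_small(
    read: pysam.AlignedSegment,
    pair: ReferencePair,
    window: int,
    eps_div: float = 0.5,
    include_rc: bool = True,
    x_scale: float = 1.0,
) -> Optional[ReadScore]:
    """Distance-based score of one fully spanning read against (R_o, R_a)."""
    seq, dx = _segment_by_ref(read, pair.window_start, pair.window_end)
    if len(seq) < window:
        return None
    mat_o = recurrence_matrix(seq, pair.original, window, include_rc).shifted(dx)
    mat_a = recurrence_matrix(seq, pair.altered, window, include_rc).shifted(dx)
    if mat_o.n_records == 0 and mat_a.n_records == 0:
        return None  # carries no evidence either way
    stat = directed_distance_score if pair.has_dup else mean_diagonal_distance
    # a side with no matches at all gets the maximal possible distance
    score_o = (
        stat(mat_o, x_scale, dx) if mat_o.n_records else float(len(pair.original))
    )
    score_a = (
        stat(mat_a, x_scale, dx) if mat_a.n_records else float(len(pair.altered))
    )
    return ReadScore(
        read_id=read.query_name,
        score_o=score_o,
        score_a=score_a,
        normalized=normalize_small(score_o, score_a, eps_div),
        mode=MODE_SMALL,
        used_directed=pair.has_dup,
    )


def score_read_junction(
    read: pysam.AlignedSegment,
    pair: ReferencePair,
    junction: Junction,
    jflank: int = 400,
    window: int = 10,
    include_rc: bool = True,
    x_scale: float = 1.0,
) -> Optional[ReadScore]:
    """Junction-mode score of one breakpoint-spanning read.

    The read segment around the junction is scored against the *full*
    original and altered windows, with read coordinates expressed in each
    window's frame so the predicted junction lines up with its reference
    position.  Content from the wrong side of a junction then still finds its
    k-mer matches — but displaced far from the diagonal, where the relative
    tolerance rejects them, diluting the score of the reference that lacks
    the predicted structure.
    """
    q0 = query_at_ref(read, junction.ref_anchor, junction.q_mode)
    if q0 is None:
        return None
    qlen = len(read.query_sequence)
    o_pos = junction.ref_anchor - pair.window_start
    a_pos = junction.alt_pos
    left = min(jflank, q0, o_pos, a_pos)
    right = min(jflank, qlen - q0)
    if left < window or right < window:
        return None
    seg = read.query_sequence[q0 - left : q0 + right]
    mat_o = recurrence_matrix(seg, pair.original, window, include_rc)
    mat_a = recurrence_matrix(seg, pair.altered, window, include_rc)
    m_o, m_a = mat_o.n_records, mat_a.n_records
    if m_o == 0 and m_a == 0:
        return None
    # Frames agree exactly at the junction; scale around it.  Both match
    # fractions share the larger record count as denominator: novel inserted
    # sequence produces no records at all against the reference that lacks
    # it, and must lower that reference's score rather than vanish from it.
    m_common = max(m_o, m_a)
    score_o = (
        junction_score(mat_o.shifted(o_pos - left), x_scale=x_scale, x_origin=o_pos)
        * m_o / m_common
        if m_o else 0.0
    )
    score_a = (
        junction_score(mat_a.shifted(a_pos - left), x_scale=x_scale, x_origin=a_pos)
        * m_a / m_common
        if m_a else 0.0
    )
    eps = 1.0 / (m_common + 1)
    return ReadScore(
        read_id=read.query_name,
        score_o=score_o,
        score_a=score_a,
        normalized=normalize_large(score_o, score_a, eps),
        mode=MODE_LARGE,
    )


# ---------------------------------------------------------------------------
# SV-level evaluation


def evaluate_sv(
    genome: pysam.FastaFile,
    bam: pysam.AlignmentFile,
    sv: SVRecord,
    config: Optional[RunConfig] = None,
    expansion: Optional[float] = None,
) -> SVResult:
    """Full evaluation of one SV: window QC, read collection, scoring, genotype.

    ``expansion`` is the global query/reference length ratio of the read set
    (estimated from the BAM when not given); read coordinates are divided by
    it so the insertion-heavy error profile does not tilt the dot-plot
    diagonals.
    """
    cfg = config or RunConfig()
    if expansion is None:
        expansion = estimate_read_expansion(bam)
    x_scale = 1.0 / expansion if expansion > 0 else 1.0
    pair = build_reference_pair(genome, sv, cfg.flank_len)
    qc = select_window_size(
        pair.original,
        start_window=cfg.window_start,
        step=cfg.window_step,
        max_window=cfg.window_max,
        diag_threshold=cfg.diag_threshold,
        include_rc=cfg.include_rc,
    )
    if not qc.assessable:
        return SVResult(sv, None, None, 0, NONASSESSABLE, None, None, None, [])
    window = qc.window

    mode, items = collect_spanning_reads(
        bam, sv, pair,
        flank_margin=cfg.flank_margin,
        min_span_reads=cfg.min_span_reads,
        max_reads=cfg.max_reads,
    )
    scores: list[ReadScore] = []
    if mode == MODE_SMALL:
        for read in items:
            rs = score_read_small(
                read, pair, window, cfg.eps_div, cfg.include_rc, x_scale
            )
            if rs is not None:
                scores.append(rs)
    else:
        for read, junction in items:
            rs = score_read_junction(
                read, pair, junction, cfg.junction_flank, window,
                cfg.include_rc, x_scale,
            )
            if rs is not None:
                scores.append(rs)
    if not scores:
        return SVResult(sv, None, None, 0, QC_NO_READS, mode, window, None, [])

    vapor, max_score = aggregate_vapor_score(scores)
    genotype = call_genotype([rs.normalized for rs in scores], cfg.eps)
    return SVResult(
        sv=sv,
        vapor_score=vapor,
        max_read_score=max_score,
        n_reads=len(scores),
        qc=QC_PASS,
        mode=mode,
        window=window,
        genotype=genotype,
        read_scores=scores,
    )


def breakpoint_offset_scan(
    genome: pysam.FastaFile,
    bam: pysam.AlignmentFile,
    sv: SVRecord,
    offsets: Iterable[int],
    config: Optional[RunConfig] = None,
) -> list[tuple[int, Optional[float], str]]:
    """Re-evaluate an SV with both breakpoints shifted by each offset.

    Returns (offset, vapor_score, qc) rows; offsets pushing the shifted
    window outside the contig are skipped with a warning.  Useful both for
    robustness curves and for locating the offset with the highest score
    when breakpoints are uncertain.
    """
    cfg = config or RunConfig()
    chrom_len = genome.get_reference_length(sv.chrom)
    expansion = estimate_read_expansion(bam)
    rows = []
    for delta in offsets:
        new_start, new_end = sv.start + delta, sv.end + delta
        if new_start < 0 or new_end > chrom_len:
            logger.warning(
                "offset %+d pushes %s outside the contig; skipped", delta, sv.label
            )
            continue
        shifted = replace(sv, start=new_start, end=new_end)
        res = evaluate_sv(genome, bam, shifted, cfg, expansion)
        rows.append((delta, res.vapor_score, res.qc))
    return rows
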