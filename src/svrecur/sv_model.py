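"""Structural-variant records and altered-reference construction.

A predicted SV is validated by comparing spanning long reads against two
versions of the local reference window: the original sequence ``R_o`` and an
altered sequence ``R_a`` in which the predicted rearrangement has been applied.
This module parses SV predictions (VCF / BED-like TSV), and builds the
``(R_o, R_a)`` pair for every supported SV class, including complex
rearrangements expressed through a small segment-recipe grammar.

Coordinates are 0-based half-open everywhere inside the package; conversion
from 1-based VCF coordinates happens only at the parser boundary.
"""

from __future__ import annotations

import logging
import re
import string
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import pysam

from ._sequence import revcomp

logger = logging.getLogger(__name__)

MIN_SV_LEN = 50  # predictions below this size are not structural variants here


class SVType(str, Enum):
    DEL = "DEL"
    INS = "INS"
    DUP_TANDEM = "DUP_TANDEM"
    INV = "INV"
    DUP_INV = "DUP_INV"
    DEL_INV = "DEL_INV"
    DEL_DUP = "DEL_DUP"
    CUSTOM = "CUSTOM"


#: SV types whose altered allele contains a duplicated reference segment.
#: These trigger the directed-distance correction during scoring.
_DUP_TYPES = {SVType.DUP_TANDEM, SVType.DUP_INV, SVType.DEL_DUP}


class DataError(Exception):
    """Unrecoverable problem with user-supplied input data."""


@dataclass
class SVRecord:
    """One predicted structural variant in internal 0-based half-open coords.

    ``start == end`` is permitted only for insertions; ``insert_seq`` is
    required for (and only for) insertions.  Complex events carry a
    ``recipe`` over lettered sub-segments of ``[start, end)`` (see
    :func:`parse_recipe`).
    """

    chrom: str
    start: int
    end: int
    svtype: SVType
    insert_seq: Optional[str] = None
    reported_gt: Optional[str] = None
    id: Optional[str] = None
    recipe: Optional[str] = None
    seg_bounds: Optional[Sequence[int]] = None

    def __post_init__(self) -> None:
        self.svtype = SVType(self.svtype)
        if self.svtype is SVType.INS:
            if not self.insert_seq:
                raise DataError(f"insertion {self.id} has no inserted sequence")
            if self.start != self.end:
                raise DataError("insertion must have start == end")
        else:
            if self.start >= self.end:
                raise DataError(
                    f"{self.svtype.value} {self.id}: start must be < end"
                )
            if self.insert_seq and self.svtype is not SVType.CUSTOM:
                raise DataError("insert_seq is only valid for INS/CUSTOM records")

    @property
    def length(self) -> int:
        if self.svtype is SVType.INS:
            return len(self.insert_seq)
        return self.end - self.start

    @property
    def label(self) -> str:
        return self.id or f"{self.chrom}:{self.start}-{self.end}:{self.svtype.value}"

    @property
    def has_duplication(self) -> bool:
        """True when the altered allele repeats a reference segment."""
        if self.svtype in _DUP_TYPES:
            return True
        if self.recipe is not None:
            letters = [tok.rstrip("^") for tok in self.recipe.split()]
            return len(letters) != len(set(letters))
        return False


@dataclass
class Piece:
    """One building block of an altered allele.

    Either a reference interval (``ref_start``/``ref_end``; ``strand`` -1 for
    reverse complement) or a literal inserted sequence (``seq``).
    """

    ref_start: Optional[int] = None
    ref_end: Optional[int] = None
    strand: int = 1
    seq: Optional[str] = None

    @property
    def is_ref(self) -> bool:
        return self.seq is None

    def length(self) -> int:
        if self.seq is not None:
            return len(self.seq)
        return self.ref_end - self.ref_start


@dataclass
class Junction:
    """A novel adjacency created by the rearrangement.

    ``ref_anchor`` is the reference coordinate reads must span to interrogate
    the junction; ``alt_pos`` is its position within the altered window
    string; ``q_mode`` selects how the matching query position is found on a
    read ("first": query index when the alignment first reaches the anchor;
    "adv": after any inserted bases at the anchor, used for junctions that
    sit downstream of novel sequence at the same reference coordinate).
    """

    ref_anchor: int
    alt_pos: int
    q_mode: str = "first"


@dataclass
class ReferencePair:
    """Original (R_o) and altered (R_a) window sequence for one SV."""

    original: str
    altered: str
    flank_len: int
    chrom: str
    window_start: int
    window_end: int
    pieces: list = field(default_factory=list)
    junctions: list = field(default_factory=list)
    has_dup: bool = False
    truncated: bool = False


# ---------------------------------------------------------------------------
# Recipe grammar


def parse_recipe(recipe: str) -> list[tuple[int, bool]]:
    """Parse a segment recipe into (segment index, inverted) tokens.

    The grammar is a whitespace-separated list of segment letters (``a`` is
    the first sub-segment of the SV interval, ``b`` the second, ...), each
    optionally suffixed with ``^`` for reverse complement.  Letters may
    repeat (duplication) or be omitted (deletion).  The empty string means
    "delete everything".  Example: ``"a c^ d"`` keeps segment a, drops b,
    appends the reverse complement of c, then d.
    """
    tokens = recipe.split()
    out = []
    for tok in tokens:
        m = re.fullmatch(r"([a-z])(\^?)", tok)
        if not m:
            raise DataError(f"bad recipe token {tok!r} in {recipe!r}")
        out.append((string.ascii_lowercase.index(m.group(1)), m.group(2) == "^"))
    return out


def _recipe_segments(sv: SVRecord) -> tuple[list[tuple[int, int]], str]:
    """Segment intervals and recipe string for any SV type.

    Built-in types are expressed through canonical recipes so a single code
    path constructs every altered allele; for CUSTOM records the recipe and
    optional inner breakpoints come from the input.
    """
    s, e = sv.start, sv.end
    mid = (s + e) // 2
    builtin = {
        SVType.DEL: ([(s, e)], ""),
        SVType.DUP_TANDEM: ([(s, e)], "a a"),
        SVType.INV: ([(s, e)], "a^"),
        SVType.DUP_INV: ([(s, e)], "a a^"),
        SVType.DEL_INV: ([(s, mid), (mid, e)], "b^"),
        SVType.DEL_DUP: ([(s, mid), (mid, e)], "b b"),
    }
    if sv.svtype in builtin and sv.recipe is None:
        return builtin[sv.svtype]
    if sv.recipe is None:
        raise DataError(f"{sv.label}: CUSTOM record needs a recipe")
    bounds = list(sv.seg_bounds) if sv.seg_bounds else [s, e]
    if bounds[0] != s or bounds[-1] != e or sorted(bounds) != bounds:
        raise DataError(f"{sv.label}: segment bounds must tile [start, end)")
    segments = list(zip(bounds[:-1], bounds[1:]))
    n_used = max((i for i, _ in parse_recipe(sv.recipe)), default=-1) + 1
    if n_used > len(segments):
        raise DataError(
            f"{sv.label}: recipe references segment "
            f"{string.ascii_lowercase[n_used - 1]!r} but only "
            f"{len(segments)} segments are defined"
        )
    return segments, sv.recipe


def inner_pieces(sv: SVRecord) -> list[Piece]:
    """Pieces replacing the reference interval [start, end) on the alt allele."""
    if sv.svtype is SVType.INS:
        return [Piece(seq=sv.insert_seq.upper())]
    segments, recipe = _recipe_segments(sv)
    pieces = []
    for idx, inverted in parse_recipe(recipe):
        a, b = segments[idx]
        pieces.append(Piece(ref_start=a, ref_end=b, strand=-1 if inverted else 1))
    return pieces


# ---------------------------------------------------------------------------
# Reference pair construction


def _merge_pieces(pieces: list[Piece]) -> list[Piece]:
    """Merge adjacent forward-colinear reference pieces."""
    out: list[Piece] = []
    for p in pieces:
        if p.length() == 0:
            continue
        if (
            out
            and out[-1].is_ref
            and p.is_ref
            and out[-1].strand == 1
            and p.strand == 1
            and out[-1].ref_end == p.ref_start
        ):
            out[-1] = Piece(ref_start=out[-1].ref_start, ref_end=p.ref_end)
        else:
            out.append(p)
    return out


def _find_junctions(pieces: list[Piece]) -> list[Junction]:
    junctions = []
    alt_pos = 0
    for prev, nxt in zip(pieces[:-1], pieces[1:]):
        alt_pos += prev.length()
        if (
            prev.is_ref
            and nxt.is_ref
            and prev.strand == 1
            and nxt.strand == 1
            and prev.ref_end == nxt.ref_start
        ):
            continue  # colinear, nothing new here
        if prev.is_ref and prev.strand == 1:
            junctions.append(Junction(prev.ref_end, alt_pos, "first"))
        elif nxt.is_ref and nxt.strand == 1:
            junctions.append(Junction(nxt.ref_start, alt_pos, "adv"))
        elif prev.is_ref:  # inverted piece on the left
            junctions.append(Junction(prev.ref_start, alt_pos, "first"))
        elif nxt.is_ref:
            junctions.append(Junction(nxt.ref_end, alt_pos, "adv"))
        # two novel pieces back to back cannot be anchored on the reference
    return junctions


def build_reference_pair(
    genome: pysam.FastaFile, sv: SVRecord, flank_len: int = 800
) -> ReferencePair:
    """Extract the original window and construct the SV-altered version.

    The window is the SV interval extended by ``flank_len`` bases of context
    on each side (truncated at contig edges, with ``truncated`` set).  The
    altered sequence applies the rearrangement between identical flanks.
    """
    if sv.chrom not in genome.references:
        raise DataError(f"{sv.label}: contig {sv.chrom!r} not in reference")
    if flank_len <= 0:
        raise DataError("flank_len must be positive")
    chrom_len = genome.get_reference_length(sv.chrom)
    if sv.start < 0 or sv.end > chrom_len:
        raise DataError(f"{sv.label}: interval outside contig bounds")
    ws = sv.start - flank_len
    we = sv.end + flank_len
    truncated = ws < 0 or we > chrom_len
    ws, we = max(0, ws), min(chrom_len, we)

    original = genome.fetch(sv.chrom, ws, we).upper()
    pieces = _merge_pieces(
        [Piece(ref_start=ws, ref_end=sv.start)]
        + inner_pieces(sv)
        + [Piece(ref_start=sv.end, ref_end=we)]
    )
    parts = []
    for p in pieces:
        if p.seq is not None:
            parts.append(p.seq)
        else:
            seg = original[p.ref_start - ws : p.ref_end - ws]
            parts.append(revcomp(seg) if p.strand == -1 else seg)
    return ReferencePair(
        original=original,
        altered="".join(parts),
        flank_len=flank_len,
        chrom=sv.chrom,
        window_start=ws,
        window_end=we,
        pieces=pieces,
        junctions=_find_junctions(pieces),
        has_dup=sv.has_duplication,
        truncated=truncated,
    )


# ---------------------------------------------------------------------------
# Parsing


class ParsedSVs(list):
    """List of SVRecord with parse bookkeeping attached."""

    def __init__(self, records=(), n_short=0, n_skipped=0, n_unresolvable=0):
        super().__init__(records)
        self.n_short = n_short
        self.n_skipped = n_skipped
        self.n_unresolvable = n_unresolvable


def _svtype_from_vcf(rec) -> Optional[str]:
    svtype = rec.info.get("SVTYPE")
    if svtype is None and rec.alts:
        alt = rec.alts[0]
        m = re.match(r"<([A-Z:]+)>", alt or "")
        if m:
            svtype = m.group(1)
        elif alt and re.fullmatch(r"[ACGTNacgtn]+", alt):
            svtype = "INS" if len(alt) > len(rec.ref) else "DEL"
    if svtype is None:
        return None
    svtype = svtype.split(":")[0]
    return {"DUP": "DUP_TANDEM"}.get(svtype, svtype)


def _parse_vcf(path: str) -> ParsedSVs:
    out = ParsedSVs()
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            svtype = _svtype_from_vcf(rec)
            if svtype is None or svtype not in SVType.__members__:
                out.n_skipped += 1
                logger.warning("skipping %s:%s with unknown SV type", rec.chrom, rec.pos)
                continue
            svtype = SVType(svtype)
            start = rec.start  # pysam converts 1-based POS to 0-based
            gt = None
            if rec.samples:
                g = rec.samples[0].get("GT")
                if g and g[0] is not None:
                    gt = "/".join(str(a) for a in g)
            if svtype is SVType.INS:
                alt = rec.alts[0] if rec.alts else None
                try:
                    insseq = rec.info.get("INSSEQ")
                except (KeyError, ValueError):  # key not declared in header
                    insseq = None
                if alt and re.fullmatch(r"[ACGTNacgtn]+", alt):
                    seq = alt[len(rec.ref):].upper() if alt.upper().startswith(
                        rec.ref.upper()
                    ) else alt.upper()
                elif insseq:
                    seq = str(insseq).upper()
                else:
                    out.n_unresolvable += 1
                    logger.warning(
                        "unresolvable insertion at %s:%s (no sequence in ALT)",
                        rec.chrom, rec.pos,
                    )
                    continue
                if len(seq) < MIN_SV_LEN:
                    out.n_short += 1
                    continue
                out.append(SVRecord(rec.chrom, start, start, svtype,
                                    insert_seq=seq, reported_gt=gt, id=rec.id))
            else:
                end = rec.stop  # pysam: 0-based exclusive, from END or rlen
                if end - start < MIN_SV_LEN:
                    out.n_short += 1
                    continue
                out.append(SVRecord(rec.chrom, start, end, svtype,
                                    reported_gt=gt, id=rec.id))
    return out


def _parse_bed(path: str) -> ParsedSVs:
    out = ParsedSVs()
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                raise DataError(f"{path}:{ln}: need >= 4 tab-separated columns")
            chrom, start, end, svtype = cols[0], int(cols[1]), int(cols[2]), cols[3]
            sv_id = cols[4] if len(cols) > 4 and cols[4] not in (".", "") else None
            extra = {}
            for c in cols[5:]:
                for kv in c.split(";"):
                    if "=" in kv:
                        k, v = kv.split("=", 1)
                        extra[k.upper()] = v
            svtype = svtype.upper().replace(":", "_")
            svtype = {"DUP": "DUP_TANDEM"}.get(svtype, svtype)
            if svtype not in SVType.__members__:
                if "RECIPE" in extra:
                    svtype = "CUSTOM"
                else:
                    out.n_skipped += 1
                    logger.warning("%s:%d: unknown SV type %r skipped", path, ln, svtype)
                    continue
            svtype = SVType(svtype)
            kwargs = dict(reported_gt=extra.get("GT"), id=sv_id)
            if "RECIPE" in extra:
                kwargs["recipe"] = extra["RECIPE"].replace(",", " ")
            if "SEGS" in extra:
                kwargs["seg_bounds"] = [int(x) for x in extra["SEGS"].split(",")]
            if svtype is SVType.INS:
                seq = extra.get("INSSEQ")
                if not seq:
                    out.n_unresolvable += 1
                    logger.warning("%s:%d: insertion without INSSEQ skipped", path, ln)
                    continue
                if len(seq) < MIN_SV_LEN:
                    out.n_short += 1
                    continue
                out.append(SVRecord(chrom, start, start, svtype,
                                    insert_seq=seq.upper(), **kwargs))
            else:
                if end - start < MIN_SV_LEN:
                    out.n_short += 1
                    continue
                out.append(SVRecord(chrom, start, end, svtype, **kwargs))
    return out


def parse_sv_records(path: str, format: Optional[str] = None) -> ParsedSVs:
    """Parse SV predictions from VCF 4.x or a BED-like TSV.

    Events shorter than 50 bp are dropped (counted in ``.n_short``); records
    of unknown type without a recipe are skipped (``.n_skipped``); symbolic
    insertions without a resolved sequence are skipped (``.n_unresolvable``).
    """
    if format is None:
        low = str(path).lower()
        format = "vcf" if low.endswith((".vcf", ".vcf.gz", ".bcf")) else "bed"
    if format == "vcf":
        parsed = _parse_vcf(path)
    elif format == "bed":
        parsed = _parse_bed(path)
    else:
        raise ValueError(f"unknown SV file format {format!r}")
    if parsed.n_short:
        logger.info("dropped %d events shorter than %d bp", parsed.n_short, MIN_SV_LEN)
    return parsed
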