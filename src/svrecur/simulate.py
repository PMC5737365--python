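"""Synthetic genomes, injected SVs, and noisy long reads with truth alignments.

The simulator reproduces the evaluation design of the method at desk scale:
a random reference, a diploid pair of haplotypes carrying non-overlapping
heterozygous and homozygous SVs (simple and complex), and long reads drawn
from the haplotypes with a PacBio-like error profile — mean length 12,000 bp,
mean accuracy 0.85, and the error budget split 5:75:20 between substitutions,
insertions and deletions.  Alignments are placed from the simulation truth
(via the haplotype-to-reference liftover) rather than by running an aligner,
which keeps the whole loop hermetic and deterministic; error-induced indels
are aggregated per 250-bp source block so CIGAR anchoring error stays small
while CIGARs stay short.

A relocation helper re-assigns true SVs to unaffected coordinates of the same
genome, providing the deliberately false call set used to measure the false
discovery rate.
"""

from __future__ import annotations

import os
from bisect import bisect_right
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pysam

from ._sequence import revcomp
from .sv_model import Piece, SVRecord, SVType, inner_pieces

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i

#: source-block size for CIGAR aggregation of sequencing-error indels
CIGAR_BLOCK = 250

DEFAULT_SV_COUNTS = {
    SVType.DEL: 50,
    SVType.INS: 50,
    SVType.INV: 50,
    SVType.DUP_TANDEM: 50,
    SVType.DUP_INV: 50,
    SVType.DEL_INV: 50,
    SVType.DEL_DUP: 50,
}


@dataclass
class SimConfig:
    """Study conditions for the simulated evaluation."""

    genome_len: int = 5_000_000
    gc: float = 0.5
    n_svs: dict = field(default_factory=lambda: dict(DEFAULT_SV_COUNTS))
    sv_len_min: int = 100
    sv_len_max: int = 5_000
    het_fraction: float = 0.5       # remaining SVs are homozygous
    min_gap: int = 5_000            # minimum spacing between injected SVs
    edge_margin: int = 20_000       # keep SVs away from contig ends
    depth: float = 20.0             # total diploid fold coverage
    read_len_mean: float = 12_000.0
    read_len_sigma: float = 0.3     # log-scale sd of the log-normal length law
    read_len_min: int = 500
    accuracy_mean: float = 0.85
    diff_ratio: tuple = (5, 75, 20)  # substitution : insertion : deletion
    seed: int = 1

    def error_rates(self) -> tuple[float, float, float]:
        """(p_sub, p_ins, p_del) per source base."""
        total = 1.0 - self.accuracy_mean
        s, i, d = self.diff_ratio
        if min(s, i, d) <= 0:
            raise ValueError("diff_ratio components must be positive")
        denom = s + i + d
        return total * s / denom, total * i / denom, total * d / denom


@dataclass
class TruthSV:
    sv: SVRecord
    zygosity: str  # "het" | "hom"


@dataclass
class TruthSet:
    entries: list

    def __iter__(self):
        return iter(self.entries)

    def __len__(self):
        return len(self.entries)

    def svs(self) -> list[SVRecord]:
        return [e.sv for e in self.entries]

    def write_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("#chrom\tstart\tend\tsvtype\tid\textra\n")
            for e in self.entries:
                sv = e.sv
                extra = [f"GT={'0/1' if e.zygosity == 'het' else '1/1'}"]
                if sv.insert_seq:
                    extra.append(f"INSSEQ={sv.insert_seq}")
                fh.write(
                    f"{sv.chrom}\t{sv.start}\t{sv.end}\t{sv.svtype.value}\t"
                    f"{sv.id}\t{';'.join(extra)}\n"
                )

    def write_vcf(self, path: str, genome: pysam.FastaFile) -> None:
        header = pysam.VariantHeader()
        for name in genome.references:
            header.contigs.add(name, length=genome.get_reference_length(name))
        header.info.add("SVTYPE", 1, "String", "Structural variant type")
        header.formats.add("GT", 1, "String", "Genotype")
        header.add_sample("SIM")
        with pysam.VariantFile(path, "w", header=header) as vcf:
            for e in self.entries:
                sv = e.sv
                ref_base = genome.fetch(sv.chrom, sv.start, sv.start + 1) or "N"
                rec = vcf.new_record(
                    contig=sv.chrom,
                    start=sv.start,
                    id=sv.id,
                    alleles=(
                        (ref_base, ref_base + sv.insert_seq)
                        if sv.svtype is SVType.INS
                        else (ref_base, f"<{sv.svtype.value}>")
                    ),
                )
                # SVLEN is deliberately not written: htslib would re-derive END
                # from it under the padding-base convention and shift the
                # coordinates by one
                rec.stop = max(sv.end, sv.start + 1)
                rec.info["SVTYPE"] = sv.svtype.value
                rec.samples["SIM"]["GT"] = (0, 1) if e.zygosity == "het" else (1, 1)
                vcf.write(rec)


# ---------------------------------------------------------------------------
# Reference and haplotypes


def simulate_reference(
    genome_len: int, gc: float = 0.5, seed: Optional[int] = None, rng=None
) -> str:
    """Reproducible i.i.d. random nucleotide sequence with the given GC content."""
    if genome_len <= 0:
        raise ValueError("genome_len must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=genome_len, p=p).astype(np.uint8)
    return _BASES[codes].tobytes().decode()


class HaplotypeMap:
    """One haplotype as an ordered list of reference pieces.

    Supports sequence materialisation, haplotype<->reference liftover for
    positions in unaffected (forward-colinear) segments, and per-read piece
    decomposition for truth-based alignment placement.
    """

    def __init__(self, pieces: Sequence[Piece], ref: str):
        self.pieces = [p for p in pieces if p.length() > 0]
        self.starts = []  # haplotype start offset of each piece
        off = 0
        parts = []
        for p in self.pieces:
            self.starts.append(off)
            off += p.length()
            if p.seq is not None:
                parts.append(p.seq)
            else:
                seg = ref[p.ref_start : p.ref_end]
                parts.append(revcomp(seg) if p.strand == -1 else seg)
        self.length = off
        self.seq = "".join(parts)
        self.codes = _CODE[np.frombuffer(self.seq.encode(), dtype=np.uint8)]

    def _piece_at(self, pos: int) -> int:
        if not 0 <= pos < self.length:
            raise IndexError("haplotype position out of range")
        return bisect_right(self.starts, pos) - 1

    def to_ref(self, pos: int) -> Optional[int]:
        """Reference coordinate of a haplotype position.

        Exact for forward-colinear segments; inverted segments map to the
        mirrored base; positions inside novel insertions return None.
        """
        i = self._piece_at(pos)
        p = self.pieces[i]
        off = pos - self.starts[i]
        if p.seq is not None:
            return None
        if p.strand == 1:
            return p.ref_start + off
        return p.ref_end - 1 - off

    def to_hap(self, ref_pos: int) -> Optional[int]:
        """Haplotype coordinate of a reference position (forward pieces only)."""
        for p, start in zip(self.pieces, self.starts):
            if p.seq is None and p.strand == 1 and p.ref_start <= ref_pos < p.ref_end:
                return start + (ref_pos - p.ref_start)
        return None

    def nearest_ref(self, pos: int) -> int:
        """Reference attachment point for a haplotype position (insertions
        attach at the next forward piece's start)."""
        i = self._piece_at(pos)
        for j in range(i, len(self.pieces)):
            p = self.pieces[j]
            if p.seq is None:
                off = pos - self.starts[j] if j == i else 0
                return (p.ref_start + off) if p.strand == 1 else p.ref_start
        return self.pieces[-1].ref_end if self.pieces[-1].seq is None else 0

    def pieces_in(self, u: int, v: int) -> list:
        """Pieces overlapping haplotype interval [u, v) as
        (src_a, src_b, piece, piece_offset) with src coords relative to u."""
        out = []
        i = self._piece_at(u)
        while i < len(self.pieces) and self.starts[i] < v:
            p = self.pieces[i]
            a = max(u, self.starts[i])
            b = min(v, self.starts[i] + p.length())
            if b > a:
                out.append((a - u, b - u, p, a - self.starts[i]))
            i += 1
        return out


def _sample_sv_set(ref_len: int, cfg: SimConfig, rng) -> list[tuple[SVRecord, str]]:
    specs = []
    for svtype, count in cfg.n_svs.items():
        specs += [SVType(svtype)] * int(count)
    specs = [specs[i] for i in rng.permutation(len(specs))]
    placed: list[tuple[int, int]] = []
    entries = []
    for idx, svtype in enumerate(specs):
        length = int(
            round(
                10
                ** rng.uniform(np.log10(cfg.sv_len_min), np.log10(cfg.sv_len_max))
            )
        )
        start = _place_interval(ref_len, length, placed, cfg, rng)
        if start is None:
            raise RuntimeError(
                f"could not place all SVs: {len(entries)} placed, "
                f"{len(specs) - len(entries)} left; enlarge the genome or "
                "reduce counts/min_gap"
            )
        placed.append((start, start + length))
        zyg = "het" if idx % 2 == 0 else "hom"
        if svtype is SVType.INS:
            ins = simulate_reference(length, cfg.gc, rng=rng)
            sv = SVRecord(
                "chrS", start, start, svtype, insert_seq=ins, id=f"sim{idx:04d}"
            )
        else:
            sv = SVRecord("chrS", start, start + length, svtype, id=f"sim{idx:04d}")
        entries.append((sv, zyg))
    entries.sort(key=lambda t: t[0].start)
    return entries


def _place_interval(ref_len, length, placed, cfg, rng, gap=None, max_tries=4000):
    gap = cfg.min_gap if gap is None else gap
    lo, hi = cfg.edge_margin, ref_len - cfg.edge_margin - length
    if hi <= lo:
        return None
    for _ in range(max_tries):
        start = int(rng.integers(lo, hi))
        if not any(
            start - gap < e and s < start + length + gap for s, e in placed
        ):
            return start
    return None


def inject_svs(
    ref: str, cfg: SimConfig, rng=None
) -> tuple[HaplotypeMap, HaplotypeMap, TruthSet]:
    """Place non-overlapping SVs and build the two haplotypes.

    Heterozygous SVs go to haplotype 1 only; homozygous SVs to both.  The
    truth set records reference coordinates and zygosity for every event.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    entries = _sample_sv_set(len(ref), cfg, rng)

    def build(select_hom_only: bool) -> HaplotypeMap:
        pieces: list[Piece] = []
        cursor = 0
        for sv, zyg in entries:
            if select_hom_only and zyg == "het":
                continue
            pieces.append(Piece(ref_start=cursor, ref_end=sv.start))
            pieces.extend(inner_pieces(sv))
            cursor = sv.end
        pieces.append(Piece(ref_start=cursor, ref_end=len(ref)))
        return HaplotypeMap(pieces, ref)

    hap1 = build(select_hom_only=False)
    hap2 = build(select_hom_only=True)
    truth = TruthSet([TruthSV(sv, zyg) for sv, zyg in entries])
    return hap1, hap2, truth


def relocate_svs(
    truth: TruthSet, ref_len: int, cfg: SimConfig, rng=None, clearance: int = 2_000
) -> list[SVRecord]:
    """Move every truth SV to a random non-variant locus of the same contig.

    The relocated calls are deliberately false: the reads carry no
    rearrangement there, so any validation is a false discovery.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 7)
    blocked = [(e.sv.start - clearance, e.sv.end + clearance) for e in truth]
    false_svs = []
    for e in truth:
        sv = e.sv
        length = max(sv.end - sv.start, 1)
        # relocated calls only need window-scale clearance from real variants,
        # not the injection spacing used when building the haplotypes
        start = _place_interval(ref_len, length, blocked, cfg, rng, gap=clearance)
        if start is None:
            raise RuntimeError("could not relocate all SVs to unaffected loci")
        blocked.append((start, start + length))
        end = start if sv.svtype is SVType.INS else start + (sv.end - sv.start)
        false_svs.append(replace(sv, start=start, end=end, id=f"{sv.id}_false"))
    return false_svs


# ---------------------------------------------------------------------------
# Reads


@dataclass
class SimRead:
    name: str
    hap: int
    hap_start: int
    hap_end: int
    seq: str
    ref_pos: int
    cigar: list                     # pysam-style (op, len) tuples
    n_sub: int = 0
    n_ins: int = 0
    n_del: int = 0


def _mutate(src_codes: np.ndarray, rates, rng):
    """Apply per-base substitution/insertion/deletion errors, vectorised.

    Returns (out_codes, outpos, counts): ``outpos[i]`` is the output offset
    of source base i (prefix sums), used for block-accurate CIGARs.
    """
    p_sub, p_ins, p_del = rates
    n = len(src_codes)
    rolls = rng.random(n)
    is_del = rolls < p_del
    is_ins = (rolls >= p_del) & (rolls < p_del + p_ins)
    is_sub = (rolls >= p_del + p_ins) & (rolls < p_del + p_ins + p_sub)
    reps = (~is_del).astype(np.int64) + is_ins
    outpos = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(reps, out=outpos[1:])
    out = np.repeat(src_codes, reps)
    sub_idx = outpos[:-1][is_sub]
    if len(sub_idx):
        out[sub_idx] = (out[sub_idx] + rng.integers(1, 4, size=len(sub_idx))) % 4
    ins_idx = outpos[1:][is_ins] - 1
    if len(ins_idx):
        out[ins_idx] = rng.integers(0, 4, size=len(ins_idx))
    counts = (int(is_sub.sum()), int(is_ins.sum()), int(is_del.sum()))
    return out, outpos, counts


def _compose_cigar(hap: HaplotypeMap, u: int, v: int, outpos: np.ndarray):
    """Structural CIGAR of a read over haplotype [u, v), in reference coords.

    Forward-colinear pieces become M runs with per-block I/D corrections for
    sequencing errors; inverted, inserted, or reference-backtracking pieces
    (duplications) are emitted as insertions.  Returns (ref_pos, ops) with
    leading/trailing insertions converted to soft clips; ref_pos is None when
    the read never touches the reference colinearly (fully novel content).
    """
    ops: list[tuple[int, int]] = []
    ref_cursor = None
    pos = None

    def push(op, ln):
        if ln <= 0:
            return
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + ln)
        else:
            ops.append((op, ln))

    for a, b, piece, poff in hap.pieces_in(u, v):
        qlen = int(outpos[b] - outpos[a])
        colinear = piece.seq is None and piece.strand == 1
        if colinear:
            ra = piece.ref_start + poff
            rb = ra + (b - a)
        if colinear and (ref_cursor is None or ra >= ref_cursor):
            if pos is None:
                pos = ra
            else:
                push(2, ra - ref_cursor)  # deleted reference between pieces
            for blk_a in range(a, b, CIGAR_BLOCK):
                blk_b = min(blk_a + CIGAR_BLOCK, b)
                q = int(outpos[blk_b] - outpos[blk_a])
                r = blk_b - blk_a
                push(0, min(q, r))
                if q > r:
                    push(1, q - r)
                elif r > q:
                    push(2, r - q)
            ref_cursor = rb
        else:
            push(1, qlen)  # novel relative to a colinear walk

    if pos is None:
        return None, ops
    # trim leading/trailing deletions, turn edge insertions into soft clips
    while ops and ops[0][0] == 2:
        pos += ops.pop(0)[1]
    while ops and ops[-1][0] == 2:
        ops.pop()
    if ops and ops[0][0] == 1:
        ops[0] = (4, ops[0][1])
    if ops and ops[-1][0] == 1:
        ops[-1] = (4, ops[-1][1])
    return pos, ops


def simulate_reads(
    haplotypes: Sequence[HaplotypeMap], cfg: SimConfig, rng=None
) -> list[SimRead]:
    """Draw noisy reads uniformly from each haplotype to the target depth.

    Each haplotype receives half of the total diploid depth.  Reads record
    their true origin interval and a truth-derived alignment (position +
    CIGAR) on the reference.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    rates = cfg.error_rates()
    mu = np.log(cfg.read_len_mean) - cfg.read_len_sigma**2 / 2
    reads = []
    idx = 0
    for h, hap in enumerate(haplotypes):
        target = cfg.depth / len(haplotypes) * hap.length
        total = 0
        while total < target:
            length = int(rng.lognormal(mu, cfg.read_len_sigma))
            length = max(cfg.read_len_min, min(length, hap.length))
            u = int(rng.integers(0, hap.length - length + 1))
            v = u + length
            out, outpos, counts = _mutate(hap.codes[u:v], rates, rng)
            pos, ops = _compose_cigar(hap, u, v, outpos)
            if pos is None:
                # read lies entirely inside novel sequence: park it at the
                # attachment point, fully soft-clipped but for one base
                pos = hap.nearest_ref(u)
                ops = [(0, 1), (4, len(out) - 1)] if len(out) > 1 else [(0, 1)]
            reads.append(
                SimRead(
                    name=f"r{idx:06d}_h{h + 1}_{u}_{v}",
                    hap=h,
                    hap_start=u,
                    hap_end=v,
                    seq=_BASES[out].tobytes().decode(),
                    ref_pos=pos,
                    cigar=ops,
                    n_sub=counts[0],
                    n_ins=counts[1],
                    n_del=counts[2],
                )
            )
            total += length
            idx += 1
    return reads


def write_alignments(
    reads: Sequence[SimRead], ref_name: str, ref_len: int, path: str
) -> str:
    """Write coordinate-sorted, indexed BAM from truth-placed reads."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": ref_name, "LN": ref_len}],
    }
    with pysam.AlignmentFile(path, "wb", header=header) as bam:
        for sr in sorted(reads, key=lambda r: r.ref_pos):
            a = pysam.AlignedSegment(bam.header)
            a.query_name = sr.name
            a.query_sequence = sr.seq
            a.flag = 0
            a.reference_id = 0
            a.reference_start = sr.ref_pos
            a.mapping_quality = 60
            a.cigartuples = sr.cigar
            bam.write(a)
    pysam.index(path)
    return path


def write_fasta(seq: str, name: str, path: str) -> str:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(seq), 80):
            fh.write(seq[i : i + 80] + "\n")
    pysam.faidx(path)
    return path


@dataclass
class SimBundle:
    """Everything one simulated study needs, on disk and in memory."""

    fasta: str
    bam: str
    truth_vcf: str
    truth_tsv: str
    truth: TruthSet
    false_svs: list
    config: SimConfig
    ref_name: str = "chrS"


def simulate_bundle(cfg: SimConfig, outdir: str, with_false: bool = True) -> SimBundle:
    """Run the full simulation: reference, haplotypes, reads, files."""
    os.makedirs(outdir, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    ref = simulate_reference(cfg.genome_len, cfg.gc, rng=rng)
    hap1, hap2, truth = inject_svs(ref, cfg, rng)
    reads = simulate_reads([hap1, hap2], cfg, rng)

    fasta = write_fasta(ref, "chrS", os.path.join(outdir, "genome.fa"))
    bam = write_alignments(
        reads, "chrS", len(ref), os.path.join(outdir, "reads.bam")
    )
    truth_tsv = os.path.join(outdir, "truth.tsv")
    truth.write_tsv(truth_tsv)
    truth_vcf = os.path.join(outdir, "truth.vcf")
    with pysam.FastaFile(fasta) as genome:
        truth.write_vcf(truth_vcf, genome)
    false_svs = relocate_svs(truth, len(ref), cfg, rng) if with_false else []
    return SimBundle(
        fasta=fasta,
        bam=bam,
        truth_vcf=truth_vcf,
        truth_tsv=truth_tsv,
        truth=truth,
        false_svs=false_svs,
        config=cfg,
    )
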