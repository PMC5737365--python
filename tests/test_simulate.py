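"""Synthetic reference, SV injection, liftover, read errors and alignments."""

import numpy as np
import pysam
import pytest

from svrecur.simulate import (
    SimConfig,
    _mutate,
    inject_svs,
    relocate_svs,
    simulate_reads,
    simulate_reference,
    write_alignments,
)
from svrecur.sv_model import SVType


def test_reference_is_deterministic():
    a = simulate_reference(5000, seed=1)
    b = simulate_reference(5000, seed=1)
    c = simulate_reference(5000, seed=2)
    assert a == b and a != c
    assert set(a) <= set("ACGT")


def test_reference_gc_content():
    seq = simulate_reference(1_000_000, gc=0.5, seed=3)
    gc = (seq.count("G") + seq.count("C")) / len(seq)
    assert 0.49 <= gc <= 0.51
    skewed = simulate_reference(200_000, gc=0.3, seed=3)
    gc = (skewed.count("G") + skewed.count("C")) / len(skewed)
    assert 0.29 <= gc <= 0.31


def test_zero_length_reference_rejected():
    with pytest.raises(ValueError):
        simulate_reference(0)


# ---------------------------------------------------------------------------
# SV injection


def _small_cfg(**kw):
    base = dict(
        genome_len=200_000,
        n_svs={SVType.DEL: 2, SVType.INV: 2, SVType.INS: 2},
        min_gap=3_000,
        edge_margin=10_000,
        seed=9,
    )
    base.update(kw)
    return SimConfig(**base)


def test_hom_deletion_length_bookkeeping():
    ref = simulate_reference(100_000, seed=4)
    cfg = SimConfig(
        genome_len=100_000, n_svs={SVType.DEL: 1}, sv_len_min=500,
        sv_len_max=500, het_fraction=0.0, edge_margin=5_000, seed=4,
    )
    rng = np.random.default_rng(0)
    # force homozygosity by making every SV hom: index 0 is het by the
    # alternating rule, so check with two SVs instead
    cfg.n_svs = {SVType.DEL: 2}
    hap1, hap2, truth = inject_svs(ref, cfg, rng)
    zygs = [e.zygosity for e in truth]
    assert sorted(zygs) == ["het", "hom"]
    # het DEL removed from hap1 only; hom from both
    assert hap1.length == len(ref) - 1000
    assert hap2.length == len(ref) - 500


def test_het_inversion_zygosity_semantics():
    ref = simulate_reference(120_000, seed=6)
    cfg = SimConfig(genome_len=120_000, n_svs={SVType.INV: 1},
                    edge_margin=10_000, seed=6)
    hap1, hap2, truth = inject_svs(ref, cfg, np.random.default_rng(1))
    (entry,) = truth
    assert entry.zygosity == "het"
    sv = entry.sv
    assert hap2.seq == ref  # untouched haplotype
    assert hap1.seq != ref
    assert hap1.seq[: sv.start] == ref[: sv.start]
    assert hap1.seq[sv.end :] == ref[sv.end :]


def test_liftover_roundtrip_on_unaffected_positions():
    ref = simulate_reference(200_000, seed=7)
    cfg = _small_cfg(seed=7)
    hap1, hap2, truth = inject_svs(ref, cfg, np.random.default_rng(2))
    sv_zones = [(e.sv.start - 5, e.sv.end + 5) for e in truth]
    rng = np.random.default_rng(3)
    checked = 0
    for ref_pos in rng.integers(0, 200_000, 500):
        ref_pos = int(ref_pos)
        if any(s <= ref_pos < e for s, e in sv_zones):
            continue
        for hap in (hap1, hap2):
            hp = hap.to_hap(ref_pos)
            assert hp is not None
            assert hap.to_ref(hp) == ref_pos
            assert hap.seq[hp] == ref[ref_pos]
        checked += 1
    assert checked > 300


def test_truth_files_roundtrip(tmp_path):
    from svrecur.simulate import write_fasta
    from svrecur.sv_model import parse_sv_records

    ref = simulate_reference(150_000, seed=8)
    cfg = _small_cfg(genome_len=150_000, seed=8)
    _, _, truth = inject_svs(ref, cfg, np.random.default_rng(4))
    fasta = write_fasta(ref, "chrS", str(tmp_path / "g.fa"))
    tsv, vcf = tmp_path / "t.tsv", tmp_path / "t.vcf"
    truth.write_tsv(str(tsv))
    with pysam.FastaFile(fasta) as genome:
        truth.write_vcf(str(vcf), genome)
    for path, fmt in ((tsv, "bed"), (vcf, "vcf")):
        back = parse_sv_records(str(path), fmt)
        assert len(back) == len(truth)
        for orig, parsed in zip(truth.svs(), sorted(back, key=lambda s: s.start)):
            assert (parsed.start, parsed.end, parsed.svtype) == (
                orig.start, orig.end, orig.svtype
            )


def test_relocation_avoids_true_loci():
    ref = simulate_reference(200_000, seed=10)
    cfg = _small_cfg(seed=10)
    _, _, truth = inject_svs(ref, cfg, np.random.default_rng(5))
    false_svs = relocate_svs(truth, len(ref), cfg, np.random.default_rng(6))
    assert len(false_svs) == len(truth)
    for f in false_svs:
        for e in truth:
            assert f.end + 2000 <= e.sv.start or f.start >= e.sv.end + 2000
        assert f.id.endswith("_false")


# ---------------------------------------------------------------------------
# read errors


def test_mutate_zero_error_is_identity(rng):
    src = rng.integers(0, 4, 5000).astype(np.uint8)
    out, outpos, counts = _mutate(src, (0.0, 0.0, 0.0), rng)
    assert np.array_equal(out, src)
    assert counts == (0, 0, 0)


def test_error_rates_and_ratio(rng):
    """1e6 simulated bases: identity ~0.85 and ins:del events ~75:20."""
    cfg = SimConfig(accuracy_mean=0.85)
    rates = cfg.error_rates()
    assert sum(rates) == pytest.approx(0.15)
    src = rng.integers(0, 4, 1_000_000).astype(np.uint8)
    out, outpos, (n_sub, n_ins, n_del) = _mutate(src, rates, rng)
    total_err = n_sub + n_ins + n_del
    assert 0.14 <= total_err / len(src) <= 0.16
    assert n_ins / n_del == pytest.approx(75 / 20, rel=0.05)
    assert n_sub / n_del == pytest.approx(5 / 20, rel=0.10)
    assert len(out) == len(src) + n_ins - n_del


def test_coverage_arithmetic():
    """Depth x20 over a 1 Mb diploid genome gives ~2e7 read bases +-5%."""
    ref = simulate_reference(1_000_000, seed=12)
    cfg = SimConfig(genome_len=1_000_000, n_svs={SVType.DEL: 1},
                    depth=20, seed=12, edge_margin=10_000)
    hap1, hap2, truth = inject_svs(ref, cfg, np.random.default_rng(7))
    reads = simulate_reads([hap1, hap2], cfg, np.random.default_rng(8))
    total = sum(r.hap_end - r.hap_start for r in reads)
    assert 0.95 * 2e7 <= total <= 1.05 * 2e7


def test_read_determinism():
    ref = simulate_reference(100_000, seed=13)
    cfg = SimConfig(genome_len=100_000, n_svs={SVType.DEL: 1},
                    depth=5, seed=13, edge_margin=10_000)
    out = []
    for _ in range(2):
        hap1, hap2, _ = inject_svs(ref, cfg, np.random.default_rng(9))
        reads = simulate_reads([hap1, hap2], cfg, np.random.default_rng(10))
        out.append([(r.name, r.seq, r.ref_pos, tuple(r.cigar)) for r in reads])
    assert out[0] == out[1]


# ---------------------------------------------------------------------------
# alignments


def test_clean_read_has_single_match_run(tmp_path):
    ref = simulate_reference(100_000, seed=14)
    cfg = SimConfig(genome_len=100_000, n_svs={SVType.DEL: 2}, depth=3,
                    accuracy_mean=1.0, seed=14, edge_margin=10_000)
    hap1, hap2, truth = inject_svs(ref, cfg, np.random.default_rng(11))
    reads = simulate_reads([hap1, hap2], cfg, np.random.default_rng(12))
    sv_spans = [(e.sv.start, e.sv.end) for e in truth]
    clean = [
        r for r in reads
        if not any(r.ref_pos < e and s < r.ref_pos + len(r.seq) for s, e in sv_spans)
    ]
    assert clean
    for r in clean[:20]:
        assert r.cigar == [(0, len(r.seq))]
        assert ref[r.ref_pos : r.ref_pos + len(r.seq)] == r.seq


def test_bam_roundtrip_and_deletion_read_collected(tmp_path):
    from svrecur.scoring import collect_spanning_reads
    from svrecur.simulate import write_fasta
    from svrecur.sv_model import build_reference_pair

    ref = simulate_reference(150_000, seed=15)
    cfg = SimConfig(genome_len=150_000, n_svs={SVType.DEL: 2}, depth=25,
                    sv_len_min=300, sv_len_max=600, seed=15, edge_margin=12_000)
    hap1, hap2, truth = inject_svs(ref, cfg, np.random.default_rng(13))
    reads = simulate_reads([hap1, hap2], cfg, np.random.default_rng(14))
    bam_path = write_alignments(reads, "chrS", len(ref), str(tmp_path / "r.bam"))
    fasta = write_fasta(ref, "chrS", str(tmp_path / "g.fa"))

    with pysam.AlignmentFile(bam_path) as bam:
        got = list(bam.fetch("chrS"))
        assert len(got) == len(reads)
        positions = [r.reference_start for r in got]
        assert positions == sorted(positions)  # coordinate sorted
        # a read across the hom deletion carries the deletion in its CIGAR
        hom = next(e.sv for e in truth if e.zygosity == "hom")
        spanning = [
            r for r in bam.fetch("chrS", hom.start, hom.end)
            if r.reference_start <= hom.start - 50
            and r.reference_end >= hom.end + 50
        ]
        assert spanning
        dels = [
            sum(ln for op, ln in r.cigartuples if op == 2) for r in spanning
        ]
        assert max(dels) >= 0.9 * (hom.end - hom.start)
        # and the collector finds it
        with pysam.FastaFile(fasta) as genome:
            pair = build_reference_pair(genome, hom, 800)
        mode, items = collect_spanning_reads(bam, hom, pair)
        assert len(items) > 0


def test_bundle_files_cross_validate(mini_study):
    bundle = mini_study["bundle"]
    with pysam.FastaFile(bundle.fasta) as genome:
        assert genome.references == ["chrS"]
        assert genome.get_reference_length("chrS") == bundle.config.genome_len
    with pysam.AlignmentFile(bundle.bam) as bam:
        assert bam.header["SQ"][0]["SN"] == "chrS"
        assert bam.count("chrS") > 0
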