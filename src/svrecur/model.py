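"""Model-style front end: a validator object fitted to (genome, reads, SVs).

``SVValidator`` bundles the inputs and configuration; ``fit()`` evaluates
every SV and returns a ``ValidationResults`` object carrying the per-SV
table, summary, genotypes and benchmarking utilities.  The functional
wrappers ``run_validate`` / ``run_simulate`` / ``run_benchmark`` expose the
same workflow to the command line.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
import pysam

from .config import RunConfig
from .recurrence import NONASSESSABLE
from .scoring import (
    QC_PASS,
    SVResult,
    breakpoint_offset_scan,
    estimate_read_expansion,
    evaluate_sv,
)
from .simulate import SimBundle, SimConfig, simulate_bundle
from .sv_model import DataError, SVRecord, parse_sv_records

logger = logging.getLogger(__name__)

TABLE_COLUMNS = [
    "chrom", "start", "end", "svtype", "id", "n_reads", "mode", "window",
    "vapor_score", "max_read_score", "pass_015", "pass_max01",
    "genotype", "GQ", "qc_flag",
]


class SVValidator:
    """Validator for a set of predicted SVs against long-read alignments.

    Parameters
    ----------
    genome : path to an indexed FASTA or an open pysam.FastaFile
    alignments : path to a coordinate-sorted, indexed BAM or an open
        pysam.AlignmentFile
    svs : list of SVRecord, or path to a VCF / BED-like TSV
    config : RunConfig, optional
    """

    def __init__(self, genome, alignments, svs, config: Optional[RunConfig] = None):
        self.genome = (
            genome if isinstance(genome, pysam.FastaFile) else pysam.FastaFile(genome)
        )
        self.bam = (
            alignments
            if isinstance(alignments, pysam.AlignmentFile)
            else pysam.AlignmentFile(alignments)
        )
        if isinstance(svs, (str, os.PathLike)):
            svs = parse_sv_records(str(svs))
        self.svs: list[SVRecord] = list(svs)
        self.config = config or RunConfig()

    @classmethod
    def from_files(cls, fasta: str, bam: str, sv_path: str,
                   config: Optional[RunConfig] = None,
                   sv_format: Optional[str] = None) -> "SVValidator":
        for path in (fasta, bam, sv_path):
            if not os.path.exists(path):
                raise DataError(f"input file not found: {path}")
        if not os.path.exists(bam + ".bai") and not os.path.exists(
            bam.replace(".bam", ".bai")
        ):
            raise DataError(
                f"{bam} has no index; run `samtools index {bam}` first"
            )
        return cls(fasta, bam, parse_sv_records(sv_path, sv_format), config)

    def fit(self, progress: bool = False) -> "ValidationResults":
        """Evaluate every SV; per-SV failures are logged, never fatal."""
        expansion = estimate_read_expansion(self.bam)
        logger.info("estimated read length expansion factor %.4f", expansion)
        results: list[SVResult] = []
        for i, sv in enumerate(self.svs):
            try:
                res = evaluate_sv(self.genome, self.bam, sv, self.config, expansion)
            except DataError as exc:
                logger.error("skipping %s: %s", sv.label, exc)
                res = SVResult(sv, None, None, 0, "ERROR", None, None, None, [])
            results.append(res)
            logger.info(
                "%s qc=%s score=%s", sv.label, res.qc,
                None if res.vapor_score is None else round(res.vapor_score, 3),
            )
            if progress and (i + 1) % 25 == 0:
                print(f"  evaluated {i + 1}/{len(self.svs)} SVs", flush=True)
        return ValidationResults(results, self.config)

    def offset_scan(self, sv: SVRecord, offsets: Optional[Iterable[int]] = None
                    ) -> pd.DataFrame:
        """Breakpoint-offset robustness scan for one SV."""
        offsets = self.config.offsets if offsets is None else offsets
        rows = breakpoint_offset_scan(self.genome, self.bam, sv, offsets, self.config)
        return pd.DataFrame(rows, columns=["offset", "vapor_score", "qc_flag"])

    def dotplot(self, sv: SVRecord, read_index: int = 0, png: Optional[str] = None,
                table_prefix: Optional[str] = None):
        """Dot plots of one spanning read against R_o and R_a.

        Returns ({"original": matrix, "altered": matrix}, read_name); writes
        a PNG and/or plain-text x,y tables when paths are given.
        """
        from .recurrence import plot_dotplot, recurrence_matrix, write_dotplot_table
        from .scoring import _segment_by_ref, collect_spanning_reads
        from .sv_model import build_reference_pair

        pair = build_reference_pair(self.genome, sv, self.config.flank_len)
        mode, items = collect_spanning_reads(
            self.bam, sv, pair,
            flank_margin=self.config.flank_margin,
            min_span_reads=self.config.min_span_reads,
            max_reads=self.config.max_reads,
        )
        if not items:
            raise DataError(f"{sv.label}: no reads to plot")
        read = items[read_index]
        if isinstance(read, tuple):  # LARGE mode pairs reads with junctions
            read = read[0]
        seq, _ = _segment_by_ref(read, pair.window_start, pair.window_end)
        mats = {
            "original": recurrence_matrix(seq, pair.original, 10),
            "altered": recurrence_matrix(seq, pair.altered, 10),
        }
        if table_prefix:
            for label, mat in mats.items():
                write_dotplot_table(mat, f"{table_prefix}.{label}.tsv")
        if png:
            plot_dotplot(mats, png, title=f"{sv.label} / {read.query_name}")
        return mats, read.query_name


class ValidationResults:
    """Per-SV validation scores, genotypes and QC flags."""

    def __init__(self, results: Sequence[SVResult], config: RunConfig):
        self.results = list(results)
        self.config = config
        self._table: Optional[pd.DataFrame] = None

    @property
    def table(self) -> pd.DataFrame:
        if self._table is None:
            rows = []
            for r in self.results:
                gt = r.genotype
                rows.append({
                    "chrom": r.sv.chrom,
                    "start": r.sv.start,
                    "end": r.sv.end,
                    "svtype": r.sv.svtype.value,
                    "id": r.sv.label,
                    "n_reads": r.n_reads,
                    "mode": r.mode,
                    "window": r.window,
                    "vapor_score": r.vapor_score,
                    "max_read_score": r.max_read_score,
                    "pass_015": (
                        bool(r.vapor_score > self.config.vapor_cutoff)
                        if r.vapor_score is not None else False
                    ),
                    "pass_max01": (
                        bool(r.max_read_score > self.config.max_read_cutoff)
                        if r.max_read_score is not None else False
                    ),
                    "genotype": gt.gt_string if gt else "./.",
                    "GQ": round(gt.gq, 4) if gt else None,
                    "qc_flag": r.qc,
                })
            self._table = pd.DataFrame(rows, columns=TABLE_COLUMNS)
        return self._table

    def summary(self) -> str:
        t = self.table
        n = len(t)
        counts = t["qc_flag"].value_counts().to_dict()
        lines = [
            "Structural-variant validation summary",
            "=" * 38,
            f"events evaluated        {n}",
        ]
        for flag in (QC_PASS, NONASSESSABLE, "NO_READS", "ERROR"):
            if counts.get(flag):
                lines.append(f"  {flag:<21} {counts[flag]}")
        scored = t[t["qc_flag"] == QC_PASS]
        if len(scored):
            lines += [
                f"validated (score>{self.config.vapor_cutoff:g})   "
                f"{int(scored['pass_015'].sum())} / {len(scored)}",
                f"mean validation score   {scored['vapor_score'].mean():.3f}",
                f"mean reads per event    {scored['n_reads'].mean():.1f}",
            ]
        return "\n".join(lines)

    def to_tsv(self, path: str) -> str:
        """Write the results table; the configuration is echoed in the header."""
        with open(path, "w") as fh:
            cfg = dataclasses.asdict(self.config)
            cfg.pop("offsets", None)
            fh.write("#config: " + " ".join(f"{k}={v}" for k, v in cfg.items()) + "\n")
            self.table.to_csv(fh, sep="\t", index=False)
        return path

    def annotate_vcf(self, in_vcf: str, out_vcf: str) -> str:
        """Copy the input VCF with VAPOR_SCORE / VAPOR_GT / VAPOR_QC INFO keys.

        Records are matched to results by ID when present, else by
        (chrom, 0-based start); unmatched records pass through unchanged.
        """
        by_id = {r.sv.id: r for r in self.results if r.sv.id}
        by_pos = {(r.sv.chrom, r.sv.start): r for r in self.results}
        with pysam.VariantFile(in_vcf) as src:
            # extend the source header in place so records can carry the new
            # keys while being written out under the same header
            for key, num, typ, desc in (
                ("VAPOR_SCORE", 1, "Float", "Fraction of reads supporting the SV"),
                ("VAPOR_GT", 1, "String", "Read-support genotype"),
                ("VAPOR_QC", 1, "String", "Validation QC flag"),
            ):
                if key not in src.header.info:
                    src.header.info.add(key, num, typ, desc)
            with pysam.VariantFile(out_vcf, "w", header=src.header) as dst:
                for rec in src:
                    res = by_id.get(rec.id) or by_pos.get((rec.chrom, rec.start))
                    if res is not None:
                        if res.vapor_score is not None:
                            rec.info["VAPOR_SCORE"] = float(res.vapor_score)
                        rec.info["VAPOR_GT"] = (
                            res.genotype.gt_string if res.genotype else "./."
                        )
                        rec.info["VAPOR_QC"] = res.qc
                    dst.write(rec)
        return out_vcf

    def read_score_dump(self) -> pd.DataFrame:
        """Per-read normalized scores and per-site likelihood triples."""
        rows = []
        for r in self.results:
            for rs in r.read_scores:
                rows.append({
                    "sv_id": r.sv.label,
                    "read_id": rs.read_id,
                    "mode": rs.mode,
                    "score_o": rs.score_o,
                    "score_a": rs.score_a,
                    "normalized": rs.normalized,
                    "l_0": r.genotype.loglik[0] if r.genotype else None,
                    "l_1": r.genotype.loglik[1] if r.genotype else None,
                    "l_2": r.genotype.loglik[2] if r.genotype else None,
                })
        return pd.DataFrame(rows)


@dataclass
class BenchmarkResult:
    sensitivity: float
    fdr: float
    qc_pass_rate: float
    per_type: pd.DataFrame
    sweep: pd.DataFrame
    cutoff: float

    def __str__(self) -> str:
        return (
            f"sensitivity={self.sensitivity:.3f} fdr={self.fdr:.3f} "
            f"qc_pass_rate={self.qc_pass_rate:.3f} at cutoff {self.cutoff:g}"
        )


def benchmark(
    table: pd.DataFrame,
    is_true: Union[pd.Series, Sequence[bool]],
    cutoff: float = 0.15,
    sweep_cutoffs: Sequence[float] = tuple(np.round(np.arange(0, 1.0001, 0.05), 2)),
) -> BenchmarkResult:
    """Sensitivity / FDR / QC-pass metrics over a labelled result table.

    ``is_true`` marks rows belonging to the truth set; the remainder are the
    deliberately false (relocated) calls.  Sensitivity is computed over
    assessable true events (QC failures are reported separately through the
    QC pass rate, not silently counted as misses); FDR is the fraction of
    validated events that come from the false set.
    """
    t = table.copy()
    t["is_true"] = np.asarray(is_true, dtype=bool)
    if t["is_true"].all() or not t["is_true"].any():
        logger.warning("benchmark received only one class of events")

    def metrics(df: pd.DataFrame, cut: float) -> dict:
        true, false = df[df["is_true"]], df[~df["is_true"]]
        ok_true = true[true["qc_flag"] == QC_PASS]
        ok_false = false[false["qc_flag"] == QC_PASS]
        vt = int((ok_true["vapor_score"] > cut).sum())
        vf = int((ok_false["vapor_score"] > cut).sum())
        return {
            "n_true": len(true),
            "n_false": len(false),
            "sensitivity": vt / len(ok_true) if len(ok_true) else float("nan"),
            "fdr": vf / (vt + vf) if (vt + vf) else 0.0,
            "qc_pass_rate": (
                (len(ok_true) + len(ok_false)) / len(df) if len(df) else float("nan")
            ),
        }

    overall = metrics(t, cutoff)
    per_type = pd.DataFrame(
        [{"svtype": k, **metrics(g, cutoff)} for k, g in t.groupby("svtype")]
    )
    sweep = pd.DataFrame(
        [{"cutoff": c, **metrics(t, c)} for c in sweep_cutoffs]
    )
    return BenchmarkResult(
        sensitivity=overall["sensitivity"],
        fdr=overall["fdr"],
        qc_pass_rate=overall["qc_pass_rate"],
        per_type=per_type,
        sweep=sweep,
        cutoff=cutoff,
    )


# ---------------------------------------------------------------------------
# Functional entry points (used by the CLI)


def run_validate(
    fasta: str,
    bam: str,
    sv_path: str,
    out_dir: str,
    config: Optional[RunConfig] = None,
    sv_format: Optional[str] = None,
) -> ValidationResults:
    os.makedirs(out_dir, exist_ok=True)
    model = SVValidator.from_files(fasta, bam, sv_path, config, sv_format)
    results = model.fit()
    results.to_tsv(os.path.join(out_dir, "svrecur_results.tsv"))
    print(results.summary())
    return results


def run_simulate(cfg: SimConfig, out_dir: str) -> SimBundle:
    if cfg.depth <= 0:
        raise DataError("depth must be positive")
    bundle = simulate_bundle(cfg, out_dir)
    false_path = os.path.join(out_dir, "false_calls.tsv")
    with open(false_path, "w") as fh:
        fh.write("#chrom\tstart\tend\tsvtype\tid\textra\n")
        for sv in bundle.false_svs:
            extra = f"INSSEQ={sv.insert_seq}" if sv.insert_seq else "."
            fh.write(
                f"{sv.chrom}\t{sv.start}\t{sv.end}\t{sv.svtype.value}\t"
                f"{sv.id}\t{extra}\n"
            )
    return bundle


def run_benchmark(
    results_tsv: str, truth_path: str, cutoff: float = 0.15
) -> BenchmarkResult:
    table = pd.read_csv(results_tsv, sep="\t", comment="#")
    truth_ids = {sv.label for sv in parse_sv_records(truth_path)}
    ids = set(table["id"])
    if not ids & truth_ids:
        raise DataError("result and truth ID sets are disjoint")
    is_true = table["id"].isin(truth_ids)
    return benchmark(table, is_true, cutoff)
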