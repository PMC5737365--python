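"""Run-time configuration shared by the validator, model object and CLI."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class RunConfig:
    """Tunable parameters of the validation workflow.

    Defaults follow the published operating point of the method: k-mer
    windows grown 10->40 bp in 10-bp steps with a 40% diagonal threshold,
    >10 fully spanning reads to enter small-variant mode, reporting cutoffs
    of 0.15 on the validation score and 0.1 on the best read score, and a 5%
    per-read genotyping error rate.
    """

    flank_len: int = 800            # reference context on each side of the SV
    junction_flank: int = 400       # context on each side of a junction (LARGE mode)
    flank_margin: int = 50          # extra bases a "spanning" read must cover
    window_start: int = 10          # initial k-mer size
    window_step: int = 10
    window_max: int = 40
    diag_threshold: float = 0.40    # window QC: diagonal fraction must exceed this
    min_span_reads: int = 10        # SMALL mode needs more than this many spanning reads
    max_reads: int = 100            # deterministic per-SV read cap
    eps_div: float = 0.5            # pseudocount guarding distance-score ratios
    include_rc: bool = True         # record reverse-complement k-mer matches
    vapor_cutoff: float = 0.15      # reported PASS column on the validation score
    max_read_cutoff: float = 0.1    # reported PASS column on max read score
    eps: float = 0.05               # per-read genotyping error rate
    offsets: tuple = field(
        default_factory=lambda: tuple(range(-1000, 1001, 100))
    )                               # grid for the breakpoint offset scan
    seed: int = 0
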