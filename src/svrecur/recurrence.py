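"""k-mer recurrence (dot-plot) matrices and the adaptive window-size QC.

A recurrence matrix marks every coordinate pair ``(x, y)`` at which the
k-mer starting at read position ``x`` is identical to the reference k-mer
starting at position ``y`` (1-bp step, exact matching).  Matches between the
read and the reverse complement of the reference are recorded separately in
``rc_records``: an inverted segment shows up as an anti-diagonal of RC
matches against the unmodified reference, which is what lets the distance
scores penalise a reference that lacks the predicted inversion.

Repetitive regions flood the matrix with spurious off-diagonal matches. The
window-size QC therefore compares the reference window against itself,
starting at 10 bp and growing in 10-bp steps until the proportion of
self-matches on the diagonal exceeds 40%; if 40-bp windows still fail, the
region is non-assessable and the SV is excluded from evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from ._sequence import revcomp

NONASSESSABLE = "NONASSESSABLE"


@dataclass
class RecurrenceMatrix:
    records: set = field(default_factory=set)      # forward (x, y) matches
    rc_records: set = field(default_factory=set)   # reverse-complement matches
    window: int = 10
    read_len: int = 0
    ref_len: int = 0
    too_short: bool = False

    @property
    def n_records(self) -> int:
        return len(self.records) + len(self.rc_records)

    def all_records(self) -> Iterable[tuple[int, int]]:
        yield from self.records
        yield from self.rc_records

    def shifted(self, dx: int) -> "RecurrenceMatrix":
        """Return a copy with all read coordinates shifted by ``dx``.

        Used to express read-segment coordinates in the reference-window
        frame when a read only partially covers the window.
        """
        if dx == 0:
            return self
        return RecurrenceMatrix(
            records={(x + dx, y) for x, y in self.records},
            rc_records={(x + dx, y) for x, y in self.rc_records},
            window=self.window,
            read_len=self.read_len,
            ref_len=self.ref_len,
            too_short=self.too_short,
        )


@dataclass
class WindowQC:
    window: Optional[int]          # chosen k-mer size, None if non-assessable
    diag_fraction: float

    @property
    def assessable(self) -> bool:
        return self.window is not None

    @property
    def label(self) -> str:
        return str(self.window) if self.assessable else NONASSESSABLE


def _kmer_index(seq: str, window: int) -> dict:
    """Hash k-mer -> list of start positions; k-mers containing N are skipped."""
    index: dict = {}
    n_next = seq.find("N")
    for y in range(len(seq) - window + 1):
        while 0 <= n_next < y:
            n_next = seq.find("N", y)
        if 0 <= n_next < y + window:
            continue
        index.setdefault(seq[y : y + window], []).append(y)
    return index


def recurrence_matrix(
    read_seq: str,
    ref_seq: str,
    window: int = 10,
    include_rc: bool = True,
) -> RecurrenceMatrix:
    """Build the dot-plot matrix between a read and a reference sequence.

    ``records`` holds (x, y) iff ``read_seq[x:x+window] == ref_seq[y:y+window]``;
    ``rc_records`` (when ``include_rc``) holds pairs where the read k-mer
    equals the reverse complement of the reference k-mer at y.  Matching is
    exact and N never matches anything, including another N.
    """
    read_seq = read_seq.upper()
    ref_seq = ref_seq.upper()
    mat = RecurrenceMatrix(
        window=window, read_len=len(read_seq), ref_len=len(ref_seq)
    )
    if len(read_seq) < window or len(ref_seq) < window:
        mat.too_short = True
        return mat

    fwd = _kmer_index(ref_seq, window)
    rc = _kmer_index(revcomp(ref_seq), window) if include_rc else {}
    ref_last = len(ref_seq) - window  # RC position p maps to y = ref_last - p

    n_next = read_seq.find("N")
    for x in range(len(read_seq) - window + 1):
        while 0 <= n_next < x:
            n_next = read_seq.find("N", x)
        if 0 <= n_next < x + window:
            continue
        kmer = read_seq[x : x + window]
        for y in fwd.get(kmer, ()):
            mat.records.add((x, y))
        for p in rc.get(kmer, ()):
            mat.rc_records.add((x, ref_last - p))
    return mat


def diagonal_fraction(matrix: RecurrenceMatrix) -> float:
    """Proportion of self-match records lying on the main diagonal."""
    total = matrix.n_records
    if total == 0:
        return 0.0
    on_diag = sum(1 for x, y in matrix.records if x == y)
    return on_diag / total


def select_window_size(
    ref_seq: str,
    start_window: int = 10,
    step: int = 10,
    max_window: int = 40,
    diag_threshold: float = 0.40,
    include_rc: bool = True,
) -> WindowQC:
    """Adaptive window-size QC on the reference window against itself.

    Returns the first window size at which the diagonal fraction strictly
    exceeds ``diag_threshold``; if even ``max_window`` fails the region is
    non-assessable (``window is None``).
    """
    frac = 0.0
    for window in range(start_window, max_window + 1, step):
        if len(ref_seq) <= window:
            break
        self_mat = recurrence_matrix(ref_seq, ref_seq, window, include_rc=include_rc)
        frac = diagonal_fraction(self_mat)
        if frac > diag_threshold:
            return WindowQC(window=window, diag_fraction=frac)
    return WindowQC(window=None, diag_fraction=frac)


def write_dotplot_table(matrix: RecurrenceMatrix, path: str) -> None:
    """Export the record scatter as a plain-text x,y,strand table."""
    with open(path, "w") as fh:
        fh.write("x\ty\tstrand\n")
        for x, y in sorted(matrix.records):
            fh.write(f"{x}\t{y}\t+\n")
        for x, y in sorted(matrix.rc_records):
            fh.write(f"{x}\t{y}\t-\n")


def plot_dotplot(matrices: dict, path: Optional[str] = None, title: str = ""):
    """Scatter one or two recurrence matrices (read vs R_o / R_a) side by side.

    ``matrices`` maps a panel label to a RecurrenceMatrix.  Returns the
    matplotlib figure; saves a PNG when ``path`` is given.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(matrices), figsize=(5 * len(matrices), 5),
                             squeeze=False)
    for ax, (label, mat) in zip(axes[0], matrices.items()):
        if mat.records:
            xs, ys = zip(*sorted(mat.records))
            ax.scatter(xs, ys, s=1, c="tab:blue", label="forward")
        if mat.rc_records:
            xs, ys = zip(*sorted(mat.rc_records))
            ax.scatter(xs, ys, s=1, c="tab:red", label="revcomp")
        ax.set_xlabel("read position (bp)")
        ax.set_ylabel("reference position (bp)")
        ax.set_title(label)
        ax.legend(loc="upper left", markerscale=8)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
    return fig
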