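"""Sequence-composition diagnostics for sRNA populations.

These statistics separate degradation products (rdRNAs) from canonical
Dicer products: rdRNAs show a flat size distribution, a uracil at the
penultimate read position, an over-represented uracil 2 nt upstream of the
read in the genomic flank, and purine (A/G) enrichment; canonical siRNAs
are 23-24 nt with a 5'-uracil bias.

Reads are DNA-alphabet; "U" in outputs keys on T.  All statistics are
count-weighted over raw reads by default (a unique-sequence mode is
available where noted).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CompositionProfile",
    "size_distribution",
    "positional_composition",
    "penultimate_u_statistic",
    "five_prime_u_fraction",
    "purine_skew",
]

_BASES = "ACGT"
_B2I = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _iter_seq_count(reads):
    """Yield (sequence, count) from a DataFrame or an iterable."""
    if isinstance(reads, pd.DataFrame):
        if "count" in reads.columns:
            yield from zip(reads["sequence"], reads["count"])
        else:
            yield from ((s, 1) for s in reads["sequence"])
    else:
        for item in reads:
            if isinstance(item, tuple):
                yield item
            else:
                yield item, 1


@dataclass
class CompositionProfile:
    """Position x base frequency matrix for one read size class.

    Rows are labelled ``-w..-1`` (upstream flank), ``1..L`` (read
    positions, 5'->3' in read orientation) and ``+1..+w`` (downstream
    flank); columns are A, C, G, U.  Flank positions use genomic sequence
    strand-adjusted to the read orientation.
    """

    size_class: int
    matrix: pd.DataFrame
    n_reads: float
    flank_width: int
    n_flank_excluded: int = 0

    @property
    def empty(self) -> bool:
        return self.n_reads == 0


def size_distribution(reads) -> dict:
    """Count-weighted read-length fractions (sum to 1).

    Raises ``ValueError`` on an empty read set.
    """
    hist: dict = {}
    total = 0.0
    for seq, n in _iter_seq_count(reads):
        hist[len(seq)] = hist.get(len(seq), 0.0) + n
        total += n
    if total == 0:
        raise ValueError("size_distribution needs at least one read")
    return {L: w / total for L, w in sorted(hist.items())}


def positional_composition(
    mapped: pd.DataFrame,
    genome: dict,
    flank_width: int = 5,
    size_class: int | None = None,
    mode: str = "count",
) -> CompositionProfile:
    """Per-position base frequencies of reads of one size, with genomic flanks.

    ``mapped`` is a placement table (contig, start, end, strand, count);
    minus-strand reads use the reverse-complemented genomic context, so
    position 1 is always the read's 5' end.  Reads whose flank window runs
    off the contig contribute to read positions but are excluded from the
    flank columns (tallied in ``n_flank_excluded``).

    ``mode``: ``count`` weights by read count (raw-read logos), ``unique``
    gives each placement weight 1.
    """
    if size_class is None:
        raise ValueError("size_class is required")
    if mode not in ("count", "unique"):
        raise ValueError("mode must be 'count' or 'unique'")
    L = int(size_class)
    w = int(flank_width)
    npos = L + 2 * w
    counts = np.zeros((npos, 4))
    coverage = np.zeros(npos)
    n_reads = 0.0
    n_flank_excluded = 0

    sub = mapped[(mapped["end"] - mapped["start"]) == L]
    for row in sub.itertuples(index=False):
        weight = float(row.count) if mode == "count" else 1.0
        contig_seq = genome[row.contig]
        has_flank = row.start - w >= 0 and row.end + w <= len(contig_seq)
        if has_flank:
            ctx = contig_seq[row.start - w : row.end + w]
        else:
            ctx = contig_seq[row.start : row.end]
        ctx = ctx.upper()
        if row.strand == "-":
            ctx = _revcomp(ctx)
        if has_flank:
            offset = 0
        else:
            offset = w  # read-only context sits at matrix rows w..w+L
            n_flank_excluded += 1
        for i, base in enumerate(ctx):
            j = _B2I.get(base)
            if j is None:
                continue
            counts[offset + i, j] += weight
            coverage[offset + i] += weight
        n_reads += weight

    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where(coverage[:, None] > 0, counts / coverage[:, None], np.nan)
    labels = (
        [str(-i) for i in range(w, 0, -1)]
        + [str(i) for i in range(1, L + 1)]
        + [f"+{i}" for i in range(1, w + 1)]
    )
    matrix = pd.DataFrame(freqs, index=labels, columns=["A", "C", "G", "U"])
    return CompositionProfile(
        size_class=L,
        matrix=matrix,
        n_reads=n_reads,
        flank_width=w,
        n_flank_excluded=n_flank_excluded,
    )


def penultimate_u_statistic(reads) -> tuple[float, float]:
    """Fraction of reads with U at the penultimate position, and enrichment.

    The penultimate position is the second-to-last base (index L-2,
    0-based).  Enrichment is that fraction divided by the mean U frequency
    over all *other* read positions (count-weighted, pooled over reads);
    values near 1 indicate no positional bias.
    """
    w_total = 0.0
    w_penult_u = 0.0
    other_u = 0.0
    other_n = 0.0
    for seq, n in _iter_seq_count(reads):
        L = len(seq)
        if L < 2:
            continue
        w_total += n
        if seq[L - 2] in "TU":
            w_penult_u += n
        for i, b in enumerate(seq):
            if i == L - 2:
                continue
            other_n += n
            if b in "TU":
                other_u += n
    if w_total == 0:
        raise ValueError("penultimate_u_statistic needs at least one read")
    frac = w_penult_u / w_total
    base_rate = other_u / other_n if other_n else np.nan
    enrichment = frac / base_rate if base_rate and base_rate > 0 else np.inf
    return frac, enrichment


def five_prime_u_fraction(reads) -> float:
    """Count-weighted share of reads whose 5' base is U."""
    w_total = 0.0
    w_u = 0.0
    for seq, n in _iter_seq_count(reads):
        if not seq:
            continue
        w_total += n
        if seq[0] in "TU":
            w_u += n
    if w_total == 0:
        raise ValueError("five_prime_u_fraction needs at least one read")
    return w_u / w_total


def purine_skew(reads) -> float:
    """Count-weighted A+G fraction over all read positions."""
    total = 0.0
    purine = 0.0
    for seq, n in _iter_seq_count(reads):
        for b in seq:
            if b in "ACGTU":
                total += n
                if b in "AG":
                    purine += n
    if total == 0:
        raise ValueError("purine_skew needs at least one read")
    return purine / total
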