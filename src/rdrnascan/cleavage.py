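"""Mechanistic U+2 cleavage model.

The degradation pathway modelled here posits an RNase that cleaves a
transcript two nucleotides downstream of any uracil.  Two consecutive cuts
release a fragment whose length equals the distance between the two
generating uracils; fragments whose length falls inside the sRNA library
window (18-24 nt by default) are the ones observable by small-RNA
sequencing.  A direct consequence of the cut offset is that every
cut-delimited fragment carries a uracil at its penultimate position, and
the uracil that generated the fragment's 5' cut sits 2 nt upstream of the
fragment in the flanking sequence.

All sequences are handled in DNA alphabet (T stands for U).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "CleavageModelConfig",
    "CleavageReport",
    "predict_cut_sites",
    "fragment_spectrum",
    "consistency_score",
]

_U_BASES = frozenset("TUtu")


@dataclass(frozen=True)
class CleavageModelConfig:
    """Parameters of the U+2 cleavage model.

    offset
        Cut falls this many nucleotides downstream of a uracil; a cut at
        position ``c`` separates transcript indices ``c-1`` and ``c``
        (0-based).  Default 2.
    eligible_range
        Closed interval ``[L_min, L_max]`` of fragment lengths that enter
        the sequencing library.  Default (18, 24).
    """

    offset: int = 2
    eligible_range: tuple[int, int] = (18, 24)

    def __post_init__(self) -> None:
        if self.offset < 0:
            raise ValueError("cut offset must be >= 0")
        lo, hi = self.eligible_range
        if lo > hi or lo < 1:
            raise ValueError("eligible_range must satisfy 1 <= L_min <= L_max")


DEFAULT_CONFIG = CleavageModelConfig()


@dataclass
class CleavageReport:
    """Per-transcript summary of how well a read population fits the model."""

    cut_sites: list[int]
    n_reads: float  # count-weighted sense reads scored
    n_antisense: float  # count-weighted antisense reads (not scored, lower trust)
    frac_five_prime_at_cut: float | None
    frac_three_prime_at_cut: float | None
    frac_penultimate_u: float | None
    score: float | None  # fraction of sense reads with BOTH ends at predicted cuts
    per_read: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_dict(self) -> dict:
        return {
            "n_cut_sites": len(self.cut_sites),
            "n_reads": self.n_reads,
            "n_antisense": self.n_antisense,
            "frac_five_prime_at_cut": self.frac_five_prime_at_cut,
            "frac_three_prime_at_cut": self.frac_three_prime_at_cut,
            "frac_penultimate_u": self.frac_penultimate_u,
            "score": self.score,
        }


def predict_cut_sites(
    transcript: str, config: CleavageModelConfig = DEFAULT_CONFIG
) -> list[int]:
    """Predicted cut positions on a transcript (sense strand, 5'->3').

    A cut at position ``c`` lies between indices ``c-1`` and ``c``; one is
    predicted at ``i + offset`` for every uracil index ``i``.  Cuts that
    would fall beyond the transcript end are clipped (dropped).
    """
    L = len(transcript)
    d = config.offset
    return [i + d for i, base in enumerate(transcript) if base in _U_BASES and i + d <= L]


def fragment_spectrum(
    transcript: str, config: CleavageModelConfig = DEFAULT_CONFIG
) -> list[tuple[int, int]]:
    """Fragments released by exhaustive cleavage, restricted to the library window.

    Returns half-open intervals ``(start, end)`` between *consecutive* cut
    sites with ``end - start`` inside ``eligible_range``.  Each returned
    fragment has a uracil at its penultimate position — a theorem of the
    model (cut offset 2) that is asserted here.
    """
    cuts = predict_cut_sites(transcript, config)
    lo, hi = config.eligible_range
    frags: list[tuple[int, int]] = []
    for a, b in zip(cuts, cuts[1:]):
        if lo <= b - a <= hi:
            if config.offset == 2:
                assert transcript[b - 2] in _U_BASES, "model violation: no penultimate U"
            frags.append((a, b))
    return frags


def composite_fragments(
    transcript: str,
    efficiency: float,
    config: CleavageModelConfig = DEFAULT_CONFIG,
    max_skip: int = 8,
) -> tuple[list[tuple[int, int]], list[float]]:
    """Eligible fragments and their relative weights under partial cleavage.

    With per-cut efficiency ``e`` each predicted cut is made independently
    with probability ``e``; a fragment delimited by cuts ``i`` and ``j``
    (skipping ``j-i-1`` intermediate cuts) occurs with relative weight
    ``e^2 (1-e)^(j-i-1)``.  Fragments are filtered to ``eligible_range``.
    ``max_skip`` bounds the number of skipped cuts considered (the weight
    decays geometrically).
    """
    if not 0.0 < efficiency <= 1.0:
        raise ValueError("efficiency must be in (0, 1]")
    cuts = predict_cut_sites(transcript, config)
    lo, hi = config.eligible_range
    frags: list[tuple[int, int]] = []
    weights: list[float] = []
    miss = 1.0 - efficiency
    for ii, a in enumerate(cuts):
        for jj in range(ii + 1, min(ii + 2 + max_skip, len(cuts))):
            b = cuts[jj]
            if b - a > hi:
                break
            if b - a < lo:
                continue
            frags.append((a, b))
            weights.append(efficiency * efficiency * miss ** (jj - ii - 1))
    return frags, weights


def consistency_score(
    reads,
    transcript: str,
    config: CleavageModelConfig = DEFAULT_CONFIG,
) -> CleavageReport:
    """Score an observed read population against the U+2 model.

    Parameters
    ----------
    reads
        Iterable of ``(start, end, strand, count)`` in transcript
        coordinates (0-based half-open; strand ``+`` = sense to the
        transcript), or a DataFrame with those columns.  Antisense reads
        are tallied separately and never credited.
    transcript
        Sense-strand sequence of the substrate.

    Returns a :class:`CleavageReport`; the overall ``score`` is the
    count-weighted fraction of sense reads whose 5' **and** 3' ends both
    coincide with predicted cut positions.  The two end conditions are also
    reported separately (real 3' ends could be trimmed exonucleolytically,
    which would break only one of them).
    """
    if isinstance(reads, pd.DataFrame):
        rows = reads[["start", "end", "strand", "count"]].itertuples(index=False)
    else:
        rows = iter(reads)
    cutset = set(predict_cut_sites(transcript, config))
    L = len(transcript)
    recs = []
    w_sense = 0.0
    w_anti = 0.0
    w5 = w3 = wpu = wboth = 0.0
    for start, end, strand, count in rows:
        if strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {strand!r}")
        if not (0 <= start < end <= L):
            raise ValueError(
                f"read [{start},{end}) outside transcript of length {L}"
            )
        if strand == "-":
            w_anti += count
            continue
        at5 = start in cutset
        at3 = end in cutset
        pu = transcript[end - 2] in _U_BASES if end - start >= 2 else False
        w_sense += count
        w5 += count * at5
        w3 += count * at3
        wpu += count * pu
        wboth += count * (at5 and at3)
        recs.append((start, end, count, at5, at3, pu))
    per_read = pd.DataFrame(
        recs,
        columns=["start", "end", "count", "five_prime_at_cut", "three_prime_at_cut", "penultimate_u"],
    )
    if w_sense > 0:
        report = CleavageReport(
            cut_sites=sorted(cutset),
            n_reads=w_sense,
            n_antisense=w_anti,
            frac_five_prime_at_cut=w5 / w_sense,
            frac_three_prime_at_cut=w3 / w_sense,
            frac_penultimate_u=wpu / w_sense,
            score=wboth / w_sense,
            per_read=per_read,
        )
    else:
        report = CleavageReport(
            cut_sites=sorted(cutset),
            n_reads=0.0,
            n_antisense=w_anti,
            frac_five_prime_at_cut=None,
            frac_three_prime_at_cut=None,
            frac_penultimate_u=None,
            score=None,
            per_read=per_read,
        )
    return report
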