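"""Exact (optionally 1-mismatch) short-read matching against a small genome.

Collapsed 18-25 nt reads are placed on both strands of the genome with a
sorted-array k-mer seed index (2-bit encoded, numpy searchsorted) followed
by full verification of every candidate placement against the genome
sequence.  Multi-mapping reads are resolved by a configurable policy; the
default ``fractional`` policy splits a read's count equally across its
placements so that total mapped weight is conserved for normalisation.
"""

from __future__ import annotations

import logging
from collections import Counter

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenomeIndex",
    "build_index",
    "collapse_reads",
    "map_reads",
    "MULTIMAP_POLICIES",
]

MULTIMAP_POLICIES = ("fractional", "unique-only", "all")

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


class GenomeIndex:
    """Sorted k-mer index over the forward strand of all contigs.

    Contigs are concatenated with runs of ``N`` as separators (so no k-mer
    spans two contigs); every valid k-mer's 2-bit code is stored in a
    sorted array next to its global position.  Lookups binary-search the
    code; reverse-strand placements are found by querying the reverse
    complement of the read.
    """

    def __init__(self, genome: dict, k: int = 12):
        if k < 8:
            raise ValueError("seed length k < 8 is too unspecific")
        self.k = k
        self.contigs = list(genome)
        sep = "N" * k
        self._cat = sep.join(genome[c].upper() for c in self.contigs)
        lens = [len(genome[c]) for c in self.contigs]
        offsets = []
        off = 0
        for L in lens:
            offsets.append(off)
            off += L + k
        self._offsets = np.array(offsets, dtype=np.int64)
        self._lens = np.array(lens, dtype=np.int64)

        arr = _encode(self._cat)
        n = len(arr)
        if n >= k:
            m = n - k + 1
            code = np.zeros(m, dtype=np.uint64)
            for j in range(k):
                code = (code << np.uint64(2)) | arr[j : j + m].astype(np.uint64)
            bad = (arr >= 4).astype(np.int32)
            cs = np.concatenate([[0], np.cumsum(bad)])
            valid = (cs[k:] - cs[:-k]) == 0
            codes = code[valid]
            pos = np.nonzero(valid)[0].astype(np.int64)
            order = np.argsort(codes, kind="stable")
            self._codes = codes[order]
            self._pos = pos[order]
        else:
            self._codes = np.empty(0, dtype=np.uint64)
            self._pos = np.empty(0, dtype=np.int64)
        self._arr = arr

    def seed_positions(self, code: int) -> np.ndarray:
        """Global forward-strand positions of an encoded k-mer."""
        lo = np.searchsorted(self._codes, code, side="left")
        hi = np.searchsorted(self._codes, code, side="right")
        return self._pos[lo:hi]

    def to_contig(self, gpos: int) -> tuple[str, int]:
        ci = int(np.searchsorted(self._offsets, gpos, side="right")) - 1
        local = gpos - int(self._offsets[ci])
        return self.contigs[ci], local

    def in_bounds(self, gpos: int, length: int) -> bool:
        ci = int(np.searchsorted(self._offsets, gpos, side="right")) - 1
        local = gpos - int(self._offsets[ci])
        return 0 <= local and local + length <= int(self._lens[ci])


def build_index(genome: dict, k: int = 12) -> GenomeIndex:
    """Build an exact-match index over ``genome`` (contig -> sequence)."""
    return GenomeIndex(genome, k=k)


def collapse_reads(raw_reads, library_id: str) -> tuple[pd.DataFrame, dict]:
    """Collapse raw reads to one record per unique (upper-cased) sequence.

    ``raw_reads`` is an iterable of sequences or of ``(sequence, count)``
    pairs.  Records containing characters outside A/C/G/T/N are rejected
    and tallied.  Returns the collapsed table (columns sequence, count,
    library_id) and a stats dict; total accepted count is conserved.
    """
    counter: Counter = Counter()
    rejected = 0
    total_in = 0
    allowed = set("ACGTN")
    for item in raw_reads:
        if isinstance(item, tuple):
            seq, n = item
        else:
            seq, n = item, 1
        total_in += n
        seq = seq.upper()
        if not set(seq) <= allowed:
            rejected += n
            continue
        counter[seq] += n
    if rejected:
        logger.warning(
            "%s: rejected %d reads with non-ACGTN characters", library_id, rejected
        )
    df = pd.DataFrame(
        sorted(counter.items()), columns=["sequence", "count"]
    )
    df["library_id"] = library_id
    stats = {
        "library_id": library_id,
        "total_reads": total_in,
        "accepted_reads": total_in - rejected,
        "rejected_alphabet": rejected,
        "unique_sequences": len(df),
    }
    return df, stats


def _seed_code_matrix(seeds: list[str], k: int) -> tuple[np.ndarray, np.ndarray]:
    arr = _CODE[
        np.frombuffer("".join(seeds).encode("ascii"), dtype=np.uint8)
    ].reshape(len(seeds), k)
    valid = (arr < 4).all(axis=1)
    code = np.zeros(len(seeds), dtype=np.uint64)
    for j in range(k):
        code = (code << np.uint64(2)) | arr[:, j].astype(np.uint64)
    return code, valid


def _hits_for_sequence(
    index: GenomeIndex,
    seq: str,
    positions: np.ndarray,
    max_mismatches: int,
) -> list[int]:
    """Verify candidate global positions; return those matching the genome."""
    L = len(seq)
    cat = index._cat
    out = []
    for p in positions.tolist():
        p0 = int(p)
        if not index.in_bounds(p0, L):
            continue
        sub = cat[p0 : p0 + L]
        if max_mismatches == 0:
            if sub == seq:
                out.append(p0)
        else:
            if sum(a != b for a, b in zip(sub, seq)) <= max_mismatches and "N" not in sub:
                out.append(p0)
    return out


def map_reads(
    reads: pd.DataFrame,
    index: GenomeIndex,
    max_mismatches: int = 0,
    multimap_policy: str = "fractional",
    length_window: tuple[int, int] = (18, 25),
) -> tuple[pd.DataFrame, dict]:
    """Place collapsed reads on the genome.

    Parameters
    ----------
    reads
        Collapsed reads (columns sequence, count, library_id).
    max_mismatches
        0 (default) for exact matching; 1 allows a single substitution
        (requires ``index.k <= min_read_length // 2`` so the two-seed
        lookup is exhaustive).
    multimap_policy
        ``fractional`` (count split equally over all placements),
        ``unique-only`` (multi-mappers dropped), or ``all`` (full count at
        every placement).

    Returns the placement table (columns contig, start, end, strand,
    sequence, count, library_id, n_hits, weight) and a stats dict.
    Placements are fully verified against the genome sequence.
    """
    if multimap_policy not in MULTIMAP_POLICIES:
        raise ValueError(f"unknown multimap_policy {multimap_policy!r}")
    if max_mismatches not in (0, 1):
        raise ValueError("max_mismatches must be 0 or 1")
    lo, hi = length_window
    k = index.k

    work = reads[(reads["sequence"].str.len() >= lo) & (reads["sequence"].str.len() <= hi)]
    n_len_filtered = int(reads["count"].sum() - work["count"].sum())
    if max_mismatches == 1 and work.shape[0] and k > lo // 2:
        raise ValueError(
            f"1-mismatch mapping needs seed k <= {lo // 2} (index has k={k}); "
            "rebuild the index with a smaller k"
        )

    seqs = work["sequence"].tolist()
    counts = work["count"].to_numpy()
    libs = work["library_id"].tolist()

    rows = []
    n_unmapped = 0
    w_unmapped = 0
    n_multimapped_dropped = 0
    if seqs:
        fwd_seeds = [s[:k] for s in seqs]
        rc_full = [_revcomp(s) for s in seqs]
        rc_seeds = [s[:k] for s in rc_full]
        fcode, fvalid = _seed_code_matrix(fwd_seeds, k)
        rcode, rvalid = _seed_code_matrix(rc_seeds, k)
        # optional second seed (read tail) for 1-mismatch exhaustiveness
        if max_mismatches == 1:
            f2 = [s[-k:] for s in seqs]
            r2 = [s[-k:] for s in rc_full]
            f2code, f2valid = _seed_code_matrix(f2, k)
            r2code, r2valid = _seed_code_matrix(r2, k)

        for i, seq in enumerate(seqs):
            L = len(seq)
            hits: list[tuple[int, str]] = []
            # forward strand: read equals genome substring
            cand = index.seed_positions(fcode[i]) if fvalid[i] else np.empty(0, int)
            if max_mismatches == 1 and f2valid[i]:
                cand = np.union1d(cand, index.seed_positions(f2code[i]) - (L - k))
            for p in _hits_for_sequence(index, seq, cand, max_mismatches):
                hits.append((p, "+"))
            # reverse strand: revcomp(read) equals genome substring
            rc = rc_full[i]
            cand = index.seed_positions(rcode[i]) if rvalid[i] else np.empty(0, int)
            if max_mismatches == 1 and r2valid[i]:
                cand = np.union1d(cand, index.seed_positions(r2code[i]) - (L - k))
            for p in _hits_for_sequence(index, rc, cand, max_mismatches):
                hits.append((p, "-"))

            n_hits = len(hits)
            if n_hits == 0:
                n_unmapped += 1
                w_unmapped += int(counts[i])
                continue
            if multimap_policy == "unique-only" and n_hits > 1:
                n_multimapped_dropped += 1
                continue
            if multimap_policy == "fractional":
                weight = counts[i] / n_hits
            else:
                weight = float(counts[i])
            for p, strand in hits:
                contig, local = index.to_contig(p)
                rows.append(
                    (contig, local, local + L, strand, seq, int(counts[i]), libs[i], n_hits, weight)
                )

    mapped = pd.DataFrame(
        rows,
        columns=[
            "contig", "start", "end", "strand", "sequence",
            "count", "library_id", "n_hits", "weight",
        ],
    )
    stats = {
        "input_sequences": int(reads.shape[0]),
        "length_filtered_count": n_len_filtered,
        "unmapped_sequences": n_unmapped,
        "unmapped_count": w_unmapped,
        "multimapped_dropped": n_multimapped_dropped,
        "mapped_weight": float(mapped["weight"].sum()) if len(mapped) else 0.0,
    }
    if n_unmapped:
        logger.info("%d sequences (%d reads) did not map", n_unmapped, w_unmapped)
    return mapped, stats
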