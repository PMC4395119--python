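"""Synthetic genomes, annotations and genotype-specific sRNA libraries.

The generator embodies the two biogenesis routes the downstream analysis is
designed to distinguish:

* **rdRNAs** — mRNA degradation fragments produced by an RNase cutting two
  nucleotides downstream of uracils.  Sense-only, flat length spectrum over
  the library window, uracil at the penultimate position.  Their
  accumulation requires RdRP-1 and/or RdRP-2 and the RNase R3B2, but no
  Dicer.
* **ex-siRNAs** — canonical Dicer products: 23-24 nt, mixed strands, 5'-U
  bias, classified I-IV by which silencing genes their biogenesis needs.

Each planted locus carries a per-genotype abundance multiplier (1 for
unaffected genotypes, 1/8 by default for genotypes the class depends on);
libraries are realised multinomially at a fixed sequencing depth, so the
depletion thresholds, the 50-RPM wild-type floor and the fold-change
classifier can all be exercised against a known truth table.

All on-disk sequence is DNA alphabet (T, not U).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cleavage import CleavageModelConfig, composite_fragments

__all__ = [
    "GENOTYPES",
    "CLASS_LABELS",
    "SimConfig",
    "SimulatedDataset",
    "generate_genome",
    "simulate_rdrna_reads",
    "simulate_exsirna_reads",
    "emit_libraries",
]

GENOTYPES = (
    "WT",
    "dcl1",
    "dcl2",
    "dcl1dcl2",
    "rdrp1",
    "rdrp2",
    "r3b2",
    "WT_ago1ip",
    "ago1_ago1ip",
)

#: closed vocabulary of planted-locus classes
CLASS_LABELS = (
    "rdRNA-rdrp1",
    "rdRNA-rdrp2",
    "rdRNA-both",
    "exsiRNA-I",
    "exsiRNA-II",
    "exsiRNA-III",
    "exsiRNA-IV",
    "background",
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: coarse functional-class vocabulary used for the annotation's kog_class
#: attribute (a thinned-down KOG catalogue; "" means not annotated)
KOG_CLASSES = (
    "Coenzyme transport and metabolism",
    "Cytoskeleton",
    "Inorganic ion transport and metabolism",
    "Intracellular trafficking and secretion",
    "Secondary metabolites biosynthesis, transport and catabolism",
    "Translation, ribosomal structure and biogenesis",
    "Energy production and conversion",
    "Amino acid transport and metabolism",
    "Signal transduction mechanisms",
    "Posttranslational modification, protein turnover, chaperones",
)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SimConfig:
    """Study design of a simulated experiment.

    Defaults reproduce the conditions the recovery analysis assumes: nine
    genotype libraries at depth 10^6, >=50 planted loci per class, and a
    1/8 abundance multiplier in dependent genotypes (comfortably past the
    fourfold classification threshold).
    """

    genome_length: int = 900_000
    n_contigs: int = 3
    gc_content: float = 0.40
    n_exon_features: int = 420
    n_transposon_features: int = 20
    n_rdrna_loci: dict = field(
        default_factory=lambda: {"rdrp1": 50, "rdrp2": 50, "both": 50}
    )
    n_exsirna_loci: dict = field(
        default_factory=lambda: {"I": 50, "II": 50, "III": 50, "IV": 50}
    )
    n_background_loci: int = 100
    #: share of WT library mass carried by the unaffected background loci;
    #: genome-wide sRNA libraries are dominated by loci the mutations do
    #: not touch, which keeps RPM renormalisation shifts small in mutants
    background_mass_frac: float = 0.7
    library_depth: int = 1_000_000
    genotypes: tuple = GENOTYPES
    #: share of each library placed uniformly on the genome (unstructured
    #: degradation noise); kept thin so that noise alone cannot bridge
    #: planted loci under the 200-bp merge rule
    uniform_noise_frac: float = 2e-4
    depleted_multiplier: float = 0.125
    ago1_enrichment: float = 8.0
    #: fraction of each class's loci that additionally depend on the RNase
    #: R3B2 (depleted in the r3b2 library); mirrors the graded involvement
    #: of the RNase across classes
    r3b2_dependent_frac: dict = field(
        default_factory=lambda: {
            "rdRNA-rdrp1": 1.0,
            "rdRNA-rdrp2": 1.0,
            "rdRNA-both": 1.0,
            "exsiRNA-I": 0.33,
            "exsiRNA-II": 0.66,
            "exsiRNA-III": 1.0,
            "exsiRNA-IV": 0.8,
            "background": 0.0,
        }
    )
    cut_efficiency: float = 0.9
    eligible_range: tuple = (18, 24)
    exsi_size_dist: dict = field(default_factory=lambda: {23: 0.5, 24: 0.5})
    exsi_strand_mix: float = 0.5
    exsi_five_prime_u_prob: float = 0.9
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length <= 0 or self.n_contigs <= 0:
            raise ValueError("genome_length and n_contigs must be positive")
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must be in [0, 1]")
        if self.library_depth < 0:
            raise ValueError("library_depth must be >= 0")
        if "WT" not in self.genotypes:
            raise ValueError("genotypes must include WT")
        if abs(sum(self.exsi_size_dist.values()) - 1.0) > 1e-9:
            raise ValueError("exsi_size_dist must sum to 1")


@dataclass
class SimulatedDataset:
    """A generated genome with its annotation and planted-locus truth table."""

    genome: dict  # contig -> sequence (str)
    features: pd.DataFrame  # feature_id, contig, start, end, strand, category, kog_class
    truth: pd.DataFrame  # one row per planted locus (SimTruth)
    config: SimConfig

    def locus_sequence(self, row) -> str:
        """Locus sequence in transcript (feature-sense) orientation."""
        seq = self.genome[row.contig][row.start : row.end]
        return revcomp(seq) if row.strand == "-" else seq


# ---------------------------------------------------------------------------
# genotype effects
# ---------------------------------------------------------------------------

_DEPLETED_GENOTYPES = {
    "rdRNA-rdrp1": ("rdrp1",),
    "rdRNA-rdrp2": ("rdrp2",),
    "rdRNA-both": ("rdrp1", "rdrp2"),
    "exsiRNA-I": ("dcl2", "dcl1dcl2", "rdrp2"),
    "exsiRNA-II": ("dcl2", "dcl1dcl2", "rdrp1"),
    "exsiRNA-III": ("dcl1dcl2", "rdrp1", "rdrp2"),
    "exsiRNA-IV": ("dcl1", "dcl1dcl2", "rdrp1", "rdrp2"),
    "background": (),
}

_AGO1_BOUND_CLASSES = {"exsiRNA-I", "exsiRNA-II"}


def class_multipliers(
    label: str,
    r3b2_dependent: bool,
    config: SimConfig,
    rng: np.random.Generator,
) -> dict:
    """Per-genotype expected abundance relative to WT for one locus.

    Dependent genotypes get ``depleted_multiplier`` (<= 1/4); unaffected
    genotypes get a mild jitter inside the no-change band [1/2, 2]; WT is
    exactly 1.  Ago-1-bound classes are up-weighted in the WT IP library.
    """
    dep = config.depleted_multiplier
    mult = {}
    depleted = set(_DEPLETED_GENOTYPES[label])
    if r3b2_dependent:
        depleted.add("r3b2")
    for g in config.genotypes:
        if g == "WT":
            mult[g] = 1.0
        elif g in depleted:
            mult[g] = dep
        elif g == "WT_ago1ip" and label in _AGO1_BOUND_CLASSES:
            mult[g] = config.ago1_enrichment
        else:
            mult[g] = float(np.clip(rng.lognormal(0.0, 0.12), 0.55, 1.8))
    return mult


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


def _design_rdrna_segment(rng: np.random.Generator, length: int) -> str:
    """Sequence whose uracils are spaced 18-24 nt apart.

    Under exhaustive U+2 cleavage every released fragment then falls in the
    sequencing window, giving the flat size spectrum and penultimate-U
    signature characteristic of the degradation products.  Non-U positions
    are purine-biased (A/G), echoing the composition skew of real sRNA
    populations.
    """
    t_pos = []
    p = int(rng.integers(2, 8))
    while p < length - 2:
        t_pos.append(p)
        p += int(rng.integers(18, 25))
    bases = np.array(list("ACG"))[
        rng.choice(3, size=length, p=[0.45, 0.20, 0.35])
    ]
    seq = list("".join(bases))
    for t in t_pos:
        seq[t] = "T"
    return "".join(seq)


def generate_genome(config: SimConfig) -> SimulatedDataset:
    """Build a genome, its feature annotation, and the planted-locus truth.

    Features (exons, transposons) and intergenic background segments are
    laid down left to right with >=300 nt spacing, distributed round-robin
    across contigs.  Planted loci sit strictly inside their host feature
    (or intergenic segment), so locus boundaries never touch and each locus
    overlaps exactly one annotated feature.

    Raises
    ------
    ValueError
        If the requested features do not fit in ``genome_length`` (the
        message names the limiting parameter), or if more loci are
        requested than exon features to host them.
    """
    rng = np.random.default_rng(config.rng_seed)

    locus_plan: list[str] = []
    for sub, n in sorted(config.n_rdrna_loci.items()):
        locus_plan += [f"rdRNA-{sub}"] * int(n)
    for sub, n in sorted(config.n_exsirna_loci.items()):
        locus_plan += [f"exsiRNA-{sub}"] * int(n)
    for lab in locus_plan:
        if lab not in CLASS_LABELS:
            raise ValueError(f"unknown locus class {lab}")
    if len(locus_plan) > config.n_exon_features:
        raise ValueError(
            "capacity error: n_exon_features too small to host "
            f"{len(locus_plan)} planted loci"
        )

    # items to place: exons (planted first), transposons, intergenic
    # background segments; shuffled so classes are interleaved on the genome
    items = []
    for i in range(config.n_exon_features):
        label = locus_plan[i] if i < len(locus_plan) else None
        length = int(rng.integers(700, 1101))
        items.append(["exon", length, label])
    for _ in range(config.n_transposon_features):
        items.append(["transposon", int(rng.integers(400, 801)), None])
    for _ in range(config.n_background_loci):
        items.append(["bg_segment", int(rng.integers(150, 251)), "background"])
    order = rng.permutation(len(items))
    items = [items[i] for i in order]

    spacing = 300
    need = sum(it[1] + spacing for it in items) + spacing * config.n_contigs
    if need > config.genome_length:
        raise ValueError(
            "capacity error: genome_length too small for requested features "
            f"(need >= {need} nt; limiting parameter: genome_length or "
            "n_exon_features/n_transposon_features/n_background_loci)"
        )

    contig_len = config.genome_length // config.n_contigs
    contigs = [f"contig_{i+1}" for i in range(config.n_contigs)]
    parts: dict = {c: [] for c in contigs}
    cursor = {c: 0 for c in contigs}

    feat_rows = []
    truth_rows = []
    n_feat = {"exon": 0, "transposon": 0}
    n_locus = 0
    ci = 0
    for kind, length, label in items:
        # round-robin over contigs; skip contigs that are full
        placed = False
        for _ in range(config.n_contigs):
            c = contigs[ci % config.n_contigs]
            ci += 1
            gap = spacing + int(rng.integers(0, 150))
            if cursor[c] + gap + length <= contig_len:
                placed = True
                break
        if not placed:
            raise ValueError(
                "capacity error: contigs exhausted; limiting parameter: "
                "genome_length"
            )
        parts[c].append(_random_seq(rng, gap, config.gc_content))
        start = cursor[c] + gap
        end = start + length
        cursor[c] = end
        strand = "+" if rng.random() < 0.5 else "-"

        if kind in ("exon", "transposon"):
            n_feat[kind] += 1
            fid = (
                f"gene_{n_feat['exon']:04d}"
                if kind == "exon"
                else f"TE_{n_feat['transposon']:04d}"
            )
        else:
            fid = ""

        seq = _random_seq(rng, length, config.gc_content)
        locus_interval = None
        if label is not None and label.startswith("rdRNA"):
            seg_len = 320
            off = int(rng.integers(50, length - seg_len - 50))
            segment = _design_rdrna_segment(rng, seg_len)
            # segment is written in transcript orientation
            if strand == "+":
                seq = seq[:off] + segment + seq[off + seg_len :]
                locus_interval = (start + off, start + off + seg_len)
            else:
                seq = seq[:off] + revcomp(segment) + seq[off + seg_len :]
                locus_interval = (end - off - seg_len, end - off)
        elif label is not None and label.startswith("exsiRNA"):
            loc_len = int(rng.integers(150, 301))
            off = int(rng.integers(50, length - loc_len - 50))
            locus_interval = (start + off, start + off + loc_len)
        elif label == "background":
            locus_interval = (start, end)
            strand = "+"  # intergenic loci have no transcript orientation

        parts[c].append(seq)

        if kind in ("exon", "transposon"):
            kog = ""
            if kind == "exon":
                # planted degradation targets are enriched for one class so
                # the functional-enrichment stage has signal to find
                if label is not None and label.startswith("rdRNA"):
                    if rng.random() < 0.20:
                        kog = KOG_CLASSES[0]
                    elif rng.random() < 0.70:
                        kog = KOG_CLASSES[int(rng.integers(1, len(KOG_CLASSES)))]
                else:
                    if rng.random() < 0.02:
                        kog = KOG_CLASSES[0]
                    elif rng.random() < 0.75:
                        kog = KOG_CLASSES[int(rng.integers(1, len(KOG_CLASSES)))]
            feat_rows.append((fid, c, start, end, strand, kind, kog))

        if label is not None:
            n_locus += 1
            r3b2_dep = rng.random() < config.r3b2_dependent_frac.get(label, 0.0)
            mult = class_multipliers(label, r3b2_dep, config, rng)
            weight = float(
                rng.lognormal(0.0, 0.5) if label != "background" else rng.lognormal(0.0, 2.0)
            )
            row = {
                "locus_id": f"sim_locus_{n_locus:04d}",
                "contig": c,
                "start": locus_interval[0],
                "end": locus_interval[1],
                "strand": strand,
                "category": "exon" if kind == "exon" else "intergenic",
                "feature_id": fid,
                "class_label": label,
                "weight": weight,
                "r3b2_dependent": bool(r3b2_dep),
                "ago1_bound": label in _AGO1_BOUND_CLASSES,
            }
            for g in config.genotypes:
                row[f"mult_{g}"] = mult[g]
            truth_rows.append(row)

    # tail sequence after the last feature of each contig
    genome = {}
    for c in contigs:
        tail = contig_len - cursor[c]
        if tail > 0:
            parts[c].append(_random_seq(rng, tail, config.gc_content))
        genome[c] = "".join(parts[c])

    features = pd.DataFrame(
        feat_rows,
        columns=["feature_id", "contig", "start", "end", "strand", "category", "kog_class"],
    )
    truth_cols = [
        "locus_id", "contig", "start", "end", "strand", "category", "feature_id",
        "class_label", "weight", "r3b2_dependent", "ago1_bound",
    ] + [f"mult_{g}" for g in config.genotypes]
    truth = pd.DataFrame(truth_rows, columns=truth_cols)
    # rescale weights so background loci carry `background_mass_frac` of the
    # WT library and planted class loci the rest
    if len(truth):
        is_bg = truth["class_label"] == "background"
        w = truth["weight"].to_numpy(dtype=float)
        if is_bg.any() and (~is_bg).any():
            w[is_bg.to_numpy()] *= config.background_mass_frac / w[is_bg.to_numpy()].sum()
            w[~is_bg.to_numpy()] *= (1.0 - config.background_mass_frac) / w[
                ~is_bg.to_numpy()
            ].sum()
            truth["weight"] = w
    truth = truth.sort_values(["contig", "start"], ignore_index=True)
    return SimulatedDataset(genome=genome, features=features, truth=truth, config=config)


# ---------------------------------------------------------------------------
# read generators
# ---------------------------------------------------------------------------


def simulate_rdrna_reads(
    transcript: str,
    cut_efficiency: float,
    eligible_range: tuple[int, int],
    n_reads: int,
    seed,
) -> pd.DataFrame:
    """Degradation fragments of one transcript under the U+2 model.

    Enumerates all fragments delimited by two made cuts (intermediate cuts
    skipped independently with probability ``1 - cut_efficiency``), keeps
    those with length inside ``eligible_range``, and draws ``n_reads``
    multinomially from their occurrence weights.  All reads are sense to
    the transcript; a transcript with no eligible fragment (e.g. no
    uracils) yields an empty read set.

    Returns a DataFrame with columns start, end (transcript coordinates,
    0-based half-open), strand ('+'), sequence, count.
    """
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cfg = CleavageModelConfig(offset=2, eligible_range=tuple(eligible_range))
    frags, weights = composite_fragments(transcript, cut_efficiency, cfg)
    cols = ["start", "end", "strand", "sequence", "count"]
    if not frags or n_reads == 0:
        return pd.DataFrame(columns=cols)
    p = np.asarray(weights, dtype=float)
    counts = rng.multinomial(n_reads, p / p.sum())
    rows = [
        (a, b, "+", transcript[a:b], int(k))
        for (a, b), k in zip(frags, counts)
        if k > 0
    ]
    return pd.DataFrame(rows, columns=cols)


def simulate_exsirna_reads(
    locus_seq: str,
    size_dist: dict,
    strand_mix: float,
    five_prime_u_prob: float,
    n_reads: int,
    seed,
) -> pd.DataFrame:
    """Dicer-product reads from one locus.

    Read starts are uniform within the locus; lengths follow ``size_dist``;
    a read is sense with probability ``strand_mix``.  With probability
    ``five_prime_u_prob`` the start is shifted to the nearest position
    where the read's 5' base (in RNA sense) is U, ties broken toward the
    locus centre; if the chosen strand offers no such position the read is
    left unshifted.

    Returns a DataFrame with columns start, end (locus coordinates),
    strand ('+' = sense to the locus sequence), sequence (read-orientation),
    count (per unique placement).
    """
    total = sum(size_dist.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError("size_dist must sum to 1 (within 1e-9)")
    if not 0.0 <= strand_mix <= 1.0:
        raise ValueError("strand_mix must be in [0, 1]")
    L = len(locus_seq)
    max_len = max(size_dist)
    if L < max_len:
        raise ValueError(
            f"locus ({L} nt) shorter than maximum read length ({max_len} nt)"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cols = ["start", "end", "strand", "sequence", "count"]
    if n_reads == 0:
        return pd.DataFrame(columns=cols)

    sizes = np.array(sorted(size_dist))
    size_p = np.array([size_dist[s] for s in sizes], dtype=float)
    # valid 5'-U starts per (strand, length): + strand reads start on a
    # genomic T; - strand reads start (5') at a genomic A at position
    # start+k-1
    t_pos = np.array([i for i, b in enumerate(locus_seq) if b == "T"], dtype=int)
    a_pos = np.array([i for i, b in enumerate(locus_seq) if b == "A"], dtype=int)
    valid: dict = {}
    for k in sizes:
        valid[("+", k)] = t_pos[t_pos <= L - k]
        vm = a_pos[a_pos >= k - 1] - (k - 1)
        valid[("-", k)] = vm

    ks = sizes[rng.choice(len(sizes), size=n_reads, p=size_p)]
    sense = rng.random(n_reads) < strand_mix
    force = rng.random(n_reads) < five_prime_u_prob
    starts = rng.integers(0, L - ks + 1)
    centre = L / 2.0
    for strand_flag in (True, False):
        strand = "+" if strand_flag else "-"
        for k in sizes:
            sel = force & (sense == strand_flag) & (ks == k)
            if not sel.any():
                continue
            cand = valid[(strand, k)]
            if len(cand) == 0:
                continue  # no U-compatible start on this strand: leave unshifted
            x = starts[sel]
            # nearest valid start; equidistant ties resolved toward centre
            idx = np.searchsorted(cand, x)
            left = np.clip(idx - 1, 0, len(cand) - 1)
            right = np.clip(idx, 0, len(cand) - 1)
            dl = np.abs(cand[left] - x)
            dr = np.abs(cand[right] - x)
            tie_to_centre = np.abs(cand[right] + k / 2.0 - centre) < np.abs(
                cand[left] + k / 2.0 - centre
            )
            pick_right = (dr < dl) | ((dr == dl) & tie_to_centre)
            starts[sel] = np.where(pick_right, cand[right], cand[left])
    # collapse identical placements
    key = starts * (2 * (L + 2)) + ks * 2 + sense
    uniq, inv_counts = np.unique(key, return_counts=True)
    rows = []
    for u, n in zip(uniq, inv_counts):
        s_flag = bool(u % 2)
        k = int((u // 2) % (L + 2))
        x = int(u // (2 * (L + 2)))
        strand = "+" if s_flag else "-"
        sub = locus_seq[x : x + k]
        seqr = sub if strand == "+" else revcomp(sub)
        rows.append((x, x + k, strand, seqr, int(n)))
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# library emission
# ---------------------------------------------------------------------------


def _locus_generators(dataset: SimulatedDataset):
    """Precompute per-locus fragment tables (rdRNA) / sequences (others)."""
    cfg = dataset.config
    gens = []
    ccfg = CleavageModelConfig(offset=2, eligible_range=tuple(cfg.eligible_range))
    for row in dataset.truth.itertuples(index=False):
        tseq = dataset.locus_sequence(row)
        if row.class_label.startswith("rdRNA"):
            frags, w = composite_fragments(tseq, cfg.cut_efficiency, ccfg)
            p = np.asarray(w, dtype=float)
            gens.append(("rdrna", tseq, frags, p / p.sum() if p.size else p))
        else:
            gens.append(("exsi", tseq, None, None))
    return gens


def emit_libraries(
    dataset: SimulatedDataset,
    depth: int | None = None,
    seed: int | None = None,
) -> tuple[dict, pd.DataFrame]:
    """Realise one read library per genotype.

    Per library, expected locus mass is ``weight x genotype multiplier``
    (plus a thin uniform noise component); ``depth`` reads are then drawn
    multinomially across loci and noise, so every library sums to exactly
    ``depth`` reads.  Within an rdRNA locus, reads are drawn from the
    precomputed eligible-fragment spectrum; within an ex-siRNA locus, from
    the Dicer-product generator; noise reads are uniform 18-25-mers on
    either strand.

    Returns
    -------
    libraries : dict
        library_id -> DataFrame of collapsed placements with columns
        contig, start, end, strand (genomic), sequence (read orientation),
        count.
    expected_rpm : DataFrame
        loci x libraries table of expected reads-per-million.
    """
    cfg = dataset.config
    if depth is None:
        depth = cfg.library_depth
    rng = np.random.default_rng(cfg.rng_seed if seed is None else seed)
    truth = dataset.truth
    gens = _locus_generators(dataset)
    weights = truth["weight"].to_numpy(dtype=float)
    contigs = list(dataset.genome)
    clens = np.array([len(dataset.genome[c]) for c in contigs])

    libraries: dict = {}
    expected = {}
    for g in cfg.genotypes:
        mult = truth[f"mult_{g}"].to_numpy(dtype=float)
        locus_mass = weights * mult
        p_noise = cfg.uniform_noise_frac
        mass = np.append(locus_mass * (1.0 - p_noise) / locus_mass.sum(), p_noise)
        counts = rng.multinomial(depth, mass) if depth > 0 else np.zeros(len(mass), int)
        expected[g] = mass[:-1] * 1e6  # expected RPM (all reads map)

        placements: dict = {}

        def _add(contig, start, end, strand, seqr, n):
            key = (contig, start, end, strand, seqr)
            placements[key] = placements.get(key, 0) + n

        for i, row in enumerate(truth.itertuples(index=False)):
            n = int(counts[i])
            if n == 0:
                continue
            kind, tseq, frags, fp = gens[i]
            if kind == "rdrna":
                if fp is None or fp.size == 0:
                    continue
                sub = rng.multinomial(n, fp)
                for (a, b), k in zip(frags, sub):
                    if k == 0:
                        continue
                    if row.strand == "+":
                        gs, ge, gstrand = row.start + a, row.start + b, "+"
                    else:
                        gs, ge, gstrand = row.end - b, row.end - a, "-"
                    _add(row.contig, gs, ge, gstrand, tseq[a:b], int(k))
            else:
                reads = simulate_exsirna_reads(
                    tseq,
                    cfg.exsi_size_dist,
                    cfg.exsi_strand_mix,
                    cfg.exsi_five_prime_u_prob,
                    n,
                    rng,
                )
                for r in reads.itertuples(index=False):
                    if row.strand == "+":
                        gs, ge = row.start + r.start, row.start + r.end
                        gstrand = r.strand
                    else:
                        gs, ge = row.end - r.end, row.end - r.start
                        gstrand = "-" if r.strand == "+" else "+"
                    _add(row.contig, gs, ge, gstrand, r.sequence, int(r.count))

        n_noise = int(counts[-1])
        if n_noise:
            ci = rng.choice(len(contigs), size=n_noise, p=clens / clens.sum())
            lens = rng.integers(18, 26, size=n_noise)
            strands = rng.random(n_noise) < 0.5
            for j in range(n_noise):
                c = contigs[int(ci[j])]
                k = int(lens[j])
                x = int(rng.integers(0, clens[int(ci[j])] - k + 1))
                sub = dataset.genome[c][x : x + k]
                if strands[j]:
                    _add(c, x, x + k, "+", sub, 1)
                else:
                    _add(c, x, x + k, "-", revcomp(sub), 1)

        lib = pd.DataFrame(
            [(c, s, e, st, q, n) for (c, s, e, st, q), n in sorted(placements.items())],
            columns=["contig", "start", "end", "strand", "sequence", "count"],
        )
        libraries[g] = lib

    expected_rpm = pd.DataFrame(expected, index=truth["locus_id"])
    expected_rpm.index.name = "locus_id"
    return libraries, expected_rpm


def library_to_reads(lib: pd.DataFrame) -> list[tuple[str, int]]:
    """Collapse a placement table to (sequence, count) pairs."""
    agg: dict = {}
    for r in lib.itertuples(index=False):
        agg[r.sequence] = agg.get(r.sequence, 0) + int(r.count)
    return sorted(agg.items())
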