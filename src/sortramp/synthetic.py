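"""Generative twin of the sort-and-sequence reporter experiment.

A library of 9-nt windows replaces ORF nucleotides 7-15 (codons 3-5) of
a codon-optimized eGFP reporter.  Each window is assigned an expected
log10 fluorescence by an additive model (baseline + motif effects + A/U
content effect, with stop-codon truncation and partial amber
suppression); cells carrying the variants are drawn, given log-normal
cell-to-cell noise, sorted into five bins by empirical quantile gates,
and each bin is sequenced multinomially to a configured depth.

All randomness flows from a single top-level seed through
numpy SeedSequence spawning, in a fixed order: library sampling first,
then per replicate one sort stream and one sequencing stream.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlphabetError, CapacityError, ConfigurationError
from .features import NUCLEOTIDES, STOP_CODONS, au_content, clean_sequence, split_codons
from .motifs import KNYI, MotifPattern, scan_positions
from .scoring import BinCountMatrix, N_BINS

#: Codon-optimized eGFP open reading frame used as the constant reporter
#: context (the library randomizes nucleotides 7-15 of this ORF).
EGFP_ORF = (
    "atggtcagcaagggcgaggagctgttcaccggggtggtgcccatcctggtcgagctggacggcgacgtc"
    "aacggccacaagttcagcgtgtccggcgagggcgagggcgatgccacctacggcaagctcaccctcaag"
    "ttcatctgcaccaccggcaagctgcccgtgccctggcccaccctcgtgaccaccctgacctacggcgtg"
    "cagtgcttcagccgctaccccgaccacatgaagcagcacgacttcttcaagtccgccatgcccgaaggc"
    "tacgtccaggagcgcaccatcttcttcaaggacgacggcaactacaagacccgcgccgaggtgaagttc"
    "gagggcgacaccctggtgaaccgcatcgagctgaagggcatcgacttcaaggaggacggcaacatcctg"
    "gggcacaagctggagtacaactacaacagccacaacgtctatatcatggccgacaagcagaagaacggc"
    "atcaaggtgaacttcaagatccgccacaacatcgaggacggcagcgtgcagctcgccgaccactaccag"
    "cagaacacccccatcggcgacggccccgtgctgctgcccgacaaccactacctgagcacccagtccgcc"
    "ctgagcaaagaccccaacgagaagcgcgatcacatggtcctgctggagttcgtgaccgccgccgggatc"
    "actctcggcatggacgagctgtacaagtaa"
).upper()

#: The wild-type variable window (ORF nt 7-15, encoding Ser-Lys-Gly).
WT_WINDOW = EGFP_ORF[6:15]


@dataclass
class LibraryDesign:
    """Coordinates and constant flanks of the randomized reporter window."""

    window_length: int = 9
    window_orf_start: int = 7  # 1-based ORF nucleotide; 7 -> codons 3-5
    upstream_flank: str = EGFP_ORF[:6]
    downstream_flank: str = EGFP_ORF[15:]

    def __post_init__(self) -> None:
        if self.window_length <= 0 or self.window_length % 3:
            raise ConfigurationError(
                f"window_length must be a positive codon multiple, got "
                f"{self.window_length}"
            )
        self.upstream_flank = clean_sequence(self.upstream_flank, context="upstream flank")
        self.downstream_flank = clean_sequence(
            self.downstream_flank, context="downstream flank"
        )

    @property
    def capacity(self) -> int:
        return 4 ** self.window_length


@dataclass
class ExpressionModel:
    """Additive log10 generative model mapping window sequence to expression.

    Expression is baseline plus motif effects (each motif contributes
    once if it matches at any of its anchor offsets) plus a per-A/U-
    nucleotide term.  Windows with an unsuppressed stop (ochre/opal, or
    amber in the unsuppressed fraction) express at ``stop_floor``; amber
    (TAG) windows get the suppression-efficiency-weighted mixture of
    read-through and floor.  ``cell_cv_log10`` is the log10 sd of
    cell-to-cell fluorescence around the variant expectation.
    """

    baseline_log10_rfu: float = 2.6
    motif_effects: list[tuple[MotifPattern, float]] = field(
        default_factory=lambda: [(KNYI, 0.8)]
    )
    au_effect_per_nt: float = 0.05
    stop_floor_log10_rfu: float = 0.6
    amber_suppression_efficiency: float = 0.85
    cell_cv_log10: float = 0.25

    def __post_init__(self) -> None:
        if not 0.0 <= self.amber_suppression_efficiency <= 1.0:
            raise ConfigurationError(
                "amber_suppression_efficiency must be in [0,1], got "
                f"{self.amber_suppression_efficiency}"
            )
        if self.stop_floor_log10_rfu > self.baseline_log10_rfu:
            raise ConfigurationError("stop floor must not exceed baseline")
        if self.cell_cv_log10 < 0:
            raise ConfigurationError("cell_cv_log10 must be >= 0")


@dataclass
class SortGates:
    """FACS gate design: four cumulative boundaries and five bin medians.

    The defaults follow the screen's gating: bins 1-4 cover roughly 24%
    of cells each and bin 5 the brightest 2.5%.  ``unsorted_gap`` can
    carve a discarded quantile band (lo, hi) between bin 4 and bin 5 for
    designs where the top gate does not abut bin 4.
    """

    cumulative_boundaries: tuple[float, ...] = (0.24, 0.48, 0.72, 0.975)
    bin_median_rfu: tuple[float, ...] = (20.0, 120.0, 600.0, 3600.0, 12000.0)
    unsorted_gap: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        b = self.cumulative_boundaries
        if len(b) != N_BINS - 1 or any(not 0 < x < 1 for x in b):
            raise ConfigurationError(
                f"need {N_BINS - 1} boundaries in (0,1), got {b}"
            )
        if any(b[i] >= b[i + 1] for i in range(len(b) - 1)):
            raise ConfigurationError(f"boundaries must strictly increase: {b}")
        m = self.bin_median_rfu
        if len(m) != N_BINS or any(m[i] >= m[i + 1] for i in range(len(m) - 1)):
            raise ConfigurationError(f"need {N_BINS} strictly increasing medians: {m}")
        if self.unsorted_gap is not None:
            lo, hi = self.unsorted_gap
            if not (b[-1] <= lo < hi < 1):
                raise ConfigurationError(
                    f"unsorted gap {self.unsorted_gap} must sit between the "
                    f"last boundary {b[-1]} and 1"
                )


@dataclass
class SimConfig:
    """Problem sizes for one simulated experiment."""

    n_variants: int = 5000
    cells_per_library: int = 1_000_000
    reads_per_bin: tuple[int, ...] = (1_000_000,) * N_BINS
    replicate_count: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_variants <= 0 or self.cells_per_library <= 0:
            raise ConfigurationError("n_variants and cells_per_library must be > 0")
        if len(self.reads_per_bin) != N_BINS or any(r < 0 for r in self.reads_per_bin):
            raise ConfigurationError(
                f"reads_per_bin needs {N_BINS} non-negative depths, got "
                f"{self.reads_per_bin}"
            )
        if self.replicate_count <= 0:
            raise ConfigurationError("replicate_count must be > 0")


# ---------------------------------------------------------------------------
# Library enumeration and the generative expression model
# ---------------------------------------------------------------------------

def enumerate_library(
    design: LibraryDesign,
    n_variants: int | str = "all",
    seed: int | np.random.Generator | None = None,
) -> list[str]:
    """Distinct variable-window sequences.

    With ``n_variants="all"`` the full 4^L enumeration is returned in
    lexicographic order; otherwise a uniform without-replacement sample
    of that space, reproducible per seed.
    """
    capacity = design.capacity
    if n_variants == "all":
        return [
            "".join(c)
            for c in itertools.product(NUCLEOTIDES, repeat=design.window_length)
        ]
    n = int(n_variants)
    if n > capacity:
        raise CapacityError(
            f"{n} variants requested but only {capacity} length-"
            f"{design.window_length} windows exist"
        )
    rng = np.random.default_rng(seed)
    codes = rng.choice(capacity, size=n, replace=False)
    return [_decode(int(c), design.window_length) for c in codes]


def _decode(code: int, length: int) -> str:
    out = []
    for _ in range(length):
        code, r = divmod(code, 4)
        out.append(NUCLEOTIDES[r])
    return "".join(reversed(out))


def assign_true_expression(window: str, model: ExpressionModel) -> float:
    """Expected log10 fluorescence of one window under the model.

    Read-through expression is baseline + motif effects + A/U term.  The
    first TAA/TGA kills read-through outright; each TAG before it is
    suppressed independently with the amber efficiency, so the expected
    value is the read-through probability-weighted mixture of the
    read-through expression and the stop floor.
    """
    codons = split_codons(window)
    p_readthrough = 1.0
    for codon in codons:
        if codon in ("TAA", "TGA"):
            p_readthrough = 0.0
            break
        if codon == "TAG":
            p_readthrough *= model.amber_suppression_efficiency
    full = (
        model.baseline_log10_rfu
        + model.au_effect_per_nt * au_content(window)
        + sum(
            effect
            for pattern, effect in model.motif_effects
            if scan_positions(window, pattern)
        )
    )
    return p_readthrough * full + (1.0 - p_readthrough) * model.stop_floor_log10_rfu


def true_expression_table(
    windows: Sequence[str], model: ExpressionModel
) -> np.ndarray:
    return np.array([assign_true_expression(w, model) for w in windows])


# ---------------------------------------------------------------------------
# Sorting and sequencing
# ---------------------------------------------------------------------------

@dataclass
class SortResult:
    """Per-variant per-bin cell counts plus the discard tally."""

    cell_counts: np.ndarray
    n_discarded: int

    @property
    def n_sorted(self) -> int:
        return int(self.cell_counts.sum())


def simulate_sort(
    expressions: np.ndarray,
    gates: SortGates,
    cells_per_library: int,
    cell_cv_log10: float,
    seed: int | np.random.Generator | None = None,
) -> SortResult:
    """Sort a pool of cells into the five fluorescence bins.

    Each cell draws a variant uniformly, a log10 fluorescence
    Normal(expected, cell_cv_log10), and is gated by the empirical
    quantiles of the pooled distribution (rank-based, with random
    tie-breaking, so degenerate cv=0 pools still realize the gate
    fractions).  Cells in a configured unsorted gap are discarded.
    """
    expressions = np.asarray(expressions, dtype=float)
    n = expressions.size
    if n == 0 or cells_per_library <= 0:
        raise ConfigurationError("need at least one variant and one cell")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cells = rng.multinomial(cells_per_library, np.full(n, 1.0 / n))
    variant_idx = np.repeat(np.arange(n), cells)
    fluor = np.repeat(expressions, cells)
    if cell_cv_log10 > 0:
        fluor = fluor + rng.normal(0.0, cell_cv_log10, fluor.size)
    # rank-based quantile gating with random tie-breaking
    order = np.lexsort((rng.random(fluor.size), fluor))
    ranks = np.empty(fluor.size, dtype=np.int64)
    ranks[order] = np.arange(fluor.size)
    total = fluor.size
    edges = [int(round(b * total)) for b in gates.cumulative_boundaries]
    bins = np.searchsorted(edges, ranks, side="right")
    keep = np.ones(total, dtype=bool)
    if gates.unsorted_gap is not None:
        lo, hi = (int(round(g * total)) for g in gates.unsorted_gap)
        gap = (ranks >= lo) & (ranks < hi)
        keep &= ~gap
        bins = np.where(ranks >= hi, N_BINS - 1, bins)
    flat = variant_idx[keep] * N_BINS + bins[keep]
    counts = np.bincount(flat, minlength=n * N_BINS).reshape(n, N_BINS)
    return SortResult(counts, int(total - keep.sum()))


def simulate_sequencing(
    cell_counts: np.ndarray,
    reads_per_bin: Sequence[int],
    variants: Sequence[str],
    seed: int | np.random.Generator | None = None,
) -> BinCountMatrix:
    """Multinomial sequencing of each sorted bin to a configured depth.

    Read counts in bin b follow Multinomial(reads_per_bin[b],
    proportional to cell counts in that bin); column sums equal the
    configured depths exactly.
    """
    cell_counts = np.asarray(cell_counts)
    if len(reads_per_bin) != N_BINS:
        raise ConfigurationError(f"need {N_BINS} per-bin depths")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    reads = np.zeros_like(cell_counts, dtype=np.int64)
    for b in range(N_BINS):
        depth = int(reads_per_bin[b])
        col = cell_counts[:, b].astype(float)
        tot = col.sum()
        if depth == 0:
            continue
        if tot == 0:
            raise ConfigurationError(
                f"bin {b + 1} has zero cells but {depth} reads requested"
            )
        reads[:, b] = rng.multinomial(depth, col / tot)
    return BinCountMatrix(list(variants), reads)


def write_fastq(
    matrix: BinCountMatrix,
    design: LibraryDesign,
    paths: Sequence[str | Path],
    read_length: int = 60,
) -> list[int]:
    """Write one FASTQ per bin; each read is flank + window + flank prefix.

    Reads carry uniform high quality (Phred 40, Sanger encoding); the
    per-variant read multiplicities match the count matrix exactly.
    Returns the number of reads written per bin.
    """
    if len(paths) != N_BINS:
        raise ConfigurationError(f"need {N_BINS} output paths, one per bin")
    written = []
    for b, path in enumerate(paths):
        records = []
        for v_idx, window in enumerate(matrix.variants):
            n_reads = int(matrix.counts[v_idx, b])
            if n_reads == 0:
                continue
            seq = (design.upstream_flank + window + design.downstream_flank)[
                :read_length
            ]
            for i in range(n_reads):
                rec = SeqRecord(
                    Seq(seq),
                    id=f"bin{b + 1}:{window}:{i}",
                    description="",
                )
                rec.letter_annotations["phred_quality"] = [40] * len(seq)
                records.append(rec)
        try:
            count = SeqIO.write(records, str(path), "fastq")
        except OSError as exc:  # pragma: no cover - passthrough with context
            raise OSError(f"failed writing FASTQ for bin {b + 1} to {path}: {exc}")
        written.append(count)
    return written


# ---------------------------------------------------------------------------
# Whole-experiment convenience
# ---------------------------------------------------------------------------

@dataclass
class SimulatedExperiment:
    windows: list[str]
    true_log10_expression: np.ndarray
    replicates: list[BinCountMatrix]
    sort_results: list[SortResult]


def simulate_experiment(
    sim: SimConfig,
    design: LibraryDesign | None = None,
    model: ExpressionModel | None = None,
    gates: SortGates | None = None,
) -> SimulatedExperiment:
    """Full generative run: library -> truth -> replicated sort + sequencing.

    Replicates share the library and its true expressions and re-run
    sorting and sequencing with distinct child streams of the top seed.
    """
    design = design or LibraryDesign()
    model = model or ExpressionModel()
    gates = gates or SortGates()
    streams = np.random.SeedSequence(sim.seed).spawn(1 + 2 * sim.replicate_count)
    lib_rng = np.random.default_rng(streams[0])
    windows = enumerate_library(
        design,
        "all" if sim.n_variants >= design.capacity else sim.n_variants,
        lib_rng,
    )
    truth = true_expression_table(windows, model)
    replicates, sorts = [], []
    for r in range(sim.replicate_count):
        sort_rng = np.random.default_rng(streams[1 + 2 * r])
        seq_rng = np.random.default_rng(streams[2 + 2 * r])
        sort = simulate_sort(
            truth, gates, sim.cells_per_library, model.cell_cv_log10, sort_rng
        )
        sorts.append(sort)
        replicates.append(
            simulate_sequencing(sort.cell_counts, sim.reads_per_bin, windows, seq_rng)
        )
    return SimulatedExperiment(windows, truth, replicates, sorts)
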