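"""Readers, writers and variable-region extraction.

All tabular outputs carry a provenance header (comment lines with the
package version, the run seed and a config hash) so any score table can
be traced back to the configuration that produced it.  User-facing
coordinates are 1-based inclusive (the "nucleotides 7-15" convention);
internal indices are 0-based half-open.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import __version__
from .errors import SchemaError
from .scoring import BinCountMatrix, N_BINS
from .synthetic import LibraryDesign


def provenance_lines(seed: int | None = None, config: Mapping | None = None) -> list[str]:
    lines = [f"# sortramp {__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if config is not None:
        digest = hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]
        lines.append(f"# config_sha256: {digest}")
    return lines


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    seed: int | None = None,
    config: Mapping | None = None,
) -> None:
    """Write a TSV with a provenance comment header."""
    with open(path, "w") as fh:
        for line in provenance_lines(seed, config):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_count_table(
    matrix: BinCountMatrix,
    path: str | Path,
    seed: int | None = None,
    config: Mapping | None = None,
) -> None:
    write_table(matrix.to_dataframe(), path, seed=seed, config=config)


def read_count_table(path: str | Path) -> BinCountMatrix:
    """Read a `variant, bin1..bin5` TSV with strict schema validation."""
    df = read_table(path)
    cols = ["variant"] + [f"bin{b}" for b in range(1, N_BINS + 1)]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"count table {path} missing column(s): {missing}")
    for c in cols[1:]:
        if not pd.api.types.is_integer_dtype(df[c]):
            try:
                as_int = df[c].astype("int64")
            except (ValueError, TypeError) as exc:
                raise SchemaError(
                    f"column {c!r} in {path} is not integer-valued: {exc}"
                ) from None
            if not (as_int == df[c]).all():
                raise SchemaError(f"column {c!r} in {path} has non-integer counts")
            df[c] = as_int
        if (df[c] < 0).any():
            raise SchemaError(f"column {c!r} in {path} contains negative counts")
    return BinCountMatrix.from_dataframe(df)


# ---------------------------------------------------------------------------
# Variable-region extraction from reads
# ---------------------------------------------------------------------------

@dataclass
class ExtractionQC:
    """Read accounting: retained plus each discard reason sums to total."""

    total: int = 0
    retained: int = 0
    no_upstream_anchor: int = 0
    no_downstream_anchor: int = 0
    n_in_window: int = 0
    too_short: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "total": self.total,
            "retained": self.retained,
            "no_upstream_anchor": self.no_upstream_anchor,
            "no_downstream_anchor": self.no_downstream_anchor,
            "n_in_window": self.n_in_window,
            "too_short": self.too_short,
        }


@dataclass
class ExtractionResult:
    counts: dict[str, int] = field(default_factory=dict)
    qc: ExtractionQC = field(default_factory=ExtractionQC)


def extract_variable_regions(
    fastq_path: str | Path,
    design: LibraryDesign,
    downstream_anchor_length: int = 6,
) -> ExtractionResult:
    """Window counts from a FASTQ by exact constant-flank anchoring.

    The upstream flank must occur in the read; the window is the next
    ``window_length`` nt and must be followed by the first
    ``downstream_anchor_length`` nt of the downstream flank.  Reads
    failing an anchor, too short, or with N in the window are discarded
    and tallied by reason.
    """
    res = ExtractionResult()
    anchor_up = design.upstream_flank
    anchor_down = design.downstream_flank[:downstream_anchor_length]
    try:
        records = SeqIO.parse(str(fastq_path), "fastq")
        for i, rec in enumerate(records):
            res.qc.total += 1
            read = str(rec.seq).upper()
            pos = read.find(anchor_up)
            if pos < 0:
                res.qc.no_upstream_anchor += 1
                continue
            start = pos + len(anchor_up)
            end = start + design.window_length
            if end + len(anchor_down) > len(read):
                res.qc.too_short += 1
                continue
            window = read[start:end]
            if anchor_down and read[end : end + len(anchor_down)] != anchor_down:
                res.qc.no_downstream_anchor += 1
                continue
            if set(window) - set("ACGT"):
                res.qc.n_in_window += 1
                continue
            res.qc.retained += 1
            res.counts[window] = res.counts.get(window, 0) + 1
    except ValueError as exc:
        raise SchemaError(
            f"malformed FASTQ {fastq_path} near record {res.qc.total + 1}: {exc}"
        ) from None
    return res


def matrix_from_bin_fastqs(
    paths: list[str | Path],
    design: LibraryDesign,
    downstream_anchor_length: int = 6,
) -> tuple[BinCountMatrix, list[ExtractionQC]]:
    """Build a count matrix from five per-bin FASTQ files."""
    if len(paths) != N_BINS:
        raise SchemaError(f"need {N_BINS} FASTQ paths, one per bin")
    per_bin = [
        extract_variable_regions(p, design, downstream_anchor_length) for p in paths
    ]
    variants = sorted({w for r in per_bin for w in r.counts})
    index = {v: i for i, v in enumerate(variants)}
    counts = np.zeros((len(variants), N_BINS), dtype=np.int64)
    for b, r in enumerate(per_bin):
        for w, c in r.counts.items():
            counts[index[w], b] = c
    return BinCountMatrix(variants, counts), [r.qc for r in per_bin]


def load_dg_table(path: str | Path) -> pd.DataFrame:
    """Read a `variant, dG_kcal_mol` folding-energy TSV."""
    df = read_table(path)
    if not {"variant", "dG_kcal_mol"} <= set(df.columns):
        raise SchemaError(
            f"dG table {path} must have columns 'variant' and 'dG_kcal_mol'"
        )
    return df
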