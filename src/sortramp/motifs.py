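"""Degenerate motif matching, positional scanning and enrichment statistics.

Two motif kinds are supported: IUPAC nucleotide patterns (e.g. AADTAT,
where D = not-C) scanned across the 9-nt variable window, and ordered
amino-acid class patterns (e.g. {K,N} then {Y,I}) anchored at protein
residues 3 or 4.  Enrichment between "high" (GFP score > 4) and "low"
(< 3) strata is quantified as a presence-fraction ratio plus a two-sided
Fisher exact test on the 2x2 presence table.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, PatternError
from .features import GENETIC_CODE, clean_sequence, split_codons, translate_window

IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

#: In-frame hexamer offsets within the 9-nt window: offset 1 covers codons
#: 3-4 (residues 3-4), offset 4 covers codons 4-5 (residues 4-5).
IN_FRAME_HEXAMER_OFFSETS = {1: (3, 4), 4: (4, 5)}


@dataclass(frozen=True)
class MotifPattern:
    """A degenerate nucleotide hexamer or a positional residue-class motif.

    ``pattern`` is an IUPAC string (nucleotide kind, DNA alphabet) or a
    tuple of residue-class frozensets (peptide kind).  ``anchor_offsets``
    are the allowed 1-based offsets: window positions for nucleotide
    patterns, protein residue positions (3 or 4) for peptide patterns.
    """

    kind: str  # "nucleotide" | "peptide"
    pattern: str | tuple[frozenset[str], ...]
    anchor_offsets: tuple[int, ...]

    @classmethod
    def nucleotide(
        cls, pattern: str, anchor_offsets: Sequence[int] | None = None
    ) -> "MotifPattern":
        pattern = pattern.upper().replace("U", "T")
        bad = set(pattern) - set(IUPAC_CODES)
        if bad:
            raise PatternError(f"invalid IUPAC code(s) {sorted(bad)} in {pattern!r}")
        if anchor_offsets is None:
            # all offsets where the pattern fits in a 9-nt window
            anchor_offsets = tuple(range(1, 9 - len(pattern) + 2))
        return cls("nucleotide", pattern, tuple(anchor_offsets))

    @classmethod
    def peptide(
        cls,
        classes: Sequence[Iterable[str]],
        anchor_offsets: Sequence[int] = (3, 4),
    ) -> "MotifPattern":
        classes = tuple(frozenset(c) for c in classes)
        for cl in classes:
            bad = {a for a in cl if len(a) != 1 or not a.isalpha()}
            if bad:
                raise PatternError(f"invalid residue symbols {sorted(bad)}")
        if any(o not in (3, 4, 5) for o in anchor_offsets):
            raise PatternError("peptide anchor offsets are protein residues 3-5")
        return cls("peptide", classes, tuple(anchor_offsets))

    def __len__(self) -> int:
        return len(self.pattern)

    def label(self) -> str:
        if self.kind == "nucleotide":
            return str(self.pattern)
        return "-".join("|".join(sorted(cl)) for cl in self.pattern)


#: The two most enriched hexanucleotide motifs of the screen (DNA alphabet).
AADTAT = MotifPattern.nucleotide("AADTAT")
AAVATT = MotifPattern.nucleotide("AAVATT")
#: Their shared amino-acid reading: Lys/Asn followed by Tyr/Ile.
KNYI = MotifPattern.peptide([{"K", "N"}, {"Y", "I"}])


def match_at(window: str, pattern: MotifPattern, offset: int) -> bool:
    """Does ``pattern`` match ``window`` at 1-based ``offset``?

    Nucleotide: positionwise IUPAC containment.  Peptide: the window is
    translated (any stop codon fails the match, mirroring the screen's
    stop filtering) and each residue starting at protein position
    ``offset`` must belong to its class.
    """
    window = clean_sequence(window, context="window")
    if pattern.kind == "nucleotide":
        pat = str(pattern.pattern)
        if offset < 1 or offset + len(pat) - 1 > len(window):
            raise PatternError(
                f"offset {offset} puts a {len(pat)}-mer outside a "
                f"{len(window)}-nt window"
            )
        chunk = window[offset - 1 : offset - 1 + len(pat)]
        return all(c in IUPAC_CODES[p] for c, p in zip(chunk, pat))
    # peptide kind: offsets are protein residue positions; the window
    # codes residues 3..5.
    if offset + len(pattern.pattern) - 1 > 5 or offset < 3:
        raise PatternError(
            f"peptide offset {offset} with length {len(pattern.pattern)} "
            "exceeds residues 3-5"
        )
    call = translate_window(window)
    if "*" in call.peptide:
        return False
    start = offset - 3
    return all(
        call.peptide[start + i] in cl for i, cl in enumerate(pattern.pattern)
    )


def scan_positions(window: str, pattern: MotifPattern) -> tuple[int, ...]:
    """All anchor offsets at which the pattern matches the window."""
    out = []
    for off in pattern.anchor_offsets:
        if pattern.kind == "nucleotide" and off + len(pattern.pattern) - 1 > len(
            clean_sequence(window)
        ):
            continue
        if match_at(window, pattern, off):
            out.append(off)
    return tuple(out)


def matches(window: str, pattern: MotifPattern, offset: int | str = "pooled") -> bool:
    """Presence call at one offset, or pooled over the anchor offsets."""
    if offset == "pooled":
        return bool(scan_positions(window, pattern))
    return match_at(window, pattern, int(offset))


# ---------------------------------------------------------------------------
# Stratification and enrichment
# ---------------------------------------------------------------------------

def stratify_scores(
    score_table: pd.DataFrame, high_min: float = 4.0, low_max: float = 3.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a score table into high (> high_min) and low (< low_max) strata.

    Scores "above four" are high, "below three" are low; the middle
    stratum is excluded from enrichment contrasts.
    """
    if high_min < low_max:
        raise ConfigurationError(
            f"high_min {high_min} below low_max {low_max}: strata overlap"
        )
    high = score_table[score_table["gfp_score"] > high_min]
    low = score_table[score_table["gfp_score"] < low_max]
    return high, low


@dataclass(frozen=True)
class EnrichmentResult:
    pattern: MotifPattern
    offset: int | str
    n_high_with: int
    n_high_without: int
    n_low_with: int
    n_low_without: int
    enrichment_ratio: float
    p_value: float
    mean_score_present: float
    mean_score_absent: float

    def as_dict(self) -> dict:
        d = {
            "pattern": self.pattern.label(),
            "kind": self.pattern.kind,
            "offset": self.offset,
        }
        for k in (
            "n_high_with", "n_high_without", "n_low_with", "n_low_without",
            "enrichment_ratio", "p_value", "mean_score_present",
            "mean_score_absent",
        ):
            d[k] = getattr(self, k)
        return d


def _presence(variants: Iterable[str], pattern: MotifPattern, offset) -> np.ndarray:
    return np.fromiter(
        (matches(v, pattern, offset) for v in variants), dtype=bool
    )


def enrichment(
    pattern: MotifPattern,
    high: pd.DataFrame,
    low: pd.DataFrame,
    offset: int | str = "pooled",
    full_table: pd.DataFrame | None = None,
) -> EnrichmentResult:
    """Presence-fraction enrichment ratio plus Fisher exact p.

    ratio = (fraction of high-stratum variants carrying the motif) /
    (fraction of low-stratum variants carrying it); +inf when the motif
    is absent from the low stratum.  The p-value is a two-sided Fisher
    exact test on the 2x2 presence table.  Mean scores of motif-present
    vs motif-absent variants are computed over ``full_table`` (the
    unstratified library) when given, else over high+low.
    """
    hi_with = int(_presence(high["variant"], pattern, offset).sum())
    lo_with = int(_presence(low["variant"], pattern, offset).sum())
    hi_without = len(high) - hi_with
    lo_without = len(low) - lo_with
    if len(high) == 0 or len(low) == 0:
        raise ConfigurationError("empty stratum: cannot compute enrichment")
    frac_hi = hi_with / len(high)
    frac_lo = lo_with / len(low)
    ratio = math.inf if frac_lo == 0 else frac_hi / frac_lo
    if frac_hi == 0 and frac_lo == 0:
        ratio = math.nan
    _, p = stats.fisher_exact(
        [[hi_with, hi_without], [lo_with, lo_without]], alternative="two-sided"
    )
    ref = full_table if full_table is not None else pd.concat([high, low])
    present = _presence(ref["variant"], pattern, offset)
    scores = ref["gfp_score"].to_numpy(float)
    mean_present = float(scores[present].mean()) if present.any() else math.nan
    mean_absent = float(scores[~present].mean()) if (~present).any() else math.nan
    return EnrichmentResult(
        pattern, offset, hi_with, hi_without, lo_with, lo_without,
        float(ratio), float(p), mean_present, mean_absent,
    )


def positional_profile(
    pattern: MotifPattern, score_table: pd.DataFrame
) -> pd.DataFrame:
    """Score summaries of motif-present vs -absent variants per offset.

    One row per anchor offset with n, mean, median and sd for the
    matching variants and for the rest of the table; offsets with zero
    matches are flagged empty (NaN summaries), not errors.
    """
    scores = score_table["gfp_score"].to_numpy(float)
    rows = []
    for off in pattern.anchor_offsets:
        present = _presence(score_table["variant"], pattern, off)
        rows.append(
            {
                "offset": off,
                "n_present": int(present.sum()),
                "n_absent": int((~present).sum()),
                "mean_present": _safe(np.mean, scores[present]),
                "median_present": _safe(np.median, scores[present]),
                "sd_present": _safe(
                    lambda a: np.std(a, ddof=1), scores[present], min_size=2
                ),
                "mean_absent": _safe(np.mean, scores[~present]),
                "median_absent": _safe(np.median, scores[~present]),
                "sd_absent": _safe(
                    lambda a: np.std(a, ddof=1), scores[~present], min_size=2
                ),
            }
        )
    return pd.DataFrame(rows)


def _safe(fn, arr: np.ndarray, min_size: int = 1) -> float:
    return float(fn(arr)) if arr.size >= min_size else math.nan


def codon_variant_profile(
    aa_motif: MotifPattern, score_table: pd.DataFrame, offset: int = 3
) -> pd.DataFrame:
    """Score summaries by the synonymous codon realizing each motif residue.

    For variants matching ``aa_motif`` at protein residue ``offset``,
    groups them by the exact codon encoding each motif residue slot and
    summarizes GFP scores per (slot, codon).  Stop-containing windows
    never match (the screen filtered them out).
    """
    if aa_motif.kind != "peptide":
        raise PatternError("codon_variant_profile requires a peptide motif")
    groups: dict[tuple[int, str], list[float]] = {}
    n_match = 0
    for window, score in zip(score_table["variant"], score_table["gfp_score"]):
        if not match_at(window, aa_motif, offset):
            continue
        n_match += 1
        codons = split_codons(window)
        for slot in range(len(aa_motif.pattern)):
            codon = codons[offset - 3 + slot]
            groups.setdefault((slot + 1, codon), []).append(float(score))
    rows = [
        {
            "residue_slot": slot,
            "codon": codon,
            "amino_acid": GENETIC_CODE[codon],
            "n": len(vals),
            "mean_score": float(np.mean(vals)),
            "median_score": float(np.median(vals)),
            "sd_score": float(np.std(vals, ddof=1)) if len(vals) > 1 else math.nan,
        }
        for (slot, codon), vals in sorted(groups.items())
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "residue_slot", "codon", "amino_acid", "n",
            "mean_score", "median_score", "sd_score",
        ],
    )
    df.attrs["n_match"] = n_match
    return df


def permutation_null_pvalues(
    pattern: MotifPattern,
    score_table: pd.DataFrame,
    n_high: int,
    n_permutations: int = 500,
    offset: int | str = "pooled",
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Fisher p-values under random reassignment of the high/low labels.

    Calibration utility: motif presence is held fixed while ``n_high``
    variants are relabeled "high" uniformly at random each round, so the
    returned p-values sample the enrichment test's null distribution.
    For strata large enough that the exact test's discreteness is
    negligible this distribution is approximately Uniform(0,1).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    present = _presence(score_table["variant"], pattern, offset)
    n = len(score_table)
    if not 0 < n_high < n:
        raise ConfigurationError(f"n_high must be in (0, {n}), got {n_high}")
    k_present = int(present.sum())
    out = np.empty(n_permutations)
    for i in range(n_permutations):
        lab = np.zeros(n, dtype=bool)
        lab[rng.choice(n, n_high, replace=False)] = True
        a = int((lab & present).sum())
        table = [
            [a, n_high - a],
            [k_present - a, (n - n_high) - (k_present - a)],
        ]
        out[i] = stats.fisher_exact(table, alternative="two-sided")[1]
    return out


def exhaustive_hexamer_scan(
    score_table: pd.DataFrame,
    high_min: float = 4.0,
    low_max: float = 3.0,
    offset: int | str = "pooled",
) -> pd.DataFrame:
    """Enrichment of every literal hexamer (4^6) with BH correction.

    Returns a DataFrame sorted by p-value with a Benjamini-Hochberg
    ``q_value`` column; candidates beyond the two named motifs have no
    printed ground truth and are exploratory.
    """
    high, low = stratify_scores(score_table, high_min, low_max)
    results = []
    for hexamer in ("".join(c) for c in itertools.product("ACGT", repeat=6)):
        res = enrichment(
            MotifPattern.nucleotide(hexamer), high, low, offset, score_table
        )
        results.append(res.as_dict())
    df = pd.DataFrame(results)
    df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df.sort_values("p_value", kind="stable").reset_index(drop=True)
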