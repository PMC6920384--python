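"""Codon-, nucleotide- and peptide-level features of the 9-nt variable window.

The reporter library randomizes nucleotides 7-15 of the ORF, i.e. codons
3-5 of the encoded protein.  This module annotates each variable window
with the quantities that are correlated with expression downstream:
the encoded tripeptide (with stop-codon taxonomy and optional amber
suppression), A/U content, tRNA adaptation index (tAI), Kyte-Doolittle
hydropathy, net side-chain charge, rare-codon flags, and externally
computed RNA folding energies.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .errors import AlphabetError, ConfigurationError, SchemaError, UndefinedScoreError

NUCLEOTIDES = "ACGT"

#: All 64 codons in lexicographic (A < C < G < T) order.
CODONS: tuple[str, ...] = tuple(
    "".join(c) for c in itertools.product(NUCLEOTIDES, repeat=3)
)

#: Standard genetic code, stop codons translated to '*'.
GENETIC_CODE: dict[str, str] = {c: str(Seq(c).translate()) for c in CODONS}

STOP_CODONS = ("TAA", "TAG", "TGA")
STOP_CLASS = {"TAG": "amber", "TAA": "ochre", "TGA": "opal"}

#: Classical E. coli rare codons at the N-terminus: Arg (AGG/AGA/CGA),
#: Ile (ATA) and Leu (CTA).  Configurable in rare_codon_flags.
RARE_CODONS = frozenset({"AGG", "AGA", "CGA", "ATA", "CTA"})

#: Integer side-chain charge at neutral pH; His counted as 0.
DEFAULT_CHARGE = {"K": 1.0, "R": 1.0, "D": -1.0, "E": -1.0}


def clean_sequence(seq: str, *, context: str = "sequence") -> str:
    """Uppercase, map RNA U to DNA T, and validate the alphabet."""
    out = seq.upper().replace("U", "T")
    bad = set(out) - set(NUCLEOTIDES)
    if bad:
        raise AlphabetError(
            f"{context} {seq!r} contains non-ACGT/U characters: {sorted(bad)}"
        )
    return out


def split_codons(window: str) -> tuple[str, ...]:
    window = clean_sequence(window, context="window")
    if len(window) % 3:
        raise AlphabetError(f"window length {len(window)} is not a codon multiple")
    return tuple(window[i : i + 3] for i in range(0, len(window), 3))


@dataclass(frozen=True)
class TripeptideCall:
    """Translation of the three variable codons (protein residues 3-5)."""

    codons: tuple[str, str, str]
    peptide: str
    stop_class: str  # none | amber | ochre | opal (first stop encountered)
    truncated: bool


def translate_window(window: str, amber_suppression: bool = False) -> TripeptideCall:
    """Translate a 9-nt window into its tripeptide.

    With ``amber_suppression`` (the supE44 phenotype of DH5alpha), UAG is
    decoded as Gln; ``stop_class`` still reports "amber" for provenance.
    """
    codons = split_codons(window)
    if len(codons) != 3:
        raise AlphabetError(f"expected a 9-nt window, got {len(window)} nt")
    peptide = []
    stop_class = "none"
    truncated = False
    for codon in codons:
        aa = GENETIC_CODE[codon]
        if aa == "*":
            if stop_class == "none":
                stop_class = STOP_CLASS[codon]
            if codon == "TAG" and amber_suppression:
                aa = "Q"
            else:
                truncated = True
        peptide.append(aa)
    return TripeptideCall(codons, "".join(peptide), stop_class, truncated)


def au_content(window: str) -> int:
    """Number of A or U(T) nucleotides in the window (0-9 for a 9-mer)."""
    window = clean_sequence(window, context="window")
    return sum(1 for c in window if c in "AT")


def hydropathy(
    peptide: str, scale: Mapping[str, float] = KYTE_DOOLITTLE
) -> float | None:
    """Mean Kyte-Doolittle hydropathy over non-stop residues.

    Returns None for an effectively empty peptide (all residues stops):
    a truncated peptide has no such residue, so no value is defined.
    """
    residues = [r for r in peptide if r != "*"]
    if not residues:
        return None
    return sum(scale[r] for r in residues) / len(residues)


def net_charge(
    peptide: str, scale: Mapping[str, float] = DEFAULT_CHARGE
) -> float | None:
    """Integer side-chain charge at neutral pH (+1 K/R, -1 D/E, H = 0)."""
    residues = [r for r in peptide if r != "*"]
    if not residues:
        return None
    return float(sum(scale.get(r, 0.0) for r in residues))


def rare_codon_flags(
    codons: Sequence[str], rare: frozenset[str] = RARE_CODONS
) -> tuple[bool, ...]:
    """Per-position flags for rare Arg/Ile/Leu codons at codons 3-5."""
    return tuple(clean_sequence(c, context="codon") in rare for c in codons)


# ---------------------------------------------------------------------------
# tRNA adaptation index
# ---------------------------------------------------------------------------

#: Wobble-pairing selective constraints (codon 3rd base : anticodon 1st base),
#: the dos Reis / codonR standard set.  Watson-Crick pairs carry s = 0.
DEFAULT_S_VALUES: dict[str, float] = {
    "wc": 0.0,       # U:A, C:G, A:U, G:C
    "gu": 0.41,      # codon-U read by anticodon G34
    "ic": 0.28,      # codon-C read by inosine (genomically A34)
    "ia": 0.9999,    # codon-A read by inosine (genomically A34)
    "ug": 0.68,      # codon-G read by anticodon U34
    "lysidine": 0.89,  # bacterial AUA read by lysidine-modified CAU (ileX)
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Wobble anticodon first base for each codon third base.
_WOBBLE34 = {"T": ("G", "gu"), "C": ("A", "ic"), "A": ("A", "ia"), "G": ("T", "ug")}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def recognizing_anticodons(
    codon: str, bacterial: bool = True
) -> list[tuple[str, str]]:
    """Anticodons (5'->3', DNA alphabet) able to read ``codon``.

    Returns (anticodon, pairing class) pairs: the Watson-Crick anticodon
    plus the single wobble anticodon for the codon's third base.  With
    ``bacterial`` the two prokaryotic special cases apply: AUG is read
    only by its cognate CAU (no U34:G wobble from the AUA decoder), and
    AUA is read by the lysidine-modified CAU isoleucine tRNA.
    """
    codon = clean_sequence(codon, context="codon")
    if bacterial and codon == "ATA":
        return [("CAT", "lysidine")]
    pairs = [(reverse_complement(codon), "wc")]
    w34, klass = _WOBBLE34[codon[2]]
    wobble = w34 + reverse_complement(codon)[1:]
    if not (bacterial and codon == "ATG"):
        pairs.append((wobble, klass))
    return pairs


@dataclass
class TaiModel:
    """tRNA gene copy numbers plus wobble constraints for tAI weights.

    ``tgcn`` maps anticodons (5'->3', DNA alphabet) to genomic tRNA gene
    copy numbers.  ``lysidine_copies`` is the copy number of the
    lysidine-modified AUA-reading tRNA (ileX; one gene in E. coli K-12),
    kept separate because its genomic anticodon CAT collides with Met.
    """

    tgcn: Mapping[str, float]
    s_values: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_S_VALUES))
    bacterial: bool = True
    lysidine_copies: float = 1.0

    @classmethod
    def ecoli_k12(cls) -> "TaiModel":
        """Model with the packaged E. coli K-12 MG1655 anticodon table."""
        path = resources.files("sortramp.data") / "ecoli_k12_tgcn.tsv"
        with resources.as_file(path) as p:
            return cls(tgcn=read_tgcn_table(p))


def read_tgcn_table(path) -> dict[str, float]:
    """Read an `anticodon<TAB>copies` table (comment lines start with #)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"anticodon", "copies"} <= set(df.columns):
        raise SchemaError(
            f"tGCN table {path} must have columns 'anticodon' and 'copies', "
            f"got {list(df.columns)}"
        )
    if df["anticodon"].duplicated().any():
        dups = df.loc[df["anticodon"].duplicated(), "anticodon"].tolist()
        raise SchemaError(f"duplicate anticodons in tGCN table: {dups}")
    return {
        clean_sequence(a, context="anticodon"): float(n)
        for a, n in zip(df["anticodon"], df["copies"])
    }


def tai_weights(model: TaiModel) -> dict[str, float]:
    """Relative adaptiveness w in (0,1] for the 61 sense codons.

    Raw weight W(codon) = sum over recognizing anticodons of
    (1 - s) * tGCN; w = W / max(W); codons with W = 0 are assigned the
    geometric mean of the nonzero w values.  Stop codons are excluded.
    """
    if not model.tgcn:
        raise ConfigurationError("empty tGCN table")
    raw: dict[str, float] = {}
    for codon in CODONS:
        if codon in STOP_CODONS:
            continue
        total = 0.0
        for anticodon, klass in recognizing_anticodons(codon, model.bacterial):
            copies = (
                model.lysidine_copies
                if klass == "lysidine"
                else model.tgcn.get(anticodon, 0.0)
            )
            total += (1.0 - model.s_values[klass]) * copies
        raw[codon] = total
    w_max = max(raw.values())
    if w_max <= 0:
        raise ConfigurationError("all codon weights are zero; check the tGCN table")
    w = {c: v / w_max for c, v in raw.items()}
    nonzero = [v for v in w.values() if v > 0]
    geo = math.exp(sum(math.log(v) for v in nonzero) / len(nonzero))
    return {c: (v if v > 0 else geo) for c, v in w.items()}


def tai(codons: Sequence[str], weights: Mapping[str, float]) -> float:
    """Geometric mean of per-codon tAI weights (undefined for stops)."""
    cleaned = [clean_sequence(c, context="codon") for c in codons]
    for c in cleaned:
        if c in STOP_CODONS:
            raise UndefinedScoreError(f"tAI undefined for stop codon {c}")
    return math.exp(sum(math.log(weights[c]) for c in cleaned) / len(cleaned))


# ---------------------------------------------------------------------------
# Table-level annotation
# ---------------------------------------------------------------------------

def annotate(
    score_table: pd.DataFrame,
    tai_model: TaiModel | None = None,
    amber_suppression: bool = False,
) -> pd.DataFrame:
    """Append feature columns to a score table (column 'variant' required).

    Adds: peptide, stop_class, truncated, au_content, tai (NaN for
    stop-containing windows), hydropathy, net_charge (NaN when every
    residue is a stop), rare_codon_3/4/5.
    """
    if "variant" not in score_table.columns:
        raise SchemaError("score table lacks a 'variant' column")
    weights = tai_weights(tai_model or TaiModel.ecoli_k12())
    rows = []
    for window in score_table["variant"]:
        call = translate_window(window, amber_suppression=amber_suppression)
        has_stop = any(c in STOP_CODONS for c in call.codons)
        rare = rare_codon_flags(call.codons)
        rows.append(
            {
                "peptide": call.peptide,
                "stop_class": call.stop_class,
                "truncated": call.truncated,
                "au_content": au_content(window),
                "tai": float("nan") if has_stop else tai(call.codons, weights),
                "hydropathy": _nan_if_none(hydropathy(call.peptide)),
                "net_charge": _nan_if_none(net_charge(call.peptide)),
                "rare_codon_3": rare[0],
                "rare_codon_4": rare[1],
                "rare_codon_5": rare[2],
            }
        )
    return pd.concat(
        [score_table.reset_index(drop=True), pd.DataFrame(rows)], axis=1
    )


def _nan_if_none(x: float | None) -> float:
    return float("nan") if x is None else x


def attach_folding_energies(
    score_table: pd.DataFrame, dg_table: pd.DataFrame
) -> pd.DataFrame:
    """Left-join externally computed RNA folding energies onto a score table.

    ``dg_table`` must have columns 'variant' and 'dG_kcal_mol' with unique
    variants.  Missing variants stay NaN (absent), never imputed.
    """
    if not {"variant", "dG_kcal_mol"} <= set(dg_table.columns):
        raise SchemaError(
            "dG table must have columns 'variant' and 'dG_kcal_mol', got "
            f"{list(dg_table.columns)}"
        )
    if dg_table["variant"].duplicated().any():
        dups = dg_table.loc[dg_table["variant"].duplicated(), "variant"].tolist()
        raise SchemaError(f"duplicate variant keys in dG table: {dups}")
    return score_table.merge(
        dg_table[["variant", "dG_kcal_mol"]], on="variant", how="left"
    )


def distinct_tripeptides(windows: Iterable[str], amber_suppression: bool = False) -> int:
    """Number of distinct tripeptide strings encoded by ``windows``."""
    return len(
        {translate_window(w, amber_suppression).peptide for w in windows}
    )
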