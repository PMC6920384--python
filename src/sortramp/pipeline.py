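"""End-to-end pipeline: simulate (or ingest) -> score -> features -> motifs."""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import features as feat
from . import io as sio
from . import motifs as mot
from . import scoring
from .errors import ConfigurationError
from .synthetic import (
    ExpressionModel,
    LibraryDesign,
    SimConfig,
    SortGates,
    simulate_experiment,
)

log = logging.getLogger("sortramp")

DEFAULT_PATTERNS = [mot.AADTAT, mot.AAVATT, mot.KNYI]


@dataclass
class RunConfig:
    """Everything one pipeline run needs; the seed governs all randomness."""

    seed: int = 0
    out_dir: str = "sortramp_out"
    sim: SimConfig = field(default_factory=SimConfig)
    design: LibraryDesign = field(default_factory=LibraryDesign)
    model: ExpressionModel = field(default_factory=ExpressionModel)
    gates: SortGates = field(default_factory=SortGates)
    min_total_reads: int = 10
    high_min: float = 4.0
    low_max: float = 3.0
    amber_suppression: bool = False
    counts_paths: list[str] | None = None  # ingest mode: one TSV per replicate
    dg_table: str | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.sim.seed = self.seed

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for section, klass in (
            ("sim", SimConfig),
            ("design", LibraryDesign),
            ("model", ExpressionModel),
            ("gates", SortGates),
        ):
            if section in raw:
                sub = raw.pop(section)
                _check_fields(sub, klass, section)
                if section == "gates":
                    for k in ("cumulative_boundaries", "bin_median_rfu", "unsorted_gap"):
                        if k in sub and sub[k] is not None:
                            sub[k] = tuple(sub[k])
                if section == "sim" and "reads_per_bin" in sub:
                    sub["reads_per_bin"] = tuple(sub["reads_per_bin"])
                kwargs[section] = klass(**sub)
        _check_fields(raw, cls, "run config")
        return cls(**raw, **kwargs)

    def as_dict(self) -> dict:
        return dataclasses.asdict(
            self,
            dict_factory=lambda kv: {
                k: (v if not isinstance(v, tuple) else list(v)) for k, v in kv
            },
        )


def _check_fields(sub: dict, klass, name: str) -> None:
    allowed = {f.name for f in dataclasses.fields(klass)}
    unknown = set(sub) - allowed
    if unknown:
        raise ConfigurationError(f"unknown {name} option(s): {sorted(unknown)}")


@dataclass
class PipelineResult:
    scores: list[pd.DataFrame]
    mean_scores: pd.DataFrame
    feature_table: pd.DataFrame
    enrichment: pd.DataFrame
    truth: pd.DataFrame | None
    replicate_r: float | None
    out_dir: Path


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run all stages and write provenance-stamped TSV outputs.

    Deterministic given the config (including seed): identical configs
    produce byte-identical outputs.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_dict = config.as_dict()
    hashed = {k: v for k, v in cfg_dict.items() if k not in ("out_dir", "log_level")}
    meta = dict(seed=config.seed, config=hashed)

    truth_df = None
    if config.counts_paths:
        log.info("stage ingest: reading %d count tables", len(config.counts_paths))
        matrices = [sio.read_count_table(p) for p in config.counts_paths]
    else:
        log.info(
            "stage simulate: %d variants, %d cells, %d replicate(s)",
            config.sim.n_variants,
            config.sim.cells_per_library,
            config.sim.replicate_count,
        )
        try:
            exp = simulate_experiment(
                config.sim, config.design, config.model, config.gates
            )
        except Exception as exc:
            raise RuntimeError(f"stage simulate failed: {exc}") from exc
        matrices = exp.replicates
        truth_df = pd.DataFrame(
            {"variant": exp.windows, "true_log10_rfu": exp.true_log10_expression}
        )
        sio.write_table(truth_df, out / "truth.tsv", **meta)
        for i, m in enumerate(matrices, 1):
            sio.write_count_table(m, out / f"counts_rep{i}.tsv", **meta)

    log.info("stage score: min_total=%d", config.min_total_reads)
    try:
        scores = [
            scoring.score_pipeline(m, config.min_total_reads) for m in matrices
        ]
    except Exception as exc:
        raise RuntimeError(f"stage score failed: {exc}") from exc
    for i, s in enumerate(scores, 1):
        sio.write_table(s, out / f"scores_rep{i}.tsv", **meta)
    mean = scoring.mean_scores(scores)
    sio.write_table(mean, out / "scores_mean.tsv", **meta)
    replicate_r = None
    if len(scores) >= 2:
        try:
            replicate_r, n_shared = scoring.replicate_correlation(scores[0], scores[1])
            log.info("replicate Pearson r = %.3f over %d variants", replicate_r, n_shared)
        except Exception:
            log.warning("replicate correlation unavailable (too few shared variants)")

    log.info("stage features")
    try:
        feature_table = feat.annotate(
            mean, amber_suppression=config.amber_suppression
        )
        if config.dg_table:
            feature_table = feat.attach_folding_energies(
                feature_table, sio.load_dg_table(config.dg_table)
            )
    except Exception as exc:
        raise RuntimeError(f"stage features failed: {exc}") from exc
    sio.write_table(feature_table, out / "features.tsv", **meta)

    log.info("stage motifs")
    try:
        high, low = mot.stratify_scores(mean, config.high_min, config.low_max)
        rows = []
        if len(high) and len(low):
            for pattern in DEFAULT_PATTERNS:
                rows.append(
                    mot.enrichment(pattern, high, low, "pooled", mean).as_dict()
                )
        else:
            log.warning(
                "empty score stratum (high n=%d, low n=%d); skipping enrichment",
                len(high), len(low),
            )
        enrich = pd.DataFrame(rows)
    except Exception as exc:
        raise RuntimeError(f"stage motifs failed: {exc}") from exc
    sio.write_table(enrich, out / "motif_enrichment.tsv", **meta)

    return PipelineResult(
        scores, mean, feature_table, enrich, truth_df, replicate_r, out
    )
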