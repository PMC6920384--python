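"""Single-molecule translation traces: simulation and quantification.

A translating ribosome alternates between non-rotated and rotated
conformational states once per elongation cycle.  The simulator models
early-elongation arrest as an irreversible branch before decoding each
codon: with probability q_k the ribosome aborts before codon k and
remains in a terminal non-rotated-like dwell, optionally emitting brief
A-site tRNA sampling events.  Estimators recover processivity (fraction
of ribosomes completing the ORF, with binomial standard error) and
exponential state lifetimes by maximum likelihood, with an optional
correction for the camera's frame discretization.  Bulk quantifications
(peptide accumulation ratios, relative fluorescence quantum yield) live
here too.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ConfigurationError, GapError, TraceFormatError

NON_ROTATED = "non-rotated"
ROTATED = "rotated"

#: Measured completion fractions for the three reference codon-3-5
#: constructs (high / medium / low expression), usable as simulator
#: presets.  n = 179 molecules each in the source experiments.
PROCESSIVITY_PRESETS = {"KIH": 0.84, "IGK": 0.54, "TVG": 0.27}


@dataclass
class Trace:
    """One ribosome's dwell record plus labeled-tRNA binding events.

    ``dwells`` strictly alternates non-rotated / rotated states starting
    non-rotated; each traversed codon contributes one (non-rotated,
    rotated) pair, and an aborted trace ends in a terminal non-rotated-
    like dwell.  ``trna_events`` holds (codon index, binding duration s)
    pairs.  ``outcome`` is "completed" or "aborted_at:<k>".
    """

    dwells: list[tuple[str, float]]
    trna_events: list[tuple[int, float]] = field(default_factory=list)
    outcome: str = "completed"
    frame_rate: float = 10.0
    donor_bleach_s: float | None = None
    acceptor_bleach_s: float | None = None

    def validate(self) -> None:
        expected = NON_ROTATED
        for state, dur in self.dwells:
            if state != expected:
                raise TraceFormatError(
                    f"states must strictly alternate starting {NON_ROTATED}; "
                    f"got {state!r} where {expected!r} expected"
                )
            if dur <= 0:
                raise TraceFormatError(f"non-positive dwell duration {dur}")
            expected = ROTATED if expected == NON_ROTATED else NON_ROTATED

    @property
    def n_elongation_cycles(self) -> int:
        """Completed (non-rotated, rotated) pairs, i.e. codons traversed."""
        return sum(1 for state, _ in self.dwells if state == ROTATED)

    def to_json(self) -> str:
        return json.dumps(
            {
                "dwells": self.dwells,
                "trna_events": self.trna_events,
                "outcome": self.outcome,
                "frame_rate": self.frame_rate,
                "donor_bleach_s": self.donor_bleach_s,
                "acceptor_bleach_s": self.acceptor_bleach_s,
            }
        )

    @classmethod
    def from_json(cls, line: str) -> "Trace":
        d = json.loads(line)
        return cls(
            dwells=[(s, float(t)) for s, t in d["dwells"]],
            trna_events=[(int(k), float(t)) for k, t in d.get("trna_events", [])],
            outcome=d.get("outcome", "completed"),
            frame_rate=float(d.get("frame_rate", 10.0)),
            donor_bleach_s=d.get("donor_bleach_s"),
            acceptor_bleach_s=d.get("acceptor_bleach_s"),
        )


def write_traces(traces: Iterable[Trace], path: str | Path) -> int:
    n = 0
    with open(path, "w") as fh:
        for t in traces:
            fh.write(t.to_json() + "\n")
            n += 1
    return n


def read_traces(path: str | Path) -> list[Trace]:
    with open(path) as fh:
        return [Trace.from_json(line) for line in fh if line.strip()]


@dataclass
class ElongationModel:
    """Kinetic parameters of early elongation with abortive branch points.

    ``abort_probs`` holds q_k for codons starting at ``first_codon``
    (default codon 3, the first codon after the initial elongation on
    codon 2): the probability of an irreversible arrest before decoding
    that codon.  State dwell times are exponential with the given rates
    (1/s).  Arrested complexes emit Poisson tRNA sampling events with
    exponential durations (default mostly below the 100 ms stable-
    binding threshold).
    """

    abort_probs: tuple[float, ...]
    first_codon: int = 3
    nonrotated_rate: float = 5.0
    rotated_rate: float = 2.0
    sampling_event_rate: float = 0.002
    sampling_mean_s: float = 0.04
    arrest_dwell_mean_s: float = 60.0
    frame_rate: float = 10.0

    def __post_init__(self) -> None:
        if any(not 0.0 <= q <= 1.0 for q in self.abort_probs):
            raise ConfigurationError(f"abort probabilities outside [0,1]: "
                                     f"{self.abort_probs}")
        if min(self.nonrotated_rate, self.rotated_rate) <= 0:
            raise ConfigurationError("state rates must be positive")

    @property
    def expected_completion(self) -> float:
        return float(np.prod([1.0 - q for q in self.abort_probs]))

    @classmethod
    def from_preset(
        cls, name: str, n_abort_codons: int = 2, **kwargs
    ) -> "ElongationModel":
        """Model whose expected completion matches a named preset.

        The abort probability is split evenly over ``n_abort_codons``
        codons starting at codon 4, where arrests concentrated in the
        reference experiments.
        """
        p = PROCESSIVITY_PRESETS[name]
        q = 1.0 - p ** (1.0 / n_abort_codons)
        return cls(
            abort_probs=(0.0,) + (q,) * n_abort_codons, first_codon=3, **kwargs
        )


def _discretize(durations: np.ndarray, frame_rate: float) -> np.ndarray:
    """Floor to the frame grid with a one-frame minimum."""
    dt = 1.0 / frame_rate
    return np.maximum(1, np.floor(durations / dt)) * dt


def simulate_traces(
    model: ElongationModel,
    orf_codons: int,
    n: int,
    seed: int | np.random.Generator | None = None,
) -> list[Trace]:
    """Simulate ``n`` ribosomes over an ORF of ``orf_codons`` codons.

    Codons ``first_codon`` .. ``orf_codons`` each require an elongation
    cycle; before each, the trace aborts with its q_k.  Codons beyond
    the abort_probs vector carry q = 0.  Dwell durations are
    discretized at the camera frame rate.
    """
    if n <= 0:
        raise ConfigurationError(f"n must be positive, got {n}")
    if orf_codons < model.first_codon:
        raise ConfigurationError(
            f"ORF of {orf_codons} codons ends before codon {model.first_codon}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    q = np.zeros(orf_codons + 1)
    stop = min(model.first_codon + len(model.abort_probs), orf_codons + 1)
    q[model.first_codon : stop] = model.abort_probs[: stop - model.first_codon]
    traces = []
    for _ in range(n):
        dwells: list[tuple[str, float]] = []
        # initial elongation on codon 2 has already happened; walk 3..end
        aborted_at = 0
        for k in range(model.first_codon, orf_codons + 1):
            if q[k] > 0 and rng.random() < q[k]:
                aborted_at = k
                break
            pair = _discretize(
                np.array(
                    [
                        rng.exponential(1.0 / model.nonrotated_rate),
                        rng.exponential(1.0 / model.rotated_rate),
                    ]
                ),
                model.frame_rate,
            )
            dwells.append((NON_ROTATED, float(pair[0])))
            dwells.append((ROTATED, float(pair[1])))
        events: list[tuple[int, float]] = []
        if aborted_at:
            terminal = float(
                _discretize(
                    np.array([rng.exponential(model.arrest_dwell_mean_s)]),
                    model.frame_rate,
                )[0]
            )
            dwells.append((NON_ROTATED, terminal))
            n_events = rng.poisson(model.sampling_event_rate * terminal)
            for _ in range(n_events):
                events.append(
                    (aborted_at, float(rng.exponential(model.sampling_mean_s)))
                )
            outcome = f"aborted_at:{aborted_at}"
        else:
            outcome = "completed"
        traces.append(
            Trace(
                dwells=dwells,
                trna_events=events,
                outcome=outcome,
                frame_rate=model.frame_rate,
            )
        )
    return traces


def classify_trace(
    trace: Trace, orf_codons: int, sampling_threshold_s: float = 0.1
) -> str:
    """completed | aborted_no_sampling | aborted_with_sampling.

    A trace is completed when it traversed every codon from codon 3 to
    the last sense codon (one elongation cycle each).  Aborted traces
    are subclassified by whether any post-arrest tRNA binding lasted
    strictly longer than the stable-binding threshold (default 100 ms).
    """
    trace.validate()
    needed = orf_codons - 2  # cycles for codons 3..orf_codons
    if trace.n_elongation_cycles >= needed:
        return "completed"
    if any(dur > sampling_threshold_s for _, dur in trace.trna_events):
        return "aborted_with_sampling"
    return "aborted_no_sampling"


def processivity(n_completed: int, n_total: int) -> tuple[float, float]:
    """Completion fraction and its binomial standard error.

    p = n_completed/n_total, se = sqrt(p(1-p)/n_total) -- the error bar
    convention for single-molecule completion percentages.
    """
    if n_total <= 0:
        raise ConfigurationError("n_total must be positive")
    if not 0 <= n_completed <= n_total:
        raise ConfigurationError(
            f"n_completed {n_completed} outside [0, {n_total}]"
        )
    p = n_completed / n_total
    return p, math.sqrt(p * (1.0 - p) / n_total)


def abort_profile(classes_or_traces: Sequence, orf_codons: int) -> pd.DataFrame:
    """Per-codon survival decrement: recovered abort probabilities q_k.

    Accepts Trace objects; estimates q_k = aborts at k / ribosomes
    reaching k, from the outcome fields.
    """
    reached = np.zeros(orf_codons + 2, dtype=int)
    aborted = np.zeros(orf_codons + 2, dtype=int)
    for t in classes_or_traces:
        if t.outcome == "completed":
            k_abort = None
        else:
            k_abort = int(t.outcome.split(":")[1])
        for k in range(3, orf_codons + 1):
            reached[k] += 1
            if k_abort == k:
                aborted[k] += 1
                break
    rows = [
        {
            "codon": k,
            "n_reached": int(reached[k]),
            "n_aborted": int(aborted[k]),
            "q_hat": aborted[k] / reached[k] if reached[k] else math.nan,
        }
        for k in range(3, orf_codons + 1)
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Lifetime MLE
# ---------------------------------------------------------------------------

def fit_exponential_mle(
    dwells: Sequence[float],
    confidence: float = 0.95,
    frame_rate: float | None = None,
) -> tuple[float, tuple[float, float]]:
    """Single-exponential lifetime MLE with a profile-likelihood CI.

    For exponential data the MLE of the mean is the sample mean, and the
    exact CI follows from 2*n*mean/tau ~ chi-square(2n).  When
    ``frame_rate`` is given, the estimate is corrected for camera
    discretization (dwells floored to the frame grid with a one-frame
    minimum) by inverting the exact expectation of the discretized
    observation; the CI is rescaled accordingly.
    """
    x = np.asarray(list(dwells), dtype=float)
    if x.size < 2:
        raise ConfigurationError(f"need at least 2 dwells, got {x.size}")
    if (x <= 0).any():
        raise ValueError("dwell durations must be positive")
    mean = float(x.mean())
    n = x.size
    lo = 2 * n * mean / stats.chi2.ppf(1 - (1 - confidence) / 2, 2 * n)
    hi = 2 * n * mean / stats.chi2.ppf((1 - confidence) / 2, 2 * n)
    if frame_rate is not None:
        corrected = _decensor_mean(mean, 1.0 / frame_rate)
        scale = corrected / mean if mean > 0 else 1.0
        return corrected, (lo * scale, hi * scale)
    return mean, (lo, hi)


def _decensor_mean(observed_mean: float, dt: float) -> float:
    """Invert E[dt * max(1, floor(T/dt))] for exponential T.

    With frames of length dt and q = exp(-dt/tau), the discretized
    observation has expectation dt * ((1-q) + q/(1-q)); solve for q and
    return tau.  Observed means at/below one frame give the shortest
    resolvable lifetime.
    """
    s = observed_mean / dt
    if s <= 1.0 + 1e-12:
        return dt  # everything in the first frame: lifetime unresolved
    f = lambda q: (1.0 - q) + q / (1.0 - q) - s
    q = optimize.brentq(f, 1e-12, 1.0 - 1e-12)
    return -dt / math.log(q)


def pooled_state_lifetimes(
    traces: Sequence[Trace],
    per_codon: bool = False,
    codon_range: tuple[int, int] = (3, 7),
    frame_rate: float | None = None,
) -> pd.DataFrame:
    """Exponential lifetime fits for non-rotated and rotated states.

    Pools dwells across codons by default; with ``per_codon`` fits each
    codon position in ``codon_range`` separately (terminal arrest dwells
    of aborted traces are excluded from both modes).
    """
    rows = []
    groups: dict[tuple[str, int | str], list[float]] = {}
    for t in traces:
        cycles = t.n_elongation_cycles
        usable = t.dwells[: 2 * cycles]  # drop any terminal arrest dwell
        for i, (state, dur) in enumerate(usable):
            codon = 3 + i // 2
            key = (state, codon if per_codon else "pooled")
            groups.setdefault(key, []).append(dur)
    for (state, codon), vals in sorted(groups.items(), key=str):
        if per_codon and not codon_range[0] <= int(codon) <= codon_range[1]:
            continue
        if len(vals) < 2:
            continue
        mean, (lo, hi) = fit_exponential_mle(vals, frame_rate=frame_rate)
        rows.append(
            {
                "state": state,
                "codon": codon,
                "n_dwells": len(vals),
                "lifetime_s": mean,
                "ci_low_s": lo,
                "ci_high_s": hi,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Bulk quantifications
# ---------------------------------------------------------------------------

def relative_accumulation(
    intensity_table: pd.DataFrame,
    reference_label: str,
    n_final_timepoints: int = 3,
) -> pd.Series:
    """End-of-reaction accumulation of each species relative to a reference.

    ``intensity_table`` has columns species, time_s, intensity (one lane
    per time point).  Each intensity is normalized to the total lane
    intensity at its time point, averaged over the last
    ``n_final_timepoints`` time points, and expressed relative to
    ``reference_label`` (whose ratio is 1 by construction).
    """
    required = {"species", "time_s", "intensity"}
    if not required <= set(intensity_table.columns):
        raise GapError(
            f"intensity table needs columns {sorted(required)}, got "
            f"{list(intensity_table.columns)}"
        )
    wide = intensity_table.pivot_table(
        index="time_s", columns="species", values="intensity", aggfunc="sum"
    )
    if wide.isna().any().any():
        missing = [
            f"{sp}@{t}s"
            for sp in wide.columns
            for t in wide.index[wide[sp].isna()]
        ]
        raise GapError(f"missing time points: {missing}")
    if len(wide) < n_final_timepoints:
        raise GapError(
            f"need >= {n_final_timepoints} time points per species, got {len(wide)}"
        )
    if reference_label not in wide.columns:
        raise GapError(f"reference species {reference_label!r} absent from table")
    lane_totals = wide.sum(axis=1)
    normalized = wide.div(lane_totals, axis=0)
    final = normalized.sort_index().iloc[-n_final_timepoints:].mean()
    return final / final[reference_label]


def relative_quantum_yield(
    grad: float, grad_ref: float, n: float, n_ref: float, q_ref: float
) -> float:
    """Q = Q_ref * (Grad/Grad_ref) * (n^2/n_ref^2).

    Gradient-method relative quantum yield: Grad is the slope of
    integrated fluorescence intensity vs optical density, n the solvent
    refractive index, and the reference a fluorophore of known yield.
    """
    if grad_ref <= 0 or n_ref <= 0:
        raise ValueError("reference gradient and refractive index must be positive")
    return q_ref * (grad / grad_ref) * (n**2 / n_ref**2)
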