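"""Composite candidate-peptide scoring and top-k selection.

Each mass-spectrometry candidate carries three positive quality channels:
MS abundance (score A), de novo sequencing confidence (score B), and the
magnitude of its docking binding energy against the target enzyme
(score C).  Each channel is normalized to [0, 100] and the total is a
weighted sum, 0.40*A + 0.30*B + 0.30*C by default.

The default normalization is ratio-to-maximum (value / channel max * 100),
which is the convention that reproduces published worked examples of this
scheme; classical min-max scaling is available via ``normalization="min_max"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "CandidatePeptide",
    "DEFAULT_WEIGHTS",
    "subscore",
    "score_candidates",
    "select_top",
    "load_candidates",
    "bundled_candidates",
]

DEFAULT_WEIGHTS = (0.40, 0.30, 0.30)


@dataclass(frozen=True)
class CandidatePeptide:
    """One MS candidate: sequence, abundance, confidence, binding energy."""

    sequence: str
    abundance: float
    confidence: float
    binding_energy: float  # kcal/mol; more negative = stronger binding

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("candidate needs a non-empty sequence")
        if self.abundance <= 0:
            raise ValueError(f"{self.sequence}: abundance must be > 0")
        if self.confidence <= 0:
            raise ValueError(f"{self.sequence}: confidence must be > 0")
        if self.binding_energy >= 0:
            raise ValueError(
                f"{self.sequence}: binding energy must be negative (kcal/mol)"
            )


def subscore(values, *, normalization: str = "ratio_to_max") -> np.ndarray:
    """Normalize positive channel values to [0, 100].

    ``ratio_to_max``: 100 * value / max(values) — the best value scores
    100 and ratios are preserved.  ``min_max``: classical rescaling of
    [min, max] onto [0, 100] (the worst value scores 0); degenerate
    all-equal inputs score 100 everywhere under both conventions.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("subscore needs at least one value")
    if (values <= 0).any():
        raise ValueError("subscore values must all be positive")
    if normalization == "ratio_to_max":
        return 100.0 * values / values.max()
    if normalization == "min_max":
        span = values.max() - values.min()
        if span == 0:
            return np.full_like(values, 100.0)
        return 100.0 * (values - values.min()) / span
    raise ValueError(f"unknown normalization {normalization!r}")


def _as_frame(candidates) -> pd.DataFrame:
    if isinstance(candidates, pd.DataFrame):
        required = {"sequence", "abundance", "confidence", "binding_energy"}
        missing = required - set(candidates.columns)
        if missing:
            raise ValueError(f"candidate table is missing column(s) {sorted(missing)}")
        # route through the dataclass for validation
        candidates = [
            CandidatePeptide(
                sequence=str(r.sequence),
                abundance=float(r.abundance),
                confidence=float(r.confidence),
                binding_energy=float(r.binding_energy),
            )
            for r in candidates.itertuples()
        ]
    return pd.DataFrame(
        {
            "sequence": [c.sequence for c in candidates],
            "abundance": [c.abundance for c in candidates],
            "confidence": [c.confidence for c in candidates],
            "binding_energy": [c.binding_energy for c in candidates],
        }
    )


def score_candidates(
    candidates,
    *,
    weights=DEFAULT_WEIGHTS,
    normalization: str = "ratio_to_max",
) -> pd.DataFrame:
    """Score card: subscores, weighted total, and deterministic rank.

    ``candidates`` is a list of :class:`CandidatePeptide` or a DataFrame
    with columns sequence/abundance/confidence/binding_energy.  Weights
    must be non-negative and sum to 1.  Ties on total are broken by
    descending abundance, then sequence.
    """
    w = np.asarray(weights, dtype=float)
    if w.shape != (3,) or (w < 0).any():
        raise ValueError("weights must be three non-negative numbers")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError(f"weights must sum to 1 (got {w.sum()!r})")
    card = _as_frame(candidates)
    if card.empty:
        raise ValueError("no candidates to score")
    card["score_a"] = subscore(card["abundance"], normalization=normalization)
    card["score_b"] = subscore(card["confidence"], normalization=normalization)
    card["score_c"] = subscore(-card["binding_energy"], normalization=normalization)
    card["total"] = w[0] * card["score_a"] + w[1] * card["score_b"] + w[2] * card["score_c"]
    card = card.sort_values(
        ["total", "abundance", "sequence"], ascending=[False, False, True]
    ).reset_index(drop=True)
    card["rank"] = np.arange(1, len(card) + 1)
    return card


def select_top(card: pd.DataFrame, k: int) -> pd.DataFrame:
    """The k highest-ranked rows of a score card, in rank order."""
    if not 1 <= k <= len(card):
        raise ValueError(f"k must be between 1 and {len(card)} (got {k})")
    return card.nsmallest(k, "rank").sort_values("rank").reset_index(drop=True)


def load_candidates(path) -> pd.DataFrame:
    """Read a comma-separated candidate table (sequence,abundance,confidence,binding_energy)."""
    table = pd.read_csv(path)
    required = {"sequence", "abundance", "confidence", "binding_energy"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return table


def bundled_candidates() -> pd.DataFrame:
    """The bundled example table of seven royal-jelly hydrolysate peptides.

    Columns beyond the four raw channels carry the reported subscores,
    totals, and measured ACE inhibition of the original screen, for use
    as a worked example and regression fixture.
    """
    with resources.as_file(
        resources.files("acepep.data").joinpath("candidate_peptides.csv")
    ) as p:
        return pd.read_csv(p)
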