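"""Liability model: polygenic score -> log odds -> disease prevalence.

The model treats an individual's polygenic score (PGS, in raw log-odds
units) as an additive shift on the baseline log odds of disease,

    L(pgs) = beta0 + pgs,          beta0 = logit(background_rate)

and maps liability back to prevalence through the logistic function.  A
variant that adds ``delta`` to the PGS therefore changes the log odds by
exactly ``delta`` in every genetic background — but its effect on the odds
(multiplied by exp(beta0 + pgs)) and on absolute prevalence depends strongly
on both the background PGS and the background rate of disease.  That
contrast between additivity on the log-odds scale and background-dependent
penetrance is what this module quantifies.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

__all__ = [
    "LiabilityModel",
    "VariantEffectProfile",
    "model_from_background_rate",
    "log_odds_at",
    "prevalence_at",
    "variant_effect_profile",
    "profiles_to_frame",
]

# Open-interval clamp limits for probabilities: the logistic saturates to
# exactly 0.0/1.0 in floating point around |L| ~ 745; outputs are clamped to
# the nearest representable values strictly inside (0, 1).
_P_MIN = np.nextafter(0.0, 1.0)
_P_MAX = np.nextafter(1.0, 0.0)

#: Column order of the TSV/DataFrame export of variant-effect profiles.
PROFILE_COLUMNS = [
    "background_rate",
    "pgs",
    "log_odds_change",
    "odds_ratio_change",
    "prevalence_without",
    "prevalence_with",
    "prevalence_change",
]


@dataclass(frozen=True)
class LiabilityModel:
    """Logistic liability model anchored at a reference-group disease rate.

    ``background_rate`` is the disease prevalence in the reference group
    (PGS = 0); ``baseline_log_odds`` is its logit.
    """

    background_rate: float

    def __post_init__(self) -> None:
        r = self.background_rate
        if not (0.0 < r < 1.0):
            raise ValueError(f"background_rate must be in (0, 1), got {r!r}")

    @property
    def baseline_log_odds(self) -> float:
        """beta0 = ln(rate / (1 - rate))."""
        return float(logit(self.background_rate))


def model_from_background_rate(rate: float) -> LiabilityModel:
    """Build a liability model whose PGS=0 prevalence equals ``rate``."""
    return LiabilityModel(background_rate=rate)


def log_odds_at(model: LiabilityModel, pgs: float | np.ndarray) -> float | np.ndarray:
    """Log odds of disease at a given PGS: beta0 + pgs (exactly linear)."""
    out = model.baseline_log_odds + np.asarray(pgs, dtype=float)
    return float(out) if out.ndim == 0 else out


def prevalence_at(model: LiabilityModel, pgs: float | np.ndarray) -> float | np.ndarray:
    """Disease probability at a given PGS via the logistic transform.

    Numerically stable for arbitrarily large |liability|; outputs are clamped
    into the open interval (0, 1) at the floating-point limits rather than
    saturating to 0 or 1.
    """
    L = np.asarray(log_odds_at(model, pgs), dtype=float)
    p = np.clip(expit(L), _P_MIN, _P_MAX)
    return float(p) if p.ndim == 0 else p


@dataclass(frozen=True)
class VariantEffectProfile:
    """Per-grid-point consequences of a variant of log-odds effect ``delta``.

    ``log_odds_change`` is the (constant) change in log odds; the
    multiplicative odds-ratio effect exp(delta) is likewise constant and
    exposed as :attr:`odds_ratio_multiplier`.  ``odds_ratio_change`` is the
    absolute change in odds, exp(beta0+pgs)*(exp(delta)-1), which grows with
    the background PGS; ``prevalence_change`` is the absolute change in
    disease probability.
    """

    model: LiabilityModel
    delta: float
    pgs_grid: np.ndarray
    log_odds_change: np.ndarray
    odds_ratio_change: np.ndarray
    prevalence_without: np.ndarray
    prevalence_with: np.ndarray
    prevalence_change: np.ndarray

    @property
    def odds_ratio_multiplier(self) -> float:
        """exp(delta): the background-independent multiplicative odds effect."""
        return float(np.exp(self.delta))

    def to_frame(self) -> pd.DataFrame:
        """One row per grid point, columns as in :data:`PROFILE_COLUMNS`."""
        return pd.DataFrame(
            {
                "background_rate": self.model.background_rate,
                "pgs": self.pgs_grid,
                "log_odds_change": self.log_odds_change,
                "odds_ratio_change": self.odds_ratio_change,
                "prevalence_without": self.prevalence_without,
                "prevalence_with": self.prevalence_with,
                "prevalence_change": self.prevalence_change,
            },
            columns=PROFILE_COLUMNS,
        )


def variant_effect_profile(
    model: LiabilityModel, delta: float, pgs_grid: Sequence[float]
) -> VariantEffectProfile:
    """Profile a variant's effect across a grid of background PGS values.

    The change in log odds is ``delta`` at every grid point by the additive
    identity (beta0 + pgs + delta) - (beta0 + pgs) = delta; it is stored as
    the exact constant rather than recomputed by subtraction.
    """
    grid = np.asarray(pgs_grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise ValueError("pgs_grid must be a non-empty 1-D sequence")
    if grid.size > 1 and not np.all(np.diff(grid) > 0):
        raise ValueError("pgs_grid must be strictly increasing")
    if not np.isfinite(delta):
        raise ValueError("delta must be finite")

    without = np.asarray(prevalence_at(model, grid))
    with_v = np.asarray(prevalence_at(model, grid + delta))
    odds_without = np.exp(model.baseline_log_odds + grid)
    odds_change = odds_without * (np.exp(delta) - 1.0)
    return VariantEffectProfile(
        model=model,
        delta=float(delta),
        pgs_grid=grid,
        log_odds_change=np.full_like(grid, float(delta)),
        odds_ratio_change=odds_change,
        prevalence_without=without,
        prevalence_with=with_v,
        prevalence_change=with_v - without,
    )


def profiles_to_frame(profiles: Sequence[VariantEffectProfile]) -> pd.DataFrame:
    """Stack profiles (e.g. one per background rate) into a single long table."""
    if not profiles:
        raise ValueError("need at least one profile")
    return pd.concat([p.to_frame() for p in profiles], ignore_index=True)
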