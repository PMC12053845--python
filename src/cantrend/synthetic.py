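"""Seeded generator of coupled incidence / search-interest series.

The generator emulates the premise the ratio model rests on: public
search interest for a disease topic tracks its incidence.  Each region
gets a geometric-random-walk incidence trajectory

    incidence[r, t] = incidence[r, t-1] * exp(trend[r] + eps[r, t]),
    eps ~ Normal(0, incidence_noise_sd^2)

and a search index proportional to a power of incidence with its own
multiplicative noise

    rsvi_raw[r, t] = incidence[r, t]**gamma * exp(eta[r, t]),
    eta ~ Normal(0, rsvi_noise_sd^2).

Each region's index is rescaled so its in-window maximum is 100 (the way
a search-trends service normalizes within a query window); with
``integer_rescale`` the values are additionally rounded to integers with
floor 1, emulating the published 0-100 integer scale.  Noise is
multiplicative log-normal because both quantities are positive and the
estimator is a ratio, making its error scale-free.

With ``coupling_exponent=1`` and both noise terms zero the ratio model
recovers every count up to floating rounding — the generator's headline
correctness property.  The two noise streams are seeded independently
from the master seed so one can be zeroed without shifting the other.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .core import ACTUAL, IncidenceSeries, RSVISeries

__all__ = ["SyntheticConfig", "GroundTruth", "generate"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters.

    Defaults emulate US-state-scale registries observed over five years:
    counts in the thousands-to-hundreds-of-thousands range, a small
    secular drift, mild year-to-year noise, perfect proportional
    coupling, and the integer 0-100 index scale.
    """

    n_regions: int = 50
    years: tuple[int, int] = (2016, 2020)  # inclusive
    base_count_range: tuple[int, int] = (3_000, 180_000)
    annual_trend: float = 0.01          # log-scale drift per year
    trend_sd: float = 0.02              # between-region spread of the drift
    incidence_noise_sd: float = 0.02    # log-scale, per region-year
    coupling_exponent: float = 1.0      # gamma; 1 = proportional coupling
    rsvi_noise_sd: float = 0.05         # log-scale, per region-year
    integer_rescale: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 1:
            raise ValueError("n_regions must be >= 1")
        if self.years[1] < self.years[0]:
            raise ValueError(f"empty year range {self.years}")
        lo, hi = self.base_count_range
        if not (0 < lo <= hi):
            raise ValueError(f"invalid base_count_range {self.base_count_range}")
        for name in ("trend_sd", "incidence_noise_sd", "rsvi_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """Everything the generator knows: the exact latent series."""

    config: SyntheticConfig
    trends: Mapping[str, float]
    incidence: Mapping[str, Mapping[int, float]]   # exact (float) counts
    rsvi_exact: Mapping[str, Mapping[int, float]]  # rescaled, pre-integer


def _region_codes(n: int) -> list[str]:
    return [f"R{i:03d}" for i in range(n)]


def generate(
    config: SyntheticConfig,
) -> tuple[dict[str, IncidenceSeries], dict[str, RSVISeries], GroundTruth]:
    """Generate coupled incidence and RSVI collections plus ground truth.

    Deterministic: the same config (including seed) always produces
    bit-identical output.
    """
    y0, y1 = config.years
    years = list(range(y0, y1 + 1))
    n_years = len(years)
    regions = _region_codes(config.n_regions)

    # independent child streams: base counts/trends, incidence noise, rsvi noise
    ss = np.random.SeedSequence(config.seed)
    rng_base, rng_eps, rng_eta = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )

    lo, hi = config.base_count_range
    base = rng_base.uniform(lo, hi, size=config.n_regions)
    trends = config.annual_trend + config.trend_sd * rng_base.standard_normal(
        config.n_regions
    )
    eps = (
        config.incidence_noise_sd
        * rng_eps.standard_normal((config.n_regions, n_years - 1))
        if n_years > 1
        else np.zeros((config.n_regions, 0))
    )
    eta = config.rsvi_noise_sd * rng_eta.standard_normal(
        (config.n_regions, n_years)
    )

    incidence: dict[str, IncidenceSeries] = {}
    rsvi: dict[str, RSVISeries] = {}
    gt_inc: dict[str, dict[int, float]] = {}
    gt_rsvi: dict[str, dict[int, float]] = {}

    for i, region in enumerate(regions):
        counts = np.empty(n_years)
        counts[0] = base[i]
        for t in range(1, n_years):
            counts[t] = counts[t - 1] * np.exp(trends[i] + eps[i, t - 1])
        raw = counts ** config.coupling_exponent * np.exp(eta[i])
        scaled = raw / raw.max() * 100.0
        if config.integer_rescale:
            index = np.maximum(np.floor(scaled + 0.5), 1.0)
        else:
            index = scaled
        incidence[region] = IncidenceSeries(
            region=region,
            values=dict(zip(years, counts)),
            provenance={y: ACTUAL for y in years},
        )
        rsvi[region] = RSVISeries(region=region, values=dict(zip(years, index)))
        gt_inc[region] = dict(zip(years, counts))
        gt_rsvi[region] = dict(zip(years, scaled))

    return incidence, rsvi, GroundTruth(
        config=config, trends=dict(zip(regions, trends)),
        incidence=gt_inc, rsvi_exact=gt_rsvi,
    )
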