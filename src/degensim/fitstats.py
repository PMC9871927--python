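"""Relative-fitness statistics and phenotype-trajectory summaries.

The core statistic is the competition odds ratio

    w = [x2 (1 - x1)] / [x1 (1 - x2)]

comparing a mutant's proportion before (``x1``) and after (``x2``) a
competition window; ``w > 1`` means the mutant outcompeted the reference.
Negative frequency-dependent fitness (the advantage shrinking as the mutant's
own starting frequency rises) is assessed by rank correlation of ``w``
against ``x1``, with the ``w = 1`` crossover frequency estimated by monotone
interpolation of per-frequency median fitness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .popsim import (
    MORPHOTYPES,
    GenotypeClass,
    PopulationState,
    RegimeConfig,
    grow_transfer,
)

__all__ = [
    "FitnessObservation",
    "FrequencyDependenceSummary",
    "SeriesSummary",
    "UndefinedFitnessError",
    "relative_fitness",
    "make_observation",
    "frequency_dependence",
    "generations_elapsed",
    "percent_change",
    "summarize_series",
    "simulate_competition_observations",
]


class UndefinedFitnessError(ValueError):
    """Raised when a proportion sits on the 0/1 boundary and w is undefined."""


def relative_fitness(x1: float, x2: float) -> float:
    """Competition fitness ``w = [x2 (1 - x1)] / [x1 (1 - x2)]``.

    Both proportions must lie strictly inside (0, 1); boundary values (one
    competitor below plating detection) raise :class:`UndefinedFitnessError`
    rather than returning an infinity.  ``w == 1`` iff ``x1 == x2``.
    """
    if not 0.0 < x1 < 1.0 or not 0.0 < x2 < 1.0:
        raise UndefinedFitnessError(
            f"proportions must be strictly inside (0, 1); got x1={x1}, x2={x2}"
        )
    return (x2 * (1.0 - x1)) / (x1 * (1.0 - x2))


@dataclass
class FitnessObservation:
    """One competition-assay measurement.

    ``boundary`` flags observations where either proportion hit 0 or 1
    (``w`` is then None instead of an infinity).
    """

    x1: float
    x2: float
    timepoint_h: float = 24.0
    mutant_id: str = "mutant"
    competitor_id: str = "WT"
    w: float | None = None
    boundary: bool = False


def make_observation(
    x1: float,
    x2: float,
    timepoint_h: float = 24.0,
    mutant_id: str = "mutant",
    competitor_id: str = "WT",
) -> FitnessObservation:
    """Build a :class:`FitnessObservation`, flagging boundary proportions."""
    obs = FitnessObservation(x1, x2, timepoint_h, mutant_id, competitor_id)
    try:
        obs.w = relative_fitness(x1, x2)
    except UndefinedFitnessError:
        obs.boundary = True
    return obs


@dataclass
class FrequencyDependenceSummary:
    spearman_rho: float
    spearman_p: float
    kendall_tau: float
    kendall_p: float
    crossover_x1: float | None
    negative_dependence: bool
    n_observations: int
    alpha: float


def _crossover(x1s: np.ndarray, ws: np.ndarray) -> float | None:
    """Monotone-median interpolation of the x1 where fitted w crosses 1.

    Medians per distinct x1 are made non-increasing by a running minimum
    before linear interpolation, since negative frequency dependence is the
    model under assessment.
    """
    order = np.argsort(x1s)
    xs, med = [], []
    for x in np.unique(x1s[order]):
        xs.append(x)
        med.append(float(np.median(ws[x1s == x])))
    med = np.minimum.accumulate(med)
    for (xa, wa), (xb, wb) in zip(zip(xs, med), zip(xs[1:], med[1:])):
        if wa > 1.0 >= wb:
            if wa == wb:
                return float(xb)
            return float(xa + (xb - xa) * (wa - 1.0) / (wa - wb))
    return None


def frequency_dependence(
    observations: list[FitnessObservation], alpha: float = 0.05
) -> FrequencyDependenceSummary:
    """Rank-correlation assessment of fitness against starting frequency.

    Requires at least 5 interior (non-boundary) observations spanning at
    least 3 distinct ``x1`` values.  Negative frequency dependence is
    declared iff the Spearman correlation of ``w`` with ``x1`` is negative
    with p < ``alpha``.
    """
    interior = [o for o in observations if not o.boundary and o.w is not None]
    x1s = np.array([o.x1 for o in interior])
    ws = np.array([o.w for o in interior])
    if len(interior) < 5 or len(np.unique(x1s)) < 3:
        raise ValueError(
            "need >= 5 interior observations spanning >= 3 distinct x1 values"
        )
    rho, p_rho = stats.spearmanr(x1s, ws)
    tau, p_tau = stats.kendalltau(x1s, ws)
    return FrequencyDependenceSummary(
        spearman_rho=float(rho),
        spearman_p=float(p_rho),
        kendall_tau=float(tau),
        kendall_p=float(p_tau),
        crossover_x1=_crossover(x1s, ws),
        negative_dependence=bool(rho < 0 and p_rho < alpha),
        n_observations=len(interior),
        alpha=alpha,
    )


def generations_elapsed(n_transfers: int, dilution_factor: float) -> float:
    """Regrowth generations over a transfer series: ``n * log2(1/d)``.

    Five 1:10 transfers give 16.6 generations (each transfer requires
    ``log2(10) ~ 3.32`` doublings to restore the pre-dilution density).
    """
    if n_transfers < 0:
        raise ValueError("n_transfers must be >= 0")
    if not 0.0 < dilution_factor < 1.0:
        raise ValueError("dilution_factor must be in (0, 1)")
    return n_transfers * math.log2(1.0 / dilution_factor)


def percent_change(initial: float, final: float) -> float:
    """Signed percent change ``100 * (final - initial) / initial``."""
    if initial <= 0:
        raise ValueError("initial value must be positive")
    return 100.0 * (final - initial) / initial


@dataclass
class SeriesSummary:
    solvents_max: float
    solvents_max_subculture: int
    solvents_min: float
    solvents_min_subculture: int
    solvent_percent_change: float
    acid_percent_change: float
    spore_log10: list[float]
    dominant_morphotype: dict[int, str]
    final_dominant: str


def summarize_series(phenotypes: pd.DataFrame) -> SeriesSummary:
    """Summarize a phenotype trajectory table.

    Expects the :attr:`degensim.popsim.SeriesResult.phenotypes` layout
    (indexed by subculture, with ``solvents_gL``, ``acids_gL``,
    ``spores_cfu`` and ``frac_<morphotype>`` columns; morphotype columns are
    optional).  Solvent change is measured from the solvent maximum to the
    final subculture and acid change from the same reference subculture,
    mirroring how productivity loss is reported against the early-series
    peak.  Dominant morphotype ties break in RD, DCOG, CIC, FW order.
    """
    if len(phenotypes) < 2:
        raise ValueError("need at least 2 subcultures to summarize")
    solv = phenotypes["solvents_gL"]
    acids = phenotypes["acids_gL"]
    i_max = int(solv.idxmax())
    i_min = int(solv.idxmin())
    last = phenotypes.index[-1]
    summary = SeriesSummary(
        solvents_max=float(solv.loc[i_max]),
        solvents_max_subculture=i_max,
        solvents_min=float(solv.loc[i_min]),
        solvents_min_subculture=i_min,
        solvent_percent_change=percent_change(solv.loc[i_max], solv.loc[last]),
        acid_percent_change=percent_change(acids.loc[i_max], acids.loc[last]),
        spore_log10=[
            float(np.log10(s + 1)) for s in phenotypes.get("spores_cfu", pd.Series(dtype=float))
        ],
        dominant_morphotype={},
        final_dominant="",
    )
    frac_cols = [f"frac_{m}" for m in MORPHOTYPES if f"frac_{m}" in phenotypes.columns]
    if frac_cols:
        for sub, row in phenotypes[frac_cols].iterrows():
            best = max(MORPHOTYPES, key=lambda m: (row.get(f"frac_{m}", 0.0), -MORPHOTYPES.index(m)))
            summary.dominant_morphotype[int(sub)] = best
        summary.final_dominant = summary.dominant_morphotype[int(last)]
    return summary


def simulate_competition_observations(
    mutant: GenotypeClass,
    competitor: GenotypeClass,
    x1_values: list[float],
    seed: int | None = None,
    carrying_capacity: int = 10_000,
    dilution_factor: float = 0.1,
    timepoint_h: float = 24.0,
) -> list[FitnessObservation]:
    """Simulate a pairwise competition assay over a set of starting ratios.

    For each target ``x1``, a mixed inoculum of size ``K * dilution_factor``
    is grown through one transfer interval (no mutation); the realized
    starting and final proportions (whole-culture, vegetative + spores, as a
    colony-count analogue) yield one :class:`FitnessObservation`.
    """
    rng = np.random.default_rng(seed)
    regime = RegimeConfig(
        dilution_factor=dilution_factor,
        transfer_interval_h=timepoint_h,
        carrying_capacity=carrying_capacity,
        mutation_rate=0.0,
    )
    n0 = max(int(round(carrying_capacity * dilution_factor)), 2)
    observations = []
    for x1 in x1_values:
        n_mut = int(round(x1 * n0))
        n_mut = min(max(n_mut, 1), n0 - 1)
        state = PopulationState(
            subculture_index=0,
            vegetative={mutant.id: n_mut, competitor.id: n0 - n_mut},
            spores={mutant.id: 0, competitor.id: 0},
        )
        grown = grow_transfer(state, [mutant, competitor], regime, rng)
        x1_real = n_mut / n0
        x2 = grown.frequency(mutant.id)
        observations.append(
            make_observation(
                x1_real,
                x2,
                timepoint_h=timepoint_h,
                mutant_id=mutant.id,
                competitor_id=competitor.id,
            )
        )
    return observations
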