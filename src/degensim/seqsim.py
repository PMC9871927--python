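"""Synthetic ultra-deep pooled-sequencing pileups from true allele frequencies.

Whole-population sequencing of a subculture is emulated per site as:

* total depth drawn negative-binomially around a configurable mean
  (default 368x, matching the median depth regime the filter rules were
  designed for), with overdispersion giving a coefficient of variation of
  about 0.2;
* reads split into two orientation strata ("first-forward" /
  "first-reverse") by a binomial at the orientation balance;
* alternate reads per stratum drawn binomially at
  ``q = af * (1 - e) + (1 - af) * e / 3`` where ``e`` is the per-base
  miscall rate (a miscall hits one specific alternate base with
  probability ``e/3``).

Orientation strata stand in for read-pair orientation only as two
independent read partitions; no alignment-level semantics are modeled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PileupSite",
    "SeqParams",
    "simulate_pileup",
    "simulate_pileup_batch",
    "simulate_series_pileups",
    "PILEUP_COLUMNS",
]

PILEUP_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "fwd_ref",
    "fwd_alt",
    "rev_ref",
    "rev_alt",
    "mean_bq",
    "subculture",
    "replicate",
]

_BASES = np.array(list("ACGT"))


@dataclass
class PileupSite:
    """Per-site, per-orientation read counts at one subculture."""

    chrom: str
    pos: int
    ref: str
    alt: str
    fwd_ref: int
    fwd_alt: int
    rev_ref: int
    rev_alt: int
    mean_bq: float

    @property
    def depth(self) -> int:
        return self.fwd_ref + self.fwd_alt + self.rev_ref + self.rev_alt

    @property
    def alt_total(self) -> int:
        return self.fwd_alt + self.rev_alt

    @property
    def af_fwd(self) -> float | None:
        d = self.fwd_ref + self.fwd_alt
        return self.fwd_alt / d if d else None

    @property
    def af_rev(self) -> float | None:
        d = self.rev_ref + self.rev_alt
        return self.rev_alt / d if d else None

    @property
    def af(self) -> float | None:
        return self.alt_total / self.depth if self.depth else None


@dataclass
class SeqParams:
    """Sequencing model parameters.

    ``depth_dispersion`` is the negative-binomial size parameter ``k``
    (variance ``m + m^2/k``); the default 26.8 gives CV ~ 0.2 at the default
    mean depth.  Base qualities are drawn normally and floored at
    ``bq_floor``.
    """

    mean_depth: float = 368.0
    depth_dispersion: float = 26.8
    error_rate: float = 0.001
    orientation_balance: float = 0.5
    bq_mean: float = 35.0
    bq_sd: float = 3.0
    bq_floor: float = 20.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if not 0.0 <= self.error_rate <= 0.05:
            raise ValueError("error_rate must be in [0, 0.05]")
        if not 0.0 < self.orientation_balance < 1.0:
            raise ValueError("orientation_balance must be in (0, 1)")
        if self.depth_dispersion <= 0:
            raise ValueError("depth_dispersion must be positive")


def _alt_read_prob(true_af: np.ndarray, error_rate: float) -> np.ndarray:
    return true_af * (1.0 - error_rate) + (1.0 - true_af) * error_rate / 3.0


def simulate_pileup_batch(
    true_af: np.ndarray, params: SeqParams, rng: np.random.Generator
) -> pd.DataFrame:
    """Vectorized pileup simulation: one row per entry of ``true_af``.

    Returns a DataFrame with fwd/rev ref/alt counts and mean base quality;
    callers attach coordinates/labels as needed.
    """
    true_af = np.asarray(true_af, dtype=float)
    if np.any((true_af < 0) | (true_af > 1)):
        raise ValueError("true allele frequencies must lie in [0, 1]")
    n = len(true_af)
    k = params.depth_dispersion
    depth = rng.negative_binomial(k, k / (k + params.mean_depth), size=n)
    fwd = rng.binomial(depth, params.orientation_balance)
    rev = depth - fwd
    q = _alt_read_prob(true_af, params.error_rate)
    fwd_alt = rng.binomial(fwd, q)
    rev_alt = rng.binomial(rev, q)
    bq = np.maximum(rng.normal(params.bq_mean, params.bq_sd, size=n), params.bq_floor)
    return pd.DataFrame(
        {
            "fwd_ref": fwd - fwd_alt,
            "fwd_alt": fwd_alt,
            "rev_ref": rev - rev_alt,
            "rev_alt": rev_alt,
            "mean_bq": bq,
        }
    )


def simulate_pileup(
    true_af: float,
    params: SeqParams,
    rng: np.random.Generator,
    chrom: str = "chrom",
    pos: int = 1,
    ref: str = "C",
    alt: str = "A",
) -> PileupSite:
    """Simulate one pileup site at the given true allele frequency."""
    row = simulate_pileup_batch(np.array([true_af]), params, rng).iloc[0]
    return PileupSite(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        fwd_ref=int(row.fwd_ref),
        fwd_alt=int(row.fwd_alt),
        rev_ref=int(row.rev_ref),
        rev_alt=int(row.rev_alt),
        mean_bq=float(row.mean_bq),
    )


def simulate_series_pileups(
    truth: pd.DataFrame,
    params: SeqParams,
    rng: np.random.Generator | None = None,
    replicate: str = "rep1",
    n_background: int = 0,
    genome_length: int = 6_000_000,
    background_subcultures: list[int] | None = None,
) -> pd.DataFrame:
    """Simulate pileups for a whole truth table (one row per variant x subculture).

    ``truth`` needs columns ``chrom, pos, ref, alt, subculture, true_af`` (as
    produced by :meth:`degensim.popsim.SeriesResult.truth_table`).  In
    addition, ``n_background`` true-AF = 0 sites are simulated at random
    genomic positions across the same subcultures to exercise false-positive
    behavior.  Deterministic given ``params.seed`` (or an explicit ``rng``).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    frames = []
    if len(truth):
        bad = truth["true_af"].lt(0) | truth["true_af"].gt(1)
        if bad.any():
            raise ValueError("truth table has allele frequencies outside [0, 1]")
        counts = simulate_pileup_batch(truth["true_af"].to_numpy(), params, rng)
        body = truth[["chrom", "pos", "ref", "alt", "subculture"]].reset_index(drop=True)
        frames.append(pd.concat([body, counts], axis=1))
    if n_background > 0:
        subs = background_subcultures
        if subs is None:
            subs = sorted(truth["subculture"].unique()) if len(truth) else [0]
        pos = rng.integers(1, genome_length + 1, size=n_background)
        ref_idx = rng.integers(0, 4, size=n_background)
        alt_idx = (ref_idx + rng.integers(1, 4, size=n_background)) % 4
        sites = pd.DataFrame(
            {
                "chrom": "chrom",
                "pos": pos,
                "ref": _BASES[ref_idx],
                "alt": _BASES[alt_idx],
            }
        )
        expanded = sites.loc[sites.index.repeat(len(subs))].reset_index(drop=True)
        expanded["subculture"] = np.tile(subs, n_background)
        counts = simulate_pileup_batch(np.zeros(len(expanded)), params, rng)
        frames.append(pd.concat([expanded, counts], axis=1))
    if not frames:
        return pd.DataFrame(columns=PILEUP_COLUMNS)
    out = pd.concat(frames, ignore_index=True)
    out["replicate"] = replicate
    return out[PILEUP_COLUMNS]
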