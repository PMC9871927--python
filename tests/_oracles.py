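"""Independent brute-force oracles used by the tests.

These re-derive expected filter decisions and statistics directly from raw
counts and first principles (exact binomial tails, explicit rule-by-rule
evaluation), deliberately sharing no code with the package implementation.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats


def oracle_qual(alt_total: int, depth: int, error_rate: float, cap: float = 5000.0) -> float:
    """Phred score of the exact binomial upper tail, computed independently."""
    if alt_total == 0:
        return 0.0
    p = stats.binom.sf(alt_total - 1, depth, error_rate / 3.0)
    if p <= 0:
        return cap
    return min(-10.0 * math.log10(p), cap)


def oracle_site_labels(
    fwd_ref: int,
    fwd_alt: int,
    rev_ref: int,
    rev_alt: int,
    mean_bq: float,
    error_rate: float,
    qual_min: float = 100.0,
    af_min: float = 0.04,
    min_reads: int = 4,
    min_bq: float = 20.0,
    sb_alpha: float = 1e-3,
    consensus_min_af: float = 0.01,
    consensus_min_depth: int = 10,
) -> set[str]:
    """Evaluate every site-level rule independently and return failed labels."""
    labels: set[str] = set()
    fwd = fwd_ref + fwd_alt
    rev = rev_ref + rev_alt
    depth = fwd + rev
    alt = fwd_alt + rev_alt
    if oracle_qual(alt, depth, error_rate) < qual_min:
        labels.add("low_qual")
    af = alt / depth
    sb_p = stats.fisher_exact([[fwd_ref, fwd_alt], [rev_ref, rev_alt]])[1]
    if af < consensus_min_af or depth < consensus_min_depth or sb_p < sb_alpha:
        labels.add("no_consensus")
    ok_fwd = fwd > 0 and fwd_alt / fwd > af_min
    ok_rev = rev > 0 and rev_alt / rev > af_min
    if not (ok_fwd and ok_rev):
        labels.add("low_orientation_af")
    if fwd < min_reads or rev < min_reads or mean_bq < min_bq:
        labels.add("low_reads")
    return labels


def oracle_trajectory_labels(
    pos: int,
    afs: list[float],
    depths: list[int],
    subcultures: list[int],
    exclusions: list[tuple[str, int, int]],
    chrom: str = "chrom",
    recurrence_af: float = 0.08,
    recurrence_count: int = 3,
    starter_af_max: float = 0.5,
    depth_corr_threshold: float = 0.8,
    depth_corr_min_points: int = 6,
) -> set[str]:
    """Evaluate every trajectory-level rule independently."""
    labels: set[str] = set()
    if sum(1 for a in afs if a > recurrence_af) < recurrence_count:
        labels.add("insufficient_recurrence")
    for c, s, e in exclusions:
        if c == chrom and s <= pos <= e:
            labels.add("rrna")
    if 0 in subcultures and afs[subcultures.index(0)] > starter_af_max:
        labels.add("starter_background")
    if (
        len(afs) >= depth_corr_min_points
        and len(set(afs)) > 1
        and len(set(depths)) > 1
    ):
        rho = stats.spearmanr(afs, depths).statistic
        if np.isfinite(rho) and abs(rho) >= depth_corr_threshold:
            labels.add("depth_artifact")
    return labels


def random_pileup_table(rng: np.random.Generator, n_variants: int, n_subcultures: int):
    """Random synthetic pileup rows exercising every filter rule.

    Mixes clean sites, low-frequency sites, strand-skewed sites, shallow
    strata and low base qualities so that each label fires on some rows.
    """
    import pandas as pd

    rows = []
    for v in range(n_variants):
        pos = int(rng.integers(1, 6_000_000))
        af = float(rng.choice([0.0, 0.01, 0.03, 0.06, 0.15, 0.5], p=[0.2, 0.1, 0.2, 0.2, 0.15, 0.15]))
        skew = float(rng.choice([0.5, 0.5, 0.9]))
        for t in range(n_subcultures):
            depth = int(rng.choice([6, 40, 368, 500]))
            fwd = int(rng.binomial(depth, 0.5))
            rev = depth - fwd
            fwd_alt = int(rng.binomial(fwd, min(af * 2 * skew, 1.0)))
            rev_alt = int(rng.binomial(rev, min(af * 2 * (1 - skew), 1.0)))
            rows.append(
                dict(
                    chrom="chrom",
                    pos=pos,
                    ref="C",
                    alt="A",
                    fwd_ref=fwd - fwd_alt,
                    fwd_alt=fwd_alt,
                    rev_ref=rev - rev_alt,
                    rev_alt=rev_alt,
                    mean_bq=float(rng.choice([15.0, 30.0], p=[0.1, 0.9])),
                    subculture=t,
                    replicate="rep1",
                )
            )
    return pd.DataFrame(rows)


def oracle_cascade_keep(
    pileups, error_rate: float, exclusions: list[tuple[str, int, int]]
) -> dict[tuple, set[str]]:
    """Brute-force keep decision per variant: conjunction of all rules.

    Returns a mapping (replicate, chrom, pos, ref, alt) -> trajectory label
    set, where the trajectory is assembled from site-passing AFs (failed
    sites contribute AF 0, i.e. below detection).
    """
    out: dict[tuple, set[str]] = {}
    grouped = pileups.groupby(["replicate", "chrom", "pos", "ref", "alt"], sort=True)
    for key, grp in grouped:
        grp = grp.sort_values("subculture")
        afs, depths, subs = [], [], []
        for row in grp.itertuples():
            labels = oracle_site_labels(
                row.fwd_ref, row.fwd_alt, row.rev_ref, row.rev_alt, row.mean_bq, error_rate
            )
            depth = row.fwd_ref + row.fwd_alt + row.rev_ref + row.rev_alt
            af = (row.fwd_alt + row.rev_alt) / depth if not labels else 0.0
            afs.append(af)
            depths.append(depth)
            subs.append(int(row.subculture))
        out[key] = oracle_trajectory_labels(int(key[2]), afs, depths, subs, exclusions)
    return out
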