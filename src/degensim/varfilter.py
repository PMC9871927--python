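"""Variant-calling consensus and filtering cascade for pooled pileups.

Re-implements, as internal documented criteria, the joint-calling filter
rules used for ultra-deep whole-population sequencing of degenerating
cultures:

* **Criterion A** (site score): a Phred-scaled score from the binomial
  upper-tail probability of the observed alternate reads under an
  error-only model; calls need ``qual >= 100``.
* **Criterion B** (consensus "PASS" analogue): a Fisher-exact strand-bias
  screen plus minimum combined allele frequency and depth.
* **Orientation filter**: allele frequency strictly above 0.04 in *both*
  the first-forward and first-reverse read strata, with at least 4 reads
  per stratum and mean base quality >= 20.
* **Trajectory (heatmap) filter**: a variant is kept only if it reaches
  AF > 0.08 in at least three subcultures of a single replicate, is not in
  an excluded (rRNA) region, is not already present in the starter culture
  (subculture 0 AF > 0.5), and shows no strong AF-depth correlation across
  subcultures (Spearman ``|rho| >= 0.8`` flags a depth-tracking artifact,
  generalizing a manual single-position removal).

Thresholds follow the wording they were specified with: strict ``>`` for
"above 0.04" and "AF > 0.08", non-strict ``>=`` for "QUAL >= 100".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .seqsim import PileupSite

__all__ = [
    "FILTER_LABELS",
    "FilterParams",
    "VariantCall",
    "AlleleTrajectory",
    "MultiallelicPileup",
    "CascadeResult",
    "StructureError",
    "score_site",
    "consensus_call",
    "orientation_filter",
    "split_multiallelic",
    "trajectory_filter",
    "run_filter_cascade",
]

FILTER_LABELS = frozenset(
    {
        "low_qual",
        "no_consensus",
        "low_orientation_af",
        "low_reads",
        "rrna",
        "starter_background",
        "insufficient_recurrence",
        "depth_artifact",
    }
)


class StructureError(ValueError):
    """Inconsistent replicate/subculture grouping in a pileup table."""


@dataclass
class FilterParams:
    """Filter thresholds; defaults are the study's published values.

    ``min_reads_mode`` selects whether the minimum-read rule applies per
    orientation stratum (default, conservative reading of ``--min-reads 4``)
    or to the total depth.  ``depth_corr_threshold=None`` disables the
    depth-artifact screen; it otherwise applies only when a trajectory has at
    least ``depth_corr_min_points`` subcultures.
    """

    qual_min: float = 100.0
    af_orientation_min: float = 0.04
    min_reads: int = 4
    min_bq: float = 20.0
    recurrence_af: float = 0.08
    recurrence_count: int = 3
    starter_af_max: float = 0.5
    depth_corr_threshold: float | None = 0.8
    depth_corr_min_points: int = 6
    min_reads_mode: str = "per_orientation"
    require_consecutive: bool = False
    sb_alpha: float = 1e-3
    consensus_min_af: float = 0.01
    consensus_min_depth: int = 10
    qual_cap: float = 5000.0

    def __post_init__(self) -> None:
        if self.min_reads_mode not in ("per_orientation", "total"):
            raise ValueError("min_reads_mode must be 'per_orientation' or 'total'")


@dataclass
class VariantCall:
    """A candidate variant with its score, stratified counts and filter labels."""

    chrom: str
    pos: int
    ref: str
    alt: str
    qual: float = 0.0
    fwd_ref: int = 0
    fwd_alt: int = 0
    rev_ref: int = 0
    rev_alt: int = 0
    mean_bq: float = 0.0
    filters: set[str] = field(default_factory=set)
    subculture: int | None = None
    replicate: str | None = None

    @property
    def depth_fwd(self) -> int:
        return self.fwd_ref + self.fwd_alt

    @property
    def depth_rev(self) -> int:
        return self.rev_ref + self.rev_alt

    @property
    def depth(self) -> int:
        return self.depth_fwd + self.depth_rev

    @property
    def af_fwd(self) -> float | None:
        return self.fwd_alt / self.depth_fwd if self.depth_fwd else None

    @property
    def af_rev(self) -> float | None:
        return self.rev_alt / self.depth_rev if self.depth_rev else None

    @property
    def af(self) -> float | None:
        return (self.fwd_alt + self.rev_alt) / self.depth if self.depth else None

    @property
    def is_pass(self) -> bool:
        return not self.filters


@dataclass
class AlleleTrajectory:
    """One variant's allele frequencies across ordered subcultures of a replicate.

    ``afs`` holds 0.0 where the variant was below detection (or failed the
    site-level filters) at that subculture.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    replicate: str
    subcultures: list[int]
    afs: list[float]
    depths: list[int]

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.subcultures, self.subcultures[1:])):
            raise ValueError("subculture indices must be strictly increasing")
        if any(not 0.0 <= a <= 1.0 for a in self.afs):
            raise ValueError("allele frequencies must lie in [0, 1]")
        if not (len(self.subcultures) == len(self.afs) == len(self.depths)):
            raise ValueError("subcultures, afs and depths must have equal length")


@dataclass
class MultiallelicPileup:
    """A pileup record carrying several alternate alleles at one site."""

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    fwd_ref: int
    rev_ref: int
    fwd_alts: tuple[int, ...]
    rev_alts: tuple[int, ...]
    mean_bq: float = 0.0
    subculture: int | None = None
    replicate: str | None = None

    def __post_init__(self) -> None:
        if len(self.alts) < 1:
            raise ValueError("at least one alternate allele required")
        if not (len(self.alts) == len(self.fwd_alts) == len(self.rev_alts)):
            raise ValueError("per-alt count arrays must match the number of alts")


def _qual_from_counts(
    alt_total: np.ndarray, depth: np.ndarray, error_rate: float, cap: float
) -> np.ndarray:
    """Phred score of the binomial upper tail P(X >= alt_total | depth, e/3)."""
    alt_total = np.asarray(alt_total, dtype=np.int64)
    depth = np.asarray(depth, dtype=np.int64)
    qual = np.zeros(alt_total.shape, dtype=float)
    nz = alt_total > 0
    with np.errstate(divide="ignore"):
        logsf = stats.binom.logsf(alt_total[nz] - 1, depth[nz], error_rate / 3.0)
    qual[nz] = -10.0 * logsf / np.log(10.0)
    return np.minimum(np.nan_to_num(qual, posinf=cap), cap)


def score_site(
    site: PileupSite, error_rate: float, qual_cap: float = 5000.0
) -> float:
    """Phred-scaled site score under the error-only null (criterion A input).

    ``qual = -10 log10 P(X >= alt_total)`` with ``X ~ Binomial(depth, e/3)``,
    capped at ``qual_cap``.  Zero alternate reads score 0; zero depth is an
    error.
    """
    if site.depth == 0:
        raise ValueError("site score undefined at zero depth")
    return float(
        _qual_from_counts(
            np.array([site.alt_total]), np.array([site.depth]), error_rate, qual_cap
        )[0]
    )


def _strand_bias_p(site) -> float:
    table = [[site.fwd_ref, site.fwd_alt], [site.rev_ref, site.rev_alt]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def consensus_call(
    site: PileupSite,
    params: FilterParams,
    error_rate: float,
    subculture: int | None = None,
    replicate: str | None = None,
) -> VariantCall:
    """Dual-criterion caller consensus on one pileup site.

    Criterion A: site score >= ``qual_min`` (label ``low_qual`` otherwise).
    Criterion B: Fisher-exact strand-bias screen (two-sided p >= ``sb_alpha``),
    combined AF >= ``consensus_min_af`` and depth >= ``consensus_min_depth``
    (label ``no_consensus`` otherwise).  The call is always returned with its
    labels; nothing is silently dropped.
    """
    qual = score_site(site, error_rate, params.qual_cap)
    call = VariantCall(
        chrom=site.chrom,
        pos=site.pos,
        ref=site.ref,
        alt=site.alt,
        qual=qual,
        fwd_ref=site.fwd_ref,
        fwd_alt=site.fwd_alt,
        rev_ref=site.rev_ref,
        rev_alt=site.rev_alt,
        mean_bq=site.mean_bq,
        subculture=subculture,
        replicate=replicate,
    )
    if qual < params.qual_min:
        call.filters.add("low_qual")
    af = call.af or 0.0
    if (
        af < params.consensus_min_af
        or call.depth < params.consensus_min_depth
        or _strand_bias_p(site) < params.sb_alpha
    ):
        call.filters.add("no_consensus")
    return call


def orientation_filter(call: VariantCall, params: FilterParams) -> VariantCall:
    """Orientation-stratified AF and minimum-read filter (labels appended).

    Adds ``low_orientation_af`` unless AF is strictly above the threshold in
    both orientations, and ``low_reads`` on insufficient reads per stratum
    (or in total, per ``min_reads_mode``) or mean base quality below the
    floor.
    """
    af_fwd = call.af_fwd
    af_rev = call.af_rev
    if (
        af_fwd is None
        or af_rev is None
        or af_fwd <= params.af_orientation_min
        or af_rev <= params.af_orientation_min
    ):
        call.filters.add("low_orientation_af")
    if params.min_reads_mode == "per_orientation":
        low = call.depth_fwd < params.min_reads or call.depth_rev < params.min_reads
    else:
        low = call.depth < params.min_reads
    if low or call.mean_bq < params.min_bq:
        call.filters.add("low_reads")
    return call


def split_multiallelic(record: MultiallelicPileup) -> list[VariantCall]:
    """Split a multiallelic record into one biallelic call per alternate allele.

    Per-alt counts and allele frequencies are preserved; the reference counts
    at the site are shared by every split record and positions are unchanged.
    No filters are evaluated here.
    """
    calls = []
    for alt, fa, ra in zip(record.alts, record.fwd_alts, record.rev_alts):
        calls.append(
            VariantCall(
                chrom=record.chrom,
                pos=record.pos,
                ref=record.ref,
                alt=alt,
                fwd_ref=record.fwd_ref,
                fwd_alt=fa,
                rev_ref=record.rev_ref,
                rev_alt=ra,
                mean_bq=record.mean_bq,
                subculture=record.subculture,
                replicate=record.replicate,
            )
        )
    return calls


def _in_exclusion(
    chrom: str, pos: int, exclusions: Iterable[tuple[str, int, int]]
) -> bool:
    return any(c == chrom and s <= pos <= e for c, s, e in exclusions)


def _max_run_length(flags: Sequence[bool]) -> int:
    best = run = 0
    for f in flags:
        run = run + 1 if f else 0
        best = max(best, run)
    return best


def trajectory_filter(
    traj: AlleleTrajectory,
    params: FilterParams,
    exclusions: Iterable[tuple[str, int, int]] = (),
    starter_af: float | None = None,
) -> tuple[bool, set[str]]:
    """Heatmap-level inclusion rules for one allele trajectory.

    Keeps the variant iff it recurs (AF > ``recurrence_af`` in at least
    ``recurrence_count`` subcultures, consecutively if configured), lies
    outside every exclusion interval, was not already dominant in the starter
    culture, and shows no strong AF-depth correlation.  Missing subcultures
    count as AF 0.  ``starter_af`` supplies the subculture-0 frequency when
    that subculture is not part of the trajectory itself.
    """
    if not traj.subcultures:
        raise ValueError("empty trajectory")
    labels: set[str] = set()

    above = [af > params.recurrence_af for af in traj.afs]
    hits = _max_run_length(above) if params.require_consecutive else sum(above)
    if hits < params.recurrence_count:
        labels.add("insufficient_recurrence")

    if _in_exclusion(traj.chrom, traj.pos, exclusions):
        labels.add("rrna")

    s0 = starter_af
    if 0 in traj.subcultures:
        s0 = traj.afs[traj.subcultures.index(0)]
    if s0 is not None and s0 > params.starter_af_max:
        labels.add("starter_background")

    if (
        params.depth_corr_threshold is not None
        and len(traj.afs) >= params.depth_corr_min_points
        and len(set(traj.afs)) > 1
        and len(set(traj.depths)) > 1
    ):
        rho = stats.spearmanr(traj.afs, traj.depths).statistic
        if np.isfinite(rho) and abs(rho) >= params.depth_corr_threshold:
            labels.add("depth_artifact")

    return (not labels, labels)


@dataclass
class CascadeResult:
    """Full filter-cascade output.

    ``calls`` carries every scored site with its labels (the site-level PASS
    subset is the pre-heatmap, supplementary-table-like call set);
    ``variants`` carries one row per (replicate, variant) with the
    trajectory-level keep decision; ``trajectories`` is the long-format AF
    table behind it.
    """

    calls: pd.DataFrame
    trajectories: pd.DataFrame
    variants: pd.DataFrame

    def af_matrix(self, replicate: str, kept_only: bool = True) -> pd.DataFrame:
        """Variant x subculture AF matrix for one replicate (heatmap input)."""
        t = self.trajectories[self.trajectories["replicate"] == replicate]
        if kept_only:
            kept = self.variants[
                (self.variants["replicate"] == replicate) & self.variants["keep"]
            ]
            keys = set(zip(kept["chrom"], kept["pos"], kept["ref"], kept["alt"]))
            t = t[
                [
                    (c, p, r, a) in keys
                    for c, p, r, a in zip(t["chrom"], t["pos"], t["ref"], t["alt"])
                ]
            ]
        if t.empty:
            return pd.DataFrame()
        return t.pivot_table(
            index=["chrom", "pos", "ref", "alt"],
            columns="subculture",
            values="af",
            fill_value=0.0,
        )


_CALL_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "subculture",
    "replicate",
    "fwd_ref",
    "fwd_alt",
    "rev_ref",
    "rev_alt",
    "mean_bq",
    "qual",
    "af",
    "af_fwd",
    "af_rev",
    "labels",
    "site_pass",
]


def run_filter_cascade(
    pileups: pd.DataFrame,
    params: FilterParams | None = None,
    error_rate: float = 0.001,
    exclusions: Iterable[tuple[str, int, int]] = (),
) -> CascadeResult:
    """Score -> consensus -> orientation -> trajectory filtering of a pileup table.

    ``pileups`` uses the seqsim dialect (chrom, pos, ref, alt, fwd_ref,
    fwd_alt, rev_ref, rev_alt, mean_bq, subculture, replicate).  Site-level
    filters gate which observations enter each variant's trajectory (failed
    sites count as AF 0 / below detection); the trajectory rules then decide
    the final keep set per replicate.  Deterministic.
    """
    params = params or FilterParams()
    exclusions = list(exclusions)
    if pileups.empty:
        empty_calls = pd.DataFrame(columns=_CALL_COLUMNS)
        empty_traj = pd.DataFrame(
            columns=["replicate", "chrom", "pos", "ref", "alt", "subculture", "af", "depth"]
        )
        empty_var = pd.DataFrame(
            columns=["replicate", "chrom", "pos", "ref", "alt", "keep", "labels"]
        )
        return CascadeResult(empty_calls, empty_traj, empty_var)

    df = pileups.reset_index(drop=True).copy()
    key_cols = ["replicate", "chrom", "pos", "ref", "alt", "subculture"]
    if df.duplicated(key_cols).any():
        dup = df[df.duplicated(key_cols, keep=False)].iloc[0]
        raise StructureError(
            "duplicate pileup rows for "
            f"{dup['replicate']}:{dup['chrom']}:{dup['pos']} subculture {dup['subculture']}"
        )

    fwd = df["fwd_ref"].to_numpy() + df["fwd_alt"].to_numpy()
    rev = df["rev_ref"].to_numpy() + df["rev_alt"].to_numpy()
    depth = fwd + rev
    alt_total = df["fwd_alt"].to_numpy() + df["rev_alt"].to_numpy()
    if np.any(depth == 0):
        raise StructureError("pileup rows with zero depth cannot be scored")
    qual = _qual_from_counts(alt_total, depth, error_rate, params.qual_cap)
    af = alt_total / depth
    with np.errstate(invalid="ignore", divide="ignore"):
        af_fwd = np.where(fwd > 0, df["fwd_alt"].to_numpy() / np.maximum(fwd, 1), np.nan)
        af_rev = np.where(rev > 0, df["rev_alt"].to_numpy() / np.maximum(rev, 1), np.nan)

    sb_p = np.array(
        [
            _strand_bias_p(row)
            for row in df[["fwd_ref", "fwd_alt", "rev_ref", "rev_alt"]].itertuples()
        ]
    )

    labels_per_row: list[set[str]] = [set() for _ in range(len(df))]
    low_qual = qual < params.qual_min
    no_consensus = (
        (af < params.consensus_min_af)
        | (depth < params.consensus_min_depth)
        | (sb_p < params.sb_alpha)
    )
    bad_orient = (
        (fwd == 0)
        | (rev == 0)
        | (np.nan_to_num(af_fwd) <= params.af_orientation_min)
        | (np.nan_to_num(af_rev) <= params.af_orientation_min)
    )
    if params.min_reads_mode == "per_orientation":
        low_reads = (fwd < params.min_reads) | (rev < params.min_reads)
    else:
        low_reads = depth < params.min_reads
    low_reads = low_reads | (df["mean_bq"].to_numpy() < params.min_bq)
    for i in range(len(df)):
        if low_qual[i]:
            labels_per_row[i].add("low_qual")
        if no_consensus[i]:
            labels_per_row[i].add("no_consensus")
        if bad_orient[i]:
            labels_per_row[i].add("low_orientation_af")
        if low_reads[i]:
            labels_per_row[i].add("low_reads")

    site_pass = np.array([not s for s in labels_per_row])
    calls = df[key_cols + ["fwd_ref", "fwd_alt", "rev_ref", "rev_alt", "mean_bq"]].copy()
    calls["qual"] = qual
    calls["af"] = af
    calls["af_fwd"] = af_fwd
    calls["af_rev"] = af_rev
    calls["labels"] = [",".join(sorted(s)) for s in labels_per_row]
    calls["site_pass"] = site_pass
    calls = calls[_CALL_COLUMNS]

    # trajectory assembly: AF enters as called when the site passed, else 0
    traj_df = calls.copy()
    traj_df["af"] = np.where(traj_df["site_pass"], traj_df["af"], 0.0)
    traj_df["depth"] = depth
    traj_df = traj_df[
        ["replicate", "chrom", "pos", "ref", "alt", "subculture", "af", "depth"]
    ].sort_values(["replicate", "chrom", "pos", "ref", "alt", "subculture"])

    var_rows = []
    for (rep, chrom, pos, ref, alt), grp in traj_df.groupby(
        ["replicate", "chrom", "pos", "ref", "alt"], sort=True
    ):
        traj = AlleleTrajectory(
            chrom=chrom,
            pos=int(pos),
            ref=ref,
            alt=alt,
            replicate=rep,
            subcultures=[int(s) for s in grp["subculture"]],
            afs=[float(a) for a in grp["af"]],
            depths=[int(d) for d in grp["depth"]],
        )
        keep, labels = trajectory_filter(traj, params, exclusions)
        var_rows.append(
            {
                "replicate": rep,
                "chrom": chrom,
                "pos": int(pos),
                "ref": ref,
                "alt": alt,
                "keep": keep,
                "labels": ",".join(sorted(labels)),
            }
        )
    variants = pd.DataFrame(var_rows)
    return CascadeResult(calls=calls, trajectories=traj_df.reset_index(drop=True), variants=variants)
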