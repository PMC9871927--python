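"""Mutation accounting, substitution-spectrum classification and hotspot enrichment.

Operates on flat catalogues of per-isolate mutations (SNPs and small indels)
such as those produced by comparative genome sequencing of degenerate
*Clostridium beijerinckii* isolates, or by :mod:`degensim.popsim` simulations.

The hotspot statistic is an exact binomial test per region against a
length-proportional uniform null, with Benjamini-Hochberg correction across
regions.  A Poisson approximation is available behind ``method="poisson"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SUBSTITUTION_CLASSES",
    "MutationRecord",
    "GeneModel",
    "HotspotResult",
    "classify_substitution",
    "mean_mutations_per_isolate",
    "spectrum_summary",
    "region_counts",
    "assign_regions",
    "region_lengths_from_genes",
    "hotspot_test",
    "make_uniform_gene_models",
]

#: Strand-collapsed substitution classes, keyed by the base pair they change.
#: ``G:C>T:A`` collects both the G->T and C->A transversions.
SUBSTITUTION_CLASSES = (
    "G:C>T:A",
    "G:C>A:T",
    "G:C>C:G",
    "A:T>T:A",
    "A:T>G:C",
    "A:T>C:G",
)

_TRANSITIONS = frozenset({"G:C>A:T", "A:T>G:C"})

_COLLAPSE = {
    ("C", "A"): "G:C>T:A",
    ("G", "T"): "G:C>T:A",
    ("C", "T"): "G:C>A:T",
    ("G", "A"): "G:C>A:T",
    ("C", "G"): "G:C>C:G",
    ("G", "C"): "G:C>C:G",
    ("T", "A"): "A:T>T:A",
    ("A", "T"): "A:T>T:A",
    ("T", "C"): "A:T>G:C",
    ("A", "G"): "A:T>G:C",
    ("T", "G"): "A:T>C:G",
    ("A", "C"): "A:T>C:G",
}

_KINDS = ("SNP", "insertion", "deletion")


class ClassificationError(ValueError):
    """Raised when a ref/alt pair cannot be classified as a substitution."""


@dataclass
class MutationRecord:
    """One mutation in one isolate (or one simulated lineage).

    Positions are 1-based.  ``kind`` must be consistent with the ref/alt
    lengths: a SNP has single-base ref and alt, an insertion a longer alt,
    a deletion a longer ref.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    kind: str
    isolate_id: str
    gene_id: str | None = None
    region_class: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown mutation kind {self.kind!r}")
        is_snp = len(self.ref) == 1 and len(self.alt) == 1
        if (self.kind == "SNP") != is_snp:
            raise ValueError(
                f"kind {self.kind!r} inconsistent with ref={self.ref!r} alt={self.alt!r}"
            )
        if self.kind == "insertion" and len(self.alt) <= len(self.ref):
            raise ValueError("insertion requires alt longer than ref")
        if self.kind == "deletion" and len(self.ref) <= len(self.alt):
            raise ValueError("deletion requires ref longer than alt")


@dataclass
class GeneModel:
    """A gene body on the chromosome, 1-based inclusive coordinates."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    product: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class HotspotResult:
    region_id: str
    length: int
    observed: int
    expected: float
    p_value: float
    q_value: float
    enriched: bool


def classify_substitution(ref: str, alt: str) -> tuple[str, str]:
    """Classify a single-base substitution.

    Returns ``(collapsed_class, "transition" | "transversion")`` where the
    collapsed class folds strand-complementary changes together (G->T and
    C->A both report as ``G:C>T:A``).
    """
    ref = ref.upper()
    alt = alt.upper()
    if len(ref) != 1 or len(alt) != 1:
        raise ClassificationError(f"not a substitution: {ref!r} -> {alt!r}")
    if ref not in "ACGT" or alt not in "ACGT":
        raise ClassificationError(f"non-ACGT bases: {ref!r} -> {alt!r}")
    if ref == alt:
        raise ClassificationError("ref and alt are identical")
    cls = _COLLAPSE[(ref, alt)]
    return cls, "transition" if cls in _TRANSITIONS else "transversion"


def mean_mutations_per_isolate(
    catalogue: Sequence[MutationRecord], n_isolates: int
) -> float:
    """Total mutation records divided by the number of isolates sequenced.

    Isolates carrying zero mutations contribute to the denominator, so
    ``n_isolates`` is passed explicitly rather than inferred from the
    catalogue.
    """
    if n_isolates <= 0:
        raise ValueError("n_isolates must be positive")
    return len(catalogue) / n_isolates


def spectrum_summary(catalogue: Sequence[MutationRecord]) -> pd.DataFrame:
    """Per-class SNP counts and fractions.

    Indels are excluded from the denominator.  Returns a DataFrame indexed by
    collapsed substitution class with ``count`` and ``fraction`` columns plus
    a ``ti_tv`` column; fractions are NaN when the catalogue has no SNPs
    (``df.attrs["n_snps"]`` carries the denominator).
    """
    counts = dict.fromkeys(SUBSTITUTION_CLASSES, 0)
    n_snps = 0
    for rec in catalogue:
        if rec.kind != "SNP":
            continue
        cls, _ = classify_substitution(rec.ref, rec.alt)
        counts[cls] += 1
        n_snps += 1
    df = pd.DataFrame(
        {
            "count": [counts[c] for c in SUBSTITUTION_CLASSES],
            "fraction": [
                counts[c] / n_snps if n_snps else np.nan for c in SUBSTITUTION_CLASSES
            ],
            "ti_tv": [
                "transition" if c in _TRANSITIONS else "transversion"
                for c in SUBSTITUTION_CLASSES
            ],
        },
        index=pd.Index(SUBSTITUTION_CLASSES, name="substitution_class"),
    )
    df.attrs["n_snps"] = n_snps
    df.attrs["n_indels"] = len(catalogue) - n_snps
    return df


def _gene_arrays(genes: Sequence[GeneModel]) -> dict[str, tuple[np.ndarray, np.ndarray, list[str]]]:
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    out = {}
    for chrom, gs in by_chrom.items():
        gs = sorted(gs, key=lambda g: g.start)
        for a, b in zip(gs, gs[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"overlapping gene models {a.gene_id}/{b.gene_id} on {chrom}"
                )
        out[chrom] = (
            np.array([g.start for g in gs]),
            np.array([g.end for g in gs]),
            [g.gene_id for g in gs],
        )
    return out


def assign_regions(
    chroms: Sequence[str],
    positions: np.ndarray,
    genes: Sequence[GeneModel],
    genome_length: int | None = None,
) -> list[str]:
    """Assign each position to a gene body or a named intergenic region.

    Intergenic regions are keyed by their flanking gene ids, e.g.
    ``intergenic_geneA_geneB``; positions before the first or after the last
    gene use ``START`` / ``END`` as the missing flank.
    """
    positions = np.asarray(positions)
    if genome_length is not None and (
        np.any(positions < 1) or np.any(positions > genome_length)
    ):
        bad = positions[(positions < 1) | (positions > genome_length)]
        raise ValueError(f"position(s) outside chromosome bounds: {bad[:5].tolist()}")
    arrays = _gene_arrays(genes)
    labels: list[str] = []
    for chrom, pos in zip(chroms, positions):
        if chrom not in arrays:
            raise ValueError(f"no gene models for chromosome {chrom!r}")
        starts, ends, ids = arrays[chrom]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and pos <= ends[i]:
            labels.append(ids[i])
        else:
            left = ids[i] if i >= 0 else "START"
            right = ids[i + 1] if i + 1 < len(ids) else "END"
            labels.append(f"intergenic_{left}_{right}")
    return labels


def region_counts(
    catalogue: Sequence[MutationRecord],
    genes: Sequence[GeneModel],
    genome_length: int | None = None,
) -> dict[str, int]:
    """Count mutations per gene body / named intergenic region.

    Every record is assigned to exactly one region; counts sum to the
    catalogue size.  Gene bounds are 1-based inclusive, so a mutation at a
    gene's start coordinate belongs to that gene.
    """
    if not catalogue:
        return {}
    labels = assign_regions(
        [r.chrom for r in catalogue],
        np.array([r.pos for r in catalogue]),
        genes,
        genome_length,
    )
    out: dict[str, int] = {}
    for lab in labels:
        out[lab] = out.get(lab, 0) + 1
    return out


def region_lengths_from_genes(
    genes: Sequence[GeneModel], genome_length: int
) -> dict[str, int]:
    """Lengths of all gene-body and intergenic regions spanning the genome."""
    lengths: dict[str, int] = {}
    arrays = _gene_arrays(genes)
    for chrom, (starts, ends, ids) in arrays.items():
        prev_end = 0
        prev_id = "START"
        for s, e, gid in zip(starts, ends, ids):
            if s > prev_end + 1:
                lengths[f"intergenic_{prev_id}_{gid}"] = int(s - prev_end - 1)
            lengths[gid] = int(e - s + 1)
            prev_end, prev_id = e, gid
        if genome_length > prev_end:
            lengths[f"intergenic_{prev_id}_END"] = int(genome_length - prev_end)
    return lengths


def hotspot_test(
    counts: Mapping[str, int],
    genes: Sequence[GeneModel],
    genome_length: int,
    total_mutations: int,
    fdr: float = 0.05,
    method: str = "binomial",
) -> list[HotspotResult]:
    """Per-region mutation-enrichment test against a length-proportional null.

    For each region, the p-value is the upper tail of
    ``Binomial(total_mutations, region_length / genome_length)`` at the
    observed count (or the Poisson analogue with ``method="poisson"``).
    Benjamini-Hochberg correction is applied across all regions spanning the
    genome; ``enriched`` marks regions with q <= ``fdr``.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    if total_mutations < 0:
        raise ValueError("total_mutations must be non-negative")
    lengths = region_lengths_from_genes(genes, genome_length)
    unknown = set(counts) - set(lengths)
    if unknown:
        raise ValueError(f"counts refer to unknown regions: {sorted(unknown)[:5]}")
    ids = sorted(lengths)
    length_arr = np.array([lengths[r] for r in ids], dtype=float)
    obs = np.array([counts.get(r, 0) for r in ids], dtype=int)
    p_region = length_arr / genome_length
    expected = total_mutations * p_region
    pvals = np.ones(len(ids))
    nz = obs > 0
    if method == "binomial":
        pvals[nz] = stats.binom.sf(obs[nz] - 1, total_mutations, p_region[nz])
    elif method == "poisson":
        pvals[nz] = stats.poisson.sf(obs[nz] - 1, expected[nz])
    else:
        raise ValueError(f"unknown method {method!r}")
    pvals = np.clip(pvals, 0.0, 1.0)
    _, qvals, _, _ = multipletests(pvals, alpha=fdr, method="fdr_bh")
    results = [
        HotspotResult(
            region_id=r,
            length=int(length_arr[i]),
            observed=int(obs[i]),
            expected=float(expected[i]),
            p_value=float(pvals[i]),
            q_value=float(qvals[i]),
            enriched=bool(qvals[i] <= fdr),
        )
        for i, r in enumerate(ids)
    ]
    results.sort(key=lambda h: (h.q_value, h.p_value, h.region_id))
    return results


def hotspot_table(results: Iterable[HotspotResult]) -> pd.DataFrame:
    """Tabulate :func:`hotspot_test` results for TSV export."""
    return pd.DataFrame(
        [
            {
                "region": h.region_id,
                "length": h.length,
                "observed": h.observed,
                "expected": h.expected,
                "p": h.p_value,
                "q": h.q_value,
                "enriched": h.enriched,
            }
            for h in results
        ]
    )


def make_uniform_gene_models(
    n_genes: int,
    genome_length: int,
    chrom: str = "chrom",
    coding_fraction: float = 0.85,
) -> list[GeneModel]:
    """Evenly spaced synthetic gene models covering ``coding_fraction`` of the genome.

    Deterministic layout used for null-calibration simulations: gene *i*
    occupies the first ``coding_fraction`` of its slot of size
    ``genome_length / n_genes``.
    """
    if not 0 < coding_fraction < 1:
        raise ValueError("coding_fraction must be in (0, 1)")
    slot = genome_length / n_genes
    genes = []
    for i in range(n_genes):
        start = int(round(i * slot)) + 1
        end = int(round(i * slot + slot * coding_fraction))
        genes.append(GeneModel(gene_id=f"gene{i:05d}", chrom=chrom, start=start, end=max(end, start)))
    return genes
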