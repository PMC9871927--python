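"""Stochastic serial-passage population simulator for clostridial strain degeneration.

Models a *Clostridium beijerinckii*-like culture propagated by repeated 1:10
dilution transfers.  The population is a set of genotype classes (wild type
plus mutant lineages); each transfer the culture regrows to carrying capacity
by discrete Wright-Fisher generations (``g = log2(K / N0)`` per transfer, so a
1:10 transfer costs about 3.3 generations), converts a class-specific fraction
of vegetative cells to heat-resistant spores, and optionally decays vegetative
cells that linger past 24 h of culture age.  New mutant lineages arise at an
effective heritable-mutation rate per cell birth, land in genomic regions by
configurable weights, and inherit their parent's parameters modified by the
region's effect template (a spo0A hit yields a non-sporulating, non-solventogenic
"null" class with a frequency-dependent growth advantage).

Selection is frequency dependent: the realized per-generation fitness of class
*i* is ``w_i = baseline_fitness * (1 - freq_dependence * x_i)`` where ``x_i``
is the class's own current frequency.

Two bottleneck regimes are supported: plain binomial dilution, and a
heat-shock bottleneck (80 C analogue) that kills all vegetative cells and
germinates surviving spores, so only sporulation-competent lineages propagate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .mutstats import SUBSTITUTION_CLASSES, MutationRecord

__all__ = [
    "MORPHOTYPES",
    "GenotypeClass",
    "PopulationState",
    "RegimeConfig",
    "GenomeRegion",
    "GenomeTemplate",
    "EffectTemplate",
    "SeriesResult",
    "ExtinctionError",
    "ConfigError",
    "DEFAULT_GENOME",
    "DEFAULT_TARGET_WEIGHTS",
    "DEFAULT_SPECTRUM",
    "DEFAULT_KIND_WEIGHTS",
    "DEFAULT_EFFECT_TEMPLATES",
    "wt_class",
    "null_spo0a_class",
    "partial_spo0a_class",
    "grow_transfer",
    "apply_dilution",
    "apply_heat_shock",
    "spawn_mutations",
    "simulate_series",
    "sample_isolates",
]

MORPHOTYPES = ("RD", "DCOG", "CIC", "FW")
_MORPH_CODE = {m: i for i, m in enumerate(MORPHOTYPES)}


class ExtinctionError(RuntimeError):
    """The population (or its spore pool under heat shock) has died out."""


class ConfigError(ValueError):
    """An invalid regime / parameter combination."""


@dataclass
class GenotypeClass:
    """A population subtype with its growth, sporulation and yield parameters.

    ``severity`` ranks how degenerate the class is (0 = wild type,
    3 = null-Spo0A); effect templates only overwrite parameters of a
    less-severe parent, so a spo0A-null lineage is never reverted by a later
    hit in a milder region.
    """

    id: str
    baseline_fitness: float = 1.0
    freq_dependence: float = 0.0
    sporulation_fraction: float = 0.0
    post24h_viability: float = 1.0
    solvent_yield: float = 0.0
    acid_yield: float = 0.0
    morphotype: str = "RD"
    mutations: list[MutationRecord] = field(default_factory=list)
    severity: int = 0

    def __post_init__(self) -> None:
        if self.baseline_fitness <= 0:
            raise ValueError("baseline_fitness must be positive")
        if not 0.0 <= self.sporulation_fraction <= 1.0:
            raise ValueError("sporulation_fraction must be in [0, 1]")
        if not 0.0 < self.post24h_viability <= 1.0:
            raise ValueError("post24h_viability must be in (0, 1]")
        if self.morphotype not in MORPHOTYPES:
            raise ValueError(f"unknown morphotype {self.morphotype!r}")


@dataclass
class PopulationState:
    """Per-genotype vegetative and spore counts at one subculture."""

    subculture_index: int
    vegetative: dict[str, int]
    spores: dict[str, int]
    solvents_gL: float = 0.0
    acids_gL: float = 0.0
    culture_age_h: float = 0.0

    @property
    def total_vegetative(self) -> int:
        return int(sum(self.vegetative.values()))

    @property
    def total_spores(self) -> int:
        return int(sum(self.spores.values()))

    def frequency(self, genotype_id: str) -> float:
        """Whole-culture (vegetative + spore) frequency of one class."""
        total = self.total_vegetative + self.total_spores
        if total == 0:
            return 0.0
        return (
            self.vegetative.get(genotype_id, 0) + self.spores.get(genotype_id, 0)
        ) / total


@dataclass
class RegimeConfig:
    """Transfer regime: dilution, interval, bottleneck, capacity, mutation supply."""

    dilution_factor: float = 0.1
    transfer_interval_h: float = 24.0
    heat_shock: bool = False
    n_subcultures: int = 15
    carrying_capacity: int = 10_000
    mutation_rate: float = 0.15
    germination_efficiency: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.dilution_factor < 1.0:
            raise ConfigError("dilution_factor must be in (0, 1)")
        if self.n_subcultures < 1:
            raise ConfigError("n_subcultures must be >= 1")
        if self.mutation_rate < 0:
            raise ConfigError("mutation_rate must be >= 0")
        if self.carrying_capacity < 2:
            raise ConfigError("carrying_capacity must be >= 2")
        if not 0.0 < self.germination_efficiency <= 1.0:
            raise ConfigError("germination_efficiency must be in (0, 1]")


@dataclass(frozen=True)
class EffectTemplate:
    """Parameter preset applied to lineages hit in a genomic region."""

    name: str
    severity: int
    morphotype: str | None
    overrides: Mapping[str, float]


@dataclass(frozen=True)
class GenomeRegion:
    """A named region (1-based inclusive) tied to an effect template."""

    region_id: str
    start: int
    end: int
    template: str


@dataclass(frozen=True)
class GenomeTemplate:
    chrom: str
    length: int
    regions: tuple[GenomeRegion, ...]

    def region(self, region_id: str) -> GenomeRegion | None:
        for r in self.regions:
            if r.region_id == region_id:
                return r
        return None


# Effect templates for the four mutation hotspots.  The null-Spo0A template
# removes sporulation and solvent formation entirely and carries the largest
# growth advantage with the strongest frequency dependence (realized fitness
# crosses the wild type near own-frequency 0.8); the two histidine-kinase
# templates reduce but do not abolish sporulation.  Parameter choices are
# documented in docs/methods.md.
DEFAULT_EFFECT_TEMPLATES: dict[str, EffectTemplate] = {
    "null_fw": EffectTemplate(
        "null_fw",
        severity=3,
        morphotype="FW",
        overrides=dict(
            baseline_fitness=1.14,
            freq_dependence=0.15,
            sporulation_fraction=0.0,
            post24h_viability=0.953,
            solvent_yield=0.0,
            acid_yield=6.0,
        ),
    ),
    "partial_dcog": EffectTemplate(
        "partial_dcog",
        severity=2,
        morphotype="DCOG",
        overrides=dict(
            baseline_fitness=1.06,
            freq_dependence=0.05,
            sporulation_fraction=0.30,
            post24h_viability=0.99,
            solvent_yield=5.0,
            acid_yield=3.0,
        ),
    ),
    "partial_cic": EffectTemplate(
        "partial_cic",
        severity=2,
        morphotype="CIC",
        overrides=dict(
            baseline_fitness=1.05,
            freq_dependence=0.04,
            sporulation_fraction=0.35,
            post24h_viability=0.99,
            solvent_yield=5.5,
            acid_yield=2.8,
        ),
    ),
    "mild_dcog": EffectTemplate(
        "mild_dcog",
        severity=1,
        morphotype="DCOG",
        overrides=dict(
            baseline_fitness=1.02,
            freq_dependence=0.02,
            sporulation_fraction=0.60,
            post24h_viability=0.995,
            solvent_yield=6.0,
            acid_yield=2.4,
        ),
    ),
    "carrier": EffectTemplate("carrier", severity=0, morphotype=None, overrides={}),
}

# Synthetic 6 Mb chromosome with the four mutation hotspots: two histidine
# kinases suspected to feed Spo0A phosphorylation, spo0A itself, and a short
# intergenic 0A-box region.  Coordinates are synthetic stand-ins.
DEFAULT_GENOME = GenomeTemplate(
    chrom="chrom",
    length=6_000_000,
    regions=(
        GenomeRegion("hotspot1_kinase_a", 20_001, 23_000, "partial_dcog"),
        GenomeRegion("hotspot2_spo0a", 1_900_001, 1_901_700, "null_fw"),
        GenomeRegion("hotspot3_kinase_b", 3_400_001, 3_403_000, "partial_cic"),
        GenomeRegion("hotspot4_0abox", 5_400_001, 5_400_500, "mild_dcog"),
    ),
)

# Fraction of heritable mutations landing in each region; "other" spawns
# neutral carrier lineages anywhere outside the hotspots.
DEFAULT_TARGET_WEIGHTS: dict[str, float] = {
    "hotspot1_kinase_a": 0.0035,
    "hotspot2_spo0a": 0.0045,
    "hotspot3_kinase_b": 0.0045,
    "hotspot4_0abox": 0.0020,
    "other": 0.9855,
}

# Strand-collapsed SNP spectrum: the G:C>T:A transversion carries 87% of the
# probability mass, with the remainder spread evenly over the other classes.
DEFAULT_SPECTRUM: dict[str, float] = {
    cls: (0.87 if cls == "G:C>T:A" else 0.13 / 5) for cls in SUBSTITUTION_CLASSES
}

# SNP / deletion / insertion mix (211 : 12 : 2).
DEFAULT_KIND_WEIGHTS: dict[str, float] = {
    "SNP": 211 / 225,
    "deletion": 12 / 225,
    "insertion": 2 / 225,
}

_SNP_PAIRS = {
    "G:C>T:A": (("G", "T"), ("C", "A")),
    "G:C>A:T": (("G", "A"), ("C", "T")),
    "G:C>C:G": (("G", "C"), ("C", "G")),
    "A:T>T:A": (("A", "T"), ("T", "A")),
    "A:T>G:C": (("A", "G"), ("T", "C")),
    "A:T>C:G": (("A", "C"), ("T", "G")),
}
_BASES = np.array(list("ACGT"))


def wt_class(class_id: str = "WT") -> GenotypeClass:
    """Wild-type preset: RD morphotype, solventogenic, strongly sporulating."""
    return GenotypeClass(
        id=class_id,
        baseline_fitness=1.0,
        freq_dependence=0.0,
        sporulation_fraction=0.9,
        post24h_viability=1.0,
        solvent_yield=7.2,
        acid_yield=2.0,
        morphotype="RD",
        severity=0,
    )


def _from_template(class_id: str, template: EffectTemplate) -> GenotypeClass:
    base = wt_class(class_id)
    cls = replace(base, **dict(template.overrides))
    cls.morphotype = template.morphotype or base.morphotype
    cls.severity = template.severity
    return cls


def null_spo0a_class(class_id: str = "FW") -> GenotypeClass:
    """Null-Spo0A preset: no spores, no solvents, frequency-dependent advantage."""
    return _from_template(class_id, DEFAULT_EFFECT_TEMPLATES["null_fw"])


def partial_spo0a_class(class_id: str = "DCOG") -> GenotypeClass:
    """Partially degenerate preset (histidine-kinase hit)."""
    return _from_template(class_id, DEFAULT_EFFECT_TEMPLATES["partial_dcog"])


# ---------------------------------------------------------------------------
# array helpers shared by the per-operation API and the series engine
# ---------------------------------------------------------------------------


def _realized_fitness(
    counts: np.ndarray, fitness: np.ndarray, fdep: np.ndarray
) -> np.ndarray:
    total = counts.sum()
    x = counts / total if total else np.zeros_like(counts, dtype=float)
    return fitness * np.clip(1.0 - fdep * x, 0.0, None)


def _grow_to_capacity(
    counts: np.ndarray,
    fitness: np.ndarray,
    fdep: np.ndarray,
    capacity: int,
    rng: np.random.Generator,
    on_generation=None,
) -> np.ndarray:
    """Wright-Fisher regrowth: double each generation until carrying capacity.

    ``on_generation(counts, daughters)`` is invoked after each resampling step
    with the number of daughter cells produced (two per division, i.e.
    ``2 * (N_next - N)``; a full doubling makes every cell a daughter); it may
    extend ``counts`` and the parameter arrays (used for mutation spawning
    inside :func:`simulate_series`).
    """
    counts = counts.astype(np.int64)
    n = int(counts.sum())
    while n < capacity:
        n_next = min(2 * n, capacity)
        weights = counts * _realized_fitness(counts, fitness, fdep)
        wsum = weights.sum()
        if wsum <= 0:
            raise ExtinctionError("all classes have zero realized fitness")
        counts = rng.multinomial(n_next, weights / wsum)
        if on_generation is not None:
            counts, fitness, fdep = on_generation(counts, 2 * (n_next - n))
        n = int(counts.sum())
    return counts


def _state_arrays(
    state: PopulationState, classes: Sequence[GenotypeClass]
) -> tuple[list[GenotypeClass], np.ndarray, np.ndarray]:
    by_id = {c.id: c for c in classes}
    missing = (set(state.vegetative) | set(state.spores)) - set(by_id)
    if missing:
        raise ConfigError(f"classes missing for genotype id(s): {sorted(missing)}")
    ordered = [by_id[c.id] for c in classes]
    veg = np.array([state.vegetative.get(c.id, 0) for c in ordered], dtype=np.int64)
    spores = np.array([state.spores.get(c.id, 0) for c in ordered], dtype=np.int64)
    return ordered, veg, spores


# ---------------------------------------------------------------------------
# per-operation API
# ---------------------------------------------------------------------------


def grow_transfer(
    state: PopulationState,
    classes: Sequence[GenotypeClass],
    regime: RegimeConfig,
    rng: np.random.Generator,
) -> PopulationState:
    """Regrow a freshly inoculated culture through one transfer interval.

    Transferred spores germinate into vegetative founders (at the regime's
    germination efficiency), the vegetative pool regrows to carrying capacity
    by multinomial Wright-Fisher generations under frequency-dependent
    selection, sporulation then converts a class-specific fraction of
    vegetative cells to spores, and for intervals beyond 24 h each class's
    vegetative cells survive each extra hour with probability
    ``post24h_viability``.  Solvent and acid outputs are frequency-weighted
    class yields at the end of growth.
    """
    ordered, veg, spores = _state_arrays(state, classes)
    germ = rng.binomial(spores, regime.germination_efficiency)
    veg = veg + germ
    spores = spores - germ
    n0 = int(veg.sum())
    if n0 + int(spores.sum()) == 0:
        raise ExtinctionError("empty population at inoculation")
    if regime.carrying_capacity <= n0:
        raise ConfigError(
            f"carrying capacity {regime.carrying_capacity} <= inoculum {n0}"
        )
    if n0 == 0:
        raise ExtinctionError("no vegetative founders after germination")

    fitness = np.array([c.baseline_fitness for c in ordered])
    fdep = np.array([c.freq_dependence for c in ordered])
    veg = _grow_to_capacity(veg, fitness, fdep, regime.carrying_capacity, rng)

    # phenotype outputs from the grown (pre-sporulation) composition
    x = veg / veg.sum()
    solvents = float(np.dot(x, [c.solvent_yield for c in ordered]))
    acids = float(np.dot(x, [c.acid_yield for c in ordered]))

    spor_frac = np.array([c.sporulation_fraction for c in ordered])
    new_spores = rng.binomial(veg, spor_frac)
    veg = veg - new_spores
    spores = spores + new_spores

    extra_h = max(regime.transfer_interval_h - 24.0, 0.0)
    if extra_h > 0:
        viability = np.array([c.post24h_viability for c in ordered]) ** extra_h
        veg = rng.binomial(veg, viability)

    return PopulationState(
        subculture_index=state.subculture_index + 1,
        vegetative={c.id: int(v) for c, v in zip(ordered, veg)},
        spores={c.id: int(s) for c, s in zip(ordered, spores)},
        solvents_gL=solvents,
        acids_gL=acids,
        culture_age_h=float(regime.transfer_interval_h),
    )


def apply_dilution(
    state: PopulationState, regime: RegimeConfig, rng: np.random.Generator
) -> PopulationState:
    """Binomial 1:10-style transfer: each cell and spore moves independently."""
    veg = {k: int(rng.binomial(v, regime.dilution_factor)) for k, v in state.vegetative.items()}
    spores = {k: int(rng.binomial(v, regime.dilution_factor)) for k, v in state.spores.items()}
    return PopulationState(
        subculture_index=state.subculture_index,
        vegetative=veg,
        spores=spores,
        solvents_gL=0.0,
        acids_gL=0.0,
        culture_age_h=0.0,
    )


def apply_heat_shock(
    state: PopulationState,
    germination_efficiency: float,
    rng: np.random.Generator,
) -> PopulationState:
    """80 C bottleneck: vegetative cells die, viable spores germinate.

    Raises :class:`ExtinctionError` when no spores exist to germinate.
    """
    if not 0.0 < germination_efficiency <= 1.0:
        raise ConfigError("germination_efficiency must be in (0, 1]")
    if state.total_spores == 0:
        raise ExtinctionError("heat shock with no spores: population extinct")
    veg = {
        k: int(rng.binomial(v, germination_efficiency))
        for k, v in state.spores.items()
    }
    for k in state.vegetative:
        veg.setdefault(k, 0)
    return PopulationState(
        subculture_index=state.subculture_index,
        vegetative=veg,
        spores={k: 0 for k in veg},
        solvents_gL=0.0,
        acids_gL=0.0,
        culture_age_h=0.0,
    )


def _draw_mutation_attrs(
    n: int,
    region_ids: np.ndarray,
    genome: GenomeTemplate,
    spectrum: Mapping[str, float],
    kind_weights: Mapping[str, float],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Vectorized draw of (pos, ref, alt, kind, substitution class) per event."""
    pos = np.empty(n, dtype=np.int64)
    hot = {r.region_id: r for r in genome.regions}
    for rid in np.unique(region_ids):
        m = region_ids == rid
        k = int(m.sum())
        if rid in hot:
            r = hot[rid]
            pos[m] = rng.integers(r.start, r.end + 1, size=k)
        else:
            # uniform over the genome, rejecting hotspot overlaps
            draw = rng.integers(1, genome.length + 1, size=k)
            for r in genome.regions:
                inside = (draw >= r.start) & (draw <= r.end)
                while inside.any():
                    draw[inside] = rng.integers(1, genome.length + 1, size=int(inside.sum()))
                    inside = (draw >= r.start) & (draw <= r.end)
            pos[m] = draw

    kinds = rng.choice(
        list(kind_weights), size=n, p=np.array(list(kind_weights.values()), dtype=float)
    )
    classes = np.array(list(spectrum))
    probs = np.array(list(spectrum.values()), dtype=float)
    if not np.isclose(probs.sum(), 1.0):
        raise ConfigError("spectrum probabilities must sum to 1")
    subst = rng.choice(classes, size=n, p=probs)
    strand = rng.integers(0, 2, size=n)

    refs = np.empty(n, dtype=object)
    alts = np.empty(n, dtype=object)
    subst_out = np.empty(n, dtype=object)
    for i in range(n):
        if kinds[i] == "SNP":
            ref, alt = _SNP_PAIRS[subst[i]][strand[i]]
            refs[i], alts[i] = ref, alt
            subst_out[i] = subst[i]
        elif kinds[i] == "deletion":
            b = rng.choice(_BASES, size=2)
            refs[i], alts[i] = b[0] + b[1], b[0]
            subst_out[i] = None
        else:  # insertion
            b = rng.choice(_BASES, size=2)
            refs[i], alts[i] = b[0], b[0] + b[1]
            subst_out[i] = None
    return pd.DataFrame(
        {"pos": pos, "ref": refs, "alt": alts, "kind": kinds, "substitution_class": subst_out}
    )


def _apply_template(parent: GenotypeClass, template: EffectTemplate) -> GenotypeClass:
    if template.severity <= parent.severity:
        child = replace(parent)
    else:
        child = replace(parent, **dict(template.overrides))
        child.morphotype = template.morphotype or parent.morphotype
        child.severity = template.severity
    return child


def spawn_mutations(
    state: PopulationState,
    classes: Sequence[GenotypeClass],
    regime: RegimeConfig,
    spectrum: Mapping[str, float],
    target_weights: Mapping[str, float],
    rng: np.random.Generator,
    genome: GenomeTemplate = DEFAULT_GENOME,
    templates: Mapping[str, EffectTemplate] = DEFAULT_EFFECT_TEMPLATES,
    kind_weights: Mapping[str, float] = DEFAULT_KIND_WEIGHTS,
) -> tuple[PopulationState, list[GenotypeClass], list[MutationRecord]]:
    """Spawn new mutant lineages after one transfer's growth.

    The number of new lineages is Poisson with mean ``mutation_rate * births``,
    where births count the daughter cells produced regrowing from the next
    inoculum back to the current density (``2 * (1 - dilution_factor) *
    total_veg``).  Each event picks a parent proportional to vegetative
    counts,
    a genomic region by ``target_weights``, and founds a one-cell class whose
    parameters are the parent's modified by the region's effect template.
    """
    wsum = float(sum(target_weights.values()))
    if wsum <= 0:
        raise ConfigError("target_weights must not all be zero")
    total = state.total_vegetative
    births = int(round(2 * (1.0 - regime.dilution_factor) * total))
    n_events = int(rng.poisson(regime.mutation_rate * births))
    if n_events == 0:
        return state, [], []

    by_id = {c.id: c for c in classes}
    ids = [k for k, v in state.vegetative.items() if v > 0]
    counts = np.array([state.vegetative[k] for k in ids], dtype=float)
    parents = rng.choice(len(ids), size=n_events, p=counts / counts.sum())

    region_names = np.array(list(target_weights))
    region_probs = np.array(list(target_weights.values()), dtype=float) / wsum
    regions = rng.choice(region_names, size=n_events, p=region_probs)
    attrs = _draw_mutation_attrs(n_events, regions, genome, spectrum, kind_weights, rng)

    veg = dict(state.vegetative)
    new_classes: list[GenotypeClass] = []
    records: list[MutationRecord] = []
    for i in range(n_events):
        pid = ids[parents[i]]
        if veg[pid] <= 0:
            continue
        parent = by_id[pid]
        region = str(regions[i])
        hot = genome.region(region)
        template = templates[hot.template] if hot else templates["carrier"]
        child_id = f"{pid}.m{i}"
        rec = MutationRecord(
            chrom=genome.chrom,
            pos=int(attrs.pos[i]),
            ref=str(attrs.ref[i]),
            alt=str(attrs.alt[i]),
            kind=str(attrs.kind[i]),
            isolate_id=child_id,
            region_class=region,
        )
        child = _apply_template(parent, template)
        child.id = child_id
        child.mutations = list(parent.mutations) + [rec]
        veg[pid] -= 1
        veg[child_id] = veg.get(child_id, 0) + 1
        new_classes.append(child)
        records.append(rec)

    spores = dict(state.spores)
    for c in new_classes:
        spores.setdefault(c.id, 0)
    new_state = PopulationState(
        subculture_index=state.subculture_index,
        vegetative=veg,
        spores=spores,
        solvents_gL=state.solvents_gL,
        acids_gL=state.acids_gL,
        culture_age_h=state.culture_age_h,
    )
    return new_state, new_classes, records


# ---------------------------------------------------------------------------
# vectorized series engine
# ---------------------------------------------------------------------------

_PARAM_FIELDS = (
    "baseline_fitness",
    "freq_dependence",
    "sporulation_fraction",
    "post24h_viability",
    "solvent_yield",
    "acid_yield",
)


@dataclass
class SeriesResult:
    """Output of :func:`simulate_series`.

    Attributes
    ----------
    states : list of PopulationState
        End-of-transfer states for subcultures ``0 .. n_subcultures``
        (empty when ``keep_states=False``).
    class_table : DataFrame
        One row per genotype class ever created, with parameters, lineage
        (parent id), origin subculture and cumulative mutation count.
    mutations : DataFrame
        The mutation ledger: one row per heritable mutation with genomic
        coordinates, kind, substitution class and origin.
    truth_af : DataFrame
        True whole-culture allele frequency of every ledger mutation at every
        subculture (mutations x subcultures; empty if ``compute_truth=False``).
    phenotypes : DataFrame
        Per-subculture solvents, acids, spore counts and morphotype fractions.
    """

    states: list[PopulationState]
    class_table: pd.DataFrame
    mutations: pd.DataFrame
    truth_af: pd.DataFrame
    phenotypes: pd.DataFrame
    seed: int | None
    regime: RegimeConfig

    def truth_table(self, min_af: float = 0.0) -> pd.DataFrame:
        """Tidy (mutation x subculture) truth table for sequencing simulation.

        Mutations whose frequency never reaches ``min_af`` are dropped.
        """
        if self.truth_af.empty:
            return pd.DataFrame(
                columns=["mut_id", "chrom", "pos", "ref", "alt", "subculture", "true_af"]
            )
        keep = self.truth_af.max(axis=1) >= min_af
        af = self.truth_af.loc[keep]
        long = af.reset_index().melt(
            id_vars="mut_id", var_name="subculture", value_name="true_af"
        )
        meta = self.mutations.set_index("mut_id")[["chrom", "pos", "ref", "alt"]]
        out = long.join(meta, on="mut_id")
        out["subculture"] = out["subculture"].astype(int)
        return out[["mut_id", "chrom", "pos", "ref", "alt", "subculture", "true_af"]]


def simulate_series(
    classes: Sequence[GenotypeClass] | None = None,
    regime: RegimeConfig | None = None,
    spectrum: Mapping[str, float] | None = None,
    target_weights: Mapping[str, float] | None = None,
    seed: int | None = None,
    genome: GenomeTemplate = DEFAULT_GENOME,
    templates: Mapping[str, EffectTemplate] = DEFAULT_EFFECT_TEMPLATES,
    kind_weights: Mapping[str, float] = DEFAULT_KIND_WEIGHTS,
    initial_counts: Mapping[str, int] | None = None,
    keep_states: bool = True,
    compute_truth: bool = True,
) -> SeriesResult:
    """Simulate a full subculture series with mutation, selection and bottlenecks.

    The series starts from a pure inoculum of the first class (a single
    germinated-spore colony analogue) of size ``carrying_capacity *
    dilution_factor``; subculture 0 is the first grown culture, followed by
    ``n_subcultures`` dilution (optionally heat-shock) transfers.  Mutant
    lineages spawn each growth generation with Poisson(mutation_rate x births)
    events.  Deterministic given ``seed``.
    """
    if classes is None:
        classes = [wt_class()]
    regime = regime or RegimeConfig()
    spectrum = dict(spectrum or DEFAULT_SPECTRUM)
    target_weights = dict(target_weights or DEFAULT_TARGET_WEIGHTS)
    wsum = float(sum(target_weights.values()))
    if wsum <= 0:
        raise ConfigError("target_weights must not all be zero")
    if seed is None:
        seed = regime.seed
    rng = np.random.default_rng(seed)

    # global class registry (python lists; appended per spawn batch)
    g_id: list[str] = []
    g_parent: list[int] = []
    g_origin: list[int] = []
    g_nmut: list[int] = []
    g_depth: list[int] = []
    g_morph: list[int] = []
    g_sev: list[int] = []
    ledger_rows: list[pd.DataFrame] = []

    # active arrays
    act_idx = np.arange(len(classes), dtype=np.int64)
    params = {f: np.array([getattr(c, f) for c in classes]) for f in _PARAM_FIELDS}
    act_morph = np.array([_MORPH_CODE[c.morphotype] for c in classes], dtype=np.int8)
    act_sev = np.array([c.severity for c in classes], dtype=np.int8)
    for i, c in enumerate(classes):
        g_id.append(c.id)
        g_parent.append(-1)
        g_origin.append(-1)
        g_nmut.append(len(c.mutations))
        g_depth.append(0)
        g_morph.append(_MORPH_CODE[c.morphotype])
        g_sev.append(c.severity)
        if c.mutations:
            ledger_rows.append(
                pd.DataFrame(
                    {
                        "class_idx": i,
                        "region": [m.region_class or "other" for m in c.mutations],
                        "chrom": [m.chrom for m in c.mutations],
                        "pos": [m.pos for m in c.mutations],
                        "ref": [m.ref for m in c.mutations],
                        "alt": [m.alt for m in c.mutations],
                        "kind": [m.kind for m in c.mutations],
                        "substitution_class": [None] * len(c.mutations),
                        "subculture": -1,
                        "generation": -1,
                    }
                )
            )

    region_names = np.array(list(target_weights))
    region_probs = np.array(list(target_weights.values()), dtype=float) / wsum
    hot_by_name = {r.region_id: r for r in genome.regions}

    k_cap = regime.carrying_capacity
    inoc = max(int(round(k_cap * regime.dilution_factor)), 1)
    if initial_counts is None:
        veg = np.zeros(len(classes), dtype=np.int64)
        veg[0] = inoc
    else:
        veg = np.array([initial_counts.get(c.id, 0) for c in classes], dtype=np.int64)
        if veg.sum() == 0:
            raise ConfigError("initial_counts sum to zero")
    spores = np.zeros_like(veg)

    states: list[PopulationState] = []
    pheno_rows: list[dict] = []
    recorded: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []  # (idx, veg, spore)

    transfer_ctx = {"subculture": 0, "generation": 0}

    def spawn_batch(counts: np.ndarray, births: int):
        nonlocal act_idx, act_morph, act_sev, params
        n_ev = int(rng.poisson(regime.mutation_rate * births)) if births > 0 else 0
        if n_ev == 0:
            return counts, params["baseline_fitness"], params["freq_dependence"]
        tot = counts.sum()
        if tot == 0:
            return counts, params["baseline_fitness"], params["freq_dependence"]
        par = rng.choice(len(counts), size=n_ev, p=counts / tot)
        regions = rng.choice(region_names, size=n_ev, p=region_probs)
        attrs = _draw_mutation_attrs(n_ev, regions, genome, spectrum, kind_weights, rng)

        new_params = {f: params[f][par].copy() for f in _PARAM_FIELDS}
        new_morph = act_morph[par].copy()
        new_sev = act_sev[par].copy()
        for rid in np.unique(regions):
            hot = hot_by_name.get(str(rid))
            tmpl = templates[hot.template] if hot else templates["carrier"]
            if tmpl.severity == 0 and not tmpl.overrides:
                continue
            m = (regions == rid) & (new_sev < tmpl.severity)
            if not m.any():
                continue
            for f, v in tmpl.overrides.items():
                new_params[f][m] = v
            if tmpl.morphotype is not None:
                new_morph[m] = _MORPH_CODE[tmpl.morphotype]
            new_sev[m] = tmpl.severity

        start = len(g_id)
        par_global = act_idx[par]
        for j in range(n_ev):
            g_id.append(f"g{start + j}")
            g_parent.append(int(par_global[j]))
            g_origin.append(transfer_ctx["subculture"])
            g_nmut.append(g_nmut[par_global[j]] + 1)
            g_depth.append(g_depth[par_global[j]] + 1)
            g_morph.append(int(new_morph[j]))
            g_sev.append(int(new_sev[j]))
        attrs = attrs.assign(
            class_idx=np.arange(start, start + n_ev),
            region=regions,
            chrom=genome.chrom,
            subculture=transfer_ctx["subculture"],
            generation=transfer_ctx["generation"],
        )
        ledger_rows.append(attrs)

        # move one founder cell from each parent to its new class
        np.subtract.at(counts, par, 1)
        np.clip(counts, 0, None, out=counts)
        counts = np.concatenate([counts, np.ones(n_ev, dtype=np.int64)])
        act_idx = np.concatenate([act_idx, np.arange(start, start + n_ev)])
        for f in _PARAM_FIELDS:
            params[f] = np.concatenate([params[f], new_params[f]])
        act_morph = np.concatenate([act_morph, new_morph])
        act_sev = np.concatenate([act_sev, new_sev])
        transfer_ctx["generation"] += 1
        return counts, params["baseline_fitness"], params["freq_dependence"]

    def run_growth(veg_in: np.ndarray, spores_in: np.ndarray):
        nonlocal veg, spores
        germ = rng.binomial(spores_in, regime.germination_efficiency)
        veg_in = veg_in + germ
        spores_in = spores_in - germ
        if veg_in.sum() == 0:
            raise ExtinctionError(
                f"no vegetative founders at subculture {transfer_ctx['subculture']}"
            )
        transfer_ctx["generation"] = 0
        grown = _grow_to_capacity(
            veg_in,
            params["baseline_fitness"],
            params["freq_dependence"],
            k_cap,
            rng,
            on_generation=spawn_batch,
        )
        # spores array may be shorter than the grown counts after spawning
        if len(spores_in) < len(grown):
            spores_in = np.concatenate(
                [spores_in, np.zeros(len(grown) - len(spores_in), dtype=np.int64)]
            )
        x = grown / grown.sum()
        solvents = float(np.dot(x, params["solvent_yield"]))
        acids = float(np.dot(x, params["acid_yield"]))
        new_spores = rng.binomial(grown, params["sporulation_fraction"])
        veg_out = grown - new_spores
        spores_out = spores_in + new_spores
        extra_h = max(regime.transfer_interval_h - 24.0, 0.0)
        if extra_h > 0:
            veg_out = rng.binomial(veg_out, params["post24h_viability"] ** extra_h)
        veg, spores = veg_out, spores_out
        return solvents, acids

    def record(t: int, solvents: float, acids: float) -> None:
        whole = veg + spores
        total = whole.sum()
        fr = np.zeros(len(MORPHOTYPES))
        if total > 0:
            for mi in range(len(MORPHOTYPES)):
                fr[mi] = whole[act_morph == mi].sum() / total
        pheno_rows.append(
            {
                "subculture": t,
                "solvents_gL": solvents,
                "acids_gL": acids,
                "spores_cfu": int(spores.sum()),
                "vegetative_cfu": int(veg.sum()),
                **{f"frac_{m}": fr[i] for i, m in enumerate(MORPHOTYPES)},
            }
        )
        recorded.append((act_idx.copy(), veg.copy(), spores.copy()))
        if keep_states:
            alive = whole > 0
            states.append(
                PopulationState(
                    subculture_index=t,
                    vegetative={
                        g_id[act_idx[i]]: int(veg[i]) for i in np.flatnonzero(alive)
                    },
                    spores={
                        g_id[act_idx[i]]: int(spores[i])
                        for i in np.flatnonzero(alive & (spores > 0))
                    },
                    solvents_gL=solvents,
                    acids_gL=acids,
                    culture_age_h=float(regime.transfer_interval_h),
                )
            )

    def prune() -> None:
        nonlocal act_idx, act_morph, act_sev, veg, spores, params
        keep = (veg + spores) > 0
        if keep.all():
            return
        act_idx = act_idx[keep]
        veg = veg[keep]
        spores = spores[keep]
        act_morph = act_morph[keep]
        act_sev = act_sev[keep]
        for f in _PARAM_FIELDS:
            params[f] = params[f][keep]

    # subculture 0: initial growth from the colony inoculum
    solv, ac = run_growth(veg, spores)
    record(0, solv, ac)

    for t in range(1, regime.n_subcultures + 1):
        transfer_ctx["subculture"] = t
        veg = rng.binomial(veg, regime.dilution_factor)
        spores = rng.binomial(spores, regime.dilution_factor)
        if regime.heat_shock:
            if spores.sum() == 0:
                raise ExtinctionError(f"heat shock with no spores at subculture {t}")
            veg = rng.binomial(spores, regime.germination_efficiency)
            spores = np.zeros_like(spores)
            if veg.sum() == 0:
                raise ExtinctionError(f"no germinated founders at subculture {t}")
        prune()
        solv, ac = run_growth(veg, spores)
        record(t, solv, ac)

    # assemble outputs
    n_classes = len(g_id)
    parent_arr = np.array(g_parent, dtype=np.int64)
    depth_arr = np.array(g_depth, dtype=np.int64)
    class_table = pd.DataFrame(
        {
            "class_id": g_id,
            "parent_id": [g_id[p] if p >= 0 else None for p in g_parent],
            "origin_subculture": g_origin,
            "morphotype": [MORPHOTYPES[m] for m in g_morph],
            "severity": g_sev,
            "n_mutations": g_nmut,
        }
    )

    if ledger_rows:
        mutations = pd.concat(ledger_rows, ignore_index=True)
    else:
        mutations = pd.DataFrame(
            columns=[
                "pos", "ref", "alt", "kind", "substitution_class",
                "class_idx", "region", "chrom", "subculture", "generation",
            ]
        )
    mutations = mutations.reset_index(drop=True)
    mutations.insert(0, "mut_id", [f"m{i}" for i in range(len(mutations))])
    mutations["class_id"] = [g_id[i] for i in mutations["class_idx"]]

    n_sub = regime.n_subcultures + 1
    if compute_truth and len(mutations):
        counts_global = np.zeros((n_sub, n_classes), dtype=np.float64)
        for t, (idx, v, s) in enumerate(recorded):
            counts_global[t, idx] = v + s
        totals = counts_global.sum(axis=1, keepdims=True)
        totals[totals == 0] = 1.0
        # subtree totals: push each class's count onto its parent, deepest first
        subtree = counts_global.copy()
        for d in range(int(depth_arr.max()), 0, -1):
            nodes = np.flatnonzero(depth_arr == d)
            if len(nodes) == 0:
                continue
            np.add.at(subtree.T, parent_arr[nodes], subtree[:, nodes].T)
        af = subtree / totals
        truth = pd.DataFrame(
            af[:, mutations["class_idx"].to_numpy()].T,
            index=pd.Index(mutations["mut_id"], name="mut_id"),
            columns=list(range(n_sub)),
        )
    else:
        truth = pd.DataFrame(
            index=pd.Index([], name="mut_id"), columns=list(range(n_sub)), dtype=float
        )

    phenotypes = pd.DataFrame(pheno_rows).set_index("subculture")
    return SeriesResult(
        states=states,
        class_table=class_table,
        mutations=mutations.drop(columns=["class_idx"]).assign(
            class_idx=mutations["class_idx"]
        ),
        truth_af=truth,
        phenotypes=phenotypes,
        seed=seed,
        regime=regime,
    )


def sample_isolates(
    series: SeriesResult,
    subculture: int,
    n_isolates: int,
    rng: np.random.Generator,
) -> list[MutationRecord]:
    """Sample colony isolates from a subculture and list their mutations.

    Isolates are drawn with replacement proportional to whole-culture
    (vegetative + spore) class frequencies, mimicking colony picks from a
    plated sample.  Each isolate's catalogue is its lineage's full mutation
    chain (parental mutations included, wild-type background excluded).
    """
    if not series.states:
        raise ValueError("series was run with keep_states=False")
    state = next(
        (s for s in series.states if s.subculture_index == subculture), None
    )
    if state is None:
        raise ValueError(f"no state recorded for subculture {subculture}")
    ids = sorted(set(state.vegetative) | set(state.spores))
    weights = np.array(
        [state.vegetative.get(i, 0) + state.spores.get(i, 0) for i in ids], dtype=float
    )
    if weights.sum() == 0:
        raise ExtinctionError("cannot sample isolates from an empty culture")
    picks = rng.choice(len(ids), size=n_isolates, p=weights / weights.sum())

    idx_of = {cid: i for i, cid in enumerate(series.class_table["class_id"])}
    parent = series.class_table["parent_id"].tolist()
    by_class: dict[int, list[dict]] = {}
    for row in series.mutations.to_dict("records"):
        by_class.setdefault(int(row["class_idx"]), []).append(row)

    records: list[MutationRecord] = []
    for k, p in enumerate(picks):
        iso = f"iso{k:03d}"
        cid = ids[p]
        while cid is not None:
            ci = idx_of[cid]
            for row in by_class.get(ci, []):
                records.append(
                    MutationRecord(
                        chrom=row["chrom"],
                        pos=int(row["pos"]),
                        ref=row["ref"],
                        alt=row["alt"],
                        kind=row["kind"],
                        isolate_id=iso,
                        region_class=row["region"],
                    )
                )
            cid = parent[ci]
    return records
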