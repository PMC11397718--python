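"""Synthetic pollen-phenotype studies.

The generator emulates the statistical structure the downstream
analyses assume: taxon-level trait means drawn inside realistic ranges
for *Malus* pollen, thirty within-taxon replicates at controlled
coefficients of variation, cultivar means inherited as midparent values
with a directional multiplicative drift on perforation density, and a
weak ordinal section effect on pollen size.

All randomness flows from a single integer seed through per-stage
``numpy`` sub-streams (taxa, pedigree, replicates), so regenerating
with the same :class:`SimConfig` is byte-identical and adding taxa to
one stage does not perturb the draws of another.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .traits import (
    UNKNOWN,
    BreedingRoute,
    Pedigree,
    Rank,
    TaxonRecord,
    TraitTable,
)

#: Observed span of taxon-level trait means in the reference Malus
#: pollen panel (um, um^2, count/um^2).
DEFAULT_TRAIT_MEAN_RANGES: dict[str, tuple[float, float]] = {
    "P": (29.44, 52.35),
    "E": (20.95, 29.64),
    "S": (560.25, 1108.89),
    "RW": (0.13, 0.25),
    "FW": (0.04, 0.28),
    "PD": (0.0, 11.18),
}

#: E'/E is an interior/equatorial diameter ratio; its taxon-level span.
DEFAULT_EPRIME_RATIO_RANGE: tuple[float, float] = (0.80, 0.87)

#: Observed taxon-level span of the shape ratio P/E; E is drawn through
#: this ratio so generated taxa stay inside it.
PE_RATIO_RANGE: tuple[float, float] = (1.22, 2.21)

#: Target within-taxon coefficient of variation per trait. Size and
#: ridge traits replicate tightly; furrow width and perforation density
#: are patchier on the exine and vary about twice as much.
DEFAULT_WITHIN_CV: dict[str, float] = {
    "P": 0.10, "E": 0.10, "Eprime": 0.10, "S": 0.10,
    "RW": 0.10, "FW": 0.20, "PD": 0.20,
}

#: Aberrant-grain rates observed across the panel span 0 to 95.6%.
AP_RANGE: tuple[float, float] = (0.0, 0.956)


@dataclass
class SimConfig:
    """Study conditions for the synthetic generator.

    Defaults mirror the reference study: 23 species + 84 cultivars,
    30 replicates per indicator, roughly a third of species with a
    perforation-free exine, and about a third of breeding routes with
    an unnamed second parent.
    """

    n_species: int = 23
    n_cultivars: int = 84
    replicates: int = 30
    trait_mean_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TRAIT_MEAN_RANGES))
    eprime_ratio_range: tuple[float, float] = DEFAULT_EPRIME_RATIO_RANGE
    within_cv: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_WITHIN_CV))
    #: weight of parent A in the midparent mean (0.5 = true midparent).
    midparent_weight: float = 0.5
    #: progeny deviation from midparent, as a fraction of the midparent
    #: value (relative scale keeps one knob meaningful across traits
    #: whose magnitudes differ by four orders).
    progeny_noise_sd: float = 0.05
    #: multiplicative perforation-density drift parent -> progeny (>= 1
    #: reproduces the observed low-to-high progression).
    pd_drift: float = 1.5
    #: additive shift on size traits (P, E, S) per section step, um;
    #: negative emulates the weak large-to-small trend along sections.
    section_size_slope: float = -0.8
    #: share of species with no perforations at all.
    frac_zero_pd: float = 0.327
    #: probability that a breeding route's second parent is unnamed.
    frac_unknown_parent: float = 0.35
    seed: int = 0

    def validate(self) -> None:
        if self.n_species < 0 or self.n_cultivars < 0 or self.replicates < 1:
            raise ValueError("counts must be non-negative, replicates >= 1")
        for t, (lo, hi) in self.trait_mean_ranges.items():
            if lo > hi:
                raise ValueError(f"range for {t!r} has lo > hi")
        for name, p in (("frac_zero_pd", self.frac_zero_pd),
                        ("frac_unknown_parent", self.frac_unknown_parent),
                        ("midparent_weight", self.midparent_weight)):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.pd_drift < 0:
            raise ValueError("pd_drift must be >= 0")


def _stage_rngs(seed: int) -> dict[str, np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    taxa, pedigree, replicates, extra = ss.spawn(4)
    return {
        "taxa": np.random.default_rng(taxa),
        "pedigree": np.random.default_rng(pedigree),
        "replicates": np.random.default_rng(replicates),
        "extra": np.random.default_rng(extra),
    }


def generate_taxa(config: SimConfig) -> tuple[list[TaxonRecord], pd.DataFrame]:
    """Species records with sections 1-5 and their true trait means.

    Sections are assigned round-robin so every section is represented
    once ``n_species >= 5``. Size traits (P, E, S) receive
    ``section_size_slope * section`` on top of the uniform draw; a
    ``frac_zero_pd`` share of species gets a perforation density of
    exactly zero.
    """
    config.validate()
    rng = _stage_rngs(config.seed)["taxa"]
    n = config.n_species
    records = [
        TaxonRecord(taxon_id=f"sp{i + 1:03d}", name=f"species {i + 1}",
                    rank=Rank.SPECIES, section=(i % 5) + 1)
        for i in range(n)
    ]
    means = {}
    for t in ("P", "S", "RW", "FW", "PD"):
        lo, hi = config.trait_mean_ranges[t]
        means[t] = rng.uniform(lo, hi, size=n)
    # E is drawn through the shape ratio P/E, constrained jointly so
    # that both E and P/E stay inside their observed spans
    elo, ehi = config.trait_mean_ranges["E"]
    plo_ratio, phi_ratio = PE_RATIO_RANGE
    lo_r = np.maximum(plo_ratio, means["P"] / ehi)
    hi_r = np.minimum(phi_ratio, means["P"] / elo)
    if (lo_r > hi_r).any():
        raise ValueError("P and E ranges admit no P/E inside the shape span")
    means["E"] = means["P"] / rng.uniform(lo_r, hi_r)
    sections = np.array([r.section for r in records], dtype=float)
    for t in ("P", "E", "S"):
        means[t] = np.maximum(means[t] + config.section_size_slope * sections, 0.0)
    # E' scales with the (section-adjusted) E so the shape ratio E'/E
    # stays independent of section
    rlo, rhi = config.eprime_ratio_range
    means["Eprime"] = means["E"] * rng.uniform(rlo, rhi, size=n)
    n_zero = int(round(config.frac_zero_pd * n))
    if n_zero:
        zero_idx = rng.choice(n, size=n_zero, replace=False)
        means["PD"][zero_idx] = 0.0
    df = pd.DataFrame(means, index=[r.taxon_id for r in records])
    df.index.name = "taxon_id"
    return records, df


def generate_pedigree_and_cultivars(
    config: SimConfig,
    taxonomy: list[TaxonRecord],
    true_means: pd.DataFrame,
) -> tuple[Pedigree, pd.DataFrame]:
    """Breeding routes plus cultivar true means under midparent
    inheritance.

    Each cultivar crosses two distinct species; with probability
    ``frac_unknown_parent`` the second slot is unnamed, in which case
    the single known parent supplies the whole mean (weight 1). The
    progeny mean is ``w*A + (1-w)*B`` plus relative Gaussian noise, and
    perforation density is additionally multiplied by ``pd_drift``.
    """
    config.validate()
    species = [r.taxon_id for r in taxonomy if r.rank is Rank.SPECIES]
    if len(species) < 2:
        raise ValueError("need at least 2 species to breed cultivars")
    rng = _stage_rngs(config.seed)["pedigree"]
    w = config.midparent_weight
    entries: list[BreedingRoute] = []
    rows = {}
    for j in range(config.n_cultivars):
        cid = f"cv{j + 1:03d}"
        pa, pb = rng.choice(len(species), size=2, replace=False)
        a, b = species[pa], species[pb]
        unknown_b = rng.uniform() < config.frac_unknown_parent
        if unknown_b:
            mid = true_means.loc[a].astype(float)
            entries.append(BreedingRoute(cid, a, UNKNOWN, source="synthetic"))
        else:
            mid = (w * true_means.loc[a] + (1.0 - w) * true_means.loc[b]).astype(float)
            entries.append(BreedingRoute(cid, a, b, source="synthetic"))
        noise = rng.normal(0.0, 1.0, size=len(mid))
        mean = mid * (1.0 + config.progeny_noise_sd * noise)
        mean["PD"] = mean["PD"] * config.pd_drift
        rows[cid] = np.maximum(mean, 0.0)
    cultivar_means = pd.DataFrame(rows).T
    cultivar_means = cultivar_means.reindex(columns=true_means.columns)
    cultivar_means.index.name = "taxon_id"
    return Pedigree(entries), cultivar_means


def generate_replicates(true_means: pd.DataFrame, config: SimConfig) -> TraitTable:
    """Replicate measurements around the true means.

    Each replicate is ``max(0, Normal(mean, cv * mean))``; a taxon with
    a zero mean (perforation-free exine) yields all-zero replicates.
    Aberrant rates are drawn uniformly over the observed 0-95.6% span.
    """
    config.validate()
    rng = _stage_rngs(config.seed)["replicates"]
    nrep = config.replicates
    recs = []
    for taxon in true_means.index:
        for trait in true_means.columns:
            mean = float(true_means.loc[taxon, trait])
            cv = config.within_cv.get(trait, 0.10)
            if mean == 0.0 or cv == 0.0:
                values = np.full(nrep, mean)
            else:
                values = np.maximum(
                    rng.normal(mean, cv * mean, size=nrep), 0.0)
            for k in range(nrep):
                recs.append((taxon, k + 1, trait, values[k]))
    data = pd.DataFrame(recs, columns=["taxon_id", "replicate", "trait", "value"])
    ap = pd.Series(
        rng.uniform(AP_RANGE[0], AP_RANGE[1], size=len(true_means.index)),
        index=true_means.index, name="AP",
    )
    return TraitTable(data, aberrant_rate=ap,
                      expected_replicates=nrep)


@dataclass
class SimulatedStudy:
    """Everything one synthetic study produces."""

    taxonomy: list[TaxonRecord]
    table: TraitTable
    pedigree: Pedigree
    true_means: pd.DataFrame  # species + cultivars, index taxon_id
    config: SimConfig


def generate_study(config: SimConfig | None = None, **overrides) -> SimulatedStudy:
    """One-call generator: taxa, pedigree, cultivars and replicates."""
    config = replace(config or SimConfig(), **overrides)
    species_records, species_means = generate_taxa(config)
    if config.n_cultivars and config.n_species >= 2:
        pedigree, cultivar_means = generate_pedigree_and_cultivars(
            config, species_records, species_means)
        cultivar_records = [
            TaxonRecord(taxon_id=c, name=f"cultivar {c[2:]}", rank=Rank.CULTIVAR)
            for c in cultivar_means.index
        ]
        all_means = pd.concat([species_means, cultivar_means])
        taxonomy = species_records + cultivar_records
    else:
        pedigree, taxonomy, all_means = Pedigree([]), species_records, species_means
    table = generate_replicates(all_means, config)
    return SimulatedStudy(taxonomy, table, pedigree, all_means, config)


def generate_family_study(
    n_families: int = 4,
    cultivars_per_family: int = 5,
    separation: float = 3.0,
    replicates: int = 10,
    within_cv: float = 0.03,
    seed: int = 0,
) -> tuple[SimulatedStudy, Mapping[str, int]]:
    """A study whose taxa form well-separated breeding families.

    Each family holds two parent species near a family-specific centre
    and ``cultivars_per_family`` midparent progeny. Adjacent family
    centres are ``separation`` within-family standard deviations apart
    on every trait, so a clustering that recovers the families should
    co-assign progeny with their parents (near-total family
    aggregation). Returns the study plus the true family of each taxon.
    """
    if n_families < 2:
        raise ValueError("need at least 2 families")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    traits = ("P", "E", "S", "RW", "FW", "PD")
    config = SimConfig(replicates=replicates,
                       within_cv={t: within_cv for t in
                                  ("P", "E", "Eprime", "S", "RW", "FW", "PD")},
                       seed=seed)
    records: list[TaxonRecord] = []
    entries: list[BreedingRoute] = []
    mean_rows: dict[str, pd.Series] = {}
    family_of: dict[str, int] = {}
    # each trait grades the families in its own (random) order, so any
    # two families differ strongly on several trait axes, not just one
    trait_order = {t: rng.permutation(n_families) for t in traits}
    # taxon means within a family scatter with sd <= gap / separation:
    # parents and the cultivars' extra midparent noise each get half
    # that budget, so centre spacing stays >= `separation` within-sd
    sds = {}
    centres = {}
    for t in traits:
        lo, hi = DEFAULT_TRAIT_MEAN_RANGES[t]
        gap = (hi - lo) / n_families
        sds[t] = gap / separation / 2.0
        centres[t] = [lo + (trait_order[t][f] + 0.5) * gap
                      for f in range(n_families)]
    for f in range(n_families):
        parents = []
        for p in range(2):
            tid = f"fam{f + 1}_sp{p + 1}"
            m = {t: max(centres[t][f] + rng.normal(0.0, sds[t]), 0.0)
                 for t in traits}
            m["Eprime"] = m["E"] * 0.84
            mean_rows[tid] = pd.Series(m)
            records.append(TaxonRecord(tid, tid, Rank.SPECIES,
                                       section=(f % 5) + 1))
            family_of[tid] = f
            parents.append(tid)
        for c in range(cultivars_per_family):
            tid = f"fam{f + 1}_cv{c + 1}"
            mid = (mean_rows[parents[0]] + mean_rows[parents[1]]) / 2.0
            noise = pd.Series({t: rng.normal(0.0, sds[t]) for t in traits})
            noise["Eprime"] = 0.0
            m = (mid + noise).clip(lower=0.0)
            m["Eprime"] = m["E"] * 0.84
            mean_rows[tid] = m
            records.append(TaxonRecord(tid, tid, Rank.CULTIVAR))
            family_of[tid] = f
            entries.append(BreedingRoute(tid, parents[0], parents[1],
                                         source="synthetic family"))
    order = ["P", "E", "Eprime", "S", "RW", "FW", "PD"]
    true_means = pd.DataFrame(mean_rows).T.reindex(columns=order)
    true_means.index.name = "taxon_id"
    table = generate_replicates(true_means, config)
    study = SimulatedStudy(records, table, Pedigree(entries), true_means, config)
    return study, family_of
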