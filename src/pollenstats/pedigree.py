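"""Pedigree-aware statistics: family aggregation, perforation-density
progression, section aggregation and hybridization frequency.

*Family aggregation* asks whether a cultivar lands in the same cluster
group as at least one of its known parents — co-clustering of progeny
and parent is phenotypic evidence of the recorded pedigree. The score
is reported at two resolutions: the top-level groups ("four-group")
and the finer partition in which the largest group is replaced by its
subgroups ("six-group").

*Perforation-density progression* asks whether a cultivar's
perforation density exceeds that of at least one parent, tracking the
low-to-high drift of perforation density across breeding generations.
Crosses with an unnamed (``unknown``) or unmeasured (``untested``)
parent are handled in two modes: ``exclude_unknown`` drops such
parents from the comparison, ``assume_lower`` treats them as having
lower perforation density than the progeny (the comparison
auto-succeeds), which bounds the statistic from above.

The module also ships a transcription of a published 28-cultivar
crabapple parent-traceability panel (breeding routes, cluster-group
assignments where printed, and the per-cultivar yes/no indicators) as
a reference fixture; see :func:`load_parentage_panel`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cluster import ClusterResult
from .traits import UNKNOWN, UNTESTED, Pedigree, Rank, TaxonRecord

#: Sentinel for a progeny that cannot be scored (no usable comparator).
NOT_EVALUABLE = None


class EmptyInputError(ValueError):
    """No evaluable progeny; percentage undefined."""


def percent_share(count: int, total: int) -> float:
    """A share as a percentage (e.g. 88 of 107 -> 82.24...)."""
    if total <= 0:
        raise EmptyInputError("total must be positive")
    return 100.0 * count / total


def _summarize(indicators: Mapping[str, bool | None]) -> tuple[float, int]:
    evaluable = [v for v in indicators.values() if v is not NOT_EVALUABLE]
    if not evaluable:
        raise EmptyInputError("no evaluable progeny")
    return percent_share(sum(evaluable), len(evaluable)), len(evaluable)


@dataclass
class AggregationReport:
    level: str
    indicators: dict[str, bool | None]
    percentage: float
    n_evaluable: int


@dataclass
class PDProgressionReport:
    mode: str
    indicators: dict[str, bool | None]
    percentage: float
    n_evaluable: int


@dataclass
class HybridizationFrequency:
    frequency: dict[str, float]
    classification: dict[str, str]
    total_crosses: int
    thresholds: tuple[float, float] = (0.20, 0.05)


@dataclass
class SectionAggregationReport:
    group_percentage: float
    subgroup_percentage: float
    modal_group: dict[int, tuple[str, ...]]
    modal_subgroup: dict[int, tuple[str, ...]]
    n_species: int
    ties: list[str] = field(default_factory=list)


# -- family aggregation ------------------------------------------------


def aggregation_from_labels(
    labels: Mapping[str, str],
    pedigree: Pedigree,
    rule: str = "any",
    level: str = "labels",
) -> AggregationReport:
    """Score each progeny against its known, labelled parents.

    A progeny aggregates if its label equals that of at least one
    (``rule='any'``, the default) or every (``rule='all'``) named
    parent present in ``labels``; progeny without any such parent —
    or absent from ``labels`` themselves — are not evaluable.
    """
    if rule not in ("any", "all"):
        raise ValueError(f"unknown rule {rule!r}")
    indicators: dict[str, bool | None] = {}
    for route in pedigree:
        parents = [p for p in route.named_parents if p in labels]
        if not parents or route.progeny not in labels:
            indicators[route.progeny] = NOT_EVALUABLE
            continue
        matches = [labels[route.progeny] == labels[p] for p in parents]
        indicators[route.progeny] = any(matches) if rule == "any" else all(matches)
    percentage, n_eval = _summarize(indicators)
    return AggregationReport(level=level, indicators=indicators,
                             percentage=percentage, n_evaluable=n_eval)


def family_aggregation(
    result: ClusterResult,
    pedigree: Pedigree,
    level: str = "four_group",
    rule: str = "any",
) -> AggregationReport:
    """Family aggregation on a two-level clustering.

    ``four_group`` compares top-level group letters; ``six_group``
    compares the finer labels in which the largest group is replaced
    by its subgroups. Coarsening can only merge labels, so the
    four-group percentage is always >= the six-group one.
    """
    labels = {t: result.effective_label(t, level) for t in result.taxa}
    report = aggregation_from_labels(labels, pedigree, rule=rule, level=level)
    return report


# -- perforation-density progression -----------------------------------


def pd_progression(
    pd_means: Mapping[str, float],
    pedigree: Pedigree,
    mode: str = "exclude_unknown",
) -> PDProgressionReport:
    """Share of progeny whose perforation density exceeds >= 1 parent's.

    ``exclude_unknown``: unknown/untested parents are dropped; a
    progeny with no measured parent is not evaluable. ``assume_lower``:
    such parents are assumed to carry a lower perforation density, so
    the comparison against them auto-succeeds. By construction the
    assume-lower percentage bounds the exclude-unknown one from above.
    """
    if mode not in ("exclude_unknown", "assume_lower"):
        raise ValueError(f"unknown mode {mode!r}")
    indicators: dict[str, bool | None] = {}
    missing = [r.progeny for r in pedigree if r.progeny not in pd_means]
    if missing:
        raise ValueError(f"no PD mean for progeny {missing[:5]}")
    for route in pedigree:
        child = float(pd_means[route.progeny])
        outcomes = []
        for parent in (route.parent1, route.parent2):
            token = parent.lower()
            measured = token not in (UNKNOWN, UNTESTED) and parent in pd_means
            if measured:
                outcomes.append(child > float(pd_means[parent]))
            elif mode == "assume_lower":
                outcomes.append(True)
        indicators[route.progeny] = any(outcomes) if outcomes else NOT_EVALUABLE
    percentage, n_eval = _summarize(indicators)
    return PDProgressionReport(mode=mode, indicators=indicators,
                               percentage=percentage, n_evaluable=n_eval)


# -- section aggregation -----------------------------------------------


def section_aggregation(
    result: ClusterResult, taxonomy: Sequence[TaxonRecord]
) -> SectionAggregationReport:
    """How concentrated each taxonomic section is within the clustering.

    For every section, find its modal cluster label (separately at
    group and subgroup resolution); the statistic is the share of
    sectioned species whose label equals their section's modal label.
    Modal ties accept either label and are logged in ``ties``.
    """
    species = [r for r in taxonomy
               if r.rank is Rank.SPECIES and r.section is not None
               and r.taxon_id in result.group_of]
    if not species:
        raise EmptyInputError("no clustered species with a section label")

    def run(level: str) -> tuple[float, dict[int, tuple[str, ...]], list[str]]:
        ties: list[str] = []
        by_section: dict[int, list[str]] = {}
        for r in species:
            by_section.setdefault(r.section, []).append(
                result.effective_label(r.taxon_id, level))
        modal: dict[int, tuple[str, ...]] = {}
        hits = 0
        for sec, labs in by_section.items():
            counts = pd.Series(labs).value_counts()
            top = counts[counts == counts.iloc[0]].index.tolist()
            if len(top) > 1:
                ties.append(f"section {sec} ({level}): tie among {sorted(top)}")
            modal[sec] = tuple(sorted(top))
            hits += sum(1 for lab in labs if lab in modal[sec])
        return percent_share(hits, len(species)), modal, ties

    g_pct, g_modal, g_ties = run("four_group")
    s_pct, s_modal, s_ties = run("six_group")
    return SectionAggregationReport(
        group_percentage=g_pct, subgroup_percentage=s_pct,
        modal_group=g_modal, modal_subgroup=s_modal,
        n_species=len(species), ties=g_ties + s_ties,
    )


# -- hybridization frequency -------------------------------------------


def hybridization_frequency(
    pedigree: Pedigree,
    high: float = 0.20,
    medium: float = 0.05,
    species: Sequence[str] | None = None,
) -> HybridizationFrequency:
    """Per-species share of crosses in which it appears as a parent.

    The denominator is the number of crosses (routes), and a species
    appearing in both slots of one route is counted once, so a species
    crossed into every route has frequency 1. ``species`` optionally
    names the full candidate pool, so never-used parents report
    frequency 0. Classification defaults: high >= 20%, medium >= 5%,
    else low.
    """
    if len(pedigree) == 0:
        raise EmptyInputError("empty pedigree")
    counts: dict[str, int] = {sp: 0 for sp in (species or ())}
    for route in pedigree:
        for sp in set(route.named_parents):
            counts[sp] = counts.get(sp, 0) + 1
    total = len(pedigree)
    freq = {sp: c / total for sp, c in sorted(counts.items())}
    cls = {
        sp: "high" if f >= high else ("medium" if f >= medium else "low")
        for sp, f in freq.items()
    }
    return HybridizationFrequency(frequency=freq, classification=cls,
                                  total_crosses=total,
                                  thresholds=(high, medium))


def frequency_concordance(
    study: HybridizationFrequency | Mapping[str, float],
    literature: HybridizationFrequency | Mapping[str, float],
) -> tuple[float, float]:
    """Pearson r (and r^2) between two frequency tables over the
    species they share."""
    a = study.frequency if isinstance(study, HybridizationFrequency) else dict(study)
    b = (literature.frequency
         if isinstance(literature, HybridizationFrequency) else dict(literature))
    shared = sorted(set(a) & set(b))
    if len(shared) < 3:
        raise ValueError("need >= 3 shared species")
    x = np.array([a[s] for s in shared], dtype=float)
    y = np.array([b[s] for s in shared], dtype=float)
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("zero variance in a frequency vector")
    r = float(stats.pearsonr(x, y).statistic)
    return r, r * r


# -- reference parentage panel -----------------------------------------


def load_parentage_panel() -> pd.DataFrame:
    """The 28-cultivar crabapple parent-traceability panel.

    Transcribed from published breeding-route records: progeny, the
    two parent slots (species name, ``unknown`` or — printed route
    unavailable — blank), the cluster-group assignments as printed per
    row, and four per-cultivar yes/no indicators (family aggregation
    at four- and six-group resolution; perforation-density progression
    under the assume-lower and exclude-unknown conventions). Route and
    label cells are blank for the rows whose source cells are not
    printed; the indicator columns cover all 28 rows.
    """
    with resources.files("pollenstats.data").joinpath(
            "parentage_panel.csv").open("r", encoding="utf-8") as fh:
        df = pd.read_csv(fh, dtype=str, keep_default_na=False)
    for col in ("aggregated_four_group", "aggregated_six_group",
                "pd_higher_assume_lower", "pd_higher_exclude_unknown"):
        df[col] = df[col].str.strip().str.lower().map({"yes": True, "no": False})
    return df


_PANEL_COLUMNS = {
    "four_group": "aggregated_four_group",
    "six_group": "aggregated_six_group",
    "assume_lower": "pd_higher_assume_lower",
    "exclude_unknown": "pd_higher_exclude_unknown",
}


def panel_aggregation(panel: pd.DataFrame, level: str = "four_group"
                      ) -> AggregationReport:
    """Family aggregation over the parentage panel.

    For rows whose cluster labels are printed the indicator is
    recomputed from the labels with the standard matching rule (and
    must agree with the recorded yes/no); rows without printed labels
    contribute their recorded indicator.
    """
    if level not in ("four_group", "six_group"):
        raise ValueError(f"unknown level {level!r}")
    indicators: dict[str, bool | None] = {}
    for _, row in panel.iterrows():
        recorded = bool(row[_PANEL_COLUMNS[level]])
        recomputed = _row_aggregation(row, level)
        if recomputed is not None and recomputed != recorded:
            raise ValueError(
                f"panel row {row['no']}: recomputed {level} indicator "
                f"{recomputed} contradicts recorded {recorded}")
        indicators[row["progeny"]] = recorded
    percentage, n_eval = _summarize(indicators)
    return AggregationReport(level=level, indicators=indicators,
                             percentage=percentage, n_evaluable=n_eval)


def _row_aggregation(row: pd.Series, level: str) -> bool | None:
    """Recompute one panel row's aggregation indicator from its printed
    per-row labels; None when the route/labels are not printed."""
    child = str(row["progeny_label"]).strip()
    if not child:
        return None
    parents = []
    for slot in ("parent1_label", "parent2_label"):
        lab = str(row[slot]).strip()
        if lab and lab.lower() not in (UNKNOWN, UNTESTED):
            parents.append(lab)
    if not parents:
        return None

    def coarse(lab: str) -> str:
        return lab[0] if level == "four_group" else lab

    return any(coarse(child) == coarse(p) for p in parents)


def panel_pd_progression(panel: pd.DataFrame, mode: str = "exclude_unknown"
                         ) -> PDProgressionReport:
    """Perforation-density progression over the parentage panel,
    from the recorded per-cultivar indicators (the per-taxon density
    values behind them are not printed)."""
    if mode not in ("assume_lower", "exclude_unknown"):
        raise ValueError(f"unknown mode {mode!r}")
    indicators = {
        row["progeny"]: bool(row[_PANEL_COLUMNS[mode]])
        for _, row in panel.iterrows()
    }
    percentage, n_eval = _summarize(indicators)
    return PDProgressionReport(mode=mode, indicators=indicators,
                               percentage=percentage, n_evaluable=n_eval)


def panel_pedigree(panel: pd.DataFrame) -> Pedigree:
    """The breeding routes of the panel rows whose routes are printed."""
    from .traits import BreedingRoute

    entries = []
    for _, row in panel.iterrows():
        p1 = str(row["parent1"]).strip()
        if not p1:
            continue
        p2 = str(row["parent2"]).strip() or UNKNOWN
        entries.append(BreedingRoute(progeny=row["progeny"], parent1=p1,
                                     parent2=p2, source="panel"))
    return Pedigree(entries)
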