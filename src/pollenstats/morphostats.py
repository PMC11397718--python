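"""Trait-level statistics: uniformity, distinctness, Tukey letters and
Erdtman size/shape classes.

Two coefficient-of-variation statistics drive trait screening:

* **intraspecific uniformity** ``cvbar`` — the mean over taxa of the
  within-taxon coefficient of variation, ``cvbar = (1/n) * sum_i
  S_i / Xbar_i`` with ``S_i`` the sample standard deviation of taxon
  *i*'s replicates. A trait with ``cvbar <= 0.15`` replicates stably
  within a taxon and is usable for identification.
* **interspecific distinctness** ``cv`` — the coefficient of variation
  of the per-taxon means, ``cv = S' / Xbar'``. A trait with
  ``cv >= 0.15`` spreads the taxa apart and discriminates among them.

Both use the sample (ddof=1) standard deviation. Taxa whose mean is
exactly zero for a trait (e.g. perforation-free exines) are excluded
from the uniformity average — their within-taxon CV is undefined — and
counted in the result.
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .traits import TraitTable

#: Verdict threshold for both CV statistics (15%).
CV_THRESHOLD = 0.15

#: Slack for verdicts at the threshold itself, so a statistic that is
#: exactly 15% up to floating-point representation counts as boundary.
_VERDICT_EPS = 1e-10


class EmptyInputError(ValueError):
    """No usable taxa for the requested statistic."""


@dataclass(frozen=True)
class UniformityResult:
    trait: str
    cvbar: float
    n_taxa_used: int
    n_excluded_zero_mean: int
    threshold: float = CV_THRESHOLD

    @property
    def uniform(self) -> bool:
        return self.cvbar <= self.threshold + _VERDICT_EPS


@dataclass(frozen=True)
class DistinctnessResult:
    trait: str
    cv: float
    anova_F: float
    anova_p: float
    n_taxa: int
    threshold: float = CV_THRESHOLD

    @property
    def distinct(self) -> bool:
        return self.cv >= self.threshold - _VERDICT_EPS


def intraspecific_uniformity(
    table: TraitTable, trait: str, threshold: float = CV_THRESHOLD
) -> UniformityResult:
    """Mean within-taxon coefficient of variation for one trait."""
    groups = _replicates_by_taxon(table, trait)
    cvs = []
    n_zero = 0
    for values in groups.values():
        m = values.mean()
        if m == 0.0:
            n_zero += 1
            continue
        cvs.append(values.std(ddof=1) / m)
    if not cvs:
        raise EmptyInputError(
            f"no taxon with a non-zero mean for trait {trait!r}")
    return UniformityResult(trait=trait, cvbar=float(np.mean(cvs)),
                            n_taxa_used=len(cvs),
                            n_excluded_zero_mean=n_zero,
                            threshold=threshold)


def interspecific_distinctness(
    table: TraitTable, trait: str, threshold: float = CV_THRESHOLD
) -> DistinctnessResult:
    """CV of per-taxon means, plus a one-way ANOVA across taxa."""
    groups = _replicates_by_taxon(table, trait)
    if len(groups) < 2:
        raise EmptyInputError(f"need >= 2 taxa with trait {trait!r}")
    means = np.array([v.mean() for v in groups.values()])
    grand = means.mean()
    if grand == 0.0:
        raise EmptyInputError(
            f"mean of per-taxon means is zero for {trait!r}; cv undefined")
    cv = float(means.std(ddof=1) / grand)
    F, p = stats.f_oneway(*groups.values())
    return DistinctnessResult(trait=trait, cv=cv, anova_F=float(F),
                              anova_p=float(p), n_taxa=len(groups),
                              threshold=threshold)


def _replicates_by_taxon(table: TraitTable, trait: str) -> dict[str, np.ndarray]:
    sub = table.data[table.data["trait"] == trait]
    if sub.empty:
        raise EmptyInputError(f"trait {trait!r} absent from table")
    return {
        taxon: g["value"].to_numpy(dtype=float)
        for taxon, g in sub.groupby("taxon_id", sort=False)
    }


def uniformity_distinctness_report(
    table: TraitTable,
    traits: Sequence[str] | None = None,
    threshold: float = CV_THRESHOLD,
) -> pd.DataFrame:
    """Tidy per-trait screen: cvbar/cv, thresholds and verdicts."""
    traits = list(traits) if traits is not None else table.traits_present()
    rows = []
    for t in traits:
        u = intraspecific_uniformity(table, t, threshold)
        d = interspecific_distinctness(table, t, threshold)
        rows.append({
            "trait": t,
            "cvbar": u.cvbar, "uniform": u.uniform,
            "n_zero_mean_excluded": u.n_excluded_zero_mean,
            "cv": d.cv, "distinct": d.distinct,
            "anova_F": d.anova_F, "anova_p": d.anova_p,
            "threshold": threshold,
        })
    return pd.DataFrame(rows)


# -- Tukey HSD with compact letter display -----------------------------


@dataclass
class CLDResult:
    """Compact letter display over a Tukey HSD comparison.

    Two groups share a letter iff their pairwise Tukey p-value is
    >= alpha. ``pvalues`` is a symmetric DataFrame over group labels.
    """

    letters: dict[str, str]
    pvalues: pd.DataFrame
    alpha: float


def tukey_cld(groups: Mapping[str, Sequence[float]], alpha: float = 0.05) -> CLDResult:
    """Tukey HSD pairwise tests plus insert-and-absorb letters.

    Groups are sorted by descending mean before letter insertion (so
    'a' marks the top group), ties broken lexicographically by label.
    If every value in every group is identical the comparison is
    degenerate and all groups share one letter.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {k: np.asarray(groups[k], dtype=float) for k in labels}
    for k, v in arrays.items():
        if len(v) < 1:
            raise ValueError(f"group {k!r} is empty")
    all_values = np.concatenate(list(arrays.values()))
    pmat = pd.DataFrame(np.ones((len(labels), len(labels))),
                        index=labels, columns=labels)
    if np.ptp(all_values) == 0.0:
        letters = {k: "a" for k in labels}
        return CLDResult(letters=letters, pvalues=pmat, alpha=alpha)
    values = all_values
    codes = np.concatenate([[k] * len(arrays[k]) for k in labels])
    res = pairwise_tukeyhsd(values, codes, alpha=alpha)
    # pairwise results follow combinations() over the sorted unique groups
    pairs = itertools.combinations(list(res.groupsunique), 2)
    for (a, b), p in zip(pairs, res.pvalues):
        p = float(np.nan_to_num(p, nan=1.0))
        pmat.loc[a, b] = pmat.loc[b, a] = p
    order = sorted(labels, key=lambda k: (-arrays[k].mean(), k))
    significant = [
        (a, b) for a, b in itertools.combinations(order, 2)
        if pmat.loc[a, b] < alpha
    ]
    columns = _insert_absorb(order, significant)
    letters = {k: "" for k in labels}
    for letter, col in zip(_letter_stream(), columns):
        for k in order:
            if k in col:
                letters[k] += letter
    return CLDResult(letters=letters, pvalues=pmat, alpha=alpha)


def _insert_absorb(order: list[str], significant: list[tuple[str, str]]
                   ) -> list[frozenset[str]]:
    """Insert-and-absorb letter columns: start with one all-group
    column; for each significant pair split every column containing
    both; drop columns absorbed by (subset of) another."""
    cols: list[frozenset[str]] = [frozenset(order)]
    for a, b in significant:
        for col in [c for c in cols if a in c and b in c]:
            cols.remove(col)
            for new in (col - {a}, col - {b}):
                if new and not any(new <= c for c in cols):
                    cols = [c for c in cols if not (c < new)]
                    cols.append(new)
    pos = {k: i for i, k in enumerate(order)}
    cols.sort(key=lambda c: min(pos[k] for k in c))
    return cols


def _letter_stream():
    for letter in string.ascii_lowercase:
        yield letter
    for a, b in itertools.product(string.ascii_lowercase, repeat=2):
        yield a + b


# -- Erdtman classes ---------------------------------------------------

#: Erdtman pollen size classes on the longest axis (um); the medium
#: class is inclusive on both boundaries.
SIZE_CLASSES = (("small", 0.0, 25.1), ("medium", 25.1, 50.0),
                ("large", 50.0, float("inf")))

#: Erdtman shape classes on P/E.
SHAPE_CLASSES = (("subprolate", 1.14, 1.33), ("prolate", 1.33, 2.00),
                 ("perprolate", 2.00, float("inf")))

#: Returned for P/E below the subprolate lower bound instead of raising.
OUT_OF_CATALOGUE = "out_of_catalogue"


def classify_size(mean_P: float) -> str:
    """Erdtman size class from the mean polar-axis length (um):
    small < 25.1 <= medium <= 50 < large."""
    if not mean_P > 0:
        raise ValueError("mean polar axis must be positive")
    if mean_P < 25.1:
        return "small"
    if mean_P <= 50.0:
        return "medium"
    return "large"


def classify_shape(p_over_e: float) -> str:
    """Erdtman shape class from P/E: subprolate [1.14, 1.33), prolate
    [1.33, 2.00], perprolate > 2.00; values below 1.14 return the
    ``out_of_catalogue`` flag."""
    if not p_over_e > 0:
        raise ValueError("P/E must be positive")
    if p_over_e < 1.14:
        return OUT_OF_CATALOGUE
    if p_over_e < 1.33:
        return "subprolate"
    if p_over_e <= 2.00:
        return "prolate"
    return "perprolate"
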