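"""Ordinal evolutionary-trend correlations.

Two codings relate taxonomic position to pollen traits:

* **section order** — species' sections coded 1 (most ancient) to 5
  (most derived); the Pearson correlation with a per-species trait
  mean measures a directional trend along the infrageneric sequence.
* **rank order** — species coded 1, cultivars 2; with a binary coding
  the Pearson correlation is the point-biserial coefficient and its
  t-test is identical to a pooled-variance two-sample t-test between
  the two populations (asserted as a cross-check in the test suite).

Correlations are computed on per-taxon means, not on replicates:
replicates of one taxon are pseudo-replicates for a between-taxon
question and would inflate n. A replicate-level option exists but
warns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .traits import Rank, TaxonRecord, TraitTable

logger = logging.getLogger(__name__)

ALPHA = 0.05


@dataclass(frozen=True)
class TrendResult:
    trait: str
    coding: str  # "section_order" | "rank_order"
    r: float
    p: float
    n: int

    @property
    def significant(self) -> bool:
        return self.p < ALPHA


class UndefinedCorrelationError(ValueError):
    """Constant input or too few observations."""


def _pearson(x: np.ndarray, y: np.ndarray, trait: str, coding: str) -> TrendResult:
    if len(x) < 3:
        raise UndefinedCorrelationError(
            f"{coding}/{trait}: need >= 3 observations, got {len(x)}")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise UndefinedCorrelationError(
            f"{coding}/{trait}: constant vector, correlation undefined")
    res = stats.pearsonr(x, y)
    return TrendResult(trait=trait, coding=coding,
                       r=float(res.statistic), p=float(res.pvalue), n=len(x))


def section_trend(
    means: pd.DataFrame,
    taxonomy: Sequence[TaxonRecord],
    trait: str,
) -> TrendResult:
    """Pearson r between section ordinal (1-5) and per-species trait
    mean; two-sided p on n-2 df."""
    rows = [(r.section, means.loc[r.taxon_id, trait])
            for r in taxonomy
            if r.rank is Rank.SPECIES and r.section is not None
            and r.taxon_id in means.index
            and pd.notna(means.loc[r.taxon_id, trait])]
    if not rows:
        raise UndefinedCorrelationError(f"no sectioned species with {trait!r}")
    x = np.array([s for s, _ in rows], dtype=float)
    y = np.array([v for _, v in rows], dtype=float)
    return _pearson(x, y, trait, "section_order")


def rank_trend(
    means: pd.DataFrame,
    taxonomy: Sequence[TaxonRecord],
    trait: str,
) -> TrendResult:
    """Point-biserial trend species (1) -> cultivars (2) for one trait."""
    rows = [(1.0 if r.rank is Rank.SPECIES else 2.0,
             means.loc[r.taxon_id, trait])
            for r in taxonomy
            if r.taxon_id in means.index
            and pd.notna(means.loc[r.taxon_id, trait])]
    x = np.array([c for c, _ in rows], dtype=float)
    y = np.array([v for _, v in rows], dtype=float)
    if len(np.unique(x)) < 2:
        raise UndefinedCorrelationError(
            f"rank_order/{trait}: both ranks must be present")
    return _pearson(x, y, trait, "rank_order")


def trend_report(
    table_or_means: TraitTable | pd.DataFrame,
    taxonomy: Sequence[TaxonRecord],
    traits: Sequence[str] | None = None,
    include_derived: bool = True,
    holm: bool = False,
    level: str = "taxon",
) -> pd.DataFrame:
    """Tidy trend screen over traits for both codings.

    ``level='replicate'`` correlates at replicate resolution and logs a
    pseudo-replication warning; the default uses per-taxon means.
    ``holm=True`` adds Holm-adjusted p-values per coding.
    """
    if isinstance(table_or_means, TraitTable):
        if level == "replicate":
            logger.warning(
                "replicate-level trend correlation pseudo-replicates taxa; "
                "p-values will be anticonservative")
            means = table_or_means.data.pivot_table(
                index=["taxon_id", "replicate"], columns="trait",
                values="value").reset_index(level="replicate", drop=True)
        else:
            means = table_or_means.taxon_means()
        if include_derived:
            from .traits import compute_derived_ratios
            means = means.join(compute_derived_ratios(table_or_means),
                               how="left")
    else:
        means = table_or_means
    traits = list(traits) if traits is not None else list(means.columns)
    rows = []
    for coding, fn in (("section_order", section_trend),
                       ("rank_order", rank_trend)):
        for t in traits:
            try:
                res = fn(means, taxonomy, t)
            except UndefinedCorrelationError as exc:
                logger.warning("skipping %s/%s: %s", coding, t, exc)
                continue
            rows.append({"trait": t, "coding": coding, "r": res.r,
                         "p": res.p, "n": res.n,
                         "significant": res.significant})
    out = pd.DataFrame(rows)
    if holm and len(out):
        out["p_holm"] = np.nan
        for coding, idx in out.groupby("coding").groups.items():
            out.loc[idx, "p_holm"] = multipletests(
                out.loc[idx, "p"], method="holm")[1]
        out["significant_holm"] = out["p_holm"] < ALPHA
    return out
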