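"""From raw reporter intensities to analysis-ready log2 ratio matrices.

The canonical order is: reliability filter → reference-channel normalization →
per-sample median centering → complete-in-all-groups filter. Each step records
itself in the matrix provenance; centering and the complete-case filter are
idempotent. No imputation is performed anywhere — downstream tests operate on
observed values only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import ValidationError
from .io import GROUPS, SiteTable, sample_groups

logger = logging.getLogger(__name__)


@dataclass
class NormalizedMatrix:
    """Features × samples log2 values (NaN allowed) with step provenance."""

    data: pd.DataFrame
    provenance: list[dict] = field(default_factory=list)

    def record(self, step: str, **params) -> None:
        self.provenance.append({"step": step, "n_features": int(len(self.data)), **params})


def filter_reliable_sites(table: SiteTable, loc_prob_min: float = 0.75) -> SiteTable:
    """Retain sites with localization probability >= ``loc_prob_min`` (inclusive)."""
    keep = table.meta["loc_prob"] >= loc_prob_min
    logger.info("reliability filter: %d of %d sites retained at loc_prob >= %g",
                int(keep.sum()), len(keep), loc_prob_min)
    if not keep.any():
        logger.warning("reliability filter removed every site (cutoff %g)", loc_prob_min)
    return table.subset(table.meta.index[keep])


def normalize_to_reference(table: SiteTable, sheet: pd.DataFrame) -> NormalizedMatrix:
    """log2(sample / same-plex pooled reference) per cell; missing stays missing."""
    ref_of_plex = (
        sheet[sheet["is_reference"]].set_index("plex_id")["sample_id"].to_dict()
    )
    pat = sheet[~sheet["is_reference"]]
    cols = {}
    n_lost = 0
    for sid, plex in zip(pat["sample_id"], pat["plex_id"]):
        if plex not in ref_of_plex:
            raise ValidationError(f"sample {sid}: plex {plex} has no reference channel")
        if sid not in table.intensities.columns:
            raise ValidationError(f"sample {sid} absent from the intensity matrix")
        samp = table.intensities[sid].to_numpy(dtype=float)
        ref = table.intensities[ref_of_plex[plex]].to_numpy(dtype=float)
        bad_ref = ~np.isfinite(ref) | (ref <= 0)
        n_lost += int((bad_ref & np.isfinite(samp)).sum())
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(bad_ref, np.nan, np.log2(samp / np.where(bad_ref, 1.0, ref)))
        cols[sid] = ratio
    if n_lost:
        logger.info("reference normalization: %d cells lost to missing/zero reference", n_lost)
    m = NormalizedMatrix(pd.DataFrame(cols, index=table.site_ids))
    m.record("normalize_to_reference", cells_lost_to_reference=n_lost)
    return m


def median_center(m: NormalizedMatrix) -> NormalizedMatrix:
    """Subtract each sample's observed median so per-sample medians are 0."""
    data = m.data.copy()
    med = data.median(axis=0, skipna=True)
    empty = med.index[med.isna()]
    if len(empty):
        logger.warning("median centering: all-missing sample(s) left unchanged: %s",
                       list(empty))
        med = med.fillna(0.0)
    data = data.sub(med, axis=1)
    out = NormalizedMatrix(data, list(m.provenance))
    out.record("median_center")
    return out


def complete_in_all_groups(
    m: NormalizedMatrix, sheet: pd.DataFrame, min_per_group: int = 1
) -> NormalizedMatrix:
    """Keep features observed in >= ``min_per_group`` samples of every group."""
    groups = sample_groups(sheet)
    keep = pd.Series(True, index=m.data.index)
    for g in GROUPS:
        cols = groups.index[groups == g]
        cols = [c for c in cols if c in m.data.columns]
        if not cols:
            continue
        keep &= m.data[cols].notna().sum(axis=1) >= min_per_group
    logger.info("complete-in-all-groups: %d of %d features retained (min %d per group)",
                int(keep.sum()), len(keep), min_per_group)
    out = NormalizedMatrix(m.data.loc[keep], list(m.provenance))
    out.record("complete_in_all_groups", min_per_group=min_per_group)
    return out


@dataclass
class ProteinRollup:
    """Protein-level feature view: each protein carried by one representative site."""

    data: pd.DataFrame  # proteins × samples
    site_of: pd.Series  # protein_id -> representative site_id


def rollup_to_protein(
    m: NormalizedMatrix,
    table: SiteTable,
    site_stats: pd.DataFrame,
) -> ProteinRollup:
    """Represent each protein by its most significant site for one comparison.

    ``site_stats`` must be indexed by site_id with columns ``p`` and ``log2fc``
    (the comparison at hand). Rule: smallest p; ties broken by largest
    ``|log2fc|``, then lexicographic site_id. Untestable sites (p = NaN) sort
    last.
    """
    sites = m.data.index
    stats = site_stats.reindex(sites)
    order = pd.DataFrame(
        {
            "site_id": sites,
            "protein_id": table.meta.loc[sites, "protein_id"].to_numpy(),
            "p": stats["p"].to_numpy(dtype=float),
            "absfc": np.abs(stats["log2fc"].to_numpy(dtype=float)),
        }
    )
    order["p_key"] = order["p"].fillna(np.inf)
    order["absfc_key"] = -order["absfc"].fillna(0.0)
    order = order.sort_values(["p_key", "absfc_key", "site_id"], kind="mergesort")
    best = order.drop_duplicates("protein_id", keep="first")
    site_of = best.set_index("protein_id")["site_id"]
    data = m.data.loc[site_of.to_numpy()]
    data.index = site_of.index
    return ProteinRollup(data=data, site_of=site_of)


class ReliabilityFilter(BaseEstimator):
    """Transformer form of :func:`filter_reliable_sites`."""

    def __init__(self, min_loc_prob: float = 0.75):
        self.min_loc_prob = min_loc_prob

    def fit(self, table: SiteTable, y=None):
        self.n_input_ = len(table.meta)
        return self

    def transform(self, table: SiteTable) -> SiteTable:
        return filter_reliable_sites(table, self.min_loc_prob)

    def fit_transform(self, table: SiteTable, y=None) -> SiteTable:
        return self.fit(table).transform(table)


class ReferenceNormalizer(BaseEstimator):
    """Transformer form of :func:`normalize_to_reference`; the sample sheet is
    supplied at fit time."""

    def fit(self, table: SiteTable, sheet: pd.DataFrame = None):
        if sheet is None:
            raise ValidationError("ReferenceNormalizer.fit requires the sample sheet")
        self.sheet_ = sheet
        return self

    def transform(self, table: SiteTable) -> NormalizedMatrix:
        return normalize_to_reference(table, self.sheet_)

    def fit_transform(self, table: SiteTable, sheet: pd.DataFrame = None) -> NormalizedMatrix:
        return self.fit(table, sheet).transform(table)


class MedianCenterer(BaseEstimator):
    def fit(self, m: NormalizedMatrix, y=None):
        return self

    def transform(self, m: NormalizedMatrix) -> NormalizedMatrix:
        return median_center(m)

    def fit_transform(self, m: NormalizedMatrix, y=None) -> NormalizedMatrix:
        return median_center(m)


class GroupCompletenessFilter(BaseEstimator):
    def __init__(self, min_per_group: int = 1):
        self.min_per_group = min_per_group

    def fit(self, m: NormalizedMatrix, sheet: pd.DataFrame = None):
        if sheet is None:
            raise ValidationError("GroupCompletenessFilter.fit requires the sample sheet")
        self.sheet_ = sheet
        return self

    def transform(self, m: NormalizedMatrix) -> NormalizedMatrix:
        return complete_in_all_groups(m, self.sheet_, self.min_per_group)

    def fit_transform(self, m: NormalizedMatrix, sheet: pd.DataFrame = None) -> NormalizedMatrix:
        return self.fit(m, sheet).transform(m)


def standard_preprocess(
    table: SiteTable,
    sheet: pd.DataFrame,
    loc_prob_min: float = 0.75,
    min_per_group: int = 1,
) -> NormalizedMatrix:
    """filter → normalize → center → complete-case, in the canonical order."""
    t = filter_reliable_sites(table, loc_prob_min)
    m = normalize_to_reference(t, sheet)
    m = median_center(m)
    return complete_in_all_groups(m, sheet, min_per_group)
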