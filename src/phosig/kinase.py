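"""Kinase-activity inference from substrate fold-changes, three ways.

All three schemes consume the same explicit kinase→substrate-site map and the
site-level log2 fold-changes of one contrast (kinases act on sites, so no
protein rollup here):

``zscore``
    KSEA-style z: ``z = (mean_sub_fc − mean_all_fc) · sqrt(m) / sd_all_fc``
    with the population standard deviation over all quantified sites and a
    two-sided normal p.
``overrep``
    Membership over-representation: one-sided hypergeometric tail
    ``P(X >= overlap)`` of a kinase's substrates within the regulated set.
``smoothed``
    Network-smoothed variant: substrate fold-changes are first shrunk one
    step toward their neighborhood mean, ``fc' = (1−λ)·fc + λ·mean(neighbor
    fc)``, then scored as ``zscore``. This is a deliberate approximation to
    propagation-based kinase inference, not a wrapper around any external
    tool.

A kinase is reported only when at least ``min_substrates`` of its sites are
quantified (z is unstable below ~3). The consensus is the intersection of the
per-scheme top-k lists, restricted to kinases significant in each scheme.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .differential import bh_adjust
from .errors import ConfigurationError, ValidationError
from .signature import SignatureSet

logger = logging.getLogger(__name__)


def _substrate_sets(ks: pd.DataFrame) -> dict[str, set[str]]:
    return {k: set(g["site_id"]) for k, g in ks.groupby("kinase_id")}


def ksea_z(
    site_fc: pd.Series, ks: pd.DataFrame, min_substrates: int = 3
) -> pd.DataFrame:
    """KSEA-style z score per kinase over one contrast's site fold-changes."""
    fc = site_fc.dropna()
    if fc.empty:
        raise ValidationError("site_fc is empty")
    mean_all = float(fc.mean())
    sd_all = float(fc.std(ddof=0))
    if sd_all == 0:
        raise ValidationError("degenerate fold-change distribution (sd = 0)")
    rows = []
    for kid, subs in _substrate_sets(ks).items():
        quantified = sorted(subs & set(fc.index))
        m = len(quantified)
        if m < min_substrates:
            continue
        mean_sub = float(fc.loc[quantified].mean())
        z = (mean_sub - mean_all) * np.sqrt(m) / sd_all
        rows.append((kid, m, mean_sub, z))
    out = pd.DataFrame(rows, columns=["kinase_id", "m", "mean_sub_fc", "z"]).set_index(
        "kinase_id"
    )
    out["p"] = 2.0 * stats.norm.sf(np.abs(out["z"]))
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["scheme"] = "zscore"
    return out.sort_index()


def overrep_exact(
    regulated: set[str],
    ks: pd.DataFrame,
    universe: set[str],
    min_substrates: int = 3,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of substrates in ``regulated``."""
    regulated = set(regulated)
    universe = set(universe)
    if not regulated <= universe:
        raise ValidationError(
            f"regulated set has {len(regulated - universe)} feature(s) outside the universe"
        )
    N, n = len(universe), len(regulated)
    rows = []
    for kid, subs in _substrate_sets(ks).items():
        in_uni = subs & universe
        K = len(in_uni)
        if K < min_substrates:
            continue
        k = len(in_uni & regulated)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K > 0 else 1.0
        rows.append((kid, K, k, min(p, 1.0)))
    out = pd.DataFrame(
        rows, columns=["kinase_id", "m", "overlap", "p"]
    ).set_index("kinase_id")
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["scheme"] = "overrep"
    return out.sort_index()


def build_substrate_graph(ks: pd.DataFrame) -> dict[str, list[str]]:
    """Default site neighborhood: sites sharing a substrate protein or a kinase."""
    neighbors: dict[str, set[str]] = {}
    for _, grp in ks.groupby("kinase_id"):
        ids = list(grp["site_id"])
        for s in ids:
            neighbors.setdefault(s, set()).update(ids)
    for _, grp in ks.groupby("substrate_protein_id"):
        ids = list(grp["site_id"].unique())
        for s in ids:
            neighbors.setdefault(s, set()).update(ids)
    return {s: sorted(v - {s}) for s, v in neighbors.items()}


def smooth_fc(
    site_fc: pd.Series, neighbor_graph: dict[str, list[str]], lam: float
) -> pd.Series:
    """One-step neighborhood smoothing of site fold-changes."""
    if not 0.0 <= lam < 1.0:
        raise ConfigurationError(f"lambda must lie in [0, 1); got {lam}")
    fc = site_fc.dropna()
    out = fc.copy()
    for sid in fc.index:
        nbrs = [n for n in neighbor_graph.get(sid, ()) if n in fc.index]
        if nbrs:
            out.loc[sid] = (1.0 - lam) * fc.loc[sid] + lam * fc.loc[nbrs].mean()
    return out


def smoothed_ksea(
    site_fc: pd.Series,
    ks: pd.DataFrame,
    neighbor_graph: dict[str, list[str]] | None = None,
    lam: float = 0.5,
    min_substrates: int = 3,
) -> pd.DataFrame:
    if neighbor_graph is None:
        neighbor_graph = build_substrate_graph(ks)
    out = ksea_z(smooth_fc(site_fc, neighbor_graph, lam), ks, min_substrates)
    out["scheme"] = "smoothed"
    return out


@dataclass
class ConsensusResult:
    k: int
    alpha: float
    topk: dict[str, list[str]]
    intersection: set[str]
    ranks: pd.DataFrame  # kinase × scheme rank (NaN when outside a top-k list)


def _rank_scheme(scores: pd.DataFrame, alpha: float) -> list[str]:
    df = scores[scores["p"] < alpha].copy()
    if "z" in df.columns and df["z"].notna().any():
        df["_key"] = -df["z"].abs()
    else:
        df["_key"] = df["p"]
    df = df.sort_values(["_key", "p", "kinase_id"], kind="mergesort")
    return list(df.index)


def consensus_topk(
    scores: dict[str, pd.DataFrame], k: int = 10, alpha: float = 0.05
) -> ConsensusResult:
    """Intersection of the per-scheme significant top-k kinase lists.

    Within a scheme, kinases with p < ``alpha`` are ranked by |z| (z-schemes)
    or ascending p (overrepresentation); ties break by smaller p, then
    lexicographic kinase_id.
    """
    topk: dict[str, list[str]] = {}
    for scheme, df in scores.items():
        df = df.reset_index().set_index("kinase_id", drop=False)
        df.index.name = None
        topk[scheme] = _rank_scheme(df, alpha)[:k]
    sets = [set(v) for v in topk.values()]
    inter = set.intersection(*sets) if sets else set()
    all_kin = sorted(set.union(*sets)) if sets else []
    ranks = pd.DataFrame(index=all_kin, columns=sorted(topk), dtype=float)
    for scheme, lst in topk.items():
        for r, kid in enumerate(lst, start=1):
            ranks.loc[kid, scheme] = r
    logger.info("consensus: top-%d intersection of %s has %d kinase(s): %s",
                k, sorted(topk), len(inter), sorted(inter))
    return ConsensusResult(k=k, alpha=alpha, topk=topk, intersection=inter, ranks=ranks)


def substrate_links(
    sig: SignatureSet,
    site_fc: pd.Series,
    ks: pd.DataFrame,
    top_n: int = 10,
    site_p: pd.Series | None = None,
) -> pd.DataFrame:
    """Signature substrate sites ranked by |log2fc|, linked to their kinases.

    ``sig`` may hold site ids or protein ids (the protein-level signature);
    a substrate site qualifies when either its site_id or its protein is in
    the signature. Ties break by smaller p (when given), then site_id.
    """
    cand = ks[
        ks["site_id"].isin(site_fc.dropna().index)
        & (ks["site_id"].isin(sig.feature_ids)
           | ks["substrate_protein_id"].isin(sig.feature_ids))
    ]
    if cand.empty:
        logger.warning("substrate_links: no quantified signature substrates")
        return pd.DataFrame(columns=["site_id", "kinase_id", "log2fc", "rank"])
    sites = (
        pd.DataFrame({"site_id": cand["site_id"].unique()})
        .assign(
            log2fc=lambda d: site_fc.loc[d["site_id"]].to_numpy(),
            p=lambda d: (site_p.reindex(d["site_id"]).to_numpy()
                         if site_p is not None else np.nan),
        )
    )
    sites["_p"] = pd.Series(sites["p"]).fillna(np.inf)
    sites = sites.sort_values(
        by=["log2fc", "_p", "site_id"],
        key=lambda s: -s.abs() if s.name == "log2fc" else s,
        kind="mergesort",
    ).head(top_n)
    sites["rank"] = np.arange(1, len(sites) + 1)
    out = cand.merge(sites[["site_id", "log2fc", "rank"]], on="site_id")
    return out[["site_id", "kinase_id", "log2fc", "rank"]].sort_values(
        ["rank", "kinase_id"]).reset_index(drop=True)


class _ScorerBase(BaseEstimator):
    def __init__(self, min_substrates: int = 3):
        self.min_substrates = min_substrates


class KseaScorer(_ScorerBase):
    """Estimator form of :func:`ksea_z`; ``fit(site_fc, ks)`` sets ``scores_``."""

    def fit(self, site_fc: pd.Series, ks: pd.DataFrame):
        self.scores_ = ksea_z(site_fc, ks, self.min_substrates)
        return self


class OverrepresentationScorer(_ScorerBase):
    """Estimator form of :func:`overrep_exact`."""

    def fit(self, regulated: set[str], ks: pd.DataFrame, universe: set[str] = None):
        if universe is None:
            raise ValidationError("OverrepresentationScorer.fit requires a universe")
        self.scores_ = overrep_exact(regulated, ks, universe, self.min_substrates)
        return self


class SmoothedKseaScorer(_ScorerBase):
    """Estimator form of :func:`smoothed_ksea`."""

    def __init__(self, min_substrates: int = 3, lam: float = 0.5):
        super().__init__(min_substrates)
        self.lam = lam

    def fit(self, site_fc: pd.Series, ks: pd.DataFrame,
            neighbor_graph: dict[str, list[str]] | None = None):
        self.scores_ = smoothed_ksea(site_fc, ks, neighbor_graph, self.lam,
                                     self.min_substrates)
        return self
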