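"""Cohort summary tables and exact contingency tests for clinical covariates.

Categorical covariates are compared with exact tests under the
point-probability two-sided rule: the p-value is the total probability, over
all tables with the observed margins, of tables whose point (multivariate
hypergeometric) probability does not exceed that of the observed table. For
2×2 tables this is Fisher's exact test as scipy implements it; the r×c
generalization (Freeman–Halton) is computed here by full enumeration.
Continuous covariates default to a two-sided Welch t, with Mann-Whitney as
an alternative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .differential import welch_t
from .errors import PhosigError, ValidationError
from .io import sample_groups

logger = logging.getLogger(__name__)

CONTINUOUS_COVARIATES = ["age", "wbc", "n_count", "hgb", "plt", "bm_blasts"]
CATEGORICAL_COVARIATES = ["sex", "karyotype_risk", "eln_risk"]


def _check_table(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValidationError("contingency table must be at least 2×2")
    if (t < 0).any():
        raise ValidationError("contingency table has negative counts")
    if not np.allclose(t, np.round(t)):
        raise ValidationError("contingency table must hold integer counts")
    return t.astype(np.int64)


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p for a 2×2 table (point-probability rule)."""
    t = _check_table(table)
    if t.shape != (2, 2):
        return exact_rxc(t)
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def _log_table_prob(t: np.ndarray, log_row_fact: float, log_col_fact: float,
                    log_n_fact: float) -> float:
    return log_row_fact + log_col_fact - log_n_fact - gammaln(t + 1).sum()


def exact_rxc(table, guard_total: int = 60) -> float:
    """Freeman–Halton exact test by full enumeration of fixed-margin tables."""
    t = _check_table(table)
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    n = int(t.sum())
    if n == 0:
        return 1.0
    if n > guard_total:
        raise PhosigError(
            f"total count {n} exceeds the enumeration guard ({guard_total}); "
            "a Monte Carlo fallback is not implemented"
        )
    lrf = gammaln(row + 1).sum()
    lcf = gammaln(col + 1).sum()
    lnf = gammaln(n + 1)
    logp_obs = _log_table_prob(t, lrf, lcf, lnf)
    # relative tolerance mirrors the usual practice for float-safe inclusion
    cutoff = logp_obs + 1e-7

    r, c = t.shape
    total = 0.0

    def fill(cells: list[int], row_i: int, col_rem: np.ndarray) -> None:
        nonlocal total
        if row_i == r - 1:
            last = col_rem
            full = np.array(cells + list(last)).reshape(r, c)
            lp = _log_table_prob(full, lrf, lcf, lnf)
            if lp <= cutoff:
                total += np.exp(lp)
            return
        # enumerate compositions of row[row_i] into c parts bounded by col_rem
        def comp(j: int, remaining: int, acc: list[int]) -> None:
            if j == c - 1:
                if remaining <= col_rem[j]:
                    new_rem = col_rem - np.array(acc + [remaining])
                    fill(cells + acc + [remaining], row_i + 1, new_rem)
                return
            for v in range(min(remaining, col_rem[j]) + 1):
                comp(j + 1, remaining - v, acc + [v])

        comp(0, int(row[row_i]), [])

    fill([], 0, col.copy())
    return float(min(total, 1.0))


def continuous_compare(a, b, method: str = "welch") -> float:
    """Two-sided p comparing two continuous samples."""
    if method == "welch":
        return welch_t(a, b)[1]
    if method == "mannwhitney":
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        return float(stats.mannwhitneyu(a[np.isfinite(a)], b[np.isfinite(b)],
                                        alternative="two-sided").pvalue)
    raise ValidationError(f"unknown method {method!r}")


def cr_percentage(n_cr: int, n_total: int) -> float:
    """CR rate as a percentage, e.g. 65/72 → 90.3."""
    if n_total <= 0 or n_cr < 0 or n_cr > n_total:
        raise ValidationError("need 0 <= n_cr <= n_total with n_total > 0")
    return 100.0 * n_cr / n_total


@dataclass
class CohortSummary:
    table: pd.DataFrame  # covariate rows × (per-group summaries, p1, p2)


def _fmt_cont(x: pd.Series) -> str:
    x = x.dropna()
    if x.empty:
        return "NA"
    return f"{x.mean():.2f} ({x.min():g}–{x.max():g})"


def summarize_cohort(sheet: pd.DataFrame, method: str = "welch") -> CohortSummary:
    """Per-group cohort summary with exact P1 (DA-CR vs DA-NR) and P2
    (DAV-CR vs DAV-NR) columns."""
    groups = sample_groups(sheet)
    pat = sheet[~sheet["is_reference"]].set_index("sample_id")
    present = [g for g in ["DA-CR", "DA-NR", "DAV-CR", "DAV-NR"] if (groups == g).any()]
    pairs = {"p1": ("DA-CR", "DA-NR"), "p2": ("DAV-CR", "DAV-NR")}
    rows = {}
    rows["n"] = {g: str(int((groups == g).sum())) for g in present}

    def pair_ok(pair):
        return pair[0] in present and pair[1] in present

    if not all(pair_ok(p) for p in pairs.values()):
        logger.warning("cohort summary: some comparison groups are absent; "
                       "their p columns stay empty")
    for cov in CONTINUOUS_COVARIATES:
        if cov not in pat.columns or pat[cov].dropna().empty:
            continue
        row = {g: _fmt_cont(pat.loc[groups[groups == g].index, cov]) for g in present}
        for pname, pair in pairs.items():
            if pair_ok(pair):
                a = pat.loc[groups[groups == pair[0]].index, cov].dropna()
                b = pat.loc[groups[groups == pair[1]].index, cov].dropna()
                if len(a) >= 2 and len(b) >= 2:
                    row[pname] = f"{continuous_compare(a, b, method):.3f}"
        rows[cov] = row
    for cov in CATEGORICAL_COVARIATES:
        if cov not in pat.columns or pat[cov].dropna().empty:
            continue
        levels = sorted(pat[cov].dropna().unique())
        counts = {
            g: pat.loc[groups[groups == g].index, cov].value_counts().reindex(levels).fillna(0)
            for g in present
        }
        row = {g: "/".join(str(int(v)) for v in counts[g]) for g in present}
        pct_row = {
            g: "/".join(f"{100.0 * v / max(counts[g].sum(), 1):.1f}" for v in counts[g])
            for g in present
        }
        for pname, pair in pairs.items():
            if pair_ok(pair):
                tab = np.array([counts[pair[0]].to_numpy(), counts[pair[1]].to_numpy()])
                tab = tab[:, tab.sum(axis=0) > 0]
                if tab.shape[1] >= 2:
                    p = fisher_exact(tab) if tab.shape[1] == 2 else exact_rxc(tab)
                    row[pname] = f"{p:.3f}"
        rows[f"{cov} ({'/'.join(levels)})"] = row
        rows[f"{cov} % ({'/'.join(levels)})"] = pct_row
    table = pd.DataFrame(rows).T.reindex(columns=present + list(pairs))
    return CohortSummary(table=table)
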