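"""Per-feature two-group statistics and asymmetric fold-change/p gates.

The test is a two-sided Welch t on log2 values (unequal group sizes and
variances are the norm in this design). Selection uses the raw p together
with an asymmetric fold-change gate; Benjamini–Hochberg q-values are reported
alongside for transparency but do not enter the gate. Fold change is
``2**(mean difference of log2 values)``, not a ratio of raw means, for
consistency with the log-scale model.

Three named presets cover the gates used for the cohort contrasts:

========  ======  ========  ======
preset    fc_up   fc_down   p_max
========  ======  ========  ======
broad     1.3     0.67      0.05
strict    1.5     0.67      0.05
dav       1.3     0.77      0.05
========  ======  ========  ======

``broad`` is the NR/CR screening gate, ``strict`` the resistance-signature
gate, and ``dav`` the gate used for the venetoclax-arm (DAV-NR vs DAV-CR)
contrast.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, ValidationError
from .io import sample_groups
from .preprocess import NormalizedMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ComparisonSpec:
    """A two-group contrast plus its asymmetric selection gate."""

    test_group: str
    ref_group: str
    fc_up: float = 1.3
    fc_down: float = 0.67
    p_max: float = 0.05

    def __post_init__(self):
        if not (self.fc_up > 1.0 > self.fc_down > 0.0):
            raise ConfigurationError("need fc_up > 1 > fc_down > 0")
        if not 0.0 < self.p_max < 1.0:
            raise ConfigurationError("p_max must lie in (0, 1)")

    @property
    def contrast_id(self) -> str:
        return f"{self.test_group}_vs_{self.ref_group}"


PRESETS: dict[str, dict[str, float]] = {
    "broad": {"fc_up": 1.3, "fc_down": 0.67, "p_max": 0.05},
    "strict": {"fc_up": 1.5, "fc_down": 0.67, "p_max": 0.05},
    "dav": {"fc_up": 1.3, "fc_down": 0.77, "p_max": 0.05},
}


def preset_spec(name: str, test_group: str, ref_group: str) -> ComparisonSpec:
    if name not in PRESETS:
        raise ConfigurationError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return ComparisonSpec(test_group, ref_group, **PRESETS[name])


def welch_t(a, b) -> tuple[float, float]:
    """Two-sided Welch t with Satterthwaite df; (nan, nan) when untestable."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        return (np.nan, np.nan)
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        return (np.nan, np.nan)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return (float(t), float(p))


def bh_adjust(p) -> np.ndarray:
    """Step-up Benjamini–Hochberg q-values; NaN entries stay NaN."""
    p = np.asarray(p, dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def _welch_rows(x_test: np.ndarray, x_ref: np.ndarray):
    """Row-wise Welch t over 2D arrays with NaN as missing."""
    import warnings

    n1 = np.sum(np.isfinite(x_test), axis=1)
    n2 = np.sum(np.isfinite(x_ref), axis=1)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        m1 = np.nanmean(np.where(np.isfinite(x_test), x_test, np.nan), axis=1)
        m2 = np.nanmean(np.where(np.isfinite(x_ref), x_ref, np.nan), axis=1)
        v1 = np.nanvar(x_test, axis=1, ddof=1)
        v2 = np.nanvar(x_ref, axis=1, ddof=1)
        se2 = v1 / n1 + v2 / n2
        t = (m1 - m2) / np.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    untestable = (n1 < 2) | (n2 < 2) | ((v1 == 0) & (v2 == 0)) | ~np.isfinite(t)
    t = np.where(untestable, np.nan, t)
    p = np.where(untestable, np.nan, p)
    return m1 - m2, t, p, n1, n2


class DifferentialAnalyzer(BaseEstimator):
    """Per-feature Welch t under one :class:`ComparisonSpec`.

    ``fit(X, groups)`` takes a features × samples log2 DataFrame and a Series
    mapping sample_id to group label; fitted results live in ``results_``.
    """

    def __init__(self, spec: ComparisonSpec):
        self.spec = spec

    def fit(self, X: pd.DataFrame, groups: pd.Series):
        spec = self.spec
        cols_test = [c for c in X.columns if groups.get(c) == spec.test_group]
        cols_ref = [c for c in X.columns if groups.get(c) == spec.ref_group]
        for label, cols in ((spec.test_group, cols_test), (spec.ref_group, cols_ref)):
            if not cols:
                raise ValidationError(f"group {label!r} has no samples in the matrix")
        log2fc, t, p, n1, n2 = _welch_rows(
            X[cols_test].to_numpy(dtype=float), X[cols_ref].to_numpy(dtype=float)
        )
        fc = np.exp2(log2fc)
        q = bh_adjust(p)
        status = np.where(
            (fc > spec.fc_up) & (p < spec.p_max), "up",
            np.where((fc < spec.fc_down) & (p < spec.p_max), "down", "ns"),
        )
        status = np.where(np.isfinite(p), status, "ns")
        self.results_ = pd.DataFrame(
            {
                "log2fc": log2fc,
                "fold_change": fc,
                "t": t,
                "p": p,
                "q": q,
                "status": status,
                "n_test": n1,
                "n_ref": n2,
            },
            index=X.index.rename("feature_id"),
        )
        self.n_up_ = int((status == "up").sum())
        self.n_down_ = int((status == "down").sum())
        logger.info(
            "%s: %d up, %d down of %d features (gate fc>%g or <%g, p<%g)",
            spec.contrast_id, self.n_up_, self.n_down_, len(X),
            spec.fc_up, spec.fc_down, spec.p_max,
        )
        return self


def differential_table(
    m: NormalizedMatrix | pd.DataFrame,
    sheet: pd.DataFrame,
    spec: ComparisonSpec,
) -> pd.DataFrame:
    """One row per feature: log2fc, fold_change, p, q, status, n_test, n_ref."""
    X = m.data if isinstance(m, NormalizedMatrix) else m
    return DifferentialAnalyzer(spec).fit(X, sample_groups(sheet)).results_


def swap_spec(spec: ComparisonSpec) -> ComparisonSpec:
    return replace(spec, test_group=spec.ref_group, ref_group=spec.test_group)


def abundance_shift(
    diff: pd.DataFrame, m: NormalizedMatrix | pd.DataFrame
) -> tuple[float, str]:
    """KS statistic between mean abundances of differential vs all features.

    Returns the two-sample Kolmogorov–Smirnov statistic together with the sign
    of the median difference: ``"right"`` when differential features sit at
    higher abundance than the full feature set.
    """
    X = m.data if isinstance(m, NormalizedMatrix) else m
    means_all = X.mean(axis=1, skipna=True)
    sel = diff.index[diff["status"] != "ns"]
    means_sel = means_all.loc[sel]
    if len(means_sel) == 0:
        logger.warning("abundance_shift: empty differential set")
        return (0.0, "none")
    stat = float(stats.ks_2samp(means_sel, means_all).statistic)
    med_diff = float(means_sel.median() - means_all.median())
    direction = "right" if med_diff > 0 else ("left" if med_diff < 0 else "none")
    return (stat, direction)
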