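"""Set-subtraction derivation of the "DA-resistant but DAV-sensitive" signature.

Features differential in the DA-resistance contrast (A: DA-NR vs DA-CR) that
are *not* differential in the cross-regimen contrast (B: DA-NR vs DAV-CR)
form the sensitivity signature: their dysregulation marks DA failure, yet
DAV-responders look like DA-non-responders on them, so they flag patients for
whom adding venetoclax plausibly restores sensitivity. "Not differential" is
operationalized strictly as status == ns in comparison B.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import sample_groups
from .preprocess import NormalizedMatrix

logger = logging.getLogger(__name__)

SIGNATURE_GROUPS = ("DA-CR", "DA-NR", "DAV-CR")


@dataclass
class SignatureSet:
    feature_ids: set[str]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.feature_ids)


def derive_sensitivity_signature(
    diff_a: pd.DataFrame, diff_b: pd.DataFrame
) -> SignatureSet:
    """Signature = {differential in A} minus {differential in B}.

    Both result tables must cover the same feature universe; a mismatch is an
    error rather than a silent intersection.
    """
    ua, ub = set(diff_a.index), set(diff_b.index)
    if ua != ub:
        raise ValidationError(
            f"feature universes differ between the two comparisons "
            f"(symmetric difference of {len(ua ^ ub)} features)"
        )
    set_a = set(diff_a.index[diff_a["status"] != "ns"])
    set_b = set(diff_b.index[diff_b["status"] != "ns"])
    sig = set_a - set_b
    if not sig:
        logger.warning("signature is empty: comparison B covers every A-differential feature")
    prov = {
        "n_universe": len(ua),
        "n_differential_a": len(set_a),
        "n_overlap": len(set_a & set_b),
        "n_signature": len(sig),
    }
    logger.info(
        "signature: |A|=%d, |A∩B|=%d, |signature|=%d",
        prov["n_differential_a"], prov["n_overlap"], prov["n_signature"],
    )
    return SignatureSet(feature_ids=sig, provenance=prov)


def signature_profile_matrix(
    sig: SignatureSet,
    m: NormalizedMatrix | pd.DataFrame,
    sheet: pd.DataFrame,
    groups: tuple[str, ...] = SIGNATURE_GROUPS,
) -> pd.DataFrame:
    """Row-z-scored expression of signature features over the included groups.

    The excluded group (by default DAV-NR) is absent from the columns; rows
    are standardized across the included samples (population sd; constant
    rows become all-zero).
    """
    X = m.data if isinstance(m, NormalizedMatrix) else m
    gl = sample_groups(sheet)
    cols = [c for c in X.columns if gl.get(c) in groups]
    feats = sorted(sig.feature_ids & set(X.index))
    if not feats:
        logger.warning("signature profile: no signature features present in the matrix")
        return pd.DataFrame(columns=cols)
    sub = X.loc[feats, cols]
    mu = sub.mean(axis=1, skipna=True)
    sd = sub.std(axis=1, ddof=0, skipna=True)
    z = sub.sub(mu, axis=0).div(sd.replace(0.0, np.nan), axis=0)
    const = sd == 0.0
    if const.any():  # constant rows standardize to 0 where observed, stay NaN where missing
        z.loc[const] = sub.loc[const].where(sub.loc[const].isna(), 0.0)
    return z
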