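"""Iterative position-residue motif discovery on 13-mer phospho-windows.

Greedy motif-x style search: at each step every not-yet-fixed
(offset, residue) pair is scored by the binomial tail
``P(X >= k_fg | n_fg, p_bg)`` where ``p_bg`` is the background frequency of
that residue at that offset among background windows matching the fixes so
far. The minimum-p pair is fixed when ``p < p_fix`` and its foreground support
is at least ``min_occ``; the search recurses on the matching windows and emits
a motif when no pair qualifies. Matched windows are then removed from the
foreground and the search restarts, so every emitted motif strictly shrinks
the foreground and termination is guaranteed. The procedure is deterministic:
ties break by smaller p, then offset, then residue.

Terminal padding (``_``) never matches any residue, so truncated windows do
not inflate edge positions. Serine- and threonine-centred windows are analysed
separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binom
from sklearn.base import BaseEstimator

from .errors import ValidationError

logger = logging.getLogger(__name__)

OFFSETS = [o for o in range(-6, 7) if o != 0]


def render_motif(fixed: dict[int, str], center: str) -> str:
    """13-character rendering with ``x`` at unfixed positions, e.g. ``xxxxxxSDxExxx``."""
    chars = ["x"] * 13
    chars[6] = center
    for off, res in fixed.items():
        chars[6 + off] = res
    return "".join(chars)


@dataclass
class MotifResult:
    fixed: dict[int, str]
    center: str
    fg_matches: int
    fg_total: int
    bg_rate: float
    binom_p: float
    fold: float
    steps: list[tuple[int, str, float]] = field(default_factory=list)

    @property
    def motif(self) -> str:
        return render_motif(self.fixed, self.center)


def _window_matrix(windows: list[str], center: str, name: str) -> np.ndarray:
    if len(windows) == 0:
        return np.empty((0, 13), dtype="U1")
    arr = np.array([list(w) for w in windows], dtype="U1")
    if arr.shape[1] != 13:
        bad = [w for w in windows if len(w) != 13]
        raise ValidationError(f"{name}: windows must be 13-mers; offending: {bad[:5]}")
    keep = arr[:, 6] == center
    if not keep.all():
        logger.debug("%s: dropping %d windows not centred on %s", name, int((~keep).sum()), center)
    return arr[keep]


def motifx_search(
    foreground: list[str],
    background: list[str],
    center: str = "S",
    p_fix: float = 1e-6,
    min_occ: int = 20,
) -> list[MotifResult]:
    """Run the iterative search and return motifs in order of extraction."""
    fg = _window_matrix(foreground, center, "foreground")
    bg = _window_matrix(background, center, "background")
    if len(fg) == 0:
        return []
    if len(bg) < len(fg):
        logger.warning(
            "background (%d) smaller than foreground (%d); rates will be noisy",
            len(bg), len(fg),
        )
    results: list[MotifResult] = []
    while len(fg) > 0:
        fixed, steps = {}, []
        cur_fg, cur_bg = fg, bg
        while True:
            best = None  # (p, offset, residue, k)
            n_fg, n_bg = len(cur_fg), len(cur_bg)
            if n_fg < min_occ or n_bg == 0:
                break
            for off in OFFSETS:
                if off in fixed:
                    continue
                col_fg = cur_fg[:, 6 + off]
                col_bg = cur_bg[:, 6 + off]
                res_fg, cnt_fg = np.unique(col_fg, return_counts=True)
                for res, k in zip(res_fg, cnt_fg):
                    if res == "_" or k < min_occ:
                        continue
                    k_bg = int((col_bg == res).sum())
                    # pseudo-count keeps an absent background residue finite
                    p_bg = max(k_bg, 0.5) / n_bg
                    p = float(binom.sf(k - 1, n_fg, min(p_bg, 1.0)))
                    cand = (p, off, str(res), int(k))
                    if best is None or cand[:3] < best[:3]:
                        best = cand
            if best is None or best[0] >= p_fix:
                break
            p, off, res, _k = best
            fixed[off] = res
            steps.append((off, res, p))
            cur_fg = cur_fg[cur_fg[:, 6 + off] == res]
            cur_bg = cur_bg[cur_bg[:, 6 + off] == res]
        if not fixed:
            break
        match_fg = np.ones(len(fg), dtype=bool)
        match_bg = np.ones(len(bg), dtype=bool)
        for off, res in fixed.items():
            match_fg &= fg[:, 6 + off] == res
            match_bg &= bg[:, 6 + off] == res
        fg_matches = int(match_fg.sum())
        bg_rate = float(match_bg.mean()) if len(bg) else 0.0
        fg_rate = fg_matches / len(fg)
        results.append(
            MotifResult(
                fixed=dict(sorted(fixed.items())),
                center=center,
                fg_matches=fg_matches,
                fg_total=int(len(fg)),
                bg_rate=bg_rate,
                binom_p=float(binom.sf(fg_matches - 1, len(fg), max(bg_rate, 1e-300))),
                fold=fg_rate / bg_rate if bg_rate > 0 else np.inf,
                steps=steps,
            )
        )
        fg = fg[~match_fg]
    return results


class MotifSearcher(BaseEstimator):
    """Estimator wrapper around :func:`motifx_search`.

    Parameters
    ----------
    center : {'S', 'T', 'Y'}
        Central phospho-acceptor of the windows analysed.
    p_fix : float
        Binomial-tail significance each fixed position must beat.
    min_occ : int
        Minimum foreground support for a fixed position.
    """

    def __init__(self, center: str = "S", p_fix: float = 1e-6, min_occ: int = 20):
        self.center = center
        self.p_fix = p_fix
        self.min_occ = min_occ

    def fit(self, foreground: list[str], background: list[str] | None = None):
        if background is None:
            raise ValidationError("MotifSearcher.fit requires a background window list")
        self.motifs_ = motifx_search(
            list(foreground), list(background), self.center, self.p_fix, self.min_occ
        )
        self.n_foreground_ = len(foreground)
        return self
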