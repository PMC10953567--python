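import numpy as np
import pandas as pd
import pytest

from phosig.io import SiteTable, make_site_id, validate_sample_sheet
from phosig.simulate import SimulationConfig, simulate_cohort

STANDARD_EFFECT = [("K01", "DA-NR_vs_DA-CR", 1.0)]


def make_config(seed: int = 0, **kw) -> SimulationConfig:
    """Study-condition simulation config (10/7/10/6, ~2000 sites, 20×25 map)."""
    kw.setdefault("planted_effects", list(STANDARD_EFFECT))
    return SimulationConfig(seed=seed, **kw)


@pytest.fixture(scope="session")
def standard_cohort():
    return simulate_cohort(make_config(seed=11))


@pytest.fixture(scope="session")
def null_cohort():
    return simulate_cohort(make_config(seed=12, planted_effects=[]))


def tiny_site_table(n_sites=6, n_samples=4, seed=0, with_ref=False) -> SiteTable:
    """Small hand-sized site table for unit tests."""
    rng = np.random.default_rng(seed)
    recs = {}
    meta_rows = []
    for i in range(n_sites):
        pid = f"P{i // 2 + 1:02d}"
        pos = 10 + i
        res = "S" if i % 3 else "T"
        win = "".join(rng.choice(list("ACDEFGHIKLMNPQR"), 6)) + res + "".join(
            rng.choice(list("ACDEFGHIKLMNPQR"), 6))
        meta_rows.append((make_site_id(pid, res, pos), pid, pid, pos, res, win,
                          round(float(rng.uniform(0.5, 1.0)), 3)))
    meta = pd.DataFrame(
        meta_rows,
        columns=["site_id", "protein_id", "gene_symbol", "position", "residue",
                 "window_13", "loc_prob"],
    ).set_index("site_id")
    cols = [f"S{j + 1}" for j in range(n_samples)] + (["ref1"] if with_ref else [])
    inten = pd.DataFrame(
        rng.lognormal(10, 1, size=(n_sites, len(cols))), index=meta.index, columns=cols
    )
    return SiteTable(meta, inten)


def tiny_sheet(n_per_group=(2, 2, 2, 2), plexes=1) -> pd.DataFrame:
    groups = ["DA-CR", "DA-NR", "DAV-CR", "DAV-NR"]
    rows = []
    i = 0
    for g, n in zip(groups, n_per_group):
        reg, resp = g.split("-")
        for _ in range(n):
            i += 1
            px = (i - 1) % plexes + 1
            rows.append((f"S{i}", f"plex{px}", f"ch{i}", False, reg, resp))
    for px in range(1, plexes + 1):
        rows.append((f"ref{px}", f"plex{px}", "ref", True, None, None))
    sheet = pd.DataFrame(rows, columns=["sample_id", "plex_id", "channel_id",
                                        "is_reference", "regimen", "response"])
    return validate_sample_sheet(sheet)
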