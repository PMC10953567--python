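"""Readers and writers for the tab-delimited artifacts every other module consumes.

All tables are UTF-8, tab-delimited, with a header row and ``NA`` for missing
values. Exact column orders are documented in ``FORMATS.md`` at the repository
root. Readers validate and reject rather than silently coerce; every writer
produces files its own reader accepts.

Site identifiers use the canonical form ``PROTEIN_pRESIDUEPOSITION``
(e.g. ``RBMX_pS326``): positions are 1-based on the protein sequence and the
sequence window spans the phospho-acceptor ±6 residues (13 characters,
``_``-padded at protein termini).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

GROUPS = ("DA-CR", "DA-NR", "DAV-CR", "DAV-NR")
REGIMENS = ("DA", "DAV")
RESPONSES = ("CR", "NR")
RESIDUES = ("S", "T", "Y")
WINDOW_LEN = 13
CENTER_IDX = 6  # 0-based index of the phospho-acceptor in a 13-mer

SITE_META_COLUMNS = [
    "site_id",
    "protein_id",
    "gene_symbol",
    "position",
    "residue",
    "window_13",
    "loc_prob",
]

SAMPLE_SHEET_COLUMNS = [
    "sample_id",
    "plex_id",
    "channel_id",
    "is_reference",
    "regimen",
    "response",
]

SAMPLE_SHEET_OPTIONAL = [
    "age",
    "sex",
    "wbc",
    "n_count",
    "hgb",
    "plt",
    "bm_blasts",
    "karyotype_risk",
    "eln_risk",
]

KS_MAP_COLUMNS = ["kinase_id", "substrate_protein_id", "position", "residue"]

NA_REP = "NA"


def make_site_id(protein_id: str, residue: str, position: int) -> str:
    """Canonical site identifier, e.g. ``RBMX_pS326``."""
    return f"{protein_id}_p{residue}{position}"


@dataclass
class SiteTable:
    """Phospho-site metadata plus a site × sample raw-intensity matrix.

    ``meta`` is indexed by ``site_id`` and carries the columns of
    :data:`SITE_META_COLUMNS` (minus ``site_id``); ``intensities`` shares the
    index and has one column per sample (reference channels included).
    Intensities are raw (linear-scale) nonnegative reals; NaN marks missing.
    """

    meta: pd.DataFrame
    intensities: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    @property
    def site_ids(self) -> pd.Index:
        return self.meta.index

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.columns)

    def validate(self) -> None:
        meta = self.meta
        if meta.index.has_duplicates:
            dups = meta.index[meta.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate site_id(s): {dups[:10]}")
        if not meta.index.equals(self.intensities.index):
            raise ValidationError("meta and intensity matrix index mismatch")
        bad = []
        for sid, (res, win) in meta[["residue", "window_13"]].iterrows():
            if len(win) != WINDOW_LEN or win[CENTER_IDX] != res:
                bad.append(sid)
        if bad:
            raise ValidationError(
                f"malformed sequence window (length != {WINDOW_LEN} or center != "
                f"residue) for site_id(s): {bad[:10]}"
            )
        if (meta["position"] < 1).any():
            bad = meta.index[meta["position"] < 1].tolist()
            raise ValidationError(f"position < 1 for site_id(s): {bad[:10]}")
        unknown = set(meta["residue"]) - set(RESIDUES)
        if unknown:
            raise ValidationError(f"residues outside {RESIDUES}: {sorted(unknown)}")
        vals = self.intensities.to_numpy(dtype=float)
        if np.nanmin(vals, initial=np.inf) < 0:
            raise ValidationError("negative raw intensities")

    def subset(self, site_ids) -> "SiteTable":
        return SiteTable(self.meta.loc[site_ids], self.intensities.loc[site_ids])


def read_site_table(path: str | Path) -> SiteTable:
    df = pd.read_csv(path, sep="\t", na_values=[NA_REP], keep_default_na=False)
    missing = [c for c in SITE_META_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"site table missing columns: {missing}")
    meta = df[SITE_META_COLUMNS].set_index("site_id")
    meta["position"] = meta["position"].astype(int)
    sample_cols = [c for c in df.columns if c not in SITE_META_COLUMNS]
    inten = df[sample_cols].astype(float)
    inten.index = meta.index
    return SiteTable(meta, inten)


def write_site_table(table: SiteTable, path: str | Path) -> None:
    out = pd.concat([table.meta, table.intensities], axis=1)
    out.index.name = "site_id"
    out.to_csv(path, sep="\t", na_rep=NA_REP)


def _group_label(regimen: str, response: str) -> str:
    return f"{regimen}-{response}"


def sample_groups(sheet: pd.DataFrame) -> pd.Series:
    """Regimen×response group label per non-reference sample, indexed by sample_id."""
    pat = sheet[~sheet["is_reference"]]
    return pd.Series(
        [_group_label(r, s) for r, s in zip(pat["regimen"], pat["response"])],
        index=pat["sample_id"].to_numpy(),
        name="group",
    )


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise ValidationError(f"sample sheet missing columns: {missing}")
    sheet = sheet.copy()
    sheet["is_reference"] = sheet["is_reference"].astype(bool)
    if sheet["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample_id in sample sheet")
    key = sheet[["plex_id", "channel_id"]].apply(tuple, axis=1)
    if key.duplicated().any():
        raise ValidationError("duplicate (plex_id, channel_id) assignment")
    pat = sheet[~sheet["is_reference"]]
    bad_reg = set(pat["regimen"]) - set(REGIMENS)
    if bad_reg:
        raise ValidationError(f"unknown regimen value(s): {sorted(bad_reg)}")
    bad_resp = set(pat["response"]) - set(RESPONSES)
    if bad_resp:
        raise ValidationError(f"unknown response value(s): {sorted(bad_resp)}")
    ref_per_plex = sheet.groupby("plex_id")["is_reference"].sum()
    bad_plex = ref_per_plex[ref_per_plex != 1]
    if len(bad_plex):
        raise ValidationError(
            f"each plex needs exactly one reference channel; violated by plex(es) "
            f"{bad_plex.index.tolist()}"
        )
    return sheet


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", na_values=[NA_REP], keep_default_na=False)
    return validate_sample_sheet(sheet)


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    out = sheet.copy()
    out["is_reference"] = out["is_reference"].astype(int)
    out.to_csv(path, sep="\t", index=False, na_rep=NA_REP)


def validate_ks_map(ks: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in KS_MAP_COLUMNS if c not in ks.columns]
    if missing:
        raise ValidationError(f"kinase-substrate map missing columns: {missing}")
    ks = ks.copy()
    ks["position"] = ks["position"].astype(int)
    unknown = set(ks["residue"]) - set(RESIDUES)
    if unknown:
        raise ValidationError(f"residues outside {RESIDUES}: {sorted(unknown)}")
    key = ks[["kinase_id", "substrate_protein_id", "position"]]
    dup = key.duplicated()
    if dup.any():
        logger.warning(
            "kinase-substrate map: dropping %d duplicate (kinase, protein, position) "
            "triple(s)",
            int(dup.sum()),
        )
        ks = ks[~dup].reset_index(drop=True)
    ks["site_id"] = [
        make_site_id(p, r, n)
        for p, r, n in zip(ks["substrate_protein_id"], ks["residue"], ks["position"])
    ]
    return ks


def read_ks_map(path: str | Path) -> pd.DataFrame:
    ks = pd.read_csv(path, sep="\t", na_values=[NA_REP], keep_default_na=False)
    return validate_ks_map(ks)


def write_ks_map(ks: pd.DataFrame, path: str | Path) -> None:
    ks[KS_MAP_COLUMNS].to_csv(path, sep="\t", index=False, na_rep=NA_REP)


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class ResultBundle:
    """Named tables/objects destined for one output directory."""

    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    objects: dict[str, dict] = field(default_factory=dict)


def write_results(bundle: ResultBundle, out_dir: str | Path) -> dict[str, str]:
    """Write every artifact in ``bundle`` and return a file→sha256 manifest.

    Tables become ``<name>.tsv`` (header always present), mappings become
    ``<name>.json``; the manifest itself is saved as ``manifest.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    for name in sorted(bundle.tables):
        p = out / f"{name}.tsv"
        bundle.tables[name].to_csv(p, sep="\t", na_rep=NA_REP)
        manifest[p.name] = file_sha256(p)
    for name in sorted(bundle.objects):
        p = out / f"{name}.json"
        p.write_text(json.dumps(bundle.objects[name], indent=2, sort_keys=True, default=str))
        manifest[p.name] = file_sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
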