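"""Synthetic TMT phospho-cohort generator with planted ground truth.

Emulates a four-group AML induction cohort (DA-CR / DA-NR / DAV-CR / DAV-NR)
quantified by multi-plex TMT with one pooled internal-reference channel per
plex. Intensities are simulated additively on the log2 scale::

    log2 I = protein baseline + site offset + plex batch + group effect + noise

and exponentiated for the raw table. Group effects are planted on the
substrate sites of chosen kinases, one contrast at a time, so that kinase-
activity recovery can be scored against known truth. Missingness is MNAR:
probabilistic left-censoring, logistic in the cell's log2 intensity, with the
threshold calibrated so the expected missing fraction matches the request.

The generator does not simulate spectra, peptide-spectrum matching, or TMT
reporter-ion interference.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io import (
    GROUPS,
    SiteTable,
    make_site_id,
    validate_ks_map,
    validate_sample_sheet,
    write_ks_map,
    write_sample_sheet,
    write_site_table,
)
from .motifs import render_motif

# Residue usage of a typical phosphoproteome (serine-dominated), and amino-acid
# background frequencies (approximately human proteome-wide) used to draw the
# non-central window positions.
CENTER_FREQS = {"S": 0.84, "T": 0.14, "Y": 0.02}
AA = list("ACDEFGHIKLMNPQRSTVWY")
AA_FREQS = np.array(
    [0.070, 0.023, 0.047, 0.071, 0.036, 0.066, 0.026, 0.043, 0.057, 0.100,
     0.021, 0.036, 0.063, 0.048, 0.056, 0.083, 0.053, 0.060, 0.012, 0.027]
)
AA_FREQS = AA_FREQS / AA_FREQS.sum()

DEFAULT_GROUP_SIZES = {"DA-CR": 10, "DA-NR": 7, "DAV-CR": 10, "DAV-NR": 6}


def contrast_id(test_group: str, ref_group: str) -> str:
    return f"{test_group}_vs_{ref_group}"


def parse_contrast(cid: str) -> tuple[str, str]:
    test, ref = cid.split("_vs_")
    return test, ref


@dataclass
class SimulationConfig:
    """Parameters of one synthetic cohort.

    Defaults are the study conditions: group sizes 10/7/10/6, ~2000 sites
    (800 proteins × Poisson(2.5) sites), 20 kinases × 25 substrates, per-sample
    log2 noise 0.5, 10% MNAR missingness, three TMT plexes.
    """

    group_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    n_proteins: int = 800
    sites_per_protein_mean: float = 2.5
    n_kinases: int = 20
    substrates_per_kinase: int = 25
    planted_effects: list[tuple[str, str, float]] = field(default_factory=list)
    base_log2_mean: float = 20.0
    base_log2_sd: float = 2.0
    site_sd: float = 1.0
    noise_sd: float = 0.5
    missing_fraction: float = 0.1
    motif_plant: tuple[str, dict[int, str], float] | None = None
    n_plexes: int = 3
    batch_sd: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if set(self.group_sizes) != set(GROUPS):
            raise ConfigurationError(
                f"group_sizes must name exactly the groups {GROUPS}"
            )
        for g, n in self.group_sizes.items():
            if n < 2:
                raise ConfigurationError(f"group_sizes[{g}] = {n}; need >= 2")
        if self.n_proteins < 1:
            raise ConfigurationError("n_proteins must be positive")
        if self.sites_per_protein_mean <= 0:
            raise ConfigurationError("sites_per_protein_mean must be positive")
        if not 0.0 <= self.missing_fraction <= 1.0:
            raise ConfigurationError("missing_fraction must lie in [0, 1]")
        if self.noise_sd < 0 or self.base_log2_sd <= 0 or self.batch_sd < 0:
            raise ConfigurationError("noise_sd/base_log2_sd/batch_sd out of range")
        kin_ids = {f"K{i + 1:02d}" for i in range(self.n_kinases)}
        for kid, cid, _ in self.planted_effects:
            if kid not in kin_ids:
                raise ConfigurationError(f"planted_effects: unknown kinase_id {kid!r}")
            test, ref = parse_contrast(cid)
            if test not in GROUPS or ref not in GROUPS:
                raise ConfigurationError(f"planted_effects: unknown contrast {cid!r}")
        if self.motif_plant is not None:
            kid, spec, pen = self.motif_plant
            if kid not in kin_ids:
                raise ConfigurationError(f"motif_plant: unknown kinase_id {kid!r}")
            if not 0.0 <= pen <= 1.0:
                raise ConfigurationError("motif_plant: penetrance must lie in [0, 1]")
            _check_motif_offsets(spec)
        if self.n_plexes < 1:
            raise ConfigurationError("n_plexes must be positive")


@dataclass
class GroundTruth:
    """What was planted: the answer key for recovery tests."""

    true_active_kinases: list[tuple[str, str, float]]
    true_differential_sites: dict[str, dict[str, str]]  # contrast -> site -> up/down
    planted_motif: str | None
    censoring_threshold: float | None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        d["true_active_kinases"] = [tuple(t) for t in d["true_active_kinases"]]
        return cls(**d)


def _check_motif_offsets(spec: dict[int, str]) -> None:
    for off in spec:
        if off == 0:
            raise ConfigurationError(
                "motif offset 0 is reserved for the central phospho-acceptor"
            )
        if not -6 <= off <= 6:
            raise ConfigurationError(f"motif offset {off} outside -6..+6")


def plant_motif(
    windows: list[str],
    motif_spec: dict[int, str],
    penetrance: float,
    rng: np.random.Generator | int | None = None,
) -> list[str]:
    """Overwrite fixed offsets in ~``penetrance`` of the windows.

    Offsets are relative to the central phospho-acceptor (index 6) and must lie
    in -6..+6 excluding 0. Terminal padding (``_``) is never overwritten.
    """
    _check_motif_offsets(motif_spec)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    out = []
    hit = rng.random(len(windows)) < penetrance
    for w, h in zip(windows, hit):
        if h:
            chars = list(w)
            for off, res in motif_spec.items():
                if chars[6 + off] != "_":
                    chars[6 + off] = res
            w = "".join(chars)
        out.append(w)
    return out


def _calibrate_censoring(x: np.ndarray, target: float, scale: float) -> float:
    """Threshold t such that E[sigmoid((t - x)/scale)] == target, by bisection."""
    lo, hi = x.min() - 10 * scale, x.max() + 10 * scale

    def frac(t: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp((x - t) / scale))))

    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if frac(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[SiteTable, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate one cohort: site table, sample sheet, kinase map, ground truth.

    Deterministic for a fixed ``config.seed``; one generator instance drives
    every stochastic draw.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    # --- proteins, sites, windows -------------------------------------------
    n_sites_per_prot = np.maximum(
        rng.poisson(config.sites_per_protein_mean, size=config.n_proteins), 1
    )
    protein_ids = [f"P{i + 1:04d}" for i in range(config.n_proteins)]
    prot_col, pos_col = [], []
    for pid, k in zip(protein_ids, n_sites_per_prot):
        # positions drawn away from the termini so windows carry no padding
        positions = np.sort(rng.choice(np.arange(10, 510), size=k, replace=False))
        prot_col.extend([pid] * k)
        pos_col.extend(int(p) for p in positions)
    n_total = len(prot_col)
    residues = rng.choice(list(CENTER_FREQS), size=n_total, p=list(CENTER_FREQS.values()))
    flanks = rng.choice(AA, size=(n_total, 12), p=AA_FREQS)
    windows = [
        "".join(f[:6]) + r + "".join(f[6:]) for f, r in zip(flanks, residues)
    ]
    meta = pd.DataFrame(
        {"protein_id": prot_col, "position": pos_col, "residue": residues,
         "window_13": windows}
    )
    meta["site_id"] = [
        make_site_id(p, r, n)
        for p, r, n in zip(meta["protein_id"], meta["residue"], meta["position"])
    ]
    meta["gene_symbol"] = meta["protein_id"]
    meta["loc_prob"] = np.round(rng.uniform(0.75, 1.0, size=len(meta)), 4)
    meta = meta.set_index("site_id")[
        ["protein_id", "gene_symbol", "position", "residue", "window_13", "loc_prob"]
    ]
    n_sites = len(meta)

    # --- kinase-substrate map (disjoint substrate sets) ----------------------
    need = config.n_kinases * config.substrates_per_kinase
    if need > n_sites:
        raise ConfigurationError(
            f"n_kinases × substrates_per_kinase = {need} exceeds the {n_sites} "
            "generated sites"
        )
    kinase_ids = [f"K{i + 1:02d}" for i in range(config.n_kinases)]
    site_idx = np.arange(n_sites)
    motif_kinase = config.motif_plant[0] if config.motif_plant else None
    assignment: dict[str, np.ndarray] = {}
    taken = np.zeros(n_sites, dtype=bool)
    if motif_kinase is not None:
        # kinases are residue-specific; the motif-bearing kinase gets serine sites
        s_pool = site_idx[(meta["residue"] == "S").to_numpy()]
        chosen = rng.choice(s_pool, size=config.substrates_per_kinase, replace=False)
        assignment[motif_kinase] = chosen
        taken[chosen] = True
    for kid in kinase_ids:
        if kid in assignment:
            continue
        pool = site_idx[~taken]
        chosen = rng.choice(pool, size=config.substrates_per_kinase, replace=False)
        assignment[kid] = chosen
        taken[chosen] = True
    ks = pd.concat(
        [
            pd.DataFrame(
                {
                    "kinase_id": kid,
                    "substrate_protein_id": meta["protein_id"].to_numpy()[ix],
                    "position": meta["position"].to_numpy()[ix],
                    "residue": meta["residue"].to_numpy()[ix],
                }
            )
            for kid, ix in ((k, assignment[k]) for k in kinase_ids)
        ],
        ignore_index=True,
    )
    ks = validate_ks_map(ks)

    # --- motif planting ------------------------------------------------------
    planted_motif = None
    if config.motif_plant is not None:
        kid, spec, pen = config.motif_plant
        ix = assignment[kid]
        wins = meta["window_13"].to_numpy().copy()
        wins[ix] = plant_motif(list(wins[ix]), spec, pen, rng)
        meta["window_13"] = wins
        planted_motif = render_motif(spec, center="S")

    # --- samples and plex layout --------------------------------------------
    sample_ids, groups = [], []
    for g in GROUPS:
        prefix = {"DA-CR": "A", "DA-NR": "B", "DAV-CR": "C", "DAV-NR": "D"}[g]
        for i in range(config.group_sizes[g]):
            sample_ids.append(f"{prefix}{i + 1}")
            groups.append(g)
    n_samp = len(sample_ids)
    plex_of = np.array([i % config.n_plexes for i in range(n_samp)])  # round-robin
    sheet_rows = []
    chan_counter = {px: 0 for px in range(config.n_plexes)}
    for sid, g, px in zip(sample_ids, groups, plex_of):
        chan_counter[px] += 1
        reg, resp = g.split("-")
        sheet_rows.append((sid, f"plex{px + 1}", f"ch{chan_counter[px]}", False, reg, resp))
    ref_ids = []
    for px in range(config.n_plexes):
        rid = f"ref{px + 1}"
        ref_ids.append(rid)
        sheet_rows.append((rid, f"plex{px + 1}", "ref", True, "NA", "NA"))
    sheet = pd.DataFrame(
        sheet_rows,
        columns=["sample_id", "plex_id", "channel_id", "is_reference", "regimen", "response"],
    )
    sheet.loc[sheet["is_reference"], ["regimen", "response"]] = np.nan
    # light clinical covariates so cohort summaries have something to chew on
    pat = ~sheet["is_reference"]
    sheet.loc[pat, "age"] = np.round(rng.uniform(19, 64, size=n_samp), 1)
    sheet.loc[pat, "sex"] = rng.choice(["M", "F"], size=n_samp)
    sheet.loc[pat, "wbc"] = np.round(rng.lognormal(3.2, 1.0, size=n_samp), 2)
    sheet = validate_sample_sheet(sheet)

    # --- log2 intensity model ------------------------------------------------
    prot_base = rng.normal(config.base_log2_mean, config.base_log2_sd, size=config.n_proteins)
    base_of_site = pd.Series(prot_base, index=protein_ids).loc[meta["protein_id"]].to_numpy()
    site_off = rng.normal(0.0, config.site_sd, size=n_sites)
    effect = np.zeros((n_sites, n_samp))
    group_arr = np.array(groups)
    truth_sites: dict[str, dict[str, str]] = {}
    for kid, cid, delta in config.planted_effects:
        test, _ref = parse_contrast(cid)
        rows = assignment[kid]
        cols = np.flatnonzero(group_arr == test)
        effect[np.ix_(rows, cols)] += delta
        d = truth_sites.setdefault(cid, {})
        direction = "up" if delta > 0 else "down"
        for sid in meta.index.to_numpy()[rows]:
            d[sid] = direction
    noise = rng.normal(0.0, config.noise_sd, size=(n_sites, n_samp))
    log2_clean = base_of_site[:, None] + site_off[:, None] + effect + noise

    # reference channel: per-plex pooled average of every sample (raw scale)
    raw_clean = np.exp2(log2_clean)
    ref_raw = raw_clean.mean(axis=1)
    batch = rng.normal(0.0, config.batch_sd, size=config.n_plexes)
    raw = raw_clean * np.exp2(batch[plex_of])[None, :]
    ref_cols = {rid: ref_raw * np.exp2(batch[px]) for px, rid in enumerate(ref_ids)}

    # --- MNAR left-censoring on patient cells --------------------------------
    censor_t = None
    log2_obs = np.log2(raw)
    if config.missing_fraction > 0:
        scale = 0.3 * float(np.std(log2_obs))
        censor_t = _calibrate_censoring(log2_obs.ravel(), config.missing_fraction, scale)
        p_miss = 1.0 / (1.0 + np.exp((log2_obs - censor_t) / scale))
        raw = np.where(rng.random(raw.shape) < p_miss, np.nan, raw)

    inten = pd.DataFrame(raw, index=meta.index, columns=sample_ids)
    for rid, col in ref_cols.items():
        inten[rid] = col
    table = SiteTable(meta, inten)
    truth = GroundTruth(
        true_active_kinases=list(config.planted_effects),
        true_differential_sites=truth_sites,
        planted_motif=planted_motif,
        censoring_threshold=None if censor_t is None else float(censor_t),
    )
    return table, sheet, ks, truth


def write_cohort(
    out_dir: str | Path,
    table: SiteTable,
    sheet: pd.DataFrame,
    ks: pd.DataFrame,
    truth: GroundTruth,
) -> dict[str, str]:
    """Write the four artifacts in the package's standard dialects."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_site_table(table, out / "site_table.tsv")
    write_sample_sheet(sheet, out / "sample_sheet.tsv")
    write_ks_map(ks, out / "kinase_substrate_map.tsv")
    truth.to_json(out / "ground_truth.json")
    return {p: str(out / p) for p in
            ["site_table.tsv", "sample_sheet.tsv", "kinase_substrate_map.tsv", "ground_truth.json"]}
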