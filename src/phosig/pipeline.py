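"""End-to-end orchestration: simulate/load → preprocess → differential →
signature → kinases → motifs → explore → cohort.

One structured config drives everything; all randomness flows from a single
seed. Every stage's outputs land in the output directory with a manifest of
file hashes, so a rerun with the same config yields identical hashes for the
deterministic stages. On stage failure the run aborts naming the stage, and
partial outputs stay behind next to a ``FAILED`` marker.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import differential as diffmod
from . import explore, kinase, motifs, preprocess, signature, simulate
from .cohort import summarize_cohort
from .errors import ConfigurationError, PhosigError
from .io import (
    ResultBundle,
    read_ks_map,
    read_sample_sheet,
    read_site_table,
    sample_groups,
    write_results,
)

logger = logging.getLogger(__name__)

CONTRAST_A = ("DA-NR", "DA-CR")     # DA-resistance contrast
CONTRAST_B = ("DA-NR", "DAV-CR")    # cross-regimen elimination contrast
CONTRAST_DAV = ("DAV-NR", "DAV-CR")  # venetoclax-arm contrast


@dataclass
class PipelineConfig:
    simulate: dict | None = None
    inputs: dict | None = None       # site_table / sample_sheet / ks_map paths
    out_dir: str = "phosig_out"
    seed: int = 0
    loc_prob_min: float = 0.75
    min_per_group: int = 1
    preset_a: str = "strict"
    preset_b: str = "strict"
    preset_dav: str = "dav"
    schemes: tuple[str, ...] = ("zscore", "overrep", "smoothed")
    k: int = 10
    alpha: float = 0.05
    min_substrates: int = 3
    smoothing_lambda: float = 0.5
    motif_p_fix: float = 1e-6
    motif_min_occ: int = 20
    n_clusters: int = 4
    ellipse_level: float = 0.95
    log_level: str = "INFO"

    def validate(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ConfigurationError(
                "exactly one of 'simulate' and 'inputs' must be given"
            )
        for name in (self.preset_a, self.preset_b):
            if name not in diffmod.PRESETS:
                raise ConfigurationError(f"unknown preset {name!r}")
        if self.preset_dav not in diffmod.PRESETS:
            raise ConfigurationError(f"unknown preset {self.preset_dav!r}")
        unknown = set(self.schemes) - {"zscore", "overrep", "smoothed"}
        if unknown:
            raise ConfigurationError(f"unknown scheme(s): {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ConfigurationError(f"unknown config key(s): {sorted(bad)}")
        if "schemes" in raw:
            raw["schemes"] = tuple(raw["schemes"])
        return cls(**raw)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            logger.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except PhosigError:
                raise
            except Exception as e:  # noqa: BLE001 - annotate with the stage name
                raise PhosigError(f"stage {name!r} failed: {e}") from e
        return wrapped
    return deco


def run_all(config: PipelineConfig) -> dict[str, str]:
    """Run every stage; return the file→hash manifest of the output directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    try:
        manifest = _run_all_inner(config, out)
    except Exception as e:
        failed_marker.write_text(str(e))
        raise
    return manifest


def _run_all_inner(config: PipelineConfig, out: Path) -> dict[str, str]:
    bundle = ResultBundle()
    cfg_dump = dataclasses.asdict(config)
    cfg_dump.pop("out_dir", None)  # manifest must not depend on where it lands
    provenance: dict = {"seed": config.seed, "config": cfg_dump}

    # --- inputs ---------------------------------------------------------
    if config.simulate is not None:
        sim_kwargs = dict(config.simulate)
        sim_kwargs.setdefault("seed", config.seed)
        if "motif_plant" in sim_kwargs and sim_kwargs["motif_plant"] is not None:
            kid, spec, pen = sim_kwargs["motif_plant"]
            sim_kwargs["motif_plant"] = (kid, {int(k): v for k, v in dict(spec).items()}, pen)
        sim_cfg = simulate.SimulationConfig(**sim_kwargs)
        table, sheet, ks, truth = _stage("simulate")(simulate.simulate_cohort)(sim_cfg)
        simulate.write_cohort(out / "cohort", table, sheet, ks, truth)
    else:
        table = _stage("load")(read_site_table)(config.inputs["site_table"])
        sheet = read_sample_sheet(config.inputs["sample_sheet"])
        ks = read_ks_map(config.inputs["ks_map"])

    # --- preprocess -----------------------------------------------------
    m = _stage("preprocess")(preprocess.standard_preprocess)(
        table, sheet, config.loc_prob_min, config.min_per_group
    )
    provenance["preprocess"] = m.provenance

    # --- differential ---------------------------------------------------
    groups = sample_groups(sheet)
    run = _stage("differential")(diffmod.differential_table)
    spec_a = diffmod.preset_spec(config.preset_a, *CONTRAST_A)
    spec_b = diffmod.preset_spec(config.preset_b, *CONTRAST_B)
    spec_dav = diffmod.preset_spec(config.preset_dav, *CONTRAST_DAV)
    diff_a = run(m, sheet, spec_a)
    diff_b = run(m, sheet, spec_b)
    diff_dav = run(m, sheet, spec_dav)
    bundle.tables["differential_da"] = diff_a
    bundle.tables["differential_cross"] = diff_b
    bundle.tables["differential_dav"] = diff_dav
    shift_stat, shift_dir = diffmod.abundance_shift(diff_dav, m)
    provenance["differential"] = {
        "da": {"up": int((diff_a["status"] == "up").sum()),
               "down": int((diff_a["status"] == "down").sum())},
        "dav": {"up": int((diff_dav["status"] == "up").sum()),
                "down": int((diff_dav["status"] == "down").sum())},
        "dav_abundance_shift": {"ks": shift_stat, "direction": shift_dir},
    }

    # --- protein rollup + signature --------------------------------------
    roll_a = preprocess.rollup_to_protein(m, table, diff_a[["p", "log2fc"]])
    roll_b = preprocess.rollup_to_protein(m, table, diff_b[["p", "log2fc"]])
    pdiff_a = diffmod.differential_table(roll_a.data, sheet, spec_a)
    pdiff_b = diffmod.differential_table(roll_b.data, sheet, spec_b)
    sig = _stage("signature")(signature.derive_sensitivity_signature)(pdiff_a, pdiff_b)
    profile = signature.signature_profile_matrix(sig, roll_a.data, sheet)
    bundle.tables["signature_profile"] = profile
    bundle.objects["signature"] = {
        "feature_ids": sorted(sig.feature_ids), **sig.provenance
    }

    # --- kinase inference -------------------------------------------------
    site_fc = diff_a["log2fc"].dropna()
    regulated = set(diff_a.index[diff_a["status"] != "ns"])
    universe = set(diff_a.index[diff_a["p"].notna()])
    scores: dict[str, pd.DataFrame] = {}
    kin = _stage("kinases")
    if "zscore" in config.schemes:
        scores["zscore"] = kin(kinase.ksea_z)(site_fc, ks, config.min_substrates)
    if "overrep" in config.schemes:
        scores["overrep"] = kin(kinase.overrep_exact)(
            regulated & universe, ks, universe, config.min_substrates)
    if "smoothed" in config.schemes:
        scores["smoothed"] = kin(kinase.smoothed_ksea)(
            site_fc, ks, None, config.smoothing_lambda, config.min_substrates)
    for scheme, df in scores.items():
        bundle.tables[f"kinase_{scheme}"] = df
    consensus = kinase.consensus_topk(scores, config.k, config.alpha)
    bundle.objects["consensus"] = {
        "k": consensus.k,
        "topk": consensus.topk,
        "intersection": sorted(consensus.intersection),
    }
    links = kinase.substrate_links(sig, site_fc, ks, top_n=config.k,
                                   site_p=diff_a["p"])
    bundle.tables["substrate_links"] = links.set_index("site_id")

    # --- motifs -----------------------------------------------------------
    meta = table.meta.loc[table.meta.index.intersection(diff_a.index)]
    fg_sites = [s for s in regulated if s in meta.index]
    motif_rows = []
    for center in ("S", "T"):
        fg = list(meta.loc[[s for s in fg_sites if meta.loc[s, "residue"] == center],
                           "window_13"])
        bg = list(meta.loc[meta["residue"] == center, "window_13"])
        found = _stage("motifs")(motifs.motifx_search)(
            fg, bg, center, config.motif_p_fix, config.motif_min_occ)
        for r in found:
            motif_rows.append((r.motif, center, r.fg_matches, r.fg_total,
                               r.bg_rate, r.binom_p, r.fold))
    bundle.tables["motifs"] = pd.DataFrame(
        motif_rows,
        columns=["motif", "center", "fg_matches", "fg_total", "bg_rate", "binom_p", "fold"],
    ).set_index("motif")

    # --- explore ----------------------------------------------------------
    exp = _stage("explore")
    corr = exp(explore.correlation_matrix)(m)
    bundle.tables["sample_correlation"] = corr.r
    diff_feats = diff_a.index[diff_a["status"] != "ns"]
    if len(diff_feats) >= 2:
        dend = explore.hcluster(m.data.loc[diff_feats].dropna())
        clusters = explore.cut_k(dend, min(config.n_clusters, len(diff_feats)), m, sheet)
        bundle.tables["cluster_labels"] = clusters.labels.to_frame()
        if clusters.profiles is not None:
            bundle.tables["cluster_profiles"] = clusters.profiles
        bundle.objects["dendrogram"] = {"newick": explore.to_newick(dend)}
    dav_feats = diff_dav.index[diff_dav["status"] != "ns"]
    if len(dav_feats) >= 2:
        gl = sample_groups(sheet)
        dav_cols = [c for c in m.data.columns if gl.get(c) in CONTRAST_DAV]
        pca = exp(explore.pca_with_ellipses)(
            m.data.loc[dav_feats, dav_cols], sheet, config.ellipse_level)
        bundle.tables["pca_scores"] = pca.scores
        bundle.objects["pca"] = {
            "explained": pca.explained.tolist(), "ellipses": pca.ellipses
        }

    # --- cohort -----------------------------------------------------------
    summary = _stage("cohort")(summarize_cohort)(sheet)
    bundle.tables["cohort_summary"] = summary.table

    bundle.objects["provenance"] = provenance
    manifest = write_results(bundle, out)
    logger.info("run complete: %d artifacts in %s", len(manifest), out)
    return manifest
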