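"""End-to-end pipeline stages behind the ``megaenv`` CLI.

Each stage reads a validated :class:`RunConfig`, consumes artifacts of
earlier stages from the output directory, writes CSV/JSON reports and a
manifest (config hash, package version, seed) for provenance.  Stages
are idempotent: the same config and seed reproduce byte-identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .data import METDataset, read_met_csv, write_met_csv
from .design import check_connectivity
from .errors import ParameterError, PrerequisiteError
from .gge import fit_gge, mean_vs_stability, two_way_from_blups, \
    which_won_where
from .mixed_models import extract_blups, fit_multitrial_lmm, \
    per_environment_heritability
from .mtsi import STUDY_PRESETS, run_mtsi_pipeline
from .simulate import allocate_designs, default_simulation_params, \
    simulate_met
from .summaries import botanical_composition, correlation_matrix, \
    descriptive_stats, hierarchical_clusters, pca
from .traits import DEFAULT_IDEOTYPE, TRAIT_CODES

log = logging.getLogger("megaenv")


@dataclass
class RunConfig:
    """Validated run configuration; serialized verbatim into manifests."""

    out_dir: str = "megaenv_out"
    input_csv: str | None = None        # None -> simulate
    n_genotypes: int = 220
    traits: list[str] = field(default_factory=lambda: list(TRAIT_CODES))
    seed: int = 1
    crossover_strength: float = 1.0
    gge_f: float = 0.5
    mtsi_theta_y: float = 70.0
    mtsi_theta_s: float = 30.0
    mtsi_selection_intensity: float = 15.0
    ideotype: dict = field(default_factory=lambda: dict(DEFAULT_IDEOTYPE))
    clustering_k: int = 7
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        unknown = [t for t in self.traits if t not in TRAIT_CODES]
        if unknown:
            raise ParameterError(f"unknown traits in config: {unknown}")
        if self.n_genotypes < 100:
            raise ParameterError(
                "n_genotypes must be >= 100: the study-style trials draw "
                "80 unreplicated entries plus 20 checks/standards")
        if not 0 <= self.gge_f <= 1:
            raise ParameterError("gge_f must be in [0, 1]")
        if self.clustering_k < 1:
            raise ParameterError("clustering_k must be >= 1")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        known = set(cls.__dataclass_fields__)
        bad = set(data) - known
        if bad:
            raise ParameterError(f"unknown config keys: {sorted(bad)}")
        return cls(**data)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _outdir(config: RunConfig) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def write_manifest(config: RunConfig, stage: str) -> None:
    out = _outdir(config)
    manifest = {"stage": stage, "config": asdict(config),
                "config_hash": config.digest(), "version": __version__}
    (out / f"manifest_{stage}.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise PrerequisiteError(
            f"missing artifact {path.name}; run `megaenv {producer}` first")
    return path


def _load_dataset(config: RunConfig) -> METDataset:
    out = _outdir(config)
    if config.input_csv:
        return read_met_csv(config.input_csv)
    return read_met_csv(_require(out / "met.csv", "simulate"))


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def cmd_simulate(config: RunConfig) -> Path:
    """Simulate the synthetic MET under the study conditions."""
    out = _outdir(config)
    params = default_simulation_params(
        config.n_genotypes, seed=config.seed,
        crossover_strength=config.crossover_strength)
    designs = allocate_designs(params)
    dataset = simulate_met(params, designs)
    write_met_csv(dataset, out / "met.csv")
    btypes = params.botanical_assignment or {}
    pd.Series(btypes, name="botanical_type").rename_axis("genotype_id") \
        .to_csv(out / "botanical_types.csv")
    write_manifest(config, "simulate")
    log.info("simulated %d plots into %s", len(dataset), out / "met.csv")
    return out / "met.csv"


def cmd_design(config: RunConfig) -> Path:
    """Export trial layouts and the connectivity report."""
    out = _outdir(config)
    params = default_simulation_params(
        config.n_genotypes, seed=config.seed,
        crossover_strength=config.crossover_strength)
    designs = allocate_designs(params)
    for d in designs:
        d.to_frame().to_csv(out / f"design_{d.spec.trial_id}.csv",
                            index=False)
        (out / f"design_{d.spec.trial_id}.json").write_text(d.spec.to_json())
    report = check_connectivity(designs)
    report.to_frame().to_csv(out / "connectivity.csv", index=False)
    (out / "connectivity.json").write_text(json.dumps(
        {"connected": report.connected,
         "min_overlap": report.min_overlap,
         "disconnected_pairs": [list(p)
                                for p in report.disconnected_pairs]},
        indent=2))
    write_manifest(config, "design")
    return out / "connectivity.json"


def cmd_fit(config: RunConfig) -> Path:
    """Fit per-trait multi-trial models; write components, BLUPs, H2."""
    out = _outdir(config)
    dataset = _load_dataset(config)
    comp_rows, h2_rows, blup_cols, ge_frames = [], [], {}, {}
    for trait in config.traits:
        fit = fit_multitrial_lmm(dataset, trait)
        vc = fit.variance_components()
        pct = vc.percentages()
        h2 = fit.heritability()
        comp_rows.append((trait, vc.sigma2_g, pct["genotypic"],
                          vc.sigma2_ge, pct["genotype_x_environment"],
                          vc.sigma2_rc, pct["row_and_column"],
                          vc.sigma2_e, pct["residual"], h2.h2))
        bl = extract_blups(fit)
        blup_cols[trait] = bl.standardized()
        ge_frames[trait] = bl.gei_blups
        for trial, res in per_environment_heritability(
                dataset, trait).items():
            h2_rows.append((trait, trial, res.h2))
    pd.DataFrame(comp_rows, columns=[
        "trait", "var_g", "var_g_pct", "var_ge", "var_ge_pct", "var_rc",
        "var_rc_pct", "var_e", "var_e_pct", "H2",
    ]).to_csv(out / "variance_components.csv", index=False)
    pd.DataFrame(blup_cols).rename_axis("genotype_id") \
        .to_csv(out / "blups_standardized.csv")
    for trait, ge in ge_frames.items():
        ge.rename_axis("genotype_id").to_csv(out / f"gei_blups_{trait}.csv")
    pd.DataFrame(h2_rows, columns=["trait", "trial_id", "H2"]) \
        .to_csv(out / "heritability_by_environment.csv", index=False)
    write_manifest(config, "fit")
    return out / "variance_components.csv"


def cmd_gge(config: RunConfig) -> Path:
    """Which-won-where and mean-vs-stability per trait."""
    out = _outdir(config)
    dataset = _load_dataset(config)
    env_meta = dataset.trial_meta().rename(columns={"trial_id": "env"})
    winner_rows, mega = [], {}
    for trait in config.traits:
        fit = fit_multitrial_lmm(dataset, trait)
        table = two_way_from_blups(extract_blups(fit), env_meta)
        model = fit_gge(table, config.gge_f)
        www = which_won_where(model)
        for env, sector in www.env_sector.items():
            winner_rows.append((trait, env, sector,
                                www.sector_winner[sector]))
        mega[trait] = {"repeatable": www.repeatable,
                       "mega_environments": www.mega_environments,
                       "varexp_pc12": model.varexp_pc12}
        ms = mean_vs_stability(model)
        pd.DataFrame({"mean_performance": ms.mean_performance,
                      "stability": ms.stability,
                      "ideal_distance": ms.ideal_distance}) \
            .rename_axis("genotype_id") \
            .to_csv(out / f"mean_stability_{trait}.csv")
        coords = pd.concat([
            model.genotype_coords().rename_axis("id").assign(kind="genotype"),
            model.env_coords().rename_axis("id").assign(kind="environment")])
        coords.to_csv(out / f"gge_coords_{trait}.csv")
    pd.DataFrame(winner_rows, columns=["trait", "env", "sector", "winner"]) \
        .to_csv(out / "which_won_where.csv", index=False)
    (out / "mega_environments.json").write_text(
        json.dumps(mega, indent=2, sort_keys=True))
    write_manifest(config, "gge")
    return out / "mega_environments.json"


def cmd_mtsi(config: RunConfig) -> Path:
    """MTSI rankings for the three study presets."""
    out = _outdir(config)
    dataset = _load_dataset(config)
    _require(out / "variance_components.csv", "fit")
    from .simulate import STUDY_MEGA_ENV_MAP
    summary = {}
    for name, preset in STUDY_PRESETS.items():
        ranking = run_mtsi_pipeline(
            dataset, preset["traits"], ideotype=config.ideotype,
            mega_env=preset["mega_env"], mega_env_map=STUDY_MEGA_ENV_MAP,
            theta_y=config.mtsi_theta_y, theta_s=config.mtsi_theta_s,
            selection_intensity=config.mtsi_selection_intensity)
        frame = ranking.waasby_matrix.copy()
        frame.columns = [f"WAASBY_{c}" for c in frame.columns]
        frame["MTSI"] = ranking.mtsi
        frame["rank"] = ranking.mtsi.rank(method="first").astype(int)
        frame["selected"] = frame.index.isin(ranking.selected)
        frame.rename_axis("genotype_id").sort_values("rank") \
            .to_csv(out / f"mtsi_{name}.csv")
        summary[name] = {"traits": list(preset["traits"]),
                         "mega_env": preset["mega_env"],
                         "n": int(len(ranking.mtsi)),
                         "n_selected": len(ranking.selected),
                         "best": ranking.selected[:5]}
    (out / "mtsi_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True))
    write_manifest(config, "mtsi")
    return out / "mtsi_summary.json"


def cmd_summarize(config: RunConfig) -> Path:
    """Descriptive stats, correlations, clustering, PCA, composition."""
    out = _outdir(config)
    dataset = _load_dataset(config)
    descriptive_stats(dataset, config.traits) \
        .to_csv(out / "descriptive_stats.csv", index=False)
    blup_path = _require(out / "blups_standardized.csv", "fit")
    blups = pd.read_csv(blup_path, index_col="genotype_id")
    corr = correlation_matrix(blups)
    corr.r.to_csv(out / "trait_correlations.csv")
    corr.p.to_csv(out / "trait_correlation_p.csv")
    k = min(config.clustering_k, len(blups))
    clusters = hierarchical_clusters(blups, k)
    clusters.labels.rename_axis("genotype_id") \
        .to_csv(out / "cluster_membership.csv")
    clusters.inter_distances.to_csv(out / "cluster_distances.csv")
    report = pca(blups)
    report.loadings.rename_axis("trait").to_csv(out / "pca_loadings.csv")
    pd.DataFrame({"eigenvalue": report.eigenvalues,
                  "proportion": report.proportion}) \
        .to_csv(out / "pca_eigenvalues.csv", index=False)
    bt_path = out / "botanical_types.csv"
    if bt_path.exists():
        btypes = pd.read_csv(bt_path, index_col="genotype_id")[
            "botanical_type"].to_dict()
        botanical_composition(clusters.labels, btypes) \
            .rename_axis("botanical_type") \
            .to_csv(out / "botanical_composition.csv")
    write_manifest(config, "summarize")
    return out / "descriptive_stats.csv"


def cmd_report(config: RunConfig) -> Path:
    """Assemble one markdown report from the stage outputs."""
    out = _outdir(config)
    parts = ["# megaenv run report", "",
             f"Config hash: `{config.digest()}`  |  seed: {config.seed}", ""]
    tables = [
        ("Variance components and heritability", "variance_components.csv"),
        ("Which-won-where winners", "which_won_where.csv"),
        ("Descriptive statistics", "descriptive_stats.csv"),
    ]
    for title, name in tables:
        path = out / name
        if not path.exists():
            raise PrerequisiteError(
                f"missing {name}; run the producing command first")
        frame = pd.read_csv(path)
        parts += [f"## {title}", "", frame.to_markdown(index=False), ""]
    for name in ("mega_environments.json", "mtsi_summary.json"):
        path = out / name
        if path.exists():
            parts += [f"## {name}", "", "```json", path.read_text(), "```",
                      ""]
    report = out / "report.md"
    report.write_text("\n".join(parts))
    write_manifest(config, "report")
    return report
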