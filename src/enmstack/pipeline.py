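"""End-to-end experiment orchestration.

Chains the stages — synthetic data generation, collinearity screening, model
fitting/evaluation, ensemble projection with dispersal filtering, and the
diversity analyses — through serialized text artifacts in a run directory, so
each stage can be rerun or tested in isolation. A single master seed fans out
deterministically to every stochastic component; rerunning a configuration
reproduces every output bit for bit.

Default configuration = the package's reference experiment: 20 virtual
species on a 40 × 40 grid of 10-km cells, four base climate layers plus two
near-collinear derived layers, four algorithms, two pseudo-GCMs × two
pseudo-RCPs for 2050 and 2070 under a severe warming trend, and a ~50-km
analysis grid. One virtual species is a narrow cold specialist designed to
lose all climatically suitable area in every future member — the analogue of
species predicted to have no suitable area by 2050/2070.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from . import climate as clim_mod
from . import diversity as div
from . import ensemble as ens
from . import gridio, sdm, vif
from ._seeds import child_seed

__all__ = ["RunConfig", "run_pipeline", "render_outputs", "threshold_shift_pa",
           "extinction_contraction_pa", "STAGES"]

STAGES = ("simulate", "select-vars", "fit", "project", "diversity", "report")


def _default_derived() -> dict:
    return {
        "temp_range": {"weights": {"temp_mean": 0.7, "temp_seasonality": 0.7},
                       "noise_sd": 0.05},
        "precip_wettest": {"weights": {"precip_total": 0.9, "precip_seasonality": -0.45},
                           "noise_sd": 0.05},
    }


def _default_trend() -> dict:
    # sd units per unit scenario scale; strong warming, mild drying
    return {"temp_mean": 2.5, "temp_seasonality": 0.3,
            "precip_total": -0.5, "precip_seasonality": 0.2}


def _default_scales() -> dict:
    # pathway divergence grows with the horizon, as in CO2 emission scenarios
    return {"2050": {"rcp_low": 0.8, "rcp_high": 1.0},
            "2070": {"rcp_low": 0.9, "rcp_high": 1.8}}


@dataclass
class RunConfig:
    """Every tunable of the workflow, with the reference values as defaults."""

    mode: str = "synthetic"
    seed: int = 0
    # synthetic world
    grid_shape: tuple[int, int] = (40, 40)
    cell_size_km: float = 10.0
    autocorr_length_km: float = 25.0
    base_variables: tuple[str, ...] = ("temp_mean", "temp_seasonality",
                                       "precip_total", "precip_seasonality")
    derived_variables: dict = field(default_factory=_default_derived)
    n_species: int = 20
    n_presence: int = 200
    # a cell is truly occupied when it lies within occupancy_z niche breadths
    # of the optimum on every axis: threshold = exp(-n_layers * z^2 / 2)
    occupancy_z: float = 1.25
    include_cold_specialist: bool = True
    # scenarios
    gcms: tuple[str, ...] = ("gcmA", "gcmB")
    rcps: tuple[str, ...] = ("rcp_low", "rcp_high")
    future_slices: tuple[str, ...] = ("2050", "2070")
    scenario_scales: dict = field(default_factory=_default_scales)
    trend: dict = field(default_factory=_default_trend)
    gcm_noise_sd: float = 0.15
    # modelling
    algorithms: tuple[str, ...] = sdm.ALGORITHMS
    n_background: int | None = None  # default: max(1000, n_presence)
    min_records: int = 5
    auc_min: float = 0.75
    tss_min: float = 0.3
    vif_max: float = 10.0
    dispersal_km: float = 400.0
    # diversity
    coarse_cell_km: float = 50.0
    n_perm: int = 999
    # real-data mode inputs (paths supplied by the user; no downloading)
    climate_dir: str | None = None
    occurrence_csv: str | None = None

    def background_count(self) -> int:
        return self.n_background if self.n_background is not None else max(1000, self.n_presence)

    def scenario_tags(self) -> list[clim_mod.ScenarioTag]:
        tags = [clim_mod.ScenarioTag("baseline")]
        for sl in self.future_slices:
            for g in self.gcms:
                for r in self.rcps:
                    tags.append(clim_mod.ScenarioTag(sl, g, r))
        return tags

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("grid_shape", "base_variables", "gcms", "rcps", "future_slices",
                    "algorithms"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


# ---------------------------------------------------------------------------
# virtual species roster

def make_species_roster(cfg: RunConfig) -> list[clim_mod.VirtualSpecies]:
    """Draw the virtual species set from the configuration seed.

    Ordinary species have optima within the commonly realized climate
    (uniform in [-1.5, 1.5] sd) and moderately selective tolerances (breadth
    in [0.4, 0.9] sd), giving presence samples that discriminate clearly from
    background — the regime in which niche models are reported to perform
    well. When enabled, species s000 is a cold specialist: optimum
    -2.0 sd and breadth 0.4 on the temperature layer, broad elsewhere — under
    the default warming trend its climate disappears from every future
    member.
    """
    rng = np.random.default_rng(child_seed(cfg.seed, "species"))
    roster: list[clim_mod.VirtualSpecies] = []
    variables = list(cfg.base_variables)
    occ_thr = float(np.exp(-len(variables) * cfg.occupancy_z**2 / 2.0))
    start = 0
    if cfg.include_cold_specialist:
        opt = {v: 0.0 for v in variables}
        brd = {v: 1.5 for v in variables}
        temp = variables[0]
        opt[temp], brd[temp] = -2.0, 0.4
        roster.append(clim_mod.VirtualSpecies("s000", opt, brd, occ_thr))
        start = 1
    for k in range(start, cfg.n_species):
        opt = {v: float(rng.uniform(-1.5, 1.5)) for v in variables}
        brd = {v: float(rng.uniform(0.4, 0.9)) for v in variables}
        roster.append(clim_mod.VirtualSpecies(f"s{k:03d}", opt, brd, occ_thr))
    return roster


# ---------------------------------------------------------------------------
# stages

def _dirs(run_dir: Path) -> dict[str, Path]:
    return {name: run_dir / name for name in
            ("climate", "truth", "occurrences", "vif", "models", "suitability",
             "ranges", "pa", "diversity", "figures")}


def stage_simulate(cfg: RunConfig, run_dir: Path) -> None:
    """Generate climate stacks, the species roster, occurrence samples, and
    ground-truth tables."""
    d = _dirs(run_dir)
    base = clim_mod.generate_climate(cfg.grid_shape, list(cfg.base_variables),
                                     cfg.autocorr_length_km,
                                     seed=child_seed(cfg.seed, "climate"),
                                     cell_size_km=cfg.cell_size_km)
    trend = dict(cfg.trend)
    for j, (name, spec) in enumerate(cfg.derived_variables.items()):
        clim_mod.derived_layer(base, name, spec["weights"], spec.get("noise_sd", 0.0),
                               seed=child_seed(cfg.seed, "derived", name))
        # trend of a derived layer follows its parents (unit-sd normalization)
        w = spec["weights"]
        norm = float(np.sqrt(sum(x * x for x in w.values()) + spec.get("noise_sd", 0.0) ** 2))
        trend[name] = sum(w[v] * cfg.trend[v] for v in w) / norm
    gridio.write_stack(d["climate"] / "baseline", base)
    for sl in cfg.future_slices:
        for g in cfg.gcms:
            for r in cfg.rcps:
                fut = clim_mod.shift_climate(
                    base, trend, cfg.gcm_noise_sd,
                    rcp_scale=cfg.scenario_scales[sl][r], time_slice=sl,
                    gcm_id=g, rcp_id=r, seed=child_seed(cfg.seed, "shift"))
                gridio.write_stack(d["climate"] / fut.tag.label, fut)

    roster = make_species_roster(cfg)
    rows = []
    for sp in roster:
        row = {"species_id": sp.species_id, "occupancy_threshold": sp.occupancy_threshold}
        for v in sp.niche_optimum:
            row[f"optimum_{v}"] = sp.niche_optimum[v]
            row[f"breadth_{v}"] = sp.niche_breadth[v]
        rows.append(row)
    d["truth"].mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(d["truth"] / "species_params.csv", index=False)

    occurrences = {}
    for sp in roster:
        occurrences[sp.species_id] = clim_mod.sample_occurrences(
            sp, base, cfg.n_presence, seed=child_seed(cfg.seed, "occ", sp.species_id))
    d["occurrences"].mkdir(parents=True, exist_ok=True)
    gridio.write_occurrences(d["occurrences"] / "occurrences.csv", occurrences)

    # ground-truth coarse richness (baseline) for recovery checks
    grid = div.GridSystem(cfg.grid_shape, cfg.cell_size_km, cfg.coarse_cell_km)
    true_rich = np.zeros(grid.n_sites, dtype=int)
    for sp in roster:
        true_rich += grid.aggregate(clim_mod.true_range(sp, base))
    pd.DataFrame({"site_id": grid.site_ids, "true_richness": true_rich}).to_csv(
        d["truth"] / "true_richness_baseline.csv", index=False)


def stage_select_vars(cfg: RunConfig, run_dir: Path) -> list[str]:
    """Screen covariates by iterative VIF on the baseline raster cells."""
    d = _dirs(run_dir)
    base = gridio.read_stack(d["climate"] / "baseline")
    sample, subsampled = vif.sample_cells(base, seed=child_seed(cfg.seed, "vifsample"))
    report = vif.select_variables(sample, threshold=cfg.vif_max, subsampled=subsampled)
    d["vif"].mkdir(parents=True, exist_ok=True)
    report.to_frame().to_csv(d["vif"] / "vif_report.csv", index=False)
    (d["vif"] / "retained.json").write_text(json.dumps(
        {"retained": report.retained, "removed": report.removed,
         "threshold": report.threshold, "n_observations": report.n_observations,
         "subsampled": report.subsampled}, indent=1))
    return report.retained


def _load_retained(run_dir: Path) -> list[str]:
    return json.loads((_dirs(run_dir)["vif"] / "retained.json").read_text())["retained"]


def stage_fit(cfg: RunConfig, run_dir: Path) -> pd.DataFrame:
    """Fit and evaluate all species × algorithms; write per-member
    suitability rasters (passing members only) for every scenario."""
    d = _dirs(run_dir)
    base = gridio.read_stack(d["climate"] / "baseline")
    stacks = {t.label: gridio.read_stack(d["climate"] / t.label)
              for t in cfg.scenario_tags()}
    occurrences = gridio.read_occurrences(d["occurrences"] / "occurrences.csv")
    retained = _load_retained(run_dir)

    kept, filter_log = sdm.filter_rare_species(occurrences, base, cfg.min_records)
    d["models"].mkdir(parents=True, exist_ok=True)
    filter_log.to_csv(d["models"] / "species_filter.csv", index=False)

    report_rows = []
    for sid in kept:
        occ = occurrences[sid]
        pres_cells = np.unique(base.coords_to_cells(occ.presences), axis=0)
        bg_xy = sdm.make_background(base, occ.presences, cfg.background_count(),
                                    seed=child_seed(cfg.seed, "bg", sid))
        bg_cells = base.coords_to_cells(bg_xy)
        cells = np.vstack([pres_cells, bg_cells])
        y = np.concatenate([np.ones(len(pres_cells), dtype=int),
                            np.zeros(len(bg_cells), dtype=int)])
        x = base.values_at(cells, retained)
        train, test = sdm.split_train_test(len(y), y, seed=child_seed(cfg.seed, "split", sid))
        for algo in cfg.algorithms:
            spec = sdm.ModelSpec(algo, seed=child_seed(cfg.seed, "fit", sid, algo))
            model = sdm.fit_model(spec, x[train], y[train])
            metrics = sdm.evaluate(model, x[test], y[test],
                                   auc_min=cfg.auc_min, tss_min=cfg.tss_min)
            report_rows.append({"species_id": sid, "algorithm": algo,
                                "n_presence": len(pres_cells),
                                "auc": metrics.auc, "tss": metrics.tss,
                                "threshold_eq": metrics.threshold_eq,
                                "passed": metrics.passed, "seed": spec.seed})
            if metrics.passed:
                sp_dir = d["suitability"] / sid
                sp_dir.mkdir(parents=True, exist_ok=True)
                for label, stack in stacks.items():
                    surf = model.predict_raster(stack, retained)
                    gridio.write_ascii_grid(sp_dir / f"{algo}__{label}.asc", surf,
                                            cfg.cell_size_km)
    report = pd.DataFrame(report_rows)
    report.to_csv(d["models"] / "model_report.csv", index=False)
    return report


def stage_project(cfg: RunConfig, run_dir: Path) -> None:
    """Ensemble passing members per species × slice, binarize at the mean
    equality threshold, dispersal-filter future ranges, and list species with
    no remaining suitable area."""
    d = _dirs(run_dir)
    report = pd.read_csv(d["models"] / "model_report.csv")
    occurrences = gridio.read_occurrences(d["occurrences"] / "occurrences.csv")
    d["ranges"].mkdir(parents=True, exist_ok=True)
    filter_logs, unmodelable, loss_ranges = [], [], {}
    for sid, grp in report.groupby("species_id", sort=False):
        passing = grp[grp["passed"]]
        if passing.empty:
            unmodelable.append(sid)
            continue
        thr = ens.consensus_threshold(list(passing["threshold_eq"]))
        sp_dir = d["suitability"] / sid

        def member(algo: str, tag: clim_mod.ScenarioTag) -> ens.SuitabilityMap:
            values, _ = gridio.read_ascii_grid(sp_dir / f"{algo}__{tag.label}.asc")
            return ens.SuitabilityMap(sid, tag, np.clip(values, 0, 1),
                                      members=[(algo, tag.gcm_id, tag.rcp_id)])

        base_tag = clim_mod.ScenarioTag("baseline")
        base_ens = ens.ensemble_mean([member(a, base_tag) for a in passing["algorithm"]])
        gridio.write_ascii_grid(sp_dir / "ensemble__baseline.asc", base_ens.values,
                                cfg.cell_size_km)
        base_rng = ens.binarize(base_ens, thr, cfg.cell_size_km)
        gridio.write_ascii_grid(d["ranges"] / f"{sid}__baseline.asc",
                                base_rng.mask.astype(float), cfg.cell_size_km)
        loss_ranges[sid] = {}
        for sl in cfg.future_slices:
            members = [member(a, clim_mod.ScenarioTag(sl, g, r))
                       for a in passing["algorithm"] for g in cfg.gcms for r in cfg.rcps]
            fut_ens = ens.ensemble_mean(members)
            gridio.write_ascii_grid(sp_dir / f"ensemble__{sl}.asc", fut_ens.values,
                                    cfg.cell_size_km)
            fut_rng = ens.binarize(fut_ens, thr, cfg.cell_size_km)
            filtered, log = ens.dispersal_filter(fut_rng, base_rng,
                                                 occurrences[sid].presences,
                                                 max_km=cfg.dispersal_km)
            log.insert(1, "time_slice", sl)
            filter_logs.append(log)
            gridio.write_ascii_grid(d["ranges"] / f"{sid}__{sl}.asc",
                                    filtered.mask.astype(float), cfg.cell_size_km)
            loss_ranges[sid][sl] = filtered
    pd.DataFrame({"species_id": unmodelable}).to_csv(
        d["ranges"] / "unmodelable.csv", index=False)
    filter_logs = [f for f in filter_logs if not f.empty]
    (pd.concat(filter_logs, ignore_index=True) if filter_logs
     else pd.DataFrame()).to_csv(d["ranges"] / "filter_log.csv", index=False)
    ens.detect_total_loss(loss_ranges, cfg.future_slices).to_csv(
        d["ranges"] / "table1_analogue.csv", index=False)


def _load_ranges(cfg: RunConfig, run_dir: Path, slice_label: str
                 ) -> dict[str, ens.BinaryRange]:
    d = _dirs(run_dir)
    tag = (clim_mod.ScenarioTag("baseline") if slice_label == "baseline"
           else None)
    out = {}
    for path in sorted(d["ranges"].glob(f"*__{slice_label}.asc")):
        sid = path.name.split("__")[0]
        values, cell = gridio.read_ascii_grid(path)
        out[sid] = ens.BinaryRange(species_id=sid, tag=tag, mask=values > 0.5,
                                   threshold_used=np.nan, cell_size_km=cell)
    return out


def stage_diversity(cfg: RunConfig, run_dir: Path) -> None:
    """Aggregate ranges to the coarse grid and compute all alpha/beta
    diversity outputs."""
    d = _dirs(run_dir)
    grid = div.GridSystem(cfg.grid_shape, cfg.cell_size_km, cfg.coarse_cell_km)
    d["pa"].mkdir(parents=True, exist_ok=True)
    d["diversity"].mkdir(parents=True, exist_ok=True)
    grid.site_coords_km().to_csv(d["diversity"] / "site_coords.csv", index=False)

    slices = ("baseline",) + tuple(cfg.future_slices)
    pa_by_slice, rich_by_slice = {}, {}
    beta_rows = []
    for sl in slices:
        ranges = _load_ranges(cfg, run_dir, sl)
        pa = div.build_pa_matrix(ranges, grid, tag=sl)
        pa.data.astype(int).rename_axis("site_id").to_csv(d["pa"] / f"pa_{sl}.csv")
        pa_by_slice[sl] = pa
        rich = div.richness(pa)
        rich.rename("richness").rename_axis("site_id").to_csv(
            d["diversity"] / f"richness_{sl}.csv")
        rich_by_slice[sl] = rich

        res = div.lcbd_permutation_test(pa, n_perm=cfg.n_perm,
                                        seed=child_seed(cfg.seed, "perm", sl))
        res.to_frame().to_csv(d["diversity"] / f"lcbd_{sl}.csv", index=False)
        occupied = pa.data.any(axis=1)
        trip = div.decompose_matrix(div.PresenceAbsenceMatrix(pa.data.loc[occupied]))
        trip.to_csv(d["diversity"] / f"triplets_{sl}.csv", index=False)
        centroid = div.mean_triplet(trip)
        dmat = div.jaccard_matrix(pa.data.loc[occupied].to_numpy())
        beta_rows.append({"time_slice": sl, "n_sites_used": int(occupied.sum()),
                          "n_sites_excluded_empty": int((~occupied).sum()),
                          "sstotal": res.sstotal, "bdtotal": res.bdtotal,
                          "mean_pairwise_jaccard": float(np.mean(dmat)),
                          "centroid_s": centroid.s, "centroid_repl": centroid.repl,
                          "centroid_nes": centroid.nes,
                          "frac_lcbd_significant": float(np.mean(res.p_values < 0.05))})
    pd.DataFrame(beta_rows).to_csv(d["diversity"] / "beta_summary.csv", index=False)

    ttest_rows = []
    for cur, fut in [("baseline", s) for s in cfg.future_slices] + (
            [tuple(cfg.future_slices[:2])] if len(cfg.future_slices) >= 2 else []):
        try:
            t, p, df_ = div.paired_t(rich_by_slice[cur].to_numpy(),
                                     rich_by_slice[fut].to_numpy())
        except ValueError:
            t, p, df_ = np.nan, np.nan, len(rich_by_slice[cur]) - 1
        ttest_rows.append({"comparison": f"{cur}-{fut}", "t": t, "p": p, "df": df_,
                           "mean_delta": float((rich_by_slice[fut]
                                                - rich_by_slice[cur]).mean())})
    pd.DataFrame(ttest_rows).to_csv(d["diversity"] / "paired_t.csv", index=False)

    for sl in cfg.future_slices:
        div.richness_change(rich_by_slice["baseline"], rich_by_slice[sl]
                            ).rename_axis("site_id").to_csv(
            d["diversity"] / f"richness_change_baseline_{sl}.csv")

    # recovery vs ground truth (synthetic mode only)
    truth_path = _dirs(run_dir)["truth"] / "true_richness_baseline.csv"
    if truth_path.exists():
        truth = pd.read_csv(truth_path).set_index("site_id")["true_richness"]
        pred = rich_by_slice["baseline"].reindex(truth.index)
        rho = sps.spearmanr(pred.to_numpy(), truth.to_numpy()).statistic
        pd.DataFrame([{"metric": "spearman_richness_recovery", "value": float(rho),
                       "n_sites": len(truth)}]).to_csv(
            d["diversity"] / "recovery.csv", index=False)


def threshold_shift_pa(cfg: RunConfig, run_dir: Path, delta: float
                       ) -> div.PresenceAbsenceMatrix:
    """Scenario experiment: re-binarize each species' baseline ensemble at
    threshold + delta.

    delta > 0 gives a pure range contraction (every shifted range is a subset
    of the baseline range); delta < 0 a pure expansion. Used to probe how the
    beta-diversity structure responds to contraction (nestedness share) and
    expansion (homogenization of composition).
    """
    d = _dirs(run_dir)
    report = pd.read_csv(d["models"] / "model_report.csv")
    grid = div.GridSystem(cfg.grid_shape, cfg.cell_size_km, cfg.coarse_cell_km)
    ranges = {}
    for sid, grp in report.groupby("species_id", sort=False):
        passing = grp[grp["passed"]]
        if passing.empty:
            continue
        thr = ens.consensus_threshold(list(passing["threshold_eq"]))
        values, cell = gridio.read_ascii_grid(d["suitability"] / sid / "ensemble__baseline.asc")
        smap = ens.SuitabilityMap(sid, clim_mod.ScenarioTag("baseline"),
                                  np.clip(values, 0, 1))
        ranges[sid] = ens.binarize(smap, float(np.clip(thr + delta, 0.0, 1.0)), cell)
    return div.build_pa_matrix(ranges, grid, tag=f"shift{delta:+.2f}")


def extinction_contraction_pa(cfg: RunConfig, run_dir: Path, fraction: float = 0.25
                              ) -> div.PresenceAbsenceMatrix:
    """Scenario experiment: extinction-dominated pure contraction.

    The narrowest-ranged ``fraction`` of species lose all suitable area
    (mask becomes empty); the rest keep their baseline ranges. Every species'
    range is a subset of its baseline range, so this is a pure contraction —
    the one dominated by complete loss of climatically suitable area for
    narrow-ranged species. Because narrow endemics are the species unique to
    few sites, their loss converts between-site turnover into richness-
    difference-driven nestedness, raising the mean nestedness share.
    """
    pa = threshold_shift_pa(cfg, run_dir, 0.0)
    counts = pa.data.sum(axis=0).sort_values(kind="stable")
    k = max(1, int(round(fraction * pa.data.shape[1])))
    doomed = list(counts.index[:k])
    data = pa.data.copy()
    data[doomed] = False
    return div.PresenceAbsenceMatrix(data=data, tag=f"contracted_{fraction:.2f}")


def run_pipeline(cfg: RunConfig, run_dir: str | Path, stages=STAGES) -> Path:
    """Run the configured stages in order; write a provenance manifest."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    from . import __version__

    (run_dir / "manifest.json").write_text(json.dumps(
        {"config": cfg.to_dict(), "package_version": __version__,
         "stages": list(stages)}, indent=1))
    fns = {"simulate": stage_simulate, "select-vars": stage_select_vars,
           "fit": stage_fit, "project": stage_project,
           "diversity": stage_diversity, "report": render_outputs}
    for name in stages:
        if cfg.mode == "real" and name == "simulate":
            _ingest_real_inputs(cfg, run_dir)
            continue
        try:
            fns[name](cfg, run_dir)
        except Exception as exc:  # pragma: no cover - error labeling only
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
    return run_dir


def _ingest_real_inputs(cfg: RunConfig, run_dir: Path) -> None:
    """Real-data mode: copy user-supplied climate stacks and occurrences into
    the run layout. No downloading; data acquisition is the user's job."""
    import shutil

    if cfg.climate_dir is None or cfg.occurrence_csv is None:
        raise ValueError("real mode requires climate_dir and occurrence_csv")
    d = _dirs(run_dir)
    shutil.copytree(cfg.climate_dir, d["climate"], dirs_exist_ok=True)
    d["occurrences"].mkdir(parents=True, exist_ok=True)
    shutil.copy(cfg.occurrence_csv, d["occurrences"] / "occurrences.csv")


# ---------------------------------------------------------------------------
# figures

def _coarse_map(ax, df: pd.DataFrame, coords: pd.DataFrame, col: str, cmap: str,
                title: str) -> None:
    merged = coords.merge(df, on="site_id")
    nr, nc = merged["coarse_row"].max() + 1, merged["coarse_col"].max() + 1
    img = np.full((nr, nc), np.nan)
    img[merged["coarse_row"], merged["coarse_col"]] = merged[col]
    im = ax.imshow(img, origin="lower", cmap=cmap)
    ax.figure.colorbar(im, ax=ax, shrink=0.8)
    ax.set_title(title, fontsize=9)
    ax.set_xticks([])
    ax.set_yticks([])


def render_outputs(cfg: RunConfig, run_dir: str | Path) -> list[Path]:
    """Deterministic figures: richness ladder plot, gain/loss and richness
    gradient maps, LCBD maps with significance, and ternary plots of the
    (S, Repl, Nes) triplets with their centroid."""
    from matplotlib.figure import Figure

    run_dir = Path(run_dir)
    d = _dirs(run_dir)
    out_dir = d["figures"]
    out_dir.mkdir(parents=True, exist_ok=True)
    coords = pd.read_csv(d["diversity"] / "site_coords.csv")
    slices = ("baseline",) + tuple(cfg.future_slices)
    missing = [sl for sl in slices
               if not (d["diversity"] / f"richness_{sl}.csv").exists()]
    if missing:
        raise FileNotFoundError(f"diversity outputs missing for slices {missing}; "
                                "run the diversity stage first")
    rich = {sl: pd.read_csv(d["diversity"] / f"richness_{sl}.csv") for sl in slices}
    written = []

    # ladder plot: one line per site across time slices
    fig = Figure(figsize=(5, 4))
    ax = fig.add_subplot(111)
    mat = np.column_stack([rich[sl]["richness"].to_numpy() for sl in slices])
    for row in mat:
        ax.plot(range(len(slices)), row, color="steelblue", alpha=0.25, lw=0.8)
    ax.plot(range(len(slices)), mat.mean(axis=0), color="black", lw=2, label="mean")
    ax.set_xticks(range(len(slices)), slices)
    ax.set_ylabel("species richness per grid cell")
    ax.legend(frameon=False)
    fig.savefig(out_dir / "fig_ladder.png", dpi=120)
    written.append(out_dir / "fig_ladder.png")

    # gain/loss maps and richness gradients
    fig = Figure(figsize=(3 * len(slices), 3.2))
    for i, sl in enumerate(slices):
        ax = fig.add_subplot(1, len(slices), i + 1)
        _coarse_map(ax, rich[sl], coords, "richness", "viridis", f"richness {sl}")
    fig.savefig(out_dir / "fig_richness_maps.png", dpi=120)
    written.append(out_dir / "fig_richness_maps.png")

    fig = Figure(figsize=(3 * len(cfg.future_slices), 3.2))
    for i, sl in enumerate(cfg.future_slices):
        chg = pd.read_csv(d["diversity"] / f"richness_change_baseline_{sl}.csv")
        ax = fig.add_subplot(1, len(cfg.future_slices), i + 1)
        _coarse_map(ax, chg, coords, "delta", "BrBG", f"richness change baseline→{sl}")
    fig.savefig(out_dir / "fig_gain_loss.png", dpi=120)
    written.append(out_dir / "fig_gain_loss.png")

    # LCBD maps with significance overlay
    fig = Figure(figsize=(3 * len(slices), 6.4))
    for i, sl in enumerate(slices):
        lc = pd.read_csv(d["diversity"] / f"lcbd_{sl}.csv")
        ax = fig.add_subplot(2, len(slices), i + 1)
        _coarse_map(ax, lc, coords, "lcbd", "magma", f"LCBD {sl}")
        lc["significant"] = (lc["p_value"] < 0.05).astype(float)
        ax = fig.add_subplot(2, len(slices), len(slices) + i + 1)
        _coarse_map(ax, lc, coords, "significant", "Greys", f"p < 0.05 {sl}")
    fig.savefig(out_dir / "fig_lcbd.png", dpi=120)
    written.append(out_dir / "fig_lcbd.png")

    # ternary plots
    fig = Figure(figsize=(3 * len(slices), 3.2))
    tri_x = [0, 1, 0.5, 0]
    tri_y = [0, 0, np.sqrt(3) / 2, 0]
    for i, sl in enumerate(slices):
        trip = pd.read_csv(d["diversity"] / f"triplets_{sl}.csv")
        ax = fig.add_subplot(1, len(slices), i + 1)
        ax.plot(tri_x, tri_y, color="black", lw=1)
        xy = np.array([div.ternary_coords(div.BetaTriplet(r.S, r.Repl, r.Nes))
                       for r in trip.itertuples()])
        ax.scatter(xy[:, 0], xy[:, 1], s=4, color="black", alpha=0.3)
        cx, cy = div.ternary_coords(div.mean_triplet(trip))
        ax.scatter([cx], [cy], s=60, color="royalblue", zorder=3)
        ax.text(-0.02, -0.05, "Repl", ha="right", fontsize=8)
        ax.text(1.02, -0.05, "Nes", ha="left", fontsize=8)
        ax.text(0.5, np.sqrt(3) / 2 + 0.03, "S", ha="center", fontsize=8)
        ax.set_title(sl, fontsize=9)
        ax.set_aspect("equal")
        ax.axis("off")
    fig.savefig(out_dir / "fig_ternary.png", dpi=120)
    written.append(out_dir / "fig_ternary.png")
    return written
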