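"""End-to-end orchestration: simulate -> preprocess -> score -> fit -> ED.

A single :class:`RunConfig` drives one reproducible analysis: generate (or
load) the monitoring tables, reduce them to per-site or per-fortnight
metric values, fit the Bayesian distance-decay model per metric on its
transform scale, invert each fit into ED10/ED50 with credible bands, and
write the tabular report bundle (metric tables, posterior summaries,
fitted-curve data files, an effect-distance table and a JSON run log).
"""

from __future__ import annotations

import json
import platform
import warnings
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from plume_ed.coral import exclude_dislodged, site_exceedance
from plume_ed.decay import DecayModelSpec, PosteriorDraws, apply_transform, fit_decay
from plume_ed.effect_distance import (
    EffectDistanceResult,
    ed_posterior,
    ed_table,
)
from plume_ed.preprocess import PreprocessConfig, preprocess_water_quality
from plume_ed.psd import silt_clay_fraction
from plume_ed.synthetic import SimulationConfig, SyntheticDataset, simulate_dataset
from plume_ed.transforms import get_transform

__all__ = ["RunConfig", "RunResult", "run_pipeline", "DEFAULT_TRANSFORMS"]

#: modelling scale per metric
DEFAULT_TRANSFORMS: dict[str, str] = {
    "ssc": "log10",
    "dli": "sqrt",
    "depo_index": "logit",
    "silt_clay": "logit",
    "mucus_ge3": "logit",
    "sediment_ge3": "logit",
    "mortality_nonzero": "logit",
}

#: metrics measured per fortnight (mixed model) vs pooled per site
FORTNIGHT_METRICS = ("ssc", "dli", "depo_index")
SITE_METRICS = ("silt_clay", "mucus_ge3", "sediment_ge3", "mortality_nonzero")

#: benthic light recovers with distance; everything else decays
EXPECTED_SLOPE_SIGN: dict[str, int] = {m: -1 for m in DEFAULT_TRANSFORMS}
EXPECTED_SLOPE_SIGN["dli"] = 1


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    input_dir: str | None = None  # load CSVs instead of simulating
    metrics: tuple[str, ...] = tuple(DEFAULT_TRANSFORMS)
    transforms: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_TRANSFORMS))
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    mcmc: DecayModelSpec = field(default_factory=DecayModelSpec)
    ed_levels: tuple[float, ...] = (0.1, 0.5)
    score_threshold: int = 3
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if not self.metrics:
            raise ValueError("metric list must not be empty")
        missing = [m for m in self.metrics if m not in self.transforms]
        if missing:
            raise ValueError(f"metrics without a transform: {missing}")
        for tag in self.transforms.values():
            get_transform(tag)
        unknown = set(self.metrics) - set(DEFAULT_TRANSFORMS)
        if unknown:
            raise ValueError(f"unknown metrics {sorted(unknown)}")


@dataclass
class RunResult:
    """Everything one run produced, in memory."""

    dataset: SyntheticDataset
    fortnight_metrics: pd.DataFrame
    site_metrics: pd.DataFrame
    draws: dict[str, PosteriorDraws]
    fit_summaries: dict[str, pd.DataFrame]
    ed_results: list[EffectDistanceResult]
    ed_summary: pd.DataFrame
    curves: dict[str, pd.DataFrame]
    log: dict


def _load_dataset(input_dir: str, config: SimulationConfig) -> SyntheticDataset:
    d = Path(input_dir)
    return SyntheticDataset(
        sites=pd.read_csv(d / "sites.csv"),
        water_quality=pd.read_csv(d / "water_quality.csv"),
        colonies=pd.read_csv(d / "colonies.csv"),
        psd=pd.read_csv(d / "psd.csv"),
        truth=config,
    )


def _site_metric_table(dataset: SyntheticDataset, threshold: int) -> pd.DataFrame:
    """Pooled per-site responses: coral exceedance proportions, Porites
    mortality, post-dredging silt+clay proportion."""
    sites = dataset.sites
    colonies = exclude_dislodged(dataset.colonies)
    massive = colonies[colonies["morphology"] == "massive"]
    rows = []
    for metric, score_field in (
        ("sediment_ge3", "sediment_score"),
        ("mucus_ge3", "mucus_score"),
    ):
        if massive.empty:
            continue
        summary = site_exceedance(massive, score_field, threshold, sites)
        summary["metric"] = metric
        rows.append(summary)
    if not massive.empty:
        mort = (
            massive.groupby(["site_id", "colony_id"], sort=True)["mortality_nonzero"]
            .any()
            .reset_index()
            .groupby("site_id", sort=True)["mortality_nonzero"]
            .agg(n_obs="size", proportion="mean")
            .reset_index()
        )
        mort = mort.merge(sites[["site_id", "distance_km"]], on="site_id")
        mort["metric"] = "mortality_nonzero"
        rows.append(mort[["site_id", "distance_km", "n_obs", "proportion", "metric"]])
    psd = dataset.psd
    after = psd[psd["phase"] == "after_1"]
    if not after.empty:
        sc = after.apply(silt_clay_fraction, axis=1)
        frame = pd.DataFrame(
            {
                "site_id": after["site_id"].to_numpy(),
                "distance_km": after["distance_km"].to_numpy(),
                "n_obs": 1,
                "proportion": sc.to_numpy(),
                "metric": "silt_clay",
            }
        )
        rows.append(frame)
    if not rows:
        return pd.DataFrame(
            columns=["site_id", "distance_km", "n_obs", "proportion", "metric"]
        )
    return pd.concat(rows, ignore_index=True)


def _fit_fortnight_metric(
    metric: str,
    table: pd.DataFrame,
    sites: pd.DataFrame,
    tag: str,
    spec: DecayModelSpec,
) -> PosteriorDraws:
    sub = table[table["metric"] == metric].merge(
        sites[["site_id", "distance_km"]], on="site_id"
    )
    counts = None  # continuous index; exact 0/1 handled by the n=1 correction
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # boundary-correction warning is routine here
        y = apply_transform(
            sub["value"].to_numpy(), tag, spec.empirical_logit_correction, counts
        )
    return fit_decay(
        y,
        sub["distance_km"].to_numpy(),
        site_id=sub["site_id"].to_numpy(),
        fortnight=sub["fortnight"].to_numpy(),
        spec=replace(spec, transform=tag),
    )


def _fit_site_metric(
    metric: str,
    table: pd.DataFrame,
    tag: str,
    spec: DecayModelSpec,
) -> PosteriorDraws:
    sub = table[table["metric"] == metric]
    counts = sub["n_obs"].to_numpy() if (sub["n_obs"] > 1).any() else None
    y = apply_transform(
        sub["proportion"].to_numpy(), tag, spec.empirical_logit_correction, counts
    )
    # one pooled value per site: the mixed model degenerates to a Bayesian
    # simple regression (random effects would be unidentifiable)
    site_spec = replace(spec, transform=tag, include_site=False, include_fortnight=False)
    return fit_decay(y, sub["distance_km"].to_numpy(), spec=site_spec)


def _curve_frame(
    draws: PosteriorDraws, metric: str, d_near: float, d_far: float, n_grid: int = 60
) -> pd.DataFrame:
    """Fitted-curve data on the natural scale: posterior median and 95%
    band of the population-mean prediction over a log-spaced grid."""
    grid = np.logspace(np.log10(d_near), np.log10(d_far), n_grid)
    b0 = draws.stacked("beta0")[:, None]
    b1 = draws.stacked("beta1")[:, None]
    eta = b0 + b1 * np.log10(grid)[None, :]
    inverse = get_transform(draws.transform).inverse
    if draws.transform == "sqrt":
        eta = np.clip(eta, 0.0, None)
    natural = inverse(eta)
    lo, med, hi = np.percentile(natural, [2.5, 50.0, 97.5], axis=0)
    return pd.DataFrame(
        {
            "metric": metric,
            "distance_km": grid,
            "predicted_median": med,
            "predicted_q2.5": lo,
            "predicted_q97.5": hi,
        }
    )


def run_pipeline(config: RunConfig) -> RunResult:
    """Run the full analysis described by ``config``; returns the bundle
    and, when ``config.output_dir`` is set, writes it to disk."""
    sim = replace(config.simulation, seed=config.seed)
    if config.input_dir is not None:
        dataset = _load_dataset(config.input_dir, sim)
    else:
        dataset = simulate_dataset(sim)

    fortnight_metrics = preprocess_water_quality(
        dataset.water_quality, config.preprocess, dredge_phase_only=True
    )
    site_metrics = _site_metric_table(dataset, config.score_threshold)

    draws: dict[str, PosteriorDraws] = {}
    fit_summaries: dict[str, pd.DataFrame] = {}
    ed_results: list[EffectDistanceResult] = []
    curves: dict[str, pd.DataFrame] = {}
    d_near, d_far = sim.d_near_km, sim.d_far_km
    for k, metric in enumerate(config.metrics):
        tag = config.transforms[metric]
        # fixed per-stage seed offsets keep single-metric re-runs reproducible
        spec = replace(config.mcmc, seed=(config.seed + 101 * (k + 1)) % (2**31 - 1))
        if metric in FORTNIGHT_METRICS:
            fit = _fit_fortnight_metric(
                metric, fortnight_metrics, dataset.sites, tag, spec
            )
        else:
            fit = _fit_site_metric(metric, site_metrics, tag, spec)
        draws[metric] = fit
        fit_summaries[metric] = fit.summary()
        curves[metric] = _curve_frame(fit, metric, d_near, d_far)
        for q in config.ed_levels:
            ed_results.append(
                ed_posterior(
                    fit,
                    q=q,
                    d_near_km=d_near,
                    d_far_km=d_far,
                    metric=metric,
                    expected_sign=EXPECTED_SLOPE_SIGN[metric],
                )
            )

    summary = ed_table(ed_results)
    log = {
        "config": {
            "metrics": list(config.metrics),
            "transforms": {m: config.transforms[m] for m in config.metrics},
            "ed_levels": list(config.ed_levels),
            "seed": config.seed,
            "mcmc": asdict(config.mcmc),
            "simulation": {
                k: v for k, v in asdict(sim).items() if not isinstance(v, dict)
            },
        },
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "rhat": {m: draws[m].rhat for m in draws},
    }
    result = RunResult(
        dataset=dataset,
        fortnight_metrics=fortnight_metrics,
        site_metrics=site_metrics,
        draws=draws,
        fit_summaries=fit_summaries,
        ed_results=ed_results,
        ed_summary=summary,
        curves=curves,
        log=log,
    )
    if config.output_dir is not None:
        _write_bundle(result, config)
    return result


def _write_bundle(result: RunResult, config: RunConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.dataset.to_csv(out / "data")
    result.fortnight_metrics.to_csv(out / "fortnight_metrics.csv", index=False)
    result.site_metrics.to_csv(out / "site_metrics.csv", index=False)
    pd.concat(result.curves.values(), ignore_index=True).to_csv(
        out / "fitted_curves.csv", index=False
    )
    fits = []
    for metric, summary in result.fit_summaries.items():
        s = summary.copy()
        s.insert(0, "metric", metric)
        fits.append(s)
    pd.concat(fits, ignore_index=True).to_csv(out / "fit_summaries.csv", index=False)
    result.ed_summary.to_csv(out / "ed_table.csv", index=False)
    ed_json = [
        {
            "metric": r.metric,
            "q": r.q,
            "ed_km": r.ed_km,
            "ci95_km": list(r.ci95_km),
            "d_near_km": r.d_near_km,
            "d_far_km": r.d_far_km,
            "n_draws": r.n_draws,
            "n_clipped": r.n_clipped,
            "transform": r.transform,
        }
        for r in result.ed_results
    ]
    (out / "ed_results.json").write_text(json.dumps(ed_json, indent=2))
    (out / "run_log.json").write_text(json.dumps(result.log, indent=2, default=str))
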