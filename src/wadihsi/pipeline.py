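"""End-to-end analysis: simulate (or load) sites, fit curves, score HSI,
diversity trade-offs, validation battery, conservation gap — with a
manifest recording inputs, seed and content hashes so two runs from the
same config are verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import diversity, gap, validation
from .config import PipelineConfig
from .curves import (
    SuitabilityCurve,
    TextureComposition,
    gaussian_suitability,
    texture_scores,
    weighted_gaussian_fit,
)
from .hsi import classify_quantile, geometric_mean_hsi, substrate_impact
from .io import write_ascii_grid, write_curves, write_site_table
from .synthetic import DEFAULT_PARAMETERS, TrueModel, generate_grids, generate_sites

log = logging.getLogger("wadihsi")

__all__ = ["fit_curves", "score_sites", "loocv_hsi", "run_pipeline"]


def fit_curves(
    sites: pd.DataFrame, parameters=None, unbiased: bool = False
) -> dict[str, SuitabilityCurve]:
    """Abundance-weighted Gaussian fit for each environmental parameter."""
    params = list(parameters) if parameters else [
        c for c in DEFAULT_PARAMETERS if c in sites.columns
    ]
    if not params:
        raise ValueError("no environmental parameter columns found")
    w = sites["abundance"].to_numpy(dtype=float)
    return {
        p: weighted_gaussian_fit(sites[p].to_numpy(), w, parameter=p,
                                 unbiased=unbiased)
        for p in params
    }


def _site_textures(sites: pd.DataFrame) -> np.ndarray:
    """Substrate score per site from the fines composition (gravel excluded)."""
    comps = []
    for _, row in sites.iterrows():
        fines = row["sand"] + row["silt"] + row["clay"]
        if fines <= 0:
            raise ValueError(f"site {row.get('site_id', '?')} has no fine sediment")
        comps.append(
            TextureComposition(
                sand=row["sand"] / fines,
                silt=row["silt"] / fines,
                clay=row["clay"] / fines,
            )
        )
    return texture_scores(comps)


def score_sites(
    sites: pd.DataFrame,
    curves: dict[str, SuitabilityCurve],
    include_texture: bool = True,
) -> pd.DataFrame:
    """Per-parameter suitability scores plus the composite geometric-mean HSI.

    Returns a frame indexed like ``sites`` with one column per parameter,
    an optional ``texture`` column, and the composite ``hsi``.
    """
    out = pd.DataFrame(index=sites.index)
    for name, curve in curves.items():
        out[name] = gaussian_suitability(sites[name].to_numpy(), curve)
    if include_texture:
        out["texture"] = _site_textures(sites)
    out["hsi"] = [geometric_mean_hsi(row) for row in out.to_numpy()]
    return out


def loocv_hsi(
    sites: pd.DataFrame, parameters=None, include_texture: bool = False
) -> validation.LoocvReport:
    """Leave-one-out transferability of the HSI pipeline.

    For each site the curves are re-fit on the other sites and the held-out
    site's composite HSI predicted; the reference ("observed") values are
    the full-data HSI scores, so the report measures how well the index
    transfers to an unseen site. Texture is excluded by default because its
    log-normalisation is defined across the site set being scored.
    """
    full = score_sites(sites, fit_curves(sites, parameters), include_texture)

    def predict(i: int) -> float:
        train = sites.drop(index=sites.index[i])
        curves = fit_curves(train, parameters)
        held = sites.iloc[[i]]
        return float(score_sites(held, curves, include_texture)["hsi"].iloc[0])

    return validation.loocv(
        list(sites["site_id"]), full["hsi"].to_numpy(), predict
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, out_dir, sites=None, community=None) -> dict:
    """Run every stage and write all artifacts.

    With no ``sites`` table a seeded synthetic survey is generated first.
    Stages: simulate -> fit curves -> score HSI (with and without
    substrate) -> classify -> diversity & trade-off correlations ->
    validation battery -> conservation gap. A missing community matrix
    skips the diversity stage with a notice; any stage failure aborts with
    the stage name and artifacts written so far are kept. Returns the
    manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.to_dict()}
    stage = "simulate"
    try:
        if sites is None:
            model = TrueModel(seed=config.seed)
            ds = generate_sites(model, config.n_sites)
            site_df, community = ds.sites, ds.community
        else:
            site_df = sites
        write_site_table(site_df, out / "sites.csv")
        if community is not None:
            community.to_csv(out / "community.csv")

        stage = "fit"
        curves = fit_curves(site_df, config.parameters or None)
        write_curves(curves, out / "curves.csv")

        stage = "score"
        scored = score_sites(site_df, curves, include_texture=config.include_texture)
        scored_wo = score_sites(site_df, curves, include_texture=False)
        thr, labels = classify_quantile(
            scored["hsi"], interpolation=config.quantile_interpolation,
            thresholds=config.threshold_preset,
        )
        hsi_table = pd.DataFrame(
            {
                "site_id": site_df["site_id"],
                "hsi": scored["hsi"].to_numpy(),
                "hsi_no_texture": scored_wo["hsi"].to_numpy(),
                "label": labels,
            }
        )
        write_site_table(hsi_table, out / "hsi.csv")
        if config.include_texture:
            impact = substrate_impact(
                scored["hsi"], scored_wo["hsi"], site_df["site_id"]
            )
            report["substrate_impact"] = {
                "improved": impact.attrs["improved"],
                "degraded": impact.attrs["degraded"],
                "unchanged": impact.attrs["unchanged"],
            }
        report["thresholds"] = list(thr)

        stage = "diversity"
        if community is None:
            log.info("no community matrix supplied; diversity stage skipped")
            report["diversity"] = "skipped: no community matrix"
        else:
            counts = community.to_numpy()
            metrics = pd.DataFrame(
                {
                    "site_id": site_df["site_id"].to_numpy(),
                    "shannon": [diversity.shannon(c) for c in counts],
                    "simpson": [diversity.simpson(c) for c in counts],
                    "evenness": [diversity.evenness(c) for c in counts],
                }
            )
            metrics.to_csv(out / "diversity.csv", index=False)
            corr = diversity.correlate_with_bootstrap(
                scored["hsi"].to_numpy(), metrics["shannon"].to_numpy(),
                n_boot=config.n_boot, seed=config.seed,
            )
            report["hsi_shannon"] = dataclasses.asdict(corr)

        stage = "validate"
        abund = site_df["abundance"].to_numpy(dtype=float)
        observed_pos = abund > np.median(abund)
        hsi_vals = scored["hsi"].to_numpy()
        choice = validation.select_threshold(
            hsi_vals[observed_pos], hsi_vals[~observed_pos], method="MaxSS"
        )
        predicted_pos = hsi_vals >= choice.threshold
        cc = validation.ConfusionCounts(
            tp=int(np.sum(predicted_pos & observed_pos)),
            fp=int(np.sum(predicted_pos & ~observed_pos)),
            tn=int(np.sum(~predicted_pos & ~observed_pos)),
            fn=int(np.sum(~predicted_pos & observed_pos)),
        )
        report["confusion"] = dataclasses.asdict(validation.confusion_metrics(cc))
        report["threshold"] = dataclasses.asdict(choice)
        report["auc"] = validation.auc(hsi_vals[observed_pos], hsi_vals[~observed_pos])
        loocv_rep = loocv_hsi(site_df, config.parameters or None)
        report["loocv"] = {
            "r2": loocv_rep.r2,
            "rmse": loocv_rep.rmse,
            "mae": loocv_rep.mae,
            "mean_residual": loocv_rep.mean_residual,
        }

        stage = "gap"
        suit, protected, density = generate_grids(
            *config.grid_shape, pa_fraction=config.pa_fraction, seed=config.seed
        )
        write_ascii_grid(suit, out / "suitability.asc")
        write_ascii_grid(protected.astype(float), out / "protected.asc")
        mask, thr90 = gap.high_suitability_mask(suit, config.gap_percentile)
        rate, area_h, area_p = gap.protection_rate(
            mask, protected, config.cell_area_km2
        )
        report["gap"] = {
            "threshold": thr90,
            "habitat_km2": area_h,
            "protected_km2": area_p,
            "rate_pct": rate,
            "targets": gap.target_progress(rate, config.gap_targets),
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=2, default=float))
    manifest = {
        "seed": config.seed,
        "config": config.to_dict(),
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log.info("pipeline complete: %d artifacts in %s", len(manifest["outputs"]), out)
    return manifest
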