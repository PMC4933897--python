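"""End-to-end reproducible runs: simulate -> T1 -> concentration -> fit ->
histogram -> reproducibility statistics.

A run is controlled by a :class:`RunConfig` holding every open constant
(relaxivity, input-function constants, exclusion thresholds, bin count, fit
bounds), the seeds, and the stage selection.  The run directory receives
NIfTI maps, CSV tables and a JSON manifest (config hash, seeds, package
versions, per-stage failure counts); re-running an identical config
reproduces all numeric outputs bit-identically.

The reproducibility stage emulates the full observer study on synthetic
subjects: per subject a phantom is simulated and fitted once per scan;
"raters" are independent boundary perturbations of the ROI applied to the
same fitted maps (observers re-draw ROIs, they do not re-fit), replicates
are re-draws by the first rater, and the second scan is a fresh noisy
acquisition of a slightly jittered phantom.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .acquisition import study_protocol
from .aif import AIFModel
from .concentration import to_concentration
from .histogram import DEFAULT_THRESHOLDS, roi_metrics
from .repro import cov, icc, one_way_anova, paired_t, design_matrix
from .synthetic import HeterogeneityConfig, make_phantom, perturb_mask, simulate_series
from .t1 import fit_vfa_t1
from .tofts import FitConfig, fit_map
from . import io as dio

__all__ = ["RunConfig", "run_pipeline", "measurement_table_from_maps",
           "repro_battery"]

STAGES = ("simulate", "t1fit", "conc", "fit", "histogram", "repro")
_DEPS = {"t1fit": "simulate", "conc": "t1fit", "fit": "conc",
         "histogram": "fit", "repro": "histogram"}

HIST_METRICS = ("mean", "mode", "skewness", "kurtosis")
PARAMS = ("ktrans", "ve")


@dataclass
class RunConfig:
    """Everything a pipeline run depends on, in one serialisable record."""

    stages: tuple = STAGES
    shape: tuple = (32, 32)
    n_subjects: int = 3
    n_raters: int = 3
    n_replicates: int = 2
    n_scans: int = 2
    noise_sigma: float = 0.5          # signal units; baseline signal ~ 17
    noise_kind: str = "rician"
    rater_mask_magnitude: float = 1.5  # px of boundary shift per observer
    rescan_jitter: float = 0.03        # sd of multiplicative parameter jitter
    relaxivity: float = 3.9
    aif: dict = field(default_factory=lambda: asdict(AIFModel()))
    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    n_bins: int = 50
    heterogeneity: dict = field(default_factory=lambda: asdict(HeterogeneityConfig()))
    fit: dict = field(default_factory=lambda: asdict(FitConfig()))
    seed: int = 0
    outdir: str = "runs/demo"

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        for stage, dep in _DEPS.items():
            if stage in self.stages and dep not in self.stages:
                raise ValueError(f"stage {stage!r} requires stage {dep!r}")
        if self.n_subjects < 2 and "repro" in self.stages:
            raise ValueError("repro stage needs at least 2 subjects")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stages"] = list(self.stages)
        d["shape"] = list(self.shape)
        return d


def _subject_maps(cfg: RunConfig, subject: int, scan: int):
    """Simulate and fit one subject/scan; returns (phantom, pmap, log)."""
    het = HeterogeneityConfig(**{k: tuple(v) if isinstance(v, list) else v
                                 for k, v in cfg.heterogeneity.items()})
    phantom = make_phantom(tuple(cfg.shape), het, seed=cfg.seed + 1000 * subject)
    if scan > 1 and cfg.rescan_jitter > 0:
        # biological/positioning drift between visits: small multiplicative
        # jitter of the true parameter fields
        rng = np.random.default_rng(cfg.seed + 1000 * subject + 500 + scan)
        jit = lambda m: np.clip(m * (1 + rng.normal(0, cfg.rescan_jitter, m.shape)), 0, None)
        phantom.ktrans_map = jit(phantom.ktrans_map)
        phantom.ve_map = np.clip(jit(phantom.ve_map), 0, 1)
        phantom.vp_map = np.clip(jit(phantom.vp_map), 0, 1)

    meta = study_protocol(relaxivity=cfg.relaxivity)
    series = simulate_series(phantom, meta, cfg.noise_sigma, cfg.noise_kind,
                             seed=cfg.seed + 7919 * subject + 13 * scan)
    t1map = fit_vfa_t1(series.vfa_signals, meta)
    conc = to_concentration(series, t1map, cfg.relaxivity)
    fitcfg = FitConfig(**{k: tuple(v) if isinstance(v, list) else v
                          for k, v in cfg.fit.items()})
    aif = AIFModel(**{k: tuple(v) if isinstance(v, list) else v
                      for k, v in cfg.aif.items()})
    aif = AIFModel(dose_D=aif.dose_D, amplitudes=aif.amplitudes,
                   rates=aif.rates, onset_time=meta.bolus_time)
    pmap = fit_map(conc, phantom.roi_mask, aif, fitcfg)
    log = {"t1_failed": t1map.n_failed, "conc_failed": conc.n_failed,
           "fit_nonconverged": int(phantom.roi_mask.sum()) - pmap.n_converged}
    return phantom, pmap, log


def measurement_table_from_maps(cfg: RunConfig) -> tuple[pd.DataFrame, dict]:
    """Emulate the observer study; long table of histogram metrics.

    One row per (subject, rater, scan, replicate, metric); metric names are
    ``{param}_{statistic}`` for param in ktrans/ve and statistic in
    Mean/Mode/Skewness/Kurtosis.
    """
    rows, logs = [], []
    for subj in range(1, cfg.n_subjects + 1):
        for scan in range(1, cfg.n_scans + 1):
            phantom, pmap, log = _subject_maps(cfg, subj, scan)
            logs.append({"subject": subj, "scan": scan, **log})
            for rater in range(1, cfg.n_raters + 1):
                n_reps = cfg.n_replicates if rater == 1 else 1
                for rep in range(1, n_reps + 1):
                    mseed = cfg.seed + 104729 * subj + 389 * scan + 31 * rater + rep
                    mask = perturb_mask(phantom.roi_mask,
                                        cfg.rater_mask_magnitude, seed=mseed)
                    for param in PARAMS:
                        vals = getattr(pmap, param)
                        m = roi_metrics(vals, mask, param, cfg.thresholds,
                                        cfg.n_bins)
                        for stat in HIST_METRICS:
                            rows.append({
                                "subject": subj, "rater": rater, "scan": scan,
                                "replicate": rep,
                                "metric": f"{param}_{stat}",
                                "value": getattr(m, stat),
                            })
    return pd.DataFrame(rows), {"stage_logs": logs}


def repro_battery(table: pd.DataFrame) -> pd.DataFrame:
    """ICC, CoV and difference tests per metric x design.

    Mirrors the layout of a reproducibility report: one row per
    (metric, design) with ICC (+95% CI, band), CoV (%), and the paired-t
    (intra/rescan) or ANOVA (inter) p-value.
    """
    out = []
    for metric in sorted(table["metric"].unique()):
        for design in ("intra", "inter", "rescan"):
            try:
                x = design_matrix(table, design, metric)
            except ValueError:
                continue
            r_icc = icc(table, design, metric)
            r_cov = cov(table, design, metric)
            if design == "inter":
                r_diff = one_way_anova([x[:, j] for j in range(x.shape[1])])
            else:
                r_diff = paired_t(x[:, 0], x[:, 1])
            out.append({
                "metric": metric, "design": design,
                "icc": r_icc.estimate, "icc_ci_low": r_icc.ci_low,
                "icc_ci_high": r_icc.ci_high, "icc_p": r_icc.p_value,
                "icc_category": r_icc.category,
                "cov_pct": r_cov.estimate,
                "diff_stat": r_diff.estimate, "diff_p": r_diff.p_value,
                "diff_test": r_diff.statistic,
            })
    return pd.DataFrame(out)


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the selected stages; returns the run directory."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_dict = cfg.to_dict()
    cfg_json = json.dumps(cfg_dict, sort_keys=True)
    manifest = {
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "versions": {"dcerepro": __version__, "numpy": np.__version__},
        "failure_counts": {},
    }

    # single-subject exemplar artifacts for the imaging stages
    het = HeterogeneityConfig(**{k: tuple(v) if isinstance(v, list) else v
                                 for k, v in cfg.heterogeneity.items()})
    meta = study_protocol(relaxivity=cfg.relaxivity)
    if "simulate" in cfg.stages:
        phantom = make_phantom(tuple(cfg.shape), het, seed=cfg.seed + 1000)
        series = simulate_series(phantom, meta, cfg.noise_sigma,
                                 cfg.noise_kind, seed=cfg.seed + 7932)
        dio.save_phantom(phantom, outdir)
        dio.save_series(series, outdir / "series")
    if "t1fit" in cfg.stages:
        t1map = fit_vfa_t1(series.vfa_signals, meta)
        dio.save_t1map(t1map, outdir)
        manifest["failure_counts"]["t1fit"] = t1map.n_failed
    if "conc" in cfg.stages:
        conc = to_concentration(series, t1map, cfg.relaxivity)
        dio.save_map(conc.conc, outdir / "concentration.nii")
        manifest["failure_counts"]["conc"] = conc.n_failed
    if "fit" in cfg.stages:
        aif = AIFModel(dose_D=cfg.aif["dose_D"],
                       amplitudes=tuple(cfg.aif["amplitudes"]),
                       rates=tuple(cfg.aif["rates"]),
                       onset_time=meta.bolus_time)
        pmap = fit_map(conc, phantom.roi_mask, aif,
                       FitConfig(**{k: tuple(v) if isinstance(v, list) else v
                                    for k, v in cfg.fit.items()}))
        dio.save_parameter_map(pmap, outdir)
        manifest["failure_counts"]["fit"] = \
            int(phantom.roi_mask.sum()) - pmap.n_converged
    if "histogram" in cfg.stages:
        hist = {}
        for param in PARAMS:
            m = roi_metrics(getattr(pmap, param), phantom.roi_mask, param,
                            cfg.thresholds, cfg.n_bins)
            hist[param] = m.as_dict()
            pd.DataFrame({"bin_left": m.bin_edges[:-1],
                          "bin_right": m.bin_edges[1:],
                          "count": m.bin_counts}).to_csv(
                outdir / f"histogram_{param}.csv", index=False)
        dio.save_json(hist, outdir / "histogram_metrics.json")
    if "repro" in cfg.stages:
        table, log = measurement_table_from_maps(cfg)
        dio.save_table(table, outdir / "measurements.csv")
        results = repro_battery(table)
        dio.save_table(results, outdir / "repro_results.csv")
        manifest["failure_counts"]["repro_stage_logs"] = log["stage_logs"]

    dio.save_json(manifest, outdir / "manifest.json")
    return outdir
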