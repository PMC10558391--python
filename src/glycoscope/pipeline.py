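"""Configuration layer wiring generation -> preprocessing -> classification ->
ratio analysis -> AFM analysis into one reproducible, seeded run."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, afm, chemometrics, multiphoton, spectra, synthetic

__all__ = ["RunConfig", "RunReport", "PipelineError", "run_all", "validate_config"]

log = logging.getLogger("glycoscope")


class PipelineError(RuntimeError):
    """A stage failure carrying the stage name and the underlying cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RamanStageConfig:
    n_per_class: int = 100
    days: tuple = (10, 20, 30)
    cv_k: int = 5
    n_components: int = 10
    crop_lo: float = 800.0
    crop_hi: float = 1750.0
    anchor: float = 1451.0
    half_window: float = 5.0
    basis: str = "hats"
    n_background: int = 5
    noise_sd: float = 0.01


@dataclass
class ImageStageConfig:
    size_px: int = 512  # demo default; the acquisition-scale value is 2048
    n_images_per_cell: int = 2
    days: tuple = (10, 20, 30)
    n_rois: int = 10
    roi_size: int = 100
    noise_sd: float = 5.0


@dataclass
class AfmStageConfig:
    size_px: int = 256  # demo default; the acquisition-scale value is 512
    n_images: int = 4
    n_profiles: int = 6
    d_period_nm: float = 63.8
    flatten: tuple = ("plane", "line", "poly2", "zero_min")


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "glycoscope_run"
    raman: RamanStageConfig = field(default_factory=RamanStageConfig)
    images: ImageStageConfig = field(default_factory=ImageStageConfig)
    afm: AfmStageConfig = field(default_factory=AfmStageConfig)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = dict(d)
        for name, sub in (("raman", RamanStageConfig), ("images", ImageStageConfig),
                          ("afm", AfmStageConfig)):
            if name in kwargs and isinstance(kwargs[name], dict):
                block = dict(kwargs[name])
                for key in ("days", "flatten"):
                    if key in block and isinstance(block[key], list):
                        block[key] = tuple(block[key])
                kwargs[name] = sub(**block)
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
        return cls.from_dict(data or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunReport:
    version: str
    config: dict
    ratio_table: pd.DataFrame
    cv_reports: dict  # day -> CVReport
    roughness: dict  # condition -> RoughnessResult
    d_period: dict  # condition -> pooled mean nm
    artifacts: dict  # logical name -> file path

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "config": self.config,
            "ratio_table": self.ratio_table.to_dict(orient="records"),
            "cv_reports": {str(d): r.to_dict() for d, r in self.cv_reports.items()},
            "roughness": {
                k: {"rms_nm": list(v.rms_nm), "mean_nm": v.mean_nm, "sd_nm": v.sd_nm}
                for k, v in self.roughness.items()
            },
            "d_period": self.d_period,
            "artifacts": {k: str(v) for k, v in self.artifacts.items()},
        }


def validate_config(cfg: RunConfig) -> list[str]:
    """Check every stage's preconditions; returns a list of problems (empty = OK)."""
    problems = []
    if not isinstance(cfg.seed, (int, np.integer)):
        problems.append("seed must be an integer")
    r, im, af = cfg.raman, cfg.images, cfg.afm
    if r.n_per_class < 1:
        problems.append("raman.n_per_class must be >= 1")
    if r.cv_k < 2:
        problems.append("raman.cv_k must be >= 2")
    if r.n_per_class < r.cv_k:
        problems.append("raman.n_per_class must be >= raman.cv_k (stratified folds)")
    if r.n_components < 1:
        problems.append("raman.n_components must be >= 1")
    if not r.crop_lo < r.crop_hi:
        problems.append("raman.crop_lo must be < raman.crop_hi")
    if not r.crop_lo <= r.anchor <= r.crop_hi:
        problems.append("raman.anchor must lie inside the crop interval")
    if r.noise_sd < 0:
        problems.append("raman.noise_sd must be non-negative")
    if r.basis not in ("hats", "poly"):
        problems.append("raman.basis must be 'hats' or 'poly'")
    if im.roi_size > im.size_px:
        problems.append("images.roi_size must not exceed images.size_px")
    if im.size_px < 100:
        problems.append("images.size_px must be >= 100")
    if im.n_rois < 1 or im.n_images_per_cell < 1:
        problems.append("images.n_rois and n_images_per_cell must be >= 1")
    if im.noise_sd < 0:
        problems.append("images.noise_sd must be non-negative")
    if af.n_images < 2:
        problems.append("afm.n_images must be >= 2 (mean/sd summary)")
    if af.d_period_nm <= 2 * (2500.0 / af.size_px):
        problems.append("afm.d_period_nm violates Nyquist for the configured pixel size")
    unknown = [s for s in af.flatten if s not in ("plane", "line", "poly2", "zero_min")]
    if unknown:
        problems.append(f"afm.flatten contains unknown steps {unknown}")
    return problems


def _stage(name):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - rewrapped with stage context
            raise PipelineError(name, exc) from exc

    return wrap


def run_all(cfg: RunConfig) -> RunReport:
    """Execute every stage, writing all artifacts under ``cfg.out_dir``."""
    problems = validate_config(cfg)
    if problems:
        raise PipelineError("validate", ValueError("; ".join(problems)))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.default_rng(cfg.seed).integers(2**31, size=8)
    artifacts: dict = {}

    # --- Raman: generate per day, preprocess, classify -------------------
    cv_reports = {}
    for i, day in enumerate(cfg.raman.days):
        def raman_stage(day=day, i=i):
            gen_cfg = synthetic.RamanGenConfig(noise_sd=cfg.raman.noise_sd,
                                               seed=int(seeds[0]) + i)
            ds = synthetic.generate_raman_dataset(
                gen_cfg, synthetic.default_presets(day), cfg.raman.n_per_class
            )
            spectra.write_spectra_csv(ds, out / f"raman_day{day}.csv",
                                      out / f"raman_day{day}_labels.csv")
            pre, fitlog = spectra.preprocess_dataset(
                ds, synthetic.untreated_reference(gen_cfg),
                lo=cfg.raman.crop_lo, hi=cfg.raman.crop_hi,
                n_background=cfg.raman.n_background, basis_kind=cfg.raman.basis,
                anchor=cfg.raman.anchor, half_window=cfg.raman.half_window,
            )
            fitlog.to_csv(out / f"raman_day{day}_emsc_log.csv", index=False)
            report = chemometrics.kfold_cv(
                pre, K=cfg.raman.cv_k, n_components=cfg.raman.n_components,
                seed=int(seeds[1]) + i,
            )
            model = chemometrics.fit_plslda(pre, n_components=cfg.raman.n_components)
            load = chemometrics.ld_loadings(model)
            pd.DataFrame(
                load.loadings.T,
                columns=[f"LD{j + 1}" for j in range(load.loadings.shape[0])],
            ).assign(wavenumber_cm1=load.wavenumbers).to_csv(
                out / f"ld_loadings_day{day}.csv", index=False
            )
            scores = model.transform(pre.intensities)
            pd.DataFrame(
                scores, columns=[f"LD{j + 1}" for j in range(scores.shape[1])]
            ).assign(concentration_mM=pre.labels["concentration_mM"]).to_csv(
                out / f"ld_scores_day{day}.csv", index=False
            )
            (out / f"cv_report_day{day}.json").write_text(json.dumps(report.to_dict(), indent=2))
            pd.DataFrame(report.confusion, index=report.classes,
                         columns=report.classes).to_csv(out / f"confusion_day{day}.csv")
            return report

        cv_reports[day] = _stage("classify")(raman_stage)
        log.info("day %d CV accuracy %.3f", day, cv_reports[day].accuracy)

    # --- TPEF/SHG images and ratio series --------------------------------
    def image_stage():
        entries = []
        k = 0
        for day in cfg.images.days:
            for conc in synthetic.CONCENTRATIONS_MM:
                preset = synthetic.glycation_preset(conc, day)
                for _ in range(cfg.images.n_images_per_cell):
                    icfg = synthetic.ImageGenConfig(
                        size_px=cfg.images.size_px, noise_sd=cfg.images.noise_sd,
                        seed=int(seeds[2]) + k,
                    )
                    entries.append((conc, day, synthetic.generate_image_pair(
                        synthetic.calibrate_channels(icfg), preset)))
                    k += 1
        table = multiphoton.ratio_series(
            entries, n_rois=cfg.images.n_rois, roi_size=cfg.images.roi_size,
            seed=int(seeds[3]),
        )
        table.to_csv(out / "ratio_series.csv", index=False)
        return table

    ratio_table = _stage("ratios")(image_stage)

    # --- AFM topographies -------------------------------------------------
    def afm_stage():
        roughness, d_period = {}, {}
        for cond, conc in (("untreated", 0), ("glycated_200mM", 200)):
            preset = synthetic.glycation_preset(conc, 30)
            topos = []
            for j in range(cfg.afm.n_images):
                tcfg = synthetic.TopoGenConfig(
                    size_px=cfg.afm.size_px, pixel_nm=2500.0 / cfg.afm.size_px,
                    d_period_nm=cfg.afm.d_period_nm,
                    background_rms_nm=preset.roughness_rms_nm,
                    seed=int(seeds[4]) + 10 * (conc == 200) + j,
                )
                topo = synthetic.generate_topography(tcfg)
                afm.write_topography(topo, out / f"topo_{cond}_{j}.txt")
                topos.append(afm.flatten_chain(topo, cfg.afm.flatten))
            roughness[cond] = afm.roughness_summary(topos)
            # D-period from a dedicated low-roughness banded scan per condition
            band_cfg = synthetic.TopoGenConfig(
                size_px=cfg.afm.size_px, pixel_nm=2500.0 / cfg.afm.size_px,
                d_period_nm=cfg.afm.d_period_nm, background_rms_nm=0.3,
                seed=int(seeds[5]) + (conc == 200),
            )
            banded = afm.flatten_chain(synthetic.generate_topography(band_cfg), cfg.afm.flatten)
            profiles = [afm.extract_profile(banded, line)
                        for line in synthetic.along_fiber_lines(banded, n=cfg.afm.n_profiles)]
            results = [afm.d_periods(p) for p in profiles]
            d_period[cond] = afm.mean_d_period(results)
        (out / "afm_results.json").write_text(json.dumps(
            {
                "roughness": {k: {"rms_nm": list(v.rms_nm), "mean_nm": v.mean_nm,
                                  "sd_nm": v.sd_nm} for k, v in roughness.items()},
                "d_period_nm": d_period,
            }, indent=2))
        return roughness, d_period

    roughness, d_period = _stage("afm")(afm_stage)

    report = RunReport(
        version=__version__,
        config=cfg.to_dict(),
        ratio_table=ratio_table,
        cv_reports=cv_reports,
        roughness=roughness,
        d_period=d_period,
        artifacts=artifacts,
    )
    (out / "report.json").write_text(json.dumps(report.to_dict(), indent=2, default=float))
    return report
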