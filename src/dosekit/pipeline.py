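"""Study orchestration: config, sanity checks, checkpoints, reports.

A study is described by one YAML config (inputs, calibration, nuclide,
fitting and dose-engine choices, seed).  ``run_pipeline`` executes
quantify -> kinetics -> dose, writing a checkpoint after each stage so a
study can be resumed or re-run stage by stage; a re-run with the same
config and seed is deterministic.  ``compare_runs`` reproduces the
dispersion statistics (mean / range / SD / relative SD of masses, TIACs
and mean doses) used to compare dosimetry platforms, applied here to this
package's engine and model variants.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import kinetics as kin
from . import phantom as ph
from .dose import DoseKernel, DoseReport, SValueTable, build_water_kernel, dvh as compute_dvh, dvk_dose, led_dose, mean_organ_doses, svalue_dose
from .errors import ConfigurationError, DosekitError, SpecificationError
from .quantify import build_tac, samples_to_frame, voi_activity
from .units import AcquisitionMeta, CalibrationFactor, InjectedActivity, Radionuclide, load_nuclide
from .volumes import ImageVolume, LabelMap

log = logging.getLogger("dosekit.pipeline")

STAGES = ("calibrated", "quantified", "fitted", "dosed")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class StudyConfig:
    """Validated, fully serializable description of one dosimetry run."""

    raw: dict
    nuclide: Radionuclide
    a0: InjectedActivity
    calibration: CalibrationFactor
    acquisition: AcquisitionMeta
    fit_model: str = "monoexp"           # monoexp | biexp | powerexp | trapezoid_tail | auto
    head_rule: str = "zero_line"
    tail_rate_per_h: Optional[float] = None   # None -> physical decay of the nuclide
    engines: Tuple[str, ...] = ("led",)
    tia_map_mode: str = "organ_fit"      # organ_fit | voxel_trapezoid
    kernel_radius_voxels: int = 3
    kernel_scale_mm: float = 0.3
    svalue_table_path: Optional[str] = None
    compute_dvh: bool = False
    dvh_bin_Gy: float = 0.01
    phantom_spec: Optional[ph.PhantomSpec] = None
    volume_paths: Tuple[str, ...] = ()
    label_path: Optional[str] = None
    output_dir: Path = Path("dosekit_out")
    seed: int = 0

    @classmethod
    def from_dict(cls, cfg: dict, seed: Optional[int] = None) -> "StudyConfig":
        try:
            nuc_cfg = cfg["nuclide"]
            if "half_life_h" in nuc_cfg:
                nuclide = Radionuclide(
                    nuc_cfg.get("name", "custom"),
                    float(nuc_cfg["half_life_h"]),
                    nuc_cfg.get("energy_per_decay_j"),
                )
            else:
                nuclide = load_nuclide(nuc_cfg["name"], nuc_cfg.get("energy_per_decay_j"))
            acq_cfg = cfg["acquisition"]
            acquisition = AcquisitionMeta(
                int(acq_cfg["n_projections"]), float(acq_cfg["seconds_per_projection"])
            )
            cal_cfg = cfg["calibration"]
            cal_ctx = cal_cfg.get("context", acq_cfg)
            calibration = CalibrationFactor(
                float(cal_cfg["magnitude"]),
                cal_cfg["unit_kind"],
                AcquisitionMeta(
                    int(cal_ctx["n_projections"]), float(cal_ctx["seconds_per_projection"])
                ),
            )
            a0 = InjectedActivity(float(cfg["a0_MBq"]))
        except KeyError as exc:
            raise ConfigurationError(f"missing config key: {exc}") from exc

        the_seed = int(seed if seed is not None else cfg.get("seed", 0))
        phantom_spec = None
        if "phantom" in cfg:
            pcfg = dict(cfg["phantom"])
            if pcfg.pop("preset", "default_abdominal") != "default_abdominal":
                raise ConfigurationError("unknown phantom preset")
            phantom_spec = ph.default_abdominal_spec(
                nuclide=nuclide, noise=pcfg.pop("noise", "none"), seed=the_seed
            )
            if "a0_MBq" in pcfg:
                phantom_spec.a0_MBq = float(pcfg.pop("a0_MBq"))
            if "sensitivity_cps_per_MBq" in pcfg:
                phantom_spec.sensitivity_cps_per_MBq = float(
                    pcfg.pop("sensitivity_cps_per_MBq")
                )
            if pcfg:
                raise ConfigurationError(f"unknown phantom keys: {sorted(pcfg)}")

        fit_cfg = cfg.get("fit", {})
        dose_cfg = cfg.get("dose", {})
        obj = cls(
            raw=cfg,
            nuclide=nuclide,
            a0=a0,
            calibration=calibration,
            acquisition=acquisition,
            fit_model=fit_cfg.get("model", "monoexp"),
            head_rule=fit_cfg.get("head_rule", "zero_line"),
            tail_rate_per_h=fit_cfg.get("tail_rate_per_h"),
            engines=tuple(dose_cfg.get("engines", ["led"])),
            tia_map_mode=dose_cfg.get("tia_map", "organ_fit"),
            kernel_radius_voxels=int(dose_cfg.get("kernel_radius_voxels", 3)),
            kernel_scale_mm=float(dose_cfg.get("kernel_scale_mm", 0.3)),
            svalue_table_path=dose_cfg.get("svalue_table"),
            compute_dvh=bool(dose_cfg.get("dvh", False)),
            dvh_bin_Gy=float(dose_cfg.get("dvh_bin_Gy", 0.01)),
            phantom_spec=phantom_spec,
            volume_paths=tuple(cfg.get("volumes", [])),
            label_path=cfg.get("labels"),
            output_dir=Path(cfg.get("output_dir", "dosekit_out")),
            seed=the_seed,
        )
        obj.validate()
        return obj

    @classmethod
    def from_yaml(cls, path, seed: Optional[int] = None) -> "StudyConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()), seed=seed)

    def validate(self) -> None:
        if self.fit_model not in ("auto",) + kin.FIT_FAMILIES:
            raise ConfigurationError(f"unknown fit model {self.fit_model!r}")
        for engine in self.engines:
            if engine not in ("led", "dvk", "svalue"):
                raise ConfigurationError(f"unknown dose engine {engine!r}")
        if self.tia_map_mode not in ("organ_fit", "voxel_trapezoid"):
            raise ConfigurationError(f"unknown tia_map mode {self.tia_map_mode!r}")
        if self.phantom_spec is None and not self.volume_paths:
            raise ConfigurationError("config needs either a phantom or volume paths")
        if "svalue" in self.engines and not self.svalue_table_path:
            raise ConfigurationError("svalue engine needs dose.svalue_table")

    def config_hash(self) -> str:
        canon = json.dumps(
            {"cfg": self.raw, "seed": self.seed}, sort_keys=True, default=str
        )
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# sanity checks
# ---------------------------------------------------------------------------

@dataclass
class SanityReport:
    passed: bool
    findings: List[str] = field(default_factory=list)

    def __str__(self) -> str:
        status = "PASS" if self.passed else "FAIL"
        lines = [f"sanity check: {status} ({len(self.findings)} finding(s))"]
        lines += [f"  - {f}" for f in self.findings]
        return "\n".join(lines)


def sanity_check(
    config: StudyConfig,
    volumes: Optional[Sequence[ImageVolume]] = None,
    labels: Optional[LabelMap] = None,
) -> SanityReport:
    """Verify a study is internally consistent before running anything.

    Checks shared geometry across time points and with the label map,
    strictly increasing acquisition times, positive durations, calibration
    unit consistency, and label-catalogue completeness.  Always returns a
    report; the pipeline refuses to run when it fails.
    """
    findings: List[str] = []
    if config.acquisition.total_duration_s <= 0:
        findings.append("acquisition duration is not positive")
    try:
        config.calibration.sensitivity_cps_per_MBq()
    except DosekitError as exc:
        findings.append(f"calibration factor unusable: {exc}")

    if volumes is None and config.phantom_spec is None:
        for path in config.volume_paths:
            if not Path(path).exists():
                findings.append(f"volume file missing: {path}")
    if volumes:
        ref = volumes[0]
        for i, vol in enumerate(volumes[1:], start=1):
            if not ref.same_geometry(vol):
                name = config.volume_paths[i] if i < len(config.volume_paths) else f"#{i}"
                findings.append(f"voxel geometry of time point {name} differs from reference")
        times = [v.time_post_injection_h for v in volumes]
        if any(t is None for t in times):
            findings.append("a time point lacks time-post-injection metadata")
        else:
            if sorted(times) != list(times):
                findings.append("acquisition times are not increasing")
            if len(set(times)) != len(times):
                dup = sorted({t for t in times if times.count(t) > 1})
                findings.append(f"duplicate time points: {dup}")
        if labels is not None:
            if not labels.same_geometry(ref):
                findings.append("label map geometry differs from volumes")
            present = set(np.unique(labels.data)) - {0}
            missing = present - set(labels.catalogue)
            if missing:
                findings.append(f"labels without catalogue entry: {sorted(missing)}")
    return SanityReport(passed=not findings, findings=findings)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    config: StudyConfig
    samples_frame: pd.DataFrame
    fit_results: Dict[int, kin.FitResult]
    reports: Dict[str, DoseReport]
    table: pd.DataFrame              # organ x engine summary, written to disk
    ground_truth: Optional[ph.GroundTruth] = None


def _load_inputs(config: StudyConfig):
    if config.phantom_spec is not None:
        study = ph.simulate_timepoints(config.phantom_spec)
        return list(study.counts), study.label_map, study.density, study.ground_truth
    volumes = [ImageVolume.load(p, kind="counts") for p in config.volume_paths]
    if config.label_path is None:
        raise ConfigurationError("volume inputs need a label map path")
    labels = LabelMap.load(config.label_path)
    density = _density_from_labels(labels)
    return volumes, labels, density, None


def _density_from_labels(labels: LabelMap, background_gcc: float = 1.0) -> ImageVolume:
    density = np.full(labels.data.shape, background_gcc)
    for lab in labels.labels():
        density[labels.data == lab] = labels.organ(lab).density_gcc
    return ImageVolume(density, labels.spacing, "density_gcc")


def _fit_one(config: StudyConfig, tac: kin.TimeActivityCurve) -> kin.FitResult:
    tail = config.tail_rate_per_h
    if tail is None:
        tail = config.nuclide.decay_constant_per_h
    if config.fit_model == "auto":
        return kin.auto_select(tac, head_rule=config.head_rule, tail_rate_per_h=tail)
    if config.fit_model == "monoexp":
        return kin.fit_monoexp(tac)
    if config.fit_model == "biexp":
        return kin.fit_biexp(tac)
    if config.fit_model == "powerexp":
        return kin.fit_powerexp(tac)
    return kin.integrate_trapezoid_tail(tac, head_rule=config.head_rule, tail_rate_per_h=tail)


def _organ_fit_tia_map(
    labels: LabelMap, fits: Dict[int, kin.FitResult]
) -> ImageVolume:
    """Uniform per-organ TIA map from organ-level fits (MBq.h per voxel)."""
    tia = np.zeros(labels.data.shape)
    for lab, res in fits.items():
        mask = labels.data == lab
        n = int(mask.sum())
        if n:
            tia[mask] = res.tia_MBqh / n
    return ImageVolume(tia, labels.spacing, "TIA_MBqh")


class _Checkpointer:
    """JSON checkpoints per stage keyed on the config hash."""

    def __init__(self, config: StudyConfig):
        self.dir = Path(config.output_dir) / "checkpoints"
        self.hash = config.config_hash()

    def path(self, stage: str) -> Path:
        return self.dir / f"{stage}.json"

    def load(self, stage: str) -> Optional[dict]:
        p = self.path(stage)
        if not p.exists():
            return None
        payload = json.loads(p.read_text())
        if payload.get("config_hash") != self.hash:
            return None
        return payload["data"]

    def save(self, stage: str, data: dict) -> None:
        self.dir.mkdir(parents=True, exist_ok=True)
        payload = {
            "stage": stage,
            "config_hash": self.hash,
            "written_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "data": data,
        }
        self.path(stage).write_text(json.dumps(payload, indent=2, sort_keys=True))


def run_pipeline(
    config: StudyConfig,
    stop_after: str = "dosed",
    resume: bool = False,
) -> PipelineResult:
    """Execute quantify -> kinetics -> dose for one study config.

    ``stop_after`` truncates the run at a stage boundary; with ``resume``
    stages whose checkpoint matches the config hash are loaded instead of
    recomputed.  Outputs (per-organ table, fit reports, checkpoints) land
    under ``config.output_dir``.
    """
    if stop_after not in STAGES:
        raise ConfigurationError(f"unknown stage {stop_after!r}")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    ckpt = _Checkpointer(config)
    t0 = time.time()

    volumes, labels, density, gt = _load_inputs(config)
    report = sanity_check(config, volumes, labels)
    if not report.passed:
        raise SpecificationError(f"sanity check failed:\n{report}")

    # stage: calibrated -- tie the calibration factor to the patient duration
    cf_patient = config.calibration.rescale_for_duration(config.acquisition)
    ckpt.save(
        "calibrated",
        {
            "sensitivity_cps_per_MBq": cf_patient.sensitivity_cps_per_MBq(),
            "mbq_per_count_patient": cf_patient.mbq_per_count(),
        },
    )
    log.info("calibrated in %.2fs", time.time() - t0)
    if stop_after == "calibrated":
        return PipelineResult(config, pd.DataFrame(), {}, {}, pd.DataFrame(), gt)

    # stage: quantified
    cached = ckpt.load("quantified") if resume else None
    if cached is not None:
        frame = pd.DataFrame(cached["samples"])
    else:
        samples = []
        for vol in volumes:
            acq = config.acquisition.at_time(vol.time_post_injection_h)
            samples.extend(voi_activity(vol, labels, config.calibration, acq))
        frame = samples_to_frame(samples)
        ckpt.save("quantified", {"samples": frame.to_dict(orient="records")})
    frame.to_csv(out / "organ_samples.csv", index=False)
    log.info("quantified in %.2fs", time.time() - t0)
    if stop_after == "quantified":
        return PipelineResult(config, frame, {}, {}, pd.DataFrame(), gt)

    # stage: fitted
    from .quantify import OrganSample  # deserialize for build_tac

    sample_objs = [
        OrganSample(int(r.label), r.organ, float(r.time_h), float(r.activity_MBq),
                    int(r.voxel_count), float(r.mass_g))
        for r in frame.itertuples()
    ]
    tacs = build_tac(sample_objs, config.a0)
    fits = {lab: _fit_one(config, tac) for lab, tac in tacs.items()}
    ckpt.save("fitted", {str(lab): res.to_dict() for lab, res in fits.items()})
    (out / "fits.json").write_text(
        json.dumps({tacs[lab].name: res.to_dict() for lab, res in fits.items()}, indent=2)
    )
    log.info("fitted in %.2fs", time.time() - t0)
    if stop_after == "fitted":
        return PipelineResult(config, frame, fits, {}, pd.DataFrame(), gt)

    # stage: dosed
    masses = {lab: float(frame[frame.label == lab].mass_g.iloc[0]) for lab in tacs}
    names = {lab: tacs[lab].name for lab in tacs}
    if config.tia_map_mode == "voxel_trapezoid":
        mbq_per_count = config.calibration.mbq_per_count(config.acquisition)
        activity_maps = [
            v.with_data(v.data * mbq_per_count, kind="activity_MBq") for v in volumes
        ]
        tail = config.tail_rate_per_h or config.nuclide.decay_constant_per_h
        tia_map = kin.voxel_tia_map(activity_maps, config.head_rule, tail)
    else:
        tia_map = _organ_fit_tia_map(labels, fits)

    reports: Dict[str, DoseReport] = {}
    for engine in config.engines:
        dose_map = None
        if engine == "led":
            dose_map = led_dose(tia_map, density, config.nuclide)
            organ_doses = mean_organ_doses(dose_map, labels)
        elif engine == "dvk":
            kernel = build_water_kernel(
                config.nuclide, tia_map.spacing, config.kernel_radius_voxels,
                scale_mm=config.kernel_scale_mm,
            )
            dose_map = dvk_dose(tia_map, kernel, density)
            organ_doses = mean_organ_doses(dose_map, labels)
        else:  # svalue
            table = SValueTable.from_csv(config.svalue_table_path)
            tiacs = {names[lab]: fits[lab].tiac_h for lab in fits}
            patient_masses = {names[lab]: masses[lab] for lab in fits}
            by_name = svalue_dose(tiacs, config.a0.a0_MBq, table, patient_masses)
            organ_doses = {lab: by_name[names[lab]] for lab in fits}
        rows = pd.DataFrame(
            [
                {
                    "organ": names[lab],
                    "label": lab,
                    "mass_g": masses[lab],
                    "tiac_h": fits[lab].tiac_h,
                    "mean_dose_Gy": organ_doses[lab],
                }
                for lab in sorted(fits)
            ]
        )
        rep = DoseReport(engine, rows, dose_map=dose_map)
        if config.compute_dvh and dose_map is not None:
            for lab in sorted(fits):
                rep.dvhs[lab], _ = compute_dvh(dose_map, labels, lab, config.dvh_bin_Gy)
        if dose_map is not None:
            dose_map.save(out / f"dose_{engine}.nii.gz")
        rep.to_csv(out / f"dose_report_{engine}.csv")
        reports[engine] = rep

    table = pd.concat(
        [r.rows.assign(engine=e) for e, r in reports.items()], ignore_index=True
    )[["engine", "organ", "label", "mass_g", "tiac_h", "mean_dose_Gy"]]
    table.to_csv(out / "summary.csv", index=False)
    ckpt.save("dosed", {"table": table.to_dict(orient="records")})
    log.info("dosed in %.2fs", time.time() - t0)
    return PipelineResult(config, frame, fits, reports, table, gt)


# ---------------------------------------------------------------------------
# run comparison (dispersion statistics)
# ---------------------------------------------------------------------------

def compare_runs(reports: Sequence[DoseReport]) -> pd.DataFrame:
    """Per-organ dispersion of masses, TIACs and mean doses across reports.

    Returns one row per (organ, quantity) with mean, min, max, sample SD
    (n-1 denominator) and relative SD in percent.  All reports must cover
    the same organ set.
    """
    if len(reports) < 2:
        raise ConfigurationError("compare_runs needs at least two reports")
    organ_sets = [set(r.rows.organ) for r in reports]
    if any(s != organ_sets[0] for s in organ_sets[1:]):
        diff = set.union(*organ_sets) - set.intersection(*organ_sets)
        raise ConfigurationError(f"reports cover different organs: {sorted(diff)}")
    rows = []
    for organ in sorted(organ_sets[0]):
        for quantity in ("mass_g", "tiac_h", "mean_dose_Gy"):
            vals = np.array(
                [float(r.rows.set_index("organ").loc[organ, quantity]) for r in reports]
            )
            mean = vals.mean()
            sd = vals.std(ddof=1)
            rows.append(
                {
                    "organ": organ,
                    "quantity": quantity,
                    "n": len(vals),
                    "mean": mean,
                    "min": vals.min(),
                    "max": vals.max(),
                    "sd": sd,
                    "rsd_percent": 100.0 * sd / mean if mean != 0 else np.nan,
                }
            )
    return pd.DataFrame(rows)
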