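"""Configuration-driven end-to-end run: cohorts → maps → features → models → risk.

``run_pipeline`` executes the full analysis on synthetic cohorts:

1. generate a porcine-style imaging cohort, render multi-echo volumes to
   NIfTI, refit T2* maps and extract features (skippable via
   ``imaging=False``, in which case features come straight from the
   ground-truth maps);
2. subject-stratified split, RFE-CV feature selection, RS-CV→GS-CV
   optimization of every requested model family, test-set MAE and a paired
   comparison of the best ML family against the linear benchmark;
3. generate the clinical-style cohort, harmonize per scanner, predict with
   the winning model using the frozen porcine standardization reference,
   min-max score, Youden-J dichotomize and compute revision statistics.

Every invocation creates a fresh run directory (never overwritten) holding
the config, a manifest (seeds, package versions), CSV feature tables, the
serialized winning model and a human-readable report.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import features as feat
from . import model_lab, risk_strat, synthgen
from .relaxometry import MultiEchoVolume, ValidationError, fit_t2star_map

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All knobs of an end-to-end run; round-trips through YAML unchanged."""

    seed: int = 0
    out_root: str = "runs"
    # synthetic cohorts
    n_subjects: int = 65
    n_clinical: int = 46
    volume_shape: tuple[int, int, int] = (24, 24, 40)
    voxel_size: tuple[float, float, float] = (0.5, 0.5, 0.8)
    noise_sd: float = 10.0
    # stages
    imaging: bool = True          # render volumes and refit T2* maps
    families: tuple[str, ...] = ("LM", "RF")
    fit_method: str = "nonlinear"
    # model lab
    test_fraction: float = 0.2
    n_random: int = 20
    k_folds: int = 5
    n_boot: int = 2000
    rfe_min_features: int = 3
    rfe_trees: int = 300

    def __post_init__(self) -> None:
        bad = [f for f in self.families if f not in model_lab.FAMILIES]
        if bad:
            raise ValidationError(f"unknown model families {bad}")
        if "LM" not in self.families:
            raise ValidationError("the LM benchmark must be among the families")

    def to_yaml(self, path: str | Path) -> Path:
        Path(path).write_text(yaml.safe_dump(asdict(self)))
        return Path(path)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        for key in ("volume_shape", "voxel_size", "families"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _new_run_dir(root: str | Path) -> Path:
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    stamp = time.strftime("%Y%m%d-%H%M%S")
    for i in range(10_000):
        cand = root / (f"run_{stamp}" if i == 0 else f"run_{stamp}-{i}")
        try:
            cand.mkdir(exist_ok=False)
            return cand
        except FileExistsError:
            continue
    raise RuntimeError("could not allocate a fresh run directory")


def _porcine_features(cfg: PipelineConfig, run_dir: Path) -> pd.DataFrame:
    """Porcine feature table, via imaging round trip or directly from maps."""
    synth_cfg = synthgen.SynthCohortConfig(
        n_subjects=cfg.n_subjects,
        volume_shape=cfg.volume_shape,
        voxel_size=cfg.voxel_size,
        noise_sd=cfg.noise_sd,
        seed=cfg.seed,
    )
    if not cfg.imaging:
        table = synthgen.generate_porcine_cohort(synth_cfg, seed=cfg.seed)
        table.to_csv(run_dir / "porcine_features.csv", index=False)
        return table

    raw = synthgen.write_imaging_cohort(
        run_dir / "porcine_raw", synth_cfg, seed=cfg.seed, cohort="porcine")
    meta = pd.read_csv(raw / "metadata.csv")
    rows = []
    for rec in meta.itertuples():
        limb = "surgical" if rec.limb_type else "contralateral"
        name = f"{rec.subject_id}_{limb}"
        vol = MultiEchoVolume.from_nifti(raw / f"{name}_echo.nii.gz")
        import nibabel as nib

        mask = np.asarray(nib.load(raw / f"{name}_mask.nii.gz").dataobj) > 0
        t2map = fit_t2star_map(vol, mask, method=cfg.fit_method)
        rows.append(feat.extract_features(
            t2map, rec.subject_id, limb,
            timepoint=rec.timepoint, scanner_id=rec.scanner_id,
            failure_load=rec.failure_load,
        ))
    table = pd.DataFrame(rows)
    table.to_csv(run_dir / "porcine_features.csv", index=False)
    return table


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage; returns the run directory."""
    run_dir = _new_run_dir(config.out_root)
    config.to_yaml(run_dir / "config.yaml")
    logging.basicConfig(level=logging.INFO)
    report: list[str] = [f"ligload {__version__} pipeline report", ""]
    stage = "synthgen/relaxometry/features"
    try:
        table = _porcine_features(config, run_dir)

        stage = "model_lab"
        train, test = model_lab.split_by_subject(
            table, config.test_fraction, seed=config.seed)
        rfe = model_lab.rfe_cv(
            train, k_folds=config.k_folds,
            min_features=config.rfe_min_features, seed=config.seed,
            n_estimators=config.rfe_trees)
        report += ["RFE-CV feature ranking (most to least important):",
                   "  " + " > ".join(rfe.ranking()),
                   f"  selected: {', '.join(rfe.selected)}", ""]

        evals: dict[str, model_lab.EvaluationResult] = {}
        results: dict[str, model_lab.FailureLoadResults] = {}
        for family in config.families:
            features = None if family == "LM" else rfe.selected
            res = model_lab.FailureLoadModel(
                train, family=family, features=features).fit(
                n_random=config.n_random, k_folds=config.k_folds,
                seed=config.seed)
            results[family] = res
            evals[family] = res.evaluate(test, n_boot=config.n_boot,
                                         seed=config.seed)
        report.append("Test-set mean absolute error (N):")
        for family in config.families:
            e = evals[family]
            report.append(f"  {family:<9s} {e.mae:7.1f}  "
                          f"(95% CI {e.mae_ci[0]:.1f}, {e.mae_ci[1]:.1f})")
        report.append("")

        ml = [f for f in config.families if f != "LM"]
        best = min(ml, key=lambda f: evals[f].mae) if ml else "LM"
        if ml and evals[best].n_test >= 5:
            comp = model_lab.compare_paired(
                evals["LM"].errors, evals[best].errors,
                n_boot=config.n_boot, seed=config.seed)
            report += [f"Best ML family: {best} vs LM benchmark:",
                       f"  {comp}", ""]
        elif ml:
            report += [f"Best ML family: {best}; paired comparison skipped "
                       f"(test set of {evals[best].n_test} < 5 limbs)", ""]
        results[best].save(run_dir / "best_model.joblib")

        stage = "risk_strat"
        clin_cfg = synthgen.clinical_config(
            seed=config.seed + 1,
            n_subjects=config.n_clinical,
            volume_shape=config.volume_shape,
        )
        clinical = synthgen.generate_clinical_cohort(clin_cfg, seed=config.seed + 1)
        clinical.to_csv(run_dir / "clinical_features.csv", index=False)
        harmonized = feat.harmonize_by_scanner(clinical)
        loads = results[best].predict(harmonized)
        strat = risk_strat.RevisionStratification(
            loads, harmonized["revision"].to_numpy()).fit()
        strat.to_yaml(run_dir / "stratification.yaml")
        pd.DataFrame(strat.roc_points, columns=["fpr", "tpr"]).to_csv(
            run_dir / "roc_points.csv", index=False)
        report += [f"Clinical-format cohort stratification ({best} predictions):",
                   *("  " + line for line in strat.summary().splitlines())]
    except Exception as err:
        (run_dir / "FAILED").write_text(f"stage: {stage}\n{err!r}\n")
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {err}") from err

    (run_dir / "report.txt").write_text("\n".join(report) + "\n")
    manifest = {
        "package_version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(
            (run_dir / "config.yaml").read_bytes()).hexdigest(),
    }
    (run_dir / "manifest.yaml").write_text(yaml.safe_dump(manifest))
    return run_dir
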