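"""Seeded synthetic cohorts for the ligament failure-load pipeline.

Real paired imaging/biomechanics data for healing ligaments are not openly
deposited, so this module generates cohorts with the statistical structure
the analysis assumes:

* **Tissue model.**  Per-voxel T2* inside an ellipsoidal ligament mask is a
  two-component mixture: an *organized* collagen component (short T2*,
  ~10 ms) and a *disorganized* component (long T2*, ~35 ms).  Surgical
  (healing) limbs carry a larger disorganized fraction than contralateral
  intact limbs, which raises their mean T2*, raises sub-volume proportion 4
  and shifts Q1 upward.  Subject-level random shifts of the component means
  create between-animal variation.

* **Load model.**  Tensile failure load (N) is linear in limb type, Q1 T2*
  and Prop 4, with one limb×Prop4 interaction (the nonlinearity that lets
  tree ensembles beat a purely linear benchmark), an optional small CSA
  term, and Gaussian residual.  Contralateral limbs are stronger than
  surgical limbs at identical tissue features.

* **Outcome model.**  Revision surgery is a Bernoulli draw whose log-odds
  decrease with true failure load; the intercept is calibrated so that the
  expected cohort incidence matches a configurable target (default 6/46).

All randomness flows from one cohort-level seed through
``numpy.random.SeedSequence.spawn`` — one child per subject, one grandchild
per limb — so any subset of a cohort is reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit

from . import features as feat
from .relaxometry import MultiEchoVolume, T2StarMap, ValidationError

__all__ = [
    "LimbTissue",
    "LoadModel",
    "OutcomeModel",
    "SynthCohortConfig",
    "ConfigurationError",
    "PORCINE_ECHO_TIMES",
    "CLINICAL_ECHO_TIMES",
    "generate_t2star_phantom",
    "render_multi_echo",
    "generate_failure_load",
    "generate_revision_outcomes",
    "generate_porcine_cohort",
    "generate_clinical_cohort",
    "write_imaging_cohort",
]

#: Four-echo porcine protocol echo times (ms).
PORCINE_ECHO_TIMES = (2.8, 7.9, 13.0, 18.0)

#: Six-echo clinical protocols (ms); the two scanners differ in TE_1.
CLINICAL_ECHO_TIMES = {
    "prisma": (2.5, 6.9, 11.2, 15.6, 20.0, 24.4),
    "trio": (3.4, 6.9, 11.2, 15.6, 20.0, 24.4),
}

LIMB_TYPES = ("surgical", "contralateral")


class ConfigurationError(ValueError):
    """Raised when generator coefficients violate a declared constraint."""


@dataclass(frozen=True)
class LimbTissue:
    """Mixture parameters (ms) for one limb type's T2* distribution."""

    organized_mean: float = 10.0
    organized_sd: float = 3.0
    disorganized_mean: float = 35.0
    disorganized_sd: float = 6.0
    #: Beta(a, b) prior for the per-subject disorganized voxel fraction.
    disorg_frac_a: float = 6.0
    disorg_frac_b: float = 10.0
    #: SD of the subject-level shift applied to each component mean.
    subject_shift_sd: float = 0.7
    #: SD of the disorganized-component mean shift; defaults to
    #: 2.5 x subject_shift_sd when None (scar tissue varies more).
    dis_shift_sd: float | None = None
    #: Lognormal SD of the per-subject scale on each component's spread;
    #: decouples quantile features from tail-mass features across subjects.
    spread_jitter: float = 0.45
    #: Ellipsoid semi-axes in mm (x, y, z); z is the long (ligament) axis.
    semi_axes: tuple[float, float, float] = (4.0, 4.0, 14.0)
    #: Lognormal SD of the per-subject scale factors applied to the
    #: transverse semi-axes and to the length (ligament size varies).
    geometry_jitter: float = 0.10


#: Intact limbs: mostly organized tissue, slightly slimmer ligament.
DEFAULT_TISSUE = {
    "surgical": LimbTissue(disorg_frac_a=12.0, disorg_frac_b=20.0,
                           semi_axes=(4.2, 4.2, 11.0)),
    "contralateral": LimbTissue(disorg_frac_a=3.0, disorg_frac_b=34.0,
                                semi_axes=(3.8, 3.8, 11.0)),
}


@dataclass(frozen=True)
class LoadModel:
    """Coefficients linking tissue features to tensile failure load (N).

    ``expected`` must be monotone decreasing in ``q1_t2`` and ``prop4`` for
    fixed limb type, and contralateral limbs (limb code 0) must be stronger
    than surgical (code 1); both are validated.
    """

    intercept: float = 6200.0
    limb_type: float = -1100.0      # surgical penalty, N
    q1_t2: float = -230.0           # N per ms
    prop4: float = -2400.0          # N per unit fraction
    csa: float = 4.0                # N per mm²
    limb_x_prop4: float = -2000.0   # interaction: healing tissue is costlier
    residual_sd: float = 150.0

    def __post_init__(self) -> None:
        if self.q1_t2 > 0 or self.prop4 > 0:
            raise ConfigurationError("load must decrease with q1_t2 and prop4")
        if self.limb_type > 0:
            raise ConfigurationError("surgical limbs cannot be stronger than intact")
        if self.residual_sd < 0:
            raise ConfigurationError("residual_sd must be >= 0")

    #: floor (N) applied to the expected load for rare tail subjects
    floor: float = 50.0

    def expected(self, record: Mapping[str, float]) -> float:
        limb = float(record["limb_type"])
        mu = (
            self.intercept
            + self.limb_type * limb
            + self.q1_t2 * float(record["q1_t2"])
            + self.prop4 * float(record["prop4"])
            + self.csa * float(record.get("csa", 0.0))
            + self.limb_x_prop4 * limb * float(record["prop4"])
        )
        return max(mu, self.floor)

    def validate_at(self, record: Mapping[str, float]) -> None:
        """Configuration check: typical features must give a positive load."""
        limb = float(record["limb_type"])
        mu = (
            self.intercept + self.limb_type * limb
            + self.q1_t2 * float(record["q1_t2"])
            + self.prop4 * float(record["prop4"])
            + self.csa * float(record.get("csa", 0.0))
            + self.limb_x_prop4 * limb * float(record["prop4"])
        )
        if mu <= 0:
            raise ConfigurationError(
                f"load model yields non-positive expected load ({mu:.1f} N) "
                "at typical tissue features"
            )


@dataclass(frozen=True)
class OutcomeModel:
    """Logistic model for revision risk as a function of true failure load.

    ``slope`` is per Newton and must be <= 0 (weaker ligaments fail more).
    If ``intercept`` is None it is calibrated per cohort so the mean revision
    probability equals ``target_incidence``.
    """

    slope: float = -0.004
    intercept: float | None = None
    target_incidence: float = 6.0 / 46.0

    def __post_init__(self) -> None:
        if self.slope > 0:
            raise ConfigurationError("outcome slope must be <= 0")
        if not 0 < self.target_incidence < 1:
            raise ConfigurationError("target_incidence must be in (0, 1)")

    def probabilities(self, loads: np.ndarray) -> np.ndarray:
        loads = np.asarray(loads, dtype=float)
        a = self.intercept
        if a is None:
            target = self.target_incidence

            def excess(a0: float) -> float:
                return float(np.mean(expit(a0 + self.slope * loads))) - target

            a = brentq(excess, -60.0, 60.0 - self.slope * float(loads.max()))
        return expit(a + self.slope * loads)


@dataclass(frozen=True)
class SynthCohortConfig:
    """Everything a cohort draw depends on, in one serializable object."""

    n_subjects: int = 65
    limbs_per_subject: int = 2
    echo_times: tuple[float, ...] = PORCINE_ECHO_TIMES
    volume_shape: tuple[int, int, int] = (24, 24, 40)
    voxel_size: tuple[float, float, float] = (0.5, 0.5, 0.8)
    tissue: Mapping[str, LimbTissue] = field(
        default_factory=lambda: dict(DEFAULT_TISSUE))
    s0: float = 1000.0
    noise_sd: float = 10.0
    load_model: LoadModel = field(default_factory=LoadModel)
    outcome_model: OutcomeModel = field(default_factory=OutcomeModel)
    seed: int = 0

    def __post_init__(self) -> None:
        te = np.asarray(self.echo_times, dtype=float)
        if te.size < 2 or np.any(te <= 0) or np.any(np.diff(te) <= 0):
            raise ValidationError("echo times must be positive and strictly increasing")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.n_subjects < 2:
            raise ValidationError("n_subjects must be >= 2")

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        d = {
            "n_subjects": self.n_subjects,
            "limbs_per_subject": self.limbs_per_subject,
            "echo_times": list(self.echo_times),
            "volume_shape": list(self.volume_shape),
            "voxel_size": list(self.voxel_size),
            "s0": self.s0,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
            "tissue": {k: vars(v) | {"semi_axes": list(v.semi_axes)}
                       for k, v in self.tissue.items()},
            "load_model": vars(self.load_model),
            "outcome_model": vars(self.outcome_model),
        }
        path.write_text(yaml.safe_dump(d))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SynthCohortConfig":
        d = yaml.safe_load(Path(path).read_text())
        tissue = {k: LimbTissue(**(v | {"semi_axes": tuple(v["semi_axes"])}))
                  for k, v in d.pop("tissue", {}).items()} or dict(DEFAULT_TISSUE)
        load = LoadModel(**d.pop("load_model", {}))
        outcome = OutcomeModel(**d.pop("outcome_model", {}))
        return cls(
            tissue=tissue, load_model=load, outcome_model=outcome,
            echo_times=tuple(d.pop("echo_times", PORCINE_ECHO_TIMES)),
            volume_shape=tuple(d.pop("volume_shape", (24, 24, 40))),
            voxel_size=tuple(d.pop("voxel_size", (0.5, 0.5, 0.8))),
            **d,
        )


def _ellipsoid_mask(shape: Sequence[int], voxel_size: Sequence[float],
                    semi_axes: Sequence[float]) -> np.ndarray:
    shape = tuple(shape)
    vox = np.asarray(voxel_size, dtype=float)
    centre = (np.asarray(shape) - 1) / 2.0 * vox
    grids = np.meshgrid(*[np.arange(n) * v for n, v in zip(shape, vox)],
                        indexing="ij")
    r2 = sum(((g - c) / a) ** 2
             for g, c, a in zip(grids, centre, semi_axes))
    return r2 <= 1.0


def generate_t2star_phantom(
    config: SynthCohortConfig,
    limb_type: str,
    seed: int | np.random.SeedSequence = 0,
) -> T2StarMap:
    """Draw one limb's ground-truth T2* map inside an ellipsoidal mask.

    Surgical limbs draw a larger disorganized (high-T2*) voxel fraction than
    contralateral limbs, so their mean in-mask T2* is higher in expectation.
    Values are truncated to (0.5, 80) ms, keeping every voxel positive.
    """
    if limb_type not in config.tissue:
        raise ValidationError(
            f"unknown limb_type {limb_type!r}; expected one of {sorted(config.tissue)}")
    tissue = config.tissue[limb_type]
    rng = np.random.default_rng(seed)
    ax, ay, az = tissue.semi_axes
    if tissue.geometry_jitter > 0:
        transverse = rng.lognormal(0.0, tissue.geometry_jitter)
        length = rng.lognormal(0.0, tissue.geometry_jitter)
        ax, ay, az = ax * transverse, ay * transverse, az * length
    mask = _ellipsoid_mask(config.volume_shape, config.voxel_size, (ax, ay, az))
    n = int(mask.sum())
    if n == 0:
        raise ValidationError("volume too small: empty ellipsoid mask")

    def tnorm(sd: float) -> float:
        # subject-level heterogeneity is biologically bounded: truncate at 2 SD
        return float(np.clip(rng.normal(0.0, sd), -2.0 * sd, 2.0 * sd)) if sd else 0.0

    frac = float(np.clip(rng.beta(tissue.disorg_frac_a, tissue.disorg_frac_b),
                         0.02, 0.6))
    org_mu = tissue.organized_mean + tnorm(tissue.subject_shift_sd)
    dis_shift = (2.5 * tissue.subject_shift_sd
                 if tissue.dis_shift_sd is None else tissue.dis_shift_sd)
    dis_mu = tissue.disorganized_mean + tnorm(dis_shift)
    org_sd = tissue.organized_sd * np.exp(tnorm(tissue.spread_jitter))
    dis_sd = tissue.disorganized_sd * np.exp(tnorm(tissue.spread_jitter))
    is_disorg = rng.random(n) < frac
    vals = np.where(
        is_disorg,
        rng.normal(dis_mu, dis_sd, size=n),
        rng.normal(org_mu, org_sd, size=n),
    )
    vals = np.clip(vals, 0.5, 80.0)

    t2 = np.zeros(mask.shape)
    t2[mask] = vals
    s0 = np.where(mask, config.s0, 0.0)
    return T2StarMap(
        t2star=t2, s0=s0, fit_quality=mask.astype(float),
        mask=mask, voxel_size=config.voxel_size,
    )


def render_multi_echo(
    t2map: T2StarMap,
    s0: float,
    echo_times: Sequence[float],
    noise_sd: float,
    seed: int | np.random.SeedSequence = 0,
) -> MultiEchoVolume:
    """Forward-model a T2* map to a multi-echo volume.

    In-mask voxels decay as S0·exp(−TE/T2*); additive Gaussian noise of the
    given SD is applied everywhere, so out-of-mask voxels are pure
    background noise.
    """
    te = np.asarray(echo_times, dtype=float)
    if np.any(te <= 0):
        raise ValidationError("echo times must be strictly positive")
    if np.any(np.diff(te) <= 0):
        raise ValidationError("echo times must be strictly increasing")
    if s0 <= 0:
        raise ValidationError("s0 must be positive")
    rng = np.random.default_rng(seed)
    t2 = np.where(t2map.mask, t2map.t2star, np.inf)
    with np.errstate(divide="ignore"):
        decay = np.exp(-te[None, None, None, :] / t2[..., None])
    signal = np.where(t2map.mask[..., None], s0 * decay, 0.0)
    if noise_sd > 0:
        signal = signal + rng.normal(0.0, noise_sd, size=signal.shape)
    return MultiEchoVolume(signal, te, t2map.voxel_size)


def generate_failure_load(
    record: Mapping[str, float],
    load_model: LoadModel,
    seed: int | np.random.SeedSequence = 0,
) -> float:
    """Draw a tensile failure load (N) for one limb's feature record."""
    rng = np.random.default_rng(seed)
    mu = load_model.expected(record)
    load = mu + rng.normal(0.0, load_model.residual_sd) if load_model.residual_sd else mu
    return float(max(load, 1.0))  # truncate at 1 N; loads are physically positive


def generate_revision_outcomes(
    loads_true: Sequence[float],
    outcome_model: OutcomeModel,
    seed: int | np.random.SeedSequence = 0,
) -> np.ndarray:
    """Bernoulli revision outcomes with log-odds decreasing in true load."""
    loads = np.asarray(loads_true, dtype=float)
    rng = np.random.default_rng(seed)
    p = outcome_model.probabilities(loads)
    return (rng.random(loads.size) < p).astype(int)


# ---------------------------------------------------------------------------
# cohort-level generators
# ---------------------------------------------------------------------------

def _limb_record(config: SynthCohortConfig, subject_id: str, limb_type: str,
                 limb_seed: np.random.SeedSequence, timepoint: int,
                 scanner_id: str) -> tuple[dict, T2StarMap]:
    phantom_seed, load_seed = limb_seed.spawn(2)
    t2map = generate_t2star_phantom(config, limb_type, phantom_seed)
    rec = feat.extract_features(
        t2map, subject_id, limb_type,
        timepoint=timepoint, scanner_id=scanner_id,
    )
    rec["failure_load"] = generate_failure_load(rec, config.load_model, load_seed)
    return rec, t2map


def generate_porcine_cohort(
    config: SynthCohortConfig | None = None,
    seed: int | None = None,
    return_maps: bool = False,
):
    """Paired-limb porcine-style cohort as a feature table.

    One surgical and one contralateral limb per subject; features are
    computed from the ground-truth T2* maps and failure loads drawn from the
    configured load model.  Returns a DataFrame (and the per-limb maps when
    ``return_maps``).
    """
    config = config or SynthCohortConfig()
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    rows, maps = [], {}
    timepoints = (12, 24)
    for i, subj_seed in enumerate(root.spawn(config.n_subjects)):
        sid = f"pig{i:03d}"
        tp = timepoints[i % len(timepoints)]
        for limb_type, limb_seed in zip(LIMB_TYPES[: config.limbs_per_subject],
                                        subj_seed.spawn(config.limbs_per_subject)):
            rec, t2map = _limb_record(config, sid, limb_type, limb_seed, tp, "porcine3T")
            rows.append(rec)
            maps[(sid, limb_type)] = t2map
    table = pd.DataFrame(rows)
    return (table, maps) if return_maps else table


def planted_cohort_config(seed: int = 0, **overrides) -> SynthCohortConfig:
    """Cohort for validating the feature-selection machinery.

    The load is a zero-residual function of exactly limb type, Q1 T2* and
    Prop 4.  Limb type is decoupled from tissue (both limb types share one
    tissue distribution, limb entering the load only through its own term),
    and subject variation flows mainly through the mixture-component
    spreads, so each planted feature carries signal its correlated
    neighbours cannot reproduce.
    """
    tissue = LimbTissue(
        disorg_frac_a=60.0, disorg_frac_b=100.0, disorganized_mean=33.0,
        subject_shift_sd=0.25, dis_shift_sd=2.0, spread_jitter=0.6,
        semi_axes=(4.0, 4.0, 11.0),
    )
    defaults = dict(
        load_model=LoadModel(csa=0.0, residual_sd=0.0),
        tissue={"surgical": tissue, "contralateral": tissue},
        seed=seed,
    )
    defaults.update(overrides)
    return SynthCohortConfig(**defaults)


def clinical_config(seed: int = 0, **overrides) -> SynthCohortConfig:
    """Default human-like cohort: 46 surgical limbs on two scanners."""
    defaults = dict(
        n_subjects=46, limbs_per_subject=1,
        echo_times=CLINICAL_ECHO_TIMES["trio"],
        voxel_size=(0.6, 0.6, 0.8), seed=seed,
    )
    defaults.update(overrides)
    return SynthCohortConfig(**defaults)


#: Additive per-scanner T2* bias (ms) emulating the echo-train /
#: calibration differences that harmonization must remove.
SCANNER_T2_BIAS = {"prisma": 0.0, "trio": 2.0}


def generate_clinical_cohort(
    config: SynthCohortConfig | None = None,
    seed: int | None = None,
    n_prisma: int = 10,
    scanner_bias: Mapping[str, float] = SCANNER_T2_BIAS,
    return_maps: bool = False,
):
    """Human-like cohort: surgical limbs only, two scanners, revision outcome.

    The first ``n_prisma`` subjects are assigned to the "prisma" scanner and
    the rest to "trio"; a per-scanner additive T2* bias is injected into the
    maps before feature extraction, emulating acquisition differences that
    the per-scanner harmonization step must remove.  True failure loads stay
    in the table as ``failure_load_true``; revision outcomes are Bernoulli
    draws from the configured logistic model.
    """
    config = config or clinical_config()
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    subj_seeds = root.spawn(config.n_subjects + 1)
    outcome_seed, subj_seeds = subj_seeds[-1], subj_seeds[:-1]
    rows, maps = [], {}
    for i, subj_seed in enumerate(subj_seeds):
        sid = f"pt{i:03d}"
        scanner = "prisma" if i < n_prisma else "trio"
        phantom_seed, load_seed = subj_seed.spawn(2)
        t2map = generate_t2star_phantom(config, "surgical", phantom_seed)
        true_rec = feat.extract_features(t2map, sid, "surgical")
        load = generate_failure_load(true_rec, config.load_model, load_seed)
        biased = replace(
            t2map, t2star=np.where(t2map.mask,
                                   t2map.t2star + scanner_bias.get(scanner, 0.0),
                                   t2map.t2star))
        rec = feat.extract_features(
            biased, sid, "surgical", timepoint=9, scanner_id=scanner)
        rec["failure_load_true"] = load
        rows.append(rec)
        maps[sid] = biased
    table = pd.DataFrame(rows)
    table["revision"] = generate_revision_outcomes(
        table["failure_load_true"].to_numpy(), config.outcome_model, outcome_seed)
    return (table, maps) if return_maps else table


def write_imaging_cohort(
    out_dir: str | Path,
    config: SynthCohortConfig,
    seed: int | None = None,
    cohort: str = "porcine",
) -> Path:
    """Render a cohort to disk: NIfTI volumes + masks, sidecars, metadata CSV.

    The heavyweight form of the generators, used by the end-to-end pipeline:
    each limb's ground-truth map is forward-modelled to a noisy multi-echo
    volume so the relaxometry stage has real work to do.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if cohort == "porcine":
        table, maps = generate_porcine_cohort(config, seed, return_maps=True)
        keys = [(r.subject_id, "surgical" if r.limb_type else "contralateral")
                for r in table.itertuples()]
        names = [f"{sid}_{limb}" for sid, limb in keys]
        echo_sets = [config.echo_times] * len(names)
    elif cohort == "clinical":
        table, maps = generate_clinical_cohort(config, seed, return_maps=True)
        keys = list(table["subject_id"])
        names = list(table["subject_id"])
        echo_sets = [CLINICAL_ECHO_TIMES.get(s, config.echo_times)
                     for s in table["scanner_id"]]
    else:
        raise ValidationError(f"unknown cohort kind {cohort!r}")

    root = np.random.SeedSequence(
        (config.seed if seed is None else seed) + 7_000_000)
    render_seeds = root.spawn(len(names))
    for key, name, te, rseed in zip(keys, names, echo_sets, render_seeds):
        t2map = maps[key]
        vol = render_multi_echo(t2map, config.s0, te, config.noise_sd, rseed)
        vol.to_nifti(out_dir / f"{name}_echo.nii.gz")
        t2map.mask_to_nifti(out_dir / f"{name}_mask.nii.gz")
    table.to_csv(out_dir / "metadata.csv", index=False)
    config.to_yaml(out_dir / "config.yaml")
    return out_dir
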