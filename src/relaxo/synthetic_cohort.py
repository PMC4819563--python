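"""Synthetic multi-echo relaxometry cohort generator.

Generates a full synthetic study — per-subject three-class tissue label
images and co-registered 4D multi-echo volumes — whose tissue voxels decay
as three-compartment exponential mixtures with group-level means and spreads
taken from the default cohort configuration (``cohort_defaults.yaml``).
Every pipeline stage can therefore be exercised, and its recovery of the
generating parameters measured, without any real MRI data.

Generative model per subject
----------------------------
* Tissue volumes (WM, GM, CSF, liters) are truncated-normal draws around the
  stratum means; voxel counts follow from the voxel volume.
* The WM compartment fraction vector (myelin, tissue, free water) is drawn
  around a calibrated stratum mean: the myelin fraction is logit-normal
  (mean-corrected so its expectation equals the stratum MWF mean) and the
  free-water fraction is truncated-normal around the stratum value that makes
  a mono-exponential fit of the noiseless mixture return the stratum's
  effective WM T2.  Because the effective T2 of the mixture falls with
  myelin fraction and rises with free water, this construction reproduces
  both the MWF and the effective-T2 group summaries simultaneously; an
  independent draw of the two would frequently be infeasible on the fixed
  basis.
* GM and CSF use fixed fraction vectors (configurable).
* Geometry is schematic and concentric — CSF core, WM interior, GM shell,
  ordered by distance from the grid center — with voxel counts matched to
  the drawn volumes exactly.  ROI statistics depend only on label
  membership, not on anatomy.
* Voxel signals are the noiseless multi-compartment decay plus i.i.d.
  additive Gaussian noise whose SD is (mean WM first-echo signal) / SNR.

All randomness flows from a single seed through per-subject
``numpy.random.SeedSequence`` spawns, so cohorts are bitwise reproducible
and group labels influence only stratum parameters, never the noise or
geometry code paths.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
import yaml

from .mono_fit import gauss_newton_fit, linear_init
from .roi_stats import CSF, GM, WM, TissueLabelImage, MM3_PER_LITER
from .signal_models import CompartmentBasis, EchoSeries, predict_multi

__all__ = [
    "StratumParams",
    "CohortSpec",
    "SubjectTruth",
    "default_cohort_spec",
    "effective_mono_t2",
    "calibrate_free_water_fraction",
    "sample_subject",
    "render_subject",
    "generate_cohort",
    "iterate_cohort",
    "truth_table",
    "sample_truth_table",
    "group_mean_spread",
    "volume_mediated_cohort",
]

_TISSUES = ("wm", "gm", "csf")


@dataclass(frozen=True)
class StratumParams:
    """Ground-truth distribution of one group-by-sex stratum."""

    name: str  # e.g. "preterm_female"
    n_subjects: int
    volume_mean_l: dict[str, float]  # per tissue
    volume_sd_l: dict[str, float]
    wm_mwf_mean: float
    wm_mwf_sd: float
    wm_t2_mean_ms: float
    wm_t2_sd_ms: float

    @property
    def group(self) -> str:
        return self.name.split("_")[0]

    @property
    def sex(self) -> str:
        return self.name.split("_")[1]


@dataclass(frozen=True)
class CohortSpec:
    """Complete recipe for one synthetic cohort."""

    strata: tuple[StratumParams, ...]
    echo_times: np.ndarray
    basis: CompartmentBasis
    voxel_dims: tuple[float, float, float]  # native acquisition voxel, mm
    voxel_scale: float  # desk-scale factor on each dimension
    grid_shape: tuple[int, int, int]
    snr_first_echo: float
    s0: float
    gm_fractions: np.ndarray
    csf_fractions: np.ndarray
    seed: int = 1

    def __post_init__(self) -> None:
        if not self.strata:
            raise ValueError("at least one stratum required")
        for st in self.strata:
            if st.n_subjects < 1:
                raise ValueError(f"stratum {st.name}: n_subjects must be >= 1")
            if st.wm_mwf_sd < 0 or st.wm_t2_sd_ms < 0 or any(s < 0 for s in st.volume_sd_l.values()):
                raise ValueError(f"stratum {st.name}: SDs must be non-negative")
            if not 0 < st.wm_mwf_mean < 1:
                raise ValueError(f"stratum {st.name}: MWF mean must lie in (0, 1)")
        object.__setattr__(self, "echo_times", np.asarray(self.echo_times, dtype=float))
        object.__setattr__(self, "gm_fractions", np.asarray(self.gm_fractions, dtype=float))
        object.__setattr__(self, "csf_fractions", np.asarray(self.csf_fractions, dtype=float))

    @property
    def scaled_voxel_dims(self) -> tuple[float, float, float]:
        return tuple(d * self.voxel_scale for d in self.voxel_dims)

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.scaled_voxel_dims
        return dx * dy * dz

    @property
    def n_subjects(self) -> int:
        return sum(st.n_subjects for st in self.strata)


@dataclass(frozen=True)
class SubjectTruth:
    """Ground-truth ledger for one simulated subject."""

    subject_id: str
    stratum: str
    group: str
    sex: str
    volumes_l: dict[str, float]  # realized, after voxel quantization
    voxel_counts: dict[str, int]
    fractions: dict[str, tuple[float, ...]]  # per tissue (myelin, tissue, free)
    effective_t2_ms: dict[str, float]  # mono-fit T2 of the noiseless mixture
    noise_sd: float
    seed_entropy: int


def _stratum_from_cfg(name: str, cfg: dict) -> StratumParams:
    return StratumParams(
        name=name,
        n_subjects=int(cfg["n_subjects"]),
        volume_mean_l={t: float(cfg[f"{t}_volume_l"]["mean"]) for t in _TISSUES},
        volume_sd_l={t: float(cfg[f"{t}_volume_l"]["sd"]) for t in _TISSUES},
        wm_mwf_mean=float(cfg["wm_mwf"]["mean"]),
        wm_mwf_sd=float(cfg["wm_mwf"]["sd"]),
        wm_t2_mean_ms=float(cfg["wm_t2_ms"]["mean"]),
        wm_t2_sd_ms=float(cfg["wm_t2_ms"]["sd"]),
    )


def default_cohort_spec(seed: int = 1, **overrides) -> CohortSpec:
    """The default synthetic study, loaded from ``cohort_defaults.yaml``.

    ``overrides`` replace top-level :class:`CohortSpec` fields (e.g.
    ``snr_first_echo=300`` or a different ``grid_shape``).
    """
    cfg = yaml.safe_load(resources.files("relaxo").joinpath("cohort_defaults.yaml").read_text())
    acq = cfg["acquisition"]
    fields_ = dict(
        strata=tuple(_stratum_from_cfg(name, sc) for name, sc in cfg["strata"].items()),
        echo_times=np.asarray(acq["echo_times_ms"], dtype=float),
        basis=CompartmentBasis(np.asarray(cfg["basis_t2_ms"], dtype=float)),
        voxel_dims=tuple(float(v) for v in acq["voxel_dims_mm"]),
        voxel_scale=float(acq["voxel_scale"]),
        grid_shape=tuple(int(v) for v in acq["grid_shape"]),
        snr_first_echo=float(acq["snr_first_echo"]),
        s0=float(acq["s0"]),
        gm_fractions=np.asarray(cfg["gm_fractions"], dtype=float),
        csf_fractions=np.asarray(cfg["csf_fractions"], dtype=float),
        seed=seed,
    )
    fields_.update(overrides)
    return CohortSpec(**fields_)


@lru_cache(maxsize=65536)
def _effective_mono_t2_cached(fractions: tuple, t2_values: tuple, echo_times: tuple) -> float:
    basis = CompartmentBasis(np.asarray(t2_values, dtype=float))
    sig = predict_multi(1.0, np.asarray(fractions, dtype=float), basis, echo_times)
    curve = EchoSeries(np.asarray(echo_times, dtype=float), sig)
    return gauss_newton_fit(curve, init=linear_init(curve)).t2


def effective_mono_t2(fractions, basis: CompartmentBasis, echo_times) -> float:
    """Mono-exponential T2 a single-component fit reports for a noiseless
    multi-compartment mixture sampled at the given echoes."""
    return _effective_mono_t2_cached(
        tuple(float(f) for f in np.asarray(fractions, dtype=float)),
        tuple(float(t) for t in basis.t2_values),
        tuple(float(t) for t in np.asarray(echo_times, dtype=float)),
    )


def calibrate_free_water_fraction(
    mwf: float, target_t2_ms: float, basis: CompartmentBasis, echo_times, c_max: float | None = None
) -> float:
    """Free-water fraction c such that the mixture (mwf, 1-mwf-c, c) has the
    requested effective mono-exponential T2.

    The effective T2 is monotone increasing in c, so the root is found by
    bisection.  Targets below the c = 0 floor (or above the c = c_max
    ceiling) are clamped to the nearest attainable value.
    """
    if c_max is None:
        c_max = max(1.0 - mwf - 1e-3, 0.0)

    def f(c: float) -> float:
        return effective_mono_t2((mwf, 1.0 - mwf - c, c), basis, echo_times) - target_t2_ms

    lo, hi = f(0.0), f(c_max)
    if lo >= 0:
        return 0.0
    if hi <= 0:
        return c_max
    return float(scipy.optimize.brentq(f, 0.0, c_max, xtol=1e-8))


def _logit_normal_mu(target_mean: float, sigma: float) -> float:
    """Location of a logit-normal with the requested expectation.

    Solved by Gauss–Hermite quadrature; falls back to the plain logit when
    sigma is (near) zero.
    """
    if sigma < 1e-12:
        return float(np.log(target_mean / (1 - target_mean)))
    nodes, weights = np.polynomial.hermite_e.hermegauss(40)

    def mean_of(mu: float) -> float:
        x = mu + sigma * nodes
        return float(weights @ (1.0 / (1.0 + np.exp(-x))) / weights.sum())

    lo = np.log(target_mean / (1 - target_mean)) - 3 * sigma
    hi = np.log(target_mean / (1 - target_mean)) + 3 * sigma
    return float(scipy.optimize.brentq(lambda mu: mean_of(mu) - target_mean, lo, hi))


@dataclass(frozen=True)
class _StratumCalibration:
    """Derived sampling constants of one stratum (computed once)."""

    c_mean: float  # free-water fraction at the stratum mean
    c_sd: float  # subject-level free-water spread
    c_loc: float  # truncated-normal location whose post-truncation mean is c_mean
    mwf_logit_mu: float
    mwf_logit_sigma: float


def _calibrate_stratum(st: StratumParams, spec: CohortSpec) -> _StratumCalibration:
    basis, te = spec.basis, spec.echo_times
    m = st.wm_mwf_mean
    c_mean = calibrate_free_water_fraction(m, st.wm_t2_mean_ms, basis, te)
    # Local sensitivities of the effective T2 to the myelin and free-water
    # fractions, by central differences around the stratum mean mixture.
    h = 1e-3
    dt2_dm = (
        effective_mono_t2((m + h, 1 - (m + h) - c_mean, c_mean), basis, te)
        - effective_mono_t2((m - h, 1 - (m - h) - c_mean, c_mean), basis, te)
    ) / (2 * h)
    dt2_dc = (
        effective_mono_t2((m, 1 - m - (c_mean + h), c_mean + h), basis, te)
        - effective_mono_t2((m, 1 - m - max(c_mean - h, 0), max(c_mean - h, 0)), basis, te)
    ) / (h + min(h, c_mean))
    # Subject-level T2 spread is induced partly by the MWF spread; the
    # free-water spread supplies the remainder (zero when the MWF-induced
    # spread already covers the target).
    induced_var = (dt2_dm * st.wm_mwf_sd) ** 2
    resid_var = max(st.wm_t2_sd_ms**2 - induced_var, 0.0)
    c_sd = float(np.sqrt(resid_var) / abs(dt2_dc)) if dt2_dc != 0 else 0.0
    # Delta-method logit-scale sigma for the requested MWF SD, with the
    # location corrected so the logit-normal mean hits the target exactly.
    sigma = st.wm_mwf_sd / (m * (1 - m))
    mu = _logit_normal_mu(m, sigma)
    c_loc = _truncated_normal_location(c_mean, c_sd, lower=0.0)
    return _StratumCalibration(
        c_mean=c_mean, c_sd=c_sd, c_loc=c_loc, mwf_logit_mu=mu, mwf_logit_sigma=sigma
    )


_calibration_cache: dict = {}


def _stratum_calibration(st: StratumParams, spec: CohortSpec) -> _StratumCalibration:
    key = (
        st.name,
        st.wm_mwf_mean,
        st.wm_mwf_sd,
        st.wm_t2_mean_ms,
        st.wm_t2_sd_ms,
        tuple(spec.echo_times),
        tuple(spec.basis.t2_values),
    )
    if key not in _calibration_cache:
        _calibration_cache[key] = _calibrate_stratum(st, spec)
    return _calibration_cache[key]


def _truncated_normal(mean: float, sd: float, rng: np.random.Generator, lower: float = 0.0) -> float:
    if sd == 0:
        return max(mean, lower)
    a = (lower - mean) / sd
    return float(scipy.stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, random_state=rng))


def _truncated_normal_location(target_mean: float, sd: float, lower: float = 0.0) -> float:
    """Location mu such that a normal(mu, sd) truncated at ``lower`` has the
    requested expectation (truncation shifts the mean upward; left
    uncorrected this biases quantities derived from near-boundary draws)."""
    if sd == 0 or target_mean - lower > 8 * sd:
        return target_mean

    def mean_of(mu: float) -> float:
        a = (lower - mu) / sd
        return float(scipy.stats.truncnorm.mean(a, np.inf, loc=mu, scale=sd))

    lo, hi = target_mean - 12 * sd, target_mean + sd
    return float(scipy.optimize.brentq(lambda mu: mean_of(mu) - target_mean, lo, hi))


def wm_noise_sd(st: StratumParams, spec: CohortSpec) -> float:
    """Noise SD for one stratum: mean WM first-echo signal / SNR."""
    cal = _stratum_calibration(st, spec)
    m, c = st.wm_mwf_mean, cal.c_mean
    first = predict_multi(spec.s0, (m, 1 - m - c, c), spec.basis, spec.echo_times[:1])[0]
    return float(first / spec.snr_first_echo)


def sample_subject(spec: CohortSpec, stratum: str | StratumParams, rng: np.random.Generator, subject_id: str | None = None) -> SubjectTruth:
    """Draw one subject's ground truth from a stratum distribution."""
    st = stratum if isinstance(stratum, StratumParams) else next(s for s in spec.strata if s.name == stratum)
    cal = _stratum_calibration(st, spec)

    volumes = {t: _truncated_normal(st.volume_mean_l[t], st.volume_sd_l[t], rng, lower=1e-4) for t in _TISSUES}
    vox_l = spec.voxel_volume_mm3 / MM3_PER_LITER
    counts = {t: int(round(volumes[t] / vox_l)) for t in _TISSUES}
    capacity = int(np.prod(spec.grid_shape))
    if sum(counts.values()) > capacity:
        need = sum(counts.values())
        raise ValueError(
            f"drawn volumes need {need} voxels but the grid holds {capacity}; "
            f"enlarge grid_shape (>= {need} voxels) or increase voxel_scale"
        )

    mwf = float(1.0 / (1.0 + np.exp(-(cal.mwf_logit_mu + cal.mwf_logit_sigma * rng.standard_normal()))))
    c = _truncated_normal(cal.c_loc, cal.c_sd, rng, lower=0.0)
    c = min(c, max(1.0 - mwf - 1e-3, 0.0))
    wm_fr = (mwf, 1.0 - mwf - c, c)

    fractions = {
        "wm": wm_fr,
        "gm": tuple(float(x) for x in spec.gm_fractions),
        "csf": tuple(float(x) for x in spec.csf_fractions),
    }
    eff_t2 = {t: effective_mono_t2(fractions[t], spec.basis, spec.echo_times) for t in _TISSUES}
    realized = {t: counts[t] * vox_l for t in _TISSUES}

    return SubjectTruth(
        subject_id=subject_id or f"{st.name}_subj",
        stratum=st.name,
        group=st.group,
        sex=st.sex,
        volumes_l=realized,
        voxel_counts=counts,
        fractions=fractions,
        effective_t2_ms=eff_t2,
        noise_sd=wm_noise_sd(st, spec),
        seed_entropy=int(rng.integers(0, 2**31)),
    )


def render_subject(truth: SubjectTruth, spec: CohortSpec, rng: np.random.Generator) -> tuple[TissueLabelImage, np.ndarray]:
    """Materialize one subject as a label image and a noisy 4D echo image.

    Concentric geometry: voxels sorted by distance from the grid center are
    assigned CSF (core), then WM, then GM (shell); remaining voxels are
    background.  The emitted label counts equal the truth ledger exactly.
    """
    shape = spec.grid_shape
    center = (np.array(shape) - 1) / 2.0
    grids = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    # Distances in voxel units scaled to make shells roughly isotropic in mm.
    dims = np.array(spec.scaled_voxel_dims)
    dist = np.sqrt(sum(((g - c) * d) ** 2 for g, c, d in zip(grids, center, dims)))
    order = np.argsort(dist.ravel(), kind="stable")

    labels = np.zeros(int(np.prod(shape)), dtype=np.int16)
    cursor = 0
    for tissue, code in (("csf", CSF), ("wm", WM), ("gm", GM)):
        n = truth.voxel_counts[tissue]
        labels[order[cursor : cursor + n]] = code
        cursor += n
    labels = labels.reshape(shape)

    te = spec.echo_times
    echoes = np.zeros(shape + (te.size,), dtype=float)
    for tissue, code in (("csf", CSF), ("wm", WM), ("gm", GM)):
        clean = predict_multi(spec.s0, np.asarray(truth.fractions[tissue]), spec.basis, te)
        echoes[labels == code] = clean
    echoes += rng.normal(0.0, truth.noise_sd, echoes.shape)

    affine = np.diag(list(spec.scaled_voxel_dims) + [1.0])
    return TissueLabelImage(labels, spec.scaled_voxel_dims, affine), echoes


def iterate_cohort(spec: CohortSpec):
    """Yield ``(truth, labels, echoes)`` per subject, deterministically.

    Per-subject RNG streams are spawned from ``spec.seed`` so subjects are
    independent and the whole cohort is reproducible bitwise.
    """
    root = np.random.SeedSequence(spec.seed)
    children = root.spawn(spec.n_subjects)
    i = 0
    for st in spec.strata:
        for j in range(st.n_subjects):
            rng = np.random.default_rng(children[i])
            truth = sample_subject(spec, st, rng, subject_id=f"{st.name}_{j:03d}")
            labels, echoes = render_subject(truth, spec, rng)
            yield truth, labels, echoes
            i += 1


def truth_table(truths) -> pd.DataFrame:
    """Ground-truth ledger as a DataFrame with cohort-table column names."""
    rows = []
    for t in truths:
        rows.append(
            {
                "subject_id": t.subject_id,
                "stratum": t.stratum,
                "group": t.group,
                "sex": t.sex,
                "csf_volume_l": t.volumes_l["csf"],
                "gm_volume_l": t.volumes_l["gm"],
                "wm_volume_l": t.volumes_l["wm"],
                "icv_l": sum(t.volumes_l.values()),
                "csf_t2_ms": t.effective_t2_ms["csf"],
                "gm_t2_ms": t.effective_t2_ms["gm"],
                "wm_t2_ms": t.effective_t2_ms["wm"],
                "wm_mwf": t.fractions["wm"][0],
                "wm_tissue_fraction": t.fractions["wm"][1],
                "noise_sd": t.noise_sd,
            }
        )
    return pd.DataFrame(rows)


def sample_truth_table(spec: CohortSpec) -> pd.DataFrame:
    """Subject-level ground truths only (no image rendering).

    Useful for statistical calibration studies that operate on the cohort
    table directly, e.g. null-cohort replicates for t-test calibration.
    """
    root = np.random.SeedSequence(spec.seed)
    children = root.spawn(spec.n_subjects)
    truths = []
    i = 0
    for st in spec.strata:
        for j in range(st.n_subjects):
            rng = np.random.default_rng(children[i])
            truths.append(sample_subject(spec, st, rng, subject_id=f"{st.name}_{j:03d}"))
            i += 1
    return truth_table(truths)


def group_mean_spread(spec: CohortSpec, select, n_draws: int = 2000, seed: int = 12345) -> float:
    """Monte-Carlo SD of a cohort group mean under the generator.

    ``select(truth_row) -> (include: bool, value: float)`` picks the subjects
    and per-subject quantity whose cohort mean is of interest (e.g. WM
    effective T2 over the preterm group).  The returned value estimates the
    across-seed SD of that mean, i.e. the spread a repeated-cohort study
    would show; it is computed from ``n_draws`` subject-level draws per
    stratum, with no image rendering.
    """
    rng = np.random.default_rng(seed)
    per_stratum: dict[str, np.ndarray] = {}
    weights: dict[str, int] = {}
    for st in spec.strata:
        vals = []
        draws = [sample_subject(spec, st, rng) for _ in range(n_draws)]
        rows = truth_table(draws).to_dict("records")
        for row in rows:
            inc, val = select(row)
            if inc:
                vals.append(val)
        if vals:
            per_stratum[st.name] = np.asarray(vals)
            weights[st.name] = st.n_subjects
    if not per_stratum:
        raise ValueError("selector matched no stratum")
    n_total = sum(weights.values())
    var = sum(weights[k] * per_stratum[k].var(ddof=1) for k in per_stratum) / n_total**2
    return float(np.sqrt(var))


def generate_cohort(spec: CohortSpec, out_dir: str | Path, force: bool = False) -> pd.DataFrame:
    """Write the cohort to disk as NIfTI pairs plus a truth table.

    Emits ``<subject>_labels.nii.gz`` and ``<subject>_echoes.nii.gz`` per
    subject, a ``truth.csv`` ledger and a ``manifest.json``.  Refuses to
    write into an existing non-empty directory unless ``force`` is set.
    """
    import nibabel as nib

    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"output directory {out} is not empty (use force=True)")
    out.mkdir(parents=True, exist_ok=True)

    truths = []
    manifest = {"seed": spec.seed, "n_subjects": spec.n_subjects, "subjects": []}
    for truth, labels, echoes in iterate_cohort(spec):
        affine = labels.affine
        lab_path = out / f"{truth.subject_id}_labels.nii.gz"
        echo_path = out / f"{truth.subject_id}_echoes.nii.gz"
        nib.save(nib.Nifti1Image(labels.labels.astype(np.int16), affine), lab_path)
        nib.save(nib.Nifti1Image(echoes.astype(np.float32), affine), echo_path)
        truths.append(truth)
        manifest["subjects"].append(
            {"subject_id": truth.subject_id, "labels": lab_path.name, "echoes": echo_path.name}
        )
    table = truth_table(truths)
    table.to_csv(out / "truth.csv", index=False)
    manifest["echo_times_ms"] = spec.echo_times.tolist()
    manifest["basis_t2_ms"] = spec.basis.t2_values.tolist()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return table


def volume_mediated_cohort(
    n_per_group: int = 20,
    volume_means_l: tuple[float, float] = (0.36, 0.42),
    volume_sd_l: float = 0.03,
    t2_per_liter: float = 40.0,
    t2_intercept_ms: float = 52.0,
    t2_noise_sd_ms: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Cohort table with a purely volume-mediated WM T2 group difference.

    The groups differ in WM volume only; WM T2 is a fixed linear function of
    WM volume plus independent noise.  An unadjusted group comparison of
    WM T2 should therefore reject, while the volume-adjusted comparison
    should not — the construction used to probe covariate adjustment.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for group, mean_vol in zip(("preterm", "term"), volume_means_l):
        for i in range(n_per_group):
            vol = max(rng.normal(mean_vol, volume_sd_l), 1e-3)
            t2 = t2_intercept_ms + t2_per_liter * vol + rng.normal(0.0, t2_noise_sd_ms)
            rows.append(
                {
                    "subject_id": f"{group}_{i:03d}",
                    "group": group,
                    "sex": "female" if i % 2 else "male",
                    "wm_volume_l": vol,
                    "wm_t2_ms": t2,
                }
            )
    return pd.DataFrame(rows)
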