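"""Synthetic crush-curve recordings, cohorts and CT phantoms.

Calcified nodules crush like brittle foams: an elastic ramp (Stage I), a
serrated plateau produced by repeated microfracture and local stress relief
(Stage II), and a densification upturn as fragments pack between the
platens (Stage III).  A minority of nodules instead show a smooth, gradually
convex stress rise.  The generator produces machine-realistic recordings of
both patterns, entire cohorts with a controllable CT-density/stiffness
correlation and dialysis enrichment among non-three-phase nodules, and
simple ellipsoid-blob CT phantoms for the densitometry stage.

The true stress curve sigma*(eps) is mapped to recorded load by inverting
the analysis-side correction:

    F(eps) = sigma*(eps) * Rc(eps) * A0 / (1 - eps)

so that the forward stress-strain transform recovers sigma* exactly in the
noise-free case.  Each recording carries its ground truth (contact index,
pattern, sigma* on the sample grid) in ``TestRecording.meta``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import lfilter

from .errors import SpecValidationError
from .mechanics import MAX_STRAIN, contact_ratio
from .types import PRELOAD_THRESHOLD, MachineSpec, NoduleRecord, TestRecording

#: Strain constant of the exponential stress recovery after a drop event.
DROP_RECOVERY_STRAIN = 0.02

#: Autocorrelation of the displacement-encoder noise between samples.
#: Encoder error drifts slowly; white noise at the stated accuracy would
#: imply physically impossible sample-to-sample crosshead reversals.
DISP_NOISE_AR1 = 0.995

#: Number of samples in the synthesized pre-contact preload ramp.
PRELOAD_SAMPLES = 15


@dataclass(frozen=True)
class CrushCurveParams:
    """Parameters of one true stress-strain curve sigma*(eps).

    Three-phase curves: linear Stage I with slope ``elastic_modulus`` up to
    ``yield_strain``, a constant plateau at ``plateau_stress`` serrated by a
    Poisson process of multiplicative stress drops, and a Stage III
    densification term ``plateau_stress * ((eps - onset)/(0.95 - eps))**m``
    that diverges toward full densification.

    Gradual curves: ``sigma = gradual_scale * eps ** gradual_power``.
    """

    pattern: str = "three_phase"  # or "gradual"
    elastic_modulus_mpa: float = 10.0
    yield_strain: float = 0.1
    plateau_stress_mpa: float = 1.0
    drop_rate: float = 12.0  # serration events per unit strain
    drop_depth_fraction: float = 0.12
    densification_onset: float = 0.45
    densification_exponent: float = 1.8
    gradual_scale_mpa: float = 4.0
    gradual_power: float = 2.0
    noise_load_sd_n: float = 0.1
    noise_disp_sd_mm: float = 0.01

    def __post_init__(self) -> None:
        if self.pattern not in ("three_phase", "gradual"):
            raise SpecValidationError(f"unknown crush pattern {self.pattern!r}")
        if not 0.0 < self.yield_strain <= 0.2:
            raise SpecValidationError("yield_strain must be in (0, 0.2]")
        if not self.yield_strain < self.densification_onset < 0.9:
            raise SpecValidationError(
                "densification_onset must lie in (yield_strain, 0.9)"
            )
        if self.densification_exponent <= 1.0:
            raise SpecValidationError("densification_exponent must exceed 1")
        for name in ("elastic_modulus_mpa", "plateau_stress_mpa", "gradual_scale_mpa"):
            if getattr(self, name) <= 0:
                raise SpecValidationError(f"{name} must be positive")
        if self.gradual_power <= 1.0:
            raise SpecValidationError("gradual_power must exceed 1")
        if self.drop_rate < 0:
            raise SpecValidationError("drop_rate must be non-negative")
        if not 0.0 <= self.drop_depth_fraction < 1.0:
            raise SpecValidationError("drop_depth_fraction must be in [0, 1)")
        if self.noise_load_sd_n < 0 or self.noise_disp_sd_mm < 0:
            raise SpecValidationError("noise standard deviations must be >= 0")


def draw_drop_events(params: CrushCurveParams, rng: np.random.Generator) -> np.ndarray:
    """Strain locations of Stage II serration events (Poisson process on
    [yield_strain, 0.95])."""
    if params.pattern != "three_phase" or params.drop_rate == 0:
        return np.empty(0)
    span = MAX_STRAIN - params.yield_strain
    n_events = rng.poisson(params.drop_rate * span)
    return np.sort(rng.uniform(params.yield_strain, MAX_STRAIN, size=n_events))


def true_stress(
    params: CrushCurveParams,
    strain: np.ndarray,
    drop_events: np.ndarray | None = None,
) -> np.ndarray:
    """Evaluate the noise-free true stress sigma*(eps) in MPa."""
    eps = np.asarray(strain, dtype=float)
    if params.pattern == "gradual":
        return params.gradual_scale_mpa * eps**params.gradual_power

    sigma = np.where(
        eps < params.yield_strain,
        params.elastic_modulus_mpa * eps,
        params.plateau_stress_mpa,
    )
    over = eps > params.densification_onset
    if over.any():
        x = (eps[over] - params.densification_onset) / (MAX_STRAIN - eps[over])
        sigma = sigma.copy()
        sigma[over] = sigma[over] + params.plateau_stress_mpa * (
            x**params.densification_exponent
        )
    if drop_events is not None and drop_events.size:
        factor = np.ones_like(eps)
        for e in drop_events:
            after = eps >= e
            factor[after] *= 1.0 - params.drop_depth_fraction * np.exp(
                -(eps[after] - e) / DROP_RECOVERY_STRAIN
            )
        sigma = sigma * factor
    return sigma


def simulate_crush_curve(
    params: CrushCurveParams,
    geometry: NoduleRecord,
    machine: MachineSpec | None = None,
    seed: int | np.random.Generator = 0,
) -> TestRecording:
    """Synthesize one machine recording of a compression test.

    The recording starts with a preload ramp rising to half the 0.02 N/mm^2
    contact threshold, followed by a contact sample at twice the threshold
    (the seating snap of the platen onto the nodule), after which the load
    follows ``F = sigma* . Rc . A0 / (1 - eps)``.  Sampling stops when the
    noise-free load reaches the machine limit or strain reaches 0.95.
    Gaussian white noise (load) and slowly drifting AR(1) noise
    (displacement) are added at the machine-accuracy scale; noisy loads are
    clipped to [0, load limit].
    """
    machine = machine or MachineSpec()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a0, h0 = geometry.a0_mm2, geometry.h0_mm  # NoduleRecord validates positivity

    dl = machine.speed_mm_per_ms * machine.sampling_interval_ms  # mm per sample
    d_eps = dl / h0
    n_post = int(math.floor(MAX_STRAIN / d_eps))  # samples with eps < 0.95
    eps = np.arange(n_post) * d_eps

    drops = draw_drop_events(params, rng)
    sigma = true_stress(params, eps, drops)
    force = sigma * contact_ratio(eps) * a0 / (1.0 - eps)

    # Contact sample: platen seats with a small snap to 2x the threshold,
    # guaranteeing origin detection lands exactly on the true contact index.
    contact_force = 2.0 * PRELOAD_THRESHOLD * a0
    force[0] = contact_force

    over_limit = force >= machine.load_limit_n
    if over_limit.any():
        cut = int(np.argmax(over_limit))
        eps, sigma, force = eps[:cut], sigma[:cut], force[:cut]
    if eps.size < 2:
        raise SpecValidationError(
            "parameters drive the load above the machine limit before any "
            "post-contact sample could be recorded"
        )

    ramp = np.linspace(0.0, 0.5 * PRELOAD_THRESHOLD * a0, PRELOAD_SAMPLES, endpoint=False)
    load = np.concatenate([ramp, force])
    n_total = load.size
    time_ms = np.arange(n_total) * machine.sampling_interval_ms
    disp = np.arange(n_total) * dl

    if params.noise_load_sd_n > 0:
        load = load + rng.normal(0.0, params.noise_load_sd_n, size=n_total)
        np.clip(load, 0.0, machine.load_limit_n, out=load)
    if params.noise_disp_sd_mm > 0:
        disp = disp + _ar1_noise(rng, n_total, params.noise_disp_sd_mm)

    return TestRecording(
        time_ms=time_ms,
        load_n=load,
        displacement_mm=disp,
        machine=machine,
        nodule_id=geometry.nodule_id,
        meta={
            "contact_index": PRELOAD_SAMPLES,
            "pattern": params.pattern,
            "params": params,
            "drop_events": drops,
            "true_strain": eps,
            "true_stress_mpa": sigma,
        },
    )


def _ar1_noise(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    """Stationary AR(1) noise with marginal standard deviation ``sd``."""
    innov = rng.normal(0.0, sd * math.sqrt(1.0 - DISP_NOISE_AR1**2), size=n)
    innov[0] = rng.normal(0.0, sd)  # stationary start
    return lfilter([1.0], [1.0, -DISP_NOISE_AR1], innov)


@dataclass(frozen=True)
class CohortSpec:
    """Marginals and coupling of a synthetic nodule cohort.

    Defaults reproduce the study conditions of a 129-nodule ex vivo series:
    118/129 three-phase crush patterns, CT density centred at 937 HU with
    IQR [842, 1018], a target Pearson correlation of 0.45 between CT density
    and log Stage-I stiffness (CS10), and dialysis prevalence 20/118 among
    three-phase vs 7/11 among gradual nodules.  Geometry marginals: projected
    area lognormal with median 23.67 mm^2 and quartiles [15.9, 35.22] mm^2;
    height lognormal with median 3.0 mm (log-sd 0.25), an assumption since
    no height distribution is available.
    """

    n_nodules: int = 129
    three_phase_fraction: float = 118 / 129
    ct_mean_hu: float = 937.0
    ct_iqr_hu: tuple[float, float] = (842.0, 1018.0)
    ct_stiffness_correlation: float = 0.45
    dialysis_rate_three_phase: float = 20 / 118
    dialysis_rate_gradual: float = 7 / 11
    area_log_median_mm2: float = 23.67
    area_log_sd: float = 0.589  # ln(35.22/23.67)/0.6745
    height_log_median_mm: float = 3.0
    height_log_sd: float = 0.25
    plateau_log_median_mpa: float = 0.42
    plateau_log_sd: float = 0.95
    machine: MachineSpec = field(default_factory=MachineSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodules < 1:
            raise SpecValidationError("n_nodules must be >= 1")
        for name in (
            "three_phase_fraction",
            "dialysis_rate_three_phase",
            "dialysis_rate_gradual",
        ):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise SpecValidationError(f"{name} must be in [0, 1]")
        if not -1.0 <= self.ct_stiffness_correlation <= 1.0:
            raise SpecValidationError("ct_stiffness_correlation must be in [-1, 1]")
        if self.ct_iqr_hu[0] >= self.ct_iqr_hu[1]:
            raise SpecValidationError("ct_iqr_hu must be an increasing pair")


def _draw_params(
    pattern: str, z_stiff: float, spec: CohortSpec, rng: np.random.Generator
) -> CrushCurveParams:
    """Per-nodule crush parameters; ``z_stiff`` is the latent stiffness score."""
    if pattern == "three_phase":
        plateau = float(
            np.exp(np.log(spec.plateau_log_median_mpa) + spec.plateau_log_sd * z_stiff)
        )
        yield_strain = float(rng.uniform(0.05, 0.12))
        return CrushCurveParams(
            pattern="three_phase",
            elastic_modulus_mpa=plateau / yield_strain,
            yield_strain=yield_strain,
            plateau_stress_mpa=plateau,
            drop_rate=float(rng.uniform(5.0, 25.0)),
            drop_depth_fraction=float(rng.uniform(0.05, 0.25)),
            densification_onset=float(rng.uniform(0.30, 0.50)),
            densification_exponent=float(rng.uniform(1.2, 2.2)),
        )
    scale = float(np.exp(np.log(3.5) + 0.6 * z_stiff))
    return CrushCurveParams(
        pattern="gradual",
        gradual_scale_mpa=scale,
        gradual_power=float(rng.uniform(1.3, 2.5)),
        drop_rate=0.0,
    )


def _log_cs10_proxy(params: CrushCurveParams) -> float:
    """Latent log-stiffness used to couple CT density to the curve: the log
    of the noise-free stress at 10% strain."""
    return float(np.log(true_stress(params, np.array([0.1]))[0]))


def simulate_cohort(
    spec: CohortSpec,
) -> tuple[list[NoduleRecord], list[TestRecording]]:
    """Generate a full synthetic cohort of nodule records and recordings.

    Pattern and dialysis assignments match the spec rates exactly at the
    count level (rounded); CT density is drawn as a linear-plus-noise
    function of the standardized latent log CS10, which yields the target
    Pearson correlation in expectation regardless of the stiffness mixture
    shape.  Fixed seed gives identical output.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_nodules
    n_three = int(round(n * spec.three_phase_fraction))
    patterns = np.array(["three_phase"] * n_three + ["gradual"] * (n - n_three))
    rng.shuffle(patterns)

    z_stiff = rng.normal(size=n)
    params_list = [_draw_params(p, z, spec, rng) for p, z in zip(patterns, z_stiff)]

    # CT density coupled to the realized latent stiffness.
    ell = np.array([_log_cs10_proxy(p) for p in params_list])
    ell_std = (ell - ell.mean()) / (ell.std() if ell.std() > 0 else 1.0)
    rho = spec.ct_stiffness_correlation
    ct_sd = (spec.ct_iqr_hu[1] - spec.ct_iqr_hu[0]) / 1.349
    ct = spec.ct_mean_hu + ct_sd * (
        rho * ell_std + math.sqrt(1.0 - rho**2) * rng.normal(size=n)
    )

    # Dialysis flags: exact counts per pattern group, random positions.
    dialysis = np.zeros(n, dtype=bool)
    for pat, rate in (
        ("three_phase", spec.dialysis_rate_three_phase),
        ("gradual", spec.dialysis_rate_gradual),
    ):
        idx = np.flatnonzero(patterns == pat)
        k = int(round(idx.size * rate))
        if k > 0:
            dialysis[rng.choice(idx, size=k, replace=False)] = True

    a0 = np.exp(
        np.log(spec.area_log_median_mm2) + spec.area_log_sd * rng.normal(size=n)
    )
    h0 = np.exp(
        np.log(spec.height_log_median_mm) + spec.height_log_sd * rng.normal(size=n)
    )

    records: list[NoduleRecord] = []
    recordings: list[TestRecording] = []
    curve_seeds = rng.integers(0, 2**31 - 1, size=n)
    for i in range(n):
        rec_id = f"N{i + 1:04d}"
        record = NoduleRecord(
            nodule_id=rec_id,
            patient_id=f"P{i // 3 + 1:03d}",
            a0_mm2=float(a0[i]),
            h0_mm=float(h0[i]),
            ct_hu=float(ct[i]),
            dialysis=bool(dialysis[i]),
            cusp=("L", "R", "N")[int(rng.integers(3))],
            pattern_truth=str(patterns[i]),
        )
        records.append(record)
        recordings.append(
            simulate_crush_curve(
                params_list[i],
                record,
                spec.machine,
                seed=np.random.default_rng(int(curve_seeds[i])),
            )
        )
    return records, recordings


# ---------------------------------------------------------------------------
# CT phantom
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CTBlob:
    """Uniform-intensity ellipsoid added to the phantom background."""

    center_mm: tuple[float, float, float]
    radii_mm: tuple[float, float, float]
    peak_hu: float

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.radii_mm):
            raise SpecValidationError("blob radii must be positive")


@dataclass(frozen=True)
class CTPhantomSpec:
    """Geometry of a synthetic CT volume with calcification-like blobs."""

    shape: tuple[int, int, int] = (40, 40, 40)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    background_hu: float = 0.0
    blobs: tuple[CTBlob, ...] = ()
    noise_sd_hu: float = 0.0
    slab_thickness_mm: float = 16.0
    projection_axis: int = 2
    roi_blob: int = 0
    roi_margin_mm: float = 2.0

    def __post_init__(self) -> None:
        if self.projection_axis not in (0, 1, 2):
            raise SpecValidationError("projection_axis must be 0, 1 or 2")
        extent = self.shape[self.projection_axis] * self.spacing_mm[self.projection_axis]
        if not 0 < self.slab_thickness_mm <= extent:
            raise SpecValidationError(
                f"slab thickness {self.slab_thickness_mm} mm exceeds the volume "
                f"extent {extent} mm along axis {self.projection_axis}"
            )
        for blob in self.blobs:
            for ax in range(3):
                size = self.shape[ax] * self.spacing_mm[ax]
                c, r = blob.center_mm[ax], blob.radii_mm[ax]
                if c - r < 0 or c + r > size:
                    raise SpecValidationError(
                        f"blob at {blob.center_mm} mm (radii {blob.radii_mm}) "
                        f"extends outside the volume along axis {ax}"
                    )


def simulate_ct_volume(
    spec: CTPhantomSpec, seed: int | np.random.Generator = 0
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Build the phantom volume (HU) and an ROI polygon around the designated
    blob's projection.

    Voxel values are background + additive blob contributions + Gaussian
    noise.  The ROI is a rectangle (in projection-plane pixel coordinates,
    ``(x, y) = (column, row)``) enclosing the ``roi_blob`` ellipsoid's
    projection with ``roi_margin_mm`` clearance.  With no blobs, the ROI is
    a small rectangle at the volume centre, which downstream measurement
    flags as carrying no high-density pixels.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    vol = np.full(spec.shape, spec.background_hu, dtype=float)
    grids = [
        (np.arange(spec.shape[ax]) + 0.5) * spec.spacing_mm[ax] for ax in range(3)
    ]
    xx, yy, zz = np.meshgrid(*grids, indexing="ij")
    for blob in spec.blobs:
        inside = (
            ((xx - blob.center_mm[0]) / blob.radii_mm[0]) ** 2
            + ((yy - blob.center_mm[1]) / blob.radii_mm[1]) ** 2
            + ((zz - blob.center_mm[2]) / blob.radii_mm[2]) ** 2
        ) <= 1.0
        vol[inside] += blob.peak_hu
    if spec.noise_sd_hu > 0:
        vol += rng.normal(0.0, spec.noise_sd_hu, size=spec.shape)

    plane_axes = [ax for ax in range(3) if ax != spec.projection_axis]
    if spec.blobs:
        blob = spec.blobs[spec.roi_blob]
        lo, hi = [], []
        for ax in plane_axes:  # row axis first, then column axis
            c, r = blob.center_mm[ax], blob.radii_mm[ax] + spec.roi_margin_mm
            lo.append((c - r) / spec.spacing_mm[ax] - 0.5)
            hi.append((c + r) / spec.spacing_mm[ax] - 0.5)
    else:
        lo = [spec.shape[ax] / 2 - 2 for ax in plane_axes]
        hi = [spec.shape[ax] / 2 + 2 for ax in plane_axes]
    # Polygon vertices as (x=col, y=row).
    roi = [(lo[1], lo[0]), (hi[1], lo[0]), (hi[1], hi[0]), (lo[1], hi[0])]
    return vol, roi


def default_cohort_params(seed: int = 0) -> CrushCurveParams:
    """A representative three-phase parameter set (for examples and docs)."""
    rng = np.random.default_rng(seed)
    return _draw_params("three_phase", 0.0, CohortSpec(), rng)


def noise_free(params: CrushCurveParams) -> CrushCurveParams:
    """Copy of ``params`` with measurement noise switched off."""
    return replace(params, noise_load_sd_n=0.0, noise_disp_sd_mm=0.0)
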