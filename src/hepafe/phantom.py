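"""Synthetic MR phantom and cohort generator for liver-iron quantification.

Simulates the three acquisitions the downstream estimators consume at 1.5 T:

* a 12-echo multi-echo gradient-echo (mGRE) series (TE 1.3–16.9 ms, TR 200 ms,
  flip 20°) for T2* relaxometry,
* the five-sequence gradient-echo set of the liver/muscle signal-intensity-
  ratio (SIR) method (TR 120 ms; one T1-weighted sequence at TE 4 ms / flip
  90°, then four at flip 20° with TE rising 4→21 ms),
* a MOLLI 5(3)3 inversion-recovery series for T1 mapping.

Iron load shortens liver T2* (R2* rises linearly with LIC) and shortens T1.
Magnitude images carry Rician noise.  Every generator is a pure function of
its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .units import LinearR2sCalibration, HANKINS_CALIBRATION, r2s_from_lic

__all__ = [
    "TissueParams",
    "GREAcquisition",
    "MOLLIAcquisition",
    "PhantomScene",
    "CohortSpec",
    "LIVER_BASE",
    "MUSCLE",
    "default_mgre_acquisition",
    "default_urennes_acquisitions",
    "spoiled_gre_signal",
    "molli_signal",
    "add_rician_noise",
    "simulate_mgre_series",
    "simulate_urennes_set",
    "simulate_molli_series",
    "simulate_cohort",
    "liver_tissue_for_lic",
    "r1_for_lic",
    "build_scene",
]


@dataclass(frozen=True)
class TissueParams:
    """Relaxation parameters of one tissue compartment.

    proton_density is in arbitrary signal units; t1_ms and t2star_ms are the
    longitudinal and effective transverse relaxation times in milliseconds.
    """

    proton_density: float
    t1_ms: float
    t2star_ms: float
    label: str = ""

    def __post_init__(self) -> None:
        for name in ("proton_density", "t1_ms", "t2star_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


#: Healthy liver at 1.5 T.
LIVER_BASE = TissueParams(proton_density=100.0, t1_ms=576.0, t2star_ms=33.0, label="liver")
#: Paraspinal muscle — the iron-free reference tissue of the SIR method.
#: Amplitude chosen so a normal liver's liver/muscle ratio is ≈1 on the
#: flip-20° sequences, as the ratio method assumes.
MUSCLE = TissueParams(proton_density=112.0, t1_ms=870.0, t2star_ms=30.0, label="muscle")


@dataclass(frozen=True)
class GREAcquisition:
    """Spoiled gradient-echo acquisition parameters.

    ``echo_times_ms`` holds one echo for the single-echo SIR sequences and
    twelve for the mGRE relaxometry series.
    """

    tr_ms: float
    echo_times_ms: tuple[float, ...]
    flip_deg: float

    def __post_init__(self) -> None:
        te = np.asarray(self.echo_times_ms, dtype=float)
        object.__setattr__(self, "echo_times_ms", tuple(te))
        if te.size == 0 or np.any(te <= 0) or np.any(np.diff(te) <= 0):
            raise ValueError("echo times must be positive and strictly increasing")
        if not 0 < self.flip_deg <= 90:
            raise ValueError("flip angle must be in (0, 90] degrees")
        if self.tr_ms <= 0:
            raise ValueError("TR must be positive")


def default_mgre_acquisition() -> GREAcquisition:
    """12-echo mGRE protocol: TE evenly spaced 1.3–16.9 ms, TR 200 ms, flip 20°.

    The stated range endpoints are honored exactly; the resulting step is
    ≈1.418 ms.
    """
    return GREAcquisition(
        tr_ms=200.0,
        echo_times_ms=tuple(np.linspace(1.3, 16.9, 12)),
        flip_deg=20.0,
    )


def default_urennes_acquisitions(
    te_ladder_ms: tuple[float, ...] = (4.0, 9.0, 14.0, 21.0)
) -> tuple[GREAcquisition, ...]:
    """Five-sequence SIR protocol at TR 120 ms.

    Sequence 1 is T1-weighted (TE 4 ms, flip 90°); sequences 2–5 use flip 20°
    with progressively longer TE (default ladder 4, 9, 14, 21 ms).
    """
    seqs = [GREAcquisition(tr_ms=120.0, echo_times_ms=(4.0,), flip_deg=90.0)]
    seqs += [
        GREAcquisition(tr_ms=120.0, echo_times_ms=(te,), flip_deg=20.0)
        for te in te_ladder_ms
    ]
    return tuple(seqs)


@dataclass(frozen=True)
class MOLLIAcquisition:
    """MOLLI readout pattern and the effective inversion-time ladder.

    The 5(3)3 scheme at the default pacing of 60 bpm yields five readouts
    after the first inversion (base TI 100 ms) and three after the second
    (base TI 180 ms), spaced one RR interval (1000 ms) apart.
    """

    scheme: str = "5(3)3"
    heart_rate_bpm: float = 60.0
    base_ti_ms: tuple[float, float] = (100.0, 180.0)
    ti_ms: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not self.ti_ms:
            rr = 60000.0 / self.heart_rate_bpm
            tis = [self.base_ti_ms[0] + k * rr for k in range(5)]
            tis += [self.base_ti_ms[1] + k * rr for k in range(3)]
            object.__setattr__(self, "ti_ms", tuple(sorted(tis)))
        if any(t <= 0 for t in self.ti_ms):
            raise ValueError("inversion times must be positive")


# region labels of a PhantomScene grid
LABEL_BACKGROUND = 0
LABEL_LIVER = 1
LABEL_MUSCLE_RIGHT = 2
LABEL_MUSCLE_LEFT = 3
REGION_NAMES = {
    "background": LABEL_BACKGROUND,
    "liver": LABEL_LIVER,
    "muscle_right": LABEL_MUSCLE_RIGHT,
    "muscle_left": LABEL_MUSCLE_LEFT,
}


@dataclass(frozen=True)
class PhantomScene:
    """Single-slice digital phantom: a label map plus per-region tissues.

    ``labels`` partitions the grid into background (signal 0), liver and the
    right/left paraspinal muscles.  ``pixel_size_mm`` sets the in-plane pixel
    area so ROI sizes in cm² are expressible.
    """

    labels: np.ndarray
    tissues: dict[str, TissueParams]
    noise_sigma: float = 0.5
    seed: int = 0
    pixel_size_mm: tuple[float, float] = (3.125, 3.125)

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        present = set(np.unique(self.labels))
        known = set(REGION_NAMES.values())
        if not present <= known:
            raise ValueError(f"unknown labels in scene: {present - known}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def mask(self, region: str) -> np.ndarray:
        return self.labels == REGION_NAMES[region]

    def has_region(self, region: str) -> bool:
        return bool(np.any(self.mask(region)))


def _ellipse(shape: tuple[int, int], center: tuple[float, float], radii: tuple[float, float]) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return ((rr - center[0]) / radii[0]) ** 2 + ((cc - center[1]) / radii[1]) ** 2 <= 1.0


def build_scene(
    liver: TissueParams = LIVER_BASE,
    muscle: TissueParams = MUSCLE,
    shape: tuple[int, int] = (128, 128),
    noise_sigma: float = 0.5,
    seed: int = 0,
    pixel_size_mm: tuple[float, float] | None = None,
) -> PhantomScene:
    """Build the default abdominal-slice geometry at any grid size.

    A large liver ellipse occupies the upper half of the grid; two small
    paraspinal-muscle ellipses sit posteriorly.  Geometry scales with shape.
    """
    h, w = shape
    labels = np.zeros(shape, dtype=np.int8)
    labels[_ellipse(shape, (0.42 * h, 0.42 * w), (0.30 * h, 0.32 * w))] = LABEL_LIVER
    labels[_ellipse(shape, (0.82 * h, 0.36 * w), (0.08 * h, 0.08 * w))] = LABEL_MUSCLE_RIGHT
    labels[_ellipse(shape, (0.82 * h, 0.64 * w), (0.08 * h, 0.08 * w))] = LABEL_MUSCLE_LEFT
    if pixel_size_mm is None:
        pixel_size_mm = (400.0 / h, 400.0 / w)
    return PhantomScene(
        labels=labels,
        tissues={
            "liver": replace(liver, label="liver"),
            "muscle_right": replace(muscle, label="muscle_right"),
            "muscle_left": replace(muscle, label="muscle_left"),
        },
        noise_sigma=noise_sigma,
        seed=seed,
        pixel_size_mm=pixel_size_mm,
    )


# --------------------------------------------------------------------------
# signal models


def spoiled_gre_signal(tissue: TissueParams, acq: GREAcquisition, te_ms: float | None = None):
    """Steady-state spoiled gradient-echo magnitude signal.

    S = PD · sinα · (1 − E1) / (1 − cosα·E1) · exp(−TE/T2*),  E1 = exp(−TR/T1).

    If ``te_ms`` is None the signal is evaluated at every echo of ``acq`` and
    an array is returned; otherwise a scalar at the given TE.
    """
    te = np.asarray(acq.echo_times_ms if te_ms is None else te_ms, dtype=float)
    alpha = np.deg2rad(acq.flip_deg)
    e1 = np.exp(-acq.tr_ms / tissue.t1_ms)
    s = (
        tissue.proton_density
        * np.sin(alpha)
        * (1.0 - e1)
        / (1.0 - np.cos(alpha) * e1)
        * np.exp(-te / tissue.t2star_ms)
    )
    return float(s) if np.isscalar(te_ms) else s


def molli_signal(t1star_ms: float, a_coeff: float, b_coeff: float, ti_ms):
    """Three-parameter inversion-recovery model S(TI) = A − B·exp(−TI/T1*).

    ``t1star_ms`` is the *apparent* T1 of the Look-Locker experiment; the true
    T1 follows from the correction T1 = T1*·(B/A − 1).  The returned signal is
    signed (polarity intact).
    """
    if t1star_ms <= 0:
        raise ValueError("T1* must be strictly positive")
    ti = np.asarray(ti_ms, dtype=float)
    if np.any(ti < 0):
        raise ValueError("inversion times must be non-negative")
    s = a_coeff - b_coeff * np.exp(-ti / t1star_ms)
    return float(s) if ti.ndim == 0 else s


def add_rician_noise(image: np.ndarray, sigma: float, rng) -> np.ndarray:
    """Corrupt a magnitude image with Rician noise of scale ``sigma``.

    The noisy magnitude is |S + n1 + i·n2| with n1, n2 ~ N(0, σ²); sigma = 0
    returns the input unchanged.  ``rng`` is a seed or a numpy Generator.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    image = np.asarray(image, dtype=float)
    if sigma == 0:
        return image.copy()
    rng = np.random.default_rng(rng)
    n1 = rng.normal(0.0, sigma, image.shape)
    n2 = rng.normal(0.0, sigma, image.shape)
    return np.sqrt((image + n1) ** 2 + n2**2)


# --------------------------------------------------------------------------
# image-series simulators


def _render(scene: PhantomScene, region_signal: dict[str, float]) -> np.ndarray:
    img = np.zeros(scene.shape, dtype=float)
    for region, sig in region_signal.items():
        img[scene.mask(region)] = sig
    return img


def simulate_mgre_series(
    scene: PhantomScene, acq: GREAcquisition | None = None
) -> tuple[np.ndarray, dict]:
    """Simulate the multi-echo GRE stack: one magnitude image per echo.

    Returns (stack, meta) with stack shaped (n_echoes, rows, cols) and meta
    carrying TR/TE/flip/seed.  Noise is Rician, independent per echo, seeded
    from the scene.
    """
    if acq is None:
        acq = default_mgre_acquisition()
    if len(acq.echo_times_ms) < 3:
        raise ValueError("mGRE simulation needs at least 3 echoes")
    if not scene.has_region("liver"):
        raise ValueError("scene has no liver region")
    rng = np.random.default_rng(scene.seed)
    stack = []
    for te in acq.echo_times_ms:
        sig = {
            region: spoiled_gre_signal(tissue, acq, te_ms=te)
            for region, tissue in scene.tissues.items()
        }
        stack.append(add_rician_noise(_render(scene, sig), scene.noise_sigma, rng))
    meta = {
        "tr_ms": acq.tr_ms,
        "echo_times_ms": list(acq.echo_times_ms),
        "flip_deg": acq.flip_deg,
        "noise_sigma": scene.noise_sigma,
        "seed": scene.seed,
    }
    return np.stack(stack), meta


def simulate_urennes_set(
    scene: PhantomScene, acqs: tuple[GREAcquisition, ...] | None = None
) -> tuple[np.ndarray, list[dict]]:
    """Simulate the five-sequence SIR image set.

    Returns (stack of 5 images, list of per-sequence metadata).  Requires the
    scene to contain the liver and both paraspinal muscle regions.
    """
    if acqs is None:
        acqs = default_urennes_acquisitions()
    if len(acqs) != 5:
        raise ValueError("the SIR protocol uses exactly five sequences")
    for region in ("liver", "muscle_right", "muscle_left"):
        if not scene.has_region(region):
            raise ValueError(f"scene is missing required region {region!r}")
    rng = np.random.default_rng(scene.seed + 1)
    stack, meta = [], []
    for i, acq in enumerate(acqs, start=1):
        te = acq.echo_times_ms[0]
        sig = {
            region: spoiled_gre_signal(tissue, acq, te_ms=te)
            for region, tissue in scene.tissues.items()
        }
        stack.append(add_rician_noise(_render(scene, sig), scene.noise_sigma, rng))
        meta.append({"sequence": i, "tr_ms": acq.tr_ms, "te_ms": te, "flip_deg": acq.flip_deg})
    return np.stack(stack), meta


def simulate_molli_series(
    scene: PhantomScene,
    acq: MOLLIAcquisition | None = None,
    b_over_a: float = 1.9,
) -> tuple[np.ndarray, dict]:
    """Simulate a magnitude MOLLI inversion-recovery stack.

    For each tissue, A is taken as its proton density and B = ``b_over_a``·A;
    the apparent T1* = T1/(B/A − 1) encodes the Look-Locker readout-driven
    shortening so the standard correction recovers the tissue T1 exactly.
    Polarity is lost (absolute value), as on magnitude scanner output.
    """
    if acq is None:
        acq = MOLLIAcquisition()
    if b_over_a <= 1.0:
        raise ValueError("b_over_a must exceed 1 for a physical recovery")
    rng = np.random.default_rng(scene.seed + 2)
    stack = []
    for ti in acq.ti_ms:
        sig = {}
        for region, tissue in scene.tissues.items():
            a = tissue.proton_density
            t1star = tissue.t1_ms / (b_over_a - 1.0)
            sig[region] = abs(molli_signal(t1star, a, b_over_a * a, ti))
        stack.append(add_rician_noise(_render(scene, sig), scene.noise_sigma, rng))
    meta = {"scheme": acq.scheme, "ti_ms": list(acq.ti_ms), "seed": scene.seed}
    return np.stack(stack), meta


# --------------------------------------------------------------------------
# iron → relaxation-parameter link


def liver_tissue_for_lic(
    lic_mg_g: float,
    base: TissueParams = LIVER_BASE,
    calib: LinearR2sCalibration = HANKINS_CALIBRATION,
    r1_slope_hz_per_mg_g: float = 0.1,
    r2s_floor_hz: float = 2.5,
) -> TissueParams:
    """Liver tissue parameters at a given iron concentration.

    T2* follows the inverse of the linear R2*↔LIC calibration (floored at
    ``r2s_floor_hz`` so T2* stays finite at near-zero iron); T1 shortens
    linearly in rate: R1 = R1(base) + slope·LIC.
    """
    r2s = max(r2s_from_lic(lic_mg_g, calib), r2s_floor_hz)
    r1 = 1000.0 / base.t1_ms + r1_slope_hz_per_mg_g * lic_mg_g
    return TissueParams(
        proton_density=base.proton_density,
        t1_ms=1000.0 / r1,
        t2star_ms=1000.0 / r2s,
        label="liver",
    )


def r1_for_lic(
    lic_mg_g, base: TissueParams = LIVER_BASE, r1_slope_hz_per_mg_g: float = 0.1
):
    """Liver R1 (Hz) at a given LIC under the linear iron–R1 model."""
    return 1000.0 / base.t1_ms + r1_slope_hz_per_mg_g * np.asarray(lic_mg_g, dtype=float)


# --------------------------------------------------------------------------
# cohort generator


@dataclass(frozen=True)
class MethodNoise:
    """Per-method read-noise model on the method's own reporting scale."""

    mult_sd: float = 0.05
    add_sd: float = 0.1
    bias: float = 0.0
    scale: float = 1.0  # overall inflation factor for this channel


#: Default per-method read noise.  The T1 channel carries 5× the noise of the
#: T2*-based channels, emulating the much larger dispersion of R1 reads.
DEFAULT_METHOD_NOISE = {
    "urennes": MethodNoise(mult_sd=0.05, add_sd=1.8),   # µmol/g scale
    "manual_t2s": MethodNoise(mult_sd=0.05, add_sd=0.1),  # mg/g scale
    "t2s_map": MethodNoise(mult_sd=0.05, add_sd=0.1),     # mg/g scale
    "t1_map": MethodNoise(mult_sd=0.05, add_sd=0.02, scale=5.0),  # R1, Hz
}


@dataclass(frozen=True)
class CohortSpec:
    """Study-population generator: 53 iron-overload patients, 21 controls.

    True LIC (mg/g dry weight): controls ~ normal(1.0, 0.4) truncated to
    (0.2, 2); patients ~ lognormal with median 6 mg/g and σ_log 0.8,
    truncated to ``patient_bounds``
    (default upper bound 43 mg/g).  Two raters, the first with a repeat read.
    """

    n_patients: int = 53
    n_controls: int = 21
    control_mean: float = 1.0
    control_sd: float = 0.4
    control_bounds: tuple[float, float] = (0.2, 2.0)
    patient_median: float = 6.0
    patient_sigma_log: float = 0.8
    patient_bounds: tuple[float, float] = (0.0, 43.0)
    method_noise: dict = field(default_factory=lambda: dict(DEFAULT_METHOD_NOISE))
    n_raters: int = 2
    n_repeats: int = 2  # repeats by rater 1, for intraobserver agreement
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2 or self.n_controls < 2:
            raise ValueError("need at least 2 subjects per group")
        if self.control_sd < 0:
            raise ValueError("SDs must be >= 0")


def _truncated(draw, accept, rng, n: int) -> np.ndarray:
    out = np.empty(0)
    while out.size < n:
        cand = draw(rng, 2 * n)
        out = np.concatenate([out, cand[accept(cand)]])
    return out[:n]


def sample_true_lic(spec: CohortSpec, rng) -> pd.DataFrame:
    """Draw per-subject true LIC (mg/g) and group labels."""
    controls = _truncated(
        lambda r, m: r.normal(spec.control_mean, spec.control_sd, m),
        lambda x: (x > spec.control_bounds[0]) & (x < spec.control_bounds[1]),
        rng,
        spec.n_controls,
    )
    patients = _truncated(
        lambda r, m: r.lognormal(np.log(spec.patient_median), spec.patient_sigma_log, m),
        lambda x: (x > spec.patient_bounds[0]) & (x < spec.patient_bounds[1]),
        rng,
        spec.n_patients,
    )
    return pd.DataFrame(
        {
            "subject_id": [f"S{i:03d}" for i in range(spec.n_patients + spec.n_controls)],
            "group": ["patient"] * spec.n_patients + ["control"] * spec.n_controls,
            "true_lic_mg_g": np.concatenate([patients, controls]),
        }
    )


_METHOD_UNITS = {
    "urennes": "umol_per_g_dry",
    "manual_t2s": "mg_per_g_dry",
    "t2s_map": "mg_per_g_dry",
    "t1_map": "hz",
}


def _method_true_value(method: str, lic_mg_g: np.ndarray) -> np.ndarray:
    """Noise-free reading of each method on its own reporting scale."""
    if method == "urennes":
        return lic_mg_g / 0.055845  # µmol/g (MG_PER_UMOL)
    if method == "t1_map":
        return r1_for_lic(lic_mg_g)  # R1 in Hz; no LIC conversion exists
    return np.asarray(lic_mg_g, dtype=float)  # mg/g


def simulate_cohort(spec: CohortSpec | None = None) -> pd.DataFrame:
    """Generate the full rating table: subject × method × rater/repeat.

    Each read is the method's noise-free value on its own scale, perturbed by
    multiplicative and additive Gaussian read noise (per-method magnitudes
    from ``spec.method_noise``).  Rater 1's reads are duplicated into
    ``repeat`` indices with fresh noise for intraobserver analysis.

    Returns a tidy DataFrame with columns: subject_id, group, true_lic_mg_g,
    method, rater, repeat, estimate, units.
    """
    if spec is None:
        spec = CohortSpec()
    rng = np.random.default_rng(spec.seed)
    subjects = sample_true_lic(spec, rng)
    lic = subjects["true_lic_mg_g"].to_numpy()
    rows = []
    for method, noise in spec.method_noise.items():
        truth = _method_true_value(method, lic)
        if noise.mult_sd == 0 and noise.add_sd == 0 and spec.n_raters >= 2:
            import warnings

            warnings.warn(f"degenerate (zero) read noise for method {method}")
        for rater in range(1, spec.n_raters + 1):
            repeats = range(1, spec.n_repeats + 1) if rater == 1 else [1]
            for repeat in repeats:
                mult = rng.normal(0.0, noise.mult_sd * noise.scale, lic.size)
                add = rng.normal(0.0, noise.add_sd * noise.scale, lic.size)
                est = truth * (1.0 + mult) + add + noise.bias
                block = subjects.copy()
                block["method"] = method
                block["rater"] = rater
                block["repeat"] = repeat
                block["estimate"] = est
                block["units"] = _METHOD_UNITS.get(method, "mg_per_g_dry")
                rows.append(block)
    return pd.concat(rows, ignore_index=True)
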