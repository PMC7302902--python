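"""End-to-end study runner: simulate → fit all four estimators → compare.

``run_study`` reproduces the structure of a method-comparison study of liver
iron quantification: a patient/control cohort is sampled, each subject's
liver is imaged by the three acquisition protocols, the four estimators are
applied (manual T2* relaxometry, pixelwise T2* mapping, MOLLI T1 mapping,
and the five-sequence signal-intensity-ratio method), two raters (the first
with a repeat read) produce per-method estimates, and the full statistics
battery (ICC, mean-difference tests, ROC/AUC with DeLong contrasts,
Spearman correlations) is computed.  A run is a pure function of its
``RunConfig``: identical config and seed regenerate the report bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import phantom as ph
from .molli import IRSeries, fit_molli
from .relaxometry import EchoSeries, fit_monoexp, fit_t2s_map, roi_mean
from .sir import SIRMeasurement, build_calibration, compute_ratios, estimate_lic_sir
from .stats import (
    compare_auc_paired,
    icc_two_way,
    mean_difference_test,
    rating_matrix,
    roc_auc,
    spearman_rho,
    validate_rating_table,
)
from .units import (
    HANKINS_CALIBRATION,
    MG_PER_UMOL,
    LinearR2sCalibration,
    lic_from_r2s,
)

__all__ = ["RunConfig", "StudyReport", "run_study"]

T2S_METHODS = ("urennes", "manual_t2s", "t2s_map")
ALL_METHODS = T2S_METHODS + ("t1_map",)


@dataclass(frozen=True)
class RunConfig:
    """Complete, serializable description of one study run."""

    cohort: ph.CohortSpec = field(default_factory=ph.CohortSpec)
    grid_shape: tuple[int, int] = (64, 64)
    noise_sigma: float = 0.5
    truncation_policy: str = "best_fit"
    r2s_calibration: LinearR2sCalibration = HANKINS_CALIBRATION
    molli_b_over_a: float = 1.9
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class StudyReport:
    """Per-method estimates and the derived agreement/discrimination tables."""

    ratings: pd.DataFrame
    agreement: pd.DataFrame
    roc: pd.DataFrame
    auc_contrasts: pd.DataFrame
    correlations: pd.DataFrame
    provenance: dict

    def summary_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "auc": {
                r["method"]: {"auc": r["auc"], "ci95": [r["ci_lo"], r["ci_hi"]]}
                for r in self.roc.to_dict("records")
            },
            "icc": {
                f'{r["method"]}_{r["analysis"]}': {"icc": r["icc"], "ci95": [r["icc_lo"], r["icc_hi"]]}
                for r in self.agreement.to_dict("records")
            },
        }


# --------------------------------------------------------------------------
# ROI geometry (fractions of the default scene layout in phantom.build_scene)

_LIVER_CENTER = (0.42, 0.42)
_LIVER_RADII = (0.30, 0.32)


def _circle_mask(shape, center_frac, radius_frac) -> np.ndarray:
    h, w = shape
    rr, cc = np.ogrid[:h, :w]
    r0, c0 = center_frac[0] * h, center_frac[1] * w
    return (rr - r0) ** 2 + (cc - c0) ** 2 <= (radius_frac * h) ** 2


def _liver_circle(shape, offset=(0.0, 0.0), radius_frac=0.12) -> np.ndarray:
    center = (
        _LIVER_CENTER[0] + offset[0] * _LIVER_RADII[0],
        _LIVER_CENTER[1] + offset[1] * _LIVER_RADII[1],
    )
    return _circle_mask(shape, center, radius_frac)


# three liver ROIs of the SIR protocol; six of the T1 scheme (4 right, 2 left)
_SIR_LIVER_OFFSETS = ((-0.35, -0.35), (0.25, -0.40), (-0.05, 0.35))
_T1_OFFSETS = (
    (-0.45, -0.45), (-0.45, 0.30), (0.35, -0.45), (0.00, -0.05),  # right lobe
    (0.35, 0.40), (-0.05, 0.45),                                   # left lobe
)


# --------------------------------------------------------------------------
# per-subject estimation


def _estimate_subject(lic_mg_g: float, cfg: RunConfig, sir_calib, seed: int) -> dict[str, float]:
    """Image one subject's liver and run all four estimators.

    Returns the noise-free-of-rater estimates on each method's own scale:
    mg/g for the T2* routes, µmol/g converted to mg/g for the SIR route,
    and R1 (Hz) for the T1 route.
    """
    liver = ph.liver_tissue_for_lic(lic_mg_g, calib=cfg.r2s_calibration)
    scene = ph.build_scene(
        liver=liver, shape=cfg.grid_shape, noise_sigma=cfg.noise_sigma, seed=seed
    )
    shape = cfg.grid_shape
    liver_roi = _liver_circle(shape)
    out: dict[str, float] = {}

    # manual T2*: ROI-mean decay series, truncated mono-exponential fit
    stack, meta = ph.simulate_mgre_series(scene)
    te = meta["echo_times_ms"]
    series = EchoSeries(tuple(te), tuple(roi_mean(img, liver_roi) for img in stack))
    fit = fit_monoexp(series, method="nls", policy=cfg.truncation_policy, raise_on_invalid=False)
    out["manual_t2s"] = (
        lic_from_r2s(fit.r2star_hz, cfg.r2s_calibration)[0] if fit.valid else np.nan
    )

    # automated T2* map: pixelwise fit, ROI read-off on the map
    t2map = fit_t2s_map(stack, te, policy=cfg.truncation_policy)
    try:
        t2_roi = t2map.roi_mean(liver_roi)
        out["t2s_map"] = lic_from_r2s(1000.0 / t2_roi, cfg.r2s_calibration)[0]
    except ValueError:
        out["t2s_map"] = np.nan

    # SIR: three liver + two muscle ROIs propagated to all five sequences
    sir_stack, _ = ph.simulate_urennes_set(scene)
    liver_masks = [_liver_circle(shape, off, radius_frac=0.06) for off in _SIR_LIVER_OFFSETS]
    muscle_masks = [scene.mask("muscle_right"), scene.mask("muscle_left")]
    meas = SIRMeasurement(
        liver_si={
            s + 1: tuple(roi_mean(sir_stack[s], m) for m in liver_masks) for s in range(5)
        },
        muscle_si={
            s + 1: tuple(roi_mean(sir_stack[s], m) for m in muscle_masks) for s in range(5)
        },
    )
    out["urennes"] = estimate_lic_sir(compute_ratios(meas), sir_calib).lic_umol_g

    # MOLLI T1: six circular liver ROIs, per-ROI recovery fit, averaged T1
    ir_stack, ir_meta = ph.simulate_molli_series(scene, b_over_a=cfg.molli_b_over_a)
    t1s = []
    for off in _T1_OFFSETS:
        m = _liver_circle(shape, off, radius_frac=0.02)
        sig = tuple(roi_mean(img, m) for img in ir_stack)
        t1fit = fit_molli(IRSeries(tuple(ir_meta["ti_ms"]), sig))
        if t1fit.valid:
            t1s.append(t1fit.t1_ms)
    out["t1_map"] = 1000.0 / float(np.mean(t1s)) if t1s else np.nan  # R1, Hz
    return out


def run_study(config: RunConfig | None = None) -> StudyReport:
    """Execute the full simulate → estimate → compare study.

    Stages: cohort sampling, SIR self-calibration, per-subject imaging and
    estimation, rater-read generation, unit harmonization to mg/g (the SIR
    output converts from µmol/g; the T1 channel stays on its R1 scale), and
    the statistics battery.  Raises RuntimeError tagged with the failing
    stage.
    """
    cfg = config or RunConfig()
    ss = np.random.SeedSequence(cfg.seed)
    s_cohort, s_subjects, s_raters = ss.spawn(3)

    try:
        subjects = ph.sample_true_lic(cfg.cohort, np.random.default_rng(s_cohort))
    except Exception as exc:  # pragma: no cover - config errors
        raise RuntimeError(f"[cohort] {exc}") from exc

    try:
        sir_calib = build_calibration(r2s_model=cfg.r2s_calibration)
    except Exception as exc:
        raise RuntimeError(f"[sir-calibration] {exc}") from exc

    try:
        subj_seeds = s_subjects.generate_state(len(subjects)) % (2**31)
        base_estimates = {
            row.subject_id: _estimate_subject(row.true_lic_mg_g, cfg, sir_calib, int(seed))
            for row, seed in zip(subjects.itertuples(), subj_seeds)
        }
    except Exception as exc:
        raise RuntimeError(f"[imaging] {exc}") from exc

    try:
        rng = np.random.default_rng(s_raters)
        rows = []
        for _, subj in subjects.iterrows():
            base = base_estimates[subj.subject_id]
            for method in ALL_METHODS:
                noise = cfg.cohort.method_noise[method]
                v = base[method]
                for rater, repeat in ((1, 1), (1, 2), (2, 1)):
                    est = (
                        v * (1.0 + rng.normal(0.0, noise.mult_sd * noise.scale))
                        + rng.normal(0.0, noise.add_sd * noise.scale)
                        + noise.bias
                    )
                    rows.append(
                        {
                            "subject_id": subj.subject_id,
                            "group": subj.group,
                            "true_lic_mg_g": subj.true_lic_mg_g,
                            "method": method,
                            "rater": rater,
                            "repeat": repeat,
                            "estimate": est,
                            "units": ph._METHOD_UNITS[method],
                        }
                    )
        ratings = pd.DataFrame(rows)
        bad = ratings["estimate"].isna()
        if bad.any():
            dropped = ratings.loc[bad, "subject_id"].unique()
            warnings.warn(f"dropping subjects with failed fits: {list(dropped)}")
            ratings = ratings[~ratings["subject_id"].isin(dropped)]
        validate_rating_table(ratings)
        # harmonize LIC scales to mg/g for cross-method comparison
        sel = ratings["units"] == "umol_per_g_dry"
        ratings.loc[sel, "estimate"] *= MG_PER_UMOL
        ratings.loc[sel, "units"] = "mg_per_g_dry"
    except Exception as exc:
        raise RuntimeError(f"[ratings] {exc}") from exc

    try:
        report = _analyze(ratings, cfg)
    except Exception as exc:
        raise RuntimeError(f"[stats] {exc}") from exc
    report.ratings = ratings
    return report


def _analyze(ratings: pd.DataFrame, cfg: RunConfig) -> StudyReport:
    agreement_rows, roc_rows, contrast_rows, corr_rows = [], [], [], []
    reader1 = ratings[(ratings.rater == 1) & (ratings["repeat"] == 1)]
    labels_by_subj = reader1.drop_duplicates("subject_id").set_index("subject_id")["group"]
    scores: dict[str, np.ndarray] = {}
    order = labels_by_subj.index

    for method in ALL_METHODS:
        for analysis, by in (("interobserver", "rater"), ("intraobserver", "repeat")):
            mat = rating_matrix(ratings, method, by=by)
            icc = icc_two_way(mat)
            diff, ci, p = mean_difference_test(mat[:, 0], mat[:, 1])
            agreement_rows.append(
                {
                    "method": method,
                    "analysis": analysis,
                    "mean_diff": diff,
                    "diff_lo": ci[0],
                    "diff_hi": ci[1],
                    "diff_p": p,
                    "icc": icc.icc,
                    "icc_lo": icc.ci95[0],
                    "icc_hi": icc.ci95[1],
                }
            )
        sel = reader1[reader1.method == method].set_index("subject_id").loc[order]
        scores[method] = sel["estimate"].to_numpy()

    y = (labels_by_subj == "patient").astype(int).to_numpy()
    for method in ALL_METHODS:
        r = roc_auc(scores[method], y)
        roc_rows.append(
            {"method": method, "auc": r.auc, "ci_lo": r.ci95[0], "ci_hi": r.ci95[1]}
        )
    for other in T2S_METHODS:
        diff, p = compare_auc_paired(scores["t1_map"], scores[other], y)
        contrast_rows.append({"method_a": "t1_map", "method_b": other, "auc_diff": diff, "p": p})
    for i, m1 in enumerate(ALL_METHODS):
        for m2 in ALL_METHODS[i + 1 :]:
            rho, p = spearman_rho(scores[m1], scores[m2])
            corr_rows.append({"method_a": m1, "method_b": m2, "spearman_rho": rho, "p": p})

    provenance = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "n_subjects": int(len(order)),
        "config": cfg.to_dict(),
    }
    return StudyReport(
        ratings=ratings,
        agreement=pd.DataFrame(agreement_rows),
        roc=pd.DataFrame(roc_rows),
        auc_contrasts=pd.DataFrame(contrast_rows),
        correlations=pd.DataFrame(corr_rows),
        provenance=provenance,
    )
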