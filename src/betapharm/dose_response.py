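"""Sigmoidal dose-response and single-exponential time-course fitting.

Raw plate signals are normalized within each (receptor, pathway) group
to basal activity (0%) and the maximum effect of a reference full
agonist (100%), then fitted with the four-parameter logistic (4PL)

    y = basal + (Emax - basal) / (1 + 10**(n * (logEC50 - log10 A)))

by least squares with a deterministic multi-start over log-spaced EC50
initializations.  Real-time second-messenger traces are reduced to rate
constants with a single-exponential fit, and rate-vs-concentration data
are themselves fitted with the 4PL (two-stage pipeline).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Callable, Sequence

import numpy as np
from scipy.optimize import least_squares

from betapharm.errors import (
    InsufficientDataError,
    NormalizationError,
    ValidationError,
    WindowError,
)

if TYPE_CHECKING:  # import only for type hints; avoids an io<->dose_response cycle
    from betapharm.io import DoseResponseDataset

logger = logging.getLogger("betapharm")


@dataclass
class NormalizedCurve:
    """One ligand's normalized concentration-response curve.

    Responses are percent of the reference agonist's maximal effect
    (vehicle = 0, reference max = 100); doses are molar, sorted ascending.
    """

    ligand_id: str
    receptor_id: str
    pathway_id: str
    doses: np.ndarray
    responses: np.ndarray
    reference_ligand: str

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.doses.shape != self.responses.shape:
            raise ValidationError("doses and responses must have equal length")
        if (self.doses <= 0).any():
            raise ValidationError("normalized-curve doses must be strictly positive")
        order = np.argsort(self.doses, kind="stable")
        self.doses = self.doses[order]
        self.responses = self.responses[order]


@dataclass
class HillFit:
    """Result of a 4PL fit.

    ``se`` maps parameter name -> asymptotic standard error from the
    Gauss-Newton covariance (J^T J)^-1 * RSS/dof.
    """

    log_ec50: float
    emax: float
    basal: float
    hill_n: float
    se: dict[str, float] = field(default_factory=dict)
    rss: float = float("nan")
    dof: int = 0
    converged: bool = False
    status: str = "ok"
    n_points: int = 0

    @property
    def ec50(self) -> float:
        return 10.0 ** self.log_ec50


@dataclass
class ExpRateFit:
    """Result of a single-exponential fit: rate (s^-1), amplitude, offset."""

    rate_k: float
    amplitude: float
    offset: float
    se: dict[str, float] = field(default_factory=dict)
    window: tuple[float, float] = (float("-inf"), float("inf"))
    rss: float = float("nan")
    dof: int = 0
    converged: bool = False
    status: str = "ok"


def normalize(
    dataset: "DoseResponseDataset",
    reference_ligand: str,
    basal_ligand: str | None = None,
) -> list[NormalizedCurve]:
    """Normalize raw signals per (receptor, pathway) group.

    Basal is the mean of vehicle wells (dose == 0, any ligand, or all
    wells of *basal_ligand* if given); the 100% anchor is the mean
    signal of *reference_ligand* at its highest dose in the group.

        normalized = 100 * (signal - basal_mean) / (ref_max_mean - basal_mean)
    """
    df = dataset.records
    curves: list[NormalizedCurve] = []
    for (receptor, pathway), grp in df.groupby(["receptor", "pathway"], sort=True):
        if basal_ligand is not None:
            basal_rows = grp[grp["ligand"] == basal_ligand]
        else:
            basal_rows = grp[grp["dose"] == 0]
        if basal_rows.empty:
            raise NormalizationError(
                f"no basal/vehicle wells in group (receptor={receptor}, pathway={pathway})"
            )
        ref_rows = grp[(grp["ligand"] == reference_ligand) & (grp["dose"] > 0)]
        if ref_rows.empty:
            raise NormalizationError(
                f"reference ligand {reference_ligand!r} absent from group "
                f"(receptor={receptor}, pathway={pathway})"
            )
        basal_mean = float(basal_rows["signal"].mean())
        top_dose = ref_rows["dose"].max()
        ref_max_mean = float(ref_rows[ref_rows["dose"] == top_dose]["signal"].mean())
        span = ref_max_mean - basal_mean
        if span == 0:
            raise NormalizationError(
                f"reference maximum equals basal in group "
                f"(receptor={receptor}, pathway={pathway})"
            )
        for ligand, lgrp in grp[grp["dose"] > 0].groupby("ligand", sort=True):
            curves.append(
                NormalizedCurve(
                    ligand_id=str(ligand),
                    receptor_id=str(receptor),
                    pathway_id=str(pathway),
                    doses=lgrp["dose"].to_numpy(dtype=float),
                    responses=100.0 * (lgrp["signal"].to_numpy(dtype=float) - basal_mean) / span,
                    reference_ligand=reference_ligand,
                )
            )
    return curves


def hill_response(
    dose: np.ndarray | float,
    basal: float,
    emax: float,
    log_ec50: float,
    hill_n: float,
) -> np.ndarray:
    """Evaluate the 4PL model (agonist mode, ascending)."""
    dose = np.asarray(dose, dtype=float)
    return basal + (emax - basal) / (1.0 + 10.0 ** (hill_n * (log_ec50 - np.log10(dose))))


def _covariance_se(res, n_params: int) -> tuple[dict[int, float], float, int, bool]:
    """Standard errors from the Gauss-Newton approximation at the optimum."""
    rss = float(2.0 * res.cost)
    dof = max(res.fun.size - n_params, 1)
    J = res.jac
    se: dict[int, float] = {}
    ok = True
    try:
        cov = np.linalg.inv(J.T @ J) * rss / dof
        diag = np.diag(cov)
        if (diag < 0).any() or not np.isfinite(diag).all():
            ok = False
        se = {i: float(np.sqrt(max(d, 0.0))) for i, d in enumerate(diag)}
    except np.linalg.LinAlgError:
        ok = False
        se = {i: float("nan") for i in range(n_params)}
    return se, rss, dof, ok


def fit_hill(
    curve: NormalizedCurve | tuple[Sequence[float], Sequence[float]],
    mode: str = "free_basal",
    n_starts: int = 7,
    max_iterations: int = 2000,
) -> HillFit:
    """Fit the 4PL by multi-start least squares.

    *mode* is ``free_basal`` or ``fixed_basal_zero``.  EC50 starts are
    log-spaced across the observed dose range; the best RSS wins, ties
    broken by the slope closest to 1.  Non-convergence and degenerate
    (flat) data are reported via ``status``/``converged``, never raised.
    """
    if isinstance(curve, NormalizedCurve):
        doses, responses = curve.doses, curve.responses
    else:
        doses = np.asarray(curve[0], dtype=float)
        responses = np.asarray(curve[1], dtype=float)
    if mode not in {"free_basal", "fixed_basal_zero"}:
        raise ValueError(f"unknown mode {mode!r}")
    n_distinct = np.unique(doses).size
    if n_distinct < 4:
        raise InsufficientDataError(
            f"4PL fit needs >= 4 distinct doses, got {n_distinct}"
        )
    if not np.isfinite(responses).all():
        raise ValidationError("responses must be finite")

    span = float(responses.max() - responses.min())
    if span == 0.0:
        return HillFit(
            log_ec50=float("nan"), emax=float(responses[0]), basal=float(responses[0]),
            hill_n=float("nan"), converged=False, status="unidentifiable_flat",
            n_points=doses.size,
        )

    logd = np.log10(doses)
    fixed_basal = mode == "fixed_basal_zero"

    def unpack(p: np.ndarray) -> tuple[float, float, float, float]:
        if fixed_basal:
            emax, log_ec50, log_n = p
            basal = 0.0
        else:
            basal, emax, log_ec50, log_n = p
        return basal, emax, log_ec50, float(np.exp(log_n))

    def residuals(p: np.ndarray) -> np.ndarray:
        basal, emax, log_ec50, hill_n = unpack(p)
        return hill_response(doses, basal, emax, log_ec50, hill_n) - responses

    basal0 = 0.0 if fixed_basal else float(responses.min())
    emax0 = float(responses.max())
    starts = np.linspace(logd.min(), logd.max(), n_starts)
    best = None
    for lec50 in starts:
        p0 = [emax0, lec50, 0.0] if fixed_basal else [basal0, emax0, lec50, 0.0]
        try:
            res = least_squares(residuals, p0, method="lm", max_nfev=max_iterations)
        except Exception:  # pragma: no cover - optimizer pathologies
            continue
        if not np.isfinite(res.cost):
            continue
        _, _, _, hn = unpack(res.x)
        key = (round(float(res.cost), 12), abs(hn - 1.0))
        if best is None or key < best[0]:
            best = (key, res)
    if best is None:
        return HillFit(
            log_ec50=float("nan"), emax=float("nan"), basal=float("nan"),
            hill_n=float("nan"), converged=False, status="no_convergence",
            n_points=doses.size,
        )
    res = best[1]
    basal, emax, log_ec50, hill_n = unpack(res.x)
    npar = res.x.size
    idx_se, rss, dof, cov_ok = _covariance_se(res, npar)
    if fixed_basal:
        se = {"emax": idx_se[0], "log_ec50": idx_se[1],
              "hill_n": idx_se[2] * hill_n, "basal": 0.0}
    else:
        se = {"basal": idx_se[0], "emax": idx_se[1], "log_ec50": idx_se[2],
              "hill_n": idx_se[3] * hill_n}
    status = "ok"
    # EC50 wandering far outside the dose range means the plateau was not reached
    if log_ec50 < logd.min() - 3 or log_ec50 > logd.max() + 3:
        status = "ec50_outside_dose_range"
    if not cov_ok:
        status = "covariance_singular" if status == "ok" else status
    return HillFit(
        log_ec50=float(log_ec50), emax=float(emax), basal=float(basal),
        hill_n=float(hill_n), se=se, rss=rss, dof=dof,
        converged=bool(res.success), status=status, n_points=doses.size,
    )


def fit_single_exponential(
    times: Sequence[float],
    signal: Sequence[float],
    window: tuple[float, float] | None = None,
    mode: str = "rise",
    max_iterations: int = 2000,
) -> ExpRateFit:
    """Fit a single exponential rise or decay inside *window*.

    rise:  y = offset + amplitude * (1 - exp(-k t))
    decay: y = offset + amplitude * exp(-k t)

    k > 0 is enforced by log-parameterization.  Fitting a decay with
    rise mode (or vice versa) yields a negative amplitude, which is
    flagged via ``status = 'sign_mismatch'``.
    """
    if mode not in {"rise", "decay"}:
        raise ValueError(f"unknown mode {mode!r}")
    t = np.asarray(times, dtype=float)
    y = np.asarray(signal, dtype=float)
    if window is not None:
        mask = (t >= window[0]) & (t <= window[1])
        if not mask.any():
            raise WindowError(f"window {window} excludes all {t.size} points")
        t, y = t[mask], y[mask]
    else:
        window = (float(t.min()), float(t.max()))
    if t.size < 4:
        raise InsufficientDataError(
            f"single-exponential fit needs >= 4 points in window, got {t.size}"
        )
    span = float(y.max() - y.min())
    if span == 0.0:
        return ExpRateFit(
            rate_k=float("nan"), amplitude=0.0, offset=float(y[0]),
            window=window, converged=False, status="unidentifiable_constant",
        )

    t0 = t - t.min()  # fit relative to window start for conditioning

    def model(p: np.ndarray) -> np.ndarray:
        offset, amplitude, log_k = p
        k = np.exp(log_k)
        if mode == "rise":
            return offset + amplitude * (1.0 - np.exp(-k * t0))
        return offset + amplitude * np.exp(-k * t0)

    def residuals(p: np.ndarray) -> np.ndarray:
        return model(p) - y

    t_scale = max(float(t0.max()), 1e-12)
    amp0 = y[-1] - y[0] if mode == "rise" else y[0] - y[-1]
    off0 = y[0] if mode == "rise" else y[-1]
    best = None
    for k0 in (0.3 / t_scale, 1.0 / t_scale, 5.0 / t_scale, 30.0 / t_scale):
        p0 = [off0, amp0 if amp0 != 0 else span, np.log(k0)]
        try:
            res = least_squares(residuals, p0, method="lm", max_nfev=max_iterations)
        except Exception:  # pragma: no cover
            continue
        if not np.isfinite(res.cost):
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        return ExpRateFit(rate_k=float("nan"), amplitude=float("nan"),
                          offset=float("nan"), window=window,
                          converged=False, status="no_convergence")
    offset, amplitude, log_k = best.x
    k = float(np.exp(log_k))
    idx_se, rss, dof, _ = _covariance_se(best, 3)
    se = {"offset": idx_se[0], "amplitude": idx_se[1], "rate_k": idx_se[2] * k}
    status = "ok"
    if amplitude < 0:
        status = "sign_mismatch"
    return ExpRateFit(
        rate_k=k, amplitude=float(amplitude), offset=float(offset), se=se,
        window=window, rss=rss, dof=dof, converged=bool(best.success), status=status,
    )


def camp_rate_dose_response(
    time_courses: dict[float, tuple[Sequence[float], Sequence[float]]],
    window: tuple[float, float] = (5.0, 305.0),
    mode: str = "rise",
    hill_mode: str = "free_basal",
) -> tuple[HillFit, dict[float, ExpRateFit]]:
    """Two-stage analysis of real-time cAMP accumulation.

    Stage 1 fits a single exponential (within *window*, default 5-305 s)
    to each agonist concentration's trace to extract a rate constant;
    stage 2 fits the 4PL to (concentration, rate) pairs.  Traces whose
    rate is unidentifiable (constant signal) are excluded with a warning.

    Returns the stage-2 HillFit and the stage-1 fits keyed by dose.
    """
    stage1: dict[float, ExpRateFit] = {}
    doses: list[float] = []
    rates: list[float] = []
    for dose in sorted(time_courses):
        t, y = time_courses[dose]
        fit = fit_single_exponential(t, y, window=window, mode=mode)
        stage1[dose] = fit
        if fit.converged and np.isfinite(fit.rate_k) and fit.status == "ok":
            doses.append(dose)
            rates.append(fit.rate_k)
        else:
            logger.warning(
                "excluding dose %.3g from rate dose-response (status=%s)",
                dose, fit.status,
            )
    if len(doses) < 4:
        raise InsufficientDataError(
            f"rate dose-response needs >= 4 usable concentrations, got {len(doses)}"
        )
    hill = fit_hill((np.asarray(doses), np.asarray(rates)), mode=hill_mode)
    return hill, stage1
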