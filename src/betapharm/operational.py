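"""Operational-model quantification of ligand bias.

The operational model of agonism describes the response to agonist
concentration A as

    E = Em * tau^n * A^n / ((A + KA)^n + tau^n * A^n)

where Em is the maximal response of the system, n the transducer slope,
tau the operational efficacy of the agonist and KA its functional
dissociation constant.  The transduction coefficient log(tau/KA)
captures agonism in one pathway in a single system-independent number.
Comparing a test agonist to a reference within a pathway gives
Delta log(tau/KA) and the relative effectiveness RE = 10^Delta; comparing
those deltas across two pathways gives DeltaDelta log(tau/KA) and the
bias factor 10^DeltaDelta (1 = unbiased).

For full agonists tau and KA are not separately identifiable: only
their ratio R = tau/KA is.  Such ligands are fitted in the reduced form

    E = Em * (R*A)^n / (1 + (R*A)^n)

(the tau -> inf, A << KA limit of the full model), while partial
agonists carry separate (log tau, log KA) parameters.  Em and n are
shared across ligands within one (receptor, pathway) group.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from betapharm.errors import InsufficientDataError, ValidationError
from betapharm.dose_response import NormalizedCurve, fit_hill

logger = logging.getLogger("betapharm")


@dataclass
class OperationalParams:
    """Joint operational-model fit for one (receptor, pathway) group."""

    receptor_id: str
    pathway_id: str
    em: float  # system maximal response, percent
    trans_n: float  # transducer slope
    log_r: dict[str, float]  # ligand -> log10(tau/KA)
    log_tau: dict[str, float]  # partial agonists only
    log_ka: dict[str, float]  # partial agonists only
    full_agonists: list[str]
    se_log_r: dict[str, float] = field(default_factory=dict)
    param_names: list[str] = field(default_factory=list)
    covariance: np.ndarray | None = None
    rss: float = float("nan")
    dof: int = 0
    converged: bool = False
    status: str = "ok"


@dataclass
class TransductionCoefficient:
    """log10(tau/KA) of one ligand in one pathway, with standard error."""

    ligand_id: str
    receptor_id: str
    pathway_id: str
    log_r: float
    se_log_r: float

    def __post_init__(self) -> None:
        if self.se_log_r < 0:
            raise ValidationError("se_log_r must be >= 0")


@dataclass
class BiasResult:
    """Cross-pathway bias of a test ligand against a reference ligand."""

    test_ligand: str
    reference_ligand: str
    receptor_id: str
    pathway_a: str
    pathway_b: str
    delta_log_r: dict[str, float]  # pathway -> Delta log(tau/KA)
    se_delta_log_r: dict[str, float]
    re: dict[str, float]  # pathway -> relative effectiveness 10^Delta
    delta_delta_log_r: float
    se_delta_delta_log_r: float
    bias_factor: float


def operational_response(
    dose: np.ndarray, em: float, trans_n: float, log_tau: float, log_ka: float
) -> np.ndarray:
    """Full operational model E(A)."""
    dose = np.asarray(dose, dtype=float)
    tau = 10.0 ** log_tau
    ka = 10.0 ** log_ka
    ta = (tau * dose) ** trans_n
    return em * ta / ((dose + ka) ** trans_n + ta)


def operational_response_full_agonist(
    dose: np.ndarray, em: float, trans_n: float, log_r: float
) -> np.ndarray:
    """Reduced form for full agonists, parameterized by log10(tau/KA) only."""
    dose = np.asarray(dose, dtype=float)
    ra = (10.0 ** log_r * dose) ** trans_n
    return em * ra / (1.0 + ra)


def _top_dose_mean(curve: NormalizedCurve) -> float:
    """Mean response at the highest dose (plateau fallback)."""
    top = curve.doses.max()
    return float(curve.responses[curve.doses == top].mean())


def fit_operational(
    curves: list[NormalizedCurve],
    reference_ligand: str | None = None,
    full_agonist_threshold: float = 0.9,
    n_bounds: tuple[float, float] = (0.3, 3.0),
    max_iterations: int = 4000,
) -> OperationalParams:
    """Global operational-model fit for one (receptor, pathway) group.

    Em and the transducer slope are shared across ligands; ligands whose
    observed plateau reaches *full_agonist_threshold* of the largest
    plateau in the group are treated as full agonists (reduced log R
    parameterization), the rest as partial agonists with separate
    log tau / log KA.  If every ligand is full, Em is anchored to the
    reference plateau (it is otherwise unidentifiable) with a status note.
    """
    if len(curves) < 2:
        raise InsufficientDataError(
            f"operational fit needs >= 2 ligands, got {len(curves)}"
        )
    receptors = {c.receptor_id for c in curves}
    pathways = {c.pathway_id for c in curves}
    if len(receptors) != 1 or len(pathways) != 1:
        raise ValidationError(
            f"curves span multiple groups: receptors={receptors}, pathways={pathways}"
        )
    receptor, pathway = receptors.pop(), pathways.pop()
    ligands = [c.ligand_id for c in curves]
    if len(set(ligands)) != len(ligands):
        raise ValidationError("duplicate ligand in operational fit input")
    reference_ligand = reference_ligand or curves[0].reference_ligand

    # one 4PL fit per curve supplies both the plateau classification and
    # the operational-fit starting values
    hill_pre: dict[str, tuple[float, float]] = {}
    for c in curves:
        lec50 = float(np.log10(np.median(c.doses)))
        plat = _top_dose_mean(c)
        try:
            hf = fit_hill(c, mode="free_basal", n_starts=5)
            if np.isfinite(hf.log_ec50):
                lec50 = float(hf.log_ec50)
            if hf.converged and np.isfinite(hf.emax) and hf.status == "ok":
                plat = float(hf.emax)
        except Exception:
            pass
        hill_pre[c.ligand_id] = (lec50, plat)
    plateaus = {l: p for l, (_e, p) in hill_pre.items()}
    top_plateau = max(plateaus.values())
    full = [l for l in ligands if plateaus[l] >= full_agonist_threshold * top_plateau]
    partial = [l for l in ligands if l not in full]

    anchor_em = len(partial) == 0
    status = "ok"
    if anchor_em:
        status = "em_anchored_to_reference_plateau"
        em_fixed = plateaus.get(reference_ligand, top_plateau)

    # parameter vector layout
    names: list[str] = []
    if not anchor_em:
        names.append("em")
    names.append("log_n")
    for l in ligands:
        if l in full:
            names.append(f"log_r[{l}]")
        else:
            names += [f"log_tau[{l}]", f"log_ka[{l}]"]
    idx = {n: i for i, n in enumerate(names)}
    lo, hi = math.log(n_bounds[0]), math.log(n_bounds[1])

    curve_by_ligand = {c.ligand_id: c for c in curves}

    def unpack(p: np.ndarray):
        em = em_fixed if anchor_em else float(p[idx["em"]])
        trans_n = float(np.exp(np.clip(p[idx["log_n"]], lo, hi)))
        return em, trans_n

    def residuals(p: np.ndarray) -> np.ndarray:
        em, trans_n = unpack(p)
        out = []
        for l in ligands:
            c = curve_by_ligand[l]
            if l in full:
                pred = operational_response_full_agonist(
                    c.doses, em, trans_n, p[idx[f"log_r[{l}]"]]
                )
            else:
                pred = operational_response(
                    c.doses, em, trans_n,
                    p[idx[f"log_tau[{l}]"]], p[idx[f"log_ka[{l}]"]],
                )
            out.append(pred - c.responses)
        return np.concatenate(out)

    def initial(tau_scale: float) -> np.ndarray:
        p0 = np.zeros(len(names))
        if not anchor_em:
            p0[idx["em"]] = top_plateau * 1.02
        p0[idx["log_n"]] = 0.0
        em0 = em_fixed if anchor_em else top_plateau * 1.02
        for l in ligands:
            lec50, plat = hill_pre[l]
            if l in full:
                # reduced form: EC50 = 1/R
                p0[idx[f"log_r[{l}]"]] = -lec50
            else:
                frac = min(max(plat / em0, 1e-3), 0.999)
                tau0 = frac / (1.0 - frac) * tau_scale
                p0[idx[f"log_tau[{l}]"]] = np.log10(tau0)
                # for partial agonists EC50 ~ KA*tau... keep KA near EC50*(1+tau)
                p0[idx[f"log_ka[{l}]"]] = lec50 + np.log10(1.0 + tau0)
        return p0

    best = None
    for tau_scale in (1.0, 0.3, 3.0):
        try:
            res = least_squares(residuals, initial(tau_scale), method="lm",
                                max_nfev=max_iterations)
        except Exception:  # pragma: no cover
            continue
        if not np.isfinite(res.cost):
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise ValidationError("operational fit failed to converge from any start")

    em, trans_n = unpack(best.x)
    rss = float(2.0 * best.cost)
    n_obs = sum(c.doses.size for c in curves)
    dof = max(n_obs - len(names), 1)
    cov = None
    try:
        cov = np.linalg.inv(best.jac.T @ best.jac) * rss / dof
    except np.linalg.LinAlgError:
        status = "covariance_singular" if status == "ok" else status

    log_r: dict[str, float] = {}
    log_tau: dict[str, float] = {}
    log_ka: dict[str, float] = {}
    se_log_r: dict[str, float] = {}
    for l in ligands:
        if l in full:
            log_r[l] = float(best.x[idx[f"log_r[{l}]"]])
            if cov is not None:
                se_log_r[l] = float(np.sqrt(max(cov[idx[f"log_r[{l}]"],
                                                    idx[f"log_r[{l}]"]], 0.0)))
            else:
                se_log_r[l] = float("nan")
        else:
            lt, lk = idx[f"log_tau[{l}]"], idx[f"log_ka[{l}]"]
            log_tau[l] = float(best.x[lt])
            log_ka[l] = float(best.x[lk])
            log_r[l] = log_tau[l] - log_ka[l]
            if cov is not None:
                # delta method on log_tau - log_ka using the joint covariance
                var = cov[lt, lt] + cov[lk, lk] - 2.0 * cov[lt, lk]
                se_log_r[l] = float(np.sqrt(max(var, 0.0)))
            else:
                se_log_r[l] = float("nan")

    return OperationalParams(
        receptor_id=receptor, pathway_id=pathway, em=em, trans_n=trans_n,
        log_r=log_r, log_tau=log_tau, log_ka=log_ka, full_agonists=full,
        se_log_r=se_log_r, param_names=names, covariance=cov,
        rss=rss, dof=dof, converged=bool(best.success), status=status,
    )


def transduction_coefficients(params: OperationalParams) -> list[TransductionCoefficient]:
    """Extract per-ligand log(tau/KA) +/- SE from a converged joint fit."""
    if not params.converged:
        raise ValidationError(
            f"operational fit did not converge (status={params.status})"
        )
    return [
        TransductionCoefficient(
            ligand_id=l,
            receptor_id=params.receptor_id,
            pathway_id=params.pathway_id,
            log_r=params.log_r[l],
            se_log_r=params.se_log_r.get(l, float("nan")),
        )
        for l in sorted(params.log_r)
    ]


def bias_factor(
    coeffs: dict[tuple[str, str], TransductionCoefficient],
    test_ligand: str,
    reference_ligand: str,
    pathway_a: str,
    pathway_b: str,
) -> BiasResult:
    """Relative effectiveness and bias factor from four transduction coefficients.

    *coeffs* is keyed by (ligand, pathway).  Within each pathway,
    Delta log(tau/KA) = log R(test) - log R(reference) and RE = 10^Delta;
    across pathways DeltaDelta = Delta(a) - Delta(b) and the bias factor
    is 10^DeltaDelta.  Standard errors combine in quadrature at each
    subtraction (the reference coefficient is treated as independent
    between pathways, which is mildly conservative).
    """
    needed = [(test_ligand, pathway_a), (reference_ligand, pathway_a),
              (test_ligand, pathway_b), (reference_ligand, pathway_b)]
    missing = [k for k in needed if k not in coeffs]
    if missing:
        raise ValidationError(f"missing transduction coefficient(s) for {missing}")
    receptors = {coeffs[k].receptor_id for k in needed}
    if len(receptors) != 1:
        raise ValidationError(
            f"coefficients span multiple receptors: {sorted(receptors)}"
        )
    delta: dict[str, float] = {}
    se_delta: dict[str, float] = {}
    re: dict[str, float] = {}
    for pw in (pathway_a, pathway_b):
        t = coeffs[(test_ligand, pw)]
        r = coeffs[(reference_ligand, pw)]
        delta[pw] = t.log_r - r.log_r
        se_delta[pw] = math.hypot(t.se_log_r, r.se_log_r)
        re[pw] = 10.0 ** delta[pw]
    dd = delta[pathway_a] - delta[pathway_b]
    se_dd = math.hypot(se_delta[pathway_a], se_delta[pathway_b])
    return BiasResult(
        test_ligand=test_ligand,
        reference_ligand=reference_ligand,
        receptor_id=receptors.pop(),
        pathway_a=pathway_a,
        pathway_b=pathway_b,
        delta_log_r=delta,
        se_delta_log_r=se_delta,
        re=re,
        delta_delta_log_r=dd,
        se_delta_delta_log_r=se_dd,
        bias_factor=10.0 ** dd,
    )


def bias_table(
    coeffs: list[TransductionCoefficient],
    reference_ligand: str,
    pathway_a: str,
    pathway_b: str,
) -> list[BiasResult]:
    """Bias results for every non-reference ligand present in both pathways."""
    by_key = {(c.ligand_id, c.pathway_id): c for c in coeffs}
    ligands = sorted({c.ligand_id for c in coeffs if c.ligand_id != reference_ligand})
    out = []
    for l in ligands:
        if (l, pathway_a) in by_key and (l, pathway_b) in by_key:
            out.append(bias_factor(by_key, l, reference_ligand, pathway_a, pathway_b))
    return out
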