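"""Kinetics of competitive radioligand binding.

A labeled ligand L (rates k1 on, k2 off) and an unlabeled competitor I
(rates k3, k4) bind the same receptor population under pseudo-first-order
conditions (free ligand concentrations constant; no depletion):

    dRL/dt = k1*L*(Bmax - RL - RI) - k2*RL
    dRI/dt = k3*I*(Bmax - RL - RI) - k4*RI

The closed-form solution for the labeled-ligand time course (the
"kinetics of competitive binding" model of Motulsky & Mahan) lets the
competitor's on/off rates be recovered from association traces measured
at several competitor concentrations, with the radioligand's own rates
fixed from an independent experiment.  An explicit ODE integration of
the same mass-action system is provided as the reference oracle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

from betapharm.errors import (
    DomainError,
    IdentifiabilityError,
    InsufficientDataError,
    ValidationError,
)

logger = logging.getLogger("betapharm")


@dataclass
class RadioligandKinetics:
    """Fixed kinetic parameters of the labeled ligand.

    k1: association rate (M^-1 s^-1); k2: dissociation rate (s^-1);
    conc_l: free labeled-ligand concentration (M).  These are inputs
    measured in a separate experiment, never co-fitted.
    """

    k1: float
    k2: float
    conc_l: float

    def __post_init__(self) -> None:
        if not (self.k1 > 0 and self.k2 > 0 and self.conc_l > 0):
            raise DomainError(
                f"k1, k2, conc_l must all be positive, got "
                f"({self.k1}, {self.k2}, {self.conc_l})"
            )

    @property
    def kd(self) -> float:
        """Equilibrium dissociation constant k2/k1 (M)."""
        return self.k2 / self.k1


@dataclass
class KineticTrace:
    """One time-course of bound labeled ligand."""

    trace_id: str
    trace_type: str  # 'association' | 'dissociation'
    competitor_conc: float  # molar; 0 allowed
    times: np.ndarray  # seconds, strictly increasing
    signal: np.ndarray  # bound counts, arbitrary units
    competitor: str = ""
    receptor: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.trace_type not in {"association", "dissociation"}:
            raise ValidationError(f"bad trace_type {self.trace_type!r}")
        if self.times.size < 2:
            raise ValidationError(
                f"trace {self.trace_id!r} has {self.times.size} points; need >= 2"
            )
        if (self.times < 0).any():
            raise ValidationError(f"trace {self.trace_id!r} has negative times")
        if not (np.diff(self.times) > 0).all():
            raise ValidationError(
                f"times in trace {self.trace_id!r} must be strictly increasing"
            )
        if not np.isfinite(self.signal).all():
            raise ValidationError(f"trace {self.trace_id!r} has non-finite signal")
        if self.competitor_conc < 0:
            raise ValidationError("competitor_conc must be >= 0")


@dataclass
class CompetitorKineticsFit:
    """Recovered competitor rates from a global fit across traces."""

    k3: float  # M^-1 s^-1
    k4: float  # s^-1
    bmax_scale: float  # signal units
    se: dict[str, float] = field(default_factory=dict)
    converged: bool = False
    status: str = "ok"
    rss: float = float("nan")
    dof: int = 0
    per_trace_rss: dict[str, float] = field(default_factory=dict)

    @property
    def kinetic_kd(self) -> float:
        """Kinetically derived equilibrium constant k4/k3 (M)."""
        return self.k4 / self.k3


def _check_mm_args(rl: RadioligandKinetics, k3: float, k4: float,
                   competitor_conc: float, bmax_scale: float) -> None:
    if not (k3 > 0 and k4 > 0):
        raise DomainError(f"k3, k4 must be positive, got ({k3}, {k4})")
    if competitor_conc < 0:
        raise DomainError(f"competitor_conc must be >= 0, got {competitor_conc}")
    if not bmax_scale > 0:
        raise DomainError(f"bmax_scale must be positive, got {bmax_scale}")


def mm_bound(
    t: np.ndarray | float,
    rl: RadioligandKinetics,
    k3: float,
    k4: float,
    competitor_conc: float,
    bmax_scale: float,
) -> np.ndarray:
    """Closed-form bound labeled ligand RL(t) under competition.

    With KA = k1*L + k2, KB = k3*I + k4,
    S = sqrt((KA - KB)^2 + 4*k1*k3*L*I), KF = (KA+KB+S)/2,
    KS = (KA+KB-S)/2 and Q = Bmax*k1*L/(KF - KS):

        RL(t) = Q * [ k4*(KF-KS)/(KF*KS)
                      + (k4-KF)/KF * exp(-KF*t)
                      - (k4-KS)/KS * exp(-KS*t) ]

    When KF and KS coalesce (|KF-KS| < 1e-9*KF) the removable
    singularity is evaluated by its second-order series limit.
    """
    _check_mm_args(rl, k3, k4, competitor_conc, bmax_scale)
    t = np.asarray(t, dtype=float)
    k1, k2, L = rl.k1, rl.k2, rl.conc_l
    I = competitor_conc
    KA = k1 * L + k2
    KB = k3 * I + k4
    S = np.sqrt((KA - KB) ** 2 + 4.0 * k1 * k3 * L * I)
    KF = 0.5 * (KA + KB + S)
    KS = 0.5 * (KA + KB - S)
    C = bmax_scale * k1 * L
    # extreme optimizer excursions can underflow KS to 0; the finite check
    # below turns the resulting inf/nan into a DomainError instead of warnings
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        if KF - KS < 1e-9 * KF:
            # coalescent-eigenvalue limit:
            # RL = C*[k4/K^2*(1-e^{-Kt}) - t*(k4-K)/K*e^{-Kt}]
            K = 0.5 * (KF + KS)
            out = C * (k4 / K**2 * (1.0 - np.exp(-K * t))
                       - t * (k4 - K) / K * np.exp(-K * t))
        else:
            Q = C / (KF - KS)
            out = Q * (
                k4 * (KF - KS) / (KF * KS)
                + (k4 - KF) / KF * np.exp(-KF * t)
                - (k4 - KS) / KS * np.exp(-KS * t)
            )
    if not np.isfinite(out).all():
        raise DomainError(
            "non-finite value in competition-kinetics evaluation; parameters: "
            f"k1={k1}, k2={k2}, L={L}, k3={k3}, k4={k4}, I={I}, Bmax={bmax_scale}"
        )
    return out


def equilibrium_bound(
    rl: RadioligandKinetics, k3: float, k4: float,
    competitor_conc: float, bmax_scale: float,
) -> float:
    """Equilibrium (t -> inf) bound labeled ligand under competition.

    RL_eq = Bmax * L / (L + KD_L * (1 + I/KD_I)) with KD_L = k2/k1 and
    KD_I = k4/k3 — the standard competitive-binding isotherm.
    """
    _check_mm_args(rl, k3, k4, competitor_conc, bmax_scale)
    kd_l = rl.k2 / rl.k1
    kd_i = k4 / k3
    return bmax_scale * rl.conc_l / (
        rl.conc_l + kd_l * (1.0 + competitor_conc / kd_i)
    )


def simulate_ode(
    rl: RadioligandKinetics,
    k3: float,
    k4: float,
    competitor_conc: float,
    bmax_scale: float,
    t_grid: np.ndarray,
    rtol: float = 1e-10,
    atol_frac: float = 1e-12,
) -> np.ndarray:
    """Reference implementation: integrate the two-species mass-action ODEs.

    Free ligand concentrations are held constant (no depletion).  Both
    species start unbound.  This is the independent oracle against which
    the closed form :func:`mm_bound` is validated; it is deliberately
    run at tight tolerances and is slower than the closed form.
    """
    _check_mm_args(rl, k3, k4, competitor_conc, bmax_scale)
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.size and not (np.diff(t_grid) > 0).all():
        raise ValidationError("t_grid must be strictly increasing")
    k1, k2, L = rl.k1, rl.k2, rl.conc_l
    I = competitor_conc
    B = bmax_scale

    def rhs(_t: float, y: np.ndarray) -> list[float]:
        rl_b, ri_b = y
        free = B - rl_b - ri_b
        return [k1 * L * free - k2 * rl_b, k3 * I * free - k4 * ri_b]

    t0 = float(t_grid[0]) if t_grid.size else 0.0
    # the solution starts at the origin regardless of where sampling begins
    sol = solve_ivp(
        rhs, (min(0.0, t0), float(t_grid[-1])), [0.0, 0.0],
        t_eval=t_grid, method="LSODA", rtol=rtol, atol=atol_frac * B,
    )
    if not sol.success:
        raise DomainError(
            f"ODE solver failed ({sol.message}); parameters: k3={k3}, k4={k4}, "
            f"I={I}, Bmax={B}, k1={k1}, k2={k2}, L={L}"
        )
    return sol.y[0]


def fit_competitor_kinetics(
    dataset,
    rl: RadioligandKinetics | None = None,
    n_starts: int = 6,
    max_iterations: int = 2000,
) -> CompetitorKineticsFit:
    """Global fit of (k3, k4, Bmax) over all association traces.

    *dataset* is a :class:`betapharm.io.KineticDataset` (or anything
    with ``association_traces()`` and ``radioligand_params``).  Rates
    are log-parameterized; starts span a grid of plausible kinetic KD
    values; the best RSS wins.  The radioligand's own rates are fixed.
    """
    rl = rl or getattr(dataset, "radioligand_params", None)
    if rl is None:
        raise ValidationError("radioligand kinetics (k1, k2, L) must be supplied")
    traces = [t for t in dataset.association_traces()]
    if len(traces) < 2:
        raise InsufficientDataError(
            f"global kinetic fit needs >= 2 association traces, got {len(traces)}"
        )
    concs = sorted({t.competitor_conc for t in traces})
    pos_concs = [c for c in concs if c > 0]
    if not pos_concs:
        raise IdentifiabilityError(
            "all traces are competitor-free: k3 and k4 do not enter the model "
            "and cannot be estimated (profile likelihood is flat in both)"
        )
    if len(pos_concs) < 2:
        logger.warning(
            "only one non-zero competitor concentration: k3/k4 separation "
            "relies on curve shape alone and may be weakly identified"
        )

    sig_max = max(float(t.signal.max()) for t in traces)

    def unpack(p: np.ndarray) -> tuple[float, float, float]:
        return float(np.exp(p[0])), float(np.exp(p[1])), float(np.exp(p[2]))

    def residuals(p: np.ndarray) -> np.ndarray:
        k3, k4, bmax = unpack(p)
        res = []
        for tr in traces:
            pred = mm_bound(tr.times, rl, k3, k4, tr.competitor_conc, bmax)
            res.append(pred - tr.signal)
        return np.concatenate(res)

    # starts: plausible kinetic KD grid around the competitor concentrations
    kd_grid = np.logspace(np.log10(min(pos_concs)) - 2,
                          np.log10(max(pos_concs)) + 1, n_starts)
    k4_0 = 5e-3  # generic slow-competitor scale, refined by the optimizer
    bmax0 = sig_max * 1.5
    best = None
    for kd0 in kd_grid:
        p0 = [np.log(k4_0 / kd0), np.log(k4_0), np.log(bmax0)]
        try:
            res = least_squares(residuals, p0, method="lm", max_nfev=max_iterations)
        except Exception:  # pragma: no cover
            continue
        if not np.isfinite(res.cost):
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        return CompetitorKineticsFit(
            k3=float("nan"), k4=float("nan"), bmax_scale=float("nan"),
            converged=False, status="no_convergence",
        )
    k3, k4, bmax = unpack(best.x)
    rss = float(2.0 * best.cost)
    n_obs = sum(t.times.size for t in traces)
    dof = max(n_obs - 3, 1)
    se: dict[str, float] = {}
    try:
        cov = np.linalg.inv(best.jac.T @ best.jac) * rss / dof
        d = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        # delta method from log-scale to natural scale
        se = {"k3": float(d[0] * k3), "k4": float(d[1] * k4),
              "bmax_scale": float(d[2] * bmax)}
    except np.linalg.LinAlgError:
        se = {"k3": float("nan"), "k4": float("nan"), "bmax_scale": float("nan")}
    per_trace = {}
    for tr in traces:
        pred = mm_bound(tr.times, rl, k3, k4, tr.competitor_conc, bmax)
        per_trace[tr.trace_id] = float(np.sum((pred - tr.signal) ** 2))
    return CompetitorKineticsFit(
        k3=k3, k4=k4, bmax_scale=bmax, se=se, converged=bool(best.success),
        status="ok", rss=rss, dof=dof, per_trace_rss=per_trace,
    )


def fit_dissociation(trace: KineticTrace, max_iterations: int = 2000):
    """Fit a propranolol-chase style dissociation trace.

    Model: y = ns + (y0 - ns) * exp(-koff * t), returning koff with SE
    as an :class:`betapharm.dose_response.ExpRateFit` (rate_k = koff,
    offset = ns, amplitude = y0 - ns).  A net-rising trace is rejected.
    """
    from betapharm.dose_response import fit_single_exponential

    if trace.trace_type != "dissociation":
        raise ValidationError(
            f"trace {trace.trace_id!r} is {trace.trace_type}, expected dissociation"
        )
    if trace.times.size < 5:
        raise InsufficientDataError("dissociation fit needs >= 5 points")
    fit = fit_single_exponential(trace.times, trace.signal, mode="decay",
                                 max_iterations=max_iterations)
    if fit.status == "sign_mismatch" or (fit.converged and fit.amplitude < 0):
        raise ValidationError(
            f"trace {trace.trace_id!r} rises over time: not a dissociation trace "
            "(fitted amplitude negative)"
        )
    return fit
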