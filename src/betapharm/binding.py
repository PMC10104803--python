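"""Equilibrium radioligand binding: saturation, competition, Cheng-Prusoff.

Saturation binding measures total and nonspecific binding of the
radioligand over a concentration series; specific binding follows the
one-site hyperbola Bmax*L/(KD + L).  Competition binding measures
displacement of a fixed radioligand concentration by a cold ligand and
is fitted with a descending four-parameter logistic to give IC50, which
the Cheng-Prusoff relation Ki = IC50/(1 + [L]/KD) converts to the
competitor's inhibition constant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from betapharm.errors import DomainError, InsufficientDataError, ValidationError

logger = logging.getLogger("betapharm")


@dataclass
class SaturationFit:
    """KD/Bmax estimate from one-site saturation binding."""

    kd: float  # molar
    bmax: float  # receptor density, units of the input signal
    ns_slope: float  # nonspecific binding per molar (one-step model only)
    se: dict[str, float] = field(default_factory=dict)
    rss: float = float("nan")
    dof: int = 0
    converged: bool = False
    status: str = "ok"
    model: str = "specific"  # 'specific' (NS subtracted) or 'one_step'


@dataclass
class CompetitionFit:
    """IC50 (and Ki when radioligand parameters are supplied) from competition binding."""

    log_ic50: float  # log10 molar
    top: float  # percent/signal at zero competitor
    bottom: float  # fully displaced level
    hill_n: float
    ki: float | None = None  # molar, via Cheng-Prusoff
    se: dict[str, float] = field(default_factory=dict)
    rss: float = float("nan")
    dof: int = 0
    converged: bool = False
    status: str = "ok"
    flags: list[str] = field(default_factory=list)

    @property
    def ic50(self) -> float:
        return 10.0 ** self.log_ic50


def one_site_specific(conc: np.ndarray, bmax: float, kd: float) -> np.ndarray:
    """Specific one-site binding hyperbola Bmax*L/(KD + L)."""
    conc = np.asarray(conc, dtype=float)
    return bmax * conc / (kd + conc)


def fit_saturation(
    conc: Sequence[float],
    total_binding: Sequence[float],
    nonspecific_binding: Sequence[float] | None = None,
    max_iterations: int = 2000,
) -> SaturationFit:
    """Fit one-site saturation binding.

    With matched nonspecific wells, specific = total - nonspecific is
    fitted to Bmax*L/(KD+L); without them, the one-step model
    total = Bmax*L/(KD+L) + ns_slope*L is used.  A fitted KD far above
    the highest tested concentration (no curvature in the data) is
    flagged ``kd_unidentifiable``.
    """
    L = np.asarray(conc, dtype=float)
    total = np.asarray(total_binding, dtype=float)
    if np.unique(L).size < 5:
        raise InsufficientDataError(
            f"saturation fit needs >= 5 distinct concentrations, got {np.unique(L).size}"
        )
    if (L <= 0).any():
        raise ValidationError("radioligand concentrations must be positive")

    if nonspecific_binding is not None:
        ns = np.asarray(nonspecific_binding, dtype=float)
        if ns.shape != total.shape:
            raise ValidationError("nonspecific series must match total series length")
        y = total - ns
        model_kind = "specific"

        def residuals(p: np.ndarray) -> np.ndarray:
            bmax, log_kd = p
            return one_site_specific(L, bmax, 10.0 ** log_kd) - y

        p0 = [float(y.max()), float(np.log10(np.median(L)))]
    else:
        y = total
        model_kind = "one_step"
        l_top = float(L.max())

        # nonspecific binding parameterized as its signal at the top
        # concentration (ns_top = ns_slope * L_max), keeping all three
        # parameters on comparable scales for the optimizer
        def residuals(p: np.ndarray) -> np.ndarray:
            bmax, log_kd, ns_top = p
            return one_site_specific(L, bmax, 10.0 ** log_kd) + ns_top * (L / l_top) - y

        p0 = [float(y.max()), float(np.log10(np.median(L))), 0.0]

    best = None
    for shift in (-1.0, 0.0, 1.0):
        start = list(p0)
        start[1] = p0[1] + shift
        try:
            # x_scale='jac' copes with the disparate magnitudes of
            # (bmax, log_kd, ns_slope)
            res = least_squares(residuals, start, method="lm",
                                x_scale="jac", max_nfev=max_iterations)
        except Exception:  # pragma: no cover
            continue
        if not np.isfinite(res.cost):
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        return SaturationFit(kd=float("nan"), bmax=float("nan"), ns_slope=float("nan"),
                             converged=False, status="no_convergence", model=model_kind)
    bmax = float(best.x[0])
    kd = float(10.0 ** best.x[1])
    ns_slope = float(best.x[2] / L.max()) if model_kind == "one_step" else 0.0
    rss = float(2.0 * best.cost)
    dof = max(best.fun.size - best.x.size, 1)
    se: dict[str, float] = {}
    try:
        cov = np.linalg.inv(best.jac.T @ best.jac) * rss / dof
        d = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        se = {"bmax": float(d[0]), "kd": float(d[1] * kd * np.log(10.0))}
        if model_kind == "one_step":
            se["ns_slope"] = float(d[2] / L.max())
    except np.linalg.LinAlgError:
        pass
    status = "ok"
    if kd > 10.0 * L.max():
        status = "kd_unidentifiable"  # all points in the linear regime
    return SaturationFit(kd=kd, bmax=bmax, ns_slope=ns_slope, se=se, rss=rss,
                         dof=dof, converged=bool(best.success), status=status,
                         model=model_kind)


def competition_response(
    conc: np.ndarray, top: float, bottom: float, log_ic50: float, hill_n: float
) -> np.ndarray:
    """Descending 4PL in log concentration (binding vs cold-ligand dose)."""
    conc = np.asarray(conc, dtype=float)
    return bottom + (top - bottom) / (
        1.0 + 10.0 ** (hill_n * (np.log10(conc) - log_ic50))
    )


def fit_competition(
    conc: Sequence[float],
    binding: Sequence[float],
    fix_hill: float | None = None,
    radioligand_conc: float | None = None,
    radioligand_kd: float | None = None,
    hill_caveat_range: tuple[float, float] = (0.8, 1.2),
    max_iterations: int = 2000,
) -> CompetitionFit:
    """Fit a competition binding curve; optionally convert IC50 to Ki.

    The hill slope is free by default (*fix_hill* pins it, e.g. to 1);
    because Ki conversion assumes one-site competition, a fitted slope
    outside *hill_caveat_range* is recorded in ``flags``.  Ki is
    computed when both radioligand concentration and KD are supplied.
    """
    c = np.asarray(conc, dtype=float)
    y = np.asarray(binding, dtype=float)
    if np.unique(c).size < 5:
        raise InsufficientDataError(
            f"competition fit needs >= 5 distinct concentrations, got {np.unique(c).size}"
        )
    if (c <= 0).any():
        raise ValidationError("cold-ligand concentrations must be positive")
    span = float(y.max() - y.min())
    if span == 0.0:
        return CompetitionFit(log_ic50=float("nan"), top=float(y[0]),
                              bottom=float(y[0]), hill_n=float("nan"),
                              converged=False, status="unidentifiable_flat")

    logc = np.log10(c)
    fixed = fix_hill is not None

    def unpack(p: np.ndarray):
        if fixed:
            top, bottom, log_ic50 = p
            hill = float(fix_hill)
        else:
            top, bottom, log_ic50, log_hill = p
            hill = float(np.exp(log_hill))
        return float(top), float(bottom), float(log_ic50), hill

    def residuals(p: np.ndarray) -> np.ndarray:
        top, bottom, log_ic50, hill = unpack(p)
        return competition_response(c, top, bottom, log_ic50, hill) - y

    top0, bottom0 = float(y.max()), float(y.min())
    best = None
    for lic50 in np.linspace(logc.min(), logc.max(), 5):
        p0 = [top0, bottom0, lic50] if fixed else [top0, bottom0, lic50, 0.0]
        try:
            res = least_squares(residuals, p0, method="lm", max_nfev=max_iterations)
        except Exception:  # pragma: no cover
            continue
        if not np.isfinite(res.cost):
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        return CompetitionFit(log_ic50=float("nan"), top=float("nan"),
                              bottom=float("nan"), hill_n=float("nan"),
                              converged=False, status="no_convergence")
    top, bottom, log_ic50, hill = unpack(best.x)
    rss = float(2.0 * best.cost)
    dof = max(best.fun.size - best.x.size, 1)
    se: dict[str, float] = {}
    try:
        cov = np.linalg.inv(best.jac.T @ best.jac) * rss / dof
        d = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        se = {"top": float(d[0]), "bottom": float(d[1]), "log_ic50": float(d[2])}
        if not fixed:
            se["hill_n"] = float(d[3] * hill)
    except np.linalg.LinAlgError:
        pass
    flags: list[str] = []
    if not (hill_caveat_range[0] <= hill <= hill_caveat_range[1]):
        flags.append(f"hill_slope_{hill:.2f}_outside_one_site_range")
    # monotonicity check beyond noise: positive trend of binding with dose
    order = np.argsort(c)
    rho = np.corrcoef(logc[order], y[order])[0, 1]
    if rho > 0.5:
        flags.append("non_monotonic_displacement")
    ki = None
    if radioligand_conc is not None and radioligand_kd is not None:
        ki = cheng_prusoff(10.0 ** log_ic50, radioligand_conc, radioligand_kd)
    return CompetitionFit(log_ic50=log_ic50, top=top, bottom=bottom, hill_n=hill,
                          ki=ki, se=se, rss=rss, dof=dof,
                          converged=bool(best.success), status="ok", flags=flags)


def cheng_prusoff(ic50: float, radioligand_conc: float, radioligand_kd: float) -> float:
    """Convert a competition IC50 to Ki: Ki = IC50 / (1 + [L]/KD).

    [L] is the free radioligand concentration and KD its equilibrium
    dissociation constant; at [L] = 0 the correction vanishes (Ki = IC50).
    """
    if ic50 <= 0:
        raise DomainError(f"ic50 must be positive, got {ic50}")
    if radioligand_conc < 0:
        raise DomainError(f"radioligand_conc must be >= 0, got {radioligand_conc}")
    if radioligand_kd <= 0:
        raise DomainError(f"radioligand_kd must be positive, got {radioligand_kd}")
    return ic50 / (1.0 + radioligand_conc / radioligand_kd)
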