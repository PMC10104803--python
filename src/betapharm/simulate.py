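"""Seeded synthetic-data generation for every analysis stage.

Each generator draws from the *exact* forward model that the matching
analysis module fits (4PL, operational equation, one-site hyperbola and
competition logistic, the competition-kinetics closed form, single
exponential, toy coordinate sets), adds Gaussian noise, and ships the
ground-truth parameters in a sidecar — the basis of all
parameter-recovery testing.  A fixed seed yields byte-identical output.

The default specs emulate the assay designs of a catecholamine
subtype-selectivity study: dose series spanning 1e-10 to 1e-4 M in
duplicate, competition binding at 0.25 nM radioligand against a
0.080 nM-KD radioligand, Bmax 2.7 signal units, and association
kinetics read out at a 1:3:10 ladder of competitor concentrations plus
a competitor-free trace.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from betapharm.binding import competition_response, one_site_specific
from betapharm.dose_response import hill_response
from betapharm.errors import SpecError
from betapharm.kinetics import RadioligandKinetics, mm_bound
from betapharm.operational import operational_response

ASSAY_KINDS = (
    "dose_response_hill",
    "dose_response_operational",
    "saturation",
    "competition",
    "kinetics_association",
    "kinetics_dissociation",
    "structure_fixture",
)


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic dataset: truth + design + noise + seed."""

    seed: int
    assay_kind: str
    true_params: dict[str, Any] = field(default_factory=dict)
    design: dict[str, Any] = field(default_factory=dict)
    noise: dict[str, Any] = field(default_factory=lambda: {"model": "gaussian",
                                                           "sigma": 0.0,
                                                           "scale": "percent_of_max"})

    def __post_init__(self) -> None:
        if self.assay_kind not in ASSAY_KINDS:
            raise SpecError(
                f"unknown assay_kind {self.assay_kind!r}; known: {ASSAY_KINDS}"
            )
        if not isinstance(self.seed, int) or isinstance(self.seed, bool):
            raise SpecError("seed must be an explicit integer")
        if self.noise.get("model", "gaussian") != "gaussian":
            raise SpecError("only gaussian noise is supported")
        if float(self.noise.get("sigma", 0.0)) < 0:
            raise SpecError("noise sigma must be >= 0")
        defaults = _DEFAULTS[self.assay_kind]()
        self.true_params = {**defaults["true_params"], **self.true_params}
        self.design = {**defaults["design"], **self.design}


@dataclass
class SyntheticDataset:
    """Generated tables/texts plus the ground-truth sidecar."""

    assay_kind: str
    tables: dict[str, pd.DataFrame]
    truth: dict[str, Any]
    texts: dict[str, str] = field(default_factory=dict)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write CSVs/PDBs plus truth.json; deterministic bytes for a fixed spec."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written: dict[str, Path] = {}
        for name, df in self.tables.items():
            p = outdir / f"{name}.csv"
            df.to_csv(p, index=False, lineterminator="\n")
            written[name] = p
        for name, text in self.texts.items():
            p = outdir / name
            p.write_text(text)
            written[name] = p
        tp = outdir / "truth.json"
        tp.write_text(json.dumps(_jsonable(self.truth), indent=2, sort_keys=True) + "\n")
        written["truth"] = tp
        return written


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    return obj


def _noise_sd(spec: SyntheticSpec, scale_value: float) -> float:
    sigma = float(spec.noise.get("sigma", 0.0))
    if spec.noise.get("scale", "percent_of_max") == "percent_of_max":
        return sigma / 100.0 * scale_value
    return sigma


# ---------------------------------------------------------------------------
# per-kind defaults: the study conditions the generators emulate


def _default_hill() -> dict[str, Any]:
    return {
        "true_params": {
            "reference_ligand": "ref",
            "ligands": {
                "ref": {"basal": 0.0, "emax": 100.0, "log_ec50": -7.0, "hill_n": 1.0},
                "test": {"basal": 0.0, "emax": 80.0, "log_ec50": -7.8, "hill_n": 1.0},
            },
        },
        "design": {
            "doses": np.logspace(-10, -4, 8).tolist(),
            "replicates": 2,
            "raw_basal": 200.0,
            "raw_span": 1000.0,
            "receptor": "B2AR",
            "pathway": "arrestin",
        },
    }


def _default_operational() -> dict[str, Any]:
    # built-in cross-pathway bias: ddlog(tau/KA) = 0.7 for 'test' vs 'ref'
    return {
        "true_params": {
            "reference_ligand": "ref",
            "pathways": {
                "arrestin": {
                    "em": 105.0, "trans_n": 1.0,
                    "ligands": {
                        "ref": {"log_tau": 2.5, "log_ka": -5.0},
                        "test": {"log_tau": -0.3, "log_ka": -7.5},
                    },
                },
                "camp": {
                    "em": 105.0, "trans_n": 1.0,
                    "ligands": {
                        "ref": {"log_tau": 2.5, "log_ka": -5.0},
                        "test": {"log_tau": -0.3, "log_ka": -6.8},
                    },
                },
            },
        },
        "design": {
            "doses": np.logspace(-10, -4, 8).tolist(),
            "replicates": 2,
            "raw_basal": 200.0,
            "raw_span": 1000.0,
            "receptor": "B2AR",
        },
    }


def _default_saturation() -> dict[str, Any]:
    return {
        "true_params": {"kd": 0.080e-9, "bmax": 2.7, "ns_slope": 0.3e9},
        "design": {"conc": np.logspace(np.log10(0.01e-9), np.log10(1.28e-9), 8).tolist(),
                   "replicates": 1},
    }


def _default_competition() -> dict[str, Any]:
    return {
        "true_params": {"log_ki": -7.0, "top": 100.0, "bottom": 0.0, "hill_n": 1.0,
                        "radioligand_conc": 0.25e-9, "radioligand_kd": 0.080e-9},
        "design": {"conc": np.logspace(-11, -4, 10).tolist(), "replicates": 3},
    }


def _default_assoc() -> dict[str, Any]:
    return {
        "true_params": {
            # synthetic stand-in rates for the labeled ligand; real analyses
            # must supply independently measured values
            "k1": 5.0e7, "k2": 5.0e-3, "conc_l": 0.3e-9,
            "k3": 1.0e6, "k4": 5.0e-3, "bmax_scale": 1000.0,
        },
        "design": {
            # competitor-free trace plus a 1:3:10 ladder around the
            # competitor's kinetic KD (k4/k3 = 5 nM here)
            "competitor_concs": [0.0, 3.0e-9, 10.0e-9, 30.0e-9],
            "times": np.linspace(0.0, 3600.0, 25)[1:].tolist(),
        },
    }


def _default_dissoc() -> dict[str, Any]:
    return {
        "true_params": {"koff": 1.0e-3, "y0": 1000.0, "ns": 100.0},
        "design": {"times": np.linspace(0.0, 3600.0, 20).tolist()},
    }


def _default_structure() -> dict[str, Any]:
    return {
        "true_params": {
            "b_profile": None,  # None -> smooth default profile
            "b_scale": 30.0,
        },
        "design": {
            "n_residues": 30,
            "chain_id": "A",
            "coordinate_noise": 0.0,
            "rotation_deg": 0.0,
            "translation": [0.0, 0.0, 0.0],
        },
    }


_DEFAULTS = {
    "dose_response_hill": _default_hill,
    "dose_response_operational": _default_operational,
    "saturation": _default_saturation,
    "competition": _default_competition,
    "kinetics_association": _default_assoc,
    "kinetics_dissociation": _default_dissoc,
    "structure_fixture": _default_structure,
}


# ---------------------------------------------------------------------------
# generators


def _gen_dose_response(spec: SyntheticSpec, operational: bool) -> SyntheticDataset:
    rng = np.random.default_rng(spec.seed)
    d = spec.design
    tp = spec.true_params
    doses = np.asarray(d["doses"], dtype=float)
    raw_basal = float(d["raw_basal"])
    raw_span = float(d["raw_span"])
    rows = []
    truth: dict[str, Any] = {"seed": spec.seed, "assay_kind": spec.assay_kind,
                             "true_params": tp, "design": d,
                             "noise": spec.noise}

    if operational:
        pathway_items = tp["pathways"].items()
    else:
        pathway_items = [(d["pathway"], {"ligands": tp["ligands"]})]

    sd = _noise_sd(spec, raw_span)
    ref = tp["reference_ligand"]
    norm_truth: dict[str, Any] = {}
    for pathway, pdata in pathway_items:
        # noise-free percent responses
        pct: dict[str, np.ndarray] = {}
        for ligand, lp in pdata["ligands"].items():
            if operational:
                pct[ligand] = operational_response(
                    doses, pdata["em"], pdata["trans_n"], lp["log_tau"], lp["log_ka"]
                )
            else:
                pct[ligand] = hill_response(
                    doses, lp["basal"], lp["emax"], lp["log_ec50"], lp["hill_n"]
                )
        # the normalization anchor is the reference response at the top dose;
        # record the rescaling it induces so recovery tests compare like with like
        ref_top = float(pct[ref][-1])
        norm_truth[pathway] = {"reference_top_percent": ref_top,
                               "normalization_factor": 100.0 / ref_top}
        for rep in range(int(d["replicates"])):
            rows.append({
                "ligand": "vehicle", "receptor": d["receptor"], "pathway": pathway,
                "dose": 0.0, "dose_unit": "M",
                "signal": raw_basal + rng.normal(0.0, sd) if sd else raw_basal,
                "replicate": f"r{rep + 1}",
            })
        for ligand in pdata["ligands"]:
            for rep in range(int(d["replicates"])):
                for dose, p in zip(doses, pct[ligand]):
                    sig = raw_basal + p / 100.0 * raw_span
                    if sd:
                        sig += rng.normal(0.0, sd)
                    rows.append({
                        "ligand": ligand, "receptor": d["receptor"],
                        "pathway": pathway, "dose": dose, "dose_unit": "M",
                        "signal": sig, "replicate": f"r{rep + 1}",
                    })
    truth["normalization"] = norm_truth
    if operational:
        # derived truth: log(tau/KA), per-pathway deltas, cross-pathway ddlog
        log_r = {
            pw: {l: lp["log_tau"] - lp["log_ka"]
                 for l, lp in pdata["ligands"].items()}
            for pw, pdata in tp["pathways"].items()
        }
        truth["log_r"] = log_r
        pws = sorted(tp["pathways"])
        if len(pws) == 2:
            a, b = pws
            tests = [l for l in log_r[a] if l != ref]
            truth["delta_delta_log_r"] = {
                l: (log_r[a][l] - log_r[a][ref]) - (log_r[b][l] - log_r[b][ref])
                for l in tests
            }
            truth["pathway_order"] = [a, b]
    df = pd.DataFrame(rows)
    return SyntheticDataset(assay_kind=spec.assay_kind,
                            tables={"dose_response": df}, truth=truth)


def _gen_saturation(spec: SyntheticSpec) -> SyntheticDataset:
    rng = np.random.default_rng(spec.seed)
    tp, d = spec.true_params, spec.design
    conc = np.asarray(d["conc"], dtype=float)
    specific = one_site_specific(conc, tp["bmax"], tp["kd"])
    ns = tp["ns_slope"] * conc
    sd = _noise_sd(spec, float(specific.max()))
    rows = []
    for rep in range(int(d["replicates"])):
        tot = specific + ns + (rng.normal(0.0, sd, conc.size) if sd else 0.0)
        nsp = ns + (rng.normal(0.0, sd, conc.size) if sd else 0.0)
        for c, t, n in zip(conc, tot, nsp):
            rows.append({"conc": c, "conc_unit": "M", "total": t,
                         "nonspecific": n, "replicate": f"r{rep + 1}"})
    return SyntheticDataset(
        assay_kind=spec.assay_kind,
        tables={"saturation": pd.DataFrame(rows)},
        truth={"seed": spec.seed, "assay_kind": spec.assay_kind,
               "true_params": tp, "design": d, "noise": spec.noise},
    )


def _gen_competition(spec: SyntheticSpec) -> SyntheticDataset:
    rng = np.random.default_rng(spec.seed)
    tp, d = spec.true_params, spec.design
    conc = np.asarray(d["conc"], dtype=float)
    ki = 10.0 ** tp["log_ki"]
    ic50 = ki * (1.0 + tp["radioligand_conc"] / tp["radioligand_kd"])
    y = competition_response(conc, tp["top"], tp["bottom"], np.log10(ic50),
                             tp["hill_n"])
    sd = _noise_sd(spec, float(tp["top"]))
    rows = []
    for rep in range(int(d["replicates"])):
        yy = y + (rng.normal(0.0, sd, conc.size) if sd else 0.0)
        for c, v in zip(conc, yy):
            rows.append({"conc": c, "conc_unit": "M", "binding": v,
                         "replicate": f"r{rep + 1}"})
    truth = {"seed": spec.seed, "assay_kind": spec.assay_kind,
             "true_params": tp, "design": d, "noise": spec.noise,
             "log_ic50": float(np.log10(ic50)), "ic50": float(ic50), "ki": float(ki)}
    return SyntheticDataset(assay_kind=spec.assay_kind,
                            tables={"competition": pd.DataFrame(rows)}, truth=truth)


def _gen_association(spec: SyntheticSpec) -> SyntheticDataset:
    rng = np.random.default_rng(spec.seed)
    tp, d = spec.true_params, spec.design
    rl = RadioligandKinetics(k1=tp["k1"], k2=tp["k2"], conc_l=tp["conc_l"])
    times = np.asarray(d["times"], dtype=float)
    clean = {
        c: mm_bound(times, rl, tp["k3"], tp["k4"], c, tp["bmax_scale"])
        for c in d["competitor_concs"]
    }
    plateau = max(float(v.max()) for v in clean.values())
    sd = _noise_sd(spec, plateau)
    rows = []
    for i, (c, y) in enumerate(clean.items()):
        yy = y + (rng.normal(0.0, sd, times.size) if sd else 0.0)
        for t, v in zip(times, yy):
            rows.append({
                "trace_id": f"assoc{i}", "trace_type": "association",
                "competitor": "competitor", "competitor_conc": c, "conc_unit": "M",
                "time": t, "time_unit": "s", "signal": v,
            })
    return SyntheticDataset(
        assay_kind=spec.assay_kind,
        tables={"kinetics": pd.DataFrame(rows)},
        truth={"seed": spec.seed, "assay_kind": spec.assay_kind,
               "true_params": tp, "design": d, "noise": spec.noise},
    )


def _gen_dissociation(spec: SyntheticSpec) -> SyntheticDataset:
    rng = np.random.default_rng(spec.seed)
    tp, d = spec.true_params, spec.design
    times = np.asarray(d["times"], dtype=float)
    y = tp["ns"] + (tp["y0"] - tp["ns"]) * np.exp(-tp["koff"] * times)
    sd = _noise_sd(spec, float(tp["y0"]))
    yy = y + (rng.normal(0.0, sd, times.size) if sd else 0.0)
    rows = [{
        "trace_id": "dissoc0", "trace_type": "dissociation",
        "competitor": "propranolol-chase", "competitor_conc": 0.0, "conc_unit": "M",
        "time": t, "time_unit": "s", "signal": v,
    } for t, v in zip(times, yy)]
    return SyntheticDataset(
        assay_kind=spec.assay_kind,
        tables={"kinetics": pd.DataFrame(rows)},
        truth={"seed": spec.seed, "assay_kind": spec.assay_kind,
               "true_params": tp, "design": d, "noise": spec.noise},
    )


def _helix_coords(n_residues: int) -> dict[int, dict[str, np.ndarray]]:
    """Ideal-helix backbone (N, CA, C) coordinates for a toy polyalanine chain."""
    out = {}
    for i in range(n_residues):
        theta = np.radians(100.0 * i)
        ca = np.array([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i])
        n = ca + np.array([-0.8, 0.9, -0.6])
        c = ca + np.array([0.9, 0.7, 0.7])
        out[i + 1] = {"N": n, "CA": ca, "C": c}
    return out


def _rotation_matrix(deg: float) -> np.ndarray:
    r = np.radians(deg)
    axis = np.array([1.0, 1.0, 1.0]) / np.sqrt(3.0)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(r) * K + (1 - np.cos(r)) * (K @ K)


def _format_pdb(chain_id: str, coords, b_per_res: np.ndarray) -> str:
    lines = []
    serial = 1
    for resnum in sorted(coords):
        for atom_name in ("N", "CA", "C"):
            x, y, z = coords[resnum][atom_name]
            element = atom_name[0]
            lines.append(
                f"ATOM  {serial:5d}  {atom_name:<3s}ALA {chain_id}{resnum:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{b_per_res[resnum - 1]:6.2f}"
                f"          {element:>2s}"
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def _gen_structure(spec: SyntheticSpec) -> SyntheticDataset:
    """Synthetic toy coordinate fixture (polyalanine helix) with set B-factors.

    Purely synthetic stand-in geometry for exercising distance/RMSD/
    B-factor code paths; it does not resemble any deposited structure.
    """
    rng = np.random.default_rng(spec.seed)
    tp, d = spec.true_params, spec.design
    n = int(d["n_residues"])
    b_scale = float(tp["b_scale"])
    if tp["b_profile"] is not None:
        b = np.asarray(tp["b_profile"], dtype=float)
        if b.size != n:
            raise SpecError(f"b_profile length {b.size} != n_residues {n}")
    else:
        # smooth profile with a flexible-loop bump mid-chain
        i = np.arange(n)
        b = b_scale * (1.0 + 0.5 * np.exp(-0.5 * ((i - n / 2) / 3.0) ** 2))
    coords = _helix_coords(n)
    noise = float(d["coordinate_noise"])
    R = _rotation_matrix(float(d["rotation_deg"]))
    shift = np.asarray(d["translation"], dtype=float)
    out = {}
    for resnum, atoms in coords.items():
        out[resnum] = {}
        for name, xyz in atoms.items():
            p = R @ xyz + shift
            if noise:
                p = p + rng.normal(0.0, noise, 3)
            out[resnum][name] = p
    text = _format_pdb(d["chain_id"], out, b)
    return SyntheticDataset(
        assay_kind=spec.assay_kind,
        tables={},
        truth={"seed": spec.seed, "assay_kind": spec.assay_kind,
               "true_params": {**tp, "b_profile": b.tolist()},
               "design": d, "noise": spec.noise},
        texts={"structure_synthetic.pdb": text},
    )


def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate a synthetic dataset + ground-truth sidecar from *spec*."""
    kind = spec.assay_kind
    if kind == "dose_response_hill":
        return _gen_dose_response(spec, operational=False)
    if kind == "dose_response_operational":
        return _gen_dose_response(spec, operational=True)
    if kind == "saturation":
        return _gen_saturation(spec)
    if kind == "competition":
        return _gen_competition(spec)
    if kind == "kinetics_association":
        return _gen_association(spec)
    if kind == "kinetics_dissociation":
        return _gen_dissociation(spec)
    if kind == "structure_fixture":
        return _gen_structure(spec)
    raise SpecError(f"unknown assay_kind {kind!r}")  # pragma: no cover


def default_study_specs(seed: int = 0, sigma: float = 2.0) -> list[SyntheticSpec]:
    """The packaged battery: one spec per assay kind under study conditions."""
    noise = {"model": "gaussian", "sigma": sigma, "scale": "percent_of_max"}
    return [
        SyntheticSpec(seed=seed + i, assay_kind=kind, noise=dict(noise))
        for i, kind in enumerate(ASSAY_KINDS)
    ]
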