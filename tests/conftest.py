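import numpy as np
import pytest

from betapharm.kinetics import KineticTrace, RadioligandKinetics
from betapharm.simulate import SyntheticSpec, generate


@pytest.fixture
def radioligand() -> RadioligandKinetics:
    """Synthetic labeled-ligand kinetics used throughout the kinetic tests."""
    return RadioligandKinetics(k1=5e7, k2=5e-3, conc_l=0.3e-9)


@pytest.fixture
def hill_dataset_path(tmp_path):
    """Noise-free two-ligand dose-response CSV written through the generator."""
    spec = SyntheticSpec(
        seed=1, assay_kind="dose_response_hill",
        noise={"model": "gaussian", "sigma": 0.0, "scale": "percent_of_max"},
    )
    ds = generate(spec)
    written = ds.write(tmp_path / "hill")
    return written["dose_response"], ds.truth


@pytest.fixture
def operational_dataset_path(tmp_path):
    """Noise-free two-pathway operational dataset written through the generator."""
    spec = SyntheticSpec(
        seed=2, assay_kind="dose_response_operational",
        noise={"model": "gaussian", "sigma": 0.0, "scale": "percent_of_max"},
    )
    ds = generate(spec)
    written = ds.write(tmp_path / "op")
    return written["dose_response"], ds.truth


def make_association_traces(rl, k3, k4, bmax, concs, times, sigma_frac=0.0, seed=0):
    """Build KineticTrace objects straight from the closed-form model."""
    from betapharm.kinetics import mm_bound

    rng = np.random.default_rng(seed)
    clean = {c: mm_bound(times, rl, k3, k4, c, bmax) for c in concs}
    plateau = max(float(v.max()) for v in clean.values())
    traces = []
    for i, (c, y) in enumerate(clean.items()):
        yy = y + rng.normal(0.0, sigma_frac * plateau, times.size) if sigma_frac else y
        traces.append(
            KineticTrace(trace_id=f"t{i}", trace_type="association",
                         competitor_conc=c, times=times, signal=yy)
        )
    return traces


class TraceSet:
    """Minimal stand-in for a KineticDataset in fit tests."""

    def __init__(self, traces, rl):
        self._traces = traces
        self.radioligand_params = rl

    def association_traces(self):
        return list(self._traces)
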