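import numpy as np
import pytest

from drykin import DryingCurve, MoistureObservation, MoistureRatioSeries


@pytest.fixture
def mass_curve():
    """30 g sample, 82.63 % wt. initial moisture, simple decaying masses."""

    def build(masses, temperature=50.0, thickness=0.01, **kwargs):
        obs = tuple(
            MoistureObservation(time=float(i * 3600), mass=float(m))
            for i, m in enumerate(masses)
        )
        kwargs.setdefault("initial_wet_basis_moisture", 82.63)
        return DryingCurve(
            temperature=temperature,
            slab_thickness=thickness,
            observations=obs,
            **kwargs,
        )

    return build


@pytest.fixture
def mr_series():
    """MoistureRatioSeries directly from hourly MR values (MR(0) = 1)."""

    def build(mr_values, temperature=50.0, thickness=0.01):
        mr = np.asarray(mr_values, dtype=float)
        times = np.arange(len(mr), dtype=float) * 3600.0
        return MoistureRatioSeries(
            times=times, mr_values=mr, temperature=temperature, slab_thickness=thickness
        )

    return build
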