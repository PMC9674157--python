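import numpy as np
import pytest

from ovareserve import PoiCalculator, ReserveModel


@pytest.fixture(scope="session")
def model() -> ReserveModel:
    return ReserveModel()


@pytest.fixture(scope="session")
def calc(model) -> PoiCalculator:
    return PoiCalculator(model)


class GridOracle:
    """Brute-force reference: the decline curve tabulated on a fine age grid.

    Solves every inversion by nearest-value lookup on a 0.001-year grid,
    with no root finder, so it is independent of the package's solvers.
    """

    def __init__(self, model: ReserveModel, step: float = 0.001):
        self.model = model
        p = model.params
        self.ages = np.arange(p.age_min, p.age_max + step / 2, step)
        self.log10 = model._log10_curve(self.ages)  # strictly decreasing

    def inverse_age(self, log10_count: float, z: float = 0.0) -> float:
        track = self.log10 + z * self.model.dispersion.sigma_log10
        return float(self.ages[np.argmin(np.abs(track - log10_count))])

    def age_at_threshold(self, z: float = 0.0) -> float:
        return self.inverse_age(np.log10(self.model.params.poi_threshold), z)

    def predict_poi_age(self, age: float, dose: float, z: float,
                        ld50: float = 2.0) -> float:
        sigma = self.model.dispersion.sigma_log10
        log10_count = (
            float(self.model._log10_curve(age)) + z * sigma - dose / ld50 * np.log10(2)
        )
        if 10.0 ** log10_count <= self.model.params.poi_threshold:
            return float(age)
        equivalent = self.inverse_age(log10_count, z)
        return age + (self.age_at_threshold(z) - equivalent)


@pytest.fixture(scope="session")
def grid_oracle(model) -> GridOracle:
    return GridOracle(model)
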