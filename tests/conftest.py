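import numpy as np
import pytest

from masscollide import ExperimentDesign
from masscollide.observer import GridPosterior, ObserverParams


@pytest.fixture(scope="session")
def design() -> ExperimentDesign:
    """The default 12-cell occlusion design."""
    return ExperimentDesign()


@pytest.fixture(scope="session")
def params() -> ObserverParams:
    return ObserverParams()


@pytest.fixture(scope="session")
def engine(params) -> GridPosterior:
    """One shared default-grid posterior engine (expensive to rebuild)."""
    return GridPosterior(params)


@pytest.fixture(scope="session")
def signed_ratios(design) -> list[float]:
    return sorted({c[0] for c in design.prediction_cells()})


@pytest.fixture(scope="session")
def grid_cell_predictions(design, engine):
    """Grid-posterior prediction for every signed design cell (cached)."""
    from masscollide.observer import cell_observations

    return {
        cell: float(np.mean(engine.posterior_many(cell_observations(design, cell))))
        for cell in design.prediction_cells()
    }
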