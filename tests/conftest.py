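import numpy as np
import pytest

from isomix.isodata import Period, SourceSummary, TDFSpec
from isomix.synthetic_data import ClassSpec, SimulationScenario, SourceSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tri_sources():
    """Three well-separated sources with distinct concentrations."""
    return [
        SourceSummary("src_a", Period.P2000S, 30, np.array([-22.0, 12.0]),
                      np.array([0.5, 0.5]), np.array([0.45, 0.12])),
        SourceSummary("src_b", Period.P2000S, 30, np.array([-18.0, 14.0]),
                      np.array([0.5, 0.5]), np.array([0.40, 0.10])),
        SourceSummary("src_c", Period.P2000S, 30, np.array([-20.0, 17.5]),
                      np.array([0.5, 0.5]), np.array([0.42, 0.14])),
    ]


TRI_SPECS = (
    SourceSpec("src_a", (-22.0, 12.0), (0.5, 0.5), (0.45, 0.12), 30),
    SourceSpec("src_b", (-18.0, 14.0), (0.5, 0.5), (0.40, 0.10), 30),
    SourceSpec("src_c", (-20.0, 17.5), (0.5, 0.5), (0.42, 0.14), 30),
)


def make_scenario(diets, seed, sigma=0.0, n_per=30, years=(2002,), error_mult=(1.0, 1.0)):
    """One-period scenario over the standard three-source layout."""
    classes = tuple(ClassSpec(label, diet, n_per) for label, diet in diets)
    return SimulationScenario(
        name="test",
        seed=seed,
        period=Period.P2000S,
        sources=TRI_SPECS,
        classes=classes,
        years=years,
        sigma_individual=sigma,
        error_mult=error_mult,
    )


@pytest.fixture
def consumer_csv(tmp_path):
    path = tmp_path / "consumers.csv"
    path.write_text(
        "sample_id,class,period,year,d13c,d15n\n"
        "b1,adult_male,2000s,2002,-18.5,16.2\n"
        "b2,adult_female,2000s,2001,-19.1,15.8\n"
        "b3,juvenile,2000s,2000,-18.9,15.1\n"
    )
    return path


@pytest.fixture
def prey_csv(tmp_path):
    path = tmp_path / "prey.csv"
    path.write_text(
        "sample_id,taxon,group,region,period,year,d13c,d15n,pct_c,pct_n\n"
        "p1,capelin,pelagic,LE,2000s,2002,-21.0,13.5,46.0,11.0\n"
        "p2,capelin,pelagic,LE,2000s,2002,-21.5,13.0,44.0,11.5\n"
        "p3,tomcod,tomcod,UE,2000s,2001,-19.5,16.0,45.0,13.0\n"
        "p4,tomcod,tomcod,UE,2000s,2001,-20.5,16.5,43.0,12.5\n"
    )
    return path
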