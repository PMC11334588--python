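import pytest
import yaml

from seqdta import EndpointDesign
from seqdta.datasets import example_cohort, raptor_cohort, raptor_design, simulated_design


@pytest.fixture(scope="session")
def sens_endpoint_by_positives():
    """Sensitivity endpoint of the worked example: interims at 15/25/50
    disease-positive cases, anchored to 70 planned positives, p0 = 75%."""
    return EndpointDesign("FNR", 0.75, (15, 25, 50), 70)


@pytest.fixture(scope="session")
def cohort1():
    return example_cohort(1)


@pytest.fixture(scope="session")
def cohort2():
    return example_cohort(2)


@pytest.fixture(scope="session")
def design_by_total():
    return simulated_design("by_total")


@pytest.fixture(scope="session")
def design_by_positives():
    return simulated_design("by_positives")


@pytest.fixture(scope="session")
def raptor():
    """(device, profile) -> (design, cohort) for the case-study fixtures."""

    def _get(device: str, profile: str):
        return raptor_design(profile), raptor_cohort(device)

    return _get


@pytest.fixture()
def config_file(tmp_path):
    """Write a design document to a temp YAML file and return its path."""

    def _write(doc: dict, name: str = "design.yaml"):
        path = tmp_path / name
        path.write_text(yaml.safe_dump(doc))
        return path

    return _write


@pytest.fixture()
def by_positives_doc():
    return {
        "prevalence": 0.35,
        "schedule": "by_positives",
        "interim_points": [15, 25, 50],
        "target": 70,
        "alpha": 0.05,
        "sensitivity_p0": 0.75,
        "specificity_p0": 0.90,
        "futility_rule": "either",
    }
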