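from decimal import Decimal

import pytest

from brcapath.audit_weighting import AuditCounts
from brcapath.cli_io import (
    assemble_model,
    read_audit_counts,
    read_audit_narrative,
    read_unit_costs,
)
from brcapath.config import load_config
from brcapath.cost_engine import DiscountSpec, StaffingConfig
from brcapath.pathway_catalog import load_catalog


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


@pytest.fixture(scope="session")
def unit_costs():
    return read_unit_costs()


@pytest.fixture(scope="session")
def config():
    return load_config()


@pytest.fixture(scope="session")
def discount_spec():
    return DiscountSpec(Decimal("0.035"), Decimal(30))


@pytest.fixture(scope="session")
def staffing():
    return StaffingConfig()


@pytest.fixture(scope="session")
def model():
    """(catalog, config, full cost table, calibration result, computed totals,
    reporting costs) assembled from the shipped fixtures."""
    return assemble_model()


@pytest.fixture(scope="session")
def full_table(model):
    return model[2]


@pytest.fixture(scope="session")
def reference_totals(catalog):
    return catalog.reference_totals()


@pytest.fixture(scope="session")
def audit_counts():
    return read_audit_counts()


@pytest.fixture(scope="session")
def narrative():
    return read_audit_narrative()
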