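"""Shared fixtures: packaged networks, toy networks, and a randomized
small-network generator used for EMU-vs-oracle equivalence testing."""

from __future__ import annotations

import numpy as np
import pytest

from cellflux.network import FluxMap, Network, parse_network, packaged_network
from cellflux.synth import random_toy_case  # noqa: F401  (re-exported for tests)
from cellflux.tracers import TracerSpec


@pytest.fixture(scope="session")
def lf_network() -> Network:
    return packaged_network("lf")


@pytest.fixture(scope="session")
def pasmc_network() -> Network:
    return packaged_network("pasmc")


MEASURED = [
    "AKG", "3PG", "ALA", "ASP", "CIT", "FBP",
    "GLU", "GLN", "LAC", "MAL", "PYR.ms", "SER",
]


@pytest.fixture(scope="session")
def measured_fragments():
    return [(m, None) for m in MEASURED]


@pytest.fixture()
def toy_chain() -> Network:
    return parse_network(
        """
% unbalanced: GLC.x PYR.x
GLUT: GLC.x (abcdef) -> GLC (abcdef)
GLYC: GLC (abcdef) -> PYR (cba) + PYR (def)
PYROUT: PYR (abc) -> PYR.x (abc)
"""
    )


@pytest.fixture()
def toy_tca() -> tuple[Network, FluxMap]:
    net = parse_network(
        """
% unbalanced: AcCoA.x OAC.x CO2 MAL.x
% symmetric: SUC FUM
ACIN: AcCoA.x (ab) -> AC (ab)
OACIN: OAC.x (abcd) -> OAC (abcd)
CS: AC (ef) + OAC (abcd) -> CIT (dcbfea)
IDH: CIT (abcdef) -> AKG (abcde) + CO2 (f)
OGDH: AKG (abcde) -> SUC (bcde) + CO2 (a)
SDH: SUC (abcd) <-> FUM (abcd)
FH: FUM (abcd) <-> MAL (abcd)
MDH: MAL (abcd) -> OAC (abcd)
MALOUT: MAL (abcd) -> MAL.x (abcd)
"""
    )
    flux = FluxMap(
        net={
            "ACIN": 1.2, "OACIN": 0.2, "CS": 1.2, "IDH": 1.2, "OGDH": 1.2,
            "SDH": 1.2, "FH": 1.2, "MDH": 1.0, "MALOUT": 0.2,
        },
        exch={"SDH": 0.7, "FH": 2.3},
    )
    return net, flux
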