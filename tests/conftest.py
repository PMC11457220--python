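import numpy as np
import pytest

from neaspec import (
    ExcitationTable,
    MolecularGeometry,
    NormalModeSet,
    VerticalExcitation,
)


@pytest.fixture
def water_geometry() -> MolecularGeometry:
    coords = np.array([
        [0.0000, 0.0000, 0.1173],
        [0.0000, 0.7572, -0.4692],
        [0.0000, -0.7572, -0.4692],
    ])
    return MolecularGeometry.from_symbols(["O", "H", "H"], coords)


@pytest.fixture
def water_modes(water_geometry) -> NormalModeSet:
    """A 3-mode set with synthetic orthonormal mass-weighted vectors.

    The vectors are an arbitrary orthonormal triple in R^9 (from a seeded
    QR factorization), which is all the sampling math requires; the
    frequencies are the real water fundamentals.
    """
    rng = np.random.default_rng(7)
    q, _ = np.linalg.qr(rng.standard_normal((9, 3)))
    return NormalModeSet(water_geometry,
                         np.array([1594.8, 3657.1, 3755.9]), q.T)


@pytest.fixture
def single_transition_table() -> ExcitationTable:
    return ExcitationTable(((VerticalExcitation(1, 4.0, fosc=0.01),),))


def make_table(energies, foscs) -> ExcitationTable:
    """Rectangular table helper: energies/foscs are (N_p, N_s) nested lists."""
    records = tuple(
        tuple(VerticalExcitation(i + 1, e, fosc=f)
              for i, (e, f) in enumerate(zip(row_e, row_f)))
        for row_e, row_f in zip(energies, foscs)
    )
    return ExcitationTable(records)
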