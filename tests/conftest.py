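import numpy as np
import pytest

from nitroscope.similarity import MatchParameters
from nitroscope.simulate import SimulationConfig
from nitroscope.spectra import Spectrum


@pytest.fixture
def params() -> MatchParameters:
    return MatchParameters()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240201)


@pytest.fixture
def small_cfg() -> SimulationConfig:
    return SimulationConfig(seed=13, n_proteins=60)


def make_spectrum(mz, intensity, identifier="s", precursor=500.0, charge=2, **kw):
    return Spectrum(
        identifier=identifier,
        precursor_mz=precursor,
        precursor_charge=charge,
        mz=np.asarray(mz, dtype=float),
        intensity=np.asarray(intensity, dtype=float),
        **kw,
    )


@pytest.fixture
def tiny_fasta() -> dict[str, str]:
    # P1 has tyrosines at 3, 12 and 21; P2 at 5
    return {
        "P1": "AKYLTVAAVFRYGAAKPGDLYR",
        "P2": "MKGAYRGGKRLLK",
    }
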