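import pytest

from mlcedge import SourceModel, SweepConfig, TreatmentGeometry, run_sweep

#: the oracle-equivalence grid: clinical leaf-end radii x nominal positions
ORACLE_RADII = (4.0, 6.0, 8.0, 10.0, 15.0, 20.0, 25.0)
ORACLE_NOMINALS = (-20.0, -10.0, 0.0, 10.0, 20.0)


@pytest.fixture(scope="session")
def geom() -> TreatmentGeometry:
    """Default treatment-head geometry (SAD 100, SCD 46, lh 8, mu 0.96)."""
    return TreatmentGeometry()


@pytest.fixture(scope="session")
def r15_sweep(geom):
    """Full nominal sweep for the reference leaf (R = 15 cm, 1 mm FWHM)."""
    config = SweepConfig(
        radii=(15.0,),
        fwhms=(1.0,),
        nominals=tuple(float(n) for n in range(-20, 21)),
        geometry=geom,
    )
    return run_sweep(config)


@pytest.fixture(scope="session")
def mm_source() -> SourceModel:
    """Deterministic 1 mm FWHM quadrature source."""
    return SourceModel(fwhm=1.0)
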