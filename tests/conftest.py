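import pytest

from allokin import (
    AllometryConstants,
    CellSizePrior,
    KineticRecord,
    RecordSet,
    ScalingParams,
    SyntheticConfig,
    generate_dataset,
)


@pytest.fixture(scope="session")
def constants() -> AllometryConstants:
    return AllometryConstants()


@pytest.fixture(scope="session")
def prior() -> CellSizePrior:
    return CellSizePrior()


@pytest.fixture(scope="session")
def posterior_mean_params() -> ScalingParams:
    """Chemotroph posterior-mean scaling parameters, the default truth."""
    return ScalingParams(a=4.64e-15, b=2.70, c_bar=1.83e-2, d=1.254)


@pytest.fixture(scope="session")
def synthetic_161(posterior_mean_params) -> RecordSet:
    """A default-condition synthetic record set (independent mode, n=161)."""
    return generate_dataset(SyntheticConfig(seed=20))


@pytest.fixture()
def tiny_recordset() -> RecordSet:
    return RecordSet(
        [
            KineticRecord("Escherichia coli", "aerobic respiration", vmax_dw=3.8e-3, km=1.4e-5),
            KineticRecord("Nitrosomonas sp.", "ammonia oxidation to nitrite", vmax_dw=1.0e-3, km=5.0e-5),
            KineticRecord("Shewanella putrefaciens", "Fe(III) reduction", km=2.0e-4),
        ],
        provenance="fixture",
    )


@pytest.fixture()
def records_csv(tmp_path):
    """Wide-format 3-row fixture CSV with one K_m-only row."""
    path = tmp_path / "records.csv"
    path.write_text(
        "organism,functional_group,trophic_mode,vmax_dw,km,source\n"
        "Escherichia coli,aerobic respiration,chemotroph,3.8e-3,1.4e-5,ref1\n"
        "Nitrosomonas sp.,ammonia oxidation to nitrite,chemotroph,1.0e-3,5.0e-5,ref2\n"
        "Shewanella putrefaciens,Fe(III) reduction,chemotroph,,2.0e-4,ref3\n"
    )
    return path
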