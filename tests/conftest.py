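import numpy as np
import pytest

from attnms1.maxquant_io import PeptideMeasurement


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_measurement(sequence="ACDK", intensity=1e6, pep=0.001,
                     reverse=False, contaminant=False, pool_id="pool1",
                     enzyme="Trypsin", enzyme_mode="specific"):
    return PeptideMeasurement(
        sequence=sequence, intensity=intensity, pep=pep,
        reverse_flag=reverse, contaminant_flag=contaminant,
        pool_id=pool_id, enzyme=enzyme, enzyme_mode=enzyme_mode,
    )


@pytest.fixture
def measurement_factory():
    return make_measurement


PEPTIDES_TXT = (
    "Sequence\tIntensity\tPEP\tReverse\tPotential contaminant\n"
    "ACDK\t1000000\t0.001\t\t\n"
    "LMNPQR\t2500000\t0.005\t+\t\n"
    "GGWY\t0\t0.0001\t\t\n"
)

SUMMARY_TXT = (
    "Raw file\tEnzyme\tEnzyme mode\n"
    "run01\tTrypsin\tSpecific\n"
    "Total\t\t\n"
)

SDRF_TSV = (
    "source name\tcomment[data file]\tcharacteristics[organism]\n"
    "sample 1\tpool1.zip\tHomo sapiens\n"
    "sample 2\tpool2.zip\tHomo sapiens\n"
)


@pytest.fixture
def peptides_file(tmp_path):
    p = tmp_path / "peptides.txt"
    p.write_text(PEPTIDES_TXT)
    return p


@pytest.fixture
def summary_file(tmp_path):
    p = tmp_path / "summary.txt"
    p.write_text(SUMMARY_TXT)
    return p


@pytest.fixture
def sdrf_file(tmp_path):
    p = tmp_path / "sdrf.tsv"
    p.write_text(SDRF_TSV)
    return p
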