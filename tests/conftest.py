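import numpy as np
import pytest

from mrith import (PatientMutationMatrix, PatientRecord, SimulationConfig,
                   Subtype, simulate_cohort)

TISSUE_HEADER = "patient_id\tregion_id\tsubtype\tchrom\tpos\tref\talt\tgene\tvclass\tvaf\talt_reads\tdepth"
CTDNA_HEADER = "patient_id\tchrom\tpos\tref\talt\tgene\tvclass\tmutant_reads\tdepth"


def tissue_file(tmp_path, rows, name="tissue.tsv", header=TISSUE_HEADER):
    path = tmp_path / name
    path.write_text("\n".join([header, *rows]) + "\n")
    return path


def ctdna_file(tmp_path, rows, name="ctdna.tsv"):
    path = tmp_path / name
    path.write_text("\n".join([CTDNA_HEADER, *rows]) + "\n")
    return path


def matrix(presence, patient_id="P1") -> PatientMutationMatrix:
    """Matrix from a list of 0/1 rows; keys m0..; regions R1.."""
    arr = np.asarray(presence, dtype=np.int8)
    return PatientMutationMatrix(
        patient_id,
        [f"m{i}" for i in range(arr.shape[0])],
        [f"R{j + 1}" for j in range(arr.shape[1])],
        arr)


def patient(pid="P1", n_regions=3, subtype=Subtype.WT_LUAD) -> PatientRecord:
    return PatientRecord(pid, [f"R{i + 1}" for i in range(n_regions)], subtype)


@pytest.fixture(scope="session")
def default_sim():
    """One study-scale simulated cohort (32 patients), shared across tests."""
    return simulate_cohort(SimulationConfig(seed=20190109))


@pytest.fixture
def sim_dir(tmp_path, default_sim):
    return default_sim.write(tmp_path / "sim")
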