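import pytest

from neoforest.model import EnsembleConfig
from neoforest.peptides import ExternalPredictions, PeptideRecord
from neoforest.simulate import SyntheticConfig, generate_cohort


def make_record(
    peptide_id="pep1",
    patient_id="pat1",
    mut_seq="ALDKHGYEV",
    wt_seq="ALDKHGYAV",
    label=0,
    **external,
):
    seq = mut_seq
    start = max((len(seq) - 9) // 2, 0)
    return PeptideRecord(
        peptide_id=peptide_id,
        patient_id=patient_id,
        mut_seq=seq,
        wt_seq=wt_seq,
        hla="HLA-A02:01",
        core9=seq[start : start + 9],
        core_start=start,
        label=label,
        external=ExternalPredictions(**external),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """~500-peptide planted-signal cohort shared by read-only tests."""
    return generate_cohort(
        SyntheticConfig(n_patients=10, peptides_per_patient=(50, 50), seed=7)
    )


@pytest.fixture()
def tiny_config():
    """Very small ensemble for fast unit tests of the training loop."""
    return EnsembleConfig(
        n_estimators=25, n_subsamples=2, n_negatives_per_subsample=50, seed=0
    )
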