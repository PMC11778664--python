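import numpy as np
import pytest

from hetloop import biclustering as bc
from hetloop import genotype_io as gio
from hetloop import synthetic_data as sd


def split_case_control(ds, maf_threshold=0.25):
    """Expand an arm into aligned case/control combo matrices."""
    cm = gio.expand_allele_combinations(gio.filter_by_maf(ds, maf_threshold))
    case = np.flatnonzero(ds.case_mask())
    ctrl = np.flatnonzero(~ds.case_mask())
    return cm.restrict_subjects(case), cm.restrict_subjects(ctrl)


@pytest.fixture(scope="session")
def planted_arm():
    """A small training arm with a clearly planted bicluster."""
    cfg = sd.SyntheticConfig(
        n_cases=80,
        n_controls=80,
        n_snps=300,
        effect_delta=0.5,
        arm_overlaps=(0.85,),
        seed=11,
    )
    ds, cov, truth = sd.generate_arm(cfg, 1)
    return cfg, ds, cov, truth


@pytest.fixture(scope="session")
def planted_discovery(planted_arm):
    """Discovery run (with nulls) on the planted arm, shared across tests."""
    _, ds, cov, truth = planted_arm
    D, X = split_case_control(ds)
    traj = bc.run_discovery(
        D, X, cov, bc.HalfLoopConfig(n_shuffles=16, seed=5), record_null_cols=True
    )
    return ds, cov, truth, D, X, traj


@pytest.fixture
def tiny_dataset():
    """3 subjects x 2 SNPs with one missing call, built by hand."""
    import pandas as pd

    subjects = pd.DataFrame(
        {
            "subject_id": ["s1", "s2", "s3"],
            "status": ["case", "case", "control"],
            "subtype": ["BDI", "BDII", "unknown"],
            "arm_id": ["arm1"] * 3,
        }
    )
    snps = pd.DataFrame(
        {
            "snp_id": ["rs1", "rs2"],
            "chrom": ["1", "2"],
            "pos_bp": [1000, 2000],
            "allele_major": ["A", "C"],
            "allele_minor": ["G", "T"],
            "maf": [2 / 6, 2 / 4],
        }
    )
    calls = np.array([[0.0, 1.0], [1.0, np.nan], [1.0, 1.0]])
    return gio.GenotypeDataset(subjects=subjects, snps=snps, calls=calls)
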