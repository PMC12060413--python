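import pytest

from rteshift.pipeline import run as run_pipeline
from rteshift.simulate import SyntheticConfig, generate


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A 200-locus synthetic dataset with its truth ledger."""
    outdir = tmp_path_factory.mktemp("small_sim")
    cfg = SyntheticConfig(n_loci=200, seed=7)
    paths, truth = generate(cfg, outdir)
    return cfg, paths, truth


@pytest.fixture(scope="session")
def standard_run(tmp_path_factory):
    """Full pipeline results on the standard 2000-locus, 30+30 dataset."""
    outdir = tmp_path_factory.mktemp("std_run")
    config = {
        "synthetic": {"n_loci": 2000},
        "comparisons": [
            {
                "name": "SYNTH",
                "group_a": {"condition": "tumour"},
                "group_b": {"condition": "normal"},
            }
        ],
        "stratification": {"rule": "median"},
    }
    results = run_pipeline(config, outdir, seed=7)
    truth = results.pop("_truth")
    return results, truth, outdir
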