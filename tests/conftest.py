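import numpy as np
import pytest

from trsc.synthetic_data import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """An 8-subject, 6-component cohort at the study's T and TR."""
    cfg = SimulationConfig(n_per_cell=2, n_components=6, n_timepoints=159, seed=42)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def cohort_on_disk(small_cohort, tmp_path_factory):
    """The small cohort persisted in the manifest layout."""
    from trsc import io_core

    dataset, metadata, labels = small_cohort
    root = tmp_path_factory.mktemp("cohort")
    manifest = io_core.write_dataset(dataset, str(root))
    io_core.write_metadata(metadata, str(root / "metadata.tsv"))
    io_core.write_network_labels(labels, str(root / "network_labels.tsv"))
    return {
        "root": root,
        "manifest": manifest,
        "metadata": str(root / "metadata.tsv"),
        "labels": str(root / "network_labels.tsv"),
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
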