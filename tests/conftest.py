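import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from transcomp import (
    SimulationSpec,
    expected_total,
    make_synthetic_genome,
    simulate_contacts,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def calibrated_spec(binning, truth_C, ends_per_bin, *, alpha=0.0, beta=0.0, seed=0):
    """SimulationSpec whose expected mean trans read-ends per bin is given."""
    spec = SimulationSpec(binning, truth_C, alpha=alpha, beta=beta, seed=seed)
    spec.depth_scale = (binning.n_total * ends_per_bin / 2) / expected_total(spec)
    return spec


@pytest.fixture(scope="session")
def small_sim():
    """200-bin, 4-chromosome genome with a 3-compartment truth and contacts.

    Moderate depth (~800 trans read-ends per bin) with a Rabl effect
    (alpha=0.3, beta=0.1); shared across optimizer and evaluation tests.
    """
    binning, truth_C = make_synthetic_genome(4, 5_000_000, 100_000, 3, seed=7)
    spec = calibrated_spec(binning, truth_C, 800, alpha=0.3, beta=0.1, seed=8)
    table = simulate_contacts(spec)
    return {"binning": binning, "truth_C": truth_C, "spec": spec, "table": table}


@pytest.fixture(scope="session")
def small_fit(small_sim):
    """A converged 3-compartment fit of the small simulated dataset."""
    from transcomp import SubcompartmentModel

    est = SubcompartmentModel(n_compartments=3, n_restarts=2, random_state=0)
    est.fit(small_sim["table"])
    return est


def random_instance(seed, n_chroms=3, bins_per_chrom=10, M=3, n_entries=20,
                    alpha=0.25, beta=0.1):
    """Small random model + contact table for derivative/oracle tests."""
    from transcomp import CompartmentModel, ContactTable
    from transcomp.genome_io import GenomeBinning
    from transcomp.genome_io import compute_relative_positions

    rng = np.random.default_rng(seed)
    bin_size = 100_000
    binning = GenomeBinning(
        [f"chr{c}" for c in range(n_chroms)],
        np.full(n_chroms, bins_per_chrom * bin_size, dtype=np.int64),
        bin_size,
    )
    binning = compute_relative_positions(binning)
    n = binning.n_total
    C = rng.uniform(0.2, 2.0, size=(n, M))
    cid = binning.chrom_ids
    i = rng.integers(0, n, size=4 * n_entries)
    j = rng.integers(0, n, size=4 * n_entries)
    keep = cid[i] != cid[j]
    i, j = i[keep][:n_entries], j[keep][:n_entries]
    counts = rng.integers(1, 8, size=i.size)
    table = ContactTable.from_coo(binning, i, j, counts)
    model = CompartmentModel(C, alpha=alpha, beta=beta)
    return binning, table, model
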