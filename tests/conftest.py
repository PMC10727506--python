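import numpy as np
import pytest

import enspattern as ep


@pytest.fixture(scope="session")
def default_cohort():
    """The default study-conditions cohort: 5 aged samples x 400 cells,
    500 somatic genes + 37 mito genes, 6 programs (2 MEN-like)."""
    cfg = ep.SimConfig(seed=1)
    adata, truth = ep.simulate_reference_cohort(cfg)
    return cfg, adata, truth


@pytest.fixture(scope="session")
def filtered_cohort(default_cohort):
    """QC-filtered default cohort with log10 normalization."""
    _, adata, truth = default_cohort
    mask, filt = ep.filter_cells(adata, 200, 0.20)
    lognorm = np.asarray(
        ep.LogNormalizer(10).fit(filt.X).transform(filt.X).todense())
    return filt, truth, mask, lognorm


@pytest.fixture(scope="session")
def fitted_patterns(filtered_cohort):
    """NMF (k = k_true) fit on the somatic genes of the filtered cohort."""
    filt, truth, mask, lognorm = filtered_cohort
    somatic = ~filt.var["is_mito"].to_numpy(bool)
    model = ep.nmf_fit(lognorm[:, somatic], k=6, seed=1, n_restarts=1)
    return model, somatic


@pytest.fixture(scope="session")
def small_cohort():
    """A fast 250-cell cohort for unit tests that only need structure."""
    cfg = ep.SimConfig(cells_per_sample=50, seed=7)
    adata, truth = ep.simulate_reference_cohort(cfg)
    return cfg, adata, truth


def hungarian_cosine(A, A_true):
    """Mean cosine similarity between matched pattern columns."""
    from scipy.optimize import linear_sum_assignment
    An = A / np.maximum(np.linalg.norm(A, axis=0, keepdims=True), 1e-12)
    Bn = A_true / np.maximum(np.linalg.norm(A_true, axis=0, keepdims=True), 1e-12)
    C = An.T @ Bn
    r, c = linear_sum_assignment(-C)
    return C[r, c].mean(), dict(zip(c, r))
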