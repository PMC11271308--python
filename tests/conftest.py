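import numpy as np
import pandas as pd
import pytest

from hsdquant import synthetic


@pytest.fixture(scope="session")
def fatbody():
    """Default noiseless fat-body field with planted membrane enrichment 2.0."""
    params = synthetic.ImageSimParams(
        shape=(240, 240), n_cells=16, membrane_enrichment=2.0, seed=7
    )
    return synthetic.sim_fatbody_image(params)


@pytest.fixture(scope="session")
def phospho_noiseless():
    """Small noiseless 18-plex with full blunting (knockdowns lose the response)."""
    params = synthetic.PhosphoSimParams(
        n_sites=400, n_proteins=90, frac_responsive=0.25,
        blunting=0.0, noise_sd=0.0, seed=5,
    )
    return synthetic.sim_phospho(params)


def random_curve(rng: np.random.Generator):
    """A random valid cumulative pupariation curve (may or may not reach 50%)."""
    from hsdquant.pupariation import PupariationCurve

    n = rng.integers(3, 15)
    times = np.sort(rng.uniform(20, 300, n))
    while np.any(np.diff(times) <= 0):
        times = np.sort(rng.uniform(20, 300, n))
    top = rng.uniform(0.1, 1.0)
    fracs = np.sort(rng.uniform(0, top, n))
    fracs[0] = min(fracs[0], 0.2)
    return PupariationCurve(
        genotype="g", diet="ND", vial="v",
        obs_times=tuple(times), cum_fraction=tuple(fracs),
        n_pupae_final=int(round(fracs[-1] * 30)), n_seeded=30,
    )


def p50_dense_oracle(curve, step: float = 0.01):
    """Brute-force P50: densely resample the piecewise-linear curve and take
    the first time whose value reaches 0.5."""
    t = np.asarray(curve.obs_times)
    f = np.asarray(curve.cum_fraction)
    if f.max() < 0.5:
        return None
    grid = np.arange(t[0], t[-1] + step, step)
    vals = np.interp(grid, t, f)
    return float(grid[np.argmax(vals >= 0.5)])
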