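import numpy as np
import pytest

from cocultx.decline_models import ModelParams, model_eval
from cocultx.io_model import CurveSeries
from cocultx.synthetic_data import SimConfig, default_library, simulate_experiment


@pytest.fixture(scope="session")
def library():
    return default_library()


@pytest.fixture(scope="session")
def default_experiment():
    """One default 5x5 simulated experiment shared across tests (seed 11)."""
    return simulate_experiment(SimConfig(seed=11))


@pytest.fixture
def exponential_curve():
    """Noiseless exponential growth, daily doubling over 10 days."""
    t = np.arange(10.0)
    return CurveSeries("doubling", t, 2.0**t)


def make_decline_curve(params: ModelParams, n_days: int = 60, flmax: float = 100.0,
                       noise_cv: float = 0.0, seed: int = 0) -> CurveSeries:
    """A curve that peaks at day 0 and declines under the given law."""
    tau = np.arange(float(n_days))
    y = flmax * model_eval(params, tau)
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log1p(noise_cv**2))
        y = y * rng.lognormal(-0.5 * sigma**2, sigma, len(tau))
    return CurveSeries("decline", tau, y)


@pytest.fixture
def toy_csv_trio(tmp_path):
    """A 3-culture toy CSV trio on disk."""
    curves = tmp_path / "curves.csv"
    meta = tmp_path / "metadata.csv"
    counts = tmp_path / "counts.csv"
    rows = ["culture_id,day,fluorescence"]
    for cid in ("c1", "c2", "c3"):
        for d in range(6):
            rows.append(f"{cid},{d},{10 * (d + 1)}")
    curves.write_text("\n".join(rows) + "\n")
    meta.write_text(
        "culture_id,experiment,pro_strain,alt_strain,replicate\n"
        "c1,E1,MED4,HOT1A3,1\n"
        "c2,E1,MED4,none,1\n"
        "c3,E1,none,HOT1A3,1\n"
    )
    counts.write_text(
        "culture_id,day,population,cells_per_ml\n"
        "c1,5,prochlorococcus,1e6\n"
        "c1,5,alteromonas,1e7\n"
        "c2,5,prochlorococcus,5e5\n"
        "c3,5,alteromonas,2e7\n"
    )
    return curves, meta, counts
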