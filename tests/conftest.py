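import numpy as np
import pandas as pd
import pytest

from radbench.survival import AnalysisGroup
from radbench.synthdata import SimulationConfig, simulate_cell_line_panel


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    """Small, fast simulation config with the noise channels left on."""
    return SimulationConfig(n_genes=150, n_lines=40, probes_per_gene=4, seed=0)


@pytest.fixture(scope="session")
def noiseless_linear_panel():
    """Panel whose SF2 is an exact rank-linear function of 3 planted genes.

    Coefficients sum to zero, matching the identifiability gauge of the
    rank-linear trainer, so closed-loop recovery is exact.
    """
    cfg = SimulationConfig(n_genes=150, n_lines=40, noise_sd=0.0,
                           sf2_factor_coef=0.0, seed=1)
    genes = ["g0003", "g0017", "g0042"]
    coefs = np.array([0.02, -0.035, 0.015])
    panel = simulate_cell_line_panel(cfg, genes, coefs, intercept=0.4,
                                     sf2_link="linear")
    return panel, genes, coefs, 0.4


@pytest.fixture()
def toy_group():
    """Six patients, one stratum, untied event times."""
    pats = pd.DataFrame(
        {"cohort_id": "c1", "outcome_type": "OS", "rt": 1,
         "time": [3.0, 5.0, 7.0, 2.0, 9.0, 4.0],
         "event": [1, 1, 0, 1, 1, 1]},
        index=[f"s{i}" for i in range(6)])
    scores = pd.Series([0.5, -1.2, 0.3, 2.0, -0.7, 1.1], index=pats.index)
    return AnalysisGroup(label="OS_RT", patients=pats), scores


def brute_force_cox_beta(time, event, x, strata=None, bounds=(-10, 10)):
    """Independent 1-D oracle: maximize the hand-written (Efron) partial
    likelihood over a dense golden-section search."""
    from scipy.optimize import minimize_scalar

    time = np.asarray(time, float)
    event = np.asarray(event)
    x = np.asarray(x, float)
    strata = np.zeros(len(time)) if strata is None else np.asarray(strata)

    def negpl(b):
        ll = 0.0
        for s in np.unique(strata):
            m = strata == s
            t, e, z = time[m], event[m], x[m]
            for tt in np.unique(t[e == 1]):
                dead = (t == tt) & (e == 1)
                risk = t >= tt
                d = dead.sum()
                theta = np.exp(b * z)
                s_risk = theta[risk].sum()
                s_dead = theta[dead].sum()
                ll += b * z[dead].sum()
                for l in range(d):
                    ll -= np.log(s_risk - (l / d) * s_dead)
        return -ll

    res = minimize_scalar(negpl, bounds=bounds, method="bounded",
                          options={"xatol": 1e-12})
    return float(res.x)
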