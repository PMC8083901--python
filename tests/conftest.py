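import numpy as np
import pandas as pd
import pytest

import slmarker as sl


@pytest.fixture(scope="session")
def default_panel():
    return sl.load_panel()


@pytest.fixture(scope="session")
def small_panel(default_panel):
    """Four stains over four proteins — enough for one paired marker and
    cheap to simulate against."""
    wanted = ["CSNK1E(C)", "SHC1(N)", "CDH3(C)", "STK17A(N)"]
    by_id = {s.stain_id: s for s in default_panel}
    return [by_id[w] for w in wanted]


@pytest.fixture
def toy_matrix():
    """3 cancer + 2 control samples, 4 genes, constructed by hand."""
    values = pd.DataFrame(
        {
            "T1": [8.0, 1.0, 4.0, 2.0],
            "T2": [2.0, 4.0, 4.0, 2.0],
            "T3": [3.0, 0.5, 4.0, 2.0],
            "N1": [1.0, 1.5, 4.0, 2.0],
            "N2": [2.0, 1.5, 4.0, 2.0],
        },
        index=["gA", "gB", "gC", "gD"],
    )
    labels = sl.SampleLabels(
        pd.Series(
            ["cancer", "cancer", "cancer", "control", "control"],
            index=["T1", "T2", "T3", "N1", "N2"],
        )
    )
    return sl.ExpressionMatrix(values), labels


def make_survival_frame(rng, n=120, hr=1.0, prevalence=0.3, baseline=0.02, censor=0.008):
    """Exponential PH cohort with a single binary covariate — the independent
    generator used to check the Cox/log-rank machinery."""
    x = (rng.random(n) < prevalence).astype(int)
    t_event = rng.exponential(1.0 / (baseline * np.exp(np.log(hr) * x)))
    t_cens = rng.exponential(1.0 / censor, size=n) if censor > 0 else np.full(n, np.inf)
    return pd.DataFrame(
        {
            "time": np.maximum(np.minimum(t_event, t_cens), 1e-3),
            "event": (t_event <= t_cens).astype(int),
            "x": x,
        }
    )
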