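import numpy as np
import pandas as pd
import pytest

from sepsisgrs import SNPPanel, SNPRecord


@pytest.fixture
def two_snp_panel() -> SNPPanel:
    """The worked-example panel: (OR=2, f=0.5) and (OR=1.5, f=0.2)."""
    return SNPPanel(
        trait="MI",
        snps=(
            SNPRecord("rs1", "1", 100, "A", "G", 2.0, 0.5, 1e-9),
            SNPRecord("rs2", "2", 200, "T", "C", 1.5, 0.2, 1e-9),
        ),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_survival_instance(rng: np.random.Generator, n_max: int = 50) -> pd.DataFrame:
    """Small random survival dataset with ties, for oracle comparisons."""
    n = int(rng.integers(2, n_max + 1))
    times = rng.integers(1, 8, n).astype(float)  # coarse grid forces ties
    events = rng.random(n) < 0.7
    groups = rng.integers(0, 2, n)
    if events.sum() == 0:
        events[0] = True
    # ensure both groups occupied
    groups[0], groups[-1] = 0, 1
    return pd.DataFrame({"time": times, "event": events, "group": groups})


# ---------------------------------------------------------------------------
# independent oracles (deliberately naive implementations)


def km_brute_force(times, events) -> pd.DataFrame:
    """Product-limit by explicit per-subject risk-set enumeration."""
    df = pd.DataFrame({"t": np.asarray(times, float), "e": np.asarray(events, bool)})
    rows = []
    s = 1.0
    for t in sorted(df.loc[df.e, "t"].unique()):
        n_risk = sum(1 for x in df.itertuples() if x.t >= t)
        d = sum(1 for x in df.itertuples() if x.t == t and x.e)
        s *= (n_risk - d) / n_risk
        rows.append({"time": t, "n_at_risk": n_risk, "n_events": d, "survival": s})
    return pd.DataFrame(rows, columns=["time", "n_at_risk", "n_events", "survival"])


def logrank_brute_force(times, events, groups):
    """Two-group log-rank chi2 from first principles (hypergeometric var)."""
    t = np.asarray(times, float)
    e = np.asarray(events, bool)
    g = np.asarray(groups)
    labels = sorted(pd.unique(g).tolist())
    o = np.zeros(len(labels))
    exp = np.zeros(len(labels))
    var = 0.0  # variance of group-0 O-E
    for et in sorted(np.unique(t[e])):
        at = t >= et
        n = at.sum()
        d = (e & (t == et)).sum()
        for j, lab in enumerate(labels):
            nj = (at & (g == lab)).sum()
            dj = (e & (t == et) & (g == lab)).sum()
            o[j] += dj
            exp[j] += d * nj / n
        n0 = (at & (g == labels[0])).sum()
        if n > 1:
            var += d * (n0 / n) * (1 - n0 / n) * (n - d) / (n - 1)
    chi2 = (o[0] - exp[0]) ** 2 / var if var > 0 else 0.0
    return chi2


def cox_partial_loglik(beta: float, times, events, x) -> float:
    """Breslow partial log-likelihood for a single covariate, no ties assumed."""
    t = np.asarray(times, float)
    e = np.asarray(events, bool)
    x = np.asarray(x, float)
    ll = 0.0
    for i in np.flatnonzero(e):
        risk = t >= t[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return ll
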