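"""Independent brute-force reference implementations used only by the tests.

Each oracle recomputes a statistic from first principles (explicit loops over
risk sets, raw label frequencies) so the package's implementations can be
checked against a code path they share nothing with.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import chi2


def naive_kappa(a: np.ndarray, b: np.ndarray) -> float:
    """Cohen's kappa from raw paired binary labels."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    po = float(np.mean(a == b))
    pa, pb = float(np.mean(a)), float(np.mean(b))
    pe = pa * pb + (1 - pa) * (1 - pb)
    if pe == 1.0:
        return 1.0 if po == 1.0 else 0.0
    return (po - pe) / (1.0 - pe)


def naive_km(times, events):
    """Product-limit estimate by explicit risk-set bookkeeping.

    Returns (event_times, survival, n_at_risk) at the distinct event times.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    out_t, out_s, out_n = [], [], []
    s = 1.0
    for t in np.unique(times[events]):
        n_at_risk = int(np.sum(times >= t))
        d = int(np.sum((times == t) & events))
        s *= 1.0 - d / n_at_risk
        out_t.append(float(t))
        out_s.append(s)
        out_n.append(n_at_risk)
    return out_t, out_s, out_n


def naive_logrank(t1, e1, t2, e2):
    """Two-group log-rank statistic with the hypergeometric variance."""
    t1 = np.asarray(t1, dtype=float)
    e1 = np.asarray(e1, dtype=bool)
    t2 = np.asarray(t2, dtype=float)
    e2 = np.asarray(e2, dtype=bool)
    event_times = np.unique(np.concatenate([t1[e1], t2[e2]]))
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        n1 = int(np.sum(t1 >= t))
        n2 = int(np.sum(t2 >= t))
        n = n1 + n2
        d1 = int(np.sum((t1 == t) & e1))
        d = d1 + int(np.sum((t2 == t) & e2))
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    stat = o_minus_e**2 / var if var > 0 else 0.0
    return stat, float(chi2.sf(stat, 1))
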