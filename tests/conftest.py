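import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def double_well(x):
    """Asymmetric double-well free-energy profile, depth 10 kcal/mol
    between the deep well (x = 3) and the flat plateau beyond x ~ 10."""
    x = np.asarray(x, dtype=float)
    return -10.0 * np.exp(-((x - 3.0) ** 2) / 0.8) - 2.0 * np.exp(
        -((x - 8.0) ** 2) / 0.5
    )


@pytest.fixture(scope="session")
def packaged_table():
    from etpath import table_fixture

    return table_fixture()


# log kET and log vET of the nine packaged couples, keyed (donor, acceptor)
PRINTED_TABLE = {
    ("Tyr90", "Tyr189-O."): (11.4, 9.0),
    ("Tyr219", "Tyr189-O."): (8.4, 6.0),
    ("Cys85", "Tyr189-O."): (6.4, 2.6),
    ("Cys195", "Tyr189-O."): (7.8, 3.3),
    ("Cys222", "Tyr189-O."): (6.9, 3.1),
    ("Tyr189", "Tyr90-O."): (11.4, 9.8),
    ("Cys222", "Tyr90-O."): (5.2, 1.4),
    ("Tyr189", "Tyr219-O."): (8.4, 6.7),
    ("Cys222", "Tyr219-O."): (12.0, 8.2),
}


def marcus_grid_oracle(delta_g, lambda_r, lambda_p, lo=-6.0, hi=7.0, step=2e-4):
    """Independent brute-force activation energy: scan both parabolas for
    sign changes of their difference and refine each crossing by
    bisection; return the lowest crossing energy above the reactant
    minimum and its coordinate."""
    from scipy.optimize import brentq

    def diff(x):
        return lambda_r * x * x - (delta_g + lambda_p * (x - 1.0) ** 2)

    xs = np.arange(lo, hi, step)
    d = diff(xs)
    idx = np.nonzero(np.sign(d[:-1]) != np.sign(d[1:]))[0]
    roots = [brentq(diff, xs[i], xs[i + 1], xtol=1e-12) for i in idx]
    roots += [float(xs[i]) for i in np.nonzero(d == 0)[0]]
    assert roots, "oracle found no crossing in scan range"
    energies = [lambda_r * r * r for r in roots]
    k = int(np.argmin(energies))
    return energies[k], roots[k]


def random_intersecting_triples(rng, n, dg_range=(-20.0, 20.0), lam_range=(6.0, 40.0)):
    """Random (dG, lambda_r, lambda_p) triples whose Marcus parabolas
    genuinely intersect (a narrow reactant parabola nested inside a
    lifted wider one has no real crossing and is rejected)."""
    out = []
    while len(out) < n:
        dg = rng.uniform(*dg_range)
        lr = rng.uniform(*lam_range)
        lp = rng.uniform(*lam_range)
        disc = 4.0 * (lp * lp + (lr - lp) * (lp + dg))
        if disc > 1e-6:
            out.append((dg, lr, lp))
    return out


def brute_force_fractions(pkas, W, ph, temperature=300.0):
    """Exact non-reference (deprotonated) fractions of coupled proton
    sites by direct summation over all microstates; independent of the
    package's enumeration and sampling code."""
    import itertools
    import math

    kt = 0.0019872 * temperature
    n = len(pkas)
    Z = 0.0
    sums = np.zeros(n)
    for state in itertools.product((0, 1), repeat=n):
        e = sum(
            state[i] * math.log(10.0) * kt * (pkas[i] - ph) for i in range(n)
        )
        for i in range(n):
            for j in range(i + 1, n):
                e += state[i] * state[j] * W[i][j]
        w = math.exp(-e / kt)
        Z += w
        sums += w * np.array(state)
    return sums / Z
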