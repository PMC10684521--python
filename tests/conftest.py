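import numpy as np
import pytest

from valuectx.synth import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A compact synthetic study reused across modules (fit in seconds)."""
    cfg = SynthConfig(
        n_subjects=4,
        n_trials_per_subject=120,
        n_contacts_per_roi={"OFC-central": 40},
        frac_encoding_contacts=0.5,
        noise_sd=0.5,
        seed=2,
    )
    return generate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def tfce_oracle_1d(z, E=2.0, H=2.0, dh=None, n_levels=100):
    """Brute-force level summation with an explicit run scan.

    Independent of the package's implementation: thresholds are walked
    one by one and connected runs found by linear scanning.
    """
    z = np.asarray(z, dtype=float)
    out = np.zeros_like(z)
    top = np.abs(z).max()
    if top == 0:
        return out
    if dh is None:
        dh = top / n_levels
    n_lev = int(np.ceil(top / dh - 1e-12))
    for sign in (1.0, -1.0):
        a = np.maximum(sign * z, 0.0)
        for k in range(1, n_lev + 1):
            h = k * dh
            mask = a >= h
            i = 0
            while i < len(a):
                if mask[i]:
                    j = i
                    while j < len(a) and mask[j]:
                        j += 1
                    size = j - i
                    for m in range(i, j):
                        out[m] += sign * size**E * h**H * dh
                    i = j
                else:
                    i += 1
    return out


def tfce_oracle_2d(z, E=1.0, H=2.0, dh=None, n_levels=50):
    """2D brute-force oracle with BFS flood fill (4-connectivity)."""
    z = np.asarray(z, dtype=float)
    out = np.zeros_like(z)
    top = np.abs(z).max()
    if top == 0:
        return out
    if dh is None:
        dh = top / n_levels
    n_lev = int(np.ceil(top / dh - 1e-12))
    nr, nc = z.shape
    for sign in (1.0, -1.0):
        a = np.maximum(sign * z, 0.0)
        for k in range(1, n_lev + 1):
            h = k * dh
            mask = a >= h
            seen = np.zeros_like(mask)
            for r in range(nr):
                for c in range(nc):
                    if mask[r, c] and not seen[r, c]:
                        comp = [(r, c)]
                        seen[r, c] = True
                        queue = [(r, c)]
                        while queue:
                            rr, cc = queue.pop()
                            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                                r2, c2 = rr + dr, cc + dc
                                if (
                                    0 <= r2 < nr
                                    and 0 <= c2 < nc
                                    and mask[r2, c2]
                                    and not seen[r2, c2]
                                ):
                                    seen[r2, c2] = True
                                    comp.append((r2, c2))
                                    queue.append((r2, c2))
                        score = len(comp) ** E * h**H * dh
                        for rr, cc in comp:
                            out[rr, cc] += sign * score
    return out


def ols_oracle(X, y):
    """Normal-equations OLS: beta, se, t."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    resid = y - X @ beta
    dof = X.shape[0] - X.shape[1]
    sigma2 = resid @ resid / dof
    se = np.sqrt(np.diag(xtx_inv) * sigma2)
    return beta, se, beta / se
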