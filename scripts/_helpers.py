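"""Fixture builders and independent brute-force oracles for acceptance.py."""
import numpy as np

from memprep import ChainModel, ResidueRecord
from memprep.geometry import PHI_HELIX, PSI_HELIX, nerf_backbone


def helical_chain(n, sequence=None, plddt=90.0, start=1):
    bb = nerf_backbone([(PHI_HELIX, PSI_HELIX)] * n)
    seq = sequence or "A" * n
    if np.isscalar(plddt):
        plddt = [plddt] * n
    res = [
        ResidueRecord(start + i, seq[i], {k: bb[k][i] for k in bb}, plddt[i])
        for i in range(n)
    ]
    return ChainModel(res)


def detection_oracle(model, scale, window=21, score_threshold=-8.0,
                     min_helix_fraction=0.6, max_length=35):
    """Plain-loop enumeration of the TM detection rule."""
    res = model.residues
    n = len(res)
    dg = [scale[r.aa] for r in res]
    helix = [r.ss == "helix" for r in res]
    best = None
    for i in range(n - window + 1):
        score = sum(dg[i:i + window])
        frac = sum(helix[i:i + window]) / window
        if score <= score_threshold and frac >= min_helix_fraction:
            if best is None or score < best[0] - 1e-9:
                best = (score, i)
    if best is None:
        return None
    lo = best[1]
    hi = lo + window - 1
    while hi - lo + 1 < max_length:
        left = dg[lo - 1] if lo > 0 else np.inf
        right = dg[hi + 1] if hi + 1 < n else np.inf
        if left >= 0 and right >= 0:
            break
        if left <= right:
            lo -= 1
        else:
            hi += 1
    return res[lo].seq_index, res[hi].seq_index


def window_oracle(length, tm_start, tm_end, window_length, step):
    """Independent enumeration of the fragment-window tiling rule."""
    windows, start = [], 1
    while True:
        end = min(start + window_length - 1, length)
        windows.append((start, end))
        if end >= length:
            break
        start += step
    containing = [w for w in windows if w[0] <= tm_start and tm_end <= w[1]]
    if not containing:
        return None
    tm_c = (tm_start + tm_end) / 2
    return min(containing, key=lambda w: (abs((w[0] + w[1]) / 2 - tm_c), w[0]))


def quaternion_oracle_rmsd(P, Q, n_samples=4000, seed=0):
    """Brute-force best-fit RMSD: random quaternion starts + local simplex."""
    from scipy.optimize import minimize

    P = P - P.mean(axis=0)
    Q0 = Q - Q.mean(axis=0)
    rng = np.random.default_rng(seed)

    def rot(q):
        q = q / np.linalg.norm(q)
        w, x, y, z = q
        return np.array([
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ])

    def cost(q):
        return float(((P @ rot(q).T - Q0) ** 2).sum())

    qs = rng.normal(size=(n_samples, 4))
    costs = np.array([cost(q) for q in qs])
    best = np.inf
    for idx in np.argsort(costs)[:3]:
        res = minimize(cost, qs[idx], method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12,
                                "maxiter": 5000})
        best = min(best, res.fun)
    return float(np.sqrt(best / len(P)))
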