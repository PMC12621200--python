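"""Independent reference implementations used only as test oracles."""

import numpy as np


def quaternion_superpose_rmsd(mobile: np.ndarray, ref: np.ndarray) -> float:
    """Superposition-RMSD oracle via Horn's quaternion method.

    Builds the 4x4 key matrix from the cross-covariance of the centered
    point sets; the largest eigenvalue gives the optimal proper rotation's
    residual in closed form.
    """
    p = mobile - mobile.mean(axis=0)
    q = ref - ref.mean(axis=0)
    m = p.T @ q
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam = np.linalg.eigvalsh(k)[-1]
    e = max(0.0, (np.sum(p**2) + np.sum(q**2) - 2.0 * lam))
    return float(np.sqrt(e / mobile.shape[0]))
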