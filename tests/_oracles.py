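"""Independent oracle implementations used by multiple test modules.

These deliberately avoid the package's own code paths: exhaustive search for
the lobar assignment and a textbook dense-loop EM for the Gaussian mixture.
"""

import numpy as np

from wmh_bullseye.parcellation import LOBE_ORDER
from wmh_bullseye.phantom import LOBE_CODES


def brute_force_lobes(wm_mask, cortical_labels, voxel_size=(1, 1, 1)):
    """Exhaustive nearest-cortical-voxel search with fixed-order tie-break."""
    out = np.zeros(wm_mask.shape, dtype=np.int16)
    cortex = [(np.argwhere(cortical_labels == LOBE_CODES[n])
               * np.asarray(voxel_size), LOBE_CODES[n]) for n in LOBE_ORDER]
    for idx in np.argwhere(wm_mask):
        pos = idx * np.asarray(voxel_size)
        best = (np.inf, 0)
        for pts, code in cortex:
            if len(pts) == 0:
                continue
            d = np.min(((pts - pos) ** 2).sum(axis=1))
            if d < best[0] - 1e-12:   # strict: first in order wins ties
                best = (d, code)
        out[tuple(idx)] = best[1]
    return out


def direct_em_loglik(x, means, covs, weights, n_iter=0):
    """Textbook GMM log-likelihood (and optional plain EM steps)."""
    means = [np.asarray(m, float) for m in means]
    covs = [np.asarray(c, float) for c in covs]
    weights = list(weights)
    for _ in range(n_iter + 1):
        pdfs = []
        for m, c, w in zip(means, covs, weights):
            diff = x - m
            inv = np.linalg.inv(c)
            quad = np.einsum("ni,ij,nj->n", diff, inv, diff)
            pdfs.append(w * np.exp(-0.5 * quad)
                        / (2 * np.pi * np.sqrt(np.linalg.det(c))))
        total = np.sum(pdfs, axis=0)
        ll = float(np.log(total).sum())
        resp = np.stack(pdfs, axis=1) / total[:, None]
        nk = resp.sum(axis=0)
        means = [(resp[:, j] @ x) / nk[j] for j in range(len(means))]
        covs = [((x - means[j]) * resp[:, j, None]).T @ (x - means[j])
                / nk[j] for j in range(len(means))]
        weights = nk / x.shape[0]
    return ll
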