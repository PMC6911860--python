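"""Joint T1/T2 intensity modelling with an inlier/outlier Gaussian mixture.

Voxel intensities on the two contrasts are modelled as a bivariate Gaussian
mixture in which each expected tissue (CSF, GM, WM) contributes one or more
"inlier" components and additional unconstrained "outlier" components absorb
unexpected signal (lesions, artefacts).  Spatial tissue priors (atlas-style
probability maps) enter as fixed per-class spatial factors: component k of
class c has joint density w_k · A_c(v) · N(x_v; μ_k, Σ_k), with A fixed and
the global weights w learned.  Because A is fixed, the EM updates below are
exact EM for this objective, so the log-likelihood trace is monotone.

The number of components is chosen dynamically by exhaustive search over a
small grid of per-tissue and outlier counts, scored by a Bayesian information
criterion (log-likelihood minus ½·(free parameters)·log n; higher is better).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

TISSUE_CLASSES = ("csf", "gm", "wm")
OUTLIER = "outlier"


class DegenerateInputError(ValueError):
    """Raised when the input intensities carry no usable variation."""


@dataclass
class GaussianComponent:
    mean: np.ndarray          # (2,) T1, T2
    covariance: np.ndarray    # (2, 2) symmetric positive-definite
    weight: float
    klass: str                # "csf" | "gm" | "wm" | "outlier"

    def to_dict(self):
        return {"mean": self.mean.tolist(),
                "covariance": self.covariance.tolist(),
                "weight": float(self.weight), "klass": self.klass}


@dataclass(frozen=True)
class MixtureConfig:
    k_tissue_range: tuple[int, ...] = (1, 2)
    k_outlier_range: tuple[int, ...] = (1, 2, 3)
    fixed_k: tuple[int, int] | None = None   # (k_tissue, k_outlier)
    max_iter: int = 200
    tol: float = 1e-5
    outlier_atlas_level: float = 1.0
    init_subsample: float = 0.1
    reg_scale: float = 1e-6
    seed: int = 0


@dataclass
class MixtureModel:
    components: list[GaussianComponent]
    log_likelihood: float = np.nan
    criterion_score: float = np.nan
    n_voxels: int = 0
    converged: bool = False
    ll_trace: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def fitted(self) -> bool:
        return np.isfinite(self.log_likelihood)

    def class_components(self, klass: str) -> list[GaussianComponent]:
        return [c for c in self.components if c.klass == klass]

    def class_weight(self, klass: str) -> float:
        return float(sum(c.weight for c in self.class_components(klass)))

    def class_stats(self, klass: str):
        """Moment-pooled mean and SD vector of a class's components."""
        comps = self.class_components(klass)
        if not comps:
            raise ValueError(f"model has no {klass!r} component")
        w = np.array([c.weight for c in comps])
        w = w / w.sum()
        mean = sum(wi * c.mean for wi, c in zip(w, comps))
        second = sum(wi * (c.covariance + np.outer(c.mean, c.mean))
                     for wi, c in zip(w, comps))
        cov = second - np.outer(mean, mean)
        return mean, np.sqrt(np.clip(np.diag(cov), 1e-12, None))

    def to_json(self) -> str:
        return json.dumps({
            "components": [c.to_dict() for c in self.components],
            "log_likelihood": float(self.log_likelihood),
            "criterion_score": float(self.criterion_score),
            "n_voxels": int(self.n_voxels),
            "converged": bool(self.converged)}, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "MixtureModel":
        d = json.loads(text)
        comps = [GaussianComponent(np.array(c["mean"]),
                                   np.array(c["covariance"]),
                                   c["weight"], c["klass"])
                 for c in d["components"]]
        return cls(comps, d["log_likelihood"], d["criterion_score"],
                   d["n_voxels"], d["converged"])


@dataclass
class ResponsibilityMap:
    """Per-voxel component posteriors, tied back to the volume grid."""

    resp: np.ndarray            # (n_voxels, n_components)
    mask: np.ndarray            # boolean volume
    klasses: list[str]
    data: np.ndarray            # (n_voxels, 2) the intensities that were fit

    def class_posterior(self, klass: str) -> np.ndarray:
        """Posterior probability volume of one class (0 outside the mask)."""
        valid = set(self.klasses) | {OUTLIER}
        if klass not in valid:
            raise ValueError(f"unknown class {klass!r}")
        cols = [j for j, k in enumerate(self.klasses) if k == klass]
        vol = np.zeros(self.mask.shape)
        vol[self.mask] = self.resp[:, cols].sum(axis=1) if cols else 0.0
        return vol

    def hard_tissue_labels(self, codes: dict[str, int]) -> np.ndarray:
        """Argmax tissue label over inlier classes, outliers excluded."""
        names = [k for k in codes if k != OUTLIER]
        stack = np.stack([self.resp[:, [j for j, kk in enumerate(self.klasses)
                                        if kk == k]].sum(axis=1)
                          for k in names])
        lab = np.zeros(self.mask.shape, dtype=np.int16)
        lab[self.mask] = np.array([codes[names[i]]
                                   for i in stack.argmax(axis=0)])
        return lab


def _log_gauss(x, mean, cov, reg):
    cov = cov + reg * np.eye(2)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        cov = cov + 1e3 * reg * np.eye(2) + 1e-10 * np.eye(2)
        chol = np.linalg.cholesky(cov)
    d = np.linalg.solve(chol, (x - mean).T)
    maha = (d ** 2).sum(axis=0)
    logdet = 2 * np.log(np.diag(chol)).sum()
    return -0.5 * (maha + logdet + 2 * np.log(2 * np.pi))


def n_free_parameters(n_components: int) -> int:
    """2 mean + 3 covariance entries per component, plus K−1 free weights."""
    return n_components * 5 + (n_components - 1)


def model_criterion(model: MixtureModel, n_voxels: int) -> float:
    """Penalized fit score (BIC form): LL − ½·p·log n.  Higher is better."""
    if not model.fitted:
        raise ValueError("model_criterion requires a fitted model")
    if n_voxels <= 0:
        raise ValueError("n_voxels must be positive")
    p = n_free_parameters(len(model.components))
    return float(model.log_likelihood - 0.5 * p * np.log(n_voxels))


def _prepare_inputs(t1, t2, tissue_priors, mask):
    t1 = np.asarray(t1, float)
    t2 = np.asarray(t2, float)
    if t1.shape != t2.shape:
        raise ValueError("t1 and t2 grids differ")
    if mask is None:
        mask = np.ones(t1.shape, dtype=bool)
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("brain mask is empty")
    x = np.stack([t1[mask], t2[mask]], axis=1)
    if tissue_priors is None:
        atlas = {"wm": np.ones(x.shape[0])}
    else:
        atlas = {k: np.asarray(v, float)[mask] for k, v in
                 tissue_priors.items()}
        total = sum(atlas.values())
        floor = 1e-3
        atlas = {k: (v + floor) / (total + floor * len(atlas))
                 for k, v in atlas.items()}
    return x, mask, atlas


def _init_components(x, atlas, k_tissue, k_outlier, config, rng):
    n = x.shape[0]
    sub = rng.choice(n, size=max(min(n, 500),
                                 int(config.init_subsample * n)),
                     replace=False) if n > 500 else np.arange(n)
    comps = []
    names = list(atlas)
    hard = np.stack([atlas[k] for k in names]).argmax(axis=0)
    for ci, name in enumerate(names):
        xv = x[sub][hard[sub] == ci]
        if xv.shape[0] < 2 * k_tissue:
            xv = x[sub]
        km = KMeans(n_clusters=k_tissue, n_init=3,
                    random_state=config.seed).fit(xv)
        for j in range(k_tissue):
            sel = xv[km.labels_ == j]
            cov = np.cov(sel.T) if sel.shape[0] > 2 else np.cov(xv.T)
            comps.append(GaussianComponent(
                km.cluster_centers_[j].copy(), np.atleast_2d(cov),
                0.9 / (len(names) * k_tissue), name))
    # outliers: seed from the high-T2 tail with inflated covariance
    t2v = x[sub][:, 1]
    tail = x[sub][t2v >= np.quantile(t2v, 0.95)]
    if tail.shape[0] < k_outlier:
        tail = x[sub]
    km = KMeans(n_clusters=k_outlier, n_init=3,
                random_state=config.seed + 1).fit(tail)
    gcov = np.cov(x[sub].T) * 4 + 1e-6 * np.eye(2)
    for j in range(k_outlier):
        comps.append(GaussianComponent(km.cluster_centers_[j].copy(),
                                       gcov.copy(), 0.1 / k_outlier, OUTLIER))
    return comps


def _em(x, atlas, comps, config, reg, tether=None, tether_tau=0.0):
    """Exact EM (optionally MAP-tethered to a reference model).

    ``tether`` is a list of reference components aligned with ``comps``;
    ``tether_tau`` is the pseudo-count weight of the reference statistics in
    each M-step (0 disables tethering).
    """
    n, k = x.shape[0], len(comps)
    log_a = np.zeros((n, k))
    for j, c in enumerate(comps):
        a = atlas.get(c.klass)
        if a is None:  # outlier class: flat spatial factor
            log_a[:, j] = np.log(config.outlier_atlas_level)
        else:
            log_a[:, j] = np.log(np.clip(a, 1e-12, None))
    ll_trace = []
    prev = -np.inf
    converged = False
    for _it in range(config.max_iter):
        logp = np.empty((n, k))
        for j, c in enumerate(comps):
            logp[:, j] = (np.log(max(c.weight, 1e-300)) + log_a[:, j]
                          + _log_gauss(x, c.mean, c.covariance, reg))
        m = logp.max(axis=1, keepdims=True)
        norm = m[:, 0] + np.log(np.exp(logp - m).sum(axis=1))
        ll = float(norm.sum())
        resp = np.exp(logp - norm[:, None])
        ll_trace.append(ll)
        if np.abs(ll - prev) <= config.tol * np.abs(ll):
            converged = True
            break
        prev = ll
        nk = resp.sum(axis=0)
        for j, c in enumerate(comps):
            tau = tether_tau if tether is not None else 0.0
            ref = tether[j] if tether is not None else None
            denom = nk[j] + tau
            mu = (resp[:, j] @ x + (tau * ref.mean if ref is not None
                                    else 0.0)) / max(denom, 1e-12)
            diff = x - mu
            cov = (diff * resp[:, j, None]).T @ diff
            if ref is not None:
                dm = ref.mean - mu
                cov = cov + tau * (ref.covariance + np.outer(dm, dm))
            cov = cov / max(denom, 1e-12)
            w = denom / (n + (tau * k if tether is not None else 0.0))
            comps[j] = GaussianComponent(mu, cov, w, c.klass)
    weights = np.array([c.weight for c in comps])
    for j, c in enumerate(comps):
        comps[j] = GaussianComponent(c.mean, c.covariance,
                                     c.weight / weights.sum(), c.klass)
    return comps, resp, float(ll_trace[-1]), np.array(ll_trace), converged


def _fit_single(x, atlas, k_tissue, k_outlier, config, tether_model=None,
                tether_strength=0.0):
    rng = np.random.default_rng(config.seed)
    reg = config.reg_scale * float(np.mean(np.var(x, axis=0)))
    if tether_model is not None:
        comps = [GaussianComponent(c.mean.copy(), c.covariance.copy(),
                                   c.weight, c.klass)
                 for c in tether_model.components]
        tau = tether_strength * x.shape[0] / max(len(comps), 1)
        comps, resp, ll, trace, conv = _em(x, atlas, comps, config, reg,
                                           tether=tether_model.components,
                                           tether_tau=tau)
    else:
        comps = _init_components(x, atlas, k_tissue, k_outlier, config, rng)
        comps, resp, ll, trace, conv = _em(x, atlas, comps, config, reg)
    model = MixtureModel(comps, log_likelihood=ll, n_voxels=x.shape[0],
                         converged=conv, ll_trace=trace)
    model.criterion_score = model_criterion(model, x.shape[0])
    return model, resp


def fit_mixture(t1, t2, tissue_priors=None, mask=None,
                config: MixtureConfig | None = None, tether_model=None,
                tether_strength: float = 0.0):
    """Fit the inlier/outlier mixture, selecting the component counts.

    Candidate configurations (per-tissue count × outlier count, or the single
    ``config.fixed_k`` pair) are each fit by EM from a seeded k-means
    initialization; the model with the highest penalized-likelihood criterion
    is returned together with its :class:`ResponsibilityMap`.

    When ``tether_model`` is given (longitudinal constraint), the component
    structure is frozen to that model's and the EM is MAP-tethered to its
    parameters with pseudo-count ``tether_strength · n/K``.
    """
    config = config or MixtureConfig()
    x, mask, atlas = _prepare_inputs(t1, t2, tissue_priors, mask)
    if float(np.var(x)) == 0.0:
        raise DegenerateInputError("constant image: intensity model "
                                   "is degenerate")
    if tether_model is not None:
        model, resp = _fit_single(x, atlas, 0, 0, config,
                                  tether_model=tether_model,
                                  tether_strength=tether_strength)
        klasses = [c.klass for c in model.components]
        return model, ResponsibilityMap(resp, mask, klasses, x)

    if config.fixed_k is not None:
        grid = [config.fixed_k]
    else:
        grid = [(kt, ko) for kt in config.k_tissue_range
                for ko in config.k_outlier_range]
    best = None
    for kt, ko in grid:
        model, resp = _fit_single(x, atlas, kt, ko, config)
        if best is None or model.criterion_score > best[0].criterion_score:
            best = (model, resp)
    model, resp = best
    klasses = [c.klass for c in model.components]
    return model, ResponsibilityMap(resp, mask, klasses, x)


def class_posterior(resp: ResponsibilityMap, klass: str) -> np.ndarray:
    """Posterior probability volume of one class (inlier tissue or outlier)."""
    return resp.class_posterior(klass)
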