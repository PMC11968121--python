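"""Structural path-model specifications and model-implied twin-pair moments.

A :class:`PathModel` decomposes a phenotype measured at ``T`` occasions into
additive-genetic (A), shared-environmental (C) and non-shared environmental (E)
latent processes, plus an occasion-specific residual.  Each latent kind is a sum
of *components* (simplex/autoregression chains, factor structures, free latent
covariances, diagonal residual inputs, dual-change processes).  Every matrix
cell is either a fixed constant or a free-parameter *label*; cells sharing a
label are constrained equal, which is how the classical twin design's equality
constraints and the model zoo's identification constraints are expressed.

The classical twin design enters through fixed cross-twin correlations: the
additive-genetic correlation is 1.0 for monozygotic (MZ) and 0.5 for dizygotic
(DZ) pairs, the shared-environment correlation is 1.0 for both, and the
non-shared environment is uncorrelated across twins.  These are structural
constants, never free parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Union

import numpy as np
import yaml

Cell = Union[float, str]

#: cross-twin correlation of each latent kind, by zygosity (row 0 = MZ, 1 = DZ)
KIND_CROSS_CORR = {"A": (1.0, 0.5), "C": (1.0, 1.0), "E": (0.0, 0.0)}
KINDS = ("A", "C", "E")
ZYGOSITIES = ("MZ", "DZ")


def _val(cell: Cell, vals: Mapping[str, float]) -> float:
    return vals[cell] if isinstance(cell, str) else float(cell)


def _cells_of(obj) -> list[str]:
    """Free-parameter labels in a nested cell structure, in encounter order."""
    out: list[str] = []
    stack = [obj]
    while stack:
        x = stack.pop(0)
        if isinstance(x, str):
            out.append(x)
        elif isinstance(x, (list, tuple)):
            stack = list(x) + stack
    return out


def _resolve(cells, vals: Mapping[str, float]) -> np.ndarray:
    if isinstance(cells, (str, float, int)):
        return np.float64(_val(cells, vals))
    return np.array([_resolve(c, vals) for c in cells])


def _fast_resolve(obj, attr: str, vals: Mapping[str, float]) -> np.ndarray:
    """Resolve a cell structure through a per-object compiled template.

    Builders create cell structures once and never mutate them afterwards, so
    the (template, free-position, label) triple is cached on the owner; each
    call is then a copy plus a fancy-indexed fill, which keeps the moment
    assembly cheap inside optimizer loops.
    """
    cache = getattr(obj, "_ccache", None)
    if cache is None:
        cache = obj._ccache = {}
    ent = cache.get(attr)
    if ent is None:
        a = np.array(getattr(obj, attr), dtype=object)
        flat = a.ravel()
        template = np.array([0.0 if isinstance(v, str) else float(v)
                             for v in flat], float).reshape(a.shape)
        pos = np.array([i for i, v in enumerate(flat) if isinstance(v, str)], int)
        labs = [flat[i] for i in pos]
        ent = cache[attr] = (template, pos, labs)
    template, pos, labs = ent
    out = template.copy()
    if len(pos):
        out.ravel()[pos] = [vals[l] for l in labs]
    return out


def _cross_pair(rng: np.random.Generator, n: int, m: int, r: float):
    """Two (n, m) standard-normal blocks with elementwise correlation r."""
    z1 = rng.standard_normal((n, m))
    if r == 1.0:
        return z1, z1.copy()
    z2 = r * z1 + np.sqrt(1.0 - r * r) * rng.standard_normal((n, m))
    return z1, z2


class SpecificationError(ValueError):
    """A path-model block is structurally invalid (e.g. singular I - B)."""


def _psd_factor(P: np.ndarray, what: str) -> np.ndarray:
    """Square root of a positive *semi*-definite matrix for simulation.

    Dropped components legitimately carry all-zero (or rank-deficient)
    covariances; only genuinely indefinite matrices are an error.
    """
    try:
        return np.linalg.cholesky(P)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh((P + P.T) / 2.0)
        if w.min() < -1e-10 * max(1.0, float(np.abs(w).max())):
            raise SpecificationError(
                f"{what} must be positive semi-definite to simulate")
        return V * np.sqrt(np.clip(w, 0.0, None))


# ---------------------------------------------------------------------------
# components
# ---------------------------------------------------------------------------


@dataclass
class Simplex:
    """First-order autoregressive latent chain.

    ``x_t = b_{t-1} x_{t-1} + i_t z_t`` with standard-normal innovations
    ``z_t`` (innovation variances fixed to 1; the scale is carried by the
    innovation path coefficients ``i_t``).  Loadings latent -> observed are
    fixed to 1.  Pruned occasions carry constant-zero innovation and
    transmission cells.
    """

    innovations: list   # T cells, innovation path coefficients
    transmissions: list  # T-1 cells, first-order coefficients (usually one shared label)

    def cells(self):
        return _cells_of([self.innovations, self.transmissions])

    def _matrices(self, vals, T):
        i = _fast_resolve(self, "innovations", vals)
        b = _fast_resolve(self, "transmissions", vals)
        B = np.zeros((T, T))
        B[np.arange(1, T), np.arange(T - 1)] = b
        return i, B

    def cov(self, vals, T):
        i, B = self._matrices(vals, T)
        M = np.eye(T) - B
        try:
            Minv = np.linalg.inv(M)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - strictly lower B
            raise SpecificationError("singular (I - B) in simplex block") from exc
        return Minv @ np.diag(i**2) @ Minv.T

    def draw(self, vals, rng, n, T, r):
        i, B = self._matrices(vals, T)
        b = B[np.arange(1, T), np.arange(T - 1)]
        z1, z2 = _cross_pair(rng, n, T, r)
        y1 = np.empty((n, T))
        y2 = np.empty((n, T))
        y1[:, 0] = i[0] * z1[:, 0]
        y2[:, 0] = i[0] * z2[:, 0]
        for t in range(1, T):
            y1[:, t] = b[t - 1] * y1[:, t - 1] + i[t] * z1[:, t]
            y2[:, t] = b[t - 1] * y2[:, t - 1] + i[t] * z2[:, t]
        return y1, y2


@dataclass
class FreeCov:
    """Latent covariance parameterized directly on the (co)variance scale.

    Used by the correlated-factors reference model (identity loadings, full
    symmetric T x T), the univariate ACE decomposition (1 x 1, where the shared
    C variance may go negative, its sign indicating whether shared environment
    or genetic non-additivity predominates), and the latent-growth model
    (fixed growth design loadings, free factor covariance).
    """

    cov_cells: list          # (m, m) symmetric cells
    loadings: np.ndarray | None = None  # fixed (T, m) design; identity if None

    def cells(self):
        m = len(self.cov_cells)
        tri = [self.cov_cells[i][j] for i in range(m) for j in range(i + 1)]
        return _cells_of(tri)

    def _design(self, T):
        if self.loadings is None:
            return np.eye(T)
        return np.asarray(self.loadings, float)

    def phi(self, vals):
        P = _fast_resolve(self, "cov_cells", vals)
        return (P + P.T) / 2.0

    def cov(self, vals, T):
        L = self._design(T)
        return L @ self.phi(vals) @ L.T

    def draw(self, vals, rng, n, T, r):
        C = _psd_factor(self.phi(vals), "latent covariance")
        z1, z2 = _cross_pair(rng, n, C.shape[0], r)
        L = self._design(T)
        return z1 @ C.T @ L.T, z2 @ C.T @ L.T


@dataclass
class Factor:
    """Orthogonal common factor(s) with path-coefficient scales.

    ``cov = Lam diag(scale^2) Lam'``; used by the common-pathway model (free
    loadings with the first fixed to 1 per factor, factor A/C/E path scales)
    and the independent-pathway model (one factor per kind, scale fixed to 1).
    """

    loadings: list   # (T, k) cells
    scales: list     # k cells

    def cells(self):
        return _cells_of([self.loadings, self.scales])

    def _lam(self, vals):
        return _fast_resolve(self, "loadings", vals)

    def cov(self, vals, T):
        lam = self._lam(vals)
        s = _fast_resolve(self, "scales", vals)
        return (lam * s**2) @ lam.T

    def draw(self, vals, rng, n, T, r):
        lam = self._lam(vals)
        s = _fast_resolve(self, "scales", vals)
        z1, z2 = _cross_pair(rng, n, lam.shape[1], r)
        return (z1 * s) @ lam.T, (z2 * s) @ lam.T


@dataclass
class Diag:
    """Occasion-specific latent input: contributes diag(path_t^2)."""

    paths: list  # T cells

    def cells(self):
        return _cells_of(self.paths)

    def cov(self, vals, T):
        d = _fast_resolve(self, "paths", vals)
        return np.diag(d**2)

    def draw(self, vals, rng, n, T, r):
        d = _fast_resolve(self, "paths", vals)
        z1, z2 = _cross_pair(rng, n, T, r)
        return z1 * d, z2 * d


@dataclass
class DualChange:
    """Latent difference process: eta_t = (1 + beta) eta_{t-1} + s.

    Level (eta_0) and constant-change (s) factors carry a free 2 x 2
    covariance per kind; the proportional coefficient beta folds prior level
    into the change score.  beta = 0 reduces exactly to a linear growth model
    with loadings (1, t).
    """

    phi_cells: list  # 2x2 symmetric cells for (level, slope)
    beta: Cell

    def cells(self):
        tri = [self.phi_cells[i][j] for i in range(2) for j in range(i + 1)]
        return _cells_of(tri + [self.beta])

    def design(self, vals, T):
        b = 1.0 + _val(self.beta, vals)
        L = np.empty((T, 2))
        L[:, 0] = b ** np.arange(T)
        L[0, 1] = 0.0
        for t in range(1, T):
            L[t, 1] = b * L[t - 1, 1] + 1.0
        return L

    def phi(self, vals):
        P = _fast_resolve(self, "phi_cells", vals)
        return (P + P.T) / 2.0

    def cov(self, vals, T):
        L = self.design(vals, T)
        return L @ self.phi(vals) @ L.T

    def draw(self, vals, rng, n, T, r):
        C = _psd_factor(self.phi(vals), "dual-change factor covariance")
        z1, z2 = _cross_pair(rng, n, 2, r)
        L = self.design(vals, T)
        return z1 @ C.T @ L.T, z2 @ C.T @ L.T


COMPONENT_TYPES = {
    "simplex": Simplex,
    "free_cov": FreeCov,
    "factor": Factor,
    "diag": Diag,
    "dual_change": DualChange,
}


# ---------------------------------------------------------------------------
# mean structure
# ---------------------------------------------------------------------------


@dataclass
class MeanSpec:
    """Mean vector mu = design @ coefs (occasion means when design = I)."""

    design: np.ndarray  # (T, q) fixed
    coefs: list         # q cells

    def cells(self):
        return _cells_of(self.coefs)

    def mean(self, vals):
        return np.asarray(self.design, float) @ _fast_resolve(self, "coefs", vals)

    @classmethod
    def occasion(cls, T, prefix="mu"):
        return cls(np.eye(T), [f"{prefix}_{t + 1}" for t in range(T)])


@dataclass
class ModelMoments:
    """Model-implied mean and covariance of one twin pair's stacked vector."""

    mean: np.ndarray   # (2T,)
    cov: np.ndarray    # (2T, 2T)


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------


class MomentModel:
    """Protocol base: anything the FIML engine can fit.

    Subclasses provide ``labels``, ``start`` and ``implied(theta)`` returning
    ``(mu, Sigma, beta_sex)`` with ``mu`` of shape (2, 2T) (MZ row, DZ row) and
    ``Sigma`` of shape (2, 2T, 2T).
    """

    name: str = "model"
    T: int = 1

    @property
    def labels(self) -> list[str]:  # pragma: no cover - abstract
        raise NotImplementedError

    @property
    def start(self) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def implied(self, theta):  # pragma: no cover - abstract
        raise NotImplementedError

    @property
    def n_free(self) -> int:
        return len(self.labels)

    #: optional box constraints per label (e.g. |transmission| < 1 so latent
    #: variance approaches a stable asymptote instead of exploding)
    @property
    def bounds(self) -> dict:
        return getattr(self, "_bounds", {})

    def values_from(self, theta) -> dict[str, float]:
        return dict(zip(self.labels, np.asarray(theta, float)))

    def theta_from(self, values: Mapping[str, float]) -> np.ndarray:
        return np.array([values[l] for l in self.labels], float)

    def fixing(self, fixed: Mapping[str, float]) -> "FixedView":
        return FixedView(self, dict(fixed))

    def pair_moments(self, theta, zygosity: str, sex_1: float, sex_2: float) -> ModelMoments:
        """Moments for one pair, sex covariate folded into the means."""
        mu, Sigma, beta = self.implied(theta)
        z = ZYGOSITIES.index(zygosity)
        T = self.T
        m = mu[z].copy()
        m[:T] += beta * sex_1
        m[T:] += beta * sex_2
        return ModelMoments(m, Sigma[z])


class FixedView(MomentModel):
    """A model with a subset of its labels bound to constants.

    Powers nested submodels (fix a variance to zero), innovation pruning and
    profile-likelihood confidence intervals.
    """

    def __init__(self, base: MomentModel, fixed: dict[str, float]):
        unknown = set(fixed) - set(base.labels)
        if unknown:
            raise KeyError(f"labels not in model: {sorted(unknown)}")
        self.base = base
        self.fixed = dict(fixed)
        self.T = base.T
        self.name = base.name
        free = [l for l in base.labels if l not in fixed]
        self._labels = free
        self._slots = [base.labels.index(l) for l in free]
        self._full = np.zeros(len(base.labels))
        for l, v in fixed.items():
            self._full[base.labels.index(l)] = v

    @property
    def labels(self):
        return self._labels

    @property
    def start(self):
        return np.asarray(self.base.start, float)[self._slots]

    def expand(self, theta):
        full = self._full.copy()
        full[self._slots] = theta
        return full

    def implied(self, theta):
        return self.base.implied(self.expand(theta))

    def fixing(self, fixed):
        merged = dict(self.fixed)
        merged.update(fixed)
        return FixedView(self.base, merged)

    @property
    def bounds(self):
        return {l: b for l, b in self.base.bounds.items() if l in self._labels}


class PathModel(MomentModel):
    """Biometric path model: A/C/E component lists + residual + mean structure.

    Parameters
    ----------
    T : number of occasions.
    components : mapping kind -> list of components (Simplex, FreeCov, Factor,
        Diag, DualChange).
    residual : T cells of residual path coefficients (transient, non-shared
        influences including measurement error; cross-twin covariance zero).
        A single shared label equates them across occasions.
    mean : MeanSpec for the phenotypic means.
    beta_sex : cell for the sex regression on the means (definition variable).
    start : starting value per free label (missing labels default to 0.1).
    """

    def __init__(self, T, components, residual, mean, beta_sex="beta_sex",
                 start=None, name="path_model", bounds=None):
        self.T = int(T)
        self.components = {k: list(components.get(k, ())) for k in KINDS}
        self.residual = list(residual)
        self.mean = mean
        self.beta_sex = beta_sex
        self.name = name
        self._start = dict(start or {})
        self._bounds = dict(bounds or {})
        self._labels = self._collect_labels()

    def _collect_labels(self):
        seen: dict[str, None] = {}
        for k in KINDS:
            for comp in self.components[k]:
                for l in comp.cells():
                    seen.setdefault(l)
        for l in _cells_of(self.residual):
            seen.setdefault(l)
        for l in self.mean.cells():
            seen.setdefault(l)
        for l in _cells_of([self.beta_sex]):
            seen.setdefault(l)
        return list(seen)

    @property
    def labels(self):
        return self._labels

    @property
    def start(self):
        return np.array([self._start.get(l, 0.1) for l in self._labels])

    def set_start(self, values: Mapping[str, float]):
        self._start.update(values)
        return self

    # -- moments ------------------------------------------------------------

    def kind_cov(self, kind: str, vals: Mapping[str, float]) -> np.ndarray:
        """Within-twin observed-scale covariance contributed by one kind."""
        S = np.zeros((self.T, self.T))
        for comp in self.components[kind]:
            S += comp.cov(vals, self.T)
        return S

    def residual_var(self, vals) -> np.ndarray:
        d = _fast_resolve(self, "residual", vals)
        return d**2

    def implied(self, theta):
        vals = self.values_from(theta)
        T = self.T
        within = np.zeros((T, T))
        cross = np.zeros((2, T, T))
        for k in KINDS:
            Sk = self.kind_cov(k, vals)
            within += Sk
            r_mz, r_dz = KIND_CROSS_CORR[k]
            cross[0] += r_mz * Sk
            cross[1] += r_dz * Sk
        within = within + np.diag(self.residual_var(vals))
        Sigma = np.empty((2, 2 * T, 2 * T))
        for z in range(2):
            Sigma[z, :T, :T] = within
            Sigma[z, T:, T:] = within
            Sigma[z, :T, T:] = cross[z]
            Sigma[z, T:, :T] = cross[z].T
        m = self.mean.mean(vals)
        mu = np.tile(np.concatenate([m, m]), (2, 1))
        return mu, Sigma, _val(self.beta_sex, vals)

    def standardized_components(self, theta):
        """Per-occasion A/C/E/residual variance shares and longitudinal
        correlation matrices of the A and E processes.

        Shares are signed when the negative-C convention puts a component
        below zero; they still sum to one, and the result carries a flag.
        """
        vals = self.values_from(theta)
        covs = {k: self.kind_cov(k, vals) for k in KINDS}
        res = self.residual_var(vals)
        total = sum(np.diag(covs[k]) for k in KINDS) + res
        if np.any(total <= 0):
            raise SpecificationError("total implied variance must be positive")
        shares = {k: np.diag(covs[k]) / total for k in KINDS}
        shares["residual"] = res / total
        corr = {}
        for k in ("A", "E"):
            d = np.sqrt(np.clip(np.diag(covs[k]), 0, None))
            with np.errstate(divide="ignore", invalid="ignore"):
                R = covs[k] / np.outer(d, d)
            corr[f"r{k}"] = np.where(np.outer(d, d) > 0, R, np.nan)
        return {
            "shares": shares,
            "correlations": corr,
            "negative_component": bool(any(np.any(s < 0) for s in shares.values())),
        }

    # -- serialization --------------------------------------------------------

    def to_dict(self) -> dict:
        def enc_cells(x):
            if isinstance(x, np.ndarray):
                return x.tolist()
            if isinstance(x, (list, tuple)):
                return [enc_cells(v) for v in x]
            return x

        def enc_comp(c):
            d = {"type": {v: k for k, v in COMPONENT_TYPES.items()}[type(c)]}
            for f in c.__dataclass_fields__:
                d[f] = enc_cells(getattr(c, f))
            return d

        return {
            "name": self.name,
            "T": self.T,
            "components": {k: [enc_comp(c) for c in self.components[k]] for k in KINDS},
            "residual": enc_cells(self.residual),
            "mean": {"design": enc_cells(np.asarray(self.mean.design)),
                     "coefs": enc_cells(self.mean.coefs)},
            "beta_sex": self.beta_sex,
            "start": {l: float(v) for l, v in self._start.items()},
            "bounds": {l: list(map(float, b)) for l, b in self._bounds.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PathModel":
        def dec_comp(cd):
            cd = dict(cd)
            typ = COMPONENT_TYPES[cd.pop("type")]
            if typ is FreeCov and cd.get("loadings") is not None:
                cd["loadings"] = np.asarray(cd["loadings"], float)
            return typ(**cd)

        mean = MeanSpec(np.asarray(d["mean"]["design"], float), d["mean"]["coefs"])
        return cls(
            d["T"],
            {k: [dec_comp(c) for c in d["components"].get(k, ())] for k in KINDS},
            d["residual"],
            mean,
            beta_sex=d.get("beta_sex", 0.0),
            start=d.get("start"),
            name=d.get("name", "path_model"),
            bounds={l: tuple(b) for l, b in d.get("bounds", {}).items()},
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "PathModel":
        return cls.from_dict(yaml.safe_load(text))


def implied_latent_cov(kind_components, T, values) -> np.ndarray:
    """Observed-scale covariance implied by a list of latent components.

    Thin functional wrapper over the component algebra, convenient for
    checking a single kind's block (e.g. a pure genetic simplex) against a
    Monte-Carlo oracle.
    """
    S = np.zeros((T, T))
    for comp in kind_components:
        S += comp.cov(values, T)
    return S
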