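"""Presence-background species distribution models.

The model contrasts the environment at presence locations with a background
sample of the study extent.  It is the standard exponential (Gibbs) model:
the relative occurrence rate is proportional to exp(f(x)) with f a linear
combination of feature transforms of the covariates — linear (L), quadratic
(Q) and hinge (H) classes, combined as LQH / LQ / QH / L / Q / H.  Fitting
maximizes the presence-background log-likelihood with a per-feature L1
penalty lambda_j = rm * base(class) * sd_j / sqrt(n_presence), where the
regularization multiplier rm is the single smoothness dial (grid 0.5-5.0).
The objective is convex; the L1 term is handled exactly by splitting each
coefficient into positive and negative parts and bound-constrained L-BFGS.

Suitability output uses the cloglog transform 1 - exp(-exp(eta + H)) with
eta the linear predictor normalized over the background and H the entropy
of the normalized background distribution (a logistic variant is available).

Candidate settings are scored by geographically structured cross-validation
(2x2 median blocks with background masking for species with >= 20 points,
leave-one-out jackknife otherwise) on three averaged metrics: the omission
rate of test presences under the minimum-training-presence threshold
(OR_MTP), the train-test AUC difference (AUC_DIFF, overfitting), and test
AUC (discrimination).  Selection filters AUC_TEST > 0.6 and then minimizes
OR_MTP, breaks ties by minimal AUC_DIFF, then maximal AUC_TEST.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import rankdata
from sklearn.base import BaseEstimator

from .grids import RasterStack

__all__ = [
    "FeatureSpec",
    "ModelSettings",
    "EvalMetrics",
    "BackgroundSet",
    "settings_grid",
    "build_features",
    "PresenceBackgroundSDM",
    "fit_presence_background",
    "make_bias_layer",
    "sample_background",
    "partition_occurrences",
    "auc",
    "evaluate_settings",
    "select_model",
]

log = logging.getLogger(__name__)

FEATURE_CLASS_COMBOS = ("LQH", "LQ", "QH", "L", "Q", "H")
RM_GRID = tuple(np.arange(0.5, 5.01, 0.5).round(2))
DEFAULT_PENALTY_BASE = {"L": 1.0, "Q": 1.0, "H": 0.5, "C": 1.0}
# complexity preference for deterministic tie-breaks: simplest first
_CLASS_SIMPLICITY = {c: i for i, c in enumerate(("H", "Q", "L", "QH", "LQ", "LQH"))}


@dataclass(frozen=True)
class FeatureSpec:
    """Which transforms enter the design matrix and how hinges are knotted."""

    classes: str = "LQH"
    n_hinge_knots: int = 10
    penalty_base: tuple[tuple[str, float], ...] = tuple(
        sorted(DEFAULT_PENALTY_BASE.items())
    )

    def __post_init__(self) -> None:
        cls = set(self.classes)
        if not cls or not cls <= {"L", "Q", "H"}:
            raise ValueError(f"feature classes must be a nonempty subset of LQH, got {self.classes!r}")

    @property
    def base(self) -> dict[str, float]:
        return dict(self.penalty_base)


@dataclass(frozen=True)
class ModelSettings:
    """One point of the tuning grid: a feature-class combo and an rm."""

    feature_classes: str = "LQH"
    rm: float = 1.0

    def __post_init__(self) -> None:
        if self.rm <= 0:
            raise ValueError("regularization multiplier must be positive")


def settings_grid(
    classes=FEATURE_CLASS_COMBOS, rms=RM_GRID
) -> list[ModelSettings]:
    """The full tuning grid (default 6 feature combos x 10 multipliers)."""
    return [ModelSettings(c, float(r)) for c, r in itertools.product(classes, rms)]


@dataclass
class _FeatureMap:
    """Frozen recipe turning raw covariates into the design matrix."""

    classes: str
    continuous: list[int]
    categorical: dict[int, np.ndarray]  # column -> observed levels
    knots: dict[int, np.ndarray]
    x_min: np.ndarray
    x_max: np.ndarray
    feature_class: list[str] = field(default_factory=list)  # per design column

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        cols = []
        classes = []
        for j in self.continuous:
            x = X[:, j]
            if "L" in self.classes:
                cols.append(x)
                classes.append("L")
            if "Q" in self.classes:
                cols.append(x**2)
                classes.append("Q")
            if "H" in self.classes:
                lo, hi = self.x_min[j], self.x_max[j]
                for k in self.knots[j]:
                    if hi > k:
                        cols.append(np.maximum(0.0, (x - k) / (hi - k)))
                        classes.append("H")
                    if k > lo:
                        cols.append(np.maximum(0.0, (k - x) / (k - lo)))
                        classes.append("H")
        for j, levels in self.categorical.items():
            for lev in levels:
                cols.append((X[:, j] == lev).astype(float))
                classes.append("C")
        self.feature_class = classes
        if not cols:
            raise ValueError("empty design matrix")
        return np.column_stack(cols)


def _make_feature_map(
    X: np.ndarray, spec: FeatureSpec, categorical=()
) -> _FeatureMap:
    X = np.asarray(X, dtype=float)
    categorical = set(categorical)
    continuous = [j for j in range(X.shape[1]) if j not in categorical]
    knots = {}
    for j in continuous:
        x = X[:, j]
        m = spec.n_hinge_knots
        q = (np.arange(m) + 1.0) / (m + 1.0)
        k = np.unique(np.quantile(x, q))
        if len(k) < m and len(np.unique(x)) < m:
            warnings.warn(
                f"covariate {j} has fewer distinct values than hinge knots; "
                f"knots deduplicated to {len(k)}"
            )
        knots[j] = k
    return _FeatureMap(
        classes=spec.classes,
        continuous=continuous,
        categorical={j: np.unique(X[:, j]) for j in sorted(categorical)},
        knots=knots,
        x_min=X.min(axis=0),
        x_max=X.max(axis=0),
    )


def build_features(
    X: np.ndarray, spec: FeatureSpec, categorical=()
) -> tuple[np.ndarray, _FeatureMap]:
    """Design matrix for the given feature spec (unstandardized).

    Hinge knots sit at equally spaced quantiles of each covariate; forward
    hinges are max(0, (x-k)/(x_max-k)) and reverse max(0, (k-x)/(k-x_min)).
    Categorical covariates expand to indicator columns regardless of spec.
    """
    fmap = _make_feature_map(X, spec, categorical)
    return fmap.transform(X), fmap


class PresenceBackgroundSDM(BaseEstimator):
    """Penalized presence-background exponential model (Maxent-style).

    scikit-learn estimator: ``fit(X, y)`` with ``y == 1`` marking presence
    rows and ``y == 0`` background rows of the covariate matrix ``X``;
    ``predict(X)`` returns suitability in [0, 1].

    Parameters
    ----------
    feature_classes : str
        Subset of "LQH" naming the transforms to build.
    rm : float
        Regularization multiplier scaling every feature's L1 penalty.
    n_hinge_knots : int
        Hinge knots per covariate per direction, at equally spaced quantiles.
    output : {"cloglog", "logistic"}
        Transform from the linear predictor to [0, 1].
    categorical_features : tuple of int
        Covariate columns expanded to indicators regardless of classes.

    Attributes
    ----------
    coef_ : ndarray
        Coefficients on the standardized features (zero-variance features
        get exactly 0).
    alpha_ : float
        Log normalizer of exp(f) over the background sample.
    entropy_ : float
        Entropy of the normalized background distribution (cloglog offset).
    """

    def __init__(
        self,
        feature_classes: str = "LQH",
        rm: float = 1.0,
        n_hinge_knots: int = 10,
        penalty_base: dict | None = None,
        output: str = "cloglog",
        categorical_features: tuple = (),
        max_iter: int = 500,
        tol: float = 1e-9,
    ):
        self.feature_classes = feature_classes
        self.rm = rm
        self.n_hinge_knots = n_hinge_knots
        self.penalty_base = penalty_base
        self.output = output
        self.categorical_features = categorical_features
        self.max_iter = max_iter
        self.tol = tol

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or not np.isfinite(X).all():
            raise ValueError("X must be a finite 2-D covariate matrix")
        pres, bg = X[y == 1], X[y == 0]
        if len(pres) < 2:
            raise ValueError("need at least 2 presence locations")
        if len(bg) == 0:
            raise ValueError("background is empty")
        base = dict(DEFAULT_PENALTY_BASE)
        if self.penalty_base:
            base.update(self.penalty_base)
        spec = FeatureSpec(
            classes=self.feature_classes,
            n_hinge_knots=self.n_hinge_knots,
            penalty_base=tuple(sorted(base.items())),
        )
        self._fmap = _make_feature_map(X, spec, self.categorical_features)
        F = self._fmap.transform(X)
        self.mean_ = F.mean(axis=0)
        sd = F.std(axis=0)
        self.scale_ = np.where(sd > 0, sd, 1.0)
        self._active = sd > 0
        Fs = (F - self.mean_) / self.scale_
        lam = np.array(
            [self.rm * base[c] for c in self._fmap.feature_class]
        ) / np.sqrt(len(pres))
        beta = self._solve(Fs[y == 1], Fs[y == 0], lam)
        beta[~self._active] = 0.0
        self.coef_ = beta
        fb = Fs[y == 0] @ beta
        self.alpha_ = float(logsumexp(fb))
        p = np.exp(fb - self.alpha_)
        with np.errstate(divide="ignore", invalid="ignore"):
            self.entropy_ = float(-np.sum(np.where(p > 0, p * np.log(p), 0.0)))
        self.n_features_in_ = X.shape[1]
        return self

    def _solve(self, Fp, Fb, lam):
        d = Fp.shape[1]
        act = self._active
        Fp, Fb, lam = Fp[:, act], Fb[:, act], lam[act]
        da = Fp.shape[1]
        log_nb = np.log(len(Fb))

        def value_and_grad(theta):
            beta = theta[:da] - theta[da:]
            fp = Fp @ beta
            fb = Fb @ beta
            lse = logsumexp(fb)
            obj = -fp.mean() + lse - log_nb + lam @ (theta[:da] + theta[da:])
            w = np.exp(fb - lse)
            g = -Fp.mean(axis=0) + w @ Fb
            grad = np.concatenate([g + lam, -g + lam])
            return obj, grad

        res = minimize(
            value_and_grad,
            np.zeros(2 * da),
            jac=True,
            method="L-BFGS-B",
            bounds=[(0.0, None)] * (2 * da),
            options={"maxiter": self.max_iter, "ftol": self.tol, "gtol": 1e-7},
        )
        if not res.success:
            # line searches can stall within rounding of the optimum; accept
            # the point if the bound-projected gradient is effectively zero
            pg = np.where(res.x > 0, res.jac, np.minimum(res.jac, 0.0))
            if np.abs(pg).max() > 1e-4:
                raise RuntimeError(
                    f"presence-background fit did not converge "
                    f"(classes={self.feature_classes}, rm={self.rm}): {res.message}"
                )
        beta = np.zeros(d)
        beta[act] = res.x[:da] - res.x[da:]
        return beta

    # -- prediction --------------------------------------------------------

    def decision_function(self, X):
        """Linear predictor f(x) on the standardized feature scale."""
        F = self._fmap.transform(np.asarray(X, dtype=float))
        Fs = (F - self.mean_) / self.scale_
        return Fs @ self.coef_

    def predict(self, X):
        """Relative suitability in [0, 1]."""
        eta = self.decision_function(X) - self.alpha_
        if self.output == "cloglog":
            return 1.0 - np.exp(-np.exp(eta + self.entropy_))
        if self.output == "logistic":
            z = eta + self.entropy_
            return 1.0 / (1.0 + np.exp(-z))
        raise ValueError(f"unknown output transform {self.output!r}")

    def predict_grid(self, stack: RasterStack, names=None) -> np.ndarray:
        """Suitability over a raster stack; missing env cells give NaN."""
        names = list(names) if names is not None else stack.names
        tab = stack.table(names)
        ok = np.isfinite(tab).all(axis=1)
        out = np.full(tab.shape[0], np.nan)
        if ok.any():
            out[ok] = self.predict(tab[ok])
        return out.reshape(stack.grid.shape)


def fit_presence_background(
    presence_env: np.ndarray,
    background_env: np.ndarray,
    settings: ModelSettings,
    min_presence: int = 3,
    **kwargs,
) -> PresenceBackgroundSDM:
    """Fit one model from presence and background covariate tables.

    The study-level minimum is 3 presences; cross-validation passes
    ``min_presence=2`` so that jackknife training folds of n - 1 points
    remain fittable at n = 3.
    """
    if len(presence_env) < min_presence:
        raise ValueError(f"need at least {min_presence} presence locations")
    X = np.vstack([presence_env, background_env])
    y = np.concatenate(
        [np.ones(len(presence_env)), np.zeros(len(background_env))]
    )
    model = PresenceBackgroundSDM(
        feature_classes=settings.feature_classes, rm=settings.rm, **kwargs
    )
    return model.fit(X, y)


# -- bias layer and background -------------------------------------------


@dataclass
class BackgroundSet:
    """Background sample: cell locations with attached env values."""

    lon: np.ndarray
    lat: np.ndarray
    rows: np.ndarray
    cols: np.ndarray
    env: np.ndarray
    seed: object = None


def make_bias_layer(
    occurrences,
    env: RasterStack,
    seed,
    n_background: int = 10_000,
    env_names=None,
) -> np.ndarray:
    """Sampling-bias surface from the pooled occurrences of all species.

    Fits the default presence-background model (LQH, rm = 1) on all points
    pooled against a uniform random background; high suitability marks
    environments like those that were surveyed.  Returns a [0, 1] grid.
    """
    lon = np.asarray(occurrences["lon"], dtype=float)
    lat = np.asarray(occurrences["lat"], dtype=float)
    if len(lon) < 10:
        raise ValueError("bias layer needs >= 10 pooled occurrences")
    names = list(env_names) if env_names is not None else env.names
    pres_env = env.values_at(lon, lat, names)
    ok = np.isfinite(pres_env).all(axis=1)
    if not ok.all():
        log.warning("dropping %d pooled points on missing env cells", (~ok).sum())
    pres_env = pres_env[ok]
    rng = np.random.default_rng(seed)
    tab = env.table(names)
    valid = np.flatnonzero(np.isfinite(tab).all(axis=1))
    pick = rng.choice(valid, size=n_background, replace=True)
    model = fit_presence_background(
        pres_env, tab[pick], ModelSettings("LQH", 1.0)
    )
    return model.predict_grid(env, names)


def sample_background(
    bias: np.ndarray,
    env: RasterStack,
    n: int = 10_000,
    seed=None,
    env_names=None,
) -> BackgroundSet:
    """Draw background cells with replacement, probability ~ bias value."""
    names = list(env_names) if env_names is not None else env.names
    bias = np.asarray(bias, dtype=float)
    tab = env.table(names)
    w = np.where(np.isfinite(bias.ravel()), bias.ravel(), 0.0)
    w = np.where(np.isfinite(tab).all(axis=1), w, 0.0)
    if w.sum() <= 0:
        raise ValueError("bias layer has no positive cell over valid environment")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(w), size=n, replace=True, p=w / w.sum())
    rows, cols = np.unravel_index(idx, env.grid.shape)
    lon, lat = env.grid.cell_center(rows, cols)
    return BackgroundSet(
        lon=lon, lat=lat, rows=rows, cols=cols, env=tab[idx], seed=seed
    )


# -- evaluation ----------------------------------------------------------


def partition_occurrences(
    lon,
    lat,
    bg_lon,
    bg_lat,
    n_spatial_min: int = 20,
) -> list[dict]:
    """Cross-validation folds for one species.

    With >= ``n_spatial_min`` presences: four geographically structured
    blocks split at the presence median longitude and latitude; each fold
    trains on three blocks (presences and background both masked) and tests
    on the held-out block.  With fewer presences: leave-one-out jackknife
    over presences with the full background on both sides.

    Each fold is a dict of index arrays ``train_p, test_p, train_bg, test_bg``.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    n = len(lon)
    if n < 3:
        raise ValueError("need at least 3 presence points")
    if n < n_spatial_min:
        idx = np.arange(n)
        bg = np.arange(len(np.asarray(bg_lon)))
        return [
            {
                "train_p": np.delete(idx, i),
                "test_p": np.array([i]),
                "train_bg": bg,
                "test_bg": bg,
            }
            for i in range(n)
        ]
    mlon, mlat = np.median(lon), np.median(lat)

    def block_of(x, y):
        return (np.asarray(x) >= mlon).astype(int) * 2 + (np.asarray(y) >= mlat).astype(int)

    pb = block_of(lon, lat)
    bb = block_of(bg_lon, bg_lat)
    blocks = [0, 1, 2, 3]
    counts = np.array([(pb == b).sum() for b in blocks])
    present = [b for b in blocks if counts[b] > 0]
    if len(present) < len(blocks):
        # merge empty blocks into the nearest presence-bearing block
        warnings.warn("empty spatial block merged into its nearest neighbor")
        cent = {
            b: (lon[pb == b].mean(), lat[pb == b].mean()) for b in present
        }
        for b in blocks:
            if counts[b] == 0:
                bx = mlon + (0.5 if b >= 2 else -0.5)
                by = mlat + (0.5 if b % 2 else -0.5)
                near = min(
                    present,
                    key=lambda q: (cent[q][0] - bx) ** 2 + (cent[q][1] - by) ** 2,
                )
                bb[bb == b] = near
                pb[pb == b] = near  # no-op; keeps labels consistent
    folds = []
    for b in present:
        folds.append(
            {
                "train_p": np.flatnonzero(pb != b),
                "test_p": np.flatnonzero(pb == b),
                "train_bg": np.flatnonzero(bb != b),
                "test_bg": np.flatnonzero(bb == b),
            }
        )
    return folds


def auc(pos_scores, neg_scores) -> float:
    """Rank (Mann-Whitney) AUC; ties count one half."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score sets must be nonempty")
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


@dataclass(frozen=True)
class EvalMetrics:
    """Cross-validation summary for one candidate setting."""

    or_mtp: float
    auc_diff: float
    auc_test: float
    auc_train: float
    n_folds: int


def evaluate_settings(
    presence_env: np.ndarray,
    background_env: np.ndarray,
    settings: ModelSettings,
    folds: list[dict],
    **fit_kwargs,
) -> EvalMetrics:
    """Average OR_MTP / AUC_DIFF / AUC_TEST over cross-validation folds.

    Per fold: fit on the training presences and background; the minimum
    training-presence prediction is the MTP threshold; OR_MTP is the share
    of test presences strictly below it.
    """
    or_mtp, auc_tr, auc_te = [], [], []
    for fold in folds:
        try:
            model = fit_presence_background(
                presence_env[fold["train_p"]],
                background_env[fold["train_bg"]],
                settings,
                min_presence=2,
                **fit_kwargs,
            )
        except (RuntimeError, ValueError) as exc:
            warnings.warn(f"fold skipped for {settings}: {exc}")
            continue
        p_train = model.predict(presence_env[fold["train_p"]])
        p_test = model.predict(presence_env[fold["test_p"]])
        b_train = model.predict(background_env[fold["train_bg"]])
        b_test = model.predict(background_env[fold["test_bg"]])
        mtp = p_train.min()
        or_mtp.append(float((p_test < mtp).mean()))
        auc_tr.append(auc(p_train, b_train))
        auc_te.append(auc(p_test, b_test))
    if not or_mtp:
        raise RuntimeError(f"every fold failed for {settings}")
    return EvalMetrics(
        or_mtp=float(np.mean(or_mtp)),
        auc_diff=float(np.mean(auc_tr) - np.mean(auc_te)),
        auc_test=float(np.mean(auc_te)),
        auc_train=float(np.mean(auc_tr)),
        n_folds=len(or_mtp),
    )


def select_model(
    metrics_by_settings,
    auc_filter: float = 0.6,
) -> ModelSettings:
    """Sequential best-model choice over evaluated candidates.

    Keep candidates with AUC_TEST > ``auc_filter`` (if none pass, fall back
    to the full set with a warning); among survivors minimize OR_MTP, break
    ties by minimal AUC_DIFF, then maximal AUC_TEST; residual ties prefer
    the simpler feature-class combo (H, Q, L, QH, LQ, LQH) and the larger
    rm.  A pure function of the candidate set: order never matters.
    """
    items = list(metrics_by_settings.items()) if isinstance(
        metrics_by_settings, dict
    ) else list(metrics_by_settings)
    if not items:
        raise ValueError("no candidates to select from")
    survivors = [(s, m) for s, m in items if m.auc_test > auc_filter]
    if not survivors:
        warnings.warn(
            f"no candidate exceeds AUC_TEST > {auc_filter}; "
            "selecting from the full candidate set"
        )
        survivors = items

    def key(item):
        s, m = item
        return (
            round(m.or_mtp, 12),
            round(m.auc_diff, 12),
            -round(m.auc_test, 12),
            _CLASS_SIMPLICITY.get(s.feature_classes, len(_CLASS_SIMPLICITY)),
            -s.rm,
        )

    return min(survivors, key=key)[0]
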