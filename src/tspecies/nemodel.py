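"""Estimating ancestral Ne from the variance of a Ks distribution.

Under the two-species coalescent the TMRCA of a random ortholog pair is
``T + Exponential(mean 2·Ne)``, so its standard deviation is ``2·Ne``
generations and the coalescent contribution to the Ks variance is
``Var(Ks) = (2·mu)²·(2·Ne)² = 16·mu²·Ne²``.  Inverting gives the analytic
moment estimator::

    Ne_hat = sqrt(Var(Ks)) / (4·mu)

which is reliable only when the coalescent variance dominates the
finite-length sampling noise of the per-locus Ks values — empirically when
Ne exceeds ~450,000 across the simulated grid.  Below that, the
variance–Ne relationship is strongly nonlinear and is represented by a
smooth curve fitted to coalescent simulations, one curve per substitution
rate category, frozen as a dense monotone prediction grid.

:func:`predict_ne` applies the regime switch: interpolate on the trained
curve; if the prediction exceeds the threshold, fall back to the analytic
estimator.
"""

from __future__ import annotations

import datetime as _dt
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import PchipInterpolator, make_smoothing_spline

#: Above this predicted Ne the analytic moment estimator takes over.
ANALYTIC_NE_THRESHOLD = 450_000

#: Canonical substitution-rate categories: 23 log-spaced values per site per
#: generation, spanning the empirically reported neutral-rate range.
MU_CATEGORIES = np.logspace(-10, -7, 23)

#: Input rates farther than this (relative) from every available model are
#: rejected; closer than this but not matching triggers a warning.
MU_MATCH_TOLERANCE = 0.25

#: Default training grid: Ne span of the simulation study.
DEFAULT_NE_GRID = np.logspace(np.log10(500), np.log10(500_000), 23)
DEFAULT_T_GRID = (1e4, 1e5, 1e6)


class TrainingError(RuntimeError):
    """Raised when the pooled variance–Ne relationship is not monotone."""


def estimate_ne_analytic(var_ks: float, mu: float) -> float:
    """Closed-form moment estimator ``Ne = sqrt(Var(Ks)) / (4·mu)``.

    Valid when the coalescent variance dominates the mutational (Poisson /
    finite-length) variance of per-locus Ks values.
    """
    if mu <= 0:
        raise ValueError("mu must be > 0")
    if var_ks < 0:
        raise ValueError("var_ks must be >= 0")
    return float(np.sqrt(var_ks) / (4.0 * mu))


@dataclass
class NeEstimate:
    """An ancestral-Ne estimate and the regime that produced it."""

    ne: float
    regime: str  # "analytic" | "trained-curve"
    var_ks_used: float
    mu_used: float
    model_id: str | None = None

    def to_dict(self) -> dict:
        return {
            "ne": self.ne,
            "regime": self.regime,
            "var_ks_used": self.var_ks_used,
            "mu_used": self.mu_used,
            "model_id": self.model_id,
        }


@dataclass
class VarianceModel:
    """A trained, persisted variance→Ne curve for one rate category.

    The curve is stored as a dense grid of ``(var_ks, ne_predicted)`` pairs,
    strictly increasing in ``var_ks`` and non-decreasing in ``ne_predicted``;
    prediction interpolates monotonically (PCHIP in log–log space).
    """

    mu: float
    grid_var: np.ndarray
    grid_ne: np.ndarray
    train_meta: dict
    fit_r2: float
    _interp: PchipInterpolator | None = field(default=None, repr=False)

    def __post_init__(self):
        self.grid_var = np.asarray(self.grid_var, dtype=float)
        self.grid_ne = np.asarray(self.grid_ne, dtype=float)
        if self.grid_var.size != self.grid_ne.size or self.grid_var.size < 2:
            raise ValueError("grid_var and grid_ne must be equal-length (>= 2)")
        if np.any(np.diff(self.grid_var) <= 0):
            raise ValueError("grid_var must be strictly increasing")
        if np.any(np.diff(self.grid_ne) < 0):
            raise ValueError("grid_ne must be non-decreasing")
        if not (0.0 <= self.fit_r2 <= 1.0):
            raise ValueError("fit_r2 must be in [0, 1]")

    @property
    def var_range(self) -> tuple[float, float]:
        return float(self.grid_var[0]), float(self.grid_var[-1])

    @property
    def model_id(self) -> str:
        return f"varmodel(mu={self.mu:.6g})"

    def predict(self, var_ks: float) -> float:
        """Interpolate Ne from Var(Ks); no extrapolation outside the grid."""
        lo, hi = self.var_range
        if not (lo <= var_ks <= hi):
            raise ValueError(
                f"var_ks={var_ks:.4g} outside this model's trained range "
                f"[{lo:.4g}, {hi:.4g}] (mu={self.mu:.3g}); no extrapolation"
            )
        if self._interp is None:
            # strictly-increasing x is guaranteed; ne may have flat stretches
            self._interp = PchipInterpolator(
                np.log10(self.grid_var), np.log10(self.grid_ne)
            )
        return float(10.0 ** self._interp(np.log10(var_ks)))

    # -- persistence ---------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "mu": self.mu,
            "grid": [[v, n] for v, n in zip(self.grid_var, self.grid_ne)],
            "train_meta": self.train_meta,
            "fit_r2": self.fit_r2,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VarianceModel":
        grid = np.asarray(d["grid"], dtype=float)
        return cls(
            mu=float(d["mu"]),
            grid_var=grid[:, 0],
            grid_ne=grid[:, 1],
            train_meta=dict(d.get("train_meta", {})),
            fit_r2=float(d["fit_r2"]),
        )

    def save(self, path) -> Path:
        path = Path(path)
        if path.is_dir():
            path = path / f"ne_model_mu{self.mu:.4g}.json"
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, sort_keys=True)
            fh.write("\n")
        return path

    @classmethod
    def load(cls, path) -> "VarianceModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def train_variance_model(
    mu_category: float,
    ne_values=None,
    t_values=DEFAULT_T_GRID,
    n_loci: int = 10000,
    seq_len: int = 1000,
    seed: int = 0,
    grid_points: int = 1000,
) -> VarianceModel:
    """Train the variance→Ne curve for one substitution-rate category.

    For every cell of the (Ne, T) grid a Ks distribution is simulated and its
    variance recorded; all T values are pooled and a GCV-penalized cubic
    smoothing spline of log10(Ne) on log10(Var(Ks)) is fitted, projected to a
    monotone curve, and frozen as a ``grid_points``-long prediction grid.

    Raises
    ------
    TrainingError
        If the smoothed pooled relationship is substantially non-monotone
        (a symptom of too few loci per cell).
    ValueError
        If the Ne grid does not span [500, 500,000] with >= 10 distinct values.
    """
    from .coalsim import SimulationConfig, simulate_ks_values

    ne_values = np.asarray(
        DEFAULT_NE_GRID if ne_values is None else ne_values, dtype=float
    )
    if np.unique(ne_values).size < 10:
        raise ValueError("need >= 10 distinct ne training values")
    if ne_values.min() > 500 * 1.001 or ne_values.max() < 500_000 * 0.999:
        raise ValueError("ne training values must span at least [500, 500000]")

    cells = [(ne, t) for ne in np.sort(ne_values) for t in t_values]
    child_seeds = np.random.SeedSequence(seed).generate_state(len(cells))
    log_var, log_ne = [], []
    for (ne, t), s in zip(cells, child_seeds):
        cfg = SimulationConfig(
            ne=ne, mu=mu_category, t_div=t, seq_len=seq_len,
            n_loci=n_loci, seed=int(s) % (2**31),
        )
        dist = simulate_ks_values(cfg)
        if dist.var_ks <= 0:
            raise TrainingError(
                f"degenerate training cell (ne={ne:g}, T={t:g}): zero Ks "
                "variance; increase n_loci"
            )
        log_var.append(np.log10(dist.var_ks))
        log_ne.append(np.log10(ne))
    x = np.asarray(log_var)
    y = np.asarray(log_ne)

    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    # make_smoothing_spline needs strictly increasing x; average exact ties
    ux, inv = np.unique(x, return_inverse=True)
    uy = np.bincount(inv, weights=y) / np.bincount(inv)

    # The pooled scatter is heteroscedastic (the finite-length noise floor
    # depends on T), so an unconstrained GCV penalty oscillates.  Use the
    # smallest penalty whose smooth is essentially monotone (residual dips
    # below 2% of the total rise), then project the remainder.
    xg = np.linspace(ux[0], ux[-1], grid_points)
    yg_raw = None
    for lam in np.logspace(-4, 3, 29):
        cand = make_smoothing_spline(ux, uy, lam=lam)(xg)
        inc = np.diff(cand)
        rise = inc[inc > 0].sum()
        dip = -inc[inc < 0].sum()
        if rise > 0 and dip <= 0.02 * rise:
            yg_raw = cand
            break
    if yg_raw is None:
        raise TrainingError(
            "pooled variance-Ne relationship is non-monotone at every "
            "smoothing level; increase n_loci or the grid density"
        )
    yg = np.maximum.accumulate(yg_raw)

    y_hat = np.interp(x, xg, yg)
    ss_res = float(np.sum((y - y_hat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    fit_r2 = max(0.0, 1.0 - ss_res / ss_tot)

    meta = {
        "ne_range": [float(ne_values.min()), float(ne_values.max())],
        "n_ne": int(np.unique(ne_values).size),
        "t_values": [float(t) for t in t_values],
        "n_loci": int(n_loci),
        "seq_len": int(seq_len),
        "seed": int(seed),
        "date": _dt.date.today().isoformat(),
    }
    return VarianceModel(
        mu=float(mu_category),
        grid_var=10.0 ** xg,
        grid_ne=10.0 ** yg,
        train_meta=meta,
        fit_r2=fit_r2,
    )


# -- model store --------------------------------------------------------------

def load_model_store(directory) -> dict[float, VarianceModel]:
    """Load every ``*.json`` variance model in a directory, keyed by mu."""
    store: dict[float, VarianceModel] = {}
    for p in sorted(Path(directory).glob("*.json")):
        try:
            model = VarianceModel.load(p)
        except (KeyError, ValueError, TypeError):
            continue  # unrelated JSON (e.g. provenance) living in the store
        store[model.mu] = model
    if not store:
        raise ValueError(f"no variance-model JSON files found in {directory!r}")
    return store


def load_default_models() -> dict[float, VarianceModel]:
    """Load the pre-trained bundle shipped with the package.

    Covers the decade rate categories (1e-9, 1e-8, 1e-7); other categories
    are regenerable with ``tspecies train``.
    """
    from importlib.resources import files

    store: dict[float, VarianceModel] = {}
    for res in files("tspecies.models").iterdir():
        if res.name.endswith(".json"):
            model = VarianceModel.from_dict(json.loads(res.read_text()))
            store[model.mu] = model
    return store


def find_model(store: dict[float, VarianceModel], mu: float) -> VarianceModel:
    """Pick the store's model for the rate category nearest ``mu``.

    Relative gaps above :data:`MU_MATCH_TOLERANCE` are an error (the message
    names the nearest available categories); smaller non-zero gaps warn.
    """
    if mu <= 0:
        raise ValueError("mu must be > 0")
    mus = np.array(sorted(store))
    nearest = float(mus[np.argmin(np.abs(np.log(mus) - np.log(mu)))])
    gap = abs(nearest - mu) / mu
    if gap > MU_MATCH_TOLERANCE:
        raise ValueError(
            f"no variance model within {MU_MATCH_TOLERANCE:.0%} of mu={mu:.3g}; "
            f"nearest available categories: "
            + ", ".join(f"{m:.3g}" for m in mus[np.argsort(np.abs(np.log(mus) - np.log(mu)))][:3])
        )
    if gap > 0:
        warnings.warn(
            f"using variance model for mu={nearest:.3g} "
            f"({gap:.1%} from requested {mu:.3g})",
            stacklevel=2,
        )
    return store[nearest]


def predict_ne(
    var_ks: float,
    mu: float,
    model_store: dict[float, VarianceModel] | VarianceModel,
) -> NeEstimate:
    """Estimate ancestral Ne from an observed Ks variance.

    Interpolates on the trained curve for the matching rate category; if the
    trained prediction exceeds :data:`ANALYTIC_NE_THRESHOLD` (the regime where
    coalescent variance dominates), the analytic moment estimator is used
    instead and the estimate is flagged ``regime="analytic"``.
    """
    if isinstance(model_store, VarianceModel):
        model = model_store
        if abs(model.mu - mu) / mu > MU_MATCH_TOLERANCE:
            raise ValueError(
                f"model trained for mu={model.mu:.3g} is too far from mu={mu:.3g}"
            )
    else:
        model = find_model(model_store, mu)
    trained = model.predict(var_ks)
    if trained > ANALYTIC_NE_THRESHOLD:
        return NeEstimate(
            ne=estimate_ne_analytic(var_ks, mu),
            regime="analytic",
            var_ks_used=float(var_ks),
            mu_used=float(mu),
            model_id=model.model_id,
        )
    return NeEstimate(
        ne=trained,
        regime="trained-curve",
        var_ks_used=float(var_ks),
        mu_used=float(mu),
        model_id=model.model_id,
    )
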