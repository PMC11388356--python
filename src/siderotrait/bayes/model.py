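"""Model definition: likelihood, priors, and the joint log posterior.

The observation model is a heteroscedastic hierarchical Gaussian:

* ``y_i ~ Normal(lambda[group_i, replicate_i], sigma[vargroup(group_i)])``
* ``lambda_{j,k} ~ Normal(nu_j, tau_j)`` with
  ``nu_j = alpha[X1_j] + beta[X1_j] * X2_j``
* ``alpha_t ~ HalfNormal(prior_alpha_sd)``, ``beta_t ~ Normal(0, prior_beta_sd)``
* ``sigma_v, tau_j ~ Exponential(scale)``

The residual SD can be shared (``single``), split by isolate type or by
copper, or fully per-group (4 SDs).  Replicate cells are ragged: a
``lambda`` is instantiated only for (group, replicate) pairs that occur in
the data.

Two density entry points exist: :func:`log_posterior` evaluates the joint
density for natural-space parameters (no Jacobian, out-of-support gives
``-inf``), while :class:`UnconstrainedPosterior` provides the value and
analytic gradient on log-transformed positive parameters for the sampler
and optimizer.  The transformed density folds in the log-Jacobian.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..design import X1, X2, assign_groups

__all__ = [
    "VARIANCE_STRUCTURES",
    "ModelSpec",
    "ModelData",
    "prepare_model_data",
    "log_posterior",
    "UnconstrainedPosterior",
]

#: variance structure -> map from group index (0..3) to sigma index
VARIANCE_STRUCTURES: dict[str, tuple[int, ...]] = {
    "per_group": (0, 1, 2, 3),
    "by_isolate_type": (0, 0, 1, 1),
    "by_copper": (0, 1, 0, 1),
    "single": (0, 0, 0, 0),
}

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class ModelSpec:
    """Definition of one model variant (variance structure + priors).

    ``exponential_parameterization`` selects whether the Exponential prior
    value 0.2 is read as the scale/mean (the default) or as a rate;
    ``beta_prior_parameter`` selects whether ``prior_beta_sd`` is an SD
    (default) or a variance.  ``fixed_sigma`` / ``fixed_tau`` freeze those
    parameters at given values (used for conjugate-limit checks); frozen
    parameters are excluded from sampling and carry no prior term.
    """

    variance_structure: str = "per_group"
    prior_alpha_sd: float = 1.0
    prior_beta_sd: float = 0.25
    prior_scale_sigma: float = 0.2
    prior_scale_tau: float = 0.2
    exponential_parameterization: str = "scale"
    beta_prior_parameter: str = "sd"
    fixed_sigma: tuple[float, ...] | None = None
    fixed_tau: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.variance_structure not in VARIANCE_STRUCTURES:
            raise ValueError(
                f"variance_structure must be one of {sorted(VARIANCE_STRUCTURES)}, "
                f"got {self.variance_structure!r}"
            )
        for name in ("prior_alpha_sd", "prior_beta_sd", "prior_scale_sigma",
                     "prior_scale_tau"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.exponential_parameterization not in ("scale", "rate"):
            raise ValueError("exponential_parameterization must be 'scale' or 'rate'")
        if self.beta_prior_parameter not in ("sd", "variance"):
            raise ValueError("beta_prior_parameter must be 'sd' or 'variance'")
        if self.fixed_sigma is not None and len(self.fixed_sigma) != self.n_sigma:
            raise ValueError(
                f"fixed_sigma needs {self.n_sigma} value(s) for "
                f"variance_structure={self.variance_structure!r}"
            )
        if self.fixed_tau is not None and len(self.fixed_tau) != 4:
            raise ValueError("fixed_tau needs 4 values (one per group)")

    @property
    def vargroup(self) -> tuple[int, ...]:
        return VARIANCE_STRUCTURES[self.variance_structure]

    @property
    def n_sigma(self) -> int:
        return max(VARIANCE_STRUCTURES[self.variance_structure]) + 1

    @property
    def beta_sd(self) -> float:
        if self.beta_prior_parameter == "variance":
            return math.sqrt(self.prior_beta_sd)
        return self.prior_beta_sd

    @property
    def sigma_scale(self) -> float:
        v = self.prior_scale_sigma
        return v if self.exponential_parameterization == "scale" else 1.0 / v

    @property
    def tau_scale(self) -> float:
        v = self.prior_scale_tau
        return v if self.exponential_parameterization == "scale" else 1.0 / v


@dataclass
class ModelData:
    """Observations indexed to (group, replicate) cells plus sufficient stats.

    Only cells present in the data get a ``lambda``; ``cell_group`` maps each
    cell to its 0-based group and ``cell_labels`` keeps the original
    (group, replicate) identifiers for reporting.
    """

    y: np.ndarray                    # (n,) observations
    obs_group: np.ndarray            # (n,) 0-based group index
    obs_cell: np.ndarray             # (n,) 0-based cell index
    cell_group: np.ndarray           # (C,) 0-based group per cell
    cell_labels: list[tuple[int, object]] = field(repr=False, default_factory=list)
    cell_n: np.ndarray = None        # (C,) observation counts
    cell_sum: np.ndarray = None      # (C,) sum of y
    cell_sumsq: np.ndarray = None    # (C,) sum of y^2

    @property
    def n_obs(self) -> int:
        return self.y.size

    @property
    def n_cells(self) -> int:
        return self.cell_group.size

    def cell_means(self) -> np.ndarray:
        return self.cell_sum / self.cell_n


def prepare_model_data(
    table: pd.DataFrame,
    value_col: str = "siderophore",
    replicate_col: str = "replicate",
    type_col: str = "isolate_type",
    copper_col: str = "copper",
) -> ModelData:
    """Index an isolate table into :class:`ModelData`.

    Cells are the observed (group, replicate) pairs, ordered by group then
    replicate label; missing microcosms are simply absent (ragged design).
    """
    for col in (value_col, replicate_col):
        if col not in table.columns:
            raise ValueError(f"column {col!r} not in table")
    y = table[value_col].to_numpy(float)
    if y.size == 0:
        raise ValueError("empty isolate table")
    if not np.all(np.isfinite(y)):
        raise ValueError(f"non-finite values in column {value_col!r}")
    groups0 = assign_groups(table, type_col=type_col, copper_col=copper_col) - 1
    reps = table[replicate_col].to_numpy()
    pairs = sorted(set(zip(groups0.tolist(), reps.tolist())), key=lambda p: (p[0], str(p[1])))
    cell_of = {p: i for i, p in enumerate(pairs)}
    obs_cell = np.array([cell_of[(g, r)] for g, r in zip(groups0, reps)], dtype=int)
    C = len(pairs)
    cell_n = np.bincount(obs_cell, minlength=C).astype(float)
    cell_sum = np.bincount(obs_cell, weights=y, minlength=C)
    cell_sumsq = np.bincount(obs_cell, weights=y * y, minlength=C)
    return ModelData(
        y=y,
        obs_group=groups0,
        obs_cell=obs_cell,
        cell_group=np.array([g for g, _ in pairs], dtype=int),
        cell_labels=[(g + 1, r) for g, r in pairs],
        cell_n=cell_n,
        cell_sum=cell_sum,
        cell_sumsq=cell_sumsq,
    )


# ---------------------------------------------------------------------------
# densities
# ---------------------------------------------------------------------------

def _nu(alpha: np.ndarray, beta: np.ndarray) -> np.ndarray:
    t = np.asarray(X1) - 1
    return alpha[t] + beta[t] * np.asarray(X2)


def log_posterior(params: dict, data: ModelData, spec: ModelSpec) -> float:
    """Joint log density at natural-space parameters.

    ``params`` carries ``alpha`` (2), ``beta`` (2), ``sigma`` (1/2/4 per the
    variance structure), ``tau`` (4) and ``lam`` (one per observed cell, in
    cell order).  Out-of-support parameters (negative SDs, negative alpha)
    return ``-inf``.  No change-of-variable Jacobian is included.
    """
    alpha = np.asarray(params["alpha"], dtype=float)
    beta = np.asarray(params["beta"], dtype=float)
    tau_full = (np.asarray(spec.fixed_tau, float) if spec.fixed_tau is not None
                else np.asarray(params["tau"], dtype=float))
    sigma = (np.asarray(spec.fixed_sigma, float) if spec.fixed_sigma is not None
             else np.asarray(params["sigma"], dtype=float))
    lam = np.asarray(params["lam"], dtype=float)
    if alpha.shape != (2,) or beta.shape != (2,):
        raise ValueError("alpha and beta must each have 2 entries")
    if sigma.shape != (spec.n_sigma,):
        raise ValueError(f"sigma must have {spec.n_sigma} entries")
    if tau_full.shape != (4,):
        raise ValueError("tau must have 4 entries")
    if lam.shape != (data.n_cells,):
        raise ValueError(f"lam must have one entry per cell ({data.n_cells})")
    if np.any(sigma <= 0) or np.any(tau_full <= 0) or np.any(alpha < 0):
        return -np.inf

    vg = np.asarray(spec.vargroup)
    sig_cell = sigma[vg[data.cell_group]]
    quad = data.cell_sumsq - 2.0 * lam * data.cell_sum + data.cell_n * lam * lam
    lp = float(
        np.sum(-data.cell_n * np.log(sig_cell)
               - 0.5 * data.cell_n * _LOG_2PI
               - quad / (2.0 * sig_cell**2))
    )

    nu = _nu(alpha, beta)
    tau_cell = tau_full[data.cell_group]
    dev = lam - nu[data.cell_group]
    lp += float(np.sum(-np.log(tau_cell) - 0.5 * _LOG_2PI
                       - dev**2 / (2.0 * tau_cell**2)))

    A = spec.prior_alpha_sd
    lp += float(np.sum(0.5 * math.log(2.0 / math.pi) - math.log(A)
                       - alpha**2 / (2.0 * A * A)))
    B = spec.beta_sd
    lp += float(np.sum(-math.log(B) - 0.5 * _LOG_2PI - beta**2 / (2.0 * B * B)))
    if spec.fixed_sigma is None:
        th = spec.sigma_scale
        lp += float(np.sum(-math.log(th) - sigma / th))
    if spec.fixed_tau is None:
        th = spec.tau_scale
        lp += float(np.sum(-math.log(th) - tau_full / th))
    return lp


class UnconstrainedPosterior:
    """Log posterior and gradient on the unconstrained parameterization.

    Positive parameters are log-transformed (``alpha = exp(a)`` etc.) and
    the log-Jacobian of the transform is added, so the transformed density
    is what NUTS and the MAP optimizer work with.  The parameter vector is
    ``[a(2), beta(2), log_sigma(K?), log_tau(4?), lam(C)]`` with the sigma
    and/or tau blocks absent when frozen by the spec.
    """

    def __init__(self, data: ModelData, spec: ModelSpec):
        self.data = data
        self.spec = spec
        self.K = spec.n_sigma
        self.has_sigma = spec.fixed_sigma is None
        self.has_tau = spec.fixed_tau is None
        i = 4
        if self.has_sigma:
            self.sl_sigma = slice(i, i + self.K)
            i += self.K
        if self.has_tau:
            self.sl_tau = slice(i, i + 4)
            i += 4
        self.sl_lam = slice(i, i + data.n_cells)
        self.dim = i + data.n_cells
        self._vg_cell = np.asarray(spec.vargroup)[data.cell_group]
        self._x1 = np.asarray(X1) - 1
        self._x2 = np.asarray(X2, dtype=float)

    # --- packing helpers ---------------------------------------------------

    def pack(self, params: dict) -> np.ndarray:
        z = np.empty(self.dim)
        z[0:2] = np.log(np.maximum(params["alpha"], 1e-300))
        z[2:4] = params["beta"]
        if self.has_sigma:
            z[self.sl_sigma] = np.log(params["sigma"])
        if self.has_tau:
            z[self.sl_tau] = np.log(params["tau"])
        z[self.sl_lam] = params["lam"]
        return z

    def unpack(self, z: np.ndarray) -> dict:
        out = {
            "alpha": np.exp(z[0:2]),
            "beta": np.array(z[2:4]),
            "lam": np.array(z[self.sl_lam]),
        }
        out["sigma"] = (np.exp(z[self.sl_sigma]) if self.has_sigma
                        else np.asarray(self.spec.fixed_sigma, float))
        out["tau"] = (np.exp(z[self.sl_tau]) if self.has_tau
                      else np.asarray(self.spec.fixed_tau, float))
        return out

    # --- density -----------------------------------------------------------

    def value_and_grad(self, z: np.ndarray) -> tuple[float, np.ndarray]:
        d, spec = self.data, self.spec
        alpha = np.exp(z[0:2])
        beta = z[2:4]
        sigma = np.exp(z[self.sl_sigma]) if self.has_sigma else np.asarray(spec.fixed_sigma, float)
        tau = np.exp(z[self.sl_tau]) if self.has_tau else np.asarray(spec.fixed_tau, float)
        lam = z[self.sl_lam]
        grad = np.zeros_like(z)

        # observation likelihood via per-cell sufficient statistics
        sig_cell = sigma[self._vg_cell]
        inv2 = 1.0 / sig_cell**2
        quad = d.cell_sumsq - 2.0 * lam * d.cell_sum + d.cell_n * lam * lam
        lp = np.sum(-d.cell_n * np.log(sig_cell) - 0.5 * d.cell_n * _LOG_2PI
                    - 0.5 * quad * inv2)
        dlam = (d.cell_sum - d.cell_n * lam) * inv2
        if self.has_sigma:
            dsig = np.bincount(
                self._vg_cell,
                weights=-d.cell_n / sig_cell + quad / sig_cell**3,
                minlength=self.K,
            )

        # replicate-level means
        nu = alpha[self._x1] + beta[self._x1] * self._x2
        tau_cell = tau[d.cell_group]
        dev = lam - nu[d.cell_group]
        lp += np.sum(-np.log(tau_cell) - 0.5 * _LOG_2PI - 0.5 * dev**2 / tau_cell**2)
        w = dev / tau_cell**2
        dlam += -w
        dnu = np.bincount(d.cell_group, weights=w, minlength=4)
        dalpha = np.bincount(self._x1, weights=dnu, minlength=2)
        dbeta = np.bincount(self._x1, weights=dnu * self._x2, minlength=2)
        if self.has_tau:
            dtau_cell = -1.0 / tau_cell + dev**2 / tau_cell**3
            dtau = np.bincount(d.cell_group, weights=dtau_cell, minlength=4)

        # priors
        A = spec.prior_alpha_sd
        lp += np.sum(0.5 * math.log(2.0 / math.pi) - math.log(A)
                     - alpha**2 / (2.0 * A * A))
        dalpha += -alpha / (A * A)
        B = spec.beta_sd
        lp += np.sum(-math.log(B) - 0.5 * _LOG_2PI - beta**2 / (2.0 * B * B))
        dbeta += -beta / (B * B)
        if self.has_sigma:
            th = spec.sigma_scale
            lp += np.sum(-math.log(th) - sigma / th)
            dsig += -1.0 / th
        if self.has_tau:
            th = spec.tau_scale
            lp += np.sum(-math.log(th) - tau / th)
            dtau += -1.0 / th

        # log-Jacobian of exp transforms: + sum of transformed coordinates
        lp += np.sum(z[0:2])
        grad[0:2] = dalpha * alpha + 1.0
        grad[2:4] = dbeta
        if self.has_sigma:
            lp += np.sum(z[self.sl_sigma])
            grad[self.sl_sigma] = dsig * sigma + 1.0
        if self.has_tau:
            lp += np.sum(z[self.sl_tau])
            grad[self.sl_tau] = dtau * tau + 1.0
        grad[self.sl_lam] = dlam
        return float(lp), grad

    def value(self, z: np.ndarray) -> float:
        return self.value_and_grad(z)[0]

    # --- initialization ----------------------------------------------------

    def initial_point(self, rng: np.random.Generator, jitter: float = 0.5) -> np.ndarray:
        """Data-informed start: cell means for lambda, moment estimates for
        the rest, jittered on the unconstrained scale."""
        d = self.data
        means = d.cell_means()
        type_of_group = np.asarray(X1) - 1
        grand = np.zeros(2)
        for t in (0, 1):
            mask = type_of_group[d.cell_group] == t
            grand[t] = means[mask].mean() if mask.any() else max(d.y.mean(), 0.1)
        grand = np.maximum(grand, 1e-3)
        z = np.empty(self.dim)
        z[0:2] = np.log(grand)
        z[2:4] = 0.0
        if self.has_sigma:
            resid = d.y - means[d.obs_cell]
            pooled = max(float(np.std(resid)), 1e-3)
            z[self.sl_sigma] = math.log(pooled)
        if self.has_tau:
            spread = max(float(np.std(means)) * 0.5, 1e-3)
            z[self.sl_tau] = math.log(spread)
        z[self.sl_lam] = means
        if jitter > 0:
            z = z + rng.normal(0.0, jitter * 0.1, size=self.dim)
        return z
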