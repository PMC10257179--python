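"""Bayesian linear mixed model with pooled-control borrowing.

The outcome of rat j in experiment i is modelled as

    y_ij = mu + alpha_i + sum_k beta_k 1{Trt_ij = k} + eps_ij,
    alpha_i ~ N(0, tau^2),  eps_ij ~ N(0, sigma^2),

where mu is the grand control mean, alpha_i a per-experiment random baseline
shift and beta_k the fixed effect of treatment k relative to control
(beta_control = 0 by reference coding). Fitting the model to the whole trial
lets every control animal — concurrent or not — inform mu and tau, so each
treatment is judged against the pooled control experience while experiment-
to-experiment drift is absorbed by alpha.

Priors are improper flat on the locations (mu, beta). The scale parameters
default to flat-on-SD priors (proper posterior with the trial's ~20
experiments); a half-Cauchy alternative is available for small numbers of
experiments. Sampling is blocked Gibbs: (mu, beta) jointly from their Normal
full conditional, each alpha_i from its Normal full conditional, and the
variances from their conditional inverse-gamma forms (exact under both prior
choices via the inverse-gamma mixture representation of the half-Cauchy).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .io import CONTROL_LABEL, TrialDataset


class ModelError(ValueError):
    pass


@dataclass
class McmcConfig:
    """Chain protocol; defaults are 4 chains of 10,000 with 5,000 burn-in."""

    n_chains: int = 4
    n_iter: int = 10_000
    n_burnin: int = 5_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_burnin < self.n_iter:
            raise ModelError("need 0 <= n_burnin < n_iter")
        if self.n_chains < 1:
            raise ModelError("need at least one chain")


@dataclass
class PriorConfig:
    """Flat priors on locations; configurable prior for the SDs."""

    scale_prior: str = "flat_on_sd"  # or "half_cauchy"
    half_cauchy_scale: float = 10.0

    def __post_init__(self) -> None:
        if self.scale_prior not in ("flat_on_sd", "half_cauchy"):
            raise ModelError(f"unknown scale prior {self.scale_prior!r}")


@dataclass
class ModelSpec:
    prior: PriorConfig = field(default_factory=PriorConfig)
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    #: fix sigma at a known value (conjugate test mode); None = sample it
    fixed_sigma: float | None = None
    #: fix tau (0 disables the random effect); None = sample it
    fixed_tau: float | None = None


@dataclass
class PosteriorDraws:
    """Retained MCMC draws with chain structure.

    Arrays are shaped ``(n_chains, n_retained)`` for scalars and
    ``(n_chains, n_retained, dim)`` for vectors; units are percentage points.
    ``alpha``/``tau`` are None for single-experiment (concurrent) fits.
    """

    mu: np.ndarray
    beta: np.ndarray
    sigma: np.ndarray
    treatment_labels: tuple[str, ...]
    alpha: np.ndarray | None = None
    tau: np.ndarray | None = None
    experiment_labels: tuple[str, ...] = ()
    analysis: str = "pooled"

    @property
    def n_draws(self) -> int:
        return int(self.mu.size)

    def beta_draws(self, treatment: str) -> np.ndarray:
        """Flattened draws of one treatment effect (chains concatenated)."""
        try:
            k = self.treatment_labels.index(treatment)
        except ValueError:
            raise KeyError(f"no draws for treatment {treatment!r}") from None
        return self.beta[:, :, k].reshape(-1)

    def to_dict(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {"mu": self.mu, "sigma": self.sigma}
        for k, lab in enumerate(self.treatment_labels):
            out[f"beta[{lab}]"] = self.beta[:, :, k]
        if self.tau is not None:
            out["tau"] = self.tau
        if self.alpha is not None:
            for i, lab in enumerate(self.experiment_labels):
                out[f"alpha[{lab}]"] = self.alpha[:, :, i]
        return out


def _design(dataset: TrialDataset):
    df = dataset.records
    y = df["area_loss_pct"].to_numpy(float)
    treatments = sorted(set(df["treatment"]) - {CONTROL_LABEL})
    x = np.zeros((len(df), 1 + len(treatments)))
    x[:, 0] = 1.0
    for k, lab in enumerate(treatments):
        x[:, 1 + k] = (df["treatment"] == lab).to_numpy()
    experiments = sorted(df["experiment_id"].unique())
    exp_idx = df["experiment_id"].map({e: i for i, e in enumerate(experiments)})
    return y, x, tuple(treatments), np.asarray(exp_idx), tuple(experiments)


def _draw_variance(rng, shape_base, ss, prior: PriorConfig, aux):
    """One conditional draw of a variance and its half-Cauchy auxiliary.

    flat_on_sd: p(s) ~ 1 on the SD gives s^2 | . ~ InvGamma((m-1)/2, ss/2)
    where m is the number of contributing terms. half_cauchy(A) uses the
    InvGamma mixture s^2 | a ~ IG((m+1)/2, ss/2 + 1/a), a | s^2 ~
    IG(1, 1/A^2 + 1/s^2).
    """
    if prior.scale_prior == "flat_on_sd":
        shape = (shape_base - 1) / 2.0
        scale = ss / 2.0
        var = scale / rng.gamma(shape) if scale > 0 else 1e-12
        return max(var, 1e-12), aux
    a2 = prior.half_cauchy_scale**2
    var = (ss / 2.0 + 1.0 / aux) / rng.gamma((shape_base + 1) / 2.0)
    var = max(var, 1e-12)
    aux = (1.0 / a2 + 1.0 / var) / rng.gamma(1.0)
    return var, aux


def _gibbs_chain(
    y, x, exp_idx, n_exp, spec: ModelSpec, rng, include_alpha: bool
):
    n, p = x.shape
    xtx = x.T @ x
    chol = linalg.cho_factor(xtx, lower=True)
    l_upper = linalg.cholesky(xtx, lower=False)
    xt = x.T

    data_sd = float(np.std(y)) or 1.0
    theta = linalg.cho_solve(chol, xt @ y)
    theta = theta + rng.normal(0.0, 0.1 * data_sd, size=p)  # overdispersed start
    sigma2 = (spec.fixed_sigma**2) if spec.fixed_sigma is not None else max(
        data_sd**2 * float(np.exp(rng.normal(0.0, 0.3))), 1e-8
    )
    if spec.fixed_tau is not None:
        tau2 = spec.fixed_tau**2
    else:
        tau2 = max((data_sd / 2.0) ** 2 * float(np.exp(rng.normal(0.0, 0.3))), 1e-8)
    alpha = np.zeros(n_exp)
    counts = np.bincount(exp_idx, minlength=n_exp).astype(float) if include_alpha else None
    aux_s = aux_t = 1.0

    cfg = spec.mcmc
    keep = cfg.n_iter - cfg.n_burnin
    out_theta = np.empty((keep, p))
    out_sigma = np.empty(keep)
    out_alpha = np.empty((keep, n_exp)) if include_alpha else None
    out_tau = np.empty(keep) if include_alpha else None

    for it in range(cfg.n_iter):
        ystar = y - (alpha[exp_idx] if include_alpha else 0.0)
        mean = linalg.cho_solve(chol, xt @ ystar)
        z = rng.standard_normal(p)
        theta = mean + np.sqrt(sigma2) * linalg.solve_triangular(l_upper, z, lower=False)

        r = y - x @ theta
        if include_alpha:
            if tau2 > 0:
                prec = counts / sigma2 + 1.0 / tau2
                mean_a = (np.bincount(exp_idx, weights=r, minlength=n_exp) / sigma2) / prec
                alpha = mean_a + rng.standard_normal(n_exp) / np.sqrt(prec)
            else:
                alpha = np.zeros(n_exp)
            resid = r - alpha[exp_idx]
        else:
            resid = r

        if spec.fixed_sigma is None:
            sigma2, aux_s = _draw_variance(
                rng, n, float(resid @ resid), spec.prior, aux_s
            )
        if include_alpha and spec.fixed_tau is None:
            tau2, aux_t = _draw_variance(
                rng, n_exp, float(alpha @ alpha), spec.prior, aux_t
            )

        if it >= cfg.n_burnin:
            k = it - cfg.n_burnin
            out_theta[k] = theta
            out_sigma[k] = np.sqrt(sigma2)
            if include_alpha:
                out_alpha[k] = alpha
                out_tau[k] = np.sqrt(tau2)
    return out_theta, out_sigma, out_alpha, out_tau


def _fit(dataset: TrialDataset, spec: ModelSpec, include_alpha: bool, analysis: str):
    y, x, treatments, exp_idx, experiments = _design(dataset)
    n_exp = len(experiments)
    if x.shape[0] <= x.shape[1]:
        raise ModelError("more parameters than observations")
    cfg = spec.mcmc
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_chains)
    keep = cfg.n_iter - cfg.n_burnin
    p = x.shape[1]
    mu = np.empty((cfg.n_chains, keep))
    beta = np.empty((cfg.n_chains, keep, p - 1))
    sigma = np.empty((cfg.n_chains, keep))
    alpha = np.empty((cfg.n_chains, keep, n_exp)) if include_alpha else None
    tau = np.empty((cfg.n_chains, keep)) if include_alpha else None
    for c in range(cfg.n_chains):
        rng = np.random.default_rng(seeds[c])
        th, sg, al, tu = _gibbs_chain(y, x, exp_idx, n_exp, spec, rng, include_alpha)
        mu[c] = th[:, 0]
        beta[c] = th[:, 1:]
        sigma[c] = sg
        if include_alpha:
            alpha[c] = al
            tau[c] = tu
    return PosteriorDraws(
        mu=mu,
        beta=beta,
        sigma=sigma,
        treatment_labels=treatments,
        alpha=alpha,
        tau=tau,
        experiment_labels=experiments if include_alpha else (),
        analysis=analysis,
    )


def fit_pooled(dataset: TrialDataset, spec: ModelSpec | None = None) -> PosteriorDraws:
    """Fit the borrowing model to the full trial.

    Every control animal across every experiment informs mu and tau; each
    beta_k is informed by its own experiment(s) plus the borrowed controls.
    Requires at least two experiments (tau is not identifiable from one).
    """
    spec = spec or ModelSpec()
    if len(dataset.experiments) < 2:
        raise ModelError("pooled fit needs >= 2 experiments; use fit_concurrent")
    return _fit(dataset, spec, include_alpha=True, analysis="pooled")


def fit_concurrent(
    dataset: TrialDataset, experiment_id: str, spec: ModelSpec | None = None
) -> PosteriorDraws:
    """Fit the single-experiment counterpart (no random effect).

    Restricted to one experiment the baseline shift alpha_i is not
    identifiable, so the model reduces to y = mu + beta_k + eps with the same
    priors and sampler; the result is the concurrent-control comparison.
    """
    spec = spec or ModelSpec()
    sub = dataset.experiment(experiment_id)
    if not (sub["treatment"] == CONTROL_LABEL).any():
        raise ModelError(f"experiment {experiment_id!r} lacks a control arm")
    if set(sub["treatment"]) == {CONTROL_LABEL}:
        raise ModelError(f"experiment {experiment_id!r} has no treated arm")
    ds = TrialDataset(sub.reset_index(drop=True), [f"concurrent subset {experiment_id}"])
    return _fit(ds, spec, include_alpha=False, analysis="concurrent")


def convergence_diagnostics(draws: PosteriorDraws) -> dict[str, dict[str, float]]:
    """Split R-hat and rank-normalised bulk ESS per parameter (via ArviZ).

    Flags parameters with R-hat > 1.01 or ESS < 400. With a single chain only
    ESS is reported.
    """
    import arviz as az

    data = draws.to_dict()
    out: dict[str, dict[str, float]] = {}
    single_chain = draws.mu.shape[0] < 2
    for name, arr in data.items():
        arr = np.asarray(arr)
        if np.ptp(arr) == 0:  # constant parameter (e.g. fixed sigma)
            out[name] = {"ess": float(arr.size), "rhat": 1.0, "flagged": 0.0}
            continue
        ess = float(az.ess(np.asarray(arr)))
        entry: dict[str, float] = {"ess": ess}
        if not single_chain:
            entry["rhat"] = float(az.rhat(np.asarray(arr)))
            entry["flagged"] = float(entry["rhat"] > 1.01 or ess < 400)
        else:
            entry["flagged"] = float(ess < 400)
        out[name] = entry
    return out
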