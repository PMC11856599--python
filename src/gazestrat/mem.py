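"""Multi-strategy eye-tracking mixture model (MEM).

A two-component mixture item-response model for binary accuracies ``Y_ij`` of
participant ``i`` on item ``j``:

    P(Y_ij = 1 | theta_i) = P(m_ij = 1) * expit(theta_i - b_j + e_j)
                          + P(m_ij = 2) * expit(theta_i - b_j)

where component ``m = 1`` is constructive matching (CM) and ``m = 2`` is
response elimination (RE). The sensitivity ``e_j >= 0`` is the gain in success
probability from using CM on item ``j``, so the CM success probability never
falls below the RE one. Strategy selection is a logistic function of
per-item-standardized eye metrics ``f_kij`` (by default PTM, ROT, RLT):

    P(m_ij = 1) = expit(sum_k omega_k * f_kij)

Estimation is Bayesian via adaptive random-walk Metropolis-within-Gibbs with
weakly informative priors: theta ~ N(0,1) (fixes the latent scale),
b ~ N(0, 2), e ~ HalfNormal(2), omega ~ N(0, 2). Per-trial strategies are
identified from the posterior of ``P(m_ij = 1)`` by either a cut-off rule on
the posterior mean or a highest-posterior-density (HPD) interval rule; trials
whose posterior straddles 0.5 are labelled isolate-and-eliminate (IE).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .metrics import standardize_per_item

__all__ = [
    "DEFAULT_METRICS",
    "ALT_METRICS",
    "MemData",
    "MemParameters",
    "SamplerConfig",
    "MemPosterior",
    "StrategyLabels",
    "selection_probability",
    "success_probability",
    "log_likelihood",
    "fit",
    "hpd_interval",
    "identify_cutoff",
    "identify_hpd",
]

#: metric set of the selection model: PTM, ROT, RLT
DEFAULT_METRICS = ("ptm", "rot", "rlt")
#: documented preset matching the three features selected by the forest
ALT_METRICS = ("ptm", "rlt", "lft")

_TINY = 1e-300


@dataclass
class MemData:
    """Responses and standardized eye metrics for the mixture model."""

    y: np.ndarray  # (I, J) int, 0/1; arbitrary at masked cells
    f: np.ndarray  # (I, J, K) per-item-standardized metrics
    mask: np.ndarray  # (I, J) bool, True = observed
    metric_names: tuple[str, ...]
    participant_ids: list[str] = field(default_factory=list)
    item_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.int64)
        self.f = np.asarray(self.f, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        I, J = self.y.shape
        if self.f.shape[:2] != (I, J):
            raise ValueError("y and f disagree on (I, J)")
        if self.mask.shape != (I, J):
            raise ValueError("mask shape mismatch")
        observed = self.y[self.mask]
        if observed.size and not np.isin(observed, (0, 1)).all():
            raise ValueError("y must be binary")
        if not self.participant_ids:
            self.participant_ids = [f"p{i+1:03d}" for i in range(I)]
        if not self.item_ids:
            self.item_ids = [f"i{j+1:02d}" for j in range(J)]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.f.shape

    @classmethod
    def from_features(
        cls, features: pd.DataFrame, metrics: Sequence[str] = DEFAULT_METRICS
    ) -> "MemData":
        """Build model data from a long feature table, standardizing per item."""
        std = standardize_per_item(features, list(metrics))
        pids = list(dict.fromkeys(features["participant_id"]))
        iids = list(dict.fromkeys(features["item_id"]))
        I, J, K = len(pids), len(iids), len(metrics)
        pidx = {p: i for i, p in enumerate(pids)}
        iidx = {it: j for j, it in enumerate(iids)}
        y = np.zeros((I, J), dtype=np.int64)
        f = np.zeros((I, J, K))
        mask = np.zeros((I, J), dtype=bool)
        rows_i = features["participant_id"].map(pidx).to_numpy()
        rows_j = features["item_id"].map(iidx).to_numpy()
        y[rows_i, rows_j] = features["ra"].to_numpy(dtype=np.int64)
        for k, m in enumerate(metrics):
            f[rows_i, rows_j, k] = std[m].to_numpy(dtype=float)
        mask[rows_i, rows_j] = True
        return cls(
            y=y,
            f=f,
            mask=mask,
            metric_names=tuple(metrics),
            participant_ids=[str(p) for p in pids],
            item_ids=[str(it) for it in iids],
        )


@dataclass
class MemParameters:
    theta: np.ndarray  # (I,)
    b: np.ndarray  # (J,)
    e: np.ndarray  # (J,) >= 0
    omega: np.ndarray  # (K,)

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        self.e = np.asarray(self.e, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        if (self.e < 0).any():
            raise ValueError("e must be non-negative")


def selection_probability(omega: np.ndarray, f_ij: np.ndarray) -> np.ndarray:
    """P(m = 1): logistic in the weighted standardized metrics.

    ``f_ij`` may be a single metric vector of length K or an array whose last
    axis has length K; the complement is P(m = 2).
    """
    omega = np.asarray(omega, dtype=float)
    f_ij = np.asarray(f_ij, dtype=float)
    if f_ij.shape[-1] != omega.shape[0]:
        raise ValueError("omega and f_ij length mismatch")
    return expit(f_ij @ omega)


def success_probability(theta, b, e, m: int):
    """P(Y = 1 | theta, m): expit(theta - b + e) for CM, expit(theta - b) for RE."""
    e = np.asarray(e, dtype=float)
    if (e < 0).any():
        raise ValueError("e must be non-negative")
    if m == 1:
        return expit(np.asarray(theta, dtype=float) - b + e)
    if m == 2:
        return expit(np.asarray(theta, dtype=float) - np.asarray(b, dtype=float))
    raise ValueError("m must be 1 or 2")


def _cell_loglik(y, mask, theta, b, e, p_cm):
    eta = theta[:, None] - b[None, :]
    p1 = expit(eta + e[None, :])
    p2 = expit(eta)
    b1 = np.where(y == 1, p1, 1.0 - p1)
    b2 = np.where(y == 1, p2, 1.0 - p2)
    lik = p_cm * b1 + (1.0 - p_cm) * b2
    ll = np.log(np.maximum(lik, _TINY))
    return np.where(mask, ll, 0.0)


def log_likelihood(params: MemParameters, data: MemData) -> float:
    """Observed-data log likelihood of the two-component mixture."""
    I, J, K = data.shape
    if params.theta.shape[0] != I or params.b.shape[0] != J:
        raise ValueError("parameter/data shape mismatch")
    if params.e.shape[0] != J or params.omega.shape[0] != K:
        raise ValueError("parameter/data shape mismatch")
    p_cm = selection_probability(params.omega, data.f)
    return float(
        _cell_loglik(data.y, data.mask, params.theta, params.b, params.e, p_cm).sum()
    )


@dataclass(frozen=True)
class SamplerConfig:
    chains: int = 4
    iterations: int = 5000
    burn_in: int | None = None  # default: iterations // 2
    seed: int = 0
    target_accept: float = 0.44
    prior_sd: float = 2.0  # sd of the b, e (half-normal) and omega priors

    def resolved_burn_in(self) -> int:
        return self.iterations // 2 if self.burn_in is None else self.burn_in


@dataclass
class StrategyLabels:
    """Per-trial strategy assignments and the rule that produced them."""

    labels: np.ndarray  # (I, J) of {"CM", "RE", "IE", "NA"}
    rule: str  # "cutoff" | "hpd"
    rule_params: dict
    participant_ids: list[str] = field(default_factory=list)
    item_ids: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        I, J = self.labels.shape
        pids = self.participant_ids or [f"p{i+1:03d}" for i in range(I)]
        iids = self.item_ids or [f"i{j+1:02d}" for j in range(J)]
        return pd.DataFrame(
            {
                "participant_id": np.repeat(pids, J),
                "item_id": np.tile(iids, I),
                "label": self.labels.ravel(),
                "rule": self.rule,
            }
        )


class MemPosterior:
    """Posterior draws of the mixture model, kept per chain.

    Draw arrays have shape (chains, draws, ...). The derived strategy
    probability P(m_ij = 1) depends on the draws only through omega, so it is
    computed on demand (per item) rather than stored for every draw.
    """

    def __init__(self, data, theta, b, e, omega, diagnostics, accept_rates):
        self.data = data
        self.theta = theta
        self.b = b
        self.e = e
        self.omega = omega
        self.diagnostics = diagnostics
        self.accept_rates = accept_rates

    @property
    def n_draws(self) -> int:
        return self.theta.shape[0] * self.theta.shape[1]

    @property
    def theta_mean(self) -> np.ndarray:
        return self.theta.mean(axis=(0, 1))

    @property
    def b_mean(self) -> np.ndarray:
        return self.b.mean(axis=(0, 1))

    @property
    def e_mean(self) -> np.ndarray:
        return self.e.mean(axis=(0, 1))

    @property
    def omega_mean(self) -> np.ndarray:
        return self.omega.mean(axis=(0, 1))

    def _omega_flat(self) -> np.ndarray:
        C, S, K = self.omega.shape
        return self.omega.reshape(C * S, K)

    def p_cm_draws_item(self, j: int) -> np.ndarray:
        """Draws of P(m = 1) for item ``j``; shape (I, total draws)."""
        W = self._omega_flat()  # (S*, K)
        return expit(self.data.f[:, j, :] @ W.T)

    def p_cm_mean(self) -> np.ndarray:
        """Posterior mean of P(m_ij = 1); shape (I, J)."""
        I, J, _ = self.data.shape
        out = np.empty((I, J))
        for j in range(J):
            out[:, j] = self.p_cm_draws_item(j).mean(axis=1)
        return out

    def to_frame(self, thin: int = 1) -> pd.DataFrame:
        """Long-format draws (chain, draw, parameter, value), optionally thinned."""
        recs = []
        C, S = self.theta.shape[:2]
        draw_idx = np.arange(0, S, thin)
        names = (
            [f"theta[{p}]" for p in self.data.participant_ids]
            + [f"b[{it}]" for it in self.data.item_ids]
            + [f"e[{it}]" for it in self.data.item_ids]
            + [f"omega[{m}]" for m in self.data.metric_names]
        )
        stacked = np.concatenate(
            [self.theta, self.b, self.e, self.omega], axis=2
        )  # (C, S, P)
        for c in range(C):
            for s in draw_idx:
                vals = stacked[c, s]
                recs.append(
                    pd.DataFrame(
                        {
                            "chain": c,
                            "draw": int(s),
                            "parameter": names,
                            "value": vals,
                        }
                    )
                )
        return pd.concat(recs, ignore_index=True)


def _compute_diagnostics(theta, b, e, omega) -> dict:
    import arviz as az

    ds = az.from_dict(posterior={"theta": theta, "b": b, "e": e, "omega": omega})
    rhat = az.rhat(ds)
    ess = az.ess(ds)
    out = {}
    for name in ("theta", "b", "e", "omega"):
        out[name] = {
            "rhat": np.asarray(rhat[name]).tolist(),
            "ess_bulk": np.asarray(ess[name]).tolist(),
        }
    max_rhat = max(
        float(np.nanmax(np.asarray(rhat[name]))) for name in ("theta", "b", "e", "omega")
    )
    out["max_rhat"] = max_rhat
    return out


def fit(data: MemData, config: SamplerConfig = SamplerConfig()) -> MemPosterior:
    """Sample the posterior by adaptive Metropolis-within-Gibbs.

    One iteration updates theta (all participants in parallel, each against
    its own row of the likelihood), b and e (per item, column-wise), and each
    omega_k against the full table. Proposal scales adapt towards
    ``target_accept`` during burn-in only, so the post-burn-in chain is a
    valid time-homogeneous Metropolis sampler. Non-convergence (any split-Rhat
    above 1.1) is a warning, not an error.
    """
    I, J, K = data.shape
    if I < 2 or J < 2:
        raise ValueError("need at least 2 participants and 2 items")
    burn = config.resolved_burn_in()
    if not 0 < burn < config.iterations:
        raise ValueError("burn_in must be in (0, iterations)")
    S = config.iterations - burn
    C = config.chains
    th_draws = np.empty((C, S, I))
    b_draws = np.empty((C, S, J))
    e_draws = np.empty((C, S, J))
    om_draws = np.empty((C, S, K))
    accept_rates = {}
    prior_var = config.prior_sd**2

    root = np.random.SeedSequence(config.seed)
    for c, ss in enumerate(root.spawn(C)):
        rng = np.random.default_rng(ss)
        theta = rng.normal(0.0, 1.0, I)
        b = rng.normal(0.0, 1.0, J)
        e = np.abs(rng.normal(0.0, 1.0, J))
        omega = rng.normal(0.0, 1.0, K)
        sc_th = np.full(I, 0.5)
        sc_b = np.full(J, 0.5)
        sc_e = np.full(J, 0.5)
        sc_om = np.full(K, 0.3)
        p_cm = selection_probability(omega, data.f)
        L = _cell_loglik(data.y, data.mask, theta, b, e, p_cm)
        acc_counts = np.zeros(4)
        for t in range(config.iterations):
            adapting = t < burn
            gamma = (t + 1) ** -0.6 if adapting else 0.0

            # --- theta (row-wise) ---
            prop = theta + sc_th * rng.standard_normal(I)
            L_prop = _cell_loglik(data.y, data.mask, prop, b, e, p_cm)
            ratio = (
                L_prop.sum(axis=1)
                - L.sum(axis=1)
                - 0.5 * (prop**2 - theta**2)  # theta ~ N(0, 1)
            )
            acc = np.log(rng.random(I)) < ratio
            theta = np.where(acc, prop, theta)
            L[acc, :] = L_prop[acc, :]
            if adapting:
                sc_th *= np.exp(gamma * (acc - config.target_accept))
            acc_counts[0] += acc.mean()

            # --- b (column-wise) ---
            prop = b + sc_b * rng.standard_normal(J)
            L_prop = _cell_loglik(data.y, data.mask, theta, prop, e, p_cm)
            ratio = (
                L_prop.sum(axis=0)
                - L.sum(axis=0)
                - (prop**2 - b**2) / (2 * prior_var)
            )
            acc = np.log(rng.random(J)) < ratio
            b = np.where(acc, prop, b)
            L[:, acc] = L_prop[:, acc]
            if adapting:
                sc_b *= np.exp(gamma * (acc - config.target_accept))
            acc_counts[1] += acc.mean()

            # --- e (column-wise, rejected below 0) ---
            prop = e + sc_e * rng.standard_normal(J)
            valid = prop >= 0
            prop_eval = np.where(valid, prop, e)
            L_prop = _cell_loglik(data.y, data.mask, theta, b, prop_eval, p_cm)
            ratio = np.where(
                valid,
                L_prop.sum(axis=0)
                - L.sum(axis=0)
                - (prop_eval**2 - e**2) / (2 * prior_var),
                -np.inf,
            )
            acc = np.log(rng.random(J)) < ratio
            e = np.where(acc, prop_eval, e)
            L[:, acc] = L_prop[:, acc]
            if adapting:
                sc_e *= np.exp(gamma * (acc - config.target_accept))
            acc_counts[2] += acc.mean()

            # --- omega (componentwise, full table) ---
            cur_total = L.sum()
            om_acc = 0.0
            for k in range(K):
                prop_om = omega.copy()
                prop_om[k] += sc_om[k] * rng.standard_normal()
                p_prop = selection_probability(prop_om, data.f)
                L_prop = _cell_loglik(data.y, data.mask, theta, b, e, p_prop)
                ratio = (
                    L_prop.sum()
                    - cur_total
                    - (prop_om[k] ** 2 - omega[k] ** 2) / (2 * prior_var)
                )
                accepted = np.log(rng.random()) < ratio
                if accepted:
                    omega = prop_om
                    p_cm = p_prop
                    L = L_prop
                    cur_total = L.sum()
                    om_acc += 1.0
                if adapting:
                    sc_om[k] *= np.exp(gamma * (float(accepted) - config.target_accept))
            acc_counts[3] += om_acc / K

            if t >= burn:
                s = t - burn
                th_draws[c, s] = theta
                b_draws[c, s] = b
                e_draws[c, s] = e
                om_draws[c, s] = omega
        accept_rates[f"chain_{c}"] = dict(
            zip(
                ("theta", "b", "e", "omega"),
                (acc_counts / config.iterations).round(3).tolist(),
            )
        )

    diagnostics = _compute_diagnostics(th_draws, b_draws, e_draws, om_draws)
    if diagnostics["max_rhat"] > 1.1:
        warnings.warn(
            f"possible non-convergence: max split-Rhat = "
            f"{diagnostics['max_rhat']:.3f} > 1.1",
            stacklevel=2,
        )
    return MemPosterior(
        data=data,
        theta=th_draws,
        b=b_draws,
        e=e_draws,
        omega=om_draws,
        diagnostics=diagnostics,
        accept_rates=accept_rates,
    )


def hpd_interval(draws: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``level`` posterior mass (sorted-draw scan)."""
    x = np.sort(np.asarray(draws, dtype=float))
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 draws")
    w = int(np.ceil(level * n))
    w = min(max(w, 1), n)
    if w == n:
        return float(x[0]), float(x[-1])
    widths = x[w - 1 :] - x[: n - w + 1]
    s = int(np.argmin(widths))
    return float(x[s]), float(x[s + w - 1])


def identify_cutoff(post: MemPosterior, cutoff: float = 0.5) -> StrategyLabels:
    """Label trials from the posterior mean of P(m = 1).

    Mean >= cutoff -> CM; mean < 1 - cutoff -> RE; otherwise IE (possible
    only when cutoff > 0.5). Unobserved cells are NA.
    """
    if not 0.0 < cutoff < 1.0:
        raise ValueError("cutoff must be in (0, 1)")
    pm = post.p_cm_mean()
    labels = np.where(pm >= cutoff, "CM", np.where(pm < 1.0 - cutoff, "RE", "IE"))
    labels = labels.astype("<U2")
    labels[~post.data.mask] = "NA"
    return StrategyLabels(
        labels=labels,
        rule="cutoff",
        rule_params={"cutoff": cutoff},
        participant_ids=post.data.participant_ids,
        item_ids=post.data.item_ids,
    )


def identify_hpd(post: MemPosterior, level: float = 0.95) -> StrategyLabels:
    """Label trials from the HPD interval of P(m = 1).

    Interval entirely above 0.5 -> CM; entirely below -> RE; straddling
    (inclusive of exact ties at 0.5) -> IE.
    """
    if post.n_draws < 100:
        raise ValueError("need at least 100 draws for the HPD rule")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    I, J, _ = post.data.shape
    labels = np.full((I, J), "IE", dtype="<U2")
    n = post.n_draws
    w = min(max(int(np.ceil(level * n)), 1), n)
    for j in range(J):
        P = np.sort(post.p_cm_draws_item(j), axis=1)  # (I, n)
        if w == n:
            lo, hi = P[:, 0], P[:, -1]
        else:
            widths = P[:, w - 1 :] - P[:, : n - w + 1]
            s = np.argmin(widths, axis=1)
            rows = np.arange(I)
            lo = P[rows, s]
            hi = P[rows, s + w - 1]
        labels[lo > 0.5, j] = "CM"
        labels[hi < 0.5, j] = "RE"
    labels[~post.data.mask] = "NA"
    return StrategyLabels(
        labels=labels,
        rule="hpd",
        rule_params={"level": level},
        participant_ids=post.data.participant_ids,
        item_ids=post.data.item_ids,
    )
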