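"""Synthetic participants x items datasets with known ground truth.

The generator emulates the structure of an eye-tracked Raven's Advanced
Progressive Matrices study (by default 192 participants x 36 items): each
participant has a latent ability ``theta_i``, each item a difficulty ``b_j``
rising across the test and a non-negative strategy-sensitivity ``e_j``. On
each trial the participant latently chooses constructive matching (CM) or
response elimination (RE) with probability

    P(CM) = expit(lam0 + lam_theta * theta_i - lam_b * b_j),

so able participants use CM more and hard items push towards RE. Eye metrics
are then drawn from strategy-specific profiles (CM: high PTM/RLT, few
toggles; RE: the reverse), and the response is Bernoulli with success
probability expit(theta - b + e) under CM and expit(theta - b) under RE —
the same success model the mixture model estimates. An optional
isolate-and-eliminate (IE) hybrid group draws metrics from the midpoint of
the two profiles.

Fixation streams that reproduce a feature row exactly can be synthesized for
round-trip testing of the metric formulas.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .metrics import FixationEvent, FeatureRow, AOI_MATRIX, AOI_OPTIONS

__all__ = [
    "StrategyProfile",
    "MetricProfiles",
    "SimConfig",
    "SimTruth",
    "FeasibilityError",
    "generate_truth",
    "simulate_features",
    "synthesize_fixations",
    "simulate_dataset",
    "write_dataset",
]

CM, RE, IE = "CM", "RE", "IE"


class FeasibilityError(ValueError):
    """A feature row cannot be realized as an alternating dwell sequence."""


@dataclass(frozen=True)
class StrategyProfile:
    """Metric distribution parameters for one strategy.

    ptm : (alpha, beta) of a Beta distribution for proportional time on matrix
    rlt_frac : (alpha, beta) Beta for the fraction of matrix time spent before
        the first toggle; RLT = rlt_frac * PTM, which keeps LFT <= PTM*RT and
        hence every row feasible as a fixation stream
    rt : (meanlog, sdlog) of a log-normal response time in seconds
    not_rate : Poisson rate; NOT = 1 + Poisson(not_rate)
    """

    ptm: tuple[float, float]
    rlt_frac: tuple[float, float]
    rt: tuple[float, float]
    not_rate: float

    def validate(self) -> None:
        for name, (a, b) in (("ptm", self.ptm), ("rlt_frac", self.rlt_frac)):
            if a <= 0 or b <= 0:
                raise ValueError(f"{name} Beta parameters must be > 0")
        if self.rt[1] <= 0:
            raise ValueError("rt sdlog must be > 0")
        if self.not_rate < 0:
            raise ValueError("not_rate must be >= 0")


def _midpoint(a: StrategyProfile, b: StrategyProfile) -> StrategyProfile:
    """Elementwise-average profile used for the IE hybrid group."""
    return StrategyProfile(
        ptm=((a.ptm[0] + b.ptm[0]) / 2, (a.ptm[1] + b.ptm[1]) / 2),
        rlt_frac=(
            (a.rlt_frac[0] + b.rlt_frac[0]) / 2,
            (a.rlt_frac[1] + b.rlt_frac[1]) / 2,
        ),
        rt=((a.rt[0] + b.rt[0]) / 2, (a.rt[1] + b.rt[1]) / 2),
        not_rate=(a.not_rate + b.not_rate) / 2,
    )


# Default, well-separated profiles. The constructive-matching group dwells on
# the matrix (PTM ~ 0.80, most of it before the first toggle) with few
# toggles and shorter solves; the response-elimination group toggles heavily
# with low PTM/RLT and longer solves.
DEFAULT_CM_PROFILE = StrategyProfile(
    ptm=(16.0, 4.0), rlt_frac=(8.0, 2.0), rt=(np.log(18.0), 0.35), not_rate=2.0
)
DEFAULT_RE_PROFILE = StrategyProfile(
    ptm=(6.0, 9.0), rlt_frac=(2.0, 6.0), rt=(np.log(28.0), 0.35), not_rate=9.0
)


@dataclass(frozen=True)
class MetricProfiles:
    cm: StrategyProfile = DEFAULT_CM_PROFILE
    re: StrategyProfile = DEFAULT_RE_PROFILE

    def validate(self) -> None:
        self.cm.validate()
        self.re.validate()

    def for_strategy(self, strategy: str) -> StrategyProfile:
        if strategy == CM:
            return self.cm
        if strategy == RE:
            return self.re
        if strategy == IE:
            return _midpoint(self.cm, self.re)
        raise ValueError(f"unknown strategy {strategy!r}")


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of the generator."""

    seed: int
    n_participants: int = 192
    n_items: int = 36
    #: (intercept, slope) of item difficulty on the logit scale across items
    difficulty_trend: tuple[float, float] = (-1.0, 0.06)
    #: sd of item-specific noise around the difficulty trend
    difficulty_noise_sd: float = 0.15
    #: half-normal scale of the strategy-sensitivity gain e_j
    sensitivity_scale: float = 1.0
    #: (lam0, lam_theta, lam_b) of the CM-choice logit
    strategy_link: tuple[float, float, float] = (0.5, 1.0, 1.0)
    metric_profiles: MetricProfiles = field(default_factory=MetricProfiles)
    include_hybrid: bool = False
    hybrid_proportion: float = 0.1

    def validate(self) -> None:
        if self.n_participants < 2:
            raise ValueError("n_participants must be >= 2")
        if self.n_items < 2:
            raise ValueError("n_items must be >= 2")
        if self.difficulty_noise_sd < 0:
            raise ValueError("difficulty_noise_sd must be >= 0")
        if self.sensitivity_scale < 0:
            raise ValueError("sensitivity_scale must be >= 0")
        if not 0.0 <= self.hybrid_proportion <= 1.0:
            raise ValueError("hybrid_proportion must be in [0, 1]")
        self.metric_profiles.validate()


@dataclass
class SimTruth:
    """Ground truth behind one simulated dataset."""

    theta: np.ndarray  # (I,) participant ability
    b: np.ndarray  # (J,) item difficulty
    e: np.ndarray  # (J,) non-negative strategy sensitivity
    #: reference contrast direction per metric: sign of E[metric | CM] minus
    #: E[metric | RE] under the generating profiles; the sign each selection
    #: weight should recover
    omega: dict
    strategy: np.ndarray  # (I, J) labels in {CM, RE, IE}

    @property
    def n_participants(self) -> int:
        return self.theta.shape[0]

    @property
    def n_items(self) -> int:
        return self.b.shape[0]


def _profile_metric_means(p: StrategyProfile) -> dict:
    ptm_mean = p.ptm[0] / (p.ptm[0] + p.ptm[1])
    frac_mean = p.rlt_frac[0] / (p.rlt_frac[0] + p.rlt_frac[1])
    rt_mean = float(np.exp(p.rt[0] + p.rt[1] ** 2 / 2))
    not_mean = 1.0 + p.not_rate
    rlt_mean = ptm_mean * frac_mean
    return {
        "ptm": ptm_mean,
        "rlt": rlt_mean,
        "lft": rlt_mean * rt_mean,
        "not": not_mean,
        "rot": not_mean / rt_mean,  # first-order approximation
        "rt": rt_mean,
    }


def generate_truth(config: SimConfig) -> SimTruth:
    """Draw abilities, difficulties, sensitivities and per-trial strategies."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    I, J = config.n_participants, config.n_items
    theta = rng.standard_normal(I)
    intercept, slope = config.difficulty_trend
    b = intercept + slope * np.arange(J) + config.difficulty_noise_sd * rng.standard_normal(J)
    e = config.sensitivity_scale * np.abs(rng.standard_normal(J))
    lam0, lam_theta, lam_b = config.strategy_link
    p_cm = expit(lam0 + lam_theta * theta[:, None] - lam_b * b[None, :])
    strategy = np.where(rng.random((I, J)) < p_cm, CM, RE).astype("<U2")
    if config.include_hybrid and config.hybrid_proportion > 0:
        hybrid = rng.random((I, J)) < config.hybrid_proportion
        strategy[hybrid] = IE
    means_cm = _profile_metric_means(config.metric_profiles.cm)
    means_re = _profile_metric_means(config.metric_profiles.re)
    omega = {
        m: float(np.sign(means_cm[m] - means_re[m]))
        for m in ("ptm", "rlt", "lft", "not", "rot", "rt")
    }
    return SimTruth(theta=theta, b=b, e=e, omega=omega, strategy=strategy)


def _success_probability(theta, b, e, strategy):
    p_cm = expit(theta - b + e)
    p_re = expit(theta - b)
    p = np.where(strategy == CM, p_cm, p_re)
    return np.where(strategy == IE, (p_cm + p_re) / 2, p)


def simulate_features(truth: SimTruth, config: SimConfig) -> pd.DataFrame:
    """Emit the per-trial feature table implied by the ground truth.

    Every row is feasible for :func:`synthesize_fixations`: LFT = RLT*RT,
    RLT <= PTM, and RLT == PTM exactly on single-toggle trials.
    """
    config.validate()
    I, J = config.n_participants, config.n_items
    if truth.strategy.shape != (I, J):
        raise ValueError("truth and config disagree on dimensions")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    strategy = truth.strategy
    ptm = np.empty((I, J))
    frac = np.empty((I, J))
    rt = np.empty((I, J))
    not_ = np.empty((I, J), dtype=np.int64)
    for s in (CM, RE, IE):
        mask = strategy == s
        n = int(mask.sum())
        if n == 0:
            continue
        prof = config.metric_profiles.for_strategy(s)
        ptm[mask] = rng.beta(*prof.ptm, size=n)
        frac[mask] = rng.beta(*prof.rlt_frac, size=n)
        rt[mask] = rng.lognormal(prof.rt[0], prof.rt[1], size=n)
        not_[mask] = 1 + rng.poisson(prof.not_rate, size=n)

    rlt = frac * ptm
    # a single-toggle trial spends all of its matrix time before the toggle
    rlt[not_ == 1] = ptm[not_ == 1]
    lft = rlt * rt
    rot = not_ / rt
    p_correct = _success_probability(
        truth.theta[:, None], truth.b[None, :], truth.e[None, :], strategy
    )
    ra = (rng.random((I, J)) < p_correct).astype(int)

    pid = np.repeat([f"p{i+1:03d}" for i in range(I)], J)
    iid = np.tile([f"i{j+1:02d}" for j in range(J)], I)
    return pd.DataFrame(
        {
            "participant_id": pid,
            "item_id": iid,
            "ra": ra.ravel(),
            "rt": rt.ravel(),
            "ptm": ptm.ravel(),
            "lft": lft.ravel(),
            "rlt": rlt.ravel(),
            "not": not_.ravel(),
            "rot": rot.ravel(),
        }
    )


def synthesize_fixations(row: FeatureRow | dict, tol: float = 1e-9) -> list[FixationEvent]:
    """Build an alternating matrix/options dwell sequence reproducing a row.

    The sequence starts with a matrix dwell of duration LFT; matrix time after
    the first toggle is split uniformly across the remaining matrix dwells, as
    is options time across options dwells. Feeding the result back through
    :func:`gazestrat.metrics.compute_trial_features` recovers PTM, LFT, RLT,
    NOT and ROT to within 1e-9.
    """
    if isinstance(row, FeatureRow):
        pid, iid = row.participant_id, row.item_id
        rt, ptm, lft, rlt, n_tog = row.rt, row.ptm, row.lft, row.rlt, row.not_
    else:
        pid, iid = str(row["participant_id"]), str(row["item_id"])
        rt, ptm, lft, rlt = (float(row[k]) for k in ("rt", "ptm", "lft", "rlt"))
        n_tog = int(row["not"])
    if rt <= 0:
        raise FeasibilityError("rt must be > 0")
    if not (0 < ptm <= 1):
        raise FeasibilityError("ptm must be in (0, 1]")
    if not (0 < rlt <= 1):
        raise FeasibilityError("rlt must be in (0, 1]")
    if abs(lft - rlt * rt) > tol * max(1.0, rt):
        raise FeasibilityError("lft inconsistent with rlt * rt")
    if n_tog < 0:
        raise FeasibilityError("not must be >= 0")
    matrix_total = ptm * rt
    options_total = rt - matrix_total
    if matrix_total < lft - tol * max(1.0, rt):
        raise FeasibilityError("ptm * rt < lft: not enough matrix time")
    if n_tog == 0:
        if abs(ptm - 1.0) > tol or abs(rlt - 1.0) > tol:
            raise FeasibilityError("zero toggles require ptm = rlt = 1")
        return [FixationEvent(pid, iid, AOI_MATRIX, 0.0, rt)]
    if options_total <= 0:
        raise FeasibilityError("toggling requires options time > 0")
    n_dwell = n_tog + 1
    n_matrix = (n_dwell + 1) // 2
    n_options = n_dwell // 2
    rest_matrix = matrix_total - lft
    if n_matrix == 1:
        if rest_matrix > tol * max(1.0, rt):
            raise FeasibilityError("single-toggle trial requires ptm == rlt")
        rest_matrix = 0.0
    elif rest_matrix <= 0:
        raise FeasibilityError(
            "multi-toggle trial requires matrix time after the first toggle"
        )
    if n_matrix == 1:
        matrix_durs = [lft]
    else:
        matrix_durs = [lft] + [rest_matrix / (n_matrix - 1)] * (n_matrix - 1)
    options_durs = [options_total / n_options] * n_options
    events = []
    t = 0.0
    for d in range(n_dwell):
        if d % 2 == 0:
            dur = matrix_durs[d // 2]
            aoi = AOI_MATRIX
        else:
            dur = options_durs[d // 2]
            aoi = AOI_OPTIONS
        events.append(FixationEvent(pid, iid, aoi, t, dur))
        t += dur
    return events


def simulate_dataset(config: SimConfig):
    """Truth + features + fixation and trial logs, all from one seed."""
    truth = generate_truth(config)
    features = simulate_features(truth, config)
    fix_rows = []
    for row in features.to_dict(orient="records"):
        for ev in synthesize_fixations(row):
            fix_rows.append(
                {
                    "participant_id": ev.participant_id,
                    "item_id": ev.item_id,
                    "aoi": ev.aoi,
                    "onset_s": ev.onset,
                    "duration_s": ev.duration,
                }
            )
    fixations = pd.DataFrame(fix_rows)
    trials = features[["participant_id", "item_id", "ra", "rt"]].rename(
        columns={"rt": "rt_s"}
    )
    return truth, features, fixations, trials


def write_dataset(config: SimConfig, outdir: str | Path):
    """Write fixations.csv, trials.csv and truth.json for a simulated run."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth, features, fixations, trials = simulate_dataset(config)
    fixations.to_csv(outdir / "fixations.csv", index=False)
    trials.to_csv(outdir / "trials.csv", index=False)
    truth_json = {
        "theta": truth.theta.tolist(),
        "b": truth.b.tolist(),
        "e": truth.e.tolist(),
        "omega": truth.omega,
        "strategy": truth.strategy.tolist(),
        "config": _config_dict(config),
    }
    (outdir / "truth.json").write_text(json.dumps(truth_json, indent=1))
    return truth, features, fixations, trials


def _config_dict(config: SimConfig) -> dict:
    d = asdict(config)
    return d
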