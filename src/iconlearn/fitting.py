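"""Maximum-likelihood fitting, cross-validation and model comparison.

Fitting is multi-start bounded L-BFGS-B on the negative session
log-likelihood; inverse-temperature parameters are optimized (and their
starting points sampled) on a log scale.  Model evaluation follows the
leave-one-game-out protocol: each game's likelihood is computed with
parameters fitted to the remaining games, and the summary statistic is the
geometric average likelihood per trial, exp(total held-out log-likelihood /
number of trials).  Chance level is 1/64 on the full configuration set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .task import GAME_TYPES, N_CONFIGS, Session
from .models.base import BehavioralModel
from .models.bayes import BayesianRuleLearningModel
from .models.feature_rl import FeatureRLModel
from .models.sht import SerialHypothesisTestingModel

CHANCE_LIKELIHOOD = 1.0 / N_CONFIGS


def _make_sht(**config):
    def factory(session, fixed=None):
        return SerialHypothesisTestingModel(session, fixed=fixed, **config)

    return factory


#: model name -> factory(session, fixed=None) -> BehavioralModel
MODEL_REGISTRY = {
    "feature_rl": FeatureRLModel,
    "bayes": BayesianRuleLearningModel,
    "random_sht": _make_sht(switch_policy="random"),
    "value_sht": _make_sht(switch_policy="value"),
    "value_sht_testgate": _make_sht(switch_policy="value", test_gate=True),
    "value_sht_rptarget": _make_sht(switch_policy="value", rp_target=True),
    "value_sht_superset": _make_sht(switch_policy="value", superset_choice=True),
    # "full" model: the two variant assumptions that improve fits
    "value_sht_full": _make_sht(
        switch_policy="value", test_gate=True, superset_choice=True
    ),
}


def make_model(name: str, session: Session, fixed=None) -> BehavioralModel:
    try:
        factory = MODEL_REGISTRY[name]
    except KeyError:
        raise ValueError(
            f"unknown model {name!r}; available: {sorted(MODEL_REGISTRY)}"
        ) from None
    return factory(session, fixed=fixed)


# ---------------------------------------------------------------------------
# Maximum likelihood
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Best-of-restarts MLE for one session."""

    model_name: str
    params: dict[str, float]
    llf: float
    game_logliks: np.ndarray
    n_trials: int
    converged: bool
    best_restart: int
    restart_llfs: np.ndarray
    free_names: tuple[str, ...] = ()
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def likelihood_per_trial(self) -> float:
        """Geometric average in-sample likelihood per trial."""
        return float(np.exp(self.llf / self.n_trials))

    def summary(self) -> str:
        lines = [
            f"{'Model:':<22}{self.model_name}",
            f"{'No. trials:':<22}{self.n_trials}",
            f"{'No. games:':<22}{len(self.game_logliks)}",
            f"{'Log-likelihood:':<22}{self.llf:.4f}",
            f"{'Likelihood/trial:':<22}{self.likelihood_per_trial:.4f}",
            f"{'Converged:':<22}{self.converged}",
            f"{'Restarts:':<22}{len(self.restart_llfs)}"
            f" (best: #{self.best_restart})",
            "-" * 44,
            f"{'parameter':<14}{'estimate':>12}  bounds",
        ]
        for name in self.free_names:
            lo, hi = self.bounds.get(name, (float("nan"), float("nan")))
            lines.append(
                f"{name:<14}{self.params[name]:>12.4f}  [{lo:g}, {hi:g}]"
            )
        fixed = [n for n in self.params if n not in self.free_names]
        for name in fixed:
            lines.append(f"{name:<14}{self.params[name]:>12.4f}  (fixed)")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "model": self.model_name,
            "params": self.params,
            "loglik": self.llf,
            "likelihood_per_trial": self.likelihood_per_trial,
            "game_logliks": self.game_logliks.tolist(),
            "n_trials": self.n_trials,
            "converged": self.converged,
        }


def _transform(x, names, log_scale):
    return np.array(
        [np.log(v) if n in log_scale else v for v, n in zip(x, names)]
    )


def _untransform(z, names, log_scale):
    return np.array(
        [np.exp(v) if n in log_scale else v for v, n in zip(z, names)]
    )



def _as_seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)

def fit_mle(
    model: BehavioralModel,
    n_restarts: int = 10,
    seed=None,
    maxiter: int = 200,
    warm_starts: Optional[Sequence[Mapping[str, float]]] = None,
    tol: float = 1e-6,
) -> FitResult:
    """Multi-start bounded maximum likelihood for one session.

    Starting points are uniform within bounds (log-uniform for inverse
    temperatures); ``warm_starts`` prepends explicit starting parameter
    dicts (they count toward ``n_restarts``).  Deterministic given ``seed``.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    names = model.free_names
    log_scale = model.LOG_SCALE
    bounds = model.free_bounds
    zbounds = [
        (np.log(lo), np.log(hi)) if n in log_scale else (lo, hi)
        for n, (lo, hi) in zip(names, bounds)
    ]
    rng = np.random.default_rng(seed)

    def objective(z):
        x = _untransform(z, names, log_scale)
        ll = model.loglike(x)
        if not np.isfinite(ll):
            return 1e12
        return -ll

    starts = []
    for w in warm_starts or []:
        x = np.array([w[n] for n in names], dtype=float)
        x = np.clip(x, [b[0] for b in bounds], [b[1] for b in bounds])
        starts.append(_transform(x, names, log_scale))
    while len(starts) < n_restarts:
        starts.append(
            np.array([rng.uniform(lo, hi) for lo, hi in zbounds])
        )

    best = None
    restart_llfs = []
    for i, z0 in enumerate(starts):
        res = minimize(
            objective,
            z0,
            method="L-BFGS-B",
            bounds=zbounds,
            options={"maxiter": maxiter, "ftol": tol},
        )
        restart_llfs.append(-res.fun)
        if best is None or res.fun < best[1].fun:
            best = (i, res)

    best_i, res = best
    x = _untransform(res.x, names, log_scale)
    params = model.params_from_vector(x)
    game_ll = model.game_logliks(params)
    return FitResult(
        model_name=model.name,
        params=model.full_params(params),
        llf=float(game_ll.sum()),
        game_logliks=game_ll,
        n_trials=model.n_trials,
        converged=bool(res.success),
        best_restart=best_i,
        restart_llfs=np.array(restart_llfs),
        free_names=names,
        bounds={n: b for n, b in zip(names, bounds)},
    )


# ---------------------------------------------------------------------------
# Leave-one-game-out cross-validation
# ---------------------------------------------------------------------------


@dataclass
class CVResult:
    """Held-out likelihoods from leave-one-game-out cross-validation."""

    model_name: str
    session_id: str
    fold_logliks: np.ndarray  # held-out log-likelihood per game
    fold_trials: np.ndarray
    game_types: list[str]
    fold_params: list[dict[str, float]]

    @property
    def likelihood_per_trial(self) -> float:
        """Geometric average held-out likelihood per trial."""
        return float(np.exp(self.fold_logliks.sum() / self.fold_trials.sum()))

    @property
    def loglik_per_trial(self) -> float:
        return float(self.fold_logliks.sum() / self.fold_trials.sum())

    def per_type(self) -> pd.DataFrame:
        """Held-out likelihood per trial broken down by game type."""
        df = pd.DataFrame(
            {
                "game_type": self.game_types,
                "loglik": self.fold_logliks,
                "n_trials": self.fold_trials,
            }
        )
        g = df.groupby("game_type", sort=False).sum(numeric_only=True)
        g["loglik_per_trial"] = g["loglik"] / g["n_trials"]
        g["likelihood_per_trial"] = np.exp(g["loglik_per_trial"])
        return g.reset_index()

    def to_dict(self) -> dict:
        return {
            "model": self.model_name,
            "session": self.session_id,
            "likelihood_per_trial": self.likelihood_per_trial,
            "fold_logliks": self.fold_logliks.tolist(),
            "fold_trials": self.fold_trials.tolist(),
            "game_types": self.game_types,
            "fold_params": self.fold_params,
        }


def logo_cv(
    model: BehavioralModel,
    n_restarts: int = 10,
    seed=None,
    warm_start: bool = True,
    maxiter: int = 200,
) -> CVResult:
    """Leave-one-game-out CV: fit on all other games, score the held-out one.

    With ``warm_start`` (default) the full-session MLE is computed first and
    used as one starting point of every fold fit — fold optima are near the
    full-session optimum, so this keeps refits cheap without biasing the
    held-out score (the held-out game never enters any objective).
    """
    session = model.session
    if session.n_games < 2:
        raise ValueError("leave-one-game-out CV needs at least 2 games")
    ss = _as_seedseq(seed)
    child_seeds = ss.spawn(session.n_games + 1)
    warm = None
    if warm_start:
        full = fit_mle(
            model, n_restarts=n_restarts, seed=child_seeds[-1], maxiter=maxiter
        )
        warm = [full.params]

    fold_ll, fold_n, types, fold_params = [], [], [], []
    for i in range(session.n_games):
        sub = model.spawn(session.drop_game(i))
        fit = fit_mle(
            sub,
            n_restarts=n_restarts,
            seed=child_seeds[i],
            warm_starts=warm,
            maxiter=maxiter,
        )
        spec, trials = session.games[i]
        fold_ll.append(model.game_loglike(i, fit.params))
        fold_n.append(len(trials))
        types.append(spec.game_type)
        fold_params.append(fit.params)
    return CVResult(
        model_name=model.name,
        session_id=session.session_id,
        fold_logliks=np.array(fold_ll),
        fold_trials=np.array(fold_n),
        game_types=types,
        fold_params=fold_params,
    )


# ---------------------------------------------------------------------------
# Model comparison and contribution metrics
# ---------------------------------------------------------------------------


def contribution_metrics(
    cv_hybrid: CVResult, cv_rl: CVResult, cv_sht: CVResult
) -> pd.DataFrame:
    """Contribution of each mechanism, per game type and overall.

    The SHT contribution is the hybrid model's held-out likelihood per trial
    minus the feature-RL model's (what adding hypothesis testing buys); the
    RL contribution is hybrid minus random-switch SHT.  Log-scale columns
    are included because per-type log-likelihoods per trial recombine to the
    overall value when weighted by trial counts.
    """
    if not (
        cv_hybrid.session_id == cv_rl.session_id == cv_sht.session_id
        and cv_hybrid.game_types == cv_rl.game_types == cv_sht.game_types
        and (cv_hybrid.fold_trials == cv_rl.fold_trials).all()
        and (cv_hybrid.fold_trials == cv_sht.fold_trials).all()
    ):
        raise ValueError("CV results must come from the same session")

    rows = []
    tables = {
        "hybrid": cv_hybrid.per_type().set_index("game_type"),
        "rl": cv_rl.per_type().set_index("game_type"),
        "sht": cv_sht.per_type().set_index("game_type"),
    }
    types = [t for t in GAME_TYPES if t in tables["hybrid"].index]
    types += [t for t in tables["hybrid"].index if t not in types]
    for t in types:
        rows.append(
            {
                "game_type": t,
                "n_trials": int(tables["hybrid"].loc[t, "n_trials"]),
                "lik_hybrid": tables["hybrid"].loc[t, "likelihood_per_trial"],
                "lik_rl": tables["rl"].loc[t, "likelihood_per_trial"],
                "lik_sht": tables["sht"].loc[t, "likelihood_per_trial"],
                "ll_hybrid": tables["hybrid"].loc[t, "loglik_per_trial"],
                "ll_rl": tables["rl"].loc[t, "loglik_per_trial"],
                "ll_sht": tables["sht"].loc[t, "loglik_per_trial"],
            }
        )
    rows.append(
        {
            "game_type": "overall",
            "n_trials": int(cv_hybrid.fold_trials.sum()),
            "lik_hybrid": cv_hybrid.likelihood_per_trial,
            "lik_rl": cv_rl.likelihood_per_trial,
            "lik_sht": cv_sht.likelihood_per_trial,
            "ll_hybrid": cv_hybrid.loglik_per_trial,
            "ll_rl": cv_rl.loglik_per_trial,
            "ll_sht": cv_sht.loglik_per_trial,
        }
    )
    df = pd.DataFrame(rows)
    df["contribution_sht"] = df["lik_hybrid"] - df["lik_rl"]
    df["contribution_rl"] = df["lik_hybrid"] - df["lik_sht"]
    df["contribution_sht_log"] = df["ll_hybrid"] - df["ll_rl"]
    df["contribution_rl_log"] = df["ll_hybrid"] - df["ll_sht"]
    return df


def model_comparison_table(
    cv_results: Mapping[str, Sequence[CVResult]]
) -> pd.DataFrame:
    """Mean +/- s.e.m. across sessions of held-out likelihood per trial.

    One row per model, plus the 1/64 chance likelihood for reference.
    """
    rows = []
    for name, results in cv_results.items():
        vals = np.array([r.likelihood_per_trial for r in results])
        rows.append(
            {
                "model": name,
                "mean_likelihood_per_trial": vals.mean(),
                "sem": (
                    vals.std(ddof=1) / np.sqrt(len(vals))
                    if len(vals) > 1
                    else np.nan
                ),
                "n_sessions": len(vals),
                "chance": CHANCE_LIKELIHOOD,
            }
        )
    return pd.DataFrame(rows).sort_values(
        "mean_likelihood_per_trial", ascending=False, ignore_index=True
    )


def compare_models(
    sessions: Sequence[Session],
    model_names: Sequence[str],
    n_restarts: int = 10,
    seed=None,
    fixed: Optional[Mapping[str, Mapping[str, float]]] = None,
    maxiter: int = 200,
) -> tuple[pd.DataFrame, dict[str, list[CVResult]]]:
    """Cross-validate each model on each session and tabulate the comparison."""
    ss = _as_seedseq(seed)
    seeds = iter(ss.spawn(len(sessions) * len(model_names)))
    cvs: dict[str, list[CVResult]] = {m: [] for m in model_names}
    for session in sessions:
        for name in model_names:
            model = make_model(name, session, fixed=(fixed or {}).get(name))
            cvs[name].append(
                logo_cv(model, n_restarts=n_restarts, seed=next(seeds),
                        maxiter=maxiter)
            )
    return model_comparison_table(cvs), cvs
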