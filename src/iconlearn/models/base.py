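"""Base class for behavioral likelihood models, statsmodels-style.

A model instance is bound to one :class:`~iconlearn.task.Session`; its free
parameters are declared by name with box bounds, any of which can be pinned
via ``fixed``.  ``loglike`` evaluates the session log-likelihood at a
parameter dict (or free-parameter vector) and ``fit`` runs multi-start
bounded maximum likelihood, returning a results object with estimates,
per-game log-likelihoods and a ``summary()`` table.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np

from ..task import Session, game_arrays


class BehavioralModel:
    """Abstract likelihood model over a behavioral session."""

    #: ordered names of all model parameters
    PARAM_NAMES: tuple[str, ...] = ()
    #: box bounds per parameter, used both for fitting and start sampling
    BOUNDS: dict[str, tuple[float, float]] = {}
    #: parameters optimized (and start-sampled) on a log scale
    LOG_SCALE: frozenset[str] = frozenset()
    #: default values, used for pinned parameters when not supplied
    DEFAULTS: dict[str, float] = {}

    name: str = "model"

    def __init__(self, session: Session, fixed: Optional[Mapping[str, float]] = None):
        self.session = session
        self.fixed = dict(fixed or {})
        unknown = set(self.fixed) - set(self.PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown fixed parameters: {sorted(unknown)}")
        self.free_names: tuple[str, ...] = tuple(
            n for n in self.PARAM_NAMES if n not in self.fixed
        )
        # per-game arrays, precomputed once (sessions are immutable in practice)
        self._games = [
            (spec, *game_arrays(trials)) for spec, trials in session.games
        ]

    # -- parameter plumbing -------------------------------------------------

    def params_from_vector(self, x: Sequence[float]) -> dict[str, float]:
        if len(x) != len(self.free_names):
            raise ValueError(
                f"expected {len(self.free_names)} free parameters, got {len(x)}"
            )
        params = dict(self.fixed)
        params.update(zip(self.free_names, map(float, x)))
        return params

    def full_params(self, params: Mapping[str, float]) -> dict[str, float]:
        out = {n: self.DEFAULTS[n] for n in self.PARAM_NAMES}
        out.update(self.fixed)
        out.update({k: v for k, v in params.items() if k in self.PARAM_NAMES})
        return out

    @property
    def free_bounds(self) -> list[tuple[float, float]]:
        return [self.BOUNDS[n] for n in self.free_names]

    # -- likelihood ---------------------------------------------------------

    def game_loglike(self, game_index: int, params: Mapping[str, float]) -> float:
        """Log-likelihood of one game's observed choices."""
        raise NotImplementedError

    def loglike(self, params) -> float:
        """Session log-likelihood; ``params`` is a dict or free-parameter vector."""
        if not isinstance(params, Mapping):
            params = self.params_from_vector(params)
        params = self.full_params(params)
        return sum(
            self.game_loglike(i, params) for i in range(len(self._games))
        )

    def game_logliks(self, params) -> np.ndarray:
        if not isinstance(params, Mapping):
            params = self.params_from_vector(params)
        params = self.full_params(params)
        return np.array(
            [self.game_loglike(i, params) for i in range(len(self._games))]
        )

    @property
    def n_trials(self) -> int:
        return sum(len(c) for _, c, _, _ in self._games)

    # -- fitting ------------------------------------------------------------

    def fit(self, n_restarts: int = 10, seed=None, **kwargs):
        """Multi-start bounded MLE; see :func:`iconlearn.fitting.fit_mle`."""
        from ..fitting import fit_mle

        return fit_mle(self, n_restarts=n_restarts, seed=seed, **kwargs)

    def spawn(self, session: Session) -> "BehavioralModel":
        """Same model (configuration and pins) bound to a different session."""
        return type(self)(session, fixed=self.fixed)
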