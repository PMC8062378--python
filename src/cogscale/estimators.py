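"""scikit-learn style estimator classes over the fitting routines.

These follow the sklearn estimator contract - keyword-only constructor
arguments stored verbatim, ``get_params``/``set_params`` via
:class:`~sklearn.base.BaseEstimator`, fitted attributes with a trailing
underscore, and validation at ``fit`` time - so they clone and compose with
sklearn model selection.  The numerical work is delegated to the
:mod:`cogscale.sdt`, :mod:`cogscale.rl` and :mod:`cogscale.lba` functions.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from . import lba as _lba
from . import rl as _rl
from . import sdt as _sdt

__all__ = ["SignalDetectionEstimator", "SoftmaxDeltaRuleEstimator", "LBAEstimator"]


class SignalDetectionEstimator(BaseEstimator):
    """Per-row SDT estimation from detection counts, under a scaling constraint.

    Parameters
    ----------
    constraint_which, constraint_value:
        The scaling constraint; defaults to sigma = 1 (classical estimation).
    convention:
        Sign convention for the centered criterion ("standard" or "negated").
    edge_policy:
        How 0/1 rates are handled ("half_count" or "error").

    After ``fit(X)`` with ``X`` of shape (n, 4) - columns hits, misses,
    false_alarms, correct_rejections - the attributes ``d_prime_``,
    ``criterion_``, ``sigma_`` (arrays of length n), ``estimates_`` and
    ``unit_labels_`` are available.  ``transform`` returns the (n, 3)
    parameter matrix.
    """

    def __init__(self, constraint_which: str = "sigma", constraint_value: float = 1.0,
                 convention: str = "standard", edge_policy: str = "half_count"):
        self.constraint_which = constraint_which
        self.constraint_value = constraint_value
        self.convention = convention
        self.edge_policy = edge_policy

    def _constraint(self) -> _sdt.ConstraintSpec:
        return _sdt.ConstraintSpec(self.constraint_which, self.constraint_value)

    def fit(self, X, y=None):
        X = np.asarray(X)
        if X.ndim != 2 or X.shape[1] != 4:
            raise ValueError("X must have shape (n_participants, 4): "
                             "hits, misses, false_alarms, correct_rejections")
        constraint = self._constraint()
        estimates = []
        for row in X.astype(np.int64):
            counts = _sdt.DetectionCounts(*map(int, row))
            rates = _sdt.rates_from_counts(counts, self.edge_policy)
            est = _sdt.refit_under_constraint(rates, constraint, convention=self.convention)
            estimates.append(est)
        self.estimates_ = estimates
        self.d_prime_ = np.array([e.d_prime for e in estimates])
        self.criterion_ = np.array([e.criterion for e in estimates])
        self.sigma_ = np.array([e.sigma for e in estimates])
        self.unit_labels_ = dict(_sdt.unit_labels_for(self.constraint_which))
        self.n_features_in_ = 4
        return self

    def transform(self, X=None):
        check_is_fitted(self, "estimates_")
        if X is not None:
            return type(self)(**self.get_params()).fit(X).transform()
        return np.column_stack([self.d_prime_, self.criterion_, self.sigma_])

    def fit_transform(self, X, y=None):
        return self.fit(X).transform()


class SoftmaxDeltaRuleEstimator(BaseEstimator):
    """Maximum-likelihood (alpha, scale) fit of the delta-rule/soft-max model.

    ``fixed="gamma"`` estimates beta with gamma = 1; ``fixed="beta"``
    estimates gamma with beta = 1.  ``fit(X)`` takes ``X`` of shape
    (n_trials, 2) with columns (choice index, reward).  Fitted attributes:
    ``alpha_``, ``beta_``, ``gamma_``, ``log_likelihood_``.
    """

    def __init__(self, fixed: str = "gamma", n_options: int = 2, n_restarts: int = 10,
                 v0: float = 0.0, seed=None):
        self.fixed = fixed
        self.n_options = n_options
        self.n_restarts = n_restarts
        self.v0 = v0
        self.seed = seed

    def fit(self, X, y=None):
        X = np.asarray(X)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must have shape (n_trials, 2): choice, reward")
        data = _rl.RLData(choices=X[:, 0].astype(np.int64), rewards=X[:, 1].astype(float),
                          n_options=self.n_options)
        result = _rl.fit(data, fixed=self.fixed, n_restarts=self.n_restarts,
                         seed=self.seed, v0=self.v0)
        self.result_ = result
        self.alpha_ = result.params.alpha
        self.beta_ = result.params.beta
        self.gamma_ = result.params.gamma
        self.log_likelihood_ = result.log_lik
        self.n_features_in_ = 2
        return self

    def score(self, X, y=None) -> float:
        """Mean per-trial log-likelihood of ``X`` under the fitted parameters."""
        check_is_fitted(self, "result_")
        X = np.asarray(X)
        data = _rl.RLData(choices=X[:, 0].astype(np.int64), rewards=X[:, 1].astype(float),
                          n_options=self.n_options)
        return _rl.log_likelihood(data, self.result_.params) / data.n_trials


class LBAEstimator(BaseEstimator):
    """Maximum-likelihood LBA fit on (rt, choice) trial data.

    ``fit(X)`` takes ``X`` of shape (n_trials, 2) with columns
    (rt in seconds, choice in {1, 2}).  Fitted attributes: ``params_``
    (an :class:`~cogscale.lba.LBAParams`), ``neg_log_lik_``, ``converged_``.
    """

    def __init__(self, constraint: str = "s1", n_restarts: int = 50, seed=None,
                 maxiter: int = 2000):
        self.constraint = constraint
        self.n_restarts = n_restarts
        self.seed = seed
        self.maxiter = maxiter

    @staticmethod
    def _trials(X) -> _lba.LBATrialSet:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must have shape (n_trials, 2): rt_seconds, choice")
        return _lba.LBATrialSet(rt=X[:, 0], choice=X[:, 1].astype(np.int64))

    def fit(self, X, y=None):
        fit = _lba.fit_lba(self._trials(X), n_restarts=self.n_restarts, seed=self.seed,
                           constraint=self.constraint, maxiter=self.maxiter)
        self.fit_ = fit
        self.params_ = fit.params
        self.neg_log_lik_ = fit.neg_log_lik
        self.converged_ = fit.converged
        self.n_features_in_ = 2
        return self

    def score(self, X, y=None) -> float:
        """Mean per-trial log-likelihood of ``X`` under the fitted parameters."""
        check_is_fitted(self, "params_")
        trials = self._trials(X)
        return -_lba.neg_log_likelihood(trials, self.params_) / trials.n_trials

    def rescale(self, by: str) -> _lba.RescaledLBAParams:
        check_is_fitted(self, "params_")
        return _lba.rescale_params(self.params_, by)
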