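"""Likelihood-based reaction-coordinate optimization.

The reaction coordinate is linear in a set of descriptors,
Q = a0 + sum_i a_i q_i, and the committor to state B is modelled as
phi_B(Q) = [1 + tanh(Q)] / 2.  The coefficients maximize the likelihood of
observed shooting outcomes,

    L = prod_{shots to B} phi_B[Q(r)] * prod_{shots to A} (1 - phi_B[Q(r)])

with uncommitted shots excluded.  Maximization is a Monte Carlo search with
Gaussian proposals (greedy accept-if-improved, optional Metropolis phase,
multiple restarts).  Descriptors are standardized to zero mean / unit scale
internally so coefficient magnitudes are comparable across descriptors;
coefficient uncertainties come from bootstrap resampling of the shooting
records by default (MC-spread and inverse-Hessian estimates are also
available).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import SeparationWarning, ValidationError
from .tps import ShootingRecord

_CLIP = 1e-12  # probability floor inside logs, guards against separation


def committor_model(Q) -> np.ndarray | float:
    """phi_B(Q) = [1 + tanh(Q)] / 2, strictly increasing, in (0, 1)."""
    q = np.asarray(Q, dtype=float)
    out = 0.5 * (1.0 + np.tanh(q))
    return float(out) if out.ndim == 0 else out


@dataclass
class RCModel:
    """Linear reaction coordinate on standardized descriptors.

    ``coefficients`` is (a0, a1 ... aK); ``means``/``scales`` hold the
    standardization constants of the raw descriptors.
    """

    descriptor_names: list
    coefficients: np.ndarray
    means: np.ndarray
    scales: np.ndarray
    uncertainties: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coefficients = np.atleast_1d(np.asarray(self.coefficients, dtype=float))
        self.means = np.atleast_1d(np.asarray(self.means, dtype=float))
        self.scales = np.atleast_1d(np.asarray(self.scales, dtype=float))
        k = len(self.descriptor_names)
        if self.coefficients.size != k + 1:
            raise ValidationError(
                f"need {k + 1} coefficients for {k} descriptors, "
                f"got {self.coefficients.size}"
            )
        if self.means.size != k or self.scales.size != k:
            raise ValidationError("standardization constants must match descriptors")
        if np.any(self.scales <= 0):
            raise ValidationError("scales must be positive")
        if self.uncertainties is not None:
            self.uncertainties = np.atleast_1d(
                np.asarray(self.uncertainties, dtype=float)
            )
            if self.uncertainties.size != k + 1:
                raise ValidationError("uncertainties must match coefficients")

    @property
    def n_descriptors(self) -> int:
        return len(self.descriptor_names)

    def reaction_coordinate(self, q: np.ndarray) -> np.ndarray | float:
        """Q = a0 + a . (q - mean)/scale for raw descriptor vectors q
        (single vector or stacked rows)."""
        q = np.asarray(q, dtype=float)
        single = q.ndim == 1
        q2 = np.atleast_2d(q)
        if q2.shape[1] != self.n_descriptors:
            raise ValidationError(
                f"descriptor dimension {q2.shape[1]} != model {self.n_descriptors}"
            )
        z = (q2 - self.means) / self.scales
        out = self.coefficients[0] + z @ self.coefficients[1:]
        return float(out[0]) if single else out


@dataclass
class FitReport:
    final_log_likelihood: float
    restart_optima: list
    acceptance_trace: list
    n_evaluations: int
    separation_flag: bool = False
    calibration: object = None


def _record_arrays(records: Sequence[ShootingRecord]):
    q = np.vstack([r.q for r in records])
    n_a = np.array([r.n_to_A for r in records], dtype=float)
    n_b = np.array([r.n_to_B for r in records], dtype=float)
    return q, n_a, n_b


def log_likelihood(model: RCModel, records: Sequence[ShootingRecord]) -> float:
    """Shooting-outcome log-likelihood; each committed shot contributes one
    term (tallies expand multiplicities), uncommitted shots are excluded."""
    q, n_a, n_b = _record_arrays(records)
    if n_a.sum() + n_b.sum() < 1:
        raise ValidationError("records contain no committed shots")
    p = np.clip(committor_model(model.reaction_coordinate(q)), _CLIP, 1.0 - _CLIP)
    return float(np.sum(n_b * np.log(p) + n_a * np.log(1.0 - p)))


def _ll_standardized(coef, z, n_a, n_b):
    p = np.clip(committor_model(coef[0] + z @ coef[1:]), _CLIP, 1.0 - _CLIP)
    return float(np.sum(n_b * np.log(p) + n_a * np.log(1.0 - p)))


def _mc_maximize(
    z, n_a, n_b, start, n_steps, rng, proposal_scale, metropolis_steps, bound
):
    """Gaussian-proposal Monte Carlo search: optional Metropolis phase at
    unit temperature followed by greedy accept-if-improved, with the
    proposal scale adapted every 100 steps."""
    coef = np.clip(start.astype(float).copy(), -bound, bound)
    best = coef.copy()
    ll = _ll_standardized(coef, z, n_a, n_b)
    best_ll = ll
    scale = proposal_scale
    trace = [ll]
    accepted_window = 0
    total = metropolis_steps + n_steps
    for step in range(total):
        prop = np.clip(coef + rng.normal(0.0, scale, size=coef.size), -bound, bound)
        prop_ll = _ll_standardized(prop, z, n_a, n_b)
        metropolis = step < metropolis_steps
        accept = prop_ll >= ll or (
            metropolis and rng.random() < np.exp(prop_ll - ll)
        )
        if accept:
            coef, ll = prop, prop_ll
            accepted_window += 1
            if ll > best_ll:
                best, best_ll = coef.copy(), ll
                trace.append(ll)
        if (step + 1) % 100 == 0:
            rate = accepted_window / 100.0
            if rate < 0.1:
                scale = max(scale * 0.5, 1e-4)
            elif rate > 0.4:
                scale = min(scale * 2.0, 5.0)
            accepted_window = 0
    return best, best_ll, trace, total


def fit(
    records: Sequence[ShootingRecord],
    descriptor_names: Sequence[str] | None = None,
    descriptor_subset: Sequence[int] | None = None,
    n_steps: int = 3000,
    n_restarts: int = 5,
    proposal_scale: float = 0.5,
    metropolis_steps: int = 0,
    seed=None,
    uncertainty: str = "bootstrap",
    n_bootstrap: int = 200,
    coefficient_bound: float = 20.0,
) -> tuple[RCModel, FitReport]:
    """Maximum-likelihood fit of the linear reaction coordinate.

    ``descriptor_subset`` restricts the fit to the given raw-descriptor
    columns.  ``uncertainty`` selects the coefficient-error recipe:
    'bootstrap' (default), 'mc_spread' or 'hessian'; 'none' skips it.
    """
    records = list(records)
    if len(records) < 2:
        raise ValidationError("need at least 2 shooting records")
    q, n_a, n_b = _record_arrays(records)
    if not (np.any(n_a > 0) and np.any(n_b > 0)):
        raise ValidationError("records must contain both A and B outcomes")
    if descriptor_subset is not None:
        q = q[:, list(descriptor_subset)]
    k = q.shape[1]
    if descriptor_names is None:
        descriptor_names = [f"q{i + 1}" for i in range(k)]
    else:
        descriptor_names = list(descriptor_names)
        if descriptor_subset is not None and len(descriptor_names) != k:
            descriptor_names = [descriptor_names[i] for i in descriptor_subset]
    if len(descriptor_names) != k:
        raise ValidationError("descriptor_names must match descriptor count")

    means = q.mean(axis=0)
    scales = q.std(axis=0)
    scales = np.where(scales > 0, scales, 1.0)
    z = (q - means) / scales

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    best = None
    best_ll = -np.inf
    optima = []
    trace = []
    n_eval = 0
    for restart in range(n_restarts):
        start = (
            np.zeros(k + 1) if restart == 0 else rng.normal(0.0, 1.0, size=k + 1)
        )
        coef, ll, tr, ne = _mc_maximize(
            z, n_a, n_b, start, n_steps, rng, proposal_scale, metropolis_steps,
            coefficient_bound,
        )
        optima.append(ll)
        n_eval += ne
        if ll > best_ll:
            best, best_ll, trace = coef, ll, tr

    separation = bool(np.any(np.abs(best) >= coefficient_bound - 1e-9))
    if separation:
        warnings.warn(
            "likelihood maximum at the coefficient bound: data may be "
            "completely separable; coefficients capped",
            SeparationWarning,
        )

    uncertainties = None
    if uncertainty == "bootstrap":
        boot = np.empty((n_bootstrap, k + 1))
        for b in range(n_bootstrap):
            pick = rng.integers(0, len(records), size=len(records))
            coef_b, _, _, _ = _mc_maximize(
                z[pick], n_a[pick], n_b[pick], best, max(n_steps // 4, 300),
                rng, proposal_scale / 2.0, 0, coefficient_bound,
            )
            boot[b] = coef_b
        uncertainties = boot.std(axis=0, ddof=1)
    elif uncertainty == "mc_spread":
        spread_opts = np.empty((n_restarts, k + 1))
        for r in range(n_restarts):
            start = rng.normal(0.0, 1.0, size=k + 1)
            coef_r, _, _, _ = _mc_maximize(
                z, n_a, n_b, start, n_steps, rng, proposal_scale, 0,
                coefficient_bound,
            )
            spread_opts[r] = coef_r
        uncertainties = spread_opts.std(axis=0, ddof=1)
    elif uncertainty == "hessian":
        uncertainties = _hessian_sd(best, z, n_a, n_b)
    elif uncertainty != "none":
        raise ValidationError(f"unknown uncertainty recipe {uncertainty!r}")

    model = RCModel(
        descriptor_names=descriptor_names,
        coefficients=best,
        means=means,
        scales=scales,
        uncertainties=uncertainties,
    )
    report = FitReport(
        final_log_likelihood=best_ll,
        restart_optima=optima,
        acceptance_trace=trace,
        n_evaluations=n_eval,
        separation_flag=separation,
    )
    return model, report


def _hessian_sd(coef, z, n_a, n_b, h: float = 1e-4) -> np.ndarray:
    """Standard deviations from the inverse observed information (numerical
    Hessian of the negative log-likelihood)."""
    k = coef.size
    hess = np.empty((k, k))
    f0 = _ll_standardized(coef, z, n_a, n_b)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = h
            ej[j] = h
            fpp = _ll_standardized(coef + ei + ej, z, n_a, n_b)
            fpm = _ll_standardized(coef + ei - ej, z, n_a, n_b)
            fmp = _ll_standardized(coef - ei + ej, z, n_a, n_b)
            fmm = _ll_standardized(coef - ei - ej, z, n_a, n_b)
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4 * h * h)
    info = -hess
    try:
        cov = np.linalg.inv(info)
        diag = np.diag(cov)
        return np.sqrt(np.where(diag > 0, diag, np.nan))
    except np.linalg.LinAlgError:
        return np.full(k, np.nan)


def predict(model: RCModel, q: np.ndarray) -> np.ndarray | float:
    """Predicted committor phi_B(Q(q)) for raw descriptor vector(s)."""
    return committor_model(model.reaction_coordinate(q))


@dataclass
class CalibrationResult:
    """Predicted-vs-observed committor table with coverage summary."""

    point_ids: list
    predicted: np.ndarray
    observed: np.ndarray
    n_committed: np.ndarray
    std_error: np.ndarray
    inside_interval: np.ndarray
    rmse: float
    n_inside: int

    def __len__(self) -> int:
        return len(self.point_ids)


def calibrate(
    model: RCModel, records: Sequence[ShootingRecord], level: float = 0.95
) -> CalibrationResult:
    """Compare predicted committors against observed shot fractions.

    For each validation point the observed committor is n_B / n_committed
    with binomial standard error; a point is covered when its observed count
    lies inside the ``level`` binomial interval implied by the predicted
    committor.  Summary: RMSE and number of covered points.
    """
    from scipy.stats import binom

    records = list(records)
    if not records:
        return CalibrationResult(
            [], np.empty(0), np.empty(0), np.empty(0, dtype=int), np.empty(0),
            np.empty(0, dtype=bool), float("nan"), 0,
        )
    ids, pred, obs, ncom, se, inside = [], [], [], [], [], []
    for r in records:
        n = r.n_committed
        if n < 1:
            raise ValidationError(
                f"validation point {r.point_id!r} has no committed shots"
            )
        p_hat = r.n_to_B / n
        p_pred = float(predict(model, r.q))
        lo, hi = binom.interval(level, n, p_pred)
        ids.append(r.point_id)
        pred.append(p_pred)
        obs.append(p_hat)
        ncom.append(n)
        se.append(np.sqrt(p_hat * (1 - p_hat) / n))
        inside.append(lo <= r.n_to_B <= hi)
    pred = np.array(pred)
    obs = np.array(obs)
    inside = np.array(inside, dtype=bool)
    return CalibrationResult(
        point_ids=ids,
        predicted=pred,
        observed=obs,
        n_committed=np.array(ncom, dtype=int),
        std_error=np.array(se),
        inside_interval=inside,
        rmse=float(np.sqrt(np.mean((pred - obs) ** 2))),
        n_inside=int(inside.sum()),
    )
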