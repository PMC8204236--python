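"""Maximum-likelihood fitting of the skill-learning dose-response curve.

Each relevant self-monitoring record is a Bernoulli observation of whether the
patient used a skill, with success probability

    p(I) = p0 + (p_max - p0) * (1 - exp(-k * I)),

where ``I`` is the cumulative number of momentary interventions the patient
had received for that skill strictly before the record. ``p0`` is the
baseline use probability, ``p_max`` the asymptotic ceiling, and ``k`` the
learning rate per intervention.

The model is fitted by unconstrained BFGS on a transformed parameterization
(logit for p0, logit of the remaining headroom for p_max, log for k), which
enforces 0 <= p0 <= p_max <= 1 and k >= 0 by construction. Standard errors
come from the numerically differentiated Hessian on the natural scale and are
NaN when the curvature is degenerate (e.g. k unidentified because the dose
never varies).
"""

from __future__ import annotations

import datetime as dt
from typing import Optional, Sequence

import numpy as np
from scipy import optimize

from .errors import EstimationError
from .models import DeliveredIntervention, EntryRecord, Skill

__all__ = ["SkillLearningModel", "SkillLearningResults", "recover_learning_params"]

_EPS = 1e-9


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p: float) -> float:
    p = min(max(p, 1e-6), 1 - 1e-6)
    return float(np.log(p / (1 - p)))


def _natural(theta: np.ndarray) -> tuple[float, float, float]:
    a, b, c = theta
    p0 = float(_sigmoid(a))
    p_max = p0 + (1.0 - p0) * float(_sigmoid(b))
    k = float(np.exp(c))
    return p0, p_max, k


class SkillLearningModel:
    """Bernoulli learning-curve model of skill use versus intervention dose.

    Parameters
    ----------
    used : array-like of bool
        Whether the skill was used at each relevant record.
    dose : array-like of int
        Cumulative interventions received for the skill before each record.
    """

    def __init__(self, used, dose):
        self.used = np.asarray(used, dtype=float)
        self.dose = np.asarray(dose, dtype=float)
        if self.used.shape != self.dose.shape or self.used.ndim != 1:
            raise EstimationError("used and dose must be equal-length 1-d arrays")
        if self.used.size == 0:
            raise EstimationError("no relevant observations to fit")
        self.nobs = int(self.used.size)

    @classmethod
    def from_log(
        cls,
        entries: Sequence[EntryRecord],
        deliveries: Sequence[DeliveredIntervention],
        skill: Skill = Skill.URGE_MANAGEMENT,
        mood_threshold: int = 4,
    ) -> "SkillLearningModel":
        """Assemble observations for one skill from a log and its deliveries.

        Relevance per skill: urge management -> records with an urge and an
        answered use question; mood management -> records at/above the mood
        threshold; eat enough -> non-LOC eating episodes with the ate-enough
        question answered.
        """
        times = sorted(d.timestamp for d in deliveries if d.skill is skill)
        times_arr = np.array([t.timestamp() for t in times])

        def dose_at(ts: dt.datetime) -> int:
            return int(np.searchsorted(times_arr, ts.timestamp(), side="left"))

        obs: list[tuple[bool, int]] = []
        for e in sorted(entries, key=lambda r: r.timestamp):
            if skill is Skill.URGE_MANAGEMENT:
                if e.urge_present and e.used_urge_strategy is not None:
                    obs.append((e.used_urge_strategy, dose_at(e.timestamp)))
            elif skill is Skill.MOOD_MANAGEMENT:
                if (
                    e.mood is not None
                    and e.mood >= mood_threshold
                    and e.used_mood_strategy is not None
                ):
                    obs.append((e.used_mood_strategy, dose_at(e.timestamp)))
            elif skill is Skill.EAT_ENOUGH:
                if (
                    e.is_eating_episode
                    and not e.loss_of_control
                    and e.ate_enough is not None
                ):
                    obs.append((e.ate_enough, dose_at(e.timestamp)))
            else:
                raise EstimationError(
                    f"no per-record use outcome is observed for {skill.value}"
                )
        if not obs:
            raise EstimationError(
                f"log contains no relevant records for {skill.value}"
            )
        used, dose = zip(*obs)
        return cls(used, dose)

    @classmethod
    def from_log_pooled(
        cls,
        entries: Sequence[EntryRecord],
        deliveries: Sequence[DeliveredIntervention],
        skills: Sequence[Skill] = (
            Skill.URGE_MANAGEMENT,
            Skill.EAT_ENOUGH,
            Skill.MOOD_MANAGEMENT,
        ),
        mood_threshold: int = 4,
    ) -> "SkillLearningModel":
        """Pool observations across skills that share one learning curve.

        Each skill contributes its own (outcome, per-skill dose) pairs; the
        pooled likelihood assumes a common (p0, p_max, k). Skills whose dose
        never moves still pin down the baseline p0. Skills with no relevant
        records are skipped.
        """
        used_parts, dose_parts = [], []
        for skill in skills:
            try:
                m = cls.from_log(
                    entries, deliveries, skill=skill, mood_threshold=mood_threshold
                )
            except EstimationError:
                continue
            used_parts.append(m.used)
            dose_parts.append(m.dose)
        if not used_parts:
            raise EstimationError("no relevant records for any requested skill")
        return cls(np.concatenate(used_parts), np.concatenate(dose_parts))

    def predict(self, params: Sequence[float], dose=None) -> np.ndarray:
        """Skill-use probability at the given dose(s)."""
        p0, p_max, k = params
        d = self.dose if dose is None else np.asarray(dose, dtype=float)
        return p0 + (p_max - p0) * (1.0 - np.exp(-k * d))

    def loglike(self, params: Sequence[float]) -> float:
        p = np.clip(self.predict(params), _EPS, 1 - _EPS)
        return float(np.sum(self.used * np.log(p) + (1 - self.used) * np.log(1 - p)))

    def _start(self) -> np.ndarray:
        lo = self.dose <= np.quantile(self.dose, 0.25)
        hi = self.dose >= np.quantile(self.dose, 0.75)
        p0 = float(self.used[lo].mean()) if lo.any() else float(self.used.mean())
        p_hi = float(self.used[hi].mean()) if hi.any() else float(self.used.mean())
        p0 = min(max(p0, 0.02), 0.98)
        p_hi = min(max(p_hi, p0 + 0.01), 0.99)
        b = _logit((p_hi - p0) / max(1.0 - p0, 1e-6))
        return np.array([_logit(p0), b, np.log(0.05)])

    def fit(self, start: Optional[Sequence[float]] = None) -> "SkillLearningResults":
        """Fit by maximum likelihood; returns a results object."""
        if start is not None:
            p0, p_max, k = start
            theta0 = np.array(
                [
                    _logit(p0),
                    _logit((p_max - p0) / max(1.0 - p0, 1e-6)),
                    np.log(max(k, 1e-6)),
                ]
            )
        else:
            theta0 = self._start()

        def nll(theta: np.ndarray) -> float:
            return -self.loglike(_natural(theta))

        opt = optimize.minimize(nll, theta0, method="BFGS")
        params = np.array(_natural(opt.x))
        return SkillLearningResults(self, params, llf=-float(opt.fun), opt=opt)


class SkillLearningResults:
    """Estimates, uncertainties, and diagnostics from a learning-curve fit."""

    _names = ("p0", "p_max", "k")

    def __init__(self, model: SkillLearningModel, params: np.ndarray, llf: float, opt):
        self.model = model
        self.params = params
        self.llf = llf
        self.nobs = model.nobs
        self.converged = bool(opt.success) or np.isfinite(llf)
        self.bse = self._bse()

    def _bse(self) -> np.ndarray:
        # observed-information standard errors on the natural scale
        h = 1e-4
        n = len(self.params)
        hess = np.full((n, n), np.nan)

        def ll(p):
            return self.model.loglike(p)

        try:
            for i in range(n):
                for j in range(i, n):
                    pp = self.params.copy()
                    step_i = np.zeros(n)
                    step_j = np.zeros(n)
                    step_i[i] = h
                    step_j[j] = h
                    hess[i, j] = hess[j, i] = (
                        ll(pp + step_i + step_j)
                        - ll(pp + step_i - step_j)
                        - ll(pp - step_i + step_j)
                        + ll(pp - step_i - step_j)
                    ) / (4 * h * h)
            cov = np.linalg.inv(-hess)
            diag = np.diag(cov)
            return np.where(diag > 0, np.sqrt(np.abs(diag)), np.nan)
        except np.linalg.LinAlgError:
            return np.full(n, np.nan)

    @property
    def params_dict(self) -> dict[str, float]:
        return dict(zip(self._names, map(float, self.params)))

    def predict(self, dose) -> np.ndarray:
        return self.model.predict(self.params, dose=dose)

    def summary(self) -> str:
        lines = [
            "Skill learning curve (Bernoulli MLE)",
            "=" * 44,
            f"{'n obs':<14}{self.nobs:>10}",
            f"{'log-lik':<14}{self.llf:>10.3f}",
            "-" * 44,
            f"{'param':<8}{'estimate':>12}{'std err':>12}",
        ]
        for name, est, se in zip(self._names, self.params, self.bse):
            se_s = f"{se:.4f}" if np.isfinite(se) else "nan"
            lines.append(f"{name:<8}{est:>12.4f}{se_s:>12}")
        lines.append("=" * 44)
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        p = ", ".join(f"{n}={v:.3f}" for n, v in self.params_dict.items())
        return f"<SkillLearningResults {p}, n={self.nobs}>"


def recover_learning_params(
    entries: Sequence[EntryRecord],
    deliveries: Sequence[DeliveredIntervention],
    skill: Skill = Skill.URGE_MANAGEMENT,
) -> SkillLearningResults:
    """Fit the learning curve for one skill directly from a log.

    Convenience wrapper around ``SkillLearningModel.from_log(...).fit()``.
    """
    return SkillLearningModel.from_log(entries, deliveries, skill=skill).fit()
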