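"""Bayesian two-isoform PSI estimation and differential-splicing Bayes factors.

Per event and condition, replicate-pooled inclusion/exclusion junction reads
are modelled as exchangeable Bernoulli draws: the probability θ that an
informative read comes from the inclusion isoform has a uniform prior, so
θ | (k, n) ~ Beta(k+1, n−k+1).  Percent spliced in is the length-corrected
monotone transform

    Ψ(θ) = (θ / l_inc) / (θ / l_inc + (1 − θ) / l_exc)

which reduces to Ψ = θ when the effective isoform lengths are equal.  The
Bayes factor compares M1 (independent uniform θ per condition) against M0
(a single shared θ), both with closed-form Beta-function marginals:

    BF = B(k_c+1, n_c−k_c+1) · B(k_d+1, n_d−k_d+1)
         / B(k_c+k_d+1, n_c+n_d−k_c−k_d+1)

evaluated in log space.  BF > 1 favours a splicing change; the
discovery/validation cutoffs live in :mod:`smnsplice.event_classification`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate
from scipy.special import betaln
from scipy.stats import beta as beta_dist

log = logging.getLogger(__name__)

CONTROL = "control"
DEPLETED = "depleted"
DEFAULT_MIN_READS = 20


@dataclass(frozen=True)
class EventCounts:
    """Replicate-summed inclusion (k) and total informative (n) reads."""

    event_id: str
    k_control: int
    n_control: int
    k_depleted: int
    n_depleted: int

    def __post_init__(self) -> None:
        for k, n in ((self.k_control, self.n_control),
                     (self.k_depleted, self.n_depleted)):
            if not (0 <= k <= n):
                raise ValueError(
                    f"{self.event_id}: invalid counts k={k}, n={n}"
                )


@dataclass(frozen=True)
class PsiPosterior:
    condition: str
    posterior_mean: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not (0 <= self.ci_low <= self.posterior_mean <= self.ci_high <= 1):
            raise ValueError("posterior summary outside [0, 1] ordering")


@dataclass(frozen=True)
class PsiCall:
    event_id: str
    event_type: str
    psi_control: PsiPosterior
    psi_depleted: PsiPosterior
    bayes_factor: float
    low_coverage: bool = False

    @property
    def delta_psi(self) -> float:
        return self.psi_depleted.posterior_mean - self.psi_control.posterior_mean


def _psi_transform(theta: np.ndarray, l_inc: float, l_exc: float) -> np.ndarray:
    return (theta / l_inc) / (theta / l_inc + (1.0 - theta) / l_exc)


def psi_posterior(
    k: int,
    n: int,
    l_inc: float = 1.0,
    l_exc: float = 1.0,
    condition: str = CONTROL,
    ci: float = 0.95,
) -> PsiPosterior:
    """Posterior mean and equal-tailed credible interval for Ψ.

    With equal lengths the mean is the conjugate (k+1)/(n+2); otherwise the
    mean of the transformed variable is found by quadrature and the interval
    by mapping the Beta quantiles through the monotone transform.
    """
    if not (0 <= k <= n):
        raise ValueError(f"invalid counts k={k}, n={n}")
    if l_inc <= 0 or l_exc <= 0:
        raise ValueError("effective lengths must be positive")
    a, b = k + 1, n - k + 1
    lo_q, hi_q = (1 - ci) / 2, 1 - (1 - ci) / 2
    if l_inc == l_exc:
        mean = a / (a + b)
        lo, hi = beta_dist.ppf([lo_q, hi_q], a, b)
    else:
        mean, _ = integrate.quad(
            lambda t: _psi_transform(np.asarray(t), l_inc, l_exc)
            * beta_dist.pdf(t, a, b),
            0.0, 1.0,
        )
        lo, hi = _psi_transform(
            beta_dist.ppf(np.array([lo_q, hi_q]), a, b), l_inc, l_exc
        )
    mean = float(np.clip(mean, lo, hi))
    return PsiPosterior(condition, mean, float(lo), float(hi))


def log_bayes_factor(counts: EventCounts) -> float:
    kc, nc = counts.k_control, counts.n_control
    kd, nd = counts.k_depleted, counts.n_depleted
    return (
        betaln(kc + 1, nc - kc + 1)
        + betaln(kd + 1, nd - kd + 1)
        - betaln(kc + kd + 1, nc + nd - kc - kd + 1)
    )


def bayes_factor(counts: EventCounts) -> float:
    """Marginal-likelihood ratio for "splicing differs" vs "identical"."""
    return float(np.exp(log_bayes_factor(counts)))


def pool_replicates(counts: pd.DataFrame) -> pd.DataFrame:
    """Sum inclusion/exclusion reads over replicates per (event, condition)."""
    pooled = (
        counts.groupby(["event_id", "condition"], as_index=False)[
            ["inclusion_reads", "exclusion_reads"]
        ].sum()
    )
    pooled["total_reads"] = pooled["inclusion_reads"] + pooled["exclusion_reads"]
    return pooled


def call_events(
    counts: pd.DataFrame,
    event_types: dict[str, str],
    length_model: dict[str, tuple[float, float]] | None = None,
    min_reads: int = DEFAULT_MIN_READS,
) -> list[PsiCall]:
    """One PsiCall per event with counts in both conditions.

    ``event_types`` maps event_id → "SE"/"RI".  ``length_model`` optionally
    maps event_id → (l_inc, l_exc) effective lengths (default equal).
    Events below ``min_reads`` total informative reads are emitted but
    flagged low-coverage, never filtered.
    """
    pooled = pool_replicates(counts)
    calls = []
    for event_id, group in pooled.groupby("event_id", sort=True):
        by_cond = {r.condition: r for r in group.itertuples()}
        if CONTROL not in by_cond or DEPLETED not in by_cond:
            log.warning("event %s has counts in only one condition; skipped",
                        event_id)
            continue
        ec = EventCounts(
            event_id,
            k_control=int(by_cond[CONTROL].inclusion_reads),
            n_control=int(by_cond[CONTROL].total_reads),
            k_depleted=int(by_cond[DEPLETED].inclusion_reads),
            n_depleted=int(by_cond[DEPLETED].total_reads),
        )
        l_inc, l_exc = (length_model or {}).get(event_id, (1.0, 1.0))
        calls.append(
            PsiCall(
                event_id=event_id,
                event_type=event_types.get(event_id, "SE"),
                psi_control=psi_posterior(
                    ec.k_control, ec.n_control, l_inc, l_exc, CONTROL
                ),
                psi_depleted=psi_posterior(
                    ec.k_depleted, ec.n_depleted, l_inc, l_exc, DEPLETED
                ),
                bayes_factor=bayes_factor(ec),
                low_coverage=ec.n_control + ec.n_depleted < min_reads,
            )
        )
    return calls


CALLS_COLUMNS = [
    "event_id", "event_type", "psi_control", "psi_control_lo", "psi_control_hi",
    "psi_depleted", "psi_depleted_lo", "psi_depleted_hi", "delta_psi",
    "bayes_factor", "low_coverage",
]


def calls_to_frame(calls: list[PsiCall]) -> pd.DataFrame:
    rows = [
        {
            "event_id": c.event_id,
            "event_type": c.event_type,
            "psi_control": c.psi_control.posterior_mean,
            "psi_control_lo": c.psi_control.ci_low,
            "psi_control_hi": c.psi_control.ci_high,
            "psi_depleted": c.psi_depleted.posterior_mean,
            "psi_depleted_lo": c.psi_depleted.ci_low,
            "psi_depleted_hi": c.psi_depleted.ci_high,
            "delta_psi": c.delta_psi,
            "bayes_factor": c.bayes_factor,
            "low_coverage": c.low_coverage,
        }
        for c in calls
    ]
    return pd.DataFrame(rows, columns=CALLS_COLUMNS)
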