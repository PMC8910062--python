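"""Confidence scoring of bait-prey proximity interactions against controls.

This module is a fully specified, testable stand-in for SAINT-style scorers.
Counts are modelled as Poisson per run and each prey is assessed with a
two-component empirical-Bayes mixture, mirroring the structure of the SAINT
family:

* under the *background* component the prey has one shared rate in bait and
  control runs, drawn from a contaminant rate prior Gamma(a0, b0) fitted by
  moments across all preys' control counts (so the model knows what typical
  carry-over contamination looks like);
* under the *interaction* component the control runs keep the contaminant
  prior while the bait runs draw their own rate from a diffuse
  Gamma(a1, b1) prior.

Conjugacy gives closed-form marginal likelihoods for both components, and
the mixture weight pi (the fraction of genuine interactions) is estimated
by EM across the preys of a bait-condition.  The reported confidence is

    prob = P(interaction | counts) * P(lambda_bait > lambda_control | counts),

i.e. the posterior probability that the prey is a genuine, *enriched*
interaction; the directional factor uses the closed-form Beta tail
``P(Beta(s_b + a1, s_c + a0) > (n_b + b1) / (n_b + b1 + n_c + b0))``.  On
tables too small to fit the mixture (< 50 preys) the component priors fall
back to the weak Gamma(pseudo_rate, 1) and pi is fixed at 0.5 (equal
priors), so tiny fixtures behave like a plain two-hypothesis posterior: a
prey whose bait counts exactly mirror its control counts scores <= 0.5 and
strong enrichment over empty controls scores near 1.

The Bayesian false discovery rate follows the SAINT convention: after
ranking by decreasing probability, ``BFDR(k)`` is the running mean of
``1 - prob`` over the top-k preys.  Because prob is an honest posterior,
gating at BFDR <= 1% controls the expected false-discovery proportion.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import special

from .counts import SpectralCountTable
from .errors import ValidationError


@dataclass
class ScoringConfig:
    """Thresholds and smoothing for scoring and QC."""

    bfdr_max: float = 0.01
    qc_threshold: float = 0.9
    pseudo_rate: float = 0.1

    def __post_init__(self):
        if not (0 < self.bfdr_max <= 1):
            raise ValidationError("bfdr_max must lie in (0, 1]")
        if self.pseudo_rate <= 0:
            raise ValidationError("pseudo_rate must be positive")


@dataclass
class ScoredInteraction:
    """Per (bait-condition, prey) confidence score."""

    bait_condition: str
    prey: str
    avg_count: float
    control_counts: list[int]
    prob: float
    bfdr: float = float("nan")
    is_known: bool | None = None


@dataclass(frozen=True)
class QCPair:
    run_a: str
    run_b: str
    r: float
    r_squared: float
    anti_correlated: bool


@dataclass(frozen=True)
class QCReport:
    bait_condition: str
    pairs: tuple[QCPair, ...]
    mean_r_squared: float
    threshold: float
    passed: bool


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation; 1.0 for identical vectors, 0.0 when degenerate."""
    if np.array_equal(x, y):
        return 1.0
    if x.std() == 0 or y.std() == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def replicate_qc(
    table: SpectralCountTable, bait_condition: str, qc_threshold: float = 0.9
) -> QCReport:
    """Pairwise replicate correlation QC for one bait-condition.

    For every pair of runs of the condition the squared Pearson correlation
    of per-prey counts is computed over the union of preys (absent = 0).
    The condition passes when the mean R^2 across pairs exceeds the
    threshold.  Anti-correlated pairs (r < 0) still contribute r^2 but are
    flagged explicitly in the report.
    """
    run_ids = table.run_ids(bait_condition)
    if len(run_ids) < 2:
        raise ValidationError(
            f"insufficient replicates for {bait_condition!r}: {len(run_ids)} run(s)"
        )
    mat = table.count_matrix(run_ids)
    pairs = []
    for a, b in combinations(run_ids, 2):
        r = _pearson(mat[a].to_numpy(), mat[b].to_numpy())
        pairs.append(QCPair(a, b, r, r * r, anti_correlated=r < 0))
    mean_r2 = float(np.mean([p.r_squared for p in pairs]))
    return QCReport(
        bait_condition=bait_condition,
        pairs=tuple(pairs),
        mean_r_squared=mean_r2,
        threshold=qc_threshold,
        passed=mean_r2 > qc_threshold,
    )


# Diffuse prior on the rate of a genuine interaction: mean a1/b1 = 25
# spectral counts per run but with prior weight of only 0.02 runs.
_TRUE_PRIOR_SHAPE = 0.5
_TRUE_PRIOR_RATE = 0.02

# Below this many preys the mixture weight and contaminant prior cannot be
# estimated stably; fall back to equal priors and the weak pseudo prior.
_MIN_PREYS_FOR_EB = 50


def _log_marginal(s, n, a, b):
    """Log marginal likelihood of total count s over n Poisson runs whose
    rate carries a Gamma(a, b) prior (per-run factorials dropped — they
    cancel between hypotheses for the same prey)."""
    return (
        a * np.log(b)
        - special.gammaln(a)
        + special.gammaln(a + s)
        - (a + s) * np.log(n + b)
    )


def _fit_contaminant_prior(
    s_ctrl: np.ndarray, n_ctrl: int, pseudo: float
) -> tuple[float, float]:
    """Moment-fit a Gamma(a0, b0) prior for per-run contaminant rates from
    the per-prey control-count sums.  The rate variance is floored so the
    prior never carries more weight than ~50 pseudo-runs of evidence."""
    mean_rate = float(s_ctrl.mean()) / n_ctrl
    if mean_rate <= 0:
        return pseudo, 1.0
    var_rate = (float(s_ctrl.var()) - n_ctrl * mean_rate) / n_ctrl**2
    var_rate = max(var_rate, mean_rate**2 / 50.0, 1e-8)
    b0 = mean_rate / var_rate
    return mean_rate * b0, b0


def _directional_posterior(s_bait, n_bait, s_ctrl, n_ctrl, a0, b0, a1, b1):
    """P(lambda_bait > lambda_ctrl) for independent Gamma posteriors via the
    Beta-tail identity."""
    bb = n_bait + b1
    bc = n_ctrl + b0
    t = bb / (bb + bc)
    return special.betaincc(s_bait + a1, s_ctrl + a0, t)


def _mixture_probs(
    s_bait: np.ndarray,
    n_bait: int,
    s_ctrl: np.ndarray,
    n_ctrl: int,
    pseudo: float,
    s_ctrl_all: np.ndarray | None = None,
) -> np.ndarray:
    eb = s_bait.size >= _MIN_PREYS_FOR_EB
    if eb:
        pool = s_ctrl_all if s_ctrl_all is not None else s_ctrl
        a0, b0 = _fit_contaminant_prior(pool, n_ctrl, pseudo)
    else:
        a0, b0 = pseudo, 1.0
    a1, b1 = _TRUE_PRIOR_SHAPE, _TRUE_PRIOR_RATE

    l_null = _log_marginal(s_bait + s_ctrl, n_bait + n_ctrl, a0, b0)
    l_alt = _log_marginal(s_ctrl, n_ctrl, a0, b0) + _log_marginal(s_bait, n_bait, a1, b1)

    if eb:
        pi = 0.1
        for _ in range(200):
            w = special.expit(np.log(pi / (1 - pi)) + l_alt - l_null)
            pi_new = float(np.clip(w.mean(), 1e-3, 0.5))
            if abs(pi_new - pi) < 1e-10:
                break
            pi = pi_new
    else:
        pi = 0.5
    w = special.expit(np.log(pi / (1 - pi)) + l_alt - l_null)
    direction = _directional_posterior(s_bait, n_bait, s_ctrl, n_ctrl, a0, b0, a1, b1)
    return w * direction


def score_interactions(
    table: SpectralCountTable,
    bait_condition: str,
    cfg: ScoringConfig | None = None,
) -> list[ScoredInteraction]:
    """Score every prey of a bait-condition against the control runs.

    Returns interactions sorted by decreasing probability (ties broken by
    higher average count, then prey name).  Preys absent from all bait runs
    are omitted.  BFDR values are filled by :func:`compute_bfdr`.
    """
    cfg = cfg or ScoringConfig()
    bait_runs = table.run_ids(bait_condition)
    if not bait_runs:
        raise ValidationError(f"no runs for condition {bait_condition!r}")
    ctrl_runs = table.control_run_ids()
    if not ctrl_runs:
        raise ValidationError("no control runs in table")

    bait_mat = table.count_matrix(bait_runs)
    bait_mat = bait_mat.loc[bait_mat.sum(axis=1) > 0]
    if bait_mat.empty:
        return []
    ctrl_full = table.count_matrix(ctrl_runs)
    ctrl_mat = ctrl_full.reindex(bait_mat.index, fill_value=0)
    # contaminant prior is fitted over every prey seen in these bait runs
    # or in the controls, so control-only preys inform it too
    all_preys = sorted(set(bait_mat.index) | set(ctrl_full.index))
    s_ctrl_all = ctrl_full.reindex(all_preys, fill_value=0).sum(axis=1).to_numpy()

    s_bait = bait_mat.sum(axis=1).to_numpy()
    s_ctrl = ctrl_mat.sum(axis=1).to_numpy()
    probs = _mixture_probs(
        s_bait, len(bait_runs), s_ctrl, len(ctrl_runs), cfg.pseudo_rate, s_ctrl_all
    )
    avg = s_bait / len(bait_runs)

    scored = [
        ScoredInteraction(
            bait_condition=bait_condition,
            prey=prey,
            avg_count=float(avg[i]),
            control_counts=[int(c) for c in ctrl_mat.iloc[i]],
            prob=float(probs[i]),
        )
        for i, prey in enumerate(bait_mat.index)
    ]
    scored.sort(key=lambda s: (-s.prob, -s.avg_count, s.prey))
    return scored


def compute_bfdr(scored: Sequence[ScoredInteraction]) -> list[ScoredInteraction]:
    """Fill BFDR as the running mean of (1 - prob) down the ranked list.

    The input is re-ranked by decreasing probability (ties: higher average
    count, then prey name) before the cumulative mean is taken, so the
    output BFDR is non-decreasing along the list by construction; this is
    asserted on every call.
    """
    ranked = sorted(scored, key=lambda s: (-s.prob, -s.avg_count, s.prey))
    if not ranked:
        return []
    one_minus = np.array([1.0 - s.prob for s in ranked])
    bfdr = np.cumsum(one_minus) / np.arange(1, len(ranked) + 1)
    assert np.all(np.diff(bfdr) >= -1e-12), "BFDR must be non-decreasing"
    return [replace(s, bfdr=float(b)) for s, b in zip(ranked, bfdr)]


def filter_high_confidence(
    scored: Sequence[ScoredInteraction], bfdr_max: float = 0.01
) -> list[ScoredInteraction]:
    """Subset of interactions at BFDR <= bfdr_max, order preserved."""
    if not (0 < bfdr_max <= 1):
        raise ValidationError("bfdr_max must lie in (0, 1]")
    for s in scored:
        if np.isnan(s.bfdr):
            raise ValidationError("BFDR not populated; run compute_bfdr first")
    return [s for s in scored if s.bfdr <= bfdr_max]
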