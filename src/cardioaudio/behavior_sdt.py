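"""Type-1 and type-2 signal detection indices and interoceptive measures.

Type-1 sensitivity is the classic equal-variance d' = z(HR) - z(FAR).
Metacognitive sensitivity (meta-d') is the d' an ideal observer would need
to produce the observed confidence-conditional accuracy, fitted by maximum
likelihood under the equal-variance Gaussian model with response-
conditional type-2 criteria.  The M-ratio meta-d'/d' indexes metacognitive
efficiency.  Interoceptive sensibility is the median confidence on
heartbeat-judgment trials; body-perception questionnaire subscales are
plain item sums.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import norm


@dataclass
class ConfusionCounts:
    """Counts indexed by (stimulus class, response, confidence).

    ``counts[s, r, k]``: s = 0 noise / 1 signal, r = 0 "no" / 1 "yes",
    k = confidence level - 1.
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 3 or self.counts.shape[:2] != (2, 2):
            raise ValueError("counts must have shape (2, 2, n_conf)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_conf(self) -> int:
        return self.counts.shape[2]

    @property
    def n_trials(self) -> float:
        return float(self.counts.sum())

    @classmethod
    def from_trials(cls, stimulus: Sequence[bool], response: Sequence[bool],
                    confidence: Sequence[int], n_conf: int = 4) -> "ConfusionCounts":
        stimulus = np.asarray(stimulus, dtype=int)
        response = np.asarray(response, dtype=int)
        confidence = np.asarray(confidence, dtype=int)
        if np.any((confidence < 1) | (confidence > n_conf)):
            raise ValueError(f"confidence must lie in 1..{n_conf}")
        counts = np.zeros((2, 2, n_conf))
        np.add.at(counts, (stimulus, response, confidence - 1), 1.0)
        return cls(counts)


def _corrected_rate(hits: float, n: float) -> float:
    """Hit/false-alarm rate with 0 and 1 replaced by 1/(2N) and 1 - 1/(2N)."""
    if n <= 0:
        raise ValueError("stimulus class has zero trials")
    rate = hits / n
    return float(np.clip(rate, 1.0 / (2 * n), 1.0 - 1.0 / (2 * n)))


def type1_sdt(counts: ConfusionCounts) -> tuple[float, float]:
    """Equal-variance type-1 sensitivity and criterion.

    d' = z(HR) - z(FAR);  c = -(z(HR) + z(FAR)) / 2, with extreme rates
    corrected by the 1/(2N) rule before the probit transform.
    """
    c2 = counts.counts.sum(axis=2)      # (stim, resp)
    n_signal, n_noise = c2[1].sum(), c2[0].sum()
    hr = _corrected_rate(c2[1, 1], n_signal)
    far = _corrected_rate(c2[0, 1], n_noise)
    zh, zf = norm.ppf(hr), norm.ppf(far)
    return float(zh - zf), float(-(zh + zf) / 2.0)


@dataclass
class MetaDFit:
    meta_d: float
    m_ratio: float
    d_prime: float
    criterion: float
    t2_criteria_no: np.ndarray     # descending below the type-1 criterion
    t2_criteria_yes: np.ndarray    # ascending above the type-1 criterion
    log_likelihood: float
    converged: bool


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _meta_cell_logprobs(meta_d: float, c_rel: float, off_no: np.ndarray,
                        off_yes: np.ndarray) -> np.ndarray:
    """log P(response r, confidence k | stimulus s) under the meta model.

    The type-1 criterion of the meta model sits at the same *relative*
    position c_rel = c/d' as in the data, i.e. at c_rel * meta_d.
    """
    n_conf = len(off_no) + 1
    cprime = c_rel * meta_d
    t_no = cprime - np.cumsum(_softplus(off_no))          # conf 2..n going down
    t_yes = cprime + np.cumsum(_softplus(off_yes))
    # ascending boundaries: -inf, t_no reversed, cprime, t_yes, +inf
    bounds = np.concatenate([[-np.inf], t_no[::-1], [cprime], t_yes, [np.inf]])
    out = np.empty((2, 2, n_conf))
    for s, mu in ((0, -meta_d / 2.0), (1, meta_d / 2.0)):
        cdf = norm.cdf(bounds - mu)
        p = np.maximum(np.diff(cdf), 1e-300)
        out[s, 0] = p[:n_conf][::-1]        # "no" intervals, conf n..1 -> reverse
        out[s, 1] = p[n_conf:]
    return np.log(out)


def fit_meta_d(counts: ConfusionCounts, n_conf: int = 4,
               n_restarts: int = 5, pad: bool = True) -> MetaDFit:
    """Maximum-likelihood meta-d' under the equal-variance Gaussian model.

    The likelihood is the multinomial probability of the confidence counts
    conditional on the type-1 outcome (the meta model reproduces observed
    response rates; only confidence is predicted).  Criteria are
    parameterized as ordered offsets from the scaled type-1 criterion via
    softplus.  Every confidence cell is padded by ``1/(2 * n_cells)``
    (``n_cells`` = response x confidence cells per stimulus class) to keep
    the likelihood finite with sparse cells.
    """
    if counts.n_conf != n_conf:
        raise ValueError("confusion table has wrong confidence resolution")
    d1, c1 = type1_sdt(counts)
    c_rel = c1 / d1 if abs(d1) > 1e-8 else 0.0

    obs = counts.counts.astype(float)
    if pad:
        obs = obs + 1.0 / (2.0 * 2 * n_conf)
    resp_tot = obs.sum(axis=2, keepdims=True)             # (2, 2, 1)

    def nll(theta: np.ndarray) -> float:
        meta_d = theta[0]
        lp = _meta_cell_logprobs(meta_d, c_rel, theta[1:n_conf], theta[n_conf:])
        # condition on type-1 response: log P(conf | s, r)
        p_resp = np.log(np.exp(lp).sum(axis=2, keepdims=True))
        return -float(np.sum(obs * (lp - p_resp)))

    rng = np.random.default_rng(0)
    best = None
    inits = [d1, 0.5 * d1, 1.5 * d1 + 0.1, 0.0, -d1]
    for i in range(n_restarts):
        x0 = np.concatenate([[inits[i % len(inits)]],
                             np.full(2 * (n_conf - 1), np.log(np.expm1(0.5)))])
        if i >= len(inits):
            x0[1:] += rng.normal(0, 0.3, size=x0.size - 1)
        res = optimize.minimize(nll, x0, method="L-BFGS-B",
                                bounds=[(-10, 10)] + [(-15, 5)] * (2 * (n_conf - 1)))
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("meta-d' fit failed to converge after restarts")

    meta_d = float(best.x[0])
    cprime = c_rel * meta_d
    t_no = cprime - np.cumsum(_softplus(best.x[1:n_conf]))
    t_yes = cprime + np.cumsum(_softplus(best.x[n_conf:]))
    return MetaDFit(
        meta_d=meta_d,
        m_ratio=float(meta_d / d1) if abs(d1) > 1e-8 else np.nan,
        d_prime=d1, criterion=c1,
        t2_criteria_no=t_no, t2_criteria_yes=t_yes,
        log_likelihood=-float(best.fun),
        converged=bool(best.success),
    )


@dataclass
class SDTIndices:
    """Per-subject behavioral indices of the cardio-audio task."""

    d_internal: float
    c_internal: float
    d_external: float
    c_external: float
    meta_d: float
    m_ratio: float
    sensibility: float                     # median confidence, internal trials
    bpq_awareness: Optional[float] = None
    bpq_autonomic: Optional[float] = None

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def interoceptive_indices(
    behavior: pd.DataFrame,
    bpq_awareness_items: Optional[Sequence[float]] = None,
    bpq_autonomic_items: Optional[Sequence[float]] = None,
    n_conf: int = 4,
) -> SDTIndices:
    """All behavioral indices for one subject.

    ``behavior`` needs columns attention, delay, omission_trial, response
    ("yes"/"no"), confidence (1..n_conf).  On internal trials the signal is
    a short cardio-audio delay; on external trials, the presence of an
    omission.
    """
    if behavior["confidence"].isna().any():
        raise ValueError("missing confidence values")
    internal = behavior[behavior["attention"] == "internal"]
    external = behavior[behavior["attention"] == "external"]
    if internal.empty or external.empty:
        raise ValueError("need both internal and external trials")

    yes_int = internal["response"].eq("yes").to_numpy()
    c_int = ConfusionCounts.from_trials(
        internal["delay"].eq("short").to_numpy(), yes_int,
        internal["confidence"].to_numpy(int), n_conf)
    c_ext = ConfusionCounts.from_trials(
        external["omission_trial"].astype(int).to_numpy().astype(bool),
        external["response"].eq("yes").to_numpy(),
        external["confidence"].to_numpy(int), n_conf)

    d_int, crit_int = type1_sdt(c_int)
    d_ext, crit_ext = type1_sdt(c_ext)
    fit = fit_meta_d(c_int, n_conf=n_conf)

    return SDTIndices(
        d_internal=d_int, c_internal=crit_int,
        d_external=d_ext, c_external=crit_ext,
        meta_d=fit.meta_d, m_ratio=fit.m_ratio,
        sensibility=float(np.median(internal["confidence"])),
        bpq_awareness=float(np.sum(bpq_awareness_items))
        if bpq_awareness_items is not None else None,
        bpq_autonomic=float(np.sum(bpq_autonomic_items))
        if bpq_autonomic_items is not None else None,
    )


def median_split(values: Sequence[float]) -> list[str]:
    """High/low group labels; values equal to the median go to "low"."""
    v = np.asarray(values, dtype=float)
    med = np.median(v)
    return ["high" if x > med else "low" for x in v]
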