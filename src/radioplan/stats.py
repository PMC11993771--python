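"""Statistical layer: paired absolute-error noninferiority, Mann-Whitney U,
Shapiro-Wilk, and an approximate post-hoc power for the Mann-Whitney test.

Noninferiority convention: per-case differences are
``d_i = |error_reference_arm_i| - |error_new_arm_i|`` ... concretely, the
package computes ``|errors_ec| - |errors_suh|`` (external-company minus
in-house), so a *positive* mean difference favours the in-house arm.  The
null "the new arm is inferior by more than the margin" is rejected when the
lower limit of the two-sided 95% t confidence interval exceeds ``-margin``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, erf, sqrt

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import PairingError, StatsError

__all__ = [
    "NoninferiorityResult",
    "GroupSummary",
    "paired_noninferiority",
    "noninferiority_from_interval",
    "mann_whitney_u",
    "shapiro_wilk",
    "posthoc_power_mw",
    "study_table",
    "ERROR_COLUMNS",
]

ERROR_COLUMNS = ["rot_x", "rot_y", "rot_z", "trans_x", "trans_y", "trans_z"]


@dataclass
class NoninferiorityResult:
    n: int
    mean_diff: float
    ci_lower: float
    ci_upper: float
    margin: float
    alpha: float
    noninferior: bool
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mean_diff": self.mean_diff,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
            "margin": self.margin,
            "alpha": self.alpha,
            "noninferior": self.noninferior,
            "degenerate": self.degenerate,
        }


@dataclass(frozen=True)
class GroupSummary:
    n: int
    mean: float
    sd: float

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("group size must be >= 2")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


def paired_noninferiority(
    errors_ec, errors_suh, margin: float, alpha: float = 0.05
) -> NoninferiorityResult:
    """Paired absolute-error noninferiority analysis.

    ``d_i = |errors_ec_i| - |errors_suh_i|``; the two-sided ``1 - alpha``
    t interval on the mean difference is compared against ``-margin``.
    """
    ec = np.abs(np.asarray(errors_ec, dtype=np.float64))
    suh = np.abs(np.asarray(errors_suh, dtype=np.float64))
    if ec.shape != suh.shape or ec.ndim != 1:
        raise ValueError("errors must be equal-length 1-D sequences (paired)")
    n = len(ec)
    if n < 2:
        raise StatsError("need at least 2 pairs")
    if margin <= 0:
        raise ValueError("margin must be a positive magnitude")
    d = ec - suh
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    degenerate = sd == 0.0
    hw = 0.0 if degenerate else float(
        sps.t.ppf(1 - alpha / 2, n - 1) * sd / sqrt(n)
    )
    lo, hi = mean - hw, mean + hw
    return NoninferiorityResult(
        n=n,
        mean_diff=mean,
        ci_lower=lo,
        ci_upper=hi,
        margin=margin,
        alpha=alpha,
        noninferior=bool(lo > -margin),
        degenerate=degenerate,
    )


def noninferiority_from_interval(
    mean_diff: float, ci_lower: float, ci_upper: float, margin: float
) -> bool:
    """Decision rule applied to an already-computed summary interval."""
    if not ci_lower <= mean_diff <= ci_upper:
        raise ValueError("mean_diff must lie within [ci_lower, ci_upper]")
    if margin <= 0:
        raise ValueError("margin must be a positive magnitude")
    return bool(ci_lower > -margin)


def _rank_midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def _u_from_ranks(ranks_a: np.ndarray, n_a: int) -> float:
    return float(ranks_a.sum() - n_a * (n_a + 1) / 2.0)


def mann_whitney_u(a, b, mode: str = "exact") -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    ``mode="exact"`` enumerates all ``C(n_a + n_b, n_a)`` group labelings
    (permissible up to ``n_a + n_b <= 14``); ``mode="normal_approx"`` uses
    the tie-corrected normal approximation with continuity correction.
    Returns ``(U, p)`` with ``U = min(U_a, U_b)``.
    """
    a = np.asarray(a, dtype=np.float64).reshape(-1)
    b = np.asarray(b, dtype=np.float64).reshape(-1)
    n_a, n_b = len(a), len(b)
    if n_a < 1 or n_b < 1:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([a, b])
    if np.ptp(combined) == 0.0:
        return float(n_a * n_b / 2.0), 1.0  # all values identical: no evidence
    ranks = _rank_midranks(combined)
    u_a = _u_from_ranks(ranks[:n_a], n_a)
    u_b = n_a * n_b - u_a
    u_min = min(u_a, u_b)

    if mode == "exact":
        n = n_a + n_b
        if n > 14:
            raise ValueError("exact mode requires n_a + n_b <= 14")
        count = 0
        for idx in combinations(range(n), n_a):
            u = _u_from_ranks(ranks[list(idx)], n_a)
            if u <= u_min + 1e-12:
                count += 1
        p = min(1.0, 2.0 * count / comb(n, n_a))
        return u_min, p

    if mode == "normal_approx":
        n = n_a + n_b
        _, tie_counts = np.unique(combined, return_counts=True)
        tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1)))
        sigma2 = n_a * n_b / 12.0 * ((n + 1) - tie_term)
        if sigma2 <= 0:
            return u_min, 1.0
        mu = n_a * n_b / 2.0
        z = (u_min - mu + 0.5) / sqrt(sigma2)  # continuity correction toward mu
        p = min(1.0, 2.0 * 0.5 * (1.0 + erf(z / sqrt(2.0))))
        return u_min, p

    raise ValueError(f"unknown mode {mode!r}")


def shapiro_wilk(x) -> tuple[float, float]:
    """Shapiro-Wilk normality test (Royston's approximation, via SciPy)."""
    x = np.asarray(x, dtype=np.float64).reshape(-1)
    if not 3 <= len(x) <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0.0:
        raise StatsError("W is undefined for constant input")
    w, p = sps.shapiro(x)
    return float(w), float(p)


def posthoc_power_mw(
    summary_a: GroupSummary, summary_b: GroupSummary, alpha: float = 0.05
) -> float:
    """Approximate post-hoc power of a two-sided Mann-Whitney test.

    Uses Cohen's d from the pooled SD and the power of the two-sample
    t-test with sample sizes deflated by the asymptotic relative efficiency
    3/pi of the rank test under normal parents.  This is explicitly an
    approximation; desktop power tools may use different internals.
    """
    n1, n2 = summary_a.n, summary_b.n
    pooled = sqrt(
        ((n1 - 1) * summary_a.sd**2 + (n2 - 1) * summary_b.sd**2) / (n1 + n2 - 2)
    )
    if pooled == 0:
        raise StatsError("pooled SD is zero; effect size undefined")
    d = abs(summary_a.mean - summary_b.mean) / pooled
    are = 3.0 / np.pi
    m1, m2 = are * n1, are * n2
    df = m1 + m2 - 2
    ncp = d * sqrt(m1 * m2 / (m1 + m2))
    tcrit = sps.t.ppf(1 - alpha / 2, df)
    power = sps.nct.sf(tcrit, df, ncp) + sps.nct.cdf(-tcrit, df, ncp)
    return float(np.clip(power, 0.0, 1.0))


def study_table(
    per_case_errors: pd.DataFrame,
    margin_rot_x: float = 5.0,
    margin_trans_z: float = 2.0,
    alpha: float = 0.05,
    new_arm: str = "in_house",
    reference_arm: str = "external",
):
    """Summarise a per-case error table and run both noninferiority analyses.

    Expects columns ``case_id, guide_arm, rot_x, rot_y, rot_z, trans_x,
    trans_y, trans_z`` with exactly one row per case per arm.  Returns
    ``(summary_df, {"rot_x": NoninferiorityResult, "trans_z": ...})`` where
    the summary holds mean and SD of *absolute* errors per parameter per
    arm.
    """
    df = per_case_errors.copy()
    required = {"case_id", "guide_arm", *ERROR_COLUMNS}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"per-case table is missing columns: {sorted(missing)}")

    counts = df.groupby("case_id")["guide_arm"].agg(list)
    for case_id, arms in counts.items():
        for arm in (new_arm, reference_arm):
            if arms.count(arm) != 1:
                raise PairingError(
                    f"case {case_id!r} has {arms.count(arm)} rows for arm {arm!r}"
                )

    rows = []
    for arm in (new_arm, reference_arm):
        sub = df[df["guide_arm"] == arm]
        for col in ERROR_COLUMNS:
            vals = np.abs(sub[col].to_numpy(dtype=np.float64))
            rows.append(
                {
                    "parameter": col,
                    "guide_arm": arm,
                    "n": len(vals),
                    "mean_abs": float(vals.mean()),
                    "sd_abs": float(vals.std(ddof=1)),
                }
            )
    summary = pd.DataFrame(rows)

    wide = df.pivot(index="case_id", columns="guide_arm", values=ERROR_COLUMNS)
    decisions = {
        "rot_x": paired_noninferiority(
            wide[("rot_x", reference_arm)], wide[("rot_x", new_arm)], margin_rot_x, alpha
        ),
        "trans_z": paired_noninferiority(
            wide[("trans_z", reference_arm)],
            wide[("trans_z", new_arm)],
            margin_trans_z,
            alpha,
        ),
    }
    return summary, decisions
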