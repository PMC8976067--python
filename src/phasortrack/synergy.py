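"""Coefficient of drug interaction (CDI) from cell-count tables.

CDI = (combo/control) / ((A/control) * (B/control)) on arm means.
CDI < 1.0 indicates synergy; CDI < 0.7 significant synergy.  A two-tailed
t-test compares combination counts against per-replicate product-expectation
counts (one reasonable operationalization of the p-value reported alongside
a CDI; the pairing is recorded in the result metadata).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CDIResult", "cdi"]


@dataclass
class CDIResult:
    """CDI with arm summaries and the synergy call."""

    cdi: float
    label: str
    mean_counts: dict[str, float]
    survival_ratios: dict[str, float]
    p_value: float
    per_replicate_cdi: list[float] = field(default_factory=list)
    p_value_definition: str = (
        "two-tailed two-sample t-test of combination counts vs per-replicate "
        "product-expectation counts A_i*B_i/control_mean"
    )


def _label(value: float) -> str:
    if value < 0.7:
        return "significant synergy"
    if value < 1.0:
        return "synergy"
    return "none"


def cdi(
    counts: pd.DataFrame,
    control: str = "control",
    drug_a: str = "cisplatin",
    drug_b: str = "phenformin",
    combo: str = "combo",
) -> CDIResult:
    """Compute the CDI from a (condition, replicate, count) table."""
    arms = {}
    for arm in (control, drug_a, drug_b, combo):
        vals = counts.loc[counts["condition"] == arm, "count"].to_numpy(dtype=float)
        if vals.size == 0:
            raise ValueError(f"no replicates for arm {arm!r}")
        arms[arm] = vals
    means = {k: float(v.mean()) for k, v in arms.items()}
    for arm, m in means.items():
        if m <= 0:
            raise ValueError(f"arm {arm!r} has nonpositive mean count")
    ratios = {k: means[k] / means[control] for k in (drug_a, drug_b, combo)}
    value = ratios[combo] / (ratios[drug_a] * ratios[drug_b])

    n = min(len(arms[drug_a]), len(arms[drug_b]), len(arms[combo]))
    expected = arms[drug_a][:n] * arms[drug_b][:n] / means[control]
    observed = arms[combo][:n]
    if n >= 2 and (np.ptp(observed) > 0 or np.ptp(expected) > 0):
        p = float(stats.ttest_ind(observed, expected, equal_var=True).pvalue)
    else:
        p = float("nan")
    per_rep = []
    if len({len(arms[a]) for a in (control, drug_a, drug_b, combo)}) == 1:
        c = arms[control]
        per_rep = list(
            (arms[combo] / c) / ((arms[drug_a] / c) * (arms[drug_b] / c))
        )
    return CDIResult(
        cdi=float(value),
        label=_label(value),
        mean_counts=means,
        survival_ratios=ratios,
        p_value=p,
        per_replicate_cdi=[float(x) for x in per_rep],
    )
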