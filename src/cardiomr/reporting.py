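"""Effect scaling, multiple-testing classification, and report assembly.

Estimates are reported as odds ratios with confidence intervals per a
configurable number of units of genetically predicted increase in the
exposure (scale factor 10 for continuous ECG/heart-rate-style traits, 1 for
binary exposures whose effects are already log odds).  Associations are
classified against a Bonferroni-corrected threshold (significant), the
nominal alpha (suggestive), or neither (null).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError
from .estimators import MREstimate

#: Canonical outcome ordering: any stroke, any ischemic stroke, then the
#: TOAST subtypes large-artery, cardioembolic, small-vessel.
DEFAULT_OUTCOME_ORDER = ("AS", "AIS", "LAS", "CES", "SVS")

METHOD_ORDER = (
    "ivw_random",
    "ivw_fixed",
    "wald_ratio",
    "egger_slope",
    "egger_intercept",
    "weighted_median",
    "simple_median",
)


def bonferroni_threshold(n_exposures: int, n_outcomes: int, alpha: float = 0.05) -> float:
    """alpha divided by the number of exposure-outcome tests."""
    if n_exposures < 1 or n_outcomes < 1:
        raise DomainError("exposure and outcome counts must be >= 1")
    if not 0 < alpha < 1:
        raise DomainError(f"alpha {alpha} outside (0, 1)")
    return alpha / (n_exposures * n_outcomes)


def classify_association(p: float, threshold: float, alpha: float) -> str:
    """significant (p < threshold), suggestive (threshold <= p < alpha), or null."""
    if not 0 < p <= 1:
        raise DomainError(f"p {p} outside (0, 1]")
    if not 0 < threshold <= alpha < 1:
        raise DomainError("require 0 < threshold <= alpha < 1")
    if p < threshold:
        return "significant"
    if p < alpha:
        return "suggestive"
    return "null"


def scale_estimate(
    beta: float, se: float, factor: float = 1.0, level: float = 0.95
) -> tuple[float, float, float]:
    """Odds ratio and CI per ``factor`` units of the exposure.

    or = exp(factor * beta); ci = exp(factor * (beta +/- z* se)).
    """
    if se <= 0:
        raise DomainError(f"se must be > 0, got {se}")
    if not 0 < level < 1:
        raise DomainError(f"level {level} outside (0, 1)")
    if factor <= 0:
        raise DomainError(f"factor must be > 0, got {factor}")
    z = stats.norm.ppf(0.5 + level / 2.0)
    odds = math.exp(factor * beta)
    lo = math.exp(factor * (beta - z * se))
    hi = math.exp(factor * (beta + z * se))
    return odds, lo, hi


def format_scientific(x: float, sig: int = 3) -> str:
    """Format with 3 significant digits, using 'm x 10^k' beyond |exp| >= 3."""
    if x == 0:
        return "0"
    if 1e-3 <= abs(x) < 1e3:
        return f"{x:.{sig}g}"
    exp = math.floor(math.log10(abs(x)))
    mant = x / 10**exp
    return f"{mant:.{max(sig - 1, 0)}f} x 10^{exp}"


@dataclass(frozen=True)
class AssociationVerdict:
    """One method's estimate for one exposure-outcome pair, classified."""

    exposure: str
    outcome: str
    estimate: MREstimate
    category: str
    threshold_significant: float
    threshold_suggestive: float


def make_verdict(
    exposure: str,
    outcome: str,
    estimate: MREstimate,
    threshold: float,
    alpha: float = 0.05,
) -> AssociationVerdict:
    return AssociationVerdict(
        exposure=exposure,
        outcome=outcome,
        estimate=estimate,
        category=classify_association(estimate.p_value, threshold, alpha),
        threshold_significant=threshold,
        threshold_suggestive=alpha,
    )


@dataclass
class ResultsBundle:
    """Machine-readable estimates table plus a human-readable text report."""

    table: pd.DataFrame
    text: str

    def write(self, tsv_path, text_path) -> None:
        self.table.to_csv(tsv_path, sep="\t", index=False)
        with open(text_path, "w") as fh:
            fh.write(self.text)


def _order_key(value: str, order: Sequence[str]) -> tuple[int, str]:
    try:
        return (order.index(value), value)
    except ValueError:
        return (len(order), value)


def compile_report(
    verdicts: Sequence[AssociationVerdict],
    sensitivity: Mapping[tuple[str, str], Mapping] | None = None,
    outcome_order: Sequence[str] = DEFAULT_OUTCOME_ORDER,
    exposure_order: Sequence[str] = (),
    level: float = 0.95,
) -> ResultsBundle:
    """Assemble the deterministic results bundle.

    ``sensitivity`` maps (exposure, outcome) to a dict with optional keys
    ``"pleiotropy"`` (intercept, se, p triple) and ``"leave_one_out"``
    (list of LeaveOneOutRecord).  Output ordering is exposure, then outcome
    in the canonical order, then method; identical inputs in any order
    produce byte-identical output.
    """
    if not verdicts:
        raise DomainError("compile_report requires at least one verdict")
    sensitivity = sensitivity or {}

    rows = []
    for v in verdicts:
        est = v.estimate
        odds, lo, hi = scale_estimate(est.beta, est.se, est.scale_factor, level)
        rows.append(
            {
                "exposure": v.exposure,
                "outcome": v.outcome,
                "method": est.method,
                "k": est.k,
                "beta": est.beta,
                "se": est.se,
                "p": est.p_value,
                "or": odds,
                "ci_low": lo,
                "ci_high": hi,
                "scale_factor": est.scale_factor,
                "category": v.category,
            }
        )
    table = pd.DataFrame(rows)
    table = table.sort_values(
        by=["exposure", "outcome", "method"],
        key=lambda col: (
            col.map(lambda x: _order_key(x, exposure_order))
            if col.name == "exposure"
            else col.map(lambda x: _order_key(x, outcome_order))
            if col.name == "outcome"
            else col.map(lambda x: _order_key(x, METHOD_ORDER))
        ),
        kind="mergesort",
    ).reset_index(drop=True)

    lines = ["exposure\toutcome\tmethod\tk\tOR (95% CI)\tp\tcategory"]
    pairs_seen = []
    for row in table.itertuples(index=False):
        lines.append(
            f"{row.exposure}\t{row.outcome}\t{row.method}\t{row.k}\t"
            f"{row[7]:.2f} ({row.ci_low:.2f}-{row.ci_high:.2f})\t"
            f"{format_scientific(row.p)}\t{row.category}"
        )
        if (row.exposure, row.outcome) not in pairs_seen:
            pairs_seen.append((row.exposure, row.outcome))
    lines.append("")
    lines.append("Pleiotropy (MR-Egger intercept):")
    for pair in pairs_seen:
        entry = sensitivity.get(pair, {})
        plei = entry.get("pleiotropy")
        if plei is None:
            lines.append(f"{pair[0]} -> {pair[1]}: NA (insufficient instruments)")
        else:
            intercept, _se, p = plei
            lines.append(
                f"{pair[0]} -> {pair[1]}: intercept = {format_scientific(intercept)}, "
                f"p = {format_scientific(p)}"
            )
    lines.append("")
    for pair in pairs_seen:
        entry = sensitivity.get(pair, {})
        loo = entry.get("leave_one_out")
        if loo:
            flagged = sorted(r.omitted_variant for r in loo if r.classification_changed)
            desc = ", ".join(flagged) if flagged else "none"
            lines.append(f"Leave-one-out {pair[0]} -> {pair[1]}: influential variants: {desc}")
    return ResultsBundle(table=table, text="\n".join(lines) + "\n")
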