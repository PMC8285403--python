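"""Leave-one-out influence analysis and the Egger pleiotropy test wrapper."""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import pandas as pd

from .errors import InsufficientInstrumentsError
from .estimators import MREstimate, egger, ivw
from .summary_stats import HarmonizedInstrumentSet


@dataclass(frozen=True)
class LeaveOneOutRecord:
    """IVW estimate with one instrument omitted.

    ``classification_changed`` is True when omitting the variant moves the
    estimate across the significance boundary at the stated alpha (in either
    direction) relative to the full-set estimate — the criterion under which
    a single variant's exclusion "induces" or removes a significant result.
    """

    omitted_variant: str
    estimate: MREstimate
    classification_changed: bool


class PleiotropyReport(NamedTuple):
    intercept: float
    intercept_se: float
    intercept_p: float


def leave_one_out(
    instruments: HarmonizedInstrumentSet,
    alpha: float = 0.05,
    model: str = "random",
) -> list[LeaveOneOutRecord]:
    """Re-run IVW omitting each instrument in turn.

    Returns exactly k records, one per omitted variant, each estimated on the
    remaining k-1 instruments with the same IVW model as the full set.
    """
    k = instruments.k
    if k < 2:
        raise InsufficientInstrumentsError("leave-one-out requires k >= 2")
    # k-1 = 1 cannot support a random-effects inflation; fall back to fixed
    sub_model = model if k - 1 >= 2 else "fixed"
    full = ivw(instruments, model=model)
    full_significant = full.p_value < alpha

    records = []
    df = instruments.instruments
    for i in range(k):
        rest = df.drop(df.index[i])
        est = ivw(rest, model=sub_model)
        changed = (est.p_value < alpha) != full_significant
        records.append(
            LeaveOneOutRecord(
                omitted_variant=str(df.iloc[i]["variant_id"]),
                estimate=est,
                classification_changed=changed,
            )
        )
    return records


def pleiotropy_report(instruments: HarmonizedInstrumentSet) -> PleiotropyReport:
    """MR-Egger intercept as the directional-pleiotropy test.

    Reported in results as "(intercept = ..., p = ...)"; a small intercept
    with a large p is no evidence of directional pleiotropy.
    """
    _slope, intercept = egger(instruments)
    return PleiotropyReport(intercept.beta, intercept.se, intercept.p_value)


def loo_to_frame(records: list[LeaveOneOutRecord]) -> pd.DataFrame:
    """Serialize leave-one-out records to the TSV layout."""
    return pd.DataFrame(
        {
            "omitted_variant": [r.omitted_variant for r in records],
            "beta": [r.estimate.beta for r in records],
            "se": [r.estimate.se for r in records],
            "p": [r.estimate.p_value for r in records],
            "classification_changed": [r.classification_changed for r in records],
        }
    )
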