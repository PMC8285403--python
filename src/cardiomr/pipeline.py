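"""End-to-end analysis: selection -> harmonization -> estimation -> report.

Thin orchestration over the library modules, used by the command-line
interface and by integration tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import estimators, instruments, reporting, sensitivity, summary_stats
from .errors import InsufficientInstrumentsError
from .instruments import LDReference


@dataclass
class RunConfig:
    """Thresholds and policies for one exposure-outcome analysis."""

    exposure_label: str = "exposure"
    outcome_label: str = "outcome"
    p_threshold: float = 5e-8
    ld_r2: float = 0.01
    proxy_r2: float = 0.9
    strict_ld: bool = False
    palindrome_policy: str = "infer_by_eaf"
    eaf_ambiguity_band: float = 0.08
    alpha: float = 0.05
    n_exposures: int = 1
    n_outcomes: int = 1
    scale_factor: float = 1.0
    ivw_model: str = "random"
    n_boot: int = 1000
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in d.items() if k in known})


@dataclass
class RunResult:
    instrument_set: summary_stats.HarmonizedInstrumentSet
    estimates: list
    verdicts: list
    leave_one_out: list | None
    pleiotropy: sensitivity.PleiotropyReport | None
    report: reporting.ResultsBundle
    threshold: float


def _proxy_instruments(
    hset, exposure, outcome, ld, config
) -> summary_stats.HarmonizedInstrumentSet:
    """Substitute proxies for instruments missing from the outcome study.

    When the proxy is itself in the exposure table, its exposure and outcome
    records are harmonized and recorded under the target id; otherwise the
    target's exposure stats are paired with the proxy's outcome stats as
    reported (proxy assumed aligned to its reported effect allele).
    """
    missing = hset.dropped.loc[
        hset.dropped["reason"] == "missing_in_outcome", "variant_id"
    ].tolist()
    if not missing or ld is None:
        return hset
    subs, _unsub = instruments.substitute_proxies(
        missing, ld, outcome, r2_min=config.proxy_r2, exposure=exposure
    )
    if not subs:
        return hset
    exp_by_id = {r.variant_id: r for r in exposure.itertuples(index=False)}
    new_rows, resolved = [], set()
    for target, proxy, r2 in subs:
        exp_row = exp_by_id.get(proxy, exp_by_id.get(target))
        pair = summary_stats.harmonize(
            summary_stats.associations_to_frame(
                [
                    summary_stats.VariantAssociation(
                        variant_id=proxy,
                        effect_allele=exp_row.effect_allele,
                        other_allele=exp_row.other_allele,
                        beta=exp_row.beta,
                        se=exp_row.se,
                        p_value=exp_row.p_value,
                        eaf=exp_row.eaf,
                        n=exp_row.n,
                    )
                ]
            ),
            outcome,
            palindrome_policy=config.palindrome_policy,
            eaf_ambiguity_band=config.eaf_ambiguity_band,
        )
        if pair.k != 1:
            continue
        row = pair.instruments.iloc[0].to_dict()
        row.update(
            variant_id=target,
            status="proxy",
            proxy_id=proxy,
            r2_with_proxy=r2,
        )
        new_rows.append(row)
        resolved.add(target)
    if not new_rows:
        return hset
    kept = pd.concat([hset.instruments, pd.DataFrame(new_rows)], ignore_index=True)
    dropped = hset.dropped[~hset.dropped["variant_id"].isin(resolved)].reset_index(
        drop=True
    )
    return summary_stats.HarmonizedInstrumentSet(
        instruments=kept,
        dropped=dropped,
        exposure_label=hset.exposure_label,
        outcome_label=hset.outcome_label,
    )


def run_analysis(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    config: RunConfig,
    ld: LDReference | None = None,
) -> RunResult:
    """Run the full two-sample MR analysis for one exposure-outcome pair."""
    selected = instruments.select_instruments(exposure, config.p_threshold)
    if ld is not None:
        selected = instruments.ld_prune(selected, ld, config.ld_r2, strict=config.strict_ld)
    hset = summary_stats.harmonize(
        selected,
        outcome,
        palindrome_policy=config.palindrome_policy,
        eaf_ambiguity_band=config.eaf_ambiguity_band,
        exposure_label=config.exposure_label,
        outcome_label=config.outcome_label,
    )
    # search the full exposure table so a proxy need not itself be a
    # genome-wide-significant instrument
    hset = _proxy_instruments(hset, exposure, outcome, ld, config)
    if hset.k == 0:
        raise InsufficientInstrumentsError(
            f"no instruments survive selection/harmonization for "
            f"{config.exposure_label} -> {config.outcome_label}"
        )

    ests = [estimators.ivw(hset, model=config.ivw_model)]
    loo = None
    plei = None
    if hset.k >= 2:
        loo = sensitivity.leave_one_out(hset, alpha=config.alpha, model=config.ivw_model)
    if hset.k >= 3:
        slope, intercept = estimators.egger(hset)
        ests += [slope, intercept]
        ests.append(
            estimators.median_estimate(
                hset, "weighted", n_boot=config.n_boot, seed=config.seed
            )
        )
        ests.append(
            estimators.median_estimate(
                hset, "simple", n_boot=config.n_boot, seed=config.seed + 1
            )
        )
        plei = sensitivity.pleiotropy_report(hset)

    threshold = reporting.bonferroni_threshold(
        config.n_exposures, config.n_outcomes, config.alpha
    )
    ests = [
        estimators.MREstimate(
            e.method, e.beta, e.se, e.p_value, e.k, scale_factor=config.scale_factor
        )
        for e in ests
    ]
    verdicts = [
        reporting.make_verdict(
            config.exposure_label, config.outcome_label, e, threshold, config.alpha
        )
        for e in ests
    ]
    sens_map = {
        (config.exposure_label, config.outcome_label): {
            "pleiotropy": plei,
            "leave_one_out": loo,
        }
    }
    report = reporting.compile_report(verdicts, sens_map)
    return RunResult(
        instrument_set=hset,
        estimates=ests,
        verdicts=verdicts,
        leave_one_out=loo,
        pleiotropy=plei,
        report=report,
        threshold=threshold,
    )


def write_run(result: RunResult, out_dir) -> None:
    """Write harmonization log, instrument table, estimates, sensitivity, report."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result.instrument_set.write(out_dir / "instruments.tsv")
    estimators.estimates_to_frame(
        result.estimates,
        exposure=result.instrument_set.exposure_label,
        outcome=result.instrument_set.outcome_label,
    ).to_csv(out_dir / "estimates.tsv", sep="\t", index=False)
    if result.leave_one_out is not None:
        sensitivity.loo_to_frame(result.leave_one_out).to_csv(
            out_dir / "sensitivity.tsv", sep="\t", index=False
        )
    result.report.write(out_dir / "report.tsv", out_dir / "report.txt")
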