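"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator draws per-variant true exposure effects gamma_j scaled so the
instrument set explains a target fraction of variance of a standardized
exposure, adds configurable pleiotropic direct effects alpha_j, and forms
true outcome effects Gamma_j = beta * gamma_j + alpha_j.  Observed summary
statistics add sampling noise with allele-frequency- and sample-size-driven
standard errors, sigma^2 = 1/(2 n p (1-p)) per study (optionally divided by
cf(1-cf) for a binary outcome with case fraction cf).  Allele encodings
include a configurable fraction of palindromic variants and of variants
whose outcome records are re-encoded with swapped alleles and negated betas,
so the harmonization stage is exercised end to end.  LD is block-diagonal.

Everything is reproducible from the config seed; there is no hidden global
randomness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DomainError
from .instruments import LDReference

_NONPALINDROMIC_PAIRS = (
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
)
_PALINDROMIC_PAIRS = (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"))


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic two-sample MR dataset.

    true_beta is the causal effect of a 1-SD increase in the exposure on the
    outcome (log odds when the outcome is binary); instrument_r2_total the
    exposure variance jointly explained by the variants; pleiotropy_mode one
    of none/balanced/directional with Normal(mean, sd^2) direct effects
    applied to a pleiotropy_fraction subset of variants.
    """

    n_variants: int
    n_exposure: int
    n_outcome: int
    true_beta: float
    instrument_r2_total: float
    seed: int
    pleiotropy_mode: str = "none"
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    pleiotropy_fraction: float = 1.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    palindromic_fraction: float = 0.0
    allele_swap_fraction: float = 0.0
    ld_block_sizes: tuple[int, ...] = ()
    within_block_r2: float = 0.0
    case_fraction_outcome: float | None = None

    def __post_init__(self):
        if self.n_variants < 1 or self.n_exposure < 1 or self.n_outcome < 1:
            raise ConfigError("n_variants and sample sizes must be positive")
        if not 0 < self.instrument_r2_total < 1:
            raise ConfigError("instrument_r2_total must be in (0, 1)")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise ConfigError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if self.pleiotropy_sd < 0:
            raise ConfigError("pleiotropy_sd must be >= 0")
        for name in ("pleiotropy_fraction", "palindromic_fraction", "allele_swap_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ConfigError(f"{name} must be in [0, 1]")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigError("maf_range must satisfy 0 < low <= high <= 0.5")
        if sum(self.ld_block_sizes) > self.n_variants:
            raise ConfigError("ld_block_sizes sum exceeds n_variants")
        if any(b < 1 for b in self.ld_block_sizes):
            raise ConfigError("ld_block_sizes must be positive")
        if not 0 <= self.within_block_r2 < 1:
            raise ConfigError("within_block_r2 must be in [0, 1)")
        if self.case_fraction_outcome is not None and not 0 < self.case_fraction_outcome < 1:
            raise ConfigError("case_fraction_outcome must be in (0, 1)")


@dataclass
class SyntheticTruth:
    """Ground truth behind one generated dataset."""

    true_beta: float
    per_variant_gamma: np.ndarray
    per_variant_alpha: np.ndarray
    mafs: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self):
        if len(self.per_variant_gamma) != len(self.per_variant_alpha):
            raise ConfigError("gamma and alpha lengths differ")

    def to_frame(self, variant_ids: Sequence[str]) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variant_id": list(variant_ids),
                "gamma": self.per_variant_gamma,
                "alpha": self.per_variant_alpha,
                "maf": self.mafs,
                "true_beta": self.true_beta,
            }
        )


def realized_r2(truth: SyntheticTruth, mafs: np.ndarray) -> float:
    """Variance of a standardized exposure explained: sum of 2 p (1-p) gamma^2."""
    gamma = np.asarray(truth.per_variant_gamma, float)
    p = np.asarray(mafs, float)
    if len(gamma) != len(p):
        raise DomainError("gamma and maf lengths differ")
    return float(np.sum(2.0 * p * (1.0 - p) * gamma**2))


def _wald_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta) / se)
    return np.clip(p, np.nextafter(0.0, 1.0), 1.0)


def generate_dataset(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, LDReference, SyntheticTruth]:
    """Draw one synthetic dataset: (exposure table, outcome table, LD, truth).

    The exposure and outcome tables use the pipeline's standard summary-
    statistics columns and are byte-identical across calls with the same
    config.
    """
    rng = np.random.default_rng(config.seed)
    m = config.n_variants
    ids = [f"rs{j + 1:07d}" for j in range(m)]

    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    het = 2.0 * mafs * (1.0 - mafs)

    # effect allele = exposure-increasing allele (the usual MR instrument-table
    # convention), so gamma > 0; magnitudes bounded away from zero, then
    # scaled so the realized variance explained hits the target exactly
    gamma = 0.3 + np.abs(rng.normal(0.0, 1.0, size=m))
    gamma *= np.sqrt(config.instrument_r2_total / np.sum(het * gamma**2))

    alpha = np.zeros(m)
    if config.pleiotropy_mode != "none":
        n_plei = int(round(config.pleiotropy_fraction * m))
        which = rng.choice(m, size=n_plei, replace=False)
        mean = config.pleiotropy_mean if config.pleiotropy_mode == "directional" else 0.0
        alpha[which] = rng.normal(mean, config.pleiotropy_sd, size=n_plei)
    big_gamma = config.true_beta * gamma + alpha

    se_x = np.sqrt(1.0 / (2.0 * config.n_exposure * mafs * (1.0 - mafs)))
    out_var = 1.0 / (2.0 * config.n_outcome * mafs * (1.0 - mafs))
    if config.case_fraction_outcome is not None:
        cf = config.case_fraction_outcome
        out_var = out_var / (cf * (1.0 - cf))
    se_y = np.sqrt(out_var)

    beta_x_hat = rng.normal(gamma, se_x)
    beta_y_hat = rng.normal(big_gamma, se_y)

    palindromic = rng.random(m) < config.palindromic_fraction
    pal_choice = rng.integers(0, len(_PALINDROMIC_PAIRS), size=m)
    npal_choice = rng.integers(0, len(_NONPALINDROMIC_PAIRS), size=m)
    ea = np.where(
        palindromic,
        [_PALINDROMIC_PAIRS[c][0] for c in pal_choice],
        [_NONPALINDROMIC_PAIRS[c][0] for c in npal_choice],
    )
    oa = np.where(
        palindromic,
        [_PALINDROMIC_PAIRS[c][1] for c in pal_choice],
        [_NONPALINDROMIC_PAIRS[c][1] for c in npal_choice],
    )

    exposure = pd.DataFrame(
        {
            "variant_id": ids,
            "effect_allele": ea,
            "other_allele": oa,
            "eaf": mafs,
            "beta": beta_x_hat,
            "se": se_x,
            "p_value": _wald_p(beta_x_hat, se_x),
            "n": float(config.n_exposure),
        }
    )

    swap = rng.random(m) < config.allele_swap_fraction
    outcome = pd.DataFrame(
        {
            "variant_id": ids,
            "effect_allele": np.where(swap, oa, ea),
            "other_allele": np.where(swap, ea, oa),
            "eaf": np.where(swap, 1.0 - mafs, mafs),
            "beta": np.where(swap, -beta_y_hat, beta_y_hat),
            "se": se_y,
            "p_value": _wald_p(beta_y_hat, se_y),
            "n": float(config.n_outcome),
        }
    )

    ld = LDReference()
    ld.add_variants(ids)
    start = 0
    for size in config.ld_block_sizes:
        block = ids[start : start + size]
        for i in range(len(block)):
            for j in range(i + 1, len(block)):
                ld.set(block[i], block[j], config.within_block_r2)
        start += size

    truth = SyntheticTruth(
        true_beta=config.true_beta,
        per_variant_gamma=gamma,
        per_variant_alpha=alpha,
        mafs=mafs,
    )
    return exposure, outcome, ld, truth


def write_dataset(
    config: GeneratorConfig,
    out_dir,
) -> None:
    """Generate and write exposure.tsv, outcome.tsv, ld.tsv, truth.tsv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    exposure, outcome, ld, truth = generate_dataset(config)
    column_names = {
        "eaf": "effect_allele_frequency",
        "se": "standard_error",
    }
    exposure.rename(columns=column_names).to_csv(
        out_dir / "exposure.tsv", sep="\t", index=False
    )
    outcome.rename(columns=column_names).to_csv(
        out_dir / "outcome.tsv", sep="\t", index=False
    )
    ld.to_long_frame().to_csv(out_dir / "ld.tsv", sep="\t", index=False)
    truth.to_frame(exposure["variant_id"]).to_csv(
        out_dir / "truth.tsv", sep="\t", index=False
    )
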