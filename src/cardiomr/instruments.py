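"""Instrument selection and strength diagnostics.

Selection follows the conventional two-sample MR recipe: keep genome-wide
significant variants (P < 5e-8), greedily prune to pairwise linkage
disequilibrium r^2 < 0.01 keeping the lowest-p variant of each correlated
group, and substitute high-LD proxies (r^2 > 0.9) for instruments missing
from the outcome study.  Strength diagnostics are the multi-instrument
F-statistic, the per-variant squared Wald statistic, and a normal-
approximation power calculation for a binary outcome.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, UnknownVariantError


class LDReference:
    """Symmetric pairwise r^2 lookup over candidate variants.

    Pairs absent from the lookup are treated as r^2 = 0; the diagonal is 1.
    """

    def __init__(self, r2: Mapping[tuple[str, str], float] | None = None):
        self._r2: dict[tuple[str, str], float] = {}
        self._ids: set[str] = set()
        if r2:
            for (a, b), val in r2.items():
                self.set(a, b, val)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def set(self, a: str, b: str, value: float) -> None:
        value = float(value)
        if not 0.0 <= value <= 1.0:
            raise DomainError(f"r2({a},{b})={value} outside [0, 1]")
        self._ids.update((a, b))
        if a != b:
            self._r2[self._key(a, b)] = value

    def get(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._r2.get(self._key(a, b), 0.0)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._ids

    @property
    def variant_ids(self) -> frozenset[str]:
        return frozenset(self._ids)

    def add_variants(self, ids: Iterable[str]) -> None:
        """Register variants known to the panel even if all their r2 are 0."""
        self._ids.update(ids)

    @classmethod
    def from_long_frame(cls, df: pd.DataFrame) -> "LDReference":
        """Build from long format with columns id_a, id_b, r2."""
        ref = cls()
        for a, b, v in zip(df.iloc[:, 0], df.iloc[:, 1], df.iloc[:, 2]):
            ref.set(str(a), str(b), float(v))
        return ref

    @classmethod
    def from_matrix_frame(cls, df: pd.DataFrame) -> "LDReference":
        """Build from a square matrix with variant ids as header and index."""
        ref = cls()
        ids = [str(c) for c in df.columns]
        mat = df.to_numpy(float)
        if mat.shape[0] != mat.shape[1]:
            raise DomainError("LD matrix is not square")
        if not np.allclose(mat, mat.T, atol=1e-12):
            raise DomainError("LD matrix is not symmetric")
        ref.add_variants(ids)
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                if mat[i, j] != 0.0:
                    ref.set(ids[i], ids[j], mat[i, j])
        return ref

    @classmethod
    def from_tsv(cls, path) -> "LDReference":
        """Read either dialect: long (id_a, id_b, r2) or square matrix TSV."""
        df = pd.read_csv(path, sep="\t")
        cols = [c.lower() for c in df.columns]
        if len(df.columns) == 3 and "r2" in cols:
            return cls.from_long_frame(df)
        return cls.from_matrix_frame(df.set_index(df.columns[0]))

    def to_long_frame(self) -> pd.DataFrame:
        rows = sorted((a, b, v) for (a, b), v in self._r2.items())
        return pd.DataFrame(rows, columns=["id_a", "id_b", "r2"])


@dataclass(frozen=True)
class InstrumentDiagnostics:
    """Instrument-set strength and power summary for one exposure."""

    r2_explained: float
    n_exposure: int
    k: int
    f_statistic: float
    power: float


def select_instruments(assocs: pd.DataFrame, p_threshold: float = 5e-8) -> pd.DataFrame:
    """Keep rows with p_value strictly below the significance threshold."""
    if not 0 < p_threshold < 1:
        raise DomainError(f"p_threshold {p_threshold} outside (0, 1)")
    return assocs[assocs["p_value"] < p_threshold].reset_index(drop=True)


def ld_prune(
    assocs: pd.DataFrame,
    ld: LDReference,
    r2_threshold: float = 0.01,
    strict: bool = False,
) -> pd.DataFrame:
    """Greedy lowest-p LD pruning.

    Candidates are ranked by ascending p-value (ties by variant_id); the best
    remaining variant is accepted and every remaining variant in LD with it
    (r^2 >= r2_threshold) discarded.  The accepted set is returned in
    acceptance order and is pairwise independent at the threshold.
    """
    if not 0 < r2_threshold <= 1:
        raise DomainError(f"r2_threshold {r2_threshold} outside (0, 1]")
    if strict:
        for vid in assocs["variant_id"]:
            if vid not in ld:
                raise UnknownVariantError(vid)
    ranked = assocs.sort_values(
        ["p_value", "variant_id"], kind="mergesort"
    ).reset_index(drop=True)
    accepted: list[str] = []
    remaining = list(ranked.itertuples(index=False))
    while remaining:
        best = remaining.pop(0)
        accepted.append(best.variant_id)
        remaining = [
            r for r in remaining if ld.get(best.variant_id, r.variant_id) < r2_threshold
        ]
    order = {vid: i for i, vid in enumerate(accepted)}
    kept = assocs[assocs["variant_id"].isin(order)].copy()
    kept["_rank"] = kept["variant_id"].map(order)
    return kept.sort_values("_rank").drop(columns="_rank").reset_index(drop=True)


def substitute_proxies(
    missing: Iterable[str],
    ld: LDReference,
    outcome: pd.DataFrame,
    r2_min: float = 0.9,
    exposure: pd.DataFrame | None = None,
) -> tuple[list[tuple[str, str, float]], list[str]]:
    """Find outcome-present proxies for instruments missing from the outcome.

    For each missing target the outcome-present variant with the highest
    r^2 strictly greater than ``r2_min`` is chosen; ties break by smaller
    exposure p-value (when an exposure table is supplied), then lexicographic
    variant_id.  Returns ``(substitutions, unsubstituted)`` where
    substitutions are ``(target_id, proxy_id, r2)`` triples.
    """
    outcome_ids = list(dict.fromkeys(outcome["variant_id"]))
    exp_p: dict[str, float] = {}
    if exposure is not None:
        exp_p = dict(zip(exposure["variant_id"], exposure["p_value"]))

    substitutions, unsubstituted = [], []
    for target in missing:
        candidates = [
            (cand, ld.get(target, cand))
            for cand in outcome_ids
            if cand != target and ld.get(target, cand) > r2_min
        ]
        if not candidates:
            unsubstituted.append(target)
            continue
        candidates.sort(key=lambda cr: (-cr[1], exp_p.get(cr[0], np.inf), cr[0]))
        proxy, r2 = candidates[0]
        substitutions.append((target, proxy, r2))
    return substitutions, unsubstituted


def instrument_f_statistic(r2_explained: float, n: int, k: int) -> float:
    """Multi-instrument F-statistic: (r2/(1-r2)) * ((n-k-1)/k)."""
    if not 0 <= r2_explained < 1:
        raise DomainError(f"r2_explained {r2_explained} outside [0, 1)")
    if n <= k + 1:
        raise DomainError(f"need n > k+1 (n={n}, k={k})")
    return (r2_explained / (1.0 - r2_explained)) * ((n - k - 1) / k)


def per_variant_f(beta: float, se: float) -> float:
    """Per-instrument strength: squared Wald z, (beta/se)^2."""
    if se <= 0:
        raise DomainError(f"se must be > 0, got {se}")
    return (beta / se) ** 2


def mr_power_binary(
    n: int,
    case_fraction: float,
    r2_explained: float,
    or_alternative: float,
    alpha: float = 0.05,
) -> float:
    """Approximate power of the IVW z-test for a binary outcome.

    Uses the normal-approximation non-centrality
    ``lambda = |ln OR| * sqrt(n * r2 * cf * (1 - cf))``;
    power = Phi(lambda - z*) + Phi(-lambda - z*).  Returns exactly ``alpha``
    when ``or_alternative`` is 1.
    """
    if not 0 < alpha < 1:
        raise DomainError(f"alpha {alpha} outside (0, 1)")
    if or_alternative <= 0:
        raise DomainError(f"or_alternative must be > 0, got {or_alternative}")
    if not 0 < case_fraction < 1:
        raise DomainError(f"case_fraction {case_fraction} outside (0, 1)")
    if not 0 <= r2_explained < 1:
        raise DomainError(f"r2_explained {r2_explained} outside [0, 1)")
    if n <= 0:
        raise DomainError(f"n must be positive, got {n}")
    b = np.log(or_alternative)
    z_crit = stats.norm.ppf(1.0 - alpha / 2.0)
    lam = abs(b) * np.sqrt(n * r2_explained * case_fraction * (1.0 - case_fraction))
    return float(stats.norm.cdf(lam - z_crit) + stats.norm.cdf(-lam - z_crit))


def diagnose(
    r2_explained: float,
    n_exposure: int,
    k: int,
    n_outcome: int,
    case_fraction: float,
    or_alternative: float,
    alpha: float = 0.05,
) -> InstrumentDiagnostics:
    """Bundle the F-statistic and power for a selected instrument set."""
    return InstrumentDiagnostics(
        r2_explained=r2_explained,
        n_exposure=n_exposure,
        k=k,
        f_statistic=instrument_f_statistic(r2_explained, n_exposure, k),
        power=mr_power_binary(n_outcome, case_fraction, r2_explained, or_alternative, alpha),
    )


def write_ld_reference(ld: LDReference, path) -> None:
    ld.to_long_frame().to_csv(Path(path), sep="\t", index=False)
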