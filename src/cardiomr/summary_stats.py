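"""GWAS summary-statistics data model, file I/O, and allele harmonization.

The central object is the :class:`HarmonizedInstrumentSet`: per-variant
exposure and outcome effect estimates expressed for a common effect allele,
with a full provenance log of every variant that was flipped, inferred from
allele frequency, proxied, or dropped.  Harmonization follows rsID-level
matching only; positional matching, liftover, and multi-allelic variants are
out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    EmptyFileError,
    MalformedFileError,
    MissingColumnError,
)

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Standard field names used throughout the pipeline.
STANDARD_FIELDS = (
    "variant_id",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "p_value",
    "n",
)

#: Default on-disk column names (GWAS-SSF-like dialect); overridable via column_map.
DEFAULT_COLUMN_MAP = {
    "variant_id": "variant_id",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "effect_allele_frequency",
    "beta": "beta",
    "se": "standard_error",
    "p_value": "p_value",
    "n": "n",
}

REQUIRED_FIELDS = ("variant_id", "effect_allele", "other_allele", "beta", "se", "p_value")


@dataclass(frozen=True)
class VariantAssociation:
    """One variant's association with one trait in one study.

    beta is the per-effect-allele effect on the trait (log odds for binary
    traits); se its standard error; eaf the effect-allele frequency (NaN when
    unreported); n the study sample size.
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    p_value: float
    eaf: float = float("nan")
    n: float = float("nan")

    def __post_init__(self):
        if self.effect_allele not in VALID_BASES or self.other_allele not in VALID_BASES:
            raise ValueError(f"{self.variant_id}: alleles must be single bases A/C/G/T")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.variant_id}: effect and other allele identical")
        if not self.se > 0:
            raise ValueError(f"{self.variant_id}: se must be > 0")
        if not (0 < self.p_value <= 1):
            raise ValueError(f"{self.variant_id}: p_value must be in (0, 1]")


def associations_to_frame(assocs: Sequence[VariantAssociation]) -> pd.DataFrame:
    """Convert a sequence of VariantAssociation records to a standard table."""
    return pd.DataFrame([vars(a) for a in assocs], columns=list(STANDARD_FIELDS))


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True for A/T and C/G pairs, whose strand cannot be resolved from alleles."""
    return COMPLEMENT[effect_allele] == other_allele


def _detect_delimiter(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    if "\t" in header:
        return "\t"
    if "," in header:
        return ","
    raise ValueError(
        f"{path}: cannot auto-detect delimiter (only tab and comma are recognized); "
        "pass delimiter explicitly"
    )


def read_summary_stats(
    path,
    column_map: Mapping[str, str] | None = None,
    delimiter: str | None = None,
) -> pd.DataFrame:
    """Read a delimited GWAS summary-statistics file into the standard table.

    Parameters
    ----------
    path
        Tab- or comma-delimited text file with a header row.
    column_map
        Mapping standard field name -> file column name, overriding the
        GWAS-SSF-like defaults.  Must cover variant_id, effect_allele,
        other_allele, beta, se, p_value; eaf and n are optional.
    delimiter
        Explicit delimiter; auto-detected (tab then comma) when omitted.

    Returns
    -------
    DataFrame with columns ``variant_id, effect_allele, other_allele, eaf,
    beta, se, p_value, n`` in file order.  Rows failing validation are
    dropped, logged, and recorded in ``df.attrs["rejected"]`` as
    ``(row_number, reason)`` pairs.
    """
    path = Path(path)
    colmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        colmap.update(column_map)

    sep = delimiter or _detect_delimiter(path)
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for fld in REQUIRED_FIELDS:
        if colmap[fld] not in raw.columns:
            raise MissingColumnError(fld, colmap[fld])
    if len(raw) == 0:
        raise EmptyFileError(f"{path}: no data rows")

    rows, rejected = [], []
    has_eaf = colmap["eaf"] in raw.columns
    has_n = colmap["n"] in raw.columns
    for i, rec in enumerate(raw.itertuples(index=False)):
        rec = dict(zip(raw.columns, rec))
        try:
            ea = rec[colmap["effect_allele"]].strip().upper()
            oa = rec[colmap["other_allele"]].strip().upper()
            beta = float(rec[colmap["beta"]])
            se = float(rec[colmap["se"]])
            p = float(rec[colmap["p_value"]])
            eaf = float(rec[colmap["eaf"]]) if has_eaf and rec[colmap["eaf"]] != "" else np.nan
            n = float(rec[colmap["n"]]) if has_n and rec[colmap["n"]] != "" else np.nan
            assoc = VariantAssociation(
                variant_id=str(rec[colmap["variant_id"]]).strip(),
                effect_allele=ea,
                other_allele=oa,
                beta=beta,
                se=se,
                p_value=p,
                eaf=eaf,
                n=n,
            )
            if not (np.isnan(eaf) or 0 < eaf < 1):
                raise ValueError(f"{assoc.variant_id}: eaf must be in (0, 1)")
            if not np.isfinite(beta):
                raise ValueError(f"{assoc.variant_id}: beta not finite")
            rows.append(assoc)
        except (ValueError, KeyError) as exc:
            rejected.append((i, str(exc)))
            logger.warning("rejected row %d of %s: %s", i, path.name, exc)

    if not rows:
        raise MalformedFileError(f"{path}: all {len(raw)} data rows malformed")
    out = associations_to_frame(rows)
    out.attrs["rejected"] = rejected
    return out


@dataclass
class HarmonizedInstrumentSet:
    """Exposure/outcome effects on a common effect-allele orientation.

    ``instruments`` columns: variant_id, beta_exposure, se_exposure,
    beta_outcome, se_outcome, eaf_exposure, eaf_outcome, status, proxy_id,
    r2_with_proxy.  ``dropped`` columns: variant_id, reason.
    """

    instruments: pd.DataFrame
    dropped: pd.DataFrame
    exposure_label: str = ""
    outcome_label: str = ""

    INSTRUMENT_COLUMNS = (
        "variant_id",
        "beta_exposure",
        "se_exposure",
        "beta_outcome",
        "se_outcome",
        "eaf_exposure",
        "eaf_outcome",
        "status",
        "proxy_id",
        "r2_with_proxy",
    )

    def __post_init__(self):
        ids = self.instruments["variant_id"]
        if ids.duplicated().any():
            raise ValueError("duplicate variant_id in harmonized instruments")
        overlap = set(ids) & set(self.dropped["variant_id"])
        if overlap:
            raise ValueError(f"variants both kept and dropped: {sorted(overlap)}")

    @property
    def k(self) -> int:
        return len(self.instruments)

    @property
    def beta_exposure(self) -> np.ndarray:
        return self.instruments["beta_exposure"].to_numpy(float)

    @property
    def se_exposure(self) -> np.ndarray:
        return self.instruments["se_exposure"].to_numpy(float)

    @property
    def beta_outcome(self) -> np.ndarray:
        return self.instruments["beta_outcome"].to_numpy(float)

    @property
    def se_outcome(self) -> np.ndarray:
        return self.instruments["se_outcome"].to_numpy(float)

    def write(self, path) -> None:
        """Write instruments to TSV and the drop log to a sibling *.dropped.tsv."""
        path = Path(path)
        self.instruments.to_csv(path, sep="\t", index=False)
        self.dropped.to_csv(path.with_suffix(".dropped.tsv"), sep="\t", index=False)


def _empty_instruments() -> pd.DataFrame:
    return pd.DataFrame(columns=list(HarmonizedInstrumentSet.INSTRUMENT_COLUMNS))


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    palindrome_policy: str = "infer_by_eaf",
    eaf_ambiguity_band: float = 0.08,
    exposure_label: str = "",
    outcome_label: str = "",
) -> HarmonizedInstrumentSet:
    """Pair exposure and outcome effects per variant on the exposure's effect allele.

    For each exposure variant present in the outcome table:

    * same orientation (or its strand complement) -> keep ``beta_outcome``
      as-is, status ``direct``;
    * swapped alleles (or swapped complement) -> negate ``beta_outcome`` and
      flip the outcome EAF, status ``allele_flipped``;
    * palindromic pair (A/T or C/G): under ``palindrome_policy="drop"``
      exclude; under ``"infer_by_eaf"`` orient by comparing effect-allele
      frequencies, negating the outcome effect when the frequencies fall on
      opposite sides of 0.5, and drop when either EAF lies within
      0.5 ± ``eaf_ambiguity_band`` (reason ``"ambiguous palindrome"``) or is
      missing.

    Exposure variants absent from the outcome are recorded in ``dropped`` with
    reason ``"missing_in_outcome"`` (proxy search is a separate step).  The
    operation is idempotent: re-harmonizing its own output changes nothing.
    """
    if palindrome_policy not in ("infer_by_eaf", "drop"):
        raise ValueError(f"unknown palindrome_policy {palindrome_policy!r}")
    out_by_id = {r.variant_id: r for r in outcome.itertuples(index=False)}

    kept, dropped = [], []
    for exp in exposure.itertuples(index=False):
        out = out_by_id.get(exp.variant_id)
        if out is None:
            dropped.append((exp.variant_id, "missing_in_outcome"))
            continue
        ea, oa = exp.effect_allele, exp.other_allele
        oea, ooa = out.effect_allele, out.other_allele
        by, eaf_out = float(out.beta), float(out.eaf)

        if is_palindromic(ea, oa):
            if {oea, ooa} != {ea, oa}:
                dropped.append((exp.variant_id, "allele_mismatch"))
                continue
            if palindrome_policy == "drop":
                dropped.append((exp.variant_id, "palindromic"))
                continue
            eaf_exp = float(exp.eaf)
            if np.isnan(eaf_exp) or np.isnan(eaf_out):
                dropped.append((exp.variant_id, "palindrome missing eaf"))
                continue
            # reported-letter alignment first; the frequency check then
            # resolves the residual strand ambiguity
            if oea != ea:
                by, eaf_out = -by, 1.0 - eaf_out
            if (
                abs(eaf_exp - 0.5) <= eaf_ambiguity_band
                or abs(eaf_out - 0.5) <= eaf_ambiguity_band
            ):
                dropped.append((exp.variant_id, "ambiguous palindrome"))
                continue
            if (eaf_exp - 0.5) * (eaf_out - 0.5) < 0:
                by, eaf_out = -by, 1.0 - eaf_out
            status = "palindromic_inferred"
        else:
            cea, coa = COMPLEMENT[oea], COMPLEMENT[ooa]
            if (oea, ooa) == (ea, oa) or (cea, coa) == (ea, oa):
                status = "direct"
            elif (ooa, oea) == (ea, oa) or (coa, cea) == (ea, oa):
                by, eaf_out = -by, 1.0 - eaf_out
                status = "allele_flipped"
            else:
                dropped.append((exp.variant_id, "allele_mismatch"))
                continue

        kept.append(
            {
                "variant_id": exp.variant_id,
                "beta_exposure": float(exp.beta),
                "se_exposure": float(exp.se),
                "beta_outcome": by,
                "se_outcome": float(out.se),
                "eaf_exposure": float(exp.eaf),
                "eaf_outcome": eaf_out,
                "status": status,
                "proxy_id": "",
                "r2_with_proxy": np.nan,
            }
        )

    instruments = pd.DataFrame(kept) if kept else _empty_instruments()
    drop_log = pd.DataFrame(dropped, columns=["variant_id", "reason"])
    return HarmonizedInstrumentSet(
        instruments=instruments,
        dropped=drop_log,
        exposure_label=exposure_label,
        outcome_label=outcome_label,
    )


def harmonized_to_tables(hset: HarmonizedInstrumentSet) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Re-express a harmonized set as exposure/outcome association tables.

    Both tables carry the exposure's allele orientation; feeding them back
    through :func:`harmonize` reproduces the same numeric content (idempotence).
    Alleles are synthesized as A/G for variants whose originals are not kept;
    callers needing the true alleles should retain the source tables.
    """
    ins = hset.instruments
    base = {
        "variant_id": ins["variant_id"],
        "effect_allele": "A",
        "other_allele": "G",
    }
    exp = pd.DataFrame(
        {
            **base,
            "eaf": ins["eaf_exposure"],
            "beta": ins["beta_exposure"],
            "se": ins["se_exposure"],
            "p_value": 1.0,
            "n": np.nan,
        }
    )
    out = pd.DataFrame(
        {
            **base,
            "eaf": ins["eaf_outcome"],
            "beta": ins["beta_outcome"],
            "se": ins["se_outcome"],
            "p_value": 1.0,
            "n": np.nan,
        }
    )
    return exp, out
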