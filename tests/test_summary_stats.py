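"""File I/O and allele-harmonization behavior."""

import numpy as np
import pandas as pd
import pytest

from cardiomr.errors import EmptyFileError, MalformedFileError, MissingColumnError
from cardiomr.summary_stats import (
    DEFAULT_COLUMN_MAP,
    HarmonizedInstrumentSet,
    VariantAssociation,
    harmonize,
    harmonized_to_tables,
    is_palindromic,
    read_summary_stats,
)
from cardiomr.synthetic import generate_dataset

from conftest import make_config, write_tsv


def _stats_frame(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "variant_id",
            "effect_allele",
            "other_allele",
            "effect_allele_frequency",
            "beta",
            "standard_error",
            "p_value",
            "n",
        ],
    )


class TestReadSummaryStats:
    def test_well_formed_tsv_preserves_file_order(self, tmp_path):
        df = _stats_frame(
            [
                ("rs3", "A", "G", 0.2, 0.1, 0.01, 1e-9, 500),
                ("rs1", "C", "T", 0.3, -0.2, 0.02, 1e-8, 500),
                ("rs2", "G", "A", 0.4, 0.05, 0.01, 0.5, 500),
            ]
        )
        path = write_tsv(tmp_path / "x.tsv", df)
        out = read_summary_stats(path)
        assert list(out["variant_id"]) == ["rs3", "rs1", "rs2"]
        assert len(out) == 3
        assert out.attrs["rejected"] == []

    def test_comma_delimiter_autodetected(self, tmp_path):
        df = _stats_frame([("rs1", "A", "G", 0.2, 0.1, 0.01, 1e-9, 500)])
        path = tmp_path / "x.csv"
        df.to_csv(path, index=False)
        assert len(read_summary_stats(path)) == 1

    def test_missing_se_column_raises_naming_field(self, tmp_path):
        df = _stats_frame([("rs1", "A", "G", 0.2, 0.1, 0.01, 1e-9, 500)])
        df = df.drop(columns=["standard_error"])
        path = write_tsv(tmp_path / "x.tsv", df)
        with pytest.raises(MissingColumnError, match="se"):
            read_summary_stats(path)

    def test_column_map_renames_fields(self, tmp_path):
        df = _stats_frame([("rs1", "A", "G", 0.2, 0.1, 0.01, 1e-9, 500)])
        df = df.rename(columns={"beta": "EFFECT", "standard_error": "SE"})
        path = write_tsv(tmp_path / "x.tsv", df)
        out = read_summary_stats(path, column_map={"beta": "EFFECT", "se": "SE"})
        assert out["beta"].iloc[0] == pytest.approx(0.1)

    def test_lowercase_alleles_uppercased(self, tmp_path):
        df = _stats_frame([("rs1", "a", "t", 0.2, 0.1, 0.01, 1e-9, 500)])
        path = write_tsv(tmp_path / "x.tsv", df)
        out = read_summary_stats(path)
        assert out["effect_allele"].iloc[0] == "A"
        assert out["other_allele"].iloc[0] == "T"

    def test_malformed_rows_rejected_not_fatal(self, tmp_path):
        df = _stats_frame(
            [
                ("rs1", "A", "G", 0.2, 0.1, 0.01, 1e-9, 500),
                ("rs2", "A", "G", 0.2, "bogus", 0.01, 1e-9, 500),
                ("rs3", "A", "G", 0.2, 0.1, -0.5, 1e-9, 500),
            ]
        )
        path = write_tsv(tmp_path / "x.tsv", df)
        out = read_summary_stats(path)
        assert list(out["variant_id"]) == ["rs1"]
        assert len(out.attrs["rejected"]) == 2

    def test_all_rows_malformed_is_fatal(self, tmp_path):
        df = _stats_frame([("rs1", "A", "G", 0.2, "x", 0.01, 1e-9, 500)])
        path = write_tsv(tmp_path / "x.tsv", df)
        with pytest.raises(MalformedFileError):
            read_summary_stats(path)

    def test_empty_file_raises(self, tmp_path):
        path = write_tsv(tmp_path / "x.tsv", _stats_frame([]))
        with pytest.raises(EmptyFileError):
            read_summary_stats(path)


class TestVariantAssociation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(effect_allele="A", other_allele="A"),
            dict(effect_allele="N", other_allele="G"),
            dict(se=0.0),
            dict(p_value=0.0),
            dict(p_value=1.5),
        ],
    )
    def test_invariant_violations_rejected(self, kwargs):
        base = dict(
            variant_id="rs1",
            effect_allele="A",
            other_allele="G",
            beta=0.1,
            se=0.01,
            p_value=1e-9,
        )
        base.update(kwargs)
        with pytest.raises(ValueError):
            VariantAssociation(**base)


def _pair(exp_row, out_row):
    cols = ["variant_id", "effect_allele", "other_allele", "eaf", "beta", "se", "p_value", "n"]
    return (
        pd.DataFrame([exp_row], columns=cols),
        pd.DataFrame([out_row], columns=cols),
    )


class TestHarmonize:
    def test_allele_swap_negates_outcome_beta(self):
        exp, out = _pair(
            ("rs1", "A", "G", 0.2, 0.10, 0.01, 1e-9, 500),
            ("rs1", "G", "A", 0.8, -0.05, 0.01, 1e-3, 500),
        )
        h = harmonize(exp, out)
        assert h.k == 1
        row = h.instruments.iloc[0]
        assert row["beta_outcome"] == pytest.approx(0.05)
        assert row["eaf_outcome"] == pytest.approx(0.2)
        assert row["status"] == "allele_flipped"

    def test_palindrome_inferred_by_opposite_eaf(self):
        exp, out = _pair(
            ("rs1", "A", "T", 0.20, 0.10, 0.01, 1e-9, 500),
            ("rs1", "A", "T", 0.81, 0.05, 0.01, 1e-3, 500),
        )
        h = harmonize(exp, out, palindrome_policy="infer_by_eaf", eaf_ambiguity_band=0.08)
        row = h.instruments.iloc[0]
        assert row["beta_outcome"] == pytest.approx(-0.05)
        assert row["status"] == "palindromic_inferred"

    def test_palindrome_concordant_eaf_keeps_sign(self):
        exp, out = _pair(
            ("rs1", "C", "G", 0.20, 0.10, 0.01, 1e-9, 500),
            ("rs1", "C", "G", 0.22, 0.05, 0.01, 1e-3, 500),
        )
        h = harmonize(exp, out)
        assert h.instruments.iloc[0]["beta_outcome"] == pytest.approx(0.05)

    def test_ambiguous_palindrome_dropped(self):
        exp, out = _pair(
            ("rs1", "A", "T", 0.50, 0.10, 0.01, 1e-9, 500),
            ("rs1", "A", "T", 0.20, 0.05, 0.01, 1e-3, 500),
        )
        h = harmonize(exp, out, palindrome_policy="infer_by_eaf", eaf_ambiguity_band=0.08)
        assert h.k == 0
        assert list(h.dropped["reason"]) == ["ambiguous palindrome"]

    def test_palindrome_drop_policy(self):
        exp, out = _pair(
            ("rs1", "A", "T", 0.20, 0.10, 0.01, 1e-9, 500),
            ("rs1", "A", "T", 0.20, 0.05, 0.01, 1e-3, 500),
        )
        h = harmonize(exp, out, palindrome_policy="drop")
        assert h.k == 0

    def test_palindrome_missing_eaf_dropped(self):
        exp, out = _pair(
            ("rs1", "A", "T", np.nan, 0.10, 0.01, 1e-9, 500),
            ("rs1", "A", "T", 0.20, 0.05, 0.01, 1e-3, 500),
        )
        h = harmonize(exp, out)
        assert h.k == 0
        assert "eaf" in h.dropped["reason"].iloc[0]

    def test_strand_complement_recognized(self):
        # outcome coded on the other strand: A/G reported as T/C
        exp, out = _pair(
            ("rs1", "A", "G", 0.2, 0.10, 0.01, 1e-9, 500),
            ("rs1", "T", "C", 0.2, 0.05, 0.01, 1e-3, 500),
        )
        h = harmonize(exp, out)
        assert h.instruments.iloc[0]["status"] == "direct"
        assert h.instruments.iloc[0]["beta_outcome"] == pytest.approx(0.05)

    def test_missing_in_outcome_logged(self):
        exp, _ = _pair(
            ("rs1", "A", "G", 0.2, 0.10, 0.01, 1e-9, 500),
            ("rs1", "A", "G", 0.2, 0.05, 0.01, 1e-3, 500),
        )
        out = pd.DataFrame(columns=exp.columns)
        h = harmonize(exp, out)
        assert list(h.dropped["reason"]) == ["missing_in_outcome"]

    def test_kept_plus_dropped_covers_all_inputs(self):
        exposure, outcome, _ld, _truth = generate_dataset(
            make_config(seed=11, palindromic_fraction=0.3)
        )
        h = harmonize(exposure, outcome)
        assert h.k + len(h.dropped) == len(exposure)
        assert set(h.instruments["variant_id"]).isdisjoint(h.dropped["variant_id"])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_idempotence_on_generator_data(self, seed):
        """Re-harmonizing harmonized output changes nothing numerically."""
        exposure, outcome, _ld, _truth = generate_dataset(
            make_config(seed=seed, palindromic_fraction=0.2)
        )
        h1 = harmonize(exposure, outcome)
        exp2, out2 = harmonized_to_tables(h1)
        h2 = harmonize(exp2, out2)
        num_cols = ["beta_exposure", "se_exposure", "beta_outcome", "se_outcome"]
        assert list(h2.instruments["variant_id"]) == list(h1.instruments["variant_id"])
        np.testing.assert_allclose(
            h2.instruments[num_cols].to_numpy(float),
            h1.instruments[num_cols].to_numpy(float),
        )

    @pytest.mark.parametrize("seed", [3, 4])
    def test_sign_consistency_under_outcome_recoding(self, seed):
        """Swapping outcome alleles and negating beta leaves harmonization invariant."""
        exposure, outcome, _ld, _truth = generate_dataset(
            make_config(seed=seed, palindromic_fraction=0.2)
        )
        recoded = outcome.copy()
        recoded["effect_allele"], recoded["other_allele"] = (
            outcome["other_allele"],
            outcome["effect_allele"],
        )
        recoded["beta"] = -outcome["beta"]
        recoded["eaf"] = 1.0 - outcome["eaf"]
        h1 = harmonize(exposure, outcome)
        h2 = harmonize(exposure, recoded)
        assert list(h1.instruments["variant_id"]) == list(h2.instruments["variant_id"])
        np.testing.assert_allclose(
            h1.instruments["beta_outcome"].to_numpy(float),
            h2.instruments["beta_outcome"].to_numpy(float),
        )

    def test_swapped_variants_recovered_exactly(self):
        """Generator's swapped-allele outcome rows recover the unswapped betas."""
        config = make_config(seed=9, allele_swap_fraction=0.5)
        exposure, outcome, _ld, _truth = generate_dataset(config)
        h = harmonize(exposure, outcome)
        swapped = outcome["effect_allele"].to_numpy() != exposure["effect_allele"].to_numpy()
        true_by = np.where(swapped, -outcome["beta"], outcome["beta"])
        np.testing.assert_allclose(h.instruments["beta_outcome"].to_numpy(float), true_by)

    def test_duplicate_instrument_ids_rejected(self):
        df = pd.DataFrame(
            {
                "variant_id": ["rs1", "rs1"],
                "beta_exposure": [0.1, 0.1],
                "se_exposure": [0.01, 0.01],
                "beta_outcome": [0.1, 0.1],
                "se_outcome": [0.01, 0.01],
                "eaf_exposure": [0.2, 0.2],
                "eaf_outcome": [0.2, 0.2],
                "status": ["direct", "direct"],
                "proxy_id": ["", ""],
                "r2_with_proxy": [np.nan, np.nan],
            }
        )
        with pytest.raises(ValueError, match="duplicate"):
            HarmonizedInstrumentSet(df, pd.DataFrame(columns=["variant_id", "reason"]))


def test_is_palindromic():
    assert is_palindromic("A", "T") and is_palindromic("G", "C")
    assert not is_palindromic("A", "G")
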