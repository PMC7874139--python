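from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lyticpred.errors import ConfigError, DomainError, InputError
from lyticpred.features import (
    ACSTable,
    DIPEPTIDES,
    NUCLEI,
    EncoderConfig,
    FeatureVector,
    encode_aac,
    encode_acacs,
    encode_combined,
    encode_dc,
    encode_pssm_ac,
    substitute_acs,
)
from lyticpred.io import (
    AMINO_ACIDS,
    ProteinRecord,
    PSSMProfile,
    SecondaryStructureTrack,
)

from conftest import random_record


def rec(seq, rec_id="r", label=1):
    return ProteinRecord(id=rec_id, sequence=seq, label=label)


# ---------------------------------------------------------------- oracles

def aac_oracle(seq):
    return {aa: seq.count(aa) / len(seq) for aa in AMINO_ACIDS}


def dc_oracle(seq):
    pairs = [seq[i : i + 2] for i in range(len(seq) - 1)]
    return {dp: pairs.count(dp) / (len(seq) - 1) for dp in DIPEPTIDES}


def pssm_ac_oracle(scores, lg):
    """Naive double loop over columns and lags."""
    L = scores.shape[0]
    out = {}
    for j in range(20):
        mean_j = sum(scores[i, j] for i in range(L)) / L
        for lag in range(1, lg + 1):
            total = 0.0
            for i in range(L - lag):
                total += (scores[i, j] - mean_j) * (scores[i + lag, j] - mean_j)
            out[(j, lag)] = total / (L - lag)
    return out


def acacs_oracle(values, lam):
    """Naive loop: mean of signed differences at each lag."""
    L = len(values)
    out = {}
    for lag in range(lam + 1):
        total = 0.0
        for k in range(L - lag):
            total += values[k] - values[k + lag]
        out[lag] = total / (L - lag)
    return out


# ---------------------------------------------------------------- AAC

class TestAAC:
    def test_single_letter(self):
        v = encode_aac(rec("AAAA")).as_dict()
        assert v["AAC:A"] == 1.0
        assert sum(v.values()) == pytest.approx(1.0)
        assert all(v[f"AAC:{aa}"] == 0.0 for aa in AMINO_ACIDS if aa != "A")

    def test_uniform(self):
        v = encode_aac(rec("ACDE")).as_dict()
        for aa in "ACDE":
            assert v[f"AAC:{aa}"] == 0.25

    def test_matches_oracle_random_100mer(self, rng):
        record = random_record(rng, 100)
        v = encode_aac(record).as_dict()
        expected = aac_oracle(record.sequence)
        for aa in AMINO_ACIDS:
            assert v[f"AAC:{aa}"] == pytest.approx(expected[aa], abs=1e-12)
        assert sum(v.values()) == pytest.approx(1.0, abs=1e-9)

    def test_has_20_entries(self):
        assert len(encode_aac(rec("ACDE"))) == 20


# ---------------------------------------------------------------- DC

class TestDC:
    def test_aaa(self):
        v = encode_dc(rec("AAA")).as_dict()
        assert v["DC:AA"] == 1.0
        assert sum(v.values()) == pytest.approx(1.0)

    def test_acac_hand_enumeration(self):
        # Adjacent pairs of "ACAC": AC, CA, AC.
        v = encode_dc(rec("ACAC")).as_dict()
        assert v["DC:AC"] == pytest.approx(2 / 3)
        assert v["DC:CA"] == pytest.approx(1 / 3)
        assert sum(1 for x in v.values() if x > 0) == 2

    def test_has_400_entries(self, rng):
        assert len(encode_dc(random_record(rng, 30))) == 400

    def test_length_1_rejected(self):
        with pytest.raises(DomainError):
            encode_dc(rec("A"))

    def test_matches_oracle(self, rng):
        record = random_record(rng, 80)
        v = encode_dc(record).as_dict()
        expected = dc_oracle(record.sequence)
        for dp in DIPEPTIDES:
            assert v[f"DC:{dp}"] == pytest.approx(expected[dp], abs=1e-12)

    @given(st.integers(2, 60), st.integers(0, 10**9))
    @settings(max_examples=50, deadline=None)
    def test_probability_vector(self, length, seed):
        record = random_record(np.random.default_rng(seed), length)
        v = encode_dc(record)
        assert np.all(v.values >= 0)
        assert v.values.sum() == pytest.approx(1.0, abs=1e-9)


# ---------------------------------------------------------------- PSSM-AC

class TestPSSMAC:
    def test_constant_matrix_gives_zeros(self):
        prof = PSSMProfile(record_id="p", scores=np.full((10, 20), 3.0))
        v = encode_pssm_ac(prof, lg=4)
        np.testing.assert_array_equal(v.values, 0.0)

    def test_hand_evaluated_columns(self):
        # Column A = (1, 2, 3): mean 2, lag-1 AC = 0.
        # Column C = (1, 3, 2): mean 2, lag-1 AC = ((-1)(1) + (1)(0)) / 2 = -0.5.
        scores = np.zeros((3, 20))
        scores[:, 0] = [1, 2, 3]
        scores[:, 1] = [1, 3, 2]
        v = encode_pssm_ac(PSSMProfile(record_id="p", scores=scores), lg=1).as_dict()
        assert v["PSSM-AC:A:lag1"] == pytest.approx(0.0, abs=1e-12)
        assert v["PSSM-AC:C:lag1"] == pytest.approx(-0.5, abs=1e-12)

    def test_default_lg_gives_560(self, rng):
        prof = PSSMProfile(record_id="p", scores=rng.normal(size=(40, 20)))
        assert len(encode_pssm_ac(prof, lg=28)) == 560

    def test_lg_ge_L_rejected(self, rng):
        prof = PSSMProfile(record_id="p", scores=rng.normal(size=(5, 20)))
        with pytest.raises(DomainError, match="p"):
            encode_pssm_ac(prof, lg=5)

    @given(st.integers(0, 10**9), st.integers(5, 50))
    @settings(max_examples=30, deadline=None)
    def test_matches_loop_oracle(self, seed, L):
        g = np.random.default_rng(seed)
        scores = g.normal(size=(L, 20))
        lg = int(g.integers(1, min(L, 8)))
        v = encode_pssm_ac(PSSMProfile(record_id="p", scores=scores), lg=lg)
        expected = pssm_ac_oracle(scores, lg)
        for j, aa in enumerate(AMINO_ACIDS):
            for lag in range(1, lg + 1):
                assert v.as_dict()[f"PSSM-AC:{aa}:lag{lag}"] == pytest.approx(
                    expected[(j, lag)], abs=1e-12
                )

    def test_column_shift_invariance(self, rng):
        """Adding a constant to a whole column leaves the AC unchanged."""
        scores = rng.normal(size=(20, 20))
        shifted = scores.copy()
        shifted[:, 7] += 42.0
        v1 = encode_pssm_ac(PSSMProfile(record_id="p", scores=scores), lg=3)
        v2 = encode_pssm_ac(PSSMProfile(record_id="p", scores=shifted), lg=3)
        np.testing.assert_allclose(v1.values, v2.values, atol=1e-10)

    def test_deterministic(self, rng):
        scores = rng.normal(size=(15, 20))
        prof = PSSMProfile(record_id="p", scores=scores)
        v1 = encode_pssm_ac(prof, lg=4)
        v2 = encode_pssm_ac(prof, lg=4)
        np.testing.assert_array_equal(v1.values, v2.values)


# ---------------------------------------------------------------- acACS

class TestSubstituteACS:
    def test_direct_lookup(self):
        table = ACSTable(
            {
                (aa, st_, nuc): (120.0 if aa == "A" else 1.0)
                for aa in AMINO_ACIDS
                for st_ in "HEC"
                for nuc in NUCLEI
            }
        )
        out = substitute_acs(
            rec("AA"), SecondaryStructureTrack.from_string("r", "HH"), table, "15N"
        )
        np.testing.assert_array_equal(out, [120.0, 120.0])

    def test_length_mismatch(self, synthetic_acs_table):
        with pytest.raises(Exception, match="track length"):
            substitute_acs(
                rec("ACD"),
                SecondaryStructureTrack.from_string("r", "HH"),
                synthetic_acs_table,
                "15N",
            )

    def test_missing_entry_names_triple(self):
        table = ACSTable({("A", "H", "15N"): 1.0})
        with pytest.raises(ConfigError, match="residue='C'"):
            substitute_acs(
                rec("AC"),
                SecondaryStructureTrack.from_string("r", "HH"),
                table,
                "15N",
            )

    def test_output_finite_over_random_inputs(self, rng, synthetic_acs_table):
        for _ in range(20):
            record = random_record(rng, int(rng.integers(3, 50)))
            states = "".join(rng.choice(list("HEC"), size=record.length))
            track = SecondaryStructureTrack.from_string(record.id, states)
            for nuc in NUCLEI:
                out = substitute_acs(record, track, synthetic_acs_table, nuc)
                assert out.shape == (record.length,)
                assert np.all(np.isfinite(out))


class TestAcACS:
    def test_lag0_is_exactly_zero(self, rng, synthetic_acs_table):
        record = random_record(rng, 30)
        track = SecondaryStructureTrack.from_string(
            record.id, "".join(rng.choice(list("HEC"), size=30))
        )
        v = encode_acacs(record, track, synthetic_acs_table, lam=5).as_dict()
        for nuc in NUCLEI:
            assert v[f"acACS:{nuc}:lag0"] == 0.0

    def test_constant_substitution_all_zero(self):
        table = ACSTable(
            {
                (aa, st_, nuc): 7.5
                for aa in AMINO_ACIDS
                for st_ in "HEC"
                for nuc in NUCLEI
            }
        )
        record = rec("ACDEFGHIK")
        track = SecondaryStructureTrack.from_string("r", "C" * 9)
        v = encode_acacs(record, track, table, lam=4)
        np.testing.assert_array_equal(v.values, 0.0)

    def test_hand_evaluated_lag1(self):
        # Substituted sequence (1, 3, 2): lag-1 phi = ((1-3) + (3-2)) / 2 = -0.5.
        table = {}
        for st_ in "HEC":
            for nuc in NUCLEI:
                table[("A", st_, nuc)] = 1.0
                table[("C", st_, nuc)] = 3.0
                table[("D", st_, nuc)] = 2.0
        v = encode_acacs(
            rec("ACD"),
            SecondaryStructureTrack.from_string("r", "CCC"),
            ACSTable(table),
            lam=1,
            nuclei=("15N",),
        ).as_dict()
        assert v["acACS:15N:lag1"] == pytest.approx(-0.5, abs=1e-12)

    def test_matches_loop_oracle(self, rng, synthetic_acs_table):
        for _ in range(25):
            L = int(rng.integers(10, 60))
            record = random_record(rng, L)
            track = SecondaryStructureTrack.from_string(
                record.id, "".join(rng.choice(list("HEC"), size=L))
            )
            lam = int(rng.integers(1, min(L, 10)))
            v = encode_acacs(record, track, synthetic_acs_table, lam=lam).as_dict()
            for nuc in NUCLEI:
                substituted = substitute_acs(record, track, synthetic_acs_table, nuc)
                expected = acacs_oracle(substituted, lam)
                for lag in range(lam + 1):
                    assert v[f"acACS:{nuc}:lag{lag}"] == pytest.approx(
                        expected[lag], abs=1e-12
                    )

    def test_dimension_is_nuclei_times_lags(self, rng, synthetic_acs_table):
        record = random_record(rng, 40)
        track = SecondaryStructureTrack.from_string(record.id, "H" * 40)
        v = encode_acacs(record, track, synthetic_acs_table, lam=17)
        assert len(v) == 4 * 18  # 72

    def test_lambda_ge_L_rejected(self, synthetic_acs_table):
        record = rec("ACDE")
        track = SecondaryStructureTrack.from_string("r", "HHHH")
        with pytest.raises(DomainError):
            encode_acacs(record, track, synthetic_acs_table, lam=4)

    def test_covariance_variant_differs(self, rng, synthetic_acs_table):
        record = random_record(rng, 30)
        track = SecondaryStructureTrack.from_string(
            record.id, "".join(rng.choice(list("HEC"), size=30))
        )
        diff = encode_acacs(record, track, synthetic_acs_table, lam=3)
        cov = encode_acacs(
            record, track, synthetic_acs_table, lam=3, variant="covariance"
        )
        # Lag 0 of the covariance variant is the variance: positive.
        assert cov.as_dict()["acACS:15N:lag0"] > 0
        assert not np.allclose(diff.values, cov.values)


# ---------------------------------------------------------------- combined

class TestCombined:
    @pytest.fixture
    def full_inputs(self, rng, synthetic_acs_table):
        L = 40
        record = random_record(rng, L)
        prof = PSSMProfile(
            record_id=record.id, scores=rng.integers(-9, 10, size=(L, 20))
        )
        track = SecondaryStructureTrack.from_string(
            record.id, "".join(rng.choice(list("HEC"), size=L))
        )
        return record, prof, track, synthetic_acs_table

    def test_singleton_equals_encoder(self, full_inputs):
        record, prof, track, table = full_inputs
        combined = encode_combined(record, prof, track, table, blocks=("AAC",))
        direct = encode_aac(record)
        assert combined.names == direct.names
        np.testing.assert_array_equal(combined.values, direct.values)

    def test_default_length_1052(self, full_inputs):
        record, prof, track, table = full_inputs
        v = encode_combined(
            record, prof, track, table, config=EncoderConfig(lg=28, lam=17)
        )
        assert len(v) == 20 + 400 + 72 + 560

    def test_block_order_same_multiset(self, full_inputs):
        record, prof, track, table = full_inputs
        v1 = encode_combined(record, prof, track, table, blocks=("DC", "AAC"))
        v2 = encode_combined(record, prof, track, table, blocks=("AAC", "DC"))
        assert v1.as_dict() == v2.as_dict()
        assert v1.names != v2.names

    def test_missing_profile_rejected(self, full_inputs):
        record, _, track, table = full_inputs
        with pytest.raises(InputError, match="PSSM"):
            encode_combined(record, None, track, table, blocks=("PSSM-AC",))

    def test_missing_track_rejected(self, full_inputs):
        record, prof, _, table = full_inputs
        with pytest.raises(InputError, match="track"):
            encode_combined(record, prof, None, table, blocks=("acACS",))

    def test_unknown_block_rejected(self, full_inputs):
        record, prof, track, table = full_inputs
        with pytest.raises(ConfigError):
            encode_combined(record, prof, track, table, blocks=("PseAAC",))


class TestACSTable:
    def test_default_table_complete(self):
        assert ACSTable.default().is_complete()

    def test_file_roundtrip(self, tmp_path, synthetic_acs_table):
        path = tmp_path / "acs.tsv"
        lines = []
        for aa in AMINO_ACIDS:
            for st_ in "HEC":
                for nuc in NUCLEI:
                    lines.append(
                        f"{aa} {st_} {nuc} "
                        f"{synthetic_acs_table.lookup(aa, st_, nuc)}"
                    )
        path.write_text("\n".join(lines))
        loaded = ACSTable.from_file(path)
        assert loaded.lookup("C", "E", "1Ha") == synthetic_acs_table.lookup(
            "C", "E", "1Ha"
        )

    def test_bad_line_rejected(self, tmp_path):
        path = tmp_path / "acs.tsv"
        path.write_text("A H 15N\n")
        with pytest.raises(ConfigError, match="line 1"):
            ACSTable.from_file(path)


class TestEncoderConfig:
    def test_defaults(self):
        cfg = EncoderConfig()
        assert cfg.lg == 28
        assert cfg.lam == 17
        assert cfg.nuclei == NUCLEI

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"lg": 0},
            {"lam": 0},
            {"nuclei": ()},
            {"nuclei": ("12C",)},
            {"acacs_variant": "bogus"},
        ],
    )
    def test_invalid(self, kwargs):
        with pytest.raises(ConfigError):
            EncoderConfig(**kwargs)
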