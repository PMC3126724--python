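"""Melting temperatures, calibration, and the positional duplex model."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bstag.errors import InvalidSequenceError
from bstag.thermo import (
    CALIBRATED_CONDITIONS,
    AnnealPolicy,
    ThermoConditions,
    anneals,
    calibrate_conditions,
    default_weights,
    duplex_score,
    melt_temp,
    revcomp,
    round_tm,
)

F9GAC = "CTAGTATCAGGACGAC"
F9TAC = "CTAGTATCAGGACTAC"
F9GTC = "CTAGTATGAGGACGTC"
F9GCC = "CTAGTATTAGGACGCC"

dna = st.text(alphabet="ACGT", min_size=8, max_size=40)


# ---------------------------------------------------------------------------
# independent nearest-neighbor oracle (unified parameter set, written from
# the literature values; shares no code with the implementation under test)

_NN = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
_INIT_GC = (0.1, -2.8)
_INIT_AT = (2.3, 4.1)


def _oracle_tm(seq: str, cond: ThermoConditions) -> float:
    dh = ds = 0.0
    for term in (seq[0], seq[-1]):
        h, s = _INIT_GC if term in "GC" else _INIT_AT
        dh += h
        ds += s
    for i in range(len(seq) - 1):
        h, s = _NN[seq[i : i + 2]]
        dh += h
        ds += s
    mon_mm = cond.monovalent_salt * 1e3
    mg_mm, dntp_mm = cond.divalent_salt * 1e3, cond.dntp_conc * 1e3
    if mg_mm > dntp_mm:
        mon_mm += 120.0 * math.sqrt(mg_mm - dntp_mm)
    ds_corr = 0.368 * (len(seq) - 1) * math.log(mon_mm * 1e-3)
    return (1000.0 * dh) / (ds + ds_corr + 1.987 * math.log(cond.oligo_conc)) - 273.15


class TestMeltTemp:
    @pytest.mark.parametrize(
        "seq,expected", [(F9GAC, 51.3), (F9TAC, 47.2)]
    )
    def test_published_tag_tm(self, seq, expected):
        assert melt_temp(seq) == pytest.approx(expected, abs=0.5)
        assert round_tm(melt_temp(seq)) == expected

    def test_matches_independent_oracle(self):
        """Cross-check against a from-scratch unified NN implementation."""
        for seq in (F9GAC, F9TAC, F9GCC, "ACGTACGTACGTACGTAC"):
            assert melt_temp(seq) == pytest.approx(
                _oracle_tm(seq, CALIBRATED_CONDITIONS), abs=0.05
            )

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(dna)
    def test_strand_symmetry(self, seq):
        assert melt_temp(seq) == pytest.approx(melt_temp(revcomp(seq)), abs=1e-6)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(dna, st.data())
    def test_gc_substitution_never_decreases_tm(self, seq, data):
        """Replacing an A/T with G/C at fixed length never lowers the Tm."""
        at_positions = [i for i, c in enumerate(seq) if c in "AT"]
        if not at_positions:
            return
        i = data.draw(st.sampled_from(at_positions))
        new_base = data.draw(st.sampled_from("GC"))
        mutated = seq[:i] + new_base + seq[i + 1 :]
        assert melt_temp(mutated) >= melt_temp(seq) - 1e-9

    @pytest.mark.parametrize("bad", ["ACGTACG", "ACGTNACGT", "ACGUACGU"])
    def test_invalid_sequences_rejected(self, bad):
        with pytest.raises(InvalidSequenceError):
            melt_temp(bad)

    def test_conditions_validation(self):
        with pytest.raises(ValueError):
            ThermoConditions(monovalent_salt=0.0)
        with pytest.raises(ValueError):
            ThermoConditions(oligo_conc=-1e-9)


class TestCalibration:
    def test_reproduces_published_table(self, tag_table):
        result = calibrate_conditions([(s, t) for _, s, t in tag_table])
        assert result.success
        assert result.max_residual <= 0.5
        # at the calibrated point every tag rounds to its reported value
        for _, seq, tm in tag_table:
            assert round_tm(melt_temp(seq, result.conditions)) == tm

    def test_duplication_invariance(self, tag_table):
        _, seq, tm = tag_table[0]
        single = calibrate_conditions([(seq, tm)])
        repeated = calibrate_conditions([(seq, tm)] * 6)
        assert single.conditions == repeated.conditions

    def test_leave_one_out_prediction(self, tag_table):
        """Conditions fit on five tags predict the sixth comparably well."""
        rows = [(s, t) for _, s, t in tag_table]
        for held_out in range(len(rows)):
            train = [r for i, r in enumerate(rows) if i != held_out]
            fit = calibrate_conditions(train)
            seq, tm = rows[held_out]
            err = abs(melt_temp(seq, fit.conditions) - tm)
            assert err <= max(2 * fit.max_residual, 0.5)

    def test_empty_table_is_error(self):
        with pytest.raises(ValueError):
            calibrate_conditions([])

    def test_unreachable_tolerance_reports_failure(self, tag_table):
        result = calibrate_conditions(
            [(s, t) for _, s, t in tag_table], tolerance=1e-6
        )
        assert not result.success
        assert result.residuals  # best point still reported


class TestDuplexScore:
    def test_perfect_complement(self):
        rep = duplex_score(F9GAC, revcomp(F9GAC))
        assert rep.total_mismatches == 0
        assert rep.three_prime_anchored_run == 16
        assert rep.weighted_score == 0.0

    def test_single_barcode_mismatch(self):
        # F9GAC probe on the strand displayed by an F9TAC-tagged product:
        # the tags differ only at position 14
        rep = duplex_score(F9GAC, revcomp(F9TAC))
        assert rep.mismatch_positions == (14,)
        assert rep.longest_contiguous_run == 13
        assert rep.three_prime_anchored_run == 2

    def test_split_and_barcode_mismatches(self):
        rep = duplex_score(F9GAC, revcomp(F9GTC))
        assert rep.mismatch_positions == (8, 15)

    def test_length_mismatch_is_error(self):
        with pytest.raises(ValueError):
            duplex_score("ACGTACGT", "ACGTACGTA")

    def test_brute_force_agreement_all_tag_pairs(self, tag_list):
        """The report agrees with direct base-by-base comparison on all 36
        ordered pairs of shipped tags."""
        w = default_weights(16)
        for a in tag_list:
            for b in tag_list:
                rep = duplex_score(a.full_seq, revcomp(b.full_seq))
                mism = tuple(
                    i + 1
                    for i in range(16)
                    if a.full_seq[i] != b.full_seq[i]
                )
                assert rep.mismatch_positions == mism
                assert rep.total_mismatches == len(mism)
                assert rep.weighted_score == sum(w[p - 1] for p in mism)
                # runs from the mask
                mask = [a.full_seq[i] == b.full_seq[i] for i in range(16)]
                longest = run = 0
                for ok in mask:
                    run = run + 1 if ok else 0
                    longest = max(longest, run)
                anchored = 0
                for ok in reversed(mask):
                    if not ok:
                        break
                    anchored += 1
                assert rep.longest_contiguous_run == longest
                assert rep.three_prime_anchored_run == anchored

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(dna)
    def test_zero_score_iff_perfect(self, seq):
        rep = duplex_score(seq, revcomp(seq))
        assert rep.weighted_score == 0.0 and rep.total_mismatches == 0
        assert rep.three_prime_anchored_run <= rep.longest_contiguous_run <= len(seq)


class TestAnneals:
    def test_perfect_site_at_labeling_temp(self):
        assert anneals(F9GAC, revcomp(F9GAC), 49.0)

    def test_mismatched_tag_site_rejected(self):
        assert not anneals(F9GAC, revcomp(F9TAC), 49.0)

    def test_unbounded_temperature_never_anneals(self):
        assert not anneals(F9GAC, revcomp(F9GAC), math.inf)

    def test_policy_seed_gate(self):
        # 3'-anchored run of 2 (barcode mismatch) fails any seed >= 3
        assert not anneals(
            F9GAC, revcomp(F9TAC), 20.0, policy=AnnealPolicy(seed_len=3)
        )
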