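"""Read outcome calling, indel cataloging and background subtraction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pequant.alignment_engine import align_global
from pequant.amplicon_quant import (
    IndelTable,
    call_read_outcome,
    catalog_indels,
    subtract_background,
    summarize_amplicon,
    ReadOutcome,
)
from pequant.core_model import (
    AmpliconSpec,
    EditSpec,
    build_edited_allele,
)
from pequant.synthetic_data import SCENARIOS, end_to_end_fixture


def _call(read, amplicon, edit, edited):
    aln = align_global(read, amplicon.sequence)
    return call_read_outcome(aln, amplicon, edit, edited)


class TestCallReadOutcome:
    def test_edit_without_pam_mod_is_not_precise(self, point_edit_locus):
        """The A->G conversion alone, with the PAM still AGG, must not count
        as precise editing — both changes are required."""
        amplicon, edit, edited = point_edit_locus
        seq = amplicon.sequence
        read = seq[:120] + "G" + seq[121:]  # edit installed, PAM untouched
        outcome = _call(read, amplicon, edit, edited)
        assert outcome.call == "substitution_other"

    def test_pam_mod_without_edit_is_not_precise(self, point_edit_locus):
        amplicon, edit, edited = point_edit_locus
        seq = amplicon.sequence
        read = seq[:123] + "A" + seq[124:]
        assert _call(read, amplicon, edit, edited).call == "substitution_other"

    def test_read_identical_to_amplicon_is_wild_type(self, point_edit_locus):
        amplicon, edit, edited = point_edit_locus
        outcome = _call(amplicon.sequence, amplicon, edit, edited)
        assert outcome.call == "wild_type"
        assert outcome.events == []

    def test_full_edited_allele_is_precise(self, point_edit_locus):
        amplicon, edit, edited = point_edit_locus
        assert _call(edited.sequence, amplicon, edit, edited).call == "precise_edit"

    def test_reporter_restoring_47bp_deletion_is_precise(self):
        """A read carrying exactly the 47-bp reporter-restoring deletion is
        precise, with a single deletion event of length 47."""
        parts = SCENARIOS["gfp_del47_reporter"]()
        amplicon, edit = parts["amplicon"], parts["edit"]
        edited = build_edited_allele(amplicon, edit)
        outcome = _call(edited.sequence, amplicon, edit, edited)
        assert outcome.call == "precise_edit"
        dels = [e for e in outcome.events if e.kind == "deletion"]
        assert len(dels) == 1 and dels[0].length == 47

    def test_indel_in_window_called_indel(self, point_edit_locus):
        amplicon, edit, edited = point_edit_locus
        seq = amplicon.sequence
        read = seq[:119] + seq[123:]  # 4-bp deletion at the nick
        assert _call(read, amplicon, edit, edited).call == "indel"

    def test_read_not_covering_window_is_ambiguous(self, point_edit_locus):
        amplicon, edit, edited = point_edit_locus
        aln = align_global(amplicon.sequence[:100], amplicon.sequence, infix=True)
        assert call_read_outcome(aln, amplicon, edit, edited).call == "ambiguous"

    def test_precise_molecules_always_called_precise_across_seeds(self):
        """Error-free precise molecules are never miscalled (500 seeds over
        a mix of edit geometries)."""
        specs = [
            SCENARIOS[name]()
            for name in ("serpina1_correction", "ccr5_del", "emx1_ins6", "tlr_replacement")
        ]
        built = [
            (p["amplicon"], p["edit"], build_edited_allele(p["amplicon"], p["edit"]))
            for p in specs
        ]
        for seed in range(500):
            amplicon, edit, edited = built[seed % len(built)]
            assert _call(edited.sequence, amplicon, edit, edited).call == "precise_edit"


class TestCatalogIndels:
    def test_zero_event_run_gives_empty_table(self, point_edit_locus):
        amplicon, _, _ = point_edit_locus
        outcomes = [ReadOutcome(f"r{i}", "wild_type") for i in range(10)]
        table = catalog_indels(outcomes, amplicon)
        assert table.df.empty and table.total_reads == 10

    def test_shared_deletion_frequency(self, point_edit_locus):
        amplicon, edit, edited = point_edit_locus
        seq = amplicon.sequence
        del_read = seq[:119] + seq[121:]
        outcomes = []
        for i in range(10):
            read = del_read if i < 3 else seq
            outcomes.append(_call(read, amplicon, edit, edited))
        table = catalog_indels(outcomes, amplicon)
        assert len(table.df) == 1
        row = table.df.iloc[0]
        assert row["kind"] == "deletion" and row["reads"] == 3
        assert row["freq"] == pytest.approx(0.3)

    def test_simulated_event_frequencies_match_truth(self):
        """Catalog frequencies agree with generator truth within 3 binomial
        standard errors on an indel-rich library."""
        config, lib = end_to_end_fixture(
            "serpina1_correction", seed=11, n_molecules=4000,
            error_rate=0.0,
            mixture={"wild_type": 0.7, "small_indel_sub": 0.3},
        )
        amplicon, edit = config.amplicon, config.edit
        edited = build_edited_allele(amplicon, edit)
        outcomes = [
            _call(m.sequence, amplicon, edit, edited) for m in lib.molecules
        ]
        measured = sum(o.call == "indel" for o in outcomes) / len(outcomes)
        truth = (lib.molecule_truth["category"] == "small_indel_sub").mean()
        se = np.sqrt(truth * (1 - truth) / len(outcomes))
        assert abs(measured - truth) <= 3 * se


class TestSubtractBackground:
    def _table(self, amplicon_name, rows, total=1000):
        df = pd.DataFrame(rows, columns=["kind", "ref_pos", "length", "allele", "reads"])
        df["freq"] = df["reads"] / total
        return IndelTable(df=df, total_reads=total, amplicon_name=amplicon_name)

    def test_treatment_equal_to_control_mean_cancels_exactly(self):
        t = self._table("a", [("deletion", 10, 2, "AC", 10)])
        controls = [
            self._table("a", [("deletion", 10, 2, "AC", n)]) for n in (5, 10, 15)
        ]
        net = subtract_background(t, controls)
        assert net.background_subtracted
        assert net.df["net_freq"].tolist() == [0.0]

    def test_hand_arithmetic_mean_of_three_controls(self):
        t = self._table("a", [("deletion", 7, 1, "G", 50)])  # freq 0.050
        controls = [
            self._table("a", [("deletion", 7, 1, "G", 10)]),  # 0.010
            self._table("a", [("deletion", 7, 1, "G", 20)]),  # 0.020
            self._table("a", []),                              # absent -> 0
        ]
        net = subtract_background(t, controls)
        assert net.df["net_freq"].iloc[0] == pytest.approx(0.040)

    def test_control_only_artifact_never_goes_negative(self):
        t = self._table("a", [("insertion", 3, 1, "T", 1)])  # freq 0.001
        controls = [self._table("a", [("insertion", 3, 1, "T", 500)])]  # 0.5
        net = subtract_background(t, controls)
        assert net.df["net_freq"].iloc[0] == 0.0

    def test_key_absent_from_controls_passes_through(self):
        t = self._table("a", [("deletion", 10, 2, "AC", 40)])
        controls = [self._table("a", [("deletion", 99, 2, "GG", 40)])]
        net = subtract_background(t, controls)
        assert net.df["net_freq"].iloc[0] == pytest.approx(0.040)

    def test_mismatched_amplicon_rejected(self):
        t = self._table("a", [])
        with pytest.raises(ValueError, match="amplicon"):
            subtract_background(t, [self._table("b", [])])

    @settings(max_examples=60)
    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["insertion", "deletion"]),
                st.integers(0, 50),
                st.integers(1, 10),
                st.integers(0, 200),
            ),
            min_size=1,
            max_size=8,
            unique_by=lambda r: (r[0], r[1], r[2]),
        )
    )
    def test_exact_cancellation_property(self, rows):
        """Whenever treatment frequencies equal the control mean at every
        key, every net frequency is exactly zero."""
        full = [(k, p, ln, "A" * ln, n) for k, p, ln, n in rows]
        t = self._table("a", full)
        net = subtract_background(t, [t, t, t])
        assert (net.df["net_freq"] == 0.0).all()


class TestSummarize:
    def test_counts_to_rates(self):
        outcomes = (
            [ReadOutcome(f"w{i}", "wild_type") for i in range(50)]
            + [ReadOutcome(f"p{i}", "precise_edit") for i in range(30)]
            + [ReadOutcome(f"d{i}", "indel") for i in range(20)]
        )
        summary = summarize_amplicon(outcomes)
        assert summary.rates["wild_type"] == 0.50
        assert summary.rates["precise_edit"] == 0.30
        assert summary.rates["indel"] == 0.20
        assert sum(summary.rates.values()) == pytest.approx(1.0, abs=1e-9)

    def test_all_wild_type_library_has_zero_precise(self, point_edit_locus):
        amplicon, edit, edited = point_edit_locus
        outcomes = [
            _call(amplicon.sequence, amplicon, edit, edited) for _ in range(20)
        ]
        assert summarize_amplicon(outcomes).precise_rate == 0.0

    def test_every_read_gets_exactly_one_call(self, point_edit_locus):
        amplicon, edit, edited = point_edit_locus
        gen = np.random.default_rng(5)
        seq = amplicon.sequence
        reads = []
        for _ in range(60):
            r = list(seq)
            for pos in gen.integers(0, len(seq), size=gen.integers(0, 3)):
                r[pos] = gen.choice([c for c in "ACGT" if c != r[pos]])
            reads.append("".join(r))
        outcomes = [_call(r, amplicon, edit, edited) for r in reads]
        summary = summarize_amplicon(outcomes)
        assert sum(summary.counts.values()) == 60

    def test_zero_reads_is_an_error(self):
        with pytest.raises(ValueError):
            summarize_amplicon([])
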