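"""UMI families, exemplar classification, AAV calls and BH significance."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_read
from pequant.core_model import build_edited_allele
from pequant.synthetic_data import SCENARIOS, random_sequence
from pequant.uditas_quant import (
    ClassifyParams,
    DeletionCluster,
    UmiFamily,
    build_umi_families,
    classify_family,
    cluster_deletions,
    deletion_significance,
    detect_aav_integration,
    estimate_background_rate,
    select_exemplar,
    summarize_uditas,
)


@pytest.fixture(scope="module")
def uditas_locus():
    parts = SCENARIOS["uditas_aav"]()
    amplicon, edit = parts["amplicon"], parts["edit"]
    return amplicon, edit, build_edited_allele(amplicon, edit), parts["aav_reference"]


def _family_for(sequence, umi="AAAACCCCGGGG"):
    return UmiFamily(umi=umi, members=[make_read(sequence, read_id=f"{umi}.0")])


def _primer_read(molecule, amplicon, length=200):
    """The read-2 view: from the locus primer into the molecule."""
    p0 = amplicon.uditas_primer_interval[0]
    return molecule[p0 : p0 + length]


class TestBuildFamilies:
    def test_families_group_by_umi(self):
        reads = [
            make_read("ACGT", umi=u, read_id=f"r{i}")
            for i, u in enumerate(["U1", "U2", "U1", "U3", "U2"])
        ]
        families, missing = build_umi_families(reads)
        assert len(families) == 3 and missing == 0
        assert {f.umi: f.size for f in families} == {"U1": 2, "U2": 2, "U3": 1}

    def test_empty_input_gives_empty_list(self):
        assert build_umi_families([]) == ([], 0)

    def test_reads_without_umi_counted(self):
        reads = [make_read("ACGT", read_id="r0"), make_read("ACGT", umi="U", read_id="r1")]
        families, missing = build_umi_families(reads)
        assert len(families) == 1 and missing == 1

    def test_thousand_molecules_thousand_families(self, rng):
        umis = set()
        while len(umis) < 1000:
            umis.add(random_sequence(rng, 12))
        reads = [make_read("ACGT", umi=u, read_id=u) for u in umis]
        families, _ = build_umi_families(reads)
        assert len(families) == 1000


class TestSelectExemplar:
    def test_identical_members_return_that_sequence(self):
        fam = UmiFamily("U", [make_read("ACGTACGT", read_id=f"r{i}") for i in range(4)])
        assert select_exemplar(fam).bases == "ACGTACGT"

    def test_majority_sequence_wins(self):
        fam = UmiFamily(
            "U",
            [make_read("AAAA", read_id=f"x{i}") for i in range(3)]
            + [make_read("TTTT", read_id="y")],
        )
        assert select_exemplar(fam).bases == "AAAA"

    def test_tie_broken_by_summed_quality_then_sequence(self):
        hi = make_read("TTTT", q=40, read_id="hi")
        lo = make_read("GGGG", q=39, read_id="lo")
        assert select_exemplar(UmiFamily("U", [lo, hi])).bases == "TTTT"
        # equal quality: lexicographically smaller sequence wins
        a = make_read("CCCC", q=30, read_id="a")
        b = make_read("GGGG", q=30, read_id="b")
        assert select_exemplar(UmiFamily("U", [b, a])).bases == "CCCC"


class TestClassifyFamily:
    def test_unedited_exemplar_is_wild_type(self, uditas_locus):
        amplicon, edit, edited, aav = uditas_locus
        fam = _family_for(_primer_read(amplicon.sequence, amplicon))
        assert classify_family(fam, amplicon, edit, edited, aav) == "wild_type"

    def test_precise_exemplar(self, uditas_locus):
        amplicon, edit, edited, aav = uditas_locus
        fam = _family_for(_primer_read(edited.sequence, amplicon))
        assert classify_family(fam, amplicon, edit, edited, aav) == "precise_edit"

    def test_deletion_spanning_both_nicks_is_pegnick(self, uditas_locus):
        """A 70-bp deletion covering both nick sites lands in the
        nick-to-nick category, not small or large."""
        amplicon, edit, edited, aav = uditas_locus
        seq = amplicon.sequence
        molecule = seq[:145] + seq[215:]  # [145, 215): spans nicks 150 and 210
        fam = _family_for(_primer_read(molecule, amplicon))
        assert classify_family(fam, amplicon, edit, edited, aav) == "pegnick_deletion"
        assert fam.deletion_call is not None

    def test_large_deletion_via_split_alignment(self, uditas_locus):
        amplicon, edit, edited, aav = uditas_locus
        seq = amplicon.sequence
        molecule = seq[:140] + seq[440:]  # 300-bp deletion
        fam = _family_for(_primer_read(molecule, amplicon))
        assert classify_family(fam, amplicon, edit, edited, aav) == "large_deletion"
        start, end = fam.deletion_call
        assert end - start == 300

    @pytest.mark.parametrize(
        "size,spans_nicks,expected",
        [
            (49, False, "small_indel_sub"),
            (50, False, "unclassified"),   # between the documented bands
            (99, True, "pegnick_deletion"),
            (100, True, "large_deletion"),
            (101, True, "large_deletion"),
        ],
    )
    def test_deletion_size_boundaries(self, uditas_locus, size, spans_nicks, expected):
        amplicon, edit, edited, aav = uditas_locus
        seq = amplicon.sequence
        if spans_nicks:
            start = 150 - (size - 60) // 2  # centred over both nicks
        else:
            start = 151  # begins after the pegRNA nick, ends before the other
        molecule = seq[:start] + seq[start + size :]
        fam = _family_for(_primer_read(molecule, amplicon))
        assert classify_family(fam, amplicon, edit, edited, aav) == expected

    def test_exemplar_missing_window_is_unclassified(self, uditas_locus):
        amplicon, edit, edited, aav = uditas_locus
        fam = _family_for(amplicon.sequence[300:500])  # away from the nicks
        assert classify_family(fam, amplicon, edit, edited, aav) == "unclassified"

    def test_classification_invariant_to_member_order_and_umi_label(self, uditas_locus, rng):
        amplicon, edit, edited, aav = uditas_locus
        base = _primer_read(edited.sequence, amplicon)
        reads = [make_read(base, read_id=f"r{i}") for i in range(4)]
        # one discordant member carrying an error
        reads.append(make_read("T" + base[1:], read_id="err"))
        for perm_seed, umi in [(0, "AAAA"), (1, "TTTT"), (2, "GGCC")]:
            order = np.random.default_rng(perm_seed).permutation(len(reads))
            fam = UmiFamily(umi, [reads[i] for i in order])
            assert classify_family(fam, amplicon, edit, edited, aav) == "precise_edit"


class TestDetectAavIntegration:
    def test_chimeric_junction_called(self, uditas_locus):
        amplicon, _, _, aav = uditas_locus
        molecule = amplicon.sequence[:152] + aav[300:600]
        read = make_read(_primer_read(molecule, amplicon, 150), read_id="chimera")
        hit = detect_aav_integration(read, aav, amplicon)
        assert hit is not None and hit["score"] >= 40

    def test_false_priming_read_rejected(self, uditas_locus):
        """Primer followed directly by vector sequence, with no genuine locus
        bases, is false priming — filtered, not an integration."""
        amplicon, _, _, aav = uditas_locus
        p0, p1 = amplicon.uditas_primer_interval
        read = make_read(amplicon.sequence[p0:p1] + aav[100:230], read_id="fp")
        assert detect_aav_integration(read, aav, amplicon) is None

    def test_unedited_locus_read_not_called(self, uditas_locus):
        amplicon, _, _, aav = uditas_locus
        read = make_read(_primer_read(amplicon.sequence, amplicon, 150), read_id="wt")
        assert detect_aav_integration(read, aav, amplicon) is None


class TestClusterDeletions:
    def _large_family(self, umi, call):
        fam = _family_for("ACGT" * 10, umi=umi)
        fam.category = "large_deletion"
        fam.deletion_call = call
        return fam

    def test_identical_breakpoints_form_one_cluster(self):
        fams = [self._large_family(f"U{i}", (140, 440)) for i in range(3)]
        clusters = cluster_deletions(fams)
        assert len(clusters) == 1
        assert clusters[0].umi_count == 3 and clusters[0].size == 300

    def test_distinct_breakpoints_stay_separate(self):
        fams = [
            self._large_family("U1", (140, 440)),
            self._large_family("U2", (150, 500)),
        ]
        assert len(cluster_deletions(fams)) == 2

    def test_microhomology_equivalent_breakpoints_cluster_together(self, uditas_locus):
        """Reads whose junctions differ only by microhomology shift are
        normalized to one cluster."""
        amplicon, edit, edited, aav = uditas_locus
        seq = amplicon.sequence
        # force 3-bp microhomology around a 300-bp deletion at [140, 440)
        seq = seq[:437] + seq[137:140] + seq[440:]
        amp2 = type(amplicon)(
            name="mh", sequence=seq, peg_nick=150, nick_sgrna_nick=210,
            uditas_primer_interval=amplicon.uditas_primer_interval,
        )
        molecule_a = seq[:137] + seq[437:]   # junction expressed leftmost
        molecule_b = seq[:140] + seq[440:]   # equivalent rightmost expression
        assert molecule_a == molecule_b      # truly the same molecule
        fams = []
        for i in range(2):
            fam = _family_for(_primer_read(molecule_a, amp2), umi=f"U{i}")
            classify_family(fam, amp2, edit, edited, aav)
            fams.append(fam)
        clusters = cluster_deletions(fams)
        assert len(clusters) == 1 and clusters[0].umi_count == 2


class TestDeletionSignificance:
    @staticmethod
    def _bh_by_hand(pvals):
        """Step-up closed form: p_adj(i) = min_{j>=i} m*p_(j)/j, capped at 1."""
        m = len(pvals)
        order = sorted(range(m), key=lambda i: pvals[i])
        adj = [0.0] * m
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, m * pvals[i] / rank)
            adj[i] = running
        return adj

    def test_bh_adjustment_matches_closed_form(self):
        """Adjusted p-values equal the hand-computed p*m/rank step-up rule,
        e.g. (0.01, 0.02, 0.03, 0.04) with m=4 all adjust to 0.04."""
        assert self._bh_by_hand([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)
        clusters = [
            DeletionCluster(10 * i, 10 * i + 200, umi_count=k)
            for i, k in enumerate([0, 2, 5, 9, 14])
        ]
        out = deletion_significance(clusters, total_umis=1000, background_rate=2e-3)
        expected = self._bh_by_hand([c.p_value for c in out])
        for c, e in zip(out, expected):
            assert c.p_adjusted == pytest.approx(max(e, c.p_value))

    def test_zero_support_cluster_not_significant(self):
        clusters = [DeletionCluster(10, 200, umi_count=0)]
        out = deletion_significance(clusters, total_umis=1000, background_rate=1e-3)
        assert out[0].p_value == 1.0 and not out[0].significant

    def test_enriched_cluster_is_significant(self):
        clusters = [DeletionCluster(10, 200, umi_count=30)]
        out = deletion_significance(clusters, total_umis=1000, background_rate=1e-3)
        assert out[0].significant

    def test_adjusted_p_monotone_in_raw_p(self, rng):
        clusters = [
            DeletionCluster(i, i + 200, umi_count=int(k))
            for i, k in enumerate(rng.integers(0, 20, size=25))
        ]
        out = deletion_significance(clusters, total_umis=2000, background_rate=2e-3)
        ranked = sorted(out, key=lambda c: c.p_value)
        adj = [c.p_adjusted for c in ranked]
        assert all(a <= b + 1e-15 for a, b in zip(adj, adj[1:]))
        assert all(c.p_adjusted >= c.p_value for c in out)

    def test_zero_total_umis_is_an_error(self):
        with pytest.raises(ValueError):
            deletion_significance([], 0, 0.1)

    def test_background_rate_pseudocount(self):
        assert estimate_background_rate(0, 1000) == pytest.approx(0.0005)
        assert estimate_background_rate(3, 1000) == pytest.approx(0.0035)


class TestSummarize:
    def _classified(self, cat, umi):
        fam = _family_for("ACGT" * 10, umi=umi)
        fam.category = cat
        return fam

    def test_ratios(self):
        fams = (
            [self._classified("wild_type", f"w{i}") for i in range(7)]
            + [self._classified("precise_edit", f"p{i}") for i in range(2)]
            + [self._classified("small_indel_sub", "s0")]
        )
        summary = summarize_uditas(fams)
        assert summary.ratios["wild_type"] == pytest.approx(0.7)
        assert summary.ratios["precise_edit"] == pytest.approx(0.2)
        assert summary.ratios["small_indel_sub"] == pytest.approx(0.1)
        assert sum(summary.counts.values()) == summary.total_umis == 10
        assert sum(summary.ratios.values()) == pytest.approx(1.0, abs=1e-9)
        assert summary.aav_fraction == 0.0

    def test_unclassified_family_raises(self):
        fam = _family_for("ACGT" * 10)
        with pytest.raises(ValueError):
            summarize_uditas([fam])

    def test_no_families_is_an_error(self):
        with pytest.raises(ValueError):
            summarize_uditas([])
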