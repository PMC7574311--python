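"""PSM aggregation, candidate filtering, control subtraction, coverage."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from proteopipe.ipms import (
    InputFormatError,
    PSMRecord,
    ProteinEvidence,
    aggregate_psms,
    base_accession,
    candidates_frame,
    compute_coverage,
    filter_candidates,
    read_psm_table,
    subtract_control,
)


def psm(i, pep, prots, sample="bait"):
    return PSMRecord(f"s{i}", pep, tuple(prots), sample)


class TestAggregate:
    def test_extension_grouping_collapses_onto_base_contig(self):
        records = [
            psm(1, "PEPTIDEK", ["contig_7"]),
            psm(2, "PEPTIDEK", ["contig_7"]),
            psm(3, "AAAGGGK", ["contig_7_2"]),
            psm(4, "CCCGGGK", ["contig_7"]),
        ]
        [ev] = aggregate_psms(records, group_extensions=True)
        assert (ev.accession, ev.n_peptides, ev.n_spectra) == ("contig_7", 3, 4)

    def test_empty_input(self):
        assert aggregate_psms([]) == []

    def test_shared_peptide_policies(self):
        records = [
            psm(1, "SHAREDK", ["A", "B"]),
            psm(2, "AAK", ["A"]),
            psm(3, "CCK", ["A"]),
        ]
        razor = {e.accession: e for e in aggregate_psms(records, shared_peptide_policy="razor")}
        assert razor["A"].n_peptides == 3 and razor["A"].n_spectra == 3
        assert "B" not in razor  # razor assigns the shared PSM to A only
        both = {e.accession: e for e in aggregate_psms(records, shared_peptide_policy="all")}
        assert both["B"].n_peptides == 1 and both["B"].n_spectra == 1

    def test_duplicate_spectrum_id_rejected_within_sample(self):
        records = [psm(1, "AAK", ["A"]), psm(1, "CCK", ["B"])]
        with pytest.raises(InputFormatError, match="duplicate spectrum_id"):
            aggregate_psms(records)
        # same id in different samples is fine
        ok = [psm(1, "AAK", ["A"]), PSMRecord("s1", "AAK", ("A",), "control")]
        assert len(aggregate_psms(ok)) == 2

    @given(
        st.lists(
            st.tuples(
                st.text(alphabet="ACDEFGHIK", min_size=3, max_size=8),
                st.sets(st.sampled_from(["P1", "P2", "P3", "P4"]), min_size=1),
            ),
            max_size=40,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_razor_conserves_spectra(self, rows):
        """Under razor each PSM counts once: spectra sum to the PSM count."""
        records = [psm(i, pep, sorted(ps)) for i, (pep, ps) in enumerate(rows)]
        evidence = aggregate_psms(records, shared_peptide_policy="razor")
        assert sum(e.n_spectra for e in evidence) == len(records)

    def test_base_accession_suffix_rules(self):
        assert base_accession("c9_f2_3") == "c9"
        assert base_accession("c9_f2") == "c9"
        assert base_accession("contig_1_2") == "contig_1"
        assert base_accession("contig_7") == "contig_7"
        assert base_accession("sp|P12345|XYZ") == "sp|P12345|XYZ"


class TestFilterCandidates:
    @pytest.mark.parametrize(
        "n_pep,n_spec,kept",
        [
            (6, 12, True),   # dihydroflavonol 4-reductase evidence level
            (9, 38, True),   # chalcone synthase 2 evidence level
            (3, 6, True),    # boundary: both at threshold
            (2, 10, False),
            (3, 5, False),
            (0, 0, False),
        ],
    )
    def test_at_least_three_peptides_six_spectra(self, n_pep, n_spec, kept):
        ev = ProteinEvidence("p", n_pep, n_spec)
        assert bool(filter_candidates([ev])) is kept

    @given(
        st.lists(
            st.tuples(st.integers(0, 10), st.integers(0, 40)).filter(
                lambda t: t[1] >= t[0]
            ),
            max_size=50,
        ),
        st.integers(0, 10),
        st.integers(0, 40),
    )
    @settings(max_examples=100, deadline=None)
    def test_threshold_monotonicity(self, counts, mp, ms):
        evidence = [
            ProteinEvidence(f"p{i}", p, s) for i, (p, s) in enumerate(counts)
        ]
        n = len(filter_candidates(evidence, mp, ms))
        assert len(filter_candidates(evidence, mp + 1, ms)) <= n
        assert len(filter_candidates(evidence, mp, ms + 1)) <= n

    def test_candidates_frame_reports_fail_reasons(self):
        ev = [ProteinEvidence("a", 2, 10), ProteinEvidence("b", 3, 6)]
        df = candidates_frame(ev)
        assert list(df["candidate"]) == [False, True]
        assert df.loc[0, "fail_reason"] == "n_peptides<3"


class TestSubtractControl:
    def test_rules(self):
        bait1 = ProteinEvidence("a", 3, 10)
        assert subtract_control([bait1], []) == [(bait1, True)]
        bait2 = ProteinEvidence("b", 4, 10)
        ctrl2 = ProteinEvidence("b", 2, 8, sample="control")
        assert subtract_control([bait2], [ctrl2], 0.5) == [(bait2, False)]
        # boundary: strict inequality keeps equality at fraction 1.0
        ctrl3 = ProteinEvidence("b", 2, 10, sample="control")
        assert subtract_control([bait2], [ctrl3], 1.0) == [(bait2, True)]

    def test_fraction_out_of_range(self):
        with pytest.raises(ValueError):
            subtract_control([], [], 1.5)


class TestCoverage:
    def test_interval_union(self):
        protein = "ABCDEFGHIJKLMNOPQRST"  # length 20
        # peptides covering residues 1-5 and 3-8 -> union 8 of 20 = 40%
        assert compute_coverage(protein, ["ABCDE", "CDEFGH"]) == pytest.approx(40.0)

    def test_full_and_zero(self):
        assert compute_coverage("MAKVL", ["MAKVL"]) == 100.0
        assert compute_coverage("MAKVL", ["WWW"]) == 0.0

    def test_empty_protein_rejected(self):
        with pytest.raises(ValueError):
            compute_coverage("", ["M"])

    def test_all_occurrences_counted(self):
        assert compute_coverage("AAXAA", ["AA"]) == pytest.approx(80.0)

    def test_equate_il_flag(self):
        assert compute_coverage("MILK", ["MLIK"]) == 0.0
        assert compute_coverage("MILK", ["MLIK"], equate_il=True) == 100.0

    @given(
        st.lists(st.sampled_from(["MAK", "AKV", "KVLW", "XYZ"]), max_size=8),
        st.randoms(use_true_random=False),
    )
    @settings(max_examples=50, deadline=None)
    def test_order_and_duplication_invariance(self, peps, rnd):
        protein = "MAKVLWMAKVLW"
        cov = compute_coverage(protein, peps)
        shuffled = list(peps) + list(peps)
        rnd.shuffle(shuffled)
        assert compute_coverage(protein, shuffled) == cov


class TestTableIO:
    def test_read_psm_table_with_extra_columns(self, tmp_path):
        path = tmp_path / "psms.tsv"
        path.write_text(
            "spectrum_id\tpeptide\tproteins\tsample\tscore\n"
            "s1\tMAKVLK\tA;B\tbait\t0.99\n"
            "s2\tCCCK\tA\tcontrol\t0.5\n"
        )
        records = read_psm_table(path)
        assert records[0].proteins == ("A", "B")
        assert records[1].sample == "control"

    def test_missing_column_reported(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("spectrum_id\tpeptide\n1\tMK\n")
        with pytest.raises(InputFormatError, match="missing column"):
            read_psm_table(path)
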