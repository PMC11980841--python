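"""Positional-scan classification and motif construction."""

from __future__ import annotations

import re

import pytest
from hypothesis import given, settings, strategies as st

import xreact as x
from xreact.scan_interpret import ScanError

from conftest import ANCHORS, CONTACTS


def make_scan(query, responses, bindings, wt_response=1000.0, wt_binding=20.0,
              orientation="affinity"):
    """Scan from explicit per-position response/binding values (1-indexed)."""
    variants = tuple(
        x.ScanVariant(
            position=p,
            substituted_residue="G" if query.residue(p) == "A" else "A",
            response=responses[p],
            predicted_binding=bindings[p],
        )
        for p in range(1, query.k + 1)
    )
    return x.PositionalScanTable(
        wild_type=query,
        wt_response=wt_response,
        wt_predicted_binding=wt_binding,
        variants=variants,
        orientation=orientation,
    )


class TestClassifyPositions:
    def test_planted_pattern_recovered(self, query):
        """Anchors at 2/9 (binding 100x worse), contacts at 3/4/5/8 (2% response)."""
        responses = {p: 900.0 for p in range(1, 10)}
        bindings = {p: 20.0 for p in range(1, 10)}
        for p in CONTACTS:
            responses[p] = 20.0  # 0.02 x wt
        for p in ANCHORS:
            bindings[p] = 2000.0  # 100-fold worse affinity
            responses[p] = 20.0  # presentation lost too
        cls = x.classify_positions(make_scan(query, responses, bindings),
                                   response_threshold=0.1,
                                   binding_fold_threshold=5.0)
        assert cls.anchors == ANCHORS
        assert cls.contacts == CONTACTS
        assert cls.tolerant == frozenset({1, 6, 7})

    def test_all_tolerant_when_nothing_crosses_thresholds(self, query):
        responses = {p: 1000.0 for p in range(1, 10)}
        bindings = {p: 20.0 for p in range(1, 10)}
        cls = x.classify_positions(make_scan(query, responses, bindings))
        assert cls.tolerant == frozenset(range(1, 10))

    def test_response_threshold_is_inclusive(self, query):
        """A variant exactly at theta_r x wt is a contact (direct inequality)."""
        responses = {p: 1000.0 for p in range(1, 10)}
        bindings = {p: 20.0 for p in range(1, 10)}
        responses[4] = 100.0  # exactly 0.1 x 1000
        cls = x.classify_positions(make_scan(query, responses, bindings),
                                   response_threshold=0.1)
        assert 100.0 <= 0.1 * 1000.0  # the hand-evaluated boundary comparison
        assert cls.contacts == frozenset({4})

    def test_binding_fold_threshold_is_inclusive(self, query):
        responses = {p: 1000.0 for p in range(1, 10)}
        bindings = {p: 20.0 for p in range(1, 10)}
        bindings[2] = 100.0  # exactly 5-fold worse
        cls = x.classify_positions(make_scan(query, responses, bindings),
                                   binding_fold_threshold=5.0)
        assert cls.anchors == frozenset({2})

    def test_anchor_takes_precedence_over_contact(self, query):
        responses = {p: 1000.0 for p in range(1, 10)}
        bindings = {p: 20.0 for p in range(1, 10)}
        responses[2] = 0.0
        bindings[2] = 20000.0
        cls = x.classify_positions(make_scan(query, responses, bindings))
        assert cls.labels[1] == "anchor"

    def test_score_orientation_inverts_fold(self, query):
        """With score-like binding (higher=better), a drop is a worsening."""
        responses = {p: 1000.0 for p in range(1, 10)}
        bindings = {p: 20.0 for p in range(1, 10)}
        bindings[9] = 2.0  # 10-fold score drop
        scan = make_scan(query, responses, bindings, orientation="score")
        cls = x.classify_positions(scan)
        assert cls.anchors == frozenset({9})

    def test_zero_wt_response_rejected(self, query):
        with pytest.raises(ScanError):
            make_scan(query, {p: 1.0 for p in range(1, 10)},
                      {p: 20.0 for p in range(1, 10)}, wt_response=0.0)

    def test_incomplete_scan_rejected(self, query):
        variants = tuple(
            x.ScanVariant(position=p, substituted_residue="A",
                          response=1.0, predicted_binding=20.0)
            for p in range(1, 9)  # missing position 9
        )
        with pytest.raises(ScanError):
            x.PositionalScanTable(wild_type=query, wt_response=1000.0,
                                  wt_predicted_binding=20.0, variants=variants)

    @given(
        theta_lo=st.floats(0.01, 0.5),
        delta=st.floats(0.01, 0.4),
        seed=st.integers(0, 2**20),
    )
    @settings(max_examples=50, deadline=None)
    def test_lowering_response_threshold_never_adds_contacts(
        self, theta_lo, delta, seed
    ):
        q = x.validate_peptide("FLSNDTVQL")
        scan = x.generate_scan_table(
            x.SyntheticScanSpec(wild_type=q, contact_positions=CONTACTS,
                                anchor_positions=ANCHORS, noise_sd=0.5, seed=seed)
        )
        theta_hi = min(theta_lo + delta, 0.99)
        lo = x.classify_positions(scan, response_threshold=theta_lo)
        hi = x.classify_positions(scan, response_threshold=theta_hi)
        assert lo.contacts <= hi.contacts

    @given(
        fold_lo=st.floats(1.5, 50.0),
        delta=st.floats(0.1, 100.0),
        seed=st.integers(0, 2**20),
    )
    @settings(max_examples=50, deadline=None)
    def test_raising_binding_fold_never_adds_anchors(self, fold_lo, delta, seed):
        q = x.validate_peptide("FLSNDTVQL")
        scan = x.generate_scan_table(
            x.SyntheticScanSpec(wild_type=q, contact_positions=CONTACTS,
                                anchor_positions=ANCHORS, noise_sd=0.5, seed=seed)
        )
        lo = x.classify_positions(scan, binding_fold_threshold=fold_lo)
        hi = x.classify_positions(scan, binding_fold_threshold=fold_lo + delta)
        assert hi.anchors <= lo.anchors

    def test_labels_partition_positions(self, classification):
        assert (classification.anchors | classification.contacts
                | classification.tolerant) == frozenset(range(1, 10))
        assert not classification.anchors & classification.contacts


class TestBuildMotif:
    def test_contact_motif_of_worked_example(self, motif):
        assert motif.to_regex() == "..SND..Q."

    def test_fully_constrained_motif_matches_only_wild_type(self, query):
        cls = x.PositionClassification(
            labels=tuple(["contact"] * 9),
            response_threshold=0.1,
            binding_fold_threshold=5.0,
        )
        m = x.build_motif(cls, query)
        assert m.matches("FLSNDTVQL")
        assert not m.matches("FLSNDTVQI")

    def test_single_contact_matches_agree_with_regex_oracle(self, query,
                                                            small_proteome):
        labels = ["tolerant"] * 9
        labels[2] = "contact"  # position 3 = S
        cls = x.PositionClassification(tuple(labels), 0.1, 5.0)
        m = x.build_motif(cls, query)
        hits = x.scan_proteome(small_proteome, m, query=query)
        n_impl = sum(h.n_windows for h in hits)
        aa = "[ACDEFGHIKLMNPQRSTVWY]"
        pattern = re.compile(rf"(?=({aa}{{2}}S{aa}{{6}}))")
        n_oracle = sum(
            len(pattern.findall(protein.sequence)) for protein in small_proteome
        )
        assert n_impl == n_oracle

    def test_zero_contacts_is_uninformative_scan(self, query):
        cls = x.PositionClassification(
            labels=tuple(["tolerant"] * 9),
            response_threshold=0.1,
            binding_fold_threshold=5.0,
        )
        with pytest.raises(ScanError):
            x.build_motif(cls, query)

    def test_motif_json_round_trip(self, motif):
        assert x.RecognitionMotif.from_json(motif.to_json()) == motif


class TestScanTsv:
    def test_round_trip(self, tmp_path, noise_free_scan):
        path = tmp_path / "scan.tsv"
        x.write_scan_tsv(noise_free_scan, path)
        back = x.read_scan_tsv(path)
        assert back == noise_free_scan
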