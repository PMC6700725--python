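from __future__ import annotations

import numpy as np
import pytest

from venomalt.protein_inference import (
    Identification,
    PeptideObservation,
    enumerate_counts,
    filter_evidence,
    gene_contribution_summary,
    infer_identifications,
    purge_contaminants,
    read_evidence_table,
    write_evidence_table,
)

from oracles import inference_bruteforce


def obs(pep, prob, *pids):
    return PeptideObservation(pep, prob, frozenset(pids))


class TestFilterEvidence:
    def test_single_peptide_protein_removed(self):
        observations = [obs("PEPTIDEA", 0.99, "A"), obs("PEPTIDEB", 0.99, "A"), obs("PEPTIDEC", 0.99, "B")]
        out = filter_evidence(observations, {"A": 1.0, "B": 1.0})
        matched = set().union(*(o.matched_protein_ids for o in out))
        assert matched == {"A"}

    def test_threshold_inclusive(self):
        observations = [obs("PEPA", 0.95, "A"), obs("PEPB", 0.95, "A")]
        out = filter_evidence(observations, {"A": 0.99})
        assert len(out) == 2

    def test_below_threshold_removed(self):
        observations = [obs("PEPA", 0.9499, "A"), obs("PEPB", 0.99, "A")]
        assert filter_evidence(observations, {"A": 1.0}) == []

    def test_protein_probability_filter(self):
        observations = [obs("PEPA", 0.99, "A"), obs("PEPB", 0.99, "A")]
        assert filter_evidence(observations, {"A": 0.98}) == []

    def test_empty_input(self):
        assert filter_evidence([], {}) == []

    def test_monotone_in_thresholds(self, rng):
        observations = []
        probs = {}
        for i in range(30):
            pid = f"P{i % 8}"
            observations.append(obs(f"PEP{i}", float(rng.uniform(0.8, 1.0)), pid))
            probs[pid] = float(rng.uniform(0.9, 1.0))

        def n_proteins(**kw):
            out = filter_evidence(observations, probs, **kw)
            return len(set().union(*[o.matched_protein_ids for o in out], set()))

        base = n_proteins()
        assert n_proteins(peptide_p_min=0.99) <= base
        assert n_proteins(protein_p_min=0.999) <= base
        assert n_proteins(min_peptides=4) <= base


class TestInferIdentifications:
    SEQS = {"A": "MAAA", "B": "MBBB", "C": "MAAA", "D": "MDDD"}

    def test_subsumption(self):
        observations = [
            obs("P1", 0.99, "A", "B"),
            obs("P2", 0.99, "A"),
            obs("P3", 0.99, "A"),
        ]
        idents = infer_identifications(observations, self.SEQS)
        assert len(idents) == 1
        (ident,) = idents
        assert ident.member_protein_ids == {"A"} and ident.kind == "unique"

    def test_identical_sets_group_distinct(self):
        observations = [obs("P1", 0.99, "A", "B"), obs("P2", 0.99, "A", "B")]
        (ident,) = infer_identifications(observations, self.SEQS)
        assert ident.member_protein_ids == {"A", "B"}
        assert ident.kind == "group_distinct"

    def test_identical_sets_identical_sequences(self):
        observations = [obs("P1", 0.99, "A", "C"), obs("P2", 0.99, "A", "C")]
        (ident,) = infer_identifications(observations, self.SEQS)
        assert ident.kind == "group_identical"

    def test_lone_protein_unique(self):
        observations = [obs("P1", 0.99, "A"), obs("P2", 0.99, "A")]
        (ident,) = infer_identifications(observations, self.SEQS)
        assert ident.kind == "unique"

    def test_overlapping_incomparable_sets_stay_separate_flagged(self):
        observations = [
            obs("P1", 0.99, "A", "B"),
            obs("P2", 0.99, "A"),
            obs("P3", 0.99, "B"),
        ]
        idents = infer_identifications(observations, self.SEQS)
        assert len(idents) == 2
        assert all("overlapping_evidence" in i.flags for i in idents)

    def test_met_trim_applied_before_sequence_comparison(self):
        seqs = {"A": "GGMAAA", "B": "MAAA"}
        observations = [obs("P1", 0.99, "A", "B"), obs("P2", 0.99, "A", "B")]
        (ident,) = infer_identifications(observations, seqs)
        assert ident.kind == "group_identical"

    def test_il_equivalence_flag(self):
        seqs = {"A": "MAIA", "B": "MALA"}
        observations = [obs("P1", 0.99, "A", "B"), obs("P2", 0.99, "A", "B")]
        (ident,) = infer_identifications(observations, seqs)
        assert ident.kind == "group_distinct"
        (ident,) = infer_identifications(observations, seqs, il_equivalent=True)
        assert ident.kind == "group_identical"

    def test_missing_sequence_errors(self):
        with pytest.raises(KeyError, match="Z"):
            infer_identifications([obs("P1", 0.99, "Z")], {})

    def test_matches_subset_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            n_prot = int(rng.integers(2, 11))
            n_pep = int(rng.integers(2, 13))
            peptides = [f"PEP{j}" for j in range(n_pep)]
            graph = {}
            for i in range(n_prot):
                k = int(rng.integers(1, n_pep + 1))
                graph[f"P{i}"] = set(rng.choice(peptides, size=k, replace=False))
            seqs = {pid: f"MSEQ{int(rng.integers(0, 4))}" for pid in graph}
            observations = []
            for pep in peptides:
                matched = frozenset(p for p, s in graph.items() if pep in s)
                if matched:
                    observations.append(PeptideObservation(pep, 0.99, matched))
            got = {
                (i.kind, i.member_protein_ids, i.peptide_set)
                for i in infer_identifications(observations, seqs)
            }
            expected = inference_bruteforce(graph, seqs)
            assert got == expected


class TestEnumerateCounts:
    def mk(self, kind, members, peps=("X", "Y")):
        return Identification(frozenset(members), kind, frozenset(peps))

    def test_reported_min_count(self):
        idents = [self.mk("unique", [f"U{i}"]) for i in range(53)]
        idents += [self.mk("group_distinct", [f"G{i}a", f"G{i}b"]) for i in range(26)]
        idents += [self.mk("group_identical", [f"H{i}a", f"H{i}b"]) for i in range(20)]
        inv = enumerate_counts(idents)
        assert inv.min_count == 99
        assert inv.kind_tally == {"unique": 53, "group_distinct": 26, "group_identical": 20}

    def test_group_of_three_with_two_distinct_sequences(self):
        seqs = {"A": "MX", "B": "MX", "C": "MY"}
        inv = enumerate_counts([self.mk("group_distinct", ["A", "B", "C"])], seqs)
        assert (inv.min_count, inv.max_count) == (1, 2)

    def test_all_unique_min_equals_max(self):
        idents = [self.mk("unique", [f"U{i}"]) for i in range(7)]
        inv = enumerate_counts(idents)
        assert inv.min_count == inv.max_count == 7

    def test_min_le_max_equality_iff_no_distinct_groups(self, evidence_fixture):
        from venomalt.protein_inference import filter_evidence as fe

        filtered = fe(evidence_fixture.observations, evidence_fixture.protein_probabilities)
        idents = infer_identifications(filtered, evidence_fixture.proteins)
        inv = enumerate_counts(idents, evidence_fixture.proteins)
        assert inv.min_count <= inv.max_count
        has_distinct = any(i.kind == "group_distinct" for i in idents)
        assert (inv.min_count == inv.max_count) == (not has_distinct)


class TestPurgeContaminants:
    def mk(self, members):
        return Identification(frozenset(members), "unique" if len(members) == 1 else "group_distinct", frozenset({"X", "Y"}))

    def test_keratin_removed(self):
        labels = {"A": "keratin, type II"}
        assert purge_contaminants([self.mk(["A"])], ["keratin", "trypsin"], labels) == []

    def test_empty_labels_unchanged(self):
        idents = [self.mk(["A"])]
        assert purge_contaminants(idents, [], {}) == idents

    def test_mixed_group_retained_with_flag(self):
        labels = {"A": "alpha-latrotoxin", "B": "keratin"}
        (out,) = purge_contaminants([self.mk(["A", "B"])], ["keratin"], labels)
        assert "contaminant_member" in out.flags

    def test_case_insensitive(self):
        labels = {"A": "Trypsin precursor"}
        assert purge_contaminants([self.mk(["A"])], ["TRYPSIN"], labels) == []


class TestGeneContribution:
    def test_fig3_style_locus(self):
        # 4 transcripts, 4 distinct proteins; evidence discriminates one,
        # leaves two grouped, excludes one -> (4, 4, 2, 3)
        transcript_gene = {f"t{i}": "G" for i in range(1, 5)}
        protein_transcript = {f"p{i}": f"t{i}" for i in range(1, 5)}
        seqs = {"p1": "MA", "p2": "MB", "p3": "MC", "p4": "MD"}
        idents = [
            Identification(frozenset({"p1"}), "unique", frozenset({"x", "y"})),
            Identification(frozenset({"p2", "p3"}), "group_distinct", frozenset({"z", "w"})),
        ]
        summary = gene_contribution_summary(transcript_gene, protein_transcript, seqs, idents)
        assert summary["G"] == (4, 4, 2, 3)

    def test_gene_with_no_identifications(self):
        transcript_gene = {"t1": "G", "t2": "G"}
        protein_transcript = {"p1": "t1", "p2": "t2"}
        seqs = {"p1": "MA", "p2": "MB"}
        summary = gene_contribution_summary(transcript_gene, protein_transcript, seqs, [])
        assert summary["G"] == (2, 2, 0, 0)

    def test_dangling_protein_errors(self):
        idents = [Identification(frozenset({"ghost"}), "unique", frozenset({"x"}))]
        with pytest.raises(KeyError, match="ghost"):
            gene_contribution_summary({"t1": "G"}, {"p1": "t1"}, {"p1": "MA"}, idents)

    def test_matches_bipartite_recount(self, rng):
        # random evidence graph vs direct recount of the definitions
        genes = {f"t{i}": f"G{i % 3}" for i in range(12)}
        protein_transcript = {f"p{i}": f"t{i}" for i in range(12)}
        seqs = {f"p{i}": f"MS{int(rng.integers(0, 6))}" for i in range(12)}
        idents = []
        pool = list(protein_transcript)
        rng.shuffle(pool)
        while pool:
            k = min(len(pool), int(rng.integers(1, 4)))
            members, pool = pool[:k], pool[k:]
            kind = "unique" if k == 1 else "group_distinct"
            idents.append(Identification(frozenset(members), kind, frozenset({f"q{len(pool)}", "q2"})))
        summary = gene_contribution_summary(genes, protein_transcript, seqs, idents)
        for gene in set(genes.values()):
            n_tx = sum(1 for g in genes.values() if g == gene)
            n_distinct = len(
                {seqs[p] for p, t in protein_transcript.items() if genes[t] == gene}
            )
            unamb = 0
            possible = set()
            for ident in idents:
                mg = {genes[protein_transcript[p]] for p in ident.member_protein_ids}
                if gene in mg:
                    if mg == {gene}:
                        unamb += 1
                    possible |= {
                        seqs[p]
                        for p in ident.member_protein_ids
                        if genes[protein_transcript[p]] == gene
                    }
            assert summary[gene] == (n_tx, n_distinct, unamb, len(possible))


class TestEvidenceIO:
    def test_round_trip(self, tmp_path):
        observations = [obs("PEPA", 0.99, "A"), obs("PEPB", 0.97, "A", "B")]
        probs = {"A": 0.999, "B": 0.999}
        path = tmp_path / "ev.tsv"
        write_evidence_table(observations, probs, str(path))
        back, probs_back = read_evidence_table(str(path))
        assert {(o.peptide_sequence, o.matched_protein_ids) for o in back} == {
            ("PEPA", frozenset({"A"})),
            ("PEPB", frozenset({"A", "B"})),
        }
        assert probs_back == {"A": 0.999, "B": 0.999}
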