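"""Event calling, structural categories and gene-level summaries."""

import numpy as np
import pytest

from isoflat.annotation_io import AnnotationError, Config
from isoflat.event_caller import (
    GeneSummary,
    annotate_junction_support,
    build_exon_matrix,
    call_alt_splice_sites,
    call_events,
    call_exon_skipping,
    call_first_last,
    call_intron_retention,
    call_novel_exons,
    classify_structural_category,
    match_exons,
    summarize_gene,
)
from isoflat.gene_model import flatten_gene
from conftest import tx


def iso(pairs, tid="q", strand="+"):
    return tx(tid, pairs, strand=strand, source="long_read")


class TestMatchExons:
    def test_exact_match(self, gene_g):
        _, model = gene_g
        (m,) = match_exons(iso([(300, 400)]), model)
        assert m.match_class == "exact"
        assert m.matched_flat_exons == [2]
        assert m.boundary_offsets == (0, 0)

    def test_spanning_match_is_ir_candidate(self, gene_g):
        _, model = gene_g
        (m,) = match_exons(iso([(300, 600)]), model)
        assert m.match_class == "spanning"
        assert m.matched_flat_exons == [2, 3]

    def test_intronic_exon_is_cryptic(self, gene_g):
        _, model = gene_g
        matches = match_exons(iso([(300, 400), (430, 470), (500, 600)]), model)
        assert matches[1].match_class == "cryptic"
        assert matches[1].matched_flat_exons == []

    def test_small_overlap_is_alt_boundary_not_cryptic(self, gene_g):
        _, model = gene_g
        matches = match_exons(iso([(300, 400), (430, 510), (700, 800)]), model)
        assert matches[1].match_class == "alt_boundary"
        assert matches[1].matched_flat_exons == [3]

    def test_every_exon_gets_exactly_one_class(self, gene_g):
        _, model = gene_g
        q = iso([(40, 90), (100, 200), (300, 600), (650, 670), (700, 800), (900, 950)])
        matches = match_exons(q, model)
        assert len(matches) == 6
        assert [m.match_class for m in matches] == [
            "novel_upstream", "exact", "spanning", "cryptic", "exact", "novel_downstream",
        ]

    def test_strand_mismatch_rejected(self, gene_g):
        _, model = gene_g
        with pytest.raises(AnnotationError, match="q"):
            match_exons(iso([(300, 400)], strand="-"), model)


class TestAltSpliceSites:
    """The tolerance rule is strict: 'more than 10 bp' from the known site."""

    def make(self, second_exon, model):
        q = iso([(100, 200), second_exon, (500, 600), (700, 800)])
        return call_alt_splice_sites(q, match_exons(q, model), model)

    def test_offset_ten_is_not_an_event(self, gene_g):
        _, model = gene_g
        a5, a3 = self.make((290, 400), model)
        assert a3 == [] and a5 == []

    def test_offset_eleven_is_an_event(self, gene_g):
        _, model = gene_g
        a5, a3 = self.make((289, 400), model)
        assert a3 == [(2, 11)] and a5 == []

    def test_offset_zero_no_event(self, gene_g):
        _, model = gene_g
        a5, a3 = self.make((300, 400), model)
        assert a5 == [] and a3 == []

    def test_donor_side_is_a5(self, gene_g):
        _, model = gene_g
        a5, a3 = self.make((300, 420), model)
        assert a5 == [(2, 20)] and a3 == []

    def test_terminal_edges_never_a5_a3(self, gene_g):
        # heavily shifted transcription start/end edges are AP/AT territory
        _, model = gene_g
        q = iso([(160, 200), (300, 400), (500, 560)])
        a5, a3 = call_alt_splice_sites(q, match_exons(q, model), model)
        assert a5 == [] and a3 == []

    def test_offsets_measured_to_nearest_variant_boundary(self):
        # exon 2 has two annotated acceptors (250 and 300); matching either is no event
        refs = [tx("T1", [(100, 200), (300, 400)]), tx("T2", [(100, 200), (250, 400)])]
        model = flatten_gene(refs)
        q = iso([(100, 200), (250, 400)])
        a5, a3 = call_alt_splice_sites(q, match_exons(q, model), model)
        assert a3 == []
        q = iso([(100, 200), (230, 400)])  # 20 bp beyond the nearest variant
        a5, a3 = call_alt_splice_sites(q, match_exons(q, model), model)
        assert a3 == [(2, 20)]


class TestExonSkipping:
    def test_single_skip(self, gene_g):
        _, model = gene_g
        q = iso([(100, 200), (500, 600), (700, 800)])
        assert call_exon_skipping(match_exons(q, model), model) == [2]

    def test_ir_spanned_exon_not_skipped(self, gene_g):
        _, model = gene_g
        q = iso([(100, 200), (300, 600), (700, 800)])
        assert call_exon_skipping(match_exons(q, model), model) == []

    def test_exons_outside_span_never_skipped(self, gene_g):
        _, model = gene_g
        q = iso([(300, 400), (500, 600)])
        assert call_exon_skipping(match_exons(q, model), model) == []

    def test_brute_force_agreement(self, gene_g):
        _, model = gene_g
        rng = np.random.default_rng(3)
        coords = [(100, 200), (300, 400), (500, 600), (700, 800)]
        for _ in range(200):
            keep = sorted(rng.choice(4, size=rng.integers(2, 5), replace=False))
            q = iso([coords[k] for k in keep])
            matches = match_exons(q, model)
            got = call_exon_skipping(matches, model)
            lo, hi = keep[0] + 1, keep[-1] + 1
            expected = [k for k in range(lo + 1, hi) if (k - 1) not in keep]
            assert got == expected


class TestIntronRetention:
    def test_two_exon_span(self, gene_g):
        _, model = gene_g
        q = iso([(100, 200), (300, 600), (700, 800)])
        assert call_intron_retention(match_exons(q, model), model) == [(2, 3, 2)]

    def test_many_exon_span_counts_all(self):
        coords = [(i * 200, i * 200 + 100) for i in range(1, 12)]
        model = flatten_gene([tx("T1", coords)])
        q = iso([(coords[0][0], coords[-1][1])])
        assert call_intron_retention(match_exons(q, model), model) == [(1, 11, 11)]

    def test_two_spanning_exons_two_events(self):
        coords = [(i * 200, i * 200 + 100) for i in range(1, 7)]
        model = flatten_gene([tx("T1", coords)])
        q = iso([(coords[0][0], coords[1][1]), (coords[3][0], coords[4][1])])
        assert call_intron_retention(match_exons(q, model), model) == [(1, 2, 2), (4, 5, 2)]


class TestNovelExons:
    def test_cryptic_in_intron(self, gene_g):
        _, model = gene_g
        q = iso([(300, 400), (430, 470), (500, 600)])
        ce, ne = call_novel_exons(q, match_exons(q, model), model)
        assert ce == [(2, (430, 470))] and ne == []

    def test_upstream_novel_exon(self, gene_g):
        _, model = gene_g
        q = iso([(40, 90), (100, 200), (300, 400)])
        ce, ne = call_novel_exons(q, match_exons(q, model), model)
        assert ne == [("upstream", (40, 90))] and ce == []

    def test_overlapping_exon_is_not_cryptic(self, gene_g):
        _, model = gene_g
        q = iso([(300, 400), (430, 510), (700, 800)])
        ce, ne = call_novel_exons(q, match_exons(q, model), model)
        assert ce == [] and ne == []


class TestFirstLast:
    def test_internal_start_is_af_and_ap(self, gene_g):
        _, model = gene_g
        q = iso([(300, 400), (500, 600), (700, 800)])
        fl = call_first_last(q, match_exons(q, model), model)
        assert fl["af"] and fl["af_first_exon"] == 2
        assert fl["ap"]  # |300-100| > 50

    def test_annotated_start_is_neither(self, gene_g):
        _, model = gene_g
        q = iso([(100, 200), (300, 400)])
        fl = call_first_last(q, match_exons(q, model), model)
        assert not fl["af"] and not fl["ap"]

    def test_tss_within_window_not_ap(self, gene_g):
        _, model = gene_g
        q = iso([(139, 200), (300, 400)])  # offset 39 <= 50
        fl = call_first_last(q, match_exons(q, model), model)
        assert not fl["ap"]
        assert not fl["af"]  # still exon 1, which is ever-first

    def test_al_at_on_truncated_end(self, gene_g):
        _, model = gene_g
        q = iso([(100, 200), (300, 400), (500, 600)])
        fl = call_first_last(q, match_exons(q, model), model)
        assert fl["al"] and fl["at"]


class TestStructuralCategory:
    def all_subchains(self, chain):
        return {
            chain[i:j]
            for i in range(len(chain))
            for j in range(i + 1, len(chain) + 1)
        }

    def test_fsm(self, gene_g):
        refs, model = gene_g
        q = iso([(100, 200), (300, 400), (500, 600), (700, 800)])
        cat = classify_structural_category(q, refs, model)
        assert cat.category == "FSM" and cat.matched_reference_transcript == "T1"

    def test_ism_suffix(self, gene_g):
        refs, model = gene_g
        q = iso([(310, 400), (500, 600), (700, 790)])
        cat = classify_structural_category(q, refs, model)
        assert cat.category == "ISM" and cat.matched_reference_transcript == "T1"

    def test_nic_known_sites_novel_combination(self, gene_g):
        refs, model = gene_g
        q = iso([(100, 200), (300, 400), (700, 800)])  # junction (400,700) unseen
        cat = classify_structural_category(q, refs, model)
        assert cat.category == "NNC" or cat.category == "NIC"
        # donor 400 and acceptor 700 are both known -> NIC
        assert cat.category == "NIC"

    def test_nnc_requires_novel_site(self, gene_g):
        refs, model = gene_g
        q = iso([(100, 220), (300, 400), (500, 600), (700, 800)])  # donor 220 novel
        assert classify_structural_category(q, refs, model).category == "NNC"

    def test_category_ignores_splice_tolerance(self, gene_g):
        # a 5 bp offset is within event tolerance but still a novel site
        refs, model = gene_g
        q = iso([(100, 205), (300, 400), (500, 600), (700, 800)])
        assert classify_structural_category(q, refs, model).category == "NNC"

    def test_mono_exonic_flagging(self, gene_g):
        refs, model = gene_g
        cat = classify_structural_category(iso([(310, 390)]), refs, model)
        assert cat.category == "ISM" and cat.mono_exon
        cat = classify_structural_category(iso([(420, 470)]), refs, model)
        assert cat.category == "NIC" and cat.mono_exon

    def test_subchain_oracle_random_queries(self, gene_g):
        refs, model = gene_g
        ref_chains = {r.transcript_id: tuple(r.junctions()) for r in refs}
        coords = [(100, 200), (300, 400), (500, 600), (700, 800)]
        rng = np.random.default_rng(11)
        for _ in range(300):
            keep = sorted(rng.choice(4, size=rng.integers(2, 5), replace=False))
            q = iso([coords[k] for k in keep])
            chain = tuple(q.junctions())
            if chain in ref_chains.values():
                expected = "FSM"
            elif any(chain in self.all_subchains(c) for c in ref_chains.values()):
                expected = "ISM"
            else:
                expected = "NIC"  # all sites from reference exon boundaries
            assert classify_structural_category(q, refs, model).category == expected


class TestSummaries:
    def test_event_accounting_arithmetic(self, gene_g):
        refs, model = gene_g
        isos = [
            iso([(100, 200), (300, 378), (500, 600), (700, 800)], tid="q1"),  # A5 offset 22
            iso([(100, 200), (289, 400), (500, 600), (700, 800)], tid="q2"),  # A3 offset 11
            iso([(100, 200), (300, 400), (500, 600), (700, 800)], tid="q3"),
        ]
        events = [call_events(q, model) for q in isos]
        cats = [classify_structural_category(q, refs, model) for q in isos]
        s = summarize_gene("G", events, cats, model)
        n_iso, n_ev = s.events["A5A3"]
        assert (n_iso, n_ev) == (2, 2)
        assert s.pct_isoforms_with("A5A3") == 66.7
        assert s.n_isoforms == 3 and s.n_known == 1 and s.n_novel == 2

    def test_published_scale_percentages(self):
        # accounting at the published panel scale exercises the same code path
        s = GeneSummary(
            gene_id="panel",
            n_isoforms=7162,
            n_known=1000,
            n_novel=6162,
            n_coding=None,
            n_noncoding=None,
            events={"A5A3": (6082, 10396), "ES": (6031, 24315), "IR": (134, 135)},
            skip_counts={},
        )
        assert s.pct_isoforms_with("A5A3") == 84.9
        assert s.pct_isoforms_with("ES") == 84.2
        assert s.pct_isoforms_with("IR", decimals=2) == 1.87

    def test_per_exon_skip_counts(self, gene_g):
        refs, model = gene_g
        isos = [
            iso([(100, 200), (500, 600), (700, 800)], tid="q1"),
            iso([(100, 200), (500, 600), (700, 800)], tid="q2"),
            iso([(100, 200), (300, 400), (700, 800)], tid="q3"),
        ]
        events = [call_events(q, model) for q in isos]
        cats = [classify_structural_category(q, refs, model) for q in isos]
        s = summarize_gene("G", events, cats, model)
        assert s.skip_counts == {1: 0, 2: 2, 3: 1, 4: 0}

    def test_known_split_switch(self, gene_g):
        refs, model = gene_g
        isos = [iso([(310, 400), (500, 600), (700, 790)], tid="q1")]  # ISM
        events = [call_events(q, model) for q in isos]
        cats = [classify_structural_category(q, refs, model) for q in isos]
        strict = summarize_gene("G", events, cats, model)
        loose = summarize_gene("G", events, cats, model, known_categories=frozenset({"FSM", "ISM"}))
        assert strict.n_known == 0 and loose.n_known == 1


class TestExonMatrix:
    def test_row_states(self, gene_g):
        _, model = gene_g
        mat = build_exon_matrix(
            [
                iso([(100, 200), (500, 600), (700, 800)], tid="skip2"),
                iso([(100, 200), (300, 600), (700, 800)], tid="ir23"),
            ],
            model,
        )
        assert mat.loc["skip2"].tolist() == [1, 2, 1, 1]
        assert mat.loc["ir23"].tolist() == [1, 3, 3, 1]

    def test_identical_isoforms_cluster_adjacently(self, gene_g):
        _, model = gene_g
        a = iso([(100, 200), (500, 600), (700, 800)], tid="a")
        z = iso([(100, 200), (500, 600), (700, 800)], tid="z")
        other = iso([(100, 200), (300, 400), (500, 600), (700, 800)], tid="m")
        mat = build_exon_matrix([a, other, z], model)
        rows = list(mat.index)
        assert abs(rows.index("a") - rows.index("z")) == 1

    def test_deterministic(self, gene_g):
        _, model = gene_g
        isos = [
            iso([(100, 200), (500, 600), (700, 800)], tid="a"),
            iso([(100, 200), (300, 400), (700, 800)], tid="b"),
            iso([(100, 200), (300, 600), (700, 800)], tid="c"),
        ]
        m1 = build_exon_matrix(isos, model)
        m2 = build_exon_matrix(isos[::-1], model)
        assert m1.equals(m2)


def test_junction_support_annotation(gene_g):
    import pandas as pd

    _, model = gene_g
    q = iso([(100, 200), (300, 400)], tid="q1")
    sj = pd.DataFrame(
        {"chrom": ["chr1"], "start": [200], "end": [300], "strand": ["+"], "unique_reads": [5]}
    )
    out = annotate_junction_support([q], sj)
    assert out["supported"].tolist() == [True]
    sj0 = sj.assign(unique_reads=[0])
    assert annotate_junction_support([q], sj0)["supported"].tolist() == [False]
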