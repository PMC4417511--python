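"""Tumour assignment, partitioning invariants and index file I/O."""

import pytest
from hypothesis import given, strategies as st

import tcgafed as tf
from tcgafed.distribution import (
    RoutingError,
    TSSTumourTable,
    ValidationError,
    build_tss_table,
)
from tcgafed.model import Colour, parse_result_uri


class TestAssignTumours:
    def test_seventeen_endpoint_layout(self):
        index = tf.assign_tumours(33, {"blue": 2, "pink": 6, "green": 9})
        assert len(index.endpoints) == 17
        blue = [sorted(e.tumours) for e in index.by_colour(Colour.BLUE)]
        assert sorted(len(b) for b in blue) == [16, 17]
        pink_sizes = [len(e.tumours) for e in index.by_colour(Colour.PINK)]
        assert all(s in (5, 6) for s in pink_sizes)
        green_sizes = [len(e.tumours) for e in index.by_colour(Colour.GREEN)]
        assert green_sizes == [4, 4, 4, 4, 4, 4, 3, 3, 3]
        # contiguity + full coverage once per colour
        for colour in Colour:
            seen = []
            for ep in index.by_colour(colour):
                seen.extend(sorted(ep.tumours))
            assert sorted(seen) == sorted(index.tumours())

    def test_benchmark_layout_every_tumour_once_per_colour(self):
        index = tf.assign_tumours(10, {"blue": 2, "pink": 3, "green": 5})
        assert len(index.endpoints) == 10
        for colour in Colour:
            cover = [t for e in index.by_colour(colour) for t in e.tumours]
            assert sorted(cover) == sorted(index.tumours())
            assert len(cover) == 10

    def test_degenerate_single_endpoint_per_colour(self):
        index = tf.assign_tumours(3, {"blue": 1, "pink": 1, "green": 1})
        for ep in index.endpoints:
            assert len(ep.tumours) == 3

    def test_too_few_tumours_is_an_error(self):
        with pytest.raises(ValidationError):
            tf.assign_tumours(2, {"blue": 3, "pink": 1, "green": 1})

    @given(n=st.integers(3, 40), blue=st.integers(1, 3),
           pink=st.integers(1, 6), green=st.integers(1, 9))
    def test_balanced_contiguous_ranges(self, n, blue, pink, green):
        if n < max(blue, pink, green):
            return
        index = tf.assign_tumours(
            n, {"blue": blue, "pink": pink, "green": green},
            tumour_names=[f"T{i:02d}" for i in range(n)])
        for colour, k in ((Colour.BLUE, blue), (Colour.PINK, pink),
                          (Colour.GREEN, green)):
            sizes = [len(e.tumours) for e in index.by_colour(colour)]
            assert sum(sizes) == n and len(sizes) == k
            assert max(sizes) - min(sizes) <= 1


class TestPartition:
    def test_union_and_disjointness(self, small_fixture):
        fx = small_fixture
        union = set()
        result_triples_seen = set()
        for dump in fx.dumps.values():
            union |= dump.triples
        assert union == fx.union_dump.triples
        # result-node triples appear at exactly one endpoint
        for url, dump in fx.dumps.items():
            for t in dump.triples:
                try:
                    parse_result_uri(str(t[0]), fx.index.data_ns)
                except Exception:
                    continue
                assert t not in result_triples_seen
                result_triples_seen.add(t)

    def test_colour_purity(self, small_fixture):
        fx = small_fixture
        for ep in fx.index.endpoints:
            for t in fx.dumps[ep.url].triples:
                try:
                    ref = parse_result_uri(str(t[0]), fx.index.data_ns)
                except Exception:
                    continue
                assert ref.colour is ep.colour

    def test_patients_replicated_once_per_colour(self, small_fixture):
        fx = small_fixture
        barcode_pred = tf.model.vocab("bcr_patient_barcode")
        for p in fx.patients:
            holders = [ep for ep in fx.index.endpoints
                       if any(t[1] == barcode_pred
                              and str(t[2]) == str(p.barcode)
                              for t in fx.dumps[ep.url].triples)]
            assert len(holders) == 3
            assert {ep.colour for ep in holders} == set(Colour)
            assert all(p.tumour in ep.tumours for ep in holders)

    def test_result_routed_by_colour_and_tumour(self, small_fixture):
        fx = small_fixture
        p = fx.patients[0]
        node = tf.mint_result_uri(p.barcode, "d", 1)
        holders = [ep.url for ep in fx.index.endpoints
                   if any(str(t[0]) == str(node)
                          for t in fx.dumps[ep.url].triples)]
        expected = fx.index.endpoint_for(Colour.GREEN, p.tumour)
        if fx.ground_truth[(str(p.barcode), "dna-methylation")]:
            assert holders == [expected.url]

    def test_unknown_tss_is_a_routing_error(self, small_fixture):
        fx = small_fixture
        from tcgafed.rdfizer import RawTable, rdfize_raw
        stranger = tf.parse_patient_barcode("TCGA-ZZ-0001")
        raw = RawTable("dna-methylation",
                       ["chromosome", "position", "beta_value"],
                       [("chr1", "5", "0.5")])
        dump = rdfize_raw(raw, stranger)
        with pytest.raises(RoutingError, match="ZZ"):
            tf.partition(dump, fx.index, fx.tss_table)


class TestSpecFile:
    def test_round_trip_identity(self, benchmark_fixture):
        index = benchmark_fixture.index
        loaded = tf.load_spec_file(tf.write_spec_file(index))
        assert [(e.url, e.colour, e.tumours, e.order)
                for e in loaded.endpoints] == \
               [(e.url, e.colour, e.tumours, e.order)
                for e in index.endpoints]
        assert loaded.sets == index.sets
        assert (loaded.data_ns, loaded.vocab_ns) == \
               (index.data_ns, index.vocab_ns)

    def test_duplicate_tumour_within_colour_rejected(self):
        index = tf.assign_tumours(4, {"blue": 2, "pink": 1, "green": 1})
        text = tf.write_spec_file(index)
        blue2 = index.by_colour(Colour.BLUE)[1]
        dup = sorted(index.by_colour(Colour.BLUE)[0].tumours)[0]
        text = text.replace(
            f"<{blue2.url}> fed:hasColour",
            f'<{blue2.url}> fed:storesTumour "{dup}" .\n'
            f"<{blue2.url}> fed:hasColour")
        with pytest.raises(ValidationError, match="two blue endpoints"):
            tf.load_spec_file(text)

    def test_missing_colour_rejected(self):
        index = tf.assign_tumours(3, {"blue": 1, "pink": 1, "green": 1})
        text = tf.write_spec_file(index)
        url = index.endpoints[0].url
        text = "\n".join(ln for ln in text.splitlines()
                         if not (url in ln and "hasColour" in ln))
        with pytest.raises(ValidationError, match="missing colour"):
            tf.load_spec_file(text)

    def test_endpoint_order_is_file_order(self, benchmark_fixture):
        loaded = tf.load_spec_file(tf.write_spec_file(benchmark_fixture.index))
        assert [e.order for e in loaded.endpoints] == list(range(10))


class TestTssTable:
    def test_lusc_style_row(self):
        table = build_tss_table(
            "filename\tbarcode\ttumour\n"
            "methylation.TCGA-18-3406.txt\tTCGA-18-3406-01A\tLUSC\n")
        assert table.lookup("18") == "LUSC"

    def test_empty_map(self):
        table = build_tss_table("filename\tbarcode\ttumour\n")
        assert len(table) == 0
        assert table.lookup("18") is None

    def test_conflicting_mapping_rejected(self):
        with pytest.raises(ValidationError, match="18"):
            build_tss_table(
                "barcode\ttumour\n"
                "TCGA-18-0001\tLUSC\n"
                "TCGA-18-0002\tBRCA\n")

    def test_generated_map_agrees_with_ground_truth(self, benchmark_fixture):
        fx = benchmark_fixture
        table = build_tss_table(fx.file_sample_map)
        assert len(table) >= fx.config.n_tumours
        for p in fx.patients:
            assert table.lookup(p.tss) == p.tumour

    def test_many_to_one_tss_mapping_allowed(self):
        table = TSSTumourTable()
        table.add("18", "LUSC")
        table.add("22", "LUSC")
        assert table.lookup("22") == "LUSC"
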