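"""Join-aware source selection: join graph, colour conditions, the worked
example, the ASK baseline and the triple-pattern-wise count."""

import itertools

import pytest
from hypothesis import given, strategies as st

import tcgafed as tf
from tcgafed.model import Colour, Term, bgp_from_triples, vocab
from tcgafed.selection import (
    AskCache,
    SelectionContext,
    SourceSelection,
    _pattern_signature,
    build_join_graph,
    evaluate_colour_condition,
    infer_tumour_number,
)

V = Term.variable
I = Term.iri
L = Term.literal


def tcga(name):
    return I(str(vocab(name)))


def listing6_bgp(barcode="TCGA-18-3406"):
    """Patient-specific copy-number query: barcode star result, record star
    chromosome/start/stop/seq_mean."""
    return bgp_from_triples([
        (V("p"), tcga("bcr_patient_barcode"), L(barcode)),
        (V("p"), tcga("result"), V("r")),
        (V("r"), tcga("chromosome"), V("c")),
        (V("r"), tcga("start"), V("s")),
        (V("r"), tcga("stop"), V("t")),
        (V("r"), tcga("seq_mean"), V("m")),
    ])


class TestJoinGraph:
    def test_listing6_stars_and_paths(self):
        jg = build_join_graph(listing6_bgp())
        expected_stars = {frozenset(p) for p in
                          [(0, 1)] + list(itertools.combinations((2, 3, 4, 5), 2))}
        assert jg.star_pairs == expected_stars
        assert jg.path_pairs == frozenset({(1, 2), (1, 3), (1, 4), (1, 5)})

    def test_single_pattern_bgp_is_empty(self):
        bgp = bgp_from_triples([(V("s"), V("p"), V("o"))])
        jg = build_join_graph(bgp)
        assert not jg.star_pairs and not jg.path_pairs

    @given(st.data())
    def test_matches_brute_force_all_pairs(self, data):
        terms = [V("a"), V("b"), V("c"), V("d"),
                 I("http://x.org/n1"), I("http://x.org/n2")]
        n = data.draw(st.integers(2, 8))
        triples = [(data.draw(st.sampled_from(terms[:4] + terms[4:])),
                    tcga("result"),
                    data.draw(st.sampled_from(terms)))
                   for _ in range(n)]
        bgp = bgp_from_triples(triples)
        jg = build_join_graph(bgp)
        for tp1, tp2 in itertools.combinations(bgp.patterns, 2):
            star = tp1.subject == tp2.subject
            assert (frozenset({tp1.index, tp2.index}) in jg.star_pairs) == star
        for tp1 in bgp.patterns:
            for tp2 in bgp.patterns:
                if tp1.index == tp2.index:
                    continue
                path = tp1.object == tp2.subject and \
                    tp1.object.kind != "literal"
                assert ((tp1.index, tp2.index) in jg.path_pairs) == path


@pytest.fixture(scope="module")
def deployment_ctx(deployment_fixture):
    return SelectionContext(deployment_fixture.index,
                            deployment_fixture.tss_table)


class TestInferTumour:
    def test_barcode_star_result_yields_tumour(self, deployment_ctx):
        fx_table = deployment_ctx.tss_table
        bgp = listing6_bgp()
        jg = build_join_graph(bgp)
        tumour = infer_tumour_number(bgp, jg, fx_table)
        assert tumour == fx_table.lookup("18") == "LUSC"

    def test_no_barcode_pattern_yields_null(self, deployment_ctx):
        bgp = bgp_from_triples([
            (V("r"), tcga("chromosome"), V("c")),
            (V("r"), tcga("start"), V("s")),
        ])
        assert infer_tumour_number(bgp, build_join_graph(bgp),
                                   deployment_ctx.tss_table) is None

    def test_barcode_without_result_star_yields_null(self, deployment_ctx):
        bgp = bgp_from_triples([
            (V("p"), tcga("bcr_patient_barcode"), L("TCGA-18-3406")),
            (V("r"), tcga("chromosome"), V("c")),
        ])
        assert infer_tumour_number(bgp, build_join_graph(bgp),
                                   deployment_ctx.tss_table) is None

    def test_unknown_tss_yields_null(self, deployment_ctx):
        bgp = listing6_bgp(barcode="TCGA-ZZ-9999")
        assert infer_tumour_number(bgp, build_join_graph(bgp),
                                   deployment_ctx.tss_table) is None


class TestColourConditions:
    sets = tf.PredicateSets.default()

    def conditions(self, bgp, i):
        jg = build_join_graph(bgp)
        return tuple(evaluate_colour_condition(bgp.patterns[i], jg, bgp,
                                               self.sets, colour)
                     for colour in (Colour.BLUE, Colour.PINK, Colour.GREEN))

    def test_chromosome_star_joined_with_seq_mean_is_blue_only(self):
        bgp = bgp_from_triples([
            (V("r"), tcga("chromosome"), V("c")),
            (V("r"), tcga("seq_mean"), V("m")),
        ])
        assert self.conditions(bgp, 0) == (True, False, False)

    def test_beta_value_without_joins_is_green_only(self):
        bgp = bgp_from_triples([(V("r"), tcga("beta_value"), V("b"))])
        assert self.conditions(bgp, 0) == (False, False, True)

    def test_chromosome_without_joins_satisfies_all_conditions(self):
        bgp = bgp_from_triples([(V("r"), tcga("chromosome"), V("c"))])
        assert self.conditions(bgp, 0) == (True, True, True)

    def test_barcode_inherits_colour_through_star_then_path(self):
        # the patient-barcode pattern of the worked example sees seq_mean
        # through its star partner's path join and passes only C-1
        bgp = listing6_bgp()
        assert self.conditions(bgp, 0) == (True, False, False)
        assert self.conditions(bgp, 1) == (True, False, False)

    def test_rpkm_star_is_pink_only(self):
        bgp = bgp_from_triples([
            (V("r"), tcga("chromosome"), V("c")),
            (V("r"), tcga("RPKM"), V("e")),
        ])
        assert self.conditions(bgp, 0) == (False, True, False)
        assert self.conditions(bgp, 1) == (False, True, False)

    def test_rdf_type_with_class_object(self):
        rdf_type = I("http://www.w3.org/1999/02/22-rdf-syntax-ns#type")
        bgp = bgp_from_triples([
            (V("r"), rdf_type, tcga("DnaMethylationResult")),
        ])
        assert self.conditions(bgp, 0) == (False, False, True)


@pytest.fixture(scope="module")
def selections(deployment_fixture, deployment_pool):
    fx = deployment_fixture
    text, patient = tf.worked_example_query(fx)
    parsed = tf.parse_query(text)
    ctx = SelectionContext(fx.index, fx.tss_table)
    sel = tf.select_sources(parsed.bgp, ctx, ask=deployment_pool.ask)
    bsel, ask_count = tf.ask_baseline(parsed.bgp, fx.index,
                                      deployment_pool.ask)
    return fx, patient, sel, bsel, ask_count


class TestWorkedExampleSelection:
    """The patient-specific copy-number query on the 17-endpoint layout."""

    def test_joinaware_selects_one_source_per_pattern(self, selections):
        _, _, sel, _, _ = selections
        assert [len(sel.sources(i)) for i in range(6)] == [1] * 6
        assert sel.tpws == 6

    def test_all_patterns_go_to_the_same_blue_endpoint(self, selections):
        fx, patient, sel, _, _ = selections
        urls = {sel.sources(i)[0].url for i in range(6)}
        assert len(urls) == 1
        ep = sel.sources(0)[0]
        assert ep.colour is Colour.BLUE and patient.tumour in ep.tumours

    def test_baseline_issues_one_ask_per_pattern_per_endpoint(self, selections):
        _, _, _, _, ask_count = selections
        assert ask_count == 6 * 17 == 102

    def test_baseline_per_pattern_counts(self, selections):
        _, _, _, bsel, _ = selections
        # barcode at one endpoint per colour; result/chromosome everywhere;
        # start/stop at blue+pink; seq_mean only blue
        assert [len(bsel.sources(i)) for i in range(6)] == \
            [3, 17, 17, 8, 8, 2]

    def test_warm_cache_issues_no_asks(self, deployment_fixture,
                                       deployment_pool):
        fx = deployment_fixture
        text, _ = tf.worked_example_query(fx)
        bgp = tf.parse_query(text).bgp
        cache = AskCache()
        sel1, n1 = tf.ask_baseline(bgp, fx.index, deployment_pool.ask, cache)
        sel2, n2 = tf.ask_baseline(bgp, fx.index, deployment_pool.ask, cache)
        assert n1 == 102 and n2 == 0
        assert sel1.selections == sel2.selections


class TestSelectSources:
    def test_bound_result_subject_selects_single_endpoint(
            self, deployment_fixture):
        fx = deployment_fixture
        patient = next(p for p in fx.patients if p.tss == "18")
        node = tf.mint_result_uri(patient.barcode, "e", 1)
        bgp = bgp_from_triples([(I(str(node)), tcga("RPKM"), V("v"))])
        sel = tf.select_sources(bgp, SelectionContext(fx.index, fx.tss_table))
        eps = sel.sources(0)
        assert len(eps) == 1
        assert eps[0].colour is Colour.PINK
        assert patient.tumour in eps[0].tumours

    def test_bound_methylation_subject_goes_green(self, deployment_fixture):
        fx = deployment_fixture
        patient = fx.patients[0]
        node = tf.mint_result_uri(patient.barcode, "d", 1)
        bgp = bgp_from_triples([(I(str(node)), tcga("beta_value"), V("v"))])
        sel = tf.select_sources(bgp, SelectionContext(fx.index, fx.tss_table))
        assert [e.colour for e in sel.sources(0)] == [Colour.GREEN]

    def test_foreign_subject_falls_back_to_probing(self, deployment_fixture,
                                                   deployment_pool):
        fx = deployment_fixture
        bgp = bgp_from_triples([
            (I("http://example.org/x"), tcga("chromosome"), V("c"))])
        ctx = SelectionContext(fx.index, fx.tss_table)
        sel = tf.select_sources(bgp, ctx)          # no transport: all sources
        assert len(sel.sources(0)) == 17
        sel2 = tf.select_sources(bgp, ctx, ask=deployment_pool.ask)
        assert len(sel2.sources(0)) == 0           # no endpoint holds it

    def test_fully_unbound_pattern_selects_all_endpoints(
            self, deployment_fixture):
        fx = deployment_fixture
        bgp = bgp_from_triples([(V("s"), V("p"), V("o"))])
        sel = tf.select_sources(bgp, SelectionContext(fx.index, fx.tss_table))
        assert len(sel.sources(0)) == 17

    def test_unconditioned_predicate_defaults_to_blue(self,
                                                      deployment_fixture):
        fx = deployment_fixture
        bgp = bgp_from_triples([(V("p"), tcga("drug"), V("d"))])
        sel = tf.select_sources(bgp, SelectionContext(fx.index, fx.tss_table))
        assert {e.colour for e in sel.sources(0)} == {Colour.BLUE}

    def test_union_monotone_in_endpoints(self, benchmark_fixture):
        fx = benchmark_fixture
        bgp = listing6_bgp(str(fx.patients[0].barcode))
        small = tf.assign_tumours(10, {"blue": 1, "pink": 1, "green": 1},
                                  tumour_names=fx.tumours)
        big = tf.assign_tumours(10, {"blue": 2, "pink": 2, "green": 2},
                                tumour_names=fx.tumours)
        sel_small = tf.select_sources(
            bgp, SelectionContext(small, fx.tss_table))
        sel_big = tf.select_sources(bgp, SelectionContext(big, fx.tss_table))
        for i in range(len(bgp)):
            small_urls = {e.colour for e in sel_small.sources(i)}
            big_urls = {e.colour for e in sel_big.sources(i)}
            assert small_urls <= big_urls


class TestTpws:
    def test_sum_of_cardinalities(self, deployment_fixture):
        eps = deployment_fixture.index.endpoints
        sel = SourceSelection({0: (eps[0],), 1: (eps[0], eps[1])},
                              total_sources=len(eps))
        assert tf.tpws_count(sel) == 3

    def test_empty_selection(self):
        assert tf.tpws_count(SourceSelection({}, total_sources=5)) == 0


class TestPatternSignature:
    def test_variable_names_are_normalized(self):
        a = tf.TriplePattern(V("x"), tcga("result"), V("y"), 0)
        b = tf.TriplePattern(V("p"), tcga("result"), V("r"), 0)
        c = tf.TriplePattern(V("p"), tcga("result"), V("p"), 0)
        assert _pattern_signature(a) == _pattern_signature(b)
        assert _pattern_signature(a) != _pattern_signature(c)
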