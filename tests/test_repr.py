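"""Polymer representation: grammar, graphs, tokenizer."""

import numpy as np
import pytest

from copolyvae import dataset as ds
from copolyvae.polymer_repr import (
    ChemistryError, GrammarError, Monomer, NormalizationError,
    PolymerEnsembleSpec, StructuralError, TokenizationError, Vocabulary,
    build_graph, canonical_string, combination_key,
    connectivity_from_architecture, detokenize, format_number, make_spec,
    parse_polymer_string, serialize, tokenize, tokenize_number,
    tokenize_string, validate,
)

TWO_MONO = "[*:1]c1ccc([*:2])cc1.[*:1]c1ccc([*:2])cc1|0.5|0.5|<1-2:1.0:1.0"
SINGLE = "[*:1]c1cc2sc3cc([*:2])sc3c2s1|1.0|<1-2:1.0:1.0"


def random_specs(n, seed=0):
    monos = ds.fixture_monomers(12, seed=seed)
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        pair = rng.choice(len(monos), size=2, replace=False)
        stoich, arch = ds.DEFAULT_COMBOS[rng.integers(len(ds.DEFAULT_COMBOS))]
        out.append(make_spec([monos[pair[0]], monos[pair[1]]], stoich, arch))
    return out


# -- parsing / serialization ------------------------------------------------

def test_parse_two_monomer_example():
    spec = parse_polymer_string(TWO_MONO)
    assert len(spec.monomers) == 2
    assert spec.fractions == (0.5, 0.5)
    assert len(spec.connectivity) == 2  # 1->2 and 2->1 directions


def test_parse_single_monomer_example():
    spec = parse_polymer_string(SINGLE)
    assert len(spec.monomers) == 1
    assert spec.fractions == (1.0,)


def test_round_trip_identity_on_examples():
    for s in (TWO_MONO, SINGLE):
        assert serialize(parse_polymer_string(s)) == s


def test_fraction_sum_error():
    with pytest.raises(NormalizationError):
        parse_polymer_string(
            "[*:1]c1ccc([*:2])cc1.[*:1]c1ccc([*:2])cc1|0.6|0.5|<1-2:1.0:1.0")


def test_bad_grammar_error():
    with pytest.raises(GrammarError):
        parse_polymer_string("no pipes here")


def test_bad_smiles_error():
    with pytest.raises(ChemistryError):
        parse_polymer_string("c1ccc([*:1])|1.0|<1-1:1.0:1.0")


def test_connectivity_normalization_error():
    with pytest.raises(NormalizationError):
        parse_polymer_string(
            "[*:1]c1ccc([*:2])cc1.[*:1]c1ccc([*:2])cc1|0.5|0.5|"
            "<1-2:0.4:1.0<1-4:0.4:1.0")


def test_canonical_ordering_invariance():
    monos = ds.fixture_monomers(4, seed=3)
    a = make_spec([monos[0], monos[1]], (0.5, 0.5), "random")
    b = make_spec([monos[1], monos[0]], (0.5, 0.5), "random")
    assert canonical_string(a) == canonical_string(b)


def test_format_number():
    assert format_number(0.5) == "0.5"
    assert format_number(1.0) == "1.0"
    assert format_number(0.125) == "0.125"
    assert format_number(0.33333333) == "0.3333"


def test_numeric_round_trip():
    s = serialize(parse_polymer_string(TWO_MONO))
    assert parse_polymer_string(s).fractions == (0.5, 0.5)


def test_round_trip_100_random_specs():
    for spec in random_specs(100, seed=11):
        s = serialize(spec)
        assert parse_polymer_string(s) == spec
        assert serialize(parse_polymer_string(s)) == s


def test_validity_closure():
    for spec in random_specs(30, seed=5):
        assert validate(serialize(spec)).valid


# -- combination key --------------------------------------------------------

def test_combination_key_ignores_stoichiometry_and_architecture():
    monos = ds.fixture_monomers(4, seed=0)
    k1 = combination_key(make_spec(monos[:2], (0.25, 0.75), "block"))
    k2 = combination_key(make_spec(monos[:2], (0.75, 0.25), "random"))
    k3 = combination_key(make_spec([monos[0], monos[2]], (0.5, 0.5), "random"))
    assert k1 == k2
    assert k1 != k3


# -- graphs -----------------------------------------------------------------

def test_graph_invariants_on_random_specs():
    for spec in random_specs(20, seed=7):
        g = build_graph(spec)
        w = np.asarray(g.edge_weights)
        intra = w == 1.0
        # stochastic edges in (0, 1]; intra-monomer edges exactly 1.0
        assert np.all((w > 0.0) & (w <= 1.0))
        # per-monomer node weights uniform and summing to 1 across monomers
        nw = np.asarray(g.node_weights)
        mono = np.asarray(g.monomer_of_node)
        per_mono = {m: set(np.round(nw[mono == m], 9)) for m in set(mono)}
        assert all(len(v) == 1 for v in per_mono.values())
        assert abs(sum(next(iter(v)) for v in per_mono.values()) - 1.0) < 1e-6
        # every undirected bond appears in both directions
        pairs = set(zip(g.edge_src, g.edge_dst))
        assert all((d, s) in pairs for (s, d) in pairs)
        assert intra.sum() >= 2  # at least one intramolecular bond both ways


def test_homopolymer_graph():
    g = build_graph(parse_polymer_string(SINGLE))
    assert np.allclose(g.node_weights, 1.0)
    assert np.any(np.asarray(g.edge_weights) == 1.0)


def test_two_monomer_equal_fractions_node_weights():
    g = build_graph(parse_polymer_string(TWO_MONO))
    assert np.allclose(g.node_weights, 0.5)


def test_stochastic_edge_outgoing_normalization():
    monos = ds.fixture_monomers(3, seed=1)
    spec = make_spec(monos[:2], (0.25, 0.75), "random")
    g = build_graph(spec)
    w = np.asarray(g.edge_weights, dtype=float)
    stoch = w < 1.0
    src = np.asarray(g.edge_src)[stoch]
    for s in set(src):
        assert abs(w[stoch][src == s].sum() - 1.0) < 1e-6


def test_missing_attachment_point_structural_error():
    m = Monomer("[*:1]c1ccc([*:2])cc1")
    with pytest.raises(StructuralError):
        PolymerEnsembleSpec(monomers=(m,), fractions=(1.0,),
                            connectivity={((0, 1), (0, 9)): 1.0})


# -- architecture tables ----------------------------------------------------

def test_alternating_connectivity():
    monos = ds.fixture_monomers(2, seed=0)
    conn = connectivity_from_architecture(monos, (0.5, 0.5), "alternating")
    # tails bond exclusively to the other monomer's head
    assert conn[((0, 2), (1, 1))] == 1.0
    assert conn[((1, 2), (0, 1))] == 1.0


def test_random_connectivity_proportional_to_fractions():
    monos = ds.fixture_monomers(2, seed=0)
    conn = connectivity_from_architecture(monos, (0.25, 0.75), "random")
    assert conn[((0, 2), (0, 1))] == pytest.approx(0.25)
    assert conn[((0, 2), (1, 1))] == pytest.approx(0.75)


def test_block_connectivity_epsilon():
    monos = ds.fixture_monomers(2, seed=0)
    conn = connectivity_from_architecture(monos, (0.5, 0.5), "block",
                                          block_epsilon=0.05)
    assert conn[((0, 2), (0, 1))] == pytest.approx(0.95)
    assert conn[((0, 2), (1, 1))] == pytest.approx(0.05)


def test_alternating_requires_two_monomers():
    monos = ds.fixture_monomers(3, seed=0)
    with pytest.raises(StructuralError):
        connectivity_from_architecture(monos, (0.4, 0.3, 0.3), "alternating")


# -- tokenizer --------------------------------------------------------------

def test_number_tokenization_0_125():
    toks = tokenize_number("0.125")
    assert len(toks) == 5
    assert toks[0] == "[0@0]"
    assert toks[1] == "[.num]"
    assert toks[2:] == ["[1@-1]", "[2@-2]", "[5@-3]"]


def test_wildcard_single_token():
    toks = tokenize_string(SINGLE)
    assert "[*:1]" in toks
    assert toks.count("[*:1]") == 1


def test_tokenize_detokenize_round_trip():
    vocab = Vocabulary.build([TWO_MONO, SINGLE])
    for s in (TWO_MONO, SINGLE):
        seq = tokenize(s, vocab)
        assert detokenize(seq) == s


def test_pad_suffix_neutrality():
    vocab = Vocabulary.build([TWO_MONO])
    seq = tokenize(TWO_MONO, vocab)
    padded = type(seq)(ids=list(seq.ids) + [vocab.pad_id] * 4, vocabulary=vocab)
    assert detokenize(padded) == TWO_MONO


def test_vocab_numeric_smiles_disjoint():
    vocab = Vocabulary.build([TWO_MONO, SINGLE])
    assert vocab.numeric_ids().isdisjoint(vocab.smiles_ids())


def test_out_of_vocab_error():
    vocab = Vocabulary.build([SINGLE])
    with pytest.raises(TokenizationError):
        tokenize("[*:1]CBr|1.0|<1-1:1.0:1.0", vocab)


def test_vocab_json_round_trip():
    vocab = Vocabulary.build([TWO_MONO, SINGLE])
    clone = Vocabulary.from_json(vocab.to_json())
    assert len(clone) == len(vocab)
    assert clone.pad_id == vocab.pad_id
    s = detokenize(tokenize(TWO_MONO, clone))
    assert s == TWO_MONO
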