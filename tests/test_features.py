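"""Token attributes, template expansion, and the feature alphabet."""

import pytest

from bacner import (
    ConfigError,
    Gazetteer,
    build_feature_index,
    expand_templates,
    parse_templates,
    read_iob2,
    token_attributes,
)
from bacner.corpus import Token
from bacner.features import ATTRIBUTE_NAMES, DEFAULT_TEMPLATES, FeatureIndex


class TestTokenAttributes:
    def test_genus_word(self):
        a = token_attributes("Escherichia", Gazetteer(["Escherichia coli"]))
        assert a["prefix1"] == "E"
        assert a["prefix3"] == "Esc"
        assert a["suffix3"] == "hia"
        assert a["shape2"] == "Xx"
        assert a["is_cap"] is True
        assert a["in_dict"] is True

    def test_alphanumeric(self):
        a = token_attributes("16S")
        assert a["has_digit"] is True
        assert a["shape2"] == "dX"
        assert a["shape"] == "ddX"
        assert a["suffix1"] == "S"
        assert a["in_dict"] is False

    def test_single_char_short_affixes_absent(self):
        a = token_attributes("a")
        assert a["is_single"] is True
        assert "prefix2" not in a and "suffix4" not in a
        assert a["prefix1"] == "a"

    def test_hyphen_punct_flags(self):
        assert token_attributes("gram-negative")["has_hyphen"] is True
        assert token_attributes(".")["is_punct"] is True
        assert token_attributes("E.")["is_punct"] is False

    def test_purity(self):
        gaz = Gazetteer(["Bacillus subtilis"])
        assert token_attributes("subtilis", gaz) == token_attributes("subtilis", gaz)

    def test_dictionary_word_membership_case_sensitive(self):
        gaz = Gazetteer(["Escherichia coli"])
        assert token_attributes("coli", gaz)["in_dict"] is True
        assert token_attributes("Coli", gaz)["in_dict"] is False

    def test_default_set_has_documented_names(self):
        a = token_attributes("Bacillus")
        assert set(a) <= set(ATTRIBUTE_NAMES)


class TestTemplates:
    def test_unigram_expansion(self):
        tpls = parse_templates("U:%x[0,word]")
        toks = [Token("E.", 0), Token("coli", 1)]
        attrs = [token_attributes(t) for t in toks]
        state, trans = expand_templates(toks, attrs, tpls)
        assert state[1] == ["U:word[0]=coli"]
        assert trans == [[], []]

    def test_boundary_sentinel(self):
        tpls = parse_templates("U:%x[-1,word]/%x[0,word]")
        toks = [Token("E.", 0), Token("coli", 1)]
        attrs = [token_attributes(t) for t in toks]
        state, _ = expand_templates(toks, attrs, tpls)
        assert state[0] == ["U:word[-1]|word[0]=_BOS_|E."]

    def test_eos_sentinel_and_bias(self):
        tpls = parse_templates("U:%x[1,word]\nB")
        toks = [Token("x", 0)]
        state, trans = expand_templates(toks, [token_attributes("x")], tpls)
        assert state[0] == ["U:word[1]=_EOS_"]
        assert trans[0] == ["B"]

    def test_label_free(self):
        # expansion sees only tokens and attributes, never tags: the API
        # takes no label argument at all, by construction
        tpls = parse_templates(DEFAULT_TEMPLATES)
        toks = [Token("Escherichia", 0), Token("coli", 1)]
        attrs = [token_attributes(t) for t in toks]
        s1, t1 = expand_templates(toks, attrs, tpls)
        s2, t2 = expand_templates(toks, attrs, tpls)
        assert s1 == s2 and t1 == t2

    def test_unknown_attribute_is_config_error(self):
        with pytest.raises(ConfigError, match="unknown attribute"):
            parse_templates("U:%x[0,pos_tag]")

    def test_missing_attribute_renders_none_sentinel(self):
        tpls = parse_templates("U:%x[0,prefix3]")
        toks = [Token("a", 0)]
        state, _ = expand_templates(toks, [token_attributes("a")], tpls)
        assert state[0] == ["U:prefix3[0]=_NONE_"]


class TestFeatureIndex:
    CORPUS = ["Escherichia B-BAC", "coli I-BAC", "lives O", "", "It O", "lives O", ""]

    def test_enumeration_matches_exhaustive_count(self):
        corpus = read_iob2(self.CORPUS)
        tpls = parse_templates("U:%x[0,word]\nB")
        index = build_feature_index(corpus, tpls, min_count=1)
        # by hand: distinct state strings over the two sentences
        expected_state = {
            "U:word[0]=Escherichia", "U:word[0]=coli", "U:word[0]=lives",
            "U:word[0]=It",
        }
        # bias observed on edges only
        assert set(index.strings) == expected_state | {"B"}

    def test_min_count_pruning(self):
        corpus = read_iob2(self.CORPUS)
        tpls = parse_templates("U:%x[0,word]")
        index = build_feature_index(corpus, tpls, min_count=2)
        assert set(index.strings) == {"U:word[0]=lives"}

    def test_min_count_below_one_rejected(self):
        corpus = read_iob2(self.CORPUS)
        with pytest.raises(ConfigError):
            build_feature_index(corpus, parse_templates("U:%x[0,word]"), min_count=0)

    def test_deterministic_mapping_across_runs(self):
        corpus = read_iob2(self.CORPUS)
        tpls = parse_templates(DEFAULT_TEMPLATES)
        i1 = build_feature_index(corpus, tpls)
        i2 = build_feature_index(corpus, tpls)
        assert i1.strings == i2.strings
        assert all(i1[s] == i2[s] for s in i1.strings)

    def test_ids_dense_and_lexicographic(self):
        corpus = read_iob2(self.CORPUS)
        index = build_feature_index(corpus, parse_templates(DEFAULT_TEMPLATES))
        assert list(index.strings) == sorted(index.strings)
        assert [index[s] for s in index.strings] == list(range(len(index)))

    def test_frozen_index_maps_unseen_to_none(self):
        index = FeatureIndex.from_strings(["B", "U:word[0]=coli"])
        assert index.get("U:word[0]=unseen") is None
        with pytest.raises(ConfigError):
            index.observe("new")
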